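"""Net benefit and decision curves.

Decision curve analysis (DCA) evaluates a risk prediction model by the net
benefit it delivers when every patient whose predicted risk ``p_d`` meets or
exceeds a threshold probability ``p_t`` receives the intervention:

.. math::

    NB(p_t) = \\frac{TP}{n} - \\frac{FP}{n} \\cdot \\frac{p_t}{1 - p_t} - harm

``TP`` counts intervened patients with the event, ``FP`` intervened patients
without it, and ``n`` is the cohort size.  Net benefit is expressed in
true-positive equivalents per patient: a false positive is exchanged against
true positives at the odds of the threshold, which is exactly the trade-off a
patient indifferent at ``p_t`` accepts.  The optional ``harm`` term is a
per-patient cost of the intervention (or of acquiring a predictor) subtracted
uniformly from the curve.

The classification rule is ``p_d >= p_t`` (ties count as treated), matching
the decision rule used to generate the binary decision indicator ``Z``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError, InputError

__all__ = [
    "Cohort",
    "ThresholdGrid",
    "NetBenefitCurve",
    "net_benefit",
    "net_benefit_curve",
    "reference_curves",
]


def _as_1d_float(name: str, x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise InputError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if arr.size == 0:
        raise InputError(f"{name} is empty")
    if not np.all(np.isfinite(arr)):
        raise InputError(f"{name} contains non-finite values")
    return arr


def _as_binary(name: str, x) -> np.ndarray:
    arr = _as_1d_float(name, x)
    if not np.all((arr == 0.0) | (arr == 1.0)):
        bad = np.flatnonzero((arr != 0.0) & (arr != 1.0))[0]
        raise InputError(f"{name} must be binary 0/1; row {bad} has value {arr[bad]!r}")
    return arr.astype(np.int64)


def _as_prob(name: str, x) -> np.ndarray:
    arr = _as_1d_float(name, x)
    if arr.min() < 0.0 or arr.max() > 1.0:
        bad = np.flatnonzero((arr < 0.0) | (arr > 1.0))[0]
        raise InputError(
            f"{name} must lie in [0, 1]; row {bad} has value {arr[bad]!r}"
        )
    return arr


@dataclass
class Cohort:
    """Patient-level data for decision curve analysis.

    Parameters
    ----------
    y
        Binary outcome per patient (1 = event present).
    risks
        Mapping from model label to that model's predicted event
        probabilities, one value in ``[0, 1]`` per patient.
    z
        Optional binary decision indicator per patient (1 = intervene).
    pt_true
        Optional per-patient threshold probability in ``(0, 1)``; only
        available in simulations, where it is ground truth.
    """

    y: np.ndarray
    risks: dict[str, np.ndarray]
    z: np.ndarray | None = None
    pt_true: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = _as_binary("y", self.y)
        n = self.y.size
        if not self.risks:
            raise InputError("cohort must carry at least one risk column")
        validated: dict[str, np.ndarray] = {}
        for label, pd_ in self.risks.items():
            arr = _as_prob(f"risks[{label!r}]", pd_)
            if arr.size != n:
                raise InputError(
                    f"risks[{label!r}] has length {arr.size}, expected {n}"
                )
            validated[label] = arr
        self.risks = validated
        if self.z is not None:
            self.z = _as_binary("z", self.z)
            if self.z.size != n:
                raise InputError(f"z has length {self.z.size}, expected {n}")
        if self.pt_true is not None:
            self.pt_true = _as_prob("pt_true", self.pt_true)
            if self.pt_true.size != n:
                raise InputError(
                    f"pt_true has length {self.pt_true.size}, expected {n}"
                )
            if self.pt_true.min() <= 0.0 or self.pt_true.max() >= 1.0:
                raise InputError("pt_true values must lie strictly in (0, 1)")

    @property
    def n(self) -> int:
        return int(self.y.size)

    @property
    def prevalence(self) -> float:
        return float(self.y.mean())

    def risk(self, label: str) -> np.ndarray:
        try:
            return self.risks[label]
        except KeyError:
            raise InputError(
                f"unknown model label {label!r}; available: {sorted(self.risks)}"
            ) from None

    def decisions_follow_rule(self, label: str) -> bool:
        """True when ``z == I(p_d >= pt_true)`` row-wise for the given model."""
        if self.z is None or self.pt_true is None:
            raise InputError("z and pt_true are both required to check the rule")
        return bool(np.array_equal(self.z, (self.risk(label) >= self.pt_true)))


@dataclass(frozen=True)
class ThresholdGrid:
    """Strictly increasing evaluation thresholds in the open interval (0, 1).

    ``range_of_interest`` is the clinically relevant ``(lo, hi)`` window; when
    present the grid must cover it.
    """

    values: np.ndarray
    range_of_interest: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        vals = _as_1d_float("grid values", self.values)
        if vals.min() <= 0.0 or vals.max() >= 1.0:
            raise DomainError("grid values must lie strictly in (0, 1)")
        if np.any(np.diff(vals) <= 0.0):
            raise InputError("grid values must be strictly increasing")
        object.__setattr__(self, "values", vals)
        roi = self.range_of_interest
        if roi is not None:
            lo, hi = float(roi[0]), float(roi[1])
            if not (0.0 < lo < hi < 1.0):
                raise DomainError(
                    f"range of interest must satisfy 0 < lo < hi < 1, got ({lo}, {hi})"
                )
            if vals[0] > lo + 1e-12 or vals[-1] < hi - 1e-12:
                raise InputError("grid does not cover the range of interest")
            object.__setattr__(self, "range_of_interest", (lo, hi))

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.values[0]), float(self.values[-1])

    @classmethod
    def from_range(
        cls, lo: float, hi: float, num: int = 101
    ) -> "ThresholdGrid":
        """Equally spaced grid of ``num`` points spanning ``[lo, hi]`` inclusive."""
        if not (0.0 < lo < hi < 1.0):
            raise DomainError(f"need 0 < lo < hi < 1, got ({lo}, {hi})")
        if num < 2:
            raise InputError("grid needs at least 2 points")
        return cls(np.linspace(lo, hi, num), range_of_interest=(lo, hi))

    @classmethod
    def full_range(cls, step: float = 0.001) -> "ThresholdGrid":
        # spans (0, 1) minus one step at each end; the pt/(1-pt) weight
        # diverges at 1, so the endpoint itself is never evaluated
        if not (0.0 < step < 0.5):
            raise DomainError("step must lie in (0, 0.5)")
        vals = np.arange(step, 1.0, step)
        vals = vals[vals < 1.0 - step / 2]
        return cls(vals)


@dataclass
class NetBenefitCurve:
    """Net benefit evaluated on an ordered threshold grid for one model."""

    grid: ThresholdGrid
    nb: np.ndarray
    model_label: str
    n: int

    def __post_init__(self) -> None:
        self.nb = np.asarray(self.nb, dtype=float)
        if self.nb.size != len(self.grid):
            raise InputError(
                f"nb has length {self.nb.size}, grid has {len(self.grid)} points"
            )

    def interp(self, pt) -> np.ndarray:
        """Linear interpolation of the curve at arbitrary thresholds.

        Values outside the grid span are clamped to the end values.
        """
        return np.interp(np.asarray(pt, dtype=float), self.grid.values, self.nb)


def net_benefit(y, pd, pt: float, harm: float = 0.0) -> float:
    """Net benefit of intervening on patients with ``p_d >= pt``.

    Returns ``TP/n - (FP/n) * pt/(1-pt) - harm``.
    """
    y = _as_binary("y", y)
    pd = _as_prob("pd", pd)
    if pd.size != y.size:
        raise InputError(f"y has length {y.size} but pd has length {pd.size}")
    pt = float(pt)
    if not (0.0 < pt < 1.0):
        raise DomainError(f"pt must lie strictly in (0, 1), got {pt}")
    if harm < 0.0:
        raise DomainError(f"harm must be nonnegative, got {harm}")
    pos = pd >= pt
    n = y.size
    tp = int(np.count_nonzero(pos & (y == 1)))
    fp = int(np.count_nonzero(pos & (y == 0)))
    return tp / n - (fp / n) * pt / (1.0 - pt) - harm


def _sorted_counts(y: np.ndarray, pd: np.ndarray):
    """Pre-sorted representation for fast threshold sweeps.

    Returns ``(pds, ev_suffix, tot_suffix)`` where for any threshold index
    obtained with ``searchsorted(pds, t, side='left')`` the suffix arrays give
    the number of events / patients with ``p_d >= t``.
    """
    order = np.argsort(pd, kind="stable")
    pds = pd[order]
    ys = y[order].astype(np.int64)
    ev_suffix = np.concatenate([np.cumsum(ys[::-1])[::-1], [0]])
    tot_suffix = np.concatenate([np.arange(ys.size, 0, -1, dtype=np.int64), [0]])
    return pds, ev_suffix, tot_suffix


def curve_values(y, pd, thresholds, harm: float = 0.0) -> np.ndarray:
    """Vectorized net benefit at many thresholds (one pass over sorted risks)."""
    y = _as_binary("y", y)
    pd = _as_prob("pd", pd)
    if pd.size != y.size:
        raise InputError("y and pd lengths differ")
    ts = _as_1d_float("thresholds", thresholds)
    if ts.min() <= 0.0 or ts.max() >= 1.0:
        raise DomainError("thresholds must lie strictly in (0, 1)")
    pds, ev_suffix, tot_suffix = _sorted_counts(y, pd)
    pos = np.searchsorted(pds, ts, side="left")
    tp = ev_suffix[pos]
    fp = tot_suffix[pos] - tp
    n = y.size
    return tp / n - (fp / n) * ts / (1.0 - ts) - harm


def bootstrap_curve_values(
    y: np.ndarray, pd: np.ndarray, W: np.ndarray, thresholds: np.ndarray,
    harm: float = 0.0,
) -> np.ndarray:
    """Net benefit curves for resampled cohorts given multiplicity weights.

    ``W`` is an integer matrix of shape ``(B, n)``: row ``b`` holds how many
    times each original patient appears in bootstrap resample ``b``.  Because
    resampling changes only the multiplicities, not the risk values, every
    resample reuses one sort of ``pd``.  Returns an array of shape ``(B, G)``.
    """
    ts = np.asarray(thresholds, dtype=float)
    order = np.argsort(pd, kind="stable")
    pds = pd[order]
    ys = y[order].astype(np.int64)
    Wo = np.ascontiguousarray(W[:, order]).astype(np.int64, copy=False)
    ev = Wo * ys
    tp_suffix = np.cumsum(ev[:, ::-1], axis=1)[:, ::-1]
    tot_suffix = np.cumsum(Wo[:, ::-1], axis=1)[:, ::-1]
    zeros = np.zeros((W.shape[0], 1), dtype=np.int64)
    tp_suffix = np.concatenate([tp_suffix, zeros], axis=1)
    tot_suffix = np.concatenate([tot_suffix, zeros], axis=1)
    pos = np.searchsorted(pds, ts, side="left")
    tp = tp_suffix[:, pos]
    fp = tot_suffix[:, pos] - tp
    n = W.sum(axis=1, keepdims=True).astype(float)
    return tp / n - (fp / n) * (ts / (1.0 - ts)) - harm


def net_benefit_curve(
    cohort: Cohort,
    model_label: str,
    grid: ThresholdGrid | None = None,
    harm: float = 0.0,
) -> NetBenefitCurve:
    """Net benefit of one model across a threshold grid."""
    if grid is None:
        grid = ThresholdGrid.full_range()
    nb = curve_values(cohort.y, cohort.risk(model_label), grid.values, harm=harm)
    return NetBenefitCurve(grid=grid, nb=nb, model_label=model_label, n=cohort.n)


def reference_curves(
    cohort: Cohort, grid: ThresholdGrid | None = None, harm: float = 0.0
) -> tuple[NetBenefitCurve, NetBenefitCurve]:
    """Treat-all and treat-none reference strategies.

    Treat-all intervenes on everyone (``p_d`` identically 1), giving
    ``prev - (1 - prev) * pt/(1 - pt)``; treat-none gives identically 0
    (before any harm term).
    """
    if grid is None:
        grid = ThresholdGrid.full_range()
    ts = grid.values
    prev = cohort.prevalence
    all_nb = prev - (1.0 - prev) * ts / (1.0 - ts) - harm
    none_nb = np.zeros_like(ts) - harm
    treat_all = NetBenefitCurve(grid=grid, nb=all_nb, model_label="treat_all", n=cohort.n)
    treat_none = NetBenefitCurve(grid=grid, nb=none_nb, model_label="treat_none", n=cohort.n)
    return treat_all, treat_none
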