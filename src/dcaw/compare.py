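"""Model-comparison statistics with paired bootstrap confidence intervals.

Three summaries of the difference between two models' net benefit curves
over a clinically relevant threshold range ``[lo, hi]``:

* **C-NBC** — the standard approach: pointwise percentile bootstrap CIs for
  the curve difference at each threshold; the models are equivalent at a
  threshold when the CI contains zero.
* **A-NBC** — the difference of trapezoidal areas under the two curves,
  which implicitly weights every threshold equally (a uniform threshold
  distribution).
* **WA-NBC** — the difference of the curves integrated against the
  (estimated) distribution of threshold probabilities, so the comparison is
  weighted by how many patients actually hold each threshold.

All three use the *same* bootstrap resamples for both models: resampling
rows of ``(y, p_d1, p_d2)`` jointly preserves the within-patient pairing and
shortens the CI of the difference.  Models are fit once on the original
data; resamples recompute the statistics without refitting.  CIs are
percentile intervals at ``alpha/2`` and ``1 - alpha/2`` with linear
interpolation between order statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import (
    Cohort,
    NetBenefitCurve,
    ThresholdGrid,
    bootstrap_curve_values,
    curve_values,
    net_benefit_curve,
)
from .exceptions import DomainError, InputError
from .threshold_dist import ThresholdCDF, cdf_weights, estimate_threshold_cdf

__all__ = [
    "ComparisonResult",
    "TotalNetBenefitResult",
    "anbc",
    "wanbc",
    "compare_models",
    "paired_bootstrap_ci",
    "cnbc_decide",
    "total_net_benefit",
]

_STATISTICS = ("cnbc", "anbc", "wanbc")


def _decide(ci_lo: float, ci_hi: float) -> str:
    if ci_lo > 0.0:
        return "model1_superior"
    if ci_hi < 0.0:
        return "model2_superior"
    return "equivalent"


@dataclass
class ComparisonResult:
    """A model-1-minus-model-2 statistic, its bootstrap CI and the decision.

    For ``cnbc`` the estimate, CI bounds and decisions are per-threshold
    vectors aligned with ``thresholds``; for ``anbc``/``wanbc`` they are
    scalars.  The decision is ``equivalent`` iff the CI contains zero.
    """

    statistic_name: str
    model_labels: tuple[str, str]
    estimate: float | np.ndarray
    ci_lo: float | np.ndarray
    ci_hi: float | np.ndarray
    alpha: float
    n_boot: int
    decision: str | list[str]
    seed: int | None = None
    thresholds: np.ndarray | None = None

    @property
    def rejects_equivalence(self) -> bool | np.ndarray:
        """CI excludes zero (vector-valued for ``cnbc``)."""
        lo = np.asarray(self.ci_lo)
        hi = np.asarray(self.ci_hi)
        out = (lo > 0.0) | (hi < 0.0)
        return out if out.ndim else bool(out)

    def to_dict(self) -> dict:
        def _js(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            return v

        return {
            "statistic_name": self.statistic_name,
            "model_labels": list(self.model_labels),
            "estimate": _js(self.estimate),
            "ci_lo": _js(self.ci_lo),
            "ci_hi": _js(self.ci_hi),
            "alpha": self.alpha,
            "n_boot": self.n_boot,
            "decision": self.decision,
            "seed": self.seed,
            "thresholds": _js(self.thresholds),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ComparisonResult":
        def _arr(v):
            return np.asarray(v, dtype=float) if isinstance(v, list) else v

        return cls(
            statistic_name=d["statistic_name"],
            model_labels=tuple(d["model_labels"]),
            estimate=_arr(d["estimate"]),
            ci_lo=_arr(d["ci_lo"]),
            ci_hi=_arr(d["ci_hi"]),
            alpha=d["alpha"],
            n_boot=d["n_boot"],
            decision=d["decision"],
            seed=d.get("seed"),
            thresholds=_arr(d.get("thresholds")) if d.get("thresholds") is not None else None,
        )


@dataclass
class TotalNetBenefitResult:
    """Cohort-level net benefit in true-positive-equivalent counts."""

    method: str  # true_thresholds | estimated_distribution | uniform_distribution
    total_nb: float
    n: int
    model_label: str = ""


def _restrict_curve(curve: NetBenefitCurve, lo: float, hi: float):
    ts = curve.grid.values
    if lo < ts[0] - 1e-9 or hi > ts[-1] + 1e-9:
        raise InputError(
            f"range ({lo}, {hi}) lies outside the curve grid span {curve.grid.span}"
        )
    if lo >= hi:
        raise InputError(f"empty range ({lo}, {hi})")
    inner = (ts > lo + 1e-15) & (ts < hi - 1e-15)
    xs = np.concatenate([[lo], ts[inner], [hi]])
    ys = np.interp(xs, ts, curve.nb)
    return xs, ys


def anbc(curve: NetBenefitCurve, range_of_interest: tuple[float, float] | None = None) -> float:
    """Trapezoidal area under the net benefit curve over the range of interest."""
    lo, hi = range_of_interest if range_of_interest is not None else curve.grid.span
    xs, ys = _restrict_curve(curve, float(lo), float(hi))
    return float(np.trapezoid(ys, xs))


def wanbc(
    curve: NetBenefitCurve,
    cdf: ThresholdCDF,
    range_of_interest: tuple[float, float] | None = None,
) -> float:
    """Net benefit curve integrated against the threshold distribution.

    A Riemann–Stieltjes sum: the curve (linearly interpolated) is evaluated
    at the midpoint of each CDF-increment cell.  The weights sum to
    ``F(hi) - F(lo)`` and are deliberately not renormalized — the statistic
    is the expected net benefit restricted to thresholds in the range.  A
    distribution with no mass in the range yields 0 with a warning.
    """
    lo, hi = range_of_interest if range_of_interest is not None else curve.grid.span
    xs, ys = _restrict_curve(curve, float(lo), float(hi))
    edges = np.concatenate([[xs[0]], (xs[:-1] + xs[1:]) / 2.0, [xs[-1]]])
    w = np.diff(cdf.evaluate(edges))
    if w.sum() <= 1e-12:
        warnings.warn(
            "threshold distribution has (numerically) zero mass in the range "
            "of interest; WA-NBC is 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    return float(ys @ w)


def compare_models(
    cohort: Cohort,
    labels: tuple[str, str],
    *,
    range_of_interest: tuple[float, float],
    grid: ThresholdGrid | None = None,
    statistics: Sequence[str] = _STATISTICS,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.Generator | None = None,
    cdf: ThresholdCDF | None = None,
    cdf_from: str | None = None,
    cdf_policy: str = "fixed",
    harm: float = 0.0,
) -> dict[str, ComparisonResult]:
    """Compute any of C-NBC / A-NBC / WA-NBC from one shared set of resamples.

    Parameters
    ----------
    labels
        ``(model1, model2)``; the statistic is model 1 minus model 2.
    cdf, cdf_from, cdf_policy
        Threshold distribution used by WA-NBC.  By default it is estimated
        once from the cohort's decisions ``z`` and the risks of the model
        named by ``cdf_from`` (default: model 1) and held fixed across
        resamples (``cdf_policy='fixed'``).  ``cdf_policy='per_resample'``
        re-estimates it inside every resample for sensitivity analysis.
    """
    if len(labels) != 2:
        raise InputError("labels must name exactly two models")
    lo, hi = float(range_of_interest[0]), float(range_of_interest[1])
    if not (0.0 < lo < hi < 1.0):
        raise DomainError(f"range of interest must satisfy 0 < lo < hi < 1, got ({lo}, {hi})")
    unknown = set(statistics) - set(_STATISTICS)
    if unknown:
        raise InputError(f"unknown statistics {sorted(unknown)}; choose from {_STATISTICS}")
    if not (0.0 < alpha < 1.0):
        raise DomainError("alpha must lie in (0, 1)")
    if n_boot < 2:
        raise InputError("n_boot must be at least 2")
    if n_boot < 2.0 / alpha:
        warnings.warn(
            f"n_boot={n_boot} is small for alpha={alpha}; percentile bounds "
            "are unstable",
            RuntimeWarning,
            stacklevel=2,
        )
    if grid is None:
        grid = ThresholdGrid.from_range(lo, hi, 101)
    elif grid.values[0] > lo + 1e-12 or grid.values[-1] < hi - 1e-12:
        raise InputError("grid does not cover the range of interest")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_repr = seed if isinstance(seed, (int, np.integer)) else None

    y = cohort.y
    pd1 = cohort.risk(labels[0])
    pd2 = cohort.risk(labels[1])
    ts = grid.values

    wanbc_wanted = "wanbc" in statistics
    if wanbc_wanted and cdf is None:
        if cohort.z is None:
            raise InputError(
                "WA-NBC needs a threshold distribution: pass cdf= or provide "
                "cohort decisions z to estimate it"
            )
        ref = cdf_from if cdf_from is not None else labels[0]
        cdf = estimate_threshold_cdf(cohort.z, cohort.risk(ref))

    # observed curves and one shared set of bootstrap multiplicities
    d0 = curve_values(y, pd1, ts, harm=harm) - curve_values(y, pd2, ts, harm=harm)
    idx = rng.integers(0, cohort.n, size=(n_boot, cohort.n))
    W = np.empty((n_boot, cohort.n), dtype=np.int64)
    for b in range(n_boot):
        W[b] = np.bincount(idx[b], minlength=cohort.n)
    D = bootstrap_curve_values(y, pd1, W, ts, harm=harm) - bootstrap_curve_values(
        y, pd2, W, ts, harm=harm
    )

    qs = (alpha / 2.0, 1.0 - alpha / 2.0)
    out: dict[str, ComparisonResult] = {}

    if "cnbc" in statistics:
        lo_v, hi_v = np.quantile(D, qs, axis=0, method="linear")
        out["cnbc"] = ComparisonResult(
            statistic_name="cnbc",
            model_labels=tuple(labels),
            estimate=d0,
            ci_lo=lo_v,
            ci_hi=hi_v,
            alpha=alpha,
            n_boot=n_boot,
            decision=[_decide(a, b) for a, b in zip(lo_v, hi_v)],
            seed=seed_repr,
            thresholds=ts.copy(),
        )

    if "anbc" in statistics:
        s0 = float(np.trapezoid(d0, ts))
        sb = np.trapezoid(D, ts, axis=1)
        lo_s, hi_s = np.quantile(sb, qs, method="linear")
        out["anbc"] = ComparisonResult(
            statistic_name="anbc",
            model_labels=tuple(labels),
            estimate=s0,
            ci_lo=float(lo_s),
            ci_hi=float(hi_s),
            alpha=alpha,
            n_boot=n_boot,
            decision=_decide(lo_s, hi_s),
            seed=seed_repr,
        )

    if wanbc_wanted:
        if cdf_policy == "fixed":
            w = cdf_weights(cdf, ts)
            s0 = float(d0 @ w)
            sb = D @ w
        elif cdf_policy == "per_resample":
            if cohort.z is None:
                raise InputError("per-resample CDF estimation needs cohort decisions z")
            ref = cdf_from if cdf_from is not None else labels[0]
            pdr = cohort.risk(ref)
            s0 = float(d0 @ cdf_weights(cdf, ts))
            sb = np.empty(n_boot)
            for b in range(n_boot):
                cdf_b = estimate_threshold_cdf(cohort.z[idx[b]], pdr[idx[b]])
                sb[b] = D[b] @ cdf_weights(cdf_b, ts)
        else:
            raise InputError(f"unknown cdf_policy {cdf_policy!r}")
        lo_s, hi_s = np.quantile(sb, qs, method="linear")
        out["wanbc"] = ComparisonResult(
            statistic_name="wanbc",
            model_labels=tuple(labels),
            estimate=s0,
            ci_lo=float(lo_s),
            ci_hi=float(hi_s),
            alpha=alpha,
            n_boot=n_boot,
            decision=_decide(lo_s, hi_s),
            seed=seed_repr,
        )
    return out


def paired_bootstrap_ci(
    cohort: Cohort,
    labels: tuple[str, str],
    statistic: str,
    *,
    range_of_interest: tuple[float, float],
    grid: ThresholdGrid | None = None,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.Generator | None = None,
    cdf: ThresholdCDF | None = None,
    cdf_from: str | None = None,
    cdf_policy: str = "fixed",
    harm: float = 0.0,
) -> ComparisonResult:
    """Paired percentile-bootstrap comparison for one statistic.

    ``statistic`` is one of ``'anbc'``, ``'wanbc'`` or ``'pointwise'``
    (the standard per-threshold C-NBC comparison).
    """
    name = {"pointwise": "cnbc", "cnbc": "cnbc", "anbc": "anbc", "wanbc": "wanbc"}.get(
        statistic
    )
    if name is None:
        raise InputError(
            f"unknown statistic {statistic!r}; choose anbc, wanbc or pointwise"
        )
    res = compare_models(
        cohort,
        labels,
        range_of_interest=range_of_interest,
        grid=grid,
        statistics=(name,),
        n_boot=n_boot,
        alpha=alpha,
        seed=seed,
        cdf=cdf,
        cdf_from=cdf_from,
        cdf_policy=cdf_policy,
        harm=harm,
    )
    return res[name]


def cnbc_decide(
    result: ComparisonResult, range_of_interest: tuple[float, float] | None = None
):
    """Per-threshold decisions plus the range-averaged rejection indicator.

    The scalar used in power computations is the average, over grid points in
    the range of interest, of the indicator that the pointwise CI excludes
    zero.
    """
    if result.statistic_name != "cnbc" or result.thresholds is None:
        raise InputError("cnbc_decide requires a pointwise (cnbc) result")
    ts = result.thresholds
    if range_of_interest is None:
        mask = np.ones(ts.size, dtype=bool)
    else:
        lo, hi = float(range_of_interest[0]), float(range_of_interest[1])
        mask = (ts >= lo - 1e-12) & (ts <= hi + 1e-12)
        if not mask.any():
            raise InputError("no thresholds inside the range of interest")
    rej = np.asarray(result.rejects_equivalence)
    decisions = [d for d, m in zip(result.decision, mask) if m]
    return decisions, float(rej[mask].mean())


def total_net_benefit(
    cohort: Cohort,
    label: str,
    method: str,
    cdf: ThresholdCDF | None = None,
    grid: ThresholdGrid | None = None,
    harm: float = 0.0,
) -> TotalNetBenefitResult:
    """Cohort-level ("total") net benefit under three accounting methods.

    * ``true_thresholds`` — sum over patients of the cohort curve evaluated
      (linear interpolation) at each patient's own ``pt_true``; the ground
      truth, available only in simulation.
    * ``estimated_distribution`` — ``n`` times the Stieltjes integral of the
      curve against ``cdf`` over (0, 1); ``cdf`` defaults to the recursive
      estimate from ``(z, p_d)``.
    * ``uniform_distribution`` — ``n`` times the trapezoidal area under the
      curve over its full grid span (the uniform-threshold assumption).
    """
    if grid is None:
        grid = ThresholdGrid.full_range()
    curve = net_benefit_curve(cohort, label, grid, harm=harm)
    n = cohort.n
    if method == "true_thresholds":
        if cohort.pt_true is None:
            raise InputError("method 'true_thresholds' requires cohort.pt_true")
        total = float(np.sum(curve.interp(cohort.pt_true)))
    elif method == "estimated_distribution":
        if cdf is None:
            if cohort.z is None:
                raise InputError(
                    "method 'estimated_distribution' requires a ThresholdCDF "
                    "or cohort decisions z to estimate one"
                )
            cdf = estimate_threshold_cdf(cohort.z, cohort.risk(label))
        w = cdf_weights(cdf, curve.grid.values, range_of_interest=(0.0, 1.0))
        total = float(n * (curve.nb @ w))
    elif method == "uniform_distribution":
        total = float(n * anbc(curve))
    else:
        raise InputError(
            f"unknown method {method!r}; choose true_thresholds, "
            "estimated_distribution or uniform_distribution"
        )
    return TotalNetBenefitResult(method=method, total_nb=total, n=n, model_label=label)
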