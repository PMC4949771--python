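"""Synthetic prostate-cancer cohorts and the validation experiments.

The generator emulates a cohort of prostate-cancer patients facing the
decision to remove the seminal vesicles at surgery, made by comparing the
predicted probability of seminal vesicle invasion (SVI) with the patient's
threshold probability.  Predictors:

* ``PSA`` — prostate specific antigen, Exponential with rate 0.1 (mean 10),
  heavy right tail as in real PSA distributions;
* ``GS`` — Gleason score, ``2 + Binomial(4, 0.5) + Binomial(4, 0.5)``
  (primary plus secondary grade), range 2–10, mean 6;
* ``X1`` — a generic continuous covariate, Normal(27, 6) (BMI-like);
* ``n1 … n6`` — independent standard-normal noise predictors.

The base outcome model is

.. math:: \\operatorname{logit}(p_d) = -10 + 0.1\\,PSA + 0.2\\,X_1 + 0.5\\,GS

giving an event prevalence near 0.39.  The power scenario adds
``gamma * n1 + eps`` to the linear predictor, with ``eps`` Normal(0,
``noise_sd``²); ``noise_sd`` defaults to 1 and is configurable (including 0)
because only the presence of the noise term, not its scale, is pinned down
by the study design.  Thresholds ``p_t`` are drawn from a configurable
distribution on (0, 1) — Beta(2, 7) by default, uniform or a right-truncated
exponential as alternatives — and the recorded decision is
``Z = I(p_d_true >= p_t)``.

Four experiments validate the comparison machinery: type-I error and power
of C-NBC / A-NBC / WA-NBC, convergence of the threshold-CDF estimator,
cohort total net benefit under three accounting methods, and the
crossing-curves example in which A-NBC and WA-NBC reach opposite decisions.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit

from .compare import cnbc_decide, compare_models, total_net_benefit
from .core import Cohort, ThresholdGrid, net_benefit_curve
from .exceptions import ConfigError, FitError, InputError
from .threshold_dist import ThresholdCDF, estimate_threshold_cdf

__all__ = [
    "PtDistribution",
    "SimulationConfig",
    "SimulatedCohort",
    "RiskModel",
    "simulate_cohort",
    "fit_risk_model",
    "indicator_risks",
    "run_type1_experiment",
    "run_power_experiment",
    "run_total_nb_experiment",
    "run_crossing_example",
    "TYPE1_M1",
    "TYPE1_M2",
    "POWER_M1",
    "POWER_M2",
]

# predictor sets for the equivalence (type-I) and power designs: identical
# causal parts, disjoint noise predictors
TYPE1_M1 = ("PSA", "GS", "X1", "n1", "n2", "n3")
TYPE1_M2 = ("PSA", "GS", "X1", "n4", "n5", "n6")
POWER_M1 = ("PSA", "X1", "GS", "n1", "n2", "n3")
POWER_M2 = ("PSA", "X1", "GS", "n4", "n5", "n6")

_DIST_RE = re.compile(r"^\s*([a-z_]+)\s*(?:\(\s*([^)]*)\s*\))?\s*$")


class PtDistribution:
    """A named threshold-probability distribution on (0, 1).

    Accepts ``'uniform'``, ``'beta(a,b)'`` or ``'trunc_exp(rate, upper)'``
    (an Exponential(rate) right-truncated at ``upper``).
    """

    def __init__(self, spec: "str | PtDistribution"):
        if isinstance(spec, PtDistribution):
            self.name, self.params, self._frozen = spec.name, spec.params, spec._frozen
            return
        m = _DIST_RE.match(str(spec).lower())
        if not m:
            raise ConfigError(f"cannot parse threshold distribution {spec!r}")
        name, argstr = m.group(1), m.group(2)
        args = tuple(float(a) for a in argstr.split(",")) if argstr else ()
        if name == "uniform":
            if args not in ((), (0.0, 1.0)):
                raise ConfigError("uniform threshold distribution takes no parameters")
            frozen = stats.uniform(0.0, 1.0)
        elif name == "beta":
            if len(args) != 2 or min(args) <= 0:
                raise ConfigError(f"beta needs two positive parameters, got {args}")
            frozen = stats.beta(*args)
        elif name == "trunc_exp":
            if len(args) != 2 or args[0] <= 0 or not (0 < args[1] <= 1):
                raise ConfigError(
                    f"trunc_exp needs (rate > 0, upper in (0, 1]), got {args}"
                )
            rate, upper = args
            frozen = stats.truncexpon(b=rate * upper, scale=1.0 / rate)
        else:
            raise ConfigError(f"unknown threshold distribution {name!r}")
        self.name = name
        self.params = args
        self._frozen = frozen

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        draws = self._frozen.rvs(size=size, random_state=rng)
        # keep thresholds strictly inside (0, 1)
        return np.clip(draws, 1e-12, 1.0 - 1e-12)

    def cdf(self, x) -> np.ndarray:
        return self._frozen.cdf(np.asarray(x, dtype=float))

    def as_threshold_cdf(self, grid: np.ndarray | None = None) -> ThresholdCDF:
        return ThresholdCDF.from_distribution(self._frozen, grid)

    def __repr__(self) -> str:
        args = ", ".join(f"{p:g}" for p in self.params)
        return f"{self.name}({args})" if args else self.name


@dataclass
class SimulationConfig:
    """Study conditions for the simulation experiments.

    Defaults reproduce the reference design: cohorts of 10000 patients,
    1000 replicates, the base outcome coefficients (-10, 0.1, 0.2, 0.5) and
    Beta(2, 7) thresholds.
    """

    n: int = 10000
    replicates: int = 1000
    beta0: float = -10.0
    beta_psa: float = 0.1
    beta_x1: float = 0.2
    beta_gs: float = 0.5
    gamma: float = 0.3
    noise_sd: float = 1.0
    pt_dist: str | PtDistribution = "beta(2,7)"
    range_of_interest: tuple[float, float] = (0.30, 0.50)
    n_boot: int = 1000
    alpha: float = 0.05
    seed: int | None = None
    m2_mode: str = "indicator"  # crossing example: 'indicator' or 'fitted'

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ConfigError("n must be at least 2")
        if self.replicates < 1:
            raise ConfigError("replicates must be at least 1")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be nonnegative")
        if not (0.0 < self.alpha < 1.0):
            raise ConfigError("alpha must lie in (0, 1)")
        lo, hi = self.range_of_interest
        if not (0.0 < lo < hi < 1.0):
            raise ConfigError("range_of_interest must satisfy 0 < lo < hi < 1")
        if self.m2_mode not in ("indicator", "fitted"):
            raise ConfigError("m2_mode must be 'indicator' or 'fitted'")
        self.pt_dist = PtDistribution(self.pt_dist)


@dataclass(kw_only=True)
class SimulatedCohort(Cohort):
    """A synthetic cohort carrying its predictors and generative ground truth."""

    predictors: pd.DataFrame
    p_d_true: np.ndarray

    def __post_init__(self) -> None:
        super().__post_init__()
        if len(self.predictors) != self.n:
            raise InputError("predictors frame length differs from cohort size")
        # row-wise consistency of the recorded decision with the threshold rule
        if self.z is not None and self.pt_true is not None:
            if not np.array_equal(self.z, (self.p_d_true >= self.pt_true).astype(int)):
                raise InputError("z is inconsistent with I(p_d_true >= pt_true)")


def simulate_cohort(
    config: SimulationConfig,
    scenario: str = "base",
    rng: np.random.Generator | None = None,
) -> SimulatedCohort:
    """Draw one synthetic cohort.

    ``scenario`` is ``'base'``/``'type1'`` (the base outcome model) or
    ``'power'`` (adds ``gamma * n1 + eps`` to the linear predictor).
    """
    if scenario not in ("base", "type1", "power"):
        raise ConfigError(f"unknown scenario {scenario!r}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n
    psa = rng.exponential(scale=10.0, size=n)  # rate 0.1
    gs = 2 + rng.binomial(4, 0.5, size=n) + rng.binomial(4, 0.5, size=n)
    x1 = rng.normal(27.0, 6.0, size=n)
    noise = rng.standard_normal(size=(n, 6))
    eta = config.beta0 + config.beta_psa * psa + config.beta_x1 * x1 + config.beta_gs * gs
    if scenario == "power":
        eta = eta + config.gamma * noise[:, 0]
        if config.noise_sd > 0:
            eta = eta + rng.normal(0.0, config.noise_sd, size=n)
    p_true = expit(eta)
    y = rng.binomial(1, p_true)
    pt = PtDistribution(config.pt_dist).sample(rng, n)
    z = (p_true >= pt).astype(int)
    predictors = pd.DataFrame(
        {"PSA": psa, "GS": gs.astype(float), "X1": x1}
        | {f"n{i + 1}": noise[:, i] for i in range(6)}
    )
    return SimulatedCohort(
        y=y,
        risks={"generating": p_true},
        z=z,
        pt_true=pt,
        predictors=predictors,
        p_d_true=p_true,
    )


@dataclass
class RiskModel:
    """A fitted logistic risk model: intercept + coefficients over predictors."""

    predictors: tuple[str, ...]
    intercept: float
    coef: np.ndarray
    label: str = ""

    def predict(self, data: "pd.DataFrame | SimulatedCohort") -> np.ndarray:
        df = data.predictors if isinstance(data, SimulatedCohort) else data
        X = df[list(self.predictors)].to_numpy(dtype=float)
        return expit(self.intercept + X @ self.coef)


def fit_risk_model(
    cohort: SimulatedCohort,
    predictor_set: Sequence[str],
    label: str = "",
) -> RiskModel:
    """Maximum-likelihood logistic fit of the outcome on a predictor set."""
    missing = [p for p in predictor_set if p not in cohort.predictors.columns]
    if missing:
        raise InputError(f"unknown predictors {missing}")
    y = cohort.y
    if y.min() == y.max():
        raise FitError("outcome is degenerate (all 0 or all 1); cannot fit")
    X = sm.add_constant(
        cohort.predictors[list(predictor_set)].to_numpy(dtype=float), prepend=True
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=100)
    except Exception as exc:  # separation, singular design, ...
        raise FitError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", True):
        raise FitError("logistic fit did not converge")
    params = np.asarray(res.params, dtype=float)
    return RiskModel(
        predictors=tuple(predictor_set),
        intercept=float(params[0]),
        coef=params[1:],
        label=label or "+".join(predictor_set),
    )


def indicator_risks(cohort: SimulatedCohort) -> np.ndarray:
    """The crossing-example rule-based risk score ``I(GS >= 6 and X1 > 25)``.

    Returned as a {0, 1}-valued risk column: patients flagged by the rule are
    treated at every threshold below 1, the rest at none.
    """
    gs = cohort.predictors["GS"].to_numpy()
    x1 = cohort.predictors["X1"].to_numpy()
    return ((gs >= 6) & (x1 > 25)).astype(float)


def _replicate_rngs(seed: int | None, replicates: int) -> list[np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(c) for c in ss.spawn(replicates)]


def _proportion_ci(k: int, m: int, level: float = 0.95) -> tuple[float, float]:
    """Clopper–Pearson interval for a binomial proportion."""
    if m == 0:
        return (0.0, 1.0)
    a = (1.0 - level) / 2.0
    lo = 0.0 if k == 0 else float(stats.beta.ppf(a, k, m - k + 1))
    hi = 1.0 if k == m else float(stats.beta.ppf(1.0 - a, k + 1, m - k))
    return lo, hi


@dataclass
class RejectionRates:
    """Per-statistic rejection and model-1-superiority rates across replicates.

    ``rates`` holds the proportion of replicates whose CI excludes zero (for
    C-NBC: the per-threshold rejection indicator averaged over the range);
    ``superior`` the analogous proportion with the CI entirely above zero.
    """

    rates: dict[str, float]
    superior: dict[str, float]
    mc_se: dict[str, float]
    binom_ci: dict[str, tuple[float, float]]
    per_replicate: dict[str, np.ndarray]
    replicates: int
    skipped: int = 0


def _run_comparison_replicates(
    config: SimulationConfig,
    scenario: str,
    m1_set: Sequence[str],
    m2_set: Sequence[str],
) -> RejectionRates:
    """Shared driver for the type-I and (single-gamma) power experiments.

    Per replicate: simulate, fit both models, estimate the threshold CDF
    from ``(Z, p_d^{M1})``, then run the three comparisons on the range of
    interest with shared bootstrap resamples.
    """
    stats_names = ("cnbc", "anbc", "wanbc")
    records: dict[str, list[float]] = {s: [] for s in stats_names}
    sup_records: dict[str, list[float]] = {s: [] for s in stats_names}
    skipped = 0
    lo, hi = config.range_of_interest
    for rng in _replicate_rngs(config.seed, config.replicates):
        cohort = simulate_cohort(config, scenario, rng=rng)
        try:
            m1 = fit_risk_model(cohort, m1_set, "M1")
            m2 = fit_risk_model(cohort, m2_set, "M2")
        except FitError:
            skipped += 1
            continue
        cohort.risks["M1"] = m1.predict(cohort)
        cohort.risks["M2"] = m2.predict(cohort)
        cdf = estimate_threshold_cdf(cohort.z, cohort.risks["M1"])
        res = compare_models(
            cohort,
            ("M1", "M2"),
            range_of_interest=config.range_of_interest,
            n_boot=config.n_boot,
            alpha=config.alpha,
            seed=rng,
            cdf=cdf,
        )
        _, cnbc_avg_reject = cnbc_decide(res["cnbc"], config.range_of_interest)
        records["cnbc"].append(cnbc_avg_reject)
        records["anbc"].append(float(res["anbc"].rejects_equivalence))
        records["wanbc"].append(float(res["wanbc"].rejects_equivalence))
        ts = res["cnbc"].thresholds
        mask = (ts >= lo - 1e-12) & (ts <= hi + 1e-12)
        sup_pt = np.asarray(
            [d == "model1_superior" for d in res["cnbc"].decision], dtype=float
        )
        sup_records["cnbc"].append(float(sup_pt[mask].mean()))
        sup_records["anbc"].append(float(res["anbc"].decision == "model1_superior"))
        sup_records["wanbc"].append(float(res["wanbc"].decision == "model1_superior"))
    m = len(records["cnbc"])
    if m == 0:
        raise FitError("every replicate failed to fit")
    rates, sup, se, ci, arrays = {}, {}, {}, {}, {}
    for s in stats_names:
        arr = np.asarray(records[s], dtype=float)
        arrays[s] = arr
        r = float(arr.mean())
        rates[s] = r
        sup[s] = float(np.mean(sup_records[s]))
        se[s] = float(np.sqrt(max(r * (1 - r), 1e-12) / m))
        ci[s] = _proportion_ci(int(round(arr.sum())), m)
    return RejectionRates(
        rates=rates, superior=sup, mc_se=se, binom_ci=ci, per_replicate=arrays,
        replicates=m, skipped=skipped,
    )


def run_type1_experiment(config: SimulationConfig) -> RejectionRates:
    """Type-I error: two equivalent models (same causal part, disjoint noise
    predictors) compared under the base outcome model."""
    return _run_comparison_replicates(config, "base", TYPE1_M1, TYPE1_M2)


@dataclass
class PowerResult:
    """Power of each statistic at each effect size ``gamma``."""

    gammas: tuple[float, ...]
    power: dict[float, dict[str, float]]  # CI excludes zero
    superior: dict[float, dict[str, float]]  # model 1 declared superior
    mc_se: dict[float, dict[str, float]]
    replicates: int
    skipped: dict[float, int]


def run_power_experiment(
    config: SimulationConfig, gammas: Sequence[float] = (0.3, 0.35, 0.4)
) -> PowerResult:
    """Power: M1 carries the causal predictor ``n1`` that M2 omits.

    Power for A-NBC/WA-NBC is the proportion of replicates whose CI excludes
    zero; for C-NBC the per-threshold rejection indicator is averaged over
    the range of interest before averaging over replicates.  Superiority
    rates (CI entirely above zero) are recorded alongside.
    """
    if not gammas:
        raise ConfigError("gammas must be nonempty")
    power: dict[float, dict[str, float]] = {}
    superior: dict[float, dict[str, float]] = {}
    se: dict[float, dict[str, float]] = {}
    skipped: dict[float, int] = {}
    for i, g in enumerate(gammas):
        # distinct, deterministic seed stream per gamma
        sub_seed = None if config.seed is None else config.seed + 100_003 * (i + 1)
        cfg = replace(config, gamma=float(g), seed=sub_seed)
        rej = _run_comparison_replicates(cfg, "power", POWER_M1, POWER_M2)
        power[float(g)] = rej.rates
        superior[float(g)] = rej.superior
        se[float(g)] = rej.mc_se
        skipped[float(g)] = rej.skipped
    return PowerResult(
        gammas=tuple(float(g) for g in gammas),
        power=power,
        superior=superior,
        mc_se=se,
        replicates=config.replicates,
        skipped=skipped,
    )


@dataclass
class TotalNetBenefitTable:
    """Replicate summary of cohort totals for one threshold scenario."""

    scenario: str
    mean: dict[str, float]
    ci: dict[str, tuple[float, float]]
    se: dict[str, float]
    per_replicate: dict[str, np.ndarray]
    replicates: int


_TOTAL_METHODS = ("true_thresholds", "estimated_distribution", "uniform_distribution")


def run_total_nb_experiment(
    config: SimulationConfig,
    scenarios: Sequence[str] = ("uniform", "beta(2,7)"),
) -> dict[str, TotalNetBenefitTable]:
    """Cohort total net benefit under three accounting methods.

    Per replicate: independent train/test cohorts of size ``n``; the base
    logistic model (PSA, X1, GS) is fit on train, the net benefit curve is
    computed on test, and the three totals are evaluated on test.  The
    threshold CDF for the 'estimated' method is estimated from the test
    cohort's ``(Z, p_d)`` with the *fitted* risks, never from ``pt_true``.
    """
    out: dict[str, TotalNetBenefitTable] = {}
    grid = ThresholdGrid.full_range()
    for j, scen in enumerate(scenarios):
        sub_seed = None if config.seed is None else config.seed + 200_003 * (j + 1)
        cfg = replace(config, pt_dist=scen, seed=sub_seed)
        totals: dict[str, list[float]] = {m: [] for m in _TOTAL_METHODS}
        for rng in _replicate_rngs(cfg.seed, cfg.replicates):
            train = simulate_cohort(cfg, "base", rng=rng)
            test = simulate_cohort(cfg, "base", rng=rng)
            model = fit_risk_model(train, ("PSA", "X1", "GS"))
            test.risks["fitted"] = model.predict(test)
            cdf = estimate_threshold_cdf(test.z, test.risks["fitted"])
            for method in _TOTAL_METHODS:
                res = total_net_benefit(
                    test, "fitted", method,
                    cdf=cdf if method == "estimated_distribution" else None,
                    grid=grid,
                )
                totals[method].append(res.total_nb)
        tbl = TotalNetBenefitTable(
            scenario=str(scen),
            mean={}, ci={}, se={}, per_replicate={}, replicates=cfg.replicates,
        )
        for method, vals in totals.items():
            arr = np.asarray(vals)
            tbl.per_replicate[method] = arr
            tbl.mean[method] = float(arr.mean())
            tbl.se[method] = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else float("nan")
            lo, hi = np.quantile(arr, (0.025, 0.975)) if arr.size > 1 else (arr[0], arr[0])
            tbl.ci[method] = (float(lo), float(hi))
        out[str(scen)] = tbl
    return out


@dataclass
class CrossingResult:
    """Decision discordance between A-NBC and WA-NBC on the crossing design."""

    replicates: int
    anbc_decisions: list[str]
    wanbc_decisions: list[str]
    anbc_fraction: dict[str, float]
    wanbc_fraction: dict[str, float]
    example_curves: dict[str, "np.ndarray"]
    example_results: dict[str, "object"]
    range_of_interest: tuple[float, float]


def run_crossing_example(
    config: SimulationConfig,
    replicates: int | None = None,
) -> CrossingResult:
    """The crossing-curves design: M1 is a PSA-only logistic model, M2 the
    rule ``I(GS >= 6 and X1 > 25)``; thresholds follow Beta(2, 7) and the
    comparison range is [0.15, 0.45] unless configured otherwise.

    Because the threshold distribution is right-skewed, most patients hold
    low thresholds, where M1 dominates; WA-NBC typically declares M1
    superior while the equal-weight A-NBC typically declares equivalence.

    The threshold CDF is estimated from the cohort's decisions together
    with the risks of a fitted full clinical model (PSA, X1, GS) — the
    observable stand-in for the risk assessment that actually drove the
    decisions.  Feeding the estimator a candidate model's risks instead
    violates its identifying assumption ``Z = I(p_d >= p_t)`` whenever that
    candidate is misspecified (the PSA-only M1 badly so), which visibly
    distorts the estimated weights.
    """
    reps = config.replicates if replicates is None else int(replicates)
    lo, hi = config.range_of_interest
    anbc_dec: list[str] = []
    wanbc_dec: list[str] = []
    example_curves: dict[str, np.ndarray] = {}
    example_results: dict[str, object] = {}
    for rng in _replicate_rngs(config.seed, reps):
        cohort = simulate_cohort(config, "base", rng=rng)
        m1 = fit_risk_model(cohort, ("PSA",), "M1")
        cohort.risks["M1"] = m1.predict(cohort)
        if config.m2_mode == "indicator":
            cohort.risks["M2"] = indicator_risks(cohort)
        else:
            ind = indicator_risks(cohort)
            cohort.predictors["m2_indicator"] = ind
            m2 = fit_risk_model(cohort, ("m2_indicator",), "M2")
            cohort.risks["M2"] = m2.predict(cohort)
        clinical = fit_risk_model(cohort, ("PSA", "X1", "GS"), "clinical")
        cdf = estimate_threshold_cdf(cohort.z, clinical.predict(cohort))
        res = compare_models(
            cohort,
            ("M1", "M2"),
            range_of_interest=(lo, hi),
            statistics=("anbc", "wanbc"),
            n_boot=config.n_boot,
            alpha=config.alpha,
            seed=rng,
            cdf=cdf,
        )
        anbc_dec.append(res["anbc"].decision)
        wanbc_dec.append(res["wanbc"].decision)
        grid = ThresholdGrid.from_range(lo, hi, 101)
        example_curves = {
            "thresholds": grid.values,
            "M1": net_benefit_curve(cohort, "M1", grid).nb,
            "M2": net_benefit_curve(cohort, "M2", grid).nb,
        }
        example_results = {"anbc": res["anbc"], "wanbc": res["wanbc"]}

    def _frac(decisions: list[str]) -> dict[str, float]:
        m = len(decisions)
        return {
            k: decisions.count(k) / m
            for k in ("model1_superior", "model2_superior", "equivalent")
        }

    return CrossingResult(
        replicates=reps,
        anbc_decisions=anbc_dec,
        wanbc_decisions=wanbc_dec,
        anbc_fraction=_frac(anbc_dec),
        wanbc_fraction=_frac(wanbc_dec),
        example_curves=example_curves,
        example_results=example_results,
        range_of_interest=(lo, hi),
    )
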