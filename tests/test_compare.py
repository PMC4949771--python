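import numpy as np
import pytest
from scipy import integrate, stats

from dcaw import (
    Cohort,
    ComparisonResult,
    InputError,
    ThresholdCDF,
    ThresholdGrid,
    anbc,
    cnbc_decide,
    compare_models,
    net_benefit_curve,
    paired_bootstrap_ci,
    reference_curves,
    total_net_benefit,
    wanbc,
)
from dcaw.core import NetBenefitCurve
from dcaw.threshold_dist import default_cdf_grid


def _curve(grid_vals, nb, label="m", n=100):
    return NetBenefitCurve(
        grid=ThresholdGrid(np.asarray(grid_vals)), nb=np.asarray(nb),
        model_label=label, n=n,
    )


def _beta_cdf(a=2, b=7):
    g = default_cdf_grid()
    return ThresholdCDF(grid=g, cdf=stats.beta(a, b).cdf(g))


class TestAnbc:
    def test_constant_curve(self):
        ts = np.linspace(0.2, 0.6, 21)
        assert anbc(_curve(ts, np.full(21, 0.3))) == pytest.approx(0.3 * 0.4)

    def test_linear_curve_exact(self):
        ts = np.linspace(0.1, 0.5, 41)
        nb = (ts - 0.1) / 0.4 * 0.2  # 0 at lo, 0.2 at hi
        assert anbc(_curve(ts, nb)) == pytest.approx(0.2 * 0.4 / 2)

    def test_treat_all_matches_analytic_integral(self):
        y = np.array([1] * 50 + [0] * 50)
        c = Cohort(y=y, risks={"all": np.ones(100)})
        grid = ThresholdGrid.from_range(0.1, 0.3, 101)
        curve = net_benefit_curve(c, "all", grid)
        exact, _ = integrate.quad(lambda t: 0.5 - 0.5 * t / (1 - t), 0.1, 0.3)
        assert anbc(curve) == pytest.approx(exact, abs=1e-4)

    def test_range_outside_grid_raises(self):
        ts = np.linspace(0.2, 0.4, 11)
        with pytest.raises(InputError):
            anbc(_curve(ts, np.zeros(11)), (0.1, 0.3))


class TestWanbc:
    def test_uniform_weights_reduce_to_anbc(self):
        ts = np.linspace(0.15, 0.45, 101)
        rng = np.random.default_rng(3)
        nb = rng.normal(0.1, 0.05, ts.size)
        c = _curve(ts, nb)
        assert wanbc(c, ThresholdCDF.uniform()) == pytest.approx(
            anbc(c), abs=1e-6
        )

    def test_step_cdf_picks_curve_value_at_atom(self):
        ts = np.linspace(0.15, 0.45, 301)
        nb = np.sin(ts * 3) * 0.1
        step = ThresholdCDF(grid=np.array([0.2999, 0.3001]), cdf=np.array([0.0, 1.0]))
        val = wanbc(_curve(ts, nb), step)
        assert val == pytest.approx(np.interp(0.3, ts, nb), abs=1e-4)

    def test_beta_weighted_treat_all_matches_quadrature_oracle(self):
        y = np.array([1] * 50 + [0] * 50)
        c = Cohort(y=y, risks={"all": np.ones(100)})
        grid = ThresholdGrid.from_range(0.15, 0.45, 1001)
        curve = net_benefit_curve(c, "all", grid)
        f = stats.beta(2, 7).pdf
        exact, _ = integrate.quad(lambda t: (0.5 - 0.5 * t / (1 - t)) * f(t), 0.15, 0.45)
        assert wanbc(curve, _beta_cdf()) == pytest.approx(exact, abs=1e-3)

    def test_zero_mass_in_range_warns_and_returns_zero(self):
        ts = np.linspace(0.5, 0.7, 21)
        step = ThresholdCDF(grid=np.array([0.1, 0.12]), cdf=np.array([0.0, 1.0]))
        with pytest.warns(RuntimeWarning):
            assert wanbc(_curve(ts, np.full(21, 0.2)), step) == 0.0


@pytest.fixture(scope="module")
def two_model_cohort():
    rng = np.random.default_rng(7)
    n = 600
    p = rng.uniform(0.05, 0.9, n)
    y = rng.binomial(1, p)
    noisy = np.clip(p + rng.normal(0, 0.25, n), 0, 1)
    return Cohort(
        y=y, risks={"good": p, "noisy": noisy, "same": p},
        z=(p >= rng.uniform(0, 1, n)).astype(int),
    )


class TestPairedBootstrap:
    def test_self_comparison_degenerate_null(self, two_model_cohort):
        res = paired_bootstrap_ci(
            two_model_cohort, ("good", "same"), "anbc",
            range_of_interest=(0.2, 0.6), n_boot=100, seed=1,
        )
        assert res.estimate == 0.0
        assert res.ci_lo == 0.0 and res.ci_hi == 0.0
        assert res.decision == "equivalent"

    def test_seed_reproducibility(self, two_model_cohort):
        kw = dict(range_of_interest=(0.2, 0.6), n_boot=150, seed=42)
        a = paired_bootstrap_ci(two_model_cohort, ("good", "noisy"), "anbc", **kw)
        b = paired_bootstrap_ci(two_model_cohort, ("good", "noisy"), "anbc", **kw)
        assert (a.ci_lo, a.ci_hi, a.estimate) == (b.ci_lo, b.ci_hi, b.estimate)

    def test_all_statistics_share_resamples(self, two_model_cohort):
        res = compare_models(
            two_model_cohort, ("good", "noisy"),
            range_of_interest=(0.2, 0.6), n_boot=150, seed=5,
            cdf=ThresholdCDF.uniform(),
        )
        # uniform weighting makes the WA statistic equal the area statistic,
        # resample by resample, hence identical CIs
        assert res["wanbc"].estimate == pytest.approx(res["anbc"].estimate, abs=1e-9)
        assert res["wanbc"].ci_lo == pytest.approx(res["anbc"].ci_lo, abs=1e-9)
        assert res["wanbc"].ci_hi == pytest.approx(res["anbc"].ci_hi, abs=1e-9)

    def test_label_swap_flips_sign_and_decision(self, two_model_cohort):
        kw = dict(range_of_interest=(0.2, 0.6), n_boot=150, seed=9,
                  cdf=ThresholdCDF.uniform())
        fwd = paired_bootstrap_ci(two_model_cohort, ("good", "noisy"), "wanbc", **kw)
        rev = paired_bootstrap_ci(two_model_cohort, ("noisy", "good"), "wanbc", **kw)
        assert rev.estimate == pytest.approx(-fwd.estimate)
        assert rev.ci_lo == pytest.approx(-fwd.ci_hi)
        flip = {"model1_superior": "model2_superior",
                "model2_superior": "model1_superior",
                "equivalent": "equivalent"}
        assert rev.decision == flip[fwd.decision]

    def test_monotone_dominance_gives_positive_differences(self, rng):
        # a perfect model dominates an uninformative one at every threshold
        y = rng.integers(0, 2, 400)
        c = Cohort(y=y, risks={"perfect": y.astype(float),
                               "none": np.zeros(400)})
        res = compare_models(
            c, ("perfect", "none"), range_of_interest=(0.2, 0.6),
            n_boot=100, seed=2, cdf=_beta_cdf(),
        )
        assert res["anbc"].estimate > 0
        assert res["wanbc"].estimate > 0
        assert res["anbc"].decision == "model1_superior"
        assert res["wanbc"].decision == "model1_superior"

    def test_small_n_boot_warns(self, two_model_cohort):
        with pytest.warns(RuntimeWarning):
            paired_bootstrap_ci(
                two_model_cohort, ("good", "noisy"), "anbc",
                range_of_interest=(0.2, 0.6), n_boot=10, alpha=0.05, seed=3,
            )

    def test_unknown_statistic_raises(self, two_model_cohort):
        with pytest.raises(InputError):
            paired_bootstrap_ci(
                two_model_cohort, ("good", "noisy"), "area",
                range_of_interest=(0.2, 0.6),
            )

    def test_pointwise_result_roundtrips_and_contains_estimate(self, two_model_cohort):
        res = paired_bootstrap_ci(
            two_model_cohort, ("good", "noisy"), "pointwise",
            range_of_interest=(0.2, 0.6), n_boot=200, seed=11,
        )
        assert res.thresholds is not None
        back = ComparisonResult.from_dict(res.to_dict())
        assert np.allclose(back.estimate, res.estimate)
        assert back.decision == res.decision
        # percentile CI from the bootstrap distribution brackets the observed
        # statistic at this resample count
        assert np.mean((res.ci_lo <= res.estimate) & (res.estimate <= res.ci_hi)) > 0.9


class TestCnbcDecide:
    def _result(self, lo, hi):
        ts = np.linspace(0.2, 0.6, len(lo))
        return ComparisonResult(
            statistic_name="cnbc", model_labels=("a", "b"),
            estimate=(np.asarray(lo) + np.asarray(hi)) / 2,
            ci_lo=np.asarray(lo, dtype=float), ci_hi=np.asarray(hi, dtype=float),
            alpha=0.05, n_boot=100,
            decision=["model1_superior" if l > 0 else
                      ("model2_superior" if h < 0 else "equivalent")
                      for l, h in zip(lo, hi)],
            thresholds=ts,
        )

    def test_all_exclude_zero(self):
        _, avg = cnbc_decide(self._result([0.1] * 4, [0.2] * 4))
        assert avg == 1.0

    def test_none_exclude_zero(self):
        _, avg = cnbc_decide(self._result([-0.1] * 4, [0.2] * 4))
        assert avg == 0.0

    def test_half_exclude_zero(self):
        _, avg = cnbc_decide(self._result([0.1, 0.1, -0.1, -0.1], [0.2] * 4))
        assert avg == 0.5

    def test_requires_pointwise_result(self):
        scalar = ComparisonResult(
            statistic_name="anbc", model_labels=("a", "b"), estimate=0.1,
            ci_lo=0.0, ci_hi=0.2, alpha=0.05, n_boot=100, decision="equivalent",
        )
        with pytest.raises(InputError):
            cnbc_decide(scalar)


class TestTotalNetBenefit:
    def test_zero_curve_gives_zero_totals(self, rng):
        y = rng.integers(0, 2, 100)
        c = Cohort(
            y=y, risks={"none": np.zeros(100)},
            pt_true=rng.uniform(0.01, 0.99, 100),
        )
        for method, cdf in [
            ("true_thresholds", None),
            ("estimated_distribution", ThresholdCDF.uniform()),
            ("uniform_distribution", None),
        ]:
            res = total_net_benefit(c, "none", method, cdf=cdf)
            assert res.total_nb == pytest.approx(0.0, abs=1e-12)

    def test_uniform_method_equals_n_times_anbc(self, svi_cohort):
        res = total_net_benefit(svi_cohort, "generating", "uniform_distribution")
        curve = net_benefit_curve(svi_cohort, "generating")
        assert res.total_nb == pytest.approx(svi_cohort.n * anbc(curve), abs=1e-9)

    def test_missing_requirements_raise(self, rng):
        y = rng.integers(0, 2, 50)
        c = Cohort(y=y, risks={"m": rng.uniform(0, 1, 50)})
        with pytest.raises(InputError):
            total_net_benefit(c, "m", "true_thresholds")
        with pytest.raises(InputError):
            total_net_benefit(c, "m", "estimated_distribution")
        with pytest.raises(InputError):
            total_net_benefit(c, "m", "bogus")
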