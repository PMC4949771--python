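import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dcaw import (
    Cohort,
    DomainError,
    InputError,
    NetBenefitCurve,
    ThresholdGrid,
    net_benefit,
    net_benefit_curve,
    reference_curves,
)
from dcaw.core import curve_values


def brute_force_nb(y, pd, pt, harm=0.0):
    """Independent oracle: direct enumeration of the net benefit formula."""
    y = np.asarray(y)
    pd = np.asarray(pd)
    tp = sum(1 for yi, pi in zip(y, pd) if pi >= pt and yi == 1)
    fp = sum(1 for yi, pi in zip(y, pd) if pi >= pt and yi == 0)
    n = len(y)
    return tp / n - (fp / n) * pt / (1 - pt) - harm


class TestNetBenefit:
    def test_hand_enumerated_four_patients(self):
        # TP=1, FP=1 at pt=0.5: 1/4 - (1/4)(0.5/0.5) = 0
        assert net_benefit([1, 1, 0, 0], [0.8, 0.4, 0.6, 0.2], 0.5) == pytest.approx(0.0)

    def test_treat_none_is_zero(self, rng):
        y = rng.integers(0, 2, 50)
        y[0] = 1
        assert net_benefit(y, np.zeros(50), 0.3) == 0.0

    def test_perfect_model_gives_prevalence(self, rng):
        y = rng.integers(0, 2, 200)
        assert net_benefit(y, y.astype(float), 0.5) == pytest.approx(y.mean())

    @pytest.mark.parametrize(
        "kwargs, exc",
        [
            (dict(y=[1, 0], pd=[0.5, 0.5], pt=0.0), DomainError),
            (dict(y=[1, 0], pd=[0.5, 0.5], pt=1.0), DomainError),
            (dict(y=[1, 0], pd=[0.5], pt=0.5), InputError),
            (dict(y=[], pd=[], pt=0.5), InputError),
            (dict(y=[1, 2], pd=[0.5, 0.5], pt=0.5), InputError),
            (dict(y=[1, 0], pd=[0.5, 1.2], pt=0.5), InputError),
            (dict(y=[1, 0], pd=[0.5, 0.5], pt=0.5, harm=-0.1), DomainError),
        ],
    )
    def test_invalid_inputs_raise(self, kwargs, exc):
        with pytest.raises(exc):
            net_benefit(**kwargs)

    @given(
        data=st.lists(
            st.tuples(st.integers(0, 1), st.floats(0.0, 1.0)), min_size=1, max_size=30
        ),
        pt=st.floats(0.05, 0.95),
        harm=st.floats(0.0, 0.2),
    )
    def test_matches_enumeration_and_basic_identities(self, data, pt, harm):
        y = [d[0] for d in data]
        pd = [d[1] for d in data]
        nb = net_benefit(y, pd, pt, harm=harm)
        # enumeration oracle
        assert nb == pytest.approx(brute_force_nb(y, pd, pt, harm), abs=1e-12)
        # harm is an exact shift
        assert nb == pytest.approx(net_benefit(y, pd, pt) - harm, abs=1e-12)
        # bounded above by prevalence (before harm)
        assert nb + harm <= np.mean(y) + 1e-12
        # permutation invariance
        perm = np.random.default_rng(1).permutation(len(y))
        assert net_benefit(np.array(y)[perm], np.array(pd)[perm], pt, harm=harm) == (
            pytest.approx(nb, abs=1e-12)
        )


class TestThresholdGrid:
    def test_from_range_covers_inclusive_endpoints(self):
        g = ThresholdGrid.from_range(0.3, 0.5, 101)
        assert len(g) == 101
        assert g.values[0] == pytest.approx(0.3)
        assert g.values[-1] == pytest.approx(0.5)
        assert g.range_of_interest == (0.3, 0.5)

    def test_full_range_avoids_endpoints(self):
        g = ThresholdGrid.full_range()
        assert 0.0 < g.values[0] and g.values[-1] < 1.0

    @pytest.mark.parametrize(
        "values, exc",
        [
            ([0.0, 0.5], DomainError),
            ([0.5, 1.0], DomainError),
            ([0.5, 0.4], InputError),
            ([0.4, 0.4], InputError),
        ],
    )
    def test_invalid_grids_raise(self, values, exc):
        with pytest.raises(exc):
            ThresholdGrid(np.asarray(values))

    def test_grid_must_cover_range_of_interest(self):
        with pytest.raises(InputError):
            ThresholdGrid(np.linspace(0.3, 0.4, 11), range_of_interest=(0.2, 0.5))


class TestCurves:
    def test_curve_matches_scalar_oracle_pointwise(self, rng):
        y = rng.integers(0, 2, 300)
        pd = rng.uniform(0, 1, 300)
        ts = np.linspace(0.05, 0.95, 19)
        vec = curve_values(y, pd, ts)
        for t, v in zip(ts, vec):
            assert v == pytest.approx(net_benefit(y, pd, t), abs=1e-12)

    def test_perfect_model_curve_is_constant_prevalence(self, rng):
        y = rng.integers(0, 2, 100)
        c = Cohort(y=y, risks={"perfect": y.astype(float)})
        curve = net_benefit_curve(c, "perfect", ThresholdGrid.from_range(0.1, 0.9, 21))
        assert np.allclose(curve.nb, y.mean())

    def test_treat_all_closed_form_and_crossing_at_prevalence(self, rng):
        y = np.array([1] * 50 + [0] * 50)
        c = Cohort(y=y, risks={"all": np.ones(100)})
        grid = ThresholdGrid.from_range(0.1, 0.9, 33)
        curve = net_benefit_curve(c, "all", grid)
        expected = 0.5 - 0.5 * grid.values / (1 - grid.values)
        assert np.allclose(curve.nb, expected)
        # crossing at pt = prevalence: NB = p - (1-p) p/(1-p) = 0
        assert net_benefit(y, np.ones(100), 0.5) == pytest.approx(0.0)
        # pt = 1/3 with prevalence 0.5: 0.5 - 0.5 * 0.5 = 0.25
        assert net_benefit(y, np.ones(100), 1 / 3) == pytest.approx(0.25)

    def test_reference_curves(self, four_patient_cohort):
        grid = ThresholdGrid.from_range(0.2, 0.8, 13)
        treat_all, treat_none = reference_curves(four_patient_cohort, grid)
        assert np.allclose(treat_none.nb, 0.0)
        prev = four_patient_cohort.prevalence
        assert np.allclose(
            treat_all.nb, prev - (1 - prev) * grid.values / (1 - grid.values)
        )
        assert np.all(np.diff(treat_all.nb) < 0)  # decreasing in pt

    def test_unknown_model_label_raises(self, four_patient_cohort):
        with pytest.raises(InputError):
            net_benefit_curve(four_patient_cohort, "nope")

    def test_extra_low_risk_nonevent_keeps_numerators(self, rng):
        # a patient with p_d below every threshold and y=0 adds no TP/FP;
        # only the denominator n grows
        y = rng.integers(0, 2, 40)
        pd = rng.uniform(0.2, 1.0, 40)
        ts = np.linspace(0.15, 0.9, 16)
        base = curve_values(y, pd, ts)
        grown = curve_values(np.append(y, 0), np.append(pd, 0.01), ts)
        assert np.allclose(grown * 41, base * 40)

    def test_nb_never_exceeds_prevalence_on_curve(self, svi_cohort):
        curve = net_benefit_curve(svi_cohort, "generating")
        assert np.all(curve.nb <= svi_cohort.prevalence + 1e-12)


class TestCohortValidation:
    def test_length_and_domain_checks(self):
        with pytest.raises(InputError):
            Cohort(y=[1, 0], risks={"m": [0.5]})
        with pytest.raises(InputError):
            Cohort(y=[1, 0], risks={"m": [0.5, 1.5]})
        with pytest.raises(InputError):
            Cohort(y=[1, 0], risks={"m": [0.5, 0.5]}, z=[1, 2])
        with pytest.raises(InputError):
            Cohort(y=[1, 0], risks={"m": [0.5, 0.5]}, pt_true=[0.5, 1.0])

    def test_decision_rule_check(self):
        c = Cohort(
            y=[1, 0, 1],
            risks={"m": [0.7, 0.2, 0.4]},
            z=[1, 0, 1],
            pt_true=[0.5, 0.5, 0.3],
        )
        assert c.decisions_follow_rule("m")
        c2 = Cohort(
            y=[1, 0, 1],
            risks={"m": [0.7, 0.2, 0.4]},
            z=[0, 0, 1],
            pt_true=[0.5, 0.5, 0.3],
        )
        assert not c2.decisions_follow_rule("m")

    def test_curve_length_mismatch_raises(self):
        grid = ThresholdGrid.from_range(0.1, 0.9, 9)
        with pytest.raises(InputError):
            NetBenefitCurve(grid=grid, nb=np.zeros(5), model_label="m", n=10)
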