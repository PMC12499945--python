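"""LQ survival, EUD closed form, and EQD2 conversions."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import brentq

from stepgrad import (
    DVH,
    LQParams,
    eqd2_conventional,
    eqd2_per_fraction,
    eqd2_stepwise,
    eud,
    eud_from_eqd2,
    mean_survival,
    survival_fraction,
    total_eqd2,
)

from conftest import random_dvh


def eud_bisection_oracle(dvh, params):
    """Independent numeric root of SF(EUD) = mean survival."""
    target = sum(
        nu * np.exp(-params.alpha * d - params.beta * d * d)
        for d, nu in zip(dvh.bin_dose, dvh.bin_fraction)
    )
    f = lambda x: np.exp(-params.alpha * x - params.beta * x * x) - target
    return brentq(f, 0.0, dvh.max_dose + 1e-9, xtol=1e-12)


class TestSurvival:
    @pytest.mark.parametrize(
        "d,expected",
        [(0.0, 1.0), (2.0, np.exp(-0.72)), (12.0, np.exp(-7.92))],
    )
    def test_single_dose(self, d, expected, params):
        assert survival_fraction(d, params) == pytest.approx(expected, rel=1e-12)

    def test_negative_dose_rejected(self, params):
        with pytest.raises(ValueError):
            survival_fraction(-1.0, params)

    def test_strictly_decreasing(self, params):
        d = np.linspace(0, 30, 200)
        assert np.all(np.diff(survival_fraction(d, params)) < 0)

    def test_mean_survival_examples(self, params, hetero_dvh):
        uniform3 = DVH(bin_dose=[3.0], bin_fraction=[1.0])
        assert mean_survival(uniform3, params) == pytest.approx(np.exp(-1.17), rel=1e-12)
        assert mean_survival(hetero_dvh, params) == pytest.approx(0.15537, abs=5e-6)
        zero = DVH(bin_dose=[0.0], bin_fraction=[1.0])
        assert mean_survival(zero, params) == pytest.approx(1.0)

    def test_mean_survival_bounded_by_extremes(self, params):
        rng = np.random.default_rng(11)
        for _ in range(30):
            d = random_dvh(rng)
            s = mean_survival(d, params)
            assert survival_fraction(d.max_dose, params) - 1e-12 <= s
            assert s <= survival_fraction(d.min_dose, params) + 1e-12


class TestEUD:
    @given(st.floats(0.0, 30.0))
    def test_identity_on_uniform_dvh(self, d):
        dvh = DVH(bin_dose=[d] if d > 0 else [0.0], bin_fraction=[1.0])
        assert eud(dvh) == pytest.approx(d, abs=1e-9)

    def test_two_level_example(self, params, hetero_dvh):
        assert eud(hetero_dvh, params) == pytest.approx(4.330, abs=1e-3)

    def test_pure_linear_kill_example(self):
        params = LQParams(alpha=0.3, beta=0.0)
        dvh = DVH(bin_dose=[0.0, 6.0], bin_fraction=[0.5, 0.5])
        expected = -np.log(0.5 * (1 + np.exp(-1.8))) / 0.3
        assert eud(dvh, params) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(1.801, abs=1e-3)

    def test_closed_form_matches_bisection_oracle(self, params):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            d = random_dvh(rng)
            assert eud(d, params) == pytest.approx(
                eud_bisection_oracle(d, params), abs=1e-9
            )

    def test_jensen_bounds(self, params):
        rng = np.random.default_rng(5)
        for _ in range(200):
            d = random_dvh(rng)
            e = eud(d, params)
            assert d.min_dose - 1e-9 <= e <= d.mean_dose + 1e-9

    def test_strict_jensen_for_heterogeneous(self, params, hetero_dvh):
        assert eud(hetero_dvh, params) < hetero_dvh.mean_dose

    def test_monotone_in_bin_dose(self, params):
        rng = np.random.default_rng(17)
        for _ in range(50):
            d = random_dvh(rng)
            i = int(rng.integers(d.n_bins))
            dose = d.bin_dose.copy()
            dose[i] += d.bin_dose.max() + rng.uniform(0.1, 2.0)
            order = np.argsort(dose)
            bumped = DVH(bin_dose=dose[order], bin_fraction=d.bin_fraction[order])
            assert eud(bumped, params) >= eud(d, params) - 1e-12

    def test_high_dose_underflow_handled_in_log_space(self, params):
        dvh = DVH(bin_dose=[3000.0], bin_fraction=[1.0])
        assert eud(dvh, params) == pytest.approx(3000.0, rel=1e-9)


class TestEQD2:
    @pytest.mark.parametrize(
        "e,expected",
        [(2.0, 2.0), (3.0, 3.25), (12.0, 22.0)],
    )
    def test_per_fraction(self, e, expected, params):
        assert eqd2_per_fraction(e, params) == pytest.approx(expected, rel=1e-12)

    def test_monotone_and_convex(self, params):
        x = np.linspace(0, 30, 301)
        y = np.array([eqd2_per_fraction(v, params) for v in x])
        assert np.all(np.diff(y) > 0)
        assert np.all(np.diff(y, 2) > -1e-12)

    @pytest.mark.parametrize(
        "e,n,expected",
        [(3.0, 10, 32.5), (2.25, 20, 20 * 2.25 * 12.25 / 12)],
    )
    def test_conventional_total(self, e, n, expected, params):
        assert eqd2_conventional(e, n, params) == pytest.approx(expected, rel=1e-12)

    def test_conventional_single_fraction(self, params):
        assert eqd2_conventional(3.0, 1, params) == eqd2_per_fraction(3.0, params)

    def test_invalid_fraction_count(self, params):
        with pytest.raises(ValueError):
            eqd2_conventional(3.0, 0, params)
        with pytest.raises(ValueError):
            eqd2_stepwise(4.0, 3.0, 0, params)

    def test_stepwise_regimen_example(self, params):
        # one 4.330 Gy-equivalent gradient fraction + 9 uniform 3 Gy fractions
        expected = 4.330 * 14.330 / 12 + 9 * 3.25
        assert eqd2_stepwise(4.330, 3.0, 10, params) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(34.42, abs=5e-3)

    @given(st.floats(0.0, 30.0), st.integers(1, 40))
    def test_stepwise_reduces_to_conventional_when_euds_match(self, e, n):
        params = LQParams()
        assert eqd2_stepwise(e, e, n, params) == pytest.approx(
            eqd2_conventional(e, n, params), rel=1e-12, abs=1e-12
        )

    def test_stepwise_single_fraction_is_gradient_only(self, params):
        assert eqd2_stepwise(5.0, 3.0, 1, params) == eqd2_per_fraction(5.0, params)

    @pytest.mark.parametrize(
        "phases,expected",
        [
            ([(8.7, 1), (3.38, 9)], 39.12),
            ([(7.5, 1), (3.25, 9)], 36.75),
            ([(4.2, 1)], 4.2),
        ],
    )
    def test_total_over_phases(self, phases, expected):
        assert total_eqd2(phases) == pytest.approx(expected, rel=1e-12)

    def test_total_rejects_empty_and_bad_counts(self):
        with pytest.raises(ValueError):
            total_eqd2([])
        with pytest.raises(ValueError):
            total_eqd2([(3.0, 0)])

    @given(st.floats(0.0, 30.0))
    def test_eud_eqd2_round_trip(self, x):
        params = LQParams()
        assert eud_from_eqd2(eqd2_per_fraction(x, params), params) == pytest.approx(
            x, abs=1e-9
        )

    @pytest.mark.parametrize("q,expected", [(3.25, 3.0), (2.0, 2.0), (22.0, 12.0)])
    def test_eud_from_eqd2_examples(self, q, expected, params):
        assert eud_from_eqd2(q, params) == pytest.approx(expected, abs=1e-9)


class TestLQParams:
    def test_alpha_beta_derived(self):
        assert LQParams(alpha=0.3, beta=0.03).alpha_beta == pytest.approx(10.0, abs=1e-12)
        assert np.isinf(LQParams(alpha=0.3, beta=0.0).alpha_beta)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            LQParams(alpha=0.0)
        with pytest.raises(ValueError):
            LQParams(beta=-0.01)
        with pytest.raises(ValueError):
            LQParams(cv=-0.1)
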