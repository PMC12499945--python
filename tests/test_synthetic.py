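"""Synthetic stepwise-gradient plan and cohort generators."""

import numpy as np
import pytest

from stepgrad import (
    SphericalGridSpec,
    StepwisePlanSpec,
    dvh_from_grid,
    eud,
    make_stepwise_dvh,
    make_synthetic_cohort,
    make_uniform_dvh,
)
from stepgrad.regimen import analyze_regimen


class TestStepwiseDVH:
    def test_single_shell_is_uniform(self):
        spec = StepwisePlanSpec(
            shell_doses=(3.0,), shell_fractions=(1.0,), transition_width=0, noise_sd=0
        )
        d = make_stepwise_dvh(spec)
        assert d.n_bins == 1
        assert d.bin_dose[0] == 3.0

    def test_noise_free_has_one_bin_per_distinct_dose(self):
        spec = StepwisePlanSpec(transition_width=0, noise_sd=0)
        d = make_stepwise_dvh(spec)
        np.testing.assert_allclose(d.bin_dose, [3.0, 9.0, 12.0])
        np.testing.assert_allclose(d.bin_fraction, [0.5, 0.3, 0.2])
        assert d.mean_dose == pytest.approx(6.6)

    def test_duplicate_shell_doses_merge(self):
        spec = StepwisePlanSpec(
            shell_doses=(3.0, 3.0, 12.0),
            shell_fractions=(0.3, 0.3, 0.4),
            transition_width=0,
            noise_sd=0,
        )
        d = make_stepwise_dvh(spec)
        np.testing.assert_allclose(d.bin_dose, [3.0, 12.0])
        np.testing.assert_allclose(d.bin_fraction, [0.6, 0.4])

    def test_noise_preserves_mean_dose(self):
        spec = StepwisePlanSpec(noise_sd=0.5, transition_width=0.0, seed=1)
        d = make_stepwise_dvh(spec)
        assert d.mean_dose == pytest.approx(6.6, abs=0.1)

    def test_seed_reproducibility(self):
        a = make_stepwise_dvh(StepwisePlanSpec(seed=5))
        b = make_stepwise_dvh(StepwisePlanSpec(seed=5))
        np.testing.assert_array_equal(a.bin_fraction, b.bin_fraction)

    def test_jensen_chain_through_engine(self):
        for seed in range(5):
            d = make_stepwise_dvh(StepwisePlanSpec(seed=seed))
            e = eud(d)
            assert d.min_dose - 1e-9 <= e <= d.mean_dose + 1e-9

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            StepwisePlanSpec(shell_doses=(12.0, 9.0, 3.0))
        with pytest.raises(ValueError, match="sum to 1"):
            StepwisePlanSpec(shell_fractions=(0.5, 0.5, 0.5))
        with pytest.raises(ValueError, match="equal length"):
            StepwisePlanSpec(shell_doses=(), shell_fractions=())


class TestUniformDVH:
    def test_zero_sd_single_bin(self):
        d = make_uniform_dvh(3.0)
        assert d.n_bins == 1
        assert eud(d) == pytest.approx(3.0, abs=1e-12)

    def test_small_heterogeneity_keeps_eud_near_prescription(self):
        d = make_uniform_dvh(2.25, heterogeneity_sd=0.05, seed=1)
        assert 2.2 <= eud(d) <= 2.3

    def test_two_seeds_differ_but_agree_in_mean(self):
        a = make_uniform_dvh(3.0, 0.1, seed=1)
        b = make_uniform_dvh(3.0, 0.1, seed=2)
        assert not (
            a.n_bins == b.n_bins and np.array_equal(a.bin_fraction, b.bin_fraction)
        )
        se = 0.1 / np.sqrt(20_000)
        assert abs(a.mean_dose - b.mean_dose) < 6 * se

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            make_uniform_dvh(0.0)
        with pytest.raises(ValueError):
            make_uniform_dvh(3.0, heterogeneity_sd=-0.1)


class TestGridDVH:
    def test_single_sphere_constant_profile_is_uniform(self):
        d = dvh_from_grid(SphericalGridSpec(radii=(2.0,), shell_doses=(4.0,)))
        assert d.n_bins == 1

    def test_shell_fractions_approach_analytic_ratios(self):
        d = dvh_from_grid(SphericalGridSpec(grid_spacing=0.1))
        np.testing.assert_allclose(
            d.bin_fraction, [19 / 27, 7 / 27, 1 / 27], rtol=0.02
        )

    def test_refining_grid_reduces_fraction_error(self):
        errs = []
        for h in (0.4, 0.2, 0.1):
            d = dvh_from_grid(SphericalGridSpec(grid_spacing=h))
            errs.append(
                np.abs(d.bin_fraction - np.array([19, 7, 1]) / 27).max()
            )
        assert errs[0] > errs[1] > errs[2]

    def test_agrees_with_mixture_generator(self):
        grid = dvh_from_grid(SphericalGridSpec(grid_spacing=0.1))
        mixture = make_stepwise_dvh(
            StepwisePlanSpec(
                shell_fractions=(19 / 27, 7 / 27, 1 / 27),
                transition_width=0,
                noise_sd=0,
            )
        )
        np.testing.assert_allclose(grid.bin_fraction, mixture.bin_fraction, atol=0.02)
        assert grid.mean_dose == pytest.approx(mixture.mean_dose, abs=0.15)

    def test_invalid_radii(self):
        with pytest.raises(ValueError, match="decreasing"):
            SphericalGridSpec(radii=(1.0, 2.0), shell_doses=(3.0, 9.0))


class TestSyntheticCohort:
    def test_cohort_size_and_positive_first_fraction_delta(self):
        cases = make_synthetic_cohort(29, seed=0)
        assert len(cases) == 29
        for case in cases:
            g = analyze_regimen(case.gradient)
            c = analyze_regimen(case.conventional)
            assert g.first_fraction_eqd2 > c.first_fraction_eqd2
            assert g.total_eqd2 > c.total_eqd2

    def test_deterministic_under_seed(self):
        a = make_synthetic_cohort(3, seed=1)
        b = make_synthetic_cohort(3, seed=1)
        for ca, cb in zip(a, b):
            assert ca.meta == cb.meta
            np.testing.assert_array_equal(
                ca.gradient.phases[0][0].bin_fraction,
                cb.gradient.phases[0][0].bin_fraction,
            )

    def test_schedules_and_doses_within_clinical_ranges(self):
        for case in make_synthetic_cohort(50, seed=2):
            k = case.meta["n_conventional"]
            assert 4 <= k <= 27
            assert case.gradient.n_fractions == k + 1
            assert case.conventional.n_fractions == k + 1
            assert 2.0 <= case.meta["outer_dose_gy"] <= 5.0
            assert case.meta["outer_dose_gy"] <= case.meta["intermediate_dose_gy"] <= 9.0
            assert case.meta["intermediate_dose_gy"] <= case.meta["inner_dose_gy"] <= 12.0

    def test_invalid_count(self):
        with pytest.raises(ValueError):
            make_synthetic_cohort(0)
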