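"""Unit tests for within-generation selection and the Breeder's response."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from irmsim.errors import InvalidInputError
from irmsim.generation_selection import (
    ExposureParams,
    FitnessCost,
    GeneticsParams,
    TraitDistribution,
    breeders_response,
    fitness_cost_differential,
    hatch_distribution,
    parental_pool,
    probabilistic_selection,
    truncation_intensity,
    truncation_selection,
)
from irmsim.resistance_scale import FieldCalibration, HillScale


def two_bin_toy() -> TraitDistribution:
    """The hand-arithmetic oracle: grid {0, 200}, half the cohort in each bin."""
    return TraitDistribution(
        grid=np.array([0.0, 200.0]),
        freq_female=np.array([0.5, 0.5]),
        freq_male=np.array([0.5, 0.5]),
        mean=100.0,
        sigma=100.0,
    )


class TestHatchDistribution:
    def test_mean_matches_to_discretisation_tolerance(self):
        dist = hatch_distribution(100.0, 30.0, n_bins=2001, total=1.0)
        got = float((dist.freq_female * dist.grid).sum() / dist.n_female)
        assert got == pytest.approx(100.0, abs=1e-6 * 30.0)

    def test_each_sex_holds_half_the_cohort(self):
        dist = hatch_distribution(50.0, 20.0, total=1.0)
        assert dist.n_female == pytest.approx(0.5, rel=1e-12)
        assert dist.n_male == pytest.approx(0.5, rel=1e-12)

    def test_grid_refinement_convergence(self):
        coarse = hatch_distribution(100.0, 30.0, n_bins=2001)
        fine = hatch_distribution(100.0, 30.0, n_bins=4001)
        mean = lambda d: float((d.freq_female * d.grid).sum() / d.n_female)
        assert abs(mean(fine) - mean(coarse)) < 1e-8

    def test_rejects_tiny_grids_and_bad_sigma(self):
        with pytest.raises(InvalidInputError):
            hatch_distribution(0.0, 30.0, n_bins=10)
        with pytest.raises(InvalidInputError):
            hatch_distribution(0.0, 0.0)


class TestTruncationIntensity:
    @pytest.mark.parametrize(
        "p, expected",
        [
            (1.0, 0.0),
            (0.5, np.sqrt(2.0 / np.pi)),  # closed form at the median
            (0.1, 1.7549833),  # phi(1.28155) / 0.1
        ],
    )
    def test_reference_values(self, p, expected):
        assert truncation_intensity(p) == pytest.approx(expected, rel=1e-6)

    def test_all_dead_is_an_error(self):
        with pytest.raises(InvalidInputError):
            truncation_intensity(0.0)

    @pytest.mark.parametrize("p", [0.1, 0.5])
    def test_monte_carlo_truncated_normal_oracle(self, p, rng):
        draws = rng.standard_normal(1_000_000)
        survivors = draws[draws >= stats.norm.isf(p)]
        se = survivors.std(ddof=1) / np.sqrt(len(survivors))
        assert truncation_intensity(p) == pytest.approx(survivors.mean(), abs=3 * se)


class TestTruncationSelection:
    def test_full_survival_is_no_selection(self, exposure):
        cohort = truncation_selection(100.0, 30.0, 1.0, exposure, 0.5, 0.5)
        assert cohort.z_e_female == 100.0
        assert cohort.n_e_female == pytest.approx(exposure.x * 0.5)

    def test_survivor_mean_shift(self):
        expo = ExposureParams(x=1.0, m=1.0)
        cohort = truncation_selection(100.0, 30.0, 0.5, expo, 0.5, 0.5)
        assert cohort.z_e_female == pytest.approx(100.0 + 30.0 * np.sqrt(2 / np.pi), rel=1e-9)

    def test_mixture_partner_thins_counts(self):
        expo = ExposureParams(x=1.0, m=1.0)
        cohort = truncation_selection(100.0, 30.0, 0.5, expo, 1000.0, 1000.0, mixture_survival_j=0.4)
        assert cohort.n_e_female == pytest.approx(200.0)


class TestProbabilisticSelection:
    def test_two_bin_toy_oracle(self, scale, cal):
        cohort = probabilistic_selection(
            two_bin_toy(), scale, cal, 1.0, ExposureParams(x=1.0, m=1.0)
        )
        # K_F(0)=0.15, K_F(200)=0.48*(200/1100)+0.15
        assert cohort.n_e_female == pytest.approx(0.193636, abs=1e-5)
        assert cohort.z_e_female == pytest.approx(122.535, abs=1e-2)

    def test_constant_survival_means_no_selection(self, cal, newborns, exposure):
        # omega=0: survival 1 everywhere, so the survivor mean equals the cohort mean
        cohort = probabilistic_selection(newborns, HillScale(), cal, 0.0, exposure)
        assert cohort.z_e_female == pytest.approx(newborns.mean, abs=1e-6 * newborns.sigma)


class TestParentalPool:
    def test_two_bin_toy_continuation(self, scale, cal):
        expo = ExposureParams(x=0.5, m=0.5)
        cohort = probabilistic_selection(two_bin_toy(), scale, cal, 1.0, expo)
        out = parental_pool(cohort, 100.0, expo, n_total_female=1.0, n_total_male=1.0)
        assert cohort.n_e_female == pytest.approx(0.096818, abs=1e-5)
        assert out.z_p_female == pytest.approx(103.657, abs=1e-2)
        assert out.s_insecticide_female == pytest.approx(3.657, abs=1e-2)

    def test_no_exposure_means_no_differential(self, newborns):
        expo = ExposureParams(x=0.0, m=0.5)
        cohort = probabilistic_selection(newborns, HillScale(), FieldCalibration(), 1.0, expo)
        out = parental_pool(cohort, newborns.mean, expo)
        assert out.s_insecticide_female == 0.0

    def test_unexposed_males_have_no_differential(self, newborns):
        expo = ExposureParams(x=0.9, m=0.0)
        cohort = probabilistic_selection(newborns, HillScale(), FieldCalibration(), 1.0, expo)
        out = parental_pool(cohort, newborns.mean, expo)
        assert out.s_insecticide_male == 0.0
        assert out.s_insecticide_female > 0.0

    @given(
        st.floats(min_value=0.0, max_value=1.0),
        st.floats(min_value=0.0, max_value=1.0),
        st.floats(min_value=0.05, max_value=1.0),
    )
    def test_parent_count_conservation(self, x, m, omega):
        expo = ExposureParams(x=x, m=m)
        dist = hatch_distribution(80.0, 25.0, n_bins=501)
        cohort = probabilistic_selection(dist, HillScale(), FieldCalibration(), omega, expo)
        out = parental_pool(cohort, dist.mean, expo)
        assert out.n_p_female == pytest.approx(out.n_e_female + out.n_u_female, rel=1e-12)
        assert out.n_p_male == pytest.approx(out.n_e_male + out.n_u_male, rel=1e-12)

    def test_differential_non_negative_when_survival_increases_with_resistance(self, newborns):
        expo = ExposureParams(x=0.6, m=0.4)
        cohort = probabilistic_selection(newborns, HillScale(), FieldCalibration(), 1.0, expo)
        out = parental_pool(cohort, newborns.mean, expo)
        assert out.s_insecticide_female >= 0.0
        assert out.s_insecticide_male >= 0.0


class TestFitnessAndResponse:
    @pytest.mark.parametrize(
        "cost, sigma, expected",
        [
            (FitnessCost("fixed", 0.0, 0.0), 30.0, (0.0, 0.0)),
            (FitnessCost("scaled", 0.01, 0.02), 30.0, (-0.3, -0.6)),
            (FitnessCost("fixed", 0.2, 0.1), 30.0, (-0.2, -0.1)),
        ],
    )
    def test_fitness_cost_sign_and_magnitude(self, cost, sigma, expected):
        assert fitness_cost_differential(cost, sigma) == pytest.approx(expected)

    def test_breeders_equation_arithmetic(self):
        assert breeders_response(0.3, 0.1, GeneticsParams(h2=0.2, beta=1.0)) == pytest.approx(0.04)
        assert breeders_response(0.3, 0.1, GeneticsParams(h2=0.2, beta=2.0)) == pytest.approx(0.08)

    @given(st.floats(min_value=-10, max_value=10), st.floats(min_value=-10, max_value=10))
    def test_zero_heritability_freezes_evolution(self, s_f, s_m):
        assert breeders_response(s_f, s_m, GeneticsParams(h2=0.0, beta=5.0)) == 0.0
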