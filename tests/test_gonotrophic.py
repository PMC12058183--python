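"""Unit tests for the multi-gonotrophic-cycle machinery and age profiles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from irmsim.errors import ConfigurationError
from irmsim.generation_selection import (
    ExposureParams,
    GeneticsParams,
    hatch_distribution,
    parental_pool,
    probabilistic_selection,
)
from irmsim.gonotrophic import (
    CoverageModel,
    CycleParams,
    age_profile_snapshot,
    encounter_partition,
    initial_cycle_state,
    male_selection_complex,
    multi_cycle_response,
    natural_survival,
    run_female_cycles,
)
from irmsim.resistance_scale import FieldCalibration, HillScale, bioassay_survival, field_survival


def survival_on(grid, omega=1.0):
    return field_survival(bioassay_survival(grid, HillScale()), omega, FieldCalibration())


class TestNaturalSurvival:
    @pytest.mark.parametrize(
        "d, g, expected", [(1.0, 3, 1.0), (0.9, 3, 0.729), (0.8, 3, 0.512), (0.5, 0, 1.0)]
    )
    def test_power_law(self, d, g, expected):
        assert natural_survival(d, g) == pytest.approx(expected)

    def test_cycle_params_rho(self):
        assert CycleParams(d=0.9, g=3, gmax=5).rho == pytest.approx(0.729)


class TestEncounterPartition:
    def test_single_insecticide_is_de_facto_monotherapy(self):
        p = encounter_partition(CoverageModel(c_i=1.0), 0.7)
        assert p == pytest.approx({"i": 0.7, "j": 0.0, "both": 0.0, "none": 0.3})

    def test_dual_treated_houses_with_joint_contact_are_a_de_facto_mixture(self):
        p = encounter_partition(CoverageModel.mixture(), 0.7)
        assert p == pytest.approx({"i": 0.0, "j": 0.0, "both": 0.7, "none": 0.3})

    def test_micro_mosaic_split(self):
        p = encounter_partition(CoverageModel.mosaic(0.5), 0.7)
        assert p == pytest.approx({"i": 0.35, "j": 0.35, "both": 0.0, "none": 0.3})

    @given(
        st.floats(min_value=0, max_value=1),
        st.floats(min_value=0, max_value=1),
        st.floats(min_value=0, max_value=1),
        st.floats(min_value=0, max_value=1),
    )
    def test_partition_sums_to_one(self, a, b, lam_a, x):
        c_i = a
        c_j = (1 - a) * b
        c_ij = 1 - c_i - c_j
        cov = CoverageModel(
            c_i=c_i, c_j=c_j, c_ij=c_ij, lambda_female=(lam_a, 0.0, 1 - lam_a)
        )
        p = encounter_partition(cov, x)
        assert sum(p.values()) == pytest.approx(1.0, abs=1e-9)

    def test_invalid_coverage_rejected(self):
        with pytest.raises(ConfigurationError):
            CoverageModel(c_i=0.7, c_j=0.7, c_ij=0.0)
        with pytest.raises(ConfigurationError):
            CoverageModel(c_i=1.0, lambda_female=(0.5, 0.1, 0.1))


class TestCycleStep:
    def test_no_exposure_leaves_cohort_untouched(self):
        dist = hatch_distribution(100.0, 30.0, n_bins=501)
        states = run_female_cycles(
            dist, survival_on(dist.grid), 1.0, CoverageModel.monotherapy(), 0.0, 1.0, 3
        )
        for s in states:
            assert s.z_p == pytest.approx(100.0, abs=1e-6 * 30.0)
            assert s.n_p == pytest.approx(dist.n_female, rel=1e-12)

    def test_single_cycle_equals_probabilistic_branch_exactly(self, exposure):
        dist = hatch_distribution(50.0, 30.0, n_bins=2001)
        kf = survival_on(dist.grid, omega=0.8)
        states = run_female_cycles(
            dist, kf, 1.0, CoverageModel.monotherapy(), exposure.x, 1.0, 1
        )
        cohort = probabilistic_selection(dist, HillScale(), FieldCalibration(), 0.8, exposure)
        out = parental_pool(cohort, dist.mean, exposure)
        assert states[0].z_p == pytest.approx(out.z_p_female, abs=1e-10)
        assert states[0].n_p == pytest.approx(out.n_p_female, abs=1e-12)

    def test_bookkeeping_identity_holds_each_cycle(self):
        dist = hatch_distribution(80.0, 30.0, n_bins=1001)
        cov = CoverageModel(c_i=0.4, c_j=0.4, c_ij=0.2, lambda_female=(0.3, 0.3, 0.4))
        states = run_female_cycles(dist, survival_on(dist.grid), 0.6, cov, 0.7, 0.729, 5)
        assert len(states) == 5
        for s in states:
            total = s.n_i_e + s.n_j_e + s.n_ij_e + s.n_u
            assert s.n_p == pytest.approx(total, rel=1e-12)
            assert s.n_p == pytest.approx(float(s.freq.sum()), rel=1e-10)

    def test_rho_scales_counts_but_not_means(self):
        dist = hatch_distribution(60.0, 30.0, n_bins=1001)
        kf = survival_on(dist.grid)
        cov = CoverageModel.monotherapy()
        full = run_female_cycles(dist, kf, 1.0, cov, 0.7, 1.0, 3)
        half = run_female_cycles(dist, kf, 1.0, cov, 0.7, 0.5, 3)
        for g, (a, b) in enumerate(zip(full, half)):
            assert b.z_p == pytest.approx(a.z_p, rel=1e-12)
            assert b.n_p == pytest.approx(a.n_p * 0.5**g, rel=1e-10)

    def test_parental_mean_non_decreasing_across_cycles(self):
        dist = hatch_distribution(100.0, 30.0, n_bins=1001)
        states = run_female_cycles(
            dist, survival_on(dist.grid), 1.0, CoverageModel.monotherapy(), 0.7, 0.729, 5
        )
        means = [dist.mean] + [s.z_p for s in states]
        assert all(b >= a - 1e-9 for a, b in zip(means, means[1:]))


class TestMaleSelection:
    def test_unexposed_males_have_zero_differential(self):
        dist = hatch_distribution(100.0, 30.0, n_bins=501)
        s = male_selection_complex(
            CoverageModel.monotherapy(),
            dist,
            ExposureParams(x=0.7, m=0.0),
            survival_on(dist.grid),
        )
        assert s == pytest.approx(0.0, abs=1e-9)

    def test_de_facto_mixture_equals_mixture_male_differential(self, exposure):
        dist = hatch_distribution(70.0, 30.0, n_bins=2001)
        kf = survival_on(dist.grid)
        kbar_j = 0.3
        s_complex = male_selection_complex(CoverageModel.mixture(), dist, exposure, kf, kbar_j)
        cohort = probabilistic_selection(
            dist, HillScale(), FieldCalibration(), 1.0, exposure, mixture_survival_j=kbar_j
        )
        out = parental_pool(cohort, dist.mean, exposure)
        assert s_complex == pytest.approx(out.s_insecticide_male, abs=1e-10)


class TestMultiCycleResponse:
    def _states(self, gmax, rho=0.729, x=0.7):
        dist = hatch_distribution(100.0, 30.0, n_bins=1001)
        return dist, run_female_cycles(
            dist, survival_on(dist.grid), 1.0, CoverageModel.monotherapy(), x, rho, gmax
        )

    def test_single_cycle_reduces_to_one_term(self):
        dist, states = self._states(1)
        res = multi_cycle_response(states, 0.5, GeneticsParams(0.2, 1.0), -0.1, -0.1, dist.mean)
        expected = 0.2 * ((states[0].z_p - dist.mean - 0.1) + (0.5 - 0.1)) / 2
        assert res.total == pytest.approx(expected, rel=1e-12)

    def test_constant_per_cycle_response_passes_through(self):
        dist, states = self._states(3, x=0.0)  # no exposure: all cycle responses equal
        res = multi_cycle_response(states, 0.0, GeneticsParams(0.2, 1.0), -0.2, -0.2, dist.mean)
        assert res.total == pytest.approx(res.per_cycle[0], rel=1e-6)

    def test_oviposition_weighting_arithmetic(self):
        # two cycles with responses 0.1 (80 layers) and 0.3 (20 layers)
        total = (0.1 * 80 + 0.3 * 20) / 100
        assert total == pytest.approx(0.14)
        dist, states = self._states(2)
        res = multi_cycle_response(states, 0.0, GeneticsParams(0.2, 1.0), 0.0, 0.0, dist.mean)
        manual = sum(r * w for r, w in zip(res.per_cycle, res.weights))
        assert res.total == pytest.approx(manual, rel=1e-12)


class TestAgeProfile:
    def _profile(self, omega=1.0, x=0.7, kbar_j=1.0, cov=None, mean=0.0):
        dist = hatch_distribution(mean, 30.0, n_bins=1001, total=2.0)
        kf = survival_on(dist.grid, omega)
        return age_profile_snapshot(
            dist, kf, kbar_j, cov or CoverageModel.monotherapy(), x,
            CycleParams(d=0.9, g=3, gmax=10), baseline_n=100_000.0, gmax=10,
        )

    def test_no_intervention_profile_is_geometric(self):
        profile = self._profile(x=0.0)
        np.testing.assert_allclose(profile.no_intervention, 100_000.0 * 0.729 ** np.arange(10))
        np.testing.assert_allclose(profile.with_intervention, profile.no_intervention, rtol=1e-9)

    def test_intervention_dominated_by_no_intervention(self):
        profile = self._profile(omega=1.0, x=0.7)
        assert np.all(profile.with_intervention <= profile.no_intervention + 1e-6)
        assert np.all(profile.with_intervention > 0.0)

    def test_full_dose_mixture_suppresses_at_least_as_much_as_half_dose(self):
        mean = 100.0  # 10% bioassay cohort, equal resistance to both partners
        kbar = lambda omega: field_survival(bioassay_survival(mean, HillScale()), omega)
        full = self._profile(omega=1.0, cov=CoverageModel.mixture(), kbar_j=kbar(1.0), mean=mean)
        half = self._profile(omega=0.5, cov=CoverageModel.mixture(), kbar_j=kbar(0.5), mean=mean)
        assert np.all(full.with_intervention <= half.with_intervention + 1e-9)

    def test_surviving_at_least_counts(self):
        profile = self._profile()
        with_int, no_int = profile.surviving_at_least(4)
        assert with_int < no_int
        assert no_int == pytest.approx(profile.no_intervention[3:].sum())
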