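"""Unit tests for deployment planning and the generation loop."""

import numpy as np
import pytest

from irmsim.config import ScenarioConfig, StrategyConfig
from irmsim.errors import ConfigurationError
from irmsim.experiments import comparison_scenario
from irmsim.resistance_scale import DecayProfile, HillScale, Insecticide
from irmsim.strategy_engine import (
    Trajectory,
    plan_deployment,
    run_simulation,
    simulation_duration,
)

PARAMS = {
    "x": 0.7,
    "m": 0.5,
    "h2": 0.2,
    "coverage": 0.8,
    "theta": 0.2,
    "fitness_female": 0.1,
    "fitness_male": 0.1,
}


def strategy(kind="sequence", **kw) -> StrategyConfig:
    defaults = dict(arsenal=("a", "b"), deployment_interval=10, generation_cap=100)
    defaults.update(kw)
    return StrategyConfig(kind=kind, **defaults)


class TestPlanDeployment:
    def test_sequence_starts_with_first_in_arsenal(self):
        plan = plan_deployment(0, {"a": 0.0, "b": 0.0}, strategy(), frozenset(), None)
        assert plan.deployment.active == ("a",)

    def test_sequence_moves_on_only_after_failure(self):
        strat = strategy()
        plan = plan_deployment(10, {"a": 0.05, "b": 0.0}, strat, frozenset(), "a")
        assert plan.deployment.active == ("a",)
        plan = plan_deployment(20, {"a": 0.12, "b": 0.0}, strat, frozenset(), "a")
        assert plan.deployment.active == ("b",)

    def test_rotation_switches_every_interval_and_skips_failed(self):
        strat = strategy("rotation")
        plan = plan_deployment(10, {"a": 0.12, "b": 0.03}, strat, frozenset(), "a")
        assert plan.deployment.active == ("b",)
        # a stays ineligible at 9% (between return and withdrawal)
        plan = plan_deployment(20, {"a": 0.09, "b": 0.03}, strat, plan.failed, "b")
        assert plan.deployment.active == ("b",)
        # and returns once below the 8% return threshold
        plan = plan_deployment(30, {"a": 0.07, "b": 0.03}, strat, plan.failed, "b")
        assert plan.deployment.active == ("a",)

    def test_no_option_signal_when_all_failed(self):
        plan = plan_deployment(10, {"a": 0.12, "b": 0.15}, strategy("rotation"), frozenset(), "a")
        assert plan.deployment is None

    def test_exhaustion_requires_dropping_below_return_not_withdrawal(self):
        # hysteresis: 9% is below withdrawal but a previously failed product stays out
        failed = frozenset({"a", "b"})
        plan = plan_deployment(10, {"a": 0.09, "b": 0.09}, strategy("rotation"), failed, None)
        assert plan.deployment is None

    def test_mixture_deploys_pair_until_total_exhaustion(self):
        strat = strategy("mixture")
        plan = plan_deployment(0, {"a": 0.12, "b": 0.02}, strat, frozenset(), None)
        assert plan.deployment.active == ("a", "b")
        plan = plan_deployment(10, {"a": 0.12, "b": 0.12}, strat, plan.failed, None)
        assert plan.deployment is None


class TestRunSimulation:
    def test_zero_beta_freezes_resistance_and_runs_to_cap(self):
        cfg = comparison_scenario(PARAMS, "sequence", beta=0.0, generation_cap=60)
        traj = run_simulation(cfg, branch="polysmooth")
        assert traj.termination == "cap"
        frame = traj.to_frame()
        assert frame["mean_prs"].max() == 0.0

    def test_deployments_only_change_at_interval_boundaries(self):
        cfg = comparison_scenario(PARAMS, "rotation", beta=50.0, generation_cap=60)
        traj = run_simulation(cfg, branch="polysmooth")
        frame = traj.to_frame()
        active = (
            frame[(frame.site == "intervention") & frame.deployed_flag]
            .groupby("generation")["trait"]
            .first()
        )
        changes = [g for g, (prev, cur) in enumerate(zip(active, active[1:]), start=2) if prev != cur]
        assert changes, "rotation never rotated"
        assert all((g - 1) % 10 == 0 for g in changes)

    def test_efficacy_sawtooth_resets_at_redeployment(self):
        insecticides = [
            Insecticide("i", HillScale(), DecayProfile(omega0=1.0, delta_b=0.015, tau_b=50.0)),
            Insecticide("j", HillScale(), DecayProfile(omega0=1.0, delta_b=0.015, tau_b=50.0)),
        ]
        cfg = comparison_scenario(PARAMS, "sequence", beta=0.0, generation_cap=25)
        cfg.insecticides = insecticides
        traj = run_simulation(cfg, branch="polysmooth")
        frame = traj.to_frame()
        eff = frame[(frame.site == "intervention") & frame.deployed_flag].set_index("generation")[
            "efficacy"
        ]
        # freshly deployed at generations 1, 11, 21 (tau=0 when selection ran)
        for g in (1, 11, 21):
            assert eff.loc[g] == pytest.approx(1.0)
        assert eff.loc[10] == pytest.approx(np.exp(-(9**2) * 0.015), rel=1e-9)

    def test_sequence_terminates_when_arsenal_exhausted(self):
        # no fitness costs, so a failed insecticide cannot recover below the
        # return threshold and the arsenal genuinely runs out
        params = dict(PARAMS, fitness_female=0.0, fitness_male=0.0)
        cfg = comparison_scenario(params, "sequence", beta=200.0, generation_cap=500)
        traj = run_simulation(cfg, branch="polysmooth")
        assert traj.termination == "exhausted"
        assert set(traj.failure_generations) == {"i", "j"}
        assert traj.n_generations < 500

    def test_truncation_branch_rejects_multi_cycle_and_mosaics(self):
        cfg = comparison_scenario(PARAMS, "sequence", beta=1.0)
        with pytest.raises(ConfigurationError):
            run_simulation(cfg, branch="polytruncate", cycles="multi")
        mosaic = comparison_scenario(PARAMS, "micro_mosaic", beta=1.0)
        with pytest.raises(ConfigurationError):
            run_simulation(mosaic, branch="polytruncate")
        with pytest.raises(ConfigurationError):
            run_simulation(cfg, branch="nope")

    def test_site_means_never_negative_under_heavy_costs(self):
        heavy = dict(PARAMS, fitness_female=0.58, fitness_male=0.58)
        cfg = comparison_scenario(heavy, "sequence", beta=80.0, generation_cap=80)
        traj = run_simulation(cfg, branch="polysmooth")
        assert traj.to_frame()["mean_prs"].min() >= 0.0


class TestDuration:
    def test_cap_is_fifty_years_at_default_rates(self):
        traj = Trajectory(n_generations=500, generations_per_year=10)
        assert simulation_duration(traj) == 50.0

    def test_early_termination_years(self):
        traj = Trajectory(n_generations=100, generations_per_year=10)
        assert simulation_duration(traj) == 10.0

    def test_empty_trajectory_has_zero_duration(self):
        assert simulation_duration(Trajectory()) == 0.0
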