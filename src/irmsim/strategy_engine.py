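"""Deployment scheduling and the generation loop.

This is the driver tying the other modules together.  Each generation, in
order: deployment decisions are (re)taken at interval boundaries using the
withdrawal/return bioassay thresholds; insecticide efficacies are read off
the decay curves at the per-product time-since-deployment clocks; selection
runs in the intervention site (truncation or probabilistic branch; single or
multiple gonotrophic cycles); responses -- direct, fitness-cost and
cross-resistance-correlated -- update both site means; and females disperse
between the sites.  A run ends when no insecticide in the arsenal is
deployable (all have failed) or at the generation cap, and its duration in
years is the operational lifespan of the strategy.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import generation_selection as gs
from . import gonotrophic as gc
from . import landscape as ls
from . import resistance_scale as rs
from .config import ScenarioConfig, StrategyConfig
from .errors import CohortExtinctSignal, ConfigurationError, DegenerateCohortError

logger = logging.getLogger(__name__)

__all__ = [
    "StrategyConfig",
    "Deployment",
    "PlanResult",
    "Trajectory",
    "plan_deployment",
    "run_simulation",
    "run_until_threshold",
    "simulation_duration",
]

BRANCHES = ("polysmooth", "polytruncate")
CYCLE_MODES = ("single", "multi")


@dataclass(frozen=True)
class Deployment:
    """The set of insecticides active in the intervention site."""

    kind: str
    active: tuple[str, ...]


@dataclass
class PlanResult:
    deployment: Deployment | None
    failed: frozenset[str]
    current: str | None


def _update_failed(
    failed: frozenset[str], bioassay: dict[str, float], strategy: StrategyConfig
) -> frozenset[str]:
    """Hysteresis bookkeeping: fail at/above withdrawal, return below return."""
    out = set(failed)
    for trait, b in bioassay.items():
        if b >= strategy.withdrawal_threshold:
            out.add(trait)
        elif trait in out and b < strategy.return_threshold:
            out.discard(trait)
    return frozenset(out)


def plan_deployment(
    gen: int,
    bioassay: dict[str, float],
    strategy: StrategyConfig,
    failed: frozenset[str],
    current: str | None,
) -> PlanResult:
    """Deployment decision at a decision point.

    ``bioassay`` maps each arsenal insecticide to the current bioassay
    survival implied by the intervention-site female mean.  Returns the new
    deployment (None = the no-option signal: every insecticide has failed),
    the updated failed set, and the current monotherapy product.
    """
    failed = _update_failed(failed, bioassay, strategy)
    arsenal = list(strategy.arsenal)
    available = [a for a in arsenal if a not in failed]

    if strategy.kind == "continuous":
        pick = arsenal[0]
        return PlanResult(Deployment("continuous", (pick,)), failed, pick)

    if strategy.kind in ("mixture", "micro_mosaic", "combination"):
        if not available:
            return PlanResult(None, failed, None)
        pair = tuple(arsenal[:2])
        return PlanResult(Deployment(strategy.kind, pair), failed, None)

    if strategy.kind == "sequence":
        if current is not None and current not in failed:
            pick = current
        elif available:
            pick = available[0]
        else:
            return PlanResult(None, failed, None)
        return PlanResult(Deployment("sequence", (pick,)), failed, pick)

    if strategy.kind == "rotation":
        if not available:
            return PlanResult(None, failed, None)
        if current is None or current not in arsenal:
            pick = available[0]
        else:
            idx = arsenal.index(current)
            order = arsenal[idx + 1 :] + arsenal[: idx + 1]  # current considered last
            pick = next(a for a in order if a not in failed)
        return PlanResult(Deployment("rotation", (pick,)), failed, pick)

    raise ConfigurationError(f"unknown strategy kind {strategy.kind!r}")


@dataclass
class Trajectory:
    """Per-generation record of a simulation run."""

    records: list[dict] = field(default_factory=list)
    termination: str = "cap"
    n_generations: int = 0
    generations_per_year: int = 10
    failure_generations: dict[str, int] = field(default_factory=dict)

    @property
    def duration_years(self) -> float:
        return self.n_generations / self.generations_per_year

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.records,
            columns=[
                "generation",
                "trait",
                "site",
                "mean_prs",
                "bioassay_survival",
                "deployed_flag",
                "efficacy",
            ],
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def first_crossing(self, threshold: float, trait: str | None = None) -> int | None:
        """First generation whose end-of-generation intervention bioassay
        survival reaches ``threshold`` (for ``trait``, or any trait)."""
        for rec in self.records:
            if rec["site"] != "intervention":
                continue
            if trait is not None and rec["trait"] != trait:
                continue
            if rec["bioassay_survival"] >= threshold:
                return rec["generation"]
        return None

    def summary(self) -> dict:
        return {
            "termination": self.termination,
            "n_generations": self.n_generations,
            "duration_years": self.duration_years,
            "failure_generations": dict(self.failure_generations),
        }


def simulation_duration(traj: Trajectory) -> float:
    """Operational lifespan in years (generations / generations-per-year)."""
    return traj.duration_years


# --- per-generation selection ------------------------------------------------


def _mean_field_survival(
    cfg: ScenarioConfig, trait: str, z_mean: float, sigma: float, omega: float
) -> float:
    """Population survival summary used for the truncation point and for the
    mixture-partner factor.

    By default this is the field survival evaluated *at the mean PRS* of the
    population; the ``mean_survival_integrated`` flag switches to the
    expectation of survival over the Normal trait distribution (a sensitivity
    alternative).
    """
    scale = cfg.insecticide(trait).scale
    if not cfg.mean_survival_integrated:
        return float(rs.field_survival(rs.bioassay_survival(z_mean, scale), omega, cfg.field_cal))
    dist = gs.hatch_distribution(z_mean, sigma, n_bins=max(cfg.n_bins, 201), total=1.0)
    k = rs.field_survival(rs.bioassay_survival(dist.grid, scale), omega, cfg.field_cal)
    weights = dist.freq_female / dist.n_female
    return float((k * weights).sum())


def _swap_coverage(cov: gc.CoverageModel) -> gc.CoverageModel:
    """Coverage model seen from the second product's perspective."""
    lf, lm = cov.lambda_female, cov.lambda_male
    return gc.CoverageModel(
        c_i=cov.c_j,
        c_j=cov.c_i,
        c_ij=cov.c_ij,
        lambda_female=(lf[1], lf[0], lf[2]),
        lambda_male=(lm[1], lm[0], lm[2]),
    )


def _coverage_for(cfg: ScenarioConfig, deployment: Deployment) -> gc.CoverageModel:
    if deployment.kind in ("continuous", "sequence", "rotation"):
        return gc.CoverageModel.monotherapy()
    if deployment.kind == "mixture":
        return gc.CoverageModel.mixture()
    if deployment.kind == "micro_mosaic":
        return cfg.coverage_model or gc.CoverageModel.mosaic(0.5)
    if deployment.kind == "combination":
        if cfg.coverage_model is None:
            raise ConfigurationError("combination deployments need an explicit coverage_model")
        return cfg.coverage_model
    raise ConfigurationError(f"unknown deployment kind {deployment.kind!r}")


def _truncation_responses(
    cfg: ScenarioConfig,
    deployment: Deployment | None,
    means_int: dict[str, float],
    sigmas_int: dict[str, float],
    omegas: dict[str, float],
) -> dict[str, ls.ResponseRecord]:
    """Direct responses per trait under the truncation branch (single cycle)."""
    active = deployment.active if deployment else ()
    kbar = {
        t: _mean_field_survival(cfg, t, means_int[t], sigmas_int[t], omegas[t]) for t in active
    }
    responses: dict[str, ls.ResponseRecord] = {}
    for trait in cfg.trait_ids:
        sigma = sigmas_int[trait]
        s_phi_f, s_phi_m = gs.fitness_cost_differential(cfg.fitness, sigma)
        genetics = cfg.genetics_for(trait)
        if trait not in active:
            responses[trait] = ls.ResponseRecord(
                response=gs.breeders_response(s_phi_f, s_phi_m, genetics), deployed=False
            )
            continue
        partner = math.prod(kbar[o] for o in active if o != trait) if len(active) > 1 else None
        try:
            cohort = gs.truncation_selection(
                means_int[trait],
                sigma,
                kbar[trait],
                cfg.exposure,
                mixture_survival_j=partner,
            )
            outcome = gs.parental_pool(cohort, means_int[trait], cfg.exposure)
            s_f = outcome.s_insecticide_female + s_phi_f
            s_m = outcome.s_insecticide_male + s_phi_m
        except (DegenerateCohortError, gs.InvalidInputError):
            logger.warning(
                "trait %s: all exposed mosquitoes died; only unexposed parents remain", trait
            )
            s_f, s_m = s_phi_f, s_phi_m
        responses[trait] = ls.ResponseRecord(
            response=gs.breeders_response(s_f, s_m, genetics), deployed=True
        )
    return responses


def _polysmooth_responses(
    cfg: ScenarioConfig,
    deployment: Deployment | None,
    means_int: dict[str, float],
    sigmas_int: dict[str, float],
    omegas: dict[str, float],
    gmax: int,
    rho: float,
) -> dict[str, float]:
    """Total per-trait responses (cross resistance included) for polysmooth.

    Deployed traits run the female gonotrophic-cycle machinery plus the
    single-round male selection; per-cycle responses are combined with the
    oviposition weights, adding the partner's correlated per-cycle responses.
    Undeployed traits receive the fitness-cost response plus the deployed
    traits' correlated totals.
    """
    active = tuple(deployment.active) if deployment else ()
    cov = _coverage_for(cfg, deployment) if deployment else None

    per_trait_raw: dict[str, gc.MultiCycleResult] = {}
    phi_terms: dict[str, tuple[float, float]] = {}
    for trait in cfg.trait_ids:
        phi_terms[trait] = gs.fitness_cost_differential(cfg.fitness, sigmas_int[trait])

    for pos, trait in enumerate(active):
        scale = cfg.insecticide(trait).scale
        sigma = sigmas_int[trait]
        dist = gs.hatch_distribution(means_int[trait], sigma, n_bins=cfg.n_bins, total=1.0)
        k_field = rs.field_survival(
            rs.bioassay_survival(dist.grid, scale), omegas[trait], cfg.field_cal
        )
        partners = [o for o in active if o != trait]
        kbar_j = math.prod(
            _mean_field_survival(cfg, o, means_int[o], sigmas_int[o], omegas[o]) for o in partners
        ) if partners else 1.0
        trait_cov = cov if pos == 0 else _swap_coverage(cov)
        s_phi_f, s_phi_m = phi_terms[trait]
        try:
            states = gc.run_female_cycles(
                dist, k_field, kbar_j, trait_cov, cfg.exposure.x, rho, gmax
            )
            s_male = gc.male_selection_complex(trait_cov, dist, cfg.exposure, k_field, kbar_j)
            per_trait_raw[trait] = gc.multi_cycle_response(
                states,
                s_male,
                cfg.genetics_for(trait),
                s_phi_f,
                s_phi_m,
                z_hatch=means_int[trait],
            )
        except (CohortExtinctSignal, DegenerateCohortError):
            logger.warning("trait %s: exposed cohort extinct; fitness-cost response only", trait)
            per_trait_raw[trait] = None

    totals: dict[str, float] = {}
    for trait in cfg.trait_ids:
        s_phi_f, s_phi_m = phi_terms[trait]
        genetics = cfg.genetics_for(trait)
        r_phi = gs.breeders_response(s_phi_f, s_phi_m, genetics)
        if trait in active and per_trait_raw.get(trait) is not None:
            res = per_trait_raw[trait]
            partners = [o for o in active if o != trait and per_trait_raw.get(o) is not None]
            total = 0.0
            for g, (r_g, w_g) in enumerate(zip(res.per_cycle, res.weights)):
                corr = sum(
                    cfg.cross.get(o, trait) * per_trait_raw[o].per_cycle[g]
                    for o in partners
                    if g < len(per_trait_raw[o].per_cycle)
                )
                total += (r_g + corr) * w_g
            totals[trait] = total
        else:
            total = r_phi
            for o in active:
                if o != trait and per_trait_raw.get(o) is not None:
                    res_o = per_trait_raw[o]
                    direct = sum(r * w for r, w in zip(res_o.per_cycle, res_o.weights))
                    total += cfg.cross.get(o, trait) * direct
            totals[trait] = total
    return totals


# --- main loop ----------------------------------------------------------------


def run_simulation(
    cfg: ScenarioConfig,
    branch: str = "polysmooth",
    cycles: str = "single",
    stop_at_bioassay: float | None = None,
) -> Trajectory:
    """Run the generation loop for a scenario.

    ``branch`` selects truncation ("polytruncate") or probabilistic
    ("polysmooth") insecticide selection; ``cycles`` selects a single
    gonotrophic cycle per generation or the multi-cycle extension (the
    latter is probabilistic-only).  ``stop_at_bioassay`` optionally stops the
    run as soon as any intervention-site trait reaches that bioassay
    survival (used by calibration and the sigma sweep).
    """
    if branch not in BRANCHES:
        raise ConfigurationError(f"branch must be one of {BRANCHES}, got {branch!r}")
    if cycles not in CYCLE_MODES:
        raise ConfigurationError(f"cycles must be one of {CYCLE_MODES}, got {cycles!r}")
    if branch == "polytruncate":
        if cycles == "multi":
            raise ConfigurationError(
                "multi-cycle selection is probabilistic-only: the truncation process "
                "is not defined once the within-generation distribution is non-Normal"
            )
        if cfg.strategy.kind in ("micro_mosaic", "combination"):
            raise ConfigurationError(
                f"the truncation branch does not support {cfg.strategy.kind} deployments"
            )

    strategy = cfg.strategy
    traits = cfg.trait_ids
    means_int = {t: cfg.initial_mean_for(t) for t in traits}
    means_ref = {t: cfg.initial_mean_for(t) for t in traits}
    failed: frozenset[str] = frozenset()
    current: str | None = None
    deployment: Deployment | None = None
    tau: dict[str, int] = {}
    failure_generations: dict[str, int] = {}

    traj = Trajectory(generations_per_year=strategy.generations_per_year)
    gmax = 1 if cycles == "single" else cfg.cycle.gmax
    rho = 1.0 if cycles == "single" else cfg.cycle.rho

    def bioassay_of(means: dict[str, float]) -> dict[str, float]:
        return {
            t: float(rs.bioassay_survival(means[t], cfg.insecticide(t).scale)) for t in traits
        }

    n_generations = 0
    termination = "cap"
    for gen in range(strategy.generation_cap):
        # 1. deployment decisions at interval boundaries (start of generation)
        decision_due = (
            gen % strategy.deployment_interval == 0
            or cfg.immediate_withdrawal
            or (
                strategy.kind == "combination"
                and any(gen % strategy.interval_for(p) == 0 for p in strategy.arsenal[:2])
            )
        )
        if decision_due:
            bio = {t: b for t, b in bioassay_of(means_int).items() if t in strategy.arsenal}
            before = failed
            plan = plan_deployment(gen, bio, strategy, failed, current)
            failed, current = plan.failed, plan.current
            for t in failed - before:
                failure_generations.setdefault(t, gen)
            prev_active = deployment.active if deployment else ()
            deployment = plan.deployment
            if deployment is None:
                termination = "exhausted"
                break
            for p in deployment.active:
                redeploy_boundary = gen % strategy.interval_for(p) == 0
                if p not in prev_active or redeploy_boundary:
                    tau[p] = 0

        # 2. efficacies from the per-product clocks
        omegas: dict[str, float] = {}
        if deployment is not None:
            for p in deployment.active:
                decay = cfg.insecticide(p).decay
                decay = decay.with_dose(strategy.dose_for(p, decay.omega0))
                omegas[p] = rs.efficacy_at(tau.get(p, 0), decay)

        # 3. selection and responses, intervention site
        sigmas_int = {t: rs.sigma_of_mean(means_int[t], cfg.sigma_model) for t in traits}
        sigmas_ref = {t: rs.sigma_of_mean(means_ref[t], cfg.sigma_model) for t in traits}
        if branch == "polytruncate":
            records = _truncation_responses(cfg, deployment, means_int, sigmas_int, omegas)
            means_int = ls.apply_responses(means_int, records, cfg.cross)
        else:
            totals = _polysmooth_responses(
                cfg, deployment, means_int, sigmas_int, omegas, gmax, rho
            )
            means_int = {t: max(0.0, means_int[t] + totals[t]) for t in traits}

        # refugia: fitness costs only
        ref_phi = {}
        for t in traits:
            s_f, s_m = gs.fitness_cost_differential(cfg.fitness, sigmas_ref[t])
            ref_phi[t] = gs.breeders_response(s_f, s_m, cfg.genetics_for(t))
        means_ref = ls.apply_refugia_responses(means_ref, ref_phi)

        # 4. dispersal mixes the post-response means
        for t in traits:
            means_int[t], means_ref[t] = ls.disperse(means_int[t], means_ref[t], cfg.landscape)
            means_int[t] = max(0.0, means_int[t])
            means_ref[t] = max(0.0, means_ref[t])

        # 5. advance clocks and record end-of-generation state
        for p in list(tau):
            tau[p] += 1
        n_generations = gen + 1
        active = deployment.active if deployment else ()
        bio_int, bio_ref = bioassay_of(means_int), bioassay_of(means_ref)
        for t in traits:
            traj.records.append(
                {
                    "generation": n_generations,
                    "trait": t,
                    "site": "intervention",
                    "mean_prs": means_int[t],
                    "bioassay_survival": bio_int[t],
                    "deployed_flag": t in active,
                    "efficacy": omegas.get(t, np.nan),
                }
            )
            traj.records.append(
                {
                    "generation": n_generations,
                    "trait": t,
                    "site": "refugia",
                    "mean_prs": means_ref[t],
                    "bioassay_survival": bio_ref[t],
                    "deployed_flag": False,
                    "efficacy": np.nan,
                }
            )
        if stop_at_bioassay is not None and any(
            bio_int[t] >= stop_at_bioassay for t in traits
        ):
            termination = "threshold"
            break
    else:
        n_generations = strategy.generation_cap

    traj.termination = termination
    traj.n_generations = n_generations
    traj.failure_generations = failure_generations
    return traj


def run_until_threshold(
    cfg: ScenarioConfig,
    branch: str = "polysmooth",
    threshold: float = 0.10,
    cap: int | None = None,
) -> int | None:
    """Generations of continuous deployment until the intervention-site
    bioassay survival first reaches ``threshold`` (None if never, within the
    cap)."""
    strategy = cfg.strategy
    if cap is not None or strategy.kind != "continuous":
        strategy = StrategyConfig(
            kind="continuous",
            arsenal=strategy.arsenal[:1],
            withdrawal_threshold=strategy.withdrawal_threshold,
            return_threshold=strategy.return_threshold,
            deployment_interval=strategy.deployment_interval,
            generation_cap=cap if cap is not None else strategy.generation_cap,
            generations_per_year=strategy.generations_per_year,
        )
    traj = run_simulation(cfg.with_strategy(strategy), branch=branch, stop_at_bioassay=threshold)
    if traj.termination == "threshold":
        return traj.n_generations
    return traj.first_crossing(threshold)
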