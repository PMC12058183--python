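"""Scenario configuration: dataclasses plus YAML round-tripping.

A scenario bundles everything one simulation needs: the insecticide arsenal
(Hill scale and decay profile per product), the genetics (heritability,
exposure scaling factor beta, fitness costs, cross resistance), the exposure
and landscape parameters, the gonotrophic-cycle parameters, an optional
coverage model for mosaics/combinations, and the deployment strategy rules.
Key names in the YAML dialect mirror the field's conventional symbols
(z50, omega0, delta_b, delta_r, tau_b, phi1...).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import yaml

from .errors import ConfigurationError
from .generation_selection import ExposureParams, FitnessCost, GeneticsParams
from .gonotrophic import CoverageModel, CycleParams
from .landscape import CrossResistance, LandscapeParams
from .resistance_scale import DecayProfile, FieldCalibration, HillScale, Insecticide, SigmaModel

__all__ = ["StrategyConfig", "ScenarioConfig", "load_scenario", "dump_scenario"]

STRATEGY_KINDS = ("continuous", "sequence", "rotation", "mixture", "micro_mosaic", "combination")


@dataclass(frozen=True)
class StrategyConfig:
    """Deployment rules: which insecticides go out, when, and when they fail.

    An insecticide is withdrawn when its bioassay survival (evaluated from
    the intervention-site female mean at a decision point) reaches
    ``withdrawal_threshold`` and becomes redeployable only once it falls
    below ``return_threshold`` (hysteresis).  Decisions are taken every
    ``deployment_interval`` generations; combinations may carry per-product
    intervals (e.g. nets every 3 years, spray every year).
    """

    kind: str
    arsenal: tuple[str, ...]
    withdrawal_threshold: float = 0.10
    return_threshold: float = 0.08
    deployment_interval: int = 10
    product_intervals: Mapping[str, int] | None = None
    generation_cap: int = 500
    generations_per_year: int = 10
    doses: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in STRATEGY_KINDS:
            raise ConfigurationError(f"unknown strategy kind {self.kind!r}; one of {STRATEGY_KINDS}")
        if not self.arsenal:
            raise ConfigurationError("strategy arsenal is empty")
        if self.return_threshold >= self.withdrawal_threshold:
            raise ConfigurationError("return_threshold must be below withdrawal_threshold")
        if self.deployment_interval < 1:
            raise ConfigurationError("deployment_interval must be >= 1")
        if self.kind in ("mixture", "micro_mosaic", "combination") and len(self.arsenal) < 2:
            raise ConfigurationError(f"{self.kind} strategies need at least two insecticides")
        object.__setattr__(self, "arsenal", tuple(self.arsenal))

    def interval_for(self, insecticide_id: str) -> int:
        if self.product_intervals and insecticide_id in self.product_intervals:
            return int(self.product_intervals[insecticide_id])
        return self.deployment_interval

    def dose_for(self, insecticide_id: str, default: float) -> float:
        if self.doses and insecticide_id in self.doses:
            return float(self.doses[insecticide_id])
        return default


@dataclass
class ScenarioConfig:
    """Everything a simulation run needs, minus the branch/cycles switches."""

    insecticides: list[Insecticide]
    strategy: StrategyConfig
    field_cal: FieldCalibration = field(default_factory=FieldCalibration)
    sigma_model: SigmaModel = field(default_factory=SigmaModel)
    exposure: ExposureParams = field(default_factory=ExposureParams)
    fitness: FitnessCost = field(default_factory=FitnessCost)
    h2: float | Mapping[str, float] = 0.2
    beta: float = 1.0
    cross: CrossResistance = field(default_factory=CrossResistance)
    landscape: LandscapeParams = field(default_factory=LandscapeParams)
    cycle: CycleParams = field(default_factory=CycleParams)
    coverage_model: CoverageModel | None = None
    initial_mean: float | Mapping[str, float] = 0.0
    n_bins: int = 2001
    mean_survival_integrated: bool = False
    immediate_withdrawal: bool = False

    def __post_init__(self) -> None:
        ids = [ins.id for ins in self.insecticides]
        if len(set(ids)) != len(ids):
            raise ConfigurationError(f"insecticide ids must be unique, got {ids}")
        missing = [t for t in self.strategy.arsenal if t not in ids]
        if missing:
            raise ConfigurationError(f"arsenal refers to undefined insecticide(s): {missing}")

    # --- lookups ------------------------------------------------------------
    @property
    def trait_ids(self) -> list[str]:
        return [ins.id for ins in self.insecticides]

    def insecticide(self, insecticide_id: str) -> Insecticide:
        for ins in self.insecticides:
            if ins.id == insecticide_id:
                return ins
        raise KeyError(insecticide_id)

    def h2_for(self, trait: str) -> float:
        if isinstance(self.h2, Mapping):
            return float(self.h2[trait])
        return float(self.h2)

    def genetics_for(self, trait: str) -> GeneticsParams:
        return GeneticsParams(h2=self.h2_for(trait), beta=self.beta)

    def initial_mean_for(self, trait: str) -> float:
        if isinstance(self.initial_mean, Mapping):
            return float(self.initial_mean[trait])
        return float(self.initial_mean)

    def with_strategy(self, strategy: StrategyConfig) -> "ScenarioConfig":
        return replace(self, strategy=strategy)


# --- YAML (de)serialisation -------------------------------------------------

def _insecticide_to_dict(ins: Insecticide) -> dict:
    return {
        "id": ins.id,
        "z50": ins.scale.z50,
        "kmax": ins.scale.kmax,
        "n": ins.scale.n,
        "omega0": ins.decay.omega0,
        "delta_b": ins.decay.delta_b,
        "delta_r": ins.decay.delta_r,
        "tau_b": ins.decay.tau_b,
        "decay_exponent": ins.decay.decay_exponent,
    }


def _insecticide_from_dict(d: Mapping) -> Insecticide:
    return Insecticide(
        id=str(d["id"]),
        scale=HillScale(
            z50=float(d.get("z50", 900.0)),
            kmax=float(d.get("kmax", 1.0)),
            n=float(d.get("n", 1.0)),
        ),
        decay=DecayProfile(
            omega0=float(d.get("omega0", 1.0)),
            delta_b=float(d.get("delta_b", 0.0)),
            delta_r=float(d.get("delta_r", 0.0)),
            tau_b=float(d.get("tau_b", 20.0)),
            decay_exponent=float(d.get("decay_exponent", 2.0)),
        ),
    )


def _plain(obj):
    """Recursively coerce numpy scalars to plain Python for YAML output."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if hasattr(obj, "item") and not isinstance(obj, str):
        return obj.item()  # numpy scalar (np.float64 subclasses float but YAML dispatches on exact type)
    return obj


def scenario_to_dict(cfg: ScenarioConfig) -> dict:
    d: dict = {
        "insecticides": [_insecticide_to_dict(i) for i in cfg.insecticides],
        "field_calibration": {"phi1": cfg.field_cal.phi1, "phi2": cfg.field_cal.phi2},
        "sigma": {
            "mode": cfg.sigma_model.mode,
            "sigma_fixed": cfg.sigma_model.sigma_fixed,
            # phi3/phi4 defaults are unvalidated placeholders pending field data
            "phi3": cfg.sigma_model.phi3,
            "phi4": cfg.sigma_model.phi4,
        },
        "exposure": {"x": cfg.exposure.x, "m": cfg.exposure.m},
        "fitness": {
            "mode": cfg.fitness.mode,
            "female": cfg.fitness.magnitude_female,
            "male": cfg.fitness.magnitude_male,
        },
        "genetics": {
            "h2": dict(cfg.h2) if isinstance(cfg.h2, Mapping) else cfg.h2,
            "beta": cfg.beta,
        },
        "cross_resistance": {s: dict(r) for s, r in cfg.cross.alpha.items()},
        "landscape": {
            "coverage": cfg.landscape.coverage,
            "theta": cfg.landscape.theta,
            "normalized_mixing": cfg.landscape.normalized_mixing,
        },
        "cycle": {"d": cfg.cycle.d, "g": cfg.cycle.g, "gmax": cfg.cycle.gmax},
        "strategy": {
            "kind": cfg.strategy.kind,
            "arsenal": list(cfg.strategy.arsenal),
            "withdrawal_threshold": cfg.strategy.withdrawal_threshold,
            "return_threshold": cfg.strategy.return_threshold,
            "deployment_interval": cfg.strategy.deployment_interval,
            "generation_cap": cfg.strategy.generation_cap,
            "generations_per_year": cfg.strategy.generations_per_year,
        },
        "initial_mean": dict(cfg.initial_mean)
        if isinstance(cfg.initial_mean, Mapping)
        else cfg.initial_mean,
        "n_bins": cfg.n_bins,
        "mean_survival_integrated": cfg.mean_survival_integrated,
        "immediate_withdrawal": cfg.immediate_withdrawal,
    }
    if cfg.strategy.product_intervals:
        d["strategy"]["product_intervals"] = dict(cfg.strategy.product_intervals)
    if cfg.strategy.doses:
        d["strategy"]["doses"] = dict(cfg.strategy.doses)
    if cfg.coverage_model is not None:
        cov = cfg.coverage_model
        d["coverage_model"] = {
            "c_i": cov.c_i,
            "c_j": cov.c_j,
            "c_ij": cov.c_ij,
            "lambda_female": list(cov.lambda_female),
            "lambda_male": list(cov.lambda_male),
        }
    return _plain(d)


def scenario_from_dict(d: Mapping) -> ScenarioConfig:
    strat = dict(d["strategy"])
    strategy = StrategyConfig(
        kind=strat["kind"],
        arsenal=tuple(strat["arsenal"]),
        withdrawal_threshold=float(strat.get("withdrawal_threshold", 0.10)),
        return_threshold=float(strat.get("return_threshold", 0.08)),
        deployment_interval=int(strat.get("deployment_interval", 10)),
        product_intervals=strat.get("product_intervals"),
        generation_cap=int(strat.get("generation_cap", 500)),
        generations_per_year=int(strat.get("generations_per_year", 10)),
        doses=strat.get("doses"),
    )
    sig = d.get("sigma", {})
    gen = d.get("genetics", {})
    cov = d.get("coverage_model")
    coverage_model = None
    if cov is not None:
        coverage_model = CoverageModel(
            c_i=float(cov.get("c_i", 1.0)),
            c_j=float(cov.get("c_j", 0.0)),
            c_ij=float(cov.get("c_ij", 0.0)),
            lambda_female=tuple(cov.get("lambda_female", (0, 0, 1))),
            lambda_male=tuple(cov.get("lambda_male", (0, 0, 1))),
        )
    fit = d.get("fitness", {})
    land = d.get("landscape", {})
    cyc = d.get("cycle", {})
    cal = d.get("field_calibration", {})
    expo = d.get("exposure", {})
    return ScenarioConfig(
        insecticides=[_insecticide_from_dict(i) for i in d["insecticides"]],
        strategy=strategy,
        field_cal=FieldCalibration(
            phi1=float(cal.get("phi1", 0.48)), phi2=float(cal.get("phi2", 0.15))
        ),
        sigma_model=SigmaModel(
            mode=sig.get("mode", "fixed"),
            sigma_fixed=float(sig.get("sigma_fixed", 30.0)),
            phi3=float(sig.get("phi3", 0.05)),
            phi4=float(sig.get("phi4", 25.0)),
        ),
        exposure=ExposureParams(x=float(expo.get("x", 0.7)), m=float(expo.get("m", 0.7))),
        fitness=FitnessCost(
            mode=fit.get("mode", "fixed"),
            magnitude_female=float(fit.get("female", 0.0)),
            magnitude_male=float(fit.get("male", 0.0)),
        ),
        h2=gen.get("h2", 0.2),
        beta=float(gen.get("beta", 1.0)),
        cross=CrossResistance(alpha=d.get("cross_resistance", {})),
        landscape=LandscapeParams(
            coverage=float(land.get("coverage", 0.7)),
            theta=float(land.get("theta", 0.3)),
            normalized_mixing=bool(land.get("normalized_mixing", False)),
        ),
        cycle=CycleParams(
            d=float(cyc.get("d", 0.8)), g=int(cyc.get("g", 3)), gmax=int(cyc.get("gmax", 5))
        ),
        coverage_model=coverage_model,
        initial_mean=d.get("initial_mean", 0.0),
        n_bins=int(d.get("n_bins", 2001)),
        mean_survival_integrated=bool(d.get("mean_survival_integrated", False)),
        immediate_withdrawal=bool(d.get("immediate_withdrawal", False)),
    )


def load_scenario(path: str | Path) -> ScenarioConfig:
    with open(path) as fh:
        return scenario_from_dict(yaml.safe_load(fh))


def dump_scenario(cfg: ScenarioConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scenario_to_dict(cfg), fh, sort_keys=False)
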