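"""Insecticide selection over multiple gonotrophic cycles.

A female mosquito feeds and lays eggs in repeated gonotrophic cycles (~3
days each), and every cycle brings a fresh chance of encountering the
deployed insecticide(s).  This module extends the probabilistic-selection
branch across up to ``gmax`` cycles:

* houses are treated with insecticide i only, j only or both (coverage
  fractions c_i, c_j, c_ij); inside a dual-treated house a mosquito meets
  i only, j only or both according to sex-specific encounter splits Lambda;
* between cycles a fraction ``rho = d**g`` survives natural (non-insecticidal)
  mortality, where d is the daily survival probability and g the cycle length
  in days;
* each cycle's egg-laying females contribute a per-cycle selection
  differential and response; the generation's total response is the
  oviposition-weighted average of the per-cycle responses.

Because females mate only once (in their first cycle), the male selection
differential is computed from a single round of selection and held constant
across cycles.  The machinery also yields the female age profile -- the
number of females completing each cycle -- which links resistance management
to transmission potential (females must survive ~3 cycles to transmit
falciparum malaria).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CohortExtinctSignal, ConfigurationError
from .generation_selection import ExposureParams, GeneticsParams, TraitDistribution

__all__ = [
    "CoverageModel",
    "CycleParams",
    "CycleState",
    "AgeProfile",
    "MultiCycleResult",
    "natural_survival",
    "encounter_partition",
    "initial_cycle_state",
    "cycle_step",
    "run_female_cycles",
    "male_selection_complex",
    "multi_cycle_response",
    "age_profile_snapshot",
]

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class CoverageModel:
    """Coverage split across treated houses and within-house encounter splits.

    ``c_i + c_j + c_ij = 1``; ``lambda_female``/``lambda_male`` are the
    (i-only, j-only, both) encounter probabilities inside a dual-treated
    house and each sum to 1.
    """

    c_i: float = 1.0
    c_j: float = 0.0
    c_ij: float = 0.0
    lambda_female: tuple[float, float, float] = (0.0, 0.0, 1.0)
    lambda_male: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        for name, v in (("c_i", self.c_i), ("c_j", self.c_j), ("c_ij", self.c_ij)):
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if abs(self.c_i + self.c_j + self.c_ij - 1.0) > _SUM_TOL:
            raise ConfigurationError("c_i + c_j + c_ij must sum to 1")
        for name, lam in (("lambda_female", self.lambda_female), ("lambda_male", self.lambda_male)):
            if any(v < 0 for v in lam):
                raise ConfigurationError(f"{name} entries must be non-negative")
            if abs(sum(lam) - 1.0) > _SUM_TOL:
                raise ConfigurationError(f"{name} must sum to 1")

    def lam(self, sex: str) -> tuple[float, float, float]:
        return self.lambda_female if sex == "female" else self.lambda_male

    # --- common deployments -------------------------------------------------
    @classmethod
    def monotherapy(cls) -> "CoverageModel":
        return cls(c_i=1.0, c_j=0.0, c_ij=0.0)

    @classmethod
    def mixture(cls) -> "CoverageModel":
        """Every treated house carries both products and every encounter
        contacts both: the de-facto mixture."""
        return cls(c_i=0.0, c_j=0.0, c_ij=1.0, lambda_female=(0, 0, 1), lambda_male=(0, 0, 1))

    @classmethod
    def mosaic(cls, c_i: float = 0.5) -> "CoverageModel":
        return cls(c_i=c_i, c_j=1.0 - c_i, c_ij=0.0)


@dataclass(frozen=True)
class CycleParams:
    """Natural-survival parameters of the gonotrophic cycle."""

    d: float = 0.8
    g: int = 3
    gmax: int = 5

    def __post_init__(self) -> None:
        if not 0 <= self.d <= 1:
            raise ConfigurationError(f"daily survival d must be in [0, 1], got {self.d}")
        if self.g < 1:
            raise ConfigurationError(f"cycle length g must be >= 1 day, got {self.g}")
        if self.gmax < 1:
            raise ConfigurationError(f"gmax must be >= 1, got {self.gmax}")

    @property
    def rho(self) -> float:
        return natural_survival(self.d, self.g)


def natural_survival(d: float, g: float) -> float:
    """Per-cycle natural survival rho = d**g."""
    if not 0 <= d <= 1:
        raise ConfigurationError(f"daily survival d must be in [0, 1], got {d}")
    if g < 0:
        raise ConfigurationError(f"cycle length g must be non-negative, got {g}")
    return float(d**g)


def encounter_partition(coverage: CoverageModel, x: float, sex: str = "female") -> dict[str, float]:
    """Probabilities of the four encounter outcomes in one cycle.

    {i-only, j-only, both, none}; `x` here is the sex's own total encounter
    probability (so pass m*x for males).  Probabilities sum to 1.
    """
    lam_i, lam_j, lam_ij = coverage.lam(sex)
    return {
        "i": x * (coverage.c_i + coverage.c_ij * lam_i),
        "j": x * (coverage.c_j + coverage.c_ij * lam_j),
        "both": x * coverage.c_ij * lam_ij,
        "none": 1.0 - x,
    }


@dataclass
class CycleState:
    """State of the female cohort at the end of cycle G (for one trait).

    ``freq`` is the per-bin frequency vector over ``grid`` (summing to n_p);
    the counts split the cycle's egg-layers into the four encounter groups.
    """

    cycle: int
    grid: np.ndarray
    freq: np.ndarray
    n_i_e: float
    n_j_e: float
    n_ij_e: float
    n_u: float
    n_p: float
    z_e: float
    z_p: float


def initial_cycle_state(dist: TraitDistribution, sex: str = "female") -> CycleState:
    """Cycle-0 (hatching) state from a newborn trait distribution."""
    freq = dist.freq_female if sex == "female" else dist.freq_male
    n = float(freq.sum())
    return CycleState(
        cycle=0,
        grid=dist.grid,
        freq=freq.copy(),
        n_i_e=0.0,
        n_j_e=0.0,
        n_ij_e=0.0,
        n_u=n,
        n_p=n,
        z_e=dist.mean,
        z_p=dist.mean,
    )


def cycle_step(
    state: CycleState,
    k_field_i: np.ndarray,
    kbar_j: float,
    coverage: CoverageModel,
    x: float,
    rho: float,
    sex: str = "female",
) -> CycleState:
    """Advance the cohort through one gonotrophic cycle.

    Survival to the focal insecticide i is per-bin (``k_field_i`` over the
    grid); survival to the partner j enters at the population mean
    (``kbar_j``), since the two traits are tracked as separate distributions.
    The first cycle (state.cycle == 0) carries no natural-mortality factor;
    all later cycles are multiplied through by ``rho``.
    """
    lam_i, lam_j, lam_ij = coverage.lam(sex)
    r = 1.0 if state.cycle == 0 else rho
    a_i = x * (coverage.c_i + coverage.c_ij * lam_i)
    a_j = x * (coverage.c_j + coverage.c_ij * lam_j)
    a_both = x * coverage.c_ij * lam_ij

    prev = state.freq
    n_prev = state.n_p
    surv_i_only = prev * k_field_i * a_i
    surv_both = prev * k_field_i * kbar_j * a_both
    f_exposed = (surv_i_only + surv_both) * r

    n_i_e = float(surv_i_only.sum()) * r
    n_ij_e = float(surv_both.sum()) * r
    n_j_e = kbar_j * a_j * n_prev * r
    n_u = (1.0 - x) * n_prev * r
    n_p = n_i_e + n_j_e + n_ij_e + n_u
    if n_p <= 0.0:
        raise CohortExtinctSignal(f"no females remain at cycle {state.cycle + 1}")

    freq_end = prev * (k_field_i * a_i + k_field_i * kbar_j * a_both + kbar_j * a_j + (1.0 - x)) * r

    n_e = n_i_e + n_ij_e
    z_e = float((f_exposed * state.grid).sum() / n_e) if n_e > 0 else state.z_p
    z_p = (n_i_e * z_e + n_j_e * state.z_p + n_ij_e * z_e + n_u * state.z_p) / n_p
    return CycleState(
        cycle=state.cycle + 1,
        grid=state.grid,
        freq=freq_end,
        n_i_e=n_i_e,
        n_j_e=n_j_e,
        n_ij_e=n_ij_e,
        n_u=n_u,
        n_p=n_p,
        z_e=z_e,
        z_p=float(z_p),
    )


def run_female_cycles(
    dist: TraitDistribution,
    k_field_i: np.ndarray,
    kbar_j: float,
    coverage: CoverageModel,
    x: float,
    rho: float,
    gmax: int,
) -> list[CycleState]:
    """Run the female cohort through up to ``gmax`` cycles.

    Returns the per-cycle states (cycles 1..gmax); the loop truncates early
    if the cohort goes extinct.
    """
    states: list[CycleState] = []
    state = initial_cycle_state(dist, sex="female")
    for _ in range(gmax):
        try:
            state = cycle_step(state, k_field_i, kbar_j, coverage, x, rho, sex="female")
        except CohortExtinctSignal:
            break
        states.append(state)
    return states


def male_selection_complex(
    coverage: CoverageModel,
    dist: TraitDistribution,
    exposure: ExposureParams,
    k_field_i: np.ndarray,
    kbar_j: float = 1.0,
) -> float:
    """Male insecticide selection differential under complex deployments.

    Males have a single round of selection before mating, with total
    encounter probability m*x and the male encounter split; the resulting
    differential is held constant across all female cycles.
    """
    state = initial_cycle_state(dist, sex="male")
    stepped = cycle_step(
        state, k_field_i, kbar_j, coverage, exposure.m * exposure.x, rho=1.0, sex="male"
    )
    return stepped.z_p - dist.mean


@dataclass
class MultiCycleResult:
    """Oviposition-weighted total response and its per-cycle pieces."""

    total: float
    per_cycle: list[float]
    weights: list[float]
    n_oviposition: float


def multi_cycle_response(
    cycle_states: list[CycleState],
    s_male_insecticide: float,
    genetics: GeneticsParams,
    s_phi_female: float,
    s_phi_male: float,
    z_hatch: float,
    partner_per_cycle: list[float] | None = None,
    alpha: float = 0.0,
) -> MultiCycleResult:
    """Total response for one trait across all completed cycles.

    Per cycle: S_female = z_P(G) - z_hatch plus the (constant) fitness-cost
    differential; the male differential is fixed; the Breeder's equation
    gives the per-cycle response.  The generation total is the per-cycle
    responses (plus alpha-weighted partner responses, for cross resistance)
    averaged with weights N_P(G)/N_o where N_o is the total number of
    oviposition events.
    """
    if not cycle_states:
        raise CohortExtinctSignal("no completed cycles: no oviposition events")
    n_o = sum(s.n_p for s in cycle_states)
    if n_o <= 0:
        raise CohortExtinctSignal("no oviposition events across cycles")
    per_cycle: list[float] = []
    weights: list[float] = []
    total = 0.0
    for g, s in enumerate(cycle_states):
        s_f = (s.z_p - z_hatch) + s_phi_female
        s_m = s_male_insecticide + s_phi_male
        r_g = genetics.h2 * (s_f + s_m) / 2.0 * genetics.beta
        w = s.n_p / n_o
        per_cycle.append(r_g)
        weights.append(w)
        partner = 0.0
        if partner_per_cycle is not None and g < len(partner_per_cycle):
            partner = partner_per_cycle[g]
        total += (r_g + alpha * partner) * w
    return MultiCycleResult(total=total, per_cycle=per_cycle, weights=weights, n_oviposition=n_o)


@dataclass
class AgeProfile:
    """Female counts completing each cycle, with and without intervention."""

    cycles: np.ndarray
    with_intervention: np.ndarray
    no_intervention: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle": self.cycles,
                "count_with_intervention": self.with_intervention,
                "count_no_intervention": self.no_intervention,
            }
        )

    def surviving_at_least(self, cycle: int) -> tuple[float, float]:
        """Total count completing >= ``cycle`` cycles (with, without)."""
        mask = self.cycles >= cycle
        return float(self.with_intervention[mask].sum()), float(self.no_intervention[mask].sum())


def age_profile_snapshot(
    dist: TraitDistribution,
    k_field_i: np.ndarray,
    kbar_j: float,
    coverage: CoverageModel,
    x: float,
    cycle_params: CycleParams,
    baseline_n: float = 100_000.0,
    gmax: int = 10,
) -> AgeProfile:
    """Single-generation age-profile snapshot (no evolution, no dispersal).

    Counts are scaled so that, in the absence of any intervention,
    ``baseline_n`` females complete the first cycle; the no-intervention
    profile is then geometric with ratio rho.
    """
    rho = cycle_params.rho
    states = run_female_cycles(dist, k_field_i, kbar_j, coverage, x, rho, gmax)
    scale = baseline_n / dist.n_female
    with_int = np.array([s.n_p * scale for s in states])
    if len(with_int) < gmax:  # extinct early: pad with zeros
        with_int = np.concatenate([with_int, np.zeros(gmax - len(with_int))])
    cycles = np.arange(1, gmax + 1)
    no_int = baseline_n * rho ** (cycles - 1.0)
    return AgeProfile(cycles=cycles, with_intervention=with_int, no_intervention=no_int)
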