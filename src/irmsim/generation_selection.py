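"""Within-generation selection and the between-generation response.

Each generation the newborn cohort carries a Normally distributed polygenic
resistance score (PRS).  Exposure to a deployed insecticide removes part of
the cohort; the survivors' mean PRS exceeds the newborn mean, and the
difference between the breeding parents' mean and the newborn mean is the
insecticide selection differential ``S``.  Two mechanisms are implemented:

* **truncation selection** -- only individuals above a threshold survive, so
  the survivor mean follows the classical selection-intensity formula for a
  truncated Normal;
* **probabilistic (smooth) selection** -- each individual's survival
  probability is its own field survival, evaluated per bin of a discretised
  ("polysmooth") trait distribution.

The between-generation change in the mean (the response) follows the
sex-specific Breeder's equation R = h2 * (S_female + S_male) / 2 * beta,
where beta is an exposure scaling factor used to calibrate simulations to
realistic timescales.  Fitness costs enter as a separate, negative
selection differential applied to both sexes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ConfigurationError, DegenerateCohortError, InvalidInputError
from .resistance_scale import FieldCalibration, HillScale, bioassay_survival, field_survival

__all__ = [
    "GeneticsParams",
    "ExposureParams",
    "FitnessCost",
    "TraitDistribution",
    "ExposedCohort",
    "SelectionOutcome",
    "hatch_distribution",
    "truncation_intensity",
    "truncation_selection",
    "probabilistic_selection",
    "parental_pool",
    "fitness_cost_differential",
    "breeders_response",
]


@dataclass(frozen=True)
class GeneticsParams:
    """Heritability of the resistance trait and the exposure scaling factor."""

    h2: float = 0.2
    beta: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.h2 <= 1:
            raise ConfigurationError(f"heritability must be in [0, 1], got {self.h2}")
        if self.beta < 0:
            raise ConfigurationError(f"beta must be non-negative, got {self.beta}")


@dataclass(frozen=True)
class ExposureParams:
    """Encounter probabilities: x for females, m*x for males.

    Females forage for blood meals so encounter nets and sprayed walls more
    often; m expresses male exposure as a fraction of female exposure.
    """

    x: float = 0.7
    m: float = 0.7

    def __post_init__(self) -> None:
        if not 0 <= self.x <= 1:
            raise ConfigurationError(f"x must be in [0, 1], got {self.x}")
        if self.m < 0:
            raise ConfigurationError(f"m must be non-negative, got {self.m}")
        if self.m * self.x > 1 + 1e-12:
            raise ConfigurationError(f"m*x must not exceed 1, got {self.m * self.x}")


@dataclass(frozen=True)
class FitnessCost:
    """Fitness-cost selection differential, per sex.

    mode="fixed": magnitudes are PRS units and stay constant (used with a
    fixed sigma).  mode="scaled": magnitudes are fractions of the current
    sigma (used when sigma grows with the mean).  Magnitudes are stored
    positive and applied with a negative sign -- costs reduce resistance.
    """

    mode: str = "fixed"
    magnitude_female: float = 0.0
    magnitude_male: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "scaled"):
            raise ConfigurationError(f"fitness-cost mode must be 'fixed' or 'scaled', got {self.mode!r}")
        if self.magnitude_female < 0 or self.magnitude_male < 0:
            raise ConfigurationError("fitness-cost magnitudes must be non-negative")


@dataclass
class TraitDistribution:
    """Binned PRS distribution ("polysmooth" population representation).

    ``grid`` holds the ordered bin centres; ``freq_female``/``freq_male`` the
    per-bin frequencies, which sum to the current cohort size per sex.
    """

    grid: np.ndarray
    freq_female: np.ndarray
    freq_male: np.ndarray
    mean: float
    sigma: float

    @property
    def n_female(self) -> float:
        return float(self.freq_female.sum())

    @property
    def n_male(self) -> float:
        return float(self.freq_male.sum())


@dataclass
class ExposedCohort:
    """Survivors of insecticide exposure: count and mean PRS, per sex."""

    z_e_female: float
    z_e_male: float
    n_e_female: float
    n_e_male: float


@dataclass
class SelectionOutcome:
    """Full bookkeeping of one generation's selection, per sex."""

    z_e_female: float
    z_e_male: float
    n_e_female: float
    n_e_male: float
    n_u_female: float
    n_u_male: float
    n_p_female: float
    n_p_male: float
    z_p_female: float
    z_p_male: float
    s_insecticide_female: float
    s_insecticide_male: float


def hatch_distribution(
    mean: float, sigma: float, n_bins: int = 2001, total: float = 1.0
) -> TraitDistribution:
    """Newborn cohort: a discretised Normal(mean, sigma) on mean +/- 6 sigma.

    Frequencies are proportional to the Normal density at bin centres and
    renormalised so each sex holds half of ``total`` (1:1 sex ratio at
    hatching).
    """
    if sigma <= 0:
        raise InvalidInputError(f"sigma must be positive, got {sigma}")
    if n_bins < 100:
        raise InvalidInputError(f"n_bins must be at least 100, got {n_bins}")
    grid = np.linspace(mean - 6.0 * sigma, mean + 6.0 * sigma, n_bins)
    density = np.exp(-0.5 * ((grid - mean) / sigma) ** 2)
    density /= density.sum()
    per_sex = density * (total / 2.0)
    return TraitDistribution(
        grid=grid,
        freq_female=per_sex.copy(),
        freq_male=per_sex.copy(),
        mean=float(mean),
        sigma=float(sigma),
    )


def truncation_intensity(p_survive: float) -> float:
    """Selection intensity for truncation at upper-tail mass ``p_survive``.

    Returns phi(q) / p where q is the standard-Normal point with upper-tail
    probability p and phi the unit Normal density; this is the mean of a
    standard Normal truncated to its upper p fraction.  p=1 means no
    truncation (intensity 0); p=0 (everyone dies) is an error.
    """
    if p_survive <= 0:
        raise InvalidInputError("p_survive must be positive: all exposed died, no parents")
    if p_survive > 1:
        raise InvalidInputError(f"p_survive must be at most 1, got {p_survive}")
    if p_survive == 1:
        return 0.0
    q = stats.norm.isf(p_survive)
    return float(stats.norm.pdf(q) / p_survive)


def truncation_selection(
    dist_mean: float,
    sigma: float,
    mean_field_survival: float,
    exposure: ExposureParams,
    n_total_female: float = 0.5,
    n_total_male: float = 0.5,
    mixture_survival_j: float | None = None,
) -> ExposedCohort:
    """Exposed-survivor cohort under truncation selection.

    The truncation point is set so the surviving fraction equals the
    population mean field survival ``K`` (evaluated at the mean PRS); the
    survivor mean is ``dist_mean + sigma * intensity(K)``.  Survivor counts
    are exposure * K (times the mixture partner's mean survival when a
    second insecticide is co-deployed).
    """
    k = mean_field_survival
    intensity = truncation_intensity(k)
    z_e = dist_mean + sigma * intensity
    k_j = 1.0 if mixture_survival_j is None else mixture_survival_j
    n_e_f = exposure.x * n_total_female * k * k_j
    n_e_m = exposure.x * exposure.m * n_total_male * k * k_j
    return ExposedCohort(z_e_female=z_e, z_e_male=z_e, n_e_female=n_e_f, n_e_male=n_e_m)


def probabilistic_selection(
    dist: TraitDistribution,
    scale: HillScale,
    cal: FieldCalibration,
    omega: float,
    exposure: ExposureParams,
    mixture_survival_j: float | None = None,
) -> ExposedCohort:
    """Exposed-survivor cohort under probabilistic (smooth) selection.

    Each bin survives with its own field survival K_F(z); a co-deployed
    mixture partner enters as the constant population-mean survival, so it
    thins the cohort without shifting this trait's survivor mean.
    """
    k_field = field_survival(bioassay_survival(dist.grid, scale), omega, cal)
    k_j = 1.0 if mixture_survival_j is None else mixture_survival_j
    f_e_female = dist.freq_female * k_field * exposure.x * k_j
    f_e_male = dist.freq_male * k_field * exposure.x * exposure.m * k_j
    n_e_f = float(f_e_female.sum())
    n_e_m = float(f_e_male.sum())
    if n_e_f <= 0.0 and exposure.x > 0:
        raise DegenerateCohortError("all exposed females died: survivor cohort is empty")
    z_e_f = float((f_e_female * dist.grid).sum() / n_e_f) if n_e_f > 0 else dist.mean
    z_e_m = float((f_e_male * dist.grid).sum() / n_e_m) if n_e_m > 0 else dist.mean
    return ExposedCohort(z_e_female=z_e_f, z_e_male=z_e_m, n_e_female=n_e_f, n_e_male=n_e_m)


def parental_pool(
    cohort: ExposedCohort,
    dist_mean: float,
    exposure: ExposureParams,
    n_total_female: float = 0.5,
    n_total_male: float = 0.5,
) -> SelectionOutcome:
    """Combine exposed survivors with the unexposed fraction into parents.

    Unexposed counts are N_T*(1-x) for females and N_T*(1-m*x) for males;
    they keep the newborn mean.  The parental mean is the count-weighted
    average, and the insecticide selection differential S is the parental
    mean minus the newborn mean, per sex.
    """
    n_u_f = n_total_female * (1.0 - exposure.x)
    n_u_m = n_total_male * (1.0 - exposure.m * exposure.x)
    n_p_f = cohort.n_e_female + n_u_f
    n_p_m = cohort.n_e_male + n_u_m
    if n_p_f <= 0 or n_p_m <= 0:
        raise DegenerateCohortError("no breeding parents remain in at least one sex")
    z_p_f = (cohort.n_e_female * cohort.z_e_female + n_u_f * dist_mean) / n_p_f
    z_p_m = (cohort.n_e_male * cohort.z_e_male + n_u_m * dist_mean) / n_p_m
    return SelectionOutcome(
        z_e_female=cohort.z_e_female,
        z_e_male=cohort.z_e_male,
        n_e_female=cohort.n_e_female,
        n_e_male=cohort.n_e_male,
        n_u_female=n_u_f,
        n_u_male=n_u_m,
        n_p_female=n_p_f,
        n_p_male=n_p_m,
        z_p_female=float(z_p_f),
        z_p_male=float(z_p_m),
        s_insecticide_female=float(z_p_f - dist_mean),
        s_insecticide_male=float(z_p_m - dist_mean),
    )


def fitness_cost_differential(cost: FitnessCost, sigma: float) -> tuple[float, float]:
    """Fitness-cost selection differentials (female, male), always <= 0."""
    if cost.mode == "fixed":
        return -cost.magnitude_female, -cost.magnitude_male
    return -cost.magnitude_female * sigma, -cost.magnitude_male * sigma


def breeders_response(s_female: float, s_male: float, genetics: GeneticsParams) -> float:
    """Sex-specific Breeder's equation: h2 * (S_f + S_m) / 2 * beta."""
    return genetics.h2 * (s_female + s_male) / 2.0 * genetics.beta
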