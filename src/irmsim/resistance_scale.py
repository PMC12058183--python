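"""Resistance scale: PRS <-> bioassay survival <-> field survival, and decay.

The level of insecticide resistance in a mosquito population is tracked as a
"polygenic resistance score" (PRS), an arbitrary quantitative-trait scale.
This module holds the maps between that scale and the two observable survival
proportions:

* **bioassay survival** -- the proportion of females surviving a standardised
  discriminating-dose assay, obtained from the PRS through a Hill-type
  (Michaelis-Menten variant) saturating curve, and
* **field survival** -- the proportion surviving a real insecticide encounter
  (experimental-hut proxy), linear in bioassay survival and modulated by the
  current insecticide efficacy ``omega`` raised as an exponent.

It also models the post-deployment decay of insecticide efficacy (a two-phase
curve: slow basal decay followed by rapid decay once a longevity threshold is
exceeded) and the standard deviation of the PRS, which may be fixed or grow
linearly with the population mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, InvalidInputError

logger = logging.getLogger(__name__)

__all__ = [
    "HillScale",
    "FieldCalibration",
    "DecayProfile",
    "SigmaModel",
    "Insecticide",
    "bioassay_survival",
    "bioassay_to_prs",
    "field_survival",
    "efficacy_at",
    "sigma_of_mean",
]


@dataclass(frozen=True)
class HillScale:
    """Hill curve linking PRS to bioassay survival.

    Parameters
    ----------
    z50:
        PRS giving 50% bioassay survival. The conventional scale uses
        ``z50 = 900`` so that a PRS of 100 corresponds to 10% bioassay
        survival, the usual "confirmed resistance" criterion.
    kmax:
        Maximum achievable bioassay survival (a proportion; by definition 1).
    n:
        Hill exponent (dimensionless; 1 for the standard scale).
    """

    z50: float = 900.0
    kmax: float = 1.0
    n: float = 1.0

    def __post_init__(self) -> None:
        if self.z50 <= 0:
            raise ConfigurationError(f"z50 must be positive, got {self.z50}")
        if not 0 < self.kmax <= 1:
            raise ConfigurationError(f"kmax must be in (0, 1], got {self.kmax}")
        if self.n <= 0:
            raise ConfigurationError(f"Hill exponent n must be positive, got {self.n}")


@dataclass(frozen=True)
class FieldCalibration:
    """Regression coefficients mapping bioassay survival to field survival.

    ``phi1`` (slope) and ``phi2`` (intercept) come from a linear model of
    experimental-hut survival against discriminating-dose bioassay survival;
    the shipped defaults are phi1=0.48, phi2=0.15.
    """

    phi1: float = 0.48
    phi2: float = 0.15

    def __post_init__(self) -> None:
        if self.phi1 < 0 or self.phi2 < 0:
            raise ConfigurationError("phi1 and phi2 must be non-negative")
        if self.phi1 + self.phi2 > 1.0 + 1e-12:
            raise ConfigurationError(
                "phi1 + phi2 must not exceed 1 so field survival stays a proportion"
            )


@dataclass(frozen=True)
class DecayProfile:
    """Two-phase efficacy decay of a deployed insecticide.

    Efficacy starts at ``omega0`` (1 = manufacturer's dose; <1 reduced dose,
    e.g. half-dose mixture constituents; >1 over-spray) and decays at the
    basal rate ``delta_b`` until ``tau_b`` generations post-deployment, after
    which the rapid rate ``delta_r`` applies.  ``decay_exponent`` is the power
    ``p`` in ``exp(-tau**p * delta)``; the default quadratic-in-time law can
    be switched to other exponents.
    Setting both rates to 0 disables decay entirely.
    """

    omega0: float = 1.0
    delta_b: float = 0.0
    delta_r: float = 0.0
    tau_b: float = 20.0
    decay_exponent: float = 2.0

    def __post_init__(self) -> None:
        if self.omega0 < 0:
            raise ConfigurationError("omega0 must be non-negative")
        if self.delta_b < 0 or self.delta_r < 0:
            raise ConfigurationError("decay rates must be non-negative")
        if self.tau_b < 0:
            raise ConfigurationError("tau_b must be non-negative")
        if self.decay_exponent <= 0:
            raise ConfigurationError("decay_exponent must be positive")

    def with_dose(self, omega0: float) -> "DecayProfile":
        """Return a copy deployed at a different initial efficacy (dose)."""
        return DecayProfile(
            omega0=omega0,
            delta_b=self.delta_b,
            delta_r=self.delta_r,
            tau_b=self.tau_b,
            decay_exponent=self.decay_exponent,
        )


@dataclass(frozen=True)
class SigmaModel:
    """Standard deviation of the PRS distribution.

    mode="fixed" keeps sigma constant at ``sigma_fixed`` (appropriate while
    the population mean stays low, e.g. below the 10% withdrawal threshold).
    mode="linear" sets sigma = phi3 * mean + phi4, evaluated per site, which
    keeps the coefficient of variation roughly stable at high resistance.
    The shipped phi3/phi4 defaults are unvalidated placeholders; see the
    default configuration comments.
    """

    mode: str = "fixed"
    sigma_fixed: float = 30.0
    phi3: float = 0.05
    phi4: float = 25.0

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "linear"):
            raise ConfigurationError(f"sigma mode must be 'fixed' or 'linear', got {self.mode!r}")
        if self.mode == "fixed" and self.sigma_fixed <= 0:
            raise ConfigurationError("sigma_fixed must be positive")


@dataclass(frozen=True)
class Insecticide:
    """Bundle of the per-insecticide parameters (identity, scale, decay)."""

    id: str
    scale: HillScale = HillScale()
    decay: DecayProfile = DecayProfile()


def bioassay_survival(z, scale: HillScale = HillScale()):
    """Bioassay survival at PRS ``z`` through the Hill curve.

    Returns ``kmax * z**n / (z50 + z**n)`` for z > 0 and 0 for z <= 0
    (fully susceptible mosquitoes).  Accepts scalars or arrays.
    """
    z_arr = np.asarray(z, dtype=float)
    with np.errstate(invalid="ignore"):
        pos = np.where(z_arr > 0, z_arr, np.nan)
        k = scale.kmax * pos**scale.n / (scale.z50 + pos**scale.n)
    k = np.where(z_arr > 0, k, 0.0)
    if np.ndim(z) == 0:
        return float(k)
    return k


def bioassay_to_prs(k: float, scale: HillScale = HillScale()) -> float:
    """PRS whose bioassay survival is ``k`` (algebraic inverse of the Hill map).

    Raises
    ------
    InvalidInputError
        If ``k`` is negative or >= kmax (no finite PRS exists).
    """
    if k < 0 or k >= scale.kmax:
        raise InvalidInputError(
            f"bioassay survival must be in [0, kmax={scale.kmax}), got {k}"
        )
    if k == 0:
        return 0.0
    return float((scale.z50 * k / (scale.kmax - k)) ** (1.0 / scale.n))


def field_survival(k_bioassay, omega, cal: FieldCalibration = FieldCalibration()):
    """Field survival given bioassay survival and insecticide efficacy.

    Computed as ``(phi1 * k_bioassay + phi2) ** omega`` with the base and the
    result clamped to [0, 1].  ``omega = 0`` (fully decayed insecticide) gives
    survival 1 regardless of resistance; higher efficacy lowers survival.
    """
    kb = np.asarray(k_bioassay, dtype=float)
    base = cal.phi1 * kb + cal.phi2
    clipped = np.clip(base, 0.0, 1.0)
    if np.any(clipped != base):
        logger.debug("field_survival: base %s clamped into [0, 1]", base)
    out = clipped ** np.asarray(omega, dtype=float)
    out = np.clip(out, 0.0, 1.0)
    if np.ndim(k_bioassay) == 0 and np.ndim(omega) == 0:
        return float(out)
    return out


def efficacy_at(tau: float, decay: DecayProfile) -> float:
    """Insecticide efficacy ``tau`` generations after deployment.

    Phase 1 (tau <= tau_b): ``omega0 * exp(-tau**p * delta_b)``.
    Phase 2: the phase-1 value at tau_b times ``exp(-(tau - tau_b)**p * delta_r)``.
    The two phases agree at tau = tau_b, so the curve is continuous; equal
    rates collapse it to (approximately) a single-phase curve.
    """
    if tau < 0:
        raise InvalidInputError(f"tau must be non-negative, got {tau}")
    p = decay.decay_exponent
    if tau <= decay.tau_b:
        return decay.omega0 * float(np.exp(-(tau**p) * decay.delta_b))
    at_break = decay.omega0 * float(np.exp(-(decay.tau_b**p) * decay.delta_b))
    return at_break * float(np.exp(-((tau - decay.tau_b) ** p) * decay.delta_r))


def sigma_of_mean(z_mean: float, model: SigmaModel = SigmaModel()) -> float:
    """PRS standard deviation for a population with mean ``z_mean``."""
    if model.mode == "fixed":
        sigma = model.sigma_fixed
    else:
        sigma = model.phi3 * z_mean + model.phi4
    if sigma <= 0:
        raise ConfigurationError(
            f"sigma model produced non-positive sigma ({sigma}) at mean {z_mean}"
        )
    return float(sigma)
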