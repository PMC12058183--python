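"""Two-patch landscape: between-generation updates and dispersal.

The landscape has an intervention site (where insecticides are deployed) and
a refugia (never treated).  Each generation, per-trait responses are added to
the site means -- directly for deployed traits, via genetic correlations
(cross resistance) for the others -- and then females disperse between the
patches, mixing the post-response means.  Site means are floored at zero:
fitness costs cannot drive the mean PRS negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .errors import ConfigurationError

__all__ = [
    "SiteState",
    "CrossResistance",
    "LandscapeParams",
    "ResponseRecord",
    "apply_responses",
    "disperse",
]


@dataclass
class SiteState:
    """Mean PRS (and sigma) per trait in one site."""

    site: str
    means: dict[str, float]
    sigmas: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class CrossResistance:
    """Matrix of genetic correlations alpha[source][target] between traits.

    alpha_GI is the correlation through which selection on trait G (from
    deploying insecticide g) drags trait I along.  Diagonal entries are 1;
    off-diagonal entries lie in [-1, 1].
    """

    alpha: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for src, row in self.alpha.items():
            for dst, a in row.items():
                if not -1.0 <= a <= 1.0:
                    raise ConfigurationError(
                        f"cross-resistance alpha[{src}][{dst}]={a} outside [-1, 1]"
                    )

    def get(self, source: str, target: str) -> float:
        if source == target:
            return 1.0
        return float(self.alpha.get(source, {}).get(target, 0.0))

    @classmethod
    def symmetric_pair(cls, id_a: str, id_b: str, value: float) -> "CrossResistance":
        """Convenience constructor for the common two-insecticide case."""
        return cls(alpha={id_a: {id_b: value}, id_b: {id_a: value}})


@dataclass(frozen=True)
class LandscapeParams:
    """Coverage C (fraction of the population in the intervention site) and
    dispersal theta (fraction of females moving between sites)."""

    coverage: float = 0.7
    theta: float = 0.3
    normalized_mixing: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.coverage <= 1:
            raise ConfigurationError(f"coverage must be in [0, 1], got {self.coverage}")
        if not 0 <= self.theta <= 1:
            raise ConfigurationError(f"theta must be in [0, 1], got {self.theta}")


@dataclass(frozen=True)
class ResponseRecord:
    """One trait's direct response this generation.

    ``response`` is R^{S,phi} for a deployed trait (insecticide selection plus
    fitness costs) or R^{phi} (fitness costs only) otherwise.
    """

    response: float
    deployed: bool


def apply_responses(
    means: Mapping[str, float],
    responses: Mapping[str, ResponseRecord],
    alpha: CrossResistance,
    *,
    floor: float = 0.0,
) -> dict[str, float]:
    """Intervention-site update with cross resistance.

    Each trait receives its own direct response plus, for every *other*
    deployed trait G, the correlated share alpha_GI * R_G.  Results are
    floored at ``floor`` (default 0).
    """
    missing = [t for t in means if t not in responses]
    if missing:
        raise ConfigurationError(f"no response supplied for tracked trait(s): {missing}")
    deployed = [t for t, r in responses.items() if r.deployed]
    out: dict[str, float] = {}
    for trait, z in means.items():
        delta = responses[trait].response
        for src in deployed:
            if src != trait:
                delta += alpha.get(src, trait) * responses[src].response
        out[trait] = max(floor, z + delta)
    return out


def apply_refugia_responses(
    means: Mapping[str, float],
    fitness_responses: Mapping[str, float],
    *,
    floor: float = 0.0,
) -> dict[str, float]:
    """Refugia update: fitness-cost responses only, floored at zero."""
    return {t: max(floor, z + fitness_responses[t]) for t, z in means.items()}


def disperse(z_int: float, z_ref: float, params: LandscapeParams) -> tuple[float, float]:
    """Mix post-response means between the sites.

    The fraction leaving the refugia is r_Ref = (1 - C) * theta and the
    fraction leaving the intervention site is r_Int = theta * C; the new means
    are z_Int'' = z_Int'(1 - r_Int) + z_Ref' r_Ref and symmetrically for the
    refugia.  By default the mixing weights are used literally even though
    they only sum to 1 at C = 0.5 (matching the lineage of prior two-patch
    models); ``normalized_mixing`` renormalises them.
    """
    r_ref = (1.0 - params.coverage) * params.theta
    r_int = params.theta * params.coverage
    w_int_stay, w_int_in = 1.0 - r_int, r_ref
    w_ref_stay, w_ref_in = 1.0 - r_ref, r_int
    if params.normalized_mixing:
        tot_int = w_int_stay + w_int_in
        tot_ref = w_ref_stay + w_ref_in
        w_int_stay, w_int_in = w_int_stay / tot_int, w_int_in / tot_int
        w_ref_stay, w_ref_in = w_ref_stay / tot_ref, w_ref_in / tot_ref
    new_int = z_int * w_int_stay + z_ref * w_int_in
    new_ref = z_ref * w_ref_stay + z_int * w_ref_in
    return float(new_int), float(new_ref)
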