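"""Health-insurance premium derived from the MS risk index.

The individual risk loading is β = α + R_MS·(1 − α), where α is the share
of the population already affected by MS (prevalence), and the premium
interpolates linearly between the company's minimum and maximum:
P_MS = p_min + β·(p_max − p_min).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from ._util import round_half_up
from .errors import MSRiskError
from .membership import PatientProfile

#: Italian MS prevalence used as the packaged default: ISTAT count of
#: affected subjects over the national population.
ISTAT_MS_AFFECTED = 122_000
ISTAT_POPULATION = 60_359_546


@dataclass(frozen=True)
class PopulationPrevalence:
    """Prevalence α as an affected/population count pair."""

    affected_count: int
    population_count: int

    def __post_init__(self):
        if self.population_count <= 0:
            raise MSRiskError("population_count must be positive")
        if not 0 <= self.affected_count <= self.population_count:
            raise MSRiskError(
                "affected_count must lie in [0, population_count], got "
                f"{self.affected_count}/{self.population_count}"
            )

    @property
    def alpha(self) -> float:
        return self.affected_count / self.population_count


DEFAULT_PREVALENCE = PopulationPrevalence(ISTAT_MS_AFFECTED, ISTAT_POPULATION)


@dataclass(frozen=True)
class PremiumQuote:
    """A premium quote: the inputs and every derived quantity."""

    p_min: float
    p_max: float
    rms: float
    alpha: float
    beta: float
    premium: float

    def rounded_premium(self, ndigits: int = 2) -> float:
        return round_half_up(self.premium, ndigits)


def compute_alpha(affected: int, population: int) -> float:
    """Prevalence α = affected/population (reporting rounds to 3 decimals)."""
    return PopulationPrevalence(affected, population).alpha


def compute_beta(alpha: float, rms: float) -> float:
    """Individual risk loading β = α + R_MS·(1 − α) ∈ [α, 1]."""
    for name, v in (("alpha", alpha), ("rms", rms)):
        if not 0.0 <= v <= 1.0:
            raise MSRiskError(f"{name} must be in [0, 1], got {v}")
    return alpha + rms * (1.0 - alpha)


def compute_premium(p_min: float, p_max: float, beta: float) -> float:
    """P_MS = p_min + β·(p_max − p_min)."""
    if p_min < 0:
        raise MSRiskError(f"p_min must be >= 0, got {p_min}")
    if p_min > p_max:
        raise MSRiskError(f"p_min={p_min} exceeds p_max={p_max}")
    if not 0.0 <= beta <= 1.0:
        raise MSRiskError(f"beta must be in [0, 1], got {beta}")
    return p_min + beta * (p_max - p_min)


def quote(profile: PatientProfile, p_min: float, p_max: float,
          alpha: Optional[float] = None, model=None) -> PremiumQuote:
    """Full pipeline: patient factors → R_MS → β → premium."""
    from .risk_index import compute_rms

    if alpha is None:
        alpha = DEFAULT_PREVALENCE.alpha
    rms = compute_rms(profile, model)
    beta = compute_beta(alpha, rms)
    return PremiumQuote(
        p_min=float(p_min), p_max=float(p_max), rms=rms,
        alpha=float(alpha), beta=beta,
        premium=compute_premium(p_min, p_max, beta),
    )
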