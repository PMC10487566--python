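"""Fuzzy membership functions for the four MS risk factors.

Each biological factor (age at onset, serum vitamin D, BMI, family-kinship
degree) is mapped to a *risk degree* in [0, 1] by a piecewise-linear fuzzy
membership function: 1 means the value is extremely altered, 0 means it sits
in its normal range.  The four default functions are

* age at onset ``A(x)``   — 0 at birth, rising to a full-risk plateau on
  [20, 45) years, falling back to 0 at 70;
* vitamin D ``D(x)``      — 1 below 10 nm/L, falling linearly to 0 at 30;
* BMI ``M(x)``            — 0.3 below 15 kg/m², rising to 1 at 30 (obesity);
* kinship ``K(x)``        — 1 at first degree, falling to 0 at the sixth.

All case arms are left-closed / right-open, and values beyond the last piece
take that piece's terminal constant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple

from .errors import MembershipDomainError, MSRiskError

logger = logging.getLogger(__name__)

FEMALE = "female"
MALE = "male"
SEXES = (FEMALE, MALE)

PHENOTYPES = ("RRMS", "SPMS", "PPMS")

#: factor index -> canonical column / factor name
FACTOR_NAMES: Mapping[int, str] = {
    1: "age_at_onset",
    2: "vitamin_d",
    3: "bmi",
    4: "kinship_degree",
}

#: physiologically implausible values above these trigger a logged warning
DEFAULT_SOFT_LIMITS: Mapping[str, float] = {
    "age_at_onset": 100.0,
    "vitamin_d": 200.0,
    "bmi": 60.0,
    "kinship_degree": 6.0,
}

Piece = Tuple[float, float, float, float]  # (lower, upper, value_at_lower, value_at_upper)


@dataclass(frozen=True)
class PiecewiseLinearMembership:
    """A fuzzy membership function given as contiguous linear pieces.

    Each piece ``(lower, upper, v_lo, v_hi)`` is interpolated linearly on the
    left-closed, right-open interval [lower, upper); above the last piece the
    function is constant at the last piece's ``v_hi``.
    """

    factor_name: str
    pieces: Tuple[Piece, ...]
    domain_min: float = 0.0
    soft_max: Optional[float] = None

    def __init__(self, factor_name, pieces, domain_min=0.0, soft_max=None):
        object.__setattr__(self, "factor_name", str(factor_name))
        object.__setattr__(self, "pieces", tuple(tuple(map(float, p)) for p in pieces))
        object.__setattr__(self, "domain_min", float(domain_min))
        object.__setattr__(self, "soft_max", None if soft_max is None else float(soft_max))
        self._validate()

    def _validate(self) -> None:
        if not self.pieces:
            raise MSRiskError(f"membership {self.factor_name!r} has no pieces")
        prev_upper = None
        for lo, hi, v_lo, v_hi in self.pieces:
            if not lo < hi:
                raise MSRiskError(
                    f"membership {self.factor_name!r}: piece [{lo}, {hi}) is empty"
                )
            if prev_upper is not None and lo != prev_upper:
                raise MSRiskError(
                    f"membership {self.factor_name!r}: pieces are not contiguous "
                    f"at {prev_upper} vs {lo}"
                )
            for v in (v_lo, v_hi):
                if not 0.0 <= v <= 1.0:
                    raise MSRiskError(
                        f"membership {self.factor_name!r}: value {v} outside [0, 1]"
                    )
            prev_upper = hi
        if self.pieces[0][0] != self.domain_min:
            raise MSRiskError(
                f"membership {self.factor_name!r}: first piece starts at "
                f"{self.pieces[0][0]}, expected domain_min={self.domain_min}"
            )

    def __call__(self, x: float) -> float:
        return self.evaluate(x)

    def evaluate(self, x: float) -> float:
        """Risk degree μ(x) ∈ [0, 1] for a factor value ``x``."""
        x = float(x)
        if x < self.domain_min:
            raise MembershipDomainError(self.factor_name, x, self.domain_min)
        if self.soft_max is not None and x > self.soft_max:
            logger.warning(
                "factor %s value %g exceeds plausibility limit %g; "
                "membership is still evaluated",
                self.factor_name, x, self.soft_max,
            )
        for lo, hi, v_lo, v_hi in self.pieces:
            if lo <= x < hi:
                return v_lo + (v_hi - v_lo) * (x - lo) / (hi - lo)
        # beyond the last piece: terminal constant
        return self.pieces[-1][3]

    def grid(self, xs: Sequence[float]) -> list:
        return [self.evaluate(x) for x in xs]


@dataclass(frozen=True)
class PatientProfile:
    """Sex plus the four factor values (x1..x4) and exclusion flags.

    ``kinship_degree=None`` encodes "no MS family history"; its risk degree
    is 0 (equivalent to a kinship distance of six degrees or more).
    """

    sex: str
    age_at_onset: float
    vitamin_d: float
    bmi: float
    kinship_degree: Optional[int] = None
    phenotype: str = "RRMS"
    has_comorbidity: bool = False
    is_smoker: bool = False

    def __post_init__(self):
        if self.sex not in SEXES:
            raise MSRiskError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.phenotype not in PHENOTYPES:
            raise MSRiskError(
                f"phenotype must be one of {PHENOTYPES}, got {self.phenotype!r}"
            )
        if self.age_at_onset < 0:
            raise MSRiskError(f"age_at_onset must be >= 0, got {self.age_at_onset}")
        if self.vitamin_d < 0:
            raise MSRiskError(f"vitamin_d must be >= 0, got {self.vitamin_d}")
        if self.bmi <= 0:
            raise MSRiskError(f"bmi must be > 0, got {self.bmi}")
        if self.kinship_degree is not None:
            k = self.kinship_degree
            if int(k) != k or not 1 <= int(k) <= 6:
                raise MSRiskError(
                    f"kinship_degree must be an integer in 1..6 or None, got {k!r}"
                )
            object.__setattr__(self, "kinship_degree", int(k))

    def factor_values(self) -> Tuple[float, float, float, Optional[int]]:
        return (self.age_at_onset, self.vitamin_d, self.bmi, self.kinship_degree)


@dataclass(frozen=True)
class RiskVector:
    """Per-factor risk degrees (r1, r2, r3, r4), each in [0, 1]."""

    r1: float
    r2: float
    r3: float
    r4: float

    def __post_init__(self):
        for name, v in zip(("r1", "r2", "r3", "r4"), self.as_tuple()):
            if not 0.0 <= v <= 1.0:
                raise MSRiskError(f"risk degree {name}={v} outside [0, 1]")

    def as_tuple(self) -> Tuple[float, float, float, float]:
        return (self.r1, self.r2, self.r3, self.r4)

    def __iter__(self):
        return iter(self.as_tuple())

    def __len__(self):
        return 4


def default_memberships() -> dict:
    """The four default membership functions, keyed by factor index 1..4.

    Loaded from the packaged config file (see :mod:`msrisk.config`), which
    encodes the canonical breakpoints exactly.
    """
    from .config import load_default_memberships

    return load_default_memberships()


def evaluate_membership(f: PiecewiseLinearMembership, x: float) -> float:
    """Functional alias for ``f.evaluate(x)``."""
    return f.evaluate(x)


def risk_vector(profile: PatientProfile, memberships: Optional[Mapping[int, PiecewiseLinearMembership]] = None) -> RiskVector:
    """Map a patient's factor values to the risk-degree vector r_i = μ_i(x_i)."""
    if memberships is None:
        memberships = default_memberships()
    x1, x2, x3, x4 = profile.factor_values()
    r4 = 0.0 if x4 is None else memberships[4].evaluate(x4)
    return RiskVector(
        memberships[1].evaluate(x1),
        memberships[2].evaluate(x2),
        memberships[3].evaluate(x3),
        r4,
    )
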