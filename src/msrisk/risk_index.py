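"""The overall MS risk index R_MS and its sensitivity surfaces.

R_MS(x1..x4) = C_m(μ1(x1)..μ4(x4)): the patient's factor values are mapped
to risk degrees by the fuzzy memberships and aggregated by the Choquet
integral under the sex-specific capacity.  The module also reproduces the
twelve reference patient cases p1–p12, one-factor sensitivity curves and
two-factor risk maps, and relative-change comparisons between cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._util import round_half_up
from .capacity import Capacity, reference_capacity
from .choquet import choquet_integral
from .errors import MSRiskError
from .membership import (
    FEMALE,
    MALE,
    SEXES,
    PatientProfile,
    PiecewiseLinearMembership,
    RiskVector,
    default_memberships,
    risk_vector,
)

#: the reference patient cases: case id -> (age, vitamin D, BMI, kinship degree)
CASE_FACTORS: Mapping[str, Tuple[float, float, float, int]] = {
    "p1": (15, 20, 15, 2),
    "p2": (30, 20, 15, 2),
    "p3": (15, 10, 15, 2),
    "p4": (30, 10, 15, 2),
    "p5": (30, 20, 15, 2),
    "p6": (30, 20, 30, 2),
    "p7": (30, 10, 15, 2),
    "p8": (30, 10, 30, 2),
    "p9": (30, 20, 15, 3),
    "p10": (30, 20, 15, 1),
    "p11": (30, 10, 15, 3),
    "p12": (30, 10, 15, 1),
}


@dataclass(frozen=True)
class RiskModel:
    """Memberships plus one capacity per sex; the full parameterisation."""

    memberships: Mapping[int, PiecewiseLinearMembership]
    capacities: Mapping[str, Capacity]

    def __post_init__(self):
        for sex in SEXES:
            if sex not in self.capacities:
                raise MSRiskError(f"model is missing a capacity for sex {sex!r}")
        n = next(iter(self.capacities.values())).n_factors
        if set(self.memberships) != set(range(1, n + 1)):
            raise MSRiskError(
                f"membership factor indices {sorted(self.memberships)} do not "
                f"match the capacity index set 1..{n}"
            )

    def capacity_for(self, sex: str) -> Capacity:
        try:
            return self.capacities[sex]
        except KeyError:
            raise MSRiskError(f"no capacity for sex {sex!r}")


def default_model() -> RiskModel:
    """The packaged model: canonical memberships + reference capacities."""
    return RiskModel(
        memberships=default_memberships(),
        capacities={sex: reference_capacity(sex) for sex in SEXES},
    )


@dataclass(frozen=True)
class PatientCase:
    """One reference case evaluated under both sex-specific capacities."""

    case_id: str
    factors: Tuple[float, float, float, Optional[int]]
    rms: Mapping[str, float]          # sex -> unrounded R_MS

    def rounded(self, sex: str, ndigits: int = 3) -> float:
        return round_half_up(self.rms[sex], ndigits)


@dataclass(frozen=True)
class RiskSeries:
    """R_MS along a grid of one factor, the other three held fixed."""

    sex: str
    varied_factor: int
    grid: Tuple[Tuple[float, float], ...]   # (x, R_MS) pairs, x increasing
    fixed_values: Mapping[int, float]

    def xs(self) -> np.ndarray:
        return np.array([x for x, _ in self.grid])

    def values(self) -> np.ndarray:
        return np.array([v for _, v in self.grid])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.grid, columns=["x", "rms"])


@dataclass(frozen=True)
class RiskMap:
    """R_MS over the Cartesian grid of two factors."""

    sex: str
    factor_pair: Tuple[int, int]
    row_grid: Tuple[float, ...]
    col_grid: Tuple[float, ...]
    matrix: np.ndarray                       # shape (len(row_grid), len(col_grid))
    fixed_values: Mapping[int, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.row_grid),
                            columns=list(self.col_grid))


def compute_rms(profile: PatientProfile, model: Optional[RiskModel] = None) -> float:
    """R_MS for one patient under the capacity matching the patient's sex."""
    if model is None:
        model = default_model()
    r = risk_vector(profile, model.memberships)
    return choquet_integral(r.as_tuple(), model.capacity_for(profile.sex))


def _rms_from_xs(xs: Mapping[int, float], sex: str, model: RiskModel) -> float:
    """R_MS from raw factor values (reals allowed, e.g. kinship 2.5 on curves)."""
    r = tuple(model.memberships[i].evaluate(xs[i]) for i in sorted(model.memberships))
    return choquet_integral(r, model.capacity_for(sex))


def case_table(model: Optional[RiskModel] = None) -> list:
    """The reference cases p1–p12 evaluated for both sexes (unrounded R_MS)."""
    if model is None:
        model = default_model()
    cases = []
    for case_id, (x1, x2, x3, x4) in CASE_FACTORS.items():
        rms = {
            sex: compute_rms(
                PatientProfile(sex=sex, age_at_onset=x1, vitamin_d=x2,
                               bmi=x3, kinship_degree=x4),
                model,
            )
            for sex in SEXES
        }
        cases.append(PatientCase(case_id=case_id, factors=(x1, x2, x3, x4), rms=rms))
    return cases


def case_frame(model: Optional[RiskModel] = None, ndigits: int = 3) -> pd.DataFrame:
    """Case table as a DataFrame with half-up rounded index columns."""
    rows = []
    for c in case_table(model):
        x1, x2, x3, x4 = c.factors
        rows.append({
            "case": c.case_id, "age": x1, "vitamin_d": x2, "bmi": x3,
            "kinship": x4,
            "rms_female": c.rounded(FEMALE, ndigits),
            "rms_male": c.rounded(MALE, ndigits),
        })
    return pd.DataFrame(rows).set_index("case")


def percent_change(case_a: PatientCase, case_b: PatientCase, sex: str) -> float:
    """Relative change 100·(R_MS(b) − R_MS(a))/R_MS(a), from unrounded values."""
    a, b = case_a.rms[sex], case_b.rms[sex]
    if a == 0:
        raise MSRiskError(f"baseline case {case_a.case_id} has R_MS = 0")
    return 100.0 * (b - a) / a


#: default fixed values mirroring the sensitivity-figure captions
DEFAULT_FIXED: Mapping[int, float] = {1: 30.0, 2: 20.0, 3: 15.0, 4: 2.0}


def _resolve_fixed(fixed_values, model: RiskModel) -> Dict[int, float]:
    if fixed_values is None:
        return dict(DEFAULT_FIXED)
    if isinstance(fixed_values, PatientProfile):
        x1, x2, x3, x4 = fixed_values.factor_values()
        return {1: x1, 2: x2, 3: x3, 4: 6.0 if x4 is None else float(x4)}
    return {int(k): float(v) for k, v in fixed_values.items()}


def risk_curve(model: Optional[RiskModel], sex: str, varied_factor: int,
               fixed_values=None, grid: Optional[Sequence[float]] = None,
               step: float = 0.5) -> RiskSeries:
    """One-factor sensitivity series; default grid spans the factor's pieces."""
    if model is None:
        model = default_model()
    if varied_factor not in model.memberships:
        raise MSRiskError(f"unknown factor index {varied_factor}")
    fixed = _resolve_fixed(fixed_values, model)
    mem = model.memberships[varied_factor]
    if grid is None:
        lo = mem.domain_min if varied_factor != 4 else 1.0
        hi = mem.pieces[-1][1]
        grid = np.arange(lo, hi + step / 2, step)
    xs = [float(x) for x in grid]
    if any(b <= a for a, b in zip(xs, xs[1:])):
        raise MSRiskError("grid values must be strictly increasing")
    if xs and xs[0] < mem.domain_min:
        raise MSRiskError(
            f"grid starts below the domain of factor {varied_factor} "
            f"({xs[0]} < {mem.domain_min})"
        )
    pairs = []
    for x in xs:
        vals = dict(fixed)
        vals[varied_factor] = x
        pairs.append((x, _rms_from_xs(vals, sex, model)))
    fixed.pop(varied_factor, None)
    return RiskSeries(sex=sex, varied_factor=varied_factor,
                      grid=tuple(pairs), fixed_values=fixed)


def risk_map(model: Optional[RiskModel], sex: str,
             factor_pair: Tuple[int, int],
             row_grid: Sequence[float], col_grid: Sequence[float],
             fixed_values=None) -> RiskMap:
    """Two-factor sensitivity surface on the Cartesian grid."""
    if model is None:
        model = default_model()
    fa, fb = factor_pair
    if fa == fb:
        raise MSRiskError("factor_pair must name two distinct factors")
    for f in (fa, fb):
        if f not in model.memberships:
            raise MSRiskError(f"unknown factor index {f}")
    fixed = _resolve_fixed(fixed_values, model)
    rows = [float(x) for x in row_grid]
    cols = [float(x) for x in col_grid]
    mat = np.empty((len(rows), len(cols)))
    for i, xa in enumerate(rows):
        for j, xb in enumerate(cols):
            vals = dict(fixed)
            vals[fa] = xa
            vals[fb] = xb
            mat[i, j] = _rms_from_xs(vals, sex, model)
    for f in (fa, fb):
        fixed.pop(f, None)
    return RiskMap(sex=sex, factor_pair=(fa, fb), row_grid=tuple(rows),
                   col_grid=tuple(cols), matrix=mat, fixed_values=fixed)
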