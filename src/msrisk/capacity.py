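"""Non-additive measures (capacities) over the factor index set.

A capacity assigns to every subset S of the factor index set N = {1..n} a
risk degree m(S) for the medical condition in which exactly the factors in
S are extremely abnormal, with m(∅) = 0 and monotonicity under inclusion.
Unlike a probability, m need not be additive — m({1,4}) may be smaller than
m({1}) + m({4}), expressing redundancy, or larger, expressing synergy — and
it is not required to be normalised to m(N) = 1.

This module validates user tables, ships the sex-specific reference
capacities, elicits a capacity from a patient cohort as the empirical
union-proportion of extreme factors, and provides the Möbius transform
(the interaction-coefficient representation used as an independent oracle
for the Choquet integral).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Iterable, Mapping, Optional, Sequence

from .errors import (
    CapacityCompletenessError,
    CapacityMonotonicityError,
    MSRiskError,
)
from .membership import (
    PatientProfile,
    PiecewiseLinearMembership,
    default_memberships,
    risk_vector,
)

Subset = frozenset


def all_subsets(n_factors: int):
    """Every subset of {1..n_factors}, by increasing size then lexicographic."""
    items = range(1, n_factors + 1)
    for k in range(n_factors + 1):
        for combo in combinations(items, k):
            yield frozenset(combo)


@dataclass(frozen=True)
class Capacity:
    """A validated monotone set function on subsets of {1..n_factors}."""

    n_factors: int
    values: Mapping[Subset, float]
    label: str = ""

    def __post_init__(self):
        object.__setattr__(
            self, "values",
            {frozenset(s): float(v) for s, v in self.values.items()},
        )
        _validate_table(self.values, self.n_factors)

    def __call__(self, subset) -> float:
        return self.values[frozenset(subset)]

    @property
    def total(self) -> float:
        """m(N), the upper scale of the capacity (not necessarily 1)."""
        return self.values[frozenset(range(1, self.n_factors + 1))]

    def is_additive(self, tol: float = 1e-12) -> bool:
        singles = {i: self.values[frozenset({i})] for i in range(1, self.n_factors + 1)}
        return all(
            abs(self.values[s] - sum(singles[i] for i in s)) <= tol
            for s in all_subsets(self.n_factors)
        )


@dataclass(frozen=True)
class MobiusRepresentation:
    """Interaction coefficients a(S) with m(S) = Σ_{B ⊆ S} a(B)."""

    n_factors: int
    coefficients: Mapping[Subset, float]

    def __post_init__(self):
        object.__setattr__(
            self, "coefficients",
            {frozenset(s): float(v) for s, v in self.coefficients.items()},
        )


def _monotonicity_violations(values, n_factors, tol=0.0):
    """Violating (S, S ∪ {i}) pairs; covering edges suffice for the lattice."""
    out = []
    for s in all_subsets(n_factors):
        for i in range(1, n_factors + 1):
            if i not in s:
                bigger = s | {i}
                if values[s] > values[bigger] + tol:
                    out.append(((s, bigger), values[s], values[bigger]))
    return out


def _validate_table(values, n_factors):
    expected = set(all_subsets(n_factors))
    got = set(values)
    if got != expected:
        missing = sorted(expected - got, key=lambda s: (len(s), sorted(s)))
        extra = sorted(got - expected, key=lambda s: (len(s), sorted(s)))
        parts = []
        if missing:
            parts.append(f"missing subsets {[set(s) or '{}' for s in missing]}")
        if extra:
            parts.append(f"unexpected subsets {[set(s) for s in extra]}")
        raise CapacityCompletenessError(
            f"capacity table must cover all {2 ** n_factors} subsets: "
            + "; ".join(parts)
        )
    if values[frozenset()] != 0.0:
        raise CapacityMonotonicityError(
            [], message=f"m(∅) must be 0, got {values[frozenset()]}"
        )
    for s, v in values.items():
        if not 0.0 <= v <= 1.0:
            raise MSRiskError(f"capacity value m({set(s) or '{}'})={v} outside [0, 1]")
    violations = _monotonicity_violations(values, n_factors)
    if violations:
        raise CapacityMonotonicityError(violations)


def repair_monotonicity(table: Mapping[Subset, float]) -> Dict[Subset, float]:
    """Minimal upward repair: running maximum over the subset lattice.

    Each m(S) is raised to the largest value among its subsets, visiting
    subsets in increasing size so the repair propagates. Intended for
    exploratory use on approximate user tables, not for reference data.
    """
    values = {frozenset(s): float(v) for s, v in table.items()}
    n = max((max(s) for s in values if s), default=0)
    repaired = dict(values)
    for s in sorted(values, key=lambda s: (len(s), sorted(s))):
        for i in range(1, n + 1):
            if i in s:
                smaller = s - {i}
                if repaired[smaller] > repaired[s]:
                    repaired[s] = repaired[smaller]
    repaired[frozenset()] = 0.0
    return repaired


def make_capacity(table: Mapping[Subset, float], label: str = "", *,
                  n_factors: Optional[int] = None, repair: bool = False) -> Capacity:
    """Validate a subset→value table into a Capacity.

    Raises CapacityCompletenessError if any subset is missing and
    CapacityMonotonicityError (listing the offending subset pairs) if the
    table is not monotone; with ``repair=True`` non-monotone tables are
    first lifted by :func:`repair_monotonicity`.
    """
    values = {frozenset(s): float(v) for s, v in table.items()}
    if n_factors is None:
        n_factors = max((max(s) for s in values if s), default=0)
    if repair:
        values = repair_monotonicity(values)
    return Capacity(n_factors=n_factors, values=values, label=label)


def reference_capacity(sex: str) -> Capacity:
    """The packaged sex-specific reference capacity (label 'female'/'male')."""
    from .config import load_default_capacity_tables

    tables = load_default_capacity_tables()
    if sex not in tables:
        raise MSRiskError(
            f"unknown sex label {sex!r}; available: {sorted(tables)}"
        )
    return make_capacity(tables[sex], label=sex, n_factors=4)


def extreme_indicator(profile: PatientProfile,
                      memberships: Optional[Mapping[int, PiecewiseLinearMembership]] = None,
                      threshold: float = 1.0) -> Subset:
    """Factors whose risk degree reaches the extremeness threshold τ.

    With the default τ = 1 these are the factors at full membership: age in
    [20, 45), vitamin D < 10 nm/L, BMI ≥ 30 kg/m², first-degree kinship.
    """
    if not 0.0 < threshold <= 1.0:
        raise MSRiskError(f"threshold must be in (0, 1], got {threshold}")
    r = risk_vector(profile, memberships)
    return frozenset(i for i, ri in enumerate(r, start=1) if ri >= threshold)


def elicit_capacity(cohort: Iterable[PatientProfile],
                    memberships: Optional[Mapping[int, PiecewiseLinearMembership]] = None,
                    threshold: float = 1.0,
                    label: str = "elicited") -> Capacity:
    """Empirical capacity: m(S) = share of patients with ≥1 extreme factor in S.

    The union-event rule makes m(∅) = 0 and monotonicity hold by
    construction for any cohort; under independent per-factor extremeness
    probabilities p_i it converges to m(S) = 1 − Π_{i∈S}(1 − p_i).
    """
    inner = getattr(cohort, "patients", None)
    patients: Sequence[PatientProfile] = list(inner) if inner is not None else list(cohort)
    if not patients:
        raise MSRiskError("cannot elicit a capacity from an empty cohort")
    if memberships is None:
        memberships = default_memberships()
    extremes = [extreme_indicator(p, memberships, threshold) for p in patients]
    n = len(extremes)
    values = {
        s: sum(1 for e in extremes if e & s) / n if s else 0.0
        for s in all_subsets(4)
    }
    return Capacity(n_factors=4, values=values, label=label)


def mobius_transform(m: Capacity) -> MobiusRepresentation:
    """Möbius coefficients a(S) = Σ_{B ⊆ S} (−1)^{|S\\B|} m(B)."""
    coeffs = {}
    for s in all_subsets(m.n_factors):
        items = sorted(s)
        total = 0.0
        for k in range(len(items) + 1):
            for combo in combinations(items, k):
                b = frozenset(combo)
                total += (-1) ** (len(s) - len(b)) * m.values[b]
        coeffs[s] = total
    return MobiusRepresentation(n_factors=m.n_factors, coefficients=coeffs)


def mobius_inverse(a: MobiusRepresentation, label: str = "") -> Capacity:
    """Reconstruct the capacity m(S) = Σ_{B ⊆ S} a(B)."""
    values = {}
    for s in all_subsets(a.n_factors):
        items = sorted(s)
        total = 0.0
        for k in range(len(items) + 1):
            for combo in combinations(items, k):
                total += a.coefficients[frozenset(combo)]
        values[s] = total
    # clip float dust so the reconstruction re-validates cleanly
    values[frozenset()] = 0.0
    values = {s: min(1.0, max(0.0, v)) for s, v in values.items()}
    return make_capacity(values, label=label, n_factors=a.n_factors, repair=True)
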