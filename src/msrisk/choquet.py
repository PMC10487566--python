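"""The discrete Choquet integral with respect to a capacity.

For a risk vector r = (r_1..r_n) and a capacity m, the integral sorts the
components non-decreasingly via a permutation σ and accumulates

    C_m(r) = Σ_k r_σ(k) · [ m({σ(k)..σ(n)}) − m({σ(k+1)..σ(n)}) ]

with the empty tail contributing m(∅) = 0.  For an additive m this reduces
to the weighted mean Σ m({i})·r_i; a non-additive m lets coinciding extreme
factors weigh more (or less) than the sum of their individual weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

from .capacity import Capacity
from .errors import MSRiskError


@dataclass(frozen=True)
class SortedPermutation:
    """σ sorting r non-decreasingly, with the nested tail sets of Eq. above."""

    order: Tuple[int, ...]                # factor indices, ascending by risk degree
    tail_sets: Tuple[frozenset, ...]      # {σ(k)..σ(n)} for k = 1..n

    @classmethod
    def from_vector(cls, r: Sequence[float]) -> "SortedPermutation":
        # stable tie-break by factor index: the integral is tie-invariant,
        # so this is a determinism convention only
        order = tuple(sorted(range(1, len(r) + 1), key=lambda i: (r[i - 1], i)))
        tails = tuple(frozenset(order[k:]) for k in range(len(r)))
        return cls(order=order, tail_sets=tails)


def choquet_integral(r: Sequence[float], m: Capacity) -> float:
    """C_m(r) for risk degrees r in [0, 1]^n and a capacity m on {1..n}."""
    r = tuple(float(v) for v in r)
    if len(r) != m.n_factors:
        raise MSRiskError(
            f"risk vector has {len(r)} components but capacity is on "
            f"{m.n_factors} factors"
        )
    for i, v in enumerate(r, start=1):
        if not 0.0 <= v <= 1.0:
            raise MSRiskError(f"risk degree r{i}={v} outside [0, 1]")
    perm = SortedPermutation.from_vector(r)
    empty = frozenset()
    total = 0.0
    for k, idx in enumerate(perm.order):
        tail = perm.tail_sets[k]
        next_tail = perm.tail_sets[k + 1] if k + 1 < len(perm.order) else empty
        total += r[idx - 1] * (m.values[tail] - m.values[next_tail])
    return total


def choquet_contributions(r: Sequence[float], m: Capacity):
    """Per-term breakdown (factor, risk degree, capacity increment, term)."""
    perm = SortedPermutation.from_vector(r)
    empty = frozenset()
    rows = []
    for k, idx in enumerate(perm.order):
        tail = perm.tail_sets[k]
        next_tail = perm.tail_sets[k + 1] if k + 1 < len(perm.order) else empty
        dm = m.values[tail] - m.values[next_tail]
        rows.append({
            "factor": idx,
            "risk_degree": float(r[idx - 1]),
            "tail_set": sorted(tail),
            "capacity_increment": dm,
            "term": float(r[idx - 1]) * dm,
        })
    return rows
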