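"""Capacities: validation, reference tables, elicitation, Möbius transform."""

import numpy as np
import pytest

from msrisk import (
    FEMALE,
    MALE,
    CapacityCompletenessError,
    CapacityMonotonicityError,
    MSRiskError,
    PatientProfile,
    elicit_capacity,
    extreme_indicator,
    make_capacity,
    mobius_inverse,
    mobius_transform,
    reference_capacity,
)
from msrisk.capacity import all_subsets, repair_monotonicity

from conftest import random_capacity


def _subsets4():
    return list(all_subsets(4))


class TestMakeCapacity:
    def test_additive_table_is_valid(self):
        cap = make_capacity({s: len(s) / 4 for s in _subsets4()}, n_factors=4)
        assert cap.is_additive()
        assert cap.total == 1.0

    def test_missing_subset_is_completeness_error(self):
        table = {s: len(s) / 4 for s in _subsets4()}
        del table[frozenset({1, 2})]
        with pytest.raises(CapacityCompletenessError, match="missing"):
            make_capacity(table, n_factors=4)

    def test_monotonicity_violation_names_the_pair(self):
        table = {s: len(s) / 4 for s in _subsets4()}
        table[frozenset({1})] = 0.1
        table[frozenset({1, 2})] = 0.05
        with pytest.raises(CapacityMonotonicityError) as err:
            make_capacity(table, n_factors=4)
        pairs = [pair for pair, _, _ in err.value.violations]
        assert (frozenset({1}), frozenset({1, 2})) in pairs

    def test_nonzero_empty_set_rejected(self):
        table = {s: len(s) / 4 for s in _subsets4()}
        table[frozenset()] = 0.01
        with pytest.raises(CapacityMonotonicityError, match="m\\(∅\\)"):
            make_capacity(table, n_factors=4)

    def test_repair_mode_lifts_violations(self):
        table = {s: len(s) / 4 for s in _subsets4()}
        table[frozenset({1, 2})] = 0.0
        cap = make_capacity(table, n_factors=4, repair=True)
        assert cap.values[frozenset({1, 2})] == 0.25  # lifted to max subset


class TestReferenceCapacities:
    @pytest.mark.parametrize("sex,subset,expected", [
        (FEMALE, frozenset(), 0.0),
        (FEMALE, frozenset({4}), 0.095),
        (FEMALE, frozenset({1}), 0.055),
        (FEMALE, frozenset({2, 4}), 0.110),
        (FEMALE, frozenset({1, 2, 3, 4}), 0.121),
        (MALE, frozenset({4}), 0.098),
        (MALE, frozenset({1, 2, 3}), 0.075),
        (MALE, frozenset({1, 2, 3, 4}), 0.117),
    ])
    def test_printed_values(self, sex, subset, expected):
        assert reference_capacity(sex).values[subset] == expected

    @pytest.mark.parametrize("sex", [FEMALE, MALE])
    def test_exhaustive_monotonicity(self, sex):
        """m(S1) <= m(S2) over every one of the 2^4 x 2^4 subset pairs."""
        cap = reference_capacity(sex)
        for s1 in _subsets4():
            for s2 in _subsets4():
                if s1 <= s2:
                    assert cap.values[s1] <= cap.values[s2]

    def test_unknown_sex_label(self):
        with pytest.raises(MSRiskError, match="unknown sex"):
            reference_capacity("unknown")


class TestExtremeIndicator:
    def test_three_extreme_factors(self, memberships):
        p = PatientProfile(sex=FEMALE, age_at_onset=30, vitamin_d=5, bmi=32,
                           kinship_degree=None)
        assert extreme_indicator(p, memberships) == frozenset({1, 2, 3})

    def test_single_extreme_factor(self, memberships):
        p = PatientProfile(sex=FEMALE, age_at_onset=30, vitamin_d=20, bmi=15,
                           kinship_degree=2)
        assert extreme_indicator(p, memberships) == frozenset({1})

    def test_threshold_out_of_range(self, memberships):
        p = PatientProfile(sex=FEMALE, age_at_onset=30, vitamin_d=20, bmi=15)
        for tau in (1.01, 0.0, -0.5):
            with pytest.raises(MSRiskError, match="threshold"):
                extreme_indicator(p, memberships, threshold=tau)


def _patient(extreme: frozenset) -> PatientProfile:
    """A patient whose extreme-factor set (at τ=1) is exactly `extreme`."""
    return PatientProfile(
        sex=FEMALE,
        age_at_onset=30 if 1 in extreme else 50,
        vitamin_d=5 if 2 in extreme else 25,
        bmi=32 if 3 in extreme else 20,
        kinship_degree=1 if 4 in extreme else None,
    )


class TestElicitCapacity:
    def test_union_proportion_rule_by_hand(self, memberships):
        """One in ten patients extreme only in kinship: every superset of {4}
        gets 0.10 and every subset disjoint from {4} gets 0."""
        cohort = [_patient(frozenset({4}))] + [_patient(frozenset())] * 9
        cap = elicit_capacity(cohort, memberships)
        for s in _subsets4():
            expected = 0.1 if 4 in s else 0.0
            assert cap.values[s] == pytest.approx(expected, abs=1e-12)

    def test_all_normal_cohort_gives_null_capacity(self, memberships):
        cap = elicit_capacity([_patient(frozenset())] * 5, memberships)
        assert all(v == 0.0 for v in cap.values.values())

    def test_empty_cohort_rejected(self, memberships):
        with pytest.raises(MSRiskError, match="empty"):
            elicit_capacity([], memberships)

    def test_always_monotone_on_random_cohorts(self, memberships):
        """The union rule yields a valid monotone capacity for any cohort
        (Capacity construction re-validates); 50 random cohorts."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            size = int(rng.integers(1, 40))
            cohort = [
                _patient(frozenset(
                    i for i in range(1, 5) if rng.random() < 0.4))
                for _ in range(size)
            ]
            cap = elicit_capacity(cohort, memberships)
            assert cap.values[frozenset()] == 0.0

    def test_recovers_independent_union_probabilities(self, memberships):
        """With independent per-factor extremeness probabilities p_i the
        elicited m(S) converges to 1 − Π_{i∈S}(1 − p_i); n = 5000, tol 0.02."""
        rng = np.random.default_rng(20230829)
        p = {1: 0.2, 2: 0.1, 3: 0.15, 4: 0.05}
        cohort = [
            _patient(frozenset(i for i in p if rng.random() < p[i]))
            for _ in range(5000)
        ]
        cap = elicit_capacity(cohort, memberships)
        for s in _subsets4():
            closed_form = 1.0 - np.prod([1 - p[i] for i in s]) if s else 0.0
            assert cap.values[s] == pytest.approx(closed_form, abs=0.02)


class TestMobius:
    def test_additive_capacity_has_singleton_coefficients_only(self):
        w = {1: 0.1, 2: 0.2, 3: 0.3, 4: 0.15}
        cap = make_capacity({s: sum(w[i] for i in s) for s in _subsets4()},
                            n_factors=4)
        a = mobius_transform(cap)
        for s in _subsets4():
            if len(s) == 1:
                assert a.coefficients[s] == pytest.approx(w[next(iter(s))], abs=1e-12)
            elif len(s) >= 2:
                assert a.coefficients[s] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("sex", [FEMALE, MALE])
    def test_reference_roundtrip_exact(self, sex):
        cap = reference_capacity(sex)
        back = mobius_inverse(mobius_transform(cap), label=sex)
        for s in _subsets4():
            assert back.values[s] == pytest.approx(cap.values[s], abs=1e-12)

    def test_random_roundtrip_exact(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            cap = random_capacity(rng)
            back = mobius_inverse(mobius_transform(cap))
            for s in _subsets4():
                assert back.values[s] == pytest.approx(cap.values[s], abs=1e-12)

    def test_total_mass_identity(self):
        rng = np.random.default_rng(13)
        cap = random_capacity(rng)
        a = mobius_transform(cap)
        assert sum(a.coefficients.values()) == pytest.approx(cap.total, abs=1e-12)


def test_repair_is_idempotent_and_minimal():
    rng = np.random.default_rng(3)
    table = {s: float(rng.uniform(0, 1)) for s in _subsets4()}
    table[frozenset()] = 0.0
    once = repair_monotonicity(table)
    assert repair_monotonicity(once) == once
    # repair never lowers a value
    assert all(once[s] >= table[s] for s in table)
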