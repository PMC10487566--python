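"""Exception types shared across the package."""


class MSRiskError(ValueError):
    """Base class for all validation errors raised by msrisk."""


class MembershipDomainError(MSRiskError):
    """A factor value lies below the domain of its membership function."""

    def __init__(self, factor_name: str, value: float, domain_min: float):
        self.factor_name = factor_name
        self.value = value
        self.domain_min = domain_min
        super().__init__(
            f"value {value!r} for factor {factor_name!r} is below the "
            f"domain minimum {domain_min!r}"
        )


class CapacityCompletenessError(MSRiskError):
    """A capacity table does not cover every subset of the index set."""


class CapacityMonotonicityError(MSRiskError):
    """A capacity table violates m(S1) <= m(S2) for some S1 ⊆ S2."""

    def __init__(self, violations, message=None):
        #: list of ((S1, S2), m1, m2) with S1 ⊆ S2 but m1 > m2
        self.violations = list(violations)
        if message is None:
            shown = ", ".join(
                f"(m({set(s1) or '{}'})={m1:g} > m({set(s2) or '{}'})={m2:g})"
                for (s1, s2), m1, m2 in self.violations[:5]
            )
            message = f"capacity is not monotone: {shown}"
        super().__init__(message)


class CohortFormatError(MSRiskError):
    """A cohort file is malformed (schema or row-level problems)."""

    def __init__(self, message, bad_rows=None):
        #: list of (line_number, reason) for row-level problems
        self.bad_rows = list(bad_rows or [])
        super().__init__(message)
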