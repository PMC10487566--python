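"""Cohort I/O, exclusion filtering, and descriptive summaries.

A cohort is a list of :class:`~msrisk.membership.PatientProfile` read from a
delimited text file with the canonical header. The exclusion filter removes,
in reporting order, patients with the primary-progressive phenotype, then
any comorbidity, then smokers; the retained cohort is the study population
on which capacities are elicited and summaries computed.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import CohortFormatError, MSRiskError
from .membership import FEMALE, MALE, PHENOTYPES, SEXES, PatientProfile

CANONICAL_COLUMNS = (
    "sex", "age_at_onset", "vitamin_d", "bmi", "kinship_degree",
    "phenotype", "has_comorbidity", "is_smoker",
)

_TRUE = {"1", "true", "yes", "y"}
_FALSE = {"0", "false", "no", "n", ""}


@dataclass(frozen=True)
class Cohort:
    """An immutable list of patients with a provenance note."""

    patients: Tuple[PatientProfile, ...]
    provenance: str = ""

    def __init__(self, patients, provenance=""):
        patients = tuple(patients)
        if not patients:
            raise MSRiskError("a cohort must contain at least one patient")
        object.__setattr__(self, "patients", patients)
        object.__setattr__(self, "provenance", str(provenance))

    def __len__(self):
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)


@dataclass(frozen=True)
class ExclusionReport:
    n_input: int
    n_excluded_ppms: int
    n_excluded_comorbidity: int
    n_excluded_smoker: int
    n_retained: int
    reasons: Tuple[Tuple[int, str], ...] = ()  # (patient index, first matching rule)

    def __post_init__(self):
        total = (self.n_excluded_ppms + self.n_excluded_comorbidity
                 + self.n_excluded_smoker + self.n_retained)
        if total != self.n_input:
            raise MSRiskError(
                f"exclusion counts ({total}) do not add up to n_input ({self.n_input})"
            )

    def to_json(self) -> str:
        return json.dumps({
            "n_input": self.n_input,
            "n_excluded_ppms": self.n_excluded_ppms,
            "n_excluded_comorbidity": self.n_excluded_comorbidity,
            "n_excluded_smoker": self.n_excluded_smoker,
            "n_retained": self.n_retained,
        }, indent=2)


@dataclass(frozen=True)
class VariableSummary:
    mean: float
    sd: float
    min: float
    max: float
    central95: Tuple[float, float]   # 2.5th–97.5th empirical percentiles


@dataclass(frozen=True)
class DescriptiveSummary:
    n: int
    n_female: int
    n_male: int
    sex_ratio_f_per_m: float                   # F per 1 M, 1 decimal
    variables: Mapping[str, VariableSummary]
    kinship_counts: Mapping[int, int]          # degree -> count
    n_no_kinship: int
    sd_convention: str = "sample (ddof=1)"

    def __post_init__(self):
        if sum(self.kinship_counts.values()) + self.n_no_kinship != self.n:
            raise MSRiskError("kinship counts do not sum to n")

    def to_json(self) -> str:
        return json.dumps({
            "n": self.n,
            "n_female": self.n_female,
            "n_male": self.n_male,
            "sex_ratio_f_per_m": self.sex_ratio_f_per_m,
            "sd_convention": self.sd_convention,
            "variables": {
                k: {"mean": v.mean, "sd": v.sd, "min": v.min, "max": v.max,
                    "central95": list(v.central95)}
                for k, v in self.variables.items()
            },
            "kinship_counts": {str(k): v for k, v in sorted(self.kinship_counts.items())},
            "n_no_kinship": self.n_no_kinship,
        }, indent=2)

    def to_text(self) -> str:
        lines = [
            f"N (patients)              {self.n}",
            f"Sex ratio (female/male)   {self.sex_ratio_f_per_m}/1.0",
        ]
        labels = {
            "age_at_onset": "Age at onset (years)",
            "vitamin_d": "Vitamin D (nm/L)",
            "bmi": "BMI (kg/m^2)",
        }
        for key, label in labels.items():
            v = self.variables[key]
            lines.append(
                f"{label:<26}{v.mean:.1f} ± {v.sd:.1f} "
                f"(central 95% {v.central95[0]:.1f}-{v.central95[1]:.1f}, "
                f"min {v.min:.1f}, max {v.max:.1f})"
            )
        lines.append(f"With MS family kinship    {sum(self.kinship_counts.values())}")
        for deg in range(1, 7):
            lines.append(f"  degree {deg}                {self.kinship_counts.get(deg, 0)}")
        lines.append(f"SD convention             {self.sd_convention}")
        return "\n".join(lines)


def _parse_bool(token: str, column: str, line: int) -> bool:
    t = str(token).strip().lower()
    if t in _TRUE:
        return True
    if t in _FALSE:
        return False
    raise CohortFormatError(
        f"line {line}: cannot parse boolean {token!r} in column {column!r}"
    )


def _sniff_delimiter(sample: str) -> str:
    return "\t" if "\t" in sample.splitlines()[0] else ","


def read_cohort(path, delimiter: Optional[str] = None,
                provenance: Optional[str] = None) -> Cohort:
    """Read a delimited cohort file (comma default, tab accepted).

    Raises CohortFormatError naming missing columns, or listing malformed
    rows with their line numbers.
    """
    if hasattr(path, "read"):
        text = path.read()
        source = provenance or "<stream>"
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
        source = provenance or str(path)
    if delimiter is None:
        delimiter = _sniff_delimiter(text)
    reader = csv.DictReader(io.StringIO(text), delimiter=delimiter)
    header = [h.strip() for h in (reader.fieldnames or [])]
    missing = [c for c in CANONICAL_COLUMNS if c not in header]
    if missing:
        raise CohortFormatError(f"cohort file is missing mandatory columns: {missing}")

    patients: List[PatientProfile] = []
    bad: List[Tuple[int, str]] = []
    for line, row in enumerate(reader, start=2):   # header is line 1
        try:
            kin_raw = (row.get("kinship_degree") or "").strip()
            patients.append(PatientProfile(
                sex=str(row["sex"]).strip().lower(),
                age_at_onset=float(row["age_at_onset"]),
                vitamin_d=float(row["vitamin_d"]),
                bmi=float(row["bmi"]),
                kinship_degree=None if kin_raw == "" else int(float(kin_raw)),
                phenotype=str(row["phenotype"]).strip().upper(),
                has_comorbidity=_parse_bool(row["has_comorbidity"], "has_comorbidity", line),
                is_smoker=_parse_bool(row["is_smoker"], "is_smoker", line),
            ))
        except CohortFormatError as exc:
            bad.append((line, str(exc)))
        except (MSRiskError, ValueError, TypeError, KeyError) as exc:
            bad.append((line, f"line {line}: {exc}"))
    if bad:
        shown = "; ".join(reason for _, reason in bad[:10])
        raise CohortFormatError(
            f"{len(bad)} malformed row(s): {shown}", bad_rows=bad
        )
    return Cohort(patients, provenance=source)


def cohort_frame(cohort: Cohort) -> pd.DataFrame:
    """Canonical DataFrame form of a cohort (kinship None -> empty cell)."""
    return pd.DataFrame([
        {
            "sex": p.sex,
            "age_at_onset": p.age_at_onset,
            "vitamin_d": p.vitamin_d,
            "bmi": p.bmi,
            "kinship_degree": "" if p.kinship_degree is None else p.kinship_degree,
            "phenotype": p.phenotype,
            "has_comorbidity": p.has_comorbidity,
            "is_smoker": p.is_smoker,
        }
        for p in cohort
    ], columns=list(CANONICAL_COLUMNS))


def write_cohort(cohort: Cohort, path, delimiter: str = ",") -> None:
    """Write the canonical delimited form (round-trip stable with read_cohort)."""
    frame = cohort_frame(cohort)
    if hasattr(path, "write"):
        frame.to_csv(path, sep=delimiter, index=False)
    else:
        frame.to_csv(str(path), sep=delimiter, index=False)


def apply_exclusions(cohort: Cohort) -> Tuple[Optional[Cohort], ExclusionReport]:
    """Filter PPMS, then comorbidity, then smoking (first-match attribution)."""
    retained: List[PatientProfile] = []
    reasons: List[Tuple[int, str]] = []
    counts = {"ppms": 0, "comorbidity": 0, "smoker": 0}
    for i, p in enumerate(cohort):
        if p.phenotype == "PPMS":
            counts["ppms"] += 1
            reasons.append((i, "ppms"))
        elif p.has_comorbidity:
            counts["comorbidity"] += 1
            reasons.append((i, "comorbidity"))
        elif p.is_smoker:
            counts["smoker"] += 1
            reasons.append((i, "smoker"))
        else:
            retained.append(p)
    report = ExclusionReport(
        n_input=len(cohort),
        n_excluded_ppms=counts["ppms"],
        n_excluded_comorbidity=counts["comorbidity"],
        n_excluded_smoker=counts["smoker"],
        n_retained=len(retained),
        reasons=tuple(reasons),
    )
    if not retained:
        import logging

        logging.getLogger(__name__).warning(
            "all %d patients were excluded; no retained cohort", len(cohort)
        )
        return None, report
    out = Cohort(retained, provenance=f"{cohort.provenance} [post-exclusion]")
    return out, report


def describe(cohort: Cohort) -> DescriptiveSummary:
    """Per-variable mean/SD/min/max/central-95% plus kinship tabulation."""
    frame = pd.DataFrame([
        {"sex": p.sex, "age_at_onset": p.age_at_onset,
         "vitamin_d": p.vitamin_d, "bmi": p.bmi,
         "kinship_degree": p.kinship_degree}
        for p in cohort
    ])
    n = len(frame)
    n_f = int((frame["sex"] == FEMALE).sum())
    n_m = int((frame["sex"] == MALE).sum())
    ratio = round(n_f / n_m, 1) if n_m else float("inf")
    variables: Dict[str, VariableSummary] = {}
    for col in ("age_at_onset", "vitamin_d", "bmi"):
        x = frame[col].to_numpy(dtype=float)
        lo, hi = np.percentile(x, [2.5, 97.5])
        variables[col] = VariableSummary(
            mean=float(np.mean(x)),
            sd=float(np.std(x, ddof=1)) if n > 1 else 0.0,
            min=float(np.min(x)),
            max=float(np.max(x)),
            central95=(float(lo), float(hi)),
        )
    kin = frame["kinship_degree"].dropna().astype(int)
    counts = {int(d): int(c) for d, c in kin.value_counts().sort_index().items()}
    return DescriptiveSummary(
        n=n, n_female=n_f, n_male=n_m, sex_ratio_f_per_m=ratio,
        variables=variables, kinship_counts=counts,
        n_no_kinship=n - int(kin.shape[0]),
    )
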