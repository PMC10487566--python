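"""Seeded generator of synthetic cohorts emulating the study population.

No raw patient data are available, so every data-driven code path is
exercised on synthetic cohorts whose marginals emulate the published
summaries: 700 enrolled patients (471 F / 229 M), per-sex exclusion-flag
counts (PPMS 31 F / 25 M, comorbidity 6 F / 8 M, smoking 14 F / 20 M),
truncated-normal age at onset, vitamin D and BMI, and exact kinship-degree
counts (12/26/8/8/6/5 for degrees 1-6) among the 596 retained patients.

Continuous marginals are modelled as independent truncated normals; the
published mean/SD are interpreted as the location/scale of the underlying
normal before truncation, so sample moments match the truncated-normal
closed form rather than the nominal figures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
from scipy import stats

from .cohort import Cohort
from .errors import MSRiskError
from .membership import FEMALE, MALE, PatientProfile

#: fixed seed of the packaged regression fixture
FIXTURE_SEED = 20230829

#: probability that a retained patient carries the secondary-progressive
#: phenotype (the study pools RRMS and SPMS; no split is published)
SPMS_SHARE = 0.15


@dataclass(frozen=True)
class TruncNormSpec:
    """Location/scale of the pre-truncation normal plus hard bounds."""

    mean: float
    sd: float
    min: float
    max: float

    def __post_init__(self):
        if not self.min < self.max:
            raise MSRiskError(f"truncation bounds require min < max, got "
                              f"[{self.min}, {self.max}]")
        if self.sd <= 0:
            raise MSRiskError(f"sd must be positive, got {self.sd}")

    def _frozen(self):
        a = (self.min - self.mean) / self.sd
        b = (self.max - self.mean) / self.sd
        return stats.truncnorm(a, b, loc=self.mean, scale=self.sd)

    def draw(self, size: int, rng: np.random.Generator) -> np.ndarray:
        return self._frozen().rvs(size=size, random_state=rng)

    def truncated_mean(self) -> float:
        """Closed-form mean of the truncated normal (the generator's target)."""
        return float(self._frozen().mean())

    def truncated_sd(self) -> float:
        return float(self._frozen().std())


@dataclass(frozen=True)
class CohortSpec:
    """Full parameterisation of one synthetic cohort."""

    n_female: int = 471
    n_male: int = 229
    age: TruncNormSpec = field(default_factory=lambda: TruncNormSpec(32.0, 11.8, 11.0, 65.0))
    vitamin_d: TruncNormSpec = field(default_factory=lambda: TruncNormSpec(28.0, 8.9, 10.0, 52.0))
    bmi: TruncNormSpec = field(default_factory=lambda: TruncNormSpec(17.0, 8.6, 14.3, 36.7))
    #: kinship-degree counts among *retained* patients; the rest have none
    kinship_counts: Mapping[int, int] = field(
        default_factory=lambda: {1: 12, 2: 26, 3: 8, 4: 8, 5: 6, 6: 5})
    #: (female, male) counts of each injected exclusion flag
    ppms: Tuple[int, int] = (31, 25)
    comorbidity: Tuple[int, int] = (6, 8)
    smoker: Tuple[int, int] = (14, 20)
    spms_share: float = SPMS_SHARE
    seed: int = FIXTURE_SEED

    @property
    def n_total(self) -> int:
        return self.n_female + self.n_male

    @property
    def n_retained(self) -> int:
        flags = sum(self.ppms) + sum(self.comorbidity) + sum(self.smoker)
        return self.n_total - flags

    def __post_init__(self):
        for name in ("n_female", "n_male"):
            if getattr(self, name) < 0:
                raise MSRiskError(f"{name} must be non-negative")
        for sex_idx, n_sex in ((0, self.n_female), (1, self.n_male)):
            flagged = self.ppms[sex_idx] + self.comorbidity[sex_idx] + self.smoker[sex_idx]
            if flagged > n_sex:
                raise MSRiskError(
                    f"injected flags ({flagged}) exceed the number of "
                    f"{'female' if sex_idx == 0 else 'male'} patients ({n_sex})"
                )
        if any(c < 0 for c in self.kinship_counts.values()):
            raise MSRiskError("kinship counts must be non-negative")
        if sum(self.kinship_counts.values()) > self.n_retained:
            raise MSRiskError(
                "kinship counts exceed the number of retained patients"
            )
        if not 0.0 <= self.spms_share <= 1.0:
            raise MSRiskError("spms_share must be in [0, 1]")


def generate_cohort(spec: Optional[CohortSpec] = None) -> Cohort:
    """Draw one cohort; deterministic for a fixed spec (including its seed).

    Discrete constraints (per-sex totals, flag counts, kinship counts) are
    met exactly, not just in expectation; continuous variables respect their
    truncation bounds by construction.
    """
    if spec is None:
        spec = CohortSpec()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_total

    sexes = np.array([FEMALE] * spec.n_female + [MALE] * spec.n_male, dtype=object)

    # flag assignment: within each sex, the first ppms+comorbidity+smoker
    # slots (of a seeded permutation) receive one flag each, disjointly
    phenotype = np.array(["RRMS"] * n, dtype=object)
    comorbid = np.zeros(n, dtype=bool)
    smoker = np.zeros(n, dtype=bool)
    for sex_idx, sex in enumerate((FEMALE, MALE)):
        idx = np.flatnonzero(sexes == sex)
        idx = rng.permutation(idx)
        k1 = spec.ppms[sex_idx]
        k2 = k1 + spec.comorbidity[sex_idx]
        k3 = k2 + spec.smoker[sex_idx]
        phenotype[idx[:k1]] = "PPMS"
        comorbid[idx[k1:k2]] = True
        smoker[idx[k2:k3]] = True

    retained_mask = (phenotype != "PPMS") & ~comorbid & ~smoker
    retained_idx = np.flatnonzero(retained_mask)

    # exact kinship-degree counts among retained patients; others none
    kinship = np.full(n, -1)  # -1 encodes "no MS family kinship"
    pool = rng.permutation(retained_idx)
    pos = 0
    for degree in sorted(spec.kinship_counts):
        count = spec.kinship_counts[degree]
        kinship[pool[pos:pos + count]] = degree
        pos += count

    # RRMS/SPMS split among non-PPMS patients
    spms_draw = rng.random(n) < spec.spms_share
    phenotype[(phenotype != "PPMS") & spms_draw] = "SPMS"

    age = spec.age.draw(n, rng)
    vitd = spec.vitamin_d.draw(n, rng)
    bmi = spec.bmi.draw(n, rng)

    order = rng.permutation(n)
    patients = [
        PatientProfile(
            sex=str(sexes[i]),
            age_at_onset=float(age[i]),
            vitamin_d=float(vitd[i]),
            bmi=float(bmi[i]),
            kinship_degree=None if kinship[i] < 0 else int(kinship[i]),
            phenotype=str(phenotype[i]),
            has_comorbidity=bool(comorbid[i]),
            is_smoker=bool(smoker[i]),
        )
        for i in order
    ]
    return Cohort(patients, provenance=f"synthetic(seed={spec.seed})")


def fixture_700(seed: int = FIXTURE_SEED) -> Cohort:
    """The packaged 700-patient regression fixture (default spec, fixed seed)."""
    return generate_cohort(CohortSpec(seed=seed))
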