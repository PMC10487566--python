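# Methods

## The model

A patient's medical condition is the vector (x₁, x₂, x₃, x₄): age at MS
onset (years), serum vitamin D (nm/L), BMI (kg/m²), and the degree of MS
family kinship (1 = parent–child … 6 = children of parents' cousins, or
none). Each factor is mapped to a risk degree rᵢ = μᵢ(xᵢ) ∈ [0, 1] by a
piecewise-linear fuzzy membership function; the overall index
R_MS = C_m(r₁..r₄) is the Choquet integral of the risk vector with respect
to a sex-specific capacity m on subsets of the factor index set
N = {1, 2, 3, 4}.

The capacity is the model's expression of factor interaction: m(S) is the
risk degree of the condition in which exactly the factors in S are
extremely abnormal. It satisfies m(∅) = 0 and monotonicity under inclusion
but is deliberately *not* additive and *not* normalised — the packaged
reference tables have m(N) = 0.121 (female) and 0.117 (male), and all
downstream code treats m(N) as a free upper scale, so R_MS lives in
[0, m(N)].

The premium layer is linear: β = α + R_MS·(1 − α) with α the population
prevalence (default 122 000 affected / 60 359 546 inhabitants ≈ 0.002; the
ratio is used as-is and only *printed* at 3 decimals), and
P_MS = p_min + β·(p_max − p_min). Currency is computed in doubles and
rounded half-up to 2 decimals at the reporting boundary only.

## Membership semantics

All case arms are left-closed / right-open ([lower, upper)), exactly
mirroring conditions of the form "if 20 ≤ x < 45"; beyond the last piece
the function continues at that piece's terminal constant (0 for age,
vitamin D and kinship; 1 for BMI). With these conventions all four
functions are continuous on x ≥ 0; the age function's isolated "0 at x = 0"
case coincides with the limit of its first linear arm, so no special
handling is needed. Values beyond physiological plausibility are accepted
(the functions are total on [0, ∞)) but logged as warnings above
configurable soft limits (age 100, vitamin D 200, BMI 60).

Kinship is restricted to integer degrees 1–6 or none on patient profiles;
"no family history" maps to risk degree 0, which is where K(x) vanishes
anyway (x ≥ 6). Real-valued kinship inputs in [1, 6] are accepted on
sensitivity curves and maps, where the continuous membership is the object
of interest. Degree 0 (the interval [0, 1) where K = 1) has no clinical
meaning and is not accepted on profiles.

## Capacity validation, elicitation, and the Möbius oracle

User-supplied capacity tables are validated for completeness (all 2ⁿ
subsets), m(∅) = 0, range, and monotonicity; monotonicity is checked on
covering pairs (S, S ∪ {i}), which implies the full partial order, and
violations are reported pair by pair. A documented repair mode (running
maximum over the subset lattice in increasing-size order) is available for
exploratory tables; reference data are never repaired.

Elicitation from a cohort uses the union-proportion rule: m(S) is the share
of patients with at least one factor of S at membership ≥ τ (default
τ = 1.0, the full-membership core: age in [20, 45), vitamin D < 10, BMI
≥ 30, first-degree kinship). This rule is monotone by construction for any
cohort, and under independent per-factor extremeness probabilities pᵢ it
converges to 1 − Π_{i∈S}(1 − pᵢ); the test suite verifies that recovery on
a 5 000-patient synthetic cohort to within 0.02. Alternative literal
readings of "proportion of the pairs of factors" (exactly-S, or all-of-S)
were considered and rejected: both are inconsistent with the monotone
structure of the packaged reference tables. The reference tables themselves
ship verbatim as inputs; no claim is made that the union rule regenerates
them, since the underlying patient data are not available.

The Möbius transform a(S) = Σ_{B⊆S} (−1)^{|S\B|} m(B) is provided as an
equivalent representation and serves as the independent test oracle for the
Choquet integral via C_m(r) = Σ_S a(S)·min_{i∈S} rᵢ; a second independent
oracle uses the level-increment form. The sorted-sum implementation breaks
ties in σ by factor index — a pure determinism convention, since the
integral is provably invariant to the choice among admissible sorting
permutations (property-tested).

## Synthetic cohorts

No raw patient data are published, so the generator emulates the study
population's printed structure: 700 enrolled (471 F / 229 M); per-sex
exclusion flags injected disjointly and exactly (PPMS 31 F / 25 M,
comorbidity 6 F / 8 M, smoking 14 F / 20 M), leaving 596 retained; kinship
degrees 1–6 assigned exactly as 12/26/8/8/6/5 among the retained, none
elsewhere; age, vitamin D and BMI drawn as independent truncated normals
with the printed mean/SD as pre-truncation location/scale and the printed
min/max as bounds (age 32 ± 11.8 on [11, 65]; vitamin D 28 ± 8.9 on
[10, 52]; BMI 17 ± 8.6 on [14.3, 36.7]). Everything is driven by one
`numpy` generator seed; identical seeds give byte-identical cohorts.

What the generator does **not** emulate: correlation between the continuous
variables (only univariate summaries are published, so independence is
assumed); the unpublished RRMS/SPMS split (SPMS is drawn at a typical 15%
share — nothing downstream depends on it, as the exclusion logic only
distinguishes PPMS); and the true shape of the BMI distribution. The
printed BMI summary (mean 17, range 14.3–36.7) implies heavy right skew
that a truncated normal cannot reproduce: with the printed parameters the
closed-form truncated mean is ≈ 21.6, and the generator's samples match
that closed form (tested at n = 10 000 within two standard errors) rather
than the nominal 17. Age and vitamin D land within 1 unit of their printed
means. Passing tests therefore demonstrate correctness of the pipeline
mechanics on realistically structured data, not distributional fidelity to
the unpublished raw cohort.

The retained cohort implied by the printed per-sex counts is 420 F / 176 M,
a ratio of 2.4 : 1 — the source also prints 2.1 : 1.0; the counts are
honoured exactly and the summary reports the ratio it computes.

## Cohort handling

Exclusion filtering removes, with first-match attribution in reporting
order, PPMS patients, then patients with any comorbidity, then smokers;
total retention is invariant to the rule order, only the attribution
follows it. Descriptive summaries report mean, sample SD (ddof = 1, the
convention is stated in the output metadata since the source leaves it
unstated), min, max, and a central 95% interval computed as the
2.5th–97.5th empirical percentiles. The latter label is deliberate: the
printed "CI 95%" ranges (e.g. 20–45 years around a mean of 32 with SD
11.8) are consistent with neither a confidence interval of the mean nor a
±1.96·SD band, and are treated as central empirical ranges.

Cohort files are plain delimited text (comma default, tab accepted) with a
canonical header; write∘read is the identity on canonical form, and
malformed rows are reported with their line numbers.

## Problem sizes and numerical choices

All golden comparisons against printed 3-decimal values use half-up
rounding (the convention printed tables follow); library values are kept
unrounded. Property suites run on 1 000 random capacity/vector instances
(capacities drawn uniformly and lifted to monotonicity by lattice running
maximum); elicitation consistency uses a 5 000-patient cohort; generator
moment recovery uses 10 000 draws. Sensitivity curves and maps default to a
0.5-unit grid step in natural units. These sizes keep the whole suite
within seconds while leaving sampling error well below the asserted
tolerances.

## Known discrepancies in the source material

- **Reference case p9, female.** The sorted-sum integral with the published
  female capacity gives exactly 0.0908 for (age 30, vitamin D 20, BMI 15,
  kinship 3); the source prints 0.090. No rounding convention reconciles
  the two (truncation would also corrupt the printed p2 and p3 values), so
  the recomputed value rounds to 0.091 and the corresponding golden-table
  assertion is left failing by 0.001 rather than masked. The male p9 value
  and the other 22 printed cells reproduce exactly.
- **The "typical subject" loading inputs.** The published β values are
  derived from R_MS inputs of 0.100818 (female) and 0.09529266 (male) for
  the profile (30, 20, 15, 2), which the model computes as 0.0988/0.0969
  (the printed p2 row). The premium layer therefore takes R_MS as an input
  and reproduces β_f = 0.1026 and β_m = 0.0971 from the published inputs;
  the origin of 0.100818 is not recoverable.
- **Reference capacities.** The exact counting rule behind the published
  capacity tables cannot be recovered from the text; they are treated as
  ground-truth model inputs, and elicitation is an independent, documented
  rule rather than an attempted reconstruction.

## Limitations

The model is cross-sectional and population-specific: membership
breakpoints and capacities reflect one retrospective single-centre cohort,
and no out-of-sample predictive validity is claimed. Longitudinal risk,
calibration against incidence data, EBV serostatus and smoking as model
factors, and non-linear membership shapes are out of scope.
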