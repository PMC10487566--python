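# msrisk

A multi-criterial risk index for Multiple Sclerosis (MS), built from fuzzy
risk-factor memberships aggregated by the **Choquet integral** under a
sex-specific **non-additive measure**, with a derived health-insurance
premium.

MS risk factors — age at onset, serum vitamin D, body-mass index, and the
degree of MS family kinship — are individually weak predictors but interact:
two coincident abnormal factors carry more than the sum of their separate
weights. A weighted mean cannot express that; a Choquet integral with
respect to a capacity can. This package is for epidemiologists and actuarial
analysts who want a transparent, reproducible implementation of that model:
the membership functions, the reference capacities, the aggregation, cohort
handling (exclusion filters, descriptive summaries, capacity elicitation),
a synthetic-cohort generator for testing, and the premium formula.

## Model

Each factor value `x_i` is mapped to a risk degree `r_i = μ_i(x_i) ∈ [0, 1]`
by a piecewise-linear fuzzy membership function:

- age at onset `A(x)`: 0 at 0, linear to 1 at 20, plateau at 1 on [20, 45),
  linear to 0 at 70, then 0;
- vitamin D `D(x)`: 1 below 10 nm/L, linear to 0 at 30 nm/L, then 0;
- BMI `M(x)`: 0.3 below 15 kg/m², linear to 1 at 30 kg/m² (obesity), then 1;
- kinship `K(x)`: 1 up to first degree, linear to 0 at the sixth degree.

A capacity `m` assigns to every subset `S ⊆ {1,2,3,4}` the risk degree of
the condition "exactly the factors in S are extremely abnormal", with
`m(∅) = 0` and monotonicity under inclusion (no additivity assumed). The
overall index is the Choquet integral

```
R_MS(x₁..x₄) = C_m(r₁..r₄) = Σₖ r_σ(k) · [ m({σ(k)..σ(4)}) − m({σ(k+1)..σ(4)}) ]
```

with σ sorting the risk degrees non-decreasingly. Sex enters through the
capacity: separate female and male reference tables are packaged. The
insurance premium is `P_MS = p_min + β·(p_max − p_min)` with the individual
loading `β = α + R_MS·(1 − α)`, where α is the population prevalence
(packaged default: the Italian ISTAT figures, 122 000 / 60 359 546 ≈ 0.002).

Capacities can also be *elicited* from a cohort: `m(S)` is the empirical
share of patients with at least one factor of `S` at full (or
near-full, configurable threshold) membership — a rule that is monotone by
construction and converges to the union probability `1 − Π_{i∈S}(1 − p_i)`
under independent per-factor extremeness.

## Worked example

A 30-year-old woman with vitamin D at 10 nm/L, BMI 15 and a second-degree
MS family kinship:

```sh
$ msrisk risk --sex F --age 30 --vitd 10 --bmi 15 --kinship 2
{
  "risk_vector": [1.0, 1.0, 0.3, 0.8],
  "permutation": [3, 4, 1, 2],
  "rms": 0.11,
  "rms_rounded": 0.11,
  ...
}
```

The risk vector says age (1.0) and vitamin D (1.0) are fully in their risk
ranges, BMI 15 carries the baseline degree 0.3, and second-degree kinship
0.8. Aggregated under the female capacity the index is **R_MS = 0.110** —
against 0.099 for the same patient with normal vitamin D (20 nm/L), the
low vitamin D adds 0.011 of interaction-aware risk.

The corresponding premium quote on a 100–1100 band:

```sh
$ msrisk premium --sex F --age 30 --vitd 10 --bmi 15 --kinship 2 \
      --pmin 100 --pmax 1100
{
  "alpha": 0.002021221299444499,
  "rms": 0.11,
  "beta": 0.11179888695650561,
  "premium": 211.8
}
```

i.e. β = 0.002 + 0.998·0.110 ≈ 0.112 and P_MS = 100 + β·1000 ≈ 211.80.

Other entry points: `msrisk cases` (the twelve reference patient cases as
CSV), `msrisk curve` / `msrisk map` (one- and two-factor sensitivity series),
`msrisk simulate` (seeded synthetic 700-patient cohort), `msrisk describe`
(exclusion filter + descriptive summary), `msrisk elicit` (capacity from a
cohort file). Everything is equally available as library functions
(`msrisk.compute_rms`, `msrisk.quote`, `msrisk.elicit_capacity`, ...).

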