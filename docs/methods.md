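# Methods

## Data model

The unit of analysis is a thyroid nodule with a binary FNA cytology
reference class (`malignant` / `benign`) and one binary call
(`suspicious` / `benign`) per ultrasound modality. The emulated study
conditions are a cohort of 325 nodules in 250 patients (1–4 nodules per
patient, mean 1.3), FNA-malignant prevalence 55/325 ≈ 0.169, and nodule
sizes around 1.54–1.56 cm (SD 0.16–0.17).

Confusion counts are stored under the source table's own column names.
Two of those labels are idiosyncratic: "false positive suspicious
malignant nodules" counts FNA-malignant nodules the modality called
benign (standard **false negatives**), and "false positive benign
nodules" counts FNA-benign nodules called suspicious (standard **false
positives**). This is the only reading under which each modality's rows
sum to the FNA margins (55 malignant, 270 benign), so it is adopted and
the standard synonyms (`fn`, `fp`, `tn`, `tp`) are exposed as
properties. Similarly the table's "accuracy" — correctly identified
benign nodules over all FNA-benign nodules — is standard specificity;
the package computes it under both names.

## Synthetic cohort generator

`generate_cohort(SynthConfig)` draws, per nodule:

- **FNA class** ~ Bernoulli(prevalence).
- **Calls**: each modality has an operating profile
  (P(suspicious | malignant), P(suspicious | benign)); the call is
  suspicious when a uniform variate falls below the profile rate for the
  nodule's class. Cross-modality dependence uses a rank-coupling
  mixture: with probability `agreement` the modality reuses a
  nodule-level shared uniform, otherwise an independent one.
  `agreement = 0` gives independent calls; `agreement = 1` gives
  comonotone calls (identical profiles then produce identical call
  vectors). The default `agreement = 0.7` reflects that the three reads
  are made on the same images by the same readers and the combined read
  is a function of the other two, so strong but imperfect dependence is
  the realistic regime; per-modality margins are invariant to it, so no
  reported statistic depends on this choice.
- **Sizes** ~ Normal(mean, SD) truncated at zero (defaults 1.55 ±
  0.165 cm, the midpoint of the two published arms).
- **Patients**: nodule counts per patient follow a geometric
  distribution capped at 4 with mean ≈ 1.3, adjusted ±1 to hit the
  configured totals exactly.
- **Demographics** (age 19–71 mean 48.55 SD 7.54, 79% female, 91/8/1%
  Han/Mongolian/Tibetan, 5% family history) are generated as inert
  per-patient annotations; no statistic uses them.

All randomness flows from the single `seed`; identical configs give
identical cohorts.

What the generator does *not* emulate: within-patient correlation of
FNA classes or calls beyond the shared patient id (the study states
none), any dependence of calls on nodule size, reader variability, and
the underlying image features — the grayscale/Doppler imaging criteria
exist only as the binary call labels. Tests passing on synthetic
cohorts therefore validate the statistical machinery, not the imaging
claims.

`exact_paper_cohort()` is a deterministic cohort whose three confusion
tables match the published counts cell-for-cell. The per-modality
margins underdetermine the 2×2×2×2 joint distribution of calls, so the
construction uses **maximal overlap**: ordering the 55 malignant
nodules, the combined modality's 38 suspicious calls contain the
Doppler 33, which contain the grayscale 31 (and analogously the Doppler
22 over-calls among the 270 benign nodules contain the grayscale 20 and
the combined 11). Every per-modality statistic in the package is
invariant to this convention. Sizes are deterministic truncated-normal
quantiles; 75 of the 250 patients carry two nodules (mean 1.3).

## Diagnostic parameters and tests

- Sensitivity = TP-suspicious / 55-analog; "accuracy" (specificity) =
  TP-benign / 270-analog; PPV and NPV from the standard 2×2 identities.
  Ratios with zero denominators return NaN (logged) rather than raising
  so batch reports over degenerate simulated cohorts complete.
- **Chi-square**: each modality's detection count is compared with the
  FNA reference count as two arms of `n = 325`, i.e. the 2×2 table
  `[[c_mod, n − c_mod], [c_ref, n − c_ref]]`, with the Yates continuity
  correction (via `scipy.stats.chi2_contingency`). The source never
  states the construction; this one is pinned because it reproduces all
  six printed p-values (0.008, 0.016, 0.073, 0.062, 0.041, 0.314) to 3
  decimals, and the uncorrected statistic does not. Equal counts return
  (0, 1) exactly; a table with a zero expected cell raises. (One
  inconsistency in the source: its accuracy row repeats the TP-benign
  comparisons but prints 0.067 where its own TP-benign row prints
  0.041; the computed value is 0.041.)
- **Welch t** (unequal variances) for size comparisons, two-sided, via
  `scipy.stats.ttest_ind` / `ttest_ind_from_stats`. From the published
  size summaries (1.54 ± 0.16 vs 1.56 ± 0.17 cm, n = 325 per arm) the
  test gives p ≈ 0.123, not the published 0.872; that value is not
  recoverable from the printed summaries and is documented rather than
  asserted.

## Beneficial score

`BS(p_t) = TP/n − (FP_s/n) · p_t/(1 − p_t)` — net benefit with the
threshold-odds weight (`risk_of_underdiagnosis`). Conventions, both
pinned by the reproduced bounds:

- For an imaging modality, `FP_s` is the source's "false positive
  suspicious" column (24/22/17) — missed malignancies under standard
  semantics. Only this choice reproduces the published upper bounds
  0.56 and 0.7.
- The lower bound compares against **biopsy-all** (TP = 55, FP = 270),
  the standard decision-curve reference; only this choice reproduces
  the published lower bounds 0.09 / 0.08 / 0.063. The comparison
  strategy is unnamed in the source.

Closed forms: upper bound `TP/(TP + FP_s)` (1 when `FP_s = 0`, NaN flag
when `TP = 0`); lower bound from the crossover odds
`(TP_all − TP)/(FP_all − FP_s)` (0 when the modality detects everything
the reference does; NaN flag when the reference has no false-positive
excess). Both are verified against a dense (step 1e-5) grid search of
the curves in the test suite. Curves default to the grid 0.00–0.95 in
steps of 0.01.

Known discrepancy: the published Doppler upper bound 0.61 conflicts
with the closed form 33/(33 + 22) = 0.600 from its own counts
(grayscale's PPV 31/51 = 0.608 rounds to 0.61, suggesting a row
mix-up). The package reports 0.600.

## Numerical and reporting choices

- Metrics and p-values print at 3 decimals with half-up rounding,
  matching the source's precision; range bounds are reported at both 2
  and 3 decimals (the source mixes precisions: 0.09 vs 0.063).
- The pipeline logs the toggles in effect (FP convention, rounding
  mode, grid) and stamps reports with seed, config hash and timestamp.
- Problem sizes in the test suite: Monte-Carlo recovery checks use one
  10^5-nodule cohort (3-standard-error bands), the binomial-expectation
  check 400 replicate cohorts, the null-uniformity check 1000 Welch
  tests, and the grid-search oracle 500 random count configurations —
  sizes at which the checked bands are tight while the suite stays
  interactive.

## Limitations

- The multivariate regression of false predictions on histopathological
  features in the source is out of scope: the per-feature counts are
  not printed and several printed odds ratios fall outside their own
  confidence intervals, so it is irreproducible.
- No confidence intervals on sensitivity/specificity and no bootstrap
  bands on the curves (the source prints none).
- Within-patient correlation is not modelled; the cohort generator
  treats nodules as exchangeable given their FNA class.
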