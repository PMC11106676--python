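# Methods

## Pipeline overview and assumptions

The package models fused drug × nanoparticle (NP) outcomes in five
stages: (1) desirability-directed binarization of each side's observed
assay values, (2) cartesian pairing of the two tables and stratified
resampling into fixed-size working samples with a 3/4–1/4
training/validation split, (3) per-stratum reference probabilities and
perturbation-theory (PTO) features estimated on training rows only,
(4) linear-discriminant and sigmoid-network classifiers on the fused
Boolean outcome, and (5) logistic probability simulation over candidate
grids.

The central modeling assumptions are:

* **Binarization over regression.** Observed values span dozens of
  incommensurable activity parameters, so each is dichotomized against a
  per-parameter cutoff with a desirability direction rather than modeled
  on its raw scale. The boundary `v == cutoff` is classified unfavorable
  (strict inequalities).
* **Fusion as a product.** A paired case is favorable only when both
  subsystems are; fused objective and fused reference are products of
  the per-side Boolean and probability, respectively. This treats the
  two subsystems as independent given their condition labels.
* **PT structure.** The informative part of a descriptor is its
  deviation from the mean of all training cases sharing the same joint
  combination of condition labels (a *partition*): drug biological
  labels c_I = (c_d0…c_d3), drug data-quality labels c_II = (c_d4…c_d8),
  and the single NP partition c_III = (c_n0…c_n4). Cross PTOs condition
  one side's descriptor on the other side's partition and exist only on
  the paired table.

## Tunable parameters

| Parameter | Default | Units / range | Why |
|---|---|---|---|
| cutoff per activity parameter | within-stratum median | native units of the parameter | the only dataset-agnostic, reproducible default; full per-parameter user override supported and logged |
| desirability d(c0) | by name pattern | −1 (smaller better) / +1 (larger better) | concentration-like endpoints (IC50/EC50/CC50/LC50/TC50/Ki/Imax) default −1, response-like (activity/inhibition/Bmax/Cp) +1; anything else must be explicit — no silent default |
| `cases_per_sample` | 500,000 | paired cases | study-scale working-sample size |
| `n_samples` | 3 | — | cross-sample robustness (mean ± sample SDV) |
| `train_fraction` | 0.75 | — | the conventional big-data split; largest-remainder allocation makes totals exact for any N |
| network architectures | LNN (), MLP (11,), DLN (10,10) | hidden-layer widths | the fixed reference architectures; 7 inputs by default |
| epoch budgets | 96 (MLP), 100+20 (DLN), 200 (LNN) | backprop passes | the MLP/DLN budgets follow the BP96 / BP100+CG20 training annotations of the reference setups; the 20 conjugate-gradient epochs are approximated by 20 additional full-batch epochs, since the legacy optimizer is not reproducible bit-for-bit |
| probability bands | ≥ 0.61 high, ≥ 0.17 mid, else low | probability | half-open so every p has exactly one band; the observed 0.98 maximum in published maps is not a rule, so p > 0.98 is still "high" |
| FSW entry criterion | Wilks-Λ partial F, p < 0.05 | — | classical forward-stepwise discriminant entry test; deterministic tie-break to the earlier column |

## The synthetic-data generator

The generator emulates the two input tables at their real label
cardinalities (46/21/7/7/6/3/3/4/3 drug-side, 5/53/10/8/16 NP-side) so
every downstream stage is testable without external data.

* **Label distributions** are Zipf(1) rank-frequency — real assay
  metadata is long-tailed, which stresses stratified sampling more than
  a uniform draw would. Leading vocabulary tokens are real names
  ("IC50 (nM)", "spherical", "PEG-Si(OMe)3", …) so desirability tables
  written against real names also work.
* **Descriptors are Gaussian per entity**, not per assay: all assays of
  one compound share its LOGP/PSA. This mirrors reality and is what
  makes moving-average deviations meaningful.
* **Planted signal.** `plant_outcomes` overwrites observed values so
  the positive class follows a known logistic model in *standardized*
  descriptor deviations, conditioned on the activity-parameter label
  alone (c_d0 / c_n0) — full partition tuples at realistic cardinalities
  leave about one row per group, which would null the deviations. When
  only one side carries weights, the full base rate goes to that side
  and the other is made deterministically favorable, so the fused
  log-odds equals the planted logit exactly; with weights on both sides
  the base rate splits as the square root per side. Interactions are
  restricted to descriptor pairs of the same side: a cross-side
  interaction cannot be expressed through per-assay values drawn before
  pairing. Planted cutoffs sit at 100 (concentration-scale) and values
  are drawn strictly on the favorable/unfavorable side with a 5 %
  margin, so binarization is never ambiguous.
* **One global seed** expands into independent sub-streams (drug labels,
  drug descriptors, NP labels, NP descriptors, outcomes) via fixed
  spawn keys, so regenerating one stream never perturbs another.

What passing tests on this generator do *not* show: real ChEMBL value
distributions (only configured moments are imitated), chemical realism
in descriptors, correlated descriptor structure, or label–descriptor
dependence beyond the planted signal. Recovery results demonstrate that
the pipeline estimates what it claims to estimate, not that real fused
assay data is this easy.

## Numerical and design choices

* **Linear discriminant.** Two-class Fisher form with pooled
  (n−2-normalized) covariance; the score includes the log prior-odds
  term, making it the Gaussian log posterior odds, so the logistic map
  of the score is a probability. A singular pooled covariance is
  ridge-regularized (1e−8, trace-scaled) and logged. The linear model
  consumes raw features, matching classical discriminant practice;
  standardization (training-row mean, sample n−1 sd) applies to the
  network inputs only. Constant feature columns are zeroed and flagged
  rather than divided by zero.
* **Moving-average balance (MAB) operator.** Adopted form:
  ΔΔD = ΔD(D_dk | c_I) − ½·[ΔD(D_ca1 | c_III) + ΔD(D_ca2 | c_III)], the
  drug-descriptor deviation balanced against the mean of its two
  homologous coating-agent deviations (log P ↔ ALOGPcoat/ALOGP2coat,
  PSA ↔ TPSA(NO)coat/TPSA(Tot)coat). The operator's published algebra
  is not machine-readable in its source, so this package fixes the form
  that uses exactly the three named arguments and reduces to a
  drug-vs-coating deviation difference; it is a deliberate, documented
  choice.
* **Leakage control.** Reference probabilities, group means and
  standardization statistics are computed on training rows only;
  permuting validation rows provably changes none of them (tested). An
  unseen stratum at lookup falls back to the side's global training
  rate; an unseen label combination falls back to the descriptor's
  global training mean — exact tuple or global, no partial-tuple
  backoff, for determinism.
* **Sampling.** Working samples are stratified on the fused
  activity-parameter pair (c_d0, c_n0) with proportional
  largest-remainder allocation (ties to the lower index), without
  replacement whenever the universe is large enough, with replacement
  (logged) otherwise. The train/valid split applies the same allocation
  within strata with a global correction, so totals are exactly
  round(fraction·N). All tie-breaks use stable identifiers, never hash
  order. The alphabetical label-ranked ordering of cases is a
  reproducible pre-sort only; it does not alter sampling probabilities.
* **The assay-time feature.** The default seven-feature set includes
  the deviation of assay time within c_III. Assay time is a numeric
  condition rather than a listed descriptor, so the NP schema carries an
  optional `assay_time` column; when absent the feature is an all-zero,
  flagged column (and reports sensitivity 0 by the constant-column
  convention).
* **Metrics.** Sn/Sp/Ac are derived from stored confusion counts;
  chi-square is the Pearson statistic of the 2×2 predicted-vs-observed
  table (1 df, no continuity correction, no multiple-testing
  correction); AUROC is rank-based with ties counted ½. Statistics
  undefined on the data (an absent class) are reported as a NaN
  sentinel, never raised.
* **Expert-guided selection (EGS)** is an interface, not an algorithm: a
  forced-in/forced-out feature list merged with the forward-stepwise
  output.

## Problem sizes used by the test and acceptance runs

Tests and the acceptance script use scaled synthetic studies chosen to
make every estimate stable while keeping runs interactive: study-scale
table generation (4403 × 260 assays; 1,144,780 paired cases) for the
summary arithmetic; a 1000 × 600 universe for the 500,000-case sample
and its exact 375,000/125,000 split; 50,000 paired cases for linear
parameter recovery (validation AUROC within 0.02 of the planted-truth
AUROC; planted coefficient signs recovered); 20,000 cases for the
MLP-vs-LNN gap on interaction-only signal (≥ 0.10 AUROC, observed ≈
0.33); and a 22 × 218 grid (4,796 probabilities) for the simulation
stage.

## Known limitations

* Exact membership of every label in the partitions and the published
  fitted coefficients of the reference linear models are not
  reproducible from public sources; this package reproduces the method,
  not those coefficient values.
* The LNN is fitted by logistic regression (the same model class,
  trained to convergence) rather than by a fixed-epoch legacy optimizer.
* With-replacement resampling exists only for small synthetic universes;
  overlap between the three working samples is permitted.
* The reference-probability denominators use training cases only; if a
  deployment prefers all-cases denominators, pass a precomputed
  `ReferenceTable`.
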