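# Methods

This note records what the package models, the choices made where the
design was genuinely open, and what the synthetic experiments do and do
not show.

## The synthetic claims generator

The generator (`readmit.synthetic_claims`) stands in for an all-payer
admission-level claims database with readmission linkage. It is the
package's study population: every downstream claim about the models is a
claim about data drawn from it.

**Hospitals.** `n_hospitals` (default 300) with lognormal admission
volumes (log-mean log 130, log-SD 0.7, rounded, minimum 1) and i.i.d.
hospital intercepts `u_h ~ N(0, σ_hospital²)` on the log-odds scale
(default σ = 0.2, i.e. hospital-level unadjusted rates mostly between 9
and 16% at a 12% base rate).

**Codes.** 2,000 diagnosis and 500 procedure codes with marginal
prevalence proportional to `rank^-1.6`, rescaled so the top code reaches
0.75 — matching the observed extreme skew in which one code appears in
three quarters of records while most codes are vanishingly rare. Codes
are dealt round-robin into 20 latent disease clusters so every cluster
contains frequent and rare members.

**Records.** Each admission activates one latent cluster (two with
probability 0.5); secondary-diagnosis and procedure codes are drawn
without replacement (Gumbel-top-k, i.e. sequential
probability-proportional-to-weight sampling) with weights = prevalence ×
8 for codes in active clusters. Counts follow negative binomials matched
to the published cohort moments (AMI-like: secondary diagnoses 12.4 ±
6.1 truncated at 29, procedures 5.6 ± 3.3 truncated at 15); ages are
truncated normals; a configurable fraction of patients receives 2–4
admissions (default 12%) to exercise first-admission selection;
discharge-disposition flags, zero length of stay, December admissions
and under-18 ages occur at configurable rates so every exclusion rule
has work to do.

**Outcomes.** `logit(true_p) = β0 + β_age·z(age) + β_sex·female +
Σ_c effect(c) + Σ_(a,b) γ·1[a,b both present] + u_h`, with the label a
Bernoulli draw and 5% of readmissions flagged planned. Per-code effects
are marginally `N(0, 0.12²)` with within-cluster correlation 0.5
(`effect = √ρ·cluster_mean + √(1−ρ)·noise`): clinically similar codes
carry similar risk, which is precisely the structure co-occurrence
embeddings can exploit and i.i.d. effects would deny them. Interaction
pairs (800, log-odds +0.25 each) join two same-cluster diagnosis codes,
prevalence-weighted but excluding the 8 most frequent codes — a pair
containing a near-ubiquitous code degenerates to a main effect of the
other member, which any linear model absorbs, so genuine combinatorial
signal requires both members at middling prevalence.

**Calibration.** Per-code effects are centered by their Monte-Carlo
record-inclusion probability (4,000 simulated records under the exact
sampling law) so that β0 identifies the baseline rate regardless of
which high-prevalence codes happened to draw large effects. β0 defaults
(−2.63 AMI, −2.31 HF, −2.45 PNA) were calibrated once against the
generator's own defaults to hit the published unadjusted readmission
rates (12.0 / 17.7 / 14.3%) and then frozen. With the default AMI
configuration the realized raw rate across seeds is 0.115–0.127.

**What the generator does not emulate.** Survey weights, payer and state
structure, real ICD-9 semantics, seasonal patterns, within-year visit
timing beyond a month index, the CMS planned-readmission algorithm
(replaced by a flag), and cross-hospital patient movement. Passing tests
demonstrate that the pipeline's machinery is correct and that the
qualitative model ordering follows from cluster-structured code risk —
not that any particular AUC value would be attained on real claims.

## Cohort construction

Exclusions are applied as a cascade in the listed order — zero length of
stay (AMI only), in-hospital death, discharge against medical advice,
December admission (no 30-day follow-up window), transfer to acute care,
age under 18, then hospitals with fewer than 10 remaining admissions —
each rule counted against the survivors of the previous one, and the log
checks `n_input − Σ removed = n_final` on every run. First admission per
patient is selected after the exclusions (earliest month, stable input
order breaking ties). The ≥10-occurrence code filter counts presence per
record over the full raw table; it removes codes from records, never
records. Splits are 80/10/10 within each hospital by seeded shuffle and
largest-remainder rounding, so per-hospital proportions deviate by less
than one record.

The packaged comorbidity map is a deliberately coarse, pluggable
two-column table for the synthetic universe: the 400 most prevalent
diagnosis codes map to one of 29 categories derived from their latent
cluster; rarer codes map to nothing. A real Elixhauser ICD-9 table can
be dropped in via `ComorbidityMap.from_table`.

## Embeddings

Records are unordered code sets, so co-occurrence is presence-based (a
pair counts once per record containing both codes) with no distance
weighting, and the matrix is symmetric with a zero diagonal. One joint
matrix is counted over diagnosis + procedure codes on the
train+validation records only; separate GloVe fits on the dx–dx and
proc–proc sub-blocks honor the different target dimensions (200-d
diagnosis / 50-d procedure at published scale; 50-d / 16-d in the
desk-scale experiments). GloVe uses the canonical weighting (x_max 100,
α 0.75), AdaGrad SGD over nonzero entries (numba inner loop; a
vectorized NumPy objective/gradient serves as the independent reference
for finite-difference checks), uniform ±0.5/√dim initialization, and the
standard `w + w̃` final vector. Out-of-vocabulary secondary/procedure
codes are skipped at lookup; an out-of-vocabulary principal code yields
a zero vector with a logged warning (or an error, by configuration).

## Models

All four models share one contract: probabilities in (0,1),
deterministic at inference. The neural models are implemented on a
compact NumPy Adam/backprop core (`models/nn.py`) with sparse first
layers.

- **HLR**: Laplace-approximated marginal likelihood; inner Newton over
  (β, u) via the Schur complement (the u-block is diagonal for a pure
  random intercept), σ_u profiled by bounded scalar optimization; a
  10⁻⁶ ridge on β stabilizes empty comorbidity columns. The objective
  is the same one lme4's `glmer` maximizes at nAGQ=1, and a test checks
  agreement with it.
- **GBT**: XGBoost, η 0.0002, depth 6, early stopping on validation
  logloss (with this learning rate the AUC moves too slowly between
  rounds for AUC-based stopping to register improvement), round cap
  8,000 desk-scale / 20,000 default.
- **FFNN**: hidden widths 1,024→256 by default (256→64 in desk-scale
  runs, keeping roughly the published width-to-input ratio), ReLU, one
  dropout layer at 0.3 before the two-unit softmax, Adam 0.0002,
  categorical cross-entropy, batch 256, ≤50 epochs, patience 5,
  best-validation weights restored.
- **ME-DS**: φ and ρ are single hidden layers of width 64 (configurable);
  sum pooling — not mean — because set cardinality is itself predictive
  (readmitted patients carry more codes) and the sum preserves it; the
  pool of an empty set is the zero vector; a learned scalar hospital
  embedding plays the role of the random intercept; GloVe vectors are
  frozen by default (`finetune_embeddings=True` unfreezes). Because φ
  acts on a code's fixed embedding, it is evaluated once per vocabulary
  entry per batch and pooled through the sparse record-code incidence
  matrix, making permutation invariance exact by construction. Age is
  z-scored against the profile mean/SD in all models.

Prediction modes: `actual` (each record's own hospital effect),
`forced(h)` (everyone assigned hospital h), `population` (u = 0 for HLR;
the mean hospital embedding for ME-DS). GBT and FFNN carry no hospital
effect and ignore the assignment; asking them for predictive margins is
an error rather than a constant table.

## Standardization and reclassification

Predictive margins average the forced-h prediction over the full cohort
by default (a flag restricts to the test split). The ratio method
divides each hospital's mean own-intercept prediction by its mean
population-average prediction and multiplies by the overall unadjusted
rate. Groups are top/bottom `floor(0.2N)` by rate with the remainder in
the middle — the only rounding convention consistent with all three
published cohort margins (223/672/223 of 1,118; 341/1026/341 of 1,708;
383/1153/383 of 1,919). "Top" means highest readmission rates by
default (a logged, configurable choice — the convention is not fixed by
the source material). Reclassification percentages are rounded half-up
to one decimal. Two summary percentages are reported side by side:
extreme-group moves only (the in-text arithmetic, (72+37)/1118 ≈ 9.7%)
and all off-diagonal moves (≈19.5% on the same table); the package
asserts neither as "the" canonical summary.

## Evaluation

AUC is the Mann–Whitney statistic with half credit for ties (stated
explicitly because dummy-coded models produce tied scores), computed via
average ranks and tested against brute-force pair enumeration.
`cv_auc_ci` refits on k hospital-stratified folds and reports
mean ± 1.96·SD/√k — the standard-error convention, stated in the report;
folds whose held-out labels are single-class are skipped with a warning.
The experiment runner seeds every stage from one master seed via
`SeedSequence` spawning; identical configs reproduce identical reports.

## Problem sizes

Desk-scale experiment defaults: 300 hospitals (~50,000 admissions,
~45,000 after cohort construction), 2,000 + 500 code vocabulary, 50-d /
16-d embeddings with 12 GloVe epochs, FFNN 256→64, deep-set widths 64,
GBT 8,000 rounds. These sizes were chosen so a full four-model
comparison completes in about two minutes on one CPU while preserving
the qualitative structure: roughly 0.05–0.07 AUC of the generating
signal lies in the pairwise interactions, which is the headroom
separating the code-level models from the comorbidity-index regression.
The published-scale settings (9,778 + 3,183 codes, 200-d/50-d
embeddings, 1,024→256 hidden units, 20,000 boosting rounds) remain
reachable through the same configs.

## Known limitations

- σ_u estimation at small hospital counts shows the usual Laplace
  small-sample bias; the recovery guarantees are stated at 200 hospitals
  × 250 admissions.
- The GBT at learning rate 0.0002 is still slowly improving at the
  desk-scale round cap; its reported AUC is a floor, not a plateau.
- Reclassification percentages between HLR and ME-DS on synthetic data
  depend on σ_hospital and the interaction share and run higher than the
  published extreme-move figure at the default configuration (the two
  models disagree more here than on real claims); they are reported, not
  calibrated.
- The generator's exclusion flags are mutually exclusive by
  construction; real data allow, e.g., transfers who also die.
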