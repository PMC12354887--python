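# Methods

This note records the models, conventions and design choices behind
`cohortvec`, in the order data flows through the pipeline.

## Time conventions

All ages are stored in days since birth and binned downstream: the age-week
of an event is `floor(age_days / 7)`, the age-year is
`floor(age_days / 365.25)`.  One year is 365.25 days everywhere — sentences,
onset tables, survival and progression windows share this single clock, so
records are site- and calendar-independent.

## Synthetic cohorts

The generator (`synthetic_ehr`) is the package's study population; real
coded-EHR cohorts of the relevant scale are access-restricted.  Each
patient receives:

* **Follow-up**: `1 + Poisson(mean − 1)` years (default mean 12, capped at
  25), entered at a uniform age between 30 and 60.
* **Background coding**: per year, `Poisson(8)` codes drawn from a Zipf
  (exponent 1.3) popularity distribution over 60 diagnosis + 20 procedure
  codes, with a mild age trend (one third of codes age upward, one third
  downward, factor `exp(±(age−50)/30)`).  Heavy-tailed usage exercises the
  minimum-occurrence vocabulary filter.
* **Identity signature**: 3 patient-specific codes, each present in 90 % of
  the patient's years (deterministically `ceil(0.9 n)` years, so the
  recurrence guarantee is exact).
* **Clinical episodes**: at rate 0.7 per patient-year, a code flares in two
  consecutive years (2 occurrences each).  Episodes are the only
  within-patient feature that distinguishes adjacent from non-adjacent
  years; without them the *is_next_event* task has no learnable signal
  (a gradient-boosted oracle on the raw vectors scores ≈ 0.55 against
  same-patient negatives).
* **Disease subtype**: one of 3 latent subtypes with onset age
  ~ Normal(45/55/65, 5), truncated to the follow-up window (draws outside
  it yield non-cases, giving both cases and controls).  From onset, the
  index-phecode code is emitted (always in the onset year, then with
  probability 0.5/year) and each of the subtype's 5 comorbidity phecodes
  is emitted with probability 0.9 per year.  A 3-year prodrome emits the
  same phecodes at probability 0.7 per year, emulating the pre-onset
  comorbidity divergence seen in real progression data and giving the
  onset-prediction task (never-affected controls) its signal; the
  prodrome strength was calibrated against a bag-of-codes oracle so that
  the lead-year information ceiling clears the planted-signal targets,
  not against the classifier under test.
* **Mortality**: from onset, exponential survival with subtype-specific
  hazard (defaults 0.03/0.09/0.15 per year) under exponential censoring
  (0.06/year).

Two codes are excluded from background chatter: the index-phecode codes
entirely (the phecode-defined cohort must equal the true cases) and the
comorbidity-set codes down to 10 % of their Zipf weight (retained as label
noise; at full weight a ~6-year post-onset window hits a foreign
comorbidity set with probability ≈ 0.98 and every planted contrast
saturates).

What the generator does **not** emulate: real code ontologies and their
granularity, visit/encounter structure, site-specific coding practice,
demographic confounding of disease risk (demographics are independent of
subtype), informative censoring, and measurement error in ages.  Passing
tests therefore demonstrate that the pipeline recovers structure that is
present and identifiable, not that it would perform at any particular
level on real records.

## Code VAE

Rows of the code × age-week count matrix are scaled to unit L2 norm before
encoding; raw counts span orders of magnitude and unit norm makes the
reconstruction and cosine losses commensurate.  The encoder stack is
4320 → 1024 → 256 → (μ, log σ²) at full scale (desk preset:
4320 → 128 → 64 → 48); the decoder mirrors it.  The loss is
`recon + λ_cos · cosine + λ_KL · KL` with λ_cos = 1, λ_KL = 0.1; the cosine
term compares the pairwise cosine matrices of the batch in input space and
latent-mean space.  With λ_KL = 0 the model is trained deterministically
(no latent sampling), since sampling noise without the KL constraint only
degrades reconstruction.  Full-scale preset: learning rate 1e−7, batch 64,
100 epochs, 5 % validation split.  The desk preset uses learning rate 1e−3
and the same 100 epochs — code-embedding quality proved the dominant source
of downstream run-to-run variance, and the desk VAE costs ~2 s.
Inference is deterministic (latent means; no sampling).  PAD/MASK/BOS
rows of the embedding table are not VAE-trained (they have no frequency
profile); they start at zero/small-random and train with the transformer.

## Year-sentence transformer

Pre-norm encoder–decoder, no positional encodings anywhere; attention and
pooling are therefore permutation-equivariant over the year's token
multiset by construction.  Full-scale preset L = 6, H = 10, dff = 2048,
d = 50, max_len = 250; desk preset L = 2, H = 2, dff = 128, d = 48,
max_len = 32 (dff and d were sized so that the copy-rule learnability
check clears 0.95 held-out token accuracy within 2000 steps).  Adam with
β₁ = 0.9, β₂ = 0.98, ε = 1e−9; linear warmup then inverse-square-root
decay, calibrated so the rate at step 10,000 equals 0.002 (desk: anchored
at its 2000th step).

Objective = next-year cross-entropy (decoder, teacher-forced, PAD
excluded) + encoder-head reconstruction cross-entropy over all non-PAD
input positions, with masked positions at weight 1.0 and clean positions
at 0.2.  Input sentences are masked at 20 % (`ceil(0.2 L)` positions,
uniform, never PAD).  The reduced clean weight matters: full-weight clean
supervision dilutes the decoder objective, while masked-only supervision
leaves the clean-token reconstruction path (used by sequence recovery)
untrained.

Because within-year order is meaningless, the decoder's teacher-forced
target sequence is canonicalised to sorted-token order; a BOS token
(reserved index 2) starts the decoder input.  "Next year" means
consecutive age-years; gap years break pairs.  Sentences longer than
max_len keep their earliest tokens.  Sequence-recovery precision/recall
are set-wise (positions are meaningless), reported as mean ± sd and
median with IQR.

## Siamese tower and patient vectors

The tower is `input → 128 → 50` with ReLU; both pair members share it.
Losses: (i) contrastive — squared distance for same-patient pairs, squared
hinge `max(0, margin − d)²` for different-patient pairs, margin 2.0 (a
sweep showed margin 1.0 leaves many negatives inside the no-gradient
zone); the margin term is required — the positive objective alone admits
the constant map.  (ii) next-event — a 2-layer head on (u, v, |u−v|), the
classifier input of the sentence-embedding method this stage follows, with
inverse-class-frequency weights in the BCE so the 0.5 cutoff stays
calibrated at the sampler's ~25 % positive rate.  Training: Adam 3e−4,
5000 steps, 8000 pairs (50 % same-patient, half of those adjacent).

Pair evaluation balances each task's evaluation set by class before
computing accuracy (chance = 0.5 for both tasks regardless of sampler
rates); the same-patient threshold is chosen on a 30 % calibration split,
and accuracies are reported as mean ± sd over 5 folds.

The patient vector is the exact arithmetic mean of year embeddings,
computed in float64.

## Phenotyping tasks

Phenotype calls use diagnosis codes only; one mapped occurrence qualifies,
and onset is the earliest qualifying day.  Disease-state: post-onset years
of cases vs their pre-onset years.  Onset prediction: the embedding one
year before onset vs year-frequency-matched embeddings of never-affected
patients (a `pre_onset` negative mode is available; never-affected is the
default and makes the task "prediction before any diagnosis").  Bulk:
one mean vector per patient, labelled ever-present.  Eligibility floor:
20 cases.  Classifier: plain logistic regression with a 1e−6 ridge for
separable stability; splits are stratified and grouped by patient (no
patient contributes to both sides; one reshuffle on a degenerate draw,
then the phenotype is skipped with a logged reason).

The phenotyping tasks consume the **pooled transformer vectors**, not the
siamese output: the identity-contrastive objective measurably smears
within-patient temporal differences (onset AUROC 0.86 pooled vs 0.80
fine-tuned on the synthetic cohort), while the pair tasks and subtype
clustering use the fine-tuned vectors, where identity smoothing helps.

## Stratification

Clustering input is the **disease-era mean** (years ≥ index onset) of the
fine-tuned vectors.  All-years means were evaluated and rejected: each
case's subtype component is scaled by its post-onset fraction and swamped
by the persistent identity component, capping subtype recovery at
ARI ≈ 0.45 vs ≈ 0.95 for disease-era means (`window="all"` remains
available).  The GMM/BIC scan (K = 2..8, 10 restarts, full covariance with
a diagonal fallback on singularity) optionally projects onto leading
principal components first — the pipeline uses 5 — because at n ≈ 150 a
full covariance in 50 dimensions spends more BIC on covariance parameters
than the data support; `pca_dim=None` gives the plain behaviour.

Enrichment fits, per (cluster, phecode) with ≥ 10 affected patients, a
logistic regression of phenotype presence on the one-vs-rest cluster
indicator plus age of onset and one-hot gender/race/ethnicity/site
(largest level as reference, missing as an explicit level); a single
gender covariate is used.  The cluster coefficient is the log odds ratio
with its Wald p; adjustment is Benjamini–Hochberg by default with a
Bonferroni option (sources for this procedure disagree between the two),
significance at adjusted p < 2e−5.  Non-converged or separated fits are
reported with a flag (coefficient from a ridge refit, p unavailable),
never dropped silently.

Survival: KM curves censored at the 10-year horizon; global and pairwise
log-rank tests, pairwise p BH-adjusted; clusters without events are
excluded with a warning; time origin is index-phenotype onset.
Progression: patients with all 10 post-onset years embedded are averaged
patient-wise, PCA retains 3 components, and each PC is decomposed by
type-II ANOVA on an additive model (age of onset, race, gender, site,
cluster).  Emerging phenotypes: a gain is a phecode whose first occurrence
year is strictly after the index onset year (present-before ⇒ never a
gain); frequencies are per-cluster, top-15 flagged with ties broken by
frequency desc then phecode asc; a `pre` mode counts pre-onset presence.

## Determinism and numerics

Every stochastic step takes an explicit seed or `numpy` Generator; the
pipeline derives per-stage seeds from the global seed and the stage name
(CRC-32 fold, kept below 2³¹), so stages are independently reproducible
and a rerun reproduces identical artifact hashes.  The neural engine is
float32; permutation invariance of pooled embeddings holds to ~1e−6
(float-summation order), tested at 1e−5.  Mean patient vectors are
float64 and exact to 1e−12 against explicit summation.  Non-finite losses
abort training with diagnostics.  Desk-scale problem sizes (500 patients,
~80 codes, 2000 transformer steps, 5000 siamese steps) were chosen so the
full pipeline completes in ~90 s on one CPU while every planted property
remains detectable.

## Known limitations

* The full-scale presets (d = 50, L = 6, 4320-week matrix at 35k codes)
  are faithful to their sources but have only been exercised at desk
  scale in this repository.
* Masked-token prediction on the synthetic cohort is low (~0.09): most
  masked tokens are Zipf background draws with no contextual signal, by
  construction.  The memorisable copy corpus shows the mechanism itself
  reaches ≥ 0.9.
* With two masked positions in one sentence the permutation-equivariant
  encoder necessarily predicts the same token at both; masked accuracy
  has a structural ceiling below 1 whenever distinct tokens are masked
  together.
* The enrichment model treats patients as exchangeable given covariates;
  no within-site correlation or longitudinal dependence is modelled.
* Emerging-phenotype gains are year-resolution; a first occurrence later
  in the onset year itself does not count as a gain.
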