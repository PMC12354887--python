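# cohortvec

Unsupervised patient embeddings from longitudinal coded EHR data, and the
downstream analyses those embeddings enable: phenome-wide classification,
comorbidity subtyping, survival contrasts and disease-progression analysis.

## Who this is for

Clinical-informatics and biostatistics researchers who have (or simulate)
longitudinal coded records — diagnosis codes (ICD-9/ICD-10) and procedure
codes (CPT-4) with patient age at each event — and want a fixed-length
numeric representation of each patient-year and each patient, without
hand-built phenotyping rules.  Real cohorts of this kind are
access-restricted, so the package ships a first-class synthetic-cohort
generator with planted ground truth (latent disease subtypes, onset times,
comorbidity signatures, mortality) against which every stage is tested.

## The method

1. **Code embedding (VAE).** Codes appearing more than 5 times are kept.
   Each code *v* is described by its usage histogram over patient age in
   weeks (0–4320 weeks = 90 years), giving a |V| × 4320 count matrix.  A
   variational autoencoder compresses each unit-normalised row to a latent
   mean **z**_v ∈ R^d (d = 50 at full scale).  Besides reconstruction and
   KL terms, a cosine-preservation loss keeps cos(**z**_u, **z**_v) close
   to the cosine of the corresponding frequency rows.

2. **Year sentences and transformer pre-training.**  A patient's codes in
   one age-year form an unordered "sentence" (max length 250, PAD-filled).
   An encoder–decoder transformer **without positional encodings** — the
   within-year order of diagnoses carries no temporal meaning — is trained
   to predict the next year's codes from the current year's, with 20 % of
   input tokens masked and an encoder head reconstructing the full input
   sequence.  Token embeddings are initialised from the VAE.  The pooled
   (mean over non-PAD positions) final encoder layer is the patient-year
   vector.

3. **Siamese fine-tuning.**  A shared two-layer tower (pre-embedding layer
   → 50-dim embedding) is trained on randomly formed pairs of patient-year
   vectors with two objectives: *is_same_patient* (contrastive squared
   distance, margin for negatives) and *is_next_event* (a 2-layer head on
   (u, v, |u−v|) deciding whether v is the immediately following year of
   u's patient).

4. **Patient vectors.**  The patient embedding is the arithmetic mean of
   year embeddings,
   mean_k = (1/n) Σ_{t=1..n} v_k^t.

5. **Downstream.**  Logistic regression on the 50 features gives
   phenome-wide **disease-state**, **onset-prediction** (one year before
   first diagnosis, never-affected controls) and **bulk-phenotyping**
   classifiers with 80/20 patient-grouped splits (AUROC/AUPRC).  Within an
   index phenotype, Gaussian-mixture clustering with BIC model selection
   finds comorbidity subtypes; per (cluster, phecode) a covariate-adjusted
   logistic regression (one-vs-rest cluster indicator; age of onset,
   gender, race, ethnicity, site) reports the log odds ratio with
   Benjamini–Hochberg-adjusted p (significance at p < 2e−5); Kaplan–Meier
   curves and log-rank tests contrast 10-year survival across clusters;
   PCA + type-II ANOVA decompose 10-year post-onset trajectories; and
   emerging phenotypes (phecodes first appearing strictly after index
   onset) are counted per cluster with a top-15 selection.

No GPU or autodiff framework is required: the three neural models run on a
small numpy reverse-mode autodiff engine included in the package
(`cohortvec._nn`).

## Worked example

Run the full desk-scale pipeline on a simulated 500-patient cohort with
three planted subtypes:

```sh
cohortvec run-all --out run --seed 11 --n-patients 500
```

This simulates the cohort, trains the VAE and the transformer, fine-tunes
the siamese tower, embeds every patient-year, clusters the index-disease
cases and prints per-stage metrics (about 90 s on one CPU):

```
"finetune":  {"pair_tasks": {"is_same_patient": {"mean": 0.79, ...},
                             "is_next_event":   {"mean": 0.771, ...}}}
"analyze":   {"chosen_k": 3,
              "ari_vs_true_subtype": 0.949,
              "survival_global_logrank_p": 0.0002, ...}
```

Reading: the held-out accuracy of deciding whether two patient-year
vectors belong to the same patient is 0.79 (0.77 for whether one is the
other's next year); BIC selects K = 3 mixture components among the
index-disease cases, matching the three planted subtypes with adjusted
Rand index 0.95; and the clusters differ in 10-year overall survival
(global log-rank p = 2e−4), as planted via subtype-specific mortality
hazards.  `run/enrichment.tsv` lists per-cluster comorbidity log odds
ratios with BH-adjusted p-values; `run/emerging_phenotypes.tsv` the
post-onset phenotype gains per cluster.

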