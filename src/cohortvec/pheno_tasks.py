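"""Phenome-wide classification tasks on patient embeddings.

Three labelled-dataset designs per phenotype (phecode):

* ``state``  — disease-state separation: a case's patient-year embeddings at
  or after the onset year are positives, the same patients' pre-onset years
  are negatives;
* ``onset``  — prediction before any diagnosis: each case's embedding one
  year before onset is a positive; negatives are sampled from patients who
  never acquire the phenotype, matched on the year-index distribution of
  the positives (a ``pre_onset`` negative mode is also available, using
  cases' earlier years instead);
* ``bulk``   — bulk phenotyping: one row per patient (the Eq.-1 mean
  vector), labelled by whether the phenotype is ever present.

Each dataset is scored with a plain logistic regression over the 50
embedding features (a tiny ridge stabilises separable fits), an 80/20
patient-grouped split, and AUROC / AUPRC on the held-out 20%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score

from .ehr_io import PhecodeMap
from .patient_embed import _embedding_columns

logger = logging.getLogger(__name__)


class PhenotypeSkipped(Exception):
    """Raised when a phenotype has too little signal to build a dataset."""


@dataclass
class TaskResult:
    phecode: str
    disease_class: str
    auroc: float
    auprc: float
    n_pos: int
    n_neg: int
    split_seed: int

    @property
    def pos_neg_ratio(self) -> float:
        return self.n_pos / self.n_neg if self.n_neg else np.inf


def _case_onsets(onsets: pd.DataFrame, phecode: str) -> pd.Series:
    sub = onsets[onsets["phecode"] == phecode]
    return pd.Series(sub["onset_age_years"].to_numpy(),
                     index=sub["patient_id"].to_numpy())


def build_state_dataset(year_embeddings: pd.DataFrame, onsets: pd.DataFrame,
                        phecode: str, min_cases: int = 20) -> pd.DataFrame:
    """Post-onset years (label 1) vs pre-onset years (label 0) of cases."""
    case_onset = _case_onsets(onsets, phecode)
    rows = year_embeddings[year_embeddings["patient_id"].isin(case_onset.index)]
    if not len(rows):
        raise PhenotypeSkipped(f"{phecode}: no embedded case years")
    onset_of = rows["patient_id"].map(case_onset)
    labelled = rows.assign(label=(rows["year_index"] >= onset_of).astype(int))
    per_patient = labelled.groupby("patient_id")["label"].agg(["min", "max"])
    n_complete = int(((per_patient["min"] == 0) &
                      (per_patient["max"] == 1)).sum())
    if n_complete < min_cases:
        raise PhenotypeSkipped(
            f"{phecode}: only {n_complete} cases with both pre- and "
            f"post-onset years (need {min_cases})")
    return labelled.reset_index(drop=True)


def build_onset_dataset(year_embeddings: pd.DataFrame, onsets: pd.DataFrame,
                        phecode: str, rng: np.random.Generator,
                        min_cases: int = 20,
                        negative_mode: str = "never_affected",
                        negatives_per_positive: int = 1) -> pd.DataFrame:
    """Embeddings one year before onset vs year-matched unaffected controls."""
    case_onset = _case_onsets(onsets, phecode)
    lead = year_embeddings.merge(
        case_onset.rename("onset").rename_axis("patient_id").reset_index(),
        on="patient_id")
    pos = lead[lead["year_index"] == lead["onset"] - 1].drop(columns="onset")
    if len(pos) < min_cases:
        raise PhenotypeSkipped(
            f"{phecode}: only {len(pos)} cases with an observed "
            f"pre-onset lead year (need {min_cases})")
    if negative_mode == "never_affected":
        pool = year_embeddings[
            ~year_embeddings["patient_id"].isin(case_onset.index)]
    elif negative_mode == "pre_onset":
        pre = lead[lead["year_index"] < lead["onset"] - 1]
        pool = pre.drop(columns="onset")
    else:
        raise ValueError(f"unknown negative_mode {negative_mode!r}")
    if not len(pool):
        raise PhenotypeSkipped(f"{phecode}: empty negative pool")
    # match the year-index frequency profile of the positives
    neg_parts = []
    for year, n_pos in pos["year_index"].value_counts().items():
        candidates = pool[pool["year_index"] == year]
        if not len(candidates):
            candidates = pool
        take = min(n_pos * negatives_per_positive, len(candidates))
        neg_parts.append(candidates.iloc[
            rng.choice(len(candidates), size=take, replace=False)])
    neg = pd.concat(neg_parts)
    return pd.concat([pos.assign(label=1), neg.assign(label=0)]
                     ).reset_index(drop=True)


def build_bulk_dataset(mean_vectors: pd.DataFrame, onsets: pd.DataFrame,
                       phecode: str) -> pd.DataFrame:
    """One row per patient (mean vector), labelled phenotype-ever-present."""
    affected = set(onsets.loc[onsets["phecode"] == phecode, "patient_id"])
    ds = mean_vectors.assign(
        label=mean_vectors["patient_id"].isin(affected).astype(int))
    if ds["label"].nunique() < 2:
        raise PhenotypeSkipped(f"{phecode}: single-class bulk labels")
    return ds


def _grouped_split(dataset: pd.DataFrame, train_fraction: float,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Patient-grouped split; no patient contributes to both sides."""
    patients = dataset["patient_id"].unique()
    for _ in range(2):  # one reshuffle allowed on a degenerate draw
        perm = rng.permutation(patients)
        n_train = max(int(round(train_fraction * len(patients))), 1)
        train_p = set(perm[:n_train])
        is_train = dataset["patient_id"].isin(train_p).to_numpy()
        y = dataset["label"].to_numpy()
        if (np.unique(y[is_train]).size == 2 and
                np.unique(y[~is_train]).size == 2):
            return is_train, ~is_train
    raise PhenotypeSkipped("degenerate train/test split after reshuffle")


def fit_eval_logistic(dataset: pd.DataFrame, train_fraction: float = 0.8,
                      seed: int = 0, ridge: float = 1e-6,
                      prefix: str = "s") -> TaskResult:
    """Plain logistic regression on embedding features, held-out AUROC/AUPRC."""
    cols = _embedding_columns(dataset, prefix)
    rng = np.random.default_rng(seed)
    is_train, is_test = _grouped_split(dataset, train_fraction, rng)
    X = dataset[cols].to_numpy(dtype=np.float64)
    y = dataset["label"].to_numpy()
    clf = LogisticRegression(C=1.0 / ridge, max_iter=2000)
    clf.fit(X[is_train], y[is_train])
    scores = clf.predict_proba(X[is_test])[:, 1]
    return TaskResult(
        phecode="", disease_class="",
        auroc=float(roc_auc_score(y[is_test], scores)),
        auprc=float(average_precision_score(y[is_test], scores)),
        n_pos=int(y.sum()), n_neg=int((1 - y).sum()), split_seed=seed)


def run_phenome(year_embeddings: pd.DataFrame, mean_vectors: pd.DataFrame,
                onsets: pd.DataFrame, pmap: PhecodeMap, task: str,
                min_cases: int = 20, seed: int = 0,
                negative_mode: str = "never_affected",
                ) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Run one task over every mapped phecode.

    Returns (per-phenotype results, per-disease-class medians, skip log).
    """
    if task not in {"state", "onset", "bulk"}:
        raise ValueError(f"unknown task {task!r}")
    rng = np.random.default_rng(seed)
    results, skips = [], []
    for phecode in pmap.phecodes:
        try:
            if task == "state":
                ds = build_state_dataset(year_embeddings, onsets, phecode,
                                         min_cases)
            elif task == "onset":
                ds = build_onset_dataset(year_embeddings, onsets, phecode,
                                         rng, min_cases, negative_mode)
            else:
                ds = build_bulk_dataset(mean_vectors, onsets, phecode)
            res = fit_eval_logistic(ds, seed=seed)
        except PhenotypeSkipped as exc:
            skips.append(str(exc))
            logger.info("skipped %s", exc)
            continue
        res.phecode = phecode
        res.disease_class = pmap.disease_class(phecode)
        results.append(res)
    table = pd.DataFrame([{
        "phecode": r.phecode, "disease_class": r.disease_class,
        "auroc": r.auroc, "auprc": r.auprc, "n_pos": r.n_pos,
        "n_neg": r.n_neg, "pos_neg_ratio": r.pos_neg_ratio,
        "split_seed": r.split_seed} for r in results]
    ).sort_values("phecode").reset_index(drop=True) if results else \
        pd.DataFrame(columns=["phecode", "disease_class", "auroc", "auprc",
                              "n_pos", "n_neg", "pos_neg_ratio", "split_seed"])
    class_medians = (table.groupby("disease_class")[["auroc", "auprc"]]
                     .median().reset_index()) if len(table) else \
        pd.DataFrame(columns=["disease_class", "auroc", "auprc"])
    return table, class_medians, skips
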