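"""Comorbidity subtyping and outcome contrasts within one index phenotype.

Given mean patient vectors of an index-disease cohort:

* :func:`fit_gmm_bic` clusters them with Gaussian mixtures, choosing the
  number of components by BIC;
* :func:`comorbidity_enrichment` fits, per (cluster, comorbidity phecode),
  a covariate-adjusted logistic regression (one-vs-rest cluster indicator;
  age of onset, gender, race, ethnicity and site as covariates) and reports
  the cluster coefficient as a log odds ratio with a multiplicity-adjusted
  p-value (Benjamini-Hochberg by default, Bonferroni optionally) at the
  2e-5 significance level;
* :func:`km_logrank` contrasts 10-year overall survival across clusters
  (Kaplan-Meier curves, global and pairwise log-rank tests);
* :func:`progression_pca_anova` decomposes 10-year post-onset trajectories
  by PCA and attributes per-PC variance to covariates by type-II ANOVA;
* :func:`emerging_phenotypes` counts phenotypes first appearing strictly
  after index onset (or present before it, in ``pre`` mode), normalised to
  per-cluster frequencies with a deterministic top-N selection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test, logrank_test
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture
from statsmodels.stats.multitest import multipletests

from .patient_embed import _embedding_columns

logger = logging.getLogger(__name__)

SIGNIFICANCE_LEVEL = 2e-5   # adjusted-p threshold for enrichment calls


# ---------------------------------------------------------------------------
# GMM / BIC clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterModel:
    gmm: GaussianMixture
    chosen_k: int
    bic: dict[int, float]
    assignments: pd.DataFrame      # patient_id, cluster
    seed: int
    covariance_type: str = "full"
    pca_dim: int | None = None

    @property
    def cluster_sizes(self) -> pd.Series:
        return self.assignments["cluster"].value_counts().sort_index()


def index_cohort_mean_vectors(year_embeddings: pd.DataFrame,
                              index_onsets: pd.DataFrame,
                              window: str = "post",
                              prefix: str = "s") -> pd.DataFrame:
    """Mean patient vectors of an index-disease cohort.

    ``post`` (default) averages each case's year embeddings from the index
    onset year onward — the disease-era representation used for comorbidity
    subtyping; ``all`` averages every observed year.
    """
    if window not in {"post", "all"}:
        raise ValueError("window must be 'post' or 'all'")
    cols = _embedding_columns(year_embeddings, prefix)
    onset_of = dict(zip(index_onsets["patient_id"],
                        index_onsets["onset_age_years"]))
    rows = year_embeddings[year_embeddings["patient_id"].isin(onset_of)]
    if window == "post":
        keep = rows["year_index"] >= rows["patient_id"].map(onset_of)
        rows = rows[keep]
    grouped = rows.groupby("patient_id", sort=True)
    means = grouped[cols].mean()
    means["n_years"] = grouped.size()
    return means.reset_index()


def fit_gmm_bic(mean_vectors: pd.DataFrame, k_range=range(2, 9),
                seed: int = 0, n_init: int = 10,
                prefix: str = "s", pca_dim: int | None = None) -> ClusterModel:
    """Fit one GMM per candidate K and keep the minimum-BIC model.

    Hard assignments are by maximum posterior.  A singular full covariance
    triggers a diagonal-covariance retry (logged).  With `pca_dim`, vectors
    are first projected onto their leading principal components — at small
    cohort sizes a full-covariance mixture in 50 dimensions spends more BIC
    on covariance parameters than the data can support.
    """
    cols = _embedding_columns(mean_vectors, prefix)
    X = mean_vectors[cols].to_numpy(dtype=np.float64)
    if pca_dim is not None and pca_dim < X.shape[1]:
        X = PCA(pca_dim, random_state=seed).fit_transform(X)
    k_range = [k for k in k_range if k <= len(X)]
    if not k_range:
        raise ValueError("no feasible K for the sample size")

    def fit_all(cov_type: str):
        out = {}
        for k in k_range:
            gmm = GaussianMixture(n_components=k, covariance_type=cov_type,
                                  n_init=n_init, random_state=seed,
                                  reg_covar=1e-6)
            gmm.fit(X)
            out[k] = gmm
        return out

    cov_type = "full"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", RuntimeWarning)
            models = fit_all(cov_type)
    except (np.linalg.LinAlgError, RuntimeWarning, ValueError):
        logger.warning("full-covariance GMM unstable; retrying diagonal")
        cov_type = "diag"
        models = fit_all(cov_type)

    bic = {k: float(m.bic(X)) for k, m in models.items()}
    chosen = min(bic, key=bic.get)
    best = models[chosen]
    assignments = pd.DataFrame({
        "patient_id": mean_vectors["patient_id"].to_numpy(),
        "cluster": best.predict(X).astype(int)})
    return ClusterModel(gmm=best, chosen_k=chosen, bic=bic,
                        assignments=assignments, seed=seed,
                        covariance_type=cov_type, pca_dim=pca_dim)


# ---------------------------------------------------------------------------
# Covariate-adjusted comorbidity enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    cluster: int
    phecode: str
    disease_class: str
    log_odds_ratio: float
    p_value: float
    p_adjusted: float
    significant: bool
    converged: bool
    n_with_phenotype: int


_COVARIATE_COLS = ("age_of_onset", "gender", "race", "ethnicity", "site")


def _design_matrix(covariates: pd.DataFrame) -> pd.DataFrame:
    """One-hot covariates with the largest level as reference; missing
    values become an explicit 'unknown' level."""
    parts = []
    if "age_of_onset" in covariates:
        parts.append(covariates[["age_of_onset"]].astype(float)
                     .fillna(covariates["age_of_onset"].astype(float).mean()))
    for col in covariates.columns:
        if col in ("age_of_onset", "patient_id"):
            continue
        s = covariates[col].astype(str).fillna("unknown")
        ref = s.value_counts().idxmax()
        dummies = pd.get_dummies(s, prefix=col, dtype=float)
        dummies = dummies.drop(columns=f"{col}_{ref}")
        parts.append(dummies)
    return pd.concat(parts, axis=1) if parts else pd.DataFrame(
        index=covariates.index)


def comorbidity_enrichment(assignments: pd.DataFrame,
                           phenotype_presence: pd.DataFrame,
                           covariates: pd.DataFrame,
                           disease_classes: dict[str, str] | None = None,
                           min_count: int = 10,
                           min_cluster_size: int = 10,
                           alpha: float = SIGNIFICANCE_LEVEL,
                           method: str = "bh",
                           exclude_phecodes: set[str] | None = None,
                           ) -> pd.DataFrame:
    """One-vs-rest logistic enrichment of each phecode in each cluster.

    phenotype_presence: (patient_id, phecode) rows, one per affected patient
    (duplicates tolerated).  covariates: patient_id plus age_of_onset and
    demographic columns.  The cluster-indicator coefficient is reported as
    the log odds ratio with its Wald p, adjusted across all tests.
    """
    if method not in {"bh", "bonferroni"}:
        raise ValueError("method must be 'bh' or 'bonferroni'")
    disease_classes = disease_classes or {}
    exclude_phecodes = exclude_phecodes or set()
    pres = phenotype_presence.drop_duplicates(["patient_id", "phecode"])
    cohort = assignments.merge(covariates, on="patient_id", how="left")
    sizes = cohort["cluster"].value_counts()
    clusters = sorted(sizes[sizes >= min_cluster_size].index)
    if not clusters:
        raise ValueError("no cluster meets min_cluster_size")

    X_cov = _design_matrix(cohort.drop(columns=["patient_id", "cluster"]))
    phe_counts = pres[pres["patient_id"].isin(set(cohort["patient_id"]))]\
        .groupby("phecode")["patient_id"].nunique()
    phecodes = [p for p, n in phe_counts.items()
                if n >= min_count and p not in exclude_phecodes]

    rows: list[EnrichmentResult] = []
    for phecode in sorted(phecodes):
        affected = set(pres.loc[pres["phecode"] == phecode, "patient_id"])
        y = cohort["patient_id"].isin(affected).to_numpy(dtype=float)
        if y.min() == y.max():
            continue
        for cluster in clusters:
            ind = (cohort["cluster"] == cluster).to_numpy(dtype=float)
            X = sm.add_constant(
                pd.concat([pd.Series(ind, name="cluster", index=X_cov.index),
                           X_cov], axis=1).astype(float))
            beta = p = np.nan
            converged = False
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
                if fit.mle_retvals.get("converged", False) and \
                        np.isfinite(fit.bse["cluster"]):
                    beta = float(fit.params["cluster"])
                    p = float(fit.pvalues["cluster"])
                    converged = True
            except Exception:   # separation / singular design
                pass
            if not converged:
                # small ridge recovers the coefficient; Wald p unavailable
                try:
                    from sklearn.linear_model import LogisticRegression
                    lr = LogisticRegression(C=1e2, max_iter=1000)
                    lr.fit(X.drop(columns="const"), y)
                    beta = float(lr.coef_[0][0])
                except Exception:
                    pass
            rows.append(EnrichmentResult(
                cluster=int(cluster), phecode=phecode,
                disease_class=disease_classes.get(phecode, "unclassified"),
                log_odds_ratio=beta, p_value=p, p_adjusted=np.nan,
                significant=False, converged=converged,
                n_with_phenotype=int(y.sum())))

    table = pd.DataFrame([r.__dict__ for r in rows])
    if not len(table):
        return table
    ok = table["p_value"].notna()
    if ok.any():
        mt_method = "fdr_bh" if method == "bh" else "bonferroni"
        _, p_adj, _, _ = multipletests(table.loc[ok, "p_value"],
                                       method=mt_method)
        table.loc[ok, "p_adjusted"] = p_adj
        table.loc[ok, "significant"] = (table.loc[ok, "p_adjusted"] < alpha)
    return table.sort_values(["cluster", "p_adjusted", "phecode"],
                             na_position="last").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

@dataclass
class SurvivalComparison:
    km_curves: dict[int, pd.DataFrame]       # cluster -> (time, survival)
    global_statistic: float
    global_p: float
    pairwise: pd.DataFrame                   # cluster_a, cluster_b, stat, p, p_adj
    horizon_years: float
    n_per_cluster: dict[int, int] = field(default_factory=dict)


def km_logrank(assignments: pd.DataFrame, survival: pd.DataFrame,
               horizon_years: float = 10.0) -> SurvivalComparison:
    """KM curves censored at the horizon plus global/pairwise log-rank tests."""
    df = assignments.merge(survival, on="patient_id")
    if not len(df):
        raise ValueError("no overlap between assignments and survival records")
    over = df["time_years"] > horizon_years
    df.loc[over, "event"] = 0
    df.loc[over, "time_years"] = horizon_years

    counts = df.groupby("cluster")["event"].agg(["size", "sum"])
    keep = counts[counts["sum"] >= 1].index
    dropped = sorted(set(counts.index) - set(keep))
    if dropped:
        logger.warning("clusters without events excluded from survival: %s",
                       dropped)
    df = df[df["cluster"].isin(keep)]
    if df["cluster"].nunique() < 2:
        raise ValueError("need >=2 clusters with >=1 event each")

    curves = {}
    for cluster, grp in df.groupby("cluster"):
        km = KaplanMeierFitter()
        km.fit(grp["time_years"], grp["event"])
        sf = km.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        curves[int(cluster)] = sf

    glob = multivariate_logrank_test(df["time_years"], df["cluster"],
                                     df["event"])
    pair_rows = []
    clusters = sorted(df["cluster"].unique())
    for i, a in enumerate(clusters):
        for b in clusters[i + 1:]:
            sub = df[df["cluster"].isin([a, b])]
            ga, gb = sub["cluster"] == a, sub["cluster"] == b
            res = logrank_test(sub.loc[ga, "time_years"],
                               sub.loc[gb, "time_years"],
                               sub.loc[ga, "event"], sub.loc[gb, "event"])
            pair_rows.append({"cluster_a": int(a), "cluster_b": int(b),
                              "statistic": float(res.test_statistic),
                              "p": float(res.p_value)})
    pairwise = pd.DataFrame(pair_rows)
    if len(pairwise):
        _, p_adj, _, _ = multipletests(pairwise["p"], method="fdr_bh")
        pairwise["p_adjusted"] = p_adj
    return SurvivalComparison(
        km_curves=curves, global_statistic=float(glob.test_statistic),
        global_p=float(glob.p_value), pairwise=pairwise,
        horizon_years=horizon_years,
        n_per_cluster={int(c): int(n) for c, n in
                       df.groupby("cluster").size().items()})


# ---------------------------------------------------------------------------
# Longitudinal progression
# ---------------------------------------------------------------------------

@dataclass
class ProgressionResult:
    scores: pd.DataFrame           # patient_id, cluster, PC1..PCn
    loadings: np.ndarray
    variance_explained: np.ndarray
    anova: pd.DataFrame            # covariate x PC p-values
    n_patients: int


def progression_pca_anova(year_embeddings: pd.DataFrame,
                          index_onsets: pd.DataFrame,
                          assignments: pd.DataFrame,
                          covariates: pd.DataFrame,
                          window_years: int = 10, n_pcs: int = 3,
                          prefix: str = "s") -> ProgressionResult:
    """PCA of mean post-onset trajectories + per-PC covariate ANOVA.

    Eligible patients have an embedded year for every one of the
    `window_years` years starting at index onset; their window vectors are
    averaged patient-wise before the PCA.  ANOVA is type II on an additive
    linear model with age of onset, race, gender, site and cluster.
    """
    cols = _embedding_columns(year_embeddings, prefix)
    onset_of = dict(zip(index_onsets["patient_id"],
                        index_onsets["onset_age_years"]))
    rows = []
    for pid, grp in year_embeddings.groupby("patient_id"):
        onset = onset_of.get(pid)
        if onset is None:
            continue
        wanted = set(range(int(onset), int(onset) + window_years))
        have = grp[grp["year_index"].isin(wanted)]
        if have["year_index"].nunique() == window_years:
            rows.append({"patient_id": pid,
                         **have[cols].mean().to_dict()})
    if len(rows) < 3:
        raise ValueError(
            f"only {len(rows)} patients with full {window_years}-year "
            "post-onset coverage (need >=3)")
    frame = pd.DataFrame(rows)
    n_pcs = min(n_pcs, len(frame) - 1, len(cols))
    pca = PCA(n_components=n_pcs, random_state=0)
    scores = pca.fit_transform(frame[cols].to_numpy(dtype=np.float64))

    score_df = frame[["patient_id"]].copy()
    for j in range(n_pcs):
        score_df[f"PC{j + 1}"] = scores[:, j]
    score_df = (score_df
                .merge(assignments, on="patient_id", how="left")
                .merge(covariates, on="patient_id", how="left"))
    score_df["cluster"] = score_df["cluster"].fillna(-1).astype(int)

    terms = []
    if "age_of_onset" in score_df:
        terms.append("age_of_onset")
    terms += [f"C({c})" for c in ("race", "gender", "site")
              if c in score_df and score_df[c].nunique() > 1]
    terms.append("C(cluster)")
    anova_rows = []
    for j in range(n_pcs):
        model = smf.ols(f"PC{j + 1} ~ " + " + ".join(terms),
                        data=score_df).fit()
        tbl = sm.stats.anova_lm(model, typ=2)
        for term in tbl.index:
            if term == "Residual":
                continue
            anova_rows.append({"pc": f"PC{j + 1}", "covariate": term,
                               "p_value": float(tbl.loc[term, "PR(>F)"]),
                               "F": float(tbl.loc[term, "F"])})
    return ProgressionResult(
        scores=score_df, loadings=pca.components_,
        variance_explained=pca.explained_variance_ratio_,
        anova=pd.DataFrame(anova_rows), n_patients=len(frame))


# ---------------------------------------------------------------------------
# Emerging phenotypes
# ---------------------------------------------------------------------------

def emerging_phenotypes(phenotype_occurrences: pd.DataFrame,
                        index_onsets: pd.DataFrame,
                        assignments: pd.DataFrame,
                        top_n: int = 15, window: str = "post",
                        exclude_phecodes: set[str] | None = None
                        ) -> pd.DataFrame:
    """Per-cluster frequency of phenotypes gained after index onset.

    ``post`` mode counts phecodes whose first occurrence year is strictly
    after the patient's index-onset year (phenotypes present before onset
    are never gains); ``pre`` mode counts phecodes present before onset.
    Frequencies are normalised by cluster size; the top `top_n` per cluster
    are flagged with ties broken by (frequency desc, phecode asc).
    """
    if window not in {"post", "pre"}:
        raise ValueError("window must be 'post' or 'pre'")
    exclude_phecodes = exclude_phecodes or set()
    onset_of = dict(zip(index_onsets["patient_id"],
                        index_onsets["onset_age_years"]))
    cluster_of = dict(zip(assignments["patient_id"],
                          assignments["cluster"]))
    cluster_sizes = assignments["cluster"].value_counts().to_dict()

    occ = phenotype_occurrences[
        phenotype_occurrences["patient_id"].isin(onset_of) &
        phenotype_occurrences["patient_id"].isin(cluster_of) &
        ~phenotype_occurrences["phecode"].isin(exclude_phecodes)].copy()
    if not len(occ):
        return pd.DataFrame(columns=["cluster", "phecode", "n_patients",
                                     "frequency", "rank", "top"])
    occ["year"] = (occ["age_days"] // 365.25).astype(int)
    first = occ.groupby(["patient_id", "phecode"])["year"].agg(["min", "max"])
    first = first.reset_index()
    first["onset"] = first["patient_id"].map(onset_of)
    if window == "post":
        hit = first[first["min"] > first["onset"]]
    else:
        hit = first[first["min"] < first["onset"]]
    hit = hit.assign(cluster=hit["patient_id"].map(cluster_of))
    if not len(hit):
        return pd.DataFrame(columns=["cluster", "phecode", "n_patients",
                                     "frequency", "rank", "top"])

    counts = (hit.groupby(["cluster", "phecode"])["patient_id"]
              .nunique().rename("n_patients").reset_index())
    counts["frequency"] = counts.apply(
        lambda r: r["n_patients"] / cluster_sizes[r["cluster"]], axis=1)
    counts = counts.sort_values(["cluster", "frequency", "phecode"],
                                ascending=[True, False, True],
                                kind="mergesort").reset_index(drop=True)
    counts["rank"] = counts.groupby("cluster").cumcount() + 1
    counts["top"] = counts["rank"] <= top_n
    counts["cluster"] = counts["cluster"].astype(int)
    return counts
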