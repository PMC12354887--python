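"""GMM/BIC clustering, enrichment, survival, progression, emerging phenotypes."""

import numpy as np
import pandas as pd
import pytest

from cohortvec.strat_analysis import (
    SIGNIFICANCE_LEVEL,
    comorbidity_enrichment,
    emerging_phenotypes,
    fit_gmm_bic,
    index_cohort_mean_vectors,
    km_logrank,
    progression_pca_anova,
)


def _blob_frame(centres, n_per=200, sd=0.1, dim=3, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for c, centre in enumerate(centres):
        base = np.zeros(dim)
        base[: len(centre)] = centre
        for i in range(n_per):
            rows.append((f"P{c}_{i}", *(base + rng.normal(0, sd, dim))))
    return pd.DataFrame(rows, columns=["patient_id",
                                       *[f"s{j}" for j in range(dim)]])


# -- clustering --------------------------------------------------------------

def test_three_separated_blobs_recover_k3():
    frame = _blob_frame([(0, 0), (5, 0), (0, 5)], n_per=200, seed=1)
    model = fit_gmm_bic(frame, k_range=range(2, 7), seed=1)
    assert model.chosen_k == 3
    assert model.chosen_k == min(model.bic, key=model.bic.get)


def test_single_blob_chooses_k1_when_offered():
    frame = _blob_frame([(0, 0)], n_per=300, seed=2)
    model = fit_gmm_bic(frame, k_range=range(1, 5), seed=0)
    assert model.chosen_k == 1


def test_assignments_partition_all_patients():
    frame = _blob_frame([(0, 0), (5, 0)], n_per=100, seed=3)
    model = fit_gmm_bic(frame, k_range=range(2, 4), seed=0)
    assert len(model.assignments) == len(frame)
    assert model.assignments["patient_id"].is_unique
    assert set(model.assignments["cluster"]) <= set(range(model.chosen_k))
    np.testing.assert_allclose(model.gmm.weights_.sum(), 1.0, rtol=1e-9)


def test_index_cohort_post_window_uses_only_post_onset_years():
    rows = [("A", y, float(y)) for y in range(3, 8)] + \
           [("B", y, float(10 * y)) for y in range(3, 8)]
    years = pd.DataFrame(rows, columns=["patient_id", "year_index", "s0"])
    onsets = pd.DataFrame({"patient_id": ["A", "B"],
                           "onset_age_years": [5, 6]})
    means = index_cohort_mean_vectors(years, onsets, window="post")
    got = dict(zip(means["patient_id"], means["s0"]))
    assert got["A"] == pytest.approx(np.mean([5, 6, 7]))
    assert got["B"] == pytest.approx(np.mean([60, 70]))


# -- enrichment --------------------------------------------------------------

def _enrichment_inputs(n=1000, planted_rate=0.6, other_rate=0.05, seed=0):
    rng = np.random.default_rng(seed)
    pids = [f"P{i}" for i in range(n)]
    cluster = rng.integers(0, 2, size=n)
    present = np.where(cluster == 0,
                       rng.random(n) < planted_rate,
                       rng.random(n) < other_rate)
    presence = pd.DataFrame({"patient_id": np.array(pids)[present],
                             "phecode": "PH9"})
    covariates = pd.DataFrame({
        "patient_id": pids,
        "age_of_onset": rng.normal(55, 8, n).round(1),
        "gender": rng.choice(["F", "M"], n),
        "race": rng.choice(["R1", "R2", "R3"], n),
        "ethnicity": rng.choice(["E1", "E2"], n),
        "site": rng.choice(["S1", "S2"], n),
    })
    assignments = pd.DataFrame({"patient_id": pids, "cluster": cluster})
    return assignments, presence, covariates


def test_planted_comorbidity_detected_with_positive_log_or():
    assignments, presence, covariates = _enrichment_inputs()
    table = comorbidity_enrichment(assignments, presence, covariates)
    row = table[(table["cluster"] == 0) & (table["phecode"] == "PH9")].iloc[0]
    assert row["log_odds_ratio"] > 0
    assert row["p_adjusted"] < SIGNIFICANCE_LEVEL
    assert row["significant"]


def test_adjusted_p_never_below_raw_p():
    assignments, presence, covariates = _enrichment_inputs(seed=3)
    for method in ("bh", "bonferroni"):
        table = comorbidity_enrichment(assignments, presence, covariates,
                                       method=method)
        ok = table["p_value"].notna()
        assert (table.loc[ok, "p_adjusted"] >=
                table.loc[ok, "p_value"] - 1e-15).all()


def test_null_phenotypes_rarely_reach_significance():
    """Type-I control at the 2e-5 threshold over null simulations."""
    n_sig = 0
    n_sims = 40
    for s in range(n_sims):
        rng = np.random.default_rng(1000 + s)
        n = 400
        pids = [f"P{i}" for i in range(n)]
        assignments = pd.DataFrame({"patient_id": pids,
                                    "cluster": rng.integers(0, 2, n)})
        presence = pd.DataFrame({
            "patient_id": [p for p in pids if rng.random() < 0.3],
            "phecode": "PH1"})
        covariates = pd.DataFrame({
            "patient_id": pids,
            "age_of_onset": rng.normal(55, 8, n),
            "gender": rng.choice(["F", "M"], n)})
        table = comorbidity_enrichment(assignments, presence, covariates)
        n_sig += int(table["significant"].any())
    assert n_sig <= max(1, 0.05 * n_sims)


def test_bad_method_rejected():
    assignments, presence, covariates = _enrichment_inputs(n=100)
    with pytest.raises(ValueError):
        comorbidity_enrichment(assignments, presence, covariates,
                               method="holm")


# -- survival ----------------------------------------------------------------

def _survival_inputs(hazards, n_per=250, censor=0.05, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for c, h in enumerate(hazards):
        for i in range(n_per):
            t = rng.exponential(1 / h)
            cens = rng.exponential(1 / censor)
            rows.append((f"P{c}_{i}", c, min(t, cens), int(t <= cens)))
    df = pd.DataFrame(rows, columns=["patient_id", "cluster", "time_years",
                                     "event"])
    return df[["patient_id", "cluster"]], df[["patient_id", "time_years",
                                              "event"]]


def test_planted_hazard_ratio_detected():
    assignments, survival = _survival_inputs((0.1, 0.3), seed=1)
    cmp = km_logrank(assignments, survival)
    assert cmp.global_p < 0.01
    assert set(cmp.km_curves) == {0, 1}


def test_km_curves_start_at_one_and_never_increase():
    assignments, survival = _survival_inputs((0.1, 0.3), seed=2)
    cmp = km_logrank(assignments, survival)
    for curve in cmp.km_curves.values():
        assert curve["survival"].iloc[0] == pytest.approx(1.0)
        assert (curve["survival"].diff().dropna() <= 1e-12).all()
        assert curve["time"].max() <= cmp.horizon_years


def test_null_survival_p_is_not_systematically_small():
    ps = []
    for s in range(30):
        assignments, survival = _survival_inputs((0.2, 0.2), n_per=120,
                                                 seed=100 + s)
        ps.append(km_logrank(assignments, survival).global_p)
    assert np.mean(np.array(ps) < 0.05) < 0.25
    assert np.median(ps) > 0.15


def test_single_cluster_with_events_rejected():
    assignments, survival = _survival_inputs((0.2,), n_per=50)
    with pytest.raises(ValueError):
        km_logrank(assignments, survival)


def test_pairwise_p_adjusted_with_bh():
    assignments, survival = _survival_inputs((0.05, 0.15, 0.4), n_per=150,
                                             seed=5)
    cmp = km_logrank(assignments, survival)
    assert len(cmp.pairwise) == 3
    assert (cmp.pairwise["p_adjusted"] >= cmp.pairwise["p"] - 1e-15).all()


# -- progression -------------------------------------------------------------

def _progression_inputs(n_per=30, window=10, dim=6, drift_scale=1.0, seed=0):
    rng = np.random.default_rng(seed)
    drifts = [rng.normal(size=dim) for _ in range(2)]
    rows, assign_rows, onset_rows, covar_rows = [], [], [], []
    for c in range(2):
        for i in range(n_per):
            pid = f"P{c}_{i}"
            onset = int(rng.integers(40, 50))
            for t in range(window):
                vec = drifts[c] * t * drift_scale + \
                    rng.normal(scale=0.5, size=dim)
                rows.append((pid, onset + t, *vec))
            assign_rows.append((pid, c))
            onset_rows.append((pid, onset))
            covar_rows.append((pid, float(onset), rng.choice(["F", "M"]),
                               rng.choice(["R1", "R2"]),
                               rng.choice(["S1", "S2"])))
    years = pd.DataFrame(rows, columns=["patient_id", "year_index",
                                        *[f"s{j}" for j in range(dim)]])
    assignments = pd.DataFrame(assign_rows, columns=["patient_id", "cluster"])
    onsets = pd.DataFrame(onset_rows, columns=["patient_id",
                                               "onset_age_years"])
    covariates = pd.DataFrame(covar_rows, columns=["patient_id",
                                                   "age_of_onset", "gender",
                                                   "race", "site"])
    return years, onsets, assignments, covariates


def test_divergent_trajectories_attributed_to_cluster():
    years, onsets, assignments, covariates = _progression_inputs()
    result = progression_pca_anova(years, onsets, assignments, covariates)
    assert result.n_patients == 60
    pc1_cluster = result.anova[(result.anova["pc"] == "PC1") &
                               (result.anova["covariate"] == "C(cluster)")]
    assert pc1_cluster["p_value"].iloc[0] < 0.001


def test_variance_explained_valid_and_sums_below_one():
    years, onsets, assignments, covariates = _progression_inputs(seed=2)
    result = progression_pca_anova(years, onsets, assignments, covariates)
    v = result.variance_explained
    assert np.all(v >= 0) and np.all(v <= 1)
    assert np.all(np.diff(v) <= 1e-12)
    assert v.sum() <= 1.0 + 1e-9


def test_patients_without_full_window_excluded():
    years, onsets, assignments, covariates = _progression_inputs(n_per=10)
    # drop one year from the first patient's window
    pid = years["patient_id"].iloc[0]
    onset = onsets.loc[onsets["patient_id"] == pid,
                       "onset_age_years"].iloc[0]
    years = years[~((years["patient_id"] == pid) &
                    (years["year_index"] == onset + 4))]
    result = progression_pca_anova(years, onsets, assignments, covariates)
    assert result.n_patients == 19
    assert pid not in set(result.scores["patient_id"])


def test_too_few_eligible_patients_rejected():
    years, onsets, assignments, covariates = _progression_inputs(n_per=1)
    with pytest.raises(ValueError):
        progression_pca_anova(years.head(12), onsets, assignments,
                              covariates)


# -- emerging phenotypes -----------------------------------------------------

def _occurrence(pid, phecode, year):
    return {"patient_id": pid, "phecode": phecode,
            "age_days": int(year * 365.25) + 2}


def test_emerging_frequencies_match_manual_enumeration():
    """Four hand-constructed patients; gains enumerated by hand."""
    occ = pd.DataFrame([
        _occurrence("A", "PH1", 6), _occurrence("A", "PH2", 3),
        _occurrence("A", "PH2", 7),                       # pre+post: not a gain
        _occurrence("B", "PH1", 8),
        _occurrence("C", "PH3", 9), _occurrence("C", "PH1", 2),
        _occurrence("D", "PH3", 4),                       # pre only
    ])
    onsets = pd.DataFrame({"patient_id": list("ABCD"),
                           "onset_age_years": [5, 5, 5, 5]})
    assignments = pd.DataFrame({"patient_id": list("ABCD"),
                                "cluster": [0, 0, 1, 1]})
    table = emerging_phenotypes(occ, onsets, assignments)
    freq = {(r["cluster"], r["phecode"]): r["frequency"]
            for _, r in table.iterrows()}
    # cluster 0 (A, B): PH1 gained by both; PH2 not a gain (present pre-onset)
    assert freq == {(0, "PH1"): 1.0, (1, "PH3"): 0.5}


def test_phenotype_present_before_and_after_onset_is_not_a_gain():
    occ = pd.DataFrame([_occurrence("A", "PH1", 3),
                        _occurrence("A", "PH1", 8)])
    onsets = pd.DataFrame({"patient_id": ["A"], "onset_age_years": [5]})
    assignments = pd.DataFrame({"patient_id": ["A"], "cluster": [0]})
    assert len(emerging_phenotypes(occ, onsets, assignments)) == 0


def test_pre_window_counts_pre_onset_presence():
    occ = pd.DataFrame([_occurrence("A", "PH1", 3),
                        _occurrence("A", "PH2", 8)])
    onsets = pd.DataFrame({"patient_id": ["A"], "onset_age_years": [5]})
    assignments = pd.DataFrame({"patient_id": ["A"], "cluster": [0]})
    table = emerging_phenotypes(occ, onsets, assignments, window="pre")
    assert list(table["phecode"]) == ["PH1"]


def test_no_post_onset_events_gives_empty_table():
    occ = pd.DataFrame([_occurrence("A", "PH1", 3)])
    onsets = pd.DataFrame({"patient_id": ["A"], "onset_age_years": [5]})
    assignments = pd.DataFrame({"patient_id": ["A"], "cluster": [0]})
    assert len(emerging_phenotypes(occ, onsets, assignments)) == 0


def test_top_n_flag_uses_deterministic_tie_break():
    rows = []
    for i, phe in enumerate(["PH5", "PH2", "PH9", "PH1"]):
        rows.append(_occurrence(f"P{i}", phe, 8))
    occ = pd.DataFrame(rows)
    pids = [f"P{i}" for i in range(4)]
    onsets = pd.DataFrame({"patient_id": pids, "onset_age_years": [5] * 4})
    assignments = pd.DataFrame({"patient_id": pids, "cluster": [0] * 4})
    table = emerging_phenotypes(occ, onsets, assignments, top_n=2)
    # all frequencies tie at 0.25: phecode ascending breaks the tie
    assert list(table.loc[table["top"], "phecode"]) == ["PH1", "PH2"]
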