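"""Pair sampling, siamese fine-tuning, and mean patient vectors."""

import numpy as np
import pandas as pd
import pytest

from cohortvec.patient_embed import (
    PairSamplingError,
    desk_sbert_config,
    embed_cohort,
    embed_year,
    evaluate_pair_tasks,
    mean_patient_vector,
    sample_pairs,
    train_sbert,
    SiameseModel,
)


def _year_frame(n_patients=100, n_years=5, dim=8, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_patients):
        for y in range(40, 40 + n_years):
            rows.append((f"P{p:03d}", y, *rng.normal(size=dim)))
    return pd.DataFrame(rows, columns=["patient_id", "year_index",
                                       *[f"e{j}" for j in range(dim)]])


def _structured_frame(n_patients=60, n_years=6, dim=16, seed=0):
    """Planted structure: per-patient offset + common year drift + noise."""
    rng = np.random.default_rng(seed)
    drift = rng.normal(size=dim)
    rows = []
    for p in range(n_patients):
        offset = rng.normal(scale=2.0, size=dim)
        for y in range(n_years):
            vec = offset + drift * y + rng.normal(scale=0.3, size=dim)
            rows.append((f"P{p:03d}", 40 + y, *vec))
    return pd.DataFrame(rows, columns=["patient_id", "year_index",
                                       *[f"e{j}" for j in range(dim)]])


# -- pair sampling -----------------------------------------------------------

def test_sampler_balances_same_and_different_pairs():
    frame = _year_frame()
    pairs = sample_pairs(frame, 1000, np.random.default_rng(0))
    assert len(pairs) == 1000
    assert pairs.same_patient.sum() == 500
    assert 200 <= pairs.next_event.sum() <= 320   # ~250 adjacent positives


def test_sampler_verifies_labels_against_metadata():
    pairs = sample_pairs(_year_frame(), 400, np.random.default_rng(1))
    same = pairs.meta["patient_id_a"] == pairs.meta["patient_id_b"]
    np.testing.assert_array_equal(same.to_numpy(),
                                  pairs.same_patient.astype(bool))
    adjacent = same & (pairs.meta["year_b"] == pairs.meta["year_a"] + 1)
    np.testing.assert_array_equal(adjacent.to_numpy(),
                                  pairs.next_event.astype(bool))


def test_next_event_implies_same_patient():
    pairs = sample_pairs(_year_frame(), 600, np.random.default_rng(2))
    assert not np.any((pairs.next_event == 1) & (pairs.same_patient == 0))


def test_all_single_year_patients_cannot_give_next_event_positives():
    frame = _year_frame(n_years=1)
    with pytest.raises(PairSamplingError, match="two or more"):
        sample_pairs(frame, 100, np.random.default_rng(0))


def test_same_seed_gives_identical_pair_list():
    a = sample_pairs(_year_frame(), 300, np.random.default_rng(7))
    b = sample_pairs(_year_frame(), 300, np.random.default_rng(7))
    np.testing.assert_array_equal(a.vec_a, b.vec_a)
    pd.testing.assert_frame_equal(a.meta, b.meta)


# -- Eq. 1 mean vectors ------------------------------------------------------

def test_mean_vector_matches_independent_summation():
    rng = np.random.default_rng(0)
    frame = _year_frame(n_patients=40, n_years=7, seed=3).rename(
        columns=lambda c: c.replace("e", "s") if c.startswith("e") else c)
    means = mean_patient_vector(frame)
    cols = [c for c in frame.columns if c.startswith("s")]
    for pid in rng.choice(frame["patient_id"].unique(), 10, replace=False):
        block = frame.loc[frame["patient_id"] == pid, cols].to_numpy()
        brute = np.zeros(block.shape[1])
        for row in block:            # explicit summation oracle
            brute = brute + row
        brute /= len(block)
        got = means.loc[means["patient_id"] == pid, cols].to_numpy()[0]
        np.testing.assert_allclose(got, brute, rtol=1e-12, atol=1e-12)


def test_single_year_mean_is_identity():
    frame = _year_frame(n_patients=3, n_years=1).rename(
        columns=lambda c: c.replace("e", "s") if c.startswith("e") else c)
    means = mean_patient_vector(frame)
    cols = [c for c in frame.columns if c.startswith("s")]
    np.testing.assert_allclose(
        means.sort_values("patient_id")[cols].to_numpy(),
        frame.sort_values("patient_id")[cols].to_numpy())


def test_opposite_vectors_average_to_zero():
    v = np.arange(1.0, 9.0)
    frame = pd.DataFrame([("A", 1, *v), ("A", 2, *(-v))],
                         columns=["patient_id", "year_index",
                                  *[f"s{j}" for j in range(8)]])
    means = mean_patient_vector(frame)
    np.testing.assert_allclose(
        means[[f"s{j}" for j in range(8)]].to_numpy(), 0.0, atol=1e-15)


def test_mean_vector_invariant_to_year_order():
    frame = _year_frame(n_patients=5, n_years=6).rename(
        columns=lambda c: c.replace("e", "s") if c.startswith("e") else c)
    shuffled = frame.sample(frac=1.0, random_state=1)
    pd.testing.assert_frame_equal(mean_patient_vector(frame),
                                  mean_patient_vector(shuffled))


def test_empty_series_rejected():
    with pytest.raises(ValueError):
        mean_patient_vector(pd.DataFrame(columns=["patient_id", "s0"]))


# -- training ----------------------------------------------------------------

@pytest.fixture(scope="module")
def trained_siamese():
    frame = _structured_frame()
    rng = np.random.default_rng(0)
    pairs = sample_pairs(frame, 3000, rng)
    model, history = train_sbert(pairs, desk_sbert_config(seed=0,
                                                          training_steps=2000))
    eval_pairs = sample_pairs(frame, 1200, np.random.default_rng(99))
    return {"frame": frame, "model": model, "history": history,
            "eval_pairs": eval_pairs}


def test_both_pair_tasks_learnable_on_structured_embeddings(trained_siamese):
    result = evaluate_pair_tasks(trained_siamese["model"],
                                 trained_siamese["eval_pairs"],
                                 rng=np.random.default_rng(0))
    assert result["is_same_patient"]["mean"] > 0.70
    assert result["is_next_event"]["mean"] > 0.70


def test_shuffled_labels_give_chance_accuracy(trained_siamese):
    frame = trained_siamese["frame"]
    rng = np.random.default_rng(5)
    pairs = sample_pairs(frame, 5000, rng)
    perm = rng.permutation(len(pairs))
    pairs.same_patient = pairs.same_patient[perm]
    pairs.next_event = pairs.next_event[perm]
    model, _ = train_sbert(pairs.subset(np.arange(0, 3000)),
                           desk_sbert_config(seed=1, training_steps=600))
    # held-out shuffled pairs: nothing learnable should transfer
    result = evaluate_pair_tasks(model, pairs.subset(np.arange(3000, 5000)),
                                 rng=np.random.default_rng(1))
    assert abs(result["is_same_patient"]["mean"] - 0.5) < 0.07
    assert abs(result["is_next_event"]["mean"] - 0.5) < 0.07


def test_positive_pairs_end_closer_than_negative_pairs(trained_siamese):
    model = trained_siamese["model"]
    pairs = trained_siamese["eval_pairs"]
    ea, eb = model.embed(pairs.vec_a), model.embed(pairs.vec_b)
    dist = np.linalg.norm(ea - eb, axis=1)
    assert dist[pairs.same_patient == 1].mean() < \
        dist[pairs.same_patient == 0].mean()


def test_embedding_is_deterministic_with_fixed_dim(trained_siamese):
    model = trained_siamese["model"]
    vec = trained_siamese["frame"].iloc[0, 2:].to_numpy(dtype=float)
    a = embed_year(model, vec)
    b = embed_year(model, vec)
    np.testing.assert_array_equal(a, b)
    assert a.shape == (50,)


def test_embed_cohort_preserves_keys(trained_siamese):
    out = embed_cohort(trained_siamese["model"], trained_siamese["frame"])
    assert list(out.columns[:2]) == ["patient_id", "year_index"]
    assert len(out) == len(trained_siamese["frame"])
    assert out.filter(like="s").shape[1] == 50


def test_dimension_mismatch_rejected(trained_siamese):
    with pytest.raises(ValueError):
        embed_year(trained_siamese["model"], np.zeros(7))


def test_single_class_pairs_rejected_for_evaluation(trained_siamese):
    pairs = trained_siamese["eval_pairs"]
    only_same = pairs.subset(np.where(pairs.same_patient == 1)[0])
    with pytest.raises(ValueError):
        evaluate_pair_tasks(trained_siamese["model"], only_same)
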