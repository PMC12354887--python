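"""Year sentences, pairing, masking, and transformer behaviour."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cohortvec.code2vec import MASK, PAD, filter_vocabulary
from cohortvec.seq_model import (
    YearSentence,
    build_year_sentences,
    desk_transformer_config,
    make_nextyear_pairs,
    mask_tokens,
    masked_prediction_accuracy,
    next_year_token_accuracy,
    pool_year_embedding,
    reconstruct_codes,
    sequence_recovery_metrics,
    train_transformer,
    _pad_batch,
)


def _events(rows):
    return pd.DataFrame(rows, columns=["patient_id", "age_days", "code",
                                       "code_system"])


def _vocab_for(codes):
    rows = [("Z", (i * 37) % 9000, c, "ICD10")
            for c in codes for i in range(6)]
    return filter_vocabulary(_events(rows), 5)


# -- sentences ---------------------------------------------------------------

def test_sentences_appear_only_for_observed_years():
    vocab = _vocab_for(["D1", "D2"])
    events = _events([("A", int(3 * 365.25) + 5, "D1", "ICD10"),
                      ("A", int(5 * 365.25) + 40, "D2", "ICD10")])
    corpus = build_year_sentences(events, vocab)
    assert [(s.patient_id, s.year_index) for s in corpus.sentences] == \
        [("A", 3), ("A", 5)]


def test_patient_with_no_retained_codes_has_no_sentences():
    vocab = _vocab_for(["D1"])
    events = _events([("A", 100, "UNSEEN", "ICD10")])
    assert len(build_year_sentences(events, vocab)) == 0


def test_padding_fills_to_batch_length_with_pad_token():
    ids = [np.array([5, 6, 7, 8, 9, 10, 11]), np.array([5])]
    batch, pad_mask = _pad_batch(ids, max_len=250)
    assert batch.shape == (2, 7)
    assert (batch[1, 1:] == PAD).all()
    assert pad_mask.sum() == 6


def test_oversized_year_truncates_to_max_len(caplog):
    vocab = _vocab_for(["D1", "D2", "D3"])
    rows = [("A", int(4 * 365.25) + i, ["D1", "D2", "D3"][i % 3], "ICD10")
            for i in range(9)]
    with caplog.at_level("WARNING"):
        corpus = build_year_sentences(_events(rows), vocab, max_len=5)
    assert corpus.sentences[0].length == 5
    assert "truncated" in caplog.text


# -- pairs -------------------------------------------------------------------

@pytest.mark.parametrize("years,expected_pairs", [
    ((3, 4, 5), [(3, 4), (4, 5)]),
    ((3, 5), []),            # gap breaks the pair
    ((7,), []),              # single year
    ((1, 2, 3, 7, 8), [(1, 2), (2, 3), (7, 8)]),
])
def test_pairs_require_consecutive_years(years, expected_pairs):
    vocab = _vocab_for(["D1"])
    events = _events([("A", int(y * 365.25) + 2, "D1", "ICD10")
                      for y in years])
    pairs = make_nextyear_pairs(build_year_sentences(events, vocab))
    got = [(p.input.year_index, p.target.year_index) for p in pairs]
    assert got == expected_pairs


def test_pair_count_law_on_cohort(cohort):
    events = cohort[0]
    vocab = filter_vocabulary(events, 5)
    corpus = build_year_sentences(events, vocab, max_len=32)
    pairs = make_nextyear_pairs(corpus)
    expected = 0
    for _, sents in corpus.by_patient().items():
        years = sorted(s.year_index for s in sents)
        expected += sum(1 for a, b in zip(years, years[1:]) if b == a + 1)
    assert len(pairs) == expected


# -- masking -----------------------------------------------------------------

@settings(max_examples=60, deadline=None, derandomize=True)
@given(n_tokens=st.integers(1, 40), seed=st.integers(0, 999))
def test_masking_count_is_ceil_of_fraction(n_tokens, seed):
    sentence = YearSentence("A", 0, np.arange(3, 3 + n_tokens))
    masked = mask_tokens(sentence, 0.2, np.random.default_rng(seed))
    assert (masked.input_ids == MASK).sum() == math.ceil(0.2 * n_tokens)
    np.testing.assert_array_equal(masked.labels, sentence.token_ids)
    assert (masked.input_ids[masked.mask_positions] == MASK).all()


def test_single_token_sentence_masks_one():
    masked = mask_tokens(YearSentence("A", 0, np.array([7])), 0.2,
                         np.random.default_rng(0))
    assert (masked.input_ids == MASK).sum() == 1


def test_invalid_fraction_rejected():
    with pytest.raises(ValueError):
        mask_tokens(YearSentence("A", 0, np.array([7])), 0.0,
                    np.random.default_rng(0))


# -- trained model (copy task fixture) ---------------------------------------

def test_copy_task_reaches_high_held_out_accuracy(copy_task):
    acc = next_year_token_accuracy(copy_task["model"], copy_task["held_out"])
    assert acc >= 0.95


def test_masked_reconstruction_on_memorized_corpus(copy_task):
    acc = masked_prediction_accuracy(copy_task["model"], copy_task["corpus"],
                                     0.2, np.random.default_rng(3))
    assert acc >= 0.8


def test_untrained_model_masked_accuracy_near_chance(copy_task):
    from cohortvec.seq_model import YearTransformer
    fresh = YearTransformer(copy_task["vocab"],
                            desk_transformer_config(seed=99))
    acc = masked_prediction_accuracy(fresh, copy_task["corpus"], 0.2,
                                     np.random.default_rng(0))
    assert acc < 0.3


def test_pooled_embedding_invariant_to_token_order(copy_task):
    rng = np.random.default_rng(5)
    for s in copy_task["corpus"].sentences[:10]:
        shuffled = YearSentence(s.patient_id, s.year_index,
                                rng.permutation(s.token_ids))
        a = pool_year_embedding(copy_task["model"], s)
        b = pool_year_embedding(copy_task["model"], shuffled)
        np.testing.assert_allclose(a, b, atol=1e-5)


def test_logits_invariant_to_input_token_order(copy_task):
    model = copy_task["model"]
    pair = copy_task["held_out"][0]
    rng = np.random.default_rng(6)
    ids = pair.input.token_ids
    perm = rng.permutation(ids)
    from cohortvec.seq_model import _pad_batch, _teacher_forcing
    tgt_in, tgt_out, _ = _teacher_forcing([pair.target.token_ids], 32)
    logits = []
    for variant in (ids, perm):
        batch, pad = _pad_batch([variant], 32)
        memory = model.encode(batch, pad)
        logits.append(model.decode(tgt_in, memory, pad).data)
    np.testing.assert_allclose(logits[0], logits[1], atol=2e-4)


def test_single_token_pool_equals_its_representation(copy_task):
    model = copy_task["model"]
    s = YearSentence("A", 0, copy_task["corpus"].sentences[0].token_ids[:1])
    pooled = pool_year_embedding(model, s)
    h = model.encode(s.token_ids[None, :], np.zeros((1, 1), bool))
    np.testing.assert_allclose(pooled, h.data[0, 0], atol=1e-6)


def test_duplicated_token_multiset_pools_identically(copy_task):
    model = copy_task["model"]
    base = copy_task["corpus"].sentences[0].token_ids
    doubled = YearSentence("A", 0, np.concatenate([base, base]))
    a = pool_year_embedding(model, YearSentence("A", 0, base))
    b = pool_year_embedding(model, doubled)
    np.testing.assert_allclose(a, b, atol=1e-5)


def test_all_pad_sentence_cannot_be_pooled(copy_task):
    with pytest.raises(ValueError):
        pool_year_embedding(copy_task["model"],
                            YearSentence("A", 0, np.array([PAD, PAD])))


def test_reconstructed_codes_exclude_reserved_tokens(copy_task):
    model = copy_task["model"]
    for s in copy_task["corpus"].sentences[:20]:
        decoded = reconstruct_codes(model, s)
        assert "<PAD>" not in decoded and "<MASK>" not in decoded \
            and "<BOS>" not in decoded


def test_memorized_sentences_reconstruct_their_own_codes(copy_task):
    model, corpus = copy_task["model"], copy_task["corpus"]
    vocab = copy_task["vocab"]
    recalls = []
    for s in corpus.sentences[:50]:
        true = {vocab.token_of(int(t)) for t in s.token_ids}
        pred = reconstruct_codes(model, s)
        recalls.append(len(pred & true) / len(true))
    assert np.mean(recalls) >= 0.9


# -- recovery metrics --------------------------------------------------------

@pytest.mark.parametrize("pred,true,precision,recall", [
    ({"A", "B"}, {"A", "B"}, 1.0, 1.0),
    ({"A"}, {"B"}, 0.0, 0.0),
    ({"A", "B", "C"}, {"A", "B", "D", "E"}, 2 / 3, 1 / 2),
])
def test_recovery_metrics_match_set_arithmetic(pred, true, precision, recall):
    out = sequence_recovery_metrics([pred], [true])
    assert out["per_event_precision"] == [pytest.approx(precision)]
    assert out["per_event_recall"] == [pytest.approx(recall)]


def test_recovery_metrics_reject_mismatched_lengths():
    with pytest.raises(ValueError):
        sequence_recovery_metrics([{"A"}], [])


def test_recovery_summary_reports_mean_sd_median_iqr():
    preds = [{"A"}, {"A", "B"}, {"C"}]
    trues = [{"A"}, {"A"}, {"C", "D"}]
    out = sequence_recovery_metrics(preds, trues)
    p = out["per_event_precision"]
    assert out["precision"]["mean"] == pytest.approx(np.mean(p))
    assert out["precision"]["median"] == pytest.approx(np.median(p))


def test_empty_pairs_rejected_for_training():
    vocab = _vocab_for(["D1"])
    with pytest.raises(ValueError):
        train_transformer([], None, desk_transformer_config(), vocab=vocab)


def test_dim_head_mismatch_rejected():
    with pytest.raises(ValueError):
        desk_transformer_config(d_model=30, n_heads=4)
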