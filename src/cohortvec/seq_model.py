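"""Year-sentence transformer: next-year pre-training without positional encodings.

A patient-year is a "sentence": every retained code the patient received in
one age-year, treated as an unordered token multiset (a diagnosis date
within a year carries no reliable ordering information, so the architecture
uses no positional embeddings anywhere).  The encoder-decoder transformer is
pre-trained to predict the following year's codes from the current year's,
with 20% of input tokens masked; an encoder-side head reconstructs the
masked tokens.  The pooled (mean over non-PAD positions) final encoder layer
is the patient-year embedding consumed downstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._nn import (
    Adam,
    DecoderLayer,
    Embedding,
    EncoderLayer,
    LayerNorm,
    Linear,
    Module,
    Tensor,
    WarmupInverseSqrt,
    softmax_cross_entropy,
)
from .code2vec import BOS, MASK, N_RESERVED, PAD, CodeEmbeddingMatrix, Vocabulary
from .ehr_io import year_index

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Sentences and pairs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class YearSentence:
    """All retained codes of one patient in one age-year (token ids, unpadded)."""

    patient_id: str
    year_index: int
    token_ids: np.ndarray  # int64, length >= 1, <= max_len

    @property
    def length(self) -> int:
        return len(self.token_ids)


@dataclass
class SentenceCorpus:
    sentences: list[YearSentence]
    vocab: Vocabulary
    max_len: int

    def __len__(self) -> int:
        return len(self.sentences)

    def by_patient(self) -> dict[str, list[YearSentence]]:
        out: dict[str, list[YearSentence]] = {}
        for s in self.sentences:
            out.setdefault(s.patient_id, []).append(s)
        for lst in out.values():
            lst.sort(key=lambda s: s.year_index)
        return out


@dataclass(frozen=True)
class NextYearPair:
    """Input sentence at year i, target sentence at year i+1, same patient."""

    input: YearSentence
    target: YearSentence


def build_year_sentences(events: pd.DataFrame, vocab: Vocabulary,
                         max_len: int = 250) -> SentenceCorpus:
    """One sentence per (patient, age-year) with >=1 retained code.

    Tokens appear in age order then code order; years with more than
    `max_len` codes keep the earliest `max_len` (count logged).
    """
    kept = events[events["code"].isin(vocab.index)]
    sentences: list[YearSentence] = []
    n_truncated = 0
    if len(kept):
        kept = kept.sort_values(["patient_id", "age_days", "code"],
                                kind="mergesort")
        years = year_index(kept["age_days"].to_numpy())
        for (pid, yr), grp in kept.assign(_year=years).groupby(
                ["patient_id", "_year"], sort=True):
            ids = vocab.encode(grp["code"].tolist())
            if len(ids) > max_len:
                ids = ids[:max_len]
                n_truncated += 1
            sentences.append(YearSentence(str(pid), int(yr), ids))
    if n_truncated:
        logger.warning("%d sentences truncated to max_len=%d",
                       n_truncated, max_len)
    return SentenceCorpus(sentences=sentences, vocab=vocab, max_len=max_len)


def make_nextyear_pairs(corpus: SentenceCorpus) -> list[NextYearPair]:
    """Pairs (year i -> year i+1) for consecutive observed age-years only."""
    pairs: list[NextYearPair] = []
    for _, sents in corpus.by_patient().items():
        by_year = {s.year_index: s for s in sents}
        for s in sents:
            nxt = by_year.get(s.year_index + 1)
            if nxt is not None:
                pairs.append(NextYearPair(input=s, target=nxt))
    return pairs


@dataclass(frozen=True)
class MaskedSentence:
    input_ids: np.ndarray       # with MASK substituted
    labels: np.ndarray          # original tokens
    mask_positions: np.ndarray  # indices into the (unpadded) sentence


def mask_tokens(sentence: YearSentence, fraction: float,
                rng: np.random.Generator) -> MaskedSentence:
    """Replace ceil(fraction * length) tokens by MASK, uniformly without
    replacement; PAD positions never exist in an unpadded sentence."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("mask fraction must be in (0, 1)")
    n = sentence.length
    if n == 0:
        return MaskedSentence(sentence.token_ids.copy(),
                              sentence.token_ids.copy(),
                              np.empty(0, dtype=np.int64))
    k = math.ceil(fraction * n)
    pos = rng.choice(n, size=k, replace=False)
    masked = sentence.token_ids.copy()
    masked[pos] = MASK
    return MaskedSentence(masked, sentence.token_ids.copy(), np.sort(pos))


def _pad_batch(list_of_ids: list[np.ndarray], max_len: int
               ) -> tuple[np.ndarray, np.ndarray]:
    """Stack variable-length id arrays into (B, L) with PAD and a PAD mask."""
    L = min(max(len(ids) for ids in list_of_ids), max_len)
    batch = np.full((len(list_of_ids), L), PAD, dtype=np.int64)
    for i, ids in enumerate(list_of_ids):
        ids = ids[:L]
        batch[i, :len(ids)] = ids
    return batch, batch == PAD


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass
class TransformerConfig:
    n_layers: int = 6
    n_heads: int = 10
    dff: int = 2048
    d_model: int = 50
    max_len: int = 250
    mask_fraction: float = 0.2
    batch_size: int = 32
    beta1: float = 0.9
    beta2: float = 0.98
    eps: float = 1e-9
    rate_at_anchor: float = 0.002   # learning rate reached at anchor_step
    anchor_step: int = 10_000
    warmup_steps: int = 400
    steps: int = 20_000
    mask_loss_weight: float = 1.0
    clean_recon_weight: float = 0.2   # encoder-head weight on unmasked tokens
    validation_fraction: float = 0.05
    finetune_embeddings: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        if not 0.0 < self.mask_fraction < 1.0:
            raise ValueError("mask_fraction must be in (0, 1)")


def desk_transformer_config(**overrides) -> TransformerConfig:
    """Small preset that trains in minutes on one CPU."""
    kw = dict(n_layers=2, n_heads=2, dff=128, d_model=48, max_len=32,
              steps=2000, warmup_steps=200, anchor_step=2000,
              rate_at_anchor=2e-3)
    kw.update(overrides)
    return TransformerConfig(**kw)


class YearTransformer(Module):
    """Encoder-decoder transformer over code tokens, no positional encodings.

    The token-embedding table is initialised from the VAE code embeddings
    (reserved PAD/MASK/BOS rows start at zero) and fine-tuned by default.
    """

    def __init__(self, vocab: Vocabulary, config: TransformerConfig,
                 code_embeddings: CodeEmbeddingMatrix | None = None):
        self.config = config
        self.vocab = vocab
        rng = np.random.default_rng(config.seed)
        d = config.d_model
        if code_embeddings is not None:
            if code_embeddings.vocab.tokens != vocab.tokens:
                raise ValueError("code-embedding vocabulary mismatch")
            if code_embeddings.dim != d:
                raise ValueError(
                    f"embedding dim {code_embeddings.dim} != d_model {d}")
            init = code_embeddings.full_matrix().copy()
            # give MASK/BOS small distinct vectors so they are not degenerate
            init[MASK] = rng.normal(0, 0.02, d)
            init[BOS] = rng.normal(0, 0.02, d)
            self.embed = Embedding(vocab.size, d, rng, init=init)
        else:
            self.embed = Embedding(vocab.size, d, rng)
            self.embed.weight.data[PAD] = 0.0
        self.enc_layers = [EncoderLayer(d, config.n_heads, config.dff, rng)
                           for _ in range(config.n_layers)]
        self.enc_norm = LayerNorm(d)
        self.dec_layers = [DecoderLayer(d, config.n_heads, config.dff, rng)
                           for _ in range(config.n_layers)]
        self.dec_norm = LayerNorm(d)
        self.head = Linear(d, vocab.size, rng)

    # -- forward pieces -----------------------------------------------------
    def encode(self, ids: np.ndarray, pad_mask: np.ndarray) -> Tensor:
        h = self.embed(ids)
        for layer in self.enc_layers:
            h = layer(h, pad_mask)
        return self.enc_norm(h)

    def decode(self, target_in: np.ndarray, memory: Tensor,
               memory_pad: np.ndarray) -> Tensor:
        h = self.embed(target_in)
        for layer in self.dec_layers:
            h = layer(h, memory, memory_pad)
        return self.head(self.dec_norm(h))

    def encoder_logits(self, ids: np.ndarray, pad_mask: np.ndarray) -> Tensor:
        return self.head(self.encode(ids, pad_mask))


def _canonical(ids: np.ndarray) -> np.ndarray:
    # within-year order is meaningless without positional encodings; the
    # decoder is taught to emit the target multiset in sorted-id order
    return np.sort(ids)


def _teacher_forcing(targets: list[np.ndarray], max_len: int):
    tgt_out, tgt_pad = _pad_batch([_canonical(t) for t in targets], max_len)
    tgt_in = np.full_like(tgt_out, PAD)
    tgt_in[:, 0] = BOS
    tgt_in[:, 1:] = tgt_out[:, :-1]
    return tgt_in, tgt_out, tgt_pad


def train_transformer(pairs: list[NextYearPair],
                      code_embeddings: CodeEmbeddingMatrix | None,
                      config: TransformerConfig,
                      vocab: Vocabulary | None = None
                      ) -> tuple[YearTransformer, list[dict]]:
    """Pre-train on next-year prediction with input-side masking.

    Loss = cross-entropy of the decoded next-year sequence (PAD excluded)
    + `mask_loss_weight` x cross-entropy of the encoder head at masked
    input positions.  Returns (model, step history).
    """
    if not pairs:
        raise ValueError("no training pairs")
    if vocab is None:
        if code_embeddings is None:
            raise ValueError("need a vocabulary or code embeddings")
        vocab = code_embeddings.vocab
    model = YearTransformer(vocab, config, code_embeddings)
    params = model.parameters()
    if not config.finetune_embeddings:
        params = [p for p in params if p is not model.embed.weight]
    opt = Adam(params, lr=0.0, beta1=config.beta1, beta2=config.beta2,
               eps=config.eps)
    schedule = WarmupInverseSqrt(config.rate_at_anchor, config.anchor_step,
                                 config.warmup_steps)
    rng = np.random.default_rng(config.seed)

    n_val = int(round(config.validation_fraction * len(pairs)))
    order = rng.permutation(len(pairs))
    val_pairs = [pairs[i] for i in order[:n_val]]
    train_pairs = [pairs[i] for i in order[n_val:]] or list(pairs)

    history: list[dict] = []
    for step in range(1, config.steps + 1):
        idx = rng.integers(0, len(train_pairs), size=config.batch_size)
        batch = [train_pairs[i] for i in idx]
        masked = [mask_tokens(p.input, config.mask_fraction, rng)
                  for p in batch]
        in_ids, in_pad = _pad_batch([m.input_ids for m in masked],
                                    config.max_len)
        labels, _ = _pad_batch([m.labels for m in masked], config.max_len)
        tgt_in, tgt_out, tgt_pad = _teacher_forcing(
            [p.target.token_ids for p in batch], config.max_len)

        model.zero_grad()
        memory = model.encode(in_ids, in_pad)
        dec_logits = model.decode(tgt_in, memory, in_pad)
        loss = softmax_cross_entropy(dec_logits, tgt_out,
                                     (~tgt_pad).astype(np.float32))
        if config.mask_loss_weight > 0:
            # reconstruct the full input sequence from the encoder: masked
            # positions recover the hidden token at full weight, clean
            # positions their own identity at reduced weight
            enc_logits = model.head(memory)
            is_masked = in_ids == MASK
            recon_w = np.where(is_masked, 1.0,
                               config.clean_recon_weight
                               ).astype(np.float32) * (~in_pad)
            if recon_w.any():
                loss = loss + config.mask_loss_weight * softmax_cross_entropy(
                    enc_logits, labels, recon_w)
        if not np.isfinite(loss.item()):
            raise RuntimeError(f"non-finite transformer loss at step {step}")
        loss.backward()
        opt.lr = schedule(step)
        opt.step()
        if step % 50 == 0 or step == 1 or step == config.steps:
            rec = {"step": step, "loss": loss.item(), "lr": opt.lr}
            history.append(rec)
    if val_pairs:
        history.append({"step": config.steps,
                        "val_next_year_accuracy":
                            next_year_token_accuracy(model, val_pairs)})
    return model, history


# ---------------------------------------------------------------------------
# Evaluation and pooling
# ---------------------------------------------------------------------------

def next_year_token_accuracy(model: YearTransformer,
                             pairs: list[NextYearPair],
                             batch_size: int = 64) -> float:
    """Teacher-forced token accuracy of the decoded next-year sequence."""
    correct = total = 0
    cfg = model.config
    for start in range(0, len(pairs), batch_size):
        chunk = pairs[start:start + batch_size]
        in_ids, in_pad = _pad_batch([p.input.token_ids for p in chunk],
                                    cfg.max_len)
        tgt_in, tgt_out, tgt_pad = _teacher_forcing(
            [p.target.token_ids for p in chunk], cfg.max_len)
        memory = model.encode(in_ids, in_pad)
        pred = model.decode(tgt_in, memory, in_pad).data.argmax(axis=-1)
        keep = ~tgt_pad
        correct += int((pred[keep] == tgt_out[keep]).sum())
        total += int(keep.sum())
    return correct / max(total, 1)


def reconstruct_codes(model: YearTransformer,
                      sentence: YearSentence) -> set[str]:
    """Codes decoded for the sentence's own year from unmasked input:
    argmax of the encoder head at each position, deduplicated."""
    ids = sentence.token_ids[None, :]
    pad = ids == PAD
    pred = model.encoder_logits(ids, pad).data.argmax(axis=-1)[0]
    return {model.vocab.token_of(int(t)) for t in pred if t >= N_RESERVED}


def sequence_recovery_metrics(predicted: list[set[str]],
                              truth: list[set[str]]) -> dict:
    """Set-wise precision/recall per event with mean+-sd and median (IQR)."""
    if len(predicted) != len(truth):
        raise ValueError("predicted/truth length mismatch")
    precisions, recalls = [], []
    for pred, true in zip(predicted, truth):
        if not true:
            continue
        inter = len(pred & true)
        precisions.append(inter / len(pred) if pred else 0.0)
        recalls.append(inter / len(true))
    def summary(xs):
        a = np.asarray(xs, dtype=float)
        q1, med, q3 = np.percentile(a, [25, 50, 75]) if len(a) else (0, 0, 0)
        return {"mean": float(a.mean()) if len(a) else 0.0,
                "sd": float(a.std()) if len(a) else 0.0,
                "median": float(med), "iqr": (float(q1), float(q3))}
    return {"per_event_precision": precisions, "per_event_recall": recalls,
            "precision": summary(precisions), "recall": summary(recalls)}


def masked_prediction_accuracy(model: YearTransformer, corpus: SentenceCorpus,
                               fraction: float,
                               rng: np.random.Generator,
                               batch_size: int = 64) -> float:
    """Fraction of masked positions whose argmax equals the hidden token."""
    correct = total = 0
    sents = corpus.sentences
    for start in range(0, len(sents), batch_size):
        chunk = sents[start:start + batch_size]
        masked = [mask_tokens(s, fraction, rng) for s in chunk]
        ids, pad = _pad_batch([m.input_ids for m in masked], corpus.max_len)
        labels, _ = _pad_batch([m.labels for m in masked], corpus.max_len)
        pred = model.encoder_logits(ids, pad).data.argmax(axis=-1)
        is_masked = ids == MASK
        correct += int((pred[is_masked] == labels[is_masked]).sum())
        total += int(is_masked.sum())
    return correct / max(total, 1)


def pool_year_embedding(model: YearTransformer,
                        sentence: YearSentence) -> np.ndarray:
    """Mean over non-PAD positions of the final encoder layer; deterministic."""
    real = sentence.token_ids[sentence.token_ids != PAD]
    if not len(real):
        raise ValueError("cannot pool an all-PAD sentence")
    h = model.encode(real[None, :], np.zeros((1, len(real)), bool))
    return h.data[0].mean(axis=0).astype(np.float64)


def pool_corpus(model: YearTransformer, corpus: SentenceCorpus,
                batch_size: int = 64) -> pd.DataFrame:
    """Pooled embedding for every sentence: rows (patient_id, year_index, e0..)."""
    rows = []
    sents = corpus.sentences
    for start in range(0, len(sents), batch_size):
        chunk = sents[start:start + batch_size]
        ids, pad = _pad_batch([s.token_ids for s in chunk], corpus.max_len)
        h = model.encode(ids, pad).data
        w = (~pad).astype(np.float64)
        pooled = (h * w[:, :, None]).sum(axis=1) / w.sum(axis=1, keepdims=True)
        for s, vec in zip(chunk, pooled):
            rows.append((s.patient_id, s.year_index, *vec))
    d = model.config.d_model
    return pd.DataFrame(rows, columns=["patient_id", "year_index",
                                       *[f"e{j}" for j in range(d)]])
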