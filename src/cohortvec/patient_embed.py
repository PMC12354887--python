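"""Siamese fine-tuning of pooled year vectors and mean patient embeddings.

A shared two-layer feed-forward tower (pre-embedding layer -> 50-dim
embedding) maps each pooled patient-year vector into the final embedding
space.  It is trained on randomly formed pairs of patient-year vectors with
two objectives:

* ``is_same_patient`` — a contrastive distance loss: squared distance pulled
  toward zero for pairs from the same patient and pushed beyond a margin for
  pairs from different patients (the margin term is required; with the
  positive objective alone the tower collapses to a constant map);
* ``is_next_event`` — a two-layer classification head on the concatenated
  embeddings decides whether the second vector is the immediately following
  year of the first.

The per-patient mean of the fine-tuned year vectors (arithmetic mean over
observed years) is the patient embedding used by bulk phenotyping and all
stratification analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._nn import (
    Adam,
    Linear,
    Module,
    Tensor,
    binary_cross_entropy_with_logits,
    cat,
)

EMBED_PREFIX = "s"


class PairSamplingError(ValueError):
    pass


@dataclass
class PairSet:
    """Sampled pairs of pooled year vectors with verified labels."""

    vec_a: np.ndarray        # (n, d)
    vec_b: np.ndarray        # (n, d)
    same_patient: np.ndarray  # (n,) 0/1
    next_event: np.ndarray    # (n,) 0/1
    meta: pd.DataFrame        # patient_id_a, year_a, patient_id_b, year_b

    def __len__(self) -> int:
        return len(self.same_patient)

    def subset(self, idx) -> "PairSet":
        return PairSet(self.vec_a[idx], self.vec_b[idx],
                       self.same_patient[idx], self.next_event[idx],
                       self.meta.iloc[idx].reset_index(drop=True))


def _embedding_columns(frame: pd.DataFrame, prefix: str = "e") -> list[str]:
    cols = [c for c in frame.columns if c.startswith(prefix) and
            c[len(prefix):].isdigit()]
    return sorted(cols, key=lambda c: int(c[len(prefix):]))


def sample_pairs(year_vectors: pd.DataFrame, n_pairs: int,
                 rng: np.random.Generator) -> PairSet:
    """Balanced pair sampling from a (patient_id, year_index, e0..) frame.

    50% same-patient pairs (half of them adjacent ordered years, giving
    next_event=1) and 50% different-patient pairs.  Labels are set from the
    actual sampled years, so the invariant next_event=1 => same_patient=1
    holds by construction.
    """
    cols = _embedding_columns(year_vectors)
    vecs = year_vectors[cols].to_numpy(dtype=np.float64)
    pids = year_vectors["patient_id"].to_numpy()
    years = year_vectors["year_index"].to_numpy()
    by_patient: dict[str, np.ndarray] = {}
    for i, p in enumerate(pids):
        by_patient.setdefault(p, []).append(i)
    by_patient = {p: np.asarray(ix) for p, ix in by_patient.items()}
    if len(by_patient) < 2:
        raise PairSamplingError("need at least two patients")

    multi = [p for p, ix in by_patient.items() if len(ix) >= 2]
    if not multi:
        raise PairSamplingError("no patient has two or more embedded years")
    adjacent: list[tuple[int, int]] = []
    for p in multi:
        ix = by_patient[p]
        yr = years[ix]
        order = np.argsort(yr)
        for a, b in zip(order[:-1], order[1:]):
            if yr[b] == yr[a] + 1:
                adjacent.append((ix[a], ix[b]))
    n_same = n_pairs // 2
    n_adj = n_same // 2
    if n_adj and not adjacent:
        raise PairSamplingError(
            "next_event positives impossible: no patient has two "
            "consecutive embedded years")

    rows = []
    for _ in range(n_adj):
        a, b = adjacent[rng.integers(0, len(adjacent))]
        rows.append((a, b, 1, 1))
    for _ in range(n_same - n_adj):
        p = multi[rng.integers(0, len(multi))]
        a, b = rng.choice(by_patient[p], size=2, replace=False)
        nxt = int(years[b] == years[a] + 1)
        rows.append((a, b, 1, nxt))
    patients = list(by_patient)
    for _ in range(n_pairs - n_same):
        pa, pb = rng.choice(len(patients), size=2, replace=False)
        a = rng.choice(by_patient[patients[pa]])
        b = rng.choice(by_patient[patients[pb]])
        rows.append((a, b, 0, 0))
    ia, ib, same, nxt = (np.asarray(x) for x in zip(*rows))
    meta = pd.DataFrame({"patient_id_a": pids[ia], "year_a": years[ia],
                         "patient_id_b": pids[ib], "year_b": years[ib]})
    return PairSet(vecs[ia], vecs[ib], same.astype(np.int64),
                   nxt.astype(np.int64), meta)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass
class SBertConfig:
    pre_embedding_width: int = 128
    embedding_dim: int = 50
    head_width: int = 64
    learning_rate: float = 3e-4
    training_steps: int = 5000
    batch_size: int = 64
    margin: float = 2.0
    next_event_weight: float = 1.0
    seed: int = 0


def desk_sbert_config(**overrides) -> SBertConfig:
    # the tower is tiny; the full 5,000-step schedule costs seconds
    kw = dict(training_steps=5000)
    kw.update(overrides)
    return SBertConfig(**kw)


class SiameseModel(Module):
    """Shared tower (pre-embedding -> 50-dim) + 2-layer next-event head."""

    def __init__(self, input_dim: int, config: SBertConfig):
        self.config = config
        self.input_dim = input_dim
        rng = np.random.default_rng(config.seed)
        self.tower1 = Linear(input_dim, config.pre_embedding_width, rng)
        self.tower2 = Linear(config.pre_embedding_width,
                             config.embedding_dim, rng)
        self.head1 = Linear(3 * config.embedding_dim, config.head_width, rng)
        self.head2 = Linear(config.head_width, 1, rng)

    def tower(self, x: Tensor) -> Tensor:
        return self.tower2(self.tower1(x).relu())

    def head_logits(self, ea: Tensor, eb: Tensor) -> Tensor:
        # sentence-embedding-style classifier input: (u, v, |u - v|)
        diff = ea - eb
        absdiff = (diff * diff + 1e-12) ** 0.5
        h = self.head1(cat([ea, eb, absdiff], axis=-1)).relu()
        return self.head2(h).reshape(-1)

    def embed(self, vectors: np.ndarray) -> np.ndarray:
        """Deterministic inference pass of the tower."""
        x = np.atleast_2d(np.asarray(vectors, dtype=np.float32))
        if x.shape[1] != self.input_dim:
            raise ValueError(
                f"input dim {x.shape[1]} != model dim {self.input_dim}")
        return self.tower(Tensor(x)).data.astype(np.float64)


def train_sbert(pairs: PairSet, config: SBertConfig,
                ) -> tuple[SiameseModel, list[dict]]:
    """Fine-tune the siamese tower on the two pair tasks."""
    if not len(pairs):
        raise ValueError("no training pairs")
    model = SiameseModel(pairs.vec_a.shape[1], config)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    # inverse-frequency class weights keep the head's 0.5 cutoff calibrated
    # even though only ~25% of sampled pairs are next-event positives
    pos_rate = float(np.clip(pairs.next_event.mean(), 1e-3, 1 - 1e-3))
    class_w = {1: 0.5 / pos_rate, 0: 0.5 / (1.0 - pos_rate)}
    history = []
    for step in range(1, config.training_steps + 1):
        idx = rng.integers(0, len(pairs), size=config.batch_size)
        ea = model.tower(Tensor(pairs.vec_a[idx]))
        eb = model.tower(Tensor(pairs.vec_b[idx]))
        same = pairs.same_patient[idx].astype(np.float32)
        d2 = ((ea - eb) ** 2.0).sum(axis=1)
        dist = (d2 + 1e-9) ** 0.5
        contrast = (Tensor(same) * d2
                    + Tensor(1.0 - same) * ((config.margin - dist).relu() ** 2.0)
                    ).mean()
        logits = model.head_logits(ea, eb)
        nxt = pairs.next_event[idx]
        bce = binary_cross_entropy_with_logits(
            logits, nxt, np.where(nxt == 1, class_w[1], class_w[0]))
        loss = contrast + config.next_event_weight * bce
        if not np.isfinite(loss.item()):
            raise RuntimeError(f"non-finite siamese loss at step {step}")
        model.zero_grad()
        loss.backward()
        opt.step()
        if step % 100 == 0 or step == 1:
            history.append({"step": step, "loss": loss.item(),
                            "contrastive": contrast.item(),
                            "next_event_bce": bce.item()})
    return model, history


# ---------------------------------------------------------------------------
# Embedding and Eq.-1 mean vectors
# ---------------------------------------------------------------------------

def embed_year(model: SiameseModel, pooled_vector: np.ndarray) -> np.ndarray:
    """Fine-tuned 50-dim embedding of one pooled year vector."""
    return model.embed(pooled_vector)[0]


def embed_cohort(model: SiameseModel,
                 pooled: pd.DataFrame) -> pd.DataFrame:
    """Apply the tower to every pooled patient-year vector.

    Returns a frame keyed by (patient_id, year_index) with columns s0..s49.
    """
    cols = _embedding_columns(pooled)
    emb = model.embed(pooled[cols].to_numpy(dtype=np.float64))
    out = pd.DataFrame(
        emb, columns=[f"{EMBED_PREFIX}{j}" for j in range(emb.shape[1])])
    out.insert(0, "year_index", pooled["year_index"].to_numpy())
    out.insert(0, "patient_id", pooled["patient_id"].to_numpy())
    return out


def mean_patient_vector(year_vectors: pd.DataFrame,
                        prefix: str = EMBED_PREFIX) -> pd.DataFrame:
    """Per-patient arithmetic mean of year embeddings (the patient vector).

    mean_k = (1/n) * sum_{t=1..n} v_k^t over the n observed years of
    patient k; order-free and exact to floating-point tolerance.
    """
    if not len(year_vectors):
        raise ValueError("empty year-embedding series")
    cols = _embedding_columns(year_vectors, prefix)
    if not cols:
        raise ValueError(f"no embedding columns with prefix {prefix!r}")
    grouped = year_vectors.groupby("patient_id", sort=True)
    means = grouped[cols].mean()
    means["n_years"] = grouped.size()
    return means.reset_index()


def evaluate_pair_tasks(model: SiameseModel, pairs: PairSet,
                        k_iterations: int = 5,
                        calibration_fraction: float = 0.3,
                        rng: np.random.Generator | None = None) -> dict:
    """Accuracy (mean +- sd over k folds) of both pair tasks.

    is_same_patient is decided by thresholding the embedding distance (the
    threshold maximises accuracy on a calibration split); is_next_event by
    the head's 0.5 cutoff.  Each task is scored on a class-balanced
    subsample of the evaluation pairs, so chance performance is 0.5 for
    both tasks regardless of the sampler's positive rate.
    """
    if len(np.unique(pairs.same_patient)) < 2 or \
            len(np.unique(pairs.next_event)) < 2:
        raise ValueError("pair set must contain both classes of both tasks")
    rng = rng or np.random.default_rng(0)
    n = len(pairs)
    order = rng.permutation(n)
    n_cal = max(int(calibration_fraction * n), 2)
    cal, ev = order[:n_cal], order[n_cal:]

    ea = model.embed(pairs.vec_a)
    eb = model.embed(pairs.vec_b)
    dist = np.linalg.norm(ea - eb, axis=1)
    logits = model.head_logits(
        Tensor(ea.astype(np.float32)), Tensor(eb.astype(np.float32))).data

    # threshold maximising calibration accuracy over candidate midpoints
    cand = np.unique(dist[cal])
    cuts = np.concatenate([[cand[0] - 1e-9],
                           (cand[:-1] + cand[1:]) / 2, [cand[-1] + 1e-9]])
    accs = [(np.mean((dist[cal] < c) == (pairs.same_patient[cal] == 1)), c)
            for c in cuts]
    threshold = max(accs)[1]

    def balance(idx: np.ndarray, labels: np.ndarray) -> np.ndarray:
        pos = idx[labels[idx] == 1]
        neg = idx[labels[idx] == 0]
        m = min(len(pos), len(neg))
        if m == 0:
            return idx
        return np.concatenate([rng.choice(pos, m, replace=False),
                               rng.choice(neg, m, replace=False)])

    same_pred = dist < threshold
    next_pred = logits > 0.0
    ev_same = balance(ev, pairs.same_patient)
    ev_next = balance(ev, pairs.next_event)
    acc_same = [float(np.mean(same_pred[f] == (pairs.same_patient[f] == 1)))
                for f in np.array_split(rng.permutation(ev_same),
                                        k_iterations) if len(f)]
    acc_next = [float(np.mean(next_pred[f] == (pairs.next_event[f] == 1)))
                for f in np.array_split(rng.permutation(ev_next),
                                        k_iterations) if len(f)]
    return {
        "is_same_patient": {"mean": float(np.mean(acc_same)),
                            "sd": float(np.std(acc_same))},
        "is_next_event": {"mean": float(np.mean(acc_next)),
                          "sd": float(np.std(acc_next))},
        "threshold": float(threshold),
    }
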