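"""Code-vocabulary embedding: onset-frequency matrix + variational autoencoder.

Each retained code is described by how often it occurs at every week of
patient age (default 0-4320 weeks, i.e. 90 years), pooled over the cohort.
A small VAE compresses each (unit-normalised) frequency row to a latent
mean vector; these latent means are the "vocabulary" consumed by the
year-sentence transformer.  Besides the usual reconstruction and KL terms,
the loss carries a cosine-preservation term that keeps pairwise cosine
similarity between latent code vectors close to the similarity between
their frequency rows.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._nn import Adam, Linear, Module, Tensor
from .ehr_io import week_index

logger = logging.getLogger(__name__)

#: reserved token indices, shared with the transformer
PAD, MASK, BOS = 0, 1, 2
N_RESERVED = 3


class VocabularyError(ValueError):
    pass


@dataclass(frozen=True)
class Vocabulary:
    """Retained code tokens with reserved PAD/MASK/BOS indices.

    Data codes occupy indices ``N_RESERVED .. size-1`` in the order given by
    ``tokens`` (descending total count, ties broken by code string).
    """

    tokens: tuple[str, ...]
    index: dict[str, int] = field(default_factory=dict, compare=False)

    def __post_init__(self):
        object.__setattr__(
            self, "index", {t: i + N_RESERVED for i, t in enumerate(self.tokens)})

    @property
    def size(self) -> int:
        """Total index space including reserved tokens."""
        return len(self.tokens) + N_RESERVED

    @property
    def n_codes(self) -> int:
        return len(self.tokens)

    def __contains__(self, code: str) -> bool:
        return code in self.index

    def encode(self, codes) -> np.ndarray:
        return np.array([self.index[c] for c in codes], dtype=np.int64)

    def token_of(self, idx: int) -> str:
        if idx < N_RESERVED:
            return ("<PAD>", "<MASK>", "<BOS>")[idx]
        return self.tokens[idx - N_RESERVED]


def filter_vocabulary(events: pd.DataFrame, min_occurrences: int = 5) -> Vocabulary:
    """Retain codes whose total count is strictly greater than `min_occurrences`."""
    if not len(events):
        raise VocabularyError("empty event table")
    counts = events["code"].value_counts()
    kept = counts[counts > min_occurrences]
    if not len(kept):
        raise VocabularyError(
            f"no code appears more than {min_occurrences} times; "
            "lower the threshold")
    order = sorted(kept.items(), key=lambda kv: (-kv[1], kv[0]))
    return Vocabulary(tokens=tuple(code for code, _ in order))


def build_frequency_matrix(events: pd.DataFrame, vocab: Vocabulary,
                           n_weeks: int = 4320) -> np.ndarray:
    """Codes x age-week count matrix, shape (vocab.n_codes, n_weeks).

    Row order matches ``vocab.tokens``; events of dropped codes are ignored;
    ages past the last week bin are clipped into it (with a warning).
    """
    mat = np.zeros((vocab.n_codes, n_weeks), dtype=np.float64)
    kept = events[events["code"].isin(vocab.index)]
    if not len(kept):
        return mat
    weeks = week_index(kept["age_days"].to_numpy())
    n_clip = int((weeks >= n_weeks).sum())
    if n_clip:
        logger.warning("%d events beyond week %d clipped to last bin",
                       n_clip, n_weeks - 1)
    weeks = np.clip(weeks, 0, n_weeks - 1)
    rows = np.array([vocab.index[c] - N_RESERVED for c in kept["code"]])
    np.add.at(mat, (rows, weeks), 1.0)
    return mat


# ---------------------------------------------------------------------------
# VAE
# ---------------------------------------------------------------------------

@dataclass
class VAEConfig:
    latent_dim: int = 50
    hidden: tuple[int, ...] = (1024, 256)   # 3 trained encoder layers total
    learning_rate: float = 1e-7
    batch_size: int = 64
    epochs: int = 100
    recon_weight: float = 1.0
    cosine_weight: float = 1.0
    kl_weight: float = 0.1
    validation_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        for w in (self.recon_weight, self.cosine_weight, self.kl_weight):
            if w < 0:
                raise ValueError("loss weights must be >= 0")


def desk_vae_config(**overrides) -> VAEConfig:
    """Small fast preset for desk-scale cohorts and tests."""
    kw = dict(latent_dim=48, hidden=(128, 64), learning_rate=1e-3,
              batch_size=64, epochs=100)
    kw.update(overrides)
    return VAEConfig(**kw)


def _normalize_rows(matrix: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(matrix, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return (matrix / norms).astype(np.float32)


class CodeVAE(Module):
    """Encoder (width stack -> mu, logvar) with mirrored decoder."""

    def __init__(self, n_features: int, config: VAEConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        widths = [n_features, *config.hidden]
        self.enc_layers = [Linear(a, b, rng) for a, b in zip(widths, widths[1:])]
        self.mu_head = Linear(widths[-1], config.latent_dim, rng)
        self.logvar_head = Linear(widths[-1], config.latent_dim, rng)
        rev = [config.latent_dim, *reversed(config.hidden)]
        self.dec_layers = [Linear(a, b, rng) for a, b in zip(rev, rev[1:])]
        self.dec_out = Linear(rev[-1], n_features, rng)
        self.n_features = n_features

    def encode(self, x: Tensor) -> tuple[Tensor, Tensor]:
        h = x
        for layer in self.enc_layers:
            h = layer(h).relu()
        return self.mu_head(h), self.logvar_head(h)

    def decode(self, z: Tensor) -> Tensor:
        h = z
        for layer in self.dec_layers:
            h = layer(h).relu()
        return self.dec_out(h)

    def loss_terms(self, x: Tensor, rng: np.random.Generator,
                   sample: bool = True) -> dict[str, Tensor]:
        mu, logvar = self.encode(x)
        if sample:
            eps = Tensor(rng.standard_normal(mu.shape))
            z = mu + (logvar * 0.5).exp() * eps
        else:
            z = mu
        recon = ((self.decode(z) - x) ** 2.0).mean()
        kl = ((mu ** 2.0 + logvar.exp() - logvar - 1.0) * 0.5).mean()
        # pairwise cosine preservation within the batch
        mun = mu * ((mu * mu).sum(axis=1, keepdims=True) + 1e-8) ** -0.5
        cos_lat = mun @ mun.swapaxes(0, 1)
        xn = x.data / (np.linalg.norm(x.data, axis=1, keepdims=True) + 1e-8)
        cos_in = Tensor(xn @ xn.T)
        cosine = ((cos_lat - cos_in) ** 2.0).mean()
        return {"recon": recon, "cosine": cosine, "kl": kl}


@dataclass
class CodeEmbeddingMatrix:
    """Latent code means (and log-variances) aligned to a Vocabulary."""

    vocab: Vocabulary
    means: np.ndarray      # (n_codes, latent_dim)
    logvars: np.ndarray    # (n_codes, latent_dim)

    @property
    def dim(self) -> int:
        return self.means.shape[1]

    def full_matrix(self) -> np.ndarray:
        """Embedding table over the whole index space; reserved rows are zero."""
        full = np.zeros((self.vocab.size, self.dim), dtype=np.float32)
        full[N_RESERVED:] = self.means
        return full

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.means,
                          columns=[f"z{j}" for j in range(self.dim)])
        df.insert(0, "code", list(self.vocab.tokens))
        return df

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def train_code_vae(matrix: np.ndarray, config: VAEConfig) -> tuple[CodeVAE, list[dict]]:
    """Train the VAE on unit-normalised frequency rows.

    Returns the model and a per-epoch history of training/validation loss
    terms.  Aborts on non-finite loss.
    """
    if matrix.size == 0:
        raise ValueError("empty frequency matrix")
    x = _normalize_rows(matrix)
    n = x.shape[0]
    rng = np.random.default_rng(config.seed)
    n_val = int(round(config.validation_fraction * n))
    perm = rng.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    if not len(train_idx):
        raise ValueError("no training rows after validation split")

    model = CodeVAE(x.shape[1], config)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    history: list[dict] = []

    def total(terms: dict[str, Tensor]) -> Tensor:
        return (terms["recon"] * config.recon_weight
                + terms["cosine"] * config.cosine_weight
                + terms["kl"] * config.kl_weight)

    for epoch in range(config.epochs):
        order = rng.permutation(train_idx)
        epoch_losses = []
        for start in range(0, len(order), config.batch_size):
            batch = order[start:start + config.batch_size]
            if len(batch) < 2:      # cosine term needs a pair
                continue
            model.zero_grad()
            # with no KL term the model degenerates to a plain autoencoder;
            # sampling noise would only hurt it, so encode deterministically
            terms = model.loss_terms(Tensor(x[batch]), rng,
                                     sample=config.kl_weight > 0)
            loss = total(terms)
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"non-finite VAE loss at epoch {epoch}: "
                    + {k: v.item() for k, v in terms.items()}.__repr__())
            loss.backward()
            opt.step()
            epoch_losses.append(loss.item())
        record = {"epoch": epoch, "train_loss": float(np.mean(epoch_losses))}
        if len(val_idx) >= 2:
            vterms = model.loss_terms(Tensor(x[val_idx]), rng, sample=False)
            record["val_loss"] = total(vterms).item()
            record.update({f"val_{k}": v.item() for k, v in vterms.items()})
        history.append(record)
    return model, history


def encode_codes(model: CodeVAE, matrix: np.ndarray,
                 vocab: Vocabulary) -> CodeEmbeddingMatrix:
    """Deterministic latent means for every vocabulary code (no sampling)."""
    if matrix.shape[0] != vocab.n_codes:
        raise ValueError(
            f"matrix rows {matrix.shape[0]} != vocabulary codes {vocab.n_codes}")
    if matrix.shape[1] != model.n_features:
        raise ValueError(
            f"matrix width {matrix.shape[1]} != model features {model.n_features}")
    x = _normalize_rows(matrix)
    means, logvars = [], []
    for start in range(0, x.shape[0], 256):
        mu, lv = model.encode(Tensor(x[start:start + 256]))
        means.append(mu.data.copy())
        logvars.append(lv.data.copy())
    return CodeEmbeddingMatrix(vocab=vocab,
                               means=np.concatenate(means),
                               logvars=np.concatenate(logvars))
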