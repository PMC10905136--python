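"""Paragraph-vector (PV-DBOW) document embedding with negative sampling.

Each document gets a trainable vector d; training maximizes, for target
words w sampled around each document position,

    log sigma(u_w . d) + sum_k log sigma(-u_nk . d),

with the k noise words n drawn from the unigram distribution raised to the
3/4 power. This is the distributed-bag-of-words paragraph-vector variant:
the document vector alone predicts its words, and the context window acts
as the span around each position from which the target word is sampled.
Optimization is plain sequential SGD with a linearly decaying learning
rate: one (position, target, negatives) triple per document position per
epoch, updates applied in corpus order, single-threaded, all sampling from
one seeded generator — so training is bit-reproducible. The inner loop is
JIT-compiled with numba.

Cosine similarity between trained document vectors quantifies how much two
documents share semantic content — here, how much a session's discussion
resembles the literary segment read in that session.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from numba import njit

from .preprocess import TokenDoc

DocId = tuple[str, int, str]


@dataclass(frozen=True)
class EmbedConfig:
    """Hyperparameters of the paragraph-vector model.

    ``window`` defaults downstream to the rounded mean sentence length of the
    group, reflecting the discourse span of conversation. ``epochs`` defaults
    to 30_000 full passes, the point where similarities stabilize on corpora
    of a dozen short documents; desk tests use far fewer.
    """

    dim: int = 100
    window: int = 5
    epochs: int = 30_000
    negatives: int = 5
    lr_start: float = 0.025
    lr_end: float = 0.0001
    seed: int = 0
    min_count: int = 1

    def __post_init__(self) -> None:
        if self.dim < 2:
            raise ValueError("dim must be >= 2")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.negatives < 1:
            raise ValueError("negatives must be >= 1")
        if not self.lr_start >= self.lr_end > 0:
            raise ValueError("need lr_start >= lr_end > 0")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")


@dataclass
class EmbeddingModel:
    config: EmbedConfig
    vocab: dict[str, int]  # lemma -> row index
    frequencies: np.ndarray  # corpus frequency per vocab row
    word_vectors: np.ndarray  # (|vocab|, dim)
    doc_ids: list[DocId]
    doc_vectors: np.ndarray  # (n_docs, dim)
    epoch_losses: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def final_loss(self) -> float:
        return float(self.epoch_losses[-1]) if self.epoch_losses.size else float("nan")

    def doc_vector(self, doc_id: DocId) -> np.ndarray:
        try:
            return self.doc_vectors[self.doc_ids.index(doc_id)]
        except ValueError:
            raise KeyError(f"unknown doc id {doc_id!r}") from None

    # -- persistence: vocab TSV + npz arrays + config JSON -------------------
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        with open(directory / "vocab.tsv", "w", encoding="utf-8") as fh:
            fh.write("lemma\tindex\tfrequency\n")
            for lemma, idx in sorted(self.vocab.items(), key=lambda kv: kv[1]):
                fh.write(f"{lemma}\t{idx}\t{int(self.frequencies[idx])}\n")
        np.savez(
            directory / "vectors.npz",
            word_vectors=self.word_vectors,
            doc_vectors=self.doc_vectors,
            epoch_losses=self.epoch_losses,
        )
        with open(directory / "config.json", "w", encoding="utf-8") as fh:
            json.dump(
                {"config": asdict(self.config), "doc_ids": [list(d) for d in self.doc_ids]},
                fh,
                indent=2,
            )
            fh.write("\n")

    @classmethod
    def load(cls, directory: str | Path) -> "EmbeddingModel":
        directory = Path(directory)
        vocab: dict[str, int] = {}
        freqs: list[int] = []
        with open(directory / "vocab.tsv", encoding="utf-8") as fh:
            next(fh)
            for line in fh:
                lemma, idx, freq = line.rstrip("\n").split("\t")
                vocab[lemma] = int(idx)
                freqs.append(int(freq))
        arrays = np.load(directory / "vectors.npz")
        with open(directory / "config.json", encoding="utf-8") as fh:
            meta = json.load(fh)
        return cls(
            config=EmbedConfig(**meta["config"]),
            vocab=vocab,
            frequencies=np.array(freqs, dtype=np.int64),
            word_vectors=arrays["word_vectors"],
            doc_ids=[(d[0], int(d[1]), d[2]) for d in meta["doc_ids"]],
            doc_vectors=arrays["doc_vectors"],
            epoch_losses=arrays["epoch_losses"],
        )


@dataclass
class SimilarityMatrix:
    row_ids: list[DocId]
    col_ids: list[DocId]
    values: np.ndarray  # (len(row_ids), len(col_ids))

    def lookup(self, row: DocId, col: DocId) -> float:
        return float(self.values[self.row_ids.index(row), self.col_ids.index(col)])


# ---------------------------------------------------------------------------
# Objective and gradients (the unit the finite-difference oracle checks)
# ---------------------------------------------------------------------------


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _log_sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically stable log sigma(x) = -log(1 + exp(-x))
    return -np.logaddexp(0.0, -x)


def triple_loss(d: np.ndarray, u_w: np.ndarray, u_neg: np.ndarray) -> float:
    """Negative-sampling loss for one (doc vector, target word, negatives)
    triple: -log sigma(u_w.d) - sum_k log sigma(-u_nk.d)."""
    pos = float(_log_sigmoid(np.atleast_1d(d @ u_w))[0])
    neg = float(_log_sigmoid(-(u_neg @ d)).sum())
    return -(pos + neg)


def triple_grads(
    d: np.ndarray, u_w: np.ndarray, u_neg: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Analytic gradients of :func:`triple_loss` w.r.t. (d, u_w, u_neg)."""
    s_pos = float(_sigmoid(np.atleast_1d(d @ u_w))[0])
    s_neg = _sigmoid(u_neg @ d)  # (k,)
    grad_d = -(1.0 - s_pos) * u_w + s_neg @ u_neg
    grad_w = -(1.0 - s_pos) * d
    grad_neg = s_neg[:, None] * d[None, :]
    return grad_d, grad_w, grad_neg


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


@njit(cache=True)
def _sgd_epochs(
    tokens: np.ndarray,
    doc_of_pos: np.ndarray,
    pos_in_doc: np.ndarray,
    doc_start: np.ndarray,
    doc_len: np.ndarray,
    noise_cdf: np.ndarray,
    word_vectors: np.ndarray,
    doc_vectors: np.ndarray,
    window: int,
    epochs: int,
    negatives: int,
    lr_start: float,
    lr_end: float,
    seed: int,
) -> np.ndarray:
    """Sequential negative-sampling SGD; mutates the vectors in place and
    returns the mean per-position loss of each epoch."""
    np.random.seed(seed)
    n_pos = tokens.size
    dim = word_vectors.shape[1]
    losses = np.zeros(epochs)
    neu = np.zeros(dim)
    for epoch in range(epochs):
        if epochs > 1:
            lr = lr_start + (lr_end - lr_start) * (epoch / (epochs - 1))
        else:
            lr = lr_start
        total = 0.0
        for p in range(n_pos):
            di = doc_of_pos[p]
            j = pos_in_doc[p] + np.random.randint(-window, window + 1)
            if j < 0:
                j = 0
            elif j >= doc_len[di]:
                j = doc_len[di] - 1
            target = tokens[doc_start[di] + j]
            d = doc_vectors[di]
            for c in range(dim):
                neu[c] = 0.0
            # positive pair and `negatives` noise words
            for k in range(negatives + 1):
                if k == 0:
                    w = target
                    label = 1.0
                else:
                    w = np.searchsorted(noise_cdf, np.random.random())
                    label = 0.0
                x = 0.0
                for c in range(dim):
                    x += d[c] * word_vectors[w, c]
                # stable sigma(x) and log-loss
                if x >= 0:
                    s = 1.0 / (1.0 + np.exp(-x))
                else:
                    ex = np.exp(x)
                    s = ex / (1.0 + ex)
                if label > 0.5:
                    total += np.log(s + 1e-12) * -1.0
                else:
                    total += np.log(1.0 - s + 1e-12) * -1.0
                g = lr * (label - s)
                for c in range(dim):
                    neu[c] += g * word_vectors[w, c]
                    word_vectors[w, c] += g * d[c]
            for c in range(dim):
                d[c] += neu[c]
        losses[epoch] = total / n_pos
    return losses


def train(docs: Sequence[TokenDoc], config: EmbedConfig) -> EmbeddingModel:
    """Train PV-DBOW document and word vectors on the given documents.

    Deterministic under (docs order, config): all sampling flows from one
    seeded generator and updates are accumulated synchronously per epoch.
    """
    docs = list(docs)
    if not docs:
        raise ValueError("no documents to train on")
    doc_ids = [doc.doc_id for doc in docs]
    if len(set(doc_ids)) != len(doc_ids):
        raise ValueError("duplicate doc ids in training set")

    # Vocabulary with frequency floor.
    freq_all: dict[str, int] = {}
    for doc in docs:
        for lem in doc.lemmas:
            freq_all[lem] = freq_all.get(lem, 0) + 1
    vocab = {
        lem: i
        for i, lem in enumerate(sorted(l for l, f in freq_all.items() if f >= config.min_count))
    }
    if not vocab:
        raise ValueError("vocabulary empty after min_count filtering")

    encoded: list[np.ndarray] = []
    for doc in docs:
        ids = np.array([vocab[l] for l in doc.lemmas if l in vocab], dtype=np.int64)
        if ids.size == 0:
            raise ValueError(f"{doc.doc_id}: empty after min_count filtering")
        encoded.append(ids)

    frequencies = np.zeros(len(vocab), dtype=np.int64)
    for ids in encoded:
        np.add.at(frequencies, ids, 1)

    # Flattened corpus layout: one training position per token occurrence.
    tokens = np.concatenate(encoded)
    doc_of_pos = np.concatenate(
        [np.full(ids.size, i, dtype=np.int64) for i, ids in enumerate(encoded)]
    )
    pos_in_doc = np.concatenate([np.arange(ids.size, dtype=np.int64) for ids in encoded])
    doc_len = np.array([ids.size for ids in encoded], dtype=np.int64)
    doc_start = np.concatenate([[0], np.cumsum(doc_len)[:-1]])
    n_pos = tokens.size

    # Noise distribution: unigram^0.75.
    noise = frequencies.astype(float) ** 0.75
    noise_cdf = np.cumsum(noise / noise.sum())

    rng = np.random.default_rng(config.seed)
    bound = 0.5 / config.dim
    word_vectors = rng.uniform(-bound, bound, size=(len(vocab), config.dim))
    doc_vectors = rng.uniform(-bound, bound, size=(len(docs), config.dim))

    losses = _sgd_epochs(
        tokens,
        doc_of_pos,
        pos_in_doc,
        doc_start.astype(np.int64),
        doc_len,
        noise_cdf,
        word_vectors,
        doc_vectors,
        config.window,
        config.epochs,
        config.negatives,
        config.lr_start,
        config.lr_end,
        config.seed % 2**31,
    )
    bad = np.flatnonzero(~np.isfinite(losses))
    if bad.size:
        raise FloatingPointError(f"non-finite training loss at epoch {int(bad[0])}")

    return EmbeddingModel(
        config=config,
        vocab=vocab,
        frequencies=frequencies,
        word_vectors=word_vectors,
        doc_ids=doc_ids,
        doc_vectors=doc_vectors,
        epoch_losses=losses,
    )


# ---------------------------------------------------------------------------
# Similarity analyses
# ---------------------------------------------------------------------------


def cosine(a: np.ndarray, b: np.ndarray) -> float:
    na = float(np.linalg.norm(a))
    nb = float(np.linalg.norm(b))
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine undefined for zero vector")
    return float(a @ b) / (na * nb)


def similarity_matrix(
    model: EmbeddingModel,
    rows: Sequence[DocId],
    cols: Sequence[DocId],
    rescale01: bool = False,
) -> SimilarityMatrix:
    """Cosine similarity between document vectors.

    ``rescale01`` applies the affine display map s -> (s + 1) / 2, matching a
    [0, 1] colour scale where 0 is anti-alignment and 1 identity; raw cosine
    is the analytical default.
    """
    r = np.stack([model.doc_vector(d) for d in rows])
    c = np.stack([model.doc_vector(d) for d in cols])
    rn = r / np.linalg.norm(r, axis=1, keepdims=True)
    cn = c / np.linalg.norm(c, axis=1, keepdims=True)
    values = rn @ cn.T
    if rescale01:
        values = (values + 1.0) / 2.0
    return SimilarityMatrix(row_ids=list(rows), col_ids=list(cols), values=values)


def text_discussion_similarity(
    model: EmbeddingModel, pairs: Mapping[int, tuple[DocId, DocId]]
) -> "pd.DataFrame":
    """Per-session cosine between a discussion and the text read that session.

    ``pairs`` maps session -> (discussion doc id, text doc id); returns one
    row per session plus the group-level mean, the aggregate that supports
    statements like "one group stayed more on topic than the other".
    """
    import pandas as pd

    rows = []
    for session in sorted(pairs):
        disc_id, text_id = pairs[session]
        if disc_id[1] != session or text_id[1] != session:
            raise ValueError(f"session {session}: pair ids {disc_id}/{text_id} mismatched")
        sim = cosine(model.doc_vector(disc_id), model.doc_vector(text_id))
        rows.append(
            {"group_id": disc_id[0], "session": session, "similarity": sim}
        )
    df = pd.DataFrame(rows)
    df.attrs["group_mean"] = float(df["similarity"].mean())
    return df
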