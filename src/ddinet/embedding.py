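"""Pfam2Vec: domain-token corpus, skip-gram embeddings, weighted pair vectors.

A protein pair becomes one "sentence": for every candidate domain-domain
interaction (one Pfam from each protein) the two accessions are emitted
as two sequential tokens, so a window-1 skip-gram sees each candidate DDI
as an adjacent token pair. A pair of proteins is then represented as the
frequency-weighted mean of the concatenated domain-pair vectors — a
200-dimension vector at the default per-domain dimension of 100.

The trainer is a self-contained skip-gram with negative sampling
(minibatched SGD, unigram^0.75 noise distribution, linearly decaying
learning rate), deterministic for a fixed seed.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np

from ddinet.core import DDISet, PPIRecord, Protein, ProteinCatalog

logger = logging.getLogger(__name__)


@dataclass
class Corpus:
    """Token sentences (one per protein pair); every sentence has even length."""

    sentences: list[list[str]] = field(default_factory=list)
    n_skipped: int = 0

    def vocabulary(self) -> set[str]:
        return {tok for sent in self.sentences for tok in sent}

    def __len__(self) -> int:
        return len(self.sentences)


def canonical_pair_order(a: Protein, b: Protein) -> tuple[Protein, Protein]:
    """First-token protein of a pair: the bacterial one for cross-species
    pairs, otherwise the lexicographically smaller id."""
    if a.is_human != b.is_human:
        return (a, b) if not a.is_human else (b, a)
    return (a, b) if a.id <= b.id else (b, a)


def _cross_pairs(first: Protein, second: Protein) -> list[tuple[str, str]]:
    return sorted(product(first.pfam_ids, second.pfam_ids))


def build_corpus(
    ppis: list[PPIRecord],
    catalog: ProteinCatalog,
    sentence_per_ddi: bool = False,
) -> Corpus:
    """One sentence per protein pair: all candidate DDIs as sequential tokens.

    Cross pairs are emitted in lexicographic order of (first-protein domain,
    second-protein domain); pairs with an empty domain set on either side
    are skipped with a warning. With ``sentence_per_ddi`` every candidate
    DDI becomes its own two-token sentence instead, which removes the
    spurious adjacency between consecutive cross pairs at the cost of
    longer corpora.
    """
    corpus = Corpus()
    for rec in ppis:
        pa, pb = catalog.get(rec.a), catalog.get(rec.b)
        if pa is None or pb is None or not pa.embeddable or not pb.embeddable:
            logger.warning("skipping pair %s with missing/domainless endpoint", rec.key)
            corpus.n_skipped += 1
            continue
        first, second = canonical_pair_order(pa, pb)
        if sentence_per_ddi:
            for da, db in _cross_pairs(first, second):
                corpus.sentences.append([da, db])
        else:
            sentence: list[str] = []
            for da, db in _cross_pairs(first, second):
                sentence.extend((da, db))
            corpus.sentences.append(sentence)
    return corpus


@dataclass
class EmbeddingModel:
    """Per-domain embedding vectors plus the training configuration."""

    dim: int
    vectors: dict[str, np.ndarray]
    training_meta: dict = field(default_factory=dict)

    def __contains__(self, token: str) -> bool:
        return token in self.vectors

    def __getitem__(self, token: str) -> np.ndarray:
        return self.vectors[token]

    def save(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["token"] + [f"v{i}" for i in range(self.dim)])
            for tok in sorted(self.vectors):
                w.writerow([tok] + [repr(float(x)) for x in self.vectors[tok]])

    @classmethod
    def load(cls, path: str | Path) -> "EmbeddingModel":
        with open(path, newline="") as fh:
            rows = list(csv.reader(fh, delimiter="\t"))
        dim = len(rows[0]) - 1
        vectors = {
            row[0]: np.array([float(x) for x in row[1:]]) for row in rows[1:]
        }
        return cls(dim=dim, vectors=vectors)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30.0, 30.0)))


def train_embeddings(
    corpus: Corpus,
    dim: int = 100,
    window: int = 1,
    epochs: int = 10,
    seed: int = 0,
    negative: int = 5,
    alpha: float = 0.025,
    min_alpha: float = 1e-4,
    min_count: int = 1,
    batch_size: int = 512,
) -> EmbeddingModel:
    """Skip-gram-with-negative-sampling embeddings over the domain corpus.

    Window 1 keeps the context of a token dominated by its partner within
    the same candidate DDI. Training is single-threaded minibatch SGD and
    fully reproducible for a fixed seed.
    """
    if not corpus.sentences:
        raise ValueError("corpus is empty")
    counts: dict[str, int] = {}
    for sent in corpus.sentences:
        for tok in sent:
            counts[tok] = counts.get(tok, 0) + 1
    vocab = sorted(t for t in counts if counts[t] >= min_count)
    if not vocab:
        raise ValueError(
            "no token reaches the min-count threshold; use min_count=1 "
            "(the default) for small corpora"
        )
    index = {t: i for i, t in enumerate(vocab)}

    # (center, context) training pairs within the window
    pairs: list[tuple[int, int]] = []
    for sent in corpus.sentences:
        idx = [index[t] for t in sent if t in index]
        for i, c in enumerate(idx):
            lo, hi = max(0, i - window), min(len(idx), i + window + 1)
            for j in range(lo, hi):
                if j != i:
                    pairs.append((c, idx[j]))
    pairs_arr = np.array(pairs, dtype=np.int64)

    rng = np.random.default_rng(seed)
    V = len(vocab)
    W = (rng.random((V, dim)) - 0.5) / dim  # input vectors
    C = np.zeros((V, dim))  # output (context) vectors

    freq = np.array([counts[t] for t in vocab], dtype=float)
    noise = freq ** 0.75
    noise /= noise.sum()

    n_pairs = len(pairs_arr)
    total_steps = max(1, epochs * ((n_pairs + batch_size - 1) // batch_size))
    step = 0
    for _ in range(epochs):
        order = rng.permutation(n_pairs)
        for start in range(0, n_pairs, batch_size):
            batch = pairs_arr[order[start:start + batch_size]]
            lr = max(min_alpha, alpha * (1 - step / total_steps))
            step += 1
            centers, contexts = batch[:, 0], batch[:, 1]
            negs = rng.choice(V, size=(len(batch), negative), p=noise)

            w = W[centers]  # (B, d)
            # positive examples
            cpos = C[contexts]
            spos = _sigmoid(np.sum(w * cpos, axis=1))
            gpos = (spos - 1.0)[:, None]  # d/dx of -log sigmoid
            grad_w = gpos * cpos
            np.add.at(C, contexts, -lr * gpos * w)
            # negative examples
            cneg = C[negs]  # (B, k, d)
            sneg = _sigmoid(np.einsum("bd,bkd->bk", w, cneg))
            grad_w += np.einsum("bk,bkd->bd", sneg, cneg)
            np.add.at(
                C, negs.ravel(),
                (-lr * sneg[:, :, None] * w[:, None, :]).reshape(-1, dim),
            )
            np.add.at(W, centers, -lr * grad_w)

    vectors = {t: W[index[t]].copy() for t in vocab}
    meta = {
        "dim": dim, "window": window, "epochs": epochs, "seed": seed,
        "algorithm": "skip-gram negative sampling", "negative": negative,
        "alpha": alpha, "min_count": min_count,
    }
    return EmbeddingModel(dim=dim, vectors=vectors, training_meta=meta)


class DDIWeightTable:
    """Observation counts of domain pairs in interacting training pairs.

    The weight of a pair is its count plus a pseudo-count, so domain
    combinations never seen in training still contribute at prediction
    time instead of vanishing from the representation.
    """

    def __init__(self, counts: DDISet | None = None, pseudo_count: float = 1.0):
        if pseudo_count <= 0:
            raise ValueError("pseudo_count must be positive")
        self._counts = counts if counts is not None else DDISet()
        self.pseudo_count = float(pseudo_count)

    @property
    def counts(self) -> DDISet:
        return self._counts

    def weight(self, a: str, b: str) -> float:
        return self._counts.count(a, b) + self.pseudo_count

    def __call__(self, a: str, b: str) -> float:
        return self.weight(a, b)


def build_ddi_weights(
    train_positives: list[PPIRecord],
    catalog: ProteinCatalog,
    pseudo_count: float = 1.0,
) -> DDIWeightTable:
    """Count candidate DDIs over the positive training pairs."""
    from ddinet.dataset import infer_ddis

    return DDIWeightTable(infer_ddis(train_positives, catalog), pseudo_count)


def pair_vector(
    first: Protein,
    second: Protein,
    model: EmbeddingModel,
    weights: DDIWeightTable,
) -> np.ndarray:
    """Frequency-weighted mean of concatenated domain-pair vectors.

    ``v = sum_pairs w(da, db) * [vec(da); vec(db)] / sum_pairs w`` — a convex
    combination over the candidate DDIs of the pair, of length ``2 * dim``.
    Callers are responsible for passing the proteins in canonical order
    (see :func:`canonical_pair_order`); domain listing order never matters
    because cross pairs are canonically sorted internally.
    """
    for p in (first, second):
        if not any(d in model for d in p.pfam_ids):
            raise ValueError(f"protein {p.id} has no embeddable domain in the model")
    dim = model.dim
    acc = np.zeros(2 * dim)
    total = 0.0
    for da, db in _cross_pairs(first, second):
        w = weights(da, db)
        total += w
        if da in model and db in model:
            acc[:dim] += w * model[da]
            acc[dim:] += w * model[db]
        else:
            warnings.warn(f"out-of-vocabulary domain in pair ({da}, {db}); "
                          "contributes a zero vector")
    return acc / total
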