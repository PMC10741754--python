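"""Synonym elimination via word vectors trained on the report corpus.

Attribute adjectives in narrative reports vary freely ("rough",
"unsmooth", "uneven" ...).  A small word2vec-style embedding is trained on
the tokenized corpus with a sliding context window; cosine similarity over
the resulting vectors groups variants, the most frequent member of each
group becomes the canonical term, and the knowledge graph is rewritten so
one concept has one surface form.

The trainer is a self-contained, seeded skip-gram / CBOW implementation
with negative sampling (single worker, fully deterministic for a fixed
seed), exposing vectors in the standard word2vec text format.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .extraction import SimpleKG, Triple

__all__ = [
    "WordVectorSpace", "SynonymTable", "train_embeddings",
    "cosine_similarity", "build_synonym_table", "normalize_skg",
]


# ---------------------------------------------------------------------------
# Vector space
# ---------------------------------------------------------------------------


@dataclass
class WordVectorSpace:
    """Trained word vectors plus corpus frequencies."""

    vocabulary: list[str]
    matrix: np.ndarray  # (len(vocabulary), dim)
    frequencies: dict[str, int]

    def __post_init__(self) -> None:
        self._index = {w: i for i, w in enumerate(self.vocabulary)}

    def __contains__(self, term: str) -> bool:
        return term in self._index

    @property
    def dim(self) -> int:
        return int(self.matrix.shape[1])

    def vector(self, term: str) -> np.ndarray:
        return self.matrix[self._index[term]]

    def similarity(self, a: str, b: str) -> float:
        return cosine_similarity(self.vector(a), self.vector(b))

    def save_word2vec(self, path) -> None:
        """Write vectors in the word2vec text format (header + rows)."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(self.vocabulary)} {self.dim}\n")
            for w in self.vocabulary:
                vals = " ".join(f"{x:.6f}" for x in self.vector(w))
                fh.write(f"{w.replace(' ', '_')} {vals}\n")

    @classmethod
    def load_word2vec(cls, path,
                      frequencies: Mapping[str, int] | None = None
                      ) -> "WordVectorSpace":
        with open(path, encoding="utf-8") as fh:
            n, dim = map(int, fh.readline().split())
            vocab, rows = [], []
            for line in fh:
                parts = line.rstrip("\n").split(" ")
                vocab.append(parts[0].replace("_", " "))
                rows.append([float(x) for x in parts[1:]])
        mat = np.asarray(rows, dtype=np.float64)
        if mat.shape != (n, dim):
            raise ValueError("malformed word2vec file")
        freqs = dict(frequencies) if frequencies else {w: 1 for w in vocab}
        return cls(vocab, mat, freqs)


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """u·v / (‖u‖‖v‖); raises on zero vectors or mismatched dimensions."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValueError("vectors must share one dimension")
    nu, nv = float(np.linalg.norm(u)), float(np.linalg.norm(v))
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(u, v) / (nu * nv))


# ---------------------------------------------------------------------------
# Training (skip-gram / CBOW with negative sampling)
# ---------------------------------------------------------------------------


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30.0, 30.0)))


def train_embeddings(corpus: Sequence[Sequence[str]], dim: int = 32,
                     window: int = 2, min_count: int = 1, seed: int = 0, *,
                     epochs: int = 25, negative: int = 5, lr: float = 0.05,
                     algorithm: str = "skipgram") -> WordVectorSpace:
    """Train word vectors on tokenized sentences with a sliding window.

    Parameters follow word2vec conventions: ``window`` is the one-sided
    context width, ``negative`` the number of noise words per positive pair
    (drawn from the unigram^0.75 distribution), ``algorithm`` one of
    ``"skipgram"`` (default) or ``"cbow"``.  Training is single-threaded
    and deterministic for a fixed seed.
    """
    if not corpus or all(len(s) == 0 for s in corpus):
        raise ValueError("corpus must contain at least one token")
    if dim < 2:
        raise ValueError("dim must be >= 2")
    if window < 1:
        raise ValueError("window must be >= 1")
    if algorithm not in ("skipgram", "cbow"):
        raise ValueError(f"unknown algorithm {algorithm!r}")

    counts = Counter(tok for sent in corpus for tok in sent)
    vocab = sorted(w for w, c in counts.items() if c >= min_count)
    if not vocab:
        raise ValueError("min_count filtered out the whole vocabulary")
    index = {w: i for i, w in enumerate(vocab)}
    v = len(vocab)

    rng = np.random.default_rng(seed)
    W_in = (rng.random((v, dim)) - 0.5) / dim   # input (word) vectors
    W_out = np.zeros((v, dim))                  # output (context) vectors

    # negative-sampling table: unigram counts to the 3/4 power
    probs = np.array([counts[w] for w in vocab], dtype=np.float64) ** 0.75
    probs /= probs.sum()

    sentences = [[index[t] for t in sent if t in index] for sent in corpus]
    sentences = [s for s in sentences if len(s) > 1]

    initial_lr = lr
    n_steps = 0
    total = max(1, epochs * sum(len(s) for s in sentences))
    for _epoch in range(epochs):
        for sent in sentences:
            for pos, center in enumerate(sent):
                lr_t = initial_lr * max(0.05, 1.0 - n_steps / total)
                n_steps += 1
                lo = max(0, pos - window)
                hi = min(len(sent), pos + window + 1)
                context = [sent[k] for k in range(lo, hi) if k != pos]
                if not context:
                    continue
                negs = rng.choice(v, size=negative * len(context), p=probs)
                if algorithm == "skipgram":
                    for j, ctx in enumerate(context):
                        targets = np.concatenate(
                            ([ctx], negs[j * negative:(j + 1) * negative]))
                        labels = np.zeros(len(targets))
                        labels[0] = 1.0
                        h = W_in[center]
                        scores = _sigmoid(W_out[targets] @ h)
                        g = (scores - labels) * lr_t
                        grad_h = g @ W_out[targets]
                        W_out[targets] -= np.outer(g, h)
                        W_in[center] = h - grad_h
                else:  # cbow: predict the center from the averaged context
                    h = W_in[context].mean(axis=0)
                    targets = np.concatenate(
                        ([center], negs[:negative]))
                    labels = np.zeros(len(targets))
                    labels[0] = 1.0
                    scores = _sigmoid(W_out[targets] @ h)
                    g = (scores - labels) * lr_t
                    grad_h = g @ W_out[targets]
                    W_out[targets] -= np.outer(g, h)
                    W_in[context] -= grad_h / len(context)

    return WordVectorSpace(vocab, W_in,
                           {w: int(counts[w]) for w in vocab})


# ---------------------------------------------------------------------------
# Synonym table
# ---------------------------------------------------------------------------


@dataclass
class SynonymTable:
    """canonical term -> {member term: similarity score}.

    Each canonical term belongs to its own group with score 1.0; member
    sets are disjoint across groups.
    """

    groups: dict[str, dict[str, float]] = field(default_factory=dict)

    def canonical_of(self, term: str) -> str:
        return self._member_map().get(term, term)

    def _member_map(self) -> dict[str, str]:
        out = {}
        for canon, members in self.groups.items():
            for m in members:
                out[m] = canon
        return out

    def __len__(self) -> int:
        return len(self.groups)

    def to_json(self) -> str:
        return json.dumps(self.groups, ensure_ascii=False, indent=1,
                          sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SynonymTable":
        return cls(json.loads(text))


def build_synonym_table(space: WordVectorSpace, seeds: Sequence[str],
                        threshold: float = 0.55) -> SynonymTable:
    """Group candidate terms by cosine similarity to a group anchor.

    Seeds are visited in descending corpus frequency (ties lexicographic);
    each unassigned seed anchors a new group that absorbs every remaining
    unassigned seed whose similarity to the anchor reaches ``threshold``.
    The group's canonical term is its most frequent member (ties
    lexicographic) and carries score 1.0; other members carry their
    similarity to the anchor.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly between 0 and 1")
    missing = [s for s in seeds if s not in space]
    if missing:
        raise KeyError(f"seed terms not in vocabulary: {missing}")
    order = sorted(set(seeds),
                   key=lambda w: (-space.frequencies.get(w, 0), w))
    assigned: set[str] = set()
    groups: dict[str, dict[str, float]] = {}
    for anchor in order:
        if anchor in assigned:
            continue
        members = {anchor: 1.0}
        for cand in order:
            if cand in assigned or cand == anchor:
                continue
            sim = space.similarity(anchor, cand)
            if sim >= threshold:
                members[cand] = sim
        canonical = min(members,
                        key=lambda w: (-space.frequencies.get(w, 0), w))
        members[canonical] = 1.0
        groups[canonical] = members
        assigned |= set(members)
    return SynonymTable(groups)


def normalize_skg(skg: SimpleKG, table: SynonymTable) -> SimpleKG:
    """Rewrite every head/relation/tail group member to its canonical term.

    Triple count, order and provenance are preserved; the operation is
    idempotent (canonical terms map to themselves).
    """
    mapping = table._member_map()
    out = []
    for t in skg.triples:
        out.append(Triple(
            head=t.head if t.is_placeholder else mapping.get(t.head, t.head),
            relation=mapping.get(t.relation, t.relation),
            tail=mapping.get(t.tail, t.tail),
            report_id=t.report_id,
            sentence_index=t.sentence_index))
    return SimpleKG(out)
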