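"""Translation-on-hyperplane knowledge-graph embedding and entity completion.

Each relation ``r`` owns a unit hyperplane normal ``w_r`` and a translation
vector ``d_r``.  Head and tail entity vectors are projected onto the
hyperplane and a correct triple satisfies ``e_f⊥ + d_r ≈ e_t⊥``; the TransH
score is the squared L2 residual of that identity (lower is better).  The
completion score additionally weighs a Gaussian proximity kernel
``k(e_f, e_t) = exp(−‖e_f − e_t‖² / (2σ²))`` over the *unprojected*
head-tail distance, expressing that nearby entities are the more plausible
subjects for a clause whose writer omitted its head.

Training minimizes the margin-ranking loss
``Σ max(0, γ + f(positive) − f(corrupted))`` by seeded SGD with uniform
head/tail corruption, renormalizing ``w_r`` to unit length and clipping
entity norms to 1 after every step.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .extraction import PLACEHOLDER, SimpleKG, Triple

logger = logging.getLogger(__name__)

_UNIT_TOL = 1e-6

KernelDirection = Literal["multiply", "divide"]


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------


@dataclass
class EmbeddingModel:
    """Entity vectors, relation translations and hyperplane normals.

    Invariants: all hyperplane normals are unit length (within 1e-6),
    entity norms are at most 1, every vector shares ``dimension`` and the
    kernel bandwidth ``sigma`` is positive.
    """

    entities: list[str]
    relations: list[str]
    entity_matrix: np.ndarray    # (n_entities, dim)
    relation_matrix: np.ndarray  # (n_relations, dim) translations d_r
    normal_matrix: np.ndarray    # (n_relations, dim) unit normals w_r
    sigma: float = 1.0
    loss_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        self._e_index = {e: i for i, e in enumerate(self.entities)}
        self._r_index = {r: i for i, r in enumerate(self.relations)}

    @property
    def dimension(self) -> int:
        return int(self.entity_matrix.shape[1])

    def has_entity(self, e: str) -> bool:
        return e in self._e_index

    def has_relation(self, r: str) -> bool:
        return r in self._r_index

    def entity_vector(self, e: str) -> np.ndarray:
        try:
            return self.entity_matrix[self._e_index[e]]
        except KeyError:
            raise KeyError(f"entity {e!r} not in model vocabulary") from None

    def relation_vector(self, r: str) -> np.ndarray:
        try:
            return self.relation_matrix[self._r_index[r]]
        except KeyError:
            raise KeyError(f"relation {r!r} not in model vocabulary") from None

    def hyperplane_normal(self, r: str) -> np.ndarray:
        try:
            return self.normal_matrix[self._r_index[r]]
        except KeyError:
            raise KeyError(f"relation {r!r} not in model vocabulary") from None

    # -- checkpointing -----------------------------------------------------

    def save(self, directory) -> None:
        """Checkpoint as TSV vector tables plus JSON metadata."""
        os.makedirs(directory, exist_ok=True)

        def dump(path, names, mat):
            with open(path, "w", encoding="utf-8") as fh:
                for name, row in zip(names, mat):
                    vals = "\t".join(f"{x:.10g}" for x in row)
                    fh.write(f"{name}\t{vals}\n")

        dump(os.path.join(directory, "entities.tsv"),
             self.entities, self.entity_matrix)
        dump(os.path.join(directory, "relations.tsv"),
             self.relations, self.relation_matrix)
        dump(os.path.join(directory, "hyperplanes.tsv"),
             self.relations, self.normal_matrix)
        meta = {"dimension": self.dimension, "sigma": self.sigma,
                "loss_trace": self.loss_trace}
        with open(os.path.join(directory, "meta.json"), "w",
                  encoding="utf-8") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, directory) -> "EmbeddingModel":
        def slurp(path):
            names, rows = [], []
            with open(path, encoding="utf-8") as fh:
                for line in fh:
                    parts = line.rstrip("\n").split("\t")
                    names.append(parts[0])
                    rows.append([float(x) for x in parts[1:]])
            return names, np.asarray(rows, dtype=np.float64)

        entities, emat = slurp(os.path.join(directory, "entities.tsv"))
        relations, rmat = slurp(os.path.join(directory, "relations.tsv"))
        _, wmat = slurp(os.path.join(directory, "hyperplanes.tsv"))
        with open(os.path.join(directory, "meta.json"),
                  encoding="utf-8") as fh:
            meta = json.load(fh)
        return cls(entities, relations, emat, rmat, wmat,
                   sigma=meta["sigma"], loss_trace=meta.get("loss_trace", []))


@dataclass(frozen=True)
class TrainConfig:
    """Margin-ranking training hyperparameters (all must be positive)."""

    margin: float = 1.0
    learning_rate: float = 0.05
    epochs: int = 200
    negatives: int = 1
    seed: int = 0
    batch_size: int = 1  # kept for interface symmetry; SGD is per-sample

    def __post_init__(self) -> None:
        if min(self.margin, self.learning_rate) <= 0 and self.margin != 0:
            raise ValueError("margin and learning_rate must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 0 or self.negatives < 1 or self.batch_size < 1:
            raise ValueError("epochs >= 0, negatives/batch_size >= 1 required")


# ---------------------------------------------------------------------------
# Score primitives
# ---------------------------------------------------------------------------


def project_onto_hyperplane(e: np.ndarray, w_r: np.ndarray) -> np.ndarray:
    """Project ``e`` onto the hyperplane with unit normal ``w_r``.

    Returns ``e − (w_rᵀe)·w_r``; the result is orthogonal to ``w_r``.
    """
    w_r = np.asarray(w_r, dtype=np.float64)
    if abs(float(np.linalg.norm(w_r)) - 1.0) > _UNIT_TOL:
        raise ValueError("hyperplane normal must be unit length")
    e = np.asarray(e, dtype=np.float64)
    return e - np.dot(w_r, e) * w_r


def _resolve(triple: Triple | tuple[str, str, str],
             model: EmbeddingModel) -> tuple[str, str, str]:
    h, r, t = triple.spo if isinstance(triple, Triple) else triple
    for name, kind, ok in ((h, "entity", model.has_entity(h)),
                           (r, "relation", model.has_relation(r)),
                           (t, "entity", model.has_entity(t))):
        if not ok:
            raise KeyError(f"{kind} {name!r} not in model vocabulary")
    return h, r, t


def transh_score(triple: Triple | tuple[str, str, str],
                 model: EmbeddingModel) -> float:
    """Squared translation residual ``‖e_f⊥ + d_r − e_t⊥‖₂²`` (≥ 0)."""
    h, r, t = _resolve(triple, model)
    w = model.hyperplane_normal(r)
    hp = project_onto_hyperplane(model.entity_vector(h), w)
    tp = project_onto_hyperplane(model.entity_vector(t), w)
    resid = hp + model.relation_vector(r) - tp
    return float(np.dot(resid, resid))


def gaussian_proximity(e_i: np.ndarray, e_j: np.ndarray,
                       sigma: float) -> float:
    """Gaussian kernel ``exp(−‖e_i − e_j‖² / (2σ²))`` in (0, 1]."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    d = np.asarray(e_i, dtype=np.float64) - np.asarray(e_j, dtype=np.float64)
    return float(np.exp(-np.dot(d, d) / (2.0 * sigma * sigma)))


def kgcm_score(triple: Triple | tuple[str, str, str],
               model: EmbeddingModel, *,
               kernel_direction: KernelDirection = "multiply") -> float:
    """Completion score: TransH residual combined with the proximity kernel.

    ``"multiply"`` (default) is the literal product form — residual × kernel;
    ``"divide"`` penalizes head-tail distance instead (residual / kernel),
    the form under which nearer candidates rank better at argmin.
    """
    h, r, t = _resolve(triple, model)
    base = transh_score((h, r, t), model)
    k = gaussian_proximity(model.entity_vector(h), model.entity_vector(t),
                           model.sigma)
    return base * k if kernel_direction == "multiply" else base / k


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def _normalize_rows(mat: np.ndarray) -> None:
    norms = np.linalg.norm(mat, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    mat /= norms


def _clip_rows(mat: np.ndarray, rows: Iterable[int]) -> None:
    for i in set(rows):
        n = float(np.linalg.norm(mat[i]))
        if n > 1.0:
            mat[i] /= n


def train(triples: Sequence[Triple] | SimpleKG, config: TrainConfig,
          dim: int = 16, sigma: float = 1.0) -> EmbeddingModel:
    """Fit a TransH model to the triples by margin-ranking SGD.

    Placeholder-headed triples are inference targets, not facts, and are
    rejected.  Negatives corrupt the head or tail uniformly at random over
    the entity vocabulary.  Hyperplane normals are renormalized and touched
    entity vectors clipped to the unit ball after every update; runs are
    reproducible for a fixed config seed.
    """
    triple_list = list(triples.triples if isinstance(triples, SimpleKG)
                       else triples)
    if not triple_list:
        raise ValueError("cannot train on an empty triple set")
    if any(t.head == PLACEHOLDER for t in triple_list):
        raise ValueError("placeholder-headed triples may not be trained on")

    entities = sorted({t.head for t in triple_list} |
                      {t.tail for t in triple_list})
    relations = sorted({t.relation for t in triple_list})
    e_index = {e: i for i, e in enumerate(entities)}
    r_index = {r: i for i, r in enumerate(relations)}
    facts = np.array([[e_index[t.head], r_index[t.relation], e_index[t.tail]]
                      for t in triple_list], dtype=np.int64)
    fact_set = {tuple(row) for row in facts.tolist()}

    rng = np.random.default_rng(config.seed)
    bound = 6.0 / np.sqrt(dim)
    E = rng.uniform(-bound, bound, size=(len(entities), dim))
    D = rng.uniform(-bound, bound, size=(len(relations), dim))
    W = rng.uniform(-bound, bound, size=(len(relations), dim))
    _normalize_rows(W)
    _clip_rows(E, range(len(entities)))

    n_e = len(entities)
    loss_trace: list[float] = []

    def residual(h, r, t):
        w = W[r]
        hp = E[h] - np.dot(w, E[h]) * w
        tp = E[t] - np.dot(w, E[t]) * w
        return hp + D[r] - tp

    lr = config.learning_rate
    for _epoch in range(config.epochs):
        order = rng.permutation(len(facts))
        epoch_loss = 0.0
        for idx in order:
            h, r, t = facts[idx]
            for _neg in range(config.negatives):
                h2, t2 = h, t
                # uniform head/tail corruption, resampled on collision
                for _try in range(10):
                    if rng.random() < 0.5:
                        h2, t2 = int(rng.integers(n_e)), t
                    else:
                        h2, t2 = h, int(rng.integers(n_e))
                    if (h2, int(r), t2) not in fact_set:
                        break
                res_p = residual(h, r, t)
                res_n = residual(h2, r, t2)
                loss = config.margin + np.dot(res_p, res_p) \
                    - np.dot(res_n, res_n)
                if loss <= 0:
                    continue
                epoch_loss += float(loss)
                w = W[r].copy()
                # d/dx ||res||^2 = 2*res * d(res)/dx ; projection P = I - w w^T
                def proj_grad(vec):
                    return vec - np.dot(w, vec) * w

                g_p = 2.0 * res_p
                g_n = 2.0 * res_n
                # gradients wrt entity vectors go through the projection
                E_h_g = proj_grad(g_p)
                E_t_g = -proj_grad(g_p)
                E_h2_g = -proj_grad(g_n)
                E_t2_g = proj_grad(g_n)
                D_g = g_p - g_n
                # gradient wrt w of (e - (w.e)w): -(w.e)I - e w^T acting on g
                def w_grad(res_g, eh, et):
                    diff = E[eh] - E[et]
                    return -(np.dot(w, diff) * res_g
                             + np.dot(w, res_g) * diff)

                W_g = w_grad(g_p, h, t) - w_grad(g_n, h2, t2)

                E[h] -= lr * E_h_g
                E[t] -= lr * E_t_g
                E[h2] -= lr * E_h2_g
                E[t2] -= lr * E_t2_g
                D[r] -= lr * D_g
                W[r] -= lr * W_g
                # soft constraints: unit normal, translation in-hyperplane
                # and bounded, entities in the unit ball
                W[r] /= max(float(np.linalg.norm(W[r])), 1e-12)
                D[r] -= np.dot(W[r], D[r]) * W[r]
                d_norm = float(np.linalg.norm(D[r]))
                if d_norm > 1.0:
                    D[r] /= d_norm
                _clip_rows(E, (h, t, h2, t2))
        loss_trace.append(epoch_loss)

    return EmbeddingModel(entities, relations, E, D, W, sigma=sigma,
                          loss_trace=loss_trace)


# ---------------------------------------------------------------------------
# Completion
# ---------------------------------------------------------------------------


def _report_candidates(skg: SimpleKG, target: Triple,
                       model: EmbeddingModel) -> list[str]:
    """Entities of the same report mentioned before the placeholder clause.

    Ordered by first mention; falls back to the whole model vocabulary when
    nothing usable precedes the clause.
    """
    seen: list[str] = []
    for t in skg.triples:
        if t.report_id != target.report_id:
            continue
        if (t.sentence_index >= 0 and target.sentence_index >= 0
                and t.sentence_index >= target.sentence_index):
            continue
        for ent in (t.head, t.tail):
            if ent != PLACEHOLDER and ent not in seen:
                seen.append(ent)
    usable = [e for e in seen if model.has_entity(e)]
    return usable if usable else list(model.entities)


def complete_entity(skg: SimpleKG, model: EmbeddingModel, *,
                    candidate_policy: str = "report",
                    scorer: str = "kgcm",
                    kernel_direction: KernelDirection = "divide"
                    ) -> SimpleKG:
    """Fill every placeholder head with the best-scoring candidate entity.

    For each triple ``(@, r, t)`` the candidate minimizing the completion
    score of ``(candidate, r, t)`` is substituted.  ``candidate_policy``
    is ``"report"`` (entities mentioned earlier in the same report, falling
    back to the full vocabulary) or ``"all"``.  ``scorer`` selects the
    plain TransH residual or the proximity-weighted score, where the
    default penalizes distant candidates (``kernel_direction="divide"``) —
    the omitted subject is usually the nearby, recently described entity.
    Ties break by candidate order (earlier mention first) then the
    candidate list order is stable, so results are deterministic.
    Unresolvable triples (unknown relation/tail, empty candidates) are left
    as placeholders and logged.
    """
    if candidate_policy not in ("report", "all"):
        raise ValueError(f"unknown candidate_policy {candidate_policy!r}")
    if scorer not in ("kgcm", "transh"):
        raise ValueError(f"unknown scorer {scorer!r}")
    out: list[Triple] = []
    for t in skg.triples:
        if not t.is_placeholder:
            out.append(t)
            continue
        if not (model.has_relation(t.relation) and model.has_entity(t.tail)):
            logger.warning("cannot complete %s: relation or tail not in "
                           "model vocabulary", t.spo)
            out.append(t)
            continue
        if candidate_policy == "report":
            candidates = _report_candidates(skg, t, model)
        else:
            candidates = list(model.entities)
        candidates = [c for c in candidates
                      if c != t.tail and model.has_entity(c)]
        if not candidates:
            logger.warning("no completion candidates for %s", t.spo)
            out.append(t)
            continue
        best, best_score = None, np.inf
        for cand in candidates:
            if scorer == "transh":
                s = transh_score((cand, t.relation, t.tail), model)
            else:
                s = kgcm_score((cand, t.relation, t.tail), model,
                               kernel_direction=kernel_direction)
            if s < best_score - 1e-15:
                best, best_score = cand, s
        out.append(Triple(best, t.relation, t.tail,
                          report_id=t.report_id,
                          sentence_index=t.sentence_index))
    return SimpleKG(out)
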