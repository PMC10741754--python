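"""Synthetic corpora and planted knowledge graphs for testing at desk scale.

Real abdominal-ultrasound narratives are private clinical data, so every
stage of the pipeline is exercised on generated stand-ins:

* a report grammar that emits English-like organ findings with clause
  templates, organ-specific sub-part nouns, planted adjective synonym
  groups and deliberate head-entity omission in follow-on clauses, each
  report carrying its own gold term network, gold triples and omission
  list;
* translation-consistent planted knowledge graphs whose entity vectors
  satisfy the hyperplane-translation identity up to a controlled noise
  bound, with held-out completion queries whose gold heads are known;
* a proximity fixture in which the gold head of each query is *closer* to
  its tail than a translation-equivalent distractor, separating the
  proximity-weighted completion score from the plain translation residual;
* a fixed worked-example liver passage with its gold lexicon.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .embedding import EmbeddingModel, transh_score, kgcm_score
from .extraction import PLACEHOLDER, SimpleKG, Triple
from .structuring import StructuringConfig, TagLexicon

__all__ = [
    "ReportGrammar", "GeneratedReport", "default_grammar",
    "generate_reports", "reports_to_sentences",
    "PlantedKG", "generate_planted_kg",
    "ProximityKG", "generate_proximity_kg",
    "example_report", "example_training_corpus",
]


# ---------------------------------------------------------------------------
# Report grammar
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReportGrammar:
    """Clause templates for synthetic organ-finding reports.

    ``organs`` maps an organ to its sub-part nouns, each with an adjective
    synonym group (sampling varies the member, planting distributional
    equivalence for the synonym-resolution stage).  ``organ_adjectives``
    feeds the organ-state opening clause and ``verbs`` its copular verbs.
    ``omission_probability`` is the chance that a follow-on sub-part clause
    drops its organ head.
    """

    organs: dict[str, dict[str, tuple[str, ...]]]
    organ_adjectives: dict[str, tuple[str, ...]]
    verbs: tuple[str, ...]
    omission_probability: float = 0.3

    def __post_init__(self) -> None:
        if not self.organs:
            raise ValueError("grammar must declare at least one organ")
        if not 0.0 <= self.omission_probability <= 1.0:
            raise ValueError("omission probability must lie in [0, 1]")

    def lexicon(self) -> TagLexicon:
        entries: dict[str, str] = {}
        for organ, parts in self.organs.items():
            entries[organ] = "organ"
            for part, adjs in parts.items():
                entries[part] = "n"
                for adj in adjs:
                    entries[adj] = "adj"
        for adjs in self.organ_adjectives.values():
            for adj in adjs:
                entries[adj] = "adj"
        for verb in self.verbs:
            entries[verb] = "verb"
        return TagLexicon(entries)

    def synonym_groups(self) -> list[tuple[str, ...]]:
        """The planted adjective synonym sets (groups of size >= 2)."""
        groups = [adjs for parts in self.organs.values()
                  for adjs in parts.values() if len(adjs) >= 2]
        groups += [adjs for adjs in self.organ_adjectives.values()
                   if len(adjs) >= 2]
        return groups


def default_grammar(omission_probability: float = 0.3) -> ReportGrammar:
    """Five abdominal organ domains with organ-specific sub-parts."""
    organs = {
        "liver": {
            "surface": ("unsmooth", "rough", "uneven"),
            "envelope": ("intact", "continuous"),
            "substantial echo": ("nonuniform", "heterogeneous"),
        },
        "gallbladder": {
            "wall": ("thickened", "coarse"),
            "intracavity": ("anechoic", "transparent"),
        },
        "pancreas": {
            "pancreatic duct": ("undilated", "narrow"),
            "contour": ("regular", "welldefined"),
        },
        "kidney": {
            "renal pelvis": ("unexpanded", "collapsed"),
            "cortex": ("homogeneous", "uniform"),
        },
        "spleen": {
            "splenic vein": ("unobstructed", "patent"),
            "texture": ("fine", "delicate"),
        },
    }
    organ_adjectives = {
        "liver": ("abnormal", "cirrhotic"),
        "gallbladder": ("distended", "overfilled"),
        "pancreas": ("unremarkable", "ordinary"),
        "kidney": ("symmetric", "balanced"),
        "spleen": ("enlarged", "prominent"),
    }
    verbs = ("appears", "looks", "presents")
    return ReportGrammar(organs, organ_adjectives, verbs,
                         omission_probability)


@dataclass
class GeneratedReport:
    """One synthetic report with its gold annotations.

    ``skg`` is what faithful extraction should produce (placeholder heads
    included); ``completed_skg`` restores every omitted head;
    ``omissions`` lists ``(triple_index, omitted_head)`` pairs pointing at
    the placeholder triples of ``skg``; ``gold_concepts`` is the expected
    ``(sentence_index, surface, tag)`` stream of the term network.
    """

    report_id: str
    text: str
    skg: SimpleKG
    completed_skg: SimpleKG
    omissions: list[tuple[int, str]]
    gold_concepts: list[tuple[int, str, str]]


def generate_reports(grammar: ReportGrammar, count: int, seed: int = 0, *,
                     surface_relation: bool = False
                     ) -> list[GeneratedReport]:
    """Generate ``count`` reports with gold networks, triples and omissions.

    Each report opens every chosen organ domain with a full-head state
    clause, then describes that organ's sub-parts; a follow-on sub-part
    clause omits its organ head with the grammar's omission probability.
    ``surface_relation`` selects the compact placeholder form
    ``(@, part, adj)`` instead of ``(@, has, part)`` + ``(part, show,
    adj)``; it must match the extraction-side toggle.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    rng = np.random.default_rng(seed)
    organ_names = sorted(grammar.organs)
    out: list[GeneratedReport] = []
    for idx in range(count):
        report_id = f"r{idx:04d}"
        n_organs = int(rng.integers(2, len(organ_names) + 1))
        chosen = [organ_names[i] for i in
                  sorted(rng.choice(len(organ_names), size=n_organs,
                                    replace=False))]
        clauses: list[str] = []
        triples: list[Triple] = []
        completed: list[Triple] = []
        omissions: list[tuple[int, str]] = []
        gold_concepts: list[tuple[int, str, str]] = []
        s_idx = 0
        for organ in chosen:
            verb = str(rng.choice(grammar.verbs))
            adj = str(rng.choice(grammar.organ_adjectives[organ]))
            clauses.append(f"{organ} {verb} {adj}")
            gold_concepts += [(s_idx, organ, "organ"), (s_idx, verb, "verb"),
                              (s_idx, adj, "adj")]
            t = Triple(organ, verb, adj, report_id, s_idx)
            triples.append(t)
            completed.append(t)
            s_idx += 1
            parts = sorted(grammar.organs[organ])
            for part in parts:
                padj = str(rng.choice(grammar.organs[organ][part]))
                omitted = bool(rng.random() < grammar.omission_probability)
                if omitted:
                    clauses.append(f"{part} {padj}")
                    gold_concepts += [(s_idx, part, "n"), (s_idx, padj, "adj")]
                    if surface_relation:
                        omissions.append((len(triples), organ))
                        triples.append(Triple(PLACEHOLDER, part, padj,
                                              report_id, s_idx))
                        completed.append(Triple(organ, part, padj,
                                                report_id, s_idx))
                    else:
                        omissions.append((len(triples), organ))
                        triples.append(Triple(PLACEHOLDER, "has", part,
                                              report_id, s_idx))
                        triples.append(Triple(part, "show", padj,
                                              report_id, s_idx))
                        completed.append(Triple(organ, "has", part,
                                                report_id, s_idx))
                        completed.append(Triple(part, "show", padj,
                                                report_id, s_idx))
                else:
                    clauses.append(f"{organ} {part} {padj}")
                    gold_concepts += [(s_idx, organ, "organ"),
                                      (s_idx, part, "n"), (s_idx, padj, "adj")]
                    for t in (Triple(organ, "has", part, report_id, s_idx),
                              Triple(part, "show", padj, report_id, s_idx)):
                        triples.append(t)
                        completed.append(t)
                s_idx += 1
        text = " , ".join(clauses) + " ."
        out.append(GeneratedReport(report_id, text, SimpleKG(triples),
                                   SimpleKG(completed), omissions,
                                   gold_concepts))
    return out


def reports_to_sentences(reports: Sequence[GeneratedReport]
                         ) -> list[list[str]]:
    """Clause-level token sentences (multi-word terms fused) for word2vec."""
    sentences: list[list[str]] = []
    for rep in reports:
        by_clause: dict[int, list[str]] = {}
        for s_idx, surface, _tag in rep.gold_concepts:
            by_clause.setdefault(s_idx, []).append(surface)
        sentences.extend(by_clause[k] for k in sorted(by_clause))
    return sentences


# ---------------------------------------------------------------------------
# Planted translation-consistent knowledge graphs
# ---------------------------------------------------------------------------


@dataclass
class PlantedKG:
    """A KG whose entity vectors satisfy the translation identity by design.

    ``triples`` is the training multiset, ``queries`` the completion
    targets with their ``gold_heads``; every generated triple's
    translation residual is at most ``noise_bound``.
    """

    entity_vectors: dict[str, np.ndarray]
    relation_vectors: dict[str, np.ndarray]
    normal_vectors: dict[str, np.ndarray]
    triples: list[Triple]
    queries: list[Triple]
    gold_heads: list[str]
    noise: float
    noise_bound: float
    sigma: float = 1.0

    def model(self) -> EmbeddingModel:
        """The planted vectors wrapped as a scoring model (no training)."""
        entities = sorted(self.entity_vectors)
        relations = sorted(self.relation_vectors)
        return EmbeddingModel(
            entities, relations,
            np.array([self.entity_vectors[e] for e in entities]),
            np.array([self.relation_vectors[r] for r in relations]),
            np.array([self.normal_vectors[r] for r in relations]),
            sigma=self.sigma)

    def query_skg(self) -> SimpleKG:
        return SimpleKG([Triple(PLACEHOLDER, q.relation, q.tail,
                                q.report_id, q.sentence_index)
                         for q in self.queries])


def generate_planted_kg(n_entities: int = 50, n_relations: int = 4,
                        dim: int = 8, noise: float = 0.05, seed: int = 0, *,
                        n_triples: int = 400, n_queries: int = 20
                        ) -> PlantedKG:
    """Plant a lattice KG where each relation is a hyperplane translation.

    Relation normals are mutually orthogonal directions; entities live in
    the complementary subspace at positions ``base + sum of relation
    offsets`` (subsets of size <= 2), plus isotropic noise of norm at most
    ``noise``.  A triple links each lattice point to its one-step
    translate, so its residual obeys ``score <= (2*noise)^2``.  Queries
    are edges re-posed as completion targets — the fact itself stays in the
    training multiset, emulating a corpus in which the entity omitted in
    one report is written out fully in others — and each gold head is the
    unique lattice point one translation behind the query tail.
    """
    if n_entities < 4 or dim < 2 or noise < 0:
        raise ValueError("need n_entities >= 4, dim >= 2, noise >= 0")
    if dim < n_relations + 2:
        raise ValueError("dim must exceed n_relations + 1 for the lattice")
    rng = np.random.default_rng(seed)
    q_mat, _ = np.linalg.qr(rng.standard_normal((dim, dim)))
    normals = {f"rel{r}": q_mat[:, r] for r in range(n_relations)}
    subspace = q_mat[:, n_relations:]  # entity subspace, orthogonal to normals

    def in_subspace(norm_target: float) -> np.ndarray:
        u = rng.standard_normal(subspace.shape[1])
        u *= norm_target / np.linalg.norm(u)
        return subspace @ u

    d_vecs = {f"rel{r}": in_subspace(0.25) for r in range(n_relations)}

    combos = [()] + [(r,) for r in range(n_relations)] + \
        list(itertools.combinations(range(n_relations), 2))
    n_bases = -(-n_entities // len(combos))  # ceil
    positions: dict[str, np.ndarray] = {}
    combo_of: dict[str, tuple[int, ...]] = {}
    base_of: dict[str, int] = {}
    for b in range(n_bases):
        base = in_subspace(float(rng.uniform(0.15, 0.3)))
        for combo in combos:
            if len(positions) >= n_entities:
                break
            name = f"b{b}_" + ("o" if not combo else
                               "".join(f"r{r}" for r in combo))
            pos = base + sum((d_vecs[f"rel{r}"] for r in combo),
                             np.zeros(dim))
            if noise > 0:
                eps = rng.standard_normal(dim)
                eps *= rng.uniform(0, noise) / np.linalg.norm(eps)
                pos = pos + eps
            positions[name] = pos
            combo_of[name] = combo
            base_of[name] = b

    by_combo: dict[tuple[int, tuple[int, ...]], str] = {
        (base_of[n], combo_of[n]): n for n in positions}
    edges: list[Triple] = []
    for name, combo in combo_of.items():
        for r in range(n_relations):
            if r in combo:
                continue
            target = tuple(sorted(combo + (r,)))
            other = by_combo.get((base_of[name], target))
            if other is not None:
                edges.append(Triple(name, f"rel{r}", other))

    degree: dict[str, int] = {}
    for e in edges:
        degree[e.head] = degree.get(e.head, 0) + 1
        degree[e.tail] = degree.get(e.tail, 0) + 1
    eligible = [i for i, e in enumerate(edges)
                if degree[e.head] >= 2 and degree[e.tail] >= 2]
    n_queries = min(n_queries, len(eligible))
    query_idx = set(
        int(i) for i in rng.choice(eligible, size=n_queries, replace=False)
    ) if n_queries else set()
    queries = [edges[i] for i in sorted(query_idx)]
    triples = list(edges)
    while len(triples) < n_triples:
        triples.append(edges[int(rng.integers(len(edges)))])
    triples = triples[:n_triples]

    kg = PlantedKG(
        entity_vectors=positions,
        relation_vectors=d_vecs,
        normal_vectors=normals,
        triples=triples,
        queries=queries,
        gold_heads=[q.head for q in queries],
        noise=noise,
        noise_bound=(2.0 * noise) ** 2 + 1e-9,
    )
    model = kg.model()
    for e in edges:
        score = transh_score(e, model)
        if score > kg.noise_bound:
            raise AssertionError(
                f"planted edge {e.spo} violates the noise bound: {score}")
    return kg


# ---------------------------------------------------------------------------
# Proximity fixture: translation ties broken by head-tail distance
# ---------------------------------------------------------------------------


@dataclass
class ProximityKG:
    """Queries whose gold head is nearer its tail than a better-translating
    distractor; ranks proximity-weighted completion against the plain
    residual."""

    model: EmbeddingModel
    queries: list[Triple]
    gold_heads: list[str]
    distractors: list[str]

    def query_skg(self) -> SimpleKG:
        return SimpleKG(list(self.queries))


def generate_proximity_kg(n_queries: int = 10, dim: int = 6,
                          sigma: float = 0.5, seed: int = 0) -> ProximityKG:
    """Plant (gold, distractor) head pairs for one relation.

    Both candidates sit one translation behind the query tail on the
    relation hyperplane; the distractor's translation residual is slightly
    *smaller* (so the plain score prefers it) but it carries a large
    off-hyperplane offset that puts it far from the tail, while the gold
    head stays close.  The construction is verified at generation time:
    for every query the distance-penalized completion score ranks the gold
    head first and the plain residual ranks the distractor first.
    """
    rng = np.random.default_rng(seed)
    w = rng.standard_normal(dim)
    w /= np.linalg.norm(w)

    def on_plane(vec: np.ndarray) -> np.ndarray:
        return vec - np.dot(w, vec) * w

    d_r = on_plane(rng.standard_normal(dim))
    d_r *= 0.2 / np.linalg.norm(d_r)

    # well-separated tail anchor positions on the hyperplane
    anchors: list[np.ndarray] = []
    attempts = 0
    while len(anchors) < n_queries:
        attempts += 1
        if attempts > 10000:
            raise ValueError(
                "cannot place that many well-separated queries; "
                "reduce n_queries or raise dim")
        cand = on_plane(rng.standard_normal(dim))
        cand *= rng.uniform(0.2, 0.6) / np.linalg.norm(cand)
        if all(np.linalg.norm(cand - a) >= 0.3 for a in anchors):
            anchors.append(cand)

    def plane_offset(sq_norm: float) -> np.ndarray:
        u = on_plane(rng.standard_normal(dim))
        u *= np.sqrt(sq_norm) / np.linalg.norm(u)
        return u

    entities: dict[str, np.ndarray] = {}
    queries: list[Triple] = []
    gold_heads: list[str] = []
    distractors: list[str] = []
    for i, tail_pos in enumerate(anchors):
        head_plane = tail_pos - d_r
        gold = head_plane + 0.05 * w + plane_offset(0.02)        # residual .02
        distractor = head_plane + 0.75 * w + plane_offset(0.01)  # residual .01
        entities[f"tail{i}"] = tail_pos
        entities[f"gold{i}"] = gold
        entities[f"dis{i}"] = distractor
        queries.append(Triple(PLACEHOLDER, "rel", f"tail{i}",
                              report_id=f"q{i}", sentence_index=1))
        gold_heads.append(f"gold{i}")
        distractors.append(f"dis{i}")

    names = sorted(entities)
    model = EmbeddingModel(
        names, ["rel"],
        np.array([entities[n] for n in names]),
        d_r[None, :], w[None, :], sigma=sigma)
    for i in range(n_queries):
        g, d, t = f"gold{i}", f"dis{i}", f"tail{i}"
        plain_g = transh_score((g, "rel", t), model)
        plain_d = transh_score((d, "rel", t), model)
        near_g = kgcm_score((g, "rel", t), model, kernel_direction="divide")
        near_d = kgcm_score((d, "rel", t), model, kernel_direction="divide")
        if not (plain_d < plain_g and near_g < near_d):
            raise AssertionError(
                f"proximity construction violated at query {i}: "
                f"plain ({plain_g:.4f}, {plain_d:.4f}) "
                f"penalized ({near_g:.4f}, {near_d:.4f})")
    return ProximityKG(model, queries, gold_heads, distractors)


# ---------------------------------------------------------------------------
# Worked-example liver passage
# ---------------------------------------------------------------------------


def example_report() -> tuple[str, TagLexicon, StructuringConfig]:
    """The package's worked example: a cirrhotic-liver finding passage.

    The text is a token-normalized rendering of a typical report sentence
    ("The liver is abnormal, and the right liver is reduced with an uneven
    surface ..."): multi-word domain terms appear verbatim, function words
    are already stripped, and clause boundaries are commas.  Extraction
    yields eight triples, two of them placeholder-headed.
    """
    text = ("liver has no normalcy , right liver shrink , surface uneven , "
            "substantial echo thickens nonuniform , show nodule shape , "
            "intrahepatic blood vessel structure show clear .")
    lexicon = TagLexicon({
        "liver": "organ",
        "right liver": "organ",
        "substantial echo": "organ",
        "has no normalcy": "status",
        "surface": "n",
        "blood vessel": "n",
        "structure": "n",
        "uneven": "adj",
        "nonuniform": "adj",
        "clear": "adj",
        "nodule shape": "adj",
        "shrink": "verb",
        "thickens": "verb",
        "show": "verb",
    })
    config = StructuringConfig(lemma_table={"intrahepatic": "liver"})
    return text, lexicon, config


def example_gold_skg(report_id: str = "") -> SimpleKG:
    """The eight gold triples extraction should produce for the example."""
    rows = [
        ("liver", "status", "has no normalcy", 0),
        ("right liver", "show", "shrink", 1),
        (PLACEHOLDER, "surface", "uneven", 2),
        ("substantial echo", "thickens", "nonuniform", 3),
        (PLACEHOLDER, "show", "nodule shape", 4),
        ("liver", "has", "blood vessel", 5),
        ("blood vessel", "has", "structure", 5),
        ("structure", "show", "clear", 5),
    ]
    return SimpleKG([Triple(h, r, t, report_id, s) for h, r, t, s in rows])


def example_completed_heads() -> dict[int, str]:
    """Gold heads for the example's two placeholder triples (by index)."""
    return {2: "liver", 4: "substantial echo"}


def example_training_corpus(n_reports: int = 30, seed: int = 0) -> SimpleKG:
    """A small completed-triple corpus around the worked example's entities.

    Emulates a report archive in which liver surfaces are repeatedly
    described as uneven/unsmooth and the parenchymal echo texture as
    nodular, so a completion model trained on it associates each attribute
    with its organ.  Report and clause provenance are populated so the
    same-report candidate policy applies.
    """
    rng = np.random.default_rng(seed)
    surface_adjs = ["uneven", "unsmooth", "rough"]
    echo_adjs = ["nodule shape", "granular"]
    triples: list[Triple] = []
    for i in range(n_reports):
        rid = f"c{i:03d}"
        triples.append(Triple("liver", "status", "has no normalcy", rid, 0))
        triples.append(Triple("right liver", "show", "shrink", rid, 1))
        triples.append(Triple("liver", "surface",
                              str(rng.choice(surface_adjs)), rid, 2))
        triples.append(Triple("substantial echo", "thickens",
                              "nonuniform", rid, 3))
        triples.append(Triple("substantial echo", "show",
                              str(rng.choice(echo_adjs)), rid, 4))
        triples.append(Triple("liver", "has", "blood vessel", rid, 5))
        triples.append(Triple("blood vessel", "has", "structure", rid, 5))
        triples.append(Triple("structure", "show", "clear", rid, 5))
    return SimpleKG(triples)
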