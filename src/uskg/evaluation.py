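"""Evaluation metrics: precision/recall/F1, the extraction index, summaries.

Extraction quality is scored set-wise against gold triples (optionally on
heads or tails only, since published extraction scores are sometimes
entity-level).  The extraction index

    eta = (v / baseline) * (v / n)

compares the number of valid extracted organ domains ``v`` out of ``n``
extracted against the valid-domain count of a fixed-domain text-matching
reference; the reference itself scores exactly 1.0.  Domain summaries
count organ-rooted connected components per report and tabulate relation
pattern frequencies.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .extraction import SimpleKG

logger = logging.getLogger(__name__)

MATCH_MODES = ("triple", "head", "tail")


@dataclass(frozen=True)
class EvalCounts:
    """Confusion counts with derived precision/recall/F1 (0 when undefined)."""

    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def precision(self) -> float:
        denom = self.tp + self.fp
        return self.tp / denom if denom else 0.0

    @property
    def recall(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else 0.0

    @property
    def f1(self) -> float:
        return f1_score(self.precision, self.recall)

    def as_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn,
                "precision": self.precision, "recall": self.recall,
                "f1": self.f1}


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both vanish."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass(frozen=True)
class EtaInputs:
    """Inputs to the extraction index: extracted, valid and baseline counts."""

    n: int
    v: int
    baseline: int

    def __post_init__(self) -> None:
        if not 0 <= self.v <= self.n:
            raise ValueError("require 0 <= v <= n")
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")


def score_triples(predicted: SimpleKG, gold: SimpleKG,
                  match_mode: str = "triple") -> EvalCounts:
    """Set-based comparison of predicted vs gold triples.

    ``match_mode`` is ``"triple"`` (exact (head, relation, tail) match),
    ``"head"`` or ``"tail"`` (entity-level, one side only).
    """
    if match_mode not in MATCH_MODES:
        raise ValueError(f"match_mode must be one of {MATCH_MODES}")
    if match_mode == "triple":
        p, g = predicted.spo_set(), gold.spo_set()
    elif match_mode == "head":
        p = {t.head for t in predicted if not t.is_placeholder}
        g = {t.head for t in gold if not t.is_placeholder}
    else:
        p = {t.tail for t in predicted}
        g = {t.tail for t in gold}
    tp = len(p & g)
    return EvalCounts(tp=tp, fp=len(p) - tp, fn=len(g) - tp)


def extraction_index(inp: EtaInputs) -> float:
    """eta = (v / baseline) * (v / n); 0 (with a warning) when n == 0."""
    if inp.n == 0:
        warnings.warn("extraction index undefined for n = 0; returning 0.0",
                      stacklevel=2)
        return 0.0
    return (inp.v / inp.baseline) * (inp.v / inp.n)


def extracted_domains(skg: SimpleKG, organ_terms: Iterable[str]
                      ) -> list[set[str]]:
    """Connected components of the SKG that contain an organ entity.

    The graph is taken undirected over non-placeholder triples; each
    component holding at least one organ-lexicon term is one domain.
    """
    organs = set(organ_terms)
    g = nx.Graph()
    for t in skg.triples:
        if t.is_placeholder:
            g.add_node(t.tail)
            continue
        g.add_edge(t.head, t.tail)
    return [set(comp) for comp in nx.connected_components(g)
            if comp & organs]


def valid_domain_count(skg: SimpleKG, organ_terms: Iterable[str]) -> int:
    """Domains whose root organ appears in the organ lexicon (validity proxy)."""
    return len(extracted_domains(skg, organ_terms))


def summarize_domains(skgs: Sequence[SimpleKG],
                      organ_terms: Iterable[str]
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Corpus-level summaries.

    Returns ``(domain_distribution, relation_frequencies)``:
    domain_distribution has one row per distinct per-report domain count
    (``n_domains``, ``n_reports``); relation_frequencies has one row per
    distinct (head, relation, tail) pattern with its count and percentage
    of all extracted triples, ordered by descending frequency then
    lexicographically.
    """
    organs = list(organ_terms)
    domain_counts: dict[int, int] = {}
    pattern_counts: dict[tuple[str, str, str], int] = {}
    total_triples = 0
    for skg in skgs:
        k = len(extracted_domains(skg, organs))
        domain_counts[k] = domain_counts.get(k, 0) + 1
        for t in skg.triples:
            pattern_counts[t.spo] = pattern_counts.get(t.spo, 0) + 1
            total_triples += 1
    dist = pd.DataFrame(
        [{"n_domains": k, "n_reports": c}
         for k, c in sorted(domain_counts.items())])
    rows = []
    for (h, r, t), c in sorted(pattern_counts.items(),
                               key=lambda kv: (-kv[1], kv[0])):
        rows.append({"head": h, "relation": r, "tail": t, "count": c,
                     "percent": round(100.0 * c / total_triples, 2)
                     if total_triples else 0.0})
    freq = pd.DataFrame(rows)
    return dist, freq
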