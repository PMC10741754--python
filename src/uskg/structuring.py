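"""Structuring of narrative report text into term networks.

A report is split into clauses, each clause into tokens; every token is
annotated with a normalized form and a tag (a custom tag from a domain
lexicon where available, otherwise a part-of-speech tag from a pluggable
backend).  Consecutive concepts within a clause are linked, giving an
ordered term network that downstream rule matching consumes.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

#: Default clause delimiters: Western and full-width CJK sentence/clause marks.
DEFAULT_DELIMITERS = ".,;。，；"

#: Tag emitted when a tagger backend fails on a token.
UNKNOWN_TAG = "unk"

# ---------------------------------------------------------------------------
# Tokenizer and tagger registries (pluggable backends)
# ---------------------------------------------------------------------------

Tokenizer = Callable[[str], list[str]]
Tagger = Callable[[str], str]


def _whitespace_tokenize(clause: str) -> list[str]:
    return clause.split()


TOKENIZERS: dict[str, Tokenizer] = {"whitespace": _whitespace_tokenize}


def register_tokenizer(name: str, fn: Tokenizer) -> None:
    """Register an external tokenizer backend (e.g. a Chinese segmenter)."""
    TOKENIZERS[name] = fn


_CLOSED_CLASS = {
    "the": "det", "a": "det", "an": "det",
    "is": "cop", "are": "cop", "be": "cop", "was": "cop", "were": "cop",
    "and": "conj", "or": "conj", "but": "conj",
    "of": "prep", "in": "prep", "with": "prep", "on": "prep", "at": "prep",
    "to": "prep", "by": "prep", "not": "neg", "no": "neg",
}

_ADJ_SUFFIXES = ("ous", "ful", "ive", "ible", "able", "al", "ic", "ish",
                 "less", "ar", "ed", "ish", "y")
_VERB_SUFFIXES = ("ize", "ise", "ifies", "ens", "ates")


def heuristic_tagger(token: str) -> str:
    """Small rule-of-thumb POS backend for English-like tokens.

    Closed-class words get their function tag; a few derivational suffixes
    mark adjectives and verbs; everything else defaults to noun.  Meant as a
    dependency-free default — any callable ``token -> tag`` can replace it.
    """
    low = token.lower()
    if low in _CLOSED_CLASS:
        return _CLOSED_CLASS[low]
    if low.endswith(_VERB_SUFFIXES) or (low.endswith("s") and len(low) > 3
                                        and not low.endswith("ss")):
        return "verb"
    if low.endswith(_ADJ_SUFFIXES):
        return "adj"
    return "n"


TAGGERS: dict[str, Tagger] = {"heuristic": heuristic_tagger}


def register_tagger(name: str, fn: Tagger) -> None:
    TAGGERS[name] = fn


# ---------------------------------------------------------------------------
# Configuration and domain types
# ---------------------------------------------------------------------------


class ConfigurationError(ValueError):
    """Raised for undeclared tokenizer/tagger backends or bad settings."""


@dataclass(frozen=True)
class StructuringConfig:
    """Settings for clause splitting, tokenization and normalization.

    ``lemma_table`` maps a lowercased surface (possibly multi-word) to its
    normalized form, e.g. ``{"intrahepatic": "liver", "shows": "show"}``.
    """

    delimiters: str = DEFAULT_DELIMITERS
    tokenizer: str = "whitespace"
    tagger: str = "heuristic"
    lemma_table: Mapping[str, str] = field(default_factory=dict)

    def tokenizer_fn(self) -> Tokenizer:
        try:
            return TOKENIZERS[self.tokenizer]
        except KeyError:
            raise ConfigurationError(
                f"tokenizer backend {self.tokenizer!r} is not registered; "
                f"known: {sorted(TOKENIZERS)}") from None

    def tagger_fn(self) -> Tagger:
        try:
            return TAGGERS[self.tagger]
        except KeyError:
            raise ConfigurationError(
                f"tagger backend {self.tagger!r} is not registered; "
                f"known: {sorted(TAGGERS)}") from None


@dataclass(frozen=True)
class Concept:
    """One annotated token: surface form, normalized form and tag."""

    surface: str
    normalized: str
    tag: str
    token_index: int
    sentence_index: int

    def __post_init__(self) -> None:
        if not self.surface:
            raise ValueError("Concept surface must be non-empty")


class TagLexicon:
    """Case-insensitive mapping from (normalized) domain terms to custom tags.

    Multi-word entries are honoured by longest-match merging during term
    network construction.  Unknown terms yield ``None`` so the caller can
    fall back to POS tagging.
    """

    def __init__(self, entries: Mapping[str, str] | None = None):
        self._entries: dict[str, str] = {}
        for term, tag in (entries or {}).items():
            self._entries[term.lower()] = tag
        self._max_words = max(
            (len(t.split()) for t in self._entries), default=1)

    def get(self, term: str) -> str | None:
        return self._entries.get(term.lower())

    def __contains__(self, term: str) -> bool:
        return term.lower() in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    @property
    def max_words(self) -> int:
        return self._max_words

    def tags(self) -> set[str]:
        return set(self._entries.values())

    def items(self) -> Iterable[tuple[str, str]]:
        return self._entries.items()

    @classmethod
    def from_tsv(cls, path) -> "TagLexicon":
        """Load a two-column ``term<TAB>tag`` file (blank lines, # comments ok)."""
        entries: dict[str, str] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line.strip() or line.lstrip().startswith("#"):
                    continue
                term, _, tag = line.partition("\t")
                if not tag:
                    raise ValueError(f"malformed lexicon line: {line!r}")
                entries[term.strip()] = tag.strip()
        return cls(entries)

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for term, tag in sorted(self._entries.items()):
                fh.write(f"{term}\t{tag}\n")


@dataclass
class TermNetwork:
    """Ordered concepts of one report plus edges between clause-adjacent pairs.

    Edges are stored as ``(i, j)`` pairs of ``token_index`` values with
    ``j == i + 1`` and both concepts in the same clause.
    """

    concepts: list[Concept]
    edges: list[tuple[int, int]]
    report_id: str = ""

    def concepts_in_sentence(self, sentence_index: int) -> list[Concept]:
        return [c for c in self.concepts if c.sentence_index == sentence_index]

    @property
    def n_sentences(self) -> int:
        return 1 + max((c.sentence_index for c in self.concepts), default=-1)

    def clauses(self) -> list[list[Concept]]:
        """Concepts grouped by clause, in order."""
        out: list[list[Concept]] = [[] for _ in range(self.n_sentences)]
        for c in self.concepts:
            out[c.sentence_index].append(c)
        return out

    def to_json(self) -> str:
        doc = {
            "report_id": self.report_id,
            "concepts": [
                {"surface": c.surface, "normalized": c.normalized,
                 "tag": c.tag, "token_index": c.token_index,
                 "sentence_index": c.sentence_index}
                for c in self.concepts
            ],
            "edges": [list(e) for e in self.edges],
        }
        return json.dumps(doc, ensure_ascii=False, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TermNetwork":
        doc = json.loads(text)
        concepts = [Concept(**c) for c in doc["concepts"]]
        edges = [tuple(e) for e in doc["edges"]]
        return cls(concepts, edges, doc.get("report_id", ""))

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for c in self.concepts:
            g.add_node(c.token_index, surface=c.surface,
                       normalized=c.normalized, tag=c.tag,
                       sentence_index=c.sentence_index)
        for i, j in self.edges:
            g.add_edge(i, j)
        return g

    def to_graphml(self) -> str:
        return "\n".join(nx.generate_graphml(self.to_networkx()))

    def detokenize(self, config: StructuringConfig | None = None) -> str:
        """Rebuild delimiter-separated text from the concept sequence."""
        parts = []
        for clause in self.clauses():
            if clause:
                parts.append(" ".join(c.surface for c in clause))
        return " , ".join(parts) + (" ." if parts else "")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def segment(text: str,
            config: StructuringConfig | None = None) -> list[tuple[int, str]]:
    """Split report text into ``(sentence_index, token)`` pairs.

    Clause delimiters (default ``. , ;`` plus their full-width CJK
    counterparts) bound clauses; tokens inside a clause come from the
    configured tokenizer backend.  Empty/whitespace-only text gives an empty
    sequence; empty clauses (e.g. doubled delimiters) are skipped.
    """
    config = config or StructuringConfig()
    tokenize = config.tokenizer_fn()
    if not text or not text.strip():
        return []
    pattern = "[" + re.escape(config.delimiters) + "]"
    out: list[tuple[int, str]] = []
    sentence_index = 0
    for clause in re.split(pattern, text):
        tokens = tokenize(clause)
        if not tokens:
            continue
        out.extend((sentence_index, tok) for tok in tokens)
        sentence_index += 1
    return out


def annotate(token: str, lexicon: TagLexicon,
             config: StructuringConfig | None = None, *,
             token_index: int = 0, sentence_index: int = 0) -> Concept:
    """Annotate one token with its normalized form and tag.

    Normalization is lowercasing plus an optional lemma-table lookup.  The
    lexicon tag (matched on the normalized form, then the bare lowercased
    surface) wins over the POS backend; a backend failure is logged and
    yields the tag ``"unk"``, never an exception.
    """
    if not token:
        raise ValueError("cannot annotate an empty token")
    config = config or StructuringConfig()
    low = token.lower()
    normalized = config.lemma_table.get(low, low)
    tag = lexicon.get(normalized)
    if tag is None:
        tag = lexicon.get(low)
    if tag is None:
        try:
            tag = config.tagger_fn()(token)
        except ConfigurationError:
            raise
        except Exception:  # noqa: BLE001 - backend faults degrade to "unk"
            logger.warning("tagger failed on token %r; tagging as %r",
                           token, UNKNOWN_TAG)
            tag = UNKNOWN_TAG
    return Concept(surface=token, normalized=normalized, tag=tag,
                   token_index=token_index, sentence_index=sentence_index)


def _merge_lexicon_phrases(tokens: list[str], lexicon: TagLexicon,
                           lemma_table: Mapping[str, str]) -> list[str]:
    """Greedy longest-match merge of multi-word lexicon terms.

    ``["right", "liver", "shrink"]`` with a lexicon entry for
    ``"right liver"`` becomes ``["right liver", "shrink"]``.  Matching is on
    lowercased (and lemma-mapped) phrases.
    """
    merged: list[str] = []
    i = 0
    n = len(tokens)
    max_w = lexicon.max_words
    while i < n:
        taken = False
        for width in range(min(max_w, n - i), 1, -1):
            phrase = " ".join(tokens[i:i + width])
            low = phrase.lower()
            if low in lexicon or lemma_table.get(low, low) in lexicon:
                merged.append(phrase)
                i += width
                taken = True
                break
        if not taken:
            merged.append(tokens[i])
            i += 1
    return merged


def build_term_network(text: str, lexicon: TagLexicon,
                       config: StructuringConfig | None = None,
                       report_id: str = "") -> TermNetwork:
    """Segment, annotate and link a report into its term network.

    Multi-word lexicon terms are merged into single concepts by longest
    match before tagging; edges link consecutive concepts within a clause
    (token-index distance 1), never across clause boundaries.
    """
    config = config or StructuringConfig()
    pairs = segment(text, config)
    # group tokens per clause, merge lexicon phrases, then annotate
    clauses: dict[int, list[str]] = {}
    for s_idx, tok in pairs:
        clauses.setdefault(s_idx, []).append(tok)
    concepts: list[Concept] = []
    edges: list[tuple[int, int]] = []
    token_index = 0
    for out_idx, s_idx in enumerate(sorted(clauses)):
        toks = _merge_lexicon_phrases(clauses[s_idx], lexicon,
                                      config.lemma_table)
        first = token_index
        for tok in toks:
            concepts.append(annotate(tok, lexicon, config,
                                     token_index=token_index,
                                     sentence_index=out_idx))
            token_index += 1
        edges.extend((i, i + 1) for i in range(first, token_index - 1))
    return TermNetwork(concepts=concepts, edges=edges, report_id=report_id)
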