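"""Rule-based extraction of entity-relation triples from term networks.

Tag-sequence rules are matched clause by clause over the filtered term
network.  A matched head entity is carried forward (tail-chaining) so that
chained facts like ``{liver, has, blood vessel}; {blood vessel, has,
structure}; {structure, show, clear}`` fall out of one clause.  A clause
that opens with a describable group but no head-capable entity yields a
placeholder-headed triple — the writer omitted the subject — marked with
the reserved head symbol ``"@"`` for later completion.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .structuring import (Concept, StructuringConfig, TagLexicon,
                          TermNetwork, build_term_network)

logger = logging.getLogger(__name__)

#: Reserved head symbol for a triple whose subject the writer omitted.
PLACEHOLDER = "@"

#: Tags that may head a triple: organs always, nouns once they have been
#: matched as a tail earlier in the clause (chaining).
HEAD_TAGS = ("organ", "n")

_VALUE_TAGS = frozenset({"adj", "n"})


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Emission:
    """One triple template of a rule.

    ``relation`` is either a literal string ("show", "has", "status") or an
    integer slot index, meaning the matched concept in that body slot — its
    normalized form — becomes the relation (the verb-as-relation rule).
    ``tail`` is a body slot index.
    """

    relation: str | int
    tail: int


@dataclass(frozen=True)
class TagRule:
    """A tag-sequence rule: head slot + body tags + emitted triples.

    ``body`` holds the tags following the implicit head slot, each entry a
    frozenset of acceptable tags; total pattern length is ``1 + len(body)``
    and must be 2 or 3.  ``headless`` marks rules that may fire with the
    placeholder head when no head-capable concept precedes them in the
    clause.
    """

    name: str
    body: tuple[frozenset[str], ...]
    emissions: tuple[Emission, ...]
    headless: bool = False

    def __post_init__(self) -> None:
        if not 1 <= len(self.body) <= 2:
            raise ValueError("rule pattern length must be 2 or 3")
        for em in self.emissions:
            slot = em.relation if isinstance(em.relation, int) else None
            for idx in ([slot] if slot is not None else []) + [em.tail]:
                if not 0 <= idx < len(self.body):
                    raise ValueError(
                        f"rule {self.name}: emission slot {idx} outside body")

    @property
    def pattern_length(self) -> int:
        return 1 + len(self.body)

    def pattern_tags(self) -> set[str]:
        tags = set(HEAD_TAGS)
        for slot in self.body:
            tags |= set(slot)
        return tags


@dataclass(frozen=True)
class Triple:
    """(head, relation, tail) with provenance; head ``"@"`` marks omission."""

    head: str
    relation: str
    tail: str
    report_id: str = ""
    sentence_index: int = -1

    def __post_init__(self) -> None:
        if not self.head or not self.relation or not self.tail:
            raise ValueError("triple elements must be non-empty")

    @property
    def is_placeholder(self) -> bool:
        return self.head == PLACEHOLDER

    @property
    def spo(self) -> tuple[str, str, str]:
        return (self.head, self.relation, self.tail)


@dataclass
class SimpleKG:
    """An ordered multiset of extracted triples with derived vocabularies."""

    triples: list[Triple] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.triples)

    def __iter__(self):
        return iter(self.triples)

    @property
    def entity_vocab(self) -> set[str]:
        out = set()
        for t in self.triples:
            if not t.is_placeholder:
                out.add(t.head)
            out.add(t.tail)
        return out

    @property
    def relation_vocab(self) -> set[str]:
        return {t.relation for t in self.triples}

    @property
    def placeholder_triples(self) -> list[Triple]:
        return [t for t in self.triples if t.is_placeholder]

    def spo_set(self) -> set[tuple[str, str, str]]:
        return {t.spo for t in self.triples}

    def extend(self, triples: Iterable[Triple]) -> None:
        self.triples.extend(triples)

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for t in self.triples:
                fh.write(f"{t.head}\t{t.relation}\t{t.tail}\n")

    @classmethod
    def from_tsv(cls, path) -> "SimpleKG":
        triples = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                h, r, t = line.split("\t")
                triples.append(Triple(h, r, t))
        return cls(triples)

    def to_json(self) -> str:
        return json.dumps(
            [{"head": t.head, "relation": t.relation, "tail": t.tail,
              "report_id": t.report_id, "sentence_index": t.sentence_index}
             for t in self.triples],
            ensure_ascii=False, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SimpleKG":
        return cls([Triple(**d) for d in json.loads(text)])


# ---------------------------------------------------------------------------
# Rule inventory
# ---------------------------------------------------------------------------


def default_rules() -> list[TagRule]:
    """The four stock tag-sequence rules.

    1. (organ, verb, adj|n)  -> (organ, <verb>, value) — the matched verb's
       normalized form is the relation;
    2. (organ, adj)          -> (organ, "show", adj);
    3. (organ, verb)         -> (organ, "show", verb);
    4. (organ, n[, adj])     -> (organ, "has", n) and, via tail-chaining of
       the noun into rule 2, (n, "show", adj).

    The head slot accepts an organ anywhere and a noun that an earlier match
    in the clause has made head-capable.
    """
    return [
        TagRule("verb-value", (frozenset({"verb"}), _VALUE_TAGS),
                (Emission(relation=0, tail=1),), headless=True),
        TagRule("show-adj", (frozenset({"adj"}),),
                (Emission(relation="show", tail=0),)),
        TagRule("show-verb", (frozenset({"verb"}),),
                (Emission(relation="show", tail=0),)),
        TagRule("has-n", (frozenset({"n"}),),
                (Emission(relation="has", tail=0),)),
    ]


#: Extra rule for clause-level status predicates such as "has no normalcy";
#: keeps 2-tuple clause facts uniformly triadic as (entity, "status", text).
STATUS_RULE = TagRule("status", (frozenset({"status"}),),
                      (Emission(relation="status", tail=0),))


def rules_with_status() -> list[TagRule]:
    return default_rules() + [STATUS_RULE]


def rules_to_json(rules: Sequence[TagRule]) -> str:
    return json.dumps(
        [{"name": r.name, "body": [sorted(slot) for slot in r.body],
          "emissions": [{"relation": e.relation, "tail": e.tail}
                        for e in r.emissions],
          "headless": r.headless}
         for r in rules], indent=1)


def rules_from_json(text: str) -> list[TagRule]:
    out = []
    for d in json.loads(text):
        out.append(TagRule(
            d["name"],
            tuple(frozenset(slot) for slot in d["body"]),
            tuple(Emission(e["relation"], e["tail"]) for e in d["emissions"]),
            d.get("headless", False)))
    return out


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------


def rule_tagset(rules: Sequence[TagRule]) -> set[str]:
    tags: set[str] = set()
    for r in rules:
        tags |= r.pattern_tags()
    return tags


def filter_to_ruleset(tn: TermNetwork,
                      rules: Sequence[TagRule]) -> list[list[Concept]]:
    """Keep only concepts whose tag occurs in some rule pattern.

    Order is preserved; the result is grouped by clause so that clause
    boundaries survive filtering.
    """
    tags = rule_tagset(rules)
    return [[c for c in clause if c.tag in tags] for clause in tn.clauses()]


def _body_matches(rule: TagRule, clause: Sequence[Concept],
                  start: int) -> bool:
    if start + len(rule.body) > len(clause):
        return False
    return all(clause[start + k].tag in slot
               for k, slot in enumerate(rule.body))


def _emit(rule: TagRule, head: str, clause: Sequence[Concept], start: int,
          report_id: str, sentence_index: int) -> list[Triple]:
    out = []
    for em in rule.emissions:
        # an integer relation indexes the body relative to start
        relation = (clause[start + em.relation].normalized
                    if isinstance(em.relation, int) else em.relation)
        out.append(Triple(head=head, relation=relation,
                          tail=clause[start + em.tail].normalized,
                          report_id=report_id,
                          sentence_index=sentence_index))
    return out


def match_rules(filtered: Sequence[Sequence[Concept]],
                rules: Sequence[TagRule] | None = None, *,
                report_id: str = "",
                surface_relation: bool = True) -> list[Triple]:
    """Scan each clause left-to-right and emit rule triples.

    At each position the longest rule is tried first.  The head of a match
    is the clause's most recent head-capable concept: an organ, or a noun
    that a previous match produced as its tail (tail-chaining — after
    ``(liver, has, blood vessel)`` the scan re-anchors on ``blood vessel``).
    When a clause's first describable group has no head candidate before
    it, the placeholder ``"@"`` heads the emission.  A clause-initial
    ``noun adj`` group with no head is emitted as ``(@, <noun>, adj)`` when
    ``surface_relation`` is true (the noun itself acts as the relation, the
    ``{@, surface, uneven}`` form) or as ``(@, has, noun)`` + ``(noun,
    show, adj)`` otherwise.
    """
    rules = list(default_rules()) if rules is None else list(rules)
    rules.sort(key=lambda r: -r.pattern_length)
    triples: list[Triple] = []
    for s_idx, clause in enumerate(filtered):
        head: Concept | None = None
        i = 0
        n = len(clause)
        while i < n:
            c = clause[i]
            if c.tag == "organ":
                head = c
                i += 1
                continue
            # clause-initial omitted-head noun group: noun + adj
            if (head is None and c.tag == "n" and i + 1 < n
                    and clause[i + 1].tag == "adj"):
                if surface_relation:
                    triples.append(Triple(PLACEHOLDER, c.normalized,
                                          clause[i + 1].normalized,
                                          report_id, s_idx))
                    i += 2
                else:
                    triples.append(Triple(PLACEHOLDER, "has", c.normalized,
                                          report_id, s_idx))
                    head = c  # noun becomes head-capable; adj chains via rule 2
                    i += 1
                continue
            matched = False
            for rule in rules:
                if head is None and not rule.headless:
                    continue
                if not _body_matches(rule, clause, i):
                    continue
                head_text = head.normalized if head is not None else PLACEHOLDER
                triples.extend(_emit(rule, head_text, clause, i,
                                     report_id, s_idx))
                last = clause[i + len(rule.body) - 1]
                if last.tag in HEAD_TAGS:
                    head = last  # tail-chaining: matched tail heads the next
                i += len(rule.body)
                matched = True
                break
            if not matched:
                i += 1
    return triples


def extract_skg(report: str, lexicon: TagLexicon,
                rules: Sequence[TagRule] | None = None,
                config: StructuringConfig | None = None, *,
                report_id: str = "",
                surface_relation: bool = True) -> SimpleKG:
    """Full clause-level extraction: text -> term network -> triples."""
    tn = build_term_network(report, lexicon, config, report_id=report_id)
    rules = default_rules() if rules is None else rules
    filtered = filter_to_ruleset(tn, rules)
    triples = match_rules(filtered, rules, report_id=report_id,
                          surface_relation=surface_relation)
    return SimpleKG(triples)


def extract_corpus(reports: Sequence[tuple[str, str]], lexicon: TagLexicon,
                   rules: Sequence[TagRule] | None = None,
                   config: StructuringConfig | None = None, *,
                   surface_relation: bool = True) -> SimpleKG:
    """Extract one aggregated SKG from ``(report_id, text)`` pairs."""
    kg = SimpleKG()
    for report_id, text in reports:
        kg.extend(extract_skg(text, lexicon, rules, config,
                              report_id=report_id,
                              surface_relation=surface_relation))
    return kg
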