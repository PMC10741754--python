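import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uskg import (PLACEHOLDER, SimpleKG, TagLexicon, Triple, default_rules,
                  extract_skg, filter_to_ruleset, match_rules,
                  rules_with_status)
from uskg.extraction import rules_from_json, rules_to_json
from uskg.structuring import Concept, TermNetwork


def clause_of(tagged, sentence_index=0, start=0):
    """Build a concept clause from (tag, word) pairs."""
    return [Concept(surface=w, normalized=w, tag=t,
                    token_index=start + i, sentence_index=sentence_index)
            for i, (t, w) in enumerate(tagged)]


def oracle_match(clauses, surface_relation=True):
    """Independent window-by-window enumerator with the same policy.

    Hard-codes the stock rule inventory as explicit conditionals: longest
    window first, verb relation from rule 1, literal relations otherwise,
    tail-chaining via the running head, placeholder for headless groups.
    """
    out = []
    for clause in clauses:
        seq = [(c.tag, c.normalized) for c in clause]
        head = None
        i = 0
        while i < len(seq):
            tag, word = seq[i]
            nxt = seq[i + 1] if i + 1 < len(seq) else None
            if tag == "organ":
                head = word
                i += 1
            elif tag == "verb" and nxt and nxt[0] in ("adj", "n"):
                out.append((head or PLACEHOLDER, word, nxt[1]))
                if nxt[0] == "n":
                    head = nxt[1]
                i += 2
            elif head is None and tag == "n" and nxt and nxt[0] == "adj":
                if surface_relation:
                    out.append((PLACEHOLDER, word, nxt[1]))
                    i += 2
                else:
                    out.append((PLACEHOLDER, "has", word))
                    head = word
                    i += 1
            elif head is not None and tag == "adj":
                out.append((head, "show", word))
                i += 1
            elif head is not None and tag == "verb":
                out.append((head, "show", word))
                i += 1
            elif head is not None and tag == "n":
                out.append((head, "has", word))
                head = word
                i += 1
            elif head is not None and tag == "status":
                out.append((head, "status", word))
                i += 1
            else:
                i += 1
    return out


class TestDefaultRules:
    def test_inventory_has_four_rules_over_both_lengths(self):
        rules = default_rules()
        assert len(rules) == 4
        assert sorted(r.pattern_length for r in rules) == [2, 2, 2, 3]

    def test_verb_slot_becomes_relation(self):
        triples = match_rules([clause_of([("organ", "liver"),
                                          ("verb", "thickens"),
                                          ("adj", "nonuniform")])])
        assert [t.spo for t in triples] == [("liver", "thickens",
                                            "nonuniform")]

    def test_organ_adj_uses_literal_show(self):
        triples = match_rules([clause_of([("organ", "liver"),
                                          ("adj", "rough")])])
        assert [t.spo for t in triples] == [("liver", "show", "rough")]

    def test_organ_noun_adj_emits_two_chained_triples(self):
        triples = match_rules([clause_of([("organ", "liver"), ("n", "wall"),
                                          ("adj", "thick")])])
        assert [t.spo for t in triples] == [("liver", "has", "wall"),
                                            ("wall", "show", "thick")]

    def test_rule_file_round_trip(self):
        rules = rules_with_status()
        back = rules_from_json(rules_to_json(rules))
        assert back == rules


class TestFilter:
    def test_non_rule_tags_dropped_in_order(self):
        tn = TermNetwork(clause_of([("organ", "liver"), ("det", "the"),
                                    ("adj", "rough")]), [])
        filtered = filter_to_ruleset(tn, default_rules())
        assert [(c.tag, c.surface) for c in filtered[0]] == \
            [("organ", "liver"), ("adj", "rough")]

    def test_nothing_matching_gives_empty_clauses(self):
        tn = TermNetwork(clause_of([("det", "the"), ("prep", "of")]), [])
        assert filter_to_ruleset(tn, default_rules()) == [[]]

    def test_filtering_is_idempotent(self):
        tn = TermNetwork(clause_of([("organ", "liver"), ("det", "x"),
                                    ("verb", "shows")]), [])
        once = filter_to_ruleset(tn, default_rules())
        again = filter_to_ruleset(
            TermNetwork([c for cl in once for c in cl], []), default_rules())
        assert [c.surface for cl in again for c in cl] == \
            [c.surface for cl in once for c in cl]


class TestMatchRules:
    def test_chained_noun_heads_follow_on_matches(self):
        clause = clause_of([("organ", "liver"), ("verb", "has"),
                            ("n", "blood vessel"), ("n", "structure"),
                            ("verb", "show"), ("adj", "clear")])
        triples = match_rules([clause])
        assert [t.spo for t in triples] == [
            ("liver", "has", "blood vessel"),
            ("blood vessel", "has", "structure"),
            ("structure", "show", "clear"),
        ]

    def test_headless_noun_adj_clause_gets_placeholder(self):
        triples = match_rules([clause_of([("n", "surface"),
                                          ("adj", "uneven")])])
        assert [t.spo for t in triples] == [("@", "surface", "uneven")]

    def test_headless_noun_adj_in_decomposed_mode(self):
        triples = match_rules([clause_of([("n", "surface"),
                                          ("adj", "uneven")])],
                              surface_relation=False)
        assert [t.spo for t in triples] == [("@", "has", "surface"),
                                            ("surface", "show", "uneven")]

    def test_headless_verb_group_gets_placeholder(self):
        triples = match_rules([clause_of([("verb", "show"),
                                          ("adj", "nodule shape")])])
        assert [t.spo for t in triples] == [("@", "show", "nodule shape")]

    def test_lone_organ_emits_nothing(self):
        assert match_rules([clause_of([("organ", "liver")])]) == []

    def test_organ_heads_second_group_in_same_clause(self):
        clause = clause_of([("organ", "liver"), ("adj", "rough"),
                            ("verb", "appears"), ("adj", "large")])
        triples = match_rules([clause])
        assert [t.spo for t in triples] == [("liver", "show", "rough"),
                                            ("liver", "appears", "large")]

    @pytest.mark.parametrize("surface_relation", [True, False])
    @given(data=st.data())
    @settings(max_examples=300, derandomize=True)
    def test_matches_exhaustive_window_oracle(self, surface_relation, data):
        tags = data.draw(st.lists(
            st.sampled_from(["organ", "verb", "adj", "n", "status"]),
            min_size=0, max_size=8))
        clause = clause_of([(t, f"w{i}") for i, t in enumerate(tags)])
        got = [t.spo for t in match_rules(
            [clause], rules_with_status(),
            surface_relation=surface_relation)]
        assert got == oracle_match([clause],
                                   surface_relation=surface_relation)

    @given(data=st.data())
    @settings(max_examples=100, derandomize=True)
    def test_no_fabricated_tokens_and_monotone_growth(self, data):
        n_clauses = data.draw(st.integers(1, 3))
        clauses = []
        for k in range(n_clauses):
            tags = data.draw(st.lists(
                st.sampled_from(["organ", "verb", "adj", "n"]),
                min_size=0, max_size=6))
            clauses.append(clause_of(
                [(t, f"c{k}w{i}") for i, t in enumerate(tags)],
                sentence_index=k))
        full = match_rules(clauses, rules_with_status())
        vocab = {c.normalized for cl in clauses for c in cl} | {PLACEHOLDER,
                                                                "show", "has",
                                                                "status"}
        for t in full:
            assert {t.head, t.relation, t.tail} <= vocab
        # dropping the last clause never adds triples
        partial = match_rules(clauses[:-1], rules_with_status())
        assert len(partial) <= len(full)
        assert [t.spo for t in partial] == [t.spo for t in full][:len(partial)]


class TestExtractSkg:
    def test_worked_example_reproduces_gold_rows(self, example_skg,
                                                 worked_example):
        assert [t.spo for t in example_skg.triples] == \
            [t.spo for t in worked_example["gold"].triples]
        assert len(example_skg.placeholder_triples) == 2

    def test_empty_report_gives_empty_kg(self):
        kg = extract_skg("", TagLexicon({"liver": "organ"}))
        assert len(kg) == 0

    def test_vocabularies_are_projections_of_triples(self, example_skg):
        heads = {t.head for t in example_skg if not t.is_placeholder}
        tails = {t.tail for t in example_skg}
        assert example_skg.entity_vocab == heads | tails
        assert example_skg.relation_vocab == \
            {t.relation for t in example_skg}

    def test_provenance_carries_report_and_clause(self, example_skg):
        assert {t.report_id for t in example_skg} == {"ex"}
        assert [t.sentence_index for t in example_skg.triples] == \
            [0, 1, 2, 3, 4, 5, 5, 5]

    def test_tsv_round_trip(self, tmp_path, example_skg):
        path = tmp_path / "skg.tsv"
        example_skg.to_tsv(path)
        back = SimpleKG.from_tsv(path)
        assert [t.spo for t in back] == [t.spo for t in example_skg]


class TestTriple:
    def test_placeholder_flag_tracks_head_symbol(self):
        assert Triple(PLACEHOLDER, "show", "x").is_placeholder
        assert not Triple("liver", "show", "x").is_placeholder

    def test_empty_elements_rejected(self):
        with pytest.raises(ValueError):
            Triple("", "show", "x")
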