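"""Ontology parsing, upward propagation, IC and informative-term selection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from magcat.errors import FormatError, ValidationError
from magcat.go_dag import (
    GoDag,
    GoTerm,
    ICTable,
    InformativeConfig,
    annotation_counts,
    information_content,
    informative_terms,
    parse_obo,
    propagate_up,
    write_obo,
)

from .conftest import random_propagated_counts

MINI_OBO = """format-version: 1.2
ontology: mini

[Term]
id: GO:0000001
name: root
namespace: molecular_function

[Term]
id: GO:0000002
name: mid
namespace: molecular_function
is_a: GO:0000001 ! root

[Term]
id: GO:0000003
name: leaf
namespace: molecular_function
is_a: GO:0000002 ! mid
"""


class TestParseObo:
    def test_three_term_chain(self):
        dag = parse_obo(MINI_OBO)
        assert len(dag) == 3
        assert dag.n_edges() == 2
        assert dag.parents("GO:0000003") == {"GO:0000002"}

    def test_obsolete_terms_dropped(self):
        obo = MINI_OBO + (
            "\n[Term]\nid: GO:0000004\nname: dead\n"
            "namespace: molecular_function\nis_obsolete: true\n"
        )
        dag = parse_obo(obo)
        assert "GO:0000004" not in dag
        assert len(dag) == 3

    def test_dangling_parent_pruned(self):
        obo = MINI_OBO + (
            "\n[Term]\nid: GO:0000005\nname: orphan\n"
            "namespace: molecular_function\nis_a: GO:0009999 ! missing\n"
        )
        dag = parse_obo(obo)
        assert dag.parents("GO:0000005") == frozenset()

    def test_namespace_filter(self):
        obo = MINI_OBO + (
            "\n[Term]\nid: GO:0000006\nname: process\n"
            "namespace: biological_process\n"
        )
        dag = parse_obo(obo, namespaces={"molecular_function"})
        assert "GO:0000006" not in dag and len(dag) == 3

    def test_stanza_without_id_is_a_parse_error(self):
        with pytest.raises(FormatError):
            parse_obo("format-version: 1.2\n\n[Term]\nname: nameless\n")

    def test_cycle_rejected(self):
        with pytest.raises(ValidationError, match="cycl"):
            GoDag(
                {
                    "GO:0000001": GoTerm(
                        "GO:0000001", "a", "molecular_function",
                        frozenset({"GO:0000002"}),
                    ),
                    "GO:0000002": GoTerm(
                        "GO:0000002", "b", "molecular_function",
                        frozenset({"GO:0000001"}),
                    ),
                }
            )

    def test_toy_ontology_counts_match_line_scan(self, toy):
        # independent oracle: count [Term] stanzas and is_a lines in the text
        dag, _, _ = toy
        text = write_obo(dag)
        assert len(dag) == text.count("[Term]")
        assert dag.n_edges() == sum(
            1 for line in text.splitlines() if line.startswith("is_a:")
        )

    def test_write_parse_round_trip(self, toy):
        dag, _, _ = toy
        assert parse_obo(write_obo(dag)) == dag


class TestPropagateUp:
    def test_root_has_no_ancestors(self, toy):
        dag, _, _ = toy
        assert propagate_up(dag, {"GO:0003674"}) == {"GO:0003674"}

    def test_chain_closure(self):
        dag = parse_obo(MINI_OBO)
        assert propagate_up(dag, {"GO:0000003"}) == {
            "GO:0000001",
            "GO:0000002",
            "GO:0000003",
        }

    def test_unknown_id_strict_vs_drop(self, toy):
        dag, _, _ = toy
        with pytest.raises(KeyError):
            propagate_up(dag, {"GO:9999999"})
        assert propagate_up(dag, {"GO:9999999"}, on_missing="drop") == set()

    def test_matches_exhaustive_dfs(self, toy):
        """Oracle: recursive depth-first ancestor enumeration."""
        dag, _, _ = toy

        def dfs(term):
            out = {term}
            for p in dag.parents(term):
                out |= dfs(p)
            return out

        rng = np.random.default_rng(42)
        ids = sorted(dag)
        for _ in range(30):
            chosen = set(rng.choice(ids, size=5, replace=False))
            expected = set().union(*(dfs(t) for t in chosen))
            assert propagate_up(dag, chosen) == expected

    @settings(derandomize=True, max_examples=50)
    @given(st.data())
    def test_idempotent_and_monotone(self, toy, data):
        dag, _, _ = toy
        ids = sorted(dag)
        a = set(data.draw(st.lists(st.sampled_from(ids), max_size=6)))
        b = a | set(data.draw(st.lists(st.sampled_from(ids), max_size=6)))
        ca, cb = propagate_up(dag, a), propagate_up(dag, b)
        assert propagate_up(dag, ca) == ca
        assert ca <= cb


class TestInformationContent:
    @pytest.mark.parametrize(
        "n_i,n,expected",
        [(1024, 1024, 0.0), (512, 1024, 1.0), (1, 1024, 10.0)],
    )
    def test_closed_forms(self, n_i, n, expected):
        assert information_content(n_i, n) == pytest.approx(expected)

    def test_unobserved_term_is_domain_error(self):
        with pytest.raises(ValueError):
            information_content(0, 100)
        with pytest.raises(ValueError):
            information_content(10, 0)

    def test_strictly_decreasing_in_count(self):
        vals = [information_content(k, 1000) for k in range(1, 1000, 37)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_parent_ic_never_exceeds_child_on_propagated_counts(self, toy):
        dag, counts, ic = toy
        for t in dag:
            for p in dag.parents(t):
                assert ic.ic[p] <= ic.ic[t] + 1e-12

    def test_table_from_annotation_corpus(self, toy):
        dag, _, _ = toy
        corpus = [{"GO:0000111"}, {"GO:0000111"}, {"GO:0000212"}, {"GO:0000100"}]
        counts, n = annotation_counts(dag, corpus)
        assert n == 4
        # zinc ion binding: 2 direct; binding: 2 via zinc + 1 direct
        assert counts["GO:0000111"] == 2
        assert counts["GO:0000100"] == 3
        assert counts["GO:0003674"] == 4
        table = ICTable.from_counts(counts, n)
        assert table.ic["GO:0003674"] == 0.0
        assert table.ic["GO:0000111"] == pytest.approx(1.0)

    def test_tsv_round_trip(self, toy):
        _, _, ic = toy
        assert ICTable.from_tsv(ic.to_tsv()).ic == ic.ic


class TestInformativeTerms:
    def _chain(self):
        mk = lambda i, parents: GoTerm(
            f"GO:000000{i}", f"t{i}", "molecular_function", frozenset(parents)
        )
        return GoDag(
            {
                "GO:0000001": mk(1, []),
                "GO:0000002": mk(2, ["GO:0000001"]),
                "GO:0000003": mk(3, ["GO:0000002"]),
            }
        )

    def test_chain_rule(self):
        dag = self._chain()
        counts = {"GO:0000001": 5000, "GO:0000002": 3000, "GO:0000003": 100}
        assert informative_terms(dag, counts) == {"GO:0000002"}

    def test_all_below_threshold_empty(self):
        dag = self._chain()
        counts = {"GO:0000001": 1500, "GO:0000002": 900, "GO:0000003": 100}
        assert informative_terms(dag, counts) == set()

    def test_count_equal_k_is_neither(self):
        # a term at exactly k fails the >k condition; a descendant at
        # exactly k disqualifies its ancestor (needs <k)
        dag = self._chain()
        assert informative_terms(
            dag, {"GO:0000001": 5000, "GO:0000002": 2000, "GO:0000003": 10}
        ) == set()
        assert informative_terms(
            dag, {"GO:0000001": 5000, "GO:0000002": 2001, "GO:0000003": 2000}
        ) == set()

    def test_boundary_2001_with_descendants_below(self):
        dag = self._chain()
        counts = {"GO:0000001": 5000, "GO:0000002": 2001, "GO:0000003": 1999}
        assert informative_terms(dag, counts) == {"GO:0000002"}

    def test_unpropagated_counts_rejected(self):
        dag = self._chain()
        with pytest.raises(ValidationError, match="propagated"):
            informative_terms(
                dag, {"GO:0000001": 100, "GO:0000002": 3000, "GO:0000003": 10}
            )

    def test_matches_exhaustive_two_condition_oracle(self, toy):
        dag, _, _ = toy
        rng = np.random.default_rng(11)
        k = 2000
        for _ in range(20):
            counts = random_propagated_counts(dag, rng)
            expected = {
                t
                for t in dag
                if counts.get(t, 0) > k
                and all(counts.get(d, 0) < k for d in dag.descendants(t))
            }
            got = informative_terms(dag, counts, InformativeConfig(k))
            assert got == expected

    def test_output_is_antichain(self, toy):
        dag, _, _ = toy
        rng = np.random.default_rng(5)
        for _ in range(20):
            counts = random_propagated_counts(dag, rng)
            result = informative_terms(dag, counts, InformativeConfig(500))
            for t in result:
                assert not (dag.ancestors(t) & result)

    def test_toy_planted_set_recovered(self, toy):
        from magcat.synth import TOY_INFORMATIVE

        dag, counts, _ = toy
        assert informative_terms(dag, counts) == set(TOY_INFORMATIVE)


def test_leaf_pool_shares_one_ic_level(toy):
    from magcat.synth import TOY_ANNOTATION_LEAVES, TOY_LEAF_IC_BIN

    _, _, ic = toy
    for t in TOY_ANNOTATION_LEAVES:
        assert math.floor(ic.ic[t]) == TOY_LEAF_IC_BIN
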