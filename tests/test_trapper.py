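"""Shared-term detection, parent pruning, scoring, and ranking."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import goshare
from goshare import fixtures
from goshare.errors import InputError, ScoreDomainError

from conftest import gaf_line, generated_bundle, oracle_rows, run_rows, write_text


class TestScore:
    def test_zero_at_minimum_background(self):
        assert goshare.score_term(2) == 0.0

    def test_closed_form(self):
        for g in (2, 5, 27, 100, 1000):
            assert goshare.score_term(g) == pytest.approx(math.log2(g) - 1, abs=1e-12)

    def test_strictly_increasing(self):
        scores = [goshare.score_term(g) for g in range(2, 50)]
        assert all(a < b for a, b in zip(scores, scores[1:]))

    def test_below_minimum_is_domain_error(self):
        with pytest.raises(ScoreDomainError):
            goshare.score_term(1)

    def test_min_background_override(self):
        assert goshare.score_term(8, min_background=4) == pytest.approx(1.0)


class TestSharedWithin:
    def test_parent_and_child_both_shared(self, bundle):
        """Two genes on a leaf share, after propagation, the whole lineage."""
        leaf = bundle.manifest.planted["shared_leaf"]
        sharers = bundle.index.term_to_genes[leaf] & bundle.genes_a
        assert len(sharers) >= 2
        shared = goshare.shared_terms_within(bundle.index, sharers, 2)
        assert shared[leaf] == sharers
        for ancestor in bundle.dag.ancestors(leaf):
            assert sharers <= shared[ancestor]

    def test_threshold_above_list_size_is_input_error(self, bundle):
        with pytest.raises(InputError):
            goshare.shared_terms_within(bundle.index, set(list(bundle.genes_a)[:2]), 3)

    def test_matches_exhaustive_scan(self, bundle):
        shared = goshare.shared_terms_within(bundle.index, bundle.genes_a, 5)
        brute = {
            term: genes & bundle.genes_a
            for term, genes in bundle.index.term_to_genes.items()
            if len(genes & bundle.genes_a) >= 5
        }
        assert shared == brute

    @settings(max_examples=8, derandomize=True, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=300))
    def test_threshold_antimonotone(self, seed):
        bundle = generated_bundle(seed, n_terms=10, n_genes=20)
        previous = None
        for threshold in (2, 3, 4, 5):
            shared = goshare.shared_terms_within(bundle.index, bundle.genes_a, threshold)
            if previous is not None:
                assert set(shared) <= set(previous)
            previous = shared


class TestSharedBetween:
    def test_requires_one_gene_from_each_list(self, bundle):
        shared = goshare.shared_terms_between(
            bundle.index, bundle.genes_a, bundle.genes_b, 2
        )
        only_a = bundle.genes_a - bundle.genes_b
        for term, genes in shared.items():
            annotated = bundle.index.term_to_genes[term]
            assert genes == annotated & (bundle.genes_a | bundle.genes_b)
            assert genes & bundle.genes_a and genes & bundle.genes_b
        # a term shared by two list-A genes alone must not qualify
        two_a = {
            t for t, g in bundle.index.term_to_genes.items()
            if len(g & only_a) >= 2 and not g & bundle.genes_b
        }
        assert not two_a & set(shared)

    def test_overlapping_gene_counted_once_with_warning(self, bundle):
        overlap = bundle.genes_a & bundle.genes_b
        assert overlap  # the generator plants one
        with pytest.warns(UserWarning, match="both input lists"):
            shared = goshare.shared_terms_between(
                bundle.index, bundle.genes_a, bundle.genes_b, 2
            )
        for genes in shared.values():
            assert len(genes) == len(set(genes))


class TestPrune:
    def test_parent_removed(self, chain_dag):
        shared = {"GO:0000001": {"g1", "g2"}, "GO:0000002": {"g1", "g2"}}
        assert goshare.prune_shared_parents(chain_dag, shared) == {
            "GO:0000002": {"g1", "g2"}
        }

    def test_antichain_is_fixpoint(self, bundle):
        roots_children = {
            t for t in bundle.dag.terms if not bundle.dag.descendants(t)
        }
        shared = {t: {"g"} for t in list(roots_children)[:5]}
        assert goshare.prune_shared_parents(bundle.dag, shared) == shared

    def test_matches_descendant_closure_oracle(self, bundle):
        """keep t iff no strict descendant of t is shared, by manifest edges."""
        import random

        child_map = {}
        for child, _, parent in bundle.manifest.edges:
            child_map.setdefault(parent, set()).add(child)
        rng = random.Random(0)
        terms = sorted(bundle.dag.terms)
        for _ in range(25):
            shared = {t: {"g"} for t in rng.sample(terms, k=rng.randint(1, 15))}
            pruned = goshare.prune_shared_parents(bundle.dag, shared)
            expected = {
                t: g for t, g in shared.items()
                if not fixtures._expand_to_fixpoint(t, child_map) & shared.keys()
            }
            assert pruned == expected

    def test_pruning_only_removes(self, bundle):
        shared = goshare.shared_terms_within(bundle.index, bundle.genes_a, 2)
        pruned = goshare.prune_shared_parents(bundle.dag, shared)
        assert set(pruned) <= set(shared)
        for term, genes in pruned.items():
            assert genes == shared[term]

    def test_removed_parent_gene_set_covers_a_survivor(self, bundle):
        """With propagation, each removed parent inherits some survivor's sharers."""
        shared = goshare.shared_terms_within(bundle.index, bundle.genes_a, 2)
        pruned = goshare.prune_shared_parents(bundle.dag, shared)
        for term in set(shared) - set(pruned):
            below = bundle.dag.descendants(term) & set(pruned)
            assert any(shared[term] >= pruned[d] for d in below)


class TestRank:
    def _term(self, term_id, score):
        return goshare.TrappedTerm(term_id, "BP", 2, ("A", "B"), score, "x")

    def test_ascending_by_score(self):
        terms = [self._term("GO:0000003", 5.04), self._term("GO:0000001", 3.75),
                 self._term("GO:0000002", 4.24)]
        assert [t.score for t in goshare.rank(terms)] == [3.75, 4.24, 5.04]

    def test_ties_broken_by_id(self):
        terms = [self._term("GO:0000002", 1.0), self._term("GO:0000001", 1.0)]
        assert [t.term_id for t in goshare.rank(terms)] == ["GO:0000001", "GO:0000002"]

    def test_empty(self):
        assert goshare.rank([]) == []


class TestRun:
    def test_two_gene_child_parent_scenario(self, chain_dag, tmp_path):
        """Two genes annotated to a tip share its whole lineage; only the tip
        survives pruning and is scored from its background count."""
        gaf = "\n".join(
            ["!gaf-version: 2.2",
             gaf_line("TESTDB:1", "GENEA", "GO:0000003"),
             gaf_line("TESTDB:2", "GENEB", "GO:0000003")]
        ) + "\n"
        records = goshare.read_gaf(write_text(tmp_path, "pair.gaf", gaf))
        index = goshare.build_index(records, chain_dag, propagate=True)
        genes, _ = goshare.map_genes(index, ["GENEA", "GENEB"])
        out = goshare.run(goshare.TrapConfig(mode="within", threshold=2),
                          chain_dag, index, genes)
        assert len(out) == 1
        only = out[0]
        assert only.term_id == "GO:0000003"
        assert only.shared_genes == ("GENEA", "GENEB")
        assert only.background_genes == 2
        assert only.score == pytest.approx(math.log2(2) - 1) == 0.0

    def test_apex_retained_when_only_shared_term(self, chain_dag, tmp_path):
        """Genes meeting only at the root leave the root as the sole output."""
        gaf = "\n".join(
            ["!gaf-version: 2.2",
             gaf_line("TESTDB:1", "GENEA", "GO:0000002"),
             gaf_line("TESTDB:2", "GENEB", "GO:0000003")]
        ) + "\n"
        records = goshare.read_gaf(write_text(tmp_path, "apex.gaf", gaf))
        # no propagation: the two genes share no term at all then
        index = goshare.build_index(records, chain_dag, propagate=True)
        genes, _ = goshare.map_genes(index, ["GENEA", "GENEB"])
        out = goshare.run(goshare.TrapConfig(mode="within", threshold=2),
                          chain_dag, index, genes)
        assert [t.term_id for t in out] == ["GO:0000002"]

    def test_namespace_filter(self, bundle):
        cfg = goshare.TrapConfig(mode="within", threshold=2, namespace="MF")
        out = goshare.run(cfg, bundle.dag, bundle.index, bundle.genes_a)
        assert all(t.category == "MF" for t in out)

    def test_equals_oracle_pipeline_both_modes(self, bundle):
        for mode in ("within", "between"):
            for threshold in (2, 3, 4):
                assert run_rows(bundle, mode, threshold) == oracle_rows(
                    bundle.manifest, mode, threshold
                )

    def test_between_requires_second_list(self, bundle):
        with pytest.raises(InputError):
            goshare.run(goshare.TrapConfig(mode="between"),
                        bundle.dag, bundle.index, bundle.genes_a)


class TestConfig:
    def test_threshold_below_two_rejected(self):
        with pytest.raises(InputError, match="at least two input genes"):
            goshare.TrapConfig(threshold=1)

    def test_unknown_mode_rejected(self):
        with pytest.raises(InputError):
            goshare.TrapConfig(mode="around")
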