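"""Orthogroup calling, synteny statistics, and the BIC tree score."""

import math

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tnfevol as t
from tnfevol.errors import FormatError, TreeError
from tnfevol.orthogroups import SyntenyRecord, supported_clades


def tree_of(newick):
    return dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)


def record(gene, symbols, loc, species="sp", chrom="chr1"):
    return SyntenyRecord(
        gene=gene, species=species, chromosome=chrom,
        neighbors={off: (sym, loc) for off, sym in
                   zip([-2, -1, 1, 2], symbols)})


class TestSupportedClades:
    def test_reads_supports_above_threshold(self):
        clades = supported_clades(tree_of("((a,b)100,(c,d)83);"), threshold=95)
        assert clades == [frozenset({"a", "b"})]

    def test_threshold_zero_returns_every_internal_node(self):
        clades = supported_clades(tree_of("((a,b)100,(c,d)83);"), threshold=0)
        assert frozenset({"a", "b", "c", "d"}) in clades
        assert len(clades) == 3

    def test_unrooted_tree_requires_rooting_directive(self):
        nwk = "((a:1,b:1)90:1,c:1,d:4);"
        with pytest.raises(TreeError, match="outgroup|midpoint"):
            supported_clades(tree_of(nwk))
        # midpoint rooting resolves it
        clades = supported_clades(tree_of(nwk), threshold=50, midpoint=True)
        assert frozenset({"a", "b"}) in clades

    def test_matches_simulated_truth_without_noise(self, small_truth):
        clades = supported_clades(small_truth.gene_tree, threshold=95)
        maximal = {c for c in clades if not any(c < o for o in clades)}
        families = {frozenset(m) for m in small_truth.membership.values()
                    if len(m) > 1}
        assert maximal == families


class TestChanceMatchProbability:
    def test_reference_genome_value(self):
        p = t.chance_match_probability(t.SyntenyConfig(G=20000, k=4, m=1))
        assert p == pytest.approx(2e-4, rel=1e-12)

    def test_small_genome_two_slots(self):
        p = t.chance_match_probability(t.SyntenyConfig(G=100, k=4, m=2))
        assert p == pytest.approx(1 - 0.96 ** 2, rel=1e-12)

    def test_limit_and_validation(self):
        big = t.chance_match_probability(t.SyntenyConfig(G=100, k=99, m=500))
        assert big > 0.999
        with pytest.raises(FormatError):
            t.chance_match_probability(t.SyntenyConfig(G=100, k=100, m=1))
        with pytest.raises(FormatError):
            t.chance_match_probability(t.SyntenyConfig(G=100, k=0, m=1))

    @given(g=st.integers(100, 10000), k=st.integers(1, 50),
           m=st.integers(1, 10))
    @settings(max_examples=50, derandomize=True)
    def test_monotonic_in_k_m_and_genome_size(self, g, k, m):
        p = t.chance_match_probability(t.SyntenyConfig(G=g, k=k, m=m))
        assert p <= t.chance_match_probability(t.SyntenyConfig(G=g, k=k + 1, m=m))
        assert p <= t.chance_match_probability(t.SyntenyConfig(G=g, k=k, m=m + 1))
        assert p >= t.chance_match_probability(t.SyntenyConfig(G=2 * g, k=k, m=m))

    def test_monte_carlo_agreement(self):
        """Random neighbor assignment reproduces the analytic chance rate."""
        rng = np.random.default_rng(0)
        G, k, m, n = 200, 4, 2, 200_000
        neighborhood = rng.choice(G, size=(1, k), replace=False)
        queries = rng.integers(0, G, size=(n, m))
        hits = (queries[:, :, None] == neighborhood[None, :, :]).any(axis=(1, 2))
        analytic = t.chance_match_probability(t.SyntenyConfig(G=G, k=k, m=m))
        assert hits.mean() == pytest.approx(analytic, abs=4 * math.sqrt(
            analytic * (1 - analytic) / n))


class TestSharedNeighbors:
    def test_counts_distinct_shared_symbols(self):
        a = record("a", ["RGS3", "x1", "x2", "x3"], "9q")
        b = record("b", ["y1", "y2", "RGS3", "y3"], "9q")
        assert t.shared_neighbor_count(a, b) == 1

    def test_identical_records_share_full_neighborhood(self):
        a = record("a", ["s1", "s2", "s3", "s4"], "9q")
        b = record("b", ["s1", "s2", "s3", "s4"], "9q")
        assert t.shared_neighbor_count(a, b) == 4


class TestCallOrthogroups:
    def test_split_supported_clade_by_disjoint_locations(self):
        # one 100%-supported clade, but members occupy two unrelated regions
        # with no shared neighbor: the TNFSF5/TNFSF12 separation
        tree = tree_of("((sp1|tnfsf5,sp2|tnfsf12)100,(x,y)100);")
        synteny = [
            record("sp1|tnfsf5", ["a1", "a2", "a3", "a4"], "Xq26", "sp1"),
            record("sp2|tnfsf12", ["b1", "b2", "b3", "b4"], "17p13", "sp2"),
        ]
        groups, _ = t.call_orthogroups(tree, synteny)
        split = [g for g in groups if g.members & {"sp1|tnfsf5", "sp2|tnfsf12"}]
        assert len(split) == 2

    def test_merge_sister_clades_with_shared_synteny(self):
        # two separately supported clades in the same region sharing
        # neighbors: the TNFSF18 multi-branch reunion
        tree = tree_of("(((a1,a2)100,(b1,b2)100)40,(x,y)100);")
        synteny = [
            record("a1", ["n1", "n2", "n3", "n4"], "1q25"),
            record("a2", ["n1", "n2", "n3", "n4"], "1q25"),
            record("b1", ["n1", "n2", "m3", "m4"], "1q25"),
            record("b2", ["n1", "n2", "m3", "m4"], "1q25"),
        ]
        groups, _ = t.call_orthogroups(tree, synteny)
        merged = [g for g in groups if "a1" in g.members]
        assert merged[0].members == frozenset({"a1", "a2", "b1", "b2"})

    def test_distinct_locations_never_merge(self):
        # same tree proximity but locations 6p21 vs 1q24, zero shared
        # neighbors: never one group
        tree = tree_of("(((a1,a2)100,(b1,b2)100)99,(x,y)100);")
        synteny = [
            record("a1", ["n1", "n2", "n3", "n4"], "6p21"),
            record("a2", ["n1", "n2", "n3", "n4"], "6p21"),
            record("b1", ["m1", "m2", "m3", "m4"], "1q24"),
            record("b2", ["m1", "m2", "m3", "m4"], "1q24"),
        ]
        groups, _ = t.call_orthogroups(tree, synteny)
        for g in groups:
            assert not ({"a1", "b1"} <= g.members)

    def test_output_partitions_assigned_genes(self, small_truth):
        groups, unassigned = t.call_orthogroups(
            small_truth.gene_tree, small_truth.synteny)
        seen = []
        for g in groups:
            seen.extend(g.members)
        assert len(seen) == len(set(seen))
        # idempotent on rerun
        groups2, _ = t.call_orthogroups(small_truth.gene_tree,
                                        small_truth.synteny)
        assert sorted(tuple(sorted(g.members)) for g in groups) == \
               sorted(tuple(sorted(g.members)) for g in groups2)

    def test_recovers_simulated_families_exactly(self, small_truth):
        groups, _ = t.call_orthogroups(small_truth.gene_tree,
                                       small_truth.synteny)
        called = {g.members for g in groups}
        families = {frozenset(m) for m in small_truth.membership.values()
                    if len(m) > 1}
        assert families <= called


class TestClassifyAncestral:
    def test_spanning_group_is_ancestral(self):
        groups = [t.Orthogroup("g1", frozenset({"shark|x", "zebrafish|y"})),
                  t.Orthogroup("g2", frozenset({"human|z", "frog|w"}))]
        t.classify_ancestral(groups, chondrichthyans={"shark"},
                             osteichthyans={"zebrafish", "human", "frog"})
        assert groups[0].ancestral is True
        assert groups[1].ancestral is False

    def test_matches_set_intersection_oracle(self, small_truth):
        groups = [t.Orthogroup(f, frozenset(m))
                  for f, m in small_truth.membership.items() if m]
        chond, ost = {"A", "B"}, {"C", "D"}
        t.classify_ancestral(groups, chond, ost)
        for g in groups:
            sp = {m.split("|")[0] for m in g.members}
            assert g.ancestral == (bool(sp & chond) and bool(sp & ost))

    def test_disjointness_enforced(self):
        with pytest.raises(FormatError):
            t.classify_ancestral([], {"a"}, {"a", "b"})


class TestBic:
    def test_zero_case(self):
        assert t.bic_score(0.0, 0, 10).bic == 0.0

    def test_arithmetic(self):
        score = t.bic_score(-100.0, 10, 150)
        assert score.bic == pytest.approx(10 * math.log(150) + 200, rel=1e-12)

    def test_select_best_lowest_bic_ties_to_lowest_index(self):
        scores = [t.bic_score(-50, 5, 100), t.bic_score(-10, 5, 100),
                  t.bic_score(-10, 5, 100)]
        assert t.select_best(scores) == 1
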