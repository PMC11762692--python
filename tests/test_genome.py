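"""Genome-state event application and script replay."""

import numpy as np
import pytest

import tnfevol as t
from tnfevol.errors import EventError, UnknownGeneError
from tnfevol.genome import (
    Chromosome, GeneCopy, GenomeState, LOSS, TANDEM_DUP, WGD,
)


def one_gene_state():
    return GenomeState(
        chromosomes=[Chromosome("chrA", [GeneCopy("V1", "V1")])],
        lineage_label="root")


def four_gene_state():
    return GenomeState(chromosomes=[
        Chromosome("chrA", [GeneCopy("V11", "V11"), GeneCopy("V21", "V21")]),
        Chromosome("chrB", [GeneCopy("V12", "V12"), GeneCopy("V22", "V22")]),
    ])


class TestApplyEvent:
    def test_tandem_dup_inserts_adjacent_copy(self):
        state = one_gene_state()
        new = t.apply_event(state, t.EvolutionaryEvent(
            type=TANDEM_DUP, target="V1", new_id="V1b"))
        assert [g.id for g in new.chromosomes[0].genes] == ["V1", "V1b"]
        assert t.count_genes(new) == 2
        # input not mutated
        assert t.count_genes(state) == 1

    @pytest.mark.parametrize("etype,factor", [(WGD, 2), ("TRIPLICATION", 3)])
    def test_genome_multiplication_conserves_factor(self, etype, factor):
        state = four_gene_state()
        new = t.apply_event(state, t.EvolutionaryEvent(type=etype), ordinal=5)
        assert t.count_genes(new) == factor * t.count_genes(state)
        assert len(new.chromosomes) == factor * len(state.chromosomes)

    def test_wgd_four_genes_two_chromosomes_gives_eight_on_four(self):
        new = t.apply_event(four_gene_state(), t.EvolutionaryEvent(type=WGD))
        assert t.count_genes(new) == 8
        assert len(new.chromosomes) == 4

    def test_loss_unknown_gene_errors(self):
        with pytest.raises(UnknownGeneError, match="unknown gene"):
            t.apply_event(one_gene_state(),
                          t.EvolutionaryEvent(type=LOSS, target="nope"))

    def test_loss_retains_dead_gene_but_not_in_counts(self):
        new = t.apply_event(one_gene_state(),
                            t.EvolutionaryEvent(type=LOSS, target="V1"))
        assert t.count_genes(new) == 0
        assert [g.id for g in new.iter_genes()] == ["V1"]
        # acting on a dead gene is an error
        with pytest.raises(UnknownGeneError, match="already lost"):
            t.apply_event(new, t.EvolutionaryEvent(type=LOSS, target="V1"))

    def test_inversion_reverses_range_and_rejects_cross_chromosome(self):
        state = GenomeState(chromosomes=[
            Chromosome("c1", [GeneCopy(i, i) for i in "abcd"]),
            Chromosome("c2", [GeneCopy("e", "e")]),
        ])
        new = t.apply_event(state, t.EvolutionaryEvent(
            type="INVERSION", target="b", target_end="d"))
        assert [g.id for g in new.chromosomes[0].genes] == ["a", "d", "c", "b"]
        with pytest.raises(EventError, match="spans chromosomes"):
            t.apply_event(state, t.EvolutionaryEvent(
                type="INVERSION", target="a", target_end="e"))

    def test_dup_transposition_creates_destination_chromosome(self):
        new = t.apply_event(one_gene_state(), t.EvolutionaryEvent(
            type="DUP_TRANSPOSITION", target="V1", destination="chrZ",
            new_id="V1z"))
        assert new.chromosome("chrZ").genes[0].id == "V1z"

    def test_wgd_rejects_target(self):
        with pytest.raises(EventError, match="no target"):
            t.EvolutionaryEvent(type=WGD, target="V1")


class TestReplay:
    def test_empty_event_list_is_identity(self):
        script = t.EventScript(initial_state=one_gene_state(), events=[])
        states = t.replay_script(script)
        assert list(states) == ["root"]
        assert t.count_genes(states["root"]) == 1

    def test_replay_equals_stepwise_fold(self):
        """Replay of a random valid script matches folding apply_event."""
        rng = np.random.default_rng(42)
        state = four_gene_state()
        state.lineage_label = "start"
        events = []
        folded = state
        counter = 0
        n_wgd = 0
        for i in range(30):
            alive = sorted(g.id for g in folded.iter_genes(alive_only=True))
            if not alive:
                break
            kind = rng.choice(["dup", "loss", "wgd"], p=[0.6, 0.3, 0.1])
            if kind == "wgd" and n_wgd < 2:
                ev = t.EvolutionaryEvent(type=WGD)
                n_wgd += 1
            elif kind == "dup" or kind == "wgd":
                counter += 1
                ev = t.EvolutionaryEvent(type=TANDEM_DUP,
                                         target=str(rng.choice(alive)),
                                         new_id=f"n{counter}")
            else:
                ev = t.EvolutionaryEvent(type=LOSS, target=str(rng.choice(alive)))
            events.append(("lineage", ev))
            folded = t.apply_event(folded, ev, ordinal=i)
        script = t.EventScript(initial_state=state, events=events)
        replayed = t.replay_script(script)["lineage"]
        assert [(g.id, g.origin, g.alive) for g in replayed.iter_genes()] == \
               [(g.id, g.origin, g.alive) for g in folded.iter_genes()]

    def test_replay_is_deterministic(self, fixtures):
        a = t.replay_script(fixtures["gnathostome_human"])
        b = t.replay_script(fixtures["gnathostome_human"])
        for lineage in a:
            assert [(g.id, g.origin, g.alive) for g in a[lineage].iter_genes()] \
                == [(g.id, g.origin, g.alive) for g in b[lineage].iter_genes()]

    def test_event_on_lost_gene_reports_branch(self):
        state = one_gene_state()
        events = [("b1", t.EvolutionaryEvent(type=LOSS, target="V1")),
                  ("b2", t.EvolutionaryEvent(type=TANDEM_DUP, target="V1"))]
        with pytest.raises(t.errors.ReplayError, match="b2"):
            t.replay_script(t.EventScript(initial_state=state, events=events))


class TestFixtureReplay:
    """The packaged scripts reproduce the model's lineage gene inventories."""

    @pytest.mark.parametrize("fixture,lineage,expected", [
        ("vertebrate_backbone", "metazoan_ancestor", 1),
        ("vertebrate_backbone", "early_metazoan", 2),
        ("vertebrate_backbone", "pre_vertebrate", 4),
        ("vertebrate_backbone", "vertebrate_ancestor", 8),
        ("cyclostomes", "cyclostome_ancestor", 6),
        ("cyclostomes", "Petromyzon_marinus", 9),
        ("gnathostome_human", "gnathostome_post_wgd2", 16),
        ("gnathostome_human", "gnathostome_ancestor", 21),
        ("gnathostome_human", "Homo_sapiens", 18),
        ("gnathostome_rhincodon", "Rhincodon_typus", 33),
    ])
    def test_lineage_counts(self, fixtures, fixture, lineage, expected):
        states = t.replay_script(fixtures[fixture])
        assert t.count_genes(states[lineage]) == expected

    def test_human_counts_by_ancestral_class(self, human_states):
        by_class = t.count_genes(human_states["Homo_sapiens"], by_origin=True)
        assert by_class == {"V11": 6, "V12": 4, "V21": 5, "V22": 3}

    def test_post_wgd1_is_four_tandems_on_four_chromosomes(self, fixtures):
        state = t.replay_script(fixtures["vertebrate_backbone"])["vertebrate_ancestor"]
        sizes = sorted(len([g for g in c.genes if g.alive])
                       for c in state.chromosomes)
        assert sizes == [2, 2, 2, 2]

    def test_count_genes_empty_state(self):
        assert t.count_genes(GenomeState()) == 0


class TestGenealogy:
    def test_single_tandem_dup_shares_one_root(self):
        script = t.EventScript(
            initial_state=one_gene_state(),
            events=[("b", t.EvolutionaryEvent(type=TANDEM_DUP, target="V1",
                                              new_id="V1b"))])
        g = t.derivation_genealogy(script)
        roots = [n for n in g if g.in_degree(n) == 0]
        assert roots == ["V1"]
        assert set(g.successors("V1")) == {"V1b"}

    def test_node_count_is_initial_genes_plus_copies(self, small_truth):
        """Bookkeeping: genealogy size = initial genes + copy-creating edges."""
        for script in small_truth.scripts.values():
            g = t.derivation_genealogy(
                script, species_tree=small_truth.config.species_tree())
            copy_edges = [e for e in g.edges(data=True) if e[2]["kind"] == "copy"]
            assert all(e[2]["event"] in
                       {"TANDEM_DUP", "DUP_TRANSPOSITION", "WGD", "TRIPLICATION"}
                       for e in copy_edges)
            roots = [n for n in g if g.in_degree(n) == 0]
            assert len(g) == len(roots) + len(copy_edges)
            assert len(roots) == len(list(script.initial_state.iter_genes()))

    def test_human_genes_trace_to_single_v_class(self, human_states,
                                                 human_genealogy):
        from tnfevol.genome import trace_to_class
        final = human_states["Homo_sapiens"]
        classes = {trace_to_class(human_genealogy, g.id)
                   for g in final.iter_genes(alive_only=True)}
        assert classes == {"V11", "V12", "V21", "V22"}

    def test_lost_genes_remain_as_dead_leaves(self, human_genealogy):
        assert human_genealogy.nodes["BALM"]["alive"] is False
        assert human_genealogy.out_degree("BALM") == 0
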