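"""Synthetic inputs with the statistical structure the pipeline assumes.

Three generators cover the pipeline's input surface:

* :func:`simulate_family_evolution` evolves gene families along a
  species tree with per-branch Poisson duplication/loss events and
  optional whole-genome duplications, emitting the true event scripts,
  the tip count matrix, orthogroup membership, conserved-but-imperfect
  synteny neighborhoods, and a gene tree whose supported clades match
  the true families;
* :func:`simulate_expression` draws block-correlated expression
  matrices (log-normal TPM-like marginals via a Gaussian copula, so a
  target within-module Spearman correlation can be dialled in), with
  optional immune-high modules whose top-expressing cell types are the
  immune subset;
* :func:`packaged_fixtures` returns the shipped event scripts encoding
  the TNF-superfamily evolutionary model (vertebrate backbone,
  cyclostomes, human and whale-shark lineages).

All randomness is owned by a single integer seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from .errors import FormatError
from .genome import (
    LOSS, TANDEM_DUP, WGD,
    Chromosome, EventScript, EvolutionaryEvent, GeneCopy, GenomeState,
    apply_event, count_genes, replay_script,
)
from .network import ExpressionMatrix
from .orthogroups import SyntenyRecord
from .parsimony import SpeciesTree


@dataclass
class SimulationConfig:
    """Stated world for the gene-content simulator.

    Rates are expected events per branch per family; the default sparse
    regime (well under one event per branch per family) mirrors the
    empirical situation where parsimony recovers histories exactly.
    """

    species_tree_newick: str
    dup_rate: float = 0.2
    loss_rate: float = 0.2
    wgd_branches: dict[str, list[str]] = field(default_factory=dict)
    n_families: int = 10
    root_count: int = 1
    neighborhood_k: int = 2          # neighbors per side
    rearrangement_prob: float = 0.05  # per neighbor per branch
    support_noise: float = 0.0       # P(a true clade's support drops below 95)
    seed: int = 0

    def validate(self) -> None:
        if self.dup_rate < 0 or self.loss_rate < 0:
            raise FormatError("rates must be non-negative")
        if not 0 <= self.support_noise <= 1:
            raise FormatError("support_noise must be a probability")

    def species_tree(self) -> SpeciesTree:
        return SpeciesTree.from_newick(self.species_tree_newick,
                                       polyploidy=self.wgd_branches)


@dataclass
class SimulatedTruth:
    """Everything the simulator knows, for exact scoring of every stage."""

    config: SimulationConfig
    scripts: dict[str, EventScript]
    count_matrix: pd.DataFrame                    # families x species
    membership: dict[str, list[str]]              # family -> tip gene labels
    synteny: list                                  # SyntenyRecord list
    gene_tree: dendropy.Tree
    branch_truth: pd.DataFrame                    # family, branch, dups, losses


def _family_subtree(taxa: dendropy.TaxonNamespace, labels: Sequence[str],
                    support: str) -> dendropy.Node:
    """Caterpillar clade over ``labels`` with the given support on every
    internal node."""
    tips = []
    for lbl in labels:
        taxon = taxa.get_taxon(lbl) or taxa.new_taxon(lbl)
        node = dendropy.Node(taxon=taxon)
        tips.append(node)
    node = tips[0]
    for tip in tips[1:]:
        parent = dendropy.Node()
        parent.label = support
        parent.add_child(node)
        parent.add_child(tip)
        node = parent
    return node


def simulate_family_evolution(cfg: SimulationConfig) -> SimulatedTruth:
    """Evolve ``n_families`` independent gene families along the species tree.

    Per branch and family, duplication and loss counts are Poisson
    draws; the events (plus a WGD where the branch carries one) are
    applied in random order.  A loss drawn on an extinct family is
    discarded, flooring counts at zero.  Tip counts, genealogy and
    orthogroup membership follow from replaying the recorded scripts;
    synteny neighborhoods are inherited with a per-branch rearrangement
    probability; the gene tree mirrors the true families with supports
    of 100 unless support noise demotes a clade.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    stree = cfg.species_tree()
    tree = stree.tree
    label = SpeciesTree.label_of
    for i, node in enumerate(tree.preorder_node_iter()):
        if label(node) is None:
            node.label = f"n{i}"

    tip_depth = {}
    for leaf in tree.leaf_node_iter():
        depth = 0
        node = leaf
        while node.parent_node is not None:
            depth += 1
            node = node.parent_node
        tip_depth[label(leaf)] = depth

    scripts: dict[str, EventScript] = {}
    tip_states: dict[str, dict[str, GenomeState]] = {}
    truth_rows = []

    for f in range(cfg.n_families):
        fam = f"fam{f:03d}"
        init = GenomeState(
            chromosomes=[Chromosome(
                name=f"chr_{fam}",
                genes=[GeneCopy(id=f"{fam}.g{i}", origin=fam)
                       for i in range(cfg.root_count)])],
            lineage_label="root",
        )
        events: list[tuple[str, EvolutionaryEvent]] = []
        counter = 0

        def visit(node, state: GenomeState) -> None:
            nonlocal counter
            branch = label(node)
            if node.parent_node is not None:
                n_dup = int(rng.poisson(cfg.dup_rate))
                n_loss = int(rng.poisson(cfg.loss_rate))
                plan = ["D"] * n_dup + ["L"] * n_loss
                rng.shuffle(plan)
                if branch in cfg.wgd_branches:
                    # the pre/post placement of individual events around the
                    # WGD point is itself random, as in real histories
                    for _ in cfg.wgd_branches[branch]:
                        plan.insert(int(rng.integers(0, len(plan) + 1)), "W")
                dups = losses = 0
                for op in plan:
                    alive = sorted(g.id for g in state.iter_genes(alive_only=True))
                    if op == "W":
                        ev = EvolutionaryEvent(type=WGD)
                    elif op == "D":
                        if not alive:
                            continue
                        counter += 1
                        ev = EvolutionaryEvent(
                            type=TANDEM_DUP,
                            target=str(rng.choice(alive)),
                            new_id=f"{fam}.d{counter}")
                        dups += 1
                    else:  # loss; discarded when the family is extinct
                        if not alive:
                            continue
                        ev = EvolutionaryEvent(type=LOSS,
                                               target=str(rng.choice(alive)))
                        losses += 1
                    ordinal = len(events)
                    events.append((branch, ev))
                    state = apply_event(state, ev, ordinal=ordinal)
                truth_rows.append({"family": fam, "branch": branch,
                                   "duplications": dups, "losses": losses})
            if node.is_leaf():
                tip_states.setdefault(fam, {})[branch] = state
            for child in node.child_nodes():
                visit(child, state)

        visit(tree.seed_node, init)
        scripts[fam] = EventScript(initial_state=init, events=events)

    species = [label(l) for l in tree.leaf_node_iter()]
    count_matrix = pd.DataFrame(
        {sp: [count_genes(tip_states[f"fam{f:03d}"][sp])
              for f in range(cfg.n_families)] for sp in species},
        index=[f"fam{f:03d}" for f in range(cfg.n_families)],
    )

    membership = {
        fam: sorted(f"{sp}|{g.id}"
                    for sp in species
                    for g in tip_states[fam][sp].iter_genes(alive_only=True))
        for fam in count_matrix.index
    }

    # synteny neighborhoods, inherited with occasional rearrangement
    k = cfg.neighborhood_k
    offsets = [o for o in range(-k, k + 1) if o != 0]
    synteny: list[SyntenyRecord] = []
    for fi, fam in enumerate(count_matrix.index):
        base = {off: (f"N{fi}:{off}", f"HC{fi}") for off in offsets}
        for sp in species:
            keep = (1.0 - cfg.rearrangement_prob) ** tip_depth[sp]
            for g in tip_states[fam][sp].iter_genes(alive_only=True):
                neighbors = {}
                for off in offsets:
                    if rng.random() < keep:
                        neighbors[off] = base[off]
                    else:
                        neighbors[off] = (f"R{int(rng.integers(0, 10 ** 9))}",
                                          f"HC{int(rng.integers(0, 50))}")
                synteny.append(SyntenyRecord(
                    gene=f"{sp}|{g.id}", species=sp,
                    chromosome=f"chr_{fam}", neighbors=neighbors))

    # gene tree mirroring the true families
    taxa = dendropy.TaxonNamespace()
    gtree = dendropy.Tree(taxon_namespace=taxa)
    clades = []
    for fam in count_matrix.index:
        tips = membership[fam]
        if not tips:
            continue
        clade = _family_subtree(taxa, tips, support="100")
        if len(tips) > 1 and rng.random() < cfg.support_noise:
            clade.label = "50"  # demoted below the 95% significance threshold
        clades.append(clade)
    if not clades:
        raise FormatError("all families went extinct; nothing to build a tree from")
    backbone = clades[0]
    for clade in clades[1:]:
        parent = dendropy.Node()
        parent.label = "50"   # family joins carry non-significant support
        parent.add_child(backbone)
        parent.add_child(clade)
        backbone = parent
    gtree.seed_node = backbone

    return SimulatedTruth(
        config=cfg,
        scripts=scripts,
        count_matrix=count_matrix,
        membership=membership,
        synteny=synteny,
        gene_tree=gtree,
        branch_truth=pd.DataFrame(truth_rows,
                                  columns=["family", "branch",
                                           "duplications", "losses"]),
    )


# Expression ------------------------------------------------------------------


def default_cell_types(n_types: int = 81, n_immune: int = 11
                       ) -> tuple[list[str], frozenset[str]]:
    """Cell-type labels with an immune subset, emulating the 81/11 design."""
    immune = [f"immune{i:02d}" for i in range(n_immune)]
    other = [f"cell{i:02d}" for i in range(n_types - n_immune)]
    return immune + other, frozenset(immune)


def simulate_expression(module_assignment: dict[str, str],
                        cell_types: Optional[Sequence[str]] = None,
                        immune_types: Optional[frozenset[str]] = None,
                        module_rho: float = 0.9,
                        immune_high: frozenset[str] = frozenset(),
                        seed: int = 0) -> ExpressionMatrix:
    """Block-correlated expression with log-normal TPM-like marginals.

    Genes in the same module share a latent cell-type profile plus
    independent noise calibrated so their pairwise Spearman correlation
    is approximately ``module_rho`` (Gaussian-copula relation
    ``r = 2 sin(pi * rho_s / 6)``).  Modules listed in ``immune_high``
    get a rank shift that puts the immune cell types at the top of
    every member gene's expression ranking.
    """
    if not 0 <= module_rho < 1:
        raise FormatError("module_rho must lie in [0, 1)")
    if cell_types is None:
        cell_types, immune_types = default_cell_types()
    if immune_types is None:
        immune_types = frozenset()
    rng = np.random.default_rng(seed)
    n = len(cell_types)
    genes = list(module_assignment)
    modules = sorted(set(module_assignment.values()))
    latent = {m: rng.standard_normal(n) for m in modules}
    pearson = 2.0 * math.sin(math.pi * module_rho / 6.0)
    a = math.sqrt(pearson)
    immune_mask = np.array([ct in immune_types for ct in cell_types])

    rows = []
    for gene in genes:
        m = module_assignment[gene]
        z = a * latent[m] + math.sqrt(1.0 - a * a) * rng.standard_normal(n)
        if m in immune_high:
            z = z + immune_mask * 6.0   # pushes immune types into the top ranks
        rows.append(np.exp(1.2 * z + 3.0))  # log-normal TPM-like scale
    values = pd.DataFrame(rows, index=genes, columns=list(cell_types))
    return ExpressionMatrix(values=values, immune_types=frozenset(immune_types))


# Packaged fixtures -----------------------------------------------------------

FIXTURE_NAMES = (
    "vertebrate_backbone",
    "cyclostomes",
    "gnathostome_human",
    "gnathostome_rhincodon",
)


def packaged_fixtures() -> dict[str, EventScript]:
    """The shipped event scripts encoding the superfamily's evolutionary model.

    ``vertebrate_backbone`` runs from the single ancestral gene to the
    eight-gene post-WGD1 vertebrate ancestor; ``cyclostomes`` continues
    to the six-gene cyclostome ancestor and the nine-gene *Petromyzon
    marinus* tip; ``gnathostome_human`` and ``gnathostome_rhincodon``
    continue through WGD2 (16 genes) and the 21-gene gnathostome
    ancestor to the 18-gene human and 33-gene *Rhincodon typus* tips.
    """
    out = {}
    for name in FIXTURE_NAMES:
        text = (resources.files("tnfevol") / "data" / f"{name}.json").read_text()
        out[name] = EventScript.from_dict(json.loads(text))
    return out


def replay_fixture(name: str) -> dict[str, GenomeState]:
    """Convenience: replay one packaged script and return its lineage states."""
    return replay_script(packaged_fixtures()[name])


def packaged_annotations():
    """Functional annotations of the 18 human genes.

    Feature flags (death-domain-receptor binding, NF-kB pathway
    activation) and a small ligand->receptor table compiled from
    standard interaction references.  Returns a
    :class:`~tnfevol.functions.FeatureAnnotation`.
    """
    from .functions import FeatureAnnotation
    ann = FeatureAnnotation()
    base = resources.files("tnfevol") / "data"
    for line in (base / "human_tnfsf_features.tsv").read_text().splitlines()[1:]:
        gene, feature = line.split("\t")
        ann.features.setdefault(gene, set()).add(feature)
    for line in (base / "human_tnfsf_receptors.tsv").read_text().splitlines()[1:]:
        gene, receptor = line.split("\t")
        ann.receptors.setdefault(gene, set()).add(receptor)
    return ann


def packaged_class_map() -> dict[str, str]:
    """Ancestral class (V11/V12/V21/V22) of each of the 18 human genes."""
    base = resources.files("tnfevol") / "data"
    out = {}
    for line in (base / "human_tnfsf_classes.tsv").read_text().splitlines()[1:]:
        gene, cls = line.split("\t")
        out[gene] = cls
    return out
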