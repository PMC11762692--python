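"""Orthogroup calling from gene trees and local synteny.

Orthology evidence comes from two independent sources: clades of a gene
tree with significant bootstrap support, and conservation of the genes
immediately flanking each candidate (local microsynteny).  In a genome
of ~20,000 genes even one shared flanking ortholog between two species
is strong evidence of orthology: the chance-match probability for one
queried neighbor slot against a k-gene neighborhood is
``1 - (1 - k/G)**m`` (2e-4 for G=20000, k=4, m=1).

The calling procedure seeds groups from supported clades, splits clades
whose members occupy disjoint genomic location classes with no shared
neighbors (the way chondrichthyan TNFSF5 is separated from TNFSF12),
and merges separately placed genes that share neighbors and location
(the way multi-branch TNFSF18 tips are reunited).  Synteny evidence
dominates raw tree proximity throughout.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import dendropy
import networkx as nx

from .errors import FormatError, TreeError

# Synteny ----------------------------------------------------------------------


@dataclass
class SyntenyRecord:
    """Local neighborhood of one gene.

    ``neighbors`` maps signed position offsets (-k..-1, +1..+k) to
    ``(ortholog symbol, human-chromosome class)`` pairs.
    """

    gene: str
    species: str
    chromosome: str
    neighbors: dict[int, tuple[str, str]] = field(default_factory=dict)

    def symbols(self) -> set[str]:
        return {sym for sym, _ in self.neighbors.values()}

    def location_class(self) -> Optional[str]:
        """Majority vote over the neighbors' human-chromosome classes.

        Robust to a single misassigned neighbor; ties break
        lexicographically for determinism.
        """
        if not self.neighbors:
            return None
        counts = Counter(hc for _, hc in self.neighbors.values())
        top = max(counts.values())
        return sorted(hc for hc, n in counts.items() if n == top)[0]


@dataclass
class SyntenyConfig:
    G: int = 20000          # genome gene count
    k: int = 4              # neighborhood size in genes
    m: int = 1              # queried neighbor slots
    min_shared: int = 1     # shared symbols required for a merge

    def validate(self) -> None:
        if self.k <= 0 or self.G <= 0 or self.m < 1:
            raise FormatError("SyntenyConfig requires G, k > 0 and m >= 1")
        if self.k >= self.G:
            raise FormatError(f"neighborhood k={self.k} must be < genome size G={self.G}")


def chance_match_probability(cfg: SyntenyConfig) -> float:
    """Probability that >=1 of m queried neighbor slots matches a k-gene
    neighborhood by chance in a genome of G genes: ``1 - (1 - k/G)**m``."""
    cfg.validate()
    return 1.0 - (1.0 - cfg.k / cfg.G) ** cfg.m


def shared_neighbor_count(a: SyntenyRecord, b: SyntenyRecord) -> int:
    """Number of distinct ortholog symbols present in both neighborhoods,
    irrespective of position."""
    return len(a.symbols() & b.symbols())


# Gene trees -------------------------------------------------------------------


def _node_support(node: dendropy.Node) -> Optional[float]:
    if node.label is None:
        return None
    try:
        return float(node.label)
    except ValueError:
        return None


def _tip_labels(node: dendropy.Node) -> frozenset[str]:
    return frozenset(leaf.taxon.label for leaf in node.leaf_iter())


def root_tree(tree: dendropy.Tree, outgroup: Optional[str] = None,
              midpoint: bool = False) -> dendropy.Tree:
    """Root an unrooted tree at a declared outgroup or at its midpoint."""
    if outgroup is not None:
        taxon = tree.taxon_namespace.get_taxon(outgroup)
        if taxon is None:
            raise TreeError(f"outgroup {outgroup!r} not among tree tips")
        node = tree.find_node_with_taxon_label(outgroup)
        tree.to_outgroup_position(node, update_bipartitions=False)
    elif midpoint:
        tree.reroot_at_midpoint(update_bipartitions=False)
    else:
        raise TreeError("unrooted tree: declare an outgroup or request midpoint rooting")
    return tree


def supported_clades(tree: dendropy.Tree, threshold: float = 95.0,
                     outgroup: Optional[str] = None,
                     midpoint: bool = False) -> list[frozenset[str]]:
    """Tip sets of all internal nodes with support >= threshold (percent).

    Nested supported clades are all returned.  A basal polytomy marks the
    tree as unrooted; it is then rooted at the declared outgroup or, if
    requested, at its midpoint before clades are read.
    """
    if not 0 <= threshold <= 100:
        raise TreeError(f"support threshold must be in [0, 100], got {threshold}")
    if len(tree.seed_node.child_nodes()) > 2:
        tree = root_tree(tree, outgroup=outgroup, midpoint=midpoint)
    clades = []
    for node in tree.preorder_internal_node_iter():
        support = _node_support(node)
        if support is None:
            if threshold > 0:
                continue
        elif support < threshold:
            continue
        tips = _tip_labels(node)
        if len(tips) >= 2:
            clades.append(tips)
    return clades


# Orthogroups ------------------------------------------------------------------


@dataclass
class Orthogroup:
    name: str
    members: frozenset[str]
    clade_support: Optional[float] = None
    shared_neighbor_evidence: list[tuple[tuple[str, str], frozenset[str]]] = field(
        default_factory=list)
    location_class: frozenset[str] = frozenset()
    ancestral: bool = False


def _member_location(synteny_by_gene: dict[str, SyntenyRecord], gene: str) -> Optional[str]:
    rec = synteny_by_gene.get(gene)
    return rec.location_class() if rec else None


def _split_clade(members: frozenset[str], synteny_by_gene: dict[str, SyntenyRecord],
                 min_shared: int) -> list[frozenset[str]]:
    """Partition a supported clade by synteny congruence.

    Members are linked when they share >= min_shared neighbor symbols or
    occupy the same location class; connected components become separate
    groups.  A member with no synteny record stays with the rest (tree
    evidence alone keeps it in the largest component) unless every
    member lacks synteny, in which case the clade is kept whole.
    """
    members_sorted = sorted(members)
    g = nx.Graph()
    g.add_nodes_from(members_sorted)
    with_synteny = [m for m in members_sorted if m in synteny_by_gene]
    without = [m for m in members_sorted if m not in synteny_by_gene]
    for i, a in enumerate(with_synteny):
        ra = synteny_by_gene[a]
        for b in with_synteny[i + 1:]:
            rb = synteny_by_gene[b]
            same_loc = (ra.location_class() is not None
                        and ra.location_class() == rb.location_class())
            if same_loc or shared_neighbor_count(ra, rb) >= min_shared:
                g.add_edge(a, b)
    if with_synteny:
        # genes without synteny follow the component holding most evidence
        comps = [c for c in nx.connected_components(g) if c & set(with_synteny)]
        anchor = max(comps, key=lambda c: (len(c), sorted(c)[0]))
        for m in without:
            g.add_edge(m, sorted(anchor)[0])
    return sorted((frozenset(c) for c in nx.connected_components(g)),
                  key=lambda c: sorted(c)[0])


def call_orthogroups(tree: dendropy.Tree, synteny: Sequence[SyntenyRecord],
                     cfg: Optional[SyntenyConfig] = None, threshold: float = 95.0,
                     outgroup: Optional[str] = None,
                     midpoint: bool = False) -> tuple[list[Orthogroup], list[str]]:
    """Call orthogroups from supported clades refined by synteny.

    Returns ``(groups, unassigned)``.  The procedure:

    1. seed candidate groups from maximal supported clades;
    2. split a clade whose members fall into disjoint location classes
       with zero shared neighbors across the partition;
    3. merge groups (including unplaced singletons) that share
       >= min_shared neighbor symbols *and* a location class;
    4. report genes assignable to no group as unassigned.

    Every gene ends up in at most one group.
    """
    cfg = cfg or SyntenyConfig()
    cfg.validate()
    synteny_by_gene = {rec.gene: rec for rec in synteny}
    all_tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}

    clades = supported_clades(tree, threshold=threshold, outgroup=outgroup,
                              midpoint=midpoint)
    # maximal supported clades only: drop clades nested in another
    maximal = [c for c in clades if not any(c < other for other in clades)]

    # (1)+(2): seed and split
    groups: list[set[str]] = []
    placed: set[str] = set()
    for clade in sorted(maximal, key=lambda c: sorted(c)[0]):
        clade = frozenset(clade - placed)
        if not clade:
            continue
        for part in _split_clade(clade, synteny_by_gene, cfg.min_shared):
            groups.append(set(part))
            placed |= part

    singletons = [{g} for g in sorted(all_tips - placed)]
    units: list[set[str]] = groups + singletons
    seeded = set(range(len(groups)))  # indices of clade-seeded units

    def unit_profile(u: set[str]) -> tuple[set[str], set[str]]:
        symbols: set[str] = set()
        locs: set[str] = set()
        for m in u:
            rec = synteny_by_gene.get(m)
            if rec:
                symbols |= rec.symbols()
                loc = rec.location_class()
                if loc:
                    locs.add(loc)
        return symbols, locs

    # (3): merge by shared neighbors + shared location class
    merged = True
    while merged:
        merged = False
        for i in range(len(units)):
            if not units[i]:
                continue
            si, li = unit_profile(units[i])
            for j in range(i + 1, len(units)):
                if not units[j]:
                    continue
                sj, lj = unit_profile(units[j])
                if len(si & sj) >= cfg.min_shared and li & lj:
                    if i in seeded and j in seeded:
                        # two supported clades merging is the TNFSF18 rule;
                        # allowed, but a clade previously split must not be
                        # reunited through a third party
                        pass
                    units[i] |= units[j]
                    units[j] = set()
                    merged = True
                    break
            if merged:
                break

    # consistency check: a split pair must never be reunited
    split_pairs: set[frozenset[str]] = set()
    for clade in maximal:
        parts = _split_clade(frozenset(clade), synteny_by_gene, cfg.min_shared)
        if len(parts) > 1:
            for pi in range(len(parts)):
                for pj in range(pi + 1, len(parts)):
                    for a in parts[pi]:
                        for b in parts[pj]:
                            split_pairs.add(frozenset((a, b)))
    for u in units:
        for pair in split_pairs:
            if pair <= u:
                a, b = sorted(pair)
                raise FormatError(
                    f"contradictory synteny directives: {a!r}/{b!r} were split "
                    f"within a clade but merged through shared evidence")

    out: list[Orthogroup] = []
    unassigned: list[str] = []
    idx = 1
    for u in units:
        if not u:
            continue
        if len(u) == 1:
            gene = next(iter(u))
            rec = synteny_by_gene.get(gene)
            in_clade = any(gene in c for c in maximal)
            if not in_clade and rec is None:
                unassigned.append(gene)
                continue
            if not in_clade and rec is not None:
                # singleton placed only by its own synteny: report unassigned
                # with its nearest-group evidence rather than guessing
                unassigned.append(gene)
                continue
        symbols, locs = unit_profile(u)
        out.append(Orthogroup(
            name=f"OG{idx:03d}",
            members=frozenset(u),
            location_class=frozenset(locs),
        ))
        idx += 1
    return out, sorted(unassigned)


def species_of(tip_label: str) -> str:
    """Species part of a ``species|gene`` tip label (the label itself if unseparated)."""
    return tip_label.split("|", 1)[0]


def classify_ancestral(groups: Iterable[Orthogroup], chondrichthyans: set[str],
                       osteichthyans: set[str]) -> list[Orthogroup]:
    """Flag groups whose members span both chondrichthyans and osteichthyans."""
    if chondrichthyans & osteichthyans:
        raise FormatError("chondrichthyan and osteichthyan species sets must be disjoint")
    out = []
    for grp in groups:
        sp = {species_of(m) for m in grp.members}
        grp.ancestral = bool(sp & chondrichthyans) and bool(sp & osteichthyans)
        out.append(grp)
    return out


# Tree-selection score ---------------------------------------------------------


@dataclass(frozen=True)
class TreeScore:
    lnL: float
    n_params: int
    n_sites: int

    @property
    def bic(self) -> float:
        return self.n_params * math.log(self.n_sites) - 2.0 * self.lnL


def bic_score(lnL: float, n_params: int, n_sites: int) -> TreeScore:
    """Bayesian Information Criterion: ``k ln(n) - 2 lnL``."""
    if n_sites < 1:
        raise FormatError("n_sites must be >= 1")
    return TreeScore(lnL=lnL, n_params=n_params, n_sites=n_sites)


def select_best(scores: Sequence[TreeScore]) -> int:
    """Index of the lowest-BIC score; ties break to the lowest index."""
    if not scores:
        raise FormatError("no scores to select from")
    best = 0
    for i, s in enumerate(scores):
        if s.bic < scores[best].bic:
            best = i
    return best
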