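"""Minimal duplication/loss histories of gene counts on a species tree.

Per-orthogroup gene counts at the tips are explained by per-branch
duplications (unit cost) and losses (unit cost) under a Sankoff-style
dynamic program over ancestral copy numbers 0..max_count.  Branches may
carry whole-genome duplications (WGD, x2) or triplications (WGT, x3):
the cost of such a branch is minimised over the copy number immediately
before the multiplication, and the tallied events are tagged "pre" or
"post" relative to it.

This reproduces the accounting style used for the TNF superfamily:
e.g. the vertebrate-ancestor to cyclostome-ancestor transition of eight
single-copy families, where three families drop to zero and one rises
to two, costs exactly three losses plus one duplication.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from .errors import ReconstructionError, TreeError

INF = float("inf")

MULTIPLIER = {"WGD": 2, "WGT": 3}


@dataclass
class SpeciesTree:
    """A rooted species tree with optional polyploidy-annotated branches.

    ``polyploidy`` maps a branch (identified by its child-node label) to
    an ordered list of event types (``"WGD"`` or ``"WGT"``); multiple
    annotations on one branch apply in listed order.
    """

    tree: dendropy.Tree
    polyploidy: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = set(self.node_labels())
        for branch, events in self.polyploidy.items():
            if branch not in labels:
                raise TreeError(f"polyploidy annotation references unknown branch "
                                f"{branch!r}")
            for ev in events:
                if ev not in MULTIPLIER:
                    raise TreeError(f"unknown polyploidy event {ev!r} on branch "
                                    f"{branch!r} (expected WGD or WGT)")

    @classmethod
    def from_newick(cls, newick: str,
                    polyploidy: Optional[dict[str, list[str]]] = None) -> "SpeciesTree":
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True)
        return cls(tree=tree, polyploidy=dict(polyploidy or {}))

    @staticmethod
    def label_of(node: dendropy.Node) -> Optional[str]:
        if node.taxon is not None:
            return node.taxon.label
        return node.label

    def node_labels(self) -> list[str]:
        out = []
        for node in self.tree.preorder_node_iter():
            lbl = self.label_of(node)
            if lbl:
                out.append(lbl)
        return out

    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def branch_multipliers(self, child_label: str) -> list[int]:
        return [MULTIPLIER[e] for e in self.polyploidy.get(child_label, [])]


@dataclass
class BranchTally:
    """Events tallied on one branch for one orthogroup."""

    orthogroup: str
    branch: str                      # child-node label
    parent_count: int
    child_count: int
    duplications: int = 0
    losses: int = 0
    phases: list[dict] = field(default_factory=list)
    # each phase: {"phase": "pre"|"post"|"only", "duplications": d, "losses": l}


@dataclass
class Reconstruction:
    """Per-node ancestral counts and per-branch event tallies."""

    tree: SpeciesTree
    node_counts: pd.DataFrame            # orthogroups x node labels
    branch_tallies: list[BranchTally]
    total_cost: float

    def tallies_by_branch(self) -> dict[str, list[BranchTally]]:
        out: dict[str, list[BranchTally]] = {}
        for t in self.branch_tallies:
            out.setdefault(t.branch, []).append(t)
        return out


def _segment_cost(a: int, b: int, dup_weight: float, loss_weight: float) -> float:
    return dup_weight * max(0, b - a) + loss_weight * max(0, a - b)


def branch_cost(parent: int, child: int, multipliers: Sequence[int],
                max_count: int, dup_weight: float = 1.0,
                loss_weight: float = 1.0) -> float:
    """Minimal event cost for one branch.

    Without polyploidy this is the weighted count difference.  With
    multipliers m1..mk the cost is minimised over the intermediate
    copy numbers held immediately before each multiplication.
    """
    if not multipliers:
        return _segment_cost(parent, child, dup_weight, loss_weight)
    m = multipliers[0]
    best = INF
    for c in range(max_count + 1):
        cost = _segment_cost(parent, c, dup_weight, loss_weight)
        if cost >= best:
            continue
        rest = branch_cost(m * c, child, multipliers[1:], max_count,
                           dup_weight, loss_weight)
        best = min(best, cost + rest)
    return best


def _branch_phases(parent: int, child: int, multipliers: Sequence[int],
                   max_count: int, dup_weight: float,
                   loss_weight: float) -> list[tuple[str, int, int]]:
    """Optimal (phase, from, to) segments for one branch, canonical choice.

    Ties among intermediates break toward the smallest copy number, so
    events sit as late (tip-ward) as possible.
    """
    if not multipliers:
        return [("only", parent, child)]
    m = multipliers[0]
    best: tuple[float, int] = (INF, -1)
    for c in range(max_count + 1):
        cost = (_segment_cost(parent, c, dup_weight, loss_weight)
                + branch_cost(m * c, child, multipliers[1:], max_count,
                              dup_weight, loss_weight))
        if cost < best[0]:
            best = (cost, c)
    c = best[1]
    segments = [("pre", parent, c)]
    tail = _branch_phases(m * c, child, multipliers[1:], max_count,
                          dup_weight, loss_weight)
    for phase, a, b in tail:
        segments.append(("post" if phase == "only" else phase, a, b))
    return segments


def reconstruct(tree: SpeciesTree, counts: pd.DataFrame,
                max_count: Optional[int] = None,
                root_count: Optional[int] = None,
                dup_weight: float = 1.0,
                loss_weight: float = 1.0) -> Reconstruction:
    """Sankoff dynamic program over per-node copy numbers, per orthogroup.

    ``counts`` has orthogroups as rows and species (tree tips) as
    columns.  ``max_count`` bounds the ancestral state space and
    defaults to twice the largest observed tip count plus two.
    ``root_count`` pins the root copy number for every orthogroup (e.g.
    one per ancestral family); by default the root state is free and
    minimised over.  Returns one canonical optimal reconstruction:
    ties prefer smaller ancestral counts at deeper nodes, which places
    events as close to the tips as possible.
    """
    tips = set(tree.tip_labels())
    missing = [c for c in counts.columns if c not in tips]
    if missing:
        raise ReconstructionError(f"count matrix columns not in species tree: {missing}")
    absent = [t for t in tips if t not in counts.columns]
    if absent:
        raise ReconstructionError(f"species tree tips missing from count matrix: {absent}")
    if (counts.values < 0).any():
        raise ReconstructionError("gene counts must be non-negative")

    observed_max = int(counts.values.max()) if counts.size else 0
    M = max_count if max_count is not None else 2 * observed_max + 2
    over = counts.max(axis=1)
    bad = over[over > M]
    if len(bad):
        raise ReconstructionError(
            f"max_count={M} too small for orthogroup(s) {list(bad.index)} "
            f"(largest tip count {int(bad.max())})")

    # Pre-compute branch cost tables child-state x parent-state per branch.
    nodes = list(tree.tree.postorder_node_iter())
    label = SpeciesTree.label_of
    for i, node in enumerate(nodes):
        if label(node) is None:
            node.label = f"_node{i}"  # ensure addressable internal labels
    cost_tables: dict[str, np.ndarray] = {}
    for node in nodes:
        if node.parent_node is None:
            continue
        mult = tree.branch_multipliers(label(node))
        table = np.empty((M + 1, M + 1))
        for p in range(M + 1):
            for c in range(M + 1):
                table[p, c] = branch_cost(p, c, mult, M, dup_weight, loss_weight)
        cost_tables[label(node)] = table

    node_labels = [label(n) for n in nodes]
    all_counts: dict[str, dict[str, int]] = {og: {} for og in counts.index}
    tallies: list[BranchTally] = []
    total = 0.0

    for og in counts.index:
        # bottom-up Sankoff pass
        subtree: dict[str, np.ndarray] = {}
        for node in nodes:
            lbl = label(node)
            if node.is_leaf():
                vec = np.full(M + 1, INF)
                vec[int(counts.loc[og, lbl])] = 0.0
            else:
                vec = np.zeros(M + 1)
                for child in node.child_nodes():
                    clbl = label(child)
                    tbl = cost_tables[clbl]
                    vec = vec + np.min(tbl + subtree[clbl][None, :], axis=1)
            subtree[lbl] = vec

        root = nodes[-1]
        root_vec = subtree[label(root)]
        if root_count is not None:
            if root_count > M:
                raise ReconstructionError(f"root_count {root_count} exceeds "
                                          f"max_count {M}")
            root_state = root_count
            og_cost = root_vec[root_state]
            if og_cost == INF:
                raise ReconstructionError(
                    f"orthogroup {og!r}: pinned root count {root_count} is infeasible")
        else:
            og_cost = float(root_vec.min())
            root_state = int(np.argmin(root_vec))  # smallest state on ties
        total += og_cost

        # top-down pass: smallest optimal state at each internal node
        states = {label(root): root_state}
        for node in reversed(nodes):
            if node.is_leaf():
                states[label(node)] = int(counts.loc[og, label(node)])
                continue
            p = states[label(node)]
            for child in node.child_nodes():
                clbl = label(child)
                if child.is_leaf():
                    states[clbl] = int(counts.loc[og, clbl])
                    continue
                opts = cost_tables[clbl][p, :] + subtree[clbl]
                states[clbl] = int(np.argmin(opts))
        for lbl, s in states.items():
            all_counts[og][lbl] = s

        # per-branch tallies with pre/post phase tags
        for node in nodes:
            if node.parent_node is None:
                continue
            clbl = label(node)
            p = states[label(node.parent_node)]
            c = states[clbl]
            mult = tree.branch_multipliers(clbl)
            segments = _branch_phases(p, c, mult, M, dup_weight, loss_weight)
            tally = BranchTally(orthogroup=og, branch=clbl,
                                parent_count=p, child_count=c)
            for phase, a, b in segments:
                d, l = max(0, b - a), max(0, a - b)
                tally.duplications += d
                tally.losses += l
                if d or l:
                    tally.phases.append(
                        {"phase": phase, "duplications": d, "losses": l})
            tallies.append(tally)

    node_counts = pd.DataFrame(
        {lbl: [all_counts[og][lbl] for og in counts.index] for lbl in node_labels},
        index=counts.index,
    )
    return Reconstruction(tree=tree, node_counts=node_counts,
                          branch_tallies=tallies, total_cost=total)


def clade_event_totals(rec: Reconstruction, clade_root: str,
                       exclude_polyploid_lineages: bool = False) -> tuple[int, int]:
    """Total (duplications, losses) on the branches of a clade.

    The clade comprises the branch entering ``clade_root`` (when it has
    one) and every branch below it.  With ``exclude_polyploid_lineages``
    every branch at or below a polyploidy annotation is dropped,
    mirroring how WGD lineages are set aside when summarising lineage
    dynamics.
    """
    tree = rec.tree
    label = SpeciesTree.label_of
    target = None
    for node in tree.tree.preorder_node_iter():
        if label(node) == clade_root:
            target = node
            break
    if target is None:
        raise TreeError(f"clade root {clade_root!r} not found in species tree")

    include: set[str] = set()

    def visit(node, excluded: bool) -> None:
        lbl = label(node)
        if exclude_polyploid_lineages and lbl in tree.polyploidy:
            excluded = True
        if not excluded and node.parent_node is not None:
            include.add(lbl)
        for child in node.child_nodes():
            visit(child, excluded)

    visit(target, False)

    dups = sum(t.duplications for t in rec.branch_tallies if t.branch in include)
    losses = sum(t.losses for t in rec.branch_tallies if t.branch in include)
    return dups, losses


def class_dynamics(rec: Reconstruction,
                   class_map: dict[str, str]) -> dict[str, tuple[int, int]]:
    """Per-ancestral-class (duplications, losses) summed over all branches."""
    out: dict[str, list[int]] = {}
    for t in rec.branch_tallies:
        if t.orthogroup not in class_map:
            raise ReconstructionError(f"orthogroup {t.orthogroup!r} missing from "
                                      f"class map")
        cls = class_map[t.orthogroup]
        acc = out.setdefault(cls, [0, 0])
        acc[0] += t.duplications
        acc[1] += t.losses
    return {cls: (d, l) for cls, (d, l) in out.items()}


# Brute-force reference (used by tests as an independent oracle) --------------


def brute_force_cost(tree: SpeciesTree, counts: pd.DataFrame, max_count: int,
                     root_count: Optional[int] = None,
                     dup_weight: float = 1.0, loss_weight: float = 1.0) -> float:
    """Exhaustive minimum over all ancestral count assignments.

    Exponential in the number of internal nodes; intended for tiny trees
    only, as a cross-check of the dynamic program.
    """
    label = SpeciesTree.label_of
    nodes = list(tree.tree.postorder_node_iter())
    for i, node in enumerate(nodes):
        if label(node) is None:
            node.label = f"_node{i}"
    internal = [n for n in nodes if not n.is_leaf()]
    total = 0.0
    for og in counts.index:
        best = INF
        for assignment in itertools.product(range(max_count + 1),
                                            repeat=len(internal)):
            states = {label(n): s for n, s in zip(internal, assignment)}
            if root_count is not None and states[label(nodes[-1])] != root_count:
                continue
            for leaf in nodes:
                if leaf.is_leaf():
                    states[label(leaf)] = int(counts.loc[og, label(leaf)])
            cost = 0.0
            for node in nodes:
                if node.parent_node is None:
                    continue
                mult = tree.branch_multipliers(label(node))
                cost += branch_cost(states[label(node.parent_node)],
                                    states[label(node)], mult, max_count,
                                    dup_weight, loss_weight)
                if cost >= best:
                    break
            best = min(best, cost)
        total += best
    return total
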