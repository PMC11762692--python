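"""Backward (single-origin) inference of ancestral gene functions.

Given a gene derivation genealogy and functional annotations of extant
genes (feature flags such as death-domain-receptor binding or NF-kB
pathway activation, and the receptors each ligand binds), a feature is
projected onto ancestral genes under a Dollo-style rule: a single
emergence followed by any number of losses is cheaper than repeated
independent gains.  Concretely, the feature is placed on the minimal
connected subgraph of the genealogy spanning all annotated genes — it
is present at an internal gene when at least two of its descendant
lineages (counting the gene's own extant continuation) carry it, and on
every gene on a path from such a junction down to an annotated gene.

The same genealogy answers whether ligands sharing a receptor share a
single ancestral origin, the pattern observed for the TNF superfamily.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx

from .errors import AnnotationError
from .genome import trace_to_class, trace_to_root


@dataclass
class FeatureAnnotation:
    """Feature flags and receptor assignments for extant genes."""

    features: dict[str, set[str]] = field(default_factory=dict)
    receptors: dict[str, set[str]] = field(default_factory=dict)

    def feature_vocabulary(self) -> set[str]:
        out: set[str] = set()
        for fs in self.features.values():
            out |= fs
        return out

    def genes_with(self, feature: str) -> set[str]:
        return {g for g, fs in self.features.items() if feature in fs}


@dataclass
class AncestralFeatureMap:
    """Inferred feature sets per genealogy node, with the placing rule.

    ``rules[node][feature]`` is ``"annotated"`` (directly observed),
    ``"junction"`` (supported by >=2 descendant lineages) or ``"path"``
    (on the spanning path between a junction and an annotated gene).
    """

    presence: dict[str, set[str]] = field(default_factory=dict)
    rules: dict[str, dict[str, str]] = field(default_factory=dict)

    def features_at(self, node: str) -> set[str]:
        return self.presence.get(node, set())

    def _place(self, node: str, feature: str, rule: str) -> None:
        self.presence.setdefault(node, set()).add(feature)
        self.rules.setdefault(node, {}).setdefault(feature, rule)


def _check_annotated_known(genealogy: nx.DiGraph, ann: FeatureAnnotation) -> None:
    unknown = (set(ann.features) | set(ann.receptors)) - set(genealogy.nodes)
    if unknown:
        raise AnnotationError(
            f"annotations reference genes absent from the genealogy: "
            f"{sorted(unknown)}")


def infer_ancestral_features(genealogy: nx.DiGraph,
                             ann: FeatureAnnotation) -> AncestralFeatureMap:
    """Project features onto ancestral genes under the single-origin rule.

    For each feature, presence is inferred on the minimal connected
    subtree of the genealogy spanning the annotated genes: the unique
    labelling that requires one gain and the fewest subsequent
    retentions.  A feature observed in only one gene is inferred nowhere
    above it.  Adding an annotation never removes an inferred feature.
    """
    _check_annotated_known(genealogy, ann)
    fmap = AncestralFeatureMap()
    for gene, feats in ann.features.items():
        for f in feats:
            fmap._place(gene, f, "annotated")

    for feature in sorted(ann.feature_vocabulary()):
        annotated = ann.genes_with(feature)
        # bottom-up: which nodes have the feature somewhere in their subtree
        # (a node's own annotation counts as one descendant lineage)
        carrier_count: dict[str, int] = {}
        in_subtree: dict[str, bool] = {}
        for node in nx.topological_sort(genealogy.reverse(copy=False)):
            n_lineages = int(node in annotated)
            n_lineages += sum(1 for c in genealogy.successors(node)
                              if in_subtree.get(c, False))
            carrier_count[node] = n_lineages
            in_subtree[node] = n_lineages > 0
        # top-down: presence propagates from junctions toward annotated genes
        for node in nx.topological_sort(genealogy):
            preds = list(genealogy.predecessors(node))
            parent_present = any(feature in fmap.features_at(p) for p in preds)
            if carrier_count[node] >= 2:
                fmap._place(node, feature, "junction")
            elif parent_present and in_subtree[node]:
                fmap._place(node, feature, "path")
    return fmap


@dataclass
class ReceptorReport:
    receptor: str
    ligands: tuple[str, ...]
    root_labels: tuple[str, ...]
    single_origin: bool


def shared_receptor_ancestry(genealogy: nx.DiGraph, ann: FeatureAnnotation,
                             roots: Optional[Iterable[str]] = None
                             ) -> list[ReceptorReport]:
    """Per-receptor: ancestral origins of its ligands and whether they agree.

    Each ligand gene is traced up the genealogy to its ancestral-class
    label (or to its root-era gene if no class resolves).  ``roots``
    optionally restricts the labels considered valid; labels outside it
    are reported as-is.
    """
    _check_annotated_known(genealogy, ann)
    by_receptor: dict[str, list[str]] = {}
    for gene, recs in ann.receptors.items():
        for r in recs:
            by_receptor.setdefault(r, []).append(gene)
    valid = set(roots) if roots is not None else None

    out = []
    for receptor in sorted(by_receptor):
        ligands = sorted(by_receptor[receptor])
        labels = []
        for g in ligands:
            cls = trace_to_class(genealogy, g)
            if valid is not None and cls not in valid:
                cls = trace_to_root(genealogy, g)
            labels.append(cls)
        out.append(ReceptorReport(
            receptor=receptor,
            ligands=tuple(ligands),
            root_labels=tuple(labels),
            single_origin=len(set(labels)) == 1,
        ))
    return out
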