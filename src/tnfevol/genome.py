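"""Genome states and evolutionary-event replay.

A genome state is an ordered arrangement of gene copies on named
chromosomes.  Evolutionary event scripts (tandem duplications,
duplications with transposition, whole-genome duplications and
triplications, losses, transpositions, inversions) are replayed along a
lineage — either a linear chain of branch labels or a rooted species
tree — to produce the gene inventory at every named ancestor and tip.

Gene origins carry ancestral-class labels.  The vertebrate TNF
superfamily uses ``V1``/``V2`` for the two pre-vertebrate genes,
``V11``..``V22`` for the four genes present before the first vertebrate
whole-genome duplication (WGD1), ``V111``..``V222`` for the eight
post-WGD1 genes, cyclostome ``C1``..``C6`` labels, and extant orthogroup
names.  :func:`ancestral_class` collapses any such label to its
``V11``/``V12``/``V21``/``V22`` class when possible.

Dead genes are retained in the state (flagged ``alive=False``) so that
derivation genealogies can display losses; all counts skip them.
"""

from __future__ import annotations

import copy
import json
import re
from dataclasses import dataclass, field
from typing import Iterator, Optional

import networkx as nx

from .errors import EventError, ReplayError, TreeError, UnknownGeneError

# Event type vocabulary -------------------------------------------------------

TANDEM_DUP = "TANDEM_DUP"
DUP_TRANSPOSITION = "DUP_TRANSPOSITION"
WGD = "WGD"
TRIPLICATION = "TRIPLICATION"
LOSS = "LOSS"
TRANSPOSITION = "TRANSPOSITION"
INVERSION = "INVERSION"

EVENT_TYPES = frozenset(
    {TANDEM_DUP, DUP_TRANSPOSITION, WGD, TRIPLICATION, LOSS, TRANSPOSITION, INVERSION}
)

#: Event types that create at least one new gene copy.
COPYING_EVENTS = frozenset({TANDEM_DUP, DUP_TRANSPOSITION, WGD, TRIPLICATION})

_V_CLASS_RE = re.compile(r"^V[12][12]")
_V_ROOT_RE = re.compile(r"^V[12]")


def ancestral_class(origin: str) -> str:
    """Collapse an origin label to its ancestral-class prefix.

    ``V111`` -> ``V11``; ``V12`` -> ``V12``; ``V2`` -> ``V2``; any other
    label (``C4``, ``TNFSF6``...) is returned unchanged.
    """
    m = _V_CLASS_RE.match(origin)
    if m:
        return m.group(0)
    m = _V_ROOT_RE.match(origin)
    if m:
        return m.group(0)
    return origin


# Domain types ----------------------------------------------------------------


@dataclass
class GeneCopy:
    """One gene copy: a unique id, an ancestral-origin label, and a life flag."""

    id: str
    origin: str
    alive: bool = True


@dataclass
class Chromosome:
    name: str
    genes: list[GeneCopy] = field(default_factory=list)


@dataclass
class GenomeState:
    """Ordered chromosomes of gene copies for one lineage."""

    chromosomes: list[Chromosome] = field(default_factory=list)
    lineage_label: str = ""

    def iter_genes(self, alive_only: bool = False) -> Iterator[GeneCopy]:
        for chrom in self.chromosomes:
            for gene in chrom.genes:
                if not alive_only or gene.alive:
                    yield gene

    def find(self, gene_id: str) -> tuple[int, int]:
        """Return (chromosome index, position) of ``gene_id`` or raise."""
        for ci, chrom in enumerate(self.chromosomes):
            for gi, gene in enumerate(chrom.genes):
                if gene.id == gene_id:
                    return ci, gi
        raise UnknownGeneError(f"unknown gene {gene_id!r} in state {self.lineage_label!r}")

    def get(self, gene_id: str) -> GeneCopy:
        ci, gi = self.find(gene_id)
        return self.chromosomes[ci].genes[gi]

    def chromosome(self, name: str) -> Optional[Chromosome]:
        for chrom in self.chromosomes:
            if chrom.name == name:
                return chrom
        return None

    def validate(self) -> None:
        seen: set[str] = set()
        for gene in self.iter_genes():
            if gene.id in seen:
                raise EventError(f"duplicate gene id {gene.id!r} in genome state")
            seen.add(gene.id)

    def clone(self) -> "GenomeState":
        return copy.deepcopy(self)


@dataclass
class EvolutionaryEvent:
    """A single evolutionary event.

    ``target`` names the template / lost / moved gene (absent for whole
    genome multiplications); ``target_end`` closes an inversion range;
    ``destination`` is the receiving chromosome for transposition
    variants.  ``new_id`` / ``new_origin`` label the created copy;
    ``relabel_target_id`` / ``relabel_target_origin`` optionally rename
    the template itself, mirroring how gene names change at key stages
    of the superfamily's history.  Whole-genome multiplications accept
    an ``id_map`` of ``template id -> [new ids...]`` (first entry
    renames the original, the rest name the copies) and an
    ``origin_suffixes`` list appended to every origin label (original
    first), e.g. ``["1", "2"]`` turns ``V11`` into ``V111``/``V112``.
    """

    type: str
    target: Optional[str] = None
    target_end: Optional[str] = None
    destination: Optional[str] = None
    new_id: Optional[str] = None
    new_origin: Optional[str] = None
    relabel_target_id: Optional[str] = None
    relabel_target_origin: Optional[str] = None
    id_map: Optional[dict[str, list[str]]] = None
    origin_suffixes: Optional[list[str]] = None

    def __post_init__(self) -> None:
        if self.type not in EVENT_TYPES:
            raise EventError(f"unknown event type {self.type!r}")
        if self.type in (WGD, TRIPLICATION):
            if self.target is not None:
                raise EventError(f"{self.type} events carry no target")
        elif self.target is None:
            raise EventError(f"{self.type} events require a target gene id")

    @classmethod
    def from_dict(cls, d: dict) -> "EvolutionaryEvent":
        known = {
            "type", "target", "target_end", "destination", "new_id", "new_origin",
            "relabel_target_id", "relabel_target_origin", "id_map", "origin_suffixes",
        }
        return cls(**{k: v for k, v in d.items() if k in known})

    def to_dict(self) -> dict:
        d: dict = {"type": self.type}
        for k in ("target", "target_end", "destination", "new_id", "new_origin",
                  "relabel_target_id", "relabel_target_origin", "id_map",
                  "origin_suffixes"):
            v = getattr(self, k)
            if v is not None:
                d[k] = v
        return d


@dataclass
class EventScript:
    """An ordered, branch-anchored list of evolutionary events."""

    initial_state: GenomeState
    events: list[tuple[str, EvolutionaryEvent]] = field(default_factory=list)
    version: str = "1"

    def branches(self) -> list[str]:
        """Branch labels in order of first appearance."""
        out: list[str] = []
        for branch, _ in self.events:
            if branch not in out:
                out.append(branch)
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "EventScript":
        chroms = [
            Chromosome(
                name=c["name"],
                genes=[GeneCopy(id=g["id"], origin=g["origin"], alive=g.get("alive", True))
                       for g in c["genes"]],
            )
            for c in d["initial_state"]["chromosomes"]
        ]
        state = GenomeState(chromosomes=chroms,
                            lineage_label=d["initial_state"].get("lineage_label", "root"))
        state.validate()
        events = [(e["branch"], EvolutionaryEvent.from_dict(e)) for e in d["events"]]
        return cls(initial_state=state, events=events, version=str(d.get("version", "1")))

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "initial_state": {
                "lineage_label": self.initial_state.lineage_label,
                "chromosomes": [
                    {"name": c.name,
                     "genes": [{"id": g.id, "origin": g.origin} for g in c.genes]}
                    for c in self.initial_state.chromosomes
                ],
            },
            "events": [dict(branch=b, **e.to_dict()) for b, e in self.events],
        }

    @classmethod
    def from_json(cls, path) -> "EventScript":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
            fh.write("\n")


# Event application -----------------------------------------------------------


class _GenealogyRecorder:
    """Collects derivation edges while a script is replayed."""

    def __init__(self, initial_state: GenomeState):
        self.graph = nx.DiGraph()
        for gene in initial_state.iter_genes():
            self.graph.add_node(gene.id, origin=gene.origin, alive=gene.alive,
                                root=True)

    def copy(self, parent: str, child: str, origin: str, event_type: str,
             branch: str, ordinal: int) -> None:
        self.graph.add_node(child, origin=origin, alive=True, root=False)
        self.graph.add_edge(parent, child, event=event_type, branch=branch,
                            ordinal=ordinal, kind="copy")

    def rename(self, old: str, new: str, origin: str, event_type: str,
               branch: str, ordinal: int) -> None:
        alive = self.graph.nodes[old].get("alive", True) if old in self.graph else True
        self.graph.add_node(new, origin=origin, alive=alive, root=False)
        self.graph.add_edge(old, new, event=event_type, branch=branch,
                            ordinal=ordinal, kind="rename")

    def loss(self, gene_id: str) -> None:
        if gene_id in self.graph:
            self.graph.nodes[gene_id]["alive"] = False


def _require_alive(state: GenomeState, gene_id: str) -> GeneCopy:
    gene = state.get(gene_id)
    if not gene.alive:
        raise UnknownGeneError(
            f"gene {gene_id!r} was already lost in state {state.lineage_label!r}")
    return gene


def _new_chrom_name(state: GenomeState, base: str, ordinal: int, tag: str) -> str:
    name = f"{base}-{tag}{ordinal}"
    while state.chromosome(name) is not None:  # pragma: no cover - defensive
        name += "'"
    return name


def apply_event(state: GenomeState, event: EvolutionaryEvent, ordinal: int = 0,
                _recorder: Optional[_GenealogyRecorder] = None,
                _branch: str = "") -> GenomeState:
    """Apply one event, returning a new state; the input is not mutated.

    ``ordinal`` disambiguates default ids for copies (``-d<ordinal>`` for
    local duplications, ``-b<ordinal>``/``-c<ordinal>`` for genome
    multiplications) so replays are reproducible.
    """
    new = state.clone()
    et = event.type

    if et in (WGD, TRIPLICATION):
        n_copies = 1 if et == WGD else 2
        suffixes = event.origin_suffixes
        expected = n_copies + 1
        if suffixes is not None and len(suffixes) != expected:
            raise EventError(
                f"{et} origin_suffixes must have {expected} entries, got {len(suffixes)}")
        copy_tags = ["b", "c"][:n_copies]
        originals = list(new.chromosomes)
        for chrom in originals:
            for k, tag in enumerate(copy_tags):
                new_chrom = Chromosome(name=_new_chrom_name(new, chrom.name, ordinal, tag))
                for gene in chrom.genes:
                    if not gene.alive:
                        continue
                    if event.id_map and gene.id in event.id_map:
                        ids = event.id_map[gene.id]
                        if len(ids) != expected:
                            raise EventError(
                                f"id_map for {gene.id!r} must list {expected} ids")
                        cid = ids[k + 1]
                    else:
                        cid = f"{gene.id}-{tag}{ordinal}"
                    corigin = gene.origin + (suffixes[k + 1] if suffixes else "")
                    new_chrom.genes.append(GeneCopy(id=cid, origin=corigin))
                    if _recorder:
                        _recorder.copy(gene.id, cid, corigin, et, _branch, ordinal)
                new.chromosomes.append(new_chrom)
        # rename/relabel the originals after the copies are derived from them
        for chrom in originals:
            for gene in chrom.genes:
                if not gene.alive:
                    continue
                old_id = gene.id
                if event.id_map and old_id in event.id_map:
                    gene.id = event.id_map[old_id][0]
                if suffixes:
                    gene.origin = gene.origin + suffixes[0]
                if _recorder and (gene.id != old_id or suffixes):
                    _recorder.rename(old_id, gene.id, gene.origin, et, _branch, ordinal)
        new.validate()
        return new

    if et == LOSS:
        gene = _require_alive(new, event.target)
        gene.alive = False
        if _recorder:
            _recorder.loss(gene.id)
        return new

    if et == INVERSION:
        ci, gi = new.find(event.target)
        end = event.target_end or event.target
        cj, gj = new.find(end)
        if ci != cj:
            raise EventError(
                f"inversion range {event.target!r}..{end!r} spans chromosomes")
        lo, hi = sorted((gi, gj))
        chrom = new.chromosomes[ci]
        chrom.genes[lo:hi + 1] = chrom.genes[lo:hi + 1][::-1]
        return new

    if et == TRANSPOSITION:
        gene = _require_alive(new, event.target)
        ci, gi = new.find(event.target)
        moved = new.chromosomes[ci].genes.pop(gi)
        if event.destination is None:
            raise EventError("TRANSPOSITION requires a destination chromosome")
        dest = new.chromosome(event.destination)
        if dest is None:
            dest = Chromosome(name=event.destination)
            new.chromosomes.append(dest)
        dest.genes.append(moved)
        return new

    # TANDEM_DUP / DUP_TRANSPOSITION
    template = _require_alive(new, event.target)
    ci, gi = new.find(event.target)
    new_id = event.new_id or f"{template.id}-d{ordinal}"
    new_origin = event.new_origin or template.origin
    child = GeneCopy(id=new_id, origin=new_origin)
    if et == TANDEM_DUP:
        new.chromosomes[ci].genes.insert(gi + 1, child)
    else:  # DUP_TRANSPOSITION
        dest_name = event.destination
        if dest_name is None:
            raise EventError("DUP_TRANSPOSITION requires a destination chromosome")
        dest = new.chromosome(dest_name)
        if dest is None:
            dest = Chromosome(name=dest_name)
            new.chromosomes.append(dest)
        dest.genes.append(child)
    if _recorder:
        _recorder.copy(template.id, new_id, new_origin, et, _branch, ordinal)
    if event.relabel_target_id or event.relabel_target_origin:
        old_id = template.id
        if event.relabel_target_id:
            template.id = event.relabel_target_id
        if event.relabel_target_origin:
            template.origin = event.relabel_target_origin
        if _recorder:
            _recorder.rename(old_id, template.id, template.origin, et, _branch, ordinal)
    new.validate()
    return new


# Replay ----------------------------------------------------------------------


def _branch_event_groups(script: EventScript) -> dict[str, list[tuple[int, EvolutionaryEvent]]]:
    groups: dict[str, list[tuple[int, EvolutionaryEvent]]] = {}
    for ordinal, (branch, event) in enumerate(script.events):
        groups.setdefault(branch, []).append((ordinal, event))
    return groups


def _apply_branch(state: GenomeState, branch: str,
                  events: list[tuple[int, EvolutionaryEvent]],
                  recorder: Optional[_GenealogyRecorder]) -> GenomeState:
    for ordinal, event in events:
        try:
            state = apply_event(state, event, ordinal=ordinal,
                                _recorder=recorder, _branch=branch)
        except (UnknownGeneError, EventError) as exc:
            raise ReplayError(
                f"branch {branch!r}, event #{ordinal} ({event.type}): {exc}") from exc
    state.lineage_label = branch
    return state


def _replay(script: EventScript, species_tree=None,
            recorder: Optional[_GenealogyRecorder] = None) -> dict[str, GenomeState]:
    script.initial_state.validate()
    groups = _branch_event_groups(script)
    states: dict[str, GenomeState] = {
        script.initial_state.lineage_label: script.initial_state.clone()
    }

    if species_tree is None:
        # Linear chain: branches in order of first appearance.
        state = script.initial_state
        for branch in script.branches():
            state = _apply_branch(state, branch, groups[branch], recorder)
            states[branch] = state
        return states

    # Tree replay: branch labels name child nodes of the species tree.
    tree = getattr(species_tree, "tree", species_tree)  # accept a wrapper
    labels: set[str] = set()

    def node_label(node) -> Optional[str]:
        if node.taxon is not None:
            return node.taxon.label
        return node.label

    for node in tree.preorder_node_iter():
        lbl = node_label(node)
        if lbl:
            labels.add(lbl)
    missing = set(groups) - labels
    if missing:
        raise TreeError(
            f"event branches not found in species tree: {sorted(missing)}")

    def visit(node, state: GenomeState) -> None:
        lbl = node_label(node)
        if lbl in groups:
            state = _apply_branch(state, lbl, groups[lbl], recorder)
        elif lbl:
            state = state.clone()
            state.lineage_label = lbl
        if lbl:
            states[lbl] = state
        for child in node.child_nodes():
            visit(child, state)

    visit(tree.seed_node, script.initial_state)
    return states


def replay_script(script: EventScript, species_tree=None) -> dict[str, GenomeState]:
    """Replay a script, returning the genome state at every named lineage.

    Without a species tree the branch labels form a linear chain in
    order of first appearance and each label maps to the state after all
    its events.  With a tree, branch labels must name tree nodes and a
    node's state reflects all events on its root-to-node path, in listed
    order within each branch.
    """
    return _replay(script, species_tree=species_tree, recorder=None)


def count_genes(state: GenomeState, by_origin: bool = False):
    """Count alive genes, optionally grouped by ancestral-class prefix."""
    if not by_origin:
        return sum(1 for _ in state.iter_genes(alive_only=True))
    out: dict[str, int] = {}
    for gene in state.iter_genes(alive_only=True):
        cls = ancestral_class(gene.origin)
        out[cls] = out.get(cls, 0) + 1
    return out


def derivation_genealogy(script: EventScript, species_tree=None) -> nx.DiGraph:
    """Build the gene derivation genealogy implied by a script.

    Nodes are gene ids (ancestral and extant); edges run parent -> child
    for every copy created by a duplication-type event, plus identity
    edges where an event renamed a gene.  Lost genes remain in the graph
    flagged ``alive=False``.  Roots (in-degree 0) are exactly the
    initial-state genes.
    """
    recorder = _GenealogyRecorder(script.initial_state)
    _replay(script, species_tree=species_tree, recorder=recorder)
    return recorder.graph


def trace_to_root(genealogy: nx.DiGraph, gene_id: str) -> str:
    """Follow derivation edges upward to the unique root-era gene."""
    node = gene_id
    while True:
        preds = list(genealogy.predecessors(node))
        if not preds:
            return node
        if len(preds) > 1:  # pragma: no cover - structure guarantees a tree
            raise ReplayError(f"gene {gene_id!r} has multiple derivation parents")
        node = preds[0]


def trace_to_class(genealogy: nx.DiGraph, gene_id: str) -> str:
    """Ancestral class (V11/V12/V21/V22...) of the lineage a gene derives from.

    Walks up the genealogy and returns the first origin label that
    resolves to a ``V``-class prefix; falls back to the root's class.
    """
    node = gene_id
    while True:
        origin = genealogy.nodes[node].get("origin", node)
        cls = ancestral_class(origin)
        if _V_CLASS_RE.match(cls):
            return cls
        preds = list(genealogy.predecessors(node))
        if not preds:
            return cls
        node = preds[0]
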