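"""File formats: Newick trees, TSV tables, event-script JSON, network export.

Conventions: TSV throughout (gene symbols never contain tabs), UTF-8,
Unix newlines on write and tolerant reads.  Synteny coordinates are
signed neighbor offsets (-k..+k), never base positions, so 0/1-based
genome-coordinate ambiguity does not arise.  Lines starting with ``#``
are treated as comments on read; pipeline outputs carry the run's
config hash in such a header line.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Optional

import dendropy
import networkx as nx
import pandas as pd
import yaml

from .errors import FormatError
from .genome import EventScript, GenomeState, count_genes
from .functions import FeatureAnnotation
from .network import CorrelationNetwork, ExpressionMatrix
from .orthogroups import SyntenyRecord
from .parsimony import Reconstruction, SpeciesTree

# Trees -----------------------------------------------------------------------


def read_newick(path) -> dendropy.Tree:
    """Parse a Newick tree; numeric internal node labels are supports (%)."""
    text = Path(path).read_text().strip()
    if not text:
        raise FormatError(f"{path}: empty Newick file")
    try:
        return dendropy.Tree.get(data=text, schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"{path}: Newick parse error: {exc}") from exc


def write_newick(tree: dendropy.Tree, path) -> None:
    Path(path).write_text(
        tree.as_string(schema="newick", suppress_rooting=True,
                       unquoted_underscores=True))


def read_species_tree(tree_path, events_path=None) -> SpeciesTree:
    """Species tree plus optional polyploidy sidecar TSV.

    The sidecar columns are ``branch`` (child-node label), ``event``
    (WGD or WGT) and ``order``; multiple rows per branch apply in order.
    """
    tree = read_newick(tree_path)
    polyploidy: dict[str, list[str]] = {}
    if events_path is not None:
        tab = read_tsv(events_path, required=("branch", "event"))
        if "order" in tab.columns:
            tab = tab.sort_values(["branch", "order"])
        for _, row in tab.iterrows():
            polyploidy.setdefault(str(row["branch"]), []).append(str(row["event"]))
    return SpeciesTree(tree=tree, polyploidy=polyploidy)


# Tabular ---------------------------------------------------------------------


def read_tsv(path, required: tuple[str, ...] = ()) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: ragged or malformed TSV: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def read_matrix_tsv(path, kind: str = "counts",
                    immune_path=None):
    """Read a matrix TSV (header row, first column = row ids).

    ``kind="counts"`` validates non-negative integers and returns a
    DataFrame; ``kind="expression"`` validates non-negative reals and
    returns an :class:`ExpressionMatrix` (the optional immune sidecar
    TSV has columns ``cell_type`` and ``immune`` with 0/1 flags).
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: ragged or malformed TSV: {exc}") from exc
    if df.isna().any().any():
        cell = df.stack(future_stack=True)
        bad = cell[cell.isna()].index[0]
        raise FormatError(f"{path}: missing value at row {bad[0]!r}, "
                          f"column {bad[1]!r}")
    if kind == "counts":
        as_float = df.astype(float)
        if ((as_float % 1) != 0).any().any() or (as_float < 0).any().any():
            stacked = as_float.stack()
            bad = stacked[(stacked % 1 != 0) | (stacked < 0)].index[0]
            raise FormatError(f"{path}: counts must be non-negative integers; "
                              f"offending cell row {bad[0]!r}, column {bad[1]!r}")
        return as_float.astype(int)
    if kind == "expression":
        vals = df.astype(float)
        if (vals.values < 0).any():
            stacked = vals.stack()
            bad = stacked[stacked < 0].index[0]
            raise FormatError(f"{path}: negative expression at row {bad[0]!r}, "
                              f"column {bad[1]!r}")
        immune: frozenset[str] = frozenset()
        if immune_path is not None:
            tab = read_tsv(immune_path, required=("cell_type", "immune"))
            immune = frozenset(
                str(r["cell_type"]) for _, r in tab.iterrows()
                if str(r["immune"]) in ("1", "true", "True"))
        return ExpressionMatrix(values=vals, immune_types=immune)
    raise FormatError(f"unknown matrix kind {kind!r}")


def write_matrix_tsv(df: pd.DataFrame, path, header_comment: Optional[str] = None
                     ) -> None:
    with open(path, "w", newline="\n") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t")


# Synteny ---------------------------------------------------------------------


def read_synteny_tsv(path) -> list[SyntenyRecord]:
    """Columns: gene, species, chromosome, offset, neighbor_symbol,
    human_chromosome; one row per neighbor slot."""
    tab = read_tsv(path, required=("gene", "species", "chromosome", "offset",
                                   "neighbor_symbol", "human_chromosome"))
    records: dict[str, SyntenyRecord] = {}
    for _, row in tab.iterrows():
        gene = str(row["gene"])
        rec = records.setdefault(gene, SyntenyRecord(
            gene=gene, species=str(row["species"]),
            chromosome=str(row["chromosome"])))
        off = int(row["offset"])
        if off == 0 or off in rec.neighbors:
            raise FormatError(f"{path}: bad or duplicate offset {off} for "
                              f"gene {gene!r}")
        rec.neighbors[off] = (str(row["neighbor_symbol"]),
                              str(row["human_chromosome"]))
    return list(records.values())


def write_synteny_tsv(records: list[SyntenyRecord], path) -> None:
    rows = []
    for rec in records:
        for off in sorted(rec.neighbors):
            sym, hc = rec.neighbors[off]
            rows.append({"gene": rec.gene, "species": rec.species,
                         "chromosome": rec.chromosome, "offset": off,
                         "neighbor_symbol": sym, "human_chromosome": hc})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# Annotations -----------------------------------------------------------------


def read_annotations(features_path=None, receptors_path=None) -> FeatureAnnotation:
    """Feature TSV: columns gene, feature. Receptor TSV: gene, receptor."""
    ann = FeatureAnnotation()
    if features_path is not None:
        tab = read_tsv(features_path, required=("gene", "feature"))
        for _, row in tab.iterrows():
            ann.features.setdefault(str(row["gene"]), set()).add(str(row["feature"]))
    if receptors_path is not None:
        tab = read_tsv(receptors_path, required=("gene", "receptor"))
        for _, row in tab.iterrows():
            ann.receptors.setdefault(str(row["gene"]), set()).add(str(row["receptor"]))
    return ann


# Networks --------------------------------------------------------------------


def write_network(net: CorrelationNetwork, edge_path, graphml_path=None) -> None:
    rows = []
    for a, b, data in net.graph.edges(data=True):
        row = {"gene_a": a, "gene_b": b}
        for key in ("rho", "p", "q"):
            if key in data:
                row[key] = data[key]
        if "shared_types" in data:
            row["shared_types"] = ",".join(data["shared_types"])
        rows.append(row)
    pd.DataFrame(rows).to_csv(edge_path, sep="\t", index=False)
    if graphml_path is not None:
        g = net.graph.copy()
        for _, data in g.nodes(data=True):
            for k, v in list(data.items()):
                if v is None:
                    data[k] = ""
        for _, _, data in g.edges(data=True):
            for k, v in list(data.items()):
                if isinstance(v, list):
                    data[k] = ",".join(map(str, v))
        nx.write_graphml(g, graphml_path)


# Replay reports --------------------------------------------------------------


def write_replay_tsv(states: dict[str, GenomeState], path,
                     header_comment: Optional[str] = None) -> None:
    rows = []
    for lineage, state in states.items():
        for chrom in state.chromosomes:
            alive = [g.id for g in chrom.genes if g.alive]
            if not alive:
                continue
            rows.append({"lineage": lineage, "chromosome": chrom.name,
                         "genes": ",".join(alive), "n_genes": len(alive)})
        rows.append({"lineage": lineage, "chromosome": "*total*",
                     "genes": "", "n_genes": count_genes(state)})
    with open(path, "w", newline="\n") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)


def write_reconstruction(rec: Reconstruction, out_dir,
                         header_comment: Optional[str] = None) -> None:
    out_dir = Path(out_dir)
    write_matrix_tsv(rec.node_counts, out_dir / "ancestral_counts.tsv",
                     header_comment=header_comment)
    rows = [{"orthogroup": t.orthogroup, "branch": t.branch,
             "parent_count": t.parent_count, "child_count": t.child_count,
             "duplications": t.duplications, "losses": t.losses,
             "phases": json.dumps(t.phases)}
            for t in rec.branch_tallies]
    with open(out_dir / "branch_events.tsv", "w", newline="\n") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)


# Pipeline --------------------------------------------------------------------


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: pipeline config must be a mapping")
    return cfg


def run_pipeline(cfg: dict, out_dir) -> Path:
    """Run orthogroup calling, ancestral classification, parsimony, and the
    optional function-inference and network stages.

    ``cfg`` keys (all paths): gene_tree, synteny, counts, species_tree,
    polyploidy_events, expression, immune_types, features, receptors,
    genealogy_script; thresholds: support_threshold, alpha, top_k,
    min_shared, min_shared_neighbors, max_count; species sets:
    chondrichthyans, osteichthyans; seed.  Stages whose inputs are
    absent are skipped; any stage error aborts with the stage name.
    """
    from . import functions as fn
    from . import genome, network
    from . import orthogroups as og
    from . import parsimony as pars

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    digest = config_hash(cfg)
    log: dict = {"config_hash": digest, "seed": cfg.get("seed", 0),
                 "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
                 "stages": {}}
    comment = f"config_hash={digest}"
    stage = "setup"
    try:
        if "gene_tree" in cfg:
            stage = "orthogroups"
            tree = read_newick(cfg["gene_tree"])
            synteny = read_synteny_tsv(cfg["synteny"]) if "synteny" in cfg else []
            scfg = og.SyntenyConfig(
                min_shared=int(cfg.get("min_shared_neighbors", 1)))
            grp, unassigned = og.call_orthogroups(
                tree, synteny, scfg,
                threshold=float(cfg.get("support_threshold", 95)),
                midpoint=bool(cfg.get("midpoint_root", False)),
                outgroup=cfg.get("outgroup"))
            if "chondrichthyans" in cfg and "osteichthyans" in cfg:
                og.classify_ancestral(grp, set(cfg["chondrichthyans"]),
                                      set(cfg["osteichthyans"]))
            rows = [{"orthogroup": x.name, "n_members": len(x.members),
                     "ancestral": x.ancestral,
                     "members": ",".join(sorted(x.members))} for x in grp]
            with open(out / "orthogroups.tsv", "w", newline="\n") as fh:
                fh.write(f"# {comment}\n")
                pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)
            (out / "unassigned.tsv").write_text(
                f"# {comment}\n" + "\n".join(unassigned) + "\n")
            log["stages"][stage] = {"n_orthogroups": len(grp),
                                    "n_unassigned": len(unassigned)}

        if "counts" in cfg and "species_tree" in cfg:
            stage = "parsimony"
            stree = read_species_tree(cfg["species_tree"],
                                      cfg.get("polyploidy_events"))
            counts = read_matrix_tsv(cfg["counts"], kind="counts")
            rec = pars.reconstruct(stree, counts,
                                   max_count=cfg.get("max_count"),
                                   root_count=cfg.get("root_count"))
            write_reconstruction(rec, out, header_comment=comment)
            log["stages"][stage] = {"total_cost": rec.total_cost}

        if "genealogy_script" in cfg and ("features" in cfg or "receptors" in cfg):
            stage = "functions"
            script = EventScript.from_json(cfg["genealogy_script"])
            genealogy = genome.derivation_genealogy(script)
            ann = read_annotations(cfg.get("features"), cfg.get("receptors"))
            fmap = fn.infer_ancestral_features(genealogy, ann)
            rows = [{"node": node, "feature": f, "rule": fmap.rules[node][f]}
                    for node in sorted(fmap.presence)
                    for f in sorted(fmap.presence[node])]
            with open(out / "ancestral_features.tsv", "w", newline="\n") as fh:
                fh.write(f"# {comment}\n")
                pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)
            reports = fn.shared_receptor_ancestry(genealogy, ann)
            pd.DataFrame([r.__dict__ for r in reports]).to_csv(
                out / "receptor_ancestry.tsv", sep="\t", index=False)
            log["stages"][stage] = {"n_inferred_nodes": len(fmap.presence)}

        if "expression" in cfg:
            stage = "network"
            expr = read_matrix_tsv(cfg["expression"], kind="expression",
                                   immune_path=cfg.get("immune_types"))
            ncfg = network.NetworkConfig(
                alpha=float(cfg.get("alpha", 0.05)),
                top_k=int(cfg.get("top_k", 10)),
                min_shared=int(cfg.get("min_shared", 3)),
                immune_n=len(expr.immune_types) or 11)
            net = network.correlation_network(expr, ncfg)
            write_network(net, out / "correlation_edges.tsv",
                          out / "correlation_network.graphml")
            onet = network.overlap_network(expr, ncfg)
            write_network(onet, out / "overlap_edges.tsv",
                          out / "overlap_network.graphml")
            result = {"n_correlation_links": net.graph.number_of_edges(),
                      "n_overlap_links": onet.graph.number_of_edges()}
            if bool(cfg.get("exclude_immune", False)):
                net2 = network.correlation_network(
                    expr, ncfg, exclude_cell_types=set(expr.immune_types))
                write_network(net2, out / "correlation_edges_noimmune.tsv")
                result["n_links_excluding_immune"] = net2.graph.number_of_edges()
            log["stages"][stage] = result
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"pipeline stage {stage!r} failed: {exc}") from exc

    log["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "run_log.json").write_text(json.dumps(log, indent=1, default=str) + "\n")
    return out
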