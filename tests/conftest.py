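"""Shared fixtures and independent reference implementations (oracles)."""

from __future__ import annotations

import numpy as np
import pytest

import tnfevol as t


@pytest.fixture(scope="session")
def fixtures():
    return t.packaged_fixtures()


@pytest.fixture(scope="session")
def human_states(fixtures):
    return t.replay_script(fixtures["gnathostome_human"])


@pytest.fixture(scope="session")
def human_genealogy(fixtures):
    return t.derivation_genealogy(fixtures["gnathostome_human"])


@pytest.fixture(scope="session")
def small_truth():
    cfg = t.SimulationConfig(
        species_tree_newick="((A,B)ab,(C,D)cd)root;",
        n_families=6, dup_rate=0.15, loss_rate=0.15, seed=11)
    return t.simulate_family_evolution(cfg)


# ---------------------------------------------------------------------------
# Independent oracles (deliberately naive, separate from the implementations)
# ---------------------------------------------------------------------------


def naive_spearman(x, y) -> float:
    """Pearson correlation of mid-ranked data, ranks computed by hand."""
    def midranks(v):
        v = np.asarray(v, float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks
    rx, ry = midranks(x), midranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx ** 2).sum() * (ry ** 2).sum()))


def naive_bh(pvals):
    """Textbook Benjamini-Hochberg step-up with monotone enforcement."""
    p = np.asarray(pvals, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank_from_top in range(n, 0, -1):
        idx = order[rank_from_top - 1]
        running = min(running, p[idx] * n / rank_from_top)
        adj[idx] = running
    return np.minimum(adj, 1.0)


def dollo_presence_oracle(genealogy, annotated):
    """Minimal single-gain presence set: all nodes on a path from the
    annotated genes' most recent common ancestor down to an annotated gene.

    Computed from explicit ancestor chains, independently of the
    package's bottom-up/top-down inference pass.
    """
    import networkx as nx

    annotated = [a for a in annotated if a in genealogy]
    if not annotated:
        return set()

    def chain(node):
        out = [node]
        while True:
            preds = list(genealogy.predecessors(out[-1]))
            if not preds:
                return out
            out.append(preds[0])

    chains = [chain(a) for a in annotated]
    common = set(chains[0])
    for c in chains[1:]:
        common &= set(c)
    if not common:
        # annotated genes sit under different roots: union of per-root spans
        by_root = {}
        for a, c in zip(annotated, chains):
            by_root.setdefault(c[-1], []).append(a)
        out = set()
        for members in by_root.values():
            out |= dollo_presence_oracle(genealogy, members)
        return out
    # MRCA = deepest common ancestor = first common node on any chain
    mrca = next(node for node in chains[0] if node in common)
    present = set()
    for c in chains:
        for node in c:
            present.add(node)
            if node == mrca:
                break
    return present


@pytest.fixture(scope="session")
def oracles():
    return {
        "spearman": naive_spearman,
        "bh": naive_bh,
        "dollo": dollo_presence_oracle,
    }


def random_genealogy(rng, n_leaves):
    """A random rooted derivation forest with the given number of leaves."""
    import networkx as nx

    g = nx.DiGraph()
    g.add_node("g0", origin="g0", alive=True)
    nodes = ["g0"]
    i = 1
    while sum(1 for n in g if g.out_degree(n) == 0) < n_leaves:
        parent = nodes[int(rng.integers(0, len(nodes)))]
        child = f"g{i}"
        g.add_node(child, origin=child, alive=True)
        g.add_edge(parent, child, kind="copy")
        nodes.append(child)
        i += 1
    return g
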