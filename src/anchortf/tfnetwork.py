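"""TF target-network merging, one-level expansion, and core/shell ranking.

Hit-TF target gene sets are merged into one undirected graph, expanded a
single level by pulling in external regulators with multi-evidence links,
and stratified by connectivity (degree): nodes are sorted by degree and
split into equal-frequency shells, shell 1 being the network core.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, NamedTuple, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .cooccupancy import motif_enrichment


def merge_networks(sets: Mapping[str, Iterable[str]]) -> nx.Graph:
    """Merge TF -> target sets into one undirected graph.

    Seed TFs get ``is_seed=True``; duplicate edges collapse and self-loops
    are dropped.
    """
    if not sets:
        raise ValueError("need at least one TF target set")
    g = nx.Graph()
    for tf, targets in sets.items():
        targets = set(targets)
        if not targets:
            raise ValueError(f"TF {tf!r} has an empty target set")
        g.add_node(tf)
        for t in targets:
            if t == tf:
                continue
            g.add_node(t)
            g.add_edge(tf, t)
    nx.set_node_attributes(g, False, "is_seed")
    nx.set_node_attributes(g, False, "added_by_expansion")
    for tf in sets:
        g.nodes[tf]["is_seed"] = True
    return g


def expand_network(
    net: nx.Graph,
    interactions: Sequence[tuple[str, str]],
    min_links: int = 2,
) -> nx.Graph:
    """One-level expansion: add external nodes with >= min_links distinct
    interaction edges into the current node set (no recursion)."""
    if min_links < 1:
        raise ValueError("min_links must be >= 1")
    g = net.copy()
    current = set(net.nodes)
    links: dict[str, set[str]] = {}
    for a, b in interactions:
        if a == b:
            continue
        for ext, inside in ((a, b), (b, a)):
            if ext not in current and inside in current:
                links.setdefault(ext, set()).add(inside)
    for ext, partners in sorted(links.items()):
        if len(partners) >= min_links:
            g.add_node(ext, is_seed=False, added_by_expansion=True)
            for p in sorted(partners):
                g.add_edge(ext, p)
    return g


class ShellRanking(NamedTuple):
    graph: nx.Graph
    shells: dict[str, int]
    core_report: dict[str, bool]


def rank_shells(
    net: nx.Graph,
    n_shells: int = 4,
    query_tfs: Sequence[str] = (),
) -> ShellRanking:
    """Partition nodes into equal-frequency connectivity shells.

    Nodes sort by degree descending (ties by id ascending) and split into
    ``n_shells`` near-equal bins; shell 1 holds the highest-degree nodes.
    ``core_report`` says whether each query TF (e.g. the anchor) landed in
    shell 1.
    """
    if n_shells < 2:
        raise ValueError("n_shells must be >= 2")
    nodes = sorted(net.nodes, key=lambda v: (-net.degree(v), str(v)))
    if len(nodes) < n_shells:
        warnings.warn("fewer nodes than shells; shells collapse")
    g = net.copy()
    shells: dict[str, int] = {}
    bins = [b for b in np.array_split(np.array(nodes, dtype=object), n_shells) if len(b)]
    for shell_no, members in enumerate(bins, start=1):
        for v in members:
            shells[v] = shell_no
            g.nodes[v]["shell"] = shell_no
    nx.set_node_attributes(g, dict(g.degree), "connectivity")
    core = {tf: shells.get(tf, 0) == 1 for tf in query_tfs}
    return ShellRanking(g, shells, core)


def node_table(net: nx.Graph) -> pd.DataFrame:
    """Node TSV shape: node, degree, shell, added_by_expansion, is_seed."""
    rows = [
        {
            "node": v,
            "degree": net.degree(v),
            "shell": net.nodes[v].get("shell", 0),
            "added_by_expansion": net.nodes[v].get("added_by_expansion", False),
            "is_seed": net.nodes[v].get("is_seed", False),
        }
        for v in sorted(net.nodes, key=str)
    ]
    return pd.DataFrame(rows).sort_values(
        ["shell", "degree", "node"], ascending=[True, False, True], ignore_index=True
    )


def subnetwork_motif_enrichment(
    subnetwork_genes: Iterable[str],
    promoters: Mapping[str, Mapping],
    motifs: Sequence,
    rel_threshold: float = 0.9,
    min_ic: float = 8.0,
    seed: int | None = 0,
    min_batch: int = 3,
) -> pd.DataFrame | None:
    """Per-functional-subnetwork motif enrichment of member promoters.

    Delegates to the un-anchored enrichment (batch promoters vs shuffled
    background) and returns the per-TF z ranking; batches below
    ``min_batch`` genes are skipped with a warning.
    """
    genes = [g for g in subnetwork_genes if g in promoters]
    if len(genes) < min_batch:
        warnings.warn(f"batch of {len(genes)} genes (<{min_batch}); skipped")
        return None
    seqs = {g: promoters[g]["seq"] for g in genes}
    return motif_enrichment(seqs, motifs, rel_threshold, min_ic, seed)
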