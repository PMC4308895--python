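"""Seed-gene subnetwork extraction, community detection, and hub genes.

Given a background undirected gene-interaction network and a set of seed
genes (e.g. the consensus list of differentially variable genes), the
analysis subnetwork is the subgraph induced on the seeds and their direct
neighbors, pruned of weakly connected nodes: nodes with degree below a
minimum (default 2) are removed, by default iteratively until the minimum
degree is satisfied everywhere (a k-core-style fixpoint; a single pruning
pass is available as an alternative). Communities are found with the
Louvain modularity heuristic and hub genes are reported by degree.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import networkx as nx
import pandas as pd

from .errors import ValidationError

__all__ = [
    "CommunityPartition",
    "read_edge_list",
    "write_edge_list",
    "extract_seed_subnetwork",
    "detect_communities",
    "hub_genes",
    "write_partition",
]

logger = logging.getLogger(__name__)


@dataclass
class CommunityPartition:
    """Node → community assignment with the partition's modularity."""

    assignment: dict[str, int]
    modularity: float

    def communities(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for node, cid in self.assignment.items():
            out.setdefault(cid, set()).add(node)
        return out


def _validate_graph(g: nx.Graph) -> nx.Graph:
    if any(u == v for u, v in g.edges):
        raise ValidationError("network contains self-loops")
    return g


def read_edge_list(path) -> nx.Graph:
    """Read an undirected network from a two-column TSV edge list.

    Duplicate edges collapse; self-loops are rejected.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] != 2:
        raise ValidationError(f"{path}: expected 2 columns, got {df.shape[1]}")
    g = nx.Graph()
    g.add_edges_from(df.itertuples(index=False, name=None))
    return _validate_graph(g)


def write_edge_list(g: nx.Graph, path) -> None:
    """Write edges as sorted two-column TSV (deterministic)."""
    edges = sorted(tuple(sorted(e)) for e in g.edges)
    with open(path, "w") as fh:
        for u, v in edges:
            fh.write(f"{u}\t{v}\n")


def extract_seed_subnetwork(net: nx.Graph, seeds, min_degree: int = 2,
                            single_pass: bool = False) -> nx.Graph:
    """Subgraph on seeds plus direct neighbors, pruned of low-degree nodes.

    Nodes with degree < ``min_degree`` in the induced subgraph are removed;
    by default removal is repeated until no such node remains, with
    ``single_pass`` only one round is applied. Seeds absent from the
    network are counted in a log message; if none maps, an error reports
    0/len(seeds).
    """
    _validate_graph(net)
    seeds = set(seeds)
    present = seeds & set(net.nodes)
    if not present:
        raise ValidationError(f"0/{len(seeds)} seed genes map to the network")
    if len(present) < len(seeds):
        logger.info("%d/%d seed genes absent from the network",
                    len(seeds) - len(present), len(seeds))
    nodes = set(present)
    for s in present:
        nodes.update(net.neighbors(s))
    sub = net.subgraph(nodes).copy()
    while True:
        low = [n for n, d in sub.degree if d < min_degree]
        if not low:
            break
        sub.remove_nodes_from(low)
        if single_pass:
            break
    return sub


def detect_communities(net: nx.Graph, resolution: float = 1.0,
                       seed: int = 0) -> CommunityPartition:
    """Louvain community detection, deterministic for a given seed.

    An edgeless graph yields one singleton community per node with
    modularity 0. Community ids are relabeled by decreasing size (ties by
    smallest member) so the labeling is stable.
    """
    if net.number_of_nodes() == 0:
        raise ValidationError("cannot detect communities on an empty graph")
    if net.number_of_edges() == 0:
        return CommunityPartition(
            assignment={n: i for i, n in enumerate(sorted(net.nodes))},
            modularity=0.0)
    # canonicalize node/edge insertion order so the partition depends only
    # on the graph's content, not on how it was built
    canon = nx.Graph()
    canon.add_nodes_from(sorted(net.nodes))
    canon.add_edges_from(sorted(tuple(sorted(e)) for e in net.edges))
    comms = nx.community.louvain_communities(canon, resolution=resolution,
                                             seed=seed)
    comms = sorted(comms, key=lambda c: (-len(c), min(c)))
    assignment = {n: i for i, c in enumerate(comms) for n in c}
    mod = nx.community.modularity(net, comms, resolution=resolution)
    return CommunityPartition(assignment=assignment, modularity=float(mod))


def hub_genes(net: nx.Graph, min_degree: int = 35) -> pd.DataFrame:
    """Nodes with degree >= min_degree, ordered by degree desc then id."""
    if net.number_of_nodes() == 0:
        raise ValidationError("empty network")
    rows = [(n, d) for n, d in net.degree if d >= min_degree]
    rows.sort(key=lambda r: (-r[1], r[0]))
    return pd.DataFrame(rows, columns=["gene_id", "degree"]).set_index("gene_id")


def write_partition(partition: CommunityPartition, path) -> None:
    """Write node<TAB>community TSV, sorted by node id."""
    with open(path, "w") as fh:
        for node in sorted(partition.assignment):
            fh.write(f"{node}\t{partition.assignment[node]}\n")
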