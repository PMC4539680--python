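"""Functional-interaction network analysis.

The interaction network is an undirected simple graph over gene/protein
ids.  The analysis subnetwork for one cancer keeps the selected proteins,
all proteins with harmful AASs, and their first neighbours.  The average
degree of a node set is

    D_n = (2 * E_n + E_other) / n

with E_n the edges internal to the set (counted twice, once per incident
endpoint) and E_other the edges with exactly one endpoint in the set; for
the whole network E_other = 0 and D reduces to 2|E|/|V|.  E_n and E_other
are evaluated against the full network, matching how the overall degree
is computed before any node elimination; pass the reduced graph instead
to evaluate within it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping

import networkx as nx
import pandas as pd
from networkx.algorithms.community import greedy_modularity_communities

log = logging.getLogger(__name__)


class NetworkError(ValueError):
    pass


def load_sif(path) -> nx.Graph:
    """Read a SIF / 2-column edge list into a simple undirected graph.

    Self-loops and duplicate edges are dropped with a logged count.
    Lines are ``a<TAB>b`` or ``a<TAB>relation<TAB>b``.
    """
    g = nx.Graph()
    n_self = n_dup = 0
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0]:
                continue
            a, b = (parts[0], parts[2]) if len(parts) >= 3 else (parts[0], parts[1])
            if a == b:
                n_self += 1
                continue
            if g.has_edge(a, b):
                n_dup += 1
                continue
            g.add_edge(a, b)
    if n_self or n_dup:
        log.info("dropped %d self-loops, %d duplicate edges", n_self, n_dup)
    return g


@dataclass
class DegreeSummary:
    n: int
    e_n: int
    e_other: int

    @property
    def average_degree(self) -> float:
        return (2 * self.e_n + self.e_other) / self.n


def degree_from_counts(n: int, e_n: int, e_other: int = 0) -> float:
    """Average degree straight from node/edge tallies: (2 E_n + E_other)/n."""
    if n <= 0:
        raise NetworkError("node count must be positive")
    return DegreeSummary(n=n, e_n=e_n, e_other=e_other).average_degree


def average_degree(subset: Iterable[Hashable], network: nx.Graph) -> DegreeSummary:
    """Average degree of a node set, edges counted on the given network."""
    nodes = set(subset) & set(network.nodes)
    if not nodes:
        raise NetworkError("empty node subset")
    e_n = e_other = 0
    for u, v in network.edges(nodes):
        if u in nodes and v in nodes:
            e_n += 1
        else:
            e_other += 1
    # networkx yields internal edges once per endpoint iteration order;
    # Graph.edges(nbunch) already deduplicates, so e_n is per unordered pair
    return DegreeSummary(n=len(nodes), e_n=e_n, e_other=e_other)


def reduce_network(
    network: nx.Graph,
    selected: Iterable[Hashable],
    harmful: Iterable[Hashable],
) -> nx.Graph:
    """Subnetwork of selected + harmful proteins and their first neighbours.

    Ids absent from the network are dropped with a logged count.  Returns
    the induced subgraph (copied).
    """
    selected, harmful = set(selected), set(harmful)
    core = selected | harmful
    missing = core - set(network.nodes)
    if missing:
        log.info("%d proteins not present in the network", len(missing))
    core &= set(network.nodes)
    keep = set(core)
    for node in core:
        keep.update(network.neighbors(node))
    if not keep:
        log.warning("reduced network is empty")
    return network.subgraph(keep).copy()


def cluster_modules(network: nx.Graph, seed: int = 0) -> dict[Hashable, int]:
    """Assign every node to a module by greedy modularity maximization.

    Stands in for the unspecified clustering of the original interaction
    tooling; deterministic for a given graph (module ids ordered by size,
    then smallest member).  Isolated graphs yield singleton modules.
    """
    if network.number_of_nodes() == 0:
        raise NetworkError("empty graph")
    if network.number_of_edges() == 0:
        comms = [{n} for n in network.nodes]
    else:
        comms = [set(c) for c in greedy_modularity_communities(network)]
    comms.sort(key=lambda c: (-len(c), min(map(str, c))))
    return {node: i for i, comm in enumerate(comms) for node in comm}


def cancer_overlap(
    significant_pathways: Mapping[str, Iterable[str]],
    selected_proteins: Mapping[str, Iterable[str]],
    split_cutoff: int = 20,
) -> tuple[nx.Graph, nx.Graph]:
    """Cross-cancer overlap networks, split at > ``split_cutoff`` selected.

    Nodes are cancer types with attributes n_pathways / n_selected; an
    edge exists iff two cancers share at least one significantly enriched
    pathway, weighted by the number shared, with the shared selected
    proteins as a second attribute.  Returns (many-selected network,
    few-selected network).
    """
    if len(significant_pathways) < 2:
        raise NetworkError("need at least two cancers")
    paths = {c: set(v) for c, v in significant_pathways.items()}
    prots = {c: set(selected_proteins.get(c, ())) for c in paths}

    def build(cancers: list[str]) -> nx.Graph:
        g = nx.Graph()
        for c in cancers:
            g.add_node(c, n_pathways=len(paths[c]), n_selected=len(prots[c]))
        for i, a in enumerate(cancers):
            for b in cancers[i + 1 :]:
                common_p = paths[a] & paths[b]
                if common_p:
                    g.add_edge(
                        a,
                        b,
                        n_common_pathways=len(common_p),
                        n_common_proteins=len(prots[a] & prots[b]),
                    )
        return g

    many = sorted(c for c in paths if len(prots[c]) > split_cutoff)
    few = sorted(c for c in paths if len(prots[c]) <= split_cutoff)
    return build(many), build(few)


def degree_table(summaries: Mapping[str, DegreeSummary]) -> pd.DataFrame:
    rows = [
        (name, s.n, s.e_n, s.e_other, s.average_degree)
        for name, s in summaries.items()
    ]
    return pd.DataFrame(
        rows, columns=["node_set", "n", "e_n", "e_other", "average_degree"]
    )
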