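"""Hypergeometric gene-set enrichment with Benjamini-Hochberg FDR.

Classic one-sided overrepresentation: for a query of n genes from a
universe of N, a set with K members and k query hits gets the upper-tail
hypergeometric probability P[X >= k].  Correction is BH step-up within
each tested family.  The query-selection policy mirrors the cohort
analysis: cancers with fewer than 20 selected proteins use all genes
carrying at least one harmful AAS as the query with a GO significance
tier of FDR < 0.01; other cancers use the selected genes with a GO tier
of FDR < 0.001.  Pathway enrichment uses FDR < 0.05 in both groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


class EnrichmentError(ValueError):
    pass


@dataclass
class GeneSetCollection:
    """Named gene sets over a fixed universe.

    The universe defaults to the union of all set members, matching the
    convention of annotation-driven enrichment tools.
    """

    sets: dict[str, frozenset[str]]
    universe: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        self.sets = {k: frozenset(v) for k, v in self.sets.items()}
        for name, members in self.sets.items():
            if not members:
                raise EnrichmentError(f"gene set {name!r} is empty")
        if not self.universe:
            u: set[str] = set()
            for members in self.sets.values():
                u |= members
            self.universe = frozenset(u)
        else:
            self.universe = frozenset(self.universe)
            for name, members in self.sets.items():
                if not members <= self.universe:
                    raise EnrichmentError(f"set {name!r} not within universe")

    def __len__(self):
        return len(self.sets)


@dataclass(frozen=True)
class QueryPolicy:
    """Query construction and significance tiers of the cohort analysis."""

    selection_cutoff: int = 20
    go_fdr_small: float = 0.01  # cancers with < cutoff selected proteins
    go_fdr_large: float = 0.001
    pathway_fdr: float = 0.05


def hypergeom_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P[X >= k].

    X counts query genes falling in a set of size K when n genes are drawn
    from a universe of N.  Exact, evaluated through the survival function
    (log-space internally).
    """
    if not (0 <= k <= min(K, n) and 0 <= K <= N and 0 <= n <= N):
        raise EnrichmentError(f"inconsistent counts k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_fdr(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order preserving."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise EnrichmentError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def build_query(
    selected: Iterable[str],
    harmful_genes: Iterable[str],
    policy: QueryPolicy = QueryPolicy(),
) -> tuple[frozenset[str], float]:
    """Choose the enrichment query and GO tier for one cancer.

    Fewer selected proteins than the cutoff -> query is every gene with at
    least one harmful AAS, GO tier ``go_fdr_small``; otherwise the
    selected genes themselves with the stricter ``go_fdr_large``.
    """
    selected = frozenset(selected)
    if len(selected) < policy.selection_cutoff:
        return frozenset(harmful_genes), policy.go_fdr_small
    return selected, policy.go_fdr_large


def enrich(
    query: Iterable[str],
    collection: GeneSetCollection,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric enrichment of a gene query against a collection.

    Query genes outside the universe are dropped with a warning count in
    the result attrs.  Terms with no overlap are omitted.  Returns one
    row per overlapping term: term, k, K, n, N, p, q, significant —
    sorted by p then term id.
    """
    if not collection.universe:
        raise EnrichmentError("empty universe")
    query = set(query)
    dropped = query - set(collection.universe)
    query &= set(collection.universe)
    n, N = len(query), len(collection.universe)
    rows = []
    for term in sorted(collection.sets):
        members = collection.sets[term]
        k = len(query & members)
        if k == 0:
            continue
        rows.append((term, k, len(members), n, N, hypergeom_p(k, len(members), n, N)))
    out = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p"])
    if len(out):
        out["q"] = bh_fdr(out["p"])
        out["significant"] = out["q"] < fdr
        out = out.sort_values(["p", "term"]).reset_index(drop=True)
    else:
        out["q"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    out.attrs["n_query_outside_universe"] = len(dropped)
    return out


def pathway_comembership_network(
    significant: pd.DataFrame,
    collection: GeneSetCollection,
    selected: Iterable[str],
) -> nx.Graph:
    """Network of significant pathways sharing selected proteins.

    Nodes are the significant terms; an edge carries weight = number of
    selected proteins common to both pathways, and pairs sharing none are
    not connected.
    """
    selected = set(selected)
    terms = list(significant.loc[significant["significant"], "term"])
    g = nx.Graph()
    for t in terms:
        members = collection.sets[t] & selected
        g.add_node(t, n_selected=len(members))
    for i, a in enumerate(terms):
        for b in terms[i + 1 :]:
            shared = collection.sets[a] & collection.sets[b] & selected
            if shared:
                g.add_edge(a, b, weight=len(shared))
    return g
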