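"""Direction-specific PPI subnetworks and k-clique percolation communities.

Up PPIs are interactions whose both endpoints are upregulated DEGs (likewise
down PPIs).  Communities are extracted by the clique percolation method
(CPM): enumerate all k-cliques, call two cliques adjacent when they share
k-1 nodes, and take the union of each connected component of the clique
adjacency graph.  Genes not covered by any k-community are dropped before
enrichment and drug querying.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

__all__ = [
    "Community",
    "build_ppi",
    "read_edge_list_tsv",
    "induce_direction_subgraph",
    "clique_percolation",
    "community_census",
    "filter_to_community_genes",
    "community_table",
]

#: refuse CPM on graphs larger than this (k-clique enumeration is worst-case
#: exponential); raise the guard explicitly for bigger inputs
DEFAULT_NODE_GUARD = 10_000


@dataclass
class Community:
    """One k-clique percolation community."""

    k: int
    members: frozenset[str]
    direction: str = "none"  # up | down | none
    stage: str = ""

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)
        if len(self.members) < self.k:
            raise ValueError("a k-community has at least k members")


def build_ppi(edges) -> nx.Graph:
    """Build an undirected PPI graph; self-loops and duplicates are dropped."""
    g = nx.Graph()
    for a, b in edges:
        if a != b:
            g.add_edge(str(a), str(b))
    return g


def read_edge_list_tsv(path) -> nx.Graph:
    """Read a two-column TSV edge list (header row allowed)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("edge list needs two columns")
    return build_ppi(df.iloc[:, :2].astype(str).itertuples(index=False, name=None))


def induce_direction_subgraph(ppi: nx.Graph, genes) -> nx.Graph:
    """Subgraph on edges with BOTH endpoints in the direction-specific set."""
    keep = set(genes) & set(ppi.nodes)
    return ppi.subgraph(keep).copy()


def clique_percolation(
    g: nx.Graph,
    k: int,
    direction: str = "none",
    stage: str = "",
    node_guard: int = DEFAULT_NODE_GUARD,
) -> list[Community]:
    """Standard CPM communities for one k, in deterministic order.

    Output is sorted by decreasing size, then by lexicographically smallest
    member.  Communities may overlap in nodes.
    """
    if k < 3:
        raise ValueError("clique size k must be >= 3")
    if g.number_of_nodes() > node_guard:
        raise ValueError(
            f"graph has {g.number_of_nodes()} nodes, above the guard "
            f"({node_guard}); k-clique enumeration is worst-case exponential"
        )
    raw = nx.community.k_clique_communities(g, k)
    comms = [
        Community(k=k, members=frozenset(c), direction=direction, stage=stage)
        for c in raw
    ]
    comms.sort(key=lambda c: (-len(c.members), min(c.members)))
    return comms


def community_census(communities: list[Community]) -> pd.DataFrame:
    """Counts per (k, direction): number of communities and distinct genes.

    Mirrors the published community-census layout: one row per k and
    direction with the community count and the size of the union of their
    members.
    """
    rows = {}
    for c in communities:
        key = (c.k, c.direction)
        if key not in rows:
            rows[key] = {"n_communities": 0, "genes": set()}
        rows[key]["n_communities"] += 1
        rows[key]["genes"] |= c.members
    table = pd.DataFrame(
        [
            {
                "k": k,
                "direction": direction,
                "n_communities": v["n_communities"],
                "n_distinct_genes": len(v["genes"]),
            }
            for (k, direction), v in sorted(rows.items())
        ],
        columns=["k", "direction", "n_communities", "n_distinct_genes"],
    )
    return table


def filter_to_community_genes(degs, communities: list[Community]) -> set[str]:
    """Keep only DEGs that belong to at least one k-community."""
    covered = set()
    for c in communities:
        covered |= c.members
    return set(degs) & covered


def community_table(communities: list[Community]) -> pd.DataFrame:
    """Long-format table (community_id, k, direction, stage, member)."""
    rows = []
    for i, c in enumerate(communities):
        for m in sorted(c.members):
            rows.append(
                {
                    "community_id": i,
                    "k": c.k,
                    "direction": c.direction,
                    "stage": c.stage,
                    "member": m,
                }
            )
    return pd.DataFrame(
        rows, columns=["community_id", "k", "direction", "stage", "member"]
    )
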