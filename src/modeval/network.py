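"""Retweet-network construction, k-core decomposition and community extraction.

Accounts are nodes; a weighted arc runs from the retweeting account to the
original author (credit flows to the author), with weight equal to the total
number of retweets between the ordered pair.  The k-core keeps the maximal
subgraph in which every node has at least k *distinct* neighbours, judged on
the undirected adjacency; community structure on the core comes from the
Louvain method on the weighted undirected projection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

__all__ = [
    "RetweetGraph",
    "CommunityPartition",
    "build_graph",
    "k_core",
    "detect_communities",
    "community_flows",
    "write_edges_tsv",
    "read_edges_tsv",
]

logger = logging.getLogger(__name__)

ARC_DIRECTION = "retweeter_to_author"  # recorded in output metadata


@dataclass
class CommunityPartition:
    """Node → community mapping plus activity and flow summaries."""

    membership: dict[str, int]
    modularity: float
    top_accounts: dict[int, list[str]] = field(default_factory=dict)
    flow_matrix: pd.DataFrame | None = None

    @property
    def n_communities(self) -> int:
        return len(set(self.membership.values()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.membership.items()), columns=["account_id", "community_id"]
        )


def build_graph(tweets: pd.DataFrame) -> nx.DiGraph:
    """Weighted directed retweet graph from a tweet stream.

    Each retweet record resolved to its original author adds one unit of
    weight on the arc retweeter → author; unresolvable retweets (missing
    original) are dropped and counted in ``G.graph["orphan_retweets"]``.
    """
    g = nx.DiGraph(arc_direction=ARC_DIRECTION)
    rt = tweets[tweets["is_retweet"].astype(bool)]
    originals = tweets.loc[~tweets["is_retweet"].astype(bool), ["tweet_id", "author_id"]]
    author_of = dict(zip(originals["tweet_id"], originals["author_id"]))
    orphans = 0
    pairs: dict[tuple[str, str], int] = {}
    for retweeter, ref in zip(rt["author_id"], rt["retweeted_id"]):
        author = author_of.get(ref)
        if author is None:
            orphans += 1
            continue
        if author == retweeter:
            continue  # self-retweet; no self-loops by construction
        key = (retweeter, author)
        pairs[key] = pairs.get(key, 0) + 1
    for (src, dst), w in pairs.items():
        g.add_edge(src, dst, weight=w)
    g.graph["orphan_retweets"] = orphans
    if orphans:
        logger.warning("dropped %d unresolvable retweet records", orphans)
    return g


def build_graph_from_edges(edges: pd.DataFrame) -> nx.DiGraph:
    """Directed weighted graph from a source/target/weight edge list."""
    g = nx.DiGraph(arc_direction=ARC_DIRECTION)
    for row in edges.itertuples(index=False):
        if row.source == row.target:
            continue
        g.add_edge(row.source, row.target, weight=int(row.weight))
    return g


def k_core(graph: nx.Graph, k: int = 3, weighted: bool = False) -> nx.Graph:
    """Maximal subgraph where every node keeps >= k distinct neighbours.

    The degree test runs on the undirected adjacency regardless of arc
    direction; ``weighted=True`` switches to weighted degree (sum of incident
    weights) instead of neighbour count.  Returns a subgraph view copy on the
    original node set; may be empty.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    und = nx.Graph()
    und.add_nodes_from(graph.nodes())
    for u, v, data in graph.edges(data=True):
        w = data.get("weight", 1)
        if und.has_edge(u, v):
            und[u][v]["weight"] += w
        else:
            und.add_edge(u, v, weight=w)
    und.remove_edges_from(nx.selfloop_edges(und))
    if weighted:
        keep = set(und.nodes())
        changed = True
        while changed:
            changed = False
            drop = [
                n
                for n in keep
                if sum(und[n][nb]["weight"] for nb in und.neighbors(n) if nb in keep) < k
            ]
            if drop:
                keep -= set(drop)
                und.remove_nodes_from(drop)
                changed = True
        core_nodes = keep
    else:
        core_nodes = set(nx.k_core(und, k=k).nodes())
    return graph.subgraph(core_nodes).copy()


def detect_communities(
    subgraph: nx.Graph, resolution: float = 1.0, seed: int = 0
) -> CommunityPartition:
    """Louvain modularity-maximising partition of the (undirected, weighted)
    projection; deterministic given ``seed``."""
    if subgraph.number_of_nodes() == 0:
        raise ValueError("empty subgraph")
    und = nx.Graph()
    und.add_nodes_from(subgraph.nodes())
    for u, v, data in subgraph.edges(data=True):
        w = data.get("weight", 1)
        if und.has_edge(u, v):
            und[u][v]["weight"] += w
        else:
            und.add_edge(u, v, weight=w)
    if und.number_of_edges() == 0:
        logger.warning("graph has no edges; one community per component")
        membership = {n: i for i, n in enumerate(sorted(und.nodes()))}
        return CommunityPartition(membership=membership, modularity=0.0)
    communities = nx.community.louvain_communities(
        und, weight="weight", resolution=resolution, seed=seed
    )
    mod = nx.community.modularity(und, communities, weight="weight", resolution=resolution)
    # stable ids: communities ordered by their lexicographically smallest member
    ordered = sorted(communities, key=lambda s: min(s))
    membership = {n: i for i, comm in enumerate(ordered) for n in comm}
    return CommunityPartition(membership=membership, modularity=float(mod))


def community_flows(
    graph: nx.Graph,
    partition: CommunityPartition,
    tweets: pd.DataFrame | None = None,
    top_n: int = 25,
) -> CommunityPartition:
    """Inter-community weighted flow matrix and per-community activity lists.

    Flows sum arc weights between (source community, target community);
    activity ranks accounts by tweet count in ``tweets`` when given (falling
    back to graph strength), ties broken lexicographically, top ``top_n``
    kept.
    """
    ids = sorted(set(partition.membership.values()))
    flows = pd.DataFrame(0.0, index=ids, columns=ids)
    for u, v, data in graph.edges(data=True):
        cu = partition.membership.get(u)
        cv = partition.membership.get(v)
        if cu is None or cv is None:
            continue
        flows.loc[cu, cv] += data.get("weight", 1)
    if tweets is not None:
        counts = tweets.groupby("author_id", observed=True).size()
    else:
        counts = pd.Series(
            {
                n: sum(d.get("weight", 1) for _, _, d in graph.edges(n, data=True))
                for n in graph.nodes()
            }
        )
    top_accounts: dict[int, list[str]] = {}
    for cid in ids:
        members = [n for n, c in partition.membership.items() if c == cid]
        ranked = sorted(members, key=lambda n: (-counts.get(n, 0), n))
        top_accounts[cid] = ranked[:top_n]
    partition.flow_matrix = flows
    partition.top_accounts = top_accounts
    return partition


def write_edges_tsv(graph: nx.Graph, path) -> None:
    rows = sorted((u, v, d.get("weight", 1)) for u, v, d in graph.edges(data=True))
    with open(path, "w") as fh:
        for u, v, w in rows:
            fh.write(f"{u}\t{v}\t{w}\n")


def read_edges_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", names=["source", "target", "weight"])


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)


def read_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)
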