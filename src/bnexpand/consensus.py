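"""Consensus network over the group of equally-top-scoring models.

An edge enters the consensus only if its skeleton appears in every network
of the top group: directed when the orientation is unanimous, undirected
when both orientations occur across the group.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Sequence, Set, Tuple

from .io_formats import DIRECTED, UNDIRECTED, Edge, NetworkEdgeList
from .scoring import ScoredNetwork
from .search import NetworkPool

__all__ = [
    "ConsensusNetwork",
    "top_group",
    "build_consensus",
    "compare_to_reference",
]


@dataclass
class ConsensusNetwork:
    nodes: Tuple[str, ...]
    directed_edges: Set[Tuple[str, str]] = field(default_factory=set)
    undirected_edges: Set[FrozenSet[str]] = field(default_factory=set)
    #: per skeleton {a, b}: occurrence count of each orientation across the group
    support: Dict[FrozenSet[str], Dict[Tuple[str, str], int]] = field(
        default_factory=dict
    )
    group_size: int = 0

    def to_edge_list(self) -> NetworkEdgeList:
        edges = [Edge(a, b, DIRECTED) for a, b in sorted(self.directed_edges)]
        edges += [
            Edge(a, b, UNDIRECTED)
            for a, b in sorted(tuple(sorted(s)) for s in self.undirected_edges)
        ]
        return NetworkEdgeList(edges)

    @property
    def n_edges(self) -> int:
        return len(self.directed_edges) + len(self.undirected_edges)


def top_group(pool: NetworkPool) -> List[ScoredNetwork]:
    """Networks whose score is within the pool tolerance of the maximum."""
    nets = pool.networks
    if not nets:
        raise ValueError("empty pool")
    best = nets[0].log_score
    return [n for n in nets if n.log_score >= best - pool.score_tolerance]


def build_consensus(group: Sequence[ScoredNetwork]) -> ConsensusNetwork:
    """Unanimity consensus of a group of networks on a common node set."""
    if not group:
        raise ValueError("empty group")
    node_set = set(group[0].dag.nodes)
    for net in group[1:]:
        if set(net.dag.nodes) != node_set:
            raise ValueError("networks in a consensus group must share nodes")
    nodes = tuple(group[0].dag.nodes)

    orient_counts: Dict[FrozenSet[str], Counter] = {}
    skeleton_counts: Counter = Counter()
    for net in group:
        for p, c in net.dag.edges():
            skel = frozenset((p, c))
            skeleton_counts[skel] += 1
            orient_counts.setdefault(skel, Counter())[(p, c)] += 1

    consensus = ConsensusNetwork(nodes=nodes, group_size=len(group))
    for skel, total in skeleton_counts.items():
        consensus.support[skel] = dict(orient_counts[skel])
        if total != len(group):
            continue  # skeleton missing from at least one network
        orientations = orient_counts[skel]
        if len(orientations) == 1:
            consensus.directed_edges.add(next(iter(orientations)))
        else:
            consensus.undirected_edges.add(skel)
    return consensus


def compare_to_reference(
    consensus: ConsensusNetwork, reference: NetworkEdgeList
) -> dict:
    """Fraction of consensus edges matching a reference edge list.

    Skeleton matches ignore orientation; orientation matches require a
    directed consensus edge to coincide with a directed reference edge, or
    either endpoint order for undirected edges on both sides.
    """
    ref_skeletons = set()
    ref_directed = set()
    for e in reference:
        ref_skeletons.add(frozenset((e.source, e.target)))
        if e.orientation == DIRECTED:
            ref_directed.add((e.source, e.target))
        else:
            ref_directed.add((e.source, e.target))
            ref_directed.add((e.target, e.source))

    edges = []
    for a, b in sorted(consensus.directed_edges):
        skel_hit = frozenset((a, b)) in ref_skeletons
        orient_hit = (a, b) in ref_directed
        edges.append(
            {
                "source": a,
                "target": b,
                "orientation": DIRECTED,
                "skeleton_match": skel_hit,
                "orientation_match": orient_hit,
            }
        )
    for skel in sorted(tuple(sorted(s)) for s in consensus.undirected_edges):
        a, b = skel
        skel_hit = frozenset((a, b)) in ref_skeletons
        edges.append(
            {
                "source": a,
                "target": b,
                "orientation": UNDIRECTED,
                "skeleton_match": skel_hit,
                # undirected consensus edges match in either orientation
                "orientation_match": skel_hit,
            }
        )
    n = len(edges)
    skel_frac = sum(e["skeleton_match"] for e in edges) / n if n else 0.0
    orient_frac = sum(e["orientation_match"] for e in edges) / n if n else 0.0
    return {
        "n_consensus_edges": n,
        "skeleton_fraction": skel_frac,
        "orientation_fraction": orient_frac,
        "edges": edges,
    }
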