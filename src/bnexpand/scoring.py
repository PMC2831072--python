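"""Log marginal-likelihood (BDe, Cooper–Herskovits form) scoring of discrete DAGs.

The score of a network is the natural log of the marginal likelihood of the
discretized data under a multinomial model with an all-ones (uniform)
Dirichlet prior, which decomposes into one term per (child, parent-set)
family:

    sum_j [ lnGamma(r) - lnGamma(N_j + r) + sum_k lnGamma(N_jk + 1) ]

where ``r`` is the child's arity, ``j`` ranges over joint parent
configurations, ``N_jk`` counts samples with the child in state ``k`` under
configuration ``j`` and ``N_j = sum_k N_jk``.  The structure prior is
uniform, so this log marginal likelihood is the full network score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
from scipy.special import gammaln

from .preprocess import DiscreteMatrix

__all__ = [
    "Dag",
    "FamilyCountTable",
    "ScoredNetwork",
    "family_counts",
    "log_family_score",
    "Scorer",
    "log_network_score",
]


class CyclicGraphError(ValueError):
    """Raised when a parent-set map contains a directed cycle."""


class Dag:
    """A directed acyclic graph stored as per-node parent sets.

    Nodes are opaque string identifiers; node order is preserved from
    construction (it fixes the row order used by the search engine).
    Equality and hashing use the node *set* and edge set only.
    """

    __slots__ = ("_nodes", "_parents")

    def __init__(
        self,
        nodes: Iterable[str],
        parent_sets: Mapping[str, Iterable[str]] | None = None,
    ) -> None:
        self._nodes: Tuple[str, ...] = tuple(nodes)
        if len(set(self._nodes)) != len(self._nodes):
            raise ValueError("duplicate node ids in DAG")
        node_set = set(self._nodes)
        parents: Dict[str, FrozenSet[str]] = {n: frozenset() for n in self._nodes}
        if parent_sets:
            for child, ps in parent_sets.items():
                if child not in node_set:
                    raise ValueError(f"unknown node in parent_sets: {child!r}")
                ps = frozenset(ps)
                if child in ps:
                    raise ValueError(f"self-parenting on node {child!r}")
                missing = ps - node_set
                if missing:
                    raise ValueError(f"unknown parent(s): {sorted(missing)}")
                parents[child] = ps
        self._parents = parents
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        # Kahn's algorithm on the parent-set representation.
        indeg = {n: len(self._parents[n]) for n in self._nodes}
        children: Dict[str, List[str]] = {n: [] for n in self._nodes}
        for child, ps in self._parents.items():
            for p in ps:
                children[p].append(child)
        stack = [n for n in self._nodes if indeg[n] == 0]
        seen = 0
        while stack:
            u = stack.pop()
            seen += 1
            for c in children[u]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    stack.append(c)
        if seen != len(self._nodes):
            raise CyclicGraphError("parent sets contain a directed cycle")

    @property
    def nodes(self) -> Tuple[str, ...]:
        return self._nodes

    def parents(self, node: str) -> FrozenSet[str]:
        return self._parents[node]

    def children(self, node: str) -> FrozenSet[str]:
        return frozenset(c for c, ps in self._parents.items() if node in ps)

    def edges(self) -> List[Tuple[str, str]]:
        """Directed edges as (parent, child), sorted for determinism."""
        return sorted(
            (p, c) for c, ps in self._parents.items() for p in ps
        )

    @property
    def n_edges(self) -> int:
        return sum(len(ps) for ps in self._parents.values())

    def parent_sets(self) -> Dict[str, FrozenSet[str]]:
        return dict(self._parents)

    def with_parents(self, child: str, parents: Iterable[str]) -> "Dag":
        ps = self.parent_sets()
        ps[child] = frozenset(parents)
        return Dag(self._nodes, ps)

    def topological_order(self) -> List[str]:
        order: List[str] = []
        indeg = {n: len(self._parents[n]) for n in self._nodes}
        children: Dict[str, List[str]] = {n: [] for n in self._nodes}
        for child, ps in self._parents.items():
            for p in ps:
                children[p].append(child)
        stack = sorted((n for n in self._nodes if indeg[n] == 0), reverse=True)
        while stack:
            u = stack.pop()
            order.append(u)
            ready = []
            for c in children[u]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    ready.append(c)
            stack.extend(sorted(ready, reverse=True))
        return order

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self._nodes)
        g.add_edges_from(self.edges())
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dag):
            return NotImplemented
        return set(self._nodes) == set(other._nodes) and self._parents == other._parents

    def __hash__(self) -> int:
        return hash((frozenset(self._nodes), frozenset(self._parents.items())))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Dag(nodes={len(self._nodes)}, edges={self.edges()})"


@dataclass(frozen=True)
class FamilyCountTable:
    """Sufficient statistics for one child node and its parent set.

    Parent configurations are enumerated in mixed-radix order over the
    parents sorted by identifier, first parent most significant.
    """

    child: str
    parents: Tuple[str, ...]
    r_i: int
    q_i: int
    n_ijk: np.ndarray  # shape (q_i, r_i), integer counts
    n_ij: np.ndarray  # shape (q_i,), row sums

    def __post_init__(self) -> None:
        if self.n_ijk.shape != (self.q_i, self.r_i):
            raise ValueError("count table shape mismatch")
        if np.any(self.n_ijk < 0):
            raise ValueError("negative counts")
        if not np.array_equal(self.n_ijk.sum(axis=1), self.n_ij):
            raise ValueError("N_ij must equal row sums of N_ijk")


def family_counts(
    data: DiscreteMatrix, child: str, parents: Iterable[str]
) -> FamilyCountTable:
    """Tally N_ijk for ``child`` given ``parents`` over all samples."""
    idx = {g: i for i, g in enumerate(data.gene_ids)}
    if child not in idx:
        raise KeyError(f"unknown gene id: {child!r}")
    parents = tuple(sorted(set(parents)))
    for p in parents:
        if p not in idx:
            raise KeyError(f"unknown gene id: {p!r}")
    if child in parents:
        raise ValueError(f"child {child!r} cannot be its own parent")
    r = data.arity
    m = len(data.sample_ids)
    q = r ** len(parents)
    config = np.zeros(m, dtype=np.int64)
    for p in parents:  # sorted: first parent most significant
        config = config * r + data.states[idx[p]]
    flat = config * r + data.states[idx[child]]
    counts = np.bincount(flat, minlength=q * r).reshape(q, r)
    return FamilyCountTable(
        child=child,
        parents=parents,
        r_i=r,
        q_i=q,
        n_ijk=counts,
        n_ij=counts.sum(axis=1),
    )


def log_family_score(counts: FamilyCountTable) -> float:
    """Log of prod_j (r-1)!/(N_j+r-1)! prod_k N_jk!, via log-gamma."""
    r = counts.r_i
    term = (
        gammaln(r)
        - gammaln(counts.n_ij + r)
        + gammaln(counts.n_ijk + 1.0).sum(axis=1)
    )
    return float(term.sum())


@dataclass
class ScoredNetwork:
    """A DAG with its log marginal-likelihood score, decomposed by family."""

    dag: Dag
    log_score: float
    per_family_scores: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.per_family_scores:
            total = sum(self.per_family_scores.values())
            if abs(total - self.log_score) > 1e-9:
                raise ValueError(
                    "log_score inconsistent with per-family decomposition"
                )


class Scorer:
    """Caches per-family scores keyed by (child, frozen parent set).

    Repeated families across networks (the common case during search and
    expansion) are computed once.
    """

    def __init__(self, data: DiscreteMatrix) -> None:
        self.data = data
        self._cache: Dict[Tuple[str, FrozenSet[str]], float] = {}

    def family_score(self, child: str, parents: Iterable[str]) -> float:
        key = (child, frozenset(parents))
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        val = log_family_score(family_counts(self.data, child, key[1]))
        self._cache[key] = val
        return val

    def score(self, dag: Dag) -> ScoredNetwork:
        genes = set(self.data.gene_ids)
        missing = [n for n in dag.nodes if n not in genes]
        if missing:
            raise KeyError(f"DAG nodes absent from data: {missing}")
        per_family = {
            node: self.family_score(node, dag.parents(node)) for node in dag.nodes
        }
        return ScoredNetwork(
            dag=dag,
            log_score=sum(per_family.values()),
            per_family_scores=per_family,
        )


def log_network_score(dag: Dag, data: DiscreteMatrix) -> ScoredNetwork:
    """Score ``dag`` against ``data`` with a fresh family cache."""
    return Scorer(data).score(dag)
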