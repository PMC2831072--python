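"""Stochastic structure search: annealed add/delete/reverse moves with restarts.

``anneal_run`` drives the compiled kernel in :mod:`bnexpand._engine`;
``multi_restart_search`` pools the ``keep_top`` best distinct networks from
each restart.  Everything is deterministic given the configured seed:
restart r uses the substream ``seed ^ mix(r)``, and a run with a larger
proposal budget shares its proposal prefix with a smaller one.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .preprocess import DiscreteMatrix
from .scoring import Dag, ScoredNetwork, Scorer

__all__ = [
    "SearchConfig",
    "NetworkPool",
    "propose_move",
    "anneal_run",
    "multi_restart_search",
    "derive_seed",
    "pool_to_dict",
    "pool_from_dict",
]


@dataclass(frozen=True)
class SearchConfig:
    """Tunables for one annealing run and for restart pooling."""

    networks_per_run: int = 100_000
    restarts: int = 10
    keep_top: int = 5
    max_parents: int = 5
    initial_temperature: float = 100.0
    cooling_factor: float = 0.9999
    reheat_after: int = 500
    rng_seed: int = 0
    start_density: float = 0.0
    score_tolerance: float = 1e-6

    def __post_init__(self) -> None:
        if self.networks_per_run < 0:
            raise ValueError("networks_per_run must be >= 0")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if self.keep_top < 1:
            raise ValueError("keep_top must be >= 1")
        if self.max_parents < 0:
            raise ValueError("max_parents must be >= 0")
        if not (0.0 < self.cooling_factor < 1.0):
            raise ValueError("cooling_factor must lie in (0, 1)")
        if self.initial_temperature <= 0:
            raise ValueError("initial_temperature must be positive")
        if self.reheat_after < 1:
            raise ValueError("reheat_after must be >= 1")
        if not (0.0 <= self.start_density <= 1.0):
            raise ValueError("start_density must lie in [0, 1]")


def derive_seed(*parts) -> int:
    """Stable 64-bit substream seed from arbitrary labeled parts.

    Uses blake2b, not ``hash()``, so results are identical across processes.
    """
    h = hashlib.blake2b(digest_size=8)
    for p in parts:
        h.update(repr(p).encode())
        h.update(b"\x1f")
    return int.from_bytes(h.digest(), "little")


class NetworkPool:
    """Scored networks deduplicated by DAG identity, best score first."""

    def __init__(
        self,
        networks: Iterable[ScoredNetwork] = (),
        score_tolerance: float = 1e-6,
    ) -> None:
        self.score_tolerance = float(score_tolerance)
        self._networks: List[ScoredNetwork] = []
        self._seen = set()
        for net in networks:
            self.add(net)

    def add(self, net: ScoredNetwork) -> bool:
        key = net.dag
        if key in self._seen:
            return False
        self._seen.add(key)
        self._networks.append(net)
        # deterministic order: score desc, then canonical edge list
        self._networks.sort(key=lambda s: (-s.log_score, tuple(s.dag.edges())))
        return True

    @property
    def networks(self) -> List[ScoredNetwork]:
        return list(self._networks)

    @property
    def best(self) -> ScoredNetwork:
        if not self._networks:
            raise ValueError("empty pool")
        return self._networks[0]

    def __len__(self) -> int:
        return len(self._networks)

    def __iter__(self):
        return iter(self._networks)


def _legal_moves(
    dag: Dag, max_parents: int
) -> List[Tuple[str, str, str]]:
    """All (kind, u, v) neighbors of ``dag`` under acyclicity and fan-in cap."""
    nodes = dag.nodes
    g = dag.to_networkx()
    import networkx as nx

    moves: List[Tuple[str, str, str]] = []
    for u in nodes:
        for v in nodes:
            if u == v:
                continue
            if g.has_edge(u, v):
                moves.append(("delete", u, v))
                if len(dag.parents(u)) < max_parents:
                    g.remove_edge(u, v)
                    if not nx.has_path(g, u, v):
                        moves.append(("reverse", u, v))
                    g.add_edge(u, v)
            else:
                if len(dag.parents(v)) < max_parents and not nx.has_path(g, v, u):
                    moves.append(("add", u, v))
    return moves


def _apply_move(dag: Dag, move: Tuple[str, str, str]) -> Dag:
    kind, u, v = move
    if kind == "add":
        return dag.with_parents(v, dag.parents(v) | {u})
    if kind == "delete":
        return dag.with_parents(v, dag.parents(v) - {u})
    if kind == "reverse":
        return dag.with_parents(v, dag.parents(v) - {u}).with_parents(
            u, dag.parents(u) | {v}
        )
    raise ValueError(f"unknown move kind {kind!r}")


def propose_move(
    dag: Dag, rng: np.random.Generator, max_parents: int = 5
) -> Dag:
    """Uniform draw over the legal add/delete/reverse neighbors of ``dag``.

    Returns ``dag`` itself when no legal move exists.  This is the reference
    (pure-Python) implementation of the kernel's move semantics and is used
    by tests; the hot loop lives in :mod:`bnexpand._engine`.
    """
    moves = _legal_moves(dag, max_parents)
    if not moves:
        return dag
    return _apply_move(dag, moves[int(rng.integers(len(moves)))])


def _dag_to_adj(dag: Dag, nodes: Sequence[str]) -> np.ndarray:
    index = {g: i for i, g in enumerate(nodes)}
    adj = np.zeros((len(nodes), len(nodes)), dtype=np.uint8)
    for child in dag.nodes:
        for p in dag.parents(child):
            adj[index[p], index[child]] = 1
    return adj


def _adj_to_dag(adj: np.ndarray, nodes: Sequence[str]) -> Dag:
    parent_sets = {
        nodes[v]: frozenset(nodes[u] for u in np.nonzero(adj[:, v])[0])
        for v in range(len(nodes))
    }
    return Dag(nodes, parent_sets)


def _resolve_seed(rng, config: SearchConfig) -> int:
    if rng is None:
        return config.rng_seed
    if isinstance(rng, (int, np.integer)):
        return int(rng)
    if isinstance(rng, np.random.Generator):
        return int(rng.integers(0, 2**63 - 1))
    raise TypeError(f"rng must be None, an int seed or a numpy Generator")


def anneal_run(
    data: DiscreteMatrix,
    start: Dag,
    config: SearchConfig,
    rng: Optional[int | np.random.Generator] = None,
) -> List[ScoredNetwork]:
    """One simulated-annealing run; returns the keep_top best distinct
    networks ever visited, best first.

    Acceptance: improvements always; a worsening of ``delta`` with
    probability exp(delta / T).  T cools geometrically per proposal and is
    reheated after ``reheat_after`` consecutive rejections.
    """
    from . import _engine

    genes = set(data.gene_ids)
    missing = [n for n in start.nodes if n not in genes]
    if missing:
        raise KeyError(f"start network nodes absent from data: {missing}")
    nodes = list(start.nodes)
    sub = data.subset(nodes)
    seed = _resolve_seed(rng, config)
    arities = np.full(len(nodes), data.arity, dtype=np.int64)
    topk_adj, topk_score = _engine.run_anneal(
        sub.states,
        arities,
        _dag_to_adj(start, nodes),
        config.networks_per_run,
        config.max_parents,
        config.initial_temperature,
        config.cooling_factor,
        config.reheat_after,
        config.keep_top,
        seed,
    )
    scorer = Scorer(sub)
    out: List[ScoredNetwork] = []
    for adj, kernel_score in zip(topk_adj, topk_score):
        net = scorer.score(_adj_to_dag(adj, nodes))
        if abs(net.log_score - kernel_score) > 1e-6:  # pragma: no cover
            raise AssertionError(
                "kernel/scorer disagreement: "
                f"{kernel_score} vs {net.log_score}"
            )
        out.append(net)
    return out


def _random_start(
    nodes: Sequence[str], density: float, max_parents: int, seed: int
) -> Dag:
    """Random DAG: random topological order, forward edges kept with
    probability ``density`` subject to the fan-in cap."""
    rng = np.random.default_rng(seed)
    order = list(nodes)
    rng.shuffle(order)
    parent_sets: dict = {n: set() for n in nodes}
    for j in range(1, len(order)):
        for i in range(j):
            if len(parent_sets[order[j]]) >= max_parents:
                break
            if density > 0 and rng.random() < density:
                parent_sets[order[j]].add(order[i])
    return Dag(nodes, parent_sets)


def multi_restart_search(
    data: DiscreteMatrix,
    genes: Sequence[str],
    config: SearchConfig,
    rng: Optional[int | np.random.Generator] = None,
) -> NetworkPool:
    """Pool the saved networks of ``config.restarts`` independent runs."""
    genes = list(genes)
    present = set(data.gene_ids)
    missing = [g for g in genes if g not in present]
    if missing:
        raise KeyError(f"genes absent from data: {missing}")
    seed = _resolve_seed(rng, config)
    pool = NetworkPool(score_tolerance=config.score_tolerance)
    for r in range(config.restarts):
        start = _random_start(
            genes,
            config.start_density,
            config.max_parents,
            derive_seed("start", seed, r),
        )
        run_cfg = replace(config, restarts=1)
        for net in anneal_run(data, start, run_cfg, derive_seed("run", seed, r)):
            pool.add(net)
    return pool


def pool_to_dict(pool: NetworkPool) -> dict:
    """JSON-ready representation of a pool (nodes, edges, scores)."""
    return {
        "score_tolerance": pool.score_tolerance,
        "networks": [
            {
                "nodes": list(net.dag.nodes),
                "edges": [[p, c] for p, c in net.dag.edges()],
                "log_score": net.log_score,
            }
            for net in pool.networks
        ],
    }


def pool_from_dict(doc: dict) -> NetworkPool:
    pool = NetworkPool(score_tolerance=doc.get("score_tolerance", 1e-6))
    for entry in doc["networks"]:
        parent_sets: dict = {n: set() for n in entry["nodes"]}
        for p, c in entry["edges"]:
            parent_sets[c].add(p)
        dag = Dag(entry["nodes"], parent_sets)
        pool.add(ScoredNetwork(dag=dag, log_score=float(entry["log_score"])))
    return pool
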