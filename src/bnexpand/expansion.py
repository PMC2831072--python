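"""Single-gene network expansion: rank every out-of-network gene by how much
its addition can improve the core network's score.

Each candidate is evaluated independently on the data slice restricted to
the core genes plus that candidate.  The search starts from the core
topology with the candidate attached as an isolated node; every edge,
including core edges, stays mutable during the run.  Candidate RNG
substreams are keyed by gene id, so the ranking does not depend on
evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np

from .preprocess import DiscreteMatrix
from .scoring import Dag, ScoredNetwork
from .search import SearchConfig, anneal_run, derive_seed, _resolve_seed

__all__ = [
    "ExpansionConfig",
    "ExpansionResult",
    "seed_expanded_dag",
    "expand_one",
    "bn_plus_one",
    "rerank_top",
    "induced_edges",
]


@dataclass(frozen=True)
class ExpansionConfig(SearchConfig):
    """Search tunables plus the screen/re-rank budgets of the expansion loop."""

    screen_networks_per_gene: int = 100_000
    rerank_top_n: int = 200
    rerank_networks: int = 250_000
    rerank_replicates: int = 150

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.screen_networks_per_gene < 0:
            raise ValueError("screen_networks_per_gene must be >= 0")
        if self.rerank_top_n < 1:
            raise ValueError("rerank_top_n must be >= 1")
        if self.rerank_networks < 0:
            raise ValueError("rerank_networks must be >= 0")
        if self.rerank_replicates < 1:
            raise ValueError("rerank_replicates must be >= 1")


@dataclass
class ExpansionResult:
    """Candidates ranked by best expanded score, with their induced edges."""

    #: (candidate gene, best log score, best expanded DAG), score descending
    ranking: List[Tuple[str, float, Dag]] = field(default_factory=list)
    #: per candidate: (parents of candidate, children of candidate) in its best network
    induced: Dict[str, Tuple[FrozenSet[str], FrozenSet[str]]] = field(
        default_factory=dict
    )

    @property
    def genes(self) -> List[str]:
        return [g for g, _, _ in self.ranking]

    def score_of(self, gene: str) -> float:
        for g, s, _ in self.ranking:
            if g == gene:
                return s
        raise KeyError(gene)


def seed_expanded_dag(core: Dag, candidate: str) -> Dag:
    """Core topology plus the candidate as an isolated node."""
    if candidate in core.nodes:
        raise ValueError(f"candidate {candidate!r} already in core network")
    return Dag(tuple(core.nodes) + (candidate,), core.parent_sets())


def induced_edges(
    network: ScoredNetwork | Dag, candidate: str
) -> Tuple[FrozenSet[str], FrozenSet[str]]:
    """(parents, children) of the candidate node in a network."""
    dag = network.dag if isinstance(network, ScoredNetwork) else network
    if candidate not in dag.nodes:
        raise KeyError(f"candidate {candidate!r} not in network")
    return dag.parents(candidate), dag.children(candidate)


def _screen_config(config: ExpansionConfig) -> SearchConfig:
    return SearchConfig(
        networks_per_run=config.screen_networks_per_gene,
        restarts=1,
        keep_top=1,
        max_parents=config.max_parents,
        initial_temperature=config.initial_temperature,
        cooling_factor=config.cooling_factor,
        reheat_after=config.reheat_after,
        rng_seed=config.rng_seed,
        score_tolerance=config.score_tolerance,
    )


def expand_one(
    data: DiscreteMatrix,
    core: Dag,
    candidate: str,
    config: ExpansionConfig,
    rng: Optional[int | np.random.Generator] = None,
) -> ScoredNetwork:
    """Best network found for core + one candidate, all edges mutable."""
    genes = set(data.gene_ids)
    if candidate not in genes:
        raise KeyError(f"candidate {candidate!r} absent from data")
    missing = [g for g in core.nodes if g not in genes]
    if missing:
        raise KeyError(f"core genes absent from data: {missing}")
    start = seed_expanded_dag(core, candidate)
    sub = data.subset(list(start.nodes))
    seed = _resolve_seed(rng, config)
    run_cfg = _screen_config(config)
    nets = anneal_run(sub, start, run_cfg, seed)
    return nets[0]


def _candidate_seed(root_seed: int, candidate: str, replicate: int) -> int:
    return derive_seed("bn+1", root_seed, candidate, replicate)


def bn_plus_one(
    data: DiscreteMatrix,
    core: Dag,
    candidates: Sequence[str],
    config: ExpansionConfig,
    rng: Optional[int | np.random.Generator] = None,
) -> ExpansionResult:
    """Screen every candidate independently and rank by best expanded score.

    Ties are broken lexicographically by gene id.
    """
    candidates = list(candidates)
    overlap = sorted(set(candidates) & set(core.nodes))
    if overlap:
        raise ValueError(f"candidates overlap the core network: {overlap}")
    if len(set(candidates)) != len(candidates):
        raise ValueError("duplicate candidate gene ids")
    root_seed = _resolve_seed(rng, config)
    rows: List[Tuple[str, float, Dag]] = []
    for cand in candidates:
        best = expand_one(
            data, core, cand, config, _candidate_seed(root_seed, cand, 0)
        )
        rows.append((cand, best.log_score, best.dag))
    rows.sort(key=lambda r: (-r[1], r[0]))
    result = ExpansionResult(ranking=rows)
    for gene, _, dag in rows:
        result.induced[gene] = induced_edges(dag, gene)
    return result


def rerank_top(
    data: DiscreteMatrix,
    core: Dag,
    prior_result: ExpansionResult,
    config: ExpansionConfig,
    rng: Optional[int | np.random.Generator] = None,
) -> ExpansionResult:
    """Re-run the leading candidates with replicate searches, keep the max.

    Replicate 0 reuses the screen-phase substream seed, so a re-ranked score
    can never drop below the screen score when budgets match.
    """
    if not prior_result.ranking:
        raise ValueError("prior_result is empty")
    root_seed = _resolve_seed(rng, config)
    n_lead = min(config.rerank_top_n, len(prior_result.ranking))
    rerank_cfg = replace(
        config, screen_networks_per_gene=config.rerank_networks
    )
    rows: List[Tuple[str, float, Dag]] = []
    for gene, screen_score, screen_dag in prior_result.ranking[:n_lead]:
        best_score, best_dag = -np.inf, None
        for rep in range(config.rerank_replicates):
            net = expand_one(
                data, core, gene, rerank_cfg,
                _candidate_seed(root_seed, gene, rep),
            )
            if net.log_score > best_score:
                best_score, best_dag = net.log_score, net.dag
        rows.append((gene, best_score, best_dag))
    rows.extend(prior_result.ranking[n_lead:])
    rows.sort(key=lambda r: (-r[1], r[0]))
    result = ExpansionResult(ranking=rows)
    for gene, _, dag in rows:
        result.induced[gene] = induced_edges(dag, gene)
    return result
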