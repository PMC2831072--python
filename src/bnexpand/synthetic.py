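"""Ground-truth generators: random DAGs, CPTs, discrete/continuous samples,
planted hidden regulators, noise candidates, and annotated sample metadata.

Continuous readouts are per-state Gaussian emissions with strictly
increasing state means, so equal-frequency discretization of the continuous
matrix can recover the underlying states when the emission noise is small.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .io_formats import ExpressionMatrix, SampleMetadata
from .preprocess import DiscreteMatrix
from .scoring import Dag

__all__ = [
    "GroundTruthModel",
    "sample_dag",
    "sample_cpts",
    "simulate",
    "plant_regulator",
    "make_metadata",
]

# deliberately bland filler vocabulary for metadata text
_FILLER_WORDS = (
    "culture", "growth", "medium", "aerobic", "shaking", "control",
    "replicate", "exposure", "minimal", "rich", "stationary", "exponential",
    "wildtype", "mutant", "timepoint", "harvest",
)


@dataclass
class GroundTruthModel:
    """A discrete DAG model with Gaussian per-state emissions."""

    dag: Dag
    arity: int
    #: per node: array (q, arity) of CPT rows, parent configs in mixed-radix
    #: order over parents sorted by id (first parent most significant)
    cpts: Dict[str, np.ndarray]
    #: per node: (means ascending, shape (arity,)) and scalar sd
    emission_means: Dict[str, np.ndarray]
    emission_sd: float
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.emission_sd <= 0:
            raise ValueError("emission sd must be positive")
        for node in self.dag.nodes:
            cpt = self.cpts[node]
            q = self.arity ** len(self.dag.parents(node))
            if cpt.shape != (q, self.arity):
                raise ValueError(f"CPT shape mismatch for {node!r}")
            if np.any(np.abs(cpt.sum(axis=1) - 1.0) > 1e-12):
                raise ValueError(f"CPT rows of {node!r} must sum to 1")
            means = self.emission_means[node]
            if np.any(np.diff(means) <= 0):
                raise ValueError(f"state means of {node!r} must be increasing")


def sample_dag(
    n_nodes: int,
    max_parents: int = 5,
    edge_prob: float = 0.25,
    rng: Optional[np.random.Generator] = None,
    prefix: str = "g",
) -> Dag:
    """Random DAG: random topological order, forward edges kept with
    probability ``edge_prob`` subject to the fan-in cap."""
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    if not (0.0 <= edge_prob <= 1.0):
        raise ValueError("edge_prob must lie in [0, 1]")
    rng = rng if rng is not None else np.random.default_rng()
    nodes = [f"{prefix}{i:02d}" for i in range(n_nodes)]
    order = list(nodes)
    rng.shuffle(order)
    parent_sets: Dict[str, set] = {n: set() for n in nodes}
    for j in range(1, n_nodes):
        for i in range(j):
            if len(parent_sets[order[j]]) >= max_parents:
                break
            if edge_prob >= 1.0 or rng.random() < edge_prob:
                parent_sets[order[j]].add(order[i])
    return Dag(nodes, parent_sets)


def _sharpened_rows(
    q: int, arity: int, strength: float, rng: np.random.Generator,
    peaks: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Dirichlet rows blended with a one-hot peak of mass >= strength."""
    if not (0.0 < strength <= 1.0):
        raise ValueError("strength must lie in (0, 1]")
    if peaks is None:
        peaks = rng.integers(0, arity, size=q)
    rows = np.zeros((q, arity))
    for j in range(q):
        base = rng.dirichlet(np.ones(arity))
        rows[j] = strength * np.eye(arity)[peaks[j]] + (1.0 - strength) * base
    # exact row normalization (guards against float drift)
    rows /= rows.sum(axis=1, keepdims=True)
    return rows


def _informative_peaks(
    n_par: int, arity: int, rng: np.random.Generator
) -> np.ndarray:
    """Peak states per parent configuration such that every parent matters.

    A parent is informative when, for some setting of the other parents,
    changing its state changes the peak; draws are rejected until all
    parents qualify (cheap for the small fan-ins used here).
    """
    q = arity ** n_par
    if n_par == 0:
        return rng.integers(0, arity, size=1)
    for _ in range(1000):
        peaks = rng.integers(0, arity, size=q)
        grid = peaks.reshape((arity,) * n_par)
        if all(
            np.any(np.diff(grid, axis=axis) != 0) for axis in range(n_par)
        ):
            return peaks
    # fall back to a peak pattern that provably varies along every axis
    grid = np.indices((arity,) * n_par).sum(axis=0) % arity
    return grid.reshape(q)


def sample_cpts(
    dag: Dag,
    arity: int = 3,
    strength: float = 0.9,
    rng: Optional[np.random.Generator] = None,
    emission_sd: float = 0.25,
    mean_spacing: float = 2.0,
    rng_seed: int = 0,
) -> GroundTruthModel:
    """Draw a full ground-truth model over ``dag``.

    Every CPT row carries probability >= ``strength`` on one state
    (strength=1 yields deterministic relations).  For child nodes the peak
    pattern is rejected-sampled so that every parent actually influences the
    child's distribution.
    """
    rng = rng if rng is not None else np.random.default_rng(rng_seed)
    cpts: Dict[str, np.ndarray] = {}
    means: Dict[str, np.ndarray] = {}
    for node in dag.nodes:
        n_par = len(dag.parents(node))
        q = arity ** n_par
        peaks = _informative_peaks(n_par, arity, rng)
        cpts[node] = _sharpened_rows(q, arity, strength, rng, peaks)
        means[node] = np.arange(arity, dtype=float) * mean_spacing
    return GroundTruthModel(
        dag=dag,
        arity=arity,
        cpts=cpts,
        emission_means=means,
        emission_sd=emission_sd,
        rng_seed=rng_seed,
    )


def simulate(
    model: GroundTruthModel,
    m_samples: int,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[DiscreteMatrix, ExpressionMatrix]:
    """Ancestral sampling plus Gaussian emissions.

    Returns the ground-truth discrete matrix and the continuous matrix in
    the model's node order, with samples named s0000, s0001, ...
    """
    if m_samples < 1:
        raise ValueError("m_samples must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(model.rng_seed)
    nodes = list(model.dag.nodes)
    index = {g: i for i, g in enumerate(nodes)}
    arity = model.arity
    states = np.zeros((len(nodes), m_samples), dtype=np.int64)
    for node in model.dag.topological_order():
        parents = sorted(model.dag.parents(node))
        if parents:
            config = np.zeros(m_samples, dtype=np.int64)
            for p in parents:
                config = config * arity + states[index[p]]
        else:
            config = np.zeros(m_samples, dtype=np.int64)
        cpt = model.cpts[node]
        u = rng.random(m_samples)
        cdf = np.cumsum(cpt, axis=1)
        states[index[node]] = (u[:, None] > cdf[config]).sum(axis=1)
    values = np.empty_like(states, dtype=float)
    for node in nodes:
        i = index[node]
        values[i] = (
            model.emission_means[node][states[i]]
            + model.emission_sd * rng.standard_normal(m_samples)
        )
    sample_ids = [f"s{j:04d}" for j in range(m_samples)]
    return (
        DiscreteMatrix(list(nodes), sample_ids, states, arity=arity),
        ExpressionMatrix(list(nodes), sample_ids, values),
    )


def plant_regulator(
    model: GroundTruthModel,
    n_targets: int = 2,
    n_noise_candidates: int = 20,
    rng: Optional[np.random.Generator] = None,
    strength: float = 0.9,
    hidden_name: str = "hidden00",
    noise_prefix: str = "noise",
) -> Tuple[GroundTruthModel, Dag, List[str]]:
    """Augment a model with one hidden regulator and independent noise genes.

    The hidden gene becomes a root parent of ``n_targets`` core nodes whose
    CPTs are rebuilt (over old parents + hidden) so their peak state tracks
    the hidden state.  Noise genes are independent near-uniform roots.

    Returns (augmented model, core DAG without the added genes, candidate
    gene list = [hidden] + noise genes).
    """
    if n_targets < 1:
        raise ValueError("n_targets must be >= 1")
    core_nodes = list(model.dag.nodes)
    if n_targets > len(core_nodes):
        raise ValueError("more targets than core nodes")
    rng = rng if rng is not None else np.random.default_rng(model.rng_seed)
    arity = model.arity

    # prefer low fan-in targets so the augmented family stays small
    by_fanin = sorted(core_nodes, key=lambda n: (len(model.dag.parents(n)), n))
    targets = by_fanin[:n_targets]

    noise = [f"{noise_prefix}{i:02d}" for i in range(n_noise_candidates)]
    new_nodes = core_nodes + [hidden_name] + noise
    parent_sets = {n: set(model.dag.parents(n)) for n in core_nodes}
    for t in targets:
        parent_sets[t] = parent_sets[t] | {hidden_name}
    parent_sets[hidden_name] = set()
    for g in noise:
        parent_sets[g] = set()
    aug_dag = Dag(new_nodes, parent_sets)

    cpts = dict(model.cpts)
    means = dict(model.emission_means)
    cpts[hidden_name] = np.full((1, arity), 1.0 / arity)
    means[hidden_name] = np.arange(arity, dtype=float) * 2.0
    for g in noise:
        cpts[g] = _sharpened_rows(1, arity, 1.0 / arity + 1e-9, rng)
        means[g] = np.arange(arity, dtype=float) * 2.0
    for t in targets:
        parents = sorted(parent_sets[t])
        q = arity ** len(parents)
        h_pos = parents.index(hidden_name)
        # state of the hidden parent inside each mixed-radix config index
        div = arity ** (len(parents) - 1 - h_pos)
        h_state = (np.arange(q) // div) % arity
        offset = rng.integers(0, arity)
        peaks = (h_state + offset) % arity
        cpts[t] = _sharpened_rows(q, arity, strength, rng, peaks)
    augmented = GroundTruthModel(
        dag=aug_dag,
        arity=arity,
        cpts=cpts,
        emission_means=means,
        emission_sd=model.emission_sd,
        rng_seed=model.rng_seed,
    )
    candidates = [hidden_name] + noise
    return augmented, model.dag, candidates


def make_metadata(
    states: DiscreteMatrix,
    gene_a: str,
    gene_b: str,
    term: str,
    target_bin: Tuple[int, int],
    hit_rate: float = 1.0,
    background_rate: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> List[SampleMetadata]:
    """Plant ``term`` in sample descriptions preferentially in one joint bin.

    Samples whose (gene_a, gene_b) states equal ``target_bin`` receive the
    term with probability ``hit_rate``, all others with
    ``background_rate``; every sample gets filler text.
    """
    for rate, name in ((hit_rate, "hit_rate"), (background_rate, "background_rate")):
        if not (0.0 <= rate <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1]")
    sa = int(target_bin[0])
    sb = int(target_bin[1])
    if not (0 <= sa < states.arity and 0 <= sb < states.arity):
        raise ValueError(f"target_bin {target_bin} outside [0, {states.arity})^2")
    row_a = states.row(gene_a)
    row_b = states.row(gene_b)
    rng = rng if rng is not None else np.random.default_rng()
    out: List[SampleMetadata] = []
    for j, sid in enumerate(states.sample_ids):
        words = list(rng.choice(_FILLER_WORDS, size=3, replace=False))
        in_bin = row_a[j] == sa and row_b[j] == sb
        rate = hit_rate if in_bin else background_rate
        if rng.random() < rate:
            words.insert(int(rng.integers(len(words) + 1)), term)
        out.append(
            SampleMetadata(
                sample_id=sid,
                title=f"experiment {j}",
                description=" ".join(words),
            )
        )
    return out
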