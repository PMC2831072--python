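"""Variability filtering and per-gene equal-frequency (maximum-entropy) discretization."""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix

__all__ = [
    "DiscreteMatrix",
    "cv_filter",
    "q3_discretize",
    "read_discrete_matrix",
    "write_discrete_matrix",
]


@dataclass
class DiscreteMatrix:
    """Genes x samples integer state matrix with fixed per-gene arity.

    ``states`` entries lie in [0, arity); state 0 holds the lowest values.
    ``bin_edges`` records, per gene, the (arity-1) cut values used: a value
    ``v`` maps to state = number of edges strictly below ``v``.
    """

    gene_ids: List[str]
    sample_ids: List[str]
    states: np.ndarray
    arity: int = 3
    bin_edges: np.ndarray | None = None  # shape (n_genes, arity-1)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int64)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if self.states.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("state matrix shape does not match id lists")
        if self.arity < 2:
            raise ValueError("arity must be >= 2")
        if self.states.size and (
            self.states.min() < 0 or self.states.max() >= self.arity
        ):
            raise ValueError("states must lie in [0, arity)")
        if self.bin_edges is not None:
            self.bin_edges = np.asarray(self.bin_edges, dtype=float)
            if self.bin_edges.shape != (len(self.gene_ids), self.arity - 1):
                raise ValueError("bin_edges shape must be (n_genes, arity-1)")
            if np.any(np.diff(self.bin_edges, axis=1) < 0):
                raise ValueError("bin_edges must be non-decreasing per gene")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, gene: str) -> np.ndarray:
        try:
            i = self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"unknown gene id: {gene!r}") from None
        return self.states[i]

    def subset(self, genes: Sequence[str]) -> "DiscreteMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [index[g] for g in genes]
        edges = self.bin_edges[rows] if self.bin_edges is not None else None
        return DiscreteMatrix(
            list(genes), list(self.sample_ids), self.states[rows], self.arity, edges
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.states, index=self.gene_ids, columns=self.sample_ids)


def cv_filter(
    matrix: ExpressionMatrix, threshold: float
) -> Tuple[List[str], pd.DataFrame]:
    """Keep genes whose coefficient of variation meets ``threshold``.

    c.v. = sample standard deviation (n-1 denominator) / |mean|, computed on
    the values exactly as stored.  Genes with mean exactly 0 get infinite
    c.v. and survive any finite threshold.  Returns the kept gene ids (input
    order preserved) and a per-gene table of mean, sd, c.v. and kept flag.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if matrix.values.shape[1] < 2:
        raise ValueError("need at least 2 samples to compute a c.v.")
    means = matrix.values.mean(axis=1)
    sds = matrix.values.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cvs = np.where(means == 0.0, np.inf, sds / np.abs(means))
    kept_mask = cvs >= threshold
    table = pd.DataFrame(
        {
            "gene": matrix.gene_ids,
            "mean": means,
            "sd": sds,
            "cv": cvs,
            "kept": kept_mask,
        }
    )
    kept = [g for g, k in zip(matrix.gene_ids, kept_mask) if k]
    return kept, table


def _admissible_cuts(sorted_values: np.ndarray) -> List[int]:
    """Cut positions (between sorted ranks) that do not split tied values."""
    m = len(sorted_values)
    cuts = [0]
    cuts.extend(p for p in range(1, m) if sorted_values[p - 1] < sorted_values[p])
    cuts.append(m)
    return cuts


def _candidate_positions(cuts: Sequence[int], target: float) -> List[int]:
    """Nearest admissible cut at-or-below and above a fractional target rank."""
    arr = np.asarray(cuts)
    below = arr[arr <= target]
    above = arr[arr >= target]
    cands = set()
    if below.size:
        cands.add(int(below.max()))
    if above.size:
        cands.add(int(above.min()))
    return sorted(cands)


def _choose_cuts(sorted_values: np.ndarray, levels: int) -> List[int]:
    """Pick (levels-1) admissible cut positions giving the most even bins.

    Primary criterion: bin-size vector sorted descending, lexicographically
    minimal (so the largest bin is as small as possible, then the next, ...).
    Ties are broken by preferring to fill lower bins first, so degenerate
    inputs (e.g. an all-equal gene) land in state 0.
    """
    m = len(sorted_values)
    cuts = _admissible_cuts(sorted_values)
    targets = [m * k / levels for k in range(1, levels)]
    if len(cuts) <= 24:
        pools = [cuts] * (levels - 1)
    else:
        pools = [_candidate_positions(cuts, t) for t in targets]
    best_key = None
    best = None
    for combo in itertools.product(*pools):
        if any(combo[i] > combo[i + 1] for i in range(len(combo) - 1)):
            continue
        bounds = (0,) + combo + (m,)
        sizes = tuple(bounds[i + 1] - bounds[i] for i in range(levels))
        key = (
            tuple(sorted(sizes, reverse=True)),
            tuple(-s for s in sizes),
            combo,
        )
        if best_key is None or key < best_key:
            best_key = key
            best = combo
    assert best is not None
    return list(best)


def q3_discretize(matrix: ExpressionMatrix, levels: int = 3) -> DiscreteMatrix:
    """Equal-frequency discretization of each gene independently.

    Samples are rank-ordered and split into ``levels`` groups as equal in
    size as the data's ties permit; cut points never separate equal values.
    The arity of the result is ``levels`` regardless of how many states a
    gene actually occupies.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    n, m = matrix.values.shape
    if m < levels:
        raise ValueError(f"need at least {levels} samples, got {m}")
    states = np.empty((n, m), dtype=np.int64)
    edges = np.empty((n, levels - 1), dtype=float)
    for i in range(n):
        vals = matrix.values[i]
        sorted_vals = np.sort(vals)
        cut_pos = _choose_cuts(sorted_vals, levels)
        gene_edges = np.array(
            [sorted_vals[p - 1] if p > 0 else -np.inf for p in cut_pos]
        )
        edges[i] = gene_edges
        states[i] = (vals[:, None] > gene_edges[None, :]).sum(axis=1)
    return DiscreteMatrix(
        list(matrix.gene_ids),
        list(matrix.sample_ids),
        states,
        arity=levels,
        bin_edges=edges,
    )


def write_discrete_matrix(
    matrix: DiscreteMatrix, path, edges_path=None
) -> None:
    """Write integer states as TSV; bin edges go to an optional sidecar TSV."""
    matrix.to_frame().to_csv(path, sep="\t", index_label="gene")
    if edges_path is not None and matrix.bin_edges is not None:
        cols = [f"edge{k}" for k in range(matrix.arity - 1)]
        pd.DataFrame(
            matrix.bin_edges, index=matrix.gene_ids, columns=cols
        ).to_csv(edges_path, sep="\t", index_label="gene")


def read_discrete_matrix(path, arity: int = 3) -> DiscreteMatrix:
    """Read an integer state TSV written by :func:`write_discrete_matrix`."""
    df = pd.read_csv(path, sep="\t", header=0, index_col=0)
    states = df.to_numpy(dtype=np.int64)
    observed = int(states.max(initial=0)) + 1
    return DiscreteMatrix(
        [str(g) for g in df.index],
        [str(s) for s in df.columns],
        states,
        arity=max(arity, observed),
    )
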