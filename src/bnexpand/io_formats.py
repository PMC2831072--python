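"""Readers and writers for expression matrices, gene lists, metadata and networks.

All on-disk formats are plain text: tab-delimited matrices (genes as rows,
samples as columns), one-gene-per-line lists, SIF/TSV edge lists, and
TSV/JSON result tables carrying a ``schema_version`` field.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SampleMetadata",
    "NetworkEdgeList",
    "FormatError",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gene_list",
    "find_missing_genes",
    "read_metadata",
    "write_metadata",
    "read_network",
    "write_network",
    "write_results_json",
    "SCHEMA_VERSION",
]

SCHEMA_VERSION = "1.0"

DIRECTED = "directed"
UNDIRECTED = "undirected"

_SIF_RELATION = {DIRECTED: "->", UNDIRECTED: "--"}
_SIF_ORIENTATION = {v: k for k, v in _SIF_RELATION.items()}


class FormatError(ValueError):
    """Malformed input file."""


@dataclass
class ExpressionMatrix:
    """Continuous genes x samples matrix with ordered, unique identifiers."""

    gene_ids: List[str]
    sample_ids: List[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must all be finite")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape

    def row(self, gene: str) -> np.ndarray:
        try:
            i = self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"unknown gene id: {gene!r}") from None
        return self.values[i]

    def subset(self, genes: Sequence[str]) -> "ExpressionMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [index[g] for g in genes]
        return ExpressionMatrix(list(genes), list(self.sample_ids), self.values[rows])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.values, other.values)
        )


@dataclass(frozen=True)
class SampleMetadata:
    """Free-text annotation for one sample (title and description may be empty)."""

    sample_id: str
    title: str = ""
    description: str = ""


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    orientation: str = DIRECTED

    def __post_init__(self) -> None:
        if self.orientation not in (DIRECTED, UNDIRECTED):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.source == self.target:
            raise ValueError(f"self-loop on {self.source!r}")


@dataclass
class NetworkEdgeList:
    """Serializable list of directed/undirected edges without duplicates."""

    edges: List[Edge] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.edges = [e if isinstance(e, Edge) else Edge(*e) for e in self.edges]
        seen = set()
        for e in self.edges:
            key = (e.source, e.target, e.orientation)
            if key in seen:
                raise ValueError(f"duplicate edge {key}")
            seen.add(key)

    def __iter__(self):
        return iter(self.edges)

    def __len__(self) -> int:
        return len(self.edges)


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {kind} id: {x!r}")
        seen.add(x)


def read_expression_matrix(path: str | Path, transpose: bool = False) -> ExpressionMatrix:
    """Read a tab-delimited matrix: first row sample ids, first column gene ids.

    ``transpose=True`` flips a samples-as-rows file into the canonical
    genes-as-rows orientation after reading.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    if transpose:
        df = df.T
    gene_ids = [str(g) for g in df.index]
    sample_ids = [str(s) for s in df.columns]
    _check_unique(gene_ids, "gene")
    _check_unique(sample_ids, "sample")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError:
        for i, g in enumerate(gene_ids):
            for j, s in enumerate(sample_ids):
                try:
                    float(df.iat[i, j])
                except (TypeError, ValueError):
                    raise FormatError(
                        f"non-numeric cell at gene {g!r}, sample {s!r}: "
                        f"{df.iat[i, j]!r}"
                    ) from None
        raise
    if np.any(~np.isfinite(values)):
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise FormatError(
            f"non-finite cell at gene {gene_ids[i]!r}, sample {sample_ids[j]!r}"
        )
    return ExpressionMatrix(gene_ids, sample_ids, values)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        matrix.values, index=matrix.gene_ids, columns=matrix.sample_ids
    )
    df.to_csv(path, sep="\t", index_label="gene")


def read_gene_list(
    path: str | Path, matrix: ExpressionMatrix | None = None
) -> List[str]:
    """Read one identifier per line; '#' comments and blank lines ignored.

    Duplicates are dropped (first occurrence wins, with a warning).  When a
    companion matrix is given, genes absent from it are reported via a
    warning naming each missing id.
    """
    genes: List[str] = []
    seen = set()
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line in seen:
            warnings.warn(f"duplicate gene id in list: {line!r}", stacklevel=2)
            continue
        seen.add(line)
        genes.append(line)
    if not genes:
        raise FormatError(f"gene list {path} is empty")
    if matrix is not None:
        missing = find_missing_genes(genes, matrix)
        if missing:
            warnings.warn(
                "genes absent from expression matrix: " + ", ".join(missing),
                stacklevel=2,
            )
    return genes


def find_missing_genes(
    genes: Iterable[str], matrix: ExpressionMatrix
) -> List[str]:
    present = set(matrix.gene_ids)
    return [g for g in genes if g not in present]


def read_metadata(path: str | Path) -> List[SampleMetadata]:
    """Read a TSV with columns sample_id, title, description."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample_id", "title", "description"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"metadata file must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    _check_unique(list(df["sample_id"]), "sample")
    return [
        SampleMetadata(row.sample_id, row.title, row.description)
        for row in df.itertuples()
    ]


def write_metadata(metadata: Sequence[SampleMetadata], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in metadata],
            "title": [m.title for m in metadata],
            "description": [m.description for m in metadata],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_network(
    network: NetworkEdgeList, path: str | Path, format: str = "sif"
) -> None:
    """Write a network as SIF ("A\\t->\\tB" / "A\\t--\\tB") or 3-column TSV."""
    path = Path(path)
    if format == "sif":
        lines = [
            f"{e.source}\t{_SIF_RELATION[e.orientation]}\t{e.target}"
            for e in network.edges
        ]
        path.write_text("".join(line + "\n" for line in lines))
    elif format == "tsv":
        lines = ["source\ttarget\torientation"]
        lines += [
            f"{e.source}\t{e.target}\t{e.orientation}" for e in network.edges
        ]
        path.write_text("".join(line + "\n" for line in lines))
    else:
        raise ValueError(
            f"unknown network format {format!r}; supported: sif, tsv"
        )


def read_network(path: str | Path, format: str = "sif") -> NetworkEdgeList:
    path = Path(path)
    edges: List[Edge] = []
    if format == "sif":
        for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
            if not raw.strip():
                continue
            parts = raw.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 tab-separated fields")
            src, rel, dst = parts
            if rel not in _SIF_ORIENTATION:
                raise FormatError(f"{path}:{lineno}: unknown relation {rel!r}")
            edges.append(Edge(src, dst, _SIF_ORIENTATION[rel]))
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
        for row in df.itertuples():
            edges.append(Edge(row.source, row.target, row.orientation))
    else:
        raise ValueError(
            f"unknown network format {format!r}; supported: sif, tsv"
        )
    return NetworkEdgeList(edges)


def write_results_json(payload: dict, path: str | Path) -> None:
    """Write a result bundle as JSON with a schema_version stamp."""
    doc = {"schema_version": SCHEMA_VERSION}
    doc.update(payload)
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
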