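"""Term enrichment over discretization bins of a gene pair.

Sample annotations are tokenized into lowercase words; each sample falls
into one joint bin (s_A, s_B) of the selected gene pair (and one marginal
bin per gene).  Term-by-bin association is scored with Fisher's exact test
on the 2x2 table [in-bin/with-term, in-bin/without, out-of-bin/with,
out-of-bin/without], with Benjamini-Hochberg adjustment across all (term,
bin) pairs tested.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
from scipy.special import gammaln

from .io_formats import SampleMetadata
from .preprocess import DiscreteMatrix

__all__ = [
    "TermIndex",
    "EnrichmentRecord",
    "FisherResult",
    "tokenize",
    "assign_bins",
    "fisher_pvalue",
    "enrich_gene_pair",
]

_SPLIT = re.compile(r"[^0-9a-z]+")
#: relative slack used when comparing table probabilities for the two-sided sum
_TWO_SIDED_REL_TOL = 1e-7


@dataclass
class TermIndex:
    """Per-sample token sets plus the pooled vocabulary counts."""

    sample_tokens: Dict[str, Set[str]]
    vocabulary: Dict[str, int]

    def samples_with(self, term: str) -> Set[str]:
        return {s for s, toks in self.sample_tokens.items() if term in toks}


def _tokenize_text(text: str, drop_stopwords: Sequence[str] = ()) -> Set[str]:
    stop = set(drop_stopwords)
    tokens = set()
    for tok in _SPLIT.split(text.lower()):
        if len(tok) < 2 or tok.isdigit() or tok in stop:
            continue
        tokens.add(tok)
    return tokens


def tokenize(
    metadata: Sequence[SampleMetadata], stopwords: Sequence[str] = ()
) -> TermIndex:
    """Lowercase, split on non-alphanumerics, drop 1-char and purely numeric
    tokens.  No stop-word list by default."""
    ids = [m.sample_id for m in metadata]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids in metadata")
    sample_tokens = {
        m.sample_id: _tokenize_text(m.title + " " + m.description, stopwords)
        for m in metadata
    }
    vocab: Dict[str, int] = {}
    for toks in sample_tokens.values():
        for t in toks:
            vocab[t] = vocab.get(t, 0) + 1
    return TermIndex(sample_tokens=sample_tokens, vocabulary=vocab)


def assign_bins(
    states: DiscreteMatrix, gene_a: str, gene_b: str
) -> Dict[str, Tuple[int, int]]:
    """Joint bin label (s_A, s_B) for every sample."""
    row_a = states.row(gene_a)
    row_b = states.row(gene_b)
    return {
        s: (int(a), int(b))
        for s, a, b in zip(states.sample_ids, row_a, row_b)
    }


@dataclass(frozen=True)
class FisherResult:
    two_sided: float
    one_sided: float


def fisher_pvalue(a: int, b: int, c: int, d: int) -> FisherResult:
    """Fisher's exact p-values for the 2x2 table [[a, b], [c, d]].

    Two-sided by the minimum-likelihood rule: sum hypergeometric
    probabilities of all tables with the observed margins whose probability
    is at most that of the observed table (relative slack 1e-7 in the
    comparison).  One-sided is the upper (enrichment) tail P(X >= a).
    """
    for name, x in (("a", a), ("b", b), ("c", c), ("d", d)):
        if x < 0:
            raise ValueError(f"negative count {name}={x}")
    if a + b + c + d == 0:
        raise ValueError("at least one count must be positive")
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    if row1 == 0 or c + d == 0 or col1 == 0 or b + d == 0:
        # a zero margin fixes the table: single-point support, p exactly 1
        return FisherResult(two_sided=1.0, one_sided=1.0)
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    # hypergeometric pmf over the whole support via log-gamma
    logpmf = (
        _log_binom(col1, support)
        + _log_binom(n - col1, row1 - support)
        - _log_binom(n, row1)
    )
    pmf = np.exp(logpmf)
    p_obs = pmf[a - lo]
    two = float(pmf[pmf <= p_obs * (1.0 + _TWO_SIDED_REL_TOL)].sum())
    one = float(pmf[support >= a].sum())
    return FisherResult(two_sided=min(two, 1.0), one_sided=min(one, 1.0))


def _log_binom(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


@dataclass(frozen=True)
class EnrichmentRecord:
    """One (term, bin) association test."""

    term: str
    bin_kind: str  # "joint", "marginal_a" or "marginal_b"
    bin_label: Tuple[int, ...]
    a: int  # in bin, with term
    b: int  # in bin, without term
    c: int  # out of bin, with term
    d: int  # out of bin, without term
    p_one_sided: float
    p_two_sided: float
    adjusted_p: float = float("nan")


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    if len(pvals) == 0:
        return pvals
    return multipletests(pvals, method="fdr_bh")[1]


def enrich_gene_pair(
    states: DiscreteMatrix,
    metadata: Sequence[SampleMetadata],
    gene_a: str,
    gene_b: str,
    min_term_count: int = 3,
    stopwords: Sequence[str] = (),
) -> List[EnrichmentRecord]:
    """Test every sufficiently frequent term against every joint cell and
    marginal bin of the gene pair; BH-adjust across all tests.

    Samples without metadata are excluded with a warning.  Records are
    sorted by adjusted p ascending (ties: raw two-sided p, term, bin).
    """
    index = tokenize(metadata, stopwords)
    covered = [s for s in states.sample_ids if s in index.sample_tokens]
    uncovered = [s for s in states.sample_ids if s not in index.sample_tokens]
    if uncovered:
        warnings.warn(
            f"{len(uncovered)} sample(s) lack metadata and are excluded: "
            + ", ".join(uncovered[:10]),
            stacklevel=2,
        )
    joint = assign_bins(states, gene_a, gene_b)

    # vocabulary restricted to covered samples
    vocab: Dict[str, int] = {}
    for s in covered:
        for t in index.sample_tokens[s]:
            vocab[t] = vocab.get(t, 0) + 1
    terms = sorted(t for t, cnt in vocab.items() if cnt >= min_term_count)

    bins: List[Tuple[str, Tuple[int, ...], Set[str]]] = []
    arity = states.arity
    for sa in range(arity):
        for sb in range(arity):
            members = {s for s in covered if joint[s] == (sa, sb)}
            bins.append(("joint", (sa, sb), members))
    for sa in range(arity):
        members = {s for s in covered if joint[s][0] == sa}
        bins.append(("marginal_a", (sa,), members))
    for sb in range(arity):
        members = {s for s in covered if joint[s][1] == sb}
        bins.append(("marginal_b", (sb,), members))

    n_total = len(covered)
    records: List[EnrichmentRecord] = []
    for term in terms:
        with_term = {s for s in covered if term in index.sample_tokens[s]}
        n_term = len(with_term)
        for kind, label, members in bins:
            a = len(members & with_term)
            b = len(members) - a
            c = n_term - a
            d = n_total - len(members) - c
            p = fisher_pvalue(a, b, c, d)
            records.append(
                EnrichmentRecord(
                    term=term,
                    bin_kind=kind,
                    bin_label=label,
                    a=a,
                    b=b,
                    c=c,
                    d=d,
                    p_one_sided=p.one_sided,
                    p_two_sided=p.two_sided,
                )
            )
    if records:
        adjusted = _bh_adjust(np.array([r.p_two_sided for r in records]))
        records = [
            EnrichmentRecord(
                r.term, r.bin_kind, r.bin_label, r.a, r.b, r.c, r.d,
                r.p_one_sided, r.p_two_sided, float(adj),
            )
            for r, adj in zip(records, adjusted)
        ]
    records.sort(
        key=lambda r: (r.adjusted_p, r.p_two_sided, r.p_one_sided, r.term,
                       r.bin_kind, r.bin_label)
    )
    return records
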