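"""Independent exact-arithmetic oracles used by the test suite.

Everything here is deliberately written from first principles with stdlib
integer/rational arithmetic (fractions, math.comb, math.factorial) and never
imports the package's own scoring, search or enrichment code paths.
"""

from __future__ import annotations

import math
from fractions import Fraction
from typing import Dict, Iterable, List, Sequence, Tuple


# ---------------------------------------------------------------------------
# exact family / network marginal likelihood
# ---------------------------------------------------------------------------

def family_likelihood_exact(
    child_states: Sequence[int],
    parent_rows: Sequence[Sequence[int]],
    arity: int,
) -> Fraction:
    """prod_j (r-1)!/(N_j+r-1)! prod_k N_jk! as an exact rational.

    Unobserved parent configurations contribute a factor of 1 and are
    skipped.
    """
    counts: Dict[Tuple[int, ...], List[int]] = {}
    for s, k in enumerate(child_states):
        cfg = tuple(row[s] for row in parent_rows)
        counts.setdefault(cfg, [0] * arity)[k] += 1
    val = Fraction(1)
    for row in counts.values():
        nj = sum(row)
        val *= Fraction(math.factorial(arity - 1), math.factorial(nj + arity - 1))
        for c in row:
            val *= math.factorial(c)
    return val


def log_fraction(f: Fraction) -> float:
    return math.log(f.numerator) - math.log(f.denominator)


def network_log_score_exact(
    states: Dict[str, Sequence[int]],
    parent_sets: Dict[str, Iterable[str]],
    arity: int,
) -> float:
    """Natural log of the exact-rational product of family terms."""
    total = Fraction(1)
    for node, parents in parent_sets.items():
        rows = [states[p] for p in sorted(parents)]
        total *= family_likelihood_exact(states[node], rows, arity)
    return log_fraction(total)


# ---------------------------------------------------------------------------
# exhaustive DAG enumeration (tiny n)
# ---------------------------------------------------------------------------

def _is_acyclic(n: int, edges: Sequence[Tuple[int, int]]) -> bool:
    indeg = [0] * n
    children: List[List[int]] = [[] for _ in range(n)]
    for u, v in edges:
        children[u].append(v)
        indeg[v] += 1
    stack = [i for i in range(n) if indeg[i] == 0]
    seen = 0
    while stack:
        u = stack.pop()
        seen += 1
        for c in children[u]:
            indeg[c] -= 1
            if indeg[c] == 0:
                stack.append(c)
    return seen == n


def all_dags(n: int) -> List[List[Tuple[int, int]]]:
    """Every labelled DAG on n nodes as an edge list (543 for n=4)."""
    pairs = [(i, j) for i in range(n) for j in range(n) if i != j]
    out = []
    for bits in range(1 << len(pairs)):
        edges = [pairs[k] for k in range(len(pairs)) if (bits >> k) & 1]
        if _is_acyclic(n, edges):
            out.append(edges)
    return out


# ---------------------------------------------------------------------------
# Fisher's exact test by full hypergeometric enumeration
# ---------------------------------------------------------------------------

#: same relative slack used by the implementation's two-sided comparison,
#: applied here exactly in integer arithmetic
_SLACK_NUM = 10_000_001
_SLACK_DEN = 10_000_000


def fisher_exact_oracle(a: int, b: int, c: int, d: int) -> Tuple[Fraction, Fraction]:
    """(one_sided_upper, two_sided) Fisher p-values as exact rationals."""
    n = a + b + c + d
    r1 = a + b  # in-bin row
    c1 = a + c  # with-term column
    denom = math.comb(n, r1)
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    nums = {
        x: math.comb(c1, x) * math.comb(n - c1, r1 - x) for x in range(lo, hi + 1)
    }
    assert sum(nums.values()) == denom  # oracle self-check
    num_obs = nums[a]
    one = Fraction(sum(v for x, v in nums.items() if x >= a), denom)
    two = Fraction(
        sum(v for v in nums.values() if v * _SLACK_DEN <= num_obs * _SLACK_NUM),
        denom,
    )
    return one, two
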