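"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths (and, where feasible, the libraries)
they are checking: the hypergeometric tail is obtained by exhaustive subset
enumeration with exact rational arithmetic, and the KS enrichment score by an
explicit running-sum walk down the ranked list.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import comb


def hypergeom_tail_exact(k: int, K: int, n: int, N: int) -> Fraction:
    """P(X >= k) by enumerating every size-n subset of an N-gene universe
    whose first K elements are the targets."""
    hits = sum(
        1
        for subset in combinations(range(N), n)
        if sum(1 for i in subset if i < K) >= k
    )
    return Fraction(hits, comb(N, n))


def hypergeom_tails_all_k(K: int, n: int, N: int) -> list[Fraction]:
    """P(X >= k) for every k in 0..min(K, n), from one enumeration pass."""
    kmax = min(K, n)
    counts = [0] * (kmax + 1)
    for subset in combinations(range(N), n):
        counts[sum(1 for i in subset if i < K)] += 1
    total = comb(N, n)
    tails = []
    acc = 0
    cum = []
    for k in range(kmax, -1, -1):
        acc += counts[k]
        cum.append(acc)
    cum.reverse()
    return [Fraction(c, total) for c in cum]


def ks_running_sum(positions: tuple[int, ...], N: int) -> float:
    """KS enrichment by walking ranks 1..N with a running positive count."""
    pos = set(positions)
    t = len(positions)
    seen = 0
    best_a = -2.0
    best_b = -2.0
    for rank in range(1, N + 1):
        if rank in pos:
            before = seen / t  # fraction of positives strictly above this rank
            seen += 1
            best_a = max(best_a, seen / t - rank / N)
            best_b = max(best_b, rank / N - before)
    return best_a if best_a >= best_b else -best_b
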