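"""Shared fixtures and independent oracles.

The oracles here are deliberately written from first principles (direct
summation, exhaustive dynamic programming, literal genetic-code table) so
they stay independent of the library paths they check.
"""

from __future__ import annotations

import math

import pytest
from hypothesis import settings

from morphpoly.params import CallThresholds, ErrorModelParams

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def thresholds() -> CallThresholds:
    return CallThresholds()


@pytest.fixture(scope="session")
def model() -> ErrorModelParams:
    return ErrorModelParams()


# ---------------------------------------------------------------------------
# oracle: minimum minor-allele count by direct summation of binomial terms


def brute_force_min_minor_count(depth: int, p: float = 1e-4, L: int = 1000,
                                alpha: float = 0.01, f_min: float = 0.05) -> int:
    """Least k whose error probability over the contig is <= alpha and
    whose read frequency clears f_min; direct summation, no scipy."""
    for k in range(1, depth + 1):
        p_site = sum(
            math.comb(depth, j) * p**j * (1 - p) ** (depth - j)
            for j in range(k, depth + 1)
        )
        p_any = 1.0 - (1.0 - p_site) ** L
        if p_any <= alpha and k / depth >= f_min:
            return k
    return depth + 1


# ---------------------------------------------------------------------------
# oracle: Smith-Waterman local alignment score by exhaustive DP


def smith_waterman_score(read: str, contig: str, match: float = 1.0,
                         mismatch: float = -2.0, gap: float = -2.0) -> float:
    """Best local alignment score; N is neutral (0) against anything."""
    n, m = len(contig), len(read)
    best = 0.0
    prev = [0.0] * (m + 1)
    for i in range(1, n + 1):
        cur = [0.0] * (m + 1)
        for j in range(1, m + 1):
            if "N" in (contig[i - 1], read[j - 1]):
                s = 0.0
            elif contig[i - 1] == read[j - 1]:
                s = match
            else:
                s = mismatch
            cur[j] = max(0.0, prev[j - 1] + s, prev[j] + gap, cur[j - 1] + gap)
            best = max(best, cur[j])
        prev = cur
    return best


# ---------------------------------------------------------------------------
# oracle: two-sided Fisher p by exhaustive margin-preserving enumeration


def fisher_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Sum of hypergeometric probabilities of all same-margin tables at
    most as probable as the observed one (exact rational arithmetic)."""
    from fractions import Fraction

    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0

    def prob(x: int) -> Fraction:
        return Fraction(math.comb(r1, x) * math.comb(r2, c1 - x),
                        math.comb(n, c1))

    p_obs = prob(a)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        if prob(x) <= p_obs:
            total += prob(x)
    return float(total)


# ---------------------------------------------------------------------------
# oracle: standard genetic code as a literal table (TCAG order)


_ORACLE_AAS = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
_TCAG = {"T": 0, "C": 1, "A": 2, "G": 3}


def oracle_translate(codon: str) -> str:
    i = 16 * _TCAG[codon[0]] + 4 * _TCAG[codon[1]] + _TCAG[codon[2]]
    return _ORACLE_AAS[i]


def oracle_classify(codon1: str, codon2: str) -> str:
    aa1, aa2 = oracle_translate(codon1), oracle_translate(codon2)
    if aa1 == aa2:
        return "synonymous"
    if ("*" in (aa1, aa2)) and not (aa1 == "*" and aa2 == "*"):
        return "nonsense"
    return "nonsynonymous"


# ---------------------------------------------------------------------------
# oracle: upper-tail hypergeometric by direct combinatorial summation


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    from fractions import Fraction

    total = Fraction(0)
    for j in range(max(k, max(0, n - (N - K))), min(K, n) + 1):
        total += Fraction(math.comb(K, j) * math.comb(N - K, n - j),
                          math.comb(N, n))
    return float(min(total, Fraction(1)))
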