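"""Binomial error model: the minimum trusted minor-allele count.

At a site of depth D the minor allele is accepted as genuine polymorphism
only if its count k cannot plausibly be explained by sequencing /
reverse-transcription errors anywhere along the contig, and if k/D clears
the minor-allele-frequency floor.
"""

from __future__ import annotations

import math

from scipy.stats import binom

from .params import CallThresholds, ErrorModelParams

__all__ = ["site_error_prob", "contig_error_prob", "min_minor_count"]


def site_error_prob(k: int, depth: int, model: ErrorModelParams) -> float:
    """Probability that errors alone produce (at least) k minor bases at one site.

    Upper tail P(X >= k) for X ~ Binomial(depth, p_err); the point mass
    P(X = k) when ``model.use_tail`` is False.
    """
    if model.use_tail:
        return float(binom.sf(k - 1, depth, model.p_err))
    return float(binom.pmf(k, depth, model.p_err))


def contig_error_prob(k: int, depth: int, model: ErrorModelParams) -> float:
    """Probability that >=1 of L contig positions shows k errors at this depth.

    P_any = 1 - (1 - P_site)^L, computed in log space for small P_site.
    """
    p_site = site_error_prob(k, depth, model)
    if p_site >= 1.0:
        return 1.0
    return -math.expm1(model.contig_len_for_test * math.log1p(-p_site))


def min_minor_count(
    depth: int,
    model: ErrorModelParams = ErrorModelParams(),
    thresholds: CallThresholds = CallThresholds(),
) -> int:
    """Smallest minor-allele count accepted as real polymorphism at ``depth``.

    Returns the least k with contig_error_prob(k, depth) <= alpha and
    k/depth >= f_min.  At depth 4 with the defaults this is 2.  If no
    k <= depth qualifies (vanishingly small alpha), returns ``depth + 1``,
    i.e. the site can never be called polymorphic.

    Raises
    ------
    ValueError
        If ``depth`` is below ``thresholds.d_min`` — the call is undefined
        under the minimum-depth contract.
    """
    if depth < thresholds.d_min:
        raise ValueError(
            f"depth {depth} below minimum callable depth {thresholds.d_min}"
        )
    for k in range(1, depth + 1):
        if k / depth < thresholds.f_min:
            continue
        if contig_error_prob(k, depth, model) <= model.alpha:
            return k
    return depth + 1
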