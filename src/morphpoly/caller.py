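"""Per-site polymorphism calls, cross-population classification, indel scan.

A site is polymorphic within one population when its minor allele(s) pass
both the binomial error filter and the minor-allele-frequency floor.
Sites are then compared across the two populations and classified into the
mutually exclusive classes: shared polymorphism, divergent polymorphism,
polymorphism in one morph only (known / unknown status of the other),
fixed inter-population difference, monomorphic-identical, or undetermined.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
import numpy as np

from .errormodel import min_minor_count
from .params import CallThresholds, ErrorModelParams
from .readprep import BASES, ContigPileup

POLYMORPHIC = "polymorphic"
MONOMORPHIC = "monomorphic"
INSUFFICIENT = "insufficient_depth"

SITE_CLASSES = (
    "shared_polymorphism",
    "divergent_polymorphism",
    "polymorphism_one_morph",
    "polymorphism_one_morph_unknown_other",
    "fixed_difference",
    "monomorphic_identical",
    "undetermined",
)

__all__ = [
    "SiteCall",
    "SiteClassification",
    "call_site",
    "classify_site",
    "scan_contig",
    "scan_indels",
    "SITE_CLASSES",
]


@dataclass(frozen=True)
class SiteCall:
    """Polymorphism status of one site in one population."""

    contig_id: str
    position: int  # 0-based
    population: str
    depth: int
    major_allele: str | None
    minor_allele: str | None
    minor_count: int
    alleles: tuple[str, ...]  # all alleles passing the filter (incl. major)
    status: str


@dataclass(frozen=True)
class SiteClassification:
    """Cross-population class of one site."""

    contig_id: str
    position: int  # 0-based
    site_class: str
    alleles_pop1: tuple[str, ...]
    alleles_pop2: tuple[str, ...]
    depth_pop1: int
    depth_pop2: int


def call_site(
    counts,
    contig_id: str = "contig",
    position: int = 0,
    population: str = "pop1",
    model: ErrorModelParams = ErrorModelParams(),
    thresholds: CallThresholds = CallThresholds(),
) -> SiteCall:
    """Call one site in one population from its A,C,G,T counts.

    ``counts`` is a length-4 sequence ordered A,C,G,T (masked bases must
    already be excluded).  Below ``d_min`` total depth the status is
    ``insufficient_depth``.  Otherwise every non-major base whose count
    reaches ``min_minor_count(depth)`` is retained as a minor allele; the
    site is polymorphic iff at least one is.
    """
    counts = np.asarray(counts, dtype=int)
    if counts.min() < 0:
        raise ValueError("negative base count")
    depth = int(counts.sum())
    if depth < thresholds.d_min:
        return SiteCall(contig_id, position, population, depth,
                        None, None, 0, (), INSUFFICIENT)
    order = sorted(range(4), key=lambda i: (-counts[i], BASES[i]))
    major = BASES[order[0]]
    k_req = min_minor_count(depth, model, thresholds)
    minors = [BASES[i] for i in order[1:] if counts[i] >= k_req]
    minor = minors[0] if minors else None
    minor_count = int(counts[BASES.index(minor)]) if minor else (
        int(counts[order[1]])
    )
    alleles = tuple(sorted([major] + minors))
    status = POLYMORPHIC if minors else MONOMORPHIC
    return SiteCall(contig_id, position, population, depth,
                    major, minor, minor_count if minors else 0,
                    alleles if minors else (major,), status)


def classify_site(call_pop1: SiteCall, call_pop2: SiteCall) -> SiteClassification:
    """Combine the two per-population calls at one site into a site class."""
    if (call_pop1.contig_id, call_pop1.position) != (
        call_pop2.contig_id, call_pop2.position
    ):
        raise ValueError("calls refer to different sites")
    s1, s2 = call_pop1.status, call_pop2.status
    a1, a2 = call_pop1.alleles, call_pop2.alleles

    if s1 == POLYMORPHIC and s2 == POLYMORPHIC:
        cls = ("shared_polymorphism" if set(a1) == set(a2)
               else "divergent_polymorphism")
    elif POLYMORPHIC in (s1, s2):
        other = s2 if s1 == POLYMORPHIC else s1
        if other == MONOMORPHIC:
            cls = "polymorphism_one_morph"
        else:
            cls = "polymorphism_one_morph_unknown_other"
    elif s1 == MONOMORPHIC and s2 == MONOMORPHIC:
        cls = ("monomorphic_identical" if a1 == a2 else "fixed_difference")
    else:
        cls = "undetermined"
    return SiteClassification(
        call_pop1.contig_id, call_pop1.position, cls,
        a1, a2, call_pop1.depth, call_pop2.depth,
    )


def scan_contig(
    pileup: ContigPileup,
    model: ErrorModelParams = ErrorModelParams(),
    thresholds: CallThresholds = CallThresholds(),
) -> tuple[list[SiteClassification], Counter]:
    """Classify every covered site of a contig; return per-class counts.

    A site is covered when either population has non-zero unmasked depth.
    """
    pop1, pop2 = pileup.populations[:2]
    depth = pileup.depth()
    out: list[SiteClassification] = []
    tally: Counter = Counter()
    covered = np.nonzero(depth[:, :2].sum(axis=1) > 0)[0]
    for pos in covered:
        c1 = call_site(pileup.counts[pos, 0], pileup.contig_id, int(pos),
                       pop1, model, thresholds)
        c2 = call_site(pileup.counts[pos, 1], pileup.contig_id, int(pos),
                       pop2, model, thresholds)
        sc = classify_site(c1, c2)
        out.append(sc)
        tally[sc.site_class] += 1
    return out, tally


@dataclass(frozen=True)
class FixedIndel:
    """A population-specific indel fixed in one morph and absent in the other."""

    contig_id: str
    start: int  # 0-based, first affected contig position (deletions)
    length: int
    kind: str  # "deletion" | "insertion"
    population: str
    sequence: str | None = None  # inserted bases, for insertions


def scan_indels(
    pileup: ContigPileup,
    thresholds: CallThresholds = CallThresholds(),
    coding_interval: tuple[int, int] | None = None,
) -> list[FixedIndel]:
    """Report indels fixed within one population and absent from the other.

    A deletion is fixed at a site when every read of one population covering
    the site carries the gap (at depth >= d_min reads) while no read of the
    other population does (also at depth >= d_min).  Adjacent such sites
    merge into one event.  Insertions are reported when every spanning read
    of one population carries an identical insertion and the other
    population's reads (>= d_min spanning either side) carry none.
    Restricted to ``coding_interval`` when given.
    """
    lo, hi = coding_interval if coding_interval else (0, pileup.length)
    dmin = thresholds.d_min
    depth = pileup.depth()
    out: list[FixedIndel] = []

    for p, pop in enumerate(pileup.populations[:2]):
        q = 1 - p
        run_start = None
        for pos in range(lo, hi + 1):
            fixed_here = False
            if pos < hi:
                cov_p = depth[pos, p] + pileup.gaps[pos, p]
                cov_q = depth[pos, q] + pileup.gaps[pos, q]
                fixed_here = (
                    cov_p >= dmin
                    and pileup.gaps[pos, p] == cov_p
                    and cov_q >= dmin
                    and pileup.gaps[pos, q] == 0
                )
            if fixed_here and run_start is None:
                run_start = pos
            elif not fixed_here and run_start is not None:
                out.append(FixedIndel(pileup.contig_id, run_start,
                                      pos - run_start, "deletion",
                                      pileup.populations[p]))
                run_start = None

        ins_here: Counter = Counter()
        for ipos, iseq in pileup.insertions.get(pop, []):
            if lo <= ipos < hi:
                ins_here[(ipos, iseq)] += 1
        other_ins = {ipos for ipos, _ in
                     pileup.insertions.get(pileup.populations[q], [])}
        for (ipos, iseq), n in sorted(ins_here.items()):
            span_p = min(depth[max(ipos - 1, lo), p], depth[min(ipos, hi - 1), p])
            span_q = min(depth[max(ipos - 1, lo), q], depth[min(ipos, hi - 1), q])
            if n >= dmin and n >= span_p and span_q >= dmin and ipos not in other_ins:
                out.append(FixedIndel(pileup.contig_id, ipos, len(iseq),
                                      "insertion", pileup.populations[p], iseq))
    return sorted(out, key=lambda e: (e.start, e.population, e.kind))
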