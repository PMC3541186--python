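"""Read cleaning, stringent realignment to contigs, and per-population pileups.

Coordinates are 0-based half-open internally; human-readable outputs are
1-based.  Populations are identified by the string labels used when the
reads were loaded (conventionally ``pop1``/``pop2``, i.e. the two morphs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .params import CallThresholds

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

__all__ = [
    "BASES",
    "AlignedRead",
    "ContigPileup",
    "trim_low_quality",
    "mask_low_quality",
    "make_aligner",
    "align_read_to_contig",
    "build_pileup",
    "select_contigs_per_ortholog",
]


def trim_low_quality(
    read: str,
    qualities: Sequence[int],
    thresholds: CallThresholds = CallThresholds(),
) -> tuple[str, list[int]] | None:
    """Trim low-quality extremities; reject reads left too short.

    From each end a window of ``trim_window`` bases slides inward in steps of
    ``trim_step`` while its mean quality is below ``q_min``; any residual
    terminal bases individually below ``q_min`` are then stripped.  Returns
    the trimmed (read, qualities) or None when fewer than
    ``min_read_length`` bases survive.
    """
    if len(read) != len(qualities):
        raise ValueError("read and qualities must have equal length")
    q = np.asarray(qualities, dtype=float)
    n = len(q)
    w, s, qmin = thresholds.trim_window, thresholds.trim_step, thresholds.q_min

    start = 0
    while start < n and np.mean(q[start : start + w]) < qmin:
        start += s
    end = n
    while end > start and np.mean(q[max(start, end - w) : end]) < qmin:
        end -= s
    # strip residual sub-threshold terminal bases left behind by the stride
    while start < end and q[start] < qmin:
        start += 1
    while end > start and q[end - 1] < qmin:
        end -= 1

    if end - start < thresholds.min_read_length:
        return None
    return read[start:end], list(qualities[start:end])


def mask_low_quality(
    read: str,
    qualities: Sequence[int],
    thresholds: CallThresholds = CallThresholds(),
) -> str:
    """Replace every base with quality strictly below ``q_min`` by ``N``."""
    if len(read) != len(qualities):
        raise ValueError("read and qualities must have equal length")
    return "".join(
        "N" if q < thresholds.q_min else b for b, q in zip(read, qualities)
    )


def make_aligner() -> Align.PairwiseAligner:
    """Local aligner with the stringent EST-to-contig scoring.

    Match +1, mismatch -2, gap opening free, each gapped base -2; ``N``
    is neutral (0) against everything so masked bases neither reward nor
    penalise the alignment.  Gap opening carries an infinitesimal extra
    cost (1e-6) purely as a tie-break so that, among co-optimal
    alignments, contiguous gaps are preferred over split ones — a
    deterministic canonical placement for the indel scan.
    """
    matrix = substitution_matrices.Array("ACGTN", dims=2)
    for a in "ACGTN":
        for b in "ACGTN":
            if "N" in (a, b):
                matrix[a, b] = 0.0
            else:
                matrix[a, b] = 1.0 if a == b else -2.0
    aligner = Align.PairwiseAligner(mode="local")
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -2.0 - 1e-6
    aligner.extend_gap_score = -2.0
    return aligner


_ALIGNER = make_aligner()


@dataclass
class AlignedRead:
    """Per-position correspondence of one read to its contig.

    ``columns`` holds (contig_pos, read_base) pairs over the aligned region,
    with ``"-"`` as the read base where the read has a deletion relative to
    the contig.  ``insertions`` lists (contig_pos, inserted_sequence) for
    read bases absent from the contig, keyed by the contig position they
    precede.  ``N`` read bases are carried but treated as masked downstream.
    """

    read_id: str
    contig_id: str
    population: str
    score: float
    columns: list[tuple[int, str]] = field(default_factory=list)
    insertions: list[tuple[int, str]] = field(default_factory=list)

    @property
    def aligned_unmasked_length(self) -> int:
        return sum(1 for _, b in self.columns if b in BASE_INDEX)


def align_read_to_contig(
    read: str,
    contig: str,
    read_id: str = "read",
    contig_id: str = "contig",
    population: str = "pop1",
    score_floor: float = 0.5,
) -> AlignedRead | None:
    """Locally align a masked read to its contig; reject improper alignments.

    The alignment must score at least ``score_floor`` times the number of
    unmasked bases in the read, otherwise the read is considered not to
    align properly and is dropped (returns None) — a floor relative to the
    read length, so short spurious local matches cannot qualify.  Only the
    aligned region contributes to pileups.  Alignment is forward-strand
    only: the cDNA libraries are directional.
    """
    if not read:
        return None
    unmasked_len = sum(1 for b in read if b in BASE_INDEX)
    alignments = _ALIGNER.align(contig, read)
    try:
        best = alignments[0]
    except IndexError:
        return None

    out = AlignedRead(read_id, contig_id, population, float(best.score))
    blocks_t, blocks_q = best.aligned
    prev_t_end = prev_q_end = None
    for (t0, t1), (q0, q1) in zip(blocks_t, blocks_q):
        if prev_t_end is not None:
            if t0 > prev_t_end:  # deletion in the read
                for pos in range(prev_t_end, t0):
                    out.columns.append((pos, "-"))
            if q0 > prev_q_end:  # insertion in the read
                out.insertions.append((t0, read[prev_q_end:q0]))
        for pos, qpos in zip(range(t0, t1), range(q0, q1)):
            out.columns.append((pos, read[qpos]))
        prev_t_end, prev_q_end = t1, q1

    if out.score < score_floor * max(unmasked_len, 1):
        return None
    return out


@dataclass
class ContigPileup:
    """Per-site, per-population base counts over one contig.

    ``counts`` has shape (length, n_populations, 4) over A,C,G,T; masked
    (N) bases contribute to no count.  ``gaps`` counts reads with a deletion
    spanning the site.  Per-site depth is the sum of the four base counts.
    """

    contig_id: str
    length: int
    populations: tuple[str, ...]
    counts: np.ndarray
    gaps: np.ndarray
    aligned_read_count: dict[str, int]
    insertions: dict[str, list[tuple[int, str]]] = field(default_factory=dict)

    def depth(self) -> np.ndarray:
        """(length, n_populations) total unmasked depth."""
        return self.counts.sum(axis=2)

    def pop_index(self, population: str) -> int:
        return self.populations.index(population)

    def mean_depth(self) -> float:
        """Mean per-site depth summed over populations."""
        if self.length == 0:
            return 0.0
        return float(self.depth().sum() / self.length)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (1-based positions) for TSV export."""
        rows = []
        for p, pop in enumerate(self.populations):
            for pos in range(self.length):
                a, c, g, t = (int(x) for x in self.counts[pos, p])
                rows.append(
                    (self.contig_id, pos + 1, pop, a, c, g, t,
                     int(self.gaps[pos, p]))
                )
        return pd.DataFrame(
            rows,
            columns=["contig", "pos", "pop", "nA", "nC", "nG", "nT", "nGap"],
        )


def build_pileup(
    contig_id: str,
    contig_length: int,
    aligned_reads: Iterable[AlignedRead],
    populations: tuple[str, ...] = ("pop1", "pop2"),
) -> ContigPileup:
    """Tally aligned read bases per site and population.

    N bases are excluded from all counts (and hence from depth); deletions
    are tallied separately in ``gaps``.
    """
    counts = np.zeros((contig_length, len(populations), 4), dtype=np.int32)
    gaps = np.zeros((contig_length, len(populations)), dtype=np.int32)
    n_reads = {pop: 0 for pop in populations}
    insertions: dict[str, list[tuple[int, str]]] = {pop: [] for pop in populations}
    for ar in aligned_reads:
        if ar.population not in n_reads:
            raise ValueError(f"unknown population label {ar.population!r}")
        p = populations.index(ar.population)
        n_reads[ar.population] += 1
        for pos, base in ar.columns:
            if base == "-":
                gaps[pos, p] += 1
            else:
                idx = BASE_INDEX.get(base)
                if idx is not None:
                    counts[pos, p, idx] += 1
        insertions[ar.population].extend(ar.insertions)
    return ContigPileup(
        contig_id, contig_length, tuple(populations), counts, gaps,
        n_reads, insertions,
    )


def select_contigs_per_ortholog(
    mean_depths: Mapping[str, float],
    hits: pd.DataFrame,
) -> list[str]:
    """Keep one contig per outgroup protein hit: the deepest one.

    ``hits`` must have columns ``contig_id`` and ``protein_id``.  Contigs
    without a hit are dropped; depth ties break to the lexicographically
    smallest contig_id for determinism.  Keeping a single contig per protein
    avoids double-counting the same polymorphic site assembled into two
    contigs.
    """
    df = hits[["contig_id", "protein_id"]].copy()
    df = df[df["contig_id"].isin(mean_depths.keys())]
    df["depth"] = df["contig_id"].map(mean_depths)
    df = df.sort_values(
        ["protein_id", "depth", "contig_id"],
        ascending=[True, False, True],
    )
    kept = df.groupby("protein_id", sort=True).head(1)
    return sorted(kept["contig_id"].tolist())
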