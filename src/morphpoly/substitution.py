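"""Coding-frame projection and amino-acid analysis of fixed differences.

Fixed inter-population differences are projected onto the coding frame by
aligning the translated contig to its outgroup protein (which delimits the
coding region), classified as synonymous / non-synonymous / nonsense under
the standard genetic code, polarized by outgroup parsimony (a substitution
is assigned to the lineage whose residue differs from the outgroup's), and
scored as radical when the two residues fall in different physicochemical
classes.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .codons import AMINO_ACIDS, CODON_TO_AA, translate_codon
from .params import CallThresholds
from .readprep import BASES, ContigPileup

# Default 6-class physicochemical scheme. The class names are fixed by the
# analysis (hydrophobic, aromatic, polar neutral, acidic, basic, proline);
# the membership of C, G and H is a documented choice — see docs/methods.md.
DEFAULT_AA_CLASSES: dict[str, str] = {
    **{aa: "hydrophobic" for aa in "GAVLIMC"},
    **{aa: "aromatic" for aa in "FYW"},
    **{aa: "polar_neutral" for aa in "STNQ"},
    **{aa: "acidic" for aa in "DE"},
    **{aa: "basic" for aa in "KRH"},
    "P": "proline",
}

__all__ = [
    "DEFAULT_AA_CLASSES",
    "load_aa_scheme",
    "validate_aa_scheme",
    "CodingProjection",
    "CodingSubstitution",
    "PrematureStop",
    "project_coding_frame",
    "consensus_per_population",
    "classify_substitution",
    "orient_substitution",
    "is_radical",
    "project_fixed_differences",
    "detect_premature_stop",
    "tabulate_lineage_counts",
]


def validate_aa_scheme(scheme: Mapping[str, str]) -> None:
    if set(scheme) != set(AMINO_ACIDS):
        raise ValueError("scheme must assign exactly the 20 standard amino acids")
    by_class: dict[str, list[str]] = defaultdict(list)
    for aa, cls in scheme.items():
        by_class[cls].append(aa)
    if by_class.get(scheme["P"]) != ["P"]:
        raise ValueError("proline must form a singleton class")


def load_aa_scheme(path) -> dict[str, str]:
    """Load an amino-acid class scheme from a YAML/JSON mapping file."""
    import yaml

    with open(path) as fh:
        scheme = yaml.safe_load(fh)
    scheme = {str(k): str(v) for k, v in scheme.items()}
    validate_aa_scheme(scheme)
    return scheme


def is_radical(aa1: str, aa2: str,
               scheme: Mapping[str, str] = DEFAULT_AA_CLASSES) -> bool:
    """True when the two residues fall in different physicochemical classes."""
    for aa in (aa1, aa2):
        if aa not in scheme:
            raise ValueError(f"non-standard residue {aa!r}")
    return scheme[aa1] != scheme[aa2]


def classify_substitution(codon1: str, codon2: str) -> str | None:
    """synonymous / nonsynonymous / nonsense for a pair of differing codons.

    Returns None (substitution skipped) when either codon contains an
    ambiguous base.  ``nonsense`` means exactly one side translates to a
    stop; two stops cannot arise from a single fixed difference at a sense
    ancestor and are classified synonymous by translation identity.
    """
    if len(codon1) != 3 or len(codon2) != 3:
        raise ValueError("codons must have length 3")
    aa1, aa2 = translate_codon(codon1), translate_codon(codon2)
    if aa1 is None or aa2 is None:
        return None
    if aa1 == aa2:
        return "synonymous"
    if (aa1 == "*") != (aa2 == "*"):
        return "nonsense"
    return "nonsynonymous"


def orient_substitution(aa_pop1: str, aa_pop2: str,
                        aa_outgroup: str | None) -> str:
    """Parsimony polarization of an amino-acid difference.

    The outgroup matching one population's residue places the mutation on
    the other population's lineage; an outgroup residue different from both
    (or missing) leaves the substitution unoriented.
    """
    if aa_pop1 == aa_pop2:
        raise ValueError("orientation requires differing residues")
    if aa_outgroup is None:
        return "unoriented"
    if aa_outgroup == aa_pop2:
        return "pop1"
    if aa_outgroup == aa_pop1:
        return "pop2"
    return "unoriented"


# ---------------------------------------------------------------------------
# coding-frame projection


def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner(mode="local")
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


_PROT_ALIGNER = _protein_aligner()


@dataclass
class CodingProjection:
    """Best forward reading frame of a contig against its outgroup protein.

    ``interval`` is the contig-coordinate span (0-based half-open, length a
    multiple of 3) covered by the protein alignment; ``codon_to_outgroup``
    maps codon indices within the interval to the aligned outgroup residue
    (absent where the outgroup has a gap); ``last_aligned_codon`` is the
    interval codon index aligned to the outgroup C-terminal-most residue.
    """

    contig_id: str
    protein_id: str
    frame: int
    interval: tuple[int, int]
    identity: float
    n_aligned: int
    codon_to_outgroup: dict[int, str] = field(default_factory=dict)

    @property
    def n_codons(self) -> int:
        return (self.interval[1] - self.interval[0]) // 3

    @property
    def last_aligned_codon(self) -> int:
        return max(self.codon_to_outgroup)


def _translate_frame(seq: str, frame: int) -> str:
    sub = seq[frame:]
    sub = sub[: len(sub) - len(sub) % 3]
    return "".join(
        CODON_TO_AA.get(sub[i : i + 3].upper(), "X")
        for i in range(0, len(sub), 3)
    )


def project_coding_frame(
    contig_seq: str,
    outgroup_protein: str,
    contig_id: str = "contig",
    protein_id: str = "protein",
    min_identity: float = 0.4,
    min_aligned: int = 30,
) -> CodingProjection | None:
    """Select the forward frame whose translation best matches the outgroup.

    All three forward frames are translated and locally aligned (BLOSUM62)
    to the outgroup protein; the best-scoring frame defines the coding
    interval, and the residue-level correspondence is retained to polarize
    substitutions.  Projections with < ``min_identity`` identity over
    < ``min_aligned`` aligned residues are rejected (returns None) —
    the contig is treated as non-coding or mis-assigned.
    """
    best = None
    for frame in range(3):
        pep = _translate_frame(contig_seq, frame)
        if not pep or not outgroup_protein:
            continue
        alns = _PROT_ALIGNER.align(pep, outgroup_protein)
        try:
            aln = alns[0]
        except IndexError:
            continue
        if best is None or aln.score > best[1].score:
            best = (frame, aln, pep)
    if best is None:
        return None
    frame, aln, pep = best

    blocks_q, blocks_t = aln.aligned  # query = translated contig
    n_aligned = 0
    n_ident = 0
    codon_map: dict[int, str] = {}
    q_start = int(blocks_q[0][0])
    q_end = int(blocks_q[-1][1])
    for (q0, q1), (t0, t1) in zip(blocks_q, blocks_t):
        for qi, ti in zip(range(q0, q1), range(t0, t1)):
            n_aligned += 1
            if pep[qi] == outgroup_protein[ti]:
                n_ident += 1
            codon_map[qi - q_start] = outgroup_protein[ti]
    identity = n_ident / n_aligned if n_aligned else 0.0
    if n_aligned < min_aligned or identity < min_identity:
        return None
    interval = (frame + 3 * q_start, frame + 3 * q_end)
    return CodingProjection(contig_id, protein_id, frame, interval,
                            identity, n_aligned, codon_map)


# ---------------------------------------------------------------------------
# consensus sequences


def consensus_per_population(
    pileup: ContigPileup,
    reference_seq: str,
    thresholds: CallThresholds = CallThresholds(),
) -> dict[str, tuple[str, np.ndarray]]:
    """Majority-allele consensus per population.

    Sites below ``d_min`` depth fall back to the reference contig base and
    are flagged untrusted; majority ties also fall back to the reference
    base and are flagged.  Returns {population: (sequence, untrusted)}.
    """
    out: dict[str, tuple[str, np.ndarray]] = {}
    for p, pop in enumerate(pileup.populations):
        seq = list(reference_seq)
        untrusted = np.zeros(pileup.length, dtype=bool)
        counts = pileup.counts[:, p, :]
        depth = counts.sum(axis=1)
        for pos in range(pileup.length):
            if depth[pos] < thresholds.d_min:
                untrusted[pos] = True
                continue
            c = counts[pos]
            top = c.max()
            winners = [BASES[i] for i in range(4) if c[i] == top]
            if len(winners) == 1:
                seq[pos] = winners[0]
            else:
                untrusted[pos] = True  # ambiguous tie: keep reference base
        out[pop] = ("".join(seq), untrusted)
    return out


# ---------------------------------------------------------------------------
# fixed differences at the codon level


@dataclass
class CodingSubstitution:
    """A fixed difference (or co-located pair) projected onto one codon."""

    contig_id: str
    codon_index: int  # within the coding interval
    nucleotide_positions: tuple[int, ...]  # contig coordinates, 0-based
    codon_pop1: str
    codon_pop2: str
    aa_pop1: str
    aa_pop2: str
    aa_outgroup: str | None
    kind: str  # synonymous | nonsynonymous | nonsense
    lineage: str | None  # pop1 | pop2 | unoriented; None for synonymous
    radical: bool | None  # None unless nonsynonymous


def project_fixed_differences(
    projection: CodingProjection,
    consensus_pop1: str,
    consensus_pop2: str,
    fixed_positions: Iterable[int],
    scheme: Mapping[str, str] = DEFAULT_AA_CLASSES,
) -> list[CodingSubstitution]:
    """Group fixed differences by codon and classify at the amino-acid level.

    Positions outside the coding interval are ignored.  A codon carrying
    two fixed differences yields a single amino-acid-level substitution
    (the nucleotide-level tally keeps both positions).  Codons containing
    ambiguous bases are skipped.
    """
    lo, hi = projection.interval
    by_codon: dict[int, list[int]] = defaultdict(list)
    for pos in fixed_positions:
        if lo <= pos < hi:
            by_codon[(pos - lo) // 3].append(pos)

    out: list[CodingSubstitution] = []
    for ci in sorted(by_codon):
        c1 = consensus_pop1[lo + 3 * ci: lo + 3 * ci + 3]
        c2 = consensus_pop2[lo + 3 * ci: lo + 3 * ci + 3]
        kind = classify_substitution(c1, c2) if c1 != c2 else None
        if kind is None:
            continue  # ambiguous codon (or consensus tie erased the diff)
        aa1, aa2 = translate_codon(c1), translate_codon(c2)
        aa_out = projection.codon_to_outgroup.get(ci)
        if kind == "synonymous":
            lineage, radical = None, None
        else:
            lineage = orient_substitution(aa1, aa2, aa_out)
            radical = (is_radical(aa1, aa2, scheme)
                       if kind == "nonsynonymous" else None)
        out.append(CodingSubstitution(
            projection.contig_id, ci, tuple(sorted(by_codon[ci])),
            c1, c2, aa1, aa2, aa_out, kind, lineage, radical,
        ))
    return out


@dataclass
class PrematureStop:
    """An in-frame stop in one population upstream of the aligned C-terminus."""

    contig_id: str
    codon_index: int
    population: str
    codon: str
    truncated_fraction: float  # fraction of the outgroup-aligned protein lost


def detect_premature_stop(
    projection: CodingProjection,
    consensus_pop1: str,
    consensus_pop2: str,
) -> list[PrematureStop]:
    """Stops present in exactly one population before the aligned C-terminus.

    A stop at the codon aligned to the outgroup C-terminal residue (or
    beyond) is not premature and is not reported.
    """
    lo, _ = projection.interval
    c_term = projection.last_aligned_codon
    events: list[PrematureStop] = []
    for ci in range(min(c_term, projection.n_codons)):
        c1 = consensus_pop1[lo + 3 * ci: lo + 3 * ci + 3]
        c2 = consensus_pop2[lo + 3 * ci: lo + 3 * ci + 3]
        t1, t2 = translate_codon(c1), translate_codon(c2)
        stops = [(pop, codon) for pop, t, codon in
                 (("pop1", t1, c1), ("pop2", t2, c2)) if t == "*"]
        if len(stops) == 1:
            pop, codon = stops[0]
            events.append(PrematureStop(
                projection.contig_id, ci, pop, codon,
                (c_term - ci) / (c_term + 1),
            ))
    return events


def tabulate_lineage_counts(
    substitutions: Sequence[CodingSubstitution],
) -> pd.DataFrame:
    """Contingency cube: counts by kind x lineage x radical flag.

    The margins reproduce the analysis bookkeeping: synonymous +
    nonsynonymous + nonsense = all classified codon-level substitutions,
    and the pop1/pop2/unoriented lineage counts sum to nonsynonymous +
    nonsense.
    """
    rows = []
    for s in substitutions:
        rows.append((s.kind, s.lineage if s.lineage else "n/a",
                     {True: "radical", False: "conservative",
                      None: "n/a"}[s.radical]))
    df = pd.DataFrame(rows, columns=["kind", "lineage", "radical"])
    if df.empty:
        return pd.DataFrame(columns=["kind", "lineage", "radical", "count"])
    out = (df.value_counts(["kind", "lineage", "radical"])
             .rename("count").reset_index()
             .sort_values(["kind", "lineage", "radical"])
             .reset_index(drop=True))
    return out
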