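"""Standard genetic code helpers (nuclear transcripts only)."""

from __future__ import annotations

from Bio.Data.CodonTable import standard_dna_table

CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_TO_AA[_stop] = "*"

SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c, aa in CODON_TO_AA.items() if aa != "*")
)
STOP_CODONS: tuple[str, ...] = tuple(sorted(standard_dna_table.stop_codons))
AMINO_ACIDS: tuple[str, ...] = tuple(sorted(set(standard_dna_table.forward_table.values())))


def translate_codon(codon: str) -> str | None:
    """Amino acid (or '*') for a codon; None if it contains an ambiguous base."""
    return CODON_TO_AA.get(codon.upper())


def translate_cds(seq: str) -> str:
    """Translate a frame-0 nucleotide string, 'X' at ambiguous codons."""
    return "".join(
        CODON_TO_AA.get(seq[i : i + 3].upper(), "X")
        for i in range(0, len(seq) - len(seq) % 3, 3)
    )
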