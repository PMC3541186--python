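"""Synthetic two-population EST datasets with known ground truth.

The generator emulates the sampling design the pipeline assumes: two
populations (morphs) descended from a common ancestor, each represented by
a pool of at most ``2 * n_individuals_per_pop`` alleles; within-population
polymorphic sites planted at a chosen minor-allele frequency; fixed
inter-population differences planted at a chosen per-base rate inside the
coding sequence (with a chosen fraction at non-synonymous codon positions);
full-length reads drawn per site around a mean depth, with independent
per-base errors (default 1e-4) and a two-point quality model straddling the
Q20 mask threshold; and an outgroup protein diverged from the ancestral
translation, which serves to orient substitutions by parsimony.

Every planted event is recorded in a :class:`SyntheticTruth` so downstream
stages can be scored for recovery.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .codons import CODON_TO_AA, SENSE_CODONS, translate_cds

BASES = "ACGT"

# SeedSequence spawn keys: one fixed stream per stage, all derived from the
# single run seed.
_STAGE_REFERENCE = 1
_STAGE_VARIANTS = 2
_STAGE_READS = 3
_STAGE_ANNOTATION = 4

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "Reference",
    "SimulatedRead",
    "Dataset",
    "generate_reference",
    "plant_variants",
    "simulate_reads",
    "simulate_dataset",
    "simulate_annotation",
    "write_dataset",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of a synthetic two-population EST dataset.

    Defaults follow the original study design where it states a value:
    per-base error rate 1e-4, mean read depth 6.8 per population, at least
    10 breeding individuals per morph (hence 20 sampled alleles and a 0.05
    observable allele-frequency floor), mean contig length ~985 bp (rounded
    to the codon multiple 984), a genome-wide fixed-difference density of
    ~1.5e-4 per coding base and ~24% of fixed differences non-synonymous.
    """

    n_contigs: int = 200
    contig_length: int = 984
    n_individuals_per_pop: int = 10
    polymorphic_site_rate: float = 5e-4  # per base, per population
    minor_allele_freq: float = 0.25
    fixed_diff_rate: float = 1.5e-4  # per coding base
    nonsyn_fraction: float = 0.24
    fixed_diff_pop1_fraction: float = 0.5  # share of fixed diffs on pop1's lineage
    depth_mean: float = 6.8  # reads per site per population
    error_rate: float = 1e-4
    q_low_fraction: float = 0.05
    outgroup_protein_divergence: float = 0.15
    noncoding_flank_frac: float = 0.0  # fraction of contig that is non-coding
    read_length: int | None = None  # None = full-contig-length reads
    q_low: int = 15
    q_high: int = 38
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("polymorphic_site_rate", "fixed_diff_rate",
                     "nonsyn_fraction", "error_rate", "q_low_fraction",
                     "outgroup_protein_divergence", "noncoding_flank_frac",
                     "fixed_diff_pop1_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.contig_length % 3 != 0:
            raise ValueError("contig_length must be divisible by 3")
        if not (0.0 < self.minor_allele_freq <= 0.5):
            raise ValueError("minor_allele_freq must lie in (0, 0.5]")
        if self.n_contigs < 1 or self.n_individuals_per_pop < 1:
            raise ValueError("n_contigs and n_individuals_per_pop must be >= 1")
        if self.depth_mean < 0:
            raise ValueError("depth_mean must be non-negative")

    def rng(self, stage: int) -> np.random.Generator:
        """Stage-specific generator derived from the single run seed."""
        return np.random.default_rng(np.random.SeedSequence([stage, self.seed]))


@dataclass
class PlantedPolymorphism:
    contig: str
    site: int  # 0-based contig position
    population: str
    major_allele: str
    minor_allele: str
    minor_hap_count: int  # haplotypes carrying the minor allele
    frequency: float  # realized minor-allele frequency in the pool


@dataclass
class PlantedFixedDiff:
    contig: str
    site: int
    allele_pop1: str
    allele_pop2: str
    is_nonsynonymous: bool
    lineage: str  # which population's allele is derived: "pop1" | "pop2"
    codon_index: int  # 0-based within the CDS
    aa_pop1: str
    aa_pop2: str
    aa_outgroup: str
    expected_orientation: str | None  # parsimony answer; None for synonymous


@dataclass
class SyntheticTruth:
    """Ground truth emitted by the generator for recovery scoring."""

    planted_polymorphisms: list[PlantedPolymorphism] = field(default_factory=list)
    planted_fixed_diffs: list[PlantedFixedDiff] = field(default_factory=list)
    # (population, read_id, offset, true_base, observed_base)
    error_positions: list[tuple[str, str, int, str, str]] = field(default_factory=list)
    cds_intervals: dict[str, tuple[int, int]] = field(default_factory=dict)
    outgroup_mutated_residues: dict[str, list[int]] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "planted_polymorphisms": [dataclasses.asdict(p)
                                      for p in self.planted_polymorphisms],
            "planted_fixed_diffs": [dataclasses.asdict(p)
                                    for p in self.planted_fixed_diffs],
            "error_positions": [list(e) for e in self.error_positions],
            "cds_intervals": {k: list(v) for k, v in self.cds_intervals.items()},
            "outgroup_mutated_residues": self.outgroup_mutated_residues,
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        return cls(
            [PlantedPolymorphism(**p) for p in d["planted_polymorphisms"]],
            [PlantedFixedDiff(**p) for p in d["planted_fixed_diffs"]],
            [tuple(e) for e in d["error_positions"]],
            {k: tuple(v) for k, v in d["cds_intervals"].items()},
            {k: list(v) for k, v in d["outgroup_mutated_residues"].items()},
        )


@dataclass
class Reference:
    """Ancestral contigs, their CDS intervals and diverged outgroup proteins."""

    contigs: dict[str, str]
    cds_intervals: dict[str, tuple[int, int]]
    outgroup_proteins: dict[str, str]
    protein_ids: dict[str, str]  # contig -> outgroup protein id


@dataclass
class SimulatedRead:
    read_id: str
    contig_id: str
    population: str
    start: int  # offset of the read on its contig
    sequence: str
    qualities: list[int]


@dataclass
class Dataset:
    config: SimulationConfig
    reference: Reference
    pools: dict[str, dict[str, np.ndarray]]  # contig -> pop -> (2n, L) chars
    reads: list[SimulatedRead]
    truth: SyntheticTruth


def generate_reference(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[Reference, SyntheticTruth]:
    """Ancestral coding contigs plus diverged outgroup proteins.

    The CDS is built from uniformly drawn sense codons, so it carries no
    in-frame stop.  Optional non-coding flanks are random nucleotide
    sequence.  Each outgroup protein is the ancestral translation with
    each residue independently mutated (to a different amino acid) with
    probability ``outgroup_protein_divergence``; mutated residue indices
    are recorded in the truth.
    """
    rng = rng if rng is not None else config.rng(_STAGE_REFERENCE)
    truth = SyntheticTruth()
    contigs: dict[str, str] = {}
    cds: dict[str, tuple[int, int]] = {}
    proteins: dict[str, str] = {}
    pids: dict[str, str] = {}

    L = config.contig_length
    flank_total = int(round(L * config.noncoding_flank_frac))
    left = flank_total // 2
    cds_len = L - flank_total
    cds_len -= cds_len % 3
    if cds_len < 3:
        raise ValueError("non-coding flanks leave no coding sequence")

    for i in range(config.n_contigs):
        cid = f"contig{i:04d}"
        codons = rng.choice(len(SENSE_CODONS), size=cds_len // 3)
        cds_seq = "".join(SENSE_CODONS[j] for j in codons)
        lflank = "".join(rng.choice(list(BASES), size=left)) if left else ""
        right = L - left - cds_len
        rflank = "".join(rng.choice(list(BASES), size=right)) if right else ""
        contigs[cid] = lflank + cds_seq + rflank
        cds[cid] = (left, left + cds_len)

        protein = list(translate_cds(cds_seq))
        hit = rng.random(len(protein)) < config.outgroup_protein_divergence
        mutated: list[int] = []
        for j in np.nonzero(hit)[0]:
            alt = [a for a in "ACDEFGHIKLMNPQRSTVWY" if a != protein[j]]
            protein[j] = alt[rng.integers(len(alt))]
            mutated.append(int(j))
        proteins[cid] = "".join(protein)
        pids[cid] = f"outprot{i:04d}"
        truth.outgroup_mutated_residues[cid] = mutated

    truth.cds_intervals = dict(cds)
    return Reference(contigs, cds, proteins, pids), truth


def _codon_change_options(codon: str, pos_in_codon: int) -> dict[str, list[str]]:
    """Alternative bases at one codon position, split syn/nonsyn (no stops)."""
    aa0 = CODON_TO_AA[codon]
    options: dict[str, list[str]] = {"syn": [], "nonsyn": []}
    for alt in BASES:
        if alt == codon[pos_in_codon]:
            continue
        new = codon[:pos_in_codon] + alt + codon[pos_in_codon + 1:]
        aa1 = CODON_TO_AA[new]
        if aa1 == "*":
            continue
        options["syn" if aa1 == aa0 else "nonsyn"].append(alt)
    return options


def plant_variants(
    reference: Reference,
    config: SimulationConfig,
    truth: SyntheticTruth,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, dict[str, np.ndarray]], SyntheticTruth]:
    """Derive the two population haplotype pools from the ancestor.

    Fixed differences are planted one per CDS codon (never in the first or
    last CDS codon: a variant within ~2 bp of a read end is structurally
    uncallable under the stringent local alignment); polymorphic sites are
    planted per population at the configured rate and minor-allele
    frequency, disjoint from the fixed differences and >= 3 bp from the
    contig ends.  Sites planted in both populations share the same minor
    allele (a shared polymorphism).
    """
    rng = rng if rng is not None else config.rng(_STAGE_VARIANTS)
    n_hap = 2 * config.n_individuals_per_pop
    if config.minor_allele_freq < 1.0 / n_hap:
        raise ValueError(
            f"minor_allele_freq {config.minor_allele_freq} unreachable with "
            f"{n_hap} haplotypes (floor {1.0 / n_hap})"
        )

    pools: dict[str, dict[str, np.ndarray]] = {}
    for cid, seq in reference.contigs.items():
        anc = np.array(list(seq))
        pool = {pop: np.tile(anc, (n_hap, 1)) for pop in ("pop1", "pop2")}
        L = len(seq)
        cds_lo, cds_hi = reference.cds_intervals[cid]
        n_codons = (cds_hi - cds_lo) // 3

        taken: set[int] = set()
        # ---- fixed differences, one per codon, interior codons only ----
        if n_codons > 2 and config.fixed_diff_rate > 0:
            n_fixed = rng.binomial(cds_hi - cds_lo - 6, config.fixed_diff_rate)
            n_fixed = min(n_fixed, n_codons - 2)
            codon_idx = rng.choice(np.arange(1, n_codons - 1), size=n_fixed,
                                   replace=False)
            for ci in sorted(int(c) for c in codon_idx):
                codon = seq[cds_lo + 3 * ci: cds_lo + 3 * ci + 3]
                pos_in_codon = int(rng.integers(3))
                opts = _codon_change_options(codon, pos_in_codon)
                want = "nonsyn" if rng.random() < config.nonsyn_fraction else "syn"
                choices = opts[want] or opts["nonsyn" if want == "syn" else "syn"]
                if not choices:
                    continue
                alt = choices[rng.integers(len(choices))]
                site = cds_lo + 3 * ci + pos_in_codon
                lineage = ("pop1" if rng.random() < config.fixed_diff_pop1_fraction
                           else "pop2")
                pool[lineage][:, site] = alt
                taken.add(site)

                anc_codon = codon
                der_codon = codon[:pos_in_codon] + alt + codon[pos_in_codon + 1:]
                aa_anc, aa_der = CODON_TO_AA[anc_codon], CODON_TO_AA[der_codon]
                aa1, aa2 = (aa_der, aa_anc) if lineage == "pop1" else (aa_anc, aa_der)
                aa_out = reference.outgroup_proteins[cid][ci]
                if aa1 == aa2:
                    expected = None
                elif aa_out == aa2:
                    expected = "pop1"
                elif aa_out == aa1:
                    expected = "pop2"
                else:
                    expected = "unoriented"
                truth.planted_fixed_diffs.append(PlantedFixedDiff(
                    cid, site,
                    alt if lineage == "pop1" else codon[pos_in_codon],
                    alt if lineage == "pop2" else codon[pos_in_codon],
                    aa_anc != aa_der, lineage, ci, aa1, aa2, aa_out, expected,
                ))

        # ---- within-population polymorphisms ----
        if config.polymorphic_site_rate > 0 and L > 6:
            candidates = [p for p in range(3, L - 3) if p not in taken]
            chosen_minor: dict[int, str] = {}
            for pop in ("pop1", "pop2"):
                n_poly = min(rng.binomial(len(candidates),
                                          config.polymorphic_site_rate),
                             len(candidates))
                if n_poly == 0:
                    continue
                sites = rng.choice(len(candidates), size=n_poly, replace=False)
                m = int(round(n_hap * config.minor_allele_freq))
                m = max(m, 1)
                for si in sorted(int(s) for s in sites):
                    site = candidates[si]
                    anc_base = seq[site]
                    if site in chosen_minor:
                        minor = chosen_minor[site]
                    else:
                        alts = [b for b in BASES if b != anc_base]
                        minor = alts[rng.integers(3)]
                        chosen_minor[site] = minor
                    carriers = rng.choice(n_hap, size=m, replace=False)
                    pool[pop][carriers, site] = minor
                    truth.planted_polymorphisms.append(PlantedPolymorphism(
                        cid, site, pop, anc_base, minor, m, m / n_hap,
                    ))
        pools[cid] = pool
    return pools, truth


def simulate_reads(
    pools: dict[str, dict[str, np.ndarray]],
    config: SimulationConfig,
    truth: SyntheticTruth,
    rng: np.random.Generator | None = None,
) -> tuple[list[SimulatedRead], SyntheticTruth]:
    """Draw reads per population with errors and two-point qualities.

    Per contig and population the read count is Poisson(depth_mean); each
    read copies one uniformly chosen haplotype (full contig length unless
    ``read_length`` is set), then picks up substitution errors at
    ``error_rate`` (uniform over the three alternative bases, logged in the
    truth) and per-base qualities of ``q_low`` (< 20) with probability
    ``q_low_fraction``, else ``q_high``.
    """
    rng = rng if rng is not None else config.rng(_STAGE_READS)
    reads: list[SimulatedRead] = []
    for cid in sorted(pools):
        for pop in ("pop1", "pop2"):
            pool = pools[cid][pop]
            n_hap, L = pool.shape
            n_reads = int(rng.poisson(config.depth_mean))
            for j in range(n_reads):
                rid = f"{cid}|{pop}|r{j}"
                if config.read_length is not None and config.read_length < L:
                    start = int(rng.integers(0, L - config.read_length + 1))
                    length = config.read_length
                else:
                    start, length = 0, L
                hap = pool[int(rng.integers(n_hap))]
                bases = hap[start:start + length].copy()
                err = np.nonzero(rng.random(length) < config.error_rate)[0]
                for off in err:
                    true = bases[off]
                    alts = [b for b in BASES if b != true]
                    obs = alts[rng.integers(3)]
                    bases[off] = obs
                    truth.error_positions.append(
                        (pop, rid, int(off), str(true), obs)
                    )
                quals = np.where(rng.random(length) < config.q_low_fraction,
                                 config.q_low, config.q_high)
                reads.append(SimulatedRead(
                    rid, cid, pop, start, "".join(bases),
                    [int(q) for q in quals],
                ))
    return reads, truth


def simulate_dataset(config: SimulationConfig) -> Dataset:
    """Run the three generator stages under the single run seed."""
    reference, truth = generate_reference(config)
    pools, truth = plant_variants(reference, config, truth)
    reads, truth = simulate_reads(pools, config, truth)
    return Dataset(config, reference, pools, reads, truth)


def simulate_annotation(
    reference: Reference,
    config: SimulationConfig,
    p_annotated: float = 0.7,
    p_category: float = 0.3,
    category: str = "eye",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Random gene-annotation table over the outgroup protein universe.

    Stands in for a curated expression database: each gene is annotated
    with probability ``p_annotated`` and, if annotated, carries the
    category label with probability ``p_category``.  Columns: gene, labels
    (comma-separated; empty = in universe but unannotated).
    """
    rng = rng if rng is not None else config.rng(_STAGE_ANNOTATION)
    rows = []
    for cid in sorted(reference.protein_ids):
        gene = reference.protein_ids[cid]
        labels = []
        if rng.random() < p_annotated:
            labels.append("annotated")
            if rng.random() < p_category:
                labels.append(category)
        rows.append((gene, ",".join(labels)))
    return pd.DataFrame(rows, columns=["gene", "labels"])


def _phred33(quals: list[int]) -> str:
    return "".join(chr(q + 33) for q in quals)


def write_dataset(dataset: Dataset, outdir: str | Path) -> dict[str, Path]:
    """Write FASTQ (Phred+33), FASTA, ortholog TSV and truth JSON files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reads_pop1": outdir / "reads_pop1.fastq",
        "reads_pop2": outdir / "reads_pop2.fastq",
        "contigs": outdir / "contigs.fasta",
        "outgroup": outdir / "outgroup_proteins.fasta",
        "hits": outdir / "ortholog_hits.tsv",
        "truth": outdir / "truth.json",
    }
    handles = {
        "pop1": open(paths["reads_pop1"], "w"),
        "pop2": open(paths["reads_pop2"], "w"),
    }
    try:
        for r in dataset.reads:
            handles[r.population].write(
                f"@{r.read_id}\n{r.sequence}\n+\n{_phred33(r.qualities)}\n"
            )
    finally:
        for h in handles.values():
            h.close()
    with open(paths["contigs"], "w") as fh:
        for cid in sorted(dataset.reference.contigs):
            fh.write(f">{cid}\n{dataset.reference.contigs[cid]}\n")
    with open(paths["outgroup"], "w") as fh:
        for cid in sorted(dataset.reference.outgroup_proteins):
            pid = dataset.reference.protein_ids[cid]
            fh.write(f">{pid}\n{dataset.reference.outgroup_proteins[cid]}\n")
    pd.DataFrame(
        sorted(dataset.reference.protein_ids.items()),
        columns=["contig_id", "protein_id"],
    ).to_csv(paths["hits"], sep="\t", index=False)
    paths["truth"].write_text(dataset.truth.to_json())
    return paths
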