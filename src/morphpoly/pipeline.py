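"""End-to-end orchestration: simulate -> prep -> call -> subst -> enrich.

Each stage is a thin wrapper over the corresponding library module; the
run directory receives one machine-readable output per stage (pileup TSV,
site-classification TSV, substitution TSV, summary JSON) plus a log line
per stage.  All randomness flows from the single run seed through the
stage-specific derivation documented in :mod:`morphpoly.simulate`.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import __version__
from .caller import (SITE_CLASSES, FixedIndel, SiteClassification, scan_contig,
                     scan_indels)
from .enrichment import AnnotationMap, EnrichmentReport, eye_enrichment_report
from .params import CallThresholds, ErrorModelParams
from .readprep import (AlignedRead, ContigPileup, align_read_to_contig,
                       build_pileup, mask_low_quality,
                       select_contigs_per_ortholog, trim_low_quality)
from .simulate import (Dataset, SimulationConfig, SyntheticTruth,
                       simulate_annotation, simulate_dataset, write_dataset)
from .substitution import (DEFAULT_AA_CLASSES, CodingProjection,
                           CodingSubstitution, PrematureStop,
                           consensus_per_population, detect_premature_stop,
                           is_radical, load_aa_scheme, project_coding_frame,
                           project_fixed_differences, tabulate_lineage_counts)

logger = logging.getLogger("morphpoly")

ALL_STAGES = ("simulate", "prep", "call", "subst", "enrich")

__all__ = [
    "RunConfig",
    "RunResult",
    "run_pipeline",
    "recovery_report",
    "load_reads",
    "prep_reads",
]


@dataclass
class RunConfig:
    """One reproducible pipeline run.

    Either the simulate stage generates the inputs (``sim`` set), or the
    read/contig/ortholog paths point at existing files.  ``stages`` toggles
    which stages run; later stages require their inputs in memory or on
    disk.
    """

    outdir: str = "run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    sim: SimulationConfig | None = None
    reads_pop1: str | None = None
    reads_pop2: str | None = None
    contigs: str | None = None
    hits: str | None = None
    outgroup_proteins: str | None = None
    annotation: str | None = None
    pileup: str | None = None  # precomputed pileup TSV for call-only runs
    thresholds: CallThresholds = field(default_factory=CallThresholds)
    model: ErrorModelParams = field(default_factory=ErrorModelParams)
    aa_scheme: str | None = None  # path to a YAML/JSON class scheme
    category: str = "eye"

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.sim is None and self.seed is not None and "simulate" in self.stages:
            self.sim = SimulationConfig(seed=self.seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        if d.get("sim") is not None:
            d["sim"] = SimulationConfig(**d["sim"])
        if d.get("thresholds") is not None:
            d["thresholds"] = CallThresholds(**d["thresholds"])
        if d.get("model") is not None:
            d["model"] = ErrorModelParams(**d["model"])
        d["stages"] = tuple(d.get("stages", ALL_STAGES))
        return cls(**d)


@dataclass
class RunResult:
    config: RunConfig
    dataset: Dataset | None
    pileups: dict[str, ContigPileup]
    kept_contigs: list[str]
    classifications: dict[str, list[SiteClassification]]
    class_totals: Counter
    projections: dict[str, CodingProjection]
    substitutions: list[CodingSubstitution]
    premature_stops: list[PrematureStop]
    indels: list[FixedIndel]
    enrichment: EnrichmentReport | None
    summary: dict


def load_reads(path: str | Path, population: str) -> list[tuple[str, str, list[int]]]:
    """Read a Phred+33 FASTQ into (read_id, sequence, qualities) tuples."""
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append((rec.id, str(rec.seq).upper(),
                    list(rec.letter_annotations["phred_quality"])))
    return out


def _reads_from_dataset(dataset: Dataset) -> dict[str, list[tuple[str, str, list[int]]]]:
    reads: dict[str, list] = {"pop1": [], "pop2": []}
    for r in dataset.reads:
        reads[r.population].append((r.read_id, r.sequence, r.qualities))
    return reads


def _contig_for_read(read_id: str, contigs: Mapping[str, str]) -> str | None:
    head = read_id.split("|")[0]
    return head if head in contigs else None


def prep_reads(
    reads_by_pop: Mapping[str, list[tuple[str, str, list[int]]]],
    contigs: Mapping[str, str],
    thresholds: CallThresholds,
) -> dict[str, ContigPileup]:
    """Trim, mask and align reads; build one pileup per contig.

    Reads whose id prefix (before ``|``) names a contig are aligned to that
    contig; otherwise the read is aligned to every contig and assigned to
    the best-scoring one.
    """
    aligned: dict[str, list[AlignedRead]] = defaultdict(list)
    for pop, reads in reads_by_pop.items():
        for rid, seq, quals in reads:
            trimmed = trim_low_quality(seq, quals, thresholds)
            if trimmed is None:
                continue
            tseq, tquals = trimmed
            masked = mask_low_quality(tseq, tquals, thresholds)
            target = _contig_for_read(rid, contigs)
            if target is not None:
                ar = align_read_to_contig(masked, contigs[target], rid,
                                          target, pop)
            else:
                ar = None
                for cid, cseq in contigs.items():
                    cand = align_read_to_contig(masked, cseq, rid, cid, pop)
                    if cand is not None and (ar is None or cand.score > ar.score):
                        ar = cand
            if ar is not None:
                aligned[ar.contig_id].append(ar)
    return {
        cid: build_pileup(cid, len(contigs[cid]), aligned.get(cid, []))
        for cid in sorted(contigs)
    }


def _genes_by_lineage(
    substitutions: Iterable[CodingSubstitution],
    protein_ids: Mapping[str, str],
) -> dict[str, set[str]]:
    """Genes carrying >= 1 radical mutation, keyed by lineage.

    A gene with radical mutations on both lineages appears in both sets
    (and is therefore counted twice in the report, as in the bookkeeping
    this reproduces).
    """
    out: dict[str, set[str]] = {"pop1": set(), "pop2": set(), "unoriented": set()}
    for s in substitutions:
        if s.kind == "nonsynonymous" and s.radical:
            gene = protein_ids.get(s.contig_id, s.contig_id)
            out[s.lineage or "unoriented"].add(gene)
    return out


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the configured stages and write the run directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(stage: str, msg: str) -> None:
        line = f"[{stage}] {msg}"
        logger.info(line)
        log_lines.append(line)

    scheme = (load_aa_scheme(config.aa_scheme) if config.aa_scheme
              else DEFAULT_AA_CLASSES)

    dataset: Dataset | None = None
    contigs: dict[str, str] = {}
    protein_ids: dict[str, str] = {}
    hits: pd.DataFrame | None = None
    outgroup: dict[str, str] = {}
    annotation: AnnotationMap | None = None
    reads_by_pop: dict[str, list] = {}

    # ---- simulate -----------------------------------------------------
    if "simulate" in config.stages:
        sim = config.sim if config.sim is not None else SimulationConfig(seed=config.seed)
        dataset = simulate_dataset(sim)
        write_dataset(dataset, outdir / "data")
        ann = simulate_annotation(dataset.reference, sim)
        ann.to_csv(outdir / "data" / "annotation.tsv", sep="\t", index=False)
        annotation = AnnotationMap.from_frame(ann)
        contigs = dict(dataset.reference.contigs)
        protein_ids = dict(dataset.reference.protein_ids)
        outgroup = {protein_ids[c]: p
                    for c, p in dataset.reference.outgroup_proteins.items()}
        reads_by_pop = _reads_from_dataset(dataset)
        log("simulate", f"{len(contigs)} contigs, {len(dataset.reads)} reads, "
            f"{len(dataset.truth.planted_fixed_diffs)} planted fixed diffs, "
            f"{len(dataset.truth.planted_polymorphisms)} planted polymorphisms")
    else:
        if config.contigs:
            contigs = {r.id: str(r.seq).upper()
                       for r in SeqIO.parse(config.contigs, "fasta")}
        if config.hits:
            hits = pd.read_csv(config.hits, sep="\t")
            protein_ids = dict(zip(hits["contig_id"], hits["protein_id"]))
        if config.outgroup_proteins:
            outgroup = {r.id: str(r.seq).upper()
                        for r in SeqIO.parse(config.outgroup_proteins, "fasta")}
        if config.annotation:
            annotation = AnnotationMap.from_frame(
                pd.read_csv(config.annotation, sep="\t")
            )
        if config.reads_pop1:
            reads_by_pop["pop1"] = load_reads(config.reads_pop1, "pop1")
        if config.reads_pop2:
            reads_by_pop["pop2"] = load_reads(config.reads_pop2, "pop2")

    # ---- prep ---------------------------------------------------------
    pileups: dict[str, ContigPileup] = {}
    kept: list[str] = sorted(contigs)
    if "prep" in config.stages:
        pileups = prep_reads(reads_by_pop, contigs, config.thresholds)
        depths = {cid: p.mean_depth() for cid, p in pileups.items()}
        if protein_ids:
            hits_df = pd.DataFrame(sorted(protein_ids.items()),
                                   columns=["contig_id", "protein_id"])
            kept = select_contigs_per_ortholog(depths, hits_df)
        pd.concat([pileups[c].to_frame() for c in kept],
                  ignore_index=True).to_csv(
            outdir / "pileup.tsv", sep="\t", index=False)
        log("prep", f"{sum(len(r) for r in reads_by_pop.values())} reads in, "
            f"{len(kept)} contigs kept after ortholog dedup")
    elif config.pileup:
        pileups = _pileups_from_tsv(pd.read_csv(config.pileup, sep="\t"))
        kept = sorted(pileups)
        log("prep", f"loaded precomputed pileup for {len(kept)} contigs")

    # ---- call ---------------------------------------------------------
    classifications: dict[str, list[SiteClassification]] = {}
    class_totals: Counter = Counter()
    if "call" in config.stages:
        rows = []
        for cid in kept:
            sites, tally = scan_contig(pileups[cid], config.model,
                                       config.thresholds)
            classifications[cid] = sites
            class_totals.update(tally)
            for s in sites:
                rows.append((s.contig_id, s.position + 1, s.site_class,
                             "/".join(s.alleles_pop1), "/".join(s.alleles_pop2),
                             s.depth_pop1, s.depth_pop2))
        pd.DataFrame(rows, columns=[
            "contig", "pos", "class", "alleles_pop1", "alleles_pop2",
            "depth_pop1", "depth_pop2"]).to_csv(
            outdir / "sites.tsv", sep="\t", index=False)
        log("call", f"{sum(len(v) for v in classifications.values())} covered "
            f"sites, {class_totals.get('fixed_difference', 0)} fixed differences")

    # ---- subst --------------------------------------------------------
    projections: dict[str, CodingProjection] = {}
    substitutions: list[CodingSubstitution] = []
    stops: list[PrematureStop] = []
    indels: list[FixedIndel] = []
    if "subst" in config.stages:
        for cid in kept:
            pid = protein_ids.get(cid)
            prot = outgroup.get(pid) if pid else None
            if prot is None or cid not in classifications:
                continue
            proj = project_coding_frame(contigs[cid], prot, cid, pid)
            if proj is None:
                log("subst", f"{cid}: no frame aligned to {pid}; excluded")
                continue
            projections[cid] = proj
            cons = consensus_per_population(pileups[cid], contigs[cid],
                                            config.thresholds)
            cons1, cons2 = cons["pop1"][0], cons["pop2"][0]
            fixed_pos = [s.position for s in classifications[cid]
                         if s.site_class == "fixed_difference"]
            substitutions.extend(project_fixed_differences(
                proj, cons1, cons2, fixed_pos, scheme))
            stops.extend(detect_premature_stop(proj, cons1, cons2))
            indels.extend(scan_indels(pileups[cid], config.thresholds,
                                      proj.interval))
        tabulate_lineage_counts(substitutions).to_csv(
            outdir / "substitutions_summary.tsv", sep="\t", index=False)
        pd.DataFrame([dataclasses.asdict(s) for s in substitutions]).to_csv(
            outdir / "substitutions.tsv", sep="\t", index=False)
        log("subst", f"{len(substitutions)} codon-level fixed differences, "
            f"{len(stops)} premature stops, {len(indels)} fixed indels")

    # ---- enrich -------------------------------------------------------
    enrichment: EnrichmentReport | None = None
    if "enrich" in config.stages and substitutions:
        genes = _genes_by_lineage(substitutions, protein_ids)
        enrichment = eye_enrichment_report(genes, annotation, config.category)
        enrichment.rows.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        log("enrich", f"Fisher p = {enrichment.p_value}")

    # ---- summary ------------------------------------------------------
    kinds = Counter(s.kind for s in substitutions)
    lineages = Counter(s.lineage for s in substitutions
                       if s.kind in ("nonsynonymous", "nonsense"))
    radical = Counter(s.lineage for s in substitutions if s.radical)
    poly_per_pop = {
        "pop1": sum(1 for v in classifications.values() for s in v
                    if len(s.alleles_pop1) >= 2),
        "pop2": sum(1 for v in classifications.values() for s in v
                    if len(s.alleles_pop2) >= 2),
    }
    summary = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": dataclasses.asdict(config.thresholds),
        "error_model": dataclasses.asdict(config.model),
        "aa_scheme": dict(scheme),
        "n_contigs_kept": len(kept),
        "polymorphic_positions": poly_per_pop,
        "site_classes": {c: int(class_totals.get(c, 0)) for c in SITE_CLASSES},
        "fixed_differences": {
            "nucleotide_total": int(class_totals.get("fixed_difference", 0)),
            "codon_events": int(sum(kinds.values())),
            "synonymous": int(kinds.get("synonymous", 0)),
            "nonsynonymous": int(kinds.get("nonsynonymous", 0)),
            "nonsense": int(kinds.get("nonsense", 0)),
        },
        "lineage_counts": {k or "n/a": int(v) for k, v in lineages.items()},
        "radical_counts": {k or "n/a": int(v) for k, v in radical.items()},
        "premature_stops": len(stops),
        "fixed_indels": len(indels),
        "enrichment_p": enrichment.p_value if enrichment else None,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1,
                                                    sort_keys=True))
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")

    return RunResult(config, dataset, pileups, kept, classifications,
                     class_totals, projections, substitutions, stops, indels,
                     enrichment, summary)


def _pileups_from_tsv(df: pd.DataFrame) -> dict[str, ContigPileup]:
    """Rebuild ContigPileup objects from the long-format pileup TSV."""
    pileups: dict[str, ContigPileup] = {}
    pops = ("pop1", "pop2")
    for cid, sub in df.groupby("contig"):
        length = int(sub["pos"].max())
        counts = np.zeros((length, 2, 4), dtype=np.int32)
        gaps = np.zeros((length, 2), dtype=np.int32)
        for _, row in sub.iterrows():
            p = pops.index(row["pop"])
            pos = int(row["pos"]) - 1
            counts[pos, p] = [row["nA"], row["nC"], row["nG"], row["nT"]]
            gaps[pos, p] = row.get("nGap", 0)
        pileups[cid] = ContigPileup(cid, length, pops, counts, gaps,
                                    {p: 0 for p in pops})
    return pileups


def recovery_report(
    result: RunResult,
    truth: SyntheticTruth,
    thresholds: CallThresholds = CallThresholds(),
) -> dict[str, dict]:
    """Sensitivity / precision of each event type against the planted truth.

    Planted polymorphisms whose minor-allele frequency is below the
    detectable floor ``f_min`` are flagged sub-threshold (expected false
    negatives) and reported separately.
    """
    if result.dataset is not None and truth is not result.dataset.truth:
        if result.dataset.truth.cds_intervals != truth.cds_intervals:
            raise ValueError("truth does not match this run's dataset")

    def metrics(tp: int, fp: int, fn: int) -> dict:
        return {
            "tp": tp, "fp": fp, "fn": fn,
            "sensitivity": tp / (tp + fn) if tp + fn else None,
            "precision": tp / (tp + fp) if tp + fp else None,
        }

    # polymorphic sites, per population
    pred_poly = set()
    for cid, sites in result.classifications.items():
        for s in sites:
            if len(s.alleles_pop1) >= 2:
                pred_poly.add((cid, s.position, "pop1"))
            if len(s.alleles_pop2) >= 2:
                pred_poly.add((cid, s.position, "pop2"))
    true_poly = {(p.contig, p.site, p.population)
                 for p in truth.planted_polymorphisms}
    sub_thr = {(p.contig, p.site, p.population)
               for p in truth.planted_polymorphisms
               if p.frequency < thresholds.f_min}
    poly = metrics(len(pred_poly & true_poly), len(pred_poly - true_poly),
                   len(true_poly - pred_poly))
    poly["n_subthreshold"] = len(sub_thr - pred_poly)

    # fixed differences
    pred_fd = {(cid, s.position) for cid, sites in result.classifications.items()
               for s in sites if s.site_class == "fixed_difference"}
    true_fd = {(f.contig, f.site) for f in truth.planted_fixed_diffs}
    fixed = metrics(len(pred_fd & true_fd), len(pred_fd - true_fd),
                    len(true_fd - pred_fd))

    # lineage orientation of amino-acid substitutions
    truth_by_site = {(f.contig, f.site): f for f in truth.planted_fixed_diffs}
    n_correct = n_oriented = n_orientable = 0
    for s in result.substitutions:
        if s.kind not in ("nonsynonymous", "nonsense"):
            continue
        f = next((truth_by_site.get((s.contig_id, pos))
                  for pos in s.nucleotide_positions
                  if (s.contig_id, pos) in truth_by_site), None)
        if f is None:
            continue
        if s.lineage in ("pop1", "pop2"):
            n_oriented += 1
            if s.lineage == f.lineage:
                n_correct += 1
    n_orientable = sum(1 for f in truth.planted_fixed_diffs
                       if f.expected_orientation in ("pop1", "pop2"))
    lineage = metrics(n_correct, n_oriented - n_correct,
                      max(n_orientable - n_correct, 0))

    # radical flags on recovered non-synonymous substitutions
    tp = fp = fn = 0
    for s in result.substitutions:
        if s.kind != "nonsynonymous":
            continue
        f = next((truth_by_site.get((s.contig_id, pos))
                  for pos in s.nucleotide_positions
                  if (s.contig_id, pos) in truth_by_site), None)
        if f is None or not f.is_nonsynonymous:
            continue
        truth_radical = is_radical(f.aa_pop1, f.aa_pop2)
        if s.radical and truth_radical:
            tp += 1
        elif s.radical and not truth_radical:
            fp += 1
        elif truth_radical and not s.radical:
            fn += 1
    return {
        "polymorphic_sites": poly,
        "fixed_differences": fixed,
        "lineage_calls": lineage,
        "radical_flags": metrics(tp, fp, fn),
    }
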