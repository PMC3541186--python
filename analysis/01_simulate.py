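"""Generate the synthetic two-morph EST dataset used by the analysis.

Study conditions: per-base error rate 1e-4, mean depth 6.8 reads per morph,
10 breeding individuals per morph (20 sampled alleles), fixed differences
at ~1.5e-4 per coding base with ~24% non-synonymous, and an outgroup
protein at 15% residue divergence.  Desk scale: 60 contigs of 300 bp.

Writes results/data/: per-morph FASTQ, contig FASTA, outgroup protein
FASTA, ortholog TSV, annotation TSV, truth JSON.
"""

from pathlib import Path

from morphpoly.simulate import (SimulationConfig, simulate_annotation,
                                simulate_dataset, write_dataset)

OUT = Path(__file__).resolve().parent.parent / "results" / "data"

CONFIG = SimulationConfig(
    n_contigs=60, contig_length=300, seed=2013,
    # denser events than genome-wide so the desk-scale run is informative
    fixed_diff_rate=2e-3, polymorphic_site_rate=2e-3, nonsyn_fraction=0.5,
)


def main() -> None:
    dataset = simulate_dataset(CONFIG)
    paths = write_dataset(dataset, OUT)
    ann = simulate_annotation(dataset.reference, CONFIG)
    ann.to_csv(OUT / "annotation.tsv", sep="\t", index=False)
    t = dataset.truth
    print(f"simulated {CONFIG.n_contigs} contigs x {CONFIG.contig_length} bp, "
          f"{len(dataset.reads)} reads")
    print(f"planted: {len(t.planted_fixed_diffs)} fixed differences "
          f"({sum(f.is_nonsynonymous for f in t.planted_fixed_diffs)} "
          f"non-synonymous), {len(t.planted_polymorphisms)} polymorphic sites, "
          f"{len(t.error_positions)} sequencing errors")
    for name, p in paths.items():
        print(f"  {name}: {p}")


if __name__ == "__main__":
    main()
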