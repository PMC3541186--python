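# Methods

This note documents the models, parameter choices and numerical decisions
behind `morphpoly`, and what the synthetic-data tests do and do not
demonstrate about real data.

## The error model and call thresholds

The caller treats a candidate minor allele (count *k* at depth *D*) as
explainable by sequencing / reverse-transcription errors unless it is
improbable *anywhere on the contig*: with per-base error rate *p*, the
per-site quantity is the upper tail P(X ≥ k), X ~ Binomial(D, p), and the
per-contig quantity is P_any = 1 − (1 − P_site)^L over L positions. The
site is retained only if P_any ≤ α **and** k/D clears the
minor-allele-frequency floor f_min.

Defaults, with units and rationale:

| parameter | default | meaning |
|---|---|---|
| `p_err` | 1e-4 | per-base error probability; dominated by the reverse transcriptase in EST data (RT ≈ 1/30,000, rounded up for stringency) |
| `contig_len_for_test` | 1000 bp | the L of the per-contig union; matches the ~1 kb mean contig length of the motivating data. A flag can switch to the actual contig length |
| `alpha` | 0.01 | retention cutoff on P_any |
| `d_min` | 4 reads | minimum depth per population for any call |
| `f_min` | 0.05 | at most ~10 breeding individuals → ≤ 20 sampled alleles → frequencies < 1/20 unobservable. Applied to read-count frequency k/D, not an inferred individual-level frequency |
| `q_min` | Q20 | masking threshold, strict ("below 20") |

Numerical notes: P_any is computed as `-expm1(L * log1p(-P_site))` to stay
accurate at P_site ~ 1e-7; the tail P(≥k) is used rather than the point
mass P(=k) because "could be explained by errors" is a tail statement —
at these parameter values the two give identical thresholds for every
depth up to at least 40 (tested), and the point-mass variant remains
available (`use_tail=False`). `min_minor_count` is non-decreasing in
depth: both the binomial requirement and ceil(f_min·D) grow with D (at
D = 4, k* = 2; the f_min floor starts binding around D ≈ 41 where 2/D
drops below 0.05).

## Read preparation

**Trimming.** A window of 30 bases slides inward from each extremity in
steps of 5 while its mean quality is below Q20; residual terminal bases
individually below Q20 are then stripped, so the cut lands on the exact
boundary of a low-quality run rather than on a stride multiple. (The
stripped bases would in any case be masked to `N` in the next step; the
combination makes trimming insensitive to the stride.) Reads shorter than
100 bases after trimming are discarded.

**Masking.** Bases below Q20 become `N`; `N` contributes to no pileup
count and is scored 0 (neutral) in alignment.

**Alignment.** The stringent realignment uses a local aligner with match
+1, mismatch −2, free gap opening and −2 per gapped base (the mismatch
and gap-open costs are the published Megablast settings of the motivating
analysis; match reward and per-base gap cost are our choice since none
were stated). Gap opening carries an extra 1e-6 purely as a tie-break so
that among co-optimal alignments contiguous gaps are preferred — without
it a 3-bp deletion can legally split into 1+2 bp gaps, which would
fragment the indel scan's events. A read "does not align properly" and is
discarded when its score is below 0.5 × (its unmasked length); the floor
is relative to the read, not to the aligned span, because a short perfect
local match scores 1 per column and a span-relative floor would accept
arbitrary 6–8 bp spurious matches (e.g. from reverse-complement or
foreign reads). Alignment is forward-strand-only since directional cDNA
libraries are assumed.

A structural consequence of local alignment: a mismatch within 2 bp of a
read end always scores better trimmed than included, so variants at the
very ends of reads are invisible. The generator therefore plants variants
≥ 3 bp from contig ends (fixed differences: not in the first or last CDS
codon); on real data this appears as slightly reduced sensitivity at
contig extremities.

**Ortholog deduplication.** One contig per outgroup protein hit is kept —
the one with the largest mean depth — so the same polymorphic site
assembled into two contigs is not counted twice. Depth ties break to the
lexicographically smallest contig id, for determinism.

Coordinates are 0-based half-open internally, 1-based in all TSV outputs.

## Site classification

Per site and population the call is polymorphic / monomorphic /
insufficient-depth; minor alleles beyond the second are retained if they
independently clear the threshold, and cross-population comparison uses
allele-*set* equality ("same alleles" = equal sets; unequal sets, even
overlapping, count as divergent). A site polymorphic in one morph is
classed "one morph only" when the other morph has depth ≥ 4, otherwise
"unknown status for the other morph"; a fixed difference requires both
morphs monomorphic, at depth ≥ 4 each, for different alleles. The seven
classes are mutually exclusive and exhaustive over covered sites.

## Substitution analysis

The coding frame is chosen among the three forward frames by local
BLOSUM62 alignment (gap open −11, extend −1) of the translation to the
outgroup protein; a projection needs ≥ 40% identity over ≥ 30 aligned
residues, otherwise the contig is excluded as non-coding/mis-assigned
(both thresholds are our choice; no values were stated). Per-population
consensus takes the majority base at each site, falling back to the
reference contig base (flagged untrusted) below depth 4 or at ties.

Fixed differences are grouped by codon: a codon carrying two fixed
differences is one amino-acid-level event but two nucleotide-level
counts, keeping the nucleotide and amino-acid tallies separate.
Classification uses the standard genetic code only (nuclear transcripts).
Orientation is strict parsimony on the outgroup residue aligned to the
codon; nonsense changes orient by the same rule (the outgroup never shows
a stop inside the aligned region). Premature stops are reported when
exactly one population's consensus carries an in-frame stop strictly
upstream of the codon aligned to the outgroup C-terminus, with
truncated fraction = (C-terminal codon − stop codon) / (C-terminal codon + 1).

The 6-class physicochemical scheme is: hydrophobic {G A V L I M C},
aromatic {F Y W}, polar neutral {S T N Q}, acidic {D E}, basic {K R H},
proline {P}. Only the class *names* are canonical; the memberships of C,
G and H are assignable multiple ways, so the scheme is configurable (YAML
mapping, validated to cover the 20 amino acids with proline a singleton)
and the active scheme is recorded in every summary for reproducibility.

## Enrichment

The 2×2 Fisher test is two-sided by the "sum of tables at most as
probable" convention of mainstream statistical software; a degenerate
margin returns p = 1 with a warning. Report percentages are rounded
half-up to one decimal. A gene with radical mutations on both lineages is
counted in both rows of the report. Term enrichment is a plain upper-tail
hypergeometric over a user-supplied annotation map, unadjusted by default
(BH available via flag) — it deliberately ignores any ontology DAG
structure.

## The synthetic-data generator

The generator emulates: two populations of 2×10 haplotypes derived from a
common ancestor; within-population polymorphic sites at a set minor-allele
frequency (realized counts recorded exactly); fixed differences planted
inside the CDS at a set per-base rate, with a set fraction at
non-synonymous positions and a configurable lineage bias; full-length
reads at Poisson(depth 6.8) per population; substitution errors at 1e-4
logged base-by-base; a two-point quality model (Q15/Q38) straddling the
Q20 mask; and an outgroup protein with per-residue divergence 0.15.
Where the motivating study states a value the default equals it (error
rate, depth, individuals, ~1 kb contigs, fixed-difference density
1.5e-4/bp ≈ its genome-wide count over its surveyed bases, 24%
non-synonymous); the remaining defaults (polymorphic-site rate 5e-4 per
population, minor-allele frequency 0.25, 5% sub-Q20 bases, outgroup
divergence 0.15 ≈ a ~100-My fish outgroup) are fixed, field-realistic
choices. All randomness derives from one seed through fixed per-stage
SeedSequence keys; identical configurations produce byte-identical files.

What it does **not** emulate: EST fragmentation (reads span the whole
contig by default; a `read_length` option exists), chimeric reads, vector
contamination, library normalization, quality gradients along reads,
indels (none are planted; the indel scan is exercised by constructed
fixtures), and premature-stop-creating fixed differences (the motivating
data contained exactly one; nonsense logic is tested directly). Passing
the synthetic tests therefore demonstrates the *logic* of the pipeline
under the stated sampling model, not robustness to assembly artifacts or
real quality structure.

## Validation protocols and problem sizes

Two canned protocols (`morphpoly.protocols`) back the validation suite:

* **Clean recovery** — 200 contigs × 300 bp, depth 20, no errors, no
  sub-Q20 bases, undiverged outgroup, fixed differences at 2e-3/bp with
  half non-synonymous. Under these conditions every planted fixed
  difference is observable (P(depth < 4 | Poisson(20)) ≈ 3e-6), so
  sensitivity and precision must both be 1.0 and every parsimony
  orientation must equal the planted lineage; any shortfall is a defect.
* **Error-only control** — 500 contigs × 300 bp at the study conditions
  (depth 6.8, errors 1e-4), nothing planted. A false polymorphic call
  needs ≥ 2 coincident same-base errors at one site of one morph, giving
  an expected per-contig rate of ~1e-4 — comfortably inside the α = 0.01
  design bound the filter guarantees per contig.

Contig length 300 bp (vs the realistic 984 default) keeps the
quadratic-cost alignments of these multi-hundred-contig runs in the
tens of seconds; it does not change any per-site statistics. The
analysis scripts use 60 contigs at the study depth 6.8, where ~15% of
planted fixed differences legitimately fall below callable depth in one
morph — shown as expected false negatives, with precision 1.0.

## Known limitations

* The aligner is exact dynamic programming (O(n·m)); very long contigs at
  high depth are slow. Precomputed alignments can be supplied as a
  pileup TSV instead.
* Consensus ties and sub-depth sites silently take the reference base
  (flagged); in pathological coverage this can erase a true difference
  rather than mis-call it.
* Read-to-contig assignment outside the simulator relies on read-id
  prefixes or best-alignment search; there is no k-mer index.
* The MAF floor applies to read counts, which at depth ~7 is a coarse
  proxy for allele frequency; planted 0.25-frequency alleles are missed
  whenever fewer than the required minor reads happen to sample them.
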