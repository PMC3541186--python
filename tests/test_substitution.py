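"""Coding projection, codon classification, parsimony orientation, radical
scoring, premature stops."""

import itertools

import numpy as np
import pytest

from morphpoly.codons import SENSE_CODONS, STOP_CODONS, translate_cds
from morphpoly.readprep import align_read_to_contig, build_pileup
from morphpoly.simulate import SimulationConfig, generate_reference
from morphpoly.substitution import (DEFAULT_AA_CLASSES, classify_substitution,
                                    consensus_per_population,
                                    detect_premature_stop, is_radical,
                                    orient_substitution,
                                    project_coding_frame,
                                    project_fixed_differences,
                                    tabulate_lineage_counts,
                                    validate_aa_scheme)

from conftest import oracle_classify

RNG = np.random.default_rng(1364)


def random_cds(n_codons, rng=RNG):
    return "".join(SENSE_CODONS[i]
                   for i in rng.choice(len(SENSE_CODONS), size=n_codons))


class TestProjection:
    def test_exact_back_translation_selects_frame_zero(self):
        cds = random_cds(60)
        proj = project_coding_frame(cds, translate_cds(cds))
        assert proj is not None
        assert proj.frame == 0
        assert proj.interval == (0, 180)
        assert proj.identity == 1.0

    def test_prepended_base_shifts_to_frame_one(self):
        cds = random_cds(60)
        proj = project_coding_frame("G" + cds, translate_cds(cds))
        assert proj is not None and proj.frame == 1
        assert proj.interval == (1, 181)

    def test_unrelated_protein_is_rejected(self):
        cds = random_cds(60)
        junk = "".join(RNG.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=60))
        assert project_coding_frame(cds, junk) is None

    def test_noncoding_flanks_excluded_per_generator_truth(self):
        cfg = SimulationConfig(n_contigs=2, contig_length=300,
                               noncoding_flank_frac=0.3,
                               outgroup_protein_divergence=0.0, seed=9)
        ref, truth = generate_reference(cfg)
        for cid, seq in ref.contigs.items():
            proj = project_coding_frame(seq, ref.outgroup_proteins[cid])
            assert proj is not None
            assert proj.interval == truth.cds_intervals[cid]


class TestConsensus:
    def _pileup(self, contig, reads):
        ars = [align_read_to_contig(seq, contig, f"r{i}", "c", pop,
                                    score_floor=0.3)
               for i, (seq, pop) in enumerate(reads)]
        return build_pileup("c", len(contig), [a for a in ars if a])

    def test_majority_base_wins(self):
        contig = random_cds(40)
        alt = "A" if contig[10] != "A" else "C"
        variant = contig[:10] + alt + contig[11:]
        p = self._pileup(contig, [(variant, "pop1")] * 5 + [(contig, "pop2")] * 5)
        cons = consensus_per_population(p, contig)
        assert cons["pop1"][0][10] == alt
        assert cons["pop2"][0] == contig

    def test_shallow_sites_fall_back_to_reference_and_flag(self):
        contig = random_cds(40)
        p = self._pileup(contig, [(contig, "pop1")] * 2)
        cons = consensus_per_population(p, contig)
        assert cons["pop1"][0] == contig
        assert cons["pop1"][1].all()

    def test_tie_keeps_reference_base_with_flag(self):
        contig = random_cds(40)
        alt = ("A" if contig[10] != "A" else "C")
        variant = contig[:10] + alt + contig[11:]
        p = self._pileup(contig, [(variant, "pop1")] * 3 + [(contig, "pop1")] * 3)
        cons = consensus_per_population(p, contig)
        assert cons["pop1"][0][10] == contig[10]
        assert cons["pop1"][1][10]


class TestClassifySubstitution:
    @pytest.mark.parametrize("c1,c2,kind", [
        ("CTG", "CTA", "synonymous"),
        ("GAA", "GAC", "nonsynonymous"),
        ("TAC", "TAA", "nonsense"),
    ])
    def test_canonical_examples(self, c1, c2, kind):
        assert classify_substitution(c1, c2) == kind

    def test_ambiguous_codon_skipped(self):
        assert classify_substitution("ANA", "AGA") is None

    def test_bad_codon_length_is_an_error(self):
        with pytest.raises(ValueError):
            classify_substitution("AC", "ACG")

    def test_all_sense_codon_pairs_match_table_oracle(self):
        """Exhaustive agreement with an independent literal-table oracle
        over the 61 x 61 sense-codon pairs."""
        for c1, c2 in itertools.product(SENSE_CODONS, SENSE_CODONS):
            assert classify_substitution(c1, c2) == oracle_classify(c1, c2)

    def test_sense_versus_stop_is_nonsense(self):
        for stop in STOP_CODONS:
            assert classify_substitution("TAC", stop) in ("nonsense",) \
                if classify_substitution("TAC", stop) else True
            assert classify_substitution(stop, "CAA") == "nonsense"


class TestOrientation:
    @pytest.mark.parametrize("aa1,aa2,out,lineage", [
        ("S", "A", "A", "pop1"),
        ("S", "A", "S", "pop2"),
        ("S", "A", "T", "unoriented"),
    ])
    def test_parsimony_rule(self, aa1, aa2, out, lineage):
        assert orient_substitution(aa1, aa2, out) == lineage

    def test_missing_outgroup_residue_unoriented(self):
        assert orient_substitution("S", "A", None) == "unoriented"

    def test_identical_residues_cannot_be_oriented(self):
        with pytest.raises(ValueError):
            orient_substitution("S", "S", "A")


class TestRadical:
    @pytest.mark.parametrize("a,b,expected", [
        ("D", "E", False),   # both acidic
        ("K", "E", True),    # basic vs acidic
        ("A", "P", True),    # proline is its own class
        ("F", "Y", False),   # both aromatic
    ])
    def test_examples(self, a, b, expected):
        assert is_radical(a, b) is expected

    def test_symmetric_and_irreflexive(self):
        aas = sorted(DEFAULT_AA_CLASSES)
        for a, b in itertools.product(aas, aas):
            assert is_radical(a, b) == is_radical(b, a)
        for a in aas:
            assert not is_radical(a, a)

    def test_nonstandard_residue_is_an_error(self):
        with pytest.raises(ValueError):
            is_radical("B", "A")

    def test_scheme_validation_requires_proline_singleton(self):
        bad = dict(DEFAULT_AA_CLASSES, P="hydrophobic")
        with pytest.raises(ValueError):
            validate_aa_scheme(bad)


def _projected_case(n_codons=40, mutate=None, seed=0):
    """Build contig + projection + two consensus strings, applying
    ``mutate``: list of (codon_idx, pos_in_codon, base, which_pop)."""
    rng = np.random.default_rng(seed)
    cds = random_cds(n_codons, rng)
    prot = translate_cds(cds)
    proj = project_coding_frame(cds, prot)
    assert proj is not None
    cons = {"pop1": list(cds), "pop2": list(cds)}
    positions = []
    for ci, k, base, pop in (mutate or []):
        if cds[3 * ci + k] == base:  # guarantee an actual difference
            base = "ACGT"[("ACGT".index(base) + 1) % 4]
        cons[pop][3 * ci + k] = base
        positions.append(3 * ci + k)
    return proj, "".join(cons["pop1"]), "".join(cons["pop2"]), positions


class TestProjectFixedDifferences:
    def test_substitutions_classified_and_oriented(self):
        # find a codon where changing base 0 changes the amino acid
        proj, c1, c2, pos = _projected_case(
            mutate=[(5, 1, "A", "pop2")], seed=3)
        subs = project_fixed_differences(proj, c1, c2, pos)
        assert c1[15:18] != c2[15:18]
        (s,) = subs
        kind = classify_substitution(c1[15:18], c2[15:18])
        assert s.kind == kind
        if kind in ("nonsynonymous", "nonsense"):
            # outgroup equals pop1 (ancestral), so the change is on pop2
            assert s.lineage == "pop2"

    def test_two_hits_in_one_codon_yield_one_event(self):
        proj, c1, c2, pos = _projected_case(
            mutate=[(7, 0, "A", "pop2"), (7, 2, "A", "pop2")], seed=4)
        assert c1[21:24] != c2[21:24]
        subs = project_fixed_differences(proj, c1, c2, pos)
        assert len(subs) == 1
        assert subs[0].nucleotide_positions == (21, 23)

    def test_positions_outside_interval_ignored(self):
        proj, c1, c2, _ = _projected_case()
        assert project_fixed_differences(proj, c1, c2, [999]) == []


class TestPrematureStop:
    def test_planted_stop_detected_with_truncation_fraction(self):
        # TAC -> TAA at codon 10 of 40 in pop2 only
        rng = np.random.default_rng(8)
        cds = random_cds(40, rng)
        cds = cds[:30] + "TAC" + cds[33:]
        prot = translate_cds(cds)
        proj = project_coding_frame(cds, prot)
        mutant = cds[:30] + "TAA" + cds[33:]
        events = detect_premature_stop(proj, cds, mutant)
        (e,) = events
        assert (e.population, e.codon_index) == ("pop2", 10)
        assert e.truncated_fraction == pytest.approx((39 - 10) / 40)

    def test_identical_populations_report_nothing(self):
        cds = random_cds(40)
        proj = project_coding_frame(cds, translate_cds(cds))
        assert detect_premature_stop(proj, cds, cds) == []

    def test_stop_at_aligned_terminus_is_not_premature(self):
        cds = random_cds(40)
        proj = project_coding_frame(cds, translate_cds(cds))
        mutant = cds[:117] + "TGA"
        assert detect_premature_stop(proj, cds, mutant) == []


class TestTabulate:
    def test_empty_input_gives_empty_table(self):
        assert tabulate_lineage_counts([]).empty

    def test_lineage_margin_equals_nonsynonymous_plus_nonsense(self):
        cfg = SimulationConfig(n_contigs=30, contig_length=300, depth_mean=20,
                               error_rate=0.0, q_low_fraction=0.0,
                               fixed_diff_rate=4e-3, nonsyn_fraction=0.5,
                               polymorphic_site_rate=0.0,
                               outgroup_protein_divergence=0.0, seed=10)
        from morphpoly.pipeline import RunConfig, run_pipeline
        import tempfile
        res = run_pipeline(RunConfig(outdir=tempfile.mkdtemp(), seed=10,
                                     sim=cfg))
        df = tabulate_lineage_counts(res.substitutions)
        n_aa_changing = sum(1 for s in res.substitutions
                            if s.kind in ("nonsynonymous", "nonsense"))
        lineage_total = int(df[df["lineage"] != "n/a"]["count"].sum())
        assert lineage_total == n_aa_changing
        assert int(df["count"].sum()) == len(res.substitutions)

    def test_outgroup_collision_rate_matches_truth(self):
        """With a heavily diverged outgroup, the unoriented fraction equals
        the collision fraction recorded in the generator truth."""
        cfg = SimulationConfig(n_contigs=60, contig_length=300, depth_mean=20,
                               error_rate=0.0, q_low_fraction=0.0,
                               fixed_diff_rate=4e-3, nonsyn_fraction=1.0,
                               polymorphic_site_rate=0.0,
                               outgroup_protein_divergence=0.5, seed=11)
        from morphpoly.pipeline import RunConfig, run_pipeline
        import tempfile
        res = run_pipeline(RunConfig(outdir=tempfile.mkdtemp(), seed=11,
                                     sim=cfg))
        truth = res.dataset.truth
        expected_unoriented = sum(
            1 for f in truth.planted_fixed_diffs
            if f.is_nonsynonymous and f.expected_orientation == "unoriented")
        got_unoriented = sum(1 for s in res.substitutions
                             if s.kind == "nonsynonymous"
                             and s.lineage == "unoriented")
        assert got_unoriented == expected_unoriented
        assert expected_unoriented > 0
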