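"""Read cleaning, stringent alignment, pileups, ortholog deduplication."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from morphpoly.params import CallThresholds
from morphpoly.readprep import (align_read_to_contig, build_pileup,
                                mask_low_quality, select_contigs_per_ortholog,
                                trim_low_quality)

from conftest import smith_waterman_score

RNG = np.random.default_rng(20130109)


def random_seq(n, rng=RNG):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestTrim:
    def test_high_quality_read_unchanged(self, thresholds):
        read = random_seq(500)
        out = trim_low_quality(read, [30] * 500, thresholds)
        assert out is not None and out[0] == read

    def test_all_low_quality_read_rejected(self, thresholds):
        assert trim_low_quality(random_seq(200), [10] * 200, thresholds) is None

    def test_low_quality_prefix_removed_at_its_boundary(self, thresholds):
        """60 bases of Q10 then 140 of Q30: the window walk plus terminal
        stripping removes exactly the 60 bad bases, and 140 >= 100 keeps
        the read."""
        read = random_seq(200)
        quals = [10] * 60 + [30] * 140
        out = trim_low_quality(read, quals, thresholds)
        assert out is not None
        assert out[0] == read[60:]
        assert len(out[0]) == 140

    def test_symmetric_trim_at_three_prime_end(self, thresholds):
        read = random_seq(200)
        quals = [30] * 140 + [10] * 60
        out = trim_low_quality(read, quals, thresholds)
        assert out is not None and out[0] == read[:140]

    def test_short_survivor_rejected(self, thresholds):
        # 150 bases: 60 bad + 90 good < min_read_length 100
        out = trim_low_quality(random_seq(150), [10] * 60 + [30] * 90, thresholds)
        assert out is None

    def test_length_mismatch_is_an_error(self, thresholds):
        with pytest.raises(ValueError):
            trim_low_quality("ACGT", [30] * 3, thresholds)


class TestMask:
    @pytest.mark.parametrize("q,expected", [(19, "N"), (20, "A"), (21, "A")])
    def test_q20_boundary_is_strict(self, q, expected, thresholds):
        assert mask_low_quality("A", [q], thresholds) == expected

    def test_empty_read(self, thresholds):
        assert mask_low_quality("", [], thresholds) == ""

    def test_masking_preserves_length_and_positions(self, thresholds):
        read = "ACGTACGT"
        quals = [30, 10, 30, 10, 30, 30, 5, 30]
        assert mask_low_quality(read, quals, thresholds) == "ANGNACNT"


class TestAlign:
    def test_exact_substring_aligns_full_length(self):
        contig = random_seq(200)
        read = contig[40:140]
        ar = align_read_to_contig(read, contig)
        assert ar is not None and ar.score == 100
        assert ar.columns == [(40 + i, read[i]) for i in range(100)]

    def test_single_mismatch_carried_into_columns(self):
        contig = random_seq(200)
        pos = 90
        base = "A" if contig[pos] != "A" else "C"
        read = contig[40:pos] + base + contig[pos + 1:140]
        ar = align_read_to_contig(read, contig)
        assert ar is not None
        assert (pos, base) in ar.columns

    def test_reverse_complement_rejected(self):
        contig = random_seq(200)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rc = "".join(comp[b] for b in reversed(contig[40:140]))
        assert align_read_to_contig(rc, contig) is None

    def test_empty_and_all_masked_reads_rejected(self):
        contig = random_seq(100)
        assert align_read_to_contig("", contig) is None
        assert align_read_to_contig("N" * 50, contig) is None

    @given(st.data())
    def test_score_equals_dynamic_programming_oracle(self, data):
        """On short reads/contigs the library aligner's score equals an
        exhaustive Smith-Waterman under the same scoring."""
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        contig = random_seq(data.draw(st.integers(50, 200)), rng)
        n = data.draw(st.integers(10, min(50, len(contig))))
        start = int(rng.integers(0, len(contig) - n + 1))
        read = list(contig[start:start + n])
        for _ in range(data.draw(st.integers(0, 4))):
            i = int(rng.integers(len(read)))
            read[i] = "ACGTN"[int(rng.integers(5))]
        read = "".join(read)
        expected = smith_waterman_score(read, contig)
        ar = align_read_to_contig(read, contig, score_floor=0.0)
        got = 0.0 if ar is None else ar.score
        # the library aligner carries a 1e-6 gap-open tie-break
        assert got == pytest.approx(expected, abs=1e-3)


class TestPileup:
    def test_identical_reads_count_only_their_population(self, thresholds):
        contig = random_seq(120)
        ars = [align_read_to_contig(contig, contig, f"r{i}", "c", "pop1")
               for i in range(4)]
        p = build_pileup("c", 120, ars)
        depth = p.depth()
        assert (depth[:, 0] == 4).all() and (depth[:, 1] == 0).all()

    def test_masked_base_excluded_from_depth(self):
        contig = random_seq(120)
        masked = contig[:50] + "N" + contig[51:]
        ars = [align_read_to_contig(contig, contig, "r0", "c", "pop1"),
               align_read_to_contig(masked, contig, "r1", "c", "pop1")]
        p = build_pileup("c", 120, ars)
        assert p.depth()[50, 0] == 1
        assert p.depth()[49, 0] == 2

    def test_no_reads_gives_zero_pileup(self):
        p = build_pileup("c", 50, [])
        assert p.depth().sum() == 0

    def test_unknown_population_label_is_an_error(self):
        contig = random_seq(120)
        ar = align_read_to_contig(contig, contig, "r0", "c", "pop3")
        with pytest.raises(ValueError):
            build_pileup("c", 120, [ar])

    def test_pileup_conservation(self):
        """Total depth equals the summed aligned unmasked read lengths."""
        rng = np.random.default_rng(7)
        contig = random_seq(300, rng)
        ars = []
        for i in range(12):
            s = int(rng.integers(0, 150))
            ln = int(rng.integers(60, 150))
            read = list(contig[s:s + ln])
            for j in range(ln // 10):
                read[int(rng.integers(len(read)))] = "N"
            pop = "pop1" if i % 2 else "pop2"
            ar = align_read_to_contig("".join(read), contig, f"r{i}", "c", pop)
            if ar is not None:
                ars.append(ar)
        p = build_pileup("c", 300, ars)
        assert p.depth().sum() == sum(a.aligned_unmasked_length for a in ars)

    def test_masking_monotonicity(self):
        """Raising q_min never increases any pileup count."""
        rng = np.random.default_rng(11)
        contig = random_seq(200, rng)
        reads = []
        for i in range(8):
            quals = rng.integers(5, 40, size=200)
            reads.append((contig, list(quals)))
        counts = {}
        for qmin in (10, 20, 30):
            thr = CallThresholds(q_min=qmin, min_read_length=10)
            ars = []
            for i, (seq, quals) in enumerate(reads):
                masked = mask_low_quality(seq, quals, thr)
                ar = align_read_to_contig(masked, contig, f"r{i}", "c", "pop1")
                if ar is not None:
                    ars.append(ar)
            counts[qmin] = build_pileup("c", 200, ars).counts.copy()
        assert (counts[20] <= counts[10]).all()
        assert (counts[30] <= counts[20]).all()


class TestOrthologDedup:
    def test_deepest_contig_kept_per_protein(self):
        hits = pd.DataFrame({"contig_id": ["c1", "c2", "c3"],
                             "protein_id": ["P", "P", "Q"]})
        kept = select_contigs_per_ortholog({"c1": 5.0, "c2": 9.0, "c3": 2.0}, hits)
        assert kept == ["c2", "c3"]

    def test_one_contig_per_protein_unchanged(self):
        hits = pd.DataFrame({"contig_id": ["c1", "c2"],
                             "protein_id": ["P", "Q"]})
        assert select_contigs_per_ortholog({"c1": 1.0, "c2": 1.0}, hits) == \
            ["c1", "c2"]

    def test_depth_tie_breaks_lexicographically(self):
        hits = pd.DataFrame({"contig_id": ["cB", "cA"],
                             "protein_id": ["P", "P"]})
        assert select_contigs_per_ortholog({"cA": 3.0, "cB": 3.0}, hits) == ["cA"]

    def test_contigs_without_hits_dropped(self):
        hits = pd.DataFrame({"contig_id": ["c1"], "protein_id": ["P"]})
        assert select_contigs_per_ortholog({"c1": 1.0, "orphan": 9.0}, hits) == \
            ["c1"]
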