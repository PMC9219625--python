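"""Hit parsing, translated search, consolidation, flanks, census."""

import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tetrack import mining, synth

REVC = str.maketrans("ACGT", "TGCA")


def hit(start, end, score, contig="c", strand="+", ident=90.0):
    return mining.HomologyHit(
        query_id="q",
        contig=contig,
        start=start,
        end=end,
        strand=strand,
        identity=ident,
        length=end - start,
        score=score,
    )


class TestParseHitTable:
    ROW = "q1\tctg\t95.5\t120\t5\t1\t1\t120\t{s}\t{e}\t1e-50\t222"

    def test_empty_stream(self):
        assert mining.parse_hit_table(io.StringIO("")) == []

    def test_minus_strand_normalized(self):
        h = mining.parse_hit_table(io.StringIO(self.ROW.format(s=100, e=1)))[0]
        assert (h.strand, h.start, h.end) == ("-", 0, 100)

    def test_plus_strand_normalized(self):
        h = mining.parse_hit_table(io.StringIO(self.ROW.format(s=1, e=100)))[0]
        assert (h.strand, h.start, h.end) == ("+", 0, 100)

    def test_non_numeric_identity_names_line(self):
        bad = self.ROW.format(s=1, e=10).replace("95.5", "oops")
        with pytest.raises(ValueError, match="line 1"):
            mining.parse_hit_table(io.StringIO(bad))

    def test_wrong_column_count_names_line(self):
        with pytest.raises(ValueError, match="line 2"):
            mining.parse_hit_table(
                io.StringIO(self.ROW.format(s=1, e=10) + "\na\tb\n")
            )


class TestTranslatedSearch:
    def test_finds_exact_back_translated_orf(self, element):
        rng = np.random.default_rng(0)
        genome = (
            synth.random_sequence(3000, rng)
            + element.sequence
            + synth.random_sequence(3000, rng)
        )
        hits = mining.translated_search(element.transposase, genome)
        assert hits
        best = max(hits, key=lambda h: h.score)
        assert best.identity == 100.0
        assert best.strand == "+"
        # the hit covers the planted coding region
        orf_lo = 3000 + element.orf_start
        orf_hi = 3000 + element.orf_end - 3
        assert best.start <= orf_lo + 3 and best.end >= orf_hi - 3

    def test_reverse_complement_same_score_minus_strand(self, element):
        rng = np.random.default_rng(1)
        flank5, flank3 = synth.random_sequence(2000, rng), synth.random_sequence(2000, rng)
        genome = flank5 + element.sequence + flank3
        rc = genome.translate(REVC)[::-1]
        fwd = max(
            mining.translated_search(element.transposase, genome),
            key=lambda h: h.score,
        )
        rev = max(
            mining.translated_search(element.transposase, rc),
            key=lambda h: h.score,
        )
        assert rev.score == fwd.score
        assert rev.strand == "-"
        # coordinates mirror across the sequence
        assert (rev.start, rev.end) == (len(rc) - fwd.end, len(rc) - fwd.start)

    def test_shuffled_genomes_give_no_hits(self, element):
        """Empirical null: the default score threshold admits nothing from
        shuffled sequence."""
        best = mining.empirical_score_threshold(
            element.transposase,
            synth.random_sequence(6000, np.random.default_rng(3)),
            n_shuffles=30,
            seed=9,
        )
        assert best < 60.0

    def test_too_short_genome_empty(self, element):
        assert mining.translated_search(element.transposase, "ACGTACGTA") == []

    def test_short_query_rejected(self):
        with pytest.raises(ValueError):
            mining.translated_search("MKV", "ACGT" * 100)


class TestSelectTopNonoverlapping:
    def test_all_kept_when_disjoint(self):
        hits = [hit(0, 10, 5), hit(20, 30, 4), hit(40, 50, 3)]
        assert len(mining.select_top_nonoverlapping(hits, 10)) == 3

    def test_overlap_keeps_higher_score(self):
        hits = [hit(0, 10, 40), hit(5, 15, 50)]
        out = mining.select_top_nonoverlapping(hits, 10)
        assert [h.score for h in out] == [50]

    def test_score_tie_keeps_smaller_start(self):
        hits = [hit(5, 15, 50), hit(0, 10, 50)]
        out = mining.select_top_nonoverlapping(hits, 10)
        assert out[0].start == 0

    def test_caps_at_k(self):
        hits = [hit(i * 20, i * 20 + 10, 100 - i) for i in range(15)]
        assert len(mining.select_top_nonoverlapping(hits, 10)) == 10

    def test_rejects_k_zero(self):
        with pytest.raises(ValueError):
            mining.select_top_nonoverlapping([], 0)

    @given(st.permutations(list(range(6))))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_invariant_to_input_order(self, order):
        hits = [
            hit(0, 10, 9),
            hit(8, 20, 7),
            hit(30, 45, 7),
            hit(44, 60, 6),
            hit(100, 120, 2),
            hit(110, 130, 3),
        ]
        shuffled = [hits[i] for i in order]
        a = mining.select_top_nonoverlapping(hits, 3)
        b = mining.select_top_nonoverlapping(shuffled, 3)
        assert [(h.start, h.end) for h in a] == [(h.start, h.end) for h in b]


class TestExtractFlanked:
    def test_interior_hit_arithmetic(self):
        genome = "A" * 10000
        reg = mining.extract_flanked(genome, hit(4000, 5000, 1), flank=2000)
        assert len(reg.sequence) == 5000
        assert reg.left_flank == reg.right_flank == 2000
        assert not reg.left_clipped and not reg.right_clipped

    def test_hit_at_contig_start_clipped(self):
        genome = "A" * 5000
        reg = mining.extract_flanked(genome, hit(0, 1000, 1), flank=2000)
        assert reg.left_flank == 0 and reg.left_clipped
        assert reg.right_flank == 2000

    def test_zero_flank_returns_hit_sequence(self):
        genome = "ACGT" * 100
        reg = mining.extract_flanked(genome, hit(8, 24, 1), flank=0)
        assert reg.sequence == genome[8:24]

    def test_minus_strand_reverse_complemented(self):
        genome = "AAAACCCCGGGGTTTT"
        reg = mining.extract_flanked(genome, hit(4, 8, 1, strand="-"), flank=2)
        assert reg.sequence == genome[2:10].translate(REVC)[::-1]

    def test_hit_outside_contig_rejected(self):
        with pytest.raises(ValueError):
            mining.extract_flanked("ACGT", hit(2, 10, 1))


class TestCountCopies:
    def test_passing_copy_counted(self, element):
        # a 1200 bp clean fragment: coverage ~0.42, identity 1.0
        frag = element.sequence[300:1500]
        census = mining.count_copies([frag], element.sequence)
        assert census.count == 1

    def test_identity_below_threshold_not_counted(self, element):
        rng = np.random.default_rng(0)
        diverged = synth.evolve_sequence(
            element.sequence, 0.30, synth.SubstitutionModel(), rng
        )
        census = mining.count_copies([diverged], element.sequence)
        assert census.records[0].identity <= 0.80
        assert census.count == 0

    def test_empty_copy_list(self, element):
        assert mining.count_copies([], element.sequence).count == 0

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            mining.count_copies(["ACGT"], "")

    def test_boundary_values_excluded_by_strict_thresholds(self, element):
        # exactly 1000 bp fails the >1000 bp rule
        frag = element.sequence[0:1000]
        census = mining.count_copies([frag], element.sequence)
        assert census.records[0].length == 1000
        assert census.count == 0

    @given(
        min_len=st.integers(500, 1500),
        min_cov=st.floats(0.2, 0.6),
        min_id=st.floats(0.6, 0.95),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_relaxing_thresholds_is_monotone(self, min_len, min_cov, min_id, element):
        rng = np.random.default_rng(42)
        copies = [
            synth.evolve_sequence(
                element.sequence[s : s + 1600], d, synth.SubstitutionModel(), rng
            )
            for s, d in [(0, 0.05), (400, 0.15), (900, 0.25), (0, 0.02)]
        ]
        strict = mining.count_copies(
            copies, element.sequence, min_len=min_len, min_cov=min_cov, min_id=min_id
        )
        relaxed = mining.count_copies(
            copies,
            element.sequence,
            min_len=min_len - 100,
            min_cov=min_cov - 0.1,
            min_id=min_id - 0.1,
        )
        assert relaxed.count >= strict.count


class TestClusterHits:
    def test_broken_orf_segments_merge(self):
        segs = [hit(0, 300, 100), hit(500, 900, 120), hit(1100, 1300, 80)]
        merged = mining.cluster_hits(segs, max_gap=600)
        assert len(merged) == 1
        assert (merged[0].start, merged[0].end) == (0, 1300)
        assert merged[0].score == 300

    def test_distant_loci_stay_separate(self):
        merged = mining.cluster_hits([hit(0, 300, 10), hit(5000, 5300, 10)])
        assert len(merged) == 2

    def test_strands_not_merged(self):
        merged = mining.cluster_hits(
            [hit(0, 300, 10), hit(400, 700, 10, strand="-")]
        )
        assert len(merged) == 2
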