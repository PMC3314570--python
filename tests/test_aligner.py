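import numpy as np
import pytest

from conftest import mutate, random_dna, revcomp
from oracles import sw_best_score, sw_best_score_both_strands

from numtrack.aligner import (
    encode,
    local_align,
    parse_blast_tabular,
    read_hsp_tsv,
    scan_genome,
    write_blast_tabular,
    write_hsp_tsv,
)
from numtrack.karlin import min_score_for_evalue, solve_karlin_altschul
from numtrack.model import ScoringScheme


class TestLocalAlign:
    def test_identical_sequences_score_two_per_base(self):
        rng = np.random.default_rng(0)
        seq = random_dna(rng, 100)
        hsps = local_align(seq, seq, min_score=50)
        assert len(hsps) == 1
        h = hsps[0]
        assert h.raw_score == 200
        assert h.percent_identity == 100.0
        assert h.strand == "+"
        assert (h.mito.start, h.mito.end) == (0, 100)
        assert (h.nuclear.start, h.nuclear.end) == (0, 100)

    def test_reverse_complement_subject_gives_minus_hit_same_spans(self):
        rng = np.random.default_rng(1)
        seq = random_dna(rng, 100)
        hsps = local_align(seq, revcomp(seq), min_score=50)
        assert len(hsps) == 1
        h = hsps[0]
        assert h.strand == "-"
        assert h.raw_score == 200
        assert (h.mito.start, h.mito.end) == (0, 100)
        assert (h.nuclear.start, h.nuclear.end) == (0, 100)

    def test_single_substitution_scores_197(self):
        rng = np.random.default_rng(2)
        q = random_dna(rng, 101)
        s = list(q)
        s[50] = {"A": "C", "C": "A", "G": "T", "T": "G"}[s[50]]
        s = "".join(s)
        hsps = local_align(q, s, min_score=50)
        assert hsps[0].raw_score == 197  # 2*100 - 3
        assert hsps[0].raw_score == sw_best_score(q, s)
        assert hsps[0].aln_length == 101

    def test_empty_or_invalid_sequence_rejected(self):
        with pytest.raises(ValueError):
            local_align("", "ACGT")
        with pytest.raises(ValueError):
            local_align("ACGT", "ACRT")

    def test_n_scores_as_mismatch(self):
        q = "ACGTACGTACGTACGTACGT"
        s = q[:10] + "N" + q[11:]
        hsps = local_align(q, s, min_score=10)
        assert hsps[0].raw_score == sw_best_score(q, s.replace("N", "X"))

    def test_two_separate_copies_yield_two_hsps(self):
        rng = np.random.default_rng(3)
        core = random_dna(rng, 80)
        subject = random_dna(rng, 50) + core + random_dna(rng, 100) + core
        hsps = local_align(core, subject, min_score=100)
        assert len(hsps) == 2
        assert all(h.raw_score == 160 for h in hsps)
        spans = sorted((h.nuclear.start, h.nuclear.end) for h in hsps)
        assert spans == [(50, 130), (230, 310)]


class TestStrandSymmetry:
    @pytest.mark.parametrize("seed", range(5))
    def test_reverse_complementing_subject_flips_strand_and_maps_coords(
        self, seed
    ):
        rng = np.random.default_rng(seed)
        q = random_dna(rng, 120)
        s = random_dna(rng, 40) + mutate(rng, q[10:90], 0.05) + random_dna(rng, 40)
        fwd = local_align(q, s, min_score=40)
        rev = local_align(q, revcomp(s), min_score=40)
        assert len(fwd) == len(rev) >= 1
        L = len(s)
        for hf, hr in zip(
            sorted(fwd, key=lambda h: h.nuclear.start),
            sorted(rev, key=lambda h: -h.nuclear.end),
        ):
            assert hf.raw_score == hr.raw_score
            assert hf.strand != hr.strand
            assert (hf.nuclear.start, hf.nuclear.end) == (
                L - hr.nuclear.end,
                L - hr.nuclear.start,
            )
            assert (hf.mito.start, hf.mito.end) == (hr.mito.start, hr.mito.end)


class TestScanGenome:
    def test_exact_implant_recovered_at_full_identity(self):
        rng = np.random.default_rng(7)
        mt = random_dna(rng, 16500)
        chrom = random_dna(rng, 50_000)
        chrom = chrom[:20_000] + mt[3000:3500] + chrom[20_000:]
        hsps = scan_genome(mt, {"chr1": chrom})
        assert len(hsps) == 1
        h = hsps[0]
        # the optimal local alignment may extend a few bases into flanking
        # sequence that matches by chance, so require containment plus a
        # small slack rather than exact bounds
        assert h.nuclear.start <= 20_000 and h.nuclear.end >= 20_500
        assert 20_000 - h.nuclear.start <= 10 and h.nuclear.end - 20_500 <= 10
        assert h.mito.start <= 3000 and h.mito.end >= 3500
        assert h.raw_score >= 1000
        assert h.percent_identity >= 99.0
        assert h.evalue <= 1e-3

    def test_divergent_implant_covered(self):
        rng = np.random.default_rng(8)
        mt = random_dna(rng, 16500)
        implant = mutate(rng, mt[5000:5500], 0.15)
        chrom = random_dna(rng, 50_000)
        chrom = chrom[:10_000] + implant + chrom[10_000:]
        hsps = scan_genome(mt, {"chr1": chrom})
        covered = sum(
            max(0, min(h.nuclear.end, 10_500) - max(h.nuclear.start, 10_000))
            for h in hsps
        )
        assert covered >= 0.8 * 500

    def test_minus_strand_implant_mapped_back_to_forward_coords(self):
        rng = np.random.default_rng(9)
        mt = random_dna(rng, 16500)
        implant = revcomp(mt[8000:8600])
        chrom = random_dna(rng, 40_000)
        chrom = chrom[:15_000] + implant + chrom[15_000:]
        hsps = scan_genome(mt, {"chr1": chrom})
        assert len(hsps) == 1
        h = hsps[0]
        assert h.strand == "-"
        assert h.nuclear.start <= 15_000 and h.nuclear.end >= 15_600
        assert 15_000 - h.nuclear.start <= 10 and h.nuclear.end - 15_600 <= 10
        assert h.mito.start <= 8000 and h.mito.end >= 8600
        assert h.raw_score >= 1200

    def test_evalue_threshold_excludes_marginal_scores(self):
        # a score whose E-value is ~2e-3 under m=16500, n=1e6 must be dropped
        scheme = ScoringScheme()
        params = solve_karlin_altschul(scheme, m=16_500, n=1_000_000)
        s_min = min_score_for_evalue(1e-3, params)
        from numtrack.karlin import evalue

        marginal = s_min - 1
        assert evalue(marginal, params) > 1e-3
        # a perfect match of marginal//2 bases scores just below the cutoff;
        # pad the genome to 1 Mb so the same m x n search space applies
        rng = np.random.default_rng(10)
        mt = random_dna(rng, 16500)
        frag_len = marginal // 2  # score 2*frag_len < s_min
        frag = mt[100 : 100 + frag_len]
        # flanks that mismatch the continuation of the mtDNA context base by
        # base, so chance extension past the implant is impossible
        flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
        left = "".join(flip[c] for c in mt[100 - 3000 : 100])
        right = "".join(
            flip[c] for c in mt[100 + frag_len : 100 + frag_len + 3000]
        )
        chrom = (
            random_dna(rng, 497_000) + left + frag + right
            + random_dna(rng, 497_000 - frag_len)
        )
        hsps = scan_genome(mt, {"chr1": chrom})
        implant_start = 500_000
        assert not any(
            h.nuclear.start < implant_start + frag_len
            and h.nuclear.end > implant_start
            for h in hsps
        )

    def test_all_n_chromosome_yields_no_hits(self):
        rng = np.random.default_rng(11)
        mt = random_dna(rng, 2000)
        assert scan_genome(mt, {"chr1": "N" * 5000}) == []

    def test_agrees_with_exhaustive_dp_on_small_pairs(self):
        rng = np.random.default_rng(12)
        scheme = ScoringScheme()
        for _ in range(10):
            q = random_dna(rng, int(rng.integers(60, 200)))
            s = random_dna(rng, int(rng.integers(60, 200)))
            if rng.random() < 0.5:
                ins = mutate(rng, q[: len(q) // 2], 0.1)
                s = s[:20] + ins + s[20:]
            params = solve_karlin_altschul(scheme, m=len(q), n=len(s))
            s_min = min_score_for_evalue(scheme.evalue_threshold, params)
            hsps = scan_genome(q, {"s": s}, scheme)
            oracle = sw_best_score_both_strands(q, s)
            if oracle >= s_min:
                assert hsps and max(h.raw_score for h in hsps) == oracle
            else:
                assert hsps == []


class TestBlastTabular:
    def test_coordinate_conversion_plus_strand(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(
            "chrM\tchr1\t100.00\t500\t0\t0\t1\t500\t1001\t1500\t1e-50\t924\n"
        )
        (h,) = parse_blast_tabular(p)
        assert (h.mito.start, h.mito.end) == (0, 500)
        assert (h.nuclear.start, h.nuclear.end) == (1000, 1500)
        assert h.strand == "+"

    def test_swapped_subject_coords_mean_minus_strand(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(
            "chrM\tchr1\t98.00\t500\t10\t0\t1\t500\t1500\t1001\t1e-40\t800\n"
        )
        (h,) = parse_blast_tabular(p)
        assert h.strand == "-"
        assert (h.nuclear.start, h.nuclear.end) == (1000, 1500)

    def test_wrong_column_count_rejected(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("chrM\tchr1\t100.00\t500\n")
        with pytest.raises(ValueError, match="12"):
            parse_blast_tabular(p)

    def test_writer_parser_round_trip(self, tmp_path):
        rng = np.random.default_rng(13)
        q = random_dna(rng, 300)
        s = random_dna(rng, 100) + q[50:250] + random_dna(rng, 100)
        hsps = local_align(q, s, min_score=100, subject_name="chr5")
        for h in hsps:
            assert h is not None
        p = tmp_path / "out.tsv"
        write_blast_tabular(hsps, p)
        back = parse_blast_tabular(p)
        assert [(h.mito.start, h.mito.end, h.nuclear.start, h.nuclear.end,
                 h.strand) for h in back] == [
            (h.mito.start, h.mito.end, h.nuclear.start, h.nuclear.end, h.strand)
            for h in hsps
        ]

    def test_hsp_tsv_round_trip(self, tmp_path):
        rng = np.random.default_rng(14)
        q = random_dna(rng, 200)
        s = random_dna(rng, 50) + revcomp(q[20:180]) + random_dna(rng, 50)
        hsps = local_align(q, s, min_score=80, subject_name="chr2")
        p = tmp_path / "hsp.tsv"
        write_hsp_tsv(hsps, p)
        back = read_hsp_tsv(p)
        assert len(back) == len(hsps)
        for a, b in zip(back, hsps):
            assert (a.nuclear.start, a.nuclear.end, a.strand) == (
                b.nuclear.start, b.nuclear.end, b.strand,
            )
            assert a.raw_score == b.raw_score
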