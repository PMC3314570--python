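import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from numtrack.assembly import (
    AssemblyParams,
    assemble,
    assign_ids,
    repeat_aware_assemble,
)
from numtrack.model import HSP, GenomicInterval


def hsp(chrom, ns, ne, ms, me, strand="+", pid=95.0, score=200.0):
    return HSP(
        mito=GenomicInterval("chrM", ms, me),
        nuclear=GenomicInterval(chrom, ns, ne),
        strand=strand,
        raw_score=score,
        percent_identity=pid,
        aln_length=max(ne - ns, me - ms),
        evalue=1e-10,
    )


def pair(nuclear_gap, mito_gap, strand="+", colinear=True, chrom2="chr1"):
    """Two HSPs with the given gaps; mito order colinear unless told not."""
    if strand == "+":
        a = hsp("chr1", 1000, 1500, 2000, 2500, strand)
        m2 = (2500 + mito_gap) if colinear else 500
    else:
        a = hsp("chr1", 1000, 1500, 8000, 8500, strand)
        m2 = (8000 - mito_gap - 400) if colinear else 9000
    n2 = 1500 + nuclear_gap
    return a, hsp(chrom2, n2, n2 + 400, m2, m2 + 400, strand)


class TestJoiningRule:
    def test_close_colinear_pair_merges(self):
        recs = assemble(list(pair(1500, 500)))
        assert len(recs) == 1
        assert recs[0].block_count == 2
        assert (recs[0].nuclear.start, recs[0].nuclear.end) == (1000, 3400)
        assert (recs[0].mito.start, recs[0].mito.end) == (2000, 3400)

    @pytest.mark.parametrize(
        "nuclear_gap,mito_gap,expect_merge",
        [
            # nuclear threshold is strict <2000, mito inclusive <=2000
            (1999, 0, True),
            (2000, 0, False),
            (2001, 0, False),
            (0, 1999, True),
            (0, 2000, True),
            (0, 2001, False),
            (1999, 2000, True),
            (1999, 2001, False),
        ],
    )
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_gap_boundaries(self, nuclear_gap, mito_gap, expect_merge, strand):
        recs = assemble(list(pair(nuclear_gap, mito_gap, strand)))
        assert (len(recs) == 1) is expect_merge

    def test_opposite_strands_never_merge(self):
        a = hsp("chr1", 1000, 1500, 2000, 2500, "+")
        b = hsp("chr1", 1600, 2000, 2600, 3000, "-")
        assert len(assemble([a, b])) == 2

    def test_different_chromosomes_never_merge(self):
        recs = assemble(list(pair(100, 100, chrom2="chr2")))
        assert len(recs) == 2

    def test_anticolinear_pair_stays_split(self):
        recs = assemble(list(pair(100, 0, colinear=False)))
        assert len(recs) == 2

    def test_minus_strand_requires_decreasing_mito(self):
        # inverted insertion: downstream nuclear fragment carries the
        # upstream mito piece
        a = hsp("chr1", 1000, 1500, 5000, 5500, "-")
        b = hsp("chr1", 1600, 2000, 4500, 4900, "-")
        assert len(assemble([a, b])) == 1
        # same fragments in increasing mito order must not chain
        c = hsp("chr1", 1600, 2000, 5600, 6000, "-")
        assert len(assemble([a, c])) == 2

    def test_overlapping_hsps_chain(self):
        a = hsp("chr1", 1000, 1500, 2000, 2500)
        b = hsp("chr1", 1400, 1900, 2400, 2900)
        recs = assemble([a, b])
        assert len(recs) == 1 and recs[0].block_count == 2

    def test_chain_is_transitive_along_a_run(self):
        hs = [
            hsp("chr1", i * 1000, i * 1000 + 500, i * 1000, i * 1000 + 500)
            for i in range(5)
        ]
        recs = assemble(hs)
        assert len(recs) == 1 and recs[0].block_count == 5

    def test_weighted_identity_of_assembled_record(self):
        a = hsp("chr1", 0, 300, 0, 300, pid=90.0)
        b = hsp("chr1", 400, 500, 400, 500, pid=100.0)
        (rec,) = assemble([a, b])
        assert rec.percent_identity == pytest.approx((90 * 300 + 100 * 100) / 400)


class TestRepeatAware:
    def repeats(self, *ivs):
        return [GenomicInterval("chr1", a, b) for a, b in ivs]

    def test_fully_covered_long_gap_merges_and_flags(self):
        a, b = pair(3000, 100)
        (rec,) = repeat_aware_assemble([a, b], repeats=self.repeats((1500, 4500)))
        assert rec.block_count == 2
        assert rec.via_repeat

    def test_half_covered_gap_does_not_merge(self):
        a, b = pair(3000, 100)
        recs = repeat_aware_assemble(
            [a, b], repeats=self.repeats((1500, 3000))
        )
        assert len(recs) == 2

    def test_short_repeats_do_not_count(self):
        a, b = pair(3000, 100)
        # full coverage but by sub-threshold elements (<500 bp each)
        reps = self.repeats(*[(1500 + i * 300, 1800 + i * 300) for i in range(10)])
        recs = repeat_aware_assemble([a, b], repeats=reps)
        assert len(recs) == 2

    def test_coverage_fraction_boundary(self):
        a, b = pair(3000, 100)  # gap [1500, 4500)
        recs = repeat_aware_assemble(
            [a, b], repeats=self.repeats((1500, 1500 + 2700))
        )
        assert len(recs) == 1  # exactly 90% covered
        recs = repeat_aware_assemble(
            [a, b], repeats=self.repeats((1500, 1500 + 2699))
        )
        assert len(recs) == 2

    def test_no_repeats_reduces_to_plain_assemble(self):
        hs = [h for g in [(1500, 100), (2500, 100)] for h in pair(*g)]
        assert [
            (r.nuclear.start, r.nuclear.end, r.block_count)
            for r in repeat_aware_assemble(hs)
        ] == [
            (r.nuclear.start, r.nuclear.end, r.block_count)
            for r in assemble(hs)
        ]

    def test_unsorted_repeats_rejected(self):
        a, b = pair(3000, 100)
        with pytest.raises(ValueError, match="sorted"):
            repeat_aware_assemble(
                [a, b], repeats=self.repeats((2000, 2500), (1500, 1900))
            )


class TestAssignIds:
    def test_sequential_codes_and_block_suffix(self):
        recs = assemble(
            [hsp("chr2", 100, 600, 0, 500)] + list(pair(1500, 500))
            + [
                hsp("chr1", 50_000, 50_400, 7000, 7400),
                hsp("chr1", 50_500, 50_900, 7500, 7900),
                hsp("chr1", 51_000, 51_400, 8000, 8400),
            ]
        )
        comp = assign_ids(recs, "Ptr")
        assert [r.numts_id for r in comp.records] == [
            "Ptr_NumtS_001", "Ptr_NumtS_002", "Ptr_NumtS_003",
        ]
        assert comp.records[0].track_name == "Ptr_NumtS_001_b2"
        assert comp.records[1].track_name == "Ptr_NumtS_002_b3"
        assert comp.records[2].track_name == "Ptr_NumtS_003_b1"

    def test_ids_invariant_under_input_permutation(self):
        rng = np.random.default_rng(0)
        hs = [
            hsp("chr1", s, s + 200, s, s + 200)
            for s in range(0, 50_000, 5000)
        ]
        recs = assemble(hs)
        base = [(r.numts_id, r.nuclear.start) for r in assign_ids(recs, "Mms")]
        for _ in range(5):
            perm = [recs[i] for i in rng.permutation(len(recs))]
            assert [
                (r.numts_id, r.nuclear.start) for r in assign_ids(perm, "Mms")
            ] == base

    def test_bad_prefix_rejected(self):
        with pytest.raises(ValueError):
            assign_ids([], "chimp")

    def test_wide_codes_beyond_999(self):
        recs = [
            next(iter(assemble([hsp("chr1", s, s + 100, 0, 100)])))
            for s in range(0, 1001 * 3000, 3000)
        ]
        with pytest.warns(UserWarning, match="4 digits"):
            comp = assign_ids(recs, "Hsa")
        assert comp.records[-1].numts_id == "Hsa_NumtS_1001"


class TestProperties:
    @given(
        st.lists(
            st.tuples(
                st.integers(0, 30),     # nuclear start (x500)
                st.integers(1, 6),      # length (x100)
                st.integers(0, 30),     # mito start (x500)
                st.sampled_from(["+", "-"]),
                st.sampled_from(["chr1", "chr2"]),
            ),
            min_size=1,
            max_size=12,
        )
    )
    @settings(max_examples=120, deadline=None, derandomize=True)
    def test_conservation_and_no_cross_chrom_or_strand_merges(self, raw):
        hs = [
            hsp(c, ns * 500, ns * 500 + ln * 100, ms * 500,
                ms * 500 + ln * 100, strand)
            for ns, ln, ms, strand, c in raw
        ]
        recs = assemble(hs)
        # conservation: every input HSP lands in exactly one record
        assert sum(r.block_count for r in recs) == len(hs)
        for r in recs:
            assert len({h.nuclear.chrom for h in r.members}) == 1
            assert len({h.strand for h in r.members}) == 1

    @given(
        st.lists(
            st.tuples(st.integers(0, 40), st.integers(1, 5)),
            min_size=1,
            max_size=10,
        ),
        st.integers(0, 3000),
        st.integers(0, 1500),
    )
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_merge_count_monotone_in_nuclear_gap(self, raw, gap_a, delta):
        hs = [
            hsp("chr1", s * 400, s * 400 + ln * 100, s * 400,
                s * 400 + ln * 100)
            for s, ln in raw
        ]
        n_small = len(assemble(hs, AssemblyParams(max_nuclear_gap=gap_a)))
        n_large = len(
            assemble(hs, AssemblyParams(max_nuclear_gap=gap_a + delta))
        )
        assert n_large <= n_small

    def test_idempotence_on_decomposed_members(self):
        rng = np.random.default_rng(1)
        hs = []
        pos = 0
        for _ in range(20):
            pos += int(rng.integers(100, 4000))
            ln = int(rng.integers(100, 800))
            hs.append(hsp("chr1", pos, pos + ln, pos, pos + ln))
            pos += ln
        recs = assemble(hs)
        again = assemble([h for r in recs for h in r.members])
        assert [
            (r.nuclear.start, r.nuclear.end, r.block_count) for r in again
        ] == [(r.nuclear.start, r.nuclear.end, r.block_count) for r in recs]
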