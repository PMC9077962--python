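import numpy as np
import pysam
import pytest

from asmsv.intervals import IntervalSet
from asmsv.liftover import (
    ContigAlignment,
    OrthologyMap,
    build_orthology_map,
    read_contig_alignments,
    slice_alignment,
    trim_overlaps,
)
from asmsv.simulate import write_contig_sam

from conftest import make_random_alignment, per_base_liftover


def identity_alignment(length=100, contig="tig", chrom="chr1"):
    return ContigAlignment(
        contig_name=contig, contig_length=length, ref_chrom=chrom,
        ref_start=0, ref_end=length, contig_start=0, contig_end=length,
        strand="+", cigar=[("M", length)],
    )


class TestReadContigAlignments:
    def _write(self, tmp_path, records, sort_order="coordinate"):
        path = str(tmp_path / "a.sam")
        header = {
            "HD": {"VN": "1.6", "SO": sort_order},
            "SQ": [{"SN": "chr1", "LN": 100000}],
        }
        with pysam.AlignmentFile(path, "w", header=header) as fh:
            for name, flag, pos, cigar in records:
                rec = pysam.AlignedSegment(fh.header)
                rec.query_name = name
                rec.flag = flag
                rec.reference_id = 0
                rec.reference_start = pos
                rec.mapping_quality = 60
                if cigar:
                    rec.cigarstring = cigar
                fh.write(rec)
        return path

    def test_secondary_records_dropped(self, tmp_path):
        path = self._write(
            tmp_path,
            [("a", 0, 100, "100M"), ("a", 256, 500, "100M")],
        )
        alns = read_contig_alignments(path)
        assert len(alns) == 1

    def test_cigar_arithmetic_simple(self, tmp_path):
        path = self._write(tmp_path, [("a", 0, 0, "100M")])
        (aln,) = read_contig_alignments(path)
        assert aln.ref_end == 100
        assert aln.contig_end - aln.contig_start == 100

    def test_cigar_with_clip_and_deletion(self, tmp_path):
        # 10S50M10D40M from ref 100: consumes 100 ref bases, 90 contig bases
        path = self._write(tmp_path, [("a", 0, 100, "10S50M10D40M")])
        (aln,) = read_contig_alignments(path)
        assert aln.ref_start == 100 and aln.ref_end == 200
        assert aln.contig_end - aln.contig_start == 90
        assert aln.contig_start == 10  # soft clip offsets the contig start

    def test_unsorted_file_rejected(self, tmp_path):
        path = self._write(
            tmp_path, [("a", 0, 0, "100M")], sort_order="unsorted"
        )
        with pytest.raises(ValueError, match="samtools sort"):
            read_contig_alignments(path)

    def test_missing_cigar_skipped(self, tmp_path):
        path = self._write(
            tmp_path, [("nocig", 4, 0, None), ("ok", 0, 10, "50M")]
        )
        alns = read_contig_alignments(path)
        assert [a.contig_name for a in alns] == ["ok"]


class TestTrimOverlaps:
    def _aln(self, contig, clen, lo, hi):
        return ContigAlignment(
            contig_name=contig, contig_length=clen, ref_chrom="chr1",
            ref_start=lo, ref_end=hi, contig_start=0, contig_end=hi - lo,
            strand="+", cigar=[("M", hi - lo)],
        )

    def test_shorter_contig_trimmed(self):
        a = self._aln("A", 10_000, 0, 1000)
        b = self._aln("B", 5_000, 900, 2000)
        kept, trimmed = trim_overlaps([a, b])
        spans = {(k.contig_name, k.ref_start, k.ref_end) for k in kept}
        assert ("A", 0, 1000) in spans
        assert ("B", 1000, 2000) in spans
        assert trimmed["chr1"].intervals == [(900, 1000)]

    def test_disjoint_unchanged(self):
        a = self._aln("A", 10_000, 0, 1000)
        b = self._aln("B", 5_000, 2000, 3000)
        kept, trimmed = trim_overlaps([a, b])
        assert len(kept) == 2
        assert trimmed["chr1"].total_length() == 0

    def test_contained_alignment_removed(self):
        a = self._aln("A", 10_000, 0, 2000)
        b = self._aln("B", 5_000, 500, 1500)
        kept, _ = trim_overlaps([a, b])
        assert [k.contig_name for k in kept] == ["A"]

    def test_three_way_overlap_is_overlap_free(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            alns = [
                self._aln("A", 30_000, 0, 1500),
                self._aln("B", 20_000, int(rng.integers(0, 1400)), 2500),
                self._aln("C", 10_000, int(rng.integers(0, 2400)), 3500),
            ]
            kept, _ = trim_overlaps(alns)
            # brute force: every reference base covered at most once
            cover = np.zeros(4000, dtype=int)
            for k in kept:
                cover[k.ref_start:k.ref_end] += 1
            assert cover.max() <= 1
            # longest contig untouched
            a = [k for k in kept if k.contig_name == "A"]
            assert a and a[0].ref_start == 0 and a[0].ref_end == 1500
            # union preserved
            union = IntervalSet(
                [(x.ref_start, x.ref_end) for x in alns]
            ).total_length()
            assert cover.sum() == union


class TestOrthologyMap:
    def test_identity_map_entries(self):
        m = build_orthology_map([identity_alignment(100)], spacing=20)
        got = [m.lookup("chr1", g) for g in (0, 20, 40, 60, 80)]
        assert got == [("tig", g, "+") for g in (0, 20, 40, 60, 80)]
        assert m.n_records() == 5

    def test_deletion_maps_to_left_edge(self):
        aln = ContigAlignment(
            contig_name="tig", contig_length=100, ref_chrom="chr1",
            ref_start=0, ref_end=110, contig_start=0, contig_end=100,
            strand="+", cigar=[("M", 50), ("D", 10), ("M", 50)],
        )
        m = build_orthology_map([aln], spacing=20)
        assert m.lookup("chr1", 60) == ("tig", 50, "+")

    def test_minus_strand_monotonic_decreasing(self):
        aln = ContigAlignment(
            contig_name="tig", contig_length=100, ref_chrom="chr1",
            ref_start=0, ref_end=100, contig_start=0, contig_end=100,
            strand="-", cigar=[("M", 100)],
        )
        m = build_orthology_map([aln], spacing=20)
        cpos = [m.lookup("chr1", g)[1] for g in (0, 20, 40, 60, 80)]
        assert cpos == sorted(cpos, reverse=True)

    def test_lookup_floors_to_grid(self):
        m = build_orthology_map([identity_alignment(100)], spacing=20)
        assert m.lookup("chr1", 47) == ("tig", 40, "+")

    def test_lookup_outside_coverage(self):
        aln = identity_alignment(100)
        aln.ref_start, aln.ref_end = 50, 150
        aln.cigar = [("M", 100)]
        m = build_orthology_map([aln], spacing=20)
        assert m.lookup("chr1", 30) is None
        assert m.lookup("chr1", 55) is None  # before first grid point (60)
        assert m.lookup("chrX", 60) is None  # unknown chromosome

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_lookup_matches_per_base_oracle(self, strand):
        rng = np.random.default_rng(42)
        for rep in range(25):
            aln = make_random_alignment(
                rng, ref_start=int(rng.integers(0, 50)), strand=strand
            )
            m = build_orthology_map([aln], spacing=20)
            oracle = per_base_liftover(aln)
            grid = [
                g for g in range(0, aln.ref_end, 20) if g >= aln.ref_start
            ]
            for g in grid:
                got = m.lookup(aln.ref_chrom, g)
                assert got is not None
                assert got[1] == oracle[g], (rep, g, aln.cigar)

    def test_map_size_equals_grid_points_in_coverage(self):
        rng = np.random.default_rng(7)
        alns = [
            make_random_alignment(rng, ref_start=i * 5000, contig=f"t{i}")
            for i in range(5)
        ]
        m = build_orthology_map(alns, spacing=20)
        expected = sum(
            len(range(-(-a.ref_start // 20) * 20, a.ref_end, 20))
            for a in alns
        )
        assert m.n_records() == expected

    def test_empty_alignment_list(self):
        m = build_orthology_map([], spacing=20)
        assert m.n_records() == 0
        assert m.lookup("chr1", 0) is None


class TestSliceAlignment:
    def test_slice_consistency_with_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            aln = make_random_alignment(rng)
            oracle = per_base_liftover(aln)
            lo = int(rng.integers(aln.ref_start, aln.ref_end - 1))
            hi = int(rng.integers(lo + 1, aln.ref_end))
            piece = slice_alignment(aln, lo, hi)
            if piece is None:
                continue
            piece.validate()
            sub = per_base_liftover(piece)
            for p, c in sub.items():
                assert oracle[p] == c


class TestRoundTrip:
    def test_tsv_round_trip_preserves_lookup(self, tmp_path):
        rng = np.random.default_rng(9)
        alns = [
            make_random_alignment(rng, ref_start=i * 3000, contig=f"t{i}")
            for i in range(4)
        ]
        m = build_orthology_map(alns, spacing=20)
        path = str(tmp_path / "map.tsv")
        m.to_tsv(path)
        m2 = OrthologyMap.from_tsv(path, spacing=20)
        for aln in alns:
            for g in range(0, aln.ref_end, 20):
                if g < aln.ref_start:
                    continue
                assert m.lookup("chr1", g) == m2.lookup("chr1", g)

    def test_sam_round_trip(self, tmp_path):
        rng = np.random.default_rng(13)
        alns = sorted(
            (
                make_random_alignment(rng, ref_start=i * 3000, contig=f"t{i}")
                for i in range(4)
            ),
            key=lambda a: a.ref_start,
        )
        path = str(tmp_path / "a.sam")
        write_contig_sam(path, alns, {"chr1": 100_000})
        back = read_contig_alignments(path)
        assert len(back) == len(alns)
        for a, b in zip(alns, back):
            assert (a.ref_start, a.ref_end) == (b.ref_start, b.ref_end)
            assert (a.contig_start, a.contig_end) == (b.contig_start, b.contig_end)
            assert a.strand == b.strand
            assert per_base_liftover(a) == per_base_liftover(b)
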