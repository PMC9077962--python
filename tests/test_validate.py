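import math
from dataclasses import replace

import numpy as np
import pytest

from asmsv.intervals import IntervalSet
from asmsv.liftover import build_orthology_map
from asmsv.qc import build_confidence_filter
from asmsv.simulate import (
    SVPlan,
    make_diploid,
    random_sequence,
    simulate_duplications,
)
from asmsv.svmodel import SVCall
from asmsv.validate import (
    ClassifierParams,
    classify,
    extract_intervals,
    genotype_concordance,
    relative_length,
    relative_score,
    score_alignment,
    search_breakpoints,
    validate_call,
    validate_interspersed_dup,
)

from conftest import gotoh_score

PARAMS = ClassifierParams()


class TestEvidenceArithmetic:
    @pytest.mark.parametrize(
        "clen,rlen,svlen,expected",
        [
            (700, 1000, -300, 1.0),  # true deletion shortens the contig
            (1000, 1000, -300, 0.0),  # no length change: FP deletion
            (1120, 1000, 120, 1.0),  # true insertion
        ],
    )
    def test_relative_length(self, clen, rlen, svlen, expected):
        assert relative_length(clen, rlen, svlen) == expected

    def test_relative_length_rejects_zero_svlen(self):
        with pytest.raises(ValueError):
            relative_length(100, 100, 0)

    @pytest.mark.parametrize(
        "after,before,expected",
        [
            (100, 50, 1.0),
            (-20, -50, 0.6),  # improvement from a negative baseline
            (50, 50, 0.0),
        ],
    )
    def test_relative_score(self, after, before, expected):
        assert relative_score(after, before) == pytest.approx(expected)

    def test_relative_score_zero_baseline_sentinel(self):
        assert relative_score(10, 0) == math.inf
        assert relative_score(-10, 0) == -math.inf
        assert relative_score(0, 0) == 0.0


class TestScoreAlignment:
    def test_identical_sequences_closed_form(self):
        seq = "ACGT" * 25
        assert score_alignment(seq, seq) == 100 * PARAMS.match

    def test_single_mismatch_closed_form(self):
        a = "A" * 49 + "C" + "A" * 50
        b = "A" * 100
        assert score_alignment(a, b) == 99 * PARAMS.match + PARAMS.mismatch

    def test_non_iupac_rejected(self):
        with pytest.raises(ValueError, match="non-IUPAC"):
            score_alignment("ACGT", "AC-T")

    def test_matches_quadratic_dp_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(15):
            a = random_sequence(rng, int(rng.integers(5, 200)))
            b = random_sequence(rng, int(rng.integers(5, 200)))
            assert score_alignment(a, b) == pytest.approx(gotoh_score(a, b))


class TestClassify:
    def test_center_of_upper_branch(self):
        assert classify(1.0, 2 * PARAMS.gamma, "DEL", False, PARAMS)

    def test_negative_score_outside_region(self):
        assert not classify(0.0, -0.5, "DEL", False, PARAMS)

    def test_region_matches_direct_inequalities_on_grid(self):
        """Piecewise TP region == direct inequality evaluation, 200x200."""
        rls = np.linspace(-1, 3, 200)
        rss = np.linspace(-1, 3, 200)
        p = PARAMS
        for rl in rls:
            for rs in rss:
                direct = (
                    0 <= rs <= p.gamma
                    and -p.alpha * rs + 1 - p.beta <= rl <= p.alpha * rs + 1 + p.beta
                ) or (rs > p.gamma and 1 - p.delta <= rl <= 1 + p.delta)
                assert classify(rl, rs, "DEL", True, p) == direct

    def test_inversion_by_score_sign_only(self):
        assert classify(0.0, 0.01, "INV", False, PARAMS)
        assert not classify(1.0, -0.01, "INV", False, PARAMS)

    def test_length_only_insertion_band(self):
        assert classify(1.05, math.nan, "INS", False, PARAMS)
        assert not classify(0.5, math.nan, "INS", False, PARAMS)


class TestGenotypeConcordance:
    def test_both_haplotypes_hom(self):
        assert genotype_concordance(True, True, "1/1") is True

    def test_one_haplotype_called_hom_discordant(self):
        assert genotype_concordance(True, False, "1/1") is False

    def test_het_concordant_and_phased_input(self):
        assert genotype_concordance(False, True, "0/1") is True
        assert genotype_concordance(True, False, "1|0") is True

    def test_missing_genotype_undefined(self):
        assert genotype_concordance(True, True, None) is None
        assert genotype_concordance(True, True, "./.") is None


def _het_del_fixture(seed=21):
    plans = [SVPlan("DEL", 300, zygosity="het", pos=50_000)]
    return make_diploid(seed, 120_000, plans)


def _maps(fixture):
    return {
        h: build_orthology_map(fixture.alignments[h], haplotype=h)
        for h in (1, 2)
    }


class TestExtractIntervals:
    def test_identity_window(self):
        fx = make_diploid(3, 60_000, [])
        m = _maps(fx)[1]
        call = SVCall("x", fx.chrom, 1000, 1300, "DEL", -300)
        (ref_iv, contig_iv) = extract_intervals(call, m, w=500)
        assert ref_iv == (500, 1800)
        assert contig_iv[1:3] == (500, 1800)

    def test_flanks_on_different_contigs_not_liftable(self):
        fx = make_diploid(4, 100_000, [], uncovered={1: [(40_000, 42_000)]})
        m = _maps(fx)[1]
        call = SVCall("x", fx.chrom, 39_900, 42_100, "DEL", -2200)
        assert extract_intervals(call, m, w=500) is None

    def test_contig_deletion_shortens_interval(self):
        fx = _het_del_fixture()
        hap_with_del = 1 if fx.truth_hap[fx.truth[0].id][0] else 2
        m = _maps(fx)[hap_with_del]
        call = fx.truth[0]
        (ref_iv, contig_iv) = extract_intervals(call, m, w=500)
        ref_len = ref_iv[1] - ref_iv[0]
        contig_len = contig_iv[2] - contig_iv[1]
        assert abs((ref_len - contig_len) - 300) <= m.spacing


class TestSearchBreakpoints:
    def test_non_repetitive_optimum_is_default(self):
        fx = _het_del_fixture()
        hap = 1 if fx.truth_hap[fx.truth[0].id][0] else 2
        m = _maps(fx)[hap]
        call = fx.truth[0]
        best = search_breakpoints(
            call, m, {fx.chrom: fx.reference}, fx.hap_seqs[hap], PARAMS
        )
        sp = PARAMS.spacing
        assert best.ref_lo == ((call.start - PARAMS.w) // sp) * sp
        assert best.ref_hi == ((call.end + PARAMS.w) // sp) * sp
        assert best.rl == pytest.approx(1.0, abs=0.15)
        assert best.rs > 0

    def test_radius_zero_degenerates_to_default_interval(self):
        fx = _het_del_fixture()
        hap = 1 if fx.truth_hap[fx.truth[0].id][0] else 2
        m = _maps(fx)[hap]
        call = fx.truth[0]
        p0 = replace(PARAMS, search_radius=1)
        # radius cannot be 0 by construction; compare k=0 candidate of a
        # minimal search with the documented default interval instead
        best = search_breakpoints(
            call, m, {fx.chrom: fx.reference}, fx.hap_seqs[hap], p0
        )
        ref_iv, contig_iv = extract_intervals(call, m, w=PARAMS.w)
        sp = m.spacing
        assert abs(best.ref_lo - ref_iv[0]) <= sp
        assert abs(best.ref_hi - ref_iv[1]) <= sp


class TestValidateCall:
    def test_true_het_deletion_tp_with_genotype(self):
        fx = _het_del_fixture()
        maps = _maps(fx)
        call = fx.truth[0]
        res = validate_call(
            call, maps, fx.hap_seqs, {fx.chrom: fx.reference}, None, PARAMS
        )
        assert res.classification == "TP"
        assert res.relative_length == pytest.approx(1.0, abs=0.15)
        assert res.relative_score > 0
        assert res.gt_concordant is True

    def test_random_interval_fp_deletion(self):
        fx = _het_del_fixture()
        maps = _maps(fx)
        call = SVCall("fp", fx.chrom, 20_000, 20_400, "DEL", -400,
                      genotype="0/1")
        res = validate_call(
            call, maps, fx.hap_seqs, {fx.chrom: fx.reference}, None, PARAMS
        )
        assert res.classification == "FP"
        assert abs(res.relative_length) < 0.3

    def test_call_in_centromere_is_na(self):
        fx = make_diploid(6, 100_000, [], centromere=(40_000, 50_000))
        maps = _maps(fx)
        cen = {fx.chrom: IntervalSet([fx.centromere])}
        filt = build_confidence_filter(
            maps[1], maps[2], cen, {fx.chrom: fx.genome_len}
        )
        call = SVCall("c", fx.chrom, 44_000, 44_300, "DEL", -300)
        res = validate_call(
            call, maps, fx.hap_seqs, {fx.chrom: fx.reference}, filt, PARAMS
        )
        assert res.classification == "NA"
        assert res.na_reason == "centromere"

    def test_haplotype_symmetry(self):
        fx = _het_del_fixture()
        maps = _maps(fx)
        call = fx.truth[0]
        ref = {fx.chrom: fx.reference}
        res = validate_call(call, maps, fx.hap_seqs, ref, None, PARAMS)
        swapped_maps = {1: maps[2], 2: maps[1]}
        swapped_asm = {1: fx.hap_seqs[2], 2: fx.hap_seqs[1]}
        res_sw = validate_call(
            call, swapped_maps, swapped_asm, ref, None, PARAMS
        )
        assert res.classification == res_sw.classification
        assert res.best_haplotype != res_sw.best_haplotype

    def test_congruence_peaks_at_true_svlen(self):
        """Relative score is maximal at the true deletion length and falls
        off when the candidate claims a length off by +/-50%."""
        fx = _het_del_fixture()
        maps = _maps(fx)
        hap = 1 if fx.truth_hap[fx.truth[0].id][0] else 2
        t = fx.truth[0]
        ref = {fx.chrom: fx.reference}
        scores = {}
        for frac in (0.5, 1.0, 1.5):
            dlen = int(300 * frac)
            call = SVCall("p", fx.chrom, t.start, t.start + dlen, "DEL", -dlen)
            best = search_breakpoints(
                call, maps[hap], ref, fx.hap_seqs[hap], PARAMS
            )
            scores[frac] = best.rs
        assert scores[1.0] > scores[0.5]
        assert scores[1.0] > scores[1.5]


class TestInterspersedDup:
    def _sim(self, **kw):
        fx, dups, audit = simulate_duplications(
            31, n=6, len_min=500, len_max=3000, genome_len=400_000, **kw
        )
        maps = _maps(fx)
        return fx, dups, audit, maps

    def test_true_copy_validates(self):
        fx, dups, audit, maps = self._sim(true_fraction=1.0)
        for call in dups:
            cls, hap, cov = validate_interspersed_dup(
                call, maps, fx.hap_seqs, {fx.chrom: fx.reference}, PARAMS
            )
            assert cls == "TP" and cov >= 0.9

    def test_absent_copy_is_fp(self):
        fx, dups, audit, maps = self._sim(true_fraction=0.0)
        for call in dups:
            cls, _, _ = validate_interspersed_dup(
                call, maps, fx.hap_seqs, {fx.chrom: fx.reference}, PARAMS
            )
            assert cls == "FP"

    def test_partial_copy_below_coverage_threshold_is_fp(self):
        # plant an 85% copy by hand: below the 0.90 coverage requirement
        rng = np.random.default_rng(40)
        ref = random_sequence(rng, 200_000)
        s, e = 50_000, 52_000
        partial = ref[s : s + int(0.85 * (e - s))]
        ins = SVCall("c", "chr1", 150_000, 150_001, "INS",
                     len(partial), alt_seq=partial)
        from asmsv.simulate import _build_haplotype

        h1, a1 = _build_haplotype(ref, [ins], "h1", "chr1")
        h2, a2 = _build_haplotype(ref, [], "h2", "chr1")
        maps = {
            1: build_orthology_map([a1], haplotype=1),
            2: build_orthology_map([a2], haplotype=2),
        }
        call = SVCall("d", "chr1", s, e, "DUP", e - s)
        cls, _, cov = validate_interspersed_dup(
            call, maps, {1: {"h1": h1}, 2: {"h2": h2}}, {"chr1": ref}, PARAMS
        )
        assert cls == "FP"
        assert cov < 0.90

    def test_too_short_duplication_is_na(self):
        fx, dups, _, maps = self._sim(true_fraction=1.0)
        call = SVCall("tiny", fx.chrom, 1000, 1030, "DUP", 30)
        cls, _, _ = validate_interspersed_dup(
            call, maps, fx.hap_seqs, {fx.chrom: fx.reference}, PARAMS
        )
        assert cls == "NA"
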