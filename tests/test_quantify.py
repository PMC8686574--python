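import math

import numpy as np
import pysam
import pytest
from scipy.stats import binomtest

from mosaicscreen.core import VariantKey, is_undefined
from mosaicscreen.quantify import (
    DropletCounts,
    amplicon_vaf_from_counts,
    amplicon_vaf_indel,
    amplicon_vaf_snv,
    apply_lod,
    clopper_pearson,
    count_snv_in_sam,
    ddpcr_vaf,
    lambda_from_droplets,
    left_align_indel,
    lod_from_dilution,
)
from mosaicscreen.simulate import simulate_droplets


class TestClopperPearson:
    def test_boundary_pinning(self):
        lo, hi = clopper_pearson(0, 500)
        assert lo == 0.0 and hi < 0.02
        lo, hi = clopper_pearson(500, 500)
        assert hi == 1.0

    def test_matches_independent_exact_inversion(self):
        """Beta-quantile form vs scipy's direct binomial test inversion."""
        for k, n in [(5, 1000), (1, 100), (50, 100), (0, 10), (10, 10), (300, 10000)]:
            lo, hi = clopper_pearson(k, n)
            ref = binomtest(k, n).proportion_ci(0.95, method="exact")
            assert lo == pytest.approx(ref.low, abs=1e-12)
            assert hi == pytest.approx(ref.high, abs=1e-12)

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError):
            clopper_pearson(1, 10, level=1.5)


class TestAmpliconSnv:
    def test_count_ratio(self):
        m = amplicon_vaf_from_counts(300, 10_000)
        assert m.vaf == pytest.approx(0.03)
        assert m.ci_low <= m.vaf <= m.ci_high
        assert m.detected

    def test_zero_alt(self):
        m = amplicon_vaf_from_counts(0, 10_000)
        assert m.vaf == 0.0 and m.ci_low == 0.0
        assert not m.detected

    def test_zero_depth_flagged(self):
        m = amplicon_vaf_from_counts(0, 0)
        assert is_undefined(m.vaf)
        assert "insufficient_depth" in m.qc_flags

    def test_base_quality_floor(self):
        key = VariantKey("chr1", 100, "A", "G")
        calls = [("G", 30)] * 3 + [("A", 30)] * 7 + [("G", 10)] * 5  # low-q dropped
        m = amplicon_vaf_snv(calls, key, qmin=20)
        assert m.depth == 10 and m.alt_count == 3

    def test_equals_naive_enumeration_counter(self):
        rng = np.random.default_rng(7)
        key = VariantKey("chr1", 100, "A", "G")
        bases = rng.choice(list("ACGT"), size=5000)
        quals = rng.integers(2, 41, size=5000)
        m = amplicon_vaf_snv(zip(bases, quals), key, qmin=20)
        naive_depth = sum(1 for q in quals if q >= 20)
        naive_alt = sum(1 for b, q in zip(bases, quals) if q >= 20 and b == "G")
        assert (m.alt_count, m.depth) == (naive_alt, naive_depth)

    def test_deep_sample_ci_covers_truth_at_nominal_rate(self):
        """At 600,000x and true VAF 0.3%, the exact interval covers the truth
        with probability >= 95% (exact binomial coverage enumeration)."""
        from scipy.stats import binom as binom_dist

        n, p = 600_000, 0.003
        mean = n * p
        half = 8 * math.sqrt(n * p * (1 - p))
        ks = np.arange(max(0, int(mean - half)), int(mean + half) + 1)
        coverage = sum(
            float(binom_dist.pmf(k, n, p))
            for k in ks
            if clopper_pearson(int(k), n)[0] <= p <= clopper_pearson(int(k), n)[1]
        )
        assert coverage >= 0.95


def _sam_reads(tmp_path, rows):
    """Write a one-contig SAM and return its reads. rows: (name, pos1, cigar, seq)."""
    path = tmp_path / "amplicon.sam"
    header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": 10_000}]}
    with pysam.AlignmentFile(path, "w", header=pysam.AlignmentHeader.from_dict(header)) as out:
        for name, pos1, cigar, seq in rows:
            a = pysam.AlignedSegment(out.header)
            a.query_name = name
            a.reference_id = 0
            a.reference_start = pos1 - 1
            a.cigarstring = cigar
            a.query_sequence = seq
            a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            a.mapping_quality = 60
            out.write(a)
    with pysam.AlignmentFile(path, "r") as fh:
        return list(fh)


class TestAmpliconIndel:
    def test_direct_count_of_exact_duplication(self, tmp_path):
        # 1-bp duplication: ref T at 100, alt TT -> 1-bp insertion after pos 100
        key = VariantKey("chr1", 100, "T", "TT")
        ref_reads = [(f"r{i}", 90, "21M", "A" * 21) for i in range(7)]
        alt_reads = [(f"a{i}", 90, "11M1I10M", "A" * 10 + "T" + "T" + "A" * 10) for i in range(3)]
        reads = _sam_reads(tmp_path, ref_reads + alt_reads)
        m = amplicon_vaf_indel(reads, key)
        assert (m.alt_count, m.depth) == (3, 10)
        assert m.vaf == pytest.approx(0.3)

    def test_indel_at_wrong_position_not_counted(self, tmp_path):
        key = VariantKey("chr1", 100, "T", "TT")
        reads = _sam_reads(
            tmp_path,
            [("r1", 90, "21M", "A" * 21), ("r2", 90, "5M1I15M", "A" * 21)],
        )
        m = amplicon_vaf_indel(reads, key)
        assert (m.alt_count, m.depth) == (0, 2)

    def test_deletion_counted_by_length(self, tmp_path):
        key = VariantKey("chr1", 100, "TAG", "T")  # 2-bp deletion at 101-102
        reads = _sam_reads(
            tmp_path,
            [
                ("d1", 90, "11M2D10M", "A" * 21),
                ("d2", 90, "11M1D10M", "A" * 21),  # wrong length
                ("r1", 90, "23M", "A" * 23),
            ],
        )
        m = amplicon_vaf_indel(reads, key)
        assert (m.alt_count, m.depth) == (1, 3)

    def test_nonspanning_reads_excluded_and_tallied(self, tmp_path):
        key = VariantKey("chr1", 100, "T", "TT")
        reads = _sam_reads(
            tmp_path,
            [("r1", 99, "4M", "AAAA"), ("r2", 90, "21M", "A" * 21)],
        )
        m = amplicon_vaf_indel(reads, key, flank=5)
        assert m.depth == 1
        assert any(f.startswith("nonspanning") for f in m.qc_flags)

    def test_snv_key_rejected(self):
        with pytest.raises(ValueError):
            amplicon_vaf_indel([], VariantKey("chr1", 100, "A", "G"))


class TestLeftAlign:
    def test_shifts_duplication_to_leftmost_position(self):
        # ref A C T T T G: inserting a T anywhere in the TTT run (pos 3-5) is
        # equivalent; the canonical form anchors at the C before the run
        refseq = "ACTTTG"
        pos, ref, alt = left_align_indel(5, "T", "TT", refseq, seq_start=1)
        assert (pos, ref, alt) == (2, "C", "CT")

    def test_deletion_shifts_through_homopolymer(self):
        # deleting any single T of the run is equivalent; canonical anchor is C
        refseq = "ACTTTG"
        pos, ref, alt = left_align_indel(4, "TT", "T", refseq, seq_start=1)
        assert (pos, ref, alt) == (2, "CT", "C")

    def test_non_repetitive_indel_unmoved(self):
        refseq = "ACGTAG"
        assert left_align_indel(3, "G", "GA", refseq, seq_start=1) == (3, "G", "GA")

    def test_snv_untouched(self):
        assert left_align_indel(5, "A", "G", "AAAAA", 1) == (5, "A", "G")


class TestSnvFromSam:
    def test_counts_base_at_target_position(self, tmp_path):
        key = VariantKey("chr1", 100, "A", "G")
        reads = _sam_reads(
            tmp_path,
            [
                ("r1", 96, "9M", "AAAAGAAAA"),  # pos 100 = offset 4 -> G
                ("r2", 96, "9M", "AAAAAAAAA"),  # ref
                ("r3", 200, "9M", "AAAAAAAAA"),  # does not cover target
            ],
        )
        alt, depth = count_snv_in_sam(reads, key)
        assert (alt, depth) == (1, 2)


class TestDdpcr:
    def test_lambda_closed_form(self):
        assert lambda_from_droplets(9000, 10000) == pytest.approx(0.10536051565782628)

    def test_all_negative_lambda_zero(self):
        assert lambda_from_droplets(10000, 10000) == 0.0

    def test_saturated_assay_rejected(self):
        with pytest.raises(ValueError):
            lambda_from_droplets(0, 10000)

    def test_symmetric_counts_give_half(self):
        d = DropletCounts(n_mut_only=500, n_wt_only=500, n_double_pos=30, n_neg=8970)
        r = ddpcr_vaf(d)
        assert r.vaf == pytest.approx(0.5)

    def test_no_mutant_droplets_give_zero(self):
        d = DropletCounts(n_mut_only=0, n_wt_only=4000, n_double_pos=0, n_neg=6000)
        r = ddpcr_vaf(d)
        assert r.vaf == 0.0
        assert not r.detected

    def test_no_template_flagged(self):
        d = DropletCounts(n_mut_only=0, n_wt_only=0, n_double_pos=0, n_neg=10000)
        r = ddpcr_vaf(d)
        assert is_undefined(r.vaf)
        assert "no_template" in r.qc_flags

    def test_channel_swap_symmetry(self):
        """Swapping channels maps the estimate (and interval) to 1 - vaf."""
        d = DropletCounts(n_mut_only=150, n_wt_only=7000, n_double_pos=120, n_neg=12730)
        s = DropletCounts(n_mut_only=7000, n_wt_only=150, n_double_pos=120, n_neg=12730)
        r, rs = ddpcr_vaf(d), ddpcr_vaf(s)
        assert rs.vaf == pytest.approx(1.0 - r.vaf)
        assert rs.ci_low == pytest.approx(1.0 - r.ci_high)
        assert rs.ci_high == pytest.approx(1.0 - r.ci_low)

    def test_round_trip_recovery_within_ci(self):
        """Simulated wells at true VAF 2% are covered by the CI in >= 90%
        of seeded replicates."""
        covered = 0
        for seed in range(100):
            d = simulate_droplets(20_000, 1.0, 0.02, seed=seed)
            r = ddpcr_vaf(d)
            covered += r.ci_low <= 0.02 <= r.ci_high
        assert covered / 100 >= 0.90

    def test_lambda_estimate_consistency(self):
        """Bias of the λ estimator shrinks as droplet count grows."""
        true_lam = 0.8
        biases = []
        for n in (1_000, 10_000, 100_000):
            errs = []
            for seed in range(30):
                rng = np.random.default_rng(seed + n)
                n_neg = int(rng.binomial(n, math.exp(-true_lam)))
                errs.append(lambda_from_droplets(n_neg, n) - true_lam)
            biases.append(abs(float(np.mean(errs))))
        assert biases[2] < biases[0]
        assert biases[2] < 5e-3


class TestLod:
    @pytest.mark.parametrize(
        "v,expected", [(0.003, False), (0.0213, True), (0.005, True)]
    )
    def test_detection_call_inclusive(self, v, expected):
        assert apply_lod(v) is expected

    def test_dilution_series_finds_half_percent(self):
        series = [
            (0.02, [True, True, True]),
            (0.01, [True, True, True]),
            (0.005, [True, True, True]),
            (0.0025, [True, False, True]),
        ]
        assert lod_from_dilution(series) == 0.005

    def test_single_fully_detected_level(self):
        assert lod_from_dilution([(0.01, [True, True])]) == 0.01

    def test_all_partial_is_undefined(self):
        assert lod_from_dilution([(0.01, [True, False]), (0.005, [False])]) is None

    def test_non_decreasing_series_rejected(self):
        with pytest.raises(ValueError):
            lod_from_dilution([(0.005, [True]), (0.01, [True])])
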