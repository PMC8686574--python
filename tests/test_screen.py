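import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mosaicscreen.core import (
    Genotype,
    PopulationFrequencies,
    SampleCall,
    ScreenConfig,
    TrioSiteCall,
    VariantKey,
)
from mosaicscreen.screen import (
    FILTER_INCOMPLETE_TRIO,
    RegionMask,
    is_apparent_denovo,
    passes_depth,
    passes_het_window,
    passes_popfreq,
    passes_region_mask,
    read_freq_table,
    read_trio_vcf,
    screen_trio,
    screen_trios,
    write_candidates_tsv,
    read_candidates_tsv,
)

from conftest import make_trio, write_trio_vcf


class TestApparentDenovo:
    def test_het_proband_ref_parents_is_denovo(self, clean_trio):
        flag, qc = is_apparent_denovo(clean_trio)
        assert flag and qc is None

    def test_inherited_variant_is_not_denovo(self):
        trio = make_trio(mother=("het", 120, 55))
        flag, _ = is_apparent_denovo(trio)
        assert not flag

    def test_hemizygous_proband_on_x_is_denovo(self):
        trio = make_trio(chrom="chrX", proband=("hemi", 60, 58))
        flag, qc = is_apparent_denovo(trio)
        assert flag and qc is None

    def test_missing_parent_flags_incomplete_trio_never_passes(self):
        trio = make_trio(father=("missing", 0, 0))
        flag, qc = is_apparent_denovo(trio)
        assert not flag
        assert qc == FILTER_INCOMPLETE_TRIO


class TestHetWindow:
    @pytest.mark.parametrize(
        "v,expected",
        [
            (0.47, True),
            (0.29, False),
            (0.30, True),  # boundary kept: only strictly <30% is eliminated
            (0.70, True),  # boundary kept: only strictly >70% is eliminated
            (0.71, False),
        ],
    )
    def test_het_window_boundaries(self, v, expected, cfg):
        assert passes_het_window(v, cfg) is expected

    def test_hemizygous_uses_hemi_floor_instead(self, cfg):
        assert passes_het_window(0.85, cfg, hemizygous=True)
        assert not passes_het_window(0.5, cfg, hemizygous=True)

    def test_undefined_vaf_fails(self, cfg):
        assert not passes_het_window(math.nan, cfg)


class TestDepthAndFrequency:
    @pytest.mark.parametrize("depth,expected", [(20, True), (19, False), (0, False)])
    def test_depth_threshold_inclusive_at_20(self, depth, expected, cfg):
        assert passes_depth(depth, cfg) is expected

    @pytest.mark.parametrize(
        "gnomad,internal,expected",
        [
            (0.0, 0.0, (True, True)),
            (2e-4, 0.0, (False, True)),  # exceeds 0.01%
            (None, None, (True, True)),  # unobserved allele passes
            (9.9e-5, 1.49e-4, (True, True)),
            (1e-4, 0.0, (False, True)),  # strict comparison
            (0.0, 1.5e-4, (True, False)),
        ],
    )
    def test_popfreq_strict_thresholds(self, gnomad, internal, expected, cfg):
        freqs = PopulationFrequencies(gnomad_af=gnomad, internal_af=internal)
        assert passes_popfreq(freqs, cfg) == expected


class TestRegionMask:
    def test_inside_interval_masked(self):
        mask = RegionMask()
        mask.add("chr1", 100, 200)
        key = VariantKey("chr1", 150, "A", "G")
        assert not passes_region_mask(key, mask)

    def test_outside_interval_unmasked(self):
        mask = RegionMask()
        mask.add("chr1", 100, 200)
        assert passes_region_mask(VariantKey("chr1", 250, "A", "G"), mask)

    def test_empty_mask_passes_everything(self):
        assert passes_region_mask(VariantKey("chr7", 1, "A", "G"), RegionMask())
        assert passes_region_mask(VariantKey("chr7", 1, "A", "G"), None)

    def test_bed_half_open_conversion(self, tmp_path):
        # BED [100, 200) covers 1-based positions 101..200
        bed = tmp_path / "mask.bed"
        bed.write_text("chr1\t100\t200\trepetitive\n")
        mask = RegionMask.from_bed(bed)
        assert passes_region_mask(VariantKey("chr1", 100, "A", "G"), mask)
        assert not passes_region_mask(VariantKey("chr1", 101, "A", "G"), mask)
        assert not passes_region_mask(VariantKey("chr1", 200, "A", "G"), mask)
        assert passes_region_mask(VariantKey("chr1", 201, "A", "G"), mask)

    def test_unknown_chromosome_treated_unmasked(self):
        mask = RegionMask()
        mask.add("chr1", 100, 200)
        assert passes_region_mask(VariantKey("chr9", 150, "A", "G"), mask)


def _five_record_stream():
    """One inherited, one depth 15, one VAF 0.75, one masked, one clean."""
    return [
        make_trio(pos=10, mother=("het", 120, 60), trio_id="t1"),
        make_trio(pos=20, proband=("het", 15, 7), mother=("ref_hom", 15, 0), father=("ref_hom", 15, 0), trio_id="t2"),
        make_trio(pos=30, proband=("het", 100, 75), trio_id="t3"),
        make_trio(pos=150, trio_id="t4"),  # inside mask below
        make_trio(pos=500, trio_id="t5"),
    ]


class TestScreenTrios:
    @pytest.fixture
    def mask(self):
        m = RegionMask()
        m.add("chr1", 100, 200)
        return m

    def test_toy_stream_exactly_one_pass(self, mask, cfg):
        decisions = screen_trios(_five_record_stream(), None, mask, cfg)
        assert len(decisions) == 5
        assert sum(d.passed for d in decisions) == 1
        assert decisions[4].passed

    def test_empty_stream(self, cfg):
        assert screen_trios([], None, None, cfg) == []

    def test_all_passing_stream_has_empty_failed_filters(self, cfg):
        decisions = screen_trios([make_trio(pos=p) for p in (1, 2, 3)], None, None, cfg)
        assert all(d.passed and not d.failed_filters for d in decisions)

    def test_order_invariance_as_multiset(self, mask, cfg):
        records = _five_record_stream()
        a = screen_trios(records, None, mask, cfg)
        b = screen_trios(list(reversed(records)), None, mask, cfg)
        as_set = {(d.key, tuple(sorted(d.failed_filters))) for d in a}
        bs_set = {(d.key, tuple(sorted(d.failed_filters))) for d in b}
        assert as_set == bs_set

    def test_tightening_depth_threshold_never_increases_passes(self, mask):
        records = _five_record_stream()
        passed = [
            sum(d.passed for d in screen_trios(records, None, mask, ScreenConfig(min_depth=md)))
            for md in (10, 20, 50, 101)
        ]
        assert passed == sorted(passed, reverse=True)

    @given(st.data())
    @settings(max_examples=200, deadline=None)
    def test_conjunction_of_predicates(self, data):
        """A record passes iff every individual predicate passes."""
        cfg = ScreenConfig()
        gt = data.draw(st.sampled_from(["het", "hemi", "ref_hom"]))
        dp = data.draw(st.integers(0, 60))
        ad = data.draw(st.integers(0, dp))
        mdp = data.draw(st.integers(15, 40))
        mad = data.draw(st.integers(0, 3))
        mgt = data.draw(st.sampled_from(["ref_hom", "het"]))
        pos = data.draw(st.integers(1, 300))
        gn = data.draw(st.sampled_from([None, 0.0, 5e-5, 2e-4]))
        trio = make_trio(
            pos=pos,
            proband=(gt, dp, min(ad, dp)),
            mother=(mgt, mdp, min(mad, mdp)),
            father=("ref_hom", 30, 0),
        )
        freqs = PopulationFrequencies(gnomad_af=gn)
        mask = RegionMask()
        mask.add("chr1", 100, 200)

        decision = screen_trio(trio, freqs, mask, cfg)

        denovo, _ = is_apparent_denovo(trio)
        expected = (
            denovo
            and passes_het_window(trio.proband_vaf, cfg, hemizygous=gt == "hemi")
            and passes_depth(min(dp, mdp, 30), cfg)
            and all(passes_popfreq(freqs, cfg))
            and passes_region_mask(trio.key, mask)
        )
        assert decision.passed == expected


class TestVcfIO:
    def test_read_trio_vcf_basic_and_multiallelic(self, tmp_path):
        path = write_trio_vcf(
            tmp_path / "trio.vcf",
            [
                ("chr1", 1000, "A", ["G"], [("0/1", (53, 47), 100), ("0/0", (120, 0), 120), ("0/0", (110, 0), 110)]),
                ("chr1", 2000, "C", ["T", "CA"], [("0/1", (50, 40, 10), 100), ("0/0", (99, 1, 0), 100), ("0/2", (60, 0, 40), 100)]),
            ],
        )
        records = list(read_trio_vcf(path, "kid", "mom", "dad"))
        # multi-allelic decomposed into one record per alt
        assert len(records) == 3
        first = records[0]
        assert first.key == VariantKey("chr1", 1000, "A", "G")
        assert first.proband.genotype is Genotype.HET
        assert first.proband.alt_depth == 47
        assert first.mother.genotype is Genotype.REF_HOM
        # second alt of the multi-allelic site: father carries it
        third = records[2]
        assert third.key.alt == "CA"
        assert third.father.genotype is Genotype.HET
        assert third.father.alt_depth == 40

    def test_hemizygous_and_missing_genotypes(self, tmp_path):
        path = write_trio_vcf(
            tmp_path / "x.vcf",
            [("chrX", 500, "T", ["C"], [("1", (2, 58), 60), ("0/0", (80, 0), 80), ("./.", (0, 0), 0)])],
        )
        rec = next(read_trio_vcf(path, "kid", "mom", "dad"))
        assert rec.proband.genotype is Genotype.HEMI
        assert rec.father.genotype is Genotype.MISSING

    def test_candidates_tsv_round_trip(self, tmp_path, cfg):
        decisions = screen_trios(_five_record_stream(), None, None, cfg)
        out = tmp_path / "cand.tsv"
        write_candidates_tsv(decisions, out, version="0.0-test")
        back = read_candidates_tsv(out)
        assert [d.key for d in back] == [d.key for d in decisions]
        assert [d.passed for d in back] == [d.passed for d in decisions]
        assert [d.failed_filters for d in back] == [d.failed_filters for d in decisions]

    def test_freq_table_absent_values(self, tmp_path):
        p = tmp_path / "freq.tsv"
        p.write_text(
            "chrom\tpos\tref\talt\tgnomad_af\tinternal_af\n"
            "chr1\t1000\tA\tG\t0.00005\t.\n"
            "chr1\t2000\tC\tT\t\t0.0002\n"
        )
        table = read_freq_table(p)
        k1 = VariantKey("chr1", 1000, "A", "G")
        assert table[k1].gnomad_af == pytest.approx(5e-5)
        assert table[k1].internal_af is None
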