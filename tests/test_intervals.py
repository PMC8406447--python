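import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peakgene import (
    ExpansionSpec,
    GenomicInterval,
    ParseError,
    PeakSet,
    PeakgeneError,
    TadSet,
    expand_peak,
    expand_peak_set,
    expand_peak_to_tads,
    load_peaks_bed,
    load_tads_bed,
    overlapping_genes,
)

from conftest import brute_force_overlap, random_instance


class TestExpandPeak:
    @pytest.mark.parametrize(
        "start,end,lam,expected",
        [
            (100, 200, 50, (100, 200)),   # centre 150 +/- 50
            (100, 200, 1000, (0, 1150)),  # clamped at 0
            (100, 200, 0, (100, 200)),    # lambda=0 keeps the raw peak
            (0, 1, 10, (0, 10)),          # 1-bp SNP peak, centre 0
        ],
    )
    def test_centre_based_expansion(self, start, end, lam, expected):
        peak = GenomicInterval("chr1", start, end, label="p1")
        out = expand_peak(peak, lam)
        assert (out.start, out.end) == expected
        assert out.chrom == "chr1" and out.label == "p1"

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            expand_peak(GenomicInterval("chr1", 0, 10), -1)

    @given(
        start=st.integers(0, 10**6),
        width=st.integers(1, 10_000),
        lam=st.integers(0, 10**6),
    )
    @settings(max_examples=200, derandomize=True)
    def test_expansion_contains_centre(self, start, width, lam):
        peak = GenomicInterval("chrX", start, start + width)
        out = expand_peak(peak, lam)
        assert out.start <= peak.centre < out.end


class TestTadExpansion:
    @pytest.fixture
    def tads(self):
        return TadSet(
            [GenomicInterval("chr1", 0, 1000), GenomicInterval("chr1", 1000, 2000)]
        )

    def test_containment(self, tads):
        out = expand_peak_to_tads(GenomicInterval("chr1", 500, 600), tads)
        assert (out.start, out.end) == (0, 1000)

    def test_spanning_two_tads_takes_outermost_boundaries(self, tads):
        out = expand_peak_to_tads(GenomicInterval("chr1", 990, 1010), tads)
        assert (out.start, out.end) == (0, 2000)

    def test_no_tad_on_chrom_gives_absent(self, tads):
        assert expand_peak_to_tads(GenomicInterval("chr9", 500, 600), tads) is None

    def test_gap_between_tads_gives_absent(self):
        tads = TadSet([GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 500, 900)])
        assert expand_peak_to_tads(GenomicInterval("chr1", 200, 300), tads) is None

    def test_touching_tad_boundary_is_not_overlap(self, tads):
        # Peak [2000, 2100) touches but does not overlap TAD [1000, 2000).
        assert expand_peak_to_tads(GenomicInterval("chr1", 2000, 2100), tads) is None

    def test_idempotent(self, tads):
        once = expand_peak_to_tads(GenomicInterval("chr1", 990, 1010), tads)
        twice = expand_peak_to_tads(once, tads)
        assert once == twice

    def test_overlapping_tads_merged_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="peakgene.intervals"):
            tads = TadSet(
                [GenomicInterval("chr1", 0, 600), GenomicInterval("chr1", 400, 1000)]
            )
        assert tads.intervals == (GenomicInterval("chr1", 0, 1000),)
        assert "merged" in caplog.text

    def test_tadless_peaks_dropped_and_logged(self, tads, caplog):
        peaks = PeakSet(
            "p",
            (GenomicInterval("chr1", 10, 20), GenomicInterval("chr5", 10, 20)),
        )
        with caplog.at_level("INFO", logger="peakgene.intervals"):
            regions = expand_peak_set(peaks, ExpansionSpec.tads(), tads)
        assert len(regions) == 1
        assert "no TAD" in caplog.text

    def test_tad_mode_without_tads_errors(self):
        peaks = PeakSet("p", (GenomicInterval("chr1", 10, 20),))
        with pytest.raises(PeakgeneError):
            expand_peak_set(peaks, ExpansionSpec.tads(), None)


class TestOverlappingGenes:
    def test_half_open_boundary(self, toy_reference):
        # chr1 TSSs at 150 (geneA) and 200 (geneB): end coordinate excluded.
        got = overlapping_genes([GenomicInterval("chr1", 100, 200)], toy_reference)
        assert got == {"geneA"}

    def test_duplicate_coverage_counts_once(self, toy_reference):
        regions = [GenomicInterval("chr1", 100, 200), GenomicInterval("chr1", 140, 160)]
        assert overlapping_genes(regions, toy_reference) == {"geneA"}

    def test_empty_regions(self, toy_reference):
        assert overlapping_genes([], toy_reference) == set()

    @pytest.mark.parametrize("seed", range(20))
    def test_sweep_matches_brute_force(self, seed):
        """The binary-search sweep equals the naive all-pairs scan."""
        rng = np.random.default_rng(seed)
        regions, ref = random_instance(
            rng, n_regions=int(rng.integers(1, 300)), n_tss=int(rng.integers(1, 300))
        )
        assert overlapping_genes(regions, ref) == brute_force_overlap(regions, ref)

    def test_lambda_monotonicity(self, default_fixture):
        """Gene sets recovered at nested distances are themselves nested."""
        fx = default_fixture
        previous = set()
        for lam in (1_000, 5_000, 50_000, 500_000):
            regions = expand_peak_set(fx.peaks, ExpansionSpec.distance(lam))
            current = overlapping_genes(regions, fx.reference)
            assert previous <= current
            previous = current


class TestBedIO:
    def test_load_peaks_skips_comments_and_keeps_labels(self, tmp_path):
        bed = tmp_path / "peaks.bed"
        bed.write_text(
            "# comment\n"
            "track name=x\n"
            "browser position chr1\n"
            "chr1\t10\t20\tsummit1\textra\tignored\n"
            "chr2\t5\t8\n"
        )
        ps = load_peaks_bed(bed)
        assert ps.name == "peaks"
        assert ps.intervals[0].label == "summit1"
        assert ps.intervals[1].label is None

    def test_invalid_interval_names_line(self, tmp_path):
        bed = tmp_path / "bad.bed"
        bed.write_text("chr1\t10\t20\nchr1\t30\t30\n")
        with pytest.raises(ParseError, match=":2:"):
            load_peaks_bed(bed)

    def test_load_tads_merges(self, tmp_path):
        bed = tmp_path / "tads.bed"
        bed.write_text("chr1\t0\t600\nchr1\t400\t900\n")
        assert load_tads_bed(bed).intervals == (GenomicInterval("chr1", 0, 900),)


class TestExpansionSpec:
    @pytest.mark.parametrize(
        "bp,label", [(5000, "5 kb"), (50_000, "50 kb"), (1_500_000, "1.5 Mb"), (37, "37 bp")]
    )
    def test_display_labels(self, bp, label):
        assert ExpansionSpec.distance(bp).display_label == label

    def test_tad_sentinel(self):
        spec = ExpansionSpec.tads()
        assert spec.is_tad and spec.label == "TAD"
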