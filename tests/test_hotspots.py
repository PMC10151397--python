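import numpy as np
import pytest
from scipy import stats

from crypteqtl import (
    EQTLRecord,
    ParameterError,
    ValidationError,
    WS220_CHROM_LENGTHS,
    compare_transbands,
    count_trans_per_bin,
    genome_bins,
    poisson_transbands,
)
from crypteqtl.hotspots import TransBand


def trans_record(chrom, pos, spot="sp", gene=None):
    return EQTLRecord(
        spot_id=spot, gene_id=gene or f"gene_{spot}", peak_marker="m",
        chromosome=chrom, position_bp=pos, neg_log10_p=5.0, effect=1.0,
        variance_explained=0.3, ci_left_bp=max(1, pos - 100), ci_right_bp=pos + 100,
        qtl_type="trans", treatment="t",
    )


class TestGenomeBins:
    def test_ws220_genome_gives_203_bins(self):
        assert len(genome_bins(WS220_CHROM_LENGTHS, width_bp=500_000)) == 203

    def test_short_chromosome_single_bin(self):
        assert len(genome_bins({"c": 400_000})) == 1

    def test_exact_tiling(self):
        bins = genome_bins({"c": 1_000_000})
        assert len(bins) == 2
        assert bins.start_bp.tolist() == [1, 500_001]

    def test_bin_widths_cover_genome(self):
        bins = genome_bins()
        covered = (bins.end_bp - bins.start_bp).sum()
        assert covered >= sum(WS220_CHROM_LENGTHS.values())
        # half-open tiling: every position maps to exactly one bin
        assert covered == 203 * 500_000

    def test_non_positive_width_rejected(self):
        with pytest.raises(ParameterError):
            genome_bins(width_bp=0)


class TestCountTransPerBin:
    def test_no_records_all_zero(self):
        bins = genome_bins()
        counts, _ = count_trans_per_bin([], bins)
        assert counts.sum() == 0

    def test_boundary_position_falls_in_first_bin(self):
        bins = genome_bins({"I": 1_500_000})
        counts, _ = count_trans_per_bin([trans_record("I", 500_000)], bins)
        assert counts[0] == 1  # [1, 500001) contains 500,000
        counts, _ = count_trans_per_bin([trans_record("I", 500_001)], bins)
        assert counts[1] == 1

    def test_stacked_records_count_per_spot(self):
        bins = genome_bins({"I": 1_000_000})
        recs = [trans_record("I", 250_000, spot=f"s{i}") for i in range(10)]
        counts, members = count_trans_per_bin(recs, bins)
        assert counts[0] == 10
        assert len(members[0]) == 10

    def test_cis_records_ignored(self):
        bins = genome_bins({"I": 1_000_000})
        rec = trans_record("I", 250_000)
        rec.qtl_type = "cis"
        counts, _ = count_trans_per_bin([rec], bins)
        assert counts.sum() == 0

    def test_position_beyond_chromosome_named_in_error(self):
        bins = genome_bins({"I": 1_000_000})
        with pytest.raises(ValidationError, match="sp"):
            count_trans_per_bin([trans_record("I", 2_000_000)], bins)


class TestPoissonBands:
    def test_minimal_significant_count_at_lambda_two(self):
        # 203 bins, 406 eQTL -> lambda = 2; Poisson pmf summation:
        # P(X>=10) ~ 4.6e-5 < 1e-4 <= P(X>=9) ~ 2.3e-4
        assert stats.poisson.sf(9, 2) < 1e-4 <= stats.poisson.sf(8, 2)
        bins = genome_bins()
        counts = np.full(203, 2)
        counts[5], counts[6] = 9, 10  # +15 total
        counts[100:115] = 1  # -15: keeps the total at 406, lambda = 2
        assert counts.sum() == 406
        bands = poisson_transbands(counts, bins)
        assert [b.bin_index for b in bands] == [6]
        assert bands[0].count == 10

    def test_low_uniform_counts_give_no_bands(self):
        bins = genome_bins({"I": 2_000_000, "II": 2_000_000})
        counts = np.array([0, 1, 1, 0, 1, 0, 1, 0])
        assert poisson_transbands(counts, bins) == []

    def test_zero_total_warns_and_returns_empty(self):
        bins = genome_bins({"I": 1_000_000})
        with pytest.warns(UserWarning):
            assert poisson_transbands(np.zeros(2, dtype=int), bins) == []

    def test_alpha_calibration_on_uniform_scatter(self, rng):
        # uniformly scattered counts: flagged fraction ~ alpha
        bins = genome_bins()
        flagged = 0
        for _ in range(50):
            counts = rng.poisson(2.0, size=203)
            flagged += len(poisson_transbands(counts, bins))
        assert flagged / (50 * 203) < 5e-3


class TestCompareTransbands:
    def _band(self, chrom, start, end, genes):
        return TransBand(0, chrom, start, end, len(genes), 1e-5, (), tuple(genes))

    def test_identical_bands_maximal_overlap(self):
        genes = [f"g{i}" for i in range(10)]
        a = self._band("I", 1, 500_001, genes)
        pairs = compare_transbands([a], [a], universe=set(genes) | {"x", "y"})
        assert len(pairs) == 1
        assert pairs[0]["shared_genes"] == set(genes)
        # maximal possible overlap: tail equals the single-point pmf
        expected = stats.hypergeom.pmf(10, 12, 10, 10)
        assert pairs[0]["p_hypergeometric"] == pytest.approx(float(expected), rel=1e-9)

    def test_disjoint_intervals_no_pairs(self):
        a = self._band("I", 1, 500_001, ["g1"])
        b = self._band("I", 600_000, 1_100_000, ["g1"])
        assert compare_transbands([a], [b], {"g1"}) == []

    def test_gene_overlap_matches_exhaustive_sum(self):
        universe = {f"u{i}" for i in range(1000)}
        genes_a = [f"u{i}" for i in range(50)]
        genes_b = [f"u{i}" for i in range(40, 80)]  # shared 10
        a = self._band("I", 1, 500_001, genes_a)
        b = self._band("I", 400_000, 900_000, genes_b)
        (pair,) = compare_transbands([a], [b], universe)
        assert len(pair["shared_genes"]) == 10
        from math import comb
        exhaustive = sum(
            comb(50, k) * comb(950, 40 - k) for k in range(10, 41)
        ) / comb(1000, 40)
        assert pair["p_hypergeometric"] == pytest.approx(exhaustive, rel=1e-9)

    def test_empty_universe_rejected(self):
        with pytest.raises(ParameterError):
            compare_transbands([], [], set())
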