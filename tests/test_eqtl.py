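import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from crypteqtl import (
    EQTLRecord,
    SimulationDesign,
    ValidationError,
    call_peaks,
    classify_cis_trans,
    compare_eqtl_sets,
    confidence_interval,
    default_marker_map,
    map_single_marker,
    permutation_threshold,
    simulate_expression,
    simulate_ril_genotypes,
    variance_explained,
)
from crypteqtl.eqtl import AssociationProfile, Peak

from conftest import make_expression, make_genotypes


def profile_on(mm, values, effects=None):
    values = np.asarray(values, dtype=float)
    return AssociationProfile(
        "s0", values, np.asarray(effects if effects is not None else np.zeros_like(values))
    )


class TestMapSingleMarker:
    def test_constant_expression_gives_null_profile(self, rng):
        g = make_genotypes(rng.integers(0, 2, size=(10, 5)))
        e = make_expression(np.full((3, 10), 7.0), strains=list(g.strains))
        for p in map_single_marker(e, g):
            assert np.all(p.neg_log10_p <= 1e-9)

    def test_matches_two_group_t_test_oracle(self, rng):
        # independent oracle: scipy pooled two-sample t test, marker by marker
        for _ in range(100):
            n = int(rng.integers(8, 24))
            k = int(rng.integers(2, 8))
            calls = rng.integers(0, 2, size=(n, k))
            calls[:2] = 0  # guarantee both classes occupied somewhere
            calls[2:4] = 1
            g = make_genotypes(calls.astype(np.int8))
            y = rng.normal(size=(3, n))
            e = make_expression(y, strains=list(g.strains))
            profiles = map_single_marker(e, g)
            for i, p in enumerate(profiles):
                for j in range(k):
                    a = y[i, calls[:, j] == 0]
                    b = y[i, calls[:, j] == 1]
                    if min(len(a), len(b)) < 2:
                        continue
                    t, p_oracle = stats.ttest_ind(b, a, equal_var=True)
                    assert 10 ** (-p.neg_log10_p[j]) == pytest.approx(
                        p_oracle, abs=1e-9
                    )
                    assert p.effect[j] == pytest.approx(b.mean() - a.mean(), abs=1e-9)

    def test_joint_permutation_leaves_p_values_unchanged(self, rng):
        calls = rng.integers(0, 2, size=(12, 6)).astype(np.int8)
        g = make_genotypes(calls)
        y = rng.normal(size=(4, 12))
        e = make_expression(y, strains=list(g.strains))
        base = map_single_marker(e, g)
        perm = rng.permutation(12)
        g2 = make_genotypes(calls[perm], strains=[g.strains[i] for i in perm])
        e2 = make_expression(y[:, perm], strains=[g.strains[i] for i in perm])
        shuffled = map_single_marker(e2, g2)
        for a, b in zip(base, shuffled):
            assert np.allclose(a.neg_log10_p, b.neg_log10_p, atol=1e-9)

    def test_missing_calls_drop_samples_per_marker(self, rng):
        calls = rng.integers(0, 2, size=(14, 3)).astype(np.int8)
        calls[:3, :] = np.array([[0], [0], [1]])  # both classes everywhere
        calls[0, 1] = -1
        g = make_genotypes(calls)
        y = rng.normal(size=(2, 14))
        e = make_expression(y, strains=list(g.strains))
        (p0, _) = map_single_marker(e, g)
        keep = calls[:, 1] != -1
        a = y[0, keep & (calls[:, 1] == 0)]
        b = y[0, keep & (calls[:, 1] == 1)]
        _, p_oracle = stats.ttest_ind(b, a, equal_var=True)
        assert 10 ** (-p0.neg_log10_p[1]) == pytest.approx(p_oracle, abs=1e-9)

    def test_degenerate_marker_warned_and_set_to_p_one(self, rng):
        calls = rng.integers(0, 2, size=(10, 2)).astype(np.int8)
        calls[:, 1] = 0
        calls[0, 1] = 1  # single ALT strain: class too small
        g = make_genotypes(calls)
        calls[:2, 0] = [0, 1]
        e = make_expression(rng.normal(size=(1, 10)), strains=list(g.strains))
        with pytest.warns(UserWarning, match="m1"):
            (p,) = map_single_marker(e, g)
        assert p.neg_log10_p[1] == 0.0


class TestPermutationThreshold:
    def _dataset(self, rng, n_planted=40, n_null=160, n_strains=40):
        mm = default_marker_map(n_markers=80)
        d = SimulationDesign(
            n_strains=n_strains, marker_map=mm, seed=int(rng.integers(2**30)),
            planted_cis=[
                (f"hit{i}", mm.marker_ids[int(rng.integers(80))], 1.0)
                for i in range(n_planted)
            ],
            n_background_spots=n_null,
        )
        g = simulate_ril_genotypes(d)
        expr, truth = simulate_expression(g, d)
        return expr.subset_treatment("empty_vector"), g, truth

    def test_deterministic_under_seed(self, rng):
        e, g, _ = self._dataset(rng)
        a = permutation_threshold(e, g, n_permutations=4, seed=9)
        b = permutation_threshold(e, g, n_permutations=4, seed=9)
        assert a.threshold == b.threshold
        assert np.array_equal(a.fds, b.fds)

    def test_pure_noise_has_no_qualifying_threshold(self, rng):
        mm = default_marker_map(n_markers=40)
        d = SimulationDesign(n_strains=20, marker_map=mm, seed=3, n_background_spots=60)
        g = simulate_ril_genotypes(d)
        e, _ = simulate_expression(g, d)
        e = e.subset_treatment("empty_vector")
        with pytest.raises(ValidationError):
            permutation_threshold(e, g, n_permutations=5, seed=1)

    def test_discovery_curves_monotone_in_threshold(self, rng):
        e, g, _ = self._dataset(rng)
        res = permutation_threshold(e, g, n_permutations=5, seed=2)
        assert np.all(np.diff(res.rds) <= 0)
        assert np.all(np.diff(res.fds) <= 0)

    def test_chosen_threshold_is_smallest_qualifying(self, rng):
        e, g, _ = self._dataset(rng)
        res = permutation_threshold(e, g, n_permutations=5, seed=2)
        i = np.flatnonzero(res.grid == res.threshold)[0]
        ratio = res.fds / np.maximum(res.rds, 1e-12)
        ok = (ratio <= res.q) & (res.rds > 0)
        assert ok[i] and not ok[:i].any()

    def test_corrected_bound_changes_threshold_algebra(self, rng):
        e, g, _ = self._dataset(rng)
        plain = permutation_threshold(e, g, n_permutations=5, seed=2)
        corr = permutation_threshold(e, g, n_permutations=5, seed=2, corrected=True)
        i = np.flatnonzero(corr.grid == corr.threshold)[0]
        bound = corr.q * (corr.m0[i] / corr.m) * np.log(corr.m)
        assert corr.fds[i] / corr.rds[i] <= bound
        assert corr.m0[i] == corr.m - corr.rds[i]
        assert plain.m == corr.m == 200


class TestPeaksAndIntervals:
    mm = default_marker_map(n_markers=12)  # >= 1 marker per chromosome

    def test_all_below_threshold_gives_no_peaks(self):
        p = profile_on(self.mm, np.ones(12))
        assert call_peaks(p, 3.9, self.mm) == []

    def test_single_chromosome_max(self):
        vals = np.zeros(12)
        vals[3] = 5.0  # chromosome I has markers 0..(k-1)
        p = profile_on(self.mm, vals)
        peaks = call_peaks(p, 3.9, self.mm)
        assert len(peaks) == 1 and peaks[0].marker_index == 3

    def test_one_peak_per_passing_chromosome(self):
        vals = np.full(12, 0.5)
        chrom = self.mm.chromosome
        first_I = np.flatnonzero(chrom == "I")[0]
        first_V = np.flatnonzero(chrom == "V")[0]
        vals[[first_I, first_V]] = 6.0
        peaks = call_peaks(profile_on(self.mm, vals), 3.9, self.mm)
        assert {p.chromosome for p in peaks} == {"I", "V"}

    def test_tie_goes_to_leftmost_marker(self):
        vals = np.zeros(12)
        cols = np.flatnonzero(self.mm.chromosome == "I")
        vals[cols[:2]] = 4.5
        (peak,) = call_peaks(profile_on(self.mm, vals), 3.9, self.mm)
        assert peak.marker_index == cols[0]

    def test_ci_hand_walk_oracle(self):
        # single-chromosome profile [5,6,8,7,6.4,4], peak at index 2,
        # drop 1.5 -> contiguous markers with value >= 6.5: indices 2..3
        # (6 and 6.4 fall below the floor on either side)
        mm = make_genotypes(np.zeros((4, 6), dtype=np.int8)).markers
        vals = np.array([5, 6, 8, 7, 6.4, 4], dtype=float)
        p = profile_on(mm, vals)
        (peak,) = call_peaks(p, 3.9, mm)
        assert peak.marker_index == 2
        ci = confidence_interval(p, peak, mm, drop=1.5)
        assert ci == (mm.position_bp[2], mm.position_bp[3])

    def test_sharp_peak_has_degenerate_ci(self):
        mm = make_genotypes(np.zeros((4, 5), dtype=np.int8)).markers
        vals = np.array([1.0, 2.0, 8.0, 2.0, 1.0])
        p = profile_on(mm, vals)
        (peak,) = call_peaks(p, 3.9, mm)
        assert confidence_interval(p, peak, mm) == (
            mm.position_bp[2], mm.position_bp[2]
        )

    def test_flat_profile_ci_spans_chromosome(self):
        mm = make_genotypes(np.zeros((4, 5), dtype=np.int8)).markers
        p = profile_on(mm, np.full(5, 6.0))
        (peak,) = call_peaks(p, 3.9, mm)
        assert confidence_interval(p, peak, mm) == (
            mm.position_bp[0], mm.position_bp[-1]
        )


class TestCisTrans:
    def _peak(self, chrom, pos):
        return Peak("m", 0, chrom, pos, 5.0, 1.0)

    @pytest.mark.parametrize(
        "peak_chrom,peak_pos,gene_chrom,gene_pos,expected",
        [
            ("II", 3_800_000, "II", 3_000_000, "cis"),     # 0.8 Mb away
            ("III", 3_000_000, "II", 3_000_000, "trans"),  # other chromosome
            ("I", 3_050_000, "I", 2_000_000, "trans"),     # 1.05 Mb away
            ("I", 3_000_000, "I", 2_000_000, "cis"),       # exactly 1 Mb
        ],
    )
    def test_window_rule(self, peak_chrom, peak_pos, gene_chrom, gene_pos, expected):
        assert classify_cis_trans(self._peak(peak_chrom, peak_pos), gene_chrom, gene_pos) == expected

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(1, 20_000_000), st.integers(1, 20_000_000))
    def test_symmetric_in_positional_difference(self, a, b):
        assert classify_cis_trans(self._peak("I", a), "I", b) == classify_cis_trans(
            self._peak("I", b), "I", a
        )


class TestVarianceExplained:
    def test_perfect_separation_gives_r2_one(self):
        g = np.array([0, 0, 0, 1, 1, 1])
        assert variance_explained(g.astype(float), g) == pytest.approx(1.0)

    def test_null_r2_small_at_large_n(self, rng):
        g = rng.integers(0, 2, 200)
        y = rng.standard_normal(200)
        assert variance_explained(y, g) < 0.1

    def test_sums_of_squares_oracle_balanced_groups(self):
        # group means 0 and 2 around grand mean 1: SS_between = 4+4 = 8,
        # SS_within = 4+4 = 8, so R^2 = 8/16 = 0.5 by direct computation
        y = np.array([-1.0, 1.0, -1.0, 1.0, 1.0, 3.0, 1.0, 3.0])
        g = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        grand = y.mean()
        ss_b = sum(4 * (y[g == c].mean() - grand) ** 2 for c in (0, 1))
        ss_t = ((y - grand) ** 2).sum()
        assert variance_explained(y, g) == pytest.approx(ss_b / ss_t, rel=1e-12)
        assert ss_b / ss_t == pytest.approx(0.5)


class TestCompareSets:
    def _rec(self, gene, qtl_type, chrom="I", ci=(1_000_000, 2_000_000), pos=None):
        pos = pos if pos is not None else (ci[0] + ci[1]) // 2
        return EQTLRecord(
            spot_id=f"sp_{gene}", gene_id=gene, peak_marker="m", chromosome=chrom,
            position_bp=pos, neg_log10_p=5.0, effect=1.0, variance_explained=0.3,
            ci_left_bp=ci[0], ci_right_bp=ci[1], qtl_type=qtl_type, treatment="t",
        )

    def test_identical_sets_fully_shared(self):
        a = [self._rec("g1", "cis"), self._rec("g2", "trans")]
        res = compare_eqtl_sets(a, list(a))
        assert res["shared_cis"] == {"g1"}
        assert res["shared_trans"] == {"g2"}
        assert res["a_specific"] == res["b_specific"] == set()

    def test_touching_trans_intervals_count_as_shared(self):
        a = [self._rec("g", "trans", ci=(1_000_000, 2_000_000))]
        b = [self._rec("g", "trans", ci=(2_000_000, 3_000_000))]
        assert compare_eqtl_sets(a, b)["shared_trans"] == {"g"}

    def test_trans_on_different_chromosomes_is_specific(self):
        a = [self._rec("g", "trans", chrom="I")]
        b = [self._rec("g", "trans", chrom="II")]
        res = compare_eqtl_sets(a, b)
        assert res["shared_trans"] == set()
        assert res["a_specific"] == {"g"} and res["b_specific"] == {"g"}
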