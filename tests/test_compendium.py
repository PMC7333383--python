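import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from sklearn.metrics import adjusted_rand_score

from screg import compendium as comp
from screg.genome import BinCountMatrix, segment_genome


def _matrix(counts, L=None, bin_width=200):
    counts = np.asarray(counts)
    index = segment_genome({"chr1": counts.shape[0] * bin_width}, bin_width)
    if L is None:
        L = np.ones(counts.shape[1])
    return BinCountMatrix(
        index=index,
        counts=counts,
        library_factors=np.asarray(L, dtype=float),
        sample_ids=[f"s{j}" for j in range(counts.shape[1])],
    )


class TestNormalize:
    def test_zero_maps_to_zero(self):
        norm = comp.normalize_counts(_matrix([[0], [2]], L=[2.0]))
        assert norm.values[0, 0] == 0.0

    def test_forced_arithmetic(self):
        norm = comp.normalize_counts(_matrix([[2]], L=[2.0]))
        assert norm.values[0, 0] == pytest.approx(1.0)

    def test_direct_evaluation(self):
        norm = comp.normalize_counts(_matrix([[300]], L=[3.0]))
        assert norm.values[0, 0] == pytest.approx(np.log2(101), abs=1e-10)
        assert norm.values[0, 0] == pytest.approx(6.6582, abs=1e-4)

    def test_zero_library_with_counts_errors(self):
        with pytest.raises(ValueError):
            comp.normalize_counts(_matrix([[5]], L=[0.0]))


class TestSignalBins:
    def test_low_count_never_signal(self):
        m = _matrix([[9]] * 5)
        flags = comp.detect_signal_bins(m, comp.normalize_counts(m))
        assert not flags.any()

    def test_bright_bin_with_zero_background(self):
        counts = np.zeros((11, 1), dtype=int)
        counts[5, 0] = 64
        m = _matrix(counts)
        norm = comp.normalize_counts(m)
        assert norm.values[5, 0] == pytest.approx(np.log2(65))  # ~6.02
        flags = comp.detect_signal_bins(m, norm)
        assert flags[5, 0]
        assert flags.sum() == 1

    def test_background_ratio_rejects(self):
        # center ~5.52 normalized, neighbors exactly 2 -> 5x background = 10
        counts = np.full((11, 1), 3, dtype=int)
        counts[5, 0] = 45
        m = _matrix(counts)
        norm = comp.normalize_counts(m)
        assert norm.values[5, 0] == pytest.approx(np.log2(46))
        flags = comp.detect_signal_bins(m, norm)
        assert not flags[5, 0]
        # mouse factor 3 -> threshold 6 > 5.52, still rejected
        assert not comp.detect_signal_bins(m, norm, species_factor=3.0)[5, 0]

    def test_masked_bins_never_flagged(self, blacklist_350_360):
        index = segment_genome({"chr1": 1000}, 200, blacklist_350_360)
        counts = np.zeros((5, 1), dtype=int)
        counts[1, 0] = 1000
        m = BinCountMatrix(index=index, counts=counts, library_factors=np.ones(1), sample_ids=["s"])
        flags = comp.detect_signal_bins(m, comp.normalize_counts(m))
        assert not flags[1, 0]

    def test_window_smaller_than_bin_errors(self):
        m = _matrix([[0]] * 3)
        with pytest.raises(ValueError):
            comp.detect_signal_bins(m, comp.normalize_counts(m), bg_window_bp=100)


class TestCatalog:
    def test_union_semantics(self):
        flags = np.array(
            [[True, False, False], [False, False, False], [False, False, True]]
        )
        catalog = comp.compile_cres(flags)
        assert catalog.bin_indices.tolist() == [0, 2]

    def test_three_sample_brute_force(self):
        rng = np.random.default_rng(3)
        flags = rng.random((50, 3)) < 0.2
        catalog = comp.compile_cres(flags)
        expected = sorted({i for i in range(50) for j in range(3) if flags[i, j]})
        assert catalog.bin_indices.tolist() == expected

    def test_saturation_subset_is_zero(self):
        assert comp.catalog_saturation(np.arange(10), np.array([2, 5])) == 0.0

    def test_saturation_empty_catalog_is_one(self):
        assert comp.catalog_saturation(np.array([]), np.array([1])) == 1.0

    def test_saturation_brute_force(self):
        catalog = np.arange(98)
        new = np.array([0, 1, 98, 99])
        assert comp.catalog_saturation(catalog, new) == pytest.approx(2 / 100)


class TestLocusEffects:
    def test_constant_row_fallback(self):
        eff = comp.estimate_locus_effects(np.full((1, 4), 5), np.ones(4))
        assert eff.s[0] == 0.0
        assert eff.m[0] == pytest.approx(np.log(5))
        assert eff.fallback[0]

    def test_two_sample_hand_computation(self):
        eff = comp.estimate_locus_effects(np.array([[1, 3]]), np.ones(2))
        # moments 2, 5, 2 -> ratio (5-2)/4 = 0.75 < 1 -> degenerate branch
        assert eff.s[0] == 0.0
        assert eff.m[0] == pytest.approx(np.log(2), abs=1e-12)

    def test_all_zero_row_sentinel(self):
        eff = comp.estimate_locus_effects(np.zeros((1, 3), dtype=int), np.ones(3))
        assert eff.m[0] == -np.inf
        assert not eff.finite_mask()[0]

    def test_monte_carlo_recovery(self):
        # generative model: y ~ Poisson(L e^{m + s*delta}), delta ~ N(0,1)
        rng = np.random.default_rng(0)
        J = 10_000
        y = rng.poisson(np.exp(1.0 + 0.8 * rng.standard_normal(J)))
        eff = comp.estimate_locus_effects(y[None, :], np.ones(J))
        assert abs(eff.m[0] - 1.0) < 0.05
        assert abs(eff.s[0] - 0.8) < 0.05

    def test_moment_identity(self):
        # empirical moments of y/L converge to the closed forms at L=1
        rng = np.random.default_rng(1)
        J = 100_000
        m_true, s_true = 0.5, 0.7
        y = rng.poisson(np.exp(m_true + s_true * rng.standard_normal(J))).astype(float)
        e1 = np.exp(m_true + s_true**2 / 2)
        e2 = e1 + e1**2 * np.exp(s_true**2)
        assert y.mean() == pytest.approx(e1, rel=0.01)
        assert (y**2).mean() == pytest.approx(e2, rel=0.01)

    def test_consistency_error_shrinks_with_J(self):
        rng = np.random.default_rng(2)
        n = 500
        m = rng.uniform(-1, 2, n)
        s = rng.uniform(0.3, 1.2, n)
        med_err = []
        for J in (50, 100, 200):
            delta = rng.standard_normal((n, J))
            y = rng.poisson(np.exp(m[:, None] + s[:, None] * delta))
            eff = comp.estimate_locus_effects(y, np.ones(J))
            med_err.append(np.median(np.abs(eff.m - m)))
        assert med_err[0] > med_err[1] > med_err[2]

    @given(
        hnp.arrays(
            np.int64,
            hnp.array_shapes(min_dims=2, max_dims=2, min_side=2, max_side=6),
            elements=st.integers(0, 1000),
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_fallback_safety(self, y):
        eff = comp.estimate_locus_effects(y, np.ones(y.shape[1]))
        assert not np.isnan(eff.m).any()
        assert not np.isnan(eff.s).any()
        assert (eff.s >= 0).all()
        nonzero = y.sum(axis=1) > 0
        assert np.isfinite(eff.m[nonzero]).all()


class TestLowVariability:
    def test_full_strata_give_ten_thousand(self):
        rng = np.random.default_rng(0)
        n = 50_000
        eff = comp.LocusEffects(
            m=rng.normal(0, 1, n), s=rng.uniform(0, 2, n), fallback=np.zeros(n, bool)
        )
        assert len(comp.select_low_variability(eff)) == 10_000

    def test_small_catalog_selects_all(self):
        rng = np.random.default_rng(1)
        eff = comp.LocusEffects(
            m=rng.normal(size=50), s=rng.uniform(size=50), fallback=np.zeros(50, bool)
        )
        assert len(comp.select_low_variability(eff)) == 50

    def test_stable_tie_break(self):
        n = 40
        eff = comp.LocusEffects(
            m=np.linspace(0, 1, n), s=np.zeros(n), fallback=np.zeros(n, bool)
        )
        lv = comp.select_low_variability(eff, n_strata=2, per_stratum=5)
        # all s equal: lowest-index elements win within each stratum
        first = np.flatnonzero(eff.m <= np.quantile(eff.m, 0.5))
        in_first = [mm for mm in lv.members if mm in set(first)]
        assert sorted(in_first) == first[:5].tolist()

    def test_members_sorted_by_genome_order(self):
        rng = np.random.default_rng(2)
        eff = comp.LocusEffects(
            m=rng.normal(size=200), s=rng.uniform(size=200), fallback=np.zeros(200, bool)
        )
        lv = comp.select_low_variability(eff, per_stratum=5)
        assert np.all(np.diff(lv.members) > 0)


class TestClustering:
    def test_paper_halving_sequence(self):
        assert comp.halving_levels(5000) == [156, 312, 625, 1250, 2500]

    def test_planted_blocks_recovered(self):
        rng = np.random.default_rng(0)
        truth = np.repeat(np.arange(4), 5)
        base = rng.normal(0, 3, (4, 12))
        values = base[truth] + rng.normal(0, 0.01, (20, 12))
        hier = comp.cluster_cres(values, stage1_k=4, seed=0)
        assert adjusted_rand_score(truth, hier.assignments[4]) == 1.0

    def test_finest_level_is_singletons(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=(30, 8))
        hier = comp.cluster_cres(values, stage1_k=5, seed=0)
        finest = hier.levels[-1]
        assert finest == 30
        assert len(np.unique(hier.assignments[finest])) == 30

    def test_hierarchy_nesting(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=(60, 10))
        hier = comp.cluster_cres(values, stage1_k=8, seed=0)
        for coarse, fine in zip(hier.levels[:-1], hier.levels[1:]):
            fine_labels = hier.assignments[fine]
            coarse_labels = hier.assignments[coarse]
            for k in np.unique(fine_labels):
                parents = np.unique(coarse_labels[fine_labels == k])
                assert len(parents) == 1

    def test_each_level_is_partition(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=(40, 6))
        hier = comp.cluster_cres(values, stage1_k=6, seed=0)
        for K in hier.levels:
            labels = hier.assignments[K]
            assert len(labels) == 40
            assert len(np.unique(labels)) == K

    def test_constant_row_standardized_to_zero(self):
        values = np.vstack([np.ones(6), np.arange(6, dtype=float)])
        Z = comp.standardize_rows(values)
        assert np.all(Z[0] == 0)
        assert Z[1].mean() == pytest.approx(0, abs=1e-12)
        assert Z[1].std() == pytest.approx(1, abs=1e-12)


class TestVarianceExplained:
    def test_identical_columns_full(self):
        v = np.tile(np.array([[1.0], [3.0], [2.0]]), (1, 4))
        assert comp.variance_explained(v, comp.mean_profile(v)) == pytest.approx(1.0)

    def test_constant_profile_zero(self):
        v = np.array([[1.0, 3.0], [3.0, 1.0]])
        assert comp.variance_explained(v, comp.mean_profile(v)) == 0.0

    def test_two_by_two_hand_value(self):
        v = np.array([[0.0, 2.0], [1.0, 3.0]])
        # a = (1, 2); J*sum (a - 1.5)^2 = 1; total SS around 1.5 = 5
        assert comp.variance_explained(v, comp.mean_profile(v)) == pytest.approx(0.2)

    def test_bounded_and_profile_in_range(self):
        rng = np.random.default_rng(4)
        v = rng.normal(size=(30, 7))
        prof = comp.mean_profile(v)
        assert np.all(prof.a >= v.min(axis=1)) and np.all(prof.a <= v.max(axis=1))
        frac = comp.variance_explained(v, prof)
        assert 0.0 <= frac <= 1.0


class TestTabularIO:
    def test_effects_round_trip(self, small_artifacts, tmp_path):
        arts = small_artifacts
        comp.write_locus_effects(
            arts.effects, arts.catalog, tmp_path / "eff.tsv", index=arts.catalog.index
        )
        eff, df = comp.read_locus_effects(tmp_path / "eff.tsv")
        assert np.allclose(eff.m, arts.effects.m)
        assert np.allclose(eff.s, arts.effects.s)
        assert list(df.columns) == ["chrom", "start", "end", "m", "s", "fallback"]

    def test_hierarchy_round_trip(self, small_artifacts, tmp_path):
        hier = small_artifacts.hierarchy
        comp.write_hierarchy(hier, tmp_path / "h.tsv")
        back = comp.read_hierarchy(tmp_path / "h.tsv")
        assert back.levels == hier.levels
        for K in hier.levels:
            assert np.array_equal(back.assignments[K], hier.assignments[K])
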