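"""QMDR/GMDR engine: cell partitions, labelling rules, statistics,
cross-validated search and permutation significance."""

import numpy as np
import pytest
from scipy import stats

import copd_epistasis as ce
from copd_epistasis.mdr import (
    HIGH,
    LOW,
    T_CAP,
    UNDEFINED_ACC,
    _make_folds,
    _pooled_t,
)
from copd_epistasis.simulate import _spec_values

from naive_mdr import naive_cv_search


class TestAdjustTrait:
    def test_residual_mean_zero(self, rng):
        y = rng.normal(2.0, 1.0, 500)
        cov = rng.normal(size=(500, 3))
        assert abs(ce.adjust_trait(y, cov).mean()) < 1e-10

    def test_null_covariates_residuals_equal_centred_trait(self, rng):
        y = rng.normal(size=500)
        cov = rng.normal(size=(500, 3))  # no effect on y
        r = ce.adjust_trait(y, cov)
        c = y - y.mean()
        assert np.corrcoef(r, c)[0, 1] > 0.99

    def test_exact_linear_trait_gives_zero_residuals(self, rng):
        age = rng.uniform(40, 75, 100)
        y = 3.0 - 0.02 * age
        r = ce.adjust_trait(y, age[:, None])
        assert np.abs(r).max() < 1e-8

    def test_rank_deficient_covariates_error(self, rng):
        cov = np.column_stack([np.ones(50), np.ones(50)])
        with pytest.raises(ValueError, match="rank"):
            ce.adjust_trait(rng.normal(size=50), cov)


class TestPartitionCells:
    def test_pairs_form_two_cells(self):
        G = np.array([[0, 0], [0, 0], [1, 2], [1, 2]])
        part = ce.partition_cells(G, ("snp001", "snp002"))
        assert len(part.cells) == 2
        assert {len(v) for v in part.cells.values()} == {2}

    def test_k1_gives_single_snp_groups(self):
        G = np.array([[0], [1], [1], [2]])
        part = ce.partition_cells(G, ("snp001",))
        assert sorted(part.cells) == [(0,), (1,), (2,)]

    def test_partition_property_and_missing_exclusion(self, rng):
        G = rng.integers(0, 3, size=(100, 5))
        G[0, 1] = ce.MISSING
        part = ce.partition_cells(G, ("snp001", "snp002", "snp004"))
        assert part.member_count() == 99
        assert part.n_excluded_missing == 1
        assert len(part.cells) <= 27

    def test_bad_tuple_size(self, rng):
        G = rng.integers(0, 3, size=(10, 3))
        with pytest.raises(ValueError):
            ce.partition_cells(G, ())


class TestLabelling:
    def _pair_partition(self):
        G = np.array([[0, 0], [0, 0], [1, 1], [1, 1]])
        return ce.partition_cells(G, ("snp001", "snp002"))

    def test_qmdr_high_low_and_tie_goes_low(self):
        part = self._pair_partition()
        y = np.array([1.2, 1.2, 0.8, 0.8])
        ce.label_cells_qmdr(part, y, overall_mean=1.0)
        assert part.labels[(0, 0)] == HIGH and part.labels[(1, 1)] == LOW
        ce.label_cells_qmdr(part, y, overall_mean=1.2)  # exact tie -> Low
        assert part.labels[(0, 0)] == LOW

    def test_qmdr_negating_trait_swaps_labels(self):
        part = self._pair_partition()
        y = np.array([1.2, 1.2, 0.8, 0.8])
        ce.label_cells_qmdr(part, y)
        flipped = ce.label_cells_qmdr(self._pair_partition(), -y)
        assert all(part.labels[c] != flipped.labels[c] for c in part.labels)

    def test_gmdr_sign_rule_and_zero_sum_low(self):
        part = self._pair_partition()
        ce.label_cells_gmdr(part, np.array([1.0, 1.0, -0.5, 0.5]))
        assert part.labels[(0, 0)] == HIGH
        assert part.labels[(1, 1)] == LOW  # sum exactly 0 -> Low
        ce.label_cells_gmdr(part, np.zeros(4))
        assert set(part.labels.values()) == {LOW}


class TestStatistics:
    def test_qmdr_statistic_matches_textbook_formula(self, rng):
        G = rng.integers(0, 3, size=(20, 2))
        y = rng.normal(size=20)
        part = ce.partition_cells(G, ("snp001", "snp002"))
        ce.label_cells_qmdr(part, y)
        t = ce.qmdr_statistic(part, y, np.arange(20))
        hi = [i for i in range(20)
              if part.labels.get(tuple(G[i]), LOW) == HIGH]
        lo = [i for i in range(20) if i not in hi]
        ref = stats.ttest_ind(y[hi], y[lo], equal_var=True).statistic
        assert t == pytest.approx(ref, abs=1e-10)

    def test_degenerate_variance_capped(self):
        assert _pooled_t(np.array([2.0, 2.0, 2.0]), np.array([0.0, 0.0])) == T_CAP
        assert _pooled_t(np.array([1.0]), np.array([])) == -1e6

    def test_equal_means_give_zero(self):
        assert _pooled_t(np.array([1.0, -1.0]), np.array([2.0, -2.0])) == 0.0

    def test_gmdr_perfect_and_swapped(self):
        G = np.array([[0, 0], [0, 0], [1, 1], [1, 1]])
        z = np.array([1.0, 0.5, -1.0, -0.5])
        part = ce.partition_cells(G, ("snp001", "snp002"))
        ce.label_cells_gmdr(part, z)
        assert ce.gmdr_statistic(part, z, np.arange(4)) == 1.0
        part.labels = {c: (LOW if lab == HIGH else HIGH)
                       for c, lab in part.labels.items()}
        assert ce.gmdr_statistic(part, z, np.arange(4)) == 0.0

    def test_gmdr_one_sided_mass_sentinel(self):
        G = np.array([[0, 0], [1, 1]])
        part = ce.partition_cells(G, ("snp001", "snp002"))
        ce.label_cells_gmdr(part, np.array([1.0, 2.0]))
        assert ce.gmdr_statistic(part, np.array([1.0, 2.0]),
                                 np.arange(2)) == UNDEFINED_ACC

    def test_gmdr_random_labels_near_half(self, rng):
        G = rng.integers(0, 3, size=(2000, 2))
        z = rng.normal(size=2000)
        part = ce.partition_cells(G, ("snp001", "snp002"))
        # labels independent of the scores
        part.labels = {c: (HIGH if rng.random() < 0.5 else LOW)
                       for c in part.cells}
        acc = ce.gmdr_statistic(part, z, np.arange(2000))
        assert acc == pytest.approx(0.5, abs=0.05)


class TestSearch:
    def test_engine_agrees_with_bruteforce_on_small_instances(self, rng):
        for method in ("qmdr", "gmdr"):
            G = rng.integers(0, 3, size=(60, 5))
            cov = rng.normal(size=(60, 2))
            y = rng.normal(size=60) + 0.5 * (G[:, 1] == G[:, 3])
            ids = [f"snp{j + 1:03d}" for j in range(5)]
            model = ce.cross_validated_search(
                G, y, cov, method=method, k=2, seed=5, snp_ids=ids
            )
            ref = naive_cv_search(G, ids, y, cov, method, 2, 10, seed=5)
            assert model.snp_tuple == ref["winner"]
            assert model.cv_consistency == ref["cv_consistency"]
            assert model.t_cv_score == pytest.approx(ref["t_cv_score"],
                                                     abs=1e-10)

    def test_single_candidate_tuple_has_full_consistency(self, rng):
        G = rng.integers(0, 3, size=(80, 2))
        y = rng.normal(size=80)
        model = ce.cross_validated_search(G, y, method="qmdr", k=2, seed=1)
        assert model.cv_consistency == 10
        assert len(model.per_fold) == 10

    def test_selection_optimality_per_fold(self, rng):
        """The selected tuple's training statistic is the fold maximum
        (checked by rebuilding each fold's statistics via the granular
        per-tuple operations)."""
        import itertools
        G = rng.integers(0, 3, size=(70, 4))
        y = rng.normal(size=70)
        ids = [f"snp{j + 1:03d}" for j in range(4)]
        model = ce.cross_validated_search(G, y, method="qmdr", k=2, seed=9,
                                          snp_ids=ids)
        rng_f = np.random.default_rng(np.random.SeedSequence(9))
        fold_ids = _make_folds(70, 10, rng_f)
        yw = ce.adjust_trait(y)
        for fr in model.per_fold:
            train = np.flatnonzero(fold_ids != fr.fold)
            test = np.flatnonzero(fold_ids == fr.fold)
            stats_by_tuple = {}
            for combo in itertools.combinations(ids, 2):
                part = ce.partition_cells(G, combo, subjects=train,
                                          snp_ids=ids)
                ce.label_cells_qmdr(part, yw)
                stats_by_tuple[combo] = ce.qmdr_statistic(part, yw, train)
                if combo == fr.selected:
                    assert ce.qmdr_statistic(part, yw, test) == pytest.approx(
                        fr.test_stat, abs=1e-10
                    )
            assert stats_by_tuple[fr.selected] == pytest.approx(
                max(stats_by_tuple.values()), abs=1e-10
            )

    def test_planted_pair_power_monotone_in_offset(self):
        panel = ce.make_panel(8, n_blocks=2,
                              maf=[0.5 if i in (1, 5) else 0.3
                                   for i in range(8)])
        ids = panel.snp_ids
        planted = (ids[1], ids[5])
        rates = []
        for offset in (0.0, 0.25, 0.5, 1.0):
            hits = 0
            for rep in range(10):
                g = ce.simulate_genotypes(300, panel, seed=100 + rep)
                spec = ce.EffectSpec(
                    "y", noise_sd=1.0,
                    epistasis_terms=[ce.checkerboard_epistasis(*planted,
                                                               offset=offset)],
                )
                cov = ce.simulate_covariates(300, seed=200 + rep)
                y = _spec_values(spec, g, cov, np.random.default_rng(300 + rep))
                m = ce.cross_validated_search(g, y, method="qmdr", k=2,
                                              seed=rep)
                hits += set(m.snp_tuple) == set(planted)
            rates.append(hits)
        assert rates == sorted(rates)
        assert rates[-1] >= 9

    def test_adjustment_invariance_without_covariate_effects(self, rng):
        """With covariates that do not influence the trait, adjusted and
        unadjusted searches almost always agree on the winner."""
        agree = 0
        for rep in range(20):
            r = np.random.default_rng(rep)
            G = r.integers(0, 3, size=(300, 6))
            cov = r.normal(size=(300, 3))
            y = r.normal(size=300) + 1.0 * ((G[:, 0] + G[:, 4]) % 2)
            a = ce.cross_validated_search(G, y, cov, method="qmdr", k=2,
                                          seed=rep)
            b = ce.cross_validated_search(G, y, None, method="qmdr", k=2,
                                          seed=rep)
            agree += a.snp_tuple == b.snp_tuple
        assert agree >= 19

    def test_k_bounds_and_missing_rejected(self, rng):
        G = rng.integers(0, 3, size=(50, 3))
        with pytest.raises(ValueError):
            ce.cross_validated_search(G, rng.normal(size=50), k=4)
        G2 = G.copy()
        G2[0, 0] = ce.MISSING
        with pytest.raises(ValueError, match="complete"):
            ce.cross_validated_search(G2, rng.normal(size=50), k=2)


class TestPermutation:
    def test_p_floor_and_exceeding_all(self, rng):
        panel = ce.make_panel(6, n_blocks=2,
                              maf=[0.5, 0.3, 0.5, 0.3, 0.3, 0.3])
        g = ce.simulate_genotypes(200, panel, seed=55)
        spec = ce.EffectSpec(
            "y", noise_sd=1.0,
            epistasis_terms=[ce.checkerboard_epistasis(
                panel.snp_ids[0], panel.snp_ids[2], offset=1.5)],
        )
        cov = ce.simulate_covariates(200, seed=56)
        y = _spec_values(spec, g, cov, np.random.default_rng(57))
        res = ce.permutation_test(g, y, method="qmdr", k=2, B=99, seed=58)
        # strong signal beats every permuted search: p at the add-one floor
        assert res.b == 0
        assert res.p == pytest.approx(1 / 100)
        assert res.p >= 1 / (99 + 1)
        assert res.model.permuted_p == res.p

    def test_null_p_not_extreme(self, rng):
        G = rng.integers(0, 3, size=(120, 5))
        y = rng.normal(size=120)
        res = ce.permutation_test(G, y, method="qmdr", k=2, B=49, seed=3)
        assert res.p > 0.02
        assert len(res.null_stats) == 49
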