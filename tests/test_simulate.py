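"""Synthetic cohort generator: marginal frequencies, LD structure,
trait models, clinical scores, determinism."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import copd_epistasis as ce
from copd_epistasis.simulate import _spec_values, default_case_specs


class TestGenotypes:
    def test_marginal_maf_converges(self):
        panel = ce.make_panel(1, maf=0.3)
        g = ce.simulate_genotypes(1000, panel, seed=1)
        # binomial bound: 3 * sqrt(p(1-p)/2n) ~ 0.022
        assert abs(ce.compute_maf(g.calls[:, 0]) - 0.3) < 0.03

    def test_zero_rho_gives_independent_neighbours(self):
        panel = ce.make_panel(4, n_blocks=1, maf=0.3, block_ld_rho=0.0)
        g = ce.simulate_genotypes(2000, panel, seed=2)
        r = np.corrcoef(g.calls[:, 0], g.calls[:, 1])[0, 1]
        assert abs(r) < 0.1

    def test_high_rho_gives_tag_level_ld(self):
        panel = ce.make_panel(4, n_blocks=1, maf=0.3, block_ld_rho=0.95)
        g = ce.simulate_genotypes(2000, panel, seed=3)
        r = np.corrcoef(g.calls[:, 0], g.calls[:, 1])[0, 1]
        assert r**2 > 0.8  # haplotype-copy model: r^2 ~ rho^2 = 0.9025

    def test_cross_block_independence(self):
        panel = ce.make_panel(4, n_blocks=2, maf=0.3, block_ld_rho=0.95)
        g = ce.simulate_genotypes(2000, panel, seed=4)
        r = np.corrcoef(g.calls[:, 1], g.calls[:, 2])[0, 1]  # block boundary
        assert abs(r) < 0.1

    def test_unequal_mafs_keep_their_marginals_under_ld(self):
        panel = ce.make_panel(2, maf=[0.1, 0.4], block_ld_rho=0.9)
        g = ce.simulate_genotypes(4000, panel, seed=5)
        assert abs(ce.compute_maf(g.calls[:, 0]) - 0.1) < 0.02
        assert abs(ce.compute_maf(g.calls[:, 1]) - 0.4) < 0.03

    def test_values_in_range_and_deterministic(self, small_panel):
        a = ce.simulate_genotypes(100, small_panel, seed=6)
        b = ce.simulate_genotypes(100, small_panel, seed=6)
        assert set(np.unique(a.calls)) <= {0, 1, 2}
        np.testing.assert_array_equal(a.calls, b.calls)

    def test_missing_rate(self, small_panel):
        g = ce.simulate_genotypes(500, small_panel, seed=7, missing_rate=0.1)
        frac = (g.calls == ce.MISSING).mean()
        assert 0.05 < frac < 0.15

    def test_rejects_bad_inputs(self, small_panel):
        with pytest.raises(ValueError):
            ce.simulate_genotypes(0, small_panel, seed=1)
        with pytest.raises(ValueError):
            ce.make_panel(2, maf=0.6)
        with pytest.raises(ValueError):
            ce.make_panel(2, maf=0.04)  # panel invariant: MAF > 0.05


class TestCovariates:
    def test_ranges_and_determinism(self):
        cov = ce.simulate_covariates(10000, seed=8)
        assert cov["age"].between(40, 75).all()
        assert set(cov["sex"].unique()) <= {0, 1}
        assert (cov["pack_years"] >= 0).all()
        pd.testing.assert_frame_equal(cov, ce.simulate_covariates(10000, seed=8))

    def test_rejects_nonpositive_n(self):
        with pytest.raises(ValueError):
            ce.simulate_covariates(0, seed=1)


class TestTraits:
    def test_null_spec_recovers_intercept(self, small_panel):
        n = 4000
        g = ce.simulate_genotypes(n, small_panel, seed=9)
        cov = ce.simulate_covariates(n, seed=10)
        spec = ce.EffectSpec("y", intercept=5.0, noise_sd=1.0)
        y = _spec_values(spec, g, cov, np.random.default_rng(11))
        assert abs(y.mean() - 5.0) < 3.0 / np.sqrt(n)

    def test_planted_additive_effect_recovered_by_ols(self, small_panel):
        n = 500
        g = ce.simulate_genotypes(n, small_panel, seed=12)
        cov = ce.simulate_covariates(n, seed=13)
        spec = ce.EffectSpec(
            "y", intercept=1.0, noise_sd=1.0,
            main_effects={small_panel.snp_ids[0]: 0.5},
        )
        y = _spec_values(spec, g, cov, np.random.default_rng(14))
        res = ce.fit_additive_model(y, g.calls[:, 0], cov)
        assert abs(res.beta - 0.5) < 3 * res.se

    def test_pure_epistasis_has_cell_effect_without_marginal_slope(self):
        panel = ce.make_panel(2, maf=0.5)
        n = 3000
        g = ce.simulate_genotypes(n, panel, seed=15)
        cov = ce.simulate_covariates(n, seed=16)
        term = ce.checkerboard_epistasis(*panel.snp_ids, offset=1.0)
        spec = ce.EffectSpec("y", noise_sd=1.0, epistasis_terms=[term])
        y = _spec_values(spec, g, cov, np.random.default_rng(17))
        parity = (g.calls[:, 0] + g.calls[:, 1]) % 2
        # joint cells separate by ~2 offsets ...
        assert y[parity == 0].mean() - y[parity == 1].mean() > 1.5
        # ... but the additive marginal slope is tiny
        res = ce.fit_additive_model(y, g.calls[:, 0], None)
        assert abs(res.beta) < 0.15

    def test_spec_with_unknown_snp_errors(self, small_panel):
        g = ce.simulate_genotypes(50, small_panel, seed=18)
        cov = ce.simulate_covariates(50, seed=18)
        spec = ce.EffectSpec("y", main_effects={"nope": 1.0})
        with pytest.raises(KeyError):
            _spec_values(spec, g, cov, np.random.default_rng(0))

    def test_simulate_traits_controls_lack_case_only_traits(self, small_panel):
        g = ce.simulate_genotypes(30, small_panel, seed=19)
        cov = ce.simulate_covariates(30, seed=20)
        pheno = ce.simulate_traits(g, cov, default_case_specs(), seed=21,
                                   status="control")
        assert pheno.df["six_mwt"].isna().all()
        assert pheno.df["mmrc"].isna().all()
        assert pheno.df["bode"].isna().all()
        assert pheno.df["fev1"].notna().all()


class TestBode:
    @pytest.mark.parametrize(
        "args,expected",
        [
            ((25, 70, 0, 400), 0),   # every component in its best band
            ((20, 30, 4, 100), 10),  # every component in its worst band
            ((21, 65, 1, 350), 1),   # boundary values: only BMI scores
            ((22, 50, 2, 250), 3),
            ((22, 36, 3, 150), 6),
            ((20, 35, 5, 149), 10),
        ],
    )
    def test_banding(self, args, expected):
        assert ce.derive_bode(*args) == expected

    @given(
        bmi=st.floats(12, 45), pct=st.floats(10, 150),
        mmrc=st.integers(0, 4), walk=st.floats(0, 700),
    )
    @settings(max_examples=60, derandomize=True)
    def test_monotone_as_inputs_degrade(self, bmi, pct, mmrc, walk):
        base = ce.derive_bode(bmi, pct, mmrc, walk)
        assert ce.derive_bode(min(bmi, 21), pct, mmrc, walk) >= base
        assert ce.derive_bode(bmi, max(pct - 20, 10), mmrc, walk) >= base
        assert ce.derive_bode(bmi, pct, mmrc + 1, walk) >= base
        assert ce.derive_bode(bmi, pct, mmrc, max(walk - 110, 0)) >= base

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            ce.derive_bode(0, 70, 0, 400)
        with pytest.raises(ValueError):
            ce.derive_bode(25, 170, 0, 400)
        with pytest.raises(ValueError):
            ce.derive_bode(25, 70, 6, 400)
        with pytest.raises(ValueError):
            ce.derive_bode(25, 70, 0, -1)


class TestDiseaseStatus:
    def test_thresholds_are_strict(self):
        assert ce.assign_disease_status(0.65, 0.70) == "case"
        assert ce.assign_disease_status(0.75, 0.90) == "control"
        assert ce.assign_disease_status(0.70, 0.50) == "control"  # boundary
        assert ce.assign_disease_status(0.50, 0.80) == "control"  # boundary

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            ce.assign_disease_status(0.0, 0.5)


class TestCohort:
    def test_study_shape_and_determinism(self, tiny_cohort):
        assert tiny_cohort.n_subjects == 100
        assert int(tiny_cohort.phenotypes.case_mask().sum()) == 60
        again = ce.simulate_cohort(
            ce.CohortConfig(panel=ce.make_panel(12, n_blocks=3, maf=0.25),
                            n_cases=60, n_controls=40),
            seed=42,
        )
        np.testing.assert_array_equal(tiny_cohort.genotypes.calls,
                                      again.genotypes.calls)
        pd.testing.assert_frame_equal(tiny_cohort.phenotypes.df,
                                      again.phenotypes.df)

    def test_status_labels_honour_spirometric_definition(self, tiny_cohort):
        df = tiny_cohort.phenotypes.df
        got = ce.assign_disease_status(
            df["fev1_fvc"].to_numpy(), df["fev1_pct_pred"].to_numpy() / 100.0
        )
        assert (got == df["status"].to_numpy()).all()
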