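"""Mixed-model estimation, contrast inference, adaptive FDR, collinearity."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

import netlmm as nl
from netlmm.design import DesignMatrix
from netlmm.lmm import CONTRAST_GRID, adaptive_fdr, _bh_reject


def _random_design(rng, n=1200, p=6, g=24, sigma_b=0.3, sigma_e=0.7):
    X = rng.normal(size=(n, p))
    X[:, 0] = 1.0
    beta = rng.normal(size=p) * 0.5
    groups = np.repeat(np.arange(g), n // g)
    y = X @ beta + rng.normal(0, sigma_b, g)[groups] + rng.normal(0, sigma_e, n)
    dm = DesignMatrix(
        X=X, columns=[f"c{i}" for i in range(p)], y=y, groups=groups,
        model="model1", centers={},
    )
    return dm, beta


class TestFit:
    def test_agrees_with_statsmodels_mixedlm(self, rng):
        """Dual-route check: the profiled REML fit must match an
        independent general-purpose mixed-model implementation."""
        dm, _ = _random_design(rng)
        fit = nl.fit_lmm(dm)
        # statsmodels' default scoring can stall on this fixture; Powell
        # converges cleanly and serves as the independent reference
        ref = sm.MixedLM(dm.y, dm.X, groups=dm.groups).fit(
            reml=True, method="powell", maxiter=2000
        )
        np.testing.assert_allclose(fit.params.to_numpy(), ref.fe_params, atol=1e-6)
        np.testing.assert_allclose(
            np.sqrt(np.diag(fit.cov_params)), ref.bse_fe, atol=1e-5
        )
        assert fit.sigma_e == pytest.approx(np.sqrt(ref.scale), abs=1e-4)
        assert fit.sigma_b == pytest.approx(
            np.sqrt(float(np.asarray(ref.cov_re)[0, 0])), abs=1e-4
        )
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-5)

    def test_ml_flag_matches_statsmodels(self, rng):
        dm, _ = _random_design(rng)
        fit = nl.fit_lmm(dm, reml=False)
        ref = sm.MixedLM(dm.y, dm.X, groups=dm.groups).fit(
            reml=False, method="powell", maxiter=2000
        )
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-5)
        np.testing.assert_allclose(fit.params.to_numpy(), ref.fe_params, atol=1e-6)

    def test_zero_variance_limit_equals_ols(self):
        """On oracle data generated without a subject random effect, REML
        puts the variance ratio at the boundary and the fit collapses to
        ordinary least squares."""
        nodes = nl.generate_node_layout(30, 8, 160.0, seed=11)
        subjects = nl.generate_subject_table(5, seed=3)
        truth = nl.truth_from_contrasts("model1", sigma_e=0.05, sigma_b=0.0, seed=5)
        coh = nl.simulate_oracle_cohort(nodes, subjects, truth)
        dm = nl.assemble_design_matrix(coh.edge_table(), "model1")
        fit = nl.fit_lmm(dm)
        beta_ols, *_ = np.linalg.lstsq(dm.X, dm.y, rcond=None)
        np.testing.assert_allclose(fit.params.to_numpy(), beta_ols, atol=1e-6)

    def test_rank_deficiency_names_dependent_column(self, rng):
        dm, _ = _random_design(rng)
        dm.X[:, 5] = dm.X[:, 1] + dm.X[:, 2]
        with pytest.raises(ValueError, match="rank deficient"):
            nl.fit_lmm(dm)

    def test_single_subject_rejected(self, rng):
        dm, _ = _random_design(rng, g=1)
        with pytest.raises(ValueError, match="subjects"):
            nl.fit_lmm(dm)

    def test_variance_components_recovered_on_oracle_cohort(self, m1_fit):
        assert m1_fit.sigma_e == pytest.approx(0.05, rel=0.05)
        assert m1_fit.sigma_b == pytest.approx(0.02, rel=0.5)
        assert m1_fit.converged

    def test_wald_and_lrt_agree_on_moderate_effects(self, rng):
        dm, _ = _random_design(rng, n=1000, p=4, g=20, sigma_e=0.5)
        fit = nl.fit_lmm(dm)
        for term in ("c1", "c2", "c3"):
            pw = nl.wald_test(fit, pd.Series({term: 1.0})).p
            pl = nl.likelihood_ratio_pvalue(dm, term)
            assert abs(pw - pl) < 0.02


class TestContrastVectors:
    def test_single_group_within_selects_two_terms(self):
        L = nl.group_contrast_vector("model1", "HIV+MJ-", "within", "clustering")
        nz = L[L != 0]
        assert set(nz.index) == {"hiv:clust", "hiv:clust:dmn_within"}
        assert (nz == 1.0).all()

    def test_combined_group_within_sums_six_terms(self):
        L = nl.group_contrast_vector("model1", "HIV+MJ+", "within", "efficiency")
        expected = {
            "hiv:eff", "mj:eff", "hivmj:eff",
            "hiv:eff:dmn_within", "mj:eff:dmn_within", "hivmj:eff:dmn_within",
        }
        assert set(L[L != 0].index) == expected

    def test_outside_contrast_has_no_dmn_terms(self):
        L = nl.group_contrast_vector("model1", "HIV+MJ+", "outside", "efficiency")
        assert all("dmn_within" not in t for t in L[L != 0].index)

    def test_moderated_contrast_uses_globalT_terms(self):
        L = nl.group_contrast_vector(
            "model2", "HIV-MJ+", "within", "efficiency", moderated_by_globalT=True
        )
        assert set(L[L != 0].index) == {"globalT:mj:eff", "globalT:mj:eff:dmn_within"}

    def test_moderated_contrast_requires_model2(self):
        with pytest.raises(ValueError, match="model2"):
            nl.group_contrast_vector(
                "model1", "HIV+MJ-", "within", "clustering", moderated_by_globalT=True
            )


class TestWald:
    def _unit_fit(self):
        terms = ["a", "b"]
        return nl.ModelFit(
            params=pd.Series([2.0, 0.0], index=terms),
            cov_params=pd.DataFrame(np.eye(2), index=terms, columns=terms),
            sigma_b=0.0, sigma_e=1.0, loglik=0.0, n_rows=10, n_subjects=2,
            converged=True, method="reml", model="model1", centers={},
        )

    def test_z_two_matches_normal_tail(self):
        res = nl.wald_test(self._unit_fit(), pd.Series({"a": 1.0}))
        assert res.z == pytest.approx(2.0)
        assert res.p == pytest.approx(0.0455, abs=2e-4)

    def test_null_coefficient_gives_p_one(self):
        res = nl.wald_test(self._unit_fit(), pd.Series({"b": 1.0}))
        assert res.estimate == 0.0 and res.p == 1.0

    def test_all_zero_contrast_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            nl.wald_test(self._unit_fit(), pd.Series({"a": 0.0}))

    def test_unknown_term_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            nl.wald_test(self._unit_fit(), pd.Series({"nope": 1.0}))


class TestAdaptiveFDR:
    def test_all_ones_reject_nothing(self):
        p_adj, reject = adaptive_fdr([1.0, 1.0, 1.0], q=0.05)
        assert reject.sum() == 0
        assert (p_adj == 1.0).all()

    def test_hand_run_two_stage_example(self):
        # stage 1: BH at 0.05/1.05 = 0.0476 rejects the three small p-values;
        # m0 = 3, stage 2: BH at 0.05*6/3 = 0.1 rejects the same three
        p = [0.001, 0.002, 0.003, 0.8, 0.9, 0.95]
        p_adj, reject = adaptive_fdr(p, q=0.05)
        assert reject.tolist() == [True, True, True, False, False, False]
        assert (p_adj[:3] <= 0.05).all() and (p_adj[3:] > 0.05).all()

    def test_stage_components_match_statsmodels_bh(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(0.001, 1, 40)
        level = 0.05 / 1.05
        r = _bh_reject(p, level)
        ref = multipletests(p, alpha=level, method="fdr_bh")[0].sum()
        assert r == ref

    def test_adjusted_p_is_smallest_rejecting_level(self):
        p = [0.004, 0.02, 0.2, 0.6]
        p_adj, _ = adaptive_fdr(p, q=0.05)
        from netlmm.lmm import _two_stage_reject

        for i, pa in enumerate(p_adj):
            if pa < 1:
                assert _two_stage_reject(np.array(p), min(pa + 1e-6, 1 - 1e-9))[i]
                assert not _two_stage_reject(np.array(p), pa - 1e-6)[i]

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_monotone_in_q_and_step_up_coherent(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0.0005, 1, int(rng.integers(3, 15)))
        _, r1 = adaptive_fdr(p, q=0.05)
        _, r2 = adaptive_fdr(p, q=0.1)
        assert r1.sum() <= r2.sum()
        # never reject a hypothesis whose p exceeds that of an accepted one
        if r1.any() and (~r1).any():
            assert p[r1].max() <= p[~r1].min() + 1e-15

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            adaptive_fdr([0.0, 0.5])
        with pytest.raises(ValueError):
            adaptive_fdr([1.5])

    def test_empty_input(self):
        p_adj, reject = adaptive_fdr([])
        assert len(p_adj) == 0 and len(reject) == 0


class TestCollinearity:
    def test_duplicated_column_is_flagged(self, rng):
        n = 200
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x, x])
        dm = DesignMatrix(
            X=X, columns=["Intercept", "clust", "hiv:clust"], y=rng.normal(size=n),
            groups=np.repeat([0, 1], n // 2), model="model1", centers={},
        )
        rep = nl.collinearity_check(dm)
        assert rep.loc[rep.interaction == "hiv:clust", "flagged"].item()

    def test_product_with_balanced_centered_binary_is_uncorrelated(self, rng):
        n = 4000
        x = rng.normal(size=n)
        c = rng.permutation(np.repeat([-0.5, 0.5], n // 2))
        X = np.column_stack([np.ones(n), x, x * c])
        dm = DesignMatrix(
            X=X, columns=["Intercept", "eff", "mj:eff"], y=rng.normal(size=n),
            groups=np.repeat([0, 1], n // 2), model="model1", centers={},
        )
        rep = nl.collinearity_check(dm)
        assert abs(rep.loc[rep.interaction == "mj:eff", "r"].item()) < 0.1

    def test_default_oracle_design_is_well_conditioned(self, m1_design):
        rep = nl.collinearity_check(m1_design)
        assert len(rep) > 0
        assert not rep["flagged"].any()


class TestSamplingBehaviour:
    def test_contrast_se_shrinks_with_more_subjects(self):
        nodes = nl.generate_node_layout(40, 10, 160.0, seed=5)
        ses = {}
        for npg in (15, 30):
            subs = nl.generate_subject_table(npg, seed=21)
            truth = nl.truth_from_contrasts("model1", seed=22)
            coh = nl.simulate_oracle_cohort(nodes, subs, truth)
            fit = nl.fit_lmm(nl.assemble_design_matrix(coh.edge_table(), "model1"))
            L = nl.group_contrast_vector("model1", "HIV+MJ+", "within", "efficiency")
            ses[npg] = nl.wald_test(fit, L).se
        assert ses[30] < ses[15]

    def test_contrasts_are_unbiased_with_nominal_coverage(self):
        """100 replicate oracle cohorts: every contrast's 95% Wald interval
        covers its truth in >= 90 of 100 replicates, and the mean error is
        within 3 standard errors of the replicate mean (no systematic bias)."""
        from netlmm.cohort import DEFAULT_GROUP_DIFFERENCES

        nodes = nl.generate_node_layout(30, 8, 160.0, seed=11)
        est = {k: [] for k in CONTRAST_GRID}
        ses = {k: [] for k in CONTRAST_GRID}
        reps = 100
        for rep in range(reps):
            subs = nl.generate_subject_table(8, seed=5000 + rep)
            truth = nl.truth_from_contrasts("model1", seed=6000 + rep)
            coh = nl.simulate_oracle_cohort(nodes, subs, truth)
            fit = nl.fit_lmm(nl.assemble_design_matrix(coh.edge_table(), "model1"))
            for key in CONTRAST_GRID:
                group, loc, metric = key
                r = nl.wald_test(fit, nl.group_contrast_vector("model1", group, loc, metric))
                est[key].append(r.estimate)
                ses[key].append(r.se)
        for key in CONTRAST_GRID:
            group, loc, metric = key
            v = DEFAULT_GROUP_DIFFERENCES[(group, metric, loc if loc == "within" else "outside")]
            e, s = np.array(est[key]), np.array(ses[key])
            coverage = np.mean(np.abs(e - v) <= 1.96 * s)
            assert coverage >= 0.90, (key, coverage)
            assert abs(e.mean() - v) <= 3 * s.mean() / np.sqrt(reps), key
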