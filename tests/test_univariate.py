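"""Covariate-adjusted group tests, FDR correction and fold changes."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import ftldmet
from ftldmet.data import MetaboliteMatrix, ValidationError
from ftldmet.univariate import (
    adjust_fdr,
    bonferroni_flags,
    fit_metabolite_glm,
    fold_changes,
    glm_group_scan,
    run_univariate,
)

from conftest import scaled_cohort


def _random_design(seed, n=40):
    rng = np.random.default_rng(seed)
    group = (rng.random(n) < 0.5).astype(float)
    age = rng.normal(70, 8, n)
    sex = (rng.random(n) < 0.5).astype(float)
    y = 0.4 * group + 0.02 * age - 0.1 * sex + rng.normal(0, 1, n)
    return y, group, age, sex


class TestGLM:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_statsmodels_ols(self, seed):
        y, group, age, sex = _random_design(seed)
        coef, p = fit_metabolite_glm(y, group, age, sex)
        X = sm.add_constant(np.column_stack([group, age, sex]))
        fit = sm.OLS(y, X).fit()
        assert coef == pytest.approx(fit.params[1], abs=1e-10)
        assert p == pytest.approx(fit.pvalues[1], abs=1e-10)

    def test_matches_normal_equations_on_toy_design(self):
        # independent oracle: solve the 6x4 least-squares system by hand
        y = np.array([1.2, 0.8, 1.9, 2.4, 0.3, 1.1])
        group = np.array([0.0, 0.0, 1.0, 1.0, 0.0, 1.0])
        age = np.array([61.0, 70.0, 66.0, 75.0, 68.0, 72.0])
        sex = np.array([1.0, 0.0, 1.0, 0.0, 0.0, 1.0])
        X = np.column_stack([np.ones(6), group, age, sex])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        coef, _ = fit_metabolite_glm(y, group, age, sex)
        assert coef == pytest.approx(beta[1], abs=1e-12)

    def test_perfect_separation_limit(self):
        group = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
        age = np.array([60.0, 65.0, 70.0, 62.0, 67.0, 72.0])
        sex = np.array([0.0, 1.0, 0.0, 1.0, 0.0, 1.0])
        coef, p = fit_metabolite_glm(group.copy(), group, age, sex)
        assert coef == pytest.approx(1.0, abs=1e-10)
        assert p < 1e-20

    def test_collinear_design_is_an_error(self):
        y, group, age, _ = _random_design(3)
        with pytest.raises(ValidationError, match="collinear"):
            fit_metabolite_glm(y, group, age, np.ones_like(y))

    def test_constant_metabolite_is_an_error(self):
        _, group, age, sex = _random_design(4)
        with pytest.raises(ValidationError):
            fit_metabolite_glm(np.ones_like(age), group, age, sex)

    def test_balanced_orthogonal_covariates_reduce_to_mean_difference(self):
        # same age/sex composition in both groups: the adjusted group
        # coefficient equals the raw two-sample mean difference
        rng = np.random.default_rng(5)
        age = np.tile(rng.normal(70, 5, 10), 2)
        sex = np.tile((rng.random(10) < 0.5).astype(float), 2)
        group = np.r_[np.zeros(10), np.ones(10)]
        y = rng.normal(0, 1, 20) + 0.7 * group
        coef, _ = fit_metabolite_glm(y, group, age, sex)
        assert coef == pytest.approx(y[10:].mean() - y[:10].mean(), abs=1e-10)

    def test_null_p_values_uniform(self):
        """Under no group effect, scan p-values are uniform (KS check)."""
        from scipy import stats

        rng = np.random.default_rng(6)
        n = 80
        group = np.r_[np.zeros(40), np.ones(40)]
        age = rng.normal(70, 8, n)
        sex = (rng.random(n) < 0.5).astype(float)
        Y = rng.normal(0, 1, (n, 2000))
        _, pvals = glm_group_scan(Y, group, age, sex)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestFDR:
    def test_bh_matches_brute_force_and_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        p = np.array([0.001, 0.02, 0.03, 0.9])
        adj = adjust_fdr(p, "bh")
        # brute-force BH: min over tail of m * p_(j) / j
        m = len(p)
        order = np.argsort(p)
        brute = np.empty(m)
        for rank_pos, idx in enumerate(order):
            tail = [m * p[order[j]] / (j + 1) for j in range(rank_pos, m)]
            brute[idx] = min(1.0, min(tail))
        np.testing.assert_allclose(adj, brute, atol=1e-12)
        np.testing.assert_allclose(adj, [0.004, 0.04, 0.04, 0.9], atol=1e-12)
        np.testing.assert_allclose(
            adj, multipletests(p, method="fdr_bh")[1], atol=1e-12
        )

    def test_degenerate_inputs(self):
        assert adjust_fdr(np.ones(5), "bh").tolist() == [1.0] * 5
        assert adjust_fdr(np.array([0.05]), "bh")[0] == pytest.approx(0.05)
        with pytest.raises(ValidationError):
            adjust_fdr(np.array([0.5, 1.2]), "bh")

    def test_adjusted_at_least_raw_and_monotone(self):
        rng = np.random.default_rng(7)
        p = rng.random(200)
        adj = adjust_fdr(p, "bh")
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_storey_never_exceeds_bh(self):
        rng = np.random.default_rng(8)
        p = rng.random(500) ** 2  # enriched near 0
        assert (adjust_fdr(p, "storey") <= adjust_fdr(p, "bh") + 1e-15).all()


class TestBonferroni:
    def test_effective_threshold_at_m_750(self):
        p = np.full(750, 0.5)
        p[0] = 1.0e-5  # below 0.01/750 = 1.333e-5
        p[1] = 1.4e-5  # above
        flags = bonferroni_flags(p, alpha=0.01)
        assert flags[0] and not flags[1]

    def test_single_test_and_exact_boundary(self):
        assert bonferroni_flags(np.array([0.009]), 0.01)[0]
        # p exactly alpha/m is not flagged (strict <)
        assert not bonferroni_flags(np.array([0.01]), 0.01)[0]
        with pytest.raises(ValidationError):
            bonferroni_flags(np.array([]), 0.01)


class TestFoldChanges:
    def _meta(self, groups):
        return ftldmet.CohortMetadata(
            pd.DataFrame(
                {
                    "group": groups,
                    "age": 70.0,
                    "sex": "M",
                    "survival_days": np.nan,
                    "event": np.nan,
                },
                index=[f"P{i}" for i in range(len(groups))],
            )
        )

    def test_closed_form_examples(self):
        meta = self._meta(["bvFTD", "bvFTD", "Control", "Control"])
        m = MetaboliteMatrix(
            pd.DataFrame(
                {"a": [2.0, 2.0, 1.0, 1.0], "b": [3.0, 3.0, 3.0, 3.0]},
                index=meta.participant_ids,
            )
        )
        fc = fold_changes(m, meta, case_groups=("bvFTD",))
        assert fc["a"] == pytest.approx(2.0)
        assert fc["b"] == pytest.approx(1.0)

    def test_zero_control_mean_is_an_error(self):
        meta = self._meta(["bvFTD", "Control"])
        m = MetaboliteMatrix(
            pd.DataFrame({"a": [2.0, 0.0]}, index=meta.participant_ids)
        )
        with pytest.raises(ValidationError, match="a"):
            fold_changes(m, meta)

    def test_planted_shift_is_recovered(self):
        """Median fold change of up-shifted metabolites ~ exp(delta)."""
        matrix, pmap, meta, truth = scaled_cohort(seed=31)
        pre = ftldmet.preprocess(matrix, pmap)
        fc = fold_changes(pre.unscaled, meta)
        delta = pd.Series(truth.affected_metabolites)
        up = delta[delta > 0].index.intersection(fc.index)
        assert len(up) > 2
        med = fc.loc[up].median()
        assert med == pytest.approx(np.exp(delta[up].median()), rel=0.10)


class TestScan:
    def test_power_monotone_in_effect_size(self):
        counts = []
        for mag in (0.0, 0.35, 0.7):
            n_sig = 0
            for seed in (51, 52, 53):
                matrix, pmap, meta, _ = scaled_cohort(
                    seed=seed,
                    log_fc_magnitude=mag,
                    n_factor_subpathways=0,
                    factor_loading=0.0,
                    severity_patient_shift=0.0,
                )
                pre = ftldmet.preprocess(matrix, pmap)
                n_sig += len(run_univariate(pre, meta).significant)
            counts.append(n_sig)
        assert counts[0] <= counts[1] <= counts[2]
        assert counts[2] > counts[0]

    def test_result_table_is_complete_and_sorted(self, planted_preprocessed):
        pre, meta, _ = planted_preprocessed
        res = run_univariate(pre, meta)
        assert len(res.table) == pre.scaled.n_metabolites
        assert (res.table["p_raw"].diff().dropna() >= 0).all()
        assert (res.table["p_fdr"] >= res.table["p_raw"] - 1e-15).all()
        assert set(res.table["bonferroni_flag"].unique()) <= {0, 1}
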