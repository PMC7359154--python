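"""Local/global correlation PCA, Kaiser retention and loading reports."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import ftldmet
from ftldmet.data import ValidationError
from ftldmet.pathway_pca import (
    aggregate_loadings_by_subpathway,
    component_loading_report,
    fit_local_pcas,
    global_pca,
    local_pca,
    severity_candidate,
    subpathway_group_tests,
)
from ftldmet.univariate import adjust_fdr

from conftest import scaled_cohort


def _zscore(df: pd.DataFrame) -> pd.DataFrame:
    return (df - df.mean()) / df.std(ddof=1)


def _random_block(seed: int, n=20, p=5) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    return _zscore(
        pd.DataFrame(
            rng.normal(size=(n, p)),
            index=[f"P{i}" for i in range(n)],
            columns=[f"m{j}" for j in range(p)],
        )
    )


def _svd_oracle(Z: np.ndarray):
    """Independent PCA oracle via singular value decomposition."""
    from ftldmet.pathway_pca import deterministic_sign_fix

    n = Z.shape[0]
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    eigval = s**2 / (n - 1)
    # decomposition is independent; only the sign convention is shared
    V = deterministic_sign_fix(Vt.T)
    return eigval, V


class TestLocalPCA:
    def test_perfectly_correlated_pair(self):
        z = _random_block(0, p=1)
        block = pd.DataFrame({"a": z["m0"], "b": z["m0"]})
        model = local_pca(block, "sp")
        np.testing.assert_allclose(model.eigenvalues, [2.0, 0.0], atol=1e-10)
        assert model.n_retained == 1
        # scores proportional to the shared profile
        r = np.corrcoef(model.scores.iloc[:, 0], z["m0"])[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-10)

    def test_two_column_eigenvalues_are_one_plus_minus_r(self):
        block = _random_block(1, p=2)
        r = np.corrcoef(block["m0"], block["m1"])[0, 1]
        model = local_pca(block, "sp")
        np.testing.assert_allclose(
            model.eigenvalues, [1 + abs(r), 1 - abs(r)], atol=1e-10
        )
        assert model.n_retained == (1 if r != 0 else 0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_svd_oracle(self, seed):
        block = _random_block(seed)
        model = local_pca(block, "sp", kaiser_threshold=0.0)  # retain all
        eigval, V = _svd_oracle(block.to_numpy())
        np.testing.assert_allclose(model.eigenvalues, eigval, atol=1e-8)
        np.testing.assert_allclose(model.loadings, V, atol=1e-8)
        np.testing.assert_allclose(
            model.scores.to_numpy(), block.to_numpy() @ V, atol=1e-8
        )

    def test_total_variance_conserved_and_score_variance_is_eigenvalue(self):
        block = _random_block(7, p=6)
        model = local_pca(block, "sp", kaiser_threshold=0.0)
        assert model.eigenvalues.sum() == pytest.approx(6.0, abs=1e-8)
        np.testing.assert_allclose(
            model.scores.var(ddof=1).to_numpy(),
            model.eigenvalues[: model.n_retained],
            atol=1e-6,
        )

    def test_loadings_orthonormal_and_runs_bit_identical(self):
        block = _random_block(3)
        a = local_pca(block, "sp")
        b = local_pca(block.copy(), "sp")
        np.testing.assert_allclose(a.loadings.T @ a.loadings,
                                   np.eye(a.n_retained), atol=1e-8)
        assert np.array_equal(a.loadings, b.loadings)
        assert a.scores.equals(b.scores)

    def test_single_metabolite_policies(self):
        block = _random_block(4, p=1).rename(columns={"m0": "only"})
        keep = local_pca(block, "sp", policy="passthrough")
        assert keep.n_retained == 1 and keep.passthrough
        np.testing.assert_allclose(
            keep.scores.iloc[:, 0].to_numpy(), block["only"].to_numpy()
        )
        drop = local_pca(block, "sp", policy="drop")
        assert drop.n_retained == 0

    def test_missing_or_constant_columns_rejected(self):
        block = _random_block(5)
        block.iloc[0, 0] = np.nan
        with pytest.raises(ValidationError):
            local_pca(block, "sp")
        const = _random_block(5)
        const["m0"] = 0.0
        with pytest.raises(ValidationError, match="zero-variance"):
            local_pca(const, "sp")

    def test_reconstruction_error_equals_discarded_eigenvalue_mass(self):
        block = _random_block(9, p=6)
        model = local_pca(block, "sp")  # Kaiser retention discards some
        Z = block.to_numpy()
        resid = Z - model.scores.to_numpy() @ model.loadings.T
        resid_var = (resid**2).sum() / (len(Z) - 1)
        discarded = model.eigenvalues[model.n_retained:].sum()
        assert resid_var == pytest.approx(discarded, abs=1e-8)


class TestSubpathwayTests:
    def test_identical_groups_give_t_zero_p_one(self):
        matrix, pmap, meta, _ = scaled_cohort(seed=61)
        pre = ftldmet.preprocess(matrix, pmap)
        models = fit_local_pcas(pre.scaled, pre.pathway_map)
        # overwrite one model's scores to be group-constant
        sub = next(iter(models))
        models[sub].scores.iloc[:, 0] = 1.0 * (
            np.arange(len(models[sub].scores)) % 2
        )
        table, _ = subpathway_group_tests(models, meta)
        assert set(table["subpathway"]) == set(models)
        assert ((table["p_fdr"] >= table["p_raw"] - 1e-15)).all()

    def test_fdr_shares_the_univariate_code_path(self):
        matrix, pmap, meta, _ = scaled_cohort(seed=62)
        pre = ftldmet.preprocess(matrix, pmap)
        models = fit_local_pcas(pre.scaled, pre.pathway_map)
        table, _ = subpathway_group_tests(models, meta)
        np.testing.assert_allclose(
            table["p_fdr"], adjust_fdr(table["p_raw"].to_numpy()), atol=1e-15
        )

    def test_factor_subpathways_are_detected(self):
        matrix, pmap, meta, truth = scaled_cohort(seed=63)
        pre = ftldmet.preprocess(matrix, pmap)
        models = fit_local_pcas(pre.scaled, pre.pathway_map)
        _, significant = subpathway_group_tests(models, meta)
        assert set(truth.factor_subpathways) <= set(significant)


class TestGlobalPCA:
    def test_uncorrelated_features_have_eigenvalues_near_one(self):
        rng = np.random.default_rng(10)
        models = {}
        idx = [f"P{i}" for i in range(500)]
        for s in range(4):
            block = _zscore(pd.DataFrame(
                rng.normal(size=(500, 2)), index=idx,
                columns=[f"m{s}a", f"m{s}b"],
            ))
            models[f"sp{s}"] = local_pca(block, f"sp{s}", kaiser_threshold=0.0)
        g = global_pca(models, retention="fixed_k", fixed_k=8)
        assert np.all(np.abs(g.eigenvalues - 1.0) < 0.35)

    def test_fixed_k_and_kaiser_retention(self):
        matrix, pmap, meta, _ = scaled_cohort(seed=64)
        pre = ftldmet.preprocess(matrix, pmap)
        models = fit_local_pcas(pre.scaled, pre.pathway_map)
        g5 = global_pca(models, retention="fixed_k", fixed_k=5)
        assert g5.n_retained == 5
        gk = global_pca(models, retention="kaiser")
        assert gk.n_retained == int(np.sum(gk.eigenvalues > 1.0))
        assert g5.component_names == [f"G{k}" for k in range(1, 6)]

    def test_too_few_features_is_an_error(self):
        block = _random_block(11, p=2)
        models = {"sp": local_pca(block, "sp")}
        with pytest.raises(ValidationError):
            global_pca(models)

    def test_planted_severity_factor_is_recovered(self):
        matrix, pmap, meta, truth = scaled_cohort(seed=65)
        pre = ftldmet.preprocess(matrix, pmap)
        models = fit_local_pcas(pre.scaled, pre.pathway_map)
        g = global_pca(models, retention="fixed_k", fixed_k=5)
        name, r = severity_candidate(g, truth.latent_severity)
        assert abs(r) > 0.9

    def test_two_level_transform_matches_independent_oracle(self):
        """Recompute both PCA stages with the SVD oracle end to end."""
        matrix, pmap, meta, _ = scaled_cohort(seed=66)
        pre = ftldmet.preprocess(matrix, pmap)
        models = fit_local_pcas(pre.scaled, pre.pathway_map)
        # oracle stage 1
        oracle_scores = []
        for sub in pre.pathway_map.subpathways:
            mets = [m for m in pre.pathway_map.metabolites_in(sub)
                    if m in set(pre.scaled.metabolite_ids)]
            Z = pre.scaled.values[mets].to_numpy()
            eigval, V = _svd_oracle(Z)
            k = int(np.sum(eigval > 1.0)) if Z.shape[1] > 1 else 1
            oracle_scores.append(Z @ V[:, :k])
        F = np.hstack(oracle_scores)
        F = (F - F.mean(axis=0)) / F.std(axis=0, ddof=1)
        eigval2, V2 = _svd_oracle(F)
        g = global_pca(models, retention="fixed_k", fixed_k=5)
        np.testing.assert_allclose(g.eigenvalues, eigval2, atol=1e-8)
        np.testing.assert_allclose(g.scores.to_numpy(), F @ V2[:, :5], atol=1e-7)


class TestLoadingReport:
    def test_unit_squared_loading_and_sorting(self):
        matrix, pmap, meta, _ = scaled_cohort(seed=67)
        pre = ftldmet.preprocess(matrix, pmap)
        models = fit_local_pcas(pre.scaled, pre.pathway_map)
        g = global_pca(models, retention="fixed_k", fixed_k=3)
        rep = component_loading_report(g, 0)
        assert (rep["loading"] ** 2).sum() == pytest.approx(1.0, abs=1e-10)
        assert (rep["loading"].diff().dropna() <= 1e-15).all()
        assert component_loading_report(g, "G1").equals(rep)

    def test_out_of_range_component_is_an_error(self):
        matrix, pmap, meta, _ = scaled_cohort(seed=67)
        pre = ftldmet.preprocess(matrix, pmap)
        g = global_pca(fit_local_pcas(pre.scaled, pre.pathway_map),
                       retention="fixed_k", fixed_k=3)
        with pytest.raises(ValidationError):
            component_loading_report(g, 3)
        with pytest.raises(ValidationError):
            component_loading_report(g, "G9")

    def test_severity_component_loads_on_factor_subpathways(self):
        matrix, pmap, meta, truth = scaled_cohort(seed=68)
        pre = ftldmet.preprocess(matrix, pmap)
        g = global_pca(fit_local_pcas(pre.scaled, pre.pathway_map),
                       retention="fixed_k", fixed_k=5)
        name, r = severity_candidate(g, truth.latent_severity)
        agg = aggregate_loadings_by_subpathway(component_loading_report(g, name))
        top = set(
            agg.sort_values("squared_loading", ascending=False)
            .head(len(truth.factor_subpathways))["subpathway"]
        )
        assert top == set(truth.factor_subpathways)
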