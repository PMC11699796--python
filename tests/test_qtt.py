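import numpy as np
import pandas as pd
import pytest

import fermtx as fx
from fermtx.errors import ValidationError
from fermtx.qtt import (
    HiddenFactors,
    QTTModelFit,
    call_qtts,
    compute_pcs,
    estimate_hidden_factors,
    fit_qtt_model,
    select_pcs,
)


def frame(values):
    values = np.asarray(values, float)
    return pd.DataFrame(
        values,
        index=[f"g{i}" for i in range(values.shape[0])],
        columns=[f"s{j}" for j in range(values.shape[1])],
    )


class TestComputePCs:
    def test_zero_components_gives_empty_matrix(self):
        pcs = compute_pcs(frame(np.random.default_rng(0).normal(size=(20, 8))), 0)
        assert pcs.shape == (8, 0)

    def test_rank_one_factor_recovered(self):
        rng = np.random.default_rng(1)
        factor = rng.normal(size=10)
        loadings = rng.normal(size=200)
        values = np.outer(loadings, factor) + rng.normal(0, 1e-4, (200, 10))
        pcs = compute_pcs(frame(values), 1)
        r = np.corrcoef(pcs["PC1"], factor)[0, 1]
        assert abs(r) > 0.999

    def test_columns_centered(self):
        rng = np.random.default_rng(2)
        pcs = compute_pcs(frame(rng.normal(5, 2, size=(50, 9))), 3)
        np.testing.assert_allclose(pcs.mean(axis=0), 0, atol=1e-9)

    def test_k_too_large_rejected(self):
        with pytest.raises(ValidationError):
            compute_pcs(frame(np.zeros((10, 5))), 5)


class TestSelectPCs:
    def test_phenotype_collinear_pc_skipped(self):
        rng = np.random.default_rng(3)
        phen = rng.uniform(1, 8, 23)
        pcs = pd.DataFrame(
            {
                "PC1": phen - phen.mean() + rng.normal(0, 1e-3, 23),
                "PC2": rng.normal(size=23),
                "PC3": rng.normal(size=23),
            }
        )
        kept, excluded = select_pcs(pcs, phen, 2)
        assert excluded == ["PC1"]
        assert list(kept.columns) == ["PC2", "PC3"]

    def test_surrogate_duplicate_pc_skipped(self):
        rng = np.random.default_rng(4)
        phen = rng.uniform(1, 8, 23)
        shared = rng.normal(size=23)
        pcs = pd.DataFrame({"PC1": shared + rng.normal(0, 0.05, 23), "PC2": rng.normal(size=23)})
        hfs = pd.DataFrame({"HF1": shared})
        kept, excluded = select_pcs(pcs, phen, 1, hidden_factors=hfs)
        assert excluded == ["PC1"]
        assert list(kept.columns) == ["PC2"]


class TestHiddenFactors:
    def test_pure_noise_usually_yields_zero_factors(self):
        rng = np.random.default_rng(5)
        n, g = 23, 400
        la = rng.uniform(1, 8, n)
        mm = np.column_stack([np.ones(n), la])
        zero = 0
        runs = 25
        for run in range(runs):
            values = frame(rng.normal(size=(g, n)))
            hfs = estimate_hidden_factors(values, mm, n_permutations=100, seed=run)
            zero += hfs.n_factors == 0
        assert zero / runs >= 0.9

    def test_planted_batch_factor_recovered(self):
        rng = np.random.default_rng(6)
        n, g = 23, 500
        la = rng.uniform(1, 8, n)
        batch = rng.normal(size=n)
        batch = (batch - batch.mean()) / batch.std()
        values = rng.normal(size=(g, n))
        loaded = rng.random(g) < 0.3
        signs = rng.choice([-1.0, 1.0], loaded.sum())
        values[loaded] += np.outer(2.0 * signs, batch)
        hfs = estimate_hidden_factors(
            frame(values), np.column_stack([np.ones(n), la]), seed=7
        )
        assert hfs.n_factors >= 1
        r = np.corrcoef(hfs.scores["HF1"], batch)[0, 1]
        assert abs(r) > 0.8

    def test_unit_variance_scores(self):
        rng = np.random.default_rng(7)
        n, g = 20, 300
        batch = rng.normal(size=n)
        values = rng.normal(size=(g, n))
        values[: g // 2] += np.outer(rng.normal(0, 2, g // 2), batch)
        hfs = estimate_hidden_factors(
            frame(values), np.column_stack([np.ones(n), rng.normal(size=n)]), seed=8
        )
        if hfs.n_factors:
            np.testing.assert_allclose(hfs.scores.std(ddof=1), 1.0, rtol=1e-8)

    def test_zero_permutations_rejected(self):
        values = frame(np.zeros((10, 8)))
        with pytest.raises(ValidationError, match="n_permutations"):
            estimate_hidden_factors(values, np.ones((8, 1)), n_permutations=0)

    def test_too_few_samples_rejected(self):
        values = frame(np.random.default_rng(0).normal(size=(10, 3)))
        with pytest.raises(ValidationError, match="samples"):
            estimate_hidden_factors(values, np.ones((3, 2)), n_permutations=5)


class TestModelFit:
    def test_noise_free_gene_recovered_exactly(self):
        la = np.array([1.0, 2.0, 4.0, 5.5, 7.0, 8.0])
        values = frame((2.0 + 0.5 * la)[None, :])
        fit = fit_qtt_model(values, la)
        assert fit.coefficients.loc["g0", "phenotype"] == pytest.approx(0.5, abs=1e-12)
        assert fit.coefficients.loc["g0", "intercept"] == pytest.approx(2.0, abs=1e-12)

    def test_six_sample_toy_matches_normal_equations(self):
        rng = np.random.default_rng(9)
        la = np.array([1.0, 3.0, 3.5, 5.0, 7.5, 8.0])
        pcs = pd.DataFrame({"PC1": rng.normal(size=6)})
        values = frame(rng.normal(size=(5, 6)))
        fit = fit_qtt_model(values, la, pcs)
        X = np.column_stack([np.ones(6), la, pcs["PC1"]])
        oracle = np.linalg.inv(X.T @ X) @ X.T @ values.to_numpy().T
        np.testing.assert_allclose(
            fit.coefficients.to_numpy(), oracle.T, atol=1e-8
        )

    def test_residuals_sum_to_zero(self):
        rng = np.random.default_rng(10)
        la = rng.uniform(1, 8, 12)
        values = frame(rng.normal(size=(20, 12)))
        fit = fit_qtt_model(values, la)
        X = fit.design.to_numpy()
        resid = values.to_numpy().T - X @ fit.coefficients.to_numpy().T
        np.testing.assert_allclose(resid.sum(axis=0), 0, atol=1e-8)

    def test_constant_phenotype_rejected_as_collinear(self):
        values = frame(np.random.default_rng(0).normal(size=(5, 8)))
        with pytest.raises(ValidationError, match="phenotype"):
            fit_qtt_model(values, np.full(8, 3.0))


class TestCallQTTs:
    @staticmethod
    def make_fit(alphas, pvals):
        genes = pd.Index([f"g{i}" for i in range(len(alphas))], name="gene_id")
        coef = pd.DataFrame(
            {"intercept": 0.0, "phenotype": alphas}, index=genes
        )
        return QTTModelFit(
            coefficients=coef,
            se_alpha=pd.Series(1.0, index=genes),
            t_alpha=pd.Series(np.asarray(alphas), index=genes),
            pvalue_alpha=pd.Series(np.asarray(pvals), index=genes),
            df_resid=10,
            design=pd.DataFrame({"intercept": [1.0], "phenotype": [0.0]}),
        )

    def test_all_p_one_gives_no_qtts(self):
        table = call_qtts(self.make_fit([1.0, -1.0], [1.0, 1.0]))
        assert (table["qtt_class"] == "none").all()

    def test_threshold_is_inclusive(self):
        table = call_qtts(self.make_fit([2.0], [0.001]))
        assert table["qtt_class"].iloc[0] == "positive"
        table = call_qtts(self.make_fit([2.0], [0.001 + 1e-6]))
        assert table["qtt_class"].iloc[0] == "none"

    def test_class_sign_matches_alpha(self):
        table = call_qtts(self.make_fit([3.0, -3.0], [1e-6, 1e-6]))
        assert list(table["qtt_class"]) == ["positive", "negative"]


def planted_design(seed, n_genes=1200, frac=0.05, alpha=1.0, sd=0.5, n_factor=1):
    """Expression drawn directly from the QTT model under the study's
    lactic-acid spread (group tiers + strain-level noise)."""
    rng = np.random.default_rng(seed)
    config = fx.GeneratorConfig()
    sizes = tuple(s * n_factor for s in config.group_sizes)
    groups = np.repeat(np.arange(6), sizes)
    la = np.array([config.la_group_means[g] for g in groups])
    la = np.maximum(la + rng.normal(0, config.la_within_sd, len(groups)), 0.05)
    n_true = int(frac * n_genes)
    values = rng.normal(7, 1.5, n_genes)[:, None] + rng.normal(
        0, sd, (n_genes, len(la))
    )
    values[:n_true] += alpha * (la - la.mean())[None, :]
    truth = {f"g{i}": alpha for i in range(n_true)}
    return frame(values), la, truth


class TestRecovery:
    def test_alpha_unbiased_and_rmse_shrinks_with_n(self):
        rmse = {}
        bias = {}
        for factor in (1, 4):
            errors = []
            for seed in range(4):
                values, la, truth = planted_design(seed + 50, n_factor=factor)
                result = fx.qtt_analysis(
                    values, la, fx.AnalysisConfig(seed=seed, sva_permutations=30)
                )
                est = result.table.loc[list(truth), "alpha"].to_numpy()
                errors.append(est - 1.0)
            errors = np.concatenate(errors)
            rmse[factor] = float(np.sqrt(np.mean(errors**2)))
            bias[factor] = float(errors.mean())
        assert abs(bias[1]) < 0.1
        assert rmse[4] < rmse[1]
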