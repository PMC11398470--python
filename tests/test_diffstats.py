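"""Size factors, dispersions, NB Wald tests, BH adjustment and hit calls."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ciberseq import diffstats as ds
from ciberseq import tabulate as tb
from ciberseq.manifest import validate_manifest


def make_matrix(values, n_cond=1, n_rep=None, conditions=None, index=None):
    """A count matrix with standard (sample, condition, replicate, channel)
    columns; one channel per (condition, replicate) unless doubled."""
    values = np.asarray(values)
    n = values.shape[1]
    if conditions is None:
        n_rep = n // n_cond
        conditions = [f"cond{c}" for c in range(n_cond) for _ in range(n_rep)]
    reps = {}
    rows = []
    for cond in conditions:
        reps[cond] = reps.get(cond, 0) + 1
        rows.append(("f", f"{cond}_r{reps[cond]}", cond, str(reps[cond]), "red"))
    manifest = validate_manifest(pd.DataFrame(
        rows, columns=["fastq_path", "sample_id", "condition", "replicate", "channel"]))
    cols = tb.make_columns(manifest)
    idx = index if index is not None else [f"f{i}" for i in range(values.shape[0])]
    return pd.DataFrame(values, index=idx, columns=cols)


def make_paired_matrix(red, ir, conditions):
    """Channel-paired matrix: one red and one ir column per sample."""
    red, ir = np.asarray(red), np.asarray(ir)
    rows = []
    reps = {}
    for cond in conditions:
        reps[cond] = reps.get(cond, 0) + 1
        sample = f"{cond}_r{reps[cond]}"
        rows.append(("f", sample, cond, str(reps[cond]), "red"))
        rows.append(("f", sample, cond, str(reps[cond]), "ir"))
    manifest = validate_manifest(pd.DataFrame(
        rows, columns=["fastq_path", "sample_id", "condition", "replicate", "channel"]))
    cols = tb.make_columns(manifest)
    values = np.empty((red.shape[0], 2 * red.shape[1]), dtype=red.dtype)
    values[:, 0::2] = red
    values[:, 1::2] = ir
    return pd.DataFrame(values, index=[f"f{i}" for i in range(red.shape[0])],
                        columns=cols)


class TestSizeFactors:
    def test_identical_columns_are_unity(self):
        m = make_matrix([[10, 10], [7, 7], [3, 3]])
        sf = ds.size_factors(m)
        assert np.allclose(sf, [1.0, 1.0])

    def test_doubled_column_closed_form(self):
        a = np.array([[10], [20], [7], [100]])
        m = make_matrix(np.hstack([a, 2 * a]))
        sf = ds.size_factors(m)
        assert np.allclose(sf, [1 / np.sqrt(2), np.sqrt(2)], atol=1e-12)

    def test_random_matrix_matches_brute_force(self, rng):
        counts = rng.integers(1, 1000, size=(100, 4))
        m = make_matrix(counts, n_cond=2)
        sf = ds.size_factors(m).to_numpy()
        # brute force straight from the definition
        geo = np.exp(np.mean(np.log(counts), axis=1))
        raw = np.array([np.median(counts[:, j] / geo) for j in range(4)])
        expected = raw / np.exp(np.mean(np.log(raw)))
        assert np.allclose(sf, expected, atol=1e-12)

    def test_geometric_mean_is_one(self, rng):
        counts = rng.integers(1, 500, size=(60, 6))
        sf = ds.size_factors(make_matrix(counts, n_cond=3))
        assert np.isclose(np.exp(np.mean(np.log(sf))), 1.0, atol=1e-12)

    def test_no_all_positive_feature_errors_without_fallback(self):
        m = make_matrix([[5, 0], [0, 5]])
        with pytest.raises(ValueError, match="pseudo_reference"):
            ds.size_factors(m)
        sf = ds.size_factors(m, pseudo_reference=True)
        assert (sf > 0).all()


class TestEstimateDispersions:
    def test_poisson_counts_get_near_zero_dispersion(self, rng):
        mu = rng.lognormal(np.log(500), 0.5, size=2000)
        counts = rng.poisson(mu[:, None], size=(2000, 6))
        m = make_matrix(counts, n_cond=2)
        sf = ds.size_factors(m)
        params = ds.estimate_dispersions(m, sf, cells=["a"] * 3 + ["b"] * 3)
        assert float(params.dispersion.median()) <= 0.01

    def test_nb_dispersion_recovered(self, rng):
        alpha = 0.1
        mu = rng.lognormal(np.log(500), 0.5, size=2000)
        lam = rng.gamma(1 / alpha, alpha * mu[:, None], size=(2000, 6))
        counts = rng.poisson(lam)
        m = make_matrix(counts, n_cond=2)
        sf = ds.size_factors(m)
        params = ds.estimate_dispersions(m, sf, cells=["a"] * 3 + ["b"] * 3)
        assert 0.05 <= float(params.dispersion.median()) <= 0.2

    def test_constant_feature_has_zero_raw_dispersion(self):
        m = make_matrix(np.vstack([[50, 50, 50, 50]] * 12), n_cond=2)
        sf = pd.Series(1.0, index=m.columns)
        params = ds.estimate_dispersions(m, sf, cells=["a", "a", "b", "b"])
        assert float(params.raw_dispersion.iloc[0]) == 0.0

    def test_few_usable_features_falls_back_with_warning(self):
        m = make_matrix(np.vstack([[50, 50, 50, 50]] * 12), n_cond=2)
        sf = pd.Series(1.0, index=m.columns)
        with pytest.warns(RuntimeWarning, match="median dispersion"):
            ds.estimate_dispersions(m, sf, cells=["a", "a", "b", "b"])


class TestNbWald:
    def test_null_identity_when_groups_identical(self):
        counts = np.tile([[40, 55, 62, 40, 55, 62]], (5, 1))
        m = make_matrix(counts, n_cond=2)
        sf = pd.Series(1.0, index=m.columns)
        params = ds.NBModelParams(size_factors=sf,
                                  dispersion=pd.Series(0.05, index=m.index),
                                  trend=(0.0, 0.0))
        design = ds.DesignSpec(kind="condition_effect", condition_test="cond1",
                               condition_ref="cond0", channel="red")
        res = ds.nb_wald(m, params, design)
        assert np.allclose(res["log2FC"], 0.0, atol=1e-8)
        assert (res["pvalue"] >= 0.99).all()

    def test_two_group_effect_recovered(self, rng):
        """Planted log2FC of 2 at mean 500, alpha 0.05: mean estimate ~2."""
        F = 200
        mu0 = np.full(F, 500.0)
        alpha = 0.05
        lam0 = rng.gamma(1 / alpha, alpha * mu0[:, None], size=(F, 3))
        lam1 = rng.gamma(1 / alpha, alpha * (4 * mu0)[:, None], size=(F, 3))
        counts = np.hstack([rng.poisson(lam0), rng.poisson(lam1)])
        m = make_matrix(counts, n_cond=2)
        sf = pd.Series(1.0, index=m.columns)
        params = ds.estimate_dispersions(m, sf, cells=["a"] * 3 + ["b"] * 3)
        design = ds.DesignSpec(kind="condition_effect", condition_test="cond1",
                               condition_ref="cond0", channel="red")
        res = ds.nb_wald(m, params, design)
        assert abs(float(res["log2FC"].mean()) - 2.0) <= 0.2

    def test_poisson_limit_matches_poisson_glm(self, rng):
        """With alpha ~ 0 and large counts the fit equals a Poisson GLM."""
        import statsmodels.api as sm
        counts = rng.poisson(2000, size=(20, 6))
        m = make_matrix(counts, n_cond=2)
        sf = pd.Series(1.0, index=m.columns)
        params = ds.NBModelParams(size_factors=sf,
                                  dispersion=pd.Series(1e-12, index=m.index),
                                  trend=(0.0, 0.0))
        design = ds.DesignSpec(kind="condition_effect", condition_test="cond1",
                               condition_ref="cond0", channel="red")
        res = ds.nb_wald(m, params, design)
        X = np.column_stack([np.ones(6), [0, 0, 0, 1, 1, 1]])
        for i in range(20):
            fit = sm.GLM(counts[i], X, family=sm.families.Poisson()).fit()
            assert np.isclose(res["log2FC"].iloc[i], fit.params[1] / np.log(2),
                              atol=1e-3)

    def test_all_zero_feature_gets_na(self):
        counts = np.vstack([[0, 0, 0, 0, 0, 0], [10, 12, 9, 11, 10, 13]])
        m = make_matrix(counts, n_cond=2)
        sf = pd.Series(1.0, index=m.columns)
        params = ds.NBModelParams(size_factors=sf,
                                  dispersion=pd.Series(0.05, index=m.index),
                                  trend=(0.0, 0.0))
        design = ds.DesignSpec(kind="condition_effect", condition_test="cond1",
                               condition_ref="cond0", channel="red")
        res = ds.nb_wald(m, params, design)
        assert np.isnan(res["pvalue"].iloc[0])
        assert np.isfinite(res["pvalue"].iloc[1])

    def test_rank_deficient_design_rejected(self):
        m = make_matrix([[5, 6, 7]], conditions=["a", "a", "a"])
        sf = pd.Series(1.0, index=m.columns)
        params = ds.NBModelParams(size_factors=sf,
                                  dispersion=pd.Series(0.0, index=m.index),
                                  trend=(0.0, 0.0))
        with pytest.raises(ValueError):
            ds.nb_wald(m, params, ds.DesignSpec(
                kind="condition_effect", condition_test="a",
                condition_ref="a", channel="red"))

    def test_baseline_offset_removes_pair_bias(self, rng):
        """Planted per-feature red:ir biases vanish when the baseline enters."""
        F = 300
        beta0 = rng.normal(0, 1.0, size=F)
        mu = 800.0
        red = rng.poisson(mu * 2.0 ** beta0[:, None], size=(F, 3))
        ir = rng.poisson(mu, size=(F, 3))
        m = make_paired_matrix(red, ir, ["c0", "c0", "c0"])
        sf = pd.Series(1.0, index=m.columns)
        params = ds.NBModelParams(size_factors=sf,
                                  dispersion=pd.Series(1e-8, index=m.index),
                                  trend=(0.0, 0.0))
        design = ds.DesignSpec(kind="channel_ratio", condition=None)
        naked = ds.nb_wald(m, params, design)
        baseline = pd.DataFrame({"beta0": beta0, "se": 0.0}, index=m.index)
        corrected = ds.nb_wald(m, params, design, baseline=baseline)
        assert float(np.abs(naked["log2FC"]).mean()) > 0.5
        assert float(np.abs(corrected["log2FC"]).mean()) <= 0.1


class TestBHAdjust:
    def test_single_p(self):
        assert ds.bh_adjust([0.03]) == pytest.approx([0.03])

    def test_closed_form_step_up(self):
        out = ds.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_random_vectors_match_brute_force_definition(self, rng):
        for _ in range(20):
            p = rng.random(size=rng.integers(1, 40))
            got = ds.bh_adjust(p)
            m = len(p)
            order = np.argsort(p)
            expected = np.empty(m)
            for rank_pos, i in enumerate(order):
                candidates = [min(1.0, p[order[k]] * m / (k + 1))
                              for k in range(rank_pos, m)]
                expected[i] = min(candidates)
            assert np.allclose(got, expected, atol=1e-12)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        p = rng.random(200)
        assert np.allclose(ds.bh_adjust(p),
                           multipletests(p, method="fdr_bh")[1], atol=1e-12)

    def test_na_passthrough(self):
        out = ds.bh_adjust([0.01, np.nan, 0.5])
        assert np.isnan(out[1])
        assert out[0] == pytest.approx(0.02)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            ds.bh_adjust([1.2])


class TestCallHits:
    @pytest.fixture()
    def results(self):
        return pd.DataFrame({
            "log2FC": [-2.0, 1.0, 3.0],
            "padj": [0.009, 0.009, 0.02],
        }, index=["a", "b", "c"])

    def test_rule_application(self, results):
        out = ds.call_hits(results, alpha=0.01, lfc_threshold=1.5)
        assert out.loc["a", "hit"] and out.loc["a", "direction"] == "down"
        assert out.loc["b", "significant"] and not out.loc["b", "hit"]
        assert not out.loc["c", "significant"] and not out.loc["c", "hit"]

    def test_requires_padj(self):
        with pytest.raises(ValueError, match="padj"):
            ds.call_hits(pd.DataFrame({"log2FC": [1.0]}))


class TestEstimateBaseline:
    def test_symmetric_control_centers_at_zero(self, rng):
        F = 400
        mu = rng.lognormal(np.log(600), 0.3, size=F)
        red = rng.poisson(mu[:, None], size=(F, 3))
        ir = rng.poisson(mu[:, None], size=(F, 3))
        m = make_paired_matrix(red, ir, ["c0", "c0", "c0"])
        table, excluded = ds.estimate_baseline(m)
        assert excluded == []
        assert abs(float(table["beta0"].mean())) <= 0.05

    def test_planted_eightfold_bias_recovered(self, rng):
        F = 200
        mu = np.full(F, 800.0)
        bias = np.zeros(F)
        bias[0] = 3.0  # an 8-fold differentially expressed pair
        red = rng.poisson(mu * 2.0 ** bias)[:, None] * np.ones(3, dtype=int)
        red = rng.poisson(mu[:, None] * 2.0 ** bias[:, None], size=(F, 3))
        ir = rng.poisson(mu[:, None], size=(F, 3))
        m = make_paired_matrix(red, ir, ["c0", "c0", "c0"])
        table, _ = ds.estimate_baseline(m)
        assert table["beta0"].iloc[0] == pytest.approx(3.0, abs=0.3)
        assert abs(float(table["beta0"].iloc[1:].mean())) <= 0.05

    def test_single_channel_features_excluded(self, rng):
        red = rng.poisson(500, size=(5, 2))
        ir = rng.poisson(500, size=(5, 2))
        ir[0] = 0
        m = make_paired_matrix(red, ir, ["c0", "c0"])
        table, excluded = ds.estimate_baseline(m)
        assert excluded == ["f0"]
        assert "f0" not in table.index

    def test_empty_control_errors(self):
        with pytest.raises(ValueError):
            ds.estimate_baseline(pd.DataFrame())


class TestInteractionContrast:
    def test_ratio_change_between_conditions_recovered(self, rng):
        """A construct whose red:ir ratio drops 4-fold upon induction shows
        an interaction log2FC near -2, regardless of a static pair bias."""
        F = 60
        bias = rng.normal(0, 0.5, size=F)      # static red:ir bias, both conditions
        effect = np.zeros(F)
        effect[:10] = -2.0                      # induced-only ratio change
        mu = 1500.0
        red_u = rng.poisson(mu * 2.0 ** bias[:, None], size=(F, 3))
        ir_u = rng.poisson(mu, size=(F, 3))
        red_i = rng.poisson(mu * 2.0 ** (bias + effect)[:, None], size=(F, 3))
        ir_i = rng.poisson(mu, size=(F, 3))
        m = make_paired_matrix(np.hstack([red_u, red_i]), np.hstack([ir_u, ir_i]),
                               ["uninduced"] * 3 + ["induced"] * 3)
        sf = pd.Series(1.0, index=m.columns)
        params = ds.NBModelParams(size_factors=sf,
                                  dispersion=pd.Series(1e-8, index=m.index),
                                  trend=(0.0, 0.0))
        design = ds.DesignSpec(kind="interaction", condition_test="induced",
                               condition_ref="uninduced")
        res = ds.nb_wald(m, params, design)
        assert np.allclose(res["log2FC"].iloc[:10], -2.0, atol=0.25)
        assert np.abs(res["log2FC"].iloc[10:]).mean() <= 0.1
        res["padj"] = ds.bh_adjust(res["pvalue"].to_numpy())
        hits = ds.call_hits(res, alpha=0.01, lfc_threshold=1.5)
        assert hits["hit"].iloc[:10].all()
        assert not hits["hit"].iloc[10:].any()
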