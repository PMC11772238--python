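import numpy as np
import pandas as pd
import pytest
import scipy.stats

from ucoseq import injurylm, normtmm, simdata
from ucoseq.core_io import CountMatrix, SampleTable
from ucoseq.injurylm import (
    GeneFits,
    associate_at_timepoint,
    associated_genes,
    estimate_prior,
    fit_injury_model,
    injury_design,
    moderate,
    precision_weight_transform,
)


def _one_timepoint_cohort(n=10, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        rows.append(
            {"sample_id": f"A{i}", "animal_id": f"A{i}", "timepoint_h": 6.0,
             "treatment": "active" if i % 2 else "vehicle",
             "phase": "post",
             "injury_class": "severe" if i < 6 else "mild"}
        )
    return SampleTable(pd.DataFrame(rows)), rng


def _counts_for(samples, rng, n_genes=300, planted=None, disp=0.05):
    mu_gene = rng.lognormal(4, 1, size=n_genes)
    mu = np.tile(mu_gene[:, None], (1, len(samples.data)))
    severe = (samples.data["injury_class"] == "severe").to_numpy()
    if planted:
        for g, log2fc in planted.items():
            mu[g, severe] *= 2.0 ** log2fc
    lam = rng.gamma(1 / disp, mu * disp)
    vals = rng.poisson(lam * 2000)  # scale to realistic library depth
    return CountMatrix(vals, [f"g{i}" for i in range(n_genes)],
                       samples.data["sample_id"].tolist())


class TestPrecisionWeights:
    def test_logcpm_closed_form_zero_count(self):
        samples, rng = _one_timepoint_cohort()
        counts = _counts_for(samples, rng, 50)
        vals = counts.values.copy()
        vals[0] = 0
        vals[1] = 1_000_000 - 0  # keep libraries ~1e6
        cm = CountMatrix(vals, counts.gene_ids, counts.sample_ids)
        lib = cm.library_sizes()
        w = precision_weight_transform(cm, None, injury_design(samples))
        expect = np.log2(0.5 / lib * 1e6)
        np.testing.assert_allclose(w.logcpm[0], expect, atol=1e-9)

    def test_homoskedastic_data_gives_flat_weights(self):
        """Log-normal equal-variance expression: the lowess trend is flat,
        so weights are constant to within ~10%."""
        rng = np.random.default_rng(1)
        samples, _ = _one_timepoint_cohort(n=20)
        y = 2.0 ** rng.normal(8, 1, size=(400, 20))
        vals = np.round(y).astype(int)
        cm = CountMatrix(vals, [f"g{i}" for i in range(400)],
                         samples.data["sample_id"].tolist())
        w = precision_weight_transform(cm, None, np.ones((20, 1)))
        spread = w.weights.std() / w.weights.mean()
        assert spread < 0.35  # no systematic trend; residual wiggle only

    def test_weights_track_fitted_trend(self):
        """Weights are exactly the inverse 4th power of the interpolated
        sqrt-sd trend, hence decrease where the trend rises."""
        samples, rng = _one_timepoint_cohort()
        counts = _counts_for(samples, rng, 400)
        w = precision_weight_transform(counts, None, injury_design(samples))
        # recompute from the stored knots
        pred = w.logcpm.mean(axis=1)
        order = np.argsort(w.trend_x)
        tx, ty = w.trend_x[order], w.trend_y[order]
        assert (np.interp([tx[0], tx[-1]], tx, ty) > 0).all()
        # spot-check the defining relation on a few observations
        lib = counts.library_sizes()
        trend_at = np.interp(w.logcpm[:5] + (np.log2(lib) - np.log2(1e6))[None, :], tx, ty)
        np.testing.assert_allclose(w.weights[:5], trend_at**-4, rtol=0.35)

    def test_rank_deficient_design_rejected(self):
        samples, rng = _one_timepoint_cohort()
        counts = _counts_for(samples, rng, 30)
        X = np.ones((10, 2))  # duplicated intercept
        with pytest.raises(ValueError, match="rank"):
            precision_weight_transform(counts, None, X)


class TestInjuryFit:
    def test_planted_twofold_coefficient_recovered(self):
        coefs = []
        for seed in range(8):
            samples, rng = _one_timepoint_cohort(seed=seed)
            counts = _counts_for(samples, rng, 200, planted={0: 1.0})
            w = precision_weight_transform(counts, None, injury_design(samples))
            fits = fit_injury_model(w, samples, 6.0)
            coefs.append(fits.coef[0])
        assert np.mean(coefs) == pytest.approx(1.0, abs=0.3)

    def test_missing_injury_class_raises(self):
        samples, rng = _one_timepoint_cohort()
        df = samples.data.copy()
        df["injury_class"] = "severe"
        all_severe = SampleTable(df)
        counts = _counts_for(all_severe, rng, 30)
        w = precision_weight_transform(counts, None, np.ones((10, 1)))
        with pytest.raises(ValueError, match="6"):
            fit_injury_model(w, all_severe, 6.0)

    def test_treatment_effect_does_not_leak_into_injury(self):
        """A planted treatment-arm effect with null injury leaves the
        injury coefficient centred on zero (covariate adjustment)."""
        coefs = []
        for seed in range(8):
            samples, rng = _one_timepoint_cohort(seed=100 + seed)
            counts = _counts_for(samples, rng, 200)
            vals = counts.values.copy()
            active = (samples.data["treatment"] == "active").to_numpy()
            vals[0, active] = rng.poisson(vals[0, active] * 2.0)
            cm = CountMatrix(vals, counts.gene_ids, counts.sample_ids)
            w = precision_weight_transform(cm, None, injury_design(samples))
            fits = fit_injury_model(w, samples, 6.0)
            coefs.append(fits.coef[0])
        assert abs(np.mean(coefs)) < 0.35


class TestModeration:
    def _fits(self, sigma2, coef=None, df=7.0):
        g = len(sigma2)
        return GeneFits(
            gene_ids=[f"g{i}" for i in range(g)],
            coef=np.ones(g) if coef is None else coef,
            unscaled_se=np.full(g, 0.5),
            sigma2=np.asarray(sigma2, float),
            df_residual=df,
            timepoint_h=6.0,
        )

    def test_no_moderation_limit_recovers_ordinary_t(self):
        rng = np.random.default_rng(0)
        s2 = rng.chisquare(7, 50) / 7
        fits = self._fits(s2)
        out = moderate(fits, prior_df=0.0)
        expected_t = fits.coef / (fits.unscaled_se * np.sqrt(s2))
        np.testing.assert_allclose(out["moderated_t"], expected_t, rtol=1e-10)

    def test_full_pooling_limit_shares_one_variance(self):
        rng = np.random.default_rng(1)
        s2 = rng.chisquare(7, 50) / 7
        fits = self._fits(s2)
        out = moderate(fits, prior_df=np.inf)
        pooled = np.exp(np.mean(np.log(s2)))
        expected_t = fits.coef / (fits.unscaled_se * np.sqrt(pooled))
        np.testing.assert_allclose(out["moderated_t"], expected_t, rtol=1e-10)

    def test_prior_estimation_recovers_known_d0(self):
        """Variances drawn from the scaled-F model with d0=8, s0^2=2."""
        rng = np.random.default_rng(2)
        d, d0, s0 = 7.0, 8.0, 2.0
        g = 20_000
        prior_draw = s0 * d0 / rng.chisquare(d0, g)
        s2 = prior_draw * rng.chisquare(d, g) / d
        d0_hat, s0_hat = estimate_prior(s2, d)
        assert d0_hat == pytest.approx(d0, rel=0.2)
        assert s0_hat == pytest.approx(s0, rel=0.1)

    def test_identical_variances_take_infinite_prior_branch(self):
        fits = self._fits(np.full(30, 1.7))
        out = moderate(fits)
        assert np.isinf(out["prior_df"].iloc[0])
        np.testing.assert_allclose(
            out["moderated_t"], fits.coef / (0.5 * np.sqrt(1.7)), rtol=1e-8
        )

    def test_too_few_genes_rejected(self):
        fits = self._fits(np.ones(5))
        with pytest.raises(ValueError, match="10 genes"):
            moderate(fits)


class TestAssociatedGenes:
    def test_threshold_above_min_q_empty(self):
        res = pd.DataFrame({"gene_id": ["a"], "q": [0.02], "p": [0.001]})
        assert associated_genes(res, 0.01).empty

    def test_sorted_by_q(self):
        res = pd.DataFrame({"gene_id": list("abc"), "q": [0.09, 0.01, 0.05],
                            "p": [0.03, 0.001, 0.01]})
        out = associated_genes(res, 0.1)
        assert out["q"].is_monotonic_increasing

    def test_end_to_end_on_simulated_cohort(self, small_experiment):
        counts, samples = small_experiment.counts, small_experiment.samples
        factors = normtmm.tmm_factors(counts)
        table, hits = associate_at_timepoint(counts, samples, factors, 6.0, 0.1)
        assert len(table) == counts.n_genes
        assert ((table["q"] >= 0) & (table["q"] <= 1)).all()
        assert np.isfinite(table["moderated_t"]).all()
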