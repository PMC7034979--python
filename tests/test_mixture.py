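import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from txstate.io import AbundanceMatrix, SampleMetadata
from txstate.mixture import (
    GlobalComponents,
    MixtureConfig,
    assign_cv_folds,
    augment_with_dummies,
    classify_unimodal,
    crossvalidated_elpd,
    elpd_from_draw_likelihoods,
    fit_gene,
    global_components,
    infer_expression_probabilities,
    log_transform,
    posterior_on_probability,
    select_model,
)

FAST = MixtureConfig(chains=2, iters=200, seed=1)


class TestLogTransform:
    def test_closed_forms(self):
        np.testing.assert_allclose(log_transform([np.exp(3.0)]), [3.0])
        np.testing.assert_allclose(log_transform([0.0], floor=0.01), [np.log(0.01)])
        # exp(3) ~ 21 TPM: a 21-TPM observation lands just above 3 on the log scale
        assert log_transform([21.0])[0] == pytest.approx(3.0445, abs=1e-4)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            log_transform([-1.0])


class TestPosteriorOnProbability:
    def test_symmetric_midpoint_returns_prior_weight(self):
        # equal component densities at the midpoint: posterior = mixing weight
        for pi, expected in [(0.5, 0.5), (0.8, 0.8)]:
            p = posterior_on_probability([3.0], mu_off=1, mu_on=5, sigma=1, pi=pi)
            assert p == pytest.approx(expected, abs=1e-12)

    def test_two_replicates_multiply_likelihood_ratios(self):
        # each observation has on/off likelihood ratio 4 -> odds 16 -> 16/17
        y = 3.0 + np.log(4.0) / 4.0  # slope (mu_on-mu_off)/sigma^2 = 4
        p = posterior_on_probability([y, y], mu_off=1, mu_on=5, sigma=1, pi=0.5)
        assert p == pytest.approx(16 / 17, abs=1e-12)

    def test_empty_observations_rejected(self):
        with pytest.raises(ValueError):
            posterior_on_probability([], mu_off=1, mu_on=5, sigma=1, pi=0.5)

    def test_extreme_observations_stay_finite(self):
        # +-30 sigma from the components must not overflow to nan
        lo = posterior_on_probability([1 - 30.0], mu_off=1, mu_on=5, sigma=1, pi=0.5)
        hi = posterior_on_probability([5 + 30.0], mu_off=1, mu_on=5, sigma=1, pi=0.5)
        assert 0.0 <= lo <= 1.0 and 0.0 <= hi <= 1.0
        assert lo < 1e-6 and hi > 1 - 1e-6

    @given(
        mu_off=st.floats(-2, 4),
        gap=st.floats(0.1, 8),
        sigma=st.floats(0.05, 3),
        pi=st.floats(0.01, 0.99),
        y1=st.floats(-10, 15),
        step=st.floats(0.01, 5),
    )
    def test_monotone_in_abundance(self, mu_off, gap, sigma, pi, y1, step):
        """Shared sigma guarantees P(on) is non-decreasing in abundance."""
        p1 = posterior_on_probability([y1], mu_off=mu_off, mu_on=mu_off + gap, sigma=sigma, pi=pi)
        p2 = posterior_on_probability([y1 + step], mu_off=mu_off, mu_on=mu_off + gap, sigma=sigma, pi=pi)
        assert p2 >= p1 - 1e-12


class TestElpd:
    def test_single_draw_reduces_to_log_likelihood(self):
        assert elpd_from_draw_likelihoods([0.37]) == pytest.approx(np.log(0.37), abs=1e-12)

    def test_two_draw_closed_form(self):
        got = elpd_from_draw_likelihoods([1.0, np.exp(-2.0)])
        assert got == pytest.approx(np.log((1 + np.exp(-2)) / 2), abs=1e-12)

    def test_fold_additivity_is_exact(self):
        rng = np.random.default_rng(4)
        y = np.concatenate([rng.normal(1, 0.5, 5), rng.normal(5, 0.5, 5)])
        res = crossvalidated_elpd(y, "unimodal", k=5, config=FAST)
        assert res.elpd_hat == np.sum(res.fold_elpd)
        assert res.elpd_hat == pytest.approx(np.nansum(res.pointwise), abs=1e-12)

    def test_negative_one_folds_never_held_out(self):
        y = np.linspace(0, 5, 12)
        folds = np.array([-1, -1] + list(np.arange(10) % 5))
        res = crossvalidated_elpd(y, "unimodal", k=5, config=FAST, folds=folds)
        assert np.isnan(res.pointwise[:2]).all()
        assert np.isfinite(res.pointwise[2:]).all()


class TestSelectModel:
    @pytest.mark.parametrize(
        "diffs, expected",
        [
            (np.full(10, 1.0), "bimodal"),  # delta 10, zero variance
            (np.array([0.3] * 5 + [0.3] * 5) + np.array([0.6, -0.6] * 5), "unimodal"),
            (np.full(10, -0.5), "unimodal"),  # bimodal worse
        ],
    )
    def test_two_se_rule(self, diffs, expected):
        uni = np.zeros(10)
        sel = select_model(uni + diffs, uni)
        k = len(diffs)
        se = np.sqrt(k * diffs.var(ddof=1))
        assert sel.delta_elpd == pytest.approx(diffs.sum())
        assert sel.se_delta == pytest.approx(se)
        assert sel.choice == expected
        assert (sel.choice == "bimodal") == (sel.delta_elpd > 2 * se)

    def test_mismatched_folds_rejected(self):
        with pytest.raises(ValueError, match="fold"):
            select_model(np.zeros(10), np.zeros(8))
        a = pd.Series(np.zeros(3), index=[0, 1, 2])
        b = pd.Series(np.zeros(3), index=[0, 1, 5])
        with pytest.raises(ValueError, match="fold"):
            select_model(a, b)


class TestFitGene:
    def test_recovers_generating_parameters(self):
        rng = np.random.default_rng(11)
        z = rng.random(30) < 0.5
        y = np.where(z, rng.normal(7, 0.5, 30), rng.normal(2, 0.5, 30))
        fit = fit_gene(y, "bimodal", FAST)
        means, sds = fit.posterior_means, fit.posterior_sds
        for name, truth in [("mu_off", 2.0), ("mu_on", 7.0), ("sigma", 0.5), ("pi", 0.5)]:
            assert abs(means[name] - truth) < 3 * max(sds[name], 0.05), name

    def test_ordered_constraint_in_every_draw(self):
        rng = np.random.default_rng(2)
        y = np.concatenate([rng.normal(1, 0.3, 10), rng.normal(6, 0.3, 10)])
        fit = fit_gene(y, "bimodal", FAST)
        assert (fit.draws.params["mu_off"] <= fit.draws.params["mu_on"]).all()

    def test_identical_observations(self):
        y = np.full(10, 4.2)
        uni = fit_gene(y, "unimodal", FAST)
        assert uni.posterior_means["mu"] == pytest.approx(4.2, abs=0.1)
        bim = fit_gene(y, "bimodal", FAST)
        assert bim.diagnostics["degenerate"]

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            fit_gene([1.0, 2.0, 3.0], "bimodal", FAST)

    def test_default_sampler_configuration(self):
        # defaults mirror 4 chains x 500 iterations, >= 500 retained draws
        cfg = MixtureConfig()
        assert (cfg.chains, cfg.iters) == (4, 500)
        rng = np.random.default_rng(5)
        y = rng.normal(3, 0.5, 12)
        fit = fit_gene(y, "unimodal", cfg)
        assert fit.diagnostics["n_draws"] >= 500


class TestGlobalComponents:
    def test_toy_pools(self):
        y = np.array([[7.0] * 6 + [2.0] * 4])
        probs = np.array([[0.95] * 6 + [0.05] * 4])
        glob = global_components(y, probs, np.array([12.0]))
        assert glob.mu_on_glob == pytest.approx(7.0)
        assert glob.mu_off_glob == pytest.approx(2.0)
        assert glob.pi_glob == pytest.approx(0.6)

    def test_no_qualifying_genes_instructs_relaxing(self):
        y = np.array([[7.0, 2.0]])
        probs = np.array([[0.95, 0.05]])
        with pytest.raises(ValueError, match="relax"):
            global_components(y, probs, np.array([3.0]))  # delta below 10

    def test_pooled_recovery_on_synthetic_two_component_data(self, rng):
        on = rng.normal(6.0, 0.4, 400)
        off = rng.normal(1.0, 0.6, 600)
        y = np.concatenate([on, off]).reshape(1, -1)
        probs = np.concatenate([np.full(400, 0.99), np.full(600, 0.01)]).reshape(1, -1)
        glob = global_components(y, probs, np.array([50.0]))
        assert glob.mu_on_glob == pytest.approx(6.0, abs=2 * 0.4 / np.sqrt(400))
        assert glob.mu_off_glob == pytest.approx(1.0, abs=2 * 0.6 / np.sqrt(600))
        assert glob.pi_glob == pytest.approx(0.4)


class TestClassifyUnimodal:
    GLOB = GlobalComponents(mu_on_glob=6.0, sigma_on_glob=1.0, mu_off_glob=2.0, sigma_off_glob=1.0, pi_glob=0.5)

    def test_midpoint_symmetry(self):
        assert classify_unimodal(4.0, self.GLOB) == pytest.approx(0.5, abs=1e-12)

    def test_at_on_mean_with_four_sigma_separation(self):
        assert classify_unimodal(6.0, self.GLOB) == pytest.approx(1 / (1 + np.exp(-8)), abs=1e-9)

    def test_midpoint_with_prior_weight(self):
        glob = GlobalComponents(6.0, 1.0, 2.0, 1.0, pi_glob=0.8)
        assert classify_unimodal(4.0, glob) == pytest.approx(0.8, abs=1e-12)


class TestAugmentWithDummies:
    def test_dissected_extremes_outflank_catalog(self):
        aug, mask = augment_with_dummies([5.0, 7.0], [2.0, 100.0])
        np.testing.assert_array_equal(aug, [5, 7, 2, 100])
        np.testing.assert_array_equal(mask, [False, False, True, True])

    def test_dissected_inside_catalog_range_duplicates_extremes(self):
        aug, _ = augment_with_dummies([5.0, 7.0], [5.5])
        np.testing.assert_array_equal(aug[-2:], [5, 7])

    def test_no_dissected_uses_catalog_extremes(self):
        aug, _ = augment_with_dummies([5.0, 6.0, 7.0])
        np.testing.assert_array_equal(aug[-2:], [5, 7])

    def test_empty_catalog_rejected(self):
        with pytest.raises(ValueError):
            augment_with_dummies([], [1.0])


class TestFoldAssignment:
    def test_replicates_spread_and_singletons_kept_in_training(self, rng):
        rows = []
        for d in range(6):
            n_rep = 1 if d == 0 else 3
            for r in range(1, n_rep + 1):
                rows.append((f"d{d}_r{r}", f"d{d}", f"c{d % 3}", r, "cell_catalog"))
        meta = SampleMetadata(pd.DataFrame(rows, columns=["sample_id", "driver_id", "cell_type_id", "replicate", "sample_class"]))
        folds = assign_cv_folds(meta, k=5, rng=rng)
        assert folds["d0_r1"] == -1  # sole replicate, never held out
        for d in range(1, 6):
            assigned = folds[[f"d{d}_r{r}" for r in range(1, 4)]]
            assert assigned.nunique() == 3  # distinct folds per driver


class TestInferencePipeline:
    def test_single_replicate_driver_equals_sample_probability(self):
        """Driver-level aggregation with one replicate is the sample value."""
        rng = np.random.default_rng(9)
        genes = [f"g{i}" for i in range(12)]
        z = rng.random((12, 10)) < 0.5
        values = np.exp(np.where(z, rng.normal(6, 0.4, (12, 10)), rng.normal(1, 0.4, (12, 10))))
        samples, rows = [], []
        for d in range(5):
            for r in (1, 2):
                samples.append(f"d{d}_r{r}")
                rows.append((f"d{d}_r{r}", f"d{d}", f"c{d}", r, "cell_catalog"))
        samples.append("solo_r1")
        rows.append(("solo_r1", "solo", "c_solo", 1, "cell_catalog"))
        values = np.concatenate([values, np.exp(rng.normal(3, 1, (12, 1)))], axis=1)
        matrix = AbundanceMatrix(pd.DataFrame(values, index=genes, columns=samples))
        meta = SampleMetadata(pd.DataFrame(rows, columns=["sample_id", "driver_id", "cell_type_id", "replicate", "sample_class"]))
        res = infer_expression_probabilities(matrix, meta, MixtureConfig(chains=2, iters=200, folds=5, seed=2))
        bimodal = res.fits["model"] == "bimodal"
        assert bimodal.any()
        pd.testing.assert_series_equal(
            res.driver_probs.loc[bimodal, "solo"],
            res.sample_probs.loc[bimodal, "solo_r1"],
            check_names=False,
        )
        # cell with a single driver: cell level equals driver level
        pd.testing.assert_series_equal(
            res.cell_probs.loc[bimodal, "c_solo"],
            res.driver_probs.loc[bimodal, "solo"],
            check_names=False,
        )

    def test_same_seed_reproduces_output_exactly(self, small_catalog):
        cfg = MixtureConfig(chains=2, iters=100, folds=4, seed=42)
        a = infer_expression_probabilities(small_catalog.matrix, small_catalog.metadata, cfg)
        b = infer_expression_probabilities(small_catalog.matrix, small_catalog.metadata, cfg)
        pd.testing.assert_frame_equal(a.cell_probs, b.cell_probs)
        pd.testing.assert_frame_equal(a.fits, b.fits)

    def test_probabilities_within_unit_interval(self, small_inference):
        for level in ("sample", "driver", "cell"):
            p = small_inference.probabilities(level).to_numpy()
            finite = p[np.isfinite(p)]
            assert ((finite >= 0) & (finite <= 1)).all()

    def test_dissected_samples_scored_not_fit(self, small_inference, small_catalog):
        dis = small_catalog.metadata.dissected_samples()
        assert list(small_inference.dissected_probs.columns) == dis
        assert not set(dis) & set(small_inference.sample_probs.columns)

    def test_fit_table_reports_selection_diagnostics(self, small_inference):
        fits = small_inference.fits
        assert {"model", "delta_elpd", "se_delta", "mu_off", "mu_on"} <= set(fits.columns)
        chosen = fits.loc[fits["model"] == "bimodal"]
        assert (chosen["delta_elpd"] > 2 * chosen["se_delta"]).all()
        assert (fits.loc[fits["model"] != "failed", "mu_off"] <= fits.loc[fits["model"] != "failed", "mu_on"]).all()
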