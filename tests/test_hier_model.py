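import math

import numpy as np
import pytest
from scipy import integrate, stats
from scipy.special import polygamma

from bitescope.hier_model import (
    MCMCConfig, ModelSpec, PosteriorSummary, build_design, contrasts,
    diagnostics, duration_effect, effective_sample_size,
    expected_severity_draws, fit, hdi, icc, log_likelihood, split_rhat,
)
from bitescope.simulate import VideoSimConfig, simulate_videos
from conftest import make_record

FULL = ModelSpec(True, True, True, True)


class TestBuildDesign:
    def test_baseline_columns(self, record_factory):
        records = [
            record_factory(video_id=f"v{i}", dog_size=size, context=ctx,
                           interaction_duration_s=10.0 + i)
            for i, (size, ctx) in enumerate(
                zip(["small", "medium", "big", "small", "big"],
                    ["play", "benign", "play", "territorial", "benign"])
            )
        ]
        design = build_design(records, ModelSpec())
        assert design.columns == ["duration_z", "dog_size[medium]", "dog_size[big]"]
        assert design.X.shape == (5, 3)
        assert design.reference_levels == {"dog_size": "small"}

    def test_duration_standardised(self, study_scale_records):
        design = build_design(study_scale_records, ModelSpec())
        z = design.X[:, 0]
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_zero_variance_duration_rejected(self, record_factory):
        records = [
            record_factory(video_id=f"v{i}", dog_size=s, context=c,
                           interaction_duration_s=30.0)
            for i, (s, c) in enumerate([("small", "play"), ("big", "benign")])
        ]
        with pytest.raises(ValueError, match="duration"):
            build_design(records, ModelSpec())

    def test_missing_initiator_flagged_only_when_included(self, record_factory):
        records = [
            record_factory(video_id=f"v{i}", initiator=init, dog_size=s,
                           interaction_duration_s=10.0 + i, victim_sex=sex,
                           context=("play" if i % 2 else "benign"))
            for i, (init, s, sex) in enumerate(
                [("dog", "small", "male"), ("victim", "big", "female"),
                 ("missing", "medium", "male"), ("victim", "big", "female")]
            )
        ]
        with_init = build_design(records, ModelSpec(include_initiator=True))
        assert with_init.missing_initiator_rows.tolist() == [2]
        without = build_design(records, ModelSpec(include_victim_sex=True))
        assert without.missing_initiator_rows.size == 0
        assert without.initiator_column is None

    def test_single_level_categorical_rejected(self, record_factory):
        records = [
            record_factory(video_id=f"v{i}", dog_size="big",
                           context=("play" if i % 2 else "benign"),
                           interaction_duration_s=10.0 + i)
            for i in range(4)
        ]
        with pytest.raises(ValueError, match="dog_size"):
            build_design(records, ModelSpec())


class TestGammaLogLikelihood:
    def test_matches_scipy(self):
        for y, mu, s in [(5.0, 5.0, 2.0), (1.0, 3.0, 0.7), (12.0, 4.0, 5.0)]:
            expected = stats.gamma.logpdf(y, a=s, scale=mu / s)
            assert log_likelihood(y, mu, s) == pytest.approx(expected, abs=1e-12)

    def test_density_normalises(self):
        mu, s = 4.0, 2.5
        total, _ = integrate.quad(
            lambda y: math.exp(float(log_likelihood(y, mu, s))), 1e-9, 200
        )
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_shape_one_is_exponential(self):
        y, mu = 3.0, 2.0
        assert log_likelihood(y, mu, 1.0) == pytest.approx(
            stats.expon.logpdf(y, scale=mu), abs=1e-12
        )

    def test_positive_inputs_required(self):
        with pytest.raises(ValueError):
            log_likelihood(-1.0, 2.0, 1.0)
        with pytest.raises(ValueError):
            log_likelihood(1.0, 2.0, 0.0)


def brute_force_hdi(samples, mass=0.95):
    """Enumerate every candidate interval over the sorted draws."""
    x = np.sort(samples)
    n = len(x)
    m = math.ceil(mass * n)
    best = None
    for i in range(n - m + 1):
        width = x[i + m - 1] - x[i]
        if best is None or width < best[0]:
            best = (width, x[i], x[i + m - 1])
    return best[1], best[2]


class TestHDI:
    def test_uniform_grid(self):
        low, high = hdi(np.arange(101.0))
        assert high - low == pytest.approx(95.0, abs=1.0)

    def test_standard_normal_limits(self):
        rng = np.random.default_rng(42)
        draws = rng.standard_normal(200_000)
        low, high = hdi(draws)
        assert low == pytest.approx(-1.96, abs=0.03)
        assert high == pytest.approx(1.96, abs=0.03)

    def test_all_equal_zero_width(self):
        assert hdi([3.0, 3.0, 3.0]) == (3.0, 3.0)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            hdi([1.0])

    def test_matches_brute_force(self):
        rng = np.random.default_rng(7)
        for draws in (rng.gamma(2, 2, 500), rng.standard_normal(301), rng.random(97)):
            assert hdi(draws) == pytest.approx(brute_force_hdi(draws), abs=1e-12)

    def test_never_wider_than_equal_tailed(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            draws = rng.gamma(1.5, 3, 400)
            low, high = hdi(draws)
            lo_et, hi_et = np.percentile(draws, [2.5, 97.5])
            assert high - low <= hi_et - lo_et + 1e-9


class TestDiagnostics:
    def test_stationary_chains_rhat_near_one(self):
        rng = np.random.default_rng(0)
        chains = rng.standard_normal((4, 2000))
        rhat, ess = diagnostics(chains)
        assert rhat < 1.01
        assert ess > 2000  # independent draws: ESS near the draw count

    def test_shifted_chains_flag_divergence(self):
        rng = np.random.default_rng(1)
        chains = rng.standard_normal((2, 1000))
        chains[1] += 5.0
        assert split_rhat(chains) > 2.0

    def test_ar1_ess_matches_analytic_ratio(self):
        phi = 0.7
        rng = np.random.default_rng(2)
        n, m = 40_000, 2
        chains = np.empty((m, n))
        for c in range(m):
            e = rng.standard_normal(n)
            x = np.empty(n)
            x[0] = e[0] / math.sqrt(1 - phi**2)
            for t in range(1, n):
                x[t] = phi * x[t - 1] + e[t]
            chains[c] = x
        ess = effective_sample_size(chains)
        expected = m * n * (1 - phi) / (1 + phi)
        assert ess == pytest.approx(expected, rel=0.15)

    def test_matches_arviz(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(4)
        raw = rng.standard_normal((4, 3000))
        # mild autocorrelation so the comparison is non-trivial
        chains = raw.copy()
        for t in range(1, raw.shape[1]):
            chains[:, t] = 0.5 * chains[:, t - 1] + raw[:, t]
        data = az.convert_to_dataset(chains, group="posterior")
        az_ess = float(az.ess(data, method="mean")["x"])
        ours = effective_sample_size(chains)
        assert ours == pytest.approx(az_ess, rel=0.1)
        az_rhat = float(az.rhat(data)["x"])
        assert split_rhat(chains) == pytest.approx(az_rhat, abs=0.01)

    def test_wrong_shapes_rejected(self):
        with pytest.raises(ValueError):
            diagnostics(np.zeros(10))
        with pytest.raises(ValueError):
            split_rhat(np.zeros((1, 100)))


def _fake_posterior(sigma_draws, shape_draws, pooling="varying"):
    return PosteriorSummary(
        spec=ModelSpec(context_pooling=pooling),
        config=MCMCConfig(seed=0),
        design=None,
        draws={
            "sigma_alpha": np.asarray(sigma_draws, dtype=float).reshape(2, -1),
            "shape": np.asarray(shape_draws, dtype=float).reshape(2, -1),
        },
        summaries=[],
        log_lik=np.zeros((2, 1)),
        converged=True,
    )


class TestICC:
    def test_zero_between_context_variance(self):
        post = _fake_posterior([0.0] * 4, [2.0] * 4)
        assert icc(post)["mean"] == 0.0

    def test_large_sigma_limit(self):
        post = _fake_posterior([1e6] * 4, [2.0] * 4)
        assert icc(post)["mean"] == pytest.approx(1.0, abs=1e-9)

    def test_closed_form_sigma1_shape2(self):
        # trigamma(2) = pi^2/6 - 1
        post = _fake_posterior([1.0] * 4, [2.0] * 4)
        expected = 1.0 / (1.0 + (math.pi**2 / 6 - 1.0))
        assert icc(post)["mean"] == pytest.approx(expected, abs=1e-12)

    def test_undefined_for_fixed_effects(self):
        post = _fake_posterior([1.0] * 4, [2.0] * 4, pooling="fixed")
        with pytest.raises(ValueError):
            icc(post)


@pytest.fixture(scope="module")
def recovery_fit():
    """One fit of the full model on synthetic data with known parameters."""
    config = VideoSimConfig(n_videos=200, seed=314)
    records = simulate_videos(config)
    post = fit(records, FULL, MCMCConfig(chains=2, draws=1500, warmup=700, seed=99))
    return config, post


class TestFit:
    def test_parameter_recovery_within_3_posterior_sd(self, recovery_fit):
        config, post = recovery_fit
        truths = {
            "mu_alpha": config.true_mu_alpha,
            "sigma_alpha": config.true_sigma_alpha,
            "shape": config.true_shape,
        }
        for col in post.design.columns:
            truths[f"beta[{col}]"] = config.true_beta.get(col, 0.0)
        for name, truth in truths.items():
            s = post.summary(name)
            if name.startswith("beta["):
                j = post.design.columns.index(name[5:-1])
                sd = post.draws_flat("beta")[:, j].std(ddof=1)
            else:
                sd = post.draws_flat(name.split("[")[0]).std(ddof=1)
            assert abs(s.mean - truth) < 3 * sd, f"{name}: {s.mean} vs {truth}"

    def test_imputation_recovers_masking_proportion(self, recovery_fit):
        config, post = recovery_fit
        p_victim = config.covariate_probs["initiator_victim"]
        assert post.summary("p_init").mean == pytest.approx(p_victim, abs=0.12)

    def test_reproducible_given_seed(self, study_scale_records):
        cfg = MCMCConfig(chains=2, draws=100, warmup=100, seed=5)
        a = fit(study_scale_records, ModelSpec(), cfg)
        b = fit(study_scale_records, ModelSpec(), cfg)
        assert np.array_equal(a.draws["beta"], b.draws["beta"])
        assert np.array_equal(a.log_lik, b.log_lik)

    def test_summaries_carry_diagnostics_and_hdi(self, recovery_fit):
        _, post = recovery_fit
        for s in post.summaries:
            assert s.hdi_low <= s.mean <= s.hdi_high
            assert s.ess >= 0
            assert s.rhat > 0.9

    def test_null_data_shrinks_sigma_and_icc(self):
        config = VideoSimConfig(
            n_videos=200, seed=55, true_sigma_alpha=0.0,
            true_beta={}, missing_initiator_prob=0.0,
        )
        records = simulate_videos(config)
        post = fit(records, ModelSpec(), MCMCConfig(chains=2, draws=1200,
                                                    warmup=600, seed=8))
        assert post.summary("sigma_alpha").mean < 0.3
        assert icc(post)["hdi_low"] == pytest.approx(0.0, abs=0.01)
        # with no covariate effects the model-implied mean tracks the data mean
        sample_mean = np.mean(post.design.y)
        model_mean = np.mean(expected_severity_draws(post, at="mean"))
        assert model_mean == pytest.approx(sample_mean, rel=0.15)


class TestContrasts:
    def test_identity_contrast_is_zero(self, recovery_fit):
        _, post = recovery_fit
        (c,) = contrasts(post, [("victim_age", "child", "child")])
        assert c["mean"] == 0.0
        assert (c["hdi_low"], c["hdi_high"]) == (0.0, 0.0)
        assert not c["significant"]

    def test_known_effect_recovered_on_response_scale(self):
        # a strong multiple-site effect: exp(1.55+0.8) - exp(1.55) ~ +5.8 points
        config = VideoSimConfig(n_videos=250, seed=77)
        records = simulate_videos(config)
        post = fit(records, ModelSpec(include_bite_site=True),
                   MCMCConfig(chains=2, draws=1500, warmup=700, seed=21))
        (c,) = contrasts(post, [("bite_site", "multiple", "limbs")])
        truth = math.exp(config.true_mu_alpha + 0.8) - math.exp(config.true_mu_alpha)
        draws_sd = (c["hdi_high"] - c["hdi_low"]) / 3.92
        assert abs(c["mean"] - truth) < 3 * draws_sd

    def test_unknown_level_rejected(self, recovery_fit):
        _, post = recovery_fit
        with pytest.raises(ValueError):
            contrasts(post, [("victim_age", "elder", "adult")])
        with pytest.raises(ValueError):
            contrasts(post, [("location", "indoor", "outdoor")])


def test_duration_effect_labels_both_scales(recovery_fit):
    _, post = recovery_fit
    eff = duration_effect(post)
    assert set(eff) == {"sd_seconds", "multiplier", "slope_points"}
    # generating duration coefficient is 0.20 -> multiplier near exp(0.2)
    assert eff["multiplier"]["mean"] == pytest.approx(math.exp(0.20), abs=0.12)
    assert eff["multiplier"]["hdi_low"] <= eff["multiplier"]["mean"]


def test_prior_predictive_severity_is_positive_finite():
    rng = np.random.default_rng(0)
    beta = rng.standard_normal((1000, 5))
    x = rng.standard_normal(5)
    mu = np.exp(rng.normal(0, 10, 1000) + beta @ x)
    draws = rng.gamma(2.0, mu / 2.0)
    assert np.all(draws > 0) and np.all(np.isfinite(draws))
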