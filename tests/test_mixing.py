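import numpy as np
import pytest

from trophicniche import (
    AnalysisConfig,
    IsotopeRecord,
    SourceGroup,
    TrophicDiscrimination,
    correct_sources,
    credible_intervals,
    delta_from_ratio,
    fit_mixing_model,
)
from trophicniche.mixing import MixingPosterior, SourceMixingModel, split_rhat


def source(name, c, n, sd=0.1):
    return SourceGroup(
        name=name, guild=name,
        mean={"d13c": c, "d15n": n}, sd={"d13c": sd, "d15n": sd},
    )


ZERO_TDF = TrophicDiscrimination(
    mean={"d13c": 0.0, "d15n": 0.0}, sd={"d13c": 0.0, "d15n": 0.0}
)


def consumers(mean_c, mean_n, n=10, spread=0.05, seed=0):
    rng = np.random.default_rng(seed)
    return [
        IsotopeRecord(
            f"c{i}", "sp",
            mean_c + spread * rng.standard_normal(),
            mean_n + spread * rng.standard_normal(),
        )
        for i in range(n)
    ]


def fast_config(seed=0, **kw):
    kw.setdefault("mcmc_chains", 2)
    kw.setdefault("mcmc_iterations", 8000)
    kw.setdefault("mcmc_thin", 2)
    return AnalysisConfig(tdf=ZERO_TDF, rng_seed=seed, **kw)


class TestDeltaNotation:
    def test_sample_equal_to_standard_is_zero(self):
        assert delta_from_ratio(0.011, 0.011) == pytest.approx(0.0)

    @pytest.mark.parametrize("factor, expected", [(1.01, 10.0), (0.98, -20.0)])
    def test_per_mil_scaling(self, factor, expected):
        assert delta_from_ratio(factor * 0.0112, 0.0112) == pytest.approx(expected)

    def test_nonpositive_standard_rejected(self):
        with pytest.raises(ValueError):
            delta_from_ratio(0.01, 0.0)


class TestCorrectSources:
    def test_means_shift_by_tdf(self):
        tdf = TrophicDiscrimination(
            mean={"d13c": 2.2, "d15n": 2.6}, sd={"d13c": 0.1, "d15n": 0.2}
        )
        (out,) = correct_sources([source("c3", -27.0, 2.0)], tdf)
        assert out.mean["d13c"] == pytest.approx(-24.8)
        assert out.mean["d15n"] == pytest.approx(4.6)

    def test_zero_tdf_is_identity(self):
        src = source("s", -20.0, 5.0, sd=0.7)
        (out,) = correct_sources([src], ZERO_TDF)
        assert out == src

    def test_sds_add_in_quadrature(self):
        tdf = TrophicDiscrimination(
            mean={"d13c": 0.0, "d15n": 0.0}, sd={"d13c": 0.4, "d15n": 0.4}
        )
        (out,) = correct_sources([source("s", 0.0, 0.0, sd=0.3)], tdf)
        assert out.sd["d13c"] == pytest.approx(0.5)


class TestMixingModel:
    def test_consumers_on_a_source_pin_its_contribution(self):
        sources = [source("a", -30.0, 0.0), source("b", -10.0, 10.0)]
        post = fit_mixing_model(
            consumers(-30.0, 0.0), sources, fast_config(1), species="sp"
        )
        ci = credible_intervals(post)
        assert ci.set_index("source").loc["a", "lower"] > 0.9

    def test_midpoint_consumers_split_evenly(self):
        sources = [source("a", -30.0, 0.0, sd=0.5), source("b", -10.0, 10.0, sd=0.5)]
        post = fit_mixing_model(
            consumers(-20.0, 5.0, n=30, spread=0.3), sources, fast_config(2)
        )
        np.testing.assert_allclose(post.mean(), [0.5, 0.5], atol=0.05)

    def test_three_source_parameter_recovery(self):
        """Consumers drawn from the model's own likelihood at
        p* = (0.6, 0.3, 0.1) put p* inside every source's 95% CI."""
        from trophicniche.simulate import ScenarioConfig, generate_sources, simulate_blood

        scen = ScenarioConfig(
            species=("sp",), source_names=("a", "b", "c"),
            source_means={"a": (-30.0, 0.0), "b": (-10.0, 10.0),
                          "c": (-20.0, -8.0)},
            source_sd=0.2, residual_sd=(0.2, 0.2), tdf=ZERO_TDF,
            true_p={"sp": (0.6, 0.3, 0.1)}, n_consumers=40, rng_seed=5,
        )
        post = fit_mixing_model(
            simulate_blood(scen, generate_sources(scen)),
            generate_sources(scen), fast_config(3), species="sp",
        )
        ci = credible_intervals(post)
        p_true = np.array([0.6, 0.3, 0.1])
        assert ((p_true >= ci["lower"] - 1e-9) & (p_true <= ci["upper"] + 1e-9)).all()

    def test_draws_stay_on_simplex_and_midpoints_sane(self):
        sources = [source("a", -30.0, 0.0), source("b", -10.0, 10.0),
                   source("c", -25.0, 8.0)]
        post = fit_mixing_model(consumers(-22.0, 5.0, n=15), sources, fast_config(4))
        draws = post.draws
        assert (draws >= 0).all()
        np.testing.assert_allclose(draws.sum(axis=1), 1.0, atol=1e-9)
        assert (post.sigma > 0).all()
        ci = credible_intervals(post)
        assert 0.5 <= ci["midpoint"].sum() <= 1.5
        assert (ci["lower"] <= ci["upper"]).all()

    def test_determinism_under_fixed_seed(self):
        sources = [source("a", -30.0, 0.0), source("b", -10.0, 10.0)]
        cfg = fast_config(6, mcmc_iterations=2000)
        p1 = fit_mixing_model(consumers(-25.0, 3.0), sources, cfg, species="x")
        p2 = fit_mixing_model(consumers(-25.0, 3.0), sources, cfg, species="x")
        np.testing.assert_array_equal(p1.p, p2.p)

    def test_widening_tdf_sd_never_narrows_intervals(self):
        raw = [source("a", -30.0, 0.0, sd=0.3), source("b", -10.0, 10.0, sd=0.3)]
        data = consumers(-24.0, 3.0, n=20, spread=0.5, seed=8)
        widths = {}
        for label, sds in [("tight", (0.1, 0.2)), ("wide", (0.9, 1.0))]:
            tdf = TrophicDiscrimination(
                mean={"d13c": 2.2, "d15n": 2.6},
                sd={"d13c": sds[0], "d15n": sds[1]},
            )
            cfg = AnalysisConfig(tdf=tdf, rng_seed=9, mcmc_chains=2,
                                 mcmc_iterations=12000, mcmc_thin=2)
            post = fit_mixing_model(data, correct_sources(raw, tdf), cfg)
            ci = credible_intervals(post)
            widths[label] = (ci["upper"] - ci["lower"]).to_numpy()
        # Monte Carlo slack: a genuinely wider model may wobble by a hair
        assert (widths["wide"] >= widths["tight"] - 0.02).all()

    def test_too_few_sources_rejected(self):
        with pytest.raises(ValueError):
            SourceMixingModel([source("a", 0, 0)], fast_config())


class TestCredibleIntervals:
    def make_posterior(self, draws):
        draws = np.asarray(draws, float)[None, :, :]
        return MixingPosterior(
            species="sp", sources=tuple(f"s{k}" for k in range(draws.shape[-1])),
            p=draws, sigma=np.ones((1, draws.shape[1], 2)),
            acceptance=0.3, rhat=np.ones(draws.shape[-1]), converged=True,
        )

    def test_degenerate_posterior_collapses_interval(self):
        post = self.make_posterior(np.tile([0.2, 0.8], (1500, 1)))
        ci = credible_intervals(post)
        np.testing.assert_allclose(ci["lower"], ci["upper"])
        np.testing.assert_allclose(ci["midpoint"], [0.2, 0.8])

    def test_percentile_definition_on_uniform_stub(self):
        rng = np.random.default_rng(0)
        u = rng.random((20000, 1))
        post = self.make_posterior(np.concatenate([u, 1 - u], axis=1))
        ci = credible_intervals(post, level=0.95)
        assert ci["lower"].iloc[0] == pytest.approx(0.025, abs=0.01)
        assert ci["upper"].iloc[0] == pytest.approx(0.975, abs=0.01)

    def test_too_few_draws_instructs_longer_run(self):
        post = self.make_posterior(np.tile([0.5, 0.5], (200, 1)))
        with pytest.raises(ValueError, match="longer"):
            credible_intervals(post)


def test_split_rhat_detects_disagreeing_chains():
    rng = np.random.default_rng(0)
    mixed = rng.normal(size=(4, 400))
    stuck = mixed + np.array([[0.0], [0.0], [5.0], [5.0]])
    assert split_rhat(mixed) < 1.05
    assert split_rhat(stuck) > 1.5
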