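import numpy as np
import pytest
import scipy.stats as sps
from hypothesis import given, settings
from hypothesis import strategies as st

from scmforage.race import (
    LatencySample,
    analytic_preference,
    censored_latency_summary,
    predict_preference,
    race_trial,
)
from scmforage.stats import ecdf_score


def _combined_se(p, n_races, n_sample):
    """MC + finite-sample uncertainty of a race-probability estimate."""
    return np.sqrt(max(p * (1 - p), 1e-4) * (1.0 / n_races + 2.0 / n_sample))


class TestRaceTrial:
    def test_minimum_rule(self, rng):
        assert race_trial(0.5, 0.9, rng) == (0, 0.5)
        assert race_trial(0.9, 0.5, rng) == (1, 0.5)

    def test_tie_break_is_fair(self):
        wins = [
            race_trial(0.7, 0.7, np.random.default_rng(s))[0] for s in range(400)
        ]
        assert 0.4 < np.mean(wins) < 0.6
        assert all(race_trial(0.7, 0.7, np.random.default_rng(s))[1] == 0.7 for s in range(5))

    def test_nonpositive_latency_rejected(self, rng):
        with pytest.raises(ValueError):
            race_trial(0.0, 1.0, rng)
        with pytest.raises(ValueError):
            race_trial(1.0, -0.5, rng)

    def test_exponential_closed_form(self):
        # P(A wins) = rate_a / (rate_a + rate_b) = 1/3 for rates (1, 2)
        rng = np.random.default_rng(8)
        la = rng.exponential(1.0, 100_000)  # rate 1
        lb = rng.exponential(0.5, 100_000)  # rate 2
        p = np.mean(la < lb)
        assert p == pytest.approx(1 / 3, abs=3 * np.sqrt(p * (1 - p) / 100_000))


class TestPredictPreference:
    def test_identical_samples_near_half(self):
        lat = np.array([0.4, 0.5, 0.6, 0.8, 1.1])
        pred = predict_preference(
            LatencySample("x", lat), LatencySample("y", lat.copy()), 96, 2000, seed=3
        )
        assert abs(pred.preference["x"] - 0.5) < 3 * max(pred.mc_se, 1e-4)

    def test_disjoint_supports_certain(self):
        pred = predict_preference(
            LatencySample("fast", [0.4, 0.5]),
            LatencySample("slow", [0.6, 0.7]),
            50,
            200,
            seed=1,
        )
        assert pred.preference["fast"] == 1.0
        assert pred.preference["slow"] == 0.0
        assert pred.mc_sd == 0.0

    def test_normalization_per_experiment(self):
        rng = np.random.default_rng(2)
        pred = predict_preference(
            LatencySample("a", rng.exponential(1.0, 500)),
            LatencySample("b", rng.exponential(0.7, 500)),
            96,
            500,
            seed=4,
        )
        assert pred.preference["a"] + pred.preference["b"] == pytest.approx(1.0)
        assert np.all((0 <= pred.per_experiment) & (pred.per_experiment <= 1))
        total = sum(len(v) for v in pred.winner_latencies.values())
        assert total == 500 * 96  # every race has exactly one winner

    def test_matches_exponential_oracle(self):
        rng = np.random.default_rng(5)
        m = 50_000
        pred = predict_preference(
            LatencySample("a", rng.exponential(1.0, m)),
            LatencySample("b", rng.exponential(0.5, m)),
            96,
            10_000,
            seed=6,
        )
        p = pred.preference["a"]
        assert abs(p - 1 / 3) < 3 * _combined_se(p, 96 * 10_000, m)

    def test_matches_lognormal_quadrature(self):
        rng = np.random.default_rng(7)
        m = 50_000
        da, db = sps.lognorm(s=0.6, scale=0.8), sps.lognorm(s=0.9, scale=1.1)
        target = analytic_preference(da, db)
        pred = predict_preference(
            LatencySample("a", da.rvs(m, random_state=rng)),
            LatencySample("b", db.rvs(m, random_state=rng)),
            96,
            4000,
            seed=8,
        )
        p = pred.preference["a"]
        assert abs(p - target) < 3 * _combined_se(p, 96 * 4000, m)

    def test_child_streams_extend_not_perturb(self):
        rng = np.random.default_rng(9)
        a = LatencySample("a", rng.exponential(1.0, 100))
        b = LatencySample("b", rng.exponential(1.0, 100))
        short = predict_preference(a, b, 20, 50, seed=11)
        long = predict_preference(a, b, 20, 150, seed=11)
        assert np.array_equal(short.per_experiment, long.per_experiment[:50])

    def test_upward_shift_cannot_increase_preference(self):
        rng = np.random.default_rng(10)
        base = rng.lognormal(0, 0.5, 400)
        other = LatencySample("b", rng.lognormal(0, 0.5, 400))
        p0 = predict_preference(
            LatencySample("a", base), other, 96, 1000, seed=12
        ).preference["a"]
        p1 = predict_preference(
            LatencySample("a", base + 0.3), other, 96, 1000, seed=12
        ).preference["a"]
        assert p1 <= p0

    def test_nonparametric_cdf_route_agrees(self):
        """Sampling from an interpolated ECDF estimate instead of resampling
        the raw latencies gives the same prediction within 3 SE."""
        rng = np.random.default_rng(13)
        m = 20_000
        raw_a = rng.lognormal(-0.3, 0.7, m)
        raw_b = rng.lognormal(0.1, 0.7, m)
        u = rng.random(m)
        ecdf_a = np.quantile(raw_a, u, method="linear")
        ecdf_b = np.quantile(raw_b, rng.random(m), method="linear")
        p_raw = predict_preference(
            LatencySample("a", raw_a), LatencySample("b", raw_b), 96, 3000, seed=14
        ).preference["a"]
        p_ecdf = predict_preference(
            LatencySample("a", ecdf_a), LatencySample("b", ecdf_b), 96, 3000, seed=15
        ).preference["a"]
        assert abs(p_raw - p_ecdf) < 3 * _combined_se(p_raw, 96 * 3000, m)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            LatencySample("a", [])


class TestAnalyticPreference:
    def test_identical_laws(self):
        d = sps.lognorm(s=0.5, scale=1.0)
        assert analytic_preference(d, sps.lognorm(s=0.5, scale=1.0)) == pytest.approx(
            0.5, abs=1e-8
        )

    def test_exponential_closed_form(self):
        assert analytic_preference(
            sps.expon(scale=0.5), sps.expon(scale=1.0)
        ) == pytest.approx(2 / 3, abs=1e-8)

    def test_point_masses(self):
        assert analytic_preference(0.5, 0.7) == 1.0
        assert analytic_preference(0.7, 0.5) == 0.0
        assert analytic_preference(0.6, 0.6) == 0.5

    def test_point_mass_vs_continuous(self):
        d = sps.expon(scale=1.0)
        assert analytic_preference(0.5, d) == pytest.approx(d.sf(0.5))
        assert analytic_preference(d, 0.5) == pytest.approx(d.cdf(0.5))


class TestCensoring:
    @pytest.fixture
    def bc_prediction(self, full_config):
        from scmforage.synth import draw_latency, subjective_value

        rng = np.random.default_rng(16)
        vp = full_config.value
        samples = {}
        for oid in ("B", "C"):
            v = subjective_value(full_config.design.options[oid], vp)
            samples[oid] = LatencySample(oid, draw_latency(v, vp, rng, 4000))
        return samples, predict_preference(
            samples["B"], samples["C"], 96, 2000, seed=17
        )

    def test_winner_ecdf_dominates_unconditional(self, bc_prediction):
        samples, pred = bc_prediction
        for oid in ("B", "C"):
            uncond = samples[oid].latencies
            winners = pred.winner_latencies[oid]
            grid = np.quantile(uncond, np.arange(1, 10) / 10)
            for g in grid:
                assert np.mean(winners <= g) >= np.mean(uncond <= g)

    def test_shortening_larger_for_less_preferred(self, bc_prediction):
        from scmforage.stats import shortening

        samples, pred = bc_prediction
        assert pred.preference["B"] < pred.preference["C"]
        short_b = shortening(samples["B"].latencies, pred.winner_latencies["B"])
        short_c = shortening(samples["C"].latencies, pred.winner_latencies["C"])
        assert short_b > short_c > 0

    def test_identical_samples_censored_median_shorter(self):
        rng = np.random.default_rng(18)
        lat = rng.lognormal(0, 0.8, 2000)
        pred = predict_preference(
            LatencySample("x", lat), LatencySample("y", lat.copy()), 96, 1000, seed=19
        )
        summary = censored_latency_summary(pred, "x")
        assert not summary.empty
        assert summary.median < np.median(lat)

    def test_dominated_option_empty_summary(self):
        pred = predict_preference(
            LatencySample("fast", [0.4, 0.5]),
            LatencySample("slow", [0.6, 0.7]),
            50,
            100,
            seed=20,
        )
        summary = censored_latency_summary(pred, "slow")
        assert summary.empty
        assert summary.n_wins == 0
        assert summary.median is None

    def test_unknown_option_raises(self):
        pred = predict_preference(
            LatencySample("a", [1.0]), LatencySample("b", [2.0]), 10, 10, seed=0
        )
        with pytest.raises(KeyError):
            censored_latency_summary(pred, "z")
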