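"""Heterogeneity estimation, pooling and the prediction interval."""

import math

import numpy as np
import pytest

from vapbench.logit_core import LogitEstimate, invlogit, logit
from vapbench.random_effects import (
    cochran_q,
    dl_tau2,
    pool_random_effects,
    prediction_interval,
    reml_tau2,
    summaries_to_csv,
)


def est(y: float, v: float) -> LogitEstimate:
    return LogitEstimate(logit_value=y, variance=v, source_events=0,
                         source_denominator=1)


def dl_oracle(y, v) -> float:
    """Moment-matching oracle for the DL estimator, independent of its
    closed form: solve E[Q](tau2) = Q_obs by bisection, where Q = y'Ay and
    E[Q](tau2) = tr(A diag(v + tau2)) for the fixed-effect projection A."""
    y = np.asarray(y, float)
    v = np.asarray(v, float)
    w = np.diag(1.0 / v)
    one = np.ones((len(y), 1))
    a = w - (w @ one @ one.T @ w) / (one.T @ w @ one).item()
    q_obs = float(y @ a @ y)

    def expected_q(tau2):
        return float(np.trace(a @ np.diag(v + tau2)))

    if expected_q(0.0) >= q_obs:
        return 0.0
    lo, hi = 0.0, 1.0
    while expected_q(hi) < q_obs:
        hi *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if expected_q(mid) < q_obs:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class TestCochranQ:
    def test_identical_estimates_give_zero(self):
        q, df = cochran_q([est(0.3, 0.2)] * 4)
        assert q == pytest.approx(0.0)
        assert df == 3

    def test_two_group_hand_arithmetic(self):
        q, df = cochran_q([est(0.0, 1.0), est(1.0, 1.0)])
        assert q == pytest.approx(0.5)
        assert df == 1

    def test_invariant_to_common_weight_rescaling(self):
        a = [est(-1.0, 0.2), est(0.5, 0.4), est(0.1, 0.3)]
        b = [est(e.logit_value, 10 * e.variance) for e in a]
        # rescaling all variances by c divides Q by c, so compare c*Q
        assert 10 * cochran_q(b)[0] == pytest.approx(cochran_q(a)[0])

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            cochran_q([est(0.0, 1.0)])


class TestDLTau2:
    def test_homogeneous_truncates_to_zero(self):
        assert dl_tau2([est(0.5, 1.0)] * 5) == 0.0

    def test_three_group_closed_form(self):
        # equal weights 10: Q = 20, df = 2, S1 = 30, S2 = 300 -> tau2 = 0.9
        estimates = [est(-2.0, 0.1), est(-1.0, 0.1), est(0.0, 0.1)]
        assert dl_tau2(estimates) == pytest.approx(0.9, abs=1e-12)

    @pytest.mark.parametrize(
        "y,v",
        [
            ([-2.0, -1.0, 0.0], [0.1, 0.1, 0.1]),
            ([-1.5, -0.3, 0.7], [0.05, 0.5, 0.2]),
            ([0.0, 0.1, -0.1], [1.0, 2.0, 0.5]),
            ([-3.0, 1.0, 2.0, -1.0], [0.3, 0.1, 0.7, 0.2]),
        ],
    )
    def test_agrees_with_moment_matching_oracle(self, y, v):
        estimates = [est(yi, vi) for yi, vi in zip(y, v)]
        assert dl_tau2(estimates) == pytest.approx(dl_oracle(y, v), abs=1e-6)

    def test_agrees_with_statsmodels(self):
        statsmodels = pytest.importorskip("statsmodels.stats.meta_analysis")
        y = [-1.8, -0.9, -1.3, 0.2, -0.5]
        v = [0.12, 0.4, 0.08, 0.3, 0.2]
        res = statsmodels.combine_effects(np.array(y), np.array(v),
                                          method_re="chi2")
        assert dl_tau2([est(a, b) for a, b in zip(y, v)]) == pytest.approx(
            res.tau2, rel=1e-8
        )

    def test_large_k_recovers_true_heterogeneity(self):
        rng = np.random.default_rng(2026)
        tau2, v = 0.34, 0.05
        y = rng.normal(-1.26, math.sqrt(tau2 + v), size=3000)
        estimates = [est(yi, v) for yi in y]
        mcse = 3 * tau2 * math.sqrt(2 / 3000)
        assert dl_tau2(estimates) == pytest.approx(tau2, abs=4 * mcse + 0.02)


class TestREMLTau2:
    def test_maximizes_restricted_likelihood(self):
        y = np.array([-1.8, -0.9, -1.3, 0.2, -0.5])
        v = np.array([0.12, 0.4, 0.08, 0.3, 0.2])
        tau2 = reml_tau2(y, v)

        def nll(t2):
            wi = 1.0 / (v + t2)
            mu = np.sum(wi * y) / np.sum(wi)
            return 0.5 * (
                -np.sum(np.log(wi)) + math.log(np.sum(wi))
                + np.sum(wi * (y - mu) ** 2)
            )

        assert nll(tau2) <= nll(tau2 + 0.01) + 1e-9
        assert nll(tau2) <= nll(max(tau2 - 0.01, 0.0)) + 1e-9

    def test_homogeneous_data_gives_zero(self):
        y = np.full(6, -1.0)
        v = np.full(6, 0.2)
        assert reml_tau2(y, v) == 0.0


class TestPooling:
    def test_symmetric_pair_pools_to_even_odds(self):
        summary = pool_random_effects([est(-1.0, 0.3), est(1.0, 0.3)])
        assert summary.mu_logit == pytest.approx(0.0, abs=1e-12)
        assert summary.mean_pct == pytest.approx(50.0)

    def test_fixed_effect_limit(self):
        # heterogeneity below chance: DL truncates to 0, weights become 1/v
        y = [-1.30, -1.25, -1.28, -1.27]
        v = [0.05, 0.08, 0.04, 0.1]
        summary = pool_random_effects([est(a, b) for a, b in zip(y, v)])
        assert summary.tau2 == 0.0
        w = 1.0 / np.array(v)
        fe = float(np.sum(w * np.array(y)) / np.sum(w))
        assert summary.mu_logit == pytest.approx(fe, abs=1e-10)
        assert summary.se == pytest.approx(1 / math.sqrt(np.sum(w)), abs=1e-12)

    def test_i2_in_range_and_pi_contains_ci(self):
        rng = np.random.default_rng(9)
        estimates = [
            est(rng.normal(-1.26, 0.6), 0.02 + rng.random() * 0.1)
            for _ in range(45)
        ]
        s = pool_random_effects(estimates)
        assert 0.0 <= s.i2 <= 100.0
        assert s.pi_logit[0] <= s.ci_logit[0] <= s.ci_logit[1] <= s.pi_logit[1]
        assert s.mean_pct == pytest.approx(100 * invlogit(s.mu_logit))

    def test_single_estimate_rejected(self):
        with pytest.raises(ValueError):
            pool_random_effects([est(0.0, 1.0)])


class TestPredictionInterval:
    def test_printed_benchmark_summary_reproduces_band(self):
        # pooled 22.1%, logit SE 0.09, tau^2 0.34 -> upper limit approx 47.4%
        from vapbench.random_effects import PooledSummary

        mu = logit(0.221)
        summary = PooledSummary(
            k=45, mu_logit=mu, se=0.09, tau2=0.34, i2=90.0, q=0.0,
            ci_logit=(mu - 1.96 * 0.09, mu + 1.96 * 0.09),
            pi_logit=(0.0, 0.0),
        )
        (_, _), (lo_pct, hi_pct) = prediction_interval(summary, z=1.96)
        assert hi_pct == pytest.approx(47.4, abs=0.1)
        assert lo_pct == pytest.approx(8.2, abs=0.1)

    def test_zero_heterogeneity_reduces_to_ci(self):
        y = [-1.30, -1.25, -1.28, -1.27]
        v = [0.05, 0.08, 0.04, 0.1]
        s = pool_random_effects([est(a, b) for a, b in zip(y, v)])
        assert s.tau2 == 0.0
        assert s.pi_logit == pytest.approx(s.ci_logit)

    def test_width_increasing_in_tau2(self):
        widths = []
        mu = -1.26
        for tau2 in (0.0, 0.2, 0.34, 0.6):
            from vapbench.random_effects import PooledSummary

            s = PooledSummary(
                k=45, mu_logit=mu, se=0.09, tau2=tau2, i2=0, q=0,
                ci_logit=(mu, mu), pi_logit=(mu, mu),
            )
            (lo, hi), _ = prediction_interval(s)
            widths.append(hi - lo)
        assert widths == sorted(widths)
        assert all(b > a for a, b in zip(widths, widths[1:]))


def test_summaries_csv_layout(tmp_path):
    s = pool_random_effects([est(-1.5, 0.1), est(-1.0, 0.2), est(-0.8, 0.15)],
                            stratum="benchmark/benchmark")
    path = tmp_path / "table.csv"
    frame = summaries_to_csv([s], path)
    assert list(frame.columns) == [
        "stratum", "mean_pct", "ci_low_pct", "ci_high_pct", "n", "se",
        "tau2", "i2_pct", "pi_low_pct", "pi_high_pct",
    ]
    assert path.exists()
    assert frame.loc[0, "n"] == 3
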