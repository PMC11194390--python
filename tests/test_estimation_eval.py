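"""Surrogate fits, statistics toolkit, and the noise-robustness harness."""

import numpy as np
import pandas as pd
import pytest

from pulsekfd.errors import DataError, FitError, ParameterError
from pulsekfd.estimation_eval import (
    add_noise,
    fit_surrogate,
    noise_robustness_experiment,
    partial_correlation,
    pearson_with_ci,
    welch_t_test,
)

# coefficients of the reference AC surrogate fitted on the 1D virtual
# database: AC_est = -0.98 + 40.56 dV + 51.62 / PP (mL, mmHg units)
AC_COEFS = (-0.98, 40.56, 51.62)


def synthetic_surrogate_table(n=500, noise_frac=0.0, seed=0):
    rng = np.random.default_rng(seed)
    dv = rng.uniform(0.01, 0.06, n)
    pp = rng.uniform(30.0, 70.0, n)
    ac = AC_COEFS[0] + AC_COEFS[1] * dv + AC_COEFS[2] / pp
    if noise_frac > 0:
        ac = ac + rng.normal(0.0, noise_frac * np.ptp(ac), n)
    kfd = 1.02 + 0.004 * rng.normal(size=n)
    return pd.DataFrame({"delta_v": dv, "PP": pp, "AC": ac, "KFD": kfd})


class TestFitSurrogate:
    def test_exact_recovery_without_noise(self):
        model = fit_surrogate(synthetic_surrogate_table(), target="AC")
        assert model.intercept == pytest.approx(AC_COEFS[0], abs=1e-8)
        assert model.coef_dvppg == pytest.approx(AC_COEFS[1], rel=1e-8)
        assert model.coef_main == pytest.approx(AC_COEFS[2], rel=1e-8)
        assert model.r_insample == pytest.approx(1.0, abs=1e-9)

    def test_recovery_with_one_percent_noise(self):
        model = fit_surrogate(synthetic_surrogate_table(noise_frac=0.01), target="AC")
        assert model.coef_dvppg == pytest.approx(AC_COEFS[1], rel=0.05)
        assert model.coef_main == pytest.approx(AC_COEFS[2], rel=0.05)

    def test_inv_pp_target_recovery(self):
        rng = np.random.default_rng(1)
        n = 400
        dv = rng.uniform(0.01, 0.06, n)
        kfd = 1.0 + rng.uniform(0.01, 0.08, n)
        inv_pp = 0.002 - 0.05 * dv + 0.02 * kfd
        df = pd.DataFrame({"delta_v": dv, "PP": 1.0 / inv_pp, "KFD": kfd, "AC": np.ones(n)})
        model = fit_surrogate(df, target="inv_PP")
        assert model.coef_dvppg == pytest.approx(-0.05, rel=1e-6)
        assert model.coef_main == pytest.approx(0.02, rel=1e-6)

    def test_constant_target_rejected(self):
        df = synthetic_surrogate_table()
        df["AC"] = 1.0
        with pytest.raises(FitError):
            fit_surrogate(df, target="AC")

    def test_chain_consistency_when_pp_is_exact_in_kfd(self):
        # when 1/PP is exactly linear in (delta_v, KFD) and AC exactly
        # linear in (delta_v, 1/PP), composing g into f reproduces the
        # direct AC-on-(delta_v, KFD) regression
        rng = np.random.default_rng(2)
        n = 300
        dv = rng.uniform(0.01, 0.06, n)
        kfd = 1.0 + rng.uniform(0.01, 0.08, n)
        inv_pp = 0.004 - 0.03 * dv + 0.015 * kfd
        ac = -0.98 + 40.56 * dv + 51.62 * inv_pp
        df = pd.DataFrame({"delta_v": dv, "PP": 1.0 / inv_pp, "KFD": kfd, "AC": ac})
        f = fit_surrogate(df, target="AC")
        g = fit_surrogate(df, target="inv_PP")
        composed = f.intercept + f.coef_dvppg * dv + f.coef_main * g.predict(dv, kfd)
        X = np.column_stack([np.ones(n), dv, kfd])
        direct = X @ np.linalg.lstsq(X, ac, rcond=None)[0]
        np.testing.assert_allclose(composed, direct, atol=1e-8)


class TestPearsonWithCi:
    def test_perfect_line_has_degenerate_interval(self):
        x = np.arange(10.0)
        rep = pearson_with_ci(x, 2 * x + 1)
        assert rep.r == pytest.approx(1.0)
        assert rep.ci_low == rep.ci_high == rep.r

    def test_large_sample_estimate_near_truth(self):
        rng = np.random.default_rng(0)
        n = 4374
        x = rng.normal(size=n)
        y = 0.75 * x + np.sqrt(1 - 0.75**2) * rng.normal(size=n)
        rep = pearson_with_ci(x, y)
        assert 0.73 <= rep.r <= 0.77
        assert rep.ci_low <= rep.r <= rep.ci_high

    def test_interval_coverage_under_independence(self):
        covered = 0
        for s in range(100):
            rng = np.random.default_rng(s)
            rep = pearson_with_ci(rng.normal(size=1000), rng.normal(size=1000))
            covered += rep.ci_low <= 0.0 <= rep.ci_high
        assert 88 <= covered <= 100

    def test_zero_variance_rejected(self):
        with pytest.raises(DataError):
            pearson_with_ci(np.ones(10), np.arange(10.0))


class TestAddNoise:
    def test_noise_variance_matches_snr_definition(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200_000)
        noisy = add_noise(x, 15.0, seed=1)
        noise_var = np.var(noisy - x)
        assert noise_var == pytest.approx(np.var(x) * 10 ** (-1.5), rel=0.02)

    def test_infinite_snr_is_identity(self):
        x = np.sin(np.linspace(0, 10, 500))
        np.testing.assert_array_equal(add_noise(x, np.inf, seed=0), x)

    def test_seed_reproducibility(self):
        x = np.sin(np.linspace(0, 10, 500))
        np.testing.assert_array_equal(add_noise(x, 20, 3), add_noise(x, 20, 3))

    def test_constant_signal_rejected(self):
        with pytest.raises(ParameterError):
            add_noise(np.ones(100), 20.0, 0)


class TestWelchTTest:
    def test_identical_groups(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        t, p = welch_t_test(a, a.copy())
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_separated_groups_highly_significant(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 1.0, 50)
        b = rng.normal(5.0, 1.0, 50)
        _, p = welch_t_test(a, b)
        assert p < 1e-6

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=30), rng.normal(1.0, 1.0, 40)
        t1, p1 = welch_t_test(a, b)
        t2, p2 = welch_t_test(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)


class TestPartialCorrelation:
    def test_no_controls_reduces_to_pearson(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=100), rng.normal(size=100)
        assert partial_correlation(x, y).r == pytest.approx(pearson_with_ci(x, y).r)

    def test_controlling_for_identical_variable_zeroes_r(self):
        rng = np.random.default_rng(1)
        c = rng.normal(size=200)
        x = rng.normal(size=200)
        rep = partial_correlation(x, c, controls=c[:, None])
        assert abs(rep.r) < 1e-10

    def test_common_confounder_removed(self):
        rng = np.random.default_rng(2)
        z = rng.normal(size=2000)
        x = z + 0.3 * rng.normal(size=2000)
        y = z + 0.3 * rng.normal(size=2000)
        raw = pearson_with_ci(x, y).r
        part = partial_correlation(x, y, controls=z[:, None]).r
        assert raw > 0.8
        assert abs(part) < 0.1

    def test_agrees_with_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(150, 4)), columns=list("xyzw"))
        df["y"] = df.y + 0.5 * df.z - 0.2 * df.w
        df["x"] = df.x + 0.4 * df.z
        ours = partial_correlation(
            df.x.to_numpy(), df.y.to_numpy(), controls=df[["z", "w"]].to_numpy()
        )
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["z", "w"])
        assert ours.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)

    def test_collinear_controls_rejected(self):
        rng = np.random.default_rng(4)
        c = rng.normal(size=50)
        with pytest.raises(FitError):
            partial_correlation(
                rng.normal(size=50), rng.normal(size=50),
                controls=np.column_stack([c, 2 * c]),
            )


@pytest.fixture(scope="module")
def report(cohort_varying):
    return noise_robustness_experiment(
        cohort_varying, snrs=(15.0, 20.0, 30.0), n_seeds=3, base_seed=7
    )


class TestNoiseRobustness:
    def _r(self, report, feature, snr):
        rows = report[(report.feature == feature) & (report.snr == snr)]
        return rows.r.abs().median()

    def test_kfd_retains_most_correlation_at_weak_noise(self, report):
        base = self._r(report, "KFD", np.inf)
        at_30 = self._r(report, "KFD", 30.0)
        assert at_30 > 0.6 * base
        assert at_30 >= self._r(report, "KFD", 15.0)

    def test_kfd_more_robust_than_stiffness_index_at_weak_noise(self, report):
        kfd_drop = self._r(report, "KFD", np.inf) - self._r(report, "KFD", 30.0)
        si_drop = self._r(report, "inv_SI", np.inf) - self._r(report, "inv_SI", 30.0)
        assert kfd_drop < si_drop + 0.05

    def test_kfd_degrades_less_than_stiffness_index(self, report):
        kfd_drop = self._r(report, "KFD", np.inf) - self._r(report, "KFD", 15.0)
        si_drop = self._r(report, "inv_SI", np.inf) - self._r(report, "inv_SI", 15.0)
        assert kfd_drop < si_drop

    def test_morphology_degradation_monotone_in_noise(self, report):
        rs = [self._r(report, "inv_SI", s) for s in (15.0, 20.0, 30.0, np.inf)]
        assert rs[0] <= rs[1] <= rs[2] <= rs[3]

    def test_report_schema(self, report):
        assert set(report.columns) == {"feature", "snr", "seed", "r", "ci_low", "ci_high", "n"}
        assert (report.n > 0).all()
        assert ((report.ci_low <= report.r) & (report.r <= report.ci_high)).all()
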