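"""Conditional-logit likelihood, estimation and inference."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from oracles import scalar_clogit_mle
from routewalk.clogit import (
    ChoiceObservation,
    NotConvergedError,
    SeparationError,
    cl_hessian,
    cl_loglik,
    cl_score,
    fit_clogit,
    model_table,
    observations_from_frame,
)


def paired_obs(X, choices):
    return [
        ChoiceObservation(f"i{i}", X[i], int(choices[i])) for i in range(len(X))
    ]


def simulate_paired(beta, n, seed, k=None, scale=1.0):
    """Paired alternatives with Gumbel-noise choices from known beta."""
    rng = np.random.default_rng(seed)
    beta = np.asarray(beta, dtype=float)
    k = k or len(beta)
    X = rng.normal(0, scale, size=(n, 2, k))
    util = X @ beta + rng.gumbel(size=(n, 2))
    return paired_obs(X, util.argmax(axis=1))


class TestLogLikelihood:
    def test_zero_beta_gives_minus_n_log2(self):
        """With beta = 0 every paired choice has probability 1/2, exactly."""
        obs = simulate_paired([1.0, -0.5], n=73, seed=0)
        assert cl_loglik(np.zeros(2), obs) == -73 * math.log(2.0)

    def test_identical_alternatives_give_log_j_for_any_beta(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(1, 3))
        obs = [ChoiceObservation("i", np.repeat(x, 4, axis=0), 2) for _ in range(5)]
        for beta in (np.zeros(3), rng.normal(size=3), rng.normal(size=3) * 10):
            assert cl_loglik(beta, obs) == pytest.approx(-5 * math.log(4.0))

    def test_binary_logit_identity(self):
        """One observation, scalar beta: LL = -ln(1 + exp(-beta*dx))."""
        x = np.array([[1.7], [0.4]])
        obs = [ChoiceObservation("i", x, 0)]
        dx = 1.7 - 0.4
        for beta in (-2.0, -0.3, 0.0, 0.9, 3.1):
            expected = -math.log1p(math.exp(-beta * dx))
            assert cl_loglik(np.array([beta]), obs) == pytest.approx(expected)

    def test_dimension_mismatch_rejected(self):
        obs = simulate_paired([1.0], n=3, seed=2)
        with pytest.raises(ValueError, match="attributes"):
            cl_loglik(np.zeros(2), obs)

    @settings(derandomize=True, max_examples=25)
    @given(shift=st.floats(-5, 5), seed=st.integers(0, 100))
    def test_invariance_to_common_attribute_shifts(self, shift, seed):
        """Adding a constant to an attribute across alternatives changes nothing."""
        obs = simulate_paired([0.8, -0.4], n=20, seed=seed)
        beta = np.array([0.8, -0.4])
        shifted = [
            ChoiceObservation(ob.chooser_id, ob.X + np.array([shift, 0.0]), ob.chosen)
            for ob in obs
        ]
        assert cl_loglik(beta, shifted) == pytest.approx(cl_loglik(beta, obs))

    def test_gradient_matches_finite_differences(self):
        obs = simulate_paired([0.5, -1.0, 0.2], n=40, seed=3)
        beta = np.array([0.3, -0.2, 0.1])
        grad = cl_score(beta, obs)
        eps = 1e-6
        for j in range(3):
            e = np.zeros(3)
            e[j] = eps
            fd = (cl_loglik(beta + e, obs) - cl_loglik(beta - e, obs)) / (2 * eps)
            assert grad[j] == pytest.approx(fd, rel=1e-5, abs=1e-7)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_hessian_negative_semidefinite(self, seed):
        rng = np.random.default_rng(seed)
        obs = simulate_paired([1.0, -0.5], n=30, seed=seed + 10)
        for _ in range(3):
            H = cl_hessian(rng.normal(size=2), obs)
            assert np.all(np.linalg.eigvalsh(H) <= 1e-10)


class TestFit:
    def test_recovers_known_coefficients(self):
        """beta_true = (1, -0.5) at n = 1000 recovered within 3 SEs."""
        beta_true = np.array([1.0, -0.5])
        fit = fit_clogit(simulate_paired(beta_true, n=1000, seed=4), attributes=["a", "b"])
        assert fit.converged
        for b, t, s in zip(fit.beta, beta_true, fit.se):
            assert abs(b - t) < 3 * s
        assert fit.loglik >= fit.loglik_null

    def test_null_data_gives_null_coefficients(self):
        """Random choices at n = 2000: every |beta| < 3 SE."""
        rng = np.random.default_rng(5)
        X = rng.normal(size=(2000, 2, 2))
        obs = paired_obs(X, rng.integers(0, 2, size=2000))
        fit = fit_clogit(obs)
        assert np.all(np.abs(fit.beta) < 3 * fit.se)

    def test_scalar_mle_matches_ternary_search(self):
        """1-D MLE agrees with a brute-force concave search within 1e-6."""
        obs = simulate_paired([0.7], n=300, seed=6)
        fit = fit_clogit(obs)
        brute = scalar_clogit_mle(lambda b: cl_loglik(np.array([b]), obs))
        assert fit.beta[0] == pytest.approx(brute, abs=1e-6)

    def test_z_and_p_identities(self):
        fit = fit_clogit(simulate_paired([1.0, -0.5], n=400, seed=7))
        np.testing.assert_allclose(fit.z, fit.beta / fit.se)
        np.testing.assert_allclose(
            fit.p, 2 * (1 - norm.cdf(np.abs(fit.z))), atol=1e-12
        )

    def test_perfect_separation_raises(self):
        """Chosen alternative always dominates: likelihood is unbounded."""
        rng = np.random.default_rng(8)
        obs = []
        for i in range(50):
            lo = rng.normal()
            X = np.array([[lo + abs(rng.normal()) + 0.1], [lo]])
            obs.append(ChoiceObservation(f"i{i}", X, 0))
        with pytest.raises(SeparationError):
            fit_clogit(obs)

    def test_no_varying_attribute_rejected(self):
        X = np.ones((4, 2, 1))
        obs = paired_obs(X, np.zeros(4, dtype=int))
        with pytest.raises(ValueError, match="varies"):
            fit_clogit(obs)

    def test_zscore_reports_original_scale(self):
        obs = simulate_paired([0.4, -0.8], n=600, seed=9, scale=3.0)
        plain = fit_clogit(obs)
        scaled = fit_clogit(obs, zscore=True)
        np.testing.assert_allclose(scaled.beta, plain.beta, rtol=1e-4)
        np.testing.assert_allclose(scaled.se, plain.se, rtol=1e-4)

    def test_wald_coverage_calibration(self):
        """95% intervals cover the truth about 95% of the time (n=200 reps)."""
        beta_true = np.array([1.0, -0.5])
        rng = np.random.default_rng(10)
        X = rng.normal(size=(300, 2, 2))
        hits = np.zeros(2)
        reps = 120
        for r in range(reps):
            rr = np.random.default_rng(20_000 + r)
            util = X @ beta_true + rr.gumbel(size=(300, 2))
            fit = fit_clogit(paired_obs(X, util.argmax(axis=1)))
            hits += np.abs(fit.beta - beta_true) <= 1.96 * fit.se
        coverage = hits / reps
        assert np.all(coverage >= 0.90) and np.all(coverage <= 0.99)


class TestCrossChecks:
    def test_matches_statsmodels_conditional_logit(self):
        """From-scratch fit equals statsmodels ConditionalLogit."""
        from statsmodels.discrete.conditional_models import ConditionalLogit

        obs = simulate_paired([1.0, -0.5], n=400, seed=11)
        fit = fit_clogit(obs, attributes=["a", "b"])
        rows, y, groups = [], [], []
        for i, ob in enumerate(obs):
            for j in range(ob.X.shape[0]):
                rows.append(ob.X[j])
                y.append(1 if j == ob.chosen else 0)
                groups.append(i)
        sm_fit = ConditionalLogit(np.array(y), np.array(rows), groups=np.array(groups)).fit(disp=0)
        np.testing.assert_allclose(fit.beta, sm_fit.params, atol=1e-5)
        np.testing.assert_allclose(fit.se, sm_fit.bse, atol=1e-5)
        assert fit.loglik == pytest.approx(sm_fit.llf, abs=1e-6)

    def test_pairs_equal_binary_logit_on_differences(self):
        """With 2 alternatives, CL = no-intercept logit on attribute diffs."""
        import statsmodels.api as sm

        obs = simulate_paired([0.6, -0.3], n=500, seed=12)
        fit = fit_clogit(obs)
        dX = np.array([ob.X[0] - ob.X[1] for ob in obs])
        y = np.array([1 if ob.chosen == 0 else 0 for ob in obs])
        logit = sm.Logit(y, dX).fit(disp=0)
        np.testing.assert_allclose(fit.beta, logit.params, atol=1e-6)
        np.testing.assert_allclose(fit.se, logit.bse, atol=1e-6)


class TestModelTable:
    def make_fit(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(300, 2, 3))
        util = X @ np.array([0.5, -0.5, 0.2]) + rng.gumbel(size=(300, 2))
        obs = paired_obs(X, util.argmax(axis=1))
        return fit_clogit(
            obs, attributes=["green_spaces", "sidewalk_width", "garbage_bins"]
        )

    def test_rows_grouped_by_audit_category(self):
        table = model_table(self.make_fit())
        assert len(table) == 3
        assert list(table["category"]) == [
            "Roadway features", "Streetscape", "Pedestrian infrastructure",
        ]
        assert list(table["attribute"]) == [
            "sidewalk_width", "green_spaces", "garbage_bins",
        ]

    def test_z_column_recomputes_from_coef_and_se(self):
        table = model_table(self.make_fit())
        np.testing.assert_allclose(table["z"], table["coef"] / table["se"])

    def test_p_of_z_196_is_005(self):
        assert 2 * (1 - norm.cdf(1.96)) == pytest.approx(0.050, abs=5e-4)
        table = model_table(self.make_fit())
        np.testing.assert_allclose(table["p"], 2 * norm.sf(np.abs(table["z"])))


class TestLongFormat:
    def test_observations_from_frame_roundtrip(self):
        df = pd.DataFrame(
            {
                "od_id": ["t1", "t1", "t2", "t2"],
                "alternative_label": ["chosen", "shortest", "chosen", "shortest"],
                "chosen": [1, 0, 0, 1],
                "green_spaces": [2.0, 1.5, 1.0, 2.5],
            }
        )
        obs = observations_from_frame(df, ["green_spaces"])
        assert len(obs) == 2
        assert obs[0].chosen == 0  # "chosen" sorts before "shortest"
        assert obs[1].chosen == 1
        with pytest.raises(ValueError, match="exactly one chosen"):
            observations_from_frame(df.assign(chosen=[1, 1, 0, 1]), ["green_spaces"])
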