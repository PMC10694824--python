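"""EM estimator tests: E-step weights, closed-form updates, ascent, oracles."""

import numpy as np
import pytest
from scipy.stats import binom

from pnrcount import (
    EMSettings,
    MixtureParams,
    PhotonHistogram,
    SimConfig,
    expected_histogram,
    log_likelihood,
    sample_histogram,
)
from pnrcount.em import (
    e_step_weights,
    expected_species_counts,
    posterior_marginals,
    run_em,
    update_M,
    update_p,
)
from pnrcount.seeding import _batched_fixed_M_em, fit_with_search

from conftest import random_mixture


class TestEStep:
    def test_zero_total_has_single_tuple(self, theta_two):
        w = e_step_weights(0, theta_two)
        assert w == {(0, 0): pytest.approx(1.0)}

    def test_full_total_has_single_tuple(self, theta_two):
        w = e_step_weights(theta_two.M_total, theta_two)
        assert w == {(8, 10): pytest.approx(1.0)}

    def test_two_bernoulli_species_hand_value(self):
        theta = MixtureParams.from_flat([1, 0.1, 1, 0.2])
        w = e_step_weights(1, theta)
        # P(species 1 fired | one photon) = 0.1*0.8 / (0.1*0.8 + 0.9*0.2)
        assert w[(1, 0)] == pytest.approx(0.1 * 0.8 / (0.1 * 0.8 + 0.9 * 0.2), rel=1e-12)
        assert sum(w.values()) == pytest.approx(1.0, abs=1e-12)

    def test_beyond_support_raises(self, theta_two):
        with pytest.raises(ValueError):
            e_step_weights(19, theta_two)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_marginals_match_partition_enumeration(self, seed):
        """Fast leave-one-out path agrees with the explicit partition sums."""
        rng = np.random.default_rng(seed)
        theta = random_mixture(rng, int(rng.integers(2, 4)), M_max=6)
        W = posterior_marginals(theta.M_total, theta)
        for i in range(theta.M_total + 1):
            weights = e_step_weights(i, theta)
            for j in range(theta.m):
                marg = np.zeros(theta.species[j].M + 1)
                for parts, w in weights.items():
                    marg[parts[j]] += w
                np.testing.assert_allclose(W[j][i], marg, atol=1e-10)


class TestMStep:
    def test_single_species_takes_all_photons(self, hist_one_1e5, theta_one):
        S = expected_species_counts(hist_one_1e5, theta_one)
        total = float(hist_one_1e5.counts @ np.arange(hist_one_1e5.N + 1))
        assert S[0] == pytest.approx(total, rel=1e-12)

    def test_photon_conservation(self, theta_three):
        hist = sample_histogram(SimConfig(theta=theta_three, nu=10**4, seed=8))
        S = expected_species_counts(hist, theta_three)
        total = float(hist.counts @ np.arange(hist.N + 1))
        assert S.sum() == pytest.approx(total, rel=1e-10)

    def test_expected_counts_at_truth_in_infinite_data_limit(self, theta_three):
        nu = 1.0
        hist = expected_histogram(theta_three, nu)
        S = expected_species_counts(hist, theta_three)
        np.testing.assert_allclose(S, [0.8, 2.0, 3.6], atol=1e-8)

    def test_p_update_is_mean_over_M_for_one_species(self, hist_one_1e5, theta_one):
        mean = float(hist_one_1e5.counts @ np.arange(hist_one_1e5.N + 1)) / hist_one_1e5.nu
        p = update_p(hist_one_1e5, theta_one)
        assert p[0] == pytest.approx(mean / 8, rel=1e-12)

    def test_truth_is_fixed_point_of_p_update(self, theta_two):
        hist = expected_histogram(theta_two, 1e6)
        p = update_p(hist, theta_two)
        np.testing.assert_allclose(p, [0.1, 0.2], atol=1e-9)

    def test_all_counts_at_zero_drives_p_to_zero(self, theta_two):
        hist = PhotonHistogram(np.array([100.0]))
        p = update_p(hist, theta_two)
        np.testing.assert_allclose(p, 0.0, atol=1e-12)

    def test_M_scan_recovers_truth_with_p_fixed(self, theta_one):
        hist = expected_histogram(theta_one, 1e6)
        M = update_M(hist, theta_one, np.array([0.1]), M_max=20)
        assert M[0] == 8

    def test_M_scan_tie_breaks_to_smallest_on_degenerate_histogram(self):
        hist = PhotonHistogram(np.array([100.0]))
        theta = MixtureParams.from_flat([5, 0.3])
        M = update_M(hist, theta, np.array([1e-12]), M_max=20)
        assert M[0] == 1

    def test_M_scan_flags_unreachable_support(self):
        theta = MixtureParams.from_flat([4, 0.5])
        hist = PhotonHistogram(np.concatenate([np.zeros(3), [5.0]]))  # N = 3
        with pytest.raises(ValueError, match="M_max"):
            update_M(hist, theta, np.array([0.5]), M_max=2)


class TestRunEM:
    def test_truth_is_stationary_on_exact_pmf_histogram(self, theta_two):
        hist = expected_histogram(theta_two, 1e6)
        fit = run_em(hist, theta_two, EMSettings(fix_M=True))
        assert fit.converged and fit.iterations <= 2
        np.testing.assert_allclose(fit.theta_hat.ps, [0.1, 0.2], atol=1e-7)

    def test_loglik_trace_is_monotone(self, theta_two):
        hist = sample_histogram(SimConfig(theta=theta_two, nu=10**4, seed=5))
        for flat in ([5, 0.3, 12, 0.15], [9, 0.05, 11, 0.4]):
            fit = run_em(hist, MixtureParams.from_flat(flat), EMSettings(max_iter=200))
            assert np.all(np.diff(fit.trace) > -1e-9)
            assert fit.loglik == pytest.approx(
                log_likelihood(hist, fit.theta_hat), rel=1e-12
            )

    def test_fix_M_mode_keeps_emitter_counts(self, theta_two):
        hist = sample_histogram(SimConfig(theta=theta_two, nu=10**4, seed=6))
        init = MixtureParams.from_flat([8, 0.3, 10, 0.05])
        fit = run_em(hist, init, EMSettings(fix_M=True, max_iter=500))
        assert list(fit.theta_hat.Ms) == [8, 10]

    def test_nonconvergence_reported_not_raised(self, theta_two):
        hist = sample_histogram(SimConfig(theta=theta_two, nu=10**4, seed=6))
        fit = run_em(hist, theta_two, EMSettings(tol_p=1e-15, tol_ll=1e-18, max_iter=3))
        assert fit.converged is False
        assert fit.iterations == 3

    def test_search_matches_grid_search_mle_one_species(self, hist_one_1e5):
        """Combination-search MLE equals an independent dense grid search."""
        fit = fit_with_search(hist_one_1e5, 1, M_max=20)
        best = (-np.inf, None, None)
        ys = np.arange(hist_one_1e5.N + 1)
        for M in range(hist_one_1e5.N, 21):
            for p in np.arange(1e-4, 1.0, 1e-4):
                ll = float(hist_one_1e5.counts @ binom.logpmf(ys, M, p))
                if ll > best[0]:
                    best = (ll, M, p)
        assert fit.theta_hat.species[0].M == best[1]
        assert fit.theta_hat.species[0].p == pytest.approx(best[2], abs=1e-4)


def test_batched_fixed_M_em_agrees_with_reference_loop(theta_two):
    """The vectorized multi-candidate EM equals per-candidate run_em."""
    hist = sample_histogram(SimConfig(theta=theta_two, nu=10**5, seed=21))
    combos = np.array([[8, 10], [7, 11], [9, 12]])
    P0 = np.array([[0.09, 0.22], [0.12, 0.18], [0.08, 0.17]])
    # disable the log-likelihood stop so both paths run to the same p-tolerance
    settings = EMSettings(fix_M=True, tol_p=1e-10, tol_ll=1e-18, max_iter=8000)
    P, ll, _, _ = _batched_fixed_M_em(hist.counts, hist.nu, combos, P0, settings)
    for k, (Mk, p0) in enumerate(zip(combos, P0)):
        init = MixtureParams.from_flat([Mk[0], p0[0], Mk[1], p0[1]])
        ref = run_em(hist, init, settings)
        # a |dp| < tol stop on a linearly converging sequence leaves the
        # iterate within ~tol/(1-rho) of the fixed point, so the two paths
        # agree to ~1e-5 here, and the accelerated one may end slightly higher
        np.testing.assert_allclose(P[k], ref.theta_hat.ps, atol=2e-5)
        assert ll[k] == pytest.approx(ref.loglik, abs=1e-6)
        assert ll[k] >= ref.loglik - 1e-9
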