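import numpy as np
import pytest
from scipy.special import logsumexp
from scipy.stats import norm

from dsenorm import (GroupDesign, HmmFit, HmmParams, HMMNormalizer,
                     MValueTrack, ValidationError, fit_hmm, hmm_normalize,
                     init_hmm, m_values, tail_mean_init, unaltered_mask,
                     SimulationConfig, simulate_experiment,
                     synth_variable_params, to_log2)

from conftest import make_matrix


def log_forward_oracle(x, params):
    """Independent log-space forward algorithm for the HMM likelihood."""
    log_b = norm.logpdf(x[:, None], params.means[None, :],
                        params.sigmas[None, :])
    log_a = np.log(params.transmat)
    alpha = np.log(params.startprob) + log_b[0]
    for t in range(1, x.size):
        alpha = logsumexp(alpha[:, None] + log_a, axis=0) + log_b[t]
    return logsumexp(alpha)


class TestMValues:
    def test_identical_arms_give_zero(self, small_matrix, design_2x2):
        m = small_matrix
        m.values[:, 2:] = m.values[:, :2]
        track = m_values(m, design_2x2)
        np.testing.assert_allclose(track.values, 0.0, atol=1e-12)

    def test_unit_shift_gives_unit_m(self, small_matrix, design_2x2):
        small_matrix.values[:, :2] = small_matrix.values[:, 2:] + 1.0
        track = m_values(small_matrix, design_2x2)
        np.testing.assert_allclose(track.values, 1.0)

    def test_two_replicate_arithmetic_of_log_means(self, design_2x2):
        # treated log2 values (3, 5), reference (2, 2) -> M = 4 - 2 = 2
        m = make_matrix([[3.0, 5.0, 2.0, 2.0]] * 12,
                        sample_ids=["T1", "T2", "R1", "R2"])
        track = m_values(m, design_2x2)
        np.testing.assert_allclose(track.values, 2.0)

    def test_arithmetic_averaging_uses_raw_intensities(self, design_2x2):
        m = make_matrix([[3.0, 5.0, 2.0, 2.0]] * 12,
                        sample_ids=["T1", "T2", "R1", "R2"])
        track = m_values(m, design_2x2, average="arithmetic")
        # mean(8, 32) = 20 vs mean(4, 4) = 4 -> log2(5)
        np.testing.assert_allclose(track.values, np.log2(5.0))

    def test_empty_arm_is_an_error(self, small_matrix):
        d = GroupDesign({"T1": "treatment", "T2": "treatment",
                         "R1": "reference", "R2": "reference",
                         "X": "reference"})
        with pytest.raises(ValidationError):
            m_values(small_matrix, GroupDesign({"T1": "treatment",
                                                "X": "reference"}))


class TestInitHmm:
    def _track(self, values):
        return MValueTrack(values=np.asarray(values, float),
                           blocks=[(0, len(values))])

    def test_moment_matching(self, rng):
        # mean 0.1 and variance 1.0 with rho = 0.1:
        # mu2 = 0.1/0.1 = 1, sigma^2 = 1 - 0.1*0.9*1 = 0.91
        v = rng.normal(size=1000)
        v = (v - v.mean()) / v.std()  # exactly mean 0, var 1
        params = init_hmm(self._track(v + 0.1), rho_guess=0.1)
        assert params.means[1] == pytest.approx(1.0, abs=1e-9)
        assert params.sigmas[0] ** 2 == pytest.approx(0.91, abs=1e-9)

    def test_centered_data_give_zero_altered_mean(self, rng):
        v = rng.normal(size=500)
        v -= v.mean()
        params = init_hmm(self._track(v), rho_guess=0.3)
        assert params.means[1] == pytest.approx(0.0, abs=1e-12)
        assert params.sigmas[0] ** 2 == pytest.approx(v.var(), rel=1e-9)

    def test_variance_floor(self, rng):
        # mean 1, var 0.1, rho 0.1: raw sigma^2 = 0.1 - 0.09*100 < 0
        v = rng.normal(size=2000)
        v = (v - v.mean()) / v.std() * np.sqrt(0.1) + 1.0
        params = init_hmm(self._track(v), rho_guess=0.1)
        assert params.sigmas[0] ** 2 == pytest.approx(0.05, abs=1e-9)

    def test_transitions_encode_region_length_and_stationary_mix(self):
        v = np.random.default_rng(1).normal(size=200)
        params = init_hmm(self._track(v), rho_guess=0.1,
                          expected_region_length=50)
        assert params.transmat[1, 0] == pytest.approx(1 / 50)
        assert params.transmat[0, 1] == pytest.approx(0.1 / (0.9 * 50))
        np.testing.assert_allclose(params.stationary(), [0.9, 0.1])
        np.testing.assert_allclose(params.startprob, [0.9, 0.1])

    def test_constant_track_is_an_error(self):
        with pytest.raises(ValidationError, match="zero variance"):
            init_hmm(self._track(np.ones(100)))

    def test_tail_mean_rescue_of_degenerate_init(self, rng):
        # right-skewed mixture whose overall mean is ~0 (post-normalization
        # regime): the moment init collapses, the tail init does not
        v = np.concatenate([rng.normal(-0.15, 0.2, 900),
                            rng.normal(0.45, 0.2, 100)])
        v -= v.mean()
        track = self._track(v)
        degenerate = init_hmm(track, rho_guess=0.1)
        assert abs(degenerate.means[1]) < 0.05
        rescued = tail_mean_init(track, degenerate)
        assert rescued.means[1] > 0.3


class TestFitHmm:
    def _sample_hmm(self, rng, n=20_000, means=(0.0, 1.0), sigma=0.3,
                    stay=(0.98, 0.96)):
        transmat = np.array([[stay[0], 1 - stay[0]],
                             [1 - stay[1], stay[1]]])
        states = np.empty(n, dtype=int)
        states[0] = 0
        u = rng.random(n)
        for t in range(1, n):
            prev = states[t - 1]
            states[t] = prev if u[t] < transmat[prev, prev] else 1 - prev
        x = rng.normal(np.asarray(means)[states], sigma)
        return MValueTrack(values=x, blocks=[(0, n)]), states

    def test_parameter_recovery(self, rng):
        track, _ = self._sample_hmm(rng)
        init = init_hmm(track, rho_guess=0.2, expected_region_length=25)
        init = tail_mean_init(track, init)
        fit = fit_hmm(track, init)
        recovered = np.sort(fit.params.means)
        assert recovered[0] == pytest.approx(0.0, abs=0.05)
        assert recovered[1] == pytest.approx(1.0, abs=0.05)
        assert fit.converged

    def test_log_likelihood_is_non_decreasing(self, rng):
        track, _ = self._sample_hmm(rng, n=5_000)
        fit = fit_hmm(track, tail_mean_init(track, init_hmm(track, 0.2)))
        assert np.all(np.diff(fit.log_likelihoods) >= -1e-8)

    def test_first_trace_entry_matches_forward_oracle(self, rng):
        track = MValueTrack(values=rng.normal(0.2, 0.5, size=30),
                            blocks=[(0, 30)])
        init = init_hmm(track, rho_guess=0.2, expected_region_length=5)
        fit = fit_hmm(track, init, max_iter=5)
        oracle = log_forward_oracle(track.values, init)
        assert fit.log_likelihoods[0] == pytest.approx(oracle, abs=1e-8)

    def test_infinite_tolerance_stops_almost_immediately(self, rng):
        track, _ = self._sample_hmm(rng, n=2_000)
        fit = fit_hmm(track, init_hmm(track, 0.2), tol=np.inf)
        assert 1 <= fit.log_likelihoods.size <= 2
        assert np.all(np.diff(fit.log_likelihoods) >= -1e-8)

    def test_constant_track_is_an_error(self):
        with pytest.raises(ValidationError, match="zero variance"):
            fit_hmm(MValueTrack(values=np.ones(100), blocks=[(0, 100)]))

    def test_block_permutation_permutes_states_identically(self, rng):
        a, _ = self._sample_hmm(rng, n=1_500)
        b, _ = self._sample_hmm(rng, n=2_500)
        forward = MValueTrack(values=np.concatenate([a.values, b.values]),
                              blocks=[(0, 1500), (1500, 4000)])
        swapped = MValueTrack(values=np.concatenate([b.values, a.values]),
                              blocks=[(0, 2500), (2500, 4000)])
        init_f = tail_mean_init(forward, init_hmm(forward, 0.2))
        init_s = tail_mean_init(swapped, init_hmm(swapped, 0.2))
        fit_f = fit_hmm(forward, init_f)
        fit_s = fit_hmm(swapped, init_s)
        np.testing.assert_array_equal(fit_f.states[:1500], fit_s.states[2500:])
        np.testing.assert_array_equal(fit_f.states[1500:], fit_s.states[:2500])


class TestUnalteredMask:
    def _fit(self, means, transmat, states):
        params = HmmParams(rho=0.1, means=np.asarray(means, float),
                           sigmas=np.array([0.3, 0.3]),
                           transmat=np.asarray(transmat, float),
                           startprob=np.array([0.5, 0.5]))
        return HmmFit(params=params, states=np.asarray(states),
                      log_likelihoods=np.array([-1.0]), converged=True,
                      variance_floored=False)

    def test_state_nearest_zero_is_unaltered(self):
        fit = self._fit([0.05, 1.2], [[0.9, 0.1], [0.1, 0.9]], [0, 1, 0])
        np.testing.assert_array_equal(unaltered_mask(fit), [True, False, True])

    def test_tie_prefers_the_majority_state(self):
        # |means| tie at 0.5; state 0 has the larger stationary probability
        fit = self._fit([-0.5, 0.5], [[0.95, 0.05], [0.2, 0.8]], [0, 1, 1])
        np.testing.assert_array_equal(unaltered_mask(fit), [True, False, False])


class TestHmmNormalizePipeline:
    def test_recovers_truth_mask_on_region_structured_data(self):
        cfg = SimulationConfig(n=20_000, k=2, alpha=0.15, m=50, delta=2, seed=21)
        sim = simulate_experiment(cfg, synth_variable_params(cfg.n, seed=22))
        res = hmm_normalize(to_log2(sim.matrix), sim.design)
        agreement = np.mean(res.reference_set == ~sim.truth)
        assert agreement >= 0.95

    def test_identical_arms_yield_zero_m_after_pipeline(self, rng):
        values = rng.normal(9, 1, size=(60, 2))
        m = make_matrix(np.hstack([values, values]),
                        sample_ids=["T1", "T2", "R1", "R2"])
        d = GroupDesign({"T1": "treatment", "T2": "treatment",
                         "R1": "reference", "R2": "reference"})
        res = hmm_normalize(m, d)
        track = m_values(res.matrix, d)
        np.testing.assert_allclose(track.values, 0.0, atol=1e-10)
        assert res.fit is None
        assert "all variables unaltered" in res.summary()

    def test_model_wrapper_summary_reports_reference_size(self):
        cfg = SimulationConfig(n=5_000, k=2, alpha=0.25, m=50, delta=2, seed=31)
        sim = simulate_experiment(cfg, synth_variable_params(cfg.n, seed=32))
        res = HMMNormalizer(to_log2(sim.matrix), sim.design).fit()
        assert res.method == "hmm"
        assert 0.6 < res.reference_set.mean() < 0.9
        assert "unaltered (reference)" in res.summary()

    def test_skewed_data_renormalization_removes_the_negative_offset(self):
        """Standard normalization drags unaltered M-values below zero on a
        skewed experiment; the HMM re-normalization recenters them."""
        from dsenorm import quantile_normalize
        cfg = SimulationConfig(n=20_000, k=2, alpha=0.25, m=50, delta=1.5, seed=41)
        sim = simulate_experiment(cfg, synth_variable_params(cfg.n, seed=42))
        log2m = to_log2(sim.matrix)
        std_track = m_values(quantile_normalize(log2m).matrix, sim.design)
        hmm_track = m_values(hmm_normalize(log2m, sim.design).matrix, sim.design)
        std_offset = std_track.values[~sim.truth].mean()
        hmm_offset = hmm_track.values[~sim.truth].mean()
        assert std_offset < -0.05
        assert abs(hmm_offset) < 0.05
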