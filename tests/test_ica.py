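"""ICA decomposition and artifact-rejection tests."""

import numpy as np
import pytest

import sdar
from sdar.ica import (build_rejection_mask, fit_fastica, highpass_for_ica,
                      remove_and_reconstruct, score_components,
                      threshold_3sigma)
from sdar.synthetic import frontal_indices


def _as_trialset(data_2d, fs=250.0):
    """Wrap a (channels, samples) array as a single-trial TrialSet."""
    c = data_2d.shape[0]
    pos = sdar.synthetic_montage(max(8, c))[:c]
    pos = pos / np.linalg.norm(pos, axis=1, keepdims=True)
    return sdar.TrialSet(data_2d[None], fs, [f"C{i}" for i in range(c)],
                         pos, np.zeros(1, int))


class TestHighpass:
    def test_frequency_response(self):
        fs, t = 250.0, np.arange(5000) / 250.0
        rms = lambda x: np.sqrt(np.mean(x**2))
        slow = _as_trialset(np.tile(np.sin(2 * np.pi * 0.1 * t), (8, 1)))
        fast = _as_trialset(np.tile(np.sin(2 * np.pi * 10.0 * t), (8, 1)))
        assert rms(highpass_for_ica(slow).data) < 0.05 * rms(slow.data)
        assert rms(highpass_for_ica(fast).data) > 0.95 * rms(fast.data)

    def test_zero_in_zero_out(self):
        ts = _as_trialset(np.zeros((8, 500)))
        assert np.all(highpass_for_ica(ts).data == 0)

    def test_short_trial_error(self):
        ts = _as_trialset(np.random.default_rng(0).standard_normal((8, 20)))
        with pytest.raises(ValueError):
            highpass_for_ica(ts)


class TestFastICA:
    def test_recovers_independent_sources(self):
        rng = np.random.default_rng(1)
        S = rng.uniform(-1, 1, (2, 20000))
        A = np.array([[1.0, 0.6], [0.4, 1.0]])
        ts = _as_trialset(A @ S)
        ica = fit_fastica(ts, seed=0)
        corr = np.corrcoef(np.vstack([ica.sources_S, S]))[:2, 2:]
        assert np.abs(corr).max(axis=1).min() > 0.99

    def test_reconstruction_and_unit_variance(self, contaminated_session):
        ts, _ = contaminated_session
        hp = highpass_for_ica(ts)
        ica = fit_fastica(hp, seed=0)
        keep_all = build_rejection_mask(
            np.zeros((ica.n_components_Q, 1)), gamma=np.inf)
        recon = remove_and_reconstruct(hp, ica, keep_all)
        rel = (np.linalg.norm(recon.data - hp.data)
               / np.linalg.norm(hp.data))
        assert rel < 1e-6
        assert np.allclose(ica.sources_S.var(axis=1), 1.0, atol=1e-6)

    def test_determinism(self, small_session):
        ts, _ = small_session
        hp = highpass_for_ica(ts)
        a = fit_fastica(hp, seed=5)
        b = fit_fastica(hp, seed=5)
        np.testing.assert_array_equal(a.sources_S, b.sources_S)

    def test_too_few_samples(self):
        ts = _as_trialset(np.random.default_rng(0).standard_normal((16, 500)))
        with pytest.raises(ValueError):
            fit_fastica(ts)


class TestScoring:
    def test_component_equals_reference(self, small_session):
        ts, _ = small_session
        hp = highpass_for_ica(ts)
        ica = fit_fastica(hp, seed=0)
        ref = ica.sources_by_trial()[2]
        scores = score_components(ica, ref)
        assert scores[2, 0] == pytest.approx(1.0, abs=1e-12)
        # scaling the reference by -5 leaves the |r| score unchanged
        scores_scaled = score_components(ica, -5.0 * ref)
        assert scores_scaled[2, 0] == pytest.approx(scores[2, 0], abs=1e-12)

    def test_independent_noise_scores_low(self, small_session):
        ts, _ = small_session
        hp = highpass_for_ica(ts)
        ica = fit_fastica(hp, seed=0)
        rng = np.random.default_rng(7)
        ref = rng.standard_normal((ica.n_trials, ica.n_samples))
        scores = score_components(ica, ref)
        # mean |r| over 12 trials of length 750: null level ~ 1/sqrt(750)
        assert scores.max() < 0.1

    def test_zero_variance_reference_warns(self, small_session):
        ts, _ = small_session
        hp = highpass_for_ica(ts)
        ica = fit_fastica(hp, seed=0)
        with pytest.warns(RuntimeWarning):
            scores = score_components(
                ica, np.zeros((ica.n_trials, ica.n_samples)))
        assert np.all(scores == 0)


class TestThreshold:
    def test_equal_scores_reject_nothing(self):
        with pytest.warns(RuntimeWarning):
            gamma = threshold_3sigma(np.full(10, 0.3))
        assert gamma == np.inf

    def test_single_outlier_rejected(self):
        scores = np.full(64, 0.05)
        scores[17] = 0.9
        gamma = threshold_3sigma(scores)
        mask = build_rejection_mask(scores[:, None], gamma=gamma)
        assert np.flatnonzero(~mask.keep).tolist() == [17]

    def test_gaussian_rejection_fraction(self):
        # mean + 3 sd cuts ~ P(z > 3) = 0.00135 of a Gaussian sample
        vals = np.random.default_rng(0).normal(0.2, 0.05, 10_000)
        gamma = threshold_3sigma(vals)
        frac = np.mean(vals > gamma)
        assert 0.0005 < frac < 0.0025


class TestRemoveReconstruct:
    def test_projection_idempotent(self, contaminated_session):
        ts, truth = contaminated_session
        hp = highpass_for_ica(ts)
        ica = fit_fastica(hp, seed=0)
        scores = score_components(ica, truth.eog_reference)
        mask = build_rejection_mask(scores)
        once = remove_and_reconstruct(hp, ica, mask)
        twice = remove_and_reconstruct(once, ica, mask)
        assert np.abs(twice.data - once.data).max() < 1e-8

    def test_all_rejected_error(self, small_session):
        ts, _ = small_session
        hp = highpass_for_ica(ts)
        ica = fit_fastica(hp, seed=0)
        mask = build_rejection_mask(
            np.ones((ica.n_components_Q, 1)), gamma=0.5)
        with pytest.raises(ValueError):
            remove_and_reconstruct(hp, ica, mask)


class TestCleanupEndToEnd:
    @pytest.mark.parametrize("seed", [0, 1])
    def test_blink_correlation_drops(self, seed):
        ts, truth = sdar.generate_mi_trials(n_trials=40, seed=seed)
        dirty, truth2 = sdar.inject_eog(ts, truth, amplitude_uv=150.0,
                                        seed=seed + 40)
        cleaned, _, _ = sdar.clean_eog(dirty,
                                       references=truth2.eog_reference,
                                       seed=0)
        fi = frontal_indices(ts.positions)[0]
        ref = truth2.eog_reference.ravel()
        before = abs(np.corrcoef(
            highpass_for_ica(dirty).data[:, fi, :].ravel(), ref)[0, 1])
        after = abs(np.corrcoef(cleaned.data[:, fi, :].ravel(), ref)[0, 1])
        assert after < before

    def test_uncorrelated_reference_leaves_data_untouched(self, small_session):
        # references are only used for scoring: a reference that matches
        # no component must produce a no-op cleanup of the high-passed data
        ts, _ = small_session
        rng = np.random.default_rng(3)
        noise_ref = rng.standard_normal((ts.n_trials, ts.n_samples))
        cleaned, masks, _ = sdar.clean_eog(ts, references=noise_ref,
                                           seed=0, passes=1)
        assert masks[0].n_rejected == 0
        np.testing.assert_allclose(cleaned.data,
                                   highpass_for_ica(ts).data, atol=1e-9)
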