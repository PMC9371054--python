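"""Functional-connectivity estimator and feature-assembly tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sdar
from sdar.connectivity import (RHYTHM_BANDS, bandpass, build_features,
                               crop_window, fc_coherence, fc_gaussian,
                               fc_motifs, fc_pearson, fc_plv)


def _trials(data, fs=250.0, window=(0.0, None)):
    n, c, t = data.shape
    pos = sdar.synthetic_montage(max(8, c))[:c]
    end = window[1] if window[1] is not None else t / fs
    return sdar.TrialSet(data, fs, [f"C{i}" for i in range(c)], pos,
                         np.zeros(n, int), window=(window[0], end))


class TestBandpassCrop:
    def test_bandpass_response(self):
        fs, t = 250.0, np.arange(2000) / 250.0
        rms = lambda x: np.sqrt(np.mean(x**2))
        in_band = _trials(np.tile(np.sin(2 * np.pi * 10 * t), (1, 8, 1)))
        out_band = _trials(np.tile(np.sin(2 * np.pi * 30 * t), (1, 8, 1)))
        bp_in = bandpass(in_band, (8, 12))
        bp_out = bandpass(out_band, (8, 12))
        assert rms(bp_in.data) > 0.9 * rms(in_band.data)
        assert rms(bp_out.data) < 0.05 * rms(out_band.data)
        assert np.all(bandpass(_trials(np.zeros((1, 8, 500))), (8, 12)).data == 0)

    def test_band_above_nyquist_errors(self):
        ts = _trials(np.zeros((1, 8, 500)), fs=60.0)
        with pytest.raises(ValueError):
            bandpass(ts, (8, 40))

    @pytest.mark.parametrize("fs,win,expected", [
        (250.0, (0.5, 3.5), 750),
        (512.0, (0.5, 2.5), 1024),
    ])
    def test_crop_sample_counts(self, fs, win, expected):
        n = int(4.0 * fs)
        ts = _trials(np.zeros((2, 8, n)), fs=fs, window=(0.0, 4.0))
        assert crop_window(ts, *win).n_samples == expected

    def test_crop_identity_and_errors(self):
        ts = _trials(np.random.default_rng(0).standard_normal((2, 8, 500)),
                     window=(0.0, 2.0))
        np.testing.assert_array_equal(crop_window(ts, 0.0, 2.0).data, ts.data)
        with pytest.raises(ValueError):
            crop_window(ts, 1.0, 1.0)
        with pytest.raises(ValueError):
            crop_window(ts, 0.0, 3.0)


class TestPairwiseEstimators:
    def test_identity_cases_are_one(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(512)
        assert fc_pearson(x, x) == pytest.approx(1.0, abs=1e-12)
        assert fc_motifs(x, x) == 1.0
        assert fc_gaussian(x, x, sigma=1.0) == 1.0
        assert fc_coherence(x, x, fs=250.0) == pytest.approx(1.0, abs=1e-12)
        assert fc_plv(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_pearson_sign_and_hand_computed(self):
        x = np.array([2.0, 4, 1, 7, 3, 6, 5, 8])
        y = np.array([1.0, 3, 2, 6, 5, 4, 8, 7])
        assert fc_pearson(x, -x) == pytest.approx(-1.0, abs=1e-12)
        # brute-force oracle
        xc, yc = x - x.mean(), y - y.mean()
        expected = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        assert fc_pearson(x, y) == pytest.approx(expected, abs=1e-12)

    def test_pearson_zero_variance_warns(self):
        with pytest.warns(RuntimeWarning):
            assert fc_pearson(np.ones(10), np.arange(10.0)) == 0.0

    def test_motifs_monotone_sequences(self):
        up = np.arange(50.0)
        assert fc_motifs(up, up[::-1]) == 0.0
        assert fc_motifs(up, up + 100.0) == 1.0

    def test_motifs_null_coincidence(self):
        # independent sequences: 6 equiprobable degree-3 patterns -> 1/6
        rng = np.random.default_rng(11)
        f = fc_motifs(rng.standard_normal(100_000),
                      rng.standard_normal(100_000))
        assert f == pytest.approx(1.0 / 6.0, abs=0.01)

    def test_gaussian_closed_form_and_oracle(self):
        d = 2.3
        x = np.zeros(16)
        assert fc_gaussian(x, x + d, sigma=d) == pytest.approx(
            np.exp(-0.5), abs=1e-12)
        rng = np.random.default_rng(5)
        a, b = rng.standard_normal(8), rng.standard_normal(8)
        manual = np.mean([np.exp(-(ai - bi) ** 2 / 2.0)
                          for ai, bi in zip(a, b)])
        assert fc_gaussian(a, b, sigma=1.0) == pytest.approx(manual, abs=1e-12)
        with pytest.raises(ValueError):
            fc_gaussian(a, b, sigma=0.0)

    def test_coherence_delay_invariance_and_null(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(512)
        delayed = np.roll(x, 5)
        # single segment: a pure delay preserves coherence magnitude
        assert fc_coherence(x, delayed, fs=250.0,
                            nperseg=512) == pytest.approx(1.0, abs=1e-10)
        a = rng.standard_normal(10_000)
        b = rng.standard_normal(10_000)
        assert fc_coherence(a, b, fs=250.0) < 0.45

    def test_plv_constant_phase_and_null(self):
        t = np.arange(1000) / 250.0
        x = np.sin(2 * np.pi * 10 * t)
        y = np.sin(2 * np.pi * 10 * t + np.pi / 3)
        assert fc_plv(x, y) == pytest.approx(1.0, abs=1e-3)
        rng = np.random.default_rng(8)
        band = _trials(rng.standard_normal((1, 8, 10_000)))
        bp = bandpass(band, (8, 12)).data[0]
        assert fc_plv(bp[0], bp[1]) < 0.1

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_symmetry_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.standard_normal((2, 128))
        for fc, kwargs in [(fc_pearson, {}), (fc_motifs, {}),
                           (fc_gaussian, {"sigma": 1.0}),
                           (fc_coherence, {"fs": 250.0}), (fc_plv, {})]:
            a = fc(x, y, **kwargs)
            b = fc(y, x, **kwargs)
            assert a == pytest.approx(b, abs=1e-10)
            if fc is fc_pearson:
                assert -1.0 <= a <= 1.0
            else:
                assert 0.0 <= a <= 1.0 + 1e-12


class TestFeatureAssembly:
    @pytest.mark.parametrize("c,expected", [(16, 480), (22, 924), (64, 8064)])
    def test_dimensionality(self, c, expected):
        rng = np.random.default_rng(c)
        ts = _trials(rng.standard_normal((2, c, 256)))
        feats, pair_index = build_features(ts, measure="pearson")
        assert feats.shape == (2, expected)
        assert len(pair_index) == expected

    def test_pair_index_well_formed(self):
        ts = _trials(np.random.default_rng(0).standard_normal((1, 8, 256)))
        _, pair_index = build_features(ts, measure="pearson")
        assert len(set(pair_index)) == len(pair_index)
        assert all(i < j for _, i, j in pair_index)
        assert [b for b, _, _ in pair_index] == sum(
            [[name] * 28 for name, _, _ in RHYTHM_BANDS], [])

    def test_unknown_measure(self):
        ts = _trials(np.zeros((1, 8, 256)))
        with pytest.raises(ValueError):
            build_features(ts, measure="granger")

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(9)
        data = rng.standard_normal((2, 8, 300))
        perm = rng.permutation(8)
        ts = _trials(data)
        tsp = _trials(data[:, perm, :])
        f, _ = build_features(ts, measure="pearson")
        fp, _ = build_features(tsp, measure="pearson")
        # the multiset of pair values per trial/band is unchanged
        for t in range(2):
            for b in range(4):
                sl = slice(b * 28, (b + 1) * 28)
                np.testing.assert_allclose(np.sort(f[t, sl]),
                                           np.sort(fp[t, sl]), atol=1e-10)

    @pytest.mark.parametrize("measure", sdar.MEASURES)
    def test_bounds_on_generated_data(self, measure, small_session):
        ts, _ = small_session
        feats, _ = build_features(ts, measure=measure, window=(0.5, 2.5))
        if measure == "pearson":
            assert np.all((feats >= -1) & (feats <= 1))
        else:
            assert np.all((feats >= 0) & (feats <= 1 + 1e-12))
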