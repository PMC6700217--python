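"""Welch PSD, coherence, band normalization and feature assembly."""

import numpy as np
import pytest

from conftest import make_noise_epochs
from corticolfp.bands import DEFAULT_BAND_SCHEME, BandScheme
from corticolfp.preprocessing import EpochSet
from corticolfp.recording import CHANNEL_PAIRS, CHANNELS
from corticolfp.spectral import (
    SpectralEstimate,
    all_pair_coherence,
    band_coherence_features,
    band_power_features,
    build_feature_vector,
    combine_sessions,
    epoch_coherence,
    epoch_psd,
    extract_features,
    feature_names,
)


def make_tone_epochs(freq, fs=400.0, n_epochs=5, epoch_length=3.0, n_channels=2,
                     amplitude=1.0, phase_step=0.7):
    n = int(epoch_length * fs)
    eps = []
    for k in range(n_epochs):
        t = np.arange(n) / fs
        x = amplitude * np.sin(2 * np.pi * freq * t + k * phase_step)
        eps.append(np.tile(x, (n_channels, 1)))
    return EpochSet(
        epochs=eps, epoch_length=epoch_length, fs=fs,
        channel_labels=CHANNELS[:n_channels],
    )


class TestEpochPsd:
    def test_grid_resolution_is_inverse_window(self):
        eps = make_noise_epochs(0)
        est = epoch_psd(eps, window_length=1.28)
        assert est.freqs[1] - est.freqs[0] == pytest.approx(0.78125)

    def test_tone_peak_at_tone_frequency(self):
        est = epoch_psd(make_tone_epochs(8.0))
        peak = est.freqs[np.argmax(est.psd_linear[0])]
        assert abs(peak - 8.0) <= 0.78125

    def test_parseval_white_noise(self):
        """Integrated density PSD recovers the signal variance within 10%."""
        ratios = []
        for seed in range(10):
            eps = make_noise_epochs(seed, n_epochs=20)
            var = np.var(np.concatenate([e[0] for e in eps.epochs]))
            est = epoch_psd(eps)
            total = np.trapezoid(est.psd_linear[0], est.freqs)
            ratios.append(total / var)
        assert abs(np.mean(ratios) - 1.0) < 0.1

    def test_empty_epochset_rejected(self):
        eps = EpochSet(epochs=[], epoch_length=3.0, fs=400.0,
                       channel_labels=CHANNELS[:2])
        with pytest.raises(ValueError, match="empty"):
            epoch_psd(eps)

    def test_window_longer_than_epoch_rejected(self):
        with pytest.raises(ValueError, match="window_length"):
            epoch_psd(make_noise_epochs(0), window_length=5.0)


class TestEpochCoherence:
    def test_identical_channels_coherence_one(self):
        eps = make_tone_epochs(8.0)  # both channels identical
        # identical broadband noise gives 1 at every frequency too
        noisy = make_noise_epochs(3, n_channels=1)
        dup = EpochSet(
            epochs=[np.vstack([e, e]) for e in noisy.epochs],
            epoch_length=noisy.epoch_length, fs=noisy.fs,
            channel_labels=CHANNELS[:2],
        )
        _, c = epoch_coherence(dup, ("lNAcSh", "rNAcSh"))
        assert np.allclose(c, 1.0, atol=1e-9)

    def test_pure_delay_preserves_coherence(self):
        """10 ms delay leaves magnitude-squared coherence ~1."""
        rng = np.random.default_rng(4)
        fs, n, lag = 400.0, 1200, 4  # 4 samples = 10 ms
        x = rng.standard_normal(n + lag)
        eps = EpochSet(
            epochs=[np.vstack([x[lag:], x[:-lag]])],
            epoch_length=3.0, fs=fs, channel_labels=CHANNELS[:2],
        )
        f, c = epoch_coherence(eps, ("lNAcSh", "rNAcSh"))
        m = (f >= 1) & (f <= 90)
        assert c[m].mean() > 0.95

    def test_independent_noise_bias_floor_shrinks_with_windows(self):
        """MSC bias floor falls as windows per epoch grow (1/L behavior)."""
        short = np.mean([  # ~3-4 windows per 3 s epoch
            epoch_coherence(make_noise_epochs(s, n_epochs=8, epoch_length=3.0),
                            ("lNAcSh", "rNAcSh"))[1].mean()
            for s in range(5)
        ])
        long = np.mean([  # ~17-18 windows per 12 s epoch
            epoch_coherence(make_noise_epochs(s, n_epochs=2, epoch_length=12.0),
                            ("lNAcSh", "rNAcSh"))[1].mean()
            for s in range(5)
        ])
        assert short > 2 * long > 0

    def test_missing_channel_rejected(self):
        with pytest.raises(ValueError, match="not present"):
            epoch_coherence(make_noise_epochs(0), ("lNAcSh", "rmPFC"))


def constant_estimate(psd_value_db=20.0, coherence_value=0.4):
    freqs = np.arange(0, 200.0001, 0.78125)
    n = len(freqs)
    psd_db = np.full((4, n), psd_value_db)
    return SpectralEstimate(
        freqs=freqs,
        psd_db=psd_db,
        psd_linear=10 ** (psd_db / 10.0),
        coherence={p: np.full(n, coherence_value) for p in CHANNEL_PAIRS},
        channel_labels=CHANNELS,
        n_epochs=10,
    )


class TestBandNormalization:
    def test_constant_spectrum_gives_all_100(self):
        est = constant_estimate()
        power = band_power_features(est)
        for ch in CHANNELS:
            for band in DEFAULT_BAND_SCHEME.bands:
                assert power[ch][band] == pytest.approx(100.0)
        coh = band_coherence_features(est)
        for pair in CHANNEL_PAIRS:
            for band in DEFAULT_BAND_SCHEME.bands:
                assert coh[pair][band] == pytest.approx(100.0)

    def test_notch_bins_excluded_from_low_gamma(self):
        """Raising only the 59-61 Hz bins must not change any feature."""
        est = constant_estimate()
        bumped = constant_estimate()
        m = (est.freqs > 59) & (est.freqs < 61)
        assert m.any()
        bumped.psd_db[:, m] += 30.0
        assert band_power_features(bumped) == band_power_features(est)

    def test_uniform_db_shift_follows_closed_form(self):
        """+3.01 dB everywhere rescales features as 100(b+3.01)/(t+3.01)."""
        rng = np.random.default_rng(2)
        est = constant_estimate()
        est.psd_db = est.psd_db + rng.uniform(-5, 5, est.psd_db.shape)
        shifted = constant_estimate()
        shifted.psd_db = est.psd_db + 3.01
        base = band_power_features(est)
        shift = band_power_features(shifted)
        scheme = DEFAULT_BAND_SCHEME
        norm = scheme.norm_mask(est.freqs)
        for i, ch in enumerate(CHANNELS):
            t = est.psd_db[i][norm].mean()
            for band in scheme.bands:
                b = est.psd_db[i][scheme.band_mask(est.freqs, band)].mean()
                assert shift[ch][band] == pytest.approx(
                    100 * (b + 3.01) / (t + 3.01)
                )
            # ordering of band features preserved under the shift
            order = sorted(scheme.bands, key=lambda k: base[ch][k])
            assert order == sorted(scheme.bands, key=lambda k: shift[ch][k])

    def test_band_with_no_bins_rejected(self):
        est = constant_estimate()
        est.freqs = est.freqs * 10  # grid too coarse for 1-4 Hz delta
        with pytest.raises(ValueError, match="no frequency bins"):
            band_power_features(est)


class TestFeatureVector:
    def test_sixty_named_features(self):
        est = constant_estimate()
        fv = build_feature_vector(
            band_power_features(est), band_coherence_features(est), "rat01"
        )
        assert len(fv.values) == 60
        names = list(fv.values)
        assert sum(n.endswith("_pow") for n in names) == 24
        assert sum(n.endswith("_coh") for n in names) == 36
        assert names == feature_names()
        assert names[0] == "lNAcSh_delta_pow"

    def test_six_pairs_from_four_channels(self):
        assert len(CHANNEL_PAIRS) == 6
        est = constant_estimate()
        assert len(band_coherence_features(est)) == 6

    def test_missing_coherence_pair_rejected(self):
        est = constant_estimate()
        coh = band_coherence_features(est)
        coh.pop(("lmPFC", "rmPFC"))
        with pytest.raises(ValueError, match="lmPFC-rmPFC"):
            build_feature_vector(band_power_features(est), coh)

    def test_session_combination_is_entrywise_mean(self):
        est = constant_estimate()
        fv1 = build_feature_vector(
            band_power_features(est), band_coherence_features(est), "r"
        )
        est2 = constant_estimate()
        est2.psd_db = est2.psd_db + np.linspace(0, 3, est2.psd_db.shape[1])
        fv2 = build_feature_vector(
            band_power_features(est2), band_coherence_features(est2), "r"
        )
        combined = combine_sessions([fv1, fv2])
        for k in fv1.values:
            assert combined.values[k] == pytest.approx(
                (fv1.values[k] + fv2.values[k]) / 2
            )

    def test_feature_count_formula_other_configs(self):
        """n_ch x n_bands + C(n_ch,2) x n_bands for a 2-channel setup."""
        eps = make_noise_epochs(1, n_channels=2)
        fv = extract_features(eps)
        n_bands = len(DEFAULT_BAND_SCHEME.bands)
        assert len(fv.values) == 2 * n_bands + 1 * n_bands


class TestBandScheme:
    def test_default_scheme_constants(self):
        s = DEFAULT_BAND_SCHEME
        assert s.bands["delta"] == (1.0, 4.0)
        assert s.bands["hgamma"] == (70.0, 90.0)
        assert s.norm_range == (1.0, 90.0)
        assert s.exclusion == (59.0, 61.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(bands={"a": (1, 10), "b": (5, 20)}),  # overlap
            dict(bands={"a": (1, 95)}),  # outside norm range
            dict(exclusion=(0.5, 61)),  # exclusion outside norm range
        ],
    )
    def test_invalid_schemes_rejected(self, kwargs):
        with pytest.raises(ValueError):
            BandScheme(**kwargs)


class TestDirectionalRecovery:
    def test_gamma_offset_raises_gamma_power_features(self):
        """+6 dB gamma group shows higher *_lgamma_pow than baseline."""
        from corticolfp.preprocessing import preprocess
        from corticolfp.synthetic import SubjectSpec, generate_recording

        diffs = []
        for seed in range(4):
            base = SubjectSpec(subject_id="ld")
            hot = SubjectSpec(
                subject_id="hd",
                band_power_offsets={"lgamma": 6.0, "hgamma": 6.0},
            )
            f_base = extract_features(
                preprocess(generate_recording(base, 30.0, 2000.0, seed=seed))
            )
            f_hot = extract_features(
                preprocess(generate_recording(hot, 30.0, 2000.0, seed=seed))
            )
            diffs.append(
                np.mean([f_hot.values[k] - f_base.values[k]
                         for k in f_base.values if k.endswith("_lgamma_pow")])
            )
        assert np.mean(diffs) > 0
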