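"""Welch band power and magnitude-squared coherence features.

Per-epoch power spectral densities use a 1.28 s Hamming window with 50%
overlap; per-epoch estimates are averaged (linear domain) into one
representative spectrum per recording session, then converted to dB.
Band summaries are averages of the dB spectrum (or coherence spectrum)
over each band's grid bins, normalized as a percent of the 1-90 Hz
broadband average with the 59-61 Hz notch bins excluded from every sum.

With 4 channels and 6 bands a session yields 60 features: 24 power
(channels x bands) and 36 coherence (pairs x bands).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal

from .bands import DEFAULT_BAND_SCHEME, BandScheme
from .preprocessing import EpochSet
from .recording import CHANNEL_PAIRS, CHANNELS

__all__ = [
    "SpectralEstimate",
    "FeatureVector",
    "epoch_psd",
    "epoch_coherence",
    "all_pair_coherence",
    "band_power_features",
    "band_coherence_features",
    "build_feature_vector",
    "combine_sessions",
    "extract_features",
    "feature_names",
]


#: dB reference: recordings are in mV but spectra are expressed in dB re
#: 1 uV^2/Hz, the conventional reference for extracellular signals. This
#: keeps the broadband dB average positive for physiological amplitudes,
#: which the percent-of-broadband normalization relies on (a negative
#: normalizer would invert the direction of every power feature).
DB_REF_UV2 = 1e6  # (1 mV)^2 = 1e6 uV^2


@dataclass
class SpectralEstimate:
    """Session-level averaged spectra on a common frequency grid."""

    freqs: np.ndarray
    psd_db: np.ndarray  # (n_channels, n_freqs), dB re 1 uV^2/Hz
    psd_linear: np.ndarray  # (n_channels, n_freqs), mean linear PSD (mV^2/Hz)
    coherence: Dict[Tuple[str, str], np.ndarray]  # pair -> (n_freqs,)
    channel_labels: Tuple[str, ...]
    n_epochs: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        for pair, coh in self.coherence.items():
            if np.any((coh < 0) | (coh > 1 + 1e-9)):
                raise ValueError(f"coherence for {pair} outside [0, 1]")


@dataclass
class FeatureVector:
    """The named percent-scale features for one subject (60 by default)."""

    values: Dict[str, float]
    subject_id: str = ""

    def __post_init__(self) -> None:
        bad = [k for k, v in self.values.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite feature values: {bad}")

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, name=self.subject_id)


def _welch_params(fs: float, window_length: float, overlap_fraction: float):
    if not 0 <= overlap_fraction < 1:
        raise ValueError("overlap_fraction must be in [0, 1)")
    nperseg = int(round(window_length * fs))
    if nperseg < 2:
        raise ValueError("window too short for the sampling rate")
    noverlap = int(round(overlap_fraction * nperseg))
    return dict(
        window=signal.get_window("hamming", nperseg),
        nperseg=nperseg,
        noverlap=noverlap,
        detrend=False,
        scaling="density",
    )


def epoch_psd(
    epochs: EpochSet,
    window_length: float = 1.28,
    overlap_fraction: float = 0.5,
) -> SpectralEstimate:
    """Welch PSD per epoch, averaged across epochs, for every channel.

    The frequency grid spacing is ``1 / window_length`` (0.78125 Hz for a
    1.28 s window). Raises on an empty EpochSet or a window longer than
    the epoch.
    """
    if epochs.n_epochs == 0:
        raise ValueError("cannot estimate spectra from an empty EpochSet")
    if window_length > epochs.epoch_length + 1e-12:
        raise ValueError("window_length must not exceed epoch_length")
    params = _welch_params(epochs.fs, window_length, overlap_fraction)
    acc = None
    freqs = None
    for ep in epochs.epochs:
        freqs, pxx = signal.welch(ep, fs=epochs.fs, axis=1, **params)
        acc = pxx if acc is None else acc + pxx
    mean_psd = acc / epochs.n_epochs
    with np.errstate(divide="ignore"):
        psd_db = 10.0 * np.log10(DB_REF_UV2 * mean_psd)
    return SpectralEstimate(
        freqs=freqs,
        psd_db=psd_db,
        psd_linear=mean_psd,
        coherence={},
        channel_labels=epochs.channel_labels,
        n_epochs=epochs.n_epochs,
    )


def epoch_coherence(
    epochs: EpochSet,
    pair: Tuple[str, str],
    window_length: float = 1.28,
    overlap_fraction: float = 0.5,
) -> Tuple[np.ndarray, np.ndarray]:
    """Magnitude-squared coherence for one channel pair.

    Per epoch, Welch cross- and auto-spectra with the stated windowing
    give a coherence spectrum; spectra are averaged across epochs.
    Returns ``(freqs, coherence)`` with coherence in [0, 1].
    """
    if epochs.n_epochs == 0:
        raise ValueError("cannot estimate coherence from an empty EpochSet")
    if window_length > epochs.epoch_length + 1e-12:
        raise ValueError("window_length must not exceed epoch_length")
    for lab in pair:
        if lab not in epochs.channel_labels:
            raise ValueError(f"channel {lab!r} not present")
    ia = epochs.channel_labels.index(pair[0])
    ib = epochs.channel_labels.index(pair[1])
    params = _welch_params(epochs.fs, window_length, overlap_fraction)
    params.pop("scaling")  # coherence is scale-free
    acc = None
    freqs = None
    for ep in epochs.epochs:
        freqs, cxy = signal.coherence(ep[ia], ep[ib], fs=epochs.fs, **params)
        acc = cxy if acc is None else acc + cxy
    return freqs, np.clip(acc / epochs.n_epochs, 0.0, 1.0)


def all_pair_coherence(
    epochs: EpochSet,
    window_length: float = 1.28,
    overlap_fraction: float = 0.5,
) -> SpectralEstimate:
    """PSDs plus coherence spectra for every channel pair in one container."""
    est = epoch_psd(epochs, window_length, overlap_fraction)
    pairs = tuple(
        (a, b)
        for i, a in enumerate(epochs.channel_labels)
        for b in epochs.channel_labels[i + 1 :]
    )
    coh = {}
    for pair in pairs:
        _, cxy = epoch_coherence(epochs, pair, window_length, overlap_fraction)
        coh[pair] = cxy
    est.coherence = coh
    return est


def _band_percent(
    freqs: np.ndarray, spectrum: np.ndarray, scheme: BandScheme
) -> Dict[str, float]:
    """Percent-of-broadband band averages of one spectrum."""
    norm_mask = scheme.norm_mask(freqs)
    if not norm_mask.any():
        raise ValueError("normalization range contains no frequency bins")
    total = float(np.mean(spectrum[norm_mask]))
    if total == 0.0:
        raise ValueError("degenerate spectrum: zero broadband normalizer")
    out = {}
    for band in scheme.bands:
        mask = scheme.band_mask(freqs, band)
        if not mask.any():
            raise ValueError(
                f"band {band!r} contains no frequency bins; grid too coarse"
            )
        out[band] = 100.0 * float(np.mean(spectrum[mask])) / total
    return out


def band_power_features(
    est: SpectralEstimate,
    scheme: BandScheme = DEFAULT_BAND_SCHEME,
    domain: str = "db",
) -> Dict[str, Dict[str, float]]:
    """Per-channel band power as percent of broadband power.

    Band power is the average of the session PSD over the band's bins
    (59-61 Hz excluded), divided by the average over the full 1-90 Hz
    normalization range (same exclusion) and scaled to percent. Averages
    are taken on the dB spectrum by default; ``domain="linear"`` uses the
    linear PSD instead.
    """
    if domain not in ("db", "linear"):
        raise ValueError("domain must be 'db' or 'linear'")
    lo, hi = est.freqs[0], est.freqs[-1]
    if scheme.norm_range[0] < lo or scheme.norm_range[1] > hi:
        raise ValueError("normalization range outside the estimated grid")
    spectra = est.psd_db if domain == "db" else est.psd_linear
    return {
        ch: _band_percent(est.freqs, spectra[i], scheme)
        for i, ch in enumerate(est.channel_labels)
    }


def band_coherence_features(
    est: SpectralEstimate,
    scheme: BandScheme = DEFAULT_BAND_SCHEME,
) -> Dict[Tuple[str, str], Dict[str, float]]:
    """Per-pair band coherence as percent of the broadband mean coherence."""
    if not est.coherence:
        raise ValueError("estimate carries no coherence spectra")
    return {
        pair: _band_percent(est.freqs, coh, scheme)
        for pair, coh in est.coherence.items()
    }


def feature_names(
    channels: Sequence[str] = CHANNELS,
    pairs: Sequence[Tuple[str, str]] = CHANNEL_PAIRS,
    scheme: BandScheme = DEFAULT_BAND_SCHEME,
) -> List[str]:
    """Canonical feature ordering: power by channel, then coherence by pair."""
    names = [f"{ch}_{band}_pow" for ch in channels for band in scheme.bands]
    names += [f"{a}-{b}_{band}_coh" for a, b in pairs for band in scheme.bands]
    return names


def build_feature_vector(
    power: Mapping[str, Mapping[str, float]],
    coherence: Mapping[Tuple[str, str], Mapping[str, float]],
    subject_id: str = "",
    channels: Sequence[str] = CHANNELS,
    pairs: Sequence[Tuple[str, str]] = CHANNEL_PAIRS,
    scheme: BandScheme = DEFAULT_BAND_SCHEME,
) -> FeatureVector:
    """Assemble the named feature vector in the canonical order.

    Validates that every channel, pair and band is present; with the
    default 4 channels / 6 pairs / 6 bands this yields 60 entries.
    """
    missing = [ch for ch in channels if ch not in power]
    missing += [f"{a}-{b}" for a, b in pairs if (a, b) not in coherence]
    if missing:
        raise ValueError(f"missing channels/pairs: {missing}")
    values: Dict[str, float] = {}
    for ch in channels:
        for band in scheme.bands:
            if band not in power[ch]:
                raise ValueError(f"missing band {band!r} for channel {ch!r}")
            values[f"{ch}_{band}_pow"] = float(power[ch][band])
    for a, b in pairs:
        for band in scheme.bands:
            if band not in coherence[(a, b)]:
                raise ValueError(f"missing band {band!r} for pair {a}-{b}")
            values[f"{a}-{b}_{band}_coh"] = float(coherence[(a, b)][band])
    return FeatureVector(values=values, subject_id=subject_id)


def combine_sessions(vectors: Sequence[FeatureVector]) -> FeatureVector:
    """Entrywise arithmetic mean of per-session feature vectors."""
    if not vectors:
        raise ValueError("no feature vectors to combine")
    keys = list(vectors[0].values)
    for v in vectors[1:]:
        if list(v.values) != keys:
            raise ValueError("feature vectors have mismatched names/order")
    combined = {
        k: float(np.mean([v.values[k] for v in vectors])) for k in keys
    }
    return FeatureVector(values=combined, subject_id=vectors[0].subject_id)


def extract_features(
    epochs: EpochSet,
    scheme: BandScheme = DEFAULT_BAND_SCHEME,
    window_length: float = 1.28,
    overlap_fraction: float = 0.5,
    power_domain: str = "db",
) -> FeatureVector:
    """EpochSet -> 60-entry FeatureVector (one recording session)."""
    est = all_pair_coherence(epochs, window_length, overlap_fraction)
    power = band_power_features(est, scheme, domain=power_domain)
    coh = band_coherence_features(est, scheme)
    pairs = tuple(coh.keys())
    return build_feature_vector(
        power,
        coh,
        subject_id=epochs.subject_id,
        channels=epochs.channel_labels,
        pairs=pairs,
        scheme=scheme,
    )
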