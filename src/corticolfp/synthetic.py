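"""Synthetic corticostriatal LFP cohorts with known ground truth.

Emulates the study design this package analyzes: a cohort of rats with
bilateral nucleus accumbens shell (NAcSh) and medial prefrontal cortex
(mPFC) electrodes (4 channels at 2 kHz), two free-behavior recording
sessions per animal, and 12 limited-access drinking sessions measured in
g/kg, followed by stimulation sessions. Group structure (high- vs.
low-drinker, HD/LD) is injected as controllable per-band power offsets,
inter-channel coherence couplings, drinking-mean differences, and a
stimulation-phase drop in consumption.

Signal model per channel: pink (1/f) background noise plus one
band-limited Gaussian process per frequency band. Band processes are
realized by zero-phase band-pass filtering of white noise; a channel
pair's coupling weight ``w`` replaces a fraction of each channel's
independent band process with a shared source such that the expected
magnitude-squared coherence contributed by the band equals ``w**2``
(exactly ``w**2`` when the background is zero).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import signal

from .bands import DEFAULT_BAND_SCHEME, BandScheme
from .recording import CHANNEL_PAIRS, CHANNELS, RawRecording

__all__ = [
    "SubjectSpec",
    "CohortSpec",
    "generate_recording",
    "inject_artifacts",
    "generate_drinking_table",
    "build_subject_specs",
    "pair_name",
]

ARTIFACT_DETECTION_THRESHOLD_MV = 2.0
ARTIFACT_WIDTH_S = 0.02  # half-sine transient width


def pair_name(a: str, b: str) -> str:
    return f"{a}-{b}"


OffsetMap = Mapping[str, Union[float, Mapping[str, float]]]


@dataclass
class SubjectSpec:
    """Ground-truth generative parameters for one subject.

    ``band_power_offsets`` maps band name to a dB offset, either a single
    float (all channels) or a per-channel mapping. ``coherence_coupling``
    maps a pair name (``"lNAcSh-rNAcSh"``) to per-band mixing weights in
    [0, 1]; weight 1 with zero background yields coherence ~1 in that band.
    """

    subject_id: str
    group: str = "LD"  # "HD" or "LD"
    band_power_offsets: Dict[str, Union[float, Dict[str, float]]] = field(default_factory=dict)
    coherence_coupling: Dict[str, Dict[str, float]] = field(default_factory=dict)
    artifact_rate: float = 0.0  # events per minute
    drinking_mean: float = 0.8  # g/kg per session
    drinking_sd: float = 0.2  # g/kg
    background_rms: float = 0.2  # mV, pink-noise floor
    band_rms: float = 0.05  # mV, per-band process at 0 dB offset

    def __post_init__(self) -> None:
        if self.group not in ("HD", "LD"):
            raise ValueError("group must be 'HD' or 'LD'")
        if self.artifact_rate < 0:
            raise ValueError("artifact_rate must be nonnegative")
        if self.drinking_sd < 0:
            raise ValueError("drinking_sd must be nonnegative")
        if self.drinking_mean < 0:
            raise ValueError("drinking_mean must be nonnegative")
        for pair, weights in self.coherence_coupling.items():
            for band, w in weights.items():
                if not 0.0 <= w <= 1.0:
                    raise ValueError(
                        f"coupling weight for {pair}/{band} must be in [0, 1], got {w}"
                    )

    def offset_db(self, band: str, channel: str) -> float:
        entry = self.band_power_offsets.get(band, 0.0)
        if isinstance(entry, Mapping):
            return float(entry.get(channel, 0.0))
        return float(entry)

    def coupling(self, pair: Tuple[str, str], band: str) -> float:
        weights = self.coherence_coupling.get(pair_name(*pair), {})
        return float(weights.get(band, 0.0))


@dataclass
class CohortSpec:
    """Study-level design: cohort size, session structure and group effects.

    Defaults mirror the study conditions: 13 subjects, two recording
    sessions of 30 min at 2 kHz, 12 training drinking sessions and 3
    stimulation sessions. ``group_effect`` keys:

    - ``drinking_g_per_kg``: HD minus LD training drinking mean.
    - ``gamma_power_db``: extra low/high-gamma power in HD (all channels).
    - ``gamma_coherence``: extra low/high-gamma coupling weight on all
      pairs in HD.
    - ``stim_drop_g_per_kg``: drop in HD consumption during stimulation.
    """

    n_subjects: int = 13
    n_sessions_recording: int = 2
    recording_duration: float = 1800.0  # seconds per session
    sampling_rate: float = 2000.0  # Hz
    n_drinking_sessions: int = 12
    n_stim_sessions: int = 3
    group_effect: Dict[str, float] = field(default_factory=dict)
    seed: int = 0
    drinking_mean_ld: float = 0.7  # g/kg, typical limited-access intake
    drinking_sd: float = 0.2  # g/kg session-to-session noise
    band_scheme: BandScheme = DEFAULT_BAND_SCHEME

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("a cohort needs at least 2 subjects")
        if self.recording_duration <= 0:
            raise ValueError("recording_duration must be positive")
        top_edge = max(hi for _, hi in self.band_scheme.bands.values())
        if self.sampling_rate <= 2 * top_edge:
            raise ValueError("sampling_rate must exceed twice the highest band edge")


def build_subject_specs(spec: CohortSpec) -> List[SubjectSpec]:
    """Expand a cohort design into per-subject generative specs.

    The first ``ceil(n/2)`` subjects form the HD group (7/6 for n=13)
    and carry the cohort's group effects.
    """
    n_hd = (spec.n_subjects + 1) // 2
    d_drink = spec.group_effect.get("drinking_g_per_kg", 0.0)
    d_gamma_db = spec.group_effect.get("gamma_power_db", 0.0)
    d_gamma_coh = spec.group_effect.get("gamma_coherence", 0.0)
    gamma_bands = [b for b in spec.band_scheme.bands if "gamma" in b]
    subjects = []
    for i in range(spec.n_subjects):
        is_hd = i < n_hd
        offsets: Dict[str, Union[float, Dict[str, float]]] = {}
        coupling: Dict[str, Dict[str, float]] = {}
        if is_hd and d_gamma_db:
            offsets = {b: d_gamma_db for b in gamma_bands}
        if is_hd and d_gamma_coh:
            coupling = {
                pair_name(*p): {b: min(1.0, d_gamma_coh) for b in gamma_bands}
                for p in CHANNEL_PAIRS
            }
        subjects.append(
            SubjectSpec(
                subject_id=f"rat{i + 1:02d}",
                group="HD" if is_hd else "LD",
                band_power_offsets=offsets,
                coherence_coupling=coupling,
                drinking_mean=spec.drinking_mean_ld + (d_drink if is_hd else 0.0),
                drinking_sd=spec.drinking_sd,
            )
        )
    return subjects


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-RMS 1/f-amplitude noise via spectral shaping."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    nonzero = freqs > 0
    scale[nonzero] = 1.0 / np.sqrt(freqs[nonzero])
    scale[0] = 0.0
    x = np.fft.irfft(spectrum * scale, n)
    return x / np.std(x)


def _band_noise(
    rng: np.random.Generator, n: int, fs: float, low: float, high: float
) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise (zero-phase Butterworth band-pass)."""
    white = rng.standard_normal(n)
    sos = signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, white)
    sd = np.std(x)
    return x / sd if sd > 0 else x


def generate_recording(
    spec: SubjectSpec,
    duration: float,
    fs: float,
    seed: int,
    session_id: str = "session01",
    scheme: BandScheme = DEFAULT_BAND_SCHEME,
) -> RawRecording:
    """Simulate one 4-channel LFP recording for a subject.

    Each channel is pink background noise plus per-band band-limited
    processes scaled by the subject's dB offsets; channel pairs share
    band-limited sources according to the subject's coupling weights.
    Deterministic in ``(spec, duration, fs, seed)``.

    Parameters
    ----------
    duration
        Recording length in seconds (>= 10 s so every band, including
        1 Hz delta, has many cycles).
    fs
        Sampling rate in Hz (>= 200 Hz to cover the 90 Hz high-gamma edge).
    """
    if duration <= 0 or fs <= 0:
        raise ValueError("duration and fs must be positive")
    if duration < 10:
        raise ValueError("duration must be at least 10 s")
    if fs < 200:
        raise ValueError("fs must be at least 200 Hz")
    top_edge = max(hi for _, hi in scheme.bands.values())
    if fs <= 2 * top_edge:
        raise ValueError("fs must exceed twice the highest band edge")

    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    data = np.zeros((len(CHANNELS), n))

    # Independent pieces first (fixed draw order => reproducibility).
    for i in range(len(CHANNELS)):
        data[i] = spec.background_rms * _pink_noise(rng, n)
    indep = {
        (ch, band): _band_noise(rng, n, fs, lo, hi)
        for ch in CHANNELS
        for band, (lo, hi) in scheme.bands.items()
    }
    shared = {
        (pair, band): _band_noise(rng, n, fs, lo, hi)
        for pair in CHANNEL_PAIRS
        for band, (lo, hi) in scheme.bands.items()
        if spec.coupling(pair, band) > 0
    }

    for i, ch in enumerate(CHANNELS):
        for band in scheme.bands:
            amp = spec.band_rms * 10.0 ** (spec.offset_db(band, ch) / 20.0)
            w_pairs = [
                (pair, spec.coupling(pair, band))
                for pair in CHANNEL_PAIRS
                if ch in pair and spec.coupling(pair, band) > 0
            ]
            w_total = min(1.0, sum(w for _, w in w_pairs))
            comp = np.sqrt(1.0 - w_total) * indep[(ch, band)]
            for pair, w in w_pairs:
                comp = comp + np.sqrt(w) * shared[(pair, band)]
            data[i] += amp * comp

    return RawRecording(
        samples=data,
        fs=fs,
        channel_labels=CHANNELS,
        subject_id=spec.subject_id,
        session_id=session_id,
    )


def inject_artifacts(
    rec: RawRecording, rate: float, amplitude: float, seed: int
) -> RawRecording:
    """Add Poisson-placed half-sine transients to random channels.

    Events of peak ``amplitude`` (mV) and 20 ms width are superimposed at
    uniformly random times; their times and channels are recorded in the
    returned copy's ground-truth metadata. ``amplitude`` at or below the
    +/-2 mV detection threshold is allowed but triggers a warning since
    such events would be invisible to threshold-based rejection.
    """
    if rate < 0:
        raise ValueError("rate must be nonnegative")
    if amplitude <= ARTIFACT_DETECTION_THRESHOLD_MV:
        warnings.warn(
            f"artifact amplitude {amplitude} mV does not exceed the "
            f"{ARTIFACT_DETECTION_THRESHOLD_MV} mV detection threshold; "
            "injected events will not be detectable",
            UserWarning,
            stacklevel=2,
        )
    out = rec.copy()
    if rate == 0:
        return out
    rng = np.random.default_rng(seed)
    n_events = rng.poisson(rate * rec.duration / 60.0)
    width = max(2, int(round(ARTIFACT_WIDTH_S * rec.fs)))
    pulse = np.sin(np.pi * np.arange(width) / (width - 1))
    for _ in range(n_events):
        t = rng.uniform(0.0, rec.duration)
        ch = int(rng.integers(0, rec.n_channels))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        start = int(round(t * rec.fs))
        stop = min(start + width, rec.n_samples)
        out.samples[ch, start:stop] += sign * amplitude * pulse[: stop - start]
        out.artifact_times_s.append(t)
        out.artifact_channels.append(rec.channel_labels[ch])
    return out


def generate_drinking_table(spec: CohortSpec, seed: int) -> pd.DataFrame:
    """Simulate per-session alcohol consumption (g/kg) for a cohort.

    Returns a tidy table with columns ``subject_id``, ``session_index``,
    ``session_type`` ("training" or "stimulation") and ``g_per_kg``.
    Training sessions draw around each subject's mean; stimulation
    sessions subtract the cohort's ``stim_drop_g_per_kg`` effect for HD
    subjects. Values are clipped at zero (consumption cannot be negative).
    """
    if spec.n_drinking_sessions < 3:
        raise ValueError("need at least 3 drinking sessions")
    rng = np.random.default_rng(seed)
    stim_drop = spec.group_effect.get("stim_drop_g_per_kg", 0.0)
    rows = []
    for subj in build_subject_specs(spec):
        for s in range(1, spec.n_drinking_sessions + 1):
            val = rng.normal(subj.drinking_mean, subj.drinking_sd)
            rows.append((subj.subject_id, s, "training", max(0.0, val)))
        mean_stim = subj.drinking_mean - (stim_drop if subj.group == "HD" else 0.0)
        for s in range(1, spec.n_stim_sessions + 1):
            val = rng.normal(mean_stim, subj.drinking_sd)
            rows.append(
                (subj.subject_id, spec.n_drinking_sessions + s, "stimulation", max(0.0, val))
            )
    return pd.DataFrame(
        rows, columns=["subject_id", "session_index", "session_type", "g_per_kg"]
    )
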