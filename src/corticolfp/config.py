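"""Pipeline configuration: defaults, validation and YAML round-tripping."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import yaml

from .bands import DEFAULT_BAND_SCHEME, BandScheme

__all__ = ["PipelineConfig", "validate_config", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    """Every tunable of the simulate -> preprocess -> features -> stats chain.

    The defaults encode the analysis constants: 60 Hz notch (4th-order
    Chebyshev I), decimation 2 kHz -> 400 Hz, +/-2 mV artifact threshold
    with 12.5 ms / 1 s removal windows, 3 s epochs, 1.28 s Hamming Welch
    windows at 50% overlap, 1-90 Hz normalization with 59-61 Hz excluded,
    last-3-session drinking averages, and 4-fold x 100-repetition lasso
    CV with 100 label permutations.
    """

    # simulation
    n_subjects: int = 13
    n_sessions_recording: int = 2
    recording_duration: float = 1800.0  # s
    sampling_rate: float = 2000.0  # Hz
    n_drinking_sessions: int = 12
    n_stim_sessions: int = 3
    group_effect: Dict[str, float] = field(default_factory=dict)
    # preprocessing
    notch_center: float = 60.0
    notch_order: int = 4
    notch_bandwidth: float = 2.0
    notch_ripple_db: float = 0.25
    decimation_factor: int = 5
    artifact_threshold_mv: float = 2.0
    artifact_pre_window_s: float = 0.0125
    artifact_post_window_s: float = 1.0
    epoch_length_s: float = 3.0
    # spectral features
    welch_window_s: float = 1.28
    welch_overlap: float = 0.5
    power_domain: str = "db"
    band_scheme: BandScheme = field(default_factory=lambda: DEFAULT_BAND_SCHEME)
    # phenotype
    last_k_sessions: int = 3
    # classification
    folds: int = 4
    repetitions: int = 100
    permutations: int = 100
    run_feature_importance: bool = False
    # reproducibility
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["band_scheme"] = self.band_scheme.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "band_scheme" in d and not isinstance(d["band_scheme"], BandScheme):
            d["band_scheme"] = BandScheme.from_dict(d["band_scheme"])
        return cls(**d)


def validate_config(config: PipelineConfig) -> List[str]:
    """Collect every cross-parameter violation (empty list = valid)."""
    errors: List[str] = []
    c = config
    if c.n_subjects < 2:
        errors.append("n_subjects must be at least 2")
    if c.recording_duration <= 0:
        errors.append("recording_duration must be positive")
    if c.sampling_rate <= 0:
        errors.append("sampling_rate must be positive")
    if c.decimation_factor < 1:
        errors.append("decimation_factor must be at least 1")
    elif c.sampling_rate > 0 and abs(
        c.sampling_rate / c.decimation_factor
        - round(c.sampling_rate / c.decimation_factor)
    ) > 1e-9:
        errors.append("sampling_rate must be divisible by decimation_factor")
    fs_out = c.sampling_rate / max(c.decimation_factor, 1)
    nyq_out = fs_out / 2.0
    if not 0 < c.notch_center < c.sampling_rate / 2.0:
        errors.append("notch_center must lie below the input Nyquist frequency")
    top_edge = max(hi for _, hi in c.band_scheme.bands.values())
    if top_edge >= nyq_out:
        errors.append(
            f"highest band edge {top_edge} Hz exceeds the post-decimation "
            f"Nyquist frequency {nyq_out} Hz"
        )
    if c.band_scheme.norm_range[1] >= nyq_out:
        errors.append("normalization range exceeds the post-decimation Nyquist")
    if c.artifact_threshold_mv <= 0:
        errors.append("artifact_threshold_mv must be positive")
    if c.artifact_pre_window_s < 0 or c.artifact_post_window_s < 0:
        errors.append("artifact windows must be nonnegative")
    if c.epoch_length_s <= 0:
        errors.append("epoch_length_s must be positive")
    if c.welch_window_s > c.epoch_length_s:
        errors.append("welch_window_s must not exceed epoch_length_s")
    if not 0 <= c.welch_overlap < 1:
        errors.append("welch_overlap must be in [0, 1)")
    if c.power_domain not in ("db", "linear"):
        errors.append("power_domain must be 'db' or 'linear'")
    if c.last_k_sessions < 1 or c.last_k_sessions > c.n_drinking_sessions:
        errors.append("last_k_sessions must be between 1 and n_drinking_sessions")
    if c.folds < 2 or c.folds > c.n_subjects:
        errors.append("folds must be between 2 and n_subjects")
    if c.repetitions < 1 or c.permutations < 1:
        errors.append("repetitions and permutations must be at least 1")
    if c.recording_duration < c.epoch_length_s:
        errors.append("recording_duration shorter than one epoch")
    return errors


def load_config(path: Union[str, Path]) -> PipelineConfig:
    with open(path) as f:
        data = yaml.safe_load(f) or {}
    return PipelineConfig.from_dict(data)


def save_config(config: PipelineConfig, path: Union[str, Path]) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(config.to_dict(), f, sort_keys=False)
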