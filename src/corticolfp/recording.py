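"""Multichannel LFP recording container and on-disk formats (HDF5/CSV)."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import h5py
import numpy as np
import pandas as pd

__all__ = ["CHANNELS", "CHANNEL_PAIRS", "RawRecording", "save_recording", "load_recording"]

# Bilateral nucleus accumbens shell and medial prefrontal cortex.
CHANNELS: Tuple[str, ...] = ("lNAcSh", "rNAcSh", "lmPFC", "rmPFC")
CHANNEL_PAIRS: Tuple[Tuple[str, str], ...] = tuple(
    (CHANNELS[i], CHANNELS[j])
    for i in range(len(CHANNELS))
    for j in range(i + 1, len(CHANNELS))
)


@dataclass
class RawRecording:
    """A multichannel extracellular voltage recording.

    Attributes
    ----------
    samples
        Array of shape ``(n_channels, n_samples)`` in millivolts.
    fs
        Sampling rate in Hz.
    channel_labels
        Unique channel names, one per row of ``samples``.
    subject_id, session_id
        Provenance identifiers.
    artifact_times_s, artifact_channels
        Ground-truth artifact event metadata (populated by the synthetic
        generator's artifact injector; empty for clean data).
    """

    samples: np.ndarray
    fs: float
    channel_labels: Tuple[str, ...] = CHANNELS
    subject_id: str = ""
    session_id: str = ""
    artifact_times_s: List[float] = field(default_factory=list)
    artifact_channels: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        self.channel_labels = tuple(self.channel_labels)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{self.samples.shape[0]} sample rows but "
                f"{len(self.channel_labels)} channel labels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        return self.samples[self.channel_labels.index(label)]

    def copy(self) -> "RawRecording":
        return replace(
            self,
            samples=self.samples.copy(),
            artifact_times_s=list(self.artifact_times_s),
            artifact_channels=list(self.artifact_channels),
        )

    # ---- serialization -------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Wide CSV-friendly layout: time_s plus one column per channel."""
        t = np.arange(self.n_samples) / self.fs
        data = {"time_s": t}
        for i, lab in enumerate(self.channel_labels):
            data[lab] = self.samples[i]
        return pd.DataFrame(data)


def save_recording(rec: RawRecording, target: Union[str, Path, h5py.Group]) -> None:
    """Write a recording to an HDF5 file (or an open group within one).

    Layout: dataset ``samples`` (channels x time, float64, mV) with
    attributes ``fs``, ``channel_labels``, ``subject_id``, ``session_id``
    and ``units``; optional datasets ``artifact_times_s`` /
    ``artifact_channels`` carry ground-truth artifact metadata.
    """
    if isinstance(target, (str, Path)):
        with h5py.File(target, "w") as f:
            save_recording(rec, f)
        return
    g = target
    d = g.create_dataset("samples", data=rec.samples)
    d.attrs["fs"] = float(rec.fs)
    d.attrs["channel_labels"] = list(rec.channel_labels)
    d.attrs["subject_id"] = rec.subject_id
    d.attrs["session_id"] = rec.session_id
    d.attrs["units"] = "mV"
    if rec.artifact_times_s:
        g.create_dataset("artifact_times_s", data=np.asarray(rec.artifact_times_s))
        g.create_dataset(
            "artifact_channels",
            data=np.array(rec.artifact_channels, dtype=h5py.string_dtype()),
        )


def load_recording(source: Union[str, Path, h5py.Group]) -> RawRecording:
    """Read a recording written by :func:`save_recording`."""
    if isinstance(source, (str, Path)):
        with h5py.File(source, "r") as f:
            return load_recording(f)
    g = source
    d = g["samples"]
    times: List[float] = []
    chans: List[str] = []
    if "artifact_times_s" in g:
        times = [float(x) for x in g["artifact_times_s"][()]]
        chans = [
            x.decode() if isinstance(x, bytes) else str(x)
            for x in g["artifact_channels"][()]
        ]
    return RawRecording(
        samples=d[()],
        fs=float(d.attrs["fs"]),
        channel_labels=tuple(str(x) for x in d.attrs["channel_labels"]),
        subject_id=str(d.attrs.get("subject_id", "")),
        session_id=str(d.attrs.get("session_id", "")),
        artifact_times_s=times,
        artifact_channels=chans,
    )
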