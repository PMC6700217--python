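"""Frequency-band schemes for rodent LFP spectra.

The default scheme follows the canonical rodent literature bands: delta
(1-4 Hz), theta (5-10 Hz), alpha (11-14 Hz), beta (15-30 Hz), low gamma
(45-65 Hz) and high gamma (70-90 Hz). Band summaries are normalized to the
broadband 1-90 Hz range, with 59-61 Hz excluded to avoid the 60 Hz notch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np

__all__ = ["BandScheme", "DEFAULT_BAND_SCHEME"]


@dataclass(frozen=True)
class BandScheme:
    """Named, non-overlapping frequency bands plus a normalization range.

    Parameters
    ----------
    bands
        Ordered mapping of band name to ``(low, high)`` edges in Hz.
        Bands must be sorted ascending and non-overlapping, with all
        edges inside ``norm_range``.
    norm_range
        Broadband range used as the normalizer for percent features.
    exclusion
        Frequency interval (open at the interior) removed from every
        band and normalizer average, e.g. around a line-noise notch.
        Must lie strictly inside ``norm_range``.
    """

    bands: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {
            "delta": (1.0, 4.0),
            "theta": (5.0, 10.0),
            "alpha": (11.0, 14.0),
            "beta": (15.0, 30.0),
            "lgamma": (45.0, 65.0),
            "hgamma": (70.0, 90.0),
        }
    )
    norm_range: Tuple[float, float] = (1.0, 90.0)
    exclusion: Tuple[float, float] = (59.0, 61.0)

    def __post_init__(self) -> None:
        lo_n, hi_n = self.norm_range
        if not lo_n < hi_n:
            raise ValueError("norm_range must be an increasing interval")
        prev_high = -np.inf
        for name, (lo, hi) in self.bands.items():
            if not lo < hi:
                raise ValueError(f"band {name!r} edges must be increasing")
            if lo < prev_high:
                raise ValueError(f"band {name!r} overlaps the previous band")
            if lo < lo_n or hi > hi_n:
                raise ValueError(f"band {name!r} lies outside norm_range")
            prev_high = hi
        lo_e, hi_e = self.exclusion
        if not (lo_n < lo_e < hi_e < hi_n):
            raise ValueError("exclusion must lie strictly inside norm_range")

    @property
    def band_names(self) -> Tuple[str, ...]:
        return tuple(self.bands)

    def band_mask(self, freqs: np.ndarray, band: str) -> np.ndarray:
        """Boolean mask of grid frequencies inside ``band``, minus the exclusion."""
        lo, hi = self.bands[band]
        return self._mask(freqs, lo, hi)

    def norm_mask(self, freqs: np.ndarray) -> np.ndarray:
        """Boolean mask of grid frequencies inside the normalization range."""
        return self._mask(freqs, *self.norm_range)

    def _mask(self, freqs: np.ndarray, lo: float, hi: float) -> np.ndarray:
        freqs = np.asarray(freqs, dtype=float)
        inside = (freqs >= lo) & (freqs <= hi)
        lo_e, hi_e = self.exclusion
        excluded = (freqs > lo_e) & (freqs < hi_e)
        return inside & ~excluded

    def to_dict(self) -> dict:
        return {
            "bands": {k: list(v) for k, v in self.bands.items()},
            "norm_range": list(self.norm_range),
            "exclusion": list(self.exclusion),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BandScheme":
        return cls(
            bands={k: tuple(v) for k, v in d["bands"].items()},
            norm_range=tuple(d["norm_range"]),
            exclusion=tuple(d["exclusion"]),
        )


DEFAULT_BAND_SCHEME = BandScheme()
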