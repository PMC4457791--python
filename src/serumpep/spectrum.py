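"""The raw-spectrum container shared by the whole pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class RawSpectrum:
    """A single profile mass spectrum.

    Parameters
    ----------
    sample_id:
        Free-text sample identifier.
    mz:
        Strictly increasing m/z axis in Da.
    intensity:
        Nonnegative intensities (arbitrary units), same length as ``mz``.
    metadata:
        Free key/value map (seed, injected distortion, QC flags, ...).
    """

    sample_id: str
    mz: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays")
        if len(self.mz) != len(self.intensity):
            raise ValueError(
                f"mz and intensity lengths differ: {len(self.mz)} vs {len(self.intensity)}"
            )
        if len(self.mz) < 2:
            raise ValueError("a spectrum needs at least 2 points")
        if not np.all(np.diff(self.mz) > 0):
            raise ValueError("mz axis must be strictly increasing")
        if not np.all(np.isfinite(self.mz)) or not np.all(np.isfinite(self.intensity)):
            raise ValueError("mz and intensity must be finite")

    def __len__(self) -> int:
        return len(self.mz)

    def tic(self) -> float:
        """Total ion current: trapezoidal integral of intensity over m/z."""
        return float(np.trapezoid(self.intensity, self.mz))

    def copy_with(self, intensity: np.ndarray | None = None,
                  mz: np.ndarray | None = None) -> "RawSpectrum":
        return RawSpectrum(
            sample_id=self.sample_id,
            mz=self.mz.copy() if mz is None else np.asarray(mz, dtype=float),
            intensity=self.intensity.copy() if intensity is None
            else np.asarray(intensity, dtype=float),
            metadata=dict(self.metadata),
        )

    def trimmed(self, lo: float, hi: float) -> "RawSpectrum":
        """Restrict to the analyzed mass window ``[lo, hi)``."""
        keep = (self.mz >= lo) & (self.mz < hi)
        if keep.sum() < 2:
            raise ValueError(f"fewer than 2 points in [{lo}, {hi})")
        return self.copy_with(mz=self.mz[keep], intensity=self.intensity[keep])
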