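"""In-memory containers shared by the simulator and the preprocessing chain."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .montage import Montage

WAVELENGTHS_NM = (695.0, 830.0)


@dataclass
class OpticalTimeSeries:
    """Two-wavelength optical record, 44 channels at 10 Hz.

    ``intensity`` has shape (n_channels, n_samples, 2) in the wavelength
    order of ``wavelengths_nm``; ``i0`` is the reference (baseline)
    intensity from which optical-density changes are computed.
    """

    intensity: np.ndarray
    montage: Montage
    sampling_rate: float = 10.0
    wavelengths_nm: tuple[float, float] = WAVELENGTHS_NM
    i0: float = 1.0
    source_detector_mm: float = 30.0

    @property
    def n_channels(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensity.shape[1]

    def optical_density(self) -> np.ndarray:
        """Optical-density change ΔOD = -log10(I / I0), same shape as
        ``intensity``.  Raises if any intensity is non-positive."""
        if np.any(self.intensity <= 0):
            ch, t, w = np.argwhere(self.intensity <= 0)[0]
            raise ValueError(
                f"non-positive intensity at channel {ch + 1}, sample {t}, "
                f"wavelength {self.wavelengths_nm[w]} nm"
            )
        return -np.log10(self.intensity / self.i0)


@dataclass
class HemoTimeSeries:
    """Per-channel hemoglobin concentration-change traces (µM)."""

    o2hb: np.ndarray  # (n_channels, n_samples)
    hhb: np.ndarray
    sampling_rate: float = 10.0
    # per-channel provenance flags set by preprocessing stages
    ica_corrected: bool = False
    pca_corrected: bool = False
    interpolated_channels: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.o2hb.shape != self.hhb.shape:
            raise ValueError("o2hb and hhb must share a shape")

    @property
    def n_channels(self) -> int:
        return self.o2hb.shape[0]

    @property
    def n_samples(self) -> int:
        return self.o2hb.shape[1]


@dataclass
class MergedSignal:
    """CBSI-merged single activation signal per channel."""

    signal: np.ndarray  # (n_channels, n_samples)
    alpha: np.ndarray  # (n_channels,) sd(O2Hb)/sd(HHb) ratios used
    sampling_rate: float = 10.0
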