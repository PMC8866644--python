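"""In-memory containers for raw optical and hemoglobin time series.

All arrays are time-major; channel axes follow montage channel-id order
(channel 1 is column 0). Concentrations are changes from baseline in mol/L.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError

WAVELENGTHS_NM = (760.0, 850.0)


@dataclass
class RawIntensity:
    """Two-wavelength light intensities.

    data has shape (n_samples, n_channels, 2); wavelength axis ordered as
    ``wavelengths``. ``baseline`` (I0) has shape (n_channels, 2).
    """

    sampling_rate: float
    data: np.ndarray
    baseline: np.ndarray
    wavelengths: tuple[float, float] = WAVELENGTHS_NM

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.baseline = np.asarray(self.baseline, dtype=float)
        if self.data.ndim != 3 or self.data.shape[2] != 2:
            raise FormatError(
                f"intensity data must be (time, channel, 2), got {self.data.shape}"
            )
        if self.baseline.shape != self.data.shape[1:]:
            raise FormatError("baseline shape must be (n_channels, 2)")
        if np.any(self.data <= 0) or np.any(self.baseline <= 0):
            bad = int(np.count_nonzero(self.data <= 0))
            raise FormatError(f"intensities must be strictly positive ({bad} samples <= 0)")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


@dataclass
class HemoTimeSeries:
    """Hemoglobin concentration changes (mol/L) per channel.

    totalHb is derived as oxy + deoxy, so the additivity invariant holds by
    construction.
    """

    sampling_rate: float
    oxy: np.ndarray
    deoxy: np.ndarray

    def __post_init__(self) -> None:
        self.oxy = np.asarray(self.oxy, dtype=float)
        self.deoxy = np.asarray(self.deoxy, dtype=float)
        if self.oxy.shape != self.deoxy.shape or self.oxy.ndim != 2:
            raise FormatError("oxy and deoxy must both be (time, channel)")

    @property
    def total(self) -> np.ndarray:
        return self.oxy + self.deoxy

    @property
    def n_samples(self) -> int:
        return self.oxy.shape[0]

    @property
    def n_channels(self) -> int:
        return self.oxy.shape[1]

    def copy(self) -> "HemoTimeSeries":
        return HemoTimeSeries(self.sampling_rate, self.oxy.copy(), self.deoxy.copy())
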