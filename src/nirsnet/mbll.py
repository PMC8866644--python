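"""Modified Beer-Lambert law: optical density <-> hemoglobin concentration.

For each channel the decadic optical-density change at wavelength lambda is

    dOD(lambda) = [ eps_oxy(lambda) dC_oxy + eps_deoxy(lambda) dC_deoxy ]
                  * L * DPF(lambda)

with L the source-detector separation (cm), DPF the differential path-length
factor, eps the decadic molar extinction coefficients (cm^-1 M^-1) and dC
concentration changes (mol/L). With two wavelengths this is an invertible
2x2 linear system per channel and time point; the forward and inverse maps
here are exact mutual inverses, which the simulator relies on.

Default DPFs are 7.25 (760 nm) and 6.38 (850 nm). Extinction
coefficients come from a packaged compilation table (decadic, Prahl
compilation values at 760/850 nm by default) since conventions differ across
softwares; the table id is part of the configuration and is logged.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, FormatError
from .series import HemoTimeSeries, RawIntensity, WAVELENGTHS_NM

logger = logging.getLogger("nirsnet")

DEFAULT_DPF = (7.25, 6.38)
DEFAULT_EXTINCTION_TABLE = "prahl_760_850"


def load_extinction_table(table_id: str = DEFAULT_EXTINCTION_TABLE) -> np.ndarray:
    """Return the 2x2 extinction matrix eps[wavelength, species].

    Rows ordered (760, 850) nm; columns (oxyHb, deoxyHb); units cm^-1 M^-1
    (decadic).
    """
    name = f"extinction_{table_id}.tsv"
    ref = importlib.resources.files("nirsnet.data") / name
    if not ref.is_file():
        raise ConfigError(f"unknown extinction table id {table_id!r}")
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", comment="#")
    df = df.sort_values("wavelength_nm")
    eps = df[["eps_oxy", "eps_deoxy"]].to_numpy(dtype=float)
    if eps.shape != (2, 2):
        raise ConfigError(f"extinction table {table_id!r} must have 2 wavelengths")
    return eps


@dataclass
class OpticsParams:
    """Everything needed to run the MBLL on one montage."""

    separations_cm: np.ndarray
    dpf: tuple[float, float] = DEFAULT_DPF
    extinction: np.ndarray = field(default_factory=load_extinction_table)
    wavelengths: tuple[float, float] = WAVELENGTHS_NM

    def __post_init__(self) -> None:
        self.separations_cm = np.asarray(self.separations_cm, dtype=float)
        self.extinction = np.asarray(self.extinction, dtype=float)
        if np.any(self.separations_cm <= 0):
            raise ConfigError("all separations must be > 0")
        if any(d <= 0 for d in self.dpf):
            raise ConfigError("DPF must be > 0")
        if self.extinction.shape != (2, 2):
            raise ConfigError("extinction matrix must be 2x2")
        cond = np.linalg.cond(self.extinction)
        if not np.isfinite(cond) or cond > 1e12:
            raise ConfigError("extinction matrix is singular or near-singular")
        logger.debug("extinction matrix condition number: %.3g", cond)

    def pathlength_cm(self) -> np.ndarray:
        """Effective path length L*DPF, shape (n_channels, 2)."""
        return self.separations_cm[:, None] * np.asarray(self.dpf)[None, :]


def od_from_intensity(raw: RawIntensity) -> np.ndarray:
    """Optical-density change dOD = -log10(I / I0), shape (time, channel, 2)."""
    if np.any(raw.data <= 0):
        bad = np.argwhere(raw.data <= 0)[:10]
        raise FormatError(f"non-positive intensities at (t, ch, wl) {bad.tolist()}")
    return -np.log10(raw.data / raw.baseline[None, :, :])


def intensity_from_od(od: np.ndarray, baseline: np.ndarray,
                      sampling_rate: float) -> RawIntensity:
    """Exact inverse of :func:`od_from_intensity`."""
    od = np.asarray(od, dtype=float)
    data = baseline[None, :, :] * 10.0 ** (-od)
    return RawIntensity(sampling_rate=sampling_rate, data=data, baseline=baseline)


def hemoglobin_from_od(od: np.ndarray, params: OpticsParams,
                       sampling_rate: float) -> HemoTimeSeries:
    """Solve the per-channel 2x2 MBLL system for (dC_oxy, dC_deoxy)."""
    od = np.asarray(od, dtype=float)
    if od.ndim != 3 or od.shape[2] != 2:
        raise FormatError(f"OD array must be (time, channel, 2), got {od.shape}")
    if od.shape[1] != params.separations_cm.shape[0]:
        raise FormatError("OD channel count does not match optics params")
    # attenuation per unit path: A(t,c,lambda) = dOD / (L*DPF)
    att = od / params.pathlength_cm()[None, :, :]
    inv = np.linalg.inv(params.extinction)  # (species, wavelength)
    conc = np.einsum("sw,tcw->tcs", inv, att)
    return HemoTimeSeries(sampling_rate=sampling_rate,
                          oxy=conc[:, :, 0], deoxy=conc[:, :, 1])


def od_from_hemoglobin(hemo: HemoTimeSeries, params: OpticsParams) -> np.ndarray:
    """Forward MBLL; exact inverse of :func:`hemoglobin_from_od`."""
    if hemo.n_channels != params.separations_cm.shape[0]:
        raise FormatError("hemoglobin channel count does not match optics params")
    conc = np.stack([hemo.oxy, hemo.deoxy], axis=-1)  # (t, c, species)
    att = np.einsum("ws,tcs->tcw", params.extinction, conc)
    return att * params.pathlength_cm()[None, :, :]
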