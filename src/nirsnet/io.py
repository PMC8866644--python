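"""Reading and writing recordings: SNIRF (HDF5) and a documented wide CSV.

Two on-disk dialects are supported:

* **SNIRF** — the fNIRS community standard, HDF5-based; written with one
  data block whose measurement list enumerates channel x wavelength columns.
* **CSV** — one greppable wide table: first column ``time_s``, then one
  column per channel and wavelength named ``chNN_760`` / ``chNN_850``,
  followed by matching ``i0_chNN_760``-style baseline columns in the header
  comment-free layout (baselines are stored as the first data row's
  reference; see ``write_csv``).

Channel order always follows montage channel-id order.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .errors import ChannelMismatchError, FormatError
from .montage import Montage
from .series import RawIntensity, WAVELENGTHS_NM

_SNIRF_VERSION = "1.0"


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def _csv_columns(n_channels: int) -> list[str]:
    cols = []
    for ch in range(1, n_channels + 1):
        for wl in WAVELENGTHS_NM:
            cols.append(f"ch{ch:02d}_{int(wl)}")
    return cols


def write_csv(raw: RawIntensity, path: str | Path) -> None:
    """Wide CSV: time_s then chNN_760 / chNN_850 columns.

    Baseline intensities are stored as an extra leading row at time_s = -1
    (time stamps of real samples are >= 0 and uniform).
    """
    n, c, _ = raw.data.shape
    t = np.arange(n) / raw.sampling_rate
    flat = raw.data.reshape(n, c * 2)
    base = raw.baseline.reshape(1, c * 2)
    body = np.vstack([base, flat])
    times = np.concatenate([[-1.0], t])
    df = pd.DataFrame(body, columns=_csv_columns(c))
    df.insert(0, "time_s", times)
    df.to_csv(path, index=False, float_format="%.17g")


def read_csv(path: str | Path, montage: Montage) -> RawIntensity:
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise FormatError("CSV is missing the time_s column")
    expected = _csv_columns(montage.n_channels)
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ChannelMismatchError(
            f"CSV is missing channel columns for this montage: {missing[:6]}"
            + ("..." if len(missing) > 6 else ""))
    for col in df.columns:
        if col != "time_s" and col not in expected:
            raise ChannelMismatchError(f"CSV column {col!r} not in montage")
    times = df["time_s"].to_numpy()
    if times[0] != -1.0:
        raise FormatError("CSV lacks the baseline row (time_s = -1)")
    t = times[1:]
    if t.size >= 2:
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6):
            raise FormatError("non-uniform sampling in CSV time column")
        fs = 1.0 / dt[0]
    else:
        raise FormatError("CSV must contain at least 2 samples")
    vals = df[expected].to_numpy()
    baseline = vals[0].reshape(montage.n_channels, 2)
    data = vals[1:].reshape(-1, montage.n_channels, 2)
    return RawIntensity(sampling_rate=fs, data=data, baseline=baseline)


# ---------------------------------------------------------------------------
# SNIRF dialect
# ---------------------------------------------------------------------------

def write_snirf(raw: RawIntensity, path: str | Path, montage: Montage) -> None:
    """Minimal valid SNIRF: one nirs block, continuous-wave amplitude data."""
    if raw.n_channels != montage.n_channels:
        raise ChannelMismatchError("recording channel count does not match montage")
    n, c, _ = raw.data.shape
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data=_SNIRF_VERSION)
        nirs = f.create_group("nirs1")
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(raw.wavelengths))
        sources = sorted({ch.source for ch in montage.channels})
        detectors = sorted({ch.detector for ch in montage.channels})
        probe.create_dataset("sourceLabels",
                             data=np.array(sources, dtype=h5py.string_dtype()))
        probe.create_dataset("detectorLabels",
                             data=np.array(detectors, dtype=h5py.string_dtype()))
        data = nirs.create_group("data1")
        data.create_dataset("dataTimeSeries", data=raw.data.reshape(n, c * 2))
        data.create_dataset("time", data=np.arange(n) / raw.sampling_rate)
        k = 0
        for ch in sorted(montage.channels, key=lambda x: x.id):
            for wi in (1, 2):
                ml = data.create_group(f"measurementList{k + 1}")
                ml.create_dataset("sourceIndex",
                                  data=sources.index(ch.source) + 1)
                ml.create_dataset("detectorIndex",
                                  data=detectors.index(ch.detector) + 1)
                ml.create_dataset("wavelengthIndex", data=wi)
                ml.create_dataset("dataType", data=1)  # CW amplitude
                ml.create_dataset("dataTypeIndex", data=ch.id)
                k += 1
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("baselineIntensity", data=raw.baseline)


def read_snirf(path: str | Path, montage: Montage) -> RawIntensity:
    with h5py.File(path, "r") as f:
        if "nirs1" not in f:
            raise FormatError("not a SNIRF file (missing nirs1 group)")
        nirs = f["nirs1"]
        wls = np.asarray(nirs["probe/wavelengths"])
        if wls.size != 2:
            raise FormatError(f"expected two wavelengths, found {wls.size}")
        data_grp = nirs["data1"]
        flat = np.asarray(data_grp["dataTimeSeries"])
        t = np.asarray(data_grp["time"])
        if t.size >= 2:
            dt = np.diff(t)
            if not np.allclose(dt, dt[0], rtol=1e-6):
                raise FormatError("non-uniform sampling in SNIRF time vector")
            fs = 1.0 / dt[0]
        else:
            raise FormatError("SNIRF file must contain at least 2 samples")
        c = montage.n_channels
        if flat.shape[1] != c * 2:
            raise ChannelMismatchError(
                f"SNIRF has {flat.shape[1]} measurement columns; montage needs {c * 2}")
        if "metaDataTags/baselineIntensity" in nirs:
            baseline = np.asarray(nirs["metaDataTags/baselineIntensity"])
        else:
            baseline = flat[0].reshape(c, 2)
    data = flat.reshape(-1, c, 2)
    return RawIntensity(sampling_rate=fs, data=data,
                        baseline=baseline.reshape(c, 2),
                        wavelengths=(float(wls[0]), float(wls[1])))


def read_timeseries(path: str | Path, format: str, montage: Montage) -> RawIntensity:
    """Dispatch on the declared format ('snirf' or 'csv')."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format == "snirf":
        return read_snirf(path, montage)
    if format == "csv":
        return read_csv(path, montage)
    raise FormatError(f"unknown format {format!r}; expected 'snirf' or 'csv'")


def write_timeseries(raw: RawIntensity, path: str | Path, format: str,
                     montage: Montage) -> None:
    if format == "snirf":
        write_snirf(raw, path, montage)
    elif format == "csv":
        write_csv(raw, path)
    else:
        raise FormatError(f"unknown format {format!r}; expected 'snirf' or 'csv'")


def write_ground_truth_sidecar(path: str | Path, beta_true: np.ndarray,
                               latent_correlation: np.ndarray, seed: int) -> None:
    """JSON sidecar recording the simulation ground truth next to a recording."""
    doc = {
        "beta_true": [float(b) for b in beta_true],
        "latent_correlation": [[float(v) for v in row]
                               for row in latent_correlation],
        "seed": int(seed),
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True, indent=1) + "\n")
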