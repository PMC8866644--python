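"""Channel-pair functional connectivity: Pearson r, Fisher z, strong edges.

Pairwise Pearson correlations over the processed oxyHb series are
variance-stabilized with the Fisher transform z = atanh(r) before group
averaging and thresholding. Edges with mean z above a fixed threshold
(default z = 1.0, the upper 15.87% point of a standard normal) are reported
as "strong" connections with a line-thickness class for plotting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .design import BlockDesign
from .errors import NirsnetError
from .series import HemoTimeSeries

logger = logging.getLogger("nirsnet")


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher z-transform, z = atanh(r). |r| = 1 maps to signed infinity."""
    r = np.asarray(r, dtype=float)
    out = np.empty_like(r)
    sat = np.abs(r) >= 1.0
    if np.any(sat & (np.abs(r) > 1.0)):
        raise NirsnetError("correlations must lie in [-1, 1]")
    if sat.any():
        logger.warning("%d correlations with |r| = 1 mapped to signed infinity",
                       int(sat.sum()))
    with np.errstate(divide="ignore"):
        out = np.arctanh(np.clip(r, -1.0, 1.0))
    return out if out.ndim else float(out)


@dataclass
class ConnectivityMatrix:
    """Symmetric channel x channel Pearson-r matrix and its Fisher transform."""

    r: np.ndarray
    subject: int | None = None
    session: str | None = None

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if self.r.ndim != 2 or self.r.shape[0] != self.r.shape[1]:
            raise NirsnetError("connectivity matrix must be square")
        if not np.allclose(self.r, self.r.T, equal_nan=True):
            raise NirsnetError("connectivity matrix must be symmetric")

    @property
    def z(self) -> np.ndarray:
        return fisher_z(self.r)

    @property
    def n_channels(self) -> int:
        return self.r.shape[0]


def _window_slice(series: HemoTimeSeries, window: str,
                  design: BlockDesign | None) -> np.ndarray:
    if window == "full":
        return series.oxy
    if window == "task_blocks":
        if design is None:
            raise NirsnetError("task_blocks window requires a block design")
        mask = design.task_indicator().astype(bool)
        if mask.size != series.n_samples:
            raise NirsnetError("design length does not match series")
        return series.oxy[mask]
    raise NirsnetError(f"unknown correlation window {window!r}")


def correlation_matrix(series: HemoTimeSeries, window: str = "full",
                       design: BlockDesign | None = None,
                       subject: int | None = None,
                       session: str | None = None) -> ConnectivityMatrix:
    """Pearson r between every unordered channel pair over the chosen window.

    The diagonal is masked (NaN). Zero-variance channels yield NaN for all
    their pairs, with a warning.
    """
    data = _window_slice(series, window, design)
    if data.shape[0] < 30:
        raise NirsnetError(f"need >= 30 samples for correlation, got {data.shape[0]}")
    sd = data.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        logger.warning("zero-variance channels %s: correlations undefined",
                       (dead + 1).tolist())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(data, rowvar=False)
    r[dead, :] = np.nan
    r[:, dead] = np.nan
    np.fill_diagonal(r, np.nan)
    # clip tiny excursions beyond +/-1 from floating point
    r = np.clip(r, -1.0, 1.0)
    return ConnectivityMatrix(r=r, subject=subject, session=session)


def group_average(matrices: list[ConnectivityMatrix]) -> tuple[np.ndarray, np.ndarray]:
    """Elementwise mean Fisher-z across subjects with pairwise exclusion.

    Returns (mean_z, counts); entries undefined (non-finite) in every subject
    are NaN in the output with count 0.
    """
    if not matrices:
        raise NirsnetError("need at least one connectivity matrix")
    shape = matrices[0].r.shape
    for m in matrices:
        if m.r.shape != shape:
            raise NirsnetError("connectivity matrices must share dimensions")
    zs = np.stack([m.z for m in matrices])
    finite = np.isfinite(zs)
    counts = finite.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean_z = np.where(counts > 0,
                          np.where(finite, zs, 0.0).sum(axis=0) /
                          np.maximum(counts, 1),
                          np.nan)
    return mean_z, counts


def strong_edges(mean_z: np.ndarray, threshold: float = 1.0,
                 counts: np.ndarray | None = None) -> list[dict]:
    """Unordered pairs with mean z above ``threshold``, strongest first.

    Each record carries a line-thickness class (1-3 by how far z exceeds the
    threshold, in 0.5 steps) for the connectivity figure.
    """
    if np.isnan(threshold):
        raise NirsnetError("threshold must not be NaN")
    n = mean_z.shape[0]
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            z = mean_z[i, j]
            if np.isfinite(z) and z > threshold:
                thickness = int(min(3, 1 + np.floor((z - threshold) / 0.5)))
                rec = {"ch_a": i + 1, "ch_b": j + 1, "mean_z": float(z),
                       "thickness": thickness}
                if counts is not None:
                    rec["n_subjects"] = int(counts[i, j])
                edges.append(rec)
    edges.sort(key=lambda e: (-e["mean_z"], e["ch_a"], e["ch_b"]))
    return edges
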