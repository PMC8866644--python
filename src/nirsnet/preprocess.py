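"""Artifact handling and zero-phase band-pass filtering of hemoglobin series.

The band of interest is 0.01-0.2 Hz: slow enough to keep the block-design
response (block frequency 1/60 Hz) and fast drift out, low enough to reject
cardiac (~1 Hz) and respiratory (~0.25 Hz) oscillations. The filter is a
4th-order Butterworth applied forward-backward (zero phase, squared
magnitude response).

Artifact detection automates what is often done by hand: spikes are isolated
excursions from a moving median; discontinuities are large, unpaired first
differences (a baseline step). An impulse produces two adjacent large first
differences of opposite sign and is classified as a spike; a lone large
first difference is a discontinuity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .errors import PreprocessError
from .series import HemoTimeSeries

logger = logging.getLogger("nirsnet")

_MAD_SCALE = 1.4826  # consistency factor for normal data


@dataclass
class ArtifactMask:
    """Per (channel, sample) flags plus labelled segments per channel."""

    flags: np.ndarray  # bool (n_samples, n_channels)
    segments: list[list[tuple[int, int, str]]]  # per channel: (start, stop, reason)

    def __post_init__(self) -> None:
        n = self.flags.shape[0]
        for ch_segs in self.segments:
            prev_stop = -1
            for start, stop, reason in ch_segs:
                if not (0 <= start < stop <= n):
                    raise PreprocessError(f"segment ({start}, {stop}) out of bounds")
                if start < prev_stop:
                    raise PreprocessError("segments must be sorted and non-overlapping")
                prev_stop = stop

    @property
    def n_flagged(self) -> int:
        return int(self.flags.sum())

    def to_records(self, fs: float) -> list[dict]:
        """Interval table (channel, start_s, end_s, reason)."""
        out = []
        for c, segs in enumerate(self.segments):
            for start, stop, reason in segs:
                out.append({"channel": c + 1, "start_s": start / fs,
                            "end_s": stop / fs, "reason": reason})
        return out


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as half-open (start, stop) index pairs."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[::2], idx[1::2]))


def _robust_sd(x: np.ndarray) -> float:
    return _MAD_SCALE * float(np.median(np.abs(x - np.median(x))))


def detect_artifacts(series: HemoTimeSeries, spike_z: float = 5.0,
                     jump_z: float = 5.0, window_s: float = 2.0) -> ArtifactMask:
    """Flag spikes and discontinuities on each oxyHb channel.

    spike: |x - moving median| exceeds ``spike_z`` robust SDs (isolated).
    discontinuity: a first difference exceeds ``jump_z`` robust SDs and is not
    paired with an adjacent opposite-sign excursion (which would be a spike).
    """
    fs = series.sampling_rate
    win = max(3, int(round(window_s * fs)) | 1)  # odd, >= 3 samples
    if window_s * fs < 3:
        raise PreprocessError("window_s must span at least 3 samples")
    n, n_ch = series.oxy.shape
    flags = np.zeros((n, n_ch), dtype=bool)
    segments: list[list[tuple[int, int, str]]] = []
    half = win // 2
    for c in range(n_ch):
        x = series.oxy[:, c]
        ch_segs: list[tuple[int, int, str]] = []
        if np.ptp(x) == 0:
            logger.warning("channel %d is constant; no artifact detection", c + 1)
            segments.append(ch_segs)
            continue
        med = ndimage.median_filter(x, size=win, mode="nearest")
        resid = x - med
        rsd = _robust_sd(resid)
        d = np.diff(x)
        rsd_d = _robust_sd(d)

        spike_pts = np.zeros(n, dtype=bool)
        disc_pts = np.zeros(n, dtype=bool)
        if rsd > 0:
            spike_pts |= np.abs(resid) > spike_z * rsd
        if rsd_d > 0:
            big = np.abs(d) > jump_z * rsd_d
            for i in np.flatnonzero(big):
                paired = (i + 1 < d.size and big[i + 1] and d[i] * d[i + 1] < 0) or \
                         (i - 1 >= 0 and big[i - 1] and d[i] * d[i - 1] < 0)
                if paired:
                    spike_pts[i:min(i + 2, n)] = True
                else:
                    disc_pts[max(0, i):min(i + 2, n)] = True
        # spikes inside a discontinuity neighborhood belong to the step
        grow = np.zeros(n, dtype=bool)
        for s0, s1 in _runs(disc_pts):
            grow[max(0, s0 - half):min(n, s1 + half)] = True
        spike_pts &= ~grow

        ch_flags = spike_pts | disc_pts
        flags[:, c] = ch_flags
        for s0, s1 in _runs(ch_flags):
            reason = "discontinuity" if disc_pts[s0:s1].any() else "spike"
            ch_segs.append((int(s0), int(s1), reason))
        segments.append(ch_segs)
    return ArtifactMask(flags=flags, segments=segments)


def repair(series: HemoTimeSeries, mask: ArtifactMask,
           method: str = "interpolate") -> HemoTimeSeries:
    """Replace flagged spans by linear interpolation between clean neighbors.

    ``method='nan'`` inserts missing markers instead. Leading/trailing flagged
    spans are back-/forward-filled from the nearest clean sample. Untouched
    samples are returned bit-identical.
    """
    if method not in ("interpolate", "nan"):
        raise PreprocessError(f"unknown repair method {method!r}")
    if mask.flags.shape != series.oxy.shape:
        raise PreprocessError("mask shape does not match series")
    out = series.copy()
    n = series.n_samples
    idx = np.arange(n)
    for c in range(series.n_channels):
        bad = mask.flags[:, c]
        if not bad.any():
            continue
        if bad.all():
            raise PreprocessError(f"channel {c + 1} is fully flagged; cannot repair")
        if method == "nan":
            out.oxy[bad, c] = np.nan
            out.deoxy[bad, c] = np.nan
        else:
            good = ~bad
            out.oxy[bad, c] = np.interp(idx[bad], idx[good], series.oxy[good, c])
            out.deoxy[bad, c] = np.interp(idx[bad], idx[good], series.deoxy[good, c])
    return out


def bandpass(series: HemoTimeSeries, low_hz: float = 0.01,
             high_hz: float = 0.2, order: int = 4) -> HemoTimeSeries:
    """Zero-phase Butterworth band-pass of all hemoglobin channels."""
    fs = series.sampling_rate
    nyq = fs / 2.0
    if not 0 < low_hz < high_hz < nyq:
        raise PreprocessError(
            f"need 0 < low ({low_hz}) < high ({high_hz}) < Nyquist ({nyq})")
    tau = 1.0 / (2.0 * np.pi * low_hz)  # time constant of the high-pass edge
    if series.n_samples / fs < 3.0 * tau:
        raise PreprocessError(
            f"recording ({series.n_samples / fs:.0f} s) shorter than 3 filter "
            f"time constants ({3 * tau:.0f} s) at low cut {low_hz} Hz")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs,
                        output="sos")
    oxy = signal.sosfiltfilt(sos, series.oxy, axis=0)
    deoxy = signal.sosfiltfilt(sos, series.deoxy, axis=0)
    return HemoTimeSeries(sampling_rate=fs, oxy=oxy, deoxy=deoxy)
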