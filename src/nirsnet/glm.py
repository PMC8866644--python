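"""Per-channel GLM activation mapping and hotspot selection.

The oxyHb series of each channel is modelled as

    y = beta * x_task + DCT drift + intercept + error

where x_task is the task-minus-control boxcar convolved with a canonical
double-gamma hemodynamic response function (HRF). Before fitting, both data
and design are *precolored*: smoothed by convolution with the HRF kernel so
the error covariance after smoothing is dominated by the known kernel
(V = K K'). Inference then uses ordinary least squares with a sandwich
variance and Satterthwaite effective degrees of freedom

    eff_df = trace(R V)^2 / trace(R V R V),   R = I - X_s (X_s'X_s)^+ X_s'

with X_s = K X, the classical precoloring scheme of SPM-style fNIRS/fMRI
analysis. The stimulation target ("hotspot") is the channel with the largest
|t| among channels with p < alpha, relaxing alpha in fixed increments until a
channel qualifies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy import stats as sps

from .design import BlockDesign
from .errors import DesignError, StatsError

logger = logging.getLogger("nirsnet")


# ---------------------------------------------------------------------------
# HRF
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HrfParams:
    """Canonical double-gamma HRF parameters (seconds, dimensionless ratios).

    The response gamma is parameterized so its mode falls exactly at
    ``peak_delay``; likewise for the undershoot. Defaults are the
    conventional 6 s peak / 16 s undershoot / ratio 1:6 / 32 s kernel.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    kernel_length: float = 32.0

    def __post_init__(self) -> None:
        for name in ("peak_delay", "undershoot_delay", "peak_dispersion",
                     "undershoot_dispersion", "kernel_length"):
            if getattr(self, name) <= 0:
                raise DesignError(f"HRF parameter {name} must be > 0")
        if self.undershoot_ratio < 0:
            raise DesignError("undershoot_ratio must be >= 0")


def canonical_hrf(fs: float, params: HrfParams = HrfParams()) -> np.ndarray:
    """Sample the double-gamma kernel at 1/fs, normalized to unit peak."""
    if fs <= 0:
        raise DesignError("sampling rate must be > 0")
    if params.kernel_length < params.undershoot_delay:
        logger.warning(
            "HRF kernel length %.1f s shorter than undershoot delay %.1f s",
            params.kernel_length, params.undershoot_delay,
        )
    t = np.arange(0, params.kernel_length, 1.0 / fs)
    # shape = delay/dispersion + 1 puts the gamma mode exactly at the delay
    g1 = sps.gamma.pdf(t, a=params.peak_delay / params.peak_dispersion + 1.0,
                       scale=params.peak_dispersion)
    g2 = sps.gamma.pdf(t, a=params.undershoot_delay / params.undershoot_dispersion + 1.0,
                       scale=params.undershoot_dispersion)
    h = g1 - params.undershoot_ratio * g2
    peak = h.max()
    if peak <= 0:
        raise DesignError("HRF kernel has non-positive peak; check parameters")
    return h / peak


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    X: np.ndarray                # (n_samples, n_cols)
    labels: list[str]
    sampling_rate: float
    task_index: int = 0

    def __post_init__(self) -> None:
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            # name the offending columns for the error message
            bad = []
            for j in range(self.X.shape[1]):
                others = np.delete(self.X, j, axis=1)
                resid = self.X[:, j] - others @ np.linalg.lstsq(others, self.X[:, j],
                                                                rcond=None)[0]
                if np.linalg.norm(resid) < 1e-10 * max(1.0, np.linalg.norm(self.X[:, j])):
                    bad.append(self.labels[j])
            raise DesignError(f"design matrix is rank deficient; collinear columns: {bad}")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]


def dct_drift_basis(n_samples: int, fs: float, cutoff_s: float) -> np.ndarray:
    """DCT-II high-pass drift basis: columns k = 1..K, K = floor(2 T / cutoff)."""
    if cutoff_s <= 0:
        raise DesignError("DCT cutoff must be > 0")
    if np.isinf(cutoff_s):
        return np.empty((n_samples, 0))
    total_s = n_samples / fs
    K = int(np.floor(2.0 * total_s / cutoff_s))
    n = np.arange(n_samples)
    cols = [np.sqrt(2.0 / n_samples) * np.cos(np.pi * k * (2 * n + 1) / (2 * n_samples))
            for k in range(1, K + 1)]
    return np.column_stack(cols) if cols else np.empty((n_samples, 0))


def build_design(design: BlockDesign, fs: float, n_samples: int,
                 dct_cutoff_s: float, hrf_kernel: np.ndarray) -> DesignMatrix:
    """Task-minus-control regressor, DCT drift basis and intercept."""
    if n_samples != design.n_samples:
        raise DesignError(
            f"n_samples {n_samples} does not match design ({design.n_samples})"
        )
    boxcar = design.task_indicator() - design.control_indicator()
    task = np.convolve(boxcar, hrf_kernel)[:n_samples]
    drift = dct_drift_basis(n_samples, fs, dct_cutoff_s)
    intercept = np.ones(n_samples)
    X = np.column_stack([task, drift, intercept])
    labels = (["task"] + [f"dct{k}" for k in range(1, drift.shape[1] + 1)]
              + ["intercept"])
    return DesignMatrix(X=X, labels=labels, sampling_rate=fs, task_index=0)


# ---------------------------------------------------------------------------
# Precolored fit
# ---------------------------------------------------------------------------

def _convolution_matrix(kernel: np.ndarray, n: int) -> sparse.csr_matrix:
    """Lower-triangular (causal, truncated) convolution matrix K."""
    kernel = np.asarray(kernel, dtype=float)
    L = min(len(kernel), n)
    diags = [np.full(n - i, kernel[i]) for i in range(L)]
    return sparse.diags(diags, offsets=[-i for i in range(L)], format="csr")


class PrecoloredDesign:
    """Design-side quantities of the precolored GLM, reusable across channels.

    Building this object performs the expensive work (smoothing the design,
    the Satterthwaite trace terms); fitting a channel is then a convolution
    plus small linear algebra.
    """

    def __init__(self, design: DesignMatrix, kernel: np.ndarray):
        kernel = np.asarray(kernel, dtype=float)
        s = kernel.sum()
        if s <= 0:
            raise DesignError("precoloring kernel must have positive sum")
        self.kernel = kernel / s  # unit-DC smoothing; t and df invariant to scale
        self.design = design
        n = design.n_samples
        X = design.X
        self.Xs = np.apply_along_axis(
            lambda col: np.convolve(col, self.kernel)[:n], 0, X)
        self.XtX_inv = np.linalg.inv(self.Xs.T @ self.Xs)
        K = _convolution_matrix(self.kernel, n)
        V = (K @ K.T).tocsr()
        # trace terms: tr(RV) = tr(V) - tr(PV); tr(RVRV) = tr(VV) - 2 tr(PVV) + tr(PVPV)
        tr_V = V.diagonal().sum()
        VX = V @ self.Xs                       # (n, p)
        M = self.Xs.T @ VX                     # X_s' V X_s
        A = self.XtX_inv @ M
        tr_PV = np.trace(A)
        tr_VV = float((V.data ** 2).sum())  # tr(VV') = ||V||_F^2, V symmetric
        tr_PVV = np.trace(self.XtX_inv @ (VX.T @ VX))
        tr_PVPV = np.trace(A @ A)
        self.trace_RV = tr_V - tr_PV
        self.trace_RVRV = tr_VV - 2.0 * tr_PVV + tr_PVPV
        self.eff_df = self.trace_RV ** 2 / self.trace_RVRV
        if self.eff_df < 1:
            raise DesignError(
                f"effective degrees of freedom {self.eff_df:.2f} < 1; recording too short"
            )
        # contrast variance factor for the task column: c'(X'X)^+ X' V X (X'X)^+ c
        c = np.zeros(X.shape[1])
        c[design.task_index] = 1.0
        cov_beta = self.XtX_inv @ M @ self.XtX_inv
        self.task_var_factor = float(c @ cov_beta @ c)

    def fit(self, y: np.ndarray) -> tuple[float, float, float, float]:
        """Fit one channel; returns (beta_task, t, p, eff_df)."""
        y = np.asarray(y, dtype=float)
        n = self.design.n_samples
        if y.shape != (n,):
            raise DesignError(f"series length {y.shape} does not match design ({n},)")
        ys = np.convolve(y, self.kernel)[:n]
        beta = self.XtX_inv @ (self.Xs.T @ ys)
        resid = ys - self.Xs @ beta
        sigma2 = float(resid @ resid) / self.trace_RV
        b = float(beta[self.design.task_index])
        se = np.sqrt(sigma2 * self.task_var_factor)
        if se == 0:
            t = np.inf if b != 0 else 0.0
        else:
            t = b / se
        p = 2.0 * sps.t.sf(abs(t), df=self.eff_df)
        return b, float(t), float(p), float(self.eff_df)


def precolor_and_fit(y: np.ndarray, design: DesignMatrix,
                     kernel: np.ndarray) -> tuple[float, float, float, float]:
    """One-shot precolored fit of a single channel (see PrecoloredDesign)."""
    return PrecoloredDesign(design, kernel).fit(y)


@dataclass
class ActivationResult:
    """Per-channel GLM results and the selected stimulation target."""

    channel_ids: list[int]
    beta: np.ndarray
    t: np.ndarray
    p: np.ndarray
    eff_df: np.ndarray
    hotspot_channel: int
    alpha_used: float

    def to_records(self) -> list[dict]:
        return [
            {"channel": int(c), "beta": float(b), "t": float(t), "p": float(p),
             "eff_df": float(d)}
            for c, b, t, p, d in zip(self.channel_ids, self.beta, self.t,
                                     self.p, self.eff_df)
        ]


def select_hotspot(t: np.ndarray, p: np.ndarray, alpha0: float = 0.05,
                   step: float = 0.001,
                   channel_ids: list[int] | None = None) -> tuple[int, float]:
    """Largest-|t| channel among those with p < alpha, relaxing alpha by
    ``step`` until the candidate set is non-empty.

    Ties on |t| break toward the lowest channel id (logged). alpha values are
    rounded to 12 decimals so the grid is the exact decimal ladder
    alpha0, alpha0+step, ...
    """
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    if t.size == 0:
        raise StatsError("hotspot selection needs at least one channel")
    if not (0 < alpha0 < 1) or step <= 0:
        raise StatsError("alpha0 must be in (0,1) and step > 0")
    if channel_ids is None:
        channel_ids = list(range(1, t.size + 1))
    ids = np.asarray(channel_ids)
    m = 0
    while True:
        alpha = round(alpha0 + m * step, 12)
        cand = np.flatnonzero(p < alpha)
        if cand.size:
            break
        if alpha > 1.0:
            # p <= 1 always, so p < alpha for alpha > 1 unless p is NaN
            raise StatsError("no channel with a finite p-value")
        m += 1
    abs_t = np.abs(t[cand])
    best = abs_t.max()
    winners = cand[abs_t == best]
    if winners.size > 1:
        logger.info("hotspot |t| tie among channels %s; choosing lowest id",
                    ids[winners].tolist())
    choice = winners[np.argmin(ids[winners])]
    return int(ids[choice]), float(alpha)


# The design-side work of PrecoloredDesign is O(n * kernel^2) and identical
# across channels, subjects and replicate simulations that share one design;
# cache it. Keys hold a strong reference to the design so ids stay unique.
_PRECOLOR_CACHE: dict[tuple[int, bytes], tuple[DesignMatrix, "PrecoloredDesign"]] = {}


def precolored_design(design: DesignMatrix, kernel: np.ndarray) -> PrecoloredDesign:
    key = (id(design), np.asarray(kernel, dtype=float).tobytes())
    hit = _PRECOLOR_CACHE.get(key)
    if hit is None:
        if len(_PRECOLOR_CACHE) > 8:
            _PRECOLOR_CACHE.clear()
        hit = (design, PrecoloredDesign(design, kernel))
        _PRECOLOR_CACHE[key] = hit
    return hit[1]


def fit_channels(oxy: np.ndarray, design: DesignMatrix, kernel: np.ndarray,
                 channel_ids: list[int] | None = None, alpha0: float = 0.05,
                 step: float = 0.001) -> ActivationResult:
    """Fit every channel of an oxyHb matrix and select the hotspot."""
    pre = precolored_design(design, kernel)
    n_ch = oxy.shape[1]
    if channel_ids is None:
        channel_ids = list(range(1, n_ch + 1))
    beta = np.empty(n_ch)
    t = np.empty(n_ch)
    p = np.empty(n_ch)
    df = np.empty(n_ch)
    for j in range(n_ch):
        beta[j], t[j], p[j], df[j] = pre.fit(oxy[:, j])
    hot, alpha = select_hotspot(t, p, alpha0, step, channel_ids)
    return ActivationResult(channel_ids=list(channel_ids), beta=beta, t=t, p=p,
                            eff_df=df, hotspot_channel=hot, alpha_used=alpha)
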