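"""Nonparametric group tests: Wilcoxon signed-rank and Friedman.

Both tests use the tie-corrected asymptotic normal / chi-square
approximations without continuity correction — the convention of the
mainstream commercial statistics packages, and the one that reproduces the
worked clinical examples in the test suite at n = 5.

Wilcoxon (paired, two-sided): zero differences are dropped, |differences|
are midranked, W+ is the positive-rank sum, and

    z = (W+ - n(n+1)/4) / sqrt( n(n+1)(2n+1)/24 - sum(t^3 - t)/48 )

with t the sizes of tied-rank groups.

Friedman: within-subject midranks r_ij, column sums R_j, and the
tie-corrected statistic

    chi2 = (k - 1) * sum_j (R_j - n(k+1)/2)^2
           / ( sum_ij r_ij^2 - n k (k+1)^2 / 4 ),    df = k - 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import StatsError


@dataclass
class TestResult:
    statistic: float
    p: float
    n: int
    z: float | None = None
    df: float | None = None
    tie_corrected: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.p <= 1:
            raise StatsError(f"p-value {self.p} outside [0, 1]")


def wilcoxon_signed_rank(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Paired two-sided Wilcoxon signed-rank, tie-corrected asymptotic p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatsError("samples must be paired 1-D arrays of equal length")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise StatsError("all paired differences are zero; test undefined")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_groups = counts[counts > 1]
    tie_corrected = tie_groups.size > 0
    var -= float((tie_groups.astype(float) ** 3 - tie_groups).sum()) / 48.0
    if var <= 0:
        raise StatsError("degenerate variance (all differences tied at one rank)")
    z = (w_plus - mu) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return TestResult(statistic=w_plus, p=float(min(p, 1.0)), n=n, z=float(z),
                      tie_corrected=tie_corrected)


def friedman(scores: np.ndarray) -> TestResult:
    """Friedman test on a subjects x conditions matrix, tie-corrected."""
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2:
        raise StatsError("scores must be a subjects x conditions matrix")
    n, k = scores.shape
    if n < 2 or k < 2:
        raise StatsError("need >= 2 subjects and >= 2 conditions")
    ranks = np.apply_along_axis(sps.rankdata, 1, scores)  # midranks per subject
    col_sums = ranks.sum(axis=0)
    num = float(((col_sums - n * (k + 1) / 2.0) ** 2).sum())
    denom = float((ranks ** 2).sum()) - n * k * (k + 1) ** 2 / 4.0
    if denom <= 0:
        raise StatsError("degenerate Friedman denominator (all scores tied)")
    chi2 = (k - 1) * num / denom
    p = float(sps.chi2.sf(chi2, df=k - 1))
    tie_corrected = bool(np.any(np.apply_along_axis(
        lambda r: np.unique(r).size < r.size, 1, ranks)))
    return TestResult(statistic=float(chi2), p=p, n=n, df=float(k - 1),
                      tie_corrected=tie_corrected)


def normal_upper_tail(z: float) -> float:
    """Upper-tail probability 1 - Phi(z) of a standard normal."""
    if not np.isfinite(z):
        raise StatsError("z must be finite")
    return float(sps.norm.sf(z))
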