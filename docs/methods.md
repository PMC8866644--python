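# Methods

This note documents the models, conventions and numerical choices behind
each pipeline stage, what the synthetic cohort generator does and does not
emulate, and the problem sizes the validation experiments use.

## Optical conversion (modified Beer–Lambert law)

Optical-density change is decadic, ΔOD = −log10(I/I0), with I0 the
per-channel baseline intensity. Concentration changes (mol/L) solve the
2×2 system ΔOD(λ)/(L·DPF(λ)) = ε_HbO(λ)ΔC_HbO + ε_HbR(λ)ΔC_HbR per channel
and sample. The forward and inverse maps are exact mutual inverses; the
simulator generates intensities through the forward map, so the conversion
stage is validated to machine precision on noise-free series.

Parameters:

* **Wavelengths** 760/850 nm; **DPF** 7.25 (760 nm) and 6.38 (850 nm) —
  standard adult-head values for this wavelength pair.
* **Extinction coefficients**: decadic molar values from the widely used
  Prahl (OMLC) compilation, shipped as a pinned, citable TSV resource and
  selected by table id. Compilations differ by a few percent; pinning one
  and logging its condition number keeps runs reproducible. Absolute
  concentration values therefore carry the compilation's convention;
  everything downstream of the GLM/correlation stages is invariant to such
  per-channel linear rescalings.
* **Path length** L = montage source–detector separation (3 cm default).

## Preprocessing

* **Band-pass**: 4th-order Butterworth, 0.01–0.2 Hz, applied
  forward-backward (`sosfiltfilt`), i.e. zero-phase with squared magnitude
  response. The band keeps the block-design response (1/60 Hz) and rejects
  cardiac (~1 Hz) and respiratory (~0.25 Hz) oscillations and slow drift.
  Recordings shorter than three time constants of the high-pass edge
  (3/(2π·0.01 Hz) ≈ 48 s) are refused. Filtering is applied to
  concentrations; since both the MBLL solve and the filter are linear, the
  order of conversion and filtering is mathematically immaterial.
* **Artifact handling** is automated: spikes are isolated excursions
  exceeding `spike_z` (default 5) robust SDs from a running median (window
  2 s); discontinuities are unpaired first differences exceeding `jump_z`
  (default 5) robust SDs of the differenced series. An impulse produces two
  adjacent opposite-sign large differences and is classed as a spike; a
  lone large difference is a baseline step. Flagged spans are linearly
  interpolated between clean neighbors (boundary spans are back-/forward-
  filled); a `nan` mode inserts missing markers instead, and detection can
  be disabled entirely in the config.

## Activation GLM and hotspot rule

* **HRF**: double-gamma difference, normalized to unit peak. The gammas are
  parameterized so the response mode falls exactly at `peak_delay`
  (shape = delay/dispersion + 1); defaults: peak 6 s, undershoot 16 s,
  dispersions 1, undershoot ratio 1/6, kernel 32 s.
* **Design**: task regressor = (task − control boxcar) ⊗ HRF; DCT-II drift
  basis with K = floor(2T/cutoff) columns (cutoff 128 s, so K = 7 at
  T = 480 s); intercept. The drift columns are orthonormal.
* **Inference by precoloring**: data and design are smoothed with the HRF
  kernel (unit-DC normalization; results are invariant to kernel scale), so
  the error covariance after smoothing is dominated by the known V = KK′.
  OLS on the smoothed pair, sandwich variance
  σ̂²·c′(X′X)⁻¹X′VX(X′X)⁻¹c with σ̂² = RSS/tr(RV), and Satterthwaite
  effective degrees of freedom tr(RV)²/tr(RVRV). The trace terms are
  computed exactly with a sparse banded convolution matrix and reused across
  channels and replicate fits sharing one design. With an identity kernel
  the machinery reduces exactly to classical OLS (checked against the
  closed-form correlation t in the tests); on white noise the empirical
  false-positive rate at nominal 0.05 is ≈0.05.
* **Hotspot**: among channels with p < α, the largest |t| wins; if no
  channel qualifies at α = 0.05, α is relaxed in 0.001 steps until one
  does. α values are rounded to 12 decimals so the ladder is the exact
  decimal grid (p = 0.06 exits at α = 0.061, not at a floating-point
  neighbor of 0.060). |t| (not signed t) governs the choice, so a strong
  deactivation could be selected; ties break to the lowest channel id and
  are logged. The per-channel threshold is uncorrected across channels.

## Connectivity

Pearson r over the full processed recording by default (a `task_blocks`
window concatenating task samples is available). Fisher z = atanh r is
applied before any averaging or thresholding; |r| = 1 maps to signed
infinity and is excluded pairwise from group means, with counts tracked.
Strong edges are unordered pairs with mean z above 1.0 — calibrated
against the standard normal upper tail, 1 − Φ(1) = 15.866% — reported
strongest-first with a line-thickness class (0.5-wide z bins) for the
connectivity figure.

## Hemispheric networks over sparsity

Graphs are binary and undirected. At sparsity S the round(S·n(n−1)/2)
largest-weight pairs become edges (round half up; ties at the cut break by
larger weight then lexicographic pair order). Edge ranking uses signed z —
a positive strong-connectivity threshold implies positive coupling — with
an |z| option. Hemispheric profiles re-rank edges within the hemisphere's
13-channel subgraph, so sparsity is hemisphere-local. Undefined weights
are excluded from ranking with a warning.

Metrics (in-package implementations, cross-checked in the tests against
brute-force triangle enumeration, Floyd–Warshall, and networkx):

* clustering coefficient C = mean over nodes of 2tᵢ/(kᵢ(kᵢ−1)), with
  Cᵢ = 0 when kᵢ < 2;
* global efficiency E = mean over ordered pairs of 1/d_ij, 0 for
  disconnected pairs (hop distances via breadth-first shortest paths).

Profile comparison between sessions: at each grid point a paired two-sided
Wilcoxon signed-rank across subjects; grid points where every subject's
difference is zero count as non-significant (the test is undefined there).
Contiguous runs with p < 0.1 are reported as ranges with min/max p and the
sign of the median difference. The per-point alpha is uncorrected across
the sparsity grid — a reporting convention, flagged as such in the results
document.

## Group statistics

Asymptotic, tie-corrected, no continuity correction — the convention of the
mainstream commercial packages, and the one consistent with the worked
clinical examples at n = 5:

* Wilcoxon: zeros dropped, midranks on |d|,
  z = (W⁺ − n(n+1)/4)/√(n(n+1)(2n+1)/24 − Σ(t³−t)/48);
* Friedman: within-subject midranks,
  χ² = (k−1)Σ(R_j − n(k+1)/2)²/(Σr² − nk(k+1)²/4), df = k−1.

On the packaged score table these give p = 0.0431 (AQ, T0→T1), p = 0.0422
(LQ, tie-corrected), and χ² = 6.0, p = e⁻³ = 0.0498 for both Friedman
tests (printed as 0.049 under three-decimal truncation).

## Synthetic cohort generator

Each subject-session is built concentration-first and converted to
intensities by the exact MBLL inverse:

oxyHb = β·(task boxcar ⊗ HRF) + correlated AR(1) noise + systemic
sinusoids + linear drift; deoxyHb = −γ·oxyHb + small independent noise
(γ = 1/3 — a simulation convenience, not a physiological claim; the
analysis uses oxyHb only). Motion spikes are sparse impulses added in the
optical-density domain, where motion artifacts arise, so they are absent
from the returned ground truth.

Study conditions (defaults): 5 subjects × 3 sessions; 2-min rest then six
30-s task blocks alternating six 30-s control blocks (480 s); 26 channels
(12 sources, 10 detectors, 3 cm separation), 13 per hemisphere; sampling
rate 7.8125 Hz (typical of continuous-wave instruments of this class; the
source study does not state one, so it is a config parameter). One
activated channel (10) at β = 0.5 µM; AR(1) noise φ = 0.4 with innovation
SD 0.15 µM through the symmetric PSD square root of the latent correlation
(targets exact in expectation; a common φ preserves them); sinusoids at
1.0/0.25/0.1 Hz with amplitudes 0.10/0.05/0.05 µM and one phase per
frequency per recording — systemic oscillations are spatially coherent,
which is what makes them removable by filtering without destroying the
latent correlation structure; drift 2×10⁻¹⁰ M/s with random sign; spikes
at 1/min, 0.02 OD. The latent network is modular over the six
hemisphere-by-region channel groups: within-module r_w = 0.15 against a
between-module floor r_b = 0.10 — a deliberately weakly modular
("impaired") baseline. Non-PSD module specifications are repaired by
eigenvalue clipping with diagonal renormalization; a repair moving any
entry by more than 0.05 is refused, naming the offending block.

The generator does **not** emulate: photon transport or partial-volume
effects, scalp/systemic component separation, spatially varying DPF,
hemisphere-asymmetric physiology, serial dependence of sessions within a
subject, or lesion anatomy. Passing recovery tests therefore demonstrate
that the pipeline recovers the statistical structure it models — not that
real recordings satisfy that structure.

## Validation experiments (problem sizes)

* **GLM null calibration**: 200 white-noise fits on the default design;
  pass if the 0.05-level rejection rate is within the binomial band.
* **Hotspot recovery**: 100 simulated subjects at the default 0.5 µM
  amplitude (pass at ≥95 recovered); monotonicity checked at three
  amplitudes (0.3/1.2/5 nM) spanning chance to ceiling, 30 runs each.
* **Network-change recovery**: 20 replicate cohorts of 5 subjects × 2
  sessions, with left-hemisphere within-module correlation raised from
  0.15 to 0.5 at the second session; pass if ≥80% of replicates report a
  significant range of higher left clustering. The effect size was set by
  a design-stage power analysis: with ~180 effective samples in the
  0.01–0.2 Hz band, correlation estimates carry sampling error ≈0.075, and
  a rank-thresholded graph responds to modular *contrast*, not to uniform
  correlation scale — a uniform rescaling of all within-hemisphere weights
  leaves every thresholded graph unchanged. The within-module target must
  therefore clearly exceed both the between-module floor and the
  estimation noise.
* **MBLL round trip**: 2000 samples × 26 channels of random concentration
  series; max relative error must stay below 1e−8 (measured ≈4e−16).
* **Graph-metric oracle**: 60 random graphs with n ≤ 8 compared exactly
  against brute-force triangle enumeration and Floyd–Warshall.

All experiments derive their randomness from a single seed and are pure
functions of it; the full acceptance run completes in under a minute on
one CPU.

## Known limitations

* The precolored GLM assumes white pre-smoothing noise; strongly colored
  residuals (unmodelled physiology) make the Satterthwaite df approximate.
* Binary-graph metrics discard weight information; weighted variants are
  out of scope.
* The per-point network alpha (0.1) is uncorrected across sparsity;
  reported ranges are descriptive, not family-wise error controlled.
* Absolute concentration units depend on the pinned extinction table and
  DPFs; cross-study numeric comparability of β is not claimed.
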