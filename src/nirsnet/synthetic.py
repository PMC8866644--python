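"""Forward simulation of block-design fNIRS cohorts with known ground truth.

Each simulated subject-session is built concentration-first and converted to
light intensities by the exact inverse of the MBLL stage, so the analysis
pipeline can be validated end-to-end against known activation amplitudes and
a known latent inter-channel correlation structure:

    oxyHb(t, c) = beta_true(c) * (task boxcar (*) HRF)(t)
                  + correlated AR(1) noise
                  + physiological sinusoids (cardiac / respiratory / Mayer)
                  + linear drift
    deoxyHb     = -gamma * oxyHb + small independent noise

Motion spikes are sparse additive impulses applied in the optical-density
domain (motion artifacts arise optically, not hemodynamically), so they are
absent from the returned ground truth.

The latent correlation structure is modular: channel groups (by default the
six hemisphere-by-region groups of the montage) share a within-module
correlation r_w against a between-module floor r_b. Correlated innovations
are produced through the symmetric PSD square root of the latent correlation
matrix, which makes the targets exact in expectation, and a common AR(1)
coefficient preserves them after temporal filtering of the innovations.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .design import BlockDesign, default_design
from .errors import CovarianceError, DesignError, NirsnetError
from .glm import HrfParams, canonical_hrf
from .mbll import OpticsParams, intensity_from_od, od_from_hemoglobin
from .montage import Montage, default_montage
from .series import HemoTimeSeries, RawIntensity

logger = logging.getLogger("nirsnet")

SESSIONS = ("T0", "T1", "T2")


def make_design(rest_s: float, n_blocks: int, block_s: float, fs: float,
                stimulus_s: float = 2.0) -> BlockDesign:
    """Block design with n_blocks task blocks alternating n_blocks controls."""
    return BlockDesign(
        initial_rest_s=rest_s,
        n_task_blocks=n_blocks,
        n_control_blocks=n_blocks,
        block_s=block_s,
        stimulus_s=stimulus_s,
        sampling_rate=fs,
    )


# ---------------------------------------------------------------------------
# Effect specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LatentModule:
    """A channel group sharing a within-module correlation target."""

    channels: tuple[int, ...]
    r_w: float

    def __post_init__(self) -> None:
        if not 0 <= self.r_w < 1:
            raise CovarianceError("within-module correlation must be in [0, 1)")


def _default_modules(montage: Montage | None = None,
                     r_w: float = 0.15) -> tuple[LatentModule, ...]:
    """Six hemisphere-by-region modules of the default montage."""
    m = montage or default_montage()
    mods = []
    for hemi in ("left", "right"):
        for region in ("broca", "adjacent", "wernicke"):
            ch = tuple(m.region_channels(hemi, region))
            if ch:
                mods.append(LatentModule(channels=ch, r_w=r_w))
    return tuple(mods)


@dataclass(frozen=True)
class EffectSpec:
    """Ground-truth generative parameters for one subject-session.

    Amplitudes are concentration changes in mol/L. Defaults emulate a weakly
    modular ("impaired") resting network with a single activated channel at a
    strong but physiological amplitude (0.5 uM against ~0.16 uM stationary
    noise SD plus physiological oscillations).
    """

    beta: dict[int, float] = field(default_factory=lambda: {10: 5e-7})
    ar_coef: float = 0.4
    innovation_sd: float = 1.5e-7
    physio: tuple[tuple[float, float], ...] = (
        (1.0, 1.0e-7),    # cardiac
        (0.25, 5.0e-8),   # respiration
        (0.1, 5.0e-8),    # Mayer waves
    )
    drift_slope: float = 2e-10      # mol/L per second
    spike_rate_per_min: float = 1.0
    spike_od: float = 0.02          # optical-density units
    modules: tuple[LatentModule, ...] = field(default_factory=_default_modules)
    r_b: float = 0.10
    deoxy_gamma: float = 1.0 / 3.0
    deoxy_noise_sd: float = 5e-8

    def __post_init__(self) -> None:
        if not abs(self.ar_coef) < 1:
            raise CovarianceError("|AR(1) coefficient| must be < 1")
        seen: set[int] = set()
        for mod in self.modules:
            if seen & set(mod.channels):
                raise CovarianceError("latent modules must be disjoint")
            seen |= set(mod.channels)
            if not self.r_b <= mod.r_w:
                raise CovarianceError("need 0 <= r_b <= r_w < 1 for every module")
        if not 0 <= self.r_b < 1:
            raise CovarianceError("between-module correlation must be in [0, 1)")

    def beta_vector(self, n_channels: int) -> np.ndarray:
        b = np.zeros(n_channels)
        for ch, amp in self.beta.items():
            if not 1 <= ch <= n_channels:
                raise NirsnetError(f"beta assigned to unknown channel {ch}")
            b[ch - 1] = amp
        return b

    def with_hemisphere_rw(self, montage: Montage, hemisphere: str,
                           r_w: float) -> "EffectSpec":
        """Return a copy with every module inside ``hemisphere`` set to r_w."""
        hemi = set(montage.hemisphere_channels(hemisphere))
        mods = tuple(
            dataclasses.replace(mod, r_w=r_w) if set(mod.channels) <= hemi else mod
            for mod in self.modules
        )
        return dataclasses.replace(self, modules=mods)


# ---------------------------------------------------------------------------
# Latent correlation
# ---------------------------------------------------------------------------

def latent_covariance(spec: EffectSpec, n_channels: int,
                      repair_tol: float = 0.05) -> np.ndarray:
    """Latent inter-channel correlation matrix implied by the module spec.

    Off-diagonal entries are r_b except within a module, where they are that
    module's r_w. If the construction is not PSD it is repaired by eigenvalue
    clipping and diagonal renormalization; a repair that moves any entry by
    more than ``repair_tol`` raises, naming the offending module.
    """
    R = np.full((n_channels, n_channels), spec.r_b)
    np.fill_diagonal(R, 1.0)
    for mod in spec.modules:
        idx = np.array(mod.channels) - 1
        if idx.min() < 0 or idx.max() >= n_channels:
            raise CovarianceError(
                f"module channels {mod.channels} outside 1..{n_channels}")
        R[np.ix_(idx, idx)] = mod.r_w
        R[idx, idx] = 1.0
    w = np.linalg.eigvalsh(R)
    if w.min() < -1e-10:
        logger.warning("latent correlation not PSD (min eig %.3g); repairing", w.min())
        vals, vecs = np.linalg.eigh(R)
        vals = np.clip(vals, 0.0, None)
        R_fix = (vecs * vals) @ vecs.T
        d = np.sqrt(np.diag(R_fix))
        R_fix = R_fix / np.outer(d, d)
        delta = np.abs(R_fix - R)
        if delta.max() > repair_tol:
            i, j = np.unravel_index(np.argmax(delta), delta.shape)
            owner = next((m for m in spec.modules
                          if i + 1 in m.channels and j + 1 in m.channels), None)
            where = f"module {owner.channels}" if owner else f"pair ({i + 1}, {j + 1})"
            raise CovarianceError(
                f"latent correlation infeasible: PSD repair moved {where} by "
                f"{delta.max():.3f} (> {repair_tol})")
        R = R_fix
    return R


def _psd_sqrt(R: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(R)
    vals = np.clip(vals, 0.0, None)
    return (vecs * np.sqrt(vals)) @ vecs.T


# ---------------------------------------------------------------------------
# Subject simulation
# ---------------------------------------------------------------------------

@dataclass
class SubjectRecording:
    subject: int
    session: str
    raw: RawIntensity
    truth: HemoTimeSeries
    beta_true: np.ndarray
    latent_correlation: np.ndarray
    seed_entropy: int


def simulate_subject(
    montage: Montage,
    design: BlockDesign,
    spec: EffectSpec,
    hrf_params: HrfParams = HrfParams(),
    seed: int | np.random.SeedSequence | None = None,
    optics: OpticsParams | None = None,
    baseline_intensity: float = 1.0,
) -> tuple[HemoTimeSeries, RawIntensity]:
    """Simulate one recording; returns (ground-truth hemoglobin, intensities)."""
    if seed is None:
        raise NirsnetError("simulate_subject requires an explicit seed")
    rng = np.random.default_rng(seed)
    fs = design.sampling_rate
    n = design.n_samples
    n_ch = montage.n_channels
    t = np.arange(n) / fs

    beta = spec.beta_vector(n_ch)
    kernel = canonical_hrf(fs, hrf_params)
    regressor = np.convolve(design.task_indicator(), kernel)[:n]
    oxy = beta[None, :] * regressor[:, None]

    # correlated AR(1) noise: common AR coefficient preserves the lag-0
    # cross-correlation of the innovations
    R = latent_covariance(spec, n_ch)
    if spec.innovation_sd > 0:
        burn = int(np.ceil(5.0 / (1.0 - abs(spec.ar_coef)))) if spec.ar_coef else 0
        innov = rng.standard_normal((n + burn, n_ch)) * spec.innovation_sd
        innov = innov @ _psd_sqrt(R).T
        noise = signal.lfilter([1.0], [1.0, -spec.ar_coef], innov, axis=0)[burn:]
        oxy = oxy + noise

    for freq, amp in spec.physio:
        if amp > 0:
            # systemic oscillations are spatially coherent: one phase per
            # frequency per recording, shared by all channels
            phase = rng.uniform(0, 2 * np.pi)
            oxy = oxy + amp * np.sin(2 * np.pi * freq * t + phase)[:, None]

    if spec.drift_slope:
        # per-channel drift of the stated magnitude, random sign
        sign = rng.choice([-1.0, 1.0], size=n_ch)
        oxy = oxy + spec.drift_slope * sign[None, :] * t[:, None]

    deoxy = -spec.deoxy_gamma * oxy
    if spec.deoxy_noise_sd > 0:
        deoxy = deoxy + rng.standard_normal((n, n_ch)) * spec.deoxy_noise_sd

    truth = HemoTimeSeries(sampling_rate=fs, oxy=oxy, deoxy=deoxy)

    if optics is None:
        optics = OpticsParams(separations_cm=montage.separations_cm)
    od = od_from_hemoglobin(truth, optics)

    if spec.spike_rate_per_min > 0 and spec.spike_od > 0:
        lam = spec.spike_rate_per_min * (n / fs) / 60.0
        for c in range(n_ch):
            k = rng.poisson(lam)
            if k:
                pos = rng.integers(0, n, size=k)
                mag = spec.spike_od * rng.choice([-1.0, 1.0], size=k)
                od[pos, c, :] += mag[:, None]  # motion hits both wavelengths

    baseline = np.full((n_ch, 2), baseline_intensity)
    raw = intensity_from_od(od, baseline, fs)
    return truth, raw


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    montage: Montage
    design: BlockDesign
    recordings: list[SubjectRecording]
    specs: dict[str, EffectSpec]

    @property
    def subjects(self) -> list[int]:
        return sorted({r.subject for r in self.recordings})

    @property
    def sessions(self) -> list[str]:
        seen: list[str] = []
        for r in self.recordings:
            if r.session not in seen:
                seen.append(r.session)
        return seen

    def get(self, subject: int, session: str) -> SubjectRecording:
        for r in self.recordings:
            if r.subject == subject and r.session == session:
                return r
        raise KeyError((subject, session))


def simulate_cohort(
    n_subjects: int,
    sessions: list[str] | tuple[str, ...] = SESSIONS,
    spec: EffectSpec | None = None,
    session_overrides: dict[str, EffectSpec] | None = None,
    seed: int | None = None,
    montage: Montage | None = None,
    design: BlockDesign | None = None,
    hrf_params: HrfParams = HrfParams(),
) -> Cohort:
    """Simulate a cohort; subject-session seeds derive from the master seed."""
    if n_subjects < 1:
        raise NirsnetError("need at least one subject")
    if seed is None:
        raise NirsnetError("simulate_cohort requires an explicit seed")
    for s in sessions:
        if s not in SESSIONS:
            raise NirsnetError(f"unknown session label {s!r}; expected one of {SESSIONS}")
    montage = montage or default_montage()
    spec = spec or EffectSpec()
    overrides = session_overrides or {}
    for s in overrides:
        if s not in sessions:
            raise NirsnetError(f"override for session {s!r} not in {list(sessions)}")
    fs_default = 7.8125
    design = design or default_design(fs_default)

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_subjects * len(sessions))
    recordings: list[SubjectRecording] = []
    specs: dict[str, EffectSpec] = {}
    k = 0
    for subj in range(1, n_subjects + 1):
        for sess in sessions:
            sess_spec = overrides.get(sess, spec)
            specs[sess] = sess_spec
            truth, raw = simulate_subject(montage, design, sess_spec, hrf_params,
                                          seed=children[k])
            recordings.append(SubjectRecording(
                subject=subj, session=sess, raw=raw, truth=truth,
                beta_true=sess_spec.beta_vector(montage.n_channels),
                latent_correlation=latent_covariance(sess_spec, montage.n_channels),
                seed_entropy=int(children[k].entropy) % (2 ** 31),
            ))
            k += 1
    return Cohort(montage=montage, design=design, recordings=recordings, specs=specs)
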