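"""End-to-end orchestration: preprocess -> activation -> connectivity ->
network -> group statistics, with a deterministic machine-readable report.

A run is a pure function of (config, cohort): repeating it produces a
byte-identical JSON document. Every stage is logged to stderr with its
parameters.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .clinical import ClinicalScores, scores_matrix
from .config import PipelineConfig
from .connectivity import correlation_matrix, group_average, strong_edges
from .errors import NirsnetError
from .glm import canonical_hrf, fit_channels
from .mbll import OpticsParams, hemoglobin_from_od, load_extinction_table, od_from_intensity
from .network import compare_profiles, sparsity_profile
from .preprocess import bandpass, detect_artifacts, repair
from .stats import friedman, wilcoxon_signed_rank
from .synthetic import Cohort

logger = logging.getLogger("nirsnet")


@dataclass
class Report:
    """Machine-readable pipeline results."""

    config: dict
    activation: dict = field(default_factory=dict)   # "subj/sess" -> records + hotspot
    connectivity: dict = field(default_factory=dict)  # session -> strong edges
    network: dict = field(default_factory=dict)       # profiles and comparisons
    clinical: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_json(self) -> str:
        doc = {
            "config": self.config,
            "activation": self.activation,
            "connectivity": self.connectivity,
            "network": self.network,
            "clinical": self.clinical,
            "warnings": self.warnings,
        }
        return json.dumps(doc, sort_keys=True, indent=1) + "\n"

    def write(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(self.to_json())


def _round(x: float, nd: int = 10) -> float:
    """Stable rounding so report JSON is platform-reproducible."""
    return float(round(float(x), nd))


def run_pipeline(config: PipelineConfig, cohort: Cohort,
                 clinical: list[ClinicalScores] | None = None) -> Report:
    config.validate()
    if not cohort.recordings:
        raise NirsnetError("cohort has no recordings")
    montage = cohort.montage
    montage.require_bilateral()
    fs = cohort.design.sampling_rate
    kernel = canonical_hrf(fs, config.hrf)
    optics = OpticsParams(separations_cm=montage.separations_cm,
                          dpf=config.dpf,
                          extinction=load_extinction_table(config.extinction_table))
    report = Report(config=config.to_dict())
    logger.info("pipeline start: %d recordings, seed %d",
                len(cohort.recordings), config.seed)

    # per-recording stages
    matrices: dict[str, list] = {}
    processed: dict[tuple[int, str], np.ndarray] = {}
    for rec in cohort.recordings:
        ctx = f"subject {rec.subject} session {rec.session}"
        try:
            od = od_from_intensity(rec.raw)
            hemo = hemoglobin_from_od(od, optics, fs)
            if config.artifact_removal:
                mask = detect_artifacts(hemo, config.spike_z, config.jump_z,
                                        config.artifact_window_s)
                hemo = repair(hemo, mask)
                logger.info("%s: %d samples repaired", ctx, mask.n_flagged)
            hemo = bandpass(hemo, config.low_hz, config.high_hz)
            act = fit_channels(hemo.oxy, _design_matrix(cohort, config, kernel),
                               kernel, montage.channel_ids,
                               config.hotspot_alpha0, config.hotspot_step)
            logger.info("%s: hotspot channel %d (alpha %.3f)",
                        ctx, act.hotspot_channel, act.alpha_used)
            report.activation[f"{rec.subject}/{rec.session}"] = {
                "hotspot_channel": act.hotspot_channel,
                "alpha_used": _round(act.alpha_used),
                "channels": [
                    {k: (_round(v) if isinstance(v, float) else v)
                     for k, v in row.items()}
                    for row in act.to_records()
                ],
            }
            conn = correlation_matrix(hemo, config.correlation_window,
                                      cohort.design, rec.subject, rec.session)
            matrices.setdefault(rec.session, []).append(conn)
            processed[(rec.subject, rec.session)] = conn.z
        except NirsnetError as err:
            raise NirsnetError(f"stage failure at {ctx}: {err}") from err

    # group connectivity per session
    for session, mats in matrices.items():
        mean_z, counts = group_average(mats)
        edges = strong_edges(mean_z, config.strong_z, counts)
        report.connectivity[session] = {
            "strong_threshold_z": config.strong_z,
            "n_strong_edges": len(edges),
            "edges": [{**e, "mean_z": _round(e["mean_z"])} for e in edges],
        }
        logger.info("session %s: %d strong edges (z > %.2f)",
                    session, len(edges), config.strong_z)

    # hemispheric network profiles and between-session comparisons
    grid = np.asarray(config.sparsity_grid, dtype=float)
    sessions = cohort.sessions
    subjects = cohort.subjects
    profiles: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    for session in sessions:
        for hemi in ("left", "right"):
            nodes = montage.hemisphere_channels(hemi)
            C = np.empty((len(subjects), grid.size))
            E = np.empty((len(subjects), grid.size))
            for si, subj in enumerate(subjects):
                prof = sparsity_profile(processed[(subj, session)], nodes, grid,
                                        hemisphere=hemi, session=session,
                                        subject=subj,
                                        signed=config.edge_ranking_signed)
                C[si] = prof.clustering
                E[si] = prof.efficiency
            profiles[(session, hemi)] = {"clustering": C, "efficiency": E}
            report.network.setdefault("profiles", {})[f"{session}/{hemi}"] = {
                "grid": [_round(g) for g in grid],
                "mean_clustering": [_round(v) for v in C.mean(axis=0)],
                "mean_efficiency": [_round(v) for v in E.mean(axis=0)],
            }

    comparisons = {}
    if len(subjects) >= 4:
        for a_idx in range(len(sessions)):
            for b_idx in range(a_idx + 1, len(sessions)):
                sa, sb = sessions[a_idx], sessions[b_idx]
                for hemi in ("left", "right"):
                    for metric in ("clustering", "efficiency"):
                        ranges = compare_profiles(
                            profiles[(sa, hemi)][metric],
                            profiles[(sb, hemi)][metric],
                            grid, alpha=config.network_alpha)
                        comparisons[f"{sa}_vs_{sb}/{hemi}/{metric}"] = [
                            {"start": r.start, "end": r.end,
                             "p_min": _round(r.p_min), "p_max": _round(r.p_max),
                             "direction": r.direction}
                            for r in ranges
                        ]
        report.network["comparisons"] = comparisons
        report.network["per_point_alpha"] = config.network_alpha
        report.network["multiplicity_note"] = (
            "per-sparsity-point alpha without correction across the grid")
    else:
        report.warnings.append(
            f"network comparisons skipped: {len(subjects)} subjects < 4")

    # clinical statistics
    if clinical:
        report.clinical = clinical_statistics(clinical)

    logger.info("pipeline complete")
    return report


_DESIGN_CACHE: dict = {}


def _design_matrix(cohort: Cohort, config: PipelineConfig, kernel: np.ndarray):
    from .glm import build_design
    key = (cohort.design, config.dct_cutoff_s, round(float(kernel.sum()), 12),
           len(kernel))
    if key not in _DESIGN_CACHE:
        _DESIGN_CACHE[key] = build_design(cohort.design,
                                          cohort.design.sampling_rate,
                                          cohort.design.n_samples,
                                          config.dct_cutoff_s, kernel)
    return _DESIGN_CACHE[key]


def clinical_statistics(records: list[ClinicalScores]) -> dict:
    """Wilcoxon pairwise session contrasts and Friedman across sessions."""
    out: dict = {}
    for measure in ("aq", "lq"):
        m = scores_matrix(records, measure)
        if m.shape[0] < 2:
            raise NirsnetError("group statistics need at least 2 subjects")
        fr = friedman(m.to_numpy())
        entry = {
            "friedman": {"chi2": _round(fr.statistic), "df": fr.df,
                         "p": _round(fr.p), "n": fr.n},
            "pairwise": {},
        }
        for a, b in (("T0", "T1"), ("T1", "T2"), ("T0", "T2")):
            try:
                w = wilcoxon_signed_rank(m[b].to_numpy(), m[a].to_numpy())
                entry["pairwise"][f"{a}_vs_{b}"] = {
                    "w_plus": w.statistic, "z": _round(w.z or 0.0),
                    "p": _round(w.p), "n": w.n,
                    "tie_corrected": w.tie_corrected,
                }
            except NirsnetError as err:
                entry["pairwise"][f"{a}_vs_{b}"] = {"error": str(err)}
        out[measure.upper()] = entry
    return out
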