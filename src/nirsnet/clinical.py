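"""Clinical aphasia scores (Western Aphasia Battery) shipped as a fixture.

Five patients evaluated before treatment (T0), one day after the last
treatment session (T1) and one month later (T2). AQ (Aphasia Quotient) and
LQ (Language Quotient) are 0-100 summary scores; subsection raw scores are
available at T0 only. The fixture also records each patient's stimulation
site and the fNIRS channel selected as the hotspot.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import math
from dataclasses import dataclass

import pandas as pd

from .errors import FixtureError

SESSIONS = ("T0", "T1", "T2")

# sha256 of the packaged TSV; guards against silent fixture corruption
_FIXTURE_SHA256 = "7f2ef9ef2bf7c03cea5f7480fd71b355f8cd979f2fb198ff6d5eef1a8e15682b"


@dataclass(frozen=True)
class ClinicalScores:
    patient_id: int
    session: str
    aq: float
    lq: float
    stim_site: str
    hotspot_channel: int
    speech: float | None = None
    repeat: float | None = None
    reading: float | None = None
    comprehension: float | None = None
    naming: float | None = None
    writing: float | None = None

    def __post_init__(self) -> None:
        if self.session not in SESSIONS:
            raise FixtureError(f"unknown session {self.session!r}")
        for name in ("aq", "lq"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise FixtureError(f"{name.upper()} {v} outside [0, 100]")


def load_clinical_fixture() -> list[ClinicalScores]:
    """All 5 patients x 3 sessions, exactly as printed, checksum-verified."""
    ref = importlib.resources.files("nirsnet.data") / "kwab_scores.tsv"
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise FixtureError(
            f"clinical fixture checksum mismatch (got {digest[:12]}...)")
    import io as _io
    df = pd.read_csv(_io.BytesIO(raw), sep="\t")
    out: list[ClinicalScores] = []
    seen: set[tuple[int, str]] = set()
    for r in df.itertuples():
        key = (int(r.patient), str(r.session))
        if key in seen:
            raise FixtureError(f"duplicate record for patient {key[0]} {key[1]}")
        seen.add(key)

        def _opt(v: object) -> float | None:
            return None if (isinstance(v, float) and math.isnan(v)) else float(v)  # type: ignore[arg-type]

        out.append(ClinicalScores(
            patient_id=int(r.patient), session=str(r.session),
            aq=float(r.AQ), lq=float(r.LQ),
            stim_site=str(r.stim_site), hotspot_channel=int(r.hotspot_channel),
            speech=_opt(r.speech), repeat=_opt(r.repeat), reading=_opt(r.reading),
            comprehension=_opt(r.comprehension), naming=_opt(r.naming),
            writing=_opt(r.writing),
        ))
    if len(out) != 15:
        raise FixtureError(f"expected 15 records, got {len(out)}")
    return out


def scores_matrix(records: list[ClinicalScores], measure: str) -> "pd.DataFrame":
    """Patients x sessions matrix of one measure ('aq' or 'lq')."""
    rows = {}
    for rec in records:
        rows.setdefault(rec.patient_id, {})[rec.session] = getattr(rec, measure)
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    return df[list(SESSIONS)]
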