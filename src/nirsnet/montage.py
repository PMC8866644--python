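"""Optode montage: channels, hemispheres and language-region assignments.

A channel is one source-detector pair. The default montage covers Broca,
Wernicke and adjacent areas with 26 channels formed from 12 sources and 10
detectors at 3 cm separation, split 13 left / 13 right. The packaged default
geometry is synthetic (the labels are plausible 10-20 positions, not a
digitized cap) and fully overridable from a TSV file.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import MontageError

HEMISPHERES = ("left", "right")
REGIONS = ("broca", "wernicke", "adjacent")

_COLUMNS = ["channel", "source", "detector", "separation_cm", "hemisphere", "region"]


@dataclass(frozen=True)
class Channel:
    """One source-detector pair."""

    id: int
    source: str
    detector: str
    separation_cm: float
    hemisphere: str
    region: str


@dataclass(frozen=True)
class Montage:
    channels: tuple[Channel, ...]

    def __post_init__(self) -> None:
        ids = [c.id for c in self.channels]
        if not ids:
            raise MontageError("montage has no channels")
        if sorted(ids) != list(range(1, len(ids) + 1)):
            raise MontageError(
                f"channel ids must be unique and contiguous from 1, got {sorted(ids)}"
            )
        for c in self.channels:
            if c.separation_cm <= 0:
                raise MontageError(f"channel {c.id}: separation must be > 0")
            if c.hemisphere not in HEMISPHERES:
                raise MontageError(f"channel {c.id}: unknown hemisphere {c.hemisphere!r}")
            if c.region not in REGIONS:
                raise MontageError(f"channel {c.id}: unknown region {c.region!r}")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def channel_ids(self) -> list[int]:
        return [c.id for c in sorted(self.channels, key=lambda c: c.id)]

    @property
    def separations_cm(self) -> np.ndarray:
        """Separation per channel, in channel-id order."""
        return np.array(
            [c.separation_cm for c in sorted(self.channels, key=lambda c: c.id)]
        )

    def hemisphere_channels(self, hemisphere: str) -> list[int]:
        if hemisphere not in HEMISPHERES:
            raise MontageError(f"unknown hemisphere {hemisphere!r}")
        return [c.id for c in sorted(self.channels, key=lambda c: c.id)
                if c.hemisphere == hemisphere]

    def region_channels(self, hemisphere: str, region: str) -> list[int]:
        return [c.id for c in sorted(self.channels, key=lambda c: c.id)
                if c.hemisphere == hemisphere and c.region == region]

    def require_bilateral(self) -> None:
        """Hemispheric analysis needs channels on both sides."""
        for h in HEMISPHERES:
            if not self.hemisphere_channels(h):
                raise MontageError(f"hemispheric analysis requested but no {h} channels")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (c.id, c.source, c.detector, c.separation_cm, c.hemisphere, c.region)
            for c in sorted(self.channels, key=lambda c: c.id)
        ]
        return pd.DataFrame(rows, columns=_COLUMNS)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Montage":
        missing = set(_COLUMNS) - set(df.columns)
        if missing:
            raise MontageError(f"montage table missing columns: {sorted(missing)}")
        chans = tuple(
            Channel(
                id=int(r.channel),
                source=str(r.source),
                detector=str(r.detector),
                separation_cm=float(r.separation_cm),
                hemisphere=str(r.hemisphere),
                region=str(r.region),
            )
            for r in df.itertuples()
        )
        return cls(chans)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Montage":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def default_montage() -> Montage:
    """The packaged 26-channel default montage (synthetic geometry).

    13 channels per hemisphere; channels 1-5 / 14-18 over inferior-frontal
    (Broca / homologue), 6-9 / 19-22 adjacent, 10-13 / 23-26 posterior
    superior-temporal (Wernicke / homologue). Separation 3 cm throughout.
    """
    ref = importlib.resources.files("nirsnet.data") / "montage_26ch_synthetic.tsv"
    with importlib.resources.as_file(ref) as path:
        return Montage.from_tsv(path)
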