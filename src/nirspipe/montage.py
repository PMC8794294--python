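"""Probe geometry, channel tables, and channel -> ROI mappings.

A montage bundles the optode layout (sources, long- and short-separation
detectors with schematic 2D cap coordinates), the long-channel table
(source/detector pairing, hemisphere, region, ROI), and the three
four-channel quality-control regions used by the subject inclusion gate.

Long channels are numbered 1..24 (1-12 prefrontal, 13-24 somatosensory;
7-12 and 19-24 on the left hemisphere).  Short-separation channels are
assigned ids 25..33 (short channel k pairs with source k).  Every long
channel is mapped to its nearest short channel: minimum Euclidean distance
from the long channel's source-detector midpoint to the short channel's
source position, ties broken by the lowest short-channel id.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

ROIS_PREFC = ("medial_PFC", "lateral_preFC", "lateral_FC")
ROIS_S1 = ("superior_S1", "central_S1", "inferior_S1")
ROIS = ROIS_PREFC + ROIS_S1

SHORT_ID_OFFSET = 24  # short channel id = source id + offset


class MontageError(ValueError):
    """Raised when a montage file fails validation."""


@dataclass(frozen=True)
class OptodeLayout:
    """Optode positions in an arbitrary flattened-cap frame (mm)."""

    sources: dict[int, tuple[float, float]]
    long_detectors: dict[int, tuple[float, float]]
    short_detectors: dict[int, tuple[float, float]]
    short_source_pairing: dict[int, int]  # short detector id -> source id
    separation_long_mm: float = 30.0
    separation_short_mm: float = 8.0

    def validate(self) -> None:
        for name, d in (
            ("sources", self.sources),
            ("long_detectors", self.long_detectors),
            ("short_detectors", self.short_detectors),
        ):
            for oid, pos in d.items():
                if not np.all(np.isfinite(pos)):
                    raise MontageError(f"non-finite coordinate for {name} id {oid}")
        srcs = set(self.sources)
        if set(self.short_source_pairing.values()) - srcs:
            raise MontageError("short detector paired to unknown source")
        if len(self.short_source_pairing) != len(self.short_detectors):
            raise MontageError("every short detector must be paired to exactly one source")


@dataclass
class Montage:
    layout: OptodeLayout
    channels: pd.DataFrame  # long channels only; indexed 0..n-1
    quality_regions: dict[str, list[int]]
    name: str = "unnamed"

    @property
    def long_channel_ids(self) -> np.ndarray:
        return self.channels["channel_id"].to_numpy()

    @property
    def short_channel_ids(self) -> np.ndarray:
        return np.array(
            sorted(SHORT_ID_OFFSET + s for s in self.layout.short_source_pairing.values())
        )

    @property
    def all_channel_ids(self) -> np.ndarray:
        return np.concatenate([self.long_channel_ids, self.short_channel_ids])

    def channels_for(self, hemisphere: str, roi: str) -> list[int]:
        m = (self.channels["hemisphere"] == hemisphere) & (self.channels["roi"] == roi)
        return self.channels.loc[m, "channel_id"].tolist()

    def validate(self) -> None:
        self.layout.validate()
        ch = self.channels
        ids = ch["channel_id"]
        if ids.duplicated().any():
            raise MontageError("duplicate channel ids")
        if len(ch) != 24:
            raise MontageError(f"expected 24 long channels, found {len(ch)}")
        for hemi in ("left", "right"):
            if (ch["hemisphere"] == hemi).sum() != 12:
                raise MontageError(f"expected 12 channels on {hemi} hemisphere")
        for region, n in (("PreFC", 12), ("S1", 12)):
            if (ch["region"] == region).sum() != n:
                raise MontageError(f"expected {n} {region} channels")
        for hemi in ("left", "right"):
            for roi in ROIS:
                if not self.channels_for(hemi, roi):
                    raise MontageError(f"empty ROI cell ({hemi}, {roi})")
        if ch["source_id"].isna().any() or ch["detector_id"].isna().any():
            raise MontageError("channel missing source or detector id")
        unknown_src = set(ch["source_id"]) - set(self.layout.sources)
        unknown_det = set(ch["detector_id"]) - set(self.layout.long_detectors)
        if unknown_src or unknown_det:
            raise MontageError(f"channels reference unknown optodes: {unknown_src | unknown_det}")
        if ch["nearest_short_channel_id"].isna().any():
            raise MontageError("nearest-short assignment incomplete")
        all_qc = [c for chans in self.quality_regions.values() for c in chans]
        if set(all_qc) - set(ids):
            raise MontageError("quality region references unknown channel")


def nearest_short_assignment(layout: OptodeLayout, channels: pd.DataFrame) -> pd.Series:
    """Nearest short channel per long channel.

    Distance is measured from the long channel's source-detector midpoint to
    each short channel's *source* position (the short optode pair straddles
    its source, so the source is the natural anchor).  Ties go to the lowest
    short-channel id, which makes the assignment deterministic.
    """
    shorts = sorted(
        (SHORT_ID_OFFSET + src, np.asarray(layout.sources[src], dtype=float))
        for src in layout.short_source_pairing.values()
    )
    out = []
    for _, row in channels.iterrows():
        s = np.asarray(layout.sources[row["source_id"]], dtype=float)
        d = np.asarray(layout.long_detectors[row["detector_id"]], dtype=float)
        mid = (s + d) / 2.0
        dists = [(float(np.linalg.norm(mid - pos)), sid) for sid, pos in shorts]
        best = min(dists, key=lambda t: (t[0], t[1]))
        out.append(best[1])
    return pd.Series(out, index=channels.index, dtype=int)


def load_montage(path: str | Path | None = None) -> Montage:
    """Load and validate a montage JSON file (packaged default if ``path`` is None)."""
    if path is None:
        with resources.files("nirspipe.data").joinpath("default_montage.json").open() as fh:
            raw = json.load(fh)
    else:
        raw = json.loads(Path(path).read_text())

    try:
        layout = OptodeLayout(
            sources={s["id"]: tuple(s["pos"]) for s in raw["sources"]},
            long_detectors={d["id"]: tuple(d["pos"]) for d in raw["long_detectors"]},
            short_detectors={d["id"]: tuple(d["pos"]) for d in raw["short_detectors"]},
            short_source_pairing={d["id"]: d["source_id"] for d in raw["short_detectors"]},
            separation_long_mm=float(raw.get("separation_long_mm", 30.0)),
            separation_short_mm=float(raw.get("separation_short_mm", 8.0)),
        )
    except KeyError as exc:
        raise MontageError(f"montage file missing required field: {exc}") from exc

    required = {"channel_id", "source_id", "detector_id", "hemisphere", "roi"}
    for c in raw["channels"]:
        missing = required - set(c)
        if missing:
            raise MontageError(
                f"channel entry {c.get('channel_id', '?')} missing fields: {sorted(missing)}"
            )
    channels = pd.DataFrame(raw["channels"])
    if "region" not in channels:
        channels["region"] = np.where(
            channels["roi"].isin(ROIS_PREFC), "PreFC", "S1"
        )
    channels["separation_class"] = "long"
    if "nearest_short_channel_id" not in channels:
        channels["nearest_short_channel_id"] = nearest_short_assignment(layout, channels)

    montage = Montage(
        layout=layout,
        channels=channels,
        quality_regions={k: list(v) for k, v in raw.get("quality_regions", {}).items()},
        name=raw.get("name", "unnamed"),
    )
    montage.validate()
    return montage


def default_montage() -> Montage:
    return load_montage(None)
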