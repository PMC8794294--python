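"""Side mapping, ROI averaging, P0/P1/P2 epoch extraction, rolling curves.

Epoch conventions: all three epochs are 60 s.  P1 starts at the first
painful event and P2 at the last; P0 is a 60-s window centered in the
longest procedure-free gap (recording start and end count as gap
boundaries), which must be at least 120 s long.  Each raw epoch segment is
z-scored against its own mean and standard deviation, then summarized as
51 means of 10-s windows advanced in 1-s steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import EventLog
from .montage import Montage, ROIS
from .preprocess import ConcentrationSet, QualityReport, SPECIES

SIDES = ("contralateral", "ipsilateral")
EPOCH_S = 60.0
WINDOW_S = 10.0
STEP_S = 1.0
N_WINDOWS = int((EPOCH_S - WINDOW_S) / STEP_S) + 1  # 51


@dataclass
class RoiSeries:
    """One averaged series per (side, roi, species); missing ROIs are None."""

    data: dict[tuple[str, str, str], np.ndarray | None]
    fs: float
    laterality: str

    def get(self, side: str, roi: str, species: str) -> np.ndarray | None:
        return self.data[(side, roi, species)]


@dataclass(frozen=True)
class EpochDefinition:
    kind: str          # P0 | P1 | P2
    start_s: float
    length_s: float = EPOCH_S
    provenance: str = ""


def map_sides(
    conc: ConcentrationSet,
    montage: Montage,
    laterality: str,
    quality: QualityReport | None = None,
) -> RoiSeries:
    """Average long channels into (side, roi, species) series.

    The hemisphere contralateral to the operated knee is the one opposite
    ``laterality``; flipping laterality swaps the two sides exactly.
    Channels rated poor by the quality report are excluded from their ROI
    mean; an ROI with no usable channel is flagged missing (None).
    """
    if laterality not in ("R", "L"):
        raise ValueError("laterality must be 'R' or 'L'")
    contra = "left" if laterality == "R" else "right"
    side_of = {"contralateral": contra,
               "ipsilateral": "right" if contra == "left" else "left"}
    data: dict[tuple[str, str, str], np.ndarray | None] = {}
    for side in SIDES:
        for roi in ROIS:
            chans = montage.channels_for(side_of[side], roi)
            if quality is not None:
                chans = [c for c in chans if quality.channel_class.get(c) != "poor"]
            for species in SPECIES:
                key = (side, roi, species)
                if not chans:
                    data[key] = None
                    continue
                rows = [conc.series(c, species) for c in chans]
                data[key] = np.mean(rows, axis=0)
    return RoiSeries(data=data, fs=conc.fs, laterality=laterality)


def find_p0(events: EventLog, duration_s: float | None = None) -> EpochDefinition:
    """Longest procedure-free gap (ties: earliest), P0 centered inside it."""
    if duration_s is None:
        duration_s = events.duration_s
    bounds = np.concatenate([[0.0], np.sort(events.times), [duration_s]])
    gaps = np.diff(bounds)
    best = int(np.argmax(gaps))  # argmax takes the first maximum: earliest gap
    if gaps[best] < 120.0:
        raise ValueError(
            f"no valid P0: longest procedure-free gap is {gaps[best]:.1f}s < 120s"
        )
    center = (bounds[best] + bounds[best + 1]) / 2.0
    return EpochDefinition(
        kind="P0",
        start_s=center - EPOCH_S / 2.0,
        provenance=f"gap [{bounds[best]:.1f}, {bounds[best + 1]:.1f}]s",
    )


def define_epochs(events: EventLog, duration_s: float | None = None
                  ) -> dict[str, EpochDefinition]:
    """P0 from the longest gap; P1/P2 from the first/last painful event."""
    if duration_s is None:
        duration_s = events.duration_s
    pain = events.painful_times
    if pain.size == 0:
        raise ValueError("no painful events: cannot define P1/P2")
    if pain.size == 1:
        warnings.warn("single painful event: P1 and P2 coincide", stacklevel=2)
    for name, t in (("P1", pain[0]), ("P2", pain[-1])):
        if t + EPOCH_S > duration_s:
            raise ValueError(f"{name} event at {t:.1f}s lies within 60s of recording end")
    return {
        "P0": find_p0(events, duration_s),
        "P1": EpochDefinition("P1", float(pain[0]), provenance="first painful event"),
        "P2": EpochDefinition("P2", float(pain[-1]), provenance="last painful event"),
    }


def extract_segment(series: np.ndarray, fs: float, epoch: EpochDefinition) -> np.ndarray:
    """Mean-normalized raw 60-s segment at the native sampling rate."""
    i0 = int(round(epoch.start_s * fs))
    i1 = i0 + int(round(epoch.length_s * fs))
    if i0 < 0 or i1 > series.size:
        raise ValueError(f"epoch {epoch.kind} [{epoch.start_s}s, +60s) outside recording")
    seg = series[i0:i1]
    return seg - seg.mean()


def rolling_curve(segment: np.ndarray, fs: float = 25.0) -> np.ndarray:
    """Standardized 10-s rolling means at 1-s steps: 51 points.

    The segment is z-scored against its own mean and standard deviation
    (population SD; a constant segment maps to all zeros), then each point
    j = 0..50 is the mean over the half-open window [j, j+10) seconds.
    Invariant under any positive affine rescaling of the input.
    """
    n_expected = int(round(EPOCH_S * fs))
    if segment.size != n_expected:
        raise ValueError(f"segment must be {n_expected} samples at fs={fs:g}, "
                         f"got {segment.size}")
    sd = segment.std()
    if sd == 0:
        return np.zeros(N_WINDOWS)
    z = (segment - segment.mean()) / sd
    wlen = int(round(WINDOW_S * fs))
    step = int(round(STEP_S * fs))
    windows = np.lib.stride_tricks.sliding_window_view(z, wlen)[::step]
    return windows.mean(axis=1)


def epoch_curves(
    roi_series: RoiSeries, events: EventLog, duration_s: float | None = None
) -> dict[tuple[str, str, str, str], np.ndarray]:
    """All (side, roi, species, epoch) -> 51-point curve for one session.

    Missing ROIs are skipped (absent from the result, not zero-filled).
    """
    defs = define_epochs(events, duration_s)
    out = {}
    for (side, roi, species), series in roi_series.data.items():
        if series is None:
            continue
        for kind, ep in defs.items():
            seg = extract_segment(series, roi_series.fs, ep)
            out[(side, roi, species, kind)] = rolling_curve(seg, roi_series.fs)
    return out


def epoch_segments(
    roi_series: RoiSeries, events: EventLog, duration_s: float | None = None
) -> dict[tuple[str, str, str, str], np.ndarray]:
    """Raw mean-normalized 60-s segments keyed like :func:`epoch_curves`."""
    defs = define_epochs(events, duration_s)
    out = {}
    for (side, roi, species), series in roi_series.data.items():
        if series is None:
            continue
        for kind, ep in defs.items():
            out[(side, roi, species, kind)] = extract_segment(series, roi_series.fs, ep)
    return out
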