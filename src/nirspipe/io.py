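"""On-disk formats: event logs, patient tables, and raw sessions.

Sessions are stored as one whitespace-delimited intensity file per
wavelength (rows = samples, columns = channels) plus a JSON sidecar with
the sampling rate, channel ids, and patient id.  A minimal SNIRF (HDF5)
export/import is provided for interoperability; the plain-text container
is the primary format.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import Montage, default_montage

WAVELENGTHS = (690.0, 830.0)


@dataclass
class EventLog:
    """Timestamped surgical annotations over one recording."""

    times: np.ndarray        # seconds from recording start, sorted ascending
    labels: list[str]
    painful: np.ndarray      # bool per event
    duration_s: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.painful = np.asarray(self.painful, dtype=bool)
        if self.times.size and self.times.min() < 0:
            raise ValueError("negative event time")
        if self.times.size and self.times.max() > self.duration_s:
            raise ValueError(
                f"event at t={self.times.max():g}s lies beyond recording "
                f"duration {self.duration_s:g}s"
            )
        if not np.all(np.diff(self.times) >= 0):
            warnings.warn("event times were unsorted; sorting", stacklevel=2)
            order = np.argsort(self.times, kind="stable")
            self.times = self.times[order]
            self.labels = [self.labels[i] for i in order]
            self.painful = self.painful[order]

    @property
    def n_events(self) -> int:
        return int(self.times.size)

    @property
    def painful_times(self) -> np.ndarray:
        return self.times[self.painful]


@dataclass
class PatientRecord:
    patient_id: str
    age: float
    sex: str                  # 'M' | 'F'
    laterality: str           # operated knee, 'R' | 'L'
    nerve_block: bool
    pain_procedures: int
    vrs_pre: float | None = None
    vrs_post: float | None = None
    vrs_discharge: float | None = None

    def __post_init__(self) -> None:
        for name in ("vrs_pre", "vrs_post", "vrs_discharge"):
            v = getattr(self, name)
            if v is not None and not np.isnan(v) and not 0 <= v <= 10:
                raise ValueError(f"{name}={v} outside the 0-10 verbal rating scale")
        if self.laterality not in ("R", "L"):
            raise ValueError(f"laterality must be R or L, got {self.laterality!r}")

    @property
    def group(self) -> str:
        return "NB" if self.nerve_block else "non-NB"


@dataclass
class SessionRecording:
    """Raw dual-wavelength intensities for one intraoperative session."""

    intensity: np.ndarray     # (n_channels, 2, n_samples), wavelength order 690/830
    channel_ids: np.ndarray   # (n_channels,)
    fs: float = 25.0
    patient_id: str = "unknown"
    montage: Montage | None = None
    wavelengths: tuple[float, float] = WAVELENGTHS

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity)
        if not np.issubdtype(self.intensity.dtype, np.floating):
            self.intensity = self.intensity.astype(float)
        self.channel_ids = np.asarray(self.channel_ids, dtype=int)
        if self.intensity.ndim != 3 or self.intensity.shape[1] != 2:
            raise ValueError("intensity must have shape (n_channels, 2, n_samples)")
        if self.intensity.shape[0] != self.channel_ids.size:
            raise ValueError("channel_ids length does not match intensity")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("non-finite intensity values")
        if np.any(self.intensity <= 0):
            raise ValueError("non-positive intensity values")
        if self.fs != 25.0:
            warnings.warn(f"sampling rate {self.fs} Hz differs from the nominal 25 Hz",
                          stacklevel=2)

    @property
    def n_samples(self) -> int:
        return self.intensity.shape[2]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def channel_index(self, channel_id: int) -> int:
        idx = np.flatnonzero(self.channel_ids == channel_id)
        if idx.size != 1:
            raise KeyError(f"channel {channel_id} not present in recording")
        return int(idx[0])

    def validate_against(self, montage: Montage) -> None:
        missing = set(montage.all_channel_ids) - set(self.channel_ids)
        if missing:
            raise ValueError(f"recording is missing montage channels: {sorted(missing)}")


# ---------------------------------------------------------------------------
# event / patient tables

def load_events(path: str | Path, duration_s: float | None = None) -> EventLog:
    """Read a TSV event log with columns time_s, label, painful."""
    df = pd.read_csv(path, sep="\t")
    required = {"time_s", "label", "painful"}
    if missing := required - set(df.columns):
        raise ValueError(f"event file missing columns: {sorted(missing)}")
    painful = df["painful"].map(
        {True: True, False: False, "Y": True, "N": False, 1: True, 0: False,
         "true": True, "false": False, "True": True, "False": False}
    )
    if painful.isna().any():
        raise ValueError("unparseable values in 'painful' column")
    if duration_s is None:
        duration_s = float(df["time_s"].max()) if len(df) else 0.0
    return EventLog(
        times=df["time_s"].to_numpy(dtype=float),
        labels=df["label"].astype(str).tolist(),
        painful=painful.to_numpy(dtype=bool),
        duration_s=float(duration_s),
    )


def save_events(events: EventLog, path: str | Path) -> None:
    pd.DataFrame(
        {"time_s": events.times, "label": events.labels, "painful": events.painful}
    ).to_csv(path, sep="\t", index=False)


def load_patients(path: str | Path | None = None) -> list[PatientRecord]:
    """Read a patient table TSV; ``None`` loads the packaged demographic fixture."""
    if path is None:
        from importlib import resources

        path = resources.files("nirspipe.data").joinpath("patients_demographics.tsv")
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    records = []
    for _, r in df.iterrows():
        records.append(
            PatientRecord(
                patient_id=str(r["patient_id"]),
                age=float(r["age"]),
                sex=str(r["sex"]),
                laterality=str(r["laterality"]),
                nerve_block=str(r["nerve_block"]).upper() in ("Y", "TRUE", "1"),
                pain_procedures=int(r["pain_procedures"]),
                vrs_pre=None if pd.isna(r.get("vrs_pre")) else float(r["vrs_pre"]),
                vrs_post=None if pd.isna(r.get("vrs_post")) else float(r["vrs_post"]),
                vrs_discharge=None
                if pd.isna(r.get("vrs_discharge"))
                else float(r["vrs_discharge"]),
            )
        )
    return records


def patients_frame(patients: list[PatientRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in patients],
            "age": [p.age for p in patients],
            "sex": [p.sex for p in patients],
            "laterality": [p.laterality for p in patients],
            "nerve_block": [p.nerve_block for p in patients],
            "group": [p.group for p in patients],
            "pain_procedures": [p.pain_procedures for p in patients],
            "vrs_pre": [p.vrs_pre for p in patients],
            "vrs_post": [p.vrs_post for p in patients],
            "vrs_discharge": [p.vrs_discharge for p in patients],
        }
    )


# ---------------------------------------------------------------------------
# session container (text primary, SNIRF optional)

def write_session(rec: SessionRecording, path: str | Path) -> None:
    """Write a session as intensity_<wl>.tsv per wavelength + session.json sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for w, wl in enumerate(rec.wavelengths):
        # rows = samples, columns = channels; full float precision
        np.savetxt(
            path / f"intensity_{int(wl)}.tsv",
            rec.intensity[:, w, :].T,
            delimiter="\t",
            fmt="%.17g",
            header="\t".join(f"ch{c}" for c in rec.channel_ids),
            comments="",
        )
    sidecar = {
        "fs": rec.fs,
        "patient_id": rec.patient_id,
        "channel_ids": rec.channel_ids.tolist(),
        "wavelengths_nm": list(rec.wavelengths),
        "montage": rec.montage.name if rec.montage is not None else None,
    }
    (path / "session.json").write_text(json.dumps(sidecar, indent=1))


def read_session(path: str | Path, montage: Montage | None = None) -> SessionRecording:
    path = Path(path)
    sidecar = json.loads((path / "session.json").read_text())
    channel_ids = np.asarray(sidecar["channel_ids"], dtype=int)
    wavelengths = tuple(sidecar.get("wavelengths_nm", WAVELENGTHS))
    mats = []
    for wl in wavelengths:
        mat = np.loadtxt(path / f"intensity_{int(wl)}.tsv", delimiter="\t", skiprows=1)
        mats.append(np.atleast_2d(mat).T)
    intensity = np.stack(mats, axis=1)
    if montage is None:
        montage = default_montage()
    rec = SessionRecording(
        intensity=intensity,
        channel_ids=channel_ids,
        fs=float(sidecar["fs"]),
        patient_id=str(sidecar["patient_id"]),
        montage=montage,
        wavelengths=wavelengths,
    )
    rec.validate_against(montage)
    return rec


def write_snirf(rec: SessionRecording, path: str | Path) -> None:
    """Minimal SNIRF (HDF5) export: continuous-wave intensity, one data block."""
    import h5py

    n_ch = rec.channel_ids.size
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        data = nirs.create_group("data1")
        # columns ordered (channel major, wavelength minor)
        ts = rec.intensity.reshape(n_ch * 2, rec.n_samples).T
        data.create_dataset("dataTimeSeries", data=ts)
        data.create_dataset("time", data=np.array([0.0, 1.0 / rec.fs]))
        for i in range(n_ch):
            for w in range(2):
                ml = data.create_group(f"measurementList{i * 2 + w + 1}")
                ml.create_dataset("sourceIndex", data=int(rec.channel_ids[i]))
                ml.create_dataset("detectorIndex", data=int(rec.channel_ids[i]))
                ml.create_dataset("wavelengthIndex", data=w + 1)
                ml.create_dataset("dataType", data=1)
                ml.create_dataset("dataTypeIndex", data=1)
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(rec.wavelengths))
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SubjectID", data=str(rec.patient_id))
        meta.create_dataset("channelIds", data=rec.channel_ids)


def read_snirf(path: str | Path, montage: Montage | None = None) -> SessionRecording:
    import h5py

    with h5py.File(path, "r") as f:
        data = f["nirs/data1"]
        ts = np.asarray(data["dataTimeSeries"])
        t = np.asarray(data["time"])
        fs = 1.0 / (t[1] - t[0]) if t.size == 2 else 1.0 / np.median(np.diff(t))
        wavelengths = tuple(np.asarray(f["nirs/probe/wavelengths"], dtype=float))
        channel_ids = np.asarray(f["nirs/metaDataTags/channelIds"], dtype=int)
        patient_id = f["nirs/metaDataTags/SubjectID"][()]
        if isinstance(patient_id, bytes):
            patient_id = patient_id.decode()
    n_ch = channel_ids.size
    intensity = ts.T.reshape(n_ch, 2, -1)
    return SessionRecording(
        intensity=intensity,
        channel_ids=channel_ids,
        fs=float(round(fs, 6)),
        patient_id=str(patient_id),
        montage=montage,
        wavelengths=wavelengths,
    )
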