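"""Raw intensity -> cleaned hemoglobin concentrations, plus the quality gate.

The fixed processing order is:

    optical density -> wavelet despike -> 0.01-0.3 Hz bandpass -> MBLL ->
    short-separation regression -> cubic detrend -> linear detrend

applied independently per channel (and per wavelength up to the MBLL
inversion).  Each stage appends a provenance flag to the output so the
order is auditable.  The quality gate classifies channels from the cardiac
peak of the raw-intensity power spectrum, rolls channel classes up to the
three four-channel montage quality regions, and decides subject inclusion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal

from .io import SessionRecording
from .montage import Montage
from .optics import ExtinctionTable, load_extinction_table, mbll_system

SPECIES = ("HbO2", "HbR", "HbT")


@dataclass
class PreprocessConfig:
    baseline_window_s: tuple[float, float] = (0.0, 30.0)
    wavelet: str = "db4"
    wavelet_levels: int = 5
    wavelet_k: float = 3.0
    band_hz: tuple[float, float] = (0.01, 0.3)
    filter_order: int = 3
    dpf: tuple[float, float] = (6.0, 6.0)
    distance_long_cm: float = 3.0
    distance_short_cm: float = 0.8
    quality_good_ratio: float = 10.0
    quality_average_ratio: float = 3.0
    cardiac_band_hz: tuple[float, float] = (0.7, 2.5)

    def validate(self, fs: float) -> None:
        lo, hi = self.band_hz
        if not 0 < lo < hi < fs / 2:
            raise ValueError(
                f"bandpass ({lo}, {hi}) Hz must satisfy 0 < low < high < fs/2 = {fs / 2}"
            )
        if self.wavelet_k <= 0:
            raise ValueError("wavelet threshold multiplier must be positive")


@dataclass
class OpticalDensitySet:
    od: np.ndarray            # (n_channels, 2, n_samples)
    channel_ids: np.ndarray
    fs: float
    baseline_window_s: tuple[float, float]
    flags: list[str] = field(default_factory=list)


@dataclass
class ConcentrationSet:
    """Per-channel hemoglobin concentration changes in uM."""

    data: dict[str, np.ndarray]   # species -> (n_channels, n_samples)
    channel_ids: np.ndarray
    fs: float
    flags: list[str] = field(default_factory=list)

    def series(self, channel_id: int, species: str) -> np.ndarray:
        idx = int(np.flatnonzero(self.channel_ids == channel_id)[0])
        return self.data[species][idx]


@dataclass
class QualityReport:
    channel_class: dict[int, str]              # channel id -> good/average/poor
    channel_prominence: dict[int, float]
    channel_cardiac_hz: dict[int, float]
    region_class: dict[str, str]
    include_subject: bool


# ---------------------------------------------------------------------------
# stages

def intensity_to_od(
    rec: SessionRecording, baseline_window_s: tuple[float, float] = (0.0, 30.0)
) -> OpticalDensitySet:
    """dOD = -ln(I / I0) with I0 the mean intensity over the baseline window.

    Scale-invariant per channel; a constant series maps to identically zero.
    """
    lo = int(round(baseline_window_s[0] * rec.fs))
    hi = min(int(round(baseline_window_s[1] * rec.fs)), rec.n_samples)
    if hi <= lo:
        raise ValueError("empty baseline window")
    i0 = rec.intensity[:, :, lo:hi].mean(axis=2, keepdims=True)
    od = -np.log(rec.intensity / i0)
    return OpticalDensitySet(
        od=od,
        channel_ids=rec.channel_ids.copy(),
        fs=rec.fs,
        baseline_window_s=baseline_window_s,
        flags=["od"],
    )


def _despike_rows(x: np.ndarray, wavelet: str, levels: int, k: float) -> np.ndarray:
    """Despike each row of a 2D array via per-level MAD thresholding."""
    coeffs = pywt.wavedec(x, wavelet, level=levels, mode="symmetric", axis=-1)
    out = [coeffs[0]]
    for detail in coeffs[1:]:
        med = np.median(detail, axis=-1, keepdims=True)
        mad = np.median(np.abs(detail - med), axis=-1, keepdims=True)
        sigma = mad / 0.67448975  # MAD of a normal
        d = np.where(np.abs(detail) > k * sigma, detail.dtype.type(0), detail)
        out.append(d)
    rec = pywt.waverec(out, wavelet, mode="symmetric", axis=-1)
    return rec[..., : x.shape[-1]]


def wavelet_despike(ods: OpticalDensitySet, k: float = 3.0,
                    wavelet: str = "db4", levels: int = 5) -> OpticalDensitySet:
    """Suppress motion spikes by zeroing outlier wavelet detail coefficients.

    Detail coefficients beyond ``k`` robust standard deviations (estimated
    per level via the median absolute deviation) are set to zero before
    reconstruction; the slow, band-limited content lives in the
    approximation coefficients and is untouched.
    """
    if k <= 0:
        raise ValueError("threshold multiplier k must be positive")
    n_ch, _, n = ods.od.shape
    if n < 2**levels:
        raise ValueError(f"series of {n} samples too short for {levels} wavelet levels")
    out = _despike_rows(ods.od.reshape(n_ch * 2, n), wavelet, levels, k).reshape(
        n_ch, 2, n
    )
    return OpticalDensitySet(
        od=out,
        channel_ids=ods.channel_ids,
        fs=ods.fs,
        baseline_window_s=ods.baseline_window_s,
        flags=ods.flags + ["despiked"],
    )


def bandpass(
    x: np.ndarray,
    fs: float,
    low_hz: float = 0.01,
    high_hz: float = 0.3,
    order: int = 3,
    axis: int = -1,
) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth bandpass."""
    if not 0 < low_hz < high_hz < fs / 2:
        raise ValueError("need 0 < low < high < fs/2")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    padlen = 3 * (2 * order + 1)
    if np.asarray(x).shape[axis] <= 3 * padlen:
        raise ValueError("series too short for stable zero-phase filtering")
    return signal.sosfiltfilt(sos, x, axis=axis)


def bandpass_od(ods: OpticalDensitySet, low_hz: float = 0.01, high_hz: float = 0.3,
                order: int = 3) -> OpticalDensitySet:
    return OpticalDensitySet(
        od=bandpass(ods.od, ods.fs, low_hz, high_hz, order, axis=-1),
        channel_ids=ods.channel_ids,
        fs=ods.fs,
        baseline_window_s=ods.baseline_window_s,
        flags=ods.flags + ["bandpassed"],
    )


def mbll(
    ods: OpticalDensitySet,
    montage: Montage,
    extinction: ExtinctionTable | None = None,
    dpf: tuple[float, float] = (6.0, 6.0),
    distance_long_cm: float = 3.0,
    distance_short_cm: float = 0.8,
) -> ConcentrationSet:
    """Invert the two-wavelength Beer-Lambert system per channel.

    Long and short channels use their nominal separations; dHbT is appended
    as the exact sample-wise sum of dHbO2 and dHbR.
    """
    if extinction is None:
        extinction = load_extinction_table()
    a = mbll_system(extinction, (690.0, 830.0), distance_long_cm, dpf)
    if abs(np.linalg.det(a)) < 1e-30:
        raise np.linalg.LinAlgError("singular extinction system")
    a_inv = np.linalg.inv(a)
    long_mask = np.isin(ods.channel_ids, montage.long_channel_ids)
    # dOD is linear in the separation, so short channels reuse the long-
    # channel inverse scaled by the distance ratio
    conc = np.einsum("sw,cwn->scn", a_inv.astype(ods.od.dtype), ods.od)
    conc[:, ~long_mask] *= ods.od.dtype.type(distance_long_cm / distance_short_cm)
    hbo, hbr = conc[0], conc[1]
    return ConcentrationSet(
        data={"HbO2": hbo, "HbR": hbr, "HbT": hbo + hbr},
        channel_ids=ods.channel_ids,
        fs=ods.fs,
        flags=ods.flags + ["mbll"],
    )


def short_sep_regress(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """OLS nuisance regression of a long channel on its nearest short channel.

    Returns the residual y - (b0 + b1 x).  A zero-variance regressor is
    degenerate: the series is mean-centered instead, with a warning.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape:
        raise ValueError("long and short series must have equal length")
    xc = x - x.mean()
    sxx = xc @ xc
    if sxx == 0.0:
        warnings.warn("zero-variance short channel; mean-centering only", stacklevel=2)
        return y - y.mean()
    b1 = (xc @ (y - y.mean())) / sxx
    b0 = y.mean() - b1 * x.mean()
    return y - (b0 + b1 * x)


def regress_short_channels(conc: ConcentrationSet, montage: Montage) -> ConcentrationSet:
    """Apply short-separation regression per species per long channel."""
    ch = montage.channels
    long_ids = ch["channel_id"].to_numpy()
    long_idx = np.searchsorted(
        conc.channel_ids, ch["channel_id"].to_numpy(),
        sorter=np.argsort(conc.channel_ids),
    )
    long_idx = np.argsort(conc.channel_ids)[long_idx]
    short_idx = np.argsort(conc.channel_ids)[
        np.searchsorted(
            conc.channel_ids, ch["nearest_short_channel_id"].to_numpy(),
            sorter=np.argsort(conc.channel_ids),
        )
    ]
    out = {}
    # HbO2 and HbR are regressed on their own short-channel series; HbT is
    # recomputed as their exact sum so the additivity invariant survives
    # the stage (regressing HbT independently would break it, because each
    # species has its own fitted slope and regressor)
    for s in ("HbO2", "HbR"):
        y = conc.data[s][long_idx]
        x = conc.data[s][short_idx]
        yc = y - y.mean(axis=1, keepdims=True)
        xc = x - x.mean(axis=1, keepdims=True)
        sxx = np.einsum("ij,ij->i", xc, xc)
        degenerate = sxx == 0.0
        if degenerate.any():
            warnings.warn("zero-variance short channel; mean-centering only",
                          stacklevel=2)
        sxx_safe = np.where(degenerate, 1.0, sxx)
        b1 = np.einsum("ij,ij->i", xc, yc) / sxx_safe
        b1[degenerate] = 0.0
        out[s] = yc - b1[:, None] * xc
    out["HbT"] = out["HbO2"] + out["HbR"]
    return ConcentrationSet(
        data=out,
        channel_ids=long_ids.copy(),
        fs=conc.fs,
        flags=conc.flags + ["short_sep_regressed"],
    )


def _polyfit_remove(x: np.ndarray, degree: int) -> np.ndarray:
    n = x.shape[-1]
    t = np.linspace(-1.0, 1.0, n)  # scaled abscissa keeps the system well conditioned
    v = np.polynomial.polynomial.polyvander(t, degree).astype(x.dtype)
    coeffs = np.linalg.solve(v.T @ v, v.T @ x.T)
    return x - (v @ coeffs).T


def detrend(conc: ConcentrationSet) -> ConcentrationSet:
    """Remove slow drifts: least-squares cubic fit, then linear fit.

    An exact cubic input maps to (numerically) zero; the output is
    mean-free because both fits include an intercept.
    """
    n = next(iter(conc.data.values())).shape[-1]
    if n < 5:
        raise ValueError("series too short to detrend")
    stacked = np.concatenate(
        [np.atleast_2d(conc.data["HbO2"]), np.atleast_2d(conc.data["HbR"])]
    )
    resid = _polyfit_remove(_polyfit_remove(stacked, 3), 1)
    n_ch = resid.shape[0] // 2
    out = {"HbO2": resid[:n_ch], "HbR": resid[n_ch:]}
    out["HbT"] = out["HbO2"] + out["HbR"]
    return ConcentrationSet(
        data=out,
        channel_ids=conc.channel_ids,
        fs=conc.fs,
        flags=conc.flags + ["detrended_cubic", "detrended_linear"],
    )


# ---------------------------------------------------------------------------
# quality gate

_CLASS_ORDER = {"good": 2, "average": 1, "poor": 0}


def _cardiac_prominence(x: np.ndarray, fs: float,
                        band: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    """(peak power / median band power, peak frequency) from a Welch PSD.

    ``x`` may be N-dimensional with samples on the last axis; the outputs
    drop that axis.
    """
    # Welch average over non-overlapping Hann-windowed ~20 s segments:
    # ~0.05 Hz resolution, ample to isolate a cardiac line in 0.7-2.5 Hz
    nper = min(x.shape[-1], 512)
    nseg = x.shape[-1] // nper
    seg = x[..., : nseg * nper].reshape(x.shape[:-1] + (nseg, nper))
    seg = seg - seg.mean(axis=-1, keepdims=True)
    spec = np.fft.rfft(seg * np.hanning(nper), axis=-1)
    p = (np.abs(spec) ** 2).mean(axis=-2)
    f = np.fft.rfftfreq(nper, 1.0 / fs)
    m = (f >= band[0]) & (f <= band[1])
    pband = p[..., m]
    med = np.median(pband, axis=-1)
    med = np.where(med == 0, np.inf, med)
    ratio = pband.max(axis=-1) / med
    freq = f[m][np.argmax(pband, axis=-1)]
    return ratio, freq


def quality_classify(
    rec: SessionRecording,
    montage: Montage,
    config: PreprocessConfig | None = None,
) -> QualityReport:
    """Classify channels by cardiac spectral prominence and gate the subject.

    A channel is "good" when the cardiac peak stands at least
    ``quality_good_ratio`` times above the median in-band power (an
    objective stand-in for a visible heart-rate component), "average" above
    ``quality_average_ratio``, else "poor".  A quality region is good when
    at least two of its four channels are good, average when at least two
    are average-or-better, else poor; the subject is included when at least
    two regions are average-or-better.
    """
    if config is None:
        config = PreprocessConfig()
    if rec.duration_s < 60:
        raise ValueError("need at least 60 s of data for quality classification")
    for region, chans in montage.quality_regions.items():
        if set(chans) - set(rec.channel_ids.tolist()):
            raise ValueError(f"quality region {region} references absent channels")

    ratios, freqs = _cardiac_prominence(rec.intensity, rec.fs, config.cardiac_band_hz)
    mean_ratio = ratios.mean(axis=1)  # average over the two wavelengths
    channel_class, channel_prom, channel_freq = {}, {}, {}
    for i, cid in enumerate(rec.channel_ids):
        ratio = float(mean_ratio[i])
        channel_prom[int(cid)] = ratio
        channel_freq[int(cid)] = float(freqs[i, 1])
        if ratio >= config.quality_good_ratio:
            channel_class[int(cid)] = "good"
        elif ratio >= config.quality_average_ratio:
            channel_class[int(cid)] = "average"
        else:
            channel_class[int(cid)] = "poor"

    region_class = {}
    for region, chans in montage.quality_regions.items():
        classes = [channel_class[c] for c in chans]
        n_good = sum(c == "good" for c in classes)
        n_avg_up = sum(_CLASS_ORDER[c] >= 1 for c in classes)
        if n_good >= 2:
            region_class[region] = "good"
        elif n_avg_up >= 2:
            region_class[region] = "average"
        else:
            region_class[region] = "poor"

    include = sum(_CLASS_ORDER[c] >= 1 for c in region_class.values()) >= 2
    return QualityReport(
        channel_class=channel_class,
        channel_prominence=channel_prom,
        channel_cardiac_hz=channel_freq,
        region_class=region_class,
        include_subject=include,
    )


# ---------------------------------------------------------------------------
# full chain

def preprocess_session(
    rec: SessionRecording,
    montage: Montage,
    config: PreprocessConfig | None = None,
    extinction: ExtinctionTable | None = None,
) -> tuple[ConcentrationSet, QualityReport]:
    """Run the full preprocessing chain on one session.

    Returns the final long-channel ConcentrationSet (uM) and the quality
    report.  The report is informational here; subject exclusion is applied
    at the cohort level.
    """
    if config is None:
        config = PreprocessConfig()
    config.validate(rec.fs)
    rec.validate_against(montage)
    report = quality_classify(rec, montage, config)
    ods = intensity_to_od(rec, config.baseline_window_s)
    ods = wavelet_despike(ods, config.wavelet_k, config.wavelet, config.wavelet_levels)
    ods = bandpass_od(ods, *config.band_hz, config.filter_order)
    conc = mbll(ods, montage, extinction, config.dpf,
                config.distance_long_cm, config.distance_short_cm)
    conc = regress_short_channels(conc, montage)
    conc = detrend(conc)
    return conc, report
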