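"""Synthetic intraoperative fNIRS cohorts with known ground truth.

Each simulated session emulates the signal structure of a continuous-wave
recording over knee surgery under general anesthesia:

* event-locked hemodynamic responses (gamma-shaped kernel, configurable
  time-to-peak, optional early dip and post-peak undershoot) injected into
  long-separation channels only, lateralized contralateral to the operated
  knee, with the somatosensory response amplitude controlled by the
  nerve-block group assignment;
* systemic physiology (cardiac, respiratory, and ~0.1 Hz low-frequency
  oscillations with slowly drifting phase, plus AR(1) colored noise) shared
  between long channels and their paired short-separation channels through
  per-channel gains;
* slow polynomial drifts, brief motion spikes in the optical-density
  domain, and white measurement noise;
* conversion of the summed concentration signal to dual-wavelength
  intensities through the forward modified Beer-Lambert model, so the
  preprocessing chain inverts a physically consistent signal.

All randomness flows from a single seed; identical configurations produce
bitwise-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import lfilter

from .io import EventLog, PatientRecord, SessionRecording
from .montage import Montage, default_montage
from .optics import ExtinctionTable, load_extinction_table, mbll_system


@dataclass(frozen=True)
class GroupResponseParams:
    """Evoked-response parameters for one clinical group."""

    s1_hbo2_peak_um: float          # contralateral S1 HbO2 peak amplitude
    prefc_hbo2_peak_um: float       # prefrontal HbO2 peak amplitude
    hbr_ratio: float = -0.35        # HbR amplitude as a fraction of HbO2
    time_to_peak_s: float = 20.0
    dip_fraction: float = 0.0       # early (~5 s) negative deflection, S1 only
    undershoot_fraction: float = 0.1


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level simulation settings.

    Defaults reproduce the study design being emulated: 19 patients with an
    11/8 nerve-block split, sessions of 25-65 min at 25 Hz, 2-12 painful
    procedures per patient, a contralateral-S1 HbO2 response peaking at
    +0.41 uM around 20 s after incision in patients without a nerve block
    (with an early dip), and an attenuated positive response under a block.
    """

    n_patients: int = 19
    p_nerve_block: float = 11.0 / 19.0
    duration_range_s: tuple[float, float] = (1500.0, 3900.0)
    fs: float = 25.0

    # event schedule
    n_pain_events_range: tuple[int, int] = (2, 12)
    n_other_events_range: tuple[int, int] = (1, 6)
    first_pain_range_s: tuple[float, float] = (180.0, 240.0)
    min_event_gap_s: float = 45.0
    p0_gap_range_s: tuple[float, float] = (150.0, 240.0)
    end_margin_s: float = 120.0

    # hemodynamic response, per group
    non_nb: GroupResponseParams = GroupResponseParams(
        s1_hbo2_peak_um=0.41, prefc_hbo2_peak_um=0.05, dip_fraction=0.3
    )
    nb: GroupResponseParams = GroupResponseParams(
        s1_hbo2_peak_um=0.12, prefc_hbo2_peak_um=0.05, dip_fraction=0.0
    )
    ipsilateral_fraction: float = 0.25
    subject_amp_sigma: float = 0.25   # lognormal sd of per-subject amplitude factor
    event_amp_sigma: float = 0.15     # lognormal sd of per-event amplitude factor

    # systemic physiology (concentration-equivalent amplitudes, uM)
    cardiac_freq_hz: float = 1.1
    cardiac_freq_jitter_hz: float = 0.15
    cardiac_amp_um: float = 1.5
    resp_freq_hz: float = 0.25
    resp_amp_um: float = 0.5
    mayer_freq_hz: float = 0.1
    mayer_amp_um: float = 0.8
    phase_walk_sd: float = 0.01       # rad per sample, random phase drift
    ar1_coef: float = 0.9
    ar1_sd_um: float = 0.15
    systemic_gain_range: tuple[float, float] = (0.5, 1.5)
    hbr_systemic_ratio: float = 0.3

    # drifts / artifacts / noise
    drift_linear_um: float = 1.5      # max |linear drift| over the session
    drift_cubic_um: float = 1.5
    spike_rate_per_min: float = 0.5
    spike_amp_od: tuple[float, float] = (0.05, 0.2)
    spike_width_s: tuple[float, float] = (0.1, 0.3)
    noise_sd_um: float = 0.3          # white measurement noise per channel

    # storage precision of the synthesized signals; single precision more
    # than covers the dynamic range of a CW acquisition ADC
    dtype: str = "float32"

    # optics
    dpf: tuple[float, float] = (6.0, 6.0)
    distance_long_cm: float = 3.0
    distance_short_cm: float = 0.8
    baseline_intensity_range: tuple[float, float] = (0.4, 2.0)

    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 2 * self.cardiac_freq_hz:
            raise ValueError("fs must exceed twice the cardiac frequency")
        amps = (self.cardiac_amp_um, self.resp_amp_um, self.mayer_amp_um,
                self.noise_sd_um, self.ar1_sd_um)
        if any(a < 0 for a in amps):
            raise ValueError("amplitudes must be nonnegative")

    def null_variant(self) -> "SimConfig":
        """Same cohort structure with no group difference (both groups share
        the non-nerve-block response parameters)."""
        return replace(self, nb=self.non_nb)


@dataclass
class GroundTruth:
    """Injected signal parameters for one simulated session."""

    event_times: np.ndarray
    painful: np.ndarray
    group: str
    laterality: str
    # per long channel id -> per-painful-event HbO2 peak amplitude (uM)
    response_amp_hbo2: dict[int, np.ndarray]
    systemic_hbo2: np.ndarray
    systemic_hbr: np.ndarray
    spike_times: dict[int, np.ndarray]  # channel id -> spike center times (s)


@dataclass
class SimulatedSession:
    recording: SessionRecording
    events: EventLog
    patient: PatientRecord
    truth: GroundTruth


# ---------------------------------------------------------------------------
# hemodynamic response kernel

def _gamma_kernel(t: np.ndarray, tp: float, shape: float = 6.0) -> np.ndarray:
    """Gamma-variate normalized to peak 1 at t = tp; zero for t <= 0."""
    out = np.zeros_like(t, dtype=float)
    pos = t > 0
    x = t[pos] / tp
    out[pos] = x**shape * np.exp(shape * (1.0 - x))
    return out


def hrf(
    t: np.ndarray | float,
    time_to_peak_s: float = 20.0,
    dip_fraction: float = 0.0,
    undershoot_fraction: float = 0.1,
    dip_time_s: float = 5.0,
    shape: float = 6.0,
) -> np.ndarray:
    """Evoked-response kernel: unit peak at ``time_to_peak_s``.

    A gamma-variate main lobe with an optional early negative deflection
    (``dip_fraction`` of the peak, centered near ``dip_time_s``) and a late
    undershoot at 1.6x the peak time.  ``hrf(0) == 0`` (causal), and with
    both fractions zero the kernel is nonnegative everywhere.
    """
    if time_to_peak_s <= 0:
        raise ValueError("time_to_peak_s must be positive")
    t = np.atleast_1d(np.asarray(t, dtype=float))

    def compose(tt: np.ndarray) -> np.ndarray:
        return (
            _gamma_kernel(tt, time_to_peak_s, shape)
            - dip_fraction * _gamma_kernel(tt, dip_time_s, shape + 2)
            - undershoot_fraction
            * _gamma_kernel(tt, 1.6 * time_to_peak_s, shape + 4)
        )

    # the dip/undershoot lobes shift the composite maximum slightly off the
    # nominal peak time; rescale the time axis so the realized argmax sits
    # exactly at time_to_peak_s, then normalize the peak to 1
    grid = np.arange(0.0, 5.0 * time_to_peak_s, 0.01)
    raw_grid = compose(grid)
    tau = grid[int(np.argmax(raw_grid))]
    peak = float(np.max(raw_grid))
    return compose(t * (tau / time_to_peak_s)) / peak


# ---------------------------------------------------------------------------
# event schedule

def _draw_schedule(
    duration_s: float, cfg: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Event times and painful flags honoring the schedule constraints:
    first painful event >= ~3 min after start, last event >= 2 min before
    the end, and at least one procedure-free gap long enough for a baseline
    epoch."""
    end_limit = duration_s - cfg.end_margin_s
    quiet = rng.uniform(*cfg.p0_gap_range_s)
    n_pain = int(rng.integers(cfg.n_pain_events_range[0], cfg.n_pain_events_range[1] + 1))
    n_other = int(rng.integers(cfg.n_other_events_range[0], cfg.n_other_events_range[1] + 1))
    t_first = rng.uniform(*cfg.first_pain_range_s)

    while True:
        n_tot = n_pain + n_other
        gaps = rng.uniform(cfg.min_event_gap_s, cfg.min_event_gap_s + 60.0, size=n_tot - 1)
        if n_tot >= 2:
            gaps[int(rng.integers(0, n_tot - 1))] = quiet
        if t_first + gaps.sum() <= end_limit:
            break
        if n_other > 0:
            n_other -= 1
        elif n_pain > 2:
            n_pain -= 1
        else:  # minimal schedule: two painful events separated by the quiet gap
            t_first = max(120.0, min(cfg.first_pain_range_s[0], end_limit - 120.0))
            quiet = end_limit - t_first
            if quiet < 120.0:  # must still fit a procedure-free baseline epoch
                raise ValueError(
                    f"session of {duration_s:g}s too short for a valid event schedule"
                )
            gaps = np.array([quiet])
            break

    times = t_first + np.concatenate([[0.0], np.cumsum(gaps)])
    painful = np.zeros(times.size, dtype=bool)
    painful[0] = painful[-1] = True
    interior = np.arange(1, times.size - 1)
    k = min(n_pain - 2, interior.size)
    if k > 0:
        painful[rng.choice(interior, size=k, replace=False)] = True
    return times, painful


# ---------------------------------------------------------------------------
# session synthesis

def _systemic_trace(n: int, cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Shared superficial-physiology trace: three oscillators with slowly
    drifting phase plus AR(1) noise (uM)."""
    t = np.arange(n) / cfg.fs
    cardiac_f = cfg.cardiac_freq_hz + rng.uniform(
        -cfg.cardiac_freq_jitter_hz, cfg.cardiac_freq_jitter_hz
    )
    trace = np.zeros(n)
    for freq, amp in (
        (cardiac_f, cfg.cardiac_amp_um),
        (cfg.resp_freq_hz, cfg.resp_amp_um),
        (cfg.mayer_freq_hz, cfg.mayer_amp_um),
    ):
        phase = rng.uniform(0, 2 * np.pi) + np.cumsum(
            rng.normal(0.0, cfg.phase_walk_sd, size=n)
        )
        trace += amp * np.sin(2 * np.pi * freq * t + phase)
    if cfg.ar1_sd_um > 0:
        innov_sd = cfg.ar1_sd_um * np.sqrt(1 - cfg.ar1_coef**2)
        trace += lfilter([1.0], [1.0, -cfg.ar1_coef], rng.normal(0, innov_sd, size=n))
    return trace


def _drift(n: int, cfg: SimConfig, rng: np.random.Generator, n_ch: int) -> np.ndarray:
    x = np.linspace(0.0, 1.0, n)
    a1 = rng.uniform(-cfg.drift_linear_um, cfg.drift_linear_um, size=n_ch)
    a3 = rng.uniform(-cfg.drift_cubic_um, cfg.drift_cubic_um, size=n_ch)
    return a1[:, None] * x[None, :] + a3[:, None] * x[None, :] ** 3


def _spikes_od(
    n: int, cfg: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Motion artifacts for one channel: gaussian bumps in OD units."""
    duration_min = n / cfg.fs / 60.0
    n_spikes = rng.poisson(cfg.spike_rate_per_min * duration_min)
    od = np.zeros(n)
    centers = rng.uniform(0.0, n / cfg.fs, size=n_spikes)
    t = np.arange(n) / cfg.fs
    for c in centers:
        amp = rng.uniform(*cfg.spike_amp_od) * rng.choice([-1.0, 1.0])
        width = rng.uniform(*cfg.spike_width_s)
        lo = max(0, int((c - 5 * width) * cfg.fs))
        hi = min(n, int((c + 5 * width) * cfg.fs) + 1)
        od[lo:hi] += amp * np.exp(-0.5 * ((t[lo:hi] - c) / width) ** 2)
    return od, centers


def _response_amplitudes(
    montage: Montage,
    params: GroupResponseParams,
    laterality: str,
    n_events: int,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> dict[int, np.ndarray]:
    """Per (long channel, painful event) HbO2 peak amplitude in uM."""
    contra = "left" if laterality == "R" else "right"
    subj_factor = rng.lognormal(0.0, cfg.subject_amp_sigma)
    amps: dict[int, np.ndarray] = {}
    for _, row in montage.channels.iterrows():
        base = (
            params.s1_hbo2_peak_um if row["region"] == "S1" else params.prefc_hbo2_peak_um
        )
        side_factor = 1.0 if row["hemisphere"] == contra else cfg.ipsilateral_fraction
        event_factors = rng.lognormal(0.0, cfg.event_amp_sigma, size=n_events)
        amps[int(row["channel_id"])] = base * side_factor * subj_factor * event_factors
    return amps


def simulate_session(
    patient: PatientRecord,
    montage: Montage,
    cfg: SimConfig,
    rng: np.random.Generator,
    extinction: ExtinctionTable,
    duration_s: float | None = None,
) -> SimulatedSession:
    if duration_s is None:
        duration_s = rng.uniform(*cfg.duration_range_s)
    n = int(round(duration_s * cfg.fs))
    t = np.arange(n) / cfg.fs

    event_times, painful = _draw_schedule(duration_s, cfg, rng)
    events = EventLog(
        times=event_times,
        labels=["incision" if p else "scraping" for p in painful],
        painful=painful,
        duration_s=duration_s,
    )

    params = cfg.nb if patient.nerve_block else cfg.non_nb
    amps = _response_amplitudes(
        montage, params, patient.laterality, int(painful.sum()), cfg, rng
    )

    sys_hbo = _systemic_trace(n, cfg, rng)
    sys_hbr = cfg.hbr_systemic_ratio * sys_hbo

    long_ids = montage.long_channel_ids
    short_ids = montage.short_channel_ids
    n_long, n_short = long_ids.size, short_ids.size

    gains_long = rng.uniform(*cfg.systemic_gain_range, size=n_long)
    gains_short = rng.uniform(*cfg.systemic_gain_range, size=n_short)

    # evoked responses: long channels only, S1 kernels carry the early dip
    kernel_len = int(4.0 * params.time_to_peak_s * cfg.fs)
    kt = np.arange(kernel_len) / cfg.fs
    kernels = {
        "S1": hrf(kt, params.time_to_peak_s, params.dip_fraction,
                  params.undershoot_fraction),
        "PreFC": hrf(kt, params.time_to_peak_s, 0.0, params.undershoot_fraction),
    }
    resp_hbo = np.zeros((n_long, n))
    regions = montage.channels["region"].to_numpy()
    amp_matrix = np.stack([amps[int(c)] for c in long_ids])  # (n_long, n_pain)
    for e, t_ev in enumerate(event_times[painful]):
        i0 = int(round(t_ev * cfg.fs))
        i1 = min(n, i0 + kernel_len)
        for region in ("S1", "PreFC"):
            mask = regions == region
            resp_hbo[mask, i0:i1] += (
                amp_matrix[mask, e][:, None] * kernels[region][None, : i1 - i0]
            )
    resp_hbr = params.hbr_ratio * resp_hbo

    dt = np.dtype(cfg.dtype)
    drift_long = _drift(n, cfg, rng, n_long).astype(dt)
    drift_short = _drift(n, cfg, rng, n_short).astype(dt)
    noise = cfg.noise_sd_um * rng.standard_normal(
        size=(2, n_long + n_short, n), dtype=np.float32
    ).astype(dt, copy=False)
    sys_hbo_t = sys_hbo.astype(dt)
    sys_hbr_t = sys_hbr.astype(dt)
    resp_hbo = resp_hbo.astype(dt)
    resp_hbr = resp_hbr.astype(dt)
    gl = gains_long.astype(dt)[:, None]
    gs = gains_short.astype(dt)[:, None]

    hbo_long = resp_hbo + gl * sys_hbo_t[None, :] + drift_long + noise[0, :n_long]
    hbr_long = resp_hbr + gl * sys_hbr_t[None, :] + dt.type(0.3) * drift_long + noise[1, :n_long]
    hbo_short = gs * sys_hbo_t[None, :] + drift_short + noise[0, n_long:]
    hbr_short = gs * sys_hbr_t[None, :] + dt.type(0.3) * drift_short + noise[1, n_long:]

    # concentration -> OD via the forward model, then spikes, then intensity
    n_tot = n_long + n_short
    hbo_all = np.concatenate([hbo_long, hbo_short])
    hbr_all = np.concatenate([hbr_long, hbr_short])
    a_long = mbll_system(extinction, (690.0, 830.0), cfg.distance_long_cm, cfg.dpf)
    conc_stack = np.stack([hbo_all, hbr_all])  # (species, channel, sample)
    od = np.einsum("ws,scn->cwn", a_long.astype(dt), conc_stack)
    od[n_long:] *= dt.type(cfg.distance_short_cm / cfg.distance_long_cm)

    channel_ids = np.concatenate([long_ids, short_ids])
    spike_times: dict[int, np.ndarray] = {}
    for i, cid in enumerate(channel_ids):
        sp, centers = _spikes_od(n, cfg, rng)
        spike_times[int(cid)] = centers
        scale = rng.uniform(0.8, 1.2)
        od[i, 0] += sp.astype(dt)
        od[i, 1] += (scale * sp).astype(dt)

    i0 = rng.uniform(*cfg.baseline_intensity_range, size=(n_tot, 2)).astype(dt)
    intensity = i0[:, :, None] * np.exp(-od)

    recording = SessionRecording(
        intensity=intensity,
        channel_ids=channel_ids,
        fs=cfg.fs,
        patient_id=patient.patient_id,
        montage=montage,
    )
    truth = GroundTruth(
        event_times=event_times,
        painful=painful,
        group=patient.group,
        laterality=patient.laterality,
        response_amp_hbo2=amps,
        systemic_hbo2=sys_hbo,
        systemic_hbr=sys_hbr,
        spike_times=spike_times,
    )
    return SimulatedSession(recording, events, patient, truth)


def simulate_cohort(
    cfg: SimConfig,
    montage: Montage | None = None,
    extinction: ExtinctionTable | None = None,
) -> list[SimulatedSession]:
    """Generate a full cohort; group sizes follow round(n * p_nerve_block)."""
    n_nb = int(round(cfg.n_patients * cfg.p_nerve_block))
    n_non = cfg.n_patients - n_nb
    if min(n_nb, n_non) < 2:
        raise ValueError("need at least 2 patients per group for group statistics")
    if montage is None:
        montage = default_montage()
    if extinction is None:
        extinction = load_extinction_table()
    rng = np.random.default_rng(cfg.rng_seed)

    block_flags = np.array([True] * n_nb + [False] * n_non)
    rng.shuffle(block_flags)

    sessions = []
    for i in range(cfg.n_patients):
        vrs_pre = float(rng.integers(0, 4))
        vrs_post = float(min(10, vrs_pre + rng.integers(0, 7)))
        patient = PatientRecord(
            patient_id=str(i + 1),
            age=float(rng.integers(12, 26)),
            sex=str(rng.choice(["M", "F"])),
            laterality=str(rng.choice(["R", "L"])),
            nerve_block=bool(block_flags[i]),
            pain_procedures=0,  # filled after the schedule is drawn
            vrs_pre=vrs_pre,
            vrs_post=vrs_post,
            vrs_discharge=float(max(0.0, vrs_post - rng.integers(0, 4))),
        )
        sess = simulate_session(patient, montage, cfg, rng, extinction)
        patient.pain_procedures = int(sess.truth.painful.sum())
        sessions.append(sess)
    return sessions
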