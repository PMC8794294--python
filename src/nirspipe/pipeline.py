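"""End-to-end orchestration: simulate -> preprocess -> epochs -> metrics -> stats.

`analyze_cohort` runs the per-session chain (quality gate, concentration
pipeline, side mapping, epoching, curves) and assembles the cohort AUC and
dynamic-correlation tables.  `group_anova_*` wrap the split-plot ANOVA over
those tables.  `detect_s1_group_difference` is the headline readout: does
the nerve-block group effect on contralateral somatosensory AUC reach
p < 0.05 with the correct direction?  `run_all` drives the whole flow from
a config and writes tabular outputs plus a reproducibility manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .epochs import epoch_curves, epoch_segments, map_sides
from .io import patients_frame
from .montage import Montage, ROIS_S1, default_montage
from .optics import load_extinction_table
from .preprocess import PreprocessConfig, preprocess_session
from .simulate import SimConfig, SimulatedSession, simulate_cohort
from .stats import (
    ALPHA,
    anova_family_fdr,
    auc_table,
    demographic_summary,
    mixed_anova,
    pair_set_means,
    two_sample_t,
)


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    prep: PreprocessConfig = field(default_factory=PreprocessConfig)
    alpha: float = ALPHA
    apply_quality_gate: bool = True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class CohortResult:
    auc: pd.DataFrame                # one row per (patient, side, roi, species, epoch)
    dyncorr: pd.DataFrame            # pair-set windowed correlations
    curves: pd.DataFrame             # tidy 51-point curves
    excluded: list[str]              # patient ids failing the quality gate
    patients: pd.DataFrame


def analyze_cohort(
    sessions: list[SimulatedSession],
    prep: PreprocessConfig | None = None,
    montage: Montage | None = None,
    apply_quality_gate: bool = True,
    with_correlations: bool = True,
    with_curve_table: bool = True,
) -> CohortResult:
    """Per-session preprocessing + epoching, assembled into cohort tables.

    ``with_correlations`` / ``with_curve_table`` can be disabled for
    replicated power/calibration runs that only consume the AUC table.
    """
    if prep is None:
        prep = PreprocessConfig()
    if montage is None:
        montage = default_montage()
    extinction = load_extinction_table()

    auc_frames, corr_rows, curve_rows, excluded = [], [], [], []
    for sess in sessions:
        conc, report = preprocess_session(sess.recording, montage, prep, extinction)
        if apply_quality_gate and not report.include_subject:
            excluded.append(sess.patient.patient_id)
            continue
        roi = map_sides(conc, montage, sess.patient.laterality, report)
        curves = epoch_curves(roi, sess.events)

        auc_frames.append(auc_table(curves, sess.patient.patient_id, sess.patient.group))
        if with_correlations:
            segments = epoch_segments(roi, sess.events)
            pm = pair_set_means(segments, fs=conc.fs)
            pm.insert(0, "group", sess.patient.group)
            pm.insert(0, "patient_id", sess.patient.patient_id)
            corr_rows.append(pm)
        if with_curve_table:
            for (side, r, species, epoch), c in curves.items():
                for j, v in enumerate(c):
                    curve_rows.append(
                        (sess.patient.patient_id, side, r, species, epoch, j, v)
                    )

    return CohortResult(
        auc=pd.concat(auc_frames, ignore_index=True) if auc_frames else pd.DataFrame(),
        dyncorr=pd.concat(corr_rows, ignore_index=True) if corr_rows else pd.DataFrame(),
        curves=pd.DataFrame(
            curve_rows,
            columns=["patient_id", "side", "roi", "species", "epoch",
                     "window_start_s", "value"],
        ),
        excluded=excluded,
        patients=patients_frame([s.patient for s in sessions]),
    )


def s1_auc_by_patient(auc: pd.DataFrame, side: str = "contralateral",
                      species: str = "HbO2") -> pd.DataFrame:
    """Mean AUC over the three somatosensory ROIs per (patient, epoch)."""
    sel = auc[
        (auc["side"] == side) & (auc["species"] == species) & auc["roi"].isin(ROIS_S1)
    ]
    return (
        sel.groupby(["patient_id", "group", "epoch"], as_index=False)["auc"].mean()
    )


def detect_s1_group_difference(result: CohortResult) -> tuple[float, bool]:
    """(group-effect p, direction is non-NB > NB) on contralateral S1 AUC."""
    d = s1_auc_by_patient(result.auc)
    table = mixed_anova(d, dv="auc", between="group", within="epoch")
    p = float(table.loc[table["effect"] == "group", "p"].iloc[0])
    means = d.groupby("group")["auc"].mean()
    direction = bool(means.get("non-NB", np.nan) > means.get("NB", np.nan))
    return p, direction


def auc_group_anovas(result: CohortResult, side: str = "contralateral") -> pd.DataFrame:
    """Group-effect split-plot ANOVA per (roi, species) with family-wise BH FDR.

    The family is the full analysis table for one side (all ROI x species
    cells), an 18-cell family (6 ROIs x 3 hemoglobin species).
    """
    tables = []
    sel = result.auc[result.auc["side"] == side]
    for (roi, species), d in sel.groupby(["roi", "species"]):
        try:
            t = mixed_anova(d, dv="auc", between="group", within="epoch")
        except ValueError:
            continue
        tables.append((f"{roi}|{species}", t))
    return anova_family_fdr(tables, effect="group")


def dyncorr_anovas(result: CohortResult) -> pd.DataFrame:
    """Group and time effects on pair-set mean correlations, per
    (pair_set, epoch), BH FDR within each effect family."""
    frames = []
    for effect in ("group", "window_start"):
        tables = []
        for (pair_set, epoch), d in result.dyncorr.groupby(["pair_set", "epoch"]):
            d = d.dropna(subset=["r"])
            try:
                t = mixed_anova(d, dv="r", between="group", within="window_start")
            except ValueError:
                continue
            tables.append((f"{pair_set}|{epoch}", t))
        fam = anova_family_fdr(tables, effect=effect)
        fam.insert(0, "effect", effect)
        frames.append(fam)
    return pd.concat(frames, ignore_index=True)


def auc_ttests(result: CohortResult, side: str = "contralateral",
               species: str = "HbO2") -> pd.DataFrame:
    """Per (roi, epoch) two-sample t-test NB vs non-NB on AUC, BH FDR."""
    sel = result.auc[(result.auc["side"] == side) & (result.auc["species"] == species)]
    rows = []
    for (roi, epoch), d in sel.groupby(["roi", "epoch"]):
        nb = d.loc[d["group"] == "NB", "auc"].to_numpy()
        non = d.loc[d["group"] == "non-NB", "auc"].to_numpy()
        if nb.size < 2 or non.size < 2:
            continue
        try:
            t, df, p = two_sample_t(nb, non)
        except ValueError:
            continue
        rows.append((roi, epoch, t, df, p))
    out = pd.DataFrame(rows, columns=["roi", "epoch", "t", "df", "p_raw"])
    if len(out):
        from .stats import bh_fdr

        adj, rej = bh_fdr(out["p_raw"].to_numpy())
        out["p_fdr"] = adj
        out["significant_fdr"] = rej
    return out


# ---------------------------------------------------------------------------
# full run

def run_all(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Simulate a cohort, analyze it end to end, write outputs + manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    caught: list[str] = []
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        sessions = simulate_cohort(config.sim)
        result = analyze_cohort(
            sessions, config.prep, apply_quality_gate=config.apply_quality_gate
        )
        caught = [str(w.message) for w in wlist]

    result.auc.to_csv(out / "auc.tsv", sep="\t", index=False)
    result.dyncorr.to_csv(out / "dyncorr.tsv", sep="\t", index=False)
    result.curves.to_csv(out / "curves.tsv", sep="\t", index=False)
    result.patients.to_csv(out / "patients.tsv", sep="\t", index=False)
    auc_group_anovas(result).to_csv(out / "auc_anova.tsv", sep="\t", index=False)
    auc_ttests(result).to_csv(out / "auc_ttests.tsv", sep="\t", index=False)
    dyncorr_anovas(result).to_csv(out / "dyncorr_anova.tsv", sep="\t", index=False)

    patients = [s.patient for s in sessions]
    demo = demographic_summary(patients)
    demo.to_csv(out / "demographics.tsv", sep="\t")

    checksums = {
        f.name: hashlib.sha256(f.read_bytes()).hexdigest()
        for f in sorted(out.glob("*.tsv"))
    }
    manifest = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.sim.rng_seed,
        "n_subjects": len(sessions),
        "excluded_subjects": result.excluded,
        "warnings": caught,
        "elapsed_s": round(time.time() - t0, 2),
        "checksums": checksums,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def report(results_dir: str | Path) -> str:
    """Plain-text summary of a results directory; missing tables are noted."""
    results_dir = Path(results_dir)
    lines = ["nirspipe run report", "=" * 40]

    def section(title: str, fname: str, fmt) -> None:
        lines.append("")
        lines.append(title)
        lines.append("-" * len(title))
        f = results_dir / fname
        if not f.exists():
            lines.append("[missing]")
            return
        try:
            fmt(pd.read_csv(f, sep="\t"))
        except Exception as exc:  # pragma: no cover - defensive
            lines.append(f"[unreadable: {exc}]")

    def demo_fmt(df: pd.DataFrame) -> None:
        for _, r in df.iterrows():
            lines.append(
                f"{r['group']:>7}: n={r['n']:.0f} ({100 * r['fraction']:.0f}%), "
                f"age {r['age_mean']:.1f} +/- {r['age_sd']:.2f}, "
                f"{r['n_female']:.0f} F / {r['n_male']:.0f} M"
            )

    def curves_fmt(df: pd.DataFrame) -> None:
        g = df.groupby(["side", "roi", "species", "epoch"])["value"]
        summary = g.agg(["mean", "sem"]).reset_index()
        lines.append(f"{len(summary)} (side, roi, species, epoch) mean +/- SE cells")
        hb = summary[(summary["species"] == "HbO2") & (summary["side"] == "contralateral")]
        for _, r in hb.iterrows():
            lines.append(
                f"  contral. {r['roi']:>14} {r['epoch']}: "
                f"{r['mean']:+.3f} +/- {r['sem']:.3f}"
            )

    def anova_fmt(df: pd.DataFrame) -> None:
        for _, r in df.iterrows():
            flag = "*" if r.get("significant_fdr") is True else ""
            lines.append(
                f"  {r['cell']:>28}: F={r['F']:.2f} p={r['p_raw']:.4f} "
                f"p_fdr={r['p_fdr']:.4f} {flag}"
            )

    def ttest_fmt(df: pd.DataFrame) -> None:
        for _, r in df.iterrows():
            flag = "*" if r.get("significant_fdr") is True else ""
            lines.append(
                f"  {r['roi']:>14} {r['epoch']}: t={r['t']:+.2f} "
                f"p={r['p_raw']:.4f} {flag}"
            )

    section("Demographics", "demographics.tsv", demo_fmt)
    section("Epoch curve summary (per-ROI mean +/- SE)", "curves.tsv", curves_fmt)
    section("AUC group ANOVA (nerve-block effect per ROI x species)", "auc_anova.tsv", anova_fmt)
    section("AUC t-tests NB vs non-NB", "auc_ttests.tsv", ttest_fmt)
    section("Dynamic-correlation ANOVA (pair-set effects)", "dyncorr_anova.tsv", anova_fmt)
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# desk-scale study replicas

def scaled_cohort_config(seed: int, n_patients: int = 19,
                         null: bool = False) -> SimConfig:
    """Cohort config with shortened sessions for replicated simulation runs.

    The signal model (amplitudes, noise, systemic physiology) is the cohort
    default; session length is reduced to ~6-7 min with a correspondingly
    compressed event schedule so that many replicate cohorts fit in a
    desk-scale run.
    """
    cfg = SimConfig(
        n_patients=n_patients,
        duration_range_s=(375.0, 425.0),
        n_pain_events_range=(2, 4),
        n_other_events_range=(1, 2),
        first_pain_range_s=(125.0, 140.0),
        p0_gap_range_s=(125.0, 150.0),
        end_margin_s=90.0,
        rng_seed=seed,
    )
    return cfg.null_variant() if null else cfg


def detection_rate(
    n_cohorts: int, base_seed: int, null: bool = False, n_patients: int = 19
) -> tuple[float, float]:
    """Fraction of replicate cohorts where the contralateral-S1 group
    difference is detected (p < alpha), and the fraction with the injected
    direction among detections.  Under ``null`` the two groups share one
    response model, so the rate estimates the type-I error."""
    detected = 0
    correct_direction = 0
    for k in range(n_cohorts):
        cfg = scaled_cohort_config(base_seed + k, n_patients, null=null)
        sessions = simulate_cohort(cfg)
        p, direction = _detect_s1_light(sessions)
        if p < ALPHA:
            detected += 1
            if direction:
                correct_direction += 1
    rate = detected / n_cohorts
    dir_rate = correct_direction / n_cohorts
    return rate, dir_rate


def _detect_s1_light(
    sessions: list[SimulatedSession],
    prep: PreprocessConfig | None = None,
    montage: Montage | None = None,
) -> tuple[float, bool]:
    """Same readout as analyze_cohort + detect_s1_group_difference but only
    materializes the contralateral-S1 HbO2 curves it consumes."""
    from .epochs import define_epochs, extract_segment, rolling_curve
    from .stats import auc_abs

    if prep is None:
        prep = PreprocessConfig()
    if montage is None:
        montage = default_montage()
    extinction = load_extinction_table()
    rows = []
    for sess in sessions:
        conc, report = preprocess_session(sess.recording, montage, prep, extinction)
        if not report.include_subject:
            continue
        contra = "left" if sess.patient.laterality == "R" else "right"
        defs = define_epochs(sess.events)
        for kind, ep in defs.items():
            aucs = []
            for roi in ROIS_S1:
                chans = [
                    c for c in montage.channels_for(contra, roi)
                    if report.channel_class.get(c) != "poor"
                ]
                if not chans:
                    continue
                series = np.mean([conc.series(c, "HbO2") for c in chans], axis=0)
                seg = extract_segment(series, conc.fs, ep)
                aucs.append(auc_abs(rolling_curve(seg, conc.fs)))
            if aucs:
                rows.append(
                    (sess.patient.patient_id, sess.patient.group, kind,
                     float(np.mean(aucs)))
                )
    d = pd.DataFrame(rows, columns=["patient_id", "group", "epoch", "auc"])
    table = mixed_anova(d, dv="auc", between="group", within="epoch")
    p = float(table.loc[table["effect"] == "group", "p"].iloc[0])
    means = d.groupby("group")["auc"].mean()
    direction = bool(means.get("non-NB", np.nan) > means.get("NB", np.nan))
    return p, direction
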