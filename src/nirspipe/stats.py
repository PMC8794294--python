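"""Response metrics and the inferential layer.

Metrics: absolute trapezoidal area under the standardized rolling curves
(the per-epoch "pain response" scalar), and sliding-window Pearson
correlations between the 15 unique ROI-ROI pairs, grouped into the
within-prefrontal, within-somatosensory, and cross pair sets.

Inference: a classical split-plot (two-way mixed) ANOVA with one
between-subject factor (nerve-block group) and one within-subject factor
(epoch or window), pooled or Welch two-sample t-tests, and
Benjamini-Hochberg step-up FDR control at alpha = 0.05.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import PatientRecord
from .montage import ROIS_PREFC, ROIS_S1

ALPHA = 0.05
DECIMATED_WINDOWS = (0, 10, 20, 30, 40, 50)


# ---------------------------------------------------------------------------
# metrics

def auc_abs(curve: np.ndarray, dx: float = 1.0) -> float:
    """Trapezoidal integral of |curve| (unit spacing over the 51 points)."""
    curve = np.asarray(curve, dtype=float)
    if np.isnan(curve).any():
        raise ValueError("curve contains NaN")
    return float(np.trapezoid(np.abs(curve), dx=dx))


def roi_pairs(
    prefc: tuple[str, ...] = ROIS_PREFC, s1: tuple[str, ...] = ROIS_S1
) -> list[tuple[str, str, str]]:
    """All unordered ROI pairs with their pair-set label.

    With 3 + 3 ROIs: C(6,2) = 15 pairs, partitioned 3 (PreFC) + 3 (S1)
    + 9 (PreFC/S1).
    """
    rois = tuple(prefc) + tuple(s1)
    if len(set(rois)) != len(rois):
        raise ValueError("duplicate ROI labels")
    prefc_set, s1_set = set(prefc), set(s1)
    out = []
    for a, b in itertools.combinations(rois, 2):
        if a in prefc_set and b in prefc_set:
            label = "PreFC"
        elif a in s1_set and b in s1_set:
            label = "S1"
        else:
            label = "PreFC/S1"
        out.append((a, b, label))
    return out


def windowed_pearson(
    x: np.ndarray,
    y: np.ndarray,
    fs: float = 25.0,
    window_s: float = 10.0,
    step_s: float = 1.0,
) -> np.ndarray:
    """Pearson r over sliding windows [j, j+window) seconds.

    Returns one r per step (51 for a 60-s segment); windows where either
    series has zero variance yield NaN (recorded missing).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series length mismatch")
    wlen = int(round(window_s * fs))
    step = int(round(step_s * fs))
    xw = np.lib.stride_tricks.sliding_window_view(x, wlen)[::step]
    yw = np.lib.stride_tricks.sliding_window_view(y, wlen)[::step]
    xv = xw - xw.mean(axis=1, keepdims=True)
    yv = yw - yw.mean(axis=1, keepdims=True)
    num = np.einsum("ij,ij->i", xv, yv)
    denom = np.sqrt(
        np.einsum("ij,ij->i", xv, xv) * np.einsum("ij,ij->i", yv, yv)
    )
    out = np.full(xw.shape[0], np.nan)
    ok = denom > 0
    out[ok] = np.clip(num[ok] / denom[ok], -1.0, 1.0)
    return out


def decimate_windows(r: np.ndarray, keep: tuple[int, ...] = DECIMATED_WINDOWS) -> np.ndarray:
    return np.asarray(r, dtype=float)[list(keep)]


# ---------------------------------------------------------------------------
# inference

@dataclass
class StatResult:
    effect: str
    f: float
    df1: float
    df2: float
    p_raw: float
    p_fdr: float | None = None

    @property
    def significant_raw(self) -> bool:
        return not np.isnan(self.p_raw) and self.p_raw < ALPHA

    @property
    def significant_fdr(self) -> bool:
        return self.p_fdr is not None and not np.isnan(self.p_fdr) and self.p_fdr <= ALPHA


def mixed_anova(
    df: pd.DataFrame,
    dv: str,
    between: str = "group",
    within: str = "epoch",
    subject: str = "patient_id",
) -> pd.DataFrame:
    """Two-way split-plot ANOVA (between groups x repeated within levels).

    The between effect is tested against the subject-within-group mean
    square; the within and interaction effects against the subject-by-
    within residual.  Group sizes may be unequal; every subject must have
    every within level (subjects with missing levels are dropped listwise
    with a warning).  With a single within level the between-effect F
    reduces exactly to the one-way ANOVA F.  Degenerate (zero-variance)
    data yield NaN F and p.
    """
    d = df[[subject, between, within, dv]].dropna()
    levels = sorted(d[within].unique())
    counts = d.groupby(subject)[within].nunique()
    complete = counts[counts == len(levels)].index
    if len(complete) < len(counts):
        import warnings

        warnings.warn(
            f"dropping {len(counts) - len(complete)} subjects with missing "
            f"within-levels", stacklevel=2,
        )
        d = d[d[subject].isin(complete)]
    groups = d.groupby(subject)[between].first()
    group_sizes = groups.value_counts()
    if len(group_sizes) < 2 or group_sizes.min() < 2:
        raise ValueError("mixed ANOVA needs >= 2 subjects in each of >= 2 groups")

    t_levels = len(levels)
    n_subj = len(complete)
    n_groups = len(group_sizes)
    y = d[dv].to_numpy(dtype=float)
    grand = y.mean()

    subj_mean = d.groupby(subject)[dv].mean()
    group_mean = d.groupby(between)[dv].mean()
    time_mean = d.groupby(within)[dv].mean()
    cell_mean = d.groupby([between, within])[dv].mean()

    ss_total = float(((y - grand) ** 2).sum())
    ss_subject = float(t_levels * ((subj_mean - grand) ** 2).sum())
    ss_group = float(
        t_levels * sum(group_sizes[g] * (group_mean[g] - grand) ** 2
                       for g in group_sizes.index)
    )
    ss_subj_within = ss_subject - ss_group
    ss_time = float(n_subj * ((time_mean - grand) ** 2).sum())
    ss_inter = float(
        sum(
            group_sizes[g] * (cell_mean[(g, t)] - group_mean[g] - time_mean[t] + grand) ** 2
            for g in group_sizes.index
            for t in levels
        )
    )
    ss_error = ss_total - ss_subject - ss_time - ss_inter

    df_group = n_groups - 1
    df_subj_within = n_subj - n_groups
    df_time = t_levels - 1
    df_inter = df_group * df_time
    df_error = df_subj_within * df_time

    def f_test(ss_num, df_num, ss_den, df_den):
        if df_num <= 0 or df_den <= 0 or ss_den <= 0:
            return np.nan, np.nan
        f = (ss_num / df_num) / (ss_den / df_den)
        if not np.isfinite(f):
            return np.nan, np.nan
        return float(f), float(sps.f.sf(f, df_num, df_den))

    rows = []
    f, p = f_test(ss_group, df_group, ss_subj_within, df_subj_within)
    rows.append((between, f, df_group, df_subj_within, p))
    if t_levels > 1:
        f, p = f_test(ss_time, df_time, ss_error, df_error)
        rows.append((within, f, df_time, df_error, p))
        f, p = f_test(ss_inter, df_inter, ss_error, df_error)
        rows.append((f"{between} * {within}", f, df_inter, df_error, p))
    return pd.DataFrame(rows, columns=["effect", "F", "df1", "df2", "p"])


def two_sample_t(
    a: np.ndarray, b: np.ndarray, welch: bool = False
) -> tuple[float, float, float]:
    """Two-sample t-test (pooled variance by default): (t, df, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    if not welch and a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, float(a.size + b.size - 2), 1.0
        raise ValueError("zero pooled variance with unequal means")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    df = res.df if hasattr(res, "df") else a.size + b.size - 2
    return float(res.statistic), float(df), float(res.pvalue)


def bh_fdr(p_values, alpha: float = ALPHA) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted p, rejection mask).

    Adjusted p_(i) = min_{j >= i} m p_(j) / j capped at 1; reject where the
    adjusted value is <= alpha.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        adj[i] = running
    return adj, adj <= alpha


def demographic_summary(patients: list[PatientRecord]) -> pd.DataFrame:
    """Per-group age mean/SD, sex counts, group fraction, VRS change."""
    from .io import patients_frame

    df = patients_frame(patients)
    rows = []
    n_total = len(df)
    for group, g in df.groupby("group"):
        ages = g["age"]
        both = g.dropna(subset=["vrs_pre", "vrs_post"])
        delta = both["vrs_post"] - both["vrs_pre"]
        rows.append(
            {
                "group": group,
                "n": len(g),
                "fraction": len(g) / n_total,
                "age_mean": float(ages.mean()),
                "age_sd": float(ages.std(ddof=1)) if len(g) > 1 else np.nan,
                "n_female": int((g["sex"] == "F").sum()),
                "n_male": int((g["sex"] == "M").sum()),
                "vrs_delta_mean": float(delta.mean()) if len(delta) else np.nan,
                "vrs_delta_sd": float(delta.std(ddof=1)) if len(delta) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("group")


# ---------------------------------------------------------------------------
# cohort tables

def pair_set_means(
    segments: dict[tuple[str, str, str, str], np.ndarray],
    fs: float = 25.0,
    side: str = "contralateral",
    species: str = "HbO2",
) -> pd.DataFrame:
    """Windowed ROI-ROI correlations averaged over pair sets for one session.

    Rows: (pair_set in {PreFC, S1, PreFC/S1, total}, epoch, window_start).
    Zero-variance windows are missing and excluded from the set means.
    """
    pairs = roi_pairs()
    rows = []
    for epoch in ("P0", "P1", "P2"):
        per_pair = {}
        for a, b, label in pairs:
            ka, kb = (side, a, species, epoch), (side, b, species, epoch)
            if ka not in segments or kb not in segments:
                continue
            r = windowed_pearson(segments[ka], segments[kb], fs)
            per_pair[(a, b, label)] = decimate_windows(r)
        if not per_pair:
            continue
        for wi, w in enumerate(DECIMATED_WINDOWS):
            by_label = {"PreFC": [], "S1": [], "PreFC/S1": []}
            for (a, b, label), r in per_pair.items():
                if not np.isnan(r[wi]):
                    by_label[label].append(r[wi])
            all_r = [v for vs in by_label.values() for v in vs]
            for label, vals in by_label.items():
                rows.append((label, epoch, w, float(np.mean(vals)) if vals else np.nan))
            rows.append(("total", epoch, w, float(np.mean(all_r)) if all_r else np.nan))
    return pd.DataFrame(rows, columns=["pair_set", "epoch", "window_start", "r"])


def auc_table(
    curves: dict[tuple[str, str, str, str], np.ndarray],
    patient_id: str,
    group: str,
) -> pd.DataFrame:
    """AUC rows for one session's curves (missing ROIs simply absent)."""
    rows = [
        (patient_id, group, side, roi, species, epoch, auc_abs(curve))
        for (side, roi, species, epoch), curve in curves.items()
    ]
    return pd.DataFrame(
        rows, columns=["patient_id", "group", "side", "roi", "species", "epoch", "auc"]
    )


def anova_family_fdr(
    results: list[tuple[str, pd.DataFrame]], effect: str, alpha: float = ALPHA
) -> pd.DataFrame:
    """Collect one named effect across a family of ANOVA tables and apply
    BH FDR over the family."""
    rows = []
    for name, table in results:
        hit = table[table["effect"] == effect]
        if len(hit):
            r = hit.iloc[0]
            rows.append((name, r["F"], r["df1"], r["df2"], r["p"]))
    out = pd.DataFrame(rows, columns=["cell", "F", "df1", "df2", "p_raw"])
    valid = out["p_raw"].notna()
    p_fdr = np.full(len(out), np.nan)
    if valid.any():
        adj, _ = bh_fdr(out.loc[valid, "p_raw"].to_numpy(), alpha)
        p_fdr[valid.to_numpy()] = adj
    out["p_fdr"] = p_fdr
    out["significant_raw"] = out["p_raw"] < alpha
    out["significant_fdr"] = out["p_fdr"] <= alpha
    return out
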