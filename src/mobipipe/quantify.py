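"""Backprojected cluster contributions to the sensor ERP: variance and pvaf.

For a cluster (or cluster group) k with channel-space projection P_k, the
percent variance accounted for in a time window is

    pvaf_k = 100 * (1 - var(sum_{j != k} P_j) / var(sum_j P_j))

with var(.) the mean square over channels and window samples of the
grand-average, baseline-corrected ERP.  pvaf is bounded above by 100% and can
be negative when a cluster's projection cancels another's (spatially
non-orthogonal components); absolute variances (uV^2) allow comparisons across
conditions where relative values mislead.  The analysis windows are
-200..1000 ms (response-locked envelope range) and 400..800 ms (P3 range).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .clustering import OUTLIER, ClusterSolution
from .core import EventList, Montage, standard_position
from .epochs import EpochSet, epoch_data, reject_epochs  # re-exported surface
from .ica import ICADecomposition, backproject

__all__ = [
    "SubjectRecord", "epoch_data", "reject_epochs", "group_backprojection_erp",
    "absolute_variance", "pvaf", "variance_report", "erp_window_stats",
    "pz_prime",
]

CELLS = [(s, c) for s in ("standard", "distractor", "target")
         for c in ("button", "pointing")]


@dataclass
class SubjectRecord:
    """Everything needed to backproject and epoch one subject.

    ``full_montage`` (the montage before channel rejection) triggers
    spherical-spline reconstruction of this subject's removed channels so
    grand averages live in one shared channel space.
    """
    subject: str
    decomp: ICADecomposition
    events: EventList
    montage: Montage
    full_montage: Montage | None = None

    def channel_operator(self):
        if self.full_montage is None or \
                list(self.full_montage.labels) == list(self.montage.labels):
            return None
        if not hasattr(self, "_op"):
            from .preprocess import interpolation_operator
            self._op = interpolation_operator(self.montage, self.full_montage)
        return self._op


def pz_prime(montage: Montage) -> str:
    """Label of the electrode closest to the standard parieto-central site."""
    return montage.nearest(standard_position("Pz", np.linalg.norm(
        montage.positions, axis=1).max()))


def _window_slice(times, window):
    lo, hi = window
    mask = (times >= lo - 1e-9) & (times <= hi + 1e-9)
    if not np.any(mask):
        raise ValueError(f"empty analysis window {window}")
    return mask


def absolute_variance(erp: np.ndarray, times=None, window=None) -> float:
    """Mean square of the (channels x time) ERP over a time window, in uV^2."""
    erp = np.atleast_2d(np.asarray(erp, float))
    if window is not None:
        erp = erp[:, _window_slice(np.asarray(times, float), window)]
    if erp.size == 0:
        raise ValueError("empty analysis window")
    return float(np.mean(erp ** 2))


def pvaf(group_k: np.ndarray, all_groups, times=None, window=None) -> float:
    """Percent variance accounted for by one projection among a set.

    ``all_groups`` must include ``group_k``; the remainder is computed by
    subtraction so the identity total = remainder + group_k holds exactly.
    Returns NaN (flagged) when the total variance vanishes.
    """
    total = np.sum(np.stack([np.atleast_2d(g) for g in all_groups]), axis=0)
    remaining = total - np.atleast_2d(group_k)
    var_total = absolute_variance(total, times, window)
    if var_total <= 0:
        return float("nan")
    var_rem = absolute_variance(remaining, times, window)
    return 100.0 * (1.0 - var_rem / var_total)


def _cluster_cell_erps(solution: ClusterSolution, records, clusters,
                       window=(-1.0, 2.0), baseline=(-0.2, 0.0),
                       zero_fill: bool = True):
    """Grand-average backprojected ERP per cell for a set of clusters.

    Subjects without components in the set contribute zeros when
    ``zero_fill`` (keeps group sums additive); otherwise they are skipped.
    Returns (cell -> (channels, time) array, times, skipped subjects).
    """
    tbl = solution.ic_table
    acc = {cell: None for cell in CELLS}
    counts = {cell: 0 for cell in CELLS}
    times = None
    skipped = []
    for rec in records:
        rows = tbl[(tbl["subject"] == rec.subject) & tbl["cluster"].isin(clusters)]
        ics = rows["ic_index"].tolist()
        if not ics and not zero_fill:
            skipped.append(rec.subject)
            continue
        sig = backproject(rec.decomp, ics)
        eps = epoch_data(sig, rec.events, fs=rec.decomp.fs, window=window,
                         baseline=baseline, subject=rec.subject)
        times = eps.times
        op = rec.channel_operator()
        for cell in CELLS:
            sel = eps.select(stimulus=cell[0], condition=cell[1])
            if sel.data.shape[0] == 0:
                continue
            erp = sel.erp()
            if op is not None:
                erp = op @ erp  # reconstruct removed channels
            acc[cell] = erp if acc[cell] is None else acc[cell] + erp
            counts[cell] += 1
    out = {}
    for cell in CELLS:
        if counts[cell]:
            out[cell] = acc[cell] / counts[cell]
    return out, times, skipped


def group_backprojection_erp(solution: ClusterSolution, records, group,
                             window=(-1.0, 2.0), baseline=(-0.2, 0.0),
                             channels=None):
    """Grand-average ERP and min/max envelope for a cluster group.

    ``group`` is a group label ("brain", "eye", "neck") or an explicit list of
    cluster ids.  Subjects with no component in the group are skipped and
    reported.  The envelope is the per-timepoint (min, max) across channels.
    """
    clusters = (solution.clusters_in_group(group) if isinstance(group, str)
                else list(group))
    erps, times, skipped = _cluster_cell_erps(solution, records, clusters,
                                              window, baseline, zero_fill=False)
    out = {}
    for cell, erp in erps.items():
        e = erp if channels is None else erp[list(channels)]
        out[cell] = {"erp": e, "envelope": np.stack([e.min(axis=0), e.max(axis=0)]),
                     "times": times}
    return out, {"skipped_subjects": skipped, "clusters": clusters}


def variance_report(solution: ClusterSolution, records,
                    windows=None, baseline=(-0.2, 0.0)) -> pd.DataFrame:
    """Cluster-group variance/pvaf table per stimulus x condition cell.

    Window "envelope" (-0.2..1.0 s): eye / neck / brain group variances and
    pvafs against the total over all non-outlier clusters.  Window "p3"
    (0.4..0.8 s): per-brain-cluster variances and pvafs against the brain-only
    projection.  The outlier cluster is excluded from every total.
    """
    windows = windows or {"envelope": (-0.2, 1.0), "p3": (0.4, 0.8)}
    all_clusters = [c for c in range(solution.k)
                    if np.any(solution.assignment == c)]
    groups = {g: solution.clusters_in_group(g) for g in ("eye", "neck", "brain")}

    per_cluster, times, _ = {}, None, None
    for c in all_clusters:
        per_cluster[c], times, _ = _cluster_cell_erps(
            solution, records, [c], baseline=baseline)

    rows = []
    if "envelope" in windows:
        win = windows["envelope"]
        for stim, cond in CELLS:
            parts = {c: per_cluster[c].get((stim, cond)) for c in all_clusters}
            parts = {c: p for c, p in parts.items() if p is not None}
            if not parts:
                continue
            total = np.sum(np.stack(list(parts.values())), axis=0)
            tv = absolute_variance(total, times, win)
            rows.append({"group": "total", "stimulus": stim, "condition": cond,
                         "window": "envelope", "absolute_variance": tv,
                         "pvaf": 100.0})
            for g, clusters in groups.items():
                proj = [parts[c] for c in clusters if c in parts]
                gsum = (np.sum(np.stack(proj), axis=0) if proj
                        else np.zeros_like(total))
                rows.append({
                    "group": g, "stimulus": stim, "condition": cond,
                    "window": "envelope",
                    "absolute_variance": absolute_variance(gsum, times, win),
                    "pvaf": pvaf(gsum, [gsum, total - gsum], times, win)})
    if "p3" in windows:
        win = windows["p3"]
        brain = groups["brain"]
        for stim, cond in CELLS:
            proj = {c: per_cluster[c].get((stim, cond)) for c in brain}
            proj = {c: p for c, p in proj.items() if p is not None}
            if not proj:
                continue
            btotal = np.sum(np.stack(list(proj.values())), axis=0)
            rows.append({"group": "brain_total", "stimulus": stim,
                         "condition": cond, "window": "p3",
                         "absolute_variance": absolute_variance(btotal, times, win),
                         "pvaf": 100.0})
            for c, p in proj.items():
                rows.append({
                    "group": f"cluster_{c}", "stimulus": stim, "condition": cond,
                    "window": "p3",
                    "absolute_variance": absolute_variance(p, times, win),
                    "pvaf": pvaf(p, [p, btotal - p], times, win)})
    return pd.DataFrame(rows)


def erp_window_stats(amplitude_table: pd.DataFrame):
    """2 (condition) x 3 (stimulus) repeated-measures ANOVA + Tukey HSD.

    ``amplitude_table`` holds one row per subject x condition x stimulus with
    a mean P3-window amplitude.  Greenhouse-Geisser corrected p-values are
    used when Mauchly's test indicates non-sphericity; post-hoc HSD contrasts
    compare all six cells.
    """
    need = {"subject", "condition", "stimulus", "amplitude"}
    if not need <= set(amplitude_table.columns):
        raise ValueError(f"amplitude table must have columns {sorted(need)}")
    counts = amplitude_table.groupby(["subject"]).size()
    if counts.nunique() != 1 or counts.iloc[0] != 6:
        raise ValueError("table must be complete and balanced (6 cells/subject)")

    aov = pg.rm_anova(data=amplitude_table, dv="amplitude",
                      within=["condition", "stimulus"], subject="subject",
                      correction=True, detailed=True, effsize="np2")
    cols = {c.replace("-", "_"): c for c in aov.columns}

    # Mauchly's test on the only multi-level factor gates the GG correction
    stim_means = amplitude_table.groupby(["subject", "stimulus"],
                                         as_index=False)["amplitude"].mean()
    spher = pg.sphericity(stim_means, dv="amplitude", within="stimulus",
                          subject="subject")
    non_spherical = bool(spher.pval < 0.05)

    effects = {}
    for _, row in aov.iterrows():
        name = row["Source"].replace(" * ", "x")
        p = float(row[cols["p_unc"]])
        used_gg = False
        p_gg = row.get(cols.get("p_GG_corr", "p_GG_corr"))
        if float(row["ddof1"]) > 1 and non_spherical and not pd.isna(p_gg):
            p = float(p_gg)
            used_gg = True
        eps = row.get(cols.get("eps", "eps"), 1.0)
        effects[name] = {"F": float(row["F"]), "p": p,
                         "df1": float(row["ddof1"]), "df2": float(row["ddof2"]),
                         "np2": float(row["np2"]), "gg_corrected": used_gg,
                         "eps": 1.0 if pd.isna(eps) else float(eps),
                         "mauchly_p": float(spher.pval)}

    cells = (amplitude_table["stimulus"].astype(str) + "/"
             + amplitude_table["condition"].astype(str))
    hsd = pairwise_tukeyhsd(amplitude_table["amplitude"].to_numpy(float),
                            cells.to_numpy(str))
    hsd_df = pd.DataFrame(hsd.summary().data[1:], columns=hsd.summary().data[0])
    return {"anova": aov, "effects": effects, "hsd": hsd_df}
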