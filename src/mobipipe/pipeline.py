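"""End-to-end orchestration: generate -> motion -> clean -> ICA -> cluster -> quantify.

`run_pipeline` executes the stages in protocol order on a synthetic campaign
(or a stored session), writes per-stage JSON-lines logs and result tables, and
echoes the effective configuration into the output directory so every output
is reproducible from (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, ica, motion, preprocess, quantify
from .core import EventList, StreamSet, read_streamset
from .headmodel import DEFAULT_HEAD
from .synth import SessionConfig, default_sources, generate_session

__all__ = ["PipelineConfig", "run_pipeline", "make_demo_campaign",
           "process_subject"]


@dataclass
class PipelineConfig:
    out_dir: str = "results/pipeline"
    session_dir: str | None = None    # ingest an existing session instead
    synthetic: bool = True
    n_subjects: int = 3
    scale: str = "tiny"               # tiny | small | full
    seed: int = 7
    stages: dict = field(default_factory=lambda: {
        "motion": True, "preprocess": True, "ica": True,
        "cluster": True, "quantify": True})
    # stage parameters (defaults are the protocol values where stated)
    hp_hz: float = 1.0
    lp_hz: float = 120.0
    fs_out: float = 250.0
    flat_span_s: float = 5.0
    corr_thresh: float = 0.6
    window_bad_fraction: float = 0.30
    ica_n_iter: int = 10
    ica_reject_sigma: float = 4.0
    onset_frac: float = 0.05
    peak_frac: float = 0.22
    k_clusters: int = 36
    outlier_sd: float = 3.0
    windows: dict = field(default_factory=lambda: {
        "envelope": [-0.2, 1.0], "p3": [0.4, 0.8]})

    def to_yaml(self, path):
        with open(path, "w") as f:
            yaml.safe_dump(dataclasses.asdict(self), f, sort_keys=True)

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        with open(path) as f:
            return PipelineConfig(**yaml.safe_load(f))


def _jitter_sources(sources, rng):
    """Subject-level random effects: log-normal gain jitter per source."""
    out = []
    for s in sources:
        factor = float(np.exp(rng.normal(0.0, 0.15)))
        k = s.kernel
        if hasattr(k, "amplitude") and isinstance(getattr(k, "amplitude"), dict):
            k = type(k)(k.peak_latency, k.width,
                        {c: a * factor for c, a in k.amplitude.items()},
                        background_rms=k.background_rms,
                        background_band=k.background_band)
        elif hasattr(k, "locked_amplitude"):
            k = type(k)(rate=k.rate, amplitude=k.amplitude * factor,
                        locked_amplitude={c: a * factor
                                          for c, a in k.locked_amplitude.items()},
                        locked_latency=k.locked_latency,
                        locked_width=k.locked_width,
                        pursuit_amplitude=k.pursuit_amplitude)
        elif hasattr(k, "gain"):
            k = type(k)(band=k.band, duration=k.duration,
                        gain={c: g * factor for c, g in k.gain.items()},
                        baseline_gain=k.baseline_gain, latency=k.latency,
                        locked_fraction=k.locked_fraction)
        out.append(replace(s, kernel=k))
    return out


def make_demo_campaign(n_subjects: int = 12, scale: str = "tiny",
                       seed: int = 0, base_cfg: SessionConfig | None = None):
    """Per-subject synthetic sessions with subject-level random effects.

    Subjects vary in RT means (SDs matching the across-participant spread of
    the two response modes) and in source gains; per-subject seeds derive
    deterministically from the master seed.  Yields
    ``(subject_id, StreamSet, GroundTruth)`` lazily to bound memory.
    """
    base = base_cfg or SessionConfig()
    base = base.scaled(scale) if base_cfg is None else base
    master = np.random.default_rng(seed)
    for i in range(n_subjects):
        sub_seed = int(master.integers(0, 2 ** 31 - 1))
        rng = np.random.default_rng(sub_seed)
        rt_mean = {"pointing": max(0.15, rng.normal(0.3831, 0.0407)),
                   "button": max(0.2, rng.normal(0.5158, 0.0529))}
        cfg = replace(base, rt_mean=rt_mean, seed=sub_seed)
        sources = _jitter_sources(default_sources(cfg.head), rng)
        order = ("button", "pointing") if i % 2 == 0 else ("pointing", "button")
        streams, gt = generate_session(cfg, sources=sources, rng_seed=sub_seed,
                                       block_order=order)
        streams.meta["participant"] = f"s{i:02d}"
        yield f"s{i:02d}", streams, gt


def process_subject(streams: StreamSet, cfg: PipelineConfig, seed: int,
                    subject: str = "s0", log=None):
    """Single-subject stages: motion, cleaning, ICA, dipoles, measures."""
    log = log if log is not None else []

    def note(stage, **info):
        log.append({"stage": stage, "subject": subject, **info})

    events = streams.events
    rt_rows = []
    if cfg.stages.get("motion", True):
        finger = next(tr for tr in streams.mocap if tr.led_id == "finger")
        finger = motion.interpolate_occlusions(finger)
        prof = motion.compute_velocity(finger)
        vmax = float(np.max(prof.v))
        pointing = EventList(
            events.df[(events.df["condition"] == "pointing")
                      & events.df["kind"].isin(("standard", "distractor", "target"))]
            .reset_index(drop=True))
        moves = motion.detect_movements(prof, vmax, pointing,
                                        peak_frac=cfg.peak_frac,
                                        onset_frac=cfg.onset_frac)
        events, excl = motion.validate_trial_markers(events, moves)
        note("motion", n_movements=len(moves),
             excluded=len(excl["excluded_trials"]),
             exclusion_by_stimulus=excl["exclusion_fraction_by_stimulus"])
        cc = {int(r["trial_index"]): float(r["onset"])
              for _, r in pointing.color_changes().iterrows()}
        for m in moves:
            if m.trial_index in cc:
                rt_rows.append({"subject": subject, "condition": "pointing",
                                "trial_index": m.trial_index,
                                "rt": m.onset - cc[m.trial_index]})
        bdf = streams.events.df
        bresp = bdf[(bdf["kind"] == "response") & (bdf["condition"] == "button")]
        bcc = bdf[bdf["kind"].isin(("standard", "distractor", "target"))] \
            .set_index("trial_index")
        for _, r in bresp.iterrows():
            ti = int(r["trial_index"])
            rt_rows.append({"subject": subject, "condition": "button",
                            "trial_index": ti,
                            "rt": float(r["onset"]) - float(bcc.loc[ti, "onset"])})

    eeg = streams.eeg
    reports = []
    if cfg.stages.get("preprocess", True):
        eeg = preprocess.filter_and_resample(eeg, cfg.hp_hz, cfg.lp_hz, cfg.fs_out)
        eeg, rep_ch = preprocess.reject_channels(eeg, flat_span=cfg.flat_span_s,
                                                 corr_thresh=cfg.corr_thresh)
        eeg, rep_win = preprocess.reject_time_windows(
            eeg, bad_fraction=cfg.window_bad_fraction)
        events = preprocess.remap_events(events, rep_win.removed_windows, eeg.fs)
        eeg = preprocess.rereference_average(eeg)
        reports = [rep_ch]
        note("preprocess", removed_channels=rep_ch.removed_channels,
             removed_windows=len(rep_win.removed_windows),
             retained_channels=rep_ch.retained_channel_count)
    else:
        warnings.warn("preprocessing disabled; decomposing raw data")
        note("preprocess", skipped=True)

    result = {"subject": subject, "eeg": eeg, "events": events,
              "rt_rows": rt_rows, "cleaning_reports": reports, "log": log}
    if not cfg.stages.get("ica", True):
        return result

    decomp = ica.fit_ica(eeg, n_iter=cfg.ica_n_iter,
                         reject_sigma=cfg.ica_reject_sigma, seed=seed)
    note("ica", n_components=decomp.n_components,
         rejected_windows=len(decomp.rejected_spans),
         rank_reduction=decomp.n_reduced)

    from .dipoles import fit_dipole
    dips = [fit_dipole(decomp.mixing[:, i], eeg.montage)
            for i in range(decomp.n_components)]
    inside = [i for i, d in enumerate(dips) if d.inside_head]
    note("dipoles", n_inside=len(inside), n_total=len(dips))

    measures = clustering.compute_component_measures(
        decomp, events, subject=subject, montage=eeg.montage,
        dipoles=dips, full_montage=streams.eeg.montage)
    result.update({"decomp": decomp, "dipoles": dips,
                   "inside_ics": inside, "measures": measures})
    return result


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute the full pipeline and write tables under ``cfg.out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config_echo.yaml")
    log = []

    if cfg.synthetic:
        campaign = make_demo_campaign(cfg.n_subjects, cfg.scale, cfg.seed)
        sessions = ((sid, streams) for sid, streams, _ in campaign)
    elif cfg.session_dir:
        sessions = iter([("s00", read_streamset(cfg.session_dir))])
    else:
        raise ValueError("need synthetic=True or a session_dir")

    master = np.random.default_rng(cfg.seed)
    subjects, rt_rows, reports = [], [], []
    try:
        for sid, streams in sessions:
            sub_seed = int(master.integers(0, 2 ** 31 - 1))
            res = process_subject(streams, cfg, sub_seed, subject=sid, log=log)
            rt_rows.extend(res["rt_rows"])
            reports.extend(res["cleaning_reports"])
            if "decomp" in res:
                subjects.append(res)
    except Exception as err:
        (out / "log.jsonl").write_text(
            "\n".join(json.dumps(e, default=str) for e in log) + "\n")
        raise RuntimeError(f"pipeline stage failed: {err}") from err

    rt = pd.DataFrame(rt_rows)
    if len(rt):
        rt.to_csv(out / "rt_table.csv", index=False)
        means = rt.groupby(["subject", "condition"], as_index=False)["rt"].mean()
        means = means.rename(columns={"rt": "rt"})
        if means.groupby("condition").size().min() >= 2:
            stats = motion.response_time_stats(
                means.rename(columns={"subject": "participant"}))
            with open(out / "rt_stats.json", "w") as f:
                json.dump({"F": stats["F"], "p": stats["p"],
                           "hsd": stats["hsd"].to_dict(orient="records")},
                          f, indent=2, default=str)

    if reports:
        retention = preprocess.channel_retention_map(
            reports, reports[0].original_montage)
        retention.to_csv(out / "channel_retention.csv", index=False)

    if subjects and cfg.stages.get("cluster", True):
        measures, subj_of, ic_of, dips = [], [], [], []
        for res in subjects:
            for i in res["inside_ics"]:
                measures.append(res["measures"][i])
                subj_of.append(res["subject"])
                ic_of.append(i)
                dips.append(res["dipoles"][i].position)
        k = min(cfg.k_clusters, max(2, len(measures) - 1))
        vectors = clustering.build_feature_vectors(measures)
        solution = clustering.cluster_components(
            vectors, k=k, outlier_sd=cfg.outlier_sd, seed=cfg.seed,
            subjects=subj_of, dipole_positions=np.asarray(dips),
            ic_indices=ic_of)
        solution = clustering.label_cluster_group(solution, DEFAULT_HEAD)
        log.append({"stage": "cluster", "k": k,
                    "n_outliers": int(np.sum(solution.assignment == -1)),
                    "groups": {str(c): g for c, g in solution.group_label.items()}})
        solution.ic_table.assign(
            group=[solution.group_label.get(c, "outlier")
                   for c in solution.assignment]).to_csv(
            out / "cluster_assignments.csv", index=False)

        if cfg.stages.get("quantify", True):
            records = [quantify.SubjectRecord(
                res["subject"], res["decomp"], res["events"],
                res["eeg"].montage,
                full_montage=(res["cleaning_reports"][0].original_montage
                              if res["cleaning_reports"] else None))
                for res in subjects]
            windows = {name: tuple(w) for name, w in cfg.windows.items()}
            report = quantify.variance_report(solution, records, windows=windows)
            report.to_csv(out / "variance_report.csv", index=False)

            amp_rows = []
            brain = solution.clusters_in_group("brain")
            for rec in records:
                tbl = solution.ic_table
                ics = tbl[(tbl["subject"] == rec.subject)
                          & tbl["cluster"].isin(brain)]["ic_index"].tolist()
                sig = ica.backproject(rec.decomp, ics)
                eps = quantify.epoch_data(sig, rec.events, fs=rec.decomp.fs,
                                          subject=rec.subject)
                ch = rec.montage.index_of(quantify.pz_prime(rec.montage))
                w = windows.get("p3", (0.4, 0.8))
                tmask = (eps.times >= w[0]) & (eps.times <= w[1])
                for stim, cond in quantify.CELLS:
                    sel = eps.select(stimulus=stim, condition=cond)
                    if sel.data.shape[0] == 0:
                        continue
                    amp_rows.append({"subject": rec.subject, "condition": cond,
                                     "stimulus": stim,
                                     "amplitude": float(
                                         sel.erp()[ch, tmask].mean())})
            amp = pd.DataFrame(amp_rows)
            amp.to_csv(out / "pz_prime_amplitudes.csv", index=False)
            if len(amp) and amp.groupby("subject").size().eq(6).all() \
                    and amp["subject"].nunique() >= 3:
                stats = quantify.erp_window_stats(amp)
                with open(out / "erp_stats.json", "w") as f:
                    json.dump({"effects": stats["effects"],
                               "hsd": stats["hsd"].to_dict(orient="records")},
                              f, indent=2, default=str)

    with open(out / "log.jsonl", "w") as f:
        for entry in log:
            f.write(json.dumps(entry, default=str) + "\n")
    return out
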