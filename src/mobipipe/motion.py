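"""Kinematic pipeline: occlusion repair, velocity profiles, movement onsets.

Pointing responses are detected from the screen-normal velocity of the finger
LED: occluded samples are spline-interpolated, position is low-passed with a
zero-phase 6 Hz FIR filter and differentiated, velocity peaks of at least 22%
of the participant's maximum finger velocity inside a 200-1800 ms
post-stimulus window are taken as movements, and the movement onset is the
latest crossing of 5% of the subsequent peak velocity before the peak.  The
onset lag to the color change is the pointing response time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.interpolate import CubicSpline
from scipy.stats import f_oneway
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .core import COLOR_CHANGE_KINDS, EventList, MocapTrack

__all__ = [
    "VelocityProfile", "MovementEvent", "interpolate_occlusions",
    "compute_velocity", "detect_movements", "movement_onset",
    "sweep_onset_threshold", "validate_trial_markers", "response_time_stats",
]


@dataclass
class VelocityProfile:
    """Signed speed along the screen-normal axis, + toward the screen."""
    t: np.ndarray
    v: np.ndarray
    source_led: str = ""

    def __post_init__(self):
        self.t = np.asarray(self.t, float)
        self.v = np.asarray(self.v, float)
        if len(self.t) != len(self.v):
            raise ValueError("t and v must have equal length")


@dataclass
class MovementEvent:
    onset: float
    peak_time: float
    offset: float
    peak_velocity: float
    trial_index: int

    def __post_init__(self):
        if not (self.onset < self.peak_time < self.offset):
            raise ValueError("movement must satisfy onset < peak < offset")
        if self.peak_velocity <= 0:
            raise ValueError("peak velocity must be positive")


def interpolate_occlusions(track: MocapTrack) -> MocapTrack:
    """Replace reliability-0 samples by per-axis cubic-spline interpolation."""
    good = track.reliability > 0
    if good.sum() < 4:
        raise ValueError("need at least 4 reliable samples for spline repair")
    if good.all():
        return MocapTrack(track.led_id, track.t.copy(), track.xyz.copy(),
                          track.reliability.copy(), fs=track.fs)
    xyz = track.xyz.copy()
    spline = CubicSpline(track.t[good], track.xyz[good], axis=0)
    xyz[~good] = spline(track.t[~good])
    return MocapTrack(track.led_id, track.t.copy(), xyz,
                      track.reliability.copy(), fs=track.fs)


def _lowpass_taps(fs: float, cutoff: float, stop: float, atten_db: float = 65.0):
    width = 2 * (stop - cutoff)  # transition band centered on the edge midpoint
    numtaps, beta = sps.kaiserord(atten_db, width / (fs / 2))
    numtaps |= 1  # odd length -> exactly linear phase type I
    return sps.firwin(numtaps, (cutoff + stop) / 2, window=("kaiser", beta), fs=fs)


def compute_velocity(track: MocapTrack, cutoff: float = 6.0,
                     axis=(1.0, 0.0, 0.0)) -> VelocityProfile:
    """Zero-phase low-passed, central-difference velocity along ``axis``.

    ``axis`` is the screen normal (+x toward the screen); the FIR filter is
    designed for >= 60 dB stopband attenuation at twice the cutoff and applied
    forward-backward, so the net passband phase is zero.
    """
    if not np.all(np.isfinite(track.xyz)):
        raise ValueError("repair occlusions before computing velocity")
    taps = _lowpass_taps(track.fs, cutoff, 2 * cutoff)
    if track.xyz.shape[0] <= 3 * len(taps):
        raise ValueError(
            f"track too short for zero-phase filtering ({track.xyz.shape[0]} "
            f"samples, filter length {len(taps)})")
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    pos = track.xyz @ axis
    from .preprocess import zero_phase_fir
    smooth = zero_phase_fir(pos, taps)
    v = np.empty_like(smooth)
    v[1:-1] = (smooth[2:] - smooth[:-2]) / (track.t[2:] - track.t[:-2])
    v[0] = v[1]
    v[-1] = v[-2]
    return VelocityProfile(track.t.copy(), v, source_led=track.led_id)


def _interp_crossing(t0, v0, t1, v1, level):
    if v1 == v0:
        return t0
    return t0 + (level - v0) * (t1 - t0) / (v1 - v0)


def movement_onset(profile: VelocityProfile, peak_time: float,
                   frac: float = 0.05) -> float:
    """Latest upward crossing of ``frac`` * peak velocity before the peak."""
    if not 0 < frac < 1:
        raise ValueError("frac must be in (0, 1)")
    ip = int(np.searchsorted(profile.t, peak_time))
    ip = min(max(ip, 0), len(profile.t) - 1)
    if ip > 0 and abs(profile.t[ip - 1] - peak_time) < abs(profile.t[ip] - peak_time):
        ip -= 1
    level = frac * profile.v[ip]
    v, t = profile.v, profile.t
    for i in range(ip - 1, -1, -1):
        if v[i] < level <= v[i + 1]:
            return _interp_crossing(t[i], v[i], t[i + 1], v[i + 1], level)
    raise ValueError("no sub-threshold crossing found before peak "
                     "(trial flagged for exclusion)")


def _movement_offset(profile: VelocityProfile, ip: int, frac: float = 0.05) -> float:
    level = frac * profile.v[ip]
    v, t = profile.v, profile.t
    for i in range(ip, len(v) - 1):
        if v[i] >= level > v[i + 1]:
            return _interp_crossing(t[i], v[i], t[i + 1], v[i + 1], level)
    raise ValueError("no sub-threshold crossing found after peak")


def detect_movements(profile: VelocityProfile, vmax_participant: float,
                     events: EventList, window=(0.2, 1.8),
                     peak_frac: float = 0.22, onset_frac: float = 0.05) -> list:
    """At most one movement per color change: the largest qualifying peak.

    Candidate peaks are local maxima inside ``[onset + 0.2 s, onset + 1.8 s]``
    with velocity >= ``peak_frac`` of the participant's maximum finger
    velocity; onset and offset bracket the peak at ``onset_frac`` of the peak
    velocity.  Trials whose onset/offset search fails yield no event.
    """
    v, t = profile.v, profile.t
    peaks, _ = sps.find_peaks(v)
    out = []
    for _, ev in events.color_changes().iterrows():
        lo, hi = ev["onset"] + window[0], ev["onset"] + window[1]
        sel = peaks[(t[peaks] >= lo) & (t[peaks] <= hi)]
        sel = sel[v[sel] >= peak_frac * vmax_participant]
        if sel.size == 0:
            continue
        ip = int(sel[np.argmax(v[sel])])
        try:
            onset = movement_onset(profile, t[ip], onset_frac)
            offset = _movement_offset(profile, ip, onset_frac)
        except ValueError:
            continue
        out.append(MovementEvent(onset=onset, peak_time=float(t[ip]),
                                 offset=offset, peak_velocity=float(v[ip]),
                                 trial_index=int(ev["trial_index"])))
    return out


def sweep_onset_threshold(profile: VelocityProfile, movements,
                          events: EventList,
                          fracs=None) -> pd.DataFrame:
    """Per-trial RT for a range of onset threshold fractions.

    RT(frac) = onset(frac) - color-change time.  Mean RT is non-decreasing in
    frac because a higher threshold is crossed later on the rising flank.
    """
    if fracs is None:
        fracs = np.round(np.arange(0.05, 0.5301, 0.01), 4)
    cc = {int(r["trial_index"]): float(r["onset"])
          for _, r in events.color_changes().iterrows()}
    rows = []
    for frac in fracs:
        for m in movements:
            if m.trial_index not in cc:
                continue
            try:
                onset = movement_onset(profile, m.peak_time, float(frac))
            except ValueError:
                continue
            rows.append({"frac": float(frac), "trial_index": m.trial_index,
                         "rt": onset - cc[m.trial_index]})
    return pd.DataFrame(rows, columns=["frac", "trial_index", "rt"])


def validate_trial_markers(events: EventList, movements,
                           tolerance: float = 0.5):
    """Drop trials whose protocol markers and detected movements disagree.

    A trial is excluded when (a) a protocol hot-zone/response marker has no
    detected movement overlapping ``[marker - tolerance, marker + tolerance]``
    (response markers sit at the true movement onset, which the 5%-criterion
    onset trails by a known bias, so the window is symmetric), or (b) a
    detected movement on a target trial has no marker within ``tolerance`` of
    the movement offset.  The +-0.5 s tolerance spans a full pointing movement.
    """
    df = events.df
    by_trial = {}
    for m in movements:
        by_trial.setdefault(m.trial_index, []).append(m)

    markers = df[(df["kind"].isin(["hot_zone", "response"]))
                 & (df["source"] == "protocol")
                 & (df["condition"] == "pointing")]
    excluded = set()
    reasons = {}
    for _, mk in markers.iterrows():
        ti = int(mk["trial_index"])
        tm = float(mk["onset"])
        ok = any(m.onset <= tm + tolerance and m.offset >= tm - tolerance
                 for m in by_trial.get(ti, []))
        if not ok:
            excluded.add(ti)
            reasons[ti] = "marker_without_movement"

    target_trials = set(df[(df["kind"] == "target")
                           & (df["condition"] == "pointing")]["trial_index"])
    marker_times = markers.groupby("trial_index")["onset"].apply(list).to_dict()
    for ti, ms in by_trial.items():
        if ti not in target_trials or ti in excluded:
            continue
        for m in ms:
            near = any(abs(tm - m.offset) <= tolerance
                       for tm in marker_times.get(ti, []))
            if not near:
                excluded.add(ti)
                reasons[ti] = "movement_without_marker"
                break

    stim_of = {int(r["trial_index"]): r["kind"]
               for _, r in df[df["kind"].isin(COLOR_CHANGE_KINDS)].iterrows()}
    pointing_trials = set(df[df["condition"] == "pointing"]["trial_index"])
    frac = {}
    for stim in COLOR_CHANGE_KINDS:
        trials = [ti for ti in pointing_trials if stim_of.get(ti) == stim]
        if trials:
            frac[stim] = sum(ti in excluded for ti in trials) / len(trials)
        else:
            frac[stim] = 0.0
    report = {
        "excluded_trials": sorted(excluded),
        "reasons": reasons,
        "exclusion_fraction_by_stimulus": frac,
        "tolerance_s": tolerance,
    }
    retained = EventList(df[~df["trial_index"].isin(excluded)].reset_index(drop=True))
    return retained, report


def response_time_stats(rt_table: pd.DataFrame):
    """One-way ANOVA across response conditions + Tukey HSD contrasts.

    ``rt_table`` holds one row per participant x condition with columns
    ``participant``, ``condition``, ``rt`` (condition-mean RT in seconds).
    """
    groups = [g["rt"].to_numpy(float) for _, g in rt_table.groupby("condition")]
    if len(groups) < 2:
        raise ValueError("need at least two conditions for ANOVA")
    if min(len(g) for g in groups) < 2:
        raise ValueError("need at least two participants per condition")
    F, p = f_oneway(*groups)
    hsd = pairwise_tukeyhsd(rt_table["rt"].to_numpy(float),
                            rt_table["condition"].to_numpy(str))
    hsd_df = pd.DataFrame(hsd.summary().data[1:],
                          columns=hsd.summary().data[0])
    return {"F": float(F), "p": float(p), "hsd": hsd_df}
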