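"""Kinematic pipeline: repair, velocity, movement detection, onsets, RT stats."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from mobipipe.core import EventList, MocapTrack
from mobipipe.motion import (MovementEvent, VelocityProfile, compute_velocity,
                             detect_movements, interpolate_occlusions,
                             movement_onset, response_time_stats,
                             sweep_onset_threshold, validate_trial_markers)
from mobipipe.synth import (SessionConfig, generate_oddball_events,
                            generate_pointing_tracks, generate_session,
                            minimum_jerk_velocity)

FS = 480.0


def _track(xyz, rel=None):
    n = xyz.shape[0]
    t = np.arange(n) / FS
    return MocapTrack("finger", t, xyz,
                      np.ones(n) if rel is None else rel, fs=FS)


# --- occlusion repair -------------------------------------------------------

def test_interpolation_identity_without_occlusions(rng):
    tr = _track(rng.normal(size=(100, 3)))
    out = interpolate_occlusions(tr)
    np.testing.assert_array_equal(out.xyz, tr.xyz)


def test_spline_recovers_linear_gap():
    n = 500
    t = np.arange(n) / FS
    xyz = np.stack([2 * t, -t, 0.5 * t], axis=1)
    rel = np.ones(n)
    rel[200:250] = 0
    masked = xyz.copy()
    masked[200:250] = np.nan
    out = interpolate_occlusions(_track(masked, rel))
    np.testing.assert_allclose(out.xyz[200:250], xyz[200:250], atol=1e-9)


def test_spline_recovers_cubic_gap():
    n = 600
    t = np.arange(n) / FS
    xyz = np.stack([t ** 3 - t, 0.2 * t ** 2, t ** 3], axis=1)
    rel = np.ones(n)
    rel[300:340] = 0
    out = interpolate_occlusions(_track(xyz, rel))
    np.testing.assert_allclose(out.xyz[300:340], xyz[300:340], atol=1e-6)


def test_all_unreliable_track_rejected():
    with pytest.raises(ValueError, match="reliable"):
        interpolate_occlusions(_track(np.zeros((50, 3)), np.zeros(50)))


# --- velocity ---------------------------------------------------------------

def test_velocity_of_constant_position_is_zero():
    xyz = np.tile([0.2, 0.1, -0.3], (4000, 1))
    v = compute_velocity(_track(xyz)).v
    assert np.max(np.abs(v)) < 1e-12


def test_passband_sinusoid_velocity_amplitude():
    n = 4800
    t = np.arange(n) / FS
    A, f = 0.05, 2.0
    xyz = np.zeros((n, 3))
    xyz[:, 0] = A * np.sin(2 * np.pi * f * t)
    v = compute_velocity(_track(xyz)).v
    core = v[1000:-1000]
    assert np.max(np.abs(core)) == pytest.approx(2 * np.pi * f * A, rel=0.02)


def test_stopband_sinusoid_attenuated_60db():
    n = 4800
    t = np.arange(n) / FS
    A, f = 0.05, 30.0
    xyz = np.zeros((n, 3))
    xyz[:, 0] = A * np.sin(2 * np.pi * f * t)
    v = compute_velocity(_track(xyz)).v
    core = np.max(np.abs(v[1000:-1000]))
    assert core < (2 * np.pi * f * A) * 10 ** (-60 / 20)


def test_short_track_rejected():
    with pytest.raises(ValueError, match="too short"):
        compute_velocity(_track(np.zeros((100, 3))))


# --- movement detection and onsets ------------------------------------------

def _pulse_profile(t0=1.0, T=0.4, vpeak=1.0, total=3.0):
    t = np.arange(int(total * FS)) / FS
    v = minimum_jerk_velocity(T, vpeak * T / 1.875, np.clip(t - t0, 0, T))
    v[(t < t0) | (t > t0 + T)] = 0.0
    return VelocityProfile(t, v)


def _one_trial_events(cc=1.0):
    return EventList.from_rows([
        (cc - 0.5, "trial_start", "pointing", 0, "protocol"),
        (cc, "target", "pointing", 0, "protocol"),
    ])


def test_zero_profile_yields_no_movements():
    prof = VelocityProfile(np.arange(1000) / FS, np.zeros(1000))
    assert detect_movements(prof, 1.0, _one_trial_events()) == []


def test_single_pulse_peak_time_within_one_sample():
    prof = _pulse_profile(t0=1.3, T=0.4)
    out = detect_movements(prof, 1.0, _one_trial_events(cc=1.0))
    assert len(out) == 1
    assert abs(out[0].peak_time - 1.5) <= 1.0 / FS
    assert out[0].onset < out[0].peak_time < out[0].offset


def test_peak_threshold_boundary():
    lo = _pulse_profile(t0=1.3, vpeak=0.20)
    hi = _pulse_profile(t0=1.3, vpeak=0.23)
    assert detect_movements(lo, 1.0, _one_trial_events()) == []
    assert len(detect_movements(hi, 1.0, _one_trial_events())) == 1


def test_triangular_onset_geometry():
    # linear rise 0 -> 1 m/s over [0.3, 0.5]: 5% crossed at 0.31, 50% at 0.40
    t = np.arange(0, 0.8, 1 / FS)
    v = np.clip((t - 0.3) / 0.2, 0, None)
    v[t > 0.5] = np.clip(1 - (t[t > 0.5] - 0.5) / 0.2, 0, None)
    prof = VelocityProfile(t, v)
    peak = t[np.argmax(v)]
    assert movement_onset(prof, peak, 0.05) == pytest.approx(0.31, abs=1.5 / FS)
    assert movement_onset(prof, peak, 0.50) == pytest.approx(0.40, abs=1.5 / FS)


def test_min_jerk_onset_criterion_bias():
    T = 0.4
    prof = _pulse_profile(t0=1.0, T=T)
    out = detect_movements(prof, 1.0, _one_trial_events(cc=0.9))
    assert abs(out[0].onset - (1.0 + 0.0594 * T)) <= 1.0 / FS + 1e-9


def test_onset_error_without_crossing():
    t = np.arange(0, 1, 1 / FS)
    prof = VelocityProfile(t, np.ones_like(t))  # never below threshold
    with pytest.raises(ValueError, match="crossing"):
        movement_onset(prof, 0.5, 0.05)


def test_sweep_rt_affine_and_monotone():
    prof_t = np.arange(0, 0.9, 1 / FS)
    v = np.clip((prof_t - 0.3) / 0.2, 0, None)
    v[prof_t > 0.5] = np.clip(1 - (prof_t[prof_t > 0.5] - 0.5) / 0.2, 0, None)
    prof = VelocityProfile(prof_t, v)
    ev = _one_trial_events(cc=0.1)
    m = detect_movements(prof, 1.0, ev)
    fracs = np.arange(0.05, 0.531, 0.01)
    tbl = sweep_onset_threshold(prof, m, ev, fracs=fracs)
    rts = tbl.sort_values("frac")["rt"].to_numpy()
    assert np.all(np.diff(rts) >= -1e-12)
    # linear rise -> RT(frac) affine: second differences vanish
    assert np.max(np.abs(np.diff(rts, 2))) < 1e-6
    one = sweep_onset_threshold(prof, m, ev, fracs=[0.05])
    assert len(one) == 1


def test_marker_validation_consistent_session_keeps_everything():
    cfg = replace(SessionConfig().scaled("tiny"), occlusion_rate=0.0)
    ev = generate_oddball_events(cfg, "pointing", 5)
    tracks, hot = generate_pointing_tracks(ev, cfg, 5)
    events = EventList.concat([ev, hot])
    finger = interpolate_occlusions(tracks[0])
    prof = compute_velocity(finger)
    moves = detect_movements(prof, float(prof.v.max()), events)
    retained, report = validate_trial_markers(events, moves)
    assert report["excluded_trials"] == []


def test_marker_on_motionless_trial_excluded():
    cfg = replace(SessionConfig().scaled("tiny"), occlusion_rate=0.0)
    ev = generate_oddball_events(cfg, "pointing", 5)
    tracks, hot = generate_pointing_tracks(ev, cfg, 5)
    df = ev.df
    victim = int(df[df["kind"] == "standard"]["trial_index"].iloc[0])
    cc = float(df[(df["trial_index"] == victim)
                  & (df["kind"] == "standard")]["onset"].iloc[0])
    fake = EventList.from_rows([(cc + 0.8, "hot_zone", "pointing", victim,
                                 "protocol")])
    events = EventList.concat([ev, hot, fake])
    finger = interpolate_occlusions(tracks[0])
    prof = compute_velocity(finger)
    moves = detect_movements(prof, float(prof.v.max()), events)
    _, report = validate_trial_markers(events, moves)
    assert victim in report["excluded_trials"]
    assert report["reasons"][victim] == "marker_without_movement"


def test_spurious_markers_concentrate_exclusions_on_nontargets():
    cfg = replace(SessionConfig().scaled("small"), occlusion_rate=0.0,
                  spurious_marker_rate=0.4)
    ev = generate_oddball_events(cfg, "pointing", 13)
    tracks, hot = generate_pointing_tracks(ev, cfg, 13)
    events = EventList.concat([ev, hot])
    prof = compute_velocity(interpolate_occlusions(tracks[0]))
    moves = detect_movements(prof, float(prof.v.max()), events)
    _, report = validate_trial_markers(events, moves)
    frac = report["exclusion_fraction_by_stimulus"]
    assert frac["standard"] > frac["target"]
    assert frac["distractor"] > frac["target"]


def test_anova_textbook_values():
    tbl = pd.DataFrame({
        "participant": list("abc") * 2,
        "condition": ["x"] * 3 + ["y"] * 3,
        "rt": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
    })
    out = response_time_stats(tbl)
    assert out["F"] == pytest.approx(13.5, abs=1e-9)
    assert len(out["hsd"]) == 1


def test_anova_requires_two_groups():
    tbl = pd.DataFrame({"participant": ["a", "b"], "condition": ["x", "x"],
                        "rt": [1.0, 2.0]})
    with pytest.raises(ValueError, match="two conditions"):
        response_time_stats(tbl)


def test_movement_event_invariants():
    with pytest.raises(ValueError):
        MovementEvent(onset=1.0, peak_time=0.5, offset=2.0,
                      peak_velocity=1.0, trial_index=0)
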