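"""Automated EEG cleaning rules and referencing."""

import numpy as np
import pytest

from mobipipe.core import EEGRecording, EventList, make_standard_montage
from mobipipe.headmodel import DEFAULT_HEAD, dipole_potential
from mobipipe.preprocess import (channel_retention_map, filter_and_resample,
                                 interpolate_channels, reject_channels,
                                 reject_time_windows, remap_events,
                                 rereference_average)

FS = 500.0


def _rec(data, fs=FS):
    n_ch = data.shape[0]
    mont = make_standard_montage(n_ch - n_ch // 4, n_ch // 4)
    return EEGRecording(data, fs, mont)


def _smooth_background(rng, n_ch, n_s, mont=None):
    """Spatially smooth correlated background: deep random dipoles."""
    mont = mont or make_standard_montage(n_ch - n_ch // 4, n_ch // 4)
    head = DEFAULT_HEAD
    k = 40
    pos = rng.normal(size=(k, 3))
    pos = pos / np.linalg.norm(pos, axis=1)[:, None] * 0.4 * head.radius
    M = np.stack([dipole_potential(p, rng.normal(size=3), mont.positions, head)
                  for p in pos], axis=1)
    M /= np.linalg.norm(M, axis=0)
    S = rng.normal(size=(k, n_s))
    # low-pass-ish temporal structure
    S = np.cumsum(S, axis=1) - np.cumsum(S, axis=1).mean(axis=1, keepdims=True)
    X = M @ S
    return EEGRecording(5 * X / X.std(), FS, mont)


# --- filtering / resampling --------------------------------------------------

def test_highpass_removes_dc(rng):
    data = np.full((3, 5000), 42.0) + 0.0
    out = filter_and_resample(_rec(data))
    core = out.data[:, 200:-200]
    assert np.abs(core.mean()) < 1e-3


def test_passband_sinusoid_preserved(rng):
    t = np.arange(10000) / FS
    data = np.tile(np.sin(2 * np.pi * 10 * t), (2, 1))
    out = filter_and_resample(_rec(data))
    core = out.data[0, 500:-500]
    assert np.max(np.abs(core)) == pytest.approx(1.0, rel=0.02)
    assert out.fs == 250.0
    assert abs(out.n_samples - 5000) <= 1


def test_stopband_sinusoid_attenuated(rng):
    t = np.arange(10000) / FS
    data = np.tile(np.sin(2 * np.pi * 200 * t), (2, 1))
    out = filter_and_resample(_rec(data))
    assert np.max(np.abs(out.data[0, 500:-500])) < 10 ** (-40 / 20)


def test_bad_filter_edges_rejected(rng):
    with pytest.raises(ValueError, match="below"):
        filter_and_resample(_rec(np.zeros((2, 1000))), hp=130.0, lp=120.0)


# --- channel rejection -------------------------------------------------------

def test_clean_background_keeps_all_channels(rng):
    eeg = _smooth_background(rng, 40, int(40 * FS))
    out, rep = reject_channels(eeg)
    assert rep.removed_channels == []
    assert out.n_channels == 40


def test_flat_channel_removed(rng):
    eeg = _smooth_background(rng, 40, int(40 * FS))
    eeg.data[7, 1000:1000 + int(6 * FS)] = eeg.data[7, 1000]  # flat 6 s
    out, rep = reject_channels(eeg)
    lab = eeg.montage.labels[7]
    assert rep.removal_reason[lab] == "flat"
    assert lab not in out.montage.labels


def test_decorrelated_channel_removed_with_bruteforce_oracle(rng):
    eeg = _smooth_background(rng, 40, int(40 * FS))
    noise = rng.normal(size=eeg.n_samples) * eeg.data.std()
    eeg.data[12] = noise
    # independent oracle: direct full-length Pearson correlation with the
    # 4 nearest electrodes must fall below threshold
    d = np.linalg.norm(eeg.montage.positions - eeg.montage.positions[12], axis=1)
    nb = np.argsort(d)[1:5]
    cors = [np.corrcoef(eeg.data[12], eeg.data[j])[0, 1] for j in nb]
    assert np.median(cors) < 0.6
    out, rep = reject_channels(eeg)
    assert rep.removal_reason[eeg.montage.labels[12]] == "low_corr"


def test_channel_rejection_idempotent(rng):
    eeg = _smooth_background(rng, 40, int(40 * FS))
    eeg.data[7, 1000:1000 + int(6 * FS)] = 0.0
    once, _ = reject_channels(eeg)
    twice, rep2 = reject_channels(once)
    assert rep2.removed_channels == []


# --- window rejection --------------------------------------------------------

def test_clean_data_no_windows_removed(rng):
    eeg = _smooth_background(rng, 30, int(20 * FS))
    _, rep = reject_time_windows(eeg)
    assert rep.removed_windows == []


def test_broadband_burst_window_excised(rng):
    eeg = _smooth_background(rng, 30, int(20 * FS))
    s0 = int(7 * FS)
    n_noisy = 13  # > 30% of 30 channels
    eeg.data[:n_noisy, s0:s0 + int(FS)] += 200 * rng.normal(
        size=(n_noisy, int(FS)))
    out, rep = reject_time_windows(eeg)
    assert any(a <= s0 < b for a, b in rep.removed_windows)
    assert out.n_samples == eeg.n_samples - sum(b - a for a, b
                                                in rep.removed_windows)


def test_small_burst_retained(rng):
    eeg = _smooth_background(rng, 30, int(20 * FS))
    s0 = int(7 * FS)
    eeg.data[:3, s0:s0 + int(FS)] += 200 * rng.normal(size=(3, int(FS)))  # 10%
    _, rep = reject_time_windows(eeg)
    assert rep.removed_windows == []


def test_event_remapping_preserves_waveform_neighborhood(rng):
    eeg = _smooth_background(rng, 30, int(20 * FS))
    # impulse at a known time after one excised window
    t_ev = 12.35
    i_ev = int(t_ev * FS)
    eeg.data[0, i_ev] += 500.0
    s0 = int(5 * FS)
    eeg.data[:20, s0:s0 + int(FS)] += 300 * rng.normal(size=(20, int(FS)))
    out, rep = reject_time_windows(eeg)
    ev = EventList.from_rows([(t_ev, "target", "button", 0, "protocol"),
                              (5.5, "standard", "button", 1, "protocol")])
    remapped = remap_events(ev, rep.removed_windows, eeg.fs)
    # the event inside the excised span is gone
    assert len(remapped) == 1
    i_new = int(round(remapped.df["onset"].iloc[0] * eeg.fs))
    assert out.data[0, i_new] == eeg.data[0, i_ev]


# --- referencing / interpolation --------------------------------------------

def test_average_reference_zero_sum(rng):
    eeg = _rec(rng.normal(size=(8, 1000)))
    out = rereference_average(eeg)
    assert np.max(np.abs(out.data.sum(axis=0))) < 1e-9
    assert out.reference == "average"


def test_average_reference_of_balanced_pair_unchanged():
    mont = make_standard_montage(1, 1)
    data = np.vstack([np.ones(100), -np.ones(100)])
    out = rereference_average(EEGRecording(data, FS, mont))
    np.testing.assert_allclose(out.data, data, atol=1e-15)


def test_spherical_spline_reconstructs_dipolar_topography(rng):
    head = DEFAULT_HEAD
    mont = make_standard_montage(48, 12, head.radius)
    v = dipole_potential(np.array([0.2, 0.1, 0.4]) * head.radius,
                         np.array([0.0, 0.3, 1.0]), mont.positions, head)
    data = np.outer(v, np.sin(np.arange(500) / 10.0))
    eeg = EEGRecording(data, FS, mont)
    victim = 20
    _, rep = reject_channels(eeg)  # no removals; craft report manually
    rep.removed_channels = [mont.labels[victim]]
    rep.original_montage = mont
    keep = [i for i in range(len(mont)) if i != victim]
    reduced = EEGRecording(data[keep], FS, mont.subset(keep))
    recon = interpolate_channels(reduced, rep)
    r = np.corrcoef(recon.data[victim], data[victim])[0, 1]
    assert r > 0.95
    # untouched channels pass through exactly
    np.testing.assert_allclose(recon.data[keep], data[keep], atol=1e-12)


def test_interpolation_without_removals_is_identity(rng):
    eeg = _rec(rng.normal(size=(12, 300)))
    _, rep = reject_time_windows(eeg)
    rep.removed_channels = []
    out = interpolate_channels(eeg, rep)
    np.testing.assert_array_equal(out.data, eeg.data)


def test_campaign_with_noisy_neck_band_has_lowest_neck_retention(rng):
    """Sessions with elevated neck-electrode noise lose neck channels most
    often, so the retention map ranks neck electrodes lowest."""
    mont = make_standard_montage(30, 10)
    reports = []
    for k in range(6):
        eeg = _smooth_background(np.random.default_rng(k), 40, int(30 * FS),
                                 mont=mont)
        neck = [i for i, g in enumerate(mont.group) if g == "neck"]
        victims = np.random.default_rng(100 + k).choice(neck, size=4,
                                                        replace=False)
        eeg.data[victims] = 3 * eeg.data.std() * np.random.default_rng(
            200 + k).normal(size=(len(victims), eeg.n_samples))
        _, rep = reject_channels(eeg)
        reports.append(rep)
    table = channel_retention_map(reports, mont)
    mean_neck = table[table["group"] == "neck"]["retention"].mean()
    mean_scalp = table[table["group"] == "scalp"]["retention"].mean()
    assert mean_neck < mean_scalp


def test_retention_map_counting(rng):
    mont = make_standard_montage(6, 2)
    reps = []
    for k in range(10):
        _, rep = reject_time_windows(_rec(np.ones((8, 100)) * 0.0 + 1.0))
        rep.removed_channels = [mont.labels[0]] if k < 4 else []
        reps.append(rep)
    table = channel_retention_map(reps, mont)
    assert table.loc[0, "retention"] == pytest.approx(0.6)
    assert np.all(table["retention"].iloc[1:] == 1.0)
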