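"""EEG cleaning: filtering, resampling, channel/window rejection, referencing.

The cleaning stages replace visual inspection by automated rules: channels are
removed when flat for more than 5 s or poorly correlated (< 0.6) with their
nearest neighbors; 1 s time windows are excised when more than 30% of channels
are noisy there; data are then re-referenced to the common average.  Removed
channels can be reconstructed afterwards by spherical-spline interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.ndimage import maximum_filter1d, minimum_filter1d

from .core import EEGRecording, EventList

__all__ = [
    "CleaningReport", "filter_and_resample", "reject_channels",
    "reject_time_windows", "rereference_average", "interpolate_channels",
    "remap_events", "channel_retention_map",
]

FLAT_PTP = 1e-8  # uV; float-safe operationalization of "zero activity"


@dataclass
class CleaningReport:
    removed_channels: list = field(default_factory=list)
    removal_reason: dict = field(default_factory=dict)   # label -> flat | low_corr
    removed_windows: list = field(default_factory=list)  # [start, end) samples
    retained_channel_count: int = 0
    original_montage: object = None
    warnings: list = field(default_factory=list)


def _design_fir(fs, cutoff, width, pass_zero):
    numtaps = int(np.ceil(3.3 * fs / width)) | 1  # Hamming transition heuristic
    return sps.firwin(numtaps, cutoff, window="hamming", pass_zero=pass_zero, fs=fs)


def zero_phase_fir(data, taps, axis=-1):
    """Forward-backward FIR filtering via one FFT convolution.

    Applying a linear-phase FIR forward and backward equals convolving once
    with the (symmetric, exactly zero-phase) autocorrelation of the taps;
    edges use the same odd extension as the direct forward-backward form.
    """
    data = np.asarray(data, dtype=float)
    h = np.convolve(taps, taps[::-1])
    x = np.moveaxis(np.atleast_2d(data), axis, -1)
    n = x.shape[-1]
    pad = min(len(taps) * 3, n - 1)
    left = 2 * x[..., :1] - x[..., pad:0:-1]
    right = 2 * x[..., -1:] - x[..., -2:-pad - 2:-1]
    ext = np.concatenate([left, x, right], axis=-1)
    out = sps.fftconvolve(ext, h[(None,) * (ext.ndim - 1)], mode="same", axes=-1)
    out = out[..., pad:pad + n]
    out = np.moveaxis(out, -1, axis)
    return out.reshape(data.shape)


def filter_and_resample(eeg: EEGRecording, hp: float = 1.0, lp: float = 120.0,
                        fs_out: float = 250.0) -> EEGRecording:
    """Zero-phase FIR band limiting (1-120 Hz) then polyphase resampling.

    Transition widths: 1 Hz around the high-pass edge, 10 Hz around the
    low-pass edge; both filters are applied forward-backward.  The polyphase
    resampler applies its own anti-alias filter.
    """
    if hp >= lp:
        raise ValueError(f"high-pass edge {hp} must be below low-pass edge {lp}")
    if fs_out > eeg.fs:
        raise ValueError("upsampling is not supported")
    data = eeg.data
    if hp > 0:
        data = zero_phase_fir(data, _design_fir(eeg.fs, hp, 1.0, False), axis=1)
    if lp < eeg.fs / 2:
        data = zero_phase_fir(data, _design_fir(eeg.fs, lp, 10.0, True), axis=1)
    if fs_out != eeg.fs:
        frac = Fraction(fs_out / eeg.fs).limit_denominator(1000)
        data = sps.resample_poly(data, frac.numerator, frac.denominator, axis=1)
    return EEGRecording(data, fs_out, eeg.montage, reference=eeg.reference,
                        bad_channels=list(eeg.bad_channels))


def _flat_channels(data, fs, flat_span):
    w = int(round(flat_span * fs)) + 1
    if data.shape[1] < w:
        return np.zeros(data.shape[0], dtype=bool)
    hi = maximum_filter1d(data, size=w, axis=1, mode="nearest")
    lo = minimum_filter1d(data, size=w, axis=1, mode="nearest")
    # interior samples where the centered window lies fully inside the data
    half = w // 2
    core = slice(half, data.shape[1] - half)
    ptp = (hi - lo)[:, core]
    return np.any(ptp < FLAT_PTP, axis=1)


def _neighbor_correlations(data, positions, fs, n_neighbors, window):
    C, N = data.shape
    d = np.linalg.norm(positions[:, None] - positions[None, :], axis=2)
    np.fill_diagonal(d, np.inf)
    neighbors = np.argsort(d, axis=1)[:, :n_neighbors]
    w = max(2, int(round(window * fs)))
    starts = range(0, max(1, N - w + 1), w)
    med = np.empty(C)
    for ch in range(C):
        vals = []
        for s0 in starts:
            seg = data[:, s0:s0 + w]
            x = seg[ch]
            sx = x.std()
            if sx < 1e-12:
                vals.extend([0.0] * n_neighbors)
                continue
            for nb in neighbors[ch]:
                y = seg[nb]
                sy = y.std()
                vals.append(0.0 if sy < 1e-12 else
                            float(np.corrcoef(x, y)[0, 1]))
        med[ch] = np.median(vals)
    return med


def reject_channels(eeg: EEGRecording, flat_span: float = 5.0,
                    corr_thresh: float = 0.6, n_neighbors: int = 4,
                    corr_window: float = 10.0):
    """Remove flat and neighbor-decorrelated channels.

    A channel goes when (a) any contiguous span longer than ``flat_span``
    has peak-to-peak below 1e-8 uV, or (b) its median Pearson correlation with
    its ``n_neighbors`` nearest electrodes over ``corr_window`` windows falls
    below ``corr_thresh``.  Correlations are evaluated among non-flat channels.
    """
    report = CleaningReport(original_montage=eeg.montage)
    flat = _flat_channels(eeg.data, eeg.fs, flat_span)
    labels = eeg.montage.labels
    for i in np.nonzero(flat)[0]:
        report.removed_channels.append(labels[i])
        report.removal_reason[labels[i]] = "flat"
    # correlation rule iterates to a fixed point: removing a channel changes
    # its neighbors' neighbor sets, so a single pass is not idempotent
    keep = list(np.nonzero(~flat)[0])
    while keep:
        med = _neighbor_correlations(eeg.data[keep],
                                     eeg.montage.positions[keep],
                                     eeg.fs, min(n_neighbors, len(keep) - 1),
                                     corr_window)
        bad = [keep[j] for j in range(len(keep)) if med[j] < corr_thresh]
        if not bad or len(keep) <= n_neighbors + 1:
            break
        for i in bad:
            report.removed_channels.append(labels[i])
            report.removal_reason[labels[i]] = "low_corr"
        keep = [i for i in keep if i not in set(bad)]
    removed = set(report.removed_channels)
    keep_idx = [i for i, lab in enumerate(labels) if lab not in removed]
    report.retained_channel_count = len(keep_idx)
    if len(removed) > 0.5 * len(labels):
        report.warnings.append(
            f"more than half of the channels removed ({len(removed)}/{len(labels)})")
    out = EEGRecording(eeg.data[keep_idx], eeg.fs, eeg.montage.subset(keep_idx),
                       reference=eeg.reference,
                       bad_channels=sorted(set(eeg.bad_channels) | removed),
                       bad_windows=[tuple(w) for w in eeg.bad_windows])
    return out, report


def reject_time_windows(eeg: EEGRecording, window: float = 1.0,
                        bad_fraction: float = 0.30, z_thresh: float = 5.0):
    """Excise windows where more than ``bad_fraction`` of channels are noisy.

    A channel counts as noisy in a window when the robust z-score of its
    window RMS — median/MAD taken over that channel's own window history, so
    detection survives windows where most channels are contaminated — exceeds
    ``z_thresh``.  Removed spans are recorded in original-sample coordinates
    so event onsets can be remapped.
    """
    w = max(1, int(round(window * eeg.fs)))
    N = eeg.n_samples
    n_win = N // w
    if n_win == 0:
        return eeg.copy(), CleaningReport(retained_channel_count=eeg.n_channels,
                                          original_montage=eeg.montage)
    spans = [(k * w, (k + 1) * w if k < n_win - 1 else N) for k in range(n_win)]
    rms = np.stack([np.sqrt(np.mean(eeg.data[:, s0:s1] ** 2, axis=1))
                    for s0, s1 in spans], axis=1)          # (C, n_win)
    med = np.median(rms, axis=1, keepdims=True)
    mad = np.median(np.abs(rms - med), axis=1, keepdims=True) * 1.4826
    z = (rms - med) / np.maximum(mad, 1e-12)
    bad_spans = []
    keep_mask = np.ones(N, dtype=bool)
    for k, (s0, s1) in enumerate(spans):
        if np.mean(z[:, k] > z_thresh) > bad_fraction:
            bad_spans.append((s0, s1))
            keep_mask[s0:s1] = False
    report = CleaningReport(removed_windows=bad_spans,
                            retained_channel_count=eeg.n_channels,
                            original_montage=eeg.montage)
    out = EEGRecording(eeg.data[:, keep_mask], eeg.fs, eeg.montage,
                       reference=eeg.reference,
                       bad_channels=list(eeg.bad_channels),
                       bad_windows=bad_spans)
    return out, report


def remap_events(events: EventList, removed_spans, fs: float) -> EventList:
    """Shift event onsets across excised spans; drop events inside them.

    After excision, sample ``i`` of the original recording maps to ``i`` minus
    the number of removed samples before it; events falling inside a removed
    span have no waveform neighborhood left and are dropped.
    """
    if not removed_spans:
        return events
    spans = sorted(tuple(map(int, s)) for s in removed_spans)
    starts = np.array([s[0] for s in spans])
    lengths = np.array([s[1] - s[0] for s in spans])
    cum = np.cumsum(lengths)
    rows = []
    for _, ev in events.df.iterrows():
        i = int(round(ev["onset"] * fs))
        if any(s0 <= i < s1 for s0, s1 in spans):
            continue
        k = int(np.searchsorted(starts, i, side="right"))
        shift = cum[k - 1] if k else 0
        row = ev.copy()
        row["onset"] = (i - shift) / fs
        rows.append(row)
    if not rows:
        return EventList()
    return EventList(pd.DataFrame(rows).reset_index(drop=True))


def rereference_average(eeg: EEGRecording) -> EEGRecording:
    """Common average reference: per-sample mean subtracted from every channel."""
    if eeg.n_channels < 2:
        raise ValueError("average reference needs at least two channels")
    data = eeg.data - eeg.data.mean(axis=0, keepdims=True)
    return EEGRecording(data, eeg.fs, eeg.montage, reference="average",
                        bad_channels=list(eeg.bad_channels),
                        bad_windows=[tuple(w) for w in eeg.bad_windows])


# --- spherical spline interpolation (order-4 surface splines) ---------------

def _spline_g(cosang, m: int = 4, n_terms: int = 50):
    """g(cos) = 1/(4 pi) sum (2n+1) / (n(n+1))^m P_n(cos)."""
    x = np.asarray(cosang, dtype=float)
    P_prev = np.ones_like(x)
    P_cur = x.copy()
    out = np.zeros_like(x)
    for n in range(1, n_terms + 1):
        out += (2 * n + 1) / (n * (n + 1)) ** m * P_cur
        P_next = ((2 * n + 1) * x * P_cur - n * P_prev) / (n + 1)
        P_prev, P_cur = P_cur, P_next
    return out / (4 * np.pi)


def interpolate_channels(eeg: EEGRecording, report: CleaningReport,
                         order: int = 4, reg: float = 1e-5) -> EEGRecording:
    """Reconstruct removed channels with spherical-spline interpolation.

    Retained channels pass through untouched; the removed channels of
    ``report`` are re-inserted at their montage positions with interpolated
    traces.  Requires at least 3 retained channels within 90 degrees of each
    reconstructed electrode.
    """
    if not report.removed_channels:
        return eeg.copy()
    full = report.original_montage
    good_labels = eeg.montage.labels
    good_idx = [full.index_of(l) for l in good_labels]
    bad_labels = [l for l in report.removed_channels if l in full.labels]
    bad_idx = [full.index_of(l) for l in bad_labels]

    pos = full.positions / np.linalg.norm(full.positions, axis=1)[:, None]
    pg, pb = pos[good_idx], pos[bad_idx]
    for j, pbj in enumerate(pb):
        if np.sum(pg @ pbj > 0.0) < 3:
            raise ValueError(
                f"fewer than 3 retained neighbors near {bad_labels[j]}")

    G = _spline_g(np.clip(pg @ pg.T, -1, 1), m=order)
    Gb = _spline_g(np.clip(pb @ pg.T, -1, 1), m=order)
    ng = len(good_idx)
    A = np.zeros((ng + 1, ng + 1))
    A[:ng, :ng] = G + reg * np.eye(ng)
    A[:ng, ng] = 1.0
    A[ng, :ng] = 1.0
    rhs = np.vstack([eeg.data, np.zeros((1, eeg.n_samples))])
    sol = np.linalg.solve(A, rhs)
    recon = Gb @ sol[:ng] + sol[ng]

    n_full = len(full)
    data = np.empty((n_full, eeg.n_samples))
    data[good_idx] = eeg.data
    data[bad_idx] = recon
    return EEGRecording(data, eeg.fs, full, reference=eeg.reference,
                        bad_channels=[], bad_windows=[tuple(w) for w in eeg.bad_windows])


def interpolation_operator(montage, full_montage, order: int = 4,
                           reg: float = 1e-5) -> np.ndarray:
    """Linear map (n_full x n_reduced) realizing spherical-spline channel
    reconstruction; retained channels pass through exactly.

    Spline interpolation is linear in the data, so applying this operator to
    per-subject signals or ERPs places every subject in the full-montage
    channel space for group averaging.
    """
    pg = montage.positions / np.linalg.norm(montage.positions, axis=1)[:, None]
    pf = full_montage.positions / np.linalg.norm(full_montage.positions,
                                                 axis=1)[:, None]
    ng = len(pg)
    A = np.zeros((ng + 1, ng + 1))
    A[:ng, :ng] = _spline_g(np.clip(pg @ pg.T, -1, 1), m=order) + reg * np.eye(ng)
    A[:ng, ng] = A[ng, :ng] = 1.0
    Ainv = np.linalg.inv(A)
    B = np.hstack([_spline_g(np.clip(pf @ pg.T, -1, 1), m=order),
                   np.ones((len(pf), 1))]) @ Ainv[:, :ng]
    have = {lab: j for j, lab in enumerate(montage.labels)}
    for i, lab in enumerate(full_montage.labels):
        if lab in have:
            B[i] = 0.0
            B[i, have[lab]] = 1.0
    return B


def channel_retention_map(reports, montage) -> pd.DataFrame:
    """Per-electrode probability of surviving channel cleaning.

    ``reports`` is one :class:`CleaningReport` per session; the result joins
    retention probability to montage positions for topographic plotting.
    """
    if not reports:
        raise ValueError("need at least one cleaning report")
    labels = montage.labels
    counts = np.zeros(len(labels))
    for rep in reports:
        removed = set(rep.removed_channels)
        counts += np.array([lab not in removed for lab in labels], dtype=float)
    prob = counts / len(reports)
    return pd.DataFrame({
        "label": labels,
        "retention": prob,
        "x": montage.positions[:, 0],
        "y": montage.positions[:, 1],
        "z": montage.positions[:, 2],
        "group": montage.group,
    })
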