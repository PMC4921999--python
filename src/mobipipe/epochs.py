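"""Stimulus-locked epoching and iterative artifact-epoch rejection.

Epochs run from 1 s before to 2 s after a color change (3 s at 250 Hz = 750
samples) and are baseline-corrected over the immediate pre-stimulus interval.
Only correctly answered trials enter: targets require a response, standards
and distractors require its absence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import COLOR_CHANGE_KINDS, EEGRecording, EventList

__all__ = ["EpochSet", "epoch_data", "reject_epochs"]


@dataclass
class EpochSet:
    data: np.ndarray          # (epochs, rows, time) — rows are channels or ICs
    fs: float
    window: tuple             # (t_min, t_max) s relative to the color change
    baseline: tuple
    labels: pd.DataFrame      # stimulus, condition, subject, trial_index
    dropped: list = field(default_factory=list)

    @property
    def times(self):
        n = self.data.shape[2]
        return self.window[0] + np.arange(n) / self.fs

    def select(self, stimulus=None, condition=None) -> "EpochSet":
        mask = np.ones(len(self.labels), dtype=bool)
        if stimulus is not None:
            mask &= (self.labels["stimulus"] == stimulus).to_numpy()
        if condition is not None:
            mask &= (self.labels["condition"] == condition).to_numpy()
        return EpochSet(self.data[mask], self.fs, self.window, self.baseline,
                        self.labels[mask].reset_index(drop=True))

    def erp(self) -> np.ndarray:
        return self.data.mean(axis=0)


def epoch_data(signal, events: EventList, fs: float | None = None,
               window=(-1.0, 2.0), baseline=(-0.2, 0.0),
               subject="s0") -> EpochSet:
    """One epoch per correctly answered color change.

    ``signal`` is an :class:`EEGRecording` or a (rows, samples) array with
    explicit ``fs``.  Epochs exceeding the signal bounds are dropped and
    logged.  Baseline correction subtracts the per-epoch, per-row mean over
    ``baseline``.
    """
    if isinstance(signal, EEGRecording):
        data, fs = signal.data, signal.fs
    else:
        data = np.atleast_2d(np.asarray(signal, dtype=float))
        if fs is None:
            raise ValueError("fs is required for array input")
    i0 = int(round(window[0] * fs))
    i1 = int(round(window[1] * fs))
    b0 = int(round(baseline[0] * fs)) - i0
    b1 = int(round(baseline[1] * fs)) - i0

    df = events.df
    responded = set(df[df["kind"] == "response"]["trial_index"])
    eps, rows, dropped = [], [], []
    for _, ev in df[df["kind"].isin(COLOR_CHANGE_KINDS)].iterrows():
        ti = int(ev["trial_index"])
        correct = (ti in responded) == (ev["kind"] == "target")
        if not correct:
            dropped.append((ti, "incorrect_response"))
            continue
        c = int(round(float(ev["onset"]) * fs))
        if c + i0 < 0 or c + i1 > data.shape[1]:
            dropped.append((ti, "out_of_bounds"))
            continue
        ep = data[:, c + i0:c + i1].copy()
        ep -= ep[:, b0:b1].mean(axis=1, keepdims=True)
        eps.append(ep)
        rows.append({"stimulus": ev["kind"], "condition": ev["condition"],
                     "subject": subject, "trial_index": ti})
    if eps:
        cube = np.stack(eps)
    else:
        cube = np.empty((0, data.shape[0], i1 - i0))
    labels = pd.DataFrame(rows, columns=["stimulus", "condition", "subject",
                                         "trial_index"])
    return EpochSet(cube, fs, tuple(window), tuple(baseline), labels,
                    dropped=dropped)


def reject_epochs(epochs: EpochSet, abs_thresh: float = 1000.0,
                  sd_thresh: float = 5.0, keep_floor: float = 0.95) -> EpochSet:
    """Iterative amplitude/deviation rejection with a per-iteration floor.

    Each iteration flags epochs containing any |value| above ``abs_thresh`` uV
    or any value outside ``sd_thresh`` standard deviations of the per-row
    epoch-population distribution; if the flags exceed ``1 - keep_floor`` of
    the current count, only that worst fraction (ranked by max |z|) is
    rejected.  Repeats until no epoch is flagged; all rejections are logged in
    ``dropped``.
    """
    if epochs.data.shape[0] < 20:
        import warnings
        warnings.warn("fewer than 20 epochs; rejection statistics are weak")
    data = epochs.data
    keep = np.arange(data.shape[0])
    log = list(epochs.dropped)
    it = 0
    while True:
        it += 1
        cur = data[keep]
        mu = cur.mean(axis=(0, 2), keepdims=True)
        sd = cur.std(axis=(0, 2), keepdims=True)
        z = np.abs(cur - mu) / np.maximum(sd, 1e-12)
        maxz = z.max(axis=(1, 2))
        maxabs = np.abs(cur).max(axis=(1, 2))
        flagged = (maxabs > abs_thresh) | (maxz > sd_thresh)
        n_flag = int(flagged.sum())
        if n_flag == 0:
            break
        limit = max(1, int(np.floor((1 - keep_floor) * len(keep))))
        if n_flag > limit:
            order = np.argsort(-maxz)
            reject_local = order[:limit]
        else:
            reject_local = np.nonzero(flagged)[0]
        for j in reject_local:
            ti = int(epochs.labels.iloc[keep[j]]["trial_index"])
            log.append((ti, f"artifact_iter{it}"))
        keep = np.delete(keep, reject_local)
        if len(keep) == 0:
            break
    return EpochSet(data[keep], epochs.fs, epochs.window, epochs.baseline,
                    epochs.labels.iloc[keep].reset_index(drop=True), dropped=log)
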