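"""Domain types and serialization for synchronized multi-stream sessions.

A session (:class:`StreamSet`) bundles an EEG recording, motion-capture LED
tracks, an experiment event list and metadata, all on a single time base
(seconds from session start).  Motion capture is *not* resampled to the EEG
rate; downstream operations interpolate as needed, mirroring timestamped
acquisition streams.

On disk a session is a plain directory::

    meta.json                 session metadata
    montage.sfp               BESA .sfp dialect: "label x y z" per line
    eeg.dat + eeg.json        raw float64 channels-major binary + sidecar
    mocap_<led>.csv           t, x, y, z, reliability
    events.tsv                BIDS-style tab-separated event table
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Montage", "EEGRecording", "MocapTrack", "EventList", "StreamSet",
    "make_standard_montage", "standard_position",
    "write_streamset", "read_streamset",
]

COLOR_CHANGE_KINDS = ("standard", "distractor", "target")
EVENT_KINDS = COLOR_CHANGE_KINDS + ("response", "hot_zone", "trial_start", "trial_end")


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

@dataclass
class Montage:
    """Electrode montage: labels, 3-D head-centered positions (m), group tags."""

    labels: list
    positions: np.ndarray
    group: list  # per-channel: "scalp" | "neck"

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("montage labels must be unique")
        if self.positions.shape != (len(self.labels), 3):
            raise ValueError("positions must be (n_channels, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("montage positions must be finite")
        if len(self.group) != len(self.labels):
            raise ValueError("group tags must match channel count")
        bad = set(self.group) - {"scalp", "neck"}
        if bad:
            raise ValueError(f"unknown montage group tags: {sorted(bad)}")

    def __len__(self):
        return len(self.labels)

    def index_of(self, label: str) -> int:
        return self.labels.index(label)

    def nearest(self, position) -> str:
        """Label of the electrode nearest a 3-D position."""
        d = np.linalg.norm(self.positions - np.asarray(position, float), axis=1)
        return self.labels[int(np.argmin(d))]

    def subset(self, keep_idx) -> "Montage":
        keep_idx = list(keep_idx)
        return Montage(
            [self.labels[i] for i in keep_idx],
            self.positions[keep_idx],
            [self.group[i] for i in keep_idx],
        )


@dataclass
class EEGRecording:
    """Multichannel EEG in microvolts, channels x samples."""

    data: np.ndarray
    fs: float
    montage: Montage
    reference: str = "common-electrode"   # or "average"
    bad_channels: list = field(default_factory=list)
    bad_windows: list = field(default_factory=list)  # [start, end) sample spans

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.montage):
            raise ValueError("data must be (n_channels, n_samples) matching montage")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        spans = sorted(tuple(map(int, w)) for w in self.bad_windows)
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 < a1:
                raise ValueError("bad_windows must be disjoint")
        self.bad_windows = spans

    @property
    def n_channels(self):
        return self.data.shape[0]

    @property
    def n_samples(self):
        return self.data.shape[1]

    @property
    def times(self):
        return np.arange(self.n_samples) / self.fs

    def copy(self, **updates) -> "EEGRecording":
        kw = dict(data=self.data.copy(), fs=self.fs, montage=self.montage,
                  reference=self.reference, bad_channels=list(self.bad_channels),
                  bad_windows=[tuple(w) for w in self.bad_windows])
        kw.update(updates)
        return EEGRecording(**kw)


@dataclass
class MocapTrack:
    led_id: str
    t: np.ndarray
    xyz: np.ndarray
    reliability: np.ndarray
    fs: float = 480.0

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.reliability = np.asarray(self.reliability, dtype=float)
        if not (len(self.t) == self.xyz.shape[0] == len(self.reliability)):
            raise ValueError("t, xyz, reliability lengths must match")
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError("xyz must be (n, 3)")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")


class EventList:
    """Thin wrapper over a pandas event table.

    Columns: onset (s), kind, condition, trial_index, source.
    Invariants: onsets non-decreasing within a trial; at most one color-change
    event per trial.
    """

    COLUMNS = ["onset", "kind", "condition", "trial_index", "source"]

    def __init__(self, df: pd.DataFrame | None = None):
        if df is None:
            df = pd.DataFrame(columns=self.COLUMNS)
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"event table missing columns: {sorted(missing)}")
        self.df = df[self.COLUMNS].reset_index(drop=True)
        self.validate()

    def validate(self):
        df = self.df
        if len(df) == 0:
            return
        unknown = set(df["kind"]) - set(EVENT_KINDS)
        if unknown:
            raise ValueError(f"unknown event kinds: {sorted(unknown)}")
        for trial, g in df.groupby("trial_index"):
            onsets = g["onset"].to_numpy(float)
            if np.any(np.diff(onsets) < 0):
                raise ValueError(f"onsets out of order within trial {trial}")
            n_cc = int(g["kind"].isin(COLOR_CHANGE_KINDS).sum())
            if n_cc > 1:
                raise ValueError(f"trial {trial} has {n_cc} color-change events")

    def __len__(self):
        return len(self.df)

    def __eq__(self, other):
        return isinstance(other, EventList) and self.df.equals(other.df)

    def select(self, **conditions) -> pd.DataFrame:
        df = self.df
        for col, val in conditions.items():
            if isinstance(val, (list, tuple, set)):
                df = df[df[col].isin(val)]
            else:
                df = df[df[col] == val]
        return df

    def color_changes(self) -> pd.DataFrame:
        return self.df[self.df["kind"].isin(COLOR_CHANGE_KINDS)]

    @staticmethod
    def from_rows(rows) -> "EventList":
        return EventList(pd.DataFrame(rows, columns=EventList.COLUMNS))

    @staticmethod
    def concat(parts) -> "EventList":
        """Merge event lists, re-sorting into temporal order."""
        dfs = [p.df for p in parts if len(p)]
        if not dfs:
            return EventList()
        merged = pd.concat(dfs, ignore_index=True)
        merged = merged.sort_values("onset", kind="stable").reset_index(drop=True)
        return EventList(merged)


@dataclass
class StreamSet:
    eeg: EEGRecording
    mocap: list
    events: EventList
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# montage construction
# ---------------------------------------------------------------------------

_STANDARD_1020 = {
    # unit-sphere directions for a few 10-20 anchors (+x front, +y left, +z up)
    "Cz": (0.0, 0.0, 1.0),
    "Pz": (-np.sin(np.pi / 4), 0.0, np.cos(np.pi / 4)),
    "Fz": (np.sin(np.pi / 4), 0.0, np.cos(np.pi / 4)),
    "Oz": (-np.sin(np.pi / 2 * 0.9), 0.0, np.cos(np.pi / 2 * 0.9)),
}


def standard_position(name: str, radius: float = 0.09) -> np.ndarray:
    """Approximate 10-20 position on the model sphere (meters)."""
    return np.asarray(_STANDARD_1020[name]) * radius


def make_standard_montage(n_scalp: int = 128, n_neck: int = 28,
                          radius: float = 0.09) -> Montage:
    """Montage preset: ``n_scalp`` cap electrodes + ``n_neck`` neck-band ring.

    Scalp electrodes are spread on the upper spherical cap (polar angle up to
    ~115 deg) with a Fibonacci lattice; the neck band is a ring below the
    equator, densest posteriorly (electrodes "around the neck").
    """
    labels, positions, group = [], [], []
    # Fibonacci lattice over the cap cos(theta) in [cos(115deg), 1]
    golden = (1 + 5 ** 0.5) / 2
    cmin = np.cos(np.deg2rad(115))
    for i in range(n_scalp):
        z = 1 - (1 - cmin) * (i + 0.5) / n_scalp
        r = np.sqrt(max(0.0, 1 - z * z))
        phi = 2 * np.pi * ((i / golden) % 1.0)
        positions.append((r * np.cos(phi), r * np.sin(phi), z))
        labels.append(f"E{i + 1:03d}")
        group.append("scalp")
    # neck ring at polar angle 135 deg
    zn = np.cos(np.deg2rad(135))
    rn = np.sin(np.deg2rad(135))
    for j in range(n_neck):
        phi = np.pi + 2 * np.pi * j / max(n_neck, 1)  # start posterior
        positions.append((rn * np.cos(phi), rn * np.sin(phi), zn))
        labels.append(f"N{j + 1:02d}")
        group.append("neck")
    return Montage(labels, np.asarray(positions) * radius, group)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _require(path: Path, what: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"session artifact missing: {what} ({path})")
    return path


def write_streamset(s: StreamSet, path) -> Path:
    """Write a session directory; see module docstring for layout."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    with open(path / "meta.json", "w") as f:
        json.dump(s.meta, f, indent=2, sort_keys=True, default=str)

    with open(path / "montage.sfp", "w") as f:
        for lab, pos, grp in zip(s.eeg.montage.labels, s.eeg.montage.positions,
                                 s.eeg.montage.group):
            f.write(f"{lab}\t{pos[0]:.9f}\t{pos[1]:.9f}\t{pos[2]:.9f}\n")

    data = np.ascontiguousarray(s.eeg.data, dtype=np.float64)
    data.tofile(path / "eeg.dat")
    sidecar = {
        "dtype": "float64", "shape": list(data.shape), "order": "C",
        "fs": s.eeg.fs, "unit": "uV", "reference": s.eeg.reference,
        "bad_channels": list(s.eeg.bad_channels),
        "bad_windows": [list(map(int, w)) for w in s.eeg.bad_windows],
        "montage_group": list(s.eeg.montage.group),
    }
    with open(path / "eeg.json", "w") as f:
        json.dump(sidecar, f, indent=2)

    for tr in s.mocap:
        df = pd.DataFrame({"t": tr.t, "x": tr.xyz[:, 0], "y": tr.xyz[:, 1],
                           "z": tr.xyz[:, 2], "reliability": tr.reliability})
        df.to_csv(path / f"mocap_{tr.led_id}.csv", index=False,
                  float_format="%.9f")
        with open(path / f"mocap_{tr.led_id}.json", "w") as f:
            json.dump({"fs": tr.fs}, f)

    ev = s.events.df.copy()
    # exact decimal round-trip with at least 6 decimal places
    ev["onset"] = [np.format_float_positional(v, unique=True, min_digits=6, trim="k")
                   for v in ev["onset"].to_numpy(float)]
    ev.insert(1, "duration", "0.000000")
    ev = ev.rename(columns={"kind": "trial_type"})
    ev.to_csv(path / "events.tsv", sep="\t", index=False)
    return path


def _parse_sfp(path: Path):
    labels, positions = [], []
    with open(path) as f:
        for lineno, line in enumerate(f, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"malformed .sfp line {lineno}: {line.rstrip()!r}")
            try:
                xyz = [float(v) for v in parts[1:]]
            except ValueError:
                raise ValueError(f"malformed .sfp line {lineno}: non-numeric coordinate")
            labels.append(parts[0])
            positions.append(xyz)
    return labels, np.asarray(positions, dtype=float)


def read_streamset(path) -> StreamSet:
    """Read a session directory written by :func:`write_streamset`."""
    path = Path(path)
    with open(_require(path / "meta.json", "meta.json")) as f:
        meta = json.load(f)

    labels, positions = _parse_sfp(_require(path / "montage.sfp", "montage.sfp"))

    with open(_require(path / "eeg.json", "eeg.json")) as f:
        sidecar = json.load(f)
    raw = np.fromfile(_require(path / "eeg.dat", "eeg.dat"),
                      dtype=sidecar["dtype"])
    data = raw.reshape(sidecar["shape"])
    montage = Montage(labels, positions, sidecar["montage_group"])
    eeg = EEGRecording(data, sidecar["fs"], montage,
                       reference=sidecar["reference"],
                       bad_channels=sidecar["bad_channels"],
                       bad_windows=[tuple(w) for w in sidecar["bad_windows"]])

    mocap = []
    for csv_path in sorted(path.glob("mocap_*.csv")):
        led = csv_path.stem[len("mocap_"):]
        df = pd.read_csv(csv_path)
        xyz = df[["x", "y", "z"]].to_numpy(float)
        rel = df["reliability"].to_numpy(float)
        # rows with missing coordinates are unreliable by definition
        rel = np.where(np.any(~np.isfinite(xyz), axis=1), 0.0, rel)
        side = path / f"mocap_{led}.json"
        fs = 480.0
        if side.exists():
            with open(side) as f:
                fs = json.load(f).get("fs", 480.0)
        mocap.append(MocapTrack(led, df["t"].to_numpy(float), xyz, rel, fs=fs))

    ev = pd.read_csv(_require(path / "events.tsv", "events.tsv"), sep="\t",
                     float_precision="round_trip")
    ev = ev.rename(columns={"trial_type": "kind"})
    if len(ev):
        events = EventList(ev)
    else:
        events = EventList()
    return StreamSet(eeg=eeg, mocap=mocap, events=events, meta=meta)
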