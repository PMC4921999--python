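"""Ground-truthed synthetic sessions for the oddball pointing experiment.

The generator emulates the statistical structure of a three-stimulus visual
oddball task performed standing in front of a screen, with responses given
either by button press or by physically pointing at the stimulus:

* trial timing — color change uniform on [1, 5] s after trial start, 4 s
  response window, 500 ms hold, 70/15/15 standard/distractor/target mix;
* pointing kinematics — minimum-jerk forward thrusts of the finger LED with a
  slower return movement, tracker occlusions, and a "hot zone" marker when the
  finger comes within 10 cm of the screen;
* EEG — a linear mixture of dipolar sources in a spherical head: brain sources
  with event-locked P3-like potentials plus ongoing band-limited activity,
  two ocular sources (saccade steps, smooth pursuit, stimulus-locked gaze
  shifts), and neck-muscle sources with movement-locked EMG bursts; background
  is spatially structured pink noise from many weak dipoles plus sensor white
  noise.

Everything is derived from one seed, and a :class:`GroundTruth` record stores
the mixing matrix, the noise-free source time courses, true movement onsets
and response times, and the event-locked variance injected per source group.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import EEGRecording, EventList, MocapTrack, Montage, StreamSet, \
    make_standard_montage
from .headmodel import DEFAULT_HEAD, HeadModel, dipole_potential

__all__ = [
    "SessionConfig", "SourceSpec", "GroundTruth",
    "generate_oddball_events", "minimum_jerk_velocity", "minimum_jerk_position",
    "generate_pointing_tracks", "build_forward_model", "generate_session",
    "default_sources",
]

CONDITIONS = ("button", "pointing")
STIMULI = ("standard", "distractor", "target")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SessionConfig:
    """Study-design parameters; defaults follow the experimental protocol."""

    n_trials_per_block: int = 50
    n_blocks: int = 5                       # per response condition
    p_stimulus: dict = field(default_factory=lambda: {
        "standard": 0.70, "distractor": 0.15, "target": 0.15})
    color_change_window: tuple = (1.0, 5.0)  # s after trial start, uniform
    response_timeout: float = 4.0            # s
    hold: float = 0.5                        # s the sphere remains after stop
    fs_eeg: float = 500.0
    fs_mocap: float = 480.0
    n_scalp: int = 128
    n_neck: int = 28
    n_leds: int = 16
    head: HeadModel = field(default_factory=lambda: DEFAULT_HEAD)
    # behavior: log-normal RTs; means from the two response modes
    rt_mean: dict = field(default_factory=lambda: {
        "pointing": 0.3831, "button": 0.5158})
    rt_sd: float = 0.045
    # pointing kinematics (m, s)
    movement_amplitude: float = 0.30
    movement_duration: float = 0.40
    return_duration: float = 0.70
    dwell: float = 0.10                      # pause at full extension
    screen_x: float = 0.55                   # screen plane at arm length
    rest_distance: float = 0.35              # finger-to-screen distance at rest
    hot_zone_distance: float = 0.10
    # noise
    pink_rms: float = 4.0                    # uV per channel, 1/f background
    white_rms: float = 1.0                   # uV per channel, sensor noise
    n_noise_dipoles: int = 200
    mocap_noise: float = 5e-4                # m, tracker jitter
    occlusion_rate: float = 0.1              # events per second
    occlusion_mean_duration: float = 0.1     # s
    spurious_marker_rate: float = 0.0        # fake hot-zone markers, non-target
    seed: int = 0

    def __post_init__(self):
        total = sum(self.p_stimulus.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"stimulus probabilities must sum to 1, got {total}")
        if min(self.p_stimulus.values()) < 0:
            raise ValueError("stimulus probabilities must be non-negative")
        for name in ("fs_eeg", "fs_mocap", "response_timeout", "hold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def scaled(self, scale: str) -> "SessionConfig":
        """Reduced-size variants used for fast desk-scale runs.

        ``tiny`` (26 channels, 30 trials/condition) is a smoke-test scale;
        ``small`` (60 channels, 80 trials/condition) keeps the montage dense
        enough for neighbor-correlation cleaning and group analyses; ``full``
        is the complete protocol.
        """
        if scale == "full":
            return replace(self)
        if scale == "small":
            # 80 trials/condition keeps ~12 targets per cell so that
            # trial-averaged residual ocular activity stays below the
            # movement-locked neck signal, as in the full 250-trial protocol
            return replace(self, n_blocks=1, n_trials_per_block=80,
                           n_scalp=48, n_neck=12, n_leds=3, n_noise_dipoles=80)
        if scale == "tiny":
            return replace(self, n_blocks=1, n_trials_per_block=30,
                           n_scalp=20, n_neck=6, n_leds=2, n_noise_dipoles=60)
        raise ValueError(f"unknown scale {scale!r}")


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------

def _lognormal_rt(mean: float, sd: float, rng, size=None):
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2
    return np.exp(rng.normal(mu, np.sqrt(sigma2), size=size))


def generate_oddball_events(cfg: SessionConfig, condition: str, rng_seed,
                            t0: float = 0.0, trial_index0: int = 0) -> EventList:
    """Event stream for one response condition (all responses correct).

    Targets get a ``response`` event at color change + RT, where RT is the
    movement-onset lag in the pointing condition.  Non-target trials time out
    after 4 s.  Every trial ends ``hold`` seconds after the sphere stops.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    stims = list(cfg.p_stimulus)
    probs = np.array([cfg.p_stimulus[s] for s in stims])
    rows = []
    t = t0
    n_trials = cfg.n_trials_per_block * cfg.n_blocks
    for k in range(n_trials):
        trial = trial_index0 + k
        rows.append((t, "trial_start", condition, trial, "protocol"))
        cc = t + rng.uniform(*cfg.color_change_window)
        stim = stims[rng.choice(len(stims), p=probs)]
        rows.append((cc, stim, condition, trial, "protocol"))
        if stim == "target":
            rt = float(_lognormal_rt(cfg.rt_mean[condition], cfg.rt_sd, rng))
            rt = min(rt, cfg.response_timeout - 0.05)
            resp = cc + rt
            rows.append((resp, "response", condition, trial, "protocol"))
            stop = resp + (cfg.movement_duration if condition == "pointing" else 0.0)
        else:
            stop = cc + cfg.response_timeout
            if cfg.spurious_marker_rate > 0 and rng.uniform() < cfg.spurious_marker_rate:
                # emulates occlusion-corrupted online markers on no-response trials
                rows.append((cc + rng.uniform(0.3, 1.5), "hot_zone",
                             condition, trial, "protocol"))
        end = stop + cfg.hold
        rows.append((end, "trial_end", condition, trial, "protocol"))
        t = end
    rows.sort(key=lambda r: (r[3], r[0]))
    return EventList.from_rows(rows)


# ---------------------------------------------------------------------------
# kinematics
# ---------------------------------------------------------------------------

def minimum_jerk_velocity(T: float, D: float, t):
    """Minimum-jerk speed profile; peak 1.875*D/T at the midpoint.

    v(t) = (D/T) * (30 tau^2 - 60 tau^3 + 30 tau^4),  tau = t/T, 0 <= t <= T
    (zero outside the movement interval).
    """
    if T <= 0:
        raise ValueError("movement duration must be positive")
    t = np.asarray(t, dtype=float)
    tau = np.clip(t / T, 0.0, 1.0)
    v = (D / T) * (30 * tau ** 2 - 60 * tau ** 3 + 30 * tau ** 4)
    v = np.where((t < 0) | (t > T), 0.0, v)
    return v if v.ndim else float(v)


def minimum_jerk_position(T: float, D: float, t):
    """Position along the movement axis, 0 at start, D at completion."""
    if T <= 0:
        raise ValueError("movement duration must be positive")
    t = np.asarray(t, dtype=float)
    tau = np.clip(t / T, 0.0, 1.0)
    x = D * (10 * tau ** 3 - 15 * tau ** 4 + 6 * tau ** 5)
    return x if x.ndim else float(x)


def _occlusion_mask(n: int, fs: float, rate: float, mean_dur: float, rng):
    mask = np.zeros(n, dtype=bool)
    if rate <= 0 or n == 0:
        return mask
    duration = n / fs
    n_events = rng.poisson(rate * duration)
    starts = rng.uniform(0, duration, size=n_events)
    durs = rng.exponential(mean_dur, size=n_events)
    for s, d in zip(starts, durs):
        i0 = int(s * fs)
        i1 = min(n, i0 + max(1, int(round(d * fs))))
        mask[i0:i1] = True
    return mask


def generate_pointing_tracks(events: EventList, cfg: SessionConfig, rng_seed):
    """Finger (and auxiliary) LED tracks plus derived hot-zone events.

    The finger LED rests ``rest_distance`` from the screen, thrusts forward
    with a minimum-jerk profile starting at the true movement onset (color
    change + RT = the ``response`` event), dwells, and returns more slowly.
    A ``hot_zone`` event is derived at the first sample with distance to the
    screen plane below ``hot_zone_distance``.  Occluded spans get reliability
    0 and NaN coordinates.
    """
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    df = events.df
    t_end = float(df["onset"].max()) + 1.0 if len(df) else 1.0
    n = int(np.ceil(t_end * cfg.fs_mocap))
    t = np.arange(n) / cfg.fs_mocap

    rest_x = cfg.screen_x - cfg.rest_distance
    x = np.full(n, rest_x)
    y = 0.10 * np.ones(n)      # right of midline
    z = -0.30 * np.ones(n)     # below head center (hand height)

    targets = df[(df["kind"] == "response") & (df["condition"] == "pointing")]
    hot_rows = []
    for _, ev in targets.iterrows():
        onset = float(ev["onset"])
        T, D = cfg.movement_duration, cfg.movement_amplitude
        seg = (t >= onset) & (t < onset + T)
        x[seg] = rest_x + minimum_jerk_position(T, D, t[seg] - onset)
        dwell = (t >= onset + T) & (t < onset + T + cfg.dwell)
        x[dwell] = rest_x + D
        back0 = onset + T + cfg.dwell
        seg2 = (t >= back0) & (t < back0 + cfg.return_duration)
        x[seg2] = rest_x + D - minimum_jerk_position(cfg.return_duration, D,
                                                     t[seg2] - back0)

    x = x + rng.normal(0, cfg.mocap_noise, size=n)
    y = y + rng.normal(0, cfg.mocap_noise, size=n)
    z = z + rng.normal(0, cfg.mocap_noise, size=n)

    # derive hot-zone crossings from the (pre-occlusion) positions
    dist = cfg.screen_x - x
    inside = dist < cfg.hot_zone_distance
    for _, ev in targets.iterrows():
        onset = float(ev["onset"])
        i0 = int(onset * cfg.fs_mocap)
        i1 = min(n, int((onset + cfg.movement_duration + cfg.dwell) * cfg.fs_mocap) + 1)
        hits = np.nonzero(inside[i0:i1])[0]
        if hits.size:
            hot_rows.append((t[i0 + hits[0]], "hot_zone", "pointing",
                             int(ev["trial_index"]), "derived"))

    xyz = np.column_stack([x, y, z])
    rel = np.ones(n)
    occl = _occlusion_mask(n, cfg.fs_mocap, cfg.occlusion_rate,
                           cfg.occlusion_mean_duration, rng)
    rel[occl] = 0.0
    xyz_out = xyz.copy()
    xyz_out[occl] = np.nan
    tracks = [MocapTrack("finger", t, xyz_out, rel, fs=cfg.fs_mocap)]

    for k in range(max(0, cfg.n_leds - 1)):
        base = np.array([rest_x - 0.15, 0.15 - 0.03 * k, -0.1 - 0.02 * k])
        p = base + rng.normal(0, cfg.mocap_noise, size=(n, 3))
        r = np.ones(n)
        om = _occlusion_mask(n, cfg.fs_mocap, cfg.occlusion_rate,
                             cfg.occlusion_mean_duration, rng)
        r[om] = 0.0
        p[om] = np.nan
        tracks.append(MocapTrack(f"led{k + 2:02d}", t, p, r, fs=cfg.fs_mocap))

    hot_rows.sort(key=lambda r: r[0])
    return tracks, EventList.from_rows(hot_rows)


# ---------------------------------------------------------------------------
# sources and forward model
# ---------------------------------------------------------------------------

@dataclass
class SourceSpec:
    name: str
    group: str                 # brain | eye | neck
    dipole_pos: np.ndarray     # m, head coordinates
    dipole_moment: np.ndarray  # unit direction
    kernel: object             # renders the source time course

    def __post_init__(self):
        self.dipole_pos = np.asarray(self.dipole_pos, dtype=float)
        m = np.asarray(self.dipole_moment, dtype=float)
        self.dipole_moment = m / np.linalg.norm(m)


def _bandlimited_noise(n: int, fs: float, band, rng, laplacian=False) -> np.ndarray:
    """Unit-RMS band-limited noise (optionally heavy-tailed)."""
    raw = rng.laplace(size=n) if laplacian else rng.standard_normal(n)
    lo, hi = band
    hi = min(hi, 0.999 * fs / 2)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    out = sps.sosfiltfilt(sos, raw)
    rms = np.sqrt(np.mean(out ** 2))
    return out / max(rms, 1e-30)


def _gauss_bump(t, center, width):
    return np.exp(-0.5 * ((t - center) / width) ** 2)


class ErpGaussian:
    """Event-locked Gaussian potential plus ongoing band-limited activity.

    ``amplitude`` maps (stimulus, condition) to the peak amplitude in source
    units (roughly sensor microvolts after unit-norm projection spreading).
    """

    def __init__(self, peak_latency, width, amplitude: dict,
                 background_rms=0.0, background_band=(2.0, 18.0)):
        self.peak_latency = peak_latency
        self.width = width
        self.amplitude = dict(amplitude)
        self.background_rms = background_rms
        self.background_band = background_band

    def render(self, events_df, n, fs, rng):
        t = np.arange(n) / fs
        out = np.zeros(n)
        for _, ev in events_df[events_df["kind"].isin(STIMULI)].iterrows():
            a = self.amplitude.get((ev["kind"], ev["condition"]), 0.0)
            if a:
                c = ev["onset"] + self.peak_latency
                lo = max(0, int((c - 6 * self.width) * fs))
                hi = min(n, int((c + 6 * self.width) * fs))
                out[lo:hi] += a * _gauss_bump(t[lo:hi], c, self.width)
        if self.background_rms > 0:
            out += self.background_rms * _bandlimited_noise(
                n, fs, self.background_band, rng, laplacian=True)
        return out


class SaccadeStep:
    """Ocular source: saccadic gaze steps, pursuit, stimulus-locked shifts.

    Gaze is piecewise constant between Poisson saccades (step amplitudes
    Laplacian) with a slow pursuit oscillation; color changes additionally
    evoke a smooth locked gaze shift with per-cell amplitude.
    """

    def __init__(self, rate=2.0, amplitude=10.0, locked_amplitude: dict | None = None,
                 locked_latency=0.30, locked_width=0.12, pursuit_amplitude=4.0):
        # locked_width ~ a saccadic gaze shift; much slower shifts would fall
        # almost entirely below the 1 Hz analysis high-pass
        self.rate = rate
        self.amplitude = amplitude
        self.locked_amplitude = dict(locked_amplitude or {})
        self.locked_latency = locked_latency
        self.locked_width = locked_width
        self.pursuit_amplitude = pursuit_amplitude

    def render(self, events_df, n, fs, rng):
        t = np.arange(n) / fs
        out = np.zeros(n)
        n_sacc = rng.poisson(self.rate * n / fs)
        times = np.sort(rng.uniform(0, n / fs, size=n_sacc))
        levels = rng.laplace(scale=self.amplitude, size=n_sacc + 1)
        idx = np.searchsorted(times, t)
        out += levels[idx]
        out += self.pursuit_amplitude * np.sin(
            2 * np.pi * rng.uniform(0.2, 0.5) * t + rng.uniform(0, 2 * np.pi))
        for _, ev in events_df[events_df["kind"].isin(STIMULI)].iterrows():
            a = self.locked_amplitude.get((ev["kind"], ev["condition"]), 0.0)
            if a:
                c = ev["onset"] + self.locked_latency
                lo = max(0, int((c - 6 * self.locked_width) * fs))
                hi = min(n, int((c + 6 * self.locked_width) * fs))
                out[lo:hi] += a * _gauss_bump(t[lo:hi], c, self.locked_width)
        return out


class EmgBurst:
    """Neck-muscle source: amplitude-modulated band noise with bursts.

    Bursts are tied to movement (``response`` events; color changes in cells
    with a head-orienting gain).  A movement-locked slow potential component
    (``locked_fraction`` of the burst gain) models the systematic mechanical /
    movement artifact that survives trial averaging; pure zero-mean EMG would
    average out as 1/sqrt(n_trials).
    """

    def __init__(self, band=(20.0, 120.0), duration=0.5, gain: dict | None = None,
                 baseline_gain=1.0, latency=0.35, locked_fraction=0.4):
        self.band = band
        self.duration = duration
        self.gain = dict(gain or {})
        self.baseline_gain = baseline_gain
        self.latency = latency
        self.locked_fraction = locked_fraction

    def render(self, events_df, n, fs, rng):
        t = np.arange(n) / fs
        carrier = _bandlimited_noise(n, fs, self.band, rng)
        env = np.full(n, float(self.baseline_gain))
        locked = np.zeros(n)
        resp = events_df[events_df["kind"] == "response"]
        resp_trials = set(resp["trial_index"])
        w = self.duration / 2.5
        for _, ev in events_df[events_df["kind"].isin(STIMULI)].iterrows():
            g = self.gain.get((ev["kind"], ev["condition"]), 0.0)
            if not g:
                continue
            if ev["kind"] == "target" and ev["trial_index"] in resp_trials:
                onset = float(resp[resp["trial_index"] == ev["trial_index"]]
                              ["onset"].iloc[0])
            else:
                onset = float(ev["onset"]) + self.latency
            c = onset + self.duration / 2
            lo = max(0, int((c - 6 * w) * fs))
            hi = min(n, int((c + 6 * w) * fs))
            env[lo:hi] += g * _gauss_bump(t[lo:hi], c, w)
            locked[lo:hi] += self.locked_fraction * g * _gauss_bump(t[lo:hi], c, w)
        return env * carrier + locked


def _cells(pointing, button):
    """Helper: per-(stimulus, condition) dict from two stimulus->value maps."""
    d = {}
    for s, v in pointing.items():
        d[(s, "pointing")] = v
    for s, v in button.items():
        d[(s, "button")] = v
    return d


def default_sources(head: HeadModel = DEFAULT_HEAD) -> list:
    """Default source set: 4 brain, 2 eye, 4 neck dipoles.

    Amplitudes are chosen to give realistic sensor-level magnitudes (target
    P3 ~ 5-10 uV at parietal sensors, EOG steps tens of uV frontally, EMG
    bursts dominating neck channels during pointing) and to reproduce the
    qualitative group-contribution structure of the task: neck activity
    dominant for pointing targets, ocular activity dominant for button-press
    standards, brain P3 growing from standard to target.
    """
    R = head.radius
    src = [
        SourceSpec("parietal_p3", "brain", np.array([-0.30, 0.05, 0.55]) * R,
                   (-0.30, 0.05, 0.55),
                   ErpGaussian(0.55, 0.12,
                               _cells({"standard": 3.5, "distractor": 8.0, "target": 25.0},
                                      {"standard": 3.0, "distractor": 6.0, "target": 16.0}),
                               background_rms=9.0)),
        SourceSpec("acc", "brain", np.array([0.35, 0.00, 0.45]) * R,
                   (0.35, 0.0, 0.45),
                   ErpGaussian(0.35, 0.10,
                               _cells({"standard": 3.0, "distractor": 6.0, "target": 9.0},
                                      {"standard": 2.5, "distractor": 5.0, "target": 7.0}),
                               background_rms=8.0)),
        SourceSpec("occipital", "brain", np.array([-0.60, 0.10, 0.35]) * R,
                   (-0.60, 0.10, 0.35),
                   ErpGaussian(0.15, 0.05,
                               _cells({s: 5.0 for s in STIMULI}, {s: 5.0 for s in STIMULI}),
                               background_rms=10.0, background_band=(6.0, 14.0))),
        SourceSpec("motor_left", "brain", np.array([0.10, 0.35, 0.60]) * R,
                   (0.10, 0.35, 0.60),
                   ErpGaussian(0.45, 0.15,
                               _cells({"standard": 1.0, "distractor": 2.0, "target": 8.0},
                                      {"standard": 1.0, "distractor": 1.5, "target": 3.0}),
                               background_rms=8.0)),
        SourceSpec("eye_h", "eye", np.array([0.80, 0.25, -0.25]) * R,
                   (0.0, 1.0, 0.0),
                   SaccadeStep(rate=2.0, amplitude=25.0,
                               locked_amplitude=_cells(
                                   {"standard": 14.0, "distractor": 11.0, "target": 13.0},
                                   {"standard": 16.0, "distractor": 17.0, "target": 13.0}))),
        SourceSpec("eye_v", "eye", np.array([0.80, -0.25, -0.25]) * R,
                   (0.3, 0.0, 1.0),
                   SaccadeStep(rate=2.0, amplitude=20.0,
                               locked_amplitude=_cells(
                                   {"standard": 11.0, "distractor": 9.0, "target": 12.0},
                                   {"standard": 13.0, "distractor": 15.0, "target": 11.0}))),
    ]
    neck_positions = [(-0.55, 0.35, -0.55), (-0.55, -0.35, -0.55),
                      (-0.75, 0.15, -0.45), (-0.75, -0.15, -0.45)]
    neck_gain = _cells({"standard": 2.0, "distractor": 9.0, "target": 30.0},
                       {"standard": 0.5, "distractor": 1.0, "target": 1.5})
    for i, p in enumerate(neck_positions):
        src.append(SourceSpec(f"neck{i + 1}", "neck", np.array(p) * R, p,
                              EmgBurst(gain=neck_gain, baseline_gain=1.5)))
    return src


def build_forward_model(montage: Montage, sources, head: HeadModel = DEFAULT_HEAD,
                        reference_pos=None) -> np.ndarray:
    """Mixing matrix [channels x sources]: unit-norm analytic dipole projections.

    With ``reference_pos`` the potential at that point (e.g. the vertex
    recording-reference electrode) is subtracted from every channel before
    normalization, emulating common-electrode referencing.
    """
    cols = []
    for s in sources:
        if s.group == "brain" and not head.inside(s.dipole_pos):
            raise ValueError(f"brain dipole {s.name} lies outside the head sphere")
        v = dipole_potential(s.dipole_pos, s.dipole_moment, montage.positions, head)
        if reference_pos is not None:
            v = v - dipole_potential(s.dipole_pos, s.dipole_moment,
                                     np.atleast_2d(reference_pos), head)[0]
        cols.append(v / np.linalg.norm(v))
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# full session
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    mixing: np.ndarray             # channels x sources, unit-norm columns
    source_names: list
    source_groups: list
    sources: np.ndarray            # sources x samples, noise-free (uV)
    fs: float
    true_onsets: dict              # trial_index -> movement onset (s), pointing targets
    true_rt: pd.DataFrame          # trial_index, condition, rt
    injected_variance: pd.DataFrame  # group x stimulus x condition, uV^2

    def group_signal(self, group: str) -> np.ndarray:
        """Noise-free channel-space contribution of one source group."""
        idx = [i for i, g in enumerate(self.source_groups) if g == group]
        return self.mixing[:, idx] @ self.sources[idx]


def _erp_variance(signal: np.ndarray, onsets, fs: float,
                  window=(-0.2, 1.0), baseline=(-0.2, 0.0)) -> float:
    """Mean square over channels and window of the trial-averaged epoch.

    Direct indexing implementation, independent of the analysis-side epoching
    code, used to freeze injected variances into the ground truth.
    """
    i0, i1 = int(round(window[0] * fs)), int(round(window[1] * fs))
    b0, b1 = int(round(baseline[0] * fs)), int(round(baseline[1] * fs))
    acc = None
    count = 0
    for onset in onsets:
        c = int(round(onset * fs))
        if c + i0 < 0 or c + i1 > signal.shape[1]:
            continue
        ep = signal[:, c + i0:c + i1].copy()
        ep -= ep[:, (b0 - i0):(b1 - i0)].mean(axis=1, keepdims=True)
        acc = ep if acc is None else acc + ep
        count += 1
    if count == 0:
        return np.nan
    erp = acc / count
    return float(np.mean(erp ** 2))


def generate_session(cfg: SessionConfig, sources=None, rng_seed=None,
                     block_order=("button", "pointing"),
                     noise: bool = True):
    """Generate one synchronized session and its ground truth.

    EEG = mixing @ source_timecourses (+ pink dipolar noise + sensor white
    noise when ``noise``).  Returns ``(StreamSet, GroundTruth)``.
    """
    seed = cfg.seed if rng_seed is None else rng_seed
    rng = np.random.default_rng(seed)
    if sources is None:
        sources = default_sources(cfg.head)

    # events: conditions blocked, short break between
    parts = []
    t0, trial0 = 1.0, 0
    for cond in block_order:
        ev = generate_oddball_events(cfg, cond, rng, t0=t0, trial_index0=trial0)
        parts.append(ev)
        t0 = float(ev.df["onset"].max()) + 5.0
        trial0 = int(ev.df["trial_index"].max()) + 1
    events = EventList.concat(parts)

    tracks, hot = generate_pointing_tracks(events, cfg, rng)
    events = EventList.concat([events, hot])
    events = EventList(events.df.sort_values(
        ["trial_index", "onset"], kind="stable").reset_index(drop=True))

    duration = float(events.df["onset"].max()) + 1.5
    n = int(np.ceil(duration * cfg.fs_eeg))

    montage = make_standard_montage(cfg.n_scalp, cfg.n_neck, cfg.head.radius)
    ref_pos = np.array([0.0, 0.0, cfg.head.radius])  # vertex recording reference
    mixing = build_forward_model(montage, sources, cfg.head, reference_pos=ref_pos)

    S = np.empty((len(sources), n))
    for i, s in enumerate(sources):
        S[i] = s.kernel.render(events.df, n, cfg.fs_eeg, rng)

    data = mixing @ S
    if noise:
        # deep dipoles (ecc <= 0.55) give the spatially smooth, strongly
        # neighbor-correlated background of real recordings
        pos = rng.normal(size=(cfg.n_noise_dipoles, 3))
        pos = pos / np.linalg.norm(pos, axis=1)[:, None] \
            * (0.55 * rng.uniform(0, 1, cfg.n_noise_dipoles) ** (1 / 3))[:, None] \
            * cfg.head.radius
        mom = rng.normal(size=(cfg.n_noise_dipoles, 3))
        Mn = np.stack([dipole_potential(p, m, montage.positions, cfg.head)
                       - dipole_potential(p, m, np.atleast_2d(ref_pos), cfg.head)[0]
                       for p, m in zip(pos, mom)], axis=1)
        Mn = Mn / np.linalg.norm(Mn, axis=0)
        freqs = np.fft.rfftfreq(n, 1 / cfg.fs_eeg)
        shape = 1.0 / np.sqrt(freqs + 1.0)
        # accumulate dipole by dipole: avoids a (n_dipoles x n_samples) buffer
        pink = np.zeros_like(data)
        for k in range(cfg.n_noise_dipoles):
            spec = (rng.standard_normal(len(freqs))
                    + 1j * rng.standard_normal(len(freqs))) * shape
            pink += np.outer(Mn[:, k], np.fft.irfft(spec, n))
        pink *= cfg.pink_rms / np.sqrt(np.mean(pink ** 2))
        data += pink
        del pink
        data += rng.normal(0, cfg.white_rms, size=data.shape)

    eeg = EEGRecording(data, cfg.fs_eeg, montage, reference="common-electrode")

    # ground truth bookkeeping
    df = events.df
    resp = df[df["kind"] == "response"]
    cc = df[df["kind"].isin(STIMULI)].set_index("trial_index")
    rt_rows, true_onsets = [], {}
    for _, ev in resp.iterrows():
        ti = int(ev["trial_index"])
        rt = float(ev["onset"]) - float(cc.loc[ti, "onset"])
        rt_rows.append({"trial_index": ti, "condition": ev["condition"], "rt": rt})
        if ev["condition"] == "pointing":
            true_onsets[ti] = float(ev["onset"])
    true_rt = pd.DataFrame(rt_rows, columns=["trial_index", "condition", "rt"])

    groups = [s.group for s in sources]
    var_rows = []
    for group in ("brain", "eye", "neck", "total"):
        if group == "total":
            sig = mixing @ S
        else:
            idx = [i for i, g in enumerate(groups) if g == group]
            sig = mixing[:, idx] @ S[idx]
        for stim in STIMULI:
            for cond in CONDITIONS:
                sel = df[(df["kind"] == stim) & (df["condition"] == cond)]
                v = _erp_variance(sig, sel["onset"].to_numpy(float), cfg.fs_eeg)
                var_rows.append({"group": group, "stimulus": stim,
                                 "condition": cond, "variance": v})
    injected = pd.DataFrame(var_rows)

    gt = GroundTruth(mixing=mixing, source_names=[s.name for s in sources],
                     source_groups=groups, sources=S, fs=cfg.fs_eeg,
                     true_onsets=true_onsets, true_rt=true_rt,
                     injected_variance=injected)
    meta = {"participant": "synthetic", "block_order": list(block_order),
            "seed": int(seed)}
    return StreamSet(eeg=eeg, mocap=tracks, events=events, meta=meta), gt
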