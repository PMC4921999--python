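"""Epoching, artifact-epoch rejection, pvaf algebra, ERP statistics."""

import numpy as np
import pandas as pd
import pytest

from mobipipe.core import EventList
from mobipipe.epochs import epoch_data, reject_epochs
from mobipipe.quantify import absolute_variance, erp_window_stats, pvaf

FS = 250.0


def _events(n_trials=30, gap=4.0, start=2.0):
    rows = []
    for k in range(n_trials):
        t = start + k * gap
        stim = ["standard", "distractor", "target"][k % 3]
        cond = ["button", "pointing"][k % 2]
        rows.append((t, stim, cond, k, "protocol"))
        if stim == "target":
            rows.append((t + 0.4, "response", cond, k, "protocol"))
    return EventList.from_rows(rows)


# --- epoching ----------------------------------------------------------------

def test_impulse_lands_at_expected_epoch_sample():
    ev = _events(3)
    n = int(20 * FS)
    sig = np.zeros((2, n))
    t_ev = 2.0
    sig[1, int((t_ev + 0.5) * FS)] = 7.0
    eps = epoch_data(sig, ev, fs=FS)
    i = int(round((0.5 - (-1.0)) * FS))
    assert eps.data[0, 1, i] == pytest.approx(7.0)
    assert eps.data.shape[2] == 750  # 3 s at 250 Hz


def test_constant_signal_zero_after_baseline():
    ev = _events(3)
    sig = np.full((2, int(20 * FS)), 3.14)
    eps = epoch_data(sig, ev, fs=FS)
    assert np.max(np.abs(eps.data)) < 1e-12


def test_edge_epochs_dropped_and_logged():
    ev = _events(30, gap=4.0, start=0.5)  # first epoch needs t >= 1 s
    n = int(2.0 + 27 * 4.0 * FS / FS * FS)  # cut the last trials short
    sig = np.zeros((1, int(27 * 4.0 * FS)))
    eps = epoch_data(sig, ev, fs=FS)
    out_of_bounds = [d for d in eps.dropped if d[1] == "out_of_bounds"]
    assert len(out_of_bounds) >= 2
    assert eps.data.shape[0] + len(eps.dropped) == 30


def test_incorrect_trials_excluded():
    rows = [(2.0, "target", "button", 0, "protocol"),       # miss: no response
            (6.0, "standard", "button", 1, "protocol"),
            (10.0, "standard", "button", 2, "protocol"),
            (10.4, "response", "button", 2, "protocol")]    # false alarm
    ev = EventList.from_rows(rows)
    eps = epoch_data(np.zeros((1, int(20 * FS))), ev, fs=FS)
    assert len(eps.labels) == 1
    assert eps.labels.iloc[0]["trial_index"] == 1


# --- epoch rejection ---------------------------------------------------------

def test_clean_gaussian_epochs_mostly_retained(rng):
    ev = _events(60, gap=3.5)
    sig = rng.normal(size=(4, int(230 * FS)))
    eps = epoch_data(sig, ev, fs=FS)
    out = reject_epochs(eps)
    assert out.data.shape[0] >= 0.9 * eps.data.shape[0]


def test_large_spike_removed_first_iteration(rng):
    ev = _events(30)
    sig = rng.normal(size=(2, int(130 * FS)))
    sig[0, int(6.2 * FS)] = 1500.0  # trial 1
    eps = epoch_data(sig, ev, fs=FS)
    out = reject_epochs(eps)
    assert 1 not in set(out.labels["trial_index"])
    assert any(r == "artifact_iter1" for ti, r in out.dropped if ti == 1)


def test_contaminated_epochs_removed_at_most_five_percent_per_iteration(rng):
    ev = _events(60, gap=3.5)
    sig = rng.normal(size=(2, int(230 * FS)))
    bad_trials = list(range(0, 12))  # 20% contaminated
    for ti in bad_trials:
        sig[:, int((2.0 + ti * 3.5 + 0.2) * FS):int((2.0 + ti * 3.5 + 0.6) * FS)] += 40.0
    eps = epoch_data(sig, ev, fs=FS)
    out = reject_epochs(eps)
    by_iter = {}
    for ti, reason in out.dropped:
        by_iter[reason] = by_iter.get(reason, 0) + 1
    n = eps.data.shape[0]
    for it in sorted(by_iter):
        assert by_iter[it] <= max(1, int(np.floor(0.05 * n)))
        n -= by_iter[it]


# --- pvaf algebra ------------------------------------------------------------

def test_pvaf_full_set_is_hundred(rng):
    parts = [rng.normal(size=(3, 50)) for _ in range(4)]
    total = np.sum(parts, axis=0)
    assert pvaf(total, [total]) == pytest.approx(100.0)


def test_pvaf_hand_arithmetic_toy():
    p1 = np.array([[1.0, 1.0]])
    p2 = np.array([[1.0, -1.0]])
    assert pvaf(p1, [p1, p2]) == pytest.approx(50.0)
    assert pvaf(p2, [p1, p2]) == pytest.approx(50.0)


def test_pvaf_cancellation_is_negative():
    p1 = np.array([[1.0, 1.0, 1.0]])
    p2 = -p1
    p3 = np.array([[0.1, 0.05, -0.08]])
    # p1 and p2 cancel; removing p1 leaves a much larger remainder
    assert pvaf(p1, [p1, p2, p3]) < 0.0
    # degenerate zero total is flagged
    assert np.isnan(pvaf(p1, [p1, p2]))


def test_pvaf_partition_sums(rng):
    # orthogonal projections (disjoint channel support) -> pvafs sum to 100
    a = np.zeros((4, 20)); a[0] = rng.normal(size=20)
    b = np.zeros((4, 20)); b[1] = rng.normal(size=20)
    c = np.zeros((4, 20)); c[2] = rng.normal(size=20)
    s = sum(pvaf(x, [a, b, c]) for x in (a, b, c))
    assert s == pytest.approx(100.0, abs=1e-9)
    # non-orthogonal projections need not sum to 100
    d = a + 0.5 * b
    s2 = pvaf(d, [d, b, c]) + pvaf(b, [d, b, c]) + pvaf(c, [d, b, c])
    assert abs(s2 - 100.0) > 1.0


def test_absolute_variance_arithmetic():
    assert absolute_variance(np.array([[1.0, -1.0]])) == pytest.approx(1.0)
    x = np.array([[1.0, 2.0], [3.0, 4.0]])
    assert absolute_variance(3 * x) == pytest.approx(9 * absolute_variance(x))
    with pytest.raises(ValueError, match="window"):
        absolute_variance(x, times=np.array([0.0, 1.0]), window=(5.0, 6.0))


# --- repeated-measures statistics -------------------------------------------

def _rm_oracle_2x2(table):
    """Hand-computed two-way repeated-measures ANOVA for a 2x2 design.

    With two levels per factor every effect is a paired contrast:
    F = (n * mean(d)^2) / var(d) with d the per-subject contrast scores.
    """
    wide = table.pivot_table(index="subject", columns=["condition", "stimulus"],
                             values="amplitude")
    a = (wide[("c1", "s1")] + wide[("c1", "s2")]
         - wide[("c2", "s1")] - wide[("c2", "s2")]) / 2
    b = (wide[("c1", "s1")] - wide[("c1", "s2")]
         + wide[("c2", "s1")] - wide[("c2", "s2")]) / 2
    ab = (wide[("c1", "s1")] - wide[("c1", "s2")]
          - wide[("c2", "s1")] + wide[("c2", "s2")]) / 2
    out = {}
    for name, d in (("condition", a), ("stimulus", b), ("interaction", ab)):
        n = len(d)
        out[name] = float(n * d.mean() ** 2 / d.var(ddof=1))
    return out


def test_rm_anova_matches_hand_computed_contrasts(rng):
    rows = []
    for s in range(8):
        for c in ("c1", "c2"):
            for st in ("s1", "s2"):
                amp = (1.0 + (c == "c1") * 0.8 + (st == "s2") * 0.3
                       + (c == "c1") * (st == "s2") * 0.5
                       + rng.normal(0, 0.4) + 0.2 * s)
                rows.append({"subject": f"p{s}", "condition": c,
                             "stimulus": st, "amplitude": amp})
    # pad to the 2x3 interface by duplicating one stimulus level? no —
    # exercise the wrapper directly on the 2x2 table via pingouin
    import pingouin as pg
    df = pd.DataFrame(rows)
    aov = pg.rm_anova(data=df, dv="amplitude", within=["condition", "stimulus"],
                      subject="subject", detailed=True)
    oracle = _rm_oracle_2x2(df)
    got = {r["Source"].replace(" * ", "x"): r["F"] for _, r in aov.iterrows()}
    assert got["condition"] == pytest.approx(oracle["condition"], abs=1e-6)
    assert got["stimulus"] == pytest.approx(oracle["stimulus"], abs=1e-6)
    assert got["conditionxstimulus"] == pytest.approx(oracle["interaction"],
                                                      abs=1e-6)


def test_erp_window_stats_power_for_planted_interaction(rng):
    """A target-pointing P3 boost of protocol-typical size yields a
    significant condition x stimulus interaction in >= 90% of replicates."""
    hits = 0
    n_rep = 100
    for rep in range(n_rep):
        rows = []
        for s in range(12):
            base = rng.normal(0, 0.3)
            for cond in ("button", "pointing"):
                for stim in ("standard", "distractor", "target"):
                    amp = base + {"standard": 0.2, "distractor": 0.5,
                                  "target": 1.2}[stim]
                    if cond == "pointing" and stim == "target":
                        amp += 1.5
                    rows.append({"subject": f"p{s}", "condition": cond,
                                 "stimulus": stim,
                                 "amplitude": amp + rng.normal(0, 0.3)})
        out = erp_window_stats(pd.DataFrame(rows))
        if out["effects"]["conditionxstimulus"]["p"] < 0.05:
            hits += 1
        if rep == 0:
            assert out["effects"]["stimulus"]["p"] < 0.01
            assert len(out["hsd"]) == 15  # all pairs of 6 cells
    assert hits >= 0.9 * n_rep


def test_erp_window_stats_requires_balanced_table():
    df = pd.DataFrame({"subject": ["a"], "condition": ["button"],
                       "stimulus": ["target"], "amplitude": [1.0]})
    with pytest.raises(ValueError, match="balanced"):
        erp_window_stats(df)
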