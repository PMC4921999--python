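"""Component measures, weighted feature space, K-means rules, group labels."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from mobipipe.clustering import (ClusterSolution, ComponentMeasures, OUTLIER,
                                 build_feature_vectors, cluster_components,
                                 compute_component_measures,
                                 label_cluster_group)
from mobipipe.core import EventList
from mobipipe.dipoles import DipoleModel
from mobipipe.headmodel import DEFAULT_HEAD
from mobipipe.ica import ICADecomposition


def _fake_decomp(acts, fs=250.0):
    r = acts.shape[0]
    return ICADecomposition(sphere=np.eye(r), unmixing=np.eye(r),
                            mixing=np.eye(r), activations=acts,
                            loglik_trace=[], rejected_spans=[],
                            channel_labels=[f"c{i}" for i in range(r)], fs=fs)


def _events(n_trials=24, gap=4.0):
    rows = []
    for k in range(n_trials):
        t = 2.0 + k * gap
        stim = ["standard", "distractor", "target"][k % 3]
        cond = ["button", "pointing"][k % 2]
        rows.append((t - 1.5, "trial_start", cond, k, "protocol"))
        rows.append((t, stim, cond, k, "protocol"))
        if stim == "target":
            rows.append((t + 0.4, "response", cond, k, "protocol"))
        rows.append((t + 2.2, "trial_end", cond, k, "protocol"))
    return EventList.from_rows(rows)


def test_spectrum_peak_at_driving_frequency(rng):
    fs = 250.0
    n = int(110 * fs)
    t = np.arange(n) / fs
    acts = np.vstack([np.sin(2 * np.pi * 10 * t),
                      rng.normal(size=n)])
    m = compute_component_measures(_fake_decomp(acts), _events(), montage=None)
    peak = m[0].freqs[np.argmax(m[0].spectrum)]
    assert abs(peak - 10.0) < 1.5


def test_itc_phase_locked_vs_surrogate(rng):
    fs = 250.0
    ev = _events()
    n = int(110 * fs)
    t = np.arange(n) / fs
    locked = 0.1 * rng.normal(size=n)
    for _, e in ev.color_changes().iterrows():
        on = float(e["onset"])
        seg = (t >= on) & (t < on + 0.5)
        locked[seg] += np.sin(2 * np.pi * 8 * (t[seg] - on))  # constant phase
    surrogate = 0.1 * rng.normal(size=n)
    for _, e in ev.color_changes().iterrows():
        on = float(e["onset"])
        seg = (t >= on) & (t < on + 0.5)
        surrogate[seg] += np.sin(2 * np.pi * 8 * (t[seg] - on)
                                 + rng.uniform(0, 2 * np.pi))
    m = compute_component_measures(_fake_decomp(np.vstack([locked, surrogate])),
                                   ev, montage=None, min_trials=1)
    assert m[0].itc.max() > 0.8
    # surrogate coherence at the same cells stays low
    assert m[1].itc[np.argmax(m[0].itc)] < 0.5


def test_erp_of_sign_alternating_trials_cancels(rng):
    fs = 250.0
    ev = _events()
    n = int(110 * fs)
    t = np.arange(n) / fs
    act = np.zeros(n)
    seen = {}
    for _, e in ev.color_changes().iterrows():
        cell = (e["kind"], e["condition"])
        seen[cell] = seen.get(cell, 0) + 1
        on = float(e["onset"])
        seg = (t >= on) & (t < on + 0.5)
        act[seg] += (-1) ** seen[cell] * np.hanning(seg.sum())
    m = compute_component_measures(_fake_decomp(act[None]), ev, montage=None,
                                   min_trials=1)
    assert np.max(np.abs(m[0].erp)) < 0.4  # near-complete cancellation


def _measure(i, subject, dip_pos, vec, rng):
    return ComponentMeasures(
        ic_index=i, subject=subject,
        erp=vec + 0.01 * rng.normal(size=len(vec)),
        spectrum=vec + 0.01 * rng.normal(size=len(vec)),
        freqs=np.arange(len(vec), dtype=float),
        ersp=vec + 0.01 * rng.normal(size=len(vec)),
        itc=np.abs(vec) / (np.max(np.abs(vec)) + 1),
        scalp_map=vec + 0.01 * rng.normal(size=len(vec)),
        dipole=DipoleModel(position=np.asarray(dip_pos, float),
                           moment=np.zeros(3), residual_variance=0.1,
                           inside_head=True))


def test_feature_vectors_are_ten_dimensional(rng):
    vecs = [rng.normal(size=40) for _ in range(15)]
    ms = [_measure(i, "s0", rng.normal(size=3) * 0.02, v, rng)
          for i, v in enumerate(vecs)]
    out = build_feature_vectors(ms)
    assert out.shape == (15, 10)


def test_identical_measures_give_identical_vectors(rng):
    base = rng.normal(size=30)
    ms = [ComponentMeasures(ic_index=i, subject="s0", erp=base.copy(),
                            spectrum=base.copy(), freqs=np.arange(30.0),
                            ersp=base.copy(), itc=np.abs(base),
                            scalp_map=base.copy(),
                            dipole=DipoleModel(np.array([0.0, 0.0, 0.02]),
                                               np.zeros(3), 0.1, True))
          for i in range(6)]
    out = build_feature_vectors(ms)
    assert np.allclose(out - out[0], 0.0, atol=1e-9)


def test_dipole_weight_scales_distance_contribution(rng):
    # two components differing only in dipole location
    base = rng.normal(size=30)
    ms = []
    for i, z in enumerate((0.01, 0.05)):
        ms.append(ComponentMeasures(
            ic_index=i, subject="s0", erp=base.copy(), spectrum=base.copy(),
            freqs=np.arange(30.0), ersp=base.copy(), itc=np.abs(base),
            scalp_map=base.copy(),
            dipole=DipoleModel(np.array([0.0, 0.0, z]), np.zeros(3), 0.1, True)))
    d1 = np.linalg.norm(np.diff(build_feature_vectors(
        ms, weights={"dipole": 25}), axis=0))
    d2 = np.linalg.norm(np.diff(build_feature_vectors(
        ms, weights={"dipole": 50}), axis=0))
    assert d2 == pytest.approx(2 * d1, rel=1e-9)


def _blobs(rng, centers, n_per=10, scale=0.05):
    X, labels = [], []
    for k, c in enumerate(centers):
        X.append(c + scale * rng.normal(size=(n_per, len(c))))
        labels += [k] * n_per
    return np.vstack(X), np.array(labels)


def test_planted_blobs_recovered(rng):
    X, truth = _blobs(rng, [np.zeros(5), 5 * np.ones(5),
                            np.r_[5.0, -5, 5, -5, 5]])
    sol = cluster_components(X, k=3, seed=0)
    mask = sol.assignment != OUTLIER
    assert adjusted_rand_score(truth[mask], sol.assignment[mask]) == 1.0
    assert mask.mean() > 0.9


def test_far_vector_goes_to_outlier_cluster(rng):
    X, _ = _blobs(rng, [np.zeros(5), 5 * np.ones(5), np.r_[5.0, -5, 5, -5, 5]])
    # tens of within-cluster SDs from its nearest blob, but far closer to it
    # than to any other centroid so it does not capture a centroid of its own
    X = np.vstack([X, np.r_[1.5, 0, 0, 0, 0.0]])
    sol = cluster_components(X, k=3, seed=0)
    assert sol.assignment[-1] == OUTLIER


def test_one_component_per_subject_rule(rng):
    X, _ = _blobs(rng, [np.zeros(5), 5 * np.ones(5)], n_per=6)
    subjects = ["a", "a", "b", "c", "d", "e"] + ["f"] * 6
    sol = cluster_components(X, k=2, seed=0, subjects=subjects)
    first_blob = sol.assignment[:6]
    kept = [s for s, c in zip(subjects[:6], first_blob) if c != OUTLIER]
    assert sorted(kept) == ["a", "b", "c", "d", "e"]  # one of the two "a"s left


def test_permutation_invariance(rng):
    X, _ = _blobs(rng, [np.zeros(4), 4 * np.ones(4), np.r_[4.0, -4, 4, -4]])
    sol1 = cluster_components(X, k=3, seed=5)
    perm = rng.permutation(len(X))
    sol2 = cluster_components(X[perm], k=3, seed=5)
    assert adjusted_rand_score(sol1.assignment[perm], sol2.assignment) == 1.0


def test_k_larger_than_n_rejected(rng):
    with pytest.raises(ValueError, match="exceeds"):
        cluster_components(rng.normal(size=(5, 3)), k=10, seed=0)


def test_geometric_group_labels():
    R = DEFAULT_HEAD.radius
    sol = ClusterSolution(
        assignment=np.array([0, 1, 2]), centroids=np.zeros((3, 2)),
        centroid_dipole=np.array([[0.0, 0.0, 0.0],
                                  [0.80 * R, 0.25 * R, -0.25 * R],
                                  [-0.55 * R, 0.35 * R, -0.55 * R]]),
        group_label={}, k=3,
        ic_table=None)
    sol = label_cluster_group(sol, DEFAULT_HEAD)
    assert sol.group_label == {0: "brain", 1: "eye", 2: "neck"}
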