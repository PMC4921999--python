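"""Per-component measures and weighted-measure K-means clustering.

Each independent component is summarized by its condition-wise ERPs, power
spectrum (3-75 Hz), event-related spectral perturbation (ERSP), inter-trial
coherence (ITC), scalp map and equivalent-dipole location.  Every measure
except the 3-D dipole is PCA-reduced to 10 dimensions, z-normalized and
weighted (dipole x25 to promote spatially tight clusters, ERSP x10, all else
x1), the joint vector is reduced to a 10-D subspace, and K-means (k = 36)
partitions the components.  Components more than 3 SD from their nearest
centroid go to an outlier cluster, and each cluster keeps at most one
component per subject.  Cluster groups (brain / eye / neck / other) are
assigned geometrically from the centroid dipole position.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .core import EventList
from .dipoles import DipoleModel, fit_dipole
from .epochs import epoch_data
from .headmodel import DEFAULT_HEAD, HeadModel
from .ica import ICADecomposition

__all__ = ["ComponentMeasures", "ClusterSolution", "compute_component_measures",
           "build_feature_vectors", "cluster_components", "label_cluster_group"]

OUTLIER = -1


@dataclass
class ComponentMeasures:
    ic_index: int
    subject: str
    erp: np.ndarray          # concatenated per-cell trial means
    spectrum: np.ndarray     # Welch power on the 3-75 Hz grid
    freqs: np.ndarray
    ersp: np.ndarray         # flattened dB time-frequency deviation
    itc: np.ndarray          # flattened inter-trial coherence
    scalp_map: np.ndarray
    dipole: DipoleModel | None
    low_confidence: list = field(default_factory=list)

    def __post_init__(self):
        for name in ("erp", "spectrum", "ersp", "itc", "scalp_map"):
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite values in measure {name!r}")


@dataclass
class ClusterSolution:
    assignment: np.ndarray       # per-IC cluster id, OUTLIER = -1
    centroids: np.ndarray
    centroid_dipole: np.ndarray  # (k, 3) mean member dipole positions
    group_label: dict            # cluster id -> brain | eye | neck | other
    k: int
    ic_table: pd.DataFrame       # subject, ic_index per clustered component

    def members(self, cluster: int) -> np.ndarray:
        return np.nonzero(self.assignment == cluster)[0]

    def clusters_in_group(self, group: str) -> list:
        return [c for c, g in self.group_label.items() if g == group]


def _tf_maps(ep_data, fs, nperseg=256, hop_s=0.05, fmin=3.0, fmax=75.0):
    """Per-epoch STFT power and phase -> (mean power, ITC) on a t-f grid."""
    hop = max(1, int(round(hop_s * fs)))
    nseg = min(nperseg, ep_data.shape[1])
    f, t, Z = sps.stft(ep_data, fs=fs, window="hann", nperseg=nseg,
                       noverlap=nseg - hop, boundary=None, padded=False)
    sel = (f >= fmin) & (f <= fmax)
    Z = Z[:, sel]
    power = np.abs(Z) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        phase = Z / np.maximum(np.abs(Z), 1e-30)
    return f[sel], t, power, phase


CELLS = [(s, c) for s in ("standard", "distractor", "target")
         for c in ("button", "pointing")]


def _map_on_full_montage(scalp_map, montage, full_montage, order=4, reg=1e-5):
    """Spherical-spline projection of a reduced-montage map onto the full one,
    so maps from subjects with different rejected channels share one space."""
    from .preprocess import _spline_g
    pg = montage.positions / np.linalg.norm(montage.positions, axis=1)[:, None]
    pf = full_montage.positions / np.linalg.norm(full_montage.positions,
                                                 axis=1)[:, None]
    ng = len(pg)
    A = np.zeros((ng + 1, ng + 1))
    A[:ng, :ng] = _spline_g(np.clip(pg @ pg.T, -1, 1), m=order) + reg * np.eye(ng)
    A[:ng, ng] = A[ng, :ng] = 1.0
    sol = np.linalg.solve(A, np.r_[scalp_map, 0.0])
    return _spline_g(np.clip(pf @ pg.T, -1, 1), m=order) @ sol[:ng] + sol[ng]


def compute_component_measures(decomp: ICADecomposition, events: EventList,
                               subject: str = "s0", montage=None,
                               head: HeadModel = DEFAULT_HEAD,
                               window=(-1.0, 2.0), baseline=(-0.2, 0.0),
                               spectrum_band=(3.0, 75.0), dipoles=None,
                               full_montage=None, min_trials: int = 5) -> list:
    """Clustering measures for every component of one decomposition.

    ``dipoles`` may pass precomputed :class:`DipoleModel` fits; otherwise the
    scalp maps are fitted here (requires ``montage``).  With ``full_montage``
    scalp maps are splined onto that montage so they are comparable across
    subjects with different rejected channels.  Every measure covers the fixed
    stimulus x condition grid; empty cells contribute zeros and a
    low-confidence flag.
    """
    eps = epoch_data(decomp.activations, events, fs=decomp.fs, window=window,
                     baseline=baseline, subject=subject)
    n_time = eps.data.shape[2] if eps.data.size else int(
        round((window[1] - window[0]) * decomp.fs))
    f0, t0, p0, _ = _tf_maps(np.zeros((1, n_time)), decomp.fs)
    tf_shape = p0.shape[1:]
    out = []
    for i in range(decomp.n_components):
        low = []
        erp_parts, ersp_parts, itc_parts = [], [], []
        for stim, cond in CELLS:
            sel = eps.select(stimulus=stim, condition=cond)
            cube = sel.data[:, i, :] if sel.data.size else np.empty((0, n_time))
            if cube.shape[0] < min_trials:
                low.append(f"{stim}:{cond}")
            if cube.shape[0] == 0:
                erp_parts.append(np.zeros(n_time))
                ersp_parts.append(np.zeros(tf_shape))
                itc_parts.append(np.zeros(tf_shape))
                continue
            erp_parts.append(cube.mean(axis=0))
            f, t, power, phase = _tf_maps(cube, eps.fs)
            mean_pow = power.mean(axis=0)                 # (freq, frames)
            pre = t + window[0] < 0
            base = np.maximum(mean_pow[:, pre].mean(axis=1, keepdims=True), 1e-30)
            ersp_parts.append(10 * np.log10(np.maximum(mean_pow, 1e-30) / base))
            itc_parts.append(np.abs(phase.mean(axis=0)))

        freqs, spec = sps.welch(decomp.activations[i], fs=decomp.fs,
                                nperseg=min(256, decomp.activations.shape[1]))
        fsel = (freqs >= spectrum_band[0]) & (freqs <= spectrum_band[1])
        dip = None
        if dipoles is not None:
            dip = dipoles[i]
        elif montage is not None:
            dip = fit_dipole(decomp.mixing[:, i], montage, head)
        smap = decomp.mixing[:, i].copy()
        if full_montage is not None and montage is not None \
                and len(full_montage) != len(montage):
            smap = _map_on_full_montage(smap, montage, full_montage)
        out.append(ComponentMeasures(
            ic_index=i, subject=subject,
            erp=np.concatenate(erp_parts),
            spectrum=np.log10(np.maximum(spec[fsel], 1e-30)),
            freqs=freqs[fsel],
            ersp=np.concatenate([e.ravel() for e in ersp_parts]),
            itc=np.concatenate([m.ravel() for m in itc_parts]),
            scalp_map=smap, dipole=dip, low_confidence=low))
    return out


def _pca_block(X, dims):
    n, d = X.shape
    dims_eff = min(dims, n, d)
    if dims_eff < dims:
        warnings.warn(f"reducing block to {dims_eff} dims (only {n} ICs)")
    if d <= dims_eff:
        return X.copy()
    return PCA(n_components=dims_eff, random_state=0).fit_transform(X)


def _znorm(X):
    sd = X.std(axis=0)
    return (X - X.mean(axis=0)) / np.where(sd > 1e-12, sd, 1.0)


def build_feature_vectors(measures, weights=None, pca_dims: int = 10) -> np.ndarray:
    """Joint cluster-position vectors from weighted, PCA-reduced measures."""
    weights = dict(weights or {})
    w_dip = weights.get("dipole", 25.0)
    w_ersp = weights.get("ersp", 10.0)
    w_def = weights.get("default", 1.0)
    if len(measures) < 2:
        raise ValueError("need at least two components to build feature vectors")

    blocks = []
    for name, w in (("erp", w_def), ("spectrum", w_def),
                    ("ersp", w_ersp), ("itc", w_def), ("scalp_map", w_def)):
        X = np.stack([np.asarray(getattr(m, name), float) for m in measures])
        blocks.append(w * _znorm(_pca_block(X, pca_dims)))
    dip = np.stack([m.dipole.position if m.dipole is not None else np.zeros(3)
                    for m in measures])
    blocks.append(w_dip * _znorm(dip))
    joint = np.hstack(blocks)
    out_dims = min(pca_dims, *joint.shape)
    if joint.shape[1] <= out_dims:
        return joint
    return PCA(n_components=out_dims, random_state=0).fit_transform(joint)


def cluster_components(vectors, k: int = 36, outlier_sd: float = 3.0,
                       seed: int = 0, subjects=None, dipole_positions=None,
                       ic_indices=None, n_restarts: int = 50) -> ClusterSolution:
    """K-means partition with outlier and one-component-per-subject rules.

    The input is canonicalized by lexicographic sort so the partition is
    invariant to component order.  After K-means (k-means++, ``n_restarts``
    restarts, fixed seed), components farther than mean + ``outlier_sd`` * SD
    of the within-cluster distance distribution from their nearest centroid
    move to the outlier cluster, then each cluster keeps only the component
    nearest its centroid per subject.
    """
    X = np.asarray(vectors, dtype=float)
    n = X.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the number of components ({n})")
    # without subject ids there is no one-per-subject constraint
    subjects = list(subjects) if subjects is not None \
        else [f"ic{i}" for i in range(n)]

    order = np.lexsort(X.T[::-1])
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels_sorted = km.fit_predict(X[order])
    assignment = np.empty(n, dtype=int)
    assignment[order] = labels_sorted
    centroids = km.cluster_centers_

    dist = np.linalg.norm(X - centroids[assignment], axis=1)
    thr = dist.mean() + outlier_sd * dist.std()
    assignment = np.where(dist > thr, OUTLIER, assignment)

    for c in range(k):
        idx = np.nonzero(assignment == c)[0]
        by_subj = {}
        for i in idx:
            by_subj.setdefault(subjects[i], []).append(i)
        for subj, members in by_subj.items():
            if len(members) > 1:
                keep = members[int(np.argmin([dist[i] for i in members]))]
                for i in members:
                    if i != keep:
                        assignment[i] = OUTLIER

    if dipole_positions is not None:
        dp = np.asarray(dipole_positions, float)
        centroid_dipole = np.stack([
            dp[assignment == c].mean(axis=0) if np.any(assignment == c)
            else np.full(3, np.nan) for c in range(k)])
    else:
        centroid_dipole = np.full((k, 3), np.nan)

    if ic_indices is None:
        ic_indices = np.arange(n)
    table = pd.DataFrame({"subject": subjects,
                          "ic_index": np.asarray(ic_indices, dtype=int),
                          "cluster": assignment})
    return ClusterSolution(assignment=assignment, centroids=centroids,
                           centroid_dipole=centroid_dipole,
                           group_label={}, k=k, ic_table=table)


def label_cluster_group(solution: ClusterSolution,
                        head: HeadModel = DEFAULT_HEAD) -> ClusterSolution:
    """Geometric group labels from centroid dipole positions."""
    labels = {}
    for c in range(solution.k):
        p = solution.centroid_dipole[c]
        labels[c] = "other" if np.any(~np.isfinite(p)) else head.region_of(p)
    solution.group_label = labels
    return solution
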