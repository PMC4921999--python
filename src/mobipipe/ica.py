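"""Blind source separation: extended infomax ICA with likelihood rejection.

The decomposition models the cleaned, average-referenced EEG as a square
linear mixture of maximally independent sources.  Training follows the
natural-gradient extended-infomax rule with automatic sub/super-Gaussian
switching; after one full pass, time windows whose model log-likelihood falls
more than ``reject_sigma`` standard deviations below the mean are excluded and
training continues for ``n_iter`` annealed passes on the retained samples.
Backprojection (mixing columns times activations) reconstructs the channel
contribution of any component subset exactly.

Average-referenced data are rank-deficient by one; the decomposition whitens
into the retained PCA subspace and records the reduction, so the full-set
backprojection still reproduces the input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import EEGRecording

__all__ = ["ICADecomposition", "fit_ica", "backproject", "apply_decomposition",
           "amari_index", "save_decomposition", "load_decomposition"]


@dataclass
class ICADecomposition:
    sphere: np.ndarray        # (r, C) whitening matrix
    unmixing: np.ndarray      # (r, r)
    mixing: np.ndarray        # (C, r), unit-norm columns
    activations: np.ndarray   # (r, N) on the full recording
    loglik_trace: list
    rejected_spans: list      # [start, end) training samples excluded
    channel_labels: list
    fs: float
    signs: np.ndarray = None  # +1 super-, -1 sub-Gaussian per component
    n_reduced: int = 0        # dimensions dropped by rank reduction

    @property
    def n_components(self):
        return self.unmixing.shape[0]

    def transform(self, data: np.ndarray) -> np.ndarray:
        d = data - data.mean(axis=1, keepdims=True)
        return self.unmixing @ (self.sphere @ d)


def _as_data(eeg):
    if isinstance(eeg, EEGRecording):
        return eeg.data, eeg.fs, list(eeg.montage.labels)
    data = np.asarray(eeg, dtype=float)
    return data, 1.0, [f"ch{i}" for i in range(data.shape[0])]


# normalizer of exp(-u^2/2) sech(u): integral over the real line
_LOG_Z_SUPER = 0.6195404611792522


def _loglik(W_logdet, u, signs):
    """Per-sample model log-likelihood under the extended-infomax densities.

    These are exactly the densities whose score functions the natural-gradient
    updates use: super-Gaussian p(u) = exp(-u^2/2) sech(u) / Z (score
    -u - tanh u) and sub-Gaussian the symmetric Gaussian mixture N(+-1, 1)
    (score -u + tanh u), so the training passes ascend this likelihood.
    """
    ll = np.full(u.shape[1], W_logdet)
    for i in range(u.shape[0]):
        ui = u[i]
        logcosh = np.logaddexp(ui, -ui) - np.log(2.0)
        if signs[i] > 0:
            ll += -ui ** 2 / 2.0 - logcosh - _LOG_Z_SUPER
        else:
            ll += -(ui ** 2 + 1.0) / 2.0 + logcosh - 0.5 * np.log(2 * np.pi)
    return ll


def _estimate_signs(u):
    """Sub/super-Gaussian switching criterion (sign of the kurtosis proxy)."""
    sech2 = 1.0 / np.cosh(np.clip(u, -20, 20)) ** 2
    k = sech2.mean(axis=1) * (u ** 2).mean(axis=1) - (u * np.tanh(u)).mean(axis=1)
    s = np.sign(k)
    s[s == 0] = 1.0
    return s


def fit_ica(eeg, n_iter: int = 10, reject_sigma: float = 4.0, seed: int = 0,
            l_rate: float = 0.1, block: int = 512, anneal: float = 0.9,
            reject_window: float = 1.0, extended_every: int = 1) -> ICADecomposition:
    """Extended-infomax decomposition with likelihood-based window rejection.

    One natural-gradient pass over the sphered data estimates an initial
    model; 1 s windows with mean log-likelihood below ``mean - reject_sigma *
    SD`` are then excluded and ``n_iter`` further annealed passes run on the
    retained samples.  Deterministic given ``seed``.
    """
    data, fs, labels = _as_data(eeg)
    C, N = data.shape
    if N < 20 * C * C:
        warnings.warn(f"only {N} samples for {C} channels; "
                      f"recommend >= {20 * C * C} for a stable decomposition")
    rng = np.random.default_rng(seed)
    X = data - data.mean(axis=1, keepdims=True)

    # PCA whitening with rank reduction
    cov = (X @ X.T) / N
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = evals > max(evals[0], 1e-300) * 1e-9
    r = int(keep.sum())
    sphere = (evecs[:, :r] / np.sqrt(evals[:r])).T  # (r, C)
    Xw = sphere @ X

    W = np.eye(r)
    signs = np.ones(r)
    lrate = l_rate
    eye = np.eye(r)
    max_w = 1e8
    loglik_trace = []

    def one_pass(Xt, W, lrate):
        idx = rng.permutation(Xt.shape[1])
        for s0 in range(0, len(idx) - block + 1, block):
            xb = Xt[:, idx[s0:s0 + block]]
            u = W @ xb
            y = np.tanh(u)
            grad = eye - (signs[:, None] * y) @ u.T / block - (u @ u.T) / block
            W = W + lrate * grad @ W
            if not np.all(np.isfinite(W)) or np.max(np.abs(W)) > max_w:
                raise FloatingPointError
        return W

    def guarded_pass(Xt, W, lrate):
        for _ in range(12):
            try:
                return one_pass(Xt, W.copy(), lrate), lrate
            except FloatingPointError:
                lrate *= 0.5
        raise RuntimeError("ICA diverged; learning rate annealing exhausted")

    # (1-2) initial pass on everything
    signs = _estimate_signs(W @ Xw[:, rng.choice(N, size=min(N, 20000), replace=False)])
    W, lrate = guarded_pass(Xw, W, lrate)

    # (3) likelihood-based window rejection
    u_all = W @ Xw
    sgn, logdet = np.linalg.slogdet(W)
    ll = _loglik(logdet, u_all, signs)
    wlen = max(1, int(round(reject_window * fs))) if fs > 1 else max(1, int(reject_window * 500))
    n_win = max(1, N // wlen)
    win_ll = np.array([ll[k * wlen:(k + 1) * wlen].mean() for k in range(n_win)])
    thr = win_ll.mean() - reject_sigma * win_ll.std()
    rejected_spans = [(k * wlen, min(N, (k + 1) * wlen))
                      for k in range(n_win) if win_ll[k] < thr]
    keep_mask = np.ones(N, dtype=bool)
    for s0, s1 in rejected_spans:
        keep_mask[s0:s1] = False
    Xt = Xw[:, keep_mask]

    # (4) annealed training on retained samples; each pass must not decrease
    # the mean log-likelihood (backtracking on the learning rate), so the
    # trace is monotone once the sub/super-Gaussian switching has settled
    def mean_ll(Wc):
        _, logdet = np.linalg.slogdet(Wc)
        return float(_loglik(logdet, Wc @ Xt, signs).mean())

    prev_ll = -np.inf
    for it in range(n_iter):
        if extended_every and it % extended_every == 0 and it < max(1, n_iter // 2):
            sub = rng.choice(Xt.shape[1], size=min(Xt.shape[1], 20000), replace=False)
            signs = _estimate_signs(W @ Xt[:, sub])
            prev_ll = mean_ll(W)
        state = rng.bit_generator.state
        cur_lr = lrate
        accepted = False
        for attempt in range(10):
            rng.bit_generator.state = state
            W_new, cur_lr = guarded_pass(Xt, W, cur_lr)
            cur_ll = mean_ll(W_new)
            if cur_ll >= prev_ll - 1e-12:
                accepted = True
                break
            cur_lr *= 0.5
        if accepted:
            W, prev_ll = W_new, cur_ll
        # else: keep the previous weights (trace stays flat at the optimum)
        loglik_trace.append(prev_ll)
        lrate = cur_lr * anneal

    unmix_full = W @ sphere            # (r, C)
    mixing = np.linalg.pinv(unmix_full)  # (C, r)
    # normalize: unit-norm mixing columns, positive extremum
    norms = np.linalg.norm(mixing, axis=0)
    flip = np.sign(mixing[np.argmax(np.abs(mixing), axis=0), np.arange(r)])
    scale = norms * flip
    mixing = mixing / scale
    W = W * scale[:, None]
    activations = (W @ sphere) @ X

    return ICADecomposition(sphere=sphere, unmixing=W, mixing=mixing,
                            activations=activations, loglik_trace=loglik_trace,
                            rejected_spans=rejected_spans,
                            channel_labels=labels, fs=fs, signs=signs,
                            n_reduced=C - r)


def backproject(decomp: ICADecomposition, component_subset,
                channel_subset=None) -> np.ndarray:
    """Channel-space contribution of a component subset.

    ``component_subset`` may be empty (zero signal).  Backprojection is linear:
    disjoint subsets sum to the union's backprojection, and the full set
    reconstructs the (mean-removed) input.
    """
    subset = list(component_subset)
    C = decomp.mixing.shape[0]
    if any(i < 0 or i >= decomp.n_components for i in subset):
        raise IndexError(f"component index out of range 0..{decomp.n_components - 1}")
    if not subset:
        out = np.zeros((C, decomp.activations.shape[1]))
    else:
        out = decomp.mixing[:, subset] @ decomp.activations[subset]
    if channel_subset is not None:
        out = out[list(channel_subset)]
    return out


def apply_decomposition(decomp: ICADecomposition, other_eeg) -> np.ndarray:
    """Compute activations on new data with the trained weights and sphere."""
    if isinstance(other_eeg, EEGRecording):
        labels = list(other_eeg.montage.labels)
        if labels != list(decomp.channel_labels):
            missing = set(decomp.channel_labels) ^ set(labels)
            raise ValueError(f"channel set mismatch: {sorted(missing)}")
        data = other_eeg.data
    else:
        data = np.asarray(other_eeg, dtype=float)
        if data.shape[0] != len(decomp.channel_labels):
            raise ValueError(
                f"expected {len(decomp.channel_labels)} channels, got {data.shape[0]}")
    return decomp.transform(data)


def save_decomposition(decomp: ICADecomposition, path) -> None:
    """Write a decomposition as raw float64 matrices plus a JSON sidecar."""
    import json
    from pathlib import Path
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    arrays = {"sphere": decomp.sphere, "unmixing": decomp.unmixing,
              "mixing": decomp.mixing, "activations": decomp.activations}
    meta = {"channel_labels": list(decomp.channel_labels), "fs": decomp.fs,
            "loglik_trace": list(map(float, decomp.loglik_trace)),
            "rejected_spans": [list(map(int, s)) for s in decomp.rejected_spans],
            "signs": None if decomp.signs is None else decomp.signs.tolist(),
            "n_reduced": int(decomp.n_reduced), "shapes": {}}
    for name, arr in arrays.items():
        a = np.ascontiguousarray(arr, dtype=np.float64)
        a.tofile(path / f"{name}.dat")
        meta["shapes"][name] = list(a.shape)
    with open(path / "ica.json", "w") as f:
        json.dump(meta, f, indent=2)


def load_decomposition(path) -> ICADecomposition:
    import json
    from pathlib import Path
    path = Path(path)
    with open(path / "ica.json") as f:
        meta = json.load(f)
    arrays = {name: np.fromfile(path / f"{name}.dat", dtype=np.float64)
              .reshape(shape) for name, shape in meta["shapes"].items()}
    return ICADecomposition(
        sphere=arrays["sphere"], unmixing=arrays["unmixing"],
        mixing=arrays["mixing"], activations=arrays["activations"],
        loglik_trace=meta["loglik_trace"],
        rejected_spans=[tuple(s) for s in meta["rejected_spans"]],
        channel_labels=meta["channel_labels"], fs=meta["fs"],
        signs=None if meta["signs"] is None else np.asarray(meta["signs"]),
        n_reduced=meta["n_reduced"])


def amari_index(A_est: np.ndarray, A_true: np.ndarray) -> float:
    """Permutation/scale-invariant mixing-recovery error in [0, 1]; 0 = perfect."""
    P = np.abs(np.linalg.pinv(A_est) @ A_true)
    K = P.shape[0]
    rows = (P.sum(axis=1) / P.max(axis=1) - 1).sum()
    cols = (P.sum(axis=0) / P.max(axis=0) - 1).sum()
    return float((rows + cols) / (2 * K * (K - 1)))
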