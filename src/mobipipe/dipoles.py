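"""Equivalent current dipole fitting for component scalp maps.

A single dipole in the spherical head model is fitted to each scalp map by a
coarse grid search over the sphere interior (moment solved by linear least
squares at each candidate position) followed by local simplex refinement.
Residual variance — the fraction of (average-referenced) map variance the
dipole model fails to explain — is the standard goodness-of-fit figure; maps
generated by compact cortical patches fit well, spatially complex myogenic
maps fit poorly.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .core import Montage
from .headmodel import DEFAULT_HEAD, HeadModel, leadfield

__all__ = ["DipoleModel", "fit_dipole"]

_GRID_CACHE = {}


@dataclass
class DipoleModel:
    position: np.ndarray
    moment: np.ndarray
    residual_variance: float
    inside_head: bool

    def __post_init__(self):
        if not 0.0 <= self.residual_variance <= 1.0 + 1e-9:
            raise ValueError("residual variance must lie in [0, 1]")


def _grid(montage: Montage, head: HeadModel, step: float, max_ecc: float):
    key = (hashlib.sha1(montage.positions.tobytes()).hexdigest(),
           head.radius, head.conductivity, step, max_ecc)
    if key in _GRID_CACHE:
        return _GRID_CACHE[key]
    R = head.radius
    ax = np.arange(-max_ecc, max_ecc + 1e-9, step) * R
    pts = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1).reshape(-1, 3)
    pts = pts[np.linalg.norm(pts, axis=1) <= max_ecc * R]
    G = leadfield(pts, montage.positions, head)          # (P, C, 3)
    G = G - G.mean(axis=1, keepdims=True)                # average reference
    pinv = np.linalg.pinv(G)                             # (P, 3, C)
    _GRID_CACHE[key] = (pts, G, pinv)
    return pts, G, pinv


def fit_dipole(scalp_map, montage: Montage, head: HeadModel = DEFAULT_HEAD,
               grid_step: float = 0.1, max_ecc: float = 0.95,
               refine: bool = True) -> DipoleModel:
    """Best-fitting equivalent dipole for one scalp map.

    The map and the model potentials are average-referenced before comparison,
    so fits are reference-invariant.  ``residual_variance`` is
    ``var(map - model) / var(map)`` across electrodes.
    """
    v = np.asarray(scalp_map, dtype=float)
    if v.ndim != 1 or len(v) != len(montage):
        raise ValueError("scalp map length must match montage")
    if len(v) < 16:
        raise ValueError("dipole fitting needs a map over at least 16 electrodes")
    v = v - v.mean()
    denom = float(v @ v)
    if denom < 1e-24:
        raise ValueError("degenerate scalp map (all electrodes equal)")

    pts, G, pinv = _grid(montage, head, grid_step, max_ecc)
    moments = np.einsum("pkc,c->pk", pinv, v)            # (P, 3)
    models = np.einsum("pck,pk->pc", G, moments)         # (P, C)
    resid = np.sum((models - v) ** 2, axis=1)
    best = int(np.argmin(resid))
    pos = pts[best]

    def batch_resid(cands):
        Gc = leadfield(cands, montage.positions, head, tol=1e-10)
        Gc = Gc - Gc.mean(axis=1, keepdims=True)
        mc = np.einsum("pkc,c->pk", np.linalg.pinv(Gc), v)
        rc = np.einsum("pck,pk->pc", Gc, mc) - v
        return np.sum(rc ** 2, axis=1)

    if refine:
        # multi-resolution local grid search, vectorized per level
        step = grid_step * head.radius
        offsets = np.stack(np.meshgrid(*[[-1, 0, 1]] * 3, indexing="ij"),
                           axis=-1).reshape(-1, 3)
        best_r = resid[best]
        for _ in range(5):
            step /= 3.0
            for _move in range(8):  # hill-climb at this resolution
                cands = pos + offsets * step
                cands = cands[np.linalg.norm(cands, axis=1) < max_ecc * head.radius]
                if not len(cands):
                    break
                r = batch_resid(cands)
                j = int(np.argmin(r))
                if r[j] >= best_r - 1e-18:
                    break
                best_r, pos = r[j], cands[j]
    Gp = leadfield(pos, montage.positions, head)
    Gp = Gp - Gp.mean(axis=0, keepdims=True)
    moment, *_ = np.linalg.lstsq(Gp, v, rcond=None)
    r = v - Gp @ moment
    rv = min(1.0, float(r @ r) / denom)
    return DipoleModel(position=np.asarray(pos, float), moment=moment,
                       residual_variance=rv,
                       inside_head=bool(np.linalg.norm(pos) < head.radius))
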