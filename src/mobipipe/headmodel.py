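"""Spherical head model: analytic dipole potentials and geometric source regions.

The head is modeled as a single homogeneous conducting sphere with an
insulating exterior.  The surface potential of a current dipole inside the
sphere has an exact Legendre-series solution, obtained by expanding the
monopole potential in spherical harmonics, enforcing a zero radial current at
the boundary, and differentiating with respect to the source position:

    V(r) = 1 / (4 pi sigma R^2) * sum_{n>=1} (b/R)^(n-1) *
           [ (2n+1) m_r P_n(c)  +  (2n+1)/n * m_t sin(gamma) P_n'(c) ]

with ``b`` the dipole eccentricity radius, ``m_r``/``m_t`` the radial and
tangential moment components (tangential taken in the plane spanned by the
dipole position and the electrode, towards the electrode), ``gamma`` the angle
between dipole position and electrode, and ``c = cos(gamma)``.  The series
converges geometrically in ``b/R`` and is summed to machine precision.

Geometric regions replace anatomical labels: *brain* is the interior shell
above the equatorial plane, *eye* two anterior-inferior balls, *neck* the
posterior-inferior surface band.  Coordinates are right-handed head-centered
meters: +x front, +y left, +z up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["HeadModel", "dipole_potential", "DEFAULT_HEAD"]

_MIN_ECC = 1e-12


@dataclass(frozen=True)
class HeadModel:
    """Homogeneous sphere with geometric source regions.

    Parameters
    ----------
    radius : sphere radius in meters (scalp surface).
    conductivity : bulk conductivity in S/m.
    brain_shell : eccentricity (fraction of radius) bounding brain sources.
    eye_centers / eye_radius : centers (fractions of radius) and radius of the
        two eye-region balls, anterior-inferior.
    neck_z_max : neck region lies below this z (fraction of radius) and behind
        the coronal plane (x < 0).
    """

    radius: float = 0.09
    conductivity: float = 0.33
    brain_shell: float = 0.85
    eye_centers: tuple = ((0.80, 0.30, -0.25), (0.80, -0.30, -0.25))
    eye_radius: float = 0.30
    neck_z_max: float = -0.30

    def inside(self, pos: np.ndarray) -> bool:
        return float(np.linalg.norm(pos)) < self.radius

    def region_of(self, pos) -> str:
        """Classify a source/centroid position into brain / eye / neck / other."""
        p = np.asarray(pos, dtype=float) / self.radius
        r = float(np.linalg.norm(p))
        for c in self.eye_centers:
            if np.linalg.norm(p - np.asarray(c)) < self.eye_radius:
                return "eye"
        if p[0] < 0.0 and p[2] < self.neck_z_max:
            return "neck"
        # brain shell extends marginally below the equator so the head center
        # and deep midline positions classify as brain
        if r < self.brain_shell and p[2] > -0.05:
            return "brain"
        return "other"


DEFAULT_HEAD = HeadModel()


def _legendre_series(f, cosg, sing, n_terms, tol=1e-13):
    """Accumulate the radial/tangential series coefficients a, b.

    f : (P,) eccentricities b/R in [0, 1).
    cosg, sing : (P, C) angle cosines/sines between dipole and electrodes.
    Returns (a, b) of shape (P, C): V = K * (a * m_r + b * m_t).
    """
    P_prev = np.ones_like(cosg)          # P_0
    P_cur = cosg.copy()                  # P_1
    dP_cur = np.ones_like(cosg)          # P_1'
    fpow = np.ones_like(f)               # f^(n-1)
    a = np.zeros_like(cosg)
    b = np.zeros_like(cosg)
    fmax = float(np.max(f)) if f.size else 0.0
    for n in range(1, n_terms + 1):
        coef = fpow[:, None]
        a += (2 * n + 1) * coef * P_cur
        b += ((2 * n + 1) / n) * coef * sing * dP_cur
        # recurrences for P_{n+1} and P_{n+1}'
        P_next = ((2 * n + 1) * cosg * P_cur - n * P_prev) / (n + 1)
        dP_next = dP_cur * cosg + (n + 1) * P_cur
        P_prev, P_cur, dP_cur = P_cur, P_next, dP_next
        fpow = fpow * f
        # geometric tail bound: remaining terms < ~3(n+2) f^n / (1-f)
        if n > 4 and (2 * n + 5) * fmax ** n / max(1e-16, 1.0 - fmax) < tol:
            break
    return a, b


def dipole_potential(dip_pos, dip_moment, elec_pos, head: HeadModel = DEFAULT_HEAD,
                     n_terms: int = 2000) -> np.ndarray:
    """Surface potential of current dipole(s) in the homogeneous sphere.

    Parameters
    ----------
    dip_pos : (3,) or (P, 3) dipole positions (m), strictly inside the sphere.
    dip_moment : matching (3,) or (P, 3) dipole moments (A*m); linear in moment.
    elec_pos : (C, 3) electrode positions, assumed on the sphere surface.

    Returns
    -------
    (C,) or (P, C) potentials in volts (scaled arbitrarily by moment units).
    """
    pos = np.atleast_2d(np.asarray(dip_pos, dtype=float))
    mom = np.atleast_2d(np.asarray(dip_moment, dtype=float))
    elec = np.asarray(elec_pos, dtype=float)
    R = head.radius
    b = np.linalg.norm(pos, axis=1)
    if np.any(b >= R):
        raise ValueError("dipole position outside the head sphere")
    f = b / R

    # unit radial direction; arbitrary for a central dipole (m_r uses it only
    # multiplied by f^0 terms where the decomposition is still exact in the
    # limit, handled by choosing the moment direction itself)
    with np.errstate(invalid="ignore", divide="ignore"):
        rhat = np.where(b[:, None] > _MIN_ECC, pos / np.maximum(b, _MIN_ECC)[:, None], 0.0)
    central = b <= _MIN_ECC
    if np.any(central):
        # for a central dipole the radial direction is taken along the moment,
        # making m_t = 0; the n=1 closed form is exact
        mnorm = np.linalg.norm(mom[central], axis=1)
        safe = np.where(mnorm[:, None] > 0, mom[central] / np.maximum(mnorm, 1e-300)[:, None], 0.0)
        rhat[central] = safe

    ehat = elec / np.linalg.norm(elec, axis=1)[:, None]
    cosg = np.clip(rhat @ ehat.T, -1.0, 1.0)            # (P, C)
    # tangential unit vector at each (dipole, electrode) pair:
    # t = (ehat - cosg * rhat) / sing
    sing = np.sqrt(np.clip(1.0 - cosg ** 2, 0.0, None))  # (P, C)
    m_r = np.einsum("pi,pi->p", mom, rhat)               # (P,)
    # m_t * sing = m . (ehat - cosg rhat)  -> fold sing into the series term
    m_dot_e = mom @ ehat.T                               # (P, C)
    mt_sing = m_dot_e - cosg * m_r[:, None]              # = m_t * sin(gamma)

    a, bser = _legendre_series(f, cosg, sing, n_terms)
    K = 1.0 / (4.0 * np.pi * head.conductivity * R ** 2)
    # bser already contains one factor of sin(gamma); divide it out and use
    # mt_sing so electrodes collinear with the dipole are handled exactly
    with np.errstate(invalid="ignore", divide="ignore"):
        b_over_sin = np.where(sing > 1e-12, bser / np.where(sing > 1e-12, sing, 1.0), 0.0)
    V = K * (a * m_r[:, None] + b_over_sin * mt_sing)
    if np.asarray(dip_pos).ndim == 1:
        return V[0]
    return V


def leadfield(dip_pos, elec_pos, head: HeadModel = DEFAULT_HEAD,
              tol: float = 1e-13) -> np.ndarray:
    """Leadfield matrix for unit moments along x, y, z.

    Returns (C, 3) for a single position or (P, C, 3) for a stack, so that
    ``leadfield(p, e) @ m == dipole_potential(p, m, e)``.  One series
    evaluation serves all three moment directions:
    V(m) = K * (a (m.rhat) + (b/sin) (m.ehat - cosg m.rhat)), hence the
    leadfield row is K * ((a - b/sin * cosg) rhat + (b/sin) ehat).
    """
    single = np.asarray(dip_pos).ndim == 1
    pos = np.atleast_2d(np.asarray(dip_pos, dtype=float))
    elec = np.asarray(elec_pos, dtype=float)
    R = head.radius
    b = np.linalg.norm(pos, axis=1)
    if np.any(b >= R):
        raise ValueError("dipole position outside the head sphere")
    f = b / R
    central = b <= _MIN_ECC
    # central dipoles handled exactly by the n=1 closed form
    rhat = np.where(central[:, None], 0.0,
                    pos / np.maximum(b, _MIN_ECC)[:, None])
    ehat = elec / np.linalg.norm(elec, axis=1)[:, None]
    cosg = np.clip(rhat @ ehat.T, -1.0, 1.0)
    sing = np.sqrt(np.clip(1.0 - cosg ** 2, 0.0, None))
    a, bser = _legendre_series(f, cosg, sing, 4000, tol=tol)
    K = 1.0 / (4.0 * np.pi * head.conductivity * R ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        b_over_sin = np.where(sing > 1e-12, bser / np.where(sing > 1e-12, sing, 1.0), 0.0)
    out = K * ((a - b_over_sin * cosg)[:, :, None] * rhat[:, None, :]
               + b_over_sin[:, :, None] * ehat[None, :, :])
    if np.any(central):
        out[central] = 3.0 * K * ehat[None, :, :]
    if single:
        return out[0]
    return out
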