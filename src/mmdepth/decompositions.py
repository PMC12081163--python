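"""Polarization-basic-parameter (PBP) systems derived from a Mueller matrix.

Five standard parameter families are computed:

* **MMPD** (Lu-Chipman polar decomposition): ``M = M_delta . M_R . M_D``
  giving diattenuation D, depolarization Delta, linear retardance delta
  and circular retardance psi.
* **MMCD** (Cloude coherency decomposition): eigenvalues of the Hermitian
  coherency matrix give purity indices P1..P3, PI, the depolarization
  index P_Delta and the polarization entropy S.
* **MMT** (Mueller-matrix transformation): direct element combinations
  t1, t2, t3, b and the normalized anisotropy A.
* **RIP** (rotation-invariant parameters): PL, PC, DL, DC, qL, rL.
* **GPSE** (global-polarization Stokes ellipsoid): the ellipsoid traced on
  the Poincare sphere by the images of all fully polarized input states;
  its axes and center give V, E, D_dagger, and the phase-delay statistics
  RA, RD, RS.

All functions expect an m11-normalized matrix (see :func:`mmdepth.core.normalize`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .core import MuellerMatrixError, as_mueller_array, coherency_matrix

__all__ = [
    "MMPDResult",
    "MMCDResult",
    "MMTResult",
    "RIPResult",
    "GPSEResult",
    "mmpd",
    "mmcd",
    "mmt",
    "rip",
    "gpse",
    "depolarization_index",
]

_EIG_CLIP_TOL = 1e-9


# ---------------------------------------------------------------------------
# MMPD — Lu–Chipman polar decomposition


@dataclass(frozen=True)
class MMPDResult:
    """Lu-Chipman factors and scalar parameters.

    ``M_delta @ M_R @ M_D`` reproduces the input matrix; D and Delta lie
    in [0, 1], delta in [0, 180] degrees.
    """

    M_delta: np.ndarray
    M_R: np.ndarray
    M_D: np.ndarray
    D: float
    Delta: float
    delta_deg: float
    psi_deg: float


def mmpd(M) -> MMPDResult:
    """Lu-Chipman polar decomposition ``M = M_delta . M_R . M_D``.

    The diattenuator is built from the first row, removed by inversion,
    and the remaining matrix split into depolarizer and retarder via the
    matrix square root of ``m' m'^T``.  Raises for ``D >= 1`` (the
    diattenuator is then singular); a near-singular depolarizer block is
    inverted by pseudo-inverse with a warning.
    """
    arr = as_mueller_array(M)
    Dvec = arr[0, 1:]
    D = float(np.linalg.norm(Dvec))
    if D >= 1.0:
        raise MuellerMatrixError(
            f"diattenuation D = {D:.6f} >= 1: diattenuator factor is not invertible"
        )
    eye3 = np.eye(3)
    if D < 1e-14:
        mD = eye3
    else:
        dhat = Dvec / D
        mD = np.sqrt(1 - D * D) * eye3 + (1 - np.sqrt(1 - D * D)) * np.outer(dhat, dhat)
    M_D = np.eye(4)
    M_D[0, 1:] = Dvec
    M_D[1:, 0] = Dvec
    M_D[1:, 1:] = mD

    Mp = arr @ np.linalg.inv(M_D)
    mp = Mp[1:, 1:]
    pol = Mp[1:, 0]

    mmT = mp @ mp.T
    lam = np.linalg.eigvalsh(mmT)  # ascending
    sq = np.sqrt(np.clip(lam, 0.0, None))
    s1, s2, s3 = sq[::-1]
    det = np.linalg.det(mp)
    sign = -1.0 if det < 0 else 1.0
    A = mmT + (s1 * s2 + s2 * s3 + s3 * s1) * eye3
    B = (s1 + s2 + s3) * mmT + s1 * s2 * s3 * eye3
    if np.linalg.cond(A) > 1e12:
        # fully depolarizing limit: m' ~ 0
        m_delta = np.zeros((3, 3))
    else:
        m_delta = sign * np.linalg.solve(A, B)
    M_delta = np.eye(4)
    M_delta[1:, 0] = pol
    M_delta[1:, 1:] = m_delta

    if np.linalg.norm(mp) < 1e-12:
        mR = eye3  # fully depolarized: retarder is indeterminate, take identity
    elif np.linalg.cond(m_delta) > 1e12:
        warnings.warn(
            "near-singular depolarizer block; retarder recovered by pseudo-inverse",
            stacklevel=2,
        )
        mR = np.linalg.pinv(m_delta) @ mp
    else:
        mR = np.linalg.solve(m_delta, mp)
    M_R = np.eye(4)
    M_R[1:, 1:] = mR

    Delta = 1.0 - abs(np.trace(m_delta)) / 3.0
    # linear retardance from the retarder's upper-left linear block
    arg = np.sqrt((mR[0, 0] + mR[1, 1]) ** 2 + (mR[1, 0] - mR[0, 1]) ** 2) - 1.0
    delta_deg = float(np.degrees(np.arccos(np.clip(arg, -1.0, 1.0))))
    psi_deg = float(0.5 * np.degrees(np.arctan2(mR[1, 0] - mR[0, 1], mR[0, 0] + mR[1, 1])))
    return MMPDResult(M_delta, M_R, M_D, D, float(Delta), delta_deg, psi_deg)


# ---------------------------------------------------------------------------
# MMCD — Cloude coherency decomposition


@dataclass(frozen=True)
class MMCDResult:
    """Coherency eigenvalues (descending) and derived purity parameters."""

    eigenvalues: np.ndarray
    P1: float
    P2: float
    P3: float
    PI: float
    PDelta: float
    S: float


def mmcd(M, tol: float = _EIG_CLIP_TOL) -> MMCDResult:
    """Cloude decomposition of the coherency matrix.

    Eigenvalues are sorted descending and sum to m11 (trace conservation).
    Small negative eigenvalues within ``tol`` are clipped to zero with a
    warning; larger ones raise, since the input is then unphysical.
    """
    arr = as_mueller_array(M)
    H = coherency_matrix(arr)
    lam = np.linalg.eigvalsh(H)[::-1].copy()
    m11 = arr[0, 0]
    if lam[-1] < -tol:
        raise MuellerMatrixError(
            f"coherency matrix has eigenvalue {lam[-1]:.3e} < -tol: unphysical input"
        )
    if lam[-1] < 0:
        warnings.warn("clipping small negative coherency eigenvalues", stacklevel=2)
        lam = np.clip(lam, 0.0, None)
    l1, l2, l3, l4 = lam
    P1 = (l1 - l2) / m11
    P2 = (l1 + l2 - 2 * l3) / m11
    P3 = (l1 + l2 + l3 - 3 * l4) / m11
    PI = np.sqrt((P1**2 + P2**2 + P3**2) / 3.0)
    PDelta = np.sqrt((2 * P1**2 + (2.0 / 3.0) * P2**2 + (1.0 / 3.0) * P3**2) / 3.0)
    p = lam / m11
    nz = p > 0
    S = float(-(p[nz] * (np.log(p[nz]) / np.log(4.0))).sum())
    return MMCDResult(lam, float(P1), float(P2), float(P3), float(PI), float(PDelta), S)


def depolarization_index(M) -> float:
    """Classical depolarization index sqrt((sum m_ij^2 - m11^2) / 3) / m11.

    Equals the MMCD ``PDelta`` parameter; kept as an independent
    cross-check route.
    """
    arr = as_mueller_array(M)
    return float(np.sqrt((np.sum(arr**2) - arr[0, 0] ** 2) / 3.0) / arr[0, 0])


# ---------------------------------------------------------------------------
# MMT — Mueller-matrix transformation parameters


@dataclass(frozen=True)
class MMTResult:
    t1: float
    t2: float
    t3: float
    b: float
    A: float


def mmt(M) -> MMTResult:
    """Element-combination anisotropy parameters t1, t2, t3, b and A.

    ``A = 2 b t1 / (b^2 + t1^2)`` is defined as 0 when ``b = t1 = 0``.
    t2 and t3 follow the printed element combinations
    ``t2 = |m21 + m31| / 2`` and ``t3 = sqrt(m42^2 + m43^2) / 2``; both
    carry low discriminating power and are screened out downstream.
    """
    m = as_mueller_array(M)
    t1 = 0.5 * np.hypot(m[1, 1] - m[2, 2], m[1, 2] + m[2, 1])
    t2 = 0.5 * abs(m[1, 0] + m[2, 0])
    t3 = 0.5 * np.hypot(m[3, 1], m[3, 2])
    b = 0.5 * (m[1, 1] + m[2, 2])
    denom = b * b + t1 * t1
    A = 0.0 if denom == 0 else 2.0 * b * t1 / denom
    return MMTResult(float(t1), float(t2), float(t3), float(b), float(A))


# ---------------------------------------------------------------------------
# RIP — rotation-invariant parameters


@dataclass(frozen=True)
class RIPResult:
    PL: float
    PC: float
    DL: float
    DC: float
    qL: float
    rL: float


def rip(M) -> RIPResult:
    """Rotation-invariant element combinations.

    PL/PC: linear/circular polarizance; DL/DC: linear/circular
    diattenuation; qL/rL: linear-circular conversion capabilities.
    """
    m = as_mueller_array(M)
    return RIPResult(
        PL=float(np.hypot(m[1, 0], m[2, 0])),
        PC=float(m[3, 0]),
        DL=float(np.hypot(m[0, 1], m[0, 2])),
        DC=float(m[0, 3]),
        qL=float(np.hypot(m[3, 1], m[3, 2])),
        rL=float(np.hypot(m[1, 3], m[2, 3])),
    )


# ---------------------------------------------------------------------------
# GPSE — global-polarization Stokes ellipsoid


@dataclass(frozen=True)
class GPSEResult:
    """Ellipsoid geometry and phase-delay statistics.

    Semi-axes sorted ``a >= b >= c``; V is the volume-equivalent radius
    (geometric mean of the axes, the polarization-maintaining ability), E
    the ellipticity, D_dagger the normalized center offset.  RA/RD/RS are
    the mean, variance and standardized skewness of the angle phi_k
    between each input polarization direction and its (intensity-
    normalized) output direction, in radians.
    """

    a: float
    b: float
    c: float
    center: np.ndarray
    V: float
    E: float
    D_dagger: float
    RA: float
    RD: float
    RS: float
    degenerate: bool


@lru_cache(maxsize=8)
def _sphere_grid_cached(n_states: int):
    pts, w = _sphere_grid(n_states)
    pts.setflags(write=False)
    w.setflags(write=False)
    return pts, w


def _sphere_grid(n_states: int, seed=None, jitter: bool = False):
    """Quasi-uniform states on the Poincare sphere with quadrature weights.

    Gauss-Legendre rings in S3 crossed with equispaced azimuths: the
    azimuthal symmetry makes sphere averages of smooth functions exact to
    spectral accuracy under frame rotations (which act as azimuth shifts).
    Optional seeded jitter randomizes the azimuth origin per ring.
    """
    n_rings = max(4, int(round(np.sqrt(n_states / 2.0))))
    n_az = max(8, int(np.ceil(n_states / n_rings)))
    nodes, wts = np.polynomial.legendre.leggauss(n_rings)
    phase = np.zeros(n_rings)
    if jitter:
        phase = np.random.default_rng(seed).uniform(0, 2 * np.pi, n_rings)
    az = 2 * np.pi * np.arange(n_az) / n_az
    cosb = nodes[:, None]
    sinb = np.sqrt(1 - nodes**2)[:, None]
    ang = az[None, :] + phase[:, None]
    pts = np.stack(
        [sinb * np.cos(ang), sinb * np.sin(ang), cosb * np.ones_like(ang)], axis=-1
    ).reshape(-1, 3)
    w = np.repeat(wts / (2.0 * n_az), n_az)  # normalized to sum 1
    return pts, w


def _fit_ellipsoid(p: np.ndarray, w: np.ndarray):
    """Weighted algebraic least-squares quadric fit x'Qx + b'x = 1.

    Returns (semi-axes descending, center).  Exact for points lying on an
    ellipsoid; for general clouds it is the least-squares ellipsoid.
    """
    x, y, z = p.T
    X = np.column_stack(
        [x * x, y * y, z * z, 2 * x * y, 2 * x * z, 2 * y * z, x, y, z]
    )
    XtW = X.T * w
    A = XtW @ X
    rhs = XtW.sum(axis=1)
    try:
        beta = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError:
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], sw, rcond=None)
    Q = np.array(
        [
            [beta[0], beta[3], beta[4]],
            [beta[3], beta[1], beta[5]],
            [beta[4], beta[5], beta[2]],
        ]
    )
    bvec = beta[6:]
    center = np.linalg.lstsq(Q, -0.5 * bvec, rcond=None)[0]
    scale = 1.0 + center @ Q @ center
    evals = np.linalg.eigvalsh(Q)
    with np.errstate(divide="ignore", invalid="ignore"):
        axes = np.sqrt(np.clip(scale / evals, 0.0, None))
    axes = np.where(np.isfinite(axes), axes, 0.0)
    return np.sort(axes)[::-1], center


def gpse(M, n_states: int = 2048, seed=None, jitter: bool = False, tol: float = 1e-9) -> GPSEResult:
    """Map quasi-uniform fully polarized states through M and fit the ellipsoid.

    Output states are intensity-normalized before fitting.  States whose
    output degree of polarization falls below ``tol`` are excluded from
    the phase-delay statistics.  A flat ellipsoid (``c < tol``) is
    reported with ``degenerate=True`` (axes still returned).
    """
    if n_states < 100:
        raise ValueError(f"n_states must be >= 100, got {n_states}")
    arr = as_mueller_array(M)
    if jitter:
        s, w = _sphere_grid(n_states, seed=seed, jitter=True)
    else:
        s, w = _sphere_grid_cached(n_states)
    S_in = np.column_stack([np.ones(len(s)), s])
    S_out = S_in @ arr.T
    with np.errstate(divide="ignore", invalid="ignore"):
        p = S_out[:, 1:] / S_out[:, :1]
    dop = np.linalg.norm(p, axis=1)
    if np.max(dop) < tol:
        center = np.average(p, axis=0, weights=w)
        return GPSEResult(0.0, 0.0, 0.0, center, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, True)
    axes, center = _fit_ellipsoid(p, w)
    a, b, c = axes
    V = float(np.cbrt(a * b * c))
    E = float(np.sqrt(max(0.0, 1.0 - (b * b + c * c) / (2 * a * a)))) if a > 0 else 0.0
    Dd = float(np.sqrt(3.0 * center @ center) / (a + b + c)) if a + b + c > 0 else 0.0

    ok = dop > tol
    if not np.any(ok):
        RA = RD = RS = 0.0
    else:
        u = p[ok] / dop[ok, None]
        cosphi = np.clip(np.einsum("ij,ij->i", u, s[ok]), -1.0, 1.0)
        phi = np.arccos(cosphi)
        wk = w[ok] / w[ok].sum()
        RA = float(np.sum(wk * phi))
        RD = float(np.sum(wk * (phi - RA) ** 2))
        RS = float(np.sum(wk * (phi - RA) ** 3) / RD**1.5) if RD > tol**2 else 0.0
    return GPSEResult(
        float(a), float(b), float(c), center, V, E, Dd, RA, RD, RS, bool(c < tol)
    )
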