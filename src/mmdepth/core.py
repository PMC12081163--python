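"""Core Mueller-matrix types, elementary optical-element builders and I/O.

A Mueller matrix is the 4x4 real matrix mapping input to output Stokes
vectors, ``S_out = M S_in``.  Throughout this package matrices are handled
m11-normalized (``m11 = 1``), which is the convention under which all
derived polarization parameters are defined.  Indices in documentation are
1-based (``m11 .. m44``, row-major), matching the standard polarimetry
literature; internal storage is a row-major ``(4, 4)`` float array.

Angles at API boundaries are degrees, counter-clockwise positive when
looking toward the light source.  The linear-retarder sign convention is
fixed by :func:`linear_retarder`: a quarter-wave plate at axis 0 deg maps
``S3 -> S2`` positively (``m34 = +sin(delta)``).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "MuellerMatrixError",
    "MuellerMatrix",
    "StokesVector",
    "MuellerImage",
    "as_mueller_array",
    "normalize",
    "is_physical",
    "coherency_matrix",
    "rotate_frame",
    "rotation_mueller",
    "linear_retarder",
    "rotator",
    "linear_diattenuator",
    "depolarizer",
    "make_element",
    "write_mueller_image",
    "read_mueller_image",
    "save_matrix_csv",
    "load_matrix_csv",
]

#: default tolerance on coherency eigenvalues for physical realizability
REALIZABILITY_TOL = 1e-9


class MuellerMatrixError(ValueError):
    """Raised for invalid or degenerate Mueller matrices."""


@dataclass(frozen=True)
class MuellerMatrix:
    """An m11-indexed 4x4 real Mueller matrix.

    Parameters
    ----------
    m : ndarray, shape (4, 4)
        Matrix elements, row-major ``m11 .. m44``.
    normalized : bool
        Whether the matrix has been divided by its ``m11`` element.
    """

    m: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        arr = np.asarray(self.m, dtype=float)
        if arr.shape != (4, 4):
            raise MuellerMatrixError(f"expected a 4x4 matrix, got shape {arr.shape}")
        object.__setattr__(self, "m", arr)

    def element(self, i: int, j: int) -> float:
        """Return ``m_ij`` with 1-based indices (``i, j`` in 1..4)."""
        if not (1 <= i <= 4 and 1 <= j <= 4):
            raise IndexError("Mueller indices are 1-based, in 1..4")
        return float(self.m[i - 1, j - 1])

    @property
    def m11(self) -> float:
        return float(self.m[0, 0])

    def __array__(self, dtype=None, copy=None):
        return np.array(self.m, dtype=dtype)


@dataclass(frozen=True)
class StokesVector:
    """Stokes vector (S0, S1, S2, S3); S0 is intensity in arbitrary units."""

    s: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.s, dtype=float)
        if arr.shape != (4,):
            raise ValueError(f"expected a 4-vector, got shape {arr.shape}")
        object.__setattr__(self, "s", arr)

    @property
    def intensity(self) -> float:
        return float(self.s[0])

    @property
    def dop(self) -> float:
        """Degree of polarization sqrt(S1^2+S2^2+S3^2)/S0."""
        if self.s[0] == 0:
            return np.nan
        return float(np.linalg.norm(self.s[1:]) / self.s[0])


@dataclass
class MuellerImage:
    """A per-pixel Mueller-matrix image.

    ``data`` has shape ``(height, width, 4, 4)``; the 16 planes
    ``data[..., i, j]`` share identical dimensions by construction.
    """

    data: np.ndarray
    wavelength_nm: float | None = None
    normalized: bool = True
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=np.float32)
        if arr.ndim != 4 or arr.shape[2:] != (4, 4):
            raise ValueError(f"expected (H, W, 4, 4) data, got shape {arr.shape}")
        self.data = arr

    @property
    def height(self) -> int:
        return self.data.shape[0]

    @property
    def width(self) -> int:
        return self.data.shape[1]


def as_mueller_array(M) -> np.ndarray:
    """Coerce a :class:`MuellerMatrix` or array-like to a (4, 4) float array."""
    if isinstance(M, MuellerMatrix):
        return M.m
    arr = np.asarray(M, dtype=float)
    if arr.shape != (4, 4):
        raise MuellerMatrixError(f"expected a 4x4 matrix, got shape {arr.shape}")
    return arr


def normalize(M) -> MuellerMatrix:
    """Divide every element by m11 and flag the matrix as normalized.

    Idempotent.  Raises :class:`MuellerMatrixError` when ``m11 <= 0``,
    since no passive medium has a non-positive unpolarized transmittance.
    """
    arr = as_mueller_array(M)
    m11 = arr[0, 0]
    if m11 <= 0:
        raise MuellerMatrixError(f"cannot normalize: m11 = {m11!r} is not positive")
    out = arr / m11
    if np.any(np.abs(out) > 1.0 + 1e-9):
        warnings.warn(
            "element magnitudes exceed m11; passive-medium bound violated "
            "(tolerable for noisy measurements)",
            stacklevel=2,
        )
    return MuellerMatrix(out, normalized=True)


# Pauli basis in Cloude's ordering: sigma0=I, sigma1=diag(1,-1),
# sigma2=antidiag(1,1), sigma3=antidiag(-i,i).
_PAULI = np.array(
    [
        [[1, 0], [0, 1]],
        [[1, 0], [0, -1]],
        [[0, 1], [1, 0]],
        [[0, -1j], [1j, 0]],
    ],
    dtype=complex,
)

# Precomputed 16x16 map from flattened M to flattened coherency matrix.
_COH_BASIS = np.stack(
    [np.kron(_PAULI[i], _PAULI[j].conj()) for i in range(4) for j in range(4)]
)


def coherency_matrix(M) -> np.ndarray:
    """Cloude coherency matrix ``H = 1/4 sum_ij m_ij sigma_i (x) sigma_j*``.

    Hermitian positive semi-definite exactly when M is physically
    realizable; its trace equals ``m11``.
    """
    arr = as_mueller_array(M)
    H = np.tensordot(arr.ravel(), _COH_BASIS, axes=(0, 0)) / 4.0
    return H


def is_physical(M, tol: float = REALIZABILITY_TOL) -> tuple[bool, float]:
    """Check physical realizability via the coherency-matrix eigenvalues.

    Returns ``(ok, min_eigenvalue)``; ``ok`` is true iff the smallest
    eigenvalue of the coherency matrix is ``>= -tol``.
    """
    H = coherency_matrix(M)
    lam_min = float(np.linalg.eigvalsh(H)[0])
    return lam_min >= -tol, lam_min


def rotation_mueller(theta_deg: float) -> np.ndarray:
    """Mueller rotation matrix R(theta) mixing (S1, S2) by angle 2*theta."""
    c, s = np.cos(2 * np.radians(theta_deg)), np.sin(2 * np.radians(theta_deg))
    return np.array(
        [
            [1, 0, 0, 0],
            [0, c, -s, 0],
            [0, s, c, 0],
            [0, 0, 0, 1],
        ]
    )


def rotate_frame(M, theta_deg: float) -> MuellerMatrix:
    """Rotate the sample frame: ``R(theta) M R(-theta)``.

    Rotation preserves m11, m44 and physical realizability; rotating by
    180 deg is the identity (the Mueller rotation acts through 2*theta).
    """
    normalized = M.normalized if isinstance(M, MuellerMatrix) else False
    arr = as_mueller_array(M)
    R = rotation_mueller(theta_deg)
    Rinv = rotation_mueller(-theta_deg)
    return MuellerMatrix(R @ arr @ Rinv, normalized=normalized)


def linear_retarder(retardance_deg: float, axis_deg: float = 0.0) -> MuellerMatrix:
    """Linear retarder with retardance ``delta`` and fast axis ``axis``.

    At axis 0 the matrix is block-diagonal with ``m34 = +sin(delta)``,
    ``m43 = -sin(delta)`` (so a quarter-wave plate maps S3 -> S2).
    """
    d = np.radians(retardance_deg)
    M0 = np.array(
        [
            [1, 0, 0, 0],
            [0, 1, 0, 0],
            [0, 0, np.cos(d), np.sin(d)],
            [0, 0, -np.sin(d), np.cos(d)],
        ]
    )
    return rotate_frame(MuellerMatrix(M0, normalized=True), axis_deg)


def rotator(rotation_deg: float) -> MuellerMatrix:
    """Circular retarder (optical rotator) rotating linear states by ``psi``."""
    return MuellerMatrix(rotation_mueller(rotation_deg), normalized=True)


def linear_diattenuator(q: float, axis_deg: float = 0.0) -> MuellerMatrix:
    """Linear diattenuator with diattenuation ``q`` in [0, 1] along ``axis``.

    Normalized to unit mean transmittance; ``q = 0`` is the identity and
    ``q = 1`` an ideal polarizer.
    """
    if not 0.0 <= q <= 1.0:
        raise MuellerMatrixError(f"diattenuation q must be in [0, 1], got {q}")
    r = np.sqrt(1.0 - q * q)
    M0 = np.array(
        [
            [1, q, 0, 0],
            [q, 1, 0, 0],
            [0, 0, r, 0],
            [0, 0, 0, r],
        ]
    )
    return rotate_frame(MuellerMatrix(M0, normalized=True), axis_deg)


def depolarizer(d1: float, d2: float, d3: float) -> MuellerMatrix:
    """Diagonal depolarizer ``diag(1, d1, d2, d3)``.

    ``d1, d2, d3`` are the principal transmittances of the three Stokes
    polarization components, each in [-1, 1]; ``(0, 0, 0)`` is the ideal
    depolarizer.  Physical realizability additionally requires the
    Cloude criterion, e.g. ``|d3| >= |d1 + d2| - 1``; the returned matrix
    is checked and an error raised for an unrealizable combination.
    """
    for d in (d1, d2, d3):
        if not -1.0 <= d <= 1.0:
            raise MuellerMatrixError(f"depolarizer transmittance {d} outside [-1, 1]")
    M = MuellerMatrix(np.diag([1.0, d1, d2, d3]), normalized=True)
    ok, lam = is_physical(M)
    if not ok:
        raise MuellerMatrixError(
            f"depolarizer diag(1, {d1}, {d2}, {d3}) is unrealizable "
            f"(coherency eigenvalue {lam:.3e})"
        )
    return M


def make_element(kind: str, **params) -> MuellerMatrix:
    """Build a standard optical element by name.

    ``kind`` is one of ``linear_retarder`` (params ``retardance_deg``,
    ``axis_deg``), ``rotator`` (``rotation_deg``), ``linear_diattenuator``
    (``q``, ``axis_deg``) or ``depolarizer`` (``d1``, ``d2``, ``d3``).
    """
    builders = {
        "linear_retarder": linear_retarder,
        "rotator": rotator,
        "linear_diattenuator": linear_diattenuator,
        "depolarizer": depolarizer,
    }
    if kind not in builders:
        raise MuellerMatrixError(
            f"unknown element kind {kind!r}; expected one of {sorted(builders)}"
        )
    return builders[kind](**params)


# ---------------------------------------------------------------------------
# container I/O

#: file contract: page k of the TIFF is element (i, j) with k = 4*i + j
#: (row-major m11 .. m44)
PIXEL_ORDER = "row-major m11..m44"


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def write_mueller_image(path, img: MuellerImage) -> None:
    """Write a 16-page float32 TIFF (pages m11..m44) plus a JSON sidecar."""
    path = Path(path)
    planes = np.transpose(img.data, (2, 3, 0, 1)).reshape(16, img.height, img.width)
    tifffile.imwrite(path, planes.astype(np.float32))
    meta = {
        "wavelength_nm": img.wavelength_nm,
        "normalized": img.normalized,
        "height": img.height,
        "width": img.width,
        "pixel_order": PIXEL_ORDER,
    }
    meta.update(img.metadata)
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


def read_mueller_image(path) -> MuellerImage:
    """Read a Mueller image written by :func:`write_mueller_image`.

    The round trip is lossless: all 16 float32 planes are reproduced
    bit-exactly.
    """
    path = Path(path)
    planes = tifffile.imread(path)
    if planes.ndim != 3 or planes.shape[0] != 16:
        raise MuellerMatrixError(
            f"expected a 16-page Mueller TIFF, got shape {planes.shape}"
        )
    h, w = planes.shape[1:]
    data = planes.reshape(4, 4, h, w).transpose(2, 3, 0, 1)
    meta = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    known = {k: meta.pop(k, None) for k in ("wavelength_nm", "normalized")}
    for k in ("height", "width", "pixel_order"):
        meta.pop(k, None)
    return MuellerImage(
        data,
        wavelength_nm=known["wavelength_nm"],
        normalized=bool(known["normalized"]) if known["normalized"] is not None else True,
        metadata=meta,
    )


def save_matrix_csv(path, M) -> None:
    """Write a single matrix as plain 4x4 CSV (no header)."""
    np.savetxt(path, as_mueller_array(M), delimiter=",", fmt="%.17g")


def load_matrix_csv(path, normalized: bool | None = None) -> MuellerMatrix:
    """Read a 4x4 CSV matrix; ``normalized`` defaults to ``m11 == 1``."""
    arr = np.loadtxt(path, delimiter=",")
    if normalized is None:
        normalized = bool(np.isclose(arr[0, 0], 1.0))
    return MuellerMatrix(arr, normalized=normalized)
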