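"""Depth-sensitive polarization feature parameters and per-cell feature tables.

Individual PBPs respond to the depth of a buried anisotropic layer with
either DOP-like (slow, monotone) or anisotropy-like (fast, saturating)
decay.  Combining the two families multiplicatively yields four
depth-sensitive polarization feature parameters (DSPFPs) with monotone
response over the whole working range:

    Ct   = Kc^2 / t1
    CtD  = (Kc / t1) * Delta
    RV   = RA * V
    RVD  = RA * V / (1 - D_dagger)

where ``Kc = |m44|`` is the circular polarization-maintaining ability,
``t1`` the MMT anisotropy magnitude, ``Delta`` the MMPD depolarization,
``RA`` (radians) the mean Poincare-sphere phase delay, ``V`` the GPSE
volume parameter and ``D_dagger`` the GPSE center offset.  Denominators
are floored at ``eps`` and such records flagged rather than raised, so
image pipelines never abort.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .core import MuellerImage, as_mueller_array, normalize
from .decompositions import gpse, mmcd, mmpd, mmt, rip

__all__ = [
    "kc",
    "compute_dspfp",
    "compute_features",
    "features_from_image",
    "FEATURE_COLUMNS",
    "PBP_COLUMNS",
    "DSPFP_COLUMNS",
]

#: stable column order of feature tables (the CSV contract)
PBP_COLUMNS = [
    # MMPD
    "D", "Delta", "delta", "psi",
    # MMCD
    "P1", "P2", "P3", "PI", "PDelta", "S",
    # GPSE
    "gpse_a", "gpse_b", "gpse_c", "V", "E", "Ddag", "RA", "RD", "RS",
    # MMT
    "t1", "t2", "t3", "b", "A",
    # RIP
    "PL", "PC", "DL", "DC", "qL", "rL",
    # raw elements
    "Kc", "m44",
]
DSPFP_COLUMNS = ["Ct", "CtD", "RV", "RVD"]
FEATURE_COLUMNS = PBP_COLUMNS + DSPFP_COLUMNS + ["flag"]

#: default floor for DSPFP denominators (normalized units)
EPS_DEFAULT = 1e-6


def kc(M) -> float:
    """Circular polarization-maintaining ability ``Kc = |m44|``."""
    return float(abs(as_mueller_array(M)[3, 3]))


def compute_dspfp(pbp: dict, eps: float = EPS_DEFAULT, kc_squared_in_ctd: bool = False) -> dict:
    """Derive the four DSPFPs from a PBP record.

    Requires keys ``Kc, t1, Delta, RA, V, Ddag`` (RA in radians).  Returns
    the input dict extended with ``Ct, CtD, RV, RVD`` and a ``flag`` field
    set when a denominator (t1 or 1 - D_dagger) had to be floored at
    ``eps``.  ``kc_squared_in_ctd`` switches CtD to the alternative
    reading ``(Kc^2 / t1) * Delta``.
    """
    out = dict(pbp)
    Kc, t1, Delta = out["Kc"], out["t1"], out["Delta"]
    RA, V, Ddag = out["RA"], out["V"], out["Ddag"]
    flag = False
    t1f = t1
    if t1f < eps:
        t1f = eps
        flag = True
    one_minus_d = 1.0 - Ddag
    if one_minus_d < eps:
        one_minus_d = eps
        flag = True
    out["Ct"] = Kc * Kc / t1f
    out["CtD"] = (Kc * Kc / t1f) * Delta if kc_squared_in_ctd else (Kc / t1f) * Delta
    out["RV"] = RA * V
    out["RVD"] = RA * V / one_minus_d
    out["flag"] = bool(flag or out.get("flag", False))
    return out


def compute_features(
    M, n_states: int = 2048, eps: float = EPS_DEFAULT, coherency_tol: float = 0.02
) -> dict:
    """All PBPs and DSPFPs for one (normalized) Mueller matrix.

    ``coherency_tol`` bounds how negative a coherency eigenvalue may be
    before the matrix is rejected; the default admits measurement-noise
    violations of physical realizability (clipped to zero) while still
    rejecting grossly unphysical inputs.
    """
    arr = as_mueller_array(M)
    rec: dict = {}
    pd_res = mmpd(arr)
    rec.update(D=pd_res.D, Delta=pd_res.Delta, delta=pd_res.delta_deg, psi=pd_res.psi_deg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cd = mmcd(arr, tol=coherency_tol)
    rec.update(P1=cd.P1, P2=cd.P2, P3=cd.P3, PI=cd.PI, PDelta=cd.PDelta, S=cd.S)
    gp = gpse(arr, n_states=n_states)
    rec.update(
        gpse_a=gp.a, gpse_b=gp.b, gpse_c=gp.c, V=gp.V, E=gp.E, Ddag=gp.D_dagger,
        RA=gp.RA, RD=gp.RD, RS=gp.RS,
    )
    mt = mmt(arr)
    rec.update(t1=mt.t1, t2=mt.t2, t3=mt.t3, b=mt.b, A=mt.A)
    rp = rip(arr)
    rec.update(PL=rp.PL, PC=rp.PC, DL=rp.DL, DC=rp.DC, qL=rp.qL, rL=rp.rL)
    rec["Kc"] = kc(arr)
    rec["m44"] = float(arr[3, 3])
    rec["flag"] = bool(gp.degenerate)
    return compute_dspfp(rec, eps=eps)


def features_from_image(
    img: MuellerImage | np.ndarray,
    grid: tuple[int, int] = (20, 20),
    n_states: int = 2048,
    eps: float = EPS_DEFAULT,
) -> pd.DataFrame:
    """Grid-average the Mueller image and compute one feature record per cell.

    The image is divided into ``grid = (rows, cols)`` cells; Mueller
    elements are averaged per cell *first* and the parameters computed on
    the averaged (re-normalized) matrix — averaging parameters themselves
    would not commute with the nonlinear definitions.  Trailing pixels
    that do not fill a cell are dropped with a warning.
    """
    data = img.data if isinstance(img, MuellerImage) else np.asarray(img, dtype=float)
    if data.ndim != 4 or data.shape[2:] != (4, 4):
        raise ValueError(f"expected (H, W, 4, 4) image data, got {data.shape}")
    h, w = data.shape[:2]
    rows, cols = grid
    ch, cw = h // rows, w // cols
    if ch == 0 or cw == 0:
        raise ValueError(f"grid {grid} exceeds image size {(h, w)}")
    if h % rows or w % cols:
        warnings.warn(
            f"image {(h, w)} not divisible by grid {grid}; trailing pixels dropped",
            stacklevel=2,
        )
    trimmed = data[: rows * ch, : cols * cw]
    cells = trimmed.reshape(rows, ch, cols, cw, 4, 4).mean(axis=(1, 3))
    records = []
    for r in range(rows):
        for c in range(cols):
            Mcell = normalize(cells[r, c]).m
            rec = compute_features(Mcell, n_states=n_states, eps=eps)
            rec["row"], rec["col"] = r, c
            records.append(rec)
    df = pd.DataFrame.from_records(records)
    return df[["row", "col"] + FEATURE_COLUMNS]


def feature_table_to_csv(df: pd.DataFrame, path) -> None:
    """Write a feature table with the documented stable column order."""
    cols = [c for c in df.columns if c not in FEATURE_COLUMNS and c not in ("row", "col")]
    order = [c for c in ("row", "col") if c in df.columns] + cols + [
        c for c in FEATURE_COLUMNS if c in df.columns
    ]
    df[order].to_csv(path, index=False)


def exclude_flagged(df: pd.DataFrame) -> pd.DataFrame:
    """Drop records whose DSPFP denominators were floored (default policy)."""
    if "flag" not in df.columns:
        return df
    return df[~df["flag"].astype(bool)].reset_index(drop=True)
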