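"""Synthetic tissue-phantom forward model and scene builders.

The physical scene emulated here is a depth-adjustable anisotropic fiber
layer (silk-like: birefringent, weakly diattenuating, preferentially
depolarizing the cross-fiber linear component) buried at depth ``d`` in
an isotropic scattering suspension of polystyrene microspheres in water.
The measured backscattering Mueller matrix is modelled as a two-path
mixture

    M(d) = (1 - w(d)) M_bg  +  w(d) M_path(d),     w(d) = exp(-2 mu_att d)

where ``M_bg`` is the background backscatter (an isotropic partial
depolarizer ``diag(1, b_L, b_L, b_C)``) and ``M_path`` carries the
fiber signature attenuated by depth: linear/circular DOP decay factors
``exp(-d/xi_L)``, ``exp(-d/xi_C)`` and fiber anisotropy (retardance,
diattenuation, differential depolarization) decaying as ``exp(-d/xi_A)``.
The ordering ``xi_A < xi_L < xi_C`` encodes the phenomenology of such
layered phantoms: anisotropy signatures decay fastest, linear DOP next,
and circular DOP most slowly (the circular polarization memory of large
Mie spheres).  The model is phenomenological — a weighted two-path
mixture, not radiative transport — and is constructed so that the
circular polarization-maintaining ability and the anisotropy parameters
respond monotonically (and oppositely) to depth over the 2-20 mm working
range, which is what makes the composite depth features well defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import (
    MuellerImage,
    MuellerMatrixError,
    depolarizer,
    is_physical,
    linear_diattenuator,
    linear_retarder,
    normalize,
    rotation_mueller,
)
from .depth import DepthMap, DepthSweepDataset
from .features import compute_features
from .mie import mie_efficiencies
from .polarimeter import (
    IntensityFrameStack,
    ModulationConfig,
    add_frame_noise,
    design_matrix,
    reconstruct,
    simulate_frames,
)

__all__ = [
    "SuspensionSpec",
    "PhantomParams",
    "Zone",
    "SceneSpec",
    "mie_mu_s",
    "layered_mueller",
    "generate_depth_sweep",
    "render_scene",
    "dsp1_scene",
    "dsp2_scene",
    "dip_scene",
]


# ---------------------------------------------------------------------------
# suspension optics


@dataclass(frozen=True)
class SuspensionSpec:
    """A polystyrene-microsphere suspension in water.

    ``diameters_um`` and ``volume_fractions`` are per component; indices
    default to polystyrene (1.587) and water (1.332) at 625 nm.
    """

    diameters_um: tuple[float, ...] = (5.0, 1.0)
    volume_fractions: tuple[float, ...] = (0.04, 0.001)
    wavelength_nm: float = 625.0
    n_sphere: float = 1.587
    n_medium: float = 1.332

    def __post_init__(self) -> None:
        if len(self.diameters_um) != len(self.volume_fractions):
            raise ValueError("diameters and volume fractions must pair up")
        for d in self.diameters_um:
            if d <= 0:
                raise ValueError(f"sphere diameter must be positive, got {d}")
        for f in self.volume_fractions:
            if not 0 <= f < 1:
                raise ValueError(f"volume fraction must be in [0, 1), got {f}")


def mie_mu_s(spec: SuspensionSpec) -> tuple[float, dict[float, float]]:
    """Total scattering coefficient (cm^-1) of the suspension, plus a
    per-component breakdown keyed by sphere diameter.

    Independent-scattering Mie: per component,
    ``mu_s = number_density * Qsca * pi r^2``
    which for a volume fraction f reduces to ``f * Qsca * 3 / (2 d)``.
    The size parameter uses the wavelength in the medium and the relative
    refractive index.  Volume fractions above ~10% violate the
    independent-scattering assumption and trigger a warning.
    """
    lam_um = spec.wavelength_nm / 1000.0
    m_rel = spec.n_sphere / spec.n_medium
    breakdown: dict[float, float] = {}
    for d_um, f in zip(spec.diameters_um, spec.volume_fractions):
        if f > 0.10:
            warnings.warn(
                f"volume fraction {f:.0%} is beyond the independent-scattering "
                "regime; dependent-scattering corrections are not applied",
                stacklevel=2,
            )
        if f == 0:
            breakdown[d_um] = 0.0
            continue
        x = np.pi * d_um * spec.n_medium / lam_um
        qsca = mie_efficiencies(m_rel, x)["Qsca"]
        mu_per_um = f * qsca * 3.0 / (2.0 * d_um)   # um^-1
        breakdown[d_um] = mu_per_um * 1e4           # cm^-1
    return sum(breakdown.values()), breakdown


# ---------------------------------------------------------------------------
# layered forward model


@dataclass(frozen=True)
class PhantomParams:
    """Parameters of the layered two-path forward model.

    Lengths in mm, angles in degrees.  Defaults encode the working
    phenomenology: anisotropy decay length ``xi_A`` shortest, linear DOP
    decay ``xi_L`` intermediate, circular DOP decay ``xi_C`` longest.

    ``fiber_jitter`` / ``background_jitter`` are relative (lognormal)
    per-cell spreads applied by the sweep/scene generators, emulating
    winding-density and suspension inhomogeneity across the field of
    view; ``noise_level`` is the multiplicative per-frame intensity noise
    routed through the instrument model.
    """

    fiber_retardance_deg: float = 1.5    # effective silk retardance at zero depth
    fiber_diattenuation: float = 0.06
    fiber_depol_split: float = 0.065      # differential (cross-fiber) depol, nepers
    fiber_orientation_deg: float = 0.0
    mu_att_mm: float = 0.005             # fiber-signal attenuation (w = exp(-2 mu d))
    xi_A_mm: float = 3.5                 # fast anisotropy decay length
    xi_A_slow_mm: float = 60.0           # residual anisotropy decay length
    aniso_slow_fraction: float = 0.30    # weight of the residual component
    xi_L_mm: float = 22.0                # linear DOP decay length
    xi_C_mm: float = 45.0                # circular DOP decay length
    bg_linear_dop: float = 0.10          # background backscatter linear DOP
    bg_circular_dop: float = 0.45        # background circular DOP (memory)
    noise_level: float = 0.01            # per-frame multiplicative intensity noise
    pixels_per_cell: int = 400           # detector pixels averaged into one cell
    noise_model: str = "gaussian"
    fiber_jitter: float = 0.05           # per-cell fiber-strength spread (lognormal)
    dop_jitter: float = 0.03             # per-cell linear/circular DOP spread
    weight_jitter: float = 0.10          # per-cell fiber-path weight spread
    background_jitter: float = 0.02
    kL_scale: float = 1.0                # per-cell multipliers set by the jitterer
    kC_scale: float = 1.0
    w_scale: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("xi_A_mm", "xi_L_mm", "xi_C_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.xi_A_mm < self.xi_L_mm < self.xi_C_mm:
            raise ValueError(
                "decay lengths must be ordered xi_A < xi_L < xi_C "
                f"(got {self.xi_A_mm}, {self.xi_L_mm}, {self.xi_C_mm})"
            )


def layered_mueller(depth_mm: float, params: PhantomParams | None = None) -> np.ndarray:
    """Normalized backscattering Mueller matrix of the layered phantom.

    Deterministic in (depth, params).  Raises when the parameter set
    produces an unphysical matrix, naming the offending coherency
    eigenvalue.
    """
    if params is None:
        params = PhantomParams()
    d = float(depth_mm)
    if d < 0:
        raise ValueError(f"depth must be >= 0 mm, got {d}")
    w = min(np.exp(-2.0 * params.mu_att_mm * d) * params.w_scale, 1.0)
    decay_A = np.exp(-d / params.xi_A_mm)
    # the anisotropy signature carries a fast component plus a weak
    # residual tail, so it decays sharply at shallow depth yet stays
    # resolvable (above the measurement floor) across the working range
    fs = params.aniso_slow_fraction
    decay_split = (1.0 - fs) * decay_A + fs * np.exp(-d / params.xi_A_slow_mm)
    kL = min(np.exp(-d / params.xi_L_mm) * params.kL_scale, 0.999)
    kC = min(np.exp(-d / params.xi_C_mm) * params.kC_scale, 0.999)
    delta = params.fiber_retardance_deg * decay_A
    q = min(params.fiber_diattenuation * decay_A, 1.0)
    split = params.fiber_depol_split * decay_split
    # realizability bound of diag(1, a, b, c): |a - b| <= 1 - c; the
    # differential linear depolarization a medium can express is limited
    # by how well it preserves circular DOP
    split_cap = -np.log1p(-(0.95 * (1.0 - kC)) / kL) if kL > 1.0 - kC else np.inf
    split = min(split, split_cap)

    # aligned linear component kL, cross-fiber component kL*exp(-split);
    # the companion realizability face a + b <= 1 + c caps how much
    # circular depolarization can coexist with well-preserved linear DOP
    b_lin = kL * np.exp(-split)
    kC = max(kC, kL + b_lin - 1.0 + 1e-9)
    depol = depolarizer(kL, b_lin, kC).m
    fiber = linear_retarder(delta, 0.0).m @ linear_diattenuator(q, 0.0).m
    R = rotation_mueller(params.fiber_orientation_deg)
    Rinv = rotation_mueller(-params.fiber_orientation_deg)
    M_path = R @ (depol @ fiber) @ Rinv

    M_bg = np.diag([1.0, params.bg_linear_dop, params.bg_linear_dop, params.bg_circular_dop])
    M = (1.0 - w) * M_bg + w * M_path
    M = normalize(M).m
    ok, lam = is_physical(M)
    if not ok:
        raise MuellerMatrixError(
            f"layered model at depth {d} mm is unphysical "
            f"(coherency eigenvalue {lam:.3e})"
        )
    return M


def _jittered(params: PhantomParams, rng: np.random.Generator) -> PhantomParams:
    """Per-cell parameter perturbation (lognormal, relative spreads).

    Three independent inhomogeneity channels: fiber winding density
    (scales the anisotropy signature), local scattering density (scales
    the linear and circular DOP amplitudes independently), and background
    backscatter DOPs.
    """
    fs = float(np.exp(params.fiber_jitter * rng.standard_normal())) if params.fiber_jitter else 1.0
    bs = float(np.exp(params.background_jitter * rng.standard_normal())) if params.background_jitter else 1.0
    if params.dop_jitter:
        kLs = float(np.exp(params.dop_jitter * rng.standard_normal()))
        kCs = float(np.exp(params.dop_jitter * rng.standard_normal()))
    else:
        kLs = kCs = 1.0
    return replace(
        params,
        fiber_retardance_deg=params.fiber_retardance_deg * fs,
        fiber_diattenuation=min(params.fiber_diattenuation * fs, 1.0),
        fiber_depol_split=params.fiber_depol_split * fs,
        bg_linear_dop=min(params.bg_linear_dop * bs, 1.0),
        bg_circular_dop=min(params.bg_circular_dop * bs, 1.0),
        kL_scale=params.kL_scale * kLs,
        kC_scale=params.kC_scale * kCs,
        w_scale=params.w_scale
        * (float(np.exp(params.weight_jitter * rng.standard_normal())) if params.weight_jitter else 1.0),
    )


def _measure_cells(
    matrices: np.ndarray,
    params: PhantomParams,
    rng: np.random.Generator,
    cfg: ModulationConfig,
    pixel_average: int = 1,
) -> np.ndarray:
    """Route true matrices through the instrument model with frame noise.

    ``matrices`` has shape (..., 4, 4); returns reconstructed normalized
    matrices of the same shape.  ``pixel_average`` is the number of
    detector pixels each simulated element aggregates: the noise on the
    averaged frame intensity shrinks by its square root.
    """
    stack = simulate_frames(matrices, cfg)
    if params.noise_level > 0:
        level = params.noise_level / np.sqrt(max(pixel_average, 1))
        stack = add_frame_noise(
            stack, model=params.noise_model, level=level,
            seed=rng.integers(2**31),
        )
    rec = reconstruct(stack)
    rec = rec.m[None] if not isinstance(rec, np.ndarray) else np.asarray(rec)
    if rec.ndim == 2:
        rec = rec[None]
    return rec / rec[..., :1, :1]


def generate_depth_sweep(
    params: PhantomParams | None = None,
    depth_grid=None,
    grid_cells: tuple[int, int] = (20, 20),
    repeats: int = 6,
    seed: int | None = None,
    n_states: int = 2048,
    return_images: bool = False,
):
    """Simulate the movable-layer experiment over a depth grid.

    For each depth and repeat, a ``grid_cells`` field of per-cell
    measurements is generated: per-cell parameter jitter, the layered
    forward model, the 30-frame instrument simulation with seeded noise,
    reconstruction, and the full feature record.  The record count is
    ``cells x depths x repeats`` (the default 20x20 x 10 x 6 = 24,000).
    Reproducible for a fixed ``seed``.

    Returns a :class:`DepthSweepDataset`; with ``return_images=True``
    also a dict ``(depth, repeat) -> MuellerImage`` of the per-cell
    (1 pixel per cell) reconstructed images.
    """
    if params is None:
        params = PhantomParams()
    if depth_grid is None:
        depth_grid = np.arange(2.0, 21.0, 2.0)
    depth_grid = np.asarray(depth_grid, dtype=float)
    rows, cols = grid_cells
    ncells = rows * cols
    rng = np.random.default_rng(params.seed if seed is None else seed)
    cfg = ModulationConfig()
    records = []
    images = {}
    for depth in depth_grid:
        for rep in range(repeats):
            mats = np.empty((ncells, 4, 4))
            for i in range(ncells):
                mats[i] = layered_mueller(depth, _jittered(params, rng))
            meas = _measure_cells(mats, params, rng, cfg, pixel_average=params.pixels_per_cell)
            if return_images:
                images[(float(depth), rep)] = MuellerImage(
                    meas.reshape(rows, cols, 4, 4), wavelength_nm=625.0
                )
            for i in range(ncells):
                rec = compute_features(meas[i], n_states=n_states)
                rec["depth"] = float(depth)
                rec["repeat"] = rep
                rec["row"], rec["col"] = divmod(i, cols)
                records.append(rec)
    table = pd.DataFrame.from_records(records)
    ds = DepthSweepDataset(table=table, depth_grid=depth_grid, repeats=repeats)
    return (ds, images) if return_images else ds


# ---------------------------------------------------------------------------
# scenes


@dataclass(frozen=True)
class Zone:
    """A scene zone: a rectangle or annulus at a fixed layer depth.

    ``shape`` is ``("rect", r0, r1, c0, c1)`` in fractional image
    coordinates, or ``("annulus", cy, cx, r_in, r_out)`` (fractional
    center and radii).  ``orientation_deg`` is a uniform fiber
    orientation, or the string ``"radial"`` for a divergent winding.
    """

    shape: tuple
    depth_mm: float
    orientation_deg: float | str = 0.0

    def mask(self, height: int, width: int) -> np.ndarray:
        yy, xx = np.mgrid[0:height, 0:width]
        fy, fx = (yy + 0.5) / height, (xx + 0.5) / width
        kind = self.shape[0]
        if kind == "rect":
            _, r0, r1, c0, c1 = self.shape
            return (fy >= r0) & (fy < r1) & (fx >= c0) & (fx < c1)
        if kind == "annulus":
            _, cy, cx, r_in, r_out = self.shape
            rr = np.hypot(fy - cy, fx - cx)
            return (rr >= r_in) & (rr < r_out)
        raise ValueError(f"unknown zone shape {kind!r}")

    def orientation_field(self, height: int, width: int) -> np.ndarray:
        if self.orientation_deg != "radial":
            return np.full((height, width), float(self.orientation_deg))
        yy, xx = np.mgrid[0:height, 0:width]
        fy, fx = (yy + 0.5) / height, (xx + 0.5) / width
        if self.shape[0] == "annulus":
            cy, cx = self.shape[1], self.shape[2]
        else:
            cy = 0.5 * (self.shape[1] + self.shape[2])
            cx = 0.5 * (self.shape[3] + self.shape[4])
        return np.degrees(np.arctan2(fy - cy, fx - cx))


@dataclass(frozen=True)
class SceneSpec:
    """Zone layout of a fixed-depth-gradient phantom scene."""

    zones: tuple[Zone, ...]
    height: int = 100
    width: int = 100
    grid: tuple[int, int] = (20, 20)

    def __post_init__(self) -> None:
        for z in self.zones:
            if not 0.0 <= z.depth_mm <= 25.0:
                raise ValueError(f"zone depth {z.depth_mm} mm outside the working range")


def dsp1_scene(zone1_depth_mm: float = 4.0, orientation_deg: float = 0.0, **kw) -> SceneSpec:
    """Three vertical-strip zones with a 2.5 mm depth gradient."""
    zones = tuple(
        Zone(("rect", 0.0, 1.0, i / 3, (i + 1) / 3), zone1_depth_mm + 2.5 * i, orientation_deg)
        for i in range(3)
    )
    return SceneSpec(zones=zones, **kw)


def dsp2_scene(zone1_depth_mm: float = 3.0, orientation_deg: float = 0.0, **kw) -> SceneSpec:
    """Four diagonally arranged quadrant zones, 2.5 mm gradient."""
    quads = [(0.0, 0.5, 0.0, 0.5), (0.0, 0.5, 0.5, 1.0), (0.5, 1.0, 0.5, 1.0), (0.5, 1.0, 0.0, 0.5)]
    zones = tuple(
        Zone(("rect", *q), zone1_depth_mm + 2.5 * i, orientation_deg)
        for i, q in enumerate(quads)
    )
    return SceneSpec(zones=zones, **kw)


def dip_scene(depth1_mm: float = 3.0, depth2_mm: float = 8.0, **kw) -> SceneSpec:
    """Two concentric annular zones with radially divergent fiber winding."""
    zones = (
        Zone(("annulus", 0.5, 0.5, 0.0, 0.25), depth1_mm, "radial"),
        Zone(("annulus", 0.5, 0.5, 0.25, 0.48), depth2_mm, "radial"),
    )
    return SceneSpec(zones=zones, **kw)


def render_scene(
    scene: SceneSpec,
    params: PhantomParams | None = None,
    seed: int | None = None,
    background_depth_mm: float = 25.0,
):
    """Render a scene to a measured Mueller image plus ground truth.

    Pixels outside every zone carry the background at
    ``background_depth_mm`` (effectively fiber-free).  Per-pixel
    orientation follows each zone's field (radial for divergent
    phantoms).  Returns ``(MuellerImage, truth DepthMap)`` where the
    truth map holds NaN outside zones and the zone-label array marks
    cells by 1-based zone index (majority label per grid cell).

    Jitter is applied per grid cell (matching the sweep generator) and
    measurement noise per pixel through the instrument model.
    """
    if params is None:
        params = PhantomParams()
    h, w = scene.height, scene.width
    rng = np.random.default_rng(seed)
    claimed = np.zeros((h, w), dtype=bool)
    labels_px = np.zeros((h, w), dtype=int)
    depth_px = np.full((h, w), float(background_depth_mm))
    truth_px = np.full((h, w), np.nan)
    orient_px = np.zeros((h, w))
    for idx, z in enumerate(scene.zones, start=1):
        m = z.mask(h, w)
        if (m & claimed).any():
            raise ValueError(f"zone {idx} overlaps an earlier zone")
        claimed |= m
        labels_px[m] = idx
        depth_px[m] = z.depth_mm
        truth_px[m] = z.depth_mm
        orient_px[m] = z.orientation_field(h, w)[m]

    rows, cols = scene.grid
    ch, cw = h // rows, w // cols
    cell_jitter = np.empty((rows, cols), dtype=object)
    for r in range(rows):
        for c in range(cols):
            cell_jitter[r, c] = _jittered(params, rng)
    mats = np.empty((h, w, 4, 4))
    for i in range(h):
        for j in range(w):
            p = cell_jitter[min(i // ch, rows - 1), min(j // cw, cols - 1)]
            p = replace(p, fiber_orientation_deg=float(orient_px[i, j]))
            mats[i, j] = layered_mueller(depth_px[i, j], p)
    # each rendered pixel aggregates a patch of detector pixels so that a
    # grid cell always integrates pixels_per_cell detector pixels in total
    patch = max(int(round(params.pixels_per_cell * rows * cols / (h * w))), 1)
    meas = _measure_cells(mats.reshape(-1, 4, 4), params, rng, ModulationConfig(), pixel_average=patch)
    img = MuellerImage(meas.reshape(h, w, 4, 4), wavelength_nm=625.0)

    # majority zone label per grid cell
    cell_labels = np.zeros((rows, cols), dtype=int)
    trimmed = labels_px[: rows * ch, : cols * cw].reshape(rows, ch, cols, cw)
    for r in range(rows):
        for c in range(cols):
            vals, counts = np.unique(trimmed[r, :, c, :], return_counts=True)
            cell_labels[r, c] = int(vals[np.argmax(counts)])
    truth_cells = np.full((rows, cols), np.nan)
    for idx, z in enumerate(scene.zones, start=1):
        truth_cells[cell_labels == idx] = z.depth_mm
    truth = DepthMap(depth=truth_cells, zone_labels=cell_labels)
    return img, truth
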