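# Methods

This note documents the models, conventions, parameter defaults and
numerical choices behind `mmdepth`, and what the synthetic phantom does
and does not emulate.

## Conventions

Mueller matrices are handled m11-normalized; indices are 1-based
(`m11 … m44`, row-major) in documentation and file metadata, 0-based in
storage.  Angles at API boundaries are degrees, counter-clockwise
positive looking toward the source.  The linear-retarder sign convention
is fixed by the axis-0 quarter-wave form `m34 = +sin δ`, `m43 = −sin δ`;
since no measurement standard is assumed, only convention-independent
quantities (retardance magnitudes, rotation-invariant combinations) are
asserted in tests.  Physical realizability is judged by the smallest
eigenvalue of the Cloude coherency matrix (Pauli ordering `σ0 = I`,
`σ1 = diag(1, −1)`, `σ2 = antidiag(1, 1)`, `σ3 = antidiag(−i, i)`);
the default tolerance is 1e−9 for exact matrices.  The passive-medium
bound `|m_ij| ≤ m11` is a warning, not an error, because measurement
noise routinely violates it.

## Instrument model

The dual-rotating-retarder polarimeter is modelled as polarizer +
quarter-wave plate on each arm, the plates stepping at a 1:5 ratio.  The
angle schedule defaults to 6° increments over 180° (30 frames); the
number of frames must be ≥ 25 to determine the 16 Mueller elements from
the Fourier harmonics implied by the 1:5 ratio.  Reconstruction inverts
the explicit 30×16 design matrix (rows `A_k ⊗ G_k`) by pseudo-inverse:
at the nominal schedule this is numerically equivalent to
Fourier-coefficient algebra (condition number ≈ 13, noiseless round-trip
error < 1e−12) and degrades gracefully for non-ideal schedules, raising
with the condition number when the schedule no longer determines all 16
elements.  Retardance errors of the wave plates are configuration
parameters for sensitivity studies; no self-calibration is implemented.
Frame noise is multiplicative Gaussian at 1 % by default — the error
class of a well-calibrated bench instrument — with a shot-noise-like
alternative.  1 % frame noise propagates to ≈ 0.01 RMS per Mueller
element for a single-pixel measurement; grid-cell averaging over 400
detector pixels reduces this to ≈ 5e−4.

## Parameter systems

- **Lu–Chipman (MMPD)**: the diattenuator is built from the first row,
  removed by inversion; the depolarizer comes from the matrix square
  root of `m′m′ᵀ` (sign from `det m′`), the retarder from
  `m_Δ⁻¹ m′`.  A fully depolarized residual (`‖m′‖ < 1e−12`) takes the
  identity retarder; a near-singular depolarizer block falls back to a
  pseudo-inverse with a warning.  The circular-retardance denominator
  uses `M_R(2,2) + M_R(3,3)` (the standard rotator form; printed
  renderings of this formula sometimes show a difference instead).
- **Cloude (MMCD)**: eigenvalues sorted descending; small negative
  eigenvalues are clipped at a tolerance (1e−9 for exact inputs; the
  feature pipeline admits up to 0.02 for noisy measured matrices).
  Entropy uses base-4 logarithms with `0·log 0 = 0`.  The classical
  depolarization index `√[(Σm_ij² − m11²)/3]` is kept as an independent
  cross-check of `P_Δ`.
- **MMT**: `t2 = ½|m21 + m31|` and `t3 = ½√(m42² + m43²)` follow the
  printed element combinations; both renderings are typographically
  ambiguous in the literature and both parameters carry little
  discriminating power here (they are screened out).  `A` is defined as
  0 when `b = t1 = 0`.
- **GPSE**: input states are sampled on a Gauss–Legendre-ring ×
  equispaced-azimuth grid (default 2048 states) rather than a Fibonacci
  lattice: frame rotations act on the Poincaré sphere as azimuth shifts,
  so with an azimuthally symmetric quadrature every GPSE statistic is
  rotation-invariant to spectral accuracy (measured ≈ 2e−8); a lattice
  without that symmetry leaves O(1/n) sampling error, far above the
  1e−6 the invariance properties demand.  Output states are
  intensity-normalized; the ellipsoid is the weighted algebraic
  least-squares quadric (exact for true ellipsoid clouds; for matrices
  with first-row diattenuation the cloud is not exactly an ellipsoid and
  the parameters are fit-based).  Phase delays `φ_k` are great-circle
  angles between input and normalized output polarization directions,
  in radians; states with output DOP below 1e−9 are excluded, and a flat
  ellipsoid (`c` below tolerance) is flagged degenerate rather than
  raised.

## Composite depth features

`Ct = Kc²/t1`, `CtΔ = (Kc/t1)·Δ`, `RV = RA·V`, `RVD = RA·V/(1−D†)`,
with `Kc = |m44|` and RA in radians.  `CtΔ` is implemented with the
first power of `Kc` as printed; a config switch exposes the `Kc²`
alternative reading.  Denominators are floored at `eps = 1e−6`
(normalized units) and floored records flagged — image pipelines must
not abort — and flagged records are excluded from training by default.
Grid-cell feature extraction averages the Mueller elements per cell
*before* computing parameters (averaging the nonlinear parameters
instead would not commute).

## Phantom simulator

The forward model is a phenomenological two-path mixture, not radiative
transport:

    M(d) = (1 − w(d))·M_bg + w(d)·M_path(d),      w(d) = exp(−2 μ_att d)

`M_bg = diag(1, b_L, b_L, b_C)` is the isotropic background backscatter;
`M_path` carries the fiber signature: a depolarizer
`diag(1, k_L, k_L e^{−s(d)}, k_C)` rotated to the fiber orientation and
composed with a linear retarder and diattenuator whose strengths decay
as `exp(−d/ξ_A)`.  The DOP factors decay as `k_L = exp(−d/ξ_L)`,
`k_C = exp(−d/ξ_C)` with `ξ_A < ξ_L < ξ_C`: anisotropy signatures decay
fastest, linear DOP next, circular DOP slowest — the circular
polarization memory of large Mie scatterers.  Two structural choices
matter:

- the fiber's anisotropy is carried mainly by a *differential
  (cross-fiber) linear depolarization* `s(d)` rather than a strong
  retarder.  A retarder strong enough to produce a usable `t1` rotates
  polarization states so much at shallow depth that the phase-delay
  statistic RA starts high and falls, destroying the monotonicity of
  `RA·V`; differential depolarization produces an order of magnitude
  less direction tilt per unit `t1`.  Realizability caps apply: for
  `diag(1, a, b, c)` the faces `|a − b| ≤ 1 − c` and `a + b ≤ 1 + c`
  bound how much linear anisotropy can coexist with preserved circular
  DOP, and the model enforces both explicitly (so arbitrary jittered
  parameter draws can never produce an unphysical matrix);
- `s(d)` has a fast component (`ξ_A = 3.5 mm`) plus a weak residual tail
  (30 % weight, 60 mm), so the anisotropy signal decays sharply at
  shallow depth — giving the anisotropy-sensitive features their shallow
  advantage — yet stays just above the measurement floor across the
  2–20 mm range.

Defaults (all configurable): fiber retardance 1.5°, diattenuation 0.06,
depolarization split 0.065, `μ_att = 0.005 mm⁻¹`, `ξ_L = 22 mm`,
`ξ_C = 45 mm`, background DOPs `b_L = 0.10`, `b_C = 0.45`.  These were
chosen once, by a numerical
design scan, to realize the qualitative phenomenology the pipeline is
built around — `Kc` and `t1` strictly decreasing, `Δ` strictly
increasing, and all four composite features strictly increasing over
2–20 mm on the noiseless forward curves — with comfortable margins, and
then frozen.

Per-cell inhomogeneity uses three independent lognormal channels:
fiber-strength jitter (5 %, winding density), linear/circular DOP
amplitude jitter (3 % each, scattering density), and fiber-path weight
jitter (10 %).  The weight channel is what separates the feature
groups: it perturbs the DOP parameters (`Δ, V, c`) and the raw
anisotropy (`t1`) strongly but nearly cancels in the ratio features
(`Kc²/t1`), so the composite-feature model retains accuracy where the
single-family models lose it.  Measurement noise is routed through the
instrument model at the cell level, scaled by the number of detector
pixels a cell aggregates (400 by default, matching a 400×400 detector
divided into a 20×20 grid).

**What the phantom does not emulate**: polarized photon transport (no
Monte Carlo; decay constants are effective, not derived from μs and g),
specular reflections from frames or container walls, spatial correlation
of inhomogeneity between neighbouring cells, multi-wavelength effects,
and absorbing spheres.  Passing pipeline tests therefore demonstrate the
*method* — parameter extraction, screening, feature construction,
regression and mapping — under a controlled surrogate of the reported
phenomenology, not quantitative agreement with any bench measurement.

## Suspension optics

`mie_mu_s` uses independent-scattering Lorenz–Mie theory: per component,
`μs = (f/V_sphere)·Qsca·πr² = f·Qsca·3/(2d)`, with the size parameter
taken in the medium and the relative refractive index (defaults:
polystyrene 1.587, water 1.332 at 625 nm; configurable, since suppliers'
values vary by a few parts per thousand).  Mie coefficients use the
Bohren–Huffman logarithmic-derivative downward recurrence, truncated at
the Wiscombe order, and are cross-checked in the test suite against an
independent Riccati–Bessel formulation built on scipy's spherical Bessel
functions and against the Rayleigh limit.  Volume fractions above 10 %
trigger an independent-scattering warning; no dependent-scattering
correction is applied.  For the default dual-component suspension (5 µm
at 4 %, 1 µm at 0.1 %) the computed total is ≈ 292 cm⁻¹, dominated by
the 5 µm component.

## Screening and regression

PCC is computed on per-depth means (one point per depth), matching the
per-depth-summary definitions of URI and RDS; raw-point correlation is
available by passing pre-collapsed series.  URI is reported as a width
in mm from the first grid depth; a constant response scores 0 (flagged)
and a response that never reaches 80 % of its total range scores the
full width (flagged).  For RDS, parameters are min-max normalized to
[−1, 1] before their per-depth standard deviations are accumulated, and
tied totals share the best rank.

Model presets follow the feature-group construction: `Mp` (DOP-sensitive
`Δ, V, c`), `MA` (anisotropy-sensitive `D†, RA, t1`), `MD` (composite
`Ct, CtΔ, RVD`), `MM` (the raw `m44` element).  Hyperparameters: SVR
with an RBF kernel on standardized features; k-NN with k = 5 (uniform
weights) on standardized features; polynomial regression of degree 3 —
all exposed.  Cross-validation shuffles uniformly (seeded, five folds,
no depth stratification); standardization is fitted inside each training
fold; R², RMSE and the per-depth MAE table are computed from pooled
out-of-fold predictions by the explicit residual-sum formulas, which are
cross-checked against scikit-learn in the tests.

Two statistical caveats, both consequences of the anisotropy signal
meeting the noise floor at depth, are worth knowing:

- `Ct` and `CtΔ` are ratio features with a heavy upper tail where `t1`
  is smallest; their per-depth *means* are tail-dominated, so monotone
  response on the noisy sweep is asserted on per-depth medians (the
  noiseless forward curves are strictly monotone for all four features),
  and `Ct`'s mean-based PCC is correspondingly low while `CtΔ`, `RV`
  and `RVD` all exceed 0.9;
- the capability ordering of the feature-group models
  (`MD ≤ Mp ≤ MA` in cross-validated RMSE, with the anisotropy model
  best at ≤ 8 mm and degrading fastest beyond) is established with the
  k-NN regressor, which is robust to those tails and is also the
  best-performing algorithm for the composite model; global fits (SVR,
  cubic polynomial) are sensitive to the few extreme `Ct` values and do
  not order reliably.

Zone statistics of predicted depth maps are computed over unflagged
cells only, with MAE against the per-zone ground truth.

## Known limitations

- `D†` is nearly degenerate in this phantom (the center offset requires
  diattenuation *and* depolarization; with the small fiber
  diattenuation the offset stays at the noise scale), so the anisotropy
  model effectively leans on `RA` and `t1`.
- GPSE parameters are fit-based, not closed-form, for diattenuating
  media (the output cloud is only approximately an ellipsoid).
- The polarimeter model is radiometrically ideal (no oblique-incidence
  geometry, no detector nonlinearity); calibration is limited to the
  round-trip self-check.
- Absolute error levels (RMSE ≈ 1.3–1.6 mm) are properties of the
  chosen jitter/noise budget, not predictions for any physical
  instrument; only the qualitative orderings and monotonicities are
  claimed.
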