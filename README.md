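# mmdepth — Mueller-matrix polarimetry depth sensing in turbid media

Locating fibrotic (anisotropic) tissue beneath an isotropic scattering
background is a recurring problem in polarimetric diagnostics: the deeper
a birefringent fiber layer sits, the fewer polarization-carrying photons
return from it, and the harder its depth is to read off any single
polarization parameter.  `mmdepth` implements an end-to-end, simulation-
driven pipeline for retrieving that depth from backscattering
Mueller-matrix images:

1. **Instrument model** — a dual-rotating-retarder (DRR) polarimeter:
   quarter-wave plates spinning at a 1:5 speed ratio modulate the
   polarization; the 4×4 Mueller matrix `M` is recovered from the 30
   recorded intensity frames by least-squares inversion of the modulation
   design (equivalent to the classical Fourier-coefficient extraction).
2. **Polarization basic parameters (PBPs)** — five standard systems
   computed from the m11-normalized matrix:
   - *Lu–Chipman polar decomposition* `M = M_Δ · M_R · M_D`: diattenuation
     `D`, depolarization `Δ`, linear retardance `δ`, circular retardance `ψ`;
   - *Cloude coherency decomposition*: eigenvalues `λ₁ ≥ … ≥ λ₄` of
     `H = ¼ Σ m_ij σᵢ ⊗ σⱼ*`, purity indices `P₁, P₂, P₃, PI`, the
     depolarization index `P_Δ`, and the polarization entropy
     `S = −Σ (λᵢ/m11) log₄(λᵢ/m11)`;
   - *Mueller-matrix transformation*: anisotropy parameters `t₁, t₂, t₃`,
     linear parameter `b`, normalized anisotropy `A = 2bt₁/(b²+t₁²)`;
   - *rotation-invariant parameters* `PL, PC, DL, DC, qL, rL`;
   - *global-polarization Stokes ellipsoid (GPSE)*: the ellipsoid traced on
     the Poincaré sphere by the images of all fully polarized states —
     semi-axes `a ≥ b ≥ c`, volume parameter `V = (abc)^⅓`, ellipticity
     `E`, center offset `D†`, and the phase-delay statistics `RA, RD, RS`.
3. **Depth-sensitive polarization feature parameters (DSPFPs)** —
   composites that pair a degree-of-polarization (DOP)-sensitive PBP with
   an anisotropy-sensitive one so the product responds monotonically over
   the whole working range:

       Ct = Kc²/t₁,   CtΔ = (Kc/t₁)·Δ,   RV = RA·V,   RVD = RA·V/(1−D†)

   with `Kc = |m44|`, the circular polarization-maintaining ability.
4. **Screening and regression** — candidate parameters are ranked by
   Pearson correlation with depth (PCC), unsaturated response interval
   (URI: depth span to reach 80 % of the total response change) and rank
   of data stability (RDS); screened feature groups train SVR / k-NN /
   polynomial regressors under five-fold cross-validation, scored by
   `R² = 1 − SS_res/SS_tot` and `RMSE`, and produce 2-D depth-resolved
   maps with per-zone mean and MAE statistics.
5. **Phantom simulator** — a layered two-path forward model of a
   silk-like fiber layer at adjustable depth (2–20 mm) in a polystyrene-
   microsphere suspension, including Mie scattering coefficients for the
   suspension, per-cell phantom inhomogeneity, and measurement noise
   routed through the instrument model.  Scene builders emulate stepped
   depth-gradient phantoms (uniform fiber orientation) and a radially
   wound, direction-insensitive phantom.

## Worked example

```python
import numpy as np
from mmdepth import (
    SuspensionSpec, mie_mu_s, generate_depth_sweep, train_model,
    dsp1_scene, render_scene, predict_depth_map,
)

# scattering coefficient of the background suspension
total, per_component = mie_mu_s(SuspensionSpec())
print(f"suspension mu_s = {total:.1f} cm^-1")

# simulate the movable-layer experiment and train the composite-feature model
sweep = generate_depth_sweep(grid_cells=(10, 10), repeats=3, seed=7)
model = train_model(sweep, "MD", algorithm="KNN", seed=7)
print(f"MD/KNN: cross-validated R^2 = {model.cv_r2:.3f}, RMSE = {model.cv_rmse:.2f} mm")

# depth-resolved imaging of a three-zone phantom scene
scene = dsp1_scene(zone1_depth_mm=4.0, height=40, width=40, grid=(8, 8))
img, truth = render_scene(scene, seed=1)
dm = predict_depth_map(model, img, grid=(8, 8),
                       zone_labels=truth.zone_labels,
                       zone_truth={1: 4.0, 2: 6.5, 3: 9.0})
print(dm.zone_stats[["true_depth", "mean_depth", "mae"]].round(2))
```

prints

```
suspension mu_s = 291.8 cm^-1
MD/KNN: cross-validated R^2 = 0.943, RMSE = 1.38 mm
      true_depth  mean_depth   mae
zone
1            4.0        4.18  0.35
2            6.5        7.07  0.76
3            9.0        8.92  1.08
```

The scattering coefficient is the independent-scattering Mie total for
5 µm spheres at 4 % and 1 µm spheres at 0.1 % volume fraction at 625 nm
(polystyrene n = 1.587 in water n = 1.332).  The cross-validated `R²` and
`RMSE` describe how well the composite-feature (DSPFP) model retrieves
the fiber-layer depth across the 2–20 mm sweep, and the zone table shows
the recovered mean depth and mean absolute error for the three zones of a
stepped-depth scene (2.5 mm gradient starting at 4 mm).

The same workflow is available from the shell:

```bash
mmdepth sweep --cells 10 10 --repeats 3 --seed 7 --out sweep.csv
mmdepth train --features sweep.csv --model MD --algo KNN --seed 7 --out model.json
mmdepth simulate --scene dsp1 --seed 1 --out scene.tif
mmdepth map --model model.json --mueller scene.tif --zones scene_zones.json --out depth.tif
```

## Layout

- `mmdepth.core` — Mueller/Stokes types, element builders, realizability
  checks, frame rotation, TIFF/CSV containers
- `mmdepth.polarimeter` — DRR forward model, frame noise, reconstruction
- `mmdepth.decompositions` — MMPD, MMCD, MMT, RIP, GPSE
- `mmdepth.features` — `Kc`, the four DSPFPs, grid-cell feature tables
- `mmdepth.depth` — PCC/URI/RDS screening, regression models, depth maps
- `mmdepth.mie`, `mmdepth.phantom` — Mie optics and the layered phantom
  simulator with scene builders
- `mmdepth.cli` — the `mmdepth` command

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
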