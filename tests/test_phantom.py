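import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from scipy.special import spherical_jn, spherical_yn

from mmdepth.core import is_physical, normalize
from mmdepth.decompositions import mmpd
from mmdepth.features import compute_features
from mmdepth.mie import mie_efficiencies, rayleigh_qsca
from mmdepth.phantom import (
    PhantomParams,
    SceneSpec,
    SuspensionSpec,
    Zone,
    dip_scene,
    dsp1_scene,
    dsp2_scene,
    generate_depth_sweep,
    layered_mueller,
    mie_mu_s,
    render_scene,
)

DEPTHS = np.arange(2.0, 21.0, 2.0)


def qsca_riccati_bessel(m: float, x: float) -> float:
    """Independent Mie oracle via scipy Riccati-Bessel functions.

    Valid for real relative index; entirely separate from the package's
    logarithmic-derivative recurrence.
    """
    nmax = int(np.ceil(x + 4.05 * x ** (1 / 3) + 2))
    n = np.arange(1, nmax + 1)
    mx = m * x
    jx = spherical_jn(n, x); jxp = spherical_jn(n, x, derivative=True)
    yx = spherical_yn(n, x); yxp = spherical_yn(n, x, derivative=True)
    jm = spherical_jn(n, mx); jmp = spherical_jn(n, mx, derivative=True)
    psi = x * jx; psip = jx + x * jxp
    chi = -x * yx; chip = -(yx + x * yxp)
    xi = psi - 1j * chi; xip = psip - 1j * chip
    psim = mx * jm; psimp = jm + mx * jmp
    a = (m * psim * psip - psi * psimp) / (m * psim * xip - xi * psimp)
    b = (psim * psip - m * psi * psimp) / (psim * xip - m * xi * psimp)
    return float(2 / x**2 * np.sum((2 * n + 1) * (np.abs(a) ** 2 + np.abs(b) ** 2)))


class TestMie:
    @pytest.mark.parametrize("x", [0.5, 2.0, 6.7, 13.4, 33.5])
    def test_against_riccati_bessel_oracle(self, x):
        m = 1.587 / 1.332
        assert mie_efficiencies(m, x)["Qsca"] == pytest.approx(
            qsca_riccati_bessel(m, x), rel=1e-8
        )

    def test_rayleigh_limit(self):
        m = 1.5
        x = 0.01
        assert mie_efficiencies(m, x)["Qsca"] == pytest.approx(
            rayleigh_qsca(m, x), rel=0.01
        )

    def test_zero_volume_fraction(self):
        spec = SuspensionSpec(diameters_um=(5.0,), volume_fractions=(0.0,))
        total, breakdown = mie_mu_s(spec)
        assert total == 0.0 and breakdown[5.0] == 0.0

    def test_total_is_sum_of_components(self):
        total, breakdown = mie_mu_s(SuspensionSpec())
        assert total == pytest.approx(sum(breakdown.values()))
        assert total > 0

    def test_dense_suspension_warns(self):
        spec = SuspensionSpec(diameters_um=(1.0,), volume_fractions=(0.2,))
        with pytest.warns(UserWarning, match="independent-scattering"):
            mie_mu_s(spec)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            SuspensionSpec(diameters_um=(0.0,), volume_fractions=(0.1,))
        with pytest.raises(ValueError):
            SuspensionSpec(diameters_um=(1.0, 2.0), volume_fractions=(0.1,))


class TestLayeredModel:
    def test_physical_across_depths(self):
        for d in np.arange(0.0, 26.0, 1.0):
            M = layered_mueller(d)
            assert is_physical(M, tol=1e-9)[0]

    def test_physical_under_jitter(self, rng):
        from mmdepth.phantom import _jittered

        p = PhantomParams()
        for d in (2.0, 8.0, 20.0):
            for _ in range(50):
                assert is_physical(layered_mueller(d, _jittered(p, rng)))[0]

    def test_deep_limit_is_background(self):
        p = PhantomParams(mu_att_mm=0.2)
        M = layered_mueller(200.0, p)
        bg = np.diag([1.0, p.bg_linear_dop, p.bg_linear_dop, p.bg_circular_dop])
        assert np.allclose(M, bg, atol=1e-6)

    def test_zero_depth_pure_fiber_retardance_recovered(self):
        p = PhantomParams(fiber_retardance_deg=18.0, fiber_diattenuation=0.2)
        r = mmpd(layered_mueller(0.0, p))
        assert r.delta_deg == pytest.approx(18.0, abs=1e-6)
        assert r.D == pytest.approx(0.2, abs=1e-9)

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            layered_mueller(-1.0)

    def test_misordered_decay_lengths_rejected(self):
        with pytest.raises(ValueError):
            PhantomParams(xi_L_mm=50.0, xi_C_mm=45.0)

    def test_kc_t1_decreasing_ct_increasing(self):
        feats = pd.DataFrame(
            [compute_features(layered_mueller(d), n_states=512) for d in DEPTHS],
            index=DEPTHS,
        )
        assert (np.diff(feats["Kc"]) < 0).all()
        assert (np.diff(feats["t1"]) < 0).all()
        assert (np.diff(feats["Ct"]) > 0).all()


class TestDepthSweep:
    def test_record_bookkeeping_small(self):
        ds = generate_depth_sweep(
            grid_cells=(2, 2), depth_grid=[2.0, 10.0], repeats=3, seed=1, n_states=512
        )
        assert len(ds) == 2 * 2 * 2 * 3
        assert set(ds.table["depth"]) == {2.0, 10.0}

    def test_single_record(self):
        ds = generate_depth_sweep(
            grid_cells=(1, 1), depth_grid=[6.0], repeats=1, seed=1, n_states=512
        )
        assert len(ds) == 1

    def test_seed_determinism(self):
        kw = dict(grid_cells=(2, 2), depth_grid=[4.0, 12.0], repeats=2, n_states=512)
        a = generate_depth_sweep(seed=9, **kw).table
        b = generate_depth_sweep(seed=9, **kw).table
        pd.testing.assert_frame_equal(a, b)

    def test_returned_images_match_grid(self):
        ds, imgs = generate_depth_sweep(
            grid_cells=(3, 2), depth_grid=[8.0], repeats=1, seed=2, n_states=512,
            return_images=True,
        )
        img = imgs[(8.0, 0)]
        assert (img.height, img.width) == (3, 2)


def test_closed_loop_recovery_within_noise_budget():
    """Measurement noise adds at most a modest factor over the
    inhomogeneity-limited retrieval floor for the composite-feature model."""
    from mmdepth.depth import train_model

    kw = dict(grid_cells=(6, 6), repeats=2, seed=5, n_states=512)
    noisy = generate_depth_sweep(PhantomParams(), **kw)
    quiet = generate_depth_sweep(replace(PhantomParams(), noise_level=0.0), **kw)
    rmse_noisy = train_model(noisy, "MD", algorithm="KNN", seed=5).cv_rmse
    rmse_floor = train_model(quiet, "MD", algorithm="KNN", seed=5).cv_rmse
    assert rmse_noisy < 3.0 * rmse_floor


class TestScenes:
    def test_dsp1_truth_has_three_depths(self):
        scene = dsp1_scene(zone1_depth_mm=4.0, height=30, width=30, grid=(6, 6))
        img, truth = render_scene(scene, seed=0)
        vals = np.unique(truth.depth[~np.isnan(truth.depth)])
        assert np.allclose(sorted(vals), [4.0, 6.5, 9.0])
        assert (img.height, img.width) == (30, 30)

    def test_dsp2_four_zones(self):
        scene = dsp2_scene(zone1_depth_mm=3.0, height=20, width=20, grid=(4, 4))
        _, truth = render_scene(scene, seed=0)
        assert len(np.unique(truth.zone_labels[truth.zone_labels > 0])) == 4

    def test_single_full_frame_zone_constant_truth(self):
        scene = SceneSpec(
            zones=(Zone(("rect", 0.0, 1.0, 0.0, 1.0), 6.0),), height=10, width=10,
            grid=(2, 2),
        )
        _, truth = render_scene(scene, seed=0)
        assert np.allclose(truth.depth, 6.0)

    def test_overlapping_zones_rejected(self):
        scene = SceneSpec(
            zones=(
                Zone(("rect", 0.0, 0.6, 0.0, 1.0), 4.0),
                Zone(("rect", 0.4, 1.0, 0.0, 1.0), 8.0),
            ),
            height=10, width=10,
        )
        with pytest.raises(ValueError, match="overlap"):
            render_scene(scene, seed=0)

    def test_out_of_range_zone_depth_rejected(self):
        with pytest.raises(ValueError):
            SceneSpec(zones=(Zone(("rect", 0, 1, 0, 1), 40.0),))

    def test_depth_map_closed_loop_on_dsp1(self):
        """A model trained on its own sweep recovers the zone depths of a
        rendered direction-sensitive scene."""
        from mmdepth.depth import predict_depth_map, train_model

        ds = generate_depth_sweep(grid_cells=(6, 6), repeats=2, seed=3, n_states=512)
        model = train_model(ds, "MD", algorithm="KNN", seed=3)
        scene = dsp1_scene(zone1_depth_mm=4.0, height=24, width=24, grid=(6, 6))
        img, truth = render_scene(scene, seed=4)
        zone_truth = {i + 1: z.depth_mm for i, z in enumerate(scene.zones)}
        dm = predict_depth_map(
            model, img, grid=(6, 6), zone_labels=truth.zone_labels,
            zone_truth=zone_truth, n_states=512,
        )
        assert dm.zone_stats is not None
        for z, row in dm.zone_stats.iterrows():
            assert abs(row["mean_depth"] - zone_truth[z]) < 1.5
        # deeper zones map deeper
        means = dm.zone_stats["mean_depth"]
        assert means.loc[1] < means.loc[2] < means.loc[3]

    def test_constant_depth_scene_near_constant_map(self):
        from mmdepth.depth import predict_depth_map, train_model

        ds = generate_depth_sweep(grid_cells=(6, 6), repeats=2, seed=3, n_states=512)
        model = train_model(ds, "MD", algorithm="KNN", seed=3)
        scene = SceneSpec(
            zones=(Zone(("rect", 0.0, 1.0, 0.0, 1.0), 8.0),), height=12, width=12,
            grid=(4, 4),
        )
        img, _ = render_scene(scene, seed=6)
        dm = predict_depth_map(model, img, grid=(4, 4), n_states=512)
        # per-cell spread is bounded by the retrieval error at this depth
        assert np.nanstd(dm.depth) < 1.5
        assert abs(np.nanmean(dm.depth) - 8.0) < 1.0

    def test_dip_orientation_insensitive_features(self):
        # radial winding: rotation-invariant features are uniform within a
        # zone despite the spatially varying fiber orientation
        scene = dip_scene(depth1_mm=4.0, depth2_mm=10.0, height=24, width=24, grid=(6, 6))
        p = replace(
            PhantomParams(),
            noise_level=0.0, fiber_jitter=0.0, dop_jitter=0.0,
            weight_jitter=0.0, background_jitter=0.0,
        )
        img, truth = render_scene(scene, p, seed=0)
        from mmdepth.features import features_from_image

        feats = features_from_image(img, grid=(6, 6), n_states=512)
        inner = feats[truth.zone_labels.ravel() == 1]
        # orientation varies across these cells, but Kc and Delta do not
        assert inner["Kc"].std() < 1e-3
        assert inner["Delta"].std() < 2e-3
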