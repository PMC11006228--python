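"""Synthetic phantom: determinism, optics, sectioning, bead validation."""

import numpy as np
import pytest

from microreg.barcode import default_pattern
from microreg.geometry import PlaneDecomposition, compose, map_points, plane_normal
from microreg.phantom import (
    LABEL_DERMIS,
    LABEL_EPIDERMIS,
    LABEL_GEL,
    NoBeadsError,
    Phantom,
    PhantomConfig,
    apply_bleach,
    bead_colocation_error,
    beads_in_section,
    make_phantom,
    simulate_sectioning,
)

from conftest import random_decomposition


class TestMakePhantom:
    def test_same_seed_bit_identical(self, small_phantom):
        cfg = small_phantom.config
        a_oct, a_fl, _ = make_phantom(cfg, seed=3)
        b_oct, b_fl, _ = make_phantom(cfg, seed=3)
        np.testing.assert_array_equal(a_oct.data, b_oct.data)
        np.testing.assert_array_equal(a_fl.data, b_fl.data)

    def test_different_seed_differs(self, small_phantom):
        cfg = small_phantom.config
        a_oct, _, _ = make_phantom(cfg, seed=3)
        b_oct, _, _ = make_phantom(cfg, seed=4)
        assert not np.array_equal(a_oct.data, b_oct.data)

    def test_layer_intensity_ordering(self, small_phantom):
        """At comparable depth: dermis brighter than epidermis brighter
        than gel."""
        vol = small_phantom.rasterize_oct()
        lab, origin, spacing = small_phantom.rasterize_labels()
        # compare at shallow depths only, before attenuation dominates
        xs = origin[0] + np.arange(lab.shape[0]) * spacing[0]
        ys = origin[1] + np.arange(lab.shape[1]) * spacing[1]
        xx, yy = np.meshgrid(xs, ys, indexing="ij")
        surf = small_phantom.surface_height(
            np.column_stack([xx.ravel(), yy.ravel()])).reshape(xx.shape)
        z = origin[2] + np.arange(lab.shape[2]) * spacing[2]
        depth = z[None, None, :] - surf[:, :, None]
        shallow = (depth > -80) & (depth < 120)
        means = {}
        for name, code in (("gel", LABEL_GEL), ("epi", LABEL_EPIDERMIS),
                           ("dermis", LABEL_DERMIS)):
            sel = (lab == code) & shallow
            means[name] = vol.data[sel].mean()
        assert means["dermis"] > means["epi"] > means["gel"]

    def test_attenuation_slope_matches_coefficient(self):
        """Mean log-intensity in the dermis decays at the configured
        attenuation rate (within 10%)."""
        cfg = PhantomConfig(
            extent=(300.0, 300.0, 500.0), voxel_size=2.0,
            surface_depth_mean=60.0, surface_amplitude=5.0,
            surface_detail_amplitude=0.0,
            epidermis_thickness_mean=40.0, epidermis_thickness_sd=2.0,
            ridge_amplitude=0.0, dermis_texture_amplitude=0.0,
            dermis_speckle_contrast=0.8, attenuation=0.004,
            bead_count=0, follicle_count=0, chunk_count=0,
            noise_floor=0.0, seed=2)
        ph = Phantom(cfg)
        vol = ph.rasterize_oct()
        lab, origin, spacing = ph.rasterize_labels()
        z = origin[2] + np.arange(lab.shape[2]) * spacing[2]
        prof = []
        zs_used = []
        for k, zk in enumerate(z):
            sel = lab[:, :, k] == LABEL_DERMIS
            if sel.sum() > 500 and 150 < zk < 400:
                prof.append(np.log(vol.data[:, :, k][sel].mean()))
                zs_used.append(zk)
        slope = np.polyfit(zs_used, prof, 1)[0]
        assert slope == pytest.approx(-cfg.attenuation, rel=0.10)


class TestApplyBleach:
    def test_total_fluorescence_decreases(self, small_phantom, pattern):
        fl = small_phantom.rasterize_fluor()
        bleached = apply_bleach(fl, pattern)
        assert bleached.data.sum() < fl.data.sum()

    def test_far_voxels_unchanged(self, small_phantom, pattern):
        fl = small_phantom.rasterize_fluor()
        bleached = apply_bleach(fl, pattern)
        xs = fl.origin[0] + np.arange(fl.shape[0]) * fl.spacing[0]
        ys = fl.origin[1] + np.arange(fl.shape[1]) * fl.spacing[1]
        xx, yy = np.meshgrid(xs, ys, indexing="ij")
        min_dist = np.full(xx.shape, np.inf)
        for p in pattern.planes:
            d = np.abs(np.cos(p.theta) * xx + np.sin(p.theta) * yy - p.d)
            min_dist = np.minimum(min_dist, d)
        far = min_dist > 3 * pattern.line_width
        np.testing.assert_allclose(bleached.data[far], fl.data[far],
                                   rtol=1e-7)

    def test_trough_centers_at_plane_offsets(self, pattern):
        from microreg.volume_ops import Volume
        vol = Volume(np.ones((1401, 1401, 3)), np.ones(3),
                     [-50.0, -50.0, 0.0])
        bleached = apply_bleach(vol, pattern)
        profile_x = bleached.data[:, 700, 0]
        xs = -50.0 + np.arange(1401)
        for p in pattern.planes:
            if p.theta != 0.0:
                continue
            sel = np.abs(xs - p.d) < 60
            argmin = xs[sel][np.argmin(profile_x[sel])]
            assert abs(argmin - p.d) <= 0.5


class TestSimulateSectioning:
    def test_noiseless_picks_on_lines(self, study_phantom, pattern):
        rng = np.random.default_rng(1)
        dec = random_decomposition(rng)
        obs, _, _, maps = simulate_sectioning(
            study_phantom, dec, pattern, pick_noise_sigma=0.0,
            picks_per_line=3, seed=5, extent=(3000.0, 500.0))
        from microreg.barcode import predict_section_lines
        pred = predict_section_lines(pattern, maps[0], (3000.0, 500.0))
        for line in obs[0].lines:
            dists = []
            for _, (a, b, c), _ in pred:
                d = np.abs(a * line.picks[:, 0] + b * line.picks[:, 1] + c)
                dists.append(d.max())
            assert min(dists) < 1e-9

    def test_consecutive_sections_offset_by_spacing_sy(self, study_phantom,
                                                       pattern):
        rng = np.random.default_rng(2)
        dec = random_decomposition(rng)
        obs, _, _, maps = simulate_sectioning(
            study_phantom, dec, pattern, n_sections=5, spacing=25.0,
            pick_noise_sigma=0.0, seed=6, extent=(3000.0, 500.0))
        assert len(maps) == 5
        n = plane_normal(maps[0])
        for a, b in zip(maps, maps[1:]):
            np.testing.assert_allclose((b.offset - a.offset) @ n,
                                       25.0 * dec.scales[1], atol=1e-9)

    def test_rendered_images_cover_extent(self, small_phantom, pattern):
        dec = PlaneDecomposition([0.8, 0.02, -0.02], [0.9, 0.9, 0.9],
                                 [0.0, 50.0, 0.0])
        obs, fl, he, maps = simulate_sectioning(
            small_phantom, dec, pattern, pick_noise_sigma=0.0, seed=7,
            extent=(400.0, 300.0), render=True, pixel_size=2.0)
        assert fl[0].data.shape == (150, 200)
        assert he[0].data.shape == (150, 200, 3)
        # bleached lines must darken the fluorescence rendering
        assert fl[0].data.min() < 0.2

    def test_bead_visibility_matches_slab_criterion(self, study_phantom,
                                                    pattern):
        """Beads visible in a section are exactly those whose center is
        within radius + half thickness of the plane (brute force)."""
        rng = np.random.default_rng(3)
        dec = random_decomposition(rng)
        _, _, _, maps = simulate_sectioning(
            study_phantom, dec, pattern, pick_noise_sigma=0.0, seed=8,
            extent=(3000.0, 500.0))
        truth = study_phantom.truth(lateral_step=4.0)
        thickness = 5.0
        r = study_phantom.config.bead_diameter / 2.0
        n = plane_normal(maps[0])
        expected = set()
        for i, c in enumerate(truth.bead_centers):    # brute force
            if abs((c - maps[0].offset) @ n) <= r + thickness / 2.0:
                expected.add(i)
        got = set(beads_in_section(truth, maps[0], thickness).tolist())
        assert got == expected


class TestBeadColocation:
    def _scene(self, seed=4):
        ph = Phantom(PhantomConfig(), seed=123)
        rng = np.random.default_rng(seed)
        truth = ph.truth(lateral_step=4.0)
        while True:
            dec = random_decomposition(rng)
            m = compose(dec)
            if len(beads_in_section(truth, m, 5.0)):
                return ph, truth, m

    def test_truth_input_bounded_by_slab_half_width(self):
        """With the true map, the error is each bead's out-of-plane
        offset, bounded by radius + half thickness."""
        ph, truth, m = self._scene()
        err = bead_colocation_error(truth, m, m, 5.0)
        assert 0 <= err <= ph.config.bead_diameter / 2.0 + 2.5 + 1e-9

    def test_normal_shift_adds_to_error(self):
        ph, truth, m = self._scene()
        n = plane_normal(m)
        base = bead_colocation_error(truth, m, m, 5.0)
        shifted = bead_colocation_error(truth, m, m.translated(10.0 * n), 5.0)
        # Pythagorean growth: sqrt(base² + 10²) when base is the
        # perpendicular residual
        assert shifted == pytest.approx(np.hypot(base, 10.0), rel=0.35)

    def test_matches_brute_force_recomputation(self):
        """Independent per-bead recomputation (explicit normal-equation
        projection) agrees to 1e-9."""
        ph, truth, m = self._scene(seed=9)
        rng = np.random.default_rng(10)
        m_est = compose(random_decomposition(rng))
        expected = []
        r = ph.config.bead_diameter / 2.0
        n = plane_normal(m)
        for c in truth.bead_centers:     # brute force oracle
            if abs((c - m.offset) @ n) > r + 2.5:
                continue
            a = m.linear
            uv = np.linalg.inv(a.T @ a) @ a.T @ (c - m.offset)
            pred = m_est.linear @ uv + m_est.offset
            expected.append(np.linalg.norm(pred - c))
        got = bead_colocation_error(truth, m, m_est, 5.0)
        assert got == pytest.approx(np.mean(expected), abs=1e-9)

    def test_no_beads_raises(self):
        ph = Phantom(PhantomConfig(bead_count=0), seed=1)
        truth = ph.truth(lateral_step=8.0)
        m = compose(PlaneDecomposition([0.8, 0, 0], [0.9, 0.9, 0.9],
                                       [0.0, 0.0, 0.0]))
        with pytest.raises(NoBeadsError):
            bead_colocation_error(truth, m, m, 5.0)


class TestInvalidConfig:
    def test_extent_too_small_rejected(self):
        with pytest.raises(ValueError):
            PhantomConfig(extent=(200.0, 200.0, 150.0))

    def test_subvoxel_bead_rejected(self):
        with pytest.raises(ValueError):
            PhantomConfig(voxel_size=20.0, bead_diameter=25.0)
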