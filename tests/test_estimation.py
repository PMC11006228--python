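"""Plane estimation: in-plane fit, depth resolution, stack fit, alignment."""

import numpy as np
import pytest

from microreg.barcode import InsufficientFiducialsError, match_lines
from microreg.estimation import (
    DepthUnresolvedError,
    RankDeficientError,
    SectionObservation,
    StackObservation,
    estimate_section,
    fine_align,
    fit_inplane,
    joint_stack_fit,
    masked_ncc,
    offset_sweep,
    resolve_depth,
)
from microreg.geometry import (
    PlaneMap,
    compose,
    cross_plane_error,
    map_points,
    plane_normal,
)
from microreg.phantom import simulate_sectioning
from microreg.volume_ops import HeightMap, Image2D, reslice

from conftest import random_decomposition

EXTENT = (3000.0, 500.0)


def _simulate(ph, pattern, dec, noise, seed, n_sections=1, **kw):
    obs, _, _, maps = simulate_sectioning(
        ph, dec, pattern, n_sections=n_sections, pick_noise_sigma=noise,
        picks_per_line=2, seed=seed, extent=EXTENT, **kw)
    for o in obs:
        labels, _ = match_lines(o.lines, pattern)
        for i, lab in labels.items():
            o.lines[i].label = lab
    return obs, maps


class TestFitInplane:
    def test_noiseless_recovery(self, study_phantom, pattern):
        rng = np.random.default_rng(0)
        dec = random_decomposition(rng)
        obs, maps = _simulate(study_phantom, pattern, dec, 0.0, 1,
                              contour_noise_sigma=0.0)
        partial = fit_inplane(obs[0], pattern)
        np.testing.assert_allclose(partial.linear2, maps[0].linear[:2, :],
                                   atol=1e-6)
        np.testing.assert_allclose(partial.offset2, maps[0].offset[:2],
                                   atol=1e-6)
        assert partial.residual_rms < 1e-6

    def test_single_family_rank_deficient(self, pattern):
        from microreg.barcode import ObservedLine
        lines = []
        for u in (100.0, 300.0, 800.0):
            line = ObservedLine([[u, 50.0], [u, 400.0]])
            lines.append(line)
        for line, lab in zip(lines, ("A0", "A1", "A2")):
            line.label = lab
        obs = SectionObservation("s", lines)
        with pytest.raises(RankDeficientError):
            fit_inplane(obs, pattern)

    def test_too_few_picks(self, pattern):
        from microreg.barcode import ObservedLine
        a = ObservedLine([[100.0, 50.0], [100.0, 400.0]])
        a.label = "A0"
        b = ObservedLine([[40.0, 50.0], [42.0, 400.0]])
        b.label = "B0"
        obs = SectionObservation("s", [a, b])
        with pytest.raises(InsufficientFiducialsError):
            fit_inplane(obs, pattern)

    def test_error_decreases_with_more_lines(self, study_phantom, pattern):
        """Median in-plane parameter error shrinks as picks are added
        (two vs four labeled lines per family)."""
        rng = np.random.default_rng(1)
        errs_few, errs_many = [], []
        for rep in range(40):
            dec = random_decomposition(rng)
            obs, maps = _simulate(study_phantom, pattern, dec, 10.0,
                                  100 + rep)
            full = obs[0]
            partial_many = fit_inplane(full, pattern)
            kept = []
            per_family = {"A": 0, "B": 0}
            for line in full.lines:
                fam = line.label[0]
                if per_family[fam] < 2:
                    kept.append(line)
                    per_family[fam] += 1
            few = SectionObservation(full.section_id, kept,
                                     full.top_contour)
            try:
                partial_few = fit_inplane(few, pattern)
            except (RankDeficientError, InsufficientFiducialsError):
                continue
            truth2 = maps[0].linear[:2, :]
            errs_many.append(
                np.abs(partial_many.linear2 - truth2).max())
            errs_few.append(np.abs(partial_few.linear2 - truth2).max())
        assert np.median(errs_many) < np.median(errs_few)


class TestResolveDepth:
    def test_flat_surface_depth_offset(self, pattern):
        """Canonical cut over a flat surface: t_z equals the surface
        height minus the contour's v position."""
        from microreg.estimation import PartialMap
        partial = PartialMap(np.array([[1.0, 0.0], [0.0, 0.0]]),
                             np.zeros(2), 0.0)
        surface = HeightMap(np.full((50, 50), 100.0), [20.0, 20.0],
                            [0.0, 0.0])
        contour = np.column_stack([np.linspace(0, 900, 20),
                                   np.zeros(20)])
        fit = resolve_depth(partial, surface, contour)
        assert "flat-surface-fallback" in fit.flags
        assert fit.plane_map.offset[2] == pytest.approx(100.0, abs=0.5)

    def test_no_surface_raises(self, pattern):
        from microreg.estimation import PartialMap
        partial = PartialMap(np.eye(2), np.zeros(2), 0.0)
        with pytest.raises(DepthUnresolvedError):
            resolve_depth(partial, None, np.zeros((5, 2)))

    def test_noiseless_full_recovery(self, study_phantom, pattern):
        """Noiseless picks + contour recover the plane to < 5 μm
        cross-plane error."""
        rng = np.random.default_rng(2)
        truth_surface = study_phantom.truth(lateral_step=2.0).surface
        for rep in range(10):
            dec = random_decomposition(rng)
            obs, maps = _simulate(study_phantom, pattern, dec, 0.0,
                                  200 + rep, contour_noise_sigma=0.0)
            fit = estimate_section(obs[0], pattern, truth_surface)
            assert cross_plane_error(maps[0], fit.plane_map,
                                     (1000.0, 500.0)) < 5.0


class TestJointStackFit:
    def test_single_section_falls_back(self, study_phantom, pattern):
        rng = np.random.default_rng(3)
        surface = study_phantom.truth(lateral_step=2.0).surface
        dec = random_decomposition(rng)
        obs, _ = _simulate(study_phantom, pattern, dec, 5.0, 7)
        stack = StackObservation(obs, 25.0)
        sf = joint_stack_fit(stack, pattern, surface)
        single = estimate_section(obs[0], pattern, surface)
        np.testing.assert_allclose(sf.section_maps[0].linear,
                                   single.plane_map.linear)
        np.testing.assert_allclose(sf.section_maps[0].offset,
                                   single.plane_map.offset)

    def test_recovered_spacing_scales_with_sy(self, study_phantom, pattern):
        """True spacing 25 μm with known s_y: consecutive normal offsets
        recover spacing · s_y."""
        rng = np.random.default_rng(4)
        surface = study_phantom.truth(lateral_step=2.0).surface
        dec = random_decomposition(rng)
        s_y = dec.scales[1]
        obs, _ = _simulate(study_phantom, pattern, dec, 3.0, 11,
                           n_sections=5)
        sf = joint_stack_fit(StackObservation(obs, 25.0), pattern, surface)
        assert sf.effective_spacing == pytest.approx(25.0 * s_y, abs=3.0)
        assert np.all(np.diff(sf.normal_offsets) > 0)

    def test_stack_fit_beats_single_sections(self, study_phantom, pattern):
        """Joint fitting over 5 sections reduces the cross-plane error
        spread relative to per-section fits."""
        rng = np.random.default_rng(5)
        surface = study_phantom.truth(lateral_step=2.0).surface
        joint_err, single_err = [], []
        for rep in range(25):
            dec = random_decomposition(rng)
            try:
                obs, maps = _simulate(study_phantom, pattern, dec, 10.0,
                                      300 + rep, n_sections=5)
            except Exception:
                continue
            sf = joint_stack_fit(StackObservation(obs, 25.0), pattern,
                                 surface)
            joint_err += [cross_plane_error(t, m, (1000.0, 500.0))
                          for t, m in zip(maps, sf.section_maps)]
            single_err += [
                cross_plane_error(
                    t, estimate_section(o, pattern, surface).plane_map,
                    (1000.0, 500.0))
                for t, o in zip(maps, obs)]
        assert np.std(joint_err) < np.std(single_err)


class TestFineAlign:
    @pytest.fixture(scope="class")
    def aligned_scene(self, study_phantom, pattern):
        rng = np.random.default_rng(6)
        dec = random_decomposition(rng)
        obs, maps = _simulate(study_phantom, pattern, dec, 10.0, 13)
        m_true = maps[0]
        origin = np.array([900.0, 50.0])
        window = (600.0, 400.0)
        m_true_w = PlaneMap(m_true.linear,
                            m_true.offset + m_true.linear @ origin)
        corners = np.array([[0, 0], [window[0], 0],
                            [0, window[1]], [window[0], window[1]]], float)
        pts = map_points(m_true_w, corners)
        region = [(pts[:, a].min() - 80, pts[:, a].max() + 80)
                  for a in range(3)]
        vol = study_phantom.rasterize_oct(voxel_size=4.0, region=region)
        reference = reslice(vol, m_true_w, window, 4.0)
        return vol, reference, m_true_w, window

    def test_truth_is_stable_fixed_point(self, aligned_scene):
        vol, reference, m_true_w, window = aligned_scene
        refined, score, flags = fine_align(m_true_w, vol, reference,
                                           max_shift=20.0, extent=window)
        assert cross_plane_error(m_true_w, refined, window) < 2.0
        assert score > 0.95

    def test_normal_offset_recovered(self, aligned_scene):
        vol, reference, m_true_w, window = aligned_scene
        n = plane_normal(m_true_w)
        shifted = m_true_w.translated(20.0 * n)
        before = cross_plane_error(m_true_w, shifted, window)
        refined, _, _ = fine_align(shifted, vol, reference,
                                   max_shift=30.0, extent=window)
        after = cross_plane_error(m_true_w, refined, window)
        assert after < before

    def test_featureless_reference_returns_initial(self, aligned_scene):
        vol, _, m_true_w, window = aligned_scene
        flat = Image2D(np.ones((100, 150)), 4.0)
        refined, score, flags = fine_align(m_true_w, vol, flat,
                                           extent=window)
        assert "featureless-reference" in flags
        np.testing.assert_array_equal(refined.linear, m_true_w.linear)
        np.testing.assert_array_equal(refined.offset, m_true_w.offset)


class TestOffsetSweep:
    def test_zero_offset_equals_direct_reslice(self, small_phantom):
        vol = small_phantom.rasterize_oct(voxel_size=4.0)
        m = PlaneMap(np.array([[1.0, 0.0], [0.0, 0.0], [0.0, 1.0]]),
                     [0.0, 200.0, 0.0])
        direct = reslice(vol, m, (300.0, 300.0), 4.0)
        swept = offset_sweep(vol, m, [0.0], (300.0, 300.0), 4.0)
        np.testing.assert_array_equal(swept[0].data, direct.data)

    def test_symmetric_offsets_symmetric_planes(self, small_phantom):
        vol = small_phantom.rasterize_oct(voxel_size=4.0)
        m = PlaneMap(np.array([[1.0, 0.0], [0.0, 0.0], [0.0, 1.0]]),
                     [0.0, 200.0, 0.0])
        n = plane_normal(m)
        for off in (10.0, 25.0):
            lo = m.translated(-off * n)
            hi = m.translated(+off * n)
            mid_lo = 0.5 * (lo.offset + hi.offset)
            np.testing.assert_allclose(mid_lo, m.offset, atol=1e-12)

    def test_ncc_peaks_at_true_plane(self, study_phantom, pattern):
        """Parallel planes ±25 μm away decorrelate from the true
        section; NCC against the true section peaks at offset 0."""
        rng = np.random.default_rng(8)
        dec = random_decomposition(rng)
        obs, maps = _simulate(study_phantom, pattern, dec, 0.0, 17)
        m = maps[0]
        origin = np.array([900.0, 50.0])
        window = (600.0, 400.0)
        m_w = PlaneMap(m.linear, m.offset + m.linear @ origin)
        corners = np.array([[0, 0], [window[0], 0],
                            [0, window[1]], [window[0], window[1]]], float)
        pts = map_points(m_w, corners)
        region = [(pts[:, a].min() - 80, pts[:, a].max() + 80)
                  for a in range(3)]
        vol = study_phantom.rasterize_oct(voxel_size=4.0, region=region)
        true_img = reslice(vol, m_w, window, 4.0)
        sweeps = offset_sweep(vol, m_w, [-25.0, 0.0, 25.0], window, 4.0)
        scores = [masked_ncc(img, true_img) for img in sweeps]
        assert np.argmax(scores) == 1
        assert scores[1] > scores[0] + 0.1
        assert scores[1] > scores[2] + 0.1
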