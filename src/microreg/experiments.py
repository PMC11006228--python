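"""Monte-Carlo parameter-recovery experiments.

These drive the registration accuracy studies on synthetic phantoms:
random section planes are cut through random phantoms, the estimation
pipeline (barcode decoding → in-plane least squares → depth resolution
→ optional NCC fine alignment) runs on the simulated observations, and
recovery is scored by the cross-plane error against the known truth and
by bead colocation.

The study conditions model the experimental workflow: a ~3 mm-wide
histological section cut diagonally across the barcoded 1 mm³ OCT
field (yaw 40–55°, so both bleached-plane families cross the section),
out-of-plane tilts up to 5°, per-axis shrinkage scales in [0.8, 1.0],
and user line picks jittered by 10 μm (two picks per line).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .barcode import (
    BarcodePattern,
    NoCorrespondenceError,
    default_pattern,
    match_lines,
)
from .estimation import estimate_section, fine_align
from .geometry import PlaneDecomposition, PlaneMap, cross_plane_error, map_points
from .phantom import (
    NoBeadsError,
    Phantom,
    PhantomConfig,
    bead_colocation_error,
    simulate_sectioning,
)
from .volume_ops import reslice

__all__ = ["StudyConditions", "ReplicateResult", "run_replicate",
           "recovery_experiment"]


@dataclass(frozen=True)
class StudyConditions:
    """Geometry and noise of one Monte-Carlo replicate (lengths μm)."""

    yaw_range_deg: tuple[float, float] = (40.0, 55.0)
    tilt_max_deg: float = 5.0
    scale_range: tuple[float, float] = (0.8, 1.0)
    translation: tuple[float, float, float] = (-50.0, -50.0, 0.0)
    section_extent: tuple[float, float] = (3000.0, 500.0)
    pick_noise_sigma: float = 10.0
    picks_per_line: int = 2
    # cross-plane error is reported over this grid (the cropped working
    # field of a coregistered pair)
    error_extent: tuple[float, float] = (1000.0, 500.0)
    error_grid_step: float = 25.0
    # fine-alignment working resolution
    align_window: tuple[float, float] = (600.0, 400.0)
    align_origin: tuple[float, float] = (900.0, 50.0)
    align_voxel: float = 4.0
    max_shift: float = 40.0
    max_rot_deg: float = 2.0
    section_thickness: float = 5.0

    def draw_decomposition(self, rng: np.random.Generator) -> PlaneDecomposition:
        yaw = rng.uniform(*np.deg2rad(self.yaw_range_deg))
        tilts = rng.uniform(-np.deg2rad(self.tilt_max_deg),
                            np.deg2rad(self.tilt_max_deg), size=2)
        scales = rng.uniform(*self.scale_range, size=3)
        return PlaneDecomposition(
            angles=np.array([yaw, tilts[0], tilts[1]]),
            scales=scales,
            translation=np.asarray(self.translation, float),
        )


@dataclass
class ReplicateResult:
    cross_plane_initial: float
    cross_plane_refined: Optional[float] = None
    bead_error: Optional[float] = None
    n_lines: int = 0
    flags: list[str] = field(default_factory=list)


def _window_map(m: PlaneMap, origin_uv: np.ndarray) -> PlaneMap:
    """Re-express a plane map with its (u, v) origin moved to origin_uv."""
    return PlaneMap(m.linear, m.offset + m.linear @ origin_uv)


def _unwindow_map(m: PlaneMap, origin_uv: np.ndarray) -> PlaneMap:
    return PlaneMap(m.linear, m.offset - m.linear @ origin_uv)


def run_replicate(
    seed: int,
    conditions: StudyConditions = StudyConditions(),
    pattern: Optional[BarcodePattern] = None,
    phantom_config: Optional[PhantomConfig] = None,
    refine: bool = False,
    beads: bool = False,
) -> Optional[ReplicateResult]:
    """One phantom → section → estimate (→ fine-align → beads) replicate.

    Returns None when barcode decoding fails for the replicate (a
    dropped section, as in the curated real-data evaluations).
    """
    pattern = pattern or default_pattern()
    phantom_config = phantom_config or PhantomConfig()
    rng = np.random.default_rng(seed)
    ph = Phantom(phantom_config, seed=int(rng.integers(0, 2 ** 31 - 1)))
    dec = conditions.draw_decomposition(rng)
    obs, _, _, true_maps = simulate_sectioning(
        ph, dec, pattern,
        n_sections=1,
        pick_noise_sigma=conditions.pick_noise_sigma,
        picks_per_line=conditions.picks_per_line,
        seed=int(rng.integers(0, 2 ** 31 - 1)),
        extent=conditions.section_extent,
    )
    if not obs:
        return None
    try:
        labels, _ = match_lines(obs[0].lines, pattern)
    except NoCorrespondenceError:
        return None
    for i, lab in labels.items():
        obs[0].lines[i].label = lab
    truth = ph.truth(lateral_step=2.0)
    fit = estimate_section(obs[0], pattern, truth.surface)
    m_true = true_maps[0]
    m_est = fit.plane_map
    result = ReplicateResult(
        cross_plane_initial=cross_plane_error(
            m_true, m_est, conditions.error_extent, conditions.error_grid_step),
        n_lines=len(obs[0].lines),
        flags=list(fit.flags),
    )

    if refine or beads:
        origin_uv = np.asarray(conditions.align_origin, float)
        win = conditions.align_window
        m_true_w = _window_map(m_true, origin_uv)
        m_est_w = _window_map(m_est, origin_uv)
        corners = np.array([[0.0, 0.0], [win[0], 0.0],
                            [0.0, win[1]], [win[0], win[1]]])
        pts = map_points(m_true_w, corners)
        margin = conditions.max_shift + 3 * conditions.align_voxel + 30.0
        region = [(pts[:, a].min() - margin, pts[:, a].max() + margin)
                  for a in range(3)]
        vol = ph.rasterize_oct(voxel_size=conditions.align_voxel,
                               region=region)
        reference = reslice(vol, m_true_w, win, conditions.align_voxel)
        refined_w, _, align_flags = fine_align(
            m_est_w, vol, reference,
            max_shift=conditions.max_shift,
            max_rot=np.deg2rad(conditions.max_rot_deg),
            extent=win,
        )
        result.flags += align_flags
        m_ref = _unwindow_map(refined_w, origin_uv)
        result.cross_plane_refined = cross_plane_error(
            m_true, m_ref, conditions.error_extent, conditions.error_grid_step)
        if beads:
            try:
                result.bead_error = bead_colocation_error(
                    truth, m_true, m_ref, conditions.section_thickness)
            except NoBeadsError:
                result.bead_error = None
    return result


def recovery_experiment(
    n_reps: int,
    seed: int,
    conditions: StudyConditions = StudyConditions(),
    refine: bool = False,
    beads: bool = False,
) -> list[ReplicateResult]:
    """Run ``n_reps`` independent replicates with per-replicate seeds."""
    ss = np.random.SeedSequence(seed)
    out = []
    for child in ss.spawn(n_reps):
        rep_seed = int(child.generate_state(1)[0] % (2 ** 31 - 1))
        res = run_replicate(rep_seed, conditions, refine=refine, beads=beads)
        if res is not None:
            out.append(res)
    return out
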