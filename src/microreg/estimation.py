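"""Plane-map estimation from fiducial observations.

The estimation pipeline mirrors how a coregistered section is produced:

1. :func:`fit_inplane` — the bleached planes are vertical, so each pick
   on an identified line constrains only the x, y rows of the map; these
   six unknowns are solved by linear least squares.
2. :func:`resolve_depth` — the z row and depth offset are recovered by
   matching the tissue top contour seen in the section against the OCT
   surface height map, with an orthonormality (scale·rotation) check and
   a configurable out-of-plane scale assumption.
3. :func:`joint_stack_fit` — consecutive sections from one block share
   orientation and scale and differ by translation along the common
   plane normal; fitting them jointly averages down estimator noise.
4. :func:`fine_align` — automated stand-in for interactive refinement:
   maximizes masked normalized cross-correlation between the resliced
   OCT image and a reference section image over three translations and
   the in-plane rotation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import optimize

from .barcode import BarcodePattern, InsufficientFiducialsError, ObservedLine
from .geometry import (
    DegenerateGeometryError,
    PlaneDecomposition,
    PlaneMap,
    compose,
    cross_plane_error,
    decompose,
    map_points,
    plane_normal,
)
from .volume_ops import HeightMap, Image2D, Volume, reslice

__all__ = [
    "SectionObservation",
    "StackObservation",
    "PartialMap",
    "SectionFit",
    "StackFit",
    "RankDeficientError",
    "DepthUnresolvedError",
    "fit_inplane",
    "resolve_depth",
    "estimate_section",
    "joint_stack_fit",
    "fine_align",
    "offset_sweep",
    "masked_ncc",
]


class RankDeficientError(ValueError):
    """The fiducial geometry does not constrain all in-plane unknowns."""


class DepthUnresolvedError(ValueError):
    """Depth cannot be resolved (no surface information available)."""


@dataclass
class SectionObservation:
    """Fiducial picks and tissue contour for one histological section."""

    section_id: str
    lines: list[ObservedLine]
    top_contour: Optional[np.ndarray] = None   # (n, 2) of (u, v_top) μm
    nominal_index: int = 0

    def __post_init__(self) -> None:
        if self.top_contour is not None:
            self.top_contour = np.atleast_2d(
                np.asarray(self.top_contour, dtype=float))

    @property
    def n_picks(self) -> int:
        return sum(len(l.picks) for l in self.lines)


@dataclass
class StackObservation:
    """Consecutive sections cut from one block."""

    sections: list[SectionObservation]
    section_spacing: float    # μm, nominal physical spacing in the block

    def __post_init__(self) -> None:
        if self.section_spacing <= 0:
            raise ValueError("section spacing must be positive")
        idx = [s.nominal_index for s in self.sections]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("nominal_index must be strictly increasing")


@dataclass
class PartialMap:
    """In-plane (x, y) part of a plane map, from vertical fiducials."""

    linear2: np.ndarray    # 2×2, x and y rows of PlaneMap.linear
    offset2: np.ndarray    # (t_x, t_y) μm
    residual_rms: float    # μm

    def __post_init__(self) -> None:
        self.linear2 = np.asarray(self.linear2, dtype=float)
        self.offset2 = np.asarray(self.offset2, dtype=float)
        if self.linear2.shape != (2, 2) or self.offset2.shape != (2,):
            raise ValueError("linear2 must be 2x2 and offset2 length 2")
        if self.residual_rms < 0:
            raise ValueError("residual_rms must be non-negative")


@dataclass
class SectionFit:
    """Full per-section estimation result."""

    plane_map: PlaneMap
    residual_rms: float
    n_lines: int
    n_picks: int
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "plane_map": self.plane_map.to_dict(),
            "residual_rms_um": self.residual_rms,
            "n_lines": self.n_lines,
            "n_picks": self.n_picks,
            "flags": list(self.flags),
        }
        try:
            d["decomposition"] = decompose(self.plane_map).to_dict()
        except DegenerateGeometryError:
            d["decomposition"] = None
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


@dataclass
class StackFit:
    """Joint fit over a section stack: shared orientation/scale, collinear offsets."""

    shared_linear: np.ndarray           # 3×2
    normal: np.ndarray                  # common unit plane normal
    base_offset: np.ndarray             # offset of the first section
    normal_offsets: np.ndarray          # per-section offsets δ_k along normal, δ_0 = 0
    section_maps: list[PlaneMap]
    effective_spacing: float            # mean consecutive normal offset, μm
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "shared_linear": self.shared_linear.tolist(),
            "normal": self.normal.tolist(),
            "base_offset_um": self.base_offset.tolist(),
            "normal_offsets_um": self.normal_offsets.tolist(),
            "effective_spacing_um": self.effective_spacing,
            "sections": [m.to_dict() for m in self.section_maps],
            "flags": list(self.flags),
        }


# ---------------------------------------------------------------------------
# Stage 1: in-plane least squares.

def fit_inplane(obs: SectionObservation, pattern: BarcodePattern) -> PartialMap:
    """Solve the in-plane map unknowns from labeled line picks.

    Every pick (u, v) on the line of bleach plane k (in-plane normal n_k,
    offset d_k) satisfies ``n_k · (linear2 · (u, v) + offset2) = d_k``,
    one linear equation in the six unknowns (4 matrix entries + 2
    translations).  Solved by least squares over all picks; the RMS
    residual is in μm.
    """
    labeled = [l for l in obs.lines if l.label is not None]
    thetas = set()
    rows, rhs = [], []
    for line in labeled:
        plane = pattern.plane_by_label(line.label)
        thetas.add(plane.theta)
        nx, ny = plane.normal
        for u, v in line.picks:
            rows.append([nx * u, nx * v, nx, ny * u, ny * v, ny])
            rhs.append(plane.d)
    if len(rows) < 6:
        raise InsufficientFiducialsError(
            f"need at least 6 picks on labeled lines, got {len(rows)}")
    if len(thetas) < 2:
        raise RankDeficientError(
            "all labeled lines are parallel (one family); in-plane map "
            "is not identifiable")
    a = np.asarray(rows)
    b = np.asarray(rhs)
    sol, _, rank, _ = np.linalg.lstsq(a, b, rcond=None)
    if rank < 6:
        raise RankDeficientError("pick geometry is rank deficient")
    linear2 = np.array([[sol[0], sol[1]], [sol[3], sol[4]]])
    offset2 = np.array([sol[2], sol[5]])
    resid = a @ sol - b
    return PartialMap(linear2, offset2, float(np.sqrt(np.mean(resid ** 2))))


# ---------------------------------------------------------------------------
# Stage 2: depth resolution.

def _zero_tilt_fallback(
    partial: PartialMap, s_z: float
) -> np.ndarray:
    """z row for a vertical (zero out-of-plane tilt) section."""
    return np.array([0.0, s_z])


def resolve_depth(
    partial: PartialMap,
    surface: Optional[HeightMap],
    top_contour: Optional[np.ndarray],
    assume_sz_equals: Union[str, float] = "s_y",
) -> SectionFit:
    """Complete the plane map's z row and depth offset.

    For each top-contour sample (u_i, v_i) the mapped 3D point must lie
    on the OCT surface: ``m31·u_i + m32·v_i + t_z = h_i`` where h_i is
    the surface height at the (known, in-plane-determined) lateral
    position.  With a wavy surface the contour samples are not collinear
    in (u, v), so (m31, m32, t_z) follow from linear least squares.  The
    completed map is then checked to admit a positive scale·rotation
    decomposition.

    When the contour is degenerate (flat surface: samples collinear),
    the z row falls back to zero out-of-plane tilt with |z row| set by
    the scale assumption (default s_z := s_y), and only t_z is taken
    from the contour.
    """
    if surface is None:
        raise DepthUnresolvedError("no OCT surface height map available")
    if top_contour is None or len(np.atleast_2d(top_contour)) == 0:
        raise DepthUnresolvedError("no tissue top contour available")
    contour = np.atleast_2d(np.asarray(top_contour, dtype=float))
    flags: list[str] = []

    xy = contour @ partial.linear2.T + partial.offset2
    h = surface.sample(xy)
    ok = np.isfinite(h)
    if ok.sum() < 3:
        raise DepthUnresolvedError(
            "fewer than 3 contour samples fall on the OCT surface")
    contour = contour[ok]
    h = h[ok]

    design = np.column_stack([contour, np.ones(len(contour))])
    sv = np.linalg.svd(design, compute_uv=False)
    degenerate_contour = sv[-1] < 1e-6 * sv[0]

    def scale_for_fallback() -> float:
        # Out-of-plane scale from the assumption; in-plane scales come
        # from a 2D decomposition of linear2 (s_y ≈ norm of its y row
        # contribution).  Use column norms of linear2 as proxies.
        s_u = float(np.linalg.norm(partial.linear2[:, 0]))
        if isinstance(assume_sz_equals, (int, float)):
            return float(assume_sz_equals)
        return s_u   # s_y unobservable for a vertical section; use s_x proxy

    if degenerate_contour:
        flags.append("flat-surface-fallback")
        zrow = _zero_tilt_fallback(partial, scale_for_fallback())
        tz = float(np.mean(h - contour @ zrow))
    else:
        coef, *_ = np.linalg.lstsq(design, h, rcond=None)
        zrow = coef[:2]
        tz = float(coef[2])

    linear = np.vstack([partial.linear2, zrow[None, :]])
    offset = np.array([partial.offset2[0], partial.offset2[1], tz])
    m = PlaneMap(linear, offset)

    # v must increase with depth.
    if m.linear[2, 1] < 0:
        flags.append("v-axis-points-up")

    try:
        dec = decompose(m)
        if isinstance(assume_sz_equals, str) and assume_sz_equals == "s_y":
            # purely diagnostic: report disagreement with the assumption
            if dec.scales[2] > 0 and abs(dec.scales[2] - dec.scales[1]) \
                    > 0.25 * dec.scales[1]:
                flags.append("sz-deviates-from-assumption")
    except DegenerateGeometryError:
        flags.append("nonorthonormal-fallback")
        zrow = _zero_tilt_fallback(partial, scale_for_fallback())
        tz = float(np.mean(h - contour @ zrow))
        linear = np.vstack([partial.linear2, zrow[None, :]])
        offset = np.array([partial.offset2[0], partial.offset2[1], tz])
        m = PlaneMap(linear, offset)

    # Contour residual folded into the report (μm, along z).
    resid = design[:, :2] @ m.linear[2, :] + m.offset[2] - h
    rms = float(np.sqrt(np.mean(resid ** 2)))
    return SectionFit(
        plane_map=m,
        residual_rms=float(np.hypot(partial.residual_rms, rms)),
        n_lines=0,
        n_picks=0,
        flags=flags,
    )


def _joint_refine(
    obs: SectionObservation,
    pattern: BarcodePattern,
    surface: HeightMap,
    init: PlaneMap,
    sz_prior_sigma: float = 0.15,
    sxy_prior_sigma: float = 0.15,
    pick_sigma: float = 10.0,
) -> Optional[PlaneMap]:
    """Polish the plane map as a constrained 9-parameter fit.

    Re-fits angles, scales, and translation jointly to all pick and
    contour residuals with the scale·rotation structure built into the
    parametrization.  This conditions the out-of-plane terms far better
    than the sequential solve: in the two-stage path, the contour's
    narrow v-range lets the v-coefficient of the z-row trade against
    t_z almost freely, while here that coefficient is s_z·cosβ·cosγ
    with s_z anchored both by the contour and by weak priors.

    Two soft isotropy priors close the remaining gauge freedoms: the
    in-plane 2×2 block of a near-vertical section determines only four
    combinations of (α, s_x, s_y, tilts), leaving a one-parameter
    family along which (s_x, s_y) trade against yaw; tissue shrinkage
    in formalin is close to isotropic, so ``s_x ≈ s_y`` (width
    ``sxy_prior_sigma``) anchors the family and ``s_z ≈ s_y`` (width
    ``sz_prior_sigma``) anchors the depth scale.  Prior residuals are
    scaled into pick-σ units.

    Returns None when the fit fails or lands on a scale bound.
    """
    # Initialize as a vertical section from the in-plane part: the
    # sequential estimate's z-row can be ill-conditioned (and its
    # decomposition misattributes scales), while yaw and the in-plane
    # scale are reliably determined by the picks.
    l2 = init.linear[:2, :]
    s0 = float(np.linalg.norm(l2[:, 0]))
    alpha0 = float(np.arctan2(l2[1, 0], l2[0, 0]))
    x0 = np.array([alpha0, 0.0, 0.0, s0, s0, s0,
                   init.offset[0], init.offset[1], init.offset[2]])
    contour = (np.atleast_2d(obs.top_contour)
               if obs.top_contour is not None else np.zeros((0, 2)))

    rows = []
    for line in obs.lines:
        if line.label is None:
            continue
        plane = pattern.plane_by_label(line.label)
        for uv in line.picks:
            rows.append((plane.normal, float(plane.d), np.asarray(uv)))

    def unpack(x: np.ndarray) -> PlaneMap:
        return compose(PlaneDecomposition(x[:3], x[3:6], x[6:9]))

    def residuals(x: np.ndarray) -> np.ndarray:
        m = unpack(x)
        res = []
        l2, t2 = m.linear[:2, :], m.offset[:2]
        for nxy, d, uv in rows:
            res.append(nxy @ (l2 @ uv + t2) - d)
        if len(contour):
            xy = contour @ l2.T + t2
            h = surface.sample(xy)
            zp = contour @ m.linear[2, :] + m.offset[2]
            r = zp - h
            res.extend(np.where(np.isfinite(r), r, 0.0))
        res.append((x[5] - x[4]) / sz_prior_sigma * pick_sigma)
        res.append((x[4] - x[3]) / sxy_prior_sigma * pick_sigma)
        return np.asarray(res)

    lb = np.concatenate([[-np.pi, -np.pi / 2, -np.pi / 2], [0.3] * 3,
                         [-np.inf] * 3])
    ub = np.concatenate([[np.pi, np.pi / 2, np.pi / 2], [2.0] * 3,
                         [np.inf] * 3])
    try:
        sol = optimize.least_squares(residuals, x0, bounds=(lb, ub),
                                     xtol=1e-10, max_nfev=200)
    except Exception:
        return None
    if not np.all(np.isfinite(sol.x)):
        return None
    # Reject solutions pinned at the scale bounds (wrong basin).
    if np.any(sol.x[3:6] <= lb[3:6] + 1e-6) or np.any(sol.x[3:6] >= ub[3:6] - 1e-6):
        return None
    return unpack(sol.x)


def estimate_section(
    obs: SectionObservation,
    pattern: BarcodePattern,
    surface: Optional[HeightMap],
    assume_sz_equals: Union[str, float] = "s_y",
    polish: bool = True,
) -> SectionFit:
    """fit_inplane, resolve_depth, and a constrained joint polish."""
    partial = fit_inplane(obs, pattern)
    fit = resolve_depth(partial, surface, obs.top_contour, assume_sz_equals)
    if polish and surface is not None and obs.top_contour is not None:
        refined = _joint_refine(obs, pattern, surface, fit.plane_map)
        if refined is not None:
            fit.plane_map = refined
        else:
            fit.flags.append("joint-polish-failed")
    fit.n_lines = len([l for l in obs.lines if l.label is not None])
    fit.n_picks = obs.n_picks
    return fit


# ---------------------------------------------------------------------------
# Stage 3: joint multi-section fit.

def joint_stack_fit(
    stack: StackObservation,
    pattern: BarcodePattern,
    surface: Optional[HeightMap],
    assume_sz_equals: Union[str, float] = "s_y",
    average: bool = False,
) -> StackFit:
    """Fit a shared orientation/scale and collinear per-section offsets.

    Sections cut consecutively from one block share the cutting
    orientation and the shrinkage scales; only the depth of the cut
    advances.  The joint model therefore has a single ``linear`` and
    per-section translations constrained to differ along the common
    plane normal.

    Default mode: one joint least squares over every section's picks
    and contour, with shared angles, scales, and base translation, and
    one free offset along the common normal per section beyond the
    first (9 + K − 1 parameters for K sections), initialized from the
    per-section fits.  With ``average=True`` the shared linear is the
    entry-wise mean of per-section linear matrices and the per-section
    translations are kept as fitted (plain parameter averaging, for
    comparison with the joint fit).
    """
    fits = [
        estimate_section(s, pattern, surface, assume_sz_equals)
        for s in stack.sections
    ]
    flags = sorted({fl for f in fits for fl in f.flags})
    if len(fits) == 1:
        f = fits[0]
        return StackFit(
            shared_linear=f.plane_map.linear.copy(),
            normal=plane_normal(f.plane_map),
            base_offset=f.plane_map.offset.copy(),
            normal_offsets=np.zeros(1),
            section_maps=[f.plane_map],
            effective_spacing=float("nan"),
            flags=list(f.flags),
        )

    shared = np.mean([f.plane_map.linear for f in fits], axis=0)
    n = plane_normal(PlaneMap(shared, np.zeros(3)))
    offsets = np.array([f.plane_map.offset for f in fits])
    normal_comps = offsets @ n
    deltas = normal_comps - normal_comps[0]

    section_maps: Optional[list[PlaneMap]] = None
    if not average:
        joint = _joint_stack_refine(stack, pattern, surface, fits, n)
        if joint is not None:
            shared, base, deltas, n = joint
            section_maps = [PlaneMap(shared.copy(), base + d * n)
                            for d in deltas]
        else:
            flags = flags + ["joint-stack-refine-failed"]
    if section_maps is None:
        base = offsets[0]
        section_maps = [PlaneMap(shared.copy(), o.copy()) for o in offsets]
    spacing = float(np.mean(np.diff(deltas))) if len(deltas) > 1 else float("nan")
    return StackFit(
        shared_linear=shared,
        normal=n,
        base_offset=section_maps[0].offset.copy(),
        normal_offsets=deltas,
        section_maps=section_maps,
        effective_spacing=spacing,
        flags=flags,
    )


def _joint_stack_refine(
    stack: StackObservation,
    pattern: BarcodePattern,
    surface: Optional[HeightMap],
    fits: list[SectionFit],
    n_init: np.ndarray,
    sz_prior_sigma: float = 0.15,
    sxy_prior_sigma: float = 0.15,
    pick_sigma: float = 10.0,
) -> Optional[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]]:
    """Joint constrained fit over all sections.

    Parameters: shared (angles, scales, base translation) plus one
    normal offset per section after the first.  Returns
    (shared linear, base offset, normal deltas, normal) or None.
    """
    k = len(stack.sections)
    offsets = np.array([f.plane_map.offset for f in fits])
    deltas0 = (offsets - offsets[0]) @ n_init

    # Initialize the shared part from the first section's decomposition,
    # with the same robust vertical-section fallback as the single fit.
    base_map = fits[0].plane_map
    l2 = base_map.linear[:2, :]
    s0 = float(np.linalg.norm(l2[:, 0]))
    alpha0 = float(np.arctan2(l2[1, 0], l2[0, 0]))
    x0 = np.concatenate([[alpha0, 0.0, 0.0, s0, s0, s0],
                         base_map.offset, deltas0[1:]])

    rows_per_section = []
    contours = []
    for obs in stack.sections:
        rows = []
        for line in obs.lines:
            if line.label is None:
                continue
            plane = pattern.plane_by_label(line.label)
            for uv in line.picks:
                rows.append((plane.normal, float(plane.d), np.asarray(uv)))
        rows_per_section.append(rows)
        contours.append(np.atleast_2d(obs.top_contour)
                        if obs.top_contour is not None else np.zeros((0, 2)))

    def residuals(x: np.ndarray) -> np.ndarray:
        base = compose(PlaneDecomposition(x[:3], x[3:6], x[6:9]))
        nrm = plane_normal(base)
        deltas = np.concatenate([[0.0], x[9:]])
        res = []
        for rows, contour, d in zip(rows_per_section, contours, deltas):
            m = base.translated(d * nrm)
            l2, t2 = m.linear[:2, :], m.offset[:2]
            for nxy, dd, uv in rows:
                res.append(nxy @ (l2 @ uv + t2) - dd)
            if len(contour) and surface is not None:
                xy = contour @ l2.T + t2
                h = surface.sample(xy)
                zp = contour @ m.linear[2, :] + m.offset[2]
                r = zp - h
                res.extend(np.where(np.isfinite(r), r, 0.0))
        res.append((x[5] - x[4]) / sz_prior_sigma * pick_sigma)
        res.append((x[4] - x[3]) / sxy_prior_sigma * pick_sigma)
        return np.asarray(res)

    lb = np.concatenate([[-np.pi, -np.pi / 2, -np.pi / 2], [0.3] * 3,
                         [-np.inf] * 3, [-np.inf] * (k - 1)])
    ub = np.concatenate([[np.pi, np.pi / 2, np.pi / 2], [2.0] * 3,
                         [np.inf] * 3, [np.inf] * (k - 1)])
    try:
        sol = optimize.least_squares(residuals, x0, bounds=(lb, ub),
                                     xtol=1e-10, max_nfev=300)
    except Exception:
        return None
    if not np.all(np.isfinite(sol.x)):
        return None
    if np.any(sol.x[3:6] <= lb[3:6] + 1e-6) or np.any(sol.x[3:6] >= ub[3:6] - 1e-6):
        return None
    base = compose(PlaneDecomposition(sol.x[:3], sol.x[3:6], sol.x[6:9]))
    nrm = plane_normal(base)
    deltas = np.concatenate([[0.0], sol.x[9:]])
    return base.linear, base.offset, deltas, nrm


# ---------------------------------------------------------------------------
# Stage 4: automated fine alignment.

def masked_ncc(a: Image2D, b: Image2D) -> float:
    """Normalized cross-correlation over jointly valid pixels.

    Returns NaN when either image has zero variance on the joint mask
    (featureless input).
    """
    mask = a.mask & b.mask
    if mask.sum() < 16:
        return float("nan")
    x = a.data[mask].astype(float).ravel()
    y = b.data[mask].astype(float).ravel()
    x = x - x.mean()
    y = y - y.mean()
    denom = np.sqrt((x @ x) * (y @ y))
    if denom <= 0:
        return float("nan")
    return float((x @ y) / denom)


def _candidate_map(
    initial: PlaneMap, shift: np.ndarray, phi: float, center_uv: np.ndarray
) -> PlaneMap:
    """Apply a volume-frame shift and an in-plane rotation about center_uv."""
    c, s = np.cos(phi), np.sin(phi)
    r2 = np.array([[c, -s], [s, c]])
    linear = initial.linear @ r2
    offset = (initial.offset + shift
              + initial.linear @ (center_uv - r2 @ center_uv))
    return PlaneMap(linear, offset)


def fine_align(
    initial: PlaneMap,
    volume: Volume,
    reference: Image2D,
    max_shift: float = 20.0,
    max_rot: float = np.deg2rad(2.0),
    extent: Optional[tuple[float, float]] = None,
    coarse_step_um: float = 10.0,
    coarse_step_rad: float = np.deg2rad(1.0),
    smooth_px: float = 2.0,
    prior_sigma_normal: float = 5.0,
    prior_sigma_inplane: float = 20.0,
    prior_weight: float = 0.02,
) -> tuple[PlaneMap, float, list[str]]:
    """Refine translation (3 axes) and in-plane rotation by masked NCC.

    Orientation and scale stay frozen; only the four degrees of freedom
    a human aligner adjusts are optimized.  A coarse, plane-adapted
    search inside ±max_shift / ±max_rot seeds a Nelder–Mead refinement.
    The returned map never scores worse (on the regularized objective)
    than the initial one.

    Images are Gaussian-smoothed by ``smooth_px`` pixels before
    correlation: raw OCT speckle decorrelates over a few μm, which
    makes the unsmoothed NCC landscape a sharp spike at the exact plane
    surrounded by noise; smoothing suppresses speckle and leaves the
    anatomical structure a human aligner actually uses.

    The objective is NCC minus an anisotropic quadratic prior on the
    adjustment: the fiducial-based initial map localizes the plane
    accurately *across* itself (``prior_sigma_normal``) but less
    precisely *along* itself (``prior_sigma_inplane``), so a move out
    of plane must earn a correspondingly larger correlation gain.
    Layered tissue is close to translation-invariant along the plane,
    which otherwise leaves the raw-NCC optimum poorly localized in the
    out-of-plane direction.

    Returns (refined map, final raw NCC score, flags).
    """
    if extent is None:
        h_px, w_px = reference.data.shape[:2]
        extent = (w_px * reference.pixel_size, h_px * reference.pixel_size)
    center_uv = np.array([extent[0] / 2.0, extent[1] / 2.0])
    ps = reference.pixel_size

    def smooth(img: Image2D) -> Image2D:
        if smooth_px <= 0:
            return img
        from scipy import ndimage as _ndi
        return Image2D(_ndi.gaussian_filter(np.asarray(img.data, float),
                                            smooth_px),
                       img.pixel_size, img.mask)

    reference = smooth(reference)

    lo = np.array([-max_shift] * 3 + [-max_rot])
    hi = -lo
    nrm_pen = plane_normal(initial)

    def raw_ncc(params: np.ndarray) -> float:
        params = np.clip(params, lo, hi)   # stay inside the trust region
        cand = _candidate_map(initial, params[:3], params[3], center_uv)
        img = smooth(reslice(volume, cand, extent, ps))
        return masked_ncc(img, reference)

    def penalty(params: np.ndarray) -> float:
        shift = params[:3]
        c_n = shift @ nrm_pen
        c_ip2 = float(shift @ shift) - c_n * c_n
        return prior_weight * ((c_n / prior_sigma_normal) ** 2
                               + c_ip2 / prior_sigma_inplane ** 2)

    def score_of(params: np.ndarray) -> float:
        s = raw_ncc(params)
        return s - penalty(params) if np.isfinite(s) else s

    s0 = score_of(np.zeros(4))
    if not np.isfinite(s0):
        return initial, float("nan"), ["featureless-reference"]

    best_params = np.zeros(4)
    best_score = s0

    def try_params(p: np.ndarray) -> None:
        nonlocal best_params, best_score
        s = score_of(p)
        if np.isfinite(s) and s > best_score:
            best_score, best_params = s, p.copy()

    # Coarse search in a plane-adapted frame: the misalignment of a
    # barcode-estimated map is mostly an in-plane translation (picks
    # localize the plane well across itself but less well along it),
    # plus a small offset along the plane normal.
    nrm = plane_normal(initial)
    e_u = initial.linear[:, 0] / np.linalg.norm(initial.linear[:, 0])
    e_v = initial.linear[:, 1] / np.linalg.norm(initial.linear[:, 1])
    shifts = np.arange(-max_shift, max_shift + 0.5 * coarse_step_um,
                       coarse_step_um)
    normal_scan = np.arange(-max_shift, max_shift + 0.5 * coarse_step_um / 2,
                            coarse_step_um / 2)
    rots = np.arange(-max_rot, max_rot + 0.5 * coarse_step_rad,
                     coarse_step_rad)
    # 1) offset along the normal
    for d in normal_scan:
        try_params(np.concatenate([best_params[:3] + d * nrm, [0.0]]))
    # 2) in-plane 2D grid around the current best
    base = best_params.copy()
    for a in shifts:
        for b in shifts:
            try_params(np.concatenate(
                [base[:3] + a * e_u + b * e_v, [base[3]]]))
    # 3) rotation scan, then 4) re-scan the normal at the new optimum
    base = best_params.copy()
    for phi in rots:
        try_params(np.array([*base[:3], phi]))
    base = best_params.copy()
    for d in normal_scan:
        try_params(np.concatenate([base[:3] + d * nrm, [base[3]]]))

    res = optimize.minimize(
        lambda p: -np.nan_to_num(score_of(p), nan=-1.0),
        best_params,
        method="Nelder-Mead",
        options={"xatol": 0.25, "fatol": 1e-6, "maxfev": 80},
    )
    flags: list[str] = []
    final_params, final_score = best_params, best_score
    if np.isfinite(-res.fun) and -res.fun > best_score:
        final_params = np.clip(res.x, lo, hi)
        final_score = float(-res.fun)
    if final_score < s0:
        final_params, final_score = np.zeros(4), s0
        flags.append("no-improvement")
    refined = _candidate_map(initial, final_params[:3], final_params[3],
                             center_uv)
    return refined, float(raw_ncc(final_params)), flags


def offset_sweep(
    volume: Volume,
    m: PlaneMap,
    offsets: Sequence[float],
    extent: tuple[float, float],
    pixel_size: float = 1.0,
    fill: float = 0.0,
) -> list[Image2D]:
    """Reslice at planes parallel to ``m``, shifted along its normal.

    Used to probe registration accuracy: a landmark visible at offset 0
    should disappear in planes ±25 μm away if the plane is right.
    """
    n = plane_normal(m)
    return [
        reslice(volume, m.translated(off * n), extent, pixel_size, fill)
        for off in offsets
    ]
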