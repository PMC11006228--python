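"""Section-to-volume plane geometry.

A histological section is modeled as a 2D plane cut through a 3D OCT
volume.  The mapping from section coordinates (u, v), in μm on the slide,
to volume coordinates (x, y, z), in μm, is affine with nine degrees of
freedom: three rotations, three per-axis scale factors (tissue shrinkage
during fixation/processing), and three translations.

Conventions (binding throughout the package):

* The volume frame is right-handed, x = fast scan, y = slow scan,
  z = depth increasing into the sample.
* The section frame is (u, v): u along the slide, v increasing with
  section depth.
* The canonical section (all angles zero, unit scales) is the volume
  x–z plane, so ``linear = [[1, 0], [0, 0], [0, 1]]``.
* Composition: ``linear = diag(s_x, s_y, s_z) @ R(α, β, γ) @ E`` with
  intrinsic z–y–x Euler rotations ``R = Rz(α) Ry(β) Rx(γ)`` and the
  embedding ``E`` sending (u, v) to (u, 0, v).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "PlaneMap",
    "PlaneDecomposition",
    "InvalidParameterError",
    "DegenerateGeometryError",
    "compose",
    "decompose",
    "map_points",
    "plane_normal",
    "cross_plane_error",
]

# Embedding of the section plane into 3-space: (u, v) -> (u, 0, v).
_EMBED = np.array([[1.0, 0.0], [0.0, 0.0], [0.0, 1.0]])

_RANK_TOL = 1e-9


class InvalidParameterError(ValueError):
    """A plane parameter violates its domain (e.g. non-positive scale)."""


class DegenerateGeometryError(ValueError):
    """The plane map is rank deficient; no plane is defined."""


@dataclass(frozen=True)
class PlaneMap:
    """Affine map from section (u, v) μm to volume (x, y, z) μm.

    Attributes
    ----------
    linear : (3, 2) ndarray
        Volume-μm per section-μm.  Must have rank 2.
    offset : (3,) ndarray
        Translation in μm.
    """

    linear: np.ndarray
    offset: np.ndarray

    def __post_init__(self) -> None:
        linear = np.asarray(self.linear, dtype=float)
        offset = np.asarray(self.offset, dtype=float)
        if linear.shape != (3, 2):
            raise InvalidParameterError(f"linear must be 3x2, got {linear.shape}")
        if offset.shape != (3,):
            raise InvalidParameterError(f"offset must be length 3, got {offset.shape}")
        if not (np.all(np.isfinite(linear)) and np.all(np.isfinite(offset))):
            raise InvalidParameterError("plane map entries must be finite")
        object.__setattr__(self, "linear", linear)
        object.__setattr__(self, "offset", offset)

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.linear, tol=_RANK_TOL))

    def require_nondegenerate(self) -> None:
        if self.rank < 2:
            raise DegenerateGeometryError("plane map linear part is rank deficient")

    def translated(self, delta: Sequence[float]) -> "PlaneMap":
        """Return a copy with ``delta`` (μm, volume frame) added to the offset."""
        return PlaneMap(self.linear.copy(), self.offset + np.asarray(delta, float))

    def to_dict(self) -> dict:
        return {"linear": self.linear.tolist(), "offset": self.offset.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "PlaneMap":
        return cls(np.asarray(d["linear"], float), np.asarray(d["offset"], float))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "PlaneMap":
        return cls.from_dict(json.loads(s))


@dataclass(frozen=True)
class PlaneDecomposition:
    """Nine-parameter decomposition of a :class:`PlaneMap`.

    Attributes
    ----------
    angles : (3,) ndarray
        (α, β, γ) in radians; intrinsic rotations about volume z, y, x,
        applied in that order.
    scales : (3,) ndarray
        (s_x, s_y, s_z), unitless and positive.  These model per-axis
        tissue shrinkage (values < 1) or swelling.
    translation : (3,) ndarray
        Offset in μm.
    sy_degenerate : bool
        True when the out-of-plane scale s_y could not be observed (the
        section was exactly canonical) and the geometric-mean convention
        s_y := sqrt(s_x · s_z) was applied.
    """

    angles: np.ndarray
    scales: np.ndarray
    translation: np.ndarray
    sy_degenerate: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        angles = np.asarray(self.angles, dtype=float)
        scales = np.asarray(self.scales, dtype=float)
        translation = np.asarray(self.translation, dtype=float)
        for name, arr in (("angles", angles), ("scales", scales),
                          ("translation", translation)):
            if arr.shape != (3,):
                raise InvalidParameterError(f"{name} must be length 3")
        if np.any(scales <= 0):
            raise InvalidParameterError("scales must be positive")
        object.__setattr__(self, "angles", angles)
        object.__setattr__(self, "scales", scales)
        object.__setattr__(self, "translation", translation)

    def to_dict(self) -> dict:
        return {
            "angles_rad": self.angles.tolist(),
            "scales": self.scales.tolist(),
            "translation_um": self.translation.tolist(),
            "sy_degenerate": bool(self.sy_degenerate),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlaneDecomposition":
        return cls(
            np.asarray(d["angles_rad"], float),
            np.asarray(d["scales"], float),
            np.asarray(d["translation_um"], float),
            bool(d.get("sy_degenerate", False)),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "PlaneDecomposition":
        return cls.from_dict(json.loads(s))


def rotation_matrix(alpha: float, beta: float, gamma: float) -> np.ndarray:
    """Intrinsic z–y–x rotation, R = Rz(α) @ Ry(β) @ Rx(γ)."""
    ca, sa = np.cos(alpha), np.sin(alpha)
    cb, sb = np.cos(beta), np.sin(beta)
    cg, sg = np.cos(gamma), np.sin(gamma)
    rz = np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])
    ry = np.array([[cb, 0.0, sb], [0.0, 1.0, 0.0], [-sb, 0.0, cb]])
    rx = np.array([[1.0, 0.0, 0.0], [0.0, cg, -sg], [0.0, sg, cg]])
    return rz @ ry @ rx


def compose(dec: PlaneDecomposition) -> PlaneMap:
    """Build the affine plane map from its nine parameters."""
    r = rotation_matrix(*dec.angles)
    linear = np.diag(dec.scales) @ r @ _EMBED
    return PlaneMap(linear, dec.translation.copy())


def decompose(m: PlaneMap) -> PlaneDecomposition:
    """Recover angles, scales, and translation from a plane map.

    The two columns of ``m.linear`` are the first and third columns of
    ``diag(s) @ R``.  Writing w_i = 1 / s_i², the orthonormality of the
    rotation columns gives three equations *linear* in w::

        Σ_i w_i c1_i²    = 1
        Σ_i w_i c2_i²    = 1
        Σ_i w_i c1_i c2_i = 0

    which are solved directly.  When the section plane is exactly
    canonical (normal along y, both columns have zero y-component), w_y
    is unobservable: the convention s_y := sqrt(s_x · s_z) is applied
    and ``sy_degenerate`` is set.
    """
    m.require_nondegenerate()
    c1 = m.linear[:, 0]
    c2 = m.linear[:, 1]

    a = np.array([c1 * c1, c2 * c2, c1 * c2])   # rows: constraints, cols: w_i
    b = np.array([1.0, 1.0, 0.0])

    # The y-column of the constraint matrix vanishes iff the plane is
    # exactly canonical in orientation about y.
    y_scale = max(np.abs(c1).max(), np.abs(c2).max())
    degenerate = max(abs(c1[1]), abs(c2[1])) <= _RANK_TOL * y_scale

    if degenerate:
        a2 = a[:, [0, 2]]
        w2, *_ = np.linalg.lstsq(a2, b, rcond=None)
        if np.any(w2 <= 0):
            raise DegenerateGeometryError(
                "no positive scale solution; map is not a scale-rotation of the plane")
        sx, sz = 1.0 / np.sqrt(w2)
        sy = float(np.sqrt(sx * sz))
        scales = np.array([sx, sy, sz])
    else:
        # Minimum-norm solve: when the constraint matrix is rank
        # deficient (e.g. one section axis aligned with a volume axis)
        # a one-parameter scale gauge remains; any positive member
        # reproduces the map, and the min-norm one is the convention.
        w, _, rank, _ = np.linalg.lstsq(a, b, rcond=None)
        if rank < 3:
            degenerate = True
        if np.any(w <= 0) or np.max(np.abs(a @ w - b)) > 1e-6:
            raise DegenerateGeometryError(
                "no positive scale solution; map is not a scale-rotation of the plane")
        scales = 1.0 / np.sqrt(w)

    r1 = c1 / scales
    r3 = c2 / scales
    # Renormalize against round-off; r1 and r3 are rotation columns 1 and 3.
    r1 = r1 / np.linalg.norm(r1)
    r3 = r3 - r1 * (r1 @ r3)
    r3 = r3 / np.linalg.norm(r3)
    r2 = np.cross(r3, r1)

    # For R = Rz(α) Ry(β) Rx(γ):  R[2,0] = -sin β, R[0,0] = cos α cos β,
    # R[1,0] = sin α cos β, R[2,1] = cos β sin γ, R[2,2] = cos β cos γ.
    beta = float(np.arcsin(np.clip(-r1[2], -1.0, 1.0)))
    if abs(np.cos(beta)) < 1e-12:
        # Gimbal lock (plane edge-on along z): fold γ into α.
        alpha = float(np.arctan2(-r2[0], r2[1]))
        gamma = 0.0
    else:
        alpha = float(np.arctan2(r1[1], r1[0]))
        gamma = float(np.arctan2(r2[2], r3[2]))

    return PlaneDecomposition(
        angles=np.array([alpha, beta, gamma]),
        scales=scales,
        translation=m.offset.copy(),
        sy_degenerate=degenerate,
    )


def map_points(m: PlaneMap, pts: Sequence[Sequence[float]]) -> np.ndarray:
    """Map section points (u, v) μm to volume points (x, y, z) μm.

    Returns an (n, 3) array; accepts any (n, 2) array-like.
    """
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    if pts.shape[-1] != 2:
        raise InvalidParameterError("points must be (u, v) pairs")
    return pts @ m.linear.T + m.offset


def plane_normal(m: PlaneMap) -> np.ndarray:
    """Unit normal of the section plane in the volume frame.

    Sign convention: the y-component is ≥ 0; if it is zero the
    x-component is ≥ 0 (then z ≥ 0).
    """
    m.require_nondegenerate()
    n = np.cross(m.linear[:, 0], m.linear[:, 1])
    norm = np.linalg.norm(n)
    if norm <= 0:
        raise DegenerateGeometryError("columns are parallel")
    n = n / norm
    for comp in (1, 0, 2):
        if abs(n[comp]) > 1e-12:
            if n[comp] < 0:
                n = -n
            break
    return n


def _plane_grid(extent: tuple[float, float], step: float) -> np.ndarray:
    w, h = extent
    u = np.arange(0.0, w + 0.5 * step, step)
    v = np.arange(0.0, h + 0.5 * step, step)
    uu, vv = np.meshgrid(u, v, indexing="ij")
    return np.column_stack([uu.ravel(), vv.ravel()])


def cross_plane_error(
    m_true: PlaneMap,
    m_est: PlaneMap,
    extent: tuple[float, float] = (1000.0, 500.0),
    grid_step: float = 25.0,
) -> float:
    """Mean out-of-plane registration error in μm.

    Over a regular (u, v) grid spanning ``extent``, the mean of
    ``|n_true · (p_est(u, v) − p_true(u, v))|`` where ``n_true`` is the
    unit normal of the true plane.  In-plane displacements are invisible
    to this metric by construction: it measures how far the estimated
    section plane strays from the true one, which is the error that
    cannot be fixed by in-plane panning/stretching.
    """
    m_true.require_nondegenerate()
    m_est.require_nondegenerate()
    grid = _plane_grid(extent, grid_step)
    n = plane_normal(m_true)
    delta = map_points(m_est, grid) - map_points(m_true, grid)
    return float(np.mean(np.abs(delta @ n)))
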