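"""Synthetic skin-in-gel phantom with exhaustive ground truth.

The phantom emulates the imaging scene of the barcode coregistration
workflow: a slab of skin (bright, speckled dermis under a darker
nuclei-rich epidermis) embedded below a wavy surface in a transparent
fluorescent gel, with optional fluorescent calibration beads suspended
in the gel.  An OCT-like channel carries multiplicative exponential
speckle, Beer–Lambert depth attenuation, and PSF blur; a fluorescence
channel is uniform in the gel and can be photobleached with a barcode
pattern.

The phantom is defined by smooth analytic fields (surface height,
epidermis thickness) drawn deterministically from a seed, so ground
truth — surface, labels, bead centers, and the true plane map of every
simulated section — is available at any resolution without rasterizing
a full-size volume.  Rasterization to a :class:`~microreg.volume_ops.Volume`
is explicit and can be restricted to a region of interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.optimize import brentq

from .barcode import BarcodePattern, ObservedLine, predict_section_lines
from .estimation import SectionObservation
from .geometry import (
    PlaneDecomposition,
    PlaneMap,
    compose,
    map_points,
    plane_normal,
)
from .volume_ops import HeightMap, Image2D, Volume

__all__ = [
    "PhantomConfig",
    "PhantomTruth",
    "Phantom",
    "NoBeadsError",
    "make_phantom",
    "apply_bleach",
    "simulate_sectioning",
    "bead_colocation_error",
    "beads_in_section",
]

LABEL_GEL = 0
LABEL_EPIDERMIS = 1
LABEL_DERMIS = 2
LABEL_BEAD = 3
LABEL_FOLLICLE = 4
LABEL_CHUNK = 5


class NoBeadsError(ValueError):
    """No bead intersects the section."""


@dataclass(frozen=True)
class PhantomConfig:
    """Phantom geometry and optics.

    Lengths in μm.  Defaults follow the working conditions of the
    barcode coregistration experiments: 1 mm × 1 mm lateral field,
    0.6 mm depth, 1 μm/pixel working resolution, OCT lateral/axial PSF
    of 3.7/2.0 μm, and 25 μm calibration beads.
    """

    extent: tuple[float, float, float] = (1000.0, 1000.0, 600.0)
    voxel_size: float = 1.0
    surface_depth_mean: float = 150.0      # mean gel thickness above tissue
    surface_amplitude: float = 40.0        # surface waviness amplitude
    surface_period: float = 350.0          # surface waviness period
    surface_detail_amplitude: float = 8.0  # fine surface texture
    surface_detail_period: float = 180.0
    epidermis_thickness_mean: float = 100.0
    epidermis_thickness_sd: float = 15.0
    # rete-ridge-like undulation of the epidermis–dermis junction — the
    # dense lateral structure a fine aligner locks onto
    ridge_amplitude: float = 22.0
    ridge_period: float = 140.0
    # smooth multiplicative dermal reflectivity variation (collagen
    # bundles, vessels) on top of speckle
    dermis_texture_amplitude: float = 0.35
    dermis_texture_period: float = 130.0
    dermis_speckle_contrast: float = 0.8   # 0 = none, 1 = fully developed
    attenuation: float = 0.004             # 1/μm, Beer–Lambert in tissue
    psf_lateral: float = 3.7
    psf_axial: float = 2.0
    bead_count: int = 30
    bead_diameter: float = 25.0
    # Landmarks: follicle-like dark tubes descending from the epidermis
    # and gelatin chunks suspended in the gel — the structures a human
    # aligner (and the NCC fine alignment) locks onto laterally.
    follicle_count: int = 12
    follicle_radius: float = 35.0
    follicle_length: tuple[float, float] = (150.0, 300.0)
    chunk_count: int = 25
    chunk_radius: tuple[float, float] = (15.0, 35.0)
    gel_intensity: float = 0.05
    epidermis_intensity: float = 0.30
    dermis_intensity: float = 1.00
    bead_intensity: float = 1.50
    follicle_intensity: float = 0.35
    chunk_intensity: float = 0.55
    noise_floor: float = 0.01              # additive detector noise SD
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.extent) <= 0 or self.voxel_size <= 0:
            raise ValueError("extent and voxel size must be positive")
        if self.bead_diameter < 2 * self.voxel_size:
            raise ValueError("bead diameter must span at least 2 voxels")
        if (self.surface_depth_mean + self.surface_amplitude
                + self.epidermis_thickness_mean >= self.extent[2]):
            raise ValueError(
                "extent too small: dermis would not fit below the epidermis")


@dataclass
class PhantomTruth:
    """Everything the generator knows that an estimator must recover."""

    surface: HeightMap
    bead_centers: np.ndarray               # (n, 3) μm
    section_maps: list[PlaneMap] = field(default_factory=list)
    labels: Optional[np.ndarray] = None    # rasterized label volume, if made
    config: Optional[PhantomConfig] = None


class Phantom:
    """Deterministic phantom instance built from a config and seed."""

    def __init__(self, config: PhantomConfig, seed: Optional[int] = None):
        self.config = config
        if seed is None:
            seed = config.seed
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        # Smooth random fields: two-component sinusoids with random
        # phases and slightly detuned periods.
        self._surf_phase = rng.uniform(0, 2 * np.pi, size=4)
        self._surf_detune = rng.uniform(0.8, 1.2, size=2)
        self._detail_phase = rng.uniform(0, 2 * np.pi, size=2)
        self._thick_phase = rng.uniform(0, 2 * np.pi, size=2)
        self._ridge_phase = rng.uniform(0, 2 * np.pi, size=4)
        self._ridge_detune = rng.uniform(0.85, 1.15, size=2)
        self._texture_phase = rng.uniform(0, 2 * np.pi, size=6)
        self._texture_detune = rng.uniform(0.8, 1.2, size=3)
        self._speckle_seed = int(rng.integers(0, 2 ** 31 - 1))
        self.bead_centers = self._draw_beads(rng)
        c = self.config
        self.follicles = np.column_stack([
            rng.uniform(c.follicle_radius,
                        c.extent[0] - c.follicle_radius, c.follicle_count),
            rng.uniform(c.follicle_radius,
                        c.extent[1] - c.follicle_radius, c.follicle_count),
            rng.uniform(*c.follicle_length, c.follicle_count),
        ]) if c.follicle_count else np.zeros((0, 3))
        self.chunks = self._draw_chunks(rng)

    # -- analytic fields ----------------------------------------------------

    def surface_height(self, xy: np.ndarray) -> np.ndarray:
        """Gel/tissue interface depth z_s(x, y), μm."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        c = self.config
        kx = 2 * np.pi / (c.surface_period * self._surf_detune[0])
        ky = 2 * np.pi / (c.surface_period * self._surf_detune[1])
        p = self._surf_phase
        wav = (np.sin(kx * xy[:, 0] + p[0]) * np.sin(ky * xy[:, 1] + p[1])
               + 0.4 * np.sin(2.3 * kx * xy[:, 0] + p[2])
               * np.sin(1.7 * ky * xy[:, 1] + p[3]))
        kd = 2 * np.pi / c.surface_detail_period
        pd = self._detail_phase
        detail = (np.sin(kd * xy[:, 0] + pd[0])
                  * np.sin(1.3 * kd * xy[:, 1] + pd[1]))
        return (c.surface_depth_mean + c.surface_amplitude * wav / 1.4
                + c.surface_detail_amplitude * detail)

    def epidermis_thickness(self, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        c = self.config
        k = 2 * np.pi / (1.9 * c.surface_period)
        p = self._thick_phase
        wav = np.sin(k * xy[:, 0] + p[0]) * np.sin(k * xy[:, 1] + p[1])
        kr = 2 * np.pi / c.ridge_period
        pr = self._ridge_phase
        ridge = (np.sin(kr * self._ridge_detune[0] * xy[:, 0] + pr[0])
                 * np.sin(kr * self._ridge_detune[1] * xy[:, 1] + pr[1])
                 + 0.5 * np.sin(1.7 * kr * xy[:, 0] + pr[2])
                 * np.sin(2.3 * kr * xy[:, 1] + pr[3]))
        return (c.epidermis_thickness_mean + c.epidermis_thickness_sd * wav
                + c.ridge_amplitude * ridge / 1.5)

    def dermis_texture(self, xy: np.ndarray) -> np.ndarray:
        """Multiplicative reflectivity factor for the dermis, ≥ ~0."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        c = self.config
        kt = 2 * np.pi / c.dermis_texture_period
        p = self._texture_phase
        dt = self._texture_detune
        tex = (np.sin(kt * dt[0] * xy[:, 0] + p[0])
               * np.sin(kt * dt[1] * xy[:, 1] + p[1])
               + 0.6 * np.sin(1.9 * kt * dt[2] * xy[:, 0] + p[2])
               * np.sin(1.4 * kt * xy[:, 1] + p[3])
               + 0.4 * np.sin(0.6 * kt * xy[:, 0] + p[4])
               * np.sin(0.7 * kt * xy[:, 1] + p[5]))
        return 1.0 + c.dermis_texture_amplitude * tex / 2.0

    def _draw_beads(self, rng: np.random.Generator) -> np.ndarray:
        c = self.config
        r = c.bead_diameter / 2.0
        centers = []
        # Rejection-sample bead centers inside the gel above the tissue.
        for _ in range(100 * max(c.bead_count, 1)):
            if len(centers) >= c.bead_count:
                break
            x = rng.uniform(r, c.extent[0] - r)
            y = rng.uniform(r, c.extent[1] - r)
            zs = float(self.surface_height([[x, y]])[0])
            if zs - r <= r:
                continue
            z = rng.uniform(r, zs - r)
            centers.append([x, y, z])
        return np.asarray(centers, dtype=float).reshape(-1, 3)

    def _draw_chunks(self, rng: np.random.Generator) -> np.ndarray:
        """Gelatin chunks: (x, y, z, r) spheres suspended in the gel."""
        c = self.config
        out = []
        for _ in range(50 * max(c.chunk_count, 1)):
            if len(out) >= c.chunk_count:
                break
            r = rng.uniform(*c.chunk_radius)
            x = rng.uniform(r, c.extent[0] - r)
            y = rng.uniform(r, c.extent[1] - r)
            zs = float(self.surface_height([[x, y]])[0])
            if zs - r <= r:
                continue
            z = rng.uniform(r, zs - r)
            out.append([x, y, z, r])
        return np.asarray(out, dtype=float).reshape(-1, 4)

    def label_at(self, pts: np.ndarray) -> np.ndarray:
        """Material label at arbitrary (n, 3) μm points."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        zs = self.surface_height(pts[:, :2])
        thick = self.epidermis_thickness(pts[:, :2])
        z = pts[:, 2]
        lab = np.full(len(pts), LABEL_GEL, dtype=np.uint8)
        lab[z >= zs] = LABEL_EPIDERMIS
        lab[z >= zs + thick] = LABEL_DERMIS
        rf = self.config.follicle_radius
        for fx, fy, fl in self.follicles:
            lat2 = (pts[:, 0] - fx) ** 2 + (pts[:, 1] - fy) ** 2
            inside = (lat2 <= rf * rf) & (z >= zs) & (z <= zs + fl)
            lab[inside] = LABEL_FOLLICLE
        for cx, cy, cz, cr in self.chunks:
            d2 = ((pts[:, 0] - cx) ** 2 + (pts[:, 1] - cy) ** 2
                  + (pts[:, 2] - cz) ** 2)
            lab[d2 <= cr * cr] = LABEL_CHUNK
        if len(self.bead_centers):
            r = self.config.bead_diameter / 2.0
            d2 = ((pts[:, None, :] - self.bead_centers[None, :, :]) ** 2).sum(-1)
            lab[(d2 <= r * r).any(axis=1)] = LABEL_BEAD
        return lab

    # -- rasterization ------------------------------------------------------

    def _grid(
        self,
        voxel_size: Optional[float],
        region: Optional[tuple] = None,
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        vs = voxel_size if voxel_size is not None else self.config.voxel_size
        if region is None:
            lo = np.zeros(3)
            hi = np.asarray(self.config.extent, float)
        else:
            lo = np.maximum(np.asarray([r[0] for r in region], float), 0.0)
            hi = np.minimum(np.asarray([r[1] for r in region], float),
                            self.config.extent)
        axes = [np.arange(lo[a], hi[a] + 0.5 * vs, vs) for a in range(3)]
        return axes[0], axes[1], axes[2], lo

    def rasterize_labels(
        self, voxel_size: Optional[float] = None, region=None
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Label volume; returns (labels, origin, spacing)."""
        xs, ys, zs_ax, lo = self._grid(voxel_size, region)
        vs = voxel_size if voxel_size is not None else self.config.voxel_size
        xx, yy = np.meshgrid(xs, ys, indexing="ij")
        xy = np.column_stack([xx.ravel(), yy.ravel()])
        surf = self.surface_height(xy).reshape(xx.shape)
        thick = self.epidermis_thickness(xy).reshape(xx.shape)
        z = zs_ax[None, None, :]
        lab = np.full(xx.shape + (len(zs_ax),), LABEL_GEL, dtype=np.uint8)
        lab[z >= surf[:, :, None]] = LABEL_EPIDERMIS
        lab[z >= (surf + thick)[:, :, None]] = LABEL_DERMIS
        rf = self.config.follicle_radius
        for fx, fy, fl in self.follicles:
            i0 = np.searchsorted(xs, fx - rf)
            i1 = np.searchsorted(xs, fx + rf, side="right")
            j0 = np.searchsorted(ys, fy - rf)
            j1 = np.searchsorted(ys, fy + rf, side="right")
            if i0 >= i1 or j0 >= j1:
                continue
            sx, sy = np.meshgrid(xs[i0:i1], ys[j0:j1], indexing="ij")
            lat = (sx - fx) ** 2 + (sy - fy) ** 2 <= rf * rf
            s = surf[i0:i1, j0:j1]
            zz = zs_ax[None, None, :]
            inside = (lat[:, :, None] & (zz >= s[:, :, None])
                      & (zz <= (s + fl)[:, :, None]))
            lab[i0:i1, j0:j1, :][inside] = LABEL_FOLLICLE
        for cx, cy, cz, cr in self.chunks:
            i0 = np.searchsorted(xs, cx - cr)
            i1 = np.searchsorted(xs, cx + cr, side="right")
            j0 = np.searchsorted(ys, cy - cr)
            j1 = np.searchsorted(ys, cy + cr, side="right")
            k0 = np.searchsorted(zs_ax, cz - cr)
            k1 = np.searchsorted(zs_ax, cz + cr, side="right")
            if i0 >= i1 or j0 >= j1 or k0 >= k1:
                continue
            sx, sy, sz = np.meshgrid(xs[i0:i1], ys[j0:j1], zs_ax[k0:k1],
                                     indexing="ij")
            inside = ((sx - cx) ** 2 + (sy - cy) ** 2
                      + (sz - cz) ** 2) <= cr * cr
            lab[i0:i1, j0:j1, k0:k1][inside] = LABEL_CHUNK
        r = self.config.bead_diameter / 2.0
        for c in self.bead_centers:
            i0 = np.searchsorted(xs, c[0] - r)
            i1 = np.searchsorted(xs, c[0] + r, side="right")
            j0 = np.searchsorted(ys, c[1] - r)
            j1 = np.searchsorted(ys, c[1] + r, side="right")
            k0 = np.searchsorted(zs_ax, c[2] - r)
            k1 = np.searchsorted(zs_ax, c[2] + r, side="right")
            if i0 >= i1 or j0 >= j1 or k0 >= k1:
                continue
            sx, sy, sz = np.meshgrid(xs[i0:i1], ys[j0:j1], zs_ax[k0:k1],
                                     indexing="ij")
            inside = ((sx - c[0]) ** 2 + (sy - c[1]) ** 2
                      + (sz - c[2]) ** 2) <= r * r
            lab[i0:i1, j0:j1, k0:k1][inside] = LABEL_BEAD
        origin = np.array([xs[0], ys[0], zs_ax[0]])
        return lab, origin, np.full(3, vs)

    def rasterize_oct(
        self, voxel_size: Optional[float] = None, region=None
    ) -> Volume:
        """OCT-like intensity volume: layer contrast, speckle in the
        dermis, Beer–Lambert attenuation below the surface, PSF blur,
        and a small additive noise floor."""
        c = self.config
        lab, origin, spacing = self.rasterize_labels(voxel_size, region)
        vs = spacing[0]
        base = np.choose(lab, [c.gel_intensity, c.epidermis_intensity,
                               c.dermis_intensity, c.bead_intensity,
                               c.follicle_intensity, c.chunk_intensity])
        rng = np.random.default_rng(self._speckle_seed)
        if c.dermis_speckle_contrast > 0:
            sp = rng.exponential(1.0, size=lab.shape)
            mix = np.where(lab == LABEL_DERMIS, c.dermis_speckle_contrast, 0.0)
            base = base * ((1.0 - mix) + mix * sp)
        # depth below the local surface, in μm
        xs = origin[0] + np.arange(lab.shape[0]) * vs
        ys = origin[1] + np.arange(lab.shape[1]) * vs
        xx, yy = np.meshgrid(xs, ys, indexing="ij")
        lateral = np.column_stack([xx.ravel(), yy.ravel()])
        tex = self.dermis_texture(lateral).reshape(xx.shape)
        base = np.where(lab == LABEL_DERMIS,
                        base * tex[:, :, None], base)
        surf = self.surface_height(lateral).reshape(xx.shape)
        z = origin[2] + np.arange(lab.shape[2]) * vs
        depth = np.clip(z[None, None, :] - surf[:, :, None], 0.0, None)
        base = base * np.exp(-c.attenuation * depth)
        sig_lat = c.psf_lateral / 2.355 / vs
        sig_ax = c.psf_axial / 2.355 / vs
        base = ndimage.gaussian_filter(base, (sig_lat, sig_lat, sig_ax))
        if c.noise_floor > 0:
            base = np.abs(base + rng.normal(0.0, c.noise_floor, base.shape))
        return Volume(base, spacing, origin, intensity_domain="linear")

    def rasterize_fluor(
        self,
        pattern: Optional[BarcodePattern] = None,
        voxel_size: Optional[float] = None,
        region=None,
    ) -> Volume:
        """Fluorescence channel: bright gel, dim tissue, bright beads,
        optionally photobleached with a barcode pattern."""
        lab, origin, spacing = self.rasterize_labels(voxel_size, region)
        fl = np.choose(lab, _FLUOR_LEVELS)
        vol = Volume(fl, spacing, origin, intensity_domain="linear")
        if pattern is not None:
            vol = apply_bleach(vol, pattern)
        return vol

    def truth(self, lateral_step: float = 1.0) -> PhantomTruth:
        """Ground-truth container with the surface rasterized at
        ``lateral_step`` μm."""
        c = self.config
        xs = np.arange(0.0, c.extent[0] + 0.5 * lateral_step, lateral_step)
        ys = np.arange(0.0, c.extent[1] + 0.5 * lateral_step, lateral_step)
        xx, yy = np.meshgrid(xs, ys, indexing="ij")
        z = self.surface_height(
            np.column_stack([xx.ravel(), yy.ravel()])).reshape(xx.shape)
        surf = HeightMap(z, np.array([lateral_step, lateral_step]),
                         np.zeros(2))
        return PhantomTruth(
            surface=surf,
            bead_centers=self.bead_centers.copy(),
            config=c,
        )


def make_phantom(
    config: PhantomConfig, seed: Optional[int] = None
) -> tuple[Volume, Volume, PhantomTruth]:
    """Rasterize a full phantom: (OCT volume, fluorescence volume, truth).

    Memory scales with the voxel count (extent / voxel_size)³; for
    Monte-Carlo studies prefer the :class:`Phantom` object, whose
    analytic fields and region-restricted rasterization avoid building
    full-size volumes.
    """
    ph = Phantom(config, seed)
    oct_vol = ph.rasterize_oct()
    fluor = ph.rasterize_fluor()
    truth = ph.truth(lateral_step=config.voxel_size)
    lab, origin, spacing = ph.rasterize_labels()
    truth.labels = lab
    return oct_vol, fluor, truth


def apply_bleach(fluor: Volume, pattern: BarcodePattern) -> Volume:
    """Photobleach the barcode into the fluorescence volume.

    Each bleached plane multiplies the fluorescence by a Gaussian trough
    of FWHM ``line_width`` around the plane, through the full depth.
    """
    xs = fluor.origin[0] + np.arange(fluor.shape[0]) * fluor.spacing[0]
    ys = fluor.origin[1] + np.arange(fluor.shape[1]) * fluor.spacing[1]
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    sigma = pattern.line_width / 2.355
    depth_of_bleach = 0.9
    factor = np.ones_like(xx)
    for p in pattern.planes:
        dist = np.cos(p.theta) * xx + np.sin(p.theta) * yy - p.d
        factor *= 1.0 - depth_of_bleach * np.exp(-dist ** 2 / (2 * sigma ** 2))
    return Volume(fluor.data * factor[:, :, None], fluor.spacing.copy(),
                  fluor.origin.copy(), fluor.focal_depth,
                  fluor.intensity_domain)


# ---------------------------------------------------------------------------
# Sectioning simulation.

_HE_COLORS = {
    LABEL_GEL: (0.96, 0.95, 0.90),        # pale gel
    LABEL_EPIDERMIS: (0.45, 0.30, 0.58),  # hematoxylin-dark epithelium
    LABEL_DERMIS: (0.91, 0.62, 0.72),     # eosin-pink stroma
    LABEL_BEAD: (0.35, 0.35, 0.40),
    LABEL_FOLLICLE: (0.55, 0.40, 0.62),   # epithelial tube
    LABEL_CHUNK: (0.90, 0.88, 0.80),      # denser gelatin
}

# fluorescence per label: gel bright, tissue dim, beads very bright
_FLUOR_LEVELS = [1.0, 0.15, 0.10, 2.0, 0.12, 0.8]


def _section_true_map(
    base: PlaneMap, k: int, spacing: float, s_y: float
) -> PlaneMap:
    n = plane_normal(base)
    return base.translated(k * spacing * s_y * n)


def _top_contour(
    ph: Phantom, m: PlaneMap, extent: tuple[float, float],
    step: float = 25.0,
) -> np.ndarray:
    """(u, v_top) samples where the section crosses the gel/tissue surface."""
    w, h = extent
    us = np.arange(0.0, w + 0.5 * step, step)
    out = []
    for u in us:
        def f(v: float) -> float:
            p = map_points(m, [[u, v]])[0]
            return p[2] - float(ph.surface_height([p[:2]])[0])
        try:
            lo, hi = 0.0, h
            if f(lo) * f(hi) > 0:
                continue
            v = brentq(f, lo, hi, xtol=1e-6)
        except ValueError:
            continue
        out.append([u, v])
    return np.asarray(out, dtype=float)


def render_he_section(
    ph: Phantom, m: PlaneMap, extent: tuple[float, float],
    pixel_size: float = 1.0, rng: Optional[np.random.Generator] = None,
) -> Image2D:
    """Stylized H&E rendering of the section (label coloring + texture)."""
    w, h = extent
    nu = int(np.ceil(w / pixel_size))
    nv = int(np.ceil(h / pixel_size))
    uu, vv = np.meshgrid(np.arange(nu) * pixel_size,
                         np.arange(nv) * pixel_size, indexing="xy")
    pts = map_points(m, np.column_stack([uu.ravel(), vv.ravel()]))
    lab = ph.label_at(pts).reshape(nv, nu)
    img = np.zeros((nv, nu, 3))
    for l, color in _HE_COLORS.items():
        img[lab == l] = color
    if rng is not None:
        img = np.clip(img * (1.0 + rng.normal(0.0, 0.03, (nv, nu, 1))), 0, 1)
    return Image2D(img, pixel_size)


def render_fluor_section(
    ph: Phantom, m: PlaneMap, pattern: Optional[BarcodePattern],
    extent: tuple[float, float], pixel_size: float = 1.0,
    rng: Optional[np.random.Generator] = None,
) -> Image2D:
    """Fluorescence rendering of the section, with bleached barcode lines."""
    w, h = extent
    nu = int(np.ceil(w / pixel_size))
    nv = int(np.ceil(h / pixel_size))
    uu, vv = np.meshgrid(np.arange(nu) * pixel_size,
                         np.arange(nv) * pixel_size, indexing="xy")
    pts = map_points(m, np.column_stack([uu.ravel(), vv.ravel()]))
    lab = ph.label_at(pts)
    fl = np.choose(lab, _FLUOR_LEVELS)
    if pattern is not None:
        sigma = pattern.line_width / 2.355
        factor = np.ones(len(pts))
        for p in pattern.planes:
            dist = pts[:, 0] * np.cos(p.theta) + pts[:, 1] * np.sin(p.theta) - p.d
            factor *= 1.0 - 0.9 * np.exp(-dist ** 2 / (2 * sigma ** 2))
        fl = fl * factor
    img = fl.reshape(nv, nu)
    if rng is not None:
        img = np.clip(img + rng.normal(0.0, 0.02, img.shape), 0, None)
    return Image2D(img, pixel_size)


def simulate_sectioning(
    ph: Phantom,
    true_dec: PlaneDecomposition,
    pattern: BarcodePattern,
    n_sections: int = 1,
    spacing: float = 25.0,
    pick_noise_sigma: float = 10.0,
    picks_per_line: int = 2,
    seed: int = 0,
    extent: tuple[float, float] = (1000.0, 500.0),
    render: bool = False,
    pixel_size: float = 1.0,
    contour_step: float = 25.0,
    contour_noise_sigma: float = 3.0,
) -> tuple[list[SectionObservation], list[Optional[Image2D]],
           list[Optional[Image2D]], list[PlaneMap]]:
    """Simulate cutting, fluorescence imaging, and user line picks.

    Section k's true map is the composed base map translated by
    ``k · spacing · s_y`` along the plane normal (the nominal spacing in
    block μm, shrunk by the out-of-plane scale).  Picks are
    ``picks_per_line`` points along each predicted barcode line plus
    i.i.d. isotropic Gaussian jitter of ``pick_noise_sigma`` μm.  The
    top contour gets independent v jitter of ``contour_noise_sigma``
    (default 3 μm): the gel/tissue boundary is a sharp edge and is
    traced much more precisely than the center of a ~25 μm-wide
    bleached line is clicked.  Images are rendered only when
    ``render=True``.

    Returns (observations, fluorescence images, H&E images, true maps).
    Observed lines are unlabeled: correspondence is the estimator's job.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    rng = np.random.default_rng(seed)
    base = compose(true_dec)
    s_y = float(true_dec.scales[1])
    observations: list[SectionObservation] = []
    fluor_images: list[Optional[Image2D]] = []
    he_images: list[Optional[Image2D]] = []
    true_maps: list[PlaneMap] = []
    for k in range(n_sections):
        m = _section_true_map(base, k, spacing, s_y)
        predicted = predict_section_lines(pattern, m, extent)
        if len(predicted) == 0:
            continue
        lines = []
        for _, _, (p0, p1) in predicted:
            t = np.linspace(0.15, 0.85, picks_per_line)
            picks = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
            if pick_noise_sigma > 0:
                picks = picks + rng.normal(0.0, pick_noise_sigma, picks.shape)
            lines.append(ObservedLine(picks))
        contour = _top_contour(ph, m, extent, step=contour_step)
        if len(contour) and contour_noise_sigma > 0:
            contour = contour.copy()
            contour[:, 1] += rng.normal(0.0, contour_noise_sigma, len(contour))
        order = rng.permutation(len(lines))
        lines = [lines[i] for i in order]
        observations.append(SectionObservation(
            section_id=f"s{k:03d}",
            lines=lines,
            top_contour=contour if len(contour) else None,
            nominal_index=k,
        ))
        true_maps.append(m)
        if render:
            fluor_images.append(render_fluor_section(
                ph, m, pattern, extent, pixel_size, rng))
            he_images.append(render_he_section(
                ph, m, extent, pixel_size, rng))
        else:
            fluor_images.append(None)
            he_images.append(None)
    return observations, fluor_images, he_images, true_maps


# ---------------------------------------------------------------------------
# Bead validation.

def beads_in_section(
    truth: PhantomTruth, m_true: PlaneMap, section_thickness: float = 5.0
) -> np.ndarray:
    """Indices of beads whose center lies within radius + half thickness
    of the true section plane."""
    if truth.config is None:
        raise ValueError("truth must carry its config (bead diameter)")
    r = truth.config.bead_diameter / 2.0
    n = plane_normal(m_true)
    p0 = m_true.offset
    dist = np.abs((truth.bead_centers - p0) @ n)
    return np.nonzero(dist <= r + section_thickness / 2.0)[0]


def bead_colocation_error(
    truth: PhantomTruth,
    m_true: PlaneMap,
    m_est: PlaneMap,
    section_thickness: float = 5.0,
) -> float:
    """Mean 3D bead colocation error of an estimated plane map, μm.

    Each bead intersecting the true section appears in the section image
    at its in-plane coordinates (u, v) — the least-squares projection of
    its center through the true map.  Mapping those observed coordinates
    through the *estimated* map predicts a 3D position; the mean
    distance to the true centers measures coregistration accuracy the
    way the bead experiments do.  Includes the irreducible out-of-plane
    offset of each bead center within the section slab.
    """
    idx = beads_in_section(truth, m_true, section_thickness)
    if len(idx) == 0:
        raise NoBeadsError("no bead intersects the section")
    centers = truth.bead_centers[idx]
    # Observed (u, v): least-squares inverse of the true affine map.
    uv, *_ = np.linalg.lstsq(
        m_true.linear, (centers - m_true.offset).T, rcond=None)
    predicted = map_points(m_est, uv.T)
    return float(np.mean(np.linalg.norm(predicted - centers, axis=1)))
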