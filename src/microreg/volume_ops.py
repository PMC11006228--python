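"""OCT volume containers and raster operations.

Axis convention: in-memory volume data is indexed ``data[i, j, k]`` for
(x, y, z) with physical position ``origin + (i·Δx, j·Δy, k·Δz)`` in μm.
On disk a volume is a multi-page TIFF (pages along z, rows along y,
columns along x) with a JSON sidecar carrying spacing, origin, focal
depth, and intensity domain.

2D images are indexed ``data[row, col]`` = (v, u): row index increases
with section depth v, matching how a section is displayed with the
surface at the top.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import tifffile
from scipy import ndimage
from skimage.morphology import disk

from .geometry import PlaneMap, map_points

__all__ = [
    "Volume",
    "HeightMap",
    "Image2D",
    "GridMismatchError",
    "SurfaceNotFoundError",
    "reslice",
    "stitch_focus_stack",
    "detect_surface",
    "snr_mask",
    "write_volume",
    "read_volume",
]


class GridMismatchError(ValueError):
    """Volumes do not share a compatible sampling grid."""


class SurfaceNotFoundError(ValueError):
    """No intensity step resembling a tissue surface was found."""


@dataclass
class Volume:
    """3D scalar intensity raster with physical spacing.

    Attributes
    ----------
    data : (nx, ny, nz) ndarray
    spacing : (Δx, Δy, Δz) μm
    origin : (3,) μm, position of voxel (0, 0, 0)
    focal_depth : optional focal-plane depth in μm (for focus stacking)
    intensity_domain : "linear" or "dB"
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    focal_depth: Optional[float] = None
    intensity_domain: str = "linear"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3D")
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValueError("spacing must be 3 positive values")
        if self.origin.shape != (3,):
            raise ValueError("origin must be length 3")
        if self.intensity_domain not in ("linear", "dB"):
            raise ValueError("intensity_domain must be 'linear' or 'dB'")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def z_coords(self) -> np.ndarray:
        return self.origin[2] + np.arange(self.shape[2]) * self.spacing[2]

    def same_lateral_grid(self, other: "Volume", tol: float = 1e-6) -> bool:
        return (
            self.shape[:2] == other.shape[:2]
            and np.allclose(self.spacing[:2], other.spacing[:2], atol=tol)
            and np.allclose(self.origin[:2], other.origin[:2], atol=tol)
        )


@dataclass
class HeightMap:
    """Surface height z(x, y) in μm on a volume's lateral grid.

    Missing columns (no surface found) are NaN.
    """

    z: np.ndarray                # (nx, ny) μm
    spacing: np.ndarray          # (Δx, Δy)
    origin: np.ndarray           # (x0, y0)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.z.ndim != 2:
            raise ValueError("height map must be 2D")

    def sample(self, xy: np.ndarray) -> np.ndarray:
        """Bilinear height at (n, 2) lateral positions (μm); NaN outside."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        idx = (xy - self.origin) / self.spacing
        filled = self.z
        if np.any(np.isnan(filled)):
            # Fill missing columns from their nearest valid neighbor so
            # bilinear sampling stays defined near holes.
            mask = np.isnan(filled)
            ind = ndimage.distance_transform_edt(
                mask, return_distances=False, return_indices=True)
            filled = filled[tuple(ind)]
        vals = ndimage.map_coordinates(
            filled, idx.T, order=1, mode="constant", cval=np.nan)
        inside = np.all(
            (idx >= 0) & (idx <= np.array(self.z.shape) - 1), axis=1)
        vals = np.where(inside, vals, np.nan)
        return vals


@dataclass
class Image2D:
    """2D raster (scalar or RGB) with pixel size (μm) and validity mask."""

    data: np.ndarray
    pixel_size: float
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (2, 3):
            raise ValueError("image must be 2D scalar or HxWx3 RGB")
        if self.mask is None:
            self.mask = np.ones(self.data.shape[:2], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.data.shape[:2]:
            raise ValueError("mask shape must equal image shape")
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be positive")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def copy(self) -> "Image2D":
        return Image2D(self.data.copy(), self.pixel_size, self.mask.copy())


def reslice(
    volume: Volume,
    m: PlaneMap,
    extent: tuple[float, float],
    pixel_size: float = 1.0,
    fill: float = 0.0,
) -> Image2D:
    """Extract an oblique 2D image from the volume along a plane map.

    Samples the volume by trilinear interpolation at
    ``map_points(m, (i·ps, j·ps))`` for i < ceil(W/ps), j < ceil(H/ps).
    Samples falling outside the voxel grid receive ``fill`` and
    mask=False.  Trilinear interpolation is exact on multilinear
    intensity fields and reduces to a raster slice on axis-aligned
    planes that hit voxel centers.
    """
    m.require_nondegenerate()
    w, h = extent
    nu = int(np.ceil(w / pixel_size))
    nv = int(np.ceil(h / pixel_size))
    u = np.arange(nu) * pixel_size
    v = np.arange(nv) * pixel_size
    uu, vv = np.meshgrid(u, v, indexing="xy")       # rows = v, cols = u
    pts = np.column_stack([uu.ravel(), vv.ravel()])
    xyz = map_points(m, pts)
    idx = (xyz - volume.origin) / volume.spacing     # fractional voxel index
    eps = 1e-9
    inside = np.all(
        (idx >= -eps) & (idx <= np.array(volume.shape) - 1 + eps), axis=1)
    vals = ndimage.map_coordinates(
        np.asarray(volume.data, dtype=float), idx.T, order=1,
        mode="grid-constant", cval=fill)
    vals = np.where(inside, vals, fill)
    return Image2D(vals.reshape(nv, nu), pixel_size, inside.reshape(nv, nu))


def stitch_focus_stack(
    volumes: Sequence[Volume],
    sigma_f: Optional[float] = None,
    equalize: bool = True,
) -> Volume:
    """Fuse focus-translated volume scans into one volume.

    Each scan is sharpest near its focal depth, so voxels are averaged
    with Gaussian depth weights ``w_k(z) = exp(−(z − focal_k)² / 2σ_f²)``
    renormalized to sum to one wherever any scan covers z.  Before
    fusion, per-volume gains equalize median intensity over the jointly
    covered region.  σ_f defaults to the focal step between consecutive
    scans.

    Volumes must share the lateral grid and z-spacing; z-origins may
    differ by integer multiples of Δz (the acquisition translates the
    sample axially between scans).
    """
    if len(volumes) == 0:
        raise ValueError("no volumes to stitch")
    if len(volumes) == 1:
        v = volumes[0]
        return Volume(v.data.copy(), v.spacing.copy(), v.origin.copy(),
                      v.focal_depth, v.intensity_domain)

    ref = volumes[0]
    dz = ref.spacing[2]
    for v in volumes:
        if not ref.same_lateral_grid(v):
            raise GridMismatchError("volumes do not share the lateral grid")
        if not np.isclose(v.spacing[2], dz):
            raise GridMismatchError("volumes do not share the z spacing")
        off = (v.origin[2] - ref.origin[2]) / dz
        if abs(off - round(off)) > 1e-6:
            raise GridMismatchError(
                "z origins must differ by integer multiples of Δz")
        if v.focal_depth is None:
            raise ValueError("every volume needs a focal_depth for stitching")

    focals = [v.focal_depth for v in volumes]
    order = np.argsort(focals)
    vols = [volumes[i] for i in order]
    focals = [focals[i] for i in order]
    if len(set(focals)) != len(focals):
        raise ValueError("focal depths must be strictly increasing")
    if sigma_f is None:
        sigma_f = float(np.min(np.diff(focals))) if len(focals) > 1 else dz

    k_off = [int(round((v.origin[2] - ref.origin[2]) / dz)) for v in vols]
    k_lo = min(k_off)
    k_hi = max(k + v.shape[2] for k, v in zip(k_off, vols))
    nz = k_hi - k_lo
    nx, ny = ref.shape[:2]
    out_origin = ref.origin.copy()
    out_origin[2] = ref.origin[2] + k_lo * dz
    zgrid = out_origin[2] + np.arange(nz) * dz

    # Median-intensity equalization over the jointly covered z-range.
    gains = np.ones(len(vols))
    if equalize:
        lo = max(k for k in k_off) - k_lo
        hi = min(k + v.shape[2] for k, v in zip(k_off, vols)) - k_lo
        if hi > lo:
            meds = np.array([
                float(np.median(v.data[:, :, lo - (k - k_lo):hi - (k - k_lo)]))
                for k, v in zip(k_off, vols)
            ])
            target = float(np.median(meds))
            with np.errstate(divide="ignore", invalid="ignore"):
                gains = np.where(meds > 0, target / meds, 1.0)

    acc = np.zeros((nx, ny, nz))
    wsum = np.zeros(nz)
    for gain, k, v, f in zip(gains, k_off, vols, focals):
        sl = slice(k - k_lo, k - k_lo + v.shape[2])
        w = np.exp(-((zgrid[sl] - f) ** 2) / (2.0 * sigma_f ** 2))
        acc[:, :, sl] += (gain * v.data) * w
        wsum[sl] += w
    covered = wsum > 0
    out = np.zeros_like(acc)
    out[:, :, covered] = acc[:, :, covered] / wsum[covered]
    return Volume(out, ref.spacing.copy(), out_origin,
                  intensity_domain=ref.intensity_domain)


def focus_weights(
    zgrid: np.ndarray, focals: Sequence[float], sigma_f: float
) -> np.ndarray:
    """Normalized Gaussian fusion weights, shape (n_volumes, nz)."""
    w = np.exp(-((zgrid[None, :] - np.asarray(focals)[:, None]) ** 2)
               / (2.0 * sigma_f ** 2))
    return w / w.sum(axis=0, keepdims=True)


def detect_surface(
    volume: Volume,
    min_jump: float,
    smooth_sigma_um: float = 3.0,
) -> HeightMap:
    """Find the tissue/gel surface as the first bright step along depth.

    Per lateral position, A-lines are Gaussian-smoothed along z and the
    surface is the first z where the intensity crosses
    (background + min_jump), background being the per-A-line median of
    the shallowest 10% of samples.  The height map is 3×3 median
    filtered; columns with no crossing are NaN.
    """
    data = volume.data.astype(float)
    nz = data.shape[2]
    sigma_vox = max(smooth_sigma_um / volume.spacing[2], 0.5)
    smoothed = ndimage.gaussian_filter1d(data, sigma_vox, axis=2)
    n_bg = max(3, nz // 10)
    background = np.median(smoothed[:, :, :n_bg], axis=2)
    above = smoothed > (background + min_jump)[:, :, None]
    has = above.any(axis=2)
    if not has.any():
        raise SurfaceNotFoundError(
            "no A-line crosses background + min_jump anywhere")
    first = np.argmax(above, axis=2).astype(float)
    z = volume.origin[2] + first * volume.spacing[2]
    z[~has] = np.nan
    # Median filter, NaN-aware: filter on nearest-filled copy, restore NaN.
    if np.any(~has):
        ind = ndimage.distance_transform_edt(
            ~has, return_distances=False, return_indices=True)
        zf = z[tuple(ind)]
    else:
        zf = z
    zf = ndimage.median_filter(zf, size=3, mode="nearest")
    zf[~has] = np.nan
    return HeightMap(zf, volume.spacing[:2].copy(), volume.origin[:2].copy())


def snr_mask(
    image: Image2D,
    surface_trace: Optional[np.ndarray] = None,
    depth_cutoff: float = 450.0,
    noise_quantile: float = 0.10,
    k_sigma: float = 3.0,
    local_window_px: int = 5,
    opening_radius: int = 3,
) -> Image2D:
    """Mask pixels whose OCT signal falls below the noise floor.

    The noise floor is estimated from the deepest ``noise_quantile``
    fraction of image rows (optical extinction guarantees they are
    signal-starved).  A pixel is valid when its local mean intensity
    exceeds floor + k_sigma·SD and it lies no deeper than
    ``depth_cutoff`` μm below the surface trace (about the depth limit
    of reasonable OCT SNR in skin).  Morphological opening removes
    speckle-sized valid islands.  Returns a copy of the image whose
    mask is the intersection of its prior mask with the SNR mask.
    """
    if image.data.ndim != 2:
        raise ValueError("snr_mask expects a scalar image")
    data = image.data.astype(float)
    nv, nu = data.shape
    n_noise = max(1, int(np.ceil(noise_quantile * nv)))
    noise_rows = data[nv - n_noise:, :]
    floor = float(np.mean(noise_rows))
    sd = float(np.std(noise_rows))

    local_mean = ndimage.uniform_filter(data, size=local_window_px,
                                        mode="nearest")
    # a pixel needs nonzero signal AND clearance above the noise floor
    valid = (local_mean > 0) & (local_mean >= floor + k_sigma * sd)

    # Depth cutoff below the surface trace (v in μm = row · pixel size).
    v_um = np.arange(nv)[:, None] * image.pixel_size
    if surface_trace is None:
        surf = np.zeros((1, nu))
    else:
        surf = np.asarray(surface_trace, dtype=float).reshape(1, nu)
    valid &= (v_um - surf) <= depth_cutoff

    if opening_radius > 0:
        footprint = disk(opening_radius)
        # erosion treats out-of-image as valid so borders are not eaten
        valid = ndimage.binary_dilation(
            ndimage.binary_erosion(valid, footprint, border_value=1),
            footprint)
    out = image.copy()
    out.mask = image.mask & valid
    return out


# ---------------------------------------------------------------------------
# Disk I/O: multi-page TIFF (z pages) + JSON sidecar.

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_volume(path: str | Path, volume: Volume) -> None:
    """Write a volume as multi-page TIFF plus JSON sidecar (bit exact)."""
    path = Path(path)
    pages = np.ascontiguousarray(np.transpose(volume.data, (2, 1, 0)))
    tifffile.imwrite(path, pages)
    meta = {
        "spacing_um": volume.spacing.tolist(),
        "origin_um": volume.origin.tolist(),
        "focal_depth_um": volume.focal_depth,
        "intensity_domain": volume.intensity_domain,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_volume(path: str | Path) -> Volume:
    path = Path(path)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    data = np.transpose(pages, (2, 1, 0))
    meta = json.loads(_sidecar_path(path).read_text())
    return Volume(
        data,
        np.asarray(meta["spacing_um"], float),
        np.asarray(meta["origin_um"], float),
        meta.get("focal_depth_um"),
        meta.get("intensity_domain", "linear"),
    )
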