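"""Machine-learning-ready co-registered OCT/H&E pairs.

After plane estimation and reslicing, each section yields a grayscale
OCT image and an RGB H&E image on a shared 1 μm/pixel grid.  This
module turns them into training pairs: H&E stain color normalization,
cropping to 1024 × 512 pixels, joint validity masking (so that a pixel
with no reliable OCT signal is blanked in *both* modalities and the
downstream image-translation model cannot learn to hallucinate tissue
there), optional resize to 256 × 256, and a manifest for the dataset.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.color import hed2rgb, rgb2hed
from skimage.measure import block_reduce

from .volume_ops import Image2D

__all__ = [
    "PairedCrop",
    "StainStats",
    "stain_stats",
    "normalize_stain",
    "build_pair",
    "resize_for_model",
    "write_manifest",
    "read_manifest",
    "save_pair_images",
]

CROP_WIDTH = 1024    # px at 1 μm/pixel
CROP_HEIGHT = 512

OCT_FILL = 0.0
HE_FILL = 1.0        # white, background-consistent


@dataclass
class PairedCrop:
    """One co-registered OCT/H&E training pair with a shared mask."""

    oct: Image2D          # grayscale
    he: Image2D           # RGB, same grid
    mask: np.ndarray      # shared boolean raster
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.oct.data.shape[:2] != self.he.data.shape[:2]:
            raise ValueError("OCT and H&E rasters must share shape")
        if self.mask.shape != self.oct.data.shape[:2]:
            raise ValueError("mask must share the image shape")

    @property
    def mask_fraction(self) -> float:
        return float(self.mask.mean())


@dataclass(frozen=True)
class StainStats:
    """Reference percentiles of hematoxylin/eosin/DAB concentrations."""

    p99: tuple[float, float, float]
    percentile: float = 99.0


_BACKGROUND_LUMINANCE = 0.85


def _tissue_mask(rgb: np.ndarray) -> np.ndarray:
    return rgb.mean(axis=2) < _BACKGROUND_LUMINANCE


def stain_stats(he: Image2D, percentile: float = 99.0) -> StainStats:
    """Concentration percentiles of an H&E image, for use as reference."""
    rgb = np.clip(np.asarray(he.data, dtype=float), 1e-6, 1.0)
    hed = rgb2hed(rgb)
    tissue = _tissue_mask(rgb) & he.mask
    if not tissue.any():
        tissue = he.mask
    vals = tuple(
        float(np.percentile(hed[..., c][tissue], percentile))
        for c in range(3)
    )
    return StainStats(p99=vals, percentile=percentile)


def normalize_stain(
    he: Image2D, reference_stats: StainStats
) -> Image2D:
    """Normalize H&E staining against reference concentration statistics.

    The RGB image is deconvolved into hematoxylin/eosin/DAB optical
    densities with the standard Ruifrok–Johnston stain matrix, each
    concentration channel is rescaled so its tissue percentile matches
    the reference, and the *change* is applied to the original image as
    a multiplicative (optical-density) correction.  Correcting by the
    ratio of the rescaled to the plain reconstruction — rather than
    replacing the image with the reconstruction — makes normalization
    exactly the identity when the image already matches the reference
    and leaves background white untouched (near-zero concentrations are
    unaffected by channel scaling).  The operation is idempotent up to
    round-off.
    """
    rgb = np.asarray(he.data, dtype=float)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("normalize_stain expects an RGB image")
    rgb = np.clip(rgb, 1e-6, 1.0)
    tissue = _tissue_mask(rgb) & he.mask
    if not tissue.any():
        warnings.warn("no tissue pixels found; returning image unchanged")
        return he.copy()
    hed = rgb2hed(rgb)
    hed_scaled = hed.copy()
    for c in range(3):
        cur = float(np.percentile(hed[..., c][tissue],
                                  reference_stats.percentile))
        ref = reference_stats.p99[c]
        if cur > 1e-8 and ref > 1e-8:
            hed_scaled[..., c] *= ref / cur
    recon = np.clip(hed2rgb(hed), 1e-6, 1.0)
    recon_scaled = np.clip(hed2rgb(hed_scaled), 1e-6, 1.0)
    out = np.clip(rgb * (recon_scaled / recon), 0.0, 1.0)
    return Image2D(out, he.pixel_size, he.mask.copy())


def build_pair(
    oct_slice: Image2D,
    he: Image2D,
    snr: Image2D | np.ndarray,
    crop_origin: tuple[float, float] = (0.0, 0.0),
    oct_fill: float = OCT_FILL,
    he_fill: float = HE_FILL,
    provenance: Optional[dict] = None,
) -> PairedCrop:
    """Crop both modalities to 1024 × 512 px and apply the joint mask.

    ``crop_origin`` is the (u, v) position in μm of the crop's top-left
    corner.  Both images must share the 1 μm/pixel grid and cover the
    crop.  The shared mask is the intersection of both image masks with
    the SNR mask; masked pixels carry the fill value in both outputs.
    """
    if not np.isclose(oct_slice.pixel_size, he.pixel_size):
        raise ValueError("OCT and H&E images must share the pixel grid")
    ps = oct_slice.pixel_size
    snr_mask_arr = snr.mask if isinstance(snr, Image2D) else np.asarray(snr, bool)
    if snr_mask_arr.shape != oct_slice.data.shape[:2]:
        raise ValueError("SNR mask shape must equal the OCT image shape")

    col0 = int(round(crop_origin[0] / ps))
    row0 = int(round(crop_origin[1] / ps))
    row1, col1 = row0 + CROP_HEIGHT, col0 + CROP_WIDTH
    if (row0 < 0 or col0 < 0
            or row1 > oct_slice.data.shape[0] or col1 > oct_slice.data.shape[1]
            or row1 > he.data.shape[0] or col1 > he.data.shape[1]):
        raise ValueError(
            f"crop [{row0}:{row1}, {col0}:{col1}] exceeds the input images")

    sl = (slice(row0, row1), slice(col0, col1))
    mask = oct_slice.mask[sl] & he.mask[sl] & snr_mask_arr[sl]
    oct_data = np.array(oct_slice.data[sl], dtype=float)
    he_data = np.array(he.data[sl], dtype=float)
    oct_data[~mask] = oct_fill
    if he_data.ndim == 3:
        he_data[~mask] = he_fill
    else:
        he_data[~mask] = he_fill
    prov = dict(provenance or {})
    prov.setdefault("crop_origin_um", [col0 * ps, row0 * ps])
    prov.setdefault("oct_fill", oct_fill)
    prov.setdefault("he_fill", he_fill)
    return PairedCrop(
        oct=Image2D(oct_data, ps, mask.copy()),
        he=Image2D(he_data, ps, mask.copy()),
        mask=mask,
        provenance=prov,
    )


def resize_for_model(pair: PairedCrop) -> PairedCrop:
    """Downsample a 1024 × 512 pair to the model's 256 × 256 input.

    Area-weighted (block mean) resampling — anisotropic, 4× along u and
    2× along v, matching how the training code consumes the crops.  The
    mask pools with logical ALL-valid: a target cell containing any
    masked source pixel is masked.
    """
    h, w = pair.oct.data.shape[:2]
    if h % 256 or w % 256:
        raise ValueError("pair dimensions must be multiples of 256")
    fr, fc = h // 256, w // 256
    oct_small = block_reduce(pair.oct.data, (fr, fc), np.mean)
    if pair.he.data.ndim == 3:
        he_small = block_reduce(pair.he.data, (fr, fc, 1), np.mean)
    else:
        he_small = block_reduce(pair.he.data, (fr, fc), np.mean)
    mask_small = block_reduce(pair.mask, (fr, fc), np.min).astype(bool)
    ps = pair.oct.pixel_size * fc   # nominal; grid is anisotropic after this
    prov = dict(pair.provenance)
    prov["resized_to"] = [256, 256]
    return PairedCrop(
        oct=Image2D(oct_small, ps, mask_small.copy()),
        he=Image2D(he_small, ps, mask_small.copy()),
        mask=mask_small,
        provenance=prov,
    )


# ---------------------------------------------------------------------------
# Dataset output.

def _to_uint8(data: np.ndarray) -> np.ndarray:
    return np.clip(np.asarray(data, float) * 255.0 + 0.5, 0, 255).astype(np.uint8)


def save_pair_images(
    pair: PairedCrop, out_dir: str | Path, pair_id: str
) -> dict[str, str]:
    """Write OCT/H&E/mask PNGs; returns the relative file paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "oct_path": f"{pair_id}_oct.png",
        "he_path": f"{pair_id}_he.png",
        "mask_path": f"{pair_id}_mask.png",
    }
    iio.imwrite(out_dir / paths["oct_path"], _to_uint8(pair.oct.data))
    iio.imwrite(out_dir / paths["he_path"], _to_uint8(pair.he.data))
    iio.imwrite(out_dir / paths["mask_path"],
                (pair.mask.astype(np.uint8) * 255))
    return paths


def write_manifest(
    pairs: Sequence[PairedCrop],
    path: str | Path,
    pair_ids: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Write the dataset manifest as CSV; returns it as a DataFrame.

    One row per pair: pair_id, section_id, plane-map file, crop offset,
    mask fraction, image file paths.  Round-trips losslessly through
    :func:`read_manifest`.
    """
    if len(pairs) == 0:
        raise ValueError("no pairs to write")
    if pair_ids is None:
        pair_ids = [p.provenance.get("pair_id", f"pair{i:04d}")
                    for i, p in enumerate(pairs)]
    if len(set(pair_ids)) != len(pair_ids):
        raise ValueError("duplicate pair_id")
    rows = []
    for pid, p in zip(pair_ids, pairs):
        prov = p.provenance
        rows.append({
            "pair_id": pid,
            "section_id": prov.get("section_id", ""),
            "plane_map_file": prov.get("plane_map_file", ""),
            "crop_u_um": float(prov.get("crop_origin_um", [0, 0])[0]),
            "crop_v_um": float(prov.get("crop_origin_um", [0, 0])[1]),
            "mask_fraction": p.mask_fraction,
            "oct_path": prov.get("oct_path", ""),
            "he_path": prov.get("he_path", ""),
            "mask_path": prov.get("mask_path", ""),
        })
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df


def read_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path,
        dtype={"pair_id": str, "section_id": str, "plane_map_file": str,
               "oct_path": str, "he_path": str, "mask_path": str},
        keep_default_na=False,
    )
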