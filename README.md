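# microreg

Micro-registration of 2D histology sections to 3D optical coherence
tomography (OCT) volumes using photobleached barcode fiducials, and
construction of precisely aligned OCT–H&E image pairs.

## The problem

Training an image-translation model that turns label-free OCT scans of
fresh skin into virtual H&E histology requires image pairs that show the
*same* physical tissue plane in both modalities. But a histological
section is cut, shrunk, and mounted long after the OCT scan: nothing in
the standard workflow records where in the 3D volume the section came
from. `microreg` implements the fiducial-based solution: the tissue is
embedded in a fluorescent gel, a barcode of photobleached lines is
written into the gel through the OCT optics (so the barcode lives in the
scanner's coordinate frame), and each section carries the barcode's
intersection traces. From a handful of user clicks on those traces the
package recovers the nine parameters of the cut —

- 3 rotations (yaw of the cut and two out-of-plane tilts),
- 3 per-axis shrinkage scales,
- 3 translations,

as an affine map `p = L·(u, v) + t` from section coordinates (u, v) μm
to volume coordinates (x, y, z) μm — then reslices the OCT volume along
the recovered oblique plane and packages co-registered, jointly masked
1024 × 512 OCT/H&E crops (resizable to 256 × 256) for model training.

Accuracy is quantified by the **cross-plane error**: the distance, along
the true section's normal, between corresponding points of the true and
estimated mappings — the component of misregistration that in-plane
panning and stretching cannot fix.

## What is in the package

| module | contents |
| --- | --- |
| `microreg.geometry` | `PlaneMap` (3×2 linear + offset), 9-parameter decomposition, cross-plane error metric |
| `microreg.barcode` | bleached-plane patterns with scale-invariant gap codes, line prediction, correspondence decoding |
| `microreg.estimation` | in-plane least squares, depth resolution against the OCT surface, constrained joint polish, multi-section stack fitting, NCC fine alignment |
| `microreg.volume_ops` | volume container + TIFF/JSON I/O, trilinear oblique reslicing, focus-stack fusion, surface detection, SNR masking |
| `microreg.phantom` | synthetic skin-in-gel phantom with full ground truth (the test bed for everything above) |
| `microreg.pairs` | H&E stain normalization, joint masking/cropping/resizing, dataset manifests |
| `microreg.experiments` | Monte-Carlo parameter-recovery studies |

A thin CLI (`microreg simulate / estimate / pairs`) wraps the library
for shell use.

## Worked example

Recover a section cut at 47° yaw with anisotropic shrinkage from noisy
simulated line picks:

```python
import numpy as np
from microreg import (PhantomConfig, Phantom, PlaneDecomposition,
                      default_pattern, simulate_sectioning, match_lines,
                      cross_plane_error)
from microreg.estimation import estimate_section
from microreg.geometry import decompose

pattern = default_pattern()            # 2 × 4 bleached planes, 200 μm base gap
phantom = Phantom(PhantomConfig(), seed=11)

true_cut = PlaneDecomposition(
    angles=np.deg2rad([47.0, 2.5, -1.5]),   # yaw, two out-of-plane tilts
    scales=[0.88, 0.91, 0.95],              # per-axis shrinkage
    translation=[-50.0, -50.0, 0.0],
)
obs, _, _, true_maps = simulate_sectioning(
    phantom, true_cut, pattern, pick_noise_sigma=10.0, picks_per_line=2,
    seed=1, extent=(3000.0, 500.0))

labels, score = match_lines(obs[0].lines, pattern)
for i, lab in labels.items():
    obs[0].lines[i].label = lab
print(f"decoded {len(labels)} lines, worst gap deviation {score:.1%}")

surface = phantom.truth(lateral_step=2.0).surface
fit = estimate_section(obs[0], pattern, surface)
dec = decompose(fit.plane_map)
print("estimated scales:", np.round(dec.scales, 3),
      " yaw: %.1f deg" % np.rad2deg(dec.angles[0]))
print("cross-plane error vs truth: %.1f um"
      % cross_plane_error(true_maps[0], fit.plane_map))
```

Output:

```
decoded 8 lines, worst gap deviation 3.6%
estimated scales: [0.894 0.898 0.915]  yaw: 47.7 deg
cross-plane error vs truth: 2.8 um
```

All eight barcode lines were identified by their gap-ratio code despite
the 10 μm click jitter; the shrinkage scales come back within ~0.02 of
truth and the recovered plane lies within 3 μm of the true section
plane.

The same pipeline from the shell:

```sh
microreg simulate config.yaml --out data/ --seed 3     # phantom dataset
microreg estimate --picks data/picks.csv --pattern data/pattern.json \
    --volume data/oct.tif --contour data/contour.csv --out report.json
microreg pairs --report report.json --volume data/oct.tif \
    --he-dir data/ --out pairs/
```

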