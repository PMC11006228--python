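# Methods

## The plane model

A histological section is modeled as a flat 2D plane through the OCT
volume. The map from section coordinates (u, v) (μm on the slide; u
along the slide, v increasing with section depth) to volume coordinates
(x, y, z) (μm; x fast scan, y slow scan, z depth) is affine with nine
degrees of freedom:

```
p(u, v) = diag(s_x, s_y, s_z) · R(α, β, γ) · E · (u, v) + t
```

where `R = Rz(α)·Ry(β)·Rx(γ)` (intrinsic z–y–x Euler rotations),
`E` embeds (u, v) as (u, 0, v), `s` are per-axis shrinkage scales, and
`t` is the translation. The canonical all-zero section is the volume's
x–z plane — a vertical cross-section with the tissue surface near the
top, which is how skin histology is cut and mounted. α (yaw) is the
azimuth of the cut; β and γ are the out-of-plane tilts, which are small
(a few degrees) in practice.

Deviations from flatness (non-affine warping during processing) are
deliberately outside the model; they are the main unmodeled error
source on real tissue.

`decompose` inverts the composition in closed form: writing
`w_i = 1/s_i²`, orthonormality of the rotation columns gives three
equations *linear* in w, solved directly. Two geometric degeneracies
are handled by convention: for an exactly canonical section s_y is
unobservable (set to √(s_x·s_z), flagged), and when a section axis is
aligned with a volume axis a one-parameter scale gauge remains (the
minimum-norm solution is taken, flagged). Any flagged solution still
reproduces the input map exactly.

### The error metric

`cross_plane_error(m_true, m_est)` is the mean over a (u, v) grid
(default 1000 × 500 μm, 25 μm step) of `|n_true · (p_est − p_true)|`,
the displacement component along the true plane's normal. In-plane
displacements are invisible to it by construction: they are correctable
by panning/stretching during pair building, whereas cross-plane error
means the two images show physically different tissue.

## Barcode design and decoding

Photobleaching writes lines through the full gel depth, so each barcode
line is a **vertical plane** `cos θ·x + sin θ·y = d`. The default
pattern has two perpendicular families (θ = 0 and θ = π/2) of four
planes each, with offsets generated by gap codes [1, 1.25, 3.5] and
[1, 3.75, 2] times a 200 μm base gap, and a 25 μm line width.

Because a near-vertical section intersects every vertical plane in a
near-vertical trace, the two families generally *cannot* be told apart
by trace orientation; they appear as one interleaved sequence of almost
parallel lines. Decoding therefore rests entirely on gap ratios, which
survive uniform shrinkage. Three design rules make it unique:

1. **Distinct codes per family.** With identical codes, swapping the
   family assignment admits an exact mirror-image plane map — the pick
   residual cannot discriminate it.
2. **Window separation.** The two codes were chosen by exhaustive
   search so that every contiguous gap window of length ≥ 2, forward or
   reversed, of either family differs by ≥ 24% in shape from every
   other window — well above the 15% matching tolerance — so decoding
   stays unique when edge lines fall outside the slide's field of view.
3. **Minimum gap = base gap.** 10 μm click noise is then ≤ ~5% of any
   gap.

`match_lines` first clusters traces by orientation (single-linkage,
10° tolerance). If two clusters separate (strongly tilted cuts), each
cluster's ordered gap sequence is matched to a family code with a free
scale, forward or reversed. In the typical single-cluster geometry the
decoder searches over all family assignments of the position-ordered
lines (trace positions measured by projecting line centroids on the
*mean* trace normal, which suppresses per-line orientation noise),
keeps assignments whose per-family gaps match the codes, and ranks them
by the residual of the six-unknown in-plane least squares. A family
observed through fewer than three lines spans at most one gap, which
matches any code window under the free scale, so such assignments are
rejected as insufficient.

## Plane estimation

1. **In-plane least squares** (`fit_inplane`). Each pick (u, v) on the
   line of bleach plane k gives one linear equation
   `n_k · (L₂·(u,v) + t₂) = d_k` in the six in-plane unknowns (x, y
   rows of the map). Two non-parallel families are required for full
   rank.
2. **Depth resolution** (`resolve_depth`). Every sample of the tissue
   top contour traced in the section must map onto the OCT-detected
   surface: `m31·u + m32·v + t_z = h(x(u,v), y(u,v))`. With a wavy
   surface these equations determine the z row and t_z by least
   squares; for a flat surface (collinear samples) the z row falls back
   to zero out-of-plane tilt with the out-of-plane scale taken from the
   scale assumption (default s_z := s_y), and only t_z is fitted.
3. **Constrained joint polish** (default in `estimate_section`). The
   sequential solve leaves two weaknesses: the contour's narrow v-range
   lets m32 trade against t_z (harmless for the cross-plane metric,
   harmful for 3D prediction), and the in-plane block of a
   near-vertical section determines only four combinations of
   (α, tilts, s_x, s_y), leaving a one-parameter yaw-versus-scales
   gauge. A nine-parameter least squares over all pick and contour
   residuals, with the scale·rotation structure built into the
   parametrization and two soft isotropy priors (s_x ≈ s_y and
   s_z ≈ s_y, width 0.15, scaled into pick-σ units — formalin shrinkage
   is close to isotropic), closes both gaps. Scale bounds [0.3, 2.0]
   guard against wrong basins; a fit pinned at a bound is rejected and
   flagged.
4. **Stack fitting** (`joint_stack_fit`). Consecutive sections from one
   block share orientation and scales and differ only by translation
   along the common normal. The default mode is one joint least squares
   over every section's picks and contour with shared
   (angles, scales, base translation) plus one normal offset per
   additional section; `average=True` gives plain per-section parameter
   averaging for comparison. The joint fit reports the effective
   per-section spacing, which recovers nominal spacing × s_y (the
   normal offsets live in volume μm).
5. **Fine alignment** (`fine_align`). Automates the interactive
   refinement step over exactly the four degrees of freedom a human
   adjusts: three translations and the in-plane rotation (orientation
   and scales frozen). The objective is masked normalized
   cross-correlation between the resliced OCT candidate and a reference
   section image, computed on images Gaussian-smoothed by 2 px — raw
   OCT speckle decorrelates over roughly a PSF width, which makes
   unsmoothed NCC a noise-buried spike unless the orientation is
   exact — minus an anisotropic quadratic prior on the adjustment
   (σ = 5 μm along the plane normal, 20 μm in plane, weight 0.02).
   The prior encodes that the fiducial fit localizes the plane much
   more accurately across itself than along itself, while layered skin
   is nearly translation-invariant along the plane, so an out-of-plane
   move must earn a correspondingly larger correlation gain. Search is
   a plane-adapted coarse scan (normal profile, in-plane 2D grid,
   rotation scan) followed by Nelder–Mead; the result never scores
   below the initial map, and a featureless reference returns the
   initial map with a flag.

## Volume operations

- **Reslicing** is trilinear (`scipy.ndimage.map_coordinates`, order 1):
  exact on multilinear intensity fields, bit-identical to raster slices
  on axis-aligned planes, and verified against a hand-written per-pixel
  oracle. Out-of-volume samples get a fill value and mask = False.
- **Focus stacking** fuses z-translated scans with Gaussian depth
  weights `exp(−(z − focal_k)²/2σ_f²)`, σ_f defaulting to the focal
  step, after per-volume median-intensity equalization over the jointly
  covered range. Constant fields are conserved exactly and the result
  is independent of volume order.
- **Surface detection** thresholds smoothed A-lines at background +
  min_jump (background = median of the shallowest 10% of samples),
  then 3×3 median filters the height map; columns without a crossing
  are NaN.
- **SNR masking** estimates the noise floor from the deepest 10% of
  image rows, requires local mean ≥ floor + k·SD (k = 3) *and* nonzero
  signal, cuts everything deeper than 450 μm below the surface trace
  (the practical OCT depth limit in skin), and removes speckle-sized
  islands by a radius-3 morphological opening. Raising k never unmasks
  a pixel.

## Pair building

H&E stain normalization deconvolves the image into
hematoxylin/eosin/DAB optical densities (Ruifrok–Johnston matrix via
scikit-image), matches each channel's tissue percentile (99th) to a
reference, and applies the *change* to the original image as a
multiplicative optical-density correction — so normalizing an image to
its own statistics is exactly the identity and background white is
untouched. Crops are exactly 1024 × 512 px at 1 μm/px with a shared
validity mask (image masks ∩ SNR mask); masked pixels carry the fill in
*both* modalities (0 for OCT, white for H&E) so a downstream model
cannot learn to invent tissue where there is no signal. The 256 × 256
model-input resize is anisotropic block-mean pooling (4× along u, 2×
along v); the mask pools with all-valid semantics. Manifests are CSV
and round-trip losslessly.

## The phantom

The synthetic phantom provides ground truth for every stage: a
transparent fluorescent gel above a wavy tissue surface, a darker
nuclei-rich epidermis band over a bright dermis with fully developed
(multiplicative exponential) speckle, Beer–Lambert depth attenuation
(default 0.004 μm⁻¹), Gaussian PSF blur (3.7 μm lateral / 2.0 μm
axial), and a small additive noise floor. Lateral structure — what a
human (or NCC) aligner locks onto — comes from rete-ridge-scale
undulation of the epidermis–dermis junction (22 μm amplitude, 140 μm
period), fine surface detail, a smooth dermal reflectivity texture,
follicle-like dark tubes, and bright gelatin chunks in the gel. 25 μm
fluorescent beads (30 by default) are suspended in the gel for
colocation validation. All fields are analytic functions of a seeded
random state, so labels, surface, and section truth are available at
any resolution without rasterizing a full-size volume, and every output
is bit-reproducible given the seed.

Simulated sectioning translates the true plane by
(nominal spacing × s_y) along its normal per section, renders
fluorescence and stylized H&E images on demand, samples picks on the
true barcode traces with isotropic Gaussian jitter (default σ = 10 μm,
2 picks/line), and jitters the top contour's v samples by σ = 3 μm —
the gel/tissue boundary is a sharp edge localized far better than the
center of a 25 μm-wide bleached line. (Reusing the pick σ on the
contour would also introduce a textbook errors-in-variables attenuation
of the depth-scale estimate.)

**Bead colocation.** A bead appears in the section at the least-squares
projection of its center through the true map; mapping those (u, v)
through the estimated map and measuring the 3D distance to the true
center gives the colocation error. Note the metric has an irreducible
floor even for a perfect map: the bead's own out-of-plane offset within
the section slab, up to radius + half thickness (≈ 15 μm for 25 μm
beads in a 5 μm section).

## Monte-Carlo study conditions

The acceptance experiments (`microreg.experiments`,
`scripts/acceptance.py`) draw, per replicate: yaw uniform in [40°, 55°]
(the cutting procedure aims the blade diagonally across the barcode —
at yaw near 0° one plane family would be geometrically invisible from a
vertical section), out-of-plane tilts uniform in ±5°, scales uniform in
[0.8, 1.0], base translation (−50, −50, 0) μm, section extent
3000 × 500 μm (the slide image is wider than the 1 mm OCT volume; all
eight lines stay visible across this yaw/scale range), pick noise
σ = 10 μm with 2 picks per line. Cross-plane error is evaluated on a
1000 × 500 μm grid at 25 μm steps. Replicates whose barcode decoding
fails are dropped from the statistics, mirroring curated real-data
evaluations; at these conditions the failure rate is ≈ 0/200.

Working resolutions: the barcode-only experiment needs no volume at all
(picks and a 2 μm-sampled surface height map suffice). The
fine-alignment and bead experiments rasterize the OCT volume at 4 μm
voxels in a region around a 600 × 400 μm alignment window and correlate
at 4 μm sampling — comfortably finer than the tens-of-μm accuracies
being measured. 200 replicates per experiment.

## What passing does and does not show

The phantom validates the *geometry pipeline*: correspondence decoding,
least-squares identifiability, depth resolution, the error metrics, and
the alignment machinery, under realistic click noise and anisotropic
shrinkage. It does not model non-affine tissue deformation, refraction,
multiple scattering, sectioning artifacts (folds, tears), imperfect
bleaching contrast, or histology-stain variability beyond a stylized
rendering — so phantom accuracies are best-case bounds, expected to be
tighter than real-tissue performance, and are compared against
real-workflow accuracy figures only as upper bounds.

## Known limitations

- The plane model is affine; real sections warp.
- Interleaved decoding is exponential in the number of observed lines
  (fine for ≤ ~12 lines; patterns are small by design).
- `fine_align`'s prior intentionally limits out-of-plane excursions to
  what the correlation evidence can support; with a feature-poor
  reference the refinement will (correctly) do almost nothing.
- The s_z ≈ s_y ≈ s_x priors assume near-isotropic shrinkage; strongly
  anisotropic processing would need the configurable scale assumption
  and wider priors.
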