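# Methods

## Problem setting

A hand sample of winter wheat — all plants from a 0.5 m² field patch — is
strapped into a bundle and cut flat; a photograph of each cut surface
(sides `top` and `bottom`, so two images per bundle) shows every tiller as
a bright annulus (the stem wall) around a dark lumen, on a dark
background. Bundles hold roughly 100–460 tillers, most around 250. The
package estimates the per-image tiller count semi-automatically: an
automatic circle detector proposes marks, a human (or a scripted policy)
corrects them, and the corrected counts are evaluated against ground
truth.

## Detection

The detector is a gradient-vote Hough circle transform:

1. RGB input is reduced to luma (weights 0.299/0.587/0.114).
2. Noise is suppressed with a 5×5 **median** filter (edge replication).
   The kernel size is the one design constant of the preprocessing; a
   Gaussian blur of matching footprint is available behind
   `denoise(..., method="gaussian")` for users who prefer linear
   smoothing.
3. 3×3 Sobel operators give per-pixel gradients; pixels with magnitude
   ≥ `p1` are edge pixels. `p1` thresholds the raw Sobel magnitude — there
   is no hysteresis edge tracking — so its scale is specific to this
   implementation (hard wall/background edges reach magnitudes near 1000
   on 8-bit images; the default is 95).
4. Each edge pixel votes along its gradient line, in **both**
   orientations (annulus walls produce inward- and outward-facing edges),
   at every integer distance in `[r_min, r_max]`, into an accumulator at
   resolution `1/dp` (default full resolution). Votes land on the nearest
   accumulator cell.
5. Candidate centers are 8-neighborhood local maxima with ≥ `p2` votes,
   processed in descending vote order (ties by ascending (y, x)) with
   greedy non-maximum suppression at separation `d_min`.
6. For each accepted center the radius is the integer r in
   `[r_min, r_max]` whose perimeter band (|distance − r| ≤ 2 px) contains
   the most edge pixels; ties go to the smaller radius. The detection
   score is that band support divided by the perimeter length 2πr, making
   scores comparable across radii.

**Center refinement.** Integer-distance voting with nearest-cell rounding
produces aliasing in the accumulator: for a clean ring, symmetric side
lobes a few pixels from the true center can out-vote the center cell
itself, displacing the raw peak by up to ~3 px. Each accepted peak is
therefore refined with an algebraic least-squares circle fit (Kåsa fit) on
the edge pixels in a widened band (±5 px) around the current radius
estimate, iterated three times with the radius re-fitted in between. The
wide band still excludes neighboring annuli as long as wall-to-wall gaps
exceed ~10 px. A fit that moves the center implausibly far (more than the
band width) is rejected as degenerate. After refinement the `d_min`
separation is re-imposed in score order, so the returned set always
satisfies the separation contract. On synthetic bundles this brings the
median center error from ~2 px to ~0.03 px.

Default parameters (`p1=95, p2=30, d_min=50, r_min=20, r_max=54`) are the
reference set used for full-size bundles throughout the package. Because
`p1`/`p2` semantics are implementation-specific, these values do not
transfer one-to-one to other Hough implementations, and vice versa.

Coordinates are 0-based pixels, x rightward, y downward, with circle
centers at pixel centers; sub-pixel centers are returned.

## Corrections and the adjusted count

Corrections are ordered `add`/`remove` events, replayed deterministically:

- `add` appends a manual mark at the click position; its drawn radius is
  the midpoint of `[r_min, r_max]` (manual marks carry no fitted radius).
- `remove` deletes the nearest mark within `association_radius`, ties
  broken by distance then lowest mark index. The default association
  radius is `d_min / 2`: since accepted centers are at least `d_min`
  apart, a click within half that distance binds unambiguously. Removes
  may also delete manual marks (undoing a misplaced add). A remove that
  binds nothing is kept in the log as a flagged no-op and does **not**
  count into `n_removed`.

The per-image record satisfies the identity
`n_adjusted = n_hough + n_added − n_removed` by construction, with
`n_removed` counting only effective removals. Event order matters only
when removes compete for the same mark; the nearest-then-lowest-index rule
makes the outcome deterministic in every order.

## Metrics

Pearson R uses population (1/N) covariance and variances; the
normalization cancels, so sample-convention inputs give the identical
value. Relative errors require strictly positive ground truth.
Detection/truth matching is greedy one-to-one by ascending center
distance with a 5 px default threshold — well under `r_min`, so a match
cannot jump to a neighboring tiller; greedy matching equals optimal
assignment for well-separated circles and is deterministic. RMSE values
(tillers per bundle) convert to tillers/m² by dividing by the 0.5 m²
patch area.

## Synthetic bundles

The generator emulates the photographic conditions: background intensity
~10, lumen ~30, wall ~200 on a 0–255 scale (hard edges, matching the high
contrast of raking illumination on a clean cut), additive Gaussian sensor
noise (default sd 5), optional multiplicative left-to-right illumination
tilt, and leaf-like occluders — cubic Bézier ribbons of wall intensity,
3–12 px wide, stamped until a target area fraction is covered. Truth
circles whose wall is ≥ 50 % covered are flagged as occluded. A truth
radius is the wall **centerline** radius; the rendered wall spans
r ± wall_thickness/2 (default thickness 4 px), so the detector's
band-support radius fit is centered on the truth value.

Packing is random sequential adsorption: candidate circles (uniform
center in the elliptical bundle mask, radius uniform on `radius_range`,
optionally bimodal to mimic bundles mixing small and large tillers) are
accepted if the outer wall stays inside the mask and at least `min_gap`
from every accepted wall; the process stops after 10,000 rejected
candidates, reporting the achieved count with a warning when it falls
short. One seeded `numpy` generator per call makes images bit-identical
for a fixed spec.

Defaults describe the study conditions: 250 target tillers, radii uniform
on [20, 54] px, mask semi-axes 1050×950 px (sized so ~250 tillers pack
before saturation), `min_gap` 12 px. The gap default is a geometric
consequence of the reference detector parameters: two touching r=20
tillers must keep their centers ≥ `d_min` = 50 px apart to both survive
non-maximum suppression, which requires a wall gap of at least
50 − (2·20 + 4) = 6 px; 12 px leaves margin for the packing jitter. Real
close-packed bundles violate this locally — that is one of the method's
documented failure modes, not something the generator hides.

**What passing tests show, and what they do not.** The synthetic images
share the real images' geometry (annulus density, radii, gaps, occluders)
but not their texture: no straw fibers, frayed edges, strapping cables,
shadows, or perspective. Detector recovery ≥ 95 % on synthetic bundles
therefore validates the algorithmic contract (voting, suppression, radius
fitting, correction arithmetic, metrics), not field accuracy; on real
photographs the automatic count is substantially less accurate
(relative errors up to ~30 %) and the manual-correction step carries the
workflow, which is why validation on photographs remains a manual recipe
(`docs/external_validation.md`).

## Problem sizes used in the automated tests

The validation suite runs 20 full-size bundles (~250 tillers each, seeds
1–20, noise sd 5, no occluders) for detector recovery and
perfect-correction closure, and 6 smaller bundles (~40 tillers, 5 %
occluder cover) for the occluded end-to-end check; unit tests use ~40-
tiller bundles. These sizes keep the whole suite in a few minutes while
exercising the same geometry as full bundles.

## Known limitations

- The detector assumes near-circular cross-sections; strongly elliptical
  or folded tillers are missed (by design — ellipse fitting is out of
  scope).
- Wide radius ranges admit false circles in inter-tiller gaps, and large
  `d_min` suppresses small adjacent tillers; the parameter trade-off is
  inherent to the method and is the reason the workflow is
  semi-automatic.
- `dp > 1` coarsens center votes without rescaling `p2`; it is provided
  for completeness but the defaults assume `dp = 1`.
- Physical pixel scale is unknown (no px-per-mm calibration), so all
  geometry is in pixels and only counts convert to per-m² densities.
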