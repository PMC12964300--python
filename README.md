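# tillercount

Semi-automatic counting of wheat tillers in bundle cross-section images.

In field phenotyping, hand samples of winter wheat are strapped into
bundles, cut flat, and photographed from both cut surfaces; each tiller
(stem) shows up as a bright-walled circular annulus on a dark background.
The tiller count per bundle — and, through the sampled patch area, the
tiller density per m² — is a key yield parameter, but counting hundreds of
annuli by hand is slow and unreproducible. This package implements that
counting workflow end to end:

- **`tillercount.detect`** — a gradient-vote Hough circle detector built
  directly on numpy/scipy: grayscale conversion, 5×5 median denoising, 3×3
  Sobel gradients, center voting along gradient directions, non-maximum
  suppression, and an algebraic circle-fit refinement. Exactly five tunable
  parameters: edge threshold `p1`, vote threshold `p2`, minimum center
  distance `d_min`, and radius bounds `r_min`, `r_max`.
- **`tillercount.session`** — manual corrections as replayable JSON event
  logs (`add` / `remove` clicks) with the count arithmetic
  `n_adjusted = n_hough + n_added − n_removed`.
- **`tillercount.metrics`** — agreement metrics between estimated and true
  counts: Pearson *R*, MSE/RMSE, signed relative errors, RMSRE (%), density
  conversion, and one-to-one detection/truth matching
  (precision/recall at a center-distance threshold).
- **`tillercount.synthetic`** — a bundle-image generator with exact ground
  truth: packed annuli with configurable radii, gaps, noise, illumination
  tilt, and leaf-like occluders, so the whole pipeline is testable without
  any photograph.
- **`tillercount.pipeline` / CLI** — `tillercount simulate|detect|correct|
  evaluate|run` with TOML configs and deterministic, provenance-stamped
  outputs.

## The core statistic

For images *i = 0 … N−1* with ground-truth counts *yᵢ* and estimates *ŷᵢ*:

```
R     = Cov(y, ŷ) / √(Var(y) · Var(ŷ))
MSE   = (1/N) Σ (ŷᵢ − yᵢ)²,   RMSE = √MSE
relᵢ  = (ŷᵢ − yᵢ) / yᵢ × 100 %
RMSRE = √( (1/N) Σ relᵢ² )
```

A per-bundle count or RMSE divides by the patch area (0.5 m² per bundle)
to give tillers/m².

## Worked example

```python
from tillercount import (BundleSpec, HoughParams, generate_bundle, denoise,
                         hough_circles, match_detections, perfect_corrections,
                         replay, CorrectionSession)

spec = BundleSpec(n_tillers=250, occluder_density=0.05, seed=1)
img, truth = generate_bundle(spec)
dets = hough_circles(denoise(img), HoughParams())
m = match_detections(dets, truth, max_center_dist=5.0)
print("truth", truth.count, "n_hough", len(dets))
print(f"precision={m.precision:.3f} recall={m.recall:.3f}")
events = perfect_corrections(dets, truth)
_, rec = replay(CorrectionSession("b001_top", dets, events))
print(f"n_adjusted = {rec.n_hough} + {rec.n_added} - {rec.n_removed} = {rec.n_adjusted}")
```

prints

```
truth 250 n_hough 300
precision=0.817 recall=0.980
n_adjusted = 300 + 5 - 55 = 250
```

The bundle has 250 tillers; leaf-like occluders make the automatic
detector report 300 circles (55 spurious circles in gaps and on ribbons, 5
missed tillers). Scripted corrections — one `remove` per false positive,
one `add` per false negative — restore the exact count through the
adjusted-count arithmetic. On occluder-free bundles the detector alone
recovers ≥ 99 % of tillers with ≥ 99 % precision (see
`tests/test_acceptance.py`).

The same flow from the shell:

```sh
tillercount simulate --out work/ --seed 1 --n-tillers 250 --n-bundles 1
tillercount detect work/b001_top.png --p1 95 --p2 30 --dmin 50 --rmin 20 --rmax 54 \
    --out work/b001_top.detections.csv
tillercount correct work/b001_top.detections.csv session.json --out counts.csv
tillercount evaluate counts.csv hand_counts.csv --patch-area 0.5 --out report.json
```

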