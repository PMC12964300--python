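"""Synthetic bundle cross-section images with exact ground truth.

A bundle image shows densely packed bright annuli (tiller walls) on a dark
background, inside an elliptical bundle outline.  The generator emulates the
salient features of real cut-bundle photographs — high wall/lumen contrast,
variable packing with holes, heterogeneous radii, additive sensor noise, an
optional illumination gradient, and leaf-like occluding ribbons — while
keeping exact per-circle ground truth, so detection, correction, and
evaluation are testable end to end without any external data.

Coordinates are 0-based pixels, x rightward, y downward.  A truth circle's
radius ``r`` is the radius of the wall *centerline*: the rendered wall
occupies the band ``r +/- wall_thickness / 2``.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidSpecError

#: Rendered intensity levels (0-255 scale, before noise): annulus wall,
#: lumen (the hollow inside of a tiller), and background.
WALL_INTENSITY = 200.0
LUMEN_INTENSITY = 30.0
BACKGROUND_INTENSITY = 10.0

#: Random sequential packing gives up after this many failed placements.
MAX_PACKING_FAILURES = 10_000

#: Blank border (px) between the mask ellipse and the image edge.
PAD = 8


@dataclass(frozen=True)
class BundleSpec:
    """Parameters of one synthetic bundle image.

    Defaults describe a typical bundle: ~250 tillers (the modal bundle size
    in the field data this emulates), wall-centerline radii uniform on
    [20, 54] px, and a wall gap of at least ``min_gap`` px between neighbors.

    Parameters
    ----------
    n_tillers
        Target circle count; the achieved count may be lower if packing
        saturates (see :func:`generate_bundle`).
    radius_range
        (r_lo, r_hi) bounds of the uniform radius distribution, px.
    wall_thickness
        Annulus ring width, px.
    mask_shape
        Ellipse semi-axes (a along x, b along y), px; the packing region.
    min_gap
        Minimum gap between the outer wall edges of two tillers, px.
    occluder_density
        Fraction of image area to cover with leaf-like ribbons, in [0, 1].
    noise_sd
        Additive Gaussian intensity noise, 0-255 scale.
    illumination_tilt
        Fractional left-to-right intensity gradient in [0, 0.5]; the left
        edge is scaled by (1 - tilt), the right edge by 1.
    bimodal_split
        Optional (weight, lo_frac) pair for a bimodal radius mixture: with
        probability ``weight`` a radius is drawn from the lower
        ``lo_frac`` part of ``radius_range``, otherwise from the upper
        remainder — mimics bundles mixing small and large tillers.
    seed
        RNG seed; identical specs produce bit-identical images.
    """

    n_tillers: int = 250
    radius_range: tuple[float, float] = (20.0, 54.0)
    wall_thickness: float = 4.0
    mask_shape: tuple[float, float] = (1050.0, 950.0)
    min_gap: float = 12.0
    occluder_density: float = 0.0
    noise_sd: float = 5.0
    illumination_tilt: float = 0.0
    bimodal_split: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        r_lo, r_hi = self.radius_range
        a, b = self.mask_shape
        if self.n_tillers < 0:
            raise InvalidSpecError(f"n_tillers must be >= 0, got {self.n_tillers}")
        if not (0 < r_lo <= r_hi):
            raise InvalidSpecError(f"need 0 < r_lo <= r_hi, got {self.radius_range}")
        if self.wall_thickness < 1:
            raise InvalidSpecError(f"wall_thickness must be >= 1, got {self.wall_thickness}")
        if self.min_gap < 0:
            raise InvalidSpecError(f"min_gap must be >= 0, got {self.min_gap}")
        if not (0 <= self.occluder_density <= 1):
            raise InvalidSpecError(f"occluder_density must be in [0,1], got {self.occluder_density}")
        if not (0 <= self.illumination_tilt <= 0.5):
            raise InvalidSpecError(
                f"illumination_tilt must be in [0,0.5], got {self.illumination_tilt}"
            )
        if r_hi + self.wall_thickness / 2 >= min(a, b):
            raise InvalidSpecError(
                f"largest annulus (r={r_hi}) does not fit inside mask semi-axes {self.mask_shape}"
            )


@dataclass
class BundleTruth:
    """Ground truth for one synthetic bundle image.

    ``circles`` holds (cx, cy, r) wall-centerline triples; ``count`` is the
    bundle's true tiller count (the y_i of evaluation); ``occluded_ids``
    indexes circles whose wall is at least half covered by an occluder.
    """

    circles: list[tuple[float, float, float]]
    count: int
    occluded_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.count != len(self.circles):
            raise InvalidSpecError(
                f"count {self.count} != number of circles {len(self.circles)}"
            )


def _sample_radius(rng: np.random.Generator, spec: BundleSpec) -> float:
    r_lo, r_hi = spec.radius_range
    if spec.bimodal_split is None:
        return float(rng.uniform(r_lo, r_hi))
    weight, lo_frac = spec.bimodal_split
    split = r_lo + lo_frac * (r_hi - r_lo)
    if rng.uniform() < weight:
        return float(rng.uniform(r_lo, split))
    return float(rng.uniform(split, r_hi))


def _pack_circles(
    rng: np.random.Generator, spec: BundleSpec, cx0: float, cy0: float
) -> list[tuple[float, float, float]]:
    """Random sequential adsorption inside the mask ellipse.

    Each candidate (uniform center in the ellipse bounding box, radius from
    the spec distribution) is accepted iff its outer wall stays inside the
    ellipse and at least ``min_gap`` from every accepted wall; packing stops
    after MAX_PACKING_FAILURES rejected candidates.
    """
    a, b = spec.mask_shape
    w2 = spec.wall_thickness / 2.0
    placed_x = np.empty(spec.n_tillers)
    placed_y = np.empty(spec.n_tillers)
    placed_r = np.empty(spec.n_tillers)
    n = 0
    failures = 0
    while n < spec.n_tillers and failures < MAX_PACKING_FAILURES:
        r = _sample_radius(rng, spec)
        x = rng.uniform(cx0 - a, cx0 + a)
        y = rng.uniform(cy0 - b, cy0 + b)
        rout = r + w2
        # outer wall inside the ellipse (conservative: shrink semi-axes by rout)
        if ((x - cx0) / (a - rout)) ** 2 + ((y - cy0) / (b - rout)) ** 2 > 1.0:
            failures += 1
            continue
        if n:
            d = np.hypot(placed_x[:n] - x, placed_y[:n] - y)
            if (d < placed_r[:n] + r + spec.wall_thickness + spec.min_gap).any():
                failures += 1
                continue
        placed_x[n], placed_y[n], placed_r[n] = x, y, r
        n += 1
    return [(float(placed_x[i]), float(placed_y[i]), float(placed_r[i])) for i in range(n)]


def _render_annulus(img: np.ndarray, cx: float, cy: float, r: float, w2: float) -> None:
    h, wd = img.shape
    reach = int(math.ceil(r + w2)) + 1
    x0, x1 = max(0, int(cx) - reach), min(wd, int(cx) + reach + 1)
    y0, y1 = max(0, int(cy) - reach), min(h, int(cy) + reach + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dist = np.hypot(xx - cx, yy - cy)
    img[y0:y1, x0:x1][dist < r - w2] = LUMEN_INTENSITY
    img[y0:y1, x0:x1][np.abs(dist - r) <= w2] = WALL_INTENSITY


def _draw_ribbon(mask: np.ndarray, rng: np.random.Generator, cx0: float, cy0: float,
                 a: float, b: float) -> None:
    """Stamp one leaf-like ribbon (a cubic Bezier arc of random width) on mask."""
    pts = np.column_stack(
        [rng.uniform(cx0 - a, cx0 + a, size=4), rng.uniform(cy0 - b, cy0 + b, size=4)]
    )
    width = float(rng.uniform(3.0, 12.0))
    # arc length upper bound -> ~1 px sampling step
    n_samples = max(8, int(np.sum(np.hypot(*np.diff(pts, axis=0).T)) * 2))
    t = np.linspace(0.0, 1.0, n_samples)[:, None]
    curve = (
        (1 - t) ** 3 * pts[0]
        + 3 * (1 - t) ** 2 * t * pts[1]
        + 3 * (1 - t) * t**2 * pts[2]
        + t**3 * pts[3]
    )
    h, w = mask.shape
    half = width / 2.0
    rad = int(math.ceil(half))
    dy, dx = np.mgrid[-rad : rad + 1, -rad : rad + 1]
    disk = np.hypot(dx, dy) <= half
    for px, py in curve:
        ix, iy = int(round(px)), int(round(py))
        if -rad <= ix < w + rad and -rad <= iy < h + rad:
            ys = slice(max(0, iy - rad), min(h, iy + rad + 1))
            xs = slice(max(0, ix - rad), min(w, ix + rad + 1))
            mask[ys, xs] |= disk[
                ys.start - (iy - rad) : disk.shape[0] - ((iy + rad + 1) - ys.stop),
                xs.start - (ix - rad) : disk.shape[1] - ((ix + rad + 1) - xs.stop),
            ]


def _wall_coverage(
    edge_img_shape: tuple[int, int],
    circle: tuple[float, float, float],
    w2: float,
    occluder: np.ndarray,
) -> float:
    cx, cy, r = circle
    h, wd = edge_img_shape
    reach = int(math.ceil(r + w2)) + 1
    x0, x1 = max(0, int(cx) - reach), min(wd, int(cx) + reach + 1)
    y0, y1 = max(0, int(cy) - reach), min(h, int(cy) + reach + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    wall = np.abs(np.hypot(xx - cx, yy - cy) - r) <= w2
    n_wall = int(wall.sum())
    if n_wall == 0:
        return 0.0
    return float((wall & occluder[y0:y1, x0:x1]).sum()) / n_wall


def generate_bundle(spec: BundleSpec) -> tuple[np.ndarray, BundleTruth]:
    """Render one synthetic bundle image and its exact ground truth.

    Returns an 8-bit grayscale image and a :class:`BundleTruth` whose circles
    correspond one-to-one with the rendered annuli.  Deterministic for a
    fixed spec (including seed).  If fewer than ``n_tillers`` circles can be
    packed, the achieved count is returned and a warning is issued.
    """
    rng = np.random.default_rng(spec.seed)
    a, b = spec.mask_shape
    w = 2 * int(math.ceil(a + PAD))
    h = 2 * int(math.ceil(b + PAD))
    cx0, cy0 = w / 2.0, h / 2.0

    circles = _pack_circles(rng, spec, cx0, cy0)
    if len(circles) < spec.n_tillers:
        warnings.warn(
            f"packed only {len(circles)} of {spec.n_tillers} requested tillers "
            f"after {MAX_PACKING_FAILURES} failed placements",
            stacklevel=2,
        )

    img = np.full((h, w), BACKGROUND_INTENSITY, dtype=np.float64)
    w2 = spec.wall_thickness / 2.0
    for cx, cy, r in circles:
        _render_annulus(img, cx, cy, r, w2)

    occluded_ids: list[int] = []
    if spec.occluder_density > 0:
        occluder = np.zeros((h, w), dtype=bool)
        target = spec.occluder_density * img.size
        while occluder.sum() < target:
            _draw_ribbon(occluder, rng, cx0, cy0, a, b)
        img[occluder] = WALL_INTENSITY
        occluded_ids = [
            i
            for i, c in enumerate(circles)
            if _wall_coverage((h, w), c, w2, occluder) >= 0.5
        ]

    if spec.illumination_tilt > 0:
        ramp = (1.0 - spec.illumination_tilt) + spec.illumination_tilt * (
            np.arange(w) / (w - 1)
        )
        img *= ramp[None, :]

    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)

    img8 = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    truth = BundleTruth(circles=circles, count=len(circles), occluded_ids=occluded_ids)
    return img8, truth


def write_truth(truth: BundleTruth, path: str | Path, spec: BundleSpec | None = None,
                seed: int | None = None) -> None:
    """Write truth circles to CSV ``cx,cy,r`` with a JSON count sidecar.

    The sidecar (``<path stem>.json``) carries the count, the occluded circle
    ids, and optionally the generating spec and seed; :func:`read_truth`
    round-trips the truth exactly.
    """
    path = Path(path)
    # shortest-repr floats so the CSV round-trips bit-exactly
    lines = ["cx,cy,r"] + [f"{cx!r},{cy!r},{r!r}" for cx, cy, r in truth.circles]
    path.write_text("\n".join(lines) + "\n")
    sidecar: dict = {"count": truth.count, "occluded_ids": truth.occluded_ids}
    if seed is not None:
        sidecar["seed"] = seed
    elif spec is not None:
        sidecar["seed"] = spec.seed
    if spec is not None:
        sidecar["spec"] = asdict(spec)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_truth(path: str | Path) -> BundleTruth:
    """Read a truth annotation written by :func:`write_truth`."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    circles = [(float(r.cx), float(r.cy), float(r.r)) for r in df.itertuples(index=False)]
    occluded: list[int] = []
    sidecar = path.with_suffix(".json")
    count = len(circles)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        count = int(meta.get("count", count))
        occluded = [int(i) for i in meta.get("occluded_ids", [])]
    return BundleTruth(circles=circles, count=count, occluded_ids=occluded)
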