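"""Circle detection for tiller cross-sections.

The detector is a gradient-vote Hough circle transform written directly on
numpy: edge pixels (Sobel magnitude above a threshold ``p1``) cast votes for
candidate centers along their gradient direction at every radius in
``[r_min, r_max]``; accumulator local maxima with at least ``p2`` votes become
centers after greedy non-maximum suppression at separation ``d_min``; the
radius of each accepted center is the one with maximal edge support on the
circle perimeter.

Five tunable parameters (``p1``, ``p2``, ``d_min``, ``r_min``, ``r_max``)
control the detector; their defaults are the reference set used throughout
the package (r_min=20, r_max=54, p1=95, p2=30, d_min=50).  ``p1`` acts
directly on the Sobel gradient magnitude (no hysteresis edge tracking), so
values are not interchangeable with other Hough implementations.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import FormatError, ParameterError

#: Rec. 601 luma weights used for RGB -> grayscale conversion.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

#: Half-width (px) of the distance band counted as perimeter support when
#: fitting the radius of an accepted center.  A band of +/-2 px covers both
#: wall edges of a thin annulus, centering the fit on the wall midline.
RADIUS_BAND = 2

#: Wider half-width used when selecting pixels for the center fit, so a
#: ring is still fully captured from an accumulator peak displaced by a few
#: px; must stay below half the typical wall-to-wall gap to exclude
#: neighboring annuli.
FIT_BAND = 5


@dataclass(frozen=True)
class HoughParams:
    """Tunable parameters of the gradient Hough circle detector.

    Parameters
    ----------
    p1
        Edge threshold on the Sobel gradient magnitude (intensity units on a
        0-255 image; magnitudes reach ~1000 on hard edges).
    p2
        Minimum accumulator votes for a candidate center.
    d_min
        Minimum distance in px between two accepted centers.
    r_min, r_max
        Radius search bounds in px.
    dp
        Accumulator downscale factor (>= 1); 1 means full image resolution.
    """

    p1: float = 95.0
    p2: float = 30.0
    d_min: float = 50.0
    r_min: float = 20.0
    r_max: float = 54.0
    dp: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.r_min <= self.r_max):
            raise ParameterError(
                f"need 0 < r_min <= r_max, got r_min={self.r_min}, r_max={self.r_max}"
            )
        if self.d_min <= 0:
            raise ParameterError(f"d_min must be positive, got {self.d_min}")
        if self.p1 <= 0 or self.p2 <= 0:
            raise ParameterError(f"p1 and p2 must be positive, got p1={self.p1}, p2={self.p2}")
        if self.dp < 1:
            raise ParameterError(f"dp must be >= 1, got {self.dp}")


@dataclass(frozen=True)
class CircleDetection:
    """One detected circle: center (x right, y down, 0-based px), radius, score.

    ``score`` is the perimeter edge support of the fitted radius normalized by
    the perimeter length ``2*pi*r``, so scores are comparable across radii.
    """

    cx: float
    cy: float
    r: float
    score: float


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Convert a 1- or 3-channel raster to a float64 grayscale image.

    3-channel input is combined with Rec. 601 luma weights
    (0.299, 0.587, 0.114); single-channel input passes through unchanged
    (apart from dtype promotion).
    """
    arr = np.asarray(image)
    if arr.ndim == 2:
        return arr.astype(np.float64)
    if arr.ndim == 3 and arr.shape[2] == 1:
        return arr[:, :, 0].astype(np.float64)
    if arr.ndim == 3 and arr.shape[2] == 3:
        w = np.asarray(LUMA_WEIGHTS)
        return arr.astype(np.float64) @ w
    raise FormatError(f"expected 1 or 3 channels, got array of shape {arr.shape}")


def denoise(img: np.ndarray, kernel: int = 5, method: str = "median") -> np.ndarray:
    """Reduce noise with a ``kernel`` x ``kernel`` median filter (default 5x5).

    Borders are handled by edge replication.  ``method="gaussian"`` substitutes
    a Gaussian blur of matching footprint (sigma = (kernel - 1) / 4).
    """
    if kernel < 1 or kernel % 2 == 0:
        raise ParameterError(f"kernel must be odd and >= 1, got {kernel}")
    arr = np.asarray(img, dtype=np.float64)
    if method == "median":
        return ndimage.median_filter(arr, size=kernel, mode="nearest")
    if method == "gaussian":
        return ndimage.gaussian_filter(arr, sigma=(kernel - 1) / 4.0, mode="nearest")
    raise ParameterError(f"unknown denoise method {method!r}")


def gradient_field(img: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pixel 3x3 Sobel gradients ``(gx, gy, magnitude)``.

    gx responds to intensity increasing rightward, gy downward; borders use
    edge replication so interior values match the plain stencil.
    """
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 2 or min(arr.shape) < 3:
        raise ParameterError(f"need a 2D image of at least 3x3 px, got shape {arr.shape}")
    gx = ndimage.sobel(arr, axis=1, mode="nearest")
    gy = ndimage.sobel(arr, axis=0, mode="nearest")
    return gx, gy, np.hypot(gx, gy)


def _vote(
    xs: np.ndarray,
    ys: np.ndarray,
    ux: np.ndarray,
    uy: np.ndarray,
    radii: np.ndarray,
    acc_shape: tuple[int, int],
    dp: float,
) -> np.ndarray:
    """Accumulate center votes along +/- gradient directions at each radius."""
    acc = np.zeros(acc_shape[0] * acc_shape[1], dtype=np.int64)
    ah, aw = acc_shape
    for d in radii:
        for sign in (1.0, -1.0):
            cx = np.rint((xs + sign * d * ux) / dp).astype(np.int64)
            cy = np.rint((ys + sign * d * uy) / dp).astype(np.int64)
            ok = (cx >= 0) & (cx < aw) & (cy >= 0) & (cy < ah)
            if ok.any():
                acc += np.bincount(cy[ok] * aw + cx[ok], minlength=acc.size)
    return acc.reshape(acc_shape)


def _fit_circle(
    edge: np.ndarray, cx: float, cy: float, r_min: float, r_max: float
) -> tuple[float, float, float, float]:
    """Fit (cx, cy, r, score) from edge pixels around an accumulator peak.

    The radius is the integer r in [r_min, r_max] whose perimeter band
    (distance within RADIUS_BAND of r) holds the most edge pixels, ties going
    to the smallest r.  The center is then refined with an algebraic
    least-squares circle fit (Kasa fit) on the band pixels, which corrects
    accumulator peaks displaced by vote plateaus or neighboring walls; band
    selection and fit are iterated twice.  The score is the final band
    support over the perimeter length.
    """
    h, w = edge.shape
    reach = int(math.ceil(r_max)) + RADIUS_BAND + 2
    x0, x1 = max(0, int(cx) - reach), min(w, int(cx) + reach + 1)
    y0, y1 = max(0, int(cy) - reach), min(h, int(cy) + reach + 1)
    yy, xx = np.nonzero(edge[y0:y1, x0:x1])
    if yy.size == 0:
        return cx, cy, float(r_min), 0.0
    ex = (xx + x0).astype(np.float64)
    ey = (yy + y0).astype(np.float64)
    lo, hi = int(math.ceil(r_min)), int(math.floor(r_max))
    window = np.ones(2 * RADIUS_BAND + 1)

    def best_radius(fx: float, fy: float) -> tuple[float, float, np.ndarray]:
        dist = np.hypot(ex - fx, ey - fy)
        hist = np.bincount(np.rint(dist).astype(np.int64), minlength=reach + 2)
        support = np.convolve(hist, window, mode="same")
        best = int(np.argmax(support[lo : hi + 1]))
        return float(lo + best), float(support[lo + best]), dist

    fx, fy = cx, cy
    for _ in range(3):
        r_fit, support, dist = best_radius(fx, fy)
        band = np.abs(dist - r_fit) <= FIT_BAND
        if band.sum() < 3:
            break
        bx, by = ex[band], ey[band]
        # Kasa fit: minimize sum((x-a)^2 + (y-b)^2 - R^2)^2, linear in (a, b)
        A = np.column_stack([bx, by, np.ones(bx.size)])
        rhs = bx**2 + by**2
        sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
        nfx, nfy = sol[0] / 2.0, sol[1] / 2.0
        # reject degenerate fits (e.g. a near-collinear band fragment)
        if math.hypot(nfx - fx, nfy - fy) > 2 * RADIUS_BAND + 2:
            break
        fx, fy = float(nfx), float(nfy)
    r_fit, support, _ = best_radius(fx, fy)
    return fx, fy, r_fit, support / (2.0 * math.pi * r_fit)


def hough_circles(img: np.ndarray, params: HoughParams | None = None) -> list[CircleDetection]:
    """Detect circles in a (denoised) grayscale image.

    The result is deterministic for a fixed input: candidate centers are
    processed in descending vote order with ties broken by ascending (y, x),
    and the returned list is sorted by descending score (ties again by
    (y, x)).  Every pair of returned centers is at least ``d_min`` apart and
    every radius lies within ``[r_min, r_max]``.
    """
    params = params or HoughParams()
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 2:
        raise FormatError(f"expected a 2D grayscale image, got shape {arr.shape}")
    h, w = arr.shape
    if params.r_max >= min(h, w):
        raise ParameterError(
            f"r_max={params.r_max} does not fit in a {h}x{w} image"
        )

    gx, gy, mag = gradient_field(arr)
    edge = mag >= params.p1
    ys, xs = np.nonzero(edge)
    if ys.size == 0:
        return []
    m = mag[ys, xs]
    ux, uy = gx[ys, xs] / m, gy[ys, xs] / m

    dp = params.dp
    acc_shape = (int(math.ceil(h / dp)), int(math.ceil(w / dp)))
    radii = np.arange(math.ceil(params.r_min), math.floor(params.r_max) + 1, dtype=np.float64)
    acc = _vote(xs.astype(np.float64), ys.astype(np.float64), ux, uy, radii, acc_shape, dp)

    peak = (acc == ndimage.maximum_filter(acc, size=3)) & (acc >= params.p2)
    py, px = np.nonzero(peak)
    if py.size == 0:
        return []
    votes = acc[py, px]
    order = np.lexsort((px, py, -votes))  # descending votes, ties by (y, x)
    py, px, votes = py[order], px[order], votes[order]

    # map accumulator cells back to image coordinates (center of the dp block)
    cxs = (px + 0.5) * dp - 0.5 if dp != 1.0 else px.astype(np.float64)
    cys = (py + 0.5) * dp - 0.5 if dp != 1.0 else py.astype(np.float64)

    # greedy NMS at separation d_min
    acc_x: list[float] = []
    acc_y: list[float] = []
    for x, y in zip(cxs, cys):
        if acc_x:
            d2 = (np.asarray(acc_x) - x) ** 2 + (np.asarray(acc_y) - y) ** 2
            if d2.min() < params.d_min**2:
                continue
        acc_x.append(float(x))
        acc_y.append(float(y))

    # refine each accepted peak, then re-impose d_min on the refined centers
    # (refinement moves centers by a few px at most)
    detections = []
    for x, y in zip(acc_x, acc_y):
        fx, fy, r_fit, score = _fit_circle(edge, x, y, params.r_min, params.r_max)
        if score > 0:
            detections.append(CircleDetection(cx=fx, cy=fy, r=r_fit, score=score))
    detections.sort(key=lambda d: (-d.score, d.cy, d.cx))
    kept: list[CircleDetection] = []
    for d in detections:
        if all((d.cx - k.cx) ** 2 + (d.cy - k.cy) ** 2 >= params.d_min**2 for k in kept):
            kept.append(d)
    return kept


def count_detections(detections: list[CircleDetection]) -> int:
    """Number of detected circles (the automatic "Hough count")."""
    return len(detections)


def write_detections(
    detections: list[CircleDetection], path: str | Path, params: HoughParams | None = None
) -> None:
    """Write detections to CSV ``cx,cy,r,score`` with a JSON params sidecar."""
    path = Path(path)
    df = pd.DataFrame(
        [(d.cx, d.cy, d.r, d.score) for d in detections], columns=["cx", "cy", "r", "score"]
    )
    df.to_csv(path, index=False)
    if params is not None:
        path.with_suffix(".params.json").write_text(json.dumps(asdict(params), indent=1))


def read_detections(path: str | Path) -> list[CircleDetection]:
    """Read a detections CSV written by :func:`write_detections`."""
    df = pd.read_csv(path)
    return [
        CircleDetection(cx=row.cx, cy=row.cy, r=row.r, score=row.score)
        for row in df.itertuples(index=False)
    ]
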