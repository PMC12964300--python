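"""Count-agreement metrics and detection-to-truth matching.

Counts are compared image-wise between an estimate ŷ_i and the ground truth
y_i over N images: Pearson correlation R, mean squared error and its root
(MSE / RMSE, in tillers² / tillers), the per-image signed relative error in
percent, and the root mean square relative error (RMSRE), the headline
accuracy figure.  Per-bundle quantities convert to field densities through
the sampled patch area (0.5 m² per bundle by default).

Detections are matched to truth circles one-to-one, greedily by ascending
center distance, which quantifies false positives and false negatives on
synthetic data where exact truth is available.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .detect import CircleDetection
from .errors import PairingError, ParameterError, UndefinedCorrelationError
from .session import CorrectionEvent, CountRecord
from .synthetic import BundleTruth

#: Default center-matching threshold (px) for synthetic validation;
#: well under the smallest radius in the reference parameter set.
DEFAULT_MATCH_DIST = 5.0

#: Field patch area sampled per bundle, m².
DEFAULT_PATCH_AREA_M2 = 0.5


@dataclass(frozen=True)
class CountPairs:
    """Paired ground-truth and estimated counts over N images."""

    y: tuple[float, ...]
    y_hat: tuple[float, ...]
    labels: tuple[tuple[str, str], ...] | None = None  # (bundle_id, side) per image

    def __post_init__(self) -> None:
        if len(self.y) != len(self.y_hat) or len(self.y) < 1:
            raise ParameterError(
                f"need equal-length non-empty vectors, got {len(self.y)} and {len(self.y_hat)}"
            )
        if min(self.y) < 0 or min(self.y_hat) < 0:
            raise ParameterError("counts must be non-negative")
        if self.labels is not None and len(self.labels) != len(self.y):
            raise ParameterError("labels must match vector length")

    @property
    def n(self) -> int:
        return len(self.y)


@dataclass(frozen=True)
class MetricsReport:
    """Summary of all agreement metrics for one estimate/truth pairing."""

    pearson_r: float | None  # None when undefined (constant counts)
    mse: float
    rmse: float
    relative_errors: tuple[float, ...]
    rmsre: float
    rmse_density: float | None = None  # tillers/m², if a patch area was given

    def to_json(self, path: str | Path) -> None:
        payload = {
            "pearson_r": self.pearson_r,
            "mse": self.mse,
            "rmse": self.rmse,
            "rmsre_percent": self.rmsre,
            "relative_errors_percent": list(self.relative_errors),
            "rmse_density_per_m2": self.rmse_density,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass(frozen=True)
class MatchResult:
    """One-to-one matching of detections to truth circles."""

    true_positives: int
    false_positives: int
    false_negatives: int
    precision: float
    recall: float
    pairs: tuple[tuple[int, int, float], ...] = ()  # (det idx, truth idx, distance)
    unmatched_detections: tuple[int, ...] = ()
    unmatched_truth: tuple[int, ...] = ()


def pearson_r(pairs: CountPairs) -> float:
    """Pearson correlation R = Cov(y, ŷ) / sqrt(Var(y) · Var(ŷ)).

    Population (1/N) moments are used throughout; the normalization cancels,
    so the value is identical under the sample convention.  Raises for
    constant vectors, where R is undefined.
    """
    y = np.asarray(pairs.y, dtype=np.float64)
    yh = np.asarray(pairs.y_hat, dtype=np.float64)
    if pairs.n < 2:
        raise UndefinedCorrelationError("correlation needs at least 2 pairs")
    vy, vyh = y.var(), yh.var()
    if vy == 0 or vyh == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant vector")
    cov = ((y - y.mean()) * (yh - yh.mean())).mean()
    return float(cov / np.sqrt(vy * vyh))


def mse_rmse(pairs: CountPairs) -> tuple[float, float]:
    """Mean squared error and its square root, in tillers² and tillers."""
    err = np.asarray(pairs.y_hat, dtype=np.float64) - np.asarray(pairs.y, dtype=np.float64)
    mse = float(np.mean(err**2))
    return mse, float(np.sqrt(mse))


def relative_errors(pairs: CountPairs) -> tuple[float, ...]:
    """Signed per-image relative errors (ŷ_i − y_i) / y_i × 100, in percent."""
    y = np.asarray(pairs.y, dtype=np.float64)
    if (y == 0).any():
        raise ParameterError("relative error undefined where ground truth is 0")
    yh = np.asarray(pairs.y_hat, dtype=np.float64)
    return tuple(float(v) for v in (yh - y) / y * 100.0)


def rmsre(pairs: CountPairs) -> float:
    """Root mean square relative error over all images, in percent."""
    rel = np.asarray(relative_errors(pairs))
    return float(np.sqrt(np.mean(rel**2)))


def density_per_m2(count_quantity: float, patch_area_m2: float = DEFAULT_PATCH_AREA_M2) -> float:
    """Convert a per-bundle quantity (a count or an RMSE) to tillers/m²."""
    if patch_area_m2 <= 0:
        raise ParameterError(f"patch area must be positive, got {patch_area_m2}")
    return count_quantity / patch_area_m2


def compute_report(
    pairs: CountPairs, patch_area_m2: float | None = DEFAULT_PATCH_AREA_M2
) -> MetricsReport:
    """All agreement metrics for one pairing (R, MSE/RMSE, relative errors, RMSRE).

    The correlation slot is ``None`` when R is undefined (fewer than two
    images, or a constant count vector); the error metrics are always
    computed.
    """
    mse, rmse_ = mse_rmse(pairs)
    try:
        r = pearson_r(pairs)
    except UndefinedCorrelationError:
        r = None
    return MetricsReport(
        pearson_r=r,
        mse=mse,
        rmse=rmse_,
        relative_errors=relative_errors(pairs),
        rmsre=rmsre(pairs),
        rmse_density=None if patch_area_m2 is None else density_per_m2(rmse_, patch_area_m2),
    )


def _centers(objs) -> np.ndarray:
    if isinstance(objs, BundleTruth):
        return np.asarray([(c[0], c[1]) for c in objs.circles], dtype=np.float64).reshape(-1, 2)
    out = []
    for o in objs:
        if isinstance(o, CircleDetection):
            out.append((o.cx, o.cy))
        else:
            out.append((o[0], o[1]))
    return np.asarray(out, dtype=np.float64).reshape(-1, 2)


def match_detections(
    detections,
    truth,
    max_center_dist: float = DEFAULT_MATCH_DIST,
) -> MatchResult:
    """Match detections to truth circles one-to-one by ascending center distance.

    Candidate pairs closer than ``max_center_dist`` are accepted greedily
    (nearest first; ties broken by detection then truth index), each
    detection and truth circle matching at most once.  Unmatched detections
    are false positives, unmatched truth circles false negatives.  With no
    detections (or no truth), the corresponding rate is vacuously 1.
    """
    if max_center_dist <= 0:
        raise ParameterError(f"max_center_dist must be positive, got {max_center_dist}")
    det = _centers(detections)
    tru = _centers(truth)
    n_det, n_tru = len(det), len(tru)
    if n_det and n_tru:
        dist = np.hypot(det[:, 0:1] - tru[None, :, 0], det[:, 1:2] - tru[None, :, 1])
        di, ti = np.nonzero(dist <= max_center_dist)
        order = np.lexsort((ti, di, dist[di, ti]))
        used_det = np.zeros(n_det, dtype=bool)
        used_tru = np.zeros(n_tru, dtype=bool)
        matched = []
        for k in order:
            i, j = int(di[k]), int(ti[k])
            if not used_det[i] and not used_tru[j]:
                used_det[i] = used_tru[j] = True
                matched.append((i, j, float(dist[i, j])))
    else:
        matched = []
        used_det = np.zeros(n_det, dtype=bool)
        used_tru = np.zeros(n_tru, dtype=bool)
    tp = len(matched)
    fp = n_det - tp
    fn = n_tru - tp
    return MatchResult(
        true_positives=tp,
        false_positives=fp,
        false_negatives=fn,
        precision=tp / n_det if n_det else 1.0,
        recall=tp / n_tru if n_tru else 1.0,
        pairs=tuple(matched),
        unmatched_detections=tuple(int(i) for i in np.nonzero(~used_det)[0]),
        unmatched_truth=tuple(int(j) for j in np.nonzero(~used_tru)[0]),
    )


def perfect_corrections(
    detections: list[CircleDetection],
    truth: BundleTruth,
    max_center_dist: float = DEFAULT_MATCH_DIST,
) -> list[CorrectionEvent]:
    """Correction events that fix every false positive and false negative.

    Produces a remove event at each unmatched detection's center followed by
    an add event at each unmatched truth circle's center; replaying them
    drives the adjusted count to the exact ground-truth count.
    """
    match = match_detections(detections, truth, max_center_dist)
    events: list[CorrectionEvent] = []
    order = 0
    for i in match.unmatched_detections:
        d = detections[i]
        events.append(CorrectionEvent("remove", d.cx, d.cy, order))
        order += 1
    for j in match.unmatched_truth:
        cx, cy, _ = truth.circles[j]
        events.append(CorrectionEvent("add", cx, cy, order))
        order += 1
    return events


def plot_agreement(pairs: CountPairs, path: str | Path, label: str = "estimate") -> None:
    """Scatter of estimates vs ground truth beside per-image relative errors.

    Left panel: ŷ_i against y_i with the identity line; right panel: signed
    relative error (%) against y_i.  Written as PNG.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    y = np.asarray(pairs.y)
    yh = np.asarray(pairs.y_hat)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9.0, 4.0))
    lim = (0.95 * min(y.min(), yh.min()), 1.05 * max(y.max(), yh.max()))
    ax1.plot(lim, lim, color="0.6", lw=0.8, zorder=0)
    ax1.scatter(y, yh, s=14)
    ax1.set_xlabel("ground truth count")
    ax1.set_ylabel(f"{label} count")
    ax2.axhline(0.0, color="0.6", lw=0.8)
    ax2.scatter(y, relative_errors(pairs), s=14)
    ax2.set_xlabel("ground truth count")
    ax2.set_ylabel("relative error [%]")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def paired_side_agreement(
    records: list[CountRecord], count_field: str = "n_adjusted"
) -> float:
    """Pearson R between the top-side and bottom-side counts of each bundle.

    Every bundle must contribute exactly one ``top`` and one ``bottom``
    record; otherwise a pairing error listing the offending bundles is
    raised.
    """
    by_bundle: dict[str, dict[str, float]] = {}
    for rec in records:
        by_bundle.setdefault(rec.bundle_id, {})[rec.side] = float(getattr(rec, count_field))
    bad = sorted(
        b for b, sides in by_bundle.items() if set(sides) != {"top", "bottom"}
    )
    if bad:
        raise PairingError(f"bundles without exactly two sides (top/bottom): {bad}")
    bundles = sorted(by_bundle)
    top = tuple(by_bundle[b]["top"] for b in bundles)
    bottom = tuple(by_bundle[b]["bottom"] for b in bundles)
    return pearson_r(CountPairs(y=top, y_hat=bottom))
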