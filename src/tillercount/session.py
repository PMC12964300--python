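"""Replayable manual-correction sessions and the adjusted-count arithmetic.

In the semi-automatic workflow a user corrects the automatic circle
detections on each image: an *add* event places a manual mark on a missed
tiller, a *remove* event deletes the nearest existing mark (automatic or
manual) within an association radius.  Instead of a GUI, corrections are an
ordered JSON event log that replays deterministically, which makes the
workflow scriptable and testable.

Replaying a session yields the per-image count record with the adjusted
count identity::

    n_adjusted = n_hough + n_added - n_removed

where ``n_removed`` counts only effective removals; a remove that binds to
no mark is kept in the log but recorded as a no-op.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.draw import circle_perimeter

from .detect import CircleDetection, HoughParams
from .errors import ParameterError

#: Overlay colors (RGB): automatic detections green, manual marks pink.
AUTO_COLOR = (0, 255, 0)
MANUAL_COLOR = (255, 105, 180)


@dataclass(frozen=True)
class CorrectionEvent:
    """One user action: kind in {"add", "remove"} at (x, y), px."""

    kind: str
    x: float
    y: float
    order: int

    def __post_init__(self) -> None:
        if self.kind not in ("add", "remove"):
            raise ParameterError(f"event kind must be 'add' or 'remove', got {self.kind!r}")


@dataclass(frozen=True)
class Mark:
    """A mark on the image: an automatic detection or a manual addition."""

    x: float
    y: float
    r: float
    source: str  # "auto" | "manual"


@dataclass
class CorrectionSession:
    """An image's detections plus the ordered corrections applied to them.

    ``association_radius`` bounds how far a remove click may be from the mark
    it deletes; the default is half the detector's minimum center separation,
    which guarantees unambiguous binding.  ``default_mark_radius`` is the
    radius drawn for manual marks (midpoint of the radius search bounds).
    """

    image_id: str
    initial_detections: list[CircleDetection]
    events: list[CorrectionEvent] = field(default_factory=list)
    association_radius: float | None = None
    params: HoughParams = field(default_factory=HoughParams)
    image_shape: tuple[int, int] | None = None  # (height, width) for bounds checks

    def __post_init__(self) -> None:
        if self.association_radius is None:
            self.association_radius = self.params.d_min / 2.0
        if self.association_radius <= 0:
            raise ParameterError(
                f"association_radius must be positive, got {self.association_radius}"
            )
        orders = [e.order for e in self.events]
        if any(b <= a for a, b in zip(orders, orders[1:])):
            raise ParameterError("event order must be strictly increasing")

    @property
    def default_mark_radius(self) -> float:
        return (self.params.r_min + self.params.r_max) / 2.0


@dataclass(frozen=True)
class CountRecord:
    """Per-image counts: automatic, added, removed, and adjusted."""

    bundle_id: str
    side: str
    n_hough: int
    n_added: int
    n_removed: int
    n_adjusted: int

    def __post_init__(self) -> None:
        if min(self.n_hough, self.n_added, self.n_removed, self.n_adjusted) < 0:
            raise ParameterError("counts must be non-negative")
        if self.n_adjusted != self.n_hough + self.n_added - self.n_removed:
            raise ParameterError(
                f"count identity violated: {self.n_adjusted} != "
                f"{self.n_hough} + {self.n_added} - {self.n_removed}"
            )


def apply_event(
    marks: list[Mark],
    event: CorrectionEvent,
    association_radius: float,
    default_mark_radius: float,
    image_shape: tuple[int, int] | None = None,
) -> tuple[list[Mark], bool]:
    """Apply one event to the mark list; returns (new marks, effective).

    *add* appends a manual mark at the click position.  *remove* deletes the
    nearest mark within ``association_radius`` (ties broken by smallest
    distance, then lowest mark index); a remove that binds to nothing leaves
    the marks unchanged and returns ``effective=False``.
    """
    if association_radius <= 0:
        raise ParameterError(f"association_radius must be positive, got {association_radius}")
    if image_shape is not None:
        h, w = image_shape
        if not (0 <= event.x < w and 0 <= event.y < h):
            raise ParameterError(
                f"event at ({event.x}, {event.y}) outside {h}x{w} image bounds"
            )
    if event.kind == "add":
        return marks + [Mark(event.x, event.y, default_mark_radius, "manual")], True
    if not marks:
        return marks, False
    dx = np.asarray([m.x for m in marks]) - event.x
    dy = np.asarray([m.y for m in marks]) - event.y
    dist = np.hypot(dx, dy)
    idx = int(np.argmin(dist))  # np.argmin returns the lowest index on ties
    if dist[idx] > association_radius:
        return marks, False
    return marks[:idx] + marks[idx + 1 :], True


def replay(
    session: CorrectionSession,
    bundle_id: str | None = None,
    side: str | None = None,
) -> tuple[list[Mark], CountRecord]:
    """Replay a session's events in order and compute its count record.

    If ``bundle_id``/``side`` are omitted they are parsed from an image id of
    the form ``<bundle_id>_<side>``.  Replay is deterministic and idempotent:
    the same session always yields identical marks and counts.
    """
    if bundle_id is None or side is None:
        stem, _, tail = session.image_id.rpartition("_")
        if stem and tail in ("top", "bottom"):
            bundle_id, side = bundle_id or stem, side or tail
        else:
            bundle_id, side = bundle_id or session.image_id, side or "top"

    marks = [Mark(d.cx, d.cy, d.r, "auto") for d in session.initial_detections]
    n_added = n_removed = 0
    for event in sorted(session.events, key=lambda e: e.order):
        marks, effective = apply_event(
            marks,
            event,
            session.association_radius,
            session.default_mark_radius,
            session.image_shape,
        )
        if effective:
            if event.kind == "add":
                n_added += 1
            else:
                n_removed += 1
    n_hough = len(session.initial_detections)
    record = CountRecord(
        bundle_id=bundle_id,
        side=side,
        n_hough=n_hough,
        n_added=n_added,
        n_removed=n_removed,
        n_adjusted=n_hough + n_added - n_removed,
    )
    return marks, record


def mark_counts(marks: list[Mark]) -> dict[str, int]:
    """Number of marks per source category ({"auto": ..., "manual": ...})."""
    return {
        "auto": sum(m.source == "auto" for m in marks),
        "manual": sum(m.source == "manual" for m in marks),
    }


def render_overlay(img: np.ndarray, marks: list[Mark]) -> np.ndarray:
    """Draw mark outlines on a grayscale image; returns an RGB uint8 raster.

    Automatic detections are drawn green, manual marks pink, as circle
    perimeters at each mark's radius.
    """
    arr = np.asarray(img)
    if arr.ndim == 2:
        rgb = np.repeat(arr[:, :, None], 3, axis=2).astype(np.uint8)
    else:
        rgb = arr.astype(np.uint8).copy()
    shape = rgb.shape[:2]
    for m in marks:
        color = AUTO_COLOR if m.source == "auto" else MANUAL_COLOR
        rr, cc = circle_perimeter(
            int(round(m.y)), int(round(m.x)), max(1, int(round(m.r))), shape=shape
        )
        rgb[rr, cc] = color
    return rgb


# ---------------------------------------------------------------------------
# session / counts file round-trips

def write_session(session: CorrectionSession, path: str | Path) -> None:
    """Serialize a session to JSON (detections, params, ordered events)."""
    payload = {
        "image_id": session.image_id,
        "params": asdict(session.params),
        "association_radius": session.association_radius,
        "image_shape": list(session.image_shape) if session.image_shape else None,
        "initial_detections": [asdict(d) for d in session.initial_detections],
        "events": [asdict(e) for e in session.events],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_session(path: str | Path) -> CorrectionSession:
    """Load a session JSON written by :func:`write_session`."""
    data = json.loads(Path(path).read_text())
    # hand-written logs may carry only the image id and events; detections
    # are then attached separately before replay
    return CorrectionSession(
        image_id=data["image_id"],
        initial_detections=[CircleDetection(**d) for d in data.get("initial_detections", [])],
        events=[CorrectionEvent(**e) for e in data.get("events", [])],
        association_radius=data.get("association_radius"),
        params=HoughParams(**data.get("params", {})),
        image_shape=tuple(data["image_shape"]) if data.get("image_shape") else None,
    )


def write_counts(records: list[CountRecord], path: str | Path) -> None:
    """Write count records to CSV ``bundle_id,side,n_hough,n_added,n_removed,n_adjusted``."""
    pd.DataFrame([asdict(r) for r in records]).to_csv(path, index=False)


def read_counts(path: str | Path) -> list[CountRecord]:
    """Read a counts CSV written by :func:`write_counts`."""
    df = pd.read_csv(path)
    return [
        CountRecord(
            bundle_id=str(r.bundle_id),
            side=str(r.side),
            n_hough=int(r.n_hough),
            n_added=int(r.n_added),
            n_removed=int(r.n_removed),
            n_adjusted=int(r.n_adjusted),
        )
        for r in df.itertuples(index=False)
    ]
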