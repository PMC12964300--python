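"""End-to-end pipeline: simulate -> detect -> correct -> evaluate.

Each bundle contributes two images (sides ``top`` and ``bottom``), named
``<bundle_id>_<side>.png``; every stage writes plain CSV/JSON artifacts that
the next stage reads unchanged, plus a provenance sidecar (config hash,
seed, package version), so a rerun with the same config and seed reproduces
every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from . import __version__
from .detect import HoughParams, count_detections, denoise, hough_circles, to_grayscale, write_detections
from .errors import FormatError, InvalidSpecError
from .metrics import (
    DEFAULT_MATCH_DIST,
    DEFAULT_PATCH_AREA_M2,
    CountPairs,
    compute_report,
    perfect_corrections,
)
from .session import CorrectionSession, CountRecord, read_session, replay, write_counts
from .synthetic import BundleSpec, generate_bundle, read_truth, write_truth

log = logging.getLogger("tillercount")

SIDES = ("top", "bottom")


def plan_images(bundle_ids, sides: tuple[str, ...] = SIDES) -> list[tuple[str, str, str]]:
    """Image inventory for a set of bundles: one image per bundle side.

    Returns (bundle_id, side, filename) triples; with the default two sides
    every bundle contributes exactly two images.
    """
    return [(b, s, f"{b}_{s}.png") for b in bundle_ids for s in sides]


@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration for a full pipeline run."""

    out_dir: Path
    seed: int = 0
    n_bundles: int = 0  # 0 disables the simulate stage
    bundle_spec: BundleSpec = field(default_factory=BundleSpec)
    hough: HoughParams = field(default_factory=HoughParams)
    association_radius: float | None = None
    patch_area_m2: float = DEFAULT_PATCH_AREA_M2
    max_center_dist: float = DEFAULT_MATCH_DIST
    images: tuple[Path, ...] = ()  # existing images when simulate is disabled
    sessions_dir: Path | None = None  # replay user session logs if present
    auto_correct: bool = False  # generate truth-based perfect corrections

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload["out_dir"] = str(self.out_dir)
        payload["images"] = [str(p) for p in self.images]
        payload["sessions_dir"] = str(self.sessions_dir) if self.sessions_dir else None
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def load_config(path: str | Path, out_dir: str | Path, seed: int | None = None) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a TOML file.

    Recognized tables: ``[simulate]`` (BundleSpec fields plus ``n_bundles``),
    ``[detect]`` (HoughParams fields), ``[session]`` (``association_radius``),
    ``[evaluate]`` (``patch_area_m2``, ``max_center_dist``).
    """
    raw = tomllib.loads(Path(path).read_text())
    sim = dict(raw.get("simulate", {}))
    n_bundles = int(sim.pop("n_bundles", 0))
    for key in ("radius_range", "mask_shape", "bimodal_split"):
        if key in sim:
            sim[key] = tuple(sim[key])
    cfg = PipelineConfig(
        out_dir=Path(out_dir),
        seed=int(raw.get("seed", 0)) if seed is None else seed,
        n_bundles=n_bundles,
        bundle_spec=BundleSpec(**sim),
        hough=HoughParams(**raw.get("detect", {})),
        association_radius=raw.get("session", {}).get("association_radius"),
        patch_area_m2=raw.get("evaluate", {}).get("patch_area_m2", DEFAULT_PATCH_AREA_M2),
        max_center_dist=raw.get("evaluate", {}).get("max_center_dist", DEFAULT_MATCH_DIST),
        auto_correct=bool(raw.get("session", {}).get("auto_correct", False)),
    )
    return cfg


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/JPEG/TIFF raster as 8-bit; 16-bit inputs are rescaled.

    Returns a 2D (grayscale) or HxWx3 (RGB) uint8 array; an alpha channel is
    dropped.  Grayscale conversion is deferred to the detection stage.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # imageio raises various per-plugin errors
        raise FormatError(f"cannot read image {path}: {exc}") from exc
    if arr.dtype == np.uint16:
        log.info("rescaling 16-bit image %s to 8-bit", path.name)
        arr = (arr // 257).astype(np.uint8)
    elif arr.dtype != np.uint8:
        arr = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.ndim not in (2, 3) or (arr.ndim == 3 and arr.shape[2] != 3):
        raise FormatError(f"unsupported raster layout {arr.shape} in {path}")
    return arr


def write_image(img: np.ndarray, path: str | Path) -> None:
    """Write an 8-bit raster as PNG/TIFF (format chosen by extension)."""
    iio.imwrite(Path(path), np.asarray(img, dtype=np.uint8))


def _derive_seeds(seed: int, n: int) -> list[int]:
    """n per-image seeds derived reproducibly from the pipeline seed."""
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def _provenance(config: PipelineConfig) -> dict:
    return {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run simulate? -> detect -> correct? -> evaluate; returns an artifact inventory.

    Raises :class:`InvalidSpecError`/:class:`ParameterError` before any stage
    runs if the configuration is inconsistent; partially written outputs from
    previous runs are never modified in place (files are rewritten whole).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inventory: dict = {"images": [], "detections": [], "counts": None, "report": None}

    # -- simulate -----------------------------------------------------------
    image_paths: list[Path] = list(config.images)
    truths = {}
    if config.n_bundles > 0:
        seeds = _derive_seeds(config.seed, config.n_bundles * len(SIDES))
        k = 0
        for i in range(config.n_bundles):
            bundle_id = f"b{i + 1:03d}"
            for side in SIDES:
                spec = dataclasses.replace(config.bundle_spec, seed=seeds[k])
                k += 1
                img, truth = generate_bundle(spec)
                img_path = out / f"{bundle_id}_{side}.png"
                write_image(img, img_path)
                write_truth(truth, out / f"{bundle_id}_{side}.truth.csv", spec=spec)
                image_paths.append(img_path)
                truths[f"{bundle_id}_{side}"] = truth
    elif not image_paths:
        raise InvalidSpecError("no inputs: enable the simulate stage or pass images")
    inventory["images"] = [str(p) for p in image_paths]

    # -- detect -------------------------------------------------------------
    records: list[CountRecord] = []
    detections_by_image = {}
    for img_path in image_paths:
        image_id = Path(img_path).stem
        gray = denoise(to_grayscale(read_image(img_path)))
        dets = hough_circles(gray, config.hough)
        det_path = out / f"{image_id}.detections.csv"
        write_detections(dets, det_path, config.hough)
        detections_by_image[image_id] = (dets, gray.shape)
        inventory["detections"].append(str(det_path))
        log.info("%s: n_hough=%d", image_id, count_detections(dets))

    # -- correct ------------------------------------------------------------
    for image_id, (dets, shape) in detections_by_image.items():
        events = []
        if config.sessions_dir is not None:
            sess_path = Path(config.sessions_dir) / f"{image_id}.session.json"
            if sess_path.exists():
                events = read_session(sess_path).events
        elif config.auto_correct and image_id in truths:
            events = perfect_corrections(dets, truths[image_id], config.max_center_dist)
        session = CorrectionSession(
            image_id=image_id,
            initial_detections=dets,
            events=events,
            association_radius=config.association_radius,
            params=config.hough,
            image_shape=shape,
        )
        _, record = replay(session)
        records.append(record)
        log.info("%s: n_adjusted=%d", image_id, record.n_adjusted)
    counts_path = out / "counts.csv"
    write_counts(records, counts_path)
    inventory["counts"] = str(counts_path)

    # -- evaluate -----------------------------------------------------------
    truth_counts = {}
    for img_path in image_paths:
        image_id = Path(img_path).stem
        tpath = Path(img_path).parent / f"{image_id}.truth.csv"
        if image_id in truths:
            truth_counts[image_id] = truths[image_id].count
        elif tpath.exists():
            truth_counts[image_id] = read_truth(tpath).count
    if truth_counts:
        ordered = [r for r in records if f"{r.bundle_id}_{r.side}" in truth_counts]
        pairs = CountPairs(
            y=tuple(float(truth_counts[f"{r.bundle_id}_{r.side}"]) for r in ordered),
            y_hat=tuple(float(r.n_adjusted) for r in ordered),
            labels=tuple((r.bundle_id, r.side) for r in ordered),
        )
        report = compute_report(pairs, config.patch_area_m2)
        report_path = out / "report.json"
        report.to_json(report_path)
        inventory["report"] = str(report_path)

    (out / "provenance.json").write_text(json.dumps(_provenance(config), indent=1))
    return inventory
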