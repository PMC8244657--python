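"""Batch orchestration: masks → profiles → traits → shape spaces → diallel.

The pipeline walks a directory of mask PNGs named
``{genotype}_{rootid}_{barpx}.png`` (barpx = pixel length of a 100 mm
scale bar), runs each root through contour extraction, tip finding,
midline tracing, width sampling, de-tipping and trait measurement, fits
the population shape spaces, projects every root into them, and writes
CSV/JSON artifacts plus a machine-readable run manifest. Per-image
failures are logged and skipped, never fatal.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diallel import DiallelConfig, analyze, read_diallel_csv
from .errors import MalformedNameError
from .geometry import (
    DetipModel,
    detip,
    extract_contour,
    find_tip,
    sample_widths,
    straighten,
    trace_midline,
    train_detip,
)
from .masking import RootMask, read_mask_png, scale_from_bar
from .shapespace import (
    curvature_region_profile,
    fit_shape_space,
    normalize_profile,
    project,
)
from .synth import training_profiles
from .traits import measure_traits, records_to_frame

log = logging.getLogger("taproot")

__all__ = ["RunConfig", "parse_filename", "process_mask", "run_pipeline"]


def parse_filename(name: str) -> tuple[dict, float]:
    """Metadata and mm/px from ``{genotype}_{rootid}_{barpx}.png``.

    The final underscore-separated token is the pixel length of the 100 mm
    scale bar; the one before it is the root id; everything before that is
    the genotype (which may itself contain underscores).
    """
    stem = Path(name).stem
    tokens = stem.split("_")
    if len(tokens) < 3:
        raise MalformedNameError(
            f"filename {name!r} does not match {{genotype}}_{{rootid}}_{{barpx}}",
            token=stem,
        )
    try:
        bar_px = float(tokens[-1])
        mm_per_px = scale_from_bar(bar_px)
    except ValueError as exc:
        raise MalformedNameError(
            f"scale token {tokens[-1]!r} in {name!r} is not a positive number",
            token=tokens[-1],
        ) from exc
    metadata = {"genotype": "_".join(tokens[:-2]), "root_id": tokens[-2]}
    return metadata, mm_per_px


@dataclass
class RunConfig:
    """Everything needed to reproduce a batch run."""

    input_dir: Path
    output_dir: Path
    detip_model_path: Path | None = None
    diallel_csv: Path | None = None
    diallel_p: int | None = None
    diallel_r: int = 2
    diallel_F: float = 1.0
    smooth_sigma: float = 3.0
    curvature_window: int = 7
    tangent_window: int = 5
    seed: int = 0
    log_level: str = "INFO"

    def content_hash(self) -> str:
        payload = json.dumps(
            {k: str(v) for k, v in sorted(self.__dict__.items())}, sort_keys=True
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ProcessedRoot:
    """Intermediate per-root products kept for shape-space fitting."""

    profile: object
    normalized: np.ndarray
    shoulder_curv: np.ndarray
    tip_curv: np.ndarray
    record: object
    metadata: dict = field(default_factory=dict)


def process_mask(
    mask: RootMask,
    model: DetipModel,
    smooth_sigma: float = 3.0,
    curvature_window: int = 7,
    tangent_window: int = 5,
) -> ProcessedRoot:
    """One root through the full geometric pipeline."""
    contour = extract_contour(mask)
    tip = find_tip(contour, window=curvature_window)
    midline = trace_midline(mask, tip, smooth_sigma=smooth_sigma)
    profile = sample_widths(mask, midline, tangent_window=tangent_window)
    profile = detip(profile, model)
    straight = straighten(profile, detipped=True)
    record = measure_traits(profile, straight, metadata=mask.metadata)
    straight_contour = extract_contour(straight)
    shoulder = curvature_region_profile(straight_contour, "shoulder", window=curvature_window)
    tip_region = curvature_region_profile(straight_contour, "tip", window=curvature_window)
    return ProcessedRoot(
        profile=profile,
        normalized=normalize_profile(profile),
        shoulder_curv=shoulder.K,
        tip_curv=tip_region.K,
        record=record,
        metadata=dict(mask.metadata),
    )


def _default_model(seed: int) -> DetipModel:
    log.info("no de-tip model supplied; training on synthetic profiles")
    return train_detip(training_profiles(300, seed=seed), seed=seed)


def run_pipeline(config: RunConfig) -> dict:
    """Run the batch pipeline; returns the manifest dictionary.

    Writes ``traits.csv``, ``scores.csv``, three shape-space JSON files,
    an optional ``diallel.csv`` report, and ``manifest.json`` under the
    output directory. Raises ``FileNotFoundError``/``ValueError`` on an
    empty or unreadable input; per-image failures are logged and skipped.
    """
    logging.basicConfig(level=config.log_level)
    in_dir = Path(config.input_dir)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = sorted(in_dir.glob("*.png"))
    if not paths:
        raise FileNotFoundError(f"no PNG masks under {in_dir}")

    if config.detip_model_path and Path(config.detip_model_path).exists():
        model = DetipModel.load(config.detip_model_path)
    else:
        model = _default_model(config.seed)

    processed: list[ProcessedRoot] = []
    failures: list[dict] = []
    for path in paths:
        try:
            metadata, mm_per_px = parse_filename(path.name)
            mask = read_mask_png(path, mm_per_px=mm_per_px, metadata=metadata)
            processed.append(
                process_mask(
                    mask,
                    model,
                    smooth_sigma=config.smooth_sigma,
                    curvature_window=config.curvature_window,
                    tangent_window=config.tangent_window,
                )
            )
        except Exception as exc:  # noqa: BLE001 — error isolation is the contract
            log.warning("skipping %s: %s", path.name, exc)
            failures.append({"file": path.name, "error": str(exc)})

    if not processed:
        raise ValueError("every input failed; nothing to report")

    spaces = {}
    if len(processed) >= 2:
        contour_space = fit_shape_space(
            np.array([p.normalized for p in processed]), kind="contour"
        )
        shoulder_space = fit_shape_space(
            np.array([p.shoulder_curv for p in processed]), kind="curvature_shoulder"
        )
        tip_space = fit_shape_space(
            np.array([p.tip_curv for p in processed]), kind="curvature_tip"
        )
        spaces = {
            "contour": contour_space,
            "curvature_shoulder": shoulder_space,
            "curvature_tip": tip_space,
        }
        for p in processed:
            p.record.root_fill_score = float(project(contour_space, p.normalized)[0])
            p.record.shoulder_curv_pc1 = float(project(shoulder_space, p.shoulder_curv)[0])
            p.record.tip_curv_pc1 = float(project(tip_space, p.tip_curv)[0])
        for name, space in spaces.items():
            space.save(out_dir / f"shapespace_{name}.json")

    frame = records_to_frame([p.record for p in processed])
    header = (
        f"# lengths/widths in mm, areas in mm2, angles in degrees; "
        f"seed={config.seed}\n"
    )
    with open(out_dir / "traits.csv", "w") as fh:
        fh.write(header)
        frame.to_csv(fh, index=False)

    if spaces:
        scores = frame[
            ["genotype", "root_id", "root_fill_score", "shoulder_curv_pc1", "tip_curv_pc1"]
        ]
        with open(out_dir / "scores.csv", "w") as fh:
            fh.write(header)
            scores.to_csv(fh, index=False)

    if config.diallel_csv:
        table = read_diallel_csv(config.diallel_csv)
        p = config.diallel_p or len(table.parents)
        result = analyze(table, DiallelConfig(p=p, r=config.diallel_r, F=config.diallel_F))
        pd.DataFrame([result.report()]).to_csv(out_dir / "diallel.csv", index=False)

    manifest = {
        "package": "taproot",
        "version": __version__,
        "numpy": np.__version__,
        "seed": config.seed,
        "config_hash": config.content_hash(),
        "n_processed": len(processed),
        "n_failed": len(failures),
        "failures": failures,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
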