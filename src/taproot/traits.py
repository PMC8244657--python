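"""Size and shape traits of a straightened, de-tipped root.

Length, maximum width and quantile widths come from the width profile;
root size, tip angle and shoulder hull area from the straightened mask.
Shape scores (root fill, shoulder/tip curvature PC1) are projections into
the population shape spaces and are attached by the pipeline. Also
provides the validation utilities used to compare image measurements with
hand measurements: RMSE about the identity line and the least significant
difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import WidthProfile
from .masking import RootMask

__all__ = [
    "TraitRecord",
    "measure_dimensions",
    "root_size",
    "tip_angle",
    "shoulder_hull_area",
    "measure_traits",
    "rmse_identity",
    "lsd",
    "records_to_frame",
]

DEFAULT_QUANTILES = tuple(np.round(np.arange(0.1, 1.0, 0.1), 1))


@dataclass
class TraitRecord:
    """One root's measured traits; physical units are mm and mm²."""

    length_mm: float
    max_width_mm: float
    width_at_quantiles_mm: dict = field(default_factory=dict)
    aspect_ratio: float = float("nan")
    root_size_mm2: float = float("nan")
    tip_angle_deg: float = float("nan")
    shoulder_hull_area_mm2: float = float("nan")
    root_fill_score: float | None = None
    tip_curv_pc1: float | None = None
    shoulder_curv_pc1: float | None = None
    metadata: dict = field(default_factory=dict)


def measure_dimensions(
    profile: WidthProfile, quantiles=DEFAULT_QUANTILES
) -> tuple[float, float, dict]:
    """Length, maximum width and quantile widths of the de-tipped profile.

    Quantile q is the width at row floor(q·(n−1)) counted from the
    shoulder. Values are in mm.
    """
    widths = profile.body_widths_px
    if len(widths) == 0:
        raise ValueError("empty profile")
    scale = profile.mm_per_px
    length_mm = len(widths) * scale
    max_width_mm = float(widths.max()) * scale
    n = len(widths)
    qw = {
        float(q): float(widths[int(np.floor(q * (n - 1)))]) * scale for q in quantiles
    }
    return length_mm, max_width_mm, qw


def root_size(mask: RootMask) -> float:
    """Total mask area in mm² (expects the straightened, de-tipped mask)."""
    return mask.area_mm2


def tip_angle(mask: RootMask) -> float:
    """Interior angle at the tip of a straightened mask, in degrees.

    The angle is spanned by the segments from the tip (centre of the
    lowest foreground row) to the left and right boundary points located
    10% of the root length above it.
    """
    m = mask.raster
    rows = np.flatnonzero(m.any(axis=1))
    if len(rows) < 10:
        raise ValueError("mask too short for a tip angle (< 10 rows)")
    length = rows[-1] - rows[0] + 1
    tip_row = rows[-1]
    tip_col = np.flatnonzero(m[tip_row]).mean()
    ref_row = tip_row - int(round(0.1 * length))
    cols = np.flatnonzero(m[ref_row])
    left = np.array([ref_row - tip_row, cols[0] - 0.5 - tip_col])
    right = np.array([ref_row - tip_row, cols[-1] + 0.5 - tip_col])
    cosang = left @ right / (np.hypot(*left) * np.hypot(*right))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def shoulder_hull_area(mask: RootMask) -> float:
    """Background area within the bounding box of the top 10% of the root.

    A square crown fills its bounding box (area 0); a rounded crown leaves
    background in the corners. Returned in mm².
    """
    m = mask.raster
    rows = np.flatnonzero(m.any(axis=1))
    length = rows[-1] - rows[0] + 1
    k = max(1, int(round(0.1 * length)))
    region = m[rows[0] : rows[0] + k]
    cols = np.flatnonzero(region.any(axis=0))
    box = k * (cols[-1] - cols[0] + 1)
    return float(box - region.sum()) * mask.mm_per_px**2


def measure_traits(
    profile: WidthProfile,
    straight_mask: RootMask,
    quantiles=DEFAULT_QUANTILES,
    metadata: dict | None = None,
) -> TraitRecord:
    """Assemble the per-root trait record from a de-tipped profile and its
    straightened, de-tipped mask. Shape scores are left unset; the
    pipeline fills them after fitting the population shape spaces."""
    length_mm, max_width_mm, qw = measure_dimensions(profile, quantiles)
    return TraitRecord(
        length_mm=length_mm,
        max_width_mm=max_width_mm,
        width_at_quantiles_mm=qw,
        aspect_ratio=length_mm / max_width_mm,
        root_size_mm2=root_size(straight_mask),
        tip_angle_deg=tip_angle(straight_mask),
        shoulder_hull_area_mm2=shoulder_hull_area(straight_mask),
        metadata=dict(metadata or profile.metadata),
    )


def rmse_identity(a, b) -> float:
    """Root mean squared error of b against a about the line y = x."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def lsd(ms_error: float, n_per_group: int, df_error: int, alpha: float = 0.05) -> float:
    """Least significant difference: t(1−α/2, df)·sqrt(2·MS_error/n)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if ms_error < 0 or n_per_group < 1 or df_error < 1:
        raise ValueError("invalid LSD inputs")
    t = stats.t.ppf(1.0 - alpha / 2.0, df_error)
    return float(t * np.sqrt(2.0 * ms_error / n_per_group))


def records_to_frame(records: list[TraitRecord]) -> pd.DataFrame:
    """Flatten trait records into a table, metadata columns first."""
    rows = []
    for rec in records:
        row = dict(rec.metadata)
        row.update(
            length_mm=rec.length_mm,
            max_width_mm=rec.max_width_mm,
            aspect_ratio=rec.aspect_ratio,
            root_size_mm2=rec.root_size_mm2,
            tip_angle_deg=rec.tip_angle_deg,
            shoulder_hull_area_mm2=rec.shoulder_hull_area_mm2,
            root_fill_score=rec.root_fill_score,
            tip_curv_pc1=rec.tip_curv_pc1,
            shoulder_curv_pc1=rec.shoulder_curv_pc1,
        )
        for q, wq in sorted(rec.width_at_quantiles_mm.items()):
            row[f"width_q{int(round(q * 100)):02d}_mm"] = wq
        rows.append(row)
    return pd.DataFrame(rows)
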