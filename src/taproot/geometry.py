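"""Pre-processing core: contour, curvature, midline, widths, de-tipping.

Coordinate convention: every point array in this module is ``(row, col)``
with the origin at the top-left and row 0 nearest the crown (masks are
oriented shoulder-up). Curvature math internally maps ``x = col`` and
``y = row``; contours are stored with positive shoelace orientation in
that frame, which makes curvature positive where the boundary is convex
(bending toward the root interior).

The midline is traced from the detected tip to the shoulder centre by
walking along the ridge of the Gaussian-smoothed Euclidean distance
transform; widths are then sampled normal to the local midline tangent,
which keeps each slice a single segment even where a curled tip would
cross several rows of the raster.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage
from skimage import measure
from sklearn.ensemble import RandomForestClassifier

from .errors import (
    DegenerateSegmentError,
    InsufficientDataError,
    NormalEscapeError,
    WalkStalledError,
)
from .masking import RootMask

__all__ = [
    "Contour",
    "Midline",
    "WidthProfile",
    "TipResult",
    "DetipModel",
    "extract_contour",
    "curvature",
    "find_tip",
    "trace_midline",
    "sample_widths",
    "straighten",
    "train_detip",
    "detip",
    "shoelace_area",
]


# ---------------------------------------------------------------------------
# contour


@dataclass
class Contour:
    """Closed sub-pixel boundary, unit point density, positive shoelace
    orientation. ``points`` is (N, 2) in (row, col); the first point is
    adjacent to the last (closure is implicit)."""

    points: np.ndarray

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("contour points must be (N, 2)")

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def area(self) -> float:
        return shoelace_area(self.points)


def shoelace_area(points: np.ndarray) -> float:
    """Signed polygon area of a closed (row, col) point loop, positive for
    the orientation this package enforces."""
    y = points[:, 0]
    x = points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def extract_contour(mask: RootMask, smooth_sigma: float = 2.0) -> Contour:
    """Sub-pixel closed boundary of the mask at the 0.5 iso-level.

    The longest iso-contour is resampled to unit spacing (one point per
    boundary pixel) and lightly smoothed with a wrapped Gaussian so that
    local spline fits see a differentiable curve rather than pixel stairs.
    """
    padded = np.pad(mask.raster, 1).astype(float)
    loops = measure.find_contours(padded, 0.5)
    if not loops:
        raise ValueError("mask has no boundary")
    pts = max(loops, key=len) - 1.0  # undo padding
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    # resample to unit arc-length density
    closed = np.vstack([pts, pts[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    n = max(int(round(total)), 8)
    u = np.linspace(0.0, total, n, endpoint=False)
    res = np.column_stack(
        [np.interp(u, arc, closed[:, 0]), np.interp(u, arc, closed[:, 1])]
    )
    if smooth_sigma > 0:
        res = ndimage.gaussian_filter1d(res, smooth_sigma, axis=0, mode="wrap")
    if shoelace_area(res) < 0:
        res = res[::-1]
    return Contour(res)


# ---------------------------------------------------------------------------
# curvature


def curvature(points: np.ndarray, window: int = 7, closed: bool = False) -> np.ndarray:
    """Signed curvature K along an ordered point list.

    A cubic polynomial is least-squares fit to x(t) and y(t) over a centred
    window of 2·window+1 points, with t the chord-length parameter; then
    K = (x'y'' − y'x'') / (x'² + y'²)^{3/2} at the window centre. For an
    open list the returned array covers points[window:-window]; for a
    closed loop it covers every point (windows wrap).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (N, 2)")
    if closed:
        ext = np.concatenate([pts[-window:], pts, pts[:window]])
    else:
        ext = pts
    k = 2 * window + 1
    if len(ext) < k:
        raise ValueError(f"need at least {k} points for window={window}")
    d = np.diff(ext, axis=0)
    chord = np.hypot(d[:, 0], d[:, 1])
    if np.any(chord == 0):
        raise DegenerateSegmentError("consecutive points coincide")
    t = np.concatenate([[0.0], np.cumsum(chord)])
    xw = sliding_window_view(ext[:, 1], k)  # x = col
    yw = sliding_window_view(ext[:, 0], k)  # y = row
    tw = sliding_window_view(t, k)
    tc = tw - tw[:, window : window + 1]
    design = np.stack([np.ones_like(tc), tc, tc**2, tc**3], axis=-1)
    ata = np.einsum("mki,mkj->mij", design, design)
    bx = np.einsum("mki,mk->mi", design, xw)
    by = np.einsum("mki,mk->mi", design, yw)
    cx = np.linalg.solve(ata, bx[..., None])[..., 0]
    cy = np.linalg.solve(ata, by[..., None])[..., 0]
    x1, x2 = cx[:, 1], 2.0 * cx[:, 2]
    y1, y2 = cy[:, 1], 2.0 * cy[:, 2]
    return (x1 * y2 - y1 * x2) / (x1**2 + y1**2) ** 1.5


# ---------------------------------------------------------------------------
# tip finding


@dataclass(frozen=True)
class TipResult:
    """Outcome of the iterative tip search.

    ``low_confidence`` is set when the final maximum curvature is within 5%
    of the segment median — e.g. on a disk, where no point is a
    distinguished tip.
    """

    index: int
    point: tuple[float, float]
    low_confidence: bool
    k_max: float


def _argmax_lowest(k_vals: np.ndarray, rows: np.ndarray) -> int:
    """Index of maximal curvature; ties go to the point farthest from the
    shoulder row (largest row coordinate)."""
    k_max = np.max(k_vals)
    tol = 1e-9 * max(1.0, abs(k_max))
    cand = np.flatnonzero(k_vals >= k_max - tol)
    return int(cand[np.argmax(rows[cand])])


def find_tip(contour: Contour, window: int = 7) -> TipResult:
    """Locate the root tip as the curvature maximum of the lower contour.

    Starting from a segment spanning the lower half of the contour centred
    on the bottom-most point, the curvature argmax is found, the segment is
    re-centred there and halved, until it shrinks to one fitting window.
    """
    pts = contour.points
    n = len(pts)
    center = int(np.argmax(pts[:, 0]))
    size = n // 2
    k_first = None
    while True:
        half = size // 2
        idx = (center + np.arange(-half - window, half + window + 1)) % n
        seg = pts[idx]
        k_vals = curvature(seg, window=window, closed=False)
        seg_idx = idx[window:-window]
        if k_first is None:
            k_first = k_vals
        rel = _argmax_lowest(k_vals, pts[seg_idx, 0])
        center = int(seg_idx[rel])
        if size <= 2 * window + 1:
            break
        size = max(size // 2, 2 * window + 1)
    k_max = float(np.max(k_first))
    k_med = float(np.median(k_first))
    # on a shape with no distinguished tip (e.g. a disk) the curvature
    # maximum sits in the bulk of the distribution; rasterisation noise
    # alone spreads K by tens of percent, so the cutoff is a factor of two
    low_conf = k_med > 0 and k_max <= 2.0 * k_med
    return TipResult(
        index=center,
        point=(float(pts[center, 0]), float(pts[center, 1])),
        low_confidence=low_conf,
        k_max=k_max,
    )


# ---------------------------------------------------------------------------
# midline


@dataclass
class Midline:
    """Ordered (row, col) path from the tip to the shoulder centre."""

    points: np.ndarray

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)

    @property
    def arc_length_px(self) -> float:
        d = np.diff(self.points, axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())


def _bilinear(arr: np.ndarray, pts: np.ndarray) -> np.ndarray:
    return ndimage.map_coordinates(arr, pts.T, order=1, mode="constant", cval=0.0)


def _rectify_start(path: np.ndarray, mask_f: np.ndarray, edt: np.ndarray, step: float) -> np.ndarray:
    """Rebuild the first stretch of the midline along the local axis.

    On a flat-bottomed root the curvature tip is a corner of the bottom
    cap, so the walk starts off-axis and inflates the arc length by up to
    half a cap width. The axis direction is estimated from the stabilised
    ridge just above the tip region and marched back to the boundary,
    which relocates the midline start to the cap centre.
    """
    e = _bilinear(edt, path)
    if len(path) < 20:
        return path
    h = float(e[: min(len(path), 60)].max())
    a = int(min(2.0 * h, len(path) / 3))
    if a < 5:
        return path
    b = min(a + max(10, int(h)), len(path) - 1)
    d = path[a] - path[b]
    norm = np.hypot(*d)
    if norm < 1e-9:
        return path
    d /= norm
    max_march = int(2.5 * h) + 5
    q = path[a]
    for k in range(1, max_march + 1):
        cand = path[a] + k * step * d
        if _bilinear(mask_f, cand[None])[0] < 0.5:
            break
        q = cand
    n_fill = max(int(np.hypot(*(path[a] - q)) / step), 1)
    frac = np.linspace(0.0, 1.0, n_fill, endpoint=False)
    start = q + frac[:, None] * (path[a] - q)
    return np.vstack([start, path[a:]])


def trace_midline(
    mask: RootMask,
    tip: TipResult | tuple[float, float],
    smooth_sigma: float = 3.0,
    step: float = 1.0,
    cone_deg: float = 120.0,
    n_candidates: int = 13,
) -> Midline:
    """Walk the ridge of the smoothed Euclidean distance transform.

    From the tip, each step moves ``step`` px in whichever direction within
    a forward-facing cone (``cone_deg`` wide) maximises the smoothed
    distance field while staying inside the mask, until the shoulder row is
    reached; the terminal point is forced to the mid-width of the shoulder
    row. Raises :class:`WalkStalledError` if the shoulder row is not
    reached within a generous step budget (the walk is cycling).
    """
    m = mask.raster
    tip_pt = np.asarray(tip.point if isinstance(tip, TipResult) else tip, dtype=float)
    edt = ndimage.distance_transform_edt(m)
    sm = ndimage.gaussian_filter(edt, smooth_sigma)
    rows_true = np.flatnonzero(m.any(axis=1))
    top_row = int(rows_true[0])
    mask_f = m.astype(float)

    gy, gx = np.gradient(sm)
    g = np.array([_bilinear(gy, tip_pt[None])[0], _bilinear(gx, tip_pt[None])[0]])
    if np.hypot(*g) < 0.05:
        # the distance-field gradient is unreliable inside a thin residual
        # tail; aim at the mask centroid instead, which always points
        # up-root from the tip
        centroid = np.array(ndimage.center_of_mass(m))
        g = centroid - tip_pt
    if g[0] > 0:
        # masks are shoulder-up and the tip is the lowest point, so the
        # first step must move toward smaller rows
        g = np.array([-g[0], g[1]])
    heading = np.arctan2(g[1], g[0])  # angle of (drow, dcol)

    cols = np.flatnonzero(m[top_row])
    shoulder_center = np.array([float(top_row), float(cols.mean())])

    offsets = np.deg2rad(np.linspace(-cone_deg / 2, cone_deg / 2, n_candidates))
    # straight-ahead preference: decisive only where the distance field is
    # flat (thin tails), negligible against a real ridge gradient
    straight_bias = 0.02 * np.cos(offsets)
    pos = tip_pt.copy()
    points = [pos.copy()]
    max_steps = 4 * (m.shape[0] + m.shape[1])
    for _ in range(max_steps):
        angles = heading + offsets
        dirs = np.column_stack([np.cos(angles), np.sin(angles)])
        cand = pos + step * dirs
        vals = _bilinear(sm, cand) + straight_bias
        inside = _bilinear(mask_f, cand) >= 0.5
        if not inside.any():
            # dead end (e.g. the walk was launched toward the tail end):
            # search the full circle for a way back inside the mask
            angles = heading + np.deg2rad(np.arange(0.0, 360.0, 15.0))
            dirs = np.column_stack([np.cos(angles), np.sin(angles)])
            cand = pos + step * dirs
            vals = _bilinear(sm, cand)
            inside = _bilinear(mask_f, cand) >= 0.5
            if not inside.any():
                raise WalkStalledError(
                    "walk left the mask and cannot re-enter", last_position=tuple(pos)
                )
        vals = np.where(inside, vals, -np.inf)
        best = int(np.argmax(vals))
        heading = float(angles[best])
        pos = cand[best]
        points.append(pos.copy())
        if pos[0] <= top_row + 0.5:
            break
        # inside the crown zone the distance field peaks below the shoulder
        # row; the midline must end at the shoulder centre, so finish with
        # a straight run rather than orbiting the peak
        local_halfwidth = float(_bilinear(edt, pos[None])[0])
        if np.hypot(*(shoulder_center - pos)) <= max(3.0, 1.5 * local_halfwidth):
            break
    else:
        raise WalkStalledError(
            "midline walk did not reach the shoulder row", last_position=tuple(pos)
        )
    gap = float(np.hypot(*(shoulder_center - pos)))
    if gap > step:
        n_fill = int(gap / step)
        frac = np.linspace(0.0, 1.0, n_fill + 1, endpoint=True)[1:]
        points.extend(pos + f * (shoulder_center - pos) for f in frac)
    else:
        points.append(shoulder_center)
    path = np.array(points)
    # the greedy walk zigzags about the ridge; smooth it and resample to
    # unit arc-length steps so path length is not inflated by the jitter
    path = ndimage.gaussian_filter1d(path, 3.0, axis=0, mode="nearest")
    path = _rectify_start(path, mask_f, edt, step)
    seg = np.hypot(*np.diff(path, axis=0).T)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    u = np.arange(0.0, arc[-1], step)
    resampled = np.column_stack(
        [np.interp(u, arc, path[:, 0]), np.interp(u, arc, path[:, 1])]
    )
    return Midline(np.vstack([resampled, path[-1]]))


# ---------------------------------------------------------------------------
# width sampling and straightening


@dataclass
class WidthProfile:
    """Per-step root widths along the midline, ordered shoulder-first.

    ``widths_px[0]`` is the width at the shoulder; ``cut_index``, when set,
    is the number of rows belonging to the storage-root body — rows at and
    beyond it are the residual taproot and are excluded from trait
    computations (the raw widths are retained).
    """

    widths_px: np.ndarray
    mm_per_px: float = 1.0
    cut_index: int | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.widths_px = np.asarray(self.widths_px, dtype=float)
        if self.widths_px.ndim != 1:
            raise ValueError("widths_px must be 1-D")
        if self.mm_per_px <= 0:
            raise ValueError("mm_per_px must be positive")
        if self.cut_index is not None and not 0 <= self.cut_index <= len(self.widths_px):
            raise ValueError("cut_index out of range")

    def __len__(self) -> int:
        return len(self.widths_px)

    @property
    def body_widths_px(self) -> np.ndarray:
        """Widths of the storage-root body (all widths if no cut is set)."""
        if self.cut_index is None:
            return self.widths_px
        return self.widths_px[: self.cut_index]


def sample_widths(
    mask: RootMask,
    midline: Midline,
    tangent_window: int = 5,
    ray_step: float = 0.25,
) -> WidthProfile:
    """Sample root width normal to the midline tangent at every step.

    At each midline point the tangent is a centred finite difference over
    ``tangent_window`` steps; rays are cast to both sides along the normal
    until they cross the 0.5 mask iso-level, with the crossing refined by
    linear interpolation. Raises :class:`NormalEscapeError` if a ray leaves
    the raster while still inside the mask (mask touches the border).
    """
    m = mask.raster.astype(float)
    ml = midline.points[::-1]  # shoulder-first
    n = len(ml)
    if n < 2:
        raise ValueError("midline too short")
    w = tangent_window
    lo = np.maximum(np.arange(n) - w, 0)
    hi = np.minimum(np.arange(n) + w, n - 1)
    tangent = ml[hi] - ml[lo]
    norms = np.hypot(tangent[:, 0], tangent[:, 1])
    bad = norms < 0.5 * (hi - lo)  # folded or degenerate stretch
    if bad.all():
        raise ValueError("midline is degenerate everywhere")
    if bad.any():
        good = np.flatnonzero(~bad)
        for i in np.flatnonzero(bad):
            tangent[i] = tangent[good[np.argmin(np.abs(good - i))]]
        norms = np.hypot(tangent[:, 0], tangent[:, 1])
    tangent /= norms[:, None]
    normal = np.column_stack([-tangent[:, 1], tangent[:, 0]])

    edt_max = float(ndimage.distance_transform_edt(mask.raster).max())
    s_max = 2.0 * edt_max + 4.0
    s_vals = np.arange(0.0, s_max, ray_step)

    def _cast(direction: np.ndarray) -> np.ndarray:
        pts = ml[:, None, :] + s_vals[None, :, None] * direction[:, None, :]
        vals = ndimage.map_coordinates(m, pts.reshape(-1, 2).T, order=1, cval=0.0)
        vals = vals.reshape(n, len(s_vals))
        outside = vals < 0.5
        outside[:, 0] = False  # the midline point itself counts as inside
        first = np.argmax(outside, axis=1)
        if np.any(~outside.any(axis=1)):
            raise NormalEscapeError("width ray never reached background")
        v_in = vals[np.arange(n), first - 1]
        v_out = vals[np.arange(n), first]
        frac = np.clip((v_in - 0.5) / np.maximum(v_in - v_out, 1e-12), 0.0, 1.0)
        dist = s_vals[first - 1] + frac * ray_step
        # a crossing produced by running off the raster is an escape
        cross = ml + dist[:, None] * direction
        h, wd = mask.raster.shape
        # a genuine background crossing sits at least half a pixel inside
        # the raster; anything closer to the edge means the mask touched it
        if np.any((cross[:, 0] < 0.0) | (cross[:, 0] > h - 1.0)
                  | (cross[:, 1] < 0.0) | (cross[:, 1] > wd - 1.0)):
            raise NormalEscapeError("width ray exited the raster inside the mask")
        return dist

    widths = _cast(normal) + _cast(-normal)
    return WidthProfile(widths, mm_per_px=mask.mm_per_px, metadata=dict(mask.metadata))


def straighten(profile: WidthProfile, detipped: bool = False) -> RootMask:
    """Render the width profile as a straightened mask.

    Row k is a centred horizontal run of round(width_k) pixels, shoulder
    row at the top. With ``detipped`` True only body rows are rendered.
    """
    widths = profile.body_widths_px if detipped else profile.widths_px
    if len(widths) == 0:
        raise ValueError("empty profile")
    runs = np.round(widths).astype(int)
    ncols = int(runs.max()) + 4
    center = ncols / 2.0
    out = np.zeros((len(runs), ncols), dtype=bool)
    start = np.round(center - runs / 2.0).astype(int)
    for k, (s0, nk) in enumerate(zip(start, runs)):
        out[k, s0 : s0 + nk] = True
    return RootMask(out, mm_per_px=profile.mm_per_px, metadata=dict(profile.metadata))


# ---------------------------------------------------------------------------
# de-tipping


def _cut_features(widths: np.ndarray) -> np.ndarray:
    """Feature matrix over all candidate cut indices 0..n of one profile.

    Features are taken from the max-width-normalised profile: width at and
    just before the candidate, tail mean/max beyond it, tail length
    fraction, and a local width gradient — all scale-free.
    """
    u = widths / max(widths.max(), 1e-9)
    n = len(u)
    c = np.arange(n + 1)
    here = u[np.minimum(c, n - 1)]
    before = u[np.maximum(c - 1, 0)]
    suffix_sum = np.concatenate([np.cumsum(u[::-1])[::-1], [0.0]])
    tail_len = n - c
    tail_mean = np.where(tail_len > 0, suffix_sum / np.maximum(tail_len, 1), 0.0)
    suffix_max = np.concatenate([np.maximum.accumulate(u[::-1])[::-1], [0.0]])
    g = max(2, int(round(0.01 * n)))
    ahead = u[np.minimum(c + g, n - 1)]
    behind = u[np.maximum(c - g, 0)]
    grad = behind - ahead
    tail_frac = tail_len / n
    return np.column_stack([here, before, tail_mean, suffix_max, grad, tail_frac])


@dataclass
class DetipModel:
    """Random-forest scorer of candidate de-tip indices.

    Every index of a width profile is scored from scale-free local and
    tail features; the highest-scoring index is the cut. Training is
    seeded, so identical data and seed give identical predictions.
    """

    classifier: RandomForestClassifier
    version: str = "1"

    def predict_cut(self, profile: WidthProfile) -> int:
        feats = _cut_features(profile.widths_px)
        scores = self.classifier.predict_proba(feats)[:, 1]
        best = np.flatnonzero(scores >= scores.max() - 1e-12)
        return int(best[-1])  # ties resolved toward keeping more of the root

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump({"version": self.version, "classifier": self.classifier}, fh)

    @staticmethod
    def load(path: str | Path) -> "DetipModel":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        return DetipModel(classifier=payload["classifier"], version=payload["version"])


def train_detip(
    examples: list[tuple[WidthProfile, int]],
    seed: int = 0,
    n_estimators: int = 80,
    negative_rate: float = 0.1,
) -> DetipModel:
    """Train the de-tip model from (profile, true cut index) pairs.

    Candidates within a small tolerance of the true cut are positives; a
    seeded subsample of the remaining indices are negatives. Requires at
    least 50 labelled profiles spanning the range of residual-tip lengths.
    """
    if len(examples) < 50:
        raise InsufficientDataError(
            f"need at least 50 labelled profiles, got {len(examples)}"
        )
    rng = np.random.default_rng(seed)
    feats, labels = [], []
    for profile, cut in examples:
        n = len(profile.widths_px)
        f = _cut_features(profile.widths_px)
        tol = max(2, int(round(0.005 * n)))
        offset = np.abs(np.arange(n + 1) - cut)
        is_pos = offset <= tol
        # a guard band keeps near-cut indices (features nearly identical to
        # the positives) out of the negative pool
        keep_neg = (offset > max(8, 3 * tol)) & (rng.random(n + 1) < negative_rate)
        keep = is_pos | keep_neg
        feats.append(f[keep])
        labels.append(is_pos[keep])
    x = np.vstack(feats)
    y = np.concatenate(labels)
    clf = RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, n_jobs=1, min_samples_leaf=2
    )
    clf.fit(x, y)
    return DetipModel(classifier=clf)


def detip(profile: WidthProfile, model: DetipModel) -> WidthProfile:
    """Return the profile with ``cut_index`` set by the model.

    A profile whose cut is already set is returned unchanged (de-tipping is
    idempotent); the raw widths are always retained.
    """
    if profile.cut_index is not None:
        return profile
    return replace(profile, cut_index=model.predict_cut(profile))
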