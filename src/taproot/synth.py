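"""Synthetic single-root masks and half-diallel phenotype tables.

Every downstream stage (midline tracing, width sampling, de-tipping, shape
PCA, combining-ability ANOVA) is validated against data with known ground
truth. This module renders binary root masks from an analytic width
function laid out along a possibly bent midline, recording the exact
length, width function, midline and de-tip point used; and simulates
balanced half-diallel phenotype tables from known GCA/SCA/error variance
components.

The width family is a plateau–power mixture

    w(s) = W · [(1 − t) + t · (1 − s)^e],   t = 1 − tip_bluntness,

with ``s`` the arc-length fraction from crown (0) to tip (1), ``W`` the
maximum width and ``e`` the taper exponent; ``tip_bluntness`` = 1 gives a
rectangle, 0 a fully tapered (pointed) root. Crown corners may be rounded
by a circular arc, and a thin residual taproot spike may be appended past
the true tip. Rasterisation clamps body width to a 3 px floor (thinner
analytic tails are not representable as a connected 4-neighbour raster).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .masking import RootMask, write_mask_png

__all__ = [
    "RootShapeParams",
    "GroundTruth",
    "DiallelSimParams",
    "render_root",
    "render_family",
    "simulate_diallel",
    "sweep_params",
    "mask_filename",
    "save_mask",
]

MIN_RENDER_WIDTH_PX = 3.0
# a root whose analytic width is sub-floor over more than this fraction of
# its body is rejected rather than silently fattened
MAX_SUBFLOOR_FRACTION = 0.25


@dataclass(frozen=True)
class RootShapeParams:
    """Generative parameters of one synthetic root.

    ``fill_exponent`` controls taper (0 → rectangular, large → sharply
    tapered); ``shoulder_radius_frac`` is the fraction of the half-width
    rounded off at the crown; ``tip_bluntness`` in [0, 1] moves the tip
    from pointed (0) to flat (1); ``bend_amplitude_px``/``bend_wavelength_px``
    describe a sinusoidal lateral midline displacement; ``residual_tip_px``
    is the length of the thin unexpanded taproot appended past the true tip.
    """

    length_px: int = 500
    max_width_px: int = 80
    fill_exponent: float = 1.0
    shoulder_radius_frac: float = 0.0
    tip_bluntness: float = 0.0
    bend_amplitude_px: float = 0.0
    bend_wavelength_px: float = 600.0
    residual_tip_px: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.length_px < 10:
            raise ValueError("length_px must be at least 10")
        if self.max_width_px < 4:
            raise ValueError("max_width_px must be at least 4")
        if self.fill_exponent < 0:
            raise ValueError("fill_exponent must be non-negative")
        for name in ("shoulder_radius_frac", "tip_bluntness"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.bend_amplitude_px < 0:
            raise ValueError("bend_amplitude_px must be non-negative")
        if self.bend_wavelength_px <= 0:
            raise ValueError("bend_wavelength_px must be positive")
        if self.residual_tip_px < 0:
            raise ValueError("residual_tip_px must be non-negative")


@dataclass
class GroundTruth:
    """Exact generative truth for one rendered root.

    ``true_midline`` and ``true_width_function`` are ordered shoulder-first
    (index 0 = crown) at 1 px arc-length steps over the body only;
    ``true_cut_index`` is the number of body steps (the de-tip point);
    ``true_tip`` is the (row, col) of the true tip (end of the body).
    """

    true_length_px: float
    true_max_width_px: float
    true_area_px2: int
    true_midline: np.ndarray
    true_cut_index: int
    true_width_function: np.ndarray
    true_tip: tuple[float, float]
    tail_area_px2: int = 0


def _body_width_analytic(s: np.ndarray, params: RootShapeParams) -> np.ndarray:
    """Unclamped analytic body width at arc-length fractions ``s``."""
    t = 1.0 - params.tip_bluntness
    w = params.max_width_px * ((1.0 - t) + t * (1.0 - s) ** params.fill_exponent)
    radius = params.shoulder_radius_frac * params.max_width_px / 2.0
    if radius > 0:
        v = s * params.length_px
        near = v < radius
        w = w.copy()
        w[near] -= 2.0 * (
            radius - np.sqrt(np.maximum(radius**2 - (radius - v[near]) ** 2, 0.0))
        )
    return w


def _tail_widths(n_tail: int, body_end_width: float) -> np.ndarray:
    """Width profile of the residual taproot spike (≤ 5 px, tapering)."""
    if n_tail == 0:
        return np.empty(0)
    start = min(4.0, body_end_width)
    return np.linspace(start, 1.0, n_tail)


def render_root(params: RootShapeParams) -> tuple[RootMask, GroundTruth]:
    """Rasterise one root mask and record its exact generative truth.

    The mask is oriented shoulder-up (row 0 nearest the crown), forms a
    single filled component, and its analytic width function, bend,
    shoulder rounding and residual tip follow ``params``. Parameters whose
    analytic width falls below 3 px over more than 25% of the body are
    rejected with :class:`ValueError`.
    """
    n_body = int(round(params.length_px))
    n_tail = int(round(params.residual_tip_px))
    s = np.linspace(0.0, 1.0, n_body)
    w_analytic = _body_width_analytic(s, params)
    if np.mean(w_analytic < MIN_RENDER_WIDTH_PX) > MAX_SUBFLOOR_FRACTION:
        raise ValueError(
            "analytic width below the 3 px rasterisation floor over more "
            f"than {MAX_SUBFLOOR_FRACTION:.0%} of the body; "
            "increase max_width_px, tip_bluntness or reduce fill_exponent"
        )
    w_body = np.maximum(w_analytic, MIN_RENDER_WIDTH_PX)
    w_tail = _tail_widths(n_tail, w_body[-1])

    if params.bend_amplitude_px == 0:
        mask, midline, body_area, tail_area = _render_straight(w_body, w_tail)
    else:
        mask, midline, body_area, tail_area = _render_bent(params, w_body, w_tail)

    truth = GroundTruth(
        true_length_px=float(n_body),
        true_max_width_px=float(w_body.max()),
        true_area_px2=body_area,
        true_midline=midline,
        true_cut_index=n_body,
        true_width_function=w_body,
        true_tip=(float(midline[-1, 0]), float(midline[-1, 1])),
        tail_area_px2=tail_area,
    )
    meta = {"synthetic": True, **dataclasses.asdict(params)}
    return RootMask(mask, mm_per_px=1.0, metadata=meta), truth


def _rows_from_widths(widths: np.ndarray, center: float, ncols: int) -> np.ndarray:
    """Exact row-wise rasterisation: row k is a centred run of round(w_k)."""
    out = np.zeros((len(widths), ncols), dtype=bool)
    n = np.round(widths).astype(int)
    start = (np.round(center - n / 2.0)).astype(int)
    for k in range(len(widths)):
        out[k, start[k] : start[k] + n[k]] = True
    return out


def _render_straight(w_body, w_tail):
    margin = 5
    maxw = float(w_body.max())
    ncols = int(np.ceil(maxw)) + 2 * margin
    center = ncols / 2.0
    body = _rows_from_widths(w_body, center, ncols)
    tail = _rows_from_widths(w_tail, center, ncols) if len(w_tail) else np.zeros((0, ncols), bool)
    n_body, n_tail = len(w_body), len(w_tail)
    mask = np.zeros((margin + n_body + n_tail + margin, ncols), dtype=bool)
    mask[margin : margin + n_body] = body
    if n_tail:
        mask[margin + n_body : margin + n_body + n_tail] = tail
    midline = np.stack(
        [np.arange(n_body, dtype=float) + margin, np.full(n_body, center - 0.5)], axis=1
    )
    return mask, midline, int(body.sum()), int(tail.sum())


def _render_bent(params: RootShapeParams, w_body, w_tail):
    n_body, n_tail = len(w_body), len(w_tail)
    total = n_body + n_tail
    amp, lam = params.bend_amplitude_px, params.bend_wavelength_px
    # lateral cosine bend reparametrised to unit arc-length steps; zero
    # slope at y=0 keeps the crown cap horizontal, as in a photographed
    # root whose crown abuts the top of the frame
    yg = np.arange(0.0, total + 2.0, 0.25)
    xg = amp * (1.0 - np.cos(2.0 * np.pi * yg / lam))
    seg = np.hypot(np.diff(yg), np.diff(xg))
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    v = np.arange(total, dtype=float)
    y = np.interp(v, arc, yg)
    x = amp * (1.0 - np.cos(2.0 * np.pi * y / lam))

    widths = np.concatenate([w_body, w_tail])
    # dense paint along sub-pixel samples of midline and normal offsets
    vf = np.arange(0.0, total - 1 + 1e-9, 0.5)
    yf = np.interp(vf, v, y)
    xf = np.interp(vf, v, x)
    wf = np.interp(vf, v, widths)
    dy = np.gradient(yf, vf)
    dx = np.gradient(xf, vf)
    norm = np.hypot(dy, dx)
    ny, nx = dx / norm, -dy / norm  # unit normal

    halfw = float(widths.max()) / 2.0
    margin = 5
    oy = int(np.ceil(halfw * abs(amp * 2 * np.pi / lam))) + margin
    ox = int(np.ceil(halfw + max(0.0, -xf.min()))) + margin
    nrows = oy + int(np.ceil(yf.max() + halfw)) + margin
    ncols = ox + int(np.ceil(xf.max() + halfw)) + margin

    body_mask = np.zeros((nrows, ncols), dtype=bool)
    tail_mask = np.zeros((nrows, ncols), dtype=bool)
    n_body_f = np.searchsorted(vf, n_body - 1, side="right")
    for i in range(len(vf)):
        # stop half a pixel short of the analytic half-width: painting sets
        # whole pixels, so the rasterised edge then sits at ±w/2 on average
        h = max(wf[i] / 2.0 - 0.5, 0.35)
        u = np.arange(-h, h + 1e-9, 0.35)
        rr = np.round(yf[i] + u * ny[i] + oy).astype(int)
        cc = np.round(xf[i] + u * nx[i] + ox).astype(int)
        target = body_mask if i < n_body_f else tail_mask
        target[rr, cc] = True
    body_mask = ndimage.binary_fill_holes(body_mask)
    tail_mask &= ~body_mask
    mask = body_mask | tail_mask
    midline = np.stack([y[:n_body] + oy, x[:n_body] + ox], axis=1)
    return mask, midline, int(body_mask.sum()), int(tail_mask.sum())


def render_family(
    base: RootShapeParams, vary: str, values
) -> list[tuple[RootMask, GroundTruth]]:
    """Render one mask per value of a single varied parameter.

    All other parameters are held at ``base``; ``vary`` must name a
    :class:`RootShapeParams` field.
    """
    if vary not in {f.name for f in dataclasses.fields(RootShapeParams)}:
        raise ValueError(f"{vary!r} is not a RootShapeParams field")
    return [render_root(dataclasses.replace(base, **{vary: val})) for val in values]


def sweep_params(n: int, seed: int = 0) -> list[RootShapeParams]:
    """A reproducible parameter sweep spanning the generator's shape range.

    Used for validation: tapers from full to sharp, bends up to 30 px,
    rounded and square shoulders, pointed to blunt tips, and residual
    taproots on half of the roots. Pointed roots are capped at moderate
    taper exponents so the analytic width stays above the rasterisation
    floor.
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        bluntness = rng.uniform(0.0, 0.8)
        has_tail = rng.random() < 0.5
        if has_tail:
            # a residual taproot attaches where the storage root is still
            # visibly wide; a body already tapered to spike width has no
            # physical body/tail distinction
            bluntness = rng.uniform(0.15, 1.0)
        max_e = 3.0 if bluntness >= 0.1 else 1.2
        out.append(
            RootShapeParams(
                length_px=int(rng.integers(400, 901)),
                max_width_px=int(rng.integers(60, 141)),
                fill_exponent=float(rng.uniform(0.3, max_e)),
                shoulder_radius_frac=float(rng.uniform(0.0, 0.8)),
                tip_bluntness=bluntness,
                bend_amplitude_px=float(rng.uniform(0.0, 30.0)),
                bend_wavelength_px=float(rng.uniform(600.0, 1400.0)),
                residual_tip_px=int(rng.integers(30, 81)) if has_tail else 0,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return out


def mask_filename(genotype: str, root_id: str, mm_per_px: float) -> str:
    """``{genotype}_{rootid}_{barpx}.png`` with barpx = pixels per 100 mm."""
    bar_px = int(round(100.0 / mm_per_px))
    return f"{genotype}_{root_id}_{bar_px}.png"


def save_mask(mask: RootMask, directory: str | Path, genotype: str, root_id: str) -> Path:
    """Write a mask PNG under the filename convention; returns the path."""
    path = Path(directory) / mask_filename(genotype, root_id, mask.mm_per_px)
    write_mask_png(mask, path)
    return path


def training_profiles(n: int = 300, seed: int = 0, noise_px: float = 0.5):
    """Labelled (WidthProfile, true cut index) pairs for de-tip training.

    Profiles are drawn analytically from the generator's width family
    (body plus residual-taproot spike) with small per-row measurement
    jitter, spanning residual tips from absent to long — far cheaper than
    rasterising and re-measuring each root, and exact in the label.
    """
    from .geometry import WidthProfile  # local import; geometry is downstream

    rng = np.random.default_rng(seed)
    pairs = []
    for params in sweep_params(n, seed=seed + 1):
        n_body = int(round(params.length_px))
        s = np.linspace(0.0, 1.0, n_body)
        w_body = np.maximum(_body_width_analytic(s, params), MIN_RENDER_WIDTH_PX)
        w_tail = _tail_widths(int(round(params.residual_tip_px)), w_body[-1])
        widths = np.concatenate([w_body, w_tail])
        widths = np.maximum(widths + rng.normal(0.0, noise_px, len(widths)), 1.0)
        pairs.append((WidthProfile(widths), n_body))
    return pairs


@dataclass(frozen=True)
class DiallelSimParams:
    """Half-diallel simulation: p parents, r replicate plots per cross,
    n_roots phenotyped roots per plot, and known variance components.

    Phenotypes follow y_ijk = mu + g_i + g_j + s_ij + eps_ijk with
    g ~ N(0, var_gca), s ~ N(0, var_sca) (symmetric), eps ~ N(0, var_err).
    ``F`` is the parental inbreeding coefficient (carried through to the
    analysis; it does not affect simulation).
    """

    p: int = 8
    r: int = 2
    n_roots: int = 15
    mu: float = 100.0
    var_gca: float = 25.0
    var_sca: float = 5.0
    var_err: float = 50.0
    F: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.p < 4:
            raise ValueError("at least 4 parents are required")
        if self.r < 1 or self.n_roots < 1:
            raise ValueError("r and n_roots must be positive")
        for name in ("var_gca", "var_sca", "var_err"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.F <= 1.0:
            raise ValueError("F must lie in [0, 1]")


def simulate_diallel(params: DiallelSimParams) -> pd.DataFrame:
    """Simulate a balanced half-diallel phenotype table.

    Returns one record per root for every unordered cross i < j
    (p(p−1)/2 crosses × r plots × n_roots), with columns
    ``parent_i, parent_j, rep, root_id, value``. The same seed yields a
    bit-identical table.
    """
    rng = np.random.default_rng(params.seed)
    p, r, n = params.p, params.r, params.n_roots
    g = rng.normal(0.0, np.sqrt(params.var_gca), size=p)
    pairs = [(i, j) for i in range(1, p + 1) for j in range(i + 1, p + 1)]
    s = rng.normal(0.0, np.sqrt(params.var_sca), size=len(pairs))
    rows = []
    for (i, j), s_ij in zip(pairs, s):
        genetic = params.mu + g[i - 1] + g[j - 1] + s_ij
        for rep in range(1, r + 1):
            eps = rng.normal(0.0, np.sqrt(params.var_err), size=n)
            for k in range(n):
                rows.append((i, j, rep, k + 1, genetic + eps[k]))
    return pd.DataFrame(rows, columns=["parent_i", "parent_j", "rep", "root_id", "value"])
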