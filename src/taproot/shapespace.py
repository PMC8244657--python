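"""Size-independent shape analysis of straightened roots.

Root fill — the degree to which a root maintains its maximum width along
its length — is quantified as the first principal component of length-
and width-normalised width profiles (1000 samples, maximum width 1)
across a population. Shoulder and tip shape are quantified by PCA of
curvature values over 50-point contour windows centred on the crown and
the tip. Eigenvector signs are fixed deterministically: contour PC1 is
oriented so that a higher score means a more tapered root (smaller area
under the normalised profile); curvature PC1 is oriented to correlate
positively with summed curvature; remaining components have their
largest-magnitude loading positive.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import Contour, WidthProfile, curvature
from .traits import TraitRecord

__all__ = [
    "N_PROFILE_POINTS",
    "N_REGION_POINTS",
    "CurvatureProfile",
    "ShapeSpace",
    "normalize_profile",
    "fit_shape_space",
    "project",
    "reconstruct",
    "curvature_region_profile",
    "sum_curvature",
    "market_class_features",
    "MARKET_CLASS_TRAITS",
]

N_PROFILE_POINTS = 1000
N_REGION_POINTS = 50

MARKET_CLASS_TRAITS = (
    "length_mm",
    "max_width_mm",
    "root_fill_score",
    "tip_curv_pc1",
    "shoulder_curv_pc1",
    "aspect_ratio",
)


@dataclass
class CurvatureProfile:
    """Curvature K over the 50 contour points of one region."""

    region: str  # "shoulder" or "tip"
    K: np.ndarray
    window: int

    def __post_init__(self):
        self.K = np.asarray(self.K, dtype=float)
        if len(self.K) != N_REGION_POINTS:
            raise ValueError(f"curvature profile must have {N_REGION_POINTS} values")


@dataclass
class ShapeSpace:
    """A fitted PCA shape space: mean, orthonormal eigenvectors
    (component × dimension), per-component explained-variance fractions."""

    mean_vector: np.ndarray
    eigenvectors: np.ndarray
    explained_variance: np.ndarray
    n_samples: int
    kind: str
    version: str = "1"

    @property
    def explained_variance_fraction(self) -> np.ndarray:
        total = self.explained_variance.sum()
        if total == 0:
            return np.zeros_like(self.explained_variance)
        return self.explained_variance / total

    @property
    def n_components(self) -> int:
        return len(self.eigenvectors)

    def save(self, path: str | Path) -> None:
        payload = {
            "version": self.version,
            "kind": self.kind,
            "n_samples": self.n_samples,
            "mean_vector": self.mean_vector.tolist(),
            "eigenvectors": self.eigenvectors.tolist(),
            "explained_variance": self.explained_variance.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @staticmethod
    def load(path: str | Path) -> "ShapeSpace":
        payload = json.loads(Path(path).read_text())
        return ShapeSpace(
            mean_vector=np.array(payload["mean_vector"]),
            eigenvectors=np.array(payload["eigenvectors"]),
            explained_variance=np.array(payload["explained_variance"]),
            n_samples=payload["n_samples"],
            kind=payload["kind"],
            version=payload["version"],
        )


def normalize_profile(profile: WidthProfile, n_points: int = N_PROFILE_POINTS) -> np.ndarray:
    """Length- and width-normalised profile: resample the de-tipped widths
    to ``n_points`` even samples and divide by the maximum width, so every
    root has unit length and unit maximum width."""
    widths = profile.body_widths_px
    if len(widths) < 2:
        raise ValueError("need at least 2 rows to normalise")
    wmax = widths.max()
    if wmax <= 0:
        raise ValueError("zero maximum width")
    x = np.linspace(0.0, len(widths) - 1.0, n_points)
    resampled = np.interp(x, np.arange(len(widths)), widths)
    return resampled / resampled.max()


def _fix_signs(space: ShapeSpace, centered: np.ndarray) -> None:
    """Deterministic eigenvector signs (see module docstring)."""
    vecs = space.eigenvectors
    for i in range(len(vecs)):
        flip = False
        if i == 0 and space.kind in ("contour", "curvature_shoulder", "curvature_tip"):
            stat = centered.sum(axis=1)  # area under profile / summed curvature
            scores = centered @ vecs[0]
            cov = float(scores @ stat)
            if abs(cov) > 1e-12:
                # contour: higher PC1 = more tapered (less area); curvature:
                # higher PC1 = more total curvature
                flip = cov > 0 if space.kind == "contour" else cov < 0
            else:
                flip = vecs[i][np.argmax(np.abs(vecs[i]))] < 0
        else:
            flip = vecs[i][np.argmax(np.abs(vecs[i]))] < 0
        if flip:
            vecs[i] = -vecs[i]


def fit_shape_space(samples: np.ndarray, kind: str = "contour") -> ShapeSpace:
    """Mean-centred covariance PCA of profile or curvature vectors.

    Components are ordered by decreasing variance; with all
    min(n_samples−1, dim) components retained the explained fractions sum
    to 1 and reconstruction is exact.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 2 or len(x) < 2:
        raise ValueError("need a (n_samples >= 2, dim) matrix")
    mean = x.mean(axis=0)
    centered = x - mean
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    n_comp = min(len(x) - 1, x.shape[1])
    variances = svals[:n_comp] ** 2 / (len(x) - 1)
    space = ShapeSpace(
        mean_vector=mean,
        eigenvectors=vt[:n_comp].copy(),
        explained_variance=variances,
        n_samples=len(x),
        kind=kind,
    )
    _fix_signs(space, centered)
    return space


def project(space: ShapeSpace, sample: np.ndarray) -> np.ndarray:
    """Score vector of one sample (or a matrix of samples) in the space."""
    sample = np.asarray(sample, dtype=float)
    if sample.shape[-1] != len(space.mean_vector):
        raise ValueError("dimension mismatch")
    return (sample - space.mean_vector) @ space.eigenvectors.T


def reconstruct(space: ShapeSpace, scores: np.ndarray, n_components: int | None = None) -> np.ndarray:
    """Profile from leading PC scores: mean + eigenvectorsᵀ · padded scores.

    Scores beyond ``n_components`` are held at 0 (the mean), which renders
    the simulated silhouette for a chosen PC1 value.
    """
    scores = np.atleast_1d(np.asarray(scores, dtype=float))
    if n_components is None:
        n_components = len(scores)
    if n_components > space.n_components:
        raise ValueError("more components requested than available")
    padded = np.zeros(space.n_components)
    padded[: len(scores[:n_components])] = scores[:n_components]
    return space.mean_vector + padded @ space.eigenvectors


def curvature_region_profile(
    contour: Contour, region: str, window: int = 7
) -> CurvatureProfile:
    """Curvature over the 50 contour points centred on the crown (shoulder)
    or on the bottom-most point (tip) of a unit-density contour."""
    if region not in ("shoulder", "tip"):
        raise ValueError(f"region must be 'shoulder' or 'tip', got {region!r}")
    pts = contour.points
    n = len(pts)
    if n < N_REGION_POINTS + 2 * window:
        raise ValueError("contour too short for a 50-point region")
    if region == "tip":
        center = int(np.argmax(pts[:, 0]))
    else:
        y_min = pts[:, 0].min()
        top = pts[:, 0] <= y_min + 1.0
        x_center = pts[top, 1].mean()
        center = int(np.argmin((pts[:, 0] - y_min) ** 2 + (pts[:, 1] - x_center) ** 2))
    half = N_REGION_POINTS // 2
    idx = (center + np.arange(-half - window, half + window)) % n
    k_vals = curvature(pts[idx], window=window, closed=False)
    return CurvatureProfile(region=region, K=k_vals, window=window)


def sum_curvature(profile: CurvatureProfile) -> float:
    """Total curvature: the sum of the 50 K values of a region."""
    return float(profile.K.sum())


def market_class_features(
    records: list[TraitRecord],
) -> tuple[pd.DataFrame, np.ndarray, ShapeSpace]:
    """Six-trait feature matrix and PCA scores for market-class clustering.

    Uses length, maximum width, root fill, tip and shoulder curvature PC1,
    and aspect ratio; columns are z-standardised (zero-variance columns
    dropped with a warning), then decomposed by PCA. Returns the
    standardised feature table, the score matrix, and the fitted space.
    """
    rows = []
    for rec in records:
        row = {}
        for name in MARKET_CLASS_TRAITS:
            val = getattr(rec, name)
            if val is None or (isinstance(val, float) and np.isnan(val)):
                raise ValueError(f"missing trait {name!r} in record {rec.metadata}")
            row[name] = float(val)
        rows.append(row)
    df = pd.DataFrame(rows)
    std = df.std(ddof=1)
    dead = std[std == 0].index.tolist()
    if dead:
        warnings.warn(f"dropping zero-variance traits: {dead}", stacklevel=2)
        df = df.drop(columns=dead)
    if df.shape[1] == 0:
        return df, np.zeros((len(rows), 0)), None
    z = (df - df.mean()) / df.std(ddof=1)
    space = fit_shape_space(z.to_numpy(), kind="features")
    scores = project(space, z.to_numpy())
    return z, scores, space
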