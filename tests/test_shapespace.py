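"""Normalised-profile PCA (root fill), curvature regions, and clustering."""

import warnings

import numpy as np
import pytest
from sklearn.decomposition import PCA

import taproot as tp
from taproot.geometry import WidthProfile
from taproot.shapespace import (
    ShapeSpace,
    curvature_region_profile,
    fit_shape_space,
    market_class_features,
    normalize_profile,
    project,
    reconstruct,
    sum_curvature,
)
from taproot.traits import TraitRecord


def taper_family(exponents, n_rows=600, max_width=100.0):
    """Noise-free single-degree-of-freedom family of normalised profiles."""
    s = np.linspace(0.0, 1.0, n_rows)
    profiles = []
    for e in exponents:
        w = np.maximum(max_width * (1 - s) ** e, 3.0)
        profiles.append(normalize_profile(WidthProfile(w)))
    return np.array(profiles)


class TestNormalizeProfile:
    def test_constant_profile_gives_unit_vector(self):
        out = normalize_profile(WidthProfile(np.full(400, 60.0)))
        assert out.shape == (1000,)
        assert np.allclose(out, 1.0)

    def test_linear_taper_midpoint(self):
        out = normalize_profile(WidthProfile(np.linspace(50.0, 10.0, 500)))
        assert out[500] == pytest.approx(0.6, abs=1e-3)

    def test_idempotent(self):
        out = normalize_profile(WidthProfile(np.linspace(50.0, 10.0, 500)))
        again = normalize_profile(WidthProfile(out))
        assert np.allclose(out, again)
        assert out.max() == 1.0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            normalize_profile(WidthProfile(np.array([5.0])))


class TestFitShapeSpace:
    def test_two_samples_are_rank_one(self):
        x = np.vstack([np.linspace(0, 1, 50), np.linspace(1, 0, 50)])
        space = fit_shape_space(x)
        assert space.explained_variance_fraction[0] == pytest.approx(1.0)

    def test_matches_sklearn_pca(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(40, 25))
        space = fit_shape_space(x, kind="features")
        ref = PCA(n_components=25).fit(x)
        assert np.allclose(space.explained_variance, ref.explained_variance_, atol=1e-9)
        assert np.allclose(np.abs(space.eigenvectors), np.abs(ref.components_), atol=1e-8)

    def test_eigenvectors_orthonormal_and_fractions_sum_to_one(self):
        x = np.random.default_rng(1).normal(size=(30, 12))
        space = fit_shape_space(x)
        assert np.allclose(space.eigenvectors @ space.eigenvectors.T, np.eye(12), atol=1e-9)
        assert space.explained_variance_fraction.sum() == pytest.approx(1.0)

    def test_taper_family_is_one_dimensional(self):
        x = taper_family(np.linspace(0.5, 2.5, 20))
        space = fit_shape_space(x, kind="contour")
        assert space.explained_variance_fraction[0] >= 0.95

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            fit_shape_space(np.zeros((1, 10)))


class TestProjectReconstruct:
    def test_mean_projects_to_zero(self):
        x = taper_family(np.linspace(0.5, 2.5, 10))
        space = fit_shape_space(x)
        assert np.allclose(project(space, space.mean_vector), 0.0, atol=1e-12)

    def test_full_reconstruction_is_exact(self):
        x = taper_family(np.linspace(0.5, 2.5, 12))
        space = fit_shape_space(x)
        for sample in x:
            rec = reconstruct(space, project(space, sample))
            assert np.abs(rec - sample).max() < 1e-8

    def test_zero_scores_give_mean(self):
        space = fit_shape_space(taper_family([0.5, 1.0, 2.0]))
        assert np.allclose(reconstruct(space, np.zeros(2)), space.mean_vector)

    def test_pc1_score_monotone_in_taper_and_sign_fixed(self):
        x = taper_family(np.linspace(0.5, 2.5, 20))
        space = fit_shape_space(x, kind="contour")
        scores = project(space, x)[:, 0]
        assert np.all(np.diff(scores) > 0)  # more tapered => higher score

    def test_lower_pc1_reconstructs_fuller_roots(self):
        x = taper_family(np.linspace(0.5, 2.5, 20))
        space = fit_shape_space(x, kind="contour")
        sd = np.sqrt(space.explained_variance[0])
        areas = [
            reconstruct(space, np.array([c]), 1).sum() for c in (-sd, 0.0, sd)
        ]
        assert areas[0] > areas[1] > areas[2]

    def test_dimension_mismatch(self):
        space = fit_shape_space(taper_family([0.5, 1.0]))
        with pytest.raises(ValueError):
            project(space, np.zeros(13))


class TestCurvatureRegions:
    def test_square_crown_turns_ninety_degrees_at_each_corner(self):
        # 50-point window over a 30 px wide square crown: total turning of
        # the two corners is pi; the crown centre and side walls are flat
        mask, _ = tp.render_root(
            tp.RootShapeParams(length_px=300, max_width_px=30, fill_exponent=0.0,
                               tip_bluntness=1.0)
        )
        cp = curvature_region_profile(tp.extract_contour(mask), "shoulder")
        assert sum_curvature(cp) == pytest.approx(np.pi, rel=0.15)
        assert abs(cp.K[25]) < 0.005  # crown centre

    def test_semicircular_shoulder_curvature_matches_radius(self):
        mask, _ = tp.render_root(
            tp.RootShapeParams(length_px=400, max_width_px=100, fill_exponent=0.0,
                               tip_bluntness=1.0, shoulder_radius_frac=1.0)
        )
        cp = curvature_region_profile(tp.extract_contour(mask), "shoulder")
        assert np.median(cp.K) == pytest.approx(1 / 50, rel=0.15)

    def test_straight_side_wall_is_flat(self):
        mask, _ = tp.render_root(
            tp.RootShapeParams(length_px=400, max_width_px=60, fill_exponent=0.0,
                               tip_bluntness=1.0)
        )
        contour = tp.extract_contour(mask)
        from taproot.geometry import curvature

        k = curvature(contour.points, window=7, closed=True)
        rows = contour.points[:, 0]
        mid = (rows > rows.min() + 100) & (rows < rows.max() - 100)
        assert np.all(np.abs(k[mid]) < 0.005)

    def test_tip_region_centres_on_the_tip(self):
        mask, truth = tp.render_root(
            tp.RootShapeParams(length_px=400, max_width_px=80, fill_exponent=1.0,
                               tip_bluntness=0.0)
        )
        cp = curvature_region_profile(tp.extract_contour(mask), "tip")
        assert cp.K.argmax() == pytest.approx(25, abs=5)

    def test_unknown_region_rejected(self):
        with pytest.raises(ValueError):
            curvature_region_profile(tp.extract_contour(tp.RootMask(np.pad(np.ones((60, 30), bool), 3))), "flank")


class TestSumCurvature:
    def test_zero_profile(self):
        from taproot.shapespace import CurvatureProfile

        assert sum_curvature(CurvatureProfile("tip", np.zeros(50), 7)) == 0.0

    def test_closed_circle_total_turning_is_two_pi(self):
        from taproot.geometry import curvature

        theta = np.linspace(0, 2 * np.pi, 400, endpoint=False)
        r = 400 / (2 * np.pi)  # unit spacing between samples
        pts = np.column_stack([r * np.sin(theta), r * np.cos(theta)])
        k = curvature(pts, window=7, closed=True)
        ds = 2 * np.pi * r / 400
        assert np.sum(np.abs(k)) * ds == pytest.approx(2 * np.pi, rel=0.01)


class TestMarketClassFeatures:
    @staticmethod
    def _records(seed=0):
        rng = np.random.default_rng(seed)
        classes = {
            "imperator": (280, 30, 1.2, 0.02, 0.01),
            "chantenay": (120, 55, -0.8, -0.03, 0.04),
        }
        records, labels = [], []
        for name, (length, width, fill, tip_c, sh_c) in classes.items():
            for _ in range(35):
                l = length * rng.normal(1, 0.08)
                w = width * rng.normal(1, 0.08)
                records.append(
                    TraitRecord(
                        length_mm=l, max_width_mm=w, aspect_ratio=l / w,
                        root_fill_score=fill + rng.normal(0, 0.15),
                        tip_curv_pc1=tip_c + rng.normal(0, 0.01),
                        shoulder_curv_pc1=sh_c + rng.normal(0, 0.01),
                    )
                )
                labels.append(name)
        return records, np.array(labels)

    def test_two_market_classes_separate(self):
        records, labels = self._records()
        _, scores, _ = market_class_features(records)
        cents = {k: scores[labels == k, :2].mean(axis=0) for k in set(labels)}
        sep = np.hypot(*(cents["imperator"] - cents["chantenay"]))
        spreads = [
            np.mean(np.hypot(*(scores[labels == k, :2] - cents[k]).T))
            for k in set(labels)
        ]
        assert sep > 3 * np.mean(spreads)

    def test_identical_roots_drop_zero_variance_columns(self):
        rec = TraitRecord(length_mm=100, max_width_mm=20, aspect_ratio=5,
                          root_fill_score=0.1, tip_curv_pc1=0.0, shoulder_curv_pc1=0.0)
        records = [rec] * 5
        with pytest.warns(UserWarning, match="zero-variance"):
            z, scores, _ = market_class_features(records)
        assert z.shape[1] == 0

    def test_missing_trait_rejected(self):
        rec = TraitRecord(length_mm=100, max_width_mm=20, aspect_ratio=5)
        with pytest.raises(ValueError, match="missing trait"):
            market_class_features([rec])

    def test_standardisation_removes_physical_scale(self):
        records, _ = self._records()
        doubled = [
            TraitRecord(
                length_mm=2 * r.length_mm, max_width_mm=2 * r.max_width_mm,
                aspect_ratio=r.aspect_ratio, root_fill_score=r.root_fill_score,
                tip_curv_pc1=r.tip_curv_pc1, shoulder_curv_pc1=r.shoulder_curv_pc1,
            )
            for r in records
        ]
        z1, _, _ = market_class_features(records)
        z2, _, _ = market_class_features(doubled)
        assert np.allclose(z1.to_numpy(), z2.to_numpy())


def test_shape_space_roundtrip(tmp_path):
    space = fit_shape_space(taper_family(np.linspace(0.5, 2.5, 8)), kind="contour")
    path = tmp_path / "space.json"
    space.save(path)
    loaded = ShapeSpace.load(path)
    assert loaded.kind == "contour"
    assert np.allclose(loaded.eigenvectors, space.eigenvectors)
    assert np.allclose(loaded.mean_vector, space.mean_vector)
    assert loaded.n_samples == space.n_samples
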