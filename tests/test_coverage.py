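"""Color features, max-ent training, pixel classification, class fractions."""

import numpy as np
import pytest
from scipy.optimize import minimize

from plotpheno.coverage import (
    DEFAULT_L2,
    UNLABELED,
    CoverageModel,
    TrainingSet,
    class_fractions,
    classify_pixels,
    color_features,
    rgb_to_hsv,
    rgb_to_lab,
    train_model,
)
from plotpheno.geodata import GeoGrid, OrthoImage


def _lab_reference(r, g, b):
    """Independent formula-level sRGB (D65, 2 deg) -> CIELAB implementation."""
    def lin(u):
        u = u / 255.0
        return np.where(u <= 0.04045, u / 12.92, ((u + 0.055) / 1.055) ** 2.4)

    rl, gl, bl = lin(np.float64(r)), lin(np.float64(g)), lin(np.float64(b))
    X = 0.4124564 * rl + 0.3575761 * gl + 0.1804375 * bl
    Y = 0.2126729 * rl + 0.7151522 * gl + 0.0721750 * bl
    Z = 0.0193339 * rl + 0.1191920 * gl + 0.9503041 * bl
    Xn, Yn, Zn = 0.95047, 1.0, 1.08883

    def f(t):
        d = 6.0 / 29.0
        return np.where(t > d**3, np.cbrt(t), t / (3 * d**2) + 4.0 / 29.0)

    fx, fy, fz = f(X / Xn), f(Y / Yn), f(Z / Zn)
    return 116 * fy - 16, 500 * (fx - fy), 200 * (fy - fz)


class TestColorSpaces:
    @pytest.mark.parametrize(
        "rgb,expected",
        [
            ((255, 0, 0), (0.0, 1.0, 1.0)),
            ((128, 128, 128), (0.0, 0.0, 128 / 255)),
            ((0, 255, 0), (1 / 3, 1.0, 1.0)),
        ],
    )
    def test_hsv_reference_colors(self, rgb, expected):
        h, s, v = rgb_to_hsv(*rgb)
        assert (float(h), float(s), float(v)) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "rgb,expected,tol",
        [((255, 255, 255), (100.0, 0.0, 0.0), 1e-2), ((0, 0, 0), (0.0, 0.0, 0.0), 1e-9)],
    )
    def test_lab_white_and_black(self, rgb, expected, tol):
        lab = tuple(float(v) for v in rgb_to_lab(*rgb))
        assert lab == pytest.approx(expected, abs=tol)

    def test_lab_matches_published_formulas(self):
        rng = np.random.default_rng(0)
        rgb = rng.integers(0, 256, size=(200, 3))
        L, a, b = rgb_to_lab(rgb[:, 0], rgb[:, 1], rgb[:, 2])
        Lr, ar, br = _lab_reference(rgb[:, 0], rgb[:, 1], rgb[:, 2])
        np.testing.assert_allclose(L, Lr, atol=0.1)
        np.testing.assert_allclose(a, ar, atol=0.1)
        np.testing.assert_allclose(b, br, atol=0.1)

    def test_feature_vector_layout(self):
        f = color_features(255, 0, 0)
        assert f.shape == (9,)
        assert f[:3] == pytest.approx([1.0, 0.0, 0.0])
        assert f[3:6] == pytest.approx([0.0, 1.0, 1.0])


def _separable_training(n=100, seed=0, sd=5.0):
    rng = np.random.default_rng(seed)
    green = np.clip(rng.normal((60, 150, 50), sd, (n, 3)), 0, 255)
    brown = np.clip(rng.normal((150, 110, 80), sd, (n, 3)), 0, 255)
    return TrainingSet.from_rgb(["green", "brown"], [green, brown])


class TestTrainModel:
    def test_separable_colors_train_to_perfect_accuracy(self):
        ts = _separable_training()
        model = train_model(ts, seed=0)
        assert (model.predict(ts.features) == ts.labels).all()

    def test_label_permutation_symmetry(self):
        ts = _separable_training()
        permuted = TrainingSet(
            classes=ts.classes[::-1], features=ts.features, labels=1 - ts.labels
        )
        m1 = train_model(ts, seed=0)
        m2 = train_model(permuted, seed=0)
        pred1 = np.array(ts.classes)[m1.predict(ts.features)]
        pred2 = np.array(permuted.classes)[m2.predict(ts.features)]
        assert (pred1 == pred2).all()

    def test_probabilities_sum_to_one(self):
        ts = _separable_training()
        model = train_model(ts, seed=0)
        rng = np.random.default_rng(1)
        rgb = rng.integers(0, 256, size=(500, 3))
        p = model.predict_proba(color_features(rgb[:, 0], rgb[:, 1], rgb[:, 2]))
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)
        assert (p >= 0).all()

    def test_matches_independent_penalized_likelihood_solver(self):
        # 3 classes, 60 samples; oracle = direct scipy minimization of
        # mean NLL + (l2/2)*||W||^2 (intercepts unpenalized)
        rng = np.random.default_rng(2)
        colors = [(60, 150, 50), (150, 110, 80), (200, 200, 60)]
        rgb_per_class = [np.clip(rng.normal(c, 12.0, (20, 3)), 0, 255) for c in colors]
        ts = TrainingSet.from_rgb(["a", "b", "c"], rgb_per_class)
        model = train_model(ts, l2_strength=1e-2, seed=0)

        X = (ts.features - model.feature_means) / model.feature_scales
        y = ts.labels
        k, nf = 3, 9

        def objective(theta):
            W = theta[: k * nf].reshape(k, nf)
            b = theta[k * nf :]
            s = X @ W.T + b
            s = s - s.max(axis=1, keepdims=True)
            log_p = s - np.log(np.exp(s).sum(axis=1, keepdims=True))
            nll = -log_p[np.arange(len(y)), y].mean()
            return nll + 0.5 * 1e-2 * (W**2).sum()

        res = minimize(objective, np.zeros(k * (nf + 1)), method="L-BFGS-B",
                       options={"maxiter": 20000, "ftol": 1e-15, "gtol": 1e-12})
        W = res.x[: k * nf].reshape(k, nf)
        b = res.x[k * nf :]
        s = X @ W.T + b
        p_oracle = np.exp(s - s.max(axis=1, keepdims=True))
        p_oracle /= p_oracle.sum(axis=1, keepdims=True)
        p_model = model.predict_proba(ts.features)
        np.testing.assert_allclose(p_model, p_oracle, atol=1e-4)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            TrainingSet(classes=["only"], features=np.zeros((5, 9)), labels=np.zeros(5, int))

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="no samples"):
            TrainingSet(
                classes=["a", "b"], features=np.zeros((5, 9)), labels=np.zeros(5, int)
            )

    def test_six_classes_rejected(self):
        with pytest.raises(ValueError):
            TrainingSet(
                classes=list("abcdef"),
                features=np.zeros((6, 9)),
                labels=np.arange(6),
            )

    def test_duplicating_samples_leaves_classification_invariant(self):
        ts = _separable_training()
        doubled = TrainingSet(
            classes=ts.classes,
            features=np.vstack([ts.features, ts.features]),
            labels=np.concatenate([ts.labels, ts.labels]),
        )
        m1 = train_model(ts, seed=0)
        m2 = train_model(doubled, seed=0)
        rng = np.random.default_rng(3)
        rgb = rng.integers(0, 256, size=(300, 3))
        f = color_features(rgb[:, 0], rgb[:, 1], rgb[:, 2])
        assert (m1.predict(f) == m2.predict(f)).all()

    def test_csv_round_trip(self, tmp_path):
        import pandas as pd

        df = pd.DataFrame(
            {
                "class_label": ["crop"] * 3 + ["soil"] * 3,
                "r": [60, 62, 58, 150, 148, 152],
                "g": [150, 149, 151, 110, 112, 108],
                "b": [50, 52, 48, 80, 78, 82],
            }
        )
        df.to_csv(tmp_path / "s.csv", index=False)
        ts = TrainingSet.from_csv(tmp_path / "s.csv")
        assert ts.classes == ["crop", "soil"]
        assert len(ts.labels) == 6

    def test_model_json_round_trip(self, tmp_path):
        model = train_model(_separable_training(), seed=0, vegetation_classes=["green"])
        model.save(tmp_path / "m.json")
        back = CoverageModel.load(tmp_path / "m.json")
        rng = np.random.default_rng(4)
        rgb = rng.integers(0, 256, size=(100, 3))
        f = color_features(rgb[:, 0], rgb[:, 1], rgb[:, 2])
        np.testing.assert_allclose(back.predict_proba(f), model.predict_proba(f), atol=1e-12)
        assert back.vegetation_classes == ["green"]


def _uniform_image(rgb, n=20):
    grid = GeoGrid(0.0, n * 0.1, 0.1, 0.1, n, n, 32654)
    r = np.full(grid.shape, rgb[0], np.uint8)
    g = np.full(grid.shape, rgb[1], np.uint8)
    b = np.full(grid.shape, rgb[2], np.uint8)
    return OrthoImage(grid=grid, red=r, green=g, blue=b)


class TestClassifyPixels:
    def test_uniform_image_single_class(self):
        model = train_model(_separable_training(), seed=0)
        ortho = _uniform_image((60, 150, 50))
        cmap = classify_pixels(model, ortho, np.ones(ortho.grid.shape, bool))
        assert (cmap == model.classes.index("green")).all()

    def test_empty_mask(self):
        model = train_model(_separable_training(), seed=0)
        ortho = _uniform_image((60, 150, 50))
        cmap = classify_pixels(model, ortho, np.zeros(ortho.grid.shape, bool))
        assert (cmap == UNLABELED).all()

    def test_half_and_half_matches_per_pixel_argmax(self):
        model = train_model(_separable_training(), seed=0)
        ortho = _uniform_image((60, 150, 50))
        half = ortho.grid.n_cols // 2
        ortho.red[:, half:] = 150
        ortho.green[:, half:] = 110
        ortho.blue[:, half:] = 80
        mask = np.ones(ortho.grid.shape, bool)
        cmap = classify_pixels(model, ortho, mask)
        # brute force from the stored weights
        f = color_features(
            ortho.red.astype(float), ortho.green.astype(float), ortho.blue.astype(float)
        )
        Xs = (f - model.feature_means) / model.feature_scales
        scores = Xs @ model.weights.T + model.intercepts
        np.testing.assert_array_equal(cmap, np.argmax(scores, axis=-1))

    def test_invalid_pixels_unlabeled(self):
        model = train_model(_separable_training(), seed=0)
        ortho = _uniform_image((60, 150, 50))
        ortho.valid[0, :] = False
        cmap = classify_pixels(model, ortho, np.ones(ortho.grid.shape, bool))
        assert (cmap[0, :] == UNLABELED).all()
        assert (cmap[1:, :] != UNLABELED).all()


class TestClassFractions:
    def test_counting(self):
        cmap = np.full(100, UNLABELED)
        cmap[:40] = 0
        cmap[40:100] = 1
        fr, cov = class_fractions(cmap, ["veg", "soil"], ["veg"])
        assert fr == {"veg": 0.4, "soil": 0.6}
        assert cov == pytest.approx(0.4)

    def test_all_vegetation(self):
        cmap = np.zeros(50, int)
        _, cov = class_fractions(cmap, ["veg", "soil"], ["veg"])
        assert cov == 1.0

    def test_two_vegetation_classes_add(self):
        cmap = np.concatenate([np.zeros(10, int), np.ones(30, int), np.full(60, 2)])
        fr, cov = class_fractions(cmap, ["petals", "leaves", "soil"], ["petals", "leaves"])
        assert cov == pytest.approx(0.4)
        assert sum(fr.values()) == pytest.approx(1.0)

    def test_zero_labeled_pixels(self):
        with pytest.raises(ValueError, match="labeled"):
            class_fractions(np.full(10, UNLABELED), ["a", "b"], [])
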