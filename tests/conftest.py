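import numpy as np
import pytest
from dataclasses import replace

from hypothesis import settings

settings.register_profile("default", derandomize=True)
settings.load_profile("default")

from plotpheno import (
    FieldSpec,
    TrainingSet,
    make_field,
    make_training_samples,
    train_model,
)
from plotpheno.synthetic import RidgeSpec


@pytest.fixture(scope="session")
def flat_spec() -> FieldSpec:
    return FieldSpec(seed=17)


@pytest.fixture(scope="session")
def ridged_spec() -> FieldSpec:
    # crest-line base planes assume no ground slope across the ridges
    return FieldSpec(seed=17, ground_b=0.0, ridges=RidgeSpec())


@pytest.fixture(scope="session")
def flat_field(flat_spec):
    return make_field(flat_spec)


@pytest.fixture(scope="session")
def ridged_field(ridged_spec):
    return make_field(ridged_spec)


@pytest.fixture(scope="session")
def bare_ridged_field(ridged_spec):
    return make_field(replace(ridged_spec, cover_fraction=0.0))


@pytest.fixture(scope="session")
def coverage_model(flat_spec):
    df = make_training_samples(flat_spec, n_per_class=200)
    classes = list(dict.fromkeys(df.class_label))
    rgb_per_class = [
        df[df.class_label == c][["r", "g", "b"]].to_numpy(float) for c in classes
    ]
    training = TrainingSet.from_rgb(classes, rgb_per_class)
    return train_model(training, seed=0, vegetation_classes=["crop"])


def _point_in_ring(x: float, y: float, ring) -> bool:
    """Even-odd ray casting with an explicit on-segment check (boundary = inside)."""
    n = len(ring)
    inside = False
    for i in range(n):
        x1, y1 = ring[i]
        x2, y2 = ring[(i + 1) % n]
        # on-segment test
        cross = (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1)
        if abs(cross) < 1e-12 and min(x1, x2) - 1e-12 <= x <= max(x1, x2) + 1e-12 and min(
            y1, y2
        ) - 1e-12 <= y <= max(y1, y2) + 1e-12:
            return True
        if (y1 > y) != (y2 > y):
            x_cross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < x_cross:
                inside = not inside
    return inside


def brute_force_center_in_polygon(grid, ring) -> np.ndarray:
    """O(pixels * vertices) center-in-polygon evaluation, hand-rolled."""
    mask = np.zeros(grid.shape, dtype=bool)
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            x = grid.origin_x + (c + 0.5) * grid.pixel_size_x
            y = grid.origin_y - (r + 0.5) * grid.pixel_size_y
            mask[r, c] = _point_in_ring(x, y, ring)
    return mask
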