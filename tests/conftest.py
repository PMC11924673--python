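import numpy as np
import pandas as pd
import pytest

from t1tex.synthetic import SyntheticCase, SyntheticConfig, generate_case


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """Reduced-geometry generator config for fast tests."""
    return SyntheticConfig(
        grid_size=96,
        pixel_spacing_mm=1.0,
        endo_radius_mm=12.0,
        epi_radius_mm=19.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def default_case() -> SyntheticCase:
    """One full-size LGE+ case (study geometry)."""
    return generate_case(SyntheticConfig(), lge_status=1, seed=20240101)


@pytest.fixture(scope="session")
def small_case(small_config) -> SyntheticCase:
    return generate_case(small_config, lge_status=0, seed=7)


def random_level_image(rng: np.random.Generator, max_side: int = 8, max_ng: int = 4):
    """A random small discretized image with a random (non-empty) mask."""
    rows = int(rng.integers(2, max_side + 1))
    cols = int(rng.integers(2, max_side + 1))
    ng = int(rng.integers(1, max_ng + 1))
    levels = rng.integers(1, ng + 1, size=(rows, cols)).astype(np.int32)
    mask = rng.random((rows, cols)) < 0.8
    if not mask.any():
        mask[rows // 2, cols // 2] = True
    levels = np.where(mask, levels, 0)
    # re-derive ng from what is present so level ng is guaranteed occupied
    return levels, mask


@pytest.fixture(scope="session")
def feature_frame() -> tuple[pd.DataFrame, pd.Series]:
    """Synthetic feature table with one informative column among noise."""
    rng = np.random.default_rng(11)
    n = 120
    y = np.repeat([0, 1], n // 2)
    X = pd.DataFrame(
        rng.standard_normal((n, 12)), columns=[f"noise_{i:02d}" for i in range(12)]
    )
    X["signal"] = y * 2.0 + rng.standard_normal(n) * 0.6
    labels = pd.Series(y, index=X.index)
    return X, labels
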