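import numpy as np
import pytest

from spatrait import Window, PointPattern


@pytest.fixture
def window():
    return Window(0.0, 150.0, 0.0, 150.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def random_pattern(rng, window, n):
    pts = np.column_stack(
        [
            rng.uniform(window.x_min, window.x_max, n),
            rng.uniform(window.y_min, window.y_max, n),
        ]
    )
    return PointPattern(pts, window)


@pytest.fixture
def toy_census():
    """Hand-countable census: sapling-class counts {60, 50, 12} plus adults."""
    import pandas as pd

    rows = []
    rng = np.random.default_rng(7)
    stem = 0
    for sp, n_sap, n_adult in [("A", 60, 55), ("B", 50, 8), ("C", 12, 70)]:
        for _ in range(n_sap):
            stem += 1
            rows.append((stem, sp, rng.uniform(0, 100), rng.uniform(0, 100), rng.uniform(1.0, 3.0)))
        for _ in range(n_adult):
            stem += 1
            rows.append((stem, sp, rng.uniform(0, 100), rng.uniform(0, 100), rng.uniform(10.5, 40.0)))
    return pd.DataFrame(rows, columns=["stem_id", "species_id", "x", "y", "dbh"])
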