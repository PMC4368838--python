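import numpy as np
import pytest

import ivusecho as iv


@pytest.fixture(scope="session")
def disc_pullback():
    """High-contrast phantom with calcified arc + struts (shared, read-only)."""
    return iv.generate_pullback(iv.PhantomConfig.discrimination_scenario(seed=4))


@pytest.fixture(scope="session")
def disc_result(disc_pullback):
    return iv.analyze_pullback(disc_pullback.frames, disc_pullback.contours)


@pytest.fixture(scope="session")
def default_pullback():
    """Default-condition phantom (full speckle, fresh scaffold)."""
    return iv.generate_pullback(iv.PhantomConfig(seed=1, mw_kda=iv.DEFAULT_MW_SCHEDULE_KDA[0]))


@pytest.fixture(scope="session")
def default_result(default_pullback):
    return iv.analyze_pullback(default_pullback.frames, default_pullback.contours)


def random_star_polygon(rng, center, r_min, r_max, n_vertices=12):
    """Random star-shaped (hence simple) polygon around ``center``."""
    angles = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    radii = rng.uniform(r_min, r_max, n_vertices)
    rows = center[0] + radii * np.sin(angles)
    cols = center[1] + radii * np.cos(angles)
    return np.column_stack([rows, cols])
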