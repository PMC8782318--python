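import numpy as np
import pytest

from nichescreen import GridSpec, Layer
from nichescreen import synth


@pytest.fixture()
def small_grid():
    return GridSpec(n_rows=10, n_cols=10, x_origin=0.0, y_origin=0.0, cell_size=0.1)


@pytest.fixture()
def ramp_layer(small_grid):
    vals = np.arange(100, dtype=float).reshape(10, 10)
    return Layer(name="ramp", grid=small_grid, values=vals)


@pytest.fixture(scope="session")
def small_landscape(tmp_path_factory):
    """A small synthetic collection: 6 layers, 1 driver, 1 decoy, 120 presences."""
    spec = synth.SynthSpec(
        grid=GridSpec(n_rows=50, n_cols=50, x_origin=-10.0, y_origin=40.0, cell_size=0.05),
        n_vars=6,
        driver_effects={"env01": 10.0},
        decoy_correlations={"env02": ("env01", 0.95)},
        noise_spatial_scale=4.0,
        n_presences=120,
        seed=7,
    )
    directory = tmp_path_factory.mktemp("landscape")
    collection = synth.make_landscape(spec, directory)
    occurrences = synth.sample_presences(collection, spec)
    return collection, occurrences, spec


@pytest.fixture(scope="session")
def driver_sim():
    """Presence/background covariates with one informative and one noise variable."""
    from scipy.special import expit

    rng = np.random.default_rng(11)
    n_pool = 20000
    a = rng.uniform(0, 1, n_pool)
    b = rng.uniform(0, 1, n_pool)
    keep = rng.random(n_pool) < expit(8 * (a - 0.5))
    pres = np.column_stack([a[keep][:250], b[keep][:250]])
    bg = np.column_stack([rng.uniform(0, 1, 2000), rng.uniform(0, 1, 2000)])
    return pres, bg
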