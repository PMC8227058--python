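import numpy as np
import pytest

import htpyield as h


@pytest.fixture(scope="session")
def default_layout():
    return h.make_layout(seed=1)


@pytest.fixture(scope="session")
def small_layout():
    """54-plot trial: quick enough for dense-oracle comparisons."""
    cfg = h.DesignConfig(
        n_families=12, n_genitors_sexual=2, n_genitors_apomictic=2,
        n_cultivar_checks=2, n_reps=3, blocks_per_rep=3,
        n_field_rows=6, n_field_cols=9,
    )
    return h.make_layout(cfg, seed=3)


@pytest.fixture(scope="session")
def default_truths(default_layout):
    return h.simulate_trial(default_layout, seed=11)


@pytest.fixture(scope="session")
def default_images(default_truths):
    from htpyield.render import render_trial_images

    return render_trial_images(default_truths, seed=13)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
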