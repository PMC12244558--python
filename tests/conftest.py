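import numpy as np
import pytest

from stacksdm.envgrid import EnvLayer, EnvStack, GridSpec


@pytest.fixture
def grid4x4() -> GridSpec:
    """A 4x4 fully valid grid with unit cells anchored at (0, 4)."""
    return GridSpec(n_rows=4, n_cols=4, cell_size=1.0, origin_x=0.0, origin_y=4.0)


@pytest.fixture
def small_stack(grid4x4: GridSpec) -> EnvStack:
    rng = np.random.default_rng(42)
    a = rng.normal(size=(4, 4))
    return EnvStack(
        [
            EnvLayer("a", grid4x4, a),
            EnvLayer("b", grid4x4, 2.0 * a + rng.normal(scale=0.01, size=(4, 4))),
            EnvLayer("c", grid4x4, rng.normal(size=(4, 4))),
        ]
    )


@pytest.fixture(scope="session")
def recovery_result():
    """End-to-end fit of the default synthetic study (shared; expensive).

    20 virtual species with known Gaussian niches over 15 autocorrelated
    layers on a 100x100 shelf grid, 60 presence-only records each,
    modelled with the CTA-RF-SVM ensemble.
    """
    from stacksdm.pipeline import recovery_study

    return recovery_study(seed=1)
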