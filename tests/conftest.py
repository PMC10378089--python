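import numpy as np
import pytest

from entroage import KineticState, MacroMoments, PhaseGrid, maxwellian


@pytest.fixture
def grid():
    """Default-resolution phase grid (spectral quadrature at theta ~ 1)."""
    return PhaseGrid.regular(nx=33, nxi=32)


@pytest.fixture
def fine_grid():
    """Wide, dense velocity grid for strict (1e-9 level) moment checks."""
    return PhaseGrid.regular(nx=5, nxi=64, xi_max=10.0)


def random_mixture_state(grid, rng, relaxation_time=1.0, max_components=3):
    """Random positive f: a mixture of 1-3 Maxwellians with moderate moments,
    constant in x (spatial structure is irrelevant to velocity-space tests)."""
    n = rng.integers(1, max_components + 1)
    f = np.zeros(len(grid.xi_nodes))
    for _ in range(n):
        f += maxwellian(
            MacroMoments(rng.uniform(0.3, 2.0), rng.uniform(-1.0, 1.0),
                         rng.uniform(0.5, 1.2)),
            grid,
        )
    values = np.tile(f, (len(grid.x_nodes), 1))
    return KineticState(grid, values, relaxation_time)
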