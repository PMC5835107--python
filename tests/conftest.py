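import numpy as np
import pytest

from rugopt import (
    GaussianPeak,
    Landscape,
    LandscapeSpec,
    builtin_model_landscapes,
    parameter_sweep,
)

# base seed for the reduced-scale parameter sweeps; fixed once for the suite
SWEEP_BASE_SEED = 2018

SWEEP_SIGMAS = (50.0, 100.0, 200.0, 400.0)
SWEEP_FRACTIONS = (0.1, 0.2, 0.4, 0.8)


def make_landscape(peaks, name="test", bounds=((0.0, 1000.0), (0.0, 1000.0))):
    return Landscape(
        LandscapeSpec(
            name=name,
            dimensions=len(bounds),
            bounds=bounds,
            peaks=tuple(GaussianPeak(*p) for p in peaks),
        )
    )


@pytest.fixture
def single_peak_landscape():
    """One Gaussian at (500, 500), amplitude 1, spread 150 — a smooth hill."""
    return make_landscape([((500.0, 500.0), 1.0, (150.0, 150.0))], name="single")


@pytest.fixture(scope="session")
def model_trio():
    return builtin_model_landscapes()


@pytest.fixture(scope="session")
def fig4_sweeps(model_trio):
    """Reduced-scale sweep set: 3 algorithms x 3 landscapes, 4x4 lattice,
    n = 50 designs per iteration, 5 iterations, 5 replicates per cell."""
    out = {}
    for ls in model_trio:
        for alg in ("hill_climb", "projection", "cma_es"):
            out[(alg, ls.name)] = parameter_sweep(
                alg,
                ls,
                sigma_values=SWEEP_SIGMAS,
                f_values=SWEEP_FRACTIONS,
                start_coordinates=(300.0, 700.0),
                samples_per_iteration=50,
                iterations=5,
                replicates=5,
                base_seed=SWEEP_BASE_SEED,
            )
    return out
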