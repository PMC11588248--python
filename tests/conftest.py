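import numpy as np
import pytest

from frecl import (BasisSpec, CurveSet, FRDataset, ScenarioConfig, TimeGrid,
                   default_grid, simulate_dataset)


@pytest.fixture(scope="session")
def grid24() -> TimeGrid:
    return default_grid()


@pytest.fixture(scope="session")
def small_basis() -> BasisSpec:
    return BasisSpec(n_basis_t=5, n_basis_s=5)


@pytest.fixture(scope="session")
def k3_dataset():
    """A well-separated K=3 scenario small enough for fast unit tests."""
    return simulate_dataset(ScenarioConfig(m=120, k_true=3, seed=11))


def make_dataset(m: int, p: int, grid: TimeGrid, seed: int = 0) -> FRDataset:
    """Arbitrary smooth dataset with no cluster structure (plumbing tests)."""
    rng = np.random.default_rng(seed)
    t = grid.points
    ids = [f"g{i}" for i in range(m)]

    def curves():
        amp = rng.normal(1.0, 0.3, size=(m, 3))
        phase = rng.uniform(0, 2 * np.pi, size=(m, 3))
        vals = sum(amp[:, [k]] * np.sin(2 * np.pi * t / per + phase[:, [k]])
                   for k, per in enumerate((24.0, 12.0, 48.0)))
        return CurveSet(ids, vals, grid)

    response = curves()
    return FRDataset(response, [curves() for _ in range(p)])
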