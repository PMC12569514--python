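import numpy as np
import pandas as pd
import pytest

from metalspot import SimulationConfig, SpotLayout, simulate_dataset


def small_sim_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Desk-scale generator config: 200 px grid, one element, few genes,
    direct slope (skips the Monte-Carlo slope calibration)."""
    defaults = dict(
        grid_shape=(200, 200),
        n_genes=12,
        n_coupled_genes_per_element=2,
        coupling_target_rho=None,
        coupling_strength=0.6,
        elements=("Cu",),
        region_element_means={
            r: {"Cu": 3.0} for r in ("tumor", "interface", "muscularis", "serosa")
        },
        hotspot_blobs=[("Cu", (60, 60), 15, 4.0)],
        stripe_spec=[(40, 0.5)],
        celltype_element_coupling=[("Macrophage", "Cu", 0.8)],
        tissue_margin_px=10,
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def default_dataset():
    """Full-size generator output (400 px grid, 4 elements, calibrated
    couplings); shared across tests that only read from it."""
    return simulate_dataset(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_dataset(small_sim_config(seed=3))


@pytest.fixture()
def square_lattice():
    """7x7 spot lattice at 100 um pitch."""
    pitch = 100.0
    xs, ys = np.meshgrid(np.arange(7) * pitch, np.arange(7) * pitch)
    table = pd.DataFrame(
        {
            "spot_id": [f"s{i:02d}" for i in range(49)],
            "x_um": xs.ravel(),
            "y_um": ys.ravel(),
        }
    )
    return SpotLayout(table, diameter_um=55.0, pitch_um=pitch)


def gi_star_bruteforce(x: np.ndarray, coords: np.ndarray, radius: float) -> np.ndarray:
    """Independent scalar evaluation of the Gi* formula, used as the oracle.

    Loops over spots and neighbours directly from the definition:
    z_i = (sum_j w_ij x_j - xbar W_i) / (S sqrt((n sum w_ij^2 - W_i^2)/(n-1))).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    xbar = x.mean()
    s = np.sqrt(np.mean((x - xbar) ** 2))
    z = np.zeros(n)
    for i in range(n):
        lag, wi = 0.0, 0
        for j in range(n):
            d = np.hypot(coords[i, 0] - coords[j, 0], coords[i, 1] - coords[j, 1])
            if d <= radius:
                lag += x[j]
                wi += 1
        var_term = (n * wi - wi * wi) / (n - 1)
        denom = s * np.sqrt(var_term) if (s > 0 and var_term > 0) else 0.0
        z[i] = (lag - xbar * wi) / denom if denom > 0 else 0.0
    return z
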