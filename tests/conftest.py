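import numpy as np
import pytest

from spatialcomm.simulate import SimulationSpec, simulate_dataset


@pytest.fixture(scope="session")
def small_sim():
    """Small simulated dataset with planted effects (fast, reused)."""
    spec = SimulationSpec(n_cells=150, n_genes=40, n_types=3, frac_responsive=0.3,
                          effect_size=2.0, noise_sd=0.5, seed=7)
    dataset, truth = simulate_dataset(spec)
    return spec, dataset, truth


@pytest.fixture
def three_cell_fixture():
    """Hand-checkable 3-cell, 2-type spatial arrangement."""
    coords = np.array([[0.0, 0.0], [0.0, 1.0], [0.0, 3.0]])
    labels = np.array(["A", "B", "B"], dtype=object)
    type_order = np.array(["A", "B"], dtype=object)
    return coords, labels, type_order


def brute_force_raw_scores(coords, labels, type_order):
    """Independent O(Z^2 A) neighbor scorer used as an oracle."""
    coords = np.asarray(coords, float)
    z = len(coords)
    dists = np.array([[np.hypot(*(coords[i] - coords[j])) for j in range(z)]
                      for i in range(z)])
    dist0 = min(dists[i, j] for i in range(z) for j in range(z) if i != j)
    raw = np.zeros((z, len(type_order)))
    for c in range(z):
        for b, t in enumerate(type_order):
            for m in range(z):
                if m != c and labels[m] == t:
                    raw[c, b] += np.log10(dists[c, m] / dist0)
    return raw, dist0
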