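import numpy as np
import pandas as pd
import pytest

from mmrcal import synthetic


@pytest.fixture(scope="session")
def small_system():
    """8 states x 10 districts on a 8x10 lattice, modest births."""
    cfg = synthetic.SyntheticConfig(
        n_states=8,
        districts_per_state=10,
        lattice_rows=8,
        lattice_cols=10,
        births_per_district_range=(50_000, 150_000),
        seed=11,
    )
    return cfg, *synthetic.generate_system(cfg)


@pytest.fixture(scope="session")
def lattice_weights():
    """Queen weights on a 5x5 lattice with string ids."""
    from mmrcal import spatial

    edges = synthetic._queen_edges(5, 5)
    ids = [f"u{i:02d}" for i in range(25)]
    return spatial.build_weights(edges=[(ids[i], ids[j]) for i, j in edges])


def brute_force_moran(values: np.ndarray, w_binary: np.ndarray) -> float:
    """Independent O(n^2) double-sum oracle for global Moran's I.

    Row-standardises the binary matrix explicitly and evaluates
    I = (n / S0) * sum_ij w*_ij z_i z_j / sum_i z_i^2 with python loops.
    """
    n = len(values)
    z = values - values.mean()
    w_star = np.zeros_like(w_binary, dtype=float)
    for i in range(n):
        deg = w_binary[i].sum()
        if deg > 0:
            w_star[i] = w_binary[i] / deg
    s0 = w_star.sum()
    num = 0.0
    for i in range(n):
        for j in range(n):
            num += w_star[i, j] * z[i] * z[j]
    return (n / s0) * num / (z @ z).item()


@pytest.fixture(scope="session")
def moran_oracle():
    return brute_force_moran
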