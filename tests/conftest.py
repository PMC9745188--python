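import numpy as np
import pytest

import saspatial as sa


@pytest.fixture
def square6():
    """6x6 square lattice with rook row-standardized weights."""
    spots = sa.gen_lattice(6, 6, "square")
    wm = sa.row_standardize(sa.build_weights(spots, "rook"))
    return spots, wm


@pytest.fixture
def checkerboard6(square6):
    spots, wm = square6
    expr = sa.gen_pattern(spots, sa.PatternSpec("checkerboard", {"low": 0.0, "high": 1.0}))
    return spots, wm, sa.GeneVector("checker", expr.values[0])


@pytest.fixture
def random25():
    """5x5 lattice, random expression and rook weights (raw and standardized)."""
    spots = sa.gen_lattice(5, 5, "square")
    rng = np.random.default_rng(42)
    x = rng.normal(size=25)
    wm_raw = sa.build_weights(spots, "rook")
    return spots, wm_raw, sa.row_standardize(wm_raw), sa.GeneVector("rand", x)


# ---------------------------------------------------------------------------
# Independent brute-force oracles (plain double loops on dense arrays)
# ---------------------------------------------------------------------------

def brute_force_global_moran(x, W_dense):
    """Direct double-summation of the global Moran formula."""
    x = np.asarray(x, float)
    n = x.size
    z = x - x.mean()
    s0 = 0.0
    num = 0.0
    for i in range(n):
        for j in range(n):
            s0 += W_dense[i, j]
            num += W_dense[i, j] * z[i] * z[j]
    return (n / s0) * num / (z @ z)


def brute_force_local_moran(x, W_dense, si_mode="local"):
    """Direct per-spot loop of the local Moran formula."""
    x = np.asarray(x, float)
    n = x.size
    z = x - x.mean()
    out = np.empty(n)
    for i in range(n):
        lag = sum(W_dense[i, j] * z[j] for j in range(n) if j != i)
        if si_mode == "local":
            s2 = sum(z[j] ** 2 for j in range(n) if j != i) / (n - 1)
        else:
            s2 = (z @ z) / n
        out[i] = z[i] / s2 * lag
    return out


def brute_force_gi_star(x, adjacency_dense):
    """Direct per-spot Getis-Ord Gi* z-score with self-included binary
    weights."""
    x = np.asarray(x, float)
    n = x.size
    xbar = x.mean()
    s = np.sqrt((x**2).mean() - xbar**2)
    out = np.empty(n)
    for i in range(n):
        w = [1.0 if (j == i or adjacency_dense[i, j] > 0) else 0.0 for j in range(n)]
        wi = sum(w)
        s1 = sum(v * v for v in w)
        num = sum(w[j] * x[j] for j in range(n)) - xbar * wi
        out[i] = num / (s * np.sqrt((n * s1 - wi**2) / (n - 1)))
    return out
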