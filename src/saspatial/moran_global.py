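"""Global Moran's I per gene: statistic, moments, z-score, p-value and
spatial-pattern classification.

The statistic for one gene with per-spot values X_i, deviations
Z_i = X_i - mean(X), and weights omega_ij is

    I = (n / S0) * sum_ij omega_ij Z_i Z_j / sum_i Z_i^2

with expectation E[I] = -1/(n-1) under the null of no spatial structure.
The variance nu[I] = E[I^2] - E[I]^2 is computed under either the
randomization (permutation-moment) or normality assumption, or estimated
from an explicit permutation distribution. Patterns are classified from
(z, p): clustered (z > 1.65, p < 0.1), dispersed (z < -1.65, p < 0.1),
otherwise random; only clustered genes pass the gate to local analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .errors import ZeroVarianceError
from .st_io import ExpressionMatrix
from .weights import WeightMatrix, check_nonzero

logger = logging.getLogger(__name__)

#: z-score and p-value boundaries separating clustered / random / dispersed
Z_THRESHOLD = 1.65
P_THRESHOLD = 0.1

NULLS = ("randomization", "normality", "permutation")


@dataclass(frozen=True)
class GeneVector:
    """One gene's per-spot expression values and their deviations."""

    gene: str
    x: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))

    @property
    def n(self) -> int:
        return self.x.size

    @property
    def mean(self) -> float:
        return float(self.x.mean())

    @property
    def deviations(self) -> np.ndarray:
        """Z_i = X_i - mean."""
        return self.x - self.x.mean()


@dataclass(frozen=True)
class GlobalMoranStat:
    gene: str
    I: float
    expected_I: float
    variance_I: float
    z: float
    p: float
    pattern: str


def classify_pattern(z: float, p: float) -> str:
    """Classify a gene's spatial pattern from its Moran z-score and p-value:
    clustered / random / dispersed."""
    if not 0 <= p <= 1:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if z > Z_THRESHOLD and p < P_THRESHOLD:
        return "clustered"
    if z < -Z_THRESHOLD and p < P_THRESHOLD:
        return "dispersed"
    return "random"


def global_moran(
    gv: GeneVector,
    wm: WeightMatrix,
    null: str = "randomization",
    n_perm: int = 999,
    seed: int | None = None,
) -> GlobalMoranStat:
    """Compute global Moran's I for one gene with significance under the
    chosen null."""
    if null not in NULLS:
        raise ValueError(f"null must be one of {NULLS}")
    n = gv.n
    if n < 4:
        raise ValueError("global Moran's I needs at least 4 spots")
    if wm.n != n:
        raise ValueError("weight matrix size does not match gene vector")
    check_nonzero(wm)
    z_dev = gv.deviations
    m2_total = float(z_dev @ z_dev)
    if m2_total == 0:
        raise ZeroVarianceError(f"gene {gv.gene!r} is constant across spots")

    W = wm.weights
    S0 = wm.S0
    I = (n / S0) * float(z_dev @ (W @ z_dev)) / m2_total
    EI = -1.0 / (n - 1)

    if null == "permutation":
        rng = np.random.default_rng(seed)
        sims = _permutation_distribution(z_dev, W, S0, n_perm, rng)
        var = float(sims.var(ddof=1))
        sd = np.sqrt(var)
        zscore = (I - float(sims.mean())) / sd if sd > 0 else 0.0
        upper = int((sims >= I).sum())
        lower = int((sims <= I).sum())
        p = min(1.0, 2.0 * (min(upper, lower) + 1) / (n_perm + 1))
    else:
        var = _analytic_variance(z_dev, W, S0, null)
        var = max(var, 0.0)
        zscore = (I - EI) / np.sqrt(var) if var > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(zscore))

    return GlobalMoranStat(
        gene=gv.gene,
        I=I,
        expected_I=EI,
        variance_I=var,
        z=float(zscore),
        p=float(p),
        pattern=classify_pattern(float(zscore), float(p)),
    )


def _analytic_variance(z_dev: np.ndarray, W: sparse.csr_matrix, S0: float, null: str) -> float:
    """Closed-form nu[I] under the randomization or normality assumption."""
    n = z_dev.size
    Wd = W.tocsr()
    sym = Wd + Wd.T
    S1 = 0.5 * float((sym.multiply(sym)).sum())
    row = np.asarray(Wd.sum(axis=1)).ravel()
    col = np.asarray(Wd.sum(axis=0)).ravel()
    S2 = float(((row + col) ** 2).sum())
    EI2_term = 1.0 / (n - 1) ** 2
    if null == "normality":
        return (n * n * S1 - n * S2 + 3 * S0 * S0) / ((n * n - 1) * S0 * S0) - EI2_term
    m2 = float((z_dev**2).sum()) / n
    m4 = float((z_dev**4).sum()) / n
    b2 = m4 / (m2 * m2)
    num = n * ((n * n - 3 * n + 3) * S1 - n * S2 + 3 * S0 * S0) - b2 * (
        (n * n - n) * S1 - 2 * n * S2 + 6 * S0 * S0
    )
    den = (n - 1) * (n - 2) * (n - 3) * S0 * S0
    return num / den - EI2_term


def _permutation_distribution(
    z_dev: np.ndarray, W: sparse.csr_matrix, S0: float, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Moran's I over random relabelings of the values across spots."""
    if n_perm < 9:
        raise ValueError("n_perm must be at least 9")
    n = z_dev.size
    coo = W.tocoo()
    m2_total = float(z_dev @ z_dev)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    zp = z_dev[perms]  # (n_perm, n)
    cross = (zp[:, coo.row] * zp[:, coo.col]) @ coo.data
    return (n / S0) * cross / m2_total


def gene_vectors(expr: ExpressionMatrix, min_spots: int = 10):
    """Yield GeneVector per gene, skipping genes expressed (nonzero) in
    fewer than ``min_spots`` spots — Moran moments are unstable for
    near-empty vectors."""
    for i, gene in enumerate(expr.genes):
        x = expr.values[i]
        n_expressed = int((x != 0).sum())
        if n_expressed < min_spots:
            logger.info("gene skipped (expressed in %d < %d spots): %s", n_expressed, min_spots, gene)
            continue
        yield GeneVector(gene, x)


def global_moran_all(
    expr: ExpressionMatrix,
    wm: WeightMatrix,
    null: str = "randomization",
    n_perm: int = 999,
    seed: int | None = None,
    min_spots: int = 10,
) -> list[GlobalMoranStat]:
    """Global Moran statistics for every (sufficiently expressed) gene."""
    out = []
    for gv in gene_vectors(expr, min_spots=min_spots):
        try:
            out.append(global_moran(gv, wm, null=null, n_perm=n_perm, seed=seed))
        except ZeroVarianceError:
            logger.info("gene skipped (constant): %s", gv.gene)
    return out


def gate_genes(statistics: list[GlobalMoranStat]) -> list[str]:
    """Keep exactly the genes classified clustered; log each aborted gene."""
    survivors = []
    for s in statistics:
        if s.pattern == "clustered":
            survivors.append(s.gene)
        else:
            logger.info("gene aborted: pattern=%s gene=%s z=%.3f p=%.4g", s.pattern, s.gene, s.z, s.p)
    if not survivors:
        logger.warning("no gene passed the clustered-pattern gate")
    return survivors


def moran_table(statistics: list[GlobalMoranStat]) -> pd.DataFrame:
    """Per-gene results table (gene, I, expected_I, variance, z, p, pattern)."""
    return pd.DataFrame(
        [
            {
                "gene": s.gene,
                "moran_I": s.I,
                "expected_I": s.expected_I,
                "variance_I": s.variance_I,
                "z": s.z,
                "p": s.p,
                "pattern": s.pattern,
            }
            for s in statistics
        ]
    )
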