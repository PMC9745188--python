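"""Anselin local Moran's I (LISA) per spot and cluster-outlier typing.

For spot i with deviation Z_i = X_i - mean(X) and spatial lag
lag_i = sum_{j != i} omega_ij (X_j - mean(X)),

    I_i = (Z_i / S_i^2) * lag_i,     S_i^2 = sum_{j != i} Z_j^2 / (n - 1)

A positive I_i at a significant spot means the spot resembles its
neighborhood (H-H when its deviation is positive, L-L when negative); a
negative I_i marks an outlier (H-L or L-H). Significance defaults to a
conditional permutation null — the focal value is held fixed while the
remaining values are shuffled among the neighbors — with an analytic
(total-randomization moment) z-score available for speed.

``si_mode="global"`` switches the scaling denominator to sum(Z^2)/n, the
variant under which the local statistics aggregate exactly to the global
one: sum_i I_i = S0 * I.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import UnknownBarcodeError, ZeroVarianceError
from .moran_global import GeneVector
from .weights import WeightMatrix

logger = logging.getLogger(__name__)

CO_TYPES = ("NS", "HH", "LL", "HL", "LH")
NULLS = ("conditional_permutation", "analytic")


@dataclass(frozen=True)
class LocalMoranField:
    """Per-spot local Moran results for one gene."""

    gene: str
    barcodes: pd.Index
    Ii: np.ndarray
    expected_Ii: np.ndarray
    variance_Ii: np.ndarray
    z: np.ndarray
    p: np.ndarray
    co_type: np.ndarray  # strings from CO_TYPES
    lag: np.ndarray
    s_i_sq: np.ndarray
    alpha: float
    fdr: bool

    @property
    def n(self) -> int:
        return len(self.barcodes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "barcode": self.barcodes,
                "local_I": self.Ii,
                "expected_Ii": self.expected_Ii,
                "variance_Ii": self.variance_Ii,
                "z": self.z,
                "p": self.p,
                "co_type": self.co_type,
            }
        )


def classify_co_type(deviation: float, lag: float, significant: bool) -> str:
    """Assign the cluster-outlier category for one spot.

    H-H: high value in a high neighborhood; L-L: low in low; H-L / L-H:
    spatial outliers. Non-significant spots (and exact zero ties) are NS.
    """
    if not significant:
        return "NS"
    if deviation == 0 or lag == 0:
        logger.info("significant spot with zero deviation or lag; typed NS (tie)")
        return "NS"
    if deviation > 0:
        return "HH" if lag > 0 else "HL"
    return "LL" if lag < 0 else "LH"


def local_moran(
    gv: GeneVector,
    wm: WeightMatrix,
    null: str = "conditional_permutation",
    n_perm: int = 999,
    seed: int | None = None,
    alpha: float = 0.05,
    fdr: bool = False,
    two_tailed: bool = True,
    si_mode: str = "local",
    barcodes: pd.Index | None = None,
) -> LocalMoranField:
    """Compute local Moran's I, significance and CO type for every spot."""
    if null not in NULLS:
        raise ValueError(f"null must be one of {NULLS}")
    if si_mode not in ("local", "global"):
        raise ValueError("si_mode must be 'local' or 'global'")
    n = gv.n
    if wm.n != n:
        raise ValueError("weight matrix size does not match gene vector")
    z_dev = gv.deviations
    ss_total = float((z_dev**2).sum())
    if ss_total == 0:
        raise ZeroVarianceError(f"gene {gv.gene!r} is constant across spots")

    W = wm.weights.tocsr()
    lag = W @ z_dev  # diagonal is zero, so the j != i restriction holds
    if si_mode == "local":
        s_i_sq = (ss_total - z_dev**2) / (n - 1)
    else:
        s_i_sq = np.full(n, ss_total / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        Ii = np.where(s_i_sq > 0, z_dev / s_i_sq * lag, 0.0)

    wi = np.asarray(W.sum(axis=1)).ravel()
    EIi = -wi / (n - 1)

    if null == "analytic":
        var = _analytic_local_variance(z_dev, W, wi)
        var = np.maximum(var, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            zscores = np.where(var > 0, (Ii - EIi) / np.sqrt(var), 0.0)
        p = 2.0 * stats.norm.sf(np.abs(zscores)) if two_tailed else stats.norm.sf(zscores)
    else:
        if n_perm < 99:
            raise ValueError("conditional permutation needs n_perm >= 99")
        rng = np.random.default_rng(seed)
        zscores, p = _conditional_permutation(z_dev, W, s_i_sq, Ii, n_perm, rng, two_tailed)
        var = np.full(n, np.nan)

    p_eff = multipletests(p, method="fdr_bh")[1] if fdr else p
    significant = p_eff < alpha
    co = np.array(
        [classify_co_type(z_dev[i], lag[i], bool(significant[i])) for i in range(n)],
        dtype=object,
    )
    if barcodes is None:
        barcodes = pd.RangeIndex(n).astype(str)
    return LocalMoranField(
        gene=gv.gene,
        barcodes=pd.Index(barcodes),
        Ii=Ii,
        expected_Ii=EIi,
        variance_Ii=var,
        z=zscores,
        p=p_eff,
        co_type=co,
        lag=lag,
        s_i_sq=s_i_sq,
        alpha=alpha,
        fdr=fdr,
    )


def _analytic_local_variance(z_dev: np.ndarray, W, wi: np.ndarray) -> np.ndarray:
    """Total-randomization moments of I_i (Anselin's closed form).

    Derived for the global-denominator scaling; used as a fast approximation
    for the leave-one-out S_i^2 and validated against the permutation null.
    """
    n = z_dev.size
    m2 = float((z_dev**2).sum()) / n
    m4 = float((z_dev**4).sum()) / n
    b2 = m4 / (m2 * m2)
    W2 = W.multiply(W)
    wi2 = np.asarray(W2.sum(axis=1)).ravel()
    two_wikh = wi**2 - wi2
    return (
        wi2 * (n - b2) / (n - 1)
        + two_wikh * (2 * b2 - n) / ((n - 1) * (n - 2))
        - (wi / (n - 1)) ** 2
    )


def _conditional_permutation(
    z_dev: np.ndarray,
    W,
    s_i_sq: np.ndarray,
    Ii_obs: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
    two_tailed: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Conditional permutation null: hold Z_i fixed, shuffle the other
    n-1 values into the neighbor slots.

    A shared (n_perm, kmax) index pool is drawn once, and the non-focal
    values are freshly shuffled for every spot before indexing, so the
    pseudo-p-values are decorrelated across spots while the loop stays
    O(n * n_perm * max_cardinality).
    """
    n = z_dev.size
    card = np.diff(W.indptr)
    kmax = int(card.max()) if n else 0
    # (n_perm, kmax) indices into the n-1 non-focal positions
    perm_ids = np.array([rng.permutation(n - 1)[:kmax] for _ in range(n_perm)])
    zscores = np.zeros(n)
    p = np.ones(n)
    others = np.empty(n - 1)
    for i in range(n):
        k = card[i]
        if k == 0 or s_i_sq[i] == 0:
            continue
        others[:i] = z_dev[:i]
        others[i:] = z_dev[i + 1 :]
        shuffled = others[rng.permutation(n - 1)]
        w_vals = W.data[W.indptr[i] : W.indptr[i + 1]]
        sim_lag = shuffled[perm_ids[:, :k]] @ w_vals
        sims = z_dev[i] / s_i_sq[i] * sim_lag
        mu, sd = float(sims.mean()), float(sims.std(ddof=1))
        zscores[i] = (Ii_obs[i] - mu) / sd if sd > 0 else 0.0
        upper = int((sims >= Ii_obs[i]).sum())
        lower = int((sims <= Ii_obs[i]).sum())
        tail = (min(upper, lower) + 1) / (n_perm + 1)
        p[i] = min(1.0, 2.0 * tail) if two_tailed else tail
    return zscores, p


def co_type_counts(field: LocalMoranField, subset=None) -> dict[str, int]:
    """Tally the five CO types, optionally within a barcode subset."""
    if subset is None:
        mask = np.ones(field.n, dtype=bool)
    else:
        subset = set(subset)
        unknown = subset - set(field.barcodes)
        if unknown:
            raise UnknownBarcodeError(f"barcodes not in field: {sorted(unknown)}")
        mask = field.barcodes.isin(subset)
    counts = {t: 0 for t in CO_TYPES}
    types, freqs = np.unique(field.co_type[mask], return_counts=True)
    counts.update(dict(zip(types, freqs.astype(int).tolist())))
    return counts
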