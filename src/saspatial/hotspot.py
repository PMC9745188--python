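"""Getis-Ord Gi* hot-spot scores and a Wilcoxon rank-sum DEG baseline.

Gi* (self-included) renders a gene's hot and cold spots for map-style
visualization: each spot's z-score compares the weighted local sum
(including the spot itself) with its expectation under spatial randomness,

    Gi* = (sum_j w_ij x_j - Xbar * W_i) /
          (S * sqrt((n * sum_j w_ij^2 - W_i^2) / (n - 1)))

with W_i = sum_j w_ij and S the population standard deviation of x. Bins
follow the conventional 90/95/99% confidence cutoffs (|z| 1.65/1.96/2.58).

The baseline emulates the classical single-cell DEG test: per-gene
Wilcoxon rank-sum between ROI and reference on log-normalized values, a
natural-log fold change of de-logged group means, and the conventional
filters logFC > 0.25, p < 0.05, min.pct > 0.1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .errors import ZeroVarianceError
from .moran_global import GeneVector
from .st_io import ExpressionMatrix
from .weights import WeightMatrix

logger = logging.getLogger(__name__)

#: standard-normal cutoffs for the 90/95/99% confidence bins
BIN_CUTOFFS = (1.65, 1.96, 2.58)
BIN_LABELS = ("cold99", "cold95", "cold90", "ns", "hot90", "hot95", "hot99")


@dataclass(frozen=True)
class HotspotField:
    gene: str
    barcodes: pd.Index
    gi_star_z: np.ndarray
    bin: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"barcode": self.barcodes, "gi_star_z": self.gi_star_z, "bin": self.bin}
        )


@dataclass(frozen=True)
class BaselineDegResult:
    gene: str
    log_fc: float
    p: float
    pct_roi: float
    pct_ref: float
    passes: bool


def _bin_z(z: np.ndarray) -> np.ndarray:
    edges = [-BIN_CUTOFFS[2], -BIN_CUTOFFS[1], -BIN_CUTOFFS[0], BIN_CUTOFFS[0], BIN_CUTOFFS[1], BIN_CUTOFFS[2]]
    idx = np.searchsorted(edges, z, side="right")
    return np.asarray(BIN_LABELS, dtype=object)[idx]


def gi_star(gv: GeneVector, wm: WeightMatrix, barcodes: pd.Index | None = None) -> HotspotField:
    """Getis-Ord Gi* z-score per spot, with the focal spot included.

    The neighborhood is taken from the weight matrix's adjacency as binary
    weights plus a self weight of 1 (the classical Gi* formulation).
    """
    x = gv.x
    n = gv.n
    if wm.n != n:
        raise ValueError("weight matrix size does not match gene vector")
    xbar = x.mean()
    s = np.sqrt((x**2).mean() - xbar**2)
    if s == 0:
        raise ZeroVarianceError(f"gene {gv.gene!r} is constant across spots")
    adj = (wm.weights > 0).astype(float)
    adj = (adj + sparse.eye(n, format="csr")).tocsr()
    wi = np.asarray(adj.sum(axis=1)).ravel()
    s1i = wi  # binary weights: sum of squares equals the count
    num = np.asarray(adj @ x).ravel() - xbar * wi
    den = s * np.sqrt((n * s1i - wi**2) / (n - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(den > 0, num / den, 0.0)
    if barcodes is None:
        barcodes = pd.RangeIndex(n).astype(str)
    return HotspotField(gene=gv.gene, barcodes=pd.Index(barcodes), gi_star_z=z, bin=_bin_z(z))


def wilcoxon_baseline(
    expr: ExpressionMatrix,
    roi: set[str],
    reference: set[str],
    *,
    logfc_threshold: float = 0.25,
    p_threshold: float = 0.05,
    min_pct: float = 0.1,
) -> list[BaselineDegResult]:
    """Classical DEG baseline: Wilcoxon rank-sum per gene, ROI vs reference.

    ``expr`` must be log-normalized; the fold change is
    ln((mean(expm1(x_roi)) + 1) / (mean(expm1(x_ref)) + 1)). Genes detected
    (nonzero) in fewer than ``min_pct`` of spots in both groups are
    filtered before testing; all-zero genes are skipped with a log note.
    """
    if roi & reference:
        raise ValueError("ROI and reference overlap")
    if len(roi) < 3 or len(reference) < 3:
        raise ValueError("both groups need at least 3 spots")
    if not expr.normalized:
        raise ValueError("baseline expects normalized expression")
    roi_mask = expr.spots.isin(roi)
    ref_mask = expr.spots.isin(reference)
    results = []
    for i, gene in enumerate(expr.genes):
        a = expr.values[i, roi_mask]
        b = expr.values[i, ref_mask]
        if not a.any() and not b.any():
            logger.info("baseline skipped all-zero gene: %s", gene)
            continue
        pct_roi = float((a > 0).mean())
        pct_ref = float((b > 0).mean())
        if max(pct_roi, pct_ref) <= min_pct:
            continue
        log_fc = float(np.log((np.expm1(a).mean() + 1) / (np.expm1(b).mean() + 1)))
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        passes = log_fc > logfc_threshold and p < p_threshold
        results.append(
            BaselineDegResult(gene=gene, log_fc=log_fc, p=p, pct_roi=pct_roi,
                              pct_ref=pct_ref, passes=passes)
        )
    return results


@dataclass(frozen=True)
class MethodOverlap:
    """Venn triple between the spatial DEG set and the baseline DEG set."""

    n_both: int
    n_spatial_only: int
    n_baseline_only: int
    both: frozenset
    spatial_only: frozenset
    baseline_only: frozenset


def compare_methods(spatial_degs, baseline_degs) -> MethodOverlap:
    """Summarize the overlap between two DEG sets (same comparison and
    direction)."""
    a, b = set(spatial_degs), set(baseline_degs)
    return MethodOverlap(
        n_both=len(a & b),
        n_spatial_only=len(a - b),
        n_baseline_only=len(b - a),
        both=frozenset(a & b),
        spatial_only=frozenset(a - b),
        baseline_only=frozenset(b - a),
    )
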