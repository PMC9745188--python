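"""Spatial weight matrices for Moran-family statistics.

The weight omega_ij encodes whether (and how strongly) spot j is a
neighbor of spot i. Weights start binary; row standardization divides each
row by its sum so that spatial lags become neighbor means. The default
scheme, a distance band at 1.05x the lattice pitch, reproduces 6-neighbor
adjacency on hex (Visium-like) lattices and rook adjacency on square ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.spatial import cKDTree

from .errors import DegenerateWeightsError
from .st_io import SpotFrame

SCHEMES = ("knn", "distance_band", "rook", "queen")


class IsolatedSpotWarning(UserWarning):
    """Some spots have no neighbors under the chosen scheme."""


@dataclass(frozen=True)
class WeightMatrix:
    """Sparse spatial weights omega_ij >= 0 with zero diagonal.

    ``S0`` is the aggregate of all weights, the normalizing constant of
    global Moran's I. Isolated spots keep an empty row so indices stay
    aligned with the expression matrix.
    """

    weights: sparse.csr_matrix
    scheme: str
    row_standardized: bool = False

    def __post_init__(self) -> None:
        w = self.weights
        if w.shape[0] != w.shape[1]:
            raise ValueError("weight matrix must be square")
        if w.diagonal().any():
            raise ValueError("weight matrix diagonal must be zero")
        if (w.data < 0).any():
            raise ValueError("weights must be non-negative")

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    @property
    def S0(self) -> float:
        return float(self.weights.sum())

    @property
    def cardinalities(self) -> np.ndarray:
        """Number of neighbors per spot."""
        return np.diff(self.weights.indptr)

    @property
    def isolated(self) -> np.ndarray:
        """Indices of spots with no neighbors."""
        return np.flatnonzero(self.cardinalities == 0)


def build_weights(
    spots: SpotFrame, scheme: str = "distance_band", param: float | int | None = None
) -> WeightMatrix:
    """Build binary spatial weights for one section.

    ``param`` is k for ``knn`` and the radius for ``distance_band``; the
    contiguity schemes (``rook``, ``queen``) use array coordinates and take
    no parameter. Without a radius, ``distance_band`` defaults to 1.05x the
    lattice pitch (the minimum nearest-neighbor pixel distance).
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; one of {SCHEMES}")
    n = spots.n
    if n < 2:
        raise ValueError("need at least 2 spots")

    if scheme in ("rook", "queen"):
        rc = spots.array_coords
        dr = np.abs(rc[:, 0][:, None] - rc[:, 0][None, :])
        dc = np.abs(rc[:, 1][:, None] - rc[:, 1][None, :])
        same = spots.table["section_id"].to_numpy()
        same = same[:, None] == same[None, :]
        if scheme == "rook":
            adj = (dr + dc == 1) & same
        else:
            adj = (np.maximum(dr, dc) == 1) & same
        w = sparse.csr_matrix(adj.astype(float))
    else:
        xy = spots.pixel_coords
        tree = cKDTree(xy)
        if scheme == "knn":
            k = int(param) if param is not None else 6
            if k < 1 or k >= n:
                raise ValueError(f"knn k must be in [1, n-1], got {k}")
            _, idx = tree.query(xy, k=k + 1)
            rows = np.repeat(np.arange(n), k)
            cols = idx[:, 1:].ravel()
            w = sparse.csr_matrix((np.ones(n * k), (rows, cols)), shape=(n, n))
        else:
            if param is not None:
                radius = float(param)
            else:
                d, _ = tree.query(xy, k=2)
                radius = 1.05 * float(d[:, 1].min())
            pairs = tree.query_pairs(radius, output_type="ndarray")
            if pairs.size:
                rows = np.concatenate([pairs[:, 0], pairs[:, 1]])
                cols = np.concatenate([pairs[:, 1], pairs[:, 0]])
                w = sparse.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
            else:
                w = sparse.csr_matrix((n, n))

    w.setdiag(0)
    w.eliminate_zeros()
    wm = WeightMatrix(w.tocsr(), scheme=scheme, row_standardized=False)
    if wm.isolated.size:
        warnings.warn(
            f"{wm.isolated.size} spot(s) have no neighbors under scheme "
            f"{scheme!r}; their rows are empty",
            IsolatedSpotWarning,
            stacklevel=2,
        )
    return wm


def row_standardize(wm: WeightMatrix) -> WeightMatrix:
    """Divide each nonempty row by its sum (empty rows stay empty)."""
    w = wm.weights.tocsr(copy=True)
    row_sums = np.asarray(w.sum(axis=1)).ravel()
    scale = np.divide(1.0, row_sums, out=np.zeros_like(row_sums), where=row_sums > 0)
    w = sparse.diags(scale) @ w
    return WeightMatrix(w.tocsr(), scheme=wm.scheme, row_standardized=True)


def check_nonzero(wm: WeightMatrix) -> None:
    """Raise if the weights cannot support a Moran statistic (S0 = 0)."""
    if wm.S0 == 0:
        raise DegenerateWeightsError("aggregate weight S0 is zero")


def weights_to_triplets(wm: WeightMatrix, barcodes: pd.Index) -> pd.DataFrame:
    """Export weights as an (origin, neighbor, weight) triplet table."""
    coo = wm.weights.tocoo()
    return pd.DataFrame(
        {
            "origin": barcodes[coo.row],
            "neighbor": barcodes[coo.col],
            "weight": coo.data,
        }
    )
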