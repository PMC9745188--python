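"""Reading, writing and normalizing spatial transcriptomics inputs.

Two on-disk dialects are supported:

* a Visium-style directory: gene x spot counts in MatrixMarket
  (``matrix.mtx``) with ``barcodes.tsv`` / ``features.tsv`` and a
  ``tissue_positions.csv`` carrying array (lattice) and pixel coordinates;
* a flat CSV pair: a long table of (barcode, gene, expression) plus a
  (barcode, x, y) coordinate table.

Both are normalized into the same in-memory pair: a :class:`SpotFrame`
describing the spots and an :class:`ExpressionMatrix` aligned to it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .errors import (
    AlignmentError,
    DuplicateEntryError,
    MissingComponentError,
    OrphanBarcodeError,
    ZeroDepthError,
)

logger = logging.getLogger(__name__)

#: file names expected inside a Visium-style directory
VISIUM_MATRIX = "matrix.mtx"
VISIUM_BARCODES = "barcodes.tsv"
VISIUM_FEATURES = "features.tsv"
VISIUM_POSITIONS = "tissue_positions.csv"

_POSITION_COLUMNS = [
    "barcode",
    "in_tissue",
    "array_row",
    "array_col",
    "pxl_col_in_fullres",
    "pxl_row_in_fullres",
]


@dataclass(frozen=True)
class SpotFrame:
    """Per-spot metadata for one tissue section.

    ``table`` is indexed by barcode and carries ``array_row``, ``array_col``
    (integer lattice coordinates), ``px_x``, ``px_y`` (real pixel
    coordinates, used for distances and plotting), ``section_id`` and
    ``in_tissue``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"array_row", "array_col", "px_x", "px_y", "section_id", "in_tissue"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"SpotFrame table missing columns: {sorted(missing)}")
        if self.table.index.duplicated().any():
            dupes = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate barcodes in SpotFrame: {dupes}")
        rc = self.table[["section_id", "array_row", "array_col"]]
        if rc.duplicated().any():
            raise ValueError("duplicate (array_row, array_col) within a section")

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def barcodes(self) -> pd.Index:
        return self.table.index

    @property
    def pixel_coords(self) -> np.ndarray:
        """(n, 2) array of (px_x, px_y)."""
        return self.table[["px_x", "px_y"]].to_numpy(float)

    @property
    def array_coords(self) -> np.ndarray:
        """(n, 2) array of integer (array_row, array_col)."""
        return self.table[["array_row", "array_col"]].to_numpy(int)

    def subset(self, barcodes) -> "SpotFrame":
        return SpotFrame(self.table.loc[list(barcodes)])


@dataclass
class ExpressionMatrix:
    """A dense gene x spot expression matrix aligned to a SpotFrame.

    ``normalized`` is False for raw counts (required non-negative) and True
    once values have been depth-scaled/log-transformed or were provided
    pre-standardized.
    """

    genes: pd.Index
    spots: pd.Index
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.genes = pd.Index(self.genes)
        self.spots = pd.Index(self.spots)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.spots)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.spots)} spots"
            )
        if self.genes.duplicated().any():
            raise ValueError("gene names must be unique")
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains NaN")
        if not self.normalized and (self.values < 0).any():
            raise ValueError("raw counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_spots(self) -> int:
        return len(self.spots)

    def gene(self, name: str) -> np.ndarray:
        """Per-spot expression vector for one gene."""
        i = self.genes.get_loc(name)
        return self.values[i]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.spots)


# ---------------------------------------------------------------------------
# Visium-style directory dialect
# ---------------------------------------------------------------------------

def read_visium(directory, *, in_tissue_only: bool = True) -> tuple[SpotFrame, ExpressionMatrix]:
    """Read a Visium-style directory into (SpotFrame, ExpressionMatrix).

    Expects ``matrix.mtx`` (genes x spots, column order matching
    ``barcodes.tsv``), ``features.tsv`` and ``tissue_positions.csv``.
    Spots flagged ``in_tissue == 0`` are dropped unless ``in_tissue_only``
    is False; matrix columns are re-aligned to the returned SpotFrame.
    """
    directory = Path(directory)
    paths = {}
    for name in (VISIUM_MATRIX, VISIUM_BARCODES, VISIUM_FEATURES, VISIUM_POSITIONS):
        p = directory / name
        if not p.exists():
            raise MissingComponentError(f"missing {name} in {directory}")
        paths[name] = p

    raw = spio.mmread(paths[VISIUM_MATRIX])
    matrix = np.asarray(raw.todense() if sparse.issparse(raw) else raw, dtype=float)
    barcodes = pd.read_csv(paths[VISIUM_BARCODES], sep="\t", header=None)[0].astype(str)
    features = pd.read_csv(paths[VISIUM_FEATURES], sep="\t", header=None)[0].astype(str)
    positions = pd.read_csv(paths[VISIUM_POSITIONS])
    missing_cols = set(_POSITION_COLUMNS) - set(positions.columns)
    if missing_cols:
        raise MissingComponentError(
            f"tissue_positions.csv missing columns: {sorted(missing_cols)}"
        )

    if matrix.shape != (len(features), len(barcodes)):
        raise AlignmentError(
            f"matrix shape {matrix.shape} does not match features x barcodes "
            f"({len(features)}, {len(barcodes)})"
        )
    pos_barcodes = positions["barcode"].astype(str)
    if set(barcodes) != set(pos_barcodes):
        extra = sorted(set(barcodes) ^ set(pos_barcodes))
        raise AlignmentError(f"barcode mismatch between matrix and positions: {extra[:10]}")

    positions = positions.set_index(pos_barcodes).loc[barcodes]
    keep = positions["in_tissue"].astype(bool) if in_tissue_only else pd.Series(
        True, index=positions.index
    )
    positions = positions[keep.to_numpy()]
    matrix = matrix[:, keep.to_numpy()]

    table = pd.DataFrame(
        {
            "array_row": positions["array_row"].astype(int),
            "array_col": positions["array_col"].astype(int),
            "px_x": positions["pxl_col_in_fullres"].astype(float),
            "px_y": positions["pxl_row_in_fullres"].astype(float),
            "section_id": positions.get("section_id", directory.name),
            "in_tissue": positions["in_tissue"].astype(bool),
        },
        index=positions.index.rename("barcode"),
    )
    spots = SpotFrame(table)
    expr = ExpressionMatrix(features, spots.barcodes, matrix, normalized=False)
    return spots, expr


def write_visium(directory, spots: SpotFrame, expr: ExpressionMatrix) -> Path:
    """Write (SpotFrame, ExpressionMatrix) in the Visium-style layout."""
    if not expr.spots.equals(spots.barcodes):
        raise AlignmentError("expression spots do not match SpotFrame barcodes")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(directory / VISIUM_MATRIX), sparse.coo_matrix(expr.values))
    pd.Series(expr.spots).to_csv(directory / VISIUM_BARCODES, sep="\t", index=False, header=False)
    pd.Series(expr.genes).to_csv(directory / VISIUM_FEATURES, sep="\t", index=False, header=False)
    positions = pd.DataFrame(
        {
            "barcode": spots.barcodes,
            "in_tissue": spots.table["in_tissue"].astype(int).to_numpy(),
            "array_row": spots.table["array_row"].to_numpy(),
            "array_col": spots.table["array_col"].to_numpy(),
            "pxl_col_in_fullres": spots.table["px_x"].to_numpy(),
            "pxl_row_in_fullres": spots.table["px_y"].to_numpy(),
            "section_id": spots.table["section_id"].to_numpy(),
        }
    )
    positions.to_csv(directory / VISIUM_POSITIONS, index=False)
    return directory


# ---------------------------------------------------------------------------
# Flat CSV dialect (long expression table + coordinate table)
# ---------------------------------------------------------------------------

def read_flat_csv(
    expr_csv, coord_csv, *, normalized: bool = True, section_id: str | None = None
) -> tuple[SpotFrame, ExpressionMatrix]:
    """Read the flat dialect: a long (barcode, gene, value) CSV plus a
    (barcode, x, y) CSV.

    Missing (barcode, gene) pairs are filled with 0. The expression values
    are treated as already standardized (``normalized=True``) by default;
    pass ``normalized=False`` for raw counts. Lattice coordinates are
    derived as dense ranks of the unique x/y values.
    """
    expr_df = pd.read_csv(expr_csv)
    coord_df = pd.read_csv(coord_csv)
    if expr_df.shape[1] < 3:
        raise ValueError("expression CSV needs (barcode, gene, value) columns")
    if coord_df.shape[1] < 3:
        raise ValueError("coordinate CSV needs (barcode, x, y) columns")
    expr_df = expr_df.iloc[:, :3]
    expr_df.columns = ["barcode", "gene", "value"]
    expr_df["barcode"] = expr_df["barcode"].astype(str)
    coord_df = coord_df.iloc[:, :3]
    coord_df.columns = ["barcode", "x", "y"]
    coord_df["barcode"] = coord_df["barcode"].astype(str)

    dup = expr_df.duplicated(subset=["barcode", "gene"])
    if dup.any():
        pairs = expr_df.loc[dup, ["barcode", "gene"]].drop_duplicates()
        raise DuplicateEntryError(
            f"duplicate (barcode, gene) rows: {pairs.to_records(index=False).tolist()[:10]}"
        )
    orphans = sorted(set(expr_df["barcode"]) - set(coord_df["barcode"]))
    if orphans:
        raise OrphanBarcodeError(f"barcodes missing from coordinates: {orphans}")

    coord_df = coord_df.set_index("barcode")
    wide = (
        expr_df.pivot(index="gene", columns="barcode", values="value")
        .reindex(columns=coord_df.index)
        .fillna(0.0)
    )
    table = pd.DataFrame(
        {
            "array_row": _dense_rank(coord_df["y"].to_numpy()),
            "array_col": _dense_rank(coord_df["x"].to_numpy()),
            "px_x": coord_df["x"].astype(float),
            "px_y": coord_df["y"].astype(float),
            "section_id": section_id or "flat",
            "in_tissue": True,
        },
        index=coord_df.index.rename("barcode"),
    )
    spots = SpotFrame(table)
    expr = ExpressionMatrix(wide.index, spots.barcodes, wide.to_numpy(), normalized=normalized)
    return spots, expr


def write_flat_csv(expr_csv, coord_csv, spots: SpotFrame, expr: ExpressionMatrix) -> None:
    """Write the flat dialect. Zero entries are omitted from the long table
    (they are restored as 0 on read)."""
    if not expr.spots.equals(spots.barcodes):
        raise AlignmentError("expression spots do not match SpotFrame barcodes")
    long = (
        expr.to_frame()
        .rename_axis(index="gene", columns="barcode")
        .stack()
        .rename("value")
        .reset_index()[["barcode", "gene", "value"]]
    )
    long = long[long["value"] != 0]
    long.to_csv(expr_csv, index=False)
    coords = pd.DataFrame(
        {"barcode": spots.barcodes, "x": spots.table["px_x"].to_numpy(),
         "y": spots.table["px_y"].to_numpy()}
    )
    coords.to_csv(coord_csv, index=False)


def _dense_rank(values: np.ndarray) -> np.ndarray:
    _, inv = np.unique(np.asarray(values), return_inverse=True)
    return inv.astype(int)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize_expression(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Depth-normalize raw counts: scale each spot to the median total count,
    then apply log1p.

    Moran-family statistics center the data internally, so any monotone
    per-spot normalization is adequate; this median-depth log scheme mirrors
    the common log-normalization used for UMI counts.
    """
    if expr.normalized:
        raise ValueError("expression matrix is already normalized")
    totals = expr.values.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        names = expr.spots[zero].tolist()
        raise ZeroDepthError(f"spots with zero total count: {names}")
    scaled = expr.values / totals * np.median(totals)
    return ExpressionMatrix(expr.genes, expr.spots, np.log1p(scaled), normalized=True)
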