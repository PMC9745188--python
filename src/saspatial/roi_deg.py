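"""Region-of-interest definition and spatial DEG testing.

An ROI (a barcode list or a polygon over pixel coordinates) is compared
against a reference region by counting H-H (up-regulation) or L-L
(down-regulation) spots from each gene's local Moran field and testing the
2x2 contingency table with Pearson's chi-squared (1 df, no continuity
correction by default). Genes are ranked by p-value, ties broken by the
absolute rate difference; the rate difference itself (ROI minus reference
H-H/L-L proportion) is the effect size carried into bubble-plot exports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import Point, Polygon
from shapely.prepared import prep
from statsmodels.stats.multitest import multipletests

from .errors import EmptyRoiError, UnknownBarcodeError
from .moran_local import LocalMoranField, co_type_counts
from .st_io import SpotFrame

logger = logging.getLogger(__name__)

DIRECTIONS = {"up": "HH", "down": "LL"}


@dataclass(frozen=True)
class RoiDefinition:
    """A named region of interest: an explicit barcode list or a polygon in
    pixel coordinates (boundary counts as inside)."""

    name: str
    section_id: str = ""
    mode: str = "barcode_list"
    barcodes: tuple = ()
    polygon: tuple = ()

    def __post_init__(self) -> None:
        if self.mode not in ("barcode_list", "polygon"):
            raise ValueError("mode must be 'barcode_list' or 'polygon'")
        if self.mode == "barcode_list" and not self.barcodes:
            raise ValueError(f"ROI {self.name!r}: barcode_list mode needs barcodes")
        if self.mode == "polygon" and len(self.polygon) < 3:
            raise ValueError(f"ROI {self.name!r}: polygon needs >= 3 vertices")


@dataclass(frozen=True)
class DegTestResult:
    """Chi-squared comparison of target-type spot counts between an ROI and
    a reference region for one gene.

    ``table`` rows are (ROI, reference); columns are (target CO type,
    other). ``rate_difference`` = ROI target rate - reference target rate.
    """

    gene: str
    direction: str
    table: np.ndarray
    chi2: float
    p: float
    rate_roi: float
    rate_ref: float
    rate_difference: float
    p_adjusted: float | None = None
    flags: tuple = ()


def resolve_roi(roi: RoiDefinition, spots: SpotFrame) -> set[str]:
    """Resolve an ROI definition to the set of spot barcodes it contains."""
    if roi.mode == "barcode_list":
        requested = set(map(str, roi.barcodes))
        unknown = requested - set(spots.barcodes)
        if unknown:
            raise UnknownBarcodeError(
                f"ROI {roi.name!r}: barcodes not in section: {sorted(unknown)}"
            )
        resolved = requested
    else:
        poly = Polygon(roi.polygon)
        if not poly.is_valid:
            raise ValueError(f"ROI {roi.name!r}: polygon is not simple/valid")
        prepared = prep(poly)
        xy = spots.pixel_coords
        inside = [prepared.intersects(Point(x, y)) for x, y in xy]
        resolved = set(spots.barcodes[np.asarray(inside)])
    if not resolved:
        raise EmptyRoiError(f"ROI {roi.name!r} resolves to no spots")
    return resolved


def deg_chi2(
    field: LocalMoranField,
    roi: set[str],
    reference: set[str],
    direction: str = "up",
    *,
    reference_field: LocalMoranField | None = None,
    yates: bool = False,
) -> DegTestResult:
    """Pearson chi-squared test of H-H (up) or L-L (down) spot proportions,
    ROI versus reference.

    ``reference_field`` supports cross-section comparisons: CO typing is
    always within-section, only the counts are compared.
    """
    if direction not in DIRECTIONS:
        raise ValueError("direction must be 'up' or 'down'")
    ref_field = reference_field if reference_field is not None else field
    if reference_field is None and roi & reference:
        raise ValueError("ROI and reference overlap")
    if not roi or not reference:
        raise ValueError("ROI and reference must both be non-empty")
    target = DIRECTIONS[direction]

    roi_counts = co_type_counts(field, roi)
    ref_counts = co_type_counts(ref_field, reference)
    t_roi, t_ref = roi_counts[target], ref_counts[target]
    n_roi, n_ref = len(roi), len(reference)
    table = np.array([[t_roi, n_roi - t_roi], [t_ref, n_ref - t_ref]])

    rate_roi, rate_ref = t_roi / n_roi, t_ref / n_ref
    flags = []
    if t_roi == 0 and t_ref == 0:
        flags.append("untestable_zero_target")
        chi2, p = 0.0, 1.0
    else:
        chi2, p, _, expected = stats.chi2_contingency(table, correction=yates)
        if (expected < 1).any():
            flags.append("low_expectation")
    return DegTestResult(
        gene=field.gene,
        direction=direction,
        table=table,
        chi2=float(chi2),
        p=float(p),
        rate_roi=rate_roi,
        rate_ref=rate_ref,
        rate_difference=rate_roi - rate_ref,
        flags=tuple(flags),
    )


def rank_degs(
    results: list[DegTestResult], top_n: int = 20, alpha: float = 0.05, use_adjusted: bool = False
) -> list[str]:
    """Rank significant DEGs: ascending p, ties by descending
    |rate difference|, then gene name; truncate to ``top_n``."""
    def pval(r: DegTestResult) -> float:
        return r.p_adjusted if use_adjusted and r.p_adjusted is not None else r.p

    significant = [r for r in results if pval(r) < alpha]
    ordered = sorted(significant, key=lambda r: (pval(r), -abs(r.rate_difference), r.gene))
    return [r.gene for r in ordered[:top_n]]


def roi_ratio(field: LocalMoranField, roi: set[str]) -> float:
    """H-H spot count inside the ROI divided by the section's total spots."""
    return co_type_counts(field, roi)["HH"] / field.n


def region_specificity(
    field: LocalMoranField, regions: dict[str, set[str]], threshold: float = 0.5
) -> pd.DataFrame:
    """Per-region share of a gene's H-H spots.

    ``regions`` must be disjoint and cover all spots; shares sum to 1 when
    the gene has any H-H spot, otherwise they are NaN and flagged. A region
    whose share exceeds ``threshold`` is marked region-specific.
    """
    all_assigned: list[str] = []
    for bcs in regions.values():
        all_assigned.extend(bcs)
    if len(all_assigned) != len(set(all_assigned)):
        raise ValueError("regions must be disjoint")
    if set(all_assigned) != set(field.barcodes):
        raise ValueError("regions must cover all spots exactly")
    hh_per_region = {name: co_type_counts(field, bcs)["HH"] for name, bcs in regions.items()}
    total = sum(hh_per_region.values())
    rows = []
    for name, hh in hh_per_region.items():
        share = hh / total if total > 0 else float("nan")
        rows.append(
            {"region": name, "hh_count": hh, "share": share,
             "specific": bool(total > 0 and share > threshold)}
        )
    if total == 0:
        logger.info("gene %s has no H-H spots; specificity undefined", field.gene)
    return pd.DataFrame(rows)


def multiple_testing_adjust(
    results: list[DegTestResult], method: str = "fdr_bh"
) -> list[DegTestResult]:
    """Attach multiplicity-adjusted p-values (Benjamini-Hochberg default)."""
    if not results:
        return []
    adjusted = multipletests([r.p for r in results], method=method)[1]
    return [replace(r, p_adjusted=float(a)) for r, a in zip(results, adjusted)]


_DEG_COLUMNS = [
    "gene", "direction", "target_roi", "other_roi", "target_ref", "other_ref",
    "chi2", "p", "p_adjusted", "rate_roi", "rate_ref", "rate_difference", "flags",
]


def deg_table(results: list[DegTestResult]) -> pd.DataFrame:
    """Comparison results table for CSV export."""
    if not results:
        return pd.DataFrame(columns=_DEG_COLUMNS)
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "direction": r.direction,
                "target_roi": int(r.table[0, 0]),
                "other_roi": int(r.table[0, 1]),
                "target_ref": int(r.table[1, 0]),
                "other_ref": int(r.table[1, 1]),
                "chi2": r.chi2,
                "p": r.p,
                "p_adjusted": r.p_adjusted,
                "rate_roi": r.rate_roi,
                "rate_ref": r.rate_ref,
                "rate_difference": r.rate_difference,
                "flags": ";".join(r.flags),
            }
            for r in results
        ]
    )
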