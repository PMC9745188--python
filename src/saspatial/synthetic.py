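"""Synthetic spot lattices and expression patterns with known spatial
structure.

Every generator is a pure function of (lattice, spec, seed), so fixtures are
reproducible bit-for-bit and every downstream stage can be tested without
downloading any real section. Pattern kinds emulate the regimes the method
distinguishes: checkerboard (perfectly dispersed), iid noise (random),
smooth bumps / rings / layers (clustered), and ROI-enriched genes for
differential-expression power studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .st_io import ExpressionMatrix, SpotFrame

PATTERN_KINDS = (
    "checkerboard",
    "csr_noise",
    "gaussian_bump",
    "two_block",
    "ring",
    "roi_enriched",
    "layered",
)

#: vertical pitch factor between hex rows (equilateral triangle height)
_HEX_ROW_PITCH = np.sqrt(3.0) / 2.0


@dataclass(frozen=True)
class PatternSpec:
    """Specification of one synthetic single-gene expression pattern.

    ``params`` are kind-specific: e.g. ``{"low": 0, "high": 1}`` for a
    checkerboard, ``{"sigma": 5.0, "amplitude": 1.0}`` for a Gaussian bump,
    ``{"baseline": 1.0, "effect": 3.0, "barcodes": [...]}`` for an
    ROI-enriched gene.
    """

    kind: str
    params: dict = dc_field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in PATTERN_KINDS:
            raise ValueError(f"unknown pattern kind {self.kind!r}; one of {PATTERN_KINDS}")
        for key in ("effect", "sd", "noise_sd"):
            if self.params.get(key, 0) < 0:
                raise ValueError(f"{key} must be non-negative")


def gen_lattice(
    n_rows: int,
    n_cols: int,
    geometry: str = "square",
    *,
    pitch: float = 1.0,
    section_id: str = "S1",
) -> SpotFrame:
    """Generate an ``n_rows x n_cols`` spot lattice.

    ``square`` places spots on a unit grid; ``hex`` offsets every other row
    by half a pitch horizontally and compresses row spacing to the
    equilateral-triangle height, reproducing the Visium 6-neighbor layout.
    """
    if n_rows < 2 or n_cols < 2:
        raise ValueError("lattice needs n_rows >= 2 and n_cols >= 2")
    if geometry not in ("square", "hex"):
        raise ValueError(f"geometry must be 'square' or 'hex', got {geometry!r}")
    rows, cols = np.divmod(np.arange(n_rows * n_cols), n_cols)
    if geometry == "square":
        px_x = cols * pitch
        px_y = rows * pitch
    else:
        px_x = (cols + 0.5 * (rows % 2)) * pitch
        px_y = rows * pitch * _HEX_ROW_PITCH
    barcodes = [f"{section_id}-r{r}c{c}" for r, c in zip(rows, cols)]
    table = pd.DataFrame(
        {
            "array_row": rows,
            "array_col": cols,
            "px_x": px_x.astype(float),
            "px_y": px_y.astype(float),
            "section_id": section_id,
            "in_tissue": True,
        },
        index=pd.Index(barcodes, name="barcode"),
    )
    return SpotFrame(table)


def gen_pattern(spots: SpotFrame, spec: PatternSpec, gene: str = "gene") -> ExpressionMatrix:
    """Generate a one-gene expression field on ``spots`` from ``spec``."""
    rng = np.random.default_rng(spec.seed)
    p = spec.params
    rows = spots.table["array_row"].to_numpy()
    cols = spots.table["array_col"].to_numpy()
    xy = spots.pixel_coords

    if spec.kind == "checkerboard":
        low, high = p.get("low", 0.0), p.get("high", 1.0)
        values = np.where((rows + cols) % 2 == 0, low, high).astype(float)
    elif spec.kind == "csr_noise":
        values = rng.normal(p.get("mean", 0.0), p.get("sd", 1.0), spots.n)
    elif spec.kind == "gaussian_bump":
        center = np.asarray(p.get("center", xy.mean(axis=0)), float)
        sigma = float(p.get("sigma", 3.0))
        d2 = ((xy - center) ** 2).sum(axis=1)
        values = p.get("baseline", 0.0) + p.get("amplitude", 1.0) * np.exp(-d2 / (2 * sigma**2))
    elif spec.kind == "two_block":
        split = p.get("split", cols.max() / 2)
        values = np.where(cols <= split, p.get("low", 0.0), p.get("high", 1.0)).astype(float)
    elif spec.kind == "ring":
        center = np.asarray(p.get("center", xy.mean(axis=0)), float)
        radius, width = float(p.get("radius", 3.0)), float(p.get("width", 1.0))
        d = np.sqrt(((xy - center) ** 2).sum(axis=1))
        values = np.where(
            np.abs(d - radius) <= width, p.get("height", 1.0), p.get("baseline", 0.0)
        ).astype(float)
    elif spec.kind == "roi_enriched":
        inside = spots.barcodes.isin(set(p["barcodes"]))
        values = p.get("baseline", 1.0) + p.get("effect", 1.0) * inside
        noise_sd = p.get("noise_sd", 0.0)
        if noise_sd:
            values = values + rng.normal(0.0, noise_sd, spots.n)
    elif spec.kind == "layered":
        means = np.asarray(p.get("means", [0.0, 1.0]), float)
        n_layers = len(means)
        edges = np.linspace(rows.min(), rows.max() + 1, n_layers + 1)
        layer = np.clip(np.searchsorted(edges, rows, side="right") - 1, 0, n_layers - 1)
        values = means[layer]
    else:  # pragma: no cover - guarded by PatternSpec
        raise ValueError(f"unknown pattern kind {spec.kind!r}")

    return ExpressionMatrix([gene], spots.barcodes, values[None, :], normalized=True)


def gen_counts(mean_field: ExpressionMatrix, dispersion: float, seed: int) -> ExpressionMatrix:
    """Draw negative-binomial counts around a non-negative mean field.

    Parameterized by mean mu and ``dispersion`` theta with variance
    mu + mu^2 / theta — the standard overdispersed UMI noise model. A
    zero mean yields a zero count deterministically.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    mu = mean_field.values
    if (mu < 0).any():
        raise ValueError("mean field must be non-negative for count generation")
    rng = np.random.default_rng(seed)
    prob = dispersion / (dispersion + mu)
    counts = rng.negative_binomial(dispersion, prob).astype(float)
    return ExpressionMatrix(mean_field.genes, mean_field.spots, counts, normalized=False)


def gen_gene_set(
    spots: SpotFrame, specs: dict[str, PatternSpec], *, normalized: bool = True
) -> ExpressionMatrix:
    """Stack several single-gene patterns into one gene x spot matrix."""
    if not specs:
        raise ValueError("specs must be non-empty")
    rows = [gen_pattern(spots, spec, gene).values[0] for gene, spec in specs.items()]
    return ExpressionMatrix(list(specs), spots.barcodes, np.vstack(rows), normalized=normalized)
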