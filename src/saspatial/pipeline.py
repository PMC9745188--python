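"""End-to-end pipeline: load -> weights -> global gate -> local Moran ->
ROI chi-squared tests -> ranking -> hot-spot maps, driven by a validated
YAML configuration.

One global seed fans out deterministically to per-stage and per-gene seeds,
so a rerun with the same config produces byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import st_io, synthetic
from .errors import ConfigError
from .hotspot import compare_methods, gi_star, wilcoxon_baseline
from .moran_global import GeneVector, gate_genes, global_moran_all, moran_table
from .moran_local import local_moran
from .roi_deg import (
    RoiDefinition,
    deg_chi2,
    deg_table,
    multiple_testing_adjust,
    rank_degs,
    resolve_roi,
)
from .weights import build_weights, row_standardize

logger = logging.getLogger(__name__)

_SCHEMA: dict[str, set[str]] = {
    "": {"input", "weights", "global", "local", "rois", "comparisons", "top_n",
         "output_dir", "seed", "baseline", "hotspot_top"},
    "input": {"dialect", "path", "expr_csv", "coord_csv", "normalize", "normalized"},
    "weights": {"scheme", "param", "row_standardize"},
    "global": {"null", "n_perm", "min_spots"},
    "local": {"null", "n_perm", "alpha", "fdr", "two_tailed", "si_mode"},
    "baseline": {"enabled", "logfc_threshold", "p_threshold", "min_pct"},
    "roi": {"name", "mode", "barcodes", "polygon", "section_id"},
    "comparison": {"roi", "reference", "direction"},
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see ``_SCHEMA`` for keys)."""

    input: dict
    output_dir: str
    seed: int = 0
    weights: dict = field(default_factory=dict)
    global_opts: dict = field(default_factory=dict)
    local_opts: dict = field(default_factory=dict)
    baseline: dict = field(default_factory=dict)
    rois: list[RoiDefinition] = field(default_factory=list)
    comparisons: list[dict] = field(default_factory=list)
    top_n: int = 20
    hotspot_top: int = 5
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        _check_keys(d, "", "config")
        if "input" not in d or "output_dir" not in d:
            raise ConfigError("config requires 'input' and 'output_dir'")
        _check_keys(d["input"], "input", "input")
        for sect in ("weights", "global", "local", "baseline"):
            _check_keys(d.get(sect, {}), sect, sect)
        rois = []
        for r in d.get("rois", []):
            _check_keys(r, "roi", f"roi {r.get('name', '?')}")
            rois.append(
                RoiDefinition(
                    name=r["name"],
                    section_id=r.get("section_id", ""),
                    mode=r.get("mode", "barcode_list"),
                    barcodes=tuple(r.get("barcodes", ())),
                    polygon=tuple(map(tuple, r.get("polygon", ()))),
                )
            )
        comparisons = []
        for c in d.get("comparisons", []):
            _check_keys(c, "comparison", "comparison")
            if "roi" not in c:
                raise ConfigError("comparison requires 'roi'")
            comparisons.append(
                {"roi": c["roi"], "reference": c.get("reference", "rest"),
                 "direction": c.get("direction", "up")}
            )
        dialect = d["input"].get("dialect", "visium")
        if dialect not in ("visium", "flat"):
            raise ConfigError(f"unknown input dialect {dialect!r}")
        return cls(
            input=d["input"],
            output_dir=d["output_dir"],
            seed=int(d.get("seed", 0)),
            weights=d.get("weights", {}),
            global_opts=d.get("global", {}),
            local_opts=d.get("local", {}),
            baseline=d.get("baseline", {}),
            rois=rois,
            comparisons=comparisons,
            top_n=int(d.get("top_n", 20)),
            hotspot_top=int(d.get("hotspot_top", 5)),
            raw=d,
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        """Load and validate a YAML config; relative input/output paths are
        resolved against the config file's directory."""
        path = Path(path)
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise ConfigError("config file must contain a mapping")
        cfg = cls.from_dict(d)
        base = path.parent
        for key in ("path", "expr_csv", "coord_csv"):
            if key in cfg.input and not Path(cfg.input[key]).is_absolute():
                cfg.input[key] = str(base / cfg.input[key])
        if not Path(cfg.output_dir).is_absolute():
            cfg.output_dir = str(base / cfg.output_dir)
        return cfg

    def digest(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        payload = {k: v for k, v in self.raw.items() if k != "output_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _check_keys(d: dict, schema_key: str, label: str) -> None:
    if not isinstance(d, dict):
        raise ConfigError(f"{label} section must be a mapping")
    unknown = set(d) - _SCHEMA[schema_key if schema_key in _SCHEMA else ""]
    if unknown:
        raise ConfigError(f"unknown key(s) in {label}: {sorted(unknown)}")


def _load_inputs(cfg: PipelineConfig):
    inp = cfg.input
    if inp.get("dialect", "visium") == "visium":
        spots, expr = st_io.read_visium(inp["path"])
    else:
        spots, expr = st_io.read_flat_csv(
            inp["expr_csv"], inp["coord_csv"], normalized=bool(inp.get("normalized", True))
        )
    if not expr.normalized and inp.get("normalize", True):
        expr = st_io.normalize_expression(expr)
    return spots, expr


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage in order, writing result tables under the output
    directory; returns the in-memory result bundle."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(cfg.seed)
    seed_global, seed_local, seed_other = (int(c.generate_state(1)[0] >> 1) for c in ss.spawn(3))

    logger.info("stage: load inputs")
    spots, expr = _load_inputs(cfg)

    logger.info("stage: spatial weights")
    wm = build_weights(spots, cfg.weights.get("scheme", "distance_band"), cfg.weights.get("param"))
    if cfg.weights.get("row_standardize", True):
        wm = row_standardize(wm)

    logger.info("stage: global Moran gate")
    stats_all = global_moran_all(
        expr, wm,
        null=cfg.global_opts.get("null", "randomization"),
        n_perm=int(cfg.global_opts.get("n_perm", 999)),
        seed=seed_global,
        min_spots=int(cfg.global_opts.get("min_spots", 10)),
    )
    gtable = moran_table(stats_all)
    gtable.to_csv(out / "global_moran.csv", index=False)
    gated = gate_genes(stats_all)
    if not gated:
        logger.warning("empty survivor set; downstream stages skipped")

    logger.info("stage: local Moran (%d genes)", len(gated))
    local_dir = out / "local"
    local_dir.mkdir(exist_ok=True)
    gene_seeds = {g: int(c.generate_state(1)[0] >> 1)
                  for g, c in zip(gated, np.random.SeedSequence(seed_local).spawn(max(len(gated), 1)))}
    fields = {}
    lo = cfg.local_opts
    for gene in gated:
        fields[gene] = local_moran(
            GeneVector(gene, expr.gene(gene)), wm,
            null=lo.get("null", "conditional_permutation"),
            n_perm=int(lo.get("n_perm", 999)),
            seed=gene_seeds[gene],
            alpha=float(lo.get("alpha", 0.05)),
            fdr=bool(lo.get("fdr", False)),
            two_tailed=bool(lo.get("two_tailed", True)),
            si_mode=lo.get("si_mode", "local"),
            barcodes=spots.barcodes,
        )
        fields[gene].to_frame().to_csv(local_dir / f"{gene}_local_moran.csv", index=False)

    roi_sets = {r.name: resolve_roi(r, spots) for r in cfg.rois}
    all_barcodes = set(spots.barcodes)

    comparisons_out = {}
    venn_rows = []
    for comp in cfg.comparisons:
        name = f"{comp['roi']}_vs_{comp['reference']}_{comp['direction']}"
        logger.info("stage: comparison %s", name)
        roi = roi_sets[comp["roi"]]
        ref = all_barcodes - roi if comp["reference"] == "rest" else roi_sets[comp["reference"]]
        results = [deg_chi2(f, roi, ref, comp["direction"]) for f in fields.values()]
        results = multiple_testing_adjust(results)
        table = deg_table(results)
        table.to_csv(out / f"deg_{name}.csv", index=False)
        top = rank_degs(results, top_n=cfg.top_n)
        bubble = table[table["gene"].isin(top)].copy()
        bubble = bubble.set_index("gene").loc[top].reset_index()
        bubble[["gene", "p", "rate_difference"]].to_csv(out / f"bubble_{name}.csv", index=False)
        comparisons_out[name] = {"results": results, "top": top}

        if cfg.baseline.get("enabled", True) and len(roi) >= 3 and len(ref) >= 3:
            base = wilcoxon_baseline(
                expr, roi, ref,
                logfc_threshold=float(cfg.baseline.get("logfc_threshold", 0.25)),
                p_threshold=float(cfg.baseline.get("p_threshold", 0.05)),
                min_pct=float(cfg.baseline.get("min_pct", 0.1)),
            )
            base_hits = [b.gene for b in base if b.passes]
            spatial_hits = [r.gene for r in results if r.p < float(lo.get("alpha", 0.05))]
            overlap = compare_methods(spatial_hits, base_hits)
            venn_rows.append(
                {"comparison": name, "both": overlap.n_both,
                 "spatial_only": overlap.n_spatial_only, "baseline_only": overlap.n_baseline_only}
            )
            comparisons_out[name]["baseline"] = base
            comparisons_out[name]["overlap"] = overlap
    if venn_rows:
        pd.DataFrame(venn_rows).to_csv(out / "method_overlap.csv", index=False)

    logger.info("stage: hot-spot maps")
    hot_dir = out / "hotspot"
    hot_dir.mkdir(exist_ok=True)
    hot_genes = sorted({g for c in comparisons_out.values() for g in c["top"][: cfg.hotspot_top]})
    for gene in hot_genes:
        hs = gi_star(GeneVector(gene, expr.gene(gene)), wm, barcodes=spots.barcodes)
        hs.to_frame().to_csv(hot_dir / f"{gene}_gi_star.csv", index=False)

    manifest = {
        "config_digest": cfg.digest(),
        "seed": cfg.seed,
        "n_spots": spots.n,
        "n_genes": expr.n_genes,
        "n_gated": len(gated),
        "versions": _versions(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {
        "spots": spots,
        "expr": expr,
        "weights": wm,
        "global": stats_all,
        "gated": gated,
        "local": fields,
        "comparisons": comparisons_out,
        "manifest": manifest,
    }


def _versions() -> dict:
    import scipy

    from . import __version__

    return {"saspatial": __version__, "numpy": np.__version__,
            "scipy": scipy.__version__, "pandas": pd.__version__}


# ---------------------------------------------------------------------------
# Fixture generation
# ---------------------------------------------------------------------------

#: strong regional markers show several-fold enrichment over baseline
DEFAULT_FIXTURE_SPEC = {
    "n_rows": 12,
    "n_cols": 12,
    "geometry": "square",
    "n_noise_genes": 6,
    "roi": {"row_min": 3, "row_max": 8, "col_min": 3, "col_max": 8},
    "effect": 6.0,
    "baseline": 2.0,
    "dispersion": 8.0,
}


def make_fixtures(out_dir, seed: int = 0, spec: dict | None = None) -> Path:
    """Write a complete synthetic section in both dialects plus true
    pattern labels and a ready-to-run pipeline config."""
    spec = {**DEFAULT_FIXTURE_SPEC, **(spec or {})}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spots = synthetic.gen_lattice(spec["n_rows"], spec["n_cols"], spec["geometry"])
    rc = spots.table
    roi_mask = (
        rc["array_row"].between(spec["roi"]["row_min"], spec["roi"]["row_max"])
        & rc["array_col"].between(spec["roi"]["col_min"], spec["roi"]["col_max"])
    )
    roi_barcodes = list(spots.barcodes[roi_mask.to_numpy()])

    ss = np.random.SeedSequence(seed)
    seeds = [int(c.generate_state(1)[0] >> 1) for c in ss.spawn(spec["n_noise_genes"] + 4)]
    specs = {
        "roi_gene": synthetic.PatternSpec(
            "roi_enriched",
            {"baseline": spec["baseline"], "effect": spec["effect"], "barcodes": roi_barcodes},
            seeds[0],
        ),
        "bump_gene": synthetic.PatternSpec(
            "gaussian_bump",
            {"sigma": 3.0, "amplitude": spec["effect"], "baseline": spec["baseline"]},
            seeds[1],
        ),
        "checker_gene": synthetic.PatternSpec(
            "checkerboard", {"low": spec["baseline"], "high": spec["baseline"] + spec["effect"]},
            seeds[2],
        ),
    }
    for i in range(spec["n_noise_genes"]):
        specs[f"noise_{i:02d}"] = synthetic.PatternSpec(
            "csr_noise", {"mean": spec["baseline"] + spec["effect"] / 2, "sd": 0.3}, seeds[3 + i]
        )
    means = synthetic.gen_gene_set(spots, specs)
    means.values[:] = np.clip(means.values, 0, None)
    counts = synthetic.gen_counts(means, spec["dispersion"], seeds[3 + spec["n_noise_genes"]])

    st_io.write_visium(out / "visium", spots, counts)
    normalized = st_io.normalize_expression(counts)
    st_io.write_flat_csv(out / "1.csv", out / "2.csv", spots, normalized)
    pd.DataFrame(
        {"gene": list(specs), "kind": [s.kind for s in specs.values()]}
    ).to_csv(out / "truth.csv", index=False)
    pd.Series(roi_barcodes).to_csv(out / "roi_barcodes.csv", index=False, header=["barcode"])

    config = {
        "input": {"dialect": "visium", "path": "visium", "normalize": True},
        "weights": {"scheme": "distance_band", "row_standardize": True},
        "global": {"null": "randomization", "min_spots": 10},
        "local": {"null": "conditional_permutation", "n_perm": 199, "alpha": 0.05},
        "rois": [{"name": "core", "mode": "barcode_list", "barcodes": [str(b) for b in roi_barcodes]}],
        "comparisons": [{"roi": "core", "reference": "rest", "direction": "up"}],
        "top_n": 20,
        "output_dir": "results",
        "seed": seed,
    }
    (out / "config.yaml").write_text(yaml.safe_dump(config, sort_keys=False))
    return out
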