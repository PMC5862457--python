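"""End-to-end analysis pipeline and report rendering.

Sequence: load and preprocess responses (reverse-keying, missing-data
exclusion) -> per-dimension RSM calibration of both versions -> fit
diagnostics, separation, information curves, item maps -> full-vs-short
concordance.  The pipeline is a pure function of (input files, config,
seed): repeated runs produce identical numeric output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .concordance import compare_versions
from .data import (
    ResponseMatrix,
    ScaleDefinition,
    apply_reverse_keying,
    filter_missing_persons,
    load_responses,
    load_scale_definition,
    subset_dimension,
)
from .diagnostics import infit_outfit, information_function, item_map, separation
from .errors import ConfigurationError
from .model import RatingScaleModel, fit_rsm

__all__ = ["PipelineConfig", "run_full_pipeline", "render_tables", "item_table"]

logger = logging.getLogger("rsmkit")

LOGIT_DECIMALS = 4
INDEX_DECIMALS = 3


@dataclass
class PipelineConfig:
    responses_path: Path
    scale_path: Path
    output_dir: Path
    dimensions: list[str] | None = None  # None = all in the scale definition
    max_missing_fraction: float = 0.20
    anchored: bool = False
    seed: int = 0
    report_formats: tuple[str, ...] = ("tsv", "json")
    fit_config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.responses_path = Path(self.responses_path)
        self.scale_path = Path(self.scale_path)
        self.output_dir = Path(self.output_dir)
        for p in (self.responses_path, self.scale_path):
            if not p.exists():
                raise ConfigurationError(f"input file not found: {p}")


def item_table(rm: ResponseMatrix, fit: RatingScaleModel) -> pd.DataFrame:
    """Per-item report: Measure (error), MNSQ-INFIT, MNSQ-OUTFIT, item-total r."""
    stats = infit_outfit(rm, fit, margin="items")
    return pd.DataFrame(
        {
            "item": list(fit.item_ids_),
            "measure": np.round(fit.beta_, LOGIT_DECIMALS),
            "error": np.round(fit.se_beta_, LOGIT_DECIMALS),
            "mnsq_infit": np.round(stats.infit_mnsq, INDEX_DECIMALS),
            "mnsq_outfit": np.round(stats.outfit_mnsq, INDEX_DECIMALS),
            "classification": list(stats.classification),
            "item_total_correlation": np.round(
                stats.item_total_correlation, INDEX_DECIMALS
            ),
            "extreme": fit.extreme_items_,
        }
    )


def _separation_row(dimension: str, version: str, fit: RatingScaleModel) -> dict:
    ps = separation(fit, "persons")
    it = separation(fit, "items")
    return {
        "dimension": dimension,
        "version": version,
        "person_separation": round(ps.separation_index, INDEX_DECIMALS),
        "person_reliability": round(ps.reliability, INDEX_DECIMALS),
        "person_strata": round(ps.strata, INDEX_DECIMALS),
        "person_verdict": ps.verdict,
        "item_separation": round(it.separation_index, INDEX_DECIMALS),
        "item_reliability": round(it.reliability, INDEX_DECIMALS),
        "item_verdict": it.verdict,
    }


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Run the complete analysis; writes one file set per dimension.

    Returns the in-memory bundle: per-dimension fits, tables and
    concordance reports, plus the run manifest.
    """
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    logger.info("loading %s", config.responses_path)

    scale = load_scale_definition(config.scale_path)
    rm = load_responses(config.responses_path, n_categories=scale.n_categories)
    rm = apply_reverse_keying(rm, scale)
    rm, excluded = filter_missing_persons(rm, config.max_missing_fraction)
    logger.info("excluded %d persons for missing data", len(excluded))

    dimensions = config.dimensions or list(scale.dimensions)
    unknown = [d for d in dimensions if d not in scale.dimensions]
    if unknown:
        raise ConfigurationError(f"unknown dimensions requested: {unknown}")

    bundle: dict = {
        "dimensions": {},
        "separation_rows": [],
        "excluded_persons": excluded,
    }
    for dim in dimensions:
        logger.info("analysing dimension %s", dim)
        report, fit_full, fit_short = compare_versions(
            rm, scale, dim, anchored=config.anchored, **config.fit_config
        )
        entry: dict = {"concordance": report, "fits": {}}
        for version, fit in (("full", fit_full), ("short", fit_short)):
            sub = subset_dimension(rm, scale, dim, version)
            table = item_table(sub, fit)
            curve = information_function(fit)
            imap = item_map(fit)
            bundle["separation_rows"].append(_separation_row(dim, version, fit))
            entry["fits"][version] = {
                "fit": fit,
                "item_table": table,
                "information": curve.to_frame().round(LOGIT_DECIMALS),
                "item_map": imap.round(LOGIT_DECIMALS),
                "converged": fit.converged_,
            }
        bundle["dimensions"][dim] = entry

    render_tables(bundle, out, formats=config.report_formats)
    manifest = {
        "rsmkit_version": __version__,
        "responses": _file_digest(config.responses_path),
        "scale": _file_digest(config.scale_path),
        "seed": config.seed,
        "max_missing_fraction": config.max_missing_fraction,
        "anchored": config.anchored,
        "n_persons_retained": rm.n_persons,
        "n_persons_excluded": len(excluded),
        "dimensions": dimensions,
        "converged": {
            d: {v: e["fits"][v]["converged"] for v in e["fits"]}
            for d, e in bundle["dimensions"].items()
        },
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    bundle["manifest"] = manifest
    return bundle


def _file_digest(path: Path) -> dict:
    h = hashlib.sha256(Path(path).read_bytes()).hexdigest()
    return {"path": str(path), "sha256": h}


def render_tables(bundle: dict, out_dir: Path, formats=("tsv", "json")) -> list[Path]:
    """Write the bundle's tables in the requested formats; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _emit(df: pd.DataFrame, stem: str) -> None:
        if "tsv" in formats:
            p = out_dir / f"{stem}.tsv"
            df.to_csv(p, sep="\t", index=False)
            written.append(p)
        if "json" in formats:
            p = out_dir / f"{stem}.json"
            p.write_text(df.to_json(orient="records", indent=2))
            written.append(p)
        if "markdown" in formats:
            p = out_dir / f"{stem}.md"
            p.write_text(df.to_markdown(index=False))
            written.append(p)

    sep_rows = pd.DataFrame(
        bundle.get("separation_rows", []),
        columns=[
            "dimension", "version", "person_separation", "person_reliability",
            "person_strata", "person_verdict", "item_separation",
            "item_reliability", "item_verdict",
        ],
    )
    _emit(sep_rows, "separation")

    conc_rows = []
    for dim, entry in bundle.get("dimensions", {}).items():
        report = entry["concordance"]
        conc_rows.append(
            {k: v for k, v in report.to_dict().items() if k != "gap_flags"}
        )
        (out_dir / f"concordance_{dim}.json").write_text(
            json.dumps(report.to_dict(), indent=2, default=float)
        )
        for version, vdata in entry["fits"].items():
            _emit(vdata["item_table"], f"items_{dim}_{version}")
            _emit(vdata["information"], f"information_{dim}_{version}")
            _emit(vdata["item_map"], f"item_map_{dim}_{version}")
    conc_df = pd.DataFrame(
        conc_rows,
        columns=[
            "dimension", "slope", "intercept", "r", "r_squared", "riu",
            "riu_verdict", "efficiency", "efficiency_verdict", "n_persons",
            "n_dropped_pairs", "order_tau",
        ],
    ).round(INDEX_DECIMALS)
    _emit(conc_df, "concordance")
    return written
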