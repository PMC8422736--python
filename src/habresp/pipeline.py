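"""End-to-end pipeline: telemetry -> availability -> logits -> Holling types.

The pipeline reproduces the full analysis for every non-reference
land-cover category and every requested time slot (month, hour) and
sex: monthly 95%-MCP availability, focal-vs-reference logit fits
(optionally selected by grouped cross-validation), multinomial use
curves over the observed availability range, and Holling-type fits
with ecological diagnostics, written as a Table-style summary CSV plus
a JSON run manifest for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .availability import (
    AvailabilityConfig,
    LandCoverGrid,
    build_availability_table,
    read_ascii_grid,
)
from .holling import HollingModel
from .pairwise import (
    FocalLogitModel,
    ModelSpec,
    build_pairwise_dataset,
    cross_validate,
    default_candidate_specs,
)
from .use_distribution import use_curve

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_config"]


class PipelineError(RuntimeError):
    """Stage failure with the stage and offending category/slot attached."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"[{stage}] {detail}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Validated configuration of one pipeline run."""

    reference_category: str
    telemetry: str | pd.DataFrame | None = None
    raster: str | LandCoverGrid | None = None
    legend: Mapping[int, str] | None = None
    availability: str | pd.DataFrame | None = None
    output_dir: str | None = None
    mcp_level: float = 95.0
    min_fixes: int = 5
    cutoff_mode: str = "percentile"
    cutoff_percentile: float = 90.0
    cutoff_scope: str = "monthly"
    absolute_thresholds: Mapping[str, float] | None = None
    spec: ModelSpec | Mapping | None = None
    candidates: Sequence[ModelSpec] | str | None = None
    cv_folds: int = 10
    months: Sequence[int] = (6, 12)
    hours: Sequence[int] = (0, 12)
    x_grid_size: int = 200
    x_quantiles: tuple[float, float] = (0.01, 0.99)
    allow_extrapolation: bool = True
    min_rows: int = 50
    seed: int = 0

    def __post_init__(self):
        if not self.reference_category:
            raise PipelineError("config", "reference_category is required")
        if self.telemetry is None:
            raise PipelineError("config", "telemetry input is required")
        if self.availability is None and self.raster is None:
            raise PipelineError("config", "either a raster or an availability table is required")
        for m in self.months:
            if not 1 <= int(m) <= 12:
                raise PipelineError("config", f"month {m} outside 1..12")
        for h in self.hours:
            if not 0 <= int(h) <= 23:
                raise PipelineError("config", f"hour {h} outside 0..23")
        if isinstance(self.spec, Mapping):
            self.spec = ModelSpec(**self.spec)
        if isinstance(self.candidates, str):
            if self.candidates != "default":
                raise PipelineError("config", "candidates must be 'default' or a list")
            self.candidates = default_candidate_specs()
        elif self.candidates is not None:
            self.candidates = [
                c if isinstance(c, ModelSpec) else ModelSpec(**c) for c in self.candidates
            ]


def load_config(path) -> PipelineConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw.get("legend"):
        raw["legend"] = {int(k): v for k, v in raw["legend"].items()}
    try:
        return PipelineConfig(**raw)
    except TypeError as e:
        raise PipelineError("config", str(e)) from e


# design decisions surfaced in every run manifest
_DECISIONS = {
    "mcp_peeling": "points farthest from the centroid of all points removed first; "
    "ties broken by input order",
    "cell_inclusion": "raster cell counts when its center is inside the polygon; "
    "boundary centers count as inside",
    "zero_availability_rows": "dropped (offset log undefined), never floored",
    "background_rescaling": "background availabilities are the per-sex mean observed "
    "vector rescaled proportionally to 1 - x",
    "x_grid": "equally spaced between the configured quantiles of observed focal availability",
    "cv_folds": "grouped by animal id",
    "random_effects_in_curves": "population-level (random intercepts at zero)",
    "holling_tie_break": "equal-RSS ties resolved toward the lower type number",
    "x_star_report": "0 written when no crossing exists (report convention); "
    "regime column keeps the distinction",
}


def _config_digest(cfg: PipelineConfig) -> str:
    def default(o):
        if isinstance(o, pd.DataFrame):
            return f"<dataframe {o.shape}>"
        if isinstance(o, LandCoverGrid):
            return f"<grid {o.codes.shape}>"
        if isinstance(o, ModelSpec):
            return asdict(o)
        return str(o)

    blob = json.dumps(asdict(cfg), default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns a bundle dict and (optionally) writes files.

    Bundle keys: ``availability``, ``exclusions``, ``models`` (results
    per category), ``cv`` (rankings, when candidates were given),
    ``curves`` (long DataFrame), ``summary`` (Table-style DataFrame),
    ``manifest``.
    """
    out = Path(config.output_dir) if config.output_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    # ---- stage: inputs -------------------------------------------------
    telemetry = config.telemetry
    if isinstance(telemetry, (str, Path)):
        telemetry = pd.read_csv(telemetry)
    need = {"id", "sex", "year", "month", "hour", "category"}
    if not need.issubset(telemetry.columns):
        raise PipelineError("inputs", f"telemetry misses columns {sorted(need - set(telemetry.columns))}")

    # ---- stage: availability -------------------------------------------
    exclusions: list = []
    if config.availability is not None:
        availability = config.availability
        if isinstance(availability, (str, Path)):
            availability = pd.read_csv(availability)
    else:
        grid = config.raster
        if isinstance(grid, (str, Path)):
            if config.legend is None:
                raise PipelineError("availability", "raster input requires a legend")
            grid = read_ascii_grid(grid, config.legend, config.reference_category)
        acfg = AvailabilityConfig(
            mcp_level=config.mcp_level,
            min_fixes=config.min_fixes,
            cutoff_mode=config.cutoff_mode,
            cutoff_percentile=config.cutoff_percentile,
            cutoff_scope=config.cutoff_scope,
            absolute_thresholds=config.absolute_thresholds,
        )
        try:
            availability, exclusions, _ = build_availability_table(telemetry, grid, acfg)
        except ValueError as e:
            raise PipelineError("availability", str(e)) from e
        if availability.empty:
            raise PipelineError("availability", "no animal-months survived screening")
        keep = pd.MultiIndex.from_frame(telemetry[["id", "year", "month"]]).isin(
            pd.MultiIndex.from_frame(availability[["id", "year", "month"]].drop_duplicates())
        )
        telemetry = telemetry[keep]

    categories = sorted(availability["category"].unique())
    if config.reference_category not in categories:
        raise PipelineError("availability",
                            f"reference category {config.reference_category!r} not in table")
    non_ref = [c for c in categories if c != config.reference_category]

    # ---- stage: pairwise logits ----------------------------------------
    models: dict[str, object] = {}
    cv_tables: dict[str, pd.DataFrame] = {}
    drop_log: dict[str, int] = {}
    for cat in non_ref:
        try:
            data, n_drop = build_pairwise_dataset(
                telemetry, availability, cat, config.reference_category
            )
            drop_log[cat] = n_drop
            if config.candidates:
                cv = cross_validate(data, config.candidates, k=config.cv_folds,
                                    seed=config.seed, min_rows=1)
                cv_tables[cat] = cv.ranking
                spec = cv.chosen
            else:
                spec = config.spec or ModelSpec()
            models[cat] = FocalLogitModel(data, spec, focal_category=cat,
                                          min_rows=config.min_rows).fit()
        except (ValueError, np.linalg.LinAlgError) as e:
            raise PipelineError("pairwise_logit", f"category {cat!r}: {e}") from e

    # ---- stage: use curves + Holling fits ------------------------------
    sexes = sorted(telemetry["sex"].unique())
    curve_rows, summary_rows = [], []
    model_list = list(models.values())
    for cat in non_ref:
        focal_av = availability.loc[availability["category"] == cat, "proportion"]
        focal_av = focal_av[focal_av > 0]
        lo, hi = np.quantile(focal_av, config.x_quantiles)
        if hi <= lo:
            raise PipelineError("use_distribution",
                                f"category {cat!r}: degenerate availability range")
        x_grid = np.linspace(lo, hi, config.x_grid_size)
        for sex in sexes:
            av_sex = availability[availability["sex"] == sex] if "sex" in availability else availability
            mean_bg = av_sex.groupby("category")["proportion"].mean().to_dict()
            for month in config.months:
                for hour in config.hours:
                    try:
                        curve = use_curve(
                            model_list, int(hour), int(month), sex, cat, x_grid, mean_bg,
                            config.reference_category,
                            extrapolate=config.allow_extrapolation,
                        )
                        fit = HollingModel(curve.x, curve.use).fit()
                    except (ValueError, RuntimeError) as e:
                        raise PipelineError(
                            "holling", f"category {cat!r} slot (m={month}, h={hour}, {sex}): {e}"
                        ) from e
                    for xv, uv in zip(curve.x, curve.use):
                        curve_rows.append((cat, sex, month, hour, float(xv), float(uv)))
                    dg = fit.diagnostics
                    summary_rows.append({
                        "focal": cat, "sex": sex, "month": int(month), "hour": int(hour),
                        "type": fit.holling_type,
                        "a": fit.a, "b": fit.b,
                        "a_over_b": dg.a_over_b,
                        "x_star": dg.x_star if dg.x_star is not None else 0.0,
                        "crossing_low": dg.crossings[0] if dg.crossings else 0.0,
                        "crossing_high": dg.crossings[1] if dg.crossings else 0.0,
                        "inflection": dg.inflection if dg.inflection is not None else "",
                        "rss": fit.rss,
                        "regime": dg.regime,
                    })
    curves = pd.DataFrame(curve_rows, columns=["focal", "sex", "month", "hour", "x", "use"])
    summary = pd.DataFrame(summary_rows)

    manifest = {
        "package_version": __version__,
        "config_digest": _config_digest(config),
        "seed": config.seed,
        "versions": {m.__name__: m.__version__ for m in
                     (np, pd, __import__("scipy"), __import__("shapely"))},
        "decisions": _DECISIONS,
        "n_fixes": int(len(telemetry)),
        "n_animal_months": int(len(availability[["id", "year", "month"]].drop_duplicates())),
        "zero_availability_drops": drop_log,
        "exclusions": [asdict(e) for e in exclusions],
        "chosen_specs": {c: asdict(m.spec) for c, m in models.items()},
    }

    if out:
        availability.to_csv(out / "availability.csv", index=False)
        curves.to_csv(out / "curves.csv", index=False)
        summary.to_csv(out / "summary.csv", index=False)
        (out / "models").mkdir(exist_ok=True)
        for cat, res in models.items():
            res.save(out / "models" / f"{cat}.json")
        for cat, tab in cv_tables.items():
            tab.to_csv(out / f"cv_{cat}.csv", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
        with open(out / "exclusions.log", "w") as fh:
            for e in exclusions:
                fh.write(f"{e.id}\t{e.year}\t{e.month}\t{e.reason}\t{e.detail}\n")

    return {
        "availability": availability,
        "exclusions": exclusions,
        "models": models,
        "cv": cv_tables,
        "curves": curves,
        "summary": summary,
        "manifest": manifest,
    }
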