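"""Run configuration and the end-to-end pipeline driver."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import yaml
from pydantic import BaseModel, field_validator

from . import catalog as cat
from . import conversion as conv
from . import survey as svy
from . import table_builder as tb
from .errors import HeisnutrError

logger = logging.getLogger(__name__)


class RunConfig(BaseModel):
    """Single serializable source of truth for a pipeline run."""

    catalog: Path
    foods: Path
    purchases: Path
    households: Path
    scale: Path | None = None  # YAML equivalence scale; None -> illustrative default
    method: str = "mean"
    reference_days: int = 7
    outdir: Path = Path("heisnutr_out")
    log_level: str = "INFO"

    @field_validator("method")
    @classmethod
    def _method_ok(cls, v: str) -> str:
        if v not in ("mean", "median"):
            raise ValueError("method must be 'mean' or 'median'")
        return v

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute validate → build-table → convert → estimate; return artifact paths.

    Each stage's outputs are written under ``config.outdir``. Raises
    :class:`HeisnutrError` (chained to the failing stage) on any validation
    failure, so callers can exit non-zero naming the stage.
    """
    logging.basicConfig(level=config.log_level)
    logger.info("pipeline run, config hash %s", config.config_hash())
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    stage = "validate"
    try:
        catalog = cat.read_category_catalog(config.catalog)
        foods = cat.read_food_items(config.foods)
        report = cat.coverage_report(catalog, foods)
        artifacts["coverage"] = outdir / "coverage.csv"
        report.to_frame().to_csv(artifacts["coverage"], index=False)

        stage = "build-table"
        result = tb.build_conversion_table(catalog, foods, method=config.method)
        artifacts["conversion_table"] = outdir / "conversion_table.csv"
        tb.write_conversion_table(result.table, artifacts["conversion_table"])
        artifacts["drop_log"] = outdir / "drops.csv"
        result.drop_log.to_csv(artifacts["drop_log"], index=False)

        stage = "convert"
        scale = (
            conv.EquivalenceScale.from_yaml(config.scale) if config.scale else conv.DEFAULT_SCALE
        )
        households = conv.read_households(config.households, scale)
        purchases = conv.read_purchases(config.purchases)
        availability = conv.household_daily_availability(
            purchases, result.table, households, reference_days=config.reference_days
        )
        artifacts["availability"] = outdir / "availability.csv"
        availability.to_csv(artifacts["availability"], index=False)

        stage = "estimate"
        design = svy.SurveyDesign.from_households(households)
        assignment = svy.assign_income_quintiles(
            households["income"] / households["equivalent_adults"],
            households["weight"] * households["n_members"],
        )
        aligned = availability.set_index("household_id").loc[households["household_id"]]
        estimates = svy.quintile_nutrient_table(aligned.reset_index(), assignment, design)
        artifacts["estimates"] = outdir / "estimates.csv"
        estimates.to_csv(artifacts["estimates"], index=False)
        fafh = svy.fafh_summary(
            purchases, households, design, reference_days=config.reference_days
        )
        artifacts["fafh"] = outdir / "fafh.csv"
        fafh.table.to_csv(artifacts["fafh"], index=False)
    except HeisnutrError as exc:
        raise HeisnutrError(f"stage {stage!r} failed: {exc}") from exc

    return artifacts
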