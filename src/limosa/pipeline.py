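"""End-to-end analysis pipeline.

Sequences the full study: site characteristics with layered benthos
summaries, per-site sex ratios with the site-effect and within-site
bias tests, per-layer biomass ANOVA with Tukey contrasts, seasonal
cost decompositions with the cost-distance fit, the condition-score
model (APS ~ cost x sex), and the four-correlation hypothesis panel.

All results are assembled in memory first and written in one pass, so
a failing stage leaves no partial output; outputs are deterministic
(sites ordered by distance to the breeding grounds, fixed column
order, versioned JSON report) and the report echoes the configuration
and every physiological constant used.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import benthos as _benthos
from . import energetics as _energetics
from . import fieldobs as _fieldobs
from . import inference as _inference
from . import simulate as _simulate

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "write_report", "load_config"]

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = "1.0"


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either the four input CSV paths or a synthetic scenario must be
    given.  Analysis flags select the session-weighting and the
    correlation level of the hypothesis panel.
    """

    sites_csv: Optional[str] = None
    cores_csv: Optional[str] = None
    counts_csv: Optional[str] = None
    aps_csv: Optional[str] = None
    scenario: Optional[_simulate.Scenario] = None
    coeffs: _energetics.HeatLossCoefficients = field(
        default_factory=_energetics.HeatLossCoefficients
    )
    energetics: _energetics.EnergeticsConfig = field(
        default_factory=_energetics.EnergeticsConfig
    )
    weight_sessions_by_size: bool = False
    sample_level_panel: bool = True
    outdir: str = "limosa_out"
    seed: int = 0
    log_level: str = "INFO"

    def echo(self) -> dict:
        d = {
            "sites_csv": self.sites_csv,
            "cores_csv": self.cores_csv,
            "counts_csv": self.counts_csv,
            "aps_csv": self.aps_csv,
            "scenario": _tuples_to_lists(dataclasses.asdict(self.scenario))
            if self.scenario
            else None,
            "coeffs": dataclasses.asdict(self.coeffs),
            "energetics": dataclasses.asdict(self.energetics),
            "weight_sessions_by_size": self.weight_sessions_by_size,
            "sample_level_panel": self.sample_level_panel,
            "seed": self.seed,
        }
        return d


def _tuples_to_lists(obj):
    if isinstance(obj, dict):
        return {k: _tuples_to_lists(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_tuples_to_lists(v) for v in obj]
    return obj


def load_config(path) -> RunConfig:
    """Read a YAML (or JSON) run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = dict(raw)
    if "scenario" in kwargs and kwargs["scenario"] is not None:
        sc = {
            k: tuple(v) if isinstance(v, list) else v for k, v in kwargs["scenario"].items()
        }
        kwargs["scenario"] = _simulate.Scenario(**sc)
    if "coeffs" in kwargs and kwargs["coeffs"] is not None:
        kwargs["coeffs"] = _energetics.HeatLossCoefficients(**kwargs["coeffs"])
    if "energetics" in kwargs and kwargs["energetics"] is not None:
        kwargs["energetics"] = _energetics.EnergeticsConfig(**kwargs["energetics"])
    return RunConfig(**kwargs)


def _require_path(path: Optional[str], what: str, stage: str) -> Path:
    if path is None:
        raise PipelineError(stage, f"no {what} input configured")
    p = Path(path)
    if not p.exists():
        raise PipelineError(stage, f"{what} file not found: {p}")
    return p


def _load_inputs(config: RunConfig) -> dict:
    if config.scenario is not None:
        scenario = dataclasses.replace(config.scenario, seed=config.seed)
        data = _simulate.generate(scenario)
        return {
            "sites": data["sites"],
            "cores": data["cores"],
            "counts": data["counts"],
            "aps": data["aps"],
        }
    sites = _energetics.read_sites(_require_path(config.sites_csv, "site table", "load"))
    cores = _benthos.read_cores(_require_path(config.cores_csv, "benthos cores", "load"))
    counts = _fieldobs.read_counts(_require_path(config.counts_csv, "count sessions", "load"))
    aps = None
    if config.aps_csv is not None:
        aps = _fieldobs.read_aps(_require_path(config.aps_csv, "APS records", "load"))
    return {"sites": sites, "cores": cores, "counts": counts, "aps": aps}


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the result bundle (tables plus a
    JSON-ready report dict); use :func:`write_report` to persist it."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    inputs = _load_inputs(config)
    sites, cores, counts, aps = (
        inputs["sites"],
        inputs["cores"],
        inputs["counts"],
        inputs["aps"],
    )

    # --- energetics ---------------------------------------------------
    try:
        costs = _energetics.cost_table(sites, coeffs=config.coeffs, config=config.energetics)
    except Exception as exc:
        raise PipelineError("energetics", str(exc)) from exc
    logger.info(
        "energetics constants: male %s, female %s, coeffs %s, config %s",
        _energetics.MALE, _energetics.FEMALE, config.coeffs, config.energetics,
    )
    site_cost = costs.groupby("site", as_index=False)["seasonal_total_kj"].mean().rename(
        columns={"seasonal_total_kj": "cost_kj"}
    )

    # --- benthos summary ----------------------------------------------
    try:
        cores_wide = _benthos.cores_to_wide(cores)
        summary = _benthos.summarize_benthos(cores)
    except Exception as exc:
        raise PipelineError("benthos", str(exc)) from exc
    distances = costs[["site", "one_way_distance_km"]].drop_duplicates()
    characteristics = (
        summary.merge(sites[["site", "t_air_c"]], on="site")
        .merge(distances, on="site")
        .sort_values("one_way_distance_km", kind="mergesort")
        .reset_index(drop=True)
    )
    site_order = characteristics["site"].tolist()

    # --- sex ratios ----------------------------------------------------
    try:
        ratios = _fieldobs.sex_ratio_table(
            counts, weight_by_size=config.weight_sessions_by_size
        )
        ratios = (
            ratios.set_index("site").loc[site_order].reset_index()
        )
        site_effect = _inference.site_effect_test(counts)
        bias_tests = {
            s: _fieldobs.sex_bias_test(counts[counts["site"] == s]) for s in site_order
        }
    except Exception as exc:
        raise PipelineError("sexratio", str(exc)) from exc

    # --- biomass differences -------------------------------------------
    biomass_tests = {}
    try:
        for layer in ("top", "bottom"):
            col = f"{layer}_gm2"
            sub = cores_wide.dropna(subset=[col])
            biomass_tests[layer] = {
                "anova": _inference.one_way_anova(sub[col], sub["site"]),
                "tukey": _inference.tukey_hsd(sub[col], sub["site"]),
            }
    except Exception as exc:
        raise PipelineError("biomass", str(exc)) from exc

    # --- cost ~ distance (pooled sexes, single slope) -------------------
    try:
        cost_fit = _inference.linear_fit(costs, "seasonal_total_kj ~ one_way_distance_km")
    except Exception as exc:
        raise PipelineError("cost_fit", str(exc)) from exc

    # --- condition scores ----------------------------------------------
    aps_block = None
    if aps is not None and len(aps):
        try:
            aps_means = _fieldobs.aps_summary(aps)
            cost_z = costs[["site", "sex", "seasonal_total_kj"]].copy()
            sd = cost_z["seasonal_total_kj"].std(ddof=0)
            cost_z["cost_z"] = (
                cost_z["seasonal_total_kj"] - cost_z["seasonal_total_kj"].mean()
            ) / (sd if sd > 0 else 1.0)
            merged = aps.merge(cost_z[["site", "sex", "cost_z"]], on=["site", "sex"])
            aps_fit = _inference.linear_fit(merged, "score ~ cost_z * sex")
            aps_block = {"means": aps_means, "fit": aps_fit}
        except Exception as exc:
            raise PipelineError("aps", str(exc)) from exc
    else:
        logger.info("no APS records supplied; condition-score stage omitted")

    # --- hypothesis panel ----------------------------------------------
    try:
        panel_table = characteristics.merge(
            ratios[["site", "pct_female"]], on="site"
        ).merge(site_cost, on="site")
        panel = _inference.hypothesis_panel(
            panel_table, cores_wide, cost_column="cost_kj",
            sample_level=config.sample_level_panel,
        )
    except Exception as exc:
        raise PipelineError("panel", str(exc)) from exc

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config": config.echo(),
        "constants": {
            "profiles": [dataclasses.asdict(_energetics.MALE), dataclasses.asdict(_energetics.FEMALE)],
            "bmr_coefficient": _energetics.BMR_COEFFICIENT,
            "bmr_exponent": _energetics.BMR_EXPONENT,
            "kj_per_watt_day": _energetics.KJ_PER_WATT_DAY,
            "heat_loss_coefficients": dataclasses.asdict(config.coeffs),
            "energetics_config": dataclasses.asdict(config.energetics),
        },
        "site_effect": site_effect.to_dict(),
        "sex_bias": {s: t.to_dict() for s, t in bias_tests.items()},
        "biomass": {
            layer: {"anova": block["anova"].to_dict()} for layer, block in biomass_tests.items()
        },
        "cost_distance_fit": cost_fit.to_dict(),
        "aps_fit": aps_block["fit"].to_dict() if aps_block else None,
        "aps_notice": None if aps_block else "no APS records supplied; stage omitted",
        "hypothesis_panel": {k: t.to_dict() for k, t in panel.items()},
    }

    return {
        "characteristics": characteristics,
        "sex_ratios": ratios,
        "costs": costs,
        "biomass_tests": biomass_tests,
        "cost_fit": cost_fit,
        "aps": aps_block,
        "panel": panel,
        "report": report,
    }


def write_report(results: dict, outdir) -> dict:
    """Persist the result bundle: fixed file set, fixed column orders,
    deterministic bytes for identical results."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    def _csv(df: pd.DataFrame, name: str):
        p = out / name
        df.to_csv(p, index=False)
        paths[name] = str(p)

    _csv(results["characteristics"], "site_characteristics.csv")
    _csv(results["sex_ratios"], "sex_ratios.csv")
    _csv(results["costs"], "costs.csv")
    for layer, block in results["biomass_tests"].items():
        _csv(block["tukey"], f"tukey_{layer}.csv")
    if results["aps"] is not None:
        _csv(results["aps"]["means"], "aps_means.csv")
    p = out / "report.json"
    with open(p, "w") as fh:
        json.dump(results["report"], fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")
    paths["report.json"] = str(p)
    return paths
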