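"""Layered benthic biomass processing.

Benthic cores (0.0177 m^2, 30 cm deep) are sieved in two strata: the
top 0-4 cm, reachable by surface pecks, and the bottom 5-30 cm,
reachable only by deep probing.  Each layer's sample is dried and
incinerated; ash-free dry mass (AFDM) is dry mass minus ash mass and is
the edible-biomass currency throughout.

Site summaries report per-layer mean and SD of AFDM density (g/m^2)
and the percentage of each core's AFDM found in the bottom layer.  The
bottom percentage is averaged per core first (mean of ratios), not
pooled (ratio of means) — a site where one rich core is bottom-heavy
and a poor core is not gets the unweighted average of the two shares.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_CORE_AREA",
    "ash_free_dry_mass",
    "layer_density",
    "bottom_fraction",
    "cores_to_wide",
    "summarize_site",
    "summarize_benthos",
    "read_cores",
]

logger = logging.getLogger(__name__)

#: Core sampler area in m^2.
DEFAULT_CORE_AREA = 0.0177

LAYERS = ("top", "bottom")


def ash_free_dry_mass(dry_mass: float, ash_mass: float) -> float:
    """AFDM (g) = dry mass - ash mass after incineration."""
    if ash_mass < 0 or dry_mass < 0:
        raise ValueError("masses must be >= 0")
    if ash_mass > dry_mass:
        raise ValueError(f"ash mass {ash_mass} exceeds dry mass {dry_mass}")
    return dry_mass - ash_mass


def layer_density(afdm: float, core_area: float = DEFAULT_CORE_AREA) -> float:
    """AFDM density (g/m^2) of one layer of one core."""
    if core_area <= 0:
        raise ValueError("core_area must be > 0")
    return afdm / core_area


def bottom_fraction(top_afdm: float, bottom_afdm: float) -> float:
    """Percentage of a core's AFDM found in the bottom layer.

    Undefined (NaN) for an empty core, which is excluded from the
    bottom-percentage site summary.
    """
    total = top_afdm + bottom_afdm
    if total == 0:
        return float("nan")
    return 100.0 * bottom_afdm / total


def read_cores(path) -> pd.DataFrame:
    """Read a tidy core CSV (site, core_id, layer, dry_mass_g,
    ash_mass_g, optional core_area_m2)."""
    df = pd.read_csv(path)
    required = {"site", "core_id", "layer", "dry_mass_g", "ash_mass_g"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"core table missing columns: {sorted(missing)}")
    bad_layer = set(df["layer"].unique()) - set(LAYERS)
    if bad_layer:
        raise ValueError(f"unknown layer labels: {sorted(bad_layer)}")
    if "core_area_m2" not in df.columns:
        df["core_area_m2"] = DEFAULT_CORE_AREA
    return df


def cores_to_wide(cores: pd.DataFrame) -> pd.DataFrame:
    """Per-core wide table of layer AFDM densities (g/m^2).

    Records with ash mass exceeding dry mass are flagged, logged and
    excluded.  Columns: site, core_id, top_gm2, bottom_gm2, bottom_pct.
    A missing layer yields NaN for that layer (the core still counts
    for the other layer); bottom_pct is NaN when either layer is
    missing or the core is empty.
    """
    df = cores.copy()
    if "core_area_m2" not in df.columns:
        df["core_area_m2"] = DEFAULT_CORE_AREA
    invalid = df["ash_mass_g"] > df["dry_mass_g"]
    if invalid.any():
        for _, r in df.loc[invalid].iterrows():
            logger.warning(
                "excluding core %s/%s layer %s: ash %.4f g > dry %.4f g",
                r["site"], r["core_id"], r["layer"], r["ash_mass_g"], r["dry_mass_g"],
            )
        df = df.loc[~invalid]
    df = df.assign(
        afdm_g=df["dry_mass_g"] - df["ash_mass_g"],
        density_gm2=lambda d: d["afdm_g"] / d["core_area_m2"],
    )
    wide = (
        df.pivot_table(
            index=["site", "core_id"], columns="layer", values="density_gm2", aggfunc="first"
        )
        .reindex(columns=list(LAYERS))
        .rename(columns={"top": "top_gm2", "bottom": "bottom_gm2"})
        .reset_index()
    )
    wide.columns.name = None
    both = wide["top_gm2"].notna() & wide["bottom_gm2"].notna()
    total = wide["top_gm2"] + wide["bottom_gm2"]
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * wide["bottom_gm2"] / total
    pct[~both | (total == 0)] = np.nan
    empty = both & (total == 0)
    for _, r in wide.loc[empty].iterrows():
        logger.info("core %s/%s has zero AFDM in both layers; excluded from bottom-%%", r["site"], r["core_id"])
    wide["bottom_pct"] = pct
    return wide


def _mean_sd(values: pd.Series) -> tuple[float, float]:
    vals = values.dropna()
    n = len(vals)
    if n == 0:
        return float("nan"), float("nan")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if n > 1 else 0.0
    return mean, sd


def summarize_site(cores: pd.DataFrame, site: str | None = None) -> dict:
    """Summary statistics for one site's cores.

    ``cores`` is either tidy (site/core_id/layer/masses) or already the
    wide per-core density table.  Returns per-layer mean and sample SD
    (ddof=1) of density and the mean/SD of the per-core bottom
    percentage; single-core sites report SD 0 with ``sd_defined=False``.
    """
    if "layer" in cores.columns:
        wide = cores_to_wide(cores)
    else:
        wide = cores
    if site is not None:
        wide = wide[wide["site"] == site]
    if len(wide) == 0:
        raise ValueError("no cores to summarize")
    top_mean, top_sd = _mean_sd(wide["top_gm2"])
    bottom_mean, bottom_sd = _mean_sd(wide["bottom_gm2"])
    pct_mean, pct_sd = _mean_sd(wide["bottom_pct"])
    return {
        "site": site if site is not None else str(wide["site"].iloc[0]),
        "n_cores": int(len(wide)),
        "top_mean": top_mean,
        "top_sd": top_sd,
        "bottom_mean": bottom_mean,
        "bottom_sd": bottom_sd,
        "bottom_pct_mean": pct_mean,
        "bottom_pct_sd": pct_sd,
        "sd_defined": len(wide) > 1,
    }


def summarize_benthos(cores: pd.DataFrame) -> pd.DataFrame:
    """Per-site summary table over all sites present in ``cores``."""
    wide = cores_to_wide(cores) if "layer" in cores.columns else cores
    rows = [summarize_site(wide[wide["site"] == s], site=s) for s in sorted(wide["site"].unique())]
    return pd.DataFrame(rows)
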