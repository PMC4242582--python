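"""Synthetic winter-survey generator.

Builds complete synthetic studies — sites along a temperature/distance
gradient, two-layer benthic cores, sex-ratio scan sessions and
abdominal-profile scores — under a named generative hypothesis, so the
whole pipeline can be exercised and calibrated without field data.

Hypotheses
----------
``resource_partitioning``
    The per-site odds of a scanned bird being female follow the share
    of benthic biomass buried in the deep (probe-only) layer:
    logit pF = alpha + beta * (bottom share).
``bergmann``
    The odds follow the standardized wintering cost of the site
    (colder, costlier sites hold more of the larger sex).
``null``
    A constant logit (default 0: even sex ratio everywhere).

Benthos model
-------------
Site i draws a bottom share s_i (logit-normal) and a total AFDM
density T_i (lognormal, with a positive loading of the bottom share on
log-total: bottom-heavy flats are also biomass-rich, as the deep-living
large polychaetes dominate mass).  Layer expectations are T_i*(1-s_i)
(top) and T_i*s_i (bottom).  Each core multiplies both layers by a
shared lognormal core factor plus independent layer noise, giving the
positive core-level correlation between layers observed in the field
(about r = 0.5) while leaving the *share* free to drive sex ratios.

Determinism: every stage draws from its own stream spawned from the
root seed, so a fixed scenario yields byte-identical tables and stages
can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from . import benthos as _benthos
from . import energetics as _energetics

__all__ = [
    "Scenario",
    "lognormal_params_from_moments",
    "make_sites",
    "make_benthos",
    "make_counts",
    "make_aps",
    "generate",
    "write_dataset",
]

HYPOTHESES = ("resource_partitioning", "bergmann", "null")

_STREAMS = ("sites", "benthos", "counts", "aps")


@dataclass(frozen=True)
class Scenario:
    """Parameters of one synthetic study.

    Survey-scale defaults mirror the field campaign: 6 sites spanning
    0-7 degC and 1940-3093 km from the breeding grounds, 10 cores and
    10 scan sessions per site, scan sizes 117 +/- 108.4 (truncated at
    10 birds).
    """

    hypothesis: str = "resource_partitioning"
    n_sites: int = 6
    n_cores_per_site: int = 10
    n_sessions_per_site: int = 10
    seed: int = 0

    # scan sessions
    session_size_mean: float = 117.0
    session_size_sd: float = 108.4
    session_size_floor: int = 10
    overdispersion_sd: float = 0.0  # extra per-session logit SD

    # sex-ratio links (logit scale)
    rp_intercept: float = -2.9
    rp_slope: float = 4.0  # per unit bottom share (0-1)
    bergmann_intercept: float = 0.0
    bergmann_slope: float = 1.0  # per SD of site wintering cost
    null_intercept: float = 0.0

    # climate / geography gradient
    t_air_range: tuple = (0.0, 7.0)
    distance_range: tuple = (1940.0, 3093.0)
    t_air_jitter_sd: float = 0.5
    wind_range: tuple = (4.0, 8.0)
    radiation_range: tuple = (30.0, 80.0)

    # benthos structure
    total_density_meanlog: float = float(np.log(7.0))  # g AFDM/m^2
    total_density_sdlog: float = 0.4
    bottom_share_logit_mean: float = 1.1  # share ~ 0.75
    bottom_share_logit_sd: float = 1.3
    share_total_coupling: float = 0.65  # loading of logit share on log total
    core_shared_sdlog: float = 0.7  # shared core factor (both layers)
    core_layer_sdlog: float = 0.2  # independent per-layer noise
    ash_fraction_range: tuple = (0.1, 0.3)
    core_area_m2: float = _benthos.DEFAULT_CORE_AREA
    #: optional explicit per-site layer parameters: a list of
    #: {"top": (meanlog, sdlog), "bottom": (meanlog, sdlog)} dicts,
    #: one per site, overriding the share/total model (used for
    #: moment-matched generation against published site rows).
    benthos_params: Optional[tuple] = None

    # abdominal profile scores
    n_aps_per_group: int = 50
    aps_intercept: float = 3.0
    aps_cost_slope: float = 0.4  # per SD of sex-site wintering cost
    aps_male_effect: float = -0.2
    aps_interaction: float = 0.25  # males steepen with cost
    aps_sd: float = 1.0
    aps_cuts: tuple = (1.5, 2.5, 3.5, 4.5)

    def __post_init__(self) -> None:
        if self.hypothesis not in HYPOTHESES:
            raise ValueError(f"hypothesis must be one of {HYPOTHESES}")
        if min(self.n_sites, self.n_cores_per_site, self.n_sessions_per_site) < 1:
            raise ValueError("counts must be >= 1")
        if self.session_size_floor < 10:
            raise ValueError("session_size_floor below 10 risks degenerate logits")

    def streams(self) -> dict[str, np.random.Generator]:
        """Named per-stage generators spawned from the root seed."""
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))
        return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def lognormal_params_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """(meanlog, sdlog) of the lognormal with the given mean and SD."""
    if mean <= 0:
        raise ValueError("mean must be > 0")
    cv2 = (sd / mean) ** 2
    sdlog = float(np.sqrt(np.log1p(cv2)))
    meanlog = float(np.log(mean) - sdlog**2 / 2.0)
    return meanlog, sdlog


def make_sites(scenario: Scenario, rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Site table: distances ascending, temperature rising with distance
    (colder sites are closer to the Arctic breeding grounds), wind and
    radiation uniform over their configured ranges."""
    rng = rng if rng is not None else scenario.streams()["sites"]
    d_lo, d_hi = scenario.distance_range
    t_lo, t_hi = scenario.t_air_range
    dist = np.sort(rng.uniform(d_lo, d_hi, scenario.n_sites))
    frac = (dist - d_lo) / (d_hi - d_lo) if d_hi > d_lo else np.zeros_like(dist)
    t_air = t_lo + frac * (t_hi - t_lo) + rng.normal(0.0, scenario.t_air_jitter_sd, scenario.n_sites)
    t_air = np.clip(t_air, t_lo, t_hi)
    return pd.DataFrame(
        {
            "site": [f"S{i + 1}" for i in range(scenario.n_sites)],
            "distance_km_override": dist,
            "t_air_c": t_air,
            "wind_ms": rng.uniform(*scenario.wind_range, scenario.n_sites),
            "radiation_wm2": rng.uniform(*scenario.radiation_range, scenario.n_sites),
        }
    )


def make_benthos(
    scenario: Scenario,
    sites: pd.DataFrame,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Tidy core records (site, core_id, layer, dry/ash mass, area)."""
    rng = rng if rng is not None else scenario.streams()["benthos"]
    rows = []
    sigma_f, sigma_e = scenario.core_shared_sdlog, scenario.core_layer_sdlog
    # mean-one correction for the per-core lognormal noise
    corr = (sigma_f**2 + sigma_e**2) / 2.0
    for i, site in enumerate(sites["site"]):
        if scenario.benthos_params is not None:
            params = scenario.benthos_params[i]
            ml_top, sl_top = params["top"]
            ml_bot, sl_bot = params["bottom"]
            top = rng.lognormal(ml_top, sl_top, scenario.n_cores_per_site)
            bottom = rng.lognormal(ml_bot, sl_bot, scenario.n_cores_per_site)
        else:
            logit_s = rng.normal(
                scenario.bottom_share_logit_mean, scenario.bottom_share_logit_sd
            )
            share = 1.0 / (1.0 + np.exp(-logit_s))
            ln_total = (
                scenario.total_density_meanlog
                + scenario.share_total_coupling * (logit_s - scenario.bottom_share_logit_mean)
                + rng.normal(0.0, scenario.total_density_sdlog)
            )
            total = np.exp(ln_total)
            f_core = rng.normal(0.0, sigma_f, scenario.n_cores_per_site)
            e_top = rng.normal(0.0, sigma_e, scenario.n_cores_per_site)
            e_bot = rng.normal(0.0, sigma_e, scenario.n_cores_per_site)
            top = total * (1.0 - share) * np.exp(f_core + e_top - corr)
            bottom = total * share * np.exp(f_core + e_bot - corr)
        for c in range(scenario.n_cores_per_site):
            for layer, dens in (("top", top[c]), ("bottom", bottom[c])):
                afdm_g = dens * scenario.core_area_m2
                ash_frac = rng.uniform(*scenario.ash_fraction_range)
                dry = afdm_g / (1.0 - ash_frac)
                rows.append(
                    {
                        "site": site,
                        "core_id": f"{site}-c{c + 1:02d}",
                        "layer": layer,
                        "dry_mass_g": dry,
                        "ash_mass_g": dry - afdm_g,
                        "core_area_m2": scenario.core_area_m2,
                    }
                )
    return pd.DataFrame(rows)


def _site_pf(scenario: Scenario, sites, benthos_summary, costs) -> np.ndarray:
    """True per-site probability that a scanned bird is female."""
    if scenario.hypothesis == "null":
        eta = np.full(len(sites), scenario.null_intercept)
    elif scenario.hypothesis == "resource_partitioning":
        if benthos_summary is None:
            raise ValueError("resource_partitioning link needs a benthos summary")
        share = (
            benthos_summary.set_index("site")
            .loc[sites["site"], "bottom_pct_mean"]
            .to_numpy(dtype=float)
            / 100.0
        )
        eta = scenario.rp_intercept + scenario.rp_slope * share
    else:  # bergmann
        if costs is None:
            raise ValueError("bergmann link needs a cost table")
        site_cost = (
            costs.groupby("site")["seasonal_total_kj"].mean().loc[sites["site"]].to_numpy()
        )
        sd = site_cost.std(ddof=0)
        z = (site_cost - site_cost.mean()) / sd if sd > 0 else np.zeros_like(site_cost)
        eta = scenario.bergmann_intercept + scenario.bergmann_slope * z
    return 1.0 / (1.0 + np.exp(-eta))


def make_counts(
    scenario: Scenario,
    sites: pd.DataFrame,
    benthos_summary: Optional[pd.DataFrame] = None,
    costs: Optional[pd.DataFrame] = None,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Scan sessions: sizes from a truncated normal, female counts
    binomial around the hypothesis-specific site probability."""
    rng = rng if rng is not None else scenario.streams()["counts"]
    pf = _site_pf(scenario, sites, benthos_summary, costs)
    a = (scenario.session_size_floor - scenario.session_size_mean) / scenario.session_size_sd
    rows = []
    for i, site in enumerate(sites["site"]):
        sizes = stats.truncnorm.rvs(
            a,
            np.inf,
            loc=scenario.session_size_mean,
            scale=scenario.session_size_sd,
            size=scenario.n_sessions_per_site,
            random_state=rng,
        )
        sizes = np.maximum(np.rint(sizes).astype(int), scenario.session_size_floor)
        eta = np.log(pf[i] / (1.0 - pf[i]))
        if scenario.overdispersion_sd > 0:
            eta = eta + rng.normal(0.0, scenario.overdispersion_sd, scenario.n_sessions_per_site)
        else:
            eta = np.full(scenario.n_sessions_per_site, eta)
        p_sess = 1.0 / (1.0 + np.exp(-eta))
        n_f = rng.binomial(sizes, p_sess)
        for j in range(scenario.n_sessions_per_site):
            rows.append(
                {
                    "site": site,
                    "session_id": f"{site}-s{j + 1:02d}",
                    "n_male": int(sizes[j] - n_f[j]),
                    "n_female": int(n_f[j]),
                }
            )
    return pd.DataFrame(rows)


def make_aps(
    scenario: Scenario,
    sites: pd.DataFrame,
    costs: pd.DataFrame,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Abdominal-profile records from a discretized latent Gaussian.

    Latent mean = a + b*cost_z + c*male + d*(cost_z*male), with the
    wintering cost standardized across the sex-site table; the latent
    value is cut at ``aps_cuts`` into scores 1-5.
    """
    rng = rng if rng is not None else scenario.streams()["aps"]
    tab = costs[["site", "sex", "seasonal_total_kj"]].copy()
    sd = tab["seasonal_total_kj"].std(ddof=0)
    mu = tab["seasonal_total_kj"].mean()
    tab["cost_z"] = (tab["seasonal_total_kj"] - mu) / sd if sd > 0 else 0.0
    cuts = np.asarray(scenario.aps_cuts, dtype=float)
    rows = []
    for rec in tab.to_dict("records"):
        male = 1.0 if rec["sex"] == "male" else 0.0
        mean = (
            scenario.aps_intercept
            + scenario.aps_cost_slope * rec["cost_z"]
            + scenario.aps_male_effect * male
            + scenario.aps_interaction * rec["cost_z"] * male
        )
        latent = rng.normal(mean, scenario.aps_sd, scenario.n_aps_per_group)
        scores = 1 + (latent[:, None] > cuts[None, :]).sum(axis=1)
        for s in scores:
            rows.append({"site": rec["site"], "sex": rec["sex"], "score": int(s)})
    return pd.DataFrame(rows)


def generate(scenario: Scenario) -> dict:
    """Full synthetic study: sites, cores, counts, APS records, plus the
    derived benthos summary and cost table used by the links.

    Pure function of the scenario (including its seed).
    """
    streams = scenario.streams()
    sites = make_sites(scenario, streams["sites"])
    cores = make_benthos(scenario, sites, streams["benthos"])
    summary = _benthos.summarize_benthos(cores)
    costs = _energetics.cost_table(sites)
    counts = make_counts(scenario, sites, summary, costs, streams["counts"])
    aps = make_aps(scenario, sites, costs, streams["aps"])
    return {
        "scenario": scenario,
        "sites": sites,
        "cores": cores,
        "benthos_summary": summary,
        "costs": costs,
        "counts": counts,
        "aps": aps,
    }


def write_dataset(data: dict, outdir) -> dict:
    """Write the four input CSVs plus a scenario echo (JSON) to
    ``outdir``; returns the paths."""
    import json
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in ("sites", "cores", "counts", "aps"):
        p = outdir / f"{name}.csv"
        data[name].to_csv(p, index=False)
        paths[name] = str(p)
    echo = asdict(data["scenario"])
    echo = {k: (list(v) if isinstance(v, tuple) else v) for k, v in echo.items()}
    p = outdir / "scenario.json"
    with open(p, "w") as fh:
        json.dump(echo, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["scenario"] = str(p)
    return paths
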