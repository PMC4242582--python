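"""Packaged study-site fixtures.

Six intertidal wintering areas of the European bar-tailed godwit
population, spanning the species' NW-European winter range: one-way
distance to the Norwegian breeding grounds, layered benthic biomass
summaries (ash-free dry mass, AFDM) and mean winter temperature, plus
the site coordinates in decimal degrees (converted from degree-minute
notation).

Wind speed and global radiation were not published per site; the
helper :func:`site_table` fills them with assumed representative
NW-European winter values (6 m/s, 50 W/m^2) unless told otherwise.
"""

from __future__ import annotations

import io

import pandas as pd

__all__ = ["site_characteristics", "site_table", "peck_probe_success", "SITE_COORDS"]

# Published site characteristics: distance to the breeding grounds (km),
# per-layer AFDM density mean +/- SD (g/m^2), percentage of AFDM in the
# bottom layer, and mean winter temperature (degC).
_SITE_CSV = """\
site,distance_km,top_mean,top_sd,bottom_mean,bottom_sd,bottom_pct_mean,bottom_pct_sd,t_air_c
Sylt-Romo Wadden Sea,1940,1.73,0.94,14.85,13.40,80.09,24.07,0
Western Wadden Sea,2196,1.42,1.35,8.06,5.32,89.02,9.65,2
The Wash,2357,1.58,1.31,2.22,1.94,64.99,16.98,4
Dutch Delta,2388,1.11,0.67,7.82,6.58,75.28,25.61,3
Dublin bay,2502,0.47,0.65,7.35,2.96,93.25,10.13,5
Re island,3093,0.39,0.26,1.75,2.26,80.79,22.33,7
"""

#: Decimal-degree coordinates (lat, lon) of the six study sites.
SITE_COORDS = {
    "Sylt-Romo Wadden Sea": (55.0 + 1.0 / 60.0, 8.0 + 26.0 / 60.0),
    "Western Wadden Sea": (53.0 + 14.0 / 60.0, 5.0 + 15.0 / 60.0),
    "The Wash": (52.0 + 56.0 / 60.0, 0.0 + 19.0 / 60.0),
    "Dutch Delta": (51.0 + 40.0 / 60.0, 4.0 + 7.0 / 60.0),
    "Dublin bay": (53.0 + 19.0 / 60.0, -(6.0 + 11.0 / 60.0)),
    "Re island": (46.0 + 15.0 / 60.0, -(1.0 + 29.0 / 60.0)),
}

# Foraging success (%) of pecks (surface contact) versus probes (deep
# insertion) per sex, with sample sizes: the behavioural basis for
# splitting benthic cores into a peck-accessible top layer and a
# probe-only bottom layer.
_PECK_PROBE = {
    "sex": ["male", "female"],
    "pct_successful_pecks": [67, 13],
    "n_pecks": [425, 42],
    "pct_successful_probes": [33, 87],
    "n_probes": [120, 124],
}


def site_characteristics() -> pd.DataFrame:
    """The published per-site summary table (distances, layered biomass,
    bottom-layer percentage, winter temperature)."""
    return pd.read_csv(io.StringIO(_SITE_CSV))


def site_table(wind_ms: float = 6.0, radiation_wm2: float = 50.0) -> pd.DataFrame:
    """Site table ready for :func:`limosa.energetics.cost_table`.

    Adds coordinates, the published distance as ``distance_km_override``
    and assumed climate forcing columns (wind and radiation are not
    published per site; defaults are representative winter values).
    """
    df = site_characteristics()
    df["lat"] = df["site"].map(lambda s: SITE_COORDS[s][0])
    df["lon"] = df["site"].map(lambda s: SITE_COORDS[s][1])
    df["wind_ms"] = float(wind_ms)
    df["radiation_wm2"] = float(radiation_wm2)
    df["distance_km_override"] = df["distance_km"].astype(float)
    return df


def peck_probe_success() -> pd.DataFrame:
    """Per-sex peck/probe foraging success percentages."""
    return pd.DataFrame(_PECK_PROBE)
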