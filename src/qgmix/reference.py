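"""Published reference values from the motivating cohort analysis.

The package's synthetic-data generators are calibrated against a published
analysis of air-pollutant mixtures and self-reported psoriasis/eczema in a
cohort of 9,060 adults (mostly North Carolina residents).  Three groups of
constants are frozen here:

* cohort demographic marginals (age, sex, smoking, income, family history,
  outcome prevalence),
* cross-sectional summary statistics of the 17 exposure variables
  (7 PM2.5 species, 5 criteria pollutants, 4 BTEX point-source burdens,
  and road density within 5 km), with their units,
* the published logistic quantile g-computation estimates (odds ratios per
  octile increment, covariate odds ratios, the mixture odds ratio psi, and
  signed mixture weights), used as plantable generating truth.

Everything downstream (presets, calibration targets, acceptance checks)
reads these tables rather than re-declaring numbers.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

#: Canonical exposure column order; all exposure matrices use this order.
EXPOSURE_COLUMNS: list[str] = [
    "nh4",
    "black_carbon",
    "nitrate",
    "organic_matter",
    "so4",
    "sea_salt",
    "soil",
    "co",
    "no2",
    "o3",
    "pm10",
    "so2",
    "benzene",
    "ethylbenzene",
    "toluene",
    "xylene",
    "road_density",
]

#: PM2.5 compositional species delivered as gridded annual surfaces.
GRID_POLLUTANTS: list[str] = [
    "nh4",
    "black_carbon",
    "nitrate",
    "organic_matter",
    "so4",
    "sea_salt",
    "soil",
]

#: Criteria pollutants delivered as census-tract-style centroid values.
CENTROID_POLLUTANTS: list[str] = ["co", "no2", "o3", "pm10", "so2"]

#: Volatile organics accumulated from industrial point sources.
BTEX_CHEMICALS: list[str] = ["benzene", "ethylbenzene", "toluene", "xylene"]

#: Covariate order used in the adjusted model (income is a sensitivity add-on).
COVARIATE_COLUMNS: list[str] = [
    "smoked_100",
    "age",
    "sex_male",
    "family_ra",
    "other_ai",
]

# Cross-sectional mean/SD/range of each exposure in the reference cohort.
# BTEX burdens are decayed source masses summed within a 5 km buffer.
_EXPOSURE_ROWS = [
    # column, mean, sd, min, max, unit
    ("nh4", 1.050, 0.160, 0.147, 2.13, "ug/m3"),
    ("black_carbon", 0.785, 0.120, 0.212, 3.023, "ug/m3"),
    ("nitrate", 0.722, 0.297, 0.041, 5.459, "ug/m3"),
    ("organic_matter", 3.437, 0.522, 1.000, 10.182, "ug/m3"),
    ("so4", 3.154, 0.390, 0.323, 4.459, "ug/m3"),
    ("sea_salt", 0.286, 0.150, 0.012, 2.723, "ug/m3"),
    ("soil", 0.442, 0.116, 0.118, 2.894, "ug/m3"),
    ("co", 0.343, 0.059, 0.208, 0.757, "ppm"),
    ("no2", 6.891, 2.664, 1.394, 29.393, "ppb"),
    ("o3", 42.691, 7.719, 29.480, 60.012, "ppb"),
    ("pm10", 15.265, 4.416, 5.444, 44.959, "ug/m3"),
    ("so2", 1.874, 0.785, 0.708, 7.067, "ppb"),
    ("benzene", 19.820, 235.69, 0.0, 12643.11, "lb per 5 km radius"),
    ("ethylbenzene", 33.49, 372.06, 0.0, 14947.96, "lb per 5 km radius"),
    ("toluene", 839.47, 5268.06, 0.0, 181626.3, "lb per 5 km radius"),
    ("xylene", 356.90, 1715.24, 0.0, 47517.2, "lb per 5 km radius"),
    ("road_density", 1444.89, 1505.21, 0.0, 10530.76, "km"),
]

EXPOSURE_STATS: pd.DataFrame = pd.DataFrame(
    _EXPOSURE_ROWS, columns=["column", "mean", "sd", "min", "max", "unit"]
).set_index("column")

# Demographic marginals of the reference cohort (n = 9060 adults).
# p_other_ai: the published table reports 35.5% with *any* autoimmune disease
# including the 12.5% with the skin outcome; the marginal of the "any other
# autoimmune disease" covariate is not printed.  0.30 is a declared default
# between the disjoint-overlap bound (0.23) and the any-AI marginal (0.355).
REFERENCE_COHORT: dict[str, float] = {
    "n": 9060,
    "age_mean": 42.42,
    "age_sd": 15.84,
    "p_female": 0.671,
    "p_smoke": 0.395,
    "p_family_ra": 0.076,
    "p_other_ai": 0.30,
    "p_income": 0.734,
    "prevalence": 0.125,
}

# Published per-octile odds ratios for the 17 mixture components.
MIXTURE_OR: dict[str, float] = {
    "nh4": 0.976,
    "black_carbon": 1.004,
    "nitrate": 0.988,
    "organic_matter": 0.988,
    "so4": 1.059,
    "sea_salt": 1.023,
    "soil": 1.027,
    "co": 1.005,
    "no2": 0.995,
    "o3": 0.995,
    "pm10": 0.999,
    "so2": 1.019,
    "benzene": 1.019,
    "ethylbenzene": 1.025,
    "toluene": 1.003,
    "xylene": 0.988,
    "road_density": 1.007,
}

# Published signed mixture weights (positive weights sum to 1, negative
# to -1).  NOTE: the published pm10 row is internally inconsistent -- its
# printed weight (-0.1322) implies an odds ratio of ~0.989, not the printed
# 0.999 (whose log would give a weight of only -0.012).  Both printed values
# are kept verbatim; weight-recomputation checks treat pm10 separately.
MIXTURE_WEIGHTS: dict[str, float] = {
    "nh4": -0.3021,
    "black_carbon": 0.0195,
    "nitrate": -0.1437,
    "organic_matter": -0.1475,
    "so4": 0.3028,
    "sea_salt": 0.1226,
    "soil": 0.1406,
    "co": 0.0276,
    "no2": -0.0560,
    "o3": -0.0660,
    "pm10": -0.1322,
    "so2": 0.0992,
    "benzene": 0.1027,
    "ethylbenzene": 0.1320,
    "toluene": 0.0143,
    "xylene": -0.1525,
    "road_density": 0.0385,
}

# As MIXTURE_OR but with pm10 replaced by the value its printed weight
# implies (~0.989).  With this correction every recomputed signed weight
# agrees with the printed weight column to within rounding (0.01), and the
# log odds ratios sum to ~ln(1.10), the printed mixture OR -- both strong
# indications that the printed pm10 OR of 0.999 is a typo.  Used as the
# internally coherent planted truth for per-component simulations.
MIXTURE_OR_CONSISTENT: dict[str, float] = {**MIXTURE_OR, "pm10": 0.989}

# Published covariate odds ratios (age is per year of age).
COVARIATE_OR: dict[str, float] = {
    "smoked_100": 1.164,
    "age": 0.992,
    "sex_male": 0.812,
    "family_ra": 1.210,
    "other_ai": 1.678,
}

#: Published intercept odds ratio.
INTERCEPT_OR: float = 0.115

#: Published mixture odds ratio per joint one-octile increase (psi).
PSI_OR: float = 1.10
PSI_CI: tuple[float, float] = (1.028, 1.174)
PSI_P: float = 5.39e-3

#: Published drop in psi (log-odds scale) when sulfate is removed.
PSI_DROP_WITHOUT_SO4: float = 0.02

#: Years over which annual surfaces/centroid values are averaged.
EXPOSURE_YEARS: list[int] = list(range(2000, 2016))

#: Years over which point-source annual release masses are averaged.
SOURCE_YEARS: list[int] = list(range(2000, 2017))


def mixture_log_odds(consistent: bool = False) -> pd.Series:
    """Natural logs of the published mixture odds ratios, canonical order.

    ``consistent=True`` uses the pm10 correction (see
    :data:`MIXTURE_OR_CONSISTENT`)."""
    source = MIXTURE_OR_CONSISTENT if consistent else MIXTURE_OR
    return pd.Series(
        {c: math.log(source[c]) for c in EXPOSURE_COLUMNS}, name="beta"
    )


def default_correlation(columns: list[str] | None = None) -> pd.DataFrame:
    """Default inter-pollutant correlation matrix (latent Gaussian scale).

    The published analysis does not print a correlation matrix; this is a
    declared block structure: PM2.5 species correlate 0.5 among themselves,
    criteria pollutants 0.4, BTEX 0.6 (shared industrial sources), with
    weaker cross-block links concentrated on traffic-related pairs
    (CO, NO2, BTEX, road density).
    """
    cols = EXPOSURE_COLUMNS if columns is None else columns
    full = pd.DataFrame(0.15, index=EXPOSURE_COLUMNS, columns=EXPOSURE_COLUMNS)
    blocks = {
        tuple(GRID_POLLUTANTS): 0.5,
        tuple(CENTROID_POLLUTANTS): 0.4,
        tuple(BTEX_CHEMICALS): 0.6,
    }
    for block, rho in blocks.items():
        for a in block:
            for b in block:
                full.loc[a, b] = rho
    for a in GRID_POLLUTANTS:
        for b in CENTROID_POLLUTANTS:
            full.loc[a, b] = full.loc[b, a] = 0.25
    traffic = ["co", "no2"]
    for a in BTEX_CHEMICALS:
        for b in traffic:
            full.loc[a, b] = full.loc[b, a] = 0.3
    for b in traffic + BTEX_CHEMICALS:
        full.loc["road_density", b] = full.loc[b, "road_density"] = 0.35
    for b in ["o3", "pm10", "so2"]:
        full.loc["road_density", b] = full.loc[b, "road_density"] = 0.2
    np.fill_diagonal(full.values, 1.0)
    out = full.loc[cols, cols].copy()
    return out
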