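"""Synthetic exposure landscapes and a direct exposure sampler.

Two routes produce the 17-column exposure matrix:

1. :func:`generate_landscape` + :func:`link_exposures` -- the full spatial
   route.  Gridded pollutant surfaces are Gaussian-smoothed white-noise
   fields, cross-correlated through a shared latent mixing matrix and
   rescaled to the published cross-sectional means/SDs; tract-style
   centroids carry the criteria pollutants; BTEX point sources follow a
   homogeneous Poisson process with log-normal annual masses and bounded
   active-year windows; roads are random straight segments.  Source masses
   and road counts are calibrated so the population-density-weighted mean
   burden matches the published means.

2. :func:`sample_exposure_matrix` -- a fast distributional sampler (Gaussian
   copula with published means/SDs, zero-inflated log-normal BTEX burdens,
   log-normal road density) used when the spatial machinery itself is not
   under study, e.g. replicated parameter-recovery experiments.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.ndimage import gaussian_filter

from . import reference
from .cohort import ParameterError, SpatialLayout
from .linkage import (
    CentroidSet,
    DecayParams,
    PointSourceSet,
    RoadSegmentSet,
    _disc_segment_pairs,
    assemble_exposure_matrix,
    decayed_source_exposure,
    extract_grid_values,
    multi_year_mean,
    nearest_centroid_link,
    road_density,
)
from .spatial_io import Grid

logger = logging.getLogger(__name__)


def _check_correlation(corr: pd.DataFrame) -> None:
    a = corr.to_numpy(float)
    if not np.allclose(a, a.T, atol=1e-12):
        raise ParameterError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(a), 1.0, atol=1e-12):
        raise ParameterError("correlation matrix must have unit diagonal")
    if np.linalg.eigvalsh(a).min() < -1e-10:
        raise ParameterError("correlation matrix must be positive semi-definite")


def _mixing_cholesky(corr: pd.DataFrame) -> np.ndarray:
    a = corr.to_numpy(float)
    try:
        return np.linalg.cholesky(a)
    except np.linalg.LinAlgError:
        # PSD but singular: fall back to an eigendecomposition square root
        w, v = np.linalg.eigh(a)
        return v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


@dataclass(frozen=True)
class LandscapeParams:
    """Everything the spatial generator needs; defaults match the published
    cross-sectional exposure summary over a 400 x 300 km domain."""

    layout: SpatialLayout = SpatialLayout()
    cell_km: float = 10.0
    years: tuple[int, ...] = tuple(reference.EXPOSURE_YEARS)
    source_years: tuple[int, ...] = tuple(reference.SOURCE_YEARS)
    stats: pd.DataFrame = field(
        default_factory=lambda: reference.EXPOSURE_STATS[["mean", "sd"]].copy()
    )
    correlation: pd.DataFrame | None = None
    spatial_range_km: float = 25.0       # autocorrelation scale of the fields
    year_sd_frac: float = 0.2            # year-to-year wiggle as fraction of SD
    n_centroids: int = 2000
    site_intensity: float = 0.02         # industrial sites per km^2
    chem_prob: float = 0.85              # P(site releases a given chemical)
    mass_log_sd: float = 1.0             # dispersion of annual release masses
    mass_year_jitter: float = 0.2
    segment_length_mean_km: float = 15.0
    segment_length_max_km: float = 30.0
    calibrate: bool = True               # rescale fields/burdens/roads to targets
    n_ref_field: int = 20000
    n_ref_btex: int = 40000
    n_ref_road: int = 3000

    def validate(self) -> None:
        if (self.stats["sd"] < 0).any():
            raise ParameterError("all SD targets must be >= 0")
        if self.cell_km <= 0:
            raise ParameterError("cell_km must be > 0")
        if self.site_intensity < 0:
            raise ParameterError("site_intensity must be >= 0")
        if self.correlation is not None:
            _check_correlation(self.correlation)

    @property
    def grid_pollutants(self) -> list[str]:
        return [c for c in self.stats.index if c in reference.GRID_POLLUTANTS]

    @property
    def centroid_pollutants(self) -> list[str]:
        return [c for c in self.stats.index if c in reference.CENTROID_POLLUTANTS]

    @property
    def btex_chemicals(self) -> list[str]:
        return [c for c in self.stats.index if c in reference.BTEX_CHEMICALS]

    @property
    def has_roads(self) -> bool:
        return "road_density" in self.stats.index

    def field_correlation(self) -> pd.DataFrame:
        cols = self.grid_pollutants + self.centroid_pollutants
        if self.correlation is not None:
            return self.correlation.loc[cols, cols]
        return reference.default_correlation(cols)


@dataclass
class Landscape:
    """All spatial inputs the linkage stage consumes."""

    grids: dict[str, dict[int, Grid]]
    centroids: CentroidSet | None
    sources: PointSourceSet
    roads: RoadSegmentSet
    params: LandscapeParams


def _smoothed_standard_fields(
    k: int, ny: int, nx: int, sigma_cells: float, rng: np.random.Generator
) -> np.ndarray:
    """k independent smoothed white-noise fields, each standardized to
    zero mean / unit SD over the cells."""
    fields = rng.standard_normal((k, ny, nx))
    if sigma_cells > 0:
        fields = gaussian_filter(fields, sigma=(0, sigma_cells, sigma_cells),
                                 mode="reflect")
    m = fields.mean(axis=(1, 2), keepdims=True)
    s = fields.std(axis=(1, 2), keepdims=True)
    s[s == 0] = 1.0
    return (fields - m) / s


def _pollutant_fields(
    params: LandscapeParams, rng: np.random.Generator
) -> dict[str, dict[int, np.ndarray]]:
    """Per-pollutant per-year value arrays (south-up) for all field-borne
    pollutants, rescaled to target mean/SD and clipped at zero."""
    cols = params.grid_pollutants + params.centroid_pollutants
    if not cols:
        return {}
    lay = params.layout
    nx = max(int(round((lay.xmax - lay.xmin) / params.cell_km)), 1)
    ny = max(int(round((lay.ymax - lay.ymin) / params.cell_km)), 1)
    corr = params.field_correlation()
    _check_correlation(corr)
    mix = _mixing_cholesky(corr)
    sigma_cells = params.spatial_range_km / params.cell_km
    k = len(cols)
    base = np.einsum(
        "ij,jyx->iyx", mix, _smoothed_standard_fields(k, ny, nx, sigma_cells, rng)
    )
    n_years = len(params.years)
    means = params.stats.loc[cols, "mean"].to_numpy(float)
    sds = params.stats.loc[cols, "sd"].to_numpy(float)
    tau = params.year_sd_frac * sds
    # the *multi-year mean* surface should carry the target SD:
    # Var(mean over years) = c^2 + tau^2 / n_years = sd^2
    c = np.sqrt(np.clip(sds**2 - tau**2 / n_years, 0.0, None))
    out: dict[str, dict[int, np.ndarray]] = {col: {} for col in cols}
    for year in params.years:
        eta = np.einsum(
            "ij,jyx->iyx", mix, _smoothed_standard_fields(k, ny, nx, sigma_cells, rng)
        )
        for i, col in enumerate(cols):
            vals = means[i] + c[i] * base[i] + tau[i] * eta[i]
            out[col][year] = np.clip(vals, 0.0, None)
    return out


def _generate_sources(
    params: LandscapeParams, rng: np.random.Generator
) -> PointSourceSet:
    chems = params.btex_chemicals
    lay = params.layout
    n_sites = rng.poisson(params.site_intensity * lay.area) if chems else 0
    if n_sites == 0 or not chems:
        return PointSourceSet(
            table=pd.DataFrame(
                columns=["source_id", "x", "y", "chemical", "year", "mass_lb"]
            )
        )
    # homogeneous point process over the full extent
    xs = rng.uniform(lay.xmin, lay.xmax, n_sites)
    ys = rng.uniform(lay.ymin, lay.ymax, n_sites)
    start = rng.integers(params.source_years[0], params.source_years[0] + 9, n_sites)
    end = np.minimum(
        start + rng.integers(1, 18, n_sites), params.source_years[-1]
    )
    frames = []
    years = np.asarray(params.source_years)
    for chem in chems:
        has = rng.random(n_sites) < params.chem_prob
        idx = np.flatnonzero(has)
        if not len(idx):
            continue
        base_mass = rng.lognormal(0.0, params.mass_log_sd, len(idx))
        jitter = rng.lognormal(
            0.0, params.mass_year_jitter, (len(idx), len(years))
        )
        active = (years[None, :] >= start[idx, None]) & (
            years[None, :] <= end[idx, None]
        )
        mass = base_mass[:, None] * jitter * active
        frames.append(
            pd.DataFrame(
                {
                    "source_id": np.repeat(idx, len(years)),
                    "x": np.repeat(xs[idx], len(years)),
                    "y": np.repeat(ys[idx], len(years)),
                    "chemical": chem,
                    "year": np.tile(years, len(idx)),
                    "mass_lb": mass.ravel(),
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    return PointSourceSet(table=table)


def _generate_roads(
    params: LandscapeParams, rng: np.random.Generator, ref_points: np.ndarray
) -> RoadSegmentSet:
    if not params.has_roads:
        return RoadSegmentSet(
            table=pd.DataFrame(columns=["segment_id", "x1", "y1", "x2", "y2", "length"])
        )
    lay = params.layout
    target = float(params.stats.loc["road_density", "mean"])
    radius = 5.0
    disc_area = np.pi * radius**2
    n_needed = target * lay.area / (disc_area * params.segment_length_mean_km)
    n_pool = int(np.ceil(1.6 * n_needed)) if params.calibrate else int(
        np.ceil(n_needed)
    )
    cx = rng.uniform(lay.xmin, lay.xmax, n_pool)
    cy = rng.uniform(lay.ymin, lay.ymax, n_pool)
    theta = rng.uniform(0, np.pi, n_pool)
    length = np.clip(
        rng.exponential(params.segment_length_mean_km, n_pool),
        0.5,
        params.segment_length_max_km,
    )
    dx = 0.5 * length * np.cos(theta)
    dy = 0.5 * length * np.sin(theta)
    pool = pd.DataFrame(
        {
            "segment_id": np.arange(n_pool),
            "x1": cx - dx,
            "y1": cy - dy,
            "x2": cx + dx,
            "y2": cy + dy,
            "length": length,
        }
    )
    if not params.calibrate:
        return RoadSegmentSet(table=pool)
    # per-segment mean contribution to the reference-point density, then
    # keep the shortest prefix whose cumulative contribution hits target
    contrib = np.zeros(n_pool)
    pool_set = RoadSegmentSet(table=pool)
    for _, seg_idx, lengths in _disc_segment_pairs(ref_points, pool_set, radius):
        np.add.at(contrib, seg_idx, lengths)
    contrib /= len(ref_points)
    csum = np.cumsum(contrib)
    if csum[-1] < target:
        logger.warning(
            "road pool exhausted below target density (%.1f < %.1f)",
            csum[-1], target,
        )
        n_keep = n_pool
    else:
        n_keep = int(np.searchsorted(csum, target)) + 1
    return RoadSegmentSet(table=pool.iloc[:n_keep].reset_index(drop=True))


def generate_landscape(
    params: LandscapeParams, seed: int | np.random.SeedSequence
) -> Landscape:
    """Generate grids, centroids, point sources and roads for one study area.

    Randomness derives from named substreams of the given seed, so each
    ingredient is independently reproducible.
    """
    params.validate()
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    s_fields, s_centroids, s_sources, s_roads, s_ref = ss.spawn(5)
    fields = _pollutant_fields(params, np.random.default_rng(s_fields))
    lay = params.layout
    rng_ref = np.random.default_rng(s_ref)

    if params.calibrate and fields:
        # affinely rescale each pollutant's surfaces so that the multi-year
        # mean, sampled at residential-density-weighted reference points,
        # matches the target cross-sectional mean/SD (the published summary
        # describes the cohort's exposure distribution, not the raw cells)
        ref_field = lay.sample_points(params.n_ref_field, rng_ref)
        for col, per_year in fields.items():
            vals = np.column_stack(
                [
                    extract_grid_values(
                        Grid(v, xll=lay.xmin, yll=lay.ymin, cellsize=params.cell_km),
                        ref_field,
                    )
                    for v in per_year.values()
                ]
            )
            mym = vals.mean(axis=1)
            m_ref, s_ref_sd = float(mym.mean()), float(mym.std())
            tgt_m = float(params.stats.loc[col, "mean"])
            tgt_s = float(params.stats.loc[col, "sd"])
            scale = tgt_s / s_ref_sd if s_ref_sd > 0 and tgt_s > 0 else 1.0
            for year in per_year:
                per_year[year] = np.clip(
                    tgt_m + (per_year[year] - m_ref) * scale, 0.0, None
                )

    grids: dict[str, dict[int, Grid]] = {}
    for col in params.grid_pollutants:
        grids[col] = {
            year: Grid(
                values=vals, xll=lay.xmin, yll=lay.ymin, cellsize=params.cell_km
            )
            for year, vals in fields[col].items()
        }

    centroids = None
    if params.centroid_pollutants:
        rng_c = np.random.default_rng(s_centroids)
        xy = lay.sample_points(params.n_centroids, rng_c)
        values = {}
        for col in params.centroid_pollutants:
            mat = np.empty((len(xy), len(params.years)))
            for j, year in enumerate(params.years):
                g = Grid(
                    values=fields[col][year],
                    xll=lay.xmin,
                    yll=lay.ymin,
                    cellsize=params.cell_km,
                )
                mat[:, j] = extract_grid_values(g, xy)
            values[col] = mat
        centroids = CentroidSet(
            ids=np.arange(params.n_centroids),
            xy=xy,
            years=list(params.years),
            values=values,
        )

    sources = _generate_sources(params, np.random.default_rng(s_sources))
    ref_btex = lay.sample_points(params.n_ref_btex, rng_ref)
    ref_road = lay.sample_points(params.n_ref_road, rng_ref)

    if params.calibrate and len(sources) and params.btex_chemicals:
        decay = DecayParams()
        table = sources.table.copy()
        for chem in params.btex_chemicals:
            burden = decayed_source_exposure(ref_btex, sources, chem, decay)
            realized = float(burden.mean())
            target = float(params.stats.loc[chem, "mean"])
            if realized > 0:
                factor = target / realized
                table.loc[table["chemical"] == chem, "mass_lb"] *= factor
                logger.info(
                    "calibrated %s source masses by factor %.3g", chem, factor
                )
        sources = PointSourceSet(table=table)

    roads = _generate_roads(params, np.random.default_rng(s_roads), ref_road)
    return Landscape(
        grids=grids, centroids=centroids, sources=sources, roads=roads, params=params
    )


def link_exposures(
    cohort: pd.DataFrame,
    landscape: Landscape,
    decay: DecayParams = DecayParams(),
    allow_drop: bool = False,
) -> pd.DataFrame:
    """Run the full linkage chain for a cohort against a landscape.

    Nearest-centroid linkage for tract-level pollutants, raster extraction
    for gridded pollutants (both followed by the multi-year mean), decayed
    point-source burdens for BTEX, and 5 km road density; assembled into
    the canonical 17-column matrix keyed by participant id.
    """
    params = landscape.params
    pts = cohort[["x", "y"]].to_numpy(float)
    columns: dict[str, np.ndarray] = {}

    for col in params.grid_pollutants:
        per_year = np.column_stack(
            [
                extract_grid_values(landscape.grids[col][year], pts)
                for year in params.years
            ]
        )
        columns[col] = multi_year_mean(per_year)

    if landscape.centroids is not None and params.centroid_pollutants:
        link = nearest_centroid_link(pts, landscape.centroids)
        for col in params.centroid_pollutants:
            columns[col] = multi_year_mean(landscape.centroids.values[col][link])

    for chem in params.btex_chemicals:
        columns[chem] = decayed_source_exposure(pts, landscape.sources, chem, decay)

    if params.has_roads:
        columns["road_density"] = road_density(
            pts, landscape.roads, radius_km=decay.buffer_km
        )

    return assemble_exposure_matrix(cohort, columns, allow_drop=allow_drop)


def save_landscape(landscape: Landscape, out_dir) -> None:
    """Write a landscape as plain-text files: one ESRI ASCII grid per
    pollutant-year (``<pollutant>_<year>.asc``), a long-format centroid CSV,
    and GeoJSON sources/roads, plus a small metadata JSON."""
    import json
    from pathlib import Path

    from .spatial_io import (
        write_esri_ascii,
        write_roads_geojson,
        write_sources_geojson,
    )

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for col, per_year in landscape.grids.items():
        for year, grid in per_year.items():
            write_esri_ascii(grid, out / f"{col}_{year}.asc")
    if landscape.centroids is not None:
        landscape.centroids.to_csv(out / "centroids.csv")
    write_sources_geojson(landscape.sources.table, out / "sources.geojson")
    write_roads_geojson(landscape.roads.table, out / "roads.geojson")
    p = landscape.params
    meta = {
        "years": list(p.years),
        "grid_pollutants": p.grid_pollutants,
        "centroid_pollutants": p.centroid_pollutants,
        "btex_chemicals": p.btex_chemicals,
        "has_roads": p.has_roads,
        "cell_km": p.cell_km,
        "extent": [p.layout.xmin, p.layout.xmax, p.layout.ymin, p.layout.ymax],
    }
    (out / "landscape.json").write_text(json.dumps(meta, indent=2))


def load_landscape(in_dir) -> Landscape:
    """Read a landscape written by :func:`save_landscape`."""
    import json
    from pathlib import Path

    from .spatial_io import (
        read_esri_ascii,
        read_roads_geojson,
        read_sources_geojson,
    )

    src = Path(in_dir)
    meta = json.loads((src / "landscape.json").read_text())
    cols = (
        meta["grid_pollutants"]
        + meta["centroid_pollutants"]
        + meta["btex_chemicals"]
        + (["road_density"] if meta["has_roads"] else [])
    )
    params = dataclasses.replace(
        LandscapeParams(),
        stats=reference.EXPOSURE_STATS.loc[cols, ["mean", "sd"]].copy(),
        years=tuple(meta["years"]),
        cell_km=meta["cell_km"],
        layout=dataclasses.replace(
            SpatialLayout(),
            xmin=meta["extent"][0],
            xmax=meta["extent"][1],
            ymin=meta["extent"][2],
            ymax=meta["extent"][3],
        ),
    )
    grids = {
        col: {
            year: read_esri_ascii(src / f"{col}_{year}.asc")
            for year in meta["years"]
        }
        for col in meta["grid_pollutants"]
    }
    centroids = (
        CentroidSet.from_csv(src / "centroids.csv")
        if meta["centroid_pollutants"]
        else None
    )
    sources_df = read_sources_geojson(src / "sources.geojson")
    if sources_df.empty:
        sources_df = pd.DataFrame(
            columns=["source_id", "x", "y", "chemical", "year", "mass_lb"]
        )
    roads_df = read_roads_geojson(src / "roads.geojson")
    if roads_df.empty:
        roads_df = pd.DataFrame(
            columns=["segment_id", "x1", "y1", "x2", "y2", "length"]
        )
    return Landscape(
        grids=grids,
        centroids=centroids,
        sources=PointSourceSet(table=sources_df),
        roads=RoadSegmentSet(table=roads_df),
        params=params,
    )


def _zero_inflated_lognormal_params(
    mean: float, sd: float, p_zero: float
) -> tuple[float, float]:
    """(mu, sigma) of the positive log-normal part matching overall moments."""
    if not 0 <= p_zero < 1:
        raise ParameterError("p_zero must be in [0, 1)")
    m1 = mean / (1.0 - p_zero)
    m2 = (sd * sd + mean * mean) / (1.0 - p_zero)
    ratio = m2 / (m1 * m1)
    if ratio <= 1:
        raise ParameterError("sd too small for a zero-inflated log-normal")
    sigma2 = np.log(ratio)
    mu = np.log(m1) - sigma2 / 2.0
    return float(mu), float(np.sqrt(sigma2))


def sample_exposure_matrix(
    n: int,
    seed: int | np.random.SeedSequence,
    stats: pd.DataFrame | None = None,
    correlation: pd.DataFrame | None = None,
    btex_zero_prob: float = 0.45,
) -> pd.DataFrame:
    """Draw an n x 17 exposure matrix directly from the distributional model.

    A Gaussian copula carries the inter-pollutant correlation; marginals are
    normal (clipped at zero) for the 12 field-borne pollutants, zero-inflated
    log-normal for the BTEX burdens, and log-normal for road density, all
    matched to the published means/SDs.
    """
    stats = reference.EXPOSURE_STATS[["mean", "sd"]] if stats is None else stats
    cols = list(stats.index)
    corr = (
        reference.default_correlation(cols) if correlation is None else correlation
    )
    _check_correlation(corr)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, len(cols))) @ _mixing_cholesky(corr).T
    out = {}
    for j, col in enumerate(cols):
        mean = float(stats.loc[col, "mean"])
        sd = float(stats.loc[col, "sd"])
        if col in reference.BTEX_CHEMICALS:
            mu, sigma = _zero_inflated_lognormal_params(mean, sd, btex_zero_prob)
            u = sps.norm.cdf(z[:, j])
            pos = u >= btex_zero_prob
            vals = np.zeros(n)
            tail = (u[pos] - btex_zero_prob) / (1.0 - btex_zero_prob)
            tail = np.clip(tail, 1e-12, 1 - 1e-12)
            vals[pos] = np.exp(mu + sigma * sps.norm.ppf(tail))
            out[col] = vals
        elif col == "road_density":
            sigma2 = np.log(1.0 + (sd / mean) ** 2)
            mu = np.log(mean) - sigma2 / 2.0
            out[col] = np.exp(mu + np.sqrt(sigma2) * z[:, j])
        else:
            out[col] = np.clip(mean + sd * z[:, j], 0.0, None)
    return pd.DataFrame(out)
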