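"""Synthetic landscapes, climates and site records for desk-scale studies.

The generator emulates the statistical structure the model assumes about
its real inputs: a coherent land/sea domain with topography, twelve monthly
temperature and precipitation fields for a warm (interstadial-like) and a
cold (stadial-like) period, and presence-only site records sampled from a
known "true" existence-potential surface so that the full training pipeline
can be exercised as a parameter-recovery experiment. Synthetic and real
inputs are interchangeable downstream (same NetCDF/CSV containers).

The default cold period applies a uniform cooling and precipitation scaling
(stadials over the study region were much colder and drier); with the
default niche parameters this contracts habitable terrain toward warm,
low-elevation coastal cells, the refugial pattern the simulator is meant to
be exercised against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt, gaussian_filter, uniform_filter

from .bioclim import (DEFAULT_PREDICTORS, BioclimStack, MonthlyClimate,
                      Standardizer, compute_bioclim)
from .errors import ParameterError
from .hep import HepModelParams, ModFuncParams, accessible_hep
from .landscape_io import GridSpec, LandscapeBundle, SiteTable


@dataclass
class SynthSpec:
    """Parameters of the synthetic world (one seed reproduces everything)."""

    nx: int = 48
    ny: int = 48
    cell_size: float = 20.0
    lon_origin: float = -8.0
    lat_origin: float = 36.0
    land_frac: float = 0.6
    relief: float = 1200.0          # m, interior elevation amplitude
    coast_sigma: float = 3.0        # cells, coastline smoothness
    t_south: float = 16.0           # degC, sea-level annual mean at south edge
    merid_grad: float = 0.65        # degC per 100 km northward
    lapse: float = 6.5              # degC per km of elevation
    seasonal_amp: float = 7.0       # degC, annual half-range
    temp_noise: float = 0.4         # degC, smooth spatial noise
    precip_base: float = 45.0       # mm/month interior baseline
    precip_coast: float = 30.0      # mm/month coastal enhancement
    precip_orog: float = 15.0       # mm/month per km of elevation
    precip_seasonal: float = 0.5    # relative winter-peak amplitude
    precip_noise: float = 0.15      # relative smooth noise
    cold_dt: float = -5.0           # degC, stadial cooling
    cold_precip_scale: float = 0.6  # stadial drying factor
    n_sites: int = 200
    seed: int = 0

    def grid(self) -> GridSpec:
        return GridSpec(nx=self.nx, ny=self.ny, cell_size=self.cell_size,
                        lon_origin=self.lon_origin, lat_origin=self.lat_origin)


# "true" niche coefficients on the standardized default predictors
# (Bio1, Bio4, Bio16, Bio15, Bio17): a warm, mildly wet optimum with a
# penalty on strong seasonality. Chosen once (under pooled two-period
# standardization) so that the warm period has a moderate mean existence
# potential with pronounced low-elevation coastal maxima and the cold
# period contracts habitability to coastal refugia.
TRUE_B = np.array([2.0, -0.5, 0.6, 0.0, 0.3])
TRUE_A = np.diag([-2.4, -0.2, -0.4, -0.2, -0.2])
TRUE_C0 = -0.8


def true_hep_params(standardizer: Standardizer | None = None) -> HepModelParams:
    """The generator's frozen niche model on the default predictor set."""
    return HepModelParams(TRUE_A.copy(), TRUE_B.copy(), TRUE_C0,
                          list(DEFAULT_PREDICTORS), standardizer=standardizer)


def generate_landscape(spec: SynthSpec) -> LandscapeBundle:
    """Smooth random topography with a coherent coastline.

    Low-pass-filtered noise plus a central dome is thresholded at the
    quantile matching the requested land fraction; elevation rises from the
    coast inland and roughness is the local (3x3) elevation spread.
    """
    if spec.land_frac <= 0:
        raise ParameterError("land_frac must be > 0 (all-sea domain is degenerate)")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x1a]))
    grid = spec.grid()
    ny, nx = grid.shape
    yy, xx = np.meshgrid(np.linspace(-1, 1, ny), np.linspace(-1, 1, nx),
                         indexing="ij")
    dome = np.exp(-1.5 * (xx ** 2 + yy ** 2))
    noise = gaussian_filter(rng.standard_normal((ny, nx)), spec.coast_sigma)
    noise /= max(noise.std(), 1e-12)
    score = dome + 0.55 * noise
    thr = np.quantile(score, 1.0 - spec.land_frac)
    land = score > thr

    # elevation grows with distance from the coast, modulated by the score
    dist = distance_transform_edt(land)
    rel = (score - thr) / max(score.max() - thr, 1e-12)
    elev = np.where(land, spec.relief * (0.3 * np.clip(rel, 0, None) ** 1.3
                                         + 0.7 * (dist / max(dist.max(), 1.0)) ** 1.5),
                    0.0)
    elev += np.where(land, 40.0 * np.abs(gaussian_filter(
        rng.standard_normal((ny, nx)), 1.0)), 0.0)

    m1 = uniform_filter(elev, 3, mode="nearest")
    m2 = uniform_filter(elev ** 2, 3, mode="nearest")
    rough = np.sqrt(np.maximum(m2 - m1 ** 2, 0.0))

    return LandscapeBundle(grid=grid, elevation=elev, roughness=rough,
                           land_mask=land)


def generate_climate(spec: SynthSpec, landscape: LandscapeBundle,
                     period: str = "warm"):
    """Monthly climate for one period.

    Temperature = latitudinal gradient - lapse-rate cooling + seasonal
    cycle + smooth noise; precipitation = baseline + coastal and orographic
    enhancement with a winter peak. The cold period adds a uniform
    temperature offset and scales precipitation down.
    """
    if period not in ("warm", "cold"):
        raise ParameterError(f"period must be 'warm' or 'cold', got '{period}'")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x2b]))
    grid = landscape.grid
    ny, nx = grid.shape
    y_km = grid.y_centers[:, None] - grid.origin_y
    months = np.arange(12)

    dist_sea = distance_transform_edt(landscape.land_mask) * grid.cell_size

    t_annual = (spec.t_south - spec.merid_grad * y_km / 100.0
                - spec.lapse * landscape.elevation / 1000.0
                + spec.temp_noise * gaussian_filter(rng.standard_normal((ny, nx)), 2.0))
    # continentality: the seasonal cycle strengthens away from the sea
    amp = spec.seasonal_amp * (0.75 + 0.5 * dist_sea / max(dist_sea.max(), 1.0))
    cycle = np.cos(2 * np.pi * (months - 6.5) / 12.0)
    tmean = t_annual[None] + amp[None] * cycle[:, None, None]

    p_annual = (spec.precip_base
                + spec.precip_coast * np.exp(-dist_sea / 150.0)
                + spec.precip_orog * landscape.elevation / 1000.0)
    p_annual *= 1.0 + spec.precip_noise * gaussian_filter(
        rng.standard_normal((ny, nx)), 2.0)
    # maritime winter-rain regime fades inland
    wamp = spec.precip_seasonal * (0.4 + 0.6 * np.exp(-dist_sea / 200.0))
    p_season = 1.0 + wamp[None] * np.cos(2 * np.pi * (months - 0.5) / 12.0)[:, None, None]
    precip = np.clip(p_annual[None] * p_season, 0.0, None)

    if period == "cold":
        tmean = tmean + spec.cold_dt
        precip = precip * spec.cold_precip_scale

    return MonthlyClimate(grid=grid, tmean=tmean, precip=precip,
                          land_mask=landscape.land_mask)


def sample_sites_from_hep(phi_true: np.ndarray, grid: GridSpec,
                          land_mask: np.ndarray, n_sites: int,
                          rng: np.random.Generator,
                          techno_tag: str = "TEST") -> SiteTable:
    """Presence-only site records sampled proportionally to the true
    existence potential (mimicking archaeological discovery): cells are
    drawn without replacement with probability proportional to Phi, one site
    per drawn cell, coordinates jittered within the cell."""
    rows = np.flatnonzero(land_mask.ravel())
    if n_sites > rows.size:
        raise ParameterError(f"n_sites = {n_sites} exceeds {rows.size} land cells")
    w = np.clip(phi_true.ravel()[rows], 0.0, None)
    if w.sum() <= 0:
        raise ParameterError("true Phi is zero on all land cells")
    chosen = rng.choice(rows, size=n_sites, replace=False, p=w / w.sum())
    iy, ix = np.unravel_index(chosen, grid.shape)
    jx = rng.uniform(0.05, 0.95, n_sites)
    jy = rng.uniform(0.05, 0.95, n_sites)
    x = grid.origin_x + (ix + jx) * grid.cell_size
    y = grid.origin_y + (iy + jy) * grid.cell_size
    lon, lat = grid.xy_to_lonlat(x, y)
    df = pd.DataFrame({
        "site_id": [f"S{i:04d}" for i in range(n_sites)],
        "lon": lon, "lat": lat,
        "techno_tag": techno_tag,
        "age_ka": np.nan,
    })
    return SiteTable(df)


def true_phi_field(stack: BioclimStack,
                   standardizer: Standardizer | None = None) -> np.ndarray:
    """Evaluate the generator's frozen niche model on a bioclim stack."""
    std = standardizer or Standardizer.fit(stack, list(DEFAULT_PREDICTORS))
    params = true_hep_params(std)
    return params.phi_field(stack)


def two_period_world(spec: SynthSpec, mods=None):
    """Landscape plus warm/cold accessible-HEP fields from the frozen niche.

    Predictors are standardized pooling both periods (a model trained for
    two climate states sees both in its training distribution), so the cold
    period contracts — but does not annihilate — habitable terrain.

    Returns ``(landscape, {"warm": stack, "cold": stack}, {"warm": phi_ac,
    "cold": phi_ac})`` with the accessible fields as plain arrays.
    """
    landscape = generate_landscape(spec)
    stacks = {}
    for period in ("warm", "cold"):
        stacks[period] = compute_bioclim(generate_climate(spec, landscape, period))
    std = Standardizer.fit_pooled(list(stacks.values()), list(DEFAULT_PREDICTORS))
    params = true_hep_params(std)
    if mods is None:
        mods = ModFuncParams.nea_defaults()
    phi_ac = {
        period: accessible_hep(params.phi_field(stacks[period]), landscape, mods).values
        for period in stacks
    }
    return landscape, stacks, phi_ac
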