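"""Grid definitions, raster and site-table I/O, and static landscape layers.

All model fields live on a projected km lattice. Longitude/latitude appear
only at I/O boundaries; internally an equirectangular mapping with a cosine
correction at a reference latitude converts degrees to km. Cells are
0-based, row-major and cell-centered; a coordinate belongs to the cell with
half-open edges ``[x_edge, x_edge + cell_size)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import xarray as xr

from .errors import FormatError, GridMismatchError, ParameterError

#: km per degree of latitude (spherical Earth, equirectangular projection)
KM_PER_DEG = 111.32

SITE_COLUMNS = ["site_id", "lon", "lat", "techno_tag", "age_ka"]

_GRID_ATTRS = ("cell_size", "origin_x", "origin_y", "lon_origin", "lat_origin", "lat_ref")


@dataclass(frozen=True)
class GridSpec:
    """A regular km-projected grid with an equirectangular lon/lat mapping.

    ``origin_x``/``origin_y`` are the km coordinates of the lower-left *edge*
    of cell (0, 0); ``lon_origin``/``lat_origin`` are the geographic
    coordinates of that corner, and ``lat_ref`` the latitude at which the
    meridian-convergence cosine is evaluated.
    """

    nx: int
    ny: int
    cell_size: float = 20.0
    origin_x: float = 0.0
    origin_y: float = 0.0
    lon_origin: float = 0.0
    lat_origin: float = 40.0
    lat_ref: float | None = None

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ParameterError(f"cell_size must be > 0, got {self.cell_size}")
        if self.nx < 2 or self.ny < 2:
            raise ParameterError(f"grid must be at least 2x2, got {self.nx}x{self.ny}")
        if self.lat_ref is None:
            # centre-of-domain latitude
            object.__setattr__(
                self, "lat_ref",
                self.lat_origin + 0.5 * self.ny * self.cell_size / KM_PER_DEG,
            )

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def cell_area_km2(self) -> float:
        return self.cell_size ** 2

    @property
    def x_max(self) -> float:
        return self.origin_x + self.nx * self.cell_size

    @property
    def y_max(self) -> float:
        return self.origin_y + self.ny * self.cell_size

    @property
    def x_centers(self) -> np.ndarray:
        return self.origin_x + (np.arange(self.nx) + 0.5) * self.cell_size

    @property
    def y_centers(self) -> np.ndarray:
        return self.origin_y + (np.arange(self.ny) + 0.5) * self.cell_size

    # -- coordinate transforms ---------------------------------------------
    def lonlat_to_xy(self, lon, lat):
        """Degrees -> projected km (equirectangular, cosine-corrected)."""
        coslat = np.cos(np.deg2rad(self.lat_ref))
        x = self.origin_x + (np.asarray(lon, float) - self.lon_origin) * KM_PER_DEG * coslat
        y = self.origin_y + (np.asarray(lat, float) - self.lat_origin) * KM_PER_DEG
        return x, y

    def xy_to_lonlat(self, x, y):
        coslat = np.cos(np.deg2rad(self.lat_ref))
        lon = self.lon_origin + (np.asarray(x, float) - self.origin_x) / (KM_PER_DEG * coslat)
        lat = self.lat_origin + (np.asarray(y, float) - self.origin_y) / KM_PER_DEG
        return lon, lat

    def deg_to_km(self, deg: float) -> float:
        """Convert a meridional distance in degrees to km (used for init std)."""
        return deg * KM_PER_DEG

    def cell_of(self, x, y):
        """(row, col) of the cell containing each km coordinate (half-open)."""
        ix = np.floor((np.asarray(x, float) - self.origin_x) / self.cell_size).astype(int)
        iy = np.floor((np.asarray(y, float) - self.origin_y) / self.cell_size).astype(int)
        return iy, ix

    def in_bounds(self, x, y):
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        return (
            (x >= self.origin_x) & (x < self.x_max)
            & (y >= self.origin_y) & (y < self.y_max)
        )

    def to_attrs(self) -> dict:
        return {
            "cell_size": self.cell_size,
            "origin_x": self.origin_x,
            "origin_y": self.origin_y,
            "lon_origin": self.lon_origin,
            "lat_origin": self.lat_origin,
            "lat_ref": self.lat_ref,
            "nx": self.nx,
            "ny": self.ny,
        }

    @classmethod
    def from_attrs(cls, attrs: dict) -> "GridSpec":
        missing = [a for a in _GRID_ATTRS + ("nx", "ny") if a not in attrs]
        if missing:
            raise FormatError(f"grid metadata incomplete, missing attributes: {missing}")
        return cls(
            nx=int(attrs["nx"]), ny=int(attrs["ny"]),
            cell_size=float(attrs["cell_size"]),
            origin_x=float(attrs["origin_x"]), origin_y=float(attrs["origin_y"]),
            lon_origin=float(attrs["lon_origin"]), lat_origin=float(attrs["lat_origin"]),
            lat_ref=float(attrs["lat_ref"]),
        )


@dataclass
class RasterField:
    """A gridded scalar layer with units and a validity (land) mask.

    Masked (sea) cells are excluded from all statistics.
    """

    grid: GridSpec
    values: np.ndarray
    units: str = ""
    mask: np.ndarray | None = None  # True where valid (land)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.shape != self.grid.shape:
            raise GridMismatchError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.mask is None:
            self.mask = np.ones(self.grid.shape, bool)
        else:
            self.mask = np.asarray(self.mask, bool)
            if self.mask.shape != self.grid.shape:
                raise GridMismatchError("mask shape does not match grid")

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]

    def mean(self) -> float:
        return float(self.valid_values.mean())

    def std(self) -> float:
        return float(self.valid_values.std())

    def with_values(self, values: np.ndarray, units: str | None = None) -> "RasterField":
        return RasterField(self.grid, values, self.units if units is None else units,
                           self.mask.copy())


@dataclass
class LandscapeBundle:
    """Static landscape layers sharing one grid: elevation, roughness, masks."""

    grid: GridSpec
    elevation: np.ndarray      # m
    roughness: np.ndarray      # m
    land_mask: np.ndarray      # True on land
    water_mask: np.ndarray | None = None    # inland + sea water
    forest_mask: np.ndarray = field(default=None)  # dense forest

    def __post_init__(self) -> None:
        self.elevation = np.asarray(self.elevation, float)
        self.roughness = np.asarray(self.roughness, float)
        self.land_mask = np.asarray(self.land_mask, bool)
        if self.water_mask is None:
            self.water_mask = ~self.land_mask
        else:
            self.water_mask = np.asarray(self.water_mask, bool)
        if self.forest_mask is None:
            self.forest_mask = np.zeros(self.grid.shape, bool)
        else:
            self.forest_mask = np.asarray(self.forest_mask, bool)
        for name in ("elevation", "roughness", "land_mask", "water_mask", "forest_mask"):
            arr = getattr(self, name)
            if arr.shape != self.grid.shape:
                raise GridMismatchError(f"layer '{name}' shape {arr.shape} != grid "
                                        f"shape {self.grid.shape}")


# ---------------------------------------------------------------------------
# NetCDF raster I/O
# ---------------------------------------------------------------------------

def write_raster(path, fields: dict[str, RasterField]) -> None:
    """Write named RasterFields sharing one grid to a NetCDF file."""
    grids = {id(f.grid) for f in fields.values()}
    first = next(iter(fields.values()))
    for f in fields.values():
        if f.grid.shape != first.grid.shape:
            raise GridMismatchError("fields passed to write_raster differ in shape")
    data = {}
    for name, f in fields.items():
        data[name] = xr.DataArray(f.values, dims=("y", "x"), attrs={"units": f.units})
        data[name + "_mask"] = xr.DataArray(f.mask.astype(np.int8), dims=("y", "x"))
    ds = xr.Dataset(
        data,
        coords={"x": first.grid.x_centers, "y": first.grid.y_centers},
        attrs=first.grid.to_attrs(),
    )
    ds.to_netcdf(path, engine="scipy")


def read_raster(path, layer_name: str) -> RasterField:
    """Read one named layer (with its mask) from a NetCDF raster file."""
    with xr.open_dataset(path, engine="scipy") as ds:
        grid = GridSpec.from_attrs(dict(ds.attrs))
        if layer_name not in ds:
            raise FormatError(
                f"layer '{layer_name}' not found in {path}; "
                f"available: {sorted(v for v in ds.data_vars if not v.endswith('_mask'))}"
            )
        values = ds[layer_name].values.astype(float)
        units = str(ds[layer_name].attrs.get("units", ""))
        mask_name = layer_name + "_mask"
        mask = ds[mask_name].values.astype(bool) if mask_name in ds else None
    if values.shape != grid.shape:
        raise GridMismatchError(
            f"layer '{layer_name}' shape {values.shape} != grid shape {grid.shape}")
    return RasterField(grid, values, units, mask)


def write_landscape(path, bundle: LandscapeBundle) -> None:
    fields = {
        "elevation": RasterField(bundle.grid, bundle.elevation, "m", bundle.land_mask),
        "roughness": RasterField(bundle.grid, bundle.roughness, "m", bundle.land_mask),
        "land_mask": RasterField(bundle.grid, bundle.land_mask.astype(float), "", None),
        "water_mask": RasterField(bundle.grid, bundle.water_mask.astype(float), "", None),
        "forest_mask": RasterField(bundle.grid, bundle.forest_mask.astype(float), "", None),
    }
    write_raster(path, fields)


def read_landscape(path) -> LandscapeBundle:
    elev = read_raster(path, "elevation")
    rough = read_raster(path, "roughness")
    land = read_raster(path, "land_mask")
    water = read_raster(path, "water_mask")
    forest = read_raster(path, "forest_mask")
    return LandscapeBundle(
        grid=elev.grid,
        elevation=elev.values,
        roughness=rough.values,
        land_mask=land.values.astype(bool),
        water_mask=water.values.astype(bool),
        forest_mask=forest.values.astype(bool),
    )


# ---------------------------------------------------------------------------
# Site tables
# ---------------------------------------------------------------------------

@dataclass
class SiteTable:
    """Archaeological (or synthetic) site records: id, lon, lat, techno tag."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in SITE_COLUMNS[:4] if c not in df.columns]
        if missing:
            raise FormatError(f"site table missing columns: {missing}")
        if "age_ka" not in df.columns:
            df = df.assign(age_ka=np.nan)
        if df["site_id"].duplicated().any():
            dups = df.loc[df["site_id"].duplicated(), "site_id"].tolist()
            raise FormatError(f"duplicate site_id values: {dups}")
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)


def read_sites(path) -> SiteTable:
    return SiteTable(pd.read_csv(path))


def write_sites(path, sites: SiteTable) -> None:
    sites.records.to_csv(path, index=False)


def sites_to_cells(sites: SiteTable, grid: GridSpec,
                   land_mask: np.ndarray | None = None,
                   rejects_path=None):
    """Aggregate sites to per-cell counts (spatial blocking).

    Any cell containing one or more sites counts as a single presence record;
    the returned ``counts`` array holds the raw per-cell site counts and the
    presence indicator is ``counts >= 1``. Sites falling outside the grid or
    on a sea cell are reported in the ``rejects`` frame (and optionally
    written to a sidecar CSV), never silently dropped.

    Returns
    -------
    counts : (ny, nx) int array
    rejects : DataFrame of rejected records with a ``reason`` column
    """
    df = sites.records
    x, y = grid.lonlat_to_xy(df["lon"].to_numpy(), df["lat"].to_numpy())
    inside = grid.in_bounds(x, y)
    iy, ix = grid.cell_of(x, y)
    on_sea = np.zeros(len(df), bool)
    if land_mask is not None:
        ok = inside
        on_sea[ok] = ~land_mask[iy[ok], ix[ok]]
    reasons = np.where(~inside, "outside_grid", np.where(on_sea, "sea_cell", ""))
    keep = inside & ~on_sea
    counts = np.zeros(grid.shape, int)
    np.add.at(counts, (iy[keep], ix[keep]), 1)
    rejects = df.loc[~keep].assign(reason=reasons[~keep])
    if len(rejects):
        warnings.warn(f"{len(rejects)} site(s) rejected (outside grid or on sea)",
                      stacklevel=2)
        if rejects_path is not None:
            rejects.to_csv(rejects_path, index=False)
    return counts, rejects
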