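"""Bioclimatic predictor derivation from monthly climate fields.

Implements the 17 candidate predictors used for niche modelling of
Paleolithic populations (the standard BIOCLIM set minus Bio8/Bio9):
annual summaries, extreme months, and circular 3-month quarters of monthly
mean temperature and precipitation. Quarters are the 3 consecutive calendar
months (December-January-February allowed) maximising or minimising the
relevant quantity.

Conventions where the variable names alone underdetermine a formula:

* Bio4 (temperature seasonality) = std of the 12 monthly means x 100
* Bio15 (precipitation seasonality) = coefficient of variation x 100
* Bio2 (mean diurnal range) needs monthly tmax/tmin; when a climate only
  carries monthly means, Bio2 and Bio3 are produced fully masked and can
  never be selected as predictors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import GridMismatchError, ParameterError
from .landscape_io import GridSpec, RasterField, write_raster

#: candidate predictors in canonical (table) order — used for tie-breaking
BIOCLIM_ORDER = [
    "Bio1", "Bio5", "Bio6", "Bio10", "Bio11",
    "Bio4", "Bio7",
    "Bio2", "Bio3",
    "Bio12", "Bio13", "Bio16", "Bio19",
    "Bio14", "Bio15",
    "Bio17", "Bio18",
]

#: the predictor subset adopted by default for niche-model training
DEFAULT_PREDICTORS = ["Bio1", "Bio4", "Bio16", "Bio15", "Bio17"]

BIOCLIM_UNITS = {
    "Bio1": "degC", "Bio2": "degC", "Bio3": "", "Bio4": "degC*100",
    "Bio5": "degC", "Bio6": "degC", "Bio7": "degC",
    "Bio10": "degC", "Bio11": "degC",
    "Bio12": "mm", "Bio13": "mm", "Bio14": "mm", "Bio15": "",
    "Bio16": "mm", "Bio17": "mm", "Bio18": "mm", "Bio19": "mm",
}


@dataclass
class MonthlyClimate:
    """Twelve monthly mean-temperature and precipitation fields on one grid."""

    grid: GridSpec
    tmean: np.ndarray            # (12, ny, nx), degC
    precip: np.ndarray           # (12, ny, nx), mm/month
    land_mask: np.ndarray | None = None
    tmax: np.ndarray | None = None
    tmin: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.tmean = np.asarray(self.tmean, float)
        self.precip = np.asarray(self.precip, float)
        shape = (12,) + self.grid.shape
        for name in ("tmean", "precip"):
            if getattr(self, name).shape != shape:
                raise GridMismatchError(f"{name} must have shape {shape}")
        if self.land_mask is None:
            self.land_mask = np.ones(self.grid.shape, bool)
        self.land_mask = np.asarray(self.land_mask, bool)
        if np.any(self.precip[:, self.land_mask] < 0):
            raise ParameterError("precip must be >= 0 everywhere on land")


@dataclass
class BioclimStack:
    """The 17 named bioclimatic layers on one grid with a shared land mask."""

    grid: GridSpec
    layers: dict[str, np.ndarray]
    mask: np.ndarray
    layer_masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def mask_for(self, name: str) -> np.ndarray:
        return self.layer_masks.get(name, self.mask)

    @property
    def names(self) -> list[str]:
        return [n for n in BIOCLIM_ORDER if n in self.layers]

    def to_netcdf(self, path) -> None:
        fields = {
            name: RasterField(self.grid, vals, BIOCLIM_UNITS.get(name, ""),
                              self.mask_for(name))
            for name, vals in self.layers.items()
        }
        write_raster(path, fields)


def _quarter_stats(monthly: np.ndarray) -> np.ndarray:
    """All 12 circular 3-month windows: out[m] = mean of months m, m+1, m+2."""
    idx = (np.arange(12)[:, None] + np.arange(3)[None, :]) % 12
    return monthly[idx].mean(axis=1)  # (12, ny, nx)


def compute_bioclim(clim: MonthlyClimate) -> BioclimStack:
    """Derive the 17-candidate bioclimatic stack from monthly climate.

    NaN on a land cell propagates into that cell being masked out of the
    affected layers (with a warning) rather than poisoning statistics.
    """
    t, p = clim.tmean, clim.precip
    mask = clim.land_mask.copy()
    bad = np.zeros(clim.grid.shape, bool)
    for arr in (t, p):
        bad |= np.isnan(arr).any(axis=0)
    if np.any(bad & mask):
        warnings.warn(f"{int(np.sum(bad & mask))} land cell(s) contain NaN climate; "
                      "masked out of the bioclim stack", stacklevel=2)
        mask &= ~bad

    tq = _quarter_stats(t)          # quarterly mean temperature
    pq = 3.0 * _quarter_stats(p)    # quarterly total precipitation
    warm_q = np.argmax(tq, axis=0)
    cold_q = np.argmin(tq, axis=0)
    jj, ii = np.meshgrid(np.arange(t.shape[1]), np.arange(t.shape[2]), indexing="ij")

    with np.errstate(invalid="ignore", divide="ignore"):
        layers: dict[str, np.ndarray] = {}
        layers["Bio1"] = t.mean(axis=0)
        layers["Bio4"] = t.std(axis=0) * 100.0
        thi = clim.tmax if clim.tmax is not None else t
        tlo = clim.tmin if clim.tmin is not None else t
        layers["Bio5"] = thi.max(axis=0)
        layers["Bio6"] = tlo.min(axis=0)
        layers["Bio7"] = layers["Bio5"] - layers["Bio6"]
        layers["Bio10"] = tq[warm_q, jj, ii]
        layers["Bio11"] = tq[cold_q, jj, ii]
        layers["Bio12"] = p.sum(axis=0)
        layers["Bio13"] = p.max(axis=0)
        layers["Bio14"] = p.min(axis=0)
        pmean = p.mean(axis=0)
        cv = np.where(pmean > 0, p.std(axis=0) / np.where(pmean > 0, pmean, 1.0) * 100.0,
                      0.0)
        layers["Bio15"] = cv
        layers["Bio16"] = pq.max(axis=0)
        layers["Bio17"] = pq.min(axis=0)
        layers["Bio18"] = pq[warm_q, jj, ii]
        layers["Bio19"] = pq[cold_q, jj, ii]

        layer_masks: dict[str, np.ndarray] = {}
        if clim.tmax is not None and clim.tmin is not None:
            layers["Bio2"] = (clim.tmax - clim.tmin).mean(axis=0)
            rng7 = layers["Bio7"]
            layers["Bio3"] = np.where(rng7 != 0, layers["Bio2"] / np.where(rng7 != 0, rng7, 1.0) * 100.0, 0.0)
        else:
            # diurnal range unavailable from monthly means alone
            layers["Bio2"] = np.full(clim.grid.shape, np.nan)
            layers["Bio3"] = np.full(clim.grid.shape, np.nan)
            empty = np.zeros(clim.grid.shape, bool)
            layer_masks["Bio2"] = empty
            layer_masks["Bio3"] = empty

    return BioclimStack(clim.grid, layers, mask, layer_masks)


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

@dataclass
class Standardizer:
    """Per-layer means/stds fit on training cells, applied unchanged later."""

    names: list[str]
    means: np.ndarray
    stds: np.ndarray

    @classmethod
    def fit(cls, stack: BioclimStack, names: list[str],
            training_mask: np.ndarray | None = None) -> "Standardizer":
        m = stack.mask if training_mask is None else (training_mask & stack.mask)
        means, stds = [], []
        for name in names:
            vals = stack[name][m & stack.mask_for(name)]
            s = vals.std()
            if s < 1e-12:
                raise ParameterError(f"predictor '{name}' has zero variance over "
                                     "training cells")
            means.append(vals.mean())
            stds.append(s)
        return cls(list(names), np.array(means), np.array(stds))

    @classmethod
    def fit_pooled(cls, stacks: list[BioclimStack], names: list[str],
                   training_mask: np.ndarray | None = None) -> "Standardizer":
        """Fit pooling land cells across several stacks (e.g. two climate
        periods trained jointly)."""
        means, stds = [], []
        for name in names:
            vals = np.concatenate([
                s[name][(s.mask if training_mask is None else training_mask & s.mask)
                        & s.mask_for(name)]
                for s in stacks])
            sd = vals.std()
            if sd < 1e-12:
                raise ParameterError(f"predictor '{name}' has zero variance over "
                                     "training cells")
            means.append(vals.mean())
            stds.append(sd)
        return cls(list(names), np.array(means), np.array(stds))

    def transform_matrix(self, stack: BioclimStack, rows: np.ndarray) -> np.ndarray:
        """Standardized predictor matrix (n_cells, n_predictors) at flat-index rows."""
        cols = []
        for i, name in enumerate(self.names):
            cols.append((stack[name].ravel()[rows] - self.means[i]) / self.stds[i])
        return np.column_stack(cols)

    def transform_fields(self, stack: BioclimStack) -> dict[str, np.ndarray]:
        return {
            name: (stack[name] - self.means[i]) / self.stds[i]
            for i, name in enumerate(self.names)
        }


# ---------------------------------------------------------------------------
# Predictor selection helper
# ---------------------------------------------------------------------------

def cluster_predictors(stack: BioclimStack, candidates: list[str],
                       presence_mask: np.ndarray,
                       threshold: float = 0.3):
    """Group collinear candidates and pick one representative per cluster.

    Average-linkage hierarchical clustering on the distance ``1 - |r|``
    (Pearson r over land cells), cut at ``threshold``. The representative of
    each cluster is the member with the largest point-biserial correlation
    magnitude against the presence/absence indicator; ties break by the
    canonical table order.

    Returns ``(clusters, representatives)`` where clusters is a list of
    name-lists and representatives the selected layer names.
    """
    if len(candidates) < 2:
        raise ParameterError("need at least 2 candidate predictors")
    usable = [c for c in candidates if np.any(stack.mask_for(c) & stack.mask)]
    m = stack.mask.copy()
    for c in usable:
        m &= stack.mask_for(c)
    if m.sum() < 10:
        raise ParameterError(f"only {int(m.sum())} usable land cells; need >= 10")
    X = np.column_stack([stack[c][m] for c in usable])
    r = np.corrcoef(X, rowvar=False)
    dist = 1.0 - np.abs(r)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    labels = hierarchy.fcluster(link, t=threshold, criterion="distance")

    y = presence_mask[m].astype(float)
    order = {name: i for i, name in enumerate(BIOCLIM_ORDER)}
    clusters, reps = [], []
    for lab in np.unique(labels):
        members = [usable[i] for i in np.flatnonzero(labels == lab)]
        members.sort(key=lambda n: order.get(n, 99))
        scores = []
        for name in members:
            x = stack[name][m]
            if y.std() == 0 or x.std() == 0:
                scores.append(0.0)
            else:
                scores.append(abs(np.corrcoef(x, y)[0, 1]))
        best = members[int(np.argmax(scores))]
        clusters.append(members)
        reps.append(best)
    reps.sort(key=lambda n: order.get(n, 99))
    return clusters, reps
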