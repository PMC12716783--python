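"""Human Existence Potential (HEP): ensemble logistic niche model.

The climate-environment HEP of a population is a logistic regression on a
quadratic polynomial of standardized bioclimatic predictors,

    q(P) = 1/2 P^T A P + B . P + c0,      Phi_E = 1 / (1 + exp(-q)),

trained on presence cells (grid cells holding at least one archaeological
site), a-priori absence cells (bioclimatic thresholds violated), and
pseudo-absence cells whose labels are realized stochastically. An ensemble
of fits on random 80/20 train/validation splits yields the mean field
<Phi_E> and its spread. Static landscape layers then modify the mean into
the accessible HEP,

    Phi_Ac = <Phi_E> * g1(elev) * g2(roughness) * g3(water) * gx(forest),

where g1/g2 descend piecewise-linearly from 1.0 to a 0.8 plateau between
population-specific thresholds, and water / dense-forest cells are
uninhabitable (factor 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .bioclim import BioclimStack, Standardizer
from .errors import ParameterError
from .landscape_io import LandscapeBundle, RasterField

#: ensemble size used for production HEP estimates
DEFAULT_N_MEMBERS = 1000
DEFAULT_TRAIN_FRAC = 0.8

#: bioclimatic a-priori thresholds for modern humans: annual mean temperature
#: and wettest-month precipitation outside these bands preclude presence
AMH_APRIORI = {"Bio1": (-2.0, 16.0), "Bio13": (30.0, 250.0)}

PRESENCE, APRIORI_ABSENCE, PSEUDO_ABSENCE = 0, 1, 2


@dataclass
class AprioriThresholds:
    """Per-variable (lower, upper) habitability bounds."""

    bounds: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ParameterError(f"threshold for {name}: lower {lo} must be < "
                                     f"upper {hi}")

    @classmethod
    def amh_defaults(cls) -> "AprioriThresholds":
        return cls(dict(AMH_APRIORI))

    @classmethod
    def from_presences(cls, stack: BioclimStack, presence_mask: np.ndarray,
                       names: tuple[str, ...] = ("Bio1", "Bio13"),
                       coverage: float = 0.95) -> "AprioriThresholds":
        """Derive bounds as the central-coverage quantiles of each variable at
        presence cells (the procedure that produced the modern-human bounds;
        used for populations whose bounds are not tabulated)."""
        lo_q, hi_q = (1 - coverage) / 2, 1 - (1 - coverage) / 2
        bounds = {}
        for name in names:
            vals = stack[name][presence_mask & stack.mask_for(name)]
            if vals.size < 2:
                raise ParameterError(f"too few presence cells to derive bounds for {name}")
            bounds[name] = (float(np.quantile(vals, lo_q)), float(np.quantile(vals, hi_q)))
        return cls(bounds)

    def violated(self, stack: BioclimStack) -> np.ndarray:
        """Boolean field: any threshold violated (a-priori uninhabitable)."""
        out = np.zeros(stack.grid.shape, bool)
        for name, (lo, hi) in self.bounds.items():
            v = stack[name]
            out |= (v < lo) | (v > hi)
        return out


@dataclass
class PresenceAbsenceSet:
    """Labelled land cells for one training realization.

    ``rows`` are flat cell indices into the grid; ``category`` assigns each to
    presence / a-priori absence / pseudo-absence; ``labels`` holds the
    realized binary outcome and ``included`` whether the cell enters training
    (pseudo-absences may be excluded under options 1 and 2).
    """

    rows: np.ndarray
    category: np.ndarray
    labels: np.ndarray
    included: np.ndarray
    conflicts: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    @property
    def n_presence(self) -> int:
        return int(np.sum(self.category == PRESENCE))

    @property
    def n_pseudo(self) -> int:
        return int(np.sum(self.category == PSEUDO_ABSENCE))


def label_cells(presence_mask: np.ndarray, stack: BioclimStack,
                thresholds: AprioriThresholds, pa_option: int = 3,
                rng: np.random.Generator | None = None) -> PresenceAbsenceSet:
    """Partition land cells into presence / a-priori absence / pseudo-absence
    and realize binary training labels.

    Pseudo-absence handling:

    * option 1 — excluded from training entirely;
    * option 2 — per realization, one third relabelled presence, one third
      absence, one third excluded (uniformly at random);
    * option 3 — each pseudo-absence cell relabelled presence with the
      discovery-rate probability Np / (Np + Npa), else absence.

    A presence cell that also violates the a-priori thresholds keeps its
    presence label (data beats prior); the conflict is recorded and warned.
    """
    if pa_option not in (1, 2, 3):
        raise ParameterError(f"pa_option must be 1, 2 or 3, got {pa_option}")
    rng = np.random.default_rng(rng)
    land = stack.mask
    presence = presence_mask & land
    apriori = thresholds.violated(stack) & land

    conflict = presence & apriori
    if conflict.any():
        warnings.warn(f"{int(conflict.sum())} presence cell(s) violate a-priori "
                      "thresholds; presence retained", stacklevel=2)
    apriori = apriori & ~presence
    pseudo = land & ~presence & ~apriori

    rows = np.flatnonzero(land.ravel())
    category = np.full(rows.shape, PSEUDO_ABSENCE, int)
    category[presence.ravel()[rows]] = PRESENCE
    category[apriori.ravel()[rows]] = APRIORI_ABSENCE

    labels = np.zeros(rows.shape, int)
    labels[category == PRESENCE] = 1
    included = np.ones(rows.shape, bool)

    np_count = int(presence.sum())
    npa_count = int(pseudo.sum())
    is_pseudo = category == PSEUDO_ABSENCE
    if pa_option == 1:
        included[is_pseudo] = False
    elif pa_option == 2:
        thirds = rng.integers(0, 3, size=npa_count)
        sub = np.flatnonzero(is_pseudo)
        labels[sub[thirds == 0]] = 1
        labels[sub[thirds == 1]] = 0
        included[sub[thirds == 2]] = False
    else:
        p = np_count / (np_count + npa_count) if (np_count + npa_count) else 0.0
        labels[is_pseudo] = rng.random(npa_count) < p

    return PresenceAbsenceSet(rows, category, labels, included,
                              conflicts=np.flatnonzero(conflict.ravel()))


# ---------------------------------------------------------------------------
# Quadratic-logistic model
# ---------------------------------------------------------------------------

def quad_features(X: np.ndarray) -> np.ndarray:
    """Expand (n, k) predictors into k linear + k(k+1)/2 quadratic terms."""
    n, k = X.shape
    cols = [X]
    for i in range(k):
        for j in range(i, k):
            cols.append((X[:, i] * X[:, j])[:, None])
    return np.hstack(cols)


@dataclass
class HepModelParams:
    """Quadratic-logistic coefficients: symmetric A, linear B, intercept c0."""

    A: np.ndarray
    B: np.ndarray
    c0: float
    names: list[str]
    standardizer: Standardizer | None = None
    ridge_fallback: bool = False

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, float)
        self.B = np.asarray(self.B, float)
        k = len(self.B)
        if self.A.shape != (k, k):
            raise ParameterError(f"A must be {k}x{k}")
        if not np.allclose(self.A, self.A.T):
            raise ParameterError("A must be symmetric")

    def q(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        return 0.5 * np.einsum("ni,ij,nj->n", X, self.A, X) + X @ self.B + self.c0

    def phi(self, X: np.ndarray) -> np.ndarray:
        return expit(self.q(X))

    def phi_field(self, stack: BioclimStack) -> np.ndarray:
        """Phi_E over the stack's land cells (0 elsewhere)."""
        rows = np.flatnonzero(stack.mask.ravel())
        std = self.standardizer
        if std is None:
            raise ParameterError("model has no stored standardization statistics")
        X = std.transform_matrix(stack, rows)
        out = np.zeros(stack.grid.shape)
        out.ravel()[rows] = self.phi(X)
        return out

    @classmethod
    def from_flat(cls, coef: np.ndarray, intercept: float, names: list[str],
                  **kw) -> "HepModelParams":
        k = len(names)
        B = coef[:k].copy()
        A = np.zeros((k, k))
        pos = k
        for i in range(k):
            for j in range(i, k):
                c = coef[pos]
                if i == j:
                    A[i, i] = 2.0 * c            # 1/2 A_ii x_i^2 = c x_i^2
                else:
                    A[i, j] = A[j, i] = c        # off-diagonal split evenly
                pos += 1
        return cls(A, B, float(intercept), list(names), **kw)


def fit_hep(X: np.ndarray, y: np.ndarray, names: list[str] | None = None,
            standardizer: Standardizer | None = None,
            ridge: float = 1e-6, max_iter: int = 2000) -> HepModelParams:
    """Maximum-likelihood quadratic logistic regression.

    ``X`` must already be standardized. On complete separation (the
    unpenalized fit fails to converge), falls back to an L2 ridge of the
    given strength and flags the result.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ParameterError("need at least one positive and one negative label")
    k = X.shape[1]
    if names is None:
        names = [f"p{i}" for i in range(k)]
    F = quad_features(np.asarray(X, float))
    fallback = False
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            lr = LogisticRegression(C=np.inf, max_iter=max_iter).fit(F, y)
            # runaway coefficients on standardized features mean separation
            if np.max(np.abs(lr.coef_)) > 50.0:
                fallback = True
        except ConvergenceWarning:
            fallback = True
    if fallback:
        lr = LogisticRegression(C=1.0 / ridge, max_iter=max_iter).fit(F, y)
    return HepModelParams.from_flat(lr.coef_[0], lr.intercept_[0], names,
                                    standardizer=standardizer,
                                    ridge_fallback=fallback)


@dataclass
class HepEnsemble:
    """Member fits plus ensemble mean/std Phi_E fields and validation AUCs."""

    members: list[HepModelParams]
    aucs: np.ndarray
    phi_mean: RasterField
    phi_std: RasterField

    @property
    def n_members(self) -> int:
        return len(self.members)


def hep_ensemble(presence_mask: np.ndarray, stack: BioclimStack,
                 predictor_names: list[str],
                 thresholds: AprioriThresholds,
                 pa_option: int = 3,
                 n_members: int = DEFAULT_N_MEMBERS,
                 train_frac: float = DEFAULT_TRAIN_FRAC,
                 seed=None,
                 max_retries: int = 100) -> HepEnsemble:
    """Train the HEP ensemble: per member, re-realize pseudo-absence labels,
    split train/validation, fit, and score (AUC on the held-out split).

    A member whose random split lacks both classes on either side is
    resampled (never silently skipped); after ``max_retries`` failures an
    error is raised.
    """
    if n_members < 1:
        raise ParameterError("n_members must be >= 1")
    rng = np.random.default_rng(seed)
    std = Standardizer.fit(stack, predictor_names)
    land_rows = np.flatnonzero(stack.mask.ravel())
    X_land = std.transform_matrix(stack, land_rows)
    row_pos = {r: i for i, r in enumerate(land_rows)}

    members: list[HepModelParams] = []
    aucs = np.empty(n_members)
    acc = np.zeros(X_land.shape[0])
    acc2 = np.zeros(X_land.shape[0])
    resampled = 0
    for m in range(n_members):
        for _ in range(max_retries):
            labels = label_cells(presence_mask, stack, thresholds, pa_option, rng)
            use = labels.included
            rows = labels.rows[use]
            y = labels.labels[use]
            idx = np.array([row_pos[r] for r in rows])
            perm = rng.permutation(len(rows))
            n_train = int(round(train_frac * len(rows)))
            # sorted so the fit is independent of draw order
            tr, va = np.sort(perm[:n_train]), np.sort(perm[n_train:])
            validate = len(va) > 0
            if len(np.unique(y[tr])) == 2 and (not validate or len(np.unique(y[va])) == 2):
                break
            resampled += 1
        else:
            raise ParameterError(f"member {m}: could not draw a usable split in "
                                 f"{max_retries} attempts")
        model = fit_hep(X_land[idx[tr]], y[tr], predictor_names, standardizer=std)
        aucs[m] = (roc_auc_score(y[va], model.phi(X_land[idx[va]]))
                   if validate else np.nan)
        phi = model.phi(X_land)
        acc += phi
        acc2 += phi * phi
        members.append(model)
    if resampled:
        warnings.warn(f"{resampled} degenerate split(s) resampled", stacklevel=2)

    mean = acc / n_members
    var = np.maximum(acc2 / n_members - mean ** 2, 0.0)
    mean_f = np.zeros(stack.grid.shape)
    std_f = np.zeros(stack.grid.shape)
    mean_f.ravel()[land_rows] = mean
    std_f.ravel()[land_rows] = np.sqrt(var)
    return HepEnsemble(
        members, aucs,
        RasterField(stack.grid, mean_f, "", stack.mask.copy()),
        RasterField(stack.grid, std_f, "", stack.mask.copy()),
    )


# ---------------------------------------------------------------------------
# Accessibility modifications
# ---------------------------------------------------------------------------

def modification_g(x, xl: float, xu: float):
    """Piecewise-linear accessibility factor: 1 below ``xl``, descending with
    slope m = 0.2/(xu - xl) to a 0.8 plateau at and above ``xu``."""
    if not xl < xu:
        raise ParameterError(f"xl ({xl}) must be < xu ({xu})")
    x = np.asarray(x, float)
    m = 0.2 / (xu - xl)
    out = np.where(x < xl, 1.0, np.where(x >= xu, 0.8, 1.0 - (x - xl) * m))
    return out if out.ndim else float(out)


@dataclass
class ModFuncParams:
    """Population-specific accessibility modification thresholds.

    ``g1`` acts on elevation and ``g2`` on terrain roughness (``None``
    disables it, i.e. factor 1); water and dense forest zero the result.
    """

    g1: tuple[float, float] | None = None      # (xl, xu) for elevation, m
    g2: tuple[float, float] | None = None      # (xl, xu) for roughness, m
    water_zero: bool = True
    forest_zero: bool = True

    def __post_init__(self) -> None:
        for name, pair in (("g1", self.g1), ("g2", self.g2)):
            if pair is not None and not pair[0] < pair[1]:
                raise ParameterError(f"{name}: xl must be < xu, got {pair}")

    @classmethod
    def amh_defaults(cls) -> "ModFuncParams":
        return cls(g1=(350.0, 2000.0), g2=(70.0, 400.0))

    @classmethod
    def nea_defaults(cls) -> "ModFuncParams":
        # roughness excluded: no clear pattern at Middle-Paleolithic sites
        return cls(g1=(450.0, 2000.0), g2=None)


def accessible_hep(phi_mean, landscape: LandscapeBundle,
                   mods: ModFuncParams) -> RasterField:
    """Accessible HEP: Phi_Ac = <Phi_E> * g1 * g2 * g3 * gx on one grid."""
    values = phi_mean.values if isinstance(phi_mean, RasterField) else np.asarray(phi_mean, float)
    if values.shape != landscape.grid.shape:
        raise ParameterError("phi_mean and landscape are on different grids")
    out = values.astype(float).copy()
    if mods.g1 is not None:
        if landscape.elevation is None:
            raise ParameterError("g1 requires an elevation layer")
        out *= modification_g(landscape.elevation, *mods.g1)
    if mods.g2 is not None:
        if landscape.roughness is None:
            raise ParameterError("g2 requires a roughness layer")
        out *= modification_g(landscape.roughness, *mods.g2)
    if mods.water_zero:
        out[landscape.water_mask] = 0.0
    if mods.forest_zero:
        out[landscape.forest_mask] = 0.0
    out[~landscape.land_mask] = 0.0
    return RasterField(landscape.grid, np.clip(out, 0.0, 1.0), "",
                       landscape.land_mask.copy())
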