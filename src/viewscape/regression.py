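"""Negative-binomial modelling of viewshed intensity.

The response is the per-cell count of overlapping viewsheds, which is
heavily overdispersed (many zeros, a few very large counts), so it is
modelled as NB2: y ~ NB with mean mu = exp(X beta) and variance
mu + alpha mu**2.  The dispersion alpha is selected by a systematic
scan: profile out beta by IRLS at each alpha on a log-spaced grid,
compare AIC, then refine the best alpha by golden-section search.

Also here: the spatial covariate construction (class indicators,
log-distance surfaces, trail buffers), collinearity screening (VIF) and
a permutation Moran's I on residuals.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy import sparse
from scipy.special import gammaln
from scipy.stats import norm

from .grids import ElevationGrid, GridSpec
from .intensity import IntensityGrid

__all__ = [
    "COVARIATE_SCHEMA",
    "CovariateTable",
    "NBFit",
    "log_distance_raster",
    "distance_raster",
    "build_covariates",
    "nb_loglik",
    "nb_deviance",
    "fit_nb",
    "report",
    "irr",
    "mcfadden_r2",
    "nagelkerke_r2",
    "vif",
    "morans_i",
    "grid_rook_weights",
]

#: Covariate columns, in model order.  Binary class indicators first,
#: then log-distance surfaces, then continuous terrain/population terms.
COVARIATE_SCHEMA = (
    "forest",
    "agriculture",
    "fresh_water",
    "ocean",
    "woody_wetland",
    "emergent_wetland",
    "urban",
    "park",
    "trail",
    "logdist_coast",
    "logdist_lake",
    "logdist_attraction",
    "logdist_historical",
    "slope_deg",
    "pop_density",
)

#: Land-cover codes backing the binary indicators (NLCD-style; 10 = ocean).
INDICATOR_CODES: dict[str, tuple[int, ...]] = {
    "forest": (41, 42, 43),
    "agriculture": (81, 82),
    "fresh_water": (11,),
    "ocean": (10,),
    "woody_wetland": (90,),
    "emergent_wetland": (95,),
    "urban": (21, 22, 23, 24),
}

LINK_CLIP = 30.0  # |X beta| bound; exp(30) ~ 1e13 keeps mu finite


# ---------------------------------------------------------------------------
# spatial covariates
# ---------------------------------------------------------------------------

def distance_raster(features: Sequence, spec: GridSpec) -> np.ndarray:
    """Euclidean distance (m) from every cell centre to the nearest feature."""
    geoms = [g for g in features if g is not None and not g.is_empty]
    if not geoms:
        raise ValueError("feature layer is empty")
    merged = shapely.union_all(geoms)
    x, y = spec.cell_centers()
    pts = shapely.points(x.ravel(), y.ravel())
    d = shapely.distance(pts, merged)
    return d.reshape(spec.shape)


def log_distance_raster(
    features: Sequence,
    spec: GridSpec,
    unit_km: bool = False,
    epsilon: float | None = None,
) -> ElevationGrid:
    """Natural log of (distance to nearest feature + epsilon).

    The offset keeps cells lying on a feature finite; by default it is
    one cell size expressed in the chosen unit, so ln(epsilon) is the
    value *at* the feature.
    """
    d = distance_raster(features, spec)
    scale = 1e-3 if unit_km else 1.0
    if epsilon is None:
        epsilon = spec.cellsize * scale
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    return ElevationGrid(spec, np.log(d * scale + epsilon))


def _class_indicator(landcover: ElevationGrid, codes: tuple[int, ...]) -> np.ndarray:
    out = np.zeros(landcover.spec.shape)
    ok = ~np.isnan(landcover.z)
    out[ok] = np.isin(landcover.z[ok].astype(np.int64), codes)
    out[~ok] = np.nan
    return out


def _polygon_indicator(polygons: Sequence, spec: GridSpec) -> np.ndarray:
    geoms = [g for g in polygons if g is not None and not g.is_empty]
    if not geoms:
        return np.zeros(spec.shape)
    merged = shapely.union_all(geoms)
    x, y = spec.cell_centers()
    pts = shapely.points(x.ravel(), y.ravel())
    inside = shapely.intersects(pts, merged)
    return inside.reshape(spec.shape).astype(np.float64)


@dataclass
class CovariateTable:
    """Sampled cells with the intensity response and model covariates."""

    data: pd.DataFrame  # cell_id, row, col, y, + COVARIATE_SCHEMA columns
    provenance: dict = field(default_factory=dict)

    @property
    def y(self) -> np.ndarray:
        return self.data["y"].to_numpy()

    def design_matrix(self, covariates: Sequence[str] | None = None):
        names = list(covariates) if covariates is not None else list(COVARIATE_SCHEMA)
        X = np.column_stack(
            [np.ones(len(self.data))] + [self.data[c].to_numpy() for c in names]
        )
        return X, ["intercept"] + names

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        self.data.to_csv(path, index=False)
        path.with_suffix(".provenance.json").write_text(
            json.dumps(self.provenance, indent=2, sort_keys=True)
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "CovariateTable":
        path = Path(path)
        data = pd.read_csv(path)
        side = path.with_suffix(".provenance.json")
        prov = json.loads(side.read_text()) if side.exists() else {}
        return cls(data, prov)


def _layer_checksum(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def build_covariates(
    intensity: IntensityGrid,
    landcover: ElevationGrid,
    slope: ElevationGrid,
    pop_density: ElevationGrid,
    coastline: Sequence,
    lakes: Sequence,
    trails: Sequence,
    parks: Sequence,
    attractions: Sequence,
    historical: Sequence,
    fraction: float = 0.01,
    seed: int = 0,
    trail_buffer_m: float = 100.0,
) -> CovariateTable:
    """Sample cells and assemble the model table.

    A uniform without-replacement sample of ``round(fraction * N)``
    cells is drawn (seeded, reproducible) from the cells with complete
    covariates.  The trail indicator flags cells whose centre lies
    within ``trail_buffer_m`` of any trail line; lake shorelines are the
    lake polygon boundaries.
    """
    spec = intensity.spec
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    cols = {}
    for name, codes in INDICATOR_CODES.items():
        cols[name] = _class_indicator(landcover, codes)
    cols["park"] = _polygon_indicator(parks, spec)
    cols["trail"] = (distance_raster(trails, spec) <= trail_buffer_m).astype(
        np.float64
    )
    lake_shores = [g.boundary for g in lakes]
    cols["logdist_coast"] = log_distance_raster(coastline, spec, unit_km=True).z
    cols["logdist_lake"] = log_distance_raster(lake_shores, spec, unit_km=True).z
    cols["logdist_attraction"] = log_distance_raster(
        attractions, spec, unit_km=True
    ).z
    cols["logdist_historical"] = log_distance_raster(
        historical, spec, unit_km=True
    ).z
    cols["slope_deg"] = slope.z
    cols["pop_density"] = pop_density.z

    n_cells = spec.nrows * spec.ncols
    target = int(round(fraction * n_cells))
    k = len(COVARIATE_SCHEMA)
    if target < k + 2:
        raise ValueError(
            f"sample of {target} cells cannot identify a model with {k} "
            "covariates plus intercept and dispersion"
        )
    complete = np.ones(n_cells, dtype=bool)
    for name in COVARIATE_SCHEMA:
        complete &= ~np.isnan(cols[name].ravel())
    candidates = np.flatnonzero(complete)
    if len(candidates) < target:
        raise ValueError(
            f"only {len(candidates)} cells have complete covariates; "
            f"cannot draw {target}"
        )
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(candidates, size=target, replace=False))
    rows, cc = np.unravel_index(chosen, spec.shape)
    data = {"cell_id": chosen, "row": rows, "col": cc,
            "y": intensity.counts[rows, cc]}
    for name in COVARIATE_SCHEMA:
        data[name] = cols[name][rows, cc]
    prov = {
        "seed": int(seed),
        "fraction": fraction,
        "n_cells": int(n_cells),
        "n_sampled": int(target),
        "trail_buffer_m": trail_buffer_m,
        "layer_checksums": {
            "intensity": _layer_checksum(intensity.counts),
            "landcover": _layer_checksum(landcover.z),
            "slope": _layer_checksum(slope.z),
            "pop_density": _layer_checksum(pop_density.z),
        },
    }
    return CovariateTable(pd.DataFrame(data), prov)


# ---------------------------------------------------------------------------
# NB2 likelihood and fitting
# ---------------------------------------------------------------------------

def _check_counts(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=np.float64)
    if y.ndim != 1 or y.size == 0:
        raise ValueError("y must be a non-empty 1-D array")
    if (y < 0).any() or not np.allclose(y, np.round(y)):
        raise ValueError("y must contain non-negative integer counts")
    return y


def nb_loglik(
    y: np.ndarray, X: np.ndarray, beta: np.ndarray, alpha: float
) -> float:
    """NB2 log-likelihood with log link, evaluated in log space.

    Per observation, with mu = exp(x . beta):
    lgamma(y + 1/a) - lgamma(y + 1) - lgamma(1/a)
    - (1/a) ln(1 + a mu) + y ln(a mu / (1 + a mu)).
    """
    y = _check_counts(y)
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    eta = np.clip(np.asarray(X, dtype=np.float64) @ beta, -LINK_CLIP, LINK_CLIP)
    mu = np.exp(eta)
    inv_a = 1.0 / alpha
    am = alpha * mu
    ll = (
        gammaln(y + inv_a)
        - gammaln(y + 1.0)
        - gammaln(inv_a)
        - inv_a * np.log1p(am)
        + y * (np.log(am) - np.log1p(am))
    )
    return float(ll.sum())


def nb_deviance(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    """NB2 deviance: twice the log-likelihood gap to the saturated model."""
    y = np.asarray(y, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    term2 = (y + 1.0 / alpha) * np.log((1.0 + alpha * y) / (1.0 + alpha * mu))
    return float(2.0 * np.sum(term - term2))


def _irls(
    y: np.ndarray,
    X: np.ndarray,
    alpha: float,
    beta0: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[np.ndarray, float, int, list[float]]:
    """Maximise the NB2 likelihood in beta at fixed alpha by IRLS with
    step halving (so the accepted deviance path is non-increasing).

    Returns (beta, deviance, n_iter, deviance_trace).
    """
    n, p = X.shape
    if beta0 is None:
        # log-linear start from shifted counts
        zinit = np.log(y + 0.5)
        beta = np.linalg.lstsq(X, zinit, rcond=None)[0]
    else:
        beta = beta0.copy()
    eta = np.clip(X @ beta, -LINK_CLIP, LINK_CLIP)
    mu = np.exp(eta)
    dev = nb_deviance(y, mu, alpha)
    trace = [dev]
    for it in range(1, max_iter + 1):
        w = mu / (1.0 + alpha * mu)
        z = eta + (y - mu) / mu
        sw = np.sqrt(w)
        beta_new, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
        step = 1.0
        for _ in range(25):
            cand = beta + step * (beta_new - beta)
            eta_c = np.clip(X @ cand, -LINK_CLIP, LINK_CLIP)
            mu_c = np.exp(eta_c)
            dev_c = nb_deviance(y, mu_c, alpha)
            if dev_c <= dev + 1e-12:
                break
            step /= 2.0
        else:
            # no improving step: treat as converged at the current point
            return beta, dev, it, trace
        delta = dev - dev_c
        beta, eta, mu, dev = cand, eta_c, mu_c, dev_c
        trace.append(dev)
        if abs(delta) < tol * (abs(dev) + 0.1):
            return beta, dev, it, trace
    raise RuntimeError(
        f"IRLS did not converge in {max_iter} iterations at alpha={alpha:g}; "
        f"deviance trace tail: {trace[-5:]}"
    )


@dataclass
class NBFit:
    """A fitted NB2 model: coefficients on the log-mean scale, selected
    dispersion, and derived statistics."""

    names: list[str]
    beta: np.ndarray
    alpha: float
    loglik: float
    aic: float
    std_errors: np.ndarray
    p_values: np.ndarray
    irr: np.ndarray
    n_obs: int
    n_iter: int
    alpha_grid: np.ndarray = field(repr=False, default=None)
    alpha_grid_aic: np.ndarray = field(repr=False, default=None)
    deviance: float = math.nan
    # filled by report():
    standardized_beta: np.ndarray | None = None
    r2_mcfadden: float | None = None
    r2_nagelkerke: float | None = None

    def predict_mu(self, X: np.ndarray) -> np.ndarray:
        return np.exp(np.clip(X @ self.beta, -LINK_CLIP, LINK_CLIP))


def _aic(ll: float, n_params: int) -> float:
    return 2.0 * n_params - 2.0 * ll


def fit_nb(
    table: CovariateTable | tuple[np.ndarray, np.ndarray],
    covariates: Sequence[str] | None = None,
    alpha_grid: np.ndarray | None = None,
    rel_tol: float = 1e-4,
) -> NBFit:
    """Fit the NB2 model, selecting alpha by AIC.

    For each candidate alpha on a log-spaced grid (1e-3 ... 1e2, 31
    points by default) beta is profiled out by IRLS; the best grid point
    is then refined by golden-section search on log(alpha) to a relative
    tolerance of 1e-4.  Standard errors come from the observed
    information at the optimum; p-values are Wald.
    """
    if isinstance(table, CovariateTable):
        y = _check_counts(table.y)
        X, names = table.design_matrix(covariates)
    else:
        y, X = table
        y = _check_counts(y)
        X = np.asarray(X, dtype=np.float64)
        names = ["intercept"] + [f"x{j}" for j in range(1, X.shape[1])]
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"{n} observations cannot identify {p + 1} parameters")
    if alpha_grid is None:
        alpha_grid = np.logspace(-3, 2, 31)
    alpha_grid = np.asarray(alpha_grid, dtype=np.float64)

    beta_warm: np.ndarray | None = None
    grid_aic = np.empty(len(alpha_grid))
    grid_beta: list[np.ndarray] = []
    for i, a in enumerate(alpha_grid):
        beta_a, _, _, _ = _irls(y, X, a, beta0=beta_warm)
        beta_warm = beta_a
        grid_aic[i] = _aic(nb_loglik(y, X, beta_a, a), p + 1)
        grid_beta.append(beta_a)
    best = int(np.argmin(grid_aic))

    def profile_aic(log_a: float, warm: np.ndarray) -> tuple[float, np.ndarray]:
        a = math.exp(log_a)
        b, _, _, _ = _irls(y, X, a, beta0=warm)
        return _aic(nb_loglik(y, X, b, a), p + 1), b

    lo = math.log(alpha_grid[max(best - 1, 0)])
    hi = math.log(alpha_grid[min(best + 1, len(alpha_grid) - 1)])
    beta_best = grid_beta[best]
    if hi > lo:
        invphi = (math.sqrt(5.0) - 1.0) / 2.0
        a_l, b_l = lo, hi
        x1 = b_l - invphi * (b_l - a_l)
        x2 = a_l + invphi * (b_l - a_l)
        f1, bx1 = profile_aic(x1, beta_best)
        f2, bx2 = profile_aic(x2, beta_best)
        while (b_l - a_l) > rel_tol:
            if f1 <= f2:
                b_l, x2, f2 = x2, x1, f1
                x1 = b_l - invphi * (b_l - a_l)
                f1, bx1 = profile_aic(x1, bx1)
            else:
                a_l, x1, f1 = x1, x2, f2
                x2 = a_l + invphi * (b_l - a_l)
                f2, bx2 = profile_aic(x2, bx2)
        log_a_hat = x1 if f1 <= f2 else x2
        cand_alpha = math.exp(log_a_hat)
        cand_beta, _, n_iter, _ = _irls(y, X, cand_alpha, beta0=beta_best)
        cand_aic = _aic(nb_loglik(y, X, cand_beta, cand_alpha), p + 1)
        if cand_aic <= grid_aic[best]:
            alpha_hat, beta_hat, aic_hat = cand_alpha, cand_beta, cand_aic
        else:
            alpha_hat, beta_hat, aic_hat = alpha_grid[best], beta_best, grid_aic[best]
            n_iter = 0
    else:
        alpha_hat, beta_hat, aic_hat = alpha_grid[best], beta_best, grid_aic[best]
        n_iter = 0
    assert aic_hat <= grid_aic.min() + 1e-9

    ll = nb_loglik(y, X, beta_hat, alpha_hat)
    eta = np.clip(X @ beta_hat, -LINK_CLIP, LINK_CLIP)
    mu = np.exp(eta)
    # observed information for beta: sum_i x x' mu (1 + a y) / (1 + a mu)^2
    w_obs = mu * (1.0 + alpha_hat * y) / (1.0 + alpha_hat * mu) ** 2
    info = X.T @ (X * w_obs[:, None])
    cov = np.linalg.pinv(info)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        zval = np.where(se > 0, beta_hat / se, np.inf)
    pvals = 2.0 * norm.sf(np.abs(zval))
    return NBFit(
        names=names,
        beta=beta_hat,
        alpha=float(alpha_hat),
        loglik=ll,
        aic=aic_hat,
        std_errors=se,
        p_values=pvals,
        irr=np.exp(beta_hat),
        n_obs=n,
        n_iter=n_iter,
        alpha_grid=alpha_grid,
        alpha_grid_aic=grid_aic,
        deviance=nb_deviance(y, mu, alpha_hat),
    )


def irr(beta: float | np.ndarray) -> np.ndarray:
    """Incidence-rate ratio exp(beta): multiplicative effect on the mean."""
    return np.exp(beta)


def mcfadden_r2(loglik_full: float, loglik_null: float) -> float:
    return 1.0 - loglik_full / loglik_null


def nagelkerke_r2(loglik_full: float, loglik_null: float, n: int) -> float:
    cox_snell = 1.0 - math.exp(2.0 * (loglik_null - loglik_full) / n)
    max_cs = 1.0 - math.exp(2.0 * loglik_null / n)
    return cox_snell / max_cs


def report(
    fit: NBFit,
    table: CovariateTable | tuple[np.ndarray, np.ndarray],
    null_fit: NBFit | None = None,
) -> pd.DataFrame:
    """Model report: estimate, standardized estimate, SE, Wald p, IRR,
    plus McFadden and Nagelkerke pseudo-R2 against the intercept-only
    null (fitted with the same alpha-selection procedure).

    The standardized estimate is beta_j * SD(x_j) / SD(y), the
    linear-model convention applied to the raw response — approximate in
    a GLM but directly comparable across covariates.
    """
    if isinstance(table, CovariateTable):
        y = table.y.astype(np.float64)
        X, _ = table.design_matrix([n for n in fit.names if n != "intercept"])
    else:
        y, X = table
        y = np.asarray(y, dtype=np.float64)
        X = np.asarray(X, dtype=np.float64)
    if null_fit is None:
        null_fit = fit_nb((y, np.ones((len(y), 1))))
    sd_y = y.std(ddof=1)
    std_beta = np.empty_like(fit.beta)
    for j, name in enumerate(fit.names):
        if name == "intercept":
            std_beta[j] = np.nan
            continue
        sd_x = X[:, j].std(ddof=1)
        std_beta[j] = fit.beta[j] * sd_x / sd_y
    fit.standardized_beta = std_beta
    fit.r2_mcfadden = mcfadden_r2(fit.loglik, null_fit.loglik)
    fit.r2_nagelkerke = nagelkerke_r2(fit.loglik, null_fit.loglik, fit.n_obs)
    df = pd.DataFrame(
        {
            "term": fit.names,
            "estimate": fit.beta,
            "std_estimate": std_beta,
            "std_error": fit.std_errors,
            "p_value": fit.p_values,
            "irr": fit.irr,
        }
    )
    df.attrs["alpha"] = fit.alpha
    df.attrs["aic"] = fit.aic
    df.attrs["loglik"] = fit.loglik
    df.attrs["r2_mcfadden"] = fit.r2_mcfadden
    df.attrs["r2_nagelkerke"] = fit.r2_nagelkerke
    return df


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def vif(X: np.ndarray, names: Sequence[str] | None = None) -> pd.DataFrame:
    """Variance inflation factors, one per column of ``X``.

    Each column is regressed (with intercept) on the remaining columns;
    VIF_j = 1/(1 - R2_j).  A perfectly collinear column yields inf and
    is flagged rather than raising.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("vif requires at least two columns")
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    out = np.empty(p)
    for j in range(p):
        xj = X[:, j]
        others = np.column_stack(
            [np.ones(n), np.delete(X, j, axis=1)]
        )
        coef, *_ = np.linalg.lstsq(others, xj, rcond=None)
        resid = xj - others @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((xj - xj.mean()) ** 2).sum())
        if ss_tot == 0:
            out[j] = np.inf
        elif ss_res / ss_tot < 1e-12:
            out[j] = np.inf
        else:
            out[j] = 1.0 / (ss_res / ss_tot)
    return pd.DataFrame(
        {"term": list(names), "vif": out, "flagged": out > 10.0}
    )


def grid_rook_weights(nrows: int, ncols: int) -> sparse.csr_matrix:
    """Row-standardised rook-contiguity weights for a full grid, cells
    flattened in C order."""
    n = nrows * ncols
    rows, cols = [], []
    for r in range(nrows):
        for c in range(ncols):
            i = r * ncols + c
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < nrows and 0 <= cc < ncols:
                    rows.append(i)
                    cols.append(rr * ncols + cc)
    w = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )
    rs = np.asarray(w.sum(axis=1)).ravel()
    return sparse.diags(1.0 / rs) @ w


def _knn_weights(coords: np.ndarray, k: int) -> sparse.csr_matrix:
    from scipy.spatial import cKDTree

    n = len(coords)
    tree = cKDTree(coords)
    _, idx = tree.query(coords, k=k + 1)
    rows = np.repeat(np.arange(n), k)
    cols = idx[:, 1:].ravel()  # drop self
    w = sparse.csr_matrix((np.ones(n * k), (rows, cols)), shape=(n, n))
    return sparse.diags(np.full(n, 1.0 / k)) @ w


def morans_i(
    residuals: np.ndarray,
    coords: np.ndarray | None = None,
    k_neighbors: int = 8,
    n_permutations: int = 999,
    seed: int = 0,
    weights: sparse.spmatrix | None = None,
) -> tuple[float, float]:
    """Global Moran's I of residuals with a seeded permutation p-value.

    Weights default to row-standardised k-nearest-neighbour (k=8) built
    from ``coords``; pass ``weights`` to use another scheme (e.g. rook
    contiguity).  The p-value is two-sided against the permutation null.
    """
    z = np.asarray(residuals, dtype=np.float64)
    n = z.size
    if z.std() == 0:
        raise ValueError("residuals are constant; Moran's I is undefined")
    if weights is None:
        if coords is None:
            raise ValueError("provide coords for kNN weights, or explicit weights")
        coords = np.asarray(coords, dtype=np.float64)
        if n < k_neighbors + 1:
            raise ValueError("need at least k_neighbors + 1 observations")
        weights = _knn_weights(coords, k_neighbors)
    z = z - z.mean()
    w_sum = weights.sum()
    lag = weights @ z
    i_obs = (n / w_sum) * float(z @ lag) / float(z @ z)
    rng = np.random.default_rng(seed)
    denom = float(z @ z)
    count_hi = 0
    count_lo = 0
    for _ in range(n_permutations):
        zp = rng.permutation(z)
        i_p = (n / w_sum) * float(zp @ (weights @ zp)) / denom
        if i_p >= i_obs:
            count_hi += 1
        if i_p <= i_obs:
            count_lo += 1
    p_hi = (count_hi + 1) / (n_permutations + 1)
    p_lo = (count_lo + 1) / (n_permutations + 1)
    p = min(1.0, 2.0 * min(p_hi, p_lo))
    return i_obs, p
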