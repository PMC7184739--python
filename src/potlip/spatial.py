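"""Spatial surfaces: GAMM mean interpolation and extreme-quantile arrival maps.

Two penalised thin-plate-spline models over (longitude, latitude):

* :class:`SurfaceGAMM` — the mean-surface model

      Y_ij = s(longitude, latitude) + u_i + eps_ij,

  a thin-plate regression spline plus a Gaussian random intercept u_i per
  site, so both intra-site and inter-site variation enter the
  uncertainty.  The smoothing parameter and the random-intercept variance
  are chosen by restricted maximum likelihood (REML).  Predictions are
  the population surface (random intercepts excluded) with a standard
  error per grid cell; cells whose SE exceeds a threshold are masked.

* :class:`QuantileSurfaceGAMM` — an extreme-quantile surface: the same
  spline basis fitted by penalised pinball (check) loss at a low quantile
  tau (default 0.5%), replacing the fragile "earliest date = minimum"
  convention for first-arrival mapping.  Smoothing is chosen by
  cross-validated pinball loss and standard errors by case-resampling
  bootstrap (an optimistic, lower-bound uncertainty).

Coordinates are raw degrees fed to an isotropic smoother; an optional
cosine-latitude scaling of longitude is available because a degree of
longitude shrinks poleward.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, spatial as sspatial
from scipy.cluster.vq import kmeans2
from scipy.special import expit

logger = logging.getLogger("potlip")

__all__ = [
    "SpatialSurface",
    "SurfaceGAMM",
    "GammResults",
    "QuantileSurfaceGAMM",
    "QuantileSurfaceResults",
    "fit_averager",
    "predict_surface",
    "fit_spreadr",
    "arrival_map",
]


# --------------------------------------------------------------------------
# thin-plate spline basis


def _tps_eta(r: np.ndarray) -> np.ndarray:
    """Radial basis of the 2-d thin-plate spline: r^2 log r, with 0 at 0."""
    out = np.zeros_like(r)
    pos = r > 0
    out[pos] = r[pos] ** 2 * np.log(r[pos])
    return out


def _pairwise_eta(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    d = sspatial.distance.cdist(a, b)
    return _tps_eta(d)


@dataclass
class _TpsBasis:
    """Low-rank TPS basis: unpenalised null space [1, lon, lat] plus
    penalised radial functions at ``knots``, with the side constraint
    absorbed by a QR reparameterisation."""

    knots: np.ndarray           # (m, 2)
    q2: np.ndarray              # (m, m-3) null-space projector
    penalty: np.ndarray         # (m-3, m-3) positive definite

    @classmethod
    def build(cls, xy: np.ndarray, k: int, seed: int = 0) -> "_TpsBasis":
        uniq = np.unique(xy, axis=0)
        if len(uniq) <= k:
            knots = uniq
        else:
            # deterministic space-filling knot selection
            _, labels = kmeans2(uniq, k, minit="++", seed=seed)
            knots = np.array(
                [uniq[labels == j].mean(axis=0) for j in np.unique(labels)]
            )
        m = len(knots)
        if m < 4:
            raise ValueError(
                f"need >= 4 distinct locations for a thin-plate spline, got {m}"
            )
        t = np.column_stack([np.ones(m), knots])
        q, _ = np.linalg.qr(t, mode="complete")
        q2 = q[:, 3:]
        e_kk = _pairwise_eta(knots, knots)
        pen = q2.T @ e_kk @ q2
        pen = (pen + pen.T) / 2.0
        # tiny ridge guards rank deficiency from near-collinear knots
        pen += 1e-10 * np.eye(pen.shape[0]) * max(1.0, np.abs(pen).max())
        return cls(knots=knots, q2=q2, penalty=pen)

    def design(self, xy: np.ndarray) -> np.ndarray:
        """Rows [1, lon, lat, radial...] for arbitrary locations."""
        t = np.column_stack([np.ones(len(xy)), xy])
        e = _pairwise_eta(xy, self.knots)
        return np.column_stack([t, e @ self.q2])

    @property
    def n_spline(self) -> int:
        return self.q2.shape[1]


def _scale_lonlat(xy: np.ndarray, cos_lat: bool) -> np.ndarray:
    if not cos_lat:
        return xy
    out = xy.copy()
    out[:, 0] = out[:, 0] * np.cos(np.deg2rad(np.mean(xy[:, 1])))
    return out


# --------------------------------------------------------------------------
# surfaces


@dataclass
class SpatialSurface:
    """A gridded prediction with per-cell standard errors and masks.

    ``value``/``se``/``mask``/``extrapolated`` are (n_lat, n_lon) arrays
    over the ``lons`` x ``lats`` lattice.  ``mask`` is True where the SE
    meets or exceeds the masking threshold; ``extrapolated`` flags cells
    outside the convex hull of the data.
    """

    lons: np.ndarray
    lats: np.ndarray
    value: np.ndarray
    se: np.ndarray
    mask: np.ndarray
    extrapolated: np.ndarray
    units: str = ""
    se_mask: float = np.inf

    def to_frame(self):
        import pandas as pd

        lon_g, lat_g = np.meshgrid(self.lons, self.lats)
        return pd.DataFrame(
            {
                "longitude": lon_g.ravel(),
                "latitude": lat_g.ravel(),
                "value": self.value.ravel(),
                "se": self.se.ravel(),
                "mask": self.mask.ravel(),
                "extrapolated": self.extrapolated.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6g")

    def plot(self, ax=None, show_mask: bool = True):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 6))
        shown = np.where(self.mask & show_mask, np.nan, self.value)
        im = ax.pcolormesh(self.lons, self.lats, shown, shading="auto")
        plt.colorbar(im, ax=ax, label=self.units)
        ax.set_xlabel("longitude (deg E)")
        ax.set_ylabel("latitude (deg N)")
        return ax


def _default_grid(xy: np.ndarray, resolution: float, pad: float = 1.0):
    lon_min, lat_min = xy.min(axis=0) - pad
    lon_max, lat_max = xy.max(axis=0) + pad
    lons = np.arange(lon_min, lon_max + resolution / 2, resolution)
    lats = np.arange(lat_min, lat_max + resolution / 2, resolution)
    return lons, lats


def _hull_flags(xy: np.ndarray, grid_xy: np.ndarray) -> np.ndarray:
    """True for grid points outside the convex hull of the data."""
    if len(np.unique(xy, axis=0)) < 3:
        return np.ones(len(grid_xy), dtype=bool)
    try:
        tri = sspatial.Delaunay(xy)
    except sspatial.QhullError:
        return np.ones(len(grid_xy), dtype=bool)
    return tri.find_simplex(grid_xy) < 0


# --------------------------------------------------------------------------
# mean-surface GAMM


class SurfaceGAMM:
    """Thin-plate spline GAMM for a spatially varying mean with site
    random intercepts.

    Parameters
    ----------
    lon, lat : arrays (n_obs,)
        Observation coordinates (usually repeated per site).
    y : array (n_obs,)
        Response (e.g. Δ13C in ‰).
    site_ids : sequence of hashables (n_obs,)
        Site labels defining the random-intercept grouping; at least two
        distinct sites are required (with a single site the intercept is
        confounded with the smooth).
    k : int, optional
        Spline basis rank; default min(40, n_distinct_locations).
    cos_lat : bool
        Scale longitudes by cos(mean latitude) before smoothing.
    """

    def __init__(self, lon, lat, y, site_ids, k: Optional[int] = None,
                 cos_lat: bool = False, seed: int = 0):
        self.xy_raw = np.column_stack([np.asarray(lon, float), np.asarray(lat, float)])
        self.cos_lat = cos_lat
        self.xy = _scale_lonlat(self.xy_raw, cos_lat)
        self.y = np.asarray(y, dtype=float)
        self.site_ids = list(site_ids)
        if not (len(self.y) == len(self.xy) == len(self.site_ids)):
            raise ValueError("lon, lat, y, site_ids must have equal length")
        sites = sorted(set(self.site_ids), key=str)
        if len(sites) < 2:
            raise ValueError(
                "a single site cannot identify the random intercept; "
                "supply >= 2 sites"
            )
        self._site_index = {s: i for i, s in enumerate(sites)}
        self.n_sites = len(sites)

        n_loc = len(np.unique(self.xy, axis=0))
        if k is None:
            k = min(40, n_loc)
        if k > n_loc:
            raise ValueError(
                f"basis rank k={k} exceeds the {n_loc} distinct locations; "
                f"use k <= {n_loc}"
            )
        if len(self.y) < k + 2:
            raise ValueError(
                f"k={k} needs at least {k + 2} observations, have {len(self.y)}; "
                f"try k <= {len(self.y) - 2}"
            )
        self.basis = _TpsBasis.build(self.xy, k, seed=seed)

        # full design: [fixed(3) | spline | site indicators]
        self._x_smooth = self.basis.design(self.xy)
        z = np.zeros((len(self.y), self.n_sites))
        for row, s in enumerate(self.site_ids):
            z[row, self._site_index[s]] = 1.0
        self._x = np.column_stack([self._x_smooth, z])
        self._p_smooth = self._x_smooth.shape[1]

    # -- REML machinery ----------------------------------------------------

    def _penalty_total(self, lam: float, lam_u: float) -> np.ndarray:
        p = self._x.shape[1]
        s = np.zeros((p, p))
        s[3:self._p_smooth, 3:self._p_smooth] = lam * self.basis.penalty
        idx = np.arange(self._p_smooth, p)
        s[idx, idx] = lam_u
        return s

    def _reml_score(self, log_lam: float, log_lam_u: float) -> float:
        # clamp the search range: beyond ~e^30 the fit is numerically flat
        log_lam = float(np.clip(log_lam, -30.0, 30.0))
        log_lam_u = float(np.clip(log_lam_u, -30.0, 30.0))
        lam, lam_u = np.exp(log_lam), np.exp(log_lam_u)
        x, y = self._x, self.y
        n = len(y)
        s = self._penalty_total(lam, lam_u)
        a = x.T @ x + s
        try:
            chol = np.linalg.cholesky(a)
        except np.linalg.LinAlgError:
            return 1e12
        b = x.T @ y
        beta = np.linalg.solve(a, b)
        pen_rss = float(y @ y - b @ beta)
        if pen_rss <= 0:
            pen_rss = 1e-12
        n_fixed = 3
        sigma2 = pen_rss / (n - n_fixed)
        logdet_a = 2.0 * np.log(np.diag(chol)).sum()
        sign, logdet_pen = np.linalg.slogdet(self.basis.penalty)
        rank_s = self.basis.penalty.shape[0]
        logdet_s = rank_s * np.log(lam) + logdet_pen + self.n_sites * np.log(lam_u)
        return float(
            (n - n_fixed) * (np.log(2 * np.pi * sigma2) + 1.0)
            + logdet_a - logdet_s
        )

    def fit(self, lam: Optional[float] = None, lam_u: Optional[float] = None,
            method: str = "reml") -> "GammResults":
        """Estimate coefficients and smoothing/variance parameters.

        ``lam``/``lam_u`` fix the spline smoothing parameter and the
        random-intercept precision instead of estimating them by REML.
        """
        if lam is not None and lam_u is not None:
            best = (np.log(lam), np.log(lam_u))
        else:
            if method != "reml":
                raise ValueError(f"unknown smoothing selection method {method!r}")
            # coarse grid start, then Nelder-Mead polish
            grid = np.log(10.0 ** np.arange(-4.0, 6.0, 2.0))
            scores = [(self._reml_score(a, b), a, b) for a in grid for b in grid]
            _, a0, b0 = min(scores, key=lambda t: t[0])
            res = optimize.minimize(
                lambda v: self._reml_score(v[0], v[1]),
                x0=[a0, b0], method="Nelder-Mead",
                options={"xatol": 1e-3, "fatol": 1e-6, "maxiter": 400},
            )
            best = res.x
            if lam is not None:
                best = (np.log(lam), best[1])
            if lam_u is not None:
                best = (best[0], np.log(lam_u))
        best = np.clip(best, -30.0, 30.0)
        lam_hat, lam_u_hat = float(np.exp(best[0])), float(np.exp(best[1]))

        s = self._penalty_total(lam_hat, lam_u_hat)
        a = self._x.T @ self._x + s
        b = self._x.T @ self.y
        beta = np.linalg.solve(a, b)
        fitted = self._x @ beta
        resid = self.y - fitted
        pen_rss = float(self.y @ self.y - b @ beta)
        n = len(self.y)
        sigma2 = max(pen_rss, 1e-12) / (n - 3)
        vb = np.linalg.inv(a) * sigma2
        sigma_u2 = sigma2 / lam_u_hat
        logger.info(
            "SurfaceGAMM: lambda=%.4g, sigma_u^2=%.4g, sigma_eps^2=%.4g (n=%d, "
            "sites=%d, k=%d)", lam_hat, sigma_u2, sigma2, n, self.n_sites,
            self.basis.n_spline + 3,
        )
        return GammResults(
            model=self, beta=beta, vb=vb, lam=lam_hat, lam_u=lam_u_hat,
            sigma2=sigma2, sigma_u2=sigma_u2, fitted=fitted, resid=resid,
        )


@dataclass
class GammResults:
    """Fitted mean-surface GAMM.

    ``sigma2`` is the residual variance, ``sigma_u2`` the site
    random-intercept variance; ``vb`` is the Bayesian posterior
    covariance of all coefficients.
    """

    model: SurfaceGAMM
    beta: np.ndarray
    vb: np.ndarray
    lam: float
    lam_u: float
    sigma2: float
    sigma_u2: float
    fitted: np.ndarray
    resid: np.ndarray

    def predict(self, lon, lat, se: bool = False):
        """Population-surface prediction (random intercepts excluded)."""
        xy = _scale_lonlat(
            np.column_stack([np.asarray(lon, float), np.asarray(lat, float)]),
            self.model.cos_lat,
        )
        x = self.model.basis.design(xy)
        p = x.shape[1]
        mu = x @ self.beta[:p]
        if not se:
            return mu
        var = np.einsum("ij,jk,ik->i", x, self.vb[:p, :p], x)
        return mu, np.sqrt(np.maximum(var, 0.0))

    def predict_surface(
        self,
        resolution: float = 0.5,
        se_mask: float = 0.30,
        lons: Optional[np.ndarray] = None,
        lats: Optional[np.ndarray] = None,
        units: str = "permil",
    ) -> SpatialSurface:
        """Predict on a regular grid; cells with SE >= ``se_mask`` are
        masked and cells outside the data hull flagged extrapolated."""
        if lons is None or lats is None:
            lons, lats = _default_grid(self.model.xy_raw, resolution)
        lon_g, lat_g = np.meshgrid(lons, lats)
        mu, se = self.predict(lon_g.ravel(), lat_g.ravel(), se=True)
        shape = lon_g.shape
        grid_xy = np.column_stack([lon_g.ravel(), lat_g.ravel()])
        extrap = _hull_flags(self.model.xy_raw, grid_xy).reshape(shape)
        se = se.reshape(shape)
        surface = SpatialSurface(
            lons=np.asarray(lons), lats=np.asarray(lats),
            value=mu.reshape(shape), se=se, mask=se >= se_mask,
            extrapolated=extrap, units=units, se_mask=se_mask,
        )
        logger.info(
            "surface %dx%d cells, %.1f%% masked at SE >= %g",
            shape[0], shape[1], 100.0 * surface.mask.mean(), se_mask,
        )
        return surface

    def summary(self):
        import pandas as pd

        return pd.Series(
            {
                "n_obs": len(self.model.y),
                "n_sites": self.model.n_sites,
                "k": self.model.basis.n_spline + 3,
                "lambda": self.lam,
                "sigma_u2": self.sigma_u2,
                "sigma_eps2": self.sigma2,
                "rmse_fitted": float(np.sqrt(np.mean(self.resid**2))),
            }
        )


# --------------------------------------------------------------------------
# extreme-quantile surface


def _smooth_pinball(r: np.ndarray, tau: float, eps: float) -> np.ndarray:
    """Smoothed check loss: tau*r + eps*softplus(-r/eps); recovers the
    pinball loss as eps -> 0."""
    return tau * r + eps * np.logaddexp(0.0, -r / eps)


class QuantileSurfaceGAMM:
    """Penalised thin-plate-spline quantile regression over (lon, lat).

    Fits the tau-quantile surface of per-site responses (typically
    earliest arrival dates in cal BC) by minimising a smoothed pinball
    loss plus the TPS curvature penalty.
    """

    def __init__(self, lon, lat, y, tau: float = 0.005,
                 k: Optional[int] = None, cos_lat: bool = False,
                 eps: Optional[float] = None, seed: int = 0):
        if not 0.0 < tau < 0.5:
            raise ValueError(f"tau must lie in (0, 0.5), got {tau}")
        self.xy_raw = np.column_stack([np.asarray(lon, float), np.asarray(lat, float)])
        self.cos_lat = cos_lat
        self.xy = _scale_lonlat(self.xy_raw, cos_lat)
        self.y = np.asarray(y, dtype=float)
        self.tau = tau
        n_loc = len(np.unique(self.xy, axis=0))
        if k is None:
            k = min(30, n_loc)
        if len(self.y) < k + 2:
            raise ValueError(
                f"k={k} needs at least {k + 2} sites with dates, have {len(self.y)}"
            )
        self.basis = _TpsBasis.build(self.xy, k, seed=seed)
        self._x = self.basis.design(self.xy)
        scale = np.std(self.y)
        self.eps = eps if eps is not None else max(1e-6, 0.01 * (scale or 1.0))

    def _objective(self, theta: np.ndarray, lam: float, x: np.ndarray,
                   y: np.ndarray):
        r = y - x @ theta
        gamma = theta[3:]
        pen = self.basis.penalty
        loss = _smooth_pinball(r, self.tau, self.eps).sum() + lam * gamma @ pen @ gamma
        dloss_dr = self.tau - expit(-r / self.eps)
        grad = -x.T @ dloss_dr
        grad[3:] += 2.0 * lam * pen @ gamma
        return loss, grad

    def _solve(self, lam: float, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        # warm start from the penalised least-squares fit
        a = x.T @ x + 1e-8 * np.eye(x.shape[1])
        a[3:, 3:] += lam * self.basis.penalty
        theta0 = np.linalg.solve(a, x.T @ y)
        res = optimize.minimize(
            self._objective, theta0, args=(lam, x, y), jac=True,
            method="L-BFGS-B", options={"maxiter": 500},
        )
        return res.x

    def _cv_pinball(self, lam: float, n_folds: int, seed: int) -> float:
        rng = np.random.default_rng(seed)
        n = len(self.y)
        folds = rng.permutation(n) % n_folds
        total = 0.0
        for fold in range(n_folds):
            hold = folds == fold
            theta = self._solve(lam, self._x[~hold], self.y[~hold])
            r = self.y[hold] - self._x[hold] @ theta
            total += float(np.sum(np.where(r >= 0, self.tau * r, (self.tau - 1) * r)))
        return total

    def fit(self, lam: Optional[float] = None,
            lam_grid: Optional[Sequence[float]] = None,
            n_folds: int = 5, seed: int = 0) -> "QuantileSurfaceResults":
        """Fit the quantile surface; smoothing by site-fold cross-validated
        pinball loss unless ``lam`` is given."""
        if lam is None:
            if lam_grid is None:
                lam_grid = 10.0 ** np.arange(-2.0, 5.0)
            scores = {l: self._cv_pinball(l, n_folds, seed) for l in lam_grid}
            lam = min(scores, key=scores.get)
            logger.info("QuantileSurfaceGAMM: CV chose lambda=%.4g", lam)
        theta = self._solve(lam, self._x, self.y)
        return QuantileSurfaceResults(model=self, theta=theta, lam=float(lam))


@dataclass
class QuantileSurfaceResults:
    model: QuantileSurfaceGAMM
    theta: np.ndarray
    lam: float

    def predict(self, lon, lat) -> np.ndarray:
        xy = _scale_lonlat(
            np.column_stack([np.asarray(lon, float), np.asarray(lat, float)]),
            self.model.cos_lat,
        )
        return self.model.basis.design(xy) @ self.theta

    def bootstrap_se(self, lon, lat, reps: int = 200, seed: int = 0) -> np.ndarray:
        """Case-resampling bootstrap SE of the surface at given points.

        Documented caveat: resampling sites understates uncertainty at an
        extreme quantile — treat these SEs as optimistic lower bounds.
        """
        rng = np.random.default_rng(seed)
        xy = _scale_lonlat(
            np.column_stack([np.asarray(lon, float), np.asarray(lat, float)]),
            self.model.cos_lat,
        )
        xg = self.model.basis.design(xy)
        n = len(self.model.y)
        preds = np.empty((reps, len(xy)))
        for r in range(reps):
            idx = rng.integers(0, n, size=n)
            theta = self.model._solve(self.lam, self.model._x[idx], self.model.y[idx])
            preds[r] = xg @ theta
        return preds.std(axis=0, ddof=1)

    def arrival_map(
        self,
        resolution: float = 0.5,
        se_mask: float = np.inf,
        bootstrap_reps: int = 200,
        seed: int = 0,
        lons: Optional[np.ndarray] = None,
        lats: Optional[np.ndarray] = None,
    ) -> SpatialSurface:
        """Gridded arrival-date surface (cal BC) with bootstrap SEs."""
        if lons is None or lats is None:
            lons, lats = _default_grid(self.model.xy_raw, resolution)
        lon_g, lat_g = np.meshgrid(lons, lats)
        mu = self.predict(lon_g.ravel(), lat_g.ravel()).reshape(lon_g.shape)
        if bootstrap_reps > 0:
            se = self.bootstrap_se(
                lon_g.ravel(), lat_g.ravel(), reps=bootstrap_reps, seed=seed
            ).reshape(lon_g.shape)
        else:
            se = np.zeros_like(mu)
        grid_xy = np.column_stack([lon_g.ravel(), lat_g.ravel()])
        extrap = _hull_flags(self.model.xy_raw, grid_xy).reshape(lon_g.shape)
        return SpatialSurface(
            lons=np.asarray(lons), lats=np.asarray(lats), value=mu, se=se,
            mask=se >= se_mask, extrapolated=extrap, units="cal BC",
            se_mask=se_mask,
        )

    def exceedance_fraction(self) -> float:
        """Fraction of observations strictly below the fitted surface;
        should not exceed tau by more than ~2/n."""
        fitted = self.model._x @ self.theta
        return float(np.mean(self.model.y < fitted - 1e-9))


# --------------------------------------------------------------------------
# functional wrappers


def fit_averager(lon, lat, y, site_ids, k: Optional[int] = None,
                 method: str = "reml", **kwargs) -> GammResults:
    """Fit the mean-surface GAMM (thin wrapper over :class:`SurfaceGAMM`)."""
    return SurfaceGAMM(lon, lat, y, site_ids, k=k, **kwargs).fit(method=method)


def predict_surface(fit: GammResults, resolution: float = 0.5,
                    se_mask: float = 0.30, **kwargs) -> SpatialSurface:
    return fit.predict_surface(resolution=resolution, se_mask=se_mask, **kwargs)


def fit_spreadr(lon, lat, dates, tau: float = 0.005, k: Optional[int] = None,
                **kwargs) -> QuantileSurfaceResults:
    """Fit the extreme-quantile arrival surface (thin wrapper over
    :class:`QuantileSurfaceGAMM`)."""
    fit_kwargs = {key: kwargs.pop(key) for key in ("lam", "lam_grid", "n_folds", "seed")
                  if key in kwargs}
    model = QuantileSurfaceGAMM(lon, lat, dates, tau=tau, k=k, **kwargs)
    return model.fit(**fit_kwargs)


def arrival_map(fit: QuantileSurfaceResults, resolution: float = 0.5,
                se_mask: float = np.inf, **kwargs) -> SpatialSurface:
    return fit.arrival_map(resolution=resolution, se_mask=se_mask, **kwargs)
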