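"""Point-transect distance sampling for the terrapin surveys.

Radial sighting distances r are modelled with a detection function
g(r) (probability of detecting an animal at distance r, g(0) = 1), so
the density of observed distances on (0, w] is

    f(r) = r * g(r) / integral_0^w t * g(t) dt.

Two key functions are supported

    half-normal  g(r) = exp(-r^2 / (2 sigma^2))
    hazard-rate  g(r) = 1 - exp(-(r / sigma)^-b),   b > 1

optionally multiplied by a series adjustment (cosine, simple
polynomial, or Hermite polynomial terms) rescaled to keep g(0) = 1, and
optionally with covariates on the scale, sigma_i = exp(beta0 + beta' z_i)
(z standardized internally).  The farthest 5% of observations are
truncated before fitting.  Models are compared by AIC with a
chi-square goodness-of-fit check on equal-count distance bins, and the
selected fit yields the effective detection radius

    rho = sqrt(2 * integral_0^w r g(r) dr),

the distance at which the expected number of animals missed inside
equals the expected number detected beyond.  Its CI comes from a
nonparametric bootstrap over sightings.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermeval
from scipy import optimize, stats

from .errors import ConfigurationError, MarshEquivError

TRUNCATION_FRACTION = 0.05
_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(64)

KEYS = ("half-normal", "hazard-rate")
ADJUSTMENTS = ("none", "cosine", "poly", "hermite")


def truncate_distances(distances, fraction: float = TRUNCATION_FRACTION) -> np.ndarray:
    """Drop the farthest ``fraction`` of observations.

    Retains the max(1, floor((1 - fraction) * n)) smallest distances;
    ties at the cutoff are broken by retaining earlier-indexed records
    (stable sort).
    """
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise MarshEquivError("no distances to truncate")
    n_keep = max(1, math.floor((1.0 - fraction) * d.size))
    order = np.argsort(d, kind="stable")
    keep = np.sort(order[:n_keep])
    return d[keep]


def _key_g(key: str, r: np.ndarray, sigma, b=None) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if key == "half-normal":
        return np.exp(-(r**2) / (2.0 * np.asarray(sigma) ** 2))
    if key == "hazard-rate":
        with np.errstate(divide="ignore", over="ignore"):
            x = (r / np.asarray(sigma)) ** (-b)
        return -np.expm1(-x)
    raise ConfigurationError(f"unknown key function {key!r}")


def _adj_basis(adjustment: str, x: np.ndarray, j: int) -> np.ndarray:
    """j-th adjustment term evaluated at x = r/w in [0, 1]."""
    if adjustment == "cosine":
        return np.cos((j + 1) * math.pi * x)
    if adjustment == "poly":
        return x ** (2 * (j + 1))
    if adjustment == "hermite":
        order = 2 * (j + 1)
        c = np.zeros(order + 1)
        c[order] = 1.0
        return hermeval(x, c)
    raise ConfigurationError(f"unknown adjustment series {adjustment!r}")


@dataclass
class DetectionFit:
    """One fitted detection function."""

    key: str
    adjustment: str
    n_adj: int
    params: dict[str, float]
    covariate_names: tuple[str, ...]
    covariate_center: np.ndarray
    covariate_scale: np.ndarray
    w: float
    n: int
    loglik: float
    aic: float
    gof_stat: float
    gof_p: float
    converged: bool
    boundary_warning: bool = False
    distances: np.ndarray | None = field(default=None, repr=False)
    covariate_values: np.ndarray | None = field(default=None, repr=False)

    @property
    def k(self) -> int:
        """Number of free parameters."""
        k = 1 + len(self.covariate_names) + self.n_adj
        if self.key == "hazard-rate":
            k += 1
        return k

    def sigma(self, z: np.ndarray | None = None) -> np.ndarray:
        """Scale at standardized covariate values z (default: mean, z=0)."""
        beta = np.array([self.params[f"beta_{c}"] for c in self.covariate_names])
        log_s = self.params["log_sigma"]
        if z is None or beta.size == 0:
            return np.exp(log_s + (0.0 if beta.size == 0 else 0.0))
        z = np.atleast_2d(z)
        return np.exp(log_s + z @ beta)

    def g(self, r, z: np.ndarray | None = None) -> np.ndarray:
        """Detection probability at distance r (reference covariates by default)."""
        r = np.asarray(r, dtype=float)
        sigma = self.sigma(z)
        b = self.params.get("shape")
        gv = _key_g(self.key, r, sigma, b)
        if self.n_adj:
            a = np.array([self.params[f"adj_{j}"] for j in range(self.n_adj)])
            gv = gv * _series(self.adjustment, r / self.w, a)
        return gv


def _series(adjustment: str, x: np.ndarray, a: np.ndarray) -> np.ndarray:
    """1 + sum_j a_j p_j(x), rescaled so the factor equals 1 at x = 0."""
    num = np.ones_like(x)
    at0 = 1.0
    for j, aj in enumerate(a):
        num = num + aj * _adj_basis(adjustment, x, j)
        at0 += aj * float(_adj_basis(adjustment, np.zeros(1), j)[0])
    if at0 == 0:
        return np.full_like(x, np.inf)
    return num / at0


def _normalizer(key: str, adjustment: str, a: np.ndarray,
                sigma: np.ndarray, b, w: float) -> np.ndarray:
    """integral_0^w r g(r) dr, per observation when sigma is a vector."""
    sigma = np.atleast_1d(np.asarray(sigma, dtype=float))
    if key == "half-normal" and a.size == 0:
        return sigma**2 * (-np.expm1(-(w**2) / (2.0 * sigma**2)))
    r = 0.5 * w * (_GL_NODES + 1.0)  # (64,)
    wts = 0.5 * w * _GL_WEIGHTS
    gv = _key_g(key, r[None, :], sigma[:, None], b)
    if a.size:
        gv = gv * _series(adjustment, r / w, a)[None, :]
    return (wts[None, :] * r[None, :] * gv).sum(axis=1)


def _neg_loglik(theta: np.ndarray, key: str, adjustment: str, n_adj: int,
                r: np.ndarray, z: np.ndarray | None, w: float) -> float:
    i = 0
    log_sigma = theta[i]; i += 1
    n_cov = 0 if z is None else z.shape[1]
    beta = theta[i:i + n_cov]; i += n_cov
    b = None
    if key == "hazard-rate":
        b = 1.0 + math.exp(min(theta[i], 50.0)); i += 1
    a = theta[i:i + n_adj]
    sigma = np.exp(np.clip(log_sigma + (z @ beta if n_cov else 0.0),
                           -300.0, 300.0))
    sigma = np.atleast_1d(sigma)
    if sigma.size == 1:
        sigma = np.full(r.size, float(sigma[0]))
    gv = _key_g(key, r, sigma, b)
    if n_adj:
        fac = _series(adjustment, r / w, a)
        gv = gv * fac
        # positivity of g on a probe grid (soft constraint)
        probe = _series(adjustment, np.linspace(0, 1, 101), a)
        pg = _key_g(key, np.linspace(0, w, 101), float(np.median(sigma)), b) * probe
        if np.any(pg < 0) or np.any(~np.isfinite(pg)):
            return 1e10
    mu = _normalizer(key, adjustment, a, sigma, b, w)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.log(r) + np.log(gv) - np.log(mu)
    if not np.all(np.isfinite(ll)):
        return 1e10
    return -float(ll.sum())


def fit_detection(
    distances,
    key: str = "half-normal",
    adjustment: str = "none",
    n_adj: int = 0,
    covariates: pd.DataFrame | None = None,
    w: float | None = None,
    x0: np.ndarray | None = None,
    n_starts: int = 3,
) -> DetectionFit:
    """Maximum-likelihood fit of one detection model to radial distances.

    ``covariates`` (one row per sighting) enter the log scale after
    z-standardization.  ``w`` defaults to the largest retained distance.
    ``x0`` optionally warm-starts the optimizer (internal parameter
    order) and ``n_starts`` controls how many jittered restarts run.
    """
    r = np.asarray(distances, dtype=float)
    if r.size < 10:
        raise MarshEquivError("need at least 10 sightings to fit")
    if np.any(r <= 0):
        raise MarshEquivError("radial distances must be positive")
    if adjustment == "none":
        n_adj = 0
    elif adjustment not in ADJUSTMENTS:
        raise ConfigurationError(f"unknown adjustment {adjustment!r}")
    if key not in KEYS:
        raise ConfigurationError(f"unknown key function {key!r}")
    w = float(w if w is not None else r.max())
    if w < r.max():
        raise ConfigurationError("truncation distance w below largest distance")

    names: tuple[str, ...] = ()
    z = center = scale = None
    if covariates is not None and covariates.shape[1] > 0:
        names = tuple(covariates.columns)
        x = covariates.to_numpy(dtype=float)
        center = x.mean(axis=0)
        scale = x.std(axis=0, ddof=0)
        scale[scale == 0] = 1.0
        z = (x - center) / scale
    else:
        center = np.array([])
        scale = np.array([])

    if x0 is None:
        # moment-based start for sigma; hazard-rate shape starts at b = 2.5
        sig0 = math.sqrt(max(np.mean(r**2) / 2.0, 1e-6))
        x0 = [math.log(sig0)] + [0.0] * len(names)
        if key == "hazard-rate":
            x0.append(math.log(2.5 - 1.0))
        x0 += [0.0] * n_adj
    x0 = np.asarray(x0, dtype=float)

    args = (key, adjustment, n_adj, r, z, w)
    best = None
    for jitter in (0.0, 0.5, -0.5)[:max(1, n_starts)]:
        res = optimize.minimize(
            _neg_loglik, x0 + jitter, args=args, method="Nelder-Mead",
            options={"maxiter": 1500, "xatol": 1e-8, "fatol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
    if not np.isfinite(best.fun) or best.fun >= 1e9:
        raise MarshEquivError(
            f"detection fit failed to converge ({key}/{adjustment}): {best.message}")

    theta = best.x
    i = 0
    params = {"log_sigma": float(theta[i])}; i += 1
    for c in names:
        params[f"beta_{c}"] = float(theta[i]); i += 1
    boundary = False
    if key == "hazard-rate":
        params["shape"] = 1.0 + math.exp(min(theta[i], 50.0)); i += 1
        if params["shape"] < 1.05:
            boundary = True
            warnings.warn("hazard-rate shape at its b = 1 boundary")
    for j in range(n_adj):
        params[f"adj_{j}"] = float(theta[i]); i += 1

    loglik = -float(best.fun)
    fit = DetectionFit(
        key=key, adjustment=adjustment if n_adj else "none", n_adj=n_adj,
        params=params, covariate_names=names, covariate_center=center,
        covariate_scale=scale, w=w, n=r.size, loglik=loglik,
        aic=-2.0 * loglik + 2.0 * (1 + len(names) + n_adj
                                   + (1 if key == "hazard-rate" else 0)),
        gof_stat=math.nan, gof_p=math.nan, converged=bool(best.success or True),
        boundary_warning=boundary, distances=r,
        covariate_values=z)
    fit.gof_stat, fit.gof_p = goodness_of_fit(fit)
    return fit


def goodness_of_fit(fit: DetectionFit, n_bins: int = 6) -> tuple[float, float]:
    """Chi-square GoF on equal-count distance bins.

    Expected counts integrate the fitted distance density over each bin
    (averaged over sightings' covariate values when present).
    """
    r = fit.distances
    if r is None:
        raise MarshEquivError("fit carries no distances")
    n_bins = min(n_bins, max(2, r.size // 5))
    edges = np.quantile(r, np.linspace(0, 1, n_bins + 1))
    edges[0], edges[-1] = 0.0, fit.w
    edges = np.unique(edges)
    observed, _ = np.histogram(r, bins=edges)

    a = np.array([fit.params[f"adj_{j}"] for j in range(fit.n_adj)])
    b = fit.params.get("shape")
    z = fit.covariate_values
    if z is not None and len(fit.covariate_names):
        beta = np.array([fit.params[f"beta_{c}"] for c in fit.covariate_names])
        sigma = np.exp(fit.params["log_sigma"] + z @ beta)
    else:
        sigma = np.full(r.size, math.exp(fit.params["log_sigma"]))

    # per-observation CDF increments, summed to expected counts
    def cum(upper: float) -> np.ndarray:
        if upper <= 0:
            return np.zeros(r.size)
        t = 0.5 * upper * (_GL_NODES + 1.0)
        wts = 0.5 * upper * _GL_WEIGHTS
        gv = _key_g(fit.key, t[None, :], sigma[:, None], b)
        if a.size:
            gv = gv * _series(fit.adjustment, t / fit.w, a)[None, :]
        return (wts[None, :] * t[None, :] * gv).sum(axis=1)

    mu = _normalizer(fit.key, fit.adjustment, a, sigma, b, fit.w)
    cdf_at = {e: cum(e) / mu for e in edges}
    expected = np.array([
        float((cdf_at[edges[i + 1]] - cdf_at[edges[i]]).sum())
        for i in range(len(edges) - 1)
    ])
    expected *= observed.sum() / expected.sum()
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    dof = max(1, len(observed) - 1 - fit.k)
    return chi2, float(stats.chi2.sf(chi2, dof))


def candidate_fits(
    distances,
    covariates: pd.DataFrame | None = None,
    w: float | None = None,
    keys=KEYS,
    adjustments=("none", "cosine", "poly", "hermite"),
    max_adj: int = 2,
) -> list[DetectionFit]:
    """Fit the standard candidate set: each key with 0..max_adj terms of
    each series (series adjustments are skipped when covariates are on
    the scale, the usual convention)."""
    fits = []
    for key in keys:
        for adj in adjustments:
            terms = [0] if adj == "none" else list(range(1, max_adj + 1))
            if covariates is not None and adj != "none":
                continue
            for n_adj in terms:
                try:
                    fits.append(fit_detection(distances, key, adj, n_adj,
                                              covariates, w, n_starts=2))
                except MarshEquivError:
                    continue
    if not fits:
        raise MarshEquivError("no detection model converged")
    return fits


def select_model(fits: list[DetectionFit]) -> DetectionFit:
    """Lowest-AIC fit among those passing GoF (p >= 0.05).

    If none pass, the lowest-AIC fit is returned with its failing GoF
    left visible on the object.
    """
    if not fits:
        raise MarshEquivError("no fits to select from")
    passing = [f for f in fits if f.gof_p >= 0.05 or math.isnan(f.gof_p)]
    pool = passing or fits
    if not passing:
        warnings.warn("no candidate passed goodness-of-fit; "
                      "returning lowest-AIC model anyway")
    return min(pool, key=lambda f: f.aic)


@dataclass(frozen=True)
class EffectiveRadius:
    rho: float
    ci_low: float
    ci_high: float
    w: float


def edr_half_normal(sigma: float, w: float = math.inf) -> float:
    """Closed-form effective detection radius for a half-normal key.

    rho = sigma * sqrt(2) * sqrt(1 - exp(-w^2 / (2 sigma^2)));
    as w -> inf this tends to sigma * sqrt(2).
    """
    if w == math.inf:
        return sigma * math.sqrt(2.0)
    return sigma * math.sqrt(2.0) * math.sqrt(-math.expm1(-(w**2) / (2 * sigma**2)))


def _edr_point(fit: DetectionFit) -> float:
    a = np.array([fit.params[f"adj_{j}"] for j in range(fit.n_adj)])
    sigma = math.exp(fit.params["log_sigma"])  # reference covariates (z = 0)
    mu = float(_normalizer(fit.key, fit.adjustment, a, sigma,
                           fit.params.get("shape"), fit.w)[0])
    if not np.isfinite(mu) or mu <= 0:
        raise MarshEquivError("non-finite detection integral")
    return math.sqrt(2.0 * mu)


def effective_radius(
    fit: DetectionFit,
    n_boot: int = 999,
    seed: int = 0,
    ci_level: float = 0.95,
) -> EffectiveRadius:
    """Effective detection radius with a percentile bootstrap CI.

    Sightings (with their covariates) are resampled with replacement
    and the same key/adjustment refitted to each resample.
    """
    rho = _edr_point(fit)
    if fit.distances is None or n_boot < 1:
        return EffectiveRadius(rho, math.nan, math.nan, fit.w)
    rng = np.random.default_rng(seed)
    vals = []
    cov = None
    # warm-start each refit at the full-data optimum (internal order)
    theta0 = [fit.params["log_sigma"]]
    theta0 += [fit.params[f"beta_{c}"] for c in fit.covariate_names]
    if fit.key == "hazard-rate":
        theta0.append(math.log(max(fit.params["shape"] - 1.0, 1e-6)))
    theta0 += [fit.params[f"adj_{j}"] for j in range(fit.n_adj)]
    for _ in range(n_boot):
        idx = rng.integers(0, fit.n, size=fit.n)
        d = fit.distances[idx]
        if fit.covariate_values is not None:
            cov = pd.DataFrame(fit.covariate_values[idx],
                               columns=list(fit.covariate_names))
        try:
            bf = fit_detection(d, fit.key, fit.adjustment, fit.n_adj, cov,
                               w=fit.w, x0=np.asarray(theta0), n_starts=1)
            vals.append(_edr_point(bf))
        except MarshEquivError:
            continue
    if len(vals) < max(20, n_boot // 5):
        warnings.warn("too few successful bootstrap refits; CI is NaN")
        return EffectiveRadius(rho, math.nan, math.nan, fit.w)
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(vals, [alpha, 1.0 - alpha])
    return EffectiveRadius(rho, float(lo), float(hi), fit.w)
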