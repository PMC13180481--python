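"""Per-population negative-binomial trend models.

Each population's annual counts are modelled as NB(mu(year), theta) with a
log link, variance mu + mu^2/theta. Short series (6-9 observed years) get a
log-linear GLM; long series (>= 10 years) get a penalized cubic B-spline
smooth of year (a GAM), with the smoothing parameter chosen by an
approximate restricted marginal likelihood and theta by outer profile
maximum likelihood. The omnibus test of temporal change is a likelihood
ratio test of the fitted trend model against the intercept-only NB fit;
for the penalized smooth its reference distribution is chi-squared with
degrees of freedom equal to the difference in effective degrees of freedom,
which is approximate and documented as such.

Years are centered on the first observed year internally, so fits are
invariant to shifting the calendar. Gaps in a series are simply absent
rows; no imputation is performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.interpolate import BSpline
from scipy.special import gammaln
from scipy.stats import chi2, f as f_dist

logger = logging.getLogger(__name__)

MIN_OBS_GLM = 6
MIN_OBS_GAM = 10

_LOG_THETA_BOUNDS = (np.log(1e-2), np.log(1e7))
_LOG_LAMBDA_BOUNDS = (-8.0, 16.0)


class DegenerateSeriesError(ValueError):
    """All counts are zero: the population vanished before any signal."""


class NonConvergenceError(RuntimeError):
    """The iterative fit failed to converge within the iteration budget."""


@dataclass
class CountSeries:
    """One population's annual count records with site identity/coordinates."""

    site_id: str
    records: list[tuple[int, int]]
    x_m: float = 0.0
    y_m: float = 0.0

    def __post_init__(self) -> None:
        if len(self.records) < 1:
            raise ValueError("records must be non-empty")
        years = np.array([r[0] for r in self.records])
        counts = np.array([r[1] for r in self.records])
        if not np.all(np.diff(years) > 0):
            raise ValueError(f"site {self.site_id}: years must be strictly increasing")
        if (counts < 0).any():
            raise ValueError(f"site {self.site_id}: counts must be non-negative")

    @property
    def years(self) -> np.ndarray:
        return np.array([r[0] for r in self.records], dtype=float)

    @property
    def counts(self) -> np.ndarray:
        return np.array([r[1] for r in self.records], dtype=float)

    @property
    def n_obs(self) -> int:
        return len(self.records)


@dataclass
class FittedTrend:
    """A fitted per-population trend model, evaluable at any year."""

    site_id: str
    model_kind: Literal["GLM", "GAM"]
    n_obs: int
    first_year: int
    last_year: int
    coefficients: np.ndarray
    coef_covariance: np.ndarray
    basis_descriptor: dict
    theta_hat: float
    omnibus_p: float
    omnibus_stat: float
    loglik: float
    edf: float
    final_counts: tuple[int, int] = (0, 0)  # last two observed counts

    def design_matrix(self, years: np.ndarray) -> np.ndarray:
        """Model matrix rows at arbitrary (calendar) years."""
        t = np.atleast_1d(np.asarray(years, dtype=float)) - self.first_year
        bd = self.basis_descriptor
        if bd["kind"] == "linear":
            return np.column_stack([np.ones_like(t), t])
        return BSpline.design_matrix(
            t, bd["knots"], bd["degree"], extrapolate=True
        ).toarray()

    def predict_linear(self, years: np.ndarray) -> np.ndarray:
        """Linear predictor (log expected count) at the given years."""
        return self.design_matrix(years) @ self.coefficients


# ---------------------------------------------------------------------------
# eligibility / routing


def filter_eligible(
    series_set: Sequence[CountSeries],
    min_years: int = MIN_OBS_GLM,
    gam_threshold: int = MIN_OBS_GAM,
) -> tuple[list[CountSeries], dict[str, str], list[str]]:
    """Split populations into eligible (with GLM/GAM routing) and excluded.

    Populations need at least ``min_years`` distinct observed years
    (consecutive or not); 6-9 years route to the GLM, >= 10 to the GAM.
    """
    ids = [s.site_id for s in series_set]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate site_ids: {dupes}")
    eligible, routing, excluded = [], {}, []
    for s in series_set:
        n = len({year for year, _ in s.records})
        if n < min_years:
            excluded.append(s.site_id)
        else:
            eligible.append(s)
            routing[s.site_id] = "GAM" if n >= gam_threshold else "GLM"
    logger.info(
        "eligibility: %d eligible (%d GLM, %d GAM), %d excluded",
        len(eligible),
        sum(v == "GLM" for v in routing.values()),
        sum(v == "GAM" for v in routing.values()),
        len(excluded),
    )
    return eligible, routing, excluded


# ---------------------------------------------------------------------------
# NB likelihood and penalized IRLS


def _nb_loglik(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    mu = np.clip(mu, 1e-12, None)
    return float(
        np.sum(
            gammaln(y + theta)
            - gammaln(theta)
            - gammaln(y + 1)
            + theta * np.log(theta / (theta + mu))
            + y * np.log(mu / (theta + mu))
        )
    )


def _pirls(
    X: np.ndarray,
    y: np.ndarray,
    S: np.ndarray,
    lam: float,
    theta: float,
    beta0: np.ndarray | None = None,
    max_iter: int = 200,
    tol: float = 1e-9,
) -> dict:
    """Penalized IRLS for NB regression with log link and fixed theta.

    Solves for beta maximising loglik(beta) - lam/2 * beta' S beta. Returns
    the converged state (beta, eta, mu, working weights, penalized loglik).
    A warm start that fails to converge is retried from the default
    initialisation before giving up.
    """
    try:
        return _pirls_core(X, y, S, lam, theta, beta0, max_iter, tol)
    except NonConvergenceError:
        if beta0 is None:
            raise
        return _pirls_core(X, y, S, lam, theta, None, max_iter, tol)


def _pirls_core(
    X: np.ndarray,
    y: np.ndarray,
    S: np.ndarray,
    lam: float,
    theta: float,
    beta0: np.ndarray | None,
    max_iter: int,
    tol: float,
) -> dict:
    n, p = X.shape
    P = lam * S
    if beta0 is not None and np.all(np.isfinite(beta0)):
        beta = beta0.copy()
    else:
        mu0 = np.clip(y, 0.5, None)
        eta0 = np.log(mu0)
        beta, *_ = np.linalg.lstsq(X, eta0, rcond=None)
    eta = np.clip(X @ beta, -30.0, 30.0)
    mu = np.exp(eta)
    pll = _nb_loglik(y, mu, theta) - 0.5 * beta @ P @ beta
    for _ in range(max_iter):
        w = mu / (1.0 + mu / theta)
        z = eta + (y - mu) / mu
        XtW = X.T * w
        A = XtW @ X + P
        b = XtW @ z
        try:
            beta_new = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            beta_new = np.linalg.solve(A + 1e-9 * np.eye(p), b)
        # step halving on the penalized log-likelihood
        step = 1.0
        accepted = False
        for _ in range(30):
            cand = beta + step * (beta_new - beta)
            eta_c = np.clip(X @ cand, -30.0, 30.0)
            mu_c = np.exp(eta_c)
            pll_c = _nb_loglik(y, mu_c, theta) - 0.5 * cand @ P @ cand
            if np.isfinite(pll_c) and pll_c >= pll - 1e-10 * (abs(pll) + 1.0):
                accepted = True
                break
            step *= 0.5
        if not accepted:
            # no uphill step: converged if the proposal barely moves, else fail
            if np.max(np.abs(beta_new - beta)) < 1e-6 * (1.0 + np.max(np.abs(beta))):
                break
            raise NonConvergenceError("step halving failed in penalized IRLS")
        delta = abs(pll_c - pll)
        beta, eta, mu, pll = cand, eta_c, mu_c, pll_c
        if delta < tol * (abs(pll) + 1.0):
            break
    else:
        raise NonConvergenceError("penalized IRLS did not converge")
    w = mu / (1.0 + mu / theta)
    return {
        "beta": beta, "eta": eta, "mu": mu, "w": w,
        "loglik": _nb_loglik(y, mu, theta), "penalized_loglik": pll,
    }


def _reml_score(fit: dict, X: np.ndarray, S: np.ndarray, lam: float,
                log_det_S_pos: float, rank_S: int) -> float:
    """Negative Laplace-approximate restricted marginal likelihood."""
    XtWX = (X.T * fit["w"]) @ X
    sign, logdet_A = np.linalg.slogdet(XtWX + lam * S)
    if sign <= 0:
        return np.inf
    logdet_P = rank_S * np.log(lam) + log_det_S_pos
    return -fit["penalized_loglik"] + 0.5 * logdet_A - 0.5 * logdet_P


def _fit_fixed_theta(
    X: np.ndarray,
    y: np.ndarray,
    S: np.ndarray | None,
    theta: float,
    state: dict,
) -> dict:
    """GLM (S is None) or REML-smoothed penalized fit at fixed theta."""
    p = X.shape[1]
    if S is None:
        fit = _pirls(X, y, np.zeros((p, p)), 0.0, theta, beta0=state.get("beta"))
        lam = 0.0
        XtWX = (X.T * fit["w"]) @ X
        cov = np.linalg.inv(XtWX)
        edf = float(p)
    else:
        eig = np.linalg.eigvalsh(S)
        rank_S = int((eig > eig.max() * 1e-10).sum())
        log_det_S_pos = float(np.log(eig[eig > eig.max() * 1e-10]).sum())

        def score(log_lam: float) -> float:
            f = _pirls(X, y, S, np.exp(log_lam), theta, beta0=state.get("beta"))
            state["beta"] = f["beta"]
            return _reml_score(f, X, S, np.exp(log_lam), log_det_S_pos, rank_S)

        res = optimize.minimize_scalar(
            score, bounds=_LOG_LAMBDA_BOUNDS, method="bounded",
            options={"xatol": 0.1},
        )
        lam = float(np.exp(res.x))
        fit = _pirls(X, y, S, lam, theta, beta0=state.get("beta"))
        state["beta"] = fit["beta"]
        XtWX = (X.T * fit["w"]) @ X
        A_inv = np.linalg.inv(XtWX + lam * S)
        cov = A_inv
        F = A_inv @ XtWX
        edf = float(np.trace(F))
        # test df tr(2F - FF) >= edf corrects for smoothing-parameter
        # estimation; without it the omnibus LRT is anti-conservative
        edf_test = float(2.0 * edf - np.trace(F @ F))
        reml = _reml_score(fit, X, S, lam, log_det_S_pos, rank_S)
        return {**fit, "lam": lam, "cov": cov, "edf": edf,
                "edf_test": edf_test, "reml": reml}
    return {**fit, "lam": lam, "cov": cov, "edf": edf, "edf_test": edf,
            "reml": -fit["loglik"]}


def _profile_theta(X: np.ndarray, y: np.ndarray, S: np.ndarray | None) -> dict:
    """Outer profiling of the NB dispersion theta.

    For the unpenalized GLM the profile objective is the log-likelihood; for
    the penalized smooth it is the restricted marginal likelihood, so theta
    and the smoothing parameter are chosen by the same criterion and excess
    dispersion cannot be traded for spurious wiggliness.
    """
    state: dict = {}
    cache: dict[float, dict] = {}

    def objective(log_theta: float) -> float:
        fit = _fit_fixed_theta(X, y, S, np.exp(log_theta), state)
        cache[log_theta] = fit
        return fit["reml"]

    res = optimize.minimize_scalar(
        objective, bounds=_LOG_THETA_BOUNDS, method="bounded",
        options={"xatol": 0.05},
    )
    fit = cache.get(res.x) or _fit_fixed_theta(X, y, S, np.exp(res.x), state)
    fit["theta"] = float(np.exp(res.x))
    return fit


def _fit_null(y: np.ndarray) -> dict:
    """Intercept-only NB fit: mu-hat = mean(y) for any theta; profile theta."""
    mu = float(np.mean(y))

    def neg_loglik(log_theta: float) -> float:
        return -_nb_loglik(y, np.full_like(y, mu), np.exp(log_theta))

    res = optimize.minimize_scalar(
        neg_loglik, bounds=_LOG_THETA_BOUNDS, method="bounded",
        options={"xatol": 0.05},
    )
    return {"mu": mu, "theta": float(np.exp(res.x)), "loglik": -res.fun}


# ---------------------------------------------------------------------------
# public fitting API


def fit_nb_glm(series: CountSeries) -> FittedTrend:
    """Log-linear NB trend fit for short series (slope = per-year log change)."""
    y = series.counts
    _check_fittable(series, MIN_OBS_GLM)
    t = series.years - series.years[0]
    X = np.column_stack([np.ones_like(t), t])
    fit = _profile_theta(X, y, None)
    null = _fit_null(y)
    stat = max(0.0, 2.0 * (fit["loglik"] - null["loglik"]))
    # F(1, n-2) reference: the asymptotic chi2(1) is anti-conservative at
    # the 6-9 observations these series have
    p = float(f_dist.sf(stat, 1, series.n_obs - 2))
    return FittedTrend(
        site_id=series.site_id,
        model_kind="GLM",
        n_obs=series.n_obs,
        first_year=int(series.years[0]),
        last_year=int(series.years[-1]),
        coefficients=fit["beta"],
        coef_covariance=fit["cov"],
        basis_descriptor={"kind": "linear"},
        theta_hat=fit["theta"],
        omnibus_p=p,
        omnibus_stat=stat,
        loglik=fit["loglik"],
        edf=2.0,
        final_counts=_final_counts(series),
    )


def fit_nb_gam(
    series: CountSeries,
    max_basis_dim: int = 10,
    _lambda_override: float | None = None,
) -> FittedTrend:
    """Penalized cubic B-spline NB trend fit for series with >= 10 years.

    Basis dimension is ``min(max_basis_dim, n_obs - 2)``; the penalty is the
    integrated squared second derivative, whose null space (linear trends)
    is unpenalized, so the smooth may legitimately shrink to a straight
    line. ``_lambda_override`` fixes the smoothing parameter (used to check
    the infinite-penalty linear limit); the default selects it by REML.
    """
    y = series.counts
    _check_fittable(series, MIN_OBS_GAM)
    t = series.years - series.years[0]
    k = min(max_basis_dim, series.n_obs - 2)
    knots = _crs_knots(t, k)
    X = BSpline.design_matrix(t, knots, 3).toarray()
    S = _second_derivative_penalty(knots, k)
    if _lambda_override is not None:
        Xlin = np.column_stack([np.ones_like(t), t])
        theta0 = _profile_theta(Xlin, y, None)["theta"]
        fit = _pirls(X, y, S, _lambda_override, theta0)
        XtWX = (X.T * fit["w"]) @ X
        A_inv = np.linalg.inv(XtWX + _lambda_override * S)
        fit.update(cov=A_inv, edf=float(np.trace(A_inv @ XtWX)),
                   theta=theta0, lam=_lambda_override)
    else:
        fit = _profile_theta(X, y, S)
    null = _fit_null(y)
    # the penalized log-likelihood charges the smooth for its wiggliness;
    # with the tr(2F - FF) df this keeps the test near-nominal under
    # constant trends while the unpenalized version is anti-conservative
    stat = max(0.0, 2.0 * (fit["penalized_loglik"] - null["loglik"]))
    df = max(fit.get("edf_test", fit["edf"]) - 1.0, 1e-8)
    p = float(chi2.sf(stat, df))
    return FittedTrend(
        site_id=series.site_id,
        model_kind="GAM",
        n_obs=series.n_obs,
        first_year=int(series.years[0]),
        last_year=int(series.years[-1]),
        coefficients=fit["beta"],
        coef_covariance=fit["cov"],
        basis_descriptor={"kind": "bspline", "knots": knots, "degree": 3},
        theta_hat=fit["theta"],
        omnibus_p=p,
        omnibus_stat=stat,
        loglik=fit["loglik"],
        edf=fit["edf"],
        final_counts=_final_counts(series),
    )


def _check_fittable(series: CountSeries, floor: int) -> None:
    if series.n_obs < floor:
        raise ValueError(
            f"site {series.site_id}: {series.n_obs} observations, need >= {floor}"
        )
    if np.all(series.counts == 0):
        raise DegenerateSeriesError(
            f"site {series.site_id}: all counts zero (population fully disappeared)"
        )


def _final_counts(series: CountSeries) -> tuple[int, int]:
    c = series.counts.astype(int)
    return (int(c[-2]), int(c[-1])) if len(c) >= 2 else (int(c[-1]), int(c[-1]))


def _crs_knots(t: np.ndarray, k: int) -> np.ndarray:
    """Clamped cubic B-spline knot vector with interior knots at quantiles."""
    a, b = float(t.min()), float(t.max())
    n_interior = k - 4
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(np.unique(t), qs)
        # guard against coincident knots on very gappy series
        if np.any(np.diff(np.concatenate([[a], interior, [b]])) <= 0):
            interior = np.linspace(a, b, n_interior + 2)[1:-1]
    else:
        interior = np.array([])
    return np.concatenate([[a] * 4, interior, [b] * 4])


def _second_derivative_penalty(knots: np.ndarray, k: int) -> np.ndarray:
    """Gram matrix of second derivatives: S_ij = int B_i'' B_j'' dt.

    Exact via 3-point Gauss-Legendre per inter-knot span (the integrand is
    piecewise quadratic for cubic splines).
    """
    spline = BSpline(knots, np.eye(k), 3)
    d2 = spline.derivative(2)
    nodes_ref, weights_ref = np.polynomial.legendre.leggauss(3)
    S = np.zeros((k, k))
    breaks = np.unique(knots)
    for lo, hi in zip(breaks[:-1], breaks[1:]):
        half = 0.5 * (hi - lo)
        nodes = lo + half * (nodes_ref + 1.0)
        D = d2(nodes)  # (3, k)
        S += (D.T * (weights_ref * half)) @ D
    return S


# ---------------------------------------------------------------------------
# residual diagnostics


def deviance_residuals(fit: FittedTrend, series: CountSeries) -> np.ndarray:
    """NB deviance residuals at the observed years."""
    y = series.counts
    mu = np.exp(fit.predict_linear(series.years))
    th = fit.theta_hat
    term1 = np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0) / mu), 0.0)
    dev = 2.0 * (term1 - (y + th) * np.log((y + th) / (mu + th)))
    dev = np.clip(dev, 0.0, None)
    return np.sign(y - mu) * np.sqrt(dev)


def residual_autocorrelation(
    fit: FittedTrend, series: CountSeries, max_lag: int
) -> tuple[pd.DataFrame, float]:
    """ACF/PACF of deviance residuals, indexed by calendar year.

    Gaps are respected by placing residuals on the full year grid with
    missing entries; lagged products are formed only over observed pairs.
    Returns a frame with columns (lag, acf, pacf) for lags 0..max_lag and
    the +-1.96/sqrt(n) white-noise reference band.
    """
    if max_lag >= series.n_obs:
        raise ValueError("max_lag must be smaller than the number of observations")
    res = deviance_residuals(fit, series)
    years = series.years.astype(int)
    grid = np.full(years[-1] - years[0] + 1, np.nan)
    grid[years - years[0]] = res
    obs = ~np.isnan(grid)
    xbar = np.nanmean(grid)
    denom = np.nansum((grid - xbar) ** 2)
    acf = np.empty(max_lag + 1)
    acf[0] = 1.0
    for h in range(1, max_lag + 1):
        a, b = grid[:-h], grid[h:]
        ok = ~np.isnan(a) & ~np.isnan(b)
        acf[h] = np.sum((a[ok] - xbar) * (b[ok] - xbar)) / denom if denom > 0 else 0.0
    pacf = _pacf_from_acf(acf)
    band = 1.96 / np.sqrt(series.n_obs)
    frame = pd.DataFrame({"lag": np.arange(max_lag + 1), "acf": acf, "pacf": pacf})
    return frame, float(band)


def _pacf_from_acf(acf: np.ndarray) -> np.ndarray:
    """Durbin-Levinson recursion; pacf[0] defined as 1."""
    m = len(acf) - 1
    pacf = np.empty(m + 1)
    pacf[0] = 1.0
    phi = np.zeros((m + 1, m + 1))
    for h in range(1, m + 1):
        if h == 1:
            phi[1, 1] = acf[1]
        else:
            num = acf[h] - np.sum(phi[h - 1, 1:h] * acf[h - 1 : 0 : -1])
            den = 1.0 - np.sum(phi[h - 1, 1:h] * acf[1:h])
            phi[h, h] = num / den if abs(den) > 1e-12 else 0.0
            for j in range(1, h):
                phi[h, j] = phi[h - 1, j] - phi[h, h] * phi[h - 1, h - j]
        pacf[h] = phi[h, h]
    return pacf


# ---------------------------------------------------------------------------
# I/O helpers


def read_counts_csv(
    counts_path: str, sites_path: str | None = None
) -> list[CountSeries]:
    """Read long-format (site_id, year, count) CSV into CountSeries objects."""
    df = pd.read_csv(counts_path)
    coords = {}
    if sites_path is not None:
        sdf = pd.read_csv(sites_path)
        coords = {
            str(r.site_id): (float(r.x_m), float(r.y_m))
            for r in sdf.itertuples(index=False)
        }
    out = []
    for sid, grp in df.groupby("site_id", sort=True):
        grp = grp.sort_values("year")
        x, y = coords.get(str(sid), (0.0, 0.0))
        out.append(
            CountSeries(
                site_id=str(sid),
                records=list(zip(grp.year.astype(int), grp["count"].astype(int))),
                x_m=x,
                y_m=y,
            )
        )
    return out


def fits_to_frame(fits: Sequence[FittedTrend]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "site_id": f.site_id,
                "model_kind": f.model_kind,
                "n_obs": f.n_obs,
                "first_year": f.first_year,
                "last_year": f.last_year,
                "theta_hat": f.theta_hat,
                "edf": f.edf,
                "omnibus_stat": f.omnibus_stat,
                "omnibus_p": f.omnibus_p,
                "loglik": f.loglik,
            }
            for f in fits
        ]
    )
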