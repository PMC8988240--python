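"""Penalized linear regression for index abbreviation.

The abbreviation step regresses the composite empowerment score (or the
binary empowerment status, treated as a linear probability) on the full set
of binary indicators under an L1 penalty

    min_b  (1/2n) ||y - a - X b||^2  +  lam * sum_j phi_j |b_j|

with an unpenalized intercept ``a`` and per-predictor penalty loadings
``phi_j``.  Predictors are centered and (by default) scaled to unit
variance before fitting; coefficients are reported on the original scale.
With unit loadings every slope is zero once
``lam >= max_j |X~_j' y~| / n`` (the null threshold), and the KKT
conditions at a solution read ``|X~_j' r| / n <= lam * phi_j`` with
equality on the active set.

Three penalty-selection approaches are provided:

* ``cv``        — k-fold cross-validation, lam at the minimum mean
                  held-out MSE (no one-standard-error rule);
* ``aic``/``aicc``/``bic``/``ebic``
                — information criteria evaluated along the penalty path
                  with degrees of freedom equal to the active-set size;
* ``rigorous``  — a closed-form plug-in penalty
                  ``lam_native = 2 c sigma sqrt(n) PhiInv(1 - gamma/(2p))``
                  with data-dependent heteroskedasticity loadings
                  ``phi_j = sqrt(mean(x~_j^2 e^2)) / sigma`` and ``sigma``
                  iterated from residuals.  ``lam_native`` lives on the
                  ``(1/n)||r||^2 + (lam/n) sum phi|b|`` scale and is
                  converted internally (``lam = lam_native / (2n)``).

:func:`exact_k_select` searches the penalty path (with log-scale bisection
between grid points, and a deterministic drop-smallest-coefficient fallback
for unreachable support sizes) for an active set of exactly k predictors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LassoConfig",
    "LassoFit",
    "LassoError",
    "LassoConvergenceError",
    "fit_lasso",
    "lambda_grid",
    "lasso_path",
    "select_lambda",
    "exact_k_select",
    "APPROACHES",
]

log = logging.getLogger(__name__)

APPROACHES = ("cv", "aic", "aicc", "bic", "ebic", "rigorous")
_IC_NAMES = ("aic", "aicc", "bic", "ebic")


class LassoError(RuntimeError):
    pass


class LassoConvergenceError(LassoError):
    """Coordinate descent exhausted max_iter sweeps."""

    def __init__(self, message, objective=None, n_iter=None):
        super().__init__(message)
        self.objective = objective
        self.n_iter = n_iter


@dataclass
class LassoConfig:
    """Tuning knobs for the penalized fit and penalty selection."""

    n_lambda: int = 100
    lambda_min_ratio: float = 1e-4
    loadings: np.ndarray | None = None  # default: unit loadings
    standardize: bool = True
    cv_folds: int = 10
    cv_seed: int = 0
    ebic_xi: float = 0.5
    rigorous_c: float = 1.1
    rigorous_gamma: float | None = None  # default 0.1 / log(max(p, n))
    tol: float = 1e-8
    max_iter: int = 10_000

    def __post_init__(self) -> None:
        if self.n_lambda < 2:
            raise ValueError("n_lambda must be >= 2")
        if not (0 < self.lambda_min_ratio < 1):
            raise ValueError("lambda_min_ratio must lie in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if not (0.0 <= self.ebic_xi <= 1.0):
            raise ValueError("ebic_xi must lie in [0, 1]")


@dataclass
class LassoFit:
    """A fitted penalized regression, coefficients on the original scale."""

    intercept: float
    coef: pd.Series
    lam: float
    active_set: tuple[str, ...]
    n_iter: int
    objective: float
    converged: bool
    loadings: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)

    def predict(self, X) -> np.ndarray:
        Xv = X.loc[:, self.coef.index].to_numpy(float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
        return self.intercept + Xv @ self.coef.to_numpy()

    def rmse(self, X, y) -> float:
        resid = np.asarray(y, float) - self.predict(X)
        return float(np.sqrt(np.mean(resid**2)))


# ---------------------------------------------------------------------------
# Internal solver (standardized scale, Gram updates)
# ---------------------------------------------------------------------------

def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(float), [str(c) for c in X.columns]
    X = np.asarray(X, float)
    if X.ndim != 2:
        raise ValueError("X must be two-dimensional")
    return X, [f"x{j}" for j in range(X.shape[1])]


class _Problem:
    """Centered/standardized data with precomputed Gram quantities.

    Coordinate updates use G = X~'X~/n and b = X~'y~/n so each sweep costs
    O(p^2) regardless of n, which makes dense penalty paths and k-fold
    cross-validation cheap at survey scale.
    """

    def __init__(self, X, y, standardize: bool = True):
        self.Xraw, self.names = _as_matrix(X)
        self.y = np.asarray(y, float).ravel()
        if self.Xraw.shape[0] != self.y.size:
            raise ValueError("rows of X must match length of y")
        if np.isnan(self.Xraw).any() or np.isnan(self.y).any():
            raise ValueError("X and y must not contain missing values")
        self.n, self.p = self.Xraw.shape
        self.mean = self.Xraw.mean(axis=0)
        sd = self.Xraw.std(axis=0)
        self.zero_var = sd == 0.0
        self.scale = np.where(sd == 0.0, 1.0, sd) if standardize else np.ones(self.p)
        self.Xs = (self.Xraw - self.mean) / self.scale
        self.ybar = float(self.y.mean())
        self.yc = self.y - self.ybar
        self.G = self.Xs.T @ self.Xs / self.n
        self.b = self.Xs.T @ self.yc / self.n
        self.yty = float(self.yc @ self.yc) / self.n
        self.diag = np.diag(self.G).copy()

    def null_lambda(self, loadings: np.ndarray) -> float:
        with np.errstate(divide="ignore"):
            vals = np.abs(self.b) / loadings
        vals = vals[~self.zero_var]
        return float(np.max(vals)) if vals.size else 0.0

    def objective(self, beta: np.ndarray, lam: float, loadings: np.ndarray) -> float:
        quad = self.yty - 2.0 * self.b @ beta + beta @ self.G @ beta
        return 0.5 * max(quad, 0.0) + lam * float(loadings @ np.abs(beta))

    def solve(
        self,
        lam: float,
        loadings: np.ndarray,
        beta0: np.ndarray | None = None,
        tol: float = 1e-8,
        max_iter: int = 10_000,
    ) -> tuple[np.ndarray, int]:
        beta = np.zeros(self.p) if beta0 is None else beta0.copy()
        G, b, diag = self.G, self.b, self.diag
        thr = lam * loadings
        grad = b - G @ beta  # X~'r/n, maintained incrementally
        for sweep in range(1, max_iter + 1):
            delta_max = 0.0
            for j in range(self.p):
                if self.zero_var[j] or diag[j] <= 0.0:
                    continue
                z = grad[j] + diag[j] * beta[j]
                bj = np.sign(z) * max(abs(z) - thr[j], 0.0) / diag[j]
                d = bj - beta[j]
                if d != 0.0:
                    beta[j] = bj
                    grad -= G[:, j] * d
                    delta_max = max(delta_max, abs(d))
            if delta_max < tol:
                return beta, sweep
        raise LassoConvergenceError(
            f"coordinate descent did not converge in {max_iter} sweeps "
            f"(last max coefficient change {delta_max:.3e})",
            objective=self.objective(beta, lam, loadings),
            n_iter=max_iter,
        )

    def make_fit(
        self, beta: np.ndarray, lam: float, loadings: np.ndarray, n_iter: int
    ) -> LassoFit:
        coef_orig = beta / self.scale
        intercept = self.ybar - float(coef_orig @ self.mean)
        active = tuple(self.names[j] for j in range(self.p) if beta[j] != 0.0)
        return LassoFit(
            intercept=intercept,
            coef=pd.Series(coef_orig, index=self.names),
            lam=lam,
            active_set=active,
            n_iter=n_iter,
            objective=self.objective(beta, lam, loadings),
            converged=True,
            loadings=loadings.copy(),
        )

    def kkt_residuals(self, beta: np.ndarray) -> np.ndarray:
        """Gradient of the smooth part, X~'r/n, per predictor."""
        return self.b - self.G @ beta


def _loadings(config: LassoConfig | None, p: int) -> np.ndarray:
    if config is not None and config.loadings is not None:
        phi = np.asarray(config.loadings, float)
        if phi.shape != (p,):
            raise ValueError(f"loadings must have shape ({p},)")
        if np.any(phi <= 0):
            raise ValueError("loadings must be strictly positive")
        return phi
    return np.ones(p)


# ---------------------------------------------------------------------------
# Public single-fit / path API
# ---------------------------------------------------------------------------

def fit_lasso(
    X,
    y,
    lam: float,
    loadings: Sequence[float] | None = None,
    *,
    standardize: bool = True,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> LassoFit:
    """Solve the penalized least-squares problem at a single penalty level."""
    if lam < 0:
        raise ValueError("lam must be non-negative")
    prob = _Problem(X, y, standardize=standardize)
    phi = np.ones(prob.p) if loadings is None else np.asarray(loadings, float)
    if np.any(phi <= 0):
        raise ValueError("loadings must be strictly positive")
    beta, n_iter = prob.solve(lam, phi, tol=tol, max_iter=max_iter)
    fit = prob.make_fit(beta, lam, phi, n_iter)
    fit.diagnostics["kkt"] = prob.kkt_residuals(beta)
    return fit


def lambda_grid(X, y, config: LassoConfig | None = None) -> np.ndarray:
    """Log-spaced decreasing penalty grid from the null threshold down."""
    config = config or LassoConfig()
    prob = _Problem(X, y, standardize=config.standardize)
    phi = _loadings(config, prob.p)
    lam_null = prob.null_lambda(phi)
    if lam_null <= 0:
        raise LassoError("null penalty is zero: y is uncorrelated with every predictor")
    return np.geomspace(lam_null, lam_null * config.lambda_min_ratio, config.n_lambda)


def lasso_path(X, y, lambdas=None, config: LassoConfig | None = None):
    """Fit along a decreasing penalty grid with warm starts.

    Returns ``(lambdas, fits)``.
    """
    config = config or LassoConfig()
    prob = _Problem(X, y, standardize=config.standardize)
    phi = _loadings(config, prob.p)
    if lambdas is None:
        lam_null = prob.null_lambda(phi)
        if lam_null <= 0:
            raise LassoError("null penalty is zero")
        lambdas = np.geomspace(
            lam_null, lam_null * config.lambda_min_ratio, config.n_lambda
        )
    lambdas = np.asarray(lambdas, float)
    if lambdas.size and np.any(np.diff(lambdas) >= 0):
        raise ValueError("lambda grid must be strictly decreasing")
    fits, beta = [], None
    for lam in lambdas:
        beta, n_iter = prob.solve(
            lam, phi, beta0=beta, tol=config.tol, max_iter=config.max_iter
        )
        fits.append(prob.make_fit(beta, lam, phi, n_iter))
        beta = fits[-1].coef.to_numpy() * prob.scale  # warm start copy
    return lambdas, fits


# ---------------------------------------------------------------------------
# Penalty selection
# ---------------------------------------------------------------------------

def _ic_value(name: str, n: int, p: int, rss: float, df: int, xi: float) -> float:
    rss = max(rss, 1e-300)
    aic = n * np.log(rss / n) + 2.0 * df
    if name == "aic":
        return aic
    if name == "aicc":
        return aic + (2.0 * df * (df + 1) / (n - df - 1) if n - df - 1 > 0 else np.inf)
    bic = n * np.log(rss / n) + df * np.log(n)
    if name == "bic":
        return bic
    if name == "ebic":
        return bic + 2.0 * xi * df * np.log(p)
    raise ValueError(f"unknown information criterion {name!r}")


def _select_cv(X, y, config: LassoConfig):
    Xm, names = _as_matrix(X)
    y = np.asarray(y, float).ravel()
    n = y.size
    grid = lambda_grid(X, y, config)
    rng = np.random.default_rng(config.cv_seed)
    fold = np.empty(n, dtype=int)
    fold[rng.permutation(n)] = np.arange(n) % config.cv_folds

    mse = np.zeros((config.cv_folds, grid.size))
    used = np.zeros(config.cv_folds, dtype=bool)
    for f in range(config.cv_folds):
        train, test = fold != f, fold == f
        if np.std(y[train]) == 0.0 or not test.any():
            log.warning("cv fold %d skipped: degenerate training response", f)
            continue
        used[f] = True
        _, fits = lasso_path(Xm[train], y[train], lambdas=grid, config=config)
        for i, fit in enumerate(fits):
            resid = y[test] - fit.predict(Xm[test])
            mse[f, i] = float(np.mean(resid**2))
    if not used.any():
        raise LassoError("all cross-validation folds were degenerate")
    curve = mse[used].mean(axis=0)
    best = int(np.argmin(curve))
    lam = float(grid[best])
    fit = fit_lasso(
        pd.DataFrame(Xm, columns=names), y, lam,
        loadings=_loadings(config, Xm.shape[1]),
        standardize=config.standardize, tol=config.tol, max_iter=config.max_iter,
    )
    fit.diagnostics.update(cv_lambdas=grid, cv_curve=curve, cv_folds_used=int(used.sum()))
    return lam, fit


def _refit_rss(prob: _Problem, active_idx: np.ndarray) -> float:
    """RSS of the unpenalized least-squares refit on an active set."""
    if active_idx.size == 0:
        return prob.yty * prob.n
    G = prob.G[np.ix_(active_idx, active_idx)]
    b = prob.b[active_idx]
    try:
        beta = np.linalg.solve(G, b)
    except np.linalg.LinAlgError:
        beta = np.linalg.lstsq(G, b, rcond=None)[0]
    return max(prob.yty - float(b @ beta), 0.0) * prob.n


def _select_ic(X, y, criterion: str, config: LassoConfig):
    # criteria are evaluated on the least-squares refit of each active set
    # (df = active-set size); the penalized fit itself is what is returned
    y = np.asarray(y, float).ravel()
    n = y.size
    grid, fits = lasso_path(X, y, config=config)
    Xm, names = _as_matrix(X)
    p = Xm.shape[1]
    prob = _Problem(X, y, standardize=config.standardize)
    col = {name: j for j, name in enumerate(names)}
    values = np.empty(grid.size)
    for i, fit in enumerate(fits):
        idx = np.array([col[a] for a in fit.active_set], dtype=int)
        rss = _refit_rss(prob, idx)
        values[i] = _ic_value(criterion, n, p, rss, len(fit.active_set), config.ebic_xi)
    best = int(np.argmin(values))
    fit = fits[best]
    fit.diagnostics.update(ic=criterion, ic_lambdas=grid, ic_path=values)
    return float(grid[best]), fit


def rigorous_lambda(n: int, p: int, sigma: float, c: float, gamma: float) -> float:
    """Plug-in penalty on the native (1/n)RSS + (lam/n)sum scale."""
    return 2.0 * c * sigma * np.sqrt(n) * stats.norm.ppf(1.0 - gamma / (2.0 * p))


def _select_rigorous(X, y, config: LassoConfig, max_rounds: int = 15):
    prob = _Problem(X, y, standardize=config.standardize)
    n, p = prob.n, prob.p
    gamma = config.rigorous_gamma
    if gamma is None:
        gamma = 0.1 / np.log(max(p, n))
    c = config.rigorous_c

    resid = prob.yc.copy()
    sigma = float(np.sqrt(np.mean(resid**2)))
    sigma = max(sigma, 1e-12)
    beta = None
    lam = phi = None
    for round_ in range(1, max_rounds + 1):
        lam_native = rigorous_lambda(n, p, sigma, c, gamma)
        lam = lam_native / (2.0 * n)  # convert to the (1/2n)RSS + lam*sum scale
        phi = np.sqrt(np.mean(prob.Xs**2 * resid[:, None] ** 2, axis=0)) / sigma
        phi = np.maximum(phi, 1e-8)
        beta, _ = prob.solve(lam, phi, beta0=beta, tol=config.tol, max_iter=config.max_iter)
        resid = prob.yc - prob.Xs @ beta
        df = int(np.count_nonzero(beta))
        denom = max(n - df - 1, 1)
        sigma_new = float(np.sqrt(np.sum(resid**2) / denom))
        sigma_new = max(sigma_new, 1e-12)
        if abs(sigma_new - sigma) <= 1e-4 * sigma:
            break  # sigma stays the value that produced lam
        sigma = sigma_new
    fit = prob.make_fit(beta, lam, phi, n_iter=round_)
    fit.diagnostics.update(
        sigma_hat=sigma, sigma_final=sigma_new, gamma=gamma, c=c, rounds=round_,
        lambda_native=rigorous_lambda(n, p, sigma, c, gamma),
    )
    return float(lam), fit


def select_lambda(X, y, approach: str, config: LassoConfig | None = None):
    """Choose the penalty level by one of the named approaches.

    Returns ``(lam, fit)``; ``fit.diagnostics`` carries the CV curve, the
    information-criterion path, or the plug-in quantities.
    """
    config = config or LassoConfig()
    if approach == "cv":
        return _select_cv(X, y, config)
    if approach in _IC_NAMES:
        return _select_ic(X, y, approach, config)
    if approach == "rigorous":
        return _select_rigorous(X, y, config)
    raise ValueError(f"unknown approach {approach!r}; expected one of {APPROACHES}")


# ---------------------------------------------------------------------------
# Exact-k selection along the path
# ---------------------------------------------------------------------------

def _restrict_fit(prob: _Problem, fit: LassoFit, keep: set[str]) -> LassoFit:
    """Zero out coefficients outside ``keep`` and refresh the intercept."""
    coef = fit.coef.copy()
    coef[~coef.index.isin(keep)] = 0.0
    intercept = prob.ybar - float(coef.to_numpy() @ prob.mean)
    return LassoFit(
        intercept=intercept,
        coef=coef,
        lam=fit.lam,
        active_set=tuple(n for n in fit.coef.index if n in keep and fit.coef[n] != 0.0),
        n_iter=fit.n_iter,
        objective=fit.objective,
        converged=fit.converged,
        loadings=fit.loadings,
        diagnostics=dict(fit.diagnostics, fallback=True),
    )


def exact_k_select(X, y, k: int, approach: str = "cv", config: LassoConfig | None = None):
    """Find an active set of exactly ``k`` predictors along the penalty path.

    The penalty level is swept over the log grid (warm-started); if no grid
    point yields support ``k`` the bracketing interval is bisected on the
    log scale (up to 60 steps); if the support size jumps past ``k`` even
    then, the smallest support larger than ``k`` is pruned by dropping the
    predictors with the smallest standardized \\|coefficient\\| (ties broken
    in favour of earlier column order), and the fallback is logged.

    For the ``rigorous`` approach the plug-in loadings are computed first
    and held fixed while the penalty level is searched; the other
    approaches share the unit-loadings path.

    Returns ``(names, fit)`` with ``names`` ordered as in the columns of X.
    """
    config = config or LassoConfig()
    prob = _Problem(X, y, standardize=config.standardize)
    p = prob.p
    if not (0 <= k <= p):
        raise ValueError(f"k={k} outside [0, {p}]")

    if approach == "rigorous":
        _, rfit = _select_rigorous(X, y, config)
        phi = np.asarray(rfit.loadings, float)
    else:
        if approach not in APPROACHES:
            raise ValueError(f"unknown approach {approach!r}")
        phi = _loadings(config, p)

    lam_null = prob.null_lambda(phi)
    if lam_null <= 0:
        raise LassoError("null penalty is zero: response carries no signal")

    def solve_at(lam, beta0=None):
        beta, n_iter = prob.solve(lam, phi, beta0=beta0, tol=config.tol,
                                  max_iter=config.max_iter)
        return beta, n_iter

    def finish(beta, lam, n_iter):
        fit = prob.make_fit(beta, lam, phi, n_iter)
        names = tuple(n for n in prob.names if n in set(fit.active_set))
        return names, fit

    if k == 0:
        beta, n_iter = solve_at(lam_null * (1.0 + 1e-10))
        return (), prob.make_fit(beta, lam_null, phi, n_iter)
    if k == p:
        # exact least-squares solve; coordinate descent would only reach tol
        try:
            beta = np.linalg.solve(prob.G, prob.b)
        except np.linalg.LinAlgError:
            beta = np.linalg.lstsq(prob.G, prob.b, rcond=None)[0]
        fit = prob.make_fit(beta, 0.0, phi, n_iter=1)
        return tuple(prob.names), fit

    grid = np.geomspace(lam_null, lam_null * config.lambda_min_ratio, config.n_lambda)
    beta = None
    supports: list[int] = []
    betas: list[np.ndarray] = []
    for lam in grid:
        beta, n_iter = solve_at(lam, beta)
        supports.append(int(np.count_nonzero(beta)))
        betas.append(beta.copy())
        if supports[-1] == k:
            return finish(beta, lam, n_iter)

    # bracket the first crossing of k along the decreasing grid
    hi_idx = None
    for i in range(1, len(grid)):
        if supports[i - 1] < k < supports[i]:
            hi_idx = i - 1
            break
    if hi_idx is not None:
        lam_hi, lam_lo = grid[hi_idx], grid[hi_idx + 1]
        beta_warm = betas[hi_idx]
        best_over = None  # (support, lam, beta)
        for _ in range(60):
            lam_mid = float(np.sqrt(lam_hi * lam_lo))
            beta_mid, n_iter = solve_at(lam_mid, beta_warm)
            s = int(np.count_nonzero(beta_mid))
            if s == k:
                return finish(beta_mid, lam_mid, n_iter)
            if s < k:
                lam_hi, beta_warm = lam_mid, beta_mid
            else:
                lam_lo = lam_mid
                if best_over is None or s < best_over[0]:
                    best_over = (s, lam_mid, beta_mid)
    else:
        best_over = None

    # deterministic fallback: prune the smallest support exceeding k
    over = [(s, i) for i, s in enumerate(supports) if s > k]
    candidates = []
    if over:
        s_min = min(s for s, _ in over)
        i_best = min(i for s, i in over if s == s_min)  # largest lam first
        candidates.append((s_min, grid[i_best], betas[i_best]))
    if best_over is not None:
        candidates.append(best_over)
    if not candidates:
        sizes = sorted(set(supports))
        raise LassoError(
            f"support size {k} unreachable along the path; achievable sizes: {sizes}"
        )
    s_use, lam_use, beta_use = min(candidates, key=lambda t: t[0])
    log.warning(
        "exact-k fallback: support %d unreachable, pruning %d predictor(s) "
        "from a %d-predictor fit", k, s_use - k, s_use,
    )
    fit = prob.make_fit(beta_use, float(lam_use), phi, config.max_iter)
    order = {name: j for j, name in enumerate(prob.names)}
    active = [(abs(beta_use[order[n]]), order[n], n) for n in fit.active_set]
    # keep the k largest standardized coefficients; ties keep earlier columns
    active.sort(key=lambda t: (-t[0], t[1]))
    keep = {n for _, _, n in active[:k]}
    fit = _restrict_fit(prob, fit, keep)
    names = tuple(n for n in prob.names if n in keep)
    return names, fit
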