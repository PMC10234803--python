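"""Maximum-likelihood logistic regression via iteratively reweighted least
squares, written from first principles so the mixture machinery has no
model-fitting dependency.

The fit accepts fractional outcomes in [0, 1] (Bernoulli quasi-likelihood),
which the g-computation marginal structural model relies on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

MAX_ITER = 100
SCORE_TOL = 1e-8
LL_REL_TOL = 1e-10


class FitError(RuntimeError):
    pass


class SeparationError(FitError):
    """Quasi-complete separation: fitted probabilities pinned at 0/1."""


@dataclass
class LogisticFit:
    """Converged IRLS fit: coefficients, covariance, and diagnostics."""

    params: pd.Series            # coefficient estimates, named
    cov: pd.DataFrame            # inverse observed information
    loglik: float
    converged: bool
    n_iter: int
    n_obs: int

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov.values)), index=self.params.index)

    def predict(self, design: pd.DataFrame) -> np.ndarray:
        x = design[self.params.index].to_numpy(float)
        return expit(x @ self.params.to_numpy(float))


def _bernoulli_loglik(y: np.ndarray, p: np.ndarray) -> float:
    eps = 1e-300
    return float(np.sum(y * np.log(p + eps) + (1.0 - y) * np.log(1.0 - p + eps)))


def fit_logistic_mle(
    design: pd.DataFrame,
    y: np.ndarray | pd.Series,
    weights: np.ndarray | None = None,
) -> LogisticFit:
    """Fit logit(E[y]) = X b by Newton / IRLS.

    ``design`` must already contain an intercept column if one is wanted
    (see :func:`build_design`).  ``y`` may be fractional (quasi-likelihood).
    Convergence: max |score| < 1e-8 or relative log-likelihood change
    < 1e-10, within 100 iterations; covariance is the inverse observed
    information.  Raises :class:`SeparationError` when fitted probabilities
    pin at 0/1 with diverging coefficients, naming the offending columns.
    """
    x = design.to_numpy(float)
    yv = np.asarray(y, dtype=float)
    if x.ndim != 2 or len(yv) != x.shape[0]:
        raise FitError("design / outcome shape mismatch")
    if np.isnan(x).any() or np.isnan(yv).any():
        raise FitError("missing values in design or outcome")
    n, p = x.shape
    if n <= p:
        raise FitError(f"n={n} not greater than number of parameters {p}")
    if yv.min() < 0 or yv.max() > 1:
        raise FitError("outcomes must lie in [0, 1]")
    if np.ptp(yv) == 0:
        raise FitError("outcome has no variation; model is degenerate")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)

    beta = np.zeros(p)
    ll = -np.inf
    converged = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        eta = x @ beta
        mu = expit(eta)
        score = x.T @ (w * (yv - mu))
        wvar = w * mu * (1.0 - mu)
        info = (x * wvar[:, None]).T @ x
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            _raise_separation_or(design, beta, mu, exc)
        new_ll = _bernoulli_loglik(yv, expit(x @ (beta + step)))
        # step-halving keeps Newton monotone on hard designs
        halvings = 0
        while not np.isfinite(new_ll) or (new_ll < ll and halvings < 30):
            step *= 0.5
            halvings += 1
            new_ll = _bernoulli_loglik(yv, expit(x @ (beta + step)))
        beta = beta + step
        if np.max(np.abs(score)) < SCORE_TOL:
            ll = new_ll
            converged = True
            break
        if np.isfinite(ll) and abs(new_ll - ll) <= LL_REL_TOL * (abs(ll) + 1e-12):
            ll = new_ll
            converged = True
            break
        ll = new_ll

    mu = expit(x @ beta)
    pinned = (mu < 1e-10) | (mu > 1 - 1e-10)
    if pinned.any() and np.max(np.abs(beta)) > 15:
        # fitted probabilities pinned at 0/1 alongside diverging
        # coefficients: quasi-complete separation
        _raise_separation_or(design, beta, mu, None)
    if not converged:
        raise FitError(f"IRLS did not converge in {MAX_ITER} iterations")
    wvar = w * mu * (1.0 - mu)
    info = (x * wvar[:, None]).T @ x
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise FitError("information matrix singular at the optimum") from exc
    names = list(design.columns)
    return LogisticFit(
        params=pd.Series(beta, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        loglik=_bernoulli_loglik(yv, mu),
        converged=converged,
        n_iter=it,
        n_obs=n,
    )


def _raise_separation_or(design, beta, mu, exc=None):
    big = [c for c, b in zip(design.columns, beta) if abs(b) > 15]
    raise SeparationError(
        "separation or singular design detected"
        + (f"; diverging columns: {big}" if big else "")
    ) from exc


def fit_linear_probability(
    design: pd.DataFrame, y: np.ndarray | pd.Series
) -> LogisticFit:
    """Identity-link (linear probability) companion fit via least squares.

    Provided for collapsibility checks: with a linear outcome model the
    g-computation marginal slope equals the sum of the conditional mixture
    coefficients exactly.
    """
    x = design.to_numpy(float)
    yv = np.asarray(y, dtype=float)
    beta, *_ = np.linalg.lstsq(x, yv, rcond=None)
    resid = yv - x @ beta
    dof = max(x.shape[0] - x.shape[1], 1)
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.pinv(x.T @ x)
    names = list(design.columns)
    return LogisticFit(
        params=pd.Series(beta, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        loglik=float("nan"),
        converged=True,
        n_iter=1,
        n_obs=x.shape[0],
    )


def build_design(
    xq: pd.DataFrame, covariates: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Intercept + quantized exposures + covariates, in that order."""
    parts = [pd.Series(1.0, index=xq.index, name="intercept"), xq.astype(float)]
    if covariates is not None and covariates.shape[1]:
        parts.append(covariates.astype(float))
    out = pd.concat(parts, axis=1)
    if out.columns.duplicated().any():
        dupes = list(out.columns[out.columns.duplicated()])
        raise FitError(f"duplicate design columns: {dupes}")
    return out
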