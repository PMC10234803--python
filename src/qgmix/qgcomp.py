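"""Quantile g-computation for a binary outcome.

The estimator: code each exposure into octiles, fit a joint logistic model
in the octile codes plus covariates, and summarize the mixture through

* the conditional mixture effect  psi = sum_j beta_j  (log odds ratio per
  joint one-octile increase in every exposure),
* signed weights  w_j = beta_j / sum(same-sign betas)  (positive weights
  sum to 1, negative to -1),
* a g-computation marginal structural model: predict every subject's
  outcome probability under the counterfactual "all exposures at octile j"
  for j = 0..q-1, pool the n*q counterfactual records, and fit
  logit(E[Y^j]) = m0 + psi_marginal * j by Bernoulli quasi-likelihood with
  the predicted probabilities as fractional outcomes,
* nonparametric bootstrap (resampling subjects, re-estimating octile
  breakpoints per resample by default) for confidence intervals and
  p-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .logistic import (
    FitError,
    LogisticFit,
    build_design,
    fit_linear_probability,
    fit_logistic_mle,
)
from .quantize import QuantizedExposureMatrix, apply_breakpoints, quantize_columns


class InferenceError(RuntimeError):
    pass


def mixture_summary(
    fit: LogisticFit, mixture_columns: list[str]
) -> tuple[float, pd.Series]:
    """Conditional psi and signed weights from a fitted joint model.

    Weights are undefined (all-NaN) when every mixture coefficient is
    exactly zero.
    """
    betas = fit.params[list(mixture_columns)]
    psi = float(betas.sum())
    weights = signed_weights(betas)
    return psi, weights


def signed_weights(betas: pd.Series) -> pd.Series:
    """Per-component share of the same-sign partial effects."""
    w = pd.Series(np.nan, index=betas.index, name="weight")
    pos = betas[betas > 0]
    neg = betas[betas < 0]
    if len(pos):
        w[pos.index] = pos / pos.sum()
    if len(neg):
        w[neg.index] = -neg / (-neg).sum() * -1.0  # beta_j / |sum neg| with sign
    zero = betas[betas == 0].index
    if len(zero) and (len(pos) or len(neg)):
        w[zero] = 0.0
    return w


def gcomp_marginal_msm(
    fit: LogisticFit,
    xq: pd.DataFrame,
    covariates: pd.DataFrame | None,
    q: int,
    link: str = "logit",
) -> tuple[float, float]:
    """Marginal structural model slope via the g-formula.

    Returns (psi_marginal, msm_intercept).  ``link="identity"`` runs the
    linear-probability variant in both stages (used for collapsibility
    checks, where marginal == conditional exactly).
    """
    mixture_cols = list(xq.columns)
    n = len(xq)
    levels = np.arange(q, dtype=float)
    pooled_p = np.empty(n * q)
    for i, j in enumerate(levels):
        cf = xq.copy()
        cf.loc[:, mixture_cols] = j
        design = build_design(cf, covariates)
        if link == "identity":
            x = design[fit.params.index].to_numpy(float)
            pooled_p[i * n : (i + 1) * n] = x @ fit.params.to_numpy(float)
        else:
            pooled_p[i * n : (i + 1) * n] = fit.predict(design)
    if np.ptp(pooled_p) < 1e-14:
        # all counterfactual probabilities identical (e.g. a null mixture
        # with no covariates): the MSM slope is exactly zero
        p0 = float(np.clip(pooled_p.mean(), 1e-12, 1 - 1e-12))
        if link == "identity":
            return 0.0, p0
        return 0.0, float(np.log(p0 / (1 - p0)))
    msm_design = pd.DataFrame(
        {
            "intercept": np.ones(n * q),
            "level": np.repeat(levels, n),
        }
    )
    if link == "identity":
        msm = fit_linear_probability(msm_design, pooled_p)
    else:
        msm = fit_logistic_mle(msm_design, pooled_p)
    return float(msm.params["level"]), float(msm.params["intercept"])


@dataclass
class SensitivityResult:
    """Leave-one-out refit with one mixture component removed entirely."""

    component: str
    psi_full: float
    psi_reduced: float

    @property
    def delta_log(self) -> float:
        return self.psi_full - self.psi_reduced

    @property
    def delta_or(self) -> float:
        return math.exp(self.psi_full) - math.exp(self.psi_reduced)


@dataclass
class MixtureFit:
    """Complete quantile g-computation result."""

    psi_conditional: float
    psi_marginal: float
    fit: LogisticFit
    weights: pd.Series
    q: int
    mixture_columns: list[str]
    covariate_columns: list[str]
    b: int = 0
    seed: int | None = None
    level: float = 0.95
    draws: pd.DataFrame | None = None      # bootstrap archive, one row per resample
    n_failed: int = 0
    table: pd.DataFrame | None = None      # per-term OR/CI/p/weight summary

    def to_json_dict(self) -> dict:
        psi_rows = (
            self.table.loc[["psi_conditional", "psi_marginal"]]
            if self.table is not None
            else None
        )
        out = {
            "psi": {
                "conditional_log_odds": self.psi_conditional,
                "conditional_or": math.exp(self.psi_conditional),
                "marginal_log_odds": self.psi_marginal,
                "marginal_or": math.exp(self.psi_marginal),
            },
            "q": self.q,
            "bootstrap": {
                "B": self.b,
                "seed": self.seed,
                "ci_level": self.level,
                "failed_resamples": self.n_failed,
            },
            "mixture_columns": self.mixture_columns,
            "covariate_columns": self.covariate_columns,
        }
        if psi_rows is not None:
            out["psi"]["conditional_ci"] = [
                psi_rows.loc["psi_conditional", "ci_low"],
                psi_rows.loc["psi_conditional", "ci_high"],
            ]
            out["psi"]["conditional_p"] = psi_rows.loc["psi_conditional", "p"]
            out["psi"]["marginal_ci"] = [
                psi_rows.loc["psi_marginal", "ci_low"],
                psi_rows.loc["psi_marginal", "ci_high"],
            ]
            out["psi"]["marginal_p"] = psi_rows.loc["psi_marginal", "p"]
        return out


def _percentile_ci(draws: np.ndarray, level: float) -> tuple[float, float]:
    alpha = 1.0 - level
    lo, hi = np.quantile(draws, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def _normal_p(est: float, se: float) -> float:
    if se == 0:
        return float("nan")
    return float(2.0 * stats.norm.sf(abs(est / se)))


def fit_qgcomp(
    exposures: pd.DataFrame,
    covariates: pd.DataFrame | None,
    y: np.ndarray | pd.Series,
    q: int = 8,
    b: int = 0,
    seed: int | None = None,
    level: float = 0.95,
    requantize: bool = True,
    marginal: bool = True,
) -> MixtureFit:
    """Point estimation plus (optional) bootstrap inference.

    ``b=0`` skips the bootstrap (point estimates only).  With ``b >= 2``,
    subjects are resampled with replacement; octile breakpoints are
    re-estimated on each resample unless ``requantize=False`` (a
    diagnostic mode that reuses the original breakpoints).  Percentile
    intervals are primary; normal-approximation intervals and p-values
    from the bootstrap SE are reported alongside.  Resamples whose refit
    fails are skipped and counted; more than 1% failures aborts.
    """
    exposures = exposures.reset_index(drop=True)
    covariates = (
        covariates.reset_index(drop=True) if covariates is not None else None
    )
    yv = np.asarray(y, dtype=float)
    qx = quantize_columns(exposures, q)
    design = build_design(qx.codes, covariates)
    fit = fit_logistic_mle(design, yv)
    mixture_cols = list(exposures.columns)
    cov_cols = list(covariates.columns) if covariates is not None else []
    psi_c, weights = mixture_summary(fit, mixture_cols)
    psi_m = (
        gcomp_marginal_msm(fit, qx.codes, covariates, q)[0] if marginal else float("nan")
    )

    result = MixtureFit(
        psi_conditional=psi_c,
        psi_marginal=psi_m,
        fit=fit,
        weights=weights,
        q=q,
        mixture_columns=mixture_cols,
        covariate_columns=cov_cols,
        b=b,
        seed=seed,
        level=level,
    )
    if b == 0:
        result.table = _summary_table(result, draws=None)
        return result
    if b < 2:
        raise InferenceError("bootstrap requires B >= 2")

    rng = np.random.default_rng(seed)
    n = len(exposures)
    records = []
    n_failed = 0
    for _ in range(b):
        idx = rng.integers(0, n, n)
        ex_b = exposures.iloc[idx].reset_index(drop=True)
        cov_b = (
            covariates.iloc[idx].reset_index(drop=True)
            if covariates is not None
            else None
        )
        y_b = yv[idx]
        try:
            if requantize:
                qx_b = quantize_columns(ex_b, q)
            else:
                qx_b = apply_breakpoints(ex_b, qx)
            fit_b = fit_logistic_mle(build_design(qx_b.codes, cov_b), y_b)
            rec = dict(fit_b.params)
            rec["psi_conditional"] = float(fit_b.params[mixture_cols].sum())
            if marginal:
                rec["psi_marginal"] = gcomp_marginal_msm(
                    fit_b, qx_b.codes, cov_b, q
                )[0]
            records.append(rec)
        except FitError:
            n_failed += 1
    if n_failed > 0.01 * b:
        raise InferenceError(
            f"{n_failed}/{b} bootstrap resamples failed to fit "
            "(>1%); inference unreliable"
        )
    draws = pd.DataFrame.from_records(records)
    result.draws = draws
    result.n_failed = n_failed
    result.table = _summary_table(result, draws)
    return result


def _summary_table(result: MixtureFit, draws: pd.DataFrame | None) -> pd.DataFrame:
    """Per-term table (OR, CI, p, weight) mirroring the published layout."""
    fit = result.fit
    rows = []
    terms = (
        [("psi_conditional", result.psi_conditional),
         ("psi_marginal", result.psi_marginal)]
        + [("intercept", float(fit.params["intercept"]))]
        + [(c, float(fit.params[c])) for c in result.mixture_columns]
        + [(c, float(fit.params[c])) for c in result.covariate_columns]
    )
    for name, est in terms:
        row = {
            "term": name,
            "log_odds": est,
            "or": math.exp(est) if np.isfinite(est) else float("nan"),
        }
        if draws is not None and name in draws.columns and len(draws):
            d = draws[name].to_numpy(float)
            lo, hi = _percentile_ci(d, result.level)
            se = float(np.std(d, ddof=1))
            zq = stats.norm.ppf(0.5 + result.level / 2)
            row.update(
                ci_low=math.exp(lo),
                ci_high=math.exp(hi),
                ci_low_normal=math.exp(est - zq * se),
                ci_high_normal=math.exp(est + zq * se),
                se_boot=se,
                p=_normal_p(est, se),
            )
        elif name in fit.params.index:
            se = float(fit.bse[name])
            zq = stats.norm.ppf(0.5 + result.level / 2)
            row.update(
                ci_low=math.exp(est - zq * se),
                ci_high=math.exp(est + zq * se),
                se_boot=float("nan"),
                p=_normal_p(est, se),
            )
        w = result.weights.get(name, np.nan)
        row["weight"] = float(w) if w is not None else float("nan")
        rows.append(row)
    return pd.DataFrame(rows).set_index("term")


def leave_one_out_sensitivity(
    exposures: pd.DataFrame,
    covariates: pd.DataFrame | None,
    y: np.ndarray | pd.Series,
    component: str,
    q: int = 8,
) -> SensitivityResult:
    """Refit with ``component`` dropped from the mixture entirely."""
    if component not in exposures.columns:
        raise KeyError(
            f"{component!r} is not a mixture column "
            f"(have {list(exposures.columns)})"
        )
    full = fit_qgcomp(exposures, covariates, y, q=q, b=0, marginal=False)
    reduced = fit_qgcomp(
        exposures.drop(columns=[component]), covariates, y, q=q, b=0, marginal=False
    )
    return SensitivityResult(
        component=component,
        psi_full=full.psi_conditional,
        psi_reduced=reduced.psi_conditional,
    )
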