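"""Synthetic cohort generation: demographics, planted coefficients, outcomes.

The generator emulates the covariate structure the mixture analysis assumes:
independent Bernoulli indicators at published marginals, age from a normal
truncated at an adult floor, planar home coordinates partially clustered
around simulated urban centers, and a Bernoulli outcome from a logistic
model in octile-coded exposures and covariates.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit

from . import reference

logger = logging.getLogger(__name__)

#: Schema of a cohort table before the outcome is assigned.
COHORT_COLUMNS = [
    "id",
    "x",
    "y",
    "age",
    "sex_male",
    "smoked_100",
    "family_ra",
    "other_ai",
    "income_gt_30k",
]

INDICATOR_COLUMNS = [
    "sex_male",
    "smoked_100",
    "family_ra",
    "other_ai",
    "income_gt_30k",
]


class ParameterError(ValueError):
    """Invalid generator or model parameters."""


class SchemaError(ValueError):
    """Mismatched column names / row counts between model pieces."""


@dataclass(frozen=True)
class SpatialLayout:
    """Planar study domain (projected km) with simulated urban clustering.

    A fraction ``urban_fraction`` of addresses is drawn from isotropic
    Gaussian clusters around ``urban_centers``; the rest are uniform over
    the domain.  Points are redrawn until they fall inside the extent.
    """

    xmin: float = 0.0
    xmax: float = 400.0
    ymin: float = 0.0
    ymax: float = 300.0
    urban_centers: tuple[tuple[float, float], ...] = (
        (90.0, 90.0),
        (200.0, 160.0),
        (310.0, 110.0),
        (150.0, 230.0),
        (330.0, 230.0),
    )
    urban_fraction: float = 0.6
    urban_sd: float = 15.0

    @property
    def area(self) -> float:
        return (self.xmax - self.xmin) * (self.ymax - self.ymin)

    def sample_points(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` (x, y) points from the mixture density."""
        if n == 0:
            return np.empty((0, 2))
        urban = rng.random(n) < self.urban_fraction
        pts = np.column_stack(
            [
                rng.uniform(self.xmin, self.xmax, n),
                rng.uniform(self.ymin, self.ymax, n),
            ]
        )
        idx = np.flatnonzero(urban)
        if idx.size and self.urban_centers:
            centers = np.asarray(self.urban_centers)
            which = rng.integers(0, len(centers), idx.size)
            p = centers[which] + rng.normal(0.0, self.urban_sd, (idx.size, 2))
            # reflect strays back into the extent rather than rejecting
            p[:, 0] = _reflect(p[:, 0], self.xmin, self.xmax)
            p[:, 1] = _reflect(p[:, 1], self.ymin, self.ymax)
            pts[idx] = p
        return pts


def _reflect(v: np.ndarray, lo: float, hi: float) -> np.ndarray:
    span = hi - lo
    v = np.mod(v - lo, 2 * span)
    v = np.where(v > span, 2 * span - v, v)
    return v + lo


@dataclass(frozen=True)
class DemographicParams:
    """Marginal demographic targets; defaults reproduce the reference cohort."""

    n: int = int(reference.REFERENCE_COHORT["n"])
    age_mean: float = reference.REFERENCE_COHORT["age_mean"]
    age_sd: float = reference.REFERENCE_COHORT["age_sd"]
    p_female: float = reference.REFERENCE_COHORT["p_female"]
    p_smoke: float = reference.REFERENCE_COHORT["p_smoke"]
    p_family_ra: float = reference.REFERENCE_COHORT["p_family_ra"]
    p_other_ai: float = reference.REFERENCE_COHORT["p_other_ai"]
    p_income: float = reference.REFERENCE_COHORT["p_income"]
    target_prevalence: float = reference.REFERENCE_COHORT["prevalence"]
    age_floor: float = 18.0

    def validate(self) -> None:
        if self.n < 0:
            raise ParameterError(f"n must be >= 0, got {self.n}")
        for name in (
            "p_female",
            "p_smoke",
            "p_family_ra",
            "p_other_ai",
            "p_income",
            "target_prevalence",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"{name}={p} outside [0, 1]")
        if self.age_sd < 0:
            raise ParameterError("age_sd must be >= 0")


@dataclass(frozen=True)
class CoefficientSet:
    """Log-odds coefficients of the outcome model on the octile scale.

    ``mixture_betas`` are per-octile-increment log odds ratios for each
    exposure column; ``covariate_alphas`` are log odds ratios for the
    non-exposure covariates (age per year of age).
    """

    intercept: float
    mixture_betas: pd.Series
    covariate_alphas: pd.Series

    def __post_init__(self) -> None:
        vals = np.concatenate(
            [[self.intercept], self.mixture_betas.values, self.covariate_alphas.values]
        )
        if not np.all(np.isfinite(vals)):
            raise ParameterError("coefficients must be finite")

    @property
    def psi(self) -> float:
        """Conditional mixture effect: sum of mixture log odds ratios."""
        return float(self.mixture_betas.sum())

    def with_intercept(self, intercept: float) -> "CoefficientSet":
        return dataclasses.replace(self, intercept=float(intercept))

    def without(self, component: str) -> "CoefficientSet":
        if component not in self.mixture_betas.index:
            raise KeyError(component)
        return dataclasses.replace(
            self, mixture_betas=self.mixture_betas.drop(component)
        )


def reference_preset(mode: str = "per_component") -> CoefficientSet:
    """Plantable coefficient sets built from the published estimates.

    ``"uniform_psi"`` spreads the published mixture odds ratio evenly:
    every mixture beta is ln(OR_psi)/17, so their sum is exactly ln(OR_psi).
    ``"per_component"`` sets each mixture beta and covariate alpha to the
    natural log of its published odds ratio, using the internally
    consistent set (the published pm10 OR is corrected to the value its
    printed weight implies; see :mod:`qgmix.reference`).  In both modes the
    intercept is ln of the published intercept OR; in practice it is
    re-calibrated to the target prevalence with :func:`calibrate_intercept`.
    """
    alphas = pd.Series(
        {k: math.log(v) for k, v in reference.COVARIATE_OR.items()},
        name="alpha",
    )[reference.COVARIATE_COLUMNS]
    if mode == "uniform_psi":
        d = len(reference.EXPOSURE_COLUMNS)
        betas = pd.Series(
            math.log(reference.PSI_OR) / d,
            index=reference.EXPOSURE_COLUMNS,
            name="beta",
        )
    elif mode == "per_component":
        betas = reference.mixture_log_odds(consistent=True)
    else:
        raise ParameterError(f"unknown preset mode {mode!r}")
    return CoefficientSet(
        intercept=math.log(reference.INTERCEPT_OR),
        mixture_betas=betas,
        covariate_alphas=alphas,
    )


def null_preset(intercept: float | None = None) -> CoefficientSet:
    """All mixture and covariate effects zero (planted-null scenarios)."""
    if intercept is None:
        intercept = float(logit(reference.REFERENCE_COHORT["prevalence"]))
    return CoefficientSet(
        intercept=intercept,
        mixture_betas=pd.Series(0.0, index=reference.EXPOSURE_COLUMNS, name="beta"),
        covariate_alphas=pd.Series(
            0.0, index=reference.COVARIATE_COLUMNS, name="alpha"
        ),
    )


def _truncnorm_location(
    target_mean: float, sd: float, floor: float
) -> float:
    """Location mu such that a N(mu, sd) truncated below at ``floor`` has
    mean ``target_mean``."""
    if sd == 0:
        return max(target_mean, floor)

    def mean_at(mu: float) -> float:
        a = (floor - mu) / sd
        return float(stats.truncnorm.mean(a, np.inf, loc=mu, scale=sd))

    lo, hi = target_mean - 6 * sd, target_mean + sd
    return float(optimize.brentq(lambda m: mean_at(m) - target_mean, lo, hi))


def generate_covariates(
    params: DemographicParams,
    seed: int | np.random.SeedSequence,
    layout: SpatialLayout | None = None,
) -> pd.DataFrame:
    """Generate a cohort table (without the outcome column).

    Age is drawn from a normal truncated below at ``params.age_floor`` whose
    location is solved so the truncated mean equals ``age_mean``; indicators
    are independent Bernoulli draws at the stated marginals; coordinates
    come from the layout's urban-cluster mixture.
    """
    params.validate()
    layout = layout or SpatialLayout()
    rng = np.random.default_rng(seed)
    n = params.n
    if n == 0:
        return pd.DataFrame(
            {c: pd.Series(dtype=float if c in ("x", "y", "age") else int)
             for c in COHORT_COLUMNS}
        )
    pts = layout.sample_points(n, rng)
    if params.age_sd > 0:
        mu = _truncnorm_location(params.age_mean, params.age_sd, params.age_floor)
        a = (params.age_floor - mu) / params.age_sd
        age = stats.truncnorm.rvs(
            a, np.inf, loc=mu, scale=params.age_sd, size=n, random_state=rng
        )
    else:
        age = np.full(n, max(params.age_mean, params.age_floor))
    table = pd.DataFrame(
        {
            "id": np.arange(n, dtype=np.int64),
            "x": pts[:, 0],
            "y": pts[:, 1],
            "age": age,
            "sex_male": (rng.random(n) >= params.p_female).astype(np.int64),
            "smoked_100": (rng.random(n) < params.p_smoke).astype(np.int64),
            "family_ra": (rng.random(n) < params.p_family_ra).astype(np.int64),
            "other_ai": (rng.random(n) < params.p_other_ai).astype(np.int64),
            "income_gt_30k": (rng.random(n) < params.p_income).astype(np.int64),
        }
    )
    return table


def _linear_predictor(
    cohort: pd.DataFrame, xq: pd.DataFrame, coeffs: CoefficientSet
) -> np.ndarray:
    if len(cohort) != len(xq):
        raise SchemaError(
            f"cohort has {len(cohort)} rows but quantized exposures have {len(xq)}"
        )
    missing = [c for c in coeffs.mixture_betas.index if c not in xq.columns]
    if missing:
        raise SchemaError(f"mixture coefficients without exposure columns: {missing}")
    missing_z = [c for c in coeffs.covariate_alphas.index if c not in cohort.columns]
    if missing_z:
        raise SchemaError(f"covariate coefficients without cohort columns: {missing_z}")
    eta = np.full(len(cohort), coeffs.intercept, dtype=float)
    if len(coeffs.mixture_betas):
        eta += xq[coeffs.mixture_betas.index].to_numpy(float) @ (
            coeffs.mixture_betas.to_numpy(float)
        )
    if len(coeffs.covariate_alphas):
        eta += cohort[coeffs.covariate_alphas.index].to_numpy(float) @ (
            coeffs.covariate_alphas.to_numpy(float)
        )
    # clamp so expit stays strictly inside (0, 1) in floating point
    return np.clip(eta, -35.0, 35.0)


def assign_outcome(
    cohort: pd.DataFrame,
    xq: pd.DataFrame,
    coeffs: CoefficientSet,
    seed: int | np.random.SeedSequence,
) -> pd.DataFrame:
    """Draw Bernoulli outcomes from the logistic model and attach them.

    The outcome for subject i is Bernoulli(expit(b0 + sum_j beta_j xq_ij +
    sum_k alpha_k z_ik)); sampling noise plays the role of the model's
    residual term.  Deterministic given (inputs, seed).
    """
    rng = np.random.default_rng(seed)
    p = expit(_linear_predictor(cohort, xq, coeffs))
    out = cohort.copy()
    out["outcome"] = (rng.random(len(cohort)) < p).astype(np.int64)
    return out


def calibrate_intercept(
    coeffs: CoefficientSet,
    xq: pd.DataFrame,
    cohort: pd.DataFrame,
    target_prevalence: float,
) -> float:
    """Intercept b0 such that mean expit(b0 + slope terms) == target.

    Solved by monotone root finding over the realized design; the returned
    intercept reproduces the target mean probability to within 1e-6.
    """
    if not 0.0 < target_prevalence < 1.0:
        raise ParameterError("target_prevalence must be in (0, 1)")
    eta = _linear_predictor(cohort, xq, coeffs.with_intercept(0.0))

    def gap(b0: float) -> float:
        return float(np.mean(expit(b0 + eta))) - target_prevalence

    lo, hi = -40.0, 40.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise ParameterError("target prevalence unattainable for this design")
    b0 = optimize.brentq(gap, lo, hi, xtol=1e-10)
    if abs(gap(b0)) > 1e-6:
        raise ParameterError("intercept calibration did not converge")
    return float(b0)
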