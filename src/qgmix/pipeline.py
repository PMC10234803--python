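"""End-to-end orchestration: simulate -> link -> quantize -> fit -> report.

A single master seed spawns named substreams per stage (covariates,
exposures, outcome, bootstrap) so each stage is independently reproducible;
every output carries a hash of the canonical config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import reference
from .cohort import (
    CoefficientSet,
    DemographicParams,
    ParameterError,
    SpatialLayout,
    assign_outcome,
    calibrate_intercept,
    generate_covariates,
    null_preset,
    reference_preset,
)
from .landscape import (
    LandscapeParams,
    generate_landscape,
    link_exposures,
    sample_exposure_matrix,
)
from .linkage import DecayParams, exposure_summary
from .qgcomp import MixtureFit, SensitivityResult, fit_qgcomp, leave_one_out_sensitivity
from .quantize import quantize_columns

logger = logging.getLogger(__name__)

PRESETS = ("uniform_psi", "per_component", "null")


@dataclass(frozen=True)
class RunConfig:
    """Reproducible run description; serializable to/from YAML or JSON."""

    seed: int = 0
    demographics: DemographicParams = field(default_factory=DemographicParams)
    decay: DecayParams = field(default_factory=DecayParams)
    preset: str = "per_component"
    q: int = 8
    bootstrap: int = 1000
    ci_level: float = 0.95
    include_income: bool = False
    exposure_mode: str = "landscape"     # full spatial route, or "direct"
    drop_component: str | None = None
    out_dir: str | None = None
    landscape_overrides: dict = field(default_factory=dict)

    def validate(self) -> None:
        self.demographics.validate()
        if self.preset not in PRESETS:
            raise ParameterError(
                f"unknown preset {self.preset!r}; choose from {PRESETS}"
            )
        if self.exposure_mode not in ("direct", "landscape"):
            raise ParameterError("exposure_mode must be 'direct' or 'landscape'")
        if self.q < 2:
            raise ParameterError("q must be >= 2")
        if not 0 < self.ci_level < 1:
            raise ParameterError("ci_level must be in (0, 1)")

    def coefficients(self) -> CoefficientSet:
        if self.preset == "null":
            return null_preset()
        return reference_preset(self.preset)

    def landscape_params(self) -> LandscapeParams:
        return dataclasses.replace(LandscapeParams(), **self.landscape_overrides)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "demographics": dataclasses.asdict(self.demographics),
            "decay": dataclasses.asdict(self.decay),
            "preset": self.preset,
            "q": self.q,
            "bootstrap": self.bootstrap,
            "ci_level": self.ci_level,
            "include_income": self.include_income,
            "exposure_mode": self.exposure_mode,
            "drop_component": self.drop_component,
            "landscape_overrides": dict(self.landscape_overrides),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        demo = DemographicParams(**data.pop("demographics", {}))
        decay = DecayParams(**data.pop("decay", {}))
        data.pop("out_dir", None)
        return cls(demographics=demo, decay=decay, **data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Everything one pipeline run produced."""

    cohort: pd.DataFrame
    exposures: pd.DataFrame
    descriptive: pd.DataFrame
    exposure_stats: pd.DataFrame
    mixture: MixtureFit
    sensitivity: SensitivityResult | None
    provenance: dict

    def to_json_dict(self) -> dict:
        out = {
            "provenance": self.provenance,
            "mixture": self.mixture.to_json_dict(),
            "descriptive": self.descriptive.to_dict(orient="records"),
            "exposure_summary": self.exposure_stats.round(6)
            .reset_index()
            .to_dict(orient="records"),
        }
        if self.sensitivity is not None:
            s = self.sensitivity
            out["sensitivity"] = {
                "component": s.component,
                "psi_full": s.psi_full,
                "psi_reduced": s.psi_reduced,
                "delta_log_odds": s.delta_log,
                "delta_or": s.delta_or,
            }
        return out

    def write(self, out_dir: str | Path) -> None:
        """Write all outputs atomically (temp file + rename) to a directory."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _atomic_csv(self.cohort, out / "cohort.csv")
        _atomic_csv(self.exposures.reset_index(), out / "exposures.csv")
        _atomic_csv(self.descriptive, out / "descriptive.csv")
        if self.mixture.table is not None:
            _atomic_csv(
                self.mixture.table.reset_index(), out / "mixture_results.csv"
            )
        tmp = out / "report.json.tmp"
        tmp.write_text(json.dumps(self.to_json_dict(), indent=2, sort_keys=True))
        os.replace(tmp, out / "report.json")


def _atomic_csv(df: pd.DataFrame, path: Path) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    df.to_csv(tmp, index=False)
    os.replace(tmp, path)


def descriptive_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Cohort characteristics: n, mean (SD) age, counts (%) per indicator."""
    if len(cohort) == 0:
        raise ParameterError("cohort is empty")
    rows = [
        {"characteristic": "n", "statistic": "count", "value": float(len(cohort))},
        {
            "characteristic": "age",
            "statistic": "mean",
            "value": float(cohort["age"].mean()),
        },
        {
            "characteristic": "age",
            "statistic": "sd",
            "value": float(cohort["age"].std(ddof=1)) if len(cohort) > 1 else 0.0,
        },
    ]
    indicators = [
        "sex_male",
        "smoked_100",
        "family_ra",
        "other_ai",
        "income_gt_30k",
    ]
    if "outcome" in cohort.columns:
        indicators = indicators + ["outcome"]
    for col in indicators:
        if col not in cohort.columns:
            continue
        count = int(cohort[col].sum())
        rows.append(
            {"characteristic": col, "statistic": "count", "value": float(count)}
        )
        rows.append(
            {
                "characteristic": col,
                "statistic": "percent",
                "value": 100.0 * count / len(cohort),
            }
        )
    return pd.DataFrame(rows)


def covariates_for_fit(
    cohort: pd.DataFrame, include_income: bool = False
) -> pd.DataFrame:
    """The adjustment covariate block (income only in sensitivity runs)."""
    cols = list(reference.COVARIATE_COLUMNS)
    if include_income:
        cols.append("income_gt_30k")
    return cohort[cols]


def simulate_cohort(
    config: RunConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, CoefficientSet]:
    """Stages 1-3: covariates, exposures, planted outcome.

    Returns (cohort with outcome, exposure matrix, calibrated coefficients).
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    s_cov, s_expo, s_outcome, _ = ss.spawn(4)
    t0 = time.perf_counter()
    lparams = config.landscape_params()
    cohort = generate_covariates(config.demographics, s_cov, layout=lparams.layout)
    logger.info(
        "stage=covariates rows=%d elapsed=%.2fs", len(cohort), time.perf_counter() - t0
    )

    t0 = time.perf_counter()
    if config.exposure_mode == "landscape":
        landscape = generate_landscape(lparams, s_expo)
        exposures = link_exposures(cohort, landscape, decay=config.decay)
    else:
        exposures = sample_exposure_matrix(len(cohort), s_expo)
        exposures.index = pd.Index(cohort["id"].to_numpy(), name="id")
    logger.info(
        "stage=exposures mode=%s elapsed=%.2fs",
        config.exposure_mode,
        time.perf_counter() - t0,
    )

    xq = quantize_columns(exposures, config.q)
    coeffs = config.coefficients()
    b0 = calibrate_intercept(
        coeffs, xq.codes, cohort, config.demographics.target_prevalence
    )
    coeffs = coeffs.with_intercept(b0)
    cohort = assign_outcome(cohort, xq.codes, coeffs, s_outcome)
    logger.info(
        "stage=outcome prevalence=%.4f", float(cohort["outcome"].mean())
    )
    return cohort, exposures, coeffs


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full simulate -> link -> fit -> report chain."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    _, _, _, s_boot = ss.spawn(4)
    cohort, exposures, coeffs = simulate_cohort(config)

    t0 = time.perf_counter()
    z = covariates_for_fit(cohort, config.include_income)
    mixture = fit_qgcomp(
        exposures,
        z,
        cohort["outcome"].to_numpy(),
        q=config.q,
        b=config.bootstrap,
        seed=int(s_boot.generate_state(1)[0] % (2**31)),
        level=config.ci_level,
    )
    logger.info(
        "stage=fit B=%d psi_or=%.4f elapsed=%.2fs",
        config.bootstrap,
        float(np.exp(mixture.psi_conditional)),
        time.perf_counter() - t0,
    )

    sensitivity = None
    if config.drop_component:
        sensitivity = leave_one_out_sensitivity(
            exposures,
            z,
            cohort["outcome"].to_numpy(),
            config.drop_component,
            q=config.q,
        )
        logger.info(
            "stage=sensitivity component=%s delta_psi=%.4f",
            config.drop_component,
            sensitivity.delta_log,
        )

    report = RunReport(
        cohort=cohort,
        exposures=exposures,
        descriptive=descriptive_table(cohort),
        exposure_stats=exposure_summary(exposures),
        mixture=mixture,
        sensitivity=sensitivity,
        provenance={
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "planted_psi": coeffs.psi,
            "package": "qgmix",
        },
    )
    if config.out_dir:
        report.write(config.out_dir)
    return report
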