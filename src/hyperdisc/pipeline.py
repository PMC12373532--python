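"""End-to-end analysis runs: fit -> encode -> regress / mediate / Bayes factor.

Two analysis frames mirror the study design:

* **cross-section** — per-participant discount rates at one wave, regressed
  on binarised income shock (and optionally the negative-affect score),
  controlling for demographics or not: four registered models, a mediation
  analysis in both variants, and the nested Bayes factor for the affect term.
* **panel** — two waves, within-participant change in log k regressed on the
  change in binarised shock with wave-1 demographics, after excluding
  participants flagged as reporting a positive shock.

Every run logs row counts at each stage and asserts conservation
(input = analyzed + excluded).  All outputs are deterministic given the
inputs and configuration.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CohortConfig
from .encoding import DEMOGRAPHICS, build_encoded, change_scores
from .inference import (
    BayesFactorResult,
    MediationResult,
    RegressionResult,
    bayes_factor_nested,
    compare_betas,
    mediation_analysis,
    robust_fit,
)
from .instrument import ChoiceDataset, ItemBank, ValidationError
from .model import FitConfig, fit_cohort

__all__ = [
    "RunConfig",
    "CrossSectionResult",
    "PanelResult",
    "run_cross_section",
    "run_panel",
    "make_report",
]

FRAMES = ("cross_section_t1", "cross_section_t2", "panel")

MIN_PANEL_N = 30


@dataclass
class RunConfig:
    """Configuration of an orchestrated run (YAML-loadable)."""

    seed: int
    frames: tuple[str, ...] = ("cross_section_t1",)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    fit: FitConfig = field(default_factory=FitConfig)
    exclude_positive_shock: bool = True
    output_dir: str = "out"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("seed must be set explicitly (no wall-clock seeding)")
        if not self.frames:
            raise ValidationError("at least one analysis frame is required")
        unknown = set(self.frames) - set(FRAMES)
        if unknown:
            raise ValidationError(f"unknown frames {sorted(unknown)}; valid: {FRAMES}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "cohort" in kwargs:
            kwargs["cohort"] = CohortConfig(**kwargs["cohort"])
        if "fit" in kwargs:
            kwargs["fit"] = FitConfig.from_mapping(kwargs["fit"])
        if "frames" in kwargs:
            kwargs["frames"] = tuple(kwargs["frames"])
        return cls(**kwargs)


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def _regression_dict(r: RegressionResult) -> dict:
    return {
        "coefficients": {
            name: {"estimate": float(b), "se": float(s), "t": float(t), "p": float(p)}
            for name, b, s, t, p in zip(r.names, r.params, r.bse, r.tvalues, r.pvalues)
        },
        "df": int(r.df_resid),
        "n": int(r.nobs),
        "r_squared": float(r.r_squared),
        "method": r.method,
    }


def _mediation_dict(m: MediationResult) -> dict:
    return {
        "alpha": m.alpha, "se_alpha": m.se_alpha,
        "beta": m.beta, "se_beta": m.se_beta,
        "indirect": m.product, "sobel_se": m.sobel.se,
        "sobel_z": m.sobel.statistic, "p_normal": m.sobel.p_normal,
        "df": m.sobel.df, "p_t": m.sobel.p_t,
        "controls": list(m.controls),
    }


def _bf_dict(b: BayesFactorResult) -> dict:
    return {"bf": b.bf, "log_bf": b.log_bf, "n": b.nobs,
            "p_full": b.p_full, "p_reduced": b.p_reduced,
            "r2_full": b.r2_full, "r2_reduced": b.r2_reduced, "method": b.method}


@dataclass
class CrossSectionResult:
    """Everything one cross-section frame produces."""

    frame: str
    fits: pd.DataFrame
    encoded: pd.DataFrame
    models: dict[str, RegressionResult]
    mediation: dict[str, MediationResult]
    bayes_factors: dict[str, BayesFactorResult]
    beta_comparison: dict[str, float]
    counts: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "frame": self.frame,
            "counts": dict(self.counts),
            "fit_diagnostics": {
                "median_k": float(np.median(self.encoded["k"])),
                "mean_pseudo_r2": float(self.encoded["pseudo_r2"].mean()),
                "mean_balanced_accuracy": float(self.encoded["balanced_accuracy"].mean()),
                "n_boundary": int(self.encoded["boundary_flag"].sum()),
            },
            "models": {k: _regression_dict(v) for k, v in self.models.items()},
            "mediation": {k: _mediation_dict(v) for k, v in self.mediation.items()},
            "bayes_factors": {k: _bf_dict(v) for k, v in self.bayes_factors.items()},
            "beta_comparison": dict(self.beta_comparison),
        }

    def summary(self) -> str:
        lines = [f"Cross-section frame: {self.frame}", f"counts: {self.counts}"]
        for name, m in self.models.items():
            lines.append(f"\n[{name}]\n{m.summary()}")
        for name, m in self.mediation.items():
            lines.append(f"\n[mediation, {name}]\n{m.summary()}")
        for name, b in self.bayes_factors.items():
            lines.append(f"\n[BF affect, {name}]\n{b.summary()}")
        return "\n".join(lines)


@dataclass
class PanelResult:
    """Everything the panel frame produces."""

    fits: pd.DataFrame
    encoded: pd.DataFrame  # per-participant change scores
    models: dict[str, RegressionResult]
    bayes_factors: dict[str, BayesFactorResult]
    counts: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "frame": "panel",
            "counts": dict(self.counts),
            "models": {k: _regression_dict(v) for k, v in self.models.items()},
            "bayes_factors": {k: _bf_dict(v) for k, v in self.bayes_factors.items()},
        }

    def summary(self) -> str:
        lines = [f"Panel frame; counts: {self.counts}"]
        for name, m in self.models.items():
            lines.append(f"\n[{name}]\n{m.summary()}")
        for name, b in self.bayes_factors.items():
            lines.append(f"\n[BF delta-affect, {name}]\n{b.summary()}")
        return "\n".join(lines)


def _merge_fits(fits: pd.DataFrame, covariates: pd.DataFrame, timepoint: int):
    cov = covariates[covariates["timepoint"] == timepoint] if "timepoint" in covariates else covariates
    merged = cov.merge(
        fits[fits["timepoint"] == timepoint],
        on="participant_id",
        suffixes=("", "_fit"),
    )
    return merged


def run_cross_section(
    choices: Sequence[ChoiceDataset],
    covariates: pd.DataFrame,
    bank: ItemBank | None = None,
    fit_config: FitConfig | None = None,
    timepoint: int = 1,
) -> CrossSectionResult:
    """Fit every participant at one wave, encode covariates, run the four
    registered models, the mediation analysis and the affect Bayes factor."""
    bank = bank or ItemBank.kirby27()
    subset = [ds for ds in choices if ds.timepoint == timepoint]
    if not subset:
        raise ValidationError(f"no choice datasets at timepoint {timepoint}")
    fits = fit_cohort(subset, bank, fit_config)
    merged = _merge_fits(fits, covariates, timepoint)
    if merged.empty:
        raise ValidationError("no participants with both choices and covariates")
    encoded = build_encoded(merged)

    demo = list(DEMOGRAPHICS)
    y = encoded["log_k"]
    models = {
        "shock": robust_fit(encoded[["shock01"]], y),
        "shock_demographics": robust_fit(encoded[["shock01", *demo]], y),
        "shock_affect": robust_fit(encoded[["shock01", "affect_score"]], y),
        "shock_affect_demographics": robust_fit(
            encoded[["shock01", "affect_score", *demo]], y
        ),
    }
    mediation = {
        "with_demographics": mediation_analysis(encoded, controls=True),
        "without_demographics": mediation_analysis(encoded, controls=False),
    }
    bayes_factors = {
        "with_demographics": bayes_factor_nested(
            models["shock_affect_demographics"].r_squared, 2 + len(demo),
            models["shock_demographics"].r_squared, 1 + len(demo),
            n=len(encoded),
        ),
        "without_demographics": bayes_factor_nested(
            models["shock_affect"].r_squared, 2,
            models["shock"].r_squared, 1,
            n=len(encoded),
        ),
    }
    t_cmp, p_cmp = compare_betas(
        models["shock_affect_demographics"], "shock01", "affect_score"
    )
    counts = {
        "choices_in": len(subset),
        "covariate_rows_in": int((covariates["timepoint"] == timepoint).sum())
        if "timepoint" in covariates else len(covariates),
        "analyzed": len(encoded),
    }
    counts["excluded_unmatched"] = (
        counts["choices_in"] - counts["analyzed"]
    )
    assert counts["analyzed"] + counts["excluded_unmatched"] == counts["choices_in"]
    return CrossSectionResult(
        frame=f"cross_section_t{timepoint}",
        fits=fits,
        encoded=encoded,
        models=models,
        mediation=mediation,
        bayes_factors=bayes_factors,
        beta_comparison={"t": t_cmp, "p": p_cmp,
                         "delta_beta": models["shock_affect_demographics"].coef("shock01")
                         - models["shock_affect_demographics"].coef("affect_score")},
        counts=counts,
    )


def run_panel(
    choices_t1: Sequence[ChoiceDataset],
    choices_t2: Sequence[ChoiceDataset],
    covariates: pd.DataFrame,
    bank: ItemBank | None = None,
    fit_config: FitConfig | None = None,
    exclude_positive_shock: bool = True,
    force: bool = False,
) -> PanelResult:
    """Two-wave change-score analysis of log k on the change in income shock.

    Refuses to run with fewer than 30 matched participants unless ``force``.
    """
    bank = bank or ItemBank.kirby27()
    fits1 = fit_cohort([ds for ds in choices_t1 if ds.timepoint == 1], bank, fit_config)
    fits2 = fit_cohort([ds for ds in choices_t2 if ds.timepoint == 2], bank, fit_config)
    fits = pd.concat([fits1, fits2], ignore_index=True)
    m1 = _merge_fits(fits, covariates, 1)
    m2 = _merge_fits(fits, covariates, 2)
    delta = change_scores(m1, m2, exclude_positive_shock=exclude_positive_shock)
    n_matched = delta.attrs["n_matched"]
    if n_matched < MIN_PANEL_N and not force:
        raise ValidationError(
            f"only {n_matched} participants matched across waves "
            f"(< {MIN_PANEL_N}); pass force=True to run anyway"
        )

    demo = list(DEMOGRAPHICS)
    y = delta["delta_log_k"]
    try:
        models = {
            "delta_shock": robust_fit(delta[["delta_shock"]], y),
            "delta_shock_demographics": robust_fit(delta[["delta_shock", *demo]], y),
        }
    except ValidationError as exc:
        raise ValidationError(f"panel regression is degenerate: {exc}") from exc
    bayes_factors: dict[str, BayesFactorResult] = {}
    if "delta_affect" in delta.columns and delta["delta_affect"].std() > 0:
        full = robust_fit(delta[["delta_shock", "delta_affect", *demo]], y)
        bayes_factors["delta_affect_with_demographics"] = bayes_factor_nested(
            full.r_squared, 2 + len(demo),
            models["delta_shock_demographics"].r_squared, 1 + len(demo),
            n=len(delta),
        )
        models["delta_shock_affect_demographics"] = full

    counts = {
        "t1_in": delta.attrs["n_t1"],
        "t2_in": delta.attrs["n_t2"],
        "matched": n_matched,
        "excluded_positive_shock": delta.attrs["n_excluded_positive"],
        "analyzed": delta.attrs["n_analyzed"],
    }
    assert counts["analyzed"] + counts["excluded_positive_shock"] == counts["matched"]
    return PanelResult(fits=fits, encoded=delta, models=models,
                       bayes_factors=bayes_factors, counts=counts)


def make_report(
    result: CrossSectionResult | PanelResult,
    outdir,
    config: RunConfig | None = None,
    seed: int | None = None,
) -> dict[str, Path]:
    """Write results.json, fits.csv, encoded.csv and a markdown summary.

    results.json carries a meta block (package version, seed, config echo,
    timestamp) and the per-stage row counts as an audit trail.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = {
        "meta": {
            "package": "hyperdisc",
            "version": __version__,
            "seed": seed if seed is not None else (config.seed if config else None),
            "config": _jsonable(config) if config else None,
            "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        },
        "results": _jsonable(result.to_dict()),
    }
    paths = {
        "results": outdir / "results.json",
        "fits": outdir / "fits.csv",
        "encoded": outdir / "encoded.csv",
        "report": outdir / "report.md",
    }
    paths["results"].write_text(json.dumps(payload, indent=2) + "\n")
    result.fits.to_csv(paths["fits"], index=False)
    result.encoded.to_csv(paths["encoded"], index=False)
    paths["report"].write_text(
        f"# hyperdisc report\n\n```\n{result.summary()}\n```\n"
    )
    return paths
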