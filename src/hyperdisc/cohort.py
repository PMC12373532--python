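"""Synthetic two-wave cohort generator.

Generates a cohort with the statistical structure the downstream analyses
assume, so every stage (choice fitting, encoding, regression, mediation,
Bayes factors) can be validated by parameter recovery without any human data:

* demographics drawn from documented marginals (age truncated-normal 44 +/-
  15.6 on [18, 85]; P(male) = 0.477; household income log-normal with median
  52,500; five-level ordinal education);
* an income-shock Likert (1-6) obtained by thresholding a latent standard
  normal at fixed cut points (mean ~3.1, ~50% above the midpoint so the
  binarised variable is balanced);
* three emotion ratings (fear, sad, angry) from a single-factor Gaussian
  copula (pairwise latent correlation 0.65), margins scaled to mean 43,
  SD 25 and clipped to [0, 100];
* the affect factor and the shock latent correlate only weakly (0.025):
  shock and affect are *independent causes* of the discount rate, so
  mediation analyses must come out null — the pipeline's negative control;
* a true log discount rate built from standardized encoded covariates with
  configurable standardized effect sizes, plus Gaussian noise, anchored so
  the median k matches the configured value and clipped to the fit bounds;
* per-participant choice sensitivity beta drawn log-normally;
* binary choices simulated per participant from the hyperbolic + softmax
  model.

A second wave shifts the latent shock downward (targeting a mean Likert drop
of ~0.27), adds a within-person change in log k driven by the standardized
change in binarised shock, re-simulates choices, and flags a fixed fraction
of participants (exactly ``round(fraction * n)``, default 8%) as reporting a
*positive* shock, exercising the panel exclusion rule.

Everything is reproducible from ``CohortConfig.seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import encoding
from .instrument import ChoiceDataset, ItemBank, ValidationError, write_choice_data
from .model import DEFAULT_BETA_BOUNDS, DEFAULT_K_BOUNDS, ModelParams
from .recovery import simulate_choices

__all__ = ["CohortConfig", "CohortTable", "generate_cohort", "generate_panel", "save_cohort"]

#: Cut points on the latent standard normal mapping to Likert 1..6.
#: Chosen so the Likert mean is ~3.1 and ~50% of mass falls in {4,5,6}.
SHOCK_CUTPOINTS = (-0.674, -0.253, 0.0, 0.772, 1.476)


@dataclass
class CohortConfig:
    """Generator settings.  Effect sizes are standardized coefficients of the
    true log k on the z-scored encoded covariates; ``residual_sd_log_k`` is
    the SD (natural-log units) of the noise term."""

    n_participants: int = 1145
    seed: int = 0

    # standardized effects on log k
    b_shock: float = 0.12
    b_affect: float = 0.082
    b_education: float = -0.14
    b_income: float = -0.15
    b_age: float = -0.06
    b_gender: float = -0.009

    residual_sd_log_k: float = 1.3
    median_k: float = 0.0137

    # affect / shock structure
    emotion_latent_corr: float = 0.65
    shock_affect_corr: float = 0.025
    emotion_mean: float = 43.0
    emotion_sd: float = 25.0

    # demographics
    age_mean: float = 44.0
    age_sd: float = 15.6
    age_range: tuple[float, float] = (18.0, 85.0)
    p_male: float = 0.477
    income_median: float = 52_500.0
    income_sdlog: float = 0.75
    education_probs: tuple[float, ...] = (0.10, 0.25, 0.30, 0.25, 0.10)

    # choice sensitivity distribution (log-normal), clipped to beta bounds;
    # calibrated so the cohort mean pseudo-R^2 lands near 0.69 and balanced
    # accuracy near 0.87
    beta_median: float = 0.18
    beta_sdlog: float = 0.7

    # wave 2
    time2_shock_shift: float = 0.18      # latent scale; targets ~0.27 Likert drop
    time2_shock_noise_sd: float = 0.6
    # wave-2 choices are more deterministic (higher pseudo-R^2 / balanced
    # accuracy at the second administration); beta is scaled up accordingly
    time2_beta_scale: float = 2.5
    emotion_stability: float = 0.5
    b_delta_shock: float = 0.16
    delta_residual_sd_log_k: float = 1.0
    positive_shock_fraction: float = 0.08

    k_bounds: tuple[float, float] = DEFAULT_K_BOUNDS
    beta_bounds: tuple[float, float] = DEFAULT_BETA_BOUNDS
    simulate_choices: bool = True

    def effect_sizes(self) -> dict[str, float]:
        return {
            "shock01": self.b_shock,
            "affect_score": self.b_affect,
            "education": self.b_education,
            "income": self.b_income,
            "age": self.b_age,
            "gender": self.b_gender,
        }

    def validate(self) -> None:
        if self.n_participants < 2:
            raise ValidationError("need at least 2 participants")
        ss = sum(b * b for b in self.effect_sizes().values())
        if ss >= 1.0:
            raise ValidationError(
                f"effect sizes imply negative residual variance (sum of squares {ss:.3f} >= 1)"
            )
        if abs(self.b_delta_shock) >= 1.0:
            raise ValidationError("b_delta_shock must lie in (-1, 1)")
        for name, v in (("emotion_latent_corr", self.emotion_latent_corr),
                        ("shock_affect_corr", self.shock_affect_corr),
                        ("emotion_stability", self.emotion_stability)):
            if not -1.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [-1, 1], got {v}")
        if self.residual_sd_log_k <= 0 or self.delta_residual_sd_log_k <= 0:
            raise ValidationError("residual SDs must be positive")
        if not 0.0 <= self.positive_shock_fraction < 1.0:
            raise ValidationError("positive_shock_fraction must lie in [0, 1)")


@dataclass
class CohortTable:
    """Per-participant covariates (+ ``true_``-prefixed generative truths) and
    the linked simulated choice datasets."""

    covariates: pd.DataFrame
    choices: list[ChoiceDataset]
    config: CohortConfig

    @property
    def timepoints(self) -> tuple[int, ...]:
        return tuple(sorted(self.covariates["timepoint"].unique()))

    def covariates_at(self, timepoint: int) -> pd.DataFrame:
        return self.covariates[self.covariates["timepoint"] == timepoint].reset_index(drop=True)

    def choices_at(self, timepoint: int) -> list[ChoiceDataset]:
        return [ds for ds in self.choices if ds.timepoint == timepoint]


def _likert_from_latent(latent: np.ndarray) -> np.ndarray:
    return np.searchsorted(np.asarray(SHOCK_CUTPOINTS), latent) + 1


def _emotion_ratings(factor: np.ndarray, rng: np.random.Generator, cfg: CohortConfig):
    """Three ratings from a single-factor model with pairwise latent
    correlation ``emotion_latent_corr``; margins mean/SD then clipped."""
    lam = math.sqrt(cfg.emotion_latent_corr)
    n = len(factor)
    out = {}
    for name in ("fear", "sad", "angry"):
        e = lam * factor + math.sqrt(1.0 - lam * lam) * rng.standard_normal(n)
        out[name] = np.clip(cfg.emotion_mean + cfg.emotion_sd * e, 0.0, 100.0)
    return out


def _true_log_k(df: pd.DataFrame, eps: np.ndarray, cfg: CohortConfig) -> np.ndarray:
    """intercept + S * sum(b_j z_j) + sigma * eps, clipped to the k bounds.

    S is the implied total SD of log k, S = sigma / sqrt(1 - sum b^2), which
    makes each planted standardized coefficient equal its configured value.
    """
    effects = cfg.effect_sizes()
    ss = sum(b * b for b in effects.values())
    total_sd = cfg.residual_sd_log_k / math.sqrt(1.0 - ss)
    lin = np.zeros(len(df))
    for col, b in effects.items():
        if b != 0.0:
            lin += b * encoding.standardize(df[col].to_numpy())
    log_k = math.log(cfg.median_k) + total_sd * lin + cfg.residual_sd_log_k * eps
    return np.clip(log_k, math.log(cfg.k_bounds[0]), math.log(cfg.k_bounds[1]))


def generate_cohort(config: CohortConfig, bank: ItemBank | None = None) -> CohortTable:
    """Generate the wave-1 cohort (see module docstring for the model)."""
    config.validate()
    cfg = config
    n = cfg.n_participants
    rng = np.random.default_rng([cfg.seed, 1])

    age_a = (cfg.age_range[0] - cfg.age_mean) / cfg.age_sd
    age_b = (cfg.age_range[1] - cfg.age_mean) / cfg.age_sd
    age = stats.truncnorm.rvs(age_a, age_b, loc=cfg.age_mean, scale=cfg.age_sd,
                              size=n, random_state=rng)
    gender = (rng.random(n) < cfg.p_male).astype(int)
    education = rng.choice(np.arange(1, len(cfg.education_probs) + 1), size=n,
                           p=cfg.education_probs)
    income = rng.lognormal(mean=math.log(cfg.income_median), sigma=cfg.income_sdlog, size=n)

    shock_latent = rng.standard_normal(n)
    likert = _likert_from_latent(shock_latent)
    r = cfg.shock_affect_corr
    affect_factor = r * shock_latent + math.sqrt(1.0 - r * r) * rng.standard_normal(n)
    emotions = _emotion_ratings(affect_factor, rng, cfg)

    df = pd.DataFrame(
        {
            "participant_id": [f"p{i:05d}" for i in range(n)],
            "timepoint": 1,
            "age": age,
            "gender": gender,
            "education": education,
            "income": income,
            "income_shock_likert": likert,
            **emotions,
        }
    )
    df["shock01"] = encoding.binarize_income_shock(df["income_shock_likert"].to_numpy())
    df["affect_score"] = encoding.negative_affect_score(
        df["fear"].to_numpy(), df["sad"].to_numpy(), df["angry"].to_numpy()
    )
    df["true_log_k"] = _true_log_k(df, rng.standard_normal(n), cfg)
    df["true_k"] = np.exp(df["true_log_k"])
    beta = rng.lognormal(mean=math.log(cfg.beta_median), sigma=cfg.beta_sdlog, size=n)
    df["true_beta"] = np.clip(beta, *cfg.beta_bounds)
    df["true_shock_latent"] = shock_latent
    df["true_affect_factor"] = affect_factor
    df["positive_shock"] = False
    df = df.drop(columns=["shock01", "affect_score"])  # derived, not stored

    choices: list[ChoiceDataset] = []
    if cfg.simulate_choices:
        bank = bank or ItemBank.kirby27()
        for i, row in enumerate(df.itertuples()):
            params = ModelParams(k=float(row.true_k), beta=float(row.true_beta))
            choices.append(
                simulate_choices(bank, params, seed=[cfg.seed, 2, i],
                                 participant_id=row.participant_id, timepoint=1)
            )
    return CohortTable(covariates=df, choices=choices, config=cfg)


def generate_panel(cohort: CohortTable, config: CohortConfig | None = None,
                   bank: ItemBank | None = None) -> CohortTable:
    """Add a second wave to a wave-1 cohort.

    The latent shock drifts down by ``time2_shock_shift`` plus individual
    noise; the change in log k is ``b_delta_shock`` (standardized) times the
    z-scored change in binarised shock plus noise; choices are re-simulated;
    exactly ``round(positive_shock_fraction * n)`` participants are flagged
    positive-shock.  Raises if the cohort already has wave-2 rows.
    """
    cfg = config or cohort.config
    cfg.validate()
    if 2 in cohort.timepoints:
        raise ValidationError("cohort already has timepoint-2 rows")
    t1 = cohort.covariates_at(1)
    n = len(t1)
    rng = np.random.default_rng([cfg.seed, 3])

    latent2 = (
        t1["true_shock_latent"].to_numpy()
        - cfg.time2_shock_shift
        + cfg.time2_shock_noise_sd * rng.standard_normal(n)
    )
    likert2 = _likert_from_latent(latent2)
    stab = cfg.emotion_stability
    factor2 = (stab * t1["true_affect_factor"].to_numpy()
               + math.sqrt(1.0 - stab * stab) * rng.standard_normal(n))
    emotions2 = _emotion_ratings(factor2, rng, cfg)

    d_shock = (encoding.binarize_income_shock(likert2)
               - encoding.binarize_income_shock(t1["income_shock_likert"].to_numpy()))
    if np.std(d_shock) == 0:
        raise ValidationError("degenerate panel: change in binarised shock is constant")
    sigma = cfg.delta_residual_sd_log_k
    c_delta = cfg.b_delta_shock * sigma / math.sqrt(1.0 - cfg.b_delta_shock**2)
    delta_log_k = (c_delta * encoding.standardize(d_shock.astype(float))
                   + sigma * rng.standard_normal(n))
    log_k2 = np.clip(t1["true_log_k"].to_numpy() + delta_log_k,
                     math.log(cfg.k_bounds[0]), math.log(cfg.k_bounds[1]))

    n_flag = int(round(cfg.positive_shock_fraction * n))
    flagged = np.zeros(n, dtype=bool)
    if n_flag:
        flagged[rng.choice(n, size=n_flag, replace=False)] = True

    t2 = t1.copy()
    t2["timepoint"] = 2
    t2["income_shock_likert"] = likert2
    for name, vals in emotions2.items():
        t2[name] = vals
    t2["true_log_k"] = log_k2
    t2["true_k"] = np.exp(log_k2)
    t2["true_shock_latent"] = latent2
    t2["true_affect_factor"] = factor2
    t2["positive_shock"] = flagged

    t2["true_beta"] = np.clip(t2["true_beta"] * cfg.time2_beta_scale, *cfg.beta_bounds)

    choices2: list[ChoiceDataset] = []
    if cfg.simulate_choices:
        bank = bank or ItemBank.kirby27()
        for i, row in enumerate(t2.itertuples()):
            params = ModelParams(k=float(row.true_k), beta=float(row.true_beta))
            choices2.append(
                simulate_choices(bank, params, seed=[cfg.seed, 4, i],
                                 participant_id=row.participant_id, timepoint=2)
            )

    covariates = pd.concat([cohort.covariates, t2], ignore_index=True)
    return CohortTable(covariates=covariates, choices=list(cohort.choices) + choices2,
                       config=cfg)


def save_cohort(table: CohortTable, outdir: str | Path) -> dict[str, Path]:
    """Write cohort.csv and choices.csv under ``outdir``; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"cohort": outdir / "cohort.csv", "choices": outdir / "choices.csv"}
    table.covariates.to_csv(paths["cohort"], index=False)
    write_choice_data(table.choices, paths["choices"])
    return paths
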