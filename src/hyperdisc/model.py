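"""Hyperbolic-discounting softmax choice model and bounded maximum likelihood.

Model
-----
The subjective value of an amount ``A`` delivered after ``D`` days is

    U(A, D) = A / (1 + k * D),

with ``k`` (1/day) the individual's temporal discount rate; the immediate
option has D = 0 and utility equal to its amount.  The probability of
choosing the immediate option is a logistic (softmax) function of the
utility difference,

    P(immediate) = 1 / (1 + exp(-beta * (U_immediate - U_delayed))),

with ``beta`` (1/currency-unit) an inverse-temperature parameter: beta = 0
gives coin-flip choices, large beta near-deterministic ones.

Note on the sign convention: higher k lowers the delayed option's utility and
therefore raises P(immediate), which is the behaviour every diagnostic and
downstream analysis here assumes.

Estimation minimises the negative log-likelihood over box-bounded (k, beta)
(defaults k in [1e-4, 0.25] — the range recoverable with the 27-item design —
and beta in [1e-3, 10]) via multi-start L-BFGS-B in (log k, log beta) with an
analytic gradient.  Fit quality is summarised by McFadden's pseudo-R^2
against a coin-flip null, 1 - NLL / (n * ln 2), and by balanced accuracy of
the implied 0.5-threshold classifier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit

from .instrument import ChoiceDataset, ItemBank, ValidationError

__all__ = [
    "DEFAULT_K_BOUNDS",
    "DEFAULT_BETA_BOUNDS",
    "PROB_FLOOR",
    "ModelParams",
    "FitConfig",
    "DiscountFit",
    "FitError",
    "HyperbolicChoiceModel",
    "discounted_utility",
    "choice_probability",
    "negative_log_likelihood",
    "pseudo_r_squared",
    "balanced_accuracy",
    "fit_participant",
    "fit_cohort",
]

DEFAULT_K_BOUNDS = (1e-4, 0.25)
DEFAULT_BETA_BOUNDS = (1e-3, 10.0)

#: Choice probabilities are clipped to [PROB_FLOOR, 1 - PROB_FLOOR] so the
#: negative log-likelihood stays finite for arbitrarily extreme parameters.
PROB_FLOOR = 1e-12
_NLL_CAP = -math.log(PROB_FLOOR)  # per-trial NLL ceiling, ~27.63 nats

LN2 = math.log(2.0)


class FitError(RuntimeError):
    """Raised when the optimizer fails at every start."""


@dataclass(frozen=True)
class ModelParams:
    """A (k, beta) parameter pair.

    k : discount rate, 1/day, >= 0.
    beta : choice sensitivity (inverse temperature), 1/currency-unit, >= 0.
    """

    k: float
    beta: float

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValidationError(f"k must be >= 0, got {self.k}")
        if self.beta < 0:
            raise ValidationError(f"beta must be >= 0, got {self.beta}")


@dataclass
class FitConfig:
    """Configuration of the bounded multi-start maximum-likelihood fit.

    The start grid is ``n_starts_k x n_starts_beta`` log-spaced points
    spanning the bounds; all starts are screened by their NLL and the best
    ``n_polish`` are refined with L-BFGS-B.  Fully deterministic.
    """

    k_bounds: tuple[float, float] = DEFAULT_K_BOUNDS
    beta_bounds: tuple[float, float] = DEFAULT_BETA_BOUNDS
    n_starts_k: int = 5
    n_starts_beta: int = 5
    n_polish: int = 3
    max_iter: int = 200

    def __post_init__(self) -> None:
        for name, (lo, hi) in (("k_bounds", self.k_bounds), ("beta_bounds", self.beta_bounds)):
            if not (0 < lo < hi):
                raise ValidationError(f"{name} must satisfy 0 < lower < upper, got ({lo}, {hi})")
        if self.n_starts_k < 2 or self.n_starts_beta < 2:
            raise ValidationError("need at least 2 starts per parameter")

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "FitConfig":
        kwargs = {}
        for key in ("k_bounds", "beta_bounds"):
            if key in mapping:
                kwargs[key] = tuple(float(v) for v in mapping[key])
        for key in ("n_starts_k", "n_starts_beta", "n_polish", "max_iter"):
            if key in mapping:
                kwargs[key] = int(mapping[key])
        return cls(**kwargs)


def discounted_utility(amount, delay, k):
    """Hyperbolic present value ``amount / (1 + k * delay)``.

    Accepts scalars or arrays; equals ``amount`` at delay 0.
    """
    amount = np.asarray(amount, dtype=float)
    delay = np.asarray(delay, dtype=float)
    k_arr = np.asarray(k, dtype=float)
    if np.any(amount <= 0):
        raise ValidationError("amount must be positive")
    if np.any(delay < 0) or np.any(k_arr < 0):
        raise ValidationError("delay and k must be non-negative")
    out = amount / (1.0 + k_arr * delay)
    return float(out) if out.ndim == 0 else out


def choice_probability(u_immediate, u_delayed, beta):
    """P(choose immediate) = logistic(beta * (U_immediate - U_delayed)).

    Numerically stable for arbitrarily large |beta * dU|.
    """
    beta_arr = np.asarray(beta, dtype=float)
    if np.any(beta_arr < 0):
        raise ValidationError("beta must be >= 0")
    x = beta_arr * (np.asarray(u_immediate, dtype=float) - np.asarray(u_delayed, dtype=float))
    out = expit(x)
    return float(out) if np.ndim(out) == 0 else out


def pseudo_r_squared(nll: float, n_trials: int) -> float:
    """McFadden pseudo-R^2 against a coin-flip null: ``1 - nll/(n ln 2)``."""
    if n_trials < 1:
        raise ValidationError("n_trials must be >= 1")
    return 1.0 - nll / (n_trials * LN2)


def balanced_accuracy(chose_immediate: Sequence[int], p_immediate: Sequence[float]) -> float:
    """Mean per-class recall of the 0.5-threshold prediction.

    Predicted choice is immediate iff p(immediate) > 0.5 (a tie at exactly
    0.5 predicts delayed, counting against the model).  If only one class was
    observed, that class's recall is returned.
    """
    y = np.asarray(chose_immediate, dtype=int)
    p = np.asarray(p_immediate, dtype=float)
    if y.shape != p.shape:
        raise ValidationError(f"length mismatch: {y.shape} choices vs {p.shape} probabilities")
    pred = (p > 0.5).astype(int)
    recalls = [float(np.mean(pred[y == c] == c)) for c in (0, 1) if np.any(y == c)]
    return float(np.mean(recalls))


def _arrays_from(dataset: ChoiceDataset, bank: ItemBank):
    """Align (immediate amount, delayed amount, delay, chose-immediate) arrays."""
    dataset.validate_against(bank)
    ids = dataset.item_ids()
    if not ids:
        raise ValidationError("empty dataset")
    imm = np.array([bank[i].immediate_amount for i in ids], dtype=float)
    dly = np.array([bank[i].delayed_amount for i in ids], dtype=float)
    days = np.array([bank[i].delay_days for i in ids], dtype=float)
    y = dataset.immediate_indicator(bank)
    return imm, dly, days, y


def _per_trial_nll(imm, dly, days, y, k, beta):
    """Per-trial clipped negative log-likelihood (vectorised over trials)."""
    u_d = dly / (1.0 + k * days)
    x = beta * (imm - u_d)
    s = np.where(y == 1, 1.0, -1.0)
    per = np.logaddexp(0.0, -s * x)  # -log p(observed)
    return np.minimum(per, _NLL_CAP)


def negative_log_likelihood(dataset: ChoiceDataset, bank: ItemBank, params: ModelParams) -> float:
    """Summed negative log-likelihood (nats) of the observed choices."""
    imm, dly, days, y = _arrays_from(dataset, bank)
    return float(_per_trial_nll(imm, dly, days, y, params.k, params.beta).sum())


@dataclass
class DiscountFit:
    """Results of a per-participant maximum-likelihood fit.

    Carries the estimates, the natural log of k, the minimised NLL and the
    two fit diagnostics; ``boundary_flag`` marks estimates pinned at a k
    bound, where the likelihood is one-sided.
    """

    params: ModelParams
    log_k: float
    nll: float
    pseudo_r2: float
    balanced_accuracy: float
    n_trials: int
    converged: bool
    n_starts: int
    boundary_flag: bool
    participant_id: str = ""
    timepoint: int = 1

    @property
    def k(self) -> float:
        return self.params.k

    @property
    def beta(self) -> float:
        return self.params.beta

    def summary(self) -> str:
        lines = [
            "Hyperbolic discounting fit",
            "==========================",
            f"participant:        {self.participant_id or '<unnamed>'} (t{self.timepoint})",
            f"trials:             {self.n_trials}",
            f"k (1/day):          {self.k:.6g}" + ("   [at bound]" if self.boundary_flag else ""),
            f"log k:              {self.log_k:.4f}",
            f"beta:               {self.beta:.4g}",
            f"NLL (nats):         {self.nll:.4f}",
            f"pseudo-R2:          {self.pseudo_r2:.4f}",
            f"balanced accuracy:  {self.balanced_accuracy:.4f}",
            f"converged:          {self.converged} ({self.n_starts} starts)",
        ]
        return "\n".join(lines)


class HyperbolicChoiceModel:
    """Hyperbolic-discounting choice model bound to one participant's data.

    Parameters
    ----------
    dataset : ChoiceDataset
        The participant's binary answers.
    bank : ItemBank
        The item bank the answers refer to.
    config : FitConfig, optional
        Bounds and multi-start settings; defaults match the 27-item design.

    Examples
    --------
    >>> bank = ItemBank.kirby27()
    >>> # dataset: a ChoiceDataset for one participant
    >>> fit = HyperbolicChoiceModel(dataset, bank).fit()   # doctest: +SKIP
    >>> print(fit.summary())                               # doctest: +SKIP
    """

    def __init__(self, dataset: ChoiceDataset, bank: ItemBank, config: FitConfig | None = None):
        self.dataset = dataset
        self.bank = bank
        self.config = config or FitConfig()
        self._imm, self._dly, self._days, self._y = _arrays_from(dataset, bank)

    @property
    def n_trials(self) -> int:
        return len(self._y)

    def nll(self, k: float, beta: float) -> float:
        """Clipped negative log-likelihood at (k, beta)."""
        return float(_per_trial_nll(self._imm, self._dly, self._days, self._y, k, beta).sum())

    def probabilities(self, k: float, beta: float) -> np.ndarray:
        """Per-trial P(immediate), in item order."""
        u_d = self._dly / (1.0 + k * self._days)
        return expit(beta * (self._imm - u_d))

    # -- optimisation internals ------------------------------------------

    def _objective(self, theta: np.ndarray):
        """NLL and gradient in (log k, log beta) coordinates."""
        k = math.exp(theta[0])
        beta = math.exp(theta[1])
        denom = 1.0 + k * self._days
        u_d = self._dly / denom
        du = self._imm - u_d
        x = beta * du
        s = np.where(self._y == 1, 1.0, -1.0)
        per = np.logaddexp(0.0, -s * x)
        capped = per > _NLL_CAP
        f = float(np.minimum(per, _NLL_CAP).sum())
        dper_dx = -s * expit(-s * x)
        dper_dx[capped] = 0.0
        dx_dk = beta * self._dly * self._days / denom**2
        g_logk = k * float(np.dot(dper_dx, dx_dk))
        g_logbeta = beta * float(np.dot(dper_dx, du))
        return f, np.array([g_logk, g_logbeta])

    def _start_grid(self):
        cfg = self.config
        ks = np.geomspace(*cfg.k_bounds, cfg.n_starts_k)
        bs = np.geomspace(*cfg.beta_bounds, cfg.n_starts_beta)
        K, B = np.meshgrid(ks, bs, indexing="ij")
        return K.ravel(), B.ravel()

    def _screen(self, K, B):
        """Vectorised NLL over the full start grid (starts x trials)."""
        u_d = self._dly[None, :] / (1.0 + K[:, None] * self._days[None, :])
        x = B[:, None] * (self._imm[None, :] - u_d)
        s = np.where(self._y == 1, 1.0, -1.0)[None, :]
        per = np.minimum(np.logaddexp(0.0, -s * x), _NLL_CAP)
        return per.sum(axis=1)

    def fit(self) -> DiscountFit:
        """Run the bounded multi-start fit and return a :class:`DiscountFit`.

        Deterministic given the data and configuration; ties between starts
        are broken by lowest NLL, then smallest k, then smallest beta.
        """
        cfg = self.config
        K, B = self._start_grid()
        screen = self._screen(K, B)
        order = np.argsort(screen, kind="stable")
        log_bounds = [
            (math.log(cfg.k_bounds[0]), math.log(cfg.k_bounds[1])),
            (math.log(cfg.beta_bounds[0]), math.log(cfg.beta_bounds[1])),
        ]

        candidates: list[tuple[float, float, float, bool]] = []
        failures: list[str] = []
        for idx in order[: max(1, cfg.n_polish)]:
            x0 = np.array([math.log(K[idx]), math.log(B[idx])])
            try:
                res = optimize.minimize(
                    self._objective,
                    x0,
                    jac=True,
                    method="L-BFGS-B",
                    bounds=log_bounds,
                    options={"maxiter": cfg.max_iter, "ftol": 1e-12, "gtol": 1e-10},
                )
            except (ValueError, FloatingPointError) as exc:  # pragma: no cover
                failures.append(f"start (k={K[idx]:.3g}, beta={B[idx]:.3g}): {exc}")
                continue
            k_hat = math.exp(res.x[0])
            beta_hat = math.exp(res.x[1])
            candidates.append((float(res.fun), k_hat, beta_hat, bool(res.success)))
        if not candidates:
            raise FitError(
                "optimization failed at every start:\n" + "\n".join(failures)
            )

        # deterministic tie-break: NLL (to 1e-9), then k, then beta
        candidates.sort(key=lambda c: (round(c[0], 9), c[1], c[2]))
        nll_best, k_best, beta_best, success = candidates[0]

        p = self.probabilities(k_best, beta_best)
        k_lo, k_hi = cfg.k_bounds
        at_bound = k_best <= k_lo * (1 + 1e-6) or k_best >= k_hi * (1 - 1e-6)
        return DiscountFit(
            params=ModelParams(k=k_best, beta=beta_best),
            log_k=math.log(k_best),
            nll=nll_best,
            pseudo_r2=pseudo_r_squared(nll_best, self.n_trials),
            balanced_accuracy=balanced_accuracy(self._y, p),
            n_trials=self.n_trials,
            converged=any(c[3] for c in candidates),
            n_starts=cfg.n_starts_k * cfg.n_starts_beta,
            boundary_flag=bool(at_bound),
            participant_id=self.dataset.participant_id,
            timepoint=self.dataset.timepoint,
        )

    def simulate(self, params: ModelParams, seed) -> ChoiceDataset:
        """Draw a synthetic dataset from this model's bank at ``params``."""
        from .recovery import simulate_choices

        return simulate_choices(self.bank, params, seed)


def fit_participant(
    dataset: ChoiceDataset, bank: ItemBank, config: FitConfig | None = None
) -> DiscountFit:
    """Convenience wrapper: ``HyperbolicChoiceModel(dataset, bank, config).fit()``."""
    return HyperbolicChoiceModel(dataset, bank, config).fit()


def fit_cohort(
    datasets: Sequence[ChoiceDataset], bank: ItemBank, config: FitConfig | None = None
) -> pd.DataFrame:
    """Fit every dataset and tabulate the results.

    Returns a DataFrame with one row per (participant, timepoint) and the
    columns of the fits.csv interface: participant_id, timepoint, k, log_k,
    beta, nll, pseudo_r2, balanced_accuracy, boundary_flag, converged.
    """
    config = config or FitConfig()
    rows = []
    for ds in datasets:
        fit = HyperbolicChoiceModel(ds, bank, config).fit()
        rows.append(
            {
                "participant_id": fit.participant_id,
                "timepoint": fit.timepoint,
                "k": fit.k,
                "log_k": fit.log_k,
                "beta": fit.beta,
                "nll": fit.nll,
                "pseudo_r2": fit.pseudo_r2,
                "balanced_accuracy": fit.balanced_accuracy,
                "boundary_flag": fit.boundary_flag,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)
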