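"""Choice model: utilities, softmax, likelihood, diagnostics, MLE."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hyperdisc import (
    ChoiceDataset,
    ChoiceItem,
    HyperbolicChoiceModel,
    ItemBank,
    ModelParams,
    ValidationError,
    balanced_accuracy,
    choice_probability,
    discounted_utility,
    fit_participant,
    negative_log_likelihood,
    pseudo_r_squared,
)
from hyperdisc.model import FitConfig
from hyperdisc.recovery import simulate_choices

LN2 = math.log(2.0)


class TestDiscountedUtility:
    @pytest.mark.parametrize(
        "amount, delay, k, expected",
        [
            (75.0, 61, 0.0, 75.0),                 # zero discounting
            (35.0, 25, 0.016, 25.0),               # indifference with the $25 option
            (75.0, 61, (75 / 55 - 1) / 61, 55.0),  # indifference with the $55 option
            (100.0, 0, 0.2, 100.0),                # no delay -> face value
        ],
    )
    def test_values(self, amount, delay, k, expected):
        assert discounted_utility(amount, delay, k) == pytest.approx(expected, abs=1e-9)

    @settings(max_examples=100, derandomize=True)
    @given(
        amount=st.floats(0.5, 1e4),
        delay=st.floats(1.0, 365.0),
        k1=st.floats(1e-5, 0.5),
        k2=st.floats(1e-5, 0.5),
    )
    def test_strictly_decreasing_in_k_and_delay(self, amount, delay, k1, k2):
        lo, hi = sorted((k1, k2))
        if hi > lo:
            assert discounted_utility(amount, delay, hi) < discounted_utility(amount, delay, lo)
        assert discounted_utility(amount, delay * 2, hi) < discounted_utility(amount, delay, hi)

    def test_rejects_negative_inputs(self):
        with pytest.raises(ValidationError):
            discounted_utility(-1.0, 10, 0.1)
        with pytest.raises(ValidationError):
            discounted_utility(10.0, -1, 0.1)
        with pytest.raises(ValidationError):
            discounted_utility(10.0, 1, -0.1)


class TestChoiceProbability:
    def test_indifference_and_zero_sensitivity(self):
        assert choice_probability(40.0, 40.0, 3.0) == pytest.approx(0.5)
        assert choice_probability(10.0, 90.0, 0.0) == pytest.approx(0.5)

    def test_logistic_value(self):
        # beta (u_i - u_d) = 0.2 * (55 - 60) = -1
        assert choice_probability(55.0, 60.0, 0.2) == pytest.approx(1 / (1 + math.e), rel=1e-9)

    def test_numerically_stable_at_extreme_arguments(self):
        with np.errstate(all="raise"):
            hi = choice_probability(4000.0, 0.5, 10.0)
            lo = choice_probability(0.5, 4000.0, 10.0)
        assert hi == pytest.approx(1.0)
        assert lo == pytest.approx(0.0)

    @settings(max_examples=100, derandomize=True)
    @given(
        u1=st.floats(0.1, 100.0),
        u2=st.floats(0.1, 100.0),
        beta=st.floats(0.0, 20.0),
    )
    def test_complement(self, u1, u2, beta):
        assert choice_probability(u1, u2, beta) + choice_probability(u2, u1, beta) == pytest.approx(1.0)

    def test_negative_beta_rejected(self):
        with pytest.raises(ValidationError):
            choice_probability(1.0, 2.0, -0.5)


def _dataset_with_probs(probs):
    """Items engineered so each observed (delayed) choice has the target
    probability at k = 0, beta = 1: delayed amount = immediate - ln(p/(1-p))."""
    items, choices = [], {}
    for i, p in enumerate(probs, start=1):
        gap = math.log(p / (1 - p))  # u_i - u_d for P(delayed) = p is -gap
        items.append(ChoiceItem(i, 50.0, 50.0 + gap, 1))
        choices[i] = "delayed"
    return ItemBank(tuple(items)), ChoiceDataset("h", 1, choices)


class TestNegativeLogLikelihood:
    def test_single_coin_flip_trial(self):
        bank, ds = _dataset_with_probs([0.5 + 1e-15])
        # beta = 0 makes every probability exactly 0.5
        assert negative_log_likelihood(ds, bank, ModelParams(k=0.0, beta=0.0)) == pytest.approx(LN2)

    def test_hand_computed_three_trials(self):
        bank, ds = _dataset_with_probs([0.9, 0.8, 0.6])
        nll = negative_log_likelihood(ds, bank, ModelParams(k=0.0, beta=1.0))
        assert nll == pytest.approx(-(math.log(0.9) + math.log(0.8) + math.log(0.6)), rel=1e-9)
        assert nll == pytest.approx(0.839331, abs=1e-5)

    def test_near_perfect_prediction_approaches_zero(self):
        bank, ds = _dataset_with_probs([0.9, 0.8])
        assert negative_log_likelihood(ds, bank, ModelParams(k=0.0, beta=500.0)) < 1e-6

    def test_clipping_keeps_nll_finite(self):
        bank, _ = _dataset_with_probs([0.9])
        ds = ChoiceDataset("h", 1, {1: "immediate"})  # wrong side, huge beta
        nll = negative_log_likelihood(ds, bank, ModelParams(k=0.0, beta=1e6))
        assert np.isfinite(nll)
        assert nll == pytest.approx(-math.log(1e-12), rel=1e-3)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValidationError):
            ChoiceDataset("p", 1, {})


class TestPseudoR2:
    @pytest.mark.parametrize(
        "nll, n, expected",
        [(0.0, 27, 1.0), (27 * LN2, 27, 0.0), (0.31 * 27 * LN2, 27, 0.69)],
    )
    def test_values(self, nll, n, expected):
        assert pseudo_r_squared(nll, n) == pytest.approx(expected)

    def test_invariant_to_trial_order(self, bank):
        ds = simulate_choices(bank, ModelParams(k=0.01, beta=1.0), seed=3)
        params = ModelParams(k=0.02, beta=0.7)
        nll = negative_log_likelihood(ds, bank, params)
        shuffled = ChoiceDataset(ds.participant_id, 1, dict(reversed(list(ds.choices.items()))))
        assert negative_log_likelihood(shuffled, bank, params) == pytest.approx(nll)


class TestBalancedAccuracy:
    def test_perfect_and_inverted(self):
        y = [1, 1, 0, 0]
        assert balanced_accuracy(y, [0.9, 0.8, 0.1, 0.2]) == 1.0
        assert balanced_accuracy(y, [0.1, 0.2, 0.9, 0.8]) == 0.0

    def test_mixed_class_recalls(self):
        # 10 immediate (8 predicted right), 17 delayed (12 right)
        y = [1] * 10 + [0] * 17
        p = [0.9] * 8 + [0.1] * 2 + [0.1] * 12 + [0.9] * 5
        assert balanced_accuracy(y, p) == pytest.approx((0.8 + 12 / 17) / 2)
        assert balanced_accuracy(y, p) == pytest.approx(0.752941, abs=1e-5)

    def test_single_observed_class_uses_its_recall(self):
        assert balanced_accuracy([1, 1, 1], [0.9, 0.9, 0.2]) == pytest.approx(2 / 3)

    def test_tie_counts_against_the_model(self):
        # p exactly 0.5 predicts delayed
        assert balanced_accuracy([1], [0.5]) == 0.0
        assert balanced_accuracy([0], [0.5]) == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            balanced_accuracy([1, 0], [0.5])


class TestFit:
    def test_all_immediate_chooser_hits_upper_bound(self, bank):
        ds = ChoiceDataset("imp", 1, {i: "immediate" for i in bank.item_ids})
        fit = fit_participant(ds, bank)
        assert fit.k == pytest.approx(0.25, rel=1e-5)
        assert fit.boundary_flag

    def test_all_delayed_chooser_hits_lower_bound(self, bank):
        ds = ChoiceDataset("pat", 1, {i: "delayed" for i in bank.item_ids})
        fit = fit_participant(ds, bank)
        assert fit.k == pytest.approx(1e-4, rel=1e-3)
        assert fit.boundary_flag

    def test_deterministic(self, bank):
        ds = simulate_choices(bank, ModelParams(k=0.01, beta=1.0), seed=9)
        a, b = fit_participant(ds, bank), fit_participant(ds, bank)
        assert (a.k, a.beta, a.nll) == (b.k, b.beta, b.nll)

    def test_diagnostics_consistent(self, bank, simulated_datasets):
        for _, ds in simulated_datasets[:5]:
            fit = fit_participant(ds, bank)
            assert fit.nll >= 0
            assert fit.pseudo_r2 == pytest.approx(1 - fit.nll / (fit.n_trials * LN2))
            assert 0.0 <= fit.balanced_accuracy <= 1.0
            lo, hi = FitConfig().k_bounds
            assert lo <= fit.k <= hi

    def test_median_recovery_within_factor_two(self, bank):
        true = ModelParams(k=0.0137, beta=1.0)
        ks = [
            fit_participant(simulate_choices(bank, true, seed=100 + i), bank).k
            for i in range(40)
        ]
        med = float(np.median(ks))
        assert 0.0137 / 2 < med < 0.0137 * 2

    def test_beats_local_refinement_grid(self, bank, simulated_datasets):
        """Fitted NLL is never worse than a 60x30 log-grid scan (coarse
        independent check; the 1000x100 oracle lives in the acceptance suite)."""
        ks = np.geomspace(1e-4, 0.25, 60)
        bs = np.geomspace(1e-3, 10.0, 30)
        for _, ds in simulated_datasets[:8]:
            model = HyperbolicChoiceModel(ds, bank)
            grid_best = min(model.nll(k, b) for k in ks for b in bs)
            assert model.fit().nll <= grid_best + 1e-6

    def test_summary_renders(self, bank):
        ds = simulate_choices(bank, ModelParams(k=0.01, beta=1.0), seed=2)
        text = fit_participant(ds, bank).summary()
        assert "pseudo-R2" in text and "balanced accuracy" in text
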