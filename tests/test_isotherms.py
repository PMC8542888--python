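"""Isotherm evaluation, eligibility screening and fitting."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sorbfate.batch import compute_points
from sorbfate.exceptions import ValidationError
from sorbfate.isotherms import (
    Isotherm,
    IsothermModel,
    check_eligibility,
    eval_isotherm,
    fit_all_models,
    fit_isotherm,
)
from sorbfate.synth import BatchTruth, generate_batch

CE_GRID = np.geomspace(0.05, 0.8, 8)

TRUTHS = {
    "linear": {"K": 20000.0},
    "freundlich": {"K_F": 3.0, "one_over_n": 1.2},
    "langmuir": {"q_max": 800.0, "b": 2.0},
    "bet": {"q_m": 500.0, "K_B": 50.0, "c_s": 1.5},
}


def noisy_q(model, ce, cv, seed):
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(cv**2))
    return model.predict(ce) * np.exp(rng.normal(-0.5 * sigma**2, sigma, np.size(ce)))


class TestEvaluation:
    def test_langmuir_henry_limit(self):
        model = IsothermModel("langmuir", {"q_max": 1000.0, "b": 0.01})
        q = eval_isotherm(model, 0.001)
        assert q == pytest.approx(1000.0 * 0.01 * 0.001, rel=1e-4)

    @given(ce=st.floats(1e-6, 10.0))
    def test_freundlich_with_unit_exponent_equals_linear(self, ce):
        freundlich = IsothermModel("freundlich", {"K_F": 123.0, "one_over_n": 1.0})
        linear = IsothermModel("linear", {"K": 123.0})
        assert eval_isotherm(freundlich, ce) == pytest.approx(eval_isotherm(linear, ce))

    def test_bet_diverges_towards_saturation(self):
        model = IsothermModel("bet", {"q_m": 500.0, "K_B": 50.0, "c_s": 1.0})
        ce = np.array([0.9, 0.99, 0.999, 0.9999])
        q = eval_isotherm(model, ce)
        assert np.all(np.diff(q) > 0)
        assert q[-1] > 1e5
        with pytest.raises(ValidationError):
            eval_isotherm(model, 1.0)

    @pytest.mark.parametrize("kind", list(TRUTHS))
    def test_origin_and_monotonicity(self, kind):
        model = IsothermModel(kind, TRUTHS[kind])
        assert eval_isotherm(model, 0.0) == 0.0
        ce = np.linspace(0.0, 0.9, 50)
        assert np.all(np.diff(eval_isotherm(model, ce)) > 0)


class TestEligibility:
    def test_six_points_spanning_12x(self):
        ce = np.linspace(0.05, 0.6, 6)
        ok, reason = check_eligibility(np.column_stack([ce, ce * 100]))
        assert ok
        assert "eligible" in reason

    def test_four_points_rejected(self):
        ce = np.geomspace(0.01, 1.0, 4)
        ok, reason = check_eligibility(np.column_stack([ce, ce * 100]))
        assert not ok
        assert "fewer than five" in reason

    def test_narrow_span_rejected(self):
        ce = np.linspace(0.10, 0.45, 5)
        ok, reason = check_eligibility(np.column_stack([ce, ce * 100]))
        assert not ok
        assert "span 4.5" in reason

    def test_zero_ce_points_excluded_and_noted(self):
        ce = np.array([0.0, 0.05, 0.1, 0.2, 0.4, 0.6])
        ok, reason = check_eligibility(np.column_stack([ce, ce * 100]))
        assert ok
        assert "complete-removal" in reason

    def test_fit_refuses_ineligible_unless_forced(self):
        ce = np.geomspace(0.1, 0.45, 5)
        model = Isotherm(ce, 100 * ce, kind="linear")
        with pytest.raises(ValidationError, match="not eligible"):
            model.fit()
        result = model.fit(force=True)
        assert not result.eligible


class TestFitting:
    @pytest.mark.parametrize("kind", list(TRUTHS))
    def test_noiseless_recovery_within_0p1_percent(self, kind):
        truth = IsothermModel(kind, TRUTHS[kind])
        result = Isotherm(CE_GRID, truth.predict(CE_GRID), kind=kind).fit()
        for name, value in TRUTHS[kind].items():
            assert result.params[name] == pytest.approx(value, rel=1e-3)
        assert result.rsquared == pytest.approx(1.0, abs=1e-6)

    def test_multilayer_flag_for_freundlich_exponent_above_one(self):
        truth = IsothermModel("freundlich", {"K_F": 3.0, "one_over_n": 1.2})
        result = Isotherm(CE_GRID, truth.predict(CE_GRID), kind="freundlich").fit()
        assert result.multilayer_flag
        below = IsothermModel("freundlich", {"K_F": 3.0, "one_over_n": 0.8})
        result = Isotherm(CE_GRID, below.predict(CE_GRID), kind="freundlich").fit()
        assert not result.multilayer_flag

    def test_noiseless_linear_r_squared_is_one(self):
        result = Isotherm(CE_GRID, 20000.0 * CE_GRID, kind="linear").fit()
        assert result.params["K"] == pytest.approx(20000.0)
        assert result.rsquared == pytest.approx(1.0)

    def test_bet_with_fixed_saturation_concentration(self):
        truth = IsothermModel("bet", TRUTHS["bet"])
        result = Isotherm(CE_GRID, truth.predict(CE_GRID), kind="bet", c_s=1.5).fit()
        assert result.params["q_m"] == pytest.approx(500.0, rel=1e-3)
        assert result.params["c_s"] == 1.5

    def test_langmuir_noisy_recovery_coverage(self):
        """Triplicate design, 5% response noise: both parameters within 20%
        of truth in at least 90% of 50 seeded replicates."""
        truth = IsothermModel("langmuir", TRUTHS["langmuir"])
        ce = np.repeat(CE_GRID, 3)
        hits = 0
        for seed in range(50):
            result = Isotherm(ce, noisy_q(truth, ce, 0.05, seed), kind="langmuir").fit()
            hits += (
                abs(result.params["q_max"] - 800.0) / 800.0 <= 0.2
                and abs(result.params["b"] - 2.0) / 2.0 <= 0.2
            )
        assert hits >= 45

    def test_freundlich_on_linear_truth_recovers_unit_exponent(self):
        truth = IsothermModel("linear", {"K": 20000.0})
        ce = np.repeat(CE_GRID, 3)
        result = Isotherm(ce, noisy_q(truth, ce, 0.05, seed=7), kind="freundlich").fit()
        assert abs(result.params["one_over_n"] - 1.0) <= 3.0 * result.bse["one_over_n"]

    def test_langmuir_rss_beats_linear_on_langmuir_truth(self):
        truth = IsothermModel("langmuir", TRUTHS["langmuir"])
        for seed in range(10):
            q = noisy_q(truth, CE_GRID, 0.02, seed)
            langmuir = Isotherm(CE_GRID, q, kind="langmuir").fit()
            linear = Isotherm(CE_GRID, q, kind="linear").fit()
            assert langmuir.rss <= linear.rss + 1e-9

    def test_model_ranking_reports_tie_sets(self):
        truth = IsothermModel("langmuir", TRUTHS["langmuir"])
        table, ties = fit_all_models(
            np.column_stack([CE_GRID, noisy_q(truth, CE_GRID, 0.02, seed=3)])
        )
        assert "langmuir" in table.index
        assert ties  # at least one model in the best set
        best = table["aicc"].min()
        assert all(table.loc[kind, "aicc"] <= best + 2.0 for kind in ties)

    def test_generator_loop_closure(self):
        """Noiseless batch generation followed by a fit recovers the truth."""
        truth = BatchTruth(
            isotherm=IsothermModel("freundlich", {"K_F": 3000.0, "one_over_n": 1.2}),
            noise_cv=0.0,
            replicates=1,
        )
        points = compute_points(generate_batch(truth))
        result = fit_isotherm(points, "freundlich")
        assert result.params["K_F"] == pytest.approx(3000.0, rel=1e-6)
        assert result.params["one_over_n"] == pytest.approx(1.2, rel=1e-6)
        assert result.multilayer_flag

    def test_summary_mentions_parameters(self):
        result = Isotherm(CE_GRID, 20000.0 * CE_GRID, kind="linear").fit()
        text = result.summary()
        assert "Linear isotherm fit" in text and "K" in text
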