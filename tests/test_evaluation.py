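"""Distance metric, Welch test, threshold flip counting, model ranking."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qtddi import fixtures
from qtddi.evaluation import (
    ThresholdPolicy,
    best_model,
    count_flips,
    distance,
    distance_from_deltas,
    evaluate_table,
    welch_t,
)
from qtddi.interaction import InteractionModel


def _distance_bruteforce(obs, pred):
    """Independent re-derivation: build the three delta-terms one by one."""
    d_t_obs = obs[1] - obs[0]
    d_ti_obs = obs[2] - obs[0]
    d_t_pred = pred[1] - pred[0]
    d_ti_pred = pred[2] - pred[0]
    terms = [
        d_t_pred - d_t_obs,
        d_ti_pred - d_ti_obs,
        (d_ti_pred - d_t_pred) - (d_ti_obs - d_t_obs),
    ]
    return math.sqrt(sum(x * x for x in terms))


triplets = st.tuples(
    st.floats(min_value=-500, max_value=500),
    st.floats(min_value=-500, max_value=500),
    st.floats(min_value=-500, max_value=500),
)


class TestDistance:
    def test_perfect_prediction_is_zero(self):
        assert distance((400, 410, 430), (400, 410, 430)) == 0.0
        assert distance((400, 410, 430), (350, 360, 380)) == 0.0  # same deltas

    @pytest.mark.parametrize(
        "obs, pred, printed",
        [
            ((408, 416, 490), (394.5, 395, 439), 48.61),      # ketoconazole, sum
            ((381, 387, 386), (392.0, 394.5, 396.6), 4.69),   # paroxetine, sum
            ((409, 410, 430), (395.5, 401.4, 404.4), 21.43),  # clarithromycin, sum
            ((394, 408, 428), (397.5, 403.7, 420.1), 14.27),  # erythromycin, sum
            ((376, 390, 417), (430.5, 438, 452.2), 24.05),    # itraconazole, sum
        ],
    )
    def test_published_worked_examples(self, obs, pred, printed):
        assert distance(obs, pred) == pytest.approx(printed, abs=0.005)

    @settings(derandomize=True, max_examples=300, deadline=None)
    @given(triplets, triplets)
    def test_matches_bruteforce(self, obs, pred):
        assert distance(obs, pred) == pytest.approx(_distance_bruteforce(obs, pred), abs=1e-12)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(triplets, triplets, st.floats(min_value=-100, max_value=100))
    def test_invariant_to_constant_shift(self, obs, pred, c):
        shifted_obs = tuple(v + c for v in obs)
        shifted_pred = tuple(v + c for v in pred)
        assert distance(shifted_obs, shifted_pred) == pytest.approx(
            distance(obs, pred), abs=1e-7
        )

    def test_delta_form_consistent(self):
        obs, pred = (408, 416, 490), (394.5, 395, 439)
        assert distance_from_deltas(8, 82, 0.5, 44.5) == pytest.approx(
            distance(obs, pred), abs=1e-12
        )

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            distance((np.nan, 1, 2), (0, 1, 2))


class TestEvaluateTable:
    def test_recomputed_distances_match_print_where_consistent(self):
        res = evaluate_table(fixtures.table2()).set_index("study")
        # the five studies whose printed sum-model distances are exactly
        # reproducible from the rounded table values
        for study, printed in [
            ("paroxetine", 4.69),
            ("ketoconazole", 48.61),
            ("clarithromycin", 21.43),
            ("erythromycin_cr19", 14.27),
            ("itraconazole", 24.05),
        ]:
            assert res.loc[study, "D_sum"] == pytest.approx(printed, abs=0.005)
        # residual-rounding cases stay within 0.2 %
        assert res.loc["ketoconazole", "D_bliss"] == pytest.approx(64.03, rel=0.002)
        assert res.loc["ketoconazole", "D_loewe"] == pytest.approx(70.14, rel=0.002)
        assert res.loc["erythromycin_cr19", "D_bliss"] == pytest.approx(19.46, rel=0.002)

    def test_delta_only_study_uses_reported_changes(self):
        res = evaluate_table(fixtures.table2()).set_index("study")
        # observed deltas 8/39, predicted sum deltas 5.7/25.4
        expect = distance_from_deltas(8.0, 39.0, 398.5 - 392.8, 418.2 - 392.8)
        assert res.loc["erythromycin_cr15", "D_sum"] == pytest.approx(expect, abs=1e-9)


class TestWelch:
    def test_identical_lists(self):
        t, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_shifted_lists_significant(self):
        t, p = welch_t([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
        # closed form: t = -10 / sqrt(1/3 + 1/3), df = 4
        expect_t = -10.0 / math.sqrt(2.0 / 3.0)
        assert t == pytest.approx(expect_t, rel=1e-9)
        assert p < 0.01

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            welch_t([0.0, 0.0], [0.0, 0.0])

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])


class TestFlips:
    def test_all_same_side_is_zero(self):
        df = pd.DataFrame({"sum": [3.0] * 5, "bliss": [3.0] * 5, "loewe": [3.0] * 5})
        assert count_flips(df) == 0.0

    def test_straddling_subject_is_a_case(self):
        df = pd.DataFrame({"sum": [5.1], "bliss": [4.9], "loewe": [5.0]})
        assert count_flips(df) == 100.0

    def test_exact_threshold_on_both_sides(self):
        # min == threshold means every model reaches it: not a flip
        df = pd.DataFrame({"sum": [5.0], "bliss": [5.0], "loewe": [5.0]})
        assert count_flips(df) == 0.0

    def test_two_of_ten(self):
        rng = np.random.default_rng(0)
        below = rng.uniform(0, 4, size=(8, 3))
        strad = np.array([[4.9, 5.1, 5.0], [2.0, 7.0, 4.0]])
        df = pd.DataFrame(np.vstack([below, strad]), columns=["sum", "bliss", "loewe"])
        assert count_flips(df) == 20.0

    def test_invariant_to_ordering_and_duplication(self):
        df = pd.DataFrame({"sum": [6.0, 1.0], "bliss": [4.0, 1.0], "loewe": [5.5, 2.0]})
        assert count_flips(df) == count_flips(df.iloc[::-1])
        doubled = pd.concat([df, df], ignore_index=True)
        assert count_flips(doubled) == count_flips(df)

    def test_missing_values_rejected(self):
        df = pd.DataFrame({"sum": [1.0, np.nan], "bliss": [1.0, 2.0]})
        with pytest.raises(ValueError):
            count_flips(df)

    def test_threshold_policy_validation(self):
        with pytest.raises(ValueError):
            ThresholdPolicy(0.0)


class TestBestModel:
    def test_ranking(self):
        order = best_model({"sum": 1.0, "bliss": 2.0, "loewe": 3.0})
        assert order[0] is InteractionModel.SUM

    def test_tie_break_fixed_order(self):
        order = best_model({"loewe": 1.0, "bliss": 1.0, "sum": 1.0})
        assert order == [InteractionModel.SUM, InteractionModel.BLISS, InteractionModel.LOEWE]

    def test_single_model(self):
        assert best_model({InteractionModel.LOEWE: 2.0}) == [InteractionModel.LOEWE]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            best_model({})
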