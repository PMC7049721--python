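"""Property profiling, criteria inference and the retain-rate machinery."""

import math

import numpy as np
import pytest

from paretarget.duplex import GAP, GU, MATCH, MISMATCH, TargetingCriteria, passes
from paretarget.inference import (
    SweepRow,
    infer_criteria,
    position_profile,
    retain_sweep,
    se_ppv_ratio,
    select_retain,
    sweep_to_table,
)
from paretarget.seqio import ValidatedInteraction

from conftest import make_duplex, random_population


class TestPositionProfile:
    def test_all_perfect_gives_zero_proportions(self):
        duplexes = [make_duplex([MATCH] * 21) for _ in range(10)]
        profile = position_profile(duplexes)
        for p in range(1, 22):
            for prop in (MISMATCH, GU, GAP):
                assert profile.proportion(prop, p) == 0.0

    def test_single_mismatch_gives_quarter_proportion(self):
        states = [MATCH] * 21
        states[4] = MISMATCH
        duplexes = [make_duplex([MATCH] * 21) for _ in range(3)]
        duplexes.append(make_duplex(states))
        assert position_profile(duplexes).proportion(MISMATCH, 5) == 0.25

    def test_matches_hand_tabulation_and_proportions_sum_to_one(self, rng):
        duplexes = random_population(rng, 40)
        profile = position_profile(duplexes)
        for p in range(1, 22):
            # independent tabulation straight off the state tuples
            for prop in (MISMATCH, GU, GAP):
                expected = sum(d.states[p - 1] == prop for d in duplexes)
                assert profile.count(prop, p) == expected
            total = sum(
                profile.proportion(prop, p)
                for prop in (MISMATCH, GU, GAP, MATCH)
            )
            assert total == pytest.approx(1.0)

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            position_profile([])


class TestInferCriteria:
    def test_retain_one_passes_every_duplex(self, rng):
        duplexes = random_population(rng, 60)
        criteria = infer_criteria(duplexes, 1.0)
        assert all(passes(d, criteria) for d in duplexes)

    def test_degenerate_perfect_population(self):
        duplexes = [make_duplex([MATCH] * 21, mfe=1.0) for _ in range(100)]
        criteria = infer_criteria(duplexes, 0.85)
        assert criteria.max_mm == 0
        assert criteria.max_gu == 0
        assert criteria.max_score == 0.0
        assert criteria.mfe_ratio_cutoff == 1.0
        assert criteria.allow_mm_pos10 is False
        assert criteria.allow_mm_pos11 is False

    def test_score_cap_is_retained_quantile_rounded_up(self, rng):
        # scores constructed explicitly: 85th percentile (type-1) of the
        # planted score multiset is 4.0 -> cap 4.0 after rounding
        duplexes = []
        scores = [0.0] * 10 + [2.0] * 40 + [3.5] * 30 + [4.0] * 5 + [6.0] * 15
        for s in scores:
            states = [MATCH] * 21
            budget = s
            p = 21
            while budget >= 1.0 and p > 13:
                states[p - 1] = MISMATCH
                budget -= 1.0
                p -= 1
            if budget == 0.5:
                states[13] = GU
            duplexes.append(make_duplex(states, mfe=0.9, rng=rng))
        assert [d.score for d in duplexes] == scores
        criteria = infer_criteria(duplexes, 0.85)
        sorted_scores = sorted(scores)
        expected = sorted_scores[math.ceil(0.85 * len(scores)) - 1]
        assert criteria.max_score == expected == 4.0

    def test_retention_contract_on_random_populations(self, rng):
        for _ in range(40):
            duplexes = random_population(rng, int(rng.integers(5, 80)))
            for r in (0.5, 0.7, 0.85, 1.0):
                criteria = infer_criteria(duplexes, r)
                kept = sum(passes(d, criteria) for d in duplexes)
                assert kept / len(duplexes) >= r - 1e-9

    def test_monotone_pass_sets_across_retain_rates(self, rng):
        for _ in range(20):
            duplexes = random_population(rng, int(rng.integers(10, 60)))
            previous = None
            for r in [round(0.5 + 0.05 * i, 2) for i in range(11)]:
                criteria = infer_criteria(duplexes, r)
                passed = {i for i, d in enumerate(duplexes) if passes(d, criteria)}
                if previous is not None:
                    assert previous <= passed
                previous = passed

    def test_order_invariance(self, rng):
        duplexes = random_population(rng, 50)
        shuffled = [duplexes[i] for i in rng.permutation(50)]
        assert infer_criteria(duplexes, 0.85) == infer_criteria(shuffled, 0.85)

    def test_allowances_come_from_retained_subpopulation(self):
        # one terrible outlier with a position-10 mismatch must not open
        # the allowance at moderate retain rates
        good = [make_duplex([MATCH] * 21, mfe=1.0) for _ in range(19)]
        bad_states = [MISMATCH] * 21
        outlier = make_duplex(bad_states, mfe=0.1)
        criteria = infer_criteria(good + [outlier], 0.85)
        assert criteria.allow_mm_pos10 is False

    def test_invalid_retain_rate_rejected(self, rng):
        duplexes = random_population(rng, 5)
        for r in (0.0, -0.1, 1.01):
            with pytest.raises(ValueError):
                infer_criteria(duplexes, r)
        with pytest.raises(ValueError):
            infer_criteria([], 0.85)


def _row(r, se, ppv):
    return SweepRow(r, 0, 0, 0, se, ppv)


class TestSePpvRatio:
    def test_worked_example_rounds_to_seven_point_one(self):
        ratio = se_ppv_ratio(_row(0.75, 75.2, 95.1), _row(0.80, 83.7, 93.9))
        assert round(ratio, 1) == 7.1

    def test_no_precision_loss_is_infinite(self):
        assert se_ppv_ratio(_row(0.5, 50.0, 90.0), _row(0.55, 51.0, 90.3)) == math.inf

    def test_plain_arithmetic(self):
        assert se_ppv_ratio(_row(0.5, 50.0, 92.0), _row(0.55, 51.0, 90.0)) == 0.5


class TestSelectRetain:
    def test_picks_lower_endpoint_of_first_ratio_below_one(self):
        rows = [
            _row(0.75, 75.2, 95.1),
            _row(0.80, 83.7, 93.9),   # ratio 7.1
            _row(0.85, 86.8, 93.3),   # ratio ~5.2
            _row(0.90, 87.0, 92.0),   # ratio ~0.15 < 1
            _row(0.95, 88.0, 91.0),
        ]
        assert select_retain(rows) == 0.85

    def test_all_ratios_at_least_one_falls_back_to_last(self):
        rows = [_row(0.9, 80.0, 90.0), _row(0.95, 85.0, 90.0), _row(1.0, 90.0, 89.0)]
        assert select_retain(rows) == 1.0

    def test_first_increment_below_one_selects_grid_start(self):
        rows = [_row(0.50, 80.0, 90.0), _row(0.55, 80.1, 85.0)]
        assert select_retain(rows) == 0.50


class TestRetainSweep:
    def _validated_from(self, duplexes):
        return [
            ValidatedInteraction(
                mirna_id=d.mirna.name,
                mirna_sequence=d.mirna.sequence,
                transcript_id=d.transcript_id,
                cleavage_position=d.cleavage_position,
            )
            for d in duplexes
        ]

    def test_grid_has_eleven_rows(self, rng):
        duplexes = random_population(rng, 30)
        validated = self._validated_from(duplexes[:20])
        sweep = retain_sweep(duplexes, validated)
        assert len(sweep) == 11
        assert sweep[0].retain_rate == 0.50
        assert sweep[-1].retain_rate == 1.00

    def test_captured_counts_non_decreasing(self, rng):
        duplexes = random_population(rng, 60)
        validated = self._validated_from(duplexes[::2])
        sweep = retain_sweep(duplexes, validated)
        captured = [row.n_captured for row in sweep]
        assert captured == sorted(captured)

    def test_final_row_captures_everything(self, rng):
        duplexes = random_population(rng, 25)
        validated = self._validated_from(duplexes)
        sweep = retain_sweep(duplexes, validated)
        assert sweep[-1].n_captured == len({d.key() for d in duplexes})
        assert sweep[-1].sensitivity == pytest.approx(100.0)

    def test_table_includes_ratio_column(self, rng):
        duplexes = random_population(rng, 20)
        table = sweep_to_table(retain_sweep(duplexes, self._validated_from(duplexes)))
        assert list(table.columns) == [
            "retain_rate", "captured", "V", "NV", "Se", "PPV", "se_ppv_ratio",
        ]
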