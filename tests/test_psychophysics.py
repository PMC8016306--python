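"""Same-different design, differencing-rule d', and the simulated observer."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tactillusion.psychophysics import (
    StimulusPair,
    TrialRecord,
    condition_report,
    dprime_differencing,
    dprime_from_trials,
    enumerate_pairs,
    forward_differencing,
    percent_correct,
    simulate_observer,
)


class TestDesign:
    def test_three_stimuli_give_nine_ordered_pairs(self):
        pairs = enumerate_pairs(["a", "b", "c"])
        assert len(pairs) == 9
        assert sum(p.is_same for p in pairs) == 3
        assert len(set((p.first, p.second) for p in pairs)) == 9

    @pytest.mark.parametrize("n,expected", [(1, 1), (2, 4), (4, 16)])
    def test_pair_count_is_n_squared(self, n, expected):
        assert len(enumerate_pairs([str(i) for i in range(n)])) == expected

    def test_empty_stimulus_list_rejected(self):
        with pytest.raises(ValueError):
            enumerate_pairs([])

    def test_correctness_rule(self):
        same = StimulusPair("a", "a")
        diff = StimulusPair("a", "b")
        assert TrialRecord.from_response(same, "c", "same").correct
        assert not TrialRecord.from_response(same, "c", "different").correct
        assert TrialRecord.from_response(diff, "c", "different").correct
        with pytest.raises(ValueError):
            TrialRecord.from_response(same, "c", "maybe")


class TestPercentCorrect:
    def test_all_correct_block(self):
        trials = [TrialRecord.from_response(StimulusPair("a", "b"), "c", "different")
                  for _ in range(10)]
        pc, flag = percent_correct(trials)
        assert pc == 100.0 and flag

    def test_threshold_flag_at_75(self):
        diff = StimulusPair("a", "b")
        trials = [TrialRecord.from_response(diff, "c", "different")] * 3 + \
                 [TrialRecord.from_response(diff, "c", "same")] * 1
        pc, flag = percent_correct(trials)
        assert pc == 75.0 and flag

    def test_coin_flip_approaches_chance(self):
        rng = np.random.default_rng(0)
        pairs = enumerate_pairs(["a", "b", "c"])
        trials = []
        for _ in range(2000):
            for p in pairs:
                resp = "different" if rng.random() < 0.5 else "same"
                trials.append(TrialRecord.from_response(p, "c", resp))
        pc, flag = percent_correct(trials)
        assert pc == pytest.approx(50.0, abs=1.5)
        assert not flag

    def test_no_trials_rejected(self):
        with pytest.raises(ValueError):
            percent_correct([], condition="missing")


class TestDprime:
    def test_chance_performance_gives_zero(self):
        for rate in (0.2, 0.5, 0.8):
            assert dprime_differencing(rate, rate).dprime == 0.0

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.floats(0.05, 6.0), st.floats(0.2, 4.0))
    def test_forward_inverse_round_trip(self, dprime, criterion):
        H, F = forward_differencing(dprime, criterion)
        if not (1e-12 < F < 1 - 1e-12 and H < 1 - 1e-12):
            return  # saturated rates carry no information
        res = dprime_differencing(H, F)
        assert res.dprime == pytest.approx(dprime, abs=1e-6)
        assert res.criterion == pytest.approx(criterion, abs=1e-6)

    def test_monotone_in_hit_rate(self):
        d = [dprime_differencing(h, 0.2).dprime for h in (0.3, 0.5, 0.7, 0.9)]
        assert all(b > a for a, b in zip(d, d[1:]))

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            dprime_differencing(1.0, 0.2)
        with pytest.raises(ValueError):
            dprime_differencing(0.5, 0.0)


class TestObserver:
    def test_zero_sensitivity_matches_rates(self):
        pairs = enumerate_pairs(["a", "b", "c"])
        trials = simulate_observer(0.0, 1.5, pairs, n_trials=3000, seed=0)
        res = dprime_from_trials(trials)
        assert abs(res.hit_rate - res.false_alarm_rate) < 0.02

    def test_infinite_criterion_means_all_same(self):
        pairs = enumerate_pairs(["a", "b"])
        trials = simulate_observer(2.0, 50.0, pairs, n_trials=50, seed=1)
        assert all(t.response == "same" for t in trials)

    def test_high_sensitivity_beats_threshold(self):
        pairs = enumerate_pairs(["a", "b", "c"])
        trials = simulate_observer(3.5, 1.5, pairs, n_trials=500, seed=2)
        pc, flag = percent_correct(trials)
        assert flag and pc > 75.0

    def test_seed_reproducibility(self):
        pairs = enumerate_pairs(["a", "b"])
        t1 = simulate_observer(1.0, 1.0, pairs, n_trials=20, seed=9)
        t2 = simulate_observer(1.0, 1.0, pairs, n_trials=20, seed=9)
        assert [t.response for t in t1] == [t.response for t in t2]

    def test_negative_dprime_rejected(self):
        with pytest.raises(ValueError):
            simulate_observer(-0.1, 1.0, enumerate_pairs(["a"]), 1)


class TestConditionReport:
    def _session(self, dprimes, n_trials=600, seed=3):
        pairs = enumerate_pairs(["a", "b", "c"])
        trials = []
        for i, (cond, d) in enumerate(dprimes.items()):
            trials += simulate_observer(d, 1.5, pairs, n_trials=n_trials,
                                        seed=seed + i, condition=cond)
        return trials

    def test_recovers_sensitivity_ordering(self):
        dprimes = {"low": 0.4, "mid": 1.2, "high": 3.5}
        rep = condition_report(self._session(dprimes))
        pooled = rep[rep.pair == "all"].set_index("condition")
        assert pooled.loc["low", "dprime"] < pooled.loc["mid", "dprime"] \
            < pooled.loc["high", "dprime"]
        # pooled-count and mean-per-pair estimates broadly agree
        for cond in dprimes:
            assert pooled.loc[cond, "mean_pair_dprime"] == pytest.approx(
                pooled.loc[cond, "dprime"], abs=0.5)

    def test_all_correct_condition_has_finite_dprime(self):
        pairs = enumerate_pairs(["a", "b"])
        trials = [TrialRecord.from_response(p, "c", "different" if not p.is_same
                                            else "same") for p in pairs] * 5
        rep = condition_report(trials)
        row = rep[rep.pair == "all"].iloc[0]
        assert row.percent_correct == 100.0
        assert np.isfinite(row.dprime) and row.dprime > 2.0

    def test_report_has_per_pair_rows(self):
        rep = condition_report(self._session({"only": 1.0}, n_trials=50))
        assert len(rep[rep.pair != "all"]) == 9
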