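"""Bayesian change-point models against brute-force product oracles."""

import itertools

import numpy as np
import pytest

from revdyn import bayes, task


def brute_force_loglik(choices, rewards, r, p, initial_high="A"):
    """Direct product of the per-trial factors, trial by trial."""
    total = 0.0
    for k, (y, z) in enumerate(zip(choices, rewards), start=1):
        high = initial_high if k < r else task.opposite(initial_high)
        q = p if (z == 1) == (y == high) else 1 - p
        total += np.log(q) if q > 0 else -np.inf
    return total


def brute_force_behavioral(choices, p, initial="A"):
    total = []
    T = len(choices)
    for r in range(1, T + 1):
        ll = 0.0
        for k, y in enumerate(choices, start=1):
            pref = initial if k < r else task.opposite(initial)
            ll += np.log(p if y == pref else 1 - p)
        total.append(ll)
    return np.array(total)


class TestIdealObserverLikelihood:
    def test_matches_product_oracle(self):
        choices, rewards = ("A", "A", "B"), (1, 1, 1)
        for r in (1, 2, 3):
            got = bayes.ideal_observer_loglik(choices, rewards, r, 0.7)
            assert got == pytest.approx(brute_force_loglik(choices, rewards, r, 0.7))

    def test_flat_at_half(self):
        choices, rewards = ("A", "B", "A", "B"), (1, 0, 0, 1)
        vals = [bayes.ideal_observer_loglik(choices, rewards, r, 0.5) for r in (1, 2, 3, 4)]
        assert np.ptp(vals) < 1e-12

    def test_maximized_at_true_reversal(self):
        """All-rewarded choices switching at r_true peak the likelihood there."""
        r_true = 5
        choices = tuple("A" if k < r_true else "B" for k in range(1, 9))
        rewards = (1,) * 8
        lls = [bayes.ideal_observer_loglik(choices, rewards, r, 0.7) for r in range(1, 9)]
        assert int(np.argmax(lls)) + 1 == r_true

    def test_impossible_observation_gives_neg_inf(self):
        # reward for choosing A after the reversal is impossible at p = 1
        ll = bayes.ideal_observer_loglik(("A",), (1,), 1, 1.0)
        assert ll == -np.inf

    def test_random_blocks_match_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            T = int(rng.integers(2, 12))
            choices = tuple(task.CHOICES[i] for i in rng.integers(0, 2, T))
            rewards = tuple(rng.integers(0, 2, T))
            r = int(rng.integers(1, T + 1))
            init = task.CHOICES[int(rng.integers(0, 2))]
            got = bayes.ideal_observer_loglik(choices, rewards, r, 0.7, init)
            assert got == pytest.approx(brute_force_loglik(choices, rewards, r, 0.7, init))


class TestPosterior:
    def test_single_candidate(self):
        table = bayes.posterior(("A",), (1,), 1, 0.7)
        assert table.probs == pytest.approx([1.0])

    def test_uniform_at_half(self):
        table = bayes.posterior(("A", "B", "A"), (1, 0, 1), 3, 0.5)
        assert table.probs == pytest.approx([1 / 3] * 3)

    def test_behavioral_matches_normalized_products(self):
        choices = ("A", "A", "B", "B")
        table = bayes.posterior(choices, None, 4, 0.7, model="behavioral", initial_high="A")
        ll = brute_force_behavioral(choices, 0.7)
        expect = np.exp(ll) / np.exp(ll).sum()
        assert table.probs == pytest.approx(expect)

    def test_sums_to_one_and_scale_invariance(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            T = int(rng.integers(1, 30))
            choices = tuple(task.CHOICES[i] for i in rng.integers(0, 2, T))
            rewards = tuple(rng.integers(0, 2, T))
            tab = bayes.posterior(choices, rewards, T, 0.7, initial_high="A")
            assert tab.probs.sum() == pytest.approx(1.0, abs=1e-12)
            assert (tab.probs >= 0).all()

    def test_no_underflow_long_blocks(self):
        """Log-space evaluation survives T = 200 at extreme p."""
        rng = np.random.default_rng(2)
        choices = tuple(task.CHOICES[i] for i in rng.integers(0, 2, 200))
        rewards = tuple(rng.integers(0, 2, 200))
        for p in (0.55, 0.95):
            tab = bayes.posterior(choices, rewards, 200, p, initial_high="A")
            assert np.isfinite(tab.probs).all()
            assert tab.probs.sum() == pytest.approx(1.0, abs=1e-9)

    def test_requires_data(self):
        with pytest.raises(ValueError):
            bayes.posterior((), (), 0, 0.7)


class TestRunningMap:
    def test_tie_breaks_to_smallest(self):
        # p=0.5 makes every candidate equally likely: argmax must return r=1
        r_star, conv = bayes.running_map(("A", "B", "A"), (1, 0, 1), 0.5, "A")
        assert (r_star == 1).all()
        assert conv == 1

    def test_convergence_trial_definition(self):
        assert bayes.convergence_trial(np.array([1, 2, 3, 5, 5, 5])) == 4
        assert bayes.convergence_trial(np.array([4, 4, 4])) == 1
        assert bayes.convergence_trial(np.array([2, 4, 2, 4])) == 4

    def test_map_recovers_scheduled_reversal(self):
        """Full-block MAP lands within +/-2 of the scheduled reversal mostly."""
        rng = np.random.default_rng(3)
        cfg = task.TaskConfig(n_trials=24, reward_prob=0.7)
        hits = 0
        n = 300
        for _ in range(n):
            block = bayes.simulate_target_block(cfg, rng)
            r_star, _ = bayes.running_map(
                block.choices, block.rewards, 0.7, block.schedule.initial_high_value
            )
            hits += abs(r_star[-1] - block.schedule.scheduled_reversal) <= 2
        assert hits / n > 0.5


class TestTargets:
    def test_switch_trial_formula(self):
        rng = np.random.default_rng(4)
        cfg = task.TaskConfig(n_trials=24, reward_prob=0.7)
        block = bayes.simulate_target_block(cfg, rng)
        for delta in (0, 4):
            tgt = bayes.build_targets(block, 0.7, delta=delta)
            r_star, _ = bayes.running_map(
                block.choices, block.rewards, 0.7, block.schedule.initial_high_value
            )
            assert tgt.switch_trial == min(24, max(1, r_star[-1] + delta))
            init = block.schedule.initial_high_value
            for k, c in enumerate(tgt.choices, start=1):
                assert c == (init if k < tgt.switch_trial else task.opposite(init))

    def test_mirror_symmetry(self):
        """B-first blocks yield the mirrored target sequence of A-first blocks."""
        cfg = task.TaskConfig(n_trials=24, reward_prob=0.7)
        sch_a = task.BlockSchedule(12, "A")
        sch_b = task.BlockSchedule(12, "B")
        rewarded_a = ["A"] * 11 + ["B"] * 13
        rewarded_b = [task.opposite(c) for c in rewarded_a]

        def make(sch, rewarded):
            trials = []
            for k in range(1, 25):
                c = sch.initial_high_value if k < 16 else task.opposite(sch.initial_high_value)
                ft, rw = task.feedback_for(c, rewarded[k - 1])
                trials.append(task.TrialRecord(k, c, rewarded[k - 1], rw, ft))
            return task.BlockRecord(schedule=sch, trials=trials)

        tgt_a = bayes.build_targets(make(sch_a, rewarded_a), 0.7)
        tgt_b = bayes.build_targets(make(sch_b, rewarded_b), 0.7)
        assert tgt_b.switch_trial == tgt_a.switch_trial
        assert tuple(task.opposite(c) for c in tgt_a.choices) == tgt_b.choices


class TestBehavioralReversal:
    def test_clean_switch_found(self):
        for m in (5, 9, 14):
            choices = tuple("A" if k < m else "B" for k in range(1, 21))
            br = bayes.behavioral_reversal_trial(choices, 0.7)
            assert br.trial == m and not br.degenerate

    def test_constant_sequence_flagged(self):
        br = bayes.behavioral_reversal_trial(("A",) * 10, 0.7)
        assert br.trial == 10 and br.degenerate

    def test_single_stray_choice_does_not_move_map(self):
        """One stray B inside the A-run leaves the MAP at the clean switch."""
        choices = list("AAAAAAAAAAAABBBBBB")
        choices[4] = "B"
        br = bayes.behavioral_reversal_trial(tuple(choices), 0.7)
        ll = brute_force_behavioral(tuple(choices), 0.7)
        assert br.trial == int(np.argmax(ll)) + 1 == 13


class TestReversalProbability:
    def test_current_kind_peaks_near_reversal(self):
        rng = np.random.default_rng(5)
        cfg = task.TaskConfig(n_trials=36, reward_prob=0.7)
        peaks = []
        for _ in range(100):
            block = bayes.simulate_target_block(cfg, rng)
            z = bayes.reversal_probability(
                block.choices, block.rewards, 0.7,
                block.schedule.initial_high_value,
            )
            peaks.append(np.argmax(z) + 1 - block.schedule.scheduled_reversal)
        assert abs(np.median(peaks)) <= 2

    def test_cumulative_is_monotone_saturating(self):
        choices = tuple("A" if k < 12 else "B" for k in range(1, 25))
        rewards = tuple(1 for _ in choices)
        z = bayes.reversal_probability(choices, rewards, 0.7, "A", kind="cumulative")
        assert z[-1] > 0.95
        assert np.all(np.diff(z[14:]) > -1e-9)
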