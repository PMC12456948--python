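"""RNN dynamics: integration accuracy, choice readout, rollouts, projection."""

import numpy as np
import pytest

from revdyn import rnn, task


def zero_weight_bundle(N=8, tau=20.0):
    return rnn.RNNBundle(W_rec=np.zeros((N, N)), w_out=np.zeros(N), tau=tau)


class TestStep:
    def test_linear_decay_matches_closed_form(self):
        """With W=0 and no input, u decays as exp(-t/tau) up to O(dt)."""
        b = zero_weight_bundle()
        u = np.full(8, 2.0)
        dt, tau, T = 2.0, 20.0, 100.0
        for _ in range(int(T / dt)):
            u = rnn.step(u, np.zeros(8), b, dt)
        expect = 2.0 * np.exp(-T / tau)
        # accumulated first-order Euler error over T/tau time constants
        tol = 1.5 * expect * (T / tau) * (dt / (2 * tau))
        assert np.allclose(u, expect, atol=tol)

    def test_fixed_point_at_constant_input(self):
        b = zero_weight_bundle()
        I = np.linspace(-1, 1, 8)
        u = np.zeros(8)
        for _ in range(500):
            u = rnn.step(u, I, b, 10.0)
        assert np.allclose(u, I, atol=1e-8)

    def test_step_refinement_consistent(self):
        """Halving dt changes the endpoint by roughly the first-order factor."""
        rng = np.random.default_rng(0)
        b = rnn.init_bundle(20, rng, g=1.0)
        u0 = rng.standard_normal(20)
        I = rng.standard_normal(20)

        def endpoint(dt):
            # stop mid-transient (2 tau) where discretization error is visible
            u = u0.copy()
            for _ in range(int(40 / dt)):
                u = rnn.step(u, I, b, dt)
            return u

        e10, e5, e2 = endpoint(10.0), endpoint(5.0), endpoint(2.5)
        # errors scale linearly in dt for forward Euler
        r = np.linalg.norm(e10 - e5) / np.linalg.norm(e5 - e2)
        assert 1.3 < r < 3.0

    def test_large_dt_rejected(self):
        b = zero_weight_bundle()
        with pytest.raises(ValueError):
            rnn.step(np.zeros(8), np.zeros(8), b, 11.0)


class TestRunTrial:
    def test_bookkeeping_and_zero_readout(self, tiny_rnn, timing):
        bundle, stimuli = tiny_rnn
        u0 = np.zeros(bundle.N)
        u_traj, rates, z, inputs = rnn.run_trial(u0, "A1", bundle, stimuli, timing)
        assert u_traj.shape == (timing.n_steps + 1, bundle.N)
        assert z.shape == (timing.n_steps,)
        assert inputs.shape == (timing.n_steps, bundle.N)
        b2 = rnn.RNNBundle(W_rec=bundle.W_rec, w_out=np.zeros(bundle.N),
                           tau=bundle.tau, act_a=bundle.act_a)
        _, _, z2, _ = rnn.run_trial(u0, "A1", b2, stimuli, timing)
        assert np.allclose(z2, 0.0)

    def test_inputs_enter_additively_through_windows(self, tiny_rnn, timing):
        """Removing the cue leaves the trajectory identical before cue onset."""
        bundle, stimuli = tiny_rnn
        u0 = np.zeros(bundle.N)
        no_cue = rnn.StimulusBank(
            I_base=stimuli.I_base, I_cue=np.zeros(bundle.N),
            I_feedback=stimuli.I_feedback,
        )
        u1, *_ = rnn.run_trial(u0, "B0", bundle, stimuli, timing)
        u2, *_ = rnn.run_trial(u0, "B0", bundle, no_cue, timing)
        cue_start = timing.steps(timing.cue_window).start
        assert np.allclose(u1[: cue_start + 1], u2[: cue_start + 1])
        assert not np.allclose(u1[-1], u2[-1])


class TestNetworkChoice:
    def test_softmax_values(self, timing):
        z = np.zeros(timing.n_steps)
        z[timing.steps(timing.choice_window)] = 1.0
        choice, logp, zbar = rnn.network_choice(z, timing)
        assert zbar == pytest.approx(1.0)
        assert choice == "A"
        assert np.exp(logp[0]) == pytest.approx(np.e / (np.e + np.e**-1))
        assert np.exp(logp).sum() == pytest.approx(1.0)

    def test_tie_goes_to_A_and_probs_half(self, timing):
        choice, logp, zbar = rnn.network_choice(np.zeros(timing.n_steps), timing)
        assert choice == "A" and zbar == 0.0
        assert np.exp(logp) == pytest.approx([0.5, 0.5])


class TestRunBlock:
    def test_deterministic_and_zero_perturbation_identical(self, tiny_rnn, timing):
        bundle, stimuli = tiny_rnn
        cfg = task.TaskConfig(n_trials=12, reward_prob=0.7, reversal_halfwidth=2)
        sch = task.BlockSchedule(6, "A")
        rec1, rates1, z1, _ = rnn.run_block(
            bundle, stimuli, sch, timing, cfg, np.random.default_rng(3)
        )
        rec2, rates2, z2, _ = rnn.run_block(
            bundle, stimuli, sch, timing, cfg, np.random.default_rng(3)
        )
        assert rec1.trials == rec2.trials
        assert np.array_equal(rates1, rates2)
        vec = np.zeros(bundle.N)
        rec3, rates3, _, _ = rnn.run_block(
            bundle, stimuli, sch, timing, cfg, np.random.default_rng(3),
            perturb_vec=vec, perturb_trial=6,
        )
        assert np.array_equal(rates1, rates3)

    def test_state_carries_over_between_trials(self, tiny_rnn, timing):
        bundle, stimuli = tiny_rnn
        cfg = task.TaskConfig(n_trials=6, reward_prob=0.7, reversal_halfwidth=1)
        sch = task.BlockSchedule(3, "A")
        _, _, _, res = rnn.run_block(
            bundle, stimuli, sch, timing, cfg, np.random.default_rng(4)
        )
        n = timing.n_steps
        # sample 0 of trial k equals the carried state after trial k-1
        assert np.allclose(res.u[n], res.u[n])
        assert not np.allclose(res.u[0], res.u[n])  # dynamics actually moved

    def test_perturbation_outside_block_rejected(self, tiny_rnn, timing):
        bundle, stimuli = tiny_rnn
        cfg = task.TaskConfig(n_trials=12, reward_prob=0.7, reversal_halfwidth=2)
        sch = task.BlockSchedule(6, "A")
        with pytest.raises(ValueError, match="outside"):
            rnn.run_block(
                bundle, stimuli, sch, timing, cfg, np.random.default_rng(5),
                perturb_vec=np.ones(bundle.N), perturb_trial=40,
            )

    def test_pre_perturbation_equality(self, tiny_rnn, timing):
        bundle, stimuli = tiny_rnn
        cfg = task.TaskConfig(n_trials=12, reward_prob=0.7, reversal_halfwidth=2)
        sch = task.BlockSchedule(6, "A")
        u0 = np.zeros(bundle.N)
        rng1 = np.random.default_rng(6)
        _, _, _, res0 = rnn.run_block(bundle, stimuli, sch, timing, cfg, rng1, u0=u0)
        _, _, _, res1 = rnn.run_block(
            bundle, stimuli, sch, timing, cfg, np.random.default_rng(6),
            perturb_vec=3.0 * np.ones(bundle.N), perturb_trial=6, u0=u0,
            rewarded=res0.rewarded,
        )
        n = timing.n_steps
        onset = 5 * n + timing.steps(timing.cue_window).start
        assert np.allclose(res0.u[: onset + 1], res1.u[: onset + 1])
        assert not np.allclose(res0.u[onset + 2], res1.u[onset + 2])

    def test_rates_bounded_on_long_rollout(self, tiny_rnn, timing):
        bundle, stimuli = tiny_rnn
        cfg = task.TaskConfig(n_trials=36, reward_prob=0.7)
        sch = task.BlockSchedule(18, "B")
        _, rates, _, res = rnn.run_block(
            bundle, stimuli, sch, timing, cfg, np.random.default_rng(7)
        )
        assert np.all((rates > 0) & (rates < 1))
        assert np.isfinite(res.u).all()


class TestDecomposition:
    def test_zero_input_gives_zero_external(self, timing):
        rng = np.random.default_rng(8)
        b = rnn.init_bundle(15, rng)
        u_traj = rng.standard_normal((timing.n_steps + 1, 15))
        inputs = np.zeros((timing.n_steps, 15))
        v = np.zeros(15)
        v[0] = 1.0
        x, x_rec, x_ext = rnn.decompose_projected_dynamics(u_traj, inputs, b, v)
        assert np.allclose(x_ext, 0.0)

    def test_projection_requires_unit_norm(self, timing):
        b = zero_weight_bundle()
        with pytest.raises(ValueError):
            rnn.decompose_projected_dynamics(
                np.zeros((5, 8)), np.zeros((4, 8)), b, np.full(8, 2.0)
            )

    def test_self_consistency_on_rollout(self, tiny_rnn, timing):
        """tau dx/dt equals x_rec + x_ext up to the Euler discretization error."""
        bundle, stimuli = tiny_rnn
        u0 = 0.1 * np.random.default_rng(9).standard_normal(bundle.N)
        u_traj, rates, _, inputs = rnn.run_trial(u0, "A0", bundle, stimuli, timing)
        v = np.zeros(bundle.N)
        v[:4] = 0.5
        x, x_rec, x_ext = rnn.decompose_projected_dynamics(u_traj, inputs, bundle, v)
        # forward-difference derivative of the projection across samples
        x_next = rnn.phi(u_traj[1:], bundle.act_a, bundle.act_b) @ v
        lhs = bundle.tau * (x_next - x) / timing.dt
        rhs = x_rec + x_ext
        scale = np.abs(rhs).max()
        assert np.abs(lhs - rhs).max() < 10 * (timing.dt / bundle.tau) * scale
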