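"""Continuous-time inhibitory rate network for the reversal-learning task.

The network obeys

    tau du/dt = -u + W_rec phi(u) + I_base + I_cue + I_feedback

with a sigmoidal activation ``phi(x) = 1/(1 + exp(-(a x + b)))``, purely
inhibitory recurrence (``W_rec <= 0``, zero diagonal) and a scalar readout
``z = w_out . phi(u)``. Constant excitatory baseline input balances the
recurrent inhibition. Each 500 ms trial presents the previous trial's
feedback input on [0, 300) ms, the go cue on [250, 300) ms (overlapping the
feedback), and reads the choice out as the sign of the readout averaged over
[350, 400) ms. The state carries over continuously from trial to trial, so
multi-trial evidence lives in the network state.

Integration is forward Euler with ``dt`` (default 10 ms = tau/2). Time is
discretized into samples ``s = 0 .. n_steps-1`` per trial; sample ``s`` is the
state at time ``s*dt`` before that step's update, and input windows are
half-open ``[start, end)`` in ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .task import (
    CHOICES,
    BlockRecord,
    BlockSchedule,
    TaskConfig,
    TrialRecord,
    feedback_for,
    sample_rewarded_choice,
)

__all__ = [
    "RNNBundle",
    "StimulusBank",
    "TrialTiming",
    "PerturbSpec",
    "phi",
    "phi_prime",
    "init_bundle",
    "make_stimuli",
    "step",
    "run_trial",
    "network_choice",
    "run_block",
    "run_batch",
    "BatchResult",
    "decompose_projected_dynamics",
    "perturbation_experiment",
]


def phi(u: np.ndarray, a: float = 1.0, b: float = 0.0) -> np.ndarray:
    """Sigmoidal activation 1/(1+exp(-(a u + b))), elementwise."""
    return 1.0 / (1.0 + np.exp(-(a * u + b)))


def phi_prime(u: np.ndarray, a: float = 1.0, b: float = 0.0) -> np.ndarray:
    s = phi(u, a, b)
    return a * s * (1.0 - s)


@dataclass
class RNNBundle:
    """Network parameters: recurrent weights, readout, activation and tau.

    ``W_rec`` entries are nonpositive with zero diagonal at all times,
    including after every training update (inhibition-only connectivity).
    """

    W_rec: np.ndarray
    w_out: np.ndarray
    tau: float = 20.0
    act_a: float = 1.0
    act_b: float = 0.0
    mask: Optional[np.ndarray] = None  # fixed connectivity mask (1 = synapse exists)

    @property
    def N(self) -> int:
        return self.W_rec.shape[0]

    def validate(self) -> None:
        if self.W_rec.shape != (self.N, self.N):
            raise ValueError("W_rec must be square")
        if np.any(self.W_rec > 0):
            raise ValueError("W_rec must be nonpositive (inhibitory network)")
        if np.any(np.diag(self.W_rec) != 0):
            raise ValueError("W_rec diagonal must be zero")

    def rates(self, u: np.ndarray) -> np.ndarray:
        return phi(u, self.act_a, self.act_b)


@dataclass
class StimulusBank:
    """Frozen external input vectors: baseline, cue, and four feedback inputs."""

    I_base: np.ndarray
    I_cue: np.ndarray
    I_feedback: dict[str, np.ndarray]  # keyed by feedback type A1/A0/B0/B1

    @property
    def N(self) -> int:
        return len(self.I_base)

    def feedback_or_zero(self, feedback_type: Optional[str]) -> np.ndarray:
        """Feedback vector, or zeros on trial 1 where no previous trial exists."""
        if feedback_type is None:
            return np.zeros(self.N)
        return self.I_feedback[feedback_type]


@dataclass(frozen=True)
class TrialTiming:
    """Trial timing in ms and the integration step."""

    t_trial: float = 500.0
    feedback_window: tuple[float, float] = (0.0, 300.0)
    cue_window: tuple[float, float] = (250.0, 300.0)
    choice_window: tuple[float, float] = (350.0, 400.0)
    fixation_window: tuple[float, float] = (0.0, 250.0)
    dt: float = 10.0

    def __post_init__(self) -> None:
        edges = (
            *self.feedback_window, *self.cue_window,
            *self.choice_window, *self.fixation_window, self.t_trial,
        )
        for e in edges:
            if e < 0 or e > self.t_trial:
                raise ValueError("window edges must lie within [0, t_trial]")
            if abs(round(e / self.dt) * self.dt - e) > 1e-9:
                raise ValueError(f"dt={self.dt} must divide window edge {e}")

    @property
    def n_steps(self) -> int:
        return int(round(self.t_trial / self.dt))

    def steps(self, window: tuple[float, float]) -> slice:
        return slice(int(round(window[0] / self.dt)), int(round(window[1] / self.dt)))


@dataclass(frozen=True)
class PerturbSpec:
    """A subspace perturbation: direction, strength, and trial relative to reversal.

    The perturbation vector is added as an external input during the 50 ms cue
    window of the target trial. ``direction`` selects the reversal-probability
    population vector (``v_plus``), its negative (``v_minus``) or a random
    vector with matched element SD (``v_rnd``).
    """

    direction: str  # "v_plus" | "v_minus" | "v_rnd"
    strength: float
    trial_offset: int = 0  # relative to the unperturbed behavioral reversal

    def __post_init__(self) -> None:
        if self.direction not in ("v_plus", "v_minus", "v_rnd"):
            raise ValueError(f"unknown perturbation direction {self.direction!r}")


def init_bundle(
    N: int = 200,
    rng: Optional[np.random.Generator] = None,
    conn_prob: float = 0.1,
    g: float = 1.0,
    tau: float = 20.0,
    act_a: float = 1.0,
    act_b: float = 0.0,
) -> RNNBundle:
    """Random inhibitory network: W_ij = -|g xi| / sqrt(conn_prob * N) on a
    sparse mask with connection probability ``conn_prob``, zero diagonal."""
    rng = np.random.default_rng() if rng is None else rng
    mask = (rng.random((N, N)) < conn_prob).astype(float)
    np.fill_diagonal(mask, 0.0)
    W = -np.abs(g * rng.standard_normal((N, N))) / np.sqrt(conn_prob * N) * mask
    w_out = rng.standard_normal(N) / np.sqrt(N)
    return RNNBundle(W_rec=W, w_out=w_out, tau=tau, act_a=act_a, act_b=act_b, mask=mask)


def make_stimuli(
    N: int,
    rng: Optional[np.random.Generator] = None,
    input_sd: float = 0.9,
    base: float = 0.5,
) -> StimulusBank:
    """Draw the frozen stimulus bank: constant baseline, random cue and feedback
    vectors with elements from a mean-0, SD-``input_sd`` normal."""
    rng = np.random.default_rng() if rng is None else rng
    I_base = np.full(N, base)
    I_cue = input_sd * rng.standard_normal(N)
    I_feedback = {ft: input_sd * rng.standard_normal(N) for ft in ("A1", "A0", "B0", "B1")}
    return StimulusBank(I_base=I_base, I_cue=I_cue, I_feedback=I_feedback)


def step(u: np.ndarray, total_input: np.ndarray, bundle: RNNBundle, dt: float) -> np.ndarray:
    """One forward-Euler update of the rate dynamics."""
    if dt > bundle.tau / 2 + 1e-12:
        raise ValueError("dt must not exceed tau/2 for a stable Euler step")
    lam = dt / bundle.tau
    u_next = u + lam * (-u + phi(u, bundle.act_a, bundle.act_b) @ bundle.W_rec.T + total_input)
    if not np.all(np.isfinite(u_next)):
        raise FloatingPointError("non-finite network state encountered")
    return u_next


def _input_at(
    s: int,
    stimuli: StimulusBank,
    timing: TrialTiming,
    feedback_type: Optional[str],
    extra: Optional[np.ndarray] = None,
) -> np.ndarray:
    """External input at within-trial sample ``s``."""
    I = stimuli.I_base.copy()
    fb = timing.steps(timing.feedback_window)
    cue = timing.steps(timing.cue_window)
    if fb.start <= s < fb.stop:
        I = I + stimuli.feedback_or_zero(feedback_type)
    if cue.start <= s < cue.stop:
        I = I + stimuli.I_cue
        if extra is not None:
            I = I + extra
    return I


def run_trial(
    u0: np.ndarray,
    feedback_type: Optional[str],
    bundle: RNNBundle,
    stimuli: StimulusBank,
    timing: TrialTiming,
    perturb_vec: Optional[np.ndarray] = None,
):
    """Roll one trial from state ``u0``.

    Returns ``(u_traj, rates, z, inputs)`` with ``u_traj`` of shape
    ``(n_steps+1, N)`` (sample ``s`` is the state at ``s*dt``; the last row is
    the carry-over state), ``rates = phi(u_traj)``, the readout trace ``z``
    over the ``n_steps`` within-trial samples, and the external input applied
    on each step. A perturbation vector, when given, is added during the cue
    window.
    """
    n = timing.n_steps
    u_traj = np.empty((n + 1, bundle.N))
    inputs = np.empty((n, bundle.N))
    u_traj[0] = u0
    for s in range(n):
        inputs[s] = _input_at(s, stimuli, timing, feedback_type, perturb_vec)
        u_traj[s + 1] = step(u_traj[s], inputs[s], bundle, timing.dt)
    rates = phi(u_traj, bundle.act_a, bundle.act_b)
    z = rates[:n] @ bundle.w_out
    return u_traj, rates, z, inputs


def network_choice(z: np.ndarray, timing: TrialTiming) -> tuple[str, np.ndarray, float]:
    """Choice from the readout trace via the symmetrized softmax.

    The readout is averaged over the choice window to ``zbar``; the
    symmetrized pair ``(zbar, -zbar)`` is passed through a softmax and the
    choice is the argmax (A on ties at zbar = 0). Returns
    ``(choice, log_probs[A, B], zbar)``.
    """
    zbar = float(np.mean(z[timing.steps(timing.choice_window)]))
    # log softmax of (zbar, -zbar), numerically stable
    m = abs(zbar)
    logZ = m + np.log(np.exp(zbar - m) + np.exp(-zbar - m))
    log_probs = np.array([zbar - logZ, -zbar - logZ])
    choice = "A" if zbar >= 0 else "B"
    return choice, log_probs, zbar


@dataclass
class BatchResult:
    """Rollout of B blocks: behavior, readouts and (optionally) state history."""

    schedules: list[BlockSchedule]
    choices: np.ndarray        # (B, T) int codes, A=0 B=1
    rewards: np.ndarray        # (B, T)
    rewarded: np.ndarray       # (B, T) int codes of the drawn rewarded choice
    zbar: np.ndarray           # (B, T) choice-window readout mean
    z: np.ndarray              # (B, T, n_steps) readout trace
    u: Optional[np.ndarray]    # (S+1, B, N) states when stored, S = T*n_steps
    feedback_codes: np.ndarray  # (B, T) index into FEEDBACK order, -1 for none

    _FEEDBACK_ORDER = ("A1", "A0", "B0", "B1")

    def block_record(self, b: int) -> BlockRecord:
        """Assemble the BlockRecord of batch element ``b``."""
        trials = []
        for k in range(self.choices.shape[1]):
            c = CHOICES[self.choices[b, k]]
            rc = CHOICES[self.rewarded[b, k]]
            ftype, rw = feedback_for(c, rc)
            trials.append(
                TrialRecord(trial=k + 1, choice=c, rewarded_choice=rc,
                            reward=rw, feedback_type=ftype)
            )
        return BlockRecord(schedule=self.schedules[b], trials=trials)

    def rates_tensor(self, bundle: RNNBundle, b: int, timing: TrialTiming) -> np.ndarray:
        """Firing-rate tensor (N, n_steps, T) of block ``b`` (states required)."""
        if self.u is None:
            raise ValueError("states were not stored; rerun with store_states=True")
        T = self.choices.shape[1]
        n = timing.n_steps
        u_b = self.u[: T * n, b, :]  # (S, N), sample s of trial k at k*n + s
        r = phi(u_b, bundle.act_a, bundle.act_b)
        return r.reshape(T, n, -1).transpose(2, 1, 0)


def run_batch(
    bundle: RNNBundle,
    stimuli: StimulusBank,
    schedules: Sequence[BlockSchedule],
    timing: TrialTiming,
    config: TaskConfig,
    rng: np.random.Generator,
    u0: Optional[np.ndarray] = None,
    store_states: bool = False,
    perturb: Optional[tuple[np.ndarray, int]] = None,
    rewarded: Optional[np.ndarray] = None,
) -> BatchResult:
    """Simulate ``B`` blocks in parallel, state carried over across trials.

    Trial ``k``'s feedback input encodes trial ``k-1``'s choice and reward
    (zero vector on trial 1). ``perturb=(vec, trial)`` adds ``vec`` during the
    cue window of the given 1-based trial in every block. ``rewarded`` allows
    re-using pre-drawn rewarded-choice codes (B, T) so paired rollouts share
    identical reward schedules.
    """
    B, T, N, n = len(schedules), config.n_trials, bundle.N, timing.n_steps
    lam = timing.dt / bundle.tau
    fb_sl = timing.steps(timing.feedback_window)
    cue_sl = timing.steps(timing.cue_window)
    ch_sl = timing.steps(timing.choice_window)

    if rewarded is None:
        rewarded = np.empty((B, T), dtype=int)
        for b, sch in enumerate(schedules):
            for k in range(1, T + 1):
                rewarded[b, k - 1] = CHOICES.index(
                    sample_rewarded_choice(sch, k, config.reward_prob, rng)
                )
    if u0 is None:
        u = 0.1 * rng.standard_normal((B, N))
    else:
        u = np.array(u0, dtype=float).reshape(B, N).copy()

    fb_bank = np.stack([stimuli.I_feedback[ft] for ft in BatchResult._FEEDBACK_ORDER])
    choices = np.empty((B, T), dtype=int)
    rewards = np.empty((B, T), dtype=int)
    zbar = np.empty((B, T))
    z_all = np.empty((B, T, n))
    fb_codes = np.full((B, T), -1, dtype=int)
    u_store = np.empty((T * n + 1, B, N)) if store_states else None
    a, b_ = bundle.act_a, bundle.act_b
    Wt = bundle.W_rec.T

    fb_vec = np.zeros((B, N))  # trial-1 feedback: no previous trial
    for k in range(T):
        for s in range(n):
            t_glob = k * n + s
            if u_store is not None:
                u_store[t_glob] = u
            A = 1.0 / (1.0 + np.exp(-(a * u + b_)))
            z_all[:, k, s] = A @ bundle.w_out
            I = np.broadcast_to(stimuli.I_base, (B, N)).copy()
            if fb_sl.start <= s < fb_sl.stop:
                I += fb_vec
            if cue_sl.start <= s < cue_sl.stop:
                I += stimuli.I_cue
                if perturb is not None and perturb[1] == k + 1:
                    I += perturb[0]
            u = u + lam * (-u + A @ Wt + I)
        if not np.all(np.isfinite(u)):
            raise FloatingPointError(f"non-finite state at trial {k + 1}")
        zbar[:, k] = z_all[:, k, ch_sl].mean(axis=1)
        choices[:, k] = (zbar[:, k] < 0).astype(int)  # A on ties
        rewards[:, k] = (choices[:, k] == rewarded[:, k]).astype(int)
        # next trial's feedback input encodes this trial's (choice, reward)
        codes = np.where(
            choices[:, k] == 0,
            np.where(rewards[:, k] == 1, 0, 1),  # A1 / A0
            np.where(rewards[:, k] == 1, 3, 2),  # B1 / B0
        )
        fb_codes[:, k] = codes
        fb_vec = fb_bank[codes]
    if u_store is not None:
        u_store[T * n] = u

    # feedback presented during trial k is the code of trial k-1
    fb_presented = np.concatenate(
        [np.full((B, 1), -1, dtype=int), fb_codes[:, :-1]], axis=1
    )
    return BatchResult(
        schedules=list(schedules), choices=choices, rewards=rewards,
        rewarded=rewarded, zbar=zbar, z=z_all, u=u_store,
        feedback_codes=fb_presented,
    )


def run_block(
    bundle: RNNBundle,
    stimuli: StimulusBank,
    schedule: BlockSchedule,
    timing: TrialTiming,
    config: TaskConfig,
    rng: np.random.Generator,
    perturb_spec: Optional[PerturbSpec] = None,
    perturb_vec: Optional[np.ndarray] = None,
    perturb_trial: Optional[int] = None,
    u0: Optional[np.ndarray] = None,
    rewarded: Optional[np.ndarray] = None,
) -> tuple[BlockRecord, np.ndarray, np.ndarray, BatchResult]:
    """Simulate a single block; returns (record, rates (N, n_steps, T), readout
    (n_steps, T), raw batch result).

    A perturbation is given either as a prepared vector plus absolute 1-based
    trial, or via ``perturb_spec`` with the vector supplied separately.
    """
    perturb = None
    if perturb_vec is not None:
        if perturb_trial is None:
            raise ValueError("perturb_trial required with perturb_vec")
        if not (1 <= perturb_trial <= config.n_trials):
            raise ValueError(
                f"perturbation trial {perturb_trial} outside block of {config.n_trials} trials"
            )
        strength = perturb_spec.strength if perturb_spec is not None else 1.0
        perturb = (strength * perturb_vec, perturb_trial)
    res = run_batch(
        bundle, stimuli, [schedule], timing, config, rng,
        u0=None if u0 is None else u0[None, :],
        store_states=True, perturb=perturb, rewarded=rewarded,
    )
    rates = res.rates_tensor(bundle, 0, timing)
    readout = res.z[0].T  # (n_steps, T)
    return res.block_record(0), rates, readout, res


def decompose_projected_dynamics(
    u_traj: np.ndarray,
    inputs: np.ndarray,
    bundle: RNNBundle,
    v: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split the projected dynamics into recurrent and external drive.

    For the projection ``x = <phi(u), v>`` the chain rule gives
    ``tau dx/dt = x_rec + x_ext`` with ``x_rec = <phi'(u) * (-u + W phi(u)), v>``
    (leak plus recurrence through the activation Jacobian) and
    ``x_ext = <phi'(u) * I, v>`` for the summed external input ``I``.

    ``u_traj`` has one more sample than ``inputs`` (the carry-over state);
    the three traces are returned on the ``len(inputs)`` within-trial samples.
    """
    v = np.asarray(v, dtype=float)
    if abs(np.linalg.norm(v) - 1.0) > 1e-8:
        raise ValueError("projection vector must be unit norm")
    U = u_traj[:-1]
    A = phi(U, bundle.act_a, bundle.act_b)
    dphi = bundle.act_a * A * (1.0 - A)
    x = A @ v
    rec_drive = -U + A @ bundle.W_rec.T
    x_rec = (dphi * rec_drive) @ v
    x_ext = (dphi * inputs) @ v
    return x, x_rec, x_ext


def _random_direction_like(v: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random vector whose element SD matches that of ``v``."""
    return rng.standard_normal(len(v)) * np.std(v)


def perturbation_experiment(
    bundle: RNNBundle,
    stimuli: StimulusBank,
    timing: TrialTiming,
    config: TaskConfig,
    v_rev: np.ndarray,
    v_choice: np.ndarray,
    specs: Sequence[PerturbSpec],
    n_blocks: int,
    rng: np.random.Generator,
    p_task: Optional[float] = None,
):
    """Perturb the reversal-probability subspace and measure behavioral shifts.

    For each block an unperturbed rollout (fixed schedule, reward draws and
    initial state) defines the behavioral reversal trial; each spec is then
    re-run identically except for its perturbation vector injected during the
    cue window at ``behavioral reversal + trial_offset``. Returns a tidy
    DataFrame with one row per (block, spec): the reversal-trial shift and the
    perturbation-locked deviations of the reversal-probability and choice
    projections.
    """
    import pandas as pd

    from . import bayes
    from .task import sample_schedule

    p = config.reward_prob if p_task is None else p_task
    rows = []
    v_rev = np.asarray(v_rev, dtype=float)
    for blk in range(n_blocks):
        schedule = sample_schedule(config, rng)
        u0 = 0.1 * rng.standard_normal(bundle.N)
        base_rng = np.random.default_rng(rng.integers(2**31))
        rec0, rates0, _, res0 = run_block(
            bundle, stimuli, schedule, timing, config, base_rng, u0=u0
        )
        rev0 = bayes.behavioral_reversal_trial(rec0.choices, p)
        for spec in specs:
            trial = int(np.clip(rev0.trial + spec.trial_offset, 1, config.n_trials))
            if spec.direction == "v_plus":
                vec = v_rev
            elif spec.direction == "v_minus":
                vec = -v_rev
            else:
                vec = _random_direction_like(v_rev, rng)
            # u0 and rewarded draws are reused, so the paired rollout consumes
            # no randomness and differs only through the perturbation
            rec1, rates1, _, res1 = run_block(
                bundle, stimuli, schedule, timing, config, base_rng,
                perturb_spec=spec, perturb_vec=vec, perturb_trial=trial,
                u0=u0, rewarded=res0.rewarded,
            )
            rev1 = bayes.behavioral_reversal_trial(rec1.choices, p)
            d_rates = rates1 - rates0  # (N, n_steps, T)
            cue_sl = timing.steps(timing.cue_window)
            ch_sl = timing.steps(timing.choice_window)
            dx_rev = np.tensordot(v_rev, d_rates[:, cue_sl, trial - 1], axes=(0, 0)).mean()
            dx_choice = np.tensordot(
                v_choice, d_rates[:, ch_sl, trial - 1], axes=(0, 0)
            ).mean()
            rows.append(
                {
                    "block": blk,
                    "direction": spec.direction,
                    "strength": spec.strength,
                    "trial_offset": spec.trial_offset,
                    "perturb_trial": trial,
                    "reversal_unperturbed": rev0.trial,
                    "reversal_perturbed": rev1.trial,
                    "shift": rev1.trial - rev0.trial,
                    "dx_rev": dx_rev,
                    "dx_choice": dx_choice,
                }
            )
    return pd.DataFrame(rows)
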