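"""Supervised training of the inhibitory RNN on Bayesian target behavior.

Each epoch simulates a batch of blocks with the network's own choices
(closed loop), feeds every block's choices and rewards to the ideal observer
to infer the scheduled reversal, constructs target choice sequences that
switch abruptly ``delta`` trials after the inferred reversal, and minimizes
the summed per-trial cross-entropy between the symmetrized softmax of the
readout and the targets. Gradients are taken through the full block rollout
(backpropagation through time over every Euler step; the discrete
choice-to-feedback pathway is treated as given, as is standard for
closed-loop supervised training). Updates use Adam with a step-decayed
learning rate; after every update the recurrent weights are projected back
onto the inhibitory constraint (entries <= 0, zero diagonal, frozen
connectivity mask), so the trained network remains purely inhibitory.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import bayes
from .rnn import RNNBundle, StimulusBank, TrialTiming, phi, run_batch
from .task import CHOICES, TaskConfig, sample_schedule

__all__ = [
    "TrainConfig",
    "TrainResult",
    "EvalSummary",
    "block_loss",
    "train",
    "evaluate",
]


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of the supervised training loop.

    Defaults are desk-scale: batch 32 networks-worth of blocks per update and
    at most 300 epochs on a single CPU (the reference large-scale setting,
    batch 256, remains settable). ``delta`` is the reversal delay used for
    target construction; ``success_threshold`` is the evaluation reward-rate
    floor defining a successfully trained network at p = 0.7.
    """

    learning_rate: float = 1e-2
    lr_decay: float = 0.9
    lr_decay_every: int = 3
    batch_size: int = 32
    n_epochs: int = 300
    delta: int = 4
    fixation_weight: float = 0.0
    success_threshold: float = 0.65
    success_patience: int = 3
    keep_best: bool = False  # optionally return the best (smoothed-batch-reward) epoch's weights
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not (0 < self.lr_decay <= 1):
            raise ValueError("lr_decay must lie in (0, 1]")


@dataclass
class TrainResult:
    bundle: RNNBundle
    loss_curve: np.ndarray
    reward_rate_curve: np.ndarray
    final_reward_rate: float
    success: bool
    n_epochs_run: int
    lr_curve: np.ndarray = field(default_factory=lambda: np.array([]))

    def log_frame(self):
        """Training log, one row per epoch (epoch, loss, lr, reward_rate)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "epoch": np.arange(len(self.loss_curve)),
                "loss": self.loss_curve,
                "lr": self.lr_curve,
                "reward_rate": self.reward_rate_curve,
            }
        )


def block_loss(
    zbar: np.ndarray,
    target_is_A: np.ndarray,
    z_fix: Optional[np.ndarray] = None,
    fixation_weight: float = 0.0,
) -> float:
    """Loss of one block: summed per-trial cross-entropy, plus an optional
    fixation penalty (mean squared readout during the fixation window).

    ``zbar`` is the per-trial choice-window readout mean; the symmetrized
    softmax assigns P(A) = sigma(2 zbar). ``z_fix`` holds readout samples in
    the fixation window per trial when the penalty is enabled.
    """
    zbar = np.asarray(zbar, dtype=float)
    y = np.asarray(target_is_A, dtype=float)
    sgn = 2.0 * y - 1.0  # +1 for target A, -1 for target B
    ce = np.logaddexp(0.0, -2.0 * sgn * zbar).sum()
    if fixation_weight and z_fix is not None:
        ce += fixation_weight * float(np.mean(np.asarray(z_fix) ** 2, axis=-1).sum())
    return float(ce)


def _targets_for_batch(res, p: float, delta: int) -> np.ndarray:
    """Target-is-A indicator (B, T) from the ideal observer per block."""
    B, T = res.choices.shape
    y = np.empty((B, T), dtype=float)
    for b in range(B):
        record = res.block_record(b)
        targets = bayes.build_targets(record, p, delta=delta)
        y[b] = [c == "A" for c in targets.choices]
    return y


def _bptt_grads(
    res,
    bundle: RNNBundle,
    timing: TrialTiming,
    gz: np.ndarray,
    gz_fix: Optional[np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """Adjoint pass through the stored rollout.

    ``gz[b, k]`` is dL/dzbar of trial k; ``gz_fix[b, k, s]`` (optional) is
    dL/dz at fixation sample s. Returns (dL/dW_rec, dL/dw_out).
    """
    u_store = res.u
    B, T = res.choices.shape
    N = bundle.N
    n = timing.n_steps
    lam = timing.dt / bundle.tau
    ch = timing.steps(timing.choice_window)
    fix = timing.steps(timing.fixation_window)
    n_ch = ch.stop - ch.start
    a, b_ = bundle.act_a, bundle.act_b
    W = bundle.W_rec

    gW = np.zeros((N, N))
    gw_out = np.zeros(N)
    delta_next = np.zeros((B, N))
    for t in range(T * n - 1, -1, -1):
        k, s = divmod(t, n)
        A = 1.0 / (1.0 + np.exp(-(a * u_store[t] + b_)))
        dphi = a * A * (1.0 - A)
        gW += lam * (delta_next.T @ A)
        delta = (1.0 - lam) * delta_next + lam * (delta_next @ W) * dphi
        gA = None
        if ch.start <= s < ch.stop:
            coef = gz[:, k] / n_ch  # (B,)
            gA = coef[:, None] * bundle.w_out[None, :]
            gw_out += coef @ A
        if gz_fix is not None and fix.start <= s < fix.stop:
            coef = gz_fix[:, k, s - fix.start]
            g = coef[:, None] * bundle.w_out[None, :]
            gA = g if gA is None else gA + g
            gw_out += coef @ A
        if gA is not None:
            delta += gA * dphi
        delta_next = delta
    return gW, gw_out


class _Adam:
    def __init__(self, shapes, beta1, beta2, eps):
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0
        self.beta1, self.beta2, self.eps = beta1, beta2, eps

    def step(self, grads, lr):
        self.t += 1
        out = []
        for i, g in enumerate(grads):
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            mhat = self.m[i] / (1 - self.beta1**self.t)
            vhat = self.v[i] / (1 - self.beta2**self.t)
            out.append(lr * mhat / (np.sqrt(vhat) + self.eps))
        return out


def _project_inhibitory(bundle: RNNBundle) -> None:
    """Sign-preserving projection: W_rec <= 0, zero diagonal, fixed mask."""
    np.minimum(bundle.W_rec, 0.0, out=bundle.W_rec)
    if bundle.mask is not None:
        bundle.W_rec *= bundle.mask
    np.fill_diagonal(bundle.W_rec, 0.0)


def train(
    bundle0: RNNBundle,
    stimuli: StimulusBank,
    task_config: TaskConfig,
    train_config: TrainConfig,
    rng: np.random.Generator,
    timing: Optional[TrialTiming] = None,
    verbose: bool = False,
) -> TrainResult:
    """Train recurrent and readout weights on Bayesian target behavior.

    Stops at ``n_epochs`` or once the batch reward rate has stayed at or
    above ``success_threshold`` for ``success_patience`` consecutive epochs.
    Training is reproducible bit-for-bit for a fixed generator state.
    """
    timing = TrialTiming() if timing is None else timing
    bundle = copy.deepcopy(bundle0)
    bundle.validate()
    tc = train_config
    p = task_config.reward_prob
    opt = _Adam(
        [bundle.W_rec.shape, bundle.w_out.shape],
        tc.adam_beta1, tc.adam_beta2, tc.adam_eps,
    )
    fix_sl = timing.steps(timing.fixation_window)
    n_fix = fix_sl.stop - fix_sl.start

    losses, rates, lrs = [], [], []
    lr = tc.learning_rate
    streak = 0
    best_score, best_weights = -np.inf, None
    for epoch in range(tc.n_epochs):
        if epoch > 0 and epoch % tc.lr_decay_every == 0:
            lr *= tc.lr_decay
        schedules = [sample_schedule(task_config, rng) for _ in range(tc.batch_size)]
        res = run_batch(
            bundle, stimuli, schedules, timing, task_config, rng, store_states=True
        )
        y = _targets_for_batch(res, p, tc.delta)
        B = tc.batch_size
        sgn = 2.0 * y - 1.0
        loss = np.logaddexp(0.0, -2.0 * sgn * res.zbar).sum() / B
        # dL/dzbar = 2 (sigma(2 zbar) - y) / B
        gz = 2.0 * (1.0 / (1.0 + np.exp(-2.0 * res.zbar)) - y) / B
        gz_fix = None
        if tc.fixation_weight:
            z_fix = res.z[:, :, fix_sl]
            loss += tc.fixation_weight * float(np.mean(z_fix**2, axis=2).sum()) / B
            gz_fix = 2.0 * tc.fixation_weight * z_fix / (n_fix * B)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite training loss at epoch {epoch}; diverged"
            )
        gW, gw = _bptt_grads(res, bundle, timing, gz, gz_fix)
        dW, dw = opt.step([gW, gw], lr)
        bundle.W_rec -= dW
        bundle.w_out -= dw
        _project_inhibitory(bundle)

        reward_rate = float(res.rewards.mean())
        losses.append(loss)
        rates.append(reward_rate)
        lrs.append(lr)
        if tc.keep_best and len(rates) >= 3:
            score = float(np.mean(rates[-3:]))  # smoothed batch reward
            if score > best_score:
                best_score = score
                best_weights = (bundle.W_rec.copy(), bundle.w_out.copy())
        streak = streak + 1 if reward_rate >= tc.success_threshold else 0
        if verbose and epoch % 10 == 0:
            print(f"epoch {epoch:4d}  loss {loss:8.3f}  reward {reward_rate:.3f}  lr {lr:.2e}")
        if streak >= tc.success_patience:
            break

    if tc.keep_best and best_weights is not None:
        bundle.W_rec, bundle.w_out = best_weights
    final_rate = float(np.mean(rates[-tc.success_patience:]))
    return TrainResult(
        bundle=bundle,
        loss_curve=np.array(losses),
        reward_rate_curve=np.array(rates),
        lr_curve=np.array(lrs),
        final_reward_rate=final_rate,
        success=final_rate >= tc.success_threshold,
        n_epochs_run=len(losses),
    )


@dataclass
class EvalSummary:
    """Behavioral evaluation of a (trained) network over held-out blocks."""

    reward_rate: float
    rel_trials: np.ndarray           # relative-trial axis, 0 = behavioral reversal
    p_initial_best: np.ndarray       # P(choice == initial high-value) per rel trial
    no_reward_fraction: np.ndarray   # fraction of unrewarded trials per rel trial
    counts: np.ndarray               # trials contributing per rel trial
    reversal_lags: np.ndarray        # behavioral - scheduled reversal per block
    n_degenerate: int                # blocks with no detectable reversal


def evaluate(
    bundle: RNNBundle,
    stimuli: StimulusBank,
    task_config: TaskConfig,
    n_blocks: int,
    rng: np.random.Generator,
    timing: Optional[TrialTiming] = None,
    K: int = 12,
    batch: int = 64,
) -> EvalSummary:
    """Simulate held-out blocks and summarize reversal behavior.

    Curves are aligned to each block's behavioral reversal (choice-only
    Bayesian MAP); blocks with a constant choice sequence are excluded from
    the aligned curves and counted as degenerate.
    """
    timing = TrialTiming() if timing is None else timing
    p = task_config.reward_prob
    T = task_config.n_trials
    rel = np.arange(-K, K + 1)
    hit = np.zeros(len(rel))
    norew = np.zeros(len(rel))
    cnt = np.zeros(len(rel))
    lags = []
    n_deg = 0
    rewards_all = []
    done = 0
    while done < n_blocks:
        B = min(batch, n_blocks - done)
        schedules = [sample_schedule(task_config, rng) for _ in range(B)]
        res = run_batch(bundle, stimuli, schedules, timing, task_config, rng)
        rewards_all.append(res.rewards)
        for b in range(B):
            choices = [CHOICES[c] for c in res.choices[b]]
            br = bayes.behavioral_reversal_trial(choices, p)
            if br.degenerate:
                n_deg += 1
                continue
            lags.append(br.trial - schedules[b].scheduled_reversal)
            init = schedules[b].initial_high_value
            for k in range(1, T + 1):
                j = k - br.trial + K
                if 0 <= j < len(rel):
                    cnt[j] += 1
                    hit[j] += choices[k - 1] == init
                    norew[j] += 1 - res.rewards[b, k - 1]
        done += B
    with np.errstate(invalid="ignore", divide="ignore"):
        p_init = np.where(cnt > 0, hit / cnt, np.nan)
        nr = np.where(cnt > 0, norew / cnt, np.nan)
    return EvalSummary(
        reward_rate=float(np.concatenate(rewards_all).mean()),
        rel_trials=rel,
        p_initial_best=p_init,
        no_reward_fraction=nr,
        counts=cnt,
        reversal_lags=np.array(lags),
        n_degenerate=n_deg,
    )
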