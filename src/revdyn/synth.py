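"""Synthetic prefrontal-like population data with planted task coding.

The generator emulates the statistical structure the population analyses
assume, standing in for cortical recordings: a Bayesian agent produces
reversal-learning behavior over blocks (switching its preferred option once
the inferred probability that the reversal has occurred exceeds 1/2, with
occasional lapses); each neuron's firing rate is a softplus of a baseline
plus planted linear coding of trial-varying task variables, each with its
own bump- or ramp-shaped temporal profile (reversal-probability coding
peaks at cue onset); spikes are an inhomogeneous Poisson process realized
as independent 20 ms increments, and sliding 300 ms windows are summed from
those shared increments, so overlapping count bins carry the
autocorrelation that real spike-count binning induces.

Times are in ms relative to cue onset (fixation -500, cue 0, reward +800).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import bayes
from .task import CHOICES, BlockRecord, TaskConfig, opposite
from .tdr import ActivityTensor

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "SynthSession",
    "generate_behavior",
    "generate_session",
]

#: canonical variable order; reversal probability first for QR orthogonalization
VARIABLES = ("reversal_prob", "choice", "reward", "trial_number")


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions of the synthetic cortical session.

    Defaults mirror the primate task: 80-trial blocks with the reversal
    uniform in a 21-trial mid-block window, reward probability 0.7, a trial
    timeline spanning [-2600, +1000] ms around cue onset (fixation at -500,
    reward at +800), spike counts in 300 ms windows stepped by 20 ms, and a
    24-block session of 300 neurons. ``coding_snr`` scales the planted
    task-variable modulation (Hz per SD of the variable); its default is the
    calibrated operating point at which targeted dimensionality reduction
    recovers the planted reversal-probability vector with cosine ~ 0.85.
    """

    n_neurons: int = 300
    n_blocks: int = 24
    trials_per_block: int = 80
    reversal_halfwidth: int = 10
    reward_prob: float = 0.7
    t_start: float = -2600.0
    t_end: float = 1000.0
    bin_window: float = 300.0
    bin_step: float = 20.0
    coding_snr: float = 5.0
    lapse_rate: float = 0.02
    baseline_rate: float = 8.0
    regressor_kind: str = "bayes_final"
    seed: int = 0

    _REGRESSOR_KINDS = (
        "bayes_final", "bayes_current", "bayes_cumulative",
        "stereotyped_v", "integration_walk",
    )

    def __post_init__(self) -> None:
        if self.regressor_kind not in self._REGRESSOR_KINDS:
            raise ValueError(f"unknown regressor_kind {self.regressor_kind!r}")

    @property
    def time_axis(self) -> np.ndarray:
        """Count-bin centers, anchored so cue onset (0) is a bin center."""
        half = self.bin_window / 2
        lo = self.t_start + half
        hi = self.t_end - half
        first = np.ceil(lo / self.bin_step) * self.bin_step
        return np.arange(first, hi + self.bin_step / 2, self.bin_step)

    def validate_covers(self, *times: float) -> None:
        ax = self.time_axis
        for t in times:
            if t < ax.min() or t > ax.max():
                raise ValueError(f"timeline does not cover required time {t} ms")

    def task_config(self) -> TaskConfig:
        return TaskConfig(
            n_trials=self.trials_per_block,
            reward_prob=self.reward_prob,
            reversal_halfwidth=self.reversal_halfwidth,
            seed=self.seed,
        )


@dataclass
class GroundTruth:
    """What was planted: coding vectors, temporal templates, regressors."""

    coding: dict[str, np.ndarray]       # unit-norm population vectors
    templates: dict[str, np.ndarray]    # h_v on the bin-center time axis
    regressors: pd.DataFrame            # standardized z~^v(k), one row per trial
    reversal_trials: np.ndarray         # behavioral reversal per block (1-based)
    baseline: np.ndarray                # per-neuron baseline rate (Hz)


@dataclass
class SynthSession:
    tensor: ActivityTensor
    blocks: list[BlockRecord]
    truth: GroundTruth


class _PosteriorSwitchPolicy:
    """Choose the initial option until P(reversal has occurred) > 1/2.

    The agent knows the task design — the reversal falls in the mid-block
    window — so its prior over reversal trials is restricted to that window
    (an unrestricted flat prior over all T trials would cross 1/2 at
    mid-block from prior mass alone, switching without any evidence). The
    cumulative posterior P(r <= next trial | data so far) over the window
    triggers a single permanent switch; with probability ``lapse_rate`` the
    emitted choice is random without affecting the internal preference.
    """

    def __init__(self, initial_high: str, p: float, T: int,
                 window: tuple[int, int],
                 lapse_rate: float, rng: np.random.Generator):
        self.initial = initial_high
        self.p = p
        self.T = T
        self.window = window
        self.lapse = lapse_rate
        self.rng = rng
        self.switched = False

    def __call__(self, history) -> str:
        preferred = opposite(self.initial) if self.switched else self.initial
        if not self.switched and history:
            k = len(history) + 1
            choices = [t.choice for t in history]
            rewards = [t.reward for t in history]
            pre, post = bayes._log_factors(rewards=rewards, choices=choices,
                                           p=self.p, initial_high=self.initial)
            loglik = bayes._loglik_over_candidates(pre, post, self.T)
            lo, hi = self.window
            sel = np.full(self.T, -np.inf)
            sel[lo - 1 : hi] = loglik[lo - 1 : hi]
            probs = bayes._posterior_from_loglik(sel)
            if probs[: min(k, self.T)].sum() > 0.5:
                self.switched = True
                preferred = opposite(self.initial)
        if self.lapse > 0 and self.rng.random() < self.lapse:
            return CHOICES[int(self.rng.integers(0, 2))]
        return preferred


def generate_behavior(config: SynthConfig, rng: np.random.Generator) -> list[BlockRecord]:
    """Simulate the session's blocks with the posterior-switching agent.

    Each block's ``behavioral_reversal`` field is filled with the
    choice-only Bayesian MAP label used by all alignment analyses.
    """
    from .task import run_block_with_policy, sample_schedule

    tcfg = config.task_config()
    blocks = []
    for _ in range(config.n_blocks):
        sch = sample_schedule(tcfg, rng)
        mid = config.trials_per_block // 2
        window = (mid - config.reversal_halfwidth, mid + config.reversal_halfwidth)
        policy = _PosteriorSwitchPolicy(
            sch.initial_high_value, config.reward_prob,
            config.trials_per_block, window, config.lapse_rate, rng,
        )
        block = run_block_with_policy(sch, policy, tcfg, rng)
        br = bayes.behavioral_reversal_trial(block.choices, config.reward_prob)
        block.behavioral_reversal = br.trial
        blocks.append(block)
    return blocks


def _default_templates(time_axis: np.ndarray) -> dict[str, np.ndarray]:
    """Temporal coding profiles on the bin centers (ms relative to cue)."""
    t = time_axis
    return {
        # reversal-probability coding peaks at cue onset
        "reversal_prob": np.exp(-(t**2) / (2 * 300.0**2)),
        # choice coding ramps up through the choice/saccade epoch
        "choice": 1.0 / (1.0 + np.exp(-(t - 100.0) / 100.0)),
        # outcome coding follows reward delivery
        "reward": np.exp(-((t - 800.0) ** 2) / (2 * 200.0**2)),
        # slow engagement drift, flat in time
        "trial_number": np.full_like(t, 0.5),
    }


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / (sd if sd > 0 else 1.0)


def _reversal_regressor(
    block: BlockRecord, p: float, kind: str,
    rewards_override: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Per-trial reversal-probability values for one block.

    ``bayes_*`` kinds use the ideal-observer posterior (``final`` — the
    full-block posterior over reversal trials, the sharpest inverted-V —
    ``current`` or ``cumulative``, see :func:`revdyn.bayes.reversal_probability`).
    Two explicitly planted structures support recovery experiments:
    ``stereotyped_v`` plants a Gaussian inverted-V centered on the behavioral
    reversal (sd 2.5 trials), and ``integration_walk`` plants a leaky
    reward-integration walk z_k = 0.85 z_{k-1} + 0.3 (1 - reward_k), which
    jumps on no-reward and relaxes under rewards, peaking through the
    pre-reversal no-reward run and decaying once post-reversal rewards
    resume. ``rewards_override`` substitutes the reward sequence the planted
    structure integrates (used by shuffled-outcome controls).
    """
    T = block.n_trials
    k = np.arange(1, T + 1)
    rewards = block.rewards if rewards_override is None else np.asarray(rewards_override)
    if kind == "stereotyped_v":
        m = block.behavioral_reversal or T // 2
        return np.exp(-((k - m) ** 2) / (2 * 2.5**2))
    if kind == "integration_walk":
        z = np.empty(T)
        val = 0.0
        for i in range(T):
            val = 0.85 * val + 0.3 * (1 - rewards[i])
            z[i] = val
        return z
    return bayes.reversal_probability(
        block.choices, rewards, p, block.schedule.initial_high_value,
        horizon=T, kind=kind.removeprefix("bayes_"),
    )


def regressor_table(
    blocks: list[BlockRecord],
    p: float,
    kind: str = "bayes_final",
    shuffle_planted_rewards: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Raw per-trial task variables pooled over the session's blocks.

    With ``shuffle_planted_rewards`` set, the reversal-probability structure
    is computed from a within-block permutation of each block's reward
    sequence, severing the planted activity from the actual outcomes while
    leaving behavior and all other variables untouched (the shuffled-outcome
    control for reward-integration analyses).
    """
    rows = []
    for b, block in enumerate(blocks):
        override = None
        if shuffle_planted_rewards is not None:
            override = block.rewards[shuffle_planted_rewards.permutation(block.n_trials)]
        zrev = _reversal_regressor(block, p, kind, rewards_override=override)
        for k, tr in enumerate(block.trials):
            rows.append(
                {
                    "block": b,
                    "trial": tr.trial,
                    "reversal_prob": zrev[k],
                    "choice": 1.0 if tr.choice == "A" else -1.0,
                    "reward": float(tr.reward),
                    "trial_number": float(tr.trial),
                    "behavioral_reversal": block.behavioral_reversal,
                }
            )
    return pd.DataFrame(rows)


def generate_session(
    config: SynthConfig,
    rng: Optional[np.random.Generator] = None,
    blocks: Optional[list[BlockRecord]] = None,
    shuffle_planted_rewards: bool = False,
) -> SynthSession:
    """Generate a full synthetic session: behavior, rates, spike counts.

    Firing rates are ``softplus(alpha_i + snr * sum_v beta_i^v h_v(t)
    z~^v(k))`` in Hz, with unit-norm random coding vectors ``beta^v``,
    standardized trial variables ``z~^v`` and the temporal templates above;
    ``alpha_i`` sets each neuron's gamma-distributed baseline. Counts come
    from 20 ms Poisson increments summed over each sliding 300 ms window, so
    the overlapping bins share increments exactly as counts from a single
    underlying spike train do.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if blocks is None:
        blocks = generate_behavior(config, rng)
    table = regressor_table(
        blocks, config.reward_prob, kind=config.regressor_kind,
        shuffle_planted_rewards=rng if shuffle_planted_rewards else None,
    )
    K = len(table)
    z = np.column_stack([_standardize(table[v].to_numpy()) for v in VARIABLES])

    N = config.n_neurons
    coding = {}
    for v in VARIABLES:
        w = rng.standard_normal(N)
        coding[v] = w / np.linalg.norm(w)
    B = np.column_stack([coding[v] for v in VARIABLES])  # (N, V)

    baseline = rng.gamma(shape=2.0, scale=config.baseline_rate / 2.0, size=N)
    baseline = np.maximum(baseline, 0.5)
    alpha = np.log(np.expm1(baseline))  # softplus(alpha) = baseline

    # sub-bin grid of independent Poisson increments covering every window
    half = config.bin_window / 2
    centers = config.time_axis
    sub_edges = np.arange(centers[0] - half, centers[-1] + half + 1e-9, config.bin_step)
    sub_mid = (sub_edges[:-1] + sub_edges[1:]) / 2
    n_sub = len(sub_mid)
    n_per_win = int(round(config.bin_window / config.bin_step))

    templates_sub = _default_templates(sub_mid)
    H = np.column_stack([templates_sub[v] for v in VARIABLES])  # (n_sub, V)

    # modulation (N, n_sub, K) = snr * sum_v beta_iv h_v(t) z_kv, built per block
    counts = np.empty((N, len(centers), K), dtype=np.float32)
    dt_s = config.bin_step / 1000.0
    for b in range(len(blocks)):
        sel = np.flatnonzero(table["block"].to_numpy() == b)
        mod = np.einsum("iv,tv,kv->itk", B, H, z[sel])
        rate = np.log1p(np.exp(alpha[:, None, None] + config.coding_snr * mod))
        inc = rng.poisson(rate * dt_s).astype(np.float32)
        c = np.cumsum(inc, axis=1)
        c = np.concatenate([np.zeros((N, 1, len(sel)), np.float32), c], axis=1)
        counts[:, :, sel] = c[:, n_per_win:, :] - c[:, :-n_per_win, :]

    templates = _default_templates(centers)
    tensor = ActivityTensor(
        values=counts, time_axis=centers, source="spike_counts", trial_table=table
    )
    truth = GroundTruth(
        coding=coding,
        templates=templates,
        regressors=pd.DataFrame(z, columns=list(VARIABLES)).assign(
            block=table["block"].to_numpy(), trial=table["trial"].to_numpy()
        ),
        reversal_trials=np.array([b.behavioral_reversal for b in blocks]),
        baseline=baseline,
    )
    return SynthSession(tensor=tensor, blocks=blocks, truth=truth)
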