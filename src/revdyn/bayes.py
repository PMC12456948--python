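"""Bayesian change-point models for the reversal-learning task.

Two observers infer when the block reversed, both with a flat prior over
candidate reversal trials and per-trial likelihood factors of ``p`` or
``1 - p``:

* the **ideal observer** sees choices and reward bits and knows the reward
  schedule structure (which option was initially high-value and the reward
  probability ``p``); it infers the *scheduled* reversal trial;
* the **behavioral model** sees choices only and assumes the preferred choice
  switches at the *behavioral* reversal trial.

All likelihoods are computed in log space and posteriors are exponentiated
with max-subtraction, so blocks of a few hundred trials are safe at any
``p`` in (0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np

from .task import (
    CHOICES,
    BlockRecord,
    TrialRecord,
    feedback_for,
    opposite,
    sample_rewarded_choice,
    sample_schedule,
)

__all__ = [
    "PosteriorTable",
    "TargetChoices",
    "BehavioralReversal",
    "ideal_observer_loglik",
    "posterior",
    "running_map",
    "convergence_trial",
    "build_targets",
    "behavioral_reversal_trial",
    "reversal_probability",
    "BayesTargetPolicy",
]


@dataclass(frozen=True)
class PosteriorTable:
    """Posterior over candidate reversal trials given data up to ``upto_trial``."""

    upto_trial: int
    probs: np.ndarray  # over r = 1 .. len(probs)
    model: str  # "ideal_observer" | "behavioral"


@dataclass(frozen=True)
class TargetChoices:
    """Abruptly switching target choice sequence for supervised training."""

    switch_trial: int  # t*, 1-based; targets flip from this trial on
    choices: tuple[str, ...]


class BehavioralReversal(NamedTuple):
    trial: int
    degenerate: bool  # True when the choice sequence carries no reversal evidence


def _safe_log(x: float) -> float:
    with np.errstate(divide="ignore"):
        return float(np.log(x))


def _log_factors(
    choices: Sequence[str],
    rewards: Optional[Sequence[int]],
    p: float,
    initial_high: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial log-likelihood factors under the pre- and post-reversal regimes.

    For the ideal observer (``rewards`` given), the factor is ``p`` when the
    reward bit is consistent with the regime's high-value option (rewarded
    when choosing it, unrewarded when not) and ``1 - p`` otherwise. For the
    behavioral model (``rewards is None``), the factor is ``p`` when the
    choice equals the regime's preferred option and ``1 - p`` otherwise.
    """
    y = np.asarray([c == initial_high for c in choices], dtype=bool)
    lp, l1p = _safe_log(p), _safe_log(1.0 - p)
    if rewards is None:
        pre = np.where(y, lp, l1p)
        post = np.where(y, l1p, lp)
    else:
        z = np.asarray(rewards, dtype=bool)
        if len(z) != len(y):
            raise ValueError("choices and rewards must have the same length")
        consistent_pre = y == z  # reward iff chose the initially-high option
        pre = np.where(consistent_pre, lp, l1p)
        post = np.where(consistent_pre, l1p, lp)
    return pre, post


def _loglik_over_candidates(
    pre: np.ndarray, post: np.ndarray, horizon: int
) -> np.ndarray:
    """Log-likelihood of the data for every candidate r in [1, horizon].

    Data cover trials 1..t (the length of the factor arrays); candidates
    beyond t treat every observed trial as pre-reversal.
    """
    t = len(pre)
    c_pre = np.concatenate(([0.0], np.cumsum(pre)))
    c_post = np.concatenate(([0.0], np.cumsum(post)))
    r = np.arange(1, horizon + 1)
    n_pre = np.minimum(r - 1, t)
    return c_pre[n_pre] + (c_post[t] - c_post[n_pre])


def ideal_observer_loglik(
    choices: Sequence[str],
    rewards: Sequence[int],
    r: int,
    p: float,
    initial_high: str = "A",
) -> float:
    """Log-likelihood of (choices, rewards) under candidate reversal trial ``r``.

    Trials before ``r`` use the pre-reversal reward regime, trials from ``r``
    on the post-reversal regime. Impossible observations at p in {0, 1} give
    ``-inf`` rather than raising.
    """
    t = len(choices)
    if not (1 <= r <= t):
        raise ValueError(f"candidate r={r} outside data range [1, {t}]")
    pre, post = _log_factors(choices, rewards, p, initial_high)
    return float(pre[: r - 1].sum() + post[r - 1 :].sum())


def _posterior_from_loglik(loglik: np.ndarray) -> np.ndarray:
    finite = np.isfinite(loglik)
    if not finite.any():
        # every candidate is impossible (only at p in {0,1}); fall back to flat
        return np.full(len(loglik), 1.0 / len(loglik))
    w = np.zeros(len(loglik))
    w[finite] = np.exp(loglik[finite] - loglik[finite].max())
    return w / w.sum()


def posterior(
    choices: Sequence[str],
    rewards: Optional[Sequence[int]],
    t: int,
    p: float,
    model: str = "ideal_observer",
    initial_high: Optional[str] = None,
    horizon: Optional[int] = None,
) -> PosteriorTable:
    """Posterior over candidate reversal trials given data up to trial ``t``.

    ``model="ideal_observer"`` requires reward bits; ``model="behavioral"``
    ignores them. The prior is flat over ``[1, horizon]`` (default: ``[1, t]``).
    When ``initial_high`` is None it is chosen by maximum likelihood over the
    two options (ties toward 'A').
    """
    if t < 1:
        raise ValueError("posterior requires data from at least one trial")
    if model == "behavioral":
        rewards = None
    elif model == "ideal_observer":
        if rewards is None:
            raise ValueError("ideal_observer model requires rewards")
        rewards = list(rewards)[:t]
    else:
        raise ValueError(f"unknown model {model!r}")
    choices = list(choices)[:t]
    horizon = t if horizon is None else horizon
    if initial_high is None:
        initial_high = _infer_initial_high(choices, rewards, p, horizon)
    pre, post = _log_factors(choices, rewards, p, initial_high)
    loglik = _loglik_over_candidates(pre, post, horizon)
    return PosteriorTable(upto_trial=t, probs=_posterior_from_loglik(loglik), model=model)


def _infer_initial_high(choices, rewards, p, horizon) -> str:
    best, best_val = "A", -np.inf
    for label in CHOICES:
        pre, post = _log_factors(choices, rewards, p, label)
        val = _loglik_over_candidates(pre, post, horizon).max()
        if val > best_val:
            best, best_val = label, val
    return best


def running_map(
    choices: Sequence[str],
    rewards: Optional[Sequence[int]],
    p: float,
    initial_high: str,
    model: str = "ideal_observer",
) -> tuple[np.ndarray, int]:
    """Running MAP estimate r*_t for t = 1..T and its convergence trial.

    r*_t is the argmax (smallest index on ties) of the posterior over
    candidates [1, t] given data up to t. The convergence trial is the
    smallest t such that r*_s equals r*_T for every s >= t.
    """
    choices = list(choices)
    T = len(choices)
    if model == "behavioral":
        rewards = None
    pre, post = _log_factors(choices, rewards, p, initial_high)
    c_pre = np.concatenate(([0.0], np.cumsum(pre)))
    c_post = np.concatenate(([0.0], np.cumsum(post)))
    r_star = np.empty(T, dtype=int)
    for t in range(1, T + 1):
        r = np.arange(1, t + 1)
        loglik = c_pre[r - 1] + (c_post[t] - c_post[r - 1])
        r_star[t - 1] = int(np.argmax(loglik)) + 1  # first max -> smallest r
    return r_star, convergence_trial(r_star)


def convergence_trial(r_star: np.ndarray) -> int:
    """Smallest 1-based t such that the running MAP equals its final value from t on."""
    final = r_star[-1]
    t = len(r_star)
    while t > 1 and r_star[t - 2] == final:
        t -= 1
    return t


def build_targets(block: BlockRecord, p: float, delta: int = 4) -> TargetChoices:
    """Construct the abruptly switching target choices for one completed block.

    The ideal observer's full-block MAP estimate of the scheduled reversal is
    delayed by ``delta`` trials (the running-MAP convergence delay) to give the
    switch trial t*; targets are the initial high-value option before t* and
    the opposite from t* on.
    """
    T = block.n_trials
    initial = block.schedule.initial_high_value
    r_star, _ = running_map(block.choices, block.rewards, p, initial)
    t_star = int(np.clip(r_star[-1] + delta, 1, T))
    targets = tuple(
        initial if k < t_star else opposite(initial) for k in range(1, T + 1)
    )
    return TargetChoices(switch_trial=t_star, choices=targets)


def behavioral_reversal_trial(choices: Sequence[str], p: float) -> BehavioralReversal:
    """MAP behavioral reversal trial from the choice-only model.

    The initial preferred option is chosen by maximum likelihood. A constant
    choice sequence carries no reversal evidence; it returns trial T with the
    degenerate flag set.
    """
    choices = list(choices)
    T = len(choices)
    if len(set(choices)) == 1:
        return BehavioralReversal(trial=T, degenerate=True)
    table = posterior(choices, None, T, p, model="behavioral")
    return BehavioralReversal(trial=int(np.argmax(table.probs)) + 1, degenerate=False)


def reversal_probability(
    choices: Sequence[str],
    rewards: Sequence[int],
    p: float,
    initial_high: str,
    horizon: Optional[int] = None,
    kind: str = "current",
) -> np.ndarray:
    """Trial-by-trial inferred reversal probability from the ideal observer.

    With candidates spanning ``[1, horizon]`` (default: the block length) and
    data up to trial k:

    * ``kind="current"`` (default): z(k) = p(r = k | data_1:k). This rises as
      no-reward evidence accumulates, peaks around the reversal and decays
      once post-reversal rewards confirm the switch — the inverted-V profile
      of reversal-probability coding across relative trials.
    * ``kind="cumulative"``: z(k) = P(r <= k | data_1:k), the (monotone)
      posterior mass that the reversal has already occurred.
    * ``kind="final"``: z(k) = p(r = k | data_1:T), the full-block posterior
      evaluated at trial k — the sharpest inverted-V, usable post hoc.
    """
    choices = list(choices)
    T = len(choices)
    horizon = T if horizon is None else horizon
    pre, post = _log_factors(choices, rewards, p, initial_high)
    if kind == "final":
        loglik = _loglik_over_candidates(pre, post, horizon)
        return _posterior_from_loglik(loglik)[:T]
    z = np.empty(T)
    for k in range(1, T + 1):
        loglik = _loglik_over_candidates(pre[:k], post[:k], horizon)
        probs = _posterior_from_loglik(loglik)
        z[k - 1] = probs[k - 1] if kind == "current" else probs[:k].sum()
    return z


def simulate_target_block(
    config, rng: np.random.Generator, delta: int = 4
) -> BlockRecord:
    """Simulate one block whose choices follow the constructed Bayesian targets.

    Mirrors the training scheme: a first pass perseverates on the initial
    high-value option to collect reward outcomes, the full-block ideal-observer
    MAP defines the switch trial t* = r*_T + delta, and the final block applies
    the same rewarded-choice draws to the abruptly switching choice sequence.
    """
    schedule = sample_schedule(config, rng)
    T = config.n_trials
    rewarded = [
        sample_rewarded_choice(schedule, k, config.reward_prob, rng)
        for k in range(1, T + 1)
    ]
    initial = schedule.initial_high_value
    pass1_choices = [initial] * T
    pass1_rewards = [int(c == r) for c, r in zip(pass1_choices, rewarded)]
    r_star, _ = running_map(pass1_choices, pass1_rewards, config.reward_prob, initial)
    t_star = int(np.clip(r_star[-1] + delta, 1, T))
    trials = []
    for k in range(1, T + 1):
        c = initial if k < t_star else opposite(initial)
        ftype, rw = feedback_for(c, rewarded[k - 1])
        trials.append(
            TrialRecord(
                trial=k, choice=c, rewarded_choice=rewarded[k - 1],
                reward=rw, feedback_type=ftype,
            )
        )
    return BlockRecord(schedule=schedule, trials=trials)


class BayesTargetPolicy:
    """Online choice policy that mimics the Bayesian target behavior.

    Chooses the initial high-value option until the current trial reaches the
    running ideal-observer MAP estimate plus ``delta`` trials, then switches
    abruptly (and permanently) to the other option.
    """

    def __init__(self, initial_high: str, p: float, delta: int = 4):
        self.initial_high = initial_high
        self.p = p
        self.delta = delta
        self._switched_at: Optional[int] = None

    def __call__(self, history) -> str:
        k = len(history) + 1
        if self._switched_at is not None:
            return opposite(self.initial_high)
        if history:
            choices = [t.choice for t in history]
            rewards = [t.reward for t in history]
            r_star, _ = running_map(choices, rewards, self.p, self.initial_high)
            if k >= r_star[-1] + self.delta:
                self._switched_at = k
                return opposite(self.initial_high)
        return self.initial_high
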