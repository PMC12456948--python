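"""Across-trial analyses of reversal-probability activity.

All analyses operate on projections of population activity onto the
reversal-probability task vector, re-indexed by trial relative to each
block's behavioral reversal (relative trial 0). The core object is the
reward-integration equation

    x^{k+1}(t) = x^k(t) + R^{+/-}_k(t)

whose update terms are block-averaged adjacent-trial differences of the
projection, stratified by trial-k reward outcome. Around it sit the
line-attractor diagnostics: within-trial time derivatives, the AR(1)
contraction factor of mean-centered activity on short windows, and
separability statistics of the update terms and mean trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AlignedSubspaceActivity",
    "UpdateTerms",
    "align_to_reversal",
    "update_terms",
    "predict_integration",
    "time_derivative",
    "contraction_factor",
    "separability_stats",
    "SeparabilityStats",
]


@dataclass
class AlignedSubspaceActivity:
    """Subspace activity aligned to the behavioral reversal.

    ``x[block, j, time]`` with relative trial ``rel_trials[j]`` running from
    -K to K (0 = behavioral reversal). Relative trials outside a block are
    NaN with ``valid`` False; ``rewards`` holds the trial's reward bit.
    """

    x: np.ndarray
    valid: np.ndarray
    rewards: np.ndarray
    rel_trials: np.ndarray
    time_axis: np.ndarray
    reversal_trials: np.ndarray
    n_truncated: int = 0

    @property
    def K(self) -> int:
        return int(self.rel_trials.max())

    @property
    def n_blocks(self) -> int:
        return self.x.shape[0]

    def absolute_trial(self, block: int, rel: int) -> int:
        """1-based trial index of relative trial ``rel`` in ``block``."""
        return int(self.reversal_trials[block]) + rel


@dataclass
class UpdateTerms:
    """Reward-conditioned update terms of the integration equation.

    ``R_plus[j, t]`` / ``R_minus[j, t]`` are the block means of
    ``x^{k+1}(t) - x^k(t)`` over blocks rewarded / not rewarded at relative
    trial ``rel_trials[j]``; strata with no blocks are NaN with count 0.
    ``f_plus + f_minus = 1`` wherever any block contributes.
    """

    rel_trials: np.ndarray  # length 2K (source trial k of each update)
    R_plus: np.ndarray
    R_minus: np.ndarray
    n_plus: np.ndarray
    n_minus: np.ndarray
    time_axis: np.ndarray

    @property
    def f_plus(self) -> np.ndarray:
        tot = self.n_plus + self.n_minus
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, self.n_plus / tot, np.nan)

    @property
    def f_minus(self) -> np.ndarray:
        tot = self.n_plus + self.n_minus
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, self.n_minus / tot, np.nan)

    def to_frame(self) -> "pd.DataFrame":
        """Tidy table keyed by (relative_trial, time_bin)."""
        rows = []
        for j, rel in enumerate(self.rel_trials):
            for t, tt in enumerate(self.time_axis):
                rows.append(
                    {"relative_trial": int(rel), "time_bin": float(tt),
                     "R_plus": self.R_plus[j, t], "R_minus": self.R_minus[j, t],
                     "n_plus": int(self.n_plus[j]), "n_minus": int(self.n_minus[j])}
                )
        return pd.DataFrame(rows)

    def unconditional(self) -> np.ndarray:
        """f+ R+ + f- R- : equals the unconditional mean adjacent difference."""
        fp = self.f_plus[:, None]
        fm = self.f_minus[:, None]
        rp = np.where(np.isnan(self.R_plus), 0.0, self.R_plus)
        rm = np.where(np.isnan(self.R_minus), 0.0, self.R_minus)
        return np.where(fp > 0, fp * rp, 0.0) + np.where(fm > 0, fm * rm, 0.0)


def align_to_reversal(
    projections: Sequence[np.ndarray],
    reversal_trials: Sequence[int],
    rewards: Sequence[Sequence[int]],
    K: int = 10,
    time_axis: Optional[np.ndarray] = None,
) -> AlignedSubspaceActivity:
    """Extract [-K, K] relative-trial windows around each block's reversal.

    ``projections[b]`` is the (time, trials) projection of block ``b``;
    relative trials falling outside the block are dropped (NaN) and counted.
    """
    n_blocks = len(projections)
    if n_blocks == 0:
        raise ValueError("no blocks given")
    n_times = projections[0].shape[0]
    T = projections[0].shape[1]
    if K >= T:
        raise ValueError(f"window half-width K={K} must be smaller than the block length {T}")
    rel = np.arange(-K, K + 1)
    x = np.full((n_blocks, len(rel), n_times), np.nan)
    valid = np.zeros((n_blocks, len(rel)), dtype=bool)
    rew = np.full((n_blocks, len(rel)), np.nan)
    n_trunc = 0
    for b in range(n_blocks):
        proj = np.asarray(projections[b], dtype=float)
        rb = np.asarray(rewards[b], dtype=float)
        Tb = proj.shape[1]
        m = int(reversal_trials[b])
        for j, r in enumerate(rel):
            k = m + r  # 1-based trial index
            if 1 <= k <= Tb:
                x[b, j] = proj[:, k - 1]
                valid[b, j] = True
                rew[b, j] = rb[k - 1]
            else:
                n_trunc += 1
    if time_axis is None:
        time_axis = np.arange(n_times, dtype=float)
    return AlignedSubspaceActivity(
        x=x, valid=valid, rewards=rew, rel_trials=rel,
        time_axis=np.asarray(time_axis, dtype=float),
        reversal_trials=np.asarray(reversal_trials, dtype=int),
        n_truncated=n_trunc,
    )


def update_terms(aligned: AlignedSubspaceActivity) -> UpdateTerms:
    """Reward-stratified block means of adjacent-trial differences.

    Empty strata yield NaN with count 0 (never a silent zero).
    """
    x = aligned.x
    nb, nrel, nt = x.shape
    dx = x[:, 1:, :] - x[:, :-1, :]  # difference k -> k+1, indexed by source j
    ok = aligned.valid[:, 1:] & aligned.valid[:, :-1]
    rewarded = aligned.rewards[:, :-1] == 1
    R_plus = np.full((nrel - 1, nt), np.nan)
    R_minus = np.full((nrel - 1, nt), np.nan)
    n_plus = np.zeros(nrel - 1, dtype=int)
    n_minus = np.zeros(nrel - 1, dtype=int)
    for j in range(nrel - 1):
        sel_p = ok[:, j] & rewarded[:, j]
        sel_m = ok[:, j] & ~rewarded[:, j]
        n_plus[j] = sel_p.sum()
        n_minus[j] = sel_m.sum()
        if n_plus[j]:
            R_plus[j] = dx[sel_p, j].mean(axis=0)
        if n_minus[j]:
            R_minus[j] = dx[sel_m, j].mean(axis=0)
    return UpdateTerms(
        rel_trials=aligned.rel_trials[:-1], R_plus=R_plus, R_minus=R_minus,
        n_plus=n_plus, n_minus=n_minus, time_axis=aligned.time_axis,
    )


def predict_integration(
    aligned: AlignedSubspaceActivity,
    terms: UpdateTerms,
    t_index: int,
) -> pd.DataFrame:
    """Integrate the reward-update equation per block and score it.

    The prediction anchors at the first valid relative trial of each block's
    window (set to the actual value there) and accumulates the
    outcome-selected update terms; accuracy is the Pearson correlation
    between predicted and actual values across the block's valid trials
    (NaN when fewer than 3 trials or a constant series).
    """
    x = aligned.x[:, :, t_index]
    nb, nrel = x.shape
    rows = []
    for b in range(nb):
        idx = np.flatnonzero(aligned.valid[b])
        if len(idx) < 2:
            rows.append({"block": b, "accuracy": np.nan, "n_trials": len(idx)})
            continue
        pred = np.full(nrel, np.nan)
        pred[idx[0]] = x[b, idx[0]]
        for j in range(idx[0], idx[-1]):
            if not aligned.valid[b, j + 1] or np.isnan(pred[j]):
                continue
            R = terms.R_plus if aligned.rewards[b, j] == 1 else terms.R_minus
            pred[j + 1] = pred[j] + R[j, t_index]
        sel = ~np.isnan(pred) & aligned.valid[b]
        acc = np.nan
        if sel.sum() >= 3 and np.ptp(x[b, sel]) > 0 and np.ptp(pred[sel]) > 0:
            acc = float(stats.pearsonr(pred[sel], x[b, sel]).statistic)
        rows.append(
            {"block": b, "accuracy": acc, "n_trials": int(sel.sum()),
             "predicted": pred, "actual": np.where(aligned.valid[b], x[b], np.nan)}
        )
    return pd.DataFrame(rows)


def time_derivative(x: np.ndarray, step: float) -> np.ndarray:
    """dx/dt along the last axis: central differences inside, one-sided edges.

    ``step`` is the sample spacing in ms, so units are (x units)/ms.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 3:
        raise ValueError("need at least 3 time points")
    return np.gradient(x, step, axis=-1)


def contraction_factor(x: np.ndarray, L: int) -> tuple[np.ndarray, np.ndarray]:
    """AR(1) coefficient of mean-centered activity on length-L windows.

    The n-th window covers samples [nL, (n+1)L] (L+1 points, consecutive
    windows share an endpoint). With z the window-mean-centered signal, the
    factor is the no-intercept OLS slope of z(t+1) on z(t):

        a = sum_t z(t) z(t+1) / sum_t z(t)^2 ,  t = 0..L-1.

    a < 1 indicates contraction toward the window mean, a > 1 expansion.
    Returns (factors, window start indices); an identically-constant window
    raises (zero denominator).
    """
    x = np.asarray(x, dtype=float)
    if L < 2:
        raise ValueError("window length L must be at least 2")
    n_win = (len(x) - 1) // L
    if n_win < 1:
        raise ValueError("signal shorter than one window")
    factors = np.empty(n_win)
    starts = np.empty(n_win, dtype=int)
    for n in range(n_win):
        seg = x[n * L : (n + 1) * L + 1]
        z = seg - seg.mean()
        denom = float(np.dot(z[:-1], z[:-1]))
        if denom == 0.0:
            raise ZeroDivisionError(f"degenerate (constant) window at start {n * L}")
        factors[n] = float(np.dot(z[:-1], z[1:])) / denom
        starts[n] = n * L
    return factors, starts


@dataclass
class SeparabilityStats:
    """Separability of reversal-probability trajectories across trials."""

    frac_positive: np.ndarray    # fraction of relative trials with R+ + R- > 0, per time
    spearman_pre: np.ndarray     # rank corr of mean trajectories vs trial order, pre-reversal
    spearman_post: np.ndarray    # same post-reversal, against descending trial order
    slope_plus: np.ndarray       # time-slope of R+ per relative trial over the ramp window
    slope_minus: np.ndarray
    ramp_window: tuple[int, int]


def separability_stats(
    terms: UpdateTerms,
    aligned: AlignedSubspaceActivity,
    ramp_window: Optional[tuple[int, int]] = None,
) -> SeparabilityStats:
    """Sign, ordering and ramping statistics of the update terms.

    Pre-reversal Spearman correlations are computed against ascending trial
    order, post-reversal against descending order (post-reversal mean
    trajectories decrease across trials when activity is separable, so both
    conventions yield +1 for perfectly ordered trajectories). The ramp
    window (sample index range, default: full trial) is where the time-slope
    of the update terms is measured.
    """
    nt = len(terms.time_axis)
    S = terms.R_plus + terms.R_minus  # NaN where either stratum is missing
    with np.errstate(invalid="ignore"):
        frac_positive = np.array([
            np.mean(S[~np.isnan(S[:, t]), t] > 0) if np.any(~np.isnan(S[:, t])) else np.nan
            for t in range(nt)
        ])
    mean_traj = np.nanmean(np.where(aligned.valid[:, :, None], aligned.x, np.nan), axis=0)
    rel = aligned.rel_trials
    pre = rel < 0
    post = rel > 0
    spearman_pre = np.full(nt, np.nan)
    spearman_post = np.full(nt, np.nan)
    for t in range(nt):
        if pre.sum() >= 3:
            spearman_pre[t] = stats.spearmanr(rel[pre], mean_traj[pre, t]).statistic
        if post.sum() >= 3:
            spearman_post[t] = stats.spearmanr(-rel[post], mean_traj[post, t]).statistic
    if ramp_window is None:
        ramp_window = (0, nt)
    lo, hi = ramp_window
    tt = terms.time_axis[lo:hi]
    def slope(R):
        out = np.full(R.shape[0], np.nan)
        for j in range(R.shape[0]):
            y = R[j, lo:hi]
            if not np.any(np.isnan(y)):
                out[j] = np.polyfit(tt, y, 1)[0]
        return out
    return SeparabilityStats(
        frac_positive=frac_positive,
        spearman_pre=spearman_pre,
        spearman_post=spearman_post,
        slope_plus=slope(terms.R_plus),
        slope_minus=slope(terms.R_minus),
        ramp_window=ramp_window,
    )
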