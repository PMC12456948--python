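"""End-to-end experiment recipes combining the library modules.

Each function runs one self-contained experiment from scratch — simulate or
train, analyze, summarize — and is shared by the example scripts, the test
suite and the acceptance script. All randomness flows from an explicit
integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import bayes, decoding, reversal, rnn, svr, synth, task, tdr, train
from .config import derive_seed

__all__ = [
    "convergence_delay_experiment",
    "no_reward_fraction_experiment",
    "train_reference_network",
    "reward_rate_experiment",
    "collect_rnn_session",
    "rnn_task_vectors",
    "align_rnn_projection",
    "tdr_recovery_experiment",
    "integration_prediction_experiment",
    "svr_null_comparison_experiment",
    "decoding_experiment",
    "perturbation_direction_experiment",
]


def convergence_delay_experiment(
    seed: int, n_blocks: int = 2000, T: int = 24, p: float = 0.7, delta: int = 4
) -> dict:
    """Median running-MAP convergence delay over Bayesian-target-policy blocks.

    For each simulated block the ideal observer's running MAP is computed
    after every trial; the convergence trial is the earliest trial from
    which it permanently equals the final MAP, and the reported statistic is
    the median offset of that trial from the final MAP estimate.
    """
    rng = np.random.default_rng(seed)
    cfg = task.TaskConfig(n_trials=T, reward_prob=p)
    delays = np.empty(n_blocks)
    for i in range(n_blocks):
        block = bayes.simulate_target_block(cfg, rng, delta=delta)
        r_star, conv = bayes.running_map(
            block.choices, block.rewards, p, block.schedule.initial_high_value
        )
        delays[i] = conv - r_star[-1]
    return {
        "median_delay": float(np.median(delays)),
        "mean_delay": float(delays.mean()),
        "n": n_blocks,
    }


def no_reward_fraction_experiment(
    seed: int,
    n_blocks: int = 2000,
    T: int = 36,
    p: float = 0.7,
    delta: int = 4,
    rel_range: tuple[int, int] = (-12, -6),
) -> dict:
    """Fraction of unrewarded trials well before the behavioral reversal.

    Blocks follow the constructed Bayesian-target policy; trials are aligned
    to each block's behavioral reversal (choice-only MAP) and the no-reward
    fraction is pooled over relative trials in ``rel_range``.
    """
    rng = np.random.default_rng(seed)
    cfg = task.TaskConfig(n_trials=T, reward_prob=p)
    no_rew = tot = 0
    lags = []
    for _ in range(n_blocks):
        block = bayes.simulate_target_block(cfg, rng, delta=delta)
        br = bayes.behavioral_reversal_trial(block.choices, p)
        lags.append(br.trial - block.schedule.scheduled_reversal)
        for tr in block.trials:
            rel = tr.trial - br.trial
            if rel_range[0] <= rel <= rel_range[1]:
                tot += 1
                no_rew += 1 - tr.reward
    return {
        "no_reward_fraction": no_rew / tot,
        "n_trials": tot,
        "median_lag": float(np.median(lags)),
        "n": n_blocks,
    }


def train_reference_network(
    seed: int,
    N: int = 200,
    T_train: int = 24,
    n_epochs: int = 300,
    batch_size: int = 32,
    g: float = 2.0,
    act_a: float = 6.0,
    baseline_input: float = 1.0,
    success_threshold: float = 0.65,
    lr_decay_every: int = 12,
    n_attempts: int = 1,
    verbose: bool = False,
) -> tuple[rnn.RNNBundle, rnn.StimulusBank, train.TrainResult]:
    """Train one desk-scale network on the task with the supervised scheme.

    With ``n_attempts > 1``, fresh initializations are trained from derived
    seeds and the network with the best reward on a small held-out
    validation set (50 evaluation-length blocks, disjoint by seed from any
    final evaluation) is kept — training continues "until success", so a
    clearly failed initialization is replaced.
    """
    cfg = task.TaskConfig(n_trials=T_train, reward_prob=0.7)
    tc = train.TrainConfig(
        n_epochs=n_epochs, batch_size=batch_size,
        success_threshold=success_threshold, lr_decay_every=lr_decay_every,
    )
    best, best_score = None, -np.inf
    for attempt in range(n_attempts):
        attempt_seed = seed if attempt == 0 else derive_seed(seed, f"attempt{attempt}")
        rng = np.random.default_rng(attempt_seed)
        bundle = rnn.init_bundle(N, rng, g=g, act_a=act_a)
        stimuli = rnn.make_stimuli(N, rng, base=baseline_input)
        result = train.train(bundle, stimuli, cfg, tc, rng, verbose=verbose)
        if n_attempts > 1:
            val_cfg = task.TaskConfig(n_trials=36, reward_prob=0.7)
            val = train.evaluate(
                bundle=result.bundle, stimuli=stimuli, task_config=val_cfg,
                n_blocks=50, rng=np.random.default_rng(derive_seed(seed, "validation")),
            )
            score = val.reward_rate
        else:
            score = result.final_reward_rate
        if best is None or score > best_score:
            best, best_score = (result.bundle, stimuli, result), score
        if result.success:
            break
    return best


def reward_rate_experiment(
    seed: int,
    n_eval_blocks: int = 200,
    T_test: int = 36,
    trained: Optional[tuple] = None,
    **train_kwargs,
) -> dict:
    """Train a network and measure its reward rate on held-out long blocks."""
    if trained is None:
        bundle, stimuli, result = train_reference_network(seed, **train_kwargs)
    else:
        bundle, stimuli, result = trained
    rng = np.random.default_rng(derive_seed(seed, "evaluate"))
    cfg = task.TaskConfig(n_trials=T_test, reward_prob=0.7)
    ev = train.evaluate(bundle, stimuli, cfg, n_eval_blocks, rng)
    return {
        "reward_rate": ev.reward_rate,
        "train_epochs": result.n_epochs_run,
        "train_reward_rate": result.final_reward_rate,
        "median_lag": float(np.median(ev.reversal_lags)) if len(ev.reversal_lags) else np.nan,
        "n_degenerate": ev.n_degenerate,
        "summary": ev,
    }


def collect_rnn_session(
    bundle: rnn.RNNBundle,
    stimuli: rnn.StimulusBank,
    n_blocks: int,
    rng: np.random.Generator,
    T: int = 36,
    p: float = 0.7,
    timing: Optional[rnn.TrialTiming] = None,
) -> tuple[tdr.ActivityTensor, list[task.BlockRecord]]:
    """Simulate blocks and assemble the firing-rate tensor plus trial table.

    The tensor stacks all trials of all blocks on the trial axis (time axis:
    ms from trial start). The trial table carries the task variables used by
    targeted dimensionality reduction — inferred reversal probability from
    the ideal observer, signed choice, reward, trial number — plus each
    block's behavioral reversal.
    """
    timing = rnn.TrialTiming() if timing is None else timing
    cfg = task.TaskConfig(n_trials=T, reward_prob=p)
    tensors, rows, blocks = [], [], []
    for b in range(n_blocks):
        schedule = task.sample_schedule(cfg, rng)
        record, rates, _, _ = rnn.run_block(bundle, stimuli, schedule, timing, cfg, rng)
        br = bayes.behavioral_reversal_trial(record.choices, p)
        record.behavioral_reversal = br.trial
        zrev = bayes.reversal_probability(
            record.choices, record.rewards, p,
            schedule.initial_high_value, horizon=T, kind="final",
        )
        tensors.append(rates.astype(np.float32))
        blocks.append(record)
        for k, tr in enumerate(record.trials):
            rows.append(
                {
                    "block": b, "trial": tr.trial,
                    "reversal_prob": zrev[k],
                    "choice": 1.0 if tr.choice == "A" else -1.0,
                    "reward": float(tr.reward),
                    "trial_number": float(tr.trial),
                    "behavioral_reversal": br.trial,
                    "degenerate": br.degenerate,
                }
            )
    values = np.concatenate(tensors, axis=2)
    time_axis = np.arange(timing.n_steps) * timing.dt
    tensor = tdr.ActivityTensor(
        values=values, time_axis=time_axis, source="rnn_rates",
        trial_table=pd.DataFrame(rows),
    )
    return tensor, blocks


def rnn_task_vectors(
    tensor: tdr.ActivityTensor,
    variables: Sequence[str] = ("reversal_prob", "choice", "reward", "trial_number"),
) -> tdr.TaskVectors:
    """TDR task vectors from an RNN (or synthetic) session tensor."""
    coef, bias, vars_ = tdr.regress_activity(tensor, tensor.trial_table[list(variables)])
    return tdr.orthogonalize(coef, bias, vars_)


def align_rnn_projection(
    tensor: tdr.ActivityTensor,
    vector: np.ndarray,
    K: int = 10,
    zscore: bool = True,
) -> reversal.AlignedSubspaceActivity:
    """Project a session tensor onto a task vector and align to the reversal."""
    values = tensor.values
    if zscore:
        mu = values.mean(axis=(1, 2), keepdims=True)
        sd = values.std(axis=(1, 2), keepdims=True)
        values = (values - mu) / np.where(sd > 0, sd, 1.0)
    x = tdr.project(values, vector)  # (time, total trials)
    table = tensor.trial_table
    projections, reversals, rewards = [], [], []
    for b, sub in table.groupby("block"):
        idx = sub.index.to_numpy()
        projections.append(x[:, idx])
        reversals.append(int(sub["behavioral_reversal"].iloc[0]))
        rewards.append(sub["reward"].to_numpy())
    return reversal.align_to_reversal(
        projections, reversals, rewards, K=K, time_axis=tensor.time_axis
    )


def desk_synth_config(
    seed: int, regressor_kind: str = "bayes_final", **overrides
) -> synth.SynthConfig:
    """Desk-scale synthetic-session conditions used by the property suites.

    A reduced session (150 neurons, 16 blocks of 48 trials, timeline
    [-900, 1000] ms) keeps every analysis well inside a few CPU-minutes
    while preserving the statistical structure of the full default session.
    """
    kw = dict(
        n_neurons=150, n_blocks=16, trials_per_block=48, reversal_halfwidth=8,
        t_start=-900.0, t_end=1000.0, seed=seed, regressor_kind=regressor_kind,
    )
    kw.update(overrides)
    return synth.SynthConfig(**kw)


def _session_tdr_aligned(config: synth.SynthConfig, seed: int, K: int,
                         shuffle_planted_rewards: bool = False):
    session = synth.generate_session(
        config, rng=np.random.default_rng(seed),
        shuffle_planted_rewards=shuffle_planted_rewards,
    )
    tv = rnn_task_vectors(session.tensor, variables=synth.VARIABLES)
    aligned = align_rnn_projection(session.tensor, tv.vector("reversal_prob"), K=K)
    return session, tv, aligned


def tdr_recovery_experiment(
    seed: int, config: Optional[synth.SynthConfig] = None
) -> dict:
    """Cosine similarity between planted and recovered coding vectors."""
    config = desk_synth_config(seed) if config is None else config
    session = synth.generate_session(config, rng=np.random.default_rng(seed))
    tv = rnn_task_vectors(session.tensor, variables=synth.VARIABLES)
    out = {}
    for v in synth.VARIABLES:
        w = tv.vector(v, orthogonal=False)
        out[f"cosine_{v}"] = float(
            abs(np.dot(w, session.truth.coding[v])) / np.linalg.norm(w)
        )
    out["session"] = session
    out["task_vectors"] = tv
    return out


def integration_prediction_experiment(
    seed: int,
    config: Optional[synth.SynthConfig] = None,
    K: int = 10,
    t_probe: float = 0.0,
    shuffle_outcomes: bool = False,
    session_and_aligned: Optional[tuple] = None,
) -> dict:
    """Reward-integration prediction accuracy on a planted-structure session.

    The session plants a leaky reward-integration walk as its
    reversal-probability structure; the experiment recovers the coding
    vector by TDR, aligns the projection to the behavioral reversal,
    estimates the reward-conditioned update terms and integrates them per
    block from the window's first trial. Accuracy is the per-block Pearson
    correlation at the probe time (cue onset by default). With
    ``shuffle_outcomes`` the planted walk integrates a within-block
    permutation of the rewards instead of the rewards the analysis
    conditions on, severing the outcome/activity correspondence — the
    analysis pipeline itself is unchanged.
    """
    if session_and_aligned is None:
        config = (
            desk_synth_config(seed, regressor_kind="integration_walk")
            if config is None else config
        )
        session, _, aligned = _session_tdr_aligned(
            config, seed, K, shuffle_planted_rewards=shuffle_outcomes
        )
    else:
        session, aligned = session_and_aligned
    terms = reversal.update_terms(aligned)
    t_index = int(np.argmin(np.abs(aligned.time_axis - t_probe)))
    table = reversal.predict_integration(aligned, terms, t_index)
    acc = table["accuracy"].to_numpy(dtype=float)
    return {
        "median_accuracy": float(np.nanmedian(acc)),
        "accuracies": acc,
        "aligned": aligned,
        "terms": terms,
        "session": session,
    }


def svr_null_comparison_experiment(
    seed: int,
    config: Optional[synth.SynthConfig] = None,
    n_train_blocks: int = 8,
    n_repeats: int = 5,
    K: int = 10,
    max_cv_samples: int = 1200,
    session_and_aligned: Optional[tuple] = None,
) -> dict:
    """SVR trajectory generation vs the shuffled-initial-state null."""
    if session_and_aligned is None:
        config = desk_synth_config(seed) if config is None else config
        session, _, aligned = _session_tdr_aligned(config, seed, K)
    else:
        session, aligned = session_and_aligned
    split = svr.split_trials(aligned)
    table = svr.evaluate(
        split, n_train_blocks=n_train_blocks, n_repeats=n_repeats,
        rng=np.random.default_rng(derive_seed(seed, "svr")),
        max_cv_samples=max_cv_samples,
    )
    wins = table["model_wins"].to_numpy()
    return {
        "fraction_model_wins": float(wins.mean()),
        "n_trials": len(table),
        "median_nmse_model": float(np.nanmedian(table["mse_model"])),
        "median_nmse_null": float(np.nanmedian(table["mse_null"])),
        "table": table,
    }


def decoding_experiment(
    seed: int,
    aligned: Optional[reversal.AlignedSubspaceActivity] = None,
    t0: float = 0.0,
    dk: int = 10,
    n_repeats: int = 20,
    shuffle_labels: bool = False,
    config: Optional[synth.SynthConfig] = None,
) -> dict:
    """LDA decoding of the reversal trial from reversal-probability activity.

    Without a precomputed aligned projection, a session with a planted
    stereotyped inverted-V (peaked at the behavioral reversal) is generated
    and analyzed from scratch.
    """
    if aligned is None:
        config = (
            desk_synth_config(seed, regressor_kind="stereotyped_v")
            if config is None else config
        )
        _, _, aligned = _session_tdr_aligned(config, seed, K=dk)
    ds = decoding.build_decoder_dataset(aligned, t0=t0, dk=dk)
    table = decoding.decode_reversal(
        ds, n_repeats=n_repeats,
        rng=np.random.default_rng(derive_seed(seed, "decoding")),
        shuffle_labels=shuffle_labels,
    )
    acc = table.loc[~table["skipped"], "accuracy"].to_numpy(dtype=float)
    return {
        "mean_accuracy": float(np.nanmean(acc)),
        "chance": 1.0 / ds.n_classes,
        "n_classes": ds.n_classes,
        "table": table,
    }


def perturbation_direction_experiment(
    trained: Sequence[tuple[rnn.RNNBundle, rnn.StimulusBank]],
    seed: int,
    n_blocks: int = 20,
    strengths: Sequence[float] = (2.0, 4.0),
    trial_offset: int = -1,
    T: int = 36,
    n_tdr_blocks: int = 20,
) -> pd.DataFrame:
    """Perturb trained networks along their reversal-probability vectors.

    For every trained network the reversal-probability and choice population
    vectors are derived by TDR from its own activity; v_plus/v_minus/v_rnd
    perturbations at each strength are applied near the behavioral reversal,
    and the per-block reversal-trial shifts are tabulated.
    """
    frames = []
    for i, (bundle, stimuli) in enumerate(trained):
        rng = np.random.default_rng(derive_seed(seed, f"perturb{i}"))
        tensor, _ = collect_rnn_session(bundle, stimuli, n_tdr_blocks, rng, T=T)
        table = tensor.trial_table
        if table["degenerate"].mean() > 0.5:
            # network never reverses; no behavioral reversal to perturb
            continue
        variables = [
            v for v in ("reversal_prob", "choice", "reward", "trial_number")
            if np.ptp(table[v].to_numpy()) > 0
        ]
        if "reversal_prob" not in variables:
            continue
        tv = rnn_task_vectors(tensor, variables=variables)
        # the perturbation stimulus is the raw (unnormalized) coefficient
        # vector, whose scale is commensurate with the other inputs; the
        # orthonormal vectors are used only to read projections out
        v_rev = tv.vector("reversal_prob", orthogonal=False)
        v_choice = (
            tv.vector("choice") if "choice" in variables
            else np.zeros(bundle.N)
        )
        specs = [
            rnn.PerturbSpec(direction=d, strength=s, trial_offset=trial_offset)
            for s in strengths
            for d in ("v_plus", "v_minus", "v_rnd")
        ]
        cfg = task.TaskConfig(n_trials=T, reward_prob=0.7)
        df = rnn.perturbation_experiment(
            bundle, stimuli, rnn.TrialTiming(), cfg,
            v_rev, v_choice, specs, n_blocks, rng,
        )
        df["network"] = i
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
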