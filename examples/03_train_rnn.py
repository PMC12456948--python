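"""Train a small inhibitory RNN on the reversal task (abridged run).

A 100-neuron network is trained for 120 epochs with the supervised scheme:
roll a batch of blocks closed-loop, infer each block's scheduled reversal
with the ideal observer, build target choices that switch 4 trials later,
and backpropagate the summed cross-entropy through the full rollout. The
desk-scale reference run (N=200, 300 epochs) is what scripts/acceptance.py
uses; this abridged run finishes in about a minute.
"""
import numpy as np

from revdyn import task, train, workflows

bundle, stimuli, result = workflows.train_reference_network(
    seed=3, N=100, n_epochs=120
)
print(f"epochs run:        {result.n_epochs_run}")
print(f"loss:              {result.loss_curve[0]:.2f} -> {result.loss_curve[-1]:.2f}"
      f"   (confident errors near the reversal keep the summed CE near {24*np.log(2):.1f})")
print(f"train reward rate: {result.final_reward_rate:.3f}")

cfg = task.TaskConfig(n_trials=36, reward_prob=0.7)
ev = train.evaluate(bundle, stimuli, cfg, 100, np.random.default_rng(1))
print(f"eval reward rate (100 blocks, T=36): {ev.reward_rate:.3f}")
print(f"behavioral lag (median):             {np.median(ev.reversal_lags):+.0f} trials")
sl = slice(8, 17)
print("P(choose initial best) around reversal:",
      np.round(ev.p_initial_best[sl], 2), "(relative trials -4..+4)")
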