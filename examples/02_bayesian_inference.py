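"""Ideal-observer inference of the scheduled reversal in one block.

Shows the running MAP estimate converging as evidence accumulates, and the
abruptly switching target choices built from it.
"""
import numpy as np

from revdyn import bayes, task

rng = np.random.default_rng(3)
cfg = task.TaskConfig(n_trials=24, reward_prob=0.7, reversal_halfwidth=5)
block = bayes.simulate_target_block(cfg, rng, delta=4)

r_star, conv = bayes.running_map(
    block.choices, block.rewards, 0.7, block.schedule.initial_high_value
)
targets = bayes.build_targets(block, 0.7, delta=4)
zrev = bayes.reversal_probability(
    block.choices, block.rewards, 0.7,
    block.schedule.initial_high_value, kind="final",
)

print("choices:           ", "".join(block.choices))
print("rewards:           ", "".join(map(str, block.rewards)))
print("scheduled reversal:", block.schedule.scheduled_reversal)
print("running MAP r*_t:  ", r_star)
print("final MAP / converged from trial:", r_star[-1], "/", conv)
print("target switch trial (MAP + 4):   ", targets.switch_trial)
print("reversal-probability regressor peaks at trial", int(np.argmax(zrev)) + 1)
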