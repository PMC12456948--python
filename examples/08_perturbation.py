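"""Perturb the reversal-probability subspace of a trained RNN.

The raw reversal-probability population vector (from TDR on the network's
own activity) is injected during the cue window one trial before the
behavioral reversal, alongside its negation (v_minus) and a random
direction of matched element scale (v_rnd). The table reports how each
stimulus shifts the behavioral reversal trial; effect sizes vary strongly
across networks at this abridged training scale, so ensemble statistics
(ten networks or more) are needed for directional conclusions.
"""
from revdyn import workflows

bundle, stimuli, _ = workflows.train_reference_network(seed=3, N=100, n_epochs=120)
df = workflows.perturbation_direction_experiment(
    [(bundle, stimuli)], seed=5, n_blocks=20, strengths=(2.0, 4.0), trial_offset=-1
)
print(df.groupby(["direction", "strength"])["shift"].agg(["mean", "median"]))
print("negative shift = earlier behavioral reversal")
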