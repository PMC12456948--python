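"""Decode the behavioral reversal trial from reversal-probability activity.

A linear discriminant reads 17-bin windows of the projection around cue
onset for the 21 trials around the reversal; a test block's predicted
reversal is its highest-posterior trial for the reversal class. Chance is
1/21; label-shuffled decoding sits at chance.
"""
from revdyn import workflows

out = workflows.decoding_experiment(seed=7, n_repeats=20)
shuf = workflows.decoding_experiment(seed=7, n_repeats=20, shuffle_labels=True)
print(f"classes (relative trials):     {out['n_classes']}   chance = {out['chance']:.3f}")
print(f"decoding accuracy:             {out['mean_accuracy']:.3f}")
print(f"label-shuffled accuracy:       {shuf['mean_accuracy']:.3f}")
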