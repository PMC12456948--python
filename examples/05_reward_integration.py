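"""Predict reversal-probability activity across trials by integrating rewards.

On a session with a planted reward-integration walk, the update equation
x^{k+1} = x^k + R+/- (block-averaged adjacent-trial differences conditioned
on the reward outcome) predicts each block's activity at cue onset. A
control session whose planted walk integrates shuffled rewards shows how
much of the accuracy depends on the outcome/activity correspondence.
"""
from revdyn import workflows

out = workflows.integration_prediction_experiment(seed=7)
shuf = workflows.integration_prediction_experiment(seed=7, shuffle_outcomes=True)
print(f"median per-block Pearson accuracy:   {out['median_accuracy']:.3f}")
print(f"with outcome-shuffled planting:      {shuf['median_accuracy']:.3f}")
t = out["terms"]
import numpy as np
ti = int(np.argmin(np.abs(t.time_axis)))
print(f"mean R- (no reward) at cue onset:    {np.nanmean(t.R_minus[:, ti]):+.3f}  (pushes activity up)")
print(f"mean R+ (reward) at cue onset:       {np.nanmean(t.R_plus[:, ti]):+.3f}  (pulls activity down)")
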