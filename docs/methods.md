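# Methods

`revdyn` implements a complete computational pipeline for studying how
recurrent networks and cortex-like populations represent the probability
that a reward reversal has occurred: the probabilistic reversal-learning
task, Bayesian change-point observers, a continuous-time inhibitory rate
network trained to mimic the Bayesian strategy, a synthetic cortical-data
generator, and the population analyses (targeted dimensionality reduction,
reward integration, contraction factors, trajectory generation, decoding,
subspace perturbation).

## Task

A block consists of `T` trials with two options A and B. One option is
high-value: its "rewarded choice" indicator comes up with probability
`p = 0.7` per trial (the other option with `1 - p`). At a scheduled
reversal trial, uniform on the inclusive window `[T/2 - h, T/2 + h]`
(`h = 5` for RNN blocks, so 11 candidate trials), the roles switch. An
agent's reward bit is 1 exactly when its choice equals the drawn rewarded
choice, and the (choice, reward) pair is encoded in one of four feedback
types A1/A0/B0/B1. Training blocks default to `T = 24` and evaluation
blocks to `T = 36`; trial indices are 1-based.

## Bayesian observers

Both observers place a flat prior over candidate reversal trials
`r ∈ [1, t]` and multiply per-trial likelihood factors that are `p` when
the observation is consistent with the assumed regime and `1 - p`
otherwise. The **ideal observer** uses choices and rewards and knows which
option was initially high-value; the **behavioral model** uses choices only
and assumes the preferred choice flips at the behavioral reversal. All
computation is in log space with max-subtraction, so blocks of hundreds of
trials are safe at any `p ∈ (0, 1)`; MAP ties break toward the smallest
candidate, which makes results order-independent.

The **running MAP** `r*_t` is the posterior argmax given data up to trial
`t`; its convergence trial is the earliest trial from which it permanently
equals the final estimate `r*_T`. Target choices for network training
switch abruptly at `t* = r*_T + δ` with `δ = 4` — the delay models the few
trials of post-reversal evidence an observer needs, and matches the
behavioral lag of primates on this task. Empirically the literal
convergence-trial statistic has median offset ≈ 0 from `r*_T`, because the
running MAP "climbs" along the diagonal pre-reversal and happens to pass
through its final value exactly at `r*_T`; `δ = 4` is therefore treated as
a design margin, not an estimate of that statistic.

**Reversal-probability regressor.** Analyses need a per-trial scalar
"inferred reversal probability". Three definitions are implemented:
`current` (`p(r = k | data up to k)`), `cumulative`
(`P(r ≤ k | data up to k)`, monotone), and the default `final`
(`p(r = k | full block)`): the full-block posterior is the sharpest
inverted-V across trials, peaking at the inferred reversal, and is the
standard post-hoc regressor in the primate literature. The cumulative
variant cannot produce the inverted-V (it saturates at 1), which is why it
is not the default.

**Bayesian-target blocks** (used for the behavioral statistics) are built
in two passes mirroring the training scheme: perseverate on the initial
option to collect rewards, run the ideal observer on the full block, then
replay the same rewarded-choice draws against choices that switch at
`r*_T + δ`. A purely online greedy rule (switch when `k ≥ r*_t + δ`)
switches prematurely whenever the evidence walk stalls and is not used.

## Recurrent network

Dynamics: `τ du/dt = -u + W_rec φ(u) + I_base + I_cue + I_feedback` with
`τ = 20 ms`, sigmoidal activation `φ(x) = 1/(1+e^-(ax+b))` and readout
`z = w_out · φ(u)`. `W_rec` is purely inhibitory (entries ≤ 0, zero
diagonal) on a fixed random mask with connection probability 0.1; constant
excitatory baseline input balances the recurrent inhibition. Each 500 ms
trial presents the previous trial's feedback vector on [0, 300) ms and the
go cue on [250, 300) ms (overlapping); the choice is the sign of the
readout averaged over [350, 400) ms (ties to A), passed through the
symmetrized softmax `(e^z, e^-z)/Σ` for probabilities. The state carries
over between trials — the only way multi-trial evidence can persist, since
`τ` is 25× shorter than a trial.

Free constants the source description leaves open, with the defaults used
here: activation slope `a = 6`, offset `b = 0`, weight scale
`W_ij = -|g ξ|/√(conn_prob · N)` with `g = 2`, baseline input 1.0 per
neuron, `N = 200` at desk scale, initial state `0.1 × N(0, 1)`. The slope
and coupling were chosen so the linearized recurrent gain is near unity:
with `a ≈ 1` the network is strongly contractive, the stimulus imprint
decays before the choice window, and training cannot escape the
zero-readout solution. Integration is forward Euler with `dt = 10 ms`
(= τ/2, every window edge is a multiple of dt); trial 1 has no previous
trial and receives a zero feedback vector.

The one-dimensional reduction projects the dynamics onto a task vector
`v`: `x = ⟨φ(u), v⟩`, `τ dx/dt = x_rec + x_ext` with
`x_rec = ⟨φ'(u) ⊙ (-u + W φ(u)), v⟩` (leak + recurrence through the
activation Jacobian) and `x_ext = ⟨φ'(u) ⊙ I, v⟩`. The identity holds on
every rollout up to the O(dt) Euler error; tests bound the mismatch by
`10·(dt/τ)` times the drive scale.

## Training

Each epoch simulates a batch of blocks closed-loop (the network's own
choices determine feedback), feeds every block to the ideal observer,
builds the δ-delayed targets and minimizes the summed per-trial
cross-entropy between the symmetrized softmax and the targets, optionally
plus a fixation penalty (mean squared readout on [0, 250) ms). Gradients
are exact backpropagation through every Euler step of the rollout
(hand-derived adjoint recursion in numpy); the discrete choice→feedback
pathway is treated as given, as is standard for closed-loop supervised
training. Updates use Adam (lr 1e-2) with the learning rate decayed by 0.9
every 12 epochs at desk scale (batch 32 sees ~8× less data per epoch than
the reference batch of 256, for which the decay interval is 3); after
every update `W_rec` is projected back onto the constraint set (entries
≤ 0, zero diagonal, frozen mask), so the trained network remains purely
inhibitory. Training stops at `n_epochs` (≤ 300 at desk scale) or once the
batch reward rate holds above the success threshold (0.65) for 3
consecutive epochs. The reference recipe allows a second initialization
attempt (from a derived seed) and keeps the network with the better final
*training* reward — a clearly failed initialization is replaced, but
selection never touches the evaluation metric.

**What desk-scale training achieves.** The reward-rate ceiling for *any*
agent on 36-trial evaluation blocks is ≈ 0.667, not 0.70: a perfect
Bayesian-target agent earns `p` on all trials except the ≈ 4–5 trials
between the scheduled reversal and its delayed switch, costing
`≈ 4.5 · (2p - 1)/T ≈ 0.05`. Desk-scale networks (N = 200, batch 32,
≤ 300 epochs) typically reach 0.55–0.60: they reverse abruptly (the
choice-reversal curve is sigmoidal around the behavioral reversal) but
retain a win-stay/lose-shift component — single no-reward trials sometimes
trigger a switch that full multi-trial integration would suppress. Closing
that gap appears to require far more optimization (the reference setting
is batch 256 on GPU) because credit assignment across trials must travel
through near-marginal recurrent modes that only emerge during training.

## Targeted dimensionality reduction

Activity is z-scored per neuron over all (time, trial) samples
(switchable), then each (neuron, time) is regressed by OLS-with-intercept
across trials on the task variables {reversal probability, choice, reward,
trial number}. The task vector per variable is the coefficient population
vector at the time bin of maximal L2 norm (ties → earliest bin); the
vector set is orthogonalized by QR in a fixed order with the reversal
vector first (signs fixed so each orthonormal vector correlates positively
with its raw counterpart); projections are plain dot products. Constant or
collinear regressors raise with the offending variables named; no
denoising or PCA pre-projection is applied.

## Synthetic cortical sessions

The generator emulates what the analyses assume about prefrontal data.
Behavior: a Bayesian agent switches its preferred option once the
cumulative ideal-observer posterior that the reversal has occurred exceeds
1/2, with a 2% lapse rate. The agent's prior is restricted to the
mid-block reversal window it knows from the task design — with an
unrestricted flat prior over all trials, prior mass alone crosses 1/2 at
mid-block and the agent would switch without evidence.

Rates: `rate_i(t, k) = softplus(α_i + snr · Σ_v β_i^v h_v(t) z̃^v(k))` in
Hz, with unit-norm random coding vectors `β^v`, standardized trial
variables `z̃^v`, gamma-distributed baselines (mean 8 Hz) and temporal
templates: a Gaussian bump at cue onset (σ = 300 ms) for reversal
probability, a logistic ramp through the choice epoch, a bump at reward
delivery, and a flat profile for trial number. Counts are Poisson
increments on a 20 ms grid summed over each sliding 300 ms window, so
overlapping bins share increments exactly as counts from one underlying
spike train do (equivalent in distribution to drawing the train and
counting). The default timeline is [-2600, +1000] ms around cue onset
(fixation -500, reward +800) with bin centers anchored at 0.

The default `coding_snr = 5` is the calibrated operating point at which
TDR recovers the planted reversal vector with cosine ≈ 0.85–0.9 at the
desk-scale session used throughout (150 neurons, 16 blocks × 48 trials,
timeline trimmed to [-900, +1000] ms); recovery at the full default
session (300 × 24 × 80) is comparable because the recovery error scales as
`√(neurons/trials)`. Two explicitly planted reversal structures support
recovery experiments: `stereotyped_v` (a Gaussian inverted-V centered on
the behavioral reversal, σ = 2.5 trials; used for decoding recovery) and
`integration_walk` (a leaky reward-integration walk
`z_k = 0.85 z_{k-1} + 0.3 (1 - reward_k)`; used for reward-integration
recovery, including a control where the walk integrates within-block
shuffled rewards, severing the outcome/activity correspondence while
leaving the analysis pipeline untouched).

What the generator deliberately does not model: firing-rate
nonstationarity within blocks, cross-neuron noise correlations beyond
those induced by shared coding, refractoriness or non-Poisson spiking, and
any genuine within-trial dynamics (the within-trial profile is a fixed
template). Passing recovery tests therefore shows the analyses are
correct and sensitive at a known operating point — not that cortical data
have this structure.

**Operating-point ceiling.** At recovery cosine ≈ 0.85 the single-trial
projection signal-to-noise ratio is pinned near
`√(neurons/trials)/tan(arccos 0.85) ≈ 0.7–1.3` for any reasonable session
geometry; this caps the per-block Pearson accuracy of the
reward-integration prediction near 0.55–0.65. Reaching 0.7+ would require
recovery cosine ≈ 0.95, i.e. a stronger-coding operating point than the
calibration prescribes. The acceptance suite therefore reports this
statistic honestly below 0.7 at the documented operating point.

## Across-trial analyses

All analyses align each block's projection to its behavioral reversal
(relative trial 0 = choice-only MAP), keeping a ±K window (K = 10) with
out-of-range trials dropped and counted. Update terms
`R±_k(t) = ⟨x^{k+1}(t) - x^k(t)⟩` are block means stratified by the trial-k
reward; empty strata propagate as missing values, never silent zeros, and
the exact identity `f⁺R⁺ + f⁻R⁻ = unconditional mean difference` holds
wherever strata are nonempty. The integration prediction anchors at the
first valid trial of each block's window and accumulates the
outcome-selected updates; accuracy is the per-block Pearson correlation
(undefined below 3 trials or for constant series).

Contraction factors are the no-intercept OLS slope of `z(t+1)` on `z(t)`
for window-mean-centered activity on contiguous length-L windows
(consecutive windows share an endpoint); a < 1 means contraction toward
the window mean. Time derivatives use central differences with one-sided
edges at the analysis bin step. Separability statistics report the
fraction of relative trials with `R⁺ + R⁻ > 0` per time bin, Spearman rank
correlations of the mean trajectories against ascending trial order
pre-reversal and descending order post-reversal, and time-slopes of `R±`
over a configurable ramp window.

## Trajectory generation (SVR)

Each aligned trial's trajectory on [-500, +800] ms is split exactly at
-300 ms into an 11-bin initial state and a 55-bin remaining trajectory. A
single RBF-kernel support vector regression learns
`(initial state, time index s) → x(s)`; inputs are standardized and `s` is
appended as an integer feature. Hyperparameters (C ∈ {0.1, 1, 10}, RBF
width ∈ {0.1, 1, 10} × median heuristic) are selected by block-grouped
cross-validation on a capped subsample of training rows (model selection
cost only; the winner is refit on all training rows). The null model
shuffles initial states among the trials of each block before fitting;
evaluation repeats random train/test block splits and scores each test
trial with MSE normalized by the squared per-trial amplitude
(`(max - min)²`), so the value is a squared fractional error; normalization
by the unsquared amplitude is available as an option.

## Decoding and residuals

The reversal decoder takes, per block, the 21 trials around the reversal,
each represented by 17 bins of the reversal projection around a probe time
(±160 ms at 20 ms), with class = relative-trial identity. A linear
discriminant with pooled covariance and Ledoit–Wolf shrinkage (needed when
bins approach the block count) is trained on 90% of blocks; a test block's
predicted reversal is its highest-posterior trial for the relative-trial-0
class (posteriors are normalized within each trial, so monotone codes
cannot win on magnitude alone), and chance is 1/21. The permutation null
shuffles the trial/class association within every block — train and test —
making the data exchangeable and the accuracy exactly chance in
expectation. Residual analyses subtract the across-block mean at each
(relative trial, time), average residuals over [0, 500] ms and fit the
closed-form OLS slope of choice residuals on reversal residuals across
blocks.

## Perturbation experiments

For a trained network, TDR on its own activity yields the
reversal-probability vector; the perturbation stimulus is the **raw**
(unnormalized) coefficient vector, whose scale is commensurate with the
other inputs — a unit-normalized vector produces no behavioral effect.
`v₋ = -v₊`, and `v_rnd` has Gaussian elements matched to the element SD of
`v₊`. The stimulus is added during the 50 ms cue window at the behavioral
reversal or 1–2 trials earlier, with a multiplicative strength of 0.5–4.
Paired rollouts reuse the schedule, reward draws and initial state, so the
perturbation is the only difference; the reversal-trial shift is the
difference of choice-only MAP labels. In trained desk-scale networks,
boosting the reversal signal accelerates the behavioral reversal and
suppressing it delays it relative to the random control, with effects
growing in strength — clearest at strengths ≥ 2.

## Reproducibility and problem sizes

Every experiment flows from one integer seed; per-stage seeds derive by
stable hashing so stages can re-run independently. The property suites run
on reduced problem sizes chosen as the package's desk-scale reference:
2,000 simulated blocks for behavioral statistics, one N = 200 network
(≤ 300 epochs) for reward-rate evaluation on 200 blocks, ten N = 100
networks × 20 blocks for perturbation statistics, and the 150-neuron
synthetic session above for population analyses. All are configurable
upward; the statistics they estimate are stable at these sizes except
where noted.
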