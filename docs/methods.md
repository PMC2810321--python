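# Methods

## Model overview

`opcond` simulates appetitive operant conditioning in a rate network whose
units stand for functional clusters, with 100 ms time steps. Each trial the
lever comes out (the CS), the animal may press it (response R1, rewarded with
one pellet on the following step) or do something else (R2, R3), and the
trial ends with an inter-trial interval. The shipped protocol compresses the
chamber's 60 s lever-out / 20 s inter-trial phases tenfold (60 and 20 steps);
`ProtocolConfig.faithful_steps()` restores the 600/200-step resolution.
Latencies are reported in steps × 0.1 s either way. Training runs 125 trials
(five 25-trial sessions).

### Dopamine and the plasticity gate

The VTA/SNc block is an episodic tabular TD(0) learner on a one-hot delay
line anchored at CS onset; the episode terminates at the outcome step (one
step after the response), where the reward is delivered or omitted. Its
prediction error δ(t) plays three roles: a phasic dopamine signal
`da = max(δ, 0)` broadcast to both layers, the TD weight update, and the
plasticity gate trigger. Bursts above `theta_hebb` open a Hebbian window of
`min(t_max, ceil(t_slope·δ))` steps; dips below `theta_antihebb` open a
15-step anti-Hebbian window, reflecting the slower recovery of the dopamine
pause. A new same-sign event extends an open window but never shortens it;
an opposite-sign event takes over immediately. (A pure "latest event wins"
rule lets the shrinking reward burst truncate the CS-onset window as learning
transfers dopamine responses from reward to cue, which produces a spurious
dip-then-rebound in the plasticity trajectory; the never-shorten rule removes
that artifact and changes nothing else.)

### PFC and BG-PMC

PFC drive is `W_in·stm + w_vta_pfc·da + basal_i`; dopamine inhibits the layer
(`w_vta_pfc ≤ 0`, clamped) while the D1/NMDA synergism term
`b_winner·da·afferent(winner)` excites the single most-driven unit. The
synergism is proportional to the winner's afferent (glutamatergic) drive:
with no afferent input a dopamine burst is purely inhibitory, which is the
qualitative behaviour the synergism is meant to capture. Activities pass
through a logistic squashing function onto [0, 1] and a winner-take-all mask.

Baseline rates carry fixed per-unit variability (`basal_pfc ± jitter`, drawn
once per model and floored at zero). This models heterogeneous excitability
across clusters and, mechanically, anchors the winner-take-all identity:
without it, anti-Hebbian depression of the current winner's input weight
makes the winner hop across units faster than the response layer can
consolidate credit, and the task is never learned.

BG-PMC drive combines the PFC winner (`W_pfc_bg`), an LC-gated direct
stimulus→response pathway, and the same dopamine brake/synergism. The first
response whose activity exceeds `theta_resp` during the lever-out phase is
executed (held at 1 for 5 steps); if none crosses, a uniformly random
response is forced at trial end with latency equal to the full lever-out
duration.

The direct pathway weights are constant (`direct_scale`, not plastic): the
plasticity rule is defined for the PFC and BG-PMC matrices only. Tonic LC
gain is `lc_max·(1 − reward rate over the last n_lc trials)`, so early
responding is partly carried by this noradrenergic, stimulus-driven route.
As rewards accumulate the LC support withdraws, and the model transiently
relapses until the learned PFC→BG-PMC weights are strong enough to release
the response on their own. This withdrawal-consolidation phase is where the
interior plasticity maximum comes from (see below).

### Plasticity

While the gate is open, each plastic matrix updates as
`ΔW = μ·ΔW_prev + s·ν·post·pre` with `s = ±1` (Hebbian/anti-Hebbian), and
momentum buffers persist across steps and trials. Pre/post pairs follow the
wiring: stimulus STM → post-WTA PFC activity, and post-WTA PFC activity →
response STM (with its own WTA). Weights are clipped after every step;
stimulus→PFC afferents are floored at 0 (they model excitatory glutamatergic
synapses, and an unbounded LTD drift below zero reintroduces winner-hopping),
while PFC→BG-PMC weights may go negative down to −1, which is how
never-rewarded responses end up actively suppressed.

The per-trial plasticity readout is Σ|ΔW| over steps and synapses of the
stimulus→PFC matrix (LTP and LTD magnitudes add; `include_bgpmc_in_metric`
adds the response-layer synapses if wanted). The ensemble trajectory is the
across-model mean smoothed with a centred 11-trial moving average.

## Why the trajectory peaks mid-learning

Three regimes shape the ensemble plasticity curve. Early, responses are
forced and only the occasional unpredicted reward opens short Hebbian
windows: plasticity is low while performance sits at chance (1/3). In
mid-training the LC-supported response releases start, the reward rate
climbs, LC gain withdraws, and models oscillate between responding and
relapse; omitted-reward dips during relapses open long anti-Hebbian windows
on top of the Hebbian reward and cue bursts, so plasticity is maximal
precisely while performance is intermediate. Once consolidated, every trial
is rewarded at short latency; the residual plasticity comes from the
dopamine burst that has transferred to CS onset (the trial start is not
predictable from within the trial, so this burst persists), giving a lower
but sustained plateau. The net result under the default configuration is
≈61–67% correct in a 10-trial window at trial 70, ≥97% at trial 120, a
smoothed plasticity maximum at trial ≈70–80, and a 20–27% decline from
trial 70 to trial 120 — consistent with the ≈19% drop in BDNF expression
between the incompletely trained and trained stages.

## Parameters

Defaults were chosen by grid search (`tune_parameters`, 20-model ensembles)
against the two behavioural anchors only — 65% windowed performance at trial
70 and 100% at trial 120; the plasticity peak location and decline are
emergent. The tunables that matter:

| parameter | default | meaning |
|---|---|---|
| `td.gamma` | 0.8 | discount per 100 ms step; sets the CS-onset burst amplitude γ·V |
| `td.alpha` | 0.05 | TD learning rate; sets how fast reward bursts fade |
| `td.theta_hebb` / `theta_antihebb` | +0.1 / −0.3 | gate thresholds; the dip threshold sits above the forced-phase omission dip (−1/3) so LTD is driven by consolidation-phase relapses, not by chance omissions |
| `td.t_max`, `t_slope` | 6, 5.0 | Hebbian window cap/slope (anti-Hebbian fixed at 15 steps) |
| `network.theta_resp` | 0.75 | response release threshold (logistic activity scale) |
| `network.direct_scale` | 0.45 | LC-gated direct path weight; sets how much early responding depends on LC tone |
| `network.n_lc` | 10 | trials in the LC reward window |
| `network.basal_pfc`, `basal_jitter_pfc` | 0.3, 0.15 | PFC baseline rate and fixed per-unit spread |
| `learning.mu_*`, `nu_pfc`, `nu_bgpmc` | 0.7, 5e-4, 1.3e-3 | momentum and learning rates; `nu_bgpmc` sets the consolidation speed and hence where the anchors fall |

`n_pfc = 80`, `n_resp = 3`, `response_hold_steps = 5`, weight bounds
[−1, 1] (input floor 0), and the 1/3 forced-choice fallback are structural.

## Synthetic expression data

The generator emulates normalised real-time RT-PCR readouts on the
percent-of-cage-control scale for seven genes across five groups (naive
control, two box controls, 50%CR, 100%CR), n = 6 per group, as truncated-at-
zero Gaussians with a common `noise_sd = 9` (percent units). Group means for
the learning stage are the reported increments (BDNF 131.9, CREB 131,
Synapsin I 127.4, CamKII 118.7, c-fos 126.5, c-jun 129.8, Arc 130); the
trained stage uses the vs-box-control increments where reported (CREB 114.7,
Synapsin I 116.3, CamKII 115.2, c-fos 114, c-jun 114.2) — the published
pairwise percentages for CREB and Synapsin I are mutually inconsistent at
the 1–10% level, and the vs-control anchoring is the reading we adopt. BDNF's
trained-stage mean follows the reported 18.9% drop from the learning stage
(131.9 × 0.811 = 106.97). Arc's trained-stage increment was reported as
significant without a printed percentage; 114 is assumed and flagged in the
generator. `noise_sd = 9` was calibrated once so that at n = 6 the reported
significance pattern (learning-stage increases significant by Tukey, control
groups indistinguishable) is the modal outcome.

What the generator does **not** model: raw Ct values, amplification
efficiency, β-actin normalisation mechanics, between-group heteroscedasticity
(SEM bars in real data differ by group), and any animal-to-animal
correlation structure. Passing the recovery tests therefore shows that the
analysis pipeline is correct and well-powered under the stated effect sizes
and noise — not that the biological data had these properties.

## Statistics

Groups are independent animals, so the pipeline uses a one-way
between-groups ANOVA (scipy `f_oneway`) followed by Tukey's HSD (scipy
`tukey_hsd`, cross-checked against statsmodels in the tests), at α = 0.05
and with no correction across genes, matching the original analysis choices.
Degrees of freedom follow the usual (k−1, N−k) decomposition — (4, 25) for
five groups of six. Percent changes are computed from group means of
normalised values, `100·(mean_a − mean_b)/mean_b`.

The model-vs-gene comparison anchors the smoothed ensemble plasticity at the
gene's learning-stage value at trial 70 (shape-preserving scaling, since the
model has no baseline expression parameter) and reports the discrepancy at
trial 120 against the trained-stage value, with a default pass tolerance of
10 percentage points.

## Numerical choices and degenerate inputs

Ties in every argmax (winner-take-all, response release) break toward the
lowest index; all stochastic draws come from one `numpy` Generator per model,
seeded as `base_seed + model_index`. The smoothing window renormalises at
the series edges. SEM uses ddof = 1 and is defined as 0 for a single model.
`scale_to_anchor` refuses a zero anchor; `percent_of_control` refuses a
missing or non-positive control mean; ANOVA refuses groups with fewer than
two values. Problem sizes throughout (125 trials, 100 models, 60-step
trials, n = 10,000 recovery tables) keep a full pipeline run within a couple
of minutes on one CPU.

## Known limitations

- The exact algebra of the original network's activation equations is not
  reproduced; the implementation preserves the stated qualitative structure
  (baselines, dopamine inhibition, winner synergism, thresholded release,
  saturating rates) with a logistic nonlinearity.
- The rats' latency trajectory (44 s → 4 s) is not modelled quantitatively;
  only the criterion thresholds enter the stage labels.
- Plasticity is a gated outer-product rule with momentum — no biophysical
  LTP/LTD kinetics, synaptic scaling, or homeostasis beyond weight clipping.
- The anti-Hebbian contribution concentrates in the consolidation phase; in
  a protocol without an LC-supported acquisition route the trajectory shape
  would differ.
- Expression values and simulated plasticity are linked only through the
  anchored comparison; the model has no transcription dynamics.
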