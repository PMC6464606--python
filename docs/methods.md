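# Methods

This note documents the models, the synthetic-data generators, the numerical
choices, and the limitations of `photorl`. It is written for a reader who
wants to know exactly what the package computes and what passing its tests
does and does not demonstrate about real recordings.

## Behavioral model

Choices are modelled by a two-action Q-learner with a perseveration bonus.
With `c_t` the side chosen on trial `t` (contra/ipsi relative to a nominal
recording hemisphere) and `r_t ∈ {0, 1}` the outcome:

    Q_{t+1}(c_t) = Q_t(c_t) + α (r_t − Q_t(c_t)),          0 ≤ α ≤ 1
    P(c_t = c) ∝ exp(β Q_t(c) + stay · I(c, c_{t−1}))

Only the chosen action's value updates. `I` is 1 if `c` was chosen on the
previous completed trial; on the first trial of a record the stay term
contributes to neither action. Because rewards are binary and values start at
0, every `Q_t` stays in `[0, 1]`.

Q values are initialized once per subject's concatenated multi-session
record, matching the convention of concatenating sessions for analysis; a
`reset_q_per_session` flag provides the per-session alternative. Abandoned
trials (no lever press within the deadline) update nothing, and the stay
indicator carries over the last *completed* trial's choice.

### Task simulator

Defaults are the task conditions the analysis assumes: reward probabilities
0.70/0.10; a block ends after it has accumulated 10 rewarded trials plus a
Geometric(p = 0.4) number of additional trials. The geometric draw uses
support {1, 2, …}, so its mean is 1/p = 2.5 extra trials. The extension
counter starts on the trial that delivers the 10th reward and counts **all**
trials (rewarded or not, including abandoned ones); the high side alternates
on the next trial after the extension elapses.

Event timing per trial: nose poke at the trial clock, lever presentation
after a jittered delay, lever press after a log-normal latency (median 0.5 s,
log-SD 0.5; draws past the 10 s deadline mark the trial abandoned, well under
2% at the defaults), outcome after a second jittered delay, then a 3 s
inter-trial delay. Both jittered delays are drawn uniformly from the 0.1 s
grid {0.1, …, 1.0} s — the grid starts one step above zero so that the four
event timestamps are strictly ordered, which downstream alignment code
relies on.

Per-site child seeds are spawned deterministically (`numpy.random.SeedSequence`)
from a single master seed, so any one site can be regenerated in isolation.

### Default cohort parameters

Synthetic cohorts draw subject parameters from Gaussians on the
unconstrained scales (logit α, log β, raw stay) centered at group-median
values fitted to mice on this task — α = 0.612, β = 0.990, stay = 0.945 —
with SDs set from the fitted 25th/75th percentiles (IQR/1.349):
σ(logit α) ≈ 0.182, σ(log β) ≈ 0.099, σ(stay) ≈ 0.093. At these settings
the simulated stay-trial fraction lands near the ~77% observed in mice,
which the acceptance script recomputes.

## Hierarchical model fitting

Subject parameters are random effects: `x_s ~ Normal(μ, diag(σ²))` on the
unconstrained scales, with weakly informative priors `μ_j ~ Normal(0, 1.5)`
and `σ_j ~ HalfNormal(1)`; fitted values of order α ≈ 0.6, β ≈ 1, stay ≈ 1
sit well inside this prior mass. Three backends share one JIT-compiled
likelihood:

- **per_subject_mle** — independent multi-start L-BFGS fits per site on the
  unconstrained scales.
- **hierarchical_map** — joint penalized maximum a posteriori over
  `(μ, log σ, x)`. The joint mode of this hierarchy degenerates as σ → 0, so
  the optimizer bounds `log σ` in `[log 0.02, log 2]`; the backend is
  intended for fast point estimates and initialization, not for inference on
  the group scales.
- **hierarchical_mcmc** — the default. A Gibbs sweep combining (i)
  stepping-out slice updates (Neal 2003, width 0.3) for every subject
  coordinate, (ii) a conjugate normal draw for each `μ_j`, (iii) a slice
  update for each `log σ_j`, and (iv) an interweaved non-centered (ASIS)
  re-draw of `(μ_j, log σ_j)` holding the standardized subject deviations
  fixed. The ASIS step is what makes the group scales mix: without it the
  centered sweep leaves σ with autocorrelation times of tens of iterations;
  with it the chain is close to independent draws. Chains are initialized
  from the per-subject MLEs plus a small jitter.

Convergence is diagnosed with classic split-chain Rhat (each chain halved;
`sqrt(((n−1)/n · W + B/n) / W)`), reported for every sampled parameter, with
a default warning threshold of 1.003. Note that split-Rhat of byte-identical
stationary chains is 1 only up to within-chain noise. Because the sampler is
not Hamiltonian Monte Carlo, iteration counts are not comparable to Stan
defaults; the config default (4 chains × 1000 iterations, 250 warmup)
matches common practice for this model, and recovery studies in the test
suite run 4 × 4000 (1000 warmup, ~3000 effective kept draws per chain) to
push max Rhat − 1 below 0.003 across all 57 parameters.

Point estimates for downstream Q trajectories are per-subject posterior
medians on the natural scales (a single Q trajectory per subject). Group
summaries are reported two ways, since "group percentiles" is ambiguous:
`group_percentiles` gives the 25/50/75 percentiles of the *implied
subject-level distribution* (posterior median of `g(μ + z_q σ)`), and
`group_mean_percentiles` gives posterior percentiles of the transformed
group mean `g(μ)`.

`compute_q_trajectories` re-runs the Q recursion on the observed
choice/reward sequence and emits the value difference in both frames —
`dq_chosen = Q(chosen) − Q(unchosen)` and `dq_contra = Q(contra) − Q(ipsi)`,
linked by `dq_chosen = ±dq_contra` depending on the choice — plus per-site
standardized versions (mean 0, SD 1 within site), which are the regression
inputs.

## Synthetic photometry

No generative model of the fluorescence is implied by the analysis itself,
so the generator is the package's own design, built to exercise every
preprocessing and regression stage:

- transient shape: unit-peak double exponential (rise 0.1 s, decay 0.6 s), a
  GCaMP6f-like stand-in, truncated when it falls below 1e-3 of peak;
- one value-scaled transient per trial at **lever presentation** (the
  anticipatory component of an RPE is occasioned by the choice-predicting
  cue), with amplitude per hypothesis: `g_v · dq_contra` (contra_value),
  `g_v · dq_chosen` (chosen_value), or `g_v · dq_chosen + g_m · 1[contra]`
  (chosen_value_plus_movement);
- under the movement hypothesis, a second movement transient at **lever
  press**, sign-flipped when `movement_reversal` is on — emulating
  selectivity that tracks physical movement direction (toward the lever,
  then back to the reward port);
- trace = `baseline · (1 + drift + transients + noise)` in raw fluorescence
  units, so dF/F and the high-pass filter do real work; drift is white noise
  low-passed at 1/60 Hz and rescaled (SD 0.10 of baseline), far below the
  filter's 0.075 Hz stopband edge; noise is white with SD 0.05 of baseline.

Gain defaults (`g_v = 0.15` per unit ΔQ, `g_m = 0.08`) were calibrated once
so that z-scored event-locked responses are of order 1 z-unit, the scale
typical of striatal dopamine photometry; they were then frozen. The
generator is linear in the gains. What it does **not** model: shot noise,
isosbestic/motion artifacts, hemodynamics, session-to-session gain drift,
or any nonlinearity of indicator binding. Passing recovery tests therefore
shows the analysis is correct under an additive-transient world, not that
real signals obey one.

## Preprocessing

- **High-pass FIR**: Hamming-window design with cutoff at the
  passband/stopband midpoint (0.225 Hz); the odd tap count grows from the
  standard 3.3/Δf estimate until the realized response is ≥ 10 dB down at
  0.075 Hz and within ±1 dB of unity everywhere above 0.375 Hz (165 taps at
  15 Hz; the realized stopband attenuation is ~52 dB, comfortably beyond the
  10 dB requirement). The printed spec, not the tap values, is the contract.
- **Application**: zero-phase forward–backward filtering with reflection
  padding, per session segment, so event-locked features are not delayed. A
  consequence worth knowing: energy removed at low frequencies appears as a
  shallow rebound of opposite sign spread symmetrically (acausally) around
  dense transients.
- **dF/F**: filtered signal divided by the mean of the *unfiltered* signal
  over the site's full concatenated record.
- **z-score**: full-record mean and SD per site. (The alternative reading of
  z-scoring by the standard *error* would produce magnitudes inconsistent
  with GCaMP axes of order ±1, so SD is used.)
- **Epochs**: 45 samples at 15 Hz — 15 before the event and 30 from the
  event on, i.e. the window [−1 s, +2 s); a closed window would hold 46
  points. Events map to the grid by nearest sample, no sub-sample
  interpolation. Windows that leave the trace or straddle a session boundary
  are dropped and logged, never zero-padded.

## Regression engines

**Pointwise mixed model.** At each of the 45 timepoints:
`z ~ intercept + choice + value + choice:value (+ log press latency)`, with
`choice` coded contra = 1/ipsi = 0 and `value` the per-site standardized ΔQ
in a declared frame. Random effects are grouped by site: intercept plus
slopes for choice and value by default, falling back to intercepts-only when
the fuller model does not converge (with per-site z-scored data the
between-site intercept variance is typically estimated at exactly zero; the
intercept's SE is then undefined and is reported as NaN without failing the
fit). P-values are Wald z (large-sample normal) from statsmodels' MixedLM —
a deliberate, pinned choice; Satterthwaite-type degrees of freedom are not
available in that engine and at the trial counts involved (hundreds to
thousands per fit) the normal approximation is adequate. Benjamini–Hochberg
correction is applied across the 45 timepoints separately per regressor, and
significance tiers (0.05/0.01/0.001) are assigned on the adjusted values.

**Kernel regression.** The continuous z-scored trace is regressed on lagged
indicator kernels (−15…+29 samples) for three events (nose poke, lever
presentation, lever press) × four conditions (choice × previous-trial
outcome), plus one global intercept, solved by least squares on the sparse
normal equations. Identifiability requires jitter between events: with
constant event spacing the kernels are collinear shifted copies, and the
rank check reports the dependent columns (via pivoted QR). Coefficient
covariance is the CR1 cluster-robust sandwich grouped by site:
`(G/(G−1))·((N−1)/(N−K)) · (X'X)⁻¹ [Σ_g (X_g'e_g)(X_g'e_g)'] (X'X)⁻¹`.

## Discrimination rule

Pointwise regressions are run in both frames on lever-presentation epochs.
"Sustained interaction" = at least 4 consecutive BH-significant timepoints
(adjusted p < 0.05) inside 0.25–1 s after lever presentation (~0.27 s of
signal; both the run length and the window are configurable — the window is
the interval where action and value coding are strongest at these kinetics).
Then:

| chosen-frame interaction | contra-frame interaction | choice main effect | label |
|---|---|---|---|
| yes | no | — | contra_value |
| no | yes | yes | chosen_value_plus_movement |
| no | yes | no | chosen_value |
| otherwise | | | indeterminate |

The logic: a value signal tied to one *side* flips its modulation between
choices when expressed in the chosen frame (interaction), and is clean in
its own frame; a chosen-value signal behaves the opposite way. At the
default generator gains the rule labels ≥ 90% of replicates correctly
(checked over 50 seeded end-to-end replicates at 6 sites × 260 trials, sizes
chosen to keep the full study at desk scale); as gains shrink the failures
move to "indeterminate" rather than to wrong labels, which the null test
(zero gains) checks explicitly.

**Press-locked reversal.** The contra-minus-ipsi difference of press-locked
epochs reverses sign shortly after the press when the generator's
`movement_reversal` is on. Detection demands sustained (≥ 3 samples)
excursions of *both* signs, each reaching a fraction of the trace's peak
|difference| — 0.5 by default on filtered data, because the zero-phase
high-pass always creates a shallow opposite-sign rebound (~0.4 of peak at
the default event density) around dense transients that must not count as a
reversal; on unfiltered noise-free constructions a lower bar (0.3) is
appropriate, since the press transient partially cancels against the
presentation transient's decaying tail. Value modulation shows no such
reversal under any hypothesis, mirroring the asymmetry that motivates the
movement interpretation.

## Binned condition averages

The previous-outcome analysis uses stay trials only (choice equal to the
previous completed choice) and averages within site before averaging across
sites, with SE across sites. The ΔQ-binned analysis includes stay and switch
trials and bins the standardized value difference by within-site quantiles
(the bin rule is a package choice, flagged in outputs). Empty conditions are
reported as missing rows, not errors.

## Problem sizes and runtime choices

Recovery and discrimination studies in the test suite use 17 subjects ×
1000 trials (hierarchical recovery) and 50 replicates of 6 sites × 260
trials (discrimination), sizes at which every check completes on a single
CPU in minutes while keeping the statistical targets meaningful. The
acceptance script simulates 17 agents × 1000 trials for the stay-fraction
quantity.

## Known limitations

- The sampler is single-threaded Gibbs/slice; for much larger cohorts an
  HMC backend would scale better.
- The MAP backend's group SDs are bounded, not marginalized; treat them as
  initialization quality only.
- Mixed-model p-values are asymptotic (Wald z); with very few sites and
  strong random-effect structure they are anti-conservative relative to
  Satterthwaite or Kenward–Roger corrections.
- The discrimination rule is binary per frame; graded evidence (e.g.
  interaction effect sizes) is available in the regression tables but not
  folded into the label.
- Real recordings bring artifacts (motion, bleaching nonlinearity, sensor
  saturation) that the generator deliberately omits; conclusions about real
  data rest on the preprocessing assumptions above, not on these tests.
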