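# Methods

## Model

The network holds `N` decision modules (default 100).  Module `k` contains
two populations `i ∈ {A, B}` whose NMDA gating fractions `s_i^k ∈ [0, 1]`
evolve as

    ds_i^k/dt = − s_i^k / τ_s + γ (1 − s_i^k) r_i^k,
    r_i^k     = φ( I_rec,i^k + I0 + I_ext,i + η_i^k ),

with the effective f–I curve `φ(I) = (aI − b)/(1 − exp(−d(aI − b)))` (the
removable singularity at `aI = b` is evaluated by its series limit `1/d`).
Rates are instantaneous functions of the current; the gating variables are
the only dynamical state per population.

Recurrent input couples populations with the weight tensor

    W^{kl}_{ij} = w_ij · ((1 − IC) δ_kl + IC / N),

where `w_AA = w_BB = w_same > 0`, `w_AB = w_BA = w_diff < 0`, and
`IC ∈ [0, 1]` is the inter-module coupling fraction.  The `IC/N`
normalization conserves the summed drive each population receives from
each presynaptic population type for every `IC`; this is what allows the
coupling to reorganize correlations between modules without changing
first-order behavior (accuracy, mean RT).

`η_i^k` is an Ornstein–Uhlenbeck current, independent per population and
module (correlation time `ou_tau`, stationary variance `ou_var`), advanced
with its exact discretization.  The sensory current `I_ext,i` is shared
identically by all modules and is zero before stimulus onset; the
background current `I0` and the noise are always on.

### Constants

| name | value | unit | origin |
|---|---|---|---|
| τ_s (`tau_nmda`) | 0.100 | s | reduced two-variable attractor model |
| γ | 0.641 | – | same |
| w_same / w_diff | 0.2609 / −0.0497 | nA | same |
| a, b, d | 270, 108, 0.154 | Hz/nA, Hz, s | same |
| I0 | 0.3255 | nA | same |
| ou_tau | 0.010 | s | stated protocol value |
| ou_var | (0.005)² | nA² | package calibration (see below) |
| λ (`lambda_thr`) | 15 | Hz | stated protocol value |
| Δλ (`delta_lambda`) | 5 | Hz | stated protocol value |
| `readout_tau` | 0.020 | s | package choice (see below) |
| dt | 5·10⁻⁴ | s | Euler–Maruyama step |

The synaptic, f–I and background constants are the canonical values of
the reduced two-variable attractor model this network extends.  Halving
`dt` does not change the summary statistics beyond sampling error.

### Readout

A module votes for option `i` the first time the *readout-filtered* rate
`\bar r_i^k` reaches λ; `\bar r` is an exponential moving average of the
rate with time constant `readout_tau = 20 ms`.  The filter represents the
finite integration time of the threshold-detecting populations; reading
the raw instantaneous rate would make the first-passage time a property
of the integration step (finer steps sample more noise excursions) and
would let single noise spikes trigger votes, which also destroys the
median-at-threshold property below.  Votes are irrevocable.  Ties within
a step go to the higher rate, then to option A.

The network commits when one option holds a strict majority (> N/2) of
votes; trials in which no majority is ever reached (e.g. an even 50/50
vote split) are returned undecided.  At the decision step the median of
the chosen option's filtered rates across modules sits at λ (the voting
construction pins it there), and two statistics are read out over *all* N
modules: `sigma_dv`, the population SD of the chosen-option rates, and
`FMC`, the fraction of modules with chosen-option rate in the half-open
window `[λ, λ + Δλ)`.  Binary confidence is drawn from
`P(high) = 1 / (1 + exp(−(x − c)/a))` of FMC (sign flipped when σ_dv is
used as the input).

In the fixed-delay paradigm the majority rule does not end the trial: at
stimulus offset the choice goes to the option with more latched votes
(ties to the higher mean rate, then A) and the dispersion statistics are
read at the offset.  In that regime most modules have left the counting
window, so the σ_dv-based sigmoid is the natural confidence input.

## Stimuli

Two luminance patches flicker on a 40 ms frame grid around nominal means
(background/distractor 50 cd/m², target higher by the *discriminability*).
Simulation-protocol mode draws one luminance per patch per frame with
5 cd/m² SD; behavioral mode draws 4 bars per patch with 10 cd/m² SD (so
the patch mean again has 5 cd/m² SD).  The network receives the per-patch
mean, transduced as `I = g (L + b_lum)`; kernels are computed per bar.
Pulse protocols add ±1 cd/m² to one patch during the first 40 ms of
stimulation on an otherwise constant background.

### Calibration of g, b and the noise variance

The luminance gain/bias and the O-U variance are free constants of this
implementation (no authoritative values exist for this exact network).
They were calibrated once, jointly, against the qualitative structure the
model is supposed to exhibit, and then frozen:

* baseline current `g·(50 + b_lum) = 0.0156 nA`, the standard stimulus
  operating point of the reduced attractor model, keeping RTs at a few
  hundred milliseconds;
* `g = 2·10⁻³ nA·m²/cd` puts the task in the *externally* noise-limited
  regime: the shared flicker, not the private background noise, limits
  performance.  This is the design premise of the reverse-correlation
  task, and it is required for the modules to reach consensus (with a
  10× smaller gain the private noise dominates, votes split ~50/30
  across modules, and the coupling-invariance and median-at-threshold
  properties disappear);
* `ou_var = (0.005 nA)²` keeps module dissent rare while leaving enough
  private variability for the dispersion statistics to discriminate
  difficulty and for pulse effects on them to be measurable.

With these defaults accuracy spans ~0.65–1.0 over discriminabilities
1–16 cd/m², threshold-level performance sits near 2 cd/m², and mean RTs
are 0.2–0.8 s.

## Experiments

* **Coupling sweep** — 2000 trials per (IC, discriminability) cell
  (reduced runs warn); accuracy, RT split by correctness, σ_dv and FMC
  with bootstrap CIs.  The error-vs-correct RT split is always reported;
  the free-response task produces slow errors only.
* **Pulse protocols** — SP1/SP2 compared with *common random numbers*:
  the two protocols share background-noise streams, and orderings are
  tested with paired one-sided Wilcoxon tests on trials decided under
  both.  Independent runs at a few thousand trials cannot resolve the
  σ_dv/FMC orderings (the original protocol used 10⁴–10⁵ trials); CRN
  pairing is a standard variance-reduction device and does not change
  the estimated effects, only their standard errors.
* **Fixed delay** — forced readout at stimulus offset over a duration
  grid; confidence from the σ_dv sigmoid.

## Behavioral fitting

Stage 1 fits `(g, b_lum)` by CMA-ES (implemented in-package: standard
(μ/μ_w, λ) strategy with cumulative step-size adaptation and rank-1 +
rank-μ covariance updates; box constraints by projection plus a quadratic
penalty) on

    w_lsq · Σ_t w(t) [(D̂_S − D_S)² + (D̂_N − D_N)²]
      + w_chi2 · χ²(hits, misses) + pen_e · N_e + pen_d · N_d ,

where each kernel time bin is inverse-variance weighted
(`w(t) = 1 / (var_pt (1/n_target(t) + 1/n_model(t)))`, `var_pt` the
per-trial variance of a bar-averaged fluctuation) so the kernel term is a
χ²-scale statistic; `w_lsq = 0.1` balances the two fitted terms at the
self-fit point (kernel floor ≈ number of bins, Pearson floor ≈ 1).
Penalties are linear in the counts of early and undecided simulated
trials (1 s deadline, 1 s pre-stimulus wait by default).  The search runs
over `(g, I50)` — gain and background operating current — because those
axes are nearly orthogonal in behavior while `(g, b_lum)` are strongly
anti-correlated.  Objective evaluations use a fixed simulation seed
(common random numbers); because a fixed draw can flatter some
candidates, the best few are re-evaluated with an independent seed and
more trials and the re-ranked winner is returned.

Stage 2 fits the confidence sigmoid `(a, c)` by sampling binary reports
on a single pre-simulated trial set and minimizing the Pearson χ² of the
4-way (high/low × hit/miss) table.

The synthetic-subject generator runs the full model forward
(free-response behavioral task, 4 bars, 10 cd/m² frame SD, per-trial
target mean from a truncated Gaussian on [51, 70] cd/m², default
loc 53 / scale 3 — threshold-level difficulty; an easier distribution
drives accuracy to ~0.96 where fluctuations stop influencing choice and
all kernels vanish).  Fitting is validated by *behavior* recovery:
`(g, I50)` is only weakly identified along a behavioral ridge, so
recovered parameter values may differ from the generating ones while
accuracy, kernels and the confidence table agree at matched n.

## Kernels

Fluctuation = presented luminance − nominal generating mean (an
empirical-mean variant is available).  A frame enters a trial's kernel iff
its end lies at or before the response time (a frame-start rule is
available).  Decision kernels are choice-conditioned means over trials
and bars; confidence kernels are high-minus-low differences of the group
means.  Standard errors come from a seeded trial-level bootstrap (default
1000 replicates) in which the selected and non-selected traces of a trial
are resampled together.  Kernel ratios quoted by the analysis scripts use
time bins to which at least half the trials contribute, because
low-count late bins are dominated by the slow-trial conditioning
artifact (trials still undecided at a late frame show systematically
negative selected-patch fluctuations there).

## What the synthetic data does and does not emulate

The generator reproduces the stimulus statistics, free-response timing
and binary confidence structure of the reference task, but not motor/
non-decision time, lapses, session effects, or learning; passing recovery
tests therefore demonstrates the internal consistency of the estimation
pipeline, not its robustness to those human factors.

## Known limitations

* The binary-confidence kernels of this implementation are close to
  symmetric (`|C_N| ≈ 0.7 |C_S|`): the reaction-time reverse-correlation
  is strongly asymmetric (selected-patch influence ≈ 4× the other patch)
  and the pulse-protocol orderings on σ_dv and FMC are reproduced, but
  conditioning confidence on correctness re-imports a symmetric
  balance-of-evidence component through module dissent and evidence
  strength.  No surveyed parameter regime removed it; with the original
  fitted constants unavailable we report this as a property of the
  implementation.
* Mean accuracy/RT are invariant to IC within sampling error at
  threshold-level difficulty; at near-ceiling cells a residual RT
  difference of ~1% of the mean RT can reach significance at large n.
* An even number of modules can produce exact 50/50 vote splits, which
  remain undecided under free response (a few percent of trials at zero
  discriminability).

## Problem sizes

Test-suite and acceptance-script runs use: 2000 trials per sweep cell
(study scale), 10⁴ trials per pulse protocol (study scale), 5000-trial
synthetic subject for kernels, and a 600-trial subject with 800-trial
merit evaluations (20 modules) for the recovery analysis; the refitted
model's response proportions are estimated from a larger regenerated run
so the matched-n χ² comparisons carry only the target-side sampling
noise they assume.
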