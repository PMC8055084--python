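# Methods

`freqtrack` implements the full computational chain of a steady-state
relative-frequency tracking study: the stimulus design that dissociates a
relative frequency `p` from its representational uncertainty `p(1-p)`,
the behavioral probability-distortion models and their factorial
comparison, a synthetic-data generator with known ground truth, and the
neural analyses (phase-coherence entrainment, time-resolved/spatial
decoding, brain-behavior linking).

## Stimulus design

Trials are sequences of 150-ms dot displays. In **P-cycle** trials the
display-wise `p` is drawn alternately from U(0.1, 0.5) and U(0.5, 0.9),
so `p` is periodic at 1/(2 × 0.15 s) = 3.33 Hz while `p(1-p)` is
aperiodic. In **U-cycle** trials `p` is drawn alternately from
(0.1, 0.3) ∪ (0.7, 0.9) (each sub-interval with probability ½) and
(0.3, 0.7), so `p(1-p)` alternates around the boundary
0.3 × 0.7 = 0.21 while `p` is aperiodic. The starting phase (low-first
vs high-first) is randomized per trial to avoid a fixed phase confound.
Formal trials have 40 or 41 displays (6 / 6.15 s); catch-trial durations
follow an exponential truncated to [1, 6] s whose rate is calibrated by
root finding so the truncated mean is 3 s (the stable parameterization
`g(x) = 1/x − 1/(eˣ−1)` admits negative rates for means above the
interval midpoint). A default session holds 50 formal + 10 catch trials
per cycle × numerosity condition, interleaved over 10 blocks of 24
trials with balanced labels per block; a configuration that cannot tile
the blocks evenly is rejected.

Numerosity `N` is `round(lo + (hi − lo)·X)` with X ~ Beta(0.1, 10) and
[lo, hi] = [10, 90] (N-small) or [100, 900] (N-large), independent of
`p`. Dot counts are rounded to integers and the *actual* post-rounding
`p` is used everywhere downstream; when rounding would produce 0 or N
target dots (possible only at N = 10 with extreme `p`), one count is
moved inward so the log-odds of the actual `p` stays finite.

**Confounds without pixel rendering.** Each display carries the 8-vector
(N, Nt, No, AvgLumi, vCIE-L*, vCIE-a*, vCIE-b*, M-contrast). The display
is abstracted as a canvas of area cells: each dot occupies `c1 = 4`
cells, and gray filler elements (one cell each, count `c1·(N_max − N)`)
keep the total luminous area equal across displays, equating luminance
at the session's maximum numerosity. AvgLumi is the exact area-weighted
mean L* and is constant by construction; vCIE-L* is the L* variance over
canvas cells (dark elements vs background), and vCIE-a*/b* are variances
over the dot + filler element mixture with the stated CIELAB palette
(orange [43, 19.06, 52.33], blue [43, −15.49, −23.72], gray [43, 0, 0],
background [56.5, 0, 0]). This reproduces the intended correlation
structure — color variances track N strongly (|r| ≈ 0.9) and `p(1-p)`
negligibly — without dot coordinates. M-contrast,
(L_dots − L_bg)/(L_dots + L_bg) = −0.1357, is constant because the dots
are isoluminant; constant columns are dropped automatically wherever the
confounds enter a regression.

## Distortion models

Reported proportions `π(p)` are modeled on one of three internal scales
(D1): log-odds λ(p) = ln(p/(1−p)), Prelec −ln(−ln p), or linear. The
**LLO** model is linear in log-odds,
λ[π] = γ·λ(p) + (1−γ)·λ(p0) + ε, with slope γ (inverted-S distortion
for γ < 1), crossover p0, and Gaussian noise SD σλ on the log-odds
scale. The **BLO** model is generative: λ(p) is truncated to
[Δ−, Δ+] (D2), mapped linearly to a bounded Thurstone scale with slope
η, and the final estimate shrinks toward an anchor Λ0 with weight
ω = 1/(1 + α·V(p̂)), where V(p̂) = p(1−p)/ns · (N−ns)/(N−1) is the
variance of estimating `p` from a random sample of ns = b + N^a of the N
dots without replacement (clamped at 0 when ns ≥ N; defined 0 at N = 1).
D3 varies the variance law: ns = b + N^a, constant ns, or constant V.
The 3 × 2 × 3 space yields 18 models; the bounds-free log-odds
constant-V cell *is* LLO and the bounds-free Prelec constant-V cell is
the two-parameter Prelec function.

Two design choices deserve note:

* **Constant-V cells drop α.** With constant V the shrinkage weight is a
  fixed affine map not identifiable against η and an intercept, so those
  cells use mean = Λ + Λ0. This gives the documented free-parameter
  counts (BLO 8; bounded ns-const 7; bounded V-const 5; bounds-free
  6/5/3) and keeps LLO/Prelec exactly nested.
* **Likelihoods are densities over the observed proportion.** Noise
  lives on each model's transformed scale, so the change-of-variables
  Jacobian (1/(π(1−π)) for log-odds; −1/(π ln π) for Prelec) is included
  by default. Without it, likelihoods on different scales are not
  comparable and linear-scale cells win any factorial comparison by
  hundreds of AICc units regardless of the generating model.
  `include_jacobian=False` recovers the transformed-scale density.
  Responses are clipped to [1/202, 1 − 1/202] before the transform
  (half a step of a ~1%-resolution click scale) so boundary clicks keep
  finite likelihood. Linear-scale noise is plain Gaussian on the linear
  scale without support truncation — a deliberate neo-additive reading.

A Nadaraya–Watson kernel smoother (Gaussian kernel, default bandwidth
h = 0.03) provides the nonparametric view of π(p) − p; queries where all
kernel weights underflow return NaN with a warning rather than silently
zero.

## Fitting and model comparison

`fit_model` maximizes likelihood with the linear structure exploited:
given the nonlinear parameters (Δ±, and a/b/ns/α), the transformed-scale
mean is linear in (η, Λ0) and σλ has the usual Gaussian MLE, so all
three are profiled out in closed form (then projected onto their boxes).
A bounded Nelder–Mead simplex (box projection plus a mild out-of-box
penalty, fatol 1e-8) searches the remaining ≤ 5 dimensions from
Latin-hypercube starts. This profiling matters: without it, multi-start
simplex on the raw 8-dimensional BLO surface reliably misses the global
optimum by tens of log-likelihood units at realistic noise levels,
which biases factorial comparisons toward simpler cells. LLO and Prelec
cells are fully closed-form. Desk-scale default is 20 restarts; the full
protocol value is 1000.

Parameter boxes (fitting and recovery sampling): Δ± ∈ [−4, 4]
(ordered), η ∈ [0.1, 3], Λ0 ∈ [−3, 3], a ∈ [0, 2], b ∈ [0, 20],
ns ∈ [1, 100], α ∈ [0, 100], σλ ∈ [0.05, 2].

Models are compared per subject by AICc = 2·NLL + 2k + 2k(k+1)/(n−k−1),
by stratified 10-fold cross-validated −2LL (folds stratified within each
cycle × numerosity condition, fit on 9 folds, evaluated on the held-out
fold, repeated over random partitions), and at the group level by
random-effects Bayesian model selection: log evidence ≈ −AICc/2, the
variational Dirichlet scheme (uniform prior α0 = 1), exceedance
probabilities by ≥ 10⁵ Monte-Carlo Dirichlet draws, and protection by
the Bayes omnibus risk BOR = 1/(1 + exp(F1 − F0)) against the
equal-frequency null: PXP = (1 − BOR)·XP + BOR/K. Marginal PXPs per
design dimension sum the 18-model PXP over the other two factors.

Identifiability at desk scale: with 200 trials per subject the BLO
profile likelihood is nearly flat in `a` over [0, 0.8] (the (a, b, α)
ridge trades sample-size growth against compensation strength), so
parameter-recovery checks use heavy optimization (16 restarts, 3000
function evaluations) and report median absolute errors over 20
replications; model-recovery checks aggregate summed ΔAICc over 4
virtual subjects per synthetic dataset, which is the smallest desk-scale
aggregate at which the generating BLO reliably wins its own column.
Generating-parameter samplers draw subjects with pronounced uncertainty
compensation (α ∈ [20, 60], σλ ∈ [0.15, 0.3], bounds ±[1.0, 1.8]),
i.e., the regime the models are designed to distinguish.

## Synthetic behavior and recordings

A `SubjectProfile` holds ground-truth BLO parameters (defaults
Δ± = ∓1.8, a = 0.42, b = 1.91 — the median sample-size law — η = 0.9,
Λ0 = 0, α = 20, σλ = 0.3) and a log-linear RT model
log RT = c0 + cu·p(1−p) + cN·ln N + cp·p + noise with default slopes
(+1.0, −0.08, −0.15): RT rises with representational uncertainty and
falls with numerosity and `p`. Reports respond to the last display of
each trial.

Recordings superpose, per display, causal gamma-bump kernels
g(t) ∝ t^κ·e^(−t/θ) (unit energy, support 900 ms, peak κθ at 327 ms for
`p` and 419 ms for `p(1-p)`), scaled by the session-standardized display
value and projected through smooth random spatial weight maps
concentrated over posterior locations of a Fibonacci-hemisphere layout
(102 locations × {1 magnetometer + 2 gradiometers} = 306 channels by
default; the layout is a synthetic stand-in, not a real sensor
geometry). Optional confound components use a 150-ms kernel driven by
the standardized confound columns. Noise is white (SD 0.5) plus 1/f
(SD 0.2) per channel; the default signal amplitude 2.0 was calibrated
once so that desk-scale analyses (≈10 trials, small layouts) detect the
injected effects with high power, and is stored on `ForwardModel`, not
hard-coded. Recordings round-trip losslessly through HDF5.

What the generator does *not* emulate: realistic head geometry and
leadfields, artifacts (blinks, cardiac), sensor-noise spectra of real
hardware, or any nonlinearity in the response. Passing tests therefore
validate the analysis chain's correctness and calibration on data that
satisfy its assumptions — not performance on real recordings.

## Entrainment

Phase coherence between a stimulus step function (each display's value
held for 150 ms) and a channel is
κ(f) = |mean_trials S*·R| / sqrt(mean|S|²·mean|R|²), with per-trial
demeaning, Hann windowing, and zero padding to 10 000 samples at 300 Hz
(0.03 Hz resolution). The denominator uses trial-averaged power spectra
— the only reading under which Cauchy–Schwarz bounds κ in [0, 1]. κ is
invariant to channel gain and to a fixed stimulus–response delay. The
permutation null shuffles response samples within each trial (≥ 100
permutations); p-values use the +1 correction and are BH-FDR adjusted
across the 0–7 Hz bins or across channels.

## Decoding

Epochs are polyphase-resampled to 120 Hz, where a display (150 ms) is
exactly 18 samples, so onsets align to the grid without interpolation.
For each lag τ in 0–900 ms, the display value is predicted from the
sensor vector at onset + τ: channels are standardized and reduced by PCA
(default 30 components) *refit inside every leave-one-trial-out fold* —
fold-wise refitting costs a little bias but excludes leakage — followed
by ridge regression (λ = 1) on standardized values. Performance is the
Pearson correlation between predicted and true display sequences per
held-out trial, averaged over trials. Decoded variables should be
aperiodic; a lag-1 autocorrelation above 0.2 triggers a warning.

Cluster inference groups adjacent lags with right-sided one-sample
t-test p < 0.05, statistic = summed t. The faithful null re-runs the
decoding after shuffling each trial's display sequence
(`decode_shuffle_null`, passed via `null_r`); when absent, a sign-flip
surrogate across subjects is used and flagged in the returned `method`.
Peak latency is the t-weighted centroid of the largest cluster within
100–500 ms; subject-level latency differences get percentile bootstrap
CIs over subjects resampled with replacement (1000 draws).

Spatial decoding uses, per sensor location, the lags of the peak window
× the location's 3 channels, PCA to 99% variance, the same LOO ridge,
and cluster inference over locations whose gaps are < 4 cm.

**CVCR** (cross-validated confound regression) removes
confound-explained variance from the lag-indexed features using
coefficients fit on training folds only and applied to both partitions;
constant or collinear confound columns (AvgLumi and M-contrast by
construction) are dropped with a warning. It is integrated into
`timeresolved_decode` via `confounds=`, with a standalone
`cvcr_regress_out` for explicit fold control.

## Linking

Per subject and numerosity condition, behavior is summarized by the LLO
slope γ̂ (cycles collapsed — cycle has no designed effect on behavior),
and neural responses by β = κ_p/κ_u per channel, the ratio of 3.33-Hz
coherence for `p` (P-cycle) to that for `p(1-p)` (U-cycle). The
condition contrasts Δγ̂ = ln(γ̂_large/γ̂_small) and
Δβ = ln(β_large/β_small) are unitless and scale-free; their
across-subject Pearson correlation is tested one-tailed for r > 0 (the
direction is fixed a priori by the compensation account: a relatively
stronger uncertainty response should accompany a flatter distortion
slope), with BH-FDR across channels and pairwise-complete handling of
missing values. The pipeline's coupled generator gives subject i a
compensation weight α_i and boosts the `p(1-p)` encoding amplitude in
N-small trials by 1 + 0.04·α_i, so ground truth guarantees a positive
linking correlation for the analysis to recover.

`run_pipeline` executes simulate → fit → entrain → link at desk scale
(default 8 subjects, 10 formal trials per condition, 12 sensor
locations, 300 Hz) on one CPU in seconds, writes CSV/JSON outputs when
given an output directory, and embeds pass/fail sanity checks in its
manifest.

## Problem sizes and numerical choices

Tests and the acceptance checks run everything at desk scale — sessions
of 8–25 trials per condition, 6–12 sensor locations at 300 Hz, 100–200
permutations, 20 fitting restarts or fewer with the profiled optimizer,
4 virtual subjects per recovery dataset — sizes chosen so the full suite
runs on one CPU in minutes while every statistical property being
asserted (detection power, type-I control, recovery tolerances) was
verified once at those sizes and frozen with the seeds. Paper-protocol
scales (1000 restarts, 500 permutations, 306 channels at 1000 Hz, 50
formal trials per condition) remain plain function arguments.

Other numerics: optimizer tolerance 1e-8 on NLL with ≤ 5000 evaluations
per restart; permutation p-values never exactly zero (+1 correction);
κ clipped to 1 against floating-point overshoot; PCA via eigendecomposition
of the fold covariance; qcut-free equal-count RT binning by rank to
tolerate ties.

## Known limitations

* The (a, b, α) sub-space of BLO is weakly identified at 200 trials;
  point estimates of `a` carry ~±0.3 uncertainty and α substantially
  more. Group-level model selection is robust to this; individual
  parameter values should be interpreted with care.
* The sensor layout, weight maps, and noise model are synthetic
  stand-ins; topographic claims validate machinery, not anatomy.
* The sign-flip cluster null is a surrogate for the stimulus-shuffle
  null when the latter's compute is prohibitive; results carry a method
  tag so the two are never conflated.
* Real-data ingestion is out of scope; `Recording.load` defines the
  expected schema for externally produced HDF5 files.
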