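# Methods

This note records the models, conventions and design choices behind
`memflex`, in enough detail to judge what a passing test suite does and
does not establish.

## The HC–PFC memory network

The network is a two-store consolidation model in the TraceLink
tradition: a small hippocampal layer (42 binary nodes) with fast
Hebbian plasticity, a large prefrontal layer (200 nodes) with slow
plasticity, and random Bernoulli(0.5) connectivity within and between
layers (no self-connections). Dynamics are synchronous: each cycle,
every node sums its weighted inputs from both layers, adds a fresh
uniform noise draw from [0, 0.5], and a k-winners-take-all rule
activates exactly the k highest-input nodes per layer (k = 7 in HC,
k = 10 in PFC). Weights obey Δω = λ₊·a_post·a_pre − λ₋·a_post·(1−a_pre),
clipped to [0, 1].

Phases:

* **Acquisition** — activity is clamped to the pattern and weights
  updated once, with λ₊ = 0.4 on associative connections (within HC,
  both between-layer directions) and 0.06 within PFC.
* **Consolidation** — three episodes per acquisition; each episode
  imposes a uniformly chosen already-learned pattern as the initial
  state and runs eight free cycles, applying intra-PFC learning
  (λ₊ = 0.0025) after each cycle. The free dynamics may drift to a
  different stored memory mid-episode; whatever is active is what gets
  consolidated.
* **Recall** — half of a pattern's PFC nodes are clamped for one cycle
  from silent activity, then eight free cycles run with learning off.
  The recall score is |retrieved ∩ (pattern − cue)| / |pattern − cue|,
  evaluated on the final cycle's activity; success means score ≥ 0.75.
* **Lesion** — exactly round(fraction × M) of the M present HC→PFC
  connections are removed permanently, uniformly at random (rounding
  half away from zero so 20% steps are exact for even M).

λ₋ is always 75% of the block's λ₊; the *forgetting ratio* is the
tunable that the flexibility sweep varies (default grid
{0, 0.25, 0.5, 0.75, 1}).

Choices made where the design was genuinely open:

* **Weight initialisation**: all present weights start at 0; structure
  is built entirely by learning.
* **Directionality**: the two between-layer blocks are independent
  directed projections, each sampled at p = 0.5; lesioning touches
  only PFC←HC. (A symmetric shared-mask variant was considered and
  rejected: the lesion is explicitly directional.)
* **Cue choice**: deterministic per pattern — the lowest-indexed
  ⌊k/2⌋ PFC nodes — so repeated probes of the same memory are
  comparable; in overlap experiments the cue is the shared node set.
* **Recall length**: one clamped cycle plus eight free cycles,
  mirroring the consolidation episode length; exposed as
  `recall_cycles`.
* **Ties** in the k-WTA are broken toward the lowest node index, so
  zero-noise configurations remain deterministic. Clamped nodes count
  toward the k budget.
* **"Consolidated"** for the end-of-run statistic means final recall
  score ≥ 0.75, the same criterion as recall success.
* **Both-above-threshold** flexibility trials count toward both
  tallies (keeps the index antisymmetric); a "count neither" policy is
  available via `tie_policy`.

Protocol statistics are aggregated as in the source design: blocks of
simulations, flexibility computed per block from pooled tallies, mean
± SEM across blocks. The test suite exercises the protocol at 5 blocks
× 10 simulations with lesion grid {0, 0.4, 1.0} and forgetting grid
{0.25, 0.75, 1.0}; these sizes give comfortable Monte-Carlo margins on
every monotonicity check while each check reruns hundreds of full
protocols. The chance level is estimated by recall-testing freshly
drawn patterns verified absent from the learned list.

## Relaxometry

Multi-echo (MSME) decays on the 5–155 ms, step-5 TE grid are fitted
with a two-pool bi-exponential S(TE) = A_f·exp(−TE/T2_f) +
A_s·exp(−TE/T2_s) by bounded trust-region least squares. The myelin
pool is identified with the fast component through the bound boxes
T2_f ∈ [1, 40] ms and T2_s ∈ [40, 300] ms (40 ms is the standard
myelin-water boundary); a deterministic 3 × 3 grid of starts
(T2_f ∈ {10, 20, 30} × T2_s ∈ {60, 90, 120} ms) guards against local
minima. The myelin fraction is A_f/(A_f + A_s). Degenerate inputs
(constant signal, < 4 echoes) and non-convergence raise, never return
silently; an absent fast pool (MF ≤ 0.01) sets an unidentifiability
flag on T2_f. The generator averages two noisy repetitions before
fitting, matching the acquisition it emulates; Gaussian noise is the
default with a Rician option (the physically correct magnitude model
at low SNR).

## Evoked potentials

* **PS amplitude** (default "tangent" convention): within the analysis
  window the trace is linearly detrended (endpoints) to locate the
  trough and its two flanking positive peaks, then the amplitude is
  the vertical distance from the chord joining the raw flanking peaks
  down to the raw trough. This is invariant to DC offsets and to the
  slow EPSP envelope the spike rides on. A "baseline" (window-start to
  trough) variant is available.
* **EPSP slope**: least-squares slope of voltage vs time over the
  20–80% portion of the local rise, restricted to samples before the
  window's peak; an explicit-window override (`rise_fraction=None`)
  regresses over the whole window.
* Paired-pulse ratio (PS2/PS1), LTP percentage
  (100·(post − baseline)/baseline) and the HC→PFC propagation ratio
  (PFC amplitude / CA1 PS) are plain ratios with positive-denominator
  contracts; all are scale-invariant.

The synthetic sweep is a piecewise-linear EPSP ramp with a
piecewise-linear spike (shoulders ± trough) whose tangent-convention
amplitude equals the stated truth exactly on the noiseless trace. The
truth dictionary carries the analysis windows; the EPSP window covers
only the pre-spike rising phase.

## LFP coupling and surrogate correction

Coupling is quantified as Welch magnitude-squared coherence
(configurable `nperseg`) and normalised broadband cross-correlation
over ± `max_lag_s`. Within-subject significance comes from circular
time-shift surrogates (default n = 200): shifting one channel by a
random offset preserves each channel's autocorrelation while
destroying cross-channel phase co-fluctuations. Significance uses the
rank p-value p = (1 + #{surrogate ≥ observed})/(n + 1), flagged at
α = 0.05; with 200 surrogates the attainable level is 10/201 ≈ 0.0497,
which is what the calibration test measures on uncoupled white noise.
Phase-randomisation surrogates are available as an option.

One consequence worth knowing: a *deterministic* shared sinusoid is
not detectable against circular-shift surrogates, because a shifted
sinusoid keeps a constant phase relation to the original and the
surrogate coherence stays high. The generator therefore produces the
shared component as band-passed Gaussian noise (4th-order Butterworth
around the shared frequency, unit variance), which is both more
LFP-like and a valid target for the surrogate null.

## Cohort statistics

* **ΔFA** = (⟨FA_case⟩ − ⟨FA_ref⟩)/⟨FA_ref⟩ per ROI.
* **ROI group tests**: pooled-variance two-sample t per ROI
  (two-sided by default; directed one-tailed tests, as used in the
  animal analyses, via `sidedness`), Benjamini–Hochberg step-up across
  ROIs. Missing values are dropped per ROI, never silently imputed;
  zero-variance ROIs are flagged.
* **Effect contrast**: the target ROI's |ΔFA| versus the runner-up and
  versus the mean of the *other* affected (significant) ROIs. The
  averaging set excludes the target: with a single competitor the two
  contrasts must coincide, which pins down that convention. A
  non-maximal target is reported, not raised.
* **Summary t**: pooled two-sample t recomputed from printed
  (mean, SD, n) rows, t for the case-minus-reference difference,
  df = n₁ + n₂ − 2.
* **CTF** = integrated density − area × mean background fluorescence;
  negative values are permitted (background brighter than the ROI).
* **Cognitive PC1**: variables are z-scored (PCA on the correlation
  structure); the PC1 sign is oriented so that higher PC1 = worse
  performance, using a per-variable "worse when higher" declaration
  (completion times: yes; items completed: no). Both orientations of
  the downstream correlation are reported, since the sign of a
  principal component is arbitrary.
* **Partial Kendall tau**: tau-b for all three pairs, composed as
  τ_xy·z = (τ_xy − τ_xz τ_yz)/√((1−τ_xz²)(1−τ_yz²)). This classical
  formula does **not** vanish exactly under conditional independence:
  with strong confound loadings (e.g. 0.6 on both variables) it
  retains a residual of order 0.08 even at large n. The tests
  therefore check strong attenuation of a planted confound, not exact
  nullity — a limitation inherent to the statistic itself, not to this
  implementation.
* The end-to-end association helper screens cognitive variables by
  Pearson correlation with FA (α = 0.05) before building PC1, falling
  back to the full set when fewer than two survive.

## Synthetic cohorts

FA per ROI is Gaussian around a reference mean of 0.50 with SD 0.04
(a realistic ROI-level dispersion), case means shifted by planted
relative changes; the default deltas put the target tract at −0.10,
51.5% above the runner-up (−0.066) and 73.9% above the mean of the
other affected tracts. A latent "badness" factor generates TMT-A,
TMT-B (completion times, higher = worse) and NST (items, higher =
better) through affine maps, which preserve all rank correlations
(Gaussian copula construction). Age loads on both the target-ROI FA
and the latent factor; the FA–cognition dependence after age is
planted as a Kendall tau via τ = (2/π)·arcsin(ρ) on the residual
correlation. Age is centred within group in the latent pathways so the
planted group ΔFA equals the realised group contrast exactly; the
groups' age gap (40.9 vs 47.5 years, SD 10) is still present in the
`age` column itself.

What the generators do *not* emulate: spatially correlated FA across
ROIs, non-Gaussian FA marginals, floor/ceiling effects in cognitive
tests, scanner- or site-level batch structure, and real LFP
nonstationarity. Passing recovery tests therefore demonstrate
correctness of the estimators under the stated statistical structure,
not robustness to those real-data complications.

## Numerical conventions

* All randomness flows through explicitly passed
  `numpy.random.Generator` objects or integer seeds; full protocol
  runs are bit-reproducible given (config, seed).
* Weights are clipped into [0, 1] after every update; masked-absent
  connections are structurally zero and never learn.
* CSV output is written at 6 significant digits, JSON at full double
  precision; every CLI run writes a manifest with the resolved
  configuration, value provenance (default/file/flag), seed and
  SHA-256 checksums of its outputs.

## Known limitations

* The network is a rate-free abstraction: no spiking, conductances or
  biological time constants; it is not fitted to the
  electrophysiology it conceptually accompanies.
* Flexibility blocks in which no recall succeeds have an undefined
  index; they are flagged and excluded from block averages rather than
  imputed, which can reduce the effective block count in extreme
  corners of the parameter grid.
* The bi-exponential fit assumes exactly two pools; three-pool tissue
  or exchange effects will bias the myelin fraction.
* The partial-tau residual under strong confounding (above) applies to
  any analysis using this statistic.
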