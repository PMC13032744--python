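# Methods

`spinefate` implements the analysis chain of a longitudinal two-photon
study of dendritic-spine calcium activity and spine fate in hippocampal
slice cultures challenged with Alzheimer's-disease brain extract, and a
synthetic-data generator that reproduces the statistical structure of
such a study so that every stage can be validated by parameter recovery.

## Trace conditioning

Per-ROI fluorescence time series (60-s recordings, 20 Hz by default) are
conditioned in a fixed order: (1) baseline estimation by an order-10
least-squares polynomial on a centred/scaled frame axis, subtracted from
the raw trace; (2) denoising by the Okada filter — any sample that is a
strict single-point local extremum is replaced by the mean of its two
neighbours, four iterations by default; (3) conversion to ΔF/F by
pointwise division with the fitted baseline, floored at 1% of its median
to guard against edge dips; (4) z-scoring with the population
(n-denominator) standard deviation. Each `ProcessedTrace` records the
exact configuration used.

Choices where the convention was open:

* **ΔF/F denominator.** The fitted polynomial is the only baseline
  estimate the chain constructs, so it serves as F0 pointwise.
* **Okada update.** Synchronous (Jacobi-style) by default, so the result
  is independent of scan order; a sequential in-place variant is
  available via `synchronous=False` for sensitivity checks. Note that
  repeated application converges geometrically but not finitely:
  alternating (checkerboard) segments decay by halving rather than
  terminating, so an exact fixed point is generally not reached in any
  finite number of passes. After 20·n passes the residual one-pass
  movement is below 1% of the trace range.
* **Noise floor.** The recording's detection-noise level is estimated on
  the ΔF/F trace *before* denoising (where detector noise is still
  white), as the median of the upper half of the periodogram, corrected
  for the ln 2 bias of an exponential order statistic, and expressed in
  z-units of the final trace (`noise_sd_z`). Estimating it after the
  Okada filter would understate it badly, since the filter removes
  precisely the high-frequency band the estimator reads.

A known, quantified property of this chain: the polynomial baseline
absorbs part of every transient (it is fitted to the raw trace,
transients included), so full-chain ΔF/F amplitudes of slow-indicator
events are attenuated to roughly 60–80% of their generative value, more
at trace edges and at high event rates. Tests that verify forward-model
amplitudes therefore divide by the generative baseline; tests of the
full chain assert the characterised attenuation band instead.

## Event detection

Events are inferred by sparse non-negative AR(1) deconvolution
(OASIS-style pool-adjacent updates): `c_t = g·c_{t−1} + s_t`, `s_t ≥ 0`,
minimising `½‖z − c‖² + λ·Σs` with the constraint that accepted events
have deconvolved amplitude at least `s_min`.

* **g.** Estimated from the slope of the log-autocovariance over lags
  4–10 — the shortest lags are corrupted by the denoiser's induced noise
  correlation, while white observation noise only inflates lag 0 — and
  then refined by pooled regression on the decay segments of the largest
  isolated detected events (`optimize_g = 5` by default). The
  regression uses the whole decay segment including the post-transient
  undershoot that baseline detrending creates: the effective impulse
  response the AR(1) model must match decays faster than the indicator
  itself, and fitting only the positive part biases g high and halves
  detection.
* **λ.** When a noise level is available, λ is raised by bisection until
  the residual of the un-thresholded problem meets the noise budget of
  the input trace (its own high-frequency floor, which is lower than the
  recording noise when the trace was denoised upstream). On a pure-noise
  trace this drives c to zero and suppresses false events entirely.
* **s_min.** The event threshold is `s_min × noise sd` — on unit-sd
  z-scored traces with `s_min = 2.5` this is the operative "2.5σ"
  criterion. With `sn=None` the threshold is an absolute amplitude,
  which is the mode used for exact-recovery and oracle tests.
  Sub-threshold spikes are removed smallest-first by merging their pool
  into the predecessor and re-fitting, which re-absorbs the spike's mass
  — a transient whose rise is spread over several frames by sampling and
  denoising is thereby concentrated into a single onset spike rather
  than discarded.

On noiseless ≤20-frame problems the solver's output coincides with
exhaustive search over feasible event placements (placements whose
jointly fitted amplitudes all clear `s_min`); this is verified against a
brute-force enumerator. The greedy elimination is not guaranteed optimal
when planted amplitudes fall in a narrow band just below `s_min`, where
the global optimum can prefer clamping an event at exactly the threshold
— deliberately not emulated, because on noisy data that behaviour turns
every moderate noise bump into an event and destroys false-positive
control.

Under the default study conditions (0.2 Hz events, amplitude 8× the
noise sd, jGCaMP7b-like kernel), the full chain recovers the mean event
rate to within about ±10%, with a noise-only false-positive median of
0 Hz. Recovery degrades above ~0.3 Hz, where transients occupy most of
the recording and the polynomial baseline absorbs a growing share of the
signal; in the rate range the study design targets (0.01–0.2 Hz) the
detector is calibrated.

Event times are the frames of the deconvolved impulses; peak amplitudes
are read separately as the ΔF/F maximum within 1 s after each impulse.
Per-spine rates average over repeat recordings (two per session by
default).

## Bleaching

The bleaching profile is the per-frame integrated intensity normalised
on t = 0. It is fitted with `A·e^(−t/τ1) + B·e^(−t/τ2)` (no offset term
by default) using multi-start nonlinear least squares over a fast/slow τ
grid, reporting the best-SSE fit canonicalised to τ1 ≤ τ2; a fit that
fails everywhere is flagged rather than raised. The bleach rate is
F0 − F60 with F0 the mean over frames 5–10 (read as 0-based inclusive —
the indexing origin is not fixed by convention — and configurable) and
F60 the mean of the last five frames.

## Longitudinal tracking and proximity

Day-1/Day-2 fields of the same dendrite are aligned by a single rigid
translation: candidate shifts are generated from all point-pair
differences (bounded by `max_shift_px`), scored by summed
nearest-neighbour distance, and refined as the mean displacement of the
implied matches. Matching is greedy nearest-first, one-to-one, with
deterministic index tie-breaking; a Day-1 spine survives iff its match
lies within the spine radius. Rotation is omitted by default (the same
field re-imaged is translation-dominant) and survived + lost equals the
Day-1 count by construction.

A spine is astrocyte-proximal iff any astrocyte-mask pixel lies within
twice the spine-head radius of its centroid (ROI extent plus one spine
radius, boundary inclusive) — the most literal reading of "within one
synapse radius of the ROI"; the factor is configurable. The classifier
is exact (KD-tree over mask pixels) and is tested against exhaustive
per-pixel distance.

Relative changes use (POST − PRE)/PRE. A spine silent at PRE and active
at POST yields +inf, which is carried as a sentinel, excluded from means
and counted separately; silent at both yields 0.

## Statistics

Spines are pseudoreplicates: group summaries average within animal
first, then across animals unweighted. Inference is by a hierarchical
permutation test whose statistic is the difference of animal-averaged
means and whose labels are permuted at the level treatment was assigned
— slices within animal for the within-animal design, or whole animals —
with a design check refusing factors that vary below the exchange unit.
The p-value is (1 + #{|perm| ≥ |obs|})/(1 + n_perm). On nested null data
(animal and slice random effects, 6 animals × 4 slices × 6 spines) the
empirical type-I error at α = 0.05 is ≈0.04–0.05 over 1000 datasets, and
the configured 2× rate effect with 10 animals is detected at p < 0.01
essentially always. Mixed-effects REML models can be fitted through
statsmodels by users who want them, but the package's own inferential
surface is the permutation test.

The Tukey ladder-of-powers transform selects λ over −2…2 (step 0.25) by
maximising Shapiro–Wilk W, after shifting to strict positivity; negative
powers are negated so the transform is rank-preserving for every λ.

Concentration conversion: pg/mL equals ng/L, so dividing by the molar
mass in g/mol gives nmol/L and a factor of 1000 lands on pM. Default
molar masses are the average isotopic masses of Aβ1-40 (4329.8 g/mol)
and Aβ1-42 (4514.1 g/mol).

## Synthetic data generator

The generator defines the study conditions the pipeline is validated
against.

* **Event trains.** Homogeneous Poisson, default 0.1 Hz per spine
  (plausible for spontaneous synaptic events; the empirical per-spine
  distribution is not published, so this is a modelling choice) over
  60 s at 20 Hz.
* **Kernels.** Difference-of-exponentials with unit-normalised peak:
  GCaMP6s-like (amplitude 1.0 ΔF/F, rise 0.10 s, decay 1.0 s),
  jGCaMP7b-like (1.5×, 0.12 s, 1.2 s — the brighter, slower variant the
  study standardises on), jGCaMP8s-like (1.2×, 0.03 s, 0.25 s). Values
  are literature-flavoured somatic kinetics.
* **Trace model.** `F0 · bleach(t) · (1 + drift(t) + Σ kernel) + ε`:
  bleaching multiplies the whole fluorescent signal (fluorophore-level
  photophysics), drift is a random polynomial (default order 3,
  amplitude 5% of F0) emulating slow focus/physiology trends, and ε is
  white detection noise (default sd 10% of F0). Default bleach
  `(0.15, 3 s, 0.85, 400 s)` reproduces the sharp immobile-fraction
  decline plus slow steady loss seen in real profiles.
* **Population.** Animals × slices × dendrites × spines with all four
  treatment arms (Aβ± × TBOA±) represented inside every animal. PRE
  rates carry lognormal animal/slice/spine heterogeneity (CVs
  0.1/0.1/0.2) so nested inference is exercised against genuine
  clustering. POST rates double in Aβ+ arms (×2 default), with an extra
  ×1.5 on Aβ+ spines destined to be lost, producing the lost-spine
  activity excess. Survival is logistic with defaults placing Aβ−
  survival at 0.90, Aβ+/astrocyte-free at 0.60 and Aβ+/proximal at 0.85
  under vehicle, with the protection term cancelled under TBOA.
  PsVue changes add effects for Aβ, for loss and for astrocyte absence
  on a 5% baseline with 10% noise. Lost spines have no 24-h session.
* **Proximity scenes.** Non-overlapping Gaussian-profile spines over a
  thresholded smoothed-noise astrocyte mask at a requested coverage;
  ground-truth labels are computed by exhaustive pixel distance at
  generation time.

What the generator does not emulate: photorealistic point-spread
functions and scan noise, motion artefacts, ROI segmentation error,
overlapping structures, and amplitude variability of unitary events.
Passing recovery tests therefore demonstrate correctness of the
computations under the stated generative model, not performance on real
micrographs.

## Problem sizes

Validation runs use sizes chosen to make sampling error small relative
to the tested tolerances while keeping the default suite quick: 200
spines for rate recovery, 200 noise-only recordings for the
false-positive bound, 500 spine layouts for the proximity oracle, 1000
null datasets × 500 permutations for test calibration, and the default
10-animal population for directional effects.
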