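# Methods

`spineglia` re-implements, as a tested library, the analysis chain of an
in-vivo study of microglia–dendritic-spine interactions and odor responses
in adult-born granule cells (abGCs) of the mouse olfactory bulb: contact
scoring against a channel-offset chance null, a ΔF/F_σ calcium-response
pipeline with ROC thresholding and lifetime sparseness, spine morphometry
rules, voltage-clamp QC and passive-property estimation, and
hierarchical-bootstrap group inference. Because the corresponding raw
imaging and electrophysiology data are not packaged for download, a
synthetic-data module generates every input with known ground truth; all
quantitative guarantees in the test suite are statements about that
generating model.

## Microglia–spine contact scoring (`contact`)

**Model.** A spine head is a 2-D polygon drawn in its single brightest
plane; the microglia channel is a binary segmentation per frame. The
coverage fraction of a spine in a frame is the fraction of its rasterized
polygon pixels that are mask-positive. A frame is an interaction frame
when coverage ≥ 0.05 (at least 5% of the head area overlapped); maximal
runs of consecutive valid frames form interactions, with length = run
length × frame interval (3 min by default) and the run's peak coverage.
Dendrite summaries: proportion of spines with ≥1 interaction, interaction
rate normalized to 10 min, and mean length / mean peak coverage over
spines that interacted at least once.

**Choices.** The interaction criterion is inclusive (≥ 0.05), with a
`strict` flag; invalid (unsegmentable) frames break runs rather than
bridging them. Coverage is strictly 2-D per plane.

**Chance null.** The microglia stack is circularly translated relative to
the ROIs: shift magnitudes start at the maximum spine width (32 px),
step by the mean spine width (10 px), and run to the field edge, applied
horizontally, vertically and diagonally (equal components). On an 800-px
field this yields 3 × 77 = 231 offsets; the wrap-around (circular) reading
is the one under which that count is reproduced, and a full-period shift
is exactly the identity. Offsets that park somata on spines are *not*
excluded, which makes the null conservative. The one-tailed permutation
p-value uses the add-one convention, p = (1 + #{null ≥ observed})/(N + 1),
so p is never 0; per-offset failures propagate as missing entries that are
excluded from N with a warning.

**Rasterization.** `skimage.draw.polygon` on pixel centers; the test suite
verifies exact agreement with an independent crossing-number oracle on
random float-vertex polygons (edge-through-pixel-center configurations
have measure zero there).

## Calcium QC and responses (`fluoro`)

Traces are trial-structured at 4 Hz: 10 s baseline (the default; the
baseline duration is a config value, not an inference), 2 s odor, 5 s
analysis window from odor onset. Frame QC uses the cosine similarity of
each motion-corrected frame to reference projections: discard when the
similarity deviates more than 25% (anesthetized) / 30% (awake) from the
best-trial mean, or more than 20% / 15% from the trial's baseline mean
("relative deviation" = |x − ref|/ref). Trial QC drops trials dimmer than
half the first-three-trial mean, trials whose baseline-vs-odor brightness
difference exceeds 3 first-trial SDs, and trials retaining <75% of frames
in either the baseline or the analysis window (the two windows are tested
separately). ROI QC removes ROIs whose baseline F_σ exceeds 30% of the
baseline mean.

F₀ is the plain baseline mean unless the last 2.5 s of baseline exceeds
1.1× the first 2.5 s (strict >), in which case a single exponential
a·exp(b·t)+c is fitted and its end-of-baseline value used. As printed,
this trigger fires on *rising* baselines — the opposite of photobleaching;
it is implemented verbatim with a `direction` switch (`"falling"`,
`"both"`) for users who want the bleaching reading. Responses are
(F − F₀)/F_σ averaged over surviving analysis-window frames (dropped, not
interpolated); F₀/F_σ are computed per trial. ΔF/F_σ is invariant to
channel gain. Respiration rate uses `scipy.signal.find_peaks` with a
0.1 s minimum inter-peak interval.

## Tuning metrics (`tuning`)

*ROC threshold.* Candidates are the pooled unique response values of
blank and odor trials (control and treated groups combined); θ is the
lowest candidate whose blank false-positive rate (fraction of blanks
strictly above θ) is ≤ the 10% design target, so the achieved FPR never
exceeds the target and, with continuous data, sits at the adjacent order
statistic.

*Effective odors* count responses strictly above θ. *Lifetime
sparseness* is LS = (Σr_j/m)²/(Σr_j²/m) on the thresholded vector
(sub-threshold entries zeroed); all-sub-threshold vectors get LS = 0, the
sparsest representation. LS is scale invariant, 1 for uniform vectors and
1/m for single responders (0.067 for the 15-odor panel).

*Event detection.* An event is ≥ n_min consecutive frames at ≥ k ΔF/F_σ
units (inclusive; flag available). (n_min, k) are grid-searched over
{1..5}×{1..5} for the blank-trial event rate closest to 10%, ties broken
toward larger n_min then larger k. Frames in an event in any repeat are
pooled; the across-repeat mean trace is evaluated on those frames and the
response is its mean over a 1 s window centered on the pooled-trace peak
(clipped to the response period); latency averages event onsets over
repeats with events.

*Temporal dynamics.* Each group's trace matrix (rows = cell-odor pairs,
columns = analysis-period frames) is column-centered and decomposed by
SVD; the statistic is the largest principal angle between the spans of
the first three component loading vectors (all principal angles are also
returned — which single "angle between the spaces" was meant is an open
reading). The null shuffles whole traces between groups, preserving
sizes, 1000 times by default; p uses the add-one convention.

## Morphometry (`morpho`)

Filopodial iff head max diameter < 1.5 × neck mean diameter (strict; the
ratio-only rule is scale invariant). Density = spine terminal points per
µm — branched spines count per head — on dendrites ≥ 40 µm; protrusions
≥ 10 µm are not spines and are filtered when a length column is present.
Diameter/volume units are taken as µm/µm³ as exported. Head-volume group
comparisons delegate to the hierarchical bootstrap (dendrites → spines,
100 spines per draw).

## Electrophysiology (`ephys`)

Test pulses are −10 mV, 20 ms steps sampled at 20 kHz, 50 repetitions
averaged before fitting. Rs = |ΔV|/|I_peak − I_baseline| with I_peak the
maximum current at the step onset; Rs + Rm from the steady-state current
over the last 20% of the step; τ from a log-linear fit over the samples
where the capacitive transient lies between 20% and 80% of its span; and
Cm = τ/(Rs‖Rm), the single-compartment relation (validated by parameter
recovery: exact on noiseless pulses, within 10% at 2 pA noise averaged
over 50 repetitions). In the pure-resistor limit the Rs/Rm split is
unidentifiable: I_peak = I_ss, τ and Cm are reported as 0. Cells with
initial Rs ≥ 50 MΩ fail inclusion; reported passive values are the mean
of the before/after estimates.

Sweep QC: reference Rs = mean of the first three sweeps; drop sweeps
deviating >25% or holding >100 pA in magnitude (at −70 mV); the cell is
excluded if fewer than half the sweeps remain. Line-noise conditioning is
a cascade of zero-phase IIR notches at 60–300 Hz (Q = 30), meeting the
contract ≥20 dB attenuation at each harmonic and ≤1 dB change at 30 Hz
and 1 kHz — a contract, not a particular named filter. Event detection
itself is out of scope (done upstream); the post-filters are the
sequential <3 ms doublet exclusion (kept-event anchored, so {0, 2, 4} ms
keeps 0 and 4) and user-noted noise masks, which remove both the events
and the masked time from frequency denominators.

## Hierarchical bootstrap (`hstats`)

Each iteration resamples the upper units with replacement (sample size =
number of units), then draws n_lower = 100 values with replacement within
each drawn unit — equal representation per unit regardless of raw counts;
the statistic (mean, median, or a proportion) is computed on the pooled
draw, 1000 iterations by default. The reported p is the directional
probability P(A > B) across paired iterations, with ties credited 0.5 so
p(A,B) + p(B,A) = 1; callers report p or 1 − p by direction.

The method is approximately, not exactly, calibrated: with only ~5 upper
units and between-unit variance dominating, the one-sided type-I rate at
the 0.05 cutoff runs near 8–9% (the n-vs-n−1 variance deficit of the
unit-level resample); at the nesting scale of the cell→event and
dendrite→spine datasets (tens of upper units) it is near-nominal, and the
calibration test uses that scale (10 units × 30 values, between-SD half
the within-SD). Power is checked at 5 units with a 2-between-SD shift.

## Synthetic data (`synth`)

One `numpy.random.Generator` per dataset; no global state; identical
(seed, config) pairs are byte-identical.

*Contact movies* place disk-shaped microglial "processes" performing
random walks on the image torus (wrap-around placement), so the bias-free
mask is stationary under circular shifts and independent of spine
positions — exactly the exchangeability the offset null assumes. Spines
are half mushroom (round 12-gon heads, brighter) and half filopodial
(thin headless quadrilaterals). With targeting bias b > 0, each mushroom
spine receives a deliberately placed process per frame with probability
min(1, b × 0.1), recorded as ground truth. Calibration and power studies
run on a 256-px field (69 offsets) so hundreds of replicate movies fit a
desk-scale run; the printed 231-offset construction is exercised at
800 px separately. Not modeled: photorealistic microglia morphology,
z-structure, bleed-through, registration error — so passing calibration
here shows the statistics are correct under stationarity, not that
segmentation of real movies is easy.

*Calcium traces* are F₀ = 100 a.u. plus white noise (SD 5 by default),
with responders (probability `p_respond`) carrying a
difference-of-exponentials transient (rise 0.2 s, decay 1.5 s — plausible
GCaMP6s values; the pipeline is insensitive to the kernel) of amplitude
`amp_sd_units` × noise SD from odor onset; one blank trial per repeat
set; optional exponential bleaching. Not modeled: correlated noise,
neuropil contamination, trial-to-trial amplitude variability, motion.

*Test pulses* follow the single-compartment circuit exactly (peak ΔV/Rs,
steady state ΔV/(Rs+Rm), τ = Cm·Rs·Rm/(Rs+Rm)) with white current noise.
*Hierarchical tables* are two-level Gaussians (unit means N(µ,
between²), values N(unit, within²)); the treated group is shifted by
−effect. *Event trains* are Poisson with a stated fraction of duplicates
injected at <3 ms offsets and flagged.

## Numerical notes and limitations

- Permutation and bootstrap p-values use add-one / paired-iteration
  conventions respectively; neither can be exactly 0.
- The ROC threshold is drawn from observed values, so the achieved FPR is
  a step function of n; with 1000 blanks it lands within one order
  statistic of the 10% target.
- Exponential fits (`scipy.optimize.curve_fit` for baselines, log-linear
  for the capacitive decay) fall back to the plain mean (with a logged
  warning) or raise, respectively, on failure; degenerate inputs (zero
  F_σ, all-invalid frames, empty nulls) raise typed errors distinct from
  legitimate empty results.
- Problem sizes in the test suite (200 calibration movies at 256 px,
  500 bootstrap replicate pairs at n_boot = 200, 200 subspace replicates
  at n_perm = 200) were chosen as the smallest runs whose Monte-Carlo
  error is well below the tolerances being checked.
- The offset-null reconstruction (circular shifts, equal diagonal
  components) reproduces the printed 231-offset count but is a declared
  reading, not a claim about any particular historical implementation.
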