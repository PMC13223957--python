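# Methods

## The imaging pipeline

**Stimulus protocol.** A session presents moving dots of several angular
sizes (default 2, 5, 10, 20, 30°; the set is configurable) on the frontal
visual field. One repetition is a 9 s there-and-back azimuthal sweep
(−90° → +90° → −90° at 40°/s), preceded by a 5 s pause with the dot
stationary; each size runs six repetitions with alternating clockwise /
anti-clockwise starting direction. Acquisition is 2 frames/s with 15 s of
stimulus-free recording before and after the stimulus program, giving
2×(15+15) + 2×5×6×(5+9) = 900 frames under the defaults. Segment lengths in
frames are `round(rate × duration)`; stimulus windows are half-open frame
intervals, and every frame carries exactly one label (pre / pause / stim /
post).

**Trace processing.** Per ROI the raw trace is the summed pixel
fluorescence per frame. ΔF/F = (Fₜ − F₀)/F₀ with F₀ the mean over the
pre-session frames; a non-positive F₀ is an error, not a silent NaN.
Traces are smoothed with a 3-point sliding median (truncated 2-point
window at both ends, where the median of two equals their mean; the
boundary rule is configurable in the sense that callers may skip smoothing
entirely). A neuron is *responsive* when its smoothed ΔF/F reaches 0.5
anywhere in the session — the gate is applied to the whole smoothed trace,
not per stimulus window, and the boundary is inclusive. Motion correction
is rigid translation by phase correlation (argmax of the inverse FFT of
the unit-normalized cross-power spectrum, integer shifts).

**The WMR angle.** Per size, the response rᵢ is the mean smoothed ΔF/F
within that size's stimulus windows, averaged over repetitions with both
sweep directions pooled (no direction-resolved statistics are produced).
Negative rᵢ are clamped to zero before weight normalization; a neuron with
no positive response has an *undefined* WMR and is excluded explicitly
(flagged, never zeroed). The statistic is log10-based throughout and
back-transformed by 10^(·); it always lies within [min size, max size], is
invariant to scaling all responses, and strictly increases when response
mass moves toward larger sizes.

**Population summaries.** Cumulative WMR distributions are empirical CDFs
in percent. The *median WMR angle* is the 50th percentile computed with
linear interpolation on the log10-size scale, i.e. 10^(median of log10
angles); for two neurons this is their geometric midpoint, and for odd n
the middle order statistic. A-P position is the normalized scalar
projection of the ROI centroid onto a configured oriented axis (the tectal
diagonal), mapped to a 1–10 scale and binned anterior [1, 3], medial
(3, 6], posterior (6, 10] — boundary values fall into the lower bin, a
convention the integer bin labels leave open. Per-region ΔWMR is the
absolute difference of mean WMR angles between two sessions; a region
empty in either session yields NaN rather than an error. Small/large
size-class counts assign each responsive neuron by its argmax-response
size (small ≤ 5°, large ≥ 10°).

## The synthetic imaging generator

Each neuron has a Gaussian tuning curve in log10 size with preferred
position, width σ (default 0.3 log10 deg) and peak ΔF/F amplitude
(Normal, mean 2.0, sd 0.6, clipped at 0 — comfortably above the 0.5
detection gate for most cells). Preferred log size is
`mean + slope·(AP − 5.5) + shift + Normal(0, 0.25)` with population mean
log10(5°), A-P gradient slope −0.05 per scale unit (posterior prefers
smaller, spanning ≈ ±0.22 log10 deg across the tectum), and an additive
condition shift (satiety/MTII stand-in, +0.3 log10 in the shift
experiments). `attenuation_small` multiplies the amplitude of neurons
preferring ≤ 5° (dominant-negative receptor stand-in). Traces follow
F(t) = F₀(1 + d(t)) + ε with F₀ = 100, ε i.i.d. Gaussian (sd 2, i.e.
ΔF/F noise ≈ 0.02/frame), and d(t) relaxing with first-order kinetics
(rise τ = 0.5 s, decay τ = 1.5 s; τ = 0 gives instantaneous tracking)
toward the tuning-curve amplitude during stimulus frames and zero
otherwise. No deconvolution is applied anywhere — the kinetics only need
to keep stimulus-window means ordered by the tuning curve, and because the
kinetic attenuation is common to all sizes the WMR is nearly invariant to
it. Centroids lie along the image diagonal at the neuron's A-P fraction
with small perpendicular jitter, so `default_ap_axis` recovers positions.
`render_stack` draws each ROI as a uniform disk of per-frame intensity
F(t)/area, making summed-pixel extraction an exact round trip;
overlapping disks are a generation error.

What the generator does *not* emulate: biophysical indicator dynamics,
motion artifacts, neuropil contamination, correlated noise, direction
selectivity, or non-neuronal (glial) signals. Passing tests therefore
demonstrate correctness of the statistics and their estimators under the
stated forward model, not robustness to every artifact of real recordings.

## The behavioral model and indices

Encounters are scored approach / avoidance / neutral. From tracks, the
score uses net radial displacement of the larva toward or away from the
dot with a 1 mm minimum displacement and a 5 mm encounter radius — declared
conventions, configurable, and invariant to rigid transforms of the arena.
Indices per larva and size: valence (A−V)/(A+V), activity (A+V)/(A+V+N),
and the three interaction probabilities; any zero denominator yields a
flagged missing value excluded pairwise from group statistics. The larva
is the statistical unit. Avoidance swims split into slow vs fast
(escape-like) at 20 mm/s, half-open (≥ threshold is fast) — a placeholder
convention, as is the logistic slow-weight (midpoint 5°, steepness 4 in
log10 size) used by the generator, under which slow swims dominate
avoidance of small objects. Prey-assay metrics: uptake percentage
100·uptakes/prey, and avoidance per unit exposure 100·avoidances/exposure,
where *exposure* is defined here as prey count × minutes observed (a
declared convention; the quantity is otherwise left undefined by common
usage).

The generator's per-size condition tables are the study conditions:
starved larvae approach small dots (p ≈ 0.5–0.55 at 1–2°) and rarely avoid
them, fed larvae avoid small dots at the expense of neutral interactions
(p_avoid ≈ 0.4–0.45), and the two conditions are identical at 10–30°, so
condition effects exist only at small sizes; overall activity is matched.
MTII-treated starved larvae reuse the fed table; dominant-negative and
SHU9119 fed larvae reuse the starved table. Cohort sizes default to 28
starved vs 16 fed with 9 presentations per size.

## Statistics

Benjamini-Hochberg is the step-up rule computed from its definition
(sorted q₍ᵢ₎ = min over j ≥ i of min(1, m·p₍ⱼ₎/j)), cross-checked in tests
against both a literal brute-force implementation and statsmodels. The
family for per-size tables is the size set of one group-pair comparison —
adjustment is *not* pooled across comparisons, a declared choice. The
two-group test per size is Welch's t (unequal variances) or Mann-Whitney;
sizes with < 2 observations in a group are reported NA and excluded from
the family size m. Paired Wilcoxon drops zero differences (Wilcoxon's
original convention), uses the exact null for ≤ 25 tie-free differences
and a continuity-corrected normal approximation otherwise, and flags the
all-ties case as degenerate instead of raising. Mann-Whitney is exact for
small tie-free samples. All tests are two-sided. Significance stars: *
p < 0.05, ** p < 0.01, *** p < 0.001. The two-way mixed ANOVA (one within,
one between factor) is delegated to pingouin and validated against a
hand-coded balanced sums-of-squares oracle; a constant response reports
F = 0, p = 1 by convention. Tukey HSD contrasts come from statsmodels.

## Expression quantification

Mean gray values are min-max normalized against the pooled extremes of all
conditions, so both endpoints of [0, 1] are attained and conditions share
one scale; an all-equal input is a degenerate-range error. Rostro-caudal
mapping is the clipped normalized projection of cell centroids onto a
two-anchor axis supplied in pixel coordinates (no anatomical registration
is performed — the axis stands in for it). The depth-intensity profile
bins pixels by perpendicular distance from a two-point skin-surface line
(tissue side selected by a direction vector), default 1 µm bins, with
optional normalization to the profile's own maximum.

## Problem sizes, tolerances and known limitations

The in-silico experiments use 200-neuron populations, 200 replicate
cohorts for the behavioral contrast, and 10,000-draw oracle sweeps —
sizes at which medians and rates are stable while a full run of the test
suite and the reproduction script each complete in well under a minute.
Tuning-shift recovery is asserted within 15% of the planted 0.3 log10
shift: the WMR compresses toward the center of the sampled size range
(finite stimulus grid), so the recovered shift is biased slightly low
(≈ 0.275–0.28) by construction, not by estimation error. Per-region ΔWMR
is compared to the closed-form ground-truth expectation within 3 standard
errors of the measured region means. In the replicated starved-vs-fed
contrast, a replicate is *pattern-consistent* when its BH-significant
sizes form a nonempty subset of the planted small sizes; because BH
controls FDR rather than family-wise error, roughly one replicate in ten
is expected to show a stray significant large size, putting the
consistent fraction near 0.9 by construction. Exact-test checks use
enumeration oracles at n ≤ 8. The WMR oracle check requires agreement to
12 significant digits on 10,000 random response vectors.
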