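# Methods

This note documents the models, parameter choices and limitations of the
spiralpen pipeline: what each stage computes, which decisions were open and
how they were settled, and what the synthetic cohorts do and do not emulate.

## Recording model and preprocessing

A trial is a uniform 50 Hz multichannel record: tri-axial acceleration
(m/s², gravity included), tri-axial angular velocity (deg/s) and tip force
(uncalibrated device units ≥ 0). Up to two consecutive missing samples are
restored by linear interpolation onto the nominal grid; larger gaps are a
hard error, because tremor spectra are aliasing-sensitive and silent
resampling of long gaps would bias every frequency-domain indicator.

The 1-D analysis signals are the Euclidean norms of the tri-axial channels.
The norm is rotation-invariant, which removes the unknowable orientation of
the pen in the hand; the cost is that zero-mean dynamics survive the norm
only through their projection on the dominant component (gravity for the
accelerometer, the sustained loop rotation for the gyro). Kinematic norms
are band-pass filtered to 2–12 Hz with a 4th-order Butterworth applied
forward–backward (zero phase) with reflective edge padding; "raw" norms are
mean-removed but unfiltered. Pen tilt is the angle between the low-pass
(2nd order, 1 Hz) acceleration — a gravity estimate — and the pen's long
axis (device z by default, configurable).

**Frequency/amplitude indicators use the raw norms, not the band-passed
ones.** Relative power below 2 Hz would be identically ~0 after a 2–12 Hz
band-pass, while the drawing oscillation of a spiral task lives well below
2 Hz; computing band fractions on the unfiltered (mean-removed) norm keeps
the 0–2 Hz band meaningful.

## Stroke segmentation and quality control

Tip contact is detected from the force channel with an adaptive threshold
θ = max(5% of the 95th force percentile, 10⁻³ units) and hysteresis (enter
above θ, leave below θ/2); contact bursts shorter than 100 ms are
discarded. Only gaps strictly between the first and last stroke count as
pen lifts — air time before the first or after the last touch is not a
lift. A trace with more than 20 internal lifts is excluded by QC. Force
units are uncalibrated across devices, hence the percentile-relative
threshold rather than an absolute one.

Time-domain indicators are computed on the on-paper samples only
(off-paper segments removed, the rest concatenated): force is undefined
mid-air. Execution time is the span from first to last on-paper sample,
lift time included.

## Tremor extraction (EMD)

The tremor component is isolated from the full-length mean-removed
acceleration norm by empirical mode decomposition: classic sifting with
cubic-spline envelopes through the local extrema (mirror-extended
boundaries), stopped per IMF when the standard-deviation criterion falls
below 0.2 or after 50 sifting iterations, at most 10 IMFs. An IMF belongs
to the tremor if the argmax of its Welch PSD lies in 2–12 Hz (mirroring the
kinematic band); all in-band IMFs are summed — whether one or several modes
carry the tremor depends on its bandwidth, and summing is the conservative
choice. The decomposition is deterministic given these parameters, and
IMFs + residue reconstruct the input to floating-point precision (asserted
in tests). When no IMF falls in the band, the tremor is all-zero, the peak
frequency is flagged undefined, and every "_T" indicator is reported
missing rather than computed on noise.

The tremor component uses the full recording rather than the on-paper
concatenation: tremor is a property of the limb, not of tip contact, and
concatenation seams would corrupt the cycle-duration statistics that the
stability index depends on.

## Indicator definitions and numerical choices

- **Extrema** are strict sign changes of the first difference (plateaus
  count once, at their first sample) with a prominence guard: consecutive
  extrema whose swing is below 2% of the series' interquartile range are
  pruned, smallest first. Without the guard, sensor noise inflates the
  extrema-rate indicators (NC_F/NC_A/NC_G) by an order of magnitude; the
  relative guard keeps every CV indicator invariant under positive
  rescaling. Counts are divided by the on-paper duration.
- **SPARC** uses a zero-padded FFT (grid ≤ 0.05 Hz), magnitude normalized
  to its peak, analysis cutoff at the highest frequency ≤ 20 Hz where the
  normalized magnitude is still above the threshold (10–50% of the peak,
  the six variants), and a trapezoid arc-length integral with frequency
  scaled by the cutoff.
- **LDLJ** is −ln((T/s_peak²)·∫ṡ²dt) with a central-difference derivative;
  this dimensionless form is unit-free regardless of the signal's order.
- **Welch spectra**: Hann taper, 500-sample (10 s) segments, 50% overlap,
  0.1 Hz grid; a series shorter than one window falls back to a single
  whole-series segment and is flagged. Each spectrum's trapezoid integral
  is checked against the signal variance (Parseval, within 10%).
- **Band powers** integrate the half-open band [lo, hi) by trapezoid; the
  7–8 Hz gap between the 4–7 and 8–12 Hz bands is preserved as printed.
- **"Interval around the peak"** is ±1 Hz everywhere it occurs (peak-band
  relative power, peak-band RMS, tremor SNR, mean harmonic power), a single
  configurable half-width. The spectral peak is the PSD argmax restricted
  to 2–12 Hz.
- **Mean harmonic power** is the natural log of the mean PSD density in the
  peak band with tremor acceleration expressed in mm/s²; the log base and
  band half-width are package conventions, stated here because the measure
  has no universally fixed definition.
- **Outlier level** is the z-score of the PSD peak against the 2–12 Hz grid
  densities, (max − mean)/std; the amplitude product multiplies it by the
  peak density. The std normalization makes the quantity dimensionless and
  comparable across devices; a flat spectrum (zero std) is reported missing.
- **ApEn** uses m = 2, r = 0.2 × sample SD, Chebyshev distance,
  self-matches included; a constant series scores 0.
- **Recurrence measures** use a dim-3 time-delay embedding with the delay
  at the first autocorrelation zero-crossing (capped at 10 samples),
  recurrence threshold at 20% of the maximum pairwise distance, minimum
  diagonal line length 2, series decimated to ≤ 2000 points for the O(n²)
  matrix. Implementation equals a brute-force double-loop construction
  exactly (tested).
- **TSI** band-passes the tremor to 2–12 Hz, delimits cycles by
  positive-going zero crossings located to sub-sample precision by linear
  interpolation, and reports the IQR of consecutive cycle-frequency
  differences. The sub-sample interpolation matters: integer-sample cycle
  lengths would add ~f²/fs ≈ 0.5 Hz of quantization jitter at 5 Hz, wiping
  out the index's ability to report a perfectly stable tremor as ~0. At
  least 10 cycles are required, else missing.
- **CVs and variances** use the population (n-denominator) standard
  deviation throughout.

## Synthetic cohorts

The generator builds trials from ingredients matched to what the pipeline
measures: a 0.8 Hz drawing oscillation (the loop-to-loop rhythm of a
spiral), a frequency-jittered 2.2–3.5 Hz "drawing harmonic" (tracking-speed
fluctuation), a phase-continuous tremor whose per-cycle frequency is
Normal(f₀, σ) with f₀ ~ U(4, 7) per subject — the jitter σ is the direct
ground-truth knob for TSI — an 8–12 Hz smoothness-degrading ripple, a
broadband 7–13 Hz "jerk" component in the gyro, white sensor noise, gravity
at a wandering ~40° pen tilt, and a force profile with slow modulation, an
oscillation at a controlled extrema rate, lead/trail air time and inserted
pen lifts. Oscillatory ingredients are injected with a fixed 0.7 projection
onto the norm-dominant axis so their effective 1-D amplitudes are known.

The group presets encode the qualitative patient-vs-control contrasts the
method is meant to detect: patients get stronger (0.3–0.8 m/s²) and more
frequency-stable (σ = 0.1 Hz) tremor, much stronger gyro jerk, a faster
force oscillation (4 vs 3 extrema/s), larger force variability and fewer
pen lifts; controls get negligible tremor, smooth kinematics and more
lifts. Preset magnitudes were chosen once so that the median group
difference of each key indicator has the expected sign (this is what the
presets are *for*); they are not calibrated to any particular device's
units, and absolute indicator values are not comparable to any real cohort.
Synthetic clinical scores are noisy monotone transforms of the injected
tremor amplitude — only their rank structure is meaningful, which is all
the Spearman stage uses.

What passing tests therefore show: the pipeline recovers injected
parameters, orders groups correctly when the generating process has the
assumed structure, and its statistics are calibrated under the null. What
they do not show: performance on real pen data, where tremor is
non-sinusoidal and amplitude-modulated, noise is non-white, and the
drawing product itself (which this pipeline deliberately ignores) carries
information.

## Statistics

Per-subject indicators are the mean over the (up to two) trials; a single
usable trial passes through flagged, and a value missing in one trial
falls back to the other. Between-group testing is gated on normality: the
Lilliefors test at α = 0.05 in *each* group, both normal → unpaired t-test
with mean ± SD summaries, otherwise Mann–Whitney with median (IQR)
summaries (the AND gate is the conservative reading of "normal
indicators"). No multiplicity correction is applied by default, matching
common single-cohort reporting; a Benjamini–Hochberg flag is available.
Clinical-score correlations are Spearman's ρ with tie-corrected two-sided
p-values, run per hand on the patient group, labeled weak (|ρ| ≤ 0.3),
moderate (0.3 < |ρ| < 0.7) or strong (|ρ| ≥ 0.7). The sample-size helper
uses the Fisher-z approximation n = ⌈((z₁₋α/₂ + z_power)/atanh ρ)² + 3⌉;
for ρ = 0.503 at 95% confidence and 80% power it returns 29.

## Classification and attribution

Four model families behind one interface: logistic regression (standardized,
median-imputed), random forest, LightGBM and XGBoost (the two
gradient-boosted flavors; both handle missing values natively). Evaluation
is leave-one-out cross-validation with the patient class positive. When
restricted to the significant indicators, the significant set is recomputed
inside each fold on the training subjects only — selecting on the full
cohort would leak the held-out subject's label into its own feature set,
and a test demonstrates that nested selection is not optimistic on null
data. Metrics (accuracy, precision, recall, f1) are exact functions of the
pooled confusion counts.

Attribution is Shapley-based: the tree ensembles use their exact built-in
TreeSHAP computation on the margin (log-odds) scale, so per-subject
attributions plus the base value reproduce the model output to ~10⁻⁶
(asserted); the logistic reference uses coefficient × standardized value.
Random forest has no exact Shapley backend in this package and attribution
for it raises an error naming the supported models. Positive attribution
pushes toward the patient class.

## Problem sizes used in the checks

The acceptance checks run at 29 + 29 subjects × 2 trials × 30 s (the
design sample size), 50 generator seeds for the effect-direction suite,
200 replicates for the statistics-stage null calibration and 6 smaller
(8 + 8) full-pipeline null cohorts with pooled p-values; the acceptance
script uses 10 seeds for its direction-agreement summary. These sizes make
the whole suite runnable on a laptop-class single core in a few minutes
while keeping binomial uncertainty on the reported rates small relative to
the asserted margins.

## Known limitations

- Device force units are arbitrary; all force indicators are comparable
  within a device only, and the contact threshold is percentile-relative.
- The EMD variant is the classic single-realization decomposition; no
  ensemble (EEMD/CEEMDAN) noise-robust variants.
- The band-passed norm, not the norm of band-passed axes, is used
  throughout; for signals with strong cross-axis phase structure these
  differ.
- TSI's cycle detector assumes the tremor dominates its band; a strong
  same-band artifact (e.g., a drawing harmonic overlapping 2–12 Hz)
  inflates the index.
- Pen-tip position is not reconstructed and the drawing product is not
  analyzed; indicators describe the gesture's dynamics, not its geometry.
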