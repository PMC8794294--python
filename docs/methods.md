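# Methods

`nirspipe` reimplements, as a tested pipeline, an intraoperative fNIRS
analysis of nociception under general anesthesia: continuous-wave
dual-wavelength (690/830 nm, 25 Hz) recordings over bilateral prefrontal
(PreFC) and primary somatosensory (S1) cortex are converted to hemoglobin
concentration changes, epoched around surgical pain events, summarized as
absolute areas under standardized rolling curves and as dynamic ROI–ROI
correlations, and compared between patients with and without a peripheral
nerve block (NB vs non-NB). Because no raw patient recordings are public,
the package ships a synthetic cohort generator with known ground truth;
every downstream stage is validated against it.

## Montage

The probe model has 9 sources, 14 long-separation detectors (nominal
30 mm) and 9 short-separation detectors (8 mm, one per source), wired into
24 long channels: 12 PreFC (channels 1–6 right, 7–12 left) and 12 S1
(13–18 right, 19–24 left). Six analysis ROIs (medial PFC, lateral polar
preFC, lateral FC; superior/central/inferior S1) each contain two channels
per hemisphere. The published probe layout gives topology but not
coordinates, so the packaged geometry is a 2D schematic; the only
geometry-dependent quantity is the nearest-short-channel assignment
(Euclidean distance from each long channel's source–detector midpoint to
each short channel's source, ties to the lowest short-channel id), which is
deterministic on the fixture and cross-checked against brute force in the
tests. Beer–Lambert path lengths use the nominal separations (3.0 cm long,
0.8 cm short), not schematic distances.

Three four-channel bilateral quality regions (medial preFC, lateral preFC,
central S1) drive the subject gate; they are shipped in the montage file
and deliberately distinct from the six analysis ROIs.

## Preprocessing

Fixed order, recorded in provenance flags:

1. **Optical density**: ΔOD = −ln(I / Ī₀) with Ī₀ the mean intensity over
   a baseline window (default first 30 s; the I₀ convention is a package
   choice).
2. **Wavelet despike**: 5-level `db4` decomposition per channel and
   wavelength; detail coefficients beyond k = 3 robust SDs (MAD/0.6745,
   per level) are zeroed. At fs = 25 all detail bands lie above 0.39 Hz,
   so passband (< 0.3 Hz) content is structurally preserved; conversely,
   the low-frequency tail of very wide motion spikes survives in the
   approximation band — an inherent limit of this correction family.
3. **Bandpass 0.01–0.3 Hz**: zero-phase (forward–backward) 3rd-order
   Butterworth. Zero phase preserves event-locked latencies, on which the
   ~20 s response-peak claims depend. Measured contract: ≤ 5% amplitude
   error at 0.1 Hz, ≥ 90% attenuation at the 1.2 Hz cardiac line.
4. **MBLL inversion**: per channel, the 2×2 system
   ΔOD(λ) = ε(λ)·ΔC·d·DPF(λ) is inverted for (ΔHbO₂, ΔHbR) in µM, using a
   packaged extinction table (Prahl/Cope compilation: 690 nm — 276 /
   2051.96; 830 nm — 974 / 693.04 cm⁻¹ M⁻¹) and DPF 6.0 at both
   wavelengths (configurable; the source analysis does not state its
   constants). ΔHbT is the exact sample-wise sum. The simulator uses the
   same system forward, so round-trip recovery is exact to < 1e-9.
5. **Short-separation regression**: per species and long channel, OLS of
   the long series on its nearest short channel (with intercept); the
   residual removes shared superficial physiology. A zero-variance
   regressor degenerates to mean-centering with a warning. HbO₂ and HbR
   are regressed on their own short-channel series and HbT is recomputed
   as their exact sum — regressing HbT independently would break the
   additivity invariant, since each species has its own fitted slope and
   regressor.
6. **Detrending**: least-squares cubic fit removal, then linear fit
   removal (both with intercept, evaluated on a [−1, 1] abscissa for
   conditioning).

**Quality gate.** Channels are classed good/average/poor from the cardiac
prominence of the raw-intensity PSD (Welch average of ~20 s Hann
segments): peak-to-median power ratio in 0.7–2.5 Hz ≥ 10 → good, ≥ 3 →
average. Visual inspection is the traditional screen for a beating-heart
component; these ratios are explicit, configurable surrogates for it. A quality region is good with ≥ 2 good channels
of its 4, average with ≥ 2 average-or-better; a subject is included with
≥ 2 regions average-or-better. Poor channels are also excluded from ROI
means (a package choice; an ROI with no usable channels is reported
missing, not zero).

## Epochs and metrics

The hemisphere contralateral to the operated knee is analyzed against the
ipsilateral one (right knee → left cortex). Three 60-s epochs: **P1**
starts at the first painful event (incision onset), **P2** at the last,
**P0** is centered in the longest procedure-free gap (≥ 120 s required;
recording boundaries count as gap edges; ties go to the earliest gap).
Segments are mean-normalized, z-scored against their own mean/SD
("standardized"; a constant segment maps to zeros), and summarized by
means of 10-s windows stepped at 1 s: 51 points. The per-epoch response
scalar is the trapezoidal area under the absolute curve (so a constant ±1
curve scores 50). Z-scoring makes the metric amplitude-free: it measures
how much slow, coherent structure a window has relative to its own
variability, which is what separates an evoked response from noise.

Dynamic correlations: Pearson r over the same sliding windows for each of
the 15 unique ROI pairs, averaged within pair sets (3 within-PreFC, 3
within-S1, 9 cross, 15 total) and decimated to window starts
{0,10,20,30,40,50} for the time-course statistics; zero-variance windows
are recorded missing and excluded from set means.

## Inference

Group comparisons use a classical split-plot (two-way mixed) ANOVA:
between factor = nerve block, within factor = epoch (or window), the
between effect tested against subject-within-group MS and the
within/interaction effects against the subject×within residual. The
11-vs-8 design is unbalanced between groups but complete within subjects,
for which the weighted-means decomposition is exact; no sphericity
correction is applied. The implementation is validated against the
one-way closed form (single within level), an R `stats::aov` oracle on an
unbalanced fixture, and pingouin on balanced data. Two-sample t-tests
(pooled by default, Welch optional) compare groups per cell, and
Benjamini–Hochberg step-up FDR at α = 0.05 is applied within one analysis
family (e.g., the 18 ROI × species AUC cells per side; sides analyzed
separately). Under an ideal normal null the group F rejects at 4.9%
(2000 replicates); under the full simulated pipeline null the rate is
asserted within 5% ± 2.5% over 400 cohorts.

## Synthetic cohorts

`SimConfig` defaults encode the study conditions: 19 patients, 11/8
NB/non-NB split, 25–65 min sessions at 25 Hz, 2–12 painful procedures with
a guaranteed ≥ 2 min procedure-free gap, first incision ≥ 3 min after
start. The evoked response is a gamma-variate kernel (unit peak at a
configurable 20 s time-to-peak; the time axis is rescaled after composing
dip/undershoot lobes so the realized argmax sits exactly at the nominal
peak). Non-NB patients get a +0.41 µM contralateral-S1 HbO₂ peak with an
early dip; NB patients an attenuated (+0.12 µM) slow positive response —
the attenuation is the injected group difference. PreFC responses are
small (±0.05 µM), ipsilateral responses 25% of contralateral, HbR −0.35×
HbO₂. Systemic physiology (cardiac ~1.1 Hz, respiratory 0.25 Hz, Mayer
0.1 Hz sinusoids with phase drift, plus AR(1) noise) is shared between
long channels and their paired short channels through per-channel gains —
this is what makes short-separation regression meaningfully testable.
Slow polynomial drifts, optical-density-domain motion spikes, and white
measurement noise complete the model; the sum is pushed through the
forward Beer–Lambert model to dual-wavelength intensities (stored in
float32, which exceeds acquisition ADC precision). All draws come from
one seed; identical configs are bitwise-reproducible.

What the generator does *not* emulate: photon transport through realistic
head anatomy, spatially varying DPF, pharmacokinetic drug effects,
non-stationary heart-rate trends, and correlated multi-channel motion.
Passing tests therefore demonstrate the correctness and calibration of
the *analysis*, not clinical performance on real recordings.

## Replicated-run problem sizes

Power and type-I calibration run the full pipeline (simulation →
preprocessing → quality gate → epoching → AUC → mixed ANOVA) on replicate
cohorts of 19 patients with sessions shortened to ~6–7 min and a
correspondingly compressed event schedule (`scaled_cohort_config`); the
signal model is unchanged. Measured on this package: the injected
contralateral-S1 difference is detected (group p < 0.05, correct
direction) in ~85–95% of 50-cohort replications, and the matched null
configuration rejects at ~5% over 400 cohorts.

## Known limitations

- The montage geometry is schematic; nearest-short assignments are
  fixture-dependent (the channel-level pairing, not the method, would
  change with true coordinates).
- Wavelet despiking cannot remove sub-0.39 Hz spike energy (see above).
- The mixed ANOVA assumes normal subject-level summaries; AUC values are
  mildly skewed, which the calibration test bounds empirically.
- SNIRF I/O is a minimal interoperability subset (one continuous-wave
  data block), not a full implementation of the standard.
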