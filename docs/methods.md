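# Methods

`neuromark` implements an EEG analysis chain for a block-design
neuromarketing experiment — band power topography, interelectrode
coherence, envelope long-range temporal correlations (LRTC), group
statistics, and preference clustering — together with a synthetic cohort
generator that produces recordings with *known* band powers, coherences,
and envelope scaling exponents, so that every estimator in the chain can be
validated against ground truth.

## The experiment being modeled

One session is 75 s of 21-channel EEG (10-20 montage, ear references A1/A2)
sampled at 256 Hz: a 5 s pre-stimulus baseline, an emotional-stimulation
stage S1 (five 4 s trials of car images), a 5 s decision interval D1, an
attentional-stimulation stage S2 (five 8 s trials of images plus written
specifications), and a second 5 s decision interval D2. The cohort is 45
subjects: 16 who select the electric car (group A) and 29 who do not
(group B). Analysis uses the 19 scalp derivations; coherence uses the 13
frontal/central/parietal/occipital electrodes.

## Synthetic data generator

Each scalp channel in each stage is a sum of enveloped narrowband
oscillations, a 1/f background, and white sensor noise:

    x(t) = sum_b sqrt(P_b) e_b(t) c_b(t) + pink(t) + sensor(t)    [uV]

* **Carriers.** Delta/theta/beta carriers are FIR-filtered white noise,
  normalized to unit *in-band* power (the transition skirts of a
  windowed-sinc filter hold ~15% of total power, which would otherwise bias
  band powers low). The alpha carrier is an oscillator with band-limited
  random frequency modulation: instantaneous frequency f0 + df(t), with f0
  drawn once per subject from U(9.5, 10.5) Hz (individual alpha frequency)
  and df Gaussian noise of SD 1 Hz smoothed to ~1.6 Hz bandwidth. Its
  spectrum is a compact ~2-3 Hz line with steep tails. The FM design
  balances three competing needs: the carrier's analytic amplitude is
  nearly constant (so the Hilbert envelope of the band-filtered output
  recovers the *imposed* envelope); the line is wide enough that a
  phase-randomized surrogate's envelope decorrelates within ~1 s (so the
  surrogate test has a target to destroy); and the power stays essentially
  inside 8-12 Hz. A filtered-noise carrier fails the first requirement
  badly (its own envelope fluctuations swamp the imposed ones), and a pure
  phase-diffusion (Lorentzian) line fails the second.
* **Envelopes.** The alpha envelope is exp(sigma * fGn_H(t)) with fGn_H
  exact fractional Gaussian noise of Hurst exponent H (circulant embedding
  of the fGn autocovariance, O(n log n), exact ensemble variance 1; a
  spectral-synthesis fallback covers the rare non-negative-definite
  embedding). sigma is set so the envelope coefficient of variation is 0.5.
  The Gaussian process is smoothed (Gaussian kernel, 0.05 s) *before* the
  exp transform and re-standardized: smoothing after the transform tilts
  the fluctuation function and biases DFA exponents upward by ~0.05 even at
  2-13 s scales, whereas smoothing-then-rescaling leaves the slope there
  unchanged. Enveloped components are scaled so their measured Welch band
  power equals the requested value (AM sidebands put ~15-20% of the total
  power just outside the band).
* **Coherence.** Targeted electrode pairs share a common alpha carrier:
  each member mixes x = w*s + sqrt(1-w^2)*n with w = target^(1/4), which
  gives theoretical magnitude-squared coherence w^4 between pair members
  for spectrally matched unit-variance inputs. The pairwise primitive
  `impose_coherence` implements exactly this closed form; the session
  generator generalizes it to a common-source set so Cz can be coherent
  with Pz and Fp2 simultaneously.
* **Group effects (synthetic choices).** The study reports only the
  *significance* of its group differences, never effect sizes, so the
  generator's defaults are free parameters chosen once to make the effects
  detectable at n = 16 vs 29: group A has a 1.8x frontal-central alpha
  power gain in all processing stages, alpha MSC targets of 0.5 (vs 0.05
  for group B) on Cz-Pz and Cz-Fp2, and stage-wise envelope Hurst
  exponents 0.6 (S1, S2), 0.7 (D1), 0.9 (D2) vs 0.6 everywhere for group
  B. Both groups share an attentional S2 alpha gain of 1.6x at Cz and C4.
  Between-subject variability is lognormal on band power (sigma of log:
  0.25 for alpha, 0.2 otherwise, plus 0.1 per-channel jitter). Group ages
  are N(27, 4) vs N(34, 5), clipped to the 20-43 study range.
* **Scale.** Baseline band powers are delta 30, theta 20, alpha 15, beta 8
  uV^2 with a 10 uV^2 1/f background and 2 uV^2 sensor noise — a resting
  EEG-like mixture with total SD near 9 uV. A1/A2 carry sensor noise only.

What the generator does **not** emulate: ocular/muscle artifacts, line
interference, volume conduction (channels are independent except for the
imposed coherence), non-stationarity within stages, or evoked responses.
Passing tests therefore validate the estimators and the statistical
pipeline, not robustness to real-world artifacts — on real data an
artifact-rejection stage (e.g. ICA) must precede this chain.

## Analysis chain

* **Preprocessing.** Zero-phase (forward-backward) Butterworth bandpass,
  order 4, 0.5-45 Hz. Zero-phase application avoids latency shifts at stage
  boundaries; the effective magnitude order is 8. Note an order-4 filter at
  these cutoffs only attenuates a 50 Hz tone to ~30% amplitude — with
  artifact-free synthetic data no notch is needed. Band-specific work uses
  zero-phase windowed-sinc FIR filters (Hamming, length 3*fs/low, odd).
* **PSD.** Welch, 1 s Hamming windows, 0.5 s overlap, nfft = 256: exactly
  1 Hz bins at 256 Hz. One-sided density normalized so its integral equals
  signal variance; band power is the trapezoid integral over the band
  (keeps Parseval interpretability). Bands: delta 1-4, theta 4-8, alpha
  8-12, beta 12-30, whole 1-40 Hz.
* **Coherence.** MSC(f) = |G_XY|^2 / (G_XX G_YY) with cross/auto spectra
  averaged over 10 s Hamming epochs, 3 s overlap. The 5 s decision stages
  cannot hold a 10 s epoch; they fall back to 1 s Welch subwindows and the
  estimate is flagged degenerate. MSC has a small-sample bias of roughly
  (1-MSC)^2/N for N averaged epochs — a floor of ~0.1-0.25 on short
  segments. Group contrasts ride on top of this floor; absolute MSC values
  on 5 s segments should not be over-interpreted. Topographic maps use
  biharmonic (thin-plate) spline interpolation over the unit head disc,
  exact at the electrodes.
* **DFA.** Mean-subtract, integrate, log-spaced window sizes with 50%
  overlap, per-window linear detrend, RMS residual F(t); the exponent is
  the least-squares slope of log F vs log t. Fit ranges: 2-20 s for long
  series (capped at a quarter of the series); for short segments (5 s
  stages, 4 s chunks) an adaptive 0.25 s to length/4 range. Short-range
  exponents are scale-dependent — narrowband envelopes look smooth below
  ~1 s, so absolute values run high (~1.2-1.5) there; only contrasts
  between conditions/groups are interpreted at those scales. Band-specific
  exponents are computed on the Hilbert amplitude envelope (5% edge trim)
  of the FIR-band-filtered signal.
* **Surrogates.** Phase randomization preserves Fourier amplitudes exactly
  (Hermitian symmetry enforced, DC/Nyquist real). The nonlinearity test
  pairs each channel's envelope exponent with the mean over 10 surrogates
  (envelope recomputed per surrogate from the raw band-filtered signal) and
  applies a two-sided Wilcoxon signed-rank across channels; all-zero
  differences return p = 1.
* **Group statistics.** Paired-t contrast maps per electrode, reported as
  -log10(p) with significance threshold -log10(0.05) ~ 1.3 and no
  across-electrode correction by default (a Bonferroni option exists).
  Factorial ANOVA (band x group x stage) uses Type II sums of squares
  because the 16/29 design is unbalanced; an all-constant response is
  reported as F = 0, p = 1 by convention. The "repeated-measures" ANCOVA
  reduces to a between-subject linear model feature ~ group * age because
  each feature is one scalar per subject — sphericity is not applicable;
  effect sizes are partial eta squared, SS_eff/(SS_eff + SS_err).
  Chi-square on 2x2 tables is Pearson without continuity correction
  (Yates available); Shapiro-Wilk handles normality, with constant samples
  mapped to p = 0.
* **Clustering.** Features (band powers on log10 scale, coherences, DFA
  exponents) are z-scored and concatenated per preset. k-means (k = 2) is
  Lloyd's algorithm under squared-Euclidean (mean centroids) or city-block
  (componentwise-median centroids, the L1 optimum) distance, best of 25
  seeded restarts; an emptied cluster is re-seeded at the farthest point.
  Cluster labels are aligned to self-report by maximizing accuracy
  (degenerate mappings allowed, so accuracy never falls below the majority
  prevalence); PPV takes group A as positive. The centroid-identity test
  is a PERMANOVA-style permutation pseudo-F on the pairwise distance
  matrix (999 permutations; equivalent to one-way ANOVA in 1-D); note it
  is anticonservative when the grouping under test was itself produced by
  k-means on the same features. The dispersion test compares per-subject
  distances to their own cluster centroid between clusters by one-way
  ANOVA (the beta-dispersion recipe); all-zero distances give p = 1.

## Numerical and design notes

* All randomness flows from one master seed through `numpy` SeedSequence
  spawning; per-subject streams are derived from (master seed, subject
  index), so any subject can be regenerated alone. Same configuration,
  same bytes on disk.
* EDF output uses 1 s records, 16-bit quantization over a symmetric
  per-channel range; round-trip error is bounded by range/65535. Header
  dates are fixed so files are byte-reproducible.
* The MSC calibration check (MSC vs mixing weight following c^4) uses 2 s
  epochs with 1 s overlap on 60 s signals: the default 10 s epoching fits
  only N = 8 epochs there, whose small-N bias (~1/N at c = 0) exceeds the
  0.05 tolerance the check uses. The analysis default remains 10 s / 3 s.
* Events are 0-based seconds over half-open intervals [onset,
  onset + duration); segmentation conserves samples exactly.
* Validation problem sizes: DFA anchors use n = 65536 samples; Hurst
  recovery averages 20 replicates per H; estimator-calibration checks use
  60 s signals; the pipeline-recovery study uses 20 replicate cohorts of
  45 subjects x 75 s. These sizes give standard errors comfortably inside
  the tolerances being checked.

## Known limitations

* Short-segment DFA exponents are scale-dependent summaries, not Hurst
  estimates; only their contrasts are meaningful.
* Coherence on 5 s segments carries a known positive bias floor.
* The centroid-identity p value is biased when grouping by k-means output
  (use self-report grouping for inference).
* The generator's effect sizes are synthetic choices; accuracy figures on
  synthetic cohorts characterize the pipeline, not human EEG.
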