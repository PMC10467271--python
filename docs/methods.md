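# Methods

This note documents the models and numerical choices behind `fnirsnet`: what
the synthetic cohorts contain, how each analysis stage is defined, which
parameters matter, and what the simulation studies do and do not establish.

## Synthetic cohorts

The generator produces two-group cohorts (default 19 PSD vs 18 non-PSD,
HAMD ≥ 8 vs < 8, HAMD drawn uniformly from 8–25 / 0–7) of 14-channel
bilateral-DLPFC recordings at 11 Hz: a 20-s rest baseline followed by a
360-s oddball train (25% deviants, 0.05-s stimuli, inter-stimulus intervals
uniform on 1–3 s). Each subject's HbO series is the sum of:

- **Evoked response**: the stimulus impulse train convolved with a canonical
  double-gamma HRF (peak 6 s, undershoot 16 s, undershoot ratio 1/6),
  deviants at 0.15 µM peak and standards at 0.05 µM. Hemodynamic responses
  are not perfectly reproducible, so each trial's amplitude is jittered
  uniformly by ±50% per channel, and each channel carries a fixed ±20% gain.
  Without this partial decoherence a common regressor would drive all
  task-state correlations towards 1 and erase any planted covariance
  structure.
- **Correlated background**: multivariate Gaussian noise with the planted
  group/state covariance, band-limited to the spontaneous
  low-frequency-oscillation band (0.03–0.2 Hz) by the same zero-phase filter
  family used in preprocessing and rescaled per channel to 0.1 µM SD
  (per-channel rescaling leaves correlations intact). The 0.03 Hz floor
  matters: components near 0.01 Hz complete only ~4 cycles in a 380-s record
  and make sample correlations extremely unstable (SD ≈ 0.21 vs ≈ 0.10 at
  0.03 Hz).
- **Systemic physiology**: sinusoids at 1.2 Hz (cardiac, 0.15 µM), 0.25 Hz
  (respiration, 0.10 µM) and 0.10 Hz (Mayer waves, 0.05 µM) with one global
  phase per component and a small (±0.3 rad) per-channel lag — systemic
  oscillations are near-coherent across a 14-channel prefrontal patch — plus
  a linear drift of up to ±0.2 µM over the recording. Cardiac and
  respiratory lines sit outside the 0.01–0.2 Hz analysis band by design, so
  the band-pass stage is testable; the Mayer wave deliberately sits inside it.
- **Optics**: HbR is coupled as −HbO/3; the forward modified Beer–Lambert
  model (3 cm pathlength, DPF 6, tabulated extinction coefficients at
  730/808/850 nm) maps concentrations to optical density and intensity
  I = I₀·10^(−OD) with per-channel I₀ ~ U(0.5, 2). Motion artifacts are
  injected in OD space: spikes (Hann-shaped, 0.4 s, 10× the channel's OD SD)
  and baseline shifts (step, 8× SD, persisting to the end of the recording).

**Covariance structure.** Baseline inter-channel correlation decays with the
planar distance between channel midpoints, r(d) = 0.15 + 0.45·e^(−d/5 cm),
giving heterogeneous edge weights (near-uniform weights would make the
thresholded graphs degenerate cliques). The planted PSD effect modifies the
task-state profile only, by default: coupling between the mid-frontal
channel 7 and lateral channels 1, 3, 4, 10, 11, 13, 14 is reduced by 0.35 in
correlation, and short-range pairs away from channel 7 gain +0.15 (elevated
local clustering). A rest-state knob (elevated 4–6 and 2–5 coupling) exists
but defaults to zero, so rest is a built-in negative control. Matrices are
projected onto the PSD cone (eigenvalue clipping) when planting pushes an
eigenvalue negative, with a warning. Per-subject covariance heterogeneity is
modelled as a Wishart draw around the group covariance (df = 150,
correlation SD ≈ 0.065); without any between-subject variability the
classification task would be unrealistically easy.

**Ground truth for recovery checks** is the *in-band clean HbO*: the
artifact-free hemodynamics (evoked + background + physiology + drift)
restricted to the 0.01–0.2 Hz analysis band. No band-limited pipeline can
recover out-of-band content, so recovery quality measures exactly what it
should: the OD conversion, artifact repair and Beer–Lambert inversion.

**What the generator does not emulate**: scalp/skull optical layering and
partial-volume effects, HbR-specific dynamics (HbR is a fixed multiple of
HbO), non-stationary physiology (fixed-frequency sinusoids rather than
drifting rhythms), spatially-structured motion artifacts, and behavioral
responses. Passing tests therefore validate the *pipeline* — not claims
about clinical populations.

## Analysis stages

- **OD baseline**: I₀ is the whole-recording mean per channel per wavelength
  (configurable to the rest-period mean). A constant OD offset is removed by
  the band-pass, so the choice is immaterial downstream.
- **Artifact windows** are consecutive and non-overlapping
  (round(0.5 s × fs) = 6 samples; a trailing partial window is still
  checked); the trial SD is computed on raw OD per channel per wavelength,
  and a window is flagged if any wavelength violates max−min > 6×SD. Flagged
  samples are replaced by a cubic spline through all clean samples of the
  channel; flagged stretches at the recording edge fall back to
  nearest-value extrapolation (logged). A fully flagged channel is an error.
- **Filter**: Butterworth order 3 applied forward–backward (zero phase),
  band 0.01–0.2 Hz. At 11 Hz sampling this attenuates a 1.2 Hz probe by far
  more than 20 dB and passes 0.05 Hz within 1 dB.
- **Beer–Lambert inversion** uses all three wavelengths in a least-squares
  solve (pseudoinverse of the 3×2 extinction design); the extinction table
  is a standard tabulated compilation shipped with the package, DPF 6.0 at
  all wavelengths (both configurable). ΔHbR is computed but unused
  downstream.
- **Connectivity**: Fisher z = atanh(r) with |r| clipped at 1−10⁻⁷;
  diagonal excluded everywhere. Negative weights are zeroed after the
  transform (atanh preserves sign, so the order is immaterial). Binarization
  keeps the K = floor(s·N(N−1)/2) strongest positive weights; ties break by
  ascending channel-pair lexicographic order for reproducibility.
- **Graph metrics** are implemented from first principles (BFS distances,
  Brandes betweenness halved for undirected pairs, Newman assortativity with
  both edge orientations, hierarchy as minus the OLS slope of log NCp on
  log k over nodes with k ≥ 2 and NCp > 0) and cross-checked in the test
  suite against independent brute-force and networkx oracles. Disconnected
  graphs are inevitable at sparsity 0.15: Lp averages over connected pairs
  only, efficiencies use 1/∞ = 0, and undefined values (assortativity of a
  regular graph, hierarchy without degree variance) are NaN and propagate to
  a NaN AUC, which feature assembly imputes by the column median (logged).
  Small-world references are degree-preserving double-edge-swap surrogates
  (10×E attempted swaps, seeded, connectedness not enforced), 100 per
  network by default. Betweenness is unnormalized; group comparisons are
  scale-invariant to this.
- **Statistics**: two-sample comparisons use the pooled-variance Student
  t-test when both groups pass Shapiro–Wilk at 0.05, otherwise
  Kruskal–Wallis (with two groups, a two-sided rank test; a one-tailed
  request under non-normality is reported two-sided with a flag). Edge-wise
  comparisons default to two-tailed tests: a data-driven one-tailed test has
  a 2α type-I rate, which would break calibration; one-tailed mode is
  available and reports the tested direction. No multiple-comparison
  correction by default (Benjamini–Hochberg behind a flag). Spearman
  correlations with HAMD pool both groups and use midranks.
- **Classification**: standardization and the PCA projection (95% retained
  variance) are fitted strictly inside each training fold — fitting them on
  the full cohort before cross-validation leaks held-out information and
  inflates accuracy. Class weights are inversely proportional to class
  frequency ("balanced"); the kernel is linear by default, C = 1. Accuracy
  per repeat is pooled correct/total over the 8 stratified folds; the report
  gives mean ± SD over 10 repeats.

## Simulation studies and problem sizes

`fnirsnet.simulations` packages two cohort-level studies. Both generate
cohorts at the HbO stage — the optical forward model and its inversion are
linear and validated separately, so skipping them does not change
connectivity — and run within minutes on one CPU:

- **Null calibration** (200 cohorts of 19 vs 18): with no planted effect,
  the fraction of significant edge-wise tests (91 per state, two-tailed,
  uncorrected) and metric-wise tests should match α = 0.05. The metric-wise
  check uses the six surrogate-free global metrics (Cp, Lp, Eloc, Eg, r, b);
  the small-world ratios are quotients of two of these and would multiply
  the cost a hundredfold without adding calibration information. Because
  edges within a cohort share subjects, fractions are aggregated at the
  cohort level and compared with the binomial 95% interval
  α ± 1.96·√(α(1−α)/200). The normality-gated cascade is mildly
  conservative (observed ≈ 0.047 for edges), as expected when a slice of
  tests is routed to the rank test.
- **Effect recovery** (50 cohorts, task-state effect only, 6 surrogates for
  the small-world features, 10 CV repeats): counts how often the task state
  shows more significant edges, more significant metrics, and higher
  classification accuracy than rest. Under the default planted effect all
  three hold in well over 90% of cohorts; typical accuracies are ~0.65–0.80
  (task) vs ~0.40–0.55 (rest).

## Known limitations

- The 20-s rest baseline yields only 220 samples; rest-state correlations
  are noisy and rest-state results should be read as a negative control, not
  as a powered analysis. The generator exposes `rest_duration_s` for studies
  that need a longer baseline.
- At 79 features and 37 subjects the classifier operates far into the
  p ≫ n regime; cross-validated accuracy sits well below the asymptotic
  optimum for a given feature-space separation and varies substantially
  across cohort draws.
- Hierarchy (b) follows the C ∝ k^(−b) log-log regression convention;
  eligibility excludes NCp = 0 nodes, so on sparse graphs it may rest on few
  points and is frequently NaN at low sparsity.
- Fisher-z clipping at |r| = 1−10⁻⁷ caps z at ≈ 8.4; exactly duplicated
  channels therefore produce a finite, arbitrary-but-documented weight.
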