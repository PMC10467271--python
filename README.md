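# fnirsnet

Graph-theoretic analysis of prefrontal fNIRS functional connectivity for
separating post-stroke depression (PSD) from non-depressed stroke survivors,
with a fully synthetic data generator so the entire pipeline is testable
without clinical recordings.

## The problem and the method

Post-stroke depression is common, clinically important and still diagnosed
by subjective rating scales. Functional near-infrared spectroscopy (fNIRS)
over the dorsolateral prefrontal cortex offers a cheap, portable window on
cortical hemodynamics. The analysis implemented here characterises the brain
*network* rather than single channels, during an auditory oddball attention
task and at rest:

1. **Acquisition model** — 14 channels (7 sources, 6 detectors, 3 cm
   separation) over bilateral DLPFC at 11 Hz and 730/808/850 nm; a 20-s rest
   baseline followed by a 360-s oddball train (25% deviant tones, 0.05-s
   stimuli, 1–3 s intervals).
2. **Preprocessing** — light intensity → optical density
   OD(t) = −log₁₀(I/I₀); motion-artifact windows (0.5 s windows flagged when
   max−min > 6 × whole-trial SD) repaired by cubic-spline interpolation;
   zero-phase 0.01–0.2 Hz band-pass; modified Beer–Lambert inversion
   ΔOD(λ) = [ε_HbO(λ)ΔHbO + ε_HbR(λ)ΔHbR]·d·DPF(λ) solved by least squares
   over the three wavelengths.
3. **Connectivity** — Pearson correlation of HbO between all channel pairs,
   Fisher-z transformed, separately for the rest and task segments; negative
   weights zeroed; binarized at sparsity thresholds 0.15–0.50 (step 0.05).
4. **Graph metrics** — per network: clustering Cp, characteristic path
   length Lp, small-world Gamma = Cp/⟨Cp_rand⟩, Lambda = Lp/⟨Lp_rand⟩,
   Sigma = Gamma/Lambda (100 degree-preserving rewired surrogates), local and
   global efficiency Eloc/Eg, assortativity r, hierarchy b (slope of
   log NCp vs log k); nodal NCp, Ne, NLe, Dc, Bc. Each metric is summarised
   across the sparsity sweep by its area under the curve (AUC), giving
   9 + 5×14 = 79 features per subject per state.
5. **Statistics** — edge-wise and metric-wise two-group comparisons
   (Shapiro–Wilk-gated t / Kruskal–Wallis), Fisher's exact test for
   demographics, Spearman correlation of metrics with HAMD scores.
6. **Classification** — cost-sensitive linear SVM (class weights inverse to
   class frequency) on principal components retaining 95% of training-fold
   variance, stratified 8-fold cross-validation repeated 10 times.

The synthetic generator plants a group difference in the task-state channel
covariance (weakened mid-frontal-to-lateral coupling and elevated local
clustering in the PSD group), so the pipeline's headline claim — task-state
network features discriminate the groups better than rest-state features —
can be verified against known ground truth.

## Worked example

```python
import fnirsnet as fn

model = fn.CohortNetworkModel.from_synthetic(n_psd=19, n_nonpsd=18, seed=11)
results = model.fit()
print(results.summary())
```

prints (seed 11, default study conditions; the synthetic cohort is generated
at the raw-intensity stage and preprocessed in full):

```
fNIRS Brain-Network Cohort Analysis
============================================================
Subjects: 19 PSD vs 18 non-PSD (79 features/state)
Sparsity sweep: 0.15-0.50 (8 thresholds), alpha=0.05, uncorrected

state    sig.edges sig.metrics sig.HAMD-rho            accuracy
---------------------------------------------------------------
rest             2           5            4        52.70% ± 7.67%
task            32          20           25        86.22% ± 2.37%
---------------------------------------------------------------
CV: 8-fold × 10 repeats, PCA variance retained 0.95, linear SVM with balanced class costs
```

Reading the table: the planted task-state effect produces many more
significantly different connectivity edges (32 vs 2 of 91), more
significantly different metric AUCs (20 vs 5 of 79) and a clearly
higher cross-validated classification accuracy in the task state than at
rest — the qualitative signature this analysis is designed to expose.
`results.edge_stats`, `results.metric_stats`, `results.spearman`,
`results.classification` and `results.features` hold the full tables.

A command-line interface mirrors the stages:

```bash
fnirsnet simulate --n-psd 19 --n-nonpsd 18 --seed 1 --out cohort/
fnirsnet run-all --seed 1 --outdir run/
fnirsnet preprocess cohort/S001.csv
```

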