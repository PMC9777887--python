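# Methods

This note records the modelling choices behind specfuse: what each stage
computes, the parameters that matter, what the synthetic generator does
and does not emulate, and the decisions taken where the design was
genuinely open.

## Classification model

Class membership over `k` classes is one-hot ("node") coded and fitted by
multi-response PLS regression on the preprocessed calibration spectra.
The PLS core is **SIMPLS** (de Jong 1993): deterministic, intercepts
handled by centering X and Y with calibration means, and the whole
coefficient path available from a single fit — which makes cross-validated
selection of the latent-variable count cost one fit per fold. At
`n_components = rank(X_c)` the coefficients coincide with least squares
(asserted in the tests against an explicit normal-equations oracle);
scikit-learn's NIPALS `PLSRegression` serves as an independent
cross-check, not as the implementation.

* `n_lv` — latent variables. Policy `"cv"` (default) picks the count
  minimizing stratified 10-fold cross-validated misclassification, ties
  to the smallest count; `max_lv` defaults to 15–20, consistent with the
  5–17 range typical for spectra of this dimensionality.
* Class assignment is the argmax node value; exact ties break to the
  lowest class index.
* Cross-validation is stratified k-fold with a fixed derived seed.
  Preprocessing statistics (MC means, MSC reference) are refit inside
  every training fold; variable selection is performed once on the full
  calibration partition and held fixed across folds (selection-inside-CV
  is a different, far costlier estimator; the out-of-fold numbers should
  be read accordingly).

## Preprocessing semantics

All operators are row-local except MC/MSC fitting, so permuting sample
rows commutes with every operator.

* **SNV** divides by the sample standard deviation (n−1 divisor, the
  Unscrambler convention); the choice only rescales rows by a constant
  factor.
* **FD** (first derivative) is implemented as Savitzky-Golay with
  derivative order 1, window 15, polynomial order 2, scaled by the grid
  step — the standard chemometric derivative, less noise-amplifying than
  simple differencing. Window and order are configurable.
* **BA** (baseline) subtracts the straight line through each row's first
  and last points, then shifts the row minimum to zero. An `offset`
  mode (minimum subtraction only) is available; the linear term guards
  tilted baselines. Constant rows map to zeros rather than erroring.
* **MSC** regresses each row on the calibration-mean reference spectrum
  and inverts the fitted affine map; the reference is refit on every
  pipeline fit (and inside every CV fold).
* Degenerate rows (constant where spread is required) raise an error
  naming the sample rather than emitting NaNs.

## Wavenumber selection

All selectors rank/score against RMSECV — the root mean squared
out-of-fold node error of a 5-fold PLS fit (fixed folds per call,
stratified by class), with `n_lv` capped at 10 inside selection loops.
Ties everywhere break to the lowest column index.

* **CARS** runs `N = 100` Monte-Carlo iterations; each draws 80% of the
  calibration rows, fits PLS on the surviving variables and weights
  variables by mean absolute regression coefficient across the k nodes
  (a single ranking is needed; the mean is the aggregation choice).
  The retention count follows the exponentially decreasing function
  `rᵢ = a·e^{−k·i}` with `a = (p/2)^{1/(N−1)}`, `k = ln(p/2)/(N−1)`, so
  run 1 keeps all `p` variables and the final run keeps exactly 2.
  Adaptive reweighted sampling is implemented as coefficient-weighted
  sampling *without* replacement of exactly the retained count — this
  keeps the subset-size trace deterministic and non-increasing (the
  canonical with-replacement draw yields a random unique count); the
  stochastic competition between variables is preserved through the
  weights. The subset with minimal RMSECV (earliest run on ties) wins.
* **SPA** builds one greedy chain per starting column by successive
  orthogonal projections (add the column with maximal residual norm
  against the span of the chain), then scores every chain prefix by
  cross-validated misclassification count of a PLS-DA fit on the chain.
  Integer error counts make the enumeration exactly reproducible; ties
  break to the shorter chain, then the lower start index.
* **IRIV** repeats classification rounds: a 500-row binary inclusion
  design (inclusion probability 0.5), RMSECV per row-subset, and per
  variable the difference `dmean = mean(error | excluded) −
  mean(error | included)` with a two-sided Mann-Whitney p-value
  (α = 0.05 splits strong from weak informative). Variables with
  `dmean > 0` are retained; rounds iterate until a round drops nothing,
  then greedy backward elimination removes survivors whose removal does
  not raise RMSECV.

## Bayesian decision fusion

Node values are mapped to probabilities by clipping negatives to zero
and renormalizing; the fused posterior is the normalized product of the
two modality vectors, optionally prior-weighted (the prior is exposed
but defaults to uniform). Decisions require the argmax posterior to
exceed the runner-up by strictly more than the threshold (default 0.01;
the comparison uses a 1e-12 guard so a margin *equal* to the threshold
stays unassigned under float arithmetic).

Degenerate cases, decided once and flagged in reports:

* all-nonpositive node rows map to the uniform distribution (the
  relative-probability rule is undefined at zero mass) with a warning;
* disjoint supports (zero product mass, posterior undefined) fall back
  to the normalized average of the two vectors;
* `UNASSIGNED` samples count as errors — false negatives for their true
  class and never false positives for any class — keeping accuracy
  comparable across models that always assign.

Data-layer fusion concatenates the full preprocessed grids; feature-layer
fusion concatenates the per-modality selected variables. Each block is
autoscaled column-wise with calibration statistics before concatenation
(NIR absorbance and Raman counts are incommensurate in scale), and the
fused matrix feeds a single PLS-DA. For cross-validation rows the fused
decision model combines each modality's out-of-fold node values (same
fold assignment in both modalities) rather than refitting.

## Evaluation

Metrics are one-vs-rest per class: sensitivity TP/(TP+FN), specificity
TN/(FP+TN), accuracy (TP+TN)/total, in percent. Headline values are
unweighted macro-averages — for a balanced design macro- and pooled
averaging coincide in expectation; macro is the documented choice.
Classes with no true samples are excluded from the macro sensitivity
with a warning. The confusion matrix carries an extra UNASSIGNED column.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes:
two modalities on fixed grids (4000–9000 cm⁻¹ × 2593 points NIR-like,
1000–2000 cm⁻¹ × 669 points Raman-like), 8 classes × 40 samples × 3
replicate scans. Each spectrum is a sum of Gaussian peaks — a backbone
at recognizable band positions (water O-H overtones near 5145/6920 cm⁻¹
and a fat C-H band near 8387 cm⁻¹ in NIR; phenylalanine 1004 cm⁻¹,
CH₂ 1443 cm⁻¹, amide I 1662 cm⁻¹ in Raman; amplitudes are free
parameters, not chemical claims) plus three class-specific peaks per
modality — corrupted by per-peak amplitude jitter (10%), a degree-2
polynomial baseline, per-sample affine scatter (slope SD 0.1, offset SD
0.02) and i.i.d. noise (SD 0.02 against peak amplitudes of order 1).
Replicates share all sample-level effects and differ by noise only, so
SNV applied to a scatter-corrupted noiseless spectrum recovers the SNV
of the clean template (asserted).

**Complementarity** pairs classes and makes a configured fraction of
pairs share an identical peak library in one modality while staying
distinct in the other, alternating the blind modality between pairs. At
the default 0.5 with 8 classes, one pair is NIR-blind and one
Raman-blind: each single modality is capped near 87.5% accuracy while
the fused model can approach 100% — the regime the decision-fusion claim
is tested in. Peak widths (30–120 cm⁻¹ NIR, 6–25 cm⁻¹ Raman) follow the
qualitative morphology of the two techniques; peaks are Gaussian, not
Voigt.

What the generator does **not** emulate: fluorescence backgrounds,
detector nonlinearity, wavelength-calibration drift, correlated
(pink/structured) noise, water-band saturation, or any real covariance
between NIR and Raman responses of one chemistry. Passing tests
demonstrate correctness of the algorithms and the fusion mechanism under
the assumed structure, not instrument-level performance on real cod
spectra.

`oracle_bayes_error` provides Monte-Carlo nearest-template accuracies
(after SNV, fused channel = both blocks weighted by 1/√p) as a reference
ceiling for calibrating test expectations.

## Numerical choices and problem sizes

* Degenerate-spread guards at 1e-12; SIMPLS deflation stops at component
  norms below 1e-10 (the fit then carries fewer components).
* All stochastic stages draw named sub-seeds (below 2³¹) from the master
  seed via one generator, making full pipeline reruns byte-identical.
* Split rule: per class `round(fraction × class size)` calibration
  samples with ties resolved downward, clamped so both partitions keep
  every class (0.75 × 40 → 30/10).
* The test suite and the acceptance script run the full-size generator
  (320 × 2593 + 320 × 669) for the fusion comparison, and reduced grids
  (200–500 NIR points, 100–250 Raman points) for end-to-end pipeline
  runs involving IRIV, whose inner loop (500 subsets × 5 folds per
  round) dominates runtime; these sizes are the package's documented
  desk-scale defaults for examples and CI-style runs.

## Known limitations

* Selection happens once on the calibration partition, outside the CV
  loop (see above); cross-validated metrics for selected-variable models
  are mildly optimistic, as in most chemometric practice.
* The RMSECV magnitude depends on the node-coding scale (k one-hot
  columns); traces are comparable within a run, not across codings.
* Fusion is pairwise; more than two modalities would need an explicit
  product chain (the math extends, the interfaces do not yet).
* IRIV's runtime grows linearly in design rows × folds and is the
  pipeline's bottleneck on full grids.
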