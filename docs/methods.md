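# Methods

This note documents the models, parameter defaults and numerical
choices behind `neoms`, and what the synthetic validation does and does
not establish about real neonatal EEG.

## The microstate model

EEG is modelled as a sequence of microstates: intervals during which the
scalp potential topography is quasi-stable up to polarity and amplitude.
A microstate map is a zero-mean (average-referenced), unit-norm vector
with one entry per electrode, defined only up to sign; every comparison
in the package is therefore polarity-invariant (absolute spatial
correlation). Amplitude is carried by the global field power (GFP), the
per-sample standard deviation across channels; topographic
signal-to-noise is highest at GFP peaks, so only peak samples enter the
clustering.

### Modified k-means

Clustering alternates (i) assigning each peak topography to the map
with maximal squared spatial correlation and (ii) re-estimating each map
as the first principal eigenvector of its cluster's outer-product sum.
Defaults: 20 restarts, at most 500 iterations, convergence when the
relative change in explained variance is below 1e-6. An emptied cluster
is reseeded from the currently worst-fit sample. The best restart by
explained variance wins. On tiny inputs the result matches exhaustive
search over all assignments (verified in the tests to 1e-9).

### Choosing the number of maps

The Krzanowski–Lai criterion is computed on the within-cluster
dispersion `W(k)` for k = 3…15 (clustering also runs at k = 2 and 16 so
the statistic is defined at both ends):

    DIFF(k) = (k-1)^(2/m) W(k-1) - k^(2/m) W(k),   m = n_channels - 1
    KL(k)   = |DIFF(k)| / |DIFF(k+1)|,             k_opt = argmax KL(k)

Two choices deserve explanation because the elbow statistic is fragile:

* **Dispersion form.** `W(k)` is the trace of the within-cluster
  scatter *orthogonal to each cluster's principal axis*:
  `W = Σ_i (|x_i|² − (x_i·m_{l(i)})²)`. Clusters of topographies are
  axes, not centroids (polarity is meaningless), so the residual is
  taken about the map axis rather than about a mean. This is also
  exactly the quantity the modified k-means minimizes, which makes the
  W(k) curve smooth in k. A GFP-discarding alternative (mean pairwise
  polarity-invariant distance between normalized topographies) was
  evaluated and rejected: its tail is dominated by sensor noise and the
  KL ratio then peaks at arbitrary large k instead of the generating k.
* **Positivity guard.** Candidates for the argmax are restricted to
  k with `DIFF(k) > 0` — a genuine elbow requires an actual dispersion
  improvement at k. Without the guard, near-zero DIFF values on the
  flat tail of the curve occasionally produce enormous
  `|DIFF(k)|/|DIFF(k+1)|` ratios and spurious selections. If no k has
  positive DIFF the unrestricted argmax is used.

The effective dimension is m = 8 for the 9-channel montage: the common
average reference removes one degree of freedom.

### Backfitting and smoothing

Every sample of the continuous epoch (not only GFP peaks) is labelled
with the best-correlated map; ties break to the lowest map index, and
zero-variance samples inherit the previous label (map 0 at the epoch
start) and are flagged. Scaling the epoch or flipping any map's sign
changes no labels.

Smoothing follows the classical segmentation-smoothing scheme: each
sample's misfit term — the variance its map leaves unexplained, divided
by `2e(C−1)` where `e` is the mean residual variance of the unsmoothed
fit and C the channel count — is reduced by `penalty × (number of
same-label neighbours within ±w samples)`, and samples are relabelled
iteratively to a fixed point (at most 100 sweeps). Defaults: window
30 ms (w = 3 samples at 100 Hz, interpreted one-sided) and penalty 1.
Penalty 0 returns the input labels unchanged.

### Metrics

Run-length encoding of the label sequence gives, per map: duration =
mean run length / fs (s), occurrence = runs per second (Hz), coverage =
fraction of samples. `coverage = occurrence × duration` holds exactly
per map, as does `1 = overall occurrence × overall duration`. Boundary
runs truncated by the epoch edges are included (the bias is < 0.2% for
5-minute epochs at ~0.2 s runs); the occurrence denominator is the full
epoch length (epochs carry no missing data). Maps with no runs get
zeros and are flagged.

## Statistics

* **Syntax chi-square.** Transition counts between consecutive runs are
  compared with the no-self-transition chance expectation
  `E(A→B) = n_out(A) · q_B / (1 − q_A)` (q = run-label shares). The
  null distribution shuffles the run-label sequence preserving the
  label multiset; shuffles with adjacent equal labels are repaired by
  local redraws (random swaps accepted only when they remove a
  violation without creating one). The p-value uses the add-one
  estimator `(1 + #{null ≥ obs}) / (1 + n_perm)`, which can never
  return 0 and has floor 1/(n_perm+1). For groups, counts are pooled
  across epochs and each epoch is shuffled independently.
* **Per-transition tests.** Across the epochs of a group, observed
  minus expected transition probabilities are tested against zero with
  two-sided paired t-tests, Benjamini–Hochberg-corrected across the
  k(k−1) ordered transitions of that group; directions and two
  significance tiers (0.05, 0.1) are reported.
* **TANOVA.** The similarity of two maps is their absolute spatial
  correlation; the null permutes the channel order of *one* map
  (permuting one side already destroys spatial alignment, and absolute
  correlation matches the package-wide polarity convention).
  Significance means *similarity*. Under the channel-permutation null
  the p-values are uniform (calibrated in the tests, KS < 0.05).
* **Hurst exponent.** A categorical sequence has no canonical random
  walk, so each of the `2^(k−1) − 1` nontrivial bipartitions of the
  label alphabet is mapped to ±1, integrated, and analysed with
  order-1 detrended fluctuation analysis over 15 log-spaced box sizes
  in [10, N/4]; H is the mean log-log slope across bipartitions. The
  estimate is invariant under relabelling. Constant bipartition series
  are skipped; a fully constant sequence is an error.
* **Age trends.** Per sleep state, Pearson r (with two-sided p) and the
  least-squares slope of each individual-track metric against PMA; the
  tidy long table (subject, PMA, GA, sleep state, metric, value) is
  exported for external mixed-effects modelling, which is deliberately
  out of scope here.

## The synthetic cohort

The generator is the package's validation instrument; its defaults are
the study conditions every recovery test runs under.

* **Maps:** random zero-mean unit-norm 9-channel vectors, resampled
  until all pairs satisfy |corr| ≤ 0.6 (distinguishability); infeasible
  requests (e.g. 2 maps on 2 channels, whose average-referenced space
  is one-dimensional) fail after a bounded number of attempts. No
  dipole/head model is used: the analysis is reference- and
  geometry-agnostic, so only map separation matters.
* **Label sequences:** either semi-Markov — i.i.d. geometric run
  lengths with mean `fs · duration_ms / 1000` and run labels from a
  zero-diagonal transition matrix — or long-range dependent — exact
  fractional Gaussian noise (circulant embedding) thresholded at its
  empirical quantiles into equiprobable symbols. The two constructions
  make duration/occurrence/syntax and the Hurst exponent independently
  controllable dials. The cohort combines them: geometric run lengths
  plus run labels read off a thresholded fGn series (skipping repeats
  so adjacent runs differ).
* **Forward model:** `epoch(t) = m_{L(t)} · a(t) + noise`, with `a(t)`
  Gaussian noise bandpassed to 0.5–4 Hz (the delta band dominating
  neonatal EEG) at 50 µV RMS, and spatially white average-referenced
  Gaussian noise scaled to the configured snr. At infinite snr the
  topography at every GFP peak equals the active map exactly.
* **snr calibration:** the default snr (0.37) was fixed by bisection
  (`calibrate_snr`) so that the full pipeline — preprocess, 4-map
  clustering, smoothed backfit — yields a mean GEV of ≈ 0.695, the
  level typical of neonatal recordings. GEV grows monotonically with
  snr, so the bisection is well-posed.
* **Cohort design:** 48 subjects by default, gestational ages uniform
  in 24.6–32.0 weeks, 2–4 recordings per subject placed in *distinct*
  PMA age groups (≤31, 32–33, 34–36, ≥37 weeks; boundaries 32/34/37 on
  real-valued PMA), one QS and one NQS epoch per recording. Maturation
  rules are linear in PMA with per-subject Gaussian intercepts
  (duration sd 10 ms, Hurst sd 0.015) emulating the random-intercept
  structure a mixed model would absorb: duration 260 ms at 30 weeks
  falling 10 ms/week; Hurst target 0.73 at 30 weeks falling 0.012/week.
  Slopes were chosen at the magnitude reported for preterm cohorts and
  so that the rules stay inside physiological bounds over PMA 26–44
  weeks without clipping. The QS−NQS effect defaults to 0 for both
  rules (no direction is imposed; it is a config parameter).

### What the simulation does not emulate

No artefacts, no discontinuous (tracé alternant) background, no
sleep-state-specific spectra, no volume-conduction geometry, no
electrode noise correlations, and only the QS/NQS dichotomy. Passing
recovery tests therefore show the *analysis chain* is correct and
well-calibrated under a plausible generative model — not that the
clinical findings would replicate on any particular real dataset.

### Known limitation: duration attenuation at realistic snr

At the GEV-calibrated snr, noise around the zero-crossings of the
activation waveform fragments label runs faster than the 30 ms/penalty-1
smoothing can repair, so recovered mean durations are compressed toward
shorter values (the tests freeze the measured band: a 200 ms target is
recovered at ~130–165 ms at default snr, and within 180–220 ms at
snr = 10). Rank order across epochs is preserved — recovered duration
correlates with the generating duration at r ≥ 0.9 on 5-minute epochs —
so trend analyses (correlations with PMA) are unaffected, but absolute
durations at low snr should be read as lower bounds.

## Simulation sizes

The test suite and `scripts/acceptance.py` use scaled problem sizes
chosen as a practical compromise while keeping every threshold
meaningful: 60-s epochs for the KL/GEV/map-recovery and cohort checks,
20 epochs or seed pairs per recovery rate, 1000
replicates with 199 or 500 permutations for the calibration of the
randomization tests, and a 20-subject cohort (~100 epochs) for the PMA
trend recovery. The truth-correlation check runs at the full 300-s
epoch length, where per-epoch measurement noise is small enough for the
r ≥ 0.9 criterion.

## Degenerate inputs and tie-breaking

GFP peaks are strict left / non-strict right local maxima (plateau
onset wins); assignment ties break to the lowest map index; zero-GFP
samples inherit the previous label and are flagged; empty clusters are
reseeded; single-label sequences are rejected by the syntax tests;
transitions whose expectation is undefined (absent labels) are excluded
and flagged; non-finite KL values are recorded in the returned curve
but excluded from the argmax. All stochastic stages derive their seeds
from one root seed through fixed spawn keys, so every pipeline output
is a pure function of (inputs, config, seed).
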