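# Methods

`motornet` analyses resting-state near-infrared spectroscopy (NIRS)
recordings of the motor cortex as binary functional networks and asks two
questions: how do the network's small-world properties differ between
healthy controls and stroke patients with mild or moderate-to-severe (MtS)
dyskinesia, and how well do those properties predict the clinical grading at
the level of a single subject.  This note documents the model at each stage,
the tunable parameters and their defaults, what the synthetic cohort
generator does and does not emulate, and the numerical choices that a reader
of the results should know about.

## Pipeline model

**Preprocessing.** Each recording is a channels × samples matrix of Δ[HbO₂]
in mM·mm (22 channels, 10 Hz, 6 min by default).  Four steps run in order:

1. *Motion-artifact detection and correction.*  A sample is flagged when
   the max−min excursion inside a 1-s moving window exceeds `k` times the
   channel's robust SD (1.4826 × median absolute deviation, so the spikes
   being hunted do not inflate their own threshold); flags are dilated by
   half a window.  Default `k = 6`, which keeps the false-positive rate on
   Gaussian noise below 1% while still catching 10-SD spikes.  Flagged
   segments are corrected by fitting a cubic smoothing spline inside the
   segment (smoothing parameter: generalized cross-validation by default),
   subtracting it, and re-seating the residual on a linear baseline joining
   the clean levels on either side — the movement-artifact reduction
   (MARA) scheme.  Segments shorter than 5 samples are replaced by the
   baseline directly.
2. *Band-pass.*  Zero-phase Butterworth of design order 2, 0.01–0.1 Hz —
   the band carrying spontaneous low-frequency hemodynamic fluctuations.
   Zero-phase (forward–backward) application preserves zero-lag
   correlations; the effective order is therefore 4.  Initial conditions
   use Gustafsson's method and the channel mean is removed before
   filtering: the low corner has a 100-s time constant, and with default
   reflect padding the start/end transients of a 350-s record otherwise
   dominate its variance (measured effective sample count collapses from
   ≈ 67 to ≈ 7).
3. *Common average reference (CAR).*  The cross-channel mean is subtracted
   at every sample, suppressing the shared superficial (scalp) component.
   Note CAR also shifts all pairwise correlations downward by roughly the
   mean channel covariance over the channel count; this is inherent to the
   method, not an artifact of the implementation.
4. *Trimming.*  First and last 5 s dropped, so a 360-s recording yields
   350 s of analysed signal (3500 samples).

If, after correction, more than `residual_limit` (default 5%) of samples
still look artifactual, the cleanest contiguous 180-s window is analysed
instead of the full record; the decision is logged per subject.

**Connectivity.**  Pearson correlation between every channel pair, Fisher-Z
transformed (`atanh`, inputs clipped to ±(1−10⁻⁷)), diagonal set to zero.
The weighted matrix is binarized by *proportional* thresholding: at
sparseness threshold *t* the strongest (1−*t*) fraction of |Z| values become
edges — `round((1−t)·n(n−1)/2)` of them — so every subject's network has the
same edge count and group comparisons are not confounded by overall
correlation strength.  Ties at the cut break by ascending (row, column)
index, making sweeps reproducible and the edge sets nested.  The default
sweep is t = 0.30 … 0.70 in steps of 0.01 (41 networks).  Negative
correlations enter by absolute value.

**Small-world metrics.**  On each binary network with *m* nodes:

* clustering coefficient `C = (1/m) Σᵢ 2eᵢ/(Kᵢ(Kᵢ−1))` with `Cᵢ := 0` for
  degree < 2 (`eᵢ` = edges among node i's neighbours);
* characteristic path length `L` = mean shortest-path length over
  *reachable* ordered pairs (the reachable fraction is reported; a
  fragmented network at a sparse threshold would otherwise give L = ∞);
* global efficiency `GE` = mean of 1/dᵢⱼ over ordered pairs with 1/∞ := 0;
* local efficiency `LE` = mean over nodes of the global efficiency of the
  subgraph induced by each node's neighbours (0 for degree < 2) — the
  plain per-node mean, i.e. the Brain Connectivity Toolbox convention;
* transitivity `T` = 3 × triangles / connected triples (0 when no triples).

Normalized ratios γ = C/C_rand, λ = L/L_rand and small-worldness δ = γ/λ
compare against an ensemble (default 100) of degree-preserving
Maslov–Sneppen rewirings of the same network (10 attempted double-edge
swaps per edge, igraph's simple rewiring), with C_rand and L_rand the
ensemble means.  A small-world network shows γ > 1, λ ≈ 1, δ > 1.  Each
metric's curve over the sweep is reduced to a scalar subject feature by
trapezoidal integration over the threshold grid (the metric "AUC").

**Group statistics.**  Per feature, an ANCOVA — OLS of
`feature ~ group + age + gender`, type-II partial F for the group factor —
followed by pairwise Fisher-LSD posthoc contrasts (unadjusted pairwise
t-tests on the covariate-adjusted means, gated by the omnibus test at
α = 0.05).  A covariate with no variation in the supplied table (e.g. a
single-gender cohort) is dropped from the model rather than failing.
Per-threshold group tests reuse the same model, with Benjamini–Hochberg FDR
applied within each metric across the 41 thresholds (the FDR family is
per-metric; pooling across metrics would be the more conservative
alternative).  Patient features are related to motor function by partial
correlation between each AUC and the Fugl-Meyer Assessment (FMA) score with
age and gender residualized out; p-values use a t reference with
n − 2 − k degrees of freedom.

**Classification.**  One-versus-rest (OVR) linear SVMs on the eight AUC
features.  Feature selection is recursive feature elimination: repeatedly
drop the feature with the smallest aggregate |weight| across the three OVR
classifiers.  Accuracy is estimated by nested cross-validation —
leave-one-out outer loop; inside each outer training fold a stratified
10-fold grid search selects the SVM regularization C (default grid
10⁻²…10², 5 points) and the retained-feature count (1–8); scaler, ranking
and hyperparameters are all fitted on the training fold only.  Pooled
out-of-fold predictions yield the confusion matrix, accuracy, per-class
sensitivity/specificity and OVR ROC curves.  A separate full-data RFE run
provides a single reported feature ranking with weights normalized to sum
to 1; it is labelled as such and never used for accuracy estimation.

## Synthetic cohort generator

No patient recordings are distributed with studies of this kind, so the
package generates cohorts whose *latent* network topology differs by group
and whose recordings pass through the identical pipeline.

* **Latent topology.**  Each subject owns a binary 22-node graph from the
  Watts–Strogatz family: a ring lattice with k = 8 neighbours (88 edges,
  density 88/231) whose edges are rewired independently with probability
  *p*.  Small *p* gives a regular, highly clustered, long-path network;
  large *p* an essentially random one.  Group defaults: Healthy *p* = 0.70,
  Mild 0.22, MtS 0.04, with per-subject uniform jitter of half-width
  0.04/0.03/0.015.  These values were calibrated in pilot simulations to
  reproduce the qualitative ordering and significance pattern of the
  metrics (C, LE, T: MtS > Mild > Healthy; GE reversed); effect sizes are
  not calibrated to any reported data.  Global efficiency is the binding
  constraint in that calibration: under proportional thresholding the
  edge count is fixed, so GE moves only through path structure, and its
  usable span across the rewiring range is roughly two within-subject
  standard deviations at the study's 350-s recording length.  The chosen
  Mild level is a deliberate compromise between the GE omnibus contrast
  (which peaks with Mild nearer 0.3) and single-subject Mild-vs-Healthy
  discriminability (which needs Mild nearer 0.2); no setting achieves
  both fully at this signal-to-noise ratio.
* **Covariance model.**  The latent graph maps to a target covariance via a
  network-diffusion (resolvent) kernel: correlations proportional to the
  normalized (I − αA)⁻¹ with α = 0.7/λ_max(A), rescaled so the mean
  correlation of directly connected pairs is `edge_strength` (default
  0.45), with geometric diagonal loading as a positive-definiteness
  safety net.  Correlation therefore decays with graph distance, as in
  real cortical recordings; a strict two-valued covariance was rejected
  because it gives two-step neighbours exactly zero true correlation and
  the thresholded empirical networks then carry almost none of the latent
  topology.
* **Signals.**  Correlated Gaussian series (Cholesky) are band-limited by
  an ideal FFT band-pass to 0.01–0.1 Hz — flat in-band power, so 350 s
  carries the full ≈ 2·BW·T ≈ 63 effective samples — then a shared
  band-limited superficial component (amplitude 0.5, removed later by CAR)
  and broadband white sensor noise (SD 0.3 relative to the unit neural
  series) are added, and everything is scaled to a realistic 0.03 mM·mm
  amplitude.
* **Artifacts.**  Motion spikes arrive as a Poisson process (default
  2/min); each is a half-sine deflection of width 0.2–0.8 s with random
  sign on one random channel, peaking at 10 clean-signal SDs.  Exact
  positions are returned for testing the detector.
* **Clinical metadata.**  FMA = 328 − 300·(1 − pᵢ) + N(0, 8), truncated
  to the group's range (Mild ≥ 85, MtS < 85: the clinical cutoff), so FMA
  decreases with latent regularity and the expected correlation signs
  (negative for C/LE/T, positive for GE) are recoverable.  Ages and
  male/female proportions per group mimic a typical poststroke cohort
  (controls ≈ 51 ± 3 y, patients 60–65 y, mostly male), which deliberately
  confounds age with group — the reason the group statistics adjust for
  age and gender.  Healthy subjects carry no FMA.
* **Reproducibility.**  Per-subject random streams are spawned from the
  master seed keyed by subject index, so enlarging one group never shifts
  another subject's realization.  The whole pipeline is deterministic
  given the config.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: hemodynamic response shapes and vascular
physiology (Mayer waves, respiration, cardiac harmonics above the band),
optode-geometry and scalp-coupling effects, Hb/HbO₂ coupling, baseline
shifts and slow drifts (only transient spikes are injected),
lesion-location heterogeneity, and any nonstationarity of connectivity.
Recovery results on this cohort demonstrate that the pipeline measures what
it claims on band-limited, static-covariance signals of realistic length
and noise level; they do not certify effect sizes on patient data.

## Numerical choices and degenerate inputs

* Effective correlation dof at 350 s in the 0.01–0.1 Hz band is ≈ 60; all
  sampling-noise expectations in the tests derive from this.
* Edge counts use round-half-up of the retained fraction; the spec of
  "first 60%" at t = 0.4 on 10 pairs gives exactly 6 edges.
* A constant channel's correlations are set to 0 with a warning (not an
  error); constant features are centred but not scaled.
* Fragmented networks: L over reachable pairs with the fraction logged;
  GE uses 1/∞ = 0; an empty graph has undefined L (NaN).
* δ is computed as γ/λ exactly; ensemble seeds are spawned per threshold
  from the subject seed, so profiles are reproducible one by one.
* Networks with fewer than two edges cannot be rewired and are returned
  unchanged (with a warning) by the null-model generator.
* All tabular outputs are plain CSV/JSON; the run manifest records SHA-256
  hashes of every written file.

## Problem sizes

Default analyses use the full study geometry: 42 subjects × 22 channels ×
350 s at 10 Hz, 41 thresholds, 100 random references per network (≈ 172k
reference networks per cohort run).  The test suite exercises the same
geometry with a reduced 20-reference ensemble for the small-world recovery
check and reduced hyperparameter grids in classification tests; the
acceptance script uses the full 100-reference ensemble.

## Known limitations

* Static covariance only; dynamic or windowed connectivity is out of scope.
* Weighted-network metrics, partial-correlation/coherence connectivity,
  nodal statistics beyond what the five base metrics need, and nonlinear
  SVM kernels are not implemented.
* The LSD posthoc convention means per-contrast (not family-wise) error
  control beyond the omnibus gate.
* Whether RFE belongs inside or outside the outer CV loop is genuinely
  ambiguous in this design; both are provided (per-fold selection for
  honest accuracy, a full-data ranking for interpretation) and clearly
  labelled.
* With 42 subjects and ≈ 60 effective samples per correlation, the
  global-efficiency group contrast is intrinsically weak; occasional
  non-significant GE ANCOVAs on resimulated cohorts are expected behaviour,
  not a pipeline defect.
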