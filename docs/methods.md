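# Methods

This note documents the models, estimators and numerical choices behind
`phaseconn`, and what the synthetic-data validation does and does not
establish.

## Signal model and preprocessing

Input is a continuous multichannel EEG recording (microvolts) with
stimulus markers carrying one of three repetition labels. The
preprocessing chain is fixed and deterministic:

1. **Zero-phase FIR bandpass**, default 0.5–80 Hz with 60 dB stopband
   attenuation over 0.5 Hz transitions, plus an optional IIR notch at
   50 Hz (Q = 35). The FIR is a Kaiser-window design; at 1000 Hz the
   printed spec lands at ~7000 taps. Zero phase is realized as a single
   convolution with the symmetric kernel h∗reverse(h) (identical to
   forward–reverse filtering), so the group delay is exactly zero and
   the effective attenuation doubles in dB. Recordings shorter than 3×
   the filter length are rejected with the required minimum.
2. **Epoching** 0–10 s after each marker, with per-trial, per-channel
   scalar baseline correction over the closed window −200 to −2 ms
   (samples with −0.200 ≤ t ≤ −0.002 s at the pre-resampling rate).
   Events too close to the recording edge are dropped and counted in a
   logged warning; trial counts are otherwise conserved.
3. **Polyphase resampling** to 500 Hz (anti-aliased; equal rates are an
   explicit no-op, upsampling is rejected).
4. **Induced response**: the per-condition trial-mean waveform (ERP) is
   subtracted from every trial; the residual trial mean is zero to
   numerical tolerance. Groups of fewer than two trials are rejected.
   An artifact-removal hook (`ica_clean`) is exposed as identity —
   synthetic data are artifact-free, and visual component selection is
   not reproducible.

## Spectra and WPLI

Each 10 s epoch (5000 samples at 500 Hz) is tapered with a single
symmetric Parzen (de la Vallée Poussin) window and Fourier-transformed
at its native 0.1 Hz resolution. The analysis grid selects the native
bins that are exact multiples of 0.5 Hz in [4, 45] Hz — 83 bins; since
a 10 s epoch makes every 0.5 Hz multiple an exact bin, no zero padding
or bin averaging is involved.

The weighted phase lag index per pair (i, j) and bin f is

    WPLI_ij(f) = | Σ_k Im S_ij^k(f) | / Σ_k |Im S_ij^k(f)| ,
    S_ij^k(f)  = X_i^k(f) conj(X_j^k(f)) ,

with k running over trials; the per-trial single-taper cross-spectrum
is the expectation estimate, and the trial ensemble enters only through
the two sums. Statistics downstream use the magnitude (a non-negative
synchronization strength in [0, 1]); the diagonal is zero. A denominator
that vanishes up to rounding — a purely real cross-spectrum, e.g. an
exact zero-lag copy — yields value 0 with a degeneracy flag rather than
0/0. The estimator is validated edge-by-edge against a literal
per-trial loop over the definition (1e−12 agreement).

Band averages are arithmetic means over member bins. Bands are
half-open [low, high) — theta [5–8), alpha [8–13), beta1 [13–17),
beta2 [17–22), beta3 [23–28), beta4 [28–33), gamma1 [33–38) — except
the topmost band gamma2 [38–45], closed so 45.0 Hz is included. Theta
therefore averages exactly the six bins 5.0–7.5 Hz, and the grid bins
4.0, 4.5, 22.0 and 22.5 Hz belong to no band and are excluded. This
realization reproduces the canonical theta worked example exactly;
whether the original toolboxes selected or averaged sub-bins is not
documented, so the choice is isolated behind `BandScheme`.

## Cluster Span Threshold

CST picks a binarization density without a tunable parameter. For each
candidate density d (grid 1–100 % in 1 % steps) the top-d fraction of
edges by weight is retained (zero-weight pairs carry no connectivity
and are never retained); each retained edge is a *cluster* edge if it
participates in at least one triangle of the retained graph, else a
*span* edge. The selected density is the grid point whose cluster-edge
proportion is nearest 0.5 (ties to the lower density). Equal weights
are ordered lexicographically by pair index when the deterministic
tie-break is enabled (the default); with it disabled, a fully tied
matrix is rejected. A sweep in which no density produces a triangle
(e.g. a star graph) selects the lowest density and raises a degeneracy
flag. Triangle detection is validated against brute-force triple
enumeration, and selection is equivariant under node relabeling.

The mask is computed per band on the group-mean WPLI matrix (mean over
subjects and conditions) and the *same fixed mask* is applied to the
observed and every permuted statistic map. Because the grand mean is
invariant under within-subject condition permutations, this keeps the
permutation null exchangeable. The proportion definition, grid and tie
handling operationalize the cluster-vs-span idea and are deliberately
isolated behind this module's interface.

## Edge statistics and cluster permutation correction

Per edge and band, the three repetitions are compared with a one-way
repeated-measures ANOVA with subject as blocking factor,
F = MS_condition / MS_(condition × subject), df = (k−1, (k−1)(n−1)) —
(2, 38) at the full scale of 20 subjects — or, for pairwise contrasts,
a paired t on per-subject differences (df = 19 at n = 20). Zero
residual variance yields an infinity sentinel plus a degeneracy flag;
an entirely constant table yields F = 0.

Multiplicity over the masked edge set is controlled non-parametrically:

1. cluster-forming threshold = the parametric critical value of the
   statistic at `cluster_forming_alpha` (default 0.005);
2. supra-threshold masked edges are grouped into clusters, two edges
   being adjacent iff they share an electrode (equivalently, clusters
   are the connected components of the graph drawn by the
   supra-threshold edges, per band);
3. cluster mass = sum of the statistic over member edges; for each
   permutation (within-subject condition-label permutation for F;
   per-subject condition swaps, i.e. sign flips of the differences, for
   t) the full statistic map is recomputed, the same mask and threshold
   applied, and the maximum cluster mass recorded;
4. corrected p = (1 + #{perm max ≥ observed mass}) / (1 + n_perm),
   which can never be exactly zero. Clusters with p below
   `cluster_alpha` (default 0.005) are significant.

F is inherently one-tailed; for t contrasts the positive and negative
tails are clustered and tested separately, each against its own
max-mass null at the same alpha — this reconciles a one-tailed cluster
rule with a two-tailed 0.01/2 = 0.005 level. The cluster statistic
(mass rather than size) and shared-electrode adjacency are the standard
graph analogues of sensor-neighborhood clustering; both sit behind
`PermutationScheme`/`permutation_cluster_test` so alternatives can be
swapped in. When the requested permutation count exceeds the number of
distinct relabelings (6^n for F, 2^n for t), the test warns and
enumerates exhaustively. The default permutation count is 1000 for
desk-scale runs; the full-scale 50,000 is a configuration value.

## ROI pooling, FDR and the behavior GLM

Six regions of interest are fixed electrode groups (right/left frontal:
F2/F4/F6/FC2/FC4/FC6 and F1/F3/F5/FC1/FC3/FC5; right/left parietal:
CP2/CP4/P4/P6/CP6 and CP1/CP3/P3/P5/CP5; right/left temporal:
FT10/FT8/T8/TP8/P8 and FT9/FT7/T7/TP7/P7). The 12 analyzed pairings are
all bilateral frontal–parietal, frontal–temporal and temporal–parietal
combinations. Pooled connectivity is the mean WPLI over the Cartesian
product of the two groups' electrodes (30 pairs for right frontal ×
right parietal), excluding self-pairs. Each band × pair is tested with
the same RM-ANOVA engine and corrected with Benjamini–Hochberg FDR over
the full 8 × 12 = 96 family at 0.05 ("FDR" is read as
Benjamini–Hochberg, its default meaning in this literature).

The behavior link is a regression through the origin: per subject, the
pooled-connectivity difference between two repetitions is regressed on
the corresponding behavior-score difference (mean Likert score per
condition), under a normal GLM with identity link and no constant, so
slope = Σxy/Σx² with the slope's t-test on n−1 df (fit via OLS without
intercept). An all-zero predictor or an exact fit is flagged degenerate
with no p-value. FDR is applied within each contrast's family of
2 bands × 12 pairs = 24 analyses (contrast families are reported
separately, matching how such tables are printed; pooling all 72 into
one family is the obvious alternative and a one-line change).

## Synthetic studies

The generator emulates the statistical structure the analysis assumes,
not the biophysics. Per subject and trial, each channel is the sum of:

- 1/f^α background noise (α = 1 by default), synthesized by spectral
  shaping of white noise and normalized to unit RMS;
- a zero-lag broadband common source shared by all channels with
  per-subject fixed random channel gains (uniform 0.5–1.5 × the
  configured gain) — a static volume-conduction confound;
- planted narrowband couplings: for edge (a, b, band, lag, κ), channel
  a receives a band-limited source s(t) (zero-phase band-filtered white
  noise, unit RMS) and channel b receives κ_condition · s delayed by
  lag/(360 · f_center) seconds — a pure delay gives an approximately
  constant phase lag within a narrow band. The source is regenerated
  independently per trial with the same lag sign; a 0° lag is rejected
  at construction since the WPLI is blind to it by design.

Behavior scores are 2 + slope · f_s · (repetition index 0,1,2) + N(0,
0.5), clipped to the 1–7 scale; f_s is a per-subject factor
(N(1, 0.3), floored at 0.2) that also scales the planted coupling
strengths, so that subjects who familiarize faster show both larger
behavior gains and larger connectivity gains — the structure the GLM is
meant to detect. The defaults plant one theta edge (F4–CP4) and one
alpha edge (FC6–P6) with κ = (0, 0.4, 0.8) across repetitions, equal
source and noise RMS, and a unit-gain common source.

Scales: the default test scale is 10 subjects × 16 channels (the
right-hemisphere ROI subset) × 12 trials per condition;
`StudyConfig.full_scale()` gives 20 subjects × 51 channels × 28 trials,
matching the acquisition design. Generation is at 1000 Hz by default;
validation studies run the generator at 500 Hz (the analysis rate),
which leaves the 0.5 Hz analysis grid and everything downstream
unchanged while halving synthesis cost. The generator does **not**
emulate head-model mixing beyond the single common source, artifacts
(blinks, muscle), non-stationarity across a session, or realistic
trial-count spread across subjects (trial count is a config value, not
a distribution). Passing tests therefore establish correctness of the
estimators and calibration/power of the inference chain under the
assumed signal structure — not robustness to real-world artifacts.

## Numerical and reproducibility choices

- Simulation arithmetic is single precision (float32) for speed and
  memory; all statistics run in double precision.
- Every stochastic component is driven by `numpy` `SeedSequence`
  fan-out from one global seed, so identical configuration + seed
  reproduces every result table bit-exactly, and each stage rerun in
  isolation reproduces its output.
- Validation problem sizes: family-wise error calibration uses 200
  common-source-only studies (10 subjects × 16 channels × 12 trials,
  1000 permutations, α = 0.05); planted-edge recovery uses 25 seeded
  replicates of the default design; estimator oracles run on 100
  random spectral tensors and 50 random RM-ANOVA tables; the
  planted-coupling monotonicity check averages over 100 simulated
  subjects.
- TSV tables print floats at 4 decimals; the HDF5 artifacts keep full
  precision.

## Known limitations

- The exact CST variant (proportion definition, grid, tie handling) and
  the cluster statistic definition are interpretations of
  under-specified published procedure; both are isolated behind single
  interfaces and validated for their own invariants.
- The paper-scale permutation count (50,000) and full-scale study are
  supported but not exercised by the default test suite.
- EDF files are read but not written (no writer dependency); the
  BrainVision writer stores float32 multiplexed data and Stimulus
  markers only.
- The epoch-domain preprocessing path (used for synthetic epochs) skips
  the continuous bandpass filter; the continuous path applies it.
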