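# Methods

This note records the models, estimators, parameter choices and known
limitations of `betasw`, stage by stage.

## Signal model and synthetic cohorts

The generator (`betasw.synthetic`) emulates the data entering the
connectivity stage: per-subject current-density time series for 26
Brodmann-area ROIs at 250 Hz, band-limited to beta (13–30 Hz).

Each ROI carries an independent **base oscillation**: white Gaussian noise
filtered to the band with a zero-phase Hamming windowed-sinc FIR (~1 Hz
transition), normalized to unit variance.  A **coupling edge**
(source → target, gain g ∈ [0, 1], lag ℓ > 0 ms) adds g × the source's
base oscillation delayed by ℓ to the target.  Contributions are taken from
base oscillations, not from the accumulated signals, so arbitrary edge
sets cannot create feedback loops.  Independent white measurement noise
(default SD 0.3 relative to the unit-variance oscillation) is added last;
an optional shared zero-lag component (`instantaneous_mix`) emulates
volume-conduction-like instantaneous mixing for robustness tests.

**Cohort layout** mirrors a two-group stroke cohort: 29 subjects, 16
low- / 13 high-fatigue, sexes 13 M/3 F (low) and 5 M/8 F (high).  FSS-7
scores are truncated normals on the group's own side of the > 4 boundary
(low: mean 2.1, SD 0.8 on [1, 4]; high: mean 5.6, SD 0.6 on (4, 7]), so a
generated label can never contradict the grouping rule; degenerate
parameter sets (a group mean on the wrong side) are rejected.  Clinical
covariates (age, grip and nine-hole-peg percentages, HADS anxiety and
depression with the ≤ 11 inclusion cap, affected hemisphere, stroke type,
vascular territory with ~17% missing, time post-stroke) are independent
draws with plausible marginals; no covariate correlations are modelled.

**Planted group effect.**  Every network of every subject carries a weak
lagged coupling ring (gain 0.35) as shared baseline structure.  The group
difference is a **coupling hub**: one ROI per target network coupled to
every other ROI of that network with gain 0.5 at a common 20 ms lag — in
the sensory networks for high-fatigue subjects and in the motor networks
for low-fatigue subjects.  Two properties make the hub the right planted
topology:

1. Because all hub→spoke lags are equal, any two spokes share the hub's
   signal at zero relative lag; lagged coherence discards instantaneous
   dependence, so the connectivity matrix acquires a clean *star* of
   strong edges rather than a clique.
2. Under the weight-multiset-preserving surrogate null, a star raises
   normalized clustering (the hub's triangles have high geometric-mean
   intensity under the cube-root weighting) while *shortening* normalized
   paths (two strong hops through the hub connect every pair), so Sw
   rises.  Concentrating strong weights into triangles or cliques does the
   opposite — it lengthens normalized paths faster than it raises
   clustering and *lowers* Sw (measured: a strong 4-clique on a dense
   background gives Sw ≈ 0.59) — which is why the effect is planted as a
   hub and not as triads.

The hub gain (0.5) was calibrated once so that the network × fatigue
interaction is detected in ≥ 80% of 100 seeded cohorts at 60-s recordings,
then frozen.  The sensory response (ΔSw ≈ +0.24) is larger than the motor
response (ΔSw ≈ −0.08): star salience scales with network size and the
6-node motor networks respond more weakly than the 7-node sensory ones.
The crossover sign — sensory Sw up, motor Sw down in high fatigue — is the
modelled pattern; the asymmetry also induces a fatigue main effect that a
real cohort need not show.

Scalp projections mix the ROI series through a random Gaussian full-rank
matrix to 64 channels at 1 kHz (µV-scale), not through a physical head
model; blink-like frontal transients and broadband spikes can be injected
at known times with a ground-truth log.  What passing tests show is
therefore that the *pipeline* behaves correctly on signals with the
assumed statistical structure — band-limited Gaussian oscillations with
lagged linear coupling — not that real EEG satisfies those assumptions
(real data add 1/f background, nonstationarity, muscle/ocular artifacts
and genuine source geometry).

## Preprocessing

Fixed stage order: downsample → band-pass → bad-channel detection →
epoch → reject → ICA slot → interpolate → common-average re-reference.

- **Downsampling** (default 1 kHz → 250 Hz): polyphase resampling with the
  built-in anti-alias FIR (`resample_poly`, linear-edge padding), > 40 dB
  alias attenuation, DC-exact.
- **Band-pass** 0.1–47 Hz: Hamming windowed-sinc FIR, ~0.5 Hz transition
  (≈ 1651 taps at 250 Hz), applied centred so the symmetric kernel is
  exactly zero-phase; passband ripple < 0.1 dB, stopband > 50 dB.
- **Bad channels**: robust variance z-score across channels
  (median/MAD, |z| > 3) plus a flatline check; an all-flagged recording is
  an error.  The criterion is deterministic and documented in the output.
- **Epoching**: consecutive non-overlapping 2-s windows; a trailing
  partial window is discarded.
- **Epoch rejection**: the across-channel mean signal m(t) is computed
  (bad channels excluded); each epoch's statistic is fenced at
  mean ± 2 SD.  The default variant (`epoch_mean`) uses the per-epoch mean
  of m(t), with the SD taken across epochs.  Any two-sided 2-SD fence
  flags ≈ 4.5% of clean Gaussian epochs by construction, so artifact-free
  retention sits at ≈ 95.5%; high-amplitude transients shift an epoch's
  statistic many fences away and are removed.  A stricter `sample_wise`
  variant (reject if any sample of m(t) leaves the global ± 2 SD band) is
  provided as a switch for sensitivity analyses; on continuous Gaussian
  data it rejects most epochs and is not the default.  Known limitation:
  because the fence is estimated from all epochs, one very large artifact
  inflates the SD and can mask a weaker one (masking is inherent to
  mean ± 2 SD rules; a robust median/MAD fence would avoid it but is not
  the modelled procedure).
- **ICA slot**: ocular-component removal requires manual component
  selection, which cannot be automated faithfully; the stage is a
  pluggable no-op that accepts an external callable when real data are
  processed.
- **Interpolation**: spherical splines (via MNE) when montage positions
  are available; inverse-squared-distance weighting as a dependency-light
  fallback.  **Re-referencing**: per-sample channel-mean subtraction
  (idempotent, mean-annihilating).

## Connectivity

Cross-spectra are estimated per 2-s epoch with a Hann taper and averaged
across epochs (Welch-style; 0.5 Hz resolution at 250 Hz).  LagR is
computed per frequency bin as Im(S_ij)²/(S_ii S_jj − Re(S_ij)²) and
averaged over bins with centre frequency in [13, 30] Hz inclusive
(`per_bin`, the default); a `band_collapsed` switch first sums the
cross-spectra over the band.  Degenerate denominators (perfectly
instantaneously correlated pairs) yield weight 0 with a warning.  Output
matrices are symmetric, zero-diagonal, clipped to [0, 1], and assembled
per network by ROI label, so they are invariant to input row order.

## Graph metrics

- **Clustering**: Onnela geometric-mean form on weights normalized by the
  matrix maximum; nodes of degree < 2 contribute 0; n < 3 is an error.
- **Path length**: edge lengths 1/w, Dijkstra all-pairs, mean over ordered
  pairs of distinct nodes; disconnected graphs raise an error naming the
  components rather than silently averaging infinities.
- **Surrogates** (default 100, seeded): Maslov–Sneppen double-edge swaps
  on the binary topology, then the original edge-weight multiset randomly
  reassigned to the surviving edges — preserving node count, degree
  sequence and weight multiset.  On complete graphs (the typical case for
  LagR matrices, which are dense) no swap is admissible, so the scheme
  reduces to a weight permutation on the fixed topology; this fast path is
  vectorized.  A `weight_shuffle` mode fixes the topology explicitly.
  Disconnected surrogates (possible for sparse inputs) are redrawn, up to
  20 rounds.  Ensemble statistics are arithmetic means.
- **Normalization**: Cw = C_brain/C_random, Lw = L_brain/L_random,
  Sw = Cw/Lw, all ratios exact to machine precision by construction.
  Scale behaviour: multiplying all weights by k leaves C (normalized) and
  Sw invariant and scales L by 1/k.

## Group statistics

- Grouping: high fatigue ⇔ FSS-7 > 4 (strict).
- Extreme outliers: per network × hemisphere cell, values outside
  [Q1 − 3·IQR, Q3 + 3·IQR] are excluded with a logged reason.
- Assumptions: Shapiro–Wilk per network × hemisphere × group cell (n ≥ 3
  and non-constant, otherwise "not assessable"); Levene across fatigue and
  across sex per network × hemisphere.
- **Mixed ANOVA** (fatigue, sex between; network, hemisphere within):
  computed by the orthonormal within-contrast decomposition.  The four
  cell values of each subject are rotated by the orthonormal contrasts
  (average, network, hemisphere, network × hemisphere); each rotated
  variable is analysed as a univariate 2 × 2 between-subjects regression
  with sum-to-zero coding and Type III partial SS.  This is exactly the
  classical mixed-model decomposition; with two-level within factors
  sphericity holds trivially (Greenhouse–Geisser ε = 1), which the result
  records explicitly.  Effect sizes are generalized η²
  (SS_effect / (SS_effect + Σ error SS over all four strata)).  Subjects
  with any missing cell are dropped listwise; a between cell with < 2
  subjects is an error.
- Post-hocs: Welch-free Student t-tests low vs high per
  network × hemisphere; Bonferroni within two separate families — 4
  pooled contrasts (m = 4) and 8 sex-stratified contrasts (m = 8) — so
  family size is never silently inflated.
- Demographics: Spearman ρ for continuous covariates vs FSS-7; Wilcoxon
  rank-sum (exact p when feasible, tie-corrected normal approximation for
  the z behind the effect size r = |z|/√n) for two-level categoricals;
  Kruskal–Wallis with rank η² = (H − k + 1)/(n − k) for vascular
  territory, skipped when any territory has < 2 subjects.  Missing values
  are dropped pairwise per test.

## Numerical and design choices

- All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence`; cohorts are bit-reproducible, and the
  per-subject × per-network surrogate seeds are derived from the run seed
  via spawn keys, so results are independent of iteration order.
- Simulation-heavy calibration checks (type-I error over 200 cohorts,
  power over 100) use 60-s recordings per subject; 60 s gives 30 epochs,
  enough for stable LagR ranking while keeping an entire 300-cohort study
  in minutes.  The study-scale default (420 s → 210 epochs before
  rejection, ~160 after at realistic artifact rates) is used everywhere a
  single cohort is analysed.
- Epoch-rejection fences use the sample SD (ddof = 1); ties at the fence
  are kept (strict inequality).
- The eLORETA inverse solution is out of scope by design: the pipeline
  ingests ROI-level series, and real scalp data require external source
  reconstruction whose output is read through the ROI TSV format.

## Known limitations

- The synthetic forward model (random Gaussian mixing) has no spatial
  structure, so scalp-level results exercise the preprocessing machinery,
  not topographic realism.
- LagR matrices are dense, so the degree-preserving surrogate mode is in
  practice a weight permutation; the two modes differ only for sparse or
  thresholded inputs.
- The planted effect produces a fatigue main effect alongside the
  intended network × fatigue crossover (see above).
- The ± 2 SD rejection rule is not robust to masking by extreme
  artifacts.
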