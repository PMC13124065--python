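# Methods

This note documents the models and procedures `eegdyn` implements, the
parameter choices that matter, what the synthetic-data generator does and
does not emulate, and the numerical conventions that pin down edge cases.

## Preprocessing and segmentation

Recordings (channels × samples, µV) are reduced to the analysis montage
(default: the 19 standard 10–20 electrodes, configurable — sparse montages
limit spurious synchronization from volume conduction between neighboring
sites), decimated to 250 Hz with a zero-phase FIR low-pass at 0.8× the
target Nyquist (zero-phase filtering avoids phase distortion that would bias
the circular correlations), and cut into consecutive non-overlapping 10-s
segments (N_t = 2500 samples), each channel mean-centered within segment.
Inputs are assumed artifact-cleaned; an optional per-sample artifact mask
excludes any segment overlapping a masked sample. ICA correction and
re-referencing are out of scope.

## Univariate variability metrics

- **Power spectrum**: Welch averaged modified periodograms, 1-s Hann
  windows, 50% overlap → 1-Hz frequency resolution; density scaling, so the
  integral over frequency matches channel variance to within taper loss.
- **Coarse-graining**: non-overlapping block averages with factor *s*
  (scales 1…25 at 250 Hz = 4–100 ms), the classic multiscale-entropy
  construction. A boxcar block average is itself a FIR low-pass followed by
  decimation; a different FIR kernel can be slotted in where needed.
- **Sample entropy**: SampEn(m, r) = −ln(A/B), Chebyshev distance, `d ≤ r`
  counts a match, self-matches excluded, and both A and B counted over the
  same N−m templates, so a constant series gives exactly 0. Defaults
  m = 2, r = 0.5·SD (configurable; these are conventional EEG values, and
  tests verify SampEn's approximate m-invariance for iid input rather than a
  specific (m, r) pair). A = 0 or B = 0 yields an explicit NaN, which
  propagates as a flagged missing value — never a substituted number.
- **MSE vs MSEn**: MSE fixes r from the scale-1 SD; MSEn re-derives r from
  each coarse scale's SD (equivalently, z-scores every coarse series). MSEn
  thereby removes the mechanical entropy decrease caused by SD shrinking
  under coarse-graining and is scale-invariant by construction.

## Phase-synchronization pipeline

- **Wavelet phase**: complex Morlet kernels at 2–20 Hz in 2-Hz steps
  (10 bins), cycle number c = 7, σ_t = c/(2πf), σ_f = f/c (so σ_t·σ_f =
  1/2π identically). The kernel is truncated at ±5σ_t and amplitude-scaled
  so a unit sinusoid at the center frequency yields unit coefficient
  magnitude; convolution runs in the frequency domain with zero padding.
  Edge-contaminated coefficients are handled downstream by trimming (below).
- **CCorr**: computed within a sliding window of 251 samples (1.004 s at
  250 Hz), step 1 sample for EEG; 250 samples, step 25 (100 ms) for the
  oscillator pipeline. The deviation reference φ̄ is the *arithmetic* sample
  mean of the wrapped phase within the window, exactly as the defining
  formula states; a circular-mean variant is available
  (`phase_mean="circular"`). The convention is pinned by a regression test.
  Note the formula measures phase *covariance*: phases offset by a constant
  (unwrapped) correlate at +1, mirrored phases at −1. Windows with zero
  sine-deviation energy (constant phase) are flagged NaN.
  The sliding computation expands the CCorr sums into windowed sums of
  sin/cos products evaluated with cumulative sums; a direct per-window
  implementation serves as its oracle in tests.
- **|PS| norm**: quadratic mean of all connection values per window;
  windows with > 5% flagged connections are flagged. μ and σ over time use
  the sample SD (n−1).
- **PSD matrix**: 1 − Pearson correlation across connections for every
  window pair; scale- and shift-invariant in the network vector, so it
  tracks topology, not magnitude. Constant or flagged network vectors flag
  their row/column.
- **Jump lengths**: the τ-diagonal, τ from 1.004 to 2.000 s in steps of one
  window-center step (0.004 s EEG → 250 timescales; 0.1 s simulation → 11).
  Edge trimming keeps pairs whose window centers both lie ≥ 0.5 s from the
  segment boundaries (the geometric reading of the conventional
  [0.5τ + step, T − 0.5] s restriction; the literal range is available as
  `trim="literal"`). Statistics per (τ, f): sample mean, sample SD, and
  Pearson kurtosis m₄/m₂² with population central moments and no
  small-sample correction — sequences are long (~2000 points at the EEG
  step) and the normal-→3 reference motivates the non-excess convention.
  Degenerate sequences yield σ = 0 with kurtosis flagged NaN.

## Mean-centered Task-PLS

Per metric block, rows are (subject, condition) observations (subject =
mean over that subject's segments), columns are metric elements. The
group × condition cell-mean matrix (group-major row order) is centered by
the grand mean over cells and decomposed by SVD with rank capped at
cells − 1; covariance explained per LV is S²/ΣS². Sign convention: the
largest-magnitude element of each brain salience is positive.

- **Permutation test** (default 1000): rows permuted across group and
  condition without replacement; p = (#{S_perm ≥ S_obs} + 1)/(n_perm + 1)
  per LV (the add-one estimator never returns exactly 0). A within-subject
  condition-shuffle variant exists for designs where subject identity
  should be preserved.
- **Bootstrap test** (default 500): subjects resampled with replacement
  within each cell. Replicate singular vectors are aligned to the observed
  solution by an orthogonal Procrustes rotation (SVD axes are defined only
  up to reflection/rotation across replicates). Replicate brain saliences
  carry their singular values (saliences are proportional to
  element–contrast covariance; the unit-norm vectors alone understate
  replicate variance and make null bootstrap ratios anti-conservative —
  with the S-scaling, ~2–6% of pure-noise elements exceed the threshold,
  close to the nominal 1%). Bootstrap ratio = observed V·S over the SD of
  aligned replicate V·S; |ratio| > 2.5758 marks the two-tailed 99%
  standard-normal criterion. Brain-score cell means are mean-centered
  across cells, normalized by the singular value, and given 95% percentile
  CIs from the same replicates.
- **Missing elements** are excluded pairwise from cell means; elements
  missing in > 20% of rows are dropped with a logged report.

## Phase-oscillator model

dθ_i/dt = ω(1 − a·cosθ_i + (1 − cosθ_i)·(K/N)·Σ_j w_ij cosθ_j + Q·η_i),
ω = 2π·10 Hz, N = 10 nodes, Q = 0.01. Weights come from a bundled
*synthetic* symmetric connectome with log-normal (tractography-like) weight
distribution, normalized by the 95th percentile of its off-diagonal entries
(linear-interpolation percentile; the diagonal is structurally zero). A
user-supplied whitespace-delimited matrix can be substituted.

Integration is Euler(-Maruyama). Two conventions are provided:

- `sqrt_dt` (SDE reading): noise increment ω·Q·√dt·N(0,1) per node/step,
  dt = 1 ms, phases subsampled by 4 to a 250-Hz grid.
- `per_step` (replication reading): dt = 10 ms with a per-step unit-normal
  noise term ω·Q·dt·N(0,1), analysis on the resulting 100-Hz grid.

The two differ in *effective* noise by an order of magnitude (phase
diffusion ω·Q ≈ 0.63 rad/√s vs ≈ 0.06). The regime structure of the model —
weak coupling pinned near one attractor (suppressed switching), intermediate
(a ≈ 0.5, K ≈ 2) metastable wandering with maximal jump-length dispersion,
strong coupling saturated — expresses itself cleanly under the low-noise
replication reading and is validated there (paired sign tests on σ_JL across
seeds); under the stronger SDE-default noise, phase diffusion alone
decorrelates the networks at weak coupling and flattens the profile. Initial
phases are uniform on (−π, π], seeded; the first 1 s is discarded as
transient. The metastable regime is chaotic, so integration accuracy is
verified over a 1-s horizon (halving dt changes wrapped phases by < 5%
circular RMS there); trajectory-level agreement over the full 10 s is not a
meaningful target for any integrator.

**k-medoids**: partitioning-around-medoids on the precomputed PSD distance
matrix (assign to nearest medoid; re-pick each medoid as the member
minimizing the within-cluster distance sum; cost is nonincreasing).
Initialization is a seeded greedy farthest-point heuristic, or explicit
medoids; k defaults to 3 for state visualization. The embedding coordinate
of window t on axis k is 1 − D[t, m_k], so each medoid sits at 1 on its own
axis.

## Synthetic cohorts

`gen_switching_segment` builds multichannel signals as band-limited
oscillations (default 4 and 10 Hz) over a spectrally shaped 1/f background
(exponent 1, SNR 3 by default — oscillation-to-background power typical of
band-limited EEG activity). Coupling follows one of a small set of latent
topologies (connection-weight vectors; helper `partition_topology` builds
module structures): while a topology is active, every connected component of
its thresholded coupling graph shares one latent phase process
(Ornstein–Uhlenbeck jitter, SD 0.4 rad, correlation time 0.25 s — slow
enough to survive 1-s windows, fast enough to decorrelate uncoupled pairs)
plus a state-specific phase offset; channels also carry small independent
jitter (SD 0.15 rad). Topologies alternate at gamma-distributed dwell times
(mean/CV parameterization, no immediate repeats). Dwell means must exceed
~2 periods of the slowest band for phase estimates to resolve a state.

Because the analysis window is ~1 s, the dwell → μ_JL mapping is
non-monotone: dwells below the window length make every window a state
mixture and μ_JL falls toward its random ceiling (the saturated regime);
above the window length, faster switching yields larger jumps at 1–2-s lags.
The planted-effect experiments operate in the super-window regime.

`gen_study` assembles a full design (default 4 groups × 3 conditions,
24 subjects/group, 5–25 segments per cell — the cohort shape of the target
study class) with per-group planted effects: a slow-band (2–8 Hz) amplitude
gain and the dwell mean/CV of the switching process. All randomness derives
from one seed via `SeedSequence` spawning; regeneration is bit-identical.

What the generator does **not** emulate: volume conduction and electrode
geometry, evoked potentials, inter-subject spectral variability beyond the
planted effects, non-gamma dwell processes, amplitude–phase coupling.
Passing tests therefore demonstrate that the *pipeline recovers planted
effects of the assumed form*, not that real EEG carries them.

## Reference experiment (planted inverted-U)

The end-to-end check uses a scaled-down lifespan-like cohort: 4 groups
(YC, OC, YA, OA) × 1 condition, 12 subjects/group, 3 ten-second segments
each, 8 channels, bands {4, 10} Hz, sliding-window step 25 samples, τ grid
1–2 s. Planted values (fixed from the generator's μ_JL response curve
before running the experiment, then left alone): dwell means
1.6/2.1/3.8/2.7 s, dwell CVs 0.3/0.4/0.8/0.5, slow-band gains
1.5/1.3/1.0/0.9 — young adults switch slowest and most heterogeneously,
children fastest, old adults intermediate. A single condition is used
because no condition effect is planted; with several identical conditions
the LV1/LV2 rotation is only weakly identified and LV1 can absorb chance
condition asymmetries. Success criteria: group-mean μ_JL strictly inverts
the dwell ordering, and LV1's bootstrap CIs separate the YA cells from every
other group. PLS uses 200 permutations and 300 bootstrap samples here;
problem sizes throughout (subjects, segments, seed counts, sweep sizes) are
chosen so the whole validation runs in minutes on one CPU while keeping the
relevant test powers high.

## Known limitations

- CCorr with the arithmetic-mean reference is wrap-sensitive; the
  convention is pinned by tests, and the circular-mean variant is offered
  for sensitivity analyses.
- Bootstrap CIs for brain scores inherit SVD-rotation instability when an
  LV is weak; interpret CIs only for LVs that pass the permutation test.
- The oscillator model is a phase model: amplitude dynamics, delays and
  neural-mass biophysics are out of scope.
- Sample entropy is O(n²) in the series length; at the default segment
  length this is fast, but very long recordings should be segmented first.
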