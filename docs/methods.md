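# Methods

`seqrsa` re-implements, at desk scale and on synthetic data, a multivariate
pattern pipeline for studying how learned sequences are represented across
memory domains. A dual serial reaction time task (SRTT) crosses a motor
sequence (fixed order of 8 key presses, random objects), an object sequence
(fixed order of 8 pictured objects, random key presses), and a fully random
condition. Because the object-to-key mapping changes after every 8-element
stream, motor and object learning are orthogonalized while every stream
remains a permutation of both item sets. The question the pipeline answers
is representational: do a region's multivoxel patterns code items, temporal
positions, or items bound to their learned positions — within each domain
and across domains?

## Protocol generator

The generator is a pure function of `(seed, n_subjects)`.

* Canonical sequences: motor `4,7,3,8,6,2,5,1` (1 and 8 the little
  fingers), objects `pineapple, plane, giraffe, saw, elephant, banana, axe,
  car` (two from each of four semantic categories). Each subject starts the
  cyclic sequences at rotation `(subject − 1) mod 8`, so no item is tied to
  the same ordinal slot across subjects.
* A scanning run holds 15 streams (5 per condition), pseudo-randomized so
  no condition occurs more than twice in a row (bounded rejection
  sampling), with three 10 s rest periods placed uniformly at non-adjacent
  stream boundaries. Inter-stimulus intervals are uniform on [1.5, 2.5] s
  (only the range is prescribed; the uniform law is our choice). Eight runs
  give 40 stream repetitions per condition.
* Random streams are uniform permutations of the 8 items — not i.i.d.
  draws — because only permutation streams give every key, object and
  position exactly 5 events per condition per run, the bookkeeping the GLMs
  rely on. By default a random stream is resampled if it reproduces the
  learned sequence of its domain (`exclude_learned`, configurable); we
  verified empirically that this exclusion does not measurably bias any
  similarity matrix.
* Behavioral sessions (two per subject: 4 random + 20 training + 4 test
  blocks, response-to-stimulus interval 0.75 s) are generated alongside for
  the behavior module.

Events round-trip through BIDS-style TSVs (`onset`, `duration` = 0 for the
delta-function cues, `trial_type`, plus task columns).

## Synthetic multivoxel data

The simulator plants coding as independent standard-normal latent patterns
over `V` voxels: one per key, object and position, one per learned ordinal
slot (item-position patterns, present only in sequence-condition events;
shared between domains when `domain_general` is set), and a single boundary
pattern added at stream positions 1 and 8. An event's signal is the
amplitude-weighted sum of its patterns; a regressor's simulated t-map is
the mean of its five events' signals plus i.i.d. Gaussian regressor noise
(`noise_sigma`).

Two modeling choices deserve emphasis:

* **Pattern banks are per subject.** The analyses this mirrors are done in
  native space; there is no voxel correspondence across individuals, so no
  group-level pattern component is shared. (`subject_sigma` additionally
  jitters a bank when one bank is deliberately reused, e.g. to model
  pattern instability.) During development we found that sharing one bank
  across a simulated cohort makes the group test anti-conservative for
  mixture-structured matrices — all subjects inherit the same bank-specific
  bias — which is exactly why the validation studies draw banks per
  subject.
* **Default amplitudes** (`a_key` 0.7, `a_pos` 0.5, `a_itempos` 0.5,
  `a_boundary` 0.4, `a_obj` 0.4, noise 1.0) describe a moderate-SNR regime:
  item effects comparable to post-averaging noise, recovery possible but
  not trivial. No empirical effect-size scale exists for these quantities,
  so parameter *recovery*, not value matching, is what the tests assert.

`simulate_bold` is the optional slow front end: the same event signals
placed as impulses at cue onsets, convolved with the canonical double-gamma
HRF on the identical oversampled grid the GLM stage uses for its design
columns, plus optional cosine drift and white scan noise. Noiseless
simulations therefore lie exactly in the GLM's model class *when the
planted amplitudes are constant within each regressor's events* (position,
item-position and boundary coding under the position scheme); key/object
content of random streams varies event-to-event within a group and is
averaged by the GLM, as in the real experiment.

Behavioral responses follow an exponential learning curve from
`baseline_rt_s` (0.9 s) toward an asymptote (0.45 s) with a constant
sequence advantage (80 ms default) and i.i.d. Bernoulli errors.

## First-level GLMs

Three labeling schemes regroup the same 120 events per run: by temporal
position, by key, and by object. Sequence-condition events keep one fixed
partition (by stream position, i.e. learned slot) under all three schemes,
because item and position are locked together there; only random events
regroup. Each run yields 8 labels × 3 conditions = 24 interest regressors
(5 events each), 192 across runs. Interest columns are 0 s delta functions
convolved with the double-gamma HRF (peak 6 s, undershoot 16 s, ratio 1:6,
sampled on a tr/16 grid); a DCT basis implements the 128 s high-pass;
nuisance columns are caller-supplied. Estimation is OLS with per-voxel
t = β/(σ̂·√[(XᵀX)⁻¹]ⱼⱼ); an AR(1) (Cochrane–Orcutt) flag is available but
off by default — the contract downstream is only "a t-map per regressor",
and OLS keeps the desk-scale path exactly checkable against closed forms.
Normalization subtracts, per voxel and run, the mean t over that scheme's
24 regressors (the literal reading of the run-wise normalization; it is
idempotent and makes each run's regressor set mean-zero).

## Cross-validated similarity matrices

For one subject × ROI, all C(8,4) = 70 divisions of the runs into two
4-run halves are enumerated, each crossed with both orientations (which
half supplies matrix rows): 140 iterations. Per iteration, t-maps are
averaged within each half and the 8 row-side regressors are
Pearson-correlated with the 8 column-side regressors across voxels; r is
clipped to ±(1 − 1e−7) before the Fisher transform (noiseless fixtures
would otherwise produce infinities) and the z matrices are averaged.
Exhaustive enumeration replaces random sampling because 70 subsets is the
complete population being averaged. For matrices whose rows and columns
come from the same regressor family, the second orientation of a subset is
the exact transpose of the first; the implementation exploits this so the
averaged matrix is symmetric to the last bit, and an independent
brute-force re-enumeration agrees to 1e−12.

Seven kinds are built: within-condition matrices for the motor sequence
(key labels), object sequence (object labels) and the random condition
(key, position, object labels), plus two slot-aligned cross-scheme
matrices: `SQ_ACROSS` (object-sequence patterns × motor-sequence patterns,
rows = objects by learned slot, columns = keys by learned slot) and
`RD_ITEM` (the same alignment on random-condition regressors, controlling
for accidental item similarity across domains). The boundary control trims
rows/columns 1 and 8 from an 8×8 position matrix (6×6). Lag profiles pool
|row − col| = k cells over both triangles, non-circular.

## Group statistics

The subject-level statistic is delta similarity: mean diagonal minus mean
strict off-diagonal Fisher-z. Coding is tested with one-tailed paired t
(diagonal > off-diagonal; Cohen's d = mean/sd of the paired differences),
Bonferroni-corrected over the 5 ROIs by default with Benjamini–Hochberg
selectable (`fdr_bh` corrects within the supplied family). All-zero
difference vectors return t = 0, p = 0.5; constant non-zero vectors return
a flagged sign-test fallback instead of a silent infinite t.

Attribution regressions are forward stepwise: sequence-matrix deltas on the
random-matrix deltas (key/object/item and position), entering the largest
ΔR² first, each step tested with F(1, n−k−1); ties broken by predictor
name with a warning; the full-model F (df1 = k) is also reported so both
df conventions are available. Stepwise gains agree with direct hierarchical
R² differences to 1e−10.

The surrogate null permutes labels on one correlation side only (columns):
permuting both sides identically maps diagonal to diagonal and provably
preserves delta similarity, which would contradict a null that shows no
diagonal/off-diagonal difference. Averaged over *all* column permutations
each surrogate row is constant, so the exhaustive surrogate has delta
exactly zero (tested at sizes 3–4); the default is 1,000 random
permutations, and the corrected matrix is observed minus surrogate mean.

Split-half reliability partitions the 8 runs into two disjoint 4-run
halves (all 35 unordered partitions by default), computes each kind's
matrix within each half from the 2+2 sub-splits (12 iterations), and
averages the Pearson correlation of the vectorized matrices over
partitions. Lag effects use a one-way repeated-measures ANOVA (partial eta
squared from the F identity F·df1/(F·df1 + df2); no sphericity correction
by default) with Bonferroni-corrected pairwise paired t tests; behavior
uses the analogous two-way condition × block decomposition, where speed is
mean RT on correct trials only and accuracy counts all trials of a block.
Repeated-measures ANOVAs are delegated to `pingouin.rm_anova`; t tests and
F distributions to `scipy`; BH to `statsmodels`.

## Validation studies (sizes used)

The calibration and recovery claims are recomputed by simulation:

* **Type-I calibration**: 500 cohorts × 30 subjects × 16 voxels under the
  all-zero null; the one-tailed coding test's rejection rate must lie in
  the binomial 95% interval around α = 0.05.
* **Selective recovery**: 100 cohorts × 30 subjects × 24 voxels per
  planted amplitude (item-position domain-general, key, position, boundary,
  each 1.5 in pattern-SD units at noise 1.0): power ≥ 90% in the matching
  matrix kinds, false-positive rate at nominal α elsewhere; the
  boundary-planted run loses position coding after 6×6 trimming.

Every cohort generates fresh protocols and per-subject banks. Reusing one
protocol set across cohorts is avoided deliberately: a fixed protocol's
finite random streams carry accidental object–key co-occurrence that
biases every cohort identically and inflates the selectivity
false-positive rate (we measured ≈ +0.008 delta in the item matrix from a
60-protocol pool against ≈ 0 with fresh protocols). Voxel counts are far
below anatomical ROI sizes; they set the Monte-Carlo noise level of a
single similarity matrix, and the claims under test (calibration,
selectivity, trimming dissociation) are scale-free in V.

## What the synthetic data do and do not show

The generator reproduces the protocol's combinatorial structure, planted
linear pattern coding, regressor-level noise, and (optionally) HRF
dynamics with drift. It does not model physiological noise, motion,
spatial autocorrelation within an ROI, inter-regional correlation,
attention or fatigue dynamics, or any empirical effect-size scale. Passing
tests therefore demonstrate that the *pipeline* is correct and calibrated
— that it finds exactly the coding that is present and nothing else —
not that the biological findings would replicate.

## Known limitations

* The rapid event design (cues every ~2 s, 0 s durations) makes the 24 HRF
  regressors strongly collinear; single-subject t-maps from the BOLD path
  are noise-dominated at realistic scan noise, as in real data — group
  aggregation is where the effects live.
* OLS (not ReML-AR(1)) is the default estimator; the AR(1) flag is a
  first-order approximation.
* The `2 × 70` iteration scheme is read as "both orientations of each
  half-split"; for within-condition matrices the doubling is provably
  redundant, and for the across-domain matrix the convention (rows =
  object-sequence patterns) is fixed and documented.
* Methods prescribe Bonferroni over 5 ROIs while parts of the source
  results use FDR; both are implemented and the choice is surfaced in the
  config rather than resolved.
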