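# seqrsa

Cross-validated representational similarity analysis (RSA) of sequence
learning across memory domains — as a fully synthetic, testable pipeline.

## The problem

In a dual serial reaction time task, people learn two 8-element sequences
at once: a *motor* sequence (a fixed order of key presses under a random
stream of pictured objects) and an *object* sequence (a fixed order of
objects under random key presses), alongside a fully random control.
Because the object-to-key mapping changes after every 8-element stream, the
two learning domains are orthogonal. The representational question is
whether a brain region's multivoxel patterns code **items** (fingers,
objects), **temporal positions**, or **item–position conjunctions** — and
whether the conjunctive code is shared across memory domains.

The pipeline answers it with split-half cross-validated pattern
correlations. Per subject and region of interest (ROI), the 8 scanning
runs are divided into two 4-run halves; per-regressor GLM t-maps are
averaged within each half and correlated across voxels for all 8 × 8 label
pairs; Pearson r is Fisher-transformed (z = atanh r) and averaged over all
70 half-splits × 2 orientations = 140 iterations. Seven matrices are built
(motor sequence, object sequence, across-domain by learned slot, and
random-condition key / position / object / item controls). The core
statistic is **delta similarity**

    Δz = mean(diagonal) − mean(off-diagonal)

tested across subjects with a one-tailed paired t (Bonferroni over 5
ROIs), attributed to overlapping codes by forward stepwise regression with
ΔR² F-tests, and checked against label-permutation surrogate nulls,
boundary-trimmed (6×6) controls, lag profiles and split-half reliability.

No scanner data is needed anywhere: the package generates the experimental
protocol itself and simulates multivoxel t-maps (or voxel time series for
the GLM stage) with planted, parameterized coding — so every downstream
claim is testable against ground truth.

## Worked example

Plant a strong finger/key pattern — and nothing else — in one simulated
subject, then ask every matrix what it sees (`examples/simulate_and_rsa.py`):

```
kind          diag  offdiag   delta
SQ_MOT       1.484   -0.130   1.614
SQ_OBJ      -0.016   -0.003  -0.013
SQ_ACROSS    0.035   -0.003   0.038
RD_KEY       1.462   -0.128   1.589
RD_POS      -0.042    0.001  -0.043
RD_OBJ      -0.009   -0.004  -0.006
RD_ITEM      0.090   -0.009   0.099
```

Key coding appears exactly where repetitions share a finger: in the random
condition's key matrix (`RD_KEY`) and in the motor sequence matrix
(`SQ_MOT`, where each learned slot always repeats its key). The object,
position and across-domain matrices stay near zero — this selectivity,
together with type-I calibration under the all-zero null, is what the
acceptance suite verifies at cohort scale.

Other short scripts in `examples/` cover protocol generation, the
BOLD → GLM → RSA path, the end-to-end pipeline with its report, and the
behavioral metrics. A thin CLI (`seqrsa protocol|simulate|rsa|stats|report|all`)
wraps the same stages for seeded shell runs.

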