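"""Group-level statistics for the similarity matrices.

The subject-level summary statistic throughout is *delta similarity*: mean
Fisher-z similarity on the matrix diagonal minus the mean over the strict
off-diagonal.  Coding is inferred when delta exceeds zero across subjects
(one-tailed paired or one-sample t, Bonferroni- or FDR-corrected over the
five ROIs); overlapping representations are disentangled with forward
stepwise regressions on the random-condition deltas; and permutation
surrogate matrices provide an empirical null.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from math import factorial

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .protocol import OBJECT_CATEGORIES
from .rsa import (SimilarityMatrix, compute_matrix, enumerate_splits,
                  lag_profile)

N_ROIS_DEFAULT = 5


# ---------------------------------------------------------------------------
# result records
# ---------------------------------------------------------------------------

@dataclass
class DeltaSimilarity:
    """Diagonal minus off-diagonal mean similarity for one matrix."""

    diag_mean: float
    offdiag_mean: float
    delta: float
    subject: int | None = None
    roi: str | None = None
    kind: str | None = None


@dataclass
class TestResult:
    statistic: float
    df: float
    p: float
    p_corrected: float
    effect_size: float
    effect_size_name: str = "cohen_d"
    method: str = "bonferroni"
    tails: str = "one-tailed"
    note: str | None = None


@dataclass
class StepRecord:
    step: int
    predictor: str
    coefficient: float
    coefficient_t: float
    r2: float
    delta_r2: float
    f: float
    df1: int
    df2: int
    p: float


@dataclass
class RegressionResult:
    steps: list[StepRecord]
    r2_total: float
    full_model_f: float
    full_model_df1: int
    full_model_df2: int
    full_model_p: float
    note: str | None = None


# ---------------------------------------------------------------------------
# delta similarity and coding tests
# ---------------------------------------------------------------------------

def delta_similarity(matrix, **ids) -> DeltaSimilarity:
    """Mean diagonal minus mean strict-off-diagonal similarity."""
    values = matrix.values if isinstance(matrix, SimilarityMatrix) else np.asarray(matrix, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("delta_similarity requires a square matrix")
    if values.shape[0] < 2:
        raise ValueError("matrix must be at least 2x2")
    off_mask = ~np.eye(values.shape[0], dtype=bool)
    diag = float(np.diagonal(values).mean())
    off = float(values[off_mask].mean())
    kind = ids.pop("kind", getattr(matrix, "kind", None))
    return DeltaSimilarity(diag_mean=diag, offdiag_mean=off, delta=diag - off,
                           kind=kind, **ids)


def _corrected(p: float, n_comparisons: int, method: str) -> float:
    if method == "bonferroni":
        return min(1.0, p * n_comparisons)
    raise ValueError("per-test correction supports 'bonferroni' only; use "
                     "correct_pvalues for FDR across a family")


def diag_vs_offdiag_test(
    diag: np.ndarray,
    offdiag: np.ndarray,
    n_comparisons: int = N_ROIS_DEFAULT,
    method: str = "bonferroni",
) -> TestResult:
    """One-tailed paired t across subjects: diagonal > off-diagonal.

    Cohen's d is the paired-difference effect size mean(diff)/sd(diff).  If
    the differences have zero variance the t statistic is undefined and a
    sign-test fallback p is reported with a flag.
    """
    diag = np.asarray(diag, dtype=float)
    offdiag = np.asarray(offdiag, dtype=float)
    if diag.shape != offdiag.shape or diag.ndim != 1:
        raise ValueError("diag and offdiag must be equal-length vectors")
    n = diag.size
    if n < 3:
        raise ValueError("need at least 3 subjects")
    diff = diag - offdiag
    sd = diff.std(ddof=1)
    if sd == 0 and np.all(diff == 0):
        # degenerate but defined: no difference anywhere, no evidence
        return TestResult(statistic=0.0, df=n - 1, p=0.5,
                          p_corrected=_corrected(0.5, n_comparisons, method),
                          effect_size=0.0, method=method)
    if sd == 0:
        n_pos = int((diff > 0).sum())
        p = sps.binomtest(n_pos, n, 0.5, alternative="greater").pvalue
        return TestResult(statistic=np.nan, df=n - 1, p=p,
                          p_corrected=_corrected(p, n_comparisons, method),
                          effect_size=np.nan, method=method,
                          note="zero-variance differences; sign-test fallback")
    res = sps.ttest_rel(diag, offdiag, alternative="greater")
    d = diff.mean() / sd
    p = float(res.pvalue)
    return TestResult(statistic=float(res.statistic), df=n - 1, p=p,
                      p_corrected=_corrected(p, n_comparisons, method),
                      effect_size=float(d), method=method)


def one_sample_delta_test(
    deltas: np.ndarray,
    n_comparisons: int = N_ROIS_DEFAULT,
    method: str = "bonferroni",
) -> TestResult:
    """One-tailed one-sample t of per-subject deltas against zero."""
    deltas = np.asarray(deltas, dtype=float)
    n = deltas.size
    if n < 3:
        raise ValueError("need at least 3 subjects")
    sd = deltas.std(ddof=1)
    if sd == 0 and np.all(deltas == 0):
        return TestResult(statistic=0.0, df=n - 1, p=0.5,
                          p_corrected=_corrected(0.5, n_comparisons, method),
                          effect_size=0.0, method=method)
    if sd == 0:
        n_pos = int((deltas > 0).sum())
        p = sps.binomtest(n_pos, n, 0.5, alternative="greater").pvalue
        return TestResult(statistic=np.nan, df=n - 1, p=p,
                          p_corrected=_corrected(p, n_comparisons, method),
                          effect_size=np.nan, method=method,
                          note="zero-variance deltas; sign-test fallback")
    res = sps.ttest_1samp(deltas, 0.0, alternative="greater")
    p = float(res.pvalue)
    return TestResult(statistic=float(res.statistic), df=n - 1, p=p,
                      p_corrected=_corrected(p, n_comparisons, method),
                      effect_size=float(deltas.mean() / sd), method=method)


def correct_pvalues(pvalues, method: str = "bonferroni",
                    m: int | None = None) -> np.ndarray:
    """Multiple-comparison correction across a family of p-values.

    Bonferroni uses ``m`` comparisons (default: family size); FDR uses the
    Benjamini-Hochberg step-up over the supplied family.
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bonferroni":
        m = m if m is not None else p.size
        return np.minimum(1.0, p * m)
    if method == "fdr_bh":
        if m is not None and m != p.size:
            raise ValueError("fdr_bh corrects within the supplied family; "
                             "m must equal len(pvalues)")
        return multipletests(p, method="fdr_bh")[1]
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# forward stepwise attribution regression
# ---------------------------------------------------------------------------

def _ols_r2(y: np.ndarray, X: np.ndarray):
    """R^2, coefficients and coefficient t-values of y ~ [1, X]."""
    n = y.size
    Z = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    resid = y - Z @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot
    df = n - Z.shape[1]
    sigma2 = ss_res / df if df > 0 else np.nan
    cov = sigma2 * np.linalg.pinv(Z.T @ Z)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    return r2, beta, t


def stepwise_attribution(
    dv,
    predictors: pd.DataFrame,
    alpha_enter: float | None = None,
) -> RegressionResult:
    """Forward stepwise regression of sequence deltas on random deltas.

    At each step the candidate with the largest increase in explained
    variance enters; the change is tested with F(1, n-k-1) where k counts
    entered predictors.  With ``alpha_enter`` set, selection stops when no
    candidate's delta-R^2 is significant at that level; by default all
    predictors enter (the full models of the attribution tables).  A
    full-model F over all entered predictors is also reported.
    """
    y = np.asarray(dv, dtype=float)
    X = predictors.copy()
    n = y.size
    if n <= X.shape[1] + 2:
        raise ValueError("need n subjects > n predictors + 2")
    entered: list[str] = []
    steps: list[StepRecord] = []
    r2_prev = 0.0
    note = None
    remaining = sorted(X.columns)
    while remaining:
        gains = {}
        for name in remaining:
            cols = entered + [name]
            r2, _, _ = _ols_r2(y, X[cols].to_numpy())
            gains[name] = r2 - r2_prev
        best_gain = max(gains.values())
        ties = sorted(name for name, g in gains.items()
                      if np.isclose(g, best_gain, rtol=0, atol=1e-12))
        if len(ties) > 1 and note is None:
            note = f"tie on delta-R2 broken by predictor name: {ties}"
            warnings.warn(note, RuntimeWarning, stacklevel=2)
        best = ties[0]
        cols = entered + [best]
        r2, beta, t = _ols_r2(y, X[cols].to_numpy())
        k = len(cols)
        df2 = n - k - 1
        delta_r2 = r2 - r2_prev
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (delta_r2 / 1) / ((1.0 - r2) / df2) if r2 < 1 else np.inf
        p = float(sps.f.sf(f, 1, df2)) if np.isfinite(f) else 0.0
        if alpha_enter is not None and p > alpha_enter:
            break
        steps.append(StepRecord(
            step=k, predictor=best, coefficient=float(beta[-1]),
            coefficient_t=float(t[-1]), r2=float(r2),
            delta_r2=float(delta_r2), f=float(f), df1=1, df2=df2, p=p,
        ))
        entered.append(best)
        remaining.remove(best)
        r2_prev = r2
    if not steps:
        raise ValueError("no predictor entered the model")
    k = len(entered)
    r2_full = steps[-1].r2
    df2 = n - k - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        f_full = (r2_full / k) / ((1.0 - r2_full) / df2) if r2_full < 1 else np.inf
    p_full = float(sps.f.sf(f_full, k, df2)) if np.isfinite(f_full) else 0.0
    return RegressionResult(steps=steps, r2_total=float(r2_full),
                            full_model_f=float(f_full), full_model_df1=k,
                            full_model_df2=df2, full_model_p=p_full, note=note)


# ---------------------------------------------------------------------------
# surrogate permutation null
# ---------------------------------------------------------------------------

def surrogate_null(
    matrix,
    n_perm: int = 1000,
    seed=None,
    exhaustive: bool = False,
    perms=None,
):
    """Label-permutation surrogate of a similarity matrix.

    Column labels are shuffled within the matrix (one correlation side
    only); the surrogate is the mean over permutations and the corrected
    matrix is observed minus surrogate.  Averaging over *all* column
    permutations makes every row constant, so the exhaustive surrogate has
    delta similarity exactly zero.

    Returns ``(surrogate_mean, corrected)``, matching the input type.
    """
    is_sm = isinstance(matrix, SimilarityMatrix)
    values = matrix.values if is_sm else np.asarray(matrix, dtype=float)
    n = values.shape[1]
    if perms is not None:
        perms = [list(p) for p in perms]
    elif exhaustive:
        if factorial(n) > 50_000:
            raise ValueError("exhaustive surrogate is infeasible beyond 7x7")
        perms = list(itertools.permutations(range(n)))
    else:
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        perms = [rng.permutation(n) for _ in range(n_perm)]
    acc = np.zeros_like(values)
    for perm in perms:
        acc += values[:, list(perm)]
    surrogate = acc / len(perms)
    corrected = values - surrogate
    if not is_sm:
        return surrogate, corrected
    mk = lambda v: SimilarityMatrix(kind=matrix.kind, values=v,
                                    row_labels=list(matrix.row_labels),
                                    col_labels=list(matrix.col_labels),
                                    n_iterations=matrix.n_iterations)
    return mk(surrogate), mk(corrected)


# ---------------------------------------------------------------------------
# split-half reliability
# ---------------------------------------------------------------------------

def split_half_reliability(
    tmaps,
    kind: str,
    sequence_pair=None,
    n_partitions: int | None = None,
    seed=None,
) -> float:
    """Reliability of a matrix kind: correlation between half-data matrices.

    The 8 runs are partitioned into two disjoint 4-run halves; the matrix
    is computed independently within each half (2+2 splits, 12 iterations),
    the two matrices are vectorized and Pearson-correlated, and r is
    averaged over partitions (all 35 by default, or a random subset).
    """
    runs = tmaps.runs()
    if len(runs) < 4:
        raise ValueError("split-half reliability needs at least 4 runs")
    half = len(runs) // 2
    partitions = [
        (subset, tuple(r for r in runs if r not in subset))
        for subset in itertools.combinations(runs, half)
        if runs[0] in subset  # unordered partitions: fix run 1 in half A
    ]
    if n_partitions is not None and n_partitions < len(partitions):
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(partitions), size=n_partitions, replace=False)
        partitions = [partitions[i] for i in idx]
    rs = []
    for half_a, half_b in partitions:
        vecs = []
        for half_runs in (half_a, half_b):
            splits = enumerate_splits(len(half_runs), len(half_runs) // 2,
                                      runs=half_runs)
            m = compute_matrix(tmaps, kind, sequence_pair=sequence_pair,
                               splits=splits)
            vecs.append(m.values.ravel())
        rs.append(sps.pearsonr(vecs[0], vecs[1]).statistic)
    return float(np.mean(rs))


# ---------------------------------------------------------------------------
# lag analyses
# ---------------------------------------------------------------------------

def _partial_eta_sq(f: float, df1: float, df2: float) -> float:
    """Partial eta squared via the F identity: F*df1 / (F*df1 + df2)."""
    return float(f * df1 / (f * df1 + df2))


def lag_anova(
    profiles: pd.DataFrame,
    n_comparisons: int = N_ROIS_DEFAULT,
) -> tuple[TestResult, pd.DataFrame]:
    """Repeated-measures ANOVA of similarity across lags.

    ``profiles``: rows = subjects, columns = lags.  Returns the main-effect
    result (F, dfs, partial eta squared) and a Bonferroni-corrected table
    of pairwise paired t-tests between lags.
    """
    import pingouin as pg

    if profiles.isna().any().any():
        raise ValueError("missing lag value for at least one subject")
    n_sub, n_lags = profiles.shape
    if n_sub < 3 or n_lags < 2:
        raise ValueError("need >= 3 subjects and >= 2 lags")
    long = profiles.reset_index(names="subject").melt(
        id_vars="subject", var_name="lag", value_name="z")
    aov = pg.rm_anova(data=long, dv="z", within="lag", subject="subject",
                      detailed=True)
    eff = aov[aov["Source"] == "lag"].iloc[0]
    df1 = float(eff["DF"])
    df2 = float(aov.loc[aov["Source"] == "Error", "DF"].iloc[0])
    if eff["SS"] == 0:
        # no between-lag variance at all: F is 0 by definition
        f_val, p, np2 = 0.0, 1.0, 0.0
    else:
        f_val = float(eff["F"])
        np2 = _partial_eta_sq(f_val, df1, df2)
        p = float(eff["p_unc"])
    result = TestResult(
        statistic=f_val, df=df1, p=p,
        p_corrected=min(1.0, p * n_comparisons), effect_size=np2,
        effect_size_name="partial_eta_sq", tails="two-tailed",
        note=f"df = ({int(df1)}, {int(df2)})",
    )
    pairs = []
    lags = list(profiles.columns)
    n_pairs = len(lags) * (len(lags) - 1) // 2
    for a, b in itertools.combinations(lags, 2):
        res = sps.ttest_rel(profiles[a], profiles[b])
        pairs.append({"lag_a": a, "lag_b": b, "t": float(res.statistic),
                      "df": n_sub - 1, "p": float(res.pvalue),
                      "p_corrected": min(1.0, float(res.pvalue) * n_pairs)})
    return result, pd.DataFrame(pairs)


def offdiag_pattern_correlation(
    matrices_a: list,
    matrices_b: list,
    n_comparisons: int = N_ROIS_DEFAULT,
) -> tuple[np.ndarray, TestResult]:
    """Correlate off-diagonal lag profiles (lags 1-7) between two matrix kinds.

    Per subject, the lag 1..n-1 mean similarities of each matrix are
    Pearson-correlated; the per-subject r values are tested against zero
    with a two-tailed one-sample t, corrected across ROIs.
    """
    if len(matrices_a) != len(matrices_b):
        raise ValueError("need one matrix pair per subject")
    rs = []
    for ma, mb in zip(matrices_a, matrices_b):
        va = ma.values if isinstance(ma, SimilarityMatrix) else np.asarray(ma)
        vb = mb.values if isinstance(mb, SimilarityMatrix) else np.asarray(mb)
        if va.shape != vb.shape:
            raise ValueError("matrix shapes differ within a subject")
        prof_a = lag_profile(va)
        prof_b = lag_profile(vb)
        lags = sorted(prof_a)[1:]  # off-diagonal lags only
        rs.append(sps.pearsonr([prof_a[k] for k in lags],
                               [prof_b[k] for k in lags]).statistic)
    rs = np.asarray(rs)
    res = sps.ttest_1samp(rs, 0.0)
    p = float(res.pvalue)
    n = rs.size
    test = TestResult(statistic=float(res.statistic), df=n - 1, p=p,
                      p_corrected=min(1.0, p * n_comparisons),
                      effect_size=float(rs.mean() / rs.std(ddof=1)),
                      tails="two-tailed")
    return rs, test


# ---------------------------------------------------------------------------
# object-category contrast
# ---------------------------------------------------------------------------

@dataclass
class CategoryContrast:
    same_mean: float
    different_mean: float
    contrast: float
    per_category: dict[str, float] = field(default_factory=dict)


def category_contrast(
    matrix: SimilarityMatrix,
    categories: dict[str, str] = OBJECT_CATEGORIES,
) -> CategoryContrast:
    """Same-category vs different-category similarity in an object matrix.

    Off-diagonal cells are partitioned by whether the row and column
    objects share a semantic category (4 categories of 2 objects each; the
    same-category set holds 4 unordered pairs, 8 ordered cells).
    """
    labels = [str(l) for l in matrix.row_labels]
    if set(labels) != set(categories):
        raise ValueError("matrix labels do not match the category map")
    cats = sorted(set(categories.values()))
    sizes = {c: sum(1 for v in categories.values() if v == c) for c in cats}
    if len(cats) != 4 or any(s != 2 for s in sizes.values()):
        raise ValueError("category map must partition 8 objects into 4 pairs")
    values = matrix.values
    n = len(labels)
    same_cells, diff_cells = [], []
    per_cat: dict[str, list[float]] = {c: [] for c in cats}
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if categories[labels[i]] == categories[labels[j]]:
                same_cells.append(values[i, j])
                per_cat[categories[labels[i]]].append(values[i, j])
            else:
                diff_cells.append(values[i, j])
    same = float(np.mean(same_cells))
    diff = float(np.mean(diff_cells))
    return CategoryContrast(
        same_mean=same, different_mean=diff, contrast=same - diff,
        per_category={c: float(np.mean(v)) for c, v in per_cat.items()},
    )


def category_contrast_test(
    matrices: list[SimilarityMatrix],
    categories: dict[str, str] = OBJECT_CATEGORIES,
    n_comparisons: int = 1,
) -> tuple[pd.DataFrame, TestResult]:
    """Paired t across subjects: same-category vs different-category mean."""
    rows = [category_contrast(m, categories) for m in matrices]
    df = pd.DataFrame({"same": [r.same_mean for r in rows],
                       "different": [r.different_mean for r in rows]})
    res = sps.ttest_rel(df["same"], df["different"])
    diff = df["same"] - df["different"]
    p = float(res.pvalue)
    test = TestResult(statistic=float(res.statistic), df=len(df) - 1, p=p,
                      p_corrected=min(1.0, p * n_comparisons),
                      effect_size=float(diff.mean() / diff.std(ddof=1)),
                      tails="two-tailed")
    return df, test


# ---------------------------------------------------------------------------
# behavioral metrics
# ---------------------------------------------------------------------------

def behavior_metrics(responses: pd.DataFrame, block_col: str = "block"):
    """Per-block speed and accuracy plus a condition x block RM-ANOVA.

    Speed is mean RT on correct trials only (missing, with a warning, if a
    block has none); accuracy is the percentage of correct responses over
    *all* trials of the block.  The ANOVA decomposes block-mean RT with
    condition and block as within-subject factors and reports partial eta
    squared per effect; it requires the two factors to be fully crossed
    (for scanner sessions pass ``block_col='run'``, since every run holds
    all conditions while a within-run block holds only one).
    """
    import pingouin as pg

    required = {"subject", "condition", block_col, "rt_s", "correct"}
    missing = required - set(responses.columns)
    if missing:
        raise ValueError(f"responses table missing column(s) {sorted(missing)}")
    responses = responses.reset_index(drop=True)
    responses = responses.assign(
        _rt_correct=responses["rt_s"].where(responses["correct"].astype(bool)))
    crossed = responses.groupby("condition")[block_col].nunique()
    if crossed.nunique() != 1:
        raise ValueError("condition and block factors are not crossed; "
                         "choose block_col accordingly")
    grp = responses.groupby(["subject", "condition", block_col])
    metrics = grp.agg(
        mean_rt_s=("_rt_correct", "mean"),
        pct_correct=("correct", lambda s: 100.0 * s.mean()),
        n_trials=("rt_s", "size"),
    ).reset_index()
    if metrics["mean_rt_s"].isna().any():
        warnings.warn("block(s) with zero correct trials: mean RT recorded "
                      "as missing", RuntimeWarning, stacklevel=2)
    anovas = {}
    for dv in ("mean_rt_s", "pct_correct"):
        data = metrics.dropna(subset=[dv])
        aov = pg.rm_anova(data=data, dv=dv, within=["condition", block_col],
                          subject="subject", detailed=True)
        aov = aov.assign(np2=[
            _partial_eta_sq(row["F"], row["ddof1"], row["ddof2"])
            for _, row in aov.iterrows()
        ])
        anovas[dv] = aov
    return metrics, anovas
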