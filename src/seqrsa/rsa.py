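"""Split-half cross-validated similarity matrices.

For one subject x ROI, the eight runs are divided into two independent
4-run halves; t-values are averaged within each half and the two halves'
regressor vectors are Pearson-correlated across voxels for all 8 x 8 label
pairs.  Every one of the C(8,4) = 70 half-subsets is used, crossed with
both orientations (which half supplies the matrix rows), giving 140
iterations whose Fisher-z-transformed correlations are averaged.

Seven matrix kinds cover the study's questions:

========= ============================== ==============================
kind      rows                           columns
========= ============================== ==============================
SQ_MOT    key-scheme SQ_MOT (keys)       same
SQ_OBJ    object-scheme SQ_OBJ (objects) same
SQ_ACROSS object-scheme SQ_OBJ by slot   key-scheme SQ_MOT by slot
RD_KEY    key-scheme RD (keys)           same
RD_POS    position-scheme RD (positions) same
RD_OBJ    object-scheme RD (objects)     same
RD_ITEM   object-scheme RD by slot       key-scheme RD by slot
========= ============================== ==============================

"by slot" means rows/columns are reordered to the learned ordinal slots of
the subject's sequences, so the diagonal pairs items sharing a learned
temporal position across domains.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd

from .protocol import CANONICAL_OBJECT_SEQUENCE, SequencePair
from .tmaps import OBJECT_INDEX, TMapSet

MATRIX_KINDS = ("SQ_MOT", "SQ_OBJ", "SQ_ACROSS", "RD_KEY", "RD_POS",
                "RD_OBJ", "RD_ITEM")

#: r is clipped to +/- this before atanh so noiseless data stays finite
R_CLIP = 1.0 - 1e-7


@dataclass(frozen=True)
class SplitIteration:
    """One half split: set1/set2 run indices and which supplies the rows."""

    set1: tuple[int, ...]
    set2: tuple[int, ...]
    orientation: int  # 1: rows from set1; 2: rows from set2


@dataclass
class SimilarityMatrix:
    """Iteration-averaged Fisher-z similarity matrix (z = atanh r)."""

    kind: str
    values: np.ndarray
    row_labels: list
    col_labels: list
    n_iterations: int

    @property
    def shape(self):
        return self.values.shape

    def to_csv(self, path: str | Path, **meta) -> None:
        df = pd.DataFrame(self.values, index=self.row_labels,
                          columns=self.col_labels)
        df.to_csv(path)
        sidecar = {"kind": self.kind, "n_iterations": self.n_iterations, **meta}
        Path(str(path) + ".json").write_text(json.dumps(sidecar))

    @classmethod
    def from_csv(cls, path: str | Path) -> "SimilarityMatrix":
        df = pd.read_csv(path, index_col=0)
        meta = json.loads(Path(str(path) + ".json").read_text())
        return cls(kind=meta["kind"], values=df.to_numpy(dtype=float),
                   row_labels=list(df.index), col_labels=list(df.columns),
                   n_iterations=int(meta["n_iterations"]))


def enumerate_splits(n_runs: int = 8, half: int = 4,
                     runs=None) -> list[SplitIteration]:
    """All C(n_runs, half) subsets crossed with both orientations.

    (8, 4) gives 70 subsets and 140 iterations.  Deterministic order:
    subsets lexicographic, orientation 1 before 2.
    """
    if half > n_runs:
        raise ValueError(f"half ({half}) cannot exceed n_runs ({n_runs})")
    runs = tuple(runs) if runs is not None else tuple(range(1, n_runs + 1))
    if len(runs) != n_runs:
        raise ValueError("runs must have length n_runs")
    out = []
    for subset in itertools.combinations(runs, half):
        complement = tuple(r for r in runs if r not in subset)
        out.append(SplitIteration(subset, complement, 1))
        out.append(SplitIteration(subset, complement, 2))
    assert len(out) == 2 * comb(n_runs, half)
    return out


def _slot_orders(sequence_pair: SequencePair):
    """Object-scheme and key-scheme label orders sorted by learned slot."""
    obj_order = [OBJECT_INDEX[o] for o in sequence_pair.object_sequence]
    key_order = list(sequence_pair.motor_sequence)
    return obj_order, key_order


def _matrix_sides(kind: str, sequence_pair: SequencePair | None):
    """(row side, col side, labels); each side = (scheme, condition, label order)."""
    ident = list(range(1, 9))
    if kind in ("SQ_ACROSS", "RD_ITEM"):
        if sequence_pair is None:
            raise ValueError(f"{kind} requires the subject's SequencePair "
                             "for slot alignment")
        obj_order, key_order = _slot_orders(sequence_pair)
        cond_row = "SQ_OBJ" if kind == "SQ_ACROSS" else "RD"
        cond_col = "SQ_MOT" if kind == "SQ_ACROSS" else "RD"
        return (("object", cond_row, obj_order), ("key", cond_col, key_order),
                [f"slot{i}" for i in ident])
    table = {
        "SQ_MOT": ("key", "SQ_MOT"),
        "SQ_OBJ": ("object", "SQ_OBJ"),
        "RD_KEY": ("key", "RD"),
        "RD_POS": ("position", "RD"),
        "RD_OBJ": ("object", "RD"),
    }
    if kind not in table:
        raise ValueError(f"unknown matrix kind {kind!r}")
    scheme, condition = table[kind]
    if scheme == "object":
        labels = list(CANONICAL_OBJECT_SEQUENCE)
    elif scheme == "key":
        labels = [f"key{i}" for i in ident]
    else:
        labels = ident
    return ((scheme, condition, ident), (scheme, condition, ident), labels)


def _zscore_rows(A: np.ndarray) -> np.ndarray:
    """Center along the voxel axis and scale to unit norm (per row)."""
    A = A - A.mean(axis=-1, keepdims=True)
    return A / np.linalg.norm(A, axis=-1, keepdims=True)


def compute_matrix(
    tmaps: TMapSet,
    kind: str,
    sequence_pair: SequencePair | None = None,
    splits: list[SplitIteration] | None = None,
) -> SimilarityMatrix:
    """Cross-validated similarity matrix of one kind for one subject x ROI.

    For every split iteration the t-maps are averaged over each 4-run half,
    the row-side regressors of one half are Pearson-correlated with the
    col-side regressors of the other across voxels, and the Fisher-z
    matrices are averaged over iterations.  When row and column sides are
    the same regressor family, the second orientation of a subset is the
    exact transpose of the first, so the averaged matrix is symmetric to
    machine precision.
    """
    if tmaps.n_voxels < 2:
        raise ValueError("need at least 2 voxels")
    (row_scheme, row_cond, row_order), (col_scheme, col_cond, col_order), labels = \
        _matrix_sides(kind, sequence_pair)
    runs = tmaps.runs()
    if splits is None:
        splits = enumerate_splits(len(runs), len(runs) // 2, runs=runs)
    R = tmaps.tensor(row_scheme, row_cond, row_order, runs=runs)
    same_side = (row_scheme, row_cond, row_order) == (col_scheme, col_cond, col_order)
    C = R if same_side else tmaps.tensor(col_scheme, col_cond, col_order, runs=runs)
    run_pos = {r: i for i, r in enumerate(runs)}

    # orientation 1 iterations are batched over subsets; an orientation-2
    # iteration whose subset already appeared with orientation 1 is, for a
    # shared regressor family, the exact transpose of that iteration
    # (corr(avg2_i, avg1_j) == corr(avg1_j, avg2_i)), so its contribution
    # is deferred to a flipped accumulator and transposed once at the end —
    # the final average is then A + A.T, symmetric to the last bit.
    z_sum = np.zeros((len(row_order), len(col_order)))
    z_sum_flipped = np.zeros_like(z_sum)
    n_iter = 0

    def _batch(pairs) -> np.ndarray:
        """Fisher-z matrices, (n_pairs, rows, cols), one per (rows, cols) split."""
        idx_r = np.array([[run_pos[r] for r in rows] for rows, _ in pairs])
        idx_c = np.array([[run_pos[r] for r in cols] for _, cols in pairs])
        zr = _zscore_rows(R[idx_r].mean(axis=1))
        zc = _zscore_rows(C[idx_c].mean(axis=1))
        r = np.einsum("sik,sjk->sij", zr, zc)
        return np.arctanh(np.clip(r, -R_CLIP, R_CLIP))

    o1 = [it for it in splits if it.orientation == 1]
    o2 = [it for it in splits if it.orientation == 2]
    z1_by_subset: dict[tuple, np.ndarray] = {}
    if o1:
        Z1 = _batch([(it.set1, it.set2) for it in o1])
        z_sum += Z1.sum(axis=0)
        n_iter += len(o1)
        z1_by_subset = {it.set1: Z1[i] for i, it in enumerate(o1)}
    rest = []
    for it in o2:
        if same_side and it.set1 in z1_by_subset:
            z_sum_flipped += z1_by_subset[it.set1]
            n_iter += 1
        else:
            rest.append(it)
    if rest:
        Z2 = _batch([(it.set2, it.set1) for it in rest])
        z_sum += Z2.sum(axis=0)
        n_iter += len(rest)
    z_total = z_sum + z_sum_flipped.T
    return SimilarityMatrix(kind=kind, values=z_total / n_iter,
                            row_labels=list(labels), col_labels=list(labels),
                            n_iterations=n_iter)


def build_all_matrices(
    tmaps: TMapSet,
    sequence_pair: SequencePair,
    splits: list[SplitIteration] | None = None,
) -> dict[str, SimilarityMatrix]:
    """The seven matrices for one subject x ROI, keyed by kind."""
    if not tmaps.normalized:
        raise ValueError("tmaps must be run-normalized before RSA")
    return {
        kind: compute_matrix(tmaps, kind, sequence_pair=sequence_pair,
                             splits=splits)
        for kind in MATRIX_KINDS
    }


def trim_boundaries(matrix: SimilarityMatrix) -> SimilarityMatrix:
    """Drop the boundary positions (first and last rows/columns): 8x8 -> 6x6."""
    if matrix.shape != (8, 8):
        raise ValueError(f"expected an 8x8 matrix, got {matrix.shape}")
    return SimilarityMatrix(
        kind=matrix.kind, values=matrix.values[1:7, 1:7].copy(),
        row_labels=matrix.row_labels[1:7], col_labels=matrix.col_labels[1:7],
        n_iterations=matrix.n_iterations,
    )


def lag_profile(matrix: SimilarityMatrix | np.ndarray) -> dict[int, float]:
    """Mean similarity by ordinal lag |row - col| (lag 0 = diagonal).

    Off-diagonal lags pool the upper and lower triangles; non-circular.
    """
    values = matrix.values if isinstance(matrix, SimilarityMatrix) else np.asarray(matrix)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("lag_profile requires a square matrix")
    n = values.shape[0]
    i, j = np.indices(values.shape)
    lag = np.abs(i - j)
    return {k: float(values[lag == k].mean()) for k in range(n)}
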