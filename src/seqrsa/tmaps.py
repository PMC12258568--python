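"""Container for per-regressor t-maps.

A :class:`TMapSet` maps ``(run, scheme, condition, label)`` to a vector of
t-values over an ROI's voxels.  Labels are integers 1-8: stream positions
under the position scheme, keys under the key scheme, and canonical object
indices under the object scheme.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .protocol import CANONICAL_OBJECT_SEQUENCE

SCHEMES = ("position", "key", "object")

#: canonical 1-based index of each object (labels under the object scheme)
OBJECT_INDEX = {obj: i + 1 for i, obj in enumerate(CANONICAL_OBJECT_SEQUENCE)}

Key = tuple[int, str, str, int]  # (run, scheme, condition, label)


def _regressor_name(key: Key) -> str:
    run, scheme, cond, lab = key
    return f"run-{run}_{scheme}_{cond}_{lab}"


def _parse_regressor_name(name: str) -> Key:
    """Inverse of :func:`_regressor_name`; condition may contain '_'."""
    run_part, rest = name.split("_", 1)
    scheme, rest = rest.split("_", 1)
    cond, lab = rest.rsplit("_", 1)
    return (int(run_part.split("-")[1]), scheme, cond, int(lab))


@dataclass
class TMapSet:
    """t-value vectors for every regressor of one subject x ROI."""

    data: dict[Key, np.ndarray]
    n_voxels: int
    normalized: bool = False
    dof: dict[int, float] = field(default_factory=dict)  # per-run residual df

    def __getitem__(self, key: Key) -> np.ndarray:
        return self.data[key]

    def runs(self) -> list[int]:
        return sorted({k[0] for k in self.data})

    def tensor(self, scheme: str, condition: str, labels,
               runs=None) -> np.ndarray:
        """Stack vectors into a (n_runs, n_labels, n_voxels) tensor.

        ``labels`` fixes the row order (e.g. slot-aligned orders for the
        across-domain matrices).
        """
        runs = list(runs) if runs is not None else self.runs()
        try:
            return np.stack([
                np.stack([self.data[(r, scheme, condition, lab)] for lab in labels])
                for r in runs
            ])
        except KeyError as err:
            raise ValueError(f"missing regressor {err.args[0]} in TMapSet") from None

    def to_frame(self) -> pd.DataFrame:
        """Wide layout: rows = voxels, one column per regressor."""
        cols = {_regressor_name(k): v for k, v in sorted(self.data.items())}
        return pd.DataFrame(cols)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)
        meta = {"n_voxels": self.n_voxels, "normalized": self.normalized,
                "dof": {str(k): v for k, v in self.dof.items()}}
        Path(str(path) + ".json").write_text(json.dumps(meta))

    @classmethod
    def from_csv(cls, path: str | Path) -> "TMapSet":
        df = pd.read_csv(path)
        data: dict[Key, np.ndarray] = {
            _parse_regressor_name(col): df[col].to_numpy(dtype=float)
            for col in df.columns
        }
        meta_path = Path(str(path) + ".json")
        normalized, dof = False, {}
        if meta_path.exists():
            meta = json.loads(meta_path.read_text())
            normalized = bool(meta.get("normalized", False))
            dof = {int(k): v for k, v in meta.get("dof", {}).items()}
        return cls(data=data, n_voxels=len(df), normalized=normalized, dof=dof)


def to_nifti(tmaps: TMapSet, mask):
    """Pack a TMapSet into a 4D NIfTI image within an ROI mask.

    ``mask`` is a boolean 3D array or a nibabel image; the 4th axis follows
    the sorted regressor order (also returned, for the sidecar).
    """
    import nibabel as nib

    if hasattr(mask, "get_fdata"):
        affine, mask_arr = mask.affine, mask.get_fdata().astype(bool)
    else:
        affine, mask_arr = np.eye(4), np.asarray(mask, dtype=bool)
    if mask_arr.sum() != tmaps.n_voxels:
        raise ValueError("mask voxel count does not match TMapSet")
    keys = sorted(tmaps.data)
    vol = np.zeros(mask_arr.shape + (len(keys),))
    for i, k in enumerate(keys):
        vol[mask_arr, i] = tmaps.data[k]
    return nib.Nifti1Image(vol, affine), [_regressor_name(k) for k in keys]


def from_nifti(img, mask, names, normalized: bool = False) -> TMapSet:
    """Inverse of :func:`to_nifti`; voxel order follows the mask raveling."""
    if hasattr(mask, "get_fdata"):
        mask_arr = mask.get_fdata().astype(bool)
    else:
        mask_arr = np.asarray(mask, dtype=bool)
    vol = img.get_fdata()
    data: dict[Key, np.ndarray] = {
        _parse_regressor_name(name): vol[mask_arr, i]
        for i, name in enumerate(names)
    }
    return TMapSet(data=data, n_voxels=int(mask_arr.sum()), normalized=normalized)
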