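"""Construction of structural and functional connectivity matrices.

Structural networks start from raw symmetric streamline-count matrices: a
group prevalence mask keeps edges present (count > 0) in at least a given
fraction of subjects, and surviving counts are log(x+1)-transformed to tame
the heavy right tail. Functional networks are pairwise Pearson correlations
of regional time series, Fisher-Z transformed, with negative correlations
set to zero. Group-average functional networks are proportionally
thresholded to a fixed edge density before community detection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "ConnectivityMatrix",
    "prevalence_mask",
    "build_scn",
    "build_fcn",
    "group_average_fcn",
    "proportional_threshold",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_mask_tsv",
    "write_mask_tsv",
]

#: correlations are clipped to +-(1 - CORR_CLIP) before atanh so Fisher-Z
#: weights stay finite for numerically perfect correlations.
CORR_CLIP = 1e-7


def _as_array(matrix) -> np.ndarray:
    """Accept a ConnectivityMatrix or a plain 2-D array."""
    values = matrix.values if isinstance(matrix, ConnectivityMatrix) else np.asarray(matrix)
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise InputError(f"expected a square matrix, got shape {values.shape}")
    return values


@dataclass
class ConnectivityMatrix:
    """A processed symmetric weighted network.

    ``kind`` is ``"structural"`` (log streamline counts) or ``"functional"``
    (Fisher-Z of nonnegative correlations). Values are symmetric,
    nonnegative, with a zero diagonal.
    """

    values: np.ndarray
    kind: str = "structural"
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise InputError(f"connectivity matrix must be square, got {v.shape}")
        if not np.allclose(v, v.T, atol=1e-12):
            raise InputError("connectivity matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise InputError("connectivity matrix must have a zero diagonal")
        if np.any(v < 0):
            raise InputError("connectivity weights must be nonnegative")
        if not self.node_labels:
            self.node_labels = [f"roi_{i + 1}" for i in range(v.shape[0])]
        if len(self.node_labels) != v.shape[0]:
            raise InputError("node_labels length does not match matrix size")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


def _check_counts(counts: np.ndarray) -> np.ndarray:
    counts = np.asarray(counts)
    if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
        raise InputError(f"count matrix must be square, got {counts.shape}")
    if np.any(counts < 0):
        raise InputError("streamline counts must be nonnegative")
    return counts


def prevalence_mask(count_matrices: Sequence[np.ndarray], threshold: float = 0.90) -> np.ndarray:
    """Group edge mask: true where count > 0 in at least ``threshold`` of subjects.

    Parameters
    ----------
    count_matrices
        Per-subject raw streamline-count matrices, all the same shape.
    threshold
        Minimum prevalence fraction; the comparison is ``>=`` so an edge
        present in exactly 90% of subjects is kept at the default.
    """
    if len(count_matrices) == 0:
        raise InputError("prevalence_mask needs at least one count matrix")
    mats = [_check_counts(m) for m in count_matrices]
    shape = mats[0].shape
    if any(m.shape != shape for m in mats):
        raise InputError("count matrices differ in shape")
    present = np.stack([m > 0 for m in mats]).mean(axis=0)
    mask = present >= threshold
    np.fill_diagonal(mask, False)
    return mask & mask.T


def build_scn(counts: np.ndarray, mask: np.ndarray,
              node_labels: Sequence[str] | None = None) -> ConnectivityMatrix:
    """Structural network: ln(count + 1) on masked-in edges, zero elsewhere."""
    counts = _check_counts(counts)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != counts.shape:
        raise InputError("mask shape does not match count matrix")
    values = np.where(mask, np.log1p(counts.astype(float)), 0.0)
    values = (values + values.T) / 2.0  # symmetrise exact float ties
    np.fill_diagonal(values, 0.0)
    return ConnectivityMatrix(values, kind="structural",
                              node_labels=list(node_labels or []))


def build_fcn(timeseries, node_labels: Sequence[str] | None = None) -> ConnectivityMatrix:
    """Functional network from a time-by-node signal table.

    Pearson correlations for all region pairs, clipped to ±(1 - 1e-7),
    Fisher-Z transformed (atanh), then negative values set to zero.
    """
    if isinstance(timeseries, pd.DataFrame):
        if node_labels is None:
            node_labels = [str(c) for c in timeseries.columns]
        ts = timeseries.to_numpy(dtype=float)
    else:
        ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2:
        raise InputError("timeseries must be a 2-D time-by-node table")
    if ts.shape[0] < 3:
        raise InputError("timeseries needs at least 3 time samples")
    sd = ts.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        labels = node_labels or [f"roi_{i + 1}" for i in range(ts.shape[1])]
        names = ", ".join(str(labels[i]) for i in dead[:5])
        raise InputError(f"constant signal (zero variance) at node(s): {names}")
    r = np.corrcoef(ts, rowvar=False)
    r = np.clip(r, -1.0 + CORR_CLIP, 1.0 - CORR_CLIP)
    z = np.arctanh(r)
    z[z < 0] = 0.0
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0
    return ConnectivityMatrix(z, kind="functional", node_labels=list(node_labels or []))


def group_average_fcn(fcns: Sequence[ConnectivityMatrix | np.ndarray]) -> ConnectivityMatrix:
    """Elementwise mean of per-subject functional networks."""
    if len(fcns) == 0:
        raise InputError("group_average_fcn needs at least one matrix")
    arrays = [_as_array(f) for f in fcns]
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise InputError("functional matrices differ in shape")
    mean = np.mean(arrays, axis=0)
    labels = fcns[0].node_labels if isinstance(fcns[0], ConnectivityMatrix) else None
    return ConnectivityMatrix(mean, kind="functional", node_labels=list(labels or []))


def proportional_threshold(matrix: ConnectivityMatrix | np.ndarray,
                           density: float = 0.10) -> ConnectivityMatrix:
    """Keep the strongest ``density`` fraction of edges, zero the rest.

    The surviving edge count is k = round(density * n(n-1)/2) with
    half-away-from-zero rounding. Ties at the cutoff weight are broken by
    ascending (i, j) order in the upper triangle, so the result is
    deterministic.
    """
    values = _as_array(matrix).copy()
    if not 0.0 < density <= 1.0:
        raise InputError(f"density must be in (0, 1], got {density}")
    labels = matrix.node_labels if isinstance(matrix, ConnectivityMatrix) else None
    kind = matrix.kind if isinstance(matrix, ConnectivityMatrix) else "functional"
    if not np.any(values):
        warnings.warn("proportional_threshold: all-zero matrix returned unchanged")
        return ConnectivityMatrix(values, kind=kind, node_labels=list(labels or []))
    n = values.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    weights = values[iu, ju]
    k = int(np.floor(density * len(weights) + 0.5))
    # stable sort on -weight keeps ascending (i, j) order among ties
    order = np.argsort(-weights, kind="stable")
    keep = order[:k]
    out = np.zeros_like(values)
    out[iu[keep], ju[keep]] = weights[keep]
    out = out + out.T
    return ConnectivityMatrix(out, kind=kind, node_labels=list(labels or []))


# ---------------------------------------------------------------------------
# TSV round-tripping (node labels as header row and index column)

def write_matrix_tsv(matrix: ConnectivityMatrix | np.ndarray, path: str | Path,
                     node_labels: Sequence[str] | None = None) -> None:
    values = _as_array(matrix)
    if node_labels is None and isinstance(matrix, ConnectivityMatrix):
        node_labels = matrix.node_labels
    if node_labels is None:
        node_labels = [f"roi_{i + 1}" for i in range(values.shape[0])]
    pd.DataFrame(values, index=node_labels, columns=node_labels).to_csv(path, sep="\t")


def read_matrix_tsv(path: str | Path, kind: str = "structural") -> ConnectivityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ConnectivityMatrix(df.to_numpy(dtype=float), kind=kind,
                              node_labels=[str(c) for c in df.columns])


def write_mask_tsv(mask: np.ndarray, path: str | Path,
                   node_labels: Sequence[str] | None = None) -> None:
    mask = np.asarray(mask, dtype=int)
    if node_labels is None:
        node_labels = [f"roi_{i + 1}" for i in range(mask.shape[0])]
    pd.DataFrame(mask, index=node_labels, columns=node_labels).to_csv(path, sep="\t")


def read_mask_tsv(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=int).astype(bool)
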