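"""Structure-function coupling coefficients and structural global efficiency.

The coupling coefficient is the Pearson correlation between a subject's
nonzero structural edge weights and the functional weights at the same
edges, restricted to the group-prevalent edge set. It is computed for the
whole brain and, restricted to within-community edges, per functional
community. Structural global efficiency (mean inverse shortest-path length
with 1/weight edge lengths) accompanies it as the standard covariate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .community import Partition
from .errors import InputError
from .netbuild import ConnectivityMatrix, _as_array

__all__ = [
    "CouplingProfile",
    "coupling_coefficient",
    "community_coupling",
    "global_efficiency",
    "coupling_profile",
    "cohort_coupling_table",
]

#: minimum number of eligible edges for a correlation to be reported.
MIN_EDGES = 3


@dataclass
class CouplingProfile:
    """Per-subject coupling summary.

    ``whole_brain_r`` and entries of ``community_r`` are NaN when fewer than
    three eligible edges (or zero-variance weight vectors) make the
    correlation undefined; undefined values are flagged, never fabricated.
    """

    subject_id: str
    timepoint: int
    whole_brain_r: float
    community_r: dict[int, float] = field(default_factory=dict)
    global_efficiency: float = 0.0
    n_edges_used: int = 0


def _eligible_edges(scn: np.ndarray, mask: np.ndarray):
    n = scn.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    keep = mask[iu, ju] & (scn[iu, ju] > 0)
    return iu[keep], ju[keep]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < MIN_EDGES:
        return float("nan")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def coupling_coefficient(scn, fcn, edge_mask: np.ndarray) -> float:
    """Whole-brain coupling: Pearson r over eligible edges.

    Eligible edges are upper-triangle entries that are true in the group
    prevalence mask and carry a nonzero structural weight for this subject.
    Functional weights enter as stored (zeros from negative-zeroing are
    legitimate values). Returns NaN when undefined (< 3 eligible edges or a
    zero-variance weight vector).
    """
    s = _as_array(scn)
    f = _as_array(fcn)
    mask = np.asarray(edge_mask, dtype=bool)
    if s.shape != f.shape or s.shape != mask.shape:
        raise InputError("SCN, FCN and mask shapes differ")
    iu, ju = _eligible_edges(s, mask)
    return _pearson(s[iu, ju], f[iu, ju])


def community_coupling(scn, fcn, edge_mask: np.ndarray,
                       partition: Partition | Sequence[int]) -> dict[int, float]:
    """Coupling per community: eligible edges with both endpoints inside it."""
    s = _as_array(scn)
    f = _as_array(fcn)
    mask = np.asarray(edge_mask, dtype=bool)
    if s.shape != f.shape or s.shape != mask.shape:
        raise InputError("SCN, FCN and mask shapes differ")
    assignment = np.asarray(
        partition.assignment if isinstance(partition, Partition) else partition)
    if assignment.shape[0] != s.shape[0]:
        raise InputError("partition length does not match matrix size")
    iu, ju = _eligible_edges(s, mask)
    out: dict[int, float] = {}
    for c in np.unique(assignment):
        inside = (assignment[iu] == c) & (assignment[ju] == c)
        out[int(c)] = _pearson(s[iu[inside], ju[inside]], f[iu[inside], ju[inside]])
    return out


def global_efficiency(scn) -> float:
    """Mean inverse shortest-path length with 1/weight edge lengths.

    Stronger edges are shorter; absent edges are unreachable and the
    corresponding pairs contribute 0 (1/infinity).
    """
    w = _as_array(scn)
    n = w.shape[0]
    if n < 2:
        raise InputError("global efficiency needs at least 2 nodes")
    if np.any(w < 0):
        raise InputError("global efficiency requires nonnegative weights")
    rows, cols = np.nonzero(np.triu(w, k=1))
    lengths = csr_matrix((1.0 / w[rows, cols], (rows, cols)), shape=(n, n))
    d = dijkstra(lengths, directed=False)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def coupling_profile(subject_id: str, timepoint: int, scn, fcn,
                     edge_mask: np.ndarray,
                     partition: Partition | Sequence[int] | None = None
                     ) -> CouplingProfile:
    """Assemble the full per-subject coupling record."""
    s = _as_array(scn)
    iu, ju = _eligible_edges(s, np.asarray(edge_mask, dtype=bool))
    return CouplingProfile(
        subject_id=subject_id,
        timepoint=timepoint,
        whole_brain_r=coupling_coefficient(scn, fcn, edge_mask),
        community_r=(community_coupling(scn, fcn, edge_mask, partition)
                     if partition is not None else {}),
        global_efficiency=global_efficiency(scn),
        n_edges_used=int(len(iu)),
    )


def cohort_coupling_table(profiles: Sequence[CouplingProfile]) -> pd.DataFrame:
    """Tabulate coupling profiles, one row per subject-timepoint."""
    community_ids = sorted({c for p in profiles for c in p.community_r})
    rows = []
    for p in profiles:
        row: dict = {
            "subject_id": p.subject_id,
            "timepoint": p.timepoint,
            "whole_brain_r": p.whole_brain_r,
        }
        for c in community_ids:
            row[f"community_{c}_r"] = p.community_r.get(c, np.nan)
        row["global_efficiency"] = p.global_efficiency
        row["n_edges_used"] = p.n_edges_used
        rows.append(row)
    return pd.DataFrame(rows)
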