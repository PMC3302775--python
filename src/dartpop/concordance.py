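"""Concordance of ancestry estimates and data-resolution analysis.

Covers membership thresholding (strictly greater than 0.6 by default),
cluster-label alignment across runs (label switching), the per-individual
and average dissimilarity index of ancestry, and the data-resolution
statistic: correlation between dissimilarity matrices built from two
independent half-samples of markers, as a function of marker number.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import pearsonr

from .core import (
    UNASSIGNED,
    BiallelicGenotypeMatrix,
    GroupAssignment,
    QMatrix,
)
from .diversity import dissimilarity_matrix

__all__ = [
    "assign_groups",
    "align_cluster_labels",
    "ancestry_dissimilarity",
    "ConcordanceResult",
    "data_resolution_curve",
    "ResolutionCurve",
]


def assign_groups(q: QMatrix, threshold: float = 0.6) -> GroupAssignment:
    """Assign accession i to argmax_k q_ik iff that membership is
    strictly greater than ``threshold``; otherwise UNASSIGNED.

    Group labels are 1..K.
    """
    labels: list[int | str] = []
    best = q.q.argmax(axis=1)
    for i, k in enumerate(best):
        labels.append(int(k) + 1 if q.q[i, k] > threshold else UNASSIGNED)
    return GroupAssignment.from_labels(q.accession_ids, labels)


def align_cluster_labels(q: QMatrix, q_ref: QMatrix) -> tuple[QMatrix, tuple[int, ...]]:
    """Permute the columns of ``q`` to best match ``q_ref``.

    Maximizes sum_i sum_k min(q_ref_ik, q_i,sigma(k)).  The objective is
    a sum of per-column scores, so the assignment problem solves it
    exactly for any K.  Returns the aligned matrix and the permutation
    sigma (aligned column k = original column sigma[k]).
    """
    if q.K != q_ref.K:
        raise ValueError(f"K mismatch: {q.K} vs {q_ref.K}")
    if q.accession_ids != q_ref.accession_ids:
        raise ValueError("accession sets/order differ between Q-matrices")
    score = np.empty((q.K, q.K))
    for k in range(q.K):
        for l in range(q.K):
            score[k, l] = np.minimum(q_ref.q[:, k], q.q[:, l]).sum()
    rows, cols = linear_sum_assignment(-score)
    sigma = tuple(int(cols[np.argwhere(rows == k)[0, 0]]) for k in range(q.K))
    aligned = QMatrix(list(q.accession_ids), q.q[:, list(sigma)])
    return aligned, sigma


@dataclass
class ConcordanceResult:
    """Per-accession and average ancestry dissimilarity between two runs."""

    accession_ids: list[str]
    d_i: np.ndarray
    mode: str
    permutation: tuple[int, ...]

    @property
    def average(self) -> float:
        return float(self.d_i.mean())


def _one_hot_threshold(q: QMatrix, threshold: float) -> np.ndarray:
    """Rows -> one-hot over K+1 categories (K groups + unassigned)."""
    out = np.zeros((q.n_accessions, q.K + 1))
    best = q.q.argmax(axis=1)
    for i, k in enumerate(best):
        if q.q[i, k] > threshold:
            out[i, k] = 1.0
        else:
            out[i, q.K] = 1.0
    return out


def ancestry_dissimilarity(
    q: QMatrix,
    q2: QMatrix,
    mode: str = "quantitative",
    threshold: float = 0.6,
    align: bool = True,
) -> ConcordanceResult:
    """Dissimilarity index of ancestry between two runs or marker systems.

    Quantitative mode: D_i = (1/2) sum_k |q_ik - q'_ik|, identically
    1 - sum_k min(q_ik, q'_ik) for probability rows.  Thresholded mode:
    rows are first replaced by one-hot vectors over K+1 categories
    (assigned group or unassigned), so D_i is 0 or 1 and the average is
    the fraction of accessions whose assignment differs.  Labels are
    aligned internally before comparing (flagged in the result).
    """
    if q.accession_ids != q2.accession_ids:
        raise ValueError("accession sets differ")
    if align:
        q2_aligned, sigma = align_cluster_labels(q2, q)
    else:
        q2_aligned, sigma = q2, tuple(range(q2.K))
    if mode == "quantitative":
        d_i = 0.5 * np.abs(q.q - q2_aligned.q).sum(axis=1)
    elif mode == "thresholded":
        a = _one_hot_threshold(q, threshold)
        b = _one_hot_threshold(q2_aligned, threshold)
        d_i = 0.5 * np.abs(a - b).sum(axis=1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return ConcordanceResult(list(q.accession_ids), d_i, mode, sigma)


@dataclass
class ResolutionCurve:
    """Mean half-split dissimilarity correlation vs marker number."""

    table: pd.DataFrame  # columns: m, mean_r, sd_r, n_reps
    scope: str
    index: str

    def write(self, path) -> None:
        out = self.table.copy()
        out["scope"] = self.scope
        out.to_csv(path, sep="\t", index=False)


def _pair_mask(ids: list[str], groups: GroupAssignment | None, scope: str) -> np.ndarray:
    """Boolean mask over condensed (upper-triangle) accession pairs."""
    n = len(ids)
    iu = np.triu_indices(n, k=1)
    if scope == "all_pairs":
        return np.ones(iu[0].size, dtype=bool)
    if groups is None:
        raise ValueError(f"scope {scope!r} requires a group assignment")
    lab = np.array([groups.group_of(a) for a in ids], dtype=object)
    assigned = lab != UNASSIGNED
    same = (lab[iu[0]] == lab[iu[1]]) & assigned[iu[0]] & assigned[iu[1]]
    diff = (lab[iu[0]] != lab[iu[1]]) & assigned[iu[0]] & assigned[iu[1]]
    if scope == "intragroup":
        return same
    if scope == "intergroup":
        return diff
    raise ValueError(f"unknown scope {scope!r}")


def data_resolution_curve(
    gm: BiallelicGenotypeMatrix,
    index: str = "simple_matching",
    step: int = 50,
    n_reps: int = 1000,
    groups: GroupAssignment | None = None,
    scope: str = "all_pairs",
    seed: int | None = None,
) -> ResolutionCurve:
    """Data-resolution statistic: for each marker number m (2*step,
    4*step, ... up to the panel size), repeatedly sample m markers
    without replacement, split them into two disjoint halves, build a
    dissimilarity matrix from each half, and correlate the two matrices
    over unordered accession pairs (optionally restricted to intra- or
    inter-group pairs).  Reports the mean and SD of Pearson's r over
    replicates.
    """
    total = gm.n_markers
    if total < 2 * step:
        raise ValueError("need at least 2*step markers")
    rng = np.random.default_rng(seed)
    mask = _pair_mask(gm.accession_ids, groups, scope)
    ms = list(range(2 * step, total + 1, 2 * step))
    rows = []
    for m in ms:
        rs = []
        for _ in range(n_reps):
            chosen = rng.choice(total, size=m, replace=False)
            half = m // 2
            first, second = chosen[:half], chosen[half : 2 * half]
            d1 = dissimilarity_matrix(
                gm.subset_markers([gm.marker_ids[j] for j in first]), index
            ).condensed()[mask]
            d2 = dissimilarity_matrix(
                gm.subset_markers([gm.marker_ids[j] for j in second]), index
            ).condensed()[mask]
            ok = ~np.isnan(d1) & ~np.isnan(d2)
            if ok.sum() < 3 or d1[ok].std() == 0 or d2[ok].std() == 0:
                continue
            rs.append(pearsonr(d1[ok], d2[ok]).statistic)
        rows.append(
            {
                "m": m,
                "mean_r": float(np.mean(rs)) if rs else np.nan,
                "sd_r": float(np.std(rs, ddof=1)) if len(rs) > 1 else np.nan,
                "n_reps": len(rs),
            }
        )
    return ResolutionCurve(pd.DataFrame(rows), scope=scope, index=index)
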