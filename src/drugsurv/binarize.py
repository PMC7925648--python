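"""Adaptive high/low binarization of expression by step-function fitting.

Each gene's log-scale expression values are sorted and fitted with a
two-level step function; the threshold is the candidate cut minimizing the
pooled within-group mean squared error (the StepMiner idea).  Candidates
come from two 200-point grids: one over sample ranks (midpoints between the
order statistics bracketing evenly spaced rank positions) and one evenly
spaced through the value range.  The same routine binarizes any per-patient
score vector, which is how gene-set expression fractions are thresholded
downstream.

"Low" is defined as value <= threshold.  A gene whose values admit no valid
split (constant vector) is degenerate: all calls low, threshold NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UsageError
from .ingest import ExpressionMatrix

N_RANK_CANDIDATES = 200
N_RANGE_CANDIDATES = 200


@dataclass(frozen=True)
class StepFit:
    """A two-level step fit of sorted values at a given threshold."""

    threshold: float
    low_mean: float
    high_mean: float
    mse: float
    n_low: int
    n_high: int


@dataclass
class BinaryMatrix:
    """Per-gene high/low calls with the thresholds that produced them.

    ``calls`` is a boolean genes x samples DataFrame (True = high).
    ``thresholds`` maps gene id -> threshold (NaN for degenerate genes,
    which are all-low).
    """

    calls: pd.DataFrame
    thresholds: pd.Series

    @property
    def gene_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.calls.columns)

    def is_degenerate(self, gene_id: str) -> bool:
        return bool(np.isnan(self.thresholds.loc[gene_id]))

    @property
    def degenerate_genes(self) -> list[str]:
        return list(self.thresholds.index[self.thresholds.isna()])

    def to_tsv(self, path) -> None:
        self.calls.astype(int).to_csv(path, sep="\t", index_label="gene_id")

    def thresholds_to_tsv(self, path) -> None:
        n_high = self.calls.sum(axis=1)
        out = pd.DataFrame(
            {
                "threshold": self.thresholds,
                "n_low": self.calls.shape[1] - n_high,
                "n_high": n_high,
                "degenerate": self.thresholds.isna().astype(int),
            }
        )
        out.to_csv(path, sep="\t", index_label="gene_id")


def candidate_thresholds(values) -> np.ndarray:
    """Candidate cut points for one gene: up to 200 rank-grid midpoints plus
    200 range-grid points, deduplicated, sorted, all strictly inside
    (min, max).  A constant vector yields an empty array."""
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n < 2:
        raise UsageError("need at least 2 values to propose thresholds")
    if v[0] == v[-1]:
        return np.empty(0)
    # Rank grid: split positions k (low side gets v[:k]) at 200 evenly
    # spaced ranks; candidate is the midpoint of the bracketing order stats.
    ks = np.unique(np.round(np.linspace(1, n - 1, N_RANK_CANDIDATES)).astype(int))
    rank_cands = (v[ks - 1] + v[ks]) / 2.0
    range_cands = np.linspace(v[0], v[-1], N_RANGE_CANDIDATES + 2)[1:-1]
    cands = np.unique(np.concatenate([rank_cands, range_cands]))
    return cands[(cands > v[0]) & (cands < v[-1])]


def step_fit(values, threshold: float) -> StepFit | None:
    """Fit a two-level step at ``threshold``: low group = values <= threshold.

    Returns None (invalid fit) when either side is empty; such candidates
    are excluded from the minimization.
    """
    v = np.asarray(values, dtype=float)
    low = v[v <= threshold]
    high = v[v > threshold]
    if low.size == 0 or high.size == 0:
        return None
    ss = np.sum((low - low.mean()) ** 2) + np.sum((high - high.mean()) ** 2)
    return StepFit(
        threshold=float(threshold),
        low_mean=float(low.mean()),
        high_mean=float(high.mean()),
        mse=float(ss / v.size),
        n_low=int(low.size),
        n_high=int(high.size),
    )


def _scan(values) -> StepFit | None:
    """Vectorized candidate scan; returns the winning fit or None."""
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    cands = candidate_thresholds(v)
    if cands.size == 0:
        return None
    k = np.searchsorted(v, cands, side="right")  # low-group sizes
    valid = (k > 0) & (k < n)
    if not valid.any():
        return None
    cands, k = cands[valid], k[valid]
    cs = np.concatenate([[0.0], np.cumsum(v)])
    cs2 = np.concatenate([[0.0], np.cumsum(v * v)])
    s_low, s2_low = cs[k], cs2[k]
    s_high, s2_high = cs[n] - s_low, cs2[n] - s2_low
    nh = n - k
    ss = (s2_low - s_low**2 / k) + (s2_high - s_high**2 / nh)
    mse = ss / n
    # Ties (same split, or equal mse) broken by: more balanced split, then
    # threshold closest to the midpoint of its bracketing order statistics
    # (the canonical step location, centred in the expression gap), then
    # smaller threshold.
    gap_mid = (v[k - 1] + v[np.minimum(k, n - 1)]) / 2.0
    order = np.lexsort((cands, np.abs(cands - gap_mid), np.abs(k - nh), mse))
    i = order[0]
    return StepFit(
        threshold=float(cands[i]),
        low_mean=float(s_low[i] / k[i]),
        high_mean=float(s_high[i] / nh[i]),
        mse=float(mse[i]),
        n_low=int(k[i]),
        n_high=int(nh[i]),
    )


def stepminer_threshold(values) -> float:
    """Best step-function threshold for one value vector, or NaN when the
    vector admits no valid split (degenerate)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise UsageError("need at least 2 values to fit a threshold")
    fit = _scan(v)
    return float("nan") if fit is None else fit.threshold


def stepminer_fit(values) -> StepFit | None:
    """Like :func:`stepminer_threshold` but returns the full winning fit."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise UsageError("need at least 2 values to fit a threshold")
    return _scan(v)


def binarize_scores(scores) -> tuple[np.ndarray, float]:
    """Binarize a per-patient score vector with the step-fit threshold.

    Returns (boolean high calls, threshold).  Degenerate vectors give
    all-low calls and a NaN threshold.  This is the single thresholding
    routine in the codebase; gene-set fractions reuse it verbatim.
    """
    v = np.asarray(scores, dtype=float)
    t = stepminer_threshold(v)
    if np.isnan(t):
        return np.zeros(v.size, dtype=bool), t
    return v > t, t


def binarize_matrix(matrix: ExpressionMatrix) -> BinaryMatrix:
    """Binarize every gene of a log-scale expression matrix.

    Thresholds are computed per gene across ALL samples (not per patient
    group), so a gene's high/low call is a cohort-level property.
    """
    if matrix.scale != "log":
        raise UsageError("binarize_matrix expects a log-scale matrix")
    vals = matrix.values.to_numpy(dtype=float)
    thresholds = np.empty(vals.shape[0])
    calls = np.zeros(vals.shape, dtype=bool)
    for i in range(vals.shape[0]):
        t = stepminer_threshold(vals[i])
        thresholds[i] = t
        if not np.isnan(t):
            calls[i] = vals[i] > t
    return BinaryMatrix(
        calls=pd.DataFrame(
            calls, index=matrix.values.index, columns=matrix.values.columns
        ),
        thresholds=pd.Series(thresholds, index=matrix.values.index, name="threshold"),
    )
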