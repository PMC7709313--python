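"""Restart random walks on miRNA similarity networks and pair features.

Each lncRNA (or disease) seeds a walk uniformly over the miRNAs it is known
to interact with; the walk diffuses along a row-normalized miRNA similarity
network and teleports back to the seeds with probability ``restart``.  The
stationary column of walk probabilities is the entity's feature vector, and
a lncRNA-disease pair is represented by the elementwise product of its two
feature vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RwrConfig
from .core_data import IncidenceMatrix
from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)


@dataclass
class FeatureMatrix:
    """Walk-probability matrix: one column per target entity, one row per miRNA.

    Columns whose seed column was nonzero are probability vectors; columns of
    isolated entities (no miRNA partner) stay identically zero.
    """

    row_labels: list[str]
    col_labels: list[str]
    values: np.ndarray
    converged: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("feature matrix shape does not match labels")

    def column(self, j: int) -> np.ndarray:
        return self.values[:, j]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_labels, columns=self.col_labels)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def row_normalize(sim: SimilarityMatrix) -> np.ndarray:
    """Divide each row by its sum; all-zero rows stay zero (logged)."""
    values = sim.values
    sums = values.sum(axis=1, keepdims=True)
    zero_rows = (sums == 0).ravel()
    if zero_rows.any():
        logger.warning("row_normalize: %d all-zero rows left unnormalized", zero_rows.sum())
    safe = np.where(sums == 0, 1.0, sums)
    return values / safe


def column_normalize_seeds(assoc: IncidenceMatrix) -> np.ndarray:
    """Uniform seed distribution over the ones of each column.

    All-zero columns (isolated entities) remain zero; they still receive a
    (zero) feature vector downstream rather than an error.
    """
    values = assoc.values
    sums = values.sum(axis=0, keepdims=True)
    n_zero = int((sums == 0).sum())
    if n_zero:
        logger.warning("column_normalize_seeds: %d isolated entities (all-zero seed columns)", n_zero)
    safe = np.where(sums == 0, 1.0, sums)
    return values / safe


def rwr(
    seeds: np.ndarray,
    transition: np.ndarray,
    cfg: RwrConfig,
    row_labels: list[str] | None = None,
    col_labels: list[str] | None = None,
) -> FeatureMatrix:
    """Iterate P_{s+1} = (1 - r) W^T P_s + r P_0 to stationarity.

    Stops when the max-abs difference between successive iterates drops below
    ``cfg.tol``, or at ``cfg.max_iter`` (then the result carries
    ``converged=False`` and a warning is logged).  At convergence the result
    equals the closed form r (I - (1 - r) W^T)^{-1} P_0.
    """
    seeds = np.asarray(seeds, dtype=float)
    transition = np.asarray(transition, dtype=float)
    if transition.shape[0] != transition.shape[1] or transition.shape[1] != seeds.shape[0]:
        raise ValueError("transition must be square and match the seed dimension")
    r = cfg.restart
    wt = transition.T
    p = seeds.copy()
    converged = False
    for _ in range(cfg.max_iter):
        p_next = (1.0 - r) * (wt @ p) + r * seeds
        if np.max(np.abs(p_next - p)) < cfg.tol:
            p = p_next
            converged = True
            break
        p = p_next
    if not converged:
        logger.warning("rwr: max_iter=%d reached without convergence", cfg.max_iter)
    n, m = p.shape if p.ndim == 2 else (p.shape[0], 1)
    rows = row_labels if row_labels is not None else [str(i) for i in range(n)]
    cols = col_labels if col_labels is not None else [str(j) for j in range(m)]
    return FeatureMatrix(rows, cols, p.reshape(n, m), converged=converged)


def rwr_closed_form(seeds: np.ndarray, transition: np.ndarray, restart: float) -> np.ndarray:
    """Direct solve of the stationary equation; the oracle for the iteration."""
    seeds = np.asarray(seeds, dtype=float)
    n = transition.shape[0]
    return restart * np.linalg.solve(
        np.eye(n) - (1.0 - restart) * np.asarray(transition, dtype=float).T,
        seeds,
    )


def pair_feature(pl: FeatureMatrix, pd_: FeatureMatrix, i: int, j: int) -> np.ndarray:
    """Elementwise product of lncRNA column i and disease column j."""
    a = pl.column(i)
    b = pd_.column(j)
    if a.shape != b.shape:
        raise ValueError(f"feature length mismatch: {a.shape} vs {b.shape}")
    return a * b


def pair_feature_matrix(pl: FeatureMatrix, pd_: FeatureMatrix) -> np.ndarray:
    """All pair features at once, shaped (n_lncRNA, n_disease, n_miRNA)."""
    if pl.values.shape[0] != pd_.values.shape[0]:
        raise ValueError("feature matrices must share the miRNA axis")
    return pl.values.T[:, None, :] * pd_.values.T[None, :, :]
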