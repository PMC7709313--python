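"""Graded association-probability targets from the binary lncRNA-disease matrix.

A 0/1 association matrix says nothing about the strength of a link and
nothing about unobserved pairs.  The "Disease Clique" smoothing replaces it
with graded targets: each pair receives attenuated similarity-weighted votes
from the known associations of similar lncRNAs (lncRNA side) and of
semantically similar diseases (disease side); known pairs additionally keep
most of their own unit evidence.  The two sides are mixed with ``rate`` and
the result is min-max normalized over the whole matrix.

The Disease Clique itself (the set of diseases with nonzero semantic
similarity to a given disease) needs no explicit construction: zero
similarities contribute zero to the vote, so summing over all diseases is
algebraically identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import TargetParams
from .core_data import IncidenceMatrix
from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)


@dataclass
class TargetMatrix:
    """Smoothed targets in [0, 1], axes labelled like the LD matrix."""

    row_labels: list[str]
    col_labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("target matrix shape does not match labels")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_labels, columns=self.col_labels)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def fout(ld: IncidenceMatrix, fl: SimilarityMatrix, k1: float) -> np.ndarray:
    """lncRNA-side smoothing: attenuated votes of similar lncRNAs.

    FOUT(i, j) = k1 * sum_n LD(n, j) FL(i, n), plus (1 - k1) when
    LD(i, j) = 1.  The sum includes n = i, so a known pair with no other
    support scores exactly k1 * FL(i, i) + 1 - k1 = 1.
    """
    if fl.labels != ld.rows.names:
        raise ValueError("fl must be indexed by the lncRNAs of ld")
    return k1 * (fl.values @ ld.values) + (1.0 - k1) * ld.values


def dout(ld: IncidenceMatrix, ds_ld: SimilarityMatrix, k2: float) -> np.ndarray:
    """Disease-side smoothing, the mirror of :func:`fout`."""
    if ds_ld.labels != ld.cols.names:
        raise ValueError("ds_ld must be indexed by the diseases of ld")
    return k2 * (ld.values @ ds_ld.values) + (1.0 - k2) * ld.values


def combine_and_normalize(
    fout_m: np.ndarray,
    dout_m: np.ndarray,
    params: TargetParams,
    row_labels: list[str] | None = None,
    col_labels: list[str] | None = None,
) -> TargetMatrix:
    """Mix the two sides and min-max normalize over the whole matrix.

    OUT = rate * FOUT + (1 - rate) * DOUT; OUTPUT = (OUT - min) / (max - min)
    with the min and max taken globally.  A constant OUT degenerates to all
    zeros with a warning.
    """
    fout_m = np.asarray(fout_m, dtype=float)
    dout_m = np.asarray(dout_m, dtype=float)
    if fout_m.shape != dout_m.shape:
        raise ValueError("FOUT and DOUT shapes differ")
    out = params.rate * fout_m + (1.0 - params.rate) * dout_m
    lo, hi = out.min(), out.max()
    if hi == lo:
        logger.warning("combine_and_normalize: constant OUT matrix, targets set to 0")
        values = np.zeros_like(out)
    else:
        values = (out - lo) / (hi - lo)
    rows = row_labels if row_labels is not None else [str(i) for i in range(out.shape[0])]
    cols = col_labels if col_labels is not None else [str(j) for j in range(out.shape[1])]
    return TargetMatrix(rows, cols, values)


def target_matrix(
    ld: IncidenceMatrix,
    fl: SimilarityMatrix,
    ds_ld: SimilarityMatrix,
    params: TargetParams,
) -> TargetMatrix:
    """Full smoothing pipeline: fout + dout + mix + normalize."""
    return combine_and_normalize(
        fout(ld, fl, params.k1),
        dout(ld, ds_ld, params.k2),
        params,
        row_labels=list(ld.rows.names),
        col_labels=list(ld.cols.names),
    )
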