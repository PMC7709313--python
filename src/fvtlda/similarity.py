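"""miRNA/lncRNA similarity kernels.

Two similarity notions feed the random walks: a Gaussian interaction-profile
(GIP) kernel over binary interaction profiles, and a best-match-average
functional similarity that scores two entities by how semantically close
their associated disease sets are.  One functional-similarity code path
serves both miRNAs (against the miRNA-disease matrix) and lncRNAs (against
the lncRNA-disease matrix).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import IncidenceMatrix


@dataclass
class SimilarityMatrix:
    """Square nonnegative similarity matrix with entity labels."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(f"expected {n}x{n} matrix, got {self.values.shape}")
        if (self.values < 0).any():
            raise ValueError("similarity entries must be nonnegative")

    def __len__(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    def submatrix(self, labels: list[str]) -> "SimilarityMatrix":
        """Restriction to a label subset, e.g. the diseases of the lncRNA-disease
        matrix extracted from the full disease similarity."""
        pos = {lab: k for k, lab in enumerate(self.labels)}
        idx = np.array([pos[lab] for lab in labels])
        return SimilarityMatrix(labels=list(labels), values=self.values[np.ix_(idx, idx)])


def gip_kernel(
    profiles: IncidenceMatrix,
    gamma_prime: float = 1.0,
    average_norm: bool = False,
) -> SimilarityMatrix:
    """Gaussian interaction-profile kernel between the rows of ``profiles``.

    KM(i, j) = exp(-gamma * ||IP(i) - IP(j)||^2) with the bandwidth
    gamma = gamma_prime / sum_k ||IP(k)||^2.  ``average_norm=True`` switches
    the denominator to the mean squared norm (the variant used by some GIP
    formulations); the plain sum is the default.
    """
    if gamma_prime <= 0:
        raise ValueError("gamma_prime must be positive")
    ip = profiles.values
    sq_norms = (ip ** 2).sum(axis=1)
    denom = sq_norms.sum()
    if denom == 0:
        raise ValueError("all interaction profiles are zero; GIP bandwidth undefined")
    if average_norm:
        denom /= ip.shape[0]
    gamma = gamma_prime / denom
    # ||a-b||^2 = ||a||^2 + ||b||^2 - 2 a.b
    sq_dist = sq_norms[:, None] + sq_norms[None, :] - 2.0 * ip @ ip.T
    np.maximum(sq_dist, 0.0, out=sq_dist)
    return SimilarityMatrix(labels=list(profiles.rows.names), values=np.exp(-gamma * sq_dist))


def functional_similarity(
    assoc: IncidenceMatrix,
    disease_sim: SimilarityMatrix,
) -> SimilarityMatrix:
    """Best-match-average functional similarity between the rows of ``assoc``.

    For entities i, j with associated disease sets of sizes p and q, the score
    is the sum of each disease's best semantic match in the other set,
    averaged over p + q.  An entity with no diseases scores 0 against every
    other entity and 1 against itself.
    """
    if assoc.cols.names != disease_sim.labels:
        raise ValueError("assoc columns must be indexed by the diseases of disease_sim")
    a = assoc.values
    ds = disease_sim.values
    n = a.shape[0]
    disease_sets = [np.flatnonzero(a[i]) for i in range(n)]
    values = np.eye(n)
    for i in range(n):
        di = disease_sets[i]
        if di.size == 0:
            continue
        for j in range(i + 1, n):
            dj = disease_sets[j]
            if dj.size == 0:
                continue
            block = ds[np.ix_(di, dj)]
            score = (block.max(axis=1).sum() + block.max(axis=0).sum()) / (di.size + dj.size)
            values[i, j] = values[j, i] = score
    return SimilarityMatrix(labels=list(assoc.rows.names), values=values)
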