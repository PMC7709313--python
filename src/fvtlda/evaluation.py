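"""Cross-validation, ROC/AUC, candidate ranking and case-study scoring.

Link-prediction evaluation here follows the field's ranking convention: a
held-out known association is scored by a model trained without it and
compared against all pairs that were never observed.  The AUC is the
probability that a random held-out positive outranks a random unobserved
pair (ties counted half), which coincides with the trapezoidal area under
the rank-threshold ROC sweep.

Because the graded training targets are derived from the known association
matrix, every held-out entry is zeroed before target construction (the
lncRNA functional similarity, which also reads that matrix, is recomputed on
the masked matrix as well); the walk-based features never touch the
lncRNA-disease matrix and need no masking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .config import AnnConfig, FvtldaParams
from .core_data import IncidenceMatrix
from .models import fit_ann, fit_mlr, predict_ann, predict_mlr
from .similarity import SimilarityMatrix, functional_similarity
from .targets import target_matrix

ModelKind = Literal["mlr", "ann"]


@dataclass(frozen=True)
class CvPlan:
    """k-fold cross-validation plan (seeded, optionally repeated)."""

    scheme: Literal["loocv", "kfold"] = "kfold"
    k: int = 5
    repeats: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme == "kfold" and self.k < 2:
            raise ValueError("kfold requires k >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class RocResult:
    """ROC sweep points plus the area under them."""

    points: list[tuple[float, float]]
    auc: float
    meta: dict = field(default_factory=dict)


@dataclass
class CaseStudyReport:
    """Ranked unobserved candidates for one disease."""

    disease: str
    candidates: list[str]
    scores: list[float]
    ranks: list[int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lncRNA": self.candidates, "score": self.scores, "rank": self.ranks}
        )

    def top(self, n: int = 10) -> "CaseStudyReport":
        return CaseStudyReport(
            self.disease, self.candidates[:n], self.scores[:n], self.ranks[:n]
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def auc(pos_scores: Sequence[float], neg_scores: Sequence[float]) -> float:
    """Concordance AUC: P(random positive > random negative), ties half."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("auc needs non-empty positive and negative score lists")
    greater = (pos[:, None] > neg[None, :]).sum()
    equal = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * equal) / (pos.size * neg.size))


def contrast_score(verified_ranks: Sequence[int]) -> float:
    """Case-study contrast score exp(sum 1/R_i - sum 1/i).

    ``verified_ranks`` lists, in table order, the 1-based ranks of the
    verified candidates; the score is 1 exactly when they occupy ranks
    1..m consecutively and decays as any rank worsens.
    """
    ranks = list(verified_ranks)
    if not ranks:
        raise ValueError("contrast_score needs at least one verified rank")
    if any(int(r) != r or r < 1 for r in ranks):
        raise ValueError("ranks must be positive integers")
    m = len(ranks)
    return math.exp(sum(1.0 / r for r in ranks) - sum(1.0 / i for i in range(1, m + 1)))


def rank_candidates(
    scores: np.ndarray,
    disease: int,
    ld: IncidenceMatrix,
) -> CaseStudyReport:
    """Rank the lncRNAs with no known link to ``disease`` by descending score.

    Ties are broken by registry order (stable sort), so reports are
    deterministic.
    """
    scores = np.asarray(scores, dtype=float)
    col = ld.values[:, disease]
    candidates = np.flatnonzero(col == 0)
    order = candidates[np.argsort(-scores[candidates, disease], kind="stable")]
    return CaseStudyReport(
        disease=ld.cols.names[disease],
        candidates=[ld.rows.names[i] for i in order],
        scores=[float(scores[i, disease]) for i in order],
        ranks=list(range(1, len(order) + 1)),
    )


def _fit_predict(
    model_kind: ModelKind,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_all: np.ndarray,
    ann_cfg: AnnConfig,
    seed: int,
) -> np.ndarray:
    if model_kind == "mlr":
        model = fit_mlr(x_train, y_train)
        return np.asarray(predict_mlr(model, x_all))
    if model_kind == "ann":
        model = fit_ann(x_train, y_train, cfg=ann_cfg, seed=seed)
        return np.asarray(predict_ann(model, x_all))
    raise ValueError(f"unknown model kind {model_kind!r}")


def _masked_targets(
    ld: IncidenceMatrix,
    ds_ld: SimilarityMatrix,
    params: FvtldaParams,
    masked: Sequence[tuple[int, int]],
) -> np.ndarray:
    """Targets rebuilt from the association matrix with test entries zeroed."""
    values = ld.values.copy()
    for i, j in masked:
        values[i, j] = 0.0
    ld_masked = IncidenceMatrix(ld.rows, ld.cols, values)
    fl = functional_similarity(ld_masked, ds_ld)
    return target_matrix(ld_masked, fl, ds_ld, params.target_params()).values


def _roc_points(one_minus_u: np.ndarray) -> list[tuple[float, float]]:
    """Step-curve ROC from per-positive normalized exceedance fractions."""
    m = one_minus_u.size
    points = [(0.0, 0.0)]
    for k, fpr in enumerate(np.sort(one_minus_u), start=1):
        points.append((float(fpr), k / m))
    points.append((1.0, 1.0))
    return points


def _holdout_evaluation(
    pair_feats: np.ndarray,
    ld: IncidenceMatrix,
    ds_ld: SimilarityMatrix,
    params: FvtldaParams,
    folds: Sequence[Sequence[tuple[int, int]]],
    model_kind: ModelKind,
    seed: int,
    permute_targets: bool,
) -> tuple[list[float], list[float]]:
    """Shared engine for LOOCV (singleton folds) and k-fold CV.

    Returns the list of per-positive normalized ranks u (fraction of
    unobserved pairs scored strictly below, ties half) and the per-fold AUCs.
    """
    n_l, n_d, n_m = pair_feats.shape
    x_all = pair_feats.reshape(n_l * n_d, n_m)
    flat_known = np.flatnonzero(ld.values.ravel() == 1)
    flat_unknown = np.flatnonzero(ld.values.ravel() == 0)
    seeds = np.random.SeedSequence(seed).generate_state(len(folds) + 1)
    perm_rng = np.random.default_rng(seeds[-1])

    u_values: list[float] = []
    fold_aucs: list[float] = []
    for f, fold in enumerate(folds):
        y = _masked_targets(ld, ds_ld, params, fold).ravel()
        if permute_targets:
            y = perm_rng.permutation(y)
        test_flat = np.array([i * n_d + j for i, j in fold])
        train_mask = np.ones(n_l * n_d, dtype=bool)
        train_mask[test_flat] = False
        preds = _fit_predict(
            model_kind,
            x_all[train_mask],
            y[train_mask],
            x_all,
            params.ann,
            int(seeds[f] % (2 ** 31)),
        )
        pos = preds[test_flat]
        neg = preds[flat_unknown]
        fold_aucs.append(auc(pos, neg))
        for p in pos:
            u_values.append(auc([p], neg))
    return u_values, fold_aucs


def loocv_run(
    pair_feats: np.ndarray,
    ld: IncidenceMatrix,
    ds_ld: SimilarityMatrix,
    model_kind: ModelKind = "mlr",
    params: FvtldaParams | None = None,
    seed: int = 0,
    permute_targets: bool = False,
) -> RocResult:
    """Leave-one-out CV over the known associations.

    Each known pair is masked and held out in turn; the model trains on every
    other pair and the held-out pair is ranked against all unobserved pairs.
    ``permute_targets=True`` shuffles the training targets across pairs
    (seeded) and serves as the no-signal control.
    """
    params = params or FvtldaParams()
    known = list(zip(*np.nonzero(ld.values)))
    if len(known) < 2:
        raise ValueError("loocv needs at least 2 known associations")
    folds = [[(int(i), int(j))] for i, j in known]
    u_values, _ = _holdout_evaluation(
        pair_feats, ld, ds_ld, params, folds, model_kind, seed, permute_targets
    )
    u = np.asarray(u_values)
    return RocResult(
        points=_roc_points(1.0 - u),
        auc=float(u.mean()),
        meta={"scheme": "loocv", "n_known": len(known), "model": model_kind},
    )


def kfold_run(
    pair_feats: np.ndarray,
    ld: IncidenceMatrix,
    ds_ld: SimilarityMatrix,
    model_kind: ModelKind = "mlr",
    plan: CvPlan | None = None,
    params: FvtldaParams | None = None,
) -> list[RocResult]:
    """Repeated k-fold CV; one RocResult per repeat (folds pooled).

    Known pairs are partitioned at random (seeded) into k near-equal parts;
    each part is masked and held out in turn.  Per repeat, the held-out
    positives of all folds are pooled into one ROC; ``summarize`` gives the
    mean and standard deviation of AUC across repeats.
    """
    params = params or FvtldaParams()
    plan = plan or CvPlan()
    known = [(int(i), int(j)) for i, j in zip(*np.nonzero(ld.values))]
    if plan.k > len(known):
        raise ValueError(f"k={plan.k} exceeds the {len(known)} known associations")
    results: list[RocResult] = []
    repeat_seeds = np.random.SeedSequence(plan.seed).generate_state(plan.repeats)
    for rep in range(plan.repeats):
        rng = np.random.default_rng(repeat_seeds[rep])
        order = rng.permutation(len(known))
        folds = [
            [known[t] for t in order[f::plan.k]] for f in range(plan.k)
        ]
        u_values, fold_aucs = _holdout_evaluation(
            pair_feats, ld, ds_ld, params, folds, model_kind,
            int(repeat_seeds[rep] % (2 ** 31)), False,
        )
        u = np.asarray(u_values)
        results.append(
            RocResult(
                points=_roc_points(1.0 - u),
                auc=float(u.mean()),
                meta={
                    "scheme": "kfold", "k": plan.k, "repeat": rep,
                    "fold_aucs": fold_aucs, "model": model_kind,
                },
            )
        )
    return results


def summarize(results: Sequence[RocResult]) -> tuple[float, float]:
    """Mean and standard deviation of AUC across repeats."""
    aucs = np.array([r.auc for r in results])
    return float(aucs.mean()), float(aucs.std())


def roc_to_frame(result: RocResult) -> pd.DataFrame:
    return pd.DataFrame(result.points, columns=["fpr", "tpr"])
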