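"""End-to-end assembly: tables -> similarities -> features -> targets -> scores.

`build_pipeline_data` performs the full deterministic front half of the
method (everything before model fitting): registry construction, the
lncRNA-disease filter, the GIP and functional similarity matrices, the two
restart random walks and the per-pair feature tensor.  The fitted half
(train/score/case-study) lives in thin helpers so that cross-validation can
reuse the precomputed features.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .config import FvtldaParams
from .core_data import (
    AssociationTable,
    EntityRegistry,
    IncidenceMatrix,
    build_incidence,
    filter_ld_associations,
    read_association_table,
)
from .disease_ontology import MeshCodeTable, semantic_similarity_matrix
from .evaluation import CaseStudyReport, rank_candidates
from .models import AnnModel, MlrModel, fit_ann, fit_mlr, predict_ann, predict_mlr
from .rwr import FeatureMatrix, column_normalize_seeds, pair_feature_matrix, row_normalize, rwr
from .similarity import SimilarityMatrix, functional_similarity, gip_kernel
from .targets import TargetMatrix, target_matrix


@dataclass
class PipelineData:
    """All precomputed matrices of one dataset at one parameter setting."""

    mirnas: EntityRegistry
    md: IncidenceMatrix          # miRNA x disease (full disease universe)
    ml: IncidenceMatrix          # miRNA x lncRNA (full lncRNA universe)
    ld: IncidenceMatrix          # filtered lncRNA x disease universe
    ds_md: SimilarityMatrix
    ds_ld: SimilarityMatrix
    km: SimilarityMatrix
    fm: SimilarityMatrix
    fl: SimilarityMatrix
    pl: FeatureMatrix            # miRNA x lncRNA walk probabilities (LD lncRNAs)
    pd: FeatureMatrix            # miRNA x disease walk probabilities (LD diseases)
    pair_feats: np.ndarray       # (n_lncRNA_LD, n_disease_LD, n_miRNA)
    targets: TargetMatrix
    params: FvtldaParams


def build_pipeline_data(
    md_table: AssociationTable,
    ml_table: AssociationTable,
    ld_table: AssociationTable,
    mesh: MeshCodeTable,
    params: FvtldaParams | None = None,
    on_missing_codes: str = "error",
) -> PipelineData:
    """Run the deterministic front half of the pipeline on parsed tables."""
    params = params or FvtldaParams()

    # registries: miRNAs from both miRNA tables, diseases/lncRNAs per table
    mirna_names = list(dict.fromkeys(md_table.left_names() + ml_table.left_names()))
    mirnas = EntityRegistry("miRNA", mirna_names)
    diseases_md = EntityRegistry("disease", md_table.right_names())
    lncrnas_ml = EntityRegistry("lncRNA", ml_table.right_names())

    md = build_incidence(md_table, mirnas, diseases_md)
    ml = build_incidence(ml_table, mirnas, lncrnas_ml)

    ld_filtered, lnc_ld, dis_ld = filter_ld_associations(ld_table, lncrnas_ml, diseases_md)
    if not len(ld_filtered):
        raise ValueError("no lncRNA-disease associations survive the universe filter")
    ld = build_incidence(ld_filtered, lnc_ld, dis_ld)

    ds_md = semantic_similarity_matrix(
        diseases_md, mesh, delta=params.delta, on_missing=on_missing_codes
    )
    ds_ld = ds_md.submatrix(dis_ld.names)

    km = gip_kernel(ml, gamma_prime=params.gamma_prime)
    fm = functional_similarity(md, ds_md)
    fl = functional_similarity(ld, ds_ld)

    # lncRNA walks: seeds from ML, transitions from the GIP kernel
    pl_full = rwr(
        column_normalize_seeds(ml),
        row_normalize(km),
        params.rwr_lncrna(),
        row_labels=list(mirnas.names),
        col_labels=list(lncrnas_ml.names),
    )
    # disease walks: seeds from MD, transitions from the functional similarity
    pd_full = rwr(
        column_normalize_seeds(md),
        row_normalize(fm),
        params.rwr_disease(),
        row_labels=list(mirnas.names),
        col_labels=list(diseases_md.names),
    )
    lnc_cols = [lncrnas_ml.index_of(n) for n in lnc_ld.names]
    dis_cols = [diseases_md.index_of(n) for n in dis_ld.names]
    pl = FeatureMatrix(
        list(mirnas.names), list(lnc_ld.names), pl_full.values[:, lnc_cols],
        converged=pl_full.converged,
    )
    pd_ = FeatureMatrix(
        list(mirnas.names), list(dis_ld.names), pd_full.values[:, dis_cols],
        converged=pd_full.converged,
    )

    return PipelineData(
        mirnas=mirnas,
        md=md,
        ml=ml,
        ld=ld,
        ds_md=ds_md,
        ds_ld=ds_ld,
        km=km,
        fm=fm,
        fl=fl,
        pl=pl,
        pd=pd_,
        pair_feats=pair_feature_matrix(pl, pd_),
        targets=target_matrix(ld, fl, ds_ld, params.target_params()),
        params=params,
    )


def load_pipeline_data(
    data_dir: str | Path,
    params: FvtldaParams | None = None,
    on_missing_codes: str = "error",
) -> PipelineData:
    """Read md.tsv / ml.tsv / ld.tsv / mesh_codes.tsv from a directory."""
    data_dir = Path(data_dir)
    return build_pipeline_data(
        read_association_table(data_dir / "md.tsv"),
        read_association_table(data_dir / "ml.tsv"),
        read_association_table(data_dir / "ld.tsv"),
        MeshCodeTable.read_tsv(data_dir / "mesh_codes.tsv"),
        params=params,
        on_missing_codes=on_missing_codes,
    )


def train_model(
    data: PipelineData, model_kind: str = "mlr", seed: int = 0
) -> MlrModel | AnnModel:
    """Fit a scorer on all pairs with the full (unmasked) targets."""
    n_l, n_d, n_m = data.pair_feats.shape
    x = data.pair_feats.reshape(n_l * n_d, n_m)
    y = data.targets.values.ravel()
    if model_kind == "mlr":
        return fit_mlr(x, y)
    if model_kind == "ann":
        return fit_ann(x, y, cfg=data.params.ann, seed=seed)
    raise ValueError(f"unknown model kind {model_kind!r}")


def score_matrix(data: PipelineData, model: MlrModel | AnnModel) -> np.ndarray:
    """Score every (lncRNA, disease) pair; shape matches the LD matrix."""
    n_l, n_d, n_m = data.pair_feats.shape
    x = data.pair_feats.reshape(n_l * n_d, n_m)
    if isinstance(model, MlrModel):
        scores = predict_mlr(model, x)
    else:
        scores = predict_ann(model, x)
    return np.asarray(scores).reshape(n_l, n_d)


def case_study(
    data: PipelineData,
    disease: str,
    model_kind: str = "mlr",
    seed: int = 0,
    top: int | None = 10,
) -> CaseStudyReport:
    """Train on all known data and rank the unlinked lncRNAs for one disease."""
    model = train_model(data, model_kind=model_kind, seed=seed)
    scores = score_matrix(data, model)
    report = rank_candidates(scores, data.ld.cols.index_of(disease), data.ld)
    return report.top(top) if top is not None else report
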