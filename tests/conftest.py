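"""Shared fixtures: one study-scale paired synthetic dataset and one fitted
cross-modal model, computed once per session and reused by the heavier tests."""
from __future__ import annotations

import warnings
from types import SimpleNamespace

import pytest

import morpholink as ml


@pytest.fixture(scope="session")
def study():
    """Paired dataset under the shared-population study design (14
    populations x 200 cells per modality) with planted QC artifacts."""
    cfg = ml.SyntheticConfig(
        seed=1,
        artifact_spec=ml.ArtifactSpec(blur_fields=2, tiny=5, huge=5,
                                      dim_nucleus=5, density_outliers=5),
    )
    cp, expr, truth = ml.generate_paired_dataset(cfg)
    return SimpleNamespace(config=cfg, cp=cp, expr=expr, truth=truth)


@pytest.fixture(scope="session")
def xfit(study):
    """QC -> regularize -> select -> metacells -> lasso on the study dataset."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        filtered, report = ml.apply_qc(study.cp)
        reg, catalog = ml.regularize_features(
            filtered.feature_matrix(), families=study.truth.family_assignment)
        sel = ml.select_nonredundant_features(reg)
        mat = reg[sel.retained]
        common = ml.select_common_populations(filtered.cells, study.expr.meta)
        cp_mc = ml.build_metacells(mat, filtered.cells["population"], include=common, seed=5)
        ex_mc = ml.build_metacells(study.expr.matrix, study.expr.meta["population"],
                                   include=common, seed=6)
        model = ml.fit_lasso_crossmodal(ex_mc, cp_mc)
        gene_coeffs = ml.per_gene_linear_coefficients(ex_mc, cp_mc)
    return SimpleNamespace(
        filtered=filtered, qc_report=report, regularized=reg, catalog=catalog,
        selection=sel, matrix=mat, common=common,
        cp_mc=cp_mc, ex_mc=ex_mc, model=model, gene_coeffs=gene_coeffs,
    )
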