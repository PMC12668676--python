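"""Pipeline orchestration: qc -> regularize -> subsample -> select ->
cluster/modules -> metacells -> lasso -> predict -> annotate, with per-stage
output directories, a hash manifest, and resume from cached stage outputs."""
from __future__ import annotations

import hashlib
import json
import logging
import os
from pathlib import Path


import pandas as pd

from . import annotation, crossmodal, features, io, modules, qc, synthetic
from .config import PipelineConfig, StageError, logger

STAGE_ORDER = [
    "simulate", "qc", "regularize", "subsample", "select_features",
    "cluster_modules", "metacells", "lasso", "predict", "annotate",
]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _mark_done(stage_dir: Path) -> None:
    files = {
        str(p.relative_to(stage_dir)): _sha256(p)
        for p in sorted(stage_dir.rglob("*"))
        if p.is_file() and p.name != "_done.json"
    }
    with open(stage_dir / "_done.json", "w") as fh:
        json.dump({"files": files}, fh, indent=1, sort_keys=True)


def _is_done(stage_dir: Path) -> bool:
    return (stage_dir / "_done.json").exists()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages; returns the run directory.

    Completed stages (marked by ``_done.json``) are not recomputed; a
    toggled-off stage whose outputs a later stage needs raises a clear
    dependency error.
    """
    run_dir = Path(config.run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(run_dir / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s: %(message)s"))
    logger.addHandler(fh)
    try:
        with open(run_dir / "config.yaml", "w") as cfg_fh:
            import yaml
            yaml.safe_dump(config.model_dump(), cfg_fh, sort_keys=True)
        for stage in STAGE_ORDER:
            if stage not in config.stages:
                continue
            stage_dir = run_dir / stage
            if _is_done(stage_dir):
                logger.info("stage %s: cached, skipping", stage)
                continue
            stage_dir.mkdir(exist_ok=True)
            try:
                _STAGES[stage](config, run_dir, stage_dir)
            except Exception as exc:
                raise StageError(f"stage {stage!r} failed: {exc}") from exc
            _mark_done(stage_dir)
        manifest = {}
        for stage in STAGE_ORDER:
            done = run_dir / stage / "_done.json"
            if done.exists():
                with open(done) as mfh:
                    manifest[stage] = json.load(mfh)["files"]
        with open(run_dir / "manifest.json", "w") as mfh:
            json.dump(manifest, mfh, indent=1, sort_keys=True)
    finally:
        logger.removeHandler(fh)
        fh.close()
    return run_dir


def _need(run_dir: Path, stage: str, fname: str) -> Path:
    p = run_dir / stage / fname
    if not p.exists():
        raise StageError(f"missing upstream output {stage}/{fname}; run the {stage!r} stage first")
    return p


def _load_cells(run_dir: Path, stage: str) -> synthetic.CellFeatureTable:
    return io.read_feature_table(
        str(_need(run_dir, stage, "cells.csv")), str(_need(run_dir, stage, "fields.csv"))
    )


# --- stages ----------------------------------------------------------------

def _stage_simulate(config: PipelineConfig, run_dir: Path, out: Path) -> None:
    if config.simulate is not None:
        p = config.simulate
        cfg = synthetic.SyntheticConfig(
            n_lines_per_day=p.n_lines_per_day,
            cells_per_population=p.cells_per_population,
            n_genes=p.n_genes, n_features=p.n_features, n_programs=p.n_programs,
            link_density=p.link_density, noise_sd=p.noise_sd,
            n_redundant_pairs=p.n_redundant_pairs, n_module_blocks=p.n_module_blocks,
            artifact_spec=synthetic.ArtifactSpec(
                blur_fields=p.blur_fields, tiny=p.tiny, huge=p.huge,
                dim_nucleus=p.dim_nucleus, density_outliers=p.density_outliers,
            ),
            seed=p.seed,
        )
        cp, expr, truth = synthetic.generate_paired_dataset(cfg)
        io.write_ground_truth(truth, str(out / "ground_truth"))
    elif config.feature_table is not None:
        cp = io.read_feature_table(config.feature_table)
        expr = None
        if config.expression_dir is not None:
            m, genes, barcodes = io.read_expression_mtx(config.expression_dir)
            mat = pd.DataFrame(m.toarray(), index=barcodes, columns=genes)
            meta = pd.read_csv(os.path.join(config.expression_dir, "cell_meta.csv"), index_col=0)
            cc = (pd.read_csv(config.cellcycle_scores, index_col=0)
                  if config.cellcycle_scores else pd.DataFrame(index=mat.index))
            expr = synthetic.ExpressionTable(
                matrix=mat, meta=meta,
                s_score=cc.get("S", pd.Series(0.0, index=mat.index)),
                g2m_score=cc.get("G2M", pd.Series(0.0, index=mat.index)),
            )
    else:
        raise StageError("config provides neither simulate parameters nor a feature_table")
    io.write_feature_table(cp, str(out / "cells.csv"), str(out / "fields.csv"))
    if expr is not None:
        io.write_expression_table(expr, str(out / "expression"))


def _stage_qc(config: PipelineConfig, run_dir: Path, out: Path) -> None:
    table = _load_cells(run_dir, "simulate")
    filtered, report = qc.apply_qc(table, config.qc)
    io.write_feature_table(filtered, str(out / "cells.csv"), str(out / "fields.csv"))
    with open(out / "qc_report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=1, sort_keys=True)


def _stage_regularize(config: PipelineConfig, run_dir: Path, out: Path) -> None:
    table = _load_cells(run_dir, "qc")
    reg, catalog = features.regularize_features(
        table.feature_matrix(), scale_max=config.regularize.scale_max,
        logit_eps=config.regularize.logit_eps,
    )
    reg.rename_axis("cell_id").to_csv(out / "regularized.csv")
    catalog.to_csv(out / "catalog.tsv", sep="\t")
    table.cells[["field", "well", "plate", "line", "day", "population"]].rename_axis(
        "cell_id").to_csv(out / "meta.csv")


def _stage_subsample(config: PipelineConfig, run_dir: Path, out: Path) -> None:
    reg = pd.read_csv(_need(run_dir, "regularize", "regularized.csv"), index_col=0)
    meta = pd.read_csv(_need(run_dir, "regularize", "meta.csv"), index_col=0)
    sub = features.stratified_subsample(
        reg, meta["population"], max_per_pop=config.subsample.max_per_population,
        target_range=(config.subsample.target_min, config.subsample.target_max),
        seed=config.subsample.seed,
    )
    sub.rename_axis("cell_id").to_csv(out / "subsampled.csv")
    meta.loc[sub.index].rename_axis("cell_id").to_csv(out / "meta.csv")


def _stage_select(config: PipelineConfig, run_dir: Path, out: Path) -> None:
    sub = pd.read_csv(_need(run_dir, "subsample", "subsampled.csv"), index_col=0)
    sel = features.select_nonredundant_features(
        sub, r_threshold=config.select.r_threshold,
        exclusion_patterns=config.select.exclusion_patterns,
    )
    with open(out / "selection.json", "w") as fh:
        json.dump(sel.to_dict(), fh, indent=1, sort_keys=True)
    sub[sel.retained].rename_axis("cell_id").to_csv(out / "matrix.csv")


def _stage_cluster_modules(config: PipelineConfig, run_dir: Path, out: Path) -> None:
    mat = pd.read_csv(_need(run_dir, "select_features", "matrix.csv"), index_col=0)
    labels = modules.cluster_cells(
        mat, n_neighbors=config.cluster.n_neighbors,
        resolution=config.cluster.resolution, seed=config.cluster.seed,
    )
    keep = ~labels.labels.isin(config.cluster.excluded_clusters)
    labels.labels.rename("cluster").rename_axis("cell_id").to_csv(out / "clusters.tsv", sep="\t")
    emb = modules.embed_umap(mat, n_neighbors=config.cluster.n_neighbors, seed=config.cluster.seed)
    emb.rename_axis("cell_id").to_csv(out / "embedding.csv")
    mods = modules.detect_feature_modules(
        mat.loc[keep], k_range=(config.modules.k_min, config.modules.k_max),
        metric=config.modules.metric, k_override=config.modules.k_override,
    )
    with open(out / "modules.json", "w") as fh:
        json.dump(mods.to_dict(), fh, indent=1, sort_keys=True)
    modules.module_activation_scores(mat.loc[keep], mods).rename_axis("cell_id").to_csv(
        out / "activation.csv")


def _load_modules(run_dir: Path) -> modules.FeatureModuleSet:
    with open(_need(run_dir, "cluster_modules", "modules.json")) as fh:
        payload = json.load(fh)
    mods, loads, names = {}, {}, {}
    for mid_s, entry in payload["modules"].items():
        mid = int(mid_s)
        mods[mid] = entry["features"]
        loads[mid] = pd.Series(entry["pc1_loading"], index=entry["features"])
        names[mid] = entry["name"]
    return modules.FeatureModuleSet(modules=mods, loadings=loads, names=names,
                                    k_selected=payload["k_selected"],
                                    no_elbow=payload["no_elbow"])


def _load_expression(run_dir: Path) -> synthetic.ExpressionTable:
    d = str(_need(run_dir, "simulate", "expression/matrix.mtx").parent)
    m, genes, barcodes = io.read_expression_mtx(d)
    mat = pd.DataFrame(m.toarray(), index=barcodes, columns=genes)
    meta = pd.read_csv(os.path.join(d, "cell_meta.csv"), index_col=0)
    cc = pd.read_csv(os.path.join(d, "cellcycle_scores.csv"), index_col=0)
    return synthetic.ExpressionTable(matrix=mat, meta=meta,
                                     s_score=cc["S"], g2m_score=cc["G2M"])


def _stage_metacells(config: PipelineConfig, run_dir: Path, out: Path) -> None:
    mat = pd.read_csv(_need(run_dir, "select_features", "matrix.csv"), index_col=0)
    meta = pd.read_csv(_need(run_dir, "subsample", "meta.csv"), index_col=0)
    expr = _load_expression(run_dir)
    common = crossmodal.select_common_populations(meta, expr.meta)
    cp_mc = crossmodal.build_metacells(mat, meta["population"], include=common,
                                       k=config.crossmodal.n_metacells,
                                       seed=config.crossmodal.seed)
    ex_mc = crossmodal.build_metacells(expr.matrix, expr.meta["population"], include=common,
                                       k=config.crossmodal.n_metacells,
                                       seed=config.crossmodal.seed + 1)
    for name, mc in (("cp", cp_mc), ("expr", ex_mc)):
        mc.values.rename_axis("metacell").to_csv(out / f"{name}_metacells.csv")
        mc.meta.to_csv(out / f"{name}_metacell_meta.csv")
        with open(out / f"{name}_members.json", "w") as fh:
            json.dump({k: [str(x) for x in v] for k, v in mc.members.items()}, fh, sort_keys=True)


def _load_metacells(run_dir: Path, name: str) -> crossmodal.MetacellMatrix:
    values = pd.read_csv(_need(run_dir, "metacells", f"{name}_metacells.csv"), index_col=0)
    meta = pd.read_csv(_need(run_dir, "metacells", f"{name}_metacell_meta.csv"), index_col=0)
    with open(_need(run_dir, "metacells", f"{name}_members.json")) as fh:
        members = json.load(fh)
    return crossmodal.MetacellMatrix(values=values, meta=meta, members=members)


def _stage_lasso(config: PipelineConfig, run_dir: Path, out: Path) -> None:
    cp_mc = _load_metacells(run_dir, "cp")
    ex_mc = _load_metacells(run_dir, "expr")
    model = crossmodal.fit_lasso_crossmodal(
        ex_mc, cp_mc, alpha=config.crossmodal.alpha, max_iter=config.crossmodal.max_iter,
        tol=config.crossmodal.tol, standardize=config.crossmodal.standardize,
    )
    model.coef_frame().rename_axis("gene").to_csv(out / "coefficients.tsv", sep="\t")
    with open(out / "model.json", "w") as fh:
        json.dump({
            "alpha": model.alpha, "max_iter": model.max_iter, "tol": model.tol,
            "intercepts": {f: float(v) for f, v in model.intercept.items()},
            "cv_stats": {f: {"pearson_r": float(r.pearson_r), "r2": float(r.r2)}
                         for f, r in model.cv_stats.iterrows()},
        }, fh, indent=1, sort_keys=True)
    gc = crossmodal.per_gene_linear_coefficients(ex_mc, cp_mc)
    gc.slopes.rename_axis("gene").to_csv(out / "gene_coefficients.tsv", sep="\t")
    gc.intercepts.rename("intercept").rename_axis("feature").to_csv(
        out / "gene_coefficient_intercepts.tsv", sep="\t")
    mods = _load_modules(run_dir)
    ranks_dir = out / "module_gene_ranks"
    ranks_dir.mkdir(exist_ok=True)
    for mid, tbl in crossmodal.module_median_gene_ranks(gc, mods).items():
        tbl.rename_axis("gene").to_csv(ranks_dir / f"module_{mid}.rnk", sep="\t", header=False)


def _stage_predict(config: PipelineConfig, run_dir: Path, out: Path) -> None:
    coef = pd.read_csv(_need(run_dir, "lasso", "coefficients.tsv"), sep="\t", index_col=0)
    with open(_need(run_dir, "lasso", "model.json")) as fh:
        payload = json.load(fh)
    model = crossmodal.CrossModalModel(
        genes=list(coef.index), features=list(coef.columns), coef=coef.to_numpy(),
        intercept=pd.Series(payload["intercepts"]).reindex(coef.columns),
        cv_stats=pd.DataFrame(payload["cv_stats"]).T,
        alpha=payload["alpha"], max_iter=payload["max_iter"], tol=payload["tol"],
    )
    expr = _load_expression(run_dir)
    pred = crossmodal.predict_cp_features(expr.matrix, model)
    pred.rename_axis("cell_id").to_csv(out / "predicted_cp.csv")


def _stage_annotate(config: PipelineConfig, run_dir: Path, out: Path) -> None:
    pred = pd.read_csv(_need(run_dir, "predict", "predicted_cp.csv"), index_col=0)
    mat = pd.read_csv(_need(run_dir, "select_features", "matrix.csv"), index_col=0)
    meta = pd.read_csv(_need(run_dir, "subsample", "meta.csv"), index_col=0)
    labels = pd.read_csv(_need(run_dir, "cluster_modules", "clusters.tsv"),
                         sep="\t", index_col=0)["cluster"]
    expr = _load_expression(run_dir)

    cc_model = annotation.fit_cellcycle_transfer(
        pred, expr.s_score, expr.g2m_score, alpha=config.annotate.cellcycle_alpha)
    cc_model.predict(mat).rename_axis("cell_id").to_csv(out / "cellcycle_predicted.csv")

    ms_cp = annotation.marker_scores(mat, labels, method=config.annotate.marker_score)
    ms_pred = annotation.marker_scores(pred, expr.meta["population"],
                                       method=config.annotate.marker_score)
    ms_cp.rename_axis("group").to_csv(out / "marker_scores_cp.tsv", sep="\t")
    ms_pred.rename_axis("group").to_csv(out / "marker_scores_predicted.tsv", sep="\t")
    annotation.correlate_marker_scores(ms_cp, ms_pred).rename_axis("cp_cluster").to_csv(
        out / "marker_score_correlation.tsv", sep="\t")

    mods = _load_modules(run_dir)
    coef = pd.read_csv(_need(run_dir, "lasso", "coefficients.tsv"), sep="\t", index_col=0)
    with open(_need(run_dir, "lasso", "model.json")) as fh:
        payload = json.load(fh)
    model = crossmodal.CrossModalModel(
        genes=list(coef.index), features=list(coef.columns), coef=coef.to_numpy(),
        intercept=pd.Series(payload["intercepts"]).reindex(coef.columns),
        cv_stats=pd.DataFrame(payload["cv_stats"]).T,
        alpha=payload["alpha"], max_iter=payload["max_iter"], tol=payload["tol"],
    )
    reps = annotation.select_representative_features(mods, model)
    reps.to_csv(out / "representative_features.tsv", sep="\t")

    gc_slopes = pd.read_csv(_need(run_dir, "lasso", "gene_coefficients.tsv"),
                            sep="\t", index_col=0)
    gc_inter = pd.read_csv(_need(run_dir, "lasso", "gene_coefficient_intercepts.tsv"),
                           sep="\t", index_col=0)["intercept"]
    gc = crossmodal.GeneCoefficientMatrix(slopes=gc_slopes, intercepts=gc_inter)
    sets = {}
    for (mid, feat), row in reps[reps["selected"]].iterrows():
        mk = annotation.feature_marker_genes(gc, feat,
                                             sd_threshold=config.annotate.marker_sd_threshold)
        sets[f"{row['module_name']}|{feat}"] = (f"module {mid}", list(mk.index))
    io.write_gmt(sets, str(out / "marker_genes.gmt"))

    if meta["line"].nunique() >= 2 and labels.nunique() >= 2:
        or_table, ami, abundance = annotation.abundance_association(
            labels, meta["line"], strata=meta["day"])
        or_table.to_csv(out / "log2_odds_ratios.tsv", sep="\t")
        abundance.to_csv(out / "abundance.tsv", sep="\t")
        with open(out / "ami.json", "w") as fh:
            json.dump(ami, fh, indent=1, sort_keys=True)


_STAGES = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "regularize": _stage_regularize,
    "subsample": _stage_subsample,
    "select_features": _stage_select,
    "cluster_modules": _stage_cluster_modules,
    "metacells": _stage_metacells,
    "lasso": _stage_lasso,
    "predict": _stage_predict,
    "annotate": _stage_annotate,
}
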