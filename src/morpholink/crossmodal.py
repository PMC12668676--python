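"""Metacell construction and cross-modality lasso prediction of morphology
features from gene expression.

Cells of the experimental populations shared by both modalities are randomly
split into three metacells per population per modality and mean-aggregated,
giving two aligned matrices (42 metacells for the default 14-population
design).  Per morphology feature, an L1-penalized regression (alpha = 0.02,
max_iter = 10,000) is trained on two metacells per population, with the third
held out for cross-validation.  A companion dense genes x features matrix of
simple univariate regression slopes provides one value per gene for ranking
and enrichment input; per-module gene rankings are medians of those slopes
over the module's features.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso

from .config import ConfigurationError, logger
from .modules import FeatureModuleSet


def select_common_populations(cp_meta: pd.DataFrame, expr_meta: pd.DataFrame) -> list[str]:
    """Sorted intersection of the experimental-population sets."""
    for name, meta in (("morphology", cp_meta), ("expression", expr_meta)):
        if "population" not in meta.columns:
            raise ConfigurationError(f"{name} metadata lacks a 'population' column")
    common = sorted(set(cp_meta["population"]) & set(expr_meta["population"]))
    if not common:
        raise ConfigurationError("no common experimental populations between modalities")
    return common


@dataclass
class MetacellMatrix:
    """Mean-aggregated metacells: values plus (population, replicate, role)."""

    values: pd.DataFrame                  # metacell id x (genes or features)
    meta: pd.DataFrame                    # population, replicate (1..k), role
    members: dict[str, list]              # metacell id -> member cell ids

    def rows(self, role: str) -> pd.DataFrame:
        return self.values.loc[self.meta.index[self.meta["role"] == role]]


def build_metacells(
    matrix: pd.DataFrame,
    populations: pd.Series,
    include: list[str] | None = None,
    k: int = 3,
    seed: int = 0,
) -> MetacellMatrix:
    """Randomly assign each population's cells to ``k`` balanced metacells and
    mean-aggregate; one seeded-random replicate per population (index k) is
    marked for cross-validation."""
    pops = populations.reindex(matrix.index)
    targets = sorted(include) if include is not None else sorted(pops.dropna().unique())
    rng = np.random.default_rng(seed)
    rows, metas, members = [], [], {}
    for pop in targets:
        ids = matrix.index[pops == pop].to_numpy()
        if len(ids) < k:
            raise ConfigurationError(f"population {pop!r} has {len(ids)} cells; needs >= {k}")
        perm = rng.permutation(ids)
        groups = np.array_split(perm, k)
        # which group carries replicate index k (the validation replicate)
        rep_of_group = rng.permutation(np.arange(1, k + 1))
        for g, grp in enumerate(groups):
            rep = int(rep_of_group[g])
            mc_id = f"{pop}|r{rep}"
            rows.append(matrix.loc[grp].mean(axis=0).rename(mc_id))
            metas.append({"metacell": mc_id, "population": pop, "replicate": rep,
                          "role": "validation" if rep == k else "train"})
            members[mc_id] = list(grp)
    values = pd.DataFrame(rows)
    meta = pd.DataFrame(metas).set_index("metacell")
    order = meta.sort_values(["population", "replicate"]).index
    return MetacellMatrix(values=values.loc[order], meta=meta.loc[order], members=members)


@dataclass
class CrossModalModel:
    """Per-feature intercept and sparse gene coefficients with CV statistics."""

    genes: list[str]
    features: list[str]
    coef: np.ndarray                      # genes x features
    intercept: pd.Series                  # per feature
    cv_stats: pd.DataFrame                # per feature: pearson_r, r2
    alpha: float = 0.02
    max_iter: int = 10000
    tol: float = 1e-4

    def coef_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.coef, index=self.genes, columns=self.features)


def _align(expr_mc: MetacellMatrix, cp_mc: MetacellMatrix) -> pd.Index:
    a = expr_mc.meta[["population", "replicate", "role"]]
    b = cp_mc.meta[["population", "replicate", "role"]]
    if not a.reset_index(drop=True).equals(b.reset_index(drop=True)):
        raise ConfigurationError("metacell matrices are not aligned by (population, replicate)")
    return expr_mc.meta.index


def fit_lasso_crossmodal(
    expr_mc: MetacellMatrix,
    cp_mc: MetacellMatrix,
    alpha: float = 0.02,
    max_iter: int = 10000,
    tol: float = 1e-4,
    standardize: bool = False,
) -> CrossModalModel:
    """One lasso fit per morphology feature on the training metacells
    (objective (1/2n)*sum(residual^2) + alpha*sum(|beta|)); validation
    metacells never touch the fit and provide per-feature Pearson r and R2.

    ``alpha = 0`` falls back to ordinary least squares via the normal
    equations (minimum-norm solution when rank-deficient).
    """
    _align(expr_mc, cp_mc)
    train_idx = expr_mc.meta.index[expr_mc.meta["role"] == "train"]
    val_idx = expr_mc.meta.index[expr_mc.meta["role"] == "validation"]
    if len(train_idx) < 2:
        raise ConfigurationError("need >= 2 training metacells")
    X = expr_mc.values.loc[train_idx].to_numpy(dtype=float)
    Y = cp_mc.values.loc[train_idx].to_numpy(dtype=float)
    if not (np.isfinite(X).all() and np.isfinite(Y).all()):
        raise ConfigurationError("non-finite values in metacell matrices")
    mu, sd = X.mean(axis=0), X.std(axis=0)
    if standardize:
        sd_safe = np.where(sd > 0, sd, 1.0)
        X = (X - mu) / sd_safe

    if alpha == 0:
        Xi = np.column_stack([np.ones(len(X)), X])
        beta, *_ = np.linalg.lstsq(Xi, Y, rcond=None)
        intercept, coef = beta[0], beta[1:]
    else:
        model = Lasso(alpha=alpha, max_iter=max_iter, tol=tol, precompute=True)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            model.fit(X, Y)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            warnings.warn(f"lasso did not fully converge within max_iter={max_iter}")
        coef = model.coef_.T.reshape(X.shape[1], -1)
        intercept = np.atleast_1d(model.intercept_)
    if standardize:
        coef = coef / np.where(sd > 0, sd, 1.0)[:, None]
        intercept = intercept - mu @ coef

    features = list(cp_mc.values.columns)
    genes = list(expr_mc.values.columns)
    Xv = expr_mc.values.loc[val_idx].to_numpy(dtype=float)
    Yv = cp_mc.values.loc[val_idx].to_numpy(dtype=float)
    pred = intercept + Xv @ coef
    stats_rows = []
    for j, f in enumerate(features):
        y, p = Yv[:, j], pred[:, j]
        if y.std() == 0 or p.std() == 0:
            r = 0.0
        else:
            r = float(np.corrcoef(y, p)[0, 1])
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - float(((y - p) ** 2).sum()) / ss_tot if ss_tot > 0 else 0.0
        stats_rows.append({"feature": f, "pearson_r": r, "r2": r2})
    cv = pd.DataFrame(stats_rows).set_index("feature")
    logger.info("lasso: %d features, median validation r = %.3f",
                len(features), cv["pearson_r"].median())
    return CrossModalModel(
        genes=genes, features=features, coef=np.asarray(coef, dtype=float),
        intercept=pd.Series(np.asarray(intercept, dtype=float), index=features),
        cv_stats=cv, alpha=alpha, max_iter=max_iter, tol=tol,
    )


def predict_cp_features(expr_matrix: pd.DataFrame, model: CrossModalModel) -> pd.DataFrame:
    """Per-cell predicted morphology features: beta0 + X @ beta."""
    missing = [g for g in model.genes if g not in expr_matrix.columns]
    if missing:
        raise ConfigurationError(
            f"expression matrix lacks {len(missing)} model genes, e.g. {missing[:5]}"
        )
    X = expr_matrix[model.genes].to_numpy(dtype=float)
    pred = model.intercept.to_numpy() + X @ model.coef
    return pd.DataFrame(pred, index=expr_matrix.index, columns=model.features)


@dataclass
class GeneCoefficientMatrix:
    """Dense genes x features univariate regression slopes (one value per gene)."""

    slopes: pd.DataFrame                  # genes x features
    intercepts: pd.Series                 # per feature (response mean)
    zero_variance_genes: list[str] = field(default_factory=list)


def per_gene_linear_coefficients(
    expr_mc: MetacellMatrix, cp_mc: MetacellMatrix
) -> GeneCoefficientMatrix:
    """Simple per-gene regression slope cov(x_g, y_f)/var(x_g) on all
    metacells, for every (gene, feature) pair; zero-variance genes get slope
    0 and are flagged."""
    idx = _align(expr_mc, cp_mc)
    if len(idx) < 3:
        raise ConfigurationError("need >= 3 metacells for per-gene regressions")
    X = expr_mc.values.loc[idx].to_numpy(dtype=float)
    Y = cp_mc.values.loc[idx].to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    ss = (Xc ** 2).sum(axis=0)
    zero = ss == 0
    ss_safe = np.where(zero, 1.0, ss)
    slopes = (Xc.T @ Yc) / ss_safe[:, None]
    slopes[zero, :] = 0.0
    genes = list(expr_mc.values.columns)
    return GeneCoefficientMatrix(
        slopes=pd.DataFrame(slopes, index=genes, columns=cp_mc.values.columns),
        intercepts=pd.Series(Y.mean(axis=0), index=cp_mc.values.columns),
        zero_variance_genes=[g for g, z in zip(genes, zero) if z],
    )


def module_median_gene_ranks(
    coeffs: GeneCoefficientMatrix, modules: FeatureModuleSet
) -> dict[int, pd.DataFrame]:
    """Per module: each gene's median slope across the module's features,
    sorted descending (stable tie-break by gene name) — the ranked input for
    pre-ranked gene-set enrichment."""
    out = {}
    for mid, members in modules.modules.items():
        if not members:
            raise ConfigurationError(f"module {mid} is empty")
        missing = [f for f in members if f not in coeffs.slopes.columns]
        if missing:
            raise ConfigurationError(f"module {mid} features missing from coefficients: {missing[:5]}")
        med = coeffs.slopes[members].median(axis=1)
        tbl = med.rename("median_coefficient").to_frame()
        tbl = tbl.sort_index().sort_values("median_coefficient", ascending=False, kind="stable")
        out[mid] = tbl
    return out


def support_recovery_auroc(
    slopes: pd.DataFrame,
    true_w: pd.DataFrame,
    gene_sd: pd.Series | None = None,
    feature_sd: pd.Series | None = None,
) -> float:
    """AUROC of ranking (gene, feature) pairs by |coefficient| against the
    planted nonzero entries of the true weight matrix.

    When gene and feature standard deviations are supplied, coefficients are
    standardized (slope * sd_gene / sd_feature, i.e. the gene-feature Pearson
    correlation): raw slopes of near-constant genes are variance-inflated and
    make a pooled ranking meaningless.
    """
    from sklearn.metrics import roc_auc_score

    common_g = slopes.index.intersection(true_w.index)
    common_f = slopes.columns.intersection(true_w.columns)
    s = slopes.loc[common_g, common_f]
    if gene_sd is not None:
        s = s.mul(gene_sd.reindex(common_g), axis=0)
    if feature_sd is not None:
        s = s.div(feature_sd.reindex(common_f).replace(0.0, np.nan), axis=1).fillna(0.0)
    score = np.abs(s.to_numpy()).ravel()
    label = (true_w.loc[common_g, common_f].to_numpy() != 0).ravel().astype(int)
    if label.min() == label.max():
        raise ConfigurationError("true weight matrix has no class contrast")
    return float(roc_auc_score(label, score))


def permutation_null_cv(
    expr_mc: MetacellMatrix,
    cp_mc: MetacellMatrix,
    n_permutations: int = 3,
    n_features: int | None = 50,
    seed: int = 0,
    **lasso_kwargs,
) -> np.ndarray:
    """Negative control: refit the lasso after permuting the expression
    metacell rows (destroying the population correspondence between the
    modalities) and pool per-feature validation Pearson r over permutations.

    ``n_features`` caps the response features per permutation (seeded random
    subset) to keep the control affordable; None uses all features.
    """
    rng = np.random.default_rng(seed)
    rs = []
    feats = list(cp_mc.values.columns)
    for _ in range(n_permutations):
        vals = expr_mc.values.copy()
        vals[:] = vals.to_numpy()[rng.permutation(len(vals))]
        shuffled = MetacellMatrix(values=vals, meta=expr_mc.meta, members={})
        sub = feats
        if n_features is not None and n_features < len(feats):
            sub = list(rng.choice(feats, size=n_features, replace=False))
        cp_sub = MetacellMatrix(values=cp_mc.values[sub], meta=cp_mc.meta, members={})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = fit_lasso_crossmodal(shuffled, cp_sub, **lasso_kwargs)
        rs.extend(m.cv_stats["pearson_r"].tolist())
    return np.asarray(rs)
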