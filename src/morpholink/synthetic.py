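"""Synthetic paired morphology/expression data with planted ground truth.

The generator emulates the experimental design the analysis assumes: a set of
experimental populations (cell line x differentiation day, by default 6 lines
at day 20 and 4 lines at days 40 and 70, i.e. 14 populations shared across
modalities), a sparse latent-program model linearly linking genes to
morphology features, the six feature-distribution families on their raw
(pre-regularization) scales, near-duplicate redundant features, correlated
feature blocks, and unambiguous planted QC artifacts (blurry fields,
tiny/huge cells, dim nuclei, density outliers).

The latent model: each cell carries a program-activation vector
``state = population_mean + perturbation``; genes load sparsely on programs;
features are linear in programs.  The induced gene x feature weight matrix
``W = L @ A`` is returned as ground truth.  Raw feature values are the latent
linear values pushed through the *inverse* of the per-family regularization
transform, so regularization is testable by round trip.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional

import numpy as np
import pandas as pd

from .config import ConfigurationError, QC_CHANNELS

CELLS_PER_FIELD = 20
ARTIFACT_KINDS = ("blur", "tiny", "huge", "dim_nucleus", "density_outlier")

#: channel cycle used when naming synthetic features
_CHANNELS = ("nucleus", "er", "mito", "cgan")
_CLASSES = ("Intensity", "Texture", "AreaShape", "Neighbors", "Granularity", "RadialDistribution")
_COMPARTMENTS = ("Cell", "Nuclei", "Cytoplasm")


@dataclass
class ArtifactSpec:
    """Counts of planted QC artifacts."""

    blur_fields: int = 0
    tiny: int = 0
    huge: int = 0
    dim_nucleus: int = 0
    density_outliers: int = 0

    def total_cells(self) -> int:
        return self.tiny + self.huge + self.dim_nucleus + self.density_outliers

    def validate(self) -> None:
        for name in ("blur_fields", "tiny", "huge", "dim_nucleus", "density_outliers"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"artifact count {name!r} must be >= 0")


@dataclass
class SyntheticConfig:
    """Generator settings; defaults are the shared-population study design."""

    n_lines_per_day: Mapping[int, int] = field(default_factory=lambda: {20: 6, 40: 4, 70: 4})
    cells_per_population: int = 200
    n_genes: int = 2000
    n_features: int = 300
    n_programs: int = 10
    link_density: float = 0.005
    noise_sd: float = 0.1
    n_redundant_pairs: int = 10
    n_module_blocks: int = 3
    family_assignment: Optional[Mapping[str, int]] = None
    artifact_spec: ArtifactSpec = field(default_factory=ArtifactSpec)
    seed: int = 0
    #: between-cell spread of program activations within a population
    state_sd: float = 0.3

    def validate(self) -> None:
        if self.cells_per_population < 3:
            raise ConfigurationError("cells_per_population must be >= 3 (metacells need 3 cells)")
        for name in ("n_genes", "n_features", "n_redundant_pairs", "n_module_blocks", "n_programs"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not (0 <= self.link_density <= 1):
            raise ConfigurationError("link_density must be in [0, 1]")
        if self.n_features < self.n_module_blocks:
            raise ConfigurationError("n_features must be >= n_module_blocks")
        if self.n_redundant_pairs * 2 > self.n_features:
            raise ConfigurationError("too many redundant pairs for n_features")
        self.artifact_spec.validate()

    @property
    def populations(self) -> list[str]:
        pops = []
        for day in sorted(self.n_lines_per_day):
            for i in range(self.n_lines_per_day[day]):
                pops.append(f"line{i + 1}_d{day}")
        return pops


@dataclass
class CellFeatureTable:
    """Cells x features with per-cell metadata and per-field image QC."""

    cells: pd.DataFrame          # index: cell id; metadata + QC columns + features
    fields: pd.DataFrame         # index: field id; slope_<channel> x4 + cellprofiler_blur_flag
    feature_cols: list[str]

    def feature_matrix(self) -> pd.DataFrame:
        return self.cells[self.feature_cols]


@dataclass
class ExpressionTable:
    """Cells x genes log-normalized-scale values plus cell-cycle scores."""

    matrix: pd.DataFrame         # dense cells x genes
    meta: pd.DataFrame           # population, line, day per cell
    s_score: pd.Series
    g2m_score: pd.Series


@dataclass
class SyntheticGroundTruth:
    """Everything planted, for parameter-recovery tests."""

    W: pd.DataFrame                                  # genes x features true weights
    module_blocks: dict[str, int]                    # feature -> planted block id
    redundant_pairs: list[tuple[str, str]]           # (source, duplicate)
    artifact_flags: pd.Series                        # cp cell -> flag ("clean" or kind)
    true_state: dict[str, pd.DataFrame]              # modality -> cells x programs
    true_cycle: dict[str, pd.DataFrame]              # modality -> cells x [S, G2M]
    latent_features: dict[str, pd.DataFrame]         # modality -> pre-distortion values
    family_assignment: dict[str, int]
    cycle_weights: pd.DataFrame                      # programs x [S, G2M]


# ---------------------------------------------------------------------------
# Family distortions: the inverse of the regularization transforms
# ---------------------------------------------------------------------------

_LOG_OFFSET = 6.0  # keeps intensity-like raw values positive for typical latents


def family_distortion(family: int) -> Callable[[np.ndarray], np.ndarray]:
    """Raw-scale distortion applied to latent linear values, per family."""
    if family in (1, 2):
        def f(y):
            x = np.exp2(y + _LOG_OFFSET) - 1.0
            return np.rint(np.clip(x, 0, None)) if family == 2 else x
        return f
    if family == 3:
        return lambda y: 1.0 / (1.0 + np.exp(-y))
    if family == 4:
        return lambda y: y
    if family == 5:
        return lambda y: np.sign(y) * (np.exp2(np.abs(y)) - 1.0)
    if family == 6:
        return np.sinh
    raise ConfigurationError(f"unknown family {family}")


def invert_family_distortion(x: np.ndarray, family: int) -> np.ndarray:
    """Recover latent linear values from raw feature values (exact except the
    count family, where rounding is irreversible)."""
    x = np.asarray(x, dtype=float)
    if family in (1, 2):
        return np.log2(x + 1.0) - _LOG_OFFSET
    if family == 3:
        return np.log(x / (1.0 - x))
    if family == 4:
        return x
    if family == 5:
        return np.sign(x) * np.log2(1.0 + np.abs(x))
    if family == 6:
        return np.arcsinh(x)
    raise ConfigurationError(f"unknown family {family}")


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _feature_names(n: int) -> list[str]:
    names = []
    for i in range(n):
        comp = _COMPARTMENTS[i % len(_COMPARTMENTS)]
        cls = _CLASSES[(i // 3) % len(_CLASSES)]
        chan = _CHANNELS[(i // 18) % len(_CHANNELS)]
        names.append(f"{comp}_{cls}_Stat{i:04d}_{chan}")
    return names


def _population_meta(config: SyntheticConfig) -> pd.DataFrame:
    rows = []
    for day in sorted(config.n_lines_per_day):
        for i in range(config.n_lines_per_day[day]):
            rows.append({"population": f"line{i + 1}_d{day}", "line": f"line{i + 1}", "day": day})
    return pd.DataFrame(rows).set_index("population")


def _simulate_modality(config: SyntheticConfig, pop_means: np.ndarray, rng: np.random.Generator,
                       prefix: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell program states for one modality; returns (state df, meta df)."""
    popmeta = _population_meta(config)
    n_per = config.cells_per_population
    states, metas, ids = [], [], []
    for pi, pop in enumerate(popmeta.index):
        st = pop_means[pi] + rng.normal(0.0, config.state_sd,
                                        size=(n_per, max(config.n_programs, 1)))
        if config.n_programs == 0:
            st = np.zeros((n_per, 0))
        states.append(st)
        for j in range(n_per):
            ids.append(f"{prefix}_{pop}_c{j:04d}")
            metas.append({"population": pop, "line": popmeta.loc[pop, "line"],
                          "day": int(popmeta.loc[pop, "day"])})
    state = pd.DataFrame(np.vstack(states) if states else np.zeros((0, config.n_programs)),
                         index=ids,
                         columns=[f"program{p}" for p in range(config.n_programs)]
                         if config.n_programs else [])
    meta = pd.DataFrame(metas, index=ids)
    return state, meta


def generate_paired_dataset(
    config: SyntheticConfig,
) -> tuple[CellFeatureTable, ExpressionTable, SyntheticGroundTruth]:
    """Generate paired morphology/expression tables plus complete ground truth.

    Deterministic given ``config.seed``: one named pseudo-random stream drives
    every draw.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_prog = config.n_programs
    feat_names = _feature_names(config.n_features)
    gene_names = [f"gene{g:05d}" for g in range(config.n_genes)]

    # --- latent design -----------------------------------------------------
    n_pops = len(config.populations)
    pop_means = rng.normal(0.0, 1.0, size=(n_pops, max(n_prog, 1)))

    # gene loadings: each program recruits ~link_density * n_genes genes
    L = np.zeros((config.n_genes, n_prog))
    genes_per_prog = max(1, round(config.link_density * config.n_genes)) if n_prog else 0
    for p in range(n_prog):
        idx = rng.choice(config.n_genes, size=min(genes_per_prog, config.n_genes), replace=False)
        L[idx, p] = rng.uniform(0.5, 1.5, size=len(idx)) * rng.choice([-1.0, 1.0], size=len(idx))

    # feature loadings: block-structured (planted modules), plus a weaker
    # per-feature secondary program so block members are correlated but never
    # near-duplicates
    n_dup = config.n_redundant_pairs
    n_base = config.n_features - n_dup
    A = np.zeros((n_prog, config.n_features))
    module_blocks: dict[str, int] = {}
    if n_prog:
        for f in range(n_base):
            block = f % config.n_module_blocks
            module_blocks[feat_names[f]] = block
            dominant = block % n_prog
            A[dominant, f] = rng.uniform(0.6, 1.0) * (1 if rng.random() < 0.9 else -1)
            if n_prog > 1:
                others = [p for p in range(n_prog) if p != dominant]
                sec = rng.choice(others)
                A[sec, f] = rng.uniform(0.3, 0.6) * rng.choice([-1.0, 1.0])
    else:
        for f in range(n_base):
            module_blocks[feat_names[f]] = f % config.n_module_blocks

    # redundant duplicates: last n_dup features copy a random base feature
    redundant_pairs: list[tuple[str, str]] = []
    dup_source = rng.choice(max(n_base, 1), size=n_dup, replace=False) if n_dup else np.array([], int)
    new_names = list(feat_names)
    for k, src in enumerate(dup_source):
        fi = n_base + k
        A[:, fi] = A[:, src]
        new_names[fi] = feat_names[src] + "_Dup"
        module_blocks[new_names[fi]] = module_blocks[feat_names[src]]
        redundant_pairs.append((feat_names[src], new_names[fi]))
    feat_names = new_names

    # family assignment: cycle the six families; duplicates inherit the source
    if config.family_assignment is not None:
        families = dict(config.family_assignment)
    else:
        families = {feat_names[f]: (f % 6) + 1 for f in range(n_base)}
        for k, src in enumerate(dup_source):
            families[feat_names[n_base + k]] = families[feat_names[src]]

    # cell-cycle scores are linear in programs (hence linear in features)
    cyc_w = rng.normal(0.0, 1.0, size=(max(n_prog, 1), 2))
    if n_prog == 0:
        cyc_w = np.zeros((0, 2))
    cycle_weights = pd.DataFrame(cyc_w, columns=["S", "G2M"],
                                 index=[f"program{p}" for p in range(n_prog)])

    # --- per-modality cells ------------------------------------------------
    tables: dict[str, dict] = {}
    for prefix in ("cp", "rna"):
        state, meta = _simulate_modality(config, pop_means, rng, prefix)
        sarr = state.to_numpy() if n_prog else np.zeros((len(meta), 0))
        latent = sarr @ A + rng.normal(0.0, config.noise_sd, size=(len(meta), config.n_features))
        # duplicates: tiny jitter on the source latent value -> r > 0.99
        for k, src in enumerate(dup_source):
            fi = n_base + k
            sd = max(latent[:, src].std(), 1e-12)
            latent[:, fi] = latent[:, src] + rng.normal(0.0, 0.03 * sd, size=len(meta))
        cyc = sarr @ cyc_w + rng.normal(0.0, 0.05, size=(len(meta), 2))
        tables[prefix] = {"state": state, "meta": meta, "latent": latent, "cycle": cyc}

    # --- morphology modality: distort, add QC metadata and fields ----------
    cp = tables["cp"]
    n_cp = len(cp["meta"])
    raw = np.empty_like(cp["latent"])
    for f, name in enumerate(feat_names):
        raw[:, f] = family_distortion(families[name])(cp["latent"][:, f])
    cells = pd.DataFrame(raw, index=cp["meta"].index, columns=feat_names)

    # clean QC metadata, comfortably inside every filter
    cells.insert(0, "cytoplasm_area", rng.uniform(20000, 60000, n_cp))
    cells.insert(1, "nucleus_area", rng.uniform(15000, 40000, n_cp))
    cells.insert(2, "nucleus_intensity", rng.uniform(0.05, 0.5, n_cp))
    cells.insert(3, "er_intensity", rng.uniform(0.05, 0.5, n_cp))
    cells.insert(4, "mito_intensity", rng.uniform(0.05, 0.5, n_cp))
    cells.insert(5, "cgan_intensity", rng.uniform(0.05, 0.5, n_cp))

    meta = cp["meta"].copy()
    pops = sorted(meta["population"].unique())
    well_of = {p: f"{chr(65 + i // 12)}{i % 12 + 1:02d}" for i, p in enumerate(pops)}
    field_ids = []
    for pop in pops:
        members = meta.index[meta["population"] == pop]
        for j, cid in enumerate(members):
            field_ids.append((cid, f"{well_of[pop]}_f{j // CELLS_PER_FIELD + 1:02d}"))
    fid = pd.Series(dict(field_ids))
    meta["field"] = fid.reindex(meta.index)
    meta["well"] = meta["population"].map(well_of)
    meta["plate"] = "plate1"
    cells = pd.concat([meta[["field", "well", "plate", "line", "day", "population"]], cells], axis=1)

    uniq_fields = sorted(cells["field"].unique())
    fields = pd.DataFrame(
        {f"slope_{ch}": rng.normal(-1.5, 0.1, len(uniq_fields)) for ch in QC_CHANNELS},
        index=pd.Index(uniq_fields, name="field"),
    )
    fields["cellprofiler_blur_flag"] = False

    cp_table = CellFeatureTable(cells=cells, fields=fields, feature_cols=feat_names)

    # --- expression modality ----------------------------------------------
    rna = tables["rna"]
    sarr = rna["state"].to_numpy() if n_prog else np.zeros((len(rna["meta"]), 0))
    baseline = rng.uniform(0.1, 2.0, size=config.n_genes)
    expr = baseline + sarr @ L.T + rng.normal(0.0, config.noise_sd,
                                              size=(len(rna["meta"]), config.n_genes))
    expr_df = pd.DataFrame(expr, index=rna["meta"].index, columns=gene_names)
    expr_table = ExpressionTable(
        matrix=expr_df,
        meta=rna["meta"][["population", "line", "day"]],
        s_score=pd.Series(rna["cycle"][:, 0], index=rna["meta"].index, name="S"),
        g2m_score=pd.Series(rna["cycle"][:, 1], index=rna["meta"].index, name="G2M"),
    )

    truth = SyntheticGroundTruth(
        W=pd.DataFrame(L @ A if n_prog else np.zeros((config.n_genes, config.n_features)),
                       index=gene_names, columns=feat_names),
        module_blocks=module_blocks,
        redundant_pairs=redundant_pairs,
        artifact_flags=pd.Series("clean", index=cells.index, name="artifact"),
        true_state={"cp": cp["state"], "rna": rna["state"]},
        true_cycle={
            m: pd.DataFrame(tables[m]["cycle"], index=tables[m]["meta"].index,
                            columns=["S", "G2M"])
            for m in ("cp", "rna")
        },
        latent_features={
            m: pd.DataFrame(tables[m]["latent"], index=tables[m]["meta"].index,
                            columns=feat_names)
            for m in ("cp", "rna")
        },
        family_assignment=families,
        cycle_weights=cycle_weights,
    )

    # plant artifacts last so clean statistics are untouched elsewhere
    cp_table, truth = plant_qc_artifacts(cp_table, config.artifact_spec,
                                         seed=rng.integers(2**31), truth=truth)
    return cp_table, expr_table, truth


def plant_qc_artifacts(
    table: CellFeatureTable,
    spec: ArtifactSpec,
    seed: int,
    truth: Optional[SyntheticGroundTruth] = None,
) -> tuple[CellFeatureTable, SyntheticGroundTruth]:
    """Plant unambiguous QC violations into a cell table.

    Blurry fields get channel slopes of -3.0 (mean well below -2.16); tiny and
    huge cells get cytoplasm areas in (0, 1000] and [100000, 150000]; dim
    nuclei get intensity in (0, 0.003]; density outliers are moved far from
    the data cloud in the (nucleus intensity, summed other intensities) plane.
    Artifact kinds never overlap on a cell.
    """
    spec.validate()
    if len(table.cells) == 0:
        raise ConfigurationError("cannot plant artifacts in an empty table")
    rng = np.random.default_rng(seed)
    cells = table.cells.copy()
    fields = table.fields.copy()
    flags = (truth.artifact_flags.copy() if truth is not None
             else pd.Series("clean", index=cells.index, name="artifact"))

    if spec.blur_fields > len(fields):
        raise ConfigurationError("more blurry fields requested than fields available")
    blur_fields = list(rng.choice(fields.index.to_numpy(), size=spec.blur_fields, replace=False))
    for f in blur_fields:
        for ch in QC_CHANNELS:
            fields.loc[f, f"slope_{ch}"] = -3.0
    blurred_cells = cells.index[cells["field"].isin(blur_fields)]
    flags.loc[blurred_cells] = "blur"

    pool = cells.index[flags == "clean"].to_numpy()
    need = spec.total_cells()
    if need > len(pool):
        raise ConfigurationError(f"requested {need} artifact cells but only {len(pool)} available")
    picked = rng.choice(pool, size=need, replace=False)
    cursor = 0

    def take(n):
        nonlocal cursor
        sel = picked[cursor:cursor + n]
        cursor += n
        return sel

    tiny = take(spec.tiny)
    cells.loc[tiny, "cytoplasm_area"] = rng.uniform(1.0, 1000.0, size=len(tiny))
    flags.loc[tiny] = "tiny"

    huge = take(spec.huge)
    cells.loc[huge, "cytoplasm_area"] = rng.uniform(100000.0, 150000.0, size=len(huge))
    flags.loc[huge] = "huge"

    dim = take(spec.dim_nucleus)
    cells.loc[dim, "nucleus_intensity"] = rng.uniform(1e-4, 0.003, size=len(dim))
    flags.loc[dim] = "dim_nucleus"

    # density outliers are spaced >= 10 units apart so each sits alone in its
    # kernel box regardless of how many are planted
    dens = take(spec.density_outliers)
    offsets = 10.0 * np.arange(len(dens))
    cells.loc[dens, "nucleus_intensity"] = 50.0 + offsets + rng.uniform(0.0, 1.0, size=len(dens))
    for col in ("er_intensity", "mito_intensity", "cgan_intensity"):
        cells.loc[dens, col] = 50.0 + offsets + rng.uniform(0.0, 1.0, size=len(dens))
    flags.loc[dens] = "density_outlier"

    out = CellFeatureTable(cells=cells, fields=fields, feature_cols=list(table.feature_cols))
    if truth is None:
        truth = SyntheticGroundTruth(
            W=pd.DataFrame(), module_blocks={}, redundant_pairs=[], artifact_flags=flags,
            true_state={}, true_cycle={}, latent_features={}, family_assignment={},
            cycle_weights=pd.DataFrame(),
        )
    else:
        truth.artifact_flags = flags
    return out, truth
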