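"""Quality control: blurry-field, morphology, and intensity/density filters.

Filters mirror the image-analysis QC of the source assay: fields whose mean
PowerLogLogSlope (a blur metric, more negative = blurrier) across the four
channels is not strictly greater than -2.16 are dropped along with all their
cells; poorly segmented cells are removed on inclusive cytoplasm/nucleus area
bounds; dying or mis-segmented cells are removed on a nucleus-intensity floor
and a 2-D uniform-kernel density cut in the (nucleus intensity, summed other
channel intensities) plane.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .config import ConfigurationError, QCParams, QC_CHANNELS, logger
from .synthetic import CellFeatureTable

_INTENSITY_COLS = ("er_intensity", "mito_intensity", "cgan_intensity")


@dataclass
class QCReport:
    """Counts removed per rule, for the JSON QC report."""

    n_input_cells: int = 0
    n_retained: int = 0
    removed_blur_field: int = 0
    removed_morphology: int = 0
    removed_intensity: int = 0
    removed_density: int = 0
    removed_fields: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_input_cells": self.n_input_cells,
            "n_retained": self.n_retained,
            "removed": {
                "blur_field": self.removed_blur_field,
                "morphology": self.removed_morphology,
                "intensity": self.removed_intensity,
                "density": self.removed_density,
            },
            "removed_fields": self.removed_fields,
        }


def filter_fields_by_blur(qc: pd.DataFrame, threshold: float = -2.16) -> set[str]:
    """Retain fields whose mean channel slope is strictly greater than
    ``threshold`` and that carry no CellProfiler blur flag."""
    if len(qc) == 0:
        raise ConfigurationError("image-quality table is empty")
    slope_cols = [f"slope_{ch}" for ch in QC_CHANNELS]
    for col in slope_cols:
        if col not in qc.columns:
            raise ConfigurationError(f"image-quality table lacks column {col!r}")
        bad = qc.index[~np.isfinite(qc[col].to_numpy(dtype=float))]
        if len(bad):
            raise ConfigurationError(f"missing channel slope {col!r} for field {bad[0]!r}")
    mean_slope = qc[slope_cols].mean(axis=1)
    flags = qc.get("cellprofiler_blur_flag", pd.Series(False, index=qc.index))
    keep = (mean_slope > threshold) & ~flags.astype(bool)
    return set(qc.index[keep])


def filter_cells_by_morphology(
    cells: pd.DataFrame,
    cytoplasm_area_min: float = 1000.0,
    cytoplasm_area_max: float = 100000.0,
    nucleus_area_min: float = 10000.0,
) -> set:
    """Retain cells with cytoplasm area in (min, max) and nucleus area > min;
    all bounds removed inclusively, as indicative of poor segmentation."""
    for col in ("cytoplasm_area", "nucleus_area"):
        if col not in cells.columns:
            raise ConfigurationError(f"cell table lacks column {col!r}")
        if (cells[col].to_numpy(dtype=float) < 0).any():
            raise ConfigurationError(f"negative values in {col!r}")
    cyt = cells["cytoplasm_area"].to_numpy(dtype=float)
    nuc = cells["nucleus_area"].to_numpy(dtype=float)
    keep = (cyt > cytoplasm_area_min) & (cyt < cytoplasm_area_max) & (nuc > nucleus_area_min)
    return set(cells.index[keep])


def uniform_kde_density(points: np.ndarray, bandwidth: float = 1.0) -> np.ndarray:
    """Self-inclusive 2-D product-uniform (box) kernel density at each point.

    A box kernel of half-width ``bandwidth`` on each axis: density at p =
    (# points within Chebyshev distance bandwidth of p) / (n * (2*bandwidth)^2),
    so a point mass of k cells in one box gives k / (n * (2b)^2).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ConfigurationError("density expects an n x 2 coordinate array")
    n = len(pts)
    tree = cKDTree(pts)
    counts = np.array([len(ix) for ix in tree.query_ball_point(pts, r=bandwidth, p=np.inf)])
    return counts / (n * (2.0 * bandwidth) ** 2)


def filter_cells_by_intensity_density(
    cells: pd.DataFrame,
    min_nuc_intensity: float = 0.003,
    bandwidth: float = 1.0,
    min_density: float = 0.0001,
) -> set:
    """Remove cells with nucleus intensity <= floor, or that are outliers in
    the (nucleus intensity, sum of other channel intensities) projection per
    a uniform-kernel density estimate (removal at density <= min_density)."""
    needed = ("nucleus_intensity",) + _INTENSITY_COLS
    for col in needed:
        if col not in cells.columns:
            raise ConfigurationError(f"cell table lacks column {col!r}")
    if len(cells) < 2:
        raise ConfigurationError("density filter needs at least 2 cells")
    x = cells["nucleus_intensity"].to_numpy(dtype=float)
    y = cells[list(_INTENSITY_COLS)].sum(axis=1).to_numpy(dtype=float)
    dens = uniform_kde_density(np.column_stack([x, y]), bandwidth=bandwidth)
    keep = (x > min_nuc_intensity) & (dens > min_density)
    return set(cells.index[keep])


def apply_qc(table: CellFeatureTable, params: QCParams | None = None) -> tuple[CellFeatureTable, QCReport]:
    """Compose the three filters (fields -> morphology -> intensity/density)
    and return the filtered table plus a per-rule report."""
    params = params or QCParams()
    cells = table.cells
    report = QCReport(n_input_cells=len(cells))

    good_fields = filter_fields_by_blur(table.fields, threshold=params.blur_threshold)
    on_good_field = cells["field"].isin(good_fields)
    report.removed_blur_field = int((~on_good_field).sum())
    report.removed_fields = sorted(set(table.fields.index) - good_fields)
    cells = cells[on_good_field]

    keep_morph = filter_cells_by_morphology(
        cells,
        cytoplasm_area_min=params.cytoplasm_area_min,
        cytoplasm_area_max=params.cytoplasm_area_max,
        nucleus_area_min=params.nucleus_area_min,
    )
    report.removed_morphology = len(cells) - len(keep_morph)
    cells = cells.loc[cells.index.isin(keep_morph)]

    keep_int = filter_cells_by_intensity_density(
        cells,
        min_nuc_intensity=params.min_nucleus_intensity,
        bandwidth=params.kde_bandwidth,
        min_density=params.min_density,
    )
    # split the count between the two sub-rules for the report
    dim = cells["nucleus_intensity"].to_numpy(dtype=float) <= params.min_nucleus_intensity
    report.removed_intensity = int(dim.sum())
    report.removed_density = len(cells) - len(keep_int) - report.removed_intensity
    cells = cells.loc[cells.index.isin(keep_int)]

    report.n_retained = len(cells)
    logger.info(
        "QC: %d -> %d cells (blur %d, morphology %d, intensity %d, density %d)",
        report.n_input_cells, report.n_retained, report.removed_blur_field,
        report.removed_morphology, report.removed_intensity, report.removed_density,
    )
    out = CellFeatureTable(
        cells=cells,
        fields=table.fields.loc[sorted(good_fields)],
        feature_cols=list(table.feature_cols),
    )
    return out, report
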