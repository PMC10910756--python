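"""Cell quality control, expression scaling and batch-adjusted PCA.

Scaling follows the CODEX convention: arcsinh (cofactor 150) transform,
z-score within marker columns, then z-score across cell rows. Batch
adjustment is a location-only simplification of integration: per-core
centering of principal components (a hook allows swapping in a full
integration method).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from spatialtma.config import PipelineConfig
from spatialtma.errors import ConfigurationError, EmptyTableError

log = logging.getLogger(__name__)


def qc_filter_cells(
    cells: pd.DataFrame, cfg: PipelineConfig
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Remove artifactual nuclei by DAPI floor then strict size exclusion.

    Cells are removed when DAPI < ``dapi_min`` or nuclear area < ``area_min``
    or > ``area_max`` (areas exactly at a bound are retained). When
    ``dapi_min`` is None the threshold is the 5th percentile of DAPI within
    each core, logged per core.

    Returns the filtered table and a per-rule removal count report.
    """
    if "DAPI" not in cells.columns:
        raise ConfigurationError("DAPI column required for QC filtering")
    if cfg.dapi_min is not None:
        dapi_fail = cells["DAPI"].to_numpy() < cfg.dapi_min
    else:
        thresholds = cells.groupby("sample_id")["DAPI"].transform(
            lambda s: np.percentile(s, 5)
        )
        for sample_id, thr in (
            cells.groupby("sample_id")["DAPI"].quantile(0.05).items()
        ):
            log.info("adaptive DAPI threshold for %s: %.3f", sample_id, thr)
        dapi_fail = cells["DAPI"].to_numpy() < thresholds.to_numpy()

    area = cells["nuclear_area_um2"].to_numpy()
    too_small = ~dapi_fail & (area < cfg.area_min)
    too_large = ~dapi_fail & (area > cfg.area_max)
    keep = ~(dapi_fail | too_small | too_large)

    report = {
        "input": len(cells),
        "removed_dapi": int(dapi_fail.sum()),
        "removed_small": int(too_small.sum()),
        "removed_large": int(too_large.sum()),
        "kept": int(keep.sum()),
    }
    out = cells.loc[keep].reset_index(drop=True)
    if out.empty:
        log.warning("QC filtering removed every cell")
    return out, report


def arcsinh_transform(x, cofactor: float = 150.0) -> np.ndarray:
    """First scaling stage: arcsinh(x / cofactor); arcsinh(0) = 0."""
    return np.arcsinh(np.asarray(x, dtype=float) / cofactor)


def _zscore(matrix: np.ndarray, axis: int) -> np.ndarray:
    """Z-score along axis; constant slices map to 0."""
    mean = matrix.mean(axis=axis, keepdims=True)
    sd = matrix.std(axis=axis, ddof=0, keepdims=True)
    # relative tolerance: constant slices yield sd at rounding-noise scale
    degenerate = sd <= 1e-12 * (np.abs(mean) + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (matrix - mean) / sd
    return np.where(degenerate, 0.0, z)


def transform_and_scale(
    cells: pd.DataFrame, markers: list[str], cfg: PipelineConfig
) -> pd.DataFrame:
    """arcsinh(x / cofactor), z-score per marker column, z-score per cell row."""
    if len(markers) < 2:
        raise ConfigurationError("row scaling is undefined with fewer than 2 markers")
    missing = [m for m in markers if m not in cells.columns]
    if missing:
        raise ConfigurationError(f"markers absent from cell table: {missing}")
    if cells.empty:
        raise EmptyTableError("cannot scale an empty cell table")
    x = cells[markers].to_numpy(dtype=float)
    if (x < 0).any():
        raise ConfigurationError("raw intensities must be nonnegative")
    y = arcsinh_transform(x, cfg.arcsinh_cofactor)
    y = _zscore(y, axis=0)  # within columns (markers)
    y = _zscore(y, axis=1)  # across rows (cells)
    return pd.DataFrame(y, columns=markers, index=cells.index)


def reduce_and_adjust(
    scaled: pd.DataFrame,
    sample_ids: pd.Series,
    cfg: PipelineConfig,
    nuclear_area: pd.Series | None = None,
) -> pd.DataFrame:
    """PCA with a fixed sign convention, then per-core location centering.

    Nuclear area (z-scored) is appended to the feature set before PCA when
    provided. Adjustment subtracts each core's per-component mean and adds
    back the global mean; cores with fewer than 2 cells are passed through
    unadjusted with a warning.
    """
    features = scaled.to_numpy(dtype=float)
    if nuclear_area is not None:
        area_z = _zscore(nuclear_area.to_numpy(dtype=float)[:, None], axis=0)
        features = np.hstack([features, area_z])
    n_pcs = min(cfg.n_pcs, features.shape[1] - 1, features.shape[0] - 1)
    if n_pcs < 1:
        raise ConfigurationError("not enough cells/features for PCA")
    pca = PCA(n_components=n_pcs, svd_solver="full")
    pcs = pca.fit_transform(features)
    # deterministic sign: largest-magnitude loading positive per component
    for j in range(n_pcs):
        loading = pca.components_[j]
        if loading[np.argmax(np.abs(loading))] < 0:
            pcs[:, j] *= -1.0
    global_mean = pcs.mean(axis=0)
    adjusted = pcs.copy()
    ids = np.asarray(sample_ids)
    for sample_id in pd.unique(ids):
        rows = np.flatnonzero(ids == sample_id)
        if rows.size < 2:
            log.warning("core %s has <2 cells; PCs passed through", sample_id)
            continue
        adjusted[rows] = pcs[rows] - pcs[rows].mean(axis=0) + global_mean
    return pd.DataFrame(
        adjusted, columns=[f"PC{i + 1}" for i in range(n_pcs)], index=scaled.index
    )
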