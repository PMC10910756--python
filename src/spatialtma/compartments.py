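"""Tumour / margin / stroma compartments derived from annotated cell points.

Tumour-typed cells are stamped onto a raster as small discs, closed
morphologically, filtered by a minimum component area, then dilated by the
margin distance. Cells are labelled by point-in-raster lookup with
precedence tumour > margin > stroma.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from spatialtma.config import PipelineConfig
from spatialtma.errors import ConfigurationError

log = logging.getLogger(__name__)


@dataclass
class CompartmentGeometry:
    """Rasterized tumour mask and margin band for one core."""

    raster_pixel: float
    origin: tuple[float, float]  # (x, y) of pixel (0, 0) centre, µm
    tumour_mask: np.ndarray  # bool, shape (ny, nx)
    margin_mask: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.tumour_mask.shape

    def to_index(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        col = np.round((np.asarray(x) - self.origin[0]) / self.raster_pixel).astype(int)
        row = np.round((np.asarray(y) - self.origin[1]) / self.raster_pixel).astype(int)
        return row, col

    def tumour_area_um2(self) -> float:
        return float(self.tumour_mask.sum()) * self.raster_pixel**2

    def margin_area_um2(self) -> float:
        if self.margin_mask is None:
            return 0.0
        return float(self.margin_mask.sum()) * self.raster_pixel**2


def _disc(radius_px: float) -> np.ndarray:
    r = int(np.ceil(radius_px))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (xx**2 + yy**2) <= radius_px**2


def build_tumour_mask(
    cells: pd.DataFrame, cfg: PipelineConfig, pad_um: float = 50.0
) -> CompartmentGeometry:
    """Rasterize tumour-typed cells, close, and drop small components.

    Components smaller than ``cfg.min_nest_area`` µm² (8-connectivity) are
    removed. An empty mask (no tumour cells) is returned with a warning;
    downstream labelling then treats the core as all-stroma.
    """
    if "cell_type" not in cells.columns:
        raise ConfigurationError("cell_type column required to build tumour mask")
    px = cfg.raster_pixel
    pad = pad_um + cfg.margin_distance
    x = cells["x_um"].to_numpy(dtype=float)
    y = cells["y_um"].to_numpy(dtype=float)
    x0, y0 = x.min() - pad, y.min() - pad
    nx = int(np.ceil((x.max() + pad - x0) / px)) + 1
    ny = int(np.ceil((y.max() + pad - y0) / px)) + 1
    mask = np.zeros((ny, nx), dtype=bool)

    tumour = cells[cells["cell_type"].isin(cfg.tumour_types)]
    provenance = {
        "raster_pixel": px,
        "cell_stamp_radius": cfg.cell_stamp_radius,
        "closing_radius": cfg.closing_radius,
        "min_nest_area": cfg.min_nest_area,
        "n_tumour_cells": len(tumour),
    }
    if tumour.empty:
        log.warning("no tumour cells; core treated as all-stroma")
        return CompartmentGeometry(px, (x0, y0), mask, provenance=provenance)

    rows = np.round((tumour["y_um"].to_numpy() - y0) / px).astype(int)
    cols = np.round((tumour["x_um"].to_numpy() - x0) / px).astype(int)
    mask[np.clip(rows, 0, ny - 1), np.clip(cols, 0, nx - 1)] = True
    # union of per-cell disc stamps == dilation of the centre points by a disc
    mask = ndimage.binary_dilation(mask, structure=_disc(cfg.cell_stamp_radius / px))

    if cfg.closing_radius > 0:
        mask = ndimage.binary_closing(mask, structure=_disc(cfg.closing_radius / px))

    labelled, n_comp = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n_comp:
        areas = ndimage.sum_labels(
            np.ones_like(mask, dtype=float), labelled, index=np.arange(1, n_comp + 1)
        ) * px**2
        keep = np.flatnonzero(areas >= cfg.min_nest_area) + 1
        mask = np.isin(labelled, keep)
        provenance["n_components_kept"] = int(len(keep))
        provenance["n_components_dropped"] = int(n_comp - len(keep))
    return CompartmentGeometry(px, (x0, y0), mask, provenance=provenance)


def expand_margin(
    geom: CompartmentGeometry, cfg: PipelineConfig
) -> CompartmentGeometry:
    """Margin band = Euclidean dilation of the tumour mask minus the mask."""
    if not geom.tumour_mask.any() or cfg.margin_distance <= 0:
        geom.margin_mask = np.zeros_like(geom.tumour_mask)
        return geom
    dist = ndimage.distance_transform_edt(
        ~geom.tumour_mask, sampling=geom.raster_pixel
    )
    geom.margin_mask = (dist > 0) & (dist <= cfg.margin_distance)
    geom.provenance["margin_distance"] = cfg.margin_distance
    return geom


def assign_compartments(
    cells: pd.DataFrame, geom: CompartmentGeometry
) -> np.ndarray:
    """Label each cell tumour/margin/stroma by raster lookup.

    Cells outside the raster extent fall back to stroma with a warning.
    """
    rows, cols = geom.to_index(cells["x_um"], cells["y_um"])
    ny, nx = geom.shape
    inside = (rows >= 0) & (rows < ny) & (cols >= 0) & (cols < nx)
    if (~inside).any():
        log.warning("%d cells outside raster extent labelled stroma", (~inside).sum())
    labels = np.full(len(cells), "stroma", dtype=object)
    r = np.clip(rows, 0, ny - 1)
    c = np.clip(cols, 0, nx - 1)
    in_tumour = inside & geom.tumour_mask[r, c]
    margin_mask = (
        geom.margin_mask
        if geom.margin_mask is not None
        else np.zeros_like(geom.tumour_mask)
    )
    in_margin = inside & margin_mask[r, c] & ~in_tumour
    labels[in_tumour] = "tumour"
    labels[in_margin] = "margin"
    return labels


def compartments_per_sample(
    cells: pd.DataFrame, cfg: PipelineConfig
) -> tuple[pd.Series, dict[str, CompartmentGeometry]]:
    """Build geometry and assign compartments independently per core."""
    labels = pd.Series(index=cells.index, dtype=object)
    geoms: dict[str, CompartmentGeometry] = {}
    for sample_id, sub in cells.groupby("sample_id", sort=False):
        geom = expand_margin(build_tumour_mask(sub, cfg), cfg)
        labels.loc[sub.index] = assign_compartments(sub, geom)
        geoms[sample_id] = geom
    return labels, geoms


def mask_to_geojson(geom: CompartmentGeometry, which: str = "tumour") -> dict:
    """Export a mask's component outlines as a GeoJSON FeatureCollection."""
    mask = geom.tumour_mask if which == "tumour" else geom.margin_mask
    features = []
    if mask is not None and mask.any():
        padded = np.pad(mask.astype(float), 1)
        for contour in measure.find_contours(padded, 0.5):
            coords = [
                [
                    geom.origin[0] + (c - 1) * geom.raster_pixel,
                    geom.origin[1] + (r - 1) * geom.raster_pixel,
                ]
                for r, c in contour
            ]
            if coords[0] != coords[-1]:
                coords.append(coords[0])
            features.append(
                {
                    "type": "Feature",
                    "properties": {"classification": which},
                    "geometry": {"type": "Polygon", "coordinates": [coords]},
                }
            )
    return {"type": "FeatureCollection", "features": features}


def write_geojson(geojson: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(geojson, fh)
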