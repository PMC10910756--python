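"""End-to-end pipeline driver: preprocess through outcome statistics.

Each stage writes its outputs into the run directory and records row counts
and timings in the manifest; a stage failure halts the run with the stage
name while keeping the partial outputs already written.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from spatialtma import __version__, composition, interactions, io
from spatialtma import neighbourhoods as nbhd
from spatialtma import outcomes as outc
from spatialtma import spatialscore as sscore
from spatialtma.compartments import compartments_per_sample, mask_to_geojson, write_geojson
from spatialtma.config import PipelineConfig
from spatialtma.errors import EmptyTableError, SpatialTMAError
from spatialtma.phenotype import (
    annotate_clusters,
    assign_cell_types,
    cluster_cells,
    cluster_means,
)
from spatialtma.preprocess import qc_filter_cells, reduce_and_adjust, transform_and_scale

log = logging.getLogger(__name__)


class StageFailure(SpatialTMAError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline halted at stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(
    cells: pd.DataFrame,
    clinical: pd.DataFrame,
    cfg: PipelineConfig,
    out_dir,
) -> dict:
    """Run all stages on a cell table + clinical table; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config": asdict(cfg),
        "stages": {},
        "outputs": [],
    }

    def _record(stage: str, t0: float, **counts) -> None:
        manifest["stages"][stage] = {
            "seconds": round(time.perf_counter() - t0, 3),
            **counts,
        }

    def _write(frame: pd.DataFrame, name: str, index: bool = False) -> None:
        path = out / name
        frame.to_csv(path, index=index)
        manifest["outputs"].append(name)

    if cfg.excluded_cores:
        cells = cells[~cells["sample_id"].isin(cfg.excluded_cores)]
        clinical = clinical[~clinical["sample_id"].isin(cfg.excluded_cores)]

    stage = "preprocess"
    try:
        t0 = time.perf_counter()
        cells, qc_report = qc_filter_cells(cells, cfg)
        if cells.empty:
            raise EmptyTableError("no cells survive QC")
        scaled = transform_and_scale(cells, cfg.markers, cfg)
        pcs = reduce_and_adjust(
            scaled, cells["sample_id"], cfg, nuclear_area=cells["nuclear_area_um2"]
        )
        _record(stage, t0, **qc_report)

        stage = "phenotype"
        t0 = time.perf_counter()
        cluster_ids = cluster_cells(pcs, cfg)
        means = cluster_means(scaled, cluster_ids)
        mapping = annotate_clusters(
            means, cfg.signatures, cfg.tumour_types, cfg.annotation_floor
        )
        cells = cells.copy()
        cells["cluster_id"] = cluster_ids
        cells["cell_type"] = assign_cell_types(cluster_ids, mapping)
        _write(means.round(6), "cluster_means.csv", index=True)
        _record(stage, t0, n_clusters=len(means),
                n_types=cells["cell_type"].nunique())

        stage = "compartments"
        t0 = time.perf_counter()
        labels, geoms = compartments_per_sample(cells, cfg)
        cells["compartment"] = labels
        for sample_id, geom in geoms.items():
            write_geojson(
                mask_to_geojson(geom, "tumour"), out / f"tumour_{sample_id}.geojson"
            )
            manifest["outputs"].append(f"tumour_{sample_id}.geojson")
        _record(stage, t0, n_cores=len(geoms))

        stage = "composition"
        t0 = time.perf_counter()
        props = composition.cell_proportions(cells, "none")
        props_comp = composition.cell_proportions(cells, "compartment")
        _write(props, "proportions.csv", index=True)
        _write(props_comp, "proportions_by_compartment.csv", index=True)
        _record(stage, t0, n_features=props.shape[1] + props_comp.shape[1])

        stage = "interactions"
        t0 = time.perf_counter()
        inter_wide, inter_long = interactions.all_pair_scores(cells, cfg=cfg)
        _write(inter_long, "interactions_long.csv")
        _record(stage, t0, n_features=inter_wide.shape[1])

        stage = "neighbourhoods"
        t0 = time.perf_counter()
        windows = nbhd.compute_windows(cells, cfg.window_k)
        cn_labels, centroids = nbhd.cluster_neighbourhoods(
            windows, cfg.n_neighbourhoods, cfg.seed
        )
        cells["neighbourhood_id"] = cn_labels
        cn_freq = nbhd.neighbourhood_frequencies(
            cn_labels, cells["sample_id"], cfg.n_neighbourhoods
        )
        _write(centroids.round(6), "cn_centroids.csv", index=True)
        _write(cn_freq, "cn_frequencies.csv", index=True)
        if clinical is not None and "response" in clinical.columns:
            groups = clinical.set_index("sample_id")["response"]
            enrich = nbhd.differential_enrichment(
                cells, cn_labels, groups, cfg.pseudofrequency
            )
            _write(enrich, "cn_enrichment.csv")
        else:
            log.warning("no response labels; neighbourhood enrichment skipped")
        _record(stage, t0, n_neighbourhoods=cfg.n_neighbourhoods)

        stage = "spatialscore"
        t0 = time.perf_counter()
        sscores = sscore.score_panel(cells, cfg=cfg)
        _write(sscores, "spatial_scores.csv", index=True)
        _record(stage, t0, n_features=sscores.shape[1])

        stage = "outcomes"
        t0 = time.perf_counter()
        if clinical is None or "response" not in clinical.columns:
            raise SpatialTMAError("clinical table with response column required")
        features = pd.concat(
            [props, props_comp, inter_wide, cn_freq, sscores], axis=1
        )
        _write(features, "features.csv", index=True)
        tests = outc.feature_response_tests(features, clinical, cfg.pseudofrequency)
        _write(tests, "response_tests.csv")
        if {"os_days", "event"}.issubset(clinical.columns):
            surv = outc.survival_screen(features, clinical)
            _write(surv, "survival_tests.csv")
        summary = outc.cohort_summary(clinical)
        _write(summary, "cohort_summary.csv")
        _write(cells, "cells_annotated.csv")
        _record(stage, t0, n_features=features.shape[1])
    except Exception as exc:
        io.write_manifest(manifest, out / "manifest.json")
        raise StageFailure(stage, exc) from exc

    manifest["output_hashes"] = {
        name: io.file_sha256(out / name) for name in sorted(manifest["outputs"])
    }
    io.write_manifest(manifest, out / "manifest.json")
    return manifest


def manifest_fingerprint(manifest: dict) -> dict:
    """Deterministic view of a manifest: everything except wall-clock timings."""
    stages = {
        name: {k: v for k, v in info.items() if k != "seconds"}
        for name, info in manifest.get("stages", {}).items()
    }
    return {
        "version": manifest.get("version"),
        "seed": manifest.get("seed"),
        "config": manifest.get("config"),
        "stages": stages,
        "outputs": manifest.get("outputs"),
        "output_hashes": manifest.get("output_hashes"),
    }
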