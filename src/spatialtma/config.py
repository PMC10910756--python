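"""Pipeline configuration and the default marker panel / signature table.

Every numeric constant used by the pipeline lives on :class:`PipelineConfig`
so that a run is fully described by one YAML file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from spatialtma.errors import ConfigurationError

#: 25-marker clustering panel (DAPI is carried separately for QC only).
DEFAULT_MARKERS: tuple[str, ...] = (
    "PanCK", "CD117", "Ki67", "CD45", "CD20", "CD3e", "CD4", "CD45RO",
    "CD45RA", "CD8", "CD107a", "CD44", "FoxP3", "CD25", "CD197", "CD11b",
    "CD14", "CD15", "CD68", "HLADR", "CD141", "CD31", "CD34", "Podoplanin",
    "Vimentin",
)

#: Canonical required-positive marker signatures for the 19 cell types.
DEFAULT_SIGNATURES: dict[str, tuple[str, ...]] = {
    "B cell": ("CD45", "CD45RA", "CD20"),
    "Blood vessel": ("CD31", "CD34"),
    "Lymphatic": ("Podoplanin",),
    "CD4 T cell": ("CD45", "CD3e", "CD4", "CD45RO"),
    "CD8 T cell": ("CD45", "CD3e", "CD8", "CD45RO"),
    "Granulocyte": ("CD15", "CD141", "CD11b"),
    "Lymphocyte": ("CD45",),
    "Vessel lymphocyte": ("CD45", "CD31"),
    "Macrophage": ("CD68", "CD107a", "CD14"),
    "Mast cell": ("CD117",),
    "Monocyte": ("CD14",),
    "Proliferating lymphocyte": ("CD45", "Ki67"),
    "Stroma": ("Vimentin",),
    "Treg": ("CD45", "CD4", "FoxP3", "CD25"),
    "Effector CD4 T cell": ("CD45", "CD4", "HLADR", "CD197"),
    "CCR7 CD8 T cell": ("CD45", "CD45RO", "CD8", "CD197"),
    "Tumour HLADR": ("PanCK", "HLADR"),
    "Tumour CD44": ("PanCK", "CD44"),
    "Tumour Ki67": ("PanCK", "Ki67"),
}

#: Cell types treated as the tumour super-type throughout the pipeline.
TUMOUR_TYPES: tuple[str, ...] = ("Tumour HLADR", "Tumour CD44", "Tumour Ki67")


def default_signatures() -> dict[str, list[str]]:
    """Return a mutable copy of the canonical signature table."""
    return {k: list(v) for k, v in DEFAULT_SIGNATURES.items()}


@dataclass
class PipelineConfig:
    """All fixed numeric parameters of the analysis pipeline.

    Attributes
    ----------
    arcsinh_cofactor
        Divisor applied before the arcsinh transform.
    dapi_min
        Minimum median DAPI intensity; ``None`` means data-adaptive
        (5th percentile of per-core DAPI, logged per core).
    area_min, area_max
        Nuclear-area exclusion bounds in µm²; removal is strict
        (``area < area_min`` or ``area > area_max``).
    n_pcs
        Number of principal components retained for clustering.
    knn_graph_k
        Neighbours in the phenotyping kNN graph.
    leiden_resolution
        Resolution of Leiden community detection.
    interaction_radius
        Pairwise proximity radius in µm (boundary inclusive).
    interaction_knn
        Retained for knn-mode parity; inert in radius mode.
    window_k
        Window size (index cell included) for neighbourhood features.
    n_neighbourhoods
        Number of k-means neighbourhood clusters.
    margin_distance
        Dilation distance of the tumour mask defining the margin band, µm.
    min_nest_area
        Minimum tumour-component area retained, µm².
    raster_pixel
        Compartment raster resolution, µm.
    cell_stamp_radius
        Radius used to stamp each tumour cell onto the raster, µm.
    closing_radius
        Disc radius for morphological closing of the tumour mask, µm.
    pseudofrequency
        Additive epsilon keeping log-fold-changes finite.
    annotation_floor
        Minimum signature score below which a cluster is "unclassified".
    """

    arcsinh_cofactor: float = 150.0
    dapi_min: float | None = None
    area_min: float = 10.0
    area_max: float = 220.0
    n_pcs: int = 20
    knn_graph_k: int = 30
    leiden_resolution: float = 2.0
    interaction_radius: float = 20.0
    interaction_knn: int = 3
    window_k: int = 10
    n_neighbourhoods: int = 10
    margin_distance: float = 30.0
    min_nest_area: float = 100.0
    raster_pixel: float = 2.0
    cell_stamp_radius: float = 5.0
    closing_radius: float = 10.0
    pseudofrequency: float = 1e-3
    annotation_floor: float = 0.2
    seed: int = 0
    markers: list[str] = field(default_factory=lambda: list(DEFAULT_MARKERS))
    signatures: dict[str, list[str]] = field(default_factory=default_signatures)
    tumour_types: list[str] = field(default_factory=lambda: list(TUMOUR_TYPES))
    excluded_cores: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = {
            "arcsinh_cofactor": self.arcsinh_cofactor,
            "area_min": self.area_min,
            "area_max": self.area_max,
            "interaction_radius": self.interaction_radius,
            "margin_distance": self.margin_distance,
            "min_nest_area": self.min_nest_area,
            "raster_pixel": self.raster_pixel,
            "pseudofrequency": self.pseudofrequency,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ConfigurationError(f"{name} must be positive, got {value}")
        if self.area_min >= self.area_max:
            raise ConfigurationError(
                f"area_min ({self.area_min}) must be < area_max ({self.area_max})"
            )
        for count_name in ("n_pcs", "knn_graph_k", "window_k", "n_neighbourhoods"):
            if getattr(self, count_name) < 1:
                raise ConfigurationError(f"{count_name} must be >= 1")
        panel = set(self.markers)
        for cell_type, sig in self.signatures.items():
            missing = [m for m in sig if m not in panel]
            if missing:
                raise ConfigurationError(
                    f"signature for {cell_type!r} references markers "
                    f"absent from the panel: {missing}"
                )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)
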