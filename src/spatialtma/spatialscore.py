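"""Triplet distance-ratio score per sample.

For each center cell of type C: D1 = distance to the nearest partner cell
(type P, excluding self when C == P), D2 = distance to the nearest
reference cell (type T, tumour by default). The per-cell ratio is D2/D1 and
the sample score is the mean ratio; higher values mean partner proximity
dominates tumour proximity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from spatialtma.config import PipelineConfig
from spatialtma.errors import ConfigurationError

log = logging.getLogger(__name__)

#: floor applied to zero distances (coincident points), µm
DISTANCE_FLOOR = 0.2


@dataclass
class TripletScore:
    sample_id: str
    center: str
    partner: str
    reference: str
    ratios: np.ndarray
    n_center: int
    score: float


def _nearest_other(
    centers: np.ndarray, targets: np.ndarray, same: bool
) -> np.ndarray:
    """Distance from each center to its nearest target, excluding identity
    matches when centers and targets are the same set."""
    tree = cKDTree(targets)
    if same:
        d, _ = tree.query(centers, k=2)
        return d[:, 1]
    d, _ = tree.query(centers, k=1)
    return d


def spatial_score(
    cells: pd.DataFrame,
    center: str,
    partner: str,
    reference: str,
    type_column: str = "cell_type",
    invert: bool = False,
    aggregate: str = "mean",
) -> TripletScore | None:
    """Score one (center, partner, reference) triplet in one sample.

    Returns None (missing) when any of the three types is absent; same-type
    center/partner pairs need at least two center cells. Zero partner
    distances are floored at ``DISTANCE_FLOOR`` and flagged.
    """
    sample_id = str(cells["sample_id"].iloc[0]) if len(cells) else ""
    xy = cells[["x_um", "y_um"]].to_numpy(dtype=float)
    c_xy = xy[(cells[type_column] == center).to_numpy()]
    p_xy = xy[(cells[type_column] == partner).to_numpy()]
    t_xy = xy[(cells[type_column] == reference).to_numpy()]
    if len(c_xy) == 0 or len(t_xy) == 0 or len(p_xy) == 0:
        log.debug("missing triplet (%s,%s,%s) in %s", center, partner, reference,
                  sample_id)
        return None
    if center == partner and len(c_xy) < 2:
        return None
    d1 = _nearest_other(c_xy, p_xy, same=(center == partner))
    d2 = _nearest_other(c_xy, t_xy, same=(center == reference))
    if (d1 == 0).any():
        log.warning("%d coincident center/partner points floored", (d1 == 0).sum())
        d1 = np.maximum(d1, DISTANCE_FLOOR)
    d2 = np.maximum(d2, DISTANCE_FLOOR)
    ratios = d1 / d2 if invert else d2 / d1
    agg = np.median(ratios) if aggregate == "median" else np.mean(ratios)
    return TripletScore(
        sample_id, center, partner, reference, ratios, len(c_xy), float(agg)
    )


def spatial_score_bruteforce(
    cells: pd.DataFrame,
    center: str,
    partner: str,
    reference: str,
    type_column: str = "cell_type",
) -> float | None:
    """Exhaustive all-distances reference implementation."""
    from scipy.spatial.distance import cdist

    xy = cells[["x_um", "y_um"]].to_numpy(dtype=float)
    idx_c = np.flatnonzero((cells[type_column] == center).to_numpy())
    idx_p = np.flatnonzero((cells[type_column] == partner).to_numpy())
    idx_t = np.flatnonzero((cells[type_column] == reference).to_numpy())
    if not (len(idx_c) and len(idx_p) and len(idx_t)):
        return None
    if center == partner and len(idx_c) < 2:
        return None
    d_p = cdist(xy[idx_c], xy[idx_p])
    d_t = cdist(xy[idx_c], xy[idx_t])
    # mask identity matches (same cell appearing on both sides)
    d_p[idx_c[:, None] == idx_p[None, :]] = np.inf
    d_t[idx_c[:, None] == idx_t[None, :]] = np.inf
    d1 = np.maximum(d_p.min(axis=1), DISTANCE_FLOOR)
    d2 = np.maximum(d_t.min(axis=1), DISTANCE_FLOOR)
    return float(np.mean(d2 / d1))


def default_triplets(tumour_types: list[str]) -> list[tuple[str, str, str]]:
    """Default triplets: T-cell centers, macrophage partner, tumour reference."""
    reference = tumour_types[0] if len(tumour_types) == 1 else "__tumour__"
    return [
        ("CD4 T cell", "Macrophage", reference),
        ("CD8 T cell", "Macrophage", reference),
    ]


def score_panel(
    cells: pd.DataFrame,
    triplets: list[tuple[str, str, str]] | None = None,
    cfg: PipelineConfig | None = None,
    type_column: str = "cell_type",
    symmetric: bool = False,
) -> pd.DataFrame:
    """One feature per triplet per sample.

    The reference pseudo-type ``"__tumour__"`` pools the configured tumour
    subsets. With ``symmetric=True`` the swapped (partner-as-center)
    orientation is emitted as an extra feature. Missing scores (absent
    types) propagate as NaN and are logged.
    """
    cfg = cfg or PipelineConfig()
    if triplets is None:
        triplets = default_triplets(list(cfg.tumour_types))
    work = cells.copy()
    work["_ss_type"] = work[type_column].where(
        ~work[type_column].isin(cfg.tumour_types), "__tumour__"
    )

    def _resolve(t: str) -> str:
        return t if t != "__tumour__" else "__tumour__"

    requested = list(triplets)
    if symmetric:
        requested += [(p, c, t) for c, p, t in triplets]
    records = []
    for sample_id, sub in work.groupby("sample_id", sort=True):
        for c, p, t in requested:
            ts = spatial_score(
                sub, _resolve(c), _resolve(p), _resolve(t), type_column="_ss_type"
            )
            records.append(
                {
                    "sample_id": sample_id,
                    "center": c,
                    "partner": p,
                    "reference": t,
                    "n_center": ts.n_center if ts else 0,
                    "score": ts.score if ts else np.nan,
                }
            )
            if ts is None:
                log.info(
                    "sample %s lacks a type for triplet (%s, %s, %s); "
                    "feature missing",
                    sample_id, c, p, t,
                )
    long = pd.DataFrame(records)
    wide = long.assign(
        feature="sscore|" + long["center"] + "|" + long["partner"] + "|"
        + long["reference"]
    ).pivot(index="sample_id", columns="feature", values="score")
    wide.columns.name = None
    return wide
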