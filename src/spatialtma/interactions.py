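"""Pairwise proximity-density interaction scores.

For each unordered cell-type pair per sample: the number of qualifying
pairs within a fixed radius (boundary inclusive), divided by the number of
cells of that pair in the sample. Computed with a KD-tree but contractually
equal to the O(n²) scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations_with_replacement

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from spatialtma.config import PipelineConfig
from spatialtma.errors import ConfigurationError

log = logging.getLogger(__name__)


@dataclass
class InteractionScore:
    sample_id: str
    type_a: str
    type_b: str
    pair_count: int
    denominator: int
    density: float | None  # None when denominator is 0 (missing, not 0)


def proximity_density(
    cells: pd.DataFrame,
    type_a: str,
    type_b: str,
    radius: float = 20.0,
    type_column: str = "cell_type",
) -> InteractionScore:
    """Score one type pair in one sample.

    pair_count counts unordered (a, b) pairs with distance <= radius,
    excluding self-pairs; the denominator is |A| + |B| for distinct types
    and |A| for same-type pairs. Missing (None) when either type is absent.
    """
    if radius <= 0:
        raise ConfigurationError("radius must be positive")
    sample_id = str(cells["sample_id"].iloc[0]) if len(cells) else ""
    xy = cells[["x_um", "y_um"]].to_numpy(dtype=float)
    mask_a = (cells[type_column] == type_a).to_numpy()
    mask_b = (cells[type_column] == type_b).to_numpy()
    n_a, n_b = int(mask_a.sum()), int(mask_b.sum())
    if type_a == type_b:
        denominator = n_a
    else:
        denominator = n_a + n_b
    if n_a == 0 or n_b == 0:
        log.debug("missing score for (%s, %s) in %s", type_a, type_b, sample_id)
        return InteractionScore(sample_id, type_a, type_b, 0, denominator, None)
    if type_a == type_b:
        tree = cKDTree(xy[mask_a])
        pair_count = len(tree.query_pairs(radius))
    else:
        tree_a = cKDTree(xy[mask_a])
        tree_b = cKDTree(xy[mask_b])
        pair_count = int(
            sum(len(v) for v in tree_a.query_ball_tree(tree_b, radius))
        )
    return InteractionScore(
        sample_id, type_a, type_b, pair_count, denominator, pair_count / denominator
    )


def proximity_density_bruteforce(
    cells: pd.DataFrame,
    type_a: str,
    type_b: str,
    radius: float = 20.0,
    type_column: str = "cell_type",
) -> InteractionScore:
    """O(n²) full distance-matrix reference used for contract checks."""
    from scipy.spatial.distance import cdist

    xy = cells[["x_um", "y_um"]].to_numpy(dtype=float)
    sample_id = str(cells["sample_id"].iloc[0]) if len(cells) else ""
    idx_a = np.flatnonzero((cells[type_column] == type_a).to_numpy())
    idx_b = np.flatnonzero((cells[type_column] == type_b).to_numpy())
    denominator = len(idx_a) if type_a == type_b else len(idx_a) + len(idx_b)
    if len(idx_a) == 0 or len(idx_b) == 0:
        return InteractionScore(sample_id, type_a, type_b, 0, denominator, None)
    d = cdist(xy[idx_a], xy[idx_b])
    if type_a == type_b:
        count = int((np.triu(d <= radius, k=1)).sum())
    else:
        count = int((d <= radius).sum())
    return InteractionScore(
        sample_id, type_a, type_b, count, denominator, count / denominator
    )


def all_pair_scores(
    cells: pd.DataFrame,
    type_list: list[str] | None = None,
    cfg: PipelineConfig | None = None,
    type_column: str = "cell_type",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every unordered type pair in every sample.

    Returns a (samples × pair-features) matrix with missing values
    propagated, and a long-format table (sample, type pair, counts,
    density).
    """
    cfg = cfg or PipelineConfig()
    if type_list is None:
        type_list = sorted(
            t for t in cells[type_column].unique() if t != "unclassified"
        )
    pairs = list(combinations_with_replacement(type_list, 2))
    records = []
    for sample_id, sub in cells.groupby("sample_id", sort=True):
        for type_a, type_b in pairs:
            score = proximity_density(
                sub, type_a, type_b, cfg.interaction_radius, type_column
            )
            records.append(
                {
                    "sample_id": sample_id,
                    "type_a": type_a,
                    "type_b": type_b,
                    "pair_count": score.pair_count,
                    "denominator": score.denominator,
                    "density": score.density,
                }
            )
    long = pd.DataFrame(records)
    wide = long.assign(
        feature="interact|" + long["type_a"] + "|" + long["type_b"]
    ).pivot(index="sample_id", columns="feature", values="density")
    wide.columns.name = None
    return wide, long
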