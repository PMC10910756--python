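"""Cellular neighbourhood detection from k-nearest-neighbour windows.

Each cell's feature vector is the cell-type composition of its window (the
cell itself plus its k-1 nearest neighbours within the same sample; a flag
gives the strict exclude-self variant). Windows are pooled across samples
and clustered by k-means; per-sample neighbourhood frequencies and a
per-neighbourhood differential cell-type enrichment model follow.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors

from spatialtma.errors import ConfigurationError

log = logging.getLogger(__name__)


def compute_windows(
    cells: pd.DataFrame,
    window_k: int = 10,
    type_column: str = "cell_type",
    include_self: bool = True,
) -> pd.DataFrame:
    """Window composition matrix (cells × cell types), rows summing to 1.

    Windows never cross sample boundaries. Samples with fewer than
    ``window_k`` cells use all their cells (flagged in the log). Neighbour
    ties at equal distance break by table order (cell_id order within a
    sample).
    """
    types = sorted(cells[type_column].unique())
    type_index = {t: i for i, t in enumerate(types)}
    out = np.zeros((len(cells), len(types)))
    positions = {c: i for i, c in enumerate(cells.index)}
    for sample_id, sub in cells.groupby("sample_id", sort=False):
        n = len(sub)
        k = min(window_k, n) if include_self else min(window_k, n - 1)
        if (include_self and n < window_k) or (not include_self and n - 1 < window_k):
            log.warning(
                "sample %s has %d cells; window truncated to %d", sample_id, n, k
            )
        xy = sub[["x_um", "y_um"]].to_numpy(dtype=float)
        codes = sub[type_column].map(type_index).to_numpy()
        if include_self:
            nn = NearestNeighbors(n_neighbors=k).fit(xy)
            _, idx = nn.kneighbors(xy)  # self returned as nearest neighbour
        else:
            nn = NearestNeighbors(n_neighbors=k + 1).fit(xy)
            _, idx = nn.kneighbors(xy)
            idx = idx[:, 1:]
        rows = [positions[c] for c in sub.index]
        counts = np.zeros((n, len(types)))
        for t in range(len(types)):
            counts[:, t] = (codes[idx] == t).sum(axis=1)
        out[rows] = counts / counts.sum(axis=1, keepdims=True)
    return pd.DataFrame(out, columns=types, index=cells.index)


def cluster_neighbourhoods(
    windows: pd.DataFrame, n_clusters: int = 10, seed: int = 0
) -> tuple[np.ndarray, pd.DataFrame]:
    """K-means (k-means++ init, 10 restarts, fixed seed) on window vectors.

    Returns per-cell labels and the centroid compositions. Empty clusters
    are permitted by k-means' construction only transiently; occupied-label
    count is logged.
    """
    if len(windows) < n_clusters:
        raise ConfigurationError("fewer windows than requested clusters")
    x = windows.to_numpy(dtype=float)
    if np.allclose(x, x[0]):
        log.warning("all windows identical; single occupied cluster")
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
    labels = km.fit_predict(x)
    centroids = pd.DataFrame(
        km.cluster_centers_,
        columns=windows.columns,
        index=[f"CN{i}" for i in range(n_clusters)],
    )
    occupied = len(np.unique(labels))
    if occupied < n_clusters:
        log.warning("%d of %d neighbourhood clusters occupied", occupied, n_clusters)
    return labels, centroids


def neighbourhood_frequencies(
    labels: np.ndarray, sample_ids: pd.Series, n_clusters: int | None = None
) -> pd.DataFrame:
    """Per-sample fraction of cells in each neighbourhood (rows sum to 1)."""
    if n_clusters is None:
        n_clusters = int(np.max(labels)) + 1
    frame = pd.DataFrame({"sample_id": np.asarray(sample_ids), "cn": labels})
    freq = (
        frame.groupby(["sample_id", "cn"])
        .size()
        .unstack(fill_value=0)
        .reindex(columns=range(n_clusters), fill_value=0)
    )
    freq = freq.div(freq.sum(axis=1), axis=0)
    freq.columns = [f"cnfreq|CN{c}" for c in freq.columns]
    return freq


def differential_enrichment(
    cells: pd.DataFrame,
    labels: np.ndarray,
    groups: pd.Series,
    epsilon: float = 1e-3,
    type_column: str = "cell_type",
) -> pd.DataFrame:
    """OLS of per-sample log2 within-neighbourhood enrichment on group.

    For each (neighbourhood n, type c) and sample s:
    e = log2((f_{s,n,c} + eps) / (f_{s,c} + eps)), where f_{s,n,c} is the
    fraction of type c among cells of n in s and f_{s,c} the overall
    fraction in s. The model e ~ intercept + group reports the group
    coefficient and its t-test p-value. Samples lacking neighbourhood n are
    omitted from that fit.
    """
    groups = groups.dropna()
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ConfigurationError("differential enrichment requires exactly 2 groups")
    frame = pd.DataFrame(
        {
            "sample_id": cells["sample_id"].to_numpy(),
            "cn": labels,
            "ct": cells[type_column].to_numpy(),
        }
    )
    overall = (
        frame.groupby("sample_id")["ct"].value_counts(normalize=True).rename("f_sc")
    )
    within = (
        frame.groupby(["sample_id", "cn"])["ct"]
        .value_counts(normalize=True)
        .rename("f_snc")
    )
    types = sorted(frame["ct"].unique())
    cns = sorted(frame["cn"].unique())
    rows = []
    for cn in cns:
        present = frame.loc[frame["cn"] == cn, "sample_id"].unique()
        samples = [s for s in present if s in groups.index]
        n_omitted = len(groups) - len(samples)
        if n_omitted:
            log.debug("CN%s absent in %d samples", cn, n_omitted)
        if len(samples) < 4:
            continue
        g = groups.loc[samples]
        if (g == levels[0]).sum() < 2 or (g == levels[1]).sum() < 2:
            continue
        x = sm.add_constant((g == levels[1]).astype(float).to_numpy())
        for ct in types:
            e = []
            for s in samples:
                f_snc = within.get((s, cn, ct), 0.0)
                f_sc = overall.get((s, ct), 0.0)
                e.append(np.log2((f_snc + epsilon) / (f_sc + epsilon)))
            fit = sm.OLS(np.asarray(e), x).fit()
            rows.append(
                {
                    "neighbourhood": f"CN{cn}",
                    "cell_type": ct,
                    "coef": float(fit.params[1]),
                    "p": float(fit.pvalues[1]) if len(samples) > 2 else np.nan,
                    "n_samples": len(samples),
                    "group_high": levels[1],
                }
            )
    return pd.DataFrame(rows)
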