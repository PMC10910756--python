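"""Graph-based cell clustering and signature annotation.

Clustering re-implements the published Phenograph recipe: a k-nearest-
neighbour graph in PC space, edges weighted by Jaccard overlap of neighbour
sets, then Leiden community detection at a fixed resolution and seed.
Annotation scores each cluster's mean scaled expression against canonical
required-positive signatures; clusters mapping to the same type are merged
implicitly.
"""

from __future__ import annotations

import logging

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score, confusion_matrix, f1_score
from sklearn.neighbors import NearestNeighbors

from spatialtma.config import PipelineConfig
from spatialtma.errors import ConfigurationError

log = logging.getLogger(__name__)


def _jaccard_knn_graph(pcs: np.ndarray, k: int) -> ig.Graph:
    nn = NearestNeighbors(n_neighbors=k + 1).fit(pcs)
    _, indices = nn.kneighbors(pcs)
    neighbour_sets = [set(row[1:]) for row in indices]  # drop self
    edges: dict[tuple[int, int], float] = {}
    for i, row in enumerate(indices):
        for j in row[1:]:
            a, b = (i, int(j)) if i < j else (int(j), i)
            if (a, b) in edges:
                continue
            inter = len(neighbour_sets[a] & neighbour_sets[b])
            union = len(neighbour_sets[a] | neighbour_sets[b])
            edges[(a, b)] = inter / union if union else 0.0
    graph = ig.Graph(n=len(pcs), edges=list(edges))
    graph.es["weight"] = list(edges.values())
    return graph


def cluster_cells(pcs: pd.DataFrame, cfg: PipelineConfig) -> np.ndarray:
    """Phenograph-style clustering: kNN graph + Jaccard weights + Leiden.

    Returns integer labels 0..C-1; C is data dependent.
    """
    x = np.asarray(pcs, dtype=float)
    n = len(x)
    if cfg.knn_graph_k >= n:
        raise ConfigurationError(
            f"knn_graph_k={cfg.knn_graph_k} must be smaller than the number of "
            f"cells ({n}); choose a smaller k"
        )
    graph = _jaccard_knn_graph(x, cfg.knn_graph_k)
    partition = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=cfg.leiden_resolution,
        seed=cfg.seed,
    )
    return np.asarray(partition.membership, dtype=int)


def cluster_means(
    scaled: pd.DataFrame, cluster_ids: np.ndarray
) -> pd.DataFrame:
    """Mean scaled expression per cluster (clusters × markers)."""
    return scaled.groupby(pd.Series(cluster_ids, index=scaled.index)).mean()


def annotate_clusters(
    means: pd.DataFrame,
    signatures: dict[str, list[str]],
    tumour_types: list[str],
    floor: float = 0.2,
) -> dict[int, str]:
    """Assign each cluster the signature with the highest mean score.

    score(cluster, type) = mean of the cluster's mean scaled expression over
    the type's signature markers. Clusters whose single top marker is PanCK
    compete among the tumour subsets only. Ties break to the larger
    signature, then lexicographically. Max score below ``floor`` yields
    "unclassified". Pure function of its inputs (no RNG).
    """
    for cell_type, sig in signatures.items():
        missing = [m for m in sig if m not in means.columns]
        if missing:
            raise ConfigurationError(
                f"signature {cell_type!r} references markers missing from the "
                f"expression table: {missing}"
            )
    mapping: dict[int, str] = {}
    for cluster_id, row in means.iterrows():
        panck_dominant = (
            "PanCK" in means.columns and row.idxmax() == "PanCK"
        )
        candidates = (
            {t: signatures[t] for t in tumour_types if t in signatures}
            if panck_dominant
            else signatures
        )
        scored = [
            (float(np.mean([row[m] for m in sig])), len(sig), name)
            for name, sig in candidates.items()
        ]
        # sort: score desc, signature size desc, name asc
        scored.sort(key=lambda t: (-t[0], -t[1], t[2]))
        best_score, _, best_name = scored[0]
        mapping[cluster_id] = best_name if best_score >= floor else "unclassified"
    return mapping


def assign_cell_types(
    cluster_ids: np.ndarray, mapping: dict[int, str]
) -> np.ndarray:
    return np.array([mapping[c] for c in cluster_ids])


def phenotyping_recovery_report(
    assigned: np.ndarray, truth: np.ndarray
) -> dict:
    """Concordance of assigned types against ground truth."""
    labels = sorted(set(truth) | set(assigned))
    return {
        "ari": float(adjusted_rand_score(truth, assigned)),
        "confusion": pd.DataFrame(
            confusion_matrix(truth, assigned, labels=labels),
            index=labels,
            columns=labels,
        ),
        "per_type_f1": pd.Series(
            f1_score(truth, assigned, labels=labels, average=None, zero_division=0),
            index=labels,
        ),
        "fraction_classified": float(np.mean(assigned != "unclassified")),
    }
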