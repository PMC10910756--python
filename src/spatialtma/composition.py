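"""Per-sample cell-type proportions, differential abundance and composition PCA."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from spatialtma.errors import ConfigurationError

log = logging.getLogger(__name__)


def cell_proportions(
    cells: pd.DataFrame,
    stratify_by: str = "none",
    type_column: str = "cell_type",
    exclude_unclassified: bool = True,
) -> pd.DataFrame:
    """Fraction of each cell type among typed cells per sample.

    With ``stratify_by="compartment"`` proportions are computed within each
    (sample, compartment) block and features are named
    ``prop|<type>|<compartment>``; otherwise ``prop|<type>|all``. Absent
    types get 0; a block with zero typed cells yields missing values.
    """
    if stratify_by not in ("none", "compartment"):
        raise ConfigurationError(f"unknown stratify_by: {stratify_by!r}")
    typed = cells
    if exclude_unclassified:
        typed = cells[cells[type_column] != "unclassified"]
    all_types = sorted(typed[type_column].unique())
    all_samples = sorted(cells["sample_id"].unique())

    def _block(frame: pd.DataFrame, suffix: str) -> pd.DataFrame:
        counts = (
            frame.groupby(["sample_id", type_column], observed=True)
            .size()
            .unstack(fill_value=0)
            .reindex(columns=all_types, fill_value=0)
            .reindex(index=all_samples)
        )
        totals = counts.sum(axis=1)
        empty = totals == 0
        if empty.any():
            log.warning(
                "samples with zero typed cells in block %r: %s",
                suffix,
                list(counts.index[empty]),
            )
        props = counts.div(totals.replace(0, np.nan), axis=0)
        props.columns = [f"prop|{t}|{suffix}" for t in props.columns]
        return props

    if stratify_by == "none":
        return _block(typed, "all")
    if "compartment" not in cells.columns:
        raise ConfigurationError("compartment column required for stratification")
    blocks = [
        _block(typed[typed["compartment"] == comp], comp)
        for comp in ("tumour", "margin", "stroma")
    ]
    return pd.concat(blocks, axis=1)


def differential_abundance(
    features: pd.DataFrame,
    groups: pd.Series,
    epsilon: float = 1e-3,
    orientation: tuple[str, str] = ("NR", "R"),
) -> pd.DataFrame:
    """Welch t-test per feature between response groups, with log2 fold change.

    log2FC = log2((mean_<numerator> + eps) / (mean_<denominator> + eps)); the
    default orientation is NR over R. Features with zero variance in both
    groups are reported with p = 1 and flagged.
    """
    num, den = orientation
    groups = groups.reindex(features.index)
    mask_num = (groups == num).to_numpy()
    mask_den = (groups == den).to_numpy()
    if mask_num.sum() < 2 or mask_den.sum() < 2:
        raise ConfigurationError("need at least 2 samples per group")
    rows = []
    for feat in features.columns:
        col = features[feat].to_numpy(dtype=float)
        a = col[mask_num]
        b = col[mask_den]
        a = a[~np.isnan(a)]
        b = b[~np.isnan(b)]
        if len(a) < 2 or len(b) < 2:
            rows.append((feat, np.nan, np.nan, np.nan, np.nan, 1.0, "insufficient"))
            continue
        mean_a, mean_b = a.mean(), b.mean()
        log2fc = float(np.log2((mean_a + epsilon) / (mean_b + epsilon)))
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            t_stat, p = 0.0, 1.0
            flag = "zero_variance"
        else:
            t_stat, p = stats.ttest_ind(a, b, equal_var=False)
            p = float(min(max(p, np.finfo(float).tiny), 1.0))
            flag = ""
        rows.append((feat, mean_a, mean_b, log2fc, float(t_stat), p, flag))
    out = pd.DataFrame(
        rows,
        columns=["feature", f"mean_{num}", f"mean_{den}", "log2fc", "t", "p", "flag"],
    )
    valid = out["p"].notna()
    out["q"] = np.nan
    if valid.any():
        out.loc[valid, "q"] = multipletests(out.loc[valid, "p"], method="fdr_bh")[1]
    return out


def composition_pca(features: pd.DataFrame) -> dict:
    """Centered PCA of composition features via SVD (handles p > n).

    Sign convention: the largest-magnitude loading of each component is
    positive. Returns loadings (features × components), sample scores and
    the explained-variance vector.
    """
    if len(features) < 3:
        raise ConfigurationError("composition PCA needs at least 3 samples")
    x = features.fillna(0.0).to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    for j in range(vt.shape[0]):
        if vt[j, np.argmax(np.abs(vt[j]))] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    n = len(features)
    explained = s**2 / (n - 1)
    k = min(len(s), len(features.columns))
    return {
        "loadings": pd.DataFrame(
            vt[:k].T,
            index=features.columns,
            columns=[f"PC{i + 1}" for i in range(k)],
        ),
        "scores": pd.DataFrame(
            u[:, :k] * s[:k],
            index=features.index,
            columns=[f"PC{i + 1}" for i in range(k)],
        ),
        "explained_variance": explained[:k],
    }
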