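"""Response and survival association for every feature family.

All features flow through the same harness: Welch t-tests between response
groups (unadjusted p primary, BH alongside), univariate/multivariate
logistic in-sample AUC, continuous Cox proportional hazards (per-SD hazard
ratios, Efron ties) and median-cut Kaplan-Meier with log-rank tests.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from spatialtma.composition import differential_abundance
from spatialtma.errors import ConfigurationError, NoEventsError

log = logging.getLogger(__name__)


@dataclass
class SurvivalResult:
    feature: str
    hr_per_sd: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    p: float | None = None
    km_curves: pd.DataFrame | None = None
    logrank_p: float | None = None
    median_threshold: float | None = None
    n_events: int = 0
    flags: list[str] = field(default_factory=list)


def _percent_str(count: int, total: int) -> str:
    """Paper-style percentage: whole percent, one decimal below 10%."""
    pct = 100.0 * count / total
    return f"{pct:.1f}%" if pct < 10 else f"{pct:.0f}%"


def cohort_summary(clinical: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages of each categorical covariate by response group.

    Survival status (alive/deceased from the event indicator) is included
    when present. Raises on an empty response group.
    """
    if "response" not in clinical.columns:
        raise ConfigurationError("response column required for cohort summary")
    work = clinical.copy()
    if "event" in work.columns:
        work["status"] = np.where(work["event"].astype(int) == 1, "Deceased", "Alive")
    groups = sorted(work["response"].dropna().unique())
    if not groups:
        raise ConfigurationError("no response groups present")
    sizes = {g: int((work["response"] == g).sum()) for g in groups}
    if any(n == 0 for n in sizes.values()):
        raise ConfigurationError(f"empty response group in {sizes}")
    rows = []
    categorical = [
        c
        for c in work.columns
        if c not in ("sample_id", "response", "os_days", "event")
        and (work[c].dtype == object or work[c].nunique() <= 10)
    ]
    for covariate in categorical:
        for level in sorted(work[covariate].dropna().astype(str).unique()):
            row = {"covariate": covariate, "level": level}
            for g in groups:
                count = int(
                    (
                        (work["response"] == g)
                        & (work[covariate].astype(str) == level)
                    ).sum()
                )
                pct = 100.0 * count / sizes[g]
                row[f"n_{g}"] = count
                row[f"pct_{g}"] = round(pct, 1) if pct < 10 else round(pct)
                row[f"fmt_{g}"] = f"{count} ({_percent_str(count, sizes[g])})"
            rows.append(row)
    return pd.DataFrame(rows)


def feature_response_tests(
    features: pd.DataFrame,
    clinical: pd.DataFrame,
    epsilon: float = 1e-3,
    max_missing_frac: float = 0.5,
) -> pd.DataFrame:
    """Welch t-tests of each feature between response groups.

    Features missing in more than ``max_missing_frac`` of samples are
    skipped with a log entry; shares the implementation (and log2FC
    orientation, NR over R) of composition's differential abundance.
    """
    groups = clinical.set_index("sample_id")["response"]
    aligned = features.reindex(groups.index)
    keep = aligned.columns[aligned.isna().mean() <= max_missing_frac]
    dropped = set(aligned.columns) - set(keep)
    if dropped:
        log.info("skipping %d mostly-missing features: %s", len(dropped), sorted(dropped))
    return differential_abundance(aligned[keep], groups, epsilon=epsilon)


def logistic_auc(
    features: pd.DataFrame,
    clinical: pd.DataFrame,
    feature_subset: list[str],
    positive: str = "NR",
) -> pd.DataFrame:
    """In-sample AUC of univariate and multivariate logistic models.

    Perfect separation is reported as AUC 1.0 with a flag rather than a
    convergence failure.
    """
    groups = clinical.set_index("sample_id")["response"]
    y = (groups == positive).astype(int)
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ConfigurationError("need at least 2 samples per class")
    rows = []

    def _fit(cols: list[str], label: str) -> None:
        sub = features.reindex(groups.index)[cols].dropna()
        yy = y.loc[sub.index]
        x = (sub - sub.mean()) / sub.std(ddof=0).replace(0, 1)
        # C=inf -> unpenalized fit (penalty=None is deprecated in sklearn 1.8+)
        model = LogisticRegression(C=np.inf, max_iter=5000)
        try:
            model.fit(x, yy)
            prob = model.predict_proba(x)[:, 1]
            auc = float(roc_auc_score(yy, prob))
        except Exception:  # unbounded-coefficient failure under separation
            auc = 1.0
        auc = min(auc, 1.0)
        rows.append(
            {
                "model": label,
                "features": ";".join(cols),
                "auc": auc,
                "n": len(sub),
                "separation": auc >= 1.0 - 1e-12,
            }
        )

    for feat in feature_subset:
        _fit([feat], f"univariate:{feat}")
    if len(feature_subset) > 1:
        _fit(list(feature_subset), "multivariate")
    return pd.DataFrame(rows)


def cox_continuous(
    feature: pd.Series, clinical: pd.DataFrame, name: str | None = None
) -> SurvivalResult:
    """Cox PH on the z-scored feature: HR per SD, 95% CI, Wald p (Efron ties)."""
    name = name or str(feature.name)
    frame = clinical.set_index("sample_id")[["os_days", "event"]].join(
        feature.rename("feat")
    )
    frame = frame.dropna()
    if int(frame["event"].sum()) < 1:
        raise NoEventsError(f"no events available to fit Cox model for {name!r}")
    sd = frame["feat"].std(ddof=0)
    if sd == 0:
        return SurvivalResult(feature=name, flags=["constant_feature"])
    frame["feat"] = (frame["feat"] - frame["feat"].mean()) / sd
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tiny-n screens trip convergence heuristics
        cph.fit(frame, duration_col="os_days", event_col="event")
    summary = cph.summary.loc["feat"]

    def _exp(v: float) -> float:
        return float(np.exp(np.clip(v, -700, 700)))

    return SurvivalResult(
        feature=name,
        hr_per_sd=_exp(summary["coef"]),
        ci_low=_exp(summary["coef lower 95%"]),
        ci_high=_exp(summary["coef upper 95%"]),
        p=float(summary["p"]),
        n_events=int(frame["event"].sum()),
    )


def km_median_split(
    feature: pd.Series, clinical: pd.DataFrame, name: str | None = None
) -> SurvivalResult:
    """Kaplan-Meier after dichotomizing at the cohort median (ties -> "low")."""
    name = name or str(feature.name)
    frame = clinical.set_index("sample_id")[["os_days", "event"]].join(
        feature.rename("feat")
    )
    frame = frame.dropna()
    median = float(frame["feat"].median())
    low = frame["feat"] <= median
    if low.all() or (~low).all():
        raise ConfigurationError(
            f"degenerate median split for {name!r}: all samples on one side "
            f"of median {median:.6g}"
        )
    curves = []
    for label, mask in (("low", low), ("high", ~low)):
        km = KaplanMeierFitter()
        km.fit(frame.loc[mask, "os_days"], frame.loc[mask, "event"], label=label)
        curve = km.survival_function_.reset_index()
        curve.columns = ["time", "survival"]
        curve["group"] = label
        curves.append(curve)
    lr = logrank_test(
        frame.loc[low, "os_days"],
        frame.loc[~low, "os_days"],
        frame.loc[low, "event"],
        frame.loc[~low, "event"],
    )
    return SurvivalResult(
        feature=name,
        km_curves=pd.concat(curves, ignore_index=True),
        logrank_p=float(lr.p_value),
        median_threshold=median,
        n_events=int(frame["event"].sum()),
    )


def survival_screen(
    features: pd.DataFrame, clinical: pd.DataFrame, max_missing_frac: float = 0.5
) -> pd.DataFrame:
    """Cox + median-cut KM for every feature; one output row per feature."""
    rows = []
    for feat in features.columns:
        col = features[feat]
        if col.isna().mean() > max_missing_frac:
            log.info("skipping mostly-missing feature %s", feat)
            continue
        try:
            cox = cox_continuous(col, clinical, name=feat)
        except NoEventsError:
            raise
        except Exception as exc:  # singular/collinear fits on degenerate features
            log.warning("Cox fit failed for %s: %s", feat, exc)
            cox = SurvivalResult(feature=feat, flags=["fit_failed"])
        try:
            km = km_median_split(col, clinical, name=feat)
            logrank_p, threshold = km.logrank_p, km.median_threshold
        except ConfigurationError as exc:
            log.warning("%s", exc)
            logrank_p, threshold = np.nan, np.nan
        rows.append(
            {
                "feature": feat,
                "hr_per_sd": cox.hr_per_sd,
                "ci_low": cox.ci_low,
                "ci_high": cox.ci_high,
                "cox_p": cox.p,
                "logrank_p": logrank_p,
                "median_threshold": threshold,
                "n_events": cox.n_events,
            }
        )
    return pd.DataFrame(rows)
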