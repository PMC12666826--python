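"""Cohort-level QC aggregation: success rates, descriptive group summaries,
covariate correlations, and the end-to-end batch analysis driver.

Inference is deliberately limited to descriptive statistics, exact binomial
confidence intervals and Pearson bivariate correlation; group comparisons
are reported as mean percent differences, not tested.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

from .metrics import (
    DEFAULT_PARAMS,
    DetectionParams,
    RuptureMetrics,
    extract_metrics,
    segment_phases,
)
from .outcome import ClassifierThresholds, ReferenceDistribution, classify_outcome
from .protocol import LoadingProtocol, default_protocol
from .trace_io import ColumnMap, DEFAULT_COLUMN_MAP, read_trace

logger = logging.getLogger("aclrqc")

__all__ = [
    "SuccessRate",
    "CohortSummary",
    "success_rate",
    "pearson_correlation",
    "summarize",
    "batch_report",
    "metrics_to_row",
    "METRIC_COLUMNS",
]

METRIC_COLUMNS = [
    "rupture_displacement",
    "rupture_load",
    "ultimate_displacement",
    "ultimate_load",
    "linear_stiffness",
    "total_creep",
    "precond_amplitude_error_pct",
    "displacement_error_pct",
    "catch_detected",
    "drop_count",
    "post_drop_floor_load",
]

#: covariate pairs reported by default (mirrors the cohort validation plots)
DEFAULT_CORRELATION_PAIRS = (
    ("mass_g", "rupture_load"),
    ("mass_g", "rupture_displacement"),
    ("age_days", "rupture_load"),
    ("age_days", "rupture_displacement"),
)


@dataclass(frozen=True)
class SuccessRate:
    percent: float
    ci_low: float  # exact (Clopper-Pearson) 95 % CI, percent
    ci_high: float
    n_success: int
    n_total: int

    @property
    def display(self) -> str:
        return f"{self.percent:.1f} % ({self.n_success}/{self.n_total})"


def success_rate(n_success: int, n_total: int) -> SuccessRate:
    """Success percentage with an exact binomial 95 % confidence interval."""
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not 0 <= n_success <= n_total:
        raise ValueError("n_success must lie in [0, n_total]")
    lo, hi = proportion_confint(n_success, n_total, alpha=0.05, method="beta")
    return SuccessRate(
        percent=100.0 * n_success / n_total,
        ci_low=100.0 * float(lo),
        ci_high=100.0 * float(hi),
        n_success=int(n_success),
        n_total=int(n_total),
    )


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float, float]:
    """Pearson (r, r^2, p) with p from the t-transform on n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the inputs")
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    return r, r * r, float(res.pvalue)


@dataclass
class CohortSummary:
    success: SuccessRate
    group_stats: pd.DataFrame  # per-group n / mean / sd per metric
    group_success: pd.DataFrame  # per-group success rate
    percent_differences: Optional[pd.DataFrame]  # between first two groups
    correlations: pd.DataFrame  # r, r2, p, n per covariate pair


def _numeric_metric_columns(df: pd.DataFrame) -> List[str]:
    cols = []
    for c in METRIC_COLUMNS:
        if c in df.columns and pd.api.types.is_numeric_dtype(
            pd.to_numeric(df[c], errors="coerce")
        ):
            cols.append(c)
    return cols


def summarize(
    cohort: pd.DataFrame,
    group_by: Union[str, Sequence[str]] = "sex",
    correlation_pairs: Sequence[Tuple[str, str]] = DEFAULT_CORRELATION_PAIRS,
) -> CohortSummary:
    """Descriptive cohort summary: per-group n/mean/SD for each metric,
    per-group success rates, mean percent differences between groups, and
    Pearson correlations for the covariate pairs.
    """
    if len(cohort) == 0:
        raise ValueError("cohort table is empty")
    if isinstance(group_by, str):
        group_by = [group_by]
    for g in group_by:
        if g not in cohort.columns:
            raise ValueError(f"unknown group field {g!r}")

    metric_cols = _numeric_metric_columns(cohort)
    grouped = cohort.groupby(list(group_by), dropna=False)
    stats_frames = []
    for name, g in grouped:
        key = name if not isinstance(name, tuple) else "/".join(map(str, name))
        row: Dict[str, object] = {"group": key, "n": len(g)}
        for c in metric_cols:
            vals = pd.to_numeric(g[c], errors="coerce").dropna()
            row[f"{c}_mean"] = float(vals.mean()) if len(vals) else np.nan
            row[f"{c}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else np.nan
        stats_frames.append(row)
    group_stats = pd.DataFrame(stats_frames).set_index("group")

    if "label" in cohort.columns:
        n_success_total = int((cohort["label"] == "successful_aclr").sum())
        succ_rows = []
        for name, g in grouped:
            key = name if not isinstance(name, tuple) else "/".join(map(str, name))
            sr = success_rate(int((g["label"] == "successful_aclr").sum()), len(g))
            succ_rows.append(
                {
                    "group": key,
                    "success_pct": sr.percent,
                    "ci_low": sr.ci_low,
                    "ci_high": sr.ci_high,
                    "n": sr.n_total,
                }
            )
        group_success = pd.DataFrame(succ_rows).set_index("group")
    else:
        n_success_total = len(cohort)
        group_success = pd.DataFrame(
            {"success_pct": [], "ci_low": [], "ci_high": [], "n": []}
        )
    overall = success_rate(n_success_total, len(cohort))

    pct_diff = None
    if len(group_stats) >= 2:
        a, b = group_stats.index[0], group_stats.index[1]
        rows = []
        for c in metric_cols:
            ma, mb = group_stats.loc[a, f"{c}_mean"], group_stats.loc[b, f"{c}_mean"]
            denom = 0.5 * (abs(ma) + abs(mb))
            rows.append(
                {
                    "metric": c,
                    f"mean_{a}": ma,
                    f"mean_{b}": mb,
                    "percent_difference": (
                        100.0 * abs(ma - mb) / denom if denom > 0 else np.nan
                    ),
                }
            )
        pct_diff = pd.DataFrame(rows).set_index("metric")

    corr_rows = []
    for xcol, ycol in correlation_pairs:
        if xcol not in cohort.columns or ycol not in cohort.columns:
            continue
        sub = cohort[[xcol, ycol]].apply(pd.to_numeric, errors="coerce").dropna()
        if len(sub) < 3 or sub[xcol].nunique() < 2 or sub[ycol].nunique() < 2:
            continue
        r, r2, p = pearson_correlation(sub[xcol].to_numpy(), sub[ycol].to_numpy())
        corr_rows.append({"x": xcol, "y": ycol, "r": r, "r2": r2, "p": p, "n": len(sub)})
    correlations = pd.DataFrame(corr_rows)

    return CohortSummary(
        success=overall,
        group_stats=group_stats,
        group_success=group_success,
        percent_differences=pct_diff,
        correlations=correlations,
    )


def metrics_to_row(metrics: RuptureMetrics) -> Dict[str, object]:
    """Flatten a metric vector to the documented one-row CSV schema."""
    return {c: getattr(metrics, c) for c in METRIC_COLUMNS}


def batch_report(
    trace_paths: Sequence[Union[str, Path]],
    metadata: Optional[pd.DataFrame] = None,
    protocol: Optional[LoadingProtocol] = None,
    params: DetectionParams = DEFAULT_PARAMS,
    column_map: ColumnMap = DEFAULT_COLUMN_MAP,
    reference: Optional[ReferenceDistribution] = None,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
    group_by: Union[str, Sequence[str]] = "sex",
) -> Tuple[pd.DataFrame, Optional[CohortSummary], List[Tuple[str, str]]]:
    """Run read -> segment -> metrics -> classify -> summarize over a batch.

    Per-trace errors are logged and collected without aborting the batch.
    Returns (cohort table, summary or None if empty, list of
    (path, error-message) failures).  Deterministic given inputs.
    """
    if protocol is None:
        protocol = default_protocol()
    if metadata is not None and "id" in metadata.columns:
        meta_by_id = metadata.set_index(metadata["id"].astype(str))
    else:
        meta_by_id = None

    rows: List[Dict[str, object]] = []
    failures: List[Tuple[str, str]] = []
    for path in trace_paths:
        path = Path(path)
        try:
            trace = read_trace(path, column_map)
            seg = segment_phases(trace, protocol, params=params)
            metrics = extract_metrics(trace, seg, protocol, params)
            row: Dict[str, object] = {"id": path.stem}
            if meta_by_id is not None and path.stem in meta_by_id.index:
                meta_row = meta_by_id.loc[path.stem]
                for c in (
                    "sex",
                    "age_days",
                    "mass_g",
                    "operator",
                    "institution",
                    "strain_group",
                ):
                    if c in meta_row.index:
                        row[c] = meta_row[c]
            row.update(metrics_to_row(metrics))
            call = classify_outcome(
                metrics, reference, thresholds, sex=row.get("sex")
            )
            row["label"] = call.label
            row["warnings"] = ";".join(call.warnings)
            rows.append(row)
            logger.info("analyzed %s: %s", path.name, call.label)
        except Exception as err:  # noqa: BLE001 - batch must not abort
            failures.append((str(path), str(err)))
            logger.error("failed %s: %s", path.name, err)

    if not rows:
        raise ValueError(
            "no readable traces in batch; first error: "
            + (failures[0][1] if failures else "none")
        )
    table = pd.DataFrame(rows)
    if metadata is not None and "id" in metadata.columns:
        known = set(metadata["id"].astype(str))
        missing = sorted(set(table["id"]) - known)
        if missing:
            logger.warning("trace ids missing from metadata: %s", missing)
    summary = None
    gb = [group_by] if isinstance(group_by, str) else list(group_by)
    if all(g in table.columns for g in gb):
        summary = summarize(table, gb)
    return table, summary, failures
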