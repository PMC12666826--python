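"""Rule-based classification of procedure outcome from QC metrics.

The mechanical signatures of the four outcomes are qualitative but
distinct: a successful rupture shows an abrupt partial load drop followed
by a catch; an unsuccessful procedure shows no failure event at all; a
tibial fracture unloads the joint completely with no catch; a physeal
displacement shows a failure event with markedly elevated linear stiffness
(bone rather than ligament engagement).  Stiffness and creep outliers are
judged by z-scores against a reference distribution built from previously
reviewed successful procedures; elevated creep raises a positioning
warning on any label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .metrics import RuptureMetrics

__all__ = [
    "OutcomeCall",
    "ReferenceDistribution",
    "ClassifierThresholds",
    "build_reference",
    "classify_outcome",
    "OUTCOME_LABELS",
]

OUTCOME_LABELS = (
    "successful_aclr",
    "unsuccessful_rupture",
    "tibial_fracture",
    "physis_rupture",
)

#: metrics the reference tracks for z-scoring
_REFERENCE_METRICS = (
    "rupture_displacement",
    "rupture_load",
    "ultimate_load",
    "linear_stiffness",
    "total_creep",
)


@dataclass(frozen=True)
class ClassifierThresholds:
    z_stiffness: float = 2.5  # physis rule
    z_creep: float = 2.5  # positioning warning
    floor_min: float = 0.5  # N, below which a drop means full unloading


@dataclass(frozen=True)
class OutcomeCall:
    label: str
    fired_rules: Tuple[str, ...]
    warnings: Tuple[str, ...] = ()
    reference_zscores: Optional[Dict[str, float]] = None

    def __post_init__(self) -> None:
        if self.label not in OUTCOME_LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if not self.fired_rules:
            raise ValueError("fired_rules must be non-empty")


@dataclass(frozen=True)
class ReferenceDistribution:
    """Per-metric mean/SD from a cohort of successful procedures.

    ``stats`` maps stratum -> metric -> (mean, sd); the unstratified
    reference uses the single stratum ``"all"``.
    """

    stats: Dict[str, Dict[str, Tuple[float, float]]]
    n: Dict[str, int]
    provenance: str = "unspecified"

    def stratum(self, sex: Optional[str] = None) -> Dict[str, Tuple[float, float]]:
        if sex is not None and sex in self.stats:
            return self.stats[sex]
        return self.stats["all"] if "all" in self.stats else next(iter(self.stats.values()))


def build_reference(
    metric_table: pd.DataFrame,
    stratify_by_sex: bool = False,
    min_n: int = 20,
    provenance: str = "cohort",
) -> ReferenceDistribution:
    """Build a reference distribution from successful procedures only.

    ``metric_table`` holds one row per procedure with RuptureMetrics columns
    (and a ``sex`` column if stratifying).  Raises when a stratum has fewer
    than ``min_n`` rows or a metric with zero spread.
    """
    if stratify_by_sex:
        if "sex" not in metric_table.columns:
            raise ValueError("stratified reference requires a 'sex' column")
        groups = {str(s): g for s, g in metric_table.groupby("sex")}
    else:
        groups = {"all": metric_table}

    stats: Dict[str, Dict[str, Tuple[float, float]]] = {}
    counts: Dict[str, int] = {}
    for name, g in groups.items():
        if len(g) < min_n:
            raise ValueError(
                f"reference stratum {name!r} has n={len(g)}, needs at least {min_n}"
            )
        entry = {}
        for metric in _REFERENCE_METRICS:
            if metric not in g.columns:
                continue
            vals = pd.to_numeric(g[metric], errors="coerce").dropna().to_numpy()
            if vals.size < min_n:
                continue
            mean = float(np.mean(vals))
            sd = float(np.std(vals, ddof=1))
            if sd <= 0:
                raise ValueError(
                    f"metric {metric!r} has zero spread in stratum {name!r}; "
                    "cannot form z-scores"
                )
            entry[metric] = (mean, sd)
        stats[name] = entry
        counts[name] = int(len(g))
    return ReferenceDistribution(stats=stats, n=counts, provenance=provenance)


def _zscores(
    metrics: RuptureMetrics, reference: ReferenceDistribution, sex: Optional[str]
) -> Dict[str, float]:
    ref = reference.stratum(sex)
    out = {}
    for name, (mean, sd) in ref.items():
        value = getattr(metrics, name, None)
        if value is not None:
            out[name] = (float(value) - mean) / sd
    return out


def classify_outcome(
    metrics: RuptureMetrics,
    reference: Optional[ReferenceDistribution] = None,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
    sex: Optional[str] = None,
) -> OutcomeCall:
    """Classify one procedure.  Deterministic given metrics + reference.

    Decision rules in order: no rupture event -> unsuccessful rupture;
    rupture whose post-drop load floor falls below ``floor_min`` with no
    catch -> tibial fracture; rupture + catch with stiffness z-score at or
    above ``z_stiffness`` -> physis rupture; rupture + catch otherwise ->
    successful rupture.  Without a reference the z-rules are disabled and
    that is recorded in ``fired_rules``.
    """
    fired: List[str] = []
    warnings: List[str] = []
    z = _zscores(metrics, reference, sex) if reference is not None else None

    ruptured = metrics.rupture_displacement is not None
    if not ruptured:
        fired.append("no_rupture_event")
        label = "unsuccessful_rupture"
    elif not metrics.catch_detected and (
        metrics.post_drop_floor_load is None
        or metrics.post_drop_floor_load < thresholds.floor_min
    ):
        fired.append("full_unloading_no_catch")
        label = "tibial_fracture"
    else:
        stiff_z = None if z is None else z.get("linear_stiffness")
        if reference is None:
            fired.append("zscore_rules_disabled_no_reference")
        if stiff_z is not None and stiff_z >= thresholds.z_stiffness:
            fired.append("stiffness_outlier_physis")
            label = "physis_rupture"
        else:
            fired.append("rupture_with_catch")
            label = "successful_aclr"

    if z is not None:
        creep_z = z.get("total_creep")
        if creep_z is not None and creep_z >= thresholds.z_creep:
            warnings.append("high_creep_possible_improper_positioning")

    return OutcomeCall(
        label=label,
        fired_rules=tuple(fired),
        warnings=tuple(warnings),
        reference_zscores=z,
    )
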