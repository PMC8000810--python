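"""Conventional SUV baseline: one-way ANOVA of SUV metrics between label
groups, and SUV-only predictive models run through the identical Monte Carlo
validation machinery for a cell-for-cell comparison with holomic models."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .extract import FeatureTable
from .preprocessing import PreprocessPlan
from .suv import SUV_METRICS
from .validation import ModelReport, monte_carlo_cv

SIGNIFICANCE_LEVEL = 0.05


@dataclass
class SuvComparison:
    label_name: str
    f_stats: dict[str, float]
    p_values: dict[str, float]

    def significant(self, metric: str) -> bool:
        return self.p_values[metric] < SIGNIFICANCE_LEVEL

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "metric": list(self.f_stats),
            "F": list(self.f_stats.values()),
            "p": list(self.p_values.values()),
            "significant": [self.significant(m) for m in self.f_stats],
        })


def anova_suv(table: FeatureTable, label_name: str) -> SuvComparison:
    """One-way ANOVA F and p per SUV metric between the label groups.

    Rows with an NA label are excluded. With two groups this is the squared
    two-sample t test; identical group values give F = 0, p = 1.
    """
    sub = table.rows_with_label(label_name)
    y = sub.labels[label_name].to_numpy(dtype=float)
    groups = np.unique(y)
    if len(groups) < 2:
        raise ValueError(f"label {label_name!r} has fewer than 2 groups")
    f_stats, p_values = {}, {}
    for metric in SUV_METRICS:
        samples = [sub.features.loc[y == g, metric].to_numpy() for g in groups]
        if any(len(s) < 2 for s in samples):
            raise ValueError(f"label {label_name!r}: a group has fewer than 2 rows")
        if np.ptp(np.concatenate(samples)) == 0:
            f, p = 0.0, 1.0
        else:
            f, p = stats.f_oneway(*samples)
        f_stats[metric] = float(f)
        p_values[metric] = float(p)
    return SuvComparison(label_name, f_stats, p_values)


def suv_only_validate(
    table: FeatureTable,
    label_name: str,
    plan: PreprocessPlan | None = None,
    which: str = "suvmax_only",
    **cv_kwargs,
) -> ModelReport:
    """The Monte Carlo CV pipeline restricted to SUV features.

    ``which`` selects ``suvmax_only`` (a single feature) or ``all_suv`` (all
    five SUV metrics). The R² selection step is skipped — with at most five
    features there is nothing to select — while the other plan steps apply
    unchanged, so reports compare cell-for-cell with holomic reports.
    """
    if which == "suvmax_only":
        cols = ["suv_max"]
    elif which == "all_suv":
        cols = list(SUV_METRICS)
    else:
        raise ValueError(f"unknown SUV subset {which!r}")
    plan = plan if plan is not None else PreprocessPlan.none()
    reduced_plan = PreprocessPlan(
        steps=tuple(s for s in plan.steps if s != "select"),
        outlier_k=plan.outlier_k, outlier_min_frac=plan.outlier_min_frac,
        rank_top_n=plan.rank_top_n, corr_threshold=plan.corr_threshold,
        smote_k=plan.smote_k, seed=plan.seed,
    )
    sub_table = FeatureTable(
        table.features[cols], table.labels, table.patient_ids, table.groups
    )
    return monte_carlo_cv(sub_table, label_name, reduced_plan, **cv_kwargs)
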