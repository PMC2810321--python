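"""Group statistics on expression tables: percent-of-control
normalization, one-way ANOVA, Tukey HSD, percent-change summaries, and
the model-vs-gene match report.

The analysis treats groups as independent animals, so a one-way
between-groups ANOVA with Tukey's post-hoc test is used, and degrees of
freedom follow the usual (k-1, N-k) decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


@dataclass(frozen=True)
class ComparisonReport:
    gene: str
    group_a: str
    group_b: str
    percent_change: float
    tukey_p: float
    significant: bool


def percent_of_control(
    table: pd.DataFrame, control_group: str = "Control"
) -> pd.DataFrame:
    """Rescale each gene so the control-group mean maps to exactly 100.

    Idempotent on tables whose control mean is already 100.
    """
    out = table.copy()
    for gene, sub in table.groupby("gene"):
        ctrl = sub.loc[sub["group"] == control_group, "value"]
        if len(ctrl) == 0:
            raise ValueError(f"gene {gene}: control group {control_group!r} missing")
        m = ctrl.mean()
        if m <= 0:
            raise ValueError(f"gene {gene}: control mean is not positive")
        out.loc[sub.index, "value"] = sub["value"] * 100.0 / m
    return out


def one_way_anova(values: np.ndarray, labels: np.ndarray) -> AnovaResult:
    """Classical between/within decomposition, F = MSB/MSW."""
    groups = _split(values, labels)
    f, p = stats.f_oneway(*groups)
    k = len(groups)
    n = sum(len(g) for g in groups)
    return AnovaResult(F=float(f), df_between=k - 1, df_within=n - k, p=float(p))


def tukey_hsd(
    values: np.ndarray, labels: np.ndarray, gene: str = "", alpha: float = 0.05
) -> list[ComparisonReport]:
    """All pairwise comparisons with studentized-range p-values."""
    labels = np.asarray(labels)
    names = list(dict.fromkeys(labels))  # preserve first-appearance order
    groups = _split(values, labels, names)
    res = stats.tukey_hsd(*groups)
    means = [float(np.mean(g)) for g in groups]
    reports = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            pval = float(res.pvalue[i, j])
            change = _pct_change(means[i], means[j])
            reports.append(
                ComparisonReport(
                    gene=gene,
                    group_a=names[i],
                    group_b=names[j],
                    percent_change=change,
                    tukey_p=pval,
                    significant=pval < alpha,
                )
            )
    return reports


def percent_change(
    table: pd.DataFrame, gene: str, group_a: str, group_b: str
) -> float:
    """100 * (mean_a - mean_b) / mean_b for one gene."""
    sub = table[table["gene"] == gene]
    means = {}
    for g in (group_a, group_b):
        vals = sub.loc[sub["group"] == g, "value"]
        if len(vals) == 0:
            raise ValueError(f"gene {gene}: group {g!r} missing")
        means[g] = vals.mean()
    return _pct_change(means[group_a], means[group_b])


def gene_anova_table(table: pd.DataFrame) -> dict[str, AnovaResult]:
    return {
        gene: one_way_anova(sub["value"].to_numpy(), sub["group"].to_numpy())
        for gene, sub in table.groupby("gene")
    }


def gene_tukey_table(table: pd.DataFrame, alpha: float = 0.05) -> list[ComparisonReport]:
    out: list[ComparisonReport] = []
    for gene, sub in table.groupby("gene"):
        out.extend(
            tukey_hsd(sub["value"].to_numpy(), sub["group"].to_numpy(), gene, alpha)
        )
    return out


def match_report(
    scaled_plasticity: np.ndarray,
    gene_values: dict[str, float],
    anchor_trial: int = 70,
    compare_trial: int = 120,
    tolerance: float = 10.0,
) -> dict:
    """Compare the anchored plasticity trajectory with a gene's two
    stage values (50%CR at the anchor trial, 100%CR at the comparison
    trial), both on the percent-of-control scale.

    ``gene_values`` maps the stage group names ("50%CR", "100%CR") to
    mean expression.  Passing requires the trajectory value at the
    comparison trial to lie within ``tolerance`` percentage points of
    the gene's trained-stage value.
    """
    n = len(scaled_plasticity)
    for trial in (anchor_trial, compare_trial):
        if not 1 <= trial <= n:
            raise ValueError(f"trial {trial} outside the scaled series")
    sim_anchor = float(scaled_plasticity[anchor_trial - 1])
    sim_compare = float(scaled_plasticity[compare_trial - 1])
    gene_anchor = float(gene_values["50%CR"])
    gene_compare = float(gene_values["100%CR"])
    abs_disc = abs(sim_compare - gene_compare)
    rel_disc = abs_disc / gene_compare * 100.0
    sim_decline = 100.0 * (sim_anchor - sim_compare) / sim_anchor
    gene_decline = 100.0 * (gene_anchor - gene_compare) / gene_anchor
    return {
        "anchor_trial": anchor_trial,
        "compare_trial": compare_trial,
        "sim_anchor": sim_anchor,
        "sim_compare": sim_compare,
        "gene_anchor": gene_anchor,
        "gene_compare": gene_compare,
        "abs_discrepancy": abs_disc,
        "rel_discrepancy_pct": rel_disc,
        "sim_decline_pct": sim_decline,
        "gene_decline_pct": gene_decline,
        "tolerance": tolerance,
        "pass": bool(abs_disc <= tolerance),
    }


def _split(values, labels, names=None):
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if names is None:
        names = list(dict.fromkeys(labels))
    if len(names) < 2:
        raise ValueError("need at least two groups")
    groups = [values[labels == name] for name in names]
    for name, g in zip(names, groups):
        if len(g) < 2:
            raise ValueError(f"group {name!r} has fewer than two values")
    return groups


def _pct_change(mean_a: float, mean_b: float) -> float:
    if mean_b == 0:
        raise ValueError("reference group mean is zero; percent change undefined")
    return float(100.0 * (mean_a - mean_b) / mean_b)
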