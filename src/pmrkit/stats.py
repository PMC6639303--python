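"""Two-group comparisons and figure-style summary output.

The assays these tools quantify are presented as two-group comparisons
(healthy vs patient, treated vs vehicle): unpaired Student's t-test when
both samples pass a Shapiro–Wilk normality check and a median-centred
Levene equal-variance check, otherwise the Mann–Whitney rank-sum test.
Tests are two-sided throughout.  The exact Mann–Whitney null distribution
is used for small samples (both n ≤ 8, no ties); otherwise the normal
approximation with tie correction.  No multiple-testing correction is
applied by default; Holm adjustment is available behind a flag for users
comparing many metrics at once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["GroupComparison", "compare_groups", "holm_adjust", "render_summary"]

_ALPHA = 0.05  # significance level of the pre-tests in auto mode


@dataclass
class GroupComparison:
    """Result of one two-group comparison."""

    group_a: str
    group_b: str
    test: str                   # student_t | mann_whitney
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    effect_summary: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must be in [0, 1]")


def compare_groups(
    values_a,
    values_b,
    test: str = "auto",
    group_a: str = "A",
    group_b: str = "B",
) -> GroupComparison:
    """Compare two independent samples.

    ``test='auto'`` runs Shapiro–Wilk on each sample and a median-centred
    Levene test across them; Student's unpaired t is used when all three
    pass at α = 0.05, otherwise Mann–Whitney.  The chosen test is recorded.
    Two identical constant samples give p = 1 with a zero-variance warning.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least two values")
    if test not in ("auto", "student_t", "mann_whitney"):
        raise ValueError(f"unknown test {test!r}")

    effect = {
        "mean_a": float(a.mean()),
        "sem_a": float(a.std(ddof=1) / np.sqrt(len(a))),
        "mean_b": float(b.mean()),
        "sem_b": float(b.std(ddof=1) / np.sqrt(len(b))),
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
    }
    meta: dict = {"requested": test}

    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        warnings.warn(
            "both samples are constant and identical; comparison is vacuous",
            stacklevel=2,
        )
        chosen = "mann_whitney" if test in ("auto", "mann_whitney") else test
        return GroupComparison(
            group_a, group_b, chosen, float("nan"), 1.0, len(a), len(b),
            effect, {**meta, "zero_variance": True},
        )

    if test == "auto":
        if min(len(a), len(b)) < 3:
            raise ValueError("auto test selection needs ≥3 values per sample")
        normal_a = np.ptp(a) > 0 and sps.shapiro(a).pvalue > _ALPHA
        normal_b = np.ptp(b) > 0 and sps.shapiro(b).pvalue > _ALPHA
        equal_var = sps.levene(a, b, center="median").pvalue > _ALPHA
        chosen = "student_t" if (normal_a and normal_b and equal_var) else "mann_whitney"
        meta.update(
            {"shapiro_ok": (normal_a, normal_b), "levene_ok": bool(equal_var)}
        )
    else:
        chosen = test

    if chosen == "student_t":
        res = sps.ttest_ind(a, b, equal_var=True)
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        ties = len(np.unique(pooled)) < len(pooled)
        exact = max(len(a), len(b)) <= 8 and not ties
        method = "exact" if exact else "asymptotic"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        stat, p = float(res.statistic), float(res.pvalue)
        meta["mwu_method"] = method
    return GroupComparison(
        group_a, group_b, chosen, stat, min(p, 1.0), len(a), len(b), effect, meta
    )


def holm_adjust(p_values: list[float]) -> list[float]:
    """Holm step-down adjusted p-values (optional; off by default)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(running, 1.0)
    return adjusted.tolist()


def render_summary(
    per_cell_tables: dict[str, pd.DataFrame],
    grouping: str = "group",
    out_dir: str | Path = ".",
) -> dict[str, pd.DataFrame]:
    """Figure-style mean ± SEM summaries for assay output tables.

    For each named table, every numeric column is summarised per group
    (mean, SEM, n) into ``<name>_summary.csv``, and a bar-with-scatter plot
    per metric is written as ``<name>_<metric>.png``.  With exactly two
    groups each plot is annotated with the auto-selected test's p-value.
    Kinetic tables (with a ``time`` column) get a mean ± SEM time-course
    plot instead.  Returns the summary tables.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not per_cell_tables:
        raise ValueError("no input tables supplied")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summaries: dict[str, pd.DataFrame] = {}

    for name, table in per_cell_tables.items():
        if grouping not in table.columns:
            raise ValueError(f"table {name!r} is missing column {grouping!r}")
        groups = list(pd.unique(table[grouping]))

        if "time" in table.columns:
            value_cols = [
                c
                for c in table.select_dtypes("number").columns
                if c != "time"
            ]
            fig, axes = plt.subplots(
                1, len(value_cols), figsize=(4 * len(value_cols), 3), squeeze=False
            )
            for ax, col in zip(axes[0], value_cols):
                for g in groups:
                    sub = table[table[grouping] == g]
                    agg = sub.groupby("time")[col].agg(["mean", "sem", "count"])
                    ax.plot(agg.index, agg["mean"], label=str(g))
                    ax.fill_between(
                        agg.index,
                        agg["mean"] - agg["sem"].fillna(0),
                        agg["mean"] + agg["sem"].fillna(0),
                        alpha=0.3,
                    )
                ax.set_xlabel("time (s)")
                ax.set_ylabel(col)
                ax.legend(fontsize=7)
            fig.tight_layout()
            fig.savefig(out_dir / f"{name}_timecourse.png", dpi=120)
            plt.close(fig)
            summary = (
                table.groupby([grouping, "time"])[value_cols]
                .agg(["mean", "sem", "count"])
                .reset_index()
            )
        else:
            value_cols = list(table.select_dtypes("number").columns)
            if not value_cols:
                raise ValueError(f"table {name!r} has no numeric columns")
            rows = []
            for col in value_cols:
                fig, ax = plt.subplots(figsize=(3, 3))
                for i, g in enumerate(groups):
                    vals = table.loc[table[grouping] == g, col].dropna().to_numpy()
                    if len(vals) == 0:
                        continue
                    mean = vals.mean()
                    sem = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0
                    ax.bar(i, mean, yerr=sem, capsize=4, alpha=0.6)
                    ax.scatter(
                        np.full(len(vals), i)
                        + np.linspace(-0.15, 0.15, len(vals)),
                        vals,
                        s=8,
                        color="k",
                        zorder=3,
                    )
                    rows.append(
                        {
                            grouping: g,
                            "metric": col,
                            "mean": mean,
                            "sem": sem,
                            "n": len(vals),
                        }
                    )
                ax.set_xticks(range(len(groups)))
                ax.set_xticklabels([str(g) for g in groups], fontsize=8)
                ax.set_ylabel(col)
                if len(groups) == 2:
                    va = table.loc[table[grouping] == groups[0], col].dropna()
                    vb = table.loc[table[grouping] == groups[1], col].dropna()
                    if len(va) >= 3 and len(vb) >= 3:
                        cmp = compare_groups(
                            va, vb, group_a=str(groups[0]), group_b=str(groups[1])
                        )
                        ax.set_title(
                            f"{cmp.test}: p = {cmp.p_value:.3g}", fontsize=8
                        )
                fig.tight_layout()
                fig.savefig(out_dir / f"{name}_{col}.png", dpi=120)
                plt.close(fig)
            summary = pd.DataFrame(rows)
        summary.to_csv(out_dir / f"{name}_summary.csv", index=False)
        summaries[name] = summary
    return summaries
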