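"""Cohort aggregation, two-group comparison, and the stacked-contribution
figure.

The unit of analysis is one row per subject per task, carrying the total
reach displacement, each component in mm, and each component as a signed
percentage.  Group comparisons are run on the percentages with a
pooled-variance two-sample t test by default (a Welch variant is available
and generally preferable with unequal group sizes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .decomposition import component_names, components_mapping, percents_mapping
from .errors import CohortDataError
from .markers import Task
from .trial import SubjectRecord

GROUPS = ("healthy", "stroke")


def table_columns(task: Task) -> list[str]:
    comps = component_names(task)
    return (
        ["subject_id", "group", "task", "total_mm"]
        + [f"{c}_mm" for c in comps]
        + [f"{c}_pct" for c in comps]
        + ["denominator_mode"]
    )


def build_cohort_table(
    entries: list[tuple[SubjectRecord, object]],
) -> pd.DataFrame:
    """Assemble per-trial decompositions into a flat cohort table.

    ``entries`` pairs each subject with a decomposition result (forward
    reach or hand-to-mouth; mixing tasks in one table is allowed — rows
    carry their task and task-specific component columns).
    """
    rows = []
    for subject, dec in entries:
        row: dict[str, object] = {
            "subject_id": subject.subject_id,
            "group": subject.group,
            "task": dec.task.value,
            "total_mm": dec.total,
            "denominator_mode": dec.denominator_mode,
        }
        for name, mm in components_mapping(dec).items():
            row[f"{name}_mm"] = mm
        for name, pct in percents_mapping(dec).items():
            row[f"{name}_pct"] = pct
        rows.append(row)
    return pd.DataFrame(rows)


def _task_rows(table: pd.DataFrame, task: Task) -> pd.DataFrame:
    task = Task(task)
    rows = table[table["task"] == task.value]
    if rows.empty:
        raise CohortDataError(f"no rows for task {task.value}")
    return rows


def summarize_cohort(table: pd.DataFrame, task: Task | str) -> pd.DataFrame:
    """Per-group, per-component mean and sample SD (n-1) of the percents.

    Single-subject groups get an SD of NaN with a warning; empty groups in
    the table raise :class:`CohortDataError`.
    """
    task = Task(task)
    rows = _task_rows(table, task)
    out = []
    for group, sub in rows.groupby("group", sort=True):
        if sub.empty:
            raise CohortDataError(f"group {group} has no rows")
        if len(sub) == 1:
            warnings.warn(f"group {group!r} has a single subject; SD undefined")
        for comp in component_names(task):
            vals = sub[f"{comp}_pct"].to_numpy(dtype=float)
            out.append(
                {
                    "group": group,
                    "component": comp,
                    "n": len(vals),
                    "mean_pct": float(np.mean(vals)),
                    "sd_pct": float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan,
                    "mean_mm": float(sub[f"{comp}_mm"].mean()),
                }
            )
    return pd.DataFrame(out)


@dataclass(frozen=True)
class TTestResult:
    """Two-sample comparison of one component between groups."""

    component: str
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t: float
    df: float
    p: float
    significant: bool
    degenerate: bool = False
    method: str = "student"


def student_t_compare(
    a: list[float] | np.ndarray,
    b: list[float] | np.ndarray,
    alpha: float = 0.05,
    *,
    welch: bool = False,
    component: str = "",
) -> TTestResult:
    """Two-sided two-sample t test (pooled variance by default).

    With zero pooled variance, equal means give ``t = 0, p = 1`` by
    convention; unequal means are flagged degenerate (``p = 0``).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise CohortDataError("each group needs >= 2 values for a t test")
    method = "welch" if welch else "student"
    df = (len(a) + len(b) - 2) if not welch else np.nan
    base = dict(
        component=component,
        mean_a=float(np.mean(a)),
        sd_a=float(np.std(a, ddof=1)),
        n_a=len(a),
        mean_b=float(np.mean(b)),
        sd_b=float(np.std(b, ddof=1)),
        n_b=len(b),
        method=method,
    )
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return TTestResult(**base, t=0.0, df=float(df), p=1.0, significant=False)
        return TTestResult(
            **base, t=np.inf, df=float(df), p=0.0, significant=True, degenerate=True
        )
    res = stats.ttest_ind(a, b, equal_var=not welch)
    t = float(res.statistic)
    p = float(res.pvalue)
    df = float(res.df)
    return TTestResult(**base, t=t, df=df, p=p, significant=bool(p < alpha))


def _holm(pvals: list[float]) -> list[float]:
    """Holm step-down adjusted p values."""
    m = len(pvals)
    order = np.argsort(pvals)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted.tolist()


def compare_components_table(
    table: pd.DataFrame,
    task: Task | str,
    alpha: float = 0.05,
    *,
    welch: bool = False,
    holm: bool = False,
) -> pd.DataFrame:
    """Per-component healthy-vs-stroke comparison of percent contributions.

    Returns one row per component: group means/SDs, t, df, p, and a
    significance flag at ``alpha``.  No multiplicity correction by default;
    ``holm=True`` applies a Holm step-down adjustment before flagging.
    """
    task = Task(task)
    rows = _task_rows(table, task)
    for group in GROUPS:
        if (rows["group"] == group).sum() == 0:
            raise CohortDataError(f"group {group!r} missing from table")
    results = []
    for comp in component_names(task):
        healthy = rows.loc[rows["group"] == "healthy", f"{comp}_pct"].to_numpy()
        stroke = rows.loc[rows["group"] == "stroke", f"{comp}_pct"].to_numpy()
        results.append(
            student_t_compare(healthy, stroke, alpha, welch=welch, component=comp)
        )
    pvals = [r.p for r in results]
    adj = _holm(pvals) if holm else pvals
    return pd.DataFrame(
        {
            "component": [r.component for r in results],
            "healthy_mean_pct": [r.mean_a for r in results],
            "healthy_sd_pct": [r.sd_a for r in results],
            "healthy_n": [r.n_a for r in results],
            "stroke_mean_pct": [r.mean_b for r in results],
            "stroke_sd_pct": [r.sd_b for r in results],
            "stroke_n": [r.n_b for r in results],
            "t": [r.t for r in results],
            "df": [r.df for r in results],
            "p": pvals,
            "p_adjusted": adj,
            "significant": [bool(p < alpha) for p in adj],
            "degenerate": [r.degenerate for r in results],
            "method": [r.method for r in results],
        }
    )


# ---------------------------------------------------------------------------
# plotting

_COMPONENT_COLORS = {
    "shoulder_elbow": "tab:orange",
    "trunk_flexion": "tab:green",
    "trunk_rotation": "gold",
    "shoulder_elbow_flexion": "tab:orange",
    "cervical_flexion": "tab:green",
    "girdle_elevation": "gold",
    "shoulder_abduction": "lightskyblue",
}


def plot_stacked_contributions(
    table: pd.DataFrame,
    task: Task | str,
    output: str,
    alpha: float = 0.05,
) -> str:
    """Render per-group stacked bars of mean component contributions.

    Left panel: mean component displacements (mm) stacked per group, with
    negative components stacked below the baseline.  Right panel: the same
    as percent of the total.  When both groups are present, components
    whose comparison is significant at ``alpha`` are starred.  Output is
    deterministic for fixed input (SVG hash salt pinned).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    matplotlib.rcParams["svg.hashsalt"] = "reachcomp"

    task = Task(task)
    summary = summarize_cohort(table, task)
    groups = sorted(summary["group"].unique())
    comps = component_names(task)

    sig: dict[str, bool] = {}
    pvals: dict[str, float] = {}
    if set(GROUPS) <= set(groups):
        comparison = compare_components_table(table, task, alpha)
        sig = dict(zip(comparison["component"], comparison["significant"]))
        pvals = dict(zip(comparison["component"], comparison["p"]))

    fig, (ax_mm, ax_pct) = plt.subplots(1, 2, figsize=(9, 4.5))
    for ax, field in ((ax_mm, "mean_mm"), (ax_pct, "mean_pct")):
        for gi, group in enumerate(groups):
            gsum = summary[summary["group"] == group].set_index("component")
            up, down = 0.0, 0.0
            for comp in comps:
                v = float(gsum.loc[comp, field])
                bottom = up if v >= 0 else down
                ax.bar(
                    gi,
                    v,
                    bottom=bottom,
                    width=0.6,
                    color=_COMPONENT_COLORS.get(comp, "gray"),
                    edgecolor="black",
                    linewidth=0.5,
                    label=comp if gi == 0 else None,
                )
                if v >= 0:
                    up += v
                else:
                    down += v
        ax.axhline(0.0, color="black", linewidth=0.8)
        ax.set_xticks(range(len(groups)))
        ax.set_xticklabels(groups)
    ax_mm.set_ylabel("mean component displacement (mm)")
    ax_pct.set_ylabel("mean contribution (% of total)")
    ax_pct.set_ylim(bottom=min(0, ax_pct.get_ylim()[0]))

    starred = [c for c in comps if sig.get(c)]
    if starred:
        notes = [
            f"* {c}: p={pvals[c]:.3g}" for c in starred
        ]
        fig.suptitle(f"{task.value}   " + "   ".join(notes), fontsize=9)
    else:
        fig.suptitle(task.value, fontsize=10)
    handles, labels = ax_mm.get_legend_handles_labels()
    fig.legend(handles, labels, loc="lower center", ncol=len(comps), fontsize=8,
               frameon=False)
    fig.tight_layout(rect=(0, 0.08, 1, 0.95))
    try:
        fig.savefig(output, metadata=_deterministic_metadata(output))
    except OSError as exc:
        plt.close(fig)
        raise OSError(f"cannot write figure to {output}: {exc}") from exc
    plt.close(fig)
    return str(output)


def _deterministic_metadata(output: str) -> dict | None:
    """Strip timestamps so identical inputs give identical bytes."""
    out = str(output).lower()
    if out.endswith(".svg"):
        return {"Date": None}
    if out.endswith(".png"):
        return {"Software": None}
    return None
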