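"""Contribution quantification and group comparison.

Fitted band areas are expressed as percentages of the overall fitted
(positive) spectral area; absolute contributions are the percentages
rescaled by each sample's measured pre-normalization integrated area.
The arachidonic-acid / retinol percentage ratio summarizes the balance
between lipid- and retinol-derived emission.  Group summaries report
mean ± standard error per component with two-sided tests of each
treatment group against the reference group (Welch's unequal-variance
t-test by default, Mann–Whitney rank-sum as an alternative), starred
``*`` for p <= 0.05 and ``**`` for p <= 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import FitResult

__all__ = [
    "ContributionRecord",
    "CohortTable",
    "percent_contributions",
    "absolute_contributions",
    "aa_ret_ratio",
    "contribution_record",
    "summarize_groups",
    "reporting_filter",
    "compare_total_areas",
    "render_table",
]


@dataclass(frozen=True)
class ContributionRecord:
    """Per-sample component contributions, relative and absolute."""

    sample_id: str
    group: str
    excitation: int
    percent: dict[str, float]
    absolute: dict[str, float]
    total_measured_area: float
    aa_ret_ratio: float
    negative_percent: dict[str, float] = field(default_factory=dict)


@dataclass
class CohortTable:
    """Group-level summary: records, mean ± SE, tests vs reference."""

    records: list[ContributionRecord]
    summaries: pd.DataFrame  # columns: group, component, mean, se, n
    tests: pd.DataFrame      # columns: group, component, p_value, flag
    reference_group: str
    n_per_group: dict[str, int]
    value_kind: str = "percent"


def percent_contributions(fit: FitResult) -> dict[str, float]:
    """Component areas as percent of the overall (positive) fitted area.

    Negative compensation bands are excluded from the denominator and
    reported with negative sign; positive components sum to 100.
    """
    if not fit.converged:
        raise ValueError(f"{fit.sample_id}: fit did not converge")
    pos_total = sum(a for a in fit.component_areas.values() if a > 0)
    if pos_total <= 0:
        raise ValueError(f"{fit.sample_id}: zero positive fitted area")
    return {name: 100.0 * a / pos_total for name, a in fit.component_areas.items()}


def absolute_contributions(percent: dict[str, float],
                           total_measured_area: float) -> dict[str, float]:
    """Rescale percentage contributions by the measured integrated area."""
    if not (total_measured_area > 0):
        raise ValueError(f"total_measured_area must be > 0, got {total_measured_area}")
    return {name: p / 100.0 * total_measured_area for name, p in percent.items()}


def aa_ret_ratio(percent: dict[str, float], decimals: int | None = None) -> float:
    """Arachidonic-acid / retinol percentage ratio.

    ``decimals=2`` gives report-style rounding (used on group means).
    """
    ret = percent.get("retinol", 0.0)
    if ret <= 0:
        raise ZeroDivisionError("retinol percent must be > 0 for the AA/Ret ratio")
    ratio = percent.get("arachidonic_acid", 0.0) / ret
    return round(ratio, decimals) if decimals is not None else ratio


def contribution_record(fit: FitResult) -> ContributionRecord:
    """Build the per-sample contribution record from a converged fit."""
    pct = percent_contributions(fit)
    if fit.total_measured_area is None:
        raise ValueError(f"{fit.sample_id}: fit carries no measured total area")
    positive = {k: v for k, v in pct.items() if v >= 0}
    negative = {k: v for k, v in pct.items() if v < 0}
    return ContributionRecord(
        sample_id=fit.sample_id,
        group=fit.group,
        excitation=fit.excitation,
        percent=positive,
        absolute=absolute_contributions(positive, fit.total_measured_area),
        total_measured_area=fit.total_measured_area,
        aa_ret_ratio=aa_ret_ratio(pct),
        negative_percent=negative,
    )


def _flag(p: float) -> str:
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def summarize_groups(
    records: list[ContributionRecord],
    reference_group: str = "sham",
    test: str = "welch",
    value: str = "percent",
) -> CohortTable:
    """Mean ± SE per group × component, with tests vs the reference group.

    Parameters
    ----------
    records:
        Per-sample contribution records (one excitation).
    reference_group:
        Group against which every other group is tested.
    test:
        ``"welch"`` (unequal-variance t) or ``"ranksum"`` (Mann–Whitney).
    value:
        ``"percent"`` or ``"absolute"`` contributions.
    """
    if test not in ("welch", "ranksum"):
        raise ValueError(f"test must be 'welch' or 'ranksum', got {test!r}")
    if value not in ("percent", "absolute"):
        raise ValueError(f"value must be 'percent' or 'absolute', got {value!r}")
    groups = sorted({r.group for r in records})
    if reference_group not in groups:
        raise ValueError(f"reference group {reference_group!r} absent from records")
    components = sorted({c for r in records for c in getattr(r, value)})

    def values(group, comp):
        return np.array([getattr(r, value).get(comp, 0.0)
                         for r in records if r.group == group])

    n_per_group = {g: sum(r.group == g for r in records) for g in groups}
    sum_rows, test_rows = [], []
    for g in groups:
        for comp in components:
            v = values(g, comp)
            n = v.size
            se = float(np.std(v, ddof=1) / np.sqrt(n)) if n >= 2 else float("nan")
            sum_rows.append({"group": g, "component": comp,
                             "mean": float(np.mean(v)), "se": se, "n": n})
            if g != reference_group:
                ref = values(reference_group, comp)
                if n >= 2 and ref.size >= 2:
                    if test == "welch":
                        p = float(stats.ttest_ind(ref, v, equal_var=False).pvalue)
                    else:
                        p = float(stats.mannwhitneyu(
                            ref, v, alternative="two-sided").pvalue)
                else:
                    p = float("nan")
                test_rows.append({"group": g, "component": comp,
                                  "p_value": p,
                                  "flag": _flag(p) if np.isfinite(p) else "n/a"})
    return CohortTable(
        records=list(records),
        summaries=pd.DataFrame(sum_rows,
                               columns=["group", "component", "mean", "se", "n"]),
        tests=pd.DataFrame(test_rows,
                           columns=["group", "component", "p_value", "flag"]),
        reference_group=reference_group,
        n_per_group=n_per_group,
        value_kind=value,
    )


def reporting_filter(summary: CohortTable, threshold: float = 5.0) -> CohortTable:
    """Drop minor components from the rendered report.

    A component whose group-mean percentage is <= ``threshold`` in every
    group is omitted from the summary and test tables (raw records are
    retained untouched).  Mirrors the reporting convention of giving no
    numbers for bands contributing at most 5%.
    """
    pct = summarize_groups(summary.records, summary.reference_group,
                           value="percent").summaries
    keep = set()
    for comp, sub in pct.groupby("component"):
        if (sub["mean"] > threshold).any():
            keep.add(comp)
    return CohortTable(
        records=summary.records,
        summaries=summary.summaries[summary.summaries["component"].isin(keep)]
        .reset_index(drop=True),
        tests=summary.tests[summary.tests["component"].isin(keep)]
        .reset_index(drop=True),
        reference_group=summary.reference_group,
        n_per_group=summary.n_per_group,
        value_kind=summary.value_kind,
    )


def compare_total_areas(records: list[ContributionRecord],
                        reference_group: str = "sham",
                        test: str = "welch") -> pd.DataFrame:
    """Compare total measured spectral areas of each group vs reference."""
    groups = sorted({r.group for r in records})
    rows = []
    for g in groups:
        v = np.array([r.total_measured_area for r in records if r.group == g])
        row = {"group": g, "mean": float(np.mean(v)),
               "se": float(np.std(v, ddof=1) / np.sqrt(v.size)) if v.size >= 2 else float("nan"),
               "n": v.size, "p_value": float("nan"), "flag": ""}
        if g != reference_group and v.size >= 2:
            ref = np.array([r.total_measured_area for r in records
                            if r.group == reference_group])
            if test == "welch":
                p = float(stats.ttest_ind(ref, v, equal_var=False).pvalue)
            else:
                p = float(stats.mannwhitneyu(ref, v, alternative="two-sided").pvalue)
            row["p_value"] = p
            row["flag"] = _flag(p)
        rows.append(row)
    return pd.DataFrame(rows)


def render_table(table: CohortTable, ratio: bool = True) -> str:
    """Render a cohort table as TSV: one row per group, ``mean ± SE``
    cells with significance stars, and (optionally) the AA/Ret ratio of
    group means rounded to 2 decimals."""
    s = table.summaries
    components = [c for c in (
        "retinol", "arachidonic_acid", "linoleic_acid", "oleic_acid",
        "proteins", "undefined_440", "flavin_560",
    ) if c in set(s["component"])]
    lines = ["\t".join(["group"] + components + (["AA/Ret"] if ratio else []))]
    for g in sorted(set(s["group"]), key=lambda g: (g != table.reference_group, g)):
        cells = [g]
        means = {}
        for comp in components:
            row = s[(s["group"] == g) & (s["component"] == comp)].iloc[0]
            means[comp] = row["mean"]
            star = ""
            t = table.tests
            hit = t[(t["group"] == g) & (t["component"] == comp)]
            if len(hit):
                star = f" {hit.iloc[0]['flag']}".rstrip()
            cells.append(f"{row['mean']:.2f} ± {row['se']:.2f}{star}")
        if ratio:
            if means.get("retinol", 0.0) > 0:
                cells.append(f"{aa_ret_ratio(means, decimals=2):.2f}")
            else:
                cells.append("----")
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"
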