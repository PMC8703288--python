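"""Condition comparisons and survey-style summary tables.

Fold changes between salinity conditions, one-way ANOVA with Tukey HSD
multiple comparison (studentized-range p-values via scipy), significance
labels at the conventional thresholds (** for p <= 0.01, * for p <= 0.05),
and a mean +- SD survey table with "+" / "-" censoring marks.

Fold changes are computed on per-cell amounts (fmol/cell), the scale on
which the salinity responses are reported.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .quant import CensorFlag, QuantResult

__all__ = [
    "GroupSeries",
    "ComparisonResult",
    "fold_change",
    "one_way_anova",
    "tukey_hsd",
    "significance_label",
    "survey_table",
]


@dataclass(frozen=True)
class GroupSeries:
    """Replicate per-cell amounts for one condition."""

    label: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) < 1:
            raise ValueError(f"group {self.label!r} needs >= 1 value")
        if any(v < 0 for v in self.values):
            raise ValueError(f"group {self.label!r} has negative values")
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if len(self.values) > 1 else 0.0


@dataclass(frozen=True)
class ComparisonResult:
    """One pairwise contrast from the ANOVA + Tukey procedure."""

    pair: tuple[str, str]
    fold_change: float
    anova_f: float
    anova_p: float
    tukey_p: float
    label: str  # "**", "*", or "n.s."


def fold_change(reference: GroupSeries, treatment: GroupSeries) -> float:
    """Ratio of group means, treatment over reference."""
    if reference.mean <= 0:
        raise ValueError("reference group mean must be > 0")
    return treatment.mean / reference.mean


def one_way_anova(groups: list[GroupSeries]) -> tuple[float, float]:
    """Classical one-way ANOVA over >= 2 groups with >= 2 values each.

    Degenerate inputs (zero within-group variance everywhere) return
    F = 0, p = 1 with a warning when the means also coincide, and
    F = inf, p = 0 when they differ.
    """
    if len(groups) < 2 or any(len(g.values) < 2 for g in groups):
        raise ValueError("ANOVA needs >= 2 groups with >= 2 values each")
    data = [np.asarray(g.values) for g in groups]
    grand = np.mean(np.concatenate(data))
    ss_between = sum(len(d) * (d.mean() - grand) ** 2 for d in data)
    ss_within = sum(((d - d.mean()) ** 2).sum() for d in data)
    df_between = len(data) - 1
    df_within = sum(len(d) for d in data) - len(data)
    if ss_within == 0:
        if ss_between == 0:
            warnings.warn("all groups identical: ANOVA undefined, returning p=1",
                          stacklevel=2)
            return 0.0, 1.0
        return math.inf, 0.0
    f = (ss_between / df_between) / (ss_within / df_within)
    p = float(_stats.f.sf(f, df_between, df_within))
    return float(f), p


def significance_label(p: float) -> str:
    """The conventional asterisk label: ** for p<=0.01, * for p<=0.05."""
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "n.s."


def tukey_hsd(groups: list[GroupSeries], alpha: float = 0.05) -> list[ComparisonResult]:
    """All pairwise contrasts with Tukey-adjusted p-values.

    Adjusted p-values come from the studentized-range distribution with
    the pooled within-group mean square (scipy's implementation).  Each
    result carries the shared ANOVA F and p plus the pair's fold change
    (second group over first, in input order).
    """
    f, p_anova = one_way_anova(groups)
    data = [np.asarray(g.values) for g in groups]
    degenerate = all(np.var(d) == 0 for d in data)
    if degenerate:
        pmat = None
    else:
        pmat = _stats.tukey_hsd(*data).pvalue
    out: list[ComparisonResult] = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            if pmat is None:
                p_adj = 1.0 if groups[i].mean == groups[j].mean else 0.0
            else:
                p_adj = float(pmat[i, j])
            fc = (groups[j].mean / groups[i].mean
                  if groups[i].mean > 0 else math.nan)
            out.append(ComparisonResult(
                pair=(groups[i].label, groups[j].label),
                fold_change=fc,
                anova_f=f,
                anova_p=p_anova,
                tukey_p=p_adj,
                label=significance_label(p_adj),
            ))
    return out


def _format_mean_sd(values: list[float]) -> str:
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    if sd > 0:
        decimals = max(0, -int(math.floor(math.log10(sd))) + 1)
    else:
        decimals = 2
    decimals = min(decimals, 3)
    return f"{mean:.{decimals}f} ± {sd:.{decimals}f}"


def survey_table(
    results: dict[str, dict[str, list[QuantResult]]],
    unit: str = "per_cell_fmol",
) -> pd.DataFrame:
    """Mean +- SD summary table, one row per species, one column per analyte.

    Follows the survey reporting convention: a "+" marks analytes whose
    signal sits between LOD and LOQ in every quantifiable replicate, a
    "-" marks analytes below LOD in all replicates.  ``unit`` selects the
    reported quantity (``per_cell_fmol`` or ``intracellular_mm``).
    """
    rows = {}
    for species, per_analyte in results.items():
        row = {}
        for analyte, quants in per_analyte.items():
            flags = [q.flag for q in quants]
            if all(f == CensorFlag.BELOW_LOD for f in flags):
                row[analyte] = "−"
            elif not any(f == CensorFlag.QUANTIFIABLE for f in flags):
                row[analyte] = "+"
            else:
                values = [getattr(q, unit) for q in quants
                          if q.flag == CensorFlag.QUANTIFIABLE]
                row[analyte] = _format_mean_sd(values)
        rows[species] = row
    return pd.DataFrame.from_dict(rows, orient="index")
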