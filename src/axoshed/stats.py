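"""Per-animal aggregation and group comparisons.

The aggregation order is fixed — object values are averaged within each
animal first, and N is the number of animals — and comparisons are run on
the per-animal values: unpaired two-tailed t-tests for two groups, one- or
two-way ANOVA followed by Tukey's post hoc test for multiple groups, with
the usual star convention (* p<0.05, ** p<0.01, *** p<0.001).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupedMeasure",
    "ComparisonResult",
    "per_animal_aggregate",
    "compare_groups",
    "significance_stars",
]


@dataclass
class GroupedMeasure:
    name: str
    per_animal: pd.DataFrame     # columns: animal, group [, class], value
    group_stats: pd.DataFrame    # group: mean, sem, n_animals

    def values(self, group) -> np.ndarray:
        df = self.per_animal
        return df.loc[df["group"] == group, "value"].to_numpy()

    @property
    def groups(self) -> list:
        return list(self.per_animal["group"].unique())


@dataclass
class ComparisonResult:
    test_name: str
    statistic: float
    p_value: float
    comparisons: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value out of [0, 1]")


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def per_animal_aggregate(objects: pd.DataFrame, value_col: str,
                         animal_col: str = "animal",
                         group_col: str = "group",
                         name: str | None = None) -> GroupedMeasure:
    """Average an object-level table within animals, then across animals.

    One value per animal (the mean over its objects); group means and SEMs
    are over animals, not objects.  Animals contributing no finite values
    are excluded with a warning; a single-animal group reports a missing
    SEM.
    """
    for col in (value_col, animal_col, group_col):
        if col not in objects.columns:
            raise ValueError(f"missing column {col!r}")
    rows = []
    for (grp, animal), df in objects.groupby([group_col, animal_col]):
        vals = df[value_col].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            warnings.warn(f"animal {animal!r} in group {grp!r} has no "
                          "objects; excluded")
            continue
        rows.append({"group": grp, "animal": animal,
                     "value": float(vals.mean()), "n_objects": len(vals)})
    per_animal = pd.DataFrame(rows)
    stats_rows = []
    for grp, df in per_animal.groupby("group"):
        v = df["value"].to_numpy()
        sem = float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 \
            else np.nan
        if len(v) == 1:
            warnings.warn(f"group {grp!r} has a single animal; SEM missing")
        stats_rows.append({"group": grp, "mean": float(v.mean()),
                           "sem": sem, "n_animals": len(v)})
    return GroupedMeasure(name or value_col, per_animal,
                          pd.DataFrame(stats_rows))


def _tukey(per_animal: pd.DataFrame, label_col: str) -> pd.DataFrame:
    from statsmodels.stats.multicomp import pairwise_tukeyhsd
    res = pairwise_tukeyhsd(per_animal["value"].to_numpy(),
                            per_animal[label_col].to_numpy())
    tbl = pd.DataFrame(res.summary().data[1:],
                       columns=res.summary().data[0])
    tbl["p_adj"] = res.pvalues
    tbl["stars"] = [significance_stars(p) for p in res.pvalues]
    return tbl


def compare_groups(measure: GroupedMeasure, design: str = "ttest",
                   class_col: str = "class",
                   display_classes: tuple | None = None) -> ComparisonResult:
    """Compare groups on per-animal values.

    ``design``:

    * ``ttest`` — unpaired two-tailed t-test between exactly two groups;
    * ``anova1_tukey`` — one-way ANOVA across groups, Tukey post hoc;
    * ``anova2_tukey`` — two-way ANOVA on group x ``class_col`` (e.g.
      movement class), Tukey over all cell combinations; by convention the
      comparisons surfaced can be restricted to ``display_classes``
      (e.g. stationary only) while the adjustment still spans all cells.

    An empty cell in the two-way design raises an error naming the cell.
    """
    df = measure.per_animal
    groups = measure.groups
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if design == "ttest":
        if len(groups) != 2:
            raise ValueError("ttest design requires exactly 2 groups")
        a, b = (measure.values(g) for g in groups)
        stat, p = sps.ttest_ind(a, b, equal_var=True)
        comp = pd.DataFrame([{
            "group1": groups[0], "group2": groups[1],
            "p_adj": float(p), "stars": significance_stars(float(p)),
        }])
        return ComparisonResult("unpaired two-tailed t-test",
                                float(stat), float(p), comp)
    if design == "anova1_tukey":
        stat, p = sps.f_oneway(*(measure.values(g) for g in groups))
        comp = _tukey(df, "group")
        return ComparisonResult("one-way ANOVA + Tukey",
                                float(stat), float(p), comp)
    if design == "anova2_tukey":
        if class_col not in df.columns:
            raise ValueError(f"two-way design needs a {class_col!r} column")
        import statsmodels.api as sm
        from statsmodels.formula.api import ols
        data = df.rename(columns={class_col: "cls"})
        for g in groups:
            for c in data["cls"].unique():
                if ((data["group"] == g) & (data["cls"] == c)).sum() == 0:
                    raise ValueError(f"empty cell: group={g!r}, class={c!r}")
        model = ols("value ~ C(group) * C(cls)", data=data).fit()
        tab = sm.stats.anova_lm(model, typ=2)
        stat = float(tab.loc["C(group)", "F"])
        p = float(tab.loc["C(group)", "PR(>F)"])
        data["cell"] = data["group"].astype(str) + "|" + data["cls"].astype(str)
        comp = _tukey(data, "cell")
        if display_classes is not None:
            keep = comp.apply(
                lambda r: all(str(r[g]).split("|")[1] in display_classes
                              for g in ("group1", "group2")), axis=1)
            comp = comp[keep].reset_index(drop=True)
        return ComparisonResult("two-way ANOVA + Tukey", stat, p, comp)
    raise ValueError(f"unknown design {design!r}")
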