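"""Statistical comparisons on quantified outputs.

Thin, uniform wrappers over vetted routines: two-tailed paired/unpaired t
tests (scipy), one-way and repeated-measures ANOVA (scipy / statsmodels),
mixed treatment x time ANOVA (pingouin), with Tukey, Dunnett or Bonferroni
post-hoc tables. The contribution of this module is the uniform
:class:`TestResult` schema and explicit handling of degenerate inputs
(zero-variance samples) rather than any numerics of its own.

Significance threshold throughout the package's reports is p < 0.05.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import UsageError

ALPHA = 0.05


@dataclass(eq=False)
class TestResult:
    """Uniform result record for every test in the package."""

    name: str
    statistic: float
    df: tuple[float, ...] | float
    p_value: float
    labels: list[str] = field(default_factory=list)
    posthoc: pd.DataFrame | None = None
    table: pd.DataFrame | None = None
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return bool(np.isfinite(self.p_value) and self.p_value < ALPHA)

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "statistic": None if not np.isfinite(self.statistic) else float(self.statistic),
            "df": self.df if not isinstance(self.df, tuple) else list(self.df),
            "p_value": None if not np.isfinite(self.p_value) else float(self.p_value),
            "labels": self.labels,
            "degenerate": self.degenerate,
            "significant": self.significant,
        }
        if self.posthoc is not None:
            d["posthoc"] = self.posthoc.to_dict(orient="records")
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size < 2:
        raise UsageError(f"sample {name} needs n >= 2")
    return arr


def compare(a, b, paired: bool = False, name: str | None = None,
            labels: Sequence[str] = ("a", "b")) -> TestResult:
    """Two-tailed paired or unpaired t test.

    Degenerate inputs are reported explicitly rather than as NaN: identical
    paired samples give statistic 0 and p = 1; a constant nonzero paired
    difference (zero variance) is flagged with p = 0.
    """
    a = _as_1d(a, "a")
    b = _as_1d(b, "b")
    test_name = name or ("paired t" if paired else "unpaired t")
    if paired:
        if a.size != b.size:
            raise UsageError("paired comparison requires equal sample sizes")
        d = a - b
        df: float = float(a.size - 1)
        if np.std(d, ddof=1) == 0:
            if np.all(d == 0):
                return TestResult(test_name, 0.0, df, 1.0, list(labels), degenerate=True)
            return TestResult(test_name, float("inf") * np.sign(d.mean()), df, 0.0,
                              list(labels), degenerate=True)
        res = sps.ttest_rel(a, b)
    else:
        df = float(a.size + b.size - 2)
        if np.std(a, ddof=1) == 0 and np.std(b, ddof=1) == 0:
            if a.mean() == b.mean():
                return TestResult(test_name, 0.0, df, 1.0, list(labels), degenerate=True)
            return TestResult(test_name, float("inf") * np.sign(a.mean() - b.mean()),
                              df, 0.0, list(labels), degenerate=True)
        res = sps.ttest_ind(a, b, equal_var=True)
    return TestResult(test_name, float(res.statistic), df, float(res.pvalue), list(labels))


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------


def _posthoc_tukey(groups: list[np.ndarray], labels: list[str]) -> pd.DataFrame:
    res = sps.tukey_hsd(*groups)
    rows = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        rows.append({
            "group_a": labels[i],
            "group_b": labels[j],
            "estimate": float(groups[i].mean() - groups[j].mean()),
            "p_adj": float(res.pvalue[i, j]),
            "method": "tukey",
        })
    return pd.DataFrame(rows)


def _posthoc_dunnett(groups: list[np.ndarray], labels: list[str], control: int) -> pd.DataFrame:
    treatments = [g for k, g in enumerate(groups) if k != control]
    t_labels = [l for k, l in enumerate(labels) if k != control]
    res = sps.dunnett(*treatments, control=groups[control])
    rows = []
    for lab, g, stat, p in zip(t_labels, treatments, np.atleast_1d(res.statistic),
                               np.atleast_1d(res.pvalue)):
        rows.append({
            "group_a": lab,
            "group_b": labels[control],
            "estimate": float(g.mean() - groups[control].mean()),
            "statistic": float(stat),
            "p_adj": float(p),
            "method": "dunnett",
        })
    return pd.DataFrame(rows)


def _posthoc_bonferroni(groups: list[np.ndarray], labels: list[str],
                        paired: bool = False) -> pd.DataFrame:
    pairs = list(itertools.combinations(range(len(groups)), 2))
    rows = []
    for i, j in pairs:
        r = compare(groups[i], groups[j], paired=paired)
        rows.append({
            "group_a": labels[i],
            "group_b": labels[j],
            "estimate": float(groups[i].mean() - groups[j].mean()),
            "p_adj": float(min(1.0, r.p_value * len(pairs))),
            "method": "bonferroni",
        })
    return pd.DataFrame(rows)


def _attach_posthoc(result: TestResult, groups: list[np.ndarray], labels: list[str],
                    posthoc: str | None, control: int, paired: bool) -> TestResult:
    if posthoc in (None, "none") or result.degenerate:
        return result
    if posthoc == "tukey":
        result.posthoc = _posthoc_tukey(groups, labels)
    elif posthoc == "dunnett":
        result.posthoc = _posthoc_dunnett(groups, labels, control)
    elif posthoc == "bonferroni":
        result.posthoc = _posthoc_bonferroni(groups, labels, paired=paired)
    else:
        raise UsageError(f"unknown post-hoc method {posthoc!r}")
    return result


def anova(
    groups: Sequence = (),
    design: str = "oneway",
    posthoc: str | None = None,
    labels: Sequence[str] | None = None,
    control: int = 0,
    data: pd.DataFrame | None = None,
    dv: str = "value",
    between: str = "treatment",
    within: str = "time",
    subject: str = "subject",
) -> TestResult:
    """Omnibus ANOVA with an optional post-hoc table.

    ``design="oneway"``: independent groups (list of samples).
    ``design="oneway_rm"``: repeated measures; groups must be equal-length
    (one value per subject per condition), no silent imputation.
    ``design="twoway"``: tidy ``data`` frame with ``dv``, ``between``,
    ``within`` and ``subject`` columns; repeated measures on the within factor
    (mixed ANOVA). The primary statistic reported is the between-treatment
    effect; the full table is attached.
    """
    if design == "twoway":
        if data is None:
            raise UsageError("twoway design requires a tidy data frame")
        import pingouin as pg

        table = pg.mixed_anova(data=data, dv=dv, between=between, within=within,
                               subject=subject)
        row = table[table["Source"] == between].iloc[0]
        p_col = "p_unc" if "p_unc" in table.columns else "p-unc"
        result = TestResult(
            name="two-way mixed ANOVA (treatment effect)",
            statistic=float(row["F"]),
            df=(float(row["DF1"]), float(row["DF2"])),
            p_value=float(row[p_col]),
            labels=sorted(map(str, data[between].unique())),
            table=table,
        )
        if posthoc == "bonferroni":
            # per-time-point between-group comparisons, Bonferroni-adjusted
            times = sorted(data[within].unique())
            tgroups = sorted(data[between].unique())
            if len(tgroups) != 2:
                raise UsageError("per-time Bonferroni post-hoc expects two treatments")
            rows = []
            for t in times:
                sub = data[data[within] == t]
                r = compare(sub[sub[between] == tgroups[0]][dv],
                            sub[sub[between] == tgroups[1]][dv])
                rows.append({
                    "time": t,
                    "group_a": str(tgroups[0]),
                    "group_b": str(tgroups[1]),
                    "p_adj": float(min(1.0, r.p_value * len(times))),
                    "method": "bonferroni",
                })
            result.posthoc = pd.DataFrame(rows)
        elif posthoc not in (None, "none"):
            raise UsageError("twoway design supports only the bonferroni post-hoc")
        return result

    glist = [_as_1d(g, f"group {k}") for k, g in enumerate(groups)]
    if len(glist) < 3:
        raise UsageError("ANOVA requires at least three groups")
    glabels = list(labels) if labels is not None else [f"g{k}" for k in range(len(glist))]
    if len(glabels) != len(glist):
        raise UsageError("labels length must match the number of groups")

    if design == "oneway":
        df = (float(len(glist) - 1), float(sum(g.size for g in glist) - len(glist)))
        if all(np.std(g, ddof=1) == 0 for g in glist):
            return TestResult("one-way ANOVA", float("nan"), df, float("nan"),
                              glabels, degenerate=True)
        res = sps.f_oneway(*glist)
        result = TestResult("one-way ANOVA", float(res.statistic), df,
                            float(res.pvalue), glabels)
        return _attach_posthoc(result, glist, glabels, posthoc, control, paired=False)

    if design == "oneway_rm":
        sizes = {g.size for g in glist}
        if len(sizes) != 1:
            raise UsageError("repeated-measures design must be balanced")
        n = glist[0].size
        if all(np.std(g, ddof=1) == 0 for g in glist):
            df = (float(len(glist) - 1), float((len(glist) - 1) * (n - 1)))
            return TestResult("one-way RM ANOVA", float("nan"), df, float("nan"),
                              glabels, degenerate=True)
        from statsmodels.stats.anova import AnovaRM

        long = pd.DataFrame({
            "subject": np.repeat(np.arange(n), len(glist)),
            "condition": np.tile(glabels, n),
            "value": np.column_stack(glist).ravel(),
        })
        tbl = AnovaRM(long, depvar="value", subject="subject",
                      within=["condition"]).fit().anova_table
        result = TestResult(
            name="one-way RM ANOVA",
            statistic=float(tbl["F Value"].iloc[0]),
            df=(float(tbl["Num DF"].iloc[0]), float(tbl["Den DF"].iloc[0])),
            p_value=float(tbl["Pr > F"].iloc[0]),
            labels=glabels,
        )
        return _attach_posthoc(result, glist, glabels, posthoc, control, paired=True)

    raise UsageError("design must be 'oneway', 'oneway_rm' or 'twoway'")
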