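"""Statistical comparison layer and result-table assembly.

Repeated-measures ANOVA for per-hyperparameter effects within subjects,
two-way ANOVA with interaction for hyperparameter x decoder effects,
Tukey HSD post-hoc comparisons, per-class precision, and the summary
tables (mean / SD / max accuracy per family x selection mode, selected
hyperparameters, selection-frequency counts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.formula.api import ols
from statsmodels.stats.anova import AnovaRM, anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "AnovaResult",
    "PosthocResult",
    "rm_anova",
    "twoway_anova",
    "tukey_hsd",
    "precision_scores",
    "assemble_accuracy_table",
    "assemble_selection_table",
    "selection_frequencies",
]

ALPHA = 0.05


@dataclass
class AnovaResult:
    factors: list
    F: dict
    df: dict  # factor -> (numerator df, denominator df)
    p: dict

    def significant(self, factor: str, alpha: float = ALPHA) -> bool:
        return self.p[factor] < alpha


@dataclass
class PosthocResult:
    pairs: list  # (level_a, level_b)
    p_adj: np.ndarray
    reject: np.ndarray
    alpha: float


def _to_long(table) -> pd.DataFrame:
    """subject x level wide table -> long (subject, level, value)."""
    df = pd.DataFrame(table)
    df.index.name = "subject"
    long = df.reset_index().melt(
        id_vars="subject", var_name="level", value_name="value"
    )
    return long


def rm_anova(table) -> AnovaResult:
    """One-factor within-subject (repeated measures) ANOVA.

    ``table``: wide DataFrame/array, rows = subjects, columns = levels
    of the hyperparameter; each cell one accuracy.  Complete, balanced
    tables only.
    """
    long = _to_long(table)
    if long["value"].isna().any():
        raise ValueError("missing cells in repeated-measures table")
    wide = np.asarray(pd.DataFrame(table), dtype=float)
    n_subj, n_lev = wide.shape
    ss_treat = n_subj * np.sum((wide.mean(axis=0) - wide.mean()) ** 2)
    if ss_treat <= 1e-12 * max(1.0, np.abs(wide).max() ** 2):
        # no between-level variation at all: F = 0, p = 1 by convention
        return AnovaResult(
            factors=["level"],
            F={"level": 0.0},
            df={"level": (n_lev - 1, (n_subj - 1) * (n_lev - 1))},
            p={"level": 1.0},
        )
    res = AnovaRM(long, depvar="value", subject="subject", within=["level"]).fit()
    row = res.anova_table.iloc[0]
    return AnovaResult(
        factors=["level"],
        F={"level": float(row["F Value"])},
        df={"level": (int(row["Num DF"]), int(row["Den DF"]))},
        p={"level": float(row["Pr > F"])},
    )


def twoway_anova(
    data: pd.DataFrame,
    factor_a: str = "hp",
    factor_b: str = "model",
    value: str = "value",
) -> AnovaResult:
    """Two-way ANOVA with interaction on a long-format replicated table."""
    data = pd.DataFrame(data)
    for col in (factor_a, factor_b, value):
        if col not in data.columns:
            raise ValueError(f"column {col!r} missing from data")
    cell_counts = data.groupby([factor_a, factor_b], sort=False)[value].count()
    if (cell_counts < 2).any():
        raise ValueError(
            "two-way ANOVA with interaction needs >= 2 replicates per cell"
        )
    model = ols(
        f"{value} ~ C({factor_a}) * C({factor_b})", data=data
    ).fit()
    tab = anova_lm(model, typ=2)
    names = {
        f"C({factor_a})": factor_a,
        f"C({factor_b})": factor_b,
        f"C({factor_a}):C({factor_b})": f"{factor_a}:{factor_b}",
    }
    den_df = int(tab.loc["Residual", "df"])
    F, df, p = {}, {}, {}
    for raw, pretty in names.items():
        F[pretty] = float(tab.loc[raw, "F"])
        df[pretty] = (int(tab.loc[raw, "df"]), den_df)
        p[pretty] = float(tab.loc[raw, "PR(>F)"])
    return AnovaResult(factors=list(names.values()), F=F, df=df, p=p)


def tukey_hsd(groups: dict, alpha: float = ALPHA) -> PosthocResult:
    """Studentized-range adjusted pairwise comparisons.

    ``groups``: mapping level -> 1-D array of replicate accuracies.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for name, vals in groups.items():
        if len(np.atleast_1d(vals)) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 replicates")
    values = np.concatenate([np.atleast_1d(v) for v in groups.values()])
    labels = np.concatenate(
        [[name] * len(np.atleast_1d(v)) for name, v in groups.items()]
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        res = pairwise_tukeyhsd(values, labels, alpha=alpha)
    pairs = list(zip(res.groupsunique[res._multicomp.pairindices[0]],
                     res.groupsunique[res._multicomp.pairindices[1]]))
    p_adj = np.asarray(res.pvalues, dtype=float)
    # zero pooled variance: identical groups compare equal (p = 1),
    # separated groups differ with certainty (p = 0)
    bad = ~np.isfinite(p_adj)
    if bad.any():
        diffs = np.asarray(res.meandiffs, dtype=float)
        p_adj[bad & (np.abs(diffs) <= 1e-12)] = 1.0
        p_adj[bad & (np.abs(diffs) > 1e-12)] = 0.0
    reject = p_adj < alpha
    return PosthocResult(pairs=pairs, p_adj=p_adj, reject=reject, alpha=alpha)


def precision_scores(labels_hat: np.ndarray, y: np.ndarray, n_classes: int):
    """Per-class precision TP / (TP + FP) and their macro mean.

    Classes never predicted have undefined precision, recorded as NaN
    and excluded from the macro mean.
    """
    labels_hat = np.asarray(labels_hat)
    y = np.asarray(y)
    prec = np.full(n_classes, np.nan)
    for c in range(n_classes):
        pred = labels_hat == c
        if pred.sum() > 0:
            prec[c] = np.mean(y[pred] == c)
    macro = float(np.nanmean(prec)) if np.any(~np.isnan(prec)) else float("nan")
    return prec, macro


def results_to_frame(results: dict) -> pd.DataFrame:
    """{(subject, task, family, mode): CVResult} -> tidy accuracy rows."""
    rows = []
    for (subject, task, family, mode), res in results.items():
        for fold, acc in enumerate(res.outer_accs):
            rows.append(
                dict(
                    subject=subject, task=task, family=family, mode=mode,
                    fold=fold, split="test", accuracy=acc,
                )
            )
        rows.append(
            dict(
                subject=subject, task=task, family=family, mode=mode,
                fold=-1, split="mean", accuracy=res.mean_test_acc,
            )
        )
    return pd.DataFrame(rows).sort_values(
        ["task", "family", "mode", "subject", "fold"]
    ).reset_index(drop=True)


def assemble_accuracy_table(results: dict) -> pd.DataFrame:
    """Mean / SD / max of per-subject mean test accuracy (in %), per
    task, family and selection mode."""
    rows = []
    for (subject, task, family, mode), res in sorted(results.items()):
        rows.append(
            dict(subject=subject, task=task, family=family, mode=mode,
                 acc=100.0 * res.mean_test_acc)
        )
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["task", "family", "mode"])["acc"]
        .agg(accuracy="mean", std=lambda v: v.std(ddof=0), max="max")
        .reset_index()
    )
    return out


def assemble_selection_table(results: dict) -> pd.DataFrame:
    """Selected hyperparameter combination per subject/task/family/mode."""
    rows = []
    for (subject, task, family, mode), res in sorted(results.items()):
        row = dict(subject=subject, task=task, family=family, mode=mode)
        row.update(res.theta_star)
        rows.append(row)
    return pd.DataFrame(rows)


def selection_frequencies(results: dict) -> pd.DataFrame:
    """How often each hyperparameter value was selected, per family and
    dimension (pooled over subjects, tasks and modes)."""
    sel = assemble_selection_table(results)
    rows = []
    meta = {"subject", "task", "family", "mode"}
    for family, grp in sel.groupby("family"):
        for col in sel.columns:
            if col in meta:
                continue
            counts = grp[col].dropna().value_counts()
            for value, count in counts.items():
                rows.append(
                    dict(family=family, hyperparameter=col, value=value,
                         count=int(count))
                )
    return pd.DataFrame(rows)
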