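"""Group-level comparison of model goodness-of-fit.

Given a table of per-unit (participant x condition x outcome) R^2 or AIC
values with one column per model family, the workflow is: Shapiro-Wilk
normality check on every column -> one-way repeated-measures ANOVA
(parametric branch) or Friedman test (nonparametric) -> paired t or
Wilcoxon signed-rank tests over all C(5,2) = 10 family pairs at a
Bonferroni-corrected alpha of 0.05/10 = 0.005.

The branch is chosen per metric across all columns jointly: a single
non-normal column sends the whole metric down the nonparametric branch.
No sphericity correction is applied to the RM-ANOVA; Wilcoxon handles
zero differences with the Pratt method.  Both choices are recorded in the
report.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.anova import AnovaRM

PARAMETRIC = "parametric"
NONPARAMETRIC = "nonparametric"


def _as_table(table: pd.DataFrame) -> pd.DataFrame:
    df = pd.DataFrame(table)
    if df.shape[1] < 2:
        raise ValueError("need at least two model columns")
    if df.isna().any().any():
        raise ValueError("fitness table has missing cells")
    if df.shape[0] < 3:
        raise ValueError("need at least 3 rows for an omnibus test")
    return df.astype(float)


@dataclass
class PairComparison:
    pair: tuple[str, str]
    statistic: float
    p: float
    significant: bool
    note: str = ""


@dataclass
class ComparisonReport:
    metric: str
    normality_p: dict
    branch: str
    omnibus_statistic: float
    omnibus_p: float
    pairs: list
    corrected_alpha: float
    sphericity_correction: str = "none"
    wilcoxon_zero_method: str = "pratt"

    def pairs_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "model_a": a,
                    "model_b": b,
                    "statistic": pc.statistic,
                    "p": pc.p,
                    "significant": pc.significant,
                    "note": pc.note,
                }
                for pc in self.pairs
                for a, b in [pc.pair]
            ]
        )

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "normality_p": dict(self.normality_p),
            "branch": self.branch,
            "omnibus_statistic": self.omnibus_statistic,
            "omnibus_p": self.omnibus_p,
            "corrected_alpha": self.corrected_alpha,
            "sphericity_correction": self.sphericity_correction,
            "wilcoxon_zero_method": self.wilcoxon_zero_method,
            "pairs": [
                {
                    "pair": list(pc.pair),
                    "statistic": pc.statistic,
                    "p": pc.p,
                    "significant": pc.significant,
                    "note": pc.note,
                }
                for pc in self.pairs
            ],
        }


def shapiro_pvalues(table: pd.DataFrame) -> dict[str, float]:
    df = _as_table(table)
    out = {}
    for col in df.columns:
        x = df[col].to_numpy()
        if np.ptp(x) == 0.0:
            raise ValueError(f"column {col!r} is constant; normality test undefined")
        out[col] = float(sps.shapiro(x).pvalue)
    return out


def normality_gate(table: pd.DataFrame, alpha: float = 0.05) -> str:
    """``parametric`` iff every column passes Shapiro-Wilk at ``alpha``."""
    pvals = shapiro_pvalues(table)
    return PARAMETRIC if all(p > alpha for p in pvals.values()) else NONPARAMETRIC


def omnibus_test(table: pd.DataFrame, branch: str) -> tuple[float, float]:
    """RM-ANOVA across the model columns (parametric) or Friedman test."""
    df = _as_table(table)
    if branch == PARAMETRIC:
        long = df.copy()
        long.index = pd.RangeIndex(len(long), name="unit")
        long = long.reset_index().melt(id_vars="unit", var_name="model", value_name="value")
        res = AnovaRM(long, depvar="value", subject="unit", within=["model"]).fit()
        row = res.anova_table.iloc[0]
        return float(row["F Value"]), float(row["Pr > F"])
    if branch == NONPARAMETRIC:
        cols = [df[c].to_numpy() for c in df.columns]
        if float(np.ptp(np.column_stack(cols), axis=1).max()) == 0.0:
            # identical columns: no rank differences at all
            return 0.0, 1.0
        stat, p = sps.friedmanchisquare(*cols)
        return float(stat), float(p)
    raise ValueError(f"unknown branch {branch!r}")


def pairwise_posthoc(
    table: pd.DataFrame,
    branch: str,
    corrected_alpha: float = 0.005,
    omnibus: tuple[float, float] | None = None,
    metric: str = "metric",
) -> ComparisonReport:
    """All 10 pairwise tests at the Bonferroni-corrected alpha.

    Parametric branch: paired t-tests; nonparametric: Wilcoxon signed-rank
    with Pratt handling of zero differences.  A pair whose differences are
    all zero is reported non-significant with a diagnostic note.
    """
    df = _as_table(table)
    pvals = shapiro_pvalues(df)
    if omnibus is None:
        omnibus = omnibus_test(df, branch)
    pairs = []
    for a, b in itertools.combinations(df.columns, 2):
        diff = df[a].to_numpy() - df[b].to_numpy()
        note = ""
        if np.all(diff == 0.0):
            stat, p = math.nan, math.nan
            note = "all paired differences zero; test undefined"
        elif branch == PARAMETRIC:
            res = sps.ttest_rel(df[a], df[b])
            stat, p = float(res.statistic), float(res.pvalue)
            if not np.isfinite(p):
                note = "degenerate differences"
        else:
            res = sps.wilcoxon(df[a], df[b], zero_method="pratt")
            stat, p = float(res.statistic), float(res.pvalue)
        significant = bool(np.isfinite(p) and p < corrected_alpha)
        pairs.append(PairComparison(pair=(a, b), statistic=stat, p=p, significant=significant, note=note))
    return ComparisonReport(
        metric=metric,
        normality_p=pvals,
        branch=branch,
        omnibus_statistic=omnibus[0],
        omnibus_p=omnibus[1],
        pairs=pairs,
        corrected_alpha=corrected_alpha,
    )


def compare_models(
    table: pd.DataFrame,
    alpha: float = 0.05,
    n_pairs_alpha_split: int | None = None,
    metric: str = "metric",
) -> ComparisonReport:
    """Full workflow: normality gate -> omnibus -> pairwise at alpha / #pairs."""
    df = _as_table(table)
    branch = normality_gate(df, alpha)
    k = df.shape[1]
    n_pairs = n_pairs_alpha_split or (k * (k - 1) // 2)
    return pairwise_posthoc(df, branch, corrected_alpha=alpha / n_pairs, metric=metric)
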