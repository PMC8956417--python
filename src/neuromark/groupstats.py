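"""Group statistics: paired-t topographic maps, factorial ANOVA with
Bonferroni post hoc, group x age ANCOVA with partial eta squared,
chi-square, and Shapiro-Wilk normality testing.

Per-electrode contrasts are summarized as -log10(p) maps with the
conventional significance threshold -log10(0.05) ~ 1.3; no correction is
applied across electrodes by default (raw p thresholded at 0.05), with a
Bonferroni-across-electrodes option for stricter maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SIGNIFICANCE_THRESHOLD",
    "StatMap",
    "AncovaResult",
    "paired_t_map",
    "factorial_anova",
    "bonferroni_posthoc",
    "ancova_group_age",
    "chi_square_2x2",
    "normality_test",
]

#: -log10(0.05): a map value above this marks p < 0.05.
SIGNIFICANCE_THRESHOLD = -float(np.log10(0.05))


@dataclass
class StatMap:
    """Per-electrode paired-t contrast, mapped as -log10(p)."""

    electrodes: list[str]
    t_values: np.ndarray
    p_values: np.ndarray
    contrast: str
    band: str = ""
    significance_threshold: float = SIGNIFICANCE_THRESHOLD

    @property
    def neg_log10_p(self) -> np.ndarray:
        return -np.log10(np.maximum(self.p_values, np.finfo(float).tiny))

    @property
    def significant(self) -> np.ndarray:
        return self.neg_log10_p > self.significance_threshold

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "electrode": self.electrodes,
            "t": self.t_values,
            "p": self.p_values,
            "neg_log10_p": self.neg_log10_p,
            "significant": self.significant,
        })

    def is_significant(self, electrode: str) -> bool:
        return bool(self.significant[self.electrodes.index(electrode)])


def paired_t_map(feature_a: np.ndarray, feature_b: np.ndarray,
                 electrodes: list[str], contrast: str = "A>B", band: str = "",
                 bonferroni_electrodes: bool = False) -> StatMap:
    """Paired t-test per electrode between two within-subject conditions.

    ``feature_a``/``feature_b`` are subjects x electrodes, paired by row.
    """
    a = np.asarray(feature_a, dtype=float)
    b = np.asarray(feature_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError(f"paired features must share shape, got {a.shape} vs {b.shape}")
    if a.shape[1] != len(electrodes):
        raise ValueError("electrode list does not match feature columns")
    if a.shape[0] < 3:
        raise ValueError("paired t-test needs at least 3 subjects")
    diffs = a - b
    t = np.empty(a.shape[1])
    p = np.empty(a.shape[1])
    for j in range(a.shape[1]):
        if np.allclose(diffs[:, j], 0.0):
            t[j], p[j] = 0.0, 1.0
        else:
            res = stats.ttest_rel(a[:, j], b[:, j])
            t[j], p[j] = res.statistic, res.pvalue
    if bonferroni_electrodes:
        p = np.minimum(p * len(electrodes), 1.0)
    return StatMap(electrodes=list(electrodes), t_values=t, p_values=p,
                   contrast=contrast, band=band)


def factorial_anova(data: pd.DataFrame, response: str,
                    factors: list[str]) -> pd.DataFrame:
    """Fixed-effects factorial ANOVA (all main effects and interactions),
    Type II sums of squares — appropriate for the unbalanced 16/29 design.

    Returns the statsmodels ANOVA table with an added ``partial_eta_sq``
    column. A response with zero variance yields F = 0 and p = 1 for every
    term (nothing to explain).
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    for f in factors:
        if data[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has a single level")
    terms = " * ".join(f"C({f})" for f in factors)
    if np.ptp(data[response].to_numpy()) == 0:
        idx = []
        for r in range(1, len(factors) + 1):
            idx += [":".join(f"C({f})" for f in c) for c in combinations(factors, r)]
        out = pd.DataFrame({"sum_sq": 0.0, "df": np.nan, "F": 0.0,
                            "PR(>F)": 1.0, "partial_eta_sq": 0.0}, index=idx + ["Residual"])
        out.loc["Residual", ["F", "PR(>F)", "partial_eta_sq"]] = np.nan
        return out
    model = ols(f"{response} ~ {terms}", data=data).fit()
    table = sm.stats.anova_lm(model, typ=2)
    resid_ss = table.loc["Residual", "sum_sq"]
    table["partial_eta_sq"] = table["sum_sq"] / (table["sum_sq"] + resid_ss)
    table.loc["Residual", "partial_eta_sq"] = np.nan
    return table


def bonferroni_posthoc(data: pd.DataFrame, response: str, factor: str) -> pd.DataFrame:
    """Pairwise two-sample t-tests between factor levels with Bonferroni
    adjustment (raw p multiplied by the number of comparisons, capped at 1)."""
    levels = sorted(data[factor].unique())
    pairs = list(combinations(levels, 2))
    rows = []
    for a, b in pairs:
        xa = data.loc[data[factor] == a, response]
        xb = data.loc[data[factor] == b, response]
        res = stats.ttest_ind(xa, xb)
        rows.append({"level_a": a, "level_b": b, "t": res.statistic,
                     "p_raw": res.pvalue,
                     "p_bonferroni": min(res.pvalue * len(pairs), 1.0)})
    return pd.DataFrame(rows)


@dataclass
class AncovaResult:
    """F, p and partial eta squared for the terms of
    ``feature ~ group + age + group:age``."""

    table: pd.DataFrame = field(repr=False)

    def f(self, term: str) -> float:
        return float(self.table.loc[term, "F"])

    def p(self, term: str) -> float:
        return float(self.table.loc[term, "PR(>F)"])

    def partial_eta_sq(self, term: str) -> float:
        return float(self.table.loc[term, "partial_eta_sq"])

    @property
    def terms(self) -> list[str]:
        return [t for t in self.table.index if t != "Residual"]


def ancova_group_age(feature: np.ndarray, group: np.ndarray,
                     age: np.ndarray) -> AncovaResult:
    """Between-subject ANCOVA of one scalar EEG feature on group with age as
    covariate, including the group x age interaction.

    Each feature is a single scalar per subject, so the 'repeated measures'
    design collapses to a between-subject linear model; sphericity checks do
    not apply. Effect sizes are partial eta squared
    SS_effect / (SS_effect + SS_error).
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = pd.DataFrame({"feature": np.asarray(feature, dtype=float),
                       "group": np.asarray(group),
                       "age": np.asarray(age, dtype=float)})
    if df["group"].nunique() < 2:
        raise ValueError("both groups must be present for the ANCOVA")
    if df["age"].var() == 0:
        raise ValueError("age has zero variance; covariate is degenerate")
    model = ols("feature ~ C(group) * age", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    resid_ss = table.loc["Residual", "sum_sq"]
    table["partial_eta_sq"] = table["sum_sq"] / (table["sum_sq"] + resid_ss)
    table.loc["Residual", "partial_eta_sq"] = np.nan
    table = table.rename(index={"C(group)": "group", "C(group):age": "group:age"})
    return AncovaResult(table=table)


def chi_square_2x2(table: np.ndarray, yates: bool = False) -> tuple[float, int, float]:
    """Pearson chi-square on a 2x2 contingency table (df = 1).

    No continuity correction by default; pass ``yates=True`` to apply it.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("table must hold nonnegative integer counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("a zero marginal makes the chi-square undefined")
    res = stats.chi2_contingency(t, correction=yates)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def normality_test(sample: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk W and p. Constant samples are degenerate (p = 0 by
    convention: a point mass is maximally non-normal)."""
    x = np.asarray(sample, dtype=float)
    if not 3 <= len(x) <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        return float("nan"), 0.0
    res = stats.shapiro(x)
    return float(res.statistic), float(res.pvalue)
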