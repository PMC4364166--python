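"""Factorial statistics for the 2x2 strain x context design.

The design's statistical layer: two-way between-subjects ANOVAs with factors
strain (BTBR vs. B6) and social odor context (clean vs. soiled bedding),
follow-up unpaired Student's t-tests, Pearson correlations, and a sex
screen.  Emission outcomes (call counts, latency, calling time) use all
subjects; acoustic feature outcomes exclude subjects that never called,
which is why residual degrees of freedom drop from 56 to 54 in a 60-subject
cohort with two non-callers, and follow-up t df from 28 to 26.

ANOVAs are fit by ordinary least squares with Type-II sums of squares
(equivalent to the classical balanced-design decomposition when cells are
balanced; well-defined when non-callers unbalance the cells).  Per-test
alpha is 0.05 with no multiple-testing correction by default, matching the
convention of this literature; Holm adjustment is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "AnovaTable",
    "two_way_anova",
    "unpaired_t",
    "pearson_correlation",
    "sex_effect_screen",
    "holm_adjust",
    "EMISSION_OUTCOMES",
    "FEATURE_OUTCOMES",
    "cohort_anova_report",
]

# Outcomes computed on all subjects vs. only on subjects with >= 1 call.
EMISSION_OUTCOMES = ("n_calls", "latency_s", "calling_time_s")
FEATURE_OUTCOMES = ("mean_duration_ms", "mean_peak_freq_khz",
                    "mean_peak_amp_db", "mean_fm_khz")


@dataclass
class AnovaTable:
    """F, degrees of freedom and p for each effect of the 2x2 ANOVA."""

    effects: pd.DataFrame  # index: strain, context, interaction
    residual_df: int

    def f(self, effect: str) -> float:
        return float(self.effects.loc[effect, "F"])

    def p(self, effect: str) -> float:
        return float(self.effects.loc[effect, "p"])


def _validate_factors(table: pd.DataFrame, factors: tuple[str, str]) -> None:
    for f in factors:
        levels = table[f].dropna().unique()
        if len(levels) != 2:
            raise ValueError(f"factor {f!r} must have exactly 2 levels, "
                             f"got {list(levels)}")
    counts = table.groupby(list(factors), observed=True).size()
    if len(counts) < 4 or (counts < 2).any():
        raise ValueError("each of the 4 cells needs >= 2 observations")


def two_way_anova(table: pd.DataFrame, outcome: str,
                  factors: tuple[str, str] = ("strain", "context")
                  ) -> AnovaTable:
    """Two-way between-subjects ANOVA with interaction (Type-II SS).

    ``table`` holds one row per subject.  Raises on empty cells or zero
    residual variance.
    """
    data = table[[outcome, *factors]].dropna()
    _validate_factors(data, factors)
    a, b = factors
    model = smf.ols(f"Q('{outcome}') ~ C(Q('{a}')) * C(Q('{b}'))",
                    data=data).fit()
    if model.ssr <= 1e-12 * max(float(model.centered_tss), 1.0):
        raise ValueError("zero residual variance; F undefined")
    aov = sm.stats.anova_lm(model, typ=2)
    resid_df = int(aov.loc["Residual", "df"])
    rows = {}
    key_map = {f"C(Q('{a}'))": a, f"C(Q('{b}'))": b,
               f"C(Q('{a}')):C(Q('{b}'))": "interaction"}
    for src, name in key_map.items():
        rows[name] = {"F": float(aov.loc[src, "F"]),
                      "df_num": int(aov.loc[src, "df"]),
                      "df_den": resid_df,
                      "p": float(aov.loc[src, "PR(>F)"])}
    eff = pd.DataFrame.from_dict(rows, orient="index")
    return AnovaTable(effects=eff, residual_df=resid_df)


def unpaired_t(group_a: np.ndarray, group_b: np.ndarray
               ) -> tuple[float, int, float]:
    """Student's (equal-variance) unpaired t-test; df = nA + nB - 2.

    The equal-variance form matches the degrees of freedom conventionally
    reported (e.g. t(28) for two cells of 15).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 observations")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise ValueError("zero pooled variance; t undefined")
    res = sps.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), a.size + b.size - 2, float(res.pvalue)


def pearson_correlation(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson product-moment correlation (r, p)."""
    res = sps.pearsonr(np.asarray(x, float), np.asarray(y, float))
    return float(res.statistic), float(res.pvalue)


def sex_effect_screen(table: pd.DataFrame, outcomes: tuple[str, ...],
                      factors: tuple[str, str] = ("strain", "context")
                      ) -> pd.DataFrame:
    """Screen each outcome for a sex effect alongside the design factors.

    Adds sex as a main effect to the strain x context model (Type-II SS) and
    reports its p-value per outcome; used to justify collapsing across sex.
    Single-sex cohorts are skipped with a notice row.
    """
    rows = []
    a, b = factors
    for outcome in outcomes:
        data = table[[outcome, "sex", a, b]].dropna()
        if data["sex"].nunique() < 2:
            rows.append({"outcome": outcome, "p_sex": np.nan,
                         "note": "single-sex cohort; skipped"})
            continue
        model = smf.ols(
            f"Q('{outcome}') ~ C(sex) + C(Q('{a}')) * C(Q('{b}'))",
            data=data).fit()
        if model.ssr <= 1e-12 * max(float(model.centered_tss), 1.0):
            raise ValueError(f"zero residual variance for {outcome!r}")
        aov = sm.stats.anova_lm(model, typ=2)
        rows.append({"outcome": outcome,
                     "p_sex": float(aov.loc["C(sex)", "PR(>F)"]), "note": ""})
    return pd.DataFrame(rows)


def holm_adjust(p_values: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values (optional; off by default in the
    reporting layer)."""
    from statsmodels.stats.multitest import multipletests
    return multipletests(np.asarray(p_values, float), method="holm")[1]


def cohort_anova_report(table: pd.DataFrame) -> pd.DataFrame:
    """Run the full outcome battery on a subject-level cohort table.

    Emission outcomes keep every subject; feature outcomes drop non-callers
    (their feature means are NaN and fall out in ``dropna``).  Returns tidy
    rows (outcome, effect, F, df_num, df_den, p).
    """
    rows = []
    for outcome in (*EMISSION_OUTCOMES, *FEATURE_OUTCOMES):
        if outcome not in table.columns:
            continue
        try:
            aov = two_way_anova(table, outcome)
        except ValueError as e:
            rows.append({"outcome": outcome, "effect": "unavailable",
                         "F": np.nan, "df_num": 1, "df_den": 0,
                         "p": np.nan, "note": str(e)})
            continue
        for effect, r in aov.effects.iterrows():
            rows.append({"outcome": outcome, "effect": effect,
                         "F": r["F"], "df_num": int(r["df_num"]),
                         "df_den": int(r["df_den"]), "p": r["p"], "note": ""})
    return pd.DataFrame(rows)
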