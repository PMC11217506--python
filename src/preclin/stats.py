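"""Normality-gated statistical comparisons.

The decision procedure used throughout the analysis:

1. screen each group for a single gross outlier with the two-sided Grubbs
   test (one pass, at most one removal per group),
2. test every group for normality with Shapiro-Wilk at alpha = 0.05,
3. dispatch: two normal groups -> unpaired two-sided t test; more than two
   normal groups -> one-way ANOVA with Holm-Sidak-corrected pairwise
   comparisons; two non-normal groups -> two-sided Mann-Whitney; more than
   two non-normal -> Kruskal-Wallis with Dunn's post-hoc; factorial designs
   -> two-way ANOVA with Holm-Sidak pairwise comparisons,
4. categorical 2x2 data -> two-sided Fisher's exact test.

Grubbs' critical value and Dunn's rank-based z post-hoc are implemented here
from their closed forms; the underlying distribution functions come from
scipy, the Holm-Sidak step-down from statsmodels.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from preclin.io import ValidationError

ALPHA_DEFAULT = 0.05


@dataclass
class ComparisonResult:
    """Outcome of a gated group comparison.

    ``p_values`` maps a pair label "a vs b" to its (corrected, where
    applicable) two-sided p; ``statistic`` is the omnibus statistic (t, F, U
    or H depending on the dispatched test).
    """

    test_name: str
    branch: str  # parametric | nonparametric | categorical
    statistic: float
    p_values: dict[str, float]
    alpha: float = ALPHA_DEFAULT
    warnings: list[str] = field(default_factory=list)

    @property
    def p_value(self) -> float:
        """The single p for two-group tests; smallest corrected p otherwise."""
        return min(self.p_values.values())


def grubbs_critical(n: int, alpha: float = ALPHA_DEFAULT) -> float:
    """Two-sided Grubbs critical value from the t-distribution closed form."""
    t = sps.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t**2 / (n - 2 + t**2))


def grubbs_filter(
    values, alpha: float = ALPHA_DEFAULT
) -> tuple[np.ndarray, list[float]]:
    """Single-pass two-sided Grubbs screen; removes at most one value.

    Samples with n < 3 or zero variance cannot be screened and are returned
    unchanged with a warning.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        warnings.warn("Grubbs test needs n >= 3; no screening applied", stacklevel=2)
        return x, []
    sd = x.std(ddof=1)
    if sd == 0:
        warnings.warn("zero variance; Grubbs screening not applicable", stacklevel=2)
        return x, []
    dev = np.abs(x - x.mean())
    g = dev.max() / sd
    if g > grubbs_critical(x.size, alpha):
        idx = int(np.argmax(dev))
        return np.delete(x, idx), [float(x[idx])]
    return x, []


def normality_gate(groups, alpha: float = ALPHA_DEFAULT) -> str:
    """Shapiro-Wilk gate: "parametric" iff every group's p >= alpha.

    Any group smaller than 3 cannot be tested and forces the nonparametric
    branch (with a warning).
    """
    for g in groups:
        g = np.asarray(g, dtype=float)
        if g.size < 3:
            warnings.warn(
                "group with n < 3 cannot be tested for normality; "
                "falling back to the nonparametric branch",
                stacklevel=2,
            )
            return "nonparametric"
        if sps.shapiro(g).pvalue < alpha:
            return "nonparametric"
    return "parametric"


def holm_sidak(p_values) -> np.ndarray:
    """Holm-Sidak step-down corrected p-values (same order as input)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="holm-sidak")[1]


def _pairwise_pooled_t(groups: list[np.ndarray], labels: list[str]) -> dict[str, float]:
    """Pairwise t statistics using the pooled within-group variance (ANOVA
    mean-square error, df = N - k), Holm-Sidak corrected."""
    k = len(groups)
    n_total = sum(g.size for g in groups)
    df_err = n_total - k
    mse = sum(((g - g.mean()) ** 2).sum() for g in groups) / df_err
    raw = []
    pairs = list(itertools.combinations(range(k), 2))
    for i, j in pairs:
        a, b = groups[i], groups[j]
        se = math.sqrt(mse * (1.0 / a.size + 1.0 / b.size))
        if se == 0:
            raw.append(1.0)
            continue
        t = (a.mean() - b.mean()) / se
        raw.append(2.0 * sps.t.sf(abs(t), df_err))
    corrected = holm_sidak(raw)
    return {
        f"{labels[i]} vs {labels[j]}": float(p)
        for (i, j), p in zip(pairs, corrected)
    }


def dunn_test(groups, labels=None) -> dict[str, float]:
    """Dunn's rank-based post-hoc for Kruskal-Wallis, tie-corrected,
    Bonferroni-adjusted over all pairwise comparisons."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    labels = labels or [f"g{i}" for i in range(len(groups))]
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks = []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start : start + g.size].mean())
        start += g.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term
    m = len(groups) * (len(groups) - 1) // 2
    out: dict[str, float] = {}
    for i, j in itertools.combinations(range(len(groups)), 2):
        se = math.sqrt(var_base * (1.0 / groups[i].size + 1.0 / groups[j].size))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        out[f"{labels[i]} vs {labels[j]}"] = float(min(1.0, p * m))
    return out


def _mann_whitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney: exact for combined n <= 20 without ties, else
    normal approximation with tie correction."""
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size + b.size <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    groups,
    labels=None,
    alpha: float = ALPHA_DEFAULT,
    branch: str | None = None,
) -> ComparisonResult:
    """Normality-gated comparison of two or more groups.

    ``branch`` overrides the Shapiro-Wilk gate when the caller has already
    decided (e.g. a known-asymmetric metric); otherwise the gate decides.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    if any(g.size == 0 for g in groups):
        raise ValidationError("empty group")
    labels = list(labels) if labels is not None else [f"g{i}" for i in range(len(groups))]
    if len(labels) != len(groups):
        raise ValidationError("labels must match groups")

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        branch = branch or normality_gate(groups, alpha)
        notes = [str(w.message) for w in caught]

    pair = f"{labels[0]} vs {labels[1]}"
    if len(groups) == 2:
        a, b = groups
        if branch == "parametric":
            res = sps.ttest_ind(a, b)
            return ComparisonResult(
                "t_unpaired", branch, float(res.statistic), {pair: float(res.pvalue)},
                alpha, notes,
            )
        stat, p = _mann_whitney(a, b)
        return ComparisonResult("mann_whitney", branch, stat, {pair: p}, alpha, notes)

    if branch == "parametric":
        f_stat, _ = sps.f_oneway(*groups)
        return ComparisonResult(
            "anova_holm_sidak", branch, float(f_stat),
            _pairwise_pooled_t(groups, labels), alpha, notes,
        )
    h_stat, _ = sps.kruskal(*groups)
    return ComparisonResult(
        "kruskal_dunn", branch, float(h_stat), dunn_test(groups, labels), alpha, notes
    )


def compare_factorial(
    data: pd.DataFrame,
    value: str,
    factor_a: str,
    factor_b: str,
    alpha: float = ALPHA_DEFAULT,
) -> ComparisonResult:
    """Two-way ANOVA (with interaction) plus Holm-Sidak pairwise comparisons
    of the ``factor_a`` levels pooled over ``factor_b``."""
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = data.rename(columns={value: "y", factor_a: "fa", factor_b: "fb"})
    model = smf.ols("y ~ C(fa) * C(fb)", data=df).fit()
    table = anova_lm(model, typ=2)
    p_values = {
        factor_a: float(table.loc["C(fa)", "PR(>F)"]),
        factor_b: float(table.loc["C(fb)", "PR(>F)"]),
        "interaction": float(table.loc["C(fa):C(fb)", "PR(>F)"]),
    }
    levels = sorted(df["fa"].unique())
    groups = [df.loc[df["fa"] == lv, "y"].to_numpy() for lv in levels]
    if len(groups) > 1:
        p_values.update(_pairwise_pooled_t(groups, [str(lv) for lv in levels]))
    return ComparisonResult(
        "two_way_anova_holm_sidak", "parametric",
        float(table.loc["C(fa)", "F"]), p_values, alpha,
    )


def fisher_exact(table_2x2) -> float:
    """Two-sided Fisher's exact p for a 2x2 contingency table.

    The two-sided p sums the probabilities of all tables with the observed
    margins that are no more likely than the observed one.
    """
    t = np.asarray(table_2x2)
    if t.shape != (2, 2):
        raise ValidationError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        if np.any(t < 0) or np.any(t != np.floor(t)):
            raise ValidationError("cells must be non-negative integers")
        t = t.astype(int)
    return float(sps.fisher_exact(t, alternative="two-sided")[1])
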