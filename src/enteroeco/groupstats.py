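"""Group-contrast statistics linking enterotypes to season, altitude and
host physiology: chi-square tests on enterotype proportions and
Kruskal-Wallis / Mann-Whitney / one-way ANOVA contrasts on per-sample
measurements."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ConfigError, SchemaError, TestResult
from .enterotypes import MIN_CLUSTER_SIZE

__all__ = [
    "chi_square_proportions",
    "compare_groups",
    "enterotype_distribution",
]


def chi_square_proportions(tab: pd.DataFrame) -> TestResult:
    """Pearson chi-square test of homogeneity on a contingency table.

    chi2 = sum (O - E)^2 / E with E = row_total * col_total / grand_total,
    df = (r-1)(c-1). Warns when any expected count is below 5.
    """
    obs = np.asarray(tab, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise SchemaError("contingency table needs at least 2 rows and 2 columns")
    if (obs < 0).any():
        raise SchemaError("negative counts in contingency table")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise SchemaError("zero marginal in contingency table")
    chi2, p, df, expected = stats.chi2_contingency(obs, correction=False)
    note = None
    if (expected < 5).any():
        note = f"{int((expected < 5).sum())} expected counts below 5"
        warnings.warn("chi-square: " + note, stacklevel=2)
    return TestResult(method="chi-square", statistic=float(chi2),
                      p_value=float(p), df=int(df), note=note)


def _mwu_z(x: np.ndarray, y: np.ndarray) -> float:
    """Tie-corrected normal-approximation Z for the Mann-Whitney U."""
    n1, n2 = len(x), len(y)
    u = stats.mannwhitneyu(x, y, alternative="two-sided",
                           method="asymptotic").statistic
    mu = n1 * n2 / 2.0
    pooled = np.concatenate([x, y])
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return 0.0
    return float((u - mu) / np.sqrt(sigma2))


def compare_groups(values, labels, family: str = "auto",
                   min_group_size: int = MIN_CLUSTER_SIZE,
                   alternative: str = "two-sided",
                   method: str = "asymptotic") -> TestResult:
    """Compare a per-sample measurement between groups.

    ``family='auto'``: two groups use the Mann-Whitney U (tie-corrected Z),
    three or more the tie-corrected Kruskal-Wallis H; ``family='anova'``
    forces one-way ANOVA. Groups below ``min_group_size`` observations are
    excluded and flagged; with fewer than two usable groups the contrast
    is skipped (NaN statistic, noted).
    """
    if family not in ("auto", "anova", "kruskal", "mannwhitney"):
        raise ConfigError(f"unknown family {family!r}")
    s = pd.DataFrame({"value": np.asarray(values, dtype=float),
                      "label": np.asarray(labels)}).dropna()
    groups = {lab: g["value"].to_numpy() for lab, g in s.groupby("label")}
    dropped = [lab for lab, v in groups.items() if len(v) < min_group_size]
    groups = {lab: v for lab, v in groups.items() if len(v) >= min_group_size}
    note = f"excluded groups below n={min_group_size}: {dropped}" if dropped else None
    if len(groups) < 2:
        return TestResult(method="skipped", statistic=float("nan"),
                          p_value=float("nan"),
                          note=(note or "") + "; fewer than 2 usable groups")
    arrays = [groups[k] for k in sorted(groups)]
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):  # complete ties: no evidence either way
        method_name = "mann-whitney" if len(arrays) == 2 else "kruskal-wallis"
        return TestResult(method=method_name, statistic=0.0, p_value=1.0,
                          note=note)
    if family == "anova":
        f, p = stats.f_oneway(*arrays)
        n = sum(len(a) for a in arrays)
        return TestResult(method="one-way ANOVA", statistic=float(f),
                          p_value=float(p), df=len(arrays) - 1, note=note)
    if family == "mannwhitney" or (family == "auto" and len(arrays) == 2):
        if len(arrays) != 2:
            raise ConfigError("mannwhitney requires exactly 2 groups")
        res = stats.mannwhitneyu(arrays[0], arrays[1],
                                 alternative=alternative, method=method)
        z = _mwu_z(arrays[0], arrays[1])
        return TestResult(method="mann-whitney", statistic=z,
                          p_value=float(res.pvalue), note=note)
    h, p = stats.kruskal(*arrays)
    return TestResult(method="kruskal-wallis", statistic=float(h),
                      p_value=float(p), df=len(arrays) - 1, note=note)


def enterotype_distribution(assignments: pd.Series, metadata: pd.DataFrame,
                            factor: str = "season",
                            min_cluster_size: int = MIN_CLUSTER_SIZE):
    """Cross-tabulate a metadata factor against enterotypes and test the
    shift in proportions with the chi-square test.

    Returns (contingency table, TestResult, row-normalised proportions).
    Enterotypes smaller than ``min_cluster_size`` overall are excluded
    from the test, mirroring the handling of tiny clusters elsewhere.
    """
    if factor not in metadata.columns:
        raise SchemaError(f"metadata has no column {factor!r}")
    joined = pd.DataFrame({
        "enterotype": assignments,
        "factor": metadata.loc[assignments.index, factor],
    })
    tab = pd.crosstab(joined["factor"], joined["enterotype"])
    sizes = assignments.value_counts()
    small = [c for c in tab.columns if sizes.get(c, 0) < min_cluster_size]
    tested = tab.drop(columns=small) if small else tab
    result = chi_square_proportions(tested)
    if small:
        result.note = ((result.note + "; ") if result.note else "") + \
            f"enterotypes excluded for size < {min_cluster_size}: {small}"
    proportions = tab.div(tab.sum(axis=1), axis=0)
    return tab, result, proportions
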