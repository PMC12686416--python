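"""Cohort-level statistics on isoform proportions.

Group contrasts (Welch t-test / one-way ANOVA) with the conventional star
notation, Pearson correlations of an isoform proportion against per-sample
features, genome-wide correlation ranking against expression or dependency
matrices, and perturbation fold changes (ratio of condition means).

Samples with undefined (NaN) proportions are excluded per analysis and the
excluded count reported; they are never imputed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ContrastResult",
    "CorrelationResult",
    "FoldChangeResult",
    "star_label",
    "compare_groups",
    "correlate_with_feature",
    "rank_correlations",
    "perturbation_fold_change",
]

# star notation boundaries (inclusive)
STAR_BOUNDS = ((0.0005, "***"), (0.005, "**"), (0.05, "*"))


def star_label(p: float) -> str:
    """Map a p-value to the star notation: *** p<=0.0005, ** p<=0.005, * p<=0.05."""
    if p is None or not np.isfinite(p):
        return "ns"
    for bound, stars in STAR_BOUNDS:
        if p <= bound:
            return stars
    return "ns"


@dataclasses.dataclass(frozen=True)
class ContrastResult:
    statistic: float
    p_value: float
    direction: int  # sign of (last group mean - first group mean); 0 for >2 groups
    star: str
    group_means: dict[str, float]
    group_ns: dict[str, int]
    n_excluded: int
    test: str


@dataclasses.dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int
    n_excluded: int


@dataclasses.dataclass(frozen=True)
class FoldChangeResult:
    fold: float
    p_value: float  # NaN when either arm has < 2 replicates
    star: str
    control_mean: float
    treated_mean: float
    n_control: int
    n_treated: int


def compare_groups(
    cohort: pd.DataFrame,
    label: str,
    grouping: str,
    test: str = "anova",
) -> ContrastResult:
    """Two-sided group contrast of one isoform's proportions.

    ``test="anova"`` runs a one-way ANOVA over all groups; ``test="t"`` runs a
    Welch (unequal-variance) t-test and requires exactly two groups.  Every
    group must contribute at least two defined values.
    """
    if label not in cohort.columns:
        raise KeyError(f"no column {label!r} in cohort table")
    values = cohort[label]
    n_excluded = int(values.isna().sum())
    sub = cohort.loc[values.notna(), [label, grouping]]
    groups = {k: g[label].to_numpy(float) for k, g in sub.groupby(grouping, observed=True, sort=True)}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups with defined values")
    for name, arr in groups.items():
        if arr.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 defined values")
    arrays = list(groups.values())
    if test == "anova":
        stat, p = sps.f_oneway(*arrays)
    elif test == "t":
        if len(arrays) != 2:
            raise ValueError("t-test requires exactly 2 groups")
        stat, p = sps.ttest_ind(arrays[0], arrays[1], equal_var=False)
    else:
        raise ValueError(f"unknown test: {test!r}")
    means = {k: float(v.mean()) for k, v in groups.items()}
    keys = list(groups)
    direction = 0
    if len(keys) == 2:
        direction = int(np.sign(means[keys[1]] - means[keys[0]]))
    return ContrastResult(
        statistic=float(stat),
        p_value=float(p),
        direction=direction,
        star=star_label(float(p)),
        group_means=means,
        group_ns={k: int(v.size) for k, v in groups.items()},
        n_excluded=n_excluded,
        test=test,
    )


def correlate_with_feature(cohort: pd.DataFrame, label: str, feature) -> CorrelationResult:
    """Pearson correlation between an isoform proportion and a per-sample feature.

    ``feature`` is aligned positionally (array-like) or by index (Series with
    the cohort's index).  Incomplete pairs are dropped; at least three complete
    pairs and a non-constant feature are required.
    """
    y = cohort[label].to_numpy(float)
    if isinstance(feature, pd.Series):
        x = feature.reindex(cohort.index).to_numpy(float)
    else:
        x = np.asarray(feature, dtype=float)
    if x.shape != y.shape:
        raise ValueError("feature length does not match cohort")
    mask = np.isfinite(x) & np.isfinite(y)
    n_excluded = int((~mask).sum())
    x, y = x[mask], y[mask]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(r=float(r), p_value=float(p), n=int(x.size), n_excluded=n_excluded)


def _pearson_p(r: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Two-sided p-value of a Pearson r via the t distribution with n-2 df."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1 - r**2))
        p = 2 * sps.t.sf(np.abs(t), np.maximum(n - 2, 1))
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    return np.where(n > 2, p, np.nan)


def rank_correlations(
    cohort: pd.DataFrame,
    label: str,
    feature_matrix: pd.DataFrame,
    sample_key: str = "sample_id",
    mode: str = "expression",
    fdr: bool = False,
) -> pd.DataFrame:
    """Rank all genes of a (genes x samples) matrix by Pearson r with an isoform proportion.

    ``mode="expression"`` ranks by descending r (strongest positive
    association first, as for an expression matrix); ``mode="dependency"``
    ranks ascending (strongest negative association first, the expected sign
    for essentiality scores).  Ties are broken by gene key so the ranking is
    deterministic; genes with undefined r sort last.  ``fdr=True`` appends a
    Benjamini-Hochberg q-value column.
    """
    if feature_matrix.shape[0] == 0:
        raise ValueError("empty feature matrix")
    samples = cohort[sample_key].astype(str)
    overlap = [s for s in samples if s in set(map(str, feature_matrix.columns))]
    if not overlap:
        raise ValueError("no overlapping samples between cohort and feature matrix")
    props = pd.Series(
        cohort.set_index(samples)[label].astype(float).loc[overlap].to_numpy(),
        index=overlap,
    )
    fm = feature_matrix.copy()
    fm.columns = fm.columns.map(str)
    fm = fm[overlap].astype(float)
    r = fm.T.corrwith(props)  # pairwise-complete Pearson per gene
    n = (fm.notna() & props.notna().to_numpy()).sum(axis=1)
    out = pd.DataFrame({"gene": fm.index.astype(str), "r": r.to_numpy(), "n": n.to_numpy()})
    out["p"] = _pearson_p(out["r"].to_numpy(), out["n"].to_numpy(float))
    ascending = mode == "dependency"
    out["_undef"] = ~np.isfinite(out["r"])
    out = out.sort_values(["_undef", "r", "gene"], ascending=[True, ascending, True], kind="mergesort")
    out = out.drop(columns="_undef").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    if fdr:
        from statsmodels.stats.multitest import multipletests

        q = np.full(len(out), np.nan)
        ok = np.isfinite(out["p"].to_numpy())
        if ok.any():
            q[ok] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
        out["q"] = q
    return out


def perturbation_fold_change(
    cohort: pd.DataFrame,
    label: str,
    control: str,
    treated: str,
    condition: str = "condition",
) -> FoldChangeResult:
    """Fold change of an isoform proportion between two conditions.

    fold = mean(treated proportions) / mean(control proportions), computed on
    per-sample proportions.  A two-sided Welch t-test is attached when both
    arms have at least two replicates; otherwise the p-value is NaN.
    """
    for cond in (control, treated):
        if not (cohort[condition] == cond).any():
            raise ValueError(f"condition {cond!r} not present")
    c = cohort.loc[cohort[condition] == control, label].dropna().to_numpy(float)
    t = cohort.loc[cohort[condition] == treated, label].dropna().to_numpy(float)
    if c.size < 1 or t.size < 1:
        raise ValueError("both conditions need at least 1 defined value")
    if c.mean() == 0:
        raise ValueError("undefined fold: control mean is 0")
    fold = t.mean() / c.mean()
    if c.size >= 2 and t.size >= 2:
        _, p = sps.ttest_ind(t, c, equal_var=False)
        p = float(p)
    else:
        p = float("nan")
    return FoldChangeResult(
        fold=float(fold),
        p_value=p,
        star=star_label(p),
        control_mean=float(c.mean()),
        treated_mean=float(t.mean()),
        n_control=int(c.size),
        n_treated=int(t.size),
    )
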