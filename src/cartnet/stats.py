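"""Per-feature three-group differential testing.

The testing policy for each feature (protein abundance or gene
expression):

1. optional log2 transform (abundances are positive and multiplicative);
2. Brown–Forsythe homoscedasticity check (median-centered Levene);
3. if variances are homogeneous: one-way ANOVA with Tukey HSD post hoc;
   otherwise: Kruskal–Wallis with Dunn post hoc;
4. post hoc tests are run only when the omnibus p < alpha;
5. optional Benjamini–Hochberg FDR across features (constant features are
   untestable and excluded from the FDR family).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DiffResult",
    "homoscedasticity_check",
    "one_way_anova",
    "tukey_hsd",
    "kruskal_wallis",
    "dunn_test",
    "bh_fdr",
    "diff_table",
]


@dataclass
class DiffResult:
    """Outcome of the testing policy for one feature."""

    feature: str
    test_used: str  # "anova" | "kruskal" | "untestable"
    statistic: float = float("nan")
    p_value: float = float("nan")
    p_adjusted: float = float("nan")
    levene_p: float = float("nan")
    transform: str = "none"
    posthoc: pd.DataFrame | None = field(default=None, repr=False)
    note: str = ""


def _as_groups(groups) -> list[np.ndarray]:
    out = [np.asarray(g, dtype=float) for g in groups]
    out = [g[np.isfinite(g)] for g in out]
    return out


def homoscedasticity_check(groups, alpha: float = 0.05) -> tuple[bool, float]:
    """Brown–Forsythe test; returns (variances-homogeneous, p).

    Groups whose values are all identical within each group give p = 1
    (no dispersion to compare).
    """
    gs = _as_groups(groups)
    if len(gs) < 2 or any(len(g) < 2 for g in gs):
        raise ValueError("need >= 2 groups with >= 2 finite values each")
    devs = [np.abs(g - np.median(g)) for g in gs]
    if all(np.ptp(d) == 0 for d in devs) and len({d[0] for d in devs}) == 1:
        return True, 1.0
    stat, p = sps.levene(*gs, center="median")
    if math.isnan(p):
        return True, 1.0
    return p >= alpha, float(p)


def one_way_anova(groups) -> tuple[float, float]:
    """Classical one-way ANOVA: F = MSB/MSW with (k-1, N-k) df."""
    gs = _as_groups(groups)
    if len(gs) < 2 or any(len(g) < 2 for g in gs):
        raise ValueError("need >= 2 groups with >= 2 values each")
    pooled = np.concatenate(gs)
    if np.ptp(pooled) == 0:
        raise ValueError("zero total variance: F statistic undefined")
    f, p = sps.f_oneway(*gs)
    return float(f), float(p)


def tukey_hsd(groups, labels=None, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons (studentized-range p-values).

    Returns one row per unordered pair with the mean difference, its sign,
    the p-value, and significance at ``alpha``.
    """
    gs = _as_groups(groups)
    if labels is None:
        labels = [f"group{i}" for i in range(len(gs))]
    res = sps.tukey_hsd(*gs)
    rows = []
    for i, j in itertools.combinations(range(len(gs)), 2):
        diff = float(np.mean(gs[i]) - np.mean(gs[j]))
        p = float(res.pvalue[i, j])
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "mean_diff": diff,
                "direction": int(np.sign(diff)),
                "p_value": p,
                "significant": p < alpha,
            }
        )
    return pd.DataFrame(rows)


def kruskal_wallis(groups) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H with chi-square (k-1) p-value."""
    gs = _as_groups(groups)
    if len(gs) < 2 or any(len(g) < 1 for g in gs):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(gs)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = sps.kruskal(*gs)
    return float(h), float(p)


def dunn_test(groups, labels=None, p_adjust: str = "bh", alpha: float = 0.05) -> pd.DataFrame:
    """Dunn's post hoc z-tests on mean ranks with tie correction.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) * (1/n_i + 1/n_j))
    where T = sum(t^3 - t) / (12 (N - 1)) over tie groups.  Two-sided
    normal p-values, adjusted by ``p_adjust`` ("bh", "bonferroni", "none").
    """
    gs = _as_groups(groups)
    if labels is None:
        labels = [f"group{i}" for i in range(len(gs))]
    pooled = np.concatenate(gs)
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    sizes = [len(g) for g in gs]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [ranks[bounds[i]:bounds[i + 1]].mean() for i in range(len(gs))]
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n_total - 1)) if n_total > 1 else 0.0
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    for i, j in itertools.combinations(range(len(gs)), 2):
        denom = math.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / denom if denom > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "z": z,
                "direction": int(np.sign(z)),
                "p_value": min(1.0, p),
            }
        )
    out = pd.DataFrame(rows)
    if p_adjust == "bh":
        out["p_adjusted"] = bh_fdr(out["p_value"].to_numpy())
    elif p_adjust == "bonferroni":
        out["p_adjusted"] = np.minimum(1.0, out["p_value"] * len(out))
    elif p_adjust == "none":
        out["p_adjusted"] = out["p_value"]
    else:
        raise ValueError(f"unknown p_adjust {p_adjust!r}")
    out["significant"] = out["p_adjusted"] < alpha
    return out


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def diff_table(
    values: pd.DataFrame,
    groups: pd.Series,
    transform: str = "log2",
    alpha: float = 0.05,
    fdr: str = "features",
) -> pd.DataFrame:
    """Apply the full testing policy to every row of a feature x sample table.

    Parameters
    ----------
    values
        Feature x sample table (abundances or expression).
    groups
        Group label per sample (index must cover ``values`` columns).
    transform
        "log2" (default for positive multiplicative data) or "none".
    fdr
        "features" (BH across feature-level omnibus p-values), or "none".

    Returns a per-feature DataFrame with the test used, statistic, raw and
    BH-adjusted p, the Brown–Forsythe p, a significance call, and post hoc
    results (as a nested object column) for features whose omnibus
    p < alpha.  Constant features are recorded as untestable and excluded
    from the FDR family.
    """
    if transform not in ("log2", "none"):
        raise ValueError(f"unknown transform {transform!r}")
    if fdr not in ("features", "none"):
        raise ValueError(f"unknown fdr mode {fdr!r}")
    labels = list(dict.fromkeys(groups.loc[values.columns]))
    results: list[DiffResult] = []
    for feature, row in values.iterrows():
        res = DiffResult(feature=str(feature), test_used="untestable", transform=transform)
        vals = row.astype(float)
        gs = [vals[groups.loc[values.columns] == g].dropna().to_numpy() for g in labels]
        if any(len(g) < 2 for g in gs):
            res.note = "insufficient observations in at least one group"
            results.append(res)
            continue
        pooled = np.concatenate(gs)
        if np.ptp(pooled) == 0:
            res.note = "constant feature"
            results.append(res)
            continue
        if transform == "log2":
            if np.any(pooled <= 0):
                res.note = "non-positive values; log2 transform not applicable"
                results.append(res)
                continue
            gs = [np.log2(g) for g in gs]
        try:
            homogeneous, levene_p = homoscedasticity_check(gs, alpha=alpha)
            res.levene_p = levene_p
            if homogeneous:
                res.test_used = "anova"
                res.statistic, res.p_value = one_way_anova(gs)
                if res.p_value < alpha:
                    res.posthoc = tukey_hsd(gs, labels=labels, alpha=alpha)
            else:
                res.test_used = "kruskal"
                res.statistic, res.p_value = kruskal_wallis(gs)
                if res.p_value < alpha:
                    res.posthoc = dunn_test(gs, labels=labels, alpha=alpha)
        except ValueError as exc:  # recorded per feature, table not aborted
            res.test_used = "untestable"
            res.note = str(exc)
        results.append(res)

    out = pd.DataFrame(
        {
            "feature": [r.feature for r in results],
            "test_used": [r.test_used for r in results],
            "statistic": [r.statistic for r in results],
            "p_value": [r.p_value for r in results],
            "levene_p": [r.levene_p for r in results],
            "transform": [r.transform for r in results],
            "note": [r.note for r in results],
            "posthoc": [r.posthoc for r in results],
        }
    ).set_index("feature")

    testable = out["test_used"] != "untestable"
    out["p_adjusted"] = np.nan
    if fdr == "features" and testable.any():
        out.loc[testable, "p_adjusted"] = bh_fdr(out.loc[testable, "p_value"].to_numpy())
    elif fdr == "none":
        out.loc[testable, "p_adjusted"] = out.loc[testable, "p_value"]
    out["significant"] = (out["p_adjusted"] < alpha).fillna(False)
    return out
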