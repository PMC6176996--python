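"""Correlation-threshold stability analysis.

Rationale: at small sample size (n = 8 per group), the retained edge set
is sensitive to the correlation threshold and to individual samples.  This
module characterizes that sensitivity so a threshold can be chosen where
the main graph properties (density, transitivity, diameter) are stable:

* **threshold sweep** — full-data network metrics across a threshold grid
  (link counts are non-increasing in the threshold by construction);
* **jackknife** — leave-one-sample-out recomputation of the metrics,
  summarized by the coefficient of variation (CV = sd/mean, 0 when the
  mean is 0);
* **recommendation** — smallest threshold above a floor at which the
  jackknife CV of density has plateaued (within a relative tolerance of
  its value at the next grid point).

Leave-one-out is used rather than random subsampling because it is
deterministic and exhaustive at these sample sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import build_network, correlation_matrix, network_metrics
from .quant import AbundanceMatrix

__all__ = [
    "StabilityReport",
    "threshold_sweep",
    "jackknife_stability",
    "stability_report",
    "recommend_threshold",
]

_WATCHED = ("density", "transitivity", "diameter")


@dataclass
class StabilityReport:
    """Sweep + jackknife summary for one group, with a recommendation."""

    group: str
    alpha: float
    sweep: pd.DataFrame  # index threshold; n_nodes, n_links, density, ...
    jackknife: pd.DataFrame  # index threshold; <metric>_mean/_sd/_cv
    recommended_threshold: float
    criterion_trace: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "alpha": self.alpha,
            "sweep": self.sweep.reset_index().to_dict(orient="list"),
            "jackknife": self.jackknife.reset_index().to_dict(orient="list"),
            "recommended_threshold": self.recommended_threshold,
            "criterion_trace": self.criterion_trace,
        }


def _single_group(matrix: AbundanceMatrix, group: str | None) -> str:
    groups = matrix.groups()
    if group is None:
        if len(groups) != 1:
            raise ValueError(f"matrix has groups {groups}; specify one")
        return groups[0]
    return group


def threshold_sweep(
    matrix: AbundanceMatrix,
    thresholds,
    group: str | None = None,
    alpha: float = 0.05,
    scale: str = "log2",
) -> pd.DataFrame:
    """Full-data network metrics at each threshold of a sorted grid."""
    group = _single_group(matrix, group)
    thresholds = list(thresholds)
    if any(not (0 <= t <= 1) for t in thresholds):
        raise ValueError("thresholds must lie in [0, 1]")
    if thresholds != sorted(thresholds):
        raise ValueError("threshold grid must be sorted ascending")
    corr = correlation_matrix(matrix, group, scale=scale)
    rows = []
    for t in thresholds:
        m = network_metrics(build_network(corr, r_min=t, alpha=alpha))
        rows.append(
            {
                "threshold": t,
                "n_nodes": m.n_nodes,
                "n_links": m.n_links,
                "density": m.density,
                "transitivity": m.transitivity,
                "diameter": m.diameter,
            }
        )
    return pd.DataFrame(rows).set_index("threshold")


def jackknife_stability(
    matrix: AbundanceMatrix,
    threshold: float,
    group: str | None = None,
    alpha: float = 0.05,
    scale: str = "log2",
) -> dict:
    """Leave-one-sample-out distribution of the watched metrics.

    Returns ``{"distribution": DataFrame (one row per left-out sample),
    "summary": DataFrame (mean, sd, cv per metric)}``.  Subsets yielding
    empty networks contribute metric value 0.
    """
    group = _single_group(matrix, group)
    cols = list(matrix.samples.index[matrix.samples["group"] == group])
    if len(cols) < 5:
        raise ValueError(
            f"group {group!r} has {len(cols)} samples; jackknife needs >= 5 "
            "so each subset keeps >= 4"
        )
    rows = []
    for left_out in cols:
        keep = [c for c in cols if c != left_out]
        sub = AbundanceMatrix(
            values=matrix.values[keep], samples=matrix.samples.loc[keep]
        )
        corr = correlation_matrix(sub, group, scale=scale)
        m = network_metrics(build_network(corr, r_min=threshold, alpha=alpha))
        rows.append(
            {
                "left_out": left_out,
                "density": m.density,
                "transitivity": m.transitivity,
                "diameter": float(m.diameter),
            }
        )
    dist = pd.DataFrame(rows).set_index("left_out")
    summary = pd.DataFrame(
        {
            "mean": dist.mean(),
            "sd": dist.std(ddof=1),
        }
    )
    summary["cv"] = np.where(
        summary["mean"] == 0, 0.0, summary["sd"] / summary["mean"].abs()
    )
    return {"distribution": dist, "summary": summary}


def stability_report(
    matrix: AbundanceMatrix,
    thresholds,
    group: str | None = None,
    alpha: float = 0.05,
    scale: str = "log2",
    floor: float = 0.5,
    tolerance: float = 0.20,
) -> StabilityReport:
    """Sweep + jackknife over a shared grid, with a threshold recommendation."""
    group = _single_group(matrix, group)
    sweep = threshold_sweep(matrix, thresholds, group=group, alpha=alpha, scale=scale)
    jk_rows = {}
    for t in sweep.index:
        summary = jackknife_stability(
            matrix, t, group=group, alpha=alpha, scale=scale
        )["summary"]
        row = {}
        for metric in _WATCHED:
            for stat in ("mean", "sd", "cv"):
                row[f"{metric}_{stat}"] = float(summary.loc[metric, stat])
        jk_rows[t] = row
    jackknife = pd.DataFrame.from_dict(jk_rows, orient="index")
    jackknife.index.name = "threshold"
    recommended, trace = recommend_threshold(
        jackknife["density_cv"], floor=floor, tolerance=tolerance
    )
    return StabilityReport(
        group=group,
        alpha=alpha,
        sweep=sweep,
        jackknife=jackknife,
        recommended_threshold=recommended,
        criterion_trace=trace,
    )


def recommend_threshold(
    density_cv: pd.Series, floor: float = 0.5, tolerance: float = 0.20
) -> tuple[float, list[str]]:
    """Smallest threshold >= floor where the density CV has plateaued.

    Plateau at grid point t: |CV(t) - CV(t_next)| <= tolerance * max(CV(t_next), eps).
    If no grid point qualifies (including the last point, which has no
    successor), the grid maximum is returned with a warning in the trace.
    A single-point grid returns that point.
    """
    cv = density_cv.sort_index()
    grid = list(cv.index)
    trace: list[str] = []
    if len(grid) == 1:
        trace.append(f"single-point grid; returning {grid[0]}")
        return float(grid[0]), trace
    eps = 1e-12
    for i, t in enumerate(grid[:-1]):
        if t < floor:
            trace.append(f"t={t}: below floor {floor}, skipped")
            continue
        here, nxt = float(cv.iloc[i]), float(cv.iloc[i + 1])
        rel = abs(here - nxt) / max(abs(nxt), eps)
        if rel <= tolerance:
            trace.append(
                f"t={t}: CV {here:.4g} within {tolerance:.0%} of next CV {nxt:.4g} -> plateau"
            )
            return float(t), trace
        trace.append(f"t={t}: CV {here:.4g} vs next {nxt:.4g} (rel {rel:.3g}) -> no plateau")
    trace.append(f"no plateau found; returning grid maximum {grid[-1]} (warning)")
    return float(grid[-1]), trace
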