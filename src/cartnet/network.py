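"""Group-specific thresholded Pearson correlation networks.

For each diet group, pairwise Pearson correlations are computed across the
group's biological replicates (log2 abundances by default).  Two-sided
p-values come from the exact t transform

    t = r * sqrt(n - 2) / sqrt(1 - r^2),   df = n - 2.

An edge joins two proteins when |r| >= r_min AND p <= alpha (defaults
r_min = 0.8, alpha = 0.05).  Nodes are proteins with at least one retained
edge.  Topology summaries: density 2L/(N(N-1)), transitivity (global
clustering coefficient), diameter of the largest connected component,
positive/negative edge counts, pathway-intrinsic densities, and hub
(highest-degree) proteins.  Edge overlap across the three diet networks is
reported as Venn region counts.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .quant import AbundanceMatrix

__all__ = [
    "CorrelationResult",
    "CorrelationNetwork",
    "NetworkMetrics",
    "correlation_matrix",
    "correlation_pvalues",
    "build_network",
    "network_metrics",
    "pathway_density",
    "hub_ranking",
    "edge_overlap",
]


@dataclass
class CorrelationResult:
    """Symmetric Pearson r and two-sided p matrices for one group."""

    group: str
    r: pd.DataFrame
    p: pd.DataFrame
    n: int
    dropped: list[str] = field(default_factory=list)


@dataclass
class CorrelationNetwork:
    """One group's thresholded, signed, undirected protein graph."""

    group: str
    edges: pd.DataFrame  # columns: protein_a, protein_b, r, p, sign
    r_min: float
    alpha: float
    n_samples: int

    @property
    def nodes(self) -> list[str]:
        if self.edges.empty:
            return []
        return sorted(set(self.edges["protein_a"]) | set(self.edges["protein_b"]))

    def edge_keys(self, signed: bool = False) -> set:
        """Unordered protein pairs, optionally tagged with correlation sign."""
        if self.edges.empty:
            return set()
        pairs = zip(self.edges["protein_a"], self.edges["protein_b"], self.edges["sign"])
        if signed:
            return {(a, b, s) for a, b, s in pairs}
        return {(a, b) for a, b, _ in pairs}

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(group=self.group, r_min=self.r_min, alpha=self.alpha)
        for row in self.edges.itertuples(index=False):
            g.add_edge(
                row.protein_a, row.protein_b,
                r=float(row.r), p=float(row.p), sign=int(row.sign),
            )
        return g


@dataclass
class NetworkMetrics:
    """Topology summary of one correlation network."""

    group: str
    n_nodes: int
    n_links: int
    density: float
    transitivity: float
    diameter: int
    n_positive: int
    n_negative: int
    density_all: float | None = None  # over all quantified proteins, if known
    pathway_density: dict[str, float] = field(default_factory=dict)
    hubs: list[tuple[str, int]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "n_nodes": self.n_nodes,
            "n_links": self.n_links,
            "density": self.density,
            "transitivity": self.transitivity,
            "diameter": self.diameter,
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
            "density_all": self.density_all,
            "pathway_density": self.pathway_density,
            "hubs": [[p, d] for p, d in self.hubs],
        }


def correlation_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Pearson r at sample size n via the t transform."""
    if n < 3:
        raise ValueError("need n >= 3 for correlation p-values (df = n - 2)")
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    return np.where(np.abs(r) >= 1.0, 0.0, p)


def correlation_matrix(
    matrix: AbundanceMatrix, group: str, scale: str = "log2"
) -> CorrelationResult:
    """Pairwise Pearson correlations among one group's samples.

    Proteins with any missing value or zero variance within the group are
    dropped from that group's network (pairwise-complete correlations would
    give a per-pair n that breaks the fixed-df p model).
    """
    if scale not in ("log2", "linear"):
        raise ValueError(f"unknown scale {scale!r}")
    values = matrix.group_values(group)
    n = values.shape[1]
    if n < 4:
        raise ValueError(f"group {group!r} has {n} samples; need >= 4")
    complete = values.dropna(axis=0)
    if scale == "log2":
        if (complete <= 0).any().any():
            raise ValueError("log2 scale requires strictly positive abundances")
        complete = np.log2(complete)
    variances = complete.var(axis=1)
    zero_var = variances.index[variances == 0].tolist()
    dropped = sorted(set(values.index) - set(complete.index)) + zero_var
    if dropped:
        warnings.warn(
            f"group {group}: dropped {len(dropped)} protein(s) with missing "
            f"values or zero variance: {dropped[:5]}{'...' if len(dropped) > 5 else ''}",
            stacklevel=2,
        )
    complete = complete.drop(index=zero_var)
    ids = list(complete.index)
    r = np.corrcoef(complete.to_numpy())
    r = np.clip(r, -1.0, 1.0)
    p = correlation_pvalues(r, n)
    np.fill_diagonal(p, 0.0)
    return CorrelationResult(
        group=group,
        r=pd.DataFrame(r, index=ids, columns=ids),
        p=pd.DataFrame(p, index=ids, columns=ids),
        n=n,
        dropped=dropped,
    )


def build_network(
    corr: CorrelationResult, r_min: float = 0.8, alpha: float = 0.05
) -> CorrelationNetwork:
    """Retain edges with |r| >= r_min and p <= alpha (canonical pair order)."""
    ids = list(corr.r.index)
    rows = []
    rmat, pmat = corr.r.to_numpy(), corr.p.to_numpy()
    iu, ju = np.triu_indices(len(ids), k=1)
    mask = (np.abs(rmat[iu, ju]) >= r_min) & (pmat[iu, ju] <= alpha)
    for i, j in zip(iu[mask], ju[mask]):
        a, b = sorted((ids[i], ids[j]))
        r = float(rmat[i, j])
        rows.append((a, b, r, float(pmat[i, j]), 1 if r > 0 else -1))
    edges = pd.DataFrame(
        rows, columns=["protein_a", "protein_b", "r", "p", "sign"]
    ).sort_values(["protein_a", "protein_b"], ignore_index=True)
    return CorrelationNetwork(
        group=corr.group, edges=edges, r_min=r_min, alpha=alpha, n_samples=corr.n
    )


def network_metrics(
    net: CorrelationNetwork,
    annotation: dict[str, str] | None = None,
    n_hubs: int = 10,
    universe_size: int | None = None,
) -> NetworkMetrics:
    """Topology summary of a thresholded network.

    Density uses N = nodes with degree >= 1 (a node is a protein with at
    least one significant correlation); when ``universe_size`` (the number
    of quantified proteins) is given, the density over that universe is
    additionally reported as ``density_all``.
    """
    g = net.to_networkx()
    n_nodes = g.number_of_nodes()
    n_links = g.number_of_edges()
    density = 2.0 * n_links / (n_nodes * (n_nodes - 1)) if n_nodes >= 2 else 0.0
    transitivity = nx.transitivity(g) if n_nodes else 0.0
    if n_nodes:
        largest = max(nx.connected_components(g), key=len)
        diameter = nx.diameter(g.subgraph(largest)) if len(largest) >= 2 else 0
    else:
        diameter = 0
    n_pos = int((net.edges["sign"] > 0).sum()) if not net.edges.empty else 0
    n_neg = n_links - n_pos
    density_all = None
    if universe_size is not None and universe_size >= 2:
        density_all = 2.0 * n_links / (universe_size * (universe_size - 1))
    per_pathway: dict[str, float] = {}
    if annotation is not None:
        for pathway in sorted(set(annotation.values())):
            per_pathway[pathway] = pathway_density(net, annotation, pathway)
    return NetworkMetrics(
        group=net.group,
        n_nodes=n_nodes,
        n_links=n_links,
        density=density,
        transitivity=transitivity,
        diameter=diameter,
        n_positive=n_pos,
        n_negative=n_neg,
        density_all=density_all,
        pathway_density=per_pathway,
        hubs=hub_ranking(net, k=n_hubs),
    )


def pathway_density(
    net: CorrelationNetwork, annotation: dict[str, str], pathway: str
) -> float:
    """Density of the subgraph induced by one pathway's network members.

    Edges with both endpoints annotated to ``pathway``, divided by
    C(m, 2) where m is the number of pathway members present in the node
    set; 0 when m < 2.  Unannotated proteins fall in category "other".
    """
    known = sorted(set(annotation.values()) | {"other"})
    if pathway not in known:
        raise ValueError(f"unknown pathway {pathway!r}; known: {known}")
    members = [p for p in net.nodes if annotation.get(p, "other") == pathway]
    m = len(members)
    if m < 2:
        return 0.0
    member_set = set(members)
    within = sum(
        1
        for row in net.edges.itertuples(index=False)
        if row.protein_a in member_set and row.protein_b in member_set
    )
    return within / (m * (m - 1) / 2.0)


def hub_ranking(net: CorrelationNetwork, k: int = 10) -> list[tuple[str, int]]:
    """Top-k proteins by degree, ties broken lexicographically by id."""
    g = net.to_networkx()
    ranked = sorted(g.degree(), key=lambda item: (-item[1], item[0]))
    return [(p, int(d)) for p, d in ranked[:k]]


def edge_overlap(
    networks: list[CorrelationNetwork], signed: bool = False
) -> dict[str, int]:
    """Venn region counts of edge sets across networks (sign ignored by default).

    For three networks returns the 7 region counts keyed
    ``"<g>"`` (exclusive), ``"<g1>&<g2>"`` (pairwise-only) and
    ``"<g1>&<g2>&<g3>"``, plus ``"total_distinct"``.
    """
    labels = [n.group for n in networks]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate group labels: {labels}")
    keys = {n.group: n.edge_keys(signed=signed) for n in networks}
    regions: dict[str, int] = {}
    all_edges: set = set().union(*keys.values()) if keys else set()
    for size in range(1, len(labels) + 1):
        for combo in itertools.combinations(labels, size):
            inside = set.intersection(*(keys[g] for g in combo))
            outside = set().union(
                *(keys[g] for g in labels if g not in combo), set()
            )
            regions["&".join(combo)] = len(inside - outside)
    regions["total_distinct"] = len(all_edges)
    return regions
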