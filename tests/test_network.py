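"""Correlation networks: edge filter, topology metrics, overlap, hubs."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cartnet import (
    AbundanceMatrix,
    CorrelationNetwork,
    CorrelationResult,
    SimConfig,
    build_network,
    correlation_matrix,
    correlation_pvalues,
    edge_overlap,
    hub_ranking,
    network_metrics,
    pathway_density,
    simulate_true_abundance,
)
from conftest import matrix_from_truth


def make_corr(pairs: dict, ids: list[str], n: int = 8) -> CorrelationResult:
    r = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
    p = pd.DataFrame(np.ones((len(ids), len(ids))), index=ids, columns=ids)
    np.fill_diagonal(p.to_numpy(), 0.0)
    for (a, b), (rv, pv) in pairs.items():
        r.loc[a, b] = r.loc[b, a] = rv
        p.loc[a, b] = p.loc[b, a] = pv
    return CorrelationResult(group="g", r=r, p=p, n=n)


def net_from_edges(edges: list[tuple[str, str]], group="g", signs=None) -> CorrelationNetwork:
    rows = []
    for k, (a, b) in enumerate(edges):
        a, b = sorted((a, b))
        sign = signs[k] if signs else 1
        rows.append((a, b, 0.9 * sign, 0.001, sign))
    return CorrelationNetwork(
        group=group,
        edges=pd.DataFrame(rows, columns=["protein_a", "protein_b", "r", "p", "sign"]),
        r_min=0.8,
        alpha=0.05,
        n_samples=8,
    )


class TestCorrelationPvalues:
    def test_r_08_n_8_worked_example(self):
        # t = 0.8*sqrt(6)/0.6 ~= 3.266, two-sided p at df 6 ~= 0.0171
        p = correlation_pvalues(np.array([[1.0, 0.8], [0.8, 1.0]]), n=8)[0, 1]
        t = 0.8 * np.sqrt(6) / 0.6
        assert p == pytest.approx(2 * sps.t.sf(t, 6), rel=1e-12)
        assert p == pytest.approx(0.0171, abs=2e-4)

    def test_zero_r_gives_p_one(self):
        assert correlation_pvalues(np.array([0.0]), n=10)[0] == pytest.approx(1.0)

    def test_matches_scipy_pearsonr(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            x, y = rng.normal(size=9), rng.normal(size=9)
            r_sp, p_sp = sps.pearsonr(x, y)
            p = correlation_pvalues(np.array([r_sp]), n=9)[0]
            assert p == pytest.approx(p_sp, rel=1e-9)


class TestCorrelationMatrix:
    def _matrix(self, values: np.ndarray, ids: list[str]) -> AbundanceMatrix:
        cols = [f"s{i}" for i in range(values.shape[1])]
        return AbundanceMatrix(
            values=pd.DataFrame(values, index=ids, columns=cols),
            samples=pd.DataFrame({"group": "G", "run": "r"}, index=cols),
        )

    def test_affine_transform_invariance_and_sign_flip(self):
        rng = np.random.default_rng(1)
        base = 2.0 ** rng.normal(3, 1, (3, 8))
        m = self._matrix(base, ["A", "B", "C"])
        corr = correlation_matrix(m, "G", scale="log2")
        # scaling a protein by a constant (affine in log space) keeps r
        scaled = base.copy()
        scaled[0] = base[0] ** 1.0 * 4.0  # positive scale -> log2 affine, a > 0
        corr2 = correlation_matrix(self._matrix(scaled, ["A", "B", "C"]), "G")
        np.testing.assert_allclose(corr.r, corr2.r, atol=1e-12)
        # inversion (negative slope in log space) flips the sign only
        flipped = base.copy()
        flipped[0] = 1.0 / base[0]
        corr3 = correlation_matrix(self._matrix(flipped, ["A", "B", "C"]), "G")
        assert corr3.r.loc["A", "B"] == pytest.approx(-corr.r.loc["A", "B"], abs=1e-12)
        assert corr3.r.loc["B", "C"] == pytest.approx(corr.r.loc["B", "C"], abs=1e-12)

    def test_zero_variance_protein_dropped_with_warning(self):
        rng = np.random.default_rng(2)
        vals = 2.0 ** rng.normal(0, 1, (3, 8))
        vals[2] = 5.0
        with pytest.warns(UserWarning, match="zero variance"):
            corr = correlation_matrix(self._matrix(vals, ["A", "B", "flat"]), "G")
        assert "flat" in corr.dropped and "flat" not in corr.r.index

    def test_too_few_samples_rejected(self):
        vals = 2.0 ** np.random.default_rng(0).normal(0, 1, (2, 3))
        with pytest.raises(ValueError, match="need >= 4"):
            correlation_matrix(self._matrix(vals, ["A", "B"]), "G")


class TestBuildNetwork:
    def test_filter_worked_example(self):
        corr = make_corr(
            {
                ("A", "B"): (0.85, 0.007),
                ("A", "C"): (0.75, 0.03),
                ("B", "C"): (-0.9, 0.002),
            },
            ["A", "B", "C"],
        )
        net = build_network(corr, r_min=0.8, alpha=0.05)
        assert net.edge_keys() == {("A", "B"), ("B", "C")}
        assert net.nodes == ["A", "B", "C"]
        signs = net.edges.set_index(["protein_a", "protein_b"])["sign"]
        assert signs.loc[("A", "B")] == 1 and signs.loc[("B", "C")] == -1

    def test_empty_pass_set(self):
        corr = make_corr({("A", "B"): (0.5, 0.2)}, ["A", "B"])
        net = build_network(corr)
        assert net.nodes == [] and len(net.edges) == 0

    def test_p_clause_redundant_at_n_8(self):
        """At n = 8 the critical |r| for p = 0.05 is ~0.707 < 0.8, so the
        p <= 0.05 clause never removes an edge that |r| >= 0.8 admits."""
        t_crit = sps.t.isf(0.025, df=6)
        r_crit = t_crit / np.sqrt(t_crit**2 + 6)
        assert r_crit == pytest.approx(0.707, abs=5e-4)
        rng = np.random.default_rng(3)
        for seed in range(5):
            truth = simulate_true_abundance(SimConfig(seed=seed), seed=seed)
            m = matrix_from_truth(truth)
            for group in ("LFLS", "LFHS", "HFLS"):
                corr = correlation_matrix(m, group)
                with_p = build_network(corr, r_min=0.8, alpha=0.05)
                without_p = build_network(corr, r_min=0.8, alpha=1.0)
                assert with_p.edge_keys() == without_p.edge_keys()
        del rng

    def test_monotone_in_threshold(self):
        truth = simulate_true_abundance(SimConfig(), seed=5)
        corr = correlation_matrix(matrix_from_truth(truth), "LFHS")
        e_08 = build_network(corr, r_min=0.8).edge_keys()
        e_09 = build_network(corr, r_min=0.9).edge_keys()
        assert e_09 <= e_08


# ---------------------------------------------------------------------------
# Brute-force graph oracles


def brute_force_metrics(edges: list[tuple[int, int]], n_vertices: int):
    """Density/transitivity/diameter from adjacency-matrix arithmetic."""
    adj = np.zeros((n_vertices, n_vertices), dtype=int)
    for a, b in edges:
        adj[a, b] = adj[b, a] = 1
    deg = adj.sum(axis=1)
    connected = np.where(deg > 0)[0]
    n = len(connected)
    links = len(edges)
    density = 2 * links / (n * (n - 1)) if n >= 2 else 0.0
    triangles = np.trace(adj @ adj @ adj) / 6
    triples = sum(d * (d - 1) / 2 for d in deg)
    transitivity = 3 * triangles / triples if triples else 0.0
    # Floyd–Warshall on the largest component
    big = 10**6
    dist = np.where(adj == 1, 1, big)
    np.fill_diagonal(dist, 0)
    for k in range(n_vertices):
        dist = np.minimum(dist, dist[:, k : k + 1] + dist[k : k + 1, :])
    comps: list[set[int]] = []
    seen: set[int] = set()
    for v in connected:
        if v in seen:
            continue
        comp = {u for u in connected if dist[v, u] < big}
        comps.append(comp)
        seen |= comp
    if not comps:
        return density, transitivity, 0
    largest = max(comps, key=len)
    idx = sorted(largest)
    diameter = int(dist[np.ix_(idx, idx)].max()) if len(idx) >= 2 else 0
    return density, transitivity, diameter


class TestMetricsOracle:
    def test_small_worked_examples(self):
        # 4 nodes, 3 links -> density 0.5
        m = network_metrics(net_from_edges([("A", "B"), ("B", "C"), ("C", "D")]))
        assert m.density == pytest.approx(0.5)
        # complete K5 -> density 1, transitivity 1, diameter 1
        k5 = net_from_edges(list(itertools.combinations("ABCDE", 2)))
        mk = network_metrics(k5)
        assert (mk.density, mk.transitivity, mk.diameter) == (1.0, 1.0, 1)
        # path A-B-C -> transitivity 0, diameter 2
        mp = network_metrics(net_from_edges([("A", "B"), ("B", "C")]))
        assert mp.transitivity == 0.0 and mp.diameter == 2

    def test_agrees_with_brute_force_on_random_graphs(self):
        """Density, transitivity and diameter match adjacency-matrix and
        Floyd–Warshall computations exactly on 100 random graphs."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            n_vertices = int(rng.integers(3, 21))
            p_edge = rng.uniform(0.05, 0.6)
            edges = [
                (i, j)
                for i, j in itertools.combinations(range(n_vertices), 2)
                if rng.random() < p_edge
            ]
            net = net_from_edges([(f"n{i:02d}", f"n{j:02d}") for i, j in edges])
            m = network_metrics(net)
            density, transitivity, diameter = brute_force_metrics(edges, n_vertices)
            assert m.density == pytest.approx(density, abs=1e-12)
            assert m.transitivity == pytest.approx(transitivity, abs=1e-12)
            assert m.diameter == diameter

    def test_sign_bookkeeping(self):
        net = net_from_edges(
            [("A", "B"), ("B", "C"), ("C", "D")], signs=[1, -1, -1]
        )
        m = network_metrics(net)
        assert m.n_positive + m.n_negative == m.n_links == 3
        assert (m.n_positive, m.n_negative) == (1, 2)


class TestPathwayDensity:
    ANNOTATION = {"A": "pw", "B": "pw", "C": "pw", "D": "other_pw"}

    def test_induced_subgraph_density(self):
        net = net_from_edges([("A", "B"), ("C", "D")])
        assert pathway_density(net, self.ANNOTATION, "pw") == pytest.approx(1 / 3)

    def test_single_member_degenerate(self):
        net = net_from_edges([("A", "D")])
        assert pathway_density(net, {"A": "pw", "D": "x"}, "pw") == 0.0

    def test_unknown_pathway_lists_known(self):
        net = net_from_edges([("A", "B")])
        with pytest.raises(ValueError, match="known"):
            pathway_density(net, self.ANNOTATION, "nope")

    def test_planted_block_dominates_null_group(self):
        """A pathway with block_rho = 0.9 in one group yields higher
        intrinsic density there than in a rho = 0 group (50 seeds here;
        the full 1000-rep comparison runs in the acceptance suite)."""
        cfg = SimConfig(
            groups=("planted", "null"),
            n_replicates_per_group=8,
            pathways=(("pw", 12), ("bg", 12)),
            block_rho={"planted": {"pw": 0.9}, "null": {}},
            group_log2_effects={},
        )
        ann = cfg.annotation()
        wins = 0
        for seed in range(50):
            truth = simulate_true_abundance(cfg, seed=seed)
            m = matrix_from_truth(truth)
            dens = {}
            for g in ("planted", "null"):
                net = build_network(correlation_matrix(m, g))
                dens[g] = pathway_density(net, ann, "pw")
            wins += dens["planted"] > dens["null"]
        assert wins >= 48


class TestHubs:
    def test_star_center_first(self):
        net = net_from_edges([("H", leaf) for leaf in "ABCDE"])
        ranking = hub_ranking(net, k=3)
        assert ranking[0] == ("H", 5)

    def test_empty_network_empty_ranking(self):
        net = net_from_edges([])
        assert hub_ranking(net) == []

    def test_degree_ties_break_lexicographically(self):
        net = net_from_edges([("B", "Z"), ("A", "Y")])
        ranking = hub_ranking(net, k=4)
        assert [p for p, _ in ranking] == ["A", "B", "Y", "Z"]


class TestEdgeOverlap:
    def test_worked_example(self):
        nets = [
            net_from_edges([("A", "B"), ("B", "C")], group="g1"),
            net_from_edges([("A", "B")], group="g2"),
            net_from_edges([("A", "B"), ("C", "D")], group="g3"),
        ]
        regions = edge_overlap(nets)
        assert regions["g1&g2&g3"] == 1
        assert regions["g1"] == 1 and regions["g3"] == 1 and regions["g2"] == 0
        assert regions["total_distinct"] == 3

    def test_identical_networks_all_in_core(self):
        nets = [
            net_from_edges([("A", "B"), ("C", "D")], group=g) for g in "xyz"
        ]
        regions = edge_overlap(nets)
        assert regions["x&y&z"] == 2
        assert all(regions[k] == 0 for k in regions if k not in ("x&y&z", "total_distinct"))

    def test_disjoint_networks_empty_core(self):
        nets = [
            net_from_edges([("A", "B")], group="x"),
            net_from_edges([("C", "D")], group="y"),
            net_from_edges([("E", "F")], group="z"),
        ]
        assert edge_overlap(nets)["x&y&z"] == 0

    def test_duplicate_labels_rejected(self):
        nets = [net_from_edges([("A", "B")], group="x")] * 2
        with pytest.raises(ValueError, match="duplicate"):
            edge_overlap(nets)

    def test_signed_mode_distinguishes_flipped_edges(self):
        pos = net_from_edges([("A", "B")], group="x", signs=[1])
        neg = net_from_edges([("A", "B")], group="y", signs=[-1])
        filler = net_from_edges([], group="z")
        unsigned = edge_overlap([pos, neg, filler])
        signed = edge_overlap([pos, neg, filler], signed=True)
        assert unsigned["x&y"] == 1 and signed["x&y"] == 0


class TestNullCalibration:
    def test_null_edge_rate_matches_analytic_t_tail(self):
        """For independent Gaussian features at n = 8, P(|r| >= 0.8) equals
        the analytic two-sided t tail ~0.0171; empirical rate over > 10,000
        simulated pairs is within 3 binomial standard errors."""
        t_08 = 0.8 * np.sqrt(6) / 0.6
        analytic = 2 * sps.t.sf(t_08, df=6)
        cfg = SimConfig(
            groups=("A",),
            n_replicates_per_group=8,
            pathways=(("null", 60),),
            block_rho={"A": {"null": 0.0}},
            group_log2_effects={},
        )
        passed = total = 0
        for seed in range(8):  # 8 x C(60,2) = 14,160 pairs
            truth = simulate_true_abundance(cfg, seed=seed)
            corr = correlation_matrix(matrix_from_truth(truth), "A")
            net = build_network(corr, r_min=0.8, alpha=0.05)
            k = corr.r.shape[0]
            total += k * (k - 1) // 2
            passed += len(net.edges)
        rate = passed / total
        se = np.sqrt(analytic * (1 - analytic) / total)
        assert abs(rate - analytic) < 3 * se

    def test_within_block_edge_rate_monotone_in_rho(self):
        """Planted rho in {0.3, 0.6, 0.9} gives monotonically increasing
        within-block edge probability (fixed seeds)."""
        rates = []
        for rho in (0.3, 0.6, 0.9):
            cfg = SimConfig(
                groups=("A",),
                n_replicates_per_group=8,
                pathways=(("block", 15),),
                block_rho={"A": {"block": rho}},
                group_log2_effects={},
            )
            passed = total = 0
            for seed in range(40):
                truth = simulate_true_abundance(cfg, seed=seed)
                corr = correlation_matrix(matrix_from_truth(truth), "A")
                net = build_network(corr)
                k = corr.r.shape[0]
                total += k * (k - 1) // 2
                passed += len(net.edges)
            rates.append(passed / total)
        assert rates[0] < rates[1] < rates[2]
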