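import math
from itertools import combinations

import numpy as np
import pytest

import herbnet.proximity as prox_mod
from herbnet.proximity import (
    ProximityResult,
    combination_proximity,
    compare_rule_z_to_reference,
    is_proximal,
    relative_proximity,
)
from herbnet.synthetic import SyntheticSpec, generate_interactome

# Published herb-level proximity z values used as a threshold-contract
# fixture (asthma, diabetes, arthritis, stroke and inflammation combinations).
PUBLISHED_HERB_Z = {
    ("asthma", "Morus alba"): -0.17,
    ("asthma", "Ephedra sinica"): -0.43,
    ("asthma", "Perilla frutescens"): -0.19,
    ("asthma", "Pinellia ternata"): -1.20,
    ("diabetes", "Trichosanthes kirilowii"): -2.59,
    ("diabetes", "Nelumbo nucifera"): -2.59,
    ("diabetes", "Dioscorea polystachya"): -1.02,
    ("diabetes", "Rehmannia glutinosa"): -2.13,
    ("arthritis", "Gentiana macrophylla"): -2.40,
    ("arthritis", "Angelica pubescens"): -3.92,
    ("arthritis", "Achyranthes bidentata"): -4.48,
    ("stroke", "Acorus gramineus"): -2.02,
    ("stroke", "Pinellia ternata"): -4.34,
    ("stroke", "Arisaema amurense"): -1.85,
    ("inflammation", "Manis pentadactyla"): -3.34,
    ("inflammation", "Citrus unshiu"): -3.38,
    ("inflammation", "Gleditsia sinensis"): -2.59,
}


def _result(z, degenerate=False):
    return ProximityResult(
        entity_id="e", phenotype_id="p", observed_d=1.0, null_mean=1.0,
        null_sd=0.0 if degenerate else 1.0, z=float("nan") if degenerate else z,
        n_permutations=10, seed=0, n_targets_used=1, n_phenotype_genes_used=1,
        degenerate=degenerate,
    )


class TestRelativeProximity:
    def test_z_standardisation_identity(self):
        spec = SyntheticSpec(n_genes=300, seed=0)
        g = generate_interactome(spec)
        rng = np.random.default_rng(1)
        nodes = sorted(g.nodes)
        P = set(rng.choice(nodes, 10, replace=False))
        S = set(rng.choice(nodes, 8, replace=False))
        r = relative_proximity(g, P, S, n_perm=100, rng=4)
        assert r.z == pytest.approx((r.observed_d - r.null_mean) / r.null_sd)
        assert r.n_permutations == 100

    def test_targets_inside_module_give_zero_distance_and_negative_z(self):
        spec = SyntheticSpec(n_genes=300, seed=0)
        g = generate_interactome(spec)
        nodes = sorted(g.nodes)
        P = set(nodes[:30])
        S = set(nodes[5:15])  # subset of P
        r = relative_proximity(g, P, S, n_perm=100, rng=0)
        assert r.observed_d == 0.0
        assert r.null_mean > 0
        assert r.z < 0

    def test_seed_reproducibility(self):
        spec = SyntheticSpec(n_genes=300, seed=0)
        g = generate_interactome(spec)
        nodes = sorted(g.nodes)
        P, S = set(nodes[10:20]), set(nodes[40:48])
        r1 = relative_proximity(g, P, S, n_perm=50, rng=11)
        r2 = relative_proximity(g, P, S, n_perm=50, rng=11)
        assert (r1.z, r1.null_mean, r1.null_sd) == (r2.z, r2.null_mean, r2.null_sd)

    def test_z_invariant_under_order_preserving_relabeling(self):
        spec = SyntheticSpec(n_genes=200, seed=7)
        g = generate_interactome(spec)
        import networkx as nx

        from herbnet.interactome import Interactome

        mapping = {n: "X" + n for n in g.graph.nodes}  # preserves sort order
        g2 = Interactome(graph=nx.relabel_nodes(g.graph, mapping))
        nodes = sorted(g.nodes)
        P, S = set(nodes[20:30]), set(nodes[50:58])
        r1 = relative_proximity(g, P, S, n_perm=80, rng=3)
        r2 = relative_proximity(
            g2, {"X" + n for n in P}, {"X" + n for n in S}, n_perm=80, rng=3
        )
        assert r1.z == pytest.approx(r2.z)

    def test_exhaustive_null_on_small_graph(self):
        """MC z agrees with the exact null enumerated over all degree-
        consistent sample pairs on a 60-node graph with |P| = |S| = 2."""
        from oracles import enumerate_degree_matched_pairs

        spec = SyntheticSpec(n_genes=60, attachment=2, seed=3)
        g = generate_interactome(spec)
        bins = g.degree_bins(min_bin_size=5)
        nodes = sorted(g.nodes)
        P = {nodes[7], nodes[23]}
        S = {nodes[40], nodes[55]}
        from herbnet.interactome import closest_distance

        d_obs = closest_distance(g, P, S)
        P_sets = enumerate_degree_matched_pairs(bins.bins, bins.node_bin, P)
        S_sets = enumerate_degree_matched_pairs(bins.bins, bins.node_bin, S)
        null = [
            closest_distance(g, Pr, Sr) for Pr in P_sets for Sr in S_sets
        ]
        mu, sd = float(np.mean(null)), float(np.std(null, ddof=0))
        z_exact = (d_obs - mu) / sd
        n_perm = 1000
        r = relative_proximity(g, P, S, n_perm=n_perm, rng=5, min_bin_size=5, ddof=1)
        se = math.sqrt((1 + z_exact**2 / 2) / n_perm)
        assert abs(r.z - z_exact) <= 3 * se


class TestIsProximal:
    def test_boundary_inclusive(self):
        assert is_proximal(_result(-0.15)) is True
        assert is_proximal(_result(-0.1499)) is False

    def test_degenerate_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            is_proximal(_result(0.0, degenerate=True))

    def test_published_combination_z_values_all_pass_threshold(self):
        for (_, herb), z in PUBLISHED_HERB_Z.items():
            assert is_proximal(_result(z)), herb


class TestCombinationVerdict:
    def _patched(self, monkeypatch, zs, toy_kb):
        calls = iter(zs)

        def fake(g, P, S, n_perm, rng, **kw):
            return _result(next(calls))

        monkeypatch.setattr(prox_mod, "relative_proximity", fake)
        from herbnet.interactome import prepare_graph

        g = prepare_graph([("g1", "g2"), ("g2", "g3"), ("g3", "g4")])
        return combination_proximity(g, toy_kb, ["hA", "hB"], "ph1", 10, 0)

    def test_majority_passes(self, monkeypatch, toy_kb):
        v = self._patched(monkeypatch, [-1.0, 1.0], toy_kb)
        assert v.n_evaluated == 2 and v.n_pass == 1
        assert not v.proximal  # 1/2 is not a strict majority

    def test_two_of_three_majority(self, monkeypatch, toy_kb):
        toy_kb.herb_compounds["hC"] = frozenset({"c1"})
        calls = iter([-1.0, -1.0, 1.0])
        monkeypatch.setattr(
            prox_mod, "relative_proximity",
            lambda g, P, S, n_perm, rng, **kw: _result(next(calls)),
        )
        from herbnet.interactome import prepare_graph

        g = prepare_graph([("g1", "g2"), ("g2", "g3"), ("g3", "g4")])
        v = combination_proximity(g, toy_kb, ["hA", "hB", "hC"], "ph1", 10, 0)
        assert v.proximal

    def test_single_failing_herb_not_proximal(self, monkeypatch, toy_kb):
        calls = iter([0.5])
        monkeypatch.setattr(
            prox_mod, "relative_proximity",
            lambda g, P, S, n_perm, rng, **kw: _result(next(calls)),
        )
        from herbnet.interactome import prepare_graph

        g = prepare_graph([("g1", "g2"), ("g2", "g3"), ("g3", "g4")])
        v = combination_proximity(g, toy_kb, ["hA"], "ph1", 10, 0)
        assert not v.proximal

    def test_unresolvable_herb_excluded_from_denominator(self, toy_kb):
        # hC's only compound has no targets -> unresolved
        from herbnet.interactome import prepare_graph

        g = prepare_graph([("g1", "g2"), ("g2", "g3"), ("g3", "g4")])
        v = combination_proximity(g, toy_kb, ["hA", "hC"], "ph1", 10, 0, min_bin_size=1)
        assert v.unresolved == ["hC"]
        assert v.n_evaluated == 1


class TestGroupComparison:
    def test_identical_lists_give_p_near_one(self):
        x = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]
        stat, p, method = compare_rule_z_to_reference(x, list(x))
        assert method == "t"
        assert p == pytest.approx(1.0)

    def test_auto_switches_to_mannwhitney_for_small_samples(self):
        _, _, method = compare_rule_z_to_reference([1.0, 2.0], [0.1, 0.2, 0.3])
        assert method == "mannwhitney"

    def test_singleton_with_t_requested_raises(self):
        with pytest.raises(ValueError, match="mannwhitney"):
            compare_rule_z_to_reference([1.0], [0.1, 0.2], method="t")

    def test_mannwhitney_exact_small_sample(self):
        """U = 0 for fully separated {1,2,3} vs {4,5,6}; exact two-sided p
        from enumerating all rank assignments."""
        stat, p, _ = compare_rule_z_to_reference([1, 2, 3], [4, 5, 6], method="mannwhitney")
        assert stat == 0.0
        # enumeration oracle: U statistic over all C(6,3) group assignments
        values = [1, 2, 3, 4, 5, 6]
        u_obs = 0
        count_extreme = 0
        total = 0
        for group in combinations(range(6), 3):
            xs = [values[i] for i in group]
            ys = [values[i] for i in range(6) if i not in group]
            u = sum(1 for a in xs for b in ys if a > b)
            u = min(u, 9 - u)
            total += 1
            if u <= u_obs:
                count_extreme += 1
        assert p == pytest.approx(count_extreme / total)

    def test_power_against_shifted_normal(self):
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(40):
            a = rng.normal(-2.5, 1, 50)
            b = rng.normal(0, 1, 50)
            _, p, _ = compare_rule_z_to_reference(a, b)
            hits += p < 0.001
        assert hits >= 38
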