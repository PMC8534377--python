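"""Modularity arithmetic, Louvain optimality and multiscale module counts.

Two independent oracles guard the Louvain implementation: exhaustive
enumeration of all set partitions on graphs small enough for it (Bell-number
brute force), and igraph's multilevel algorithm on structured graphs where
both should find the optimum.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from funcstate import (
    GeneratorSpec,
    ValidationError,
    WeightedNetwork,
    decompose,
    functional_partition,
    generate,
    louvain,
    modularity,
    module_count_curve,
    modules_entropy_relation,
    rescaled_tau_grid,
    sbm_block_sizes,
)


def set_partitions(n: int):
    """All partitions of range(n) as label arrays (Bell(n) of them)."""

    def rec(i, parts):
        if i == n:
            yield [list(p) for p in parts]
            return
        for p in parts:
            p.append(i)
            yield from rec(i + 1, parts)
            p.pop()
        parts.append([i])
        yield from rec(i + 1, parts)
        parts.pop()

    for blocks in rec(0, []):
        labels = np.empty(n, dtype=int)
        for c, block in enumerate(blocks):
            labels[block] = c
        yield labels


def brute_force_best_q(weights: np.ndarray) -> float:
    return max(modularity(weights, a) for a in set_partitions(weights.shape[0]))


def two_cliques_weights(bridge: float | None) -> np.ndarray:
    """Two unit-weight 4-cliques, optionally joined by one bridge edge."""
    w = np.zeros((8, 8))
    for block in (range(4), range(4, 8)):
        for i in block:
            for j in block:
                if i != j:
                    w[i, j] = 1.0
    if bridge is not None:
        w[0, 4] = w[4, 0] = bridge
    return w


class TestModularity:
    def test_two_disconnected_cliques_split_gives_half(self):
        w = two_cliques_weights(bridge=None)
        assignment = np.array([0] * 4 + [1] * 4)
        assert modularity(w, assignment) == pytest.approx(0.5, abs=1e-12)

    def test_matches_networkx_on_weighted_graph(self, ws_net):
        import networkx as nx

        g = nx.from_numpy_array(ws_net.weights)
        rng = np.random.default_rng(0)
        assignment = rng.integers(0, 4, size=ws_net.n_nodes)
        communities = [set(np.flatnonzero(assignment == c)) for c in range(4)]
        expected = nx.community.modularity(g, communities, weight="weight")
        assert modularity(ws_net.weights, assignment) == pytest.approx(expected, abs=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_trivial_partition_identities(self, seed):
        """Q(all-in-one) = 0 and Q(singletons) = -sum (k_i/2m)^2 on random graphs."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 12))
        w = np.triu(rng.uniform(0, 2, (n, n)) * (rng.uniform(size=(n, n)) < 0.6), k=1)
        w = w + w.T
        if w.sum() == 0:
            w[0, 1] = w[1, 0] = 1.0
        k = w.sum(axis=1)
        two_m = k.sum()
        assert modularity(w, np.zeros(n, dtype=int)) == pytest.approx(0.0, abs=1e-12)
        assert modularity(w, np.arange(n)) == pytest.approx(
            -np.sum((k / two_m) ** 2), abs=1e-12
        )

    def test_assignment_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            modularity(two_cliques_weights(1.0), np.zeros(5, dtype=int))


class TestLouvain:
    def test_two_cliques_with_weak_bridge(self):
        w = two_cliques_weights(bridge=0.1)
        part = louvain(w, seed=0)
        assert part.n_modules == 2
        assert len(set(part.assignment[:4])) == 1
        assert len(set(part.assignment[4:])) == 1
        # brute force over all 4140 partitions of 8 nodes confirms optimality
        assert part.modularity == pytest.approx(brute_force_best_q(w), abs=1e-12)

    @pytest.mark.parametrize(
        "make_weights",
        [
            lambda: two_cliques_weights(bridge=1.0),
            lambda: generate(GeneratorSpec("path", 7, 0)).weights,
            lambda: generate(GeneratorSpec("complete", 6, 0)).weights,
            lambda: generate(
                GeneratorSpec(
                    "watts_strogatz", 8, 2,
                    {"k": 4, "p": 0.3,
                     "weights": {"distribution": "uniform", "low": 0.2, "high": 2.0}},
                )
            ).weights,
        ],
        ids=["two_cliques", "path7", "complete6", "weighted_ws8"],
    )
    def test_matches_exhaustive_optimum_on_small_graphs(self, make_weights):
        w = make_weights()
        part = louvain(w, seed=1, n_restarts=10)
        assert part.modularity == pytest.approx(brute_force_best_q(w), abs=1e-12)

    def test_complete_graph_is_one_module(self):
        w = generate(GeneratorSpec("complete", 8, 0)).weights
        assert louvain(w, seed=0).n_modules == 1

    def test_never_worse_than_trivial_partitions(self, ws_net, fungal_like_net):
        for net in (ws_net, fungal_like_net):
            w = net.weights
            part = louvain(w, seed=3)
            q_single = modularity(w, np.zeros(net.n_nodes, dtype=int))
            q_isolated = modularity(w, np.arange(net.n_nodes))
            assert part.modularity >= max(q_single, q_isolated) - 1e-12

    def test_deterministic_given_seed(self, ws_net):
        a = louvain(ws_net.weights, seed=42)
        b = louvain(ws_net.weights, seed=42)
        np.testing.assert_array_equal(a.assignment, b.assignment)
        assert a.modularity == b.modularity

    def test_module_ids_contiguous_from_zero(self, ws_net):
        part = louvain(ws_net.weights, seed=7)
        assert sorted(set(part.assignment)) == list(range(part.n_modules))

    def test_matches_igraph_on_structured_graph(self):
        igraph = pytest.importorskip("igraph")
        net = generate(
            GeneratorSpec("stochastic_block", 60, 4, {"p_intra": 0.5, "p_inter": 0.02})
        )
        g = igraph.Graph.Weighted_Adjacency(net.weights.tolist(), mode="undirected")
        best_ig = max(
            g.modularity(g.community_multilevel(weights="weight"), weights="weight")
            for _ in range(5)
        )
        ours = louvain(net.weights, seed=0, n_restarts=10).modularity
        assert ours >= best_ig - 1e-9

    def test_empty_graph_rejected(self):
        with pytest.raises(ValidationError):
            louvain(np.zeros((0, 0)), seed=0)
        with pytest.raises(ValidationError):
            louvain(np.zeros((3, 3)), seed=0)


class TestFunctionalPartition:
    def test_small_tau_many_modules_large_tau_few(self, ws_net):
        dec = decompose(ws_net)
        tiny = functional_partition(ws_net, 1e-10 * dec.diffusion_time, seed=0, dec=dec)
        huge = functional_partition(ws_net, 10.0 * dec.diffusion_time, seed=0, dec=dec)
        assert tiny.n_modules > huge.n_modules

    def test_invariant_to_phi0(self, ws_net):
        dec = decompose(ws_net)
        tau = dec.diffusion_time
        a = functional_partition(ws_net, tau, phi0=1.0, seed=5, dec=dec)
        b = functional_partition(ws_net, tau, phi0=13.0, seed=5, dec=dec)
        np.testing.assert_array_equal(a.assignment, b.assignment)

    def test_planted_blocks_recovered_at_intermediate_scale(self):
        """Assortative 4-block networks are perfectly recovered from W~(tau)."""
        from sklearn.metrics import adjusted_rand_score

        n = 80
        planted = np.repeat(np.arange(4), sbm_block_sizes(n, 4))
        aris = []
        for seed in range(20):
            net = generate(
                GeneratorSpec(
                    "stochastic_block", n, seed, {"p_intra": 0.5, "p_inter": 1e-3}
                )
            )
            dec = decompose(net)
            part = functional_partition(
                net, 0.05 * dec.diffusion_time, seed=seed, dec=dec
            )
            aris.append(adjusted_rand_score(planted, part.assignment))
        assert np.mean(aris) >= 0.95


class TestModuleCountCurve:
    def test_endpoints_and_columns(self, ws_net):
        dec = decompose(ws_net)
        grid = rescaled_tau_grid(dec, 1e-10, 10.0, 12)
        curve = module_count_curve(ws_net, grid, seed=0, dec=dec)
        assert list(curve.columns) == ["tau_over_taud", "tau", "n_modules", "modularity"]
        assert len(curve) == 12
        assert curve.n_modules.iloc[0] >= curve.n_modules.iloc[-1]

    def test_median_count_non_increasing_between_extremes(self, small_fixture_nets):
        for name, net in small_fixture_nets.items():
            if not net.is_connected or net.n_nodes < 8:
                continue
            dec = decompose(net)
            firsts, lasts = [], []
            for seed in range(5):
                tiny = functional_partition(
                    net, 1e-10 * dec.diffusion_time, seed=seed, dec=dec
                )
                huge = functional_partition(
                    net, 10.0 * dec.diffusion_time, seed=seed, dec=dec
                )
                firsts.append(tiny.n_modules)
                lasts.append(huge.n_modules)
            assert np.median(firsts) >= np.median(lasts), name

    def test_empty_grid_gives_empty_table(self, ws_net):
        curve = module_count_curve(ws_net, [], seed=0)
        assert len(curve) == 0

    def test_sbm_plateau_of_four_modules(self):
        net = generate(
            GeneratorSpec("stochastic_block", 80, 1, {"p_intra": 0.5, "p_inter": 1e-3})
        )
        dec = decompose(net)
        window = [(r, r * dec.diffusion_time) for r in (1e-3, 1e-2, 0.05, 0.1)]
        curve = module_count_curve(net, window, seed=0, dec=dec)
        assert (curve.n_modules == 4).all()


class TestModulesEntropyRelation:
    def test_constructed_identity_recovers_unit_slope(self):
        s = np.linspace(0.5, 3.0, 20)
        fit = modules_entropy_relation(np.exp(s), s)
        assert fit.slope == pytest.approx(1.0, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_constant_module_count_gives_zero_slope(self):
        s = np.linspace(0.5, 3.0, 10)
        fit = modules_entropy_relation(np.ones(10), s)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            modules_entropy_relation([2, 4], [0.5, 1.0])

    def test_synthetic_ensemble_has_positive_slope(self):
        """Across mixed topologies, more entropy goes with more modules."""
        from funcstate import entropy_curve

        specs = [
            GeneratorSpec("watts_strogatz", 40, s, {"k": 4, "p": 0.05}) for s in range(4)
        ] + [
            GeneratorSpec("barabasi_albert", 40, s, {"m": 1}) for s in range(4)
        ] + [
            GeneratorSpec("random_geometric", 40, s, {"radius": 0.3}) for s in range(4)
        ]
        pooled_m, pooled_s = [], []
        for spec in specs:
            net = generate(spec)
            dec = decompose(net)
            grid = rescaled_tau_grid(dec, 1e-8, 10.0, 8)
            curve = module_count_curve(net, grid, seed=spec.seed, dec=dec)
            scurve = entropy_curve(net, grid, dec=dec)
            pooled_m.extend(curve.n_modules)
            pooled_s.extend(scurve.entropy)
        fit = modules_entropy_relation(pooled_m, pooled_s)
        assert fit.slope > 0
        assert 0 < fit.r_squared <= 1
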