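import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from physarum import (
    ResponseParams,
    SingularFlowError,
    TubeNetwork,
    adapt_network,
    integrate_two_path,
    maze_network,
    read_network,
    response_f,
    solve_flows,
    two_path_network,
    two_path_rhs,
    write_network,
)
from physarum.equilibrium_analysis import branch_ratio_roots


def three_param_response(q, alpha, gamma, mu):
    """Original three-parameter sigmoid (gamma + alpha) Q^mu / (gamma + alpha Q^mu)."""
    return (gamma + alpha) * q**mu / (gamma + alpha * q**mu)


class TestResponseF:
    @pytest.mark.parametrize(
        "q,eps,mu,expected",
        [
            (0.0, 0.2, 2.0, 0.0),
            (0.0, 1.7, 3.0, 0.0),
            (1.0, 0.2, 2.0, 1.0),
            (1.0, 0.9, 1.0, 1.0),
            (0.5, 0.2, 2.0, (1.2 * 0.25) / (0.2 + 0.25)),
        ],
    )
    def test_pointwise_values(self, q, eps, mu, expected):
        assert response_f(q, ResponseParams(eps, mu)) == pytest.approx(expected)

    def test_negative_flux_rejected(self, response):
        with pytest.raises(ValueError):
            response_f(-0.1, response)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        q=st.floats(0.01, 5.0),
        alpha=st.floats(0.1, 10.0),
        scale=st.floats(0.1, 10.0),
    )
    def test_depends_only_on_gamma_over_alpha(self, q, alpha, scale):
        """Rescaling (alpha, gamma) jointly leaves the response unchanged."""
        eps = 0.2
        gamma = eps * alpha
        two_param = response_f(q, ResponseParams(eps, 2.0))
        assert three_param_response(q, alpha, gamma, 2.0) == pytest.approx(two_param)
        assert three_param_response(
            q, alpha * scale, gamma * scale, 2.0
        ) == pytest.approx(two_param)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(q=st.floats(0.01, 50.0), dq=st.floats(0.01, 5.0))
    def test_monotone_and_saturating(self, response, q, dq):
        lo = response_f(q, response)
        hi = response_f(q + dq, response)
        assert lo < hi < 1.0 + response.epsilon


class TestSolveFlows:
    def test_single_edge_ohms_law(self):
        net = TubeNetwork.from_edges([("N1", "N2", 1.0, 1.0)], "N1", "N2")
        sol = solve_flows(net)
        assert sol.fluxes[0] == pytest.approx(1.0)
        assert sol.pressures["N1"] - sol.pressures["N2"] == pytest.approx(1.0)

    def test_parallel_edges_split_by_conductance(self):
        equal = solve_flows(two_path_network(D1=1.0, D2=1.0))
        np.testing.assert_allclose(equal.fluxes, [0.5, 0.5])
        divider = solve_flows(two_path_network(D1=2.0, D2=1.0))
        np.testing.assert_allclose(divider.fluxes, [2.0 / 3.0, 1.0 / 3.0])

    def test_disconnected_sources_raise(self):
        net = TubeNetwork.from_edges(
            [("N1", "a", 1.0, 1.0), ("b", "N2", 1.0, 1.0), ("a", "b", 1.0, 0.0)],
            "N1",
            "N2",
        )
        with pytest.raises(SingularFlowError):
            solve_flows(net)

    def test_kirchhoff_balance_on_random_graph(self):
        rng = np.random.default_rng(7)
        g = nx.gnm_random_graph(10, 20, seed=3)
        assert nx.is_connected(g)
        edges = [
            (u, v, float(rng.uniform(0.5, 2.0)), float(rng.uniform(0.1, 2.0)))
            for u, v in g.edges
        ]
        net = TubeNetwork.from_edges(edges, source=0, sink=9)
        sol = solve_flows(net)
        net_flux = {n: 0.0 for n in net.nodes}
        for (u, v), q in zip(net.edges, sol.fluxes):
            net_flux[u] -= q
            net_flux[v] += q
        for n, total in net_flux.items():
            if n == 0:
                assert total == pytest.approx(-1.0, abs=1e-9)
            elif n == 9:
                assert total == pytest.approx(1.0, abs=1e-9)
            else:
                assert abs(total) < 1e-9


class TestValidation:
    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            TubeNetwork.from_edges([("N1", "N2", 0.0, 1.0)], "N1", "N2")

    def test_negative_conductivity_rejected(self):
        with pytest.raises(ValueError):
            TubeNetwork.from_edges([("N1", "N2", 1.0, -0.5)], "N1", "N2")

    def test_missing_source_rejected(self):
        with pytest.raises(ValueError):
            TubeNetwork.from_edges([("a", "b", 1.0, 1.0)], "N1", "N2")


class TestAdaptation:
    def test_single_edge_converges_to_response_fixed_point(self, response):
        # dD/dt = f(S0) - delta D with Q = S0 = 1 fixed -> D* = f(1)/delta = 1
        net = TubeNetwork.from_edges([("N1", "N2", 1.0, 0.3)], "N1", "N2")
        res = adapt_network(net, response, t_end=20.0)
        assert res.final.conductivities[0] == pytest.approx(1.0, abs=1e-4)

    def test_two_path_single_path_basin(self, response):
        # (1, 0.2) lies below the a3 ray -> path 1 wins, D -> (1/delta, 0)
        a3 = branch_ratio_roots(response.epsilon)[2]
        assert 0.2 < a3 * 1.0
        res = adapt_network(two_path_network(D1=1.0, D2=0.2), response, t_end=40.0)
        np.testing.assert_allclose(res.final.conductivities, [1.0, 0.0], atol=1e-3)

    def test_matches_direct_two_path_integration(self, response):
        net = two_path_network(D1=0.9, D2=0.4)
        res = adapt_network(net, response, dt=0.01, t_end=5.0, record_every=100)
        d1, d2 = integrate_two_path(0.9, 0.4, response, dt=0.01, t_end=5.0)
        np.testing.assert_allclose(
            res.final.conductivities, [d1, d2], rtol=1e-10, atol=1e-12
        )

    def test_maze_converges_to_shortest_path(self, response):
        net = maze_network(D0=1.0)
        res = adapt_network(net, response, dt=0.01, t_end=60.0, record_every=500)
        surviving = {
            frozenset(e)
            for e, d in zip(res.edges, res.final.conductivities)
            if d > 0.1
        }
        g = nx.Graph()
        for (u, v), length in zip(net.edges, net.lengths):
            g.add_edge(u, v, weight=length)
        shortest = nx.shortest_path(g, "N1", "N2", weight="weight")
        shortest_edges = {
            frozenset(p) for p in zip(shortest[:-1], shortest[1:])
        }
        assert surviving == shortest_edges

    def test_invalid_step_rejected(self, response):
        with pytest.raises(ValueError):
            adapt_network(two_path_network(), response, dt=-0.1)


class TestTwoPathRhs:
    def test_symmetric_state(self, response):
        r1, r2 = two_path_rhs(0.8, 0.8, response)
        assert r1 == pytest.approx(r2)
        assert r1 == pytest.approx(-0.8 + response_f(0.5, response))

    def test_equilibria_are_fixed_points(self, response):
        eps = response.epsilon
        d_sym = (1 + eps) / (1 + 4 * eps)  # delta = 1
        for d1, d2 in [(d_sym, d_sym), (1.0, 0.0)]:
            r1, r2 = two_path_rhs(d1, d2, response)
            assert abs(r1) < 1e-12 and abs(r2) < 1e-12

    def test_undefined_at_origin(self, response):
        with pytest.raises(ValueError):
            two_path_rhs(0.0, 0.0, response)

    @pytest.mark.parametrize("d1,d2", [(0.3, 1.2), (1.4, 0.2), (0.9, 0.8)])
    def test_invariant_rays_never_crossed(self, response, d1, d2):
        """The rays D2 = a2 D1 and D2 = a3 D1 separate trajectories forever."""
        _, a2, a3 = branch_ratio_roots(response.epsilon)
        sides0 = (np.sign(d2 - a2 * d1), np.sign(d2 - a3 * d1))
        x, y = d1, d2
        for _ in range(200):
            x, y = integrate_two_path(x, y, response, dt=0.01, t_end=0.25)
            if x + y < 1e-8:
                break
            sides = (np.sign(y - a2 * x), np.sign(y - a3 * x))
            assert sides == sides0


def test_network_io_roundtrip(tmp_path):
    net = maze_network(D0=0.7)
    path = tmp_path / "maze.txt"
    write_network(net, path)
    loaded = read_network(path)
    assert loaded.edges == [(str(u), str(v)) for u, v in net.edges]
    np.testing.assert_allclose(loaded.lengths, net.lengths)
    np.testing.assert_allclose(loaded.conductivities, net.conductivities)
    assert loaded.source == "N1" and loaded.sink == "N2"
    assert loaded.source_strength == net.source_strength
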