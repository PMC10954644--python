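import numpy as np
import pytest

from hogrc.structures import Complex
from hogrc.systems import (
    CouplingNetwork,
    DivergenceError,
    Trajectory,
    add_observation_noise,
    cl63_field,
    find_triangles,
    generate_network,
    kuramoto_ho_field,
    lorenz63_field,
    nds_field,
    rk4_integrate,
    simulate,
    true_structure,
    variable_names,
)


class TestRK4:
    def test_one_step_exponential_decay(self):
        # dx/dt = -x from x=1: one RK4 step matches exp(-0.1) to O(dt^5)
        traj = rk4_integrate(lambda x: -x, [1.0], 0.1, 2)
        assert traj.states[1, 0] == pytest.approx(0.9048375, abs=1e-9)
        # one-step local error against the exact exponential is O(dt^5)
        assert traj.states[1, 0] == pytest.approx(np.exp(-0.1), abs=1e-7)

    def test_global_error_is_fourth_order(self):
        # halving dt must shrink the max error against exp(-t) by ~16x
        errs = []
        for dt, steps in [(0.2, 26), (0.1, 51)]:
            traj = rk4_integrate(lambda x: -x, [1.0], dt, steps)
            errs.append(np.abs(traj.states[:, 0] - np.exp(-traj.times)).max())
        assert 10 < errs[0] / errs[1] < 22

    def test_origin_is_lorenz_fixed_point(self):
        traj = rk4_integrate(lorenz63_field(), [0.0, 0.0, 0.0], 0.02, 50)
        assert np.all(traj.states == 0.0)

    def test_transient_discarded(self):
        traj = rk4_integrate(lambda x: -x, [1.0], 0.1, 5, transient=3)
        assert traj.states[0, 0] == pytest.approx(np.exp(-0.3), abs=1e-6)
        assert len(traj) == 5

    def test_divergence_reported_with_step(self):
        with pytest.raises(DivergenceError, match=r"step \d+"):
            rk4_integrate(lambda x: x**3, [2.0], 0.5, 100)


class TestFields:
    def test_lorenz_values_by_substitution(self):
        f = lorenz63_field()
        assert np.allclose(f(np.array([1.0, 1.0, 1.0])), [0.0, 26.0, 1 - 8 / 3])
        assert f(np.array([1.0, 2.0, 3.0]))[0] == pytest.approx(10.0)

    def test_cl63_decoupled_limit_is_scaled_lorenz(self):
        net = CouplingNetwork(np.zeros((2, 2)))
        h = np.array([0.3, -0.2])
        f = cl63_field(net, h, params={"gamma": 0.0})
        state = np.array([1.0, 2.0, 3.0, -1.0, 0.5, 2.0])
        out = f(state)
        for i in range(2):
            x, y, z = state[3 * i : 3 * i + 3]
            expected = [10 * (y - x), 28 * (1 + h[i]) * x - y - x * z, x * y - 8 / 3 * z]
            assert np.allclose(out[3 * i : 3 * i + 3], expected)

    @pytest.mark.parametrize("coupling", ["linear", "sine"])
    def test_identical_subsystems_feel_no_coupling(self, coupling):
        net = generate_network("regular", 4, degree=2, seed=1)
        h = np.ones(4)
        f_c = cl63_field(net, h, coupling=coupling, params={"gamma": 0.7})
        f_0 = cl63_field(net, h, coupling=coupling, params={"gamma": 0.0})
        state = np.tile([1.2, -0.5, 3.0], 4)  # all subsystems identical
        assert np.allclose(f_c(state), f_0(state))

    def test_fhn_second_component_is_affine(self):
        net = CouplingNetwork(np.zeros((5, 5)))
        f = nds_field("fhn", net, params={"gamma": 0.0})
        state = np.zeros(10)
        state[0], state[1] = 0.7, -0.3
        out = f(state)
        assert out[1] == pytest.approx(0.28 + 0.5 * 0.7 + (-0.04) * (-0.3))

    def test_cros_substitution_at_origin(self):
        net = CouplingNetwork(np.zeros((1, 1)))
        f = nds_field("cros", net, h=np.array([1.0]))
        assert np.allclose(f(np.zeros(3)), [0.0, 0.0, 0.2])

    def test_hodgkin_huxley_sigmoid_midpoint(self):
        from hogrc.systems import _mu

        for lam in (1.0, 10.0, 100.0):
            assert _mu(np.array([1.0]), lam, 1.0)[0] == pytest.approx(0.5)

    def test_fhn_coupling_normalised_by_indegree(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[0, 2] = 1.0
        f = nds_field("fhn", CouplingNetwork(W), params={"gamma": 1.0})
        state = np.zeros(6)
        state[0], state[2], state[4] = 1.0, 0.0, 0.0  # x1=1, neighbors at 0
        out = f(state)
        # self part: 1 - 1 - 0 = 0; coupling: mean of (x1 - xj) = 1
        assert out[0] == pytest.approx(0.0 + 1.0)


class TestKuramoto:
    @pytest.fixture()
    def tri_net(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = W[1, 2] = W[2, 1] = W[0, 2] = W[2, 0] = 1.0
        return find_triangles(CouplingNetwork(W))

    def test_synchronised_state_drifts_at_omega(self, tri_net):
        omega = np.array([0.3, -0.2, 1.0])
        f = kuramoto_ho_field(omega, tri_net)
        assert np.allclose(f(np.full(3, 1.234)), omega)

    def test_zero_couplings_give_omega(self, tri_net):
        omega = np.array([0.1, 0.2, 0.3])
        f = kuramoto_ho_field(omega, tri_net, gamma1=0.0, gamma2=0.0)
        theta = np.array([0.0, 1.0, 2.0])
        assert np.allclose(f(theta), omega)

    def test_global_phase_shift_invariance(self, tri_net):
        omega = np.array([0.1, -0.4, 0.25])
        f = kuramoto_ho_field(omega, tri_net)
        theta = np.array([0.3, 2.1, -1.0])
        assert np.allclose(f(theta), f(theta + 5.4321), atol=1e-12)

    def test_triangle_listing_finds_all_3_cliques(self, tri_net):
        assert len(tri_net.triangles) == 3  # one clique, one entry per member


class TestNetworks:
    def test_regular_degree_two_is_a_cycle(self):
        net = generate_network("regular", 5, degree=2, seed=0)
        assert np.all(net.in_degree == 2)
        assert np.count_nonzero(net.weights) == 10

    def test_er_edge_count_and_mean_degree(self):
        net = generate_network("er", 30, n_edges=33, seed=3)
        assert np.count_nonzero(net.weights) == 66  # symmetric entries
        assert net.in_degree.mean() == pytest.approx(2.2)

    def test_seed_determinism(self):
        a = generate_network("ba", 20, seed=5)
        b = generate_network("ba", 20, seed=5)
        assert np.array_equal(a.weights, b.weights)

    def test_diagonal_rejected(self):
        with pytest.raises(ValueError):
            CouplingNetwork(np.eye(3))

    def test_edge_list_round_trip(self, tmp_path):
        net = generate_network("er", 8, n_edges=10, seed=2)
        net.to_files(tmp_path / "e.tsv")
        back = CouplingNetwork.from_files(tmp_path / "e.tsv", m=8)
        assert np.allclose(net.weights, back.weights)


class TestNoise:
    def test_zero_noise_returns_input_unchanged(self, lorenz_traj):
        out = add_observation_noise(lorenz_traj, 0.0, seed=1)
        assert out is lorenz_traj

    def test_relative_noise_scale(self, lorenz_traj):
        out = add_observation_noise(lorenz_traj, 0.2, mode="per-variable-std", seed=1)
        resid = out.states - lorenz_traj.states
        target = 0.2 * lorenz_traj.states.std(axis=0)
        assert np.allclose(resid.std(axis=0), target, rtol=0.05)

    def test_absolute_mode(self, lorenz_traj):
        out = add_observation_noise(lorenz_traj, 1.5, mode="absolute", seed=2)
        resid = out.states - lorenz_traj.states
        assert np.allclose(resid.std(axis=0), 1.5, rtol=0.05)


class TestTrueStructure:
    def test_lorenz_neighbor_sets(self):
        s = true_structure("lorenz63")
        assert set(s["z"]) == {Complex("z"), Complex("xy")}
        assert set(s["x"]) == {Complex("x"), Complex("y")}
        assert set(s["y"]) == {Complex("y"), Complex("xz")}

    def test_cl63_linear_coupling_adds_pairwise_y_terms(self):
        net = generate_network("regular", 3, degree=2, seed=0)
        s = true_structure("cl63", net=net, coupling="linear")
        assert Complex(["y2"]) in s["x1"] and Complex(["y3"]) in s["x1"]
        assert Complex(["y1"]) in s["x1"]

    def test_cl63_nonlinear_coupling_uses_joint_complexes(self):
        net = generate_network("regular", 3, degree=2, seed=0)
        s = true_structure("cl63", net=net, coupling="sine")
        assert Complex(["y1", "y2"]) in s["x1"]
        # {y1} is subsumed by the joint complex and must not appear
        assert Complex(["y1"]) not in s["x1"]

    def test_decoupled_cl63_has_no_cross_subsystem_complexes(self):
        net = CouplingNetwork(np.zeros((2, 2)))
        s = true_structure("cl63", net=net)
        for u in s.nodes:
            suffix = u[1:]
            for c in s[u]:
                assert all(v[1:] == suffix for v in c.members)

    def test_kuramoto_triangles_subsume_pairs(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = W[1, 2] = W[2, 1] = W[0, 2] = W[2, 0] = 1.0
        net = find_triangles(CouplingNetwork(W))
        s = true_structure("kuramoto_ho", net=net)
        assert Complex(["th1", "th2", "th3"]) in s["th1"]
        # the pairwise complexes are subsets of the triangle and must vanish
        assert Complex(["th1", "th2"]) not in s["th1"]
        assert s.degree("th1") == 1

    def test_variable_names_layout(self):
        assert variable_names("cl63", 2) == ["x1", "y1", "z1", "x2", "y2", "z2"]
        assert variable_names("fhn", 2) == ["x1_1", "x1_2", "x2_1", "x2_2"]


class TestTrajectoryIO:
    def test_csv_round_trip(self, tmp_path, lorenz_traj):
        path = tmp_path / "traj.csv"
        lorenz_traj.to_csv(path, metadata={"seed": 11})
        back = Trajectory.from_csv(path)
        assert back.names == lorenz_traj.names
        assert back.dt == lorenz_traj.dt
        assert np.allclose(back.states, lorenz_traj.states)

    def test_simulate_is_seed_deterministic(self):
        a = simulate("lorenz63", steps=100, transient=10, seed=4)
        b = simulate("lorenz63", steps=100, transient=10, seed=4)
        assert np.array_equal(a.states, b.states)

    def test_simulate_shapes(self):
        net = generate_network("regular", 5, degree=2, seed=1)
        t = simulate("cl63", net=net, steps=50, transient=10, seed=0)
        assert t.states.shape == (50, 15)
        assert np.all(np.isfinite(t.states))
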