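import numpy as np
import pytest

from osteoadapt.network import (A0_UM2, Cell, CellNetwork, Process,
                                StimulusField, assemble_stiffness,
                                cm2_s_to_um2_day, osteocyte_stimulus,
                                solve_fluxes)


def two_cell_network(length=10.0, area=A0_UM2):
    cells = [Cell("ocy0", "osteocyte", 0.0, 0.0),
             Cell("ob0", "osteoblast", length, 0.0, "periosteal")]
    return CellNetwork(cells, [Process("ocy0", "ob0", length, area)])


def random_tree_network(rng, n_nodes=50, with_junctions=False):
    """Random spanning tree over mixed cell kinds."""
    kinds = []
    cells = []
    for i in range(n_nodes):
        u = rng.uniform()
        if i == 0 or u < 0.2:
            kind, surface = "osteoblast", "periosteal"
        elif with_junctions and u < 0.35:
            kind, surface = "junction", "intracortical"
        else:
            kind, surface = "osteocyte", "intracortical"
        kinds.append(kind)
        cells.append(Cell(f"c{i}", kind, float(rng.uniform(-100, 100)),
                          float(rng.uniform(-100, 100)), surface))
    edges = []
    for i in range(1, n_nodes):
        j = int(rng.integers(0, i))
        edges.append(Process(f"c{i}", f"c{j}", float(rng.uniform(5, 50)),
                             float(rng.uniform(0.01, 0.05))))
    return CellNetwork(cells, edges), kinds


def dense_oracle(network, s_nM, D_cm2_s=5.3e-6):
    """Brute-force dense solve of the same boundary-value problem."""
    n = len(network)
    K = np.zeros((n, n))
    d = cm2_s_to_um2_day(D_cm2_s)
    for e in network.processes:
        i, j = network.index[e.a], network.index[e.b]
        c = d * e.area_um2 / e.length_um
        K[i, i] += c
        K[j, j] += c
        K[i, j] -= c
        K[j, i] -= c
    psi = np.zeros(n)
    prescribed = np.zeros(n, bool)
    for i, cell in enumerate(network.cells):
        if cell.kind == "osteocyte":
            psi[i] = s_nM.get(cell.id, 0.0) * 1e-15
            prescribed[i] = True
        elif cell.kind == "osteoblast":
            prescribed[i] = True
    free = ~prescribed
    if free.any():
        psi[free] = np.linalg.solve(K[np.ix_(free, free)],
                                    -K[np.ix_(free, prescribed)] @ psi[prescribed])
    return K @ psi


class TestStimulus:
    def test_subthreshold_zero(self):
        assert osteocyte_stimulus(846.126, 1.0, 0.123, 856.126, 50, 3, 0.4, 0.465) == 0.0

    def test_osteoblast_always_zero(self):
        s = osteocyte_stimulus(2000.0, 1.0, 0.123, 856.126, 50, 3, 0.4, 0.465,
                               is_osteocyte=False)
        assert s == 0.0

    def test_worked_example_magnitude(self):
        # gain 0.123 nM/ue on a 1546 ue single pulse: ~84.85 nM
        s = osteocyte_stimulus(1546.0, 1.0, 0.123, 856.126, 1, 1, 0.4, 0.465)
        assert s == pytest.approx(0.123 * (1546.0 - 856.126), rel=1e-12)
        assert s == pytest.approx(84.85, abs=0.01)

    def test_vectorized_threshold(self):
        eps = np.array([100.0, 856.126, 900.0, 2000.0])
        s = osteocyte_stimulus(eps, 1.0, 0.1, 856.126, 1, 1, 0.5, 0.5)
        assert s[0] == 0.0
        assert s[1] == pytest.approx(0.0)
        assert np.all(s[2:] > 0)


class TestAssembly:
    def test_single_edge_matrix(self):
        net = two_cell_network(length=10.0, area=0.025)
        K = assemble_stiffness(net, 5.3e-6).toarray()
        c = cm2_s_to_um2_day(5.3e-6) * 0.025 / 10.0
        np.testing.assert_allclose(K, [[c, -c], [-c, c]], rtol=1e-12)

    def test_row_sums_zero(self, rng):
        net, _ = random_tree_network(rng, 40)
        K = assemble_stiffness(net)
        np.testing.assert_allclose(np.asarray(K.sum(axis=1)).ravel(), 0.0,
                                   atol=1e-9 * abs(K).max())

    def test_duplicate_edges_merge(self):
        cells = [Cell("a", "osteocyte", 0, 0), Cell("b", "osteoblast", 10, 0, "periosteal")]
        net = CellNetwork(cells, [Process("a", "b", 10.0, 0.025),
                                  Process("a", "b", 10.0, 0.025)])
        K = assemble_stiffness(net, 5.3e-6).toarray()
        c = 2 * cm2_s_to_um2_day(5.3e-6) * 0.025 / 10.0
        assert K[0, 0] == pytest.approx(c)

    def test_series_condensation_oracle(self):
        # ocy - junction - ob: condensed conductance c1*c2/(c1+c2)
        cells = [Cell("ocy", "osteocyte", 0, 0),
                 Cell("j", "junction", 10, 0),
                 Cell("ob", "osteoblast", 30, 0, "periosteal")]
        net = CellNetwork(cells, [Process("ocy", "j", 10.0, 0.025),
                                  Process("j", "ob", 20.0, 0.025)])
        K = assemble_stiffness(net)
        stim = StimulusField({"ocy": 100.0}, 0.123)
        sol = solve_fluxes(K, stim, net)
        d = cm2_s_to_um2_day(5.3e-6)
        c1 = d * 0.025 / 10.0
        c2 = d * 0.025 / 20.0
        c_eq = c1 * c2 / (c1 + c2)
        assert sol.q_osteoblasts_nmol_day["ob"] == pytest.approx(
            -c_eq * 100.0 * 1e-15, rel=1e-12)

    def test_zero_length_edge_rejected(self):
        with pytest.raises(ValueError, match="length"):
            Process("a", "b", 0.0, 0.025)


class TestSolve:
    def test_single_edge_flux(self):
        net = two_cell_network(length=12.0)
        K = assemble_stiffness(net)
        sol = solve_fluxes(K, StimulusField({"ocy0": 85.0}, 0.123), net)
        c = cm2_s_to_um2_day(5.3e-6) * A0_UM2 / 12.0
        expected = c * 85.0 * 1e-15
        assert sol.q_osteoblasts_nmol_day["ob0"] == pytest.approx(-expected, rel=1e-12)
        assert sol.Q_nmol_day[net.index["ocy0"]] == pytest.approx(expected, rel=1e-12)

    def test_zero_stimulus_zero_flow(self, rng):
        net, _ = random_tree_network(rng, 30)
        K = assemble_stiffness(net)
        sol = solve_fluxes(K, StimulusField({}, 0.123), net)
        np.testing.assert_allclose(sol.Q_nmol_day, 0.0, atol=1e-300)

    @pytest.mark.parametrize("with_junctions", [False, True])
    def test_dense_oracle_random_trees(self, rng, with_junctions):
        for _ in range(10):
            net, kinds = random_tree_network(rng, 50, with_junctions)
            s = {c.id: float(rng.uniform(0, 100)) for c in net.cells
                 if c.kind == "osteocyte"}
            K = assemble_stiffness(net)
            sol = solve_fluxes(K, StimulusField(s, 0.123), net)
            oracle = dense_oracle(net, s)
            scale = max(np.abs(oracle).max(), 1e-300)
            np.testing.assert_allclose(sol.Q_nmol_day, oracle, rtol=1e-10,
                                       atol=1e-10 * scale)
            # conservation and osteoblast sign
            assert sol.conservation_residual < 1e-10
            assert all(q <= 1e-12 * scale for q in sol.q_osteoblasts_nmol_day.values())

    def test_proportionality_in_h_and_D(self, rng):
        net, _ = random_tree_network(rng, 40)
        s = {c.id: float(rng.uniform(10, 50)) for c in net.cells if c.kind == "osteocyte"}
        K = assemble_stiffness(net, 5.3e-6)
        q1 = solve_fluxes(K, StimulusField(s, 0.123), net).Q_nmol_day
        # scaling every stimulus by 3 (as h would) scales fluxes by 3
        s3 = {k: 3 * v for k, v in s.items()}
        q3 = solve_fluxes(K, StimulusField(s3, 0.369), net).Q_nmol_day
        np.testing.assert_allclose(q3, 3 * q1, rtol=1e-12)
        # scaling D by 2 scales fluxes by 2
        K2 = assemble_stiffness(net, 2 * 5.3e-6)
        q2 = solve_fluxes(K2, StimulusField(s, 0.123), net).Q_nmol_day
        np.testing.assert_allclose(q2, 2 * q1, rtol=1e-12)

    def test_superposition(self, rng):
        net, _ = random_tree_network(rng, 40, with_junctions=True)
        ocy = [c.id for c in net.cells if c.kind == "osteocyte"]
        s1 = {i: float(rng.uniform(0, 50)) for i in ocy}
        s2 = {i: float(rng.uniform(0, 50)) for i in ocy}
        s12 = {i: s1[i] + s2[i] for i in ocy}
        K = assemble_stiffness(net)
        q1 = solve_fluxes(K, StimulusField(s1, 0.1), net).Q_nmol_day
        q2 = solve_fluxes(K, StimulusField(s2, 0.1), net).Q_nmol_day
        q12 = solve_fluxes(K, StimulusField(s12, 0.1), net).Q_nmol_day
        np.testing.assert_allclose(q12, q1 + q2, rtol=1e-10,
                                   atol=1e-10 * np.abs(q12).max())

    def test_isolated_free_node_raises(self):
        cells = [Cell("ocy", "osteocyte", 0, 0),
                 Cell("ob", "osteoblast", 10, 0, "periosteal"),
                 Cell("lone", "junction", 50, 50)]
        net = CellNetwork(cells, [Process("ocy", "ob", 10.0, 0.025)])
        K = assemble_stiffness(net)
        with pytest.raises(ValueError, match="lone"):
            solve_fluxes(K, StimulusField({"ocy": 10.0}, 0.1), net)

    def test_sinkless_component_flagged(self):
        cells = [Cell("a", "osteocyte", 0, 0), Cell("b", "osteocyte", 10, 0),
                 Cell("ob", "osteoblast", 20, 0, "periosteal")]
        net = CellNetwork(cells, [Process("a", "b", 10.0, 0.025)])
        assert len(net.components_without_sink()) == 1
        sol = solve_fluxes(assemble_stiffness(net), StimulusField({"a": 1.0}, 0.1), net)
        assert any("sink" in f for f in sol.flags)


class TestCellValidation:
    def test_osteoblast_needs_surface(self):
        with pytest.raises(ValueError, match="surface"):
            Cell("x", "osteoblast", 0, 0, "intracortical")

    def test_osteocyte_is_intracortical(self):
        with pytest.raises(ValueError):
            Cell("x", "osteocyte", 0, 0, "periosteal")

    def test_duplicate_ids_rejected(self):
        cells = [Cell("a", "osteocyte", 0, 0), Cell("a", "osteocyte", 1, 1)]
        with pytest.raises(ValueError, match="duplicate"):
            CellNetwork(cells, [])
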