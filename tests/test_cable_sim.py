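"""SWC handling, morphology morphing and the passive clamp solver.

The solver's quantitative oracle is the finite sealed-end cable:
clamping one end of a uniform passive cable to V0 gives the steady
state V(x) = V0 * cosh((L - x)/lambda) / cosh((L - x0)/lambda), with
lambda = sqrt(Rm * a / (2 * Ra)).
"""

import numpy as np
import pytest

from nvcpipe.cable_sim import CableSolution, ClampSpec, CompartmentGraph, \
    DENDRITE, Morphology, PassiveParams, SOMA, discretize, morph_and_solve, \
    orient_depth, read_swc, scale_z, solve_clamped, stretch_to_layer5
from nvcpipe.synthgen import synthetic_bipolar_swc

STICK = """# three-node stick
1 1 0 0 0 5 -1
2 3 0 0 10 1 1
3 3 0 0 20 1 2
"""


class TestReadSwc:
    def test_stick_parses_with_comments_skipped(self):
        m = read_swc(STICK)
        assert m.n_nodes == 3
        assert list(m.parent_index) == [-1, 0, 1]
        assert m.types[0] == SOMA

    def test_missing_parent_names_node(self):
        bad = "1 1 0 0 0 5 -1\n2 3 0 0 10 1 9\n"
        with pytest.raises(ValueError, match="9"):
            read_swc(bad)

    def test_non_positive_radius_names_line(self):
        bad = "1 1 0 0 0 5 -1\n2 3 0 0 10 0 1\n"
        with pytest.raises(ValueError, match="line 2"):
            read_swc(bad)

    def test_two_roots_rejected(self):
        bad = "1 1 0 0 0 5 -1\n2 3 0 0 10 1 -1\n"
        with pytest.raises(ValueError, match="root"):
            read_swc(bad)

    def test_wrong_column_count_rejected(self):
        with pytest.raises(ValueError, match="columns"):
            read_swc("1 1 0 0 0 5\n")


class TestMorphing:
    def test_scale_z_only_touches_depth(self):
        m = read_swc(STICK)
        out = scale_z(m, 0.6)
        assert out.z[2] == pytest.approx(12.0)
        assert np.array_equal(out.xyz[:, :2], m.xyz[:, :2])
        assert np.array_equal(out.radius, m.radius)

    def test_scale_factor_one_is_identity(self):
        m = read_swc(STICK)
        assert np.array_equal(scale_z(m, 1.0).xyz, m.xyz)

    def test_scale_changes_length_only_through_z(self):
        # oblique segment: length scales from the z component only
        swc = "1 1 0 0 100 5 -1\n2 3 30 0 140 1 1\n"
        m = read_swc(swc)
        before = m.total_length()
        after = scale_z(m, 0.5).total_length()
        assert before == pytest.approx(50.0)
        assert after == pytest.approx(np.hypot(30.0, 20.0))

    def test_stretch_moves_soma_to_target(self):
        swc = ("1 1 0 0 300 5 -1\n"
               "2 3 0 0 200 1 1\n"      # middle section
               "3 3 0 0 50 1 2\n"       # above the fixed boundary
               "4 3 0 0 400 1 1\n")     # below the soma
        out = stretch_to_layer5(read_swc(swc))
        assert out.soma_z() == pytest.approx(600.0)
        # middle node: 100 + (200-100) * (500/200) = 350
        assert out.z[1] == pytest.approx(350.0)
        assert out.z[2] == pytest.approx(50.0)          # unchanged
        assert out.z[3] == pytest.approx(400.0 + 300.0)  # rigid shift

    def test_stretch_factor_matches_arithmetic(self):
        # soma at 300 um -> stretch factor (600-100)/(300-100) = 2.5
        swc = "1 1 0 0 300 5 -1\n2 3 0 0 150 1 1\n"
        out = stretch_to_layer5(read_swc(swc))
        assert (out.z[1] - 100.0) / (150.0 - 100.0) == pytest.approx(2.5)

    def test_middle_section_lengths_scale_in_z_only(self):
        swc = "1 1 0 0 300 5 -1\n2 3 40 0 200 1 1\n"
        m = read_swc(swc)
        out = stretch_to_layer5(m)
        k = 500.0 / 200.0
        expected = np.hypot(40.0, (300.0 - 200.0) * k)
        assert out.total_length(types=(3,)) == pytest.approx(expected)

    def test_soma_above_boundary_rejected(self):
        swc = "1 1 0 0 80 5 -1\n2 3 0 0 40 1 1\n"
        with pytest.raises(ValueError):
            stretch_to_layer5(read_swc(swc))

    def test_orient_flips_inverted_reconstruction(self):
        # dendrites extending toward positive z (downward): must be flipped
        swc = "1 1 0 0 0 5 -1\n2 3 0 0 100 1 1\n3 3 0 0 300 1 2\n"
        out = orient_depth(read_swc(swc), tip_depth=20.0)
        dend_z = out.z[out.types == DENDRITE]
        assert dend_z.min() == pytest.approx(20.0)
        assert out.soma_z() > dend_z.min()


class TestDiscretize:
    def _cable(self, n_nodes=11, spacing=10.0, radius=1.0):
        lines = ["1 1 0 0 0 2 -1"]
        for i in range(1, n_nodes):
            lines.append(f"{i+1} 3 0 0 {i*spacing} {radius} {i}")
        return read_swc("\n".join(lines))

    def test_uniform_cable_compartment_count(self):
        g = discretize(self._cable(), max_compartment_length=10.0)
        assert (g.types == DENDRITE).sum() == 10

    def test_halving_max_length_doubles_count(self):
        m = self._cable()
        n10 = (discretize(m, 10.0).types == DENDRITE).sum()
        n5 = (discretize(m, 5.0).types == DENDRITE).sum()
        assert n5 == 2 * n10

    def test_membrane_area_conserved(self):
        m = read_swc(synthetic_bipolar_swc())
        fine = discretize(m, 2.0)
        coarse = discretize(m, 10.0)
        a_fine = fine.area_um2[fine.types != SOMA].sum()
        a_coarse = coarse.area_um2[coarse.types != SOMA].sum()
        assert a_coarse == pytest.approx(a_fine, rel=0.01)

    def test_grid_convergence_of_steady_state(self):
        soma_mv = {}
        for h in (10.0, 5.0):
            sol = morph_and_solve(synthetic_bipolar_swc(), ClampSpec(100.0, 0.0),
                                  max_compartment_length=h, duration_ms=5.0)
            soma_mv[h] = sol.soma_steady_mV
        assert abs(soma_mv[10.0] - soma_mv[5.0]) < 0.5


def sealed_cable_graph(n=60, length_um=10.0, radius_um=0.5):
    """Straight dendritic cable along z; compartment 0 sits in the slab."""
    z = (np.arange(n) + 0.5) * length_um
    return CompartmentGraph(
        length_um=np.full(n, length_um),
        radius_um=np.full(n, radius_um),
        area_um2=2 * np.pi * radius_um * np.full(n, length_um),
        z_um=z,
        types=np.full(n, DENDRITE),
        parent=np.arange(-1, n - 1),
        soma_index=n - 1,
    )


class TestSolver:
    def test_whole_cell_clamp_is_identity(self):
        g = discretize(read_swc(synthetic_bipolar_swc()), 10.0)
        # clamp slab covering the entire dendritic tree
        sol = solve_clamped(g, PassiveParams(), ClampSpec(2000.0, 0.0),
                            duration_ms=5.0)
        dend = np.isin(g.types, (3, 4))
        assert np.allclose(sol.v_steady_mV[dend], 0.0)

    def test_sealed_end_cable_matches_cosh_solution(self):
        params = PassiveParams(membrane_resistance=30.0, membrane_capacitance=1.0,
                               axial_resistivity=150.0, resting_potential=-70.0)
        g = sealed_cable_graph()
        sol = solve_clamped(g, params, ClampSpec(slab_depth_um=10.0,
                                                 clamp_voltage_mV=0.0),
                            duration_ms=5.0)
        lam_um = np.sqrt(params.membrane_resistance * 1e3
                         * (g.radius_um[0] * 1e-4)
                         / (2 * params.axial_resistivity)) * 1e4
        x = g.z_um - g.z_um[0]
        L = g.z_um[-1] + g.length_um[-1] / 2 - g.z_um[0]
        v_inf = params.resting_potential
        expected = v_inf + (0.0 - v_inf) * np.cosh((L - x) / lam_um) / np.cosh(L / lam_um)
        free = ~sol.clamped
        err = np.abs(sol.v_steady_mV[free] - expected[free])
        span = abs(0.0 - v_inf)
        assert err.max() / span < 0.01

    def test_no_overshoot_between_rest_and_clamp(self):
        sol = morph_and_solve(synthetic_bipolar_swc(), ClampSpec(100.0, 0.0),
                              duration_ms=100.0)
        assert np.all(sol.v_steady_mV >= -70.0 - 1e-9)
        assert np.all(sol.v_steady_mV <= 0.0 + 1e-9)
        assert np.all(sol.soma_trace_mV >= -70.0 - 1e-9)
        assert np.all(sol.soma_trace_mV <= 0.0 + 1e-9)

    def test_deeper_slab_never_reduces_soma_depolarization(self):
        v = [morph_and_solve(synthetic_bipolar_swc(), ClampSpec(s, 0.0),
                             duration_ms=5.0).soma_steady_mV
             for s in (50.0, 100.0, 150.0)]
        assert v[0] <= v[1] <= v[2]          # toward 0 mV

    def test_transient_approaches_direct_steady_state(self):
        sol = morph_and_solve(synthetic_bipolar_swc(), ClampSpec(100.0, 0.0),
                              duration_ms=400.0)
        assert sol.soma_trace_mV[-1] == pytest.approx(sol.soma_steady_mV, abs=0.1)
        assert 0.0 < sol.time_to_90pct_ms < 400.0

    def test_second_morphology_also_depolarizes_strongly(self):
        # an independently grown cell processed identically
        sol = morph_and_solve(synthetic_bipolar_swc(seed=12345),
                              ClampSpec(100.0, 0.0), duration_ms=5.0)
        assert -70.0 < sol.soma_steady_mV < 0.0
        assert sol.soma_steady_mV > -55.0    # strong depolarization at the soma

    def test_clamp_missing_dendrites_raises(self):
        g = sealed_cable_graph()
        g.z_um = g.z_um + 500.0              # nothing inside the slab
        with pytest.raises(ValueError):
            solve_clamped(g, PassiveParams(), ClampSpec(10.0, 0.0), duration_ms=1.0)

    def test_invalid_parameters_raise(self):
        with pytest.raises(ValueError):
            PassiveParams(membrane_resistance=-1.0)
        with pytest.raises(ValueError):
            ClampSpec(slab_depth_um=0.0)
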