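import numpy as np
import pytest

from fontansim import _engine
from fontansim.cardiac_chambers import ATRIAL_PHASE_FRACTION
from fontansim.simulator import (
    StateLayout,
    _pack,
    initial_state,
    run_to_steady_state,
    state_derivative,
)


def _kernel_rhs(x, t, topo, params, mv_mode, av_mode, mv_b=0.0, mv_l=1.0):
    pk = _pack(topo, params)
    dx = np.empty_like(x)
    n_nodes = pk.layout.n_comp + 3
    net, p_all, p_ch = np.empty(n_nodes), np.empty(n_nodes), np.empty(3)
    _engine._rhs(
        t, x, dx, net, p_all, p_ch,
        pk.layout.n_comp, pk.layout.n_seg,
        pk.seg_up, pk.seg_dn, pk.seg_r, pk.seg_l, pk.seg_b, pk.seg_kind,
        pk.comp_c, pk.comp_pext,
        pk.ch_es, pk.ch_ed, pk.ch_ks, pk.ch_pext,
        params.T_0, params.T_vcp, params.T_vrp, ATRIAL_PHASE_FRACTION * params.T_0,
        mv_mode, av_mode, mv_b, mv_l,
    )
    return dx


def _random_state(topo, params, seed):
    rng = np.random.default_rng(seed)
    x = initial_state(topo, params)
    x = x + rng.normal(0.0, 1.0, x.size)
    x[-3:] = np.abs(x[-3:]) + 5.0  # chamber volumes positive
    return x


class TestStateDerivative:
    @pytest.mark.parametrize("config", ["BCPA", "TCPC"])
    @pytest.mark.parametrize("mv_mode,av_mode", [(1, 1), (1, 0), (0, 1), (0, 0)])
    def test_compiled_kernel_matches_reference(self, config, mv_mode, av_mode, params):
        from fontansim import build_topology

        topo = build_topology(config, params)
        for seed, t in [(0, 0.05), (1, 0.3), (2, 0.61)]:
            x = _random_state(topo, params, seed)
            ref = state_derivative(x, t, topo, params, mv_mode, av_mode)
            ker = _kernel_rhs(x, t, topo, params, mv_mode, av_mode)
            np.testing.assert_allclose(ker, ref, rtol=1e-12, atol=1e-9)

    def test_compiled_kernel_matches_reference_in_regurgitant_mode(self, params):
        from fontansim import build_topology
        from fontansim.valves import regurgitant_parameters

        p = params.model_copy(update={"mv_areg_cm2": 0.1})
        topo = build_topology("BCPA", p)
        x = _random_state(topo, p, 3)
        layout = StateLayout(topo)
        b_reg, l_reg = regurgitant_parameters(0.1, x[layout.v_index("LA")], p.rho)
        ref = state_derivative(x, 0.1, topo, p, _engine.REGURGITANT, 1)
        ker = _kernel_rhs(x, 0.1, topo, p, _engine.REGURGITANT, 1, b_reg, l_reg)
        np.testing.assert_allclose(ker, ref, rtol=1e-12, atol=1e-9)

    def test_quiescent_uniform_pressure_is_a_fixed_point(self, params, bcpa_topology):
        # during diastasis (no chamber activation) a state with zero flows
        # and one common luminal pressure everywhere has zero derivative
        layout = StateLayout(bcpa_topology)
        p_common = 7.0
        x = np.zeros(layout.n)
        for c in bcpa_topology.compartments:
            x[layout.p_index(c.name)] = p_common
        for ch, e_d in [("RA", params.E_rad), ("LA", params.E_lad), ("LV", params.E_lvd)]:
            x[layout.v_index(ch)] = (p_common - params.P_pc - params.P_it) / e_d
        t_quiet = 0.45  # after ventricular relaxation, before atrial kick
        dx = state_derivative(x, t_quiet, bcpa_topology, params, mv_mode=1, av_mode=1)
        np.testing.assert_allclose(dx, 0.0, atol=1e-10)

    def test_closed_loop_conserves_volume_at_any_state(self, params, bcpa_topology):
        layout = StateLayout(bcpa_topology)
        for seed in range(3):
            x = _random_state(bcpa_topology, params, seed)
            dx = state_derivative(x, 0.2, bcpa_topology, params, 1, 1)
            dv_total = sum(
                c.C * dx[layout.p_index(c.name)] for c in bcpa_topology.compartments
            ) + dx[layout.v_index("RA")] + dx[layout.v_index("LA")] + dx[layout.v_index("LV")]
            assert dv_total == pytest.approx(0.0, abs=1e-9)

    def test_perturbation_only_affects_adjacent_segments(self, params, bcpa_topology):
        layout = StateLayout(bcpa_topology)
        x = _random_state(bcpa_topology, params, 7)
        base = state_derivative(x, 0.2, bcpa_topology, params, 1, 1)
        xp = x.copy()
        xp[layout.p_index("ivc")] += 1.0
        pert = state_derivative(xp, 0.2, bcpa_topology, params, 1, 1)
        changed = set(np.nonzero(np.abs(pert - base) > 1e-12)[0])
        adjacent = {
            layout.q_index(s.name)
            for s in bcpa_topology.segments
            if "ivc" in (s.upstream, s.downstream)
        }
        assert changed == adjacent

    def test_nonfinite_state_rejected(self, params, bcpa_topology):
        x = initial_state(bcpa_topology, params)
        x[0] = np.nan
        with pytest.raises(ValueError):
            state_derivative(x, 0.0, bcpa_topology, params)


class TestInitialState:
    def test_total_volume_is_exact(self, params, bcpa_topology):
        layout = StateLayout(bcpa_topology)
        x = initial_state(bcpa_topology, params)
        total = sum(
            c.C * (x[layout.p_index(c.name)] - c.external_pressure(params.P_it))
            for c in bcpa_topology.compartments
        ) + x[layout.v_index("RA")] + x[layout.v_index("LA")] + x[layout.v_index("LV")]
        assert total == pytest.approx(params.V_tot, rel=1e-12)

    def test_insufficient_volume_rejected(self, params, bcpa_topology):
        p = params.model_copy(update={"V_tot": 10.0})
        with pytest.raises(ValueError):
            initial_state(bcpa_topology, p)


class TestIntegration:
    def test_deterministic_bit_identical(self, params, bcpa_topology):
        a = run_to_steady_state(bcpa_topology, params, tol=1e-3, max_cycles=14)
        b = run_to_steady_state(bcpa_topology, params, tol=1e-3, max_cycles=14)
        assert np.array_equal(a.states, b.states)
        assert np.array_equal(a.cycle_means, b.cycle_means)

    def test_dt_must_divide_cycle(self, params, bcpa_topology):
        with pytest.raises(ValueError):
            run_to_steady_state(bcpa_topology, params, dt=1.1e-4)

    def test_convergence_metadata(self, bcpa_result):
        assert bcpa_result.converged
        assert bcpa_result.residual < 1e-6
        assert bcpa_result.states.shape[0] == bcpa_result.n_keep * 6700

    def test_nonconvergence_is_flagged_not_fatal(self, params, bcpa_topology):
        res = run_to_steady_state(bcpa_topology, params, tol=1e-12, max_cycles=14)
        assert not res.converged

    def test_mean_flow_consistency_at_junctions(self, bcpa_result):
        # in the periodic steady state, cycle-mean inflow equals cycle-mean
        # outflow at every compliant node
        topo = bcpa_result.topology
        for c in topo.compartments:
            q_in = sum(bcpa_result.mean(f"Q_{s.name}") for s in topo.inflows(c.name))
            q_out = sum(bcpa_result.mean(f"Q_{s.name}") for s in topo.outflows(c.name))
            scale = max(abs(q_out), 1.0)
            assert abs(q_in - q_out) / scale < 5e-3, c.name

    def test_larger_blood_volume_raises_arterial_pressure(self, params, bcpa_topology):
        maps = []
        for v_tot in (280.0, 370.0, 460.0):
            p = params.model_copy(update={"V_tot": v_tot})
            res = run_to_steady_state(bcpa_topology, p, tol=1e-5, max_cycles=400)
            maps.append(res.mean("P_ao"))
        assert maps[0] < maps[1] < maps[2]
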