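import dataclasses

import numpy as np
import pytest

from fontansim.experiments import (
    HemodynamicSummary,
    perioperative_change,
    parameter_sweep,
    regurgitation_sweep,
    summarize,
    waveform_features,
)
from fontansim.simulator import SimulationResult, StateLayout


def _dummy_summary(**overrides):
    base = dict(
        config="BCPA",
        mP_svc=10.0, mP_ivc=5.3, mP_pa=9.0, mP_la=5.0, mP_art=72.1,
        SV=20.1, EDV=32.5, EF=61.9, mQ_pul=15.7, CO=30.0,
        regurgitation_fraction=0.0,
    )
    base.update(overrides)
    return HemodynamicSummary(**base)


class TestSummaries:
    def test_internal_consistency_of_cycle_averages(self, bcpa_summary, params):
        # EF is SV/EDV by definition; CO equals SV per beat because the
        # aortic valve admits no retrograde volume
        assert bcpa_summary.EF == pytest.approx(
            100.0 * bcpa_summary.SV / bcpa_summary.EDV, rel=1e-9
        )
        assert bcpa_summary.CO == pytest.approx(bcpa_summary.SV / params.T_0, rel=5e-3)
        assert bcpa_summary.regurgitation_fraction == 0.0

    def test_pulmonary_flow_vs_cardiac_output(self, bcpa_summary, tcpc_summary):
        # Glenn: only upper-body return crosses the lungs; Fontan: series
        # circuit, all output does
        assert bcpa_summary.mQ_pul < bcpa_summary.CO
        assert tcpc_summary.mQ_pul == pytest.approx(tcpc_summary.CO, rel=5e-3)

    def test_glenn_flow_partition(self, bcpa_result, bcpa_summary):
        # pulmonary flow equals SVC flow and the IVC carries the rest
        q_svc = bcpa_result.mean("Q_svc")
        q_ivc = bcpa_result.mean("Q_ivc")
        assert bcpa_summary.mQ_pul == pytest.approx(q_svc, rel=5e-3)
        assert bcpa_summary.CO - bcpa_summary.mQ_pul == pytest.approx(q_ivc, rel=2e-2)

    def test_nonconverged_run_rejected(self, bcpa_result, params):
        broken = dataclasses.replace(bcpa_result, converged=False)
        with pytest.raises(ValueError):
            summarize(broken, params)


class TestPerioperativeChange:
    def test_identical_summaries_give_zero_change(self):
        s = _dummy_summary()
        ch = perioperative_change(s, s)
        assert ch.dQ_pul_pct == 0.0
        assert ch.dP_ivc_pct == 0.0

    def test_reference_arithmetic(self):
        glenn = _dummy_summary()
        tcpc = _dummy_summary(config="TCPC", mQ_pul=17.4, mP_ivc=8.0)
        ch = perioperative_change(glenn, tcpc)
        assert ch.dQ_pul_pct == pytest.approx(10.83, abs=0.01)
        assert ch.dP_ivc_pct == pytest.approx(50.94, abs=0.01)

    def test_zero_reference_rejected(self):
        with pytest.raises(ZeroDivisionError):
            perioperative_change(_dummy_summary(mQ_pul=0.0), _dummy_summary())


class TestWaveformFeatures:
    def _synthetic_result(self, q_ivc, bcpa_topology):
        layout = StateLayout(bcpa_topology)
        n = q_ivc.size
        states = np.zeros((n, layout.n))
        states[:, layout.q_index("ivc")] = q_ivc
        return SimulationResult(
            topology=bcpa_topology, layout=layout,
            time=np.arange(n) * 1e-4, states=states,
            cycle_means=states.mean(axis=0), dt=1e-4,
            cycles_run=1, n_keep=1, converged=True, residual=0.0,
        )

    def test_constant_waveform_has_no_peaks(self, bcpa_topology):
        res = self._synthetic_result(np.full(1000, 7.0), bcpa_topology)
        f = waveform_features(res, "IVC")
        assert f.n_peaks == 0 and not f.retrograde and f.pulse == 0.0

    def test_biphasic_waveform_with_retrograde_flow(self, bcpa_topology):
        t = np.linspace(0, 1, 2000, endpoint=False)
        q = 10.0 + 8.0 * np.sin(2 * np.pi * t) + 6.0 * np.sin(4 * np.pi * t + 1.0)
        q -= 12.0  # push the trough below zero
        res = self._synthetic_result(q, bcpa_topology)
        f = waveform_features(res, "IVC")
        assert f.n_peaks == 2
        assert f.retrograde

    def test_peak_at_cycle_wrap_is_counted_once(self, bcpa_topology):
        t = np.linspace(0, 1, 2000, endpoint=False)
        q = 5.0 + 3.0 * np.cos(2 * np.pi * t)  # single peak, at the wrap point
        res = self._synthetic_result(q, bcpa_topology)
        assert waveform_features(res, "IVC").n_peaks == 1


class TestSweeps:
    def test_identity_factor_row_matches_baseline(self, params, bcpa_summary, tcpc_summary):
        table = parameter_sweep("E_lvd", params, grid=[1.0])
        row = table.iloc[0]
        assert row["glenn_mQ_pul"] == pytest.approx(bcpa_summary.mQ_pul, rel=1e-5)
        assert row["tcpc_mP_ivc"] == pytest.approx(tcpc_summary.mP_ivc, rel=1e-5)
        baseline = perioperative_change(bcpa_summary, tcpc_summary)
        assert row["dQ_pul_pct"] == pytest.approx(baseline.dQ_pul_pct, abs=0.05)

    def test_sweep_table_is_reproducible(self, params):
        a = parameter_sweep("R_art_l", params, grid=[0.8], tol=1e-5, max_cycles=400)
        b = parameter_sweep("R_art_l", params, grid=[0.8], tol=1e-5, max_cycles=400)
        assert a.equals(b)

    def test_small_orifice_approaches_competent_baseline(
        self, params, bcpa_summary, tcpc_summary
    ):
        table = regurgitation_sweep(params, areas=[0.005], tol=1e-5, max_cycles=400)
        row = table.iloc[0]
        baseline = perioperative_change(bcpa_summary, tcpc_summary)
        assert row["regurgitation_fraction"] < 0.05
        assert row["dQ_pul_pct"] == pytest.approx(baseline.dQ_pul_pct, abs=1.5)
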