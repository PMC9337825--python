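"""Solver verification against closed-form passive solutions, plus
discretization and spike-detection behavior."""

import numpy as np
import pytest
from dataclasses import replace as dc_replace

from nociterm import (
    NumericalError,
    SimulationResult,
    build_terminal_tree,
    detect_spikes,
    discretize,
    integrate,
    total_membrane_area,
)
from nociterm.protocols import run_step_protocol, step_current_protocol
from conftest import make_passive_cable, _discretize_unvalidated

RM = 10_000.0  # ohm cm^2
CM = 1.0  # uF/cm^2
TAU = RM * CM / 1000.0  # membrane time constant, ms


class TestDiscretize:
    def test_ceiling_division_of_sections(self):
        cable = make_passive_cable(length_um=50.0, n_segments=1)
        from nociterm.cable import discretize as disc
        import nociterm.cable as cm

        orig = cm.validate_tree
        cm.validate_tree = lambda t: None
        try:
            refined = disc(cable.tree, max_seg_len=5.0)
        finally:
            cm.validate_tree = orig
        assert refined.n_comp == 10

    def test_total_area_matches_analytic(self, generic_tree):
        cable = discretize(generic_tree)
        analytic = total_membrane_area(generic_tree) * 1e-8  # um^2 -> cm^2
        assert cable.area.sum() == pytest.approx(analytic, rel=1e-3)

    def test_refinement_preserves_tree_structure(self, generic_tree):
        coarse = discretize(generic_tree)
        fine = discretize(generic_tree, refine=2)
        assert fine.n_comp == 2 * coarse.n_comp
        # each compartment except the root has exactly one parent with a
        # positive coupling conductance: a tree
        assert np.all(fine.g_axial[1:] > 0)
        assert np.all(fine.parent[1:] < np.arange(1, fine.n_comp))

    def test_terminal_passives_survive_discretization(self, small_cable):
        idx = [i for i, s in enumerate(small_cable.section_id) if s == "ending_0"]
        axon = [i for i, s in enumerate(small_cable.section_id) if s == "peripheral_axon"]
        # 4x membrane resistance -> per-area leak 4x smaller
        g_end = small_cable.g_pas[idx[0]] / small_cable.area[idx[0]]
        g_ax = small_cable.g_pas[axon[0]] / small_cable.area[axon[0]]
        assert g_ax / g_end == pytest.approx(4.0)


class TestPassiveAnalytics:
    def test_rc_step_response_matches_closed_form(self, passive_compartment):
        cable = passive_compartment
        amp_pa = 10.0
        res = run_step_protocol(
            cable,
            step_current_protocol("cable", amp_pa, 60.0, t_start=5.0, t_stop=70.0),
            dt=0.005,
        )
        v = res.voltages["injection_site"]
        t = res.time
        r_in = RM / cable.area[0]  # ohm
        dv_inf = amp_pa * 1e-12 * r_in * 1e3  # mV
        sel = (t > 5.0) & (t <= 65.0)
        expect = -60.0 + dv_inf * (1.0 - np.exp(-(t[sel] - 5.0) / TAU))
        err = np.abs(v[sel] - expect).max()
        assert err < 1e-3 * dv_inf

    def test_steady_state_attenuation_matches_cosh_profile(self, passive_cable):
        cable = passive_cable  # 500 um, sealed ends, 5 um compartments
        res = run_step_protocol(
            cable,
            step_current_protocol("cable", 5.0, 400.0, t_start=0.0, position=0.0,
                                  t_stop=400.0),
            dt=0.05,
            record_sites={f"x{i}": i for i in range(0, 100, 7)},
        )
        d_cm, ra = 0.25e-4, 150.0
        lam = np.sqrt(RM * d_cm / (4.0 * ra)) * 1e4  # um
        L = 500.0
        centers = (np.arange(100) + 0.5) * 5.0
        x0 = centers[0]
        v_end = {k: res.voltages[k][-1] + 60.0 for k in res.voltages}
        profile = np.array([v_end[f"x{i}"] for i in range(0, 100, 7)])
        xs = centers[list(range(0, 100, 7))]
        expect = np.cosh((L - xs) / lam) / np.cosh((L - x0) / lam)
        assert np.allclose(profile / profile[0], expect, rtol=5e-3)

    def test_quiescent_passive_tree_holds_resting_potential(self, generic_tree):
        stripped = dc_replace(
            generic_tree,
            sections=tuple(
                dc_replace(s, channel_densities={}) for s in generic_tree.sections
            ),
        )
        cable = discretize(stripped)
        res = integrate(
            cable, dt=0.025, t_stop=500.0,
            record_sites={"soma": 0, "tip": cable.comp_index("ending_0", 1.0)},
        )
        for v in res.voltages.values():
            assert np.abs(v + 60.0).max() < 1e-6

    def test_passive_charge_balance_at_steady_state(self, passive_cable):
        cable = passive_cable
        inj = np.zeros(cable.n_comp)
        inj[0] = 0.005  # nA
        cable2 = dc_replace(cable, inj_amp=inj)
        nsteps = int(400.0 / 0.05)
        res = integrate(
            cable2, dt=0.05, t_stop=400.0,
            record_sites={f"c{i}": i for i in range(cable.n_comp)},
            inj_wave=np.ones(nsteps),
        )
        v = np.array([res.voltages[f"c{i}"][-1] for i in range(cable.n_comp)])
        # residual: injected + leak + axial, per compartment (nA)
        resid = inj + cable.g_pas * (-60.0 - v)
        for i in range(1, cable.n_comp):
            flow = cable.g_axial[i] * (v[cable.parent[i]] - v[i])
            resid[i] += flow
            resid[cable.parent[i]] -= flow
        # equivalent density threshold: 1e-9 mA/cm^2 * area -> nA
        assert np.all(np.abs(resid) < 1e-9 * cable.area * 1e6 + 1e-12)


class TestIntegrationBehavior:
    def test_divergence_raises_with_location(self, passive_compartment):
        inj = np.zeros(1)
        inj[0] = 10.0  # nA into ~0.6 GOhm: V -> thousands of mV
        cable = dc_replace(passive_compartment, inj_amp=inj)
        with pytest.raises(NumericalError) as exc:
            integrate(cable, dt=0.025, t_stop=200.0,
                      inj_wave=np.ones(8000), record_sites={"c": 0})
        assert exc.value.compartment == 0
        assert exc.value.time_ms is not None

    def test_bit_identical_reruns(self, single_chain_cable):
        kw = dict(dt=0.025, t_stop=300.0, record_sites={"soma": 0})
        a = integrate(single_chain_cable, **kw)
        b = integrate(single_chain_cable, **kw)
        assert np.array_equal(a.voltages["soma"], b.voltages["soma"])

    def test_suprathreshold_soma_step_fires(self, single_chain_cable):
        res = run_step_protocol(
            single_chain_cable,
            step_current_protocol("soma", 150.0, 500.0, t_start=100.0, t_stop=700.0),
            dt=0.025,
        )
        assert detect_spikes(res, "injection_site").count >= 1

    def test_zero_amplitude_step_leaves_trace_flat(self, passive_compartment):
        res = run_step_protocol(
            passive_compartment,
            step_current_protocol("cable", 0.0, 100.0, t_stop=300.0),
            dt=0.025,
        )
        v = res.voltages["injection_site"]
        assert np.abs(v - v[0]).max() < 1e-9


class TestDetectSpikes:
    def _result(self, t, v):
        return SimulationResult(
            time=t, voltages={"site": v}, stimulus_trace=np.zeros_like(t), metadata={}
        )

    def test_flat_trace_has_no_spikes(self):
        t = np.arange(0, 100.0, 0.1)
        res = self._result(t, np.full_like(t, -60.0))
        assert detect_spikes(res, "site").count == 0

    def test_three_well_separated_crossings(self):
        t = np.arange(0, 300.0, 0.1)
        v = -60 + 80.0 * (
            np.exp(-((t - 50) ** 2) / 4) + np.exp(-((t - 150) ** 2) / 4)
            + np.exp(-((t - 250) ** 2) / 4)
        )
        res = self._result(t, v)
        st = detect_spikes(res, "site", threshold=0.0, refractory=2.0)
        assert st.count == 3
        assert np.allclose(st.times, [48.9, 148.9, 248.9], atol=0.5)

    def test_refractory_merges_close_crossings(self):
        t = np.arange(0, 20.0, 0.05)
        v = -60 + 80.0 * (np.exp(-((t - 5.0) ** 2) / 0.02) + np.exp(-((t - 5.5) ** 2) / 0.02))
        res = self._result(t, v)
        assert detect_spikes(res, "site", refractory=2.0).count == 1
        assert detect_spikes(res, "site", refractory=0.1).count == 2

    def test_unknown_site_raises(self):
        t = np.arange(0, 10.0, 0.1)
        res = self._result(t, np.zeros_like(t))
        with pytest.raises(KeyError):
            detect_spikes(res, "elsewhere")

    def test_crossing_times_interpolated_between_samples(self):
        t = np.array([0.0, 1.0, 2.0, 3.0])
        v = np.array([-10.0, -10.0, 10.0, 10.0])
        st = detect_spikes(self._result(t, v), "site", threshold=0.0)
        assert st.times[0] == pytest.approx(1.5)
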