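"""Deterministic core: Hill algebra, RHS assembly, integrators, phases."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gliomanet.dynamics import (DETECTION_THRESHOLD, StateVector, Trajectory,
                                angiogenesis_factor, assemble_rhs,
                                compile_model, detect_phases, hill_response,
                                integrate_deterministic, logistic_factor,
                                modulation_factor)
from gliomanet.network import AngiogenesisParams, HillParams
from .conftest import make_toy_spec, toy_edge


class TestHillAlgebra:
    def test_zero_input(self):
        assert hill_response(0.0, K=3.0, n=2.0) == 0.0

    def test_half_saturation_identity(self):
        assert hill_response(3.0, K=3.0, n=4.0) == pytest.approx(0.5)

    def test_closed_form_at_ten_K(self):
        # c = 10 K, n = 2: (10^2)/(1 + 10^2)
        assert hill_response(10.0, K=1.0, n=2.0) == pytest.approx(
            100.0 / 101.0, rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            hill_response(-1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            hill_response(1.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            hill_response(1.0, 1.0, -2.0)

    @settings(max_examples=50, deadline=None)
    @given(K=st.floats(1e-3, 1e3), n=st.floats(0.2, 6.0),
           c1=st.floats(0, 1e4), c2=st.floats(0, 1e4))
    def test_monotone_in_concentration(self, K, n, c1, c2):
        lo, hi = sorted((c1, c2))
        assert hill_response(lo, K, n) <= hill_response(hi, K, n) + 1e-12

    def test_modulation_no_ligand_is_neutral(self):
        h = HillParams(K=2.0, n=2.0, a=3.0)
        assert modulation_factor(0.0, h, "up") == 1.0
        hd = HillParams(K=2.0, n=2.0, a=0.2)
        assert modulation_factor(0.0, hd, "down") == 1.0

    def test_modulation_saturates_at_amplitude(self):
        h = HillParams(K=1.0, n=2.0, a=3.0)
        assert modulation_factor(1e9, h, "up") == pytest.approx(3.0, rel=1e-6)

    def test_down_modulation_closed_form(self):
        # c = K: 1 - (1 - 0.2) * 0.5 = 0.6
        hd = HillParams(K=5.0, n=1.0, a=0.2)
        assert modulation_factor(5.0, hd, "down") == pytest.approx(0.6)

    @settings(max_examples=50, deadline=None)
    @given(K=st.floats(1e-2, 1e2), n=st.floats(0.5, 5),
           a=st.floats(1.0, 10.0), c=st.floats(0, 1e6))
    def test_up_modulation_bounds(self, K, n, a, c):
        f = modulation_factor(c, HillParams(K, n, a), "up")
        assert 1.0 <= f <= a + 1e-9

    def test_amplitude_domain_errors(self):
        with pytest.raises(ValueError):
            modulation_factor(1.0, HillParams(1, 1, 0.5), "up")
        with pytest.raises(ValueError):
            modulation_factor(1.0, HillParams(1, 1, 1.5), "down")


class TestLogisticAndAngiogenesis:
    @pytest.mark.parametrize("total,expected", [
        (0.0, 1.0), (4.2e7, 0.0), (2.1e7, 0.5), (9e7, 0.0)])
    def test_logistic_factor(self, total, expected):
        assert logistic_factor(total, 4.2e7) == pytest.approx(expected)

    def test_angiogenesis_floor_and_saturation(self):
        p = AngiogenesisParams(driver_cytokine_id="VEGF", A_min=0.2,
                               K_A=2.0, n_A=1.0)
        s0 = StateVector(0.0, {"VEGF": 0.0})
        assert angiogenesis_factor(s0, p) == pytest.approx(0.2)
        s1 = StateVector(0.0, {"VEGF": 2.0})  # at K_A: 0.2 + 0.8/2
        assert angiogenesis_factor(s1, p) == pytest.approx(0.6)
        s2 = StateVector(0.0, {"VEGF": 1e12})
        assert angiogenesis_factor(s2, p) == pytest.approx(1.0, rel=1e-6)

    def test_missing_driver_is_an_error(self):
        p = AngiogenesisParams(driver_cytokine_id="VEGF")
        with pytest.raises(KeyError):
            angiogenesis_factor(StateVector(0.0, {"IL6": 1.0}), p)


class TestRHSAssembly:
    def test_default_system_has_20_equations(self, spec, model):
        y0 = model.initial_state()
        dy = model.rhs(y0)
        assert dy.shape == (20,)

    def test_pure_decay_reduction(self):
        toy = make_toy_spec(decay=0.3, secretion=0.0)
        rhs = assemble_rhs(toy)
        dy = rhs(np.array([100.0, 0.0]), 0.0)
        assert dy[0] == pytest.approx(-0.3 * 100.0)
        assert dy[1] == 0.0

    def test_secretion_modulation_enters_every_producer_term(self):
        # X up-regulates its own secretion; the factor must multiply the
        # producer term exactly once
        e = toy_edge("auto", "secretion", cytokine_id="X", species_id="X",
                     a=2.0, K=1.0, n=1.0)
        toy = make_toy_spec(secretion=1e-6, half_life=0.5, edges=[e])
        rhs = assemble_rhs(toy)
        y = np.array([1e5, 1.0])  # X at K -> factor 1.5
        dy = rhs(y, 0.0)
        expected = 1e-6 * 1.5 * 1e5 - (np.log(2) / 0.5) * 1.0
        assert dy[1] == pytest.approx(expected, rel=1e-12)

    def test_removing_an_edge_changes_only_its_own_term(self, spec):
        import copy
        m_full = compile_model(spec)
        reduced = copy.deepcopy(spec)
        # drop one GC-proliferation edge and audit the factor slots
        victim = next(e for e in reduced.edges
                      if e.target.process == "proliferation"
                      and e.target.species_id == "GC")
        reduced.edges = [e for e in reduced.edges if e.id != victim.id]
        reduced.expected_counts = None
        m_red = compile_model(reduced)
        y = m_full.initial_state() + 1.0
        f_full = m_full.factors(y)
        f_red = m_red.factors(y)
        gc = m_full.species_ids.index("GC")
        assert f_full["prolif"][gc] != pytest.approx(f_red["prolif"][gc])
        np.testing.assert_allclose(f_full["cell_decay"], f_red["cell_decay"])
        np.testing.assert_allclose(f_full["secretion_cyt"],
                                   f_red["secretion_cyt"])

    def test_unvalidated_spec_is_refused(self, spec):
        import copy
        bad = copy.deepcopy(spec)
        bad.edges[0].source_cytokine_id = "IL99"
        from gliomanet.network import ValidationError
        with pytest.raises(ValidationError):
            assemble_rhs(bad)


class TestIntegration:
    def test_exponential_decay_closed_form(self):
        toy = make_toy_spec(decay=np.log(2), secretion=0.0, cell_init=100.0)
        rhs = assemble_rhs(toy)
        for method in ("rk4", "dp5"):
            tr = integrate_deterministic(rhs, [100.0, 0.0], 3.0,
                                         method=method, step=0.002,
                                         rtol=1e-10, save_every=0.5)
            assert tr.species("C")[-1] == pytest.approx(12.5, rel=1e-6)

    def test_logistic_closed_form(self):
        cbar = 1e6
        toy = make_toy_spec(prolif=1.0, decay=0.0, secretion=0.0,
                            cbar=cbar, cell_init=cbar / 100)
        rhs = assemble_rhs(toy)
        tr = integrate_deterministic(rhs, [cbar / 100, 0.0], 10.0,
                                     method="dp5", rtol=1e-10,
                                     save_every=0.25)
        t = tr.times
        x0 = cbar / 100
        analytic = cbar * x0 * np.exp(t) / (cbar + x0 * (np.exp(t) - 1))
        np.testing.assert_allclose(tr.species("C"), analytic, rtol=1e-6)

    def test_fixed_step_and_adaptive_agree_on_default(self, spec, model):
        rhs = assemble_rhs(spec)
        y0 = model.initial_state()
        tr_rk4 = integrate_deterministic(rhs, y0, 240.0, method="rk4",
                                         step=0.02, save_every=2.0)
        tr_dp5 = integrate_deterministic(rhs, y0, 240.0, method="dp5",
                                         rtol=1e-8, save_every=2.0)
        gc_rk4 = tr_rk4.species("GC")[1:]
        gc_dp5 = np.interp(tr_rk4.times, tr_dp5.times, tr_dp5.species("GC"))[1:]
        mask = gc_dp5 > 1.0  # relative comparison once populations are real
        assert np.max(np.abs(gc_rk4[mask] - gc_dp5[mask]) / gc_dp5[mask]) < 1e-3

    def test_nonnegativity_contract(self, spec, model):
        rhs = assemble_rhs(spec)
        tr = integrate_deterministic(rhs, model.initial_state(), 120.0,
                                     method="euler", step=0.02)
        assert np.all(tr.values >= 0.0)

    def test_bad_inputs(self, spec, model):
        rhs = assemble_rhs(spec)
        with pytest.raises(ValueError):
            integrate_deterministic(rhs, model.initial_state(), -1.0)
        with pytest.raises(ValueError):
            integrate_deterministic(rhs, -model.initial_state() - 1, 10.0)


class TestPhaseDetection:
    def test_no_crossing_is_flagged_absent(self):
        t = np.linspace(0, 100, 11)
        traj = Trajectory(t, np.column_stack([np.full(11, 1e4),
                                              np.linspace(0, 1e5, 11)]),
                          ["QSC", "GC"])
        rep = detect_phases(traj)
        assert rep.detection_crossing_time is None

    def test_linear_interpolation_of_crossing(self):
        # GC = t * 1e5/day crosses 1e6 exactly at t = 10 even with coarse
        # sampling
        t = np.array([0.0, 4.0, 8.0, 12.0, 16.0])
        gc = t * 1e5
        traj = Trajectory(t, gc[:, None], ["GC"])
        rep = detect_phases(traj, detection_threshold=DETECTION_THRESHOLD)
        assert rep.detection_crossing_time == pytest.approx(10.0)

    def test_milestones_are_ordered_on_default_run(self, spec, model):
        rhs = assemble_rhs(spec)
        tr = integrate_deterministic(rhs, model.initial_state(), 365.0,
                                     method="dp5", rtol=1e-7)
        rep = detect_phases(tr)
        assert rep.activation_complete_time is not None
        assert rep.detection_crossing_time is not None
        assert (rep.activation_complete_time <= rep.detection_crossing_time
                <= rep.saturation_time)
        assert set(rep.phase_windows) == {"pre_tumor", "rapid_expansion",
                                          "malignant"}
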