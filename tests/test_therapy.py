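"""Therapy engine: plans, triggers, intervention composition, pairing."""

import numpy as np
import pytest

from gliomanet.dynamics import compile_model
from gliomanet.therapy import (Intervention, TherapyPlan, Trigger,
                               combination_plan, compare_outcomes,
                               microglia_depletion_plan, plan_segments,
                               run_therapy_ensemble, simulate_with_therapy)


class TestPlanConstruction:
    def test_depletion_plan_shape(self):
        plan = microglia_depletion_plan(5e4, 10.0)
        (trig, ivs), = plan.items
        assert trig.species_id == "GC" and trig.threshold == 5e4
        assert ivs[0].kind == "apoptosis_multiplier"
        assert ivs[0].target_id == "microglia" and ivs[0].factor == 10.0

    def test_combination_plan_shape(self):
        plan = combination_plan(["VEGF", "MIF", "IL6", "HGF"], 0.1, 1e6)
        (trig, ivs), = plan.items
        assert len(ivs) == 4
        assert {iv.target_id for iv in ivs} == {"VEGF", "MIF", "IL6", "HGF"}
        assert all(iv.kind == "production_inhibition" for iv in ivs)

    def test_empty_combination_is_control(self, model, noise, jumps):
        plan = combination_plan([], 0.1, 1e6)
        treated, rep = simulate_with_therapy(model, None, plan, noise, jumps,
                                             t_span=30.0, dt=0.02, seed=6)
        assert rep.postponement_months == 0.0

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            microglia_depletion_plan(-1.0)
        with pytest.raises(ValueError):
            Intervention("apoptosis_multiplier", "microglia", 0.5)
        with pytest.raises(ValueError):
            Intervention("production_inhibition", "IL6", 2.0)
        with pytest.raises(ValueError):
            Trigger("species_threshold", "GC", -5.0)

    def test_plan_validation_against_spec(self, spec):
        plan = combination_plan(["IL99"], 0.1, 1e6)
        with pytest.raises(KeyError, match="IL99"):
            plan.validate_against(spec)
        bad = TherapyPlan("x", [(Trigger(), [
            Intervention("apoptosis_multiplier", "IL6", 10.0)])])
        with pytest.raises(KeyError):
            bad.validate_against(spec)


class TestInterventionComposition:
    def test_stacked_factors_multiply(self, model):
        # two apoptosis multipliers a then b equal one with a*b
        iv_a = Intervention("apoptosis_multiplier", "microglia", 2.0)
        iv_b = Intervention("apoptosis_multiplier", "microglia", 5.0)
        iv_ab = Intervention("apoptosis_multiplier", "microglia", 10.0)
        from gliomanet.therapy import _apply_once
        p1 = _apply_once(model, _apply_once(model, model.base, iv_a, 2.0),
                         iv_b, 5.0)
        p2 = _apply_once(model, model.base, iv_ab, 10.0)
        np.testing.assert_allclose(p1.cell_decay, p2.cell_decay, rtol=1e-12)

    def test_finite_duration_reverts_parameters(self, model):
        iv = Intervention("production_inhibition", "IL6", 0.1, duration=5.0)
        plan = TherapyPlan("washout", [(Trigger("fixed_time", time=1.0),
                                        [iv])])
        segs = plan_segments(model, plan)
        (trig, transform), = segs
        params, extra = transform(model.base.copy(), 1.0)
        idx = model.prod_param["prod_IL6"]
        assert np.allclose(params.prod_rate[idx],
                           0.1 * model.base.prod_rate[idx])
        (rev_trig, revert), = extra
        assert rev_trig == ("time", 6.0)
        restored = revert(params, 6.0)
        np.testing.assert_allclose(restored.prod_rate[idx],
                                   model.base.prod_rate[idx], rtol=1e-12)

    def test_receptor_blockade_raises_effective_K(self, model):
        from gliomanet.therapy import _apply_once
        iv = Intervention("receptor_blockade", "VEGF", 0.1)
        p = _apply_once(model, model.base, iv, 0.1)
        idx = model.receptor_param["receptor_VEGF"]
        np.testing.assert_allclose(p.e_K[idx], model.base.e_K[idx] * 10.0)
        assert p.K_A == pytest.approx(model.base.K_A * 10.0)


class TestPairedOutcomes:
    def test_null_therapy_is_bitwise_identical_to_control(self, model, noise,
                                                          jumps, tmp_path):
        plan = microglia_depletion_plan(2e5, factor=1.0)
        treated, rep = simulate_with_therapy(model, None, plan, noise, jumps,
                                             t_span=250.0, dt=0.02, seed=9)
        from gliomanet.stochastic import simulate
        control, _ = simulate(model, None, noise, jumps, 250.0, 0.02, seed=9)
        pt, pc = tmp_path / "t.csv", tmp_path / "c.csv"
        treated.to_csv(pt, sidecar=False)
        control.to_csv(pc, sidecar=False)
        assert pt.read_bytes() == pc.read_bytes()
        assert rep.postponement_months == pytest.approx(0.0, abs=1e-9)

    def test_trigger_that_never_fires(self, model, noise, jumps):
        plan = microglia_depletion_plan(1e12)
        treated, rep = simulate_with_therapy(model, None, plan, noise, jumps,
                                             t_span=30.0, dt=0.02, seed=2)
        assert rep.administered_day is None

    def test_unpaired_ensembles_are_refused(self, model, noise, jumps):
        from gliomanet.stochastic import run_ensemble
        plan = microglia_depletion_plan(2e5)
        other = run_ensemble(model, None, noise, jumps, 20.0, 0.05, 2,
                             master_seed=999)
        with pytest.raises(ValueError, match="seed-paired"):
            run_therapy_ensemble(model, None, plan, noise, jumps, 20.0, 0.05,
                                 2, master_seed=1, control=other)

    def test_identical_outcomes_give_zero_benefit(self, model, noise, jumps):
        plan = combination_plan([], 0.1, 1e6)
        _, _, outs = run_therapy_ensemble(model, None, plan, noise, jumps,
                                          40.0, 0.05, 3, master_seed=3)
        s = compare_outcomes(outs)
        assert s["median_postponement_months"] == pytest.approx(0.0, abs=1e-9)
        assert s["iqr_postponement_months"][0] == pytest.approx(0.0, abs=1e-9)

    def test_depletion_benefit_ordering_on_fixture_patient(self, model,
                                                           noise, jumps):
        """Earlier microglia depletion is at least as beneficial as later."""
        from gliomanet.patients import fixture_patient
        pat = fixture_patient(1)
        from gliomanet.stochastic import run_ensemble
        ctrl = run_ensemble(model, pat, noise, jumps, 365.0, 0.02, 4,
                            master_seed=8)
        medians = []
        for dens in (5e4, 2e5, 1e6):
            plan = microglia_depletion_plan(dens)
            _, _, outs = run_therapy_ensemble(model, pat, plan, noise, jumps,
                                              365.0, 0.02, 4, master_seed=8,
                                              control=ctrl)
            medians.append(
                compare_outcomes(outs)["median_postponement_months"])
        assert medians[0] >= medians[1] - 0.25
        assert medians[1] >= medians[2] - 0.25
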