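"""Trigger-based therapy engine.

A :class:`TherapyPlan` pairs triggers (a glioma-density threshold or a fixed
day) with rate-modifying interventions: raising a cell population's
apoptotic rate (microglia depletion), inhibiting or enhancing a cytokine's
production, or blocking its receptors.  Treated and control runs share the
same seed and therefore the same noise stream, so any difference between
them is attributable to the therapy alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .dynamics import (DETECTION_THRESHOLD, OBJECTIVE_DENSITY, CompiledModel,
                       ParamSet, PhaseReport, Trajectory, compile_model,
                       detect_phases)
from .network import NetworkSpec
from .patients import PatientProfile
from .stochastic import EnsembleResult, JumpProcess, NoiseSpec, run_ensemble, simulate

__all__ = [
    "Trigger", "Intervention", "TherapyPlan", "microglia_depletion_plan",
    "combination_plan", "simulate_with_therapy", "run_therapy_ensemble",
    "compare_outcomes", "OutcomeReport", "load_plan", "save_plan",
    "DAYS_PER_MONTH",
]

DAYS_PER_MONTH = 30.4  # fixed reporting convention

INTERVENTION_KINDS = ("apoptosis_multiplier", "production_inhibition",
                      "receptor_blockade", "production_enhancement")


@dataclass
class Trigger:
    kind: str = "species_threshold"   # species_threshold | fixed_time
    species_id: str = "GC"
    threshold: float = DETECTION_THRESHOLD  # cells/ml, first upward crossing
    time: float = 0.0                 # days, fixed_time kind

    def __post_init__(self):
        if self.kind == "species_threshold" and self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        if self.kind == "fixed_time" and self.time < 0:
            raise ValueError("time must be >= 0")
        if self.kind not in ("species_threshold", "fixed_time"):
            raise ValueError(f"unknown trigger kind {self.kind!r}")


@dataclass
class Intervention:
    kind: str          # one of INTERVENTION_KINDS
    target_id: str     # cell species (apoptosis) or cytokine (the rest)
    factor: float
    duration: Optional[float] = None  # days; None = permanent

    def __post_init__(self):
        if self.kind not in INTERVENTION_KINDS:
            raise ValueError(f"unknown intervention kind {self.kind!r}")
        if self.factor <= 0:
            raise ValueError("factor must be > 0")
        if self.kind == "apoptosis_multiplier" and self.factor < 1:
            raise ValueError("apoptosis multiplier must be >= 1")
        if self.kind == "production_inhibition" and self.factor > 1:
            raise ValueError("inhibition factor must be <= 1")
        if self.kind == "production_enhancement" and self.factor < 1:
            raise ValueError("enhancement factor must be >= 1")
        if self.kind == "receptor_blockade" and self.factor > 1:
            raise ValueError("receptor blockade factor must be <= 1")
        if self.duration is not None and self.duration <= 0:
            raise ValueError("duration must be positive or None")


@dataclass
class TherapyPlan:
    plan_id: str
    items: list[tuple[Trigger, list[Intervention]]] = field(default_factory=list)

    def validate_against(self, spec: NetworkSpec) -> None:
        cells = {s.id for s in spec.cells}
        cyts = {s.id for s in spec.cytokines}
        for trig, ivs in self.items:
            if trig.kind == "species_threshold" and trig.species_id not in (
                    cells | cyts):
                raise KeyError(f"trigger species {trig.species_id!r} unknown")
            for iv in ivs:
                if iv.kind == "apoptosis_multiplier":
                    if iv.target_id not in cells:
                        raise KeyError(
                            f"{iv.kind} target {iv.target_id!r} is not a cell")
                elif iv.target_id not in cyts:
                    raise KeyError(
                        f"{iv.kind} target {iv.target_id!r} is not a cytokine")


def microglia_depletion_plan(trigger_density: float,
                             factor: float = 10.0,
                             plan_id: Optional[str] = None) -> TherapyPlan:
    """Deplete microglia by multiplying their apoptotic rate by ``factor``
    (default 10) once glioma density first crosses ``trigger_density``."""
    if trigger_density <= 0:
        raise ValueError("trigger_density must be > 0")
    trig = Trigger("species_threshold", "GC", trigger_density)
    iv = Intervention("apoptosis_multiplier", "microglia", factor)
    return TherapyPlan(plan_id or f"microglia_depletion@{trigger_density:g}",
                       [(trig, [iv])])


def combination_plan(cytokine_ids: Sequence[str],
                     inhibition_factor: float = 0.1,
                     trigger_density: float = DETECTION_THRESHOLD,
                     mode: str = "production",
                     plan_id: Optional[str] = None) -> TherapyPlan:
    """Blockade of one or more cytokines at a shared glioma-density trigger.

    ``mode`` selects production inhibition (default) or receptor blockade;
    an empty cytokine list yields a plan identical to no treatment.
    """
    kind = ("production_inhibition" if mode == "production"
            else "receptor_blockade")
    trig = Trigger("species_threshold", "GC", trigger_density)
    ivs = [Intervention(kind, c, inhibition_factor) for c in cytokine_ids]
    return TherapyPlan(
        plan_id or f"combo_{'+'.join(cytokine_ids) or 'none'}", [(trig, ivs)])


# ---------------------------------------------------------------------------
# applying interventions to effective parameters


def _apply_once(model: CompiledModel, params: ParamSet,
                iv: Intervention, factor: float) -> ParamSet:
    p = params.copy()
    if iv.kind == "apoptosis_multiplier":
        p.cell_decay[model.species_ids.index(iv.target_id)] *= factor
    elif iv.kind in ("production_inhibition", "production_enhancement"):
        idx = model.prod_param[f"prod_{iv.target_id}"]
        p.prod_rate[idx] *= factor
    else:  # receptor_blockade: lower receptor level => higher effective K
        pid = f"receptor_{iv.target_id}"
        if pid not in model.receptor_param:
            raise KeyError(f"no receptor parameter for {iv.target_id!r}")
        p.e_K[model.receptor_param[pid]] /= factor
        if model.receptor_param_angio.get(pid):
            p.K_A /= factor
    return p


def plan_segments(model: CompiledModel, plan: TherapyPlan) -> list:
    """Translate a plan into the (trigger, transform) segments the
    stochastic engine consumes.  Finite-duration interventions arm a
    follow-up time segment that applies the inverse factor."""
    segs = []
    for trig, ivs in plan.items:
        if trig.kind == "species_threshold":
            tg = ("species", trig.species_id, trig.threshold)
        else:
            tg = ("time", trig.time)

        def transform(params, t_fire, ivs=ivs):
            extra = []
            for iv in ivs:
                params = _apply_once(model, params, iv, iv.factor)
                if iv.duration is not None:
                    def revert(pp, _t, iv=iv):
                        return _apply_once(model, pp, iv, 1.0 / iv.factor)
                    extra.append((("time", t_fire + iv.duration), revert))
            return (params, extra) if extra else params

        segs.append((tg, transform))
    return segs


# ---------------------------------------------------------------------------
# outcomes


@dataclass
class OutcomeReport:
    """Paired treated-vs-control outcome for one stochastic realization."""
    treated: PhaseReport
    control: PhaseReport
    administered_day: Optional[float]     # None = trigger never fired
    postponement_months: float
    postponement_censored: bool           # True if treated crossing never seen
    recurrence_within_horizon: bool
    survival_proxy_treated_months: Optional[float]
    survival_proxy_control_months: Optional[float]
    horizon_days: float


def _survival_window(traj: Trajectory, c_start: float, c_end: float,
                     gc_id: str = "GC"):
    t0 = traj.first_crossing(gc_id, c_start)
    t1 = traj.first_crossing(gc_id, c_end)
    if t0 is None or t1 is None:
        return None
    return (t1 - t0) / DAYS_PER_MONTH


def _outcome(treated: Trajectory, control: Trajectory,
             administered: Optional[float], horizon: float,
             detection: float, objective: float) -> OutcomeReport:
    ph_t = detect_phases(treated, detection_threshold=detection)
    ph_c = detect_phases(control, detection_threshold=detection)
    det_t = treated.first_crossing("GC", detection)
    det_c = control.first_crossing("GC", detection)
    censored = False
    if administered is not None and det_c is not None and \
            administered <= det_c + 1e-9:
        # therapy before clinical detection: benefit = detection postponement
        if det_t is None:
            postponement = (horizon - det_c) / DAYS_PER_MONTH
            censored = True
        else:
            postponement = (det_t - det_c) / DAYS_PER_MONTH
    else:
        # therapy at/after detection: benefit = threshold-to-objective gain
        obj_t = treated.first_crossing("GC", objective)
        obj_c = control.first_crossing("GC", objective)
        start_t = det_t if det_t is not None else administered
        start_c = det_c
        w_c = (None if obj_c is None or start_c is None
               else (obj_c - start_c) / DAYS_PER_MONTH)
        if obj_t is None and start_t is not None:
            w_t = (horizon - start_t) / DAYS_PER_MONTH
            censored = True
        elif start_t is not None:
            w_t = (obj_t - start_t) / DAYS_PER_MONTH
        else:
            w_t = None
        postponement = 0.0 if (w_t is None or w_c is None) else w_t - w_c
    # half-day tolerance: a threshold trigger fires on the step after the
    # interpolated crossing, which must not read as pre-therapy detection
    recurrence = det_t is not None and (
        administered is None or det_t >= administered - 0.5)
    return OutcomeReport(
        treated=ph_t, control=ph_c, administered_day=administered,
        postponement_months=postponement, postponement_censored=censored,
        recurrence_within_horizon=recurrence,
        survival_proxy_treated_months=_survival_window(
            treated, detection, objective),
        survival_proxy_control_months=_survival_window(
            control, detection, objective),
        horizon_days=horizon,
    )


def simulate_with_therapy(spec: NetworkSpec | CompiledModel,
                          patient: Optional[PatientProfile],
                          plan: TherapyPlan,
                          noise: Optional[NoiseSpec] = None,
                          jumps: Optional[Sequence[JumpProcess]] = None,
                          t_span: float = 365.0,
                          dt: float = 0.01,
                          seed: int = 0,
                          detection: float = DETECTION_THRESHOLD,
                          objective: float = OBJECTIVE_DENSITY,
                          control: Optional[Trajectory] = None,
                          ) -> tuple[Trajectory, OutcomeReport]:
    """Run one treated realization and its seed-paired untreated control.

    Returns the treated trajectory and the outcome report.  Pass a
    precomputed ``control`` trajectory (same seed/settings) to avoid
    re-simulating it.
    """
    model = spec if isinstance(spec, CompiledModel) else compile_model(spec)
    plan.validate_against(model.spec)
    segs = plan_segments(model, plan)
    treated, fires = simulate(model, patient, noise, jumps, t_span, dt,
                              seed=seed, segments=segs)
    if control is None:
        control, _ = simulate(model, patient, noise, jumps, t_span, dt,
                              seed=seed)
    administered = fires[0] if fires else None
    rep = _outcome(treated, control, administered, t_span, detection,
                   objective)
    return treated, rep


def run_therapy_ensemble(spec, patient, plan, noise=None, jumps=None,
                         t_span: float = 365.0, dt: float = 0.01,
                         n_reps: int = 20, master_seed: int = 0,
                         detection: float = DETECTION_THRESHOLD,
                         objective: float = OBJECTIVE_DENSITY,
                         control: Optional[EnsembleResult] = None):
    """Paired treated/control ensembles plus per-run outcome reports.

    Returns (treated_ensemble, control_ensemble, outcomes list).  The
    control ensemble can be shared across plans for the same patient and
    master seed.
    """
    model = spec if isinstance(spec, CompiledModel) else compile_model(spec)
    plan.validate_against(model.spec)
    segs = plan_segments(model, plan)
    treated = run_ensemble(model, patient, noise, jumps, t_span, dt,
                           n_reps, master_seed, segments=segs,
                           detection_threshold=detection)
    if control is None:
        control = run_ensemble(model, patient, noise, jumps, t_span, dt,
                               n_reps, master_seed,
                               detection_threshold=detection)
    if control.run_seeds != treated.run_seeds:
        raise ValueError("treated and control ensembles are not seed-paired")
    outcomes = []
    for i in range(n_reps):
        fires = treated.endpoints.loc[i, "fire_times"].split(";")
        administered = float(fires[0]) if fires and fires[0] else None
        outcomes.append(_outcome(treated.trajectories[i],
                                 control.trajectories[i],
                                 administered, t_span, detection, objective))
    return treated, control, outcomes


def compare_outcomes(outcomes: Sequence[OutcomeReport]) -> dict:
    """Benefit summary over paired runs: median and IQR postponement in
    months, fraction of runs with no recurrence, censoring count."""
    if not outcomes:
        raise ValueError("no outcomes to compare")
    post = np.array([o.postponement_months for o in outcomes], dtype=float)
    norec = np.array([not o.recurrence_within_horizon for o in outcomes])
    return {
        "n": len(outcomes),
        "median_postponement_months": float(np.median(post)),
        "iqr_postponement_months": (float(np.quantile(post, 0.25)),
                                    float(np.quantile(post, 0.75))),
        "fraction_no_recurrence": float(norec.mean()),
        "n_censored": int(sum(o.postponement_censored for o in outcomes)),
    }


# ---------------------------------------------------------------------------
# plan files


def save_plan(plan: TherapyPlan, path: str | Path) -> None:
    d = {"plan_id": plan.plan_id, "items": [
        {"trigger": vars(trig),
         "interventions": [vars(iv) for iv in ivs]}
        for trig, ivs in plan.items]}
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def load_plan(path: str | Path) -> TherapyPlan:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    items = [(Trigger(**it["trigger"]),
              [Intervention(**iv) for iv in it["interventions"]])
             for it in d.get("items", [])]
    return TherapyPlan(plan_id=d["plan_id"], items=items)
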