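"""Local sensitivity analysis of the survival-proxy objective.

The objective F is the time the glioma population takes to grow from the
clinical detection threshold (1e6/ml) to an objective density (1.5e7/ml), a
proxy for patient survival after diagnosis.  For each tunable parameter
x_i (cytokine production rates and receptor expression levels; 29 on the
default network) the sensitivity factor is the normalized central finite
difference

    S_i = [F(x_i * (1+d)) - F(x_i * (1-d))] / (2 d F(x0)),

estimated on seed-paired ensembles (common random numbers) so the Monte
Carlo error of S_i comes only from genuine trajectory differences.  A
negative S_i marks a pro-tumor parameter: inhibiting it prolongs survival.
When the tumor never reaches the start threshold the survival proxy is
undefined and the analysis falls back to tumorigenesis time (time to reach
the detection threshold), recorded per entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .dynamics import (DETECTION_THRESHOLD, OBJECTIVE_DENSITY, CompiledModel,
                       Trajectory, compile_model)
from .network import NetworkSpec
from .patients import PatientProfile, baseline_patient
from .stochastic import JumpProcess, NoiseSpec, run_seed_for, simulate
from .therapy import DAYS_PER_MONTH, Intervention, TherapyPlan, Trigger

__all__ = [
    "ObjectiveSpec", "survival_objective", "SensitivityEntry",
    "SensitivityReport", "sensitivity_factor", "sensitivity_profile",
    "design_combination",
]


@dataclass
class ObjectiveSpec:
    c_start: float = DETECTION_THRESHOLD
    c_end: float = OBJECTIVE_DENSITY
    species_id: str = "GC"
    statistic: str = "mean"  # ensemble statistic: mean | median

    def __post_init__(self):
        if not 0 < self.c_start < self.c_end:
            raise ValueError("need 0 < c_start < c_end")
        if self.statistic not in ("mean", "median"):
            raise ValueError("statistic must be 'mean' or 'median'")


def survival_objective(traj: Trajectory,
                       obj: ObjectiveSpec = ObjectiveSpec()) -> Optional[float]:
    """Months between the first upward crossings of c_start and c_end
    (linearly interpolated); None when either crossing is absent."""
    t0 = traj.first_crossing(obj.species_id, obj.c_start)
    t1 = traj.first_crossing(obj.species_id, obj.c_end)
    if t0 is None or t1 is None:
        return None
    return (t1 - t0) / DAYS_PER_MONTH


def _tumorigenesis(traj: Trajectory, obj: ObjectiveSpec) -> Optional[float]:
    t0 = traj.first_crossing(obj.species_id, obj.c_start)
    return None if t0 is None else t0 / DAYS_PER_MONTH


@dataclass
class SensitivityEntry:
    param_id: str
    S: float
    se: float
    delta: float
    objective_used: str          # "survival_proxy" | "tumorigenesis_time"
    n_effective: int             # paired runs that produced a finite value


@dataclass
class SensitivityReport:
    patient_id: str
    entries: list[SensitivityEntry]
    objective: ObjectiveSpec
    F0: float
    seed: int

    def ranking(self) -> list[SensitivityEntry]:
        """Most negative (pro-tumor) first; ties by |S| then param id."""
        return sorted(self.entries, key=lambda e: (e.S, -abs(e.S), e.param_id))

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame([vars(e) for e in self.entries])


def _perturbed(patient: PatientProfile, param_id: str,
               factor: float) -> PatientProfile:
    mult = dict(patient.multipliers)
    mult[param_id] = mult.get(param_id, 1.0) * factor
    return PatientProfile(patient_id=f"{patient.patient_id}|{param_id}x{factor:g}",
                          multipliers=mult, seed=patient.seed)


def _objective_values(model: CompiledModel, patient: PatientProfile,
                      noise, jumps, t_span, dt, n_reps, master_seed,
                      obj: ObjectiveSpec):
    """Per-run survival proxies and tumorigenesis times (None = undefined)."""
    surv, tumo = [], []
    for i in range(n_reps):
        ss = run_seed_for(master_seed, i)
        tr, _ = simulate(model, patient, noise, jumps, t_span, dt, seed=ss)
        surv.append(survival_objective(tr, obj))
        tumo.append(_tumorigenesis(tr, obj))
    return surv, tumo


def _stat(vals, statistic):
    arr = np.array([v for v in vals if v is not None], dtype=float)
    if len(arr) == 0:
        return None
    return float(np.median(arr) if statistic == "median" else arr.mean())


def sensitivity_factor(spec, patient: Optional[PatientProfile], param_id: str,
                       delta: float = 0.1,
                       n_reps: int = 5, seed: int = 0,
                       noise: Optional[NoiseSpec] = None,
                       jumps: Optional[Sequence[JumpProcess]] = None,
                       t_span: float = 365.0, dt: float = 0.02,
                       obj: ObjectiveSpec = ObjectiveSpec(),
                       _baseline_cache=None) -> SensitivityEntry:
    """Central-finite-difference sensitivity of one parameter.

    The three ensembles (baseline, up, down) share per-run seeds; the
    standard error is that of the per-run paired difference quotient.
    """
    if delta <= 0 or delta >= 1:
        raise ValueError("delta must be in (0, 1)")
    model = spec if isinstance(spec, CompiledModel) else compile_model(spec)
    patient = patient or baseline_patient()
    if param_id not in model.tunable_parameters():
        raise KeyError(f"{param_id!r} is not a tunable parameter")
    if _baseline_cache is None:
        _baseline_cache = _objective_values(model, patient, noise, jumps,
                                            t_span, dt, n_reps, seed, obj)
    surv0, tumo0 = _baseline_cache
    up = _objective_values(model, _perturbed(patient, param_id, 1 + delta),
                           noise, jumps, t_span, dt, n_reps, seed, obj)
    dn = _objective_values(model, _perturbed(patient, param_id, 1 - delta),
                           noise, jumps, t_span, dt, n_reps, seed, obj)

    for objective_used, base, plus, minus in (
            ("survival_proxy", surv0, up[0], dn[0]),
            ("tumorigenesis_time", tumo0, up[1], dn[1])):
        F0 = _stat(base, obj.statistic)
        quot = [(p - m) / (2 * delta * F0)
                for b, p, m in zip(base, plus, minus)
                if None not in (b, p, m) and F0]
        if F0 and len(quot) >= max(1, n_reps // 2):
            q = np.array(quot)
            se = float(q.std(ddof=1) / np.sqrt(len(q))) if len(q) > 1 else 0.0
            return SensitivityEntry(param_id, float(q.mean()), se, delta,
                                    objective_used, len(q))
    return SensitivityEntry(param_id, float("nan"), float("nan"), delta,
                            "undefined", 0)


def sensitivity_profile(spec, patient: Optional[PatientProfile] = None,
                        n_reps: int = 5, seed: int = 0,
                        delta: float = 0.1,
                        noise: Optional[NoiseSpec] = None,
                        jumps: Optional[Sequence[JumpProcess]] = None,
                        t_span: float = 365.0, dt: float = 0.02,
                        obj: ObjectiveSpec = ObjectiveSpec(),
                        params: Optional[Sequence[str]] = None,
                        ) -> SensitivityReport:
    """One sensitivity factor per tunable parameter (29 on the default
    network), deterministic given the seed."""
    model = spec if isinstance(spec, CompiledModel) else compile_model(spec)
    patient = patient or baseline_patient()
    baseline = _objective_values(model, patient, noise, jumps, t_span, dt,
                                 n_reps, seed, obj)
    F0 = _stat(baseline[0], obj.statistic)
    entries = [
        sensitivity_factor(model, patient, pid, delta, n_reps, seed, noise,
                           jumps, t_span, dt, obj, _baseline_cache=baseline)
        for pid in (params or model.tunable_parameters())
    ]
    return SensitivityReport(patient_id=patient.patient_id, entries=entries,
                             objective=obj, F0=F0 if F0 else float("nan"),
                             seed=seed)


def design_combination(report: SensitivityReport, k: int = 4,
                       inhibition_factor: float = 0.1,
                       trigger_density: float = DETECTION_THRESHOLD,
                       include_enhancers: int = 0) -> TherapyPlan:
    """Personalized combination therapy from a sensitivity ranking.

    The k most-negative parameters are countered (production inhibition for
    ``prod_*`` parameters, receptor blockade for ``receptor_*``); optionally
    the strongest positive parameters are enhanced.  Ties break by |S| then
    lexicographic param id; an all-zero report therefore yields a
    deterministic, flagged selection.
    """
    finite = [e for e in report.entries if np.isfinite(e.S)]
    if k > len(finite):
        raise ValueError(f"k={k} exceeds the {len(finite)} usable parameters")
    ranked = sorted(finite, key=lambda e: (e.S, -abs(e.S), e.param_id))
    ivs = []
    hit = set()
    for e in ranked:
        if len(ivs) >= k:
            break
        target = (e.param_id[5:] if e.param_id.startswith("prod_")
                  else e.param_id[9:])
        # production and receptor channels of one cytokine are locally
        # equivalent (both rescale level/K); target each cytokine once
        if target in hit:
            continue
        hit.add(target)
        if e.param_id.startswith("prod_"):
            ivs.append(Intervention("production_inhibition", target,
                                    inhibition_factor))
        else:
            ivs.append(Intervention("receptor_blockade", target,
                                    inhibition_factor))
    if include_enhancers:
        for e in [x for x in reversed(ranked) if x.S > 0][:include_enhancers]:
            target = (e.param_id[5:] if e.param_id.startswith("prod_")
                      else e.param_id[9:])
            ivs.append(Intervention("production_enhancement", target,
                                    1.0 / inhibition_factor))
    trig = Trigger("species_threshold", report.objective.species_id,
                   trigger_density)
    plan = TherapyPlan(
        plan_id=f"designed_for_{report.patient_id}_k{k}", items=[(trig, ivs)])
    return plan
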