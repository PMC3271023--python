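"""Virtual patients: parameter-multiplier profiles for inter-patient
molecular heterogeneity.

A patient is a vector of positive multipliers over the network's tunable
parameters: one production-rate multiplier per cytokine (``prod_<id>``,
scaling all of that cytokine's basal secretion rates) and one receptor
expression multiplier per signaling cytokine (``receptor_<id>``).  Receptor
expression enters through K-scaling: a multiplier m rescales every
half-saturation constant of that cytokine's edges to K/m, so higher
receptor expression means a stronger response at the same ligand level.
Profiles are sampled log-uniformly within literature-style ranges and are
reproducible from a seed; three fixture patients ship with the package as
reconstructions (the original per-patient tables are not public data).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .dynamics import CompiledModel, ParamSet, compile_model
from .network import NetworkSpec

__all__ = [
    "RangeEntry", "ParameterRanges", "PatientProfile", "default_parameter_ranges",
    "sample_patient", "apply_profile", "baseline_patient", "fixture_patient",
    "load_patient", "save_patient",
]


@dataclass
class RangeEntry:
    param_id: str
    lo: float
    hi: float
    scale: str = "log"  # "log" | "linear"


@dataclass
class ParameterRanges:
    entries: list[RangeEntry]

    def validate(self) -> None:
        for e in self.entries:
            if not (0 < e.lo <= e.hi):
                raise ValueError(f"{e.param_id}: need 0 < lo <= hi")
            if e.scale not in ("log", "linear"):
                raise ValueError(f"{e.param_id}: unknown scale {e.scale!r}")


@dataclass
class PatientProfile:
    patient_id: str
    multipliers: dict[str, float]
    seed: int | None = None
    provenance: str = ""

    def __post_init__(self):
        for k, v in self.multipliers.items():
            if v < 0:
                raise ValueError(f"{k}: multiplier must be >= 0")


def default_parameter_ranges(spec: NetworkSpec,
                             lo: float = 0.5, hi: float = 2.0,
                             scale: str = "log") -> ParameterRanges:
    """Log-uniform [0.5, 2] over every tunable parameter: a 4-fold spread in
    cytokine production and receptor expression across the cohort."""
    r = ParameterRanges([RangeEntry(p, lo, hi, scale)
                         for p in spec.tunable_parameters()])
    r.validate()
    return r


def sample_patient(ranges: ParameterRanges, seed: int,
                   patient_id: str | None = None) -> PatientProfile:
    """Draw one virtual patient; independent per-parameter draws, uniform on
    the declared scale, reproducible from the seed."""
    ranges.validate()
    rng = np.random.default_rng(seed)
    mult = {}
    for e in ranges.entries:
        u = rng.random()
        if e.scale == "log":
            mult[e.param_id] = float(np.exp(
                np.log(e.lo) + u * (np.log(e.hi) - np.log(e.lo))))
        else:
            mult[e.param_id] = float(e.lo + u * (e.hi - e.lo))
    return PatientProfile(
        patient_id=patient_id or f"patient_seed{seed}",
        multipliers=mult, seed=seed,
        provenance="sampled log-uniform from declared ranges")


def baseline_patient(patient_id: str = "baseline") -> PatientProfile:
    """The reference patient: all multipliers 1 (spec numerically unchanged)."""
    return PatientProfile(patient_id=patient_id, multipliers={},
                          provenance="baseline (all multipliers 1)")


def apply_profile(model: CompiledModel | NetworkSpec,
                  profile: PatientProfile) -> ParamSet:
    """Fold a patient's multipliers into an effective parameter set.

    Production multipliers scale basal secretion rates; receptor multipliers
    scale the half-saturation constants of the cytokine's edges by 1/m (and
    the angiogenesis K_A when the receptor governs the driver cytokine).
    The baseline profile returns parameters numerically identical to the
    spec's.
    """
    if isinstance(model, NetworkSpec):
        model = compile_model(model)
    known = set(model.prod_param) | set(model.receptor_param)
    unknown = [k for k in profile.multipliers if k not in known]
    if unknown:
        raise KeyError(f"profile {profile.patient_id!r} has unknown "
                       f"parameter ids: {sorted(unknown)}")
    p = model.base.copy()
    for pid, m in profile.multipliers.items():
        if pid in model.prod_param:
            p.prod_rate[model.prod_param[pid]] *= m
        else:
            if m <= 0:
                raise ValueError(f"{pid}: receptor multiplier must be > 0")
            p.e_K[model.receptor_param[pid]] /= m
            if model.receptor_param_angio.get(pid):
                p.K_A /= m
    return p


# ---------------------------------------------------------------------------
# file I/O and fixtures


def save_patient(profile: PatientProfile, path: str | Path) -> None:
    d = {"patient_id": profile.patient_id,
         "seed": profile.seed,
         "provenance": profile.provenance,
         "multipliers": {k: float(v)
                         for k, v in sorted(profile.multipliers.items())}}
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def load_patient(path: str | Path) -> PatientProfile:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return PatientProfile(patient_id=d["patient_id"],
                          multipliers=d.get("multipliers", {}) or {},
                          seed=d.get("seed"),
                          provenance=d.get("provenance", ""))


def fixture_patient(k: int) -> PatientProfile:
    """One of the three shipped virtual patients (k in {1, 2, 3}).

    These are synthetic reconstructions: fixed-seed draws from the default
    ranges, chosen so the trio spans the qualitative phenotypes reported for
    the original three virtual patients.
    """
    import importlib.resources
    if k not in (1, 2, 3):
        raise ValueError("fixture patients are numbered 1..3")
    ref = importlib.resources.files("gliomanet.data") / f"patient{k}.yaml"
    with importlib.resources.as_file(ref) as p:
        return load_patient(p)
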