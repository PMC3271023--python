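"""Deterministic dynamics: Hill modulation, RHS assembly, ODE integration.

The model is a well-mixed 1-ml control volume.  Each cell population obeys

    dc/dt = sum(conversions in) - sum(conversions out)
            + f * prod(up/down Hill factors) * L(total) * A(t) * c
            - d * prod(Hill factors) * c

with f the basal proliferation rate, d the basal decay rate, L the shared
logistic crowding factor 1 - c_total/c_bar, and A the VEGF-driven
angiogenesis factor (applied only to angiogenesis-gated cells, glioma cells
in the default network).  Each cytokine obeys

    dx/dt = sum_producers s_p * prod(Hill factors) * c_p - (ln2/tau) * x

where s_p are basal secretion rates and tau the half-life.  Every pathway
edge contributes one multiplicative Hill factor to exactly one process, so
removing an edge removes exactly its own terms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .network import (CELL, AngiogenesisParams, HillParams, NetworkSpec,
                      check_valid, spec_hash)

__all__ = [
    "hill_response", "modulation_factor", "logistic_factor",
    "angiogenesis_factor", "CompiledModel", "compile_model", "ParamSet",
    "assemble_rhs", "integrate_deterministic", "Trajectory", "StateVector",
    "PhaseReport", "detect_phases", "DETECTION_THRESHOLD", "OBJECTIVE_DENSITY",
]

#: assumed clinical detection density for glioma, cells/ml
DETECTION_THRESHOLD = 1e6
#: late-stage objective density used by the survival proxy, cells/ml
OBJECTIVE_DENSITY = 1.5e7

# edge slot types (which process a Hill factor multiplies)
SLOT_PROLIF = 0
SLOT_CELL_DECAY = 1
SLOT_CONVERSION = 2
SLOT_SECRETION_CYT = 3
SLOT_SECRETION_PAIR = 4
SLOT_CYT_DECAY = 5
SLOT_RECRUIT = 6


def hill_response(c: float, K: float, n: float):
    """Saturating Hill response c^n / (K^n + c^n), in [0, 1).

    Strictly increasing in c, value 1/2 at c = K.  Vectorized over c.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    if K <= 0 or n <= 0:
        raise ValueError("Hill K and n must be positive")
    with np.errstate(over="ignore"):
        r = (c / K) ** n
        out = np.where(np.isinf(r), 1.0, r / (1.0 + r))
    return float(out) if out.ndim == 0 else out


def modulation_factor(c: float, hill: HillParams, direction: str) -> float:
    """Multiplicative rate modulation by a cytokine at concentration c.

    up:   1 + (a - 1) * h, in [1, a] (a >= 1, max fold-change);
    down: 1 - (1 - a) * h, in (a, 1] (a in [0, 1], residual fraction).
    At c = 0 both directions return 1 (no ligand, no modulation).
    """
    h = hill_response(c, hill.K, hill.n)
    if direction == "up":
        if hill.a < 1:
            raise ValueError("up-modulation amplitude must be >= 1")
        return 1.0 + (hill.a - 1.0) * h
    if direction == "down":
        if not 0 <= hill.a <= 1:
            raise ValueError("down-modulation amplitude must be in [0, 1]")
        return 1.0 - (1.0 - hill.a) * h
    raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")


def logistic_factor(c_total: float, c_bar: float) -> float:
    """Crowding factor max(0, 1 - c_total/c_bar); c_bar is the saturating
    concentration shared by the competing cell populations."""
    if c_bar <= 0:
        raise ValueError("saturating concentration must be positive")
    return max(0.0, 1.0 - c_total / c_bar)


@dataclass
class StateVector:
    """Concentrations of every species at one time point (ordered as the
    network spec orders species)."""
    time: float
    values: dict[str, float]

    def __getitem__(self, sid: str) -> float:
        return self.values[sid]

    def as_array(self, species_ids: list[str]) -> np.ndarray:
        return np.array([self.values[s] for s in species_ids], dtype=float)


def angiogenesis_factor(state: StateVector, p: AngiogenesisParams) -> float:
    """Vascular-support multiplier A_min + (1 - A_min) * hill(c_driver)."""
    if p.driver_cytokine_id not in state.values:
        raise KeyError(
            f"angiogenesis driver {p.driver_cytokine_id!r} not in state")
    h = hill_response(state.values[p.driver_cytokine_id], p.K_A, p.n_A)
    return p.A_min + (1.0 - p.A_min) * h


# ---------------------------------------------------------------------------
# compiled model


@dataclass
class ParamSet:
    """The numeric parameters the RHS consumes.  Copies of these arrays are
    what virtual-patient profiles and therapy interventions rescale."""
    prolif: np.ndarray        # per cell, 1/day
    cell_decay: np.ndarray    # per cell, 1/day
    conv_rate: np.ndarray     # per conversion, 1/day
    prod_rate: np.ndarray     # per producer entry, pg/cell/day
    cyt_decay: np.ndarray     # per cytokine, ln2/half_life, 1/day
    e_K: np.ndarray           # per edge half-saturation
    K_A: float

    def copy(self) -> "ParamSet":
        return ParamSet(self.prolif.copy(), self.cell_decay.copy(),
                        self.conv_rate.copy(), self.prod_rate.copy(),
                        self.cyt_decay.copy(), self.e_K.copy(), self.K_A)


@dataclass
class CompiledModel:
    """Index-array form of a validated :class:`NetworkSpec`."""
    spec: NetworkSpec
    species_ids: list[str]
    n_cells: int
    n_cyt: int
    cbar: np.ndarray
    angio_gated: np.ndarray           # bool per cell
    crowding: np.ndarray              # bool per cell: occupies shared space
    conv_src: np.ndarray              # species index
    conv_dst: np.ndarray
    conv_keys: list[tuple[str, str]]  # (dest cell id, conversion id)
    prod_cell: np.ndarray             # species index of producing cell
    prod_cyt: np.ndarray              # cytokine index (0-based within cytokines)
    # edges
    e_src: np.ndarray                 # species index of source cytokine
    e_n: np.ndarray
    e_a: np.ndarray
    e_up: np.ndarray                  # 1 up / 0 down
    e_slot_type: np.ndarray
    e_slot_idx: np.ndarray
    angio_driver: int                 # species index of driver cytokine
    A_min: float
    n_A: float
    base: ParamSet
    # param-id bookkeeping for profiles/sensitivity
    prod_param: dict[str, np.ndarray] = field(default_factory=dict)
    receptor_param: dict[str, np.ndarray] = field(default_factory=dict)
    receptor_param_angio: dict[str, bool] = field(default_factory=dict)

    @property
    def n_species(self) -> int:
        return self.n_cells + self.n_cyt

    @property
    def n_conv(self) -> int:
        return len(self.conv_keys)

    def index(self, sid: str) -> int:
        return self.species_ids.index(sid)

    def initial_state(self) -> np.ndarray:
        return np.array([s.initial_concentration for s in self.spec.species])

    def tunable_parameters(self) -> list[str]:
        return self.spec.tunable_parameters()

    # -- factor machinery ---------------------------------------------------

    def edge_factors(self, y: np.ndarray, p: ParamSet) -> np.ndarray:
        """Per-edge multiplicative Hill factors at state y."""
        c = np.maximum(y[self.e_src], 0.0)
        with np.errstate(over="ignore", invalid="ignore"):
            r = (c / p.e_K) ** self.e_n
            h = np.where(np.isinf(r), 1.0, r / (1.0 + r))
        return np.where(self.e_up == 1,
                        1.0 + (self.e_a - 1.0) * h,
                        1.0 - (1.0 - self.e_a) * h)

    def factors(self, y: np.ndarray, p: Optional[ParamSet] = None) -> dict:
        """Aggregate modulation factors per process slot (debug/audit view)."""
        p = p or self.base
        ef = self.edge_factors(y, p)
        out = {
            "prolif": np.ones(self.n_cells),
            "cell_decay": np.ones(self.n_cells),
            "conversion": np.ones(self.n_conv),
            "secretion_cyt": np.ones(self.n_cyt),
            "secretion_pair": np.ones(len(self.prod_cell)),
            "cyt_decay": np.ones(self.n_cyt),
            "recruit": np.ones(self.n_cells),
        }
        keys = ["prolif", "cell_decay", "conversion", "secretion_cyt",
                "secretion_pair", "cyt_decay", "recruit"]
        for k in range(len(ef)):
            np.multiply.at(out[keys[self.e_slot_type[k]]],
                           self.e_slot_idx[k], ef[k])
        return out

    def angiogenesis(self, y: np.ndarray, p: Optional[ParamSet] = None) -> float:
        p = p or self.base
        c = max(float(y[self.angio_driver]), 0.0)
        r = (c / p.K_A) ** self.n_A
        h = 1.0 if math.isinf(r) else r / (1.0 + r)
        return self.A_min + (1.0 - self.A_min) * h

    def rhs(self, y: np.ndarray, p: Optional[ParamSet] = None) -> np.ndarray:
        """Time derivative of the full state (concentration units / day)."""
        p = p or self.base
        nc = self.n_cells
        y = np.maximum(y, 0.0)
        f = self.factors(y, p)
        # shared-niche cells compete for the common tissue volume; cells
        # outside the shared niche (motile immune cells) are limited only by
        # their own density (tiling)
        total = (y[:nc] * self.crowding).sum()
        occupied = np.where(self.crowding, total, y[:nc])
        L = np.maximum(0.0, 1.0 - occupied / self.cbar)
        A = self.angiogenesis(y, p)
        growth = p.prolif * f["prolif"] * L * y[:nc]
        growth = np.where(self.angio_gated, growth * A, growth)
        dy_cell = growth - p.cell_decay * f["cell_decay"] * y[:nc]
        flux = p.conv_rate * f["conversion"] * y[self.conv_src]
        np.subtract.at(dy_cell, self.conv_src, flux)
        np.add.at(dy_cell, self.conv_dst, flux)
        sec = (p.prod_rate * f["secretion_pair"] *
               f["secretion_cyt"][self.prod_cyt] * y[self.prod_cell])
        dy_cyt = -p.cyt_decay * f["cyt_decay"] * y[nc:]
        np.add.at(dy_cyt, self.prod_cyt, sec)
        return np.concatenate([dy_cell, dy_cyt])


def compile_model(spec: NetworkSpec) -> CompiledModel:
    """Validate a spec and build its index-array form."""
    check_valid(spec)
    cells = spec.cells
    cyts = spec.cytokines
    # canonical ordering: cells first, then cytokines, in spec order
    species_ids = [s.id for s in cells] + [s.id for s in cyts]
    sidx = {s: i for i, s in enumerate(species_ids)}
    nc = len(cells)

    cell_ids = [s.id for s in cells]
    cps = [spec.cell_params_for(cid) for cid in cell_ids]
    cbar = np.array([cp.saturating_concentration for cp in cps])
    angio_gated = np.array([cp.angiogenesis_gated for cp in cps])
    crowding = np.array([cp.crowding for cp in cps])
    prolif = np.array([cp.basal_proliferation_rate for cp in cps])
    cell_decay = np.array([cp.basal_decay_rate for cp in cps])

    conv_keys, conv_src, conv_dst, conv_rate = [], [], [], []
    for cp in cps:
        for cv in cp.conversions:
            conv_keys.append((cp.species_id, cv.id))
            conv_src.append(sidx[cv.source_species_id])
            conv_dst.append(sidx[cp.species_id])
            conv_rate.append(cv.basal_rate)

    cyt_ids = [s.id for s in cyts]
    kps = [spec.cytokine_params_for(cid) for cid in cyt_ids]
    prod_cell, prod_cyt, prod_rate = [], [], []
    pair_index = {}  # (cyt id, cell id) -> producer entry index
    for j, kp in enumerate(kps):
        for p in kp.producers:
            pair_index[(kp.species_id, p.cell_species_id)] = len(prod_cell)
            prod_cell.append(sidx[p.cell_species_id])
            prod_cyt.append(j)
            prod_rate.append(p.basal_secretion_rate)
    cyt_decay = np.array([math.log(2) / kp.half_life for kp in kps])

    e_src, e_K, e_n, e_a, e_up, e_st, e_si = [], [], [], [], [], [], []
    prod_param: dict[str, list] = {f"prod_{c}": [] for c in cyt_ids}
    for j, kp in enumerate(kps):
        for p in kp.producers:
            prod_param[f"prod_{kp.species_id}"].append(
                pair_index[(kp.species_id, p.cell_species_id)])
    receptor_param: dict[str, list] = {}
    for e in spec.edges:
        t = e.target
        if t.process == "proliferation":
            st, si = SLOT_PROLIF, cell_ids.index(t.species_id)
        elif t.process == "recruitment":
            st, si = SLOT_RECRUIT, cell_ids.index(t.species_id)
        elif t.process == "decay":
            if t.species_id in cell_ids:
                st, si = SLOT_CELL_DECAY, cell_ids.index(t.species_id)
            else:
                st, si = SLOT_CYT_DECAY, cyt_ids.index(t.species_id)
        elif t.process == "conversion":
            st, si = SLOT_CONVERSION, conv_keys.index(
                (t.species_id, t.conversion_id))
        elif t.process == "secretion":
            if t.cell_id is None:
                st, si = SLOT_SECRETION_CYT, cyt_ids.index(t.cytokine_id)
            else:
                st, si = SLOT_SECRETION_PAIR, pair_index[
                    (t.cytokine_id, t.cell_id)]
        else:  # pragma: no cover - validated earlier
            raise ValueError(t.process)
        k = len(e_src)
        e_src.append(sidx[e.source_cytokine_id])
        e_K.append(e.hill.K)
        e_n.append(e.hill.n)
        e_a.append(e.hill.a)
        e_up.append(1 if e.direction == "up" else 0)
        e_st.append(st)
        e_si.append(si)
        if e.receptor_scale_param_id:
            receptor_param.setdefault(e.receptor_scale_param_id, []).append(k)

    ang = spec.angiogenesis
    receptor_param_angio = {}
    if ang.receptor_scale_param_id:
        receptor_param.setdefault(ang.receptor_scale_param_id, [])
        receptor_param_angio[ang.receptor_scale_param_id] = True

    base = ParamSet(
        prolif=prolif, cell_decay=cell_decay,
        conv_rate=np.array(conv_rate, dtype=float),
        prod_rate=np.array(prod_rate, dtype=float),
        cyt_decay=cyt_decay,
        e_K=np.array(e_K, dtype=float),
        K_A=ang.K_A,
    )
    return CompiledModel(
        spec=spec, species_ids=species_ids, n_cells=nc, n_cyt=len(cyts),
        cbar=cbar, angio_gated=angio_gated, crowding=crowding,
        conv_src=np.array(conv_src, dtype=np.int64),
        conv_dst=np.array(conv_dst, dtype=np.int64),
        conv_keys=conv_keys,
        prod_cell=np.array(prod_cell, dtype=np.int64),
        prod_cyt=np.array(prod_cyt, dtype=np.int64),
        e_src=np.array(e_src, dtype=np.int64),
        e_n=np.array(e_n, dtype=float), e_a=np.array(e_a, dtype=float),
        e_up=np.array(e_up, dtype=np.int64),
        e_slot_type=np.array(e_st, dtype=np.int64),
        e_slot_idx=np.array(e_si, dtype=np.int64),
        angio_driver=sidx[ang.driver_cytokine_id],
        A_min=ang.A_min, n_A=ang.n_A, base=base,
        prod_param={k: np.array(v, dtype=np.int64)
                    for k, v in prod_param.items()},
        receptor_param={k: np.array(v, dtype=np.int64)
                        for k, v in receptor_param.items()},
        receptor_param_angio=receptor_param_angio,
    )


def assemble_rhs(spec: NetworkSpec, patient=None) -> Callable:
    """Build the derivative function (y, t) -> dy/dt for a validated spec.

    ``patient`` is an optional :class:`~gliomanet.patients.PatientProfile`;
    its multipliers are folded into the effective parameters.
    """
    model = compile_model(spec)
    if patient is not None:
        from .patients import apply_profile
        params = apply_profile(model, patient)
    else:
        params = model.base
    def rhs(y, t=0.0):
        return model.rhs(np.asarray(y, dtype=float), params)
    rhs.model = model
    rhs.params = params
    return rhs


# ---------------------------------------------------------------------------
# trajectories and integration


@dataclass
class Trajectory:
    """Time course of all species, with provenance metadata."""
    times: np.ndarray                 # days, strictly increasing
    values: np.ndarray                # (n_times, n_species)
    species_ids: list[str]
    metadata: dict = field(default_factory=dict)

    def species(self, sid: str) -> np.ndarray:
        return self.values[:, self.species_ids.index(sid)]

    def state_at(self, i: int) -> StateVector:
        return StateVector(time=float(self.times[i]),
                           values=dict(zip(self.species_ids, self.values[i])))

    def to_frame(self):
        import pandas as pd
        df = pd.DataFrame(self.values, columns=self.species_ids)
        df.insert(0, "time_days", self.times)
        return df

    def to_csv(self, path, sidecar: bool = True) -> None:
        """Write the trajectory CSV plus a metadata sidecar (same basename,
        .meta.yaml) sufficient to re-run it."""
        from pathlib import Path
        import yaml
        path = Path(path)
        self.to_frame().to_csv(path, index=False, float_format="%.10g")
        if sidecar:
            side = path.with_suffix(".meta.yaml")
            with open(side, "w") as fh:
                yaml.safe_dump(self.metadata, fh, sort_keys=True)

    def first_crossing(self, sid: str, threshold: float) -> Optional[float]:
        """Linearly interpolated first upward crossing time, or None."""
        return _first_crossing(self.times, self.species(sid), threshold)


def _first_crossing(t: np.ndarray, x: np.ndarray,
                    threshold: float) -> Optional[float]:
    if x[0] >= threshold:
        return float(t[0])
    above = np.nonzero(x >= threshold)[0]
    if len(above) == 0:
        return None
    i = above[0]
    x0, x1 = x[i - 1], x[i]
    if x1 == x0:
        return float(t[i])
    frac = (threshold - x0) / (x1 - x0)
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


class IntegrationError(RuntimeError):
    pass


def integrate_deterministic(rhs, state0, t_span: float,
                            method: str = "dp5",
                            step: float = 0.01,
                            rtol: float = 1e-8,
                            save_every: float = 0.25,
                            species_ids: Optional[list[str]] = None,
                            ) -> Trajectory:
    """Integrate the deterministic system over [0, t_span] days.

    ``method`` is "dp5" (adaptive Dormand-Prince via scipy RK45), "rk4"
    (classic fixed-step Runge-Kutta) or "euler" (fixed-step forward Euler,
    the scheme shared with the stochastic engine).  State components are
    clipped at zero; an integrator undershoot is logged as a warning, not a
    failure.  ``rhs`` may come from :func:`assemble_rhs` or be any
    ``f(y, t)``; in the latter case pass ``species_ids``.
    """
    import logging
    log = logging.getLogger(__name__)
    if t_span <= 0:
        raise ValueError("t_span must be positive")
    if species_ids is None:
        if hasattr(rhs, "model"):
            species_ids = rhs.model.species_ids
        else:
            raise ValueError("species_ids required for a bare rhs callable")
    y0 = np.asarray(state0, dtype=float)
    if np.any(y0 < 0):
        raise ValueError("initial state must be non-negative")

    meta = {"integrator": method, "t_span": float(t_span)}
    if hasattr(rhs, "model"):
        meta["spec_hash"] = spec_hash(rhs.model.spec)
    undershoot = False

    if method == "dp5":
        from scipy.integrate import solve_ivp
        t_eval = np.arange(0.0, t_span + 1e-12, save_every)
        if t_eval[-1] < t_span:
            t_eval = np.append(t_eval, t_span)
        sol = solve_ivp(lambda t, y: rhs(np.maximum(y, 0.0), t),
                        (0.0, t_span), y0, method="RK45",
                        t_eval=t_eval, rtol=rtol, atol=1e-12 * max(1.0, y0.max()))
        if not sol.success:
            raise IntegrationError(
                f"adaptive step failed at t={sol.t[-1]:.4g}: {sol.message}")
        vals = sol.y.T
        undershoot = bool(np.any(vals < 0))
        vals = np.maximum(vals, 0.0)
        times = sol.t
        meta["rtol"] = rtol
    elif method in ("rk4", "euler"):
        n_steps = int(round(t_span / step))
        stride = max(1, int(round(save_every / step)))
        times = [0.0]
        vals = [y0.copy()]
        y = y0.copy()
        t = 0.0
        for k in range(n_steps):
            if method == "rk4":
                k1 = rhs(y, t)
                k2 = rhs(np.maximum(y + 0.5 * step * k1, 0.0), t + 0.5 * step)
                k3 = rhs(np.maximum(y + 0.5 * step * k2, 0.0), t + 0.5 * step)
                k4 = rhs(np.maximum(y + step * k3, 0.0), t + step)
                y = y + (step / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            else:
                y = y + step * rhs(y, t)
            if np.any(y < 0):
                undershoot = True
                y = np.maximum(y, 0.0)
            if np.any(~np.isfinite(y)):
                raise IntegrationError(f"non-finite state at t={t + step:.4g}")
            t = (k + 1) * step
            if (k + 1) % stride == 0 or k == n_steps - 1:
                times.append(t)
                vals.append(y.copy())
        times = np.array(times)
        vals = np.array(vals)
        meta["step"] = step
    else:
        raise ValueError(f"unknown method {method!r}")

    if undershoot:
        log.warning("integrator undershoot below zero; clipped to 0")
    meta["seed"] = "deterministic"
    return Trajectory(times=np.asarray(times, dtype=float), values=vals,
                      species_ids=list(species_ids), metadata=meta)


# ---------------------------------------------------------------------------
# phase detection


@dataclass
class PhaseReport:
    """Milestones of the three-phase glioma growth curve.

    Times are days; fields are None when the corresponding crossing never
    happens within the simulated horizon.
    """
    activation_complete_time: Optional[float]
    detection_crossing_time: Optional[float]
    saturation_time: Optional[float]
    plateau_level: float
    rapid_onset_time: Optional[float] = None
    phase_windows: dict = field(default_factory=dict)


def detect_phases(traj: Trajectory,
                  detection_threshold: float = DETECTION_THRESHOLD,
                  gc_id: str = "GC", qsc_id: str = "QSC") -> PhaseReport:
    """Locate the pre-tumor, rapid-expansion and malignant phases.

    Activation is complete when the quiescent stem pool first falls to 5% of
    its initial size; detection is the interpolated first upward crossing of
    the glioma density past ``detection_threshold``; the plateau level is the
    median glioma density over the trailing 10% of the horizon, and
    saturation is the first time the density reaches 95% of it.  The rapid
    expansion phase is taken to start when the density reaches 5% of the
    plateau.
    """
    t = traj.times
    gc = traj.species(gc_id) if gc_id in traj.species_ids else None
    act = None
    if qsc_id in traj.species_ids:
        qsc = traj.species(qsc_id)
        if qsc[0] > 0:
            drop = np.nonzero(qsc <= 0.05 * qsc[0])[0]
            if len(drop):
                act = float(t[drop[0]])
    if gc is None:
        return PhaseReport(act, None, None, 0.0)
    tail = gc[t >= t[-1] - 0.1 * (t[-1] - t[0])]
    plateau = float(np.median(tail)) if len(tail) else float(gc[-1])
    detection = _first_crossing(t, gc, detection_threshold)
    saturation = _first_crossing(t, gc, 0.95 * plateau) if plateau > 0 else None
    rapid = _first_crossing(t, gc, 0.05 * plateau) if plateau > 0 else None
    windows = {}
    if rapid is not None:
        windows["pre_tumor"] = (0.0, rapid)
        end = saturation if saturation is not None else float(t[-1])
        windows["rapid_expansion"] = (rapid, end)
        if saturation is not None:
            windows["malignant"] = (saturation, float(t[-1]))
    return PhaseReport(
        activation_complete_time=act,
        detection_crossing_time=detection,
        saturation_time=saturation,
        plateau_level=plateau,
        rapid_onset_time=rapid,
        phase_windows=windows,
    )
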