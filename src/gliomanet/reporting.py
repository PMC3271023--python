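"""Trace classification and tabular reporting helpers.

The cytokine time courses of the calibrated model fall into three temporal
classes: an early peak followed by decline (immune-activation mediators
suppressed once the immunosuppressive milieu builds up), a monotone
increase spread across the whole year (mediators tracking the steadily
rising microglia pool), and phase-correlated traces that surge with the
rapid-expansion phase and then level off with the tumor.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .stochastic import EnsembleResult

__all__ = ["classify_cytokine_traces", "cytokine_class_table"]

EARLY_PEAK = "early-peak"
MONOTONE = "monotone-increase"
PHASE_CORRELATED = "phase-correlated"


def classify_cytokine_traces(ensemble: EnsembleResult,
                             cytokine_ids=None,
                             gc_id: str = "GC",
                             decline_tolerance: float = 0.10,
                             monotone_tolerance: float = 0.05,
                             rapid_fraction_max: float = 0.45,
                             ) -> dict[str, str]:
    """Assign each cytokine's ensemble-mean trace to a temporal class.

    early-peak: the global maximum precedes the detection crossing and the
    trace then declines by at least ``decline_tolerance`` of its peak.
    monotone-increase: non-decreasing within ``monotone_tolerance`` of the
    peak, with at most ``rapid_fraction_max`` of its total rise inside the
    rapid-expansion window (the increase is spread over the whole horizon).
    phase-correlated: everything else (rapid rise during expansion, then
    quasi-steady).  Thresholds are calibration choices and configurable.
    """
    t = ensemble.times
    gc = ensemble.summary[gc_id]["mean"]
    tail = gc[t >= t[-1] - 0.1 * (t[-1] - t[0])]
    plateau = float(np.median(tail)) if len(tail) else float(gc[-1])
    det = ensemble.endpoints["detection_crossing_days"].astype(float).median()
    if not np.isfinite(det):
        det = t[-1]
    rapid_on = _first_time(t, gc, 0.05 * plateau)
    rapid_off = _first_time(t, gc, 0.95 * plateau)
    out = {}
    if cytokine_ids is None:
        # by convention the state vector orders cells first; fall back to
        # classifying everything that is not the glioma readout
        cytokine_ids = [s for s in ensemble.species_ids if s != gc_id]
    for sid in cytokine_ids:
        stats = ensemble.summary[sid]
        x = stats["mean"]
        peak = x.max()
        if peak <= 0:
            continue
        ipk = int(np.argmax(x))
        if t[ipk] < det and x[-1] <= (1.0 - decline_tolerance) * peak:
            out[sid] = EARLY_PEAK
            continue
        nondecr = bool(np.all(np.diff(x) >= -monotone_tolerance * peak))
        frac = _rapid_rise_fraction(t, x, rapid_on, rapid_off)
        if nondecr and frac <= rapid_fraction_max:
            out[sid] = MONOTONE
        else:
            out[sid] = PHASE_CORRELATED
    return out


def _first_time(t, x, threshold) -> Optional[float]:
    idx = np.nonzero(x >= threshold)[0]
    return float(t[idx[0]]) if len(idx) else None


def _rapid_rise_fraction(t, x, rapid_on, rapid_off) -> float:
    inc = np.diff(x)
    pos = np.clip(inc, 0.0, None)
    total = pos.sum()
    if total <= 0 or rapid_on is None:
        return 0.0
    hi = rapid_off if rapid_off is not None else t[-1]
    win = (t[1:] >= rapid_on) & (t[1:] <= hi)
    return float(pos[win].sum() / total)


def cytokine_class_table(ensemble: EnsembleResult, cytokine_ids=None):
    """Classification as a tidy DataFrame (cytokine, temporal_class)."""
    import pandas as pd
    classes = classify_cytokine_traces(ensemble, cytokine_ids=cytokine_ids)
    return pd.DataFrame(
        [{"cytokine": k, "temporal_class": v} for k, v in classes.items()])
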