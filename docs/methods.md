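# Methods

## Model

`gliomanet` simulates the co-evolution of a brain-tumor microenvironment in
a well-mixed 1-ml control volume. The state is a 20-component vector: five
cell populations — quiescent stem-like cells (QSC), activated stem-like
cells (ASC), glioma cells (GC), astrocytes and microglia, in cells/ml —
and fifteen soluble mediators (IL-1β, IL-6, IL-10, TGF-β, TNF-α, PGE2,
G-CSF, GM-CSF, EGF, FGF, VEGF, HGF, SCF, MIF, MMP-9, in pg/ml).

Each cell population `i` follows population dynamics

    dc_i/dt = Σ conversions in − Σ conversions out
              + f_i · Π_j M_j(x) · L_i · A(x) · c_i      (proliferation)
              − d_i · Π_k M_k(x) · c_i                   (decay)

where `f_i` and `d_i` are basal proliferation and decay rates (1/day),
conversions are first-order cell-state changes (QSC⇄ASC activation and
deactivation, ASC→GC differentiation, astrocyte→GC neoplastic
transformation), and each `M(x)` is a multiplicative Hill modulation by
one cytokine:

    up:   M = 1 + (a − 1) · h(c; K, n)      in [1, a]
    down: M = 1 − (1 − a) · h(c; K, n)      in (a, 1]
    h(c; K, n) = c^n / (K^n + c^n)

Modulations compose multiplicatively across the edges that target the same
process, so each of the 69 pathway edges of the default network is
independently ablatable. `L_i = max(0, 1 − occupied/c̄_i)` is logistic
crowding and `A(x) = A_min + (1 − A_min)·h(c_VEGF; K_A, n_A)` is an
angiogenesis (vascular support) factor applied to angiogenesis-gated cells
(GC in the default network).

Each cytokine `x_j` follows

    dx_j/dt = Σ_producers s_p · Π M(x) · c_p − (ln 2 / τ_j) · Π M(x) · x_j

with basal secretion rates `s_p` (pg/cell/day) and half-life `τ_j` (days).
Secretion-modulation edges (e.g. MIF and TNF-α up-regulating VEGF
secretion, IL-10 and TGF-β suppressing TNF-α secretion) multiply every
production term of the targeted cytokine.

### Crowding niches

The shared crowding total covers the glial-niche populations (QSC, ASC,
GC, astrocytes); glioma growth displaces astrocytes through this shared
space. Microglia are motile immune cells that do not occupy the glial
parenchymal niche: their logistic term is an own-density ("tiling") limit
`1 − c_microglia/c̄_microglia`. This distinction matters for therapy:
if microglia counted toward the shared total, depleting them would free
tissue capacity and *accelerate* late-stage tumors, inverting the
stage-dependence of depletion therapy. With the tiling niche, the
late-stage no-response emerges correctly from signal saturation alone.

## Stochastic layers

Three noise sources, all driven by numpy's PCG64 with per-run seeds derived
from a master seed via `SeedSequence(master, spawn_key=(run,))`:

1. **Truncated Gaussian white noise on production constants.** Every
   cytokine's secretion rate is multiplied by `clip(1 + σξ, lo, hi)` with
   ξ ~ N(0,1) redrawn on a fixed refresh interval of 0.25 day (default
   σ = 0.1, bounds [0, 2]). The fixed refresh time—rather than redrawing
   every integration step—keeps the effective noise intensity independent
   of the step size; with per-step resampling the detection timing drifted
   by about a month between dt = 0.02 and dt = 0.01.
2. **Bounded (sine-Wiener) noise on proliferation and conversion rates.**
   The perturbation is z = sin θ with dθ = √(2/τ_n) dW (default σ = 0.1
   for proliferation, 0.2 for conversions, τ_n = 5 days), applied as
   `rate·(1 + σz)`; z never leaves [−1, 1] and its stationary law is the
   arcsine distribution.
3. **Non-homogeneous Poisson jumps** for discrete low-count events:
   chemoattractant-driven microglia immigration (rate modulated by the
   GM-CSF/VEGF/HGF recruitment edges) and stochastic stem-cell
   activation/differentiation events. Event magnitudes are
   1 + Poisson(m − 1) cells, converted to concentration through the 1-ml
   control volume. Per integration step the event count is drawn by CDF
   inversion of Poisson(λ·dt); the standalone `poisson_event_count` uses
   thinning against a supplied λ_max.

Integration is fixed-step Euler–Maruyama (default dt = 0.01 day) in a
numba-compiled kernel; all random numbers are pregenerated per run and
consumed by step index, so trajectories are bit-reproducible and a run can
be paused at a therapy trigger and resumed without disturbing the stream.
A pure-numpy right-hand side drives the deterministic integrators
(classic RK4, adaptive Dormand–Prince via scipy's RK45, and forward Euler;
the Euler option exists so the σ→0, no-jump stochastic path can be checked
against an identically discretized ODE at 1e−9 tolerance). Negative
excursions are clipped to zero and logged rather than aborting the run.

## Default calibration

The shipped network (data file `glioma_default.yaml`, editable and
revalidated on load) starts from the normal-brain state — astrocytes
2.8×10⁷/ml, microglia 2×10⁶/ml, QSC 1×10⁴/ml, no glioma cells — and is
calibrated so the untreated course reproduces the canonical disease
timeline:

* QSC→ASC activation completes inside the first month (activation rate
  0.02/day, up-modulated by TNF-α, IL-1β, MIF, SCF, EGF and FGF).
* Glioma cells appear through ASC differentiation (plus a very small
  direct astrocyte transformation term), stay below the clinical
  detection threshold of 1×10⁶/ml for months, cross it at a median of
  about month 8–9, and approach a plateau near 1.5–1.8×10⁷/ml as the
  shared niche fills and astrocytes are displaced.
* Microglia rise steadily from 2×10⁶ toward ~4×10⁶/ml, tracking the
  tumor-derived chemokines, with an inflection at expansion onset.
* The survival proxy — time from 1×10⁶ to 1.5×10⁷ glioma cells/ml — is
  1.3–1.6 months untreated.

Cytokine groups play distinct mechanistic roles:

* **Autocrine growth drivers** (IL-6, VEGF, HGF, MIF; K = 1 pg/ml, n = 1,
  fold-change 1.8–2.0, glioma-dominated secretion): saturated through most
  of the course, which is why single-target blockade achieves little while
  the four-way combination, which keeps the network below saturation for
  the whole window, is synergistic. VEGF additionally drives the
  angiogenesis factor.
* **Paracrine priming factors** (G-CSF, SCF, TGF-β up-regulating
  proliferation; EGF and FGF suppressing apoptosis; K ≈ 1.7–2.2 pg/ml,
  n = 4, secreted by microglia with a smaller glioma share): their steep
  Hill responses sit just above the microglia-derived baseline. Depleting
  microglia early collapses them below threshold and the nascent tumor
  regresses or stalls; at middle stage the partially built autocrine share
  keeps growth barely positive (months-long postponement); by detection
  the glioma's own secretion saturates them and depletion is inert.
* **Immune-axis mediators** (IL-1β from astrocytes; TNF-α from microglia,
  suppressed by IL-10 and TGF-β so it peaks at the end of the pre-tumor
  phase; monotone IL-10 and PGE2 from the steadily growing microglia
  pool; MMP-9 as a produced but non-signaling readout).

The trace classifier separates these classes on the ensemble mean:
early-peak (maximum before detection, ≥10% decline), monotone-increase
(non-decreasing within 5% of peak and at most 45% of the total rise
inside the rapid-expansion window — the midpoint of the empirical gap
between the microglia-tracking and tumor-tracking clusters), and
phase-correlated otherwise. All three thresholds are arguments.

## Virtual patients and sensitivity analysis

A virtual patient is a vector of 29 positive multipliers: one production
multiplier per cytokine (15) and one receptor-expression multiplier per
signaling cytokine (14; MMP-9 has no modeled receptor). Receptor
expression scales every half-saturation constant of that cytokine's edges
as K/m. Profiles are drawn log-uniformly from [0.5, 2] per parameter;
roughly a third of such draws do not produce a detectable tumor within a
year, which we read as cohort-level heterogeneity in tumorigenesis rather
than a defect. The three shipped fixture patients are fixed-seed draws
screened to span the reported response phenotypes (combination responder /
modest responder / non-responder); they are synthetic reconstructions, not
published profiles.

Sensitivity factors are normalized central finite differences of the
ensemble survival proxy,

    S_i = [F(x_i(1+δ)) − F(x_i(1−δ))] / (2 δ F(x⁰)),   δ = 0.1,

with common random numbers across the three ensembles and the standard
error taken over per-run paired difference quotients. When the tumor never
reaches the window start the code falls back to tumorigenesis time and
records the switch per entry. Because every effect of a cytokine passes
through level/K ratios, the production and receptor channels of one
cytokine are *locally identical* perturbations and their sensitivities
coincide pairwise; `design_combination` therefore targets each cytokine at
most once (most-negative first, ties by |S| then lexicographic id). On the
default calibration the strongest negative factors belong to the
stroma-remodeling axis (TGF-β, TNF-α, IL-1β — acting through astrocyte
displacement and stem-cell activation as much as through direct glioma
growth), a systems-level effect that a per-pathway reading would miss.

## Therapy engine

Plans pair triggers (first upward crossing of a species density, or a
fixed day) with interventions: apoptosis multipliers on a cell population,
production inhibition/enhancement or receptor blockade of a cytokine.
Interventions are permanent by default; a finite duration arms a follow-up
segment that applies the inverse factor. Factors compose multiplicatively,
so stacking a then b equals a single a·b intervention. Treated and control
runs share the pregenerated random stream of the same seed, so outcome
differences are attributable to therapy alone; with factor-1 interventions
the treated CSV is bitwise identical to the control.

The benefit metric follows the trigger stage: for therapy administered
before clinical detection the postponement of the detection crossing, and
for therapy at/after detection the gain in the survival proxy; crossings
that never occur within the horizon are censored at the horizon and
flagged. Months are days/30.4 throughout.

## Problem sizes and numerical choices

Default ensembles use dt = 0.01 day over 365 days; therapy and sensitivity
examples use dt = 0.02 where the halved cost matters, which changes
ensemble medians by about a percent (halving dt from the default changes
the ensemble-mean glioma density at day 365 by <2%). Acceptance-level
checks use 50 replicates for the untreated course and 8–12 paired
replicates per therapy arm; sensitivity profiles use 3 seed-paired
replicates per evaluation point. Cytokines start at zero and relax to
quasi-steady state within days; crossing times are linearly interpolated
between saved samples (default save interval 0.25 day).

## What the generator does and does not emulate

The synthetic dynamics reproduce the qualitative architecture of glioma
progression — three growth phases, stem-cell-driven initiation,
microglia–glioma mutual reinforcement, stage-dependent therapy response,
inter-patient heterogeneity — under a literature-shaped but ultimately
invented parameterization: the quantitative rate table behind the original
study is not public, so every rate here was chosen to match printed
population-level milestones, not measured kinetics. Passing tests
therefore demonstrate internal consistency of the model and faithfulness
to the reported phenomenology, not predictive accuracy for real patients.
There is no spatial structure (a single well-mixed compartment), no
pharmacokinetics (interventions are step changes in rates), no immune
compartment beyond microglia, and no mutation/clonal evolution within the
glioma population.

## Known limitations

* The middle-stage depletion response sits near a dynamical watershed
  (stall vs escape); its postponement distribution is bimodal and
  patient-profile dependent.
* Local sensitivities of strongly saturated parameters are near zero even
  when a 10-fold intervention on the same parameter is effective; local
  rankings and global interventions answer different questions.
* The 69-edge roster reconstructs interactions named in the primary
  literature and pads with standard glioma signaling axes; individual
  edges are hypotheses, shipped as data precisely so they can be edited.
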