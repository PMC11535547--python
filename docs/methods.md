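# Methods

This note records the modeling assumptions behind `arthrosim`, the
provenance of its defaults, the numerical choices, and what the test
suite does and does not demonstrate.

## Scope and assumptions

The model represents *established, stable* RA disease in a well-mixed
1 mL synovial volume over trial time scales (weeks to months).  Cells
are assumed mature, differentiated and activated; disease onset,
flares, long-term progression, bone and cartilage compartments, lymph
nodes, cell–cell contact effects and spatial structure are out of
scope.  Autoantigen is assumed non-limiting.  The serum compartment
exists only as the source of immune-cell influx and as the PK
compartment for drugs; serum cytokines are not matched.  All rates
are per day; densities are cells/mL, mediator concentrations ng/mL,
drug concentrations mg/L.

Proliferation and influx are zeroth-order in the cell's own density
(a crowded, growth-restricted environment that admits a stable steady
state against first-order death); death and mediator clearance are
first order.  FLS, being structural, have no influx.  B cells feed a
first-order differentiation flux into plasma cells, up-regulated by
IL-6.

## Regulation

Every life-cycle and secretion rate is multiplied by
`(1 + ProRate)(1 − AntiRate)`, where each term is a sum of Hill
functions of the regulating mediators, capped after summation at
`Prolimit = 10` and `Antilimit = 0.75` (the caps apply to the sums,
not to individual terms).  The 0.9-anti-cap arithmetic (0.1× baseline)
is reproduced only under an explicitly configured `CapPolicy`.
Essential cofactors are gates, not fold-changes: IFN-γ secretion by
Th1 carries a multiplicative Hill gate in IL-12 and vanishes without
it.  Edges are summed in canonical order (regulator, then name) so
results are bit-reproducible regardless of specification order.

### Edge parameter defaults

The 95 published `*_Maxby*` bounds define the sampling range of each
edge's maximal fold effect; the default (reference) value is the
geometric midpoint of that range.  Collective names expand to edge
groups sharing one parameter: `TCell` → {Th1, Th17, CTL}, `Lympho`
adds Treg and B cells, `Leuko` covers all immune cells with influx.
A nested qualifier (`RANTESSecFLS_byTNFa_MaxbyIFNg`) is treated as an
additional regulator of the same secretion term.

Two pieces of wiring are not printed anywhere and are curated here:

* **Signs.**  IL-10 and TGF-β act as suppressors of pro-inflammatory
  proliferation and secretion (with literature exceptions: IL-10
  promotes B-cell proliferation; TGF-β promotes Treg proliferation,
  FLS proliferation, VEGF induction and monocyte/endothelial
  recruitment).  Apoptosis edges are survival signals (anti-death)
  where the regulator is a known survival factor for that cell —
  BAFF for B cells, IL-6 for T/plasma cells, IL-12 for Th1,
  TNF-α/IFN-γ/GM-CSF for macrophages, VEGF for endothelium — and
  death signals for TNF-α on endothelium and TGF-β on CTL.
* **Secretion topology.**  Which cells secrete which mediators, with
  reference shares (macrophages dominate TNF-α and are the sole
  source of IL-12/IL-23; FLS dominate IL-6 and the chemokines; Th17
  dominates IL-17; Th1 dominates IFN-γ; Tregs dominate IL-10/TGF-β;
  plasma cells dominate autoantibody).

Half-max concentrations (`Km`) are placed at the *median
concentration the plausible cohort actually reaches* under the
default wiring, stored as per-mediator multipliers of the range
midpoint (`network.KM_PLACEMENT`, fixed once from a pilot cohort).
Cell-range-constrained steady states sit far from naive range
midpoints for mediators secreted by cells with wide density ranges
(IL-17 ≈ 300×), and a Km orders of magnitude below the operating
concentration would leave every edge saturated and the network inert
to therapy.  The default Hill slope is 2 — matching the
cooperativity of the calibrated MTX effect triple — because with
slope 1 a therapy-induced one-to-two-log drop in a regulator barely
moves its Hill term, and the cohort then contains essentially no deep
responders, contradicting the trial response rates the population is
calibrated against.  Both choices are configurable per edge through
the network JSON.

### CAM

CAM is algebraic: `CAM = F_CAM · cam_max · H(Endo)` with the Hill
half-max at the endothelial range midpoint and `cam_max` chosen so
CAM sits at its own range midpoint there.  The functional form is a
config-exposed choice.

## Rate constants

Cell death rates (1/day): Th1 0.65 — the activation-induced-cell-
death conversion `ln(100/(100 − %apoptosis))/duration` applied to 15 %
apoptosis in 6 h — with the other cell types placed once inside the
few-hours-to-few-days half-life window (FLS 0.05, endothelium 0.069,
macrophages 0.23, Th17/CTL 0.65, Treg 0.46, B cells 0.35, plasma
cells 0.14), slower for structural and long-lived cells.  Mediator
clearances correspond to half-lives of tens of minutes to a few hours
(5.5–24 per day), except the IgG-class autoantibody (0.35/day).

## Reference patient

The reference ("median") virtual patient targets the geometric
midpoint of every published cell and mediator range.  Rather than
iterating from decoupled closed forms, the regulation factors are
evaluated once *at the target state* and the baselines are back-solved
so that state is an exact equilibrium of the fully coupled system:
production splits 80 % proliferation / 20 % influx (proliferative
flux dominates in established disease; FLS all-proliferation), plasma
cells draw half their supply from B-cell differentiation, and each
mediator's clearance flux is apportioned across its secreting cells
by the reference shares.  With all regulation edges removed the same
construction reduces to the decoupled closed forms exactly.  The
baselines are re-derivations, not copies of any published patient,
and no claim of numerical identity with other implementations is
made.

## PK/PD

PK parameter values are standard published population values
(external-literature defaults, editable in config): MTX V1 20 L,
V2 15 L, CL 120 L/day, Q 30 L/day, F 0.7, 15 mg weekly; ADA V 5.5 L,
CL 0.30 L/day, ka 0.28/day, F 0.64, 40 mg SC Q2W; TCZ V1 3.5 L,
V2 2.9 L, CL 0.30 L/day, Q 0.85 L/day, 8 mg/kg IV Q4W at 70 kg body
weight.  Profiles are evaluated in closed form (superposition of
exponentials), so multi-dose linearity is exact.  Synovial drug is a
fixed partition (0.3) of the central concentration.  The MTX
"available" concentration multiplies central concentration by
bioavailability; its three effects share the calibrated (0.5,
1e-5 mg/L, 2) Hill triple and apply to pro-inflammatory secretion
(all cells but Tregs), Treg secretion (enhancement) and immune-cell
influx (endothelium excluded).  ADA binding happens in the synovium,
where TNF-α drives the network: regulators see the free TNF-α root of
the equilibrium quadratic (default KD 15 ng/mL, an effective
mass-unit constant).  TCZ scales IL-6 clearance by dividing it by
`KD/(TCZ + KD)` (default KD 0.4 mg/L); no explicit receptor species
exists.  The ACR/DAS outcome of a trial is read at the protocol's
readout week (MTX week 12, ADA and TCZ week 24) against the
treatment-naive baseline steady state.

## Cohort and Vpop workflow

Candidates are sampled log-uniformly within the 129 published bounds
(log-axis histograms motivate the law; it is config-exposed).
Plausibility requires a converged steady state, every cell density
inside its literature range and baseline DAS28-CRP > 3.2; mediator
ranges are advisory (counted, logged, never excluding) because cell
measurements come from inflamed tissue while cytokine measurements
often do not.

Because several sampled bounds span 2–4 decades while some density
windows span a fraction of one (endothelium: 0.3 decades), global
sampling alone yields under 1 % plausible patients; the workflow
therefore includes the enrichment stage of the published process:
re-sampling log-uniformly in boxes of `shrink × log-range` around
seed patients, clipped to the global bounds.  One broad round around
all plausible seeds is followed by targeted rounds around the
phenotypes the calibration targets require (severe disease, deep
responders per drug class, moderate-baseline IRs who reach low
disease activity on tocilizumab, mild-baseline IRs, severe all-class
non-responders).  Desk-scale defaults: 5 000 global candidates, 3 000
diversity children, 1 800 per phenotype, selection of 300; these
sizes are the package's working defaults and scale up freely.

Selection weights candidates by a histogram-matching importance ratio
on baseline DAS and refines a 300-patient subset by simulated
annealing with O(1) incremental objective updates, followed by a
zero-temperature polish.  The objective is a quadratic in the scaled
residuals of: baseline DAS mean and spread (overall, matched to the
adalimumab arm; over the MTX-IR subset, matched to the tocilizumab
arm), and each placebo-corrected endpoint fraction (tocilizumab
endpoints evaluated over the MTX-IR members).  Convergence requires
means within ±0.3 and endpoints within ±5 percentage points; the
spread is a soft term (scale 0.75) with its residual reported, since
no published tolerance accompanies it.  Infeasible targets return the
best-effort subset flagged not-converged together with the full
residual report.

One structural property deserves note: because ACR is defined as the
percent change of the modeled DAS28-CRP and every entrant has
baseline > 3.2, remission (post < 2.6) implies a > 18.75 % reduction,
so the remission fraction can never materially exceed the ACR20
fraction.  The published tocilizumab arms, after placebo correction,
place remission 10.4 points *above* ACR20; that pair of targets is
therefore jointly unreachable under this scoring assumption, and the
selector converges to the balanced frontier where the two residuals
split the gap (≈ ±5.2 points) while every other target is matched to
well under a point.

## Sensitivity analysis

The analyzed output is steady-state (pre-therapy) DAS28-CRP.  Local
analysis re-solves the steady state at 2× and 0.5× of each parameter
and reports percent score changes, tornado-sorted; non-converged
perturbations are flagged, never dropped.  Global analysis uses
Saltelli's radial scheme on scrambled Sobol' sequences over
log-transformed bounds, the Saltelli-2010 first-order and Jansen
total-order estimators, and bootstrap 95 % confidence half-widths;
the estimator is implemented in-package and validated against
analytic variance decompositions (additive linear function, Ishigami)
before use on the disease model.  Desk-scale base sample: 1 024
(general default), reduced in tests; failed runs are excluded with a
reported count.

## Numerical choices

Single-patient solves use LSODA with relative tolerance 1e-8 and
absolute tolerances 1e-3 cells/mL and 1e-9 ng/mL, split at dosing
discontinuities; steady state is declared when the scaled derivative
norm `max |dx/dt|/(|x| + atol)` falls below 1e-6/day.  Cohort-scale
work uses an exponential-Euler integrator vectorized across patients:
with `dx/dt = P(x) − L(x)·x` the update treats the first-order loss
exactly, is unconditionally stable for the fast cytokine clearances,
preserves positivity, and leaves any exact fixed point invariant.
Step sizes: 0.25 d for steady-state relaxation, 0.1 d for antibody
trials, 0.05 d for MTX (whose PK varies on a 6-hour scale); agreement
with the LSODA path is verified in the tests at 0.5 % relative.
States are floored at zero inside the right-hand side; the unfloored
dynamics are non-negative by construction (zeroth-order production,
first-order losses).

## What the synthetic fixtures do and do not show

`make_synthetic_selector_cohort` plants phenotypes with known
baseline-score distributions and response probabilities *without*
running the network, so selector tests verify parameter recovery
against exact ground truth; they say nothing about the realism of the
disease model itself.  Conversely, the plausibility and calibration
tests exercise the full mechanistic pipeline but against literature
summary statistics, not individual-patient data: passing them shows
the population-level statistics are reproducible, not that any single
virtual patient matches a real one.

## Known limitations

ACR is rigidly tied to percent DAS28-CRP change (see the frontier
note above); real trials measure the two on different clinical bases.
Binding calculations use effective mass-unit constants rather than
molar stoichiometry.  Drug-bound TNF-α is not explicitly cleared as a
complex.  PK defaults are population means without inter-individual
variability.  The sign and topology curation, while
literature-guided, is a modeling choice and can be overridden in the
network JSON.  A single average joint is modeled; no digital-twin or
multi-Vpop functionality is included.
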