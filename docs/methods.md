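# Methods

`icbsim` is a reduced quantitative systems pharmacology (QSP) model of
immune checkpoint blockade in metastatic breast cancer. It simulates how an
anti-CTLA-4 antibody (tremelimumab-like) and an anti-PD-L1 antibody
(durvalumab-like) perturb the tumour–immune feedforward loop, and reads the
outcome off the tumour diameter trajectory with RECIST conventions. This
note documents the model, its assumptions, the parameters that matter, the
numerical choices, and what the simulations can and cannot say about real
patients.

## Model structure

Four physiological compartments: central blood, peripheral tissue, the
tumour, and one lumped tumour-draining lymph node (TDLN) representing
`n_tdln` equivalent nodes (antibody amounts are per-node with the
appropriate multiplicity; lymphocyte pools are lumped totals). The tumour
volume used for antibody transport and T-cell trafficking is fixed at the
starting diameter; the cancer-cell count evolves freely. The full state is
42 named variables (`icbsim.STATE_NAMES`), in five groups:

1. **Cancer cells**, split into four checkpoint-expression subtypes
   (PD-L1−/PD-L2−, PD-L1+/−, −/PD-L2+, double-positive) by treating the
   patient's PD-L1 and PD-L2 expression fractions as independent
   probabilities. Growth is exponential at `ln 2 / doubling_time` with a
   logistic cap (default 1e13 cells, never reached in the studied
   scenarios). Killing distributes the effector cytotoxic capacity
   `k_kill · Teff` over subtypes by abundance, saturating at low burden
   (half-saturation `k_kill_half`), with each subtype shielded by its own
   checkpoint limiting factor. An empty tumour is absorbing.
2. **Antigen and antigen-presenting cells.** Neoantigen is shed at a
   baseline per-cell rate and released in bulk by killed cells; it degrades
   first-order and is carried to the TDLN by lymph. Tumour APCs mature at an
   antigen-saturating rate, migrate to the TDLN, and license T-cell priming
   there; a constant resident APC pool in the node matures from transported
   antigen as well. Soluble CTLA-4 secreted by regulatory T cells binds
   CD80/86 on mature APCs and inhibits maturation.
3. **The TDLN priming chain.** Naive tumour-specific T cells (constant
   influx `s_naive`) pass through primed and proliferating stages to become
   effector T cells. Each transition rate is
   `contact_rate · population · mAPC availability · antigen_intensity ·
   F_PD-L1 · F_CTLA-4 · F_Treg`, i.e. linear in antigen intensity with a
   saturating mature-APC availability and three Hill-type limiting factors.
   The proliferative burst is collapsed into a clonal expansion factor
   (`expansion_fold`, default 1600 effectors per proliferating cell
   completing the chain) rather than an explicit division cascade — this
   keeps the chain stable at baseline while allowing the order-of-magnitude
   effector amplification seen under blockade.
4. **Trafficking.** Effector T cells egress to blood and enter tissue
   through the three-step vascular scheme (reversible attachment to a
   finite adhesion-site pool, irreversible arrest, transmigration),
   instantiated separately for the tumour and the peripheral compartment.
   In the tumour they kill cancer cells, die at the apoptosis rate
   `k_apo_teff`, and transition to a permanently exhausted sink at a rate
   proportional to aggregate PD-1 engagement (the reversible part of
   inhibition is the limiting factor on killing; the exhausted sink is the
   irreversible part).
5. **Antibody PK/PD.** Each drug follows four-compartment kinetics:
   permeability–surface-area-limited exchange with available-volume-fraction
   partitioning, lymph flow tumour → TDLN → blood, linear clearance from
   plasma, and mass-action binding to its targets (anti-PD-L1: PD-L1 on
   cancer subtypes, tumour APCs, Tregs/MDSCs, and TDLN mAPCs; anti-CTLA-4:
   surface CTLA-4 on Tregs and primed T cells and soluble CTLA-4, in both
   tumour and TDLN). Doses are IV boluses by default; an infusion duration
   is configurable.

**Suppressors are algebraic.** MDSCs scale linearly with tumour burden
(`rho_mdsc` per cancer cell); TDLN Tregs scale with the node's T-lymphocyte
count; tumour Tregs are a saturating function of the MDSC level. Their
inhibitory action enters exclusively through checkpoint expression.

**Checkpoint algebra.** Synaptic ligand–receptor engagement is evaluated at
the bimolecular equilibrium of per-cell receptor densities (the quadratic
closed form), with antibody-bound receptors removed from the free pool
dynamically. Every occupancy drives a limiting factor
`F = 1 − emax · occ^h / (occ^h + ro50^h)`; multiple checkpoints combine
multiplicatively. PD-L1-negative cancer cells retain a strong baseline,
blockade-insensitive suppression of killing (`emax_baseline_kill`,
default 0.95), standing in for the physical barrier of the breast tumour
microenvironment and non-PD-1/PD-L1 pathways; the PD-L2 channel plays that
role for PD-L2-positive cells, since the anti-PD-L1 antibody does not touch
PD-1:PD-L2.

## Parameters

All ~100 rate constants live in a registry (`ParameterSet`) with a unit, a
documented plausible range and a one-line description; any subset can be
overridden per run and round-trips through YAML/JSON. Antibody clearances,
molar masses and binding constants are set to published order-of-magnitude
values; compartment volumes and permeabilities give mAb-like plasma
kinetics (terminal half-life of weeks, slow tumour uptake over days).

The immune gain parameters cannot be taken from literature one at a time —
they are jointly identifiable only through system behaviour. They were
calibrated, once, against the study conditions the package is built around
(baseline virtual patient: 30 mm tumour, antigen intensity 0.7, 25% PD-L1,
75 kg, doubling time 100 days):

* no tumour response without therapy (immune pressure at quasi-steady state
  is far below the growth flux);
* anti-CTLA-4 monotherapy (1 mg/kg × 4) strongly amplifies effector-T-cell
  production and APC maturation yet the tumour progresses;
* combination therapy raises total effector T cells well above the 3-fold
  mark over the pre-treatment steady state;
* under the anti-PD-L1 regimen (20 mg/kg monthly × 4, then 10 mg/kg q2w),
  starting sizes of 35 mm and below regress by 15 months while 40 mm and
  above escape;
* response deepens monotonically with antigen intensity, PD-L1 expression
  and dose.

The calibrated values are `k_kill = 40 /day`, `k_kill_half = 1e7` cells,
`expansion_fold = 1600`, `emax_baseline_kill = 0.95`; everything else keeps
its literature-informed default. The regression/growth boundary is a
bifurcation of the feedforward loop (killing releases antigen, antigen
drives priming, priming drives killing), so outcomes are sharply bimodal:
most responding tumours are driven to complete eradication, and the
boundary is sensitive to ~10% changes in immune gain. This is a property of
the mechanism, not a numerical artifact.

## Simulation procedure

1. **Initialization.** The drug-free system is integrated with the
   cancer-cell derivatives frozen at the starting size until the total
   effector T-cell count changes by less than 1e-4 (relative) over a 30-day
   window (typically ~1–2 months of simulated time; error after 1000 days).
   Freezing the tumour during equilibration is equivalent to the
   grow-then-reset convention — the immune state is conditioned on the
   nominal starting diameter either way — but makes the quasi-steady
   detection exact.
2. **Therapy.** Integration is event-segmented: the stiff solver (BDF)
   restarts at every bolus with an exact state handoff and a concentration
   jump in the central compartment. Outputs are sampled on a regular grid
   (default 1 day); the value stored at a dose time is post-dose.
3. **Analysis.** Tumour diameter derives from the cell count via the
   packed-sphere conversion (`d ∝ (N / packing)^{1/3}`, packing 0.74,
   cell diameter 20 µm). RECIST: PR at ≥30% diameter decrease (inclusive),
   CR below a 1 mm detection floor, PD at +20% and ≥5 mm above the nadir,
   SD otherwise; both best-overall and end-of-horizon responses are
   reported. Antigen thresholds for PR are found by bisection (tolerance
   1e-3) after verifying monotone endpoints.

## Numerical choices

* Default tolerances are `rel 1e-8` with species-class-scaled absolute
  tolerances (cell counts span 1–1e10 while molar species sit at 1e-12 to
  1e-6; a scalar atol cannot serve both). `SimulationSettings.high_accuracy()`
  switches to the very tight reference setting (abs 1e-14, rel 1e-13) for
  single high-accuracy runs. Batch analyses (grids, cohorts, sensitivity)
  use `rel 1e-6`; the tolerance-convergence test (tightening rtol moves the
  final diameter by <0.1%) justifies this.
* Small negative values produced by the implicit solver are clamped to zero
  inside the right-hand side and on the output grid.
* Problem sizes for the batch analyses: the size-boundary scan uses the
  seven-point grid {15…45} mm; monotonicity grids use 4–6 points per axis;
  the global sensitivity analysis uses 200 Latin hypercube samples over
  nine parameters (the headline analysis this package targets was designed
  around 1000; `run_global_sensitivity(n=1000)` reproduces that scale when
  wanted).

## Cohorts and sensitivity

Virtual cohorts draw patient-level biomarkers from uniform, truncated
normal, or fixed distributions; subtype presets encode PD-L1 20–40% (ER+)
and 40–60% (TNBC) with antigen intensity 0.4–0.6 for both and
subtype-specific doubling times. For normal draws the standard deviation
implied by a range defaults to `(b−a)/(2·1.96)` (95% of the mass inside the
range); truncation is at ±z·sd with `z = Φ⁻¹((1+c)/2)` per coverage level
(1.96/0.936/0.454 for 95/65/35%). Prediction bands are pointwise medians
with central empirical quantile intervals, nested by construction; a
parameter-truncation mode (resampling the cohort within ±z·sd) is available
through `CohortSpec` + `sample_cohort` composition.

LHS/PRCC: one point per equal-probability stratum per dimension, uniform
within the stratum; PRCC is the Pearson correlation of rank residuals after
regressing out all other rank-transformed parameters, with p-values from
the t distribution on `n − 2 − (d − 1)` degrees of freedom. The output
statistic is the percent tumour-size change at the 15-month horizon. Note
that the rank transform caps |PRCC| below 1 even for exactly additive
monotone test functions (≈0.97 for the weaker input of `2x₁ − 3x₂`); signs
and ordering, not the absolute magnitude, are the interpretable output.

## What the simulations do and do not show

The package is simulation-driven end to end: every experiment runs on
virtual patients defined by the generator defaults above, not on clinical
measurements. Passing tests therefore demonstrate internal consistency
(conservation laws, closed-form limits, monotone biomarker effects, the
calibrated response boundary), not clinical predictive validity. Known
limitations, intentional in the reduced scope:

* no cytokine circuits (IL-10, TGF-β, arginase/NO), so
  checkpoint-independent suppression is folded into the baseline kill
  limiter;
* a single neoantigen-specific clonotype with constant per-cell receptor
  numbers;
* one composite lesion (no multi-lesion RECIST bookkeeping) and no spatial
  heterogeneity;
* the bistable feedforward loop makes partial responses a narrow regime:
  real dose–response data would be needed to soften the eradicate-or-escape
  dichotomy;
* population PK parameters are taken as fixed inputs, not re-estimated.
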