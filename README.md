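# icbsim

A quantitative systems pharmacology (QSP) simulator of immune checkpoint
blockade in metastatic breast cancer: an anti-CTLA-4 antibody
(tremelimumab-like) combined with an anti-PD-L1 antibody (durvalumab-like),
following the clinical schedule of 75 mg + 1500 mg monthly for four cycles
and then 750 mg anti-PD-L1 every two weeks.

It is written for modellers and pharmacometricians who want to ask *which
patients respond, and why*: how starting tumour burden, PD-L1 expression on
tumour cells and neoantigen strength — individually and combined — shape
the tumour's response to mono- and combination therapy.

## The model

A stiff ODE system of 42 named states over four compartments — central
blood, peripheral tissue, tumour, and a lumped tumour-draining lymph node
(TDLN) — covering:

* the immune feedforward loop: killed tumour cells release neoantigen →
  antigen-presenting cells mature and migrate to the TDLN → naive T cells
  are primed in three stages (naive → primed → proliferating → effector) →
  effectors traffic through the vasculature (attachment, arrest,
  transmigration) into the tumour → cytotoxic killing releases more antigen;
* immune suppression via checkpoint expression: PD-1:PD-L1/PD-L2 engagement
  in the tumour, CTLA-4:CD80/86 engagement and soluble CTLA-4 in the TDLN,
  Tregs and MDSCs scaled algebraically to tumour burden and lymph-node
  cellularity. Each engaged checkpoint drives a Hill limiting factor
  `1 − emax·occ^h/(occ^h + ro50^h)` on the affected rate, with occupancies
  from the bimolecular quadratic equilibrium;
* four-compartment antibody PK with permeability–surface-area exchange,
  lymphatic recirculation, linear clearance, and competitive mass-action
  binding to every targeted checkpoint pool;
* cancer cells partitioned into four checkpoint-expression subtypes from
  the patient's PD-L1/PD-L2 fractions (treated as independent
  probabilities), growing exponentially at `ln 2 / doubling_time`.

Tumour response is read off the diameter trajectory with RECIST
conventions (partial response at a ≥30% diameter decrease). On top of the
simulator sit RECIST classification, antigen-threshold bisection, 1-D/2-D
response sweeps, virtual-patient cohorts with prediction bands, and
LHS/PRCC global sensitivity analysis.

See `docs/methods.md` for the full model description, parameter defaults
and calibration, and numerical choices.

## Worked example

Simulate the baseline virtual patient (30 mm starting tumour, antigen
intensity 0.7, 25% PD-L1-positive tumour cells, 75 kg) through the trial
combination schedule:

```bash
icbsim simulate --regimen trial_combo --out out/demo --seed 1
```

prints

```
CR: best -100.0%, end -100.0% (30.0 -> 0.0 mm)
```

i.e. the pre-treatment immune steady state is found, the 33 dose events
are applied over the 15-month horizon, and the trajectory ends in a
complete response: the checkpoint blockade releases the feedforward loop
and the tumour is eradicated. `out/demo/trajectory.csv` holds the
time-resolved outputs (one row per day):

```
time_day,tumour_diameter_mm,teff_total,mapc_ln,serum_antictla4_mol_per_l,serum_antipdl1_mol_per_l
0,30,1589014.896,28365.31732,1.006711409e-07,2.027027027e-06
1,30.03097001,3604919.632,29221.1884,7.4106425e-08,1.505708698e-06
...
```

`tumour_diameter_mm` is the composite lesion diameter, `teff_total` the
total effector T cells in the system (TDLN + blood + vascular + peripheral
+ tumour pools), `mapc_ln` the mature APCs in the lymph node, and the
`serum_*` columns the central-compartment drug concentrations (mol/L; the
day-0 values are the post-bolus peaks of 75 mg anti-CTLA-4 and 1500 mg
anti-PD-L1 in a 5 L central volume). A `manifest.json` recording inputs,
seed and versions is written next to every output.

The same machinery is available as a library:

```python
from icbsim import CheckpointBlockadeModel, PatientParameters, resolve_regimen, classify_recist

model = CheckpointBlockadeModel(PatientParameters(initial_tumour_diameter=40.0))
steady = model.steady_state()                      # drug-free immune equilibrium
traj = model.simulate(resolve_regimen("anti_pdl1_mono"), state0=steady)
print(classify_recist(traj).category)              # "PD" — 40 mm escapes
```

Other subcommands: `sweep` (1-D/2-D response grids), `threshold`
(antigen-intensity threshold for partial response), `cohort`
(virtual-patient bands for the ER+ / TNBC presets), `sensitivity`
(LHS/PRCC), `export-model` (machine-readable model description).

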