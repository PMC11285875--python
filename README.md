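# rhodocarb

Carbon budgeting of calcification–photosynthesis coupling in coralline algae
(maerl / rhodoliths) from dual-radioisotope (⁴⁵Ca + ¹⁴C) vial incubations.

Calcifying algae sit at an awkward point in marine carbon accounting:
precipitating CaCO₃ stores carbon in the skeleton but *releases* CO₂ to the
surrounding water, while photosynthesis consumes CO₂. Whether a coralline
bed is a net carbon source or sink therefore hinges on how much of the
calcification-derived CO₂ the alga recycles internally as photosynthetic
substrate before it can escape. `rhodocarb` implements the full analysis
chain for quantifying that recycling at the organismal scale from a
dual-label incubation experiment, plus a forward simulator of the experiment
so every stage is testable without any external data.

## What it computes

**Seawater release ratio ψ** (`rhodocarb.carbonate`). In seawater that stays
in contact with the atmosphere, precipitating 1 mol of carbonate
(ΔTA = −2, ΔDIC = −1) forces the evasion of ψ < 1 mol of CO₂ once the water
re-equilibrates at its original pCO₂, because the carbonate system buffers
the rest:

    ψ = 2·(∂DIC/∂TA)|pCO₂ − 1 = aH·(A − Q·(P−1)) / (R − Q·aH)

with carbonate alkalinity A = [HCO₃⁻] + 2[CO₃²⁻], and the buffer-factor
groupings P = K_B·T_B/(aH+K_B)² + K_w/aH² + 1, Q = aH + 2K₂,
R = A·Q + 2K₂·A + P·Q·aH. ψ ≈ 0.6 at 25 °C and ≈ 0.7 at 15 °C for
present-day surface seawater. The module contains a full CO₂-system solver
(any two of pH / TA / DIC / pCO₂; constants selectable among standard
literature formulations) and a finite-difference perturbation oracle that
validates the closed form by actually simulating the precipitation.

**Tracer incorporation and ψ_I** (`rhodocarb.tracer`). Counted activity
becomes moles via the specific concentration of each label
(rate = activity × Con / (M·T)), the ⁴⁵Ca channel is scaled by (1 + Mg/Ca)
for the magnesium co-precipitated in high-Mg calcite, and a per-timepoint
blank subtracts passive label deposition on bare skeleton. The organismal
release ratio is then

    ψ_I = (¹⁴CO₂ production − organic ¹⁴C fixation) / Mg-adjusted ⁴⁵Ca incorporation,

estimated in the carbonic-anhydrase-inhibited (+EZ) treatment, where
CCM-derived label does not contaminate the numerator. ψ_I < ψ is the
signature of internal CO₂ recycling.

**Carbon-budget partition** (`rhodocarb.budget`). Under the bicarbonate
calcification equilibrium 2 HCO₃⁻ + Ca²⁺ → CaCO₃ + CO₂ + H₂O, skeleton P,
organic matter O and net CO₂ release are the terminal sinks of the total
uptake U = O + P + net; the calcification DIC demand is 2P and the produced
CO₂ (= P) splits into recycled (P − net) and released (net) parts.
Uncertainties propagate by truncated-normal Monte-Carlo over the group
standard errors, with a first-order delta-method cross-check.

**Inference** (`rhodocarb.stats`): Kruskal–Wallis with tie correction,
Dunn's post-hoc z-tests with Šidák adjustment, Pearson correlation — all
computed from first principles.

**Simulator** (`rhodocarb.synthetic`): the 2 treatments × 4 timepoints × 8
replicates design (64 vials, 20 ml, 600 kBq of each label), mean-one
lognormal biological and measurement noise, truth parameters matching the
published group statistics.

## Worked example

```python
from rhodocarb import budget, carbonate, synthetic, tracer

# seawater release ratio at the incubation temperature
k = carbonate.compute_constants(15.0, 35.0)
state = carbonate.solve_system(15.0, 35.0, k, ph=8.1, ph_scale="nbs",
                               total_alkalinity=2300e-6)
print(f"psi = {carbonate.psi_analytic(state, k).psi:.3f}")

# one synthetic cohort through the tracer pipeline
table = synthetic.generate(synthetic.GeneratorConfig(seed=42))
per_vial = tracer.process_table(table)
grp = tracer.psi_i_group(per_vial, "EZ")
print(f"psi_I (+EZ, T+5h) = {grp[grp.timepoint_h == 5.0].psi_i.iloc[0]:.3f}")

# budget partition of measured group statistics (percent-of-uptake units)
stats = dict(organic=budget.GroupStat(39.0, 14.0, 8),
             skeletal=budget.GroupStat(38.0, 22.0, 8),
             net_release=budget.GroupStat(23.0, 3.0, 8))
part = budget.partition(budget.BudgetInput(**stats))
mc = budget.propagate(budget.BudgetInput(**stats), n_draws=100_000, seed=0)
print(f"calcification demand = {100*part.demand_of_uptake[0]:.0f}% of uptake")
print(f"recycled of produced CO2 = {100*mc.recycled_of_produced[0]:.1f} "
      f"+- {100*mc.recycled_of_produced[1]:.1f}%")
```

prints

```
psi = 0.736
psi_I (+EZ, T+5h) = 0.361
calcification demand = 76% of uptake
recycled of produced CO2 = 36.5 +- 16.8%
```

ψ = 0.736 is what purely abiotic seawater buffering would release per mole
precipitated at 15 °C; the simulated organism's ψ_I ≈ 0.36 is roughly half
of that — the recycling signal. The deterministic partition puts the
calcification DIC demand at 76% of total uptake; Monte-Carlo propagation of
the replicate scatter puts the internally recycled share of produced CO₂ at
36.5 ± 16.8%.

The same pipeline is scriptable from the shell:

```
rhodocarb simulate --seed 1 --out vials.csv
rhodocarb incorporate --vials vials.csv --out-prefix results/inc
rhodocarb psi --temperature-c 15 --ph 8.1 --ph-scale nbs
rhodocarb budget --organic 39,14,8 --skeleton 38,22,8 --release 23,3,8
rhodocarb stats --vials vials.csv --response act_ca45_skel_kbq
rhodocarb run-all --seed 1 --outdir results/run   # manifest + checksums
rhodocarb reproduce-paper
```

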