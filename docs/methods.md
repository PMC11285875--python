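# Methods

## Seawater CO₂ system

The solver works on the total hydrogen-ion scale in mol kg-SW⁻¹ and accepts
any two of {pH, total alkalinity, DIC, pCO₂}. The alkalinity balance carries
the carbonate, borate and water terms,

    TA = [HCO₃⁻] + 2[CO₃²⁻] + B(OH)₄⁻ + OH⁻ − H⁺,

with no nutrient or pressure terms (surface incubations, filtered seawater).
Carbonate alkalinity A — the variable the ψ model is written in — is
obtained from TA by subtracting the borate and water contributions at the
solved pH. Default constants: K₀ from Weiss (1974); K₁/K₂ from the Mehrbach
data as refit by Dickson & Millero (1987), converted from the seawater to
the total scale via the Dickson (1990) bisulfate and Dickson & Riley (1979)
fluoride constants; K_B from Dickson (1990); K_w from Millero (1995); total
boron from Uppström (1974), T_B = 4.16·10⁻⁴·S/35. Lueker et al. (2000) and
Roy et al. (1993) K₁/K₂ and Lee et al. (2010) boron are selectable; at the
conditions of interest the choice moves ψ by < 0.01, so the default set is
used everywhere. pH on the NBS scale is converted at the boundary with the
Takahashi et al. (1982) activity coefficient f_H (≈ 0.75 at 15 °C, so
pH_NBS 8.1 corresponds to pH_total ≈ 7.98).

Where a pH is not given directly, the solver runs a bracketed scalar search
on pH over [2, 12] (Brent's method, |ΔpH| < 10⁻¹², no randomness), leaving
alkalinity residuals below 10⁻¹² mol kg⁻¹. Two invariants are enforced on
every solved state: the DIC and carbonate-alkalinity decompositions close to
10⁻¹⁰ relative, and the apparent-constant identity
aH·[HCO₃⁻] = K₁·K₀·pCO₂ holds to 10⁻⁸ relative. Degenerate or impossible
input pairs (e.g. pCO₂ implying [CO₂*] ≥ DIC) raise domain errors naming the
offending quantity; a failed bracket raises a numerical error carrying both
endpoint residuals.

## The release ratio ψ

ψ is the CO₂ handed to the gas phase per mole of carbonate precipitated by
water that remains in contact with the atmosphere. Precipitation removes
alkalinity and DIC in a 2:1 ratio; gas exchange then restores the original
pCO₂ by moving DIC alone, so

    ψ = 2·(∂DIC/∂TA)|pCO₂ − 1.

At constant pCO₂ (hence constant [CO₂*]) the speciation is a one-parameter
family in aH, which makes the derivative a ratio of two closed forms.
Written with Frankignoulle's (1994) buffer-factor groupings
P = K_B·T_B/(aH+K_B)² + K_w/aH² + 1 (minus the aH-derivative of the
non-carbonate alkalinity), Q = aH + 2K₂ and R = A·Q + 2K₂·A + P·Q·aH,

    ψ = aH·(A − Q·(P − 1)) / (R − Q·aH),

strictly inside (0, 1) for surface seawater: CO₂ rises as carbonate ions
fall, but buffering absorbs part of the perturbation. The companion C_S
grouping is reported on every result for completeness.

Because printed forms of this model circulate with typesetting damage
(lost fraction bars render the intermediates ambiguous), the closed form is
never trusted on its own: `psi_finite_difference` actually performs the
perturbation experiment — solve at TA ± 2δ and the unperturbed pCO₂, take
the symmetric difference quotient of DIC (second-order in δ, default
δ = 10⁻⁸ mol kg⁻¹) — and the test suite requires agreement with the closed
form within 10⁻³ over a 24-state T × S × pH × TA grid (observed agreement
is better than 10⁻⁵). The oracle, not the printed algebra, is authoritative.

Behaviour worth knowing: ψ ≈ 0.60 at 25 °C and ψ ≈ 0.68 at 15 °C for
pH_total 8.1, TA 2300 µmol kg⁻¹. At *fixed pH and TA*, ψ falls with
temperature (warmer water holds more CO₃²⁻ at the same pH, strengthening
the buffer); along other paths (e.g. fixed pCO₂) the ordering can reverse,
so tests assert only that the closed form and the oracle agree on the
ordering. Across plausible sea-loch summer surface conditions at 15 °C
(S 34–35, TA 2200–2400 µmol kg⁻¹, pH_NBS 8.0–8.2) ψ spans 0.69–0.79 and
rounds to 0.7 over the majority of the grid (all states with
pH_NBS ≥ 8.1); the acceptance script reports that modal rounded value.

## Tracer bookkeeping

Incorporation follows the specific-concentration relation
rate = activity · Con / (M·T) with Con = carrier pool / activity added.
Defaults, all overridable: 20 ml vials (1 l ≈ 1 kg), 600 kBq per label,
seawater Ca²⁺ 10.28 mmol kg⁻¹ (Con_Ca ≈ 342.7 nmol kBq⁻¹) and vial DIC
2.1 mmol kg⁻¹ (Con_C ≈ 70 nmol kBq⁻¹). Rates are cumulative
(absolute = rate·T); per-interval rates between consecutive timepoints are
derived from group means on request. No decay correction is applied — ⁴⁵Ca
(t½ ≈ 163 d) and ¹⁴C (t½ ≈ 5730 y) lose a negligible fraction over a 5 h
incubation — and counting efficiency/quench are out of scope.

The Mg adjustment multiplies the ⁴⁵Ca channel by (1 + Mg/Ca), default molar
Mg/Ca = 0.15, typical of high-Mg calcite; applying it twice is an error.
Passive label deposition on bare (snapped) skeleton is handled as an
explicit per-timepoint blank rate subtracted from the affected channel,
floored at zero with a logged clamp — the blank is supplied by
configuration or estimated from dedicated blank vials, which keeps the
correction testable rather than buried in a counting-file convention.

ψ_I = (CO₂ production − organic fixation) / Mg-adjusted Ca+Mg incorporation
is evaluated in the CA-inhibited treatment by default. Negative values are
reported with a warning, never clamped: at early timepoints the numerator is
a small difference of noisy counts and its sign is informative about noise.
Two cohort-level estimators are provided. The mean of per-vial ratios
(`psi_i_table`, the natural companion of a per-vial table) carries the
standard ratio bias of roughly +cv² under multiplicative measurement noise
(+2.3% at the default cv = 0.15); the ratio of group means (`psi_i_group`)
is consistent for the true ratio and is what the recovery analyses use.

## Budget partition

The partition treats skeleton (P), organic matter (O) and net CO₂ release
(net) as the terminal sinks of total uptake U = O + P + net. The bicarbonate
pathway 2 HCO₃⁻ + Ca²⁺ → CaCO₃ + CO₂ + H₂O ties produced CO₂ 1:1 to
precipitated carbonate, making the calcification DIC demand 2P; produced CO₂
then splits into recycled (P − net) and released (net) shares. This
stoichiometric 1:1 production is deliberately used *instead of* the
seawater-buffered ψ (≈ 0.7): the organism controls chemistry at the
calcification site, and only the 1:1 closure is consistent with treating O,
P and net as exhaustive terminal sinks. ψ is reported alongside as the
no-recycling expectation for abiotic seawater. Recycled CO₂ is counted
inside both the calcification demand and the organic pool by construction;
U is assembled from terminal sinks only, so nothing is double-counted. Note
the recycled amount can be quoted against two denominators — as a share of
uptake (P − net)/U or of the organic pool (P − net)/O — which differ; both
are derivable from the returned fractions, and neither is privileged.

Uncertainty propagates by Monte-Carlo: each input is drawn from a normal
centred on its mean with the standard error of the mean as scale, truncated
at zero (the sinks are amounts), the partition runs per draw, and per-output
means and sds are reported; 10⁵ draws by default, reproducible by seed, with
sd estimates stable to ~1% between 10⁴ and 10⁵ draws. A first-order
delta-method propagation (`propagate_delta`) serves as the analytic
cross-check; the two agree within 5% on the fraction sds at mild input
uncertainty. For strongly skewed inputs (sd comparable to the mean) the
truncation shifts draw means upward relative to the nominal inputs — that is
a property of the error model, not a bug, and the deterministic partition is
always reported next to the Monte-Carlo summary.

The convenience conversion of a deposition rate to % dry mass day⁻¹ treats
the deposit as CaCO₃-equivalent; for rates of order 1.5 nmol h⁻¹ g⁻¹ it
yields ~4·10⁻⁴ % day⁻¹, three orders of magnitude below commonly quoted
coralline growth figures, so it is exposed as a diagnostic only and takes no
part in any validated quantity.

## Inference

Kruskal–Wallis uses mid-ranks with the tie correction
1 − Σ(t³−t)/(N³−N) always applied, and the chi-square approximation with
k − 1 degrees of freedom (adequate at n = 8 per group; no exact permutation
option in this version). The treatment × timepoint design pools into
8 groups, df = 7. Dunn's z-statistics use the tie-corrected pooled rank
variance N(N+1)/12 − Σ(t³−t)/(12(N−1)); the Šidák adjustment
1 − (1−p)^m runs over all m = k(k−1)/2 pairwise comparisons, and m is
reported in the output so the family size can be audited. Type-I error of
the H test under a null of 8 × 8 draws is verified to sit in
[0.035, 0.065] at α = 0.05 over 2000 replicates. Pearson's r uses the
sample formula with a t-distributed p-value on n − 2 degrees of freedom.

## Synthetic experiment

The generator emulates the incubation design: 2 treatments × 4 timepoints
(0.5, 1.5, 3, 5 h) × 8 replicates = 64 vials, each with 600 kBq of both
labels in 20 ml. True cumulative incorporation is rate × time × mass;
activities follow by inverting the specific-concentration relation, so with
all CVs at zero the tracer pipeline recovers every truth parameter exactly
(an identity the tests assert).

Truth defaults are calibrated once to the published group statistics and
are the study conditions, not tuning knobs: control Ca+Mg deposition
1.47 nmol h⁻¹ g⁻¹ and inhibited 0.19; control organic fixation 1.51 so the
organic sink is ≈ 39% of uptake where the skeleton is ≈ 38%; net release
23% of control uptake; inhibited-group CO₂ release fixed through
ψ_I = 0.38 with near-zero inhibited organic fixation (0.01). The skeletal
¹⁴C channel sees the externally sourced share of the 1:1 skeletal carbon
demand (default 0.646). Oxygen production defaults to
1.5 µmol h⁻¹ g⁻¹ in controls with inhibited vials scaled down 1.86× at
every timepoint after the first (the inhibitor effect has not expressed at
T+0.5 h).

Noise is multiplicative, mean-one lognormal — counts are positive and
right-skewed — in two layers: a per-vial biological multiplier shared by
all channels of a vial (CV 0.3, reflecting the wide published replicate
spreads) and independent per-channel measurement noise (CV 0.15); dry mass
is lognormal around 0.5 g (CV 0.2). Mean-one noise keeps the linear rate
estimators unbiased; recovery tests verify |bias| < 0.5 sd across cohorts
for calcification, organic fixation and ψ_I, and the acceptance run checks
the 200-cohort grand means against the truths within 2 standard errors.

What the simulator does *not* model — and hence what passing tests cannot
certify about real incubations: boundary-layer gradients, circadian
variation, isotope decay, counting efficiency, time-varying rates within
the incubation (truths are constant rates, so cumulative and per-interval
estimates coincide by design), correlated channel noise beyond the shared
biological multiplier, and any treatment effect on dry mass.

## Problem sizes

Defaults keep everything desk-scale: the full test suite runs in a few
seconds; the acceptance script (45-state ψ grid plus 200 synthetic cohorts
of 64 vials) completes in about two seconds on one CPU. Monte-Carlo budget
propagation uses 10⁵ draws; the null-calibration suite uses 2000
Kruskal–Wallis replicates.
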