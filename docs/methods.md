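# Methods

## Gating model

hERG is represented by two independent first-order gates on a single
conductance:

    da/dt = (a∞(V) − a) / τ_a(V)          activation gate (slow)
    dh/dt = (h∞(V) − h) / τ_h(V)          inactivation gate (fast)
    I_hERG = g_max · a · h · (V − E_K)

with Boltzmann steady states
`a∞(V) = 1/(1 + exp(−(V − V½ₐ)/kₐ))` and
`h∞(V) = 1/(1 + exp((V − V½ₕ)/kₕ))`.  The direct `(X∞, τ_X)`
parameterisation was chosen over rate-constant (α/β) forms so that
steady-state targets can be set per variant exactly, which is what the
calibration needs.  This is a deliberate simplification: hERG inactivation
is known to be weakly coupled to activation, and multi-state Markov models
capture drug block and state-dependent phenomena this model cannot.  For
protocol-design and analysis-validation purposes the two-gate model is
sufficient and is the conventional reduced description.

Time constants are tabulated per process and interpolated monotone-cubically
(PCHIP) in log τ over voltage; the activation and deactivation tables jointly
describe τ_a(V) (its depolarised and hyperpolarised limbs), likewise
inactivation-onset and recovery tables for τ_h(V).

### WT parameters (defaults)

| quantity | value | rationale |
| --- | --- | --- |
| V½ activation / k | −19.5 / 11.6 mV | calibration target of the SP2 analysis |
| V½ inactivation / k | −83.6 / 17.8 mV | calibration target of the SP3 analysis |
| τ_act (ms) | 500 (−50), 320 (−30), 180 (−10), 140 (0), 90 (+20), 60 (+40), 30 (+70) | slow activation, hundreds of ms at threshold; SP2 step durations are ≈5× these values |
| τ_deact (ms) | 28 (−130), 35 (−120), 50 (−110), 80 (−100) | slow deactivation; makes the last SP3 pulses measurably deactivate, exercising the compensation |
| τ_inact (ms) | 9 (−10), 8 (0), 5 (+20), 2.5 (+50), 1.5 (+70) | fast C-type inactivation |
| τ_rec (ms) | 2.5 (−130), 5 (−110), 6 (−90), 6.5 (−70), 7.5 (−50), 9 (−30) | fast recovery; 5 ms at −110 mV leaves the 5-ms relief step ≈63% complete, which sets the SP2-vs-classical tail-amplitude ratio near ten-fold |
| g_max | 16 nS | gives a WT density of ≈170 pA/pF at C_m = 15 pF |
| E_K | −90 mV | physiological K⁺ gradient at room temperature |

Recording artifacts: linear leak `g_leak·(V − E_leak)` (default reversal
0 mV), additive Gaussian current noise (seeded), cell capacitance for
density normalisation.  Series resistance and capacitive transients are not
modelled (ideal clamp).

### Variant registry

Thirteen clinical variants are packaged.  Variants reported with no current
carry `conductance_scale = 0` (T74R, R534C, A561V, R835P); variants too
small to characterise carry their density ratio with WT gating (C64Y 0.10,
I96T 0.12, P1026L 0.08).  Gating changes: D591H shifts inactivation to
−67.1 mV (k 22.1) with slower inactivation (×1.8), slower recovery (×1.2)
and faster deactivation (×0.75); G584S shifts inactivation to −92.6 mV with
faster inactivation; R176W has faster inactivation and a shallower
inactivation slope; R35W, K93E, R176W and D591H deactivate faster.  The
D591H kinetic scale factors were calibrated (directions fixed by the
measured phenotype) so that the AP-clamp repolarisation-power ratio to WT
is ≈2.6.  Conductance scales for R35W (0.52), R328C (0.55), R176W (0.29)
and G584S (0.42) place their repolarisation-power losses in the reported
severity bins; for R35W and R328C this folds the cohort-level
repolarisation deficit into conductance even though their peak tail
densities were not significantly reduced — a registry-level design choice,
since the AP-clamp deficit is the quantity the report scores.

Heterozygosity: subunits mix binomially into tetramers, C(4,j)/16 species
with j variant subunits.  Mixed species gate with subunit-weighted
parameters (linear in shifts, geometric in τ scales) and conduct the
subunit-weighted conductance times `(1 − dn_poisoning_p)`; the poisoning
probability is the dominant-negative strength (calibrated per variant:
T74R/R835P 0.5, I96T 0.35, P1026L 0.05).

## Simulation numerics

Constant-voltage segments use the closed-form mono-exponential relaxation
of each gate (exact).  Sampled waveforms (AP clamp) use exponential-Euler
stepping at the 0.1-ms sample interval, i.e. the same closed form applied
per sample with V held over the step; for the smooth AP template the
associated zero-order-hold error is far below analysis resolution (the
simulator is tested to agree with stiff ODE integration of the same
equations to better than 0.1%).  Gates are initialised at steady state for the first
sample's potential.  Command voltages more than 15 mV outside the τ-table
range raise an error rather than extrapolate.

## The AP template

One 1000-ms cycle from −88 mV to a +36 mV overshoot: a 2-ms half-cosine
upstroke, an early repolarisation to a plateau near 0 mV with a slow linear
sag, and a sigmoidal phase-3 repolarisation (12-ms steepness) whose centre
is solved so the template is exactly 90% repolarised at `apd90_ms`
(default 230 ms); the diastolic tail is flat at −88 mV.  The plateau-dwell
shape matters: it weights the AP-clamp integral toward the voltages where
inactivation availability differs most between variants, and it reproduces
the current-profile ordering in which the short-QT variant peaks earlier
(≈0.18 s) than WT (≈0.20 s).

## The analysis chain and its corrections

Order of operations: leak subtraction → segmentation → SP1 QC and
repolarisation power → SP4 deactivation fits → SP2 tails and activation
fit → activation-kinetics fits → SP5/SP6 inactivation-gate fits → SP3
availability with corrections → second-pass SP2 refinement → density and
gate.

* **Leak**: a linear leak with assumed 0 mV reversal is estimated from the
  late diastole of the first AP cycle, where the command sits ≈2 mV from
  E_K and the channel contributes almost nothing, and subtracted pointwise.
* **Tail extrapolation**: each +70 mV measurement window is fitted with
  `A·exp(−t/τ) + C` from 0.5 ms (settling guard) to 8 ms and read at the
  step onset as `A + C` — the offset is part of the signal for variants
  with incomplete inactivation.
* **SP3 corrections**.  The 15-ms test pulses are deliberately brief, so two
  systematic deficits must be undone using quantities fitted from the same
  cell: (i) *incomplete relaxation* of the inactivation gate — each
  availability point is divided by `1 − exp(−15/τ_h(V))`, with τ_h(V)
  interpolated from the SP5/SP6 fits; (ii) *the activation-gate level* —
  deactivation during the most negative pulses plus the incomplete
  re-activation carried over through the 20-ms +70 mV returns.  The
  activation trajectory is reconstructed recursively from the fitted
  τ_a(V) (SP4 deactivation fits, quadratically log-extrapolated below
  −120 mV; SP2/SP7 activation fits elsewhere) and the fitted activation
  Boltzmann, and each point is divided by the reconstructed gate level at
  its pulse end.  Corrections larger than five-fold are flagged
  unreliable.
* **Recovery fits** are detrended by the estimated deactivation decay at
  the test potential before the mono-exponential rise is fitted, and only
  the rising limb (to 95% of the extremum) is used.  Recovery at −90 mV is
  reported as unmeasurable: it carries no driving force at E_K = −90 mV.
  For the same reason SP6 includes a −130 mV step, which also anchors
  τ_h below −110 mV for the SP3 correction.
* **SP2 refinement**: the 5-ms relief at −110 mV leaves a small
  conditioning-dependent inactivation residue in each tail; once the
  availability curve and τ_h are known, each SP2 amplitude is divided by
  its relief-end availability and the activation Boltzmann refit.
* **Classical protocols**: activation tails (2-s steps, −50 mV tail) are
  read by extrapolating the post-hook decay to tail onset, so every sweep
  is measured at the same effective point; classical inactivation pulses
  are deactivation-compensated with τ values fitted from the pulses' own
  hook-times-decay product at the three most negative potentials.

Boltzmann fits are unweighted least squares with initial guesses from the
half-maximum crossing and the 25–75% spread; k is reported positive in both
directions.  Kinetic fits are mono-exponential with offset; fits whose
residual exceeds 20% of the amplitude are flagged.  Windows with
peak-to-peak signal below 0.02 pA are reported as unmeasurable, and tails
below a 1-pA floor return zero with a low-signal flag.

Quality gates: the AP2→AP3 peak-density variation must be below 10%
(periodic steady state), and a variant is analysable for voltage dependence
only at ≥20% of the WT reference density (taken from the maximum of the
SP3 Boltzmann fit, in pA/pF).

## Trafficking

The fluorescence generator emulates a whole-cell pHluorin recording:
`F = F₀·(internal + membrane·[pH = 7.4])` with optional mono-exponential
bleaching and multiplicative Gaussian noise; pH 6.0 epochs quench exactly
the membrane component.  The quantifier averages the last half of each
epoch (excluding switch transients), computes the raw quench
`(F_{7.4} − F_{6.0})/F_{7.4}`, subtracts a basal background fraction
(default 0.06, floored at 0; the exact correction formula is a design
choice of this package) and reports
`ratio = q/(1 − q)` plus a reversibility flag (post-wash plateau within 10%
of pre-switch).

Cohorts draw per-cell membrane fractions from a beta distribution around
the calibrated mean (the registry's corrected quench plus the background)
with a constant coefficient of variation of 0.12.  The CV was chosen by
variance propagation so an 18-cell cohort mean is reproducible to a few
percent; the experimental spread is larger because it folds in inter-day
and imaging variance that this generator does not model.  Heterozygous
trafficking is modelled as a retention factor on the WT membrane fraction
(dominant-negative retention, calibrated per variant).

## Structural score

Criteria A and B are pure table lookups (packaged CSV, user-overridable):
residue volumes (Zamyatnin set) binned at 30/120 Å³, and charge /
polarity / Kyte–Doolittle hydrophilicity classes with: opposite charge or
an opposed polar-hydrophobic flip → 2, any gain/loss of charge or polarity
→ 1.  The Thr→Arg volume difference in this table (57 Å³) is smaller than
values quoted under other volume conventions (≈94 Å³); the bin edges were
placed so the substitution scores 1 in either case.

Criterion C grafts the target residue's CCD ideal-geometry side chain onto
the fixed backbone (N/CA/C superposition) and enumerates a coarse
backbone-independent rotamer library (all χ combinations of −60/60/180°;
81 rotamers for Arg/Lys, 1 for Ala/Gly/Pro).  Heavy-atom clashes are
counted Chimera-style (`overlap = r_i + r_j − d ≥ 0.6 Å`, no hydrogen-bond
allowance) against all residues except the target and its sequence
neighbours (±1).  The minimum count over rotamers maps to 0 / 1 (≤3,
minimisable) / 2 (>3).  Scoring positions inside the structure's unresolved
spans (hERG residues 140–341 and 870–1006) returns `not_visible` with A/B
still reported.  Colour: red ≥4, yellow 2–3, green <2.

A synthetic toy structure (twelve residues with engineered empty,
single-contact and caged environments; clearly not a real protein) is
packaged so criterion C is testable offline; scoring real hERG variants
requires a user-supplied 5VA1 structure file.

## Severity report

Percent change is computed against the WT cohort mean (the reference
statistic is a design choice), `100·(1 − x_variant/x_WT)`, separately for
repolarisation power and corrected quench, and binned left-closed in 20%
steps into scores 1–5 (100% → 5).  Gains of function (negative loss) are
flagged rather than scored on the loss scale; their magnitude is binned on
|change| for reference, clipped at 5.  Heterozygous scores, when simulated,
are reported alongside the homozygous ones.

## What the synthetic data does and does not establish

The generator produces exactly the model class the analysis assumes
(two-gate kinetics, mono-exponential relaxations, linear leak, Gaussian
noise).  Green tests therefore establish that the protocol design and the
analysis chain are *self-consistent and unbiased for that model at the
calibrated parameters* — including the non-trivial corrections, which are
validated against deactivation-disabled paired simulations and stiff-ODE
oracles.  They do not establish robustness to real-data pathologies:
bi-exponential deactivation, endogenous background currents, series
resistance and imperfect space clamp, temperature drift, or the inward
contamination current visible at the end of real AP-clamp recordings.
Sample sizes and dispersions of the synthetic cohorts are nominal, not
re-estimates of the experimental ones.

## Problem sizes

Default runs simulate 35-s recordings at a 0.1-ms sample interval
(350 000 samples per cell); the full 13-variant pipeline plus the test
suite completes in well under a minute on one CPU, and
`scripts/acceptance.py` in a few seconds.

## Known limitations

* Two-gate model: no state-dependent drug block, no activation–inactivation
  coupling, no temperature (Q10) scaling.
* Mono-exponential deactivation only; real hERG tails are bi-exponential.
* The classical inactivation analysis, as in conventional practice, leaves
  incomplete-relaxation effects uncorrected and is steeper than the
  optimised-protocol estimate; the two midpoint estimates agree within
  3 mV.
* The structural score is a steric/physicochemical screen: no energy
  minimisation, no ΔΔG, no interaction partners, no modelling of
  unresolved regions.
* ACMG class and clinical scores are pass-through metadata, never computed.
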