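# hergkit

Standardised functional phenotyping of hERG (KCNH2 / Kv11.1) channel
variants.

Loss-of-function variants of the hERG potassium channel cause long-QT
syndrome type 2; gain-of-function variants cause short-QT syndrome 1. Most
newly sequenced missense variants are of unknown significance, and
conventional patch-clamp characterisation (10+ minutes of protocols per
cell, manual analysis) does not scale to the rate at which they are found.
`hergkit` implements a standardised phenotyping workflow for
electrophysiologists and variant-curation teams:

* **an optimised 35-s voltage-clamp protocol** — seven consecutive
  subprotocols (SP1–SP7) extracting, from a single sweep: AP-clamp currents
  (3 ventricular action potentials), steady-state activation (SP2,
  conditioning steps sized to ≈5 activation time constants per potential,
  with a −110 mV inactivation-relief step before each +70 mV tail
  measurement), steady-state inactivation (SP3, one +70 mV opening step
  then 15-ms test pulses from +50 to −130 mV), and the kinetics of
  deactivation (SP4), inactivation (SP5), recovery from inactivation (SP6)
  and activation (SP7);
* **the automated analysis** of such recordings: leak subtraction, sweep
  segmentation, mono-exponential tail extrapolation, deactivation
  compensation, Boltzmann fits `I = I_max / (1 + exp(∓(V − V½)/k))`, and
  per-process exponential kinetics;
* **the repolarisation power** — the time integral of hERG current density
  over one action-potential cycle (pC/pF), a single functional index that
  folds conductance, gating shifts and kinetics into the quantity that
  matters physiologically: how much repolarising charge the channel moves
  per beat;
* **pHluorin trafficking quantification** — percent fluorescence variation
  (pH 7.4 − pH 6.0)/pH 7.4, background-corrected, with the
  membrane-to-internal channel ratio q/(1 − q);
* **a three-criterion structural impact score** — side-chain volume change
  (A), charge/polarity/hydrophilicity change (B), and minimum rotamer
  clash count on the cryo-EM structure (C), each 0–2, with red/yellow/green
  classification of the total;
* **1–5 severity indexes** binning percent change versus WT in 20% steps,
  assembled into a per-variant pathogenicity report;
* **a calibrated two-gate Hodgkin–Huxley simulator** of hERG currents
  (`da/dt = (a∞(V) − a)/τ_a(V)`, `dh/dt = (h∞(V) − h)/τ_h(V)`,
  `I = g_max·a·h·(V − E_K)`) with a 13-variant registry, heterozygous
  binomial tetramer mixing, leak/noise/capacitance artifacts and cohort
  generation — the synthetic data source the whole pipeline is exercised
  against.

## Worked example

```python
import hergkit
from hergkit.model import WT_GATING, NOISELESS_CELL, simulate_current
from hergkit.analysis import analyse_optimised
from hergkit.variants import make_variant_params

proto = hergkit.build_optimised_protocol()
wt = analyse_optimised(simulate_current(WT_GATING, proto, NOISELESS_CELL), proto)
d591h_gating = make_variant_params("D591H").to_gating(WT_GATING)
d = analyse_optimised(
    simulate_current(d591h_gating, proto, NOISELESS_CELL, variant="D591H"), proto
)
```

prints, via the summary fields of the two `PhenotypeResult` objects:

```
WT   activation  : V1/2 =  -19.7 mV, k = 11.8 mV
WT   inactivation: V1/2 =  -83.9 mV, k = 18.1 mV
WT   density     : 170 pA/pF; repolarisation power 0.294 pC/pF
D591H inactivation: V1/2 =  -65.9 mV, k = 22.2 mV
D591H/WT repolarisation power ratio: 2.66
```

The WT Boltzmann parameters recover the calibration of the simulator
(activation −19.5/11.6 mV, inactivation −83.6/17.8 mV) through the entire
measurement chain — tail extrapolation, relief correction, deactivation
compensation, fitting — which is the package's central self-consistency
check.  The D591H row shows the short-QT phenotype: a +17 mV depolarising
shift of steady-state inactivation that turns into a 2.7-fold *gain* of
repolarisation power under AP clamp, even though its peak current density
is WT-like.

The same registry drives trafficking and reporting:

```python
from hergkit.trafficking import trafficking_cohort
_, mean_pct = trafficking_cohort("WT", n_cells=18, seed=1)
# 33.6% fluorescence variation (calibrated cohort mean 35.1%)

from hergkit.pipeline import RunConfig, run_pipeline
run_pipeline(RunConfig(variants=list(hergkit.VARIANT_NAMES), seed=1,
                       out_dir="hergkit-run"))
# writes report.csv: one row per variant with modelling, repolarisation
# and trafficking severity scores, e.g.  R35W -> 4 / 3 / 1
```

A `hergkit` command-line interface wraps the same functions
(`hergkit protocol build`, `simulate`, `analyze`, `traffic simulate|quantify`,
`score-structure`, `report`, `run`).

## Layout

| module | contents |
| --- | --- |
| `hergkit.protocols` | voltage-protocol construction, AP template, junction correction |
| `hergkit.model` | gating model, simulator, tetramer mixing, cohort generator |
| `hergkit.variants` | calibrated 13-variant registry and metadata |
| `hergkit.analysis` | automated trace analysis and QC |
| `hergkit.trafficking` | pHluorin quench quantification and synthesis |
| `hergkit.structscore` | substitution tables, rotamer clash scoring |
| `hergkit.report` | severity bins and the pathogenicity report |
| `hergkit.io`, `hergkit.cli`, `hergkit.pipeline` | file formats, CLI, end-to-end runs |

See `docs/methods.md` for the model, the analysis corrections, calibration
choices and known limitations.
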