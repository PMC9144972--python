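# phagekit

Quantitative characterization of bacteriophages from routine wet-lab
readouts, built around the published characterization of the temperate
*Burkholderia cepacia* complex podophage JC1 (genome accession
OM283127).  For microbiologists who have plate-reader kill curves, spot
titrations, one-step growth samples, mass-spectrometry protein tables,
genome annotations and larval dose–response counts, and want the derived
numbers — virulence indices, burst sizes, efficiencies of plating, coding
densities, LD50s — computed reproducibly instead of by spreadsheet.

## What it computes

- **Virulence index** from kill curves: local virulence
  `v = 1 − AUC_phage/AUC_control` per MOI over a window ending at the
  onset of stationary phase in the control, and the global virulence
  index `GVI = ∫ v d(log10 MOI) / (log-MOI range)`, 0 (avirulent) to 1
  (complete suppression at every MOI).  For seven decade MOIs
  (log −3..3) the divisor is 6.
- **One-step growth analysis**: latent period (last pre-rise sample) and
  burst size `P/I` from a free-phage titer series.
- **Host range**: efficiency of plating `EOP = PFU_test/PFU_host`,
  qualitative `+/++/+++` clearing scores, and panel summaries.
- **Genome statistics**: direct terminal-repeat trimming, coding density
  (interval union of annotated genes), G+C content, start/stop codon
  tallies, attP/attB-style overlap detection with bounded mismatches, and
  a reading-frame preservation check for integration junctions.
- **Screening tables**: virion-association filtering of proteomics hits
  (≥ 2 unique peptides), LD50 by log-dose interpolation or logistic fit,
  and serum-survival/adsorption normalizations.
- **Simulator**: a seeded bacteria–phage population model (logistic
  growth, Erlang latency, lysogeny, resistant outgrowth, Poisson plating
  and Gaussian OD noise) that generates kill-curve panels, one-step
  series, annotated genomes with planted ground truth, and dose–response
  cohorts, so every estimator is validated by parameter recovery.

The packaged reference tables under `src/phagekit/data/` are verbatim
transcriptions of the published JC1 host-range panel (85 strains), genome
annotation (76 genes over 61,182 bp) and virion proteomics (16 proteins).

## Worked example

```python
from dataclasses import replace
from phagekit.simulate import PRESET_37C, simulate_kill_curves, one_step_assay
from phagekit.virulence import virulence_profile
from phagekit.kinetics import one_step_analysis
from phagekit.hostrange import summarize_host_range
from phagekit.io_tables import load_fixture

panel = simulate_kill_curves(replace(PRESET_37C, seed=1),
                             mois=[10.0**k for k in range(-3, 4)])
prof = virulence_profile(panel, onset="auto")
print(f"window {prof.window}, GVI {prof.gvi:.3f}")

res = one_step_analysis(one_step_assay(seed=1))
print(f"latent {res.latent_period} h, burst {res.burst_size:.0f}")

print(summarize_host_range(load_fixture("table1")))
```

prints

```
window (0.0, 34.0), GVI 0.849
latent 1.0 h, burst 303
HostRangeSummary(total=85, any_activity=50, plaque_forming=29)
```

The simulated 37 °C-like panel reaches stationary phase at 34 h and gives
a global virulence index of 0.85 — strong suppression at every MOI.  The
one-step analysis recovers the simulator's true burst size of 296 within
3% and its 1.5 h latent period to within one 30-minute sampling interval
(the estimate is the last pre-rise sample, hence 1.0 h).  The host-range
summary reproduces the published panel totals: lytic activity on 50 of 85
strains, plaques on 29.

The same steps run as numbered drivers under `analysis/`
(`01_simulate_kill_curves.py` … `05_screens.py`, writing tables to
`results/`) and as a CLI:

```sh
phagekit demo --seed 1
phagekit host-range --table src/phagekit/data/table1.tsv
phagekit sim kill-curves --seed 1 -o panel.csv && phagekit virulence --panel panel.csv --onset 30
```

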