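# foulcast

Analytics for reverse-osmosis (RO) membrane biofouling under residual
coagulants.  When Fe- or Al-based coagulation pretreats an RO feed, the
leftover metal changes how the fouling layer grows; quantifying that
requires several different analyses working together.  `foulcast` packages
them as one tested library for membrane/water-treatment researchers:

- **hydraulics** — flux J = ΔV/(A·ΔT), resistance-in-series
  R_f = R_T − R_m with R_T = ΔP/(μ·J), percent flux decline, and the
  film-model concentration-polarization factor EF = exp(J/k);
- **cos2d** — generalized two-dimensional correlation spectroscopy on FTIR
  time series: synchronous Φ and asynchronous Ψ maps (Hilbert–Noda
  transform), diagonal auto-peak detection, and band appearance order via
  Noda's sign rule;
- **eemfq** — excitation–emission-matrix comparison: per-sample min–max
  normalization FI′ = 0.01 + 0.09·(FI − FI_min)/(FI_max − FI_min),
  fluorescence quotients FQ_A/B = log₁₀(FI′_A/FI′_B), per-pixel one-tailed
  Wilcoxon significance masks, and the three-way Ctrl/Al/Fe
  prominent-region classifier;
- **varpart** — commonality analysis: the full-model R² of flux decline on
  biological/inorganic/organic predictor blocks decomposed into three
  unique, three pairwise and one triadic component (signed, summing to R²
  exactly);
- **micronet** — microbial co-occurrence networks: correlation-threshold
  graphs, greedy modularity modules, within-module degree z-score Zi and
  participation coefficient Pi with the (2.5, 0.62) role thresholds, a
  simplified random-matrix threshold scan, and OTU Venn partitions;
- **synthdata** — seeded generators for all of the above with known ground
  truth (flux curves, multi-band FTIR series, scenario-shifted EEM cubes,
  fouling tables with calibrated commonality structure, abundance tables
  with planted hubs/connectors), so every stage is testable by recovery;
- **pipeline / CLI** — `foulcast run` orchestrates the whole three-scenario
  analysis from one YAML config with deterministic seed fan-out.

## Worked example

```python
import numpy as np
from foulcast import synthdata, hydraulics, cos2d, varpart

# 20-day Fe-scenario flux log (simulated bench cell: 42 cm², 2.2 MPa)
log, truth = synthdata.gen_flux_series("Fe", seed=1)
decline = hydraulics.percent_flux_decline(log["flux_lmh"])
res = hydraulics.resistance_series(log)
print(f"Fe 20-d flux decline: {decline:.1f} %")
print(f"final fouling resistance R_f: {res['R_f'].iloc[-1]:.3e} m^-1")

# FTIR series -> 2D correlation maps -> peaks and band order
series, ftruth = synthdata.gen_ftir_series("Fe", seed=1)
maps = cos2d.correlation_maps(series)
peaks = cos2d.autopeaks(maps.synchronous, maps.wavenumbers)
order = cos2d.sequence_order(maps.synchronous, maps.asynchronous,
                             maps.wavenumbers, [b.center for b in ftruth["bands"]])
print(f"Fe diagonal auto-peaks: {len(peaks)}")

# variance partitioning of flux decline into fouling contributions
ds, _ = synthdata.gen_fouling_dataset("Fe", n=500, seed=1)
part, pct = varpart.variance_partition(ds)
print(f"Fe commonality (% of explained, R^2={part.R2_full:.2f}):")
print("  C_IO = {:.1f}, C_BIO = {:.1f}".format(pct["C_IO"], pct["C_BIO"]))
```

prints

```
Fe 20-d flux decline: 70.9 %
final fouling resistance R_f: 8.673e+14 m^-1
Fe diagonal auto-peaks: 13
Fe commonality (% of explained, R^2=0.89):
  C_IO = 46.1, C_BIO = 38.8
```

Reading it: the Fe scenario loses ~71 % of its initial 25 L m⁻² h⁻¹ flux
over 20 days (the worst of the three scenarios), its fouling layer adds
~9×10¹⁴ m⁻¹ of hydraulic resistance, its fouling layer carries 13 distinct
FTIR bands along the synchronous diagonal (vs 11 for Ctrl/Al) with the
microbial >P=O (1240 cm⁻¹) and Amide II (1585 cm⁻¹) bands appearing first,
and about 46 % of the explained flux-decline variance at this seed comes
from the inorganic–organic interaction with another ~39 % from the triadic
biological–inorganic–organic term — the signature of strongly coupled
fouling.

The same analyses run from the shell:

```bash
foulcast run --seed 1 --out run1          # full three-scenario pipeline
foulcast simulate ftir --scenario Fe --out data
foulcast cos2d data/ftir_Fe.csv
foulcast network abundance.tsv --method spearman --threshold 0.42
```

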