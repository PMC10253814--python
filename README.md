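# fibrilkit

A Python toolkit for the quantitative analysis of amyloid fibrillization
experiments, built around the three measurement modalities commonly combined
in insulin-aggregation studies:

1. **ThT fluorescence kinetics** — Thioflavin T binds the cross-β structure
   of amyloid fibrils; its fluorescence time course traces the sigmoidal
   nucleation–elongation–plateau growth of fibril mass.  fibrilkit fits the
   Boltzmann sigmoid

   ```
   y(t) = y1 + (y2 − y1) / (1 + exp(−2 (t − t_half) / (t_half − t_lag)))
   ```

   and derives the lag time *t_lag*, the fibrillization half-time *t_half*,
   and the apparent aggregation rate constant
   *k_agg = 2/(t_half − t_lag)* (min⁻¹), with standard errors, replicate
   statistics, percent reductions versus a control, and Hofmeister/
   electroselectivity anion-ordering tests.

2. **AFM morphometry** — tapping-mode height maps of fibrils on mica are
   flattened, segmented into grains (8-connected objects above a noise
   threshold), and summarized by the cumulative distribution of per-object
   maximal heights and its **z₉₀%** statistic: the height below which 90% of
   the objects lie.  Lateral association and clustering of fibrils push z₉₀%
   up; thin needle-like fibrils keep it low.

3. **ATR-FTIR amide-I deconvolution** — the 1600–1700 cm⁻¹ band is
   baseline-corrected, Savitzky–Golay smoothed, area-normalized, and
   decomposed into Gaussian sub-bands whose positions report secondary
   structure (β-sheet 1620–1635 & 1690–1700, random/α-helix 1640–1658,
   β-turn 1665–1685 cm⁻¹, side chains 1600–1620 cm⁻¹), yielding per-class
   area percentages.

A synthetic-data module generates all three modalities with known ground
truth (sigmoidal traces with replicate noise, fibril fields with needles,
laterally associated pairs and clusters, spectra as Gaussian band sums), so
every pipeline stage is testable end to end without instrument files.

The package is aimed at protein-aggregation labs that want a scripted,
reproducible alternative to spreadsheet fitting, Gwyddion point-and-click
grain analysis, and Origin peak deconvolution.

## Worked example

Fit the kinetics of an IL-free insulin control (three synthetic replicates,
2% noise, ground truth t_lag = 66.93 min, t_half = 79.42 min):

```python
from fibrilkit import kinetics, synthetic

spec = synthetic.KineticsSpec(t_lag=66.93, t_half=79.42, noise_sd=0.02, seed=1)
traces = synthetic.make_kinetics(spec)
rset = kinetics.aggregate_replicates(traces)
fit = kinetics.fit_sigmoid(rset.mean_trace)
print(f"t_lag  = {fit.t_lag:.2f} +/- {fit.uncertainties['t_lag']:.2f} min")
print(f"t_half = {fit.t_half:.2f} +/- {fit.uncertainties['t_half']:.2f} min")
print(f"k_agg  = {fit.k_agg:.3f} +/- {fit.k_agg_uncertainty:.3f} min^-1")
```

prints

```
t_lag  = 67.10 +/- 0.21 min
t_half = 79.52 +/- 0.10 min
k_agg  = 0.161 +/- 0.002 min^-1
```

i.e. the generating parameters are recovered within their standard errors,
and the rate constant matches the 2/(79.42 − 66.93) = 0.160 min⁻¹ of the
reference control condition.

A full three-modality study runs from the command line:

```sh
fibrilkit simulate --out study --seed 1            # synthetic data + manifest
fibrilkit study study/manifest.yaml --out report --seed 1
fibrilkit report report                            # print the tables
```

The report directory contains a kinetics table (t_lag, t_half, k_agg ±
errors per condition), a morphometry table (z₉₀% ± bootstrap uncertainty),
a secondary-structure table, anion-ranking verdicts per concentration, and
run metadata (seed, config hash) sufficient to reproduce the run
byte-for-byte.

Reference summary tables for insulin fibrillization in five
1-ethyl-3-methylimidazolium (EMIM) ionic liquids — kinetic parameters,
z₉₀% values, and secondary-structure contents — ship with the package
(`fibrilkit.datasets`) and drive the worked examples and simulation presets.

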