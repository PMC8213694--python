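# vegcoupling

Tools for asking whether **water constraints on vegetation growth are
changing** in gridded monthly records. The pipeline standardizes a
vegetation indicator into per-calendar-month z-score anomalies
`A_{j,i} = (x_{j,i} − mean_j)/sd_j`, builds the Standardized
Precipitation–Evapotranspiration Index (SPEI) at 1–24-month timescales from
`D = P − PET` via an unbiased-PWM log-logistic fit and
`SPEI = Φ⁻¹(F(D_k))`, and then, cell by cell:

* classifies **water-deficit** regimes (growing-season Spearman rho > 0,
  p < 0.05, vegetation limited by water scarcity) vs **water-surplus**
  regimes (rho < 0, p < 0.05, growth favoured by drier conditions);
* tracks coupling and regime **area fractions through 5-year moving
  windows** (30 windows for 1982–2015) and tests their trends with both an
  OLS slope t-test and the tie-corrected, continuity-corrected
  **Mann–Kendall** test;
* computes the **minimum water-deficit response time** (smallest
  significant-positive SPEI timescale) and **maximum water-surplus period**
  (largest significant-negative timescale) and their window trends;
* tests the trend of **detrended vegetation anomalies during drought
  months** (SPEI03 < −1.28, scPDSI-type index < −1);
* **attributes** the window coupling series to precipitation, temperature,
  shortwave radiation and CO₂ via an F-test screen, partial Spearman
  correlations (dominant factor = largest |partial r|), and the exact
  Lindeman–Merenda–Gold decomposition of R².

Real satellite/climate archives are out of scope; a first-class synthetic
generator (`vegcoupling.synthetic`) produces gridded inputs with planted,
recorded ground truth — coupling sign, timescale, drift, dominant driver —
so that every stage has a parameter-recovery test. It is aimed at
ecohydrologists and remote-sensing analysts who want the analysis chain as
a reusable, tested library rather than one-off scripts.

## Worked example

Run the full pipeline on the default synthetic study (20×20 grid is the
default; here a 10×10 grid, 1982–2015, mixed planted regimes):

```python
from vegcoupling.pipeline import RunConfig, run_pipeline
from vegcoupling.coupling import area_fraction

cfg = RunConfig(out_dir="demo", seed=42, synth={"ny": 10, "nx": 10})
manifest = run_pipeline(cfg)
r = manifest["_results"]
full, valid = r["coupling_spei03"]["full"], r["dataset"].valid
print("valid cells:", int(valid.sum()))
print("deficit fraction: %.3f" % area_fraction(full.cls, "deficit", valid))
print("surplus fraction: %.3f" % area_fraction(full.cls, "surplus", valid))
```

prints

```
valid cells: 95
deficit fraction: 0.400
surplus fraction: 0.326
```

— of the 95 valid cells, 40.0% correlate significantly positively with
3-month SPEI (water-deficit regime) and 32.6% negatively (water-surplus),
close to the planted 45%/35% mix given the 5% significance screen. The run
directory contains the NetCDF maps (coupling, response times, attribution),
CSV window series (`area_fractions_spei03.csv`, drought anomaly series and
trends), the verbatim config, the ground-truth sidecar, and a JSON
manifest; rerunning with the same config and seed reproduces every file
byte-for-byte.

The recovery experiments are callable directly, e.g.

```python
from vegcoupling import experiments as E
print(E.coupling_trend_recovery(seed=1))
```

```
{'drift_detection_rate': 0.975, 'stationary_trend_rate': 0.03, 'n_windows': 30}
```

— a planted coupling drift of 0.2 → 0.8 at noise sd 0.3 is detected as a
significant positive window-rho trend in 97.5% of 200 cells, while
stationary coupling on independent windows triggers 3%.

The same stages are available from the shell:

```bash
vegcoupling synth --seed 1 --out-dir run/
vegcoupling indices --timescales 1-24 --out-dir run/
vegcoupling couple --index spei03 --window 5 --season 4-10 --out-dir run/
vegcoupling run --config config.yaml --out-dir run/   # everything at once
```

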