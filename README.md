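# leafrefix

Estimation of Farquhar–von Caemmerer–Berry (FvCB) photosynthesis parameters
and mesophyll resistance from A/Ci gas-exchange curves, computation of the
percentage of (photo)respiratory CO2 refixed inside the leaf from a
resistance-partition model, and the downstream comparative statistics
(two-factor ANOVA, Tukey HSD letter displays, nested OLS models) — together
with a synthetic study generator that reproduces the shape of a
6-species × 3-season woody-plant field campaign.

## What it does

- **`leafrefix.fvcb_refix`** — forward FvCB model coupled to mesophyll
  resistance (`Cc = Ci − rm·A` solved as a quadratic per limitation state),
  the two-flux refixation fraction
  `P_r = (r_wp + r_sc) / ((r_wp + r_sc) + (r_ch + k⁻¹))`,
  carboxylation resistance `k⁻¹ = Cc / Vc`, and all unit conversions
  (molar ↔ pressure-based resistances, stomatal conductance → CO2
  resistance).
- **`leafrefix.aci_fit`** — the inverse problem: enumerate every contiguous
  rubisco → RuBP → TPU segmentation of a Ci-sorted curve, fit each by
  bounded least squares with an analytic Jacobian, and keep the
  minimum-SSE *admissible* fit (assigned states must be the minimum of the
  three candidate rates at every point). Derived per-leaf quantities:
  A_max, stomatal resistance and P_r at the first 400-ppm record.
- **`leafrefix.stats_pipeline`** — LMA / water-content arithmetic,
  two-factor ANOVA (Type-II SS, Shapiro–Wilk screening with automatic
  log/rank transformation), Tukey HSD with compact letter displays, the
  three nested OLS models of P_r (rm; rm+rs; rm+rs+LMA) and per-species
  simple regressions.
- **`leafrefix.synthetic_data`** — seeded generator of study-shaped curves
  and trait tables (six calibrated species profiles, the 10-step CO2
  sequence 400, 300, 200, 100, 50, 400, 600, 800, 1000, 1200 ppm,
  correlated rm/LMA/Tcw draws, Gaussian measurement noise on A).
- **`leafrefix.io_cli`** — canonical gas-exchange CSV (read/write with
  validation), YAML run configuration, and the `leafrefix` command-line
  interface.

## Command line

```sh
leafrefix all --seed 7 --out results/run7          # end-to-end
leafrefix simulate --seed 7 --out results/study    # synthetic study only
leafrefix fit --input results/study/gas_exchange.csv --out results/fits.csv
leafrefix refix --fits results/fits.csv --phi-wall 0.3 --out results/fits_03.csv
leafrefix stats --fits results/fits.csv --traits results/study/traits.csv \
    --out results/stats
leafrefix report --workdir results/run7 --out results/run7/report.txt
```

Runs are reproducible: a single master seed drives all randomness, and the
run manifest (seed + design + profile hash) regenerates every output
byte-identically. Options such as the rm wall/chloroplast split
(`phi_wall`), kinetic constants, study design and fitter tolerances are
configurable through `--config config.yaml`.

Exit codes: `0` ok, `1` data error, `2` configuration/usage error.

## Units

Partial pressures in Pa (O2 in kPa), rates in µmol m⁻² s⁻¹, resistances in
m² s Pa µmol⁻¹. CO2 mole fractions in CSV files are ppm; the conversion
`Ci_Pa = Ci_ppm × 10⁻⁶ × P` uses each record's own atmospheric pressure.
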