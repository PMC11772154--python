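# bogflux

Carbon-water flux analysis for peatland eddy-covariance towers: derive
micrometeorological quantities from weekly records, compute drought
indicators, infer time-varying causal structure with empirical dynamic
modelling, and attribute photosynthesis limitation to lagged soil-moisture
dynamics — all exercisable end-to-end on a synthetic bog generator with
known causal structure.

## Modules

| module | contents |
|---|---|
| `bogflux.synthetic` | coupled logistic map pair; weekly bog generator (seasonal drivers, drought years, plug-flow soil-water memory, VPD down-regulated GPP with a soil-moisture limitation threshold); exposed ground truth |
| `bogflux.micromet` | psychrometrics, Penman PET with the `2.626 + 1.381 u` wind function, aerodynamic conductances from `u*`/`u`, Penman-Monteith inversion for bulk surface conductance, evaporative fraction |
| `bogflux.drought` | moisture coefficient (ET/PET, 0.6 weekly stress cut-off), SPEI via a log-logistic fit with unbiased probability-weighted moments, fixed-threshold annual high/low classification |
| `bogflux.edm` | time-delay embedding, simplex projection (E selection), S-maps (per-week interaction strengths), convergent cross mapping with `sqrt((1-rho^2)/(N-3))` standard errors |
| `bogflux.attribution` | 52-bin weekly aggregation and bookkeeping, lagged cross-correlation with Fisher-z confidence intervals, segmented GPP-SWC breakpoint estimation (grid search + AIC guard + bootstrap CI), redundancy analysis |
| `bogflux.pipeline` / `bogflux.cli` | seeded end-to-end orchestration and the `bogflux` command-line interface |

## CLI

```bash
bogflux simulate --seed 42 --out weekly.csv        # synthetic weekly table
bogflux derive weekly.csv --out derived.csv        # + PET, GAH, GSW, EF, ET
bogflux drought derived.csv --out drought.csv --classes-out years.csv
bogflux edm derived.csv --out-dir edm_out          # simplex + CCM + S-maps
bogflux attribute derived.csv --out attr.json      # lag test + breakpoint
bogflux run-all --seed 42 --out-dir run_out        # everything, one summary
```

Simulation settings can be supplied as a flat YAML file via `--config`
(keys mirror `bogflux.synthetic.SimConfig`).

## Notes on conventions

* Weeks are 52 exact seven-day bins per calendar year anchored at 1
  January; trailing year days fold into bin 52.
* The W m-2 to MJ m-2 day-1 factor (0.0864) is applied in exactly one
  place (`bogflux.micromet.WM2_TO_MJ_DAY`).
* Physically inconsistent weeks (negative surface conductance, zero
  denominators) are flagged as NaN, never clipped.
* Cross mapping in the pipeline runs on weekly-climatology anomalies with
  an embedding-span Theiler window; the shared annual cycle otherwise
  saturates cross-map skill at tiny libraries and masks convergence.
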