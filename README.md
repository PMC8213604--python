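# bioclimdyn

Analysis pipeline for long monthly meteorological records (sunshine duration,
precipitation, air temperature): slow/fast signal decomposition,
autoregressive modelling of the fast component, reconstruction of the slow
component as a 3-D complete-cubic polynomial ODE system fitted in phase
space, stability/limit-cycle analysis of the reconstructed system, and UTCI
(Universal Thermal Climate Index) bioclimate series under constant wind
scenarios.

## Modules

| module | what it does |
| --- | --- |
| `bioclimdyn.series` | `MonthlySeries` container and the canonical CSV dialect (`year,month,sunshine_h,precip_mm,temp_c[,vapour_hpa][,wind_ms]`) |
| `bioclimdyn.synthetic` | synthetic datasets with known ground truth: a benchmark Hopf-plus-slaved-variable ODE trend (642-month limit cycle, exactly representable in the cubic basis), Wroclaw-anchored seasonal profiles, AR noise |
| `bioclimdyn.decompose` | ten-year symmetric moving average + zero-phase Butterworth low-pass (cutoff 0.0038 month^-1) slow trend, per-calendar-month seasonal profile, standardized correlated residual |
| `bioclimdyn.ar` | ACF/PACF correlogram, PACF-run order selection, Yule-Walker AR(p) fitting, residual whiteness, seeded simulation |
| `bioclimdyn.trajectory` | phase-space trajectory method: 20-monomial cubic vector fields, doubling-horizon quality function, ridge-regularized derivative-regression initialization, least-squares refinement, stability screening, grid search |
| `bioclimdyn.dynamics` | multi-start damped-Newton equilibrium finding, analytic Jacobians, focus/node/saddle classification, long-term runs, limit-cycle period estimation |
| `bioclimdyn.bioclimate` | Tetens vapour pressure, sunshine-based cloudiness, mid-month solar altitude, absorbed solar radiation, longwave budget, mean radiant temperature, the operational UTCI polynomial, scenario series and comparisons |
| `bioclimdyn.pipeline` / `bioclimdyn.cli` | stage orchestration with on-disk artifacts and a `click` CLI |

## CLI

```bash
# generate the default 1891-2007 synthetic dataset
bioclimdyn simulate --seed 1 --out data/

# individual stages
bioclimdyn decompose --input data/input.csv --out run/
bioclimdyn fit-ar    --input data/input.csv --out run/
bioclimdyn fit-ode   --input run/slow.csv   --out run/
bioclimdyn analyze   --model run/ode_model.json --input run/slow.csv --out run/
bioclimdyn utci      --input data/input.csv --wind 0.5 --out run/

# everything at once (synthetic input unless --input is given)
bioclimdyn run-all --seed 1 --out run/
```

Every subcommand accepts `--seed`, `--out` and `--log-level`; `run-all`
writes a `report.json` whose numbers are fully recomputable from the config
snapshot stored next to it.

## Notes

- The default synthetic trend starts exactly on the benchmark limit cycle;
  use `synthetic.identification_start()` for coefficient-identification
  experiments (an on-cycle trajectory is algebraically degenerate for the
  monomial basis).
- UTCI validity (T in [-50, 50] degC, wind in [0.5, 17] m/s, Tmrt - T in
  [-30, 70] K) is enforced strictly in `bioclimate.utci`; only the scenario
  layer raises sub-0.5 m/s winds to the validity floor.
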