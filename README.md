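# vom

A coupled multi-layer soil water balance and two-big-leaf vegetation
simulator in which vegetation properties self-optimize to maximize Net
Carbon Profit (NCP = CO₂ uptake minus foliage/wood/root maintenance costs),
plus the elevated-CO₂ experiment protocol that separates medium-term from
long-term vegetation responses.

## What's inside

| module | contents |
| --- | --- |
| `vom.forcing` | synthetic daily weather generator, daily CSV IO, hourly disaggregation (even rain, energy-conserving half-sine irradiance, dawn/afternoon temperature sinusoid), PPFD conversion (4.57×10⁻⁶ mol J⁻¹) |
| `vom.soilwater` | van Genuchten–Mualem hydraulics, 0.5 m layered rectangular soil block, explicit Darcy redistribution, infiltration/runoff, Dupuit-style lateral drainage, soil evaporation; texture and site presets |
| `vom.roots` | vertical fine-root profiles, soil+radial resistance network, root-collar potential solve, maximum-supply cap, root area index |
| `vom.canopy` | electron-transport-limited photosynthesis, λ(soil suction) water-use functions, closed-form hourly stomatal optimum (∂E_t/∂A_g = λ), two-big-leaf canopy with the M_A,s + M_A,p ≤ 1 cover constraint |
| `vom.ncp` | daily carbon accounting and day-by-day hill-climbing of J_max25, seasonal cover and per-layer root areas on finite-difference NCP sensitivities |
| `vom.sce` | shuffled complex evolution (SCE-UA) global maximizer, deterministic under a fixed seed |
| `vom.experiment` | long-term (SCE at each CO₂ level) vs medium-term (frozen constants) protocol at 317/350/380 ppm, last-N-year summary tables, relative CO₂ sensitivities |
| `vom.simulate` / `vom._kernels` | the fused hourly/daily loop (numba-compiled; a 6-year hourly run takes ~0.3 s) |

## CLI

```bash
# synthetic daily weather
synthgen --years 10 --seed 1 --out daily.csv
synthgen --spec climate.yaml --years 30 --seed 1 --out daily.csv

# print a config template with every default
vom config --defaults > run.yaml

# one simulation with fixed long-term parameters
vom simulate --config run.yaml --out run/

# SCE optimization of the six long-term constants at one CO2 level
vom optimize --config run.yaml --ca 317 --out optim/

# the full CO2 x mode matrix on the configured sites; writes
# summary (absolute at baseline + % deviations) and sensitivity tables
vom experiment --config protocol.yaml --out exp/
vom report --runs exp/
```

## Notes

- Years are 365 days (no leap days); rain is spread evenly over 24 h.
- Water-balance audit: every run reports |ΣP − ΣQ − ΣE_T − Δstorage|,
  which closes to ~10⁻¹² relative.
- The desk-scale experiment protocol (synthetic sites, 4–6 forcing years,
  a few hundred SCE evaluations) is sized for CI; the full multi-decadal
  protocol is reachable through configuration.
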