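# telemap

Bayesian spatial small-area analysis of telehealth use.

Health systems want to know *where* telehealth is underused and *which
community characteristics* travel with adoption — broadband access,
deprivation, age structure, rurality. Claims databases give per-area counts
of telehealth users; census-style tables give area covariates. Raw
small-area rates are noisy and spatially correlated, so `telemap` fits the
standard disease-mapping workhorse, the Besag–York–Mollié (BYM) model:

    Y_i ~ Poisson(E_i · exp(β0 + x_i'β + u_i + v_i))

where `Y_i` counts unique telehealth patients in area *i*, `E_i` is the
area population (log offset), `u` is a spatially structured random effect
with an intrinsic CAR prior over the queen-contiguity graph of the area
polygons, and `v` is an unstructured iid effect. Exponentiated
coefficients are relative risks (RR) per 1 SD of the standardized
covariate. Inference is by a validated Metropolis-within-Gibbs sampler;
model choice uses DIC; per-area *exceedance probabilities* — the posterior
probability an area's fitted rate falls below a fraction of the
state-average rate — map likely underuse.

The package is aimed at health-services and spatial-epidemiology analysts.
Because claims data are never public, a first-class synthetic-data module
generates area lattices, CAR-distributed effects, Poisson panels and
visit-level records (with injectable invalid records), so the entire
pipeline is testable end to end and parameter recovery can be measured
against known truth.

## Worked example

```python
import numpy as np
import telemap as tm

# a simulated "state": 10x10 areas, two covariates, known truth
lattice = tm.generate_grid_lattice(10, 10, seed=42)
cfg = tm.SimulationConfig(n_rows=10, n_cols=10, beta=(0.3, -0.2), seed=42)
adjacency = tm.queen_adjacency(lattice)
panel = tm.simulate_area_panel(lattice, cfg, ["pct_broadband", "pct_over_65"],
                               adjacency=adjacency)

spec = tm.ModelSpec(("pct_broadband", "pct_over_65"),
                    include_structured=True, include_unstructured=True)
samples = tm.fit_bym_poisson(panel, adjacency, spec, tm.Priors(),
                             tm.McmcConfig(n_iterations=8000, n_burnin=3000,
                                           seed=1))
print(tm.summarize_rr(samples).round(3))
exc = tm.exceedance_probabilities(samples, panel, threshold_fraction=0.5)
print("areas with P(rate < 50% of state mean) > 0.8:",
      int((exc['probability'] > 0.8).sum()))
```

Output:

```
       covariate     rr  rr_lower  rr_upper
0  pct_broadband  1.487     1.326     1.661
1    pct_over_65  0.772     0.684     0.862
```

```
areas with P(rate < 50% of state mean) > 0.8: 29
```

The broadband RR of 1.49 means a one-SD better-connected area has ~49%
higher telehealth use in this realisation (generating truth e^0.3 ≈ 1.35,
inside the interval); the over-65 RR below 1 reproduces the simulated
negative age effect (e^-0.2 ≈ 0.82, also covered). With random-effect sd
≈ 0.5 on the log scale, rates vary several-fold across areas, so 29 of the
100 areas are confidently below half the state mean — in a real analysis
these would be drawn as a choropleth from the exported GeoJSON.

The same flow runs from the shell:

```bash
telemap simulate --rows 10 --cols 10 --seed 42 --out demo/
telemap fit --panel demo/panel.csv --lattice demo/lattice.geojson \
            --out demo/posterior.json
telemap run-all config.yaml       # full multi-year pipeline + manifest
```

Descriptive helpers cover the record level: cohort filters with a
conservation-checked ledger, unique-patient use rates, annual
telehealth-visit shares by rurality class, a Cochran–Armitage trend test,
and per-year top-k diagnosis rankings.

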