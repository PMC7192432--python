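# dfakit

Dynamic factor analysis (DFA) for multivariate ecological monitoring time
series, built for questions like: *do dozens of plankton biomass series
observed at stations across a sea share a few common interannual trends —
and are those trends organised by taxonomy, by geography, or by climate?*

DFA is a state-space dimension-reduction model. A small number *m* of
latent trends evolve as random walks and each observed (z-scored) series
loads linearly on them:

```
x_t = x_{t-1} + w_t,           w_t ~ MVN(0, I_m)
y_t = Z x_t + D d_t + v_t,     v_t ~ MVN(0, R)
```

with `Z` the n × m loading matrix, `d_t` an optional covariate (e.g. a
climate index) and `R` a structured observation covariance encoding the
hypothesis about unexplained variance (shared, per-series, shared with
covariance, or grouped by class/station). Candidate specifications —
trend count × R structure × covariate handling — are fitted by
maximum likelihood (Kalman smoother + accelerated EM, multiple random
starts) and compared by AICc, where n counts non-missing observation
cells. Post-hoc diagnostics include per-series r², residual checks, and
Spearman correlations against environmental series whose degrees of
freedom are deflated for lag-1 autocorrelation (modified Chelton
correction: `1/N* = 1/N + (2/N)·r_x(1)·r_y(1)`).

The package covers the full workflow: a synthetic-data generator that
emulates a Baltic-style monitoring panel (17 stations × 4 phytoplankton
classes, 34 years, 20–33 observed years per station, zero-inflated
biomass, whole-year class absences), preprocessing from long-format
sample tables (same-day averaging, July–August means, dominant-taxa
filtering, zero replacement, ln + z-scoring), model fitting and
selection, diagnostics, and a sensitivity analysis that masks influential
years and refits. See `docs/methods.md` for the full model and the
numerical choices.

## Worked example

Fit a small model grid to a simulated 6-station × 2-class panel whose
truth has two common trends crossing geography and class:

```python
import dfakit as dk
from dfakit.pipeline import RunConfig, run_class_analysis

cfg = RunConfig(
    mode="class",
    simulation=dk.SimulationConfig(
        n_stations=6, classes=("cyanobacteria", "cryptophytes"), T=34,
        m_true=2, loading_scheme="mixed", seed=11,
    ),
    specs=[dk.ModelSpec(m=1, r_structure="diagonal-equal"),
           dk.ModelSpec(m=2, r_structure="diagonal-equal"),
           dk.ModelSpec(m=2, r_structure="grouped-by-class")],
    n_starts=4, max_iter=1000, seed=11, out_dir="runs/demo",
)
out, sel = run_class_analysis(cfg)
print(sel.table[["r_structure", "trends", "parameters", "N",
                 "loglik", "AICc", "dAICc", "support"]].to_string(index=False))
```

prints

```
     r_structure  trends  parameters   N      loglik       AICc     dAICc     support
grouped-by-class       2          25 326 -327.847986 710.029305  0.000000      strong
  diagonal-equal       2          24 326 -338.643085 729.272881 19.243576 very little
  diagonal-equal       1          13 326 -351.102032 729.370730 19.341425 very little
```

The 2-trend model with class-grouped variances wins decisively (the next
model is ~19 AICc units behind — "very little" support), matching how
the data were generated. `N = 326` is the number of non-missing
observation cells; `parameters` counts free loadings (n·m − m(m−1)/2,
because of the identifiability zeros), variances and covariate effects.
The run directory also receives varimax-rotated trends and loadings,
per-series r² (`diagnostics.txt` reports the overall r² = 0.65 here),
and climate correlations with effective-df p-values, e.g.

```
 trend variable      rho  N     n_eff        p
     1  climate 0.586555 34 18.343701 0.009688
     2  climate 0.102215 34 17.533300 0.691018
```

— trend 1 tracks the regime-shifting index (p computed on ~18 effective
observations rather than the nominal 34), trend 2 does not.

The same workflow is scriptable from the shell:

```
dfakit simulate --config sim.json --seed 1 --out data/
dfakit run-all --config run.yaml --seed 1 --out runs/full
dfakit sensitivity --config run.yaml --mask-years 1990,2008 --out runs/sens
```

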