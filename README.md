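# borealprio

Uncertainty propagation through spatial conservation prioritisation of
boreal forests for biodiversity and carbon.

Spatial conservation plans are built from modelled inputs — stand
growth and carbon-balance simulations, habitat-suitability surfaces —
and every input carries estimation error. This package implements the
full analysis chain needed to ask *how much that error matters for the
plan*: it generates synthetic forest landscapes with realistic input
error structure, propagates stochastic perturbations through a
surrogate growth/carbon engine and parametric habitat models, ranks
grid cells with an additive-benefit-function prioritiser, and
attributes the variance of the resulting rankings back to the input
variables. It is aimed at conservation scientists and methodologists
who want a fully testable, data-free sandbox for prioritisation
uncertainty analysis.

## The method

**Prioritisation.** Each feature *j* (six bird-species suitability
surfaces, four carbon layers) contributes an additive benefit
*v<sub>j</sub>*(*r<sub>j</sub>*) = *r<sub>j</sub>*<sup>*z*</sup>, where
*r<sub>j</sub>* is the fraction of the feature's total still retained.
*z* = 0.25 for biodiversity (the species–area relationship) and
*z* = 1 for carbon. Cells are removed greedily by smallest aggregate
marginal loss Σ<sub>j</sub> *w<sub>j</sub>* [*r<sub>j</sub>*<sup>z</sup> −
(*r<sub>j</sub>* − *p<sub>ij</sub>*/*P<sub>j</sub>*)<sup>z</sup>]; a
cell's priority rank is its removal position divided by *N*, and the
top-ranked 10 % form the candidate conservation solution.

**Uncertainty ensemble.** A baseline run plus *N* (default 50)
iterations, each redrawing: segment-level structural variables from a
multivariate normal error model with rank-preserving quantile matching
onto bounded marginals; the site-fertility class from an ordered
probit; stand age from N(μ, (0.1 μ)²); a whole growth-parameter vector
bootstrapped from a correlated pool; and annual weather modifiers from
a 46-year pool.

**Attribution.** Per iteration, feature (or forest-variable) values
and priority ranks at 10 000 sampled cells enter a canonical
correlation analysis, summarised per variable by the Stewart–Love
redundancy index Rd(*v*) = Σ<sub>k</sub> loading(*v*,*k*)² ρ<sub>k</sub>²
∈ [0, 1] — the share of the variable's variance reproducible from the
ranking side.

See `docs/methods.md` for the model equations, parameter defaults and
design rationale.

## Worked example

```python
import numpy as np
from borealprio import LandscapeConfig
from borealprio.ensemble import EnsembleConfig, default_bundle, run_ensemble
from borealprio.metrics import rank_stats, inclusion_probability, regional_summary

config = LandscapeConfig(grid_rows=60, grid_cols=60, n_segments=250)
bundle = default_bundle(config, seed=42)
ens = run_ensemble(bundle, EnsembleConfig(n_iterations=10,
                                          variants=("combined",),
                                          master_seed=42))

summary = regional_summary(ens)
base = summary[summary.iteration == "baseline"].set_index("period")
print(base[["mean_volume_m3ha", "tree_c_mt", "sink_mt_per_yr",
            "habitat_PICTRI"]].round(4))

ranks = [it.rankings[("T1", "combined")] for it in ens.iterations]
stats = rank_stats(ranks)
prob = inclusion_probability([it.top_masks[("T1", "combined")]
                              for it in ens.iterations])
print(f"median rank SD: {np.median(stats.sd):.3f}")
print(f"cells ever in top 10%: {(prob > 0).sum()} of {int(ens.land_mask.sum())}")
```

prints

```
        mean_volume_m3ha  tree_c_mt  sink_mt_per_yr  habitat_PICTRI
period
T1              186.4442     0.1935          0.0034          0.4047
T2              210.4769     0.2187          0.0032          0.5181
T3              237.7142     0.2471          0.0025          0.6626
median rank SD: 0.101
cells ever in top 10%: 574 of 3240
```

Reading the numbers: with no harvest, mean stand volume grows from 186
to 238 m³ ha⁻¹ across the three periods, tree carbon rises from 0.19
to 0.25 million t over the 3 240-cell synthetic region, and the annual
carbon sink shrinks (0.0034 → 0.0025 million t C yr⁻¹, −25 %) as
stands mature; suitable habitat for the three-toed woodpecker expands
with them. Across the 10 perturbed iterations a typical cell's
priority rank moves by about ±0.1, and 574 cells — 1.8 times the size
of the 324-cell top set — land in the top 10 % at least once.

A command-line layer exposes the same pipeline
(`borealprio generate | rank | run-ensemble | metrics | attribute`)
with ESRI ASCII grid rasters, YAML configuration and resumable
per-iteration outputs.

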