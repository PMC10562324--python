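"""Ensemble orchestration: baseline plus N perturbed pipeline runs.

One iteration = draw every enabled uncertainty source once (site class,
structural errors, stand age, parameter vector, weather series), run
the growth/carbon simulation over the full horizon, build the habitat
and carbon features for each averaging period, and rank cells under up
to three prioritisation variants (combined, biodiversity-only,
carbon-only).  Site class and the parameter vector are drawn at the
start of an iteration and held constant across its whole simulation.

All randomness derives from per-iteration, per-sampler substreams of a
single master seed; iterations are mutually independent.  The random
tie-break permutation of the ranker is drawn once per ensemble, so
identical inputs yield identical rankings across iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import landscape as ls
from .growth import (GrowthParams, PeriodSpec, SimulationResult,
                     default_periods, run_simulation)
from .habitat import SpeciesSpec, default_species_specs, suitability
from .prioritize import (BIODIVERSITY, CARBON, BenefitSpec, FeatureStack,
                         PriorityRanking, rank_abf, top_fraction)
from .rng import key_to_int

__all__ = [
    "UncertaintySpec",
    "EnsembleConfig",
    "PipelineBundle",
    "IterationResult",
    "EnsembleResult",
    "build_feature_stack",
    "default_bundle",
    "run_baseline",
    "run_iteration",
    "run_ensemble",
]

VARIANTS = ("combined", "biodiversity", "carbon")

CARBON_FEATURES = ("tree_c", "soil_c", "gv_c", "sink")


@dataclass
class UncertaintySpec:
    """All stochastic-perturbation machinery for one ensemble."""

    structural: ls.StructuralErrorModel = field(
        default_factory=ls.default_structural_model)
    probit: ls.SiteTypeProbitModel = field(
        default_factory=ls.default_probit_model)
    age_cv: float = 0.10
    parameter_pool: ls.ParameterPool = field(
        default_factory=ls.default_parameter_pool)
    weather_pool: ls.WeatherPool = field(default_factory=ls.default_weather_pool)


@dataclass
class EnsembleConfig:
    """Iteration count, variant set, and uncertainty-source toggles."""

    n_iterations: int = 50
    variants: Tuple[str, ...] = VARIANTS
    master_seed: int = 0
    top_f: float = 0.10
    batch: Optional[int] = None     # None = ~200 removal passes
    rank_periods: Optional[Tuple[str, ...]] = None  # None = all periods
    # uncertainty-source toggles
    use_structural: bool = True
    use_site_type: bool = True
    use_age: bool = True
    use_parameters: bool = True
    use_weather: bool = True

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        for v in self.variants:
            if v not in VARIANTS:
                raise ValueError(f"unknown variant {v!r}")


@dataclass
class PipelineBundle:
    """Everything needed to run one pipeline realisation."""

    landscape_config: ls.LandscapeConfig
    baseline: ls.ForestState
    static: ls.StaticPredictors
    uncertainty: UncertaintySpec
    growth_params: GrowthParams
    species_specs: Dict[str, SpeciesSpec]
    benefit: BenefitSpec
    periods: PeriodSpec
    start_year: int = 2015
    eval_start_year: int = 2017


def default_bundle(config: Optional[ls.LandscapeConfig] = None,
                   seed: int = 0) -> PipelineBundle:
    """Baseline landscape plus default models for every stage."""
    config = config or ls.LandscapeConfig()
    baseline = ls.generate_landscape(config, seed)
    static = ls.generate_static_predictors(baseline, config, seed)
    return PipelineBundle(
        landscape_config=config,
        baseline=baseline,
        static=static,
        uncertainty=UncertaintySpec(
            probit=ls.default_probit_model(config.n_site_types)),
        growth_params=GrowthParams(n_site_types=config.n_site_types),
        species_specs=default_species_specs(),
        benefit=BenefitSpec(),
        periods=default_periods(),
    )


@dataclass
class IterationResult:
    """Per-period outputs of one pipeline realisation."""

    simulation: SimulationResult
    suitability: Dict[str, Dict[str, np.ndarray]]   # period -> species -> layer
    stacks: Dict[str, FeatureStack]                 # period -> combined stack
    rankings: Dict[Tuple[str, str], PriorityRanking]  # (period, variant)
    top_masks: Dict[Tuple[str, str], np.ndarray]


@dataclass
class EnsembleResult:
    bundle: PipelineBundle
    config: EnsembleConfig
    baseline: IterationResult
    iterations: List[IterationResult]

    @property
    def land_mask(self) -> np.ndarray:
        return self.bundle.baseline.land_mask


def build_feature_stack(period_state: ls.ForestState, carbon, sink: np.ndarray,
                        species_specs: Dict[str, SpeciesSpec],
                        static: ls.StaticPredictors,
                        cell_size: float) -> Tuple[FeatureStack,
                                                   Dict[str, np.ndarray]]:
    """Combined 6 + 4 feature stack for one period; returns (stack, birds)."""
    layers: Dict[str, np.ndarray] = {}
    classes: Dict[str, str] = {}
    birds: Dict[str, np.ndarray] = {}
    for code, spec in species_specs.items():
        layer = suitability(period_state, spec, static, cell_size)
        birds[code] = layer
        layers[code] = layer
        classes[code] = BIODIVERSITY
    carbon_layers = {"tree_c": carbon.tree_c, "soil_c": carbon.soil_c,
                     "gv_c": carbon.gv_c, "sink": sink}
    for name, layer in carbon_layers.items():
        layers[name] = np.clip(layer, 0.0, None)
        classes[name] = CARBON
    stack = FeatureStack.from_layers(layers, classes, period_state.land_mask)
    return stack, birds


def _iteration_seed(master_seed: int, iteration: int) -> int:
    return (key_to_int(master_seed) * 1_000_003 + iteration + 1) % (2**31)


def _auto_batch(n_cells: int) -> int:
    return max(1, n_cells // 200)


def run_iteration(bundle: PipelineBundle, config: EnsembleConfig,
                  iteration: int, perturb: bool = True) -> IterationResult:
    """One pipeline realisation (``perturb=False`` gives the baseline)."""
    state = bundle.baseline
    unc = bundle.uncertainty
    params = bundle.growth_params
    n_years = bundle.periods.last_year - bundle.start_year
    weather = np.ones(n_years)

    if perturb:
        seed = _iteration_seed(config.master_seed, iteration)
        # site class and parameters are sampled once and held constant
        if config.use_site_type:
            state = ls.sample_site_type(state, unc.probit, seed)
        if config.use_structural:
            state = ls.sample_structural_errors(state, unc.structural, seed)
        if config.use_age:
            state = ls.sample_age(state, unc.age_cv, seed)
        if config.use_parameters:
            vec = ls.sample_parameters(unc.parameter_pool, seed)
            params = params.with_multipliers(unc.parameter_pool.names, vec)
        if config.use_weather:
            weather = ls.sample_weather(unc.weather_pool, n_years, seed)

    sim = run_simulation(state, params, weather, bundle.periods,
                         bundle.start_year, bundle.eval_start_year)

    n_land = int(bundle.baseline.land_mask.sum())
    batch = config.batch if config.batch is not None else _auto_batch(n_land)

    suits: Dict[str, Dict[str, np.ndarray]] = {}
    stacks: Dict[str, FeatureStack] = {}
    rankings: Dict[Tuple[str, str], PriorityRanking] = {}
    masks: Dict[Tuple[str, str], np.ndarray] = {}
    labels = config.rank_periods or bundle.periods.labels
    for label in labels:
        stack, birds = build_feature_stack(
            sim.period_states[label], sim.period_carbons[label],
            sim.sink_features[label], bundle.species_specs, bundle.static,
            bundle.landscape_config.cell_size)
        suits[label] = birds
        stacks[label] = stack
        for variant in config.variants:
            if variant == "combined":
                vstack = stack
            elif variant == "biodiversity":
                vstack = stack.subset(BIODIVERSITY)
            else:
                vstack = stack.subset(CARBON)
            # tie-break seed shared by baseline and all iterations
            ranking = rank_abf(vstack, bundle.benefit, batch=batch,
                               seed=config.master_seed)
            rankings[(label, variant)] = ranking
            masks[(label, variant)] = top_fraction(ranking, config.top_f)

    return IterationResult(simulation=sim, suitability=suits, stacks=stacks,
                           rankings=rankings, top_masks=masks)


def run_baseline(bundle: PipelineBundle,
                 config: Optional[EnsembleConfig] = None) -> IterationResult:
    """Unperturbed pipeline run (weather modifier 1 every year)."""
    return run_iteration(bundle, config or EnsembleConfig(), 0, perturb=False)


def run_ensemble(bundle: PipelineBundle,
                 config: EnsembleConfig) -> EnsembleResult:
    """Baseline plus ``n_iterations`` independent perturbed runs."""
    baseline = run_baseline(bundle, config)
    iterations = [run_iteration(bundle, config, i, perturb=True)
                  for i in range(config.n_iterations)]
    return EnsembleResult(bundle=bundle, config=config, baseline=baseline,
                          iterations=iterations)
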