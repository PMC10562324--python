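"""Surrogate stand growth and carbon-balance engine.

Annual, harvest-free stand development: height follows a
Chapman–Richards curve per species and site-fertility class, stepped in
*effective age* so that year-to-year weather modifiers stretch or
shrink each year's progress along the curve; DBH and stem volume follow
height allometries with segment-specific multiplicative offsets so that
perturbations of the initial inventory persist through the simulation.

Carbon bookkeeping is deliberately simple but exactly mass-balanced:

* tree carbon  = volume x wood density x biomass expansion x C fraction,
* soil carbon  = one pool with litter input proportional to tree carbon
  and first-order decay (initialised at steady state),
* ground-vegetation carbon relaxes toward a site-class equilibrium that
  declines with canopy volume (shading),
* NEP          = annual change of the summed pools (g C m-2 yr-1),
  positive = sink, negative = source.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .landscape import ForestState

__all__ = [
    "GrowthParams",
    "CarbonState",
    "PeriodSpec",
    "default_periods",
    "chapman_richards",
    "grow",
    "tree_carbon",
    "init_soil_steady",
    "carbon_step",
    "simulate_carbon",
    "period_average",
    "sink_layer",
    "SimulationResult",
    "run_simulation",
]

KG_PER_HA_TO_G_PER_M2 = 0.1  # 1 kg C ha-1 = 0.1 g C m-2


@dataclass
class GrowthParams:
    """Parameters of the growth/carbon surrogate.

    Species order is (pine, spruce, deciduous); site classes are
    1..n_site_types with 1 the most fertile.
    """

    n_site_types: int = 6
    # Chapman-Richards height curve
    hmax_by_species: Tuple[float, float, float] = (25.0, 28.0, 22.0)
    hmax_site_slope: float = 0.05          # relative per class from 3.5
    k_by_species: Tuple[float, float, float] = (0.035, 0.040, 0.050)  # 1/yr
    shape_m: float = 1.3
    # allometries (height m -> dbh cm, volume m3/ha)
    dbh_coef: float = 1.25
    dbh_exp: float = 1.05
    vol_coef: float = 0.65
    vol_exp: float = 1.85
    # carbon conversion
    wood_density: Tuple[float, float, float] = (0.41, 0.38, 0.49)  # t/m3
    carbon_fraction: float = 0.5
    bef: float = 1.70                      # biomass expansion, incl. roots
    # soil pool
    # the soil pool tracks the *dynamic* fraction of soil carbon; its
    # equilibrium is litter_coef / soil_decay = 1/3 of tree carbon
    litter_coef: float = 0.015             # 1/yr, litter input per tree C
    soil_decay: float = 0.045              # 1/yr
    # ground vegetation (kg C/ha at zero canopy, per site class 1..K)
    gv_base: Tuple[float, ...] = (1800.0, 2000.0, 2400.0, 2800.0, 3200.0, 3600.0)
    gv_shade_volume: float = 400.0         # m3/ha e-folding of shading
    gv_rate: float = 0.10                  # 1/yr approach rate
    # deciduous encroachment
    encroachment_rate: float = 0.004       # fraction/yr toward the cap
    dec_share_cap: float = 0.5

    def __post_init__(self) -> None:
        if self.carbon_fraction <= 0 or self.carbon_fraction >= 1:
            raise ValueError("carbon fraction must be in (0, 1)")
        for r in (*self.k_by_species, self.litter_coef, self.soil_decay,
                  self.gv_rate):
            if r <= 0:
                raise ValueError("all rates must be positive")
        if len(self.gv_base) != self.n_site_types:
            raise ValueError("gv_base length must equal n_site_types")

    def hmax(self, species: np.ndarray, site_type: np.ndarray) -> np.ndarray:
        base = np.asarray(self.hmax_by_species)[species]
        return base * (1.0 + self.hmax_site_slope * (3.5 - site_type))

    def with_multipliers(self, names: Sequence[str],
                         vec: np.ndarray) -> "GrowthParams":
        """Apply a bootstrap multiplier vector from a :class:`ParameterPool`."""
        m = dict(zip(names, vec))
        return replace(
            self,
            k_by_species=tuple(k * m.get("growth_rate", 1.0)
                               for k in self.k_by_species),
            hmax_by_species=tuple(h * m.get("height_asymptote", 1.0)
                                  for h in self.hmax_by_species),
            vol_coef=self.vol_coef * m.get("volume_allometry", 1.0)
            * m.get("crown_base", 1.0),
            litter_coef=self.litter_coef * m.get("litter_rate", 1.0),
            soil_decay=self.soil_decay * m.get("soil_decay", 1.0),
        )


def chapman_richards(age: np.ndarray, hmax: np.ndarray, k: np.ndarray,
                     m: float) -> np.ndarray:
    """Closed-form height at a given age: ``hmax (1 - exp(-k age))^m``."""
    return hmax * (1.0 - np.exp(-k * np.asarray(age, dtype=float))) ** m


def grow(state: ForestState, params: GrowthParams,
         weather: Sequence[float], n_years: int) -> List[ForestState]:
    """Advance the landscape annually; returns ``n_years + 1`` states.

    ``weather[t]`` multiplies year ``t``'s progress along the height
    curve (modifier 1 reproduces the closed form exactly).  Height, DBH,
    volume and age are non-decreasing; the deciduous share drifts toward
    its cap at the encroachment rate.
    """
    weather = np.asarray(weather, dtype=float)
    if len(weather) != n_years:
        raise ValueError("weather series length must equal n_years")

    sp = state.segment_values("species").astype(int)
    st = state.segment_values("site_type").astype(int)
    hmax = params.hmax(sp, st)
    k = np.asarray(params.k_by_species)[sp]
    m = params.shape_m

    h = state.segment_values("height_m").astype(float)
    dbh = state.segment_values("dbh_cm").astype(float)
    vol = state.segment_values("volume_m3ha").astype(float)
    dec = state.segment_values("dec_volume_m3ha").astype(float)
    age = state.segment_values("age_yr").astype(float)

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio_dbh = np.where(h > 0, dbh / (params.dbh_coef * h**params.dbh_exp), 1.0)
        ratio_vol = np.where(h > 0, vol / (params.vol_coef * h**params.vol_exp), 1.0)
        share = np.where(vol > 0, dec / np.maximum(vol, 1e-12), 0.0)

    traj = [state.copy()]
    for t in range(n_years):
        frac = np.clip(h / hmax, 0.0, 1.0 - 1e-12)
        t_eff = -np.log1p(-frac ** (1.0 / m)) / k
        h_new = hmax * (1.0 - np.exp(-k * (t_eff + weather[t]))) ** m
        h = np.maximum(h, h_new)
        dbh = ratio_dbh * params.dbh_coef * h**params.dbh_exp
        vol = ratio_vol * params.vol_coef * h**params.vol_exp
        share = np.where(share < params.dec_share_cap,
                         share + params.encroachment_rate
                         * (params.dec_share_cap - share), share)
        dec = np.minimum(share * vol, vol)
        age = age + 1.0
        traj.append(state.replace_segments(
            height_m=h, dbh_cm=dbh, volume_m3ha=vol,
            dec_volume_m3ha=dec, age_yr=age,
        ))
    return traj


# ---------------------------------------------------------------------------
# carbon


@dataclass
class CarbonState:
    """Per-cell carbon pools (kg C/ha) and annual NEP (g C m-2 yr-1)."""

    tree_c: np.ndarray
    soil_c: np.ndarray
    gv_c: np.ndarray
    nep: np.ndarray

    def total(self) -> np.ndarray:
        return self.tree_c + self.soil_c + self.gv_c


def tree_carbon(state: ForestState, params: GrowthParams) -> np.ndarray:
    """Tree biomass carbon (kg C/ha): volume x density x BEF x C fraction."""
    dens = np.zeros(state.species.shape)
    land = state.land_mask
    dens[land] = np.asarray(params.wood_density)[state.species[land].astype(int)]
    return state.volume_m3ha * dens * params.bef * params.carbon_fraction * 1000.0


def _gv_equilibrium(state: ForestState, params: GrowthParams) -> np.ndarray:
    base = np.zeros(state.site_type.shape)
    land = state.land_mask
    base[land] = np.asarray(params.gv_base)[state.site_type[land].astype(int) - 1]
    return base * np.exp(-state.volume_m3ha / params.gv_shade_volume)


def init_soil_steady(state: ForestState, params: GrowthParams) -> np.ndarray:
    """Soil carbon at steady state with the initial litter input."""
    return params.litter_coef * tree_carbon(state, params) / params.soil_decay


def init_carbon(state: ForestState, params: GrowthParams) -> CarbonState:
    """Initial carbon pools: soil and ground vegetation at equilibrium."""
    tc = tree_carbon(state, params)
    return CarbonState(
        tree_c=tc,
        soil_c=init_soil_steady(state, params),
        gv_c=_gv_equilibrium(state, params),
        nep=np.zeros_like(tc),
    )


def carbon_step(state_t: ForestState, state_t1: ForestState,
                carbon_t: CarbonState, params: GrowthParams) -> CarbonState:
    """One annual carbon update; NEP is the exact pool-sum change."""
    tree1 = tree_carbon(state_t1, params)
    soil1 = (carbon_t.soil_c + params.litter_coef * carbon_t.tree_c
             - params.soil_decay * carbon_t.soil_c)
    gv1 = carbon_t.gv_c + params.gv_rate * (_gv_equilibrium(state_t1, params)
                                            - carbon_t.gv_c)
    if soil1.min() < 0 or gv1.min() < 0:
        raise RuntimeError("carbon pool went negative")  # cannot occur for rates < 1
    nep = ((tree1 + soil1 + gv1) - carbon_t.total()) * KG_PER_HA_TO_G_PER_M2
    return CarbonState(tree_c=tree1, soil_c=soil1, gv_c=gv1, nep=nep)


def simulate_carbon(trajectory: Sequence[ForestState],
                    params: GrowthParams) -> List[CarbonState]:
    """Carbon states along a growth trajectory (index 0 has NEP = 0)."""
    out = [init_carbon(trajectory[0], params)]
    for t in range(1, len(trajectory)):
        out.append(carbon_step(trajectory[t - 1], trajectory[t], out[-1], params))
    return out


# ---------------------------------------------------------------------------
# period averaging and sink rule


@dataclass
class PeriodSpec:
    """Contiguous, non-overlapping averaging periods (label, first, last)."""

    periods: Tuple[Tuple[str, int, int], ...] = (
        ("T1", 2017, 2025), ("T2", 2026, 2033), ("T3", 2034, 2050))

    def __post_init__(self) -> None:
        prev_last = None
        for label, first, last in self.periods:
            if last < first:
                raise ValueError(f"period {label}: last < first")
            if prev_last is not None and first != prev_last + 1:
                raise ValueError("periods must be contiguous and ascending")
            prev_last = last

    @property
    def labels(self) -> Tuple[str, ...]:
        return tuple(p[0] for p in self.periods)

    @property
    def first_year(self) -> int:
        return self.periods[0][1]

    @property
    def last_year(self) -> int:
        return self.periods[-1][2]


def default_periods() -> PeriodSpec:
    return PeriodSpec()


def period_average(trajectory: Sequence[ForestState], periods: PeriodSpec,
                   start_year: int = 2015,
                   carbons: Sequence[CarbonState] | None = None,
                   ) -> Dict[str, Tuple[ForestState, CarbonState | None]]:
    """Arithmetic period means of every annual layer.

    Continuous fields (and carbon pools / NEP) are averaged over the
    period's years; categorical fields come from the period's midpoint
    year.  ``trajectory[i]`` holds the state of year ``start_year + i``.
    """
    out: Dict[str, Tuple[ForestState, CarbonState | None]] = {}
    n = len(trajectory)
    for label, first, last in periods.periods:
        i0, i1 = first - start_year, last - start_year
        if i0 < 0 or i1 >= n:
            raise ValueError(f"trajectory does not cover period {label}")
        idx = range(i0, i1 + 1)
        mid = (i0 + i1) // 2
        fields = {}
        for name in ("height_m", "dbh_cm", "volume_m3ha",
                     "dec_volume_m3ha", "age_yr"):
            fields[name] = np.mean([getattr(trajectory[i], name) for i in idx],
                                   axis=0)
        avg_state = replace(trajectory[mid].copy(), **fields)
        avg_carbon = None
        if carbons is not None:
            avg_carbon = CarbonState(
                tree_c=np.mean([carbons[i].tree_c for i in idx], axis=0),
                soil_c=np.mean([carbons[i].soil_c for i in idx], axis=0),
                gv_c=np.mean([carbons[i].gv_c for i in idx], axis=0),
                nep=np.mean([carbons[i].nep for i in idx], axis=0),
            )
        out[label] = (avg_state, avg_carbon)
    return out


def sink_layer(period_nep: Dict[str, np.ndarray],
               mean_annual_nep: np.ndarray) -> Dict[str, np.ndarray]:
    """Carbon-sink features: zero out cells that are sources on average.

    A cell whose mean annual NEP over the whole evaluated horizon is
    <= 0 (a source, with ties counted as sources) gets value 0 in every
    period's sink feature; other cells keep their period-mean NEP.  The
    unzeroed NEP layers are left untouched for regional flux summaries.
    """
    source = mean_annual_nep <= 0.0
    return {label: np.where(source, 0.0, np.maximum(nep, 0.0))
            for label, nep in period_nep.items()}


# ---------------------------------------------------------------------------
# one full simulation


@dataclass
class SimulationResult:
    """Everything downstream modules need from one growth simulation."""

    period_states: Dict[str, ForestState]
    period_carbons: Dict[str, CarbonState]
    sink_features: Dict[str, np.ndarray]
    mean_annual_nep: np.ndarray


def run_simulation(state: ForestState, params: GrowthParams,
                   weather: Sequence[float], periods: PeriodSpec,
                   start_year: int = 2015,
                   eval_start_year: int = 2017) -> SimulationResult:
    """Grow from ``start_year``, average per period, apply the sink rule.

    The source/sink test averages annual NEP over
    ``eval_start_year .. last period year`` (initiation years excluded).
    """
    n_years = periods.last_year - start_year
    traj = grow(state, params, weather, n_years)
    carbons = simulate_carbon(traj, params)
    avgs = period_average(traj, periods, start_year, carbons)
    i0 = eval_start_year - start_year
    mean_nep = np.mean([c.nep for c in carbons[i0:]], axis=0)
    period_states = {lab: s for lab, (s, _) in avgs.items()}
    period_carbons = {lab: c for lab, (_, c) in avgs.items()}
    sinks = sink_layer({lab: c.nep for lab, c in period_carbons.items()},
                       mean_nep)
    return SimulationResult(period_states=period_states,
                            period_carbons=period_carbons,
                            sink_features=sinks,
                            mean_annual_nep=mean_nep)
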