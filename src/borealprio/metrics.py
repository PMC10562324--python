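"""Across-iteration variability of ranks, forest variables and features.

Per-cell rank statistics (mean, range, population SD), the probability
of a cell falling in the top-ranked fraction, probability-group class
layers for map legends, and per-iteration regional summary tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .habitat import habitat_area
from .prioritize import PriorityRanking

__all__ = [
    "RankStats",
    "rank_stats",
    "inclusion_probability",
    "probability_groups",
    "DEFAULT_PROB_BREAKS",
    "regional_summary",
]

#: default legend breaks for inclusion-probability maps
DEFAULT_PROB_BREAKS = (0.0, 0.02, 0.2, 0.4, 0.6, 0.8, 1.0)


@dataclass
class RankStats:
    """Per-cell rank statistics across iterations (1-D over land cells)."""

    mean: np.ndarray
    range_: np.ndarray
    sd: np.ndarray


def _as_rank_matrix(rankings: Sequence) -> np.ndarray:
    rows = []
    shape = None
    for r in rankings:
        vec = r.rank if isinstance(r, PriorityRanking) else np.asarray(r)
        if shape is None:
            shape = vec.shape
        elif vec.shape != shape:
            raise ValueError("rankings have mismatched geometry")
        rows.append(vec)
    return np.stack(rows)


def rank_stats(rankings: Sequence) -> RankStats:
    """Mean, range (max - min) and population SD of per-cell ranks."""
    mat = _as_rank_matrix(rankings)
    if mat.shape[0] < 2:
        raise ValueError("need at least two iterations")
    return RankStats(
        mean=mat.mean(axis=0),
        range_=mat.max(axis=0) - mat.min(axis=0),
        sd=mat.std(axis=0),     # population SD (descriptive, per cell)
    )


def inclusion_probability(masks: Sequence[np.ndarray]) -> np.ndarray:
    """Fraction of iterations in which each cell is in the top mask."""
    masks = list(masks)
    if not masks:
        raise ValueError("need at least one iteration")
    return np.mean([m.astype(float) for m in masks], axis=0)


def probability_groups(probability: np.ndarray,
                       breaks: Sequence[float] = DEFAULT_PROB_BREAKS,
                       ) -> np.ndarray:
    """Class index per cell by half-open binning [b_k, b_{k+1}).

    The top bin is closed at 1, so a probability of exactly 1 lands in
    the last class.  Class indices run 0 .. len(breaks) - 2.
    """
    breaks = np.asarray(breaks, dtype=float)
    if np.any(np.diff(breaks) <= 0):
        raise ValueError("breaks must be strictly ascending")
    idx = np.searchsorted(breaks, probability, side="right") - 1
    return np.clip(idx, 0, len(breaks) - 2)


def _region_row(iteration_label, period: str, it_result, bundle) -> Dict:
    state = it_result.simulation.period_states[period]
    carbon = it_result.simulation.period_carbons[period]
    sink = it_result.simulation.sink_features[period]
    land = state.land_mask
    cell_area_ha = bundle.landscape_config.cell_size**2 / 1e4
    cell_area_m2 = bundle.landscape_config.cell_size**2

    def total_mt(kg_per_ha: np.ndarray) -> float:
        return float(kg_per_ha[land].sum() * cell_area_ha / 1e9)

    def flux_mt(g_per_m2: np.ndarray) -> float:
        return float(g_per_m2[land].sum() * cell_area_m2 / 1e12)

    row = {
        "iteration": iteration_label,
        "period": period,
        "mean_height_m": float(state.height_m[land].mean()),
        "mean_dbh_cm": float(state.dbh_cm[land].mean()),
        "mean_volume_m3ha": float(state.volume_m3ha[land].mean()),
        "mean_dec_volume_m3ha": float(state.dec_volume_m3ha[land].mean()),
        "mean_age_yr": float(state.age_yr[land].mean()),
        "tree_c_mt": total_mt(carbon.tree_c),
        "soil_c_mt": total_mt(carbon.soil_c),
        "gv_c_mt": total_mt(carbon.gv_c),
        "sink_mt_per_yr": flux_mt(sink),
        "nep_mt_per_yr": flux_mt(carbon.nep),
    }
    for code, layer in it_result.suitability[period].items():
        row[f"habitat_{code}"] = habitat_area(layer, land)
    return row


def regional_summary(result) -> pd.DataFrame:
    """Study-area summary per iteration and period.

    Carbon pools are regional totals in million t C; sink/NEP fluxes in
    million t C per year; forest variables are land-cell means; habitat
    is the suitable fraction of the study area per species.
    """
    periods = [p for p in result.bundle.periods.labels
               if p in result.baseline.suitability]
    rows: List[Dict] = [
        _region_row("baseline", period, result.baseline, result.bundle)
        for period in periods
    ]
    for i, it in enumerate(result.iterations):
        for period in periods:
            rows.append(_region_row(i, period, it, result.bundle))
    return pd.DataFrame(rows)
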