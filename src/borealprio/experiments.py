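"""Controlled synthetic experiments on ranking-uncertainty behaviour.

Two studies the package uses to validate its qualitative claims:

* **Top-stability** — across a perturbation ensemble, cells ranked on
  average highest or lowest vary least: the few cells with rare high
  feature values anchor the top of the ranking, worthless cells anchor
  the bottom, while the interchangeable middle reshuffles freely.

* **Rarity drives influence** — of two equally perturbed features, the
  one spatially confined to a small part of the landscape explains more
  of the ranking variance than the widespread one, because the
  prioritisation has no substitute cells for a confined feature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
from scipy import ndimage

from .attribution import cca, redundancy_index
from .ensemble import EnsembleConfig, default_bundle, run_ensemble
from .landscape import LandscapeConfig
from .metrics import rank_stats
from .prioritize import BenefitSpec, FeatureStack, rank_abf
from .rng import substream

__all__ = ["top_stability_trial", "rarity_trial"]


def top_stability_trial(master_seed: int, grid: int = 100,
                        n_iterations: int = 50, n_segments: int = 600,
                        period: str = "T1") -> Dict[str, float | bool]:
    """One top-stability ensemble; returns median SDs and the verdict.

    The verdict compares the median per-cell rank SD of the top and
    bottom mean-rank deciles against that of the middle three quintiles
    (cells between the 20th and 80th percentile of mean rank).
    """
    config = LandscapeConfig(grid_rows=grid, grid_cols=grid,
                             n_segments=n_segments, master_seed=master_seed)
    bundle = default_bundle(config, seed=master_seed)
    ens = run_ensemble(bundle, EnsembleConfig(
        n_iterations=n_iterations, variants=("combined",),
        master_seed=master_seed, rank_periods=(period,)))

    stats = rank_stats([it.rankings[(period, "combined")]
                        for it in ens.iterations])
    order = np.argsort(stats.mean, kind="stable")
    n = len(order)
    dec = n // 10
    bottom = order[:dec]
    top = order[-dec:]
    middle = order[int(0.2 * n):int(0.8 * n)]
    med_top = float(np.median(stats.sd[top]))
    med_bottom = float(np.median(stats.sd[bottom]))
    med_middle = float(np.median(stats.sd[middle]))
    return {
        "median_sd_top_decile": med_top,
        "median_sd_bottom_decile": med_bottom,
        "median_sd_middle_quintiles": med_middle,
        "passed": med_top < med_middle and med_bottom < med_middle,
    }


def _widespread_base(rng: np.random.Generator, shape: Tuple[int, int],
                     ) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.standard_normal(shape),
                                sigma=max(2.0, min(shape) / 10),
                                mode="nearest")
    f = (f - f.mean()) / max(f.std(), 1e-12)
    return np.clip(1.0 + 0.3 * f, 0.1, None)


def rarity_trial(master_seed: int, grid: int = 60, n_iterations: int = 20,
                 confined_fraction: float = 0.05, noise_sd: float = 0.10,
                 n_background: int = 4) -> Dict[str, float | bool]:
    """One rarity-vs-influence replicate ensemble.

    Two test features receive identical additive perturbation variance
    on their support: one confined to a compact block covering
    ``confined_fraction`` of the landscape, one positive everywhere.
    They are prioritised together with ``n_background`` fixed smooth
    biodiversity features standing in for the rest of the data pool —
    without them a two-feature ranking is trivially dominated by
    whichever feature covers more cells, and the rarity mechanism
    (no substitute cells for a confined feature; a widespread feature's
    perturbations drown among equally good cells) cannot operate.
    All features enter with z = 0.25.  Per iteration, a
    univariate-response CCA of the two test-feature columns against the
    priority rank gives each feature's redundancy index; the trial
    reports across-iteration means.
    """
    rng = substream(master_seed, "rarity-base")
    shape = (grid, grid)
    n = grid * grid
    land = np.ones(shape, dtype=bool)

    side = int(round(np.sqrt(confined_fraction * n)))
    r0 = rng.integers(0, grid - side)
    c0 = rng.integers(0, grid - side)
    patch = np.zeros(shape, dtype=bool)
    patch[r0:r0 + side, c0:c0 + side] = True

    confined_base = np.where(patch, 1.0, 0.0)
    # "widespread" = good everywhere: near-uniform coverage, so any cell
    # is a substitute for any other (mild contrast keeps it non-trivial)
    widespread_base = 1.0 + 0.05 * _widespread_base(rng, shape)
    background = [_widespread_base(rng, shape) for _ in range(n_background)]

    spec = BenefitSpec()
    rd_conf, rd_wide = [], []
    for it in range(n_iterations):
        it_rng = substream(master_seed, "rarity-iter", it)
        conf = confined_base.copy()
        conf[patch] = np.clip(conf[patch]
                              + it_rng.normal(0.0, noise_sd, patch.sum()),
                              0.0, None)
        wide = np.clip(widespread_base
                       + it_rng.normal(0.0, noise_sd, shape), 0.0, None)
        layers = [conf[land], wide[land]] + [b[land] for b in background]
        names = (["confined", "widespread"]
                 + [f"background_{i}" for i in range(n_background)])
        stack = FeatureStack(
            names=tuple(names),
            classes=tuple(["biodiversity"] * len(names)),
            values=np.column_stack(layers),
            land_mask=land,
        )
        ranking = rank_abf(stack, spec, batch=max(1, n // 200),
                           seed=master_seed)
        X = stack.values[:, :2]
        res = cca(X, ranking.rank[:, None])
        rd = redundancy_index(res.x_loadings, res.correlations)
        full = np.zeros(2)
        full[res.x_kept] = rd
        rd_conf.append(full[0])
        rd_wide.append(full[1])

    mean_conf = float(np.mean(rd_conf))
    mean_wide = float(np.mean(rd_wide))
    return {
        "mean_rd_confined": mean_conf,
        "mean_rd_widespread": mean_wide,
        "confined_wins": mean_conf > mean_wide,
    }
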