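"""Variance attribution of priority rankings via canonical correlation.

Canonical correlation analysis (CCA) finds paired linear combinations
of two variable sets with maximal correlation.  The Stewart–Love /
van den Wollenberg redundancy index of a variable v in set S,

    Rd(v) = sum_k loading(v, k)^2 * rho_k^2,

is the share of v's variance reproducible from the other set's
canonical variates (0–1).  With a univariate response, Rd of the
response reduces to the OLS R^2 of regressing it on the other set —
an identity the test suite checks.

The attribution driver extracts explanatory values (prioritisation
features, or the initial forest variables) and the cell's priority rank
from a fixed sample of grid cells, runs one CCA per iteration (the
default; a pooled run stacking all iterations and periods is also
available), and tabulates the per-variable redundancy indices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import linalg

from .rng import substream

__all__ = [
    "CCAResult",
    "AttributionDesign",
    "sample_cells",
    "cca",
    "redundancy_index",
    "attribute",
]

FOREST_VARIABLES = ("height_m", "dbh_cm", "volume_m3ha", "dec_volume_m3ha",
                    "age_yr", "site_type")


def sample_cells(land_mask: np.ndarray, n: int = 10_000,
                 seed: int = 0) -> np.ndarray:
    """Uniform sample of land-cell indices without replacement.

    Indices refer to the flattened land-cell ordering used by feature
    stacks and rankings; the draw is reproducible from ``seed``.
    """
    n_land = int(land_mask.sum())
    if n > n_land:
        raise ValueError(f"cannot sample {n} of {n_land} land cells")
    rng = substream(seed, "cell-sample")
    return np.sort(rng.choice(n_land, size=n, replace=False))


@dataclass
class CCAResult:
    correlations: np.ndarray      # rho_1 >= ... >= rho_min >= 0
    x_weights: np.ndarray         # (p_kept, k) weights on standardised X
    y_weights: np.ndarray
    x_loadings: np.ndarray        # corr(original X columns, X variates)
    y_loadings: np.ndarray
    x_kept: np.ndarray            # indices of non-constant columns kept
    y_kept: np.ndarray


def _standardise(M: np.ndarray, label: str) -> Tuple[np.ndarray, np.ndarray]:
    M = np.asarray(M, dtype=float)
    if M.ndim == 1:
        M = M[:, None]
    sd = M.std(axis=0)
    kept = np.flatnonzero(sd > 0)
    if len(kept) < M.shape[1]:
        warnings.warn(f"dropping {M.shape[1] - len(kept)} constant "
                      f"column(s) from {label}", stacklevel=3)
    if len(kept) == 0:
        raise ValueError(f"all columns of {label} are constant")
    Ms = (M[:, kept] - M[:, kept].mean(axis=0)) / sd[kept]
    return Ms, kept


def cca(X: np.ndarray, Y: np.ndarray, ridge: float = 1e-8) -> CCAResult:
    """Classical CCA on internally standardised columns.

    A ridge of ``ridge`` on a within-set correlation matrix guards
    against rank deficiency; it is applied lazily, only when the
    unridged Cholesky factorisation fails, so well-conditioned problems
    are solved exactly.  Structure loadings are the empirical
    correlations of each original column with its own set's canonical
    variates.
    """
    Xs, x_kept = _standardise(X, "X")
    Ys, y_kept = _standardise(Y, "Y")
    n, p = Xs.shape
    q = Ys.shape[1]
    if n <= p + q:
        raise ValueError("need more observations than total variables")

    Cxy = Xs.T @ Ys / n

    def chol(C: np.ndarray) -> np.ndarray:
        try:
            return linalg.cholesky(C, lower=True)
        except linalg.LinAlgError:
            return linalg.cholesky(C + ridge * np.eye(len(C)), lower=True)

    Lx = chol(Xs.T @ Xs / n)
    Ly = chol(Ys.T @ Ys / n)
    M = linalg.solve_triangular(Lx, Cxy, lower=True)
    M = linalg.solve_triangular(Ly, M.T, lower=True).T
    U, s, Vt = linalg.svd(M, full_matrices=False)
    rho = np.clip(s, 0.0, 1.0)

    Wx = linalg.solve_triangular(Lx.T, U, lower=False)
    Wy = linalg.solve_triangular(Ly.T, Vt.T, lower=False)

    Ux = Xs @ Wx
    Uy = Ys @ Wy

    def loadings(Z: np.ndarray, V: np.ndarray) -> np.ndarray:
        v_sd = V.std(axis=0)
        v_sd[v_sd == 0] = 1.0
        return (Z.T @ V / n) / v_sd[None, :]

    return CCAResult(correlations=rho, x_weights=Wx, y_weights=Wy,
                     x_loadings=loadings(Xs, Ux),
                     y_loadings=loadings(Ys, Uy),
                     x_kept=x_kept, y_kept=y_kept)


def redundancy_index(loadings: np.ndarray,
                     correlations: np.ndarray) -> np.ndarray:
    """Per-variable Rd = sum_k loading^2 * rho^2 over canonical dimensions."""
    rd = (loadings**2 * correlations[None, :]**2).sum(axis=1)
    return np.clip(rd, 0.0, 1.0)


@dataclass
class AttributionDesign:
    """What to correlate with what, and over which cells."""

    n_cells: int = 10_000
    subset: str = "all"                 # "all" | "top10"
    explanatory: str = "features"       # "features" | "forest_variables"
    variant: str = "combined"
    periods: Optional[Sequence[str]] = None
    seed: int = 0
    pooled: bool = False                # stack iterations/periods in one CCA
    joint: bool = False                 # three variant ranks as multivariate Y
    ridge: float = 1e-8

    def __post_init__(self) -> None:
        if self.subset not in ("all", "top10"):
            raise ValueError("subset must be 'all' or 'top10'")
        if self.explanatory not in ("features", "forest_variables"):
            raise ValueError("unknown explanatory set")


def _explanatory_matrix(it_result, period: str, design: AttributionDesign,
                        cells: np.ndarray, land: np.ndarray,
                        ) -> Tuple[np.ndarray, Tuple[str, ...]]:
    if design.explanatory == "features":
        stack = it_result.stacks[period]
        return stack.values[cells], stack.names
    state = it_result.simulation.period_states[period]
    cols = [getattr(state, v)[land][cells].astype(float)
            for v in FOREST_VARIABLES]
    return np.column_stack(cols), FOREST_VARIABLES


def _response(it_result, period: str, design: AttributionDesign,
              cells: np.ndarray) -> np.ndarray:
    if design.joint:
        variants = sorted({v for (_, v) in it_result.rankings})
        return np.column_stack(
            [it_result.rankings[(period, v)].rank[cells] for v in variants])
    return it_result.rankings[(period, design.variant)].rank[cells][:, None]


def _rows_for(it_result, period: str, design: AttributionDesign,
              cells: np.ndarray, land: np.ndarray):
    """(X, Y, names) for one iteration and period, or None if too few rows."""
    keep = cells
    if design.subset == "top10":
        mask = it_result.top_masks[(period, design.variant)][land]
        keep = cells[mask[cells]]
    X, names = _explanatory_matrix(it_result, period, design, keep, land)
    Y = _response(it_result, period, design, keep)
    if X.shape[0] < X.shape[1] + Y.shape[1] + 1:
        warnings.warn(f"too few rows ({X.shape[0]}) for period {period}; "
                      "skipping", stacklevel=3)
        return None
    return X, Y, names


def attribute(result, design: AttributionDesign) -> pd.DataFrame:
    """Redundancy table over iterations, periods and explanatory variables.

    Long format with columns (variable, period, subset, variant,
    iteration, rd).  ``iteration`` is an integer, or ``"pooled"`` for
    the stacked run across all iterations and periods.
    """
    land = result.land_mask
    n_land = int(land.sum())
    cells = sample_cells(land, min(design.n_cells, n_land), design.seed)
    periods = tuple(design.periods or result.bundle.periods.labels)

    rows: List[Dict] = []

    def record(X, Y, names, iteration_label, period_label):
        res = cca(X, Y, ridge=design.ridge)
        rd = redundancy_index(res.x_loadings, res.correlations)
        full = np.zeros(len(names))
        full[res.x_kept] = rd
        for name, value in zip(names, full):
            rows.append({"variable": name, "period": period_label,
                         "subset": design.subset, "variant": design.variant,
                         "iteration": iteration_label, "rd": float(value)})

    if design.pooled:
        xs, ys, names = [], [], None
        for it_result in result.iterations:
            for period in periods:
                parts = _rows_for(it_result, period, design, cells, land)
                if parts is None:
                    continue
                X, Y, names = parts
                xs.append(X)
                ys.append(Y)
        if xs:
            record(np.vstack(xs), np.vstack(ys), names, "pooled", "all")
    else:
        for i, it_result in enumerate(result.iterations):
            for period in periods:
                parts = _rows_for(it_result, period, design, cells, land)
                if parts is None:
                    continue
                X, Y, names = parts
                record(X, Y, names, i, period)
    return pd.DataFrame(rows)
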