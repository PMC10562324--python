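"""Synthetic boreal forest landscapes and input-uncertainty samplers.

The landscape is a regular grid (default 96 m cells) of contiguous,
internally homogeneous forest *segments* — the simulation unit of the
whole pipeline.  Each segment carries the standard stand variables
(mean height, DBH, stem volume, deciduous volume, dominant-tree age,
dominant species, site-fertility class).  Water cells are masked out.

The samplers in this module perturb a baseline landscape the way remote
sensing and model-calibration errors would:

* structural variables — one multivariate-normal error vector per
  segment, post-processed by rank-preserving quantile matching onto
  bounded truncated-normal marginals;
* site-fertility class — redrawn from an ordered-probit model of the
  structural variables;
* stand age — normal with a 10 % coefficient of variation;
* growth/carbon parameters — whole-vector bootstrap from a pool that
  stands in for a joint posterior, with an extra N(1, 0.1^2) multiplier
  on the crown-base-analogue parameter;
* weather — annual growth modifiers resampled with replacement from a
  pool of historical years (default 46).

All samplers are pure functions of (inputs, seed) and keep every cell
of a segment identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Sequence, Tuple

import numpy as np
from scipy import ndimage, stats

from .rng import substream

__all__ = [
    "PINE",
    "SPRUCE",
    "DECIDUOUS",
    "SPECIES_NAMES",
    "LandscapeConfig",
    "ForestState",
    "StaticPredictors",
    "StructuralErrorModel",
    "SiteTypeProbitModel",
    "ParameterPool",
    "WeatherPool",
    "generate_landscape",
    "generate_static_predictors",
    "sample_structural_errors",
    "quantile_match",
    "sample_site_type",
    "sample_age",
    "sample_parameters",
    "sample_weather",
    "default_structural_model",
    "default_probit_model",
    "default_parameter_pool",
    "default_weather_pool",
]

PINE, SPRUCE, DECIDUOUS = 0, 1, 2
SPECIES_NAMES = {PINE: "pine", SPRUCE: "spruce", DECIDUOUS: "deciduous"}

#: continuous per-cell stand variables, in a fixed order used throughout
CONTINUOUS_FIELDS = ("height_m", "dbh_cm", "volume_m3ha", "dec_volume_m3ha", "age_yr")


class ConfigurationError(ValueError):
    """Raised for invalid landscape or sampler configuration."""


# ---------------------------------------------------------------------------
# configuration


@dataclass
class LandscapeConfig:
    """Geometry and baseline stand-variable distributions.

    The defaults describe a managed boreal landscape: mostly conifer,
    gamma-distributed stand ages with a long tail of old stands, and
    site-fertility classes 1 (most fertile) .. ``n_site_types``.
    """

    grid_rows: int = 100
    grid_cols: int = 100
    cell_size: float = 96.0
    n_segments: int = 600
    land_fraction: float = 0.9
    n_site_types: int = 6
    master_seed: int = 0

    # dominant-species mix (pine, spruce, deciduous)
    species_probs: Tuple[float, float, float] = (0.45, 0.35, 0.20)
    # stand age ~ Gamma(shape, scale), years
    age_gamma_shape: float = 2.2
    age_gamma_scale: float = 25.0
    age_max: float = 200.0
    # asymptotic height per species (m), modified by site fertility
    hmax_by_species: Tuple[float, float, float] = (25.0, 28.0, 22.0)
    hmax_site_slope: float = 0.05  # relative change per fertility class from 3.5
    height_k: float = 0.035       # 1/yr, saturation rate of the age-height curve
    height_shape: float = 1.3
    height_noise_sd: float = 0.12  # lognormal sigma
    # allometry dbh = dbh_coef * H^dbh_exp, volume = vol_coef * H^vol_exp
    dbh_coef: float = 1.25
    dbh_exp: float = 1.05
    dbh_noise_sd: float = 0.10
    vol_coef: float = 0.65
    vol_exp: float = 1.85
    vol_noise_sd: float = 0.25
    # deciduous share ~ Beta with these means (concentration 8)
    dec_share_mean_conifer: float = 0.12
    dec_share_mean_deciduous: float = 0.75
    # site-type class frequencies (class 1 first); length n_site_types
    site_type_probs: Tuple[float, ...] = (0.08, 0.22, 0.30, 0.25, 0.10, 0.05)
    # static predictor fields
    jan_temp_mean: float = -8.5
    jan_temp_sd: float = 1.2
    gdd5_mean: float = 1150.0
    gdd5_sd: float = 90.0
    urban_fraction: float = 0.04
    agri_fraction: float = 0.09

    def __post_init__(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ConfigurationError("grid dimensions must be positive")
        if not (1 <= self.n_segments <= self.grid_rows * self.grid_cols):
            raise ConfigurationError(
                "need 1 <= n_segments <= grid_rows * grid_cols"
            )
        if self.cell_size <= 0:
            raise ConfigurationError("cell_size must be positive")
        if not (0.0 < self.land_fraction <= 1.0):
            raise ConfigurationError("land_fraction must be in (0, 1]")
        for p in (*self.species_probs, *self.site_type_probs,
                  self.dec_share_mean_conifer, self.dec_share_mean_deciduous):
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError("probabilities and shares must be in [0, 1]")
        if len(self.site_type_probs) != self.n_site_types:
            raise ConfigurationError("site_type_probs length must equal n_site_types")


# ---------------------------------------------------------------------------
# forest state


@dataclass(eq=False)
class ForestState:
    """Per-cell stand variables on the analysis grid.

    Cells belonging to one segment share identical values; water cells
    have ``segment_id == -1`` and are excluded from every computation.
    """

    height_m: np.ndarray
    dbh_cm: np.ndarray
    volume_m3ha: np.ndarray
    dec_volume_m3ha: np.ndarray
    age_yr: np.ndarray
    species: np.ndarray
    site_type: np.ndarray
    segment_id: np.ndarray
    land_mask: np.ndarray

    def __post_init__(self) -> None:
        shape = self.height_m.shape
        for name in (*CONTINUOUS_FIELDS, "species", "site_type",
                     "segment_id", "land_mask"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"field {name} has mismatched shape")
        self._segment_ids: np.ndarray | None = None
        self._rep_flat: np.ndarray | None = None
        self._cell_pos: np.ndarray | None = None

    # -- segment bookkeeping -------------------------------------------------

    def _build_index(self) -> None:
        flat_seg = self.segment_id.ravel()
        land = self.land_mask.ravel()
        land_idx = np.flatnonzero(land)
        ids, first = np.unique(flat_seg[land_idx], return_index=True)
        self._segment_ids = ids
        self._rep_flat = land_idx[first]
        pos = np.full(flat_seg.shape, -1, dtype=np.int64)
        pos[land_idx] = np.searchsorted(ids, flat_seg[land_idx])
        self._cell_pos = pos

    @property
    def segment_ids(self) -> np.ndarray:
        if self._segment_ids is None:
            self._build_index()
        return self._segment_ids

    @property
    def n_segments(self) -> int:
        return len(self.segment_ids)

    def segment_values(self, name: str) -> np.ndarray:
        """One value per segment (the shared within-segment value)."""
        if self._rep_flat is None:
            self._build_index()
        return getattr(self, name).ravel()[self._rep_flat]

    def replace_segments(self, **per_segment: np.ndarray) -> "ForestState":
        """New state with the given fields rebuilt from per-segment vectors."""
        if self._cell_pos is None:
            self._build_index()
        pos = self._cell_pos
        land = self.land_mask.ravel()
        updates = {}
        for name, vec in per_segment.items():
            vec = np.asarray(vec)
            if vec.shape != (self.n_segments,):
                raise ValueError(f"{name}: expected one value per segment")
            old = getattr(self, name).ravel()
            new = old.copy()
            new[land] = vec[pos[land]]
            updates[name] = new.reshape(self.land_mask.shape).astype(old.dtype)
        return replace(self, **updates)

    def copy(self) -> "ForestState":
        return replace(
            self,
            **{n: getattr(self, n).copy()
               for n in (*CONTINUOUS_FIELDS, "species", "site_type",
                         "segment_id", "land_mask")},
        )

    def dec_share(self) -> np.ndarray:
        """Deciduous share of stem volume, zero where volume is zero."""
        with np.errstate(invalid="ignore", divide="ignore"):
            share = np.where(self.volume_m3ha > 0,
                             self.dec_volume_m3ha / self.volume_m3ha, 0.0)
        return share

    def assert_segment_coherent(self, atol: float = 0.0) -> None:
        """Raise if any segment's cells disagree (test/debug helper)."""
        for name in (*CONTINUOUS_FIELDS, "species", "site_type"):
            vals = self.segment_values(name)
            rebuilt = self.replace_segments(**{name: vals})
            if not np.allclose(getattr(self, name)[self.land_mask],
                               getattr(rebuilt, name)[self.land_mask], atol=atol):
                raise AssertionError(f"segment-incoherent field: {name}")


@dataclass
class StaticPredictors:
    """Non-forest predictor layers, fixed across ensemble iterations.

    Climate surfaces are smooth random fields; land-use layers are 0/1
    indicators (focal means of indicators give landscape proportions);
    shoreline marks land cells bordering water.
    """

    jan_temp: np.ndarray
    gdd5: np.ndarray
    urban: np.ndarray
    agri: np.ndarray
    water: np.ndarray
    shoreline: np.ndarray

    def as_dict(self) -> Dict[str, np.ndarray]:
        return {
            "jan_temp": self.jan_temp,
            "gdd5": self.gdd5,
            "urban": self.urban,
            "agri": self.agri,
            "water": self.water,
            "shoreline": self.shoreline,
        }


# ---------------------------------------------------------------------------
# generation


def _smooth_field(rng: np.random.Generator, shape: Tuple[int, int],
                  sigma: float) -> np.ndarray:
    """Standardised smooth Gaussian random field."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="nearest")
    sd = f.std()
    if sd == 0:
        return np.zeros(shape)
    return (f - f.mean()) / sd


def _grow_segments(rng: np.random.Generator, land: np.ndarray,
                   n_segments: int) -> np.ndarray:
    """Randomised multi-source region growing; returns a label grid.

    Land components unreachable from any seed become extra segments, so
    contiguity always holds; ``n_segments`` is a target, not exact.
    """
    rows, cols = land.shape
    seg = np.full(land.shape, -1, dtype=np.int32)
    land_flat = np.flatnonzero(land.ravel())
    n_segments = min(n_segments, len(land_flat))
    seeds = rng.choice(land_flat, size=n_segments, replace=False)
    seg.ravel()[seeds] = np.arange(n_segments, dtype=np.int32)

    frontier = list(seeds)
    segr = seg.ravel()
    landr = land.ravel()
    while frontier:
        order = rng.permutation(len(frontier))
        nxt = []
        for i in order:
            f = frontier[i]
            r, c = divmod(f, cols)
            lab = segr[f]
            for nr, nc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
                if 0 <= nr < rows and 0 <= nc < cols:
                    nf = nr * cols + nc
                    if landr[nf] and segr[nf] < 0:
                        segr[nf] = lab
                        nxt.append(nf)
        frontier = nxt

    # orphan components (blocked by water) become their own segments
    orphan = land & (seg < 0)
    if orphan.any():
        labels, n_extra = ndimage.label(orphan)
        seg[orphan] = (labels[orphan] + n_segments - 1).astype(np.int32)
    return seg


def generate_landscape(config: LandscapeConfig, seed: int) -> ForestState:
    """Draw a baseline landscape: mask, segments and stand variables.

    Deterministic given ``(config, seed)``.  Stand variables are drawn
    per segment: age from a gamma distribution, height from a saturating
    age curve modified by species and site fertility, DBH and volume
    from height allometries, each with lognormal noise.
    """
    rng = substream(seed, "landscape")
    shape = (config.grid_rows, config.grid_cols)

    # water = lowest cells of a smooth field, so the land fraction is exact
    if config.land_fraction >= 1.0:
        land = np.ones(shape, dtype=bool)
    else:
        f = _smooth_field(rng, shape, sigma=max(2.0, min(shape) / 12))
        n_water = int(round((1 - config.land_fraction) * f.size))
        thresh = np.partition(f.ravel(), n_water)[n_water] if n_water else -np.inf
        land = f >= thresh
        # exact count in case of ties
        if land.sum() != f.size - n_water:
            order = np.argsort(f.ravel(), kind="stable")
            land = np.ones(f.size, dtype=bool)
            land[order[:n_water]] = False
            land = land.reshape(shape)

    seg = _grow_segments(rng, land, config.n_segments)
    ids = np.unique(seg[land])
    n_seg = len(ids)

    species = rng.choice(3, size=n_seg, p=np.asarray(config.species_probs) /
                         sum(config.species_probs)).astype(np.int8)

    # fertility: smooth spatial field sampled at segment seeds gives mild
    # spatial autocorrelation in site type
    fert_field = _smooth_field(rng, shape, sigma=max(2.0, min(shape) / 10))
    first_cells = np.array(
        [np.flatnonzero((seg == i).ravel())[0] for i in ids]
    )
    fert = 0.6 * fert_field.ravel()[first_cells] + 0.8 * rng.standard_normal(n_seg)
    fert /= np.sqrt(0.6**2 + 0.8**2)
    cum = np.cumsum(config.site_type_probs)[:-1]
    thresholds = stats.norm.ppf(np.clip(cum, 1e-12, 1 - 1e-12))
    site_type = (np.searchsorted(thresholds, fert) + 1).astype(np.int8)

    age = rng.gamma(config.age_gamma_shape, config.age_gamma_scale, size=n_seg)
    age = np.clip(age, 3.0, config.age_max)

    hmax = np.asarray(config.hmax_by_species)[species] * (
        1.0 + config.hmax_site_slope * (3.5 - site_type)
    )
    height = hmax * (1 - np.exp(-config.height_k * age)) ** config.height_shape
    height *= np.exp(rng.normal(0.0, config.height_noise_sd, n_seg))
    height = np.clip(height, 0.5, 45.0)

    dbh = config.dbh_coef * height ** config.dbh_exp
    dbh *= np.exp(rng.normal(0.0, config.dbh_noise_sd, n_seg))

    volume = config.vol_coef * height ** config.vol_exp
    volume *= np.exp(rng.normal(0.0, config.vol_noise_sd, n_seg))

    # deciduous share: Beta draws truncated so the dominant-species label
    # stays consistent with the majority rule (share > 0.5 iff deciduous)
    conc = 8.0
    share = np.empty(n_seg)
    for mean, mask, lo_trunc in (
        (config.dec_share_mean_conifer, species != DECIDUOUS, False),
        (config.dec_share_mean_deciduous, species == DECIDUOUS, True),
    ):
        k = int(mask.sum())
        if k == 0:
            continue
        if mean <= 0.0:
            share[mask] = 0.0
        elif mean >= 1.0:
            share[mask] = 1.0
        else:
            a, b = mean * conc, (1 - mean) * conc
            f_half = stats.beta.cdf(0.5, a, b)
            u = rng.random(k)
            if lo_trunc:
                u = f_half + u * (1.0 - f_half)   # share > 0.5
            else:
                u = u * f_half                    # share <= 0.5
            share[mask] = stats.beta.ppf(np.clip(u, 1e-12, 1 - 1e-12), a, b)
    dec_volume = share * volume

    pos = np.searchsorted(ids, seg.ravel())
    landr = land.ravel()

    def broadcast(vec: np.ndarray, fill: float = 0.0,
                  dtype=np.float64) -> np.ndarray:
        out = np.full(seg.size, fill, dtype=dtype)
        out[landr] = vec[pos[landr]]
        return out.reshape(shape)

    return ForestState(
        height_m=broadcast(height),
        dbh_cm=broadcast(dbh),
        volume_m3ha=broadcast(volume),
        dec_volume_m3ha=broadcast(dec_volume),
        age_yr=broadcast(age),
        species=broadcast(species, fill=-1, dtype=np.int8),
        site_type=broadcast(site_type, fill=0, dtype=np.int8),
        segment_id=np.where(land, seg, -1).astype(np.int32),
        land_mask=land,
    )


def generate_static_predictors(state: ForestState, config: LandscapeConfig,
                               seed: int) -> StaticPredictors:
    """Fixed non-forest predictor layers for the habitat models."""
    rng = substream(seed, "static-predictors")
    shape = state.land_mask.shape
    sigma = max(2.0, min(shape) / 8)

    jan_temp = (config.jan_temp_mean
                + config.jan_temp_sd * _smooth_field(rng, shape, sigma))
    gdd5 = config.gdd5_mean + config.gdd5_sd * _smooth_field(rng, shape, sigma)

    def indicator(fraction: float) -> np.ndarray:
        f = _smooth_field(rng, shape, sigma=max(2.0, min(shape) / 16))
        n = int(round(fraction * f.size))
        if n == 0:
            return np.zeros(shape)
        thresh = np.partition(f.ravel(), f.size - n)[f.size - n]
        return (f >= thresh).astype(float)

    urban = indicator(config.urban_fraction)
    agri = indicator(config.agri_fraction)
    water = (~state.land_mask).astype(float)
    near_water = ndimage.binary_dilation(~state.land_mask,
                                         structure=np.ones((3, 3), bool))
    shoreline = (near_water & state.land_mask).astype(float)
    return StaticPredictors(jan_temp, gdd5, urban, agri, water, shoreline)


# ---------------------------------------------------------------------------
# structural errors & quantile matching


@dataclass
class StructuralErrorModel:
    """Multivariate-normal error model for the structural stand variables."""

    variables: Tuple[str, ...] = ("height_m", "dbh_cm", "volume_m3ha",
                                  "dec_volume_m3ha")
    cov: np.ndarray = field(default_factory=lambda: np.zeros((4, 4)))
    bounds: Dict[str, Tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cov = np.asarray(self.cov, dtype=float)
        v = len(self.variables)
        if self.cov.shape != (v, v):
            raise ValueError("covariance shape must match variable count")
        if not np.allclose(self.cov, self.cov.T, atol=1e-10):
            raise ValueError("covariance matrix must be symmetric")
        w = np.linalg.eigvalsh(self.cov)
        if w.min() < -1e-8 * max(1.0, w.max()):
            raise ValueError("covariance matrix must be positive semi-definite")
        for var, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"bounds for {var} must satisfy lower < upper")

    def marginal_sd(self, var: str) -> float:
        return float(np.sqrt(self.cov[self.variables.index(var),
                                      self.variables.index(var)]))


def default_structural_model() -> StructuralErrorModel:
    """Segment-level error magnitudes typical of remote-sensing inventories."""
    sds = np.array([1.5, 2.5, 25.0, 12.0])  # height m, dbh cm, vol, dec vol m3/ha
    corr = np.array([
        [1.0, 0.6, 0.5, 0.2],
        [0.6, 1.0, 0.5, 0.2],
        [0.5, 0.5, 1.0, 0.4],
        [0.2, 0.2, 0.4, 1.0],
    ])
    cov = corr * np.outer(sds, sds)
    bounds = {
        "height_m": (0.0, 45.0),
        "dbh_cm": (0.0, 90.0),
        "volume_m3ha": (0.0, 900.0),
        "dec_volume_m3ha": (0.0, 900.0),
    }
    return StructuralErrorModel(cov=cov, bounds=bounds)


def quantile_match(samples: Dict[str, np.ndarray],
                   baseline: Dict[str, np.ndarray],
                   model: StructuralErrorModel) -> Dict[str, np.ndarray]:
    """Rank-preserving remap of raw normal draws onto bounded marginals.

    Each raw value is carried through its normal quantile onto a
    truncated normal with the same (per-segment) baseline mean and the
    model's marginal SD, truncated at the variable's physical bounds.
    The map is strictly monotone in the raw value, so within-variable
    rank order is preserved, while the output always respects bounds.
    """
    out: Dict[str, np.ndarray] = {}
    for var, raw in samples.items():
        raw = np.asarray(raw, dtype=float)
        if raw.size == 0:
            out[var] = raw
            continue
        if var not in model.bounds:
            raise ValueError(f"no bounds defined for variable {var}")
        lo, hi = model.bounds[var]
        mu = np.asarray(baseline[var], dtype=float)
        sd = model.marginal_sd(var)
        if sd == 0.0:
            out[var] = raw.copy()
            continue
        u = stats.norm.cdf((raw - mu) / sd)
        u = np.clip(u, 1e-12, 1 - 1e-12)
        a = (lo - mu) / sd
        b = (hi - mu) / sd
        out[var] = stats.truncnorm.ppf(u, a, b, loc=mu, scale=sd)
    return out


def _mvn_factor(cov: np.ndarray) -> np.ndarray:
    """Square root of a PSD matrix via eigendecomposition (singular-safe)."""
    w, v = np.linalg.eigh(cov)
    w = np.clip(w, 0.0, None)
    return v * np.sqrt(w)


def sample_structural_errors(state: ForestState, model: StructuralErrorModel,
                             seed: int) -> ForestState:
    """Perturb structural variables with one MVN error vector per segment.

    After quantile matching, ``dec_volume <= volume`` is enforced and the
    dominant species is re-derived from the sampled deciduous share
    (majority rule); a segment that loses deciduous dominance falls back
    to spruce on fertile sites (class <= 3), otherwise pine.
    """
    rng = substream(seed, "structural")
    n = state.n_segments
    mu = {v: state.segment_values(v) for v in model.variables}

    z = rng.standard_normal((n, len(model.variables)))
    errors = z @ _mvn_factor(model.cov).T
    raw = {v: mu[v] + errors[:, i] for i, v in enumerate(model.variables)}
    adj = quantile_match(raw, mu, model)

    if "dec_volume_m3ha" in adj and "volume_m3ha" in adj:
        adj["dec_volume_m3ha"] = np.minimum(adj["dec_volume_m3ha"],
                                            adj["volume_m3ha"])

    updates = dict(adj)
    if "dec_volume_m3ha" in adj and "volume_m3ha" in adj:
        vol = adj["volume_m3ha"]
        share = np.where(vol > 0, adj["dec_volume_m3ha"] / np.maximum(vol, 1e-12),
                         0.0)
        old_sp = state.segment_values("species")
        site = state.segment_values("site_type")
        conifer_fallback = np.where(site <= 3, SPRUCE, PINE)
        new_sp = np.where(share > 0.5, DECIDUOUS,
                          np.where(old_sp == DECIDUOUS, conifer_fallback, old_sp))
        updates["species"] = new_sp.astype(np.int8)
    return state.replace_segments(**updates)


# ---------------------------------------------------------------------------
# site type


@dataclass
class SiteTypeProbitModel:
    """Ordered probit for the site-fertility class given structural variables.

    The latent index is a linear function of standardised predictors;
    ascending thresholds cut it into ``K`` ordered classes (1 = most
    fertile).  Coefficients are negative on variables associated with
    fertility, so a high latent value means a poor (high-numbered) class.
    """

    coef: Dict[str, float]
    standardize: Dict[str, Tuple[float, float]]
    thresholds: np.ndarray
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if not np.all(np.diff(self.thresholds) > 0):
            raise ValueError("thresholds must be strictly increasing")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    @property
    def n_classes(self) -> int:
        return len(self.thresholds) + 1

    def class_probabilities(self, predictors: Dict[str, np.ndarray]) -> np.ndarray:
        """(n, K) matrix of ordered-probit class probabilities."""
        n = len(next(iter(predictors.values())))
        eta = np.zeros(n)
        for var, w in self.coef.items():
            m, s = self.standardize[var]
            eta += w * (np.asarray(predictors[var]) - m) / s
        edges = np.concatenate(([-np.inf], self.thresholds, [np.inf]))
        cdf = stats.norm.cdf((edges[None, :] - eta[:, None]) / self.noise_sd)
        probs = np.diff(cdf, axis=1)
        sums = probs.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValueError("class probabilities do not sum to 1")
        return probs


def default_probit_model(n_classes: int = 6) -> SiteTypeProbitModel:
    base = np.array([0.08, 0.22, 0.30, 0.25, 0.10, 0.05])
    if n_classes != 6:
        base = np.full(n_classes, 1.0 / n_classes)
    cum = np.cumsum(base)[:-1]
    # latent SD after adding unit probit noise to the deterministic index
    scale = np.sqrt(1.0 + 0.6**2 + 0.3**2 + 0.5**2)
    thresholds = stats.norm.ppf(np.clip(cum, 1e-12, 1 - 1e-12)) * scale
    return SiteTypeProbitModel(
        coef={"volume_m3ha": -0.6, "height_m": -0.3, "dec_share": -0.5},
        standardize={"volume_m3ha": (150.0, 90.0), "height_m": (15.0, 6.0),
                     "dec_share": (0.15, 0.2)},
        thresholds=thresholds,
    )


def sample_site_type(state: ForestState, model: SiteTypeProbitModel,
                     seed: int) -> ForestState:
    """Redraw each segment's site class from its probit probabilities."""
    rng = substream(seed, "site-type")
    predictors = {
        "volume_m3ha": state.segment_values("volume_m3ha"),
        "height_m": state.segment_values("height_m"),
        "dec_share": np.where(
            state.segment_values("volume_m3ha") > 0,
            state.segment_values("dec_volume_m3ha")
            / np.maximum(state.segment_values("volume_m3ha"), 1e-12),
            0.0,
        ),
    }
    probs = model.class_probabilities(predictors)
    u = rng.random(len(probs))
    cls = (np.cumsum(probs, axis=1) < u[:, None]).sum(axis=1) + 1
    return state.replace_segments(site_type=cls.astype(np.int8))


# ---------------------------------------------------------------------------
# age, parameters, weather


def sample_age(state: ForestState, cv: float = 0.10, seed: int = 0) -> ForestState:
    """Per segment, age' ~ N(age, (cv * age)^2), truncated at zero."""
    if cv < 0:
        raise ValueError("cv must be non-negative")
    rng = substream(seed, "age")
    age = state.segment_values("age_yr")
    new = rng.normal(age, cv * age)
    return state.replace_segments(age_yr=np.maximum(new, 0.0))


@dataclass
class ParameterPool:
    """Pool of whole parameter vectors standing in for a joint posterior.

    Bootstrap draws return exact member vectors, so cross-parameter
    correlations are preserved by construction.  The designated
    crown-base-analogue column receives an extra N(1, sd^2) multiplier
    at draw time (its uncertainty comes from a separate empirical model
    rather than the joint posterior).
    """

    names: Tuple[str, ...]
    vectors: np.ndarray
    crown_base_index: int = -1
    crown_base_sd: float = 0.10

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2 or self.vectors.shape[0] < 1:
            raise ValueError("pool must contain at least one parameter vector")
        if self.vectors.shape[1] != len(self.names):
            raise ValueError("vector width must match names")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("pool vectors must be finite")

    @property
    def size(self) -> int:
        return self.vectors.shape[0]


def default_parameter_pool(size: int = 100) -> ParameterPool:
    """Correlated multiplier pool for the growth/carbon surrogate.

    Columns multiply: height-growth rate, asymptotic height, the volume
    allometry, litter input rate, soil decay rate, and the crown-base
    analogue (which modulates the volume allometry).  Generated once
    from a fixed internal seed — the pool is a frozen artifact, like a
    published posterior sample.
    """
    names = ("growth_rate", "height_asymptote", "volume_allometry",
             "litter_rate", "soil_decay", "crown_base")
    sds = np.array([0.06, 0.03, 0.07, 0.10, 0.10, 0.0])
    corr = np.eye(6)
    corr[0, 2] = corr[2, 0] = 0.5   # faster growth, larger volumes
    corr[3, 4] = corr[4, 3] = 0.4   # litter and decay jointly calibrated
    cov = corr * np.outer(sds, sds)
    rng = np.random.Generator(np.random.PCG64(20230901))
    log_mult = rng.standard_normal((size, 6)) @ _mvn_factor(cov).T
    vectors = np.exp(log_mult - cov.diagonal() / 2.0)
    vectors[:, 5] = 1.0
    return ParameterPool(names=names, vectors=vectors, crown_base_index=5)


def sample_parameters(pool: ParameterPool, seed: int) -> np.ndarray:
    """Bootstrap one whole vector; crown-base column gets its multiplier."""
    if pool.size < 1:
        raise ValueError("empty parameter pool")
    rng = substream(seed, "parameters")
    vec = pool.vectors[rng.integers(pool.size)].copy()
    idx = pool.crown_base_index % len(vec)
    vec[idx] = vec[idx] * rng.normal(1.0, pool.crown_base_sd)
    return vec


@dataclass
class WeatherPool:
    """Annual growth-modifier scalars for historical weather years."""

    modifiers: np.ndarray

    def __post_init__(self) -> None:
        self.modifiers = np.asarray(self.modifiers, dtype=float)
        if self.modifiers.size < 1:
            raise ValueError("weather pool must contain at least one year")
        if np.any(self.modifiers <= 0):
            raise ValueError("weather modifiers must be positive")

    @property
    def size(self) -> int:
        return self.modifiers.size


def default_weather_pool(size: int = 46) -> WeatherPool:
    """Lognormal year-to-year growth variation with mean 1 (fixed artifact)."""
    sigma = 0.08
    rng = np.random.Generator(np.random.PCG64(19712016))
    return WeatherPool(np.exp(rng.normal(-sigma**2 / 2, sigma, size)))


def sample_weather(pool: WeatherPool, n_years: int, seed: int) -> np.ndarray:
    """Series of annual modifiers drawn with replacement from the pool."""
    if n_years < 1:
        raise ValueError("n_years must be at least 1")
    rng = substream(seed, "weather")
    return pool.modifiers[rng.integers(pool.size, size=n_years)]
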