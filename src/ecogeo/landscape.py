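"""Virtual landscapes and virtual species for end-to-end testing.

The generator produces spatially autocorrelated, inter-correlated
environmental layers on a bounded lon/lat window, Gaussian-bell virtual
species, suitability-weighted presence samples, and shifted scenario
stacks — the statistical structure an ecogeographic-isolation analysis
assumes, with no external data.

Random fields are built by smoothing white noise with a Gaussian kernel
(autocorrelation length ``spatial_range`` cells), standardising each
field, then mixing fields per cell through a matrix square root of the
target inter-layer correlation matrix, so empirical cross-layer
correlations approach the target as the grid grows.  Every generator is
a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .raster import EnvStack, GridTransform

#: default layer set: mean annual temperature, isothermality, temperature
#: annual range, annual precipitation, precipitation seasonality, December
#: solar radiation — the six predictors retained after collinearity
#: screening of the WorldClim bioclim suite.
DEFAULT_LAYERS = ("bio1", "bio3", "bio7", "bio12", "bio15", "srad12")

#: per-layer (mean, sd) used to place standardized fields on realistic
#: climate-like scales (°C, %, °C, mm, CV%, kJ m-2 day-1).
DEFAULT_SCALES = {
    "bio1": (8.0, 6.0),
    "bio3": (30.0, 6.0),
    "bio7": (30.0, 6.0),
    "bio12": (800.0, 300.0),
    "bio15": (60.0, 20.0),
    "srad12": (12000.0, 3000.0),
}

#: study window (lon_min, lon_max, lat_min, lat_max): Hengduan Mountains,
#: Tai-hang Mountains and Sichuan Basin region of China.
DEFAULT_EXTENT = (91.0, 125.0, 20.0, 47.0)


@dataclass
class LandscapeSpec:
    """Parameters of a synthetic environmental landscape.

    ``inter_layer_corr`` is the target correlation matrix among layers
    (symmetric, unit diagonal, positive semidefinite); identity by default.
    ``spatial_range`` is the Gaussian autocorrelation length in cells.
    """

    n_rows: int = 200
    n_cols: int = 200
    extent: tuple[float, float, float, float] = DEFAULT_EXTENT
    layer_names: tuple[str, ...] = DEFAULT_LAYERS
    spatial_range: float = 3.0
    inter_layer_corr: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_rows < 2 or self.n_cols < 2:
            raise ValueError("grid must be at least 2x2")
        lon0, lon1, lat0, lat1 = self.extent
        if not (-180 <= lon0 < lon1 <= 180 and -90 <= lat0 < lat1 <= 90):
            raise ValueError(f"invalid lon/lat extent {self.extent}")
        p = len(self.layer_names)
        if self.inter_layer_corr is None:
            self.inter_layer_corr = np.eye(p)
        C = np.asarray(self.inter_layer_corr, dtype=float)
        if C.shape != (p, p) or not np.allclose(C, C.T) \
                or not np.allclose(np.diag(C), 1.0):
            raise ValueError("inter_layer_corr must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(C).min() < -1e-10:
            raise ValueError("inter_layer_corr must be positive semidefinite")
        self.inter_layer_corr = C


@dataclass
class VirtualSpecies:
    """A Gaussian-bell niche: suitability peaks at ``niche_center``.

    Per-layer ``niche_breadth`` (same units as the layer) sets how fast
    suitability decays away from the optimum; ``max_suitability`` scales
    the peak.
    """

    name: str
    niche_center: dict[str, float]
    niche_breadth: dict[str, float]
    max_suitability: float = 1.0

    def __post_init__(self):
        if set(self.niche_center) != set(self.niche_breadth):
            raise ValueError("center and breadth must cover the same layers")
        if any(b <= 0 for b in self.niche_breadth.values()):
            raise ValueError("niche breadths must be > 0")
        if not (0 < self.max_suitability <= 1):
            raise ValueError("max_suitability must be in (0, 1]")


@dataclass
class ScenarioShift:
    """An abstract climate scenario: per-layer x -> x * factor + offset."""

    name: str
    additive_offsets: dict[str, float] = field(default_factory=dict)
    multiplicative_factors: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if any(f <= 0 for f in self.multiplicative_factors.values()):
            raise ValueError("multiplicative factors must be > 0")


def _corr_factor(C: np.ndarray) -> np.ndarray:
    """Matrix A with A A^T = C (eigen square root; tolerates PSD rank loss)."""
    w, V = np.linalg.eigh(C)
    w = np.clip(w, 0.0, None)
    return V * np.sqrt(w)


def gen_env_stack(spec: LandscapeSpec) -> EnvStack:
    """Generate the landscape's environmental stack.

    Deterministic given ``spec.seed``.  Each layer is a smoothed Gaussian
    random field placed on a climate-like scale; cross-layer correlations
    approach ``spec.inter_layer_corr``.
    """
    rng = np.random.default_rng(spec.seed)
    p = len(spec.layer_names)
    fields = np.empty((p, spec.n_rows, spec.n_cols))
    for k in range(p):
        noise = rng.standard_normal((spec.n_rows, spec.n_cols))
        f = ndimage.gaussian_filter(noise, sigma=spec.spatial_range,
                                    mode="reflect")
        fields[k] = (f - f.mean()) / f.std()
    A = _corr_factor(spec.inter_layer_corr)
    mixed = np.einsum("ij,jrc->irc", A, fields)
    # restandardize: rank-deficient targets can shrink marginal variance
    mixed = (mixed - mixed.mean(axis=(1, 2), keepdims=True)) / \
        np.where(mixed.std(axis=(1, 2), keepdims=True) == 0, 1,
                 mixed.std(axis=(1, 2), keepdims=True))
    lon0, lon1, lat0, lat1 = spec.extent
    cellsize = (lon1 - lon0) / spec.n_cols
    transform = GridTransform(lon0, lat0, cellsize)
    layers = {}
    for k, name in enumerate(spec.layer_names):
        mu, sd = DEFAULT_SCALES.get(name, (0.0, 1.0))
        layers[name] = mu + sd * mixed[k]
    mask = np.ones((spec.n_rows, spec.n_cols), dtype=bool)
    return EnvStack(layers, mask, transform)


def true_suitability(env: EnvStack, sp: VirtualSpecies) -> np.ndarray:
    """Per-cell suitability of a virtual species on a stack.

    suitability = max_suitability * exp(-0.5 * sum_l ((x_l - c_l)/b_l)^2);
    the cell whose environment equals the niche centre attains the grid
    maximum.  Masked cells are NaN.
    """
    missing = set(sp.niche_center) - set(env.layer_names)
    if missing:
        raise KeyError(f"species references unknown layers: {sorted(missing)}")
    d2 = np.zeros(env.shape)
    for name, c in sp.niche_center.items():
        b = sp.niche_breadth[name]
        d2 += ((env.layers[name] - c) / b) ** 2
    suit = sp.max_suitability * np.exp(-0.5 * d2)
    suit[~env.mask] = np.nan
    return suit


def sample_occurrences(suit: np.ndarray, env: EnvStack, n: int, seed: int,
                       species: str = "virtual"):
    """Draw ``n`` presence points with probability proportional to suitability.

    Points sit at cell centres (no within-cell jitter), so grid thinning is
    exactly testable.  Sampling is with replacement; deterministic given
    ``seed``.
    """
    from .raster import OccurrenceSet

    if n < 1:
        raise ValueError("n must be >= 1")
    w = np.where(env.mask & np.isfinite(suit), suit, 0.0)
    total = w.sum()
    if total <= 0:
        raise ValueError("suitability is zero everywhere on the valid mask")
    rng = np.random.default_rng(seed)
    flat_idx = np.flatnonzero(w)
    probs = w.ravel()[flat_idx] / total
    draws = rng.choice(flat_idx, size=n, p=probs)
    rows, cols = np.unravel_index(draws, env.shape)
    lons = env.lon_centers()[cols]
    lats = env.lat_centers()[rows]
    return OccurrenceSet(species, np.column_stack([lons, lats]),
                         provenance="synthetic")


def four_species_system(breadth_t: float = 1.2, breadth_p: float = 70.0
                        ) -> list[VirtualSpecies]:
    """Four virtual species spanning the isolation spectrum.

    Niches sit on a temperature (bio1) x precipitation (bio12) plane:
    ``north`` and ``southwest`` are thermally allopatric (their optima lie
    ~6.7 temperature breadths apart); ``montane_a``/``montane_b`` are a
    nearly coincident sympatric pair; the remaining pairs are intermediate.
    This mirrors the classic montane-radiation layout in which one lowland
    species is fully separated from a high-elevation specialist while two
    young sister species share a niche.  Precipitation optima are
    non-monotone in temperature (the mid-temperature montane pair is the
    wettest), so the pooled occurrence table does not induce predictor
    collinearity that the screening stage would then remove.  Breadths are
    set so replicate models evaluate around TSS 0.85-0.95 — i.e. the
    species are as well-modelled as the montane endemics this layout
    emulates, and clear the usual TSS >= 0.8 ensemble gate.

    ``southwest`` additionally requires high December solar radiation
    (srad12), an axis the other species are indifferent to; a scenario
    that shifts srad12 therefore contracts and relocates only this
    species' range — a differential climate response, the mechanism by
    which scenario change raises pairwise isolation.
    """
    def sp(name, t, p, extra=()):
        centre = {"bio1": t, "bio12": p, **dict(extra)}
        breadth = {"bio1": breadth_t, "bio12": breadth_p,
                   **{k: 2000.0 for k, _ in extra}}
        return VirtualSpecies(name, centre, breadth)
    return [
        sp("montane_a", 6.0, 930.0),
        sp("montane_b", 6.3, 950.0),
        sp("southwest", 2.0, 800.0, (("srad12", 12000.0),)),
        sp("north", 12.0, 780.0),
    ]


def apply_scenario(env: EnvStack, shift: ScenarioShift) -> EnvStack:
    """Cellwise x -> x * factor + offset on the named layers; others copied."""
    names = set(shift.additive_offsets) | set(shift.multiplicative_factors)
    unknown = names - set(env.layer_names)
    if unknown:
        raise KeyError(f"scenario shifts unknown layers: {sorted(unknown)}")
    out = env.copy()
    for name in names:
        f = shift.multiplicative_factors.get(name, 1.0)
        o = shift.additive_offsets.get(name, 0.0)
        out.layers[name] = out.layers[name] * f + o
        out.layers[name][~out.mask] = np.nan
    return out
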