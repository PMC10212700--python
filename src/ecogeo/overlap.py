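"""Niche overlap, breadth, and the Monte Carlo niche identity test.

Suitability surfaces are normalized into probability distributions over
the shared valid mask; on those, Schoener's D = 1 - (1/2) sum |p - q| and
Warren's I = 1 - (1/2) sum (sqrt(p) - sqrt(q))^2 (the Bhattacharyya
coefficient) quantify overlap, and Levins' B = 1 / sum p^2 (standardized
to [0, 1] as (B - 1)/(n - 1)) quantifies breadth.

The identity test pools two species' occurrences, repartitions them at
random into groups of the original sizes, refits a single fast model
family (GLM by default) to each pseudo-group against a fixed background
sample, and compares observed D and I to the null distribution.  The
one-tailed p-value uses the add-one estimator
p = (1 + #{null <= observed}) / (n_reps + 1), so p > 0 always; small p
means the observed niches are more divergent than expected if the two
species shared one niche.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .raster import EnvStack, OccurrenceSet, extract_at_points
from .sdm import fit_replicate


@dataclass
class NicheDistribution:
    """Per-cell probabilities over a shared valid mask (sums to 1)."""

    p: np.ndarray           # 1-D, over valid cells in row-major mask order
    mask_shape: tuple[int, int]
    mask_hash: int          # cheap co-registration guard

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        if np.any(self.p < 0) or not np.isclose(self.p.sum(), 1.0, atol=1e-12):
            raise ValueError("p must be nonnegative and sum to 1")


@dataclass
class NicheOverlap:
    D_obs: float
    I_obs: float
    null_D: np.ndarray = field(default_factory=lambda: np.empty(0))
    null_I: np.ndarray = field(default_factory=lambda: np.empty(0))
    p_D: float = float("nan")
    p_I: float = float("nan")
    n_reps: int = 0

    @property
    def significant_D(self) -> bool:
        return self.p_D < 0.05

    @property
    def significant_I(self) -> bool:
        return self.p_I < 0.05


@dataclass
class NicheBreadth:
    B_raw: float
    B_std: float
    bootstrap_samples: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_skipped: int = 0


def normalize(suitability: np.ndarray, mask: np.ndarray) -> NicheDistribution:
    """Normalize a suitability grid into probabilities over valid cells."""
    vals = np.asarray(suitability, dtype=float)[mask]
    vals = np.where(np.isfinite(vals), vals, 0.0)
    if np.any(vals < 0):
        raise ValueError("suitability must be nonnegative")
    total = vals.sum()
    if total <= 0:
        raise ValueError("suitability is zero everywhere on the mask")
    return NicheDistribution(vals / total, mask.shape,
                             hash(mask.tobytes()))


def _check_pair(p: NicheDistribution, q: NicheDistribution):
    if p.mask_shape != q.mask_shape or p.mask_hash != q.mask_hash \
            or p.p.shape != q.p.shape:
        raise ValueError("distributions are not on the same mask")


def schoener_D(p: NicheDistribution, q: NicheDistribution) -> float:
    """D = 1 - (1/2) sum |p_i - q_i|; 0 = disjoint, 1 = identical."""
    _check_pair(p, q)
    return float(1.0 - 0.5 * np.abs(p.p - q.p).sum())


def warren_I(p: NicheDistribution, q: NicheDistribution) -> float:
    """I = 1 - (1/2) sum (sqrt p - sqrt q)^2 = sum sqrt(p q)."""
    _check_pair(p, q)
    return float(1.0 - 0.5 * ((np.sqrt(p.p) - np.sqrt(q.p)) ** 2).sum())


def levins_B(p: NicheDistribution) -> NicheBreadth:
    """Levins' niche breadth B = 1 / sum p^2, standardized to [0, 1]."""
    b_raw = float(1.0 / np.sum(p.p ** 2))
    n = p.p.size
    b_std = float("nan") if n == 1 else (b_raw - 1) / (n - 1)
    return NicheBreadth(b_raw, b_std)


# ---------------------------------------------------------------------
# Model-based surfaces


def _fitted_distribution(occ: OccurrenceSet, env: EnvStack,
                         background_table, model_family: str
                         ) -> NicheDistribution:
    table, _ = extract_at_points(env, occ)
    fit = fit_replicate(model_family, table, background_table, env=env)
    suit = fit.predict_stack(env)
    return normalize(suit, env.mask)


def identity_test(occ_a: OccurrenceSet, occ_b: OccurrenceSet, env: EnvStack,
                  background: OccurrenceSet, n_reps: int = 100,
                  model_family: str = "GLM", seed: int = 0) -> NicheOverlap:
    """Monte Carlo niche identity test on model-based suitability surfaces.

    Observed D and I come from single-family fits to each species; the
    null pools all occurrences and repartitions them into pseudo-groups of
    the original sizes (background held fixed across pseudoreplicates).
    One-tailed toward divergence: p = (1 + #{null <= obs}) / (n_reps + 1).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if len(occ_a) == 0 or len(occ_b) == 0:
        raise ValueError("both occurrence sets must be non-empty")
    bg_table, _ = extract_at_points(env, background)
    p = _fitted_distribution(occ_a, env, bg_table, model_family)
    q = _fitted_distribution(occ_b, env, bg_table, model_family)
    d_obs, i_obs = schoener_D(p, q), warren_I(p, q)

    pooled = np.vstack([occ_a.points, occ_b.points])
    n_a = len(occ_a)
    rng = np.random.default_rng(seed)
    null_d = np.empty(n_reps)
    null_i = np.empty(n_reps)
    for r in range(n_reps):
        perm = rng.permutation(len(pooled))
        fake_a = OccurrenceSet("nullA", pooled[perm[:n_a]])
        fake_b = OccurrenceSet("nullB", pooled[perm[n_a:]])
        pr = _fitted_distribution(fake_a, env, bg_table, model_family)
        qr = _fitted_distribution(fake_b, env, bg_table, model_family)
        null_d[r] = schoener_D(pr, qr)
        null_i[r] = warren_I(pr, qr)
    p_d = (1 + np.sum(null_d <= d_obs)) / (n_reps + 1)
    p_i = (1 + np.sum(null_i <= i_obs)) / (n_reps + 1)
    return NicheOverlap(d_obs, i_obs, null_d, null_i,
                        float(p_d), float(p_i), n_reps)


def bootstrap_breadth(occ: OccurrenceSet, env: EnvStack,
                      background: OccurrenceSet, model_family: str = "GLM",
                      n_boot: int = 100, seed: int = 0) -> NicheBreadth:
    """Bootstrap Levins' B_std of a species' model-based suitability surface.

    Occurrences are resampled with replacement, the model refitted, and
    B_std recomputed per replicate; failed fits are skipped and counted.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    bg_table, _ = extract_at_points(env, background)
    point = _fitted_distribution(occ, env, bg_table, model_family)
    base = levins_B(point)
    rng = np.random.default_rng(seed)
    samples, skipped = [], 0
    n = len(occ)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boot = OccurrenceSet(occ.species, occ.points[idx])
        try:
            dist = _fitted_distribution(boot, env, bg_table, model_family)
            samples.append(levins_B(dist).B_std)
        except Exception:
            skipped += 1
    return NicheBreadth(base.B_raw, base.B_std, np.asarray(samples), skipped)


def breadth_difference(samples_a, samples_b):
    """Two-sided Mann-Whitney U comparison of two bootstrap B_std samples.

    Exact enumeration for small samples without ties, tie-corrected normal
    approximation otherwise (scipy's auto rule).  Returns (U, p).
    """
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if np.array_equal(np.sort(a), np.sort(b)):
        # scipy's exact method rejects ties; the symmetric case is exact
        return float(a.size * b.size / 2), 1.0
    method = "exact" if (a.size <= 20 and b.size <= 20
                         and np.unique(np.r_[a, b]).size == a.size + b.size) \
        else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
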