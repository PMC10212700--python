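"""Species distribution models: replicate fits, evaluation, ensembles.

The modelling workflow mirrors the standard ensemble-SDM recipe:

1. sample pseudo-absence (background) points from the valid grid;
2. split presences and background 70/30 into train/test, independently,
   once per replicate;
3. fit replicates of three model families — a binomial GLM with linear +
   quadratic terms, a Maxent-like penalized binomial regression on
   linear/quadratic/hinge features contrasting presences against
   background, and a MARS-like forward/backward hinge-basis regression
   pruned by generalized cross-validation;
4. score each replicate on its test split by rank-based AUC and the True
   Skill Statistic (TSS = sensitivity + specificity - 1, maximized over
   score thresholds);
5. average the members with TSS >= 0.8 into an ensemble suitability
   surface, weighting by TSS; the binarization cutoff is the TSS-weighted
   mean of the members' TSS-maximizing thresholds;
6. binarize at the cutoff and project the frozen ensemble (same members,
   weights and cutoff) onto scenario stacks.

``EnsembleNicheModel`` is the model object built from one species'
occurrences plus an environmental stack; ``fit()`` returns an
``EnsembleResults`` carrying the per-member metrics, the ensemble
surface, its cutoff, and projection/binarization methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression

from .raster import EnvStack, GridTransform, OccurrenceSet, extract_at_points

EARTH_RADIUS_KM = 6371.0088
FAMILIES = ("GLM", "MAXENT_LIKE", "MARS_LIKE")
TSS_MIN_DEFAULT = 0.8
TRAIN_FRAC_DEFAULT = 0.7


# ---------------------------------------------------------------------
# Evaluation


@dataclass(frozen=True)
class EvalMetrics:
    """ROC AUC and maximized True Skill Statistic of one replicate."""

    auc: float
    tss_max: float
    tss_threshold: float


def auc_rank(presence_scores, background_scores) -> float:
    """Rank-comparison AUC (Mann-Whitney form); tied pairs count 1/2."""
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("need at least one presence and one background score")
    ranks = rankdata(np.concatenate([p, b]))
    u = ranks[:p.size].sum() - p.size * (p.size + 1) / 2
    return float(u / (p.size * b.size))


def tss_scan(presence_scores, background_scores) -> tuple[float, float]:
    """Maximize TSS over all distinct score thresholds.

    A cell is predicted present when score >= threshold.  Returns
    (tss_max, smallest argmax threshold).
    """
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("need at least one presence and one background score")
    best_tss, best_thr = -np.inf, np.nan
    for t in np.unique(np.concatenate([p, b])):
        sens = np.mean(p >= t)
        spec = np.mean(b < t)
        tss = sens + spec - 1
        if tss > best_tss + 1e-15:
            best_tss, best_thr = tss, t
    return float(best_tss), float(best_thr)


def evaluate_scores(presence_scores, background_scores) -> EvalMetrics:
    auc = auc_rank(presence_scores, background_scores)
    tss, thr = tss_scan(presence_scores, background_scores)
    return EvalMetrics(auc, tss, thr)


# ---------------------------------------------------------------------
# Background sampling and splits


def sample_background(env: EnvStack, n: int, seed: int) -> OccurrenceSet:
    """n cell-centre points uniform over the valid mask (with replacement)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    valid = np.flatnonzero(env.mask)
    if valid.size == 0:
        raise ValueError("empty valid mask")
    rng = np.random.default_rng(seed)
    draws = rng.choice(valid, size=n, replace=True)
    rows, cols = np.unravel_index(draws, env.shape)
    return OccurrenceSet(
        "background",
        np.column_stack([env.lon_centers()[cols], env.lat_centers()[rows]]),
        provenance="pseudo-absence",
    )


def _split_indices(n: int, train_frac: float, rng) -> tuple[np.ndarray, np.ndarray]:
    n_train = int(round(n * train_frac))
    n_train = min(max(n_train, 1), n - 1)
    perm = rng.permutation(n)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def split_data(n_presence: int, n_background: int,
               train_frac: float = TRAIN_FRAC_DEFAULT, seed: int = 0):
    """Independent train/test index splits for presences and background.

    Rounded to nearest with at least one index per side; disjoint;
    deterministic given seed.  Returns ((p_train, p_test), (b_train, b_test)).
    """
    if n_presence < 2:
        raise ValueError("need >= 2 presences to split")
    if n_background < 2:
        raise ValueError("need >= 2 background points to split")
    rng = np.random.default_rng(seed)
    return (_split_indices(n_presence, train_frac, rng),
            _split_indices(n_background, train_frac, rng))


# ---------------------------------------------------------------------
# Feature construction


@dataclass
class FeatureSpec:
    """Transform of raw layer values into model features.

    kinds: "linear" (z), "quadratic" (z^2), "hinge" (one-sided ramps at
    training-quantile knots, both orientations).  Standardization uses the
    training mean/sd stored here, so train/test/grid are on one scale.

    Prediction clamps each variable to its training range (the Maxent
    convention): beyond the calibration envelope the fitted polynomial and
    hinge responses are extrapolations with no data support, and clamping
    holds them at the envelope boundary instead.  This matters when
    projecting onto strongly shifted scenario stacks.
    """

    variables: list[str]
    means: np.ndarray
    sds: np.ndarray
    kinds: tuple[str, ...] = ("linear", "quadratic")
    hinge_knots: dict[str, np.ndarray] = field(default_factory=dict)
    z_min: np.ndarray | None = None
    z_max: np.ndarray | None = None

    @classmethod
    def from_training(cls, table: pd.DataFrame, kinds, n_knots: int = 5):
        X = table.to_numpy(dtype=float)
        means, sds = X.mean(axis=0), X.std(axis=0)
        sds = np.where(sds == 0, 1.0, sds)
        Z = (X - means) / sds
        knots = {}
        if "hinge" in kinds:
            qs = np.linspace(0.1, 0.9, n_knots)
            for j, v in enumerate(table.columns):
                knots[v] = np.unique(np.quantile(Z[:, j], qs))
        return cls(list(table.columns), means, sds, tuple(kinds), knots,
                   Z.min(axis=0), Z.max(axis=0))

    def build(self, table: pd.DataFrame) -> np.ndarray:
        missing = set(self.variables) - set(table.columns)
        if missing:
            raise KeyError(f"missing feature layers: {sorted(missing)}")
        Z = (table[self.variables].to_numpy(dtype=float) - self.means) / self.sds
        if self.z_min is not None:
            Z = np.clip(Z, self.z_min, self.z_max)
        cols = []
        if "linear" in self.kinds:
            cols.append(Z)
        if "quadratic" in self.kinds:
            cols.append(Z ** 2)
        if "hinge" in self.kinds:
            for j, v in enumerate(self.variables):
                for k in self.hinge_knots[v]:
                    cols.append(np.maximum(0.0, Z[:, j:j + 1] - k))
                    cols.append(np.maximum(0.0, k - Z[:, j:j + 1]))
        return np.column_stack(cols)


# ---------------------------------------------------------------------
# MARS-like hinge regression (forward selection + GCV backward pruning)


class _MarsBasis:
    """Additive hinge basis: intercept plus max(0, +/-(z - knot)) terms."""

    def __init__(self, terms: list[tuple[int, float, int]]):
        self.terms = terms  # (variable index, knot, sign)

    def design(self, Z: np.ndarray) -> np.ndarray:
        cols = [np.ones(Z.shape[0])]
        for j, k, s in self.terms:
            cols.append(np.maximum(0.0, s * (Z[:, j] - k)))
        return np.column_stack(cols)


def _gcv(sse: float, n: int, n_terms: int, penalty: float = 3.0) -> float:
    c = n_terms + penalty * max(n_terms - 1, 0) / 2
    denom = (1 - c / n) ** 2
    return np.inf if denom <= 0 else sse / n / denom


def _fit_mars(Z: np.ndarray, y: np.ndarray, max_terms: int = 12,
              n_knots: int = 5):
    """Greedy forward hinge-pair selection, then GCV backward pruning."""
    n, p = Z.shape
    qs = np.linspace(0.1, 0.9, n_knots)
    candidates = [(j, float(k))
                  for j in range(p)
                  for k in np.unique(np.quantile(Z[:, j], qs))]
    terms: list[tuple[int, float, int]] = []
    while len(terms) < max_terms:
        base = _MarsBasis(terms).design(Z)
        coef, *_ = np.linalg.lstsq(base, y, rcond=None)
        sse0 = float(np.sum((y - base @ coef) ** 2))
        best = None
        for j, k in candidates:
            h1 = np.maximum(0.0, Z[:, j] - k)
            h2 = np.maximum(0.0, k - Z[:, j])
            A = np.column_stack([base, h1, h2])
            c, *_ = np.linalg.lstsq(A, y, rcond=None)
            sse = float(np.sum((y - A @ c) ** 2))
            if best is None or sse < best[0]:
                best = (sse, j, k)
        if best is None or best[0] > sse0 - 1e-10:
            break
        _, j, k = best
        terms += [(j, k, +1), (j, k, -1)]
    # backward pruning on GCV
    def fit_sse(t):
        A = _MarsBasis(t).design(Z)
        c, *_ = np.linalg.lstsq(A, y, rcond=None)
        return float(np.sum((y - A @ c) ** 2)), c
    best_terms = list(terms)
    sse, _ = fit_sse(best_terms)
    best_gcv = _gcv(sse, n, len(best_terms) + 1)
    current = list(terms)
    while current:
        trials = []
        for i in range(len(current)):
            t = current[:i] + current[i + 1:]
            s, _ = fit_sse(t)
            trials.append((_gcv(s, n, len(t) + 1), i))
        g, i = min(trials)
        current = current[:i] + current[i + 1:]
        if g < best_gcv:
            best_gcv, best_terms = g, list(current)
    basis = _MarsBasis(best_terms)
    _, coef = fit_sse(best_terms)
    return basis, coef


# ---------------------------------------------------------------------
# Replicate model + results


class SpeciesDistributionModel:
    """One replicate presence/background model of a given family.

    Built from training feature tables (rows = points, columns = raw layer
    values, e.g. from ``extract_at_points``).  ``fit()`` returns an
    ``SDMResults``.
    """

    def __init__(self, presence_table: pd.DataFrame,
                 background_table: pd.DataFrame,
                 family: str = "GLM", regularization: float = 1.0):
        if family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        common = [c for c in presence_table.columns
                  if c in background_table.columns and c not in ("lon", "lat")]
        if not common:
            raise ValueError("no shared feature columns")
        self.family = family
        self.regularization = regularization
        self.presence_table = presence_table[common].reset_index(drop=True)
        self.background_table = background_table[common].reset_index(drop=True)
        self.variables = common

    def fit(self) -> "SDMResults":
        train = pd.concat([self.presence_table, self.background_table],
                          ignore_index=True)
        y = np.r_[np.ones(len(self.presence_table)),
                  np.zeros(len(self.background_table))]
        if y.min() == y.max():
            raise ValueError("degenerate training data: one class only")
        meta = {}
        if self.family == "GLM":
            spec = FeatureSpec.from_training(train, ("linear", "quadratic"))
            X = spec.build(train)
            est, meta = self._fit_logistic(X, y, C=1e4 / self.regularization)
            predictor = ("logistic", est)
        elif self.family == "MAXENT_LIKE":
            spec = FeatureSpec.from_training(
                train, ("linear", "quadratic", "hinge"))
            X = spec.build(train)
            est, meta = self._fit_logistic(X, y, C=1.0 / self.regularization)
            predictor = ("logistic", est)
        else:  # MARS_LIKE
            spec = FeatureSpec.from_training(train, ("linear",))
            Z = spec.build(train)
            basis, coef = _fit_mars(Z, y)
            predictor = ("mars", (basis, coef))
            meta["n_terms"] = len(basis.terms)
        return SDMResults(self, spec, predictor, meta)

    @staticmethod
    def _fit_logistic(X, y, C):
        meta = {}
        est = LogisticRegression(C=C, max_iter=2000, solver="lbfgs")
        est.fit(X, y)
        if np.abs(est.coef_).max() > 50:  # (near-)complete separation
            est = LogisticRegression(C=C / 100, max_iter=2000, solver="lbfgs")
            est.fit(X, y)
            meta["separation_fallback"] = True
        return est, meta


class SDMResults:
    """A fitted replicate: coefficients, feature spec, prediction methods.

    For the Maxent-like family the suitability is the fitted occurrence
    probability rescaled by its maximum over the calibration grid (set by
    ``calibrate_scale``); GLM and MARS probabilities are used directly,
    clipped to [0, 1].
    """

    def __init__(self, model: SpeciesDistributionModel, feature_spec,
                 predictor, meta):
        self.model = model
        self.family = model.family
        self.feature_spec = feature_spec
        self._predictor = predictor
        self.meta = dict(meta)
        self.scale = 1.0
        self.eval: EvalMetrics | None = None

    @property
    def params(self) -> np.ndarray:
        kind, obj = self._predictor
        if kind == "logistic":
            return np.r_[obj.intercept_, obj.coef_.ravel()]
        basis, coef = obj
        return np.asarray(coef)

    def _raw(self, table: pd.DataFrame) -> np.ndarray:
        kind, obj = self._predictor
        Xf = self.feature_spec.build(table)
        if kind == "logistic":
            return obj.predict_proba(Xf)[:, 1]
        basis, coef = obj
        return np.clip(basis.design(Xf) @ coef, 0.0, 1.0)

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        """Suitability in [0, 1] for a table of raw layer values."""
        return np.clip(self._raw(table) / self.scale, 0.0, 1.0)

    def predict_stack(self, env: EnvStack) -> np.ndarray:
        """Suitability grid over the valid mask of a stack (NaN elsewhere)."""
        table = env.values_table()
        out = np.full(env.shape, np.nan)
        out[env.mask] = self.predict(table)
        return out

    def calibrate_scale(self, env: EnvStack):
        """Freeze the grid-maximum rescale factor on the calibration stack."""
        if self.family == "MAXENT_LIKE":
            m = float(np.nanmax(self._raw(env.values_table())))
            self.scale = m if m > 0 else 1.0
        return self

    def evaluate(self, presence_table: pd.DataFrame,
                 background_table: pd.DataFrame) -> EvalMetrics:
        """AUC + TSS on held-out presences vs background."""
        self.eval = evaluate_scores(self.predict(presence_table),
                                    self.predict(background_table))
        return self.eval

    def summary(self) -> str:
        lines = [f"SDM replicate [{self.family}] on "
                 f"{len(self.model.presence_table)} presences / "
                 f"{len(self.model.background_table)} background"]
        if self.eval:
            lines.append(f"  AUC = {self.eval.auc:.4f}   "
                         f"TSS = {self.eval.tss_max:.4f} "
                         f"@ threshold {self.eval.tss_threshold:.4f}")
        if self.meta:
            lines.append(f"  meta: {self.meta}")
        return "\n".join(lines)


def fit_replicate(family: str, presence_table: pd.DataFrame,
                  background_table: pd.DataFrame,
                  regularization: float = 1.0,
                  env: EnvStack | None = None) -> SDMResults:
    """Fit one replicate; if ``env`` is given, freeze its rescale factor."""
    res = SpeciesDistributionModel(
        presence_table, background_table, family, regularization).fit()
    if env is not None:
        res.calibrate_scale(env)
    return res


# ---------------------------------------------------------------------
# Ensembles, binarization, areas, projection


@dataclass
class EnsembleSuitability:
    """TSS-weighted ensemble surface with its binarization cutoff."""

    suitability: np.ndarray
    mask: np.ndarray
    transform: GridTransform
    n_members: int
    member_weights: np.ndarray
    cutoff: float
    scenario: str = "current"


@dataclass
class BinaryRange:
    """Presence/absence grid plus its spherical surface area."""

    presence: np.ndarray
    area_km2: float
    scenario: str
    transform: GridTransform


def ensemble(fits: list[SDMResults], env: EnvStack,
             tss_min: float = TSS_MIN_DEFAULT,
             scenario: str = "current") -> EnsembleSuitability:
    """TSS-weighted mean of admitted members' suitability grids.

    Members must carry evaluation metrics; those with TSS >= tss_min are
    admitted with weights proportional to TSS.  The cutoff is the weighted
    mean of admitted members' TSS-maximizing thresholds.
    """
    admitted = [f for f in fits
                if f.eval is not None and f.eval.tss_max >= tss_min]
    if not admitted:
        raise ValueError(f"no admissible members: no replicate reached "
                         f"TSS >= {tss_min}")
    tss = np.array([f.eval.tss_max for f in admitted], dtype=float)
    w = tss / tss.sum()
    grids = np.stack([f.predict_stack(env) for f in admitted])
    suit = np.einsum("m,mrc->rc", w, grids)
    cutoff = float(np.dot(w, [f.eval.tss_threshold for f in admitted]))
    return EnsembleSuitability(suit, env.mask.copy(), env.transform,
                               len(admitted), w, cutoff, scenario)


def binarize(ens: EnsembleSuitability,
             cutoff: float | None = None) -> BinaryRange:
    """Presence where suitability >= cutoff on valid cells."""
    c = ens.cutoff if cutoff is None else cutoff
    if not (0 < c < 1):
        raise ValueError("cutoff must lie in (0, 1)")
    presence = ens.mask & (np.nan_to_num(ens.suitability, nan=-np.inf) >= c)
    area = area_km2(presence, ens.transform)
    return BinaryRange(presence, area, ens.scenario, ens.transform)


def area_km2(presence: np.ndarray, transform: GridTransform) -> float:
    """Spherical surface area of the presence cells.

    Cell area = R^2 * dlam * (sin(lat_top) - sin(lat_bottom)),
    R = 6371.0088 km, with row 0 at the grid's northern edge.
    """
    n_rows, n_cols = presence.shape
    cs = transform.cellsize
    lat_top_deg = transform.lat_min + (n_rows - np.arange(n_rows)) * cs
    lat_bot_deg = lat_top_deg - cs
    dlam = np.deg2rad(cs)
    row_area = (EARTH_RADIUS_KM ** 2) * dlam * (
        np.sin(np.deg2rad(lat_top_deg)) - np.sin(np.deg2rad(lat_bot_deg)))
    return float((presence.sum(axis=1) * row_area).sum())


def project(fits: list[SDMResults], scenario_env: EnvStack,
            current: EnsembleSuitability,
            scenario: str = "scenario") -> EnsembleSuitability:
    """Project the frozen current-climate ensemble onto a scenario stack.

    Uses exactly the members admitted into ``current`` (their order and
    weights) and the current cutoff — transferability.
    """
    admitted = list(fits)
    if len(current.member_weights) != len(admitted):
        raise ValueError(
            "pass exactly the members admitted into the current ensemble "
            f"({len(current.member_weights)}), got {len(admitted)}")
    missing = set(admitted[0].feature_spec.variables) - \
        set(scenario_env.layer_names)
    if missing:
        raise KeyError(f"scenario stack missing layers: {sorted(missing)}")
    grids = np.stack([f.predict_stack(scenario_env) for f in admitted])
    suit = np.einsum("m,mrc->rc", current.member_weights, grids)
    return EnsembleSuitability(suit, scenario_env.mask.copy(),
                               scenario_env.transform,
                               len(admitted), current.member_weights,
                               current.cutoff, scenario)


def average_scenarios(stacks: list[EnvStack]) -> EnvStack:
    """Cellwise mean of co-registered stacks (multi-GCM assembly stand-in)."""
    if not stacks:
        raise ValueError("need at least one stack")
    ref = stacks[0]
    for s in stacks[1:]:
        if s.shape != ref.shape or not s.transform.matches(ref.transform) \
                or s.layer_names != ref.layer_names:
            from .raster import CoRegistrationError
            raise CoRegistrationError("stacks are not co-registered")
    mask = np.logical_and.reduce([s.mask for s in stacks])
    layers = {name: np.mean([s.layers[name] for s in stacks], axis=0)
              for name in ref.layer_names}
    return EnvStack(layers, mask, ref.transform, ref.crs_note)


# ---------------------------------------------------------------------
# Ensemble model object


class EnsembleNicheModel:
    """Ensemble SDM for one species: occurrences + stack -> EnsembleResults.

    Parameters
    ----------
    occ : OccurrenceSet
        Presence records (ideally already thinned to the grid).
    env : EnvStack
        Calibration (current-climate) stack.
    n_background : int
        Pseudo-absence sample size (study default 10,000 at desk scale).
    families, n_replicates, train_frac, tss_min
        Modelling knobs; replicates are per family.
    """

    def __init__(self, occ: OccurrenceSet, env: EnvStack,
                 n_background: int = 10_000,
                 families=FAMILIES, n_replicates: int = 10,
                 train_frac: float = TRAIN_FRAC_DEFAULT,
                 tss_min: float = TSS_MIN_DEFAULT, seed: int = 0,
                 background: OccurrenceSet | None = None):
        self.occ = occ
        self.env = env
        self.families = tuple(families)
        self.n_replicates = n_replicates
        self.train_frac = train_frac
        self.tss_min = tss_min
        self.seed = seed
        self.background = background if background is not None else \
            sample_background(env, n_background, seed)
        self.presence_table, self._n_excl_p = extract_at_points(env, occ)
        self.background_table, _ = extract_at_points(env, self.background)

    def fit(self) -> "EnsembleResults":
        rng = np.random.default_rng(self.seed)
        members: list[SDMResults] = []
        failures = []
        for family in self.families:
            for r in range(self.n_replicates):
                split_seed = int(rng.integers(2 ** 31))
                (pt, pv), (bt, bv) = split_data(
                    len(self.presence_table), len(self.background_table),
                    self.train_frac, split_seed)
                try:
                    fit = fit_replicate(
                        family,
                        self.presence_table.iloc[pt],
                        self.background_table.iloc[bt],
                        env=self.env)
                    fit.evaluate(self.presence_table.iloc[pv],
                                 self.background_table.iloc[bv])
                except Exception as e:  # record, keep going
                    failures.append((family, r, str(e)))
                    continue
                members.append(fit)
        ens = ensemble(members, self.env, self.tss_min)
        return EnsembleResults(self, members, ens, failures)


class EnsembleResults:
    """Fitted ensemble: members, metrics, surface, cutoff, projections."""

    def __init__(self, model: EnsembleNicheModel, members, ens, failures):
        self.model = model
        self.members = members
        self.ensemble = ens
        self.failures = failures
        self._admitted = [m for m in members
                          if m.eval.tss_max >= model.tss_min]

    @property
    def suitability(self) -> np.ndarray:
        return self.ensemble.suitability

    @property
    def cutoff(self) -> float:
        return self.ensemble.cutoff

    def metrics_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"family": m.family, "auc": m.eval.auc, "tss": m.eval.tss_max,
              "tss_threshold": m.eval.tss_threshold,
              "admitted": m.eval.tss_max >= self.model.tss_min}
             for m in self.members])

    def binarize(self, cutoff: float | None = None) -> BinaryRange:
        return binarize(self.ensemble, cutoff)

    def project(self, scenario_env: EnvStack,
                scenario: str = "scenario") -> EnsembleSuitability:
        return project(self._admitted, scenario_env, self.ensemble, scenario)

    def summary(self) -> str:
        t = self.metrics_table()
        lines = [
            f"Ensemble niche model: {self.model.occ.species}",
            f"  presences: {len(self.model.presence_table)}   "
            f"background: {len(self.model.background_table)}",
            f"  members fitted: {len(self.members)} "
            f"({len(self.failures)} failures)   "
            f"admitted (TSS >= {self.model.tss_min}): "
            f"{self.ensemble.n_members}",
            f"  cutoff: {self.cutoff:.4f}",
            "  per-family mean AUC / TSS:",
        ]
        for fam, sub in t.groupby("family"):
            lines.append(f"    {fam:12s} AUC {sub['auc'].mean():.3f}  "
                         f"TSS {sub['tss'].mean():.3f}")
        return "\n".join(lines)
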