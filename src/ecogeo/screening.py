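"""Predictor collinearity screening and habitat-divergence ordinations.

Screening retains environmental variables so that every pairwise Pearson
|r| stays below a threshold (default 0.75) and every variance inflation
factor stays at or below a threshold (default 10).  Ordinations (PCA on
standardized variables; linear discriminant analysis with proportional
priors) summarize habitat differentiation among species' occurrence
environments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

R_THRESHOLD_DEFAULT = 0.75
VIF_THRESHOLD_DEFAULT = 10.0


@dataclass
class ScreeningResult:
    retained: list[str]
    dropped: list[tuple[str, str]]  # (variable, reason)
    corr_matrix: pd.DataFrame
    vif: dict[str, float]
    warnings: list[str] = field(default_factory=list)


@dataclass
class OrdinationResult:
    axis_loadings: pd.DataFrame         # variables x axes
    variance_explained: np.ndarray      # fraction per axis, non-increasing
    scores: np.ndarray                  # samples x axes
    group_labels: np.ndarray | None = None
    confusion: pd.DataFrame | None = None


def _complete_cases(values: pd.DataFrame) -> pd.DataFrame:
    df = pd.DataFrame(values).apply(pd.to_numeric, errors="coerce")
    return df.dropna()


def pearson_screen(values: pd.DataFrame,
                   r_threshold: float = R_THRESHOLD_DEFAULT):
    """Flag all unordered variable pairs with |r| >= r_threshold.

    Returns (flagged pairs, correlation matrix, zero-variance variables).
    Correlations are computed on complete cases; zero-variance variables
    have undefined correlations and are flagged for removal.
    """
    df = _complete_cases(values)
    if df.shape[0] < 3 or df.shape[1] < 2:
        raise ValueError("need >= 3 samples and >= 2 variables")
    sd = df.std(ddof=1)
    degenerate = list(sd.index[sd == 0])
    corr = df.corr()
    flagged = []
    cols = list(df.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            r = corr.loc[a, b]
            if np.isfinite(r) and abs(r) >= r_threshold:
                flagged.append((a, b))
    return flagged, corr, degenerate


def vif_all(values: pd.DataFrame) -> dict[str, float]:
    """Variance inflation factor per variable: VIF_j = 1/(1 - R2_j).

    R2_j comes from the least-squares regression of variable j on all the
    others (with intercept).  Exact linear dependence gives inf.
    """
    df = _complete_cases(values)
    n, p = df.shape
    if p < 2:
        return {c: float("nan") for c in df.columns}
    if n <= p:
        raise ValueError("need more samples than variables for VIF")
    X = df.to_numpy(dtype=float)
    out = {}
    for j, name in enumerate(df.columns):
        y = X[:, j]
        others = np.delete(X, j, axis=1)
        A = np.column_stack([np.ones(n), others])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        ss_tot = np.sum((y - y.mean()) ** 2)
        if ss_tot == 0:
            out[name] = float("nan")
            continue
        r2 = 1 - resid @ resid / ss_tot
        out[name] = float("inf") if r2 >= 1 - 1e-12 else float(1 / (1 - r2))
    return out


def screen(values: pd.DataFrame,
           r_threshold: float = R_THRESHOLD_DEFAULT,
           vif_threshold: float = VIF_THRESHOLD_DEFAULT) -> ScreeningResult:
    """Iterative collinearity screen: Pearson pass, then VIF pass.

    From each flagged Pearson pair the member with the larger mean absolute
    correlation to all other variables is dropped; then the variable with
    the largest VIF is dropped until all VIF <= vif_threshold.  Ties break
    by input column order, so the result is deterministic.
    """
    df = _complete_cases(values)
    order = list(df.columns)
    dropped: list[tuple[str, str]] = []
    warns: list[str] = []

    sd = df.std(ddof=1)
    for name in sd.index[sd == 0]:
        dropped.append((name, "zero variance"))
    live = [c for c in order if (c, "zero variance") not in dropped]

    # Pearson pass
    while len(live) >= 2:
        flagged, corr, _ = pearson_screen(df[live], r_threshold) \
            if len(live) >= 2 else ([], None, [])
        if not flagged:
            break
        mean_abs = corr.abs().where(~np.eye(len(live), dtype=bool)).mean()
        # drop the worst member over all flagged pairs this round
        candidates = {v for pair in flagged for v in pair}
        victim = max(sorted(candidates, key=live.index),
                     key=lambda v: mean_abs[v])
        partner = next(b if a == victim else a
                       for a, b in flagged if victim in (a, b))
        dropped.append((victim, f"|r| >= {r_threshold} with {partner}"))
        live.remove(victim)

    # VIF pass
    while len(live) >= 2:
        vifs = vif_all(df[live])
        worst = max(live, key=lambda v: (vifs[v] if np.isfinite(vifs[v])
                                         else np.inf))
        if not np.isfinite(vifs[worst]) or vifs[worst] > vif_threshold:
            dropped.append((worst, f"VIF {vifs[worst]:.3g} > {vif_threshold}"))
            live.remove(worst)
        else:
            break

    if len(live) < 2:
        msg = "fewer than 2 variables survive screening"
        warns.append(msg)
        warnings.warn(msg, stacklevel=2)
    final_corr = df[live].corr() if len(live) >= 2 else pd.DataFrame()
    final_vif = vif_all(df[live]) if len(live) >= 2 else \
        {c: float("nan") for c in live}
    return ScreeningResult(live, dropped, final_corr, final_vif, warns)


def pca_habitat(values: pd.DataFrame) -> OrdinationResult:
    """PCA of the occurrence-environment table on the correlation matrix.

    Variables are standardized to zero mean, unit variance (units are
    incommensurate), so variance-explained fractions sum to 1.
    """
    df = _complete_cases(values)
    if df.shape[0] < 3:
        raise ValueError("need >= 3 samples for PCA")
    sd = df.std(ddof=0)
    zero = list(sd.index[sd == 0])
    if zero:
        raise ValueError(f"zero-variance variable(s): {zero}")
    Z = (df - df.mean()) / sd
    pca = PCA()
    scores = pca.fit_transform(Z.to_numpy())
    loadings = pd.DataFrame(
        pca.components_.T, index=df.columns,
        columns=[f"PC{i + 1}" for i in range(pca.n_components_)])
    return OrdinationResult(loadings, pca.explained_variance_ratio_, scores)


def dfa_habitat(values: pd.DataFrame, species_labels) -> OrdinationResult:
    """Linear discriminant analysis of occurrence environments by species.

    Priors proportional to group sizes; reports the training-set
    classification (confusion) table.
    """
    df = _complete_cases(pd.DataFrame(values))
    y = np.asarray(species_labels)
    if len(y) != len(values):
        raise ValueError("labels must match rows")
    y = y[pd.DataFrame(values).apply(pd.to_numeric, errors="coerce")
          .notna().all(axis=1).to_numpy()]
    groups, counts = np.unique(y, return_counts=True)
    if len(groups) < 2:
        raise ValueError("DFA needs >= 2 groups")
    if (counts <= df.shape[1]).any():
        raise ValueError("each group needs more samples than variables")
    lda = LinearDiscriminantAnalysis()
    X = df.to_numpy(dtype=float)
    try:
        scores = lda.fit_transform(X, y)
    except np.linalg.LinAlgError as e:  # singular within-group covariance
        raise ValueError(f"singular within-group covariance: {e}") from e
    pred = lda.predict(X)
    confusion = pd.crosstab(pd.Series(y, name="true"),
                            pd.Series(pred, name="predicted"))
    loadings = pd.DataFrame(
        lda.scalings_[:, :scores.shape[1]], index=df.columns,
        columns=[f"LD{i + 1}" for i in range(scores.shape[1])])
    ev = lda.explained_variance_ratio_[:scores.shape[1]]
    return OrdinationResult(loadings, ev, scores, group_labels=y,
                            confusion=confusion)
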