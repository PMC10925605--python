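"""Brain-behaviour statistics: dominance analysis and supporting tests.

Dominance analysis apportions a regression model's explained variance
among predictors by fitting every non-empty predictor subset (2^p - 1
models).  The *total dominance* of predictor j is the average — first
within each subset size, then across sizes — of the increase in fit when
j joins a subset that excludes it.  With unadjusted R^2 this is the
classical decomposition and the dominances sum exactly to the full-model
R^2; an adjusted-R^2 variant is provided for reporting conventions that
prefer it (additivity then holds only approximately).  Relative
importance expresses each dominance as a percentage of the total.

Also here: within-dataset min-max normalisation of markers (so datasets
acquired with different scanners/contrast agents can be pooled), a
permutation test of the full-model fit, arousal dichotomisation for the
classification variant (McFadden pseudo-R^2), and Benjamini-Hochberg FDR
adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateInputError, ParameterError

__all__ = [
    "MARKER_COLUMNS",
    "DominanceResult",
    "normalize_markers",
    "dominance_analysis",
    "classification_dominance",
    "permutation_test_r2",
    "dichotomize_arousal",
    "fdr_adjust",
]

#: default predictor columns of a marker table
MARKER_COLUMNS = ("gradient_range", "hierarchical_integration", "harmonic_energy")


@dataclass(frozen=True)
class DominanceResult:
    """Outcome of a dominance analysis.

    ``total_dominance`` and ``relative_importance`` (percent) are keyed by
    predictor name; ``r2``/``adjusted_r2`` describe the full model.
    ``p_value`` and ``null_r2`` are present when a permutation test was
    run.
    """

    predictors: tuple[str, ...]
    total_dominance: dict
    relative_importance: dict
    r2: float
    adjusted_r2: float
    n_models: int
    fit_metric: str
    p_value: float | None = None
    null_r2: np.ndarray | None = None
    n_permutations: int | None = None
    seed: int | None = None

    def to_dict(self) -> dict:
        out = {
            "predictors": list(self.predictors),
            "total_dominance": dict(self.total_dominance),
            "relative_importance": dict(self.relative_importance),
            "r2": self.r2,
            "adjusted_r2": self.adjusted_r2,
            "n_models": self.n_models,
            "fit_metric": self.fit_metric,
        }
        if self.p_value is not None:
            out.update(
                p_value=self.p_value,
                n_permutations=self.n_permutations,
                seed=self.seed,
            )
        return out


def normalize_markers(
    table: pd.DataFrame,
    columns=MARKER_COLUMNS,
    by: str = "dataset",
) -> pd.DataFrame:
    """Min-max scale marker columns to [0, 1] within each dataset.

    Each marker is shifted by its within-dataset minimum and divided by
    the post-shift maximum, so every dataset attains both 0 and 1.
    """
    table = table.copy()
    for col in columns:
        if col not in table.columns:
            raise ParameterError(f"marker column {col!r} missing from table")
        table[col] = table[col].astype(float)
    for group, idx in table.groupby(by).groups.items():
        for col in columns:
            x = table.loc[idx, col].to_numpy(dtype=float)
            span = x.max() - x.min()
            if span <= 0:
                raise DegenerateInputError(
                    f"marker {col!r} is constant within dataset {group!r}"
                )
            table.loc[idx, col] = (x - x.min()) / span
    return table


def _ols_r2(x: np.ndarray, y: np.ndarray) -> float:
    design = np.column_stack([np.ones(len(y)), x]) if x.size else np.ones((len(y), 1))
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    sst = float(((y - y.mean()) ** 2).sum())
    if sst <= 0:
        raise DegenerateInputError("response has zero variance")
    return 1.0 - float((resid**2).sum()) / sst


def _adjust(r2: float, n: int, k: int) -> float:
    if n - k - 1 <= 0:
        raise ParameterError("too few observations for adjusted R^2")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)


def _subset_fits(x, y, fit, p):
    """Fit statistic for every subset of predictors (empty set -> 0)."""
    fits = {(): 0.0}
    for size in range(1, p + 1):
        for subset in combinations(range(p), size):
            fits[subset] = fit(x[:, subset], y)
    return fits


def _dominance_from_fits(fits, p):
    dom = np.zeros(p)
    others = list(range(p))
    for j in range(p):
        rest = [i for i in others if i != j]
        size_means = []
        for size in range(0, p):
            incs = [
                fits[tuple(sorted(subset + (j,)))] - fits[subset]
                for subset in combinations(rest, size)
            ]
            size_means.append(np.mean(incs))
        dom[j] = np.mean(size_means)
    return dom


def dominance_analysis(
    x,
    y,
    predictor_names=None,
    fit_metric: str = "r2",
) -> DominanceResult:
    """All-subsets total dominance of ``y`` on the columns of ``x``.

    Fits 2^p - 1 ordinary least-squares models.  ``fit_metric`` is
    ``"r2"`` (default; dominances then sum exactly to the full-model R^2)
    or ``"adjusted_r2"``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if x.ndim == 1:
        x = x[:, None]
    n, p = x.shape
    if predictor_names is None:
        predictor_names = tuple(f"x{j + 1}" for j in range(p))
    predictor_names = tuple(predictor_names)
    if len(predictor_names) != p:
        raise ParameterError("one name per predictor required")
    if n != y.size:
        raise ParameterError("x and y lengths differ")
    if not n > p:
        raise ParameterError(f"need n > p, got n={n}, p={p}")
    if fit_metric not in ("r2", "adjusted_r2"):
        raise ParameterError(f"unknown fit_metric {fit_metric!r}")
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), x])) < p + 1:
        raise DegenerateInputError("full design matrix is rank-deficient")

    if fit_metric == "r2":
        fit = _ols_r2
    else:
        def fit(xs, ys):
            return _adjust(_ols_r2(xs, ys), n, xs.shape[1])

    fits = _subset_fits(x, y, fit, p)
    dom = _dominance_from_fits(fits, p)
    total = dom.sum()
    if total <= 0:
        rel = np.full(p, 100.0 / p)
    else:
        rel = 100.0 * dom / total
    full_r2 = _ols_r2(x, y)
    return DominanceResult(
        predictors=predictor_names,
        total_dominance=dict(zip(predictor_names, dom.tolist())),
        relative_importance=dict(zip(predictor_names, rel.tolist())),
        r2=full_r2,
        adjusted_r2=_adjust(full_r2, n, p),
        n_models=len(fits) - 1,
        fit_metric=fit_metric,
    )


def _mcfadden_r2(x: np.ndarray, y: np.ndarray) -> float:
    """McFadden pseudo-R^2 of an (unpenalised) logistic fit."""
    n = len(y)
    q = y.mean()
    if q in (0.0, 1.0):
        raise DegenerateInputError("binary response has a single class")
    ll_null = n * (q * np.log(q) + (1 - q) * np.log(1 - q))
    if x.size == 0:
        return 0.0
    model = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000)
    model.fit(x, y)
    prob = np.clip(model.predict_proba(x)[:, 1], 1e-12, 1 - 1e-12)
    ll = float(np.sum(y * np.log(prob) + (1 - y) * np.log(1 - prob)))
    return 1.0 - ll / ll_null


def classification_dominance(
    x,
    y_binary,
    predictor_names=None,
) -> DominanceResult:
    """Dominance analysis with a binary target and logistic submodels.

    The fit statistic is McFadden's pseudo-R^2.  Used with dichotomised
    arousal scores to express predictor importance for classifying high
    versus low arousal.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y_binary, dtype=float).ravel()
    if x.ndim == 1:
        x = x[:, None]
    n, p = x.shape
    if predictor_names is None:
        predictor_names = tuple(f"x{j + 1}" for j in range(p))
    predictor_names = tuple(predictor_names)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ParameterError("y_binary must contain only 0/1 labels")

    fits = _subset_fits(x, y, _mcfadden_r2, p)
    dom = _dominance_from_fits(fits, p)
    total = dom.sum()
    rel = 100.0 * dom / total if total > 0 else np.full(p, 100.0 / p)
    full = fits[tuple(range(p))]
    return DominanceResult(
        predictors=predictor_names,
        total_dominance=dict(zip(predictor_names, dom.tolist())),
        relative_importance=dict(zip(predictor_names, rel.tolist())),
        r2=full,
        adjusted_r2=np.nan,
        n_models=len(fits) - 1,
        fit_metric="mcfadden_r2",
    )


def permutation_test_r2(
    x,
    y,
    n_perm: int = 1000,
    seed: int | None = None,
    fit_metric: str = "r2",
) -> tuple[float, np.ndarray]:
    """One-sided permutation test of the full-model fit.

    The response is randomly reassigned ``n_perm`` times;
    p = (1 + #{null fit >= observed fit}) / (1 + n_perm), which is never
    exactly zero (small-sample correction).  Returns ``(p, null_fits)``.
    """
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if x.ndim == 1:
        x = x[:, None]
    n, p = x.shape

    if fit_metric == "r2":
        fit = _ols_r2
    elif fit_metric == "adjusted_r2":
        def fit(xs, ys):
            return _adjust(_ols_r2(xs, ys), n, xs.shape[1])
    else:
        raise ParameterError(f"unknown fit_metric {fit_metric!r}")

    observed = fit(x, y)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = fit(x, rng.permutation(y))
    p_value = (1.0 + np.sum(null >= observed)) / (1.0 + n_perm)
    return float(p_value), null


def dichotomize_arousal(scores, cutoff: int) -> np.ndarray:
    """Binary labels: 1 iff score >= cutoff.

    Cutoff 9 separates full wakefulness and high-amplitude centro-median
    stimulation from everything else; cutoff 3 additionally counts light
    anaesthesia and low-amplitude centro-median stimulation as aroused.
    """
    if cutoff not in (3, 9):
        raise ParameterError(f"cutoff must be 3 or 9, got {cutoff}")
    scores = np.asarray(scores, dtype=float)
    if np.any((scores < 0) | (scores > 11)):
        raise ParameterError("arousal scores must lie in [0, 11]")
    return (scores >= cutoff).astype(int)


def fdr_adjust(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR adjustment.

    Returns ``(adjusted_p, reject)`` where ``reject`` marks hypotheses
    significant at level ``q``.
    """
    pvals = np.asarray(pvals, dtype=float)
    if np.any((pvals < 0) | (pvals > 1)) or not np.all(np.isfinite(pvals)):
        raise ParameterError("p-values must lie in [0, 1]")
    reject, adjusted, *_ = multipletests(pvals, alpha=q, method="fdr_bh")
    return adjusted, reject
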