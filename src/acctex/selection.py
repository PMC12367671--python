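"""Collinearity-aware feature selection.

Radiomic features are heavily redundant; before group testing, every pair
of features with absolute Spearman rank correlation above a threshold
(default 0.9) is reduced to a single member. The member kept is the one
with the higher maximum standardized mean difference across the outcome
groups:

    MaxSD = max over group pairs (i, j) of |mu_i - mu_j| / sigma_pooled

where ``sigma_pooled`` is the k-group pooled standard deviation (square
root of the group-size-weighted average of within-group variances, with
the usual n_g - 1 denominators). Pairs are processed greedily in a
deterministic order — descending |rho|, then lexicographic names — and a
feature already dropped generates no further eliminations, so the result
is invariant to input column order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

DEFAULT_RHO_THRESHOLD = 0.9


@dataclass
class SelectionResult:
    """Outcome of collinearity pruning."""

    retained: list[str]
    dropped: dict[str, str]  # dropped feature -> retained partner that beat it
    pairs: list[tuple[str, str, float]]  # (kept, dropped, |rho|) in processing order
    max_sd: dict[str, float]
    group_means: pd.DataFrame = field(default=None, repr=False)

    def representative(self, feature: str) -> str:
        """Follow the dropped->kept chain to the retained representative."""
        while feature in self.dropped:
            feature = self.dropped[feature]
        return feature

    def to_frame(self) -> pd.DataFrame:
        """Selection report: feature, max_sd, status, partner, abs_rho."""
        rho = {d: r for _, d, r in self.pairs}
        rows = [
            {
                "feature": f,
                "max_sd": self.max_sd.get(f, np.nan),
                "status": "dropped" if f in self.dropped else "retained",
                "partner": self.dropped.get(f, ""),
                "abs_rho": rho.get(f, np.nan),
            }
            for f in sorted(set(self.retained) | set(self.dropped))
        ]
        return pd.DataFrame(rows)


def pooled_sd(values: np.ndarray, groups: np.ndarray) -> float:
    """k-group pooled SD: sqrt of the (n_g - 1)-weighted mean within-group variance."""
    labels = np.unique(groups)
    num = 0.0
    den = 0
    for g in labels:
        x = values[groups == g]
        if x.size > 1:
            num += (x.size - 1) * float(np.var(x, ddof=1))
            den += x.size - 1
    return float(np.sqrt(num / den)) if den > 0 else 0.0


def max_sd(values, groups) -> float:
    """Maximum pairwise standardized mean difference across groups.

    Zero pooled SD (all groups internally constant) gives a score of 0
    with a warning rather than an error.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if not np.all(np.isfinite(values)):
        raise ValueError("max_sd requires finite values")
    labels = np.unique(groups)
    if labels.size < 2:
        raise ValueError("max_sd needs at least two groups")
    means = [float(np.mean(values[groups == g])) for g in labels]
    sp = pooled_sd(values, groups)
    if sp == 0:
        warnings.warn("pooled SD is zero; MaxSD defined as 0", stacklevel=2)
        return 0.0
    diffs = [abs(a - b) for i, a in enumerate(means) for b in means[i + 1 :]]
    return max(diffs) / sp


def prune_collinear(
    table: pd.DataFrame,
    labels: Sequence,
    rho_threshold: float = DEFAULT_RHO_THRESHOLD,
) -> SelectionResult:
    """Eliminate one member of every strongly rank-correlated feature pair.

    Parameters
    ----------
    table
        Cases x features matrix (numeric columns only). Rows with any
        missing value are dropped (complete-case) with a log message.
    labels
        Per-case group labels defining the MaxSD grouping (the analysis
        arm's own target: grade or variant).
    """
    if len(table) != len(labels):
        raise ValueError("labels must align with table rows")
    labels = np.asarray(labels)
    complete = table.notna().all(axis=1).to_numpy()
    if not complete.all():
        logger.info("dropping %d incomplete cases before pruning", int((~complete).sum()))
        table = table.loc[complete]
        labels = labels[complete]
    if len(table) < 3:
        raise ValueError("need at least 3 complete cases to estimate correlations")
    features = sorted(table.columns)
    X = table[features].to_numpy(dtype=float)

    scores = {f: max_sd(X[:, k], labels) for k, f in enumerate(features)}
    group_means = table[features].groupby(labels).mean()

    constant = X.std(axis=0) == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant feature(s): correlation undefined, treated as 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore"):
        if len(features) == 1:
            rho = np.ones((1, 1))
        elif len(features) == 2:  # scipy returns a scalar for two columns
            r = stats.spearmanr(X[:, 0], X[:, 1]).statistic
            rho = np.array([[1.0, r], [r, 1.0]])
        else:
            rho = stats.spearmanr(X).statistic
    rho = np.nan_to_num(rho, nan=0.0)  # constant features: rho treated as 0

    # candidate pairs above threshold, deterministic processing order
    cand = [
        (abs(rho[i, j]), features[i], features[j])
        for i in range(len(features))
        for j in range(i + 1, len(features))
        if abs(rho[i, j]) > rho_threshold
    ]
    cand.sort(key=lambda t: (-t[0], t[1], t[2]))

    dropped: dict[str, str] = {}
    pairs: list[tuple[str, str, float]] = []
    for r, fa, fb in cand:
        if fa in dropped or fb in dropped:
            continue
        # keep the higher-MaxSD member; lexicographic tie-break
        keep, drop = (fa, fb) if (scores[fa], fb) >= (scores[fb], fa) else (fb, fa)
        dropped[drop] = keep
        pairs.append((keep, drop, float(r)))
    retained = [f for f in features if f not in dropped]
    return SelectionResult(
        retained=retained, dropped=dropped, pairs=pairs, max_sd=scores, group_means=group_means
    )


class CollinearityPruner(BaseEstimator, TransformerMixin):
    """Sklearn-style selector wrapping :func:`prune_collinear`.

    ``fit(X, y)`` takes the cases x features frame and the grouping labels;
    ``transform`` keeps the retained columns.

    Attributes
    ----------
    retained_features_ : list of str
    result_ : SelectionResult
    """

    def __init__(self, rho_threshold: float = DEFAULT_RHO_THRESHOLD):
        self.rho_threshold = rho_threshold

    def fit(self, X: pd.DataFrame, y) -> "CollinearityPruner":
        self.result_ = prune_collinear(X, y, self.rho_threshold)
        self.retained_features_ = self.result_.retained
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "retained_features_"):
            raise RuntimeError("CollinearityPruner is not fitted")
        return X[[c for c in X.columns if c in set(self.retained_features_)]]

    def get_support(self, indices: bool = False):
        mask = np.array([c in set(self.retained_features_) for c in self.result_.max_sd])
        return np.where(mask)[0] if indices else mask
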