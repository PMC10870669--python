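"""Data-preparation chain: missingness filter, kNN imputation, correlation
screening, stratified development/test split, and 1:1 balanced cohorts.

The stages mirror the order used when developing visit-level impairment
models on registry data: variables observed in too few subjects are dropped,
the remainder are completed by k-nearest-neighbour imputation, a
coarse-to-fine correlation screen reduces the candidate set, and the cohort
is split 7:3 before cases and controls are paired 1:1 for classifier
development.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics.pairwise import nan_euclidean_distances

from .cohort import CohortTable, LabeledCohort
from .errors import (
    ConfigurationError,
    InsufficientControlsError,
    InvalidInputError,
    SchemaError,
    StratificationError,
    UnimputableRecordError,
)


@dataclass
class PreprocessConfig:
    """Knobs of the preparation chain with their conventional defaults."""

    missing_threshold: float = 0.30
    knn_k: int = 5
    alpha: float = 0.05
    split_ratio: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.missing_threshold < 1:
            raise ConfigurationError("missing_threshold must lie in (0, 1)")
        if self.knn_k < 1:
            raise ConfigurationError("knn_k must be >= 1")
        if not 0 < self.split_ratio < 1:
            raise ConfigurationError("split_ratio must lie in (0, 1)")


def filter_missingness(cohort: CohortTable, threshold: float = 0.30) -> CohortTable:
    """Drop variables whose missing fraction strictly exceeds ``threshold``.

    A variable missing in exactly ``threshold`` of subjects is retained;
    the subject set is never altered.  Idempotent.
    """
    if not 0 < threshold < 1:
        raise InvalidInputError("threshold must lie in (0, 1)")
    frac = cohort.missing_mask.mean(axis=0)
    keep = [c for c in cohort.variables if frac[c] <= threshold]
    if not keep:
        raise SchemaError("missingness filter removed every variable")
    return cohort.subset(keep)


def knn_impute(cohort: CohortTable, k: int = 5) -> CohortTable:
    """Complete the table by k-nearest-neighbour imputation.

    Distances are Euclidean on z-standardised columns, rescaled over the
    mutually observed coordinates of each subject pair.  Continuous and
    score variables take the neighbour mean; binary and ordinal variables
    take the neighbour mode (ties resolved toward the smaller value).
    Observed cells are never altered.
    """
    if k < 1:
        raise InvalidInputError("k must be >= 1")
    data = cohort.data
    if data.isna().all(axis=1).any():
        bad = data.index[data.isna().all(axis=1)][0]
        raise UnimputableRecordError(f"subject {bad!r} has no observed cell")
    n_obs = data.notna().sum(axis=0)
    thin = n_obs[n_obs < k]
    if len(thin):
        raise InvalidInputError(
            f"variables observed in fewer than k={k} subjects: {list(thin.index)}"
        )
    if not data.isna().any().any():
        return cohort

    mu = data.mean(axis=0)
    sd = data.std(axis=0, ddof=0).replace(0.0, 1.0)
    z = (data - mu) / sd
    dist = nan_euclidean_distances(z.values)
    np.fill_diagonal(dist, np.inf)
    dist = np.where(np.isnan(dist), np.inf, dist)

    out = data.copy()
    values = data.values
    for j, col in enumerate(data.columns):
        col_missing = np.flatnonzero(np.isnan(values[:, j]))
        if col_missing.size == 0:
            continue
        donors = np.flatnonzero(~np.isnan(values[:, j]))
        kind = cohort.spec(col).kind
        for i in col_missing:
            order = donors[np.argsort(dist[i, donors], kind="stable")][:k]
            neigh = values[order, j]
            if kind in ("continuous", "score"):
                imputed = float(np.mean(neigh))
            else:
                vals, counts = np.unique(neigh, return_counts=True)
                imputed = float(vals[np.argmax(counts)])  # ties -> smallest value
            out.iat[i, j] = imputed
    return CohortTable(out, list(cohort.dictionary.values()))


@dataclass
class ScreenReport:
    """Per-variable correlation screen results (coarse-to-fine selection)."""

    table: pd.DataFrame  # variable, pearson_r, pearson_p, spearman_r, spearman_p, retained

    @property
    def retained(self) -> list[str]:
        return list(self.table.loc[self.table["retained"], "variable"])

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def coarse_to_fine_select(
    cohort: LabeledCohort, alpha: float = 0.05, top_k: Optional[int] = None
) -> ScreenReport:
    """Screen predictors by Pearson (point-biserial) and Spearman tests.

    A variable is retained when either test reaches significance at
    ``alpha`` (min of the two p-values <= alpha).  Constant variables are
    untestable and never retained.  ``top_k`` optionally keeps exactly the
    k smallest-p variables instead, reproducing a fixed fine-feature count.
    """
    y = cohort.labels.values
    if len(np.unique(y)) < 2:
        raise StratificationError("both outcome classes must be present to screen")
    rows = []
    for col in cohort.features.columns:
        x = cohort.features[col].values
        ok = ~np.isnan(x)
        xi, yi = x[ok], y[ok]
        if xi.size < 3 or np.nanstd(xi) == 0 or len(np.unique(yi)) < 2:
            rows.append((col, np.nan, np.nan, np.nan, np.nan, False))
            continue
        pr, pp = stats.pearsonr(xi, yi)
        sr, sp = stats.spearmanr(xi, yi)
        rows.append((col, pr, pp, sr, sp, min(pp, sp) <= alpha))
    table = pd.DataFrame(
        rows,
        columns=["variable", "pearson_r", "pearson_p", "spearman_r", "spearman_p", "retained"],
    )
    if top_k is not None:
        minp = table[["pearson_p", "spearman_p"]].min(axis=1).fillna(np.inf)
        order = np.argsort(minp.values, kind="stable")[:top_k]
        table["retained"] = False
        table.loc[table.index[order], "retained"] = minp.iloc[order] < np.inf
    return ScreenReport(table)


def split_dev_test(
    cohort: LabeledCohort, ratio: float = 0.7, seed: int = 0
) -> tuple[LabeledCohort, LabeledCohort]:
    """Partition into development and test sets, stratified by label.

    The test set receives round(n * (1 - ratio)) subjects (banker's
    rounding), allocated across classes by largest remainder so that the
    test prevalence tracks the cohort prevalence to within one subject.
    Deterministic given the seed.
    """
    if not 0 < ratio < 1:
        raise InvalidInputError("ratio must lie in (0, 1)")
    y = cohort.labels
    counts = y.value_counts()
    if (counts < 2).any() or len(counts) < 2:
        raise StratificationError("each class needs at least 2 members to stratify")
    n = len(cohort.labels)
    n_test = int(round(n * (1.0 - ratio)))
    rng = np.random.default_rng(seed)

    exact = {c: counts[c] * n_test / n for c in counts.index}
    base = {c: int(np.floor(v)) for c, v in exact.items()}
    short = n_test - sum(base.values())
    for c in sorted(exact, key=lambda c: exact[c] - base[c], reverse=True)[:short]:
        base[c] += 1

    test_idx = []
    for c in sorted(counts.index):
        members = cohort.labels.index[y == c].to_numpy()
        picked = rng.choice(members, size=base[c], replace=False)
        test_idx.extend(picked)
    test_set = pd.Index(test_idx)
    dev_set = cohort.labels.index.difference(test_set, sort=False)
    return cohort.take(dev_set), cohort.take(test_set)


def balance_cohort(cohort: LabeledCohort, seed: int = 0) -> LabeledCohort:
    """Pair every case with a randomly drawn control at a 1:1 ratio.

    Keeps all positives and a without-replacement random sample of
    negatives of equal size; the output prevalence is exactly 50%.
    """
    y = cohort.labels
    pos = y.index[y == 1].to_numpy()
    neg = y.index[y == 0].to_numpy()
    if pos.size == 0 or neg.size == 0:
        raise StratificationError("both classes must be present to balance")
    if pos.size > neg.size:
        raise InsufficientControlsError(
            f"{pos.size} cases but only {neg.size} controls available"
        )
    rng = np.random.default_rng(seed)
    sampled = rng.choice(neg, size=pos.size, replace=False)
    chosen = np.concatenate([pos, sampled])
    chosen = chosen[rng.permutation(chosen.size)]
    return cohort.take(pd.Index(chosen))
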