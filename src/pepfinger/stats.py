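"""Cohort statistics over fingerprint feature tables.

Two-group comparisons use a two-sided t-test — Student's by default, Welch's
when Levene's test flags unequal variances — with Cohen's d (pooled SD) and
the conventional significance labels (* p <= 0.05, ** p <= 0.01,
*** p <= 0.001; effect sizes small/medium/large at |d| = 0.2/0.4/0.6).
Feature structure is summarised by Pearson biclustering (1 - r distance,
average linkage, per-column z-normalisation) and by partial-correlation
networks from the (optionally Ledoit-Wolf-shrunken) inverse covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.covariance import LedoitWolf

LEVENE_ALPHA = 0.05
EFFECT_THRESHOLDS = (0.2, 0.4, 0.6)  # small, medium, large


class StatsError(ValueError):
    pass


@dataclass
class GroupComparison:
    feature: str
    test: str  # student | welch
    p_value: float
    cohens_d: float
    label: str  # ns | * | ** | ***
    effect_label: str  # negligible | small | medium | large
    mean_a: float = 0.0
    mean_b: float = 0.0
    n_a: int = 0
    n_b: int = 0


def significance_label(p: float) -> str:
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:  # boundary p = 0.05 counts as significant
        return "*"
    return "ns"


def effect_size_label(d: float) -> str:
    a = abs(d)
    if a >= EFFECT_THRESHOLDS[2]:
        return "large"
    if a >= EFFECT_THRESHOLDS[1]:
        return "medium"
    if a >= EFFECT_THRESHOLDS[0]:
        return "small"
    return "negligible"


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's d with the pooled-SD denominator."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0:
        return 0.0 if a.mean() == b.mean() else np.inf * np.sign(a.mean() - b.mean())
    return float((a.mean() - b.mean()) / np.sqrt(sp2))


def compare_groups(
    values_a: np.ndarray, values_b: np.ndarray, feature: str = ""
) -> GroupComparison:
    """Two-sided Student/Welch comparison of one feature between groups."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise StatsError(f"{feature or 'comparison'}: each group needs n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        welch = False
    else:
        welch = sps.levene(a, b).pvalue < LEVENE_ALPHA
    t = sps.ttest_ind(a, b, equal_var=not welch)
    d = cohens_d(a, b)
    p = float(t.pvalue) if np.isfinite(t.pvalue) else 1.0
    return GroupComparison(
        feature=feature,
        test="welch" if welch else "student",
        p_value=p,
        cohens_d=d,
        label=significance_label(p),
        effect_label=effect_size_label(d),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        n_a=int(a.size),
        n_b=int(b.size),
    )


def compare_feature_table(
    features: pd.DataFrame,
    labels: np.ndarray,
    positive_label: object = "caries",
    fdr: bool = False,
) -> pd.DataFrame:
    """Per-feature group comparison table; optional Benjamini-Hochberg column."""
    labels = np.asarray(labels)
    mask = labels == positive_label
    rows = []
    for col in features.columns:
        vals = features[col].to_numpy(dtype=float)
        a, b = vals[mask], vals[~mask]
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        if a.size < 2 or b.size < 2:
            continue
        cmp = compare_groups(a, b, feature=col)
        rows.append(vars(cmp))
    out = pd.DataFrame(rows)
    if fdr and len(out):
        out = out.sort_values("p_value").reset_index(drop=True)
        m = len(out)
        ranks = np.arange(1, m + 1)
        q = out["p_value"].to_numpy() * m / ranks
        out["q_value"] = np.minimum.accumulate(q[::-1])[::-1].clip(max=1.0)
    return out


@dataclass
class BiclusterResult:
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_order: list[int]
    col_order: list[int]
    matrix: pd.DataFrame  # z-normalised, reordered


def _pearson_linkage(X: np.ndarray) -> np.ndarray:
    """Average-linkage tree on 1 - Pearson r distances between rows."""
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X)
    dist = 1.0 - corr
    dist[~np.isfinite(dist)] = 1.0  # zero-variance rows: treat as uncorrelated
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    return hierarchy.average(squareform(dist, checks=False))


def bicluster(features: pd.DataFrame) -> BiclusterResult:
    """Pearson biclustering of a samples x features matrix.

    Columns are z-normalised first; both axes are clustered with 1 - r
    distance and average linkage, as in the published heatmaps.
    """
    X = features.to_numpy(dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise StatsError("bicluster needs at least 2 rows and 2 columns")
    sd = X.std(axis=0, ddof=0)
    if np.all(sd == 0):
        raise StatsError("all-constant matrix cannot be biclustered")
    Z = (X - X.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    row_link = _pearson_linkage(Z)
    col_link = _pearson_linkage(Z.T)
    row_order = hierarchy.leaves_list(row_link).tolist()
    col_order = hierarchy.leaves_list(col_link).tolist()
    reordered = pd.DataFrame(
        Z[np.ix_(row_order, col_order)],
        index=features.index[row_order],
        columns=features.columns[col_order],
    )
    return BiclusterResult(row_link, col_link, row_order, col_order, reordered)


@dataclass
class PartialCorrelationNetwork:
    nodes: list[str]
    partial_r: np.ndarray  # symmetric, unit diagonal
    edges: list[tuple[str, str, float]] = field(default_factory=list)
    shrinkage: bool = False


def partial_correlation(
    features: pd.DataFrame,
    threshold: float = 0.0,
    shrinkage: bool | None = None,
) -> PartialCorrelationNetwork:
    """Gaussian partial-correlation network from the inverse covariance.

    ``shrinkage=None`` auto-enables Ledoit-Wolf shrinkage when the feature
    count reaches the sample count; a singular empirical covariance without
    shrinkage is an error advising it.
    """
    X = features.to_numpy(dtype=float)
    n, p = X.shape
    if n <= 2:
        raise StatsError("partial correlation needs n > 2 samples")
    if shrinkage is None:
        shrinkage = p >= n
    if shrinkage:
        cov = LedoitWolf().fit(X).covariance_
    else:
        cov = np.cov(X, rowvar=False)
    cov = np.atleast_2d(cov)
    try:
        prec = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        raise StatsError(
            "singular covariance; rerun with shrinkage=True"
        ) from None
    d = np.sqrt(np.diag(prec))
    partial = -prec / np.outer(d, d)
    np.fill_diagonal(partial, 1.0)
    partial = np.clip(partial, -1.0, 1.0)
    names = [str(c) for c in features.columns]
    edges = [
        (names[i], names[j], float(partial[i, j]))
        for i in range(p)
        for j in range(i + 1, p)
        if abs(partial[i, j]) > threshold
    ]
    return PartialCorrelationNetwork(names, partial, edges, shrinkage)
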