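"""Cohort analytics: grouping, correlation inference, clustering, PCA.

The cohort pipeline joins per-patient covariates (age, sex, BMI,
comorbidity count, Braden total and sub-scores, admitting service) with
sensor-derived mobility metrics, then:

* splits patients into high/low movers at the median movement rate,
* compares the groups with Welch unpaired t-tests (continuous) and
  Fisher's exact test (categorical),
* gates correlation reporting on Shapiro–Wilk normality,
* computes Spearman correlations with permutation p-values and
  bootstrap percentile confidence intervals, and
* phenotypes patients by K-means on z-scored movement features, with k
  chosen by silhouette score and a 2-D PCA projection for display.

All stochastic routines take explicit seeds and are reproducible.
No multiple-testing correction is applied anywhere in the pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import lgamma
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

logger = logging.getLogger(__name__)


@dataclass
class MedianSplit:
    high: np.ndarray  # indices of high movers
    low: np.ndarray
    threshold: float


@dataclass
class CorrelationResult:
    rho: float
    p_perm: float
    ci95: tuple | None = None


@dataclass
class ClusterResult:
    k: int
    labels: np.ndarray  # 1-based
    silhouette: dict  # candidate k -> mean silhouette score
    pca_coords: np.ndarray
    explained_variance: np.ndarray


def median_split(rates: Sequence[float]) -> MedianSplit:
    """Partition patients at the median movement rate into equal-size groups.

    Rates strictly above the median are high movers, strictly below are
    low movers.  Values tied with the median are assigned one at a time
    to the currently smaller group (low on a size tie), so the group
    sizes always differ by at most one.
    """
    rates = np.asarray(rates, dtype=float)
    if rates.size < 2:
        raise ValueError("median split needs at least 2 patients")
    if np.ptp(rates) == 0:
        raise ValueError("all movement rates identical; median split is undefined")
    thr = float(np.median(rates))
    high = list(np.nonzero(rates > thr)[0])
    low = list(np.nonzero(rates < thr)[0])
    for i in np.nonzero(rates == thr)[0]:
        (high if len(high) < len(low) else low).append(int(i))
    return MedianSplit(np.sort(high), np.sort(low), thr)


def fisher_exact_2xk(table: np.ndarray) -> float:
    """Two-sided Fisher exact test for a 2 x k contingency table.

    Enumerates all tables with the observed margins; the p-value is the
    total probability of tables no more probable than the observed one.
    Reduces to the classic 2 x 2 test when k = 2.  Intended for the small
    tables arising from cohort comparisons (n of a few hundred at most).
    """
    table = np.asarray(table, dtype=int)
    if table.ndim != 2 or table.shape[0] != 2:
        raise ValueError("table must be 2 x k")
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    row0 = int(table[0].sum())
    cols = table.sum(axis=0).astype(int)
    n = int(table.sum())
    if n == 0:
        raise ValueError("empty table")

    logC = lambda a, b: lgamma(a + 1) - lgamma(b + 1) - lgamma(a - b + 1)
    denom = logC(n, row0)

    def log_prob(first_row) -> float:
        return sum(logC(c, x) for c, x in zip(cols, first_row)) - denom

    p_obs = log_prob(table[0])
    total = 0.0
    k = len(cols)

    def rec(j: int, remaining: int, acc: float):
        nonlocal total
        if j == k - 1:
            if 0 <= remaining <= cols[j]:
                lp = acc + logC(cols[j], remaining) - denom
                if lp <= p_obs + 1e-9:
                    total += np.exp(lp)
            return
        tail_cap = int(cols[j + 1:].sum())
        lo = max(0, remaining - tail_cap)
        hi = min(cols[j], remaining)
        for x in range(lo, hi + 1):
            rec(j + 1, remaining - x, acc + logC(cols[j], x))

    rec(0, row0, 0.0)
    return float(min(total, 1.0))


def compare_groups(
    table: pd.DataFrame,
    groups: Sequence,
    continuous: Sequence[str] | None = None,
    categorical: Sequence[str] | None = None,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-variable two-group comparison.

    Continuous variables get an unpaired t-test (Welch by default; pass
    ``equal_var=True`` for the pooled-variance form); categorical
    variables get a two-sided Fisher exact test on the group-by-level
    contingency table.  Degenerate variables (constant, or single-level
    categories) are skipped with a note in the output.
    """
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError("exactly two groups required")
    g1, g2 = (groups == levels[0]), (groups == levels[1])
    if continuous is None:
        continuous = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    if categorical is None:
        categorical = [
            c for c in table.columns
            if not pd.api.types.is_numeric_dtype(table[c]) and c != "patient_id"
        ]
    rows = []
    for var in continuous:
        a = table.loc[g1, var].dropna().to_numpy(dtype=float)
        b = table.loc[g2, var].dropna().to_numpy(dtype=float)
        if a.size < 2 or b.size < 2:
            rows.append((var, "t", np.nan, np.nan, np.nan, np.nan, "skipped: group too small"))
            continue
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            rows.append((var, "t", a.mean(), b.mean(), np.nan, np.nan, "skipped: constant variable"))
            continue
        res = stats.ttest_ind(a, b, equal_var=equal_var)
        rows.append((var, "welch_t" if not equal_var else "pooled_t",
                     a.mean(), b.mean(), float(res.statistic), float(res.pvalue), ""))
    for var in categorical:
        ct = pd.crosstab(groups, table[var])
        if ct.shape[1] < 2:
            rows.append((var, "fisher", np.nan, np.nan, np.nan, np.nan, "skipped: single level"))
            continue
        p = fisher_exact_2xk(ct.to_numpy())
        rows.append((var, "fisher", np.nan, np.nan, np.nan, p, ""))
    return pd.DataFrame(
        rows, columns=["variable", "test", "mean_1", "mean_2", "statistic", "p", "note"]
    )


def test_normality(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro–Wilk normality test (W, p); gates Spearman vs Pearson choice."""
    values = np.asarray(values, dtype=float)
    if not 3 <= values.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(values) == 0:
        raise ValueError("constant input: normality test undefined")
    res = stats.shapiro(values)
    return float(res.statistic), float(res.pvalue)


def _rank_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc @ rxc) * (ryc @ ryc))
    return float((rxc @ ryc) / denom)


def spearman_perm(
    x: Sequence[float],
    y: Sequence[float],
    n_perm: int = 10000,
    seed: int | None = None,
    conservative: bool = False,
) -> CorrelationResult:
    """Spearman rho with a permutation p-value.

    Ranks use average ranks for ties.  The null distribution is built by
    permuting one variable ``n_perm`` times; the two-tailed p-value is
    the plain proportion of permuted |rho*| at least as extreme as the
    observed |rho| (``conservative=True`` adds the +1/+1 correction).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 4:
        raise ValueError("x and y must have equal length >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: Spearman rho undefined")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = _rank_rho(rx, ry)
    rng = np.random.default_rng(seed)
    perm = rng.permuted(np.tile(ry, (n_perm, 1)), axis=1)
    rxc = rx - rx.mean()
    pc = perm - perm.mean(axis=1, keepdims=True)
    denom = np.sqrt((rxc @ rxc) * np.sum(pc * pc, axis=1))
    rho_null = (pc @ rxc) / denom
    extreme = int(np.sum(np.abs(rho_null) >= abs(rho) - 1e-12))
    p = (extreme + 1) / (n_perm + 1) if conservative else extreme / n_perm
    return CorrelationResult(rho, float(p))


def bootstrap_ci(
    x: Sequence[float],
    y: Sequence[float],
    n_boot: int = 1000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap 95% CI for Spearman rho.

    Resamples (x_i, y_i) pairs with replacement; resamples in which
    either variable collapses to a constant are skipped (logged).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 4:
        raise ValueError("x and y must have equal length >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: Spearman rho undefined")
    rng = np.random.default_rng(seed)
    n = x.size
    idx = rng.integers(0, n, size=(n_boot, n))
    xb, yb = x[idx], y[idx]
    ok = (np.ptp(xb, axis=1) > 0) & (np.ptp(yb, axis=1) > 0)
    n_skipped = int((~ok).sum())
    if n_skipped:
        logger.warning("bootstrap_ci: skipped %d zero-variance resample(s)", n_skipped)
    rx = stats.rankdata(xb[ok], axis=1)
    ry = stats.rankdata(yb[ok], axis=1)
    rxc = rx - rx.mean(axis=1, keepdims=True)
    ryc = ry - ry.mean(axis=1, keepdims=True)
    denom = np.sqrt(np.sum(rxc * rxc, axis=1) * np.sum(ryc * ryc, axis=1))
    rhos = np.sum(rxc * ryc, axis=1) / denom
    lo, hi = np.percentile(rhos, [2.5, 97.5])
    return float(lo), float(hi)


def standardize(features: pd.DataFrame) -> pd.DataFrame:
    """Z-score each feature column; constant columns dropped with a warning."""
    out = {}
    for col in features.columns:
        v = features[col].to_numpy(dtype=float)
        sd = v.std()
        if sd == 0:
            logger.warning("standardize: dropping constant feature %r", col)
            continue
        out[col] = (v - v.mean()) / sd
    if not out:
        raise ValueError("no non-constant features to standardize")
    return pd.DataFrame(out, index=features.index)


def select_k_silhouette(
    features, k_candidates: Sequence[int] = range(2, 9), seed: int | None = 0
) -> tuple[int, dict]:
    """Pick the cluster count with maximal mean silhouette score.

    K-means is fit per candidate k with 10 restarts under a fixed seed;
    ties go to the smallest k.  Returns (k, {k: score}).
    """
    X = np.asarray(features, dtype=float)
    k_candidates = list(k_candidates)
    if X.shape[0] <= max(k_candidates):
        raise ValueError("need more rows than the largest candidate k")
    scores = {}
    for k in k_candidates:
        labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(X)
        scores[k] = float(silhouette_score(X, labels))
    best = max(sorted(scores), key=lambda k: scores[k])
    return best, scores


def kmeans_cluster(features, k: int, seed: int | None = 0) -> np.ndarray:
    """K-means labels (1-based), deterministic under a fixed seed."""
    X = np.asarray(features, dtype=float)
    if k > X.shape[0]:
        raise ValueError("k cannot exceed the number of rows")
    labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(X)
    return labels + 1


def pca_project(features, n_components: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Centered PCA projection and per-component explained-variance fractions.

    Rank-deficient inputs are handled: components beyond the data rank
    report an explained fraction of 0.
    """
    X = np.asarray(features, dtype=float)
    if X.shape[1] < 2 or X.shape[0] < 3:
        raise ValueError("PCA needs >= 2 features and >= 3 rows")
    n_fit = min(n_components, min(X.shape), np.linalg.matrix_rank(X - X.mean(axis=0)))
    n_fit = max(n_fit, 1)
    pca = PCA(n_components=n_fit)
    coords = pca.fit_transform(X)
    if n_fit < n_components:
        coords = np.hstack([coords, np.zeros((X.shape[0], n_components - n_fit))])
        evr = np.concatenate([pca.explained_variance_ratio_, np.zeros(n_components - n_fit)])
    else:
        evr = pca.explained_variance_ratio_
    return coords, evr


def cluster_pipeline(
    features: pd.DataFrame, k_candidates: Sequence[int] = range(2, 9), seed: int | None = 0
) -> ClusterResult:
    """Standardize, pick k by silhouette, cluster, and project to 2-D."""
    Z = standardize(features)
    k, scores = select_k_silhouette(Z, k_candidates, seed=seed)
    labels = kmeans_cluster(Z, k, seed=seed)
    coords, evr = pca_project(Z.to_numpy(), n_components=2)
    return ClusterResult(k, labels, scores, coords, evr)
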