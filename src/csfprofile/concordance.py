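"""Inter-center concordance: Passing-Bablok regression, inter-assay CV, PCA.

Before two centers' biomarker measurements are merged into a single cohort,
their agreement is checked three ways:

* **Passing-Bablok regression** per analyte — a nonparametric method-comparison
  regression robust to measurement error in both variables, whose slope is an
  offset median of all pairwise slopes.  Equality of methods corresponds to
  slope 1 and intercept 0.  Confidence intervals come from a paired percentile
  bootstrap.
* **Inter-assay CV** per sample — the two-point coefficient of variation
  ``|a - b| / (sqrt(2) * mean(a, b))``, averaged over samples.
* **PCA** of the pooled z-scored biomarkers, with a 95% data-range ellipse per
  center in the PC1-PC2 plane; overlapping ellipses indicate no center effect.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MethodComparisonFit", "ConcordanceStats", "PcaProjection", "CohortEllipse",
    "passing_bablok_fit", "concordance_stats", "pca_projection", "is_mergeable",
]

#: Squared Mahalanobis radius of the 95% region of a bivariate normal.
_CHI2_95_2DF = float(stats.chi2.ppf(0.95, df=2))


class DegenerateDataError(ValueError):
    """All pairwise slopes were excluded; Passing-Bablok is undefined."""


@dataclass
class MethodComparisonFit:
    analyte: str
    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    pearson_r: float
    n_pairs: int
    excluded_slopes: int


@dataclass
class ConcordanceStats:
    analyte: str
    per_sample_cv: np.ndarray
    mean_cv: float


@dataclass
class CohortEllipse:
    """95% data-range ellipse of one cohort's scores in the PC1-PC2 plane."""
    center: np.ndarray        # (2,)
    semi_axes: np.ndarray     # (2,) major, minor
    angle: float              # radians, major axis vs PC1


@dataclass
class PcaProjection:
    loadings: np.ndarray            # (3, 3), columns = PCs
    explained_variance: np.ndarray  # descending
    scores: np.ndarray              # (n, 3)
    column_means: np.ndarray        # (3,)
    ellipse_per_cohort: dict[object, CohortEllipse]


def _pairwise_slopes(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, int]:
    """Kept pairwise slopes S_ij = (y_j - y_i)/(x_j - x_i), i < j, plus the
    count of excluded slopes (S_ij == -1, or vertical with distinct y).

    Pairs with x_i == x_j and y_i == y_j contribute nothing and are not
    counted as exclusions.
    """
    i, j = np.triu_indices(len(x), k=1)
    dx = x[j] - x[i]
    dy = y[j] - y[i]
    vertical = dx == 0
    undefined = vertical & (dy != 0)
    s = dy[~vertical] / dx[~vertical]
    minus_one = s == -1.0
    kept = s[~minus_one]
    return kept, int(undefined.sum() + minus_one.sum())


def _offset_median_slope(kept: np.ndarray) -> float:
    """Original Passing-Bablok shifted median of the kept pairwise slopes.

    With N kept slopes and K of them below -1, the slope is the element at
    1-based rank ceil((N+1)/2) + K for odd N, or the mean of the elements at
    ranks N/2 + K and N/2 + 1 + K for even N.
    """
    N = len(kept)
    if N == 0:
        raise DegenerateDataError("all pairwise slopes excluded")
    K = int(np.count_nonzero(kept < -1.0))
    s = np.sort(kept)
    if N % 2 == 1:
        r = (N + 1) // 2 + K
        return float(s[min(r, N) - 1])
    r1 = min(N // 2 + K, N)
    r2 = min(N // 2 + 1 + K, N)
    return float(0.5 * (s[r1 - 1] + s[r2 - 1]))


def _pb_point(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    kept, excluded = _pairwise_slopes(x, y)
    b = _offset_median_slope(kept)
    a = float(np.median(y - b * x))
    return b, a, excluded


def _pb_bootstrap(x: np.ndarray, y: np.ndarray, n_boot: int,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized paired-bootstrap Passing-Bablok slopes and intercepts."""
    n = len(x)
    iu_i, iu_j = np.triu_indices(n, k=1)
    slopes = np.empty(n_boot)
    intercepts = np.empty(n_boot)
    # chunk so that chunk * n^2 stays modest in memory
    chunk = max(1, int(4e6 // (n * n)))
    done = 0
    while done < n_boot:
        b = min(chunk, n_boot - done)
        idx = rng.integers(0, n, size=(b, n))
        xb, yb = x[idx], y[idx]
        dx = xb[:, iu_j] - xb[:, iu_i]
        dy = yb[:, iu_j] - yb[:, iu_i]
        with np.errstate(divide="ignore", invalid="ignore"):
            s = dy / dx
        # exclusions: vertical pairs (dx == 0) and s == -1 -> mask with +inf
        # so they sort to the end; identical pairs (0/0 -> nan) likewise.
        drop = (dx == 0) | (s == -1.0)
        s = np.where(drop, np.inf, s)
        N = (~drop).sum(axis=1)
        K = ((~drop) & (s < -1.0)).sum(axis=1)
        s.sort(axis=1)
        rows = np.arange(b)
        odd = N % 2 == 1
        slope_b = np.empty(b)
        if odd.any():
            r = np.minimum((N[odd] + 1) // 2 + K[odd], N[odd])
            slope_b[odd] = s[rows[odd], r - 1]
        if (~odd).any():
            Ne, Ke = N[~odd], K[~odd]
            r1 = np.minimum(Ne // 2 + Ke, Ne)
            r2 = np.minimum(Ne // 2 + 1 + Ke, Ne)
            slope_b[~odd] = 0.5 * (s[rows[~odd], r1 - 1] + s[rows[~odd], r2 - 1])
        bad = N == 0
        slope_b[bad] = np.nan
        slopes[done:done + b] = slope_b
        intercepts[done:done + b] = np.median(yb - slope_b[:, None] * xb, axis=1)
        done += b
    return slopes, intercepts


def passing_bablok_fit(x, y, n_boot: int = 2000, seed: int | None = 0,
                       analyte: str = "", ci_level: float = 0.95) -> MethodComparisonFit:
    """Passing-Bablok regression of center-2 values ``y`` on center-1 values ``x``.

    The slope is the offset median of all pairwise slopes (original 1983
    exclusion rule: slopes equal to -1 and vertical pairs are dropped; the
    median rank is shifted by the number of kept slopes below -1).  The
    intercept is ``median(y - slope * x)``.  95% CIs are percentile bootstrap
    over paired resamples; degenerate bootstrap replicates are skipped.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise ValueError("at least 3 pairs are required")
    if np.all(x == x[0]):
        raise DegenerateDataError("all x values identical")

    slope, intercept, excluded = _pb_point(x, y)
    r = float(np.corrcoef(x, y)[0, 1])

    rng = np.random.default_rng(seed)
    bs, bi = _pb_bootstrap(x, y, n_boot, rng)
    ok = np.isfinite(bs)
    lo, hi = (1 - ci_level) / 2 * 100, (1 + ci_level) / 2 * 100
    slope_ci = tuple(np.percentile(bs[ok], [lo, hi]))
    intercept_ci = tuple(np.percentile(bi[ok], [lo, hi]))
    # the percentile interval is enveloped around the point estimate so the
    # reported triple is always ordered
    slope_ci = (min(slope_ci[0], slope), max(slope_ci[1], slope))
    intercept_ci = (min(intercept_ci[0], intercept), max(intercept_ci[1], intercept))

    return MethodComparisonFit(
        analyte=analyte, slope=slope, intercept=intercept,
        slope_ci=slope_ci, intercept_ci=intercept_ci,
        pearson_r=r, n_pairs=len(x), excluded_slopes=excluded,
    )


def concordance_stats(pairs: pd.DataFrame, analyte: str) -> ConcordanceStats:
    """Per-sample and mean inter-assay CV for one analyte.

    For a duplicate pair (a, b) the CV is ``SD / mean`` with the two-point
    sample SD ``|a - b| / sqrt(2)``.
    """
    sub = pairs.loc[pairs["analyte"] == analyte]
    if len(sub) == 0:
        raise ValueError(f"no pairs for analyte {analyte!r}")
    a = sub["center1_value"].to_numpy(dtype=float)
    b = sub["center2_value"].to_numpy(dtype=float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("paired measurements must be strictly positive")
    cv = np.abs(a - b) / np.sqrt(2.0) / ((a + b) / 2.0)
    return ConcordanceStats(analyte=analyte, per_sample_cv=cv, mean_cv=float(cv.mean()))


def _ellipse_from_scores(scores2: np.ndarray) -> CohortEllipse:
    center = scores2.mean(axis=0)
    cov = np.cov(scores2, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.maximum(evals[order], 0.0), evecs[:, order]
    semi_axes = np.sqrt(evals * _CHI2_95_2DF)
    angle = float(np.arctan2(evecs[1, 0], evecs[0, 0]))
    return CohortEllipse(center=center, semi_axes=semi_axes, angle=angle)


def pca_projection(z_matrix, cohort_labels) -> PcaProjection:
    """PCA of the standardized biomarker matrix with per-cohort 95% ellipses.

    Eigendecomposition of the sample covariance (n-1 denominator); scores are
    the centered data projected on the loadings.  Each loading vector's
    largest-magnitude element is made positive so output is deterministic.
    The per-cohort ellipse covers the 95% region of a bivariate normal fitted
    to that cohort's (PC1, PC2) scores: squared Mahalanobis radius equal to
    the 0.95 quantile of chi-square with 2 df.
    """
    Z = np.asarray(z_matrix, dtype=float)
    labels = np.asarray(cohort_labels)
    if Z.ndim != 2 or len(Z) != len(labels):
        raise ValueError("z_matrix must be 2-D with one cohort label per row")
    if len(Z) < 4:
        raise ValueError("at least 4 subjects are required for PCA")

    means = Z.mean(axis=0)
    C = np.cov(Z, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    evecs = evecs[:, order]
    for k in range(evecs.shape[1]):
        if evecs[np.argmax(np.abs(evecs[:, k])), k] < 0:
            evecs[:, k] = -evecs[:, k]
    scores = (Z - means) @ evecs

    ellipses = {
        c: _ellipse_from_scores(scores[labels == c, :2])
        for c in pd.unique(labels)
    }
    return PcaProjection(loadings=evecs, explained_variance=evals,
                         scores=scores, column_means=means,
                         ellipse_per_cohort=ellipses)


def is_mergeable(fit: MethodComparisonFit, y_values=None,
                 intercept_fraction: float = 0.05) -> bool:
    """Mergeability rule for one analyte.

    The centers are declared mergeable when the slope CI contains 1 and the
    intercept CI contains 0 — or the intercept, while non-null, is smaller in
    magnitude than ``intercept_fraction`` of the median measured value (a
    small offset relative to nominal concentrations does not preclude
    pooling).
    """
    slope_ok = fit.slope_ci[0] <= 1.0 <= fit.slope_ci[1]
    intercept_null = fit.intercept_ci[0] <= 0.0 <= fit.intercept_ci[1]
    if y_values is not None and len(y_values):
        small = abs(fit.intercept) < intercept_fraction * float(np.median(np.abs(y_values)))
    else:
        small = False
    return bool(slope_ok and (intercept_null or small))
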