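"""Gaussian-mixture clustering of z-scored biomarkers and cluster annotation.

The central model is a full-covariance Gaussian mixture over the three
z-scored biomarkers (Abeta42/Abeta40 ratio, p-tau, t-tau), fitted by
expectation-maximization.  A mixture of anisotropic Gaussians is the natural
choice here: the biomarker clouds are elongated and correlated (p-tau and
t-tau track each other), which defeats isotropic methods like K-means.

The number of components K is chosen by minimizing the Bayesian information
criterion, BIC = -2 logL + p ln n, with p = (K-1) + 3K + 6K free parameters
for d = 3 (weights + means + free covariance entries).

Downstream of the fit, clusters are summarized (median and 95% data range per
biomarker, in natural units), cross-tabulated against clinical diagnoses as a
prevalence matrix, ordered hierarchically for display, and labeled
*control* / *AD-like* / *intermediate* from the distribution of clinically
defined OND and AD subjects over clusters.  A counting argument then gives
the misdiagnosis tolerance: how many OND subjects would need to be AD
misdiagnoses before the data-driven labeling itself changed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.cluster.hierarchy import linkage, leaves_list
from scipy.special import logsumexp

from .io import FEATURES

__all__ = [
    "MixtureFit", "fit_gmm_em", "bic_score", "n_free_parameters",
    "select_num_clusters", "cluster_profiles", "prevalence_matrix",
    "hierarchical_order", "label_clusters", "misdiagnosis_tolerance",
    "fisher_exact_2x2", "LabelingConflictError", "MisdiagnosisTolerance",
]

_LOG_2PI = np.log(2.0 * np.pi)


class LabelingConflictError(ValueError):
    """The control cluster also qualifies as AD-like; the data are pathological."""


@dataclass
class MixtureFit:
    """A fitted Gaussian mixture on z-scored data."""
    K: int
    weights: np.ndarray          # (K,)
    means: np.ndarray            # (K, d)
    covariances: np.ndarray      # (K, d, d)
    log_likelihood: float
    n_params: int
    bic: float
    responsibilities: np.ndarray  # (n, K), rows sum to 1
    hard_labels: np.ndarray       # (n,) in 1..K
    n_iter: int
    converged: bool
    log_likelihood_path: np.ndarray = field(default=None, repr=False)


def n_free_parameters(K: int, d: int = 3) -> int:
    """Free parameters of a K-component full-covariance d-variate mixture."""
    return (K - 1) + K * d + K * (d * (d + 1) // 2)


def bic_score(fit: MixtureFit, n: int) -> float:
    """Bayesian information criterion, -2 logL + p ln n (lower is better)."""
    return -2.0 * fit.log_likelihood + fit.n_params * np.log(n)


def _log_gaussian(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Log density of a multivariate normal at the rows of X, via Cholesky."""
    d = X.shape[1]
    L = linalg.cholesky(cov, lower=True)
    dev = linalg.solve_triangular(L, (X - mean).T, lower=True)
    maha = np.einsum("ij,ij->j", dev, dev)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return -0.5 * (d * _LOG_2PI + logdet + maha)


def _e_step(X, weights, means, covs):
    K = len(weights)
    log_prob = np.empty((X.shape[0], K))
    for k in range(K):
        log_prob[:, k] = np.log(weights[k]) + _log_gaussian(X, means[k], covs[k])
    log_norm = logsumexp(log_prob, axis=1)
    resp = np.exp(log_prob - log_norm[:, None])
    return resp, float(log_norm.sum())


def _m_step(X, resp, reg):
    n, d = X.shape
    Nk = resp.sum(axis=0) + 10 * np.finfo(float).tiny
    weights = Nk / n
    means = (resp.T @ X) / Nk[:, None]
    covs = np.empty((len(Nk), d, d))
    eye = np.eye(d)
    for k in range(len(Nk)):
        dev = X - means[k]
        covs[k] = (resp[:, k] * dev.T) @ dev / Nk[k] + reg * eye
    return weights, means, covs


def _kmeanspp_centers(X: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++-style seeding: centers drawn with probability ∝ squared
    distance to the nearest already-chosen center."""
    n = X.shape[0]
    centers = np.empty((K, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = np.sum((X - centers[0]) ** 2, axis=1)
    for k in range(1, K):
        total = d2.sum()
        if total <= 0:
            centers[k] = X[rng.integers(n)]
        else:
            centers[k] = X[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, np.sum((X - centers[k]) ** 2, axis=1))
    return centers


_N_LLOYD_ITER = 100
_N_KMEANS_RESTARTS = 1  # one k-means per EM init: basin diversity across inits


def _lloyd(X, centers):
    """Lloyd iterations to (near) convergence; returns (assign, centers, inertia)."""
    assign = np.argmin(((X[:, None, :] - centers[None]) ** 2).sum(axis=2), axis=1)
    for _ in range(_N_LLOYD_ITER):
        for k in range(len(centers)):
            members = X[assign == k]
            if len(members):
                centers[k] = members.mean(axis=0)
        new_assign = np.argmin(((X[:, None, :] - centers[None]) ** 2).sum(axis=2), axis=1)
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
    inertia = float(((X - centers[assign]) ** 2).sum())
    return assign, centers, inertia


def _initial_parameters(X, K, rng, reg):
    """Moment initialization from the best of a few k-means++/Lloyd runs."""
    n, d = X.shape
    best = None
    for _ in range(_N_KMEANS_RESTARTS):
        assign, centers, inertia = _lloyd(X, _kmeanspp_centers(X, K, rng))
        if best is None or inertia < best[2]:
            best = (assign, centers, inertia)
    assign, centers, _ = best
    global_cov = np.cov(X, rowvar=False, ddof=0).reshape(d, d) + reg * np.eye(d)
    weights = np.empty(K)
    means = np.empty((K, d))
    covs = np.empty((K, d, d))
    for k in range(K):
        idx = np.flatnonzero(assign == k)
        weights[k] = max(len(idx), 1)
        means[k] = X[idx].mean(axis=0) if len(idx) else centers[k]
        if len(idx) >= d + 1:
            covs[k] = np.cov(X[idx], rowvar=False, ddof=0) + reg * np.eye(d)
        else:
            covs[k] = global_cov
    weights /= weights.sum()
    return weights, means, covs


_N_SHORT_CANDIDATES = 5
_N_SHORT_ITER = 20


def _short_run_select(X, K, rng, reg):
    """emEM-style start: burn in several candidate initializations for a few
    EM iterations and keep the most promising one.  Short-run likelihood
    predicts the final basin far better than the k-means inertia does."""
    best = None
    for _ in range(_N_SHORT_CANDIDATES):
        weights, means, covs = _initial_parameters(X, K, rng, reg)
        for _ in range(_N_SHORT_ITER):
            resp, _ = _e_step(X, weights, means, covs)
            weights, means, covs = _m_step(X, resp, reg)
        _, ll = _e_step(X, weights, means, covs)
        if best is None or ll > best[0]:
            best = (ll, weights, means, covs)
    return best[1], best[2], best[3]


def _em_single(X, K, rng, tol, reg, max_iter, init=None):
    if init is None:
        weights, means, covs = _short_run_select(X, K, rng, reg)
    else:
        weights, means, covs = (np.array(a, dtype=float) for a in init)
    prev_ll = -np.inf
    path = []
    resp = None
    for it in range(max_iter):
        resp, ll = _e_step(X, weights, means, covs)
        if not np.isfinite(ll):
            raise RuntimeError(f"non-finite log-likelihood at EM iteration {it}")
        path.append(ll)
        if prev_ll > -np.inf and abs(ll - prev_ll) <= tol * abs(prev_ll):
            return weights, means, covs, resp, ll, it + 1, True, np.array(path)
        prev_ll = ll
        weights, means, covs = _m_step(X, resp, reg)
    resp, ll = _e_step(X, weights, means, covs)
    path.append(ll)
    return weights, means, covs, resp, ll, max_iter, False, np.array(path)


def fit_gmm_em(z_matrix, K: int, seed: int = 0, n_init: int = 10,
               tol: float = 1e-6, reg: float = 1e-6,
               max_iter: int = 500, init=None) -> MixtureFit:
    """Fit a K-component full-covariance Gaussian mixture by EM.

    Runs ``n_init`` EM chains and keeps the one with the highest final
    log-likelihood.  Each chain starts from an emEM-style selection over
    k-means++-seeded candidates (deterministically derived from ``seed``).
    Convergence is declared when the relative log-likelihood change falls
    below ``tol``; ``reg`` is added to covariance diagonals at every M-step
    to keep them well conditioned.

    ``init`` (optional ``(weights, means, covariances)``) bypasses the
    initialization entirely and runs a single chain from those parameters —
    useful for cross-checking against other EM implementations.
    """
    X = np.asarray(z_matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("z_matrix must be 2-D (subjects x features)")
    n = X.shape[0]
    if K < 1:
        raise ValueError("K must be >= 1")
    if K >= n:
        raise ValueError(f"K = {K} must be smaller than the number of subjects n = {n}")

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(1 if init is not None else max(1, n_init)):
        chain_rng = np.random.default_rng(rng.integers(2 ** 31))
        result = _em_single(X, K, chain_rng, tol, reg, max_iter, init=init)
        if best is None or result[4] > best[4]:
            best = result
    weights, means, covs, resp, ll, n_iter, converged, path = best

    fit = MixtureFit(
        K=K, weights=weights, means=means, covariances=covs,
        log_likelihood=ll, n_params=n_free_parameters(K, X.shape[1]),
        bic=np.nan, responsibilities=resp,
        hard_labels=np.argmax(resp, axis=1) + 1,
        n_iter=n_iter, converged=converged, log_likelihood_path=path,
    )
    fit.bic = bic_score(fit, n)
    return fit


def select_num_clusters(z_matrix, k_range=range(1, 11), seed: int = 0,
                        n_init: int = 10, tol: float = 1e-6, reg: float = 1e-6,
                        max_iter: int = 500) -> tuple[int, pd.DataFrame]:
    """Choose K by minimizing BIC over ``k_range``.

    Returns ``(k_star, curve)`` where the curve records BIC and log-likelihood
    per K (and the error message for any K whose fit failed).  BIC ties within
    1e-9 break toward smaller K (parsimony).
    """
    ks = list(k_range)
    if not ks:
        raise ValueError("k_range must be non-empty")
    rows = []
    fits: dict[int, MixtureFit] = {}
    rng = np.random.default_rng(seed)
    for K in ks:
        sub_seed = int(rng.integers(2 ** 31))
        try:
            fit = fit_gmm_em(z_matrix, K, seed=sub_seed, n_init=n_init,
                             tol=tol, reg=reg, max_iter=max_iter)
            fits[K] = fit
            rows.append({"K": K, "bic": fit.bic,
                         "log_likelihood": fit.log_likelihood,
                         "converged": fit.converged, "error": ""})
        except (ValueError, RuntimeError) as exc:
            rows.append({"K": K, "bic": np.nan, "log_likelihood": np.nan,
                         "converged": False, "error": str(exc)})
    curve = pd.DataFrame(rows)
    if not fits:
        raise RuntimeError("every candidate K failed to fit")
    k_star, best_bic = None, np.inf
    for K in sorted(fits):
        if fits[K].bic < best_bic - 1e-9:
            k_star, best_bic = K, fits[K].bic
    return k_star, curve


def cluster_profiles(table: pd.DataFrame, labels,
                     biomarkers=FEATURES) -> pd.DataFrame:
    """Per-cluster median and 95% data range in natural units.

    The 95% data range is the (2.5th, 97.5th) percentile pair, computed with
    the linear-interpolation convention between order statistics.  Returns a
    long table: cluster, biomarker, n, median, lo, hi.
    """
    labels = np.asarray(labels)
    if len(labels) != len(table):
        raise ValueError("one cluster label per table row is required")
    rows = []
    for c in sorted(pd.unique(labels)):
        idx = labels == c
        if not idx.any():
            raise ValueError(f"empty cluster: {c}")
        for bm in biomarkers:
            vals = table.loc[idx, bm].to_numpy(dtype=float)
            lo, med, hi = np.percentile(vals, [2.5, 50.0, 97.5])
            rows.append({"cluster": c, "biomarker": bm, "n": int(idx.sum()),
                         "median": med, "lo": lo, "hi": hi})
    return pd.DataFrame(rows)


def prevalence_matrix(diagnoses, labels, min_n: int = 5) -> pd.DataFrame:
    """Percentage of each diagnosis's subjects falling in each cluster.

    Diagnoses with fewer than ``min_n`` subjects are excluded.  Each emitted
    row sums to 100.
    """
    diagnoses = np.asarray(diagnoses)
    labels = np.asarray(labels)
    if len(diagnoses) != len(labels):
        raise ValueError("diagnoses and labels must align")
    clusters = sorted(pd.unique(labels))
    out = {}
    for d in sorted(pd.unique(diagnoses)):
        idx = diagnoses == d
        if idx.sum() < min_n:
            continue
        counts = np.array([np.sum(labels[idx] == c) for c in clusters], dtype=float)
        out[d] = 100.0 * counts / counts.sum()
    return pd.DataFrame(out, index=clusters).T


def hierarchical_order(matrix) -> tuple[np.ndarray, np.ndarray]:
    """Dendrogram leaf order and merge heights for the rows of ``matrix``.

    Agglomerative clustering with Euclidean distance and average (UPGMA)
    linkage, as used to order heatmap rows and columns.  Apply to the
    transposed matrix for column ordering.
    """
    M = np.asarray(matrix, dtype=float)
    if M.ndim == 1:
        M = M[:, None]
    if M.shape[0] < 2:
        raise ValueError("at least 2 items are required")
    Z = linkage(M, method="average", metric="euclidean")
    return leaves_list(Z), Z[:, 2]


def _label_from_counts(ad_counts: np.ndarray, ond_counts: np.ndarray,
                       ratio_medians: np.ndarray | None,
                       ad_share_threshold: float) -> tuple[int, frozenset]:
    """Control index and AD-like index set from per-cluster AD/OND counts."""
    ond_total = ond_counts.sum()
    ad_total = ad_counts.sum()
    if ond_total <= 0 or ad_total <= 0:
        raise ValueError("both AD and OND subjects are required for labeling")
    top = np.flatnonzero(ond_counts == ond_counts.max())
    if len(top) > 1:
        if ratio_medians is None:
            raise ValueError("OND-share tie: per-cluster median ratios are "
                             "required to break it")
        control = int(top[np.argmax(ratio_medians[top])])
    else:
        control = int(top[0])
    ad_like = frozenset(
        int(c) for c in range(len(ad_counts))
        if ad_counts[c] / ad_total >= ad_share_threshold
        and ad_counts[c] > ond_counts[c]
    )
    if control in ad_like:
        raise LabelingConflictError(
            "the control cluster (largest OND share) also qualifies as AD-like")
    return control, ad_like


def label_clusters(diagnoses, labels, ad_share_threshold: float = 0.10,
                   ratio=None) -> dict:
    """Label clusters control / AD-like / intermediate from AD and OND prevalence.

    *Control* is the single cluster holding the largest share of all OND
    subjects (ties break toward the higher median ratio, which requires the
    per-subject ``ratio`` values).  *AD-like* clusters hold at least
    ``ad_share_threshold`` of all AD subjects and contain more AD than OND
    subjects.  Everything else is *intermediate*.
    """
    diagnoses = np.asarray(diagnoses)
    labels = np.asarray(labels)
    clusters = sorted(pd.unique(labels))
    ad_counts = np.array([np.sum((labels == c) & (diagnoses == "AD")) for c in clusters])
    ond_counts = np.array([np.sum((labels == c) & (diagnoses == "OND")) for c in clusters])
    ratio_medians = None
    if ratio is not None:
        ratio = np.asarray(ratio, dtype=float)
        ratio_medians = np.array([np.median(ratio[labels == c]) for c in clusters])
    control, ad_like = _label_from_counts(ad_counts, ond_counts, ratio_medians,
                                          ad_share_threshold)
    out = {}
    for i, c in enumerate(clusters):
        if i == control:
            out[c] = "control"
        elif i in ad_like:
            out[c] = "AD-like"
        else:
            out[c] = "intermediate"
    return out


@dataclass
class MisdiagnosisTolerance:
    m: int
    fraction: float
    n_ond: int
    source_cluster: object


def misdiagnosis_tolerance(diagnoses, labels, ad_share_threshold: float = 0.10,
                           ratio=None) -> MisdiagnosisTolerance:
    """Smallest number m of OND→AD relabelings that changes the cluster labeling.

    The labeling depends on OND and AD counts per cluster only, so the search
    reduces to counting: for each cluster holding OND subjects, relabel its
    OND members one at a time (which simultaneously lowers that cluster's OND
    count and raises its AD count and the AD total) and recompute the labeling
    until the control designation or the AD-like set changes.  Concentrating
    the relabelings in a single cluster is weakly optimal — splitting them
    dilutes the per-cluster effect on both the OND-share argmax and the
    AD-share threshold — so the minimum over single-cluster strategies is the
    global minimum.
    """
    diagnoses = np.asarray(diagnoses)
    labels = np.asarray(labels)
    clusters = sorted(pd.unique(labels))
    ad_counts = np.array([np.sum((labels == c) & (diagnoses == "AD")) for c in clusters])
    ond_counts = np.array([np.sum((labels == c) & (diagnoses == "OND")) for c in clusters])
    ratio_medians = None
    if ratio is not None:
        ratio = np.asarray(ratio, dtype=float)
        ratio_medians = np.array([np.median(ratio[labels == c]) for c in clusters])
    if np.count_nonzero(ond_counts > 0) < 2:
        raise ValueError("misdiagnosis tolerance is undefined with OND subjects "
                         "in fewer than 2 clusters")
    baseline = _label_from_counts(ad_counts, ond_counts, ratio_medians,
                                  ad_share_threshold)
    n_ond = int(ond_counts.sum())

    best_m, best_src = None, None
    for s in range(len(clusters)):
        for m in range(1, int(ond_counts[s]) + 1):
            ad = ad_counts.copy()
            ond = ond_counts.copy()
            ad[s] += m
            ond[s] -= m
            try:
                changed = _label_from_counts(ad, ond, ratio_medians,
                                             ad_share_threshold) != baseline
            except (ValueError, LabelingConflictError):
                changed = True
            if changed:
                if best_m is None or m < best_m:
                    best_m, best_src = m, clusters[s]
                break
    if best_m is None:
        best_m, best_src = n_ond, None
    return MisdiagnosisTolerance(m=int(best_m), fraction=best_m / n_ond,
                                 n_ond=n_ond, source_cluster=best_src)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the 2x2 table [[a, b], [c, d]].

    The two-sided p sums hypergeometric probabilities of all tables with the
    same margins whose probability does not exceed the observed table's.
    """
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("counts must be non-negative")
    if a + b + c + d == 0:
        raise ValueError("at least one margin must be positive")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
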