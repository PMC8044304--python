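"""Age/sex matching of comparison groups and cut-off recomputation.

Cut-offs derived from unmatched groups can be confounded by demographic
imbalance (AD patients run older than clinic controls).  The matching
procedure here is the simple, auditable one used in biomarker studies:

1. **Age histogram matching** — ages are binned into fixed 5-year intervals
   anchored at age 0 ([40, 45), [45, 50), ...); within each bin the larger
   group is randomly down-sampled to the smaller group's count, and bins
   present in only one group are dropped from both.
2. **Sex rebalancing** — subjects of the over-represented sex are excluded one
   at a time (from the group where that sex is over-represented) until a
   logistic regression of group membership on age and sex shows no residual
   association (both Wald p-values above a threshold, 0.25 by default).

The logistic fit is a self-contained maximum-likelihood IRLS implementation so
the balance criterion is fully specified by this module.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cutoffs import CutoffResult, DIRECTIONS, bootstrap_cutoff_ci, youden_cutoff
from .io import FEATURES

logger = logging.getLogger(__name__)

__all__ = [
    "LogisticFit", "MatchingReport", "age_histogram_match", "logistic_fit_irls",
    "gender_balance", "match_groups", "matched_cutoffs", "SeparationWarning",
]


class SeparationWarning(UserWarning):
    """Complete separation detected in the logistic fit."""


@dataclass
class LogisticFit:
    names: tuple[str, ...]
    coef: np.ndarray
    se: np.ndarray
    wald_z: np.ndarray
    p_values: np.ndarray
    deviance: float
    n_iter: int
    converged: bool
    separation: bool

    def p_for(self, name: str) -> float:
        return float(self.p_values[self.names.index(name)])


@dataclass
class MatchingReport:
    bin_width: float
    bins: list[tuple[float, float]]
    retained_a: np.ndarray
    retained_b: np.ndarray
    excluded_per_bin: dict
    excluded_per_sex: dict
    final_fit: LogisticFit | None
    p_trajectory: list[dict]
    iterations: int
    seed: int | None
    success: bool


def age_histogram_match(ids_a, ages_a, ids_b, ages_b, bin_width: float = 5.0,
                        seed: int | None = 0):
    """Equalize two groups' age histograms by random within-bin exclusion.

    Bins are ``[k*w, (k+1)*w)`` anchored at age 0.  Within each bin the larger
    group is randomly down-sampled (seeded) to the smaller count; bins empty
    in one group are dropped entirely.  Returns
    ``(retained_ids_a, retained_ids_b, report_dict)``.
    """
    ids_a, ids_b = np.asarray(ids_a), np.asarray(ids_b)
    ages_a = np.asarray(ages_a, dtype=float)
    ages_b = np.asarray(ages_b, dtype=float)
    if len(ids_a) == 0 or len(ids_b) == 0:
        raise ValueError("both groups must be non-empty")
    rng = np.random.default_rng(seed)

    bins_a = np.floor(ages_a / bin_width).astype(int)
    bins_b = np.floor(ages_b / bin_width).astype(int)
    keep_a, keep_b = [], []
    excluded_per_bin = {}
    bins_used = []
    for k in sorted(set(bins_a) | set(bins_b)):
        in_a = np.flatnonzero(bins_a == k)
        in_b = np.flatnonzero(bins_b == k)
        interval = (k * bin_width, (k + 1) * bin_width)
        if len(in_a) == 0 or len(in_b) == 0:
            excluded_per_bin[interval] = len(in_a) + len(in_b)
            continue
        target = min(len(in_a), len(in_b))
        if len(in_a) > target:
            in_a = rng.choice(in_a, size=target, replace=False)
        if len(in_b) > target:
            in_b = rng.choice(in_b, size=target, replace=False)
        excluded_per_bin[interval] = (np.sum(bins_a == k) - target) + \
                                     (np.sum(bins_b == k) - target)
        bins_used.append(interval)
        keep_a.append(np.sort(in_a))
        keep_b.append(np.sort(in_b))
    if not keep_a:
        raise ValueError("age matching produced empty groups: no overlapping bins")
    return (ids_a[np.concatenate(keep_a)], ids_b[np.concatenate(keep_b)],
            {"bins": bins_used, "excluded_per_bin": excluded_per_bin})


def logistic_fit_irls(outcome, covariates, names=None, tol: float = 1e-8,
                      max_iter: int = 100) -> LogisticFit:
    """Maximum-likelihood logistic regression by iteratively reweighted least
    squares, with Wald tests from the normal approximation.

    ``covariates`` is an (n, p) array or DataFrame; an intercept column is
    prepended.  Convergence is declared on relative deviance change below
    ``tol``.  Complete separation (fitted probabilities collapsing to 0/1
    with diverging coefficients) is flagged, not silently returned.
    """
    y = np.asarray(outcome, dtype=float)
    if isinstance(covariates, pd.DataFrame):
        if names is None:
            names = tuple(covariates.columns)
        X = covariates.to_numpy(dtype=float)
    else:
        X = np.asarray(covariates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if names is None:
            names = tuple(f"x{i + 1}" for i in range(X.shape[1]))
    n, p = X.shape
    if n < 4:
        raise ValueError("at least 4 observations are required")
    if y.min() == y.max():
        raise ValueError("outcome has a single class")
    Xd = np.column_stack([np.ones(n), X])
    names = ("intercept",) + tuple(names)

    beta = np.zeros(p + 1)
    deviance = np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        eta = Xd @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        z = eta + (y - mu) / w
        WX = Xd * w[:, None]
        try:
            beta = np.linalg.solve(Xd.T @ WX, WX.T @ z)
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"singular information matrix: {exc}") from exc
        eta = Xd @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        new_dev = -2.0 * float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
        if np.isfinite(deviance) and abs(new_dev - deviance) <= tol * (abs(deviance) + 1e-12):
            deviance = new_dev
            converged = True
            break
        deviance = new_dev

    eta = Xd @ beta
    separation = bool(np.max(np.abs(eta)) > 30) or not np.all(np.isfinite(beta))
    if separation:
        logger.warning("complete separation suspected in logistic fit "
                       "(|linear predictor| > 30); Wald tests unreliable")

    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    info = Xd.T @ (Xd * w[:, None])
    cov = np.linalg.pinv(info)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = beta / se
    from scipy import stats as _st
    pvals = 2.0 * _st.norm.sf(np.abs(wald))
    return LogisticFit(names=names, coef=beta, se=se, wald_z=wald,
                       p_values=pvals, deviance=deviance, n_iter=n_iter,
                       converged=converged, separation=separation)


def _balance_fit(group, ages, sexes) -> LogisticFit:
    sex_num = (np.asarray(sexes) == "M").astype(float)
    X = np.column_stack([np.asarray(ages, float), sex_num])
    return logistic_fit_irls(np.asarray(group, float), X, names=("age", "sex"))


def gender_balance(ids, ages, sexes, group, p_threshold: float = 0.25,
                   seed: int | None = 0, max_iter: int | None = None):
    """Iterative one-at-a-time sex rebalancing after age matching.

    Fits group ~ age + sex; while either Wald p-value is at or below
    ``p_threshold``, randomly excludes one subject of the over-represented sex
    from the group where that sex is over-represented, then refits.  Fails
    with the p-value trajectory after ``max_iter`` exclusions (default: half
    the subjects — strong imbalances, e.g. 90% vs 50% male at n = 200 per
    group, genuinely need ~40% of subjects excluded before the Wald test
    goes quiet).

    Returns ``(retained_ids, fits_trajectory, n_iterations, final_fit)``.
    """
    ids = np.asarray(ids)
    ages = np.asarray(ages, dtype=float)
    sexes = np.asarray(sexes)
    group = np.asarray(group).astype(int)
    if max_iter is None:
        max_iter = max(1, len(ids) // 2)
    rng = np.random.default_rng(seed)

    keep = np.ones(len(ids), dtype=bool)
    trajectory = []
    for it in range(max_iter + 1):
        fit = _balance_fit(group[keep], ages[keep], sexes[keep])
        p_age, p_sex = fit.p_for("age"), fit.p_for("sex")
        trajectory.append({"iteration": it, "p_age": p_age, "p_sex": p_sex,
                           "n": int(keep.sum())})
        if p_age > p_threshold and p_sex > p_threshold:
            return ids[keep], trajectory, it, fit
        # M is over-represented in whichever group has the higher male
        # proportion; remove one random subject of that sex from that group
        # (equivalently, remove an F from the other group if that group has
        # no M left)
        g1, g0 = (group == 1) & keep, (group == 0) & keep
        m1 = np.mean(sexes[g1] == "M")
        m0 = np.mean(sexes[g0] == "M")
        if m1 == m0:
            break  # sexes balanced; only p_age can be failing, exclusion by sex cannot help
        over_group = g1 if m1 > m0 else g0
        target = over_group & (sexes == "M")
        if not target.any():
            target = (g0 if m1 > m0 else g1) & (sexes == "F")
        if not target.any():
            break
        drop = rng.choice(np.flatnonzero(target))
        keep[drop] = False
    raise RuntimeError(
        "gender balance did not reach p > "
        f"{p_threshold} within {max_iter} exclusions; trajectory: {trajectory}")


def match_groups(table: pd.DataFrame, mask_a, mask_b, bin_width: float = 5.0,
                 p_threshold: float = 0.25, seed: int | None = 0,
                 max_iter: int | None = None) -> MatchingReport:
    """Full age-then-sex matching of two subject groups in a cohort table.

    Group A is the reference (e.g. AD-like clusters), group B the comparison
    (e.g. control cluster).  Returns a :class:`MatchingReport` with retained
    subject_ids per group and the final logistic balance fit.
    """
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if (mask_a & mask_b).any():
        raise ValueError("groups must be disjoint")
    sub_a = table.loc[mask_a]
    sub_b = table.loc[mask_b]
    ids_a, ids_b, age_report = age_histogram_match(
        sub_a["subject_id"].to_numpy(), sub_a["age"].to_numpy(),
        sub_b["subject_id"].to_numpy(), sub_b["age"].to_numpy(),
        bin_width=bin_width, seed=seed)

    retained = table.loc[table["subject_id"].isin(np.concatenate([ids_a, ids_b]))]
    group = retained["subject_id"].isin(ids_a).astype(int).to_numpy()
    sexes_before = retained["sex"].to_numpy()
    final_ids, trajectory, n_iter, fit = gender_balance(
        retained["subject_id"].to_numpy(), retained["age"].to_numpy(),
        sexes_before, group, p_threshold=p_threshold,
        seed=None if seed is None else seed + 1, max_iter=max_iter)

    final_a = np.asarray([i for i in final_ids if i in set(ids_a)])
    final_b = np.asarray([i for i in final_ids if i in set(ids_b)])
    dropped = set(retained["subject_id"]) - set(final_ids)
    sex_of = dict(zip(retained["subject_id"], sexes_before))
    excluded_per_sex = {"F": sum(sex_of[i] == "F" for i in dropped),
                        "M": sum(sex_of[i] == "M" for i in dropped)}
    return MatchingReport(
        bin_width=bin_width, bins=age_report["bins"],
        retained_a=final_a, retained_b=final_b,
        excluded_per_bin=age_report["excluded_per_bin"],
        excluded_per_sex=excluded_per_sex,
        final_fit=fit, p_trajectory=trajectory, iterations=n_iter,
        seed=seed, success=True)


def matched_cutoffs(table: pd.DataFrame, labels, cluster_labels: dict,
                    retained_ids, n_boot: int = 2000, seed: int | None = 0):
    """Recompute control-vs-AD-clusters cut-offs on a matched subset.

    Returns a DataFrame with matched and unmatched cut-offs side by side and a
    ``same_within_ci`` flag (matched point estimate inside the unmatched 95%
    CI).  Raises if matching lost either comparison group.
    """
    labels = np.asarray(labels)
    lab_series = pd.Series(labels, index=table.index)
    control = [c for c, l in cluster_labels.items() if l == "control"]
    ad_like = [c for c, l in cluster_labels.items() if l == "AD-like"]
    if not control or not ad_like:
        raise ValueError("control and AD-like clusters are both required")

    in_subset = table["subject_id"].isin(np.asarray(retained_ids))
    rows = []
    for i, bm in enumerate(FEATURES):
        direction = DIRECTIONS[bm]
        for name, mask in (("unmatched", pd.Series(True, index=table.index)),
                           ("matched", in_subset)):
            pos = mask & lab_series.isin(ad_like)
            neg = mask & lab_series.isin(control)
            if not pos.any() or not neg.any():
                raise ValueError(f"{name} subset lost a comparison group")
            vals = table.loc[pos | neg, bm].to_numpy(dtype=float)
            lab = pos[pos | neg].to_numpy()
            res = youden_cutoff(vals, lab, direction, biomarker=bm,
                                comparison="control_vs_AD_clusters")
            res.ci = bootstrap_cutoff_ci(
                vals, lab, direction, n_boot=n_boot,
                seed=None if seed is None else seed + i)
            rows.append({"biomarker": bm, "subset": name, "cutoff": res.cutoff,
                         "ci_low": res.ci[0], "ci_high": res.ci[1],
                         "youden_j": res.youden_j, "n_pos": res.n_pos,
                         "n_neg": res.n_neg})
    out = pd.DataFrame(rows)
    flags = {}
    for bm in FEATURES:
        um = out[(out.biomarker == bm) & (out.subset == "unmatched")].iloc[0]
        ma = out[(out.biomarker == bm) & (out.subset == "matched")].iloc[0]
        flags[bm] = bool(um.ci_low <= ma.cutoff <= um.ci_high)
    out["same_within_ci"] = out["biomarker"].map(flags)
    return out
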