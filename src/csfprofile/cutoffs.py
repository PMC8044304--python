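"""Diagnostic cut-off derivation by Youden-index maximization.

For each biomarker, a binary comparison (AD-positive vs control-negative
group) defines an ROC problem; the cut-off is the threshold maximizing
Youden's J = sensitivity + specificity - 1.  Directions are fixed a priori by
disease biology: a *low* Abeta42/Abeta40 ratio is AD-positive (amyloidosis),
*high* p-tau and t-tau are AD-positive (tauopathy / neurodegeneration).

Three comparison families are computed: the clinical contrast (AD vs OND
diagnoses), the cluster contrast (control cluster vs the union of AD-like
clusters), and each intermediate cluster vs the AD-like union.  95% CIs come
from a stratified percentile bootstrap (2000 replicates by default).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import FEATURES

logger = logging.getLogger(__name__)

__all__ = ["CutoffResult", "youden_cutoff", "bootstrap_cutoff_ci", "cutoff_table",
           "DIRECTIONS"]

#: A priori test-positive direction per biomarker.
DIRECTIONS: dict[str, str] = {
    "ratio": "lower_is_positive",
    "ptau": "higher_is_positive",
    "ttau": "higher_is_positive",
}


@dataclass
class CutoffResult:
    biomarker: str
    comparison: str
    direction: str
    cutoff: float
    youden_j: float
    sensitivity: float
    specificity: float
    ci: tuple[float, float] | None
    n_pos: int
    n_neg: int


def _candidate_thresholds(values: np.ndarray) -> np.ndarray:
    """Midpoints between adjacent distinct values, plus -inf/+inf sentinels."""
    u = np.unique(values)
    mids = (u[:-1] + u[1:]) / 2.0 if len(u) > 1 else np.empty(0)
    return np.concatenate(([-np.inf], mids, [np.inf]))


def _youden_scan(values: np.ndarray, positive: np.ndarray,
                 direction: str) -> tuple[float, float, float]:
    """Best (cutoff, sensitivity, specificity) by a single cumulative scan.

    Because candidate thresholds are midpoints between distinct values, no
    observation ever sits on a threshold, and the class counts strictly below
    each candidate are cumulative sums over the sorted distinct values.
    """
    u, inv = np.unique(values, return_inverse=True)
    pos_at = np.bincount(inv, weights=positive.astype(float), minlength=len(u)).astype(np.int64)
    neg_at = np.bincount(inv, weights=(~positive).astype(float), minlength=len(u)).astype(np.int64)
    pos_below = np.concatenate(([0], np.cumsum(pos_at)))
    neg_below = np.concatenate(([0], np.cumsum(neg_at)))
    thresholds = _candidate_thresholds(values)
    n_pos, n_neg = int(pos_below[-1]), int(neg_below[-1])
    if direction == "lower_is_positive":
        tp = pos_below
        tn = n_neg - neg_below
        extreme = thresholds
    else:
        tp = n_pos - pos_below
        tn = neg_below
        extreme = -thresholds
    # integer-exact ranking: J * n_pos * n_neg = tp*n_neg + tn*n_pos - const,
    # so mathematically tied J values tie exactly and the documented
    # tie-break (max sensitivity, then the more spec-conservative threshold)
    # is never decided by float rounding
    j_key = tp * n_neg + tn * n_pos
    i = np.lexsort((extreme, tp, j_key))[-1]
    return float(thresholds[i]), tp[i] / n_pos, tn[i] / n_neg


def youden_cutoff(values, is_positive, direction: str,
                  biomarker: str = "", comparison: str = "custom") -> CutoffResult:
    """Threshold maximizing Youden's J, without a CI.

    Candidate thresholds are midpoints between adjacent distinct values (plus
    infinite sentinels); test-positive means ``value < threshold`` for
    ``lower_is_positive`` and ``value > threshold`` otherwise.  Ties on J
    break toward the highest sensitivity, then toward the threshold more
    conservative for specificity (smaller for ``higher_is_positive``, larger
    for ``lower_is_positive``).  Reported J is clipped at 0.
    """
    values = np.asarray(values, dtype=float)
    positive = np.asarray(is_positive, dtype=bool)
    if values.shape != positive.shape or values.ndim != 1:
        raise ValueError("values and is_positive must be aligned 1-D arrays")
    if positive.all() or not positive.any():
        raise ValueError("both a positive and a negative class are required")
    if direction not in ("lower_is_positive", "higher_is_positive"):
        raise ValueError(f"unknown direction: {direction}")

    cutoff, sens, spec = _youden_scan(values, positive, direction)
    j = sens + spec - 1.0
    return CutoffResult(
        biomarker=biomarker, comparison=comparison, direction=direction,
        cutoff=float(cutoff), youden_j=max(j, 0.0),
        sensitivity=sens, specificity=spec, ci=None,
        n_pos=int(positive.sum()), n_neg=int((~positive).sum()),
    )


def bootstrap_cutoff_ci(values, is_positive, direction: str,
                        n_boot: int = 2000, seed: int | None = 0,
                        ci_level: float = 0.95) -> tuple[float, float]:
    """Stratified percentile-bootstrap CI for the Youden cut-off.

    Positives and negatives are resampled within class, so every replicate
    contains both classes.  The interval is enveloped around the point
    estimate so that ci_low <= cutoff <= ci_high always holds.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    values = np.asarray(values, dtype=float)
    positive = np.asarray(is_positive, dtype=bool)
    point = youden_cutoff(values, positive, direction).cutoff
    pos_vals = values[positive]
    neg_vals = values[~positive]
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    lab = np.concatenate([np.ones(len(pos_vals), bool), np.zeros(len(neg_vals), bool)])
    for b in range(n_boot):
        vp = pos_vals[rng.integers(0, len(pos_vals), size=len(pos_vals))]
        vn = neg_vals[rng.integers(0, len(neg_vals), size=len(neg_vals))]
        reps[b] = _youden_scan(np.concatenate([vp, vn]), lab, direction)[0]
    lo, hi = (1 - ci_level) / 2 * 100, (1 + ci_level) / 2 * 100
    finite = reps[np.isfinite(reps)]
    if len(finite) == 0:
        return (point, point)
    ci = np.percentile(finite, [lo, hi])
    return (min(float(ci[0]), point), max(float(ci[1]), point))


def _one_comparison(table, mask_pos, mask_neg, comparison, n_boot, seed,
                    directions) -> list[CutoffResult]:
    out = []
    for i, bm in enumerate(FEATURES):
        for direction in directions.get(bm) if isinstance(directions.get(bm), list) \
                else [directions.get(bm, DIRECTIONS[bm])]:
            vals = table.loc[mask_pos | mask_neg, bm].to_numpy(dtype=float)
            lab = mask_pos[mask_pos | mask_neg].to_numpy()
            res = youden_cutoff(vals, lab, direction, biomarker=bm,
                                comparison=comparison)
            res.ci = bootstrap_cutoff_ci(vals, lab, direction, n_boot=n_boot,
                                         seed=None if seed is None else seed + i)
            out.append(res)
    return out


def cutoff_table(table: pd.DataFrame, labels, cluster_labels: dict,
                 n_boot: int = 2000, seed: int | None = 0,
                 both_directions_for_intermediate: bool = True) -> list[CutoffResult]:
    """Cut-offs for all three biomarkers across the standard comparisons.

    Comparisons: ``clinical`` (AD diagnoses positive, OND negative);
    ``control_vs_AD_clusters`` (AD-like union positive, control cluster
    negative); and one comparison per intermediate cluster vs the AD-like
    union.  For intermediate comparisons the heterogeneous cluster can exceed
    the AD clusters on t-tau, so both orientations are emitted with explicit
    direction fields when ``both_directions_for_intermediate`` is set.

    A comparison whose groups are missing is skipped with a logged warning;
    the others are still computed.
    """
    labels = np.asarray(labels)
    if len(labels) != len(table):
        raise ValueError("one cluster label per table row is required")
    results: list[CutoffResult] = []
    diag = table["diagnosis"].to_numpy()

    def directions_plain():
        return {bm: [DIRECTIONS[bm]] for bm in FEATURES}

    # clinical: AD positive vs OND negative
    mask_pos = pd.Series(diag == "AD", index=table.index)
    mask_neg = pd.Series(diag == "OND", index=table.index)
    if mask_pos.any() and mask_neg.any():
        results += _one_comparison(table, mask_pos, mask_neg, "clinical",
                                   n_boot, seed, directions_plain())
    else:
        logger.warning("clinical comparison skipped: AD or OND group missing")

    control = [c for c, l in cluster_labels.items() if l == "control"]
    ad_like = [c for c, l in cluster_labels.items() if l == "AD-like"]
    intermediates = [c for c, l in cluster_labels.items() if l == "intermediate"]

    lab_series = pd.Series(labels, index=table.index)
    if control and ad_like:
        mask_pos = lab_series.isin(ad_like)
        mask_neg = lab_series.isin(control)
        results += _one_comparison(table, mask_pos, mask_neg,
                                   "control_vs_AD_clusters",
                                   n_boot, None if seed is None else seed + 10,
                                   directions_plain())
    else:
        logger.warning("cluster comparison skipped: control or AD-like clusters missing")

    for c in intermediates:
        if not ad_like:
            break
        dirs = directions_plain()
        if both_directions_for_intermediate:
            dirs = {bm: ["lower_is_positive", "higher_is_positive"] for bm in FEATURES}
        mask_pos = lab_series.isin(ad_like)
        mask_neg = lab_series == c
        results += _one_comparison(table, mask_pos, mask_neg,
                                   f"cluster{c}_vs_AD_clusters",
                                   n_boot, None if seed is None else seed + 20 + int(c),
                                   dirs)
    return results


def cutoff_results_frame(results: list[CutoffResult]) -> pd.DataFrame:
    """Flatten a list of CutoffResult into a tidy DataFrame (Table-1-style)."""
    rows = []
    for r in results:
        rows.append({
            "biomarker": r.biomarker, "comparison": r.comparison,
            "direction": r.direction, "cutoff": r.cutoff,
            "ci_low": r.ci[0] if r.ci else np.nan,
            "ci_high": r.ci[1] if r.ci else np.nan,
            "youden_j": r.youden_j, "sensitivity": r.sensitivity,
            "specificity": r.specificity, "n_pos": r.n_pos, "n_neg": r.n_neg,
        })
    return pd.DataFrame(rows)
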