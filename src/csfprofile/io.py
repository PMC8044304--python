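"""Cohort table I/O, validation, and z-score standardization.

The subject-level cohort is carried around as a plain :class:`pandas.DataFrame`
with one row per lumbar puncture and (at least) the columns

``subject_id, cohort, diagnosis, age, sex, abeta42, abeta40, ptau, ttau, ratio``

where ``ratio`` is the dimensionless Abeta42/Abeta40 concentration ratio and the
four analyte concentrations are in pg/mL.  The ratio is the primary amyloidosis
marker throughout: it is more robust than Abeta42 alone to pre-analytical
absorption losses, which act similarly on both isoforms.

Unknown extra columns are preserved on read and write so that tables can be
passed through intermediate stages without loss.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Controlled diagnosis vocabulary.  Anything outside this set is mapped to
#: ``"other"`` with a warning (rare categories are filtered by the prevalence
#: heatmap's minimum-count rule downstream anyway).
DIAGNOSES: tuple[str, ...] = (
    "AD", "OND", "FTD", "PD", "PDD", "DLB", "CJD", "NPH", "MS", "sMCI",
    "SCD", "VAD", "CAA", "ENC", "uDEM", "CVD", "PSP", "MSA", "CBD", "other",
)

#: The three clustered biomarker features, in canonical order.
FEATURES: tuple[str, str, str] = ("ratio", "ptau", "ttau")

REQUIRED_COLUMNS: tuple[str, ...] = (
    "subject_id", "cohort", "diagnosis", "age", "sex",
    "abeta42", "abeta40", "ptau", "ttau",
)

STAGES: tuple[str, ...] = ("dementia", "MCI", "none")

AGE_BOUNDS = (18.0, 110.0)
RATIO_RTOL = 1e-12


class SchemaError(ValueError):
    """A required column is missing or unusable."""


class RowError(ValueError):
    """A data row violates a record invariant (strict mode only)."""


def compute_ratio(abeta42, abeta40):
    """Abeta42/Abeta40 concentration ratio.

    Accepts scalars or arrays; ``abeta40`` must be strictly positive.
    """
    a40 = np.asarray(abeta40, dtype=float)
    if np.any(a40 <= 0):
        raise ValueError("abeta40 must be strictly positive to form the Abeta42/Abeta40 ratio")
    out = np.asarray(abeta42, dtype=float) / a40
    if out.ndim == 0:
        return float(out)
    return out


def _canonical_columns(columns: Iterable[str]) -> dict[str, str]:
    """Map actual header names to canonical lower-case names, case-insensitively."""
    mapping = {}
    wanted = {c.lower(): c for c in REQUIRED_COLUMNS + ("ratio", "stage")}
    for col in columns:
        key = col.strip().lower()
        if key in wanted:
            mapping[col] = wanted[key]
    return mapping


def validate_cohort(df: pd.DataFrame, strict: bool = True) -> tuple[pd.DataFrame, int]:
    """Validate and normalize a cohort table.

    Returns ``(clean_table, n_dropped)``.  In strict mode the first invalid row
    raises :class:`RowError` (naming the 1-based data row); otherwise invalid
    rows are dropped and the count logged.  Row order is preserved.
    """
    df = df.copy()
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column: {col}")

    numeric = ["age", "abeta42", "abeta40", "ptau", "ttau"]
    bad = pd.Series(False, index=df.index)
    reasons: dict[int, str] = {}

    for col in numeric:
        vals = pd.to_numeric(df[col], errors="coerce")
        mask = vals.isna()
        for i in df.index[mask & ~bad]:
            reasons[i] = f"non-numeric {col}"
        bad |= mask
        df[col] = vals

    df["sex"] = df["sex"].astype(str).str.strip().str.upper()
    mask = ~df["sex"].isin(["F", "M"])
    for i in df.index[mask & ~bad]:
        reasons[i] = "sex must be F or M"
    bad |= mask

    cohort = pd.to_numeric(df["cohort"], errors="coerce")
    mask = ~cohort.isin([1, 2])
    for i in df.index[mask & ~bad]:
        reasons[i] = "cohort must be 1 or 2"
    bad |= mask
    df["cohort"] = cohort.where(mask, cohort).fillna(-1).astype(int)

    for col in ("abeta42", "abeta40", "ptau", "ttau"):
        mask = ~(df[col] > 0)
        for i in df.index[mask & ~bad]:
            reasons[i] = f"{col} must be > 0"
        bad |= mask

    lo, hi = AGE_BOUNDS
    mask = ~((df["age"] > lo) & (df["age"] < hi))
    for i in df.index[mask & ~bad]:
        reasons[i] = f"age must be in ({lo:g}, {hi:g}) years"
    bad |= mask

    # diagnosis normalization: unknown labels collapse to "other"
    diag = df["diagnosis"].astype(str).str.strip()
    unknown = ~diag.isin(DIAGNOSES)
    if unknown.any():
        labels = sorted(diag[unknown].unique())
        logger.warning("mapping %d unknown diagnosis label(s) to 'other': %s",
                       int(unknown.sum()), ", ".join(labels))
        diag = diag.where(~unknown, "other")
    df["diagnosis"] = diag

    if "stage" in df.columns:
        stage = df["stage"].astype(str).str.strip()
        df["stage"] = stage.where(stage.isin(STAGES), "none")

    # ratio: recompute where absent, cross-check where present
    ok = ~bad
    if "ratio" in df.columns:
        given = pd.to_numeric(df["ratio"], errors="coerce")
        expect = df["abeta42"] / df["abeta40"]
        mismatch = ok & ~np.isclose(given, expect, rtol=RATIO_RTOL, atol=0.0)
        for i in df.index[mismatch & ~bad]:
            reasons[i] = "ratio inconsistent with abeta42/abeta40"
        bad |= mismatch.fillna(False)
    df.loc[ok, "ratio"] = df.loc[ok, "abeta42"] / df.loc[ok, "abeta40"]

    if bad.any():
        if strict:
            i = df.index[bad][0]
            raise RowError(f"row {int(i) + 1}: {reasons.get(i, 'invalid record')}")
        n_dropped = int(bad.sum())
        logger.info("dropped %d invalid row(s)", n_dropped)
        df = df.loc[~bad]
    else:
        n_dropped = 0

    df["subject_id"] = df["subject_id"].astype(str)
    return df.reset_index(drop=True), n_dropped


def load_cohort_csv(path: str | Path, strict: bool = True) -> pd.DataFrame:
    """Read a subject-level cohort CSV, validate it, and return the table.

    The header is matched case-insensitively; a missing required column raises
    :class:`SchemaError` naming it.  Extra columns pass through untouched.
    """
    path = Path(path)
    raw = pd.read_csv(path)
    raw = raw.rename(columns=_canonical_columns(raw.columns))
    for col in REQUIRED_COLUMNS:
        if col not in raw.columns:
            raise SchemaError(f"{path.name}: missing required column: {col}")
    table, n_dropped = validate_cohort(raw, strict=strict)
    if n_dropped:
        logger.info("%s: %d row(s) dropped during validation", path.name, n_dropped)
    return table


def write_cohort_csv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table as UTF-8 comma-separated CSV with a single header row."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)


@dataclass(frozen=True)
class StandardizationTransform:
    """Per-feature z-score transform fitted on a cohort.

    ``apply`` maps natural units to z-scores ``(x - mean) / sd``; ``invert``
    is its exact inverse.  The sample SD uses the n-1 denominator.
    """

    feature_names: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray

    def _matrix(self, data) -> np.ndarray:
        if isinstance(data, pd.DataFrame):
            return data.loc[:, list(self.feature_names)].to_numpy(dtype=float)
        arr = np.asarray(data, dtype=float)
        if arr.ndim == 1:
            arr = arr[None, :]
        if arr.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} feature columns, got {arr.shape[1]}")
        return arr

    def apply(self, data) -> np.ndarray:
        """Natural units -> z-scores. Accepts a cohort DataFrame or an (n, 3) array."""
        return (self._matrix(data) - self.means) / self.sds

    def invert(self, z) -> np.ndarray:
        """z-scores -> natural units."""
        z = np.asarray(z, dtype=float)
        return z * self.sds + self.means

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "means": [float(m) for m in self.means],
            "sds": [float(s) for s in self.sds],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StandardizationTransform":
        return cls(tuple(d["feature_names"]),
                   np.asarray(d["means"], float), np.asarray(d["sds"], float))


def fit_standardization(table: pd.DataFrame,
                        features: Sequence[str] = FEATURES) -> StandardizationTransform:
    """Fit a z-score transform on the pooled cohort (both centers together).

    Pooling is deliberate: the two centers are merged before clustering, so a
    single set of moments describes the clustered data.  A zero-variance
    feature is an error naming the feature.
    """
    if len(table) < 2:
        raise ValueError("at least 2 records are required to fit a standardization")
    X = table.loc[:, list(features)].to_numpy(dtype=float)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    for name, sd in zip(features, sds):
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"zero variance: {name}")
    return StandardizationTransform(tuple(features), means, sds)
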