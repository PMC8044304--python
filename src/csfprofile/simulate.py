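"""Synthetic cohort generator.

Real CSF biomarker cohorts of this kind are available only on request, so the
package ships a generator that reproduces the statistical structure the
analysis stages assume:

* a six-component trivariate Gaussian mixture over (Abeta42/Abeta40 ratio,
  p-tau, t-tau) in natural units — one high-ratio/low-tau "control-like"
  component, four low-ratio components graded upward in tau ("AD-like"), and
  one wide-variance heterogeneous component (the CJD/NPH/FTD-type profile
  with highly variable tau);
* per-component clinical-diagnosis composition, so clinically defined groups
  (AD, OND, PD, ...) are spread over components the way a memory-clinic
  series is;
* per-diagnosis age and sex models, deliberately imbalanced so that
  age/sex histogram matching has real work to do;
* paired two-center remeasurement of a subsample with per-analyte
  proportional noise at realistic inter-assay CV levels.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .io import DIAGNOSES, FEATURES

#: Default per-analyte inter-center coefficients of variation (fractions).
DEFAULT_INTERCENTER_CV: dict[str, float] = {
    "ratio": 0.07,
    "ptau": 0.04,
    "ttau": 0.09,
    "abeta42": 0.12,
    "abeta40": 0.09,
}

#: Diagnoses that imply a dementia stage when present.
_DEMENTIA_DIAGNOSES = {"FTD", "DLB", "PDD", "VAD", "uDEM", "CJD"}

#: Probability that an AD subject is sampled in the prodromal (MCI) phase.
_AD_MCI_FRACTION = 0.17

_POSITIVITY_FLOOR = 1e-6
_MAX_REDRAWS = 100


@dataclass
class MixtureSpec:
    """Parameters of the generating mixture and its clinical annotation models.

    ``means``/``covariances`` are in natural units over ``(ratio, ptau, ttau)``
    (ratio dimensionless, taus in pg/mL).  ``diagnosis_composition`` has one
    categorical row per component over the diagnosis vocabulary.
    ``age_model`` maps diagnosis -> (mean, sd, lower, upper) in years;
    ``sex_model`` maps diagnosis -> probability of female.  Both accept a
    ``"*"`` fallback key.
    """

    n_components: int
    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    diagnosis_composition: pd.DataFrame
    age_model: dict[str, tuple[float, float, float, float]]
    sex_model: dict[str, float]

    def validate(self) -> None:
        K = self.n_components
        if self.weights.shape != (K,) or abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("component weights must be a length-K simplex vector")
        if np.any(self.weights < 0):
            raise ValueError("component weights must be non-negative")
        if self.means.shape != (K, 3) or self.covariances.shape != (K, 3, 3):
            raise ValueError("means must be (K, 3) and covariances (K, 3, 3)")
        for k in range(K):
            cov = self.covariances[k]
            if not np.allclose(cov, cov.T):
                raise ValueError(f"covariance of component {k + 1} is not symmetric")
            if np.linalg.eigvalsh(cov).min() <= 0:
                raise ValueError(f"covariance of component {k + 1} is not positive definite")
        comp = self.diagnosis_composition
        if comp.shape[0] != K:
            raise ValueError("diagnosis_composition must have one row per component")
        if not set(comp.columns).issubset(DIAGNOSES):
            bad = set(comp.columns) - set(DIAGNOSES)
            raise ValueError(f"unknown diagnoses in composition: {sorted(bad)}")
        rowsums = comp.to_numpy().sum(axis=1)
        if np.any(np.abs(rowsums - 1.0) > 1e-12) or (comp.to_numpy() < 0).any():
            raise ValueError("each diagnosis_composition row must be a probability vector")

    def _age_params(self, diagnosis: str) -> tuple[float, float, float, float]:
        return self.age_model.get(diagnosis, self.age_model["*"])

    def _p_female(self, diagnosis: str) -> float:
        return self.sex_model.get(diagnosis, self.sex_model["*"])

    def to_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
            "diagnosis_composition": {
                f"component_{k + 1}": {d: float(v) for d, v in row.items() if v > 0}
                for k, (_, row) in enumerate(self.diagnosis_composition.iterrows())
            },
            "age_model": {d: list(v) for d, v in self.age_model.items()},
            "sex_model": dict(self.sex_model),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MixtureSpec":
        K = int(d["n_components"])
        comp_in = d["diagnosis_composition"]
        comp = pd.DataFrame(0.0, index=range(K), columns=list(DIAGNOSES))
        for k in range(K):
            row = comp_in[f"component_{k + 1}"]
            for diag, v in row.items():
                comp.loc[k, diag] = float(v)
        comp = comp.div(comp.sum(axis=1), axis=0)
        spec = cls(
            n_components=K,
            weights=np.asarray(d["weights"], float),
            means=np.asarray(d["means"], float),
            covariances=np.asarray(d["covariances"], float),
            diagnosis_composition=comp,
            age_model={k: tuple(v) for k, v in d["age_model"].items()},
            sex_model={k: float(v) for k, v in d["sex_model"].items()},
        )
        spec.validate()
        return spec


def _cov(sd_ratio: float, sd_ptau: float, sd_ttau: float, rho_tau: float) -> np.ndarray:
    """3x3 covariance with ptau-ttau correlation and an independent ratio axis."""
    cov = np.diag([sd_ratio ** 2, sd_ptau ** 2, sd_ttau ** 2])
    cov[1, 2] = cov[2, 1] = rho_tau * sd_ptau * sd_ttau
    return cov


def default_mixture_spec() -> MixtureSpec:
    """The default six-component cohort model.

    Component 1 is control-like (ratio ~0.095, low tau); component 2 is the
    heterogeneous profile (intermediate ratio, very wide tau variance, where
    CJD/NPH/FTD-type subjects concentrate); components 3-6 are AD-like
    (ratio ~0.045, p-tau and t-tau graded upward).  Tau pairs are positively
    correlated within components, as they are biologically.
    """
    weights = np.array([0.30, 0.10, 0.20, 0.15, 0.15, 0.10])
    means = np.array([
        [0.095, 30.0, 220.0],    # 1: control-like
        [0.075, 65.0, 900.0],    # 2: heterogeneous, high-variance tau
        [0.045, 55.0, 350.0],    # 3: AD-like, mild tau
        [0.045, 80.0, 550.0],    # 4
        [0.045, 110.0, 800.0],   # 5
        [0.045, 150.0, 1200.0],  # 6: AD-like, severe tau
    ])
    # Within-component spreads are chosen so the six components are mutually
    # resolvable at cohort scale (adjacent AD-like components sit ~3 within-
    # component SDs apart in each tau dimension), mirroring how distinct the
    # biomarker profiles of real data-driven clusters are; the heterogeneous
    # component keeps a deliberately huge t-tau variance.
    covariances = np.stack([
        _cov(0.012, 6.5, 50.0, 0.2),
        _cov(0.020, 30.0, 600.0, 0.2),
        _cov(0.008, 6.5, 50.0, 0.2),
        _cov(0.008, 7.5, 65.0, 0.2),
        _cov(0.008, 8.5, 85.0, 0.2),
        _cov(0.008, 10.0, 110.0, 0.2),
    ])

    comp = pd.DataFrame(0.0, index=range(6), columns=list(DIAGNOSES))
    # component 1: controls and non-amyloid conditions
    comp.loc[0] = pd.Series({
        "OND": 0.30, "PD": 0.24, "sMCI": 0.085, "SCD": 0.04, "PSP": 0.07,
        "MSA": 0.04, "MS": 0.03, "FTD": 0.06, "NPH": 0.04, "CVD": 0.015,
        "ENC": 0.015, "AD": 0.02, "DLB": 0.01, "CBD": 0.01, "uDEM": 0.005,
        "VAD": 0.005, "CAA": 0.005, "other": 0.03,
    }).reindex(comp.columns, fill_value=0.0)
    # component 2: heterogeneous — all CJD plus NPH/FTD/ENC/VAD-type profiles
    comp.loc[1] = pd.Series({
        "CJD": 0.12, "NPH": 0.22, "FTD": 0.18, "ENC": 0.06, "VAD": 0.05,
        "uDEM": 0.04, "AD": 0.08, "OND": 0.05, "CVD": 0.03, "DLB": 0.03,
        "PSP": 0.02, "CBD": 0.03, "PD": 0.02, "sMCI": 0.02, "other": 0.05,
    }).reindex(comp.columns, fill_value=0.0)
    # components 3-6: AD-dominated, with the dementia syndromes that share
    # amyloid/tau pathology (DLB, PDD, CBD) represented
    adlike = pd.Series({
        "AD": 0.62, "DLB": 0.07, "PDD": 0.025, "CBD": 0.02, "FTD": 0.05,
        "NPH": 0.03, "OND": 0.01, "sMCI": 0.01, "CAA": 0.02, "uDEM": 0.01,
        "VAD": 0.01, "PD": 0.01, "other": 0.02,
    }).reindex(comp.columns, fill_value=0.0)
    for k in range(2, 6):
        comp.loc[k] = adlike
    comp = comp.div(comp.sum(axis=1), axis=0)

    age_model = {
        "AD": (72.0, 8.0, 40.0, 90.0),
        "OND": (58.0, 12.0, 40.0, 90.0),
        "*": (68.0, 10.0, 40.0, 90.0),
    }
    sex_model = {"AD": 0.55, "OND": 0.45, "PD": 0.35, "*": 0.50}

    spec = MixtureSpec(6, weights, means, covariances, comp, age_model, sex_model)
    spec.validate()
    return spec


def _draw_positive_mvn(rng: np.random.Generator, mean: np.ndarray, cov: np.ndarray,
                       size: int) -> np.ndarray:
    """Multivariate normal draws with all-positive coordinates.

    Negative coordinates are rejected and redrawn up to a redraw cap, then
    clamped to a small positive floor; rejection distorts the covariance less
    than hard truncation would.
    """
    x = rng.multivariate_normal(mean, cov, size=size, method="cholesky")
    bad = (x <= 0).any(axis=1)
    tries = 0
    while bad.any() and tries < _MAX_REDRAWS:
        x[bad] = rng.multivariate_normal(mean, cov, size=int(bad.sum()), method="cholesky")
        bad = (x <= 0).any(axis=1)
        tries += 1
    if bad.any():
        x[x <= 0] = _POSITIVITY_FLOOR
    return x


def _truncnorm_rvs(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(spec: MixtureSpec | None = None, n: int = 616,
                    seed: int = 0, with_truth: bool = True) -> pd.DataFrame:
    """Draw a synthetic subject-level cohort of ``n`` subjects.

    Each subject gets a mixture component, biomarkers from that component's
    trivariate normal (rejection-sampled to positivity), a clinical diagnosis
    from the component's composition, age and sex from the per-diagnosis
    models, and an alternating center assignment.  ``with_truth`` appends the
    hidden ``_component`` column (1-based) for parameter-recovery testing.
    """
    if spec is None:
        spec = default_mixture_spec()
    spec.validate()
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    K = spec.n_components

    component = rng.choice(K, size=n, p=spec.weights)
    X = np.empty((n, 3))
    for k in range(K):
        idx = np.flatnonzero(component == k)
        if idx.size:
            X[idx] = _draw_positive_mvn(rng, spec.means[k], spec.covariances[k], idx.size)
    ratio, ptau, ttau = X.T

    vocab = list(spec.diagnosis_composition.columns)
    diagnosis = np.empty(n, dtype=object)
    for k in range(K):
        idx = np.flatnonzero(component == k)
        if idx.size:
            p = spec.diagnosis_composition.iloc[k].to_numpy()
            diagnosis[idx] = rng.choice(vocab, size=idx.size, p=p)

    age = np.empty(n)
    p_female = np.empty(n)
    for diag in np.unique(diagnosis):
        idx = np.flatnonzero(diagnosis == diag)
        mean, sd, lo, hi = spec._age_params(diag)
        age[idx] = _truncnorm_rvs(rng, mean, sd, lo, hi, idx.size)
        p_female[idx] = spec._p_female(diag)
    sex = np.where(rng.random(n) < p_female, "F", "M")

    stage = np.full(n, "none", dtype=object)
    is_ad = diagnosis == "AD"
    stage[is_ad] = np.where(rng.random(int(is_ad.sum())) < _AD_MCI_FRACTION,
                            "MCI", "dementia")
    stage[np.isin(diagnosis, list(_DEMENTIA_DIAGNOSES))] = "dementia"

    # Abeta40 is drawn independently of the mixture (amyloidosis shows in the
    # ratio, not in Abeta40 itself); Abeta42 then follows from the ratio.
    abeta40 = _truncnorm_rvs(rng, 11000.0, 2500.0, 4000.0, 20000.0, n)
    abeta42 = ratio * abeta40

    table = pd.DataFrame({
        "subject_id": [f"S{i + 1:04d}" for i in range(n)],
        "cohort": np.where(np.arange(n) % 2 == 0, 1, 2),
        "diagnosis": diagnosis,
        "stage": stage,
        "age": np.round(age, 1),
        "sex": sex,
        "abeta42": abeta42,
        "abeta40": abeta40,
        "ptau": ptau,
        "ttau": ttau,
        "ratio": ratio,
    })
    if with_truth:
        table["_component"] = component + 1
    return table


def generate_paired_measurements(table: pd.DataFrame,
                                 cv_per_analyte: Mapping[str, float] | None = None,
                                 n_pairs: int = 40,
                                 seed: int = 0) -> pd.DataFrame:
    """Simulate re-measuring a subsample of subjects in both centers.

    For each sampled subject and analyte, each center observes
    ``true * (1 + eps)`` with ``eps ~ N(0, cv^2)`` independently per center —
    a purely proportional inter-assay noise model.  Values are floored at a
    small positive constant.  Returns a long table with columns
    ``subject_id, analyte, center1_value, center2_value``.
    """
    if cv_per_analyte is None:
        cv_per_analyte = DEFAULT_INTERCENTER_CV
    for analyte, cv in cv_per_analyte.items():
        if cv < 0:
            raise ValueError(f"CV for {analyte} must be >= 0")
        if analyte not in table.columns:
            raise ValueError(f"analyte column not in table: {analyte}")
    if not 1 <= n_pairs <= len(table):
        raise ValueError("n_pairs must be between 1 and the table size")

    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(len(table), size=n_pairs, replace=False))
    sub = table.iloc[chosen]

    rows = []
    for analyte, cv in cv_per_analyte.items():
        true = sub[analyte].to_numpy(dtype=float)
        c1 = true * (1.0 + rng.normal(0.0, cv, size=n_pairs))
        c2 = true * (1.0 + rng.normal(0.0, cv, size=n_pairs))
        rows.append(pd.DataFrame({
            "subject_id": sub["subject_id"].to_numpy(),
            "analyte": analyte,
            "center1_value": np.maximum(c1, _POSITIVITY_FLOOR),
            "center2_value": np.maximum(c2, _POSITIVITY_FLOOR),
        }))
    return pd.concat(rows, ignore_index=True)
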