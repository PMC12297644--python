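"""Synthetic patient cohorts on the Cleveland heart-disease schema.

Thirteen clinical features (age, sex, chest-pain type, resting blood
pressure, serum cholesterol, fasting blood sugar flag, resting ECG, maximum
heart rate, exercise-induced angina, ST depression, ST slope, vessels
colored by fluoroscopy, thalassemia) plus a binary normal/abnormal label.

The generator draws the label first (Bernoulli at the configured
prevalence) and then the features class-conditionally: continuous features
from Gaussians centred at the published-range means and shifted apart by
``effect_scale`` standard deviations along a fixed, documented direction
vector; categorical features from class-conditional probability tables
whose separation is likewise scaled.  Because the continuous part is a
two-Gaussian equal-covariance mixture, the true posterior is a linear logit
and an exact Bayes oracle is available (:func:`bayes_oracle`), which
upper-bounds any classifier trained on the same cohort.

A reader for the processed-Cleveland CSV dialect (14 comma-separated
fields, "?" for missing, target 0-4 binarized to normal/abnormal) is
included; it is never required for building or testing the package.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

__all__ = [
    "FEATURE_NAMES",
    "PatientRecord",
    "CohortSpec",
    "generate_cohort",
    "feature_matrix",
    "impute_missing",
    "bayes_oracle",
    "read_cleveland",
    "write_cleveland",
    "split",
]

FEATURE_NAMES = [
    "age", "sex", "cp", "trestbps", "chol", "fbs", "restecg",
    "thalach", "exang", "oldpeak", "slope", "ca", "thal",
]

# continuous features: (mean, sd, clip_lo, clip_hi, direction weight w_f)
# w_f signs: disease raises age/BP/cholesterol/ST-depression, lowers max HR
_CONTINUOUS: Dict[str, Tuple[float, float, float, float, float]] = {
    "age": (54.0, 9.0, 29.0, 77.0, 0.4),
    "trestbps": (131.0, 17.0, 94.0, 200.0, 0.3),
    "chol": (246.0, 51.0, 126.0, 564.0, 0.3),
    "thalach": (149.0, 23.0, 71.0, 202.0, -0.8),
    "oldpeak": (1.0, 1.1, 0.0, 6.2, 0.9),
}
_INTEGER_CONTINUOUS = {"age", "trestbps", "chol", "thalach"}

# categorical features: levels and class-conditional tables at full
# separation (rough Cleveland empirical frequencies)
_CATEGORICAL: Dict[str, Tuple[List[float], List[float], List[float]]] = {
    # name: (levels, P(level | normal), P(level | abnormal))
    "sex": ([0, 1], [0.44, 0.56], [0.17, 0.83]),
    "cp": ([1, 2, 3, 4], [0.16, 0.25, 0.42, 0.17], [0.05, 0.06, 0.13, 0.76]),
    "fbs": ([0, 1], [0.86, 0.14], [0.84, 0.16]),
    "restecg": ([0, 1, 2], [0.58, 0.01, 0.41], [0.39, 0.03, 0.58]),
    "exang": ([0, 1], [0.86, 0.14], [0.45, 0.55]),
    "slope": ([1, 2, 3], [0.66, 0.29, 0.05], [0.26, 0.62, 0.12]),
    "ca": ([0, 1, 2, 3], [0.83, 0.12, 0.04, 0.01], [0.33, 0.32, 0.22, 0.13]),
    "thal": ([3, 6, 7], [0.79, 0.04, 0.17], [0.26, 0.10, 0.64]),
}

_FIRST_NAMES = ["Asha", "Ravi", "Meera", "John", "Priya", "Kumar", "Grace",
                "Anand", "Leela", "Vikram"]
_LOCATIONS = ["Chennai", "Mumbai", "Delhi", "Coimbatore", "Hyderabad",
              "Pollachi", "Bengaluru", "Kochi"]


@dataclass
class PatientRecord:
    """One Cleveland-schema record with identity metadata.

    ``features`` maps feature name to float; missing entries are NaN
    (written as "?" in CSV).  ``label`` is 0 normal / 1 abnormal.
    """

    patient_id: str
    features: Dict[str, float]
    label: int
    name: str = ""
    location: str = ""

    def feature_vector(self) -> np.ndarray:
        return np.array([self.features[f] for f in FEATURE_NAMES], dtype=float)


@dataclass
class CohortSpec:
    """n patients at the given prevalence; ``effect_scale`` sets the
    class separation (0 = label-independent features; 2 = strongly
    separable); ``missing_rate`` injects "?" into ca/thal, the fields
    missing in the real file."""

    n: int
    prevalence: float = 0.46
    effect_scale: float = 1.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must be in (0, 1)")
        if self.effect_scale < 0:
            raise ValueError("effect_scale must be >= 0")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")


def _categorical_tables(name: str, effect_scale: float) -> Tuple[np.ndarray, np.ndarray]:
    """Class-conditional tables with separation scaled by effect_scale.

    kappa = min(effect_scale / 2, 1) interpolates between the pooled table
    (kappa 0: features independent of the label) and the full Cleveland-like
    tables (kappa 1, reached at effect_scale >= 2).
    """
    _, p0, p1 = _CATEGORICAL[name]
    p0 = np.asarray(p0)
    p1 = np.asarray(p1)
    pooled = 0.5 * (p0 + p1)
    kappa = min(effect_scale / 2.0, 1.0)
    t0 = pooled + kappa * (p0 - pooled)
    t1 = pooled + kappa * (p1 - pooled)
    return t0 / t0.sum(), t1 / t1.sum()


def generate_cohort(spec: CohortSpec) -> List[PatientRecord]:
    """Fully reproducible synthetic cohort (see module docstring)."""
    rng = np.random.default_rng(spec.seed)
    records: List[PatientRecord] = []
    for i in range(spec.n):
        label = int(rng.random() < spec.prevalence)
        sign = label - 0.5  # class means sit +-(effect_scale/2)*sd*w_f apart
        feats: Dict[str, float] = {}
        for fname in FEATURE_NAMES:
            if fname in _CONTINUOUS:
                mu, sd, lo, hi, w = _CONTINUOUS[fname]
                shift = sign * spec.effect_scale * sd * w
                val = float(np.clip(rng.normal(mu + shift, sd), lo, hi))
                if fname in _INTEGER_CONTINUOUS:
                    val = float(round(val))
                else:
                    val = round(val, 1)
                feats[fname] = val
            else:
                levels, _, _ = _CATEGORICAL[fname]
                t0, t1 = _categorical_tables(fname, spec.effect_scale)
                table = t1 if label else t0
                feats[fname] = float(levels[rng.choice(len(levels), p=table)])
        if spec.missing_rate > 0.0:
            for fname in ("ca", "thal"):
                if rng.random() < spec.missing_rate:
                    feats[fname] = math.nan
        records.append(PatientRecord(
            patient_id=f"P{i:04d}",
            features=feats,
            label=label,
            name=str(rng.choice(_FIRST_NAMES)),
            location=str(rng.choice(_LOCATIONS)),
        ))
    return records


def feature_matrix(records: Sequence[PatientRecord]) -> Tuple[np.ndarray, np.ndarray]:
    """(n, 13) feature matrix and label vector (NaN where missing)."""
    X = np.array([r.feature_vector() for r in records], dtype=float).reshape(
        len(records), len(FEATURE_NAMES))
    y = np.array([r.label for r in records], dtype=int)
    return X, y


def impute_missing(records: Sequence[PatientRecord]) -> Dict[str, float]:
    """In-place median (continuous) / mode (categorical) imputation.

    Returns the imputation value used per feature that had any missing
    entry (empty dict when the cohort is complete).
    """
    used: Dict[str, float] = {}
    for fname in FEATURE_NAMES:
        vals = np.array([r.features[fname] for r in records], dtype=float)
        missing = np.isnan(vals)
        if not missing.any():
            continue
        present = vals[~missing]
        if present.size == 0:
            fill = 0.0
        elif fname in _CONTINUOUS:
            fill = float(np.median(present))
        else:
            uniq, counts = np.unique(present, return_counts=True)
            fill = float(uniq[np.argmax(counts)])
        used[fname] = fill
        for r in records:
            if math.isnan(r.features[fname]):
                r.features[fname] = fill
    return used


def bayes_oracle(spec: CohortSpec, X: np.ndarray) -> np.ndarray:
    """Exact Bayes-optimal labels for features generated under ``spec``.

    Computes the true log posterior odds from the generating model (Gaussian
    log-likelihood ratios for continuous features, table ratios for
    categoricals, plus the prior odds) and thresholds at 0.  Clipping and
    rounding in the generator are ignored, a negligible approximation.
    """
    X = np.asarray(X, dtype=float)
    logit = np.full(X.shape[0], math.log(spec.prevalence / (1 - spec.prevalence)))
    for j, fname in enumerate(FEATURE_NAMES):
        x = X[:, j]
        if fname in _CONTINUOUS:
            mu, sd, _, _, w = _CONTINUOUS[fname]
            delta = spec.effect_scale * sd * w  # mean(class1) - mean(class0)
            mu1 = mu + delta / 2.0
            mu0 = mu - delta / 2.0
            logit = logit + ((x - mu0) ** 2 - (x - mu1) ** 2) / (2.0 * sd ** 2)
        else:
            levels, _, _ = _CATEGORICAL[fname]
            t0, t1 = _categorical_tables(fname, spec.effect_scale)
            lookup = {lv: math.log(t1[i] / t0[i]) for i, lv in enumerate(levels)}
            logit = logit + np.array([lookup.get(v, 0.0) for v in x])
    return (logit > 0).astype(int)


def write_cleveland(records: Sequence[PatientRecord], path: str) -> None:
    """Write the 14-column processed-Cleveland dialect ("?" for missing)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        for r in records:
            row = []
            for fname in FEATURE_NAMES:
                v = r.features[fname]
                row.append("?" if (isinstance(v, float) and math.isnan(v))
                           else f"{v:g}")
            row.append(str(int(r.label)))
            writer.writerow(row)


def read_cleveland(path: str) -> Tuple[List[PatientRecord], Dict[str, float]]:
    """Parse the processed-Cleveland dialect.

    14 comma-separated fields per line, "?" for missing; the 0-4 target is
    binarized (0 -> normal, 1-4 -> abnormal).  Missing values are imputed
    by cohort median/mode; the imputation values used are returned alongside
    the records.  Raises on a wrong column count (with the line number) or
    an unparseable token (with the field name).
    """
    records: List[PatientRecord] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 14:
                raise ValueError(
                    f"line {lineno}: expected 14 fields, got {len(row)}")
            feats: Dict[str, float] = {}
            for fname, token in zip(FEATURE_NAMES, row[:13]):
                token = token.strip()
                if token == "?":
                    feats[fname] = math.nan
                    continue
                try:
                    feats[fname] = float(token)
                except ValueError as exc:
                    raise ValueError(
                        f"line {lineno}: unparseable value for {fname!r}: "
                        f"{token!r}") from exc
            try:
                target = int(float(row[13]))
            except ValueError as exc:
                raise ValueError(
                    f"line {lineno}: unparseable target {row[13]!r}") from exc
            records.append(PatientRecord(
                patient_id=f"C{lineno:04d}",
                features=feats,
                label=int(target > 0),
            ))
    if not records:
        import warnings
        warnings.warn("empty Cleveland file: returning an empty cohort")
        return [], {}
    imputed = impute_missing(records)
    return records, imputed


def split(
    records: Sequence[PatientRecord], test_fraction: float, seed: int = 0
) -> Tuple[List[PatientRecord], List[PatientRecord]]:
    """Stratified, reproducible train/test split."""
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must be in (0, 1)")
    labels = {r.label for r in records}
    if len(labels) < 2:
        raise ValueError("cohort contains a single class; cannot stratify")
    rng = np.random.default_rng(seed)
    train: List[PatientRecord] = []
    test: List[PatientRecord] = []
    for cls in sorted(labels):
        idx = [i for i, r in enumerate(records) if r.label == cls]
        idx = list(np.array(idx)[rng.permutation(len(idx))])
        n_test = int(round(test_fraction * len(idx)))
        test.extend(records[i] for i in idx[:n_test])
        train.extend(records[i] for i in idx[n_test:])
    return train, test
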