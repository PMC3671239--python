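"""Gaussian naive Bayes with a tunable decision threshold.

The classifier assumes the composition features independent given the class
and models each feature per class as a Gaussian.  A sample with feature
vector F = (f_1, ..., f_n) is scored by the log posterior ratio

    s(F) = log P(C=1)/P(C=0) + sum_i log p_i(f_i | C=1) / p_i(f_i | C=0)

(natural logarithms) and called a virion protein (class 1) when
``s(F) >= theta``.  The inclusive comparison means a score exactly at the
threshold goes to class 1.  theta = 0 is the maximum-a-posteriori rule;
:func:`tune_threshold` sweeps the candidate thresholds implied by a training
matrix to maximize accuracy or Youden's J.

Class-conditional standard deviations are floored at ``sigma_min`` so that
zero-variance features (constant within a class) cannot produce infinite
log ratios.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .features import FeatureMatrix, FeatureSubset, FeatureVector
from .seqio import PhavipError

MODEL_SCHEMA_VERSION = 1

#: Default floor on per-class per-feature standard deviations.  Composition
#: features live in [0, 1]; the floor keeps log-density ratios finite.
DEFAULT_SIGMA_MIN = 1e-6


class ModelError(PhavipError):
    """Fitting or prediction contract violated (single class, bad schema, ...)."""


class FeatureMismatchError(ModelError):
    """The input's feature names do not match the subset the model was fitted on."""


@dataclass
class NBModel:
    """A fitted naive Bayes model over a named feature subset.

    ``mu`` and ``sigma`` have shape (2, p): row 0 holds the class-0
    (nonvirion) parameters, row 1 the class-1 (virion) parameters, columns
    follow ``feature_names``.
    """

    feature_names: tuple[str, ...]
    prior_pos: float                       # P(C=1)
    mu: np.ndarray
    sigma: np.ndarray
    theta: float = 0.0
    sigma_min: float = DEFAULT_SIGMA_MIN
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=np.float64)
        self.sigma = np.asarray(self.sigma, dtype=np.float64)
        p = len(self.feature_names)
        if self.mu.shape != (2, p) or self.sigma.shape != (2, p):
            raise ModelError("density parameter shapes must be (2, n_features)")
        if not (0.0 < self.prior_pos < 1.0):
            raise ModelError("P(C=1) must lie strictly in (0, 1)")
        if not np.isfinite(self.mu).all() or not np.isfinite(self.sigma).all():
            raise ModelError("density parameters must be finite")
        if (self.sigma < self.sigma_min).any():
            raise ModelError("all sigmas must respect the sigma_min floor")

    @property
    def prior_neg(self) -> float:
        return 1.0 - self.prior_pos

    @property
    def subset(self) -> FeatureSubset:
        return FeatureSubset(self.feature_names)


def fit(
    matrix: FeatureMatrix,
    sigma_min: float = DEFAULT_SIGMA_MIN,
    provenance: dict | None = None,
) -> NBModel:
    """Fit priors and per-class Gaussian densities from a labelled matrix.

    Priors are the class frequencies; means and standard deviations are the
    maximum-likelihood estimates per class and feature, with sigma floored
    at ``sigma_min``.  The returned model has theta = 0.
    """
    matrix.require_labelled()
    y = matrix.labels
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ModelError("both classes must be present to fit the classifier")
    if sigma_min <= 0:
        raise ModelError("sigma_min must be positive")
    mu = np.empty((2, matrix.n_features))
    sigma = np.empty((2, matrix.n_features))
    for c in (0, 1):
        rows = matrix.values[y == c]
        mu[c] = rows.mean(axis=0)
        sigma[c] = rows.std(axis=0)
    sigma = np.maximum(sigma, sigma_min)
    prov = dict(provenance or {})
    prov.setdefault("training_checksum", _matrix_checksum(matrix))
    prov.setdefault("n_pos", n_pos)
    prov.setdefault("n_neg", n_neg)
    return NBModel(
        feature_names=matrix.feature_names,
        prior_pos=n_pos / (n_pos + n_neg),
        mu=mu,
        sigma=sigma,
        theta=0.0,
        sigma_min=sigma_min,
        provenance=prov,
    )


def _matrix_checksum(matrix: FeatureMatrix) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(matrix.values).tobytes())
    if matrix.labels is not None:
        h.update(np.ascontiguousarray(matrix.labels).tobytes())
    return h.hexdigest()[:16]


def _check_features(model: NBModel, names: tuple[str, ...]) -> None:
    if tuple(names) != tuple(model.feature_names):
        raise FeatureMismatchError(
            f"input has {len(names)} features, model expects "
            f"{len(model.feature_names)} ({model.feature_names[:3]}...); "
            "project the input onto the model's subset first"
        )


def score_matrix(model: NBModel, matrix: FeatureMatrix) -> np.ndarray:
    """Log posterior ratio for every row of a matrix (vectorized)."""
    _check_features(model, matrix.feature_names)
    x = matrix.values
    log_prior = math.log(model.prior_pos) - math.log(model.prior_neg)
    ll = np.zeros((2, x.shape[0]))
    for c in (0, 1):
        z = (x - model.mu[c]) / model.sigma[c]
        ll[c] = (-0.5 * z * z - np.log(model.sigma[c])).sum(axis=1)
    return log_prior + ll[1] - ll[0]


def log_posterior_ratio(model: NBModel, vector: FeatureVector | np.ndarray) -> float:
    """Log posterior ratio of one sample restricted to the model's subset."""
    values = vector.values if isinstance(vector, FeatureVector) else np.asarray(vector)
    if values.shape != (len(model.feature_names),):
        raise FeatureMismatchError(
            f"vector has {values.shape} values, model expects "
            f"{len(model.feature_names)} features"
        )
    if not np.isfinite(values).all():
        raise ModelError("feature values must be finite")
    log_prior = math.log(model.prior_pos) - math.log(model.prior_neg)
    total = log_prior
    for c, sign in ((1, +1.0), (0, -1.0)):
        z = (values - model.mu[c]) / model.sigma[c]
        total += sign * float((-0.5 * z * z - np.log(model.sigma[c])).sum())
    return total


def predict(model: NBModel, vector: FeatureVector | np.ndarray) -> int:
    """Class decision: 1 iff the log posterior ratio is >= theta."""
    return 1 if log_posterior_ratio(model, vector) >= model.theta else 0


def predict_matrix(model: NBModel, matrix: FeatureMatrix) -> np.ndarray:
    return (score_matrix(model, matrix) >= model.theta).astype(np.int64)


def tune_threshold(
    model: NBModel,
    matrix: FeatureMatrix,
    objective: str = "accuracy",
) -> float:
    """Pick the threshold maximizing an objective on a labelled matrix.

    Candidates are the midpoints between consecutive distinct sorted scores
    plus a below-minimum and an above-maximum sentinel; ties on the
    objective go to the smallest candidate.  Objectives: ``accuracy`` or
    ``youden`` (Sn + Sp - 1).
    """
    matrix.require_labelled()
    y = matrix.labels
    if (y == 1).sum() == 0 or (y == 0).sum() == 0:
        raise ModelError("threshold tuning requires both classes")
    if objective not in ("accuracy", "youden"):
        raise ModelError(f"unknown objective {objective!r}")
    scores = score_matrix(model, matrix)
    distinct = np.unique(scores)
    candidates = np.concatenate((
        [distinct[0] - 1.0],
        (distinct[:-1] + distinct[1:]) / 2.0,
        [distinct[-1] + 1.0],
    ))
    n_pos = (y == 1).sum()
    n_neg = (y == 0).sum()
    best_theta = candidates[0]
    best_obj = -math.inf
    for theta in candidates:
        pred = scores >= theta
        tp = int((pred & (y == 1)).sum())
        tn = int((~pred & (y == 0)).sum())
        if objective == "accuracy":
            obj = (tp + tn) / (n_pos + n_neg)
        else:
            obj = tp / n_pos + tn / n_neg - 1.0
        if obj > best_obj:
            best_obj = obj
            best_theta = theta
    return float(best_theta)


# --------------------------------------------------------------------------
# Persistence: a single JSON document, keys sorted for reproducible diffs
# --------------------------------------------------------------------------

def save_model(model: NBModel, path: str | Path) -> None:
    doc = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "feature_names": list(model.feature_names),
        "prior_pos": model.prior_pos,
        "densities": {
            "mu": {"0": model.mu[0].tolist(), "1": model.mu[1].tolist()},
            "sigma": {"0": model.sigma[0].tolist(), "1": model.sigma[1].tolist()},
        },
        "theta": model.theta,
        "sigma_min": model.sigma_min,
        "provenance": model.provenance,
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True, indent=1))


def load_model(path: str | Path) -> NBModel:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ModelError(f"{path}: corrupted model file ({exc})") from exc
    if not isinstance(doc, dict) or doc.get("schema_version") != MODEL_SCHEMA_VERSION:
        raise ModelError(
            f"{path}: unsupported schema version {doc.get('schema_version')!r}"
        )
    required = {"feature_names", "prior_pos", "densities", "theta", "sigma_min"}
    missing = required - doc.keys()
    if missing:
        raise ModelError(f"{path}: missing model fields {sorted(missing)}")
    dens = doc["densities"]
    if not isinstance(dens, dict) or {"mu", "sigma"} - dens.keys():
        raise ModelError(f"{path}: malformed densities block")
    mu = np.array([dens["mu"]["0"], dens["mu"]["1"]], dtype=np.float64)
    sigma = np.array([dens["sigma"]["0"], dens["sigma"]["1"]], dtype=np.float64)
    return NBModel(
        feature_names=tuple(doc["feature_names"]),
        prior_pos=float(doc["prior_pos"]),
        mu=mu,
        sigma=sigma,
        theta=float(doc["theta"]),
        sigma_min=float(doc["sigma_min"]),
        provenance=dict(doc.get("provenance", {})),
    )
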