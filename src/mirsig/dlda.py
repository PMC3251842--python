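"""Diagonal linear discriminant analysis (DLDA) of ΔCt expression.

DLDA models each class as a Gaussian with class-specific means and a shared
diagonal covariance.  For a two-class sensitivity problem the classifier
emits, for each unknown sample, one score per class,

    score_k(x) = -1/2 * sum_j (x_j - mu_kj)^2 / sigma_j^2,

the diagonal-Gaussian log-likelihood up to an additive constant shared by
both classes (the shared log-variance term cancels in the comparison and is
omitted).  Plotting (score_resistant, score_sensitive), samples above the
identity line are called sensitive and samples on or below it resistant: the
tie at zero margin is resolved to *resistant*, the conservative clinical
error direction for a borderline tumour.

Variances are pooled within-class and floored at ``variance_floor`` so that
degenerate probes (e.g. rows fully imputed at the Ct ceiling) cannot produce
infinite scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .ct import DeltaCtMatrix
from .exceptions import ValidationError

CLASS_RESISTANT = "resistant"
CLASS_SENSITIVE = "sensitive"


@dataclass
class PredictionScorePair:
    """The two class-likelihood scores and the identity-line call for one
    sample.  ``margin`` = score_sensitive − score_resistant; the call is
    sensitive iff the margin is strictly positive."""

    sample_id: str | None
    score_resistant: float
    score_sensitive: float
    call: str
    margin: float


def _class_stats(X: np.ndarray, y01: np.ndarray, variance_floor: float, pooled: bool):
    """Per-probe class means and (pooled or per-class) variances.

    Pooled variance uses the standard n-2 denominator:
    sigma_j^2 = sum_k sum_i (x_ij - mu_kj)^2 / (n - 2).
    """
    n = X.shape[0]
    means = np.empty((2, X.shape[1]))
    ss = np.empty((2, X.shape[1]))
    counts = np.empty(2, dtype=int)
    for k in (0, 1):
        Xk = X[y01 == k]
        counts[k] = Xk.shape[0]
        means[k] = Xk.mean(axis=0)
        ss[k] = ((Xk - means[k]) ** 2).sum(axis=0)
    if pooled:
        var = ss.sum(axis=0) / (n - 2)
        variances = np.vstack([var, var])
    else:
        variances = ss / np.maximum(counts - 1, 1)[:, None]
    floored = variances < variance_floor
    variances = np.maximum(variances, variance_floor)
    return means, variances, counts, floored.any(axis=0)


class DLDAClassifier(ClassifierMixin, BaseEstimator):
    """Diagonal linear discriminant classifier with the identity-line rule.

    Parameters
    ----------
    variance_floor : float, default 1e-8
        Lower bound (cycles²) applied to every per-probe variance.
    pooled : bool, default True
        Pool within-class variances (standard DLDA).  ``False`` keeps one
        diagonal variance per class (a quadratic-boundary variant).
    priors : mapping class -> prior, optional
        Class priors added as log-terms to the scores; default equal priors,
        matching a balanced training design.

    Attributes
    ----------
    classes_ : ndarray of shape (2,)
        Sorted class labels; for the canonical labels this is
        ``['resistant', 'sensitive']`` and ``classes_[1]`` is the positive
        (sensitive) class.
    class_means_ : ndarray (2, n_features)
    pooled_variances_ : ndarray (n_features,)  (pooled mode)
    variances_ : ndarray (2, n_features)
    variance_floored_ : ndarray of bool (n_features,)
    """

    def __init__(self, variance_floor: float = 1e-8, pooled: bool = True, priors=None):
        self.variance_floor = variance_floor
        self.pooled = pooled
        self.priors = priors

    # ------------------------------------------------------------------
    def _validate_X(self, X, n_features: int | None = None):
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy()
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.ndim != 2:
            raise ValidationError("X must be a 2-D samples × probes array")
        if not np.isfinite(X).all():
            raise ValidationError("X must be finite")
        if n_features is not None and X.shape[1] != n_features:
            raise ValidationError(
                f"X has {X.shape[1]} features, model was fitted with {n_features}"
            )
        return X

    def fit(self, X, y):
        if self.variance_floor <= 0:
            raise ValidationError("variance_floor must be positive")
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        X = self._validate_X(X)
        y = np.asarray(y)
        if y.shape[0] != X.shape[0]:
            raise ValidationError("X and y have mismatched sample counts")
        classes, y01 = np.unique(y, return_inverse=True)
        if classes.shape[0] != 2:
            raise ValidationError(f"exactly two classes required, got {list(classes)}")
        counts = np.bincount(y01, minlength=2)
        if counts.min() < 2:
            small = classes[int(np.argmin(counts))]
            raise ValidationError(f"class {small!r} has fewer than 2 training samples")
        self.classes_ = classes
        self.n_features_in_ = X.shape[1]
        means, variances, counts, floored = _class_stats(
            X, y01, self.variance_floor, self.pooled
        )
        self.class_means_ = means
        self.variances_ = variances
        self.pooled_variances_ = variances[0] if self.pooled else None
        self.variance_floored_ = floored
        self.n_per_class_ = dict(zip(classes.tolist(), counts.tolist()))
        if self.priors is not None:
            p = np.array([float(self.priors[c]) for c in classes])
            if (p <= 0).any():
                raise ValidationError("priors must be positive")
            self._log_priors = np.log(p / p.sum())
        else:
            self._log_priors = np.zeros(2)
        return self

    def class_scores(self, X) -> np.ndarray:
        """(n_samples, 2) log-likelihood scores, columns ordered as
        ``classes_``."""
        self._check_fitted()
        X = self._validate_X(X, self.n_features_in_)
        d = X[:, None, :] - self.class_means_[None, :, :]
        scores = -0.5 * (d**2 / self.variances_[None, :, :]).sum(axis=2)
        return scores + self._log_priors[None, :]

    def decision_function(self, X) -> np.ndarray:
        """Margin score_sensitive − score_resistant (positive class minus
        negative class); positive values fall above the identity line."""
        scores = self.class_scores(X)
        return scores[:, 1] - scores[:, 0]

    def predict(self, X) -> np.ndarray:
        margin = self.decision_function(X)
        return self.classes_[(margin > 0).astype(int)]

    def score_pair(self, x, sample_id: str | None = None) -> PredictionScorePair:
        """Score one sample and apply the identity-line rule."""
        self._check_fitted()
        if set(self.classes_) != {CLASS_RESISTANT, CLASS_SENSITIVE}:
            raise ValidationError(
                "score_pair requires the canonical resistant/sensitive labels"
            )
        scores = self.class_scores(np.asarray(x, dtype=float)[None, :])[0]
        s_res, s_sen = float(scores[0]), float(scores[1])
        margin = s_sen - s_res
        call = CLASS_SENSITIVE if margin > 0 else CLASS_RESISTANT
        return PredictionScorePair(
            sample_id=sample_id,
            score_resistant=s_res,
            score_sensitive=s_sen,
            call=call,
            margin=margin,
        )

    def _check_fitted(self):
        if not hasattr(self, "classes_"):
            raise ValidationError("classifier is not fitted")


# ---------------------------------------------------------------------------
# ΔCt-matrix level wrappers
# ---------------------------------------------------------------------------

def _labels_for(samples: Sequence[str], labels) -> pd.Series:
    s = pd.Series(labels)
    missing = [x for x in samples if x not in s.index]
    if missing:
        raise ValidationError(f"no class label for sample(s): {', '.join(missing)}")
    return s.loc[list(samples)]


def _signature_probes(signature) -> list[str]:
    return list(signature.probe_ids) if hasattr(signature, "probe_ids") else list(signature)


def fit_dlda(
    matrix: DeltaCtMatrix,
    labels,
    signature,
    *,
    variance_floor: float = 1e-8,
    pooled: bool = True,
    priors=None,
) -> DLDAClassifier:
    """Fit a :class:`DLDAClassifier` on the signature rows of a ΔCt matrix.

    ``labels`` maps sample id to 'sensitive'/'resistant'; only labelled
    samples enter the fit.
    """
    probes = _signature_probes(signature)
    lab = pd.Series(labels)
    lab = lab[lab.isin([CLASS_RESISTANT, CLASS_SENSITIVE])]
    use = [s for s in matrix.sample_ids if s in lab.index]
    X = matrix.restrict(probes)[use].T
    clf = DLDAClassifier(variance_floor=variance_floor, pooled=pooled, priors=priors)
    clf.fit(X, lab.loc[use].to_numpy())
    clf.probe_ids_ = tuple(probes)
    return clf


def score_sample(model: DLDAClassifier, x, sample_id: str | None = None) -> PredictionScorePair:
    """Score a single ΔCt vector aligned to the model's probe order."""
    x = np.asarray(pd.Series(x).to_numpy() if isinstance(x, pd.Series) else x, dtype=float)
    if x.ndim != 1 or x.shape[0] != model.n_features_in_:
        raise ValidationError(
            f"expected a vector of length {model.n_features_in_}, got shape {x.shape}"
        )
    return model.score_pair(x, sample_id=sample_id)


def predict_batch(model: DLDAClassifier, matrix: DeltaCtMatrix, actual=None) -> pd.DataFrame:
    """Score every sample of a ΔCt matrix.

    Returns a table with one row per sample: the two class scores, the
    margin, the identity-line call, and (when ``actual`` labels are given)
    the known sensitivity — mirroring a validation-cohort report.
    """
    probes = getattr(model, "probe_ids_", None)
    X = matrix.restrict(list(probes)).T if probes is not None else matrix.values.T
    if X.shape[0] == 0:
        return pd.DataFrame(
            columns=["sample_id", "score_resistant", "score_sensitive", "margin", "call", "actual"]
        )
    scores = model.class_scores(X)
    margin = scores[:, 1] - scores[:, 0]
    calls = np.where(margin > 0, CLASS_SENSITIVE, CLASS_RESISTANT)
    out = pd.DataFrame(
        {
            "sample_id": list(X.index),
            "score_resistant": scores[:, 0],
            "score_sensitive": scores[:, 1],
            "margin": margin,
            "call": calls,
        }
    )
    if actual is not None:
        lab = pd.Series(actual)
        out["actual"] = [lab.get(s, np.nan) for s in out["sample_id"]]
    else:
        out["actual"] = np.nan
    return out


@dataclass
class LOOCVResult:
    """Per-sample held-out calls and the overall accuracy fraction."""

    per_sample: pd.DataFrame
    accuracy: float

    @property
    def misclassified(self) -> list[str]:
        bad = self.per_sample[~self.per_sample["correct"]]
        return list(bad["sample_id"])


def loocv(
    matrix: DeltaCtMatrix,
    labels,
    signature,
    *,
    variance_floor: float = 1e-8,
    pooled: bool = True,
) -> LOOCVResult:
    """Leave-one-out cross-validation of the DLDA predictor.

    Each labelled sample is scored by a model refitted on all the others.
    Every fold must retain at least two samples per class, hence at least
    three labelled samples per class overall.
    """
    probes = _signature_probes(signature)
    lab = pd.Series(labels)
    lab = lab[lab.isin([CLASS_RESISTANT, CLASS_SENSITIVE])]
    use = [s for s in matrix.sample_ids if s in lab.index]
    y = lab.loc[use].to_numpy()
    classes, y01 = np.unique(y, return_inverse=True)
    if classes.shape[0] != 2:
        raise ValidationError(f"exactly two classes required, got {list(classes)}")
    counts = np.bincount(y01, minlength=2)
    if counts.min() < 3:
        small = classes[int(np.argmin(counts))]
        raise ValidationError(
            f"class {small!r} has {counts.min()} samples; LOOCV needs >=3 per class "
            "so every fold keeps >=2"
        )
    X = matrix.restrict(probes)[use].T.to_numpy()
    rows = []
    for i, sid in enumerate(use):
        keep = np.ones(len(use), dtype=bool)
        keep[i] = False
        means, variances, _, _ = _class_stats(X[keep], y01[keep], variance_floor, pooled)
        d = X[i][None, :] - means
        scores = -0.5 * (d**2 / variances).sum(axis=1)
        margin = scores[1] - scores[0]
        call = classes[1] if margin > 0 else classes[0]
        rows.append(
            {
                "sample_id": sid,
                "actual": y[i],
                "call": call,
                "margin": float(margin),
                "correct": bool(call == y[i]),
            }
        )
    per_sample = pd.DataFrame(rows)
    return LOOCVResult(per_sample=per_sample, accuracy=float(per_sample["correct"].mean()))
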