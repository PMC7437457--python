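"""ROC/AUC marker evaluation and logistic marker combination.

Single markers are scored by the area under the ROC curve (the Mann–Whitney
probability that a random case outranks a random control, ties credited ½).
Multiple markers are combined by maximum-likelihood logistic regression; the
combined score is the fitted case probability, whose ROC is compared with
the single-marker curves. Coefficient significance is assessed by Wald tests
(the convention of standard statistical packages), with an inclusion
threshold of p < 0.1 checked by :func:`combined_roc`.

AUCs here are apparent (resubstitution) estimates unless ``loo=True`` asks
for leave-one-out probabilities.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn import metrics

logger = logging.getLogger(__name__)


class SeparationError(ValueError):
    """The logistic likelihood is unbounded (perfectly separated classes)."""


class ConvergenceError(RuntimeError):
    """The logistic fit did not converge within the iteration budget."""


@dataclass
class RocResult:
    """AUC plus the full (FPR, TPR) staircase and the scoring orientation."""

    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    orientation: str = "higher-score-is-case"

    @property
    def auc_oriented(self) -> float:
        """Orientation-corrected AUC, max(auc, 1 − auc)."""
        return max(self.auc, 1.0 - self.auc)

    def curve_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr, "threshold": self.thresholds})


@dataclass
class LogisticModel:
    """Maximum-likelihood logistic fit with Wald inference."""

    feature_names: list[str]
    intercept: float
    coefficients: np.ndarray
    wald_z: np.ndarray
    wald_p: np.ndarray
    intercept_p: float
    converged: bool
    n_iter: int
    log_likelihood: float
    fitted_probabilities: np.ndarray

    def predict_probability(self, features) -> np.ndarray:
        x = np.asarray(features, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        eta = self.intercept + x @ self.coefficients
        return 1.0 / (1.0 + np.exp(-eta))

    def coefficient_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coefficient": np.concatenate([[self.intercept], self.coefficients]),
                "wald_z": np.concatenate([[np.nan], self.wald_z]),
                "wald_p": np.concatenate([[self.intercept_p], self.wald_p]),
            },
            index=["(intercept)", *self.feature_names],
        )


def _validate_labels(labels) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    return labels


def auc(scores, labels) -> float:
    """AUC by the Mann–Whitney pair statistic (ties credited ½)."""
    labels = _validate_labels(labels)
    scores = np.asarray(scores, dtype=float)
    return float(metrics.roc_auc_score(labels, scores))


def roc_curve(scores, labels) -> RocResult:
    """Full ROC staircase over all unique score thresholds.

    The trapezoidal area under the returned curve equals :func:`auc` to
    numerical precision.
    """
    labels = _validate_labels(labels)
    scores = np.asarray(scores, dtype=float)
    fpr, tpr, thresholds = metrics.roc_curve(labels, scores, drop_intermediate=False)
    return RocResult(auc=float(metrics.roc_auc_score(labels, scores)),
                     fpr=fpr, tpr=tpr, thresholds=thresholds)


def logistic_fit(features, labels, feature_names=None, tol: float = 1e-8,
                 max_iter: int = 100) -> LogisticModel:
    """Maximum-likelihood logistic regression (Newton/IRLS) with Wald tests.

    Raises :class:`SeparationError` when the classes are perfectly separated
    (unbounded likelihood) and :class:`ConvergenceError` when Newton fails to
    converge within ``max_iter`` iterations. A zero-variance feature leaves
    its direction flat; the fit falls back to L-BFGS with a warning and the
    corresponding Wald entries are undefined.
    """
    labels = _validate_labels(labels)
    x = np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n, m = x.shape
    if feature_names is None:
        feature_names = [f"x{i+1}" for i in range(m)]
    if n <= m + 1:
        raise ValueError(f"need n > m + 1 ({n} samples for {m} features)")
    design = sm.add_constant(x, has_constant="add")
    model = sm.Logit(labels, design)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            result = model.fit(method="newton", tol=tol, maxiter=max_iter, disp=0)
        except np.linalg.LinAlgError:
            warnings.warn("singular Hessian (flat likelihood direction); using L-BFGS")
            result = model.fit(method="lbfgs", maxiter=500, disp=0)
        except Exception as exc:  # statsmodels' PerfectSeparationError
            if "separat" in str(exc).lower() or type(exc).__name__ == "PerfectSeparationError":
                raise SeparationError(f"perfect separation detected: {exc}") from exc
            raise
    for w in caught:
        if "separat" in str(w.message).lower():
            raise SeparationError(f"perfect separation detected: {w.message}")
        warnings.warn_explicit(w.message, w.category, w.filename, w.lineno)
    params = np.asarray(result.params)
    if np.any(np.abs(params) > 50):
        raise SeparationError(
            "diverging coefficients (|beta| > 50) indicate quasi-perfect separation"
        )
    converged = bool(result.mle_retvals.get("converged", True))
    if not converged:
        raise ConvergenceError("logistic fit did not converge")
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.asarray(result.tvalues)
        p = np.asarray(result.pvalues)
    return LogisticModel(
        feature_names=list(feature_names),
        intercept=float(params[0]),
        coefficients=params[1:],
        wald_z=z[1:],
        wald_p=p[1:],
        intercept_p=float(p[0]),
        converged=converged,
        n_iter=int(result.mle_retvals.get("iterations", 0)),
        log_likelihood=float(result.llf),
        fitted_probabilities=np.asarray(result.predict()),
    )


def _independent_columns(x: np.ndarray) -> np.ndarray:
    """Indices of a maximal linearly independent subset of centered columns."""
    centered = x - x.mean(axis=0)
    keep: list[int] = []
    for j in range(x.shape[1]):
        trial = centered[:, keep + [j]]
        if np.linalg.matrix_rank(trial, tol=1e-10) == len(keep) + 1:
            keep.append(j)
    return np.array(keep, dtype=int)


def combined_roc(
    features,
    labels,
    feature_names=None,
    p_threshold: float = 0.1,
    loo: bool = False,
) -> tuple[RocResult, LogisticModel]:
    """Logistic combination of markers and the ROC of the combined score.

    Collinear markers are reduced to an independent subset with a warning;
    coefficients whose Wald p ≥ ``p_threshold`` are reported in a warning
    (the inclusion rule), but the combined ROC is still computed. With
    ``loo=True`` the ROC uses leave-one-out predicted probabilities instead
    of apparent (resubstitution) ones.
    """
    labels = _validate_labels(labels)
    x = np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if feature_names is None:
        feature_names = [f"x{i+1}" for i in range(x.shape[1])]
    keep = _independent_columns(x)
    if keep.size < x.shape[1]:
        dropped = [feature_names[j] for j in range(x.shape[1]) if j not in keep]
        warnings.warn(f"collinear marker(s) dropped from the combination: {dropped}")
        x = x[:, keep]
        feature_names = [feature_names[j] for j in keep]
    model = logistic_fit(x, labels, feature_names=feature_names)
    violators = [
        name for name, p in zip(model.feature_names, model.wald_p)
        if not (p < p_threshold)
    ]
    if violators:
        warnings.warn(
            f"marker coefficient(s) fail the Wald p < {p_threshold} inclusion rule: {violators}"
        )
    if loo:
        probs = np.empty(len(labels))
        idx = np.arange(len(labels))
        for i in idx:
            train = idx != i
            fold = logistic_fit(x[train], labels[train], feature_names=feature_names)
            probs[i] = fold.predict_probability(x[i][None, :])[0]
    else:
        probs = model.fitted_probabilities
    return roc_curve(probs, labels), model


def marker_auc_table(features, labels, feature_names) -> pd.DataFrame:
    """Per-marker raw and orientation-corrected AUCs."""
    x = np.asarray(features, dtype=float)
    rows = []
    for j, name in enumerate(feature_names):
        a = auc(x[:, j], labels)
        rows.append({"marker": name, "auc_raw": a, "auc_oriented": max(a, 1.0 - a)})
    return pd.DataFrame(rows).set_index("marker")
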