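"""Canonical correlation analysis with full sequential inference.

Given two aligned blocks X (n × p, e.g. the CSF triplet Aβ/TAU/PTAU) and
Y (n × q, the selected peripheral biomarkers), CCA finds standardized
coefficient vectors a_i, b_i defining variates U_i = X a_i, V_i = Y b_i that
maximize corr(U_i, V_i) subject to orthogonality with earlier variates. The
implementation whitens the cross-correlation matrix and takes its SVD
(numerically stable, equivalent to the generalized eigenproblem):

    K = R_xx^{-1/2} R_xy R_yy^{-1/2},  K = U Σ Vᵀ,
    r_i = σ_i,  a_i = R_xx^{-1/2} u_i,  b_i = R_yy^{-1/2} v_i.

Reported alongside the correlations: sequential Wilks' Λ_k = Π_{i≥k}(1−r_i²)
with Rao's F approximation and p-values (testing that functions k..s are
jointly null), eigenvalues λ_k = r_k²/(1−r_k²), canonical loadings (variable
vs own variate), cross-loadings (variable vs opposite variate, identically
r_k · loading), and redundancy indices RI_k = r_k² · mean(loading²).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

_RANK_TOL = 1e-10


class CollinearityError(ValueError):
    """A block is rank-deficient after standardization."""


def wilks_sequence(correlations, k: int) -> float:
    """Wilks' Λ_k = Π_{i=k}^{s} (1 − r_i²) for function k (1-based)."""
    r = np.asarray(correlations, dtype=float)
    if not 1 <= k <= r.shape[0]:
        raise ValueError(f"k must lie in 1..{r.shape[0]}")
    return float(np.prod(1.0 - r[k - 1:] ** 2))


def eigenvalue(r_k: float) -> float:
    """λ_k = r_k² / (1 − r_k²), the eigenvalue of canonical function k."""
    if not 0.0 <= r_k < 1.0:
        raise ValueError("canonical correlation must lie in [0, 1) for a finite eigenvalue")
    return float(r_k * r_k / (1.0 - r_k * r_k))


def rao_f(lambda_k: float, p: int, q: int, n: int, k: int) -> tuple[float, float, float, float]:
    """Rao's F approximation for the sequential Wilks test of function k.

    Effective dimensions shrink by k−1 in both blocks: p_k = p−k+1,
    q_k = q−k+1. Returns (F, df1, df2, p-value); Λ = 1 maps to F = 0, p = 1.
    """
    if not 0.0 < lambda_k <= 1.0:
        raise ValueError("Wilks lambda must lie in (0, 1]")
    p_k = p - k + 1
    q_k = q - k + 1
    if p_k <= 0 or q_k <= 0:
        raise ValueError("effective block dimensions must be positive")
    denom = p_k * p_k + q_k * q_k - 5
    if denom <= 0 or p_k * q_k == 2:
        t = 1.0
    else:
        t = np.sqrt((p_k * p_k * q_k * q_k - 4.0) / denom)
    df1 = float(p_k * q_k)
    df2 = t * ((n - 1) - (p_k + q_k + 1) / 2.0) - df1 / 2.0 + 1.0
    if df2 <= 0:
        raise ValueError(f"df2 = {df2:.3g} <= 0: sample size too small for the test")
    lam_root = lambda_k ** (1.0 / t)
    f_stat = ((1.0 - lam_root) / lam_root) * (df2 / df1)
    p_value = float(stats.f.sf(f_stat, df1, df2))
    return float(f_stat), df1, float(df2), p_value


@dataclass
class CanonicalModel:
    """Everything a CCA fit produces, on standardized variables.

    Coefficients are standardized (variates have unit n−1 variance);
    loadings/cross-loadings are Pearson correlations of each original
    variable with its own / the opposite variate; the ``wilks`` frame has one
    row per function (Λ, F, df1, df2, p).
    """

    p: int
    q: int
    n: int
    x_names: list[str]
    y_names: list[str]
    correlations: np.ndarray
    x_coefficients: np.ndarray  # p × s
    y_coefficients: np.ndarray  # q × s
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    x_cross_loadings: np.ndarray
    y_cross_loadings: np.ndarray
    eigenvalues: np.ndarray
    wilks: pd.DataFrame
    x_redundancy: np.ndarray
    y_redundancy: np.ndarray
    x_scores: np.ndarray = field(repr=False)  # n × s variates U
    y_scores: np.ndarray = field(repr=False)  # n × s variates V

    @property
    def n_functions(self) -> int:
        return int(self.correlations.shape[0])

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "correlation": self.correlations,
                "eigenvalue": self.eigenvalues,
                "wilks": self.wilks["wilks"].to_numpy(),
                "F": self.wilks["F"].to_numpy(),
                "df1": self.wilks["df1"].to_numpy(),
                "df2": self.wilks["df2"].to_numpy(),
                "p": self.wilks["p"].to_numpy(),
            },
            index=pd.RangeIndex(1, self.n_functions + 1, name="function"),
        )


def _standardize(block: np.ndarray) -> np.ndarray:
    mean = block.mean(axis=0)
    sd = block.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise CollinearityError(f"constant column(s) at index {np.flatnonzero(sd == 0).tolist()}")
    return (block - mean) / sd


def _inv_sqrt(corr: np.ndarray, names: list[str], ridge: float) -> np.ndarray:
    if ridge:
        corr = corr + ridge * np.eye(corr.shape[0])
        logger.info("applied ridge %.3g to a correlation matrix", ridge)
    vals, vecs = np.linalg.eigh(corr)
    if vals.min() < _RANK_TOL:
        j = int(np.argmin(vals))
        culprit = [names[i] for i in np.argsort(-np.abs(vecs[:, j]))[:3]]
        raise CollinearityError(
            f"block is (near-)rank-deficient; collinear columns likely involve {culprit} "
            f"(min eigenvalue {vals.min():.3g}); pass ridge=1e-8 to proceed"
        )
    return vecs @ np.diag(vals ** -0.5) @ vecs.T


def fit(
    x_block,
    y_block,
    x_names: list[str] | None = None,
    y_names: list[str] | None = None,
    ridge: float = 0.0,
) -> CanonicalModel:
    """Fit CCA between two sample-aligned blocks (rows = samples).

    Requires n > p + q and full column rank in both blocks (a small ridge can
    be requested for near-collinear data). The sign of each canonical
    function is fixed so that the variable with the largest-magnitude loading
    (across both blocks) loads positively, keeping r_k ≥ 0.
    """
    x = np.asarray(x_block, dtype=float)
    y = np.asarray(y_block, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if y.ndim == 1:
        y = y[:, None]
    n, p = x.shape
    n_y, q = y.shape
    if n != n_y:
        raise ValueError("blocks must have the same number of samples")
    if n <= p + q:
        raise ValueError(f"need n > p + q ({n} samples for {p}+{q} variables)")
    x_names = list(x_names) if x_names is not None else [f"X{i+1}" for i in range(p)]
    y_names = list(y_names) if y_names is not None else [f"Y{i+1}" for i in range(q)]

    xs = _standardize(x)
    ys = _standardize(y)
    r_xx = xs.T @ xs / (n - 1)
    r_yy = ys.T @ ys / (n - 1)
    r_xy = xs.T @ ys / (n - 1)

    rxx_isqrt = _inv_sqrt(r_xx, x_names, ridge)
    ryy_isqrt = _inv_sqrt(r_yy, y_names, ridge)
    u, sigma, vt = np.linalg.svd(rxx_isqrt @ r_xy @ ryy_isqrt)
    s = min(p, q)
    correlations = np.clip(sigma[:s], 0.0, 1.0)
    a = rxx_isqrt @ u[:, :s]
    b = ryy_isqrt @ vt[:s].T

    x_load = r_xx @ a
    y_load = r_yy @ b
    # sign convention: dominant |loading| across both blocks is positive
    for k in range(s):
        stacked = np.concatenate([x_load[:, k], y_load[:, k]])
        if stacked[np.argmax(np.abs(stacked))] < 0:
            a[:, k] *= -1
            b[:, k] *= -1
            x_load[:, k] *= -1
            y_load[:, k] *= -1

    x_cross = x_load * correlations
    y_cross = y_load * correlations
    eigenvalues = np.array([eigenvalue(r) if r < 1.0 else np.inf for r in correlations])
    rows = []
    for k in range(1, s + 1):
        lam = wilks_sequence(correlations, k)
        if lam < 1e-300:
            # perfect canonical correlation: the likelihood-ratio test degenerates
            p_k, q_k = p - k + 1, q - k + 1
            rows.append({"wilks": lam, "F": np.inf, "df1": float(p_k * q_k),
                         "df2": np.nan, "p": 0.0})
        else:
            f_stat, df1, df2, p_val = rao_f(lam, p, q, n, k)
            rows.append({"wilks": lam, "F": f_stat, "df1": df1, "df2": df2, "p": p_val})
    wilks = pd.DataFrame(rows, index=pd.RangeIndex(1, s + 1, name="function"))

    return CanonicalModel(
        p=p,
        q=q,
        n=n,
        x_names=x_names,
        y_names=y_names,
        correlations=correlations,
        x_coefficients=a,
        y_coefficients=b,
        x_loadings=x_load,
        y_loadings=y_load,
        x_cross_loadings=x_cross,
        y_cross_loadings=y_cross,
        eigenvalues=eigenvalues,
        wilks=wilks,
        x_redundancy=np.array(
            [redundancy_index_from_parts(correlations[k], x_load[:, k]) for k in range(s)]
        ),
        y_redundancy=np.array(
            [redundancy_index_from_parts(correlations[k], y_load[:, k]) for k in range(s)]
        ),
        x_scores=xs @ a,
        y_scores=ys @ b,
    )


def loadings(model: CanonicalModel, block: str) -> pd.DataFrame:
    """Canonical loadings: correlation of each variable with its own variate."""
    if block == "x":
        values, names = model.x_loadings, model.x_names
    elif block == "y":
        values, names = model.y_loadings, model.y_names
    else:
        raise ValueError("block must be 'x' or 'y'")
    cols = [f"F{k+1}" for k in range(model.n_functions)]
    return pd.DataFrame(values, index=names, columns=cols)


def cross_loadings(model: CanonicalModel, block: str) -> pd.DataFrame:
    """Cross-loadings: correlation of each variable with the opposite variate
    (identically r_k · own-loading)."""
    if block == "x":
        values, names = model.x_cross_loadings, model.x_names
    elif block == "y":
        values, names = model.y_cross_loadings, model.y_names
    else:
        raise ValueError("block must be 'x' or 'y'")
    cols = [f"F{k+1}" for k in range(model.n_functions)]
    return pd.DataFrame(values, index=names, columns=cols)


def redundancy_index_from_parts(r_k: float, block_loadings: np.ndarray) -> float:
    return float(r_k * r_k * np.mean(block_loadings**2))


def redundancy_index(model: CanonicalModel, block: str, k: int) -> float:
    """RI_k: share of a block's variance explained by the opposite variate,
    r_k² × mean squared own-loading (equivalently mean squared cross-loading)."""
    if not 1 <= k <= model.n_functions:
        raise ValueError(f"k must lie in 1..{model.n_functions}")
    if block == "x":
        return float(model.x_redundancy[k - 1])
    if block == "y":
        return float(model.y_redundancy[k - 1])
    raise ValueError("block must be 'x' or 'y'")
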