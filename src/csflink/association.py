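"""Pearson screening of peripheral variables against CSF biomarkers.

Every peripheral variable (immune-cell abundances plus plasma measures) is
correlated with every CSF variable (Aβ, TAU, PTAU); a peripheral variable is
selected when at least one of its CSF correlations is significant at the raw
α = 0.05 level. No multiple-testing correction is applied by default — the
screen reproduces a raw-α selection — but Benjamini–Hochberg adjustment is
available via ``correct="bh"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import BiomarkerBlock

DEFAULT_ALPHA = 0.05


def pearson_r(x, y) -> float:
    """Sample Pearson correlation of two equal-length vectors (n ≥ 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.shape[0] < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson correlation is undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)


def pearson_p(r: float, n: int) -> float:
    """Two-sided p-value of a Pearson correlation under the exact t reference.

    p = 2·P(T_{n−2} > |t|) with t = r·√((n−2)/(1−r²)); |r| = 1 gives p = 0.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if not -1.0 <= r <= 1.0:
        raise ValueError("correlation must lie in [-1, 1]")
    if abs(r) == 1.0:
        return 0.0
    t = abs(r) * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(t, df=n - 2))


@dataclass
class ScreenResult:
    """Full r/p matrices of the peripheral × CSF screen plus the selection."""

    r: pd.DataFrame
    p: pd.DataFrame
    selected: list[str]
    alpha: float

    def to_table(self) -> pd.DataFrame:
        """Wide table with interleaved r/p columns per CSF variable."""
        pieces = {}
        for csf_var in self.r.columns:
            pieces[f"r_{csf_var}"] = self.r[csf_var]
            pieces[f"p_{csf_var}"] = self.p[csf_var]
        return pd.DataFrame(pieces)


def screen(
    peripheral: BiomarkerBlock,
    csf: BiomarkerBlock,
    alpha: float = DEFAULT_ALPHA,
    correct: str | None = None,
) -> ScreenResult:
    """Correlate every peripheral variable with every CSF variable.

    Selection keeps peripheral variables with at least one p < alpha cell
    (after BH adjustment across all pairs when ``correct="bh"``). Constant
    variables yield undefined (NaN) rows/columns and are excluded from
    selection with a warning. Input variable ordering is preserved.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    if peripheral.sample_ids != csf.sample_ids:
        raise ValueError("peripheral and CSF blocks must share aligned samples")
    n = len(peripheral.sample_ids)
    if n < 3:
        raise ValueError("need at least 3 samples")

    per_names = peripheral.variable_names
    csf_names = csf.variable_names
    r = np.full((len(per_names), len(csf_names)), np.nan)
    p = np.full_like(r, np.nan)
    per_const = np.ptp(peripheral.values, axis=0) == 0
    csf_const = np.ptp(csf.values, axis=0) == 0
    for mask, names, kind in (
        (per_const, per_names, "peripheral"),
        (csf_const, csf_names, "CSF"),
    ):
        if mask.any():
            bad = [names[i] for i in np.flatnonzero(mask)]
            warnings.warn(f"constant {kind} variable(s) excluded from screen: {bad}")

    for i in np.flatnonzero(~per_const):
        for j in np.flatnonzero(~csf_const):
            rij = pearson_r(peripheral.values[:, i], csf.values[:, j])
            r[i, j] = rij
            p[i, j] = pearson_p(rij, n)

    p_frame = pd.DataFrame(p, index=per_names, columns=csf_names)
    if correct == "bh":
        from statsmodels.stats.multitest import multipletests

        flat = p_frame.to_numpy().ravel()
        ok = ~np.isnan(flat)
        adj = np.full_like(flat, np.nan)
        adj[ok] = multipletests(flat[ok], method="fdr_bh")[1]
        p_frame = pd.DataFrame(
            adj.reshape(p_frame.shape), index=per_names, columns=csf_names
        )
    elif correct is not None:
        raise ValueError(f"unknown correction {correct!r}")

    selected = [
        name
        for i, name in enumerate(per_names)
        if not per_const[i] and bool((p_frame.iloc[i] < alpha).any())
    ]
    return ScreenResult(
        r=pd.DataFrame(r, index=per_names, columns=csf_names),
        p=p_frame,
        selected=selected,
        alpha=alpha,
    )
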