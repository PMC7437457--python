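"""Synthetic case/control cohorts with planted ground truth.

The generator emulates the structure of a small neuroimaging-initiative
cohort — 36 blood samples (20 late-MCI cases, 16 controls) with bulk
expression, a CSF biomarker triplet (ABETA, TAU, PTAU) and a plasma amyloid
block — while every quantity the pipeline estimates has a known planted
value:

* 28 latent immune-cell abundances (standard normal per sample) drive
  coordinated log-scale expression shifts in disjoint signature gene sets
  (shift = β per SD of abundance), so enrichment scores can be validated
  against the latent truth;
* a single shared latent factor z loads on the CSF triplet and on eight
  "linked" peripheral channels (six cell abundances plus TP40 and the
  FP40/FP42 ratio), with loadings calibrated in closed form so the
  population first canonical correlation between the blocks equals ρ;
* group mean-shifts plant single-marker AUCs: δ on the designated plasma
  marker (AUC = Φ(δ/√2)) and a reduction of the designated cell type's
  abundance in cases.

All randomness flows through one explicit seed; identical (config, seed)
pairs reproduce cohorts bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import special

from . import cca as cca_mod
from .data_io import BiomarkerBlock, Cohort, ExpressionMatrix

#: the 28 immune-cell types whose abundances are simulated and scored
CELL_TYPES: tuple[str, ...] = (
    "Activated B cell",
    "Activated CD4 T cell",
    "Activated CD8 T cell",
    "Central memory CD4 T cell",
    "Central memory CD8 T cell",
    "Effector memory CD4 T cell",
    "Effector memory CD8 T cell",
    "Gamma delta T cell",
    "Immature B cell",
    "Memory B cell",
    "Regulatory T cell",
    "T follicular helper cell",
    "Type 1 T helper cell",
    "Type 17 T helper cell",
    "Type 2 T helper cell",
    "Activated dendritic cell",
    "CD56bright natural killer cell",
    "CD56dim natural killer cell",
    "Eosinophil",
    "Immature dendritic cell",
    "Macrophage",
    "Mast cell",
    "MDSC",
    "Monocyte",
    "Natural killer cell",
    "Natural killer T cell",
    "Neutrophil",
    "Plasmacytoid dendritic cell",
)

#: plasma variables of the peripheral biomarker block
PLASMA_VARS: tuple[str, ...] = ("FP40", "FP42", "TP40", "TP42", "FP40/FP42", "TP40/TP42")

#: cell types whose latent abundances carry the shared CSF factor
DEFAULT_LINKED_CELLS: tuple[str, ...] = (
    "Gamma delta T cell",
    "Immature B cell",
    "Regulatory T cell",
    "T follicular helper cell",
    "Type 1 T helper cell",
    "CD56bright natural killer cell",
)

#: plasma channels carrying the shared factor (with the six linked cells: q = 8)
DEFAULT_LINKED_PLASMA: tuple[str, ...] = ("TP40", "FP40/FP42")

CSF_VARS: tuple[str, ...] = ("ABETA", "TAU", "PTAU")

# location/scale used to put standardized channels on plausible lab units
_CSF_SCALE = {"ABETA": (165.0, 45.0), "TAU": (95.0, 40.0), "PTAU": (35.0, 14.0)}
_RATIO_F_SCALE = (4.5, 0.8)   # plasma Aβ40/Aβ42 free ratio
_TP40_SCALE = (160.0, 30.0)
_FP42_SCALE = (35.0, 8.0)
_TP42_SCALE = (38.0, 9.0)


def _default_delta() -> float:
    # plants the designated marker's single-marker AUC at 0.709
    return float(np.sqrt(2.0) * special.ndtri(0.709))


def _default_cell_shift() -> float:
    # plants the designated cell type's (reduced-in-case) AUC at 0.703
    return float(-np.sqrt(2.0) * special.ndtri(0.703))


@dataclass
class SimulationConfig:
    """Stated world of the simulator; defaults emulate the 36-sample cohort."""

    n_case: int = 20
    n_control: int = 16
    n_genes: int = 49386
    signature_size: int = 30
    beta: float = 1.0                      # log2 expression shift per SD of abundance
    baseline_mean: float = 6.0             # per-gene baseline log2 intensity mean
    baseline_gene_sd: float = 1.5          # spread of per-gene baselines
    noise_sd: float = 1.0                  # per-cell residual expression noise
    rho: float = 0.794                     # planted first canonical correlation
    delta: float = field(default_factory=_default_delta)   # plasma marker group shift
    marker: str = "FP40/FP42"              # designated shifted plasma marker
    cell_shift: float = field(default_factory=_default_cell_shift)
    shifted_cell: str = "Type 1 T helper cell"
    linked_cells: tuple[str, ...] = DEFAULT_LINKED_CELLS
    linked_plasma: tuple[str, ...] = DEFAULT_LINKED_PLASMA

    def validate(self) -> None:
        if self.n_case <= 0 or self.n_control <= 0:
            raise ValueError("both groups need at least one sample")
        if self.n_genes < 28 * self.signature_size:
            raise ValueError("n_genes too small for 28 disjoint signatures")
        if self.signature_size <= 0:
            raise ValueError("signature_size must be positive")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")
        if self.delta < 0:
            raise ValueError("delta must be non-negative")
        if self.rho > 0 and (not self.linked_cells and not self.linked_plasma):
            raise ValueError("cannot plant rho > 0 without linked peripheral channels")
        unknown = set(self.linked_cells) - set(CELL_TYPES)
        if unknown:
            raise ValueError(f"unknown linked cell types: {sorted(unknown)}")
        if self.marker not in PLASMA_VARS:
            raise ValueError(f"designated marker must be one of {PLASMA_VARS}")

    @property
    def n_samples(self) -> int:
        return self.n_case + self.n_control

    @property
    def linked_channels(self) -> tuple[str, ...]:
        return tuple(self.linked_cells) + tuple(self.linked_plasma)


@dataclass
class GroundTruth:
    """Latent quantities the cohort was generated from."""

    abundances: pd.DataFrame          # 28 cell types × samples
    factor_scores: np.ndarray         # shared latent z per sample
    linked_channels: pd.DataFrame     # samples × q standardized linked channels
    rho: float
    delta: float
    marker: str
    signatures: dict[str, list[str]]
    csf_loadings: np.ndarray
    peripheral_loadings: np.ndarray


@dataclass
class SyntheticCohort:
    cohort: Cohort
    truth: GroundTruth
    config: SimulationConfig

    @property
    def labels(self) -> np.ndarray:
        return self.cohort.labels


def calibrate_loadings(rho: float, p: int, q: int) -> tuple[np.ndarray, np.ndarray]:
    """Equal within-block factor loadings planting a population first
    canonical correlation of ρ between a p-block and a q-block.

    With X_j = c z + √(1−c²) e_j the best X-projection achieves
    corr(·, z)² = p c² / (1 + (p−1) c²); splitting ρ evenly gives
    c² = ρ / (p − ρ(p−1)) per block, and the product of the two block
    correlations is ρ.
    """
    if rho == 0.0:
        return np.zeros(p), np.zeros(q)

    def _load(m: int) -> float:
        return float(np.sqrt(rho / (m - rho * (m - 1))))

    return np.full(p, _load(p)), np.full(q, _load(q))


def population_canonical_correlation(c: np.ndarray, d: np.ndarray) -> float:
    """Closed-form population first canonical correlation of the rank-1
    shared-factor model with loadings ``c`` (X block) and ``d`` (Y block)."""
    def _block(v: np.ndarray) -> float:
        g = float(np.sum(v**2 / (1.0 - v**2))) if v.size else 0.0
        return g / (1.0 + g)

    return float(np.sqrt(_block(np.asarray(c)) * _block(np.asarray(d))))


def _factor_channel(rng: np.random.Generator, z: np.ndarray, loading: float) -> np.ndarray:
    noise = rng.standard_normal(z.shape[0])
    return loading * z + np.sqrt(1.0 - loading * loading) * noise


def generate(config: SimulationConfig | None = None, seed: int = 0) -> SyntheticCohort:
    """Generate a cohort; reproducible bit-for-bit given (config, seed)."""
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    n = config.n_samples
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    labels = np.array([1] * config.n_case + [0] * config.n_control)
    group = labels.astype(float)

    # shared latent factor and calibrated loadings
    q_linked = len(config.linked_channels)
    c_load, d_load = calibrate_loadings(config.rho, len(CSF_VARS), q_linked)
    z = rng.standard_normal(n)

    # CSF block: factor channels mapped to lab units
    csf_std = np.column_stack(
        [_factor_channel(rng, z, c_load[j]) for j in range(len(CSF_VARS))]
    )
    csf_values = np.column_stack(
        [_CSF_SCALE[v][0] + _CSF_SCALE[v][1] * csf_std[:, j] for j, v in enumerate(CSF_VARS)]
    )

    # latent cell abundances (28 × n): linked cells carry the factor, the
    # designated cell additionally carries the case/control shift
    d_by_channel = dict(zip(config.linked_channels, d_load))
    abundances = np.empty((len(CELL_TYPES), n))
    for i, cell in enumerate(CELL_TYPES):
        if cell in d_by_channel:
            a = _factor_channel(rng, z, d_by_channel[cell])
        else:
            a = rng.standard_normal(n)
        if cell == config.shifted_cell:
            a = a + config.cell_shift * group
        abundances[i] = a

    # plasma block: standardized latent channels for TP40 and the free ratio,
    # independent noise for FP42/TP42, derived columns for consistency
    tp40_std = _factor_channel(rng, z, d_by_channel.get("TP40", 0.0))
    ratio_f_std = _factor_channel(rng, z, d_by_channel.get("FP40/FP42", 0.0))
    if config.marker == "TP40":
        tp40_std = tp40_std + config.delta * group
    elif config.marker == "FP40/FP42":
        ratio_f_std = ratio_f_std + config.delta * group
    else:
        raise ValueError(f"group shift on {config.marker!r} is not supported")
    fp42 = _FP42_SCALE[0] + _FP42_SCALE[1] * rng.standard_normal(n)
    tp42 = _TP42_SCALE[0] + _TP42_SCALE[1] * rng.standard_normal(n)
    ratio_f = _RATIO_F_SCALE[0] + _RATIO_F_SCALE[1] * ratio_f_std
    tp40 = _TP40_SCALE[0] + _TP40_SCALE[1] * tp40_std
    fp40 = ratio_f * fp42
    plasma = {
        "FP40": fp40,
        "FP42": fp42,
        "TP40": tp40,
        "TP42": tp42,
        "FP40/FP42": fp40 / fp42,
        "TP40/TP42": tp40 / tp42,
    }
    peripheral_values = np.column_stack([plasma[v] for v in PLASMA_VARS])

    # expression: per-gene baselines + noise + β · abundance on signature genes
    gene_ids = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    sig_pool = rng.permutation(config.n_genes)
    signatures: dict[str, list[str]] = {}
    baselines = config.baseline_mean + config.baseline_gene_sd * rng.standard_normal(
        config.n_genes
    )
    expr = baselines[:, None] + config.noise_sd * rng.standard_normal((config.n_genes, n))
    for i, cell in enumerate(CELL_TYPES):
        idx = sig_pool[i * config.signature_size: (i + 1) * config.signature_size]
        signatures[cell] = sorted(gene_ids[g] for g in idx)
        expr[idx] += config.beta * abundances[i]

    # standardized linked channels, for ground-truth CCA checks
    linked_std = {}
    for cell in config.linked_cells:
        linked_std[cell] = abundances[CELL_TYPES.index(cell)]
    if "TP40" in config.linked_plasma:
        linked_std["TP40"] = tp40_std
    if "FP40/FP42" in config.linked_plasma:
        linked_std["FP40/FP42"] = ratio_f_std

    cohort = Cohort(
        expression=ExpressionMatrix(gene_ids, sample_ids, expr),
        csf=BiomarkerBlock(sample_ids, list(CSF_VARS), csf_values),
        peripheral=BiomarkerBlock(sample_ids, list(PLASMA_VARS), peripheral_values),
        labels=labels,
    )
    truth = GroundTruth(
        abundances=pd.DataFrame(abundances, index=list(CELL_TYPES), columns=sample_ids),
        factor_scores=z,
        linked_channels=pd.DataFrame(
            {name: linked_std[name] for name in config.linked_channels}, index=sample_ids
        ),
        rho=config.rho,
        delta=config.delta,
        marker=config.marker,
        signatures=signatures,
        csf_loadings=c_load,
        peripheral_loadings=d_load,
    )
    return SyntheticCohort(cohort=cohort, truth=truth, config=config)


def ground_truth_check(
    sc: SyntheticCohort,
    weight_alpha: float = 0.25,
    score_expression: bool = True,
) -> dict:
    """Diagnostics comparing cohort estimates with planted values.

    Reports the realized first canonical correlation between the CSF block
    and the ground-truth linked peripheral channels, the designated marker's
    sample AUC, and (optionally) per-cell Spearman correlations between
    enrichment scores and the planted abundances.
    """
    from scipy.stats import spearmanr

    from . import classify, gsea

    cohort = sc.cohort
    report: dict = {
        "planted_rho": sc.truth.rho,
        "planted_delta": sc.truth.delta,
        "planted_marker_auc": float(special.ndtr(sc.truth.delta / np.sqrt(2.0))),
    }
    if sc.truth.linked_channels.shape[1] > 0:
        model = cca_mod.fit(
            cohort.csf.values,
            sc.truth.linked_channels.to_numpy(),
            x_names=cohort.csf.variable_names,
            y_names=sc.truth.linked_channels.columns.tolist(),
        )
        report["realized_canonical_correlation"] = float(model.correlations[0])
    report["realized_marker_auc"] = classify.auc(
        cohort.peripheral.variable(sc.truth.marker), cohort.labels
    )
    if score_expression:
        table = gsea.score_cohort(cohort.expression, sc.truth.signatures, weight_alpha)
        corr = {}
        for cell in table.cell_types:
            rho_s = spearmanr(
                table.values[table.cell_types.index(cell)],
                sc.truth.abundances.loc[cell].to_numpy(),
            ).statistic
            corr[cell] = float(rho_s)
        report["abundance_spearman"] = corr
    return report


def config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["linked_cells"] = list(d["linked_cells"])
    d["linked_plasma"] = list(d["linked_plasma"])
    return d
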