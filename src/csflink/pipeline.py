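"""End-to-end orchestration: score → screen → CCA → ROC.

``run`` executes the four analysis stages on a harmonized cohort, persisting
one TSV/JSON artifact per stage under the output directory and returning a
:class:`RunReport`. The peripheral feature matrix offered to the screen is
the 28 immune-cell abundances stacked with the plasma variables; the CCA
y-block is the screened selection; the ROC marker set defaults to screened
variables whose |loading| on the first or second peripheral variate exceeds
a threshold (default 0.29, i.e. "highly contributing" variables).

Reports contain no timestamps and all randomness is seeded, so two runs on
the same inputs are byte-identical.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, association, cca, classify, gsea
from .data_io import BiomarkerBlock, Cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Tunable parameters of the end-to-end run."""

    gsea_alpha: float = gsea.DEFAULT_ALPHA_PER_SAMPLE
    gsea_mode: str = "per-sample"          # or "two-class" (phenotype ranking)
    screen_alpha: float = association.DEFAULT_ALPHA
    loading_threshold: float = 0.29        # |loading| on V1/V2 that makes a ROC marker
    roc_markers: list[str] | None = None   # explicit override of the marker set
    roc_p_threshold: float = 0.1
    cca_ridge: float = 0.0
    seed: int = 0

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        return d


@dataclass
class RunReport:
    """Human-readable per-stage summaries; every number is traceable to an
    artifact file in ``outdir``."""

    version: str
    config: dict
    n_samples: int
    n_case: int
    n_control: int
    stages: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_tsv(frame: pd.DataFrame, path: Path, index_label: str) -> None:
    frame.to_csv(path, sep="\t", index_label=index_label, lineterminator="\n")


def build_peripheral_features(abundance: gsea.AbundanceTable, plasma: BiomarkerBlock) -> BiomarkerBlock:
    """Stack immune-cell abundances (transposed) with the plasma variables."""
    if abundance.sample_ids != plasma.sample_ids:
        raise ValueError("abundance table and plasma block are not sample-aligned")
    values = np.hstack([abundance.values.T, plasma.values])
    names = list(abundance.cell_types) + list(plasma.variable_names)
    return BiomarkerBlock(list(plasma.sample_ids), names, values)


def run(
    cohort: Cohort,
    signatures: dict[str, list[str]] | None = None,
    config: PipelineConfig | None = None,
    outdir=None,
) -> RunReport:
    """Execute the full analysis on a harmonized cohort.

    Stage artifacts (abundance table, screen table, CCA tables, ROC tables)
    are written under ``outdir`` when given. Raises with the stage name on
    stage failure; artifacts of completed stages are retained.
    """
    config = config or PipelineConfig()
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(
        version=__version__,
        config=config.to_dict(),
        n_samples=cohort.n_samples,
        n_case=int(cohort.labels.sum()),
        n_control=int((1 - cohort.labels).sum()),
    )

    # ---- stage 1: immune-cell abundance scoring -------------------------
    try:
        if signatures is None:
            signatures = getattr(cohort, "signatures", None)
        if signatures is None:
            raise ValueError("no signature sets given; pass signatures= or use run_files")
        abundance = gsea.score_cohort(cohort.expression, signatures, config.gsea_alpha)
    except Exception as exc:
        raise RuntimeError(f"stage 'score' failed: {exc}") from exc
    report.stages["score"] = {
        "n_cell_types": len(abundance.cell_types),
        "overlap_counts": abundance.overlap_counts,
        "es_range": [float(abundance.values.min()), float(abundance.values.max())],
    }
    if outdir is not None:
        _write_tsv(abundance.to_frame(), outdir / "abundance.tsv", "cell_type")
        (outdir / "abundance_meta.json").write_text(
            json.dumps(
                {"weight_alpha": config.gsea_alpha, "overlap_counts": abundance.overlap_counts},
                indent=2, sort_keys=True,
            )
        )

    # ---- stage 2: Pearson screen ---------------------------------------
    try:
        peripheral = build_peripheral_features(abundance, cohort.peripheral)
        screen_result = association.screen(peripheral, cohort.csf, alpha=config.screen_alpha)
    except Exception as exc:
        raise RuntimeError(f"stage 'screen' failed: {exc}") from exc
    report.stages["screen"] = {
        "alpha": config.screen_alpha,
        "n_tested": len(peripheral.variable_names),
        "selected": screen_result.selected,
    }
    if outdir is not None:
        _write_tsv(screen_result.to_table(), outdir / "screen.tsv", "variable")
        (outdir / "selected.json").write_text(
            json.dumps(screen_result.selected, indent=2)
        )

    # ---- stage 3: canonical correlation analysis ------------------------
    try:
        selected = list(screen_result.selected)
        if not selected:
            raise ValueError("no peripheral variables passed the screen")
        max_q = cohort.n_samples - cohort.csf.values.shape[1] - 1
        if len(selected) > max_q:
            order = screen_result.p.loc[selected].min(axis=1).sort_values().index
            truncated = [v for v in selected if v not in set(order[:max_q])]
            warnings.warn(
                f"screen selected {len(selected)} variables but n={cohort.n_samples} "
                f"supports at most q={max_q}; keeping the {max_q} smallest p-values "
                f"and dropping {truncated}"
            )
            selected = [v for v in selected if v in set(order[:max_q])]
            report.stages["screen"]["truncated_for_cca"] = truncated
        y_idx = [peripheral.variable_names.index(v) for v in selected]
        model = cca.fit(
            cohort.csf.values,
            peripheral.values[:, y_idx],
            x_names=cohort.csf.variable_names,
            y_names=selected,
            ridge=config.cca_ridge,
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'cca' failed: {exc}") from exc
    report.stages["cca"] = {
        "p": model.p,
        "q": model.q,
        "correlations": model.correlations.tolist(),
        "wilks_p": model.wilks["p"].tolist(),
    }
    if outdir is not None:
        _write_tsv(model.summary_frame(), outdir / "cca_summary.tsv", "function")
        coef = pd.concat(
            [
                pd.DataFrame(model.x_coefficients, index=model.x_names),
                pd.DataFrame(model.y_coefficients, index=model.y_names),
            ]
        )
        coef.columns = [f"F{k+1}" for k in range(model.n_functions)]
        _write_tsv(coef, outdir / "cca_coefficients.tsv", "variable")
        _write_tsv(
            pd.concat([cca.loadings(model, "x"), cca.loadings(model, "y")]),
            outdir / "cca_loadings.tsv", "variable",
        )
        _write_tsv(
            pd.concat([cca.cross_loadings(model, "x"), cca.cross_loadings(model, "y")]),
            outdir / "cca_cross_loadings.tsv", "variable",
        )
        _write_tsv(
            pd.DataFrame(
                {"RI_csf": model.x_redundancy, "RI_peripheral": model.y_redundancy},
                index=pd.RangeIndex(1, model.n_functions + 1, name="function"),
            ),
            outdir / "cca_redundancy.tsv", "function",
        )
        (outdir / "cca.json").write_text(
            json.dumps(
                {
                    "correlations": model.correlations.tolist(),
                    "eigenvalues": model.eigenvalues.tolist(),
                    "wilks": model.wilks.to_dict(orient="list"),
                    "x_names": model.x_names,
                    "y_names": model.y_names,
                    "x_coefficients": model.x_coefficients.tolist(),
                    "y_coefficients": model.y_coefficients.tolist(),
                    "x_loadings": model.x_loadings.tolist(),
                    "y_loadings": model.y_loadings.tolist(),
                    "x_redundancy": model.x_redundancy.tolist(),
                    "y_redundancy": model.y_redundancy.tolist(),
                },
                indent=2, sort_keys=True,
            )
        )

    # ---- stage 4: ROC / logistic combination ----------------------------
    try:
        if config.roc_markers is not None:
            markers = list(config.roc_markers)
        else:
            n_funcs = min(2, model.n_functions)
            load = np.abs(model.y_loadings[:, :n_funcs]).max(axis=1)
            markers = [v for v, w in zip(model.y_names, load) if w >= config.loading_threshold]
            if not markers:
                markers = [model.y_names[int(np.argmax(load))]]
                warnings.warn(
                    "no peripheral variable met the loading threshold; "
                    f"falling back to the top-loading marker {markers[0]!r}"
                )
        marker_idx = [peripheral.variable_names.index(v) for v in markers]
        marker_values = peripheral.values[:, marker_idx]
        auc_table = classify.marker_auc_table(marker_values, cohort.labels, markers)
        combined = None
        logistic = None
        if len(markers) >= 2:
            try:
                roc, logistic = classify.combined_roc(
                    marker_values, cohort.labels,
                    feature_names=markers, p_threshold=config.roc_p_threshold,
                )
                combined = roc
            except (classify.SeparationError, classify.ConvergenceError) as exc:
                warnings.warn(
                    f"combined logistic model skipped ({exc}); "
                    "reporting single-marker AUCs only"
                )
    except Exception as exc:
        raise RuntimeError(f"stage 'roc' failed: {exc}") from exc
    report.stages["roc"] = {
        "markers": markers,
        "auc": {m: float(a) for m, a in auc_table["auc_raw"].items()},
        "auc_oriented": {m: float(a) for m, a in auc_table["auc_oriented"].items()},
    }
    if combined is not None:
        report.stages["roc"]["combined_auc"] = float(combined.auc)
        report.stages["roc"]["logistic_wald_p"] = {
            m: float(p) for m, p in zip(logistic.feature_names, logistic.wald_p)
        }
    if outdir is not None:
        _write_tsv(auc_table, outdir / "roc_auc.tsv", "marker")
        curves = []
        for m, j in zip(markers, range(marker_values.shape[1])):
            frame = classify.roc_curve(marker_values[:, j], cohort.labels).curve_frame()
            frame.insert(0, "marker", m)
            curves.append(frame)
        if combined is not None:
            frame = combined.curve_frame()
            frame.insert(0, "marker", "combined")
            curves.append(frame)
        pd.concat(curves, ignore_index=True).to_csv(
            outdir / "roc_curves.tsv", sep="\t", index=False, lineterminator="\n"
        )
        if logistic is not None:
            _write_tsv(logistic.coefficient_frame(), outdir / "logistic.tsv", "term")
        (outdir / "report.json").write_text(report.to_json())
    return report


def run_files(
    expression_path,
    gmt_path,
    csf_path,
    peripheral_path,
    labels_path,
    config: PipelineConfig | None = None,
    outdir=None,
) -> RunReport:
    """Read the raw input bundle, harmonize, attach signatures, and run."""
    from . import data_io

    expression = data_io.read_expression(expression_path)
    signatures = data_io.read_gmt(gmt_path)
    csf = data_io.read_biomarkers(csf_path)
    peripheral = data_io.read_biomarkers(peripheral_path)
    labels = data_io.read_labels(labels_path)
    cohort = data_io.harmonize(expression, csf, peripheral, labels)
    return run(cohort, signatures=signatures, config=config, outdir=outdir)


def export_gene_lists(cohort: Cohort, signatures: dict[str, list[str]], outdir) -> dict:
    """Write inputs for external differential-expression / network tools.

    Emits ``ranked_genes.tsv`` (all genes with their case-vs-control
    signal-to-noise statistic, descending) and ``signature_overlap.tsv``
    (ranked genes that belong to any signature set, with the set name).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ranked = gsea.rank_two_class(cohort.expression, cohort.labels)
    frame = pd.DataFrame(
        {"gene_id": ranked.gene_ids, "signal_to_noise": ranked.ranking_stats}
    )
    frame.to_csv(outdir / "ranked_genes.tsv", sep="\t", index=False, lineterminator="\n")
    membership: dict[str, str] = {}
    for name, genes in signatures.items():
        for g in genes:
            membership.setdefault(g, name)
    overlap = frame[frame["gene_id"].isin(membership)].copy()
    overlap["signature"] = overlap["gene_id"].map(membership)
    if overlap.empty:
        warnings.warn("no ranked gene belongs to any signature set; overlap file is empty")
    overlap.to_csv(outdir / "signature_overlap.tsv", sep="\t", index=False, lineterminator="\n")
    return {"n_genes": len(frame), "n_overlap": len(overlap)}
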