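"""Readers, writers and cohort harmonization.

Three external sources feed the analysis: a bulk expression matrix
(genes × samples, TSV), immune-cell signature gene sets (GMT), and two
biomarker tables (CSV keyed by ``sample_id``) plus binary diagnosis labels.
``harmonize`` intersects the sample sets, drops samples with missing
biomarker cells (listwise deletion, no imputation), and reorders everything
to one canonical, lexicographically sorted sample order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """A malformed input file (ragged row, non-numeric cell, bad GMT line)."""


def _check_unique(ids, what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dups[:5]}")


@dataclass
class ExpressionMatrix:
    """Genes × samples real matrix with identifiers.

    Values are assumed log-scale normalized upstream; the class only enforces
    structural invariants (unique IDs, matching shapes, finite values).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"value matrix {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene IDs")
        _check_unique(self.sample_ids, "sample IDs")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def column(self, sample_id: str) -> np.ndarray:
        try:
            j = self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}") from None
        return self.values[:, j]

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ExpressionMatrix(list(self.gene_ids), list(sample_ids), self.values[:, idx])


@dataclass
class BiomarkerBlock:
    """Samples × variables biomarker table; NaN marks a missing cell."""

    sample_ids: list[str]
    variable_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.variable_names = [str(v) for v in self.variable_names]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.variable_names)):
            raise ValueError(
                f"value matrix {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variable_names)} variables"
            )
        _check_unique(self.sample_ids, "sample IDs")
        _check_unique(self.variable_names, "variable names")

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.variable_names)

    def subset_samples(self, sample_ids: list[str]) -> "BiomarkerBlock":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return BiomarkerBlock(list(sample_ids), list(self.variable_names), self.values[idx])

    def variable(self, name: str) -> np.ndarray:
        try:
            j = self.variable_names.index(name)
        except ValueError:
            raise KeyError(f"unknown variable {name!r}") from None
        return self.values[:, j]


@dataclass
class Cohort:
    """A harmonized cohort: expression, CSF block, peripheral block, labels.

    All four components share the same sample-ID ordering and carry no
    missing values.
    """

    expression: ExpressionMatrix
    csf: BiomarkerBlock
    peripheral: BiomarkerBlock
    labels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        ids = self.expression.sample_ids
        for block in (self.csf, self.peripheral):
            if block.sample_ids != ids:
                raise ValueError("cohort components have mismatched sample ordering")
        if self.labels.shape != (len(ids),):
            raise ValueError("labels length does not match sample count")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary (case=1, control=0)")
        if np.isnan(self.csf.values).any() or np.isnan(self.peripheral.values).any():
            raise ValueError("harmonized cohort must not contain missing values")

    @property
    def sample_ids(self) -> list[str]:
        return self.expression.sample_ids

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_expression(path) -> ExpressionMatrix:
    """Read a genes-in-rows TSV: header = sample IDs, first column = gene IDs.

    Duplicate gene IDs (e.g. multiple probes per gene) are collapsed by the
    mean of their rows; a warning is logged with the count.
    """
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        sample_ids = header[1:]
        if not sample_ids:
            raise ParseError(f"{path}: header row has no sample IDs")
        width = len(header)
        gene_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != width:
                raise ParseError(
                    f"{path}: line {lineno} has {len(parts)} fields, expected {width}"
                )
            gene_ids.append(parts[0])
            try:
                rows.append([float(x) for x in parts[1:]])
            except ValueError as exc:
                raise ParseError(f"{path}: non-numeric value on line {lineno}: {exc}") from None
    if not rows:
        raise ParseError(f"{path}: no data rows")
    frame = pd.DataFrame(rows, index=gene_ids, columns=sample_ids)
    if frame.index.has_duplicates:
        n_dup = int(frame.index.duplicated().sum())
        logger.warning("collapsing %d duplicate gene rows by mean", n_dup)
        frame = frame.groupby(level=0, sort=False).mean()
    return ExpressionMatrix(frame.index.tolist(), frame.columns.tolist(), frame.to_numpy())


def write_expression(matrix: ExpressionMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="gene_id", lineterminator="\n")


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT file into an ordered name → de-duplicated gene list mapping.

    Lines are ``name<TAB>description<TAB>gene1<TAB>gene2…``; fewer than three
    fields, a duplicate set name, or an effectively empty set is an error.
    """
    sets: dict[str, list[str]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}: line {lineno} has fewer than 3 fields")
            name = parts[0]
            if name in sets:
                raise ParseError(f"{path}: duplicate gene-set name {name!r} on line {lineno}")
            genes = list(dict.fromkeys(g for g in parts[2:] if g))
            if not genes:
                raise ParseError(f"{path}: gene set {name!r} on line {lineno} is empty")
            sets[name] = genes
    if not sets:
        raise ParseError(f"{path}: no gene sets")
    return sets


def write_gmt(sets: dict[str, list[str]], path, descriptions: dict[str, str] | None = None) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name, genes in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_biomarkers(path) -> BiomarkerBlock:
    """Read a biomarker CSV with a ``sample_id`` column; blanks become NaN."""
    frame = pd.read_csv(path)
    if "sample_id" not in frame.columns:
        raise ParseError(f"{path}: missing 'sample_id' column")
    frame = frame.set_index("sample_id")
    try:
        values = frame.to_numpy(dtype=float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric biomarker value: {exc}") from None
    return BiomarkerBlock(frame.index.astype(str).tolist(), frame.columns.tolist(), values)


def write_biomarkers(block: BiomarkerBlock, path) -> None:
    block.to_frame().to_csv(path, index_label="sample_id", lineterminator="\n")


def read_labels(path) -> pd.Series:
    """Read a labels CSV (columns ``sample_id``, ``label``) as a 0/1 Series."""
    frame = pd.read_csv(path)
    for col in ("sample_id", "label"):
        if col not in frame.columns:
            raise ParseError(f"{path}: missing '{col}' column")
    series = frame.set_index("sample_id")["label"].astype(int)
    series.index = series.index.astype(str)
    return series


def write_labels(labels: pd.Series, path) -> None:
    frame = labels.rename("label").rename_axis("sample_id").reset_index()
    frame.to_csv(path, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

def harmonize(
    expression: ExpressionMatrix,
    csf: BiomarkerBlock,
    peripheral: BiomarkerBlock,
    labels: pd.Series | dict,
) -> Cohort:
    """Intersect the three data sources and drop samples with missing cells.

    The retained samples are the intersection of the expression, CSF,
    peripheral and label sample IDs, minus any sample with a missing (NaN)
    biomarker value; components are reordered to lexicographically sorted
    sample IDs. Idempotent by construction.
    """
    labels = pd.Series(labels)
    labels.index = labels.index.astype(str)
    common = (
        set(expression.sample_ids)
        & set(csf.sample_ids)
        & set(peripheral.sample_ids)
        & set(labels.index)
    )
    if not common:
        raise ValueError("no common samples across expression, CSF, peripheral and labels")
    kept = sorted(common)
    dropped_intersection = (
        len(set(expression.sample_ids) | set(csf.sample_ids) | set(peripheral.sample_ids))
        - len(common)
    )
    csf_sub = csf.subset_samples(kept)
    per_sub = peripheral.subset_samples(kept)
    complete = ~(csf_sub.missing_mask.any(axis=1) | per_sub.missing_mask.any(axis=1))
    n_missing = int((~complete).sum())
    if n_missing:
        logger.info("dropping %d samples with missing biomarker cells", n_missing)
        kept = [s for s, ok in zip(kept, complete) if ok]
        if not kept:
            raise ValueError("all common samples have missing biomarker data")
        csf_sub = csf_sub.subset_samples(kept)
        per_sub = per_sub.subset_samples(kept)
    logger.info(
        "harmonized cohort: %d samples kept (%d outside intersection, %d missing-data)",
        len(kept), dropped_intersection, n_missing,
    )
    return Cohort(
        expression=expression.subset_samples(kept),
        csf=csf_sub,
        peripheral=per_sub,
        labels=labels.loc[kept].to_numpy(),
    )
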