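"""Tissue-specific expression matrices and expression-level filters.

Three dataset dialects are supported, mirroring the flavours published by
Expression Atlas:

``rna_tpm``
    RNA-seq abundance in transcripts per million (TPM), non-negative reals.
``protein_ppb``
    Quantitative proteomics abundance in parts per billion, non-negative reals.
``protein_semiquant``
    Semi-quantitative proteomics with three ordinal levels, stored as
    1 (low), 2 (medium), 3 (high).

A gene survives a filter level when its expression *strictly exceeds* the
level's threshold (a value exactly equal to a threshold is filtered out).
Default thresholds are 0.5 / 1 / 5 TPM for RNA-seq and 500 / 1000 / 1500 ppb
for quantitative proteomics.  For the semi-quantitative dialect the ordinal
levels are used directly: the low filter retains levels {2, 3}; the medium
and high filters both retain level {3} (only three levels exist, so the two
stringencies coincide).

Cells left empty in the input TSV are recorded as *not measured*, which is
distinct from an expression of zero: a zero is a measured low value, an empty
cell carries no evidence either way.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Dialect",
    "FilterLevel",
    "FilterThresholds",
    "ExpressionDataset",
    "DEFAULT_THRESHOLDS",
    "SEMIQUANT_WORDS",
    "load_expression_matrix",
    "write_expression_matrix",
    "passes_filter",
    "genes_passing_filter",
    "log_summary",
    "threshold_percentile",
]


class ExpressionLoadError(ValueError):
    """Raised when an expression TSV violates the format contract."""


class Dialect(str, enum.Enum):
    RNA_TPM = "rna_tpm"
    PROTEIN_PPB = "protein_ppb"
    PROTEIN_SEMIQUANT = "protein_semiquant"

    @property
    def numeric(self) -> bool:
        return self is not Dialect.PROTEIN_SEMIQUANT


class FilterLevel(enum.IntEnum):
    """Filter stringency, ordered none < low < medium < high."""

    NONE = 0
    LOW = 1
    MEDIUM = 2
    HIGH = 3

    @classmethod
    def from_name(cls, name: str) -> "FilterLevel":
        try:
            return cls[name.upper()]
        except KeyError:
            raise ValueError(
                f"unknown filter level {name!r}; expected one of "
                f"{[m.name.lower() for m in cls]}"
            ) from None


@dataclass(frozen=True)
class FilterThresholds:
    """Per-dialect expression thresholds; must be strictly increasing."""

    low: float
    medium: float
    high: float

    def __post_init__(self) -> None:
        if not (self.low < self.medium < self.high):
            raise ValueError(
                f"thresholds must satisfy low < medium < high, got "
                f"({self.low}, {self.medium}, {self.high})"
            )

    def for_level(self, level: FilterLevel) -> float:
        if level is FilterLevel.LOW:
            return self.low
        if level is FilterLevel.MEDIUM:
            return self.medium
        if level is FilterLevel.HIGH:
            return self.high
        raise ValueError(f"no threshold for level {level!r}")


DEFAULT_THRESHOLDS: dict[Dialect, FilterThresholds] = {
    Dialect.RNA_TPM: FilterThresholds(0.5, 1.0, 5.0),
    Dialect.PROTEIN_PPB: FilterThresholds(500.0, 1000.0, 1500.0),
}

SEMIQUANT_WORDS = {"low": 1, "medium": 2, "high": 3, "1": 1, "2": 2, "3": 3}

#: ordinal levels retained by each filter level on the 3-level scale
_SEMIQUANT_RETAINED = {
    FilterLevel.LOW: {2, 3},
    FilterLevel.MEDIUM: {3},
    FilterLevel.HIGH: {3},
}


@dataclass
class ExpressionDataset:
    """A tissue x gene expression matrix of one dialect.

    ``values`` is genes (rows) x tissues (columns); NaN marks a cell that was
    not measured.  Semi-quantitative datasets store the ordinal codes 1/2/3.
    """

    dataset_id: str
    dialect: Dialect
    values: pd.DataFrame
    gene_names: dict[str, str] = field(default_factory=dict)
    thresholds: FilterThresholds | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene ids: {dupes}")
        if self.values.columns.has_duplicates:
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate tissue names: {dupes}")
        arr = self.values.to_numpy(dtype=float)
        if self.dialect.numeric:
            if np.nanmin(arr, initial=0.0) < 0:
                raise ValueError("negative expression value in numeric dataset")
        else:
            measured = arr[~np.isnan(arr)]
            if measured.size and not np.isin(measured, [1.0, 2.0, 3.0]).all():
                raise ValueError("semi-quantitative values must be in {1, 2, 3}")
        if self.thresholds is None and self.dialect.numeric:
            self.thresholds = DEFAULT_THRESHOLDS[self.dialect]

    @property
    def tissues(self) -> list[str]:
        return list(self.values.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def gene_count(self) -> int:
        return self.values.shape[0]

    def _tissue_column(self, tissue: str) -> pd.Series:
        if tissue not in self.values.columns:
            raise KeyError(
                f"tissue {tissue!r} not in dataset {self.dataset_id!r}; "
                f"available tissues: {sorted(self.values.columns)}"
            )
        return self.values[tissue]


def load_expression_matrix(
    path: str | Path,
    dialect: Dialect | str,
    dataset_id: str | None = None,
    thresholds: FilterThresholds | None = None,
) -> ExpressionDataset:
    """Load a tissue x gene TSV (`GeneID\\tGeneName\\t<tissue>...`).

    Empty cells are recorded as not measured.  Semi-quantitative cells may be
    the words low/medium/high or the digits 1/2/3.
    """
    path = Path(path)
    dialect = Dialect(dialect)
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if raw.shape[1] < 3:
        raise ExpressionLoadError(
            f"{path}: expected header GeneID<TAB>GeneName<TAB><tissue>..., "
            f"got {list(raw.columns)}"
        )
    gene_ids = raw.iloc[:, 0]
    gene_names = dict(zip(gene_ids, raw.iloc[:, 1]))
    tissue_cols = raw.columns[2:]

    def parse_cell(cell: str, gene: str, tissue: str) -> float:
        cell = cell.strip()
        if cell == "":
            return math.nan
        if dialect is Dialect.PROTEIN_SEMIQUANT:
            key = cell.lower()
            if key not in SEMIQUANT_WORDS:
                raise ExpressionLoadError(
                    f"{path}: unknown expression level {cell!r} at "
                    f"gene {gene!r}, tissue {tissue!r}"
                )
            return float(SEMIQUANT_WORDS[key])
        try:
            value = float(cell)
        except ValueError:
            raise ExpressionLoadError(
                f"{path}: non-numeric value {cell!r} at gene {gene!r}, "
                f"tissue {tissue!r}"
            ) from None
        if value < 0:
            raise ExpressionLoadError(
                f"{path}: negative value {cell!r} at gene {gene!r}, "
                f"tissue {tissue!r}"
            )
        return value

    data = {
        tissue: [
            parse_cell(cell, gene, tissue)
            for gene, cell in zip(gene_ids, raw[tissue])
        ]
        for tissue in tissue_cols
    }
    values = pd.DataFrame(data, index=pd.Index(gene_ids, name="GeneID"))
    return ExpressionDataset(
        dataset_id=dataset_id or path.stem,
        dialect=dialect,
        values=values,
        gene_names=gene_names,
        thresholds=thresholds,
    )


def write_expression_matrix(dataset: ExpressionDataset, path: str | Path) -> Path:
    """Write a dataset back to the TSV layout `load_expression_matrix` reads."""
    path = Path(path)
    out = pd.DataFrame(index=dataset.values.index)
    out.insert(0, "GeneName", [dataset.gene_names.get(g, g) for g in dataset.genes])
    for tissue in dataset.tissues:
        col = dataset.values[tissue]
        if dataset.dialect is Dialect.PROTEIN_SEMIQUANT:
            out[tissue] = ["" if math.isnan(v) else str(int(v)) for v in col]
        else:
            out[tissue] = ["" if math.isnan(v) else repr(float(v)) for v in col]
    out.index.name = "GeneID"
    out.to_csv(path, sep="\t")
    return path


def passes_filter(
    value: float,
    level: FilterLevel,
    thresholds: FilterThresholds | None,
    dialect: Dialect,
) -> bool:
    """Decide whether one measured expression value survives a filter level.

    NaN (not measured) never passes a non-trivial filter here; whether missing
    genes are dropped or kept in an augmented analysis is a policy applied at
    the interaction-filtering step, not per cell.
    """
    level = FilterLevel(level)
    if isinstance(value, float) and math.isnan(value):
        return False  # not measured
    if level is FilterLevel.NONE:
        return True
    if dialect is Dialect.PROTEIN_SEMIQUANT:
        return int(value) in _SEMIQUANT_RETAINED[level]
    if thresholds is None:
        thresholds = DEFAULT_THRESHOLDS[Dialect(dialect)]
    return value > thresholds.for_level(level)


def genes_passing_filter(
    dataset: ExpressionDataset,
    tissue: str,
    level: FilterLevel,
    thresholds: FilterThresholds | None = None,
) -> set[str]:
    """Genes measured in *tissue* whose value survives *level*.

    ``level=none`` returns every measured gene.  Raises ``KeyError`` listing
    the available tissues when *tissue* is unknown.
    """
    level = FilterLevel(level)
    col = dataset._tissue_column(tissue)
    thresholds = thresholds or dataset.thresholds
    measured = col.dropna()
    if level is FilterLevel.NONE:
        return set(measured.index)
    if dataset.dialect is Dialect.PROTEIN_SEMIQUANT:
        keep = measured.astype(int).isin(list(_SEMIQUANT_RETAINED[level]))
    else:
        keep = measured > thresholds.for_level(level)
    return set(measured.index[keep])


def log_summary(
    dataset: ExpressionDataset, pseudocount: float = 0.01
) -> pd.DataFrame:
    """Quartile summary of log10(value + pseudocount), one row per tissue.

    The pseudo-count keeps zeros finite on the log scale; it is used only for
    this summary, never for filtering.
    """
    if not dataset.dialect.numeric:
        raise ValueError(
            "log_summary is undefined for the semi-quantitative dialect"
        )
    rows = []
    for tissue in dataset.tissues:
        vals = dataset.values[tissue].dropna().to_numpy(dtype=float)
        logged = np.log10(vals + pseudocount)
        if logged.size == 0:
            rows.append([tissue, *(math.nan,) * 5, 0])
            continue
        q = np.percentile(logged, [0, 25, 50, 75, 100])
        rows.append([tissue, *q, logged.size])
    return pd.DataFrame(
        rows, columns=["tissue", "min", "q1", "median", "q3", "max", "n_measured"]
    ).set_index("tissue")


def threshold_percentile(
    dataset: ExpressionDataset, tissue: str, threshold: float
) -> float:
    """Percentile (0-100) of measured values in *tissue* that are <= threshold."""
    if not dataset.dialect.numeric:
        raise ValueError(
            "threshold_percentile is undefined for the semi-quantitative dialect"
        )
    vals = dataset._tissue_column(tissue).dropna().to_numpy(dtype=float)
    if vals.size == 0:
        raise ValueError(f"no measured values in tissue {tissue!r}")
    return 100.0 * float((vals <= threshold).sum()) / vals.size
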