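"""Chemical-protein interaction tables (STITCH-flavoured).

Interactions carry an integer confidence score on the 0-1000 STITCH scale;
700 is the conventional "high confidence" cut-off and the default here.
Protein and gene identifiers are assumed to share one namespace; an optional
two-column mapping file translates protein ids to gene ids when they differ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .expression import ExpressionDataset, FilterLevel, genes_passing_filter

__all__ = [
    "InteractionTable",
    "load_interactions",
    "write_interactions",
    "interacting_proteins",
    "filtered_interacting_proteins",
    "DEFAULT_MIN_SCORE",
]

DEFAULT_MIN_SCORE = 700

REQUIRED_COLUMNS = ("chemical", "protein", "combined_score")


@dataclass
class InteractionTable:
    """chemical id -> {protein id -> confidence score in [0, 1000]}."""

    records: dict[str, dict[str, int]] = field(default_factory=dict)

    def add(self, chemical: str, protein: str, score: int) -> None:
        score = int(score)
        if not 0 <= score <= 1000:
            raise ValueError(
                f"confidence score {score} for ({chemical!r}, {protein!r}) "
                "outside [0, 1000]"
            )
        partners = self.records.setdefault(chemical, {})
        # duplicate (chemical, protein) pairs collapse to the max score
        partners[protein] = max(score, partners.get(protein, 0))

    @property
    def chemicals(self) -> list[str]:
        return list(self.records)

    def __len__(self) -> int:
        return sum(len(p) for p in self.records.values())


def load_interactions(
    path: str | Path, id_map: dict[str, str] | None = None
) -> InteractionTable:
    """Load a TSV with columns chemical, protein, combined_score.

    gzip input (``.gz``) is accepted.  ``id_map`` optionally translates
    protein ids into the gene namespace of the expression/annotation data.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    table = InteractionTable()
    for row in df.itertuples(index=False):
        score_txt = str(getattr(row, "combined_score"))
        try:
            score = int(score_txt)
        except ValueError:
            raise ValueError(
                f"{path}: non-integer combined_score {score_txt!r} for "
                f"({row.chemical!r}, {row.protein!r})"
            ) from None
        protein = row.protein
        if id_map is not None:
            protein = id_map.get(protein, protein)
        table.add(row.chemical, protein, score)
    return table


def write_interactions(table: InteractionTable, path: str | Path) -> Path:
    path = Path(path)
    rows = [
        (chem, prot, score)
        for chem in sorted(table.records)
        for prot, score in sorted(table.records[chem].items())
    ]
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )
    return path


def load_id_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV protein_id -> gene_id (header optional)."""
    df = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def interacting_proteins(
    table: InteractionTable, chemical: str, min_score: int = DEFAULT_MIN_SCORE
) -> set[str]:
    """Partners of *chemical* with confidence >= min_score.

    An unknown chemical yields an empty set with a warning rather than an
    error: an absent chemical and a chemical with no confident partners are
    the same situation downstream.
    """
    if not chemical:
        raise ValueError("chemical id must be non-empty")
    if chemical not in table.records:
        warnings.warn(f"chemical {chemical!r} not in interaction table")
        return set()
    return {
        prot
        for prot, score in table.records[chemical].items()
        if score >= min_score
    }


def filtered_interacting_proteins(
    table: InteractionTable,
    chemical: str,
    min_score: int,
    dataset: ExpressionDataset,
    tissue: str,
    level: FilterLevel,
    missing_gene_policy: str = "drop",
) -> set[str]:
    """Interacting partners that also survive the tissue expression filter.

    This is the augmented method's protein set: step 1 partners intersected
    with the genes passing the expression filter in *tissue*.  ``level=none``
    returns the conventional partner set unchanged.  ``missing_gene_policy``
    decides the fate of partners absent from (or not measured in) the
    expression dataset: ``drop`` (default) removes them, ``keep`` retains
    them despite the lack of expression evidence.
    """
    if missing_gene_policy not in ("drop", "keep"):
        raise ValueError(f"unknown missing_gene_policy {missing_gene_policy!r}")
    partners = interacting_proteins(table, chemical, min_score)
    level = FilterLevel(level)
    if level is FilterLevel.NONE:
        return partners
    passing = genes_passing_filter(dataset, tissue, level)
    kept = partners & passing
    if missing_gene_policy == "keep":
        measured = genes_passing_filter(dataset, tissue, FilterLevel.NONE)
        kept |= partners - measured
    return kept
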