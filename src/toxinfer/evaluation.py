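"""Benchmarking inferred chemical-disease associations against curated truth.

Two precision/recall-like rates compare the inferred association set *x*
with the curated set *y*:

    discovery rate  = |x ∩ y| / |y|   (fraction of curated pairs recovered)
    enrichment rate = |x ∩ y| / |x|   (fraction of inferred pairs curated)

Both sets are restricted to tissue-relevant Disease Ontology terms before
the rates are computed, so each tissue is scored against its own disease
vocabulary.  Chemicals for which a rate is undefined (|x| = 0 or |y| = 0)
are excluded from averages rather than scored zero, and the exclusion count
is reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .expression import ExpressionDataset, FilterLevel
from .enrichment import infer_diseases
from .interactions import InteractionTable
from .ontology import AnnotationMap, OntologyGraph, tissue_terms

__all__ = [
    "UndefinedRateError",
    "CuratedAssociations",
    "EvaluationRecord",
    "discovery_rate",
    "enrichment_rate",
    "tissue_relevant_fraction",
    "top_k_tissues",
    "evaluate_disease_inference",
    "evaluate_chemical_identification",
    "load_curated_associations",
]


class UndefinedRateError(ValueError):
    """A rate whose denominator set is empty."""


def discovery_rate(x: set, y: set) -> float:
    """|x ∩ y| / |y| — recall of the curated associations."""
    x, y = set(x), set(y)
    if not y:
        raise UndefinedRateError("discovery rate undefined for empty curated set")
    return len(x & y) / len(y)


def enrichment_rate(x: set, y: set) -> float:
    """|x ∩ y| / |x| — precision of the inferred associations."""
    x, y = set(x), set(y)
    if not x:
        raise UndefinedRateError("enrichment rate undefined for empty inferred set")
    return len(x & y) / len(x)


def tissue_relevant_fraction(
    enriched_terms: Sequence[str], tissue_term_set: set[str]
) -> float:
    """Fraction of enriched terms that belong to a tissue's disease vocabulary."""
    terms = list(enriched_terms)
    if not terms:
        raise UndefinedRateError(
            "tissue-relevant fraction undefined for empty enriched list"
        )
    return sum(t in tissue_term_set for t in terms) / len(terms)


def top_k_tissues(disease_counts: Mapping[str, int], k: int = 5) -> list[str]:
    """The k tissues with the most associated disease terms.

    Tissues with only a few associated terms would make rate estimates
    noisy, so evaluation keeps only the best-annotated tissues.  Ties are
    broken lexicographically by tissue name.
    """
    if k > len(disease_counts):
        raise ValueError(
            f"k={k} exceeds the {len(disease_counts)} available tissues"
        )
    ranked = sorted(disease_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [name for name, _ in ranked[:k]]


@dataclass
class CuratedAssociations:
    """Curated (chemical, DOID) pairs plus per-tissue DOID vocabularies."""

    pairs: set[tuple[str, str]]
    tissue_doids: dict[str, set[str]]

    def pairs_for_tissue(self, tissue: str) -> set[tuple[str, str]]:
        relevant = self.tissue_doids.get(tissue, set())
        return {(c, d) for c, d in self.pairs if d in relevant}

    def tissue_disease_counts(self) -> dict[str, int]:
        curated_doids = {d for _, d in self.pairs}
        return {
            tissue: len(doids & curated_doids)
            for tissue, doids in self.tissue_doids.items()
        }


def load_curated_associations(
    path: str | Path,
    graph: OntologyGraph,
    tissues: Iterable[str],
    match_mode: str = "word",
) -> CuratedAssociations:
    """Read a `chemical<TAB>DOID` TSV and build per-tissue vocabularies.

    Each tissue's DOID vocabulary comes from keyword-matching the tissue
    name against ontology term names and synonyms.  Pairs annotated to
    DOIDs absent from the ontology are dropped with a warning.
    """
    df = pd.read_csv(
        path, sep="\t", dtype=str, header=None, names=["chemical", "doid"],
        comment="#",
    )
    pairs = set()
    dropped = 0
    for row in df.itertuples(index=False):
        if row.doid not in graph.terms:
            dropped += 1
            continue
        pairs.add((row.chemical, row.doid))
    if dropped:
        warnings.warn(f"{dropped} curated pair(s) referenced unknown DOIDs")
    tissue_doids = {
        tissue: tissue_terms(graph, [tissue], mode=match_mode)
        for tissue in tissues
    }
    return CuratedAssociations(pairs=pairs, tissue_doids=tissue_doids)


@dataclass
class EvaluationRecord:
    """One chemical's inferred-vs-curated comparison in one tissue."""

    chemical: str
    tissue: str
    mode: str
    filter_level: str
    x: set[tuple[str, str]]
    y: set[tuple[str, str]]

    @property
    def discovery(self) -> float | None:
        try:
            return discovery_rate(self.x, self.y)
        except UndefinedRateError:
            return None

    @property
    def enrichment(self) -> float | None:
        try:
            return enrichment_rate(self.x, self.y)
        except UndefinedRateError:
            return None


def _infer_tissue_associations(
    chemical: str,
    tissue: str,
    mode: str,
    level: FilterLevel,
    interactions: InteractionTable,
    annotations: AnnotationMap,
    graph: OntologyGraph,
    dataset: ExpressionDataset | None,
    curated: CuratedAssociations,
    min_score: int,
    alpha: float,
    background: str,
    missing_gene_policy: str,
) -> set[tuple[str, str]]:
    report = infer_diseases(
        chemical,
        interactions,
        annotations,
        graph,
        mode=mode,
        min_score=min_score,
        alpha=alpha,
        dataset=dataset,
        tissue=tissue if mode == "augmented" else None,
        level=level if mode == "augmented" else FilterLevel.NONE,
        background=background,
        missing_gene_policy=missing_gene_policy,
    )
    relevant = curated.tissue_doids.get(tissue, set())
    return {(chemical, t) for t in report.enriched_terms if t in relevant}


def _records_for(
    chemicals: Sequence[str],
    tissue: str,
    mode: str,
    level: FilterLevel,
    **kw,
) -> list[EvaluationRecord]:
    curated: CuratedAssociations = kw["curated"]
    y_tissue = curated.pairs_for_tissue(tissue)
    records = []
    for chemical in chemicals:
        x = _infer_tissue_associations(
            chemical, tissue, mode, level, kw["interactions"], kw["annotations"],
            kw["graph"], kw["dataset"], curated, kw["min_score"], kw["alpha"],
            kw["background"], kw["missing_gene_policy"],
        )
        y = {(c, d) for c, d in y_tissue if c == chemical}
        records.append(
            EvaluationRecord(
                chemical=chemical,
                tissue=tissue,
                mode=mode,
                filter_level=level.name.lower() if mode == "augmented" else "none",
                x=x,
                y=y,
            )
        )
    return records


def _mean(values: list[float]) -> float | None:
    return sum(values) / len(values) if values else None


def evaluate_disease_inference(
    chemicals: Sequence[str],
    tissues: Sequence[str],
    levels: Sequence[FilterLevel],
    interactions: InteractionTable,
    annotations: AnnotationMap,
    graph: OntologyGraph,
    dataset: ExpressionDataset,
    curated: CuratedAssociations,
    min_score: int = 700,
    alpha: float = 0.05,
    background: str = "filtered",
    missing_gene_policy: str = "drop",
    improvement: str = "absolute",
) -> pd.DataFrame:
    """Per-chemical rate averages for conventional vs augmented inference.

    Returns a tidy table with one row per (tissue, level, metric): the
    conventional average, the augmented average, the improvement in
    percentage points (or relative % with ``improvement='relative'``), the
    number of chemicals contributing and the number excluded for undefined
    rates.
    """
    if improvement not in ("absolute", "relative"):
        raise ValueError(f"unknown improvement mode {improvement!r}")
    kw = dict(
        interactions=interactions, annotations=annotations, graph=graph,
        dataset=dataset, curated=curated, min_score=min_score, alpha=alpha,
        background=background, missing_gene_policy=missing_gene_policy,
    )
    rows = []
    for tissue in tissues:
        conv = _records_for(chemicals, tissue, "conventional", FilterLevel.NONE, **kw)
        for level in levels:
            aug = _records_for(chemicals, tissue, "augmented", FilterLevel(level), **kw)
            for metric in ("discovery", "enrichment"):
                conv_vals = [getattr(r, metric) for r in conv]
                aug_vals = [getattr(r, metric) for r in aug]
                conv_def = [v for v in conv_vals if v is not None]
                aug_def = [v for v in aug_vals if v is not None]
                conv_mean = _mean(conv_def)
                aug_mean = _mean(aug_def)
                if conv_mean is None and aug_mean is None:
                    warnings.warn(
                        f"no chemical with a defined {metric} rate for "
                        f"tissue {tissue!r}, level {FilterLevel(level).name}"
                    )
                imp = None
                if conv_mean is not None and aug_mean is not None:
                    if improvement == "absolute":
                        imp = (aug_mean - conv_mean) * 100.0
                    elif conv_mean > 0:
                        imp = (aug_mean - conv_mean) / conv_mean * 100.0
                rows.append(
                    {
                        "tissue": tissue,
                        "dataset": dataset.dataset_id,
                        "level": FilterLevel(level).name.lower(),
                        "metric": metric,
                        "conventional": conv_mean,
                        "augmented": aug_mean,
                        "improvement": imp,
                        "n_chemicals": len(aug_def),
                        "n_excluded": len(aug_vals) - len(aug_def),
                    }
                )
    return pd.DataFrame(rows)


def evaluate_chemical_identification(
    chemicals: Sequence[str],
    tissues: Sequence[str],
    levels: Sequence[FilterLevel],
    interactions: InteractionTable,
    annotations: AnnotationMap,
    graph: OntologyGraph,
    dataset: ExpressionDataset,
    curated: CuratedAssociations,
    min_score: int = 700,
    alpha: float = 0.05,
    background: str = "filtered",
    missing_gene_policy: str = "drop",
    improvement: str = "absolute",
) -> pd.DataFrame:
    """Pooled-association rates per tissue.

    Instead of averaging per-chemical rates, the inferred and curated
    (chemical, DOID) pairs are pooled across chemicals within each tissue
    and a single rate pair is computed on the pooled sets — the view that
    asks whether chemicals relevant to a tissue's diseases are identified.
    """
    kw = dict(
        interactions=interactions, annotations=annotations, graph=graph,
        dataset=dataset, curated=curated, min_score=min_score, alpha=alpha,
        background=background, missing_gene_policy=missing_gene_policy,
    )
    rows = []
    for tissue in tissues:
        y_pool = curated.pairs_for_tissue(tissue)
        conv_records = _records_for(chemicals, tissue, "conventional", FilterLevel.NONE, **kw)
        conv_pool = set().union(*(r.x for r in conv_records)) if conv_records else set()
        for level in levels:
            aug_records = _records_for(chemicals, tissue, "augmented", FilterLevel(level), **kw)
            aug_pool = set().union(*(r.x for r in aug_records)) if aug_records else set()
            for metric, fn in (
                ("discovery", discovery_rate),
                ("enrichment", enrichment_rate),
            ):
                def safe(x, y):
                    try:
                        return fn(x, y)
                    except UndefinedRateError:
                        return None
                conv_val = safe(conv_pool, y_pool)
                aug_val = safe(aug_pool, y_pool)
                imp = None
                if conv_val is not None and aug_val is not None:
                    if improvement == "absolute":
                        imp = (aug_val - conv_val) * 100.0
                    elif conv_val > 0:
                        imp = (aug_val - conv_val) / conv_val * 100.0
                rows.append(
                    {
                        "tissue": tissue,
                        "dataset": dataset.dataset_id,
                        "level": FilterLevel(level).name.lower(),
                        "metric": metric,
                        "conventional": conv_val,
                        "augmented": aug_val,
                        "improvement": imp,
                        "n_pairs_inferred": len(aug_pool),
                        "n_pairs_curated": len(y_pool),
                    }
                )
    return pd.DataFrame(rows)
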