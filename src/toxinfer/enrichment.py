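"""Per-term hypergeometric over-representation tests with BH correction.

The inference pipeline has three steps: collect a chemical's interacting
proteins (optionally tissue-filtered), test each Disease Ontology term for
over-representation of those proteins among its annotated genes, and call
terms with Benjamini-Hochberg adjusted p < alpha the inferred diseases.

The background universe is the set of genes carrying at least one
(propagated) annotation.  In augmented mode the universe is tissue-filtered
by default, keeping foreground and background consistent; the unfiltered
global background is available via ``background='unfiltered'``.

Tests are one-sided (over-representation only) and the BH family is the set
of terms tested within one (chemical, mode, tissue, level) run.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionDataset, FilterLevel, genes_passing_filter
from .interactions import (
    InteractionTable,
    filtered_interacting_proteins,
    interacting_proteins,
)
from .ontology import AnnotationMap, OntologyGraph

__all__ = [
    "EnrichmentResult",
    "InferenceReport",
    "hypergeom_upper_tail",
    "bh_adjust",
    "enrich",
    "infer_diseases",
    "report_to_frame",
    "write_report",
]

DEFAULT_ALPHA = 0.05


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N population, K successes, n draws).

    Computed via scipy's survival function, which uses stable
    log-combinatorics internally.
    """
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
    if K > N or n > N:
        raise ValueError(f"require K <= N and n <= N, got K={K}, n={n}, N={N}")
    if k > min(K, n):
        raise ValueError(f"k={k} exceeds min(K, n)={min(K, n)}")
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


@dataclass(frozen=True)
class EnrichmentResult:
    """One term's over-representation test.

    k of the n target genes are annotated to the term, against K of the N
    universe genes; ``genes`` lists the k contributing target genes.
    """

    term: str
    name: str
    k: int
    n: int
    K: int
    N: int
    p_value: float
    adjusted_p: float
    genes: tuple[str, ...]

    @property
    def gene_ratio(self) -> float:
        return self.k / self.n

    @property
    def background_ratio(self) -> float:
        return self.K / self.N


def enrich(
    target_genes: set[str],
    annotations: AnnotationMap,
    graph: OntologyGraph | None = None,
    universe: set[str] | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> list[EnrichmentResult]:
    """Test every term hit by >= 1 target gene for over-representation.

    The universe defaults to all annotated genes; target genes outside the
    universe are intersected away with a warning.  Returns results for all
    tested terms (significant or not) sorted by adjusted p then term id; the
    caller applies the alpha cut.
    """
    if universe is None:
        universe = annotations.genes
    target = set(target_genes)
    stray = target - universe
    if stray:
        warnings.warn(
            f"{len(stray)} target gene(s) outside the annotated universe "
            "were dropped"
        )
        target &= universe
    if not target:
        warnings.warn("empty target gene set; no enrichment performed")
        return []
    term_genes = {
        term: genes & universe
        for term, genes in annotations.terms_to_genes().items()
    }
    N = len(universe)
    n = len(target)
    tested: list[tuple[str, int, int, tuple[str, ...]]] = []
    for term in sorted(term_genes):
        members = term_genes[term]
        hits = target & members
        if not hits:
            continue
        tested.append((term, len(hits), len(members), tuple(sorted(hits))))
    if not tested:
        return []
    p_values = [
        hypergeom_upper_tail(k, K, n, N) for _, k, K, _ in tested
    ]
    adjusted = bh_adjust(p_values)
    names = (graph.names if graph is not None else {})
    results = [
        EnrichmentResult(
            term=term,
            name=names.get(term, term),
            k=k,
            n=n,
            K=K,
            N=N,
            p_value=p,
            adjusted_p=q,
            genes=genes,
        )
        for (term, k, K, genes), p, q in zip(tested, p_values, adjusted)
    ]
    results.sort(key=lambda r: (r.adjusted_p, r.term))
    return results


@dataclass
class InferenceReport:
    """Full record of one conventional or augmented inference run."""

    chemical: str
    mode: str  # "conventional" | "augmented"
    min_score: int
    alpha: float
    results: list[EnrichmentResult]
    tested_count: int
    target_size: int
    universe_size: int
    dataset_id: str | None = None
    tissue: str | None = None
    filter_level: str | None = None
    background: str | None = None
    empty_after_filter: bool = False

    @property
    def enriched(self) -> list[EnrichmentResult]:
        return [r for r in self.results if r.adjusted_p < self.alpha]

    @property
    def enriched_terms(self) -> list[str]:
        return [r.term for r in self.enriched]


def infer_diseases(
    chemical: str,
    interactions: InteractionTable,
    annotations: AnnotationMap,
    graph: OntologyGraph,
    mode: str = "conventional",
    min_score: int = 700,
    alpha: float = DEFAULT_ALPHA,
    dataset: ExpressionDataset | None = None,
    tissue: str | None = None,
    level: FilterLevel = FilterLevel.NONE,
    background: str = "filtered",
    missing_gene_policy: str = "drop",
) -> InferenceReport:
    """Run the conventional or augmented disease-inference workflow.

    Conventional mode enriches over all confident interacting proteins.
    Augmented mode first removes partners whose expression in *tissue* does
    not exceed the *level* threshold of *dataset*; with
    ``background='filtered'`` the universe is restricted the same way.
    """
    if mode not in ("conventional", "augmented"):
        raise ValueError(f"unknown mode {mode!r}")
    if background not in ("filtered", "unfiltered"):
        raise ValueError(f"unknown background mode {background!r}")
    level = FilterLevel(level)
    universe = annotations.genes
    if mode == "conventional":
        target = interacting_proteins(interactions, chemical, min_score)
        dataset_id = tissue_name = level_name = None
    else:
        if dataset is None or tissue is None:
            raise ValueError("augmented mode requires dataset and tissue")
        target = filtered_interacting_proteins(
            interactions,
            chemical,
            min_score,
            dataset,
            tissue,
            level,
            missing_gene_policy=missing_gene_policy,
        )
        if background == "filtered" and level is not FilterLevel.NONE:
            passing = genes_passing_filter(dataset, tissue, level)
            filtered_universe = universe & passing
            if missing_gene_policy == "keep":
                measured = genes_passing_filter(dataset, tissue, FilterLevel.NONE)
                filtered_universe |= universe - measured
            universe = filtered_universe
        dataset_id = dataset.dataset_id
        tissue_name = tissue
        level_name = level.name.lower()
    empty = not target
    results = enrich(target, annotations, graph, universe=universe, alpha=alpha)
    return InferenceReport(
        chemical=chemical,
        mode=mode,
        min_score=min_score,
        alpha=alpha,
        results=results,
        tested_count=len(results),
        target_size=len(target & universe),
        universe_size=len(universe),
        dataset_id=dataset_id,
        tissue=tissue_name,
        filter_level=level_name,
        background=background if mode == "augmented" else None,
        empty_after_filter=empty,
    )


def report_to_frame(report: InferenceReport, enriched_only: bool = True) -> pd.DataFrame:
    """Tidy one-row-per-term table of a report (enriched terms by default)."""
    rows = report.enriched if enriched_only else report.results
    return pd.DataFrame(
        [
            {
                "term": r.term,
                "name": r.name,
                "gene_ratio": f"{r.k}/{r.n}",
                "background_ratio": f"{r.K}/{r.N}",
                "p_value": r.p_value,
                "adjusted_p": r.adjusted_p,
                "genes": ";".join(r.genes),
            }
            for r in rows
        ],
        columns=[
            "term",
            "name",
            "gene_ratio",
            "background_ratio",
            "p_value",
            "adjusted_p",
            "genes",
        ],
    )


def write_report(report: InferenceReport, out_dir: str | Path, stem: str | None = None) -> tuple[Path, Path]:
    """Write the enriched-term TSV and a full-provenance JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = stem or f"{report.chemical}_{report.mode}"
    tsv = out_dir / f"{stem}.tsv"
    report_to_frame(report).to_csv(tsv, sep="\t", index=False)
    payload = {
        "chemical": report.chemical,
        "mode": report.mode,
        "min_score": report.min_score,
        "alpha": report.alpha,
        "dataset_id": report.dataset_id,
        "tissue": report.tissue,
        "filter_level": report.filter_level,
        "background": report.background,
        "target_size": report.target_size,
        "universe_size": report.universe_size,
        "tested_count": report.tested_count,
        "empty_after_filter": report.empty_after_filter,
        "enriched": [asdict(r) | {"genes": list(r.genes)} for r in report.enriched],
    }
    js = out_dir / f"{stem}.json"
    js.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return tsv, js
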