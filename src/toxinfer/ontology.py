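"""Disease Ontology parsing, annotation propagation and tissue-term matching.

Only ``is_a`` edges are traversed; other relationship types (part_of, etc.)
are ignored.  Gene annotations are propagated to all ancestors before
enrichment by default — the true-path rule standard in over-representation
analysis — with a switch to disable propagation.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import obonet
import pandas as pd

__all__ = [
    "OntologyGraph",
    "AnnotationMap",
    "load_obo",
    "ancestors",
    "propagate_annotations",
    "load_annotations",
    "tissue_terms",
    "hierarchy_path",
]

_SYNONYM_RE = re.compile(r'"((?:[^"\\]|\\.)*)"')


@dataclass
class OntologyGraph:
    """Non-obsolete terms with names, exact synonyms and is_a parents."""

    terms: set[str]
    names: dict[str, str]
    synonyms: dict[str, list[str]] = field(default_factory=dict)
    is_a: dict[str, set[str]] = field(default_factory=dict)
    obsolete: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        dg = self.to_networkx()
        if not nx.is_directed_acyclic_graph(dg):
            cycle = nx.find_cycle(dg)
            raise ValueError(f"is_a edges contain a cycle: {cycle}")

    def to_networkx(self) -> nx.DiGraph:
        """Directed graph with child -> parent is_a edges."""
        dg = nx.DiGraph()
        dg.add_nodes_from(self.terms)
        for child, parents in self.is_a.items():
            for parent in parents:
                if child in self.terms and parent in self.terms:
                    dg.add_edge(child, parent)
        return dg

    def parents(self, term: str) -> set[str]:
        return self.is_a.get(term, set()) & self.terms


@dataclass
class AnnotationMap:
    """Gene -> DO-term annotations, direct and ancestor-propagated."""

    direct: dict[str, set[str]]
    propagated: dict[str, set[str]]

    @property
    def genes(self) -> set[str]:
        return {g for g, terms in self.propagated.items() if terms}

    def terms_to_genes(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for gene, terms in self.propagated.items():
            for term in terms:
                out.setdefault(term, set()).add(gene)
        return out


def load_obo(path: str | Path) -> OntologyGraph:
    """Parse an OBO file into an :class:`OntologyGraph`.

    Obsolete terms are recorded but excluded from analysis; a cyclic is_a
    structure is rejected with the offending cycle named.
    """
    graph = obonet.read_obo(Path(path), ignore_obsolete=False)
    terms: set[str] = set()
    names: dict[str, str] = {}
    synonyms: dict[str, list[str]] = {}
    is_a: dict[str, set[str]] = {}
    obsolete: set[str] = set()
    for node, data in graph.nodes(data=True):
        if str(data.get("is_obsolete", "false")).lower() == "true":
            obsolete.add(node)
            continue
        terms.add(node)
        names[node] = data.get("name", node)
        syns = []
        for raw in data.get("synonym", []):
            m = _SYNONYM_RE.match(raw)
            if m:
                syns.append(m.group(1))
        synonyms[node] = syns
    for child, parent, rel in graph.edges(keys=True):
        if rel == "is_a" and child not in obsolete:
            is_a.setdefault(child, set()).add(parent)
    return OntologyGraph(
        terms=terms, names=names, synonyms=synonyms, is_a=is_a, obsolete=obsolete
    )


def ancestors(graph: OntologyGraph, term: str) -> set[str]:
    """Transitive is_a closure of *term*, excluding the term itself."""
    if term not in graph.terms:
        raise KeyError(f"unknown term {term!r}")
    seen: set[str] = set()
    stack = list(graph.parents(term))
    while stack:
        node = stack.pop()
        if node in seen:
            continue
        seen.add(node)
        stack.extend(graph.parents(node))
    return seen


def propagate_annotations(
    graph: OntologyGraph, direct: dict[str, set[str]]
) -> AnnotationMap:
    """Extend each gene's annotations with all ancestors of its direct terms.

    Annotations to unknown or obsolete terms are skipped with a warning.
    Propagation is idempotent: propagating an already-propagated map is a
    no-op.
    """
    clean_direct: dict[str, set[str]] = {}
    propagated: dict[str, set[str]] = {}
    anc_cache: dict[str, set[str]] = {}
    for gene, terms in direct.items():
        kept = set()
        for term in terms:
            if term not in graph.terms:
                warnings.warn(
                    f"annotation of {gene!r} to unknown/obsolete term "
                    f"{term!r} skipped"
                )
                continue
            kept.add(term)
        clean_direct[gene] = kept
        full = set(kept)
        for term in kept:
            if term not in anc_cache:
                anc_cache[term] = ancestors(graph, term)
            full |= anc_cache[term]
        propagated[gene] = full
    return AnnotationMap(direct=clean_direct, propagated=propagated)


def load_annotations(
    path: str | Path, graph: OntologyGraph, propagate: bool = True
) -> AnnotationMap:
    """Read a `gene<TAB>DOID` TSV (no header) into an AnnotationMap."""
    df = pd.read_csv(
        path, sep="\t", dtype=str, header=None, names=["gene", "term"], comment="#"
    )
    direct: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        direct.setdefault(row.gene, set()).add(row.term)
    if propagate:
        return propagate_annotations(graph, direct)
    clean = {
        g: {t for t in terms if t in graph.terms} for g, terms in direct.items()
    }
    return AnnotationMap(direct=clean, propagated={g: set(t) for g, t in clean.items()})


def tissue_terms(
    graph: OntologyGraph, keywords: list[str], mode: str = "word"
) -> set[str]:
    """Terms whose name or any exact synonym matches any keyword.

    ``mode='word'`` (default) requires a case-insensitive whole-word match;
    ``mode='substring'`` accepts any case-insensitive substring occurrence,
    matching the behaviour of a plain website search box.
    """
    if not keywords:
        raise ValueError("keyword list must be non-empty")
    if mode not in ("word", "substring"):
        raise ValueError(f"unknown match mode {mode!r}")
    if mode == "word":
        patterns = [
            re.compile(r"\b" + re.escape(kw) + r"\b", re.IGNORECASE)
            for kw in keywords
        ]
        def hit(text: str) -> bool:
            return any(p.search(text) for p in patterns)
    else:
        lowered = [kw.lower() for kw in keywords]
        def hit(text: str) -> bool:
            low = text.lower()
            return any(kw in low for kw in lowered)
    out = set()
    for term in graph.terms:
        texts = [graph.names.get(term, "")] + graph.synonyms.get(term, [])
        if any(hit(t) for t in texts):
            out.add(term)
    return out


def hierarchy_path(
    graph: OntologyGraph, term: str, enriched: set[str] | None = None
) -> nx.DiGraph:
    """Induced subgraph of *term* plus all its ancestors.

    Each node carries ``name`` and an ``enriched`` flag marking whether it
    appears in the supplied enriched-term set — the shape used to report
    whether a method recovered a full disease hierarchy or only part of it.
    """
    nodes = {term} | ancestors(graph, term)
    enriched = enriched or set()
    sub = nx.DiGraph()
    for node in nodes:
        sub.add_node(
            node, name=graph.names.get(node, node), enriched=node in enriched
        )
    for child in nodes:
        for parent in graph.parents(child):
            if parent in nodes:
                sub.add_edge(child, parent)
    return sub
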