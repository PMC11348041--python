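"""Synthetic input bundles with planted tissue-specific disease signal.

Every loader in the package can be exercised without any database download:
:func:`generate_bundle` builds an internally consistent set of

* a random Disease Ontology-like DAG whose terms are organised into one
  branch per tissue (term names embed the tissue keyword, so keyword
  matching recovers each branch as that tissue's disease vocabulary),
* gene -> term annotations,
* a tissue x gene expression matrix in any of the three dialects,
* a chemical-protein interaction table, and
* a curated chemical-disease truth table,

all driven by one seeded random stream.

The planted mechanism mirrors the augmented method's rationale.  For each
planted (chemical, term, tissue) triple the chemical interacts with

* **signal** genes annotated to the planted term and highly expressed in the
  tissue (above the high threshold) — the true, tissue-expressed mechanism;
* a few signal genes annotated to the planted term but *not* expressed in
  the tissue, plus a **sacrificial** curated term whose supporting
  interactors are all low-expressed — true associations the expression
  filter sacrifices, so the discovery rate cannot improve under filtering;
* **decoy** genes annotated to other same-tissue terms but expressed at or
  below the low threshold in that tissue — false leads that the low filter
  removes, sharpening the enrichment signal.

Conventional inference therefore enriches the decoy terms alongside the
truth (low precision), while augmented inference drops the decoys but also
loses the unexpressed true associations (higher precision, no recall gain).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .expression import (
    DEFAULT_THRESHOLDS,
    Dialect,
    ExpressionDataset,
    FilterThresholds,
    load_expression_matrix,
    write_expression_matrix,
)
from .interactions import InteractionTable, load_interactions, write_interactions
from .ontology import (
    AnnotationMap,
    OntologyGraph,
    ancestors,
    load_annotations,
    load_obo,
    propagate_annotations,
)
from .evaluation import CuratedAssociations, load_curated_associations

__all__ = ["FixtureConfig", "FixtureBundle", "generate_bundle", "write_bundle", "load_bundle"]

DEFAULT_TISSUES = ["kidney", "brain", "liver", "heart", "lung", "skin"]


@dataclass
class FixtureConfig:
    """Knobs of the synthetic study; defaults define the benchmark conditions."""

    seed: int = 0
    n_genes: int = 500
    n_chemicals: int = 10
    n_terms: int = 50
    n_tissues: int = 4
    ontology_depth: int = 4
    frac_tissue_specific: float = 0.3
    #: planted (chemical, term, tissue) triples; None = one per chemical,
    #: cycling through the tissues, planted terms chosen per branch
    planted: list[tuple[str, str, str]] | None = None
    n_signal: int = 8
    n_signal_unexpressed: int = 2
    n_sacrificial: int = 5
    n_decoy_terms: int = 3
    genes_per_decoy: int = 6
    noise_interaction_rate: float = 0.01
    missing_rate: float = 0.02
    #: natural-log mean/sd of the background expression distribution
    #: (mu = -1, sigma = 2 puts the 0.5 / 1 / 5 TPM thresholds near the
    #: 56th / 69th / 90th percentile of background values)
    mu: float = -1.0
    sigma: float = 2.0
    specific_shift: float = 200.0
    dialect: Dialect = Dialect.RNA_TPM
    dataset_id: str = "SIM-RNA-1"

    def __post_init__(self) -> None:
        self.dialect = Dialect(self.dialect)
        for name in ("frac_tissue_specific", "noise_interaction_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_tissues > len(DEFAULT_TISSUES):
            raise ValueError(
                f"n_tissues <= {len(DEFAULT_TISSUES)} supported by the "
                "built-in tissue keyword list"
            )
        if self.n_signal_unexpressed >= self.n_signal:
            raise ValueError("n_signal_unexpressed must be < n_signal")

    @property
    def tissues(self) -> list[str]:
        return DEFAULT_TISSUES[: self.n_tissues]

    @property
    def thresholds(self) -> FilterThresholds:
        if self.dialect is Dialect.PROTEIN_SEMIQUANT:
            return FilterThresholds(1.0, 2.0, 3.0)  # nominal; levels used directly
        return DEFAULT_THRESHOLDS[self.dialect]


@dataclass
class FixtureBundle:
    config: FixtureConfig
    graph: OntologyGraph
    annotations: AnnotationMap
    direct_annotations: dict[str, set[str]]
    expression: ExpressionDataset
    interactions: InteractionTable
    curated: CuratedAssociations
    planted: list[tuple[str, str, str]]
    branch_terms: dict[str, list[str]]

    @property
    def chemicals(self) -> list[str]:
        return [f"CID{i:05d}" for i in range(self.config.n_chemicals)]


def _build_ontology(cfg: FixtureConfig, rng: np.random.Generator):
    """Random per-tissue branches under one root; extra edges keep a DAG."""
    root = "DOID:0000001"
    names = {root: "disease"}
    is_a: dict[str, set[str]] = {}
    branch_terms: dict[str, list[str]] = {}
    depths = {root: 0}
    n_branch = cfg.n_terms - 1
    per_branch = [n_branch // cfg.n_tissues] * cfg.n_tissues
    for i in range(n_branch % cfg.n_tissues):
        per_branch[i] += 1
    term_no = 1  # root is DOID:0000001
    for t_idx, tissue in enumerate(cfg.tissues):
        branch: list[str] = []
        for j in range(per_branch[t_idx]):
            term_no += 1
            term = f"DOID:{term_no:07d}"
            if j == 0:
                parent = root
                names[term] = f"{tissue} disease"
            else:
                candidates = [b for b in branch if depths[b] < cfg.ontology_depth]
                parent = candidates[rng.integers(len(candidates))] if candidates else branch[0]
                names[term] = f"{tissue} disease {j}"
            is_a[term] = {parent}
            depths[term] = depths[parent] + 1
            # occasional second parent earlier in the branch keeps it a DAG
            if j > 1 and rng.random() < 0.2:
                extra = branch[rng.integers(len(branch))]
                if extra != parent:
                    is_a[term].add(extra)
            branch.append(term)
        branch_terms[tissue] = branch
    graph = OntologyGraph(
        terms=set(names), names=names, synonyms={t: [] for t in names}, is_a=is_a
    )
    return graph, branch_terms, depths


def generate_bundle(config: FixtureConfig | None = None) -> FixtureBundle:
    """Build a complete, internally consistent synthetic input bundle."""
    cfg = config or FixtureConfig()
    rng = np.random.default_rng(cfg.seed)
    graph, branch_terms, depths = _build_ontology(cfg, rng)
    tissues = cfg.tissues
    chemicals = [f"CID{i:05d}" for i in range(cfg.n_chemicals)]
    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]

    # --- role terms per branch: planted (deepest), sacrificial, shared decoys
    chems_per_tissue: dict[str, list[str]] = {t: [] for t in tissues}
    for i, chem in enumerate(chemicals):
        chems_per_tissue[tissues[i % len(tissues)]].append(chem)
    planted_cfg = cfg.planted
    planted: list[tuple[str, str, str]] = []
    sacrificial_term: dict[tuple[str, str], str] = {}
    decoy_terms: dict[str, list[str]] = {}
    for tissue in tissues:
        branch = branch_terms[tissue]
        by_depth = sorted(branch[1:], key=lambda t: (-depths[t], t))
        n_chem = len(chems_per_tissue[tissue])
        need = 2 * n_chem + cfg.n_decoy_terms
        if len(by_depth) < need:
            raise ValueError(
                f"branch for {tissue!r} has {len(by_depth)} assignable terms "
                f"but the planted design needs {need}; increase n_terms or "
                "reduce n_chemicals/n_decoy_terms"
            )
        p_terms = by_depth[:n_chem]
        s_terms = by_depth[n_chem: 2 * n_chem]
        decoy_terms[tissue] = by_depth[2 * n_chem: 2 * n_chem + cfg.n_decoy_terms]
        for chem, pt, st in zip(chems_per_tissue[tissue], p_terms, s_terms):
            planted.append((chem, pt, tissue))
            sacrificial_term[(chem, tissue)] = st
    if planted_cfg is not None:
        known = {(c, t, s) for c, t, s in planted}
        for triple in planted_cfg:
            chem, term, tissue = triple
            if chem not in chemicals or term not in graph.terms or tissue not in tissues:
                raise ValueError(f"inconsistent planted triple {triple!r}")
        planted = list(planted_cfg)

    # --- allocate special gene blocks per planted triple
    per_triple = cfg.n_signal + cfg.n_sacrificial + cfg.n_decoy_terms * cfg.genes_per_decoy
    n_special = per_triple * len(planted)
    if n_special > cfg.n_genes:
        raise ValueError(
            f"planted design needs {n_special} genes but n_genes={cfg.n_genes}"
        )
    direct: dict[str, set[str]] = {g: set() for g in genes}
    #: (gene, tissue) -> "high" | "low" expression constraints
    forced: dict[tuple[str, str], str] = {}
    interactions = InteractionTable()
    cursor = 0

    def take(n: int) -> list[str]:
        nonlocal cursor
        block = genes[cursor: cursor + n]
        cursor += n
        return block

    def score() -> int:
        return int(rng.integers(750, 1000))

    for chem, term, tissue in planted:
        signal = take(cfg.n_signal)
        for idx, g in enumerate(signal):
            direct[g].add(term)
            forced[(g, tissue)] = (
                "low" if idx < cfg.n_signal_unexpressed else "high"
            )
            interactions.add(chem, g, score())
        sac_term = sacrificial_term.get((chem, tissue))
        if sac_term is not None:
            for g in take(cfg.n_sacrificial):
                direct[g].add(sac_term)
                forced[(g, tissue)] = "low"
                interactions.add(chem, g, score())
        for d_term in decoy_terms[tissue]:
            for g in take(cfg.genes_per_decoy):
                direct[g].add(d_term)
                forced[(g, tissue)] = "low"
                interactions.add(chem, g, score())

    # --- background genes: random annotations, optional home tissue
    background = genes[cursor:]
    all_terms = sorted(graph.terms - {"DOID:0000001"})
    home_tissue: dict[str, str] = {}
    for g in background:
        n_ann = int(rng.integers(1, 3))
        for t in rng.choice(all_terms, size=n_ann, replace=False):
            direct[g].add(str(t))
        if rng.random() < cfg.frac_tissue_specific:
            home_tissue[g] = tissues[int(rng.integers(len(tissues)))]
    # noise interactions (scores span the whole confidence range)
    for chem in chemicals:
        hits = np.flatnonzero(rng.random(len(background)) < cfg.noise_interaction_rate)
        for i in hits:
            interactions.add(chem, background[i], int(rng.integers(150, 1000)))

    # --- expression matrix
    th = cfg.thresholds
    values = np.empty((cfg.n_genes, len(tissues)))
    if cfg.dialect is Dialect.PROTEIN_SEMIQUANT:
        values = rng.choice([1.0, 2.0, 3.0], size=values.shape, p=[0.45, 0.3, 0.25])
    else:
        mu = cfg.mu if cfg.dialect is Dialect.RNA_TPM else float(np.log(700.0))
        values = rng.lognormal(mean=mu, sigma=cfg.sigma, size=values.shape)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for j, tissue in enumerate(tissues):
        for g, home in home_tissue.items():
            if home == tissue:
                forced.setdefault((g, tissue), "high")
    for (g, tissue), kind in forced.items():
        i, j = gene_pos[g], tissues.index(tissue)
        if cfg.dialect is Dialect.PROTEIN_SEMIQUANT:
            values[i, j] = 3.0 if kind == "high" else 1.0
        elif kind == "high":
            shifted = values[i, j] * cfg.specific_shift
            values[i, j] = max(shifted, th.high * 1.2)
        else:
            values[i, j] = float(rng.uniform(0.0, 0.8 * th.low))
    expr = pd.DataFrame(values, index=pd.Index(genes, name="GeneID"), columns=tissues)
    if cfg.missing_rate > 0 and cfg.dialect is not Dialect.PROTEIN_SEMIQUANT:
        mask = rng.random(values.shape) < cfg.missing_rate
        for (g, tissue) in forced:
            mask[gene_pos[g], tissues.index(tissue)] = False
        expr = expr.mask(mask)
    dataset = ExpressionDataset(
        dataset_id=cfg.dataset_id,
        dialect=cfg.dialect,
        values=expr,
        gene_names={g: f"gene_{g}" for g in genes},
    )

    # --- curated truth: planted term + its in-branch ancestors + sacrificial
    pairs: set[tuple[str, str]] = set()
    for chem, term, tissue in planted:
        branch = set(branch_terms[tissue])
        pairs.add((chem, term))
        pairs |= {(chem, a) for a in ancestors(graph, term) & branch}
        sac = sacrificial_term.get((chem, tissue))
        if sac is not None:
            pairs.add((chem, sac))
    tissue_doids = {t: set(branch_terms[t]) for t in tissues}
    curated = CuratedAssociations(pairs=pairs, tissue_doids=tissue_doids)

    annotations = propagate_annotations(graph, direct)
    return FixtureBundle(
        config=cfg,
        graph=graph,
        annotations=annotations,
        direct_annotations=direct,
        expression=dataset,
        interactions=interactions,
        curated=curated,
        planted=planted,
        branch_terms=branch_terms,
    )


def _write_obo(graph: OntologyGraph, path: Path) -> None:
    lines = ["format-version: 1.2", ""]
    for term in sorted(graph.terms):
        lines += ["[Term]", f"id: {term}", f"name: {graph.names[term]}"]
        for syn in graph.synonyms.get(term, []):
            lines.append(f'synonym: "{syn}" EXACT []')
        for parent in sorted(graph.is_a.get(term, set())):
            lines.append(f"is_a: {parent} ! {graph.names.get(parent, parent)}")
        lines.append("")
    path.write_text("\n".join(lines))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_bundle(bundle: FixtureBundle, directory: str | Path) -> Path:
    """Emit the bundle in the on-disk formats the loader modules consume.

    Returns the path of ``manifest.yaml``, which records the generating
    config, the seed and a sha256 checksum per file, so regeneration can be
    verified byte-for-byte.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    files["interactions"] = write_interactions(
        bundle.interactions, directory / "interactions.tsv"
    )
    obo = directory / "ontology.obo"
    _write_obo(bundle.graph, obo)
    files["ontology"] = obo
    ann = directory / "annotations.tsv"
    rows = [
        (g, t)
        for g in sorted(bundle.direct_annotations)
        for t in sorted(bundle.direct_annotations[g])
    ]
    pd.DataFrame(rows).to_csv(ann, sep="\t", index=False, header=False)
    files["annotations"] = ann
    files["expression"] = write_expression_matrix(
        bundle.expression, directory / "expression.tsv"
    )
    cur = directory / "curated.tsv"
    pd.DataFrame(sorted(bundle.curated.pairs)).to_csv(
        cur, sep="\t", index=False, header=False
    )
    files["curated"] = cur
    cfg = asdict(bundle.config)
    cfg["dialect"] = bundle.config.dialect.value
    if cfg.get("planted") is not None:
        cfg["planted"] = [list(p) for p in cfg["planted"]]
    manifest = {
        "config": cfg,
        "seed": bundle.config.seed,
        "dataset_id": bundle.config.dataset_id,
        "tissues": bundle.config.tissues,
        "chemicals": bundle.chemicals,
        "planted": [list(p) for p in bundle.planted],
        "files": {k: p.name for k, p in files.items()},
        "checksums": {p.name: _sha256(p) for p in files.values()},
    }
    manifest_path = directory / "manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=True))
    return manifest_path


def load_bundle(directory: str | Path) -> FixtureBundle:
    """Round-trip a written bundle through the ordinary loader modules."""
    directory = Path(directory)
    manifest = yaml.safe_load((directory / "manifest.yaml").read_text())
    cfg_d = dict(manifest["config"])
    cfg_d["planted"] = (
        [tuple(p) for p in cfg_d["planted"]] if cfg_d.get("planted") else None
    )
    cfg = FixtureConfig(**cfg_d)
    graph = load_obo(directory / manifest["files"]["ontology"])
    annotations = load_annotations(
        directory / manifest["files"]["annotations"], graph, propagate=True
    )
    direct = {g: set(t) for g, t in annotations.direct.items()}
    expression = load_expression_matrix(
        directory / manifest["files"]["expression"],
        cfg.dialect,
        dataset_id=manifest["dataset_id"],
    )
    interactions = load_interactions(directory / manifest["files"]["interactions"])
    curated = load_curated_associations(
        directory / manifest["files"]["curated"], graph, manifest["tissues"]
    )
    branch_terms = {
        t: sorted(tt) for t, tt in (
            (tissue, curated.tissue_doids[tissue]) for tissue in manifest["tissues"]
        )
    }
    return FixtureBundle(
        config=cfg,
        graph=graph,
        annotations=annotations,
        direct_annotations=direct,
        expression=expression,
        interactions=interactions,
        curated=curated,
        planted=[tuple(p) for p in manifest["planted"]],
        branch_terms=branch_terms,
    )
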