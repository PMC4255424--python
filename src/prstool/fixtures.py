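"""Synthetic KGML pathways and expression data with controlled signal.

The generators make the whole pipeline testable offline: KGML files with
known topology (chains, cycles, random digraphs, metabolic reaction chains)
and a simulated RMA-style expression table where a chosen pathway can be
given a planted differential-expression signal.

What the simulation emulates: log2-scale normalized intensities with
per-gene baselines in the typical RMA range (uniform in [4, 12]), i.i.d.
Gaussian replicate noise, one or two probes per gene, and a shift of
``log2(planted_fc)`` added to the test-group mean of planted genes.  What it
does not emulate: probe-level hybridisation artefacts, intensity-dependent
variance, correlated genes, or real KEGG pathway size distributions.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .kgml_io import (
    KgmlEntry,
    KgmlRelation,
    KgmlReaction,
    PathwayDefinition,
    write_kgml,
)

TOPOLOGIES = ("chain", "cycle", "random_dag", "random_digraph", "metabolic_chain")


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic workspace."""

    n_pathways: int = 30
    nodes_per_pathway: tuple[int, int] = (6, 12)
    topology: str = "random_digraph"
    edge_density: float = 0.3
    planted_pathway_index: int | None = None
    planted_fraction: float = 0.8
    planted_fc: float = 2.0
    n_control: int = 5
    n_test: int = 5
    noise_sd: float = 0.25
    n_background_genes: int = 150
    probes_per_gene: tuple[int, int] = (1, 2)
    unmapped_fraction: float = 0.05
    organism_code: str = "hsa"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"unknown topology {self.topology!r}")
        if not (0.0 <= self.planted_fraction <= 1.0):
            raise ValueError("planted_fraction must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class FixtureSet:
    """Everything the generator produced for one workspace."""

    definitions: list[PathwayDefinition]
    gene_sets: dict[str, list[str]]  #: pathway id -> member genes
    planted_pathway_id: str | None = None
    paths: list[Path] = field(default_factory=list)


def _gene_entries(genes: list[str], org: str) -> list[KgmlEntry]:
    return [
        KgmlEntry(
            entry_id=f"e{i + 1}",
            entry_type="gene",
            gene_ids=(g,),
            raw_names=(f"{org}:{g}",),
            display_name=f"GENE{g}",
        )
        for i, g in enumerate(genes)
    ]


def signalling_definition(
    pathway_id: str,
    genes: list[str],
    edges: list[tuple[int, int]],
    *,
    org: str = "hsa",
    title: str = "",
) -> PathwayDefinition:
    """Signalling pathway over ``genes`` with edges given as index pairs."""
    entries = _gene_entries(genes, org)
    relations = [
        KgmlRelation(f"e{a + 1}", f"e{b + 1}", "PPrel", ("activation",))
        for a, b in edges
    ]
    return PathwayDefinition(
        kegg_id=pathway_id,
        title=title or f"Synthetic signalling pathway {pathway_id}",
        organism_code=org,
        entries=entries,
        relations=relations,
    )


def metabolic_chain_definition(
    pathway_id: str, genes: list[str], *, org: str = "hsa", title: str = ""
) -> PathwayDefinition:
    """Metabolic chain C1 -E1-> C2 -E2-> C3 ... with one enzyme per step.

    The product/substrate overlap between consecutive reactions encodes the
    chain E1 -> E2 -> ... in the derived graph.
    """
    entries = []
    reactions = []
    for i, g in enumerate(genes):
        rname = f"rn:R{i + 1:05d}"
        entries.append(
            KgmlEntry(
                entry_id=f"e{i + 1}",
                entry_type="gene",
                gene_ids=(g,),
                raw_names=(f"{org}:{g}",),
                display_name=f"ENZ{g}",
                reaction_names=(rname,),
            )
        )
        reactions.append(
            KgmlReaction(
                reaction_name=rname,
                enzyme_entry_ids=(f"e{i + 1}",),
                substrate_ids=(f"C{i + 1:05d}",),
                product_ids=(f"C{i + 2:05d}",),
                reversible=False,
            )
        )
    return PathwayDefinition(
        kegg_id=pathway_id,
        title=title or f"Synthetic metabolic pathway {pathway_id}",
        organism_code=org,
        entries=entries,
        reactions=reactions,
    )


def duplicate_gene_definition(
    pathway_id: str = "hsa99001", *, org: str = "hsa"
) -> PathwayDefinition:
    """Signalling pathway that draws one gene in two separate entries.

    Genes 9101/9102/9103; gene 9102 appears as entries e2 and e4 with edges
    e1->e2, e4->e3, so deduplication must merge e2/e4 into one node carrying
    both an in- and an out-edge.
    """
    genes = ["9101", "9102", "9103", "9102"]
    entries = _gene_entries(genes, org)
    relations = [
        KgmlRelation("e1", "e2", "PPrel", ("activation",)),
        KgmlRelation("e4", "e3", "PPrel", ("activation",)),
    ]
    return PathwayDefinition(
        kegg_id=pathway_id,
        title="Synthetic duplicate-gene pathway",
        organism_code=org,
        entries=entries,
        relations=relations,
    )


def three_cycle_definition(
    pathway_id: str = "hsa99002", *, org: str = "hsa"
) -> PathwayDefinition:
    """Three genes wired in a directed 3-cycle (loop-handling fixture)."""
    return signalling_definition(
        pathway_id,
        ["9201", "9202", "9203"],
        [(0, 1), (1, 2), (2, 0)],
        org=org,
        title="Synthetic 3-cycle pathway",
    )


def group_entry_definition(
    pathway_id: str = "hsa99003", *, org: str = "hsa"
) -> PathwayDefinition:
    """A group entry (complex) of two genes targeted by a relation."""
    entries = _gene_entries(["9301", "9302", "9303"], org)
    entries.append(
        KgmlEntry(
            entry_id="g1",
            entry_type="group",
            component_ids=("e2", "e3"),
            raw_names=("undefined",),
        )
    )
    relations = [KgmlRelation("e1", "g1", "PPrel", ("activation",))]
    return PathwayDefinition(
        kegg_id=pathway_id,
        title="Synthetic group-entry pathway",
        organism_code=org,
        entries=entries,
        relations=relations,
    )


def _topology_edges(
    topology: str, n: int, density: float, rng: np.random.Generator
) -> list[tuple[int, int]]:
    if topology == "chain":
        return [(i, i + 1) for i in range(n - 1)]
    if topology == "cycle":
        return [(i, (i + 1) % n) for i in range(n)]
    edges = []
    for a in range(n):
        for b in range(n):
            if a == b:
                continue
            if topology == "random_dag" and a >= b:
                continue
            if rng.random() < density:
                edges.append((a, b))
    return edges


def make_pathway_definitions(spec: FixtureSpec) -> FixtureSet:
    """Generate ``spec.n_pathways`` definitions with disjoint gene sets."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.nodes_per_pathway
    definitions = []
    gene_sets: dict[str, list[str]] = {}
    next_gene = 1001
    for i in range(spec.n_pathways):
        n = int(rng.integers(lo, hi + 1))
        genes = [str(next_gene + j) for j in range(n)]
        next_gene += n
        pid = f"{spec.organism_code}9{i + 1:04d}"
        if spec.topology == "metabolic_chain":
            defn = metabolic_chain_definition(pid, genes, org=spec.organism_code)
        else:
            edges = _topology_edges(spec.topology, n, spec.edge_density, rng)
            defn = signalling_definition(pid, genes, edges, org=spec.organism_code)
        definitions.append(defn)
        gene_sets[pid] = genes
    planted_id = None
    if spec.planted_pathway_index is not None:
        planted_id = definitions[spec.planted_pathway_index].kegg_id
    return FixtureSet(definitions, gene_sets, planted_id)


def make_kgml_fixture(spec: FixtureSpec, out_dir: str | os.PathLike) -> FixtureSet:
    """Write the generated pathways as KGML files under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fixture = make_pathway_definitions(spec)
    for defn in fixture.definitions:
        path = out_dir / f"{defn.kegg_id}.xml"
        write_kgml(defn, path)
        fixture.paths.append(path)
    return fixture


def planted_genes_for(spec: FixtureSpec, fixture: FixtureSet,
                      rng: np.random.Generator) -> list[str]:
    if fixture.planted_pathway_id is None:
        return []
    genes = fixture.gene_sets[fixture.planted_pathway_id]
    k = math.ceil(spec.planted_fraction * len(genes))
    chosen = rng.choice(len(genes), size=k, replace=False)
    return [genes[i] for i in sorted(chosen)]


def simulate_expression(
    spec: FixtureSpec, fixture: FixtureSet
) -> tuple[ExpressionMatrix, dict[str, str], list[str]]:
    """Simulate probes for every pathway gene plus background genes.

    Returns the expression matrix, the probe -> gene mapping (a fraction of
    probes is left unmapped to exercise that code path) and the list of
    planted genes.  Fully deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed + 1)
    pathway_genes = sorted(
        {g for genes in fixture.gene_sets.values() for g in genes}, key=int
    )
    background = [
        str(500001 + i) for i in range(spec.n_background_genes)
    ]
    genes = pathway_genes + background
    planted = set(planted_genes_for(spec, fixture, rng))

    n_samples = spec.n_control + spec.n_test
    probe_ids: list[str] = []
    rows: list[np.ndarray] = []
    mapping: dict[str, str] = {}
    probe_counter = 1
    plo, phi = spec.probes_per_gene
    for gene in genes:
        baseline = rng.uniform(4.0, 12.0)
        shift = math.log2(spec.planted_fc) if gene in planted else 0.0
        n_probes = int(rng.integers(plo, phi + 1))
        for _ in range(n_probes):
            values = baseline + rng.normal(0.0, spec.noise_sd, size=n_samples)
            values[spec.n_control :] += shift
            probe = f"P{probe_counter:06d}"
            probe_counter += 1
            probe_ids.append(probe)
            rows.append(values)
            if rng.random() >= spec.unmapped_fraction:
                mapping[probe] = gene
    matrix = ExpressionMatrix(
        probe_ids, np.vstack(rows), spec.n_control, spec.n_test
    )
    return matrix, mapping, sorted(planted, key=int)


def write_expression_table(
    matrix: ExpressionMatrix, path: str | os.PathLike
) -> Path:
    """Write an expression matrix as CSV or XLSX (by extension)."""
    path = Path(path)
    n = matrix.n_control
    columns = [f"ctrl_{i + 1}" for i in range(n)] + [
        f"test_{i + 1}" for i in range(matrix.n_test)
    ]
    df = pd.DataFrame(matrix.values, columns=columns)
    df.insert(0, "probe_id", matrix.probe_ids)
    if path.suffix.lower() == ".xlsx":
        df.to_excel(path, index=False)
    else:
        df.to_csv(path, index=False)
    return path


def write_mapping_table(mapping: dict[str, str], path: str | os.PathLike) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("probe_id\tgene_id\n")
        for probe in sorted(mapping):
            fh.write(f"{probe}\t{mapping[probe]}\n")
    return path


def write_demo_workspace(
    out_dir: str | os.PathLike, spec: FixtureSpec | None = None
) -> dict[str, Path]:
    """Write a complete demo workspace: KGML dir, expression CSV+XLSX, mapping.

    Besides ``spec.n_pathways`` scored pathways the KGML directory gets the
    duplicate-gene, 3-cycle and group-entry variants (their genes are absent
    from the expression table, so they parse and build but score zero).
    """
    if spec is None:
        spec = FixtureSpec(planted_pathway_index=0)
    out_dir = Path(out_dir)
    kgml_dir = out_dir / "kgml"
    fixture = make_kgml_fixture(spec, kgml_dir)
    for extra in (
        duplicate_gene_definition(org=spec.organism_code),
        three_cycle_definition(org=spec.organism_code),
        group_entry_definition(org=spec.organism_code),
    ):
        write_kgml(extra, kgml_dir / f"{extra.kegg_id}.xml")
    matrix, mapping, planted = simulate_expression(spec, fixture)
    paths = {
        "kgml_dir": kgml_dir,
        "expression_csv": write_expression_table(matrix, out_dir / "expression.csv"),
        "expression_xlsx": write_expression_table(matrix, out_dir / "expression.xlsx"),
        "mapping_tsv": write_mapping_table(mapping, out_dir / "mapping.tsv"),
    }
    meta = {
        "planted_pathway_id": fixture.planted_pathway_id,
        "planted_genes": planted,
        "n_control": spec.n_control,
        "n_test": spec.n_test,
        "seed": spec.seed,
    }
    import json

    meta_path = out_dir / "workspace.json"
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=2)
    paths["workspace_json"] = meta_path
    return paths
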