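"""Synthetic genomes, peptides, expression matrices and toy ontologies.

Every stage of the pipeline can be exercised without any download: this
module plants duplicate families of known membership inside an otherwise
random genome, generates expression data with a controlled within-group
correlation, and builds small regular ontologies with either subtree-
clustered or uniform gene annotations.  All generators are deterministic
for a fixed seed, and each emits the same plain-text formats the pipeline
reads (gene TSV/GFF3, FASTA, expression TSV, OBO, GAF-style TSV) plus a
truth table of what was planted.

Background peptides are uniform random sequences over the 20-residue
alphabet; unrelated random proteins align far below the duplicate
thresholds, so planted families are the only true positives by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .coexpression import ExpressionDataset
from .genome_io import GeneRecord, PeptideRecord

__all__ = [
    "FixtureSpec",
    "SyntheticGenome",
    "OntologyFixture",
    "generate_genome",
    "mutate_peptide",
    "generate_expression",
    "generate_ontology",
    "write_genome_fixture",
    "write_expression_fixture",
    "write_ontology_fixture",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic study conditions.

    The genome defaults (5 chromosomes x 200 genes, 20 planted families of
    2-5 genes at adjacent ranks, within-family divergence 0.1) give a
    genome-scale detection problem that runs in well under a minute;
    expression defaults (10 datasets x 20 samples, within-group correlation
    0.9) mirror the strong co-expression planted for duplicated groups.
    Peptide lengths span 100-200 aa, compact but on the natural protein
    length scale.
    """

    n_chromosomes: int = 5
    genes_per_chromosome: int = 200
    n_families: int = 20
    family_size_range: tuple[int, int] = (2, 5)
    divergence: float = 0.1
    placement_gap: int = 1
    peptide_length_range: tuple[int, int] = (100, 200)
    gene_length_range: tuple[int, int] = (500, 5000)
    intergenic_gap_range: tuple[int, int] = (200, 2000)
    # expression
    n_datasets: int = 10
    n_samples: int = 20
    rho: float = 0.9
    noise_sd: float = 1.0
    missing_rate: float = 0.0
    # ontology
    ontology_depth: int = 3
    ontology_branching: int = 2
    terms_per_gene: int = 2
    iea_proportion: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.divergence < 1.0:
            raise ValueError("divergence must be in [0, 1)")
        if self.placement_gap < 1:
            raise ValueError("placement_gap must be >= 1")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must be in [0, 1]")
        if self.ontology_depth < 2:
            raise ValueError("ontology depth must be >= 2")


@dataclass
class SyntheticGenome:
    """A planted-truth genome: gene records, peptides and the truth table."""

    genes: list[GeneRecord]
    peptides: list[PeptideRecord]
    truth: dict[str, frozenset[str]]  # family id -> member gene ids

    @property
    def duplicated_genes(self) -> set[str]:
        return {g for members in self.truth.values() for g in members}


def _random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def mutate_peptide(
    sequence: str, divergence: float, seed: int | np.random.Generator = 0
) -> str:
    """Substitute round(divergence * length) positions with different residues.

    Length is preserved (substitutions only), so the identity between the
    original and the mutant is 1 - divergence by construction.
    """
    if not 0.0 <= divergence < 1.0:
        raise ValueError("divergence must be in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_subs = round(divergence * len(sequence))
    if n_subs == 0:
        return sequence
    positions = rng.choice(len(sequence), size=n_subs, replace=False)
    seq = list(sequence)
    for pos in positions:
        alternatives = [a for a in AMINO_ACIDS if a != seq[pos]]
        seq[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(seq)


def generate_genome(spec: FixtureSpec = FixtureSpec()) -> SyntheticGenome:
    """Generate a genome with planted duplicate families.

    Genes are laid out per chromosome with random lengths and intergenic
    gaps.  Each family takes consecutive rank slots spaced ``placement_gap``
    ranks apart on one chromosome; its members share a common random ancestor
    peptide, each independently mutated to the requested divergence.  All
    other genes get independent random peptides.  The truth table maps
    family ids to member gene ids.
    """
    rng = np.random.default_rng(spec.seed)
    n_total_slots = spec.n_chromosomes * spec.genes_per_chromosome

    # Reserve family slots: (chromosome, ranks) tuples without collisions.
    used: dict[int, set[int]] = {c: set() for c in range(spec.n_chromosomes)}
    family_slots: list[tuple[str, int, list[int]]] = []
    lo, hi = spec.family_size_range
    for fam in range(spec.n_families):
        size = int(rng.integers(lo, hi + 1))
        extent = (size - 1) * spec.placement_gap
        if extent >= spec.genes_per_chromosome:
            raise ValueError("family extent exceeds chromosome length")
        for _attempt in range(1000):
            chrom = int(rng.integers(spec.n_chromosomes))
            start_rank = int(rng.integers(spec.genes_per_chromosome - extent))
            ranks = [start_rank + k * spec.placement_gap for k in range(size)]
            if not used[chrom].intersection(ranks):
                used[chrom].update(ranks)
                family_slots.append((f"fam{fam:03d}", chrom, ranks))
                break
        else:  # pragma: no cover - pathological spec
            raise RuntimeError("could not place all families; genome too crowded")

    member_of: dict[tuple[int, int], str] = {}
    for fam_id, chrom, ranks in family_slots:
        for r in ranks:
            member_of[(chrom, r)] = fam_id

    genes: list[GeneRecord] = []
    peptides: list[PeptideRecord] = []
    truth: dict[str, set[str]] = {fam_id: set() for fam_id, _c, _r in family_slots}
    plo, phi = spec.peptide_length_range
    family_ancestor: dict[str, str] = {}

    for chrom in range(spec.n_chromosomes):
        chrom_name = f"chr{chrom + 1}"
        pos = 1
        for rank in range(spec.genes_per_chromosome):
            glen = int(rng.integers(*spec.gene_length_range))
            gap = int(rng.integers(*spec.intergenic_gap_range))
            start = pos + gap
            end = start + glen - 1
            pos = end
            gene_id = f"g{chrom + 1:02d}_{rank:04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            fam_id = member_of.get((chrom, rank))
            genes.append(
                GeneRecord(
                    gene_id=gene_id,
                    chromosome=chrom_name,
                    start=start,
                    end=end,
                    strand=strand,
                    name=fam_id or "",
                    description=f"synthetic gene rank {rank}",
                )
            )
            if fam_id is not None:
                if fam_id not in family_ancestor:
                    family_ancestor[fam_id] = _random_peptide(
                        rng, int(rng.integers(plo, phi + 1))
                    )
                seq = mutate_peptide(family_ancestor[fam_id], spec.divergence, rng)
                truth[fam_id].add(gene_id)
            else:
                seq = _random_peptide(rng, int(rng.integers(plo, phi + 1)))
            peptides.append(
                PeptideRecord(
                    peptide_id=f"pep_{gene_id}", gene_id=gene_id, sequence=seq
                )
            )

    assert len(genes) == n_total_slots
    return SyntheticGenome(
        genes=genes,
        peptides=peptides,
        truth={k: frozenset(v) for k, v in sorted(truth.items())},
    )


def generate_expression(
    groups: Sequence[Iterable[str]],
    spec: FixtureSpec = FixtureSpec(),
    universe: Sequence[str] | None = None,
) -> list[ExpressionDataset]:
    """Generate expression datasets with planted within-group correlation.

    Members of each group load on a shared per-dataset latent factor with
    loading sqrt(rho), plus independent noise scaled to keep unit variance,
    so any two members correlate at rho in expectation; all other genes in
    the universe are independent standard Gaussians.  Missing values are
    injected at ``missing_rate`` uniformly at random.
    """
    rng = np.random.default_rng(spec.seed + 1)
    group_sets = [sorted(set(g)) for g in groups]
    grouped_genes = sorted({g for gs in group_sets for g in gs})
    if universe is None:
        all_genes = grouped_genes
    else:
        all_genes = sorted(set(universe) | set(grouped_genes))

    member_to_group: dict[str, int] = {}
    for gi, gs in enumerate(group_sets):
        for g in gs:
            if g in member_to_group:
                raise ValueError(f"gene {g} appears in two groups")
            member_to_group[g] = gi

    loading = np.sqrt(spec.rho)
    resid = np.sqrt(1.0 - spec.rho)
    datasets: list[ExpressionDataset] = []
    for d in range(spec.n_datasets):
        factors = rng.standard_normal((len(group_sets), spec.n_samples))
        rows = np.empty((len(all_genes), spec.n_samples))
        for i, gene in enumerate(all_genes):
            noise = rng.standard_normal(spec.n_samples) * spec.noise_sd
            gi = member_to_group.get(gene)
            if gi is None:
                rows[i] = noise
            else:
                rows[i] = loading * factors[gi] + resid * noise
        if spec.missing_rate > 0:
            mask = rng.random(rows.shape) < spec.missing_rate
            rows[mask] = np.nan
        frame = pd.DataFrame(
            rows,
            index=all_genes,
            columns=[f"s{j + 1}" for j in range(spec.n_samples)],
        )
        datasets.append(ExpressionDataset(dataset_id=f"ds{d + 1:03d}", matrix=frame))
    return datasets


@dataclass
class OntologyFixture:
    """A toy ontology with annotations and the planted clustering truth."""

    obo_text: str
    annotation_rows: list[tuple[str, str, str, str]]  # gene, term, evidence, aspect
    clustered_genes: dict[str, str]  # gene id -> subtree root term

    @property
    def gaf_text(self) -> str:
        lines = ["gene_id\tterm_id\tevidence\taspect"]
        lines += ["\t".join(row) for row in self.annotation_rows]
        return "\n".join(lines) + "\n"


def _tree_terms(
    prefix: str, depth: int, branching: int
) -> tuple[list[str], dict[str, str]]:
    """Complete tree term ids level by level; returns (terms, child->parent)."""
    terms = [f"{prefix}0000001"]
    parent: dict[str, str] = {}
    level = [terms[0]]
    counter = 2
    for _d in range(depth):
        nxt: list[str] = []
        for node in level:
            for _b in range(branching):
                term = f"{prefix}{counter:07d}"
                counter += 1
                parent[term] = node
                terms.append(term)
                nxt.append(term)
        level = nxt
    return terms, parent


def generate_ontology(
    spec: FixtureSpec = FixtureSpec(),
    clustered_groups: Sequence[Iterable[str]] = (),
    background_genes: Sequence[str] = (),
) -> OntologyFixture:
    """Build a regular toy ontology and annotate genes onto it.

    One complete tree of the given depth and branching factor is built per
    namespace (``is_a`` edges).  Genes of each clustered group are annotated
    to leaves of a single randomly chosen depth-1 subtree of each namespace
    (the planted functional coherence); background genes are annotated to
    leaves drawn uniformly across the whole tree.  Evidence codes are IEA
    with probability ``iea_proportion``, EXP otherwise.
    """
    rng = np.random.default_rng(spec.seed + 2)
    prefixes = {"biological_process": "BP:", "molecular_function": "MF:",
                "cellular_component": "CC:"}
    aspects = {"biological_process": "P", "molecular_function": "F",
               "cellular_component": "C"}

    stanzas: list[str] = ["format-version: 1.2\nontology: tandemdup-synthetic"]
    leaves: dict[str, list[str]] = {}
    subtree_of_leaf: dict[str, dict[str, str]] = {}
    subtree_leaves: dict[str, dict[str, list[str]]] = {}
    for ns, prefix in prefixes.items():
        terms, parent = _tree_terms(prefix, spec.ontology_depth, spec.ontology_branching)
        children: dict[str, list[str]] = {}
        for c, p in parent.items():
            children.setdefault(p, []).append(c)
        for term in terms:
            stanza = [f"[Term]", f"id: {term}", f"name: synthetic term {term}",
                      f"namespace: {ns}"]
            if term in parent:
                stanza.append(f"is_a: {parent[term]} ! parent")
            stanzas.append("\n".join(stanza))
        ns_leaves = [t for t in terms if t not in children]
        leaves[ns] = ns_leaves
        # leaf -> its depth-1 subtree root
        root = terms[0]
        mapping: dict[str, str] = {}
        for leaf in ns_leaves:
            node = leaf
            while parent.get(node) is not None and parent[node] != root:
                node = parent[node]
            mapping[leaf] = node
        subtree_of_leaf[ns] = mapping
        by_subtree: dict[str, list[str]] = {}
        for leaf, sub in mapping.items():
            by_subtree.setdefault(sub, []).append(leaf)
        subtree_leaves[ns] = by_subtree
    obo_text = "\n\n".join(stanzas) + "\n"

    def evidence() -> str:
        return "IEA" if rng.random() < spec.iea_proportion else "EXP"

    rows: list[tuple[str, str, str, str]] = []
    clustered: dict[str, str] = {}
    for group in clustered_groups:
        for ns in prefixes:
            subtrees = sorted(subtree_leaves[ns])
            chosen = subtrees[int(rng.integers(len(subtrees)))]
            pool = subtree_leaves[ns][chosen]
            for gene in sorted(set(group)):
                if ns == "biological_process":
                    clustered[gene] = chosen
                for _k in range(spec.terms_per_gene):
                    term = pool[int(rng.integers(len(pool)))]
                    rows.append((gene, term, evidence(), aspects[ns]))
    for gene in background_genes:
        for ns in prefixes:
            for _k in range(spec.terms_per_gene):
                term = leaves[ns][int(rng.integers(len(leaves[ns])))]
                rows.append((gene, term, evidence(), aspects[ns]))

    # deduplicate identical (gene, term, aspect) rows keeping the first
    seen: set[tuple[str, str, str]] = set()
    unique_rows: list[tuple[str, str, str, str]] = []
    for row in rows:
        key = (row[0], row[1], row[3])
        if key not in seen:
            seen.add(key)
            unique_rows.append(row)
    return OntologyFixture(
        obo_text=obo_text, annotation_rows=unique_rows, clustered_genes=clustered
    )


def write_genome_fixture(genome: SyntheticGenome, out_dir: str | Path) -> dict[str, Path]:
    """Write gene table, peptide FASTA and truth table to *out_dir*."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genes_path = out / "genes.tsv"
    with open(genes_path, "w") as fh:
        fh.write("gene_id\tchromosome\tstart\tend\tstrand\tname\tdescription\n")
        for g in genome.genes:
            fh.write(
                f"{g.gene_id}\t{g.chromosome}\t{g.start}\t{g.end}\t{g.strand}\t"
                f"{g.name}\t{g.description}\n"
            )
    fasta_path = out / "peptides.fasta"
    with open(fasta_path, "w") as fh:
        for p in genome.peptides:
            fh.write(f">{p.peptide_id} gene:{p.gene_id}\n")
            for i in range(0, len(p.sequence), 60):
                fh.write(p.sequence[i : i + 60] + "\n")
    truth_path = out / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("family_id\tgene_ids\n")
        for fam, members in genome.truth.items():
            fh.write(f"{fam}\t{','.join(sorted(members))}\n")
    return {"genes": genes_path, "peptides": fasta_path, "truth": truth_path}


def write_expression_fixture(
    datasets: Sequence[ExpressionDataset], out_dir: str | Path
) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for ds in datasets:
        path = out / f"{ds.dataset_id}.tsv"
        ds.matrix.to_csv(path, sep="\t", index_label="gene_id", na_rep="NA")
        paths.append(path)
    return paths


def write_ontology_fixture(
    fixture: OntologyFixture, out_dir: str | Path
) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    obo_path = out / "ontology.obo"
    obo_path.write_text(fixture.obo_text)
    gaf_path = out / "annotations.tsv"
    gaf_path.write_text(fixture.gaf_text)
    return {"obo": obo_path, "gaf": gaf_path}
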