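"""Co-localisation window, duplicate-pair linking and group assembly.

Duplicate candidates are restricted to genes at most ``window`` ranks apart
on the same chromosome (ranks count genes, not base pairs).  Each query gene
is linked to the nearest downstream gene (higher rank) whose alignment passes
the duplicate criterion; groups are then the connected components of the
resulting pair graph, so A-B and B-C place A, B and C in one group even when
A and C were never directly linked.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .genome_io import GeneIndex, PeptideRecord
from .similarity import (
    AlignmentResult,
    DetectionParams,
    ScoringScheme,
    DEFAULT_SCORING,
    SimilarityDecision,
    align_local,
    best_alignment_per_pair,
    is_duplicate_pair,
)

__all__ = [
    "DuplicatePair",
    "DuplicateGroup",
    "GenomeSummary",
    "DetectionReport",
    "find_duplicate_pairs",
    "build_groups",
    "summarize",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DuplicatePair:
    """Two co-localised genes whose peptides pass the duplicate criterion."""

    gene_a: str
    gene_b: str
    decision: SimilarityDecision
    rank_distance: int

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-pair {self.gene_a!r}")
        if self.rank_distance < 1:
            raise ValueError("rank_distance must be >= 1")


@dataclass(frozen=True)
class DuplicateGroup:
    """A transitive-closure cluster of co-localised duplicated genes."""

    group_id: str
    chromosome: str
    members: frozenset[str]
    span_bp: int

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a duplicate group needs at least 2 members")
        if self.span_bp < 0:
            raise ValueError("span_bp must be >= 0")


@dataclass
class GenomeSummary:
    """Genome-level statistics over detected duplicate groups."""

    n_groups: int = 0
    n_genes_in_groups: int = 0
    size_histogram: dict[int, int] = field(default_factory=dict)
    mean_span_kb: float = 0.0
    median_span_kb: float = 0.0
    largest_group_size: int = 0

    def to_text(self) -> str:
        lines = [
            f"groups\t{self.n_groups}",
            f"genes_in_groups\t{self.n_genes_in_groups}",
            f"mean_span_kb\t{self.mean_span_kb:.3f}",
            f"median_span_kb\t{self.median_span_kb:.3f}",
            f"largest_group_size\t{self.largest_group_size}",
        ]
        for size in sorted(self.size_histogram):
            lines.append(f"groups_of_{size}\t{self.size_histogram[size]}")
        return "\n".join(lines) + "\n"


@dataclass
class DetectionReport:
    """Counts at each filtering stage of a detection run."""

    n_genes: int = 0
    n_genes_with_peptide: int = 0
    n_genes_skipped_no_peptide: int = 0
    n_pairs_tested: int = 0
    n_pairs_passing: int = 0
    n_links: int = 0


def find_duplicate_pairs(
    index: GeneIndex,
    peptides: Mapping[str, PeptideRecord],
    params: DetectionParams = DetectionParams(),
    alignments: Sequence[AlignmentResult] | None = None,
    scoring: ScoringScheme = DEFAULT_SCORING,
    closest_downstream: bool = True,
    report: DetectionReport | None = None,
) -> list[DuplicatePair]:
    """Find co-localised duplicate pairs within the gene-rank window.

    For each query gene, downstream genes (higher rank, same chromosome) at
    rank distance <= ``params.window`` are scanned in order of increasing
    distance; the first one whose alignment passes the duplicate criterion
    becomes the query's link.  Because every gene acts as a query, a gene
    whose only passing partners lie upstream is still captured by the
    upstream partner's own downstream link.  With
    ``closest_downstream=False`` all passing pairs in the window are linked
    instead (sensitivity-analysis mode); the transitive closure makes final
    groups largely insensitive to this choice.

    Alignments may be supplied from a tabular search output; otherwise the
    internal aligner is used.  Genes without a peptide keep their rank (the
    window is about genomic context) but are skipped as query/subject, with
    a warning and a count in *report*.
    """
    if params.window < 1:
        raise ValueError("window must be >= 1")
    rep = report if report is not None else DetectionReport()
    rep.n_genes = len(index)

    lookup: dict[tuple[str, str], AlignmentResult] | None = None
    if alignments is not None:
        lookup = best_alignment_per_pair(alignments)

    missing = [g.gene_id for g in index if g.gene_id not in peptides]
    rep.n_genes_skipped_no_peptide = len(missing)
    rep.n_genes_with_peptide = rep.n_genes - len(missing)
    if missing:
        logger.warning(
            "%d gene(s) without peptide skipped in detection (e.g. %s)",
            len(missing), ", ".join(missing[:5]),
        )
    missing_set = set(missing)

    pairs: dict[tuple[str, str], DuplicatePair] = {}
    for chrom, genes in index.chromosomes.items():
        n = len(genes)
        for i, query in enumerate(genes):
            if query.gene_id in missing_set:
                continue
            for j in range(i + 1, min(i + params.window + 1, n)):
                subject = genes[j]
                if subject.gene_id in missing_set:
                    continue
                if lookup is not None:
                    key = (
                        (query.gene_id, subject.gene_id)
                        if query.gene_id <= subject.gene_id
                        else (subject.gene_id, query.gene_id)
                    )
                    aln = lookup.get(key)
                    if aln is None:
                        continue
                else:
                    aln = align_local(
                        peptides[query.gene_id], peptides[subject.gene_id], scoring
                    )
                rep.n_pairs_tested += 1
                decision = is_duplicate_pair(aln, params)
                if decision.passes:
                    rep.n_pairs_passing += 1
                    a, b = sorted((query.gene_id, subject.gene_id))
                    pairs.setdefault(
                        (a, b),
                        DuplicatePair(
                            gene_a=a, gene_b=b,
                            decision=decision, rank_distance=j - i,
                        ),
                    )
                    if closest_downstream:
                        break
    rep.n_links = len(pairs)
    return [pairs[k] for k in sorted(pairs)]


class _UnionFind:
    """Union-find with path compression; the transitive-link engine."""

    def __init__(self) -> None:
        self._parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        parent = self._parent.setdefault(x, x)
        if parent != x:
            root = self.find(parent)
            self._parent[x] = root
            return root
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self._parent[rb] = ra


def build_groups(
    pairs: Sequence[DuplicatePair],
    index: GeneIndex,
) -> list[DuplicateGroup]:
    """Assemble duplicate groups as connected components of the pair graph.

    If gene A pairs with B and B with C, all three land in one group even
    when A and C were never directly paired.  Group ids are deterministic:
    chromosome plus the id of the member with the smallest start coordinate.
    Groups are returned sorted by (chromosome, min member start).
    """
    uf = _UnionFind()
    chrom_of: dict[str, str] = {}
    for p in pairs:
        ca = index.chromosome_of(p.gene_a)
        cb = index.chromosome_of(p.gene_b)
        if ca != cb:
            raise ValueError(
                f"pair {p.gene_a}/{p.gene_b} spans chromosomes {ca} and {cb}"
            )
        chrom_of[p.gene_a] = ca
        chrom_of[p.gene_b] = cb
        uf.union(p.gene_a, p.gene_b)

    components: dict[str, set[str]] = {}
    for gene in chrom_of:
        components.setdefault(uf.find(gene), set()).add(gene)

    groups: list[DuplicateGroup] = []
    for members in components.values():
        recs = [index.gene(g) for g in members]
        min_start = min(r.start for r in recs)
        max_end = max(r.end for r in recs)
        anchor = min(recs, key=lambda r: (r.start, r.end, r.gene_id))
        groups.append(
            DuplicateGroup(
                group_id=f"{anchor.chromosome}:{anchor.gene_id}",
                chromosome=anchor.chromosome,
                members=frozenset(members),
                span_bp=max_end - min_start,
            )
        )
    groups.sort(
        key=lambda g: (g.chromosome, min(index.gene(m).start for m in g.members))
    )
    return groups


def summarize(groups: Sequence[DuplicateGroup]) -> GenomeSummary:
    """Genome-level group statistics: counts, size histogram, span in kb."""
    if not groups:
        return GenomeSummary()
    sizes = [len(g.members) for g in groups]
    spans_kb = [g.span_bp / 1000.0 for g in groups]
    histogram: dict[int, int] = {}
    for s in sizes:
        histogram[s] = histogram.get(s, 0) + 1
    return GenomeSummary(
        n_groups=len(groups),
        n_genes_in_groups=sum(sizes),
        size_histogram=histogram,
        mean_span_kb=statistics.fmean(spans_kb),
        median_span_kb=statistics.median(spans_kb),
        largest_group_size=max(sizes),
    )
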