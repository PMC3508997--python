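"""Gene annotation and peptide I/O.

Reads gene coordinates (GFF3, BED or a plain tab-delimited gene table) and
peptide FASTA files, reduces each gene to its single longest peptide, and
builds the per-chromosome, coordinate-ordered gene index that the
co-localisation window operates on.  Coordinates are held 1-based inclusive
(Ensembl convention); BED input is converted on read.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Iterator, Mapping

from Bio import SeqIO

if TYPE_CHECKING:  # pragma: no cover - type-only import
    from .grouping import DuplicateGroup

__all__ = [
    "GeneRecord",
    "PeptideRecord",
    "GeneIndex",
    "GeneTableError",
    "read_gene_annotation",
    "read_peptides",
    "select_longest_peptides",
    "build_gene_index",
    "write_groups",
    "read_groups",
]

GENE_TABLE_COLUMNS = (
    "gene_id",
    "chromosome",
    "start",
    "end",
    "strand",
    "name",
    "description",
)

_VALID_STRANDS = {"+", "-", "."}


class GeneTableError(ValueError):
    """Raised for malformed annotation input; carries the offending line number."""


@dataclass(frozen=True)
class GeneRecord:
    """A gene locus: 1-based inclusive coordinates on a named chromosome."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "."
    name: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class PeptideRecord:
    """One translated peptide, mapped to its owning gene."""

    peptide_id: str
    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"peptide {self.peptide_id}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


class GeneIndex:
    """Per-chromosome, coordinate-ordered view of a gene set.

    Genes are sorted by (start, end, gene_id) within each chromosome and
    assigned a 0-based rank.  Rank distance between two genes on the same
    chromosome is the co-localisation metric used by the detection window:
    it counts genes, not base pairs, so it is insensitive to gene-density
    differences between chromosomes and species.
    """

    def __init__(self, genes: Iterable[GeneRecord]):
        by_chrom: dict[str, list[GeneRecord]] = {}
        seen: set[str] = set()
        for g in genes:
            if g.gene_id in seen:
                raise GeneTableError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)
            by_chrom.setdefault(g.chromosome, []).append(g)
        self._by_chrom = {
            c: sorted(gl, key=lambda g: (g.start, g.end, g.gene_id))
            for c, gl in sorted(by_chrom.items())
        }
        self._lookup: dict[str, tuple[str, int]] = {}
        for chrom, gl in self._by_chrom.items():
            for rank, g in enumerate(gl):
                self._lookup[g.gene_id] = (chrom, rank)

    @property
    def chromosomes(self) -> Mapping[str, list[GeneRecord]]:
        return self._by_chrom

    def __len__(self) -> int:
        return len(self._lookup)

    def __iter__(self) -> Iterator[GeneRecord]:
        for gl in self._by_chrom.values():
            yield from gl

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._lookup

    def gene(self, gene_id: str) -> GeneRecord:
        chrom, rank = self._lookup[gene_id]
        return self._by_chrom[chrom][rank]

    def rank(self, gene_id: str) -> int:
        """0-based position of the gene within its chromosome's order."""
        return self._lookup[gene_id][1]

    def chromosome_of(self, gene_id: str) -> str:
        return self._lookup[gene_id][0]

    def rank_distance(self, gene_a: str, gene_b: str) -> int:
        ca, ra = self._lookup[gene_a]
        cb, rb = self._lookup[gene_b]
        if ca != cb:
            raise ValueError(f"{gene_a} and {gene_b} are on different chromosomes")
        return abs(ra - rb)


def _parse_gff3_attributes(attrs: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in attrs.strip().split(";"):
        part = part.strip()
        if not part or "=" not in part:
            continue
        key, _, value = part.partition("=")
        out[key.strip()] = value.strip()
    return out


def _iter_rows(path: str | Path) -> Iterator[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_gene_annotation(path: str | Path, dialect: str = "tsv") -> list[GeneRecord]:
    """Read gene records from a GFF3, BED or plain tab-delimited gene table.

    GFF3: only rows of feature type ``gene`` are kept; the gene identifier is
    taken from the ``ID`` (stripped of a ``gene:`` prefix) or ``gene_id``
    attribute.  BED: half-open 0-based intervals converted to 1-based
    inclusive.  tsv: columns ``gene_id  chromosome  start  end  [strand]
    [name] [description]`` with an optional header row.
    """
    if dialect not in {"gff3", "bed", "tsv"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    for lineno, fields in _iter_rows(path):
        try:
            if dialect == "gff3":
                if len(fields) < 9:
                    raise ValueError("expected 9 columns")
                if fields[2] != "gene":
                    continue
                attrs = _parse_gff3_attributes(fields[8])
                gene_id = attrs.get("gene_id") or attrs.get("ID", "")
                gene_id = gene_id.removeprefix("gene:")
                if not gene_id:
                    raise ValueError("gene row without ID/gene_id attribute")
                rec = GeneRecord(
                    gene_id=gene_id,
                    chromosome=fields[0],
                    start=int(fields[3]),
                    end=int(fields[4]),
                    strand=fields[6] if fields[6] in _VALID_STRANDS else ".",
                    name=attrs.get("Name", ""),
                    description=attrs.get("description", ""),
                )
            elif dialect == "bed":
                if len(fields) < 3:
                    raise ValueError("expected >=3 columns")
                rec = GeneRecord(
                    gene_id=fields[3] if len(fields) > 3 else f"bed{lineno}",
                    chromosome=fields[0],
                    start=int(fields[1]) + 1,  # 0-based half-open -> 1-based
                    end=int(fields[2]),
                    strand=(
                        fields[5]
                        if len(fields) > 5 and fields[5] in _VALID_STRANDS
                        else "."
                    ),
                )
            else:
                if fields[0] == "gene_id":  # header row
                    continue
                if len(fields) < 4:
                    raise ValueError("expected >=4 columns")
                padded = list(fields) + [""] * (7 - len(fields))
                rec = GeneRecord(
                    gene_id=padded[0],
                    chromosome=padded[1],
                    start=int(padded[2]),
                    end=int(padded[3]),
                    strand=padded[4] if padded[4] in _VALID_STRANDS else ".",
                    name=padded[5],
                    description=padded[6],
                )
        except (ValueError, IndexError) as exc:
            raise GeneTableError(f"{path}, line {lineno}: {exc}") from exc
        if rec.gene_id in seen:
            raise GeneTableError(
                f"{path}, line {lineno}: duplicate gene_id {rec.gene_id!r}"
            )
        seen.add(rec.gene_id)
        genes.append(rec)
    return genes


def _gene_from_header(description: str) -> str | None:
    for token in description.split():
        if token.startswith("gene:"):
            return token[len("gene:"):]
    return None


def read_peptides(
    path: str | Path,
    mapping: str = "header-token",
    table: str | Path | Mapping[str, str] | None = None,
) -> list[PeptideRecord]:
    """Read peptide sequences from FASTA with a peptide-to-gene mapping.

    ``mapping='header-token'`` expects a ``gene:<gene_id>`` token in each
    FASTA description line; ``mapping='side-table'`` takes a two-column
    ``peptide_id<TAB>gene_id`` file (or an in-memory mapping) via *table*.
    Sequences are upper-cased and terminal stop symbols (``*``) stripped.
    """
    if mapping not in {"header-token", "side-table"}:
        raise ValueError(f"unknown mapping {mapping!r}")
    side: dict[str, str] = {}
    if mapping == "side-table":
        if table is None:
            raise ValueError("side-table mapping requires a table")
        if isinstance(table, (str, Path)):
            for _lineno, fields in _iter_rows(table):
                side[fields[0]] = fields[1]
        else:
            side = dict(table)

    peptides: list[PeptideRecord] = []
    orphans: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().rstrip("*")
        gene_id = (
            side.get(rec.id) if mapping == "side-table" else _gene_from_header(rec.description)
        )
        if gene_id is None:
            orphans.append(rec.id)
            continue
        peptides.append(PeptideRecord(peptide_id=rec.id, gene_id=gene_id, sequence=seq))
    if orphans:
        raise ValueError(
            f"{len(orphans)} peptide(s) with no gene mapping: {', '.join(orphans[:10])}"
        )
    return peptides


def select_longest_peptides(
    peptides: Iterable[PeptideRecord],
) -> dict[str, PeptideRecord]:
    """Keep only the longest peptide per gene.

    Ties are broken by lexicographically smallest peptide_id so that repeated
    runs over the same input choose the same representative.
    """
    best: dict[str, PeptideRecord] = {}
    for pep in peptides:
        cur = best.get(pep.gene_id)
        if (
            cur is None
            or len(pep) > len(cur)
            or (len(pep) == len(cur) and pep.peptide_id < cur.peptide_id)
        ):
            best[pep.gene_id] = pep
    if not best:
        raise ValueError("no peptides supplied")
    return best


def build_gene_index(genes: Iterable[GeneRecord]) -> GeneIndex:
    """Sort genes per chromosome by (start, end, gene_id) and assign ranks."""
    return GeneIndex(genes)


def write_groups(
    groups: Iterable["DuplicateGroup"],
    index: GeneIndex,
    mode: str,
    path: str | Path | io.TextIOBase,
    header_comment: str | None = None,
) -> None:
    """Write duplicate groups as a tab-delimited table.

    ``mode='gene-list'`` writes one row per member gene; ``mode='group-list'``
    writes one row per group with comma-joined member ids.  Output order is
    deterministic: groups by (chromosome, min member start), genes within a
    group by coordinate.
    """
    if mode not in {"gene-list", "group-list"}:
        raise ValueError(f"unknown mode {mode!r}")

    rows: list[tuple] = []
    ordered = []
    for grp in groups:
        members = sorted(grp.members)
        for gid in members:
            if gid not in index:
                raise KeyError(f"group {grp.group_id}: unknown gene id {gid!r}")
        recs = sorted(
            (index.gene(g) for g in members), key=lambda r: (r.start, r.end, r.gene_id)
        )
        ordered.append((grp, recs))
    ordered.sort(key=lambda t: (t[0].chromosome, t[1][0].start, t[0].group_id))

    if mode == "gene-list":
        header = ("group_id", "gene_id", "chromosome", "start", "end", "name")
        for grp, recs in ordered:
            for r in recs:
                rows.append((grp.group_id, r.gene_id, r.chromosome, r.start, r.end, r.name))
    else:
        header = ("group_id", "chromosome", "n_genes", "span_kb", "gene_ids")
        for grp, recs in ordered:
            span_kb = (max(r.end for r in recs) - min(r.start for r in recs)) / 1000.0
            rows.append(
                (
                    grp.group_id,
                    grp.chromosome,
                    len(recs),
                    f"{span_kb:.3f}",
                    ",".join(r.gene_id for r in recs),
                )
            )

    close = False
    if isinstance(path, (str, Path)):
        fh = open(path, "w")
        close = True
    else:
        fh = path
    try:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")
    finally:
        if close:
            fh.close()


def read_groups(path: str | Path) -> dict[str, set[str]]:
    """Read a gene-list group table back into ``{group_id: set of gene ids}``."""
    groups: dict[str, set[str]] = {}
    for _lineno, fields in _iter_rows(path):
        if fields[0] == "group_id":
            continue
        groups.setdefault(fields[0], set()).add(fields[1])
    return groups
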