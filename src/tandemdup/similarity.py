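"""Pairwise peptide similarity and the duplicate-pair decision rule.

Two peptides are called duplicates when (i) the alignment e-value, if one is
available, is at most ``evalue_max`` (a coarse relevance filter) and (ii) the
coverage-weighted identity

    I' = I * min(n1/L1, n2/L2)

clears a length-dependent threshold: a flat 30% cutoff for aligned regions of
at least 150 aa, and below that the steeper twilight-zone curve

    p(L) = 0.01*n + 4.8 * L**(-0.32 * (1 + exp(-L/1000)))

with offset n = 6, which makes the two branches meet at L = 150.  Here I is
the fraction of identical residues over the aligned region (gap columns count
in the denominator), L_i the full length of sequence i and n_i the number of
its residues inside the aligned region.  Weighting I by the smaller coverage
fraction stops a short protein that shares a single domain with a much longer
protein from being called its duplicate.

Alignments come either from the internal affine-gap Smith-Waterman aligner or
from a standard 12-column tabular search output; decisions depend only on the
alignment statistics, not on their origin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping

from Bio import Align
from Bio.Align import substitution_matrices

from .genome_io import PeptideRecord

__all__ = [
    "ScoringScheme",
    "AlignmentResult",
    "SimilarityDecision",
    "DetectionParams",
    "DEFAULT_SCORING",
    "align_local",
    "parse_alignment_tabular",
    "best_alignment_per_pair",
    "weighted_identity",
    "rost_threshold",
    "is_duplicate_pair",
]


@dataclass(frozen=True)
class ScoringScheme:
    """Affine-gap scoring for the internal protein aligner.

    Defaults are the conventional protein-search settings: BLOSUM62 with gap
    open 11 and gap extend 1.  The ambiguous residue X is rescored to 0
    against everything so runs of X neither reward nor punish an alignment.
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")


DEFAULT_SCORING = ScoringScheme()


@dataclass(frozen=True)
class AlignmentResult:
    """Statistics of one pairwise local alignment.

    L counts alignment columns including gaps; n_query/n_subject count the
    residues of each sequence inside the aligned region; L_query/L_subject
    are the full sequence lengths.  e_value is None for internal alignments.
    """

    query_id: str
    subject_id: str
    L: int
    identities: int
    n_query: int
    n_subject: int
    L_query: int
    L_subject: int
    score: float = 0.0
    e_value: float | None = None

    def __post_init__(self) -> None:
        if not (
            self.identities <= self.L
            and self.n_query <= self.L
            and self.n_subject <= self.L
            and self.n_query <= self.L_query
            and self.n_subject <= self.L_subject
        ):
            raise ValueError(
                f"inconsistent alignment statistics for "
                f"{self.query_id}/{self.subject_id}"
            )


@dataclass(frozen=True)
class SimilarityDecision:
    """Outcome of the duplicate criterion for one alignment."""

    I: float
    I_prime: float
    threshold_used: float | None = None
    branch: str | None = None  # 'long' (L>=150) or 'short' (L<150)
    passes: bool = False


@dataclass(frozen=True)
class DetectionParams:
    """Tunable thresholds of the detection pipeline.

    evalue_max filters irrelevant search hits; long_branch_cutoff is the flat
    identity threshold for alignments of at least length_breakpoint residues;
    rost_n offsets the short-alignment curve so the two branches are
    continuous; window is the co-localisation distance in gene ranks.
    """

    evalue_max: float = 0.2
    long_branch_cutoff: float = 0.30
    length_breakpoint: int = 150
    rost_n: float = 6.0
    window: int = 100

    def __post_init__(self) -> None:
        for name in ("evalue_max", "long_branch_cutoff", "length_breakpoint", "rost_n", "window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@lru_cache(maxsize=8)
def _aligner(scoring: ScoringScheme) -> Align.PairwiseAligner:
    matrix = substitution_matrices.load(scoring.matrix)
    if "X" in matrix.alphabet:
        matrix = matrix.copy()
        i = matrix.alphabet.index("X")
        matrix[i, :] = 0.0
        matrix[:, i] = 0.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -scoring.gap_open
    aligner.extend_gap_score = -scoring.gap_extend
    return aligner


def align_local(
    a: PeptideRecord,
    b: PeptideRecord,
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> AlignmentResult:
    """Optimal local alignment of two peptides under affine-gap scoring.

    Returns the alignment statistics needed by the duplicate criterion.  When
    no residue pair scores positively the local alignment is empty (L = 0).
    Ids in the result are the owning gene ids, matching the search-tool
    convention where queries and subjects are genes.
    """
    if not a.sequence or not b.sequence:
        raise ValueError("cannot align empty sequences")
    aligner = _aligner(scoring)
    alignments = aligner.align(a.sequence, b.sequence)
    if alignments.score <= 0:
        return AlignmentResult(
            query_id=a.gene_id, subject_id=b.gene_id,
            L=0, identities=0, n_query=0, n_subject=0,
            L_query=len(a), L_subject=len(b), score=0.0,
        )
    best = alignments[0]
    qblocks, sblocks = best.aligned
    aligned_cols = int(sum(e - s for s, e in qblocks))
    n_query = int(qblocks[-1][1] - qblocks[0][0])
    n_subject = int(sblocks[-1][1] - sblocks[0][0])
    L = n_query + n_subject - aligned_cols
    identities = int(best.counts().identities)
    return AlignmentResult(
        query_id=a.gene_id,
        subject_id=b.gene_id,
        L=L,
        identities=identities,
        n_query=n_query,
        n_subject=n_subject,
        L_query=len(a),
        L_subject=len(b),
        score=float(alignments.score),
    )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def parse_alignment_tabular(
    path: str | Path,
    lengths: Mapping[str, int] | None = None,
) -> list[AlignmentResult]:
    """Parse the standard 12-column tabular search-output dialect.

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend sstart
    send evalue bitscore, optionally extended with qlen and slen.  When the
    length columns are absent, full sequence lengths must be supplied via
    *lengths* (gene id -> peptide length).  Identity counts are reconstructed
    as round(pident * length / 100) (half up); residues inside the aligned
    region are taken from the coordinate spans.  Self hits are dropped.
    """
    results: list[AlignmentResult] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(f"{path}, line {lineno}: expected >=12 columns")
            qid, sid = fields[0], fields[1]
            if qid == sid:
                continue
            pident = float(fields[2])
            L = int(fields[3])
            qstart, qend = int(fields[6]), int(fields[7])
            sstart, send = int(fields[8]), int(fields[9])
            evalue = float(fields[10])
            bitscore = float(fields[11])
            if len(fields) >= 14:
                qlen, slen = int(fields[12]), int(fields[13])
            elif lengths is not None:
                try:
                    qlen, slen = lengths[qid], lengths[sid]
                except KeyError as exc:
                    raise ValueError(
                        f"{path}, line {lineno}: no length known for {exc.args[0]!r}"
                    ) from exc
            else:
                raise ValueError(
                    f"{path}, line {lineno}: no qlen/slen columns and no "
                    "sequence lengths supplied"
                )
            n_query = min(abs(qend - qstart) + 1, L)
            n_subject = min(abs(send - sstart) + 1, L)
            results.append(
                AlignmentResult(
                    query_id=qid,
                    subject_id=sid,
                    L=L,
                    identities=min(_round_half_up(pident * L / 100.0), L),
                    n_query=n_query,
                    n_subject=n_subject,
                    L_query=qlen,
                    L_subject=slen,
                    score=bitscore,
                    e_value=evalue,
                )
            )
    return results


def best_alignment_per_pair(
    alignments: Iterable[AlignmentResult],
) -> dict[tuple[str, str], AlignmentResult]:
    """Keep one alignment per unordered gene pair.

    When a pair has several local alignments (HSPs), the highest-scoring one
    wins; ties go to the larger L, then to the lexicographically smaller
    subject id, so repeated runs pick the same alignment.
    """
    best: dict[tuple[str, str], AlignmentResult] = {}
    for aln in alignments:
        key = (
            (aln.query_id, aln.subject_id)
            if aln.query_id <= aln.subject_id
            else (aln.subject_id, aln.query_id)
        )
        cur = best.get(key)
        if cur is None or (aln.score, aln.L, cur.subject_id) > (
            cur.score,
            cur.L,
            aln.subject_id,
        ):
            best[key] = aln
    return best


def weighted_identity(aln: AlignmentResult) -> SimilarityDecision:
    """Compute I and the coverage-weighted identity I' for an alignment.

    I = identities / L over the aligned region (gap columns included in L);
    I' scales I by the smaller of the two coverage fractions n_i/L_i.  The
    result always satisfies I' <= I, with equality only for gap-free,
    full-coverage alignments.
    """
    if aln.L <= 0:
        return SimilarityDecision(I=0.0, I_prime=0.0)
    if aln.L_query <= 0 or aln.L_subject <= 0:
        raise ValueError("full sequence lengths must be positive")
    I = aln.identities / aln.L
    coverage = min(aln.n_query / aln.L_query, aln.n_subject / aln.L_subject)
    return SimilarityDecision(I=I, I_prime=I * coverage)


def rost_threshold(L: float, n: float = 6.0) -> float:
    """Length-dependent identity threshold for short alignments.

    Evaluates ``0.01*n + 4.8 * L**(-0.32 * (1 + exp(-L/1000)))`` on the
    proportion scale.  The curve rises steeply at short aligned lengths,
    reflecting how easily short high-identity alignments arise by chance
    (the twilight zone); with n = 6 it meets the flat 30% cutoff at L = 150.
    """
    if L < 1:
        raise ValueError("aligned length must be >= 1")
    return 0.01 * n + 4.8 * L ** (-0.32 * (1.0 + math.exp(-L / 1000.0)))


def is_duplicate_pair(
    aln: AlignmentResult,
    params: DetectionParams = DetectionParams(),
) -> SimilarityDecision:
    """Apply the full duplicate criterion to one alignment.

    Criterion i: e-value <= evalue_max, evaluated only when the alignment
    carries an e-value (internal alignments do not).  Criterion ii: I' at or
    above the flat cutoff for L >= length_breakpoint, or above the
    twilight-zone curve for shorter alignments.  Empty alignments never pass.
    """
    base = weighted_identity(aln)
    if aln.L <= 0:
        return SimilarityDecision(
            I=0.0, I_prime=0.0, threshold_used=params.long_branch_cutoff,
            branch="short", passes=False,
        )
    if aln.L >= params.length_breakpoint:
        branch, threshold = "long", params.long_branch_cutoff
    else:
        branch, threshold = "short", rost_threshold(aln.L, params.rost_n)
    evalue_ok = aln.e_value is None or aln.e_value <= params.evalue_max
    passes = evalue_ok and base.I_prime >= threshold
    return SimilarityDecision(
        I=base.I,
        I_prime=base.I_prime,
        threshold_used=threshold,
        branch=branch,
        passes=passes,
    )
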