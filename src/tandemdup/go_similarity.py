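"""Wang graph-based GO semantic similarity between genes of a group.

A term's semantics are encoded by its ancestor DAG: the term itself gets an
S-value of 1, and each ancestor receives the maximum, over paths towards it,
of the product of per-edge semantic-contribution factors (by default 0.8 for
``is_a``, 0.6 for ``part_of``).  The similarity of two terms is the summed
S-values of their shared ancestors relative to their total semantic values:

    Sim(A, B) = sum_{t in T_A & T_B} (S_A(t) + S_B(t)) / (SV(A) + SV(B))

which is symmetric, equals 1 for identical terms and is bounded in [0, 1].
Gene-level similarity aggregates term similarities by best-match average,
computed separately for the three ontology branches (biological_process,
molecular_function, cellular_component).  A gene-pair value of 0.5 is the
conventional "fairly similar" boundary (FAIRLY_SIMILAR).

Evidence codes are carried through so that the share of electronic (IEA)
annotations in a group can be reported alongside its similarity values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet

__all__ = [
    "NAMESPACES",
    "FAIRLY_SIMILAR",
    "OntologyGraph",
    "ContributionWeights",
    "TermAnnotationSet",
    "GroupSemanticSimilarity",
    "load_ontology",
    "read_annotations",
    "s_values",
    "term_similarity",
    "gene_similarity",
    "group_semantic_similarity",
]

NAMESPACES = ("biological_process", "molecular_function", "cellular_component")

#: Gene-pair similarity at which two genes are conventionally called
#: "fairly similar" under this measure.
FAIRLY_SIMILAR = 0.5

#: Default cap on group size for the semantic-similarity analysis.
MAX_GROUP_SIZE_GO = 15

_ASPECT_TO_NAMESPACE = {
    "P": "biological_process",
    "F": "molecular_function",
    "C": "cellular_component",
}

_KEPT_RELATIONS = ("is_a", "part_of")


@dataclass(frozen=True)
class ContributionWeights:
    """Per-edge-type semantic contribution factors, each in (0, 1)."""

    is_a: float = 0.8
    part_of: float = 0.6

    def __post_init__(self) -> None:
        for name in ("is_a", "part_of"):
            w = getattr(self, name)
            if not 0.0 < w < 1.0:
                raise ValueError(f"weight {name}={w} outside (0, 1)")

    def __getitem__(self, relation: str) -> float:
        return getattr(self, relation)


class OntologyGraph:
    """Term DAG over the three GO namespaces with typed child->parent edges.

    Only ``is_a`` and ``part_of`` relations carry semantic contribution;
    other relationship types are dropped on load (the terms are kept).
    """

    def __init__(self, graph: nx.MultiDiGraph):
        if not nx.is_directed_acyclic_graph(graph):
            raise ValueError("ontology contains a cycle")
        self.graph = graph

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def __len__(self) -> int:
        return len(self.graph)

    def namespace(self, term: str) -> str:
        return self.graph.nodes[term].get("namespace", "")

    def parents(self, term: str) -> list[tuple[str, str]]:
        """(parent, relation) edges leaving a term."""
        return [
            (parent, rel)
            for _child, parent, rel in self.graph.out_edges(term, keys=True)
        ]

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable from *term* along child->parent edges, incl. itself."""
        if term not in self.graph:
            raise KeyError(f"unknown term {term!r}")
        return {term} | nx.descendants(self.graph, term)


def load_ontology(path: str | Path) -> OntologyGraph:
    """Load an OBO ontology, keeping is_a/part_of edges and dropping obsolete
    terms.  Edge direction is child -> parent."""
    raw = obonet.read_obo(str(path))  # obsolete terms dropped by the reader
    graph = nx.MultiDiGraph()
    for node, data in raw.nodes(data=True):
        graph.add_node(node, **data)
    for child, parent, rel in raw.edges(keys=True):
        if rel in _KEPT_RELATIONS:
            graph.add_edge(child, parent, key=rel)
    return OntologyGraph(graph)


@dataclass
class TermAnnotationSet:
    """Per-namespace (term, evidence code) annotations of one gene."""

    gene_id: str
    annotations: dict[str, set[tuple[str, str]]] = field(default_factory=dict)

    def terms(self, namespace: str) -> set[str]:
        return {t for t, _ev in self.annotations.get(namespace, set())}

    def add(self, namespace: str, term: str, evidence: str) -> None:
        self.annotations.setdefault(namespace, set()).add((term, evidence))


def read_annotations(
    path: str | Path,
    ontology: OntologyGraph | None = None,
) -> dict[str, TermAnnotationSet]:
    """Read GAF-style tab-delimited annotations.

    Columns: gene_id, term_id, evidence_code, aspect (P/F/C or the full
    namespace name), optional qualifier.  Rows with a NOT qualifier are
    dropped; when an ontology is given, rows whose term is absent from it
    (e.g. obsolete) are dropped too.
    """
    out: dict[str, TermAnnotationSet] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "!")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}, line {lineno}: expected >=4 columns")
            gene_id, term, evidence, aspect = fields[:4]
            if gene_id == "gene_id":
                continue
            qualifier = fields[4] if len(fields) > 4 else ""
            if "NOT" in qualifier.split("|"):
                continue
            namespace = _ASPECT_TO_NAMESPACE.get(aspect, aspect)
            if namespace not in NAMESPACES:
                raise ValueError(
                    f"{path}, line {lineno}: unknown aspect {aspect!r}"
                )
            if ontology is not None and term not in ontology:
                continue
            out.setdefault(gene_id, TermAnnotationSet(gene_id)).add(
                namespace, term, evidence
            )
    return out


def s_values(
    term: str,
    ontology: OntologyGraph,
    weights: ContributionWeights = ContributionWeights(),
) -> dict[str, float]:
    """Semantic contribution of *term* to each of its ancestors.

    S(term) = 1; walking towards the root, each ancestor t receives
    max over child edges (t' -> t) within the ancestor DAG of w_edge * S(t'),
    i.e. the best path product of edge weights.  Values are in (0, 1] and
    non-increasing along any child-to-parent path.
    """
    ancestors = ontology.ancestors(term)  # raises on unknown term
    sub = ontology.graph.subgraph(ancestors)
    S: dict[str, float] = {term: 1.0}
    for node in nx.topological_sort(sub):  # children before parents
        if node not in S:
            continue
        for _c, parent, rel in sub.out_edges(node, keys=True):
            candidate = weights[rel] * S[node]
            if candidate > S.get(parent, 0.0):
                S[parent] = candidate
    return S


def term_similarity(
    t1: str,
    t2: str,
    ontology: OntologyGraph,
    weights: ContributionWeights = ContributionWeights(),
) -> float:
    """Similarity of two terms from the S-values of their shared ancestors.

    Symmetric, 1.0 for identical terms, bounded in [0, 1].  Both terms must
    belong to the same namespace.
    """
    ns1, ns2 = ontology.namespace(t1), ontology.namespace(t2)
    if ns1 != ns2:
        raise ValueError(f"cross-namespace comparison: {t1} ({ns1}) vs {t2} ({ns2})")
    if t1 == t2:
        if t1 not in ontology:
            raise KeyError(f"unknown term {t1!r}")
        return 1.0
    s1 = s_values(t1, ontology, weights)
    s2 = s_values(t2, ontology, weights)
    shared = s1.keys() & s2.keys()
    if not shared:
        return 0.0
    num = sum(s1[t] + s2[t] for t in shared)
    den = sum(s1.values()) + sum(s2.values())
    return min(num / den, 1.0)  # guard summation-order rounding at the bound


def gene_similarity(
    a: TermAnnotationSet,
    b: TermAnnotationSet,
    namespace: str,
    ontology: OntologyGraph,
    weights: ContributionWeights = ContributionWeights(),
    aggregation: str = "bma",
) -> float | None:
    """Aggregate term similarities of two annotated genes in one namespace.

    Best-match average (default): every term of one gene is matched to its
    most similar term of the other, both directions, and the matches are
    averaged; ``aggregation='max'`` takes the single best term pair instead.
    Returns None when either gene has no annotation in the namespace (the
    pair is then not comparable rather than dissimilar).
    """
    if aggregation not in {"bma", "max"}:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    terms_a = sorted(a.terms(namespace))
    terms_b = sorted(b.terms(namespace))
    if not terms_a or not terms_b:
        return None
    sim = {
        (ta, tb): term_similarity(ta, tb, ontology, weights)
        for ta in terms_a
        for tb in terms_b
    }
    if aggregation == "max":
        return max(sim.values())
    best_a = [max(sim[ta, tb] for tb in terms_b) for ta in terms_a]
    best_b = [max(sim[ta, tb] for ta in terms_a) for tb in terms_b]
    return (sum(best_a) + sum(best_b)) / (len(terms_a) + len(terms_b))


@dataclass
class GroupSemanticSimilarity:
    """Per-namespace pairwise gene similarities and IEA share for one group."""

    group_id: str
    pairwise: dict[str, dict[tuple[str, str], float]] = field(default_factory=dict)
    n_not_comparable: int = 0
    iea_proportion: float | None = None
    skipped_reason: str | None = None

    def mean(self, namespace: str) -> float | None:
        values = self.pairwise.get(namespace)
        if not values:
            return None
        return sum(values.values()) / len(values)


def group_semantic_similarity(
    group_id: str,
    members: Iterable[str],
    annotations: Mapping[str, TermAnnotationSet],
    ontology: OntologyGraph,
    weights: ContributionWeights = ContributionWeights(),
    max_group_size: int | None = MAX_GROUP_SIZE_GO,
    aggregation: str = "bma",
) -> GroupSemanticSimilarity:
    """All pairwise gene similarities of a group, per namespace, plus the
    group's IEA annotation share.

    A namespace contributes values whenever at least two members are
    annotated in it.  Groups above *max_group_size* are skipped with a
    reason.  The IEA proportion counts IEA-coded annotations over all
    annotations of the members, across namespaces.
    """
    members = sorted(set(members))
    result = GroupSemanticSimilarity(group_id=group_id)
    if max_group_size is not None and len(members) > max_group_size:
        result.skipped_reason = (
            f"group size {len(members)} exceeds cap {max_group_size}"
        )
        return result

    n_annotations = 0
    n_iea = 0
    for gid in members:
        ann = annotations.get(gid)
        if ann is None:
            continue
        for pairs in ann.annotations.values():
            n_annotations += len(pairs)
            n_iea += sum(1 for _t, ev in pairs if ev == "IEA")
    if n_annotations:
        result.iea_proportion = n_iea / n_annotations

    for namespace in NAMESPACES:
        values: dict[tuple[str, str], float] = {}
        for ga, gb in combinations(members, 2):
            ann_a, ann_b = annotations.get(ga), annotations.get(gb)
            if ann_a is None or ann_b is None:
                result.n_not_comparable += 1
                continue
            value = gene_similarity(
                ann_a, ann_b, namespace, ontology, weights, aggregation
            )
            if value is None:
                result.n_not_comparable += 1
                continue
            values[(ga, gb)] = value
        if values:
            result.pairwise[namespace] = values
    return result
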