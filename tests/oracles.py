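"""Independent reference implementations used to check the package.

These deliberately re-derive results by the most transparent route available
(plain dynamic programming, path enumeration, library graph algorithms) and
share no code with the implementation under test.
"""

from __future__ import annotations


import networkx as nx
from Bio.Align import substitution_matrices

_MATRIX = substitution_matrices.load("BLOSUM62")


def blosum62_score(a: str, b: str) -> float:
    if a == "X" or b == "X":
        return 0.0
    return float(_MATRIX[a, b])


def sw_affine_score(s1: str, s2: str, gap_open: float = 11.0,
                    gap_extend: float = 1.0) -> float:
    """Smith-Waterman optimal local score with affine gaps (Gotoh DP).

    A gap of length k costs gap_open + (k - 1) * gap_extend.
    """
    n, m = len(s1), len(s2)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in s1 (consume s2)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in s2 (consume s1)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_extend)
            diag = H[i - 1][j - 1] + blosum62_score(s1[i - 1], s2[j - 1])
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def bfs_components(pairs: list[tuple[str, str]]) -> set[frozenset[str]]:
    """Connected components of a pair graph via networkx breadth-first search."""
    graph = nx.Graph()
    graph.add_edges_from(pairs)
    return {frozenset(c) for c in nx.connected_components(graph)}


def enumerate_s_values(term: str, parents: dict[str, list[tuple[str, str]]],
                       weights: dict[str, float]) -> dict[str, float]:
    """S-values by exhaustive enumeration of all child->parent paths.

    ``parents`` maps a term to its (parent, relation) edges.  The S-value of
    an ancestor is the maximum over all paths of the product of edge weights.
    """
    S = {term: 1.0}

    def walk(node: str, product: float) -> None:
        for parent, rel in parents.get(node, []):
            p = product * weights[rel]
            if p > S.get(parent, 0.0):
                S[parent] = p
            walk(parent, p)

    walk(term, 1.0)
    return S


def wang_term_similarity(t1: str, t2: str,
                         parents: dict[str, list[tuple[str, str]]],
                         weights: dict[str, float]) -> float:
    s1 = enumerate_s_values(t1, parents, weights)
    s2 = enumerate_s_values(t2, parents, weights)
    shared = s1.keys() & s2.keys()
    if not shared:
        return 0.0
    return sum(s1[t] + s2[t] for t in shared) / (sum(s1.values()) + sum(s2.values()))


def wang_gene_similarity(terms_a: list[str], terms_b: list[str],
                         parents: dict[str, list[tuple[str, str]]],
                         weights: dict[str, float]) -> float:
    """Best-match-average aggregation over all term pairs, by brute force."""
    sims = {
        (ta, tb): wang_term_similarity(ta, tb, parents, weights)
        for ta in terms_a for tb in terms_b
    }
    total = sum(max(sims[ta, tb] for tb in terms_b) for ta in terms_a)
    total += sum(max(sims[ta, tb] for ta in terms_a) for tb in terms_b)
    return total / (len(terms_a) + len(terms_b))
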