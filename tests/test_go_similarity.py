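import itertools

import numpy as np
import pytest

from tandemdup.go_similarity import (
    ContributionWeights,
    TermAnnotationSet,
    gene_similarity,
    group_semantic_similarity,
    load_ontology,
    read_annotations,
    s_values,
    term_similarity,
)
from tandemdup.synthetic import FixtureSpec, generate_ontology

from oracles import enumerate_s_values, wang_gene_similarity, wang_term_similarity

W = ContributionWeights()
WDICT = {"is_a": 0.8, "part_of": 0.6}


def write_obo(tmp_path, stanzas):
    path = tmp_path / "toy.obo"
    path.write_text(
        "format-version: 1.2\nontology: toy\n\n" + "\n\n".join(stanzas) + "\n"
    )
    return path


def stanza(term, namespace="biological_process", is_a=(), part_of=(),
           obsolete=False, extra=()):
    lines = [f"[Term]", f"id: {term}", f"name: {term}", f"namespace: {namespace}"]
    lines += [f"is_a: {p} ! x" for p in is_a]
    lines += [f"relationship: part_of {p} ! x" for p in part_of]
    lines += list(extra)
    if obsolete:
        lines.append("is_obsolete: true")
    return "\n".join(lines)


@pytest.fixture()
def chain(tmp_path):
    """A -> B -> C chain of is_a edges."""
    return load_ontology(write_obo(tmp_path, [
        stanza("GO:0000003"),
        stanza("GO:0000002", is_a=["GO:0000003"]),
        stanza("GO:0000001", is_a=["GO:0000002"]),
    ]))


class TestLoadOntology:
    def test_chain_has_two_edges(self, chain):
        assert len(chain) == 3
        assert chain.graph.number_of_edges() == 2

    def test_obsolete_terms_dropped(self, tmp_path):
        onto = load_ontology(write_obo(tmp_path, [
            stanza("GO:0000001"),
            stanza("GO:0000002", is_a=["GO:0000001"], obsolete=True),
        ]))
        assert "GO:0000002" not in onto

    def test_unknown_relationship_ignored_term_kept(self, tmp_path):
        onto = load_ontology(write_obo(tmp_path, [
            stanza("GO:0000001"),
            stanza("GO:0000002", extra=["relationship: regulates GO:0000001 ! x"]),
        ]))
        assert "GO:0000002" in onto
        assert onto.graph.number_of_edges() == 0


class TestSValues:
    def test_root_term_alone(self, chain):
        assert s_values("GO:0000003", chain, W) == {"GO:0000003": 1.0}

    def test_is_a_chain_powers_of_weight(self, chain):
        S = s_values("GO:0000001", chain, W)
        assert S == {
            "GO:0000001": 1.0,
            "GO:0000002": pytest.approx(0.8),
            "GO:0000003": pytest.approx(0.8 ** 2),
        }

    def test_diamond_takes_path_maximum(self, tmp_path):
        # two routes to the root: is_a/is_a (0.64) vs part_of (0.6)
        onto = load_ontology(write_obo(tmp_path, [
            stanza("GO:0000004"),
            stanza("GO:0000002", is_a=["GO:0000004"]),
            stanza("GO:0000001", is_a=["GO:0000002"], part_of=["GO:0000004"]),
        ]))
        S = s_values("GO:0000001", onto, W)
        assert S["GO:0000004"] == pytest.approx(max(0.8 * 0.8, 0.6))

    def test_unknown_term_is_an_error(self, chain):
        with pytest.raises(KeyError):
            s_values("GO:9999999", chain, W)


class TestTermSimilarity:
    def test_identity_is_one(self, chain):
        for t in ("GO:0000001", "GO:0000003"):
            assert term_similarity(t, t, chain, W) == pytest.approx(1.0)

    def test_cross_namespace_is_an_error(self, tmp_path):
        onto = load_ontology(write_obo(tmp_path, [
            stanza("GO:0000001"),
            stanza("GO:0000002", namespace="molecular_function"),
        ]))
        with pytest.raises(ValueError, match="namespace"):
            term_similarity("GO:0000001", "GO:0000002", onto, W)

    def test_chain_value_matches_hand_oracle(self, chain):
        parents = {"GO:0000001": [("GO:0000002", "is_a")],
                   "GO:0000002": [("GO:0000003", "is_a")]}
        expected = wang_term_similarity("GO:0000001", "GO:0000002", parents, WDICT)
        got = term_similarity("GO:0000001", "GO:0000002", chain, W)
        assert got == pytest.approx(expected)
        # hand value: shared {B, C}; S_A = {A:1, B:.8, C:.64}, S_B = {B:1, C:.8}
        assert got == pytest.approx((0.8 + 1.0 + 0.64 + 0.8) / (2.44 + 1.8))


def _random_dag_fixture(rng, n_terms):
    """Random DAG (terms 0..n-1, edges only towards lower ids) in OBO text."""
    parents: dict[str, list[tuple[str, str]]] = {}
    stanzas = [stanza("GO:0000000")]
    for i in range(1, n_terms):
        term = f"GO:{i:07d}"
        n_parents = int(rng.integers(1, min(i, 3) + 1))
        chosen = rng.choice(i, size=n_parents, replace=False)
        is_a, part_of = [], []
        for p in chosen:
            pid = f"GO:{p:07d}"
            rel = "is_a" if rng.random() < 0.7 else "part_of"
            (is_a if rel == "is_a" else part_of).append(pid)
            parents.setdefault(term, []).append((pid, rel))
        stanzas.append(stanza(term, is_a=is_a, part_of=part_of))
    return stanzas, parents


class TestOracleEquivalenceOnRandomDags:
    def test_s_values_and_similarities_match_brute_force(self, tmp_path):
        rng = np.random.default_rng(2024)
        for rep in range(10):
            n_terms = int(rng.integers(5, 16))
            stanzas, parents = _random_dag_fixture(rng, n_terms)
            onto = load_ontology(write_obo(tmp_path, stanzas))
            terms = sorted(onto.graph.nodes)
            for t in terms:
                assert s_values(t, onto, W) == pytest.approx(
                    enumerate_s_values(t, parents, WDICT)
                )
            for t1, t2 in itertools.combinations(terms, 2):
                got = term_similarity(t1, t2, onto, W)
                expected = wang_term_similarity(t1, t2, parents, WDICT)
                assert got == pytest.approx(expected)
                assert got == pytest.approx(term_similarity(t2, t1, onto, W))
                assert 0.0 <= got <= 1.0


class TestGeneSimilarity:
    def make_ann(self, gene, terms, ns="biological_process", evidence="EXP"):
        ann = TermAnnotationSet(gene)
        for t in terms:
            ann.add(ns, t, evidence)
        return ann

    def test_identical_single_term_annotations(self, chain):
        a = self.make_ann("gA", ["GO:0000001"])
        b = self.make_ann("gB", ["GO:0000001"])
        assert gene_similarity(a, b, "biological_process", chain, W) == pytest.approx(1.0)

    def test_best_match_average_matches_oracle(self, chain):
        parents = {"GO:0000001": [("GO:0000002", "is_a")],
                   "GO:0000002": [("GO:0000003", "is_a")]}
        a = self.make_ann("gA", ["GO:0000001"])
        b = self.make_ann("gB", ["GO:0000001", "GO:0000002"])
        got = gene_similarity(a, b, "biological_process", chain, W)
        expected = wang_gene_similarity(
            ["GO:0000001"], ["GO:0000001", "GO:0000002"], parents, WDICT
        )
        assert got == pytest.approx(expected)

    def test_unannotated_gene_not_comparable(self, chain):
        a = self.make_ann("gA", ["GO:0000001"])
        b = TermAnnotationSet("gB")
        assert gene_similarity(a, b, "biological_process", chain, W) is None


class TestGroupSemanticSimilarity:
    def test_identically_annotated_pair_scores_one_everywhere(self, chain):
        anns = {
            g: TermAnnotationSet(g, {"biological_process": {("GO:0000001", "EXP")}})
            for g in ("gA", "gB")
        }
        result = group_semantic_similarity("grp", ["gA", "gB"], anns, chain, W)
        assert result.pairwise["biological_process"][("gA", "gB")] == pytest.approx(1.0)
        assert result.iea_proportion == 0.0

    def test_all_iea_annotations_reported(self, chain):
        anns = {
            g: TermAnnotationSet(g, {"biological_process": {("GO:0000001", "IEA")}})
            for g in ("gA", "gB")
        }
        result = group_semantic_similarity("grp", ["gA", "gB"], anns, chain, W)
        assert result.iea_proportion == 1.0

    def test_group_over_cap_skipped(self, chain):
        members = [f"g{i}" for i in range(16)]
        result = group_semantic_similarity("grp", members, {}, chain, W)
        assert result.skipped_reason and "cap" in result.skipped_reason


class TestReadAnnotations:
    def test_not_qualifier_dropped_and_aspects_mapped(self, tmp_path, chain):
        path = tmp_path / "ann.tsv"
        path.write_text(
            "gene_id\tterm_id\tevidence\taspect\tqualifier\n"
            "gA\tGO:0000001\tEXP\tP\t\n"
            "gA\tGO:0000002\tIEA\tP\tNOT\n"
        )
        anns = read_annotations(path, chain)
        assert anns["gA"].terms("biological_process") == {"GO:0000001"}

    def test_terms_missing_from_ontology_dropped(self, tmp_path, chain):
        path = tmp_path / "ann.tsv"
        path.write_text("gA\tGO:9999999\tEXP\tP\n")
        assert read_annotations(path, chain) == {}


class TestGeneratedOntologyFixture:
    def test_clustered_genes_more_similar_than_uniform(self, tmp_path):
        spec = FixtureSpec(seed=4, ontology_depth=3, ontology_branching=2)
        groups = [[f"d{i}a", f"d{i}b"] for i in range(12)]
        background = [f"r{i}" for i in range(24)]
        fixture = generate_ontology(spec, groups, background)
        out = tmp_path / "fx"
        out.mkdir()
        (out / "t.obo").write_text(fixture.obo_text)
        (out / "t.gaf").write_text(fixture.gaf_text)
        onto = load_ontology(out / "t.obo")
        anns = read_annotations(out / "t.gaf", onto)

        def mean_bp(pairs):
            values = [
                gene_similarity(anns[a], anns[b], "biological_process", onto, W)
                for a, b in pairs
            ]
            return float(np.mean([v for v in values if v is not None]))

        clustered = mean_bp([(g[0], g[1]) for g in groups])
        rng = np.random.default_rng(0)
        uniform = mean_bp(
            [tuple(rng.choice(background, size=2, replace=False)) for _ in range(50)]
        )
        assert clustered > uniform
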