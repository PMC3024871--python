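"""Similarity graph construction, Con scoring, heuristic vs exact labeling."""

import numpy as np
import pytest

from hlagraph.graph_labeling import (
    ConstraintEdge,
    Labeling,
    SimilarityGraph,
    brute_force_label,
    build_graph,
    con_score,
    heu_label,
    is_feasible,
    sparsify,
)
from hlagraph.similarity import cached_similarity


def random_graph(rng, n_het, n_hom=0, n_free=0, n_alleles=3):
    """Random weights; het/hom constraint edges; optional free vertices."""
    n = 2 * (n_het + n_hom) + n_free
    w = rng.random((n, n))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0.0)
    alleles = [f"{a + 1:02d}01" for a in range(n_alleles)]
    constraints = []
    v = 0
    for _ in range(n_het):
        pair = tuple(sorted(rng.choice(alleles, size=2, replace=False)))
        constraints.append(ConstraintEdge(v, v + 1, pair))
        v += 2
    for _ in range(n_hom):
        a = rng.choice(alleles)
        constraints.append(ConstraintEdge(v, v + 1, (a, a)))
        v += 2
    vertices = [(f"i{k // 2}", k % 2) for k in range(n)]
    return SimilarityGraph(vertices, w, constraints)


def test_worked_example_graph(worked_fixture):
    """Two typed individuals {0201,0101} and {0201,2401}: four vertices,
    two heterozygous constraint edges, six similarity edges."""
    pop = worked_fixture.population
    haps = {i: worked_fixture.true_haplotypes[i] for i in ("I1", "I2")}
    graph = build_graph(haps, pop.hla.types, t_mis=2)
    assert graph.n_vertices == 4
    assert len(graph.constraints) == 2
    assert all(not c.homozygous for c in graph.constraints)
    off_diag = np.triu(np.ones((4, 4), bool), 1)
    assert off_diag.sum() == 6
    # the shared 0201 background carries the highest cross-individual weight
    v = graph.vertex_index
    assert graph.weights[v[("I1", 0)], v[("I2", 0)]] == max(
        graph.weights[v[("I1", 0)], v[("I2", k)]] for k in (0, 1)
    )


def test_weights_match_pairwise_similarity(worked_fixture):
    haps = worked_fixture.true_haplotypes
    graph = build_graph(haps, {}, t_mis=2)
    flat = [haps[i][c] for i in sorted(haps) for c in (0, 1)]
    for a in range(len(flat)):
        for b in range(len(flat)):
            if a != b:
                expected = cached_similarity(flat[a], flat[b], 2)
                assert graph.weights[a, b] == pytest.approx(expected)


def test_homozygous_typed_individual_gets_homozygous_edge():
    rng = np.random.default_rng(0)
    g = random_graph(rng, n_het=0, n_hom=1)
    assert g.constraints[0].homozygous


def test_con_score_examples():
    w = np.zeros((3, 3))
    w[0, 1] = w[1, 0] = 0.5
    w[0, 2] = w[2, 0] = 0.2
    w[1, 2] = w[2, 1] = 0.3
    g = SimilarityGraph([("a", 0), ("a", 1), ("b", 0)], w, [])
    assert con_score(g, Labeling(["x", "x", "x"])) == pytest.approx(1.0)
    assert con_score(g, Labeling(["x", "y", "z"])) == 0.0
    assert con_score(g, Labeling(["x", "x", None])) == pytest.approx(0.5)


def test_con_score_matches_pair_summation_oracle():
    rng = np.random.default_rng(1)
    for _ in range(30):
        g = random_graph(rng, n_het=3, n_free=2)
        labels = [
            rng.choice(["0101", "0201", None]) for _ in range(g.n_vertices)
        ]
        lab = Labeling(list(labels))
        expected = sum(
            g.weights[a, b]
            for a in range(g.n_vertices)
            for b in range(a + 1, g.n_vertices)
            if labels[a] is not None and labels[a] == labels[b]
        )
        assert con_score(g, lab) == pytest.approx(expected)


def test_sparsify_thresholds():
    rng = np.random.default_rng(2)
    g = random_graph(rng, n_het=2)
    full = sparsify(g, 0.0)
    assert full.mask().sum() == g.n_vertices * (g.n_vertices - 1)
    empty = sparsify(g, 1.01 * g.weights.max())
    assert empty.mask().sum() == 0
    mid = sparsify(g, 0.65)
    expected = (g.weights >= 0.65).sum() - np.diag(g.weights >= 0.65).sum()
    assert mid.mask().sum() == expected
    assert mid.n_vertices == g.n_vertices


def test_heu_label_homozygous_seeding():
    rng = np.random.default_rng(3)
    g = random_graph(rng, n_het=0, n_hom=1)
    lab = heu_label(g, 0.65)
    a = g.constraints[0].alleles[0]
    assert lab.labels[0] == lab.labels[1] == a


def test_heu_label_orients_with_neighbors():
    # het edge {a, b}; vertex 0 ties strongly to an a-labeled vertex and
    # vertex 1 to a b-labeled vertex
    w = np.zeros((6, 6))
    w[0, 2] = w[2, 0] = 0.9  # vertex 2: hom a
    w[1, 4] = w[4, 1] = 0.9  # vertex 4: hom b
    g = SimilarityGraph(
        [(f"i{k}", s) for k in range(3) for s in (0, 1)],
        w,
        [
            ConstraintEdge(0, 1, ("a", "b")),
            ConstraintEdge(2, 3, ("a", "a")),
            ConstraintEdge(4, 5, ("b", "b")),
        ],
    )
    lab = heu_label(g, 0.65)
    assert lab.labels[0] == "a" and lab.labels[1] == "b"
    alt = Labeling(["b", "a", "a", "a", "b", "b"])
    assert con_score(g, lab) >= con_score(g, alt)


def test_no_constraints_means_no_labels():
    rng = np.random.default_rng(4)
    g = random_graph(rng, n_het=0, n_free=6)
    lab = heu_label(g, 0.65)
    assert lab.labels == [None] * 6


def test_brute_force_tie_on_single_symmetric_edge():
    w = np.zeros((2, 2))
    g = SimilarityGraph(
        [("i", 0), ("i", 1)], w, [ConstraintEdge(0, 1, ("a", "b"))]
    )
    lab = brute_force_label(g)
    assert sorted(lab.labels) == ["a", "b"]
    assert con_score(g, lab) == 0.0


def test_brute_force_refuses_large_instances():
    rng = np.random.default_rng(5)
    g = random_graph(rng, n_het=16)
    with pytest.raises(ValueError, match="too large"):
        brute_force_label(g)


def test_heu_label_feasible_and_dominated_by_brute_force():
    rng = np.random.default_rng(6)
    for _ in range(60):
        g = random_graph(
            rng,
            n_het=int(rng.integers(1, 5)),
            n_hom=int(rng.integers(0, 2)),
            n_free=int(rng.integers(0, 3)),
        )
        lab = heu_label(g, float(rng.uniform(0.3, 0.9)))
        assert is_feasible(g, lab)
        best = brute_force_label(g)
        assert is_feasible(g, best)
        assert con_score(g, lab) <= con_score(g, best) + 1e-9
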