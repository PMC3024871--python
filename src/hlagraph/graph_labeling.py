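"""Weighted haplotype-similarity graph and constrained HLA labeling.

Every haplotype of every individual is a vertex (two vertices per
individual, one per chromosome copy).  Between every vertex pair there
is a similarity edge weighted by the haplotype similarity measure; the
two vertices of each HLA-typed individual are additionally joined by a
*constraint edge* carrying that individual's unordered allele pair
{alpha, beta} (homozygous when alpha == beta).

A labeling maps vertices to allele names (or leaves them unlabeled);
it is *feasible* when the two endpoint labels of every constraint edge
are exactly its allele pair.  Labelings are scored by

    Con(l) = sum of similarity weights over vertex pairs with the same
             (non-empty) label,

the total weight concentrated within same-allele classes.  Different
HLA alleles ride on different SNP haplotype backgrounds, so the optimal
feasible labeling groups haplotypes into their allele classes.

Exact maximization is exponential in the number of heterozygous
constraint edges; :func:`heu_label` is the production heuristic and
:func:`brute_force_label` the exact reference for small instances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .similarity import DEFAULT_T_MIS, cached_similarity

#: default weight threshold used for sparsification and call support
DEFAULT_T_S = 0.65

Vertex = tuple[str, int]  # (individual id, chromosome copy 0/1)


@dataclass(frozen=True)
class ConstraintEdge:
    i: int  # vertex indices, i < j
    j: int
    alleles: tuple[str, str]  # sorted

    @property
    def homozygous(self) -> bool:
        return self.alleles[0] == self.alleles[1]


@dataclass
class SimilarityGraph:
    vertices: list[Vertex]
    weights: np.ndarray  # (V, V) symmetric, zero diagonal
    constraints: list[ConstraintEdge]
    edge_mask: np.ndarray | None = None  # None = complete graph
    vertex_index: dict[Vertex, int] = field(init=False)

    def __post_init__(self) -> None:
        self.vertex_index = {v: k for k, v in enumerate(self.vertices)}

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def allele_universe(self) -> list[str]:
        return sorted({a for c in self.constraints for a in c.alleles})

    def mask(self) -> np.ndarray:
        if self.edge_mask is not None:
            return self.edge_mask
        m = np.ones_like(self.weights, dtype=bool)
        np.fill_diagonal(m, False)
        return m


@dataclass
class Labeling:
    """Partial vertex -> allele map; ``None`` denotes unlabeled."""

    labels: list[str | None]

    def groups(self) -> dict[str, np.ndarray]:
        out: dict[str, list[int]] = {}
        for k, a in enumerate(self.labels):
            if a is not None:
                out.setdefault(a, []).append(k)
        return {a: np.array(ix) for a, ix in out.items()}

    def copy(self) -> "Labeling":
        return Labeling(list(self.labels))


def build_graph(
    haplotypes: dict[str, tuple[np.ndarray, np.ndarray]],
    hla_types: dict[str, tuple[str, str] | None],
    t_mis: int = DEFAULT_T_MIS,
    order: list[str] | None = None,
) -> SimilarityGraph:
    """Construct the weighted similarity graph of a haplotype set.

    ``hla_types`` supplies constraint edges for typed individuals only;
    untyped individuals (``None``) contribute vertices and similarity
    edges but no constraint.
    """
    iids = order if order is not None else sorted(haplotypes)
    vertices: list[Vertex] = []
    haps: list[np.ndarray] = []
    for iid in iids:
        h0, h1 = haplotypes[iid]
        vertices.extend([(iid, 0), (iid, 1)])
        haps.extend([h0, h1])
    n = len(vertices)
    weights = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            w = cached_similarity(haps[a], haps[b], t_mis)
            weights[a, b] = weights[b, a] = w
    constraints = []
    for k, iid in enumerate(iids):
        pair = hla_types.get(iid)
        if pair is not None:
            constraints.append(ConstraintEdge(2 * k, 2 * k + 1, tuple(sorted(pair))))
    return SimilarityGraph(vertices, weights, constraints)


def is_feasible(graph: SimilarityGraph, labeling: Labeling) -> bool:
    for c in graph.constraints:
        got = tuple(
            sorted(x for x in (labeling.labels[c.i], labeling.labels[c.j]) if x)
        )
        if got != c.alleles:
            return False
    return True


def con_score(graph: SimilarityGraph, labeling: Labeling) -> float:
    """Total similarity weight within same-label vertex classes."""
    mask = graph.edge_mask
    total = 0.0
    for _, idx in labeling.groups().items():
        if idx.size < 2:
            continue
        sub = graph.weights[np.ix_(idx, idx)]
        if mask is not None:
            sub = sub * mask[np.ix_(idx, idx)]
        total += sub.sum() / 2.0  # diagonal is zero
    return float(total)


def sparsify(graph: SimilarityGraph, t_s: float) -> SimilarityGraph:
    """Retain similarity edges with weight >= ``t_s`` (vertices kept)."""
    if not 0.0 <= t_s <= 1.0:
        raise ValueError("t_s must lie in [0, 1]")
    mask = graph.weights >= t_s
    np.fill_diagonal(mask, False)
    return SimilarityGraph(graph.vertices, graph.weights, graph.constraints, mask)


# ---------------------------------------------------------------------------
# heuristic labeling


def heu_label(graph: SimilarityGraph, t_s: float = DEFAULT_T_S) -> Labeling:
    """Feasible labeling by seeded component propagation (see
    :func:`heu_label_scored`; this wrapper drops the score)."""
    return heu_label_scored(graph, t_s)[0]


def heu_label_scored(
    graph: SimilarityGraph, t_s: float = DEFAULT_T_S
) -> tuple[Labeling, float]:
    """Feasible labeling by seeded component propagation.

    1. label both endpoints of every homozygous constraint edge
       (unambiguous);
    2. sparsify at ``t_s`` and find connected components of the sparse
       similarity graph;
    3. per component, in decreasing order of total internal weight,
       orient each incident heterozygous constraint edge (processed in
       decreasing max-incident-weight order) so that the incremental
       contribution to Con against already-labeled vertices is largest,
       ties to the lexicographically smaller allele on the lower vertex;
    4. unconstrained vertices adopt their component's weight-weighted
       majority label; components without labels stay unlabeled.

    The output is always feasible: each constraint edge receives exactly
    its allele pair.  Returns the labeling together with its Con value
    on the complete graph (recovered from the running support totals at
    no extra cost).
    """
    n = graph.n_vertices
    W = graph.weights
    labels: list[str | None] = [None] * n
    alleles = graph.allele_universe
    aidx = {a: k for k, a in enumerate(alleles)}
    # running per-allele support: S[v, a] = total W weight from v to
    # vertices currently labeled a
    S = np.zeros((n, len(alleles)))
    mask = W >= t_s
    np.fill_diagonal(mask, False)
    wsp = np.where(mask, W, 0.0)

    def assign(v: int, a: str) -> None:
        labels[v] = a
        S[:, aidx[a]] += W[:, v]

    for c in graph.constraints:
        if c.homozygous:
            assign(c.i, c.alleles[0])
            assign(c.j, c.alleles[0])

    n_comp, comp = connected_components(csr_matrix(mask), directed=False)
    comp_weight = np.bincount(comp, weights=wsp.sum(axis=1), minlength=n_comp) / 2.0
    comp_order = sorted(range(n_comp), key=lambda k: (-comp_weight[k], k))

    het = [c for c in graph.constraints if not c.homozygous]
    rowmax = wsp.max(axis=1) if n else np.zeros(0)
    edges_of: dict[int, list[ConstraintEdge]] = {}
    for c in het:
        edges_of.setdefault(int(comp[c.i]), []).append(c)
        if comp[c.j] != comp[c.i]:
            edges_of.setdefault(int(comp[c.j]), []).append(c)

    oriented: set[ConstraintEdge] = set()
    for k in comp_order:
        in_comp = [c for c in edges_of.get(k, ()) if c not in oriented]
        in_comp.sort(key=lambda c: (-max(rowmax[c.i], rowmax[c.j]), c.i, c.j))
        for c in in_comp:
            a, b = c.alleles
            fwd = S[c.i, aidx[a]] + S[c.j, aidx[b]]
            rev = S[c.i, aidx[b]] + S[c.j, aidx[a]]
            # tie -> lexicographically smaller allele on the lower vertex
            if rev > fwd:
                assign(c.i, b)
                assign(c.j, a)
            else:
                assign(c.i, a)
                assign(c.j, b)
            oriented.add(c)

    constrained = {v for c in graph.constraints for v in (c.i, c.j)}
    if alleles and len(constrained) < n:
        labeled_cols = {
            a: [v for v in range(n) if labels[v] == a] for a in alleles
        }
        for k in range(n_comp):
            idx = np.nonzero(comp == k)[0]
            pending = [v for v in idx if labels[v] is None and v not in constrained]
            if not pending:
                continue
            # sparse edges never cross components, so restricting the
            # columns to each label class gives the weighted votes
            votes = np.array(
                [
                    wsp[np.ix_(idx, labeled_cols[a])].sum() if labeled_cols[a] else 0.0
                    for a in alleles
                ]
            )
            if votes.max() <= 0.0:
                continue
            best = alleles[int(np.argmax(votes))]  # first max: smallest allele
            for v in pending:
                labels[v] = best
                S[:, aidx[best]] += W[:, v]

    # Con on the full graph: S[v, a] already totals the weight from v to
    # the a-labeled class, so summing it over the class double-counts
    # each within-class pair exactly once
    con = 0.5 * sum(S[v, aidx[a]] for v, a in enumerate(labels) if a is not None)
    return Labeling(labels), float(con)


# ---------------------------------------------------------------------------
# exact reference


def brute_force_label(
    graph: SimilarityGraph,
    max_het: int = 15,
    max_states: int = 1 << 18,
) -> Labeling:
    """Globally Con-maximal feasible labeling by exhaustive search.

    Orientations of heterozygous constraint edges and assignments of
    unconstrained vertices (over the allele universe plus unlabeled) are
    enumerated; intended as a test oracle and guarded against large
    instances.
    """
    het = [c for c in graph.constraints if not c.homozygous]
    constrained = {v for c in graph.constraints for v in (c.i, c.j)}
    unconstrained = [v for v in range(graph.n_vertices) if v not in constrained]
    alleles = graph.allele_universe
    states = (1 << len(het)) * (len(alleles) + 1) ** len(unconstrained)
    if len(het) > max_het or states > max_states:
        raise ValueError(f"instance too large for brute force ({states} states)")

    base: list[str | None] = [None] * graph.n_vertices
    for c in graph.constraints:
        if c.homozygous:
            base[c.i] = base[c.j] = c.alleles[0]

    best: Labeling | None = None
    best_con = -1.0
    for orient in product((0, 1), repeat=len(het)):
        mid = list(base)
        for c, o in zip(het, orient):
            a, b = c.alleles
            mid[c.i], mid[c.j] = (a, b) if o == 0 else (b, a)
        for extra in product([None, *alleles], repeat=len(unconstrained)):
            cand = list(mid)
            for v, a in zip(unconstrained, extra):
                cand[v] = a
            lab = Labeling(cand)
            con = con_score(graph, lab)
            if con > best_con:
                best_con, best = con, lab
    assert best is not None
    return best
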