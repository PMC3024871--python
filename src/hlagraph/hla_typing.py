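"""Calling HLA types for untyped individuals, and evaluation harnesses.

Once the graph is labeled, an untyped individual ``I`` with haplotype
vertices ``V1`` and ``V2`` is called from its strongest labeled
neighbors: ``w_m(v)`` is the largest similarity-edge weight from ``v``
to any labeled vertex and ``L(v)`` the set of labels attaining it.  If
either ``w_m`` falls below the support threshold ``t_s`` the individual
is a no-call.  A unique candidate labels the chromosome directly;
ambiguous candidate sets are resolved by the allele pair maximizing the
summed best supporting weights over both pairings of the pair onto the
two chromosomes.  Called individuals are labeled into the graph
immediately, so later calls can lean on earlier ones (processing order
is the roster order, which makes runs deterministic).

Evaluation counts chromosomes, not individuals: coverage is the
fraction of analyzed chromosomes receiving a call and accuracy the
fraction of called chromosomes called correctly, with truth alleles
that are unresolved at the requested resolution or occur only once in
the data excluded from the analysis up front.  Called/truth pairs are
compared unordered via their best bipartite agreement.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .graph_labeling import DEFAULT_T_S, Labeling, SimilarityGraph
from .io_formats import Population, truncate_allele


@dataclass(frozen=True)
class Call:
    iid: str
    alleles: tuple[str, str] | None  # per-chromosome order (V1, V2)
    support: tuple[float, float]
    status: str  # "called" | "no_call" | "known"


@dataclass
class HLACallSet:
    calls: dict[str, Call]

    def __getitem__(self, iid: str) -> Call:
        return self.calls[iid]


@dataclass
class EvalMetrics:
    n_analyzed: int
    n_called: int
    n_correct: int

    @property
    def coverage(self) -> float | None:
        if self.n_analyzed == 0:
            return None
        return 100.0 * self.n_called / self.n_analyzed

    @property
    def accuracy(self) -> float | None:
        if self.n_called == 0:
            return None
        return 100.0 * self.n_correct / self.n_called

    def __add__(self, other: "EvalMetrics") -> "EvalMetrics":
        return EvalMetrics(
            self.n_analyzed + other.n_analyzed,
            self.n_called + other.n_called,
            self.n_correct + other.n_correct,
        )


# ---------------------------------------------------------------------------
# calling


def neighbor_labels(
    graph: SimilarityGraph,
    labeling: Labeling,
    v: int,
    exclude: frozenset[int] = frozenset(),
) -> tuple[float, set[str]]:
    """Best labeled-neighbor weight and the labels attaining it.

    Only labeled vertices count: a maximum weight achieved solely by
    unlabeled vertices would pass the support threshold while offering
    no candidate allele.  Returns ``(0.0, set())`` when no labeled
    vertex is reachable.
    """
    w = graph.weights[v]
    best = 0.0
    labels: set[str] = set()
    for u, a in enumerate(labeling.labels):
        if a is None or u == v or u in exclude:
            continue
        if w[u] > best + 1e-12:
            best, labels = float(w[u]), {a}
        elif abs(w[u] - best) <= 1e-12 and best > 0:
            labels.add(a)
    return best, labels


def _pair_weight(
    graph: SimilarityGraph, labeling: Labeling, v1: int, v2: int, g1: str, g2: str,
    exclude: frozenset[int],
) -> float:
    def support(v: int, g: str) -> float:
        w = graph.weights[v]
        best = 0.0
        for u, a in enumerate(labeling.labels):
            if a == g and u != v and u not in exclude:
                best = max(best, float(w[u]))
        return best

    return max(
        support(v1, g1) + support(v2, g2),
        support(v1, g2) + support(v2, g1),
    )


def hla_type(
    graph: SimilarityGraph,
    labeling: Labeling,
    untyped: list[str],
    t_s: float = DEFAULT_T_S,
) -> tuple[HLACallSet, Labeling]:
    """Call every untyped individual from the labeled graph.

    Individuals are processed in the given order; each call labels its
    two vertices so subsequent calls may use them as references.  An
    individual's own vertices never count as their own evidence (the
    component-majority step of the labeling heuristic may have labeled
    them, but such self-support would be circular).
    """
    labeling = labeling.copy()
    calls: dict[str, Call] = {}
    for iid in untyped:
        v1 = graph.vertex_index[(iid, 0)]
        v2 = graph.vertex_index[(iid, 1)]
        own = frozenset((v1, v2))
        # clear any component-majority labels on own vertices
        labeling.labels[v1] = labeling.labels[v2] = None
        w1, l1 = neighbor_labels(graph, labeling, v1, exclude=own)
        w2, l2 = neighbor_labels(graph, labeling, v2, exclude=own)
        if w1 < t_s or w2 < t_s or not l1 or not l2:
            calls[iid] = Call(iid, None, (w1, w2), "no_call")
            continue
        if len(l1) == 1 and len(l2) == 1:
            g1, g2 = next(iter(l1)), next(iter(l2))
        else:
            cands = sorted((g1, g2) for g1 in l1 for g2 in l2)
            scored = [
                (_pair_weight(graph, labeling, v1, v2, g1, g2, own), g1, g2)
                for g1, g2 in cands
            ]
            best = max(s for s, _, _ in scored)
            g1, g2 = next((g1, g2) for s, g1, g2 in scored if s >= best - 1e-12)
        labeling.labels[v1], labeling.labels[v2] = g1, g2
        calls[iid] = Call(iid, (g1, g2), (w1, w2), "called")
    return HLACallSet(calls), labeling


# ---------------------------------------------------------------------------
# metrics


def _allele_counts(truth: dict[str, tuple[str, str] | None], resolution: int) -> Counter:
    counts: Counter = Counter()
    for pair in truth.values():
        if pair is None:
            continue
        for a in pair:
            t = truncate_allele(a, resolution)
            if t is not None:
                counts[t] += 1
    return counts


def compute_metrics(
    truth: dict[str, tuple[str, str] | None],
    calls: HLACallSet,
    resolution: int = 4,
    evaluated: list[str] | None = None,
) -> EvalMetrics:
    """Chromosome-level coverage/accuracy of a call set against truth.

    ``truth`` is the full known table (used for the singleton filter);
    ``evaluated`` restricts scoring to the individuals whose types were
    actually masked and re-inferred (defaults to all of ``calls``).
    """
    counts = _allele_counts(truth, resolution)
    if evaluated is None:
        evaluated = list(calls.calls)
    n_analyzed = n_called = n_correct = 0
    for iid in evaluated:
        pair = truth.get(iid)
        if pair is None:
            continue
        t = [truncate_allele(a, resolution) for a in pair]
        incl = [a is not None and counts[a] > 1 for a in t]
        n_analyzed += sum(incl)
        call = calls.calls.get(iid)
        if call is None or call.alleles is None:
            continue
        c = [truncate_allele(a, resolution) for a in call.alleles]
        straight = sum(incl[k] and c[k] == t[k] for k in range(2))
        crossed = sum(incl[k] and c[1 - k] == t[k] for k in range(2))
        n_called += sum(incl)
        n_correct += max(straight, crossed)
    return EvalMetrics(n_analyzed, n_called, n_correct)


# ---------------------------------------------------------------------------
# cross-validation harnesses


def leave_one_out(
    population: Population, config, collect_calls: bool = False
):
    """Mask each typed individual in turn, re-infer, aggregate metrics.

    The marker window and pedigree solution spaces do not depend on the
    HLA table, so they are prepared once and shared across folds.
    """
    from .pipeline import prepare, run_wsg_hi

    prepared = prepare(population, config)
    truth = {i: t for i, t in population.hla.types.items() if t is not None}
    all_calls: dict[str, Call] = {}
    for iid in sorted(truth):
        masked = population.hla.masked([iid])
        callset, _ = run_wsg_hi(
            population, config, hla_override=masked, prepared=prepared
        )
        all_calls[iid] = callset[iid]
    callset = HLACallSet(all_calls)
    metrics = compute_metrics(truth, callset, config.resolution, sorted(truth))
    return (metrics, callset) if collect_calls else metrics


def leave_one_pedigree_out(
    population: Population, config, collect_calls: bool = False
):
    """Mask whole pedigrees in turn (harder: no within-family references)."""
    from .pipeline import prepare, run_wsg_hi

    prepared = prepare(population, config)
    truth = {i: t for i, t in population.hla.types.items() if t is not None}
    all_calls: dict[str, Call] = {}
    for family in sorted(population.pedigrees.families):
        members = [
            i for i in population.pedigrees.families[family] if i in truth
        ]
        if not members:
            continue
        masked = population.hla.masked(members)
        callset, _ = run_wsg_hi(
            population, config, hla_override=masked, prepared=prepared
        )
        for iid in members:
            all_calls[iid] = callset[iid]
    callset = HLACallSet(all_calls)
    metrics = compute_metrics(truth, callset, config.resolution, sorted(all_calls))
    return (metrics, callset) if collect_calls else metrics
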