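"""Incremental selection of one haplotype configuration per pedigree.

Pedigrees are processed in ascending order of phase ambiguity ``f``.
Unambiguous pedigrees (``f = 0``) seed the similarity graph; each
remaining pedigree is committed by choosing, among its ``2**f``
zero-recombinant configurations, the one whose addition to the graph
maximizes the Con objective after re-labeling.  Small spaces are
enumerated exhaustively; large ones (``f > t_c``) are searched with a
genetic algorithm over the free-variable bit vectors, whose fitness is
exactly the Con of the instantiated configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .graph_labeling import (
    DEFAULT_T_S,
    ConstraintEdge,
    Labeling,
    SimilarityGraph,
    heu_label_scored,
)
from .similarity import DEFAULT_T_MIS, cached_similarity


@dataclass(frozen=True)
class GAParams:
    """Genetic-algorithm settings for large solution spaces.

    Defaults: population 400, 50 generations, crossover rate 0.8,
    per-offspring mutation rate 0.2, enumeration gate ``t_c = 10``
    (spaces with at most ``2**10`` solutions are enumerated instead).
    """

    p_s: int = 400
    g_m: int = 50
    r_c: float = 0.8
    r_m: float = 0.2
    t_c: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p_s <= 0:
            raise ValueError("population size must be positive")
        if not (0 <= self.r_c <= 1 and 0 <= self.r_m <= 1):
            raise ValueError("rates must lie in [0, 1]")


@dataclass
class SearchState:
    """Accumulated haplotype set, its graph, and the current labeling."""

    t_mis: int = DEFAULT_T_MIS
    t_s: float = DEFAULT_T_S
    iids: list[str] = field(default_factory=list)
    haplotypes: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    hla_types: dict[str, tuple[str, str] | None] = field(default_factory=dict)
    weights: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    labeling: Labeling | None = None
    con: float = 0.0

    def graph(self) -> SimilarityGraph:
        return _graph_for(self.iids, self.weights, self.hla_types)


def _graph_for(iids, weights, hla_types) -> SimilarityGraph:
    vertices = [(iid, c) for iid in iids for c in (0, 1)]
    constraints = []
    for k, iid in enumerate(iids):
        pair = hla_types.get(iid)
        if pair is not None:
            constraints.append(ConstraintEdge(2 * k, 2 * k + 1, tuple(sorted(pair))))
    return SimilarityGraph(vertices, weights, constraints)


def order_pedigrees(spaces: list) -> list:
    """Ascending by free-variable count ``f``; stable on ties."""
    return sorted(spaces, key=lambda s: s.f)


#: similarity rows against a committed vertex set, keyed by
#: (committed-set fingerprint, t_mis, candidate haplotype bytes); the
#: same searches recur across cross-validation folds, so this cache is
#: shared process-wide (cleared when it grows past the cap)
_ROW_CACHE: dict[tuple, np.ndarray] = {}
_ROW_CACHE_CAP = 200_000


def _state_token(state: SearchState) -> tuple:
    payload = b"".join(
        state.haplotypes[i][c].tobytes() for i in state.iids for c in (0, 1)
    )
    return (tuple(state.iids), state.t_mis, hash(payload))


def _extend_weights(
    state: SearchState,
    new_haps: list[np.ndarray],
    row_cache: tuple | None = None,
) -> np.ndarray:
    """Weight matrix for committed + candidate vertices.

    Candidate haplotypes recur heavily across the assignments of one
    solution space (and across cross-validation folds), so the row of
    similarities against the committed set is cached by content.
    """
    old = [state.haplotypes[i][c] for i in state.iids for c in (0, 1)]
    n_old, n_new = len(old), len(new_haps)
    n = n_old + n_new
    W = np.zeros((n, n))
    W[:n_old, :n_old] = state.weights
    if len(_ROW_CACHE) > _ROW_CACHE_CAP:
        _ROW_CACHE.clear()
    for a in range(n_new):
        ha = new_haps[a]
        key = None if row_cache is None else (row_cache, ha.tobytes())
        row = None if key is None else _ROW_CACHE.get(key)
        if row is None:
            row = np.array(
                [cached_similarity(ha, hb, state.t_mis) for hb in old]
            )
            if key is not None:
                _ROW_CACHE[key] = row
        W[n_old + a, :n_old] = row
        W[:n_old, n_old + a] = row
        for b in range(a + 1, n_new):
            w = cached_similarity(ha, new_haps[b], state.t_mis)
            W[n_old + a, n_old + b] = W[n_old + b, n_old + a] = w
    return W


def evaluate_candidate(
    state: SearchState,
    config: dict[str, tuple[np.ndarray, np.ndarray]],
    row_cache: tuple | None = None,
    template: SimilarityGraph | None = None,
):
    """Con of the graph extended with one candidate configuration.

    ``template`` may carry the (candidate-independent) vertex and
    constraint structure of the extended graph; only its weight matrix
    is swapped per candidate.
    """
    new_ids = sorted(config)
    if not set(new_ids).isdisjoint(state.iids):
        raise ValueError("candidate pedigree reuses committed individual ids")
    new_haps = [config[i][c] for i in new_ids for c in (0, 1)]
    W = _extend_weights(state, new_haps, row_cache)
    if template is None:
        graph = _graph_for(state.iids + new_ids, W, state.hla_types)
    else:
        graph = template
        graph.weights = W
    labeling, con = heu_label_scored(graph, state.t_s)
    return con, labeling, W, new_ids


def _commit(state: SearchState, config, con, labeling, W, new_ids) -> SearchState:
    haps = dict(state.haplotypes)
    haps.update(config)
    return replace(
        state,
        iids=state.iids + new_ids,
        haplotypes=haps,
        weights=W,
        labeling=labeling,
        con=con,
    )


def seed_unique(state: SearchState, spaces: list) -> SearchState:
    """Commit every ``f = 0`` pedigree at once and label the seed graph.

    With no unambiguous pedigree the search starts from an empty graph
    and the first ambiguous pedigree is scored on its own similarities
    and constraints alone.
    """
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for space in spaces:
        if space.f != 0:
            raise ValueError("seed_unique expects only f = 0 spaces")
        merged.update(space.instantiate(np.zeros(0, dtype=bool)))
    if not merged:
        return state
    con, labeling, W, new_ids = evaluate_candidate(state, merged)
    return _commit(state, merged, con, labeling, W, new_ids)


def enum_alg(state: SearchState, space) -> tuple[SearchState, dict]:
    """Exhaustive scan of a pedigree's solution space.

    Commits the first-enumerated configuration attaining the maximal
    Con (lexicographic bit-vector order breaks ties deterministically).
    """
    best = None
    row_cache = _state_token(state)
    template = _graph_for(
        state.iids + sorted(space.member_ids), None, state.hla_types
    )
    for bits in space.assignments():
        config = space.instantiate(bits)
        con, labeling, W, new_ids = evaluate_candidate(
            state, config, row_cache, template
        )
        if best is None or con > best[0]:
            best = (con, config, labeling, W, new_ids, bits.copy())
    assert best is not None
    con, config, labeling, W, new_ids, bits = best
    info = {"method": "enum", "f": space.f, "con": con, "bits": bits}
    return _commit(state, config, con, labeling, W, new_ids), info


def genetic_alg(
    state: SearchState, space, params: GAParams
) -> tuple[SearchState, dict]:
    """Genetic search over the free-variable bit vectors.

    Chromosome fitness is the Con of the instantiated configuration
    (memoized per bit vector).  Each generation draws half the parents
    by size-2 tournament and half by roulette wheel on min-shifted
    fitness, applies single-point crossover with probability ``r_c``
    and a single-bit mutation with probability ``r_m`` per offspring,
    and carries over one elite.  The best chromosome ever seen is
    committed, so best-so-far fitness is non-decreasing.
    """
    f = space.f
    rng = np.random.default_rng(params.seed)
    memo: dict[tuple[int, ...], float] = {}
    row_cache = _state_token(state)
    template = _graph_for(
        state.iids + sorted(space.member_ids), None, state.hla_types
    )

    def fitness(bits: np.ndarray) -> float:
        key = tuple(int(b) for b in bits)
        if key not in memo:
            config = space.instantiate(np.array(key, dtype=bool))
            memo[key] = evaluate_candidate(state, config, row_cache, template)[0]
        return memo[key]

    pop = rng.integers(0, 2, size=(params.p_s, f)).astype(bool)
    best_bits, best_fit = None, -np.inf
    trajectory: list[float] = []
    for _gen in range(params.g_m):
        fits = np.array([fitness(ind) for ind in pop])
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit:
            best_fit = float(fits[gen_best])
            best_bits = pop[gen_best].copy()
        trajectory.append(best_fit)

        n_tour = params.p_s // 2
        parents = np.empty_like(pop)
        for k in range(n_tour):  # tournament, size 2
            a, b = rng.integers(0, params.p_s, size=2)
            parents[k] = pop[a] if fits[a] >= fits[b] else pop[b]
        shifted = fits - fits.min() + 1e-12  # roulette wheel
        probs = shifted / shifted.sum()
        idx = rng.choice(params.p_s, size=params.p_s - n_tour, p=probs)
        parents[n_tour:] = pop[idx]
        rng.shuffle(parents, axis=0)

        offspring = parents.copy()
        for k in range(0, params.p_s - 1, 2):
            if f > 1 and rng.random() < params.r_c:
                cut = int(rng.integers(1, f))
                offspring[k, cut:], offspring[k + 1, cut:] = (
                    parents[k + 1, cut:].copy(),
                    parents[k, cut:].copy(),
                )
        for k in range(params.p_s):
            if rng.random() < params.r_m:
                offspring[k, int(rng.integers(0, f))] ^= True
        offspring[0] = best_bits  # elitist carryover
        pop = offspring

    config = space.instantiate(best_bits)
    con, labeling, W, new_ids = evaluate_candidate(state, config)
    info = {
        "method": "ga",
        "f": f,
        "con": con,
        "bits": best_bits,
        "trajectory": trajectory,
        "evaluations": len(memo),
    }
    return _commit(state, config, con, labeling, W, new_ids), info
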