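"""End-to-end orchestration: window, phase, search, label, call.

The run proceeds exactly once through:

1. select the marker window around the gene and screen Mendelian
   errors;
2. build the zero-recombinant solution space of every pedigree;
3. sort pedigrees by phase ambiguity ``f`` and seed the similarity
   graph with the unambiguous ones;
4. commit each remaining pedigree's configuration by exhaustive
   enumeration (``f <= t_c``) or genetic search (``f > t_c``),
   maximizing Con incrementally;
5. derive the typed/untyped split and call every untyped individual
   from the labeled graph.

Typed individuals are passed through unchanged -- the method never
re-calls a known type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from . import config_search, pedigree_space
from .config_search import GAParams, SearchState
from .graph_labeling import DEFAULT_T_S, Labeling
from .hla_typing import Call, HLACallSet, hla_type
from .io_formats import Population, clean_mendelian, window_markers
from .similarity import DEFAULT_T_MIS

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    gene_center: int
    window_kb: int = 200
    t_mis: int = DEFAULT_T_MIS
    t_s: float = DEFAULT_T_S
    resolution: int = 4
    ga: GAParams = field(default_factory=GAParams)
    seed: int = 0


@dataclass
class Prepared:
    """Window and solution spaces; independent of the HLA table."""

    window: list[int]
    spaces: dict[str, object]  # family -> SolutionSpace | StitchedSpace


@dataclass
class RunInfo:
    seed: int
    pedigree_log: list[dict]
    ga_used: bool


def prepare(population: Population, config: RunConfig) -> Prepared:
    """Window selection, Mendelian screening, per-pedigree spaces."""
    window = window_markers(population.markers, config.gene_center, config.window_kb)
    if not window:
        raise ValueError("empty marker window: no SNPs near the gene center")
    clean_mendelian(population.pedigrees, population.genotypes)
    spaces: dict[str, object] = {}
    for family in population.pedigrees.families:
        members = population.pedigrees.members(family)
        geno = {
            m.iid: population.genotypes.row(m.iid)[window] for m in members
        }
        spaces[family] = pedigree_space.solve_pedigree(members, geno)
    return Prepared(window, spaces)


def run_wsg_hi(
    population: Population,
    config: RunConfig,
    hla_override=None,
    prepared: Prepared | None = None,
) -> tuple[HLACallSet, RunInfo]:
    """Infer HLA types for every untyped individual of the population.

    ``hla_override`` substitutes the population's HLA table (used by
    the cross-validation harnesses to mask individuals); ``prepared``
    reuses window/solution-space work across repeated runs on the same
    genotypes.
    """
    hla = hla_override if hla_override is not None else population.hla
    if prepared is None:
        prepared = prepare(population, config)

    typed = set(hla.typed())
    if not typed:
        logger.warning("no typed individuals: every call will be a no-call")

    state = SearchState(t_mis=config.t_mis, t_s=config.t_s, hla_types=dict(hla.types))
    ordered = config_search.order_pedigrees(list(prepared.spaces.values()))

    unique = [s for s in ordered if s.f == 0]
    rest = [s for s in ordered if s.f > 0]
    state = config_search.seed_unique(state, unique)
    log: list[dict] = [
        {"members": s.member_ids, "f": 0, "method": "unique", "con": state.con}
        for s in unique
    ]

    ga_used = False
    for k, space in enumerate(rest):
        if space.f <= config.ga.t_c:
            if space.f == config.ga.t_c:
                logger.info("pedigree at the enumeration gate f == t_c == %d", space.f)
            state, info = config_search.enum_alg(state, space)
        else:
            ga_used = True
            params = GAParams(
                p_s=config.ga.p_s, g_m=config.ga.g_m, r_c=config.ga.r_c,
                r_m=config.ga.r_m, t_c=config.ga.t_c,
                seed=(config.seed * 1_000_003 + k) % (1 << 31),
            )
            state, info = config_search.genetic_alg(state, space, params)
        info["members"] = space.member_ids
        log.append(info)
        logger.debug(
            "pedigree %s: f=%d method=%s con=%.3f",
            space.member_ids[0], info["f"], info["method"], info["con"],
        )

    graph = state.graph()
    labeling = state.labeling or Labeling([None] * graph.n_vertices)
    untyped = [
        ind.iid
        for ind in population.pedigrees.individuals
        if ind.iid not in typed and (ind.iid, 0) in graph.vertex_index
    ]
    callset, _ = hla_type(graph, labeling, untyped, config.t_s)

    calls = dict(callset.calls)
    for iid in typed:
        calls[iid] = Call(iid, hla.types[iid], (1.0, 1.0), "known")
    return HLACallSet(calls), RunInfo(config.seed, log, ga_used)
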