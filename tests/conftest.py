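"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import settings

from hlagraph.io_formats import HET, MISSING
from hlagraph.similarity import as_haplotype

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# similarity oracle: exhaustive region enumeration


def oracle_similarity(h_i, h_j, t_mis: int) -> float:
    """Similarity by brute force over all O(n^2) candidate regions."""
    a, b = as_haplotype(h_i), as_haplotype(h_j)
    n = len(a)
    states = []
    for x, y in zip(a, b):
        if x == MISSING or y == MISSING:
            states.append("u")
        else:
            states.append("m" if x == y else "x")
    best = 0
    for p in range(n):
        for q in range(p + 1, n):
            if states[p] != "m" or states[q] != "m":
                continue
            run = longest = 0
            for s in states[p : q + 1]:
                run = run + 1 if s == "x" else 0
                longest = max(longest, run)
            if longest > t_mis:
                continue
            best = max(best, states[p : q + 1].count("m"))
    return best / n if best else 0.0


# ---------------------------------------------------------------------------
# pedigree-space oracle: brute force over founder phasings x transmissions


def canonical_config(config) -> tuple:
    return tuple(
        (iid, config[iid][0].tobytes(), config[iid][1].tobytes())
        for iid in sorted(config)
    )


def brute_force_configs(members, geno) -> set[tuple]:
    """All Mendelian zero-recombinant configurations of a (complete-data)
    pedigree: enumerate founder phasings (normalized: allele 0 first at
    the first heterozygous locus) and per-child parental transmissions."""
    members = sorted(members, key=lambda m: m.iid)
    in_ped = {m.iid for m in members}
    founders = [m for m in members if m.father is None or m.father not in in_ped]
    children = [m for m in members if m not in founders]

    def founder_phasings(m):
        g = geno[m.iid]
        het = [l for l, x in enumerate(g) if x == HET]
        out = []
        for bits in itertools.product([0, 1], repeat=len(het)):
            if het and bits[0] != 0:
                continue
            h0 = np.zeros(len(g), np.int8)
            h1 = np.zeros(len(g), np.int8)
            for l, x in enumerate(g):
                if x == 2:
                    h0[l] = h1[l] = 1
                elif x == HET:
                    k = bits[het.index(l)]
                    h0[l], h1[l] = k, 1 - k
                elif x == MISSING:
                    h0[l] = h1[l] = MISSING
            out.append((h0, h1))
        return out

    configs: set[tuple] = set()
    for combo in itertools.product(*(founder_phasings(m) for m in founders)):
        assign = {m.iid: pair for m, pair in zip(founders, combo)}

        def rec(i):
            if i == len(children):
                configs.add(canonical_config(assign))
                return
            c = children[i]
            for tf in (0, 1):
                for tm in (0, 1):
                    hp, hm = assign[c.father][tf], assign[c.mother][tm]
                    ok = all(
                        geno[c.iid][l] == MISSING
                        or (
                            hp[l] != MISSING
                            and hm[l] != MISSING
                            and hp[l] + hm[l] == geno[c.iid][l]
                        )
                        for l in range(len(hp))
                    )
                    if ok:
                        assign[c.iid] = (hp, hm)
                        rec(i + 1)
                        del assign[c.iid]

        rec(0)
    return configs


def assert_valid_config(members, geno, config) -> None:
    """Mendelian + zero-recombinant validator (unknowns are wildcards)."""
    by_id = {m.iid: m for m in members}
    for iid, (h0, h1) in config.items():
        g = geno[iid]
        for l in range(len(g)):
            if g[l] == MISSING or h0[l] == MISSING or h1[l] == MISSING:
                continue
            assert h0[l] + h1[l] == g[l], f"{iid} locus {l} conflates wrongly"
        m = by_id[iid]
        if m.father in config:
            for hap, parent in ((h0, m.father), (h1, m.mother)):
                pa, pb = config[parent]
                assert _copies(hap, pa) or _copies(hap, pb), (
                    f"{iid} haplotype is not a zero-recombinant parental copy"
                )


def _copies(hap, parent_hap) -> bool:
    known = (hap != MISSING) & (parent_hap != MISSING)
    return bool(np.all(hap[known] == parent_hap[known]))


# ---------------------------------------------------------------------------
# shared populations


@pytest.fixture(scope="session")
def worked_fixture():
    from hlagraph.simulate import make_worked_fixture

    return make_worked_fixture()


def relabel_pedigree(members, geno, prefix: str):
    """Prefix all identifiers (disambiguates repeated fixture families)."""
    from hlagraph.io_formats import Individual

    renamed = [
        Individual(
            prefix + m.family, prefix + m.iid,
            m.father and prefix + m.father, m.mother and prefix + m.mother,
            m.sex,
        )
        for m in members
    ]
    return renamed, {prefix + iid: g for iid, g in geno.items()}


def random_pedigree(seed: int, *, missing_rate: float = 0.0, children=None,
                    n_markers=None):
    """One random nuclear pedigree with <= 5 members and <= 8 markers."""
    from hlagraph.io_formats import clean_mendelian
    from hlagraph.simulate import SimConfig, simulate_population

    rng = np.random.default_rng(seed)
    cfg = SimConfig(
        n_pedigrees=1,
        children_per_family=int(rng.integers(1, 4)) if children is None else children,
        n_markers=int(rng.integers(3, 9)) if n_markers is None else n_markers,
        min_divergence=1,
        alleles=("01", "02", "03"),
        frequencies=(0.4, 0.3, 0.3),
        missing_rate=missing_rate,
        seed=int(rng.integers(1 << 30)),
    )
    res = simulate_population(cfg)
    pop = res.population
    clean_mendelian(pop.pedigrees, pop.genotypes)
    members = pop.pedigrees.members("fam01")
    geno = {m.iid: pop.genotypes.row(m.iid) for m in members}
    return members, geno
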