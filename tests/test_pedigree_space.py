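"""Zero-recombinant solution spaces: counting, completeness, fallback."""

import numpy as np
import pytest

from hlagraph.io_formats import HET, HOM_REF, Individual, MISSING
from hlagraph.pedigree_space import (
    RecombinantPedigreeError,
    StitchedSpace,
    build_solution_space,
    segment_fallback,
    solve_pedigree,
)

from conftest import (
    assert_valid_config,
    brute_force_configs,
    canonical_config,
    random_pedigree,
)


def _trio(father_g, mother_g, child_g):
    members = [
        Individual("f", "c", "d", "m", 1),
        Individual("f", "d", None, None, 1),
        Individual("f", "m", None, None, 2),
    ]
    geno = {
        "d": np.array(father_g, dtype=np.int8),
        "m": np.array(mother_g, dtype=np.int8),
        "c": np.array(child_g, dtype=np.int8),
    }
    return members, geno


def test_homozygous_parents_leave_no_freedom():
    members, geno = _trio([0, 2, 0], [2, 2, 0], [1, 2, 0])
    space = build_solution_space(members, geno)
    assert space.f == 0
    (config,) = list(space.enumerate_solutions())
    assert list(config["c"][0]) == [0, 1, 0]  # paternal copy
    assert list(config["c"][1]) == [1, 1, 0]  # maternal copy


def test_singleton_with_three_het_loci_has_four_phasings():
    members = [Individual("f", "s", None, None, 1)]
    geno = {"s": np.array([HET, HET, HET], dtype=np.int8)}
    space = build_solution_space(members, geno)
    assert space.f == 2  # 8 ordered phasings / 2 for the unordered pair
    configs = {canonical_config(c) for c in space.enumerate_solutions()}
    assert len(configs) == 4


def test_trio_heterozygous_at_one_locus_has_two_configurations():
    members, geno = _trio([1], [1], [1])
    space = build_solution_space(members, geno)
    assert space.f == 1
    configs = list(space.enumerate_solutions())
    assert len(configs) == 2
    assert configs[0]["c"][0][0] != configs[1]["c"][0][0]


def test_instantiate_rejects_wrong_length():
    members, geno = _trio([1], [1], [1])
    space = build_solution_space(members, geno)
    with pytest.raises(ValueError):
        space.instantiate(np.zeros(3, dtype=bool))


def test_enumeration_matches_brute_force_on_random_pedigrees():
    for seed in range(40):
        members, geno = random_pedigree(seed)
        space = build_solution_space(members, geno)
        enum = {canonical_config(c) for c in space.enumerate_solutions()}
        assert len(enum) == 2**space.f  # distinctness and count
        assert enum == brute_force_configs(members, geno)


def test_every_instantiation_is_mendelian_zero_recombinant():
    for seed in range(15):
        members, geno = random_pedigree(seed + 100)
        space = build_solution_space(members, geno)
        for config in space.enumerate_solutions():
            assert_valid_config(members, geno, config)


def test_distinct_count_holds_under_missing_genotypes():
    checked = 0
    for seed in range(40):
        members, geno = random_pedigree(seed + 500, missing_rate=0.15)
        space = solve_pedigree(members, geno)
        if space.f > 8:
            continue
        seen = {canonical_config(c) for c in space.enumerate_solutions()}
        assert len(seen) == 2**space.f
        checked += 1
    assert checked >= 20


def test_deterministic_rebuild():
    members, geno = random_pedigree(7)
    a = build_solution_space(members, geno)
    b = build_solution_space(members, geno)
    assert a.f == b.f
    for ca, cb in zip(a.enumerate_solutions(), b.enumerate_solutions()):
        assert canonical_config(ca) == canonical_config(cb)


# ---------------------------------------------------------------------------
# recombinant fallback


def _obligate_crossover_family():
    # father is heterozygous everywhere, so his haplotypes are complementary;
    # child2's paternal haplotype 11110000 cannot match either complement of
    # child1's 11111111 -> one obligate crossover
    members = [
        Individual("f", "c1", "d", "m", 1),
        Individual("f", "c2", "d", "m", 2),
        Individual("f", "d", None, None, 1),
        Individual("f", "m", None, None, 2),
    ]
    geno = {
        "d": np.array([HET] * 8, dtype=np.int8),
        "m": np.array([HOM_REF] * 8, dtype=np.int8),
        "c1": np.array([HET] * 8, dtype=np.int8),
        "c2": np.array([HET] * 4 + [HOM_REF] * 4, dtype=np.int8),
    }
    return members, geno


def test_obligate_crossover_detected_and_stitched():
    members, geno = _obligate_crossover_family()
    with pytest.raises(RecombinantPedigreeError):
        build_solution_space(members, geno)
    space = segment_fallback(members, geno)
    assert isinstance(space, StitchedSpace)
    assert len(space.segments) == 2
    bits = np.zeros(space.f, dtype=bool)
    switches = space.switch_counts(bits)
    assert switches[("c2", "d")] == 1
    assert switches[("c1", "d")] == 0
    config = space.instantiate(bits)
    for iid, (h0, h1) in config.items():  # genotype consistency
        g = geno[iid]
        known = (h0 != MISSING) & (h1 != MISSING) & (g != MISSING)
        assert np.all((h0 + h1)[known] == g[known])


def test_fallback_on_consistent_window_is_single_segment():
    members, geno = random_pedigree(3)
    space = segment_fallback(members, geno)
    assert len(space.segments) == 1
    direct = build_solution_space(members, geno)
    assert space.f == direct.f
    assert canonical_config(space.instantiate(np.zeros(space.f, bool))) == (
        canonical_config(direct.instantiate(np.zeros(direct.f, bool)))
    )


def test_solve_pedigree_dispatches():
    members, geno = _obligate_crossover_family()
    assert isinstance(solve_pedigree(members, geno), StitchedSpace)
    members, geno = random_pedigree(9)
    assert not isinstance(solve_pedigree(members, geno), StitchedSpace)
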