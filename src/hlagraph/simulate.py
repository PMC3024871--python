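"""Synthetic pedigree populations with allele-specific haplotype backgrounds.

The generator emulates the regime the inference method assumes: each
HLA allele rides on one (or a few closely related) SNP haplotype
backgrounds, backgrounds of different alleles are well separated in
Hamming distance, founders draw (background, allele) chromosome pairs
i.i.d. from the allele frequency distribution, and children inherit
one unmodified haplotype per parent (optionally with a single
crossover per meiosis).  Genotypes are the conflated haplotypes with
configurable missingness and error.

What it does *not* emulate: coalescent-realistic linkage
disequilibrium, recombination hotspots, population structure or
chip-specific error modes -- results on these populations bound the
method's behaviour under its own assumptions, not on arbitrary real
cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import (
    MISSING,
    GenotypeMatrix,
    HLATable,
    Individual,
    MarkerMap,
    PedigreeSet,
    Population,
)

DEFAULT_ALLELES = ("0101", "0201", "0301", "1101", "2402", "2901")
DEFAULT_FREQS = (0.25, 0.20, 0.20, 0.15, 0.10, 0.10)


@dataclass
class SimConfig:
    """Study conditions for one synthetic population.

    Defaults describe a desk-scale cohort: 20 nuclear pedigrees of two
    founders and two children, 50 SNPs spanning a 200 kb window around
    the gene, six alleles with one divergent background each (minimum
    pairwise Hamming distance 10), clean genotypes.
    """

    n_pedigrees: int = 20
    children_per_family: int = 2
    third_generation: bool = False
    n_markers: int = 50
    alleles: tuple[str, ...] = DEFAULT_ALLELES
    frequencies: tuple[float, ...] = DEFAULT_FREQS
    backgrounds_per_allele: int = 1
    min_divergence: int = 10
    recomb_prob: float = 0.0
    missing_rate: float = 0.0
    error_rate: float = 0.0
    chrom: str = "6"
    gene_center: int = 31_500_000
    window_kb: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.alleles) != len(self.frequencies):
            raise ValueError("alleles and frequencies differ in length")
        if abs(sum(self.frequencies) - 1.0) > 1e-9:
            raise ValueError("allele frequencies must sum to 1")
        if self.min_divergence > self.n_markers:
            raise ValueError("min_divergence not achievable with n_markers")
        if not (0 <= self.recomb_prob <= 1):
            raise ValueError("recomb_prob must lie in [0, 1]")


@dataclass
class SimResult:
    population: Population
    true_haplotypes: dict[str, tuple[np.ndarray, np.ndarray]]
    true_alleles: dict[str, tuple[str, str]]  # per-chromosome order
    backgrounds: dict[str, list[np.ndarray]] = field(default_factory=dict)


def _make_backgrounds(cfg: SimConfig, rng: np.random.Generator):
    """One seed haplotype per allele (rejection-sampled to respect the
    minimum pairwise divergence) plus near-identical perturbed copies."""
    seeds: list[np.ndarray] = []
    for _ in cfg.alleles:
        for _attempt in range(10_000):
            cand = rng.integers(0, 2, cfg.n_markers).astype(np.int8)
            if all(int((cand != s).sum()) >= cfg.min_divergence for s in seeds):
                seeds.append(cand)
                break
        else:
            raise RuntimeError("could not place divergent backgrounds; lower min_divergence")
    backgrounds: dict[str, list[np.ndarray]] = {}
    for allele, seed in zip(cfg.alleles, seeds):
        variants = [seed]
        for _ in range(cfg.backgrounds_per_allele - 1):
            # flip two isolated sites: stays within the mismatch tolerance
            v = seed.copy()
            sites = rng.choice(cfg.n_markers, size=2, replace=False)
            while abs(int(sites[0]) - int(sites[1])) < 3:
                sites = rng.choice(cfg.n_markers, size=2, replace=False)
            v[sites] ^= 1
            variants.append(v)
        backgrounds[allele] = variants
    return backgrounds


def _draw_chromosome(cfg, rng, backgrounds):
    allele = cfg.alleles[rng.choice(len(cfg.alleles), p=np.asarray(cfg.frequencies))]
    hap = backgrounds[allele][rng.integers(0, cfg.backgrounds_per_allele)].copy()
    return hap, allele


def _meiosis(cfg, rng, pair, alleles):
    """Transmit one (possibly recombined) haplotype from a parent."""
    k = int(rng.integers(0, 2))
    hap, allele = pair[k].copy(), alleles[k]
    if cfg.recomb_prob > 0 and rng.random() < cfg.recomb_prob:
        cut = int(rng.integers(1, cfg.n_markers))
        other = pair[1 - k]
        hap = np.concatenate([hap[:cut], other[cut:]])
        if cut <= cfg.n_markers // 2:  # gene center sits mid-window
            allele = alleles[1 - k]
    return hap, allele


def simulate_population(cfg: SimConfig) -> SimResult:
    """Generate a pedigree population with retained truth."""
    rng = np.random.default_rng(cfg.seed)
    backgrounds = _make_backgrounds(cfg, rng)

    individuals: list[Individual] = []
    haps: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    alleles: dict[str, tuple[str, str]] = {}

    def add(iid, family, father, mother, sex, pair, pair_alleles):
        individuals.append(Individual(family, iid, father, mother, sex))
        haps[iid] = pair
        alleles[iid] = pair_alleles

    for p in range(cfg.n_pedigrees):
        fam = f"fam{p + 1:02d}"
        father, mother = f"{fam}_1", f"{fam}_2"
        for iid, sex in ((father, 1), (mother, 2)):
            h0, a0 = _draw_chromosome(cfg, rng, backgrounds)
            h1, a1 = _draw_chromosome(cfg, rng, backgrounds)
            add(iid, fam, None, None, sex, (h0, h1), (a0, a1))
        kids = []
        for c in range(cfg.children_per_family):
            iid = f"{fam}_{c + 3}"
            hp, ap = _meiosis(cfg, rng, haps[father], alleles[father])
            hm, am = _meiosis(cfg, rng, haps[mother], alleles[mother])
            add(iid, fam, father, mother, int(rng.integers(1, 3)), (hp, hm), (ap, am))
            kids.append(iid)
        if cfg.third_generation and kids:
            spouse = f"{fam}_s"
            h0, a0 = _draw_chromosome(cfg, rng, backgrounds)
            h1, a1 = _draw_chromosome(cfg, rng, backgrounds)
            add(spouse, fam, None, None, 2, (h0, h1), (a0, a1))
            for g in range(2):
                iid = f"{fam}_g{g + 1}"
                hp, ap = _meiosis(cfg, rng, haps[kids[0]], alleles[kids[0]])
                hm, am = _meiosis(cfg, rng, haps[spouse], alleles[spouse])
                add(iid, fam, kids[0], spouse, int(rng.integers(1, 3)),
                    (hp, hm), (ap, am))

    iids = [ind.iid for ind in individuals]
    codes = np.empty((len(iids), cfg.n_markers), dtype=np.int8)
    for r, iid in enumerate(iids):
        h0, h1 = haps[iid]
        codes[r] = h0 + h1
    if cfg.error_rate > 0:
        flips = rng.random(codes.shape) < cfg.error_rate
        for r, j in zip(*np.nonzero(flips)):
            codes[r, j] = rng.choice([g for g in (0, 1, 2) if g != codes[r, j]])
    if cfg.missing_rate > 0:
        codes[rng.random(codes.shape) < cfg.missing_rate] = MISSING

    half = cfg.window_kb * 1000 // 2
    step = max(1, (2 * half) // max(cfg.n_markers - 1, 1))
    pos = cfg.gene_center - half + step * np.arange(cfg.n_markers, dtype=np.int64)
    markers = MarkerMap(
        [f"rs{k + 1:05d}" for k in range(cfg.n_markers)],
        [cfg.chrom] * cfg.n_markers,
        pos,
    )
    hla = HLATable({iid: tuple(sorted(alleles[iid])) for iid in iids})
    pop = Population(PedigreeSet(individuals), GenotypeMatrix(codes, iids), markers, hla)
    return SimResult(pop, haps, alleles, backgrounds)


def make_worked_fixture() -> SimResult:
    """Tiny deterministic three-individual example for docs and tests.

    Two typed individuals with allele pairs {0201, 0101} and
    {0201, 2401} (two heterozygous constraint edges) plus one untyped
    individual sharing the 0101/2401 backgrounds; 12 markers.
    """
    b = {
        "0101": np.array([0, 0, 1, 0, 1, 1, 0, 0, 1, 0, 1, 0], dtype=np.int8),
        "0201": np.array([1, 1, 0, 0, 0, 1, 1, 0, 0, 1, 0, 1], dtype=np.int8),
        "2401": np.array([0, 1, 1, 1, 0, 0, 0, 1, 1, 1, 0, 0], dtype=np.int8),
    }
    hap_assign = {
        "I1": ("0201", "0101"),
        "I2": ("0201", "2401"),
        "I3": ("0101", "2401"),
    }
    haps = {i: (b[a].copy(), b[c].copy()) for i, (a, c) in hap_assign.items()}
    # one isolated discrepancy on I2's 0201 copy: still nearly identical
    haps["I2"][0][4] ^= 1
    individuals = [Individual(f"f{k}", iid, None, None, 0) for k, iid in
                   enumerate(hap_assign)]
    iids = list(hap_assign)
    codes = np.vstack([haps[i][0] + haps[i][1] for i in iids]).astype(np.int8)
    markers = MarkerMap(
        [f"rs{k + 1:03d}" for k in range(12)], ["6"] * 12,
        31_500_000 - 55_000 + 10_000 * np.arange(12, dtype=np.int64),
    )
    hla = HLATable(
        {"I1": ("0101", "0201"), "I2": ("0201", "2401"), "I3": None}
    )
    pop = Population(PedigreeSet(individuals), GenotypeMatrix(codes, iids), markers, hla)
    return SimResult(pop, haps, hap_assign, {a: [h] for a, h in b.items()})
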