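"""Text-format I/O, marker windowing and HLA allele-name handling.

On-disk dialect:

* genotypes: linkage/PED-style whitespace table -- family, individual,
  father, mother, sex, then two allele columns per marker.  Alleles are
  coded ``1`` (reference) / ``2`` (alternate); ``0`` means missing.
  Founders carry ``0`` in the parent columns.
* marker map: three whitespace-separated columns ``id chrom pos`` with
  1-based base-pair positions, strictly increasing per chromosome.
* HLA table: TSV ``individual allele1 allele2``; ``-`` marks an
  individual whose type is unknown (all-or-nothing per individual).

Internally genotypes are alt-allele counts (``0``/``1``/``2``) with
``-1`` for missing, and allele names are bare digit strings ("0201")
with gene prefixes and separators stripped.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np

#: genotype codes
HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1

#: token for an unknown HLA allele / gene type
UNKNOWN = "-"
_UNKNOWN_TOKENS = {"-", "–", "—", "NA", "na", "."}


class ParseError(ValueError):
    """Raised on malformed or inconsistent input files."""


# ---------------------------------------------------------------------------
# domain types


@dataclass
class MarkerMap:
    ids: list[str]
    chrom: list[str]
    pos: np.ndarray  # int64, base pairs

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        if len(self.ids) != len(set(self.ids)):
            raise ParseError("duplicate marker identifiers in map")
        by_chrom: dict[str, int] = {}
        for c, p in zip(self.chrom, self.pos):
            if c in by_chrom and p <= by_chrom[c]:
                raise ParseError(
                    f"marker positions not strictly increasing on chromosome {c}"
                )
            by_chrom[c] = int(p)

    def __len__(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class Individual:
    family: str
    iid: str
    father: str | None
    mother: str | None
    sex: int = 0

    @property
    def is_founder(self) -> bool:
        return self.father is None


@dataclass
class PedigreeSet:
    """Population roster grouped into pedigrees.

    Individual identifiers must be unique across the whole population
    (PED family scoping is not used for cross-references).
    """

    individuals: list[Individual]
    families: dict[str, list[str]] = field(init=False)
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.index = {}
        self.families = {}
        for k, ind in enumerate(self.individuals):
            if ind.iid in self.index:
                raise ParseError(f"duplicate individual identifier {ind.iid!r}")
            self.index[ind.iid] = k
            self.families.setdefault(ind.family, []).append(ind.iid)
        for ind in self.individuals:
            if (ind.father is None) != (ind.mother is None):
                raise ParseError(
                    f"individual {ind.iid!r} has exactly one parent recorded"
                )
            for parent in (ind.father, ind.mother):
                if parent is not None and parent not in self.index:
                    raise ParseError(
                        f"parent {parent!r} of {ind.iid!r} absent from roster"
                    )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}

        def visit(iid: str) -> None:
            if state.get(iid) == 1:
                raise ParseError(f"pedigree cycle involving {iid!r}")
            if state.get(iid) == 2:
                return
            state[iid] = 1
            ind = self.individuals[self.index[iid]]
            for parent in (ind.father, ind.mother):
                if parent is not None:
                    visit(parent)
            state[iid] = 2

        for ind in self.individuals:
            visit(ind.iid)

    def members(self, family: str) -> list[Individual]:
        return [self.individuals[self.index[i]] for i in self.families[family]]

    def __len__(self) -> int:
        return len(self.individuals)


@dataclass
class GenotypeMatrix:
    """n individuals x m markers of alt-allele counts, ``-1`` = missing."""

    codes: np.ndarray  # int8 (n, m)
    iids: list[str]
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2 or self.codes.shape[0] != len(self.iids):
            raise ParseError("genotype matrix shape inconsistent with roster")
        self.index = {iid: k for k, iid in enumerate(self.iids)}

    def row(self, iid: str) -> np.ndarray:
        return self.codes[self.index[iid]]


HLAPair = tuple[str, str]


@dataclass
class HLATable:
    """Unordered HLA allele pair per individual; ``None`` = untyped."""

    types: dict[str, HLAPair | None]

    def typed(self) -> list[str]:
        return [i for i, t in self.types.items() if t is not None]

    def untyped(self) -> list[str]:
        return [i for i, t in self.types.items() if t is None]

    def masked(self, iids) -> "HLATable":
        hidden = set(iids)
        return HLATable(
            {i: (None if i in hidden else t) for i, t in self.types.items()}
        )


@dataclass
class Population:
    pedigrees: PedigreeSet
    genotypes: GenotypeMatrix
    markers: MarkerMap
    hla: HLATable


# ---------------------------------------------------------------------------
# allele names


_ALLELE_RE = re.compile(r"^(?:[A-Za-z0-9]+\*)?(\d+(?::\d+)*)[LSCAQN]?$")


def normalize_allele(name: str) -> str:
    """Strip gene prefix / colon separators: ``A*02:01`` -> ``0201``."""
    name = name.strip()
    if name in _UNKNOWN_TOKENS:
        return UNKNOWN
    m = _ALLELE_RE.match(name)
    if not m:
        raise ParseError(f"malformed HLA allele name {name!r}")
    return m.group(1).replace(":", "")


def truncate_allele(name: str, resolution: int) -> str | None:
    """Truncate an allele name to 2- or 4-digit resolution.

    Returns ``None`` when the name is not resolved to the requested
    level (such chromosomes are excluded from evaluation downstream);
    the unknown token passes through unchanged.
    """
    if resolution not in (2, 4):
        raise ValueError("resolution must be 2 or 4")
    if name == UNKNOWN:
        return UNKNOWN
    if not name.isdigit():
        raise ValueError(f"allele name {name!r} is not a digit string")
    if len(name) < resolution:
        return None
    return name[:resolution]


# ---------------------------------------------------------------------------
# window selection


def window_markers(markers: MarkerMap, center_bp: int, window_kb: int) -> list[int]:
    """Indices of markers within ``window_kb`` centered at ``center_bp``.

    Both window boundaries are inclusive.  An empty window triggers a
    warning but is not an error.
    """
    if window_kb <= 0:
        raise ValueError("window_kb must be positive")
    half = window_kb * 1000 // 2
    lo, hi = center_bp - half, center_bp + half
    idx = [k for k, p in enumerate(markers.pos) if lo <= p <= hi]
    if not idx:
        warnings.warn(
            f"no markers in [{lo}, {hi}]; downstream steps will see an empty window",
            stacklevel=2,
        )
    return idx


# ---------------------------------------------------------------------------
# readers


def _read_map(path) -> MarkerMap:
    ids, chroms, pos = [], [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ParseError(f"{path}:{ln}: expected 3 columns, got {len(parts)}")
            ids.append(parts[0])
            chroms.append(parts[1])
            try:
                pos.append(int(parts[2]))
            except ValueError as exc:
                raise ParseError(f"{path}:{ln}: bad position {parts[2]!r}") from exc
    return MarkerMap(ids, chroms, np.array(pos, dtype=np.int64))


_PED_CODE = {("1", "1"): HOM_REF, ("1", "2"): HET, ("2", "1"): HET, ("2", "2"): HOM_ALT}


def _read_ped(path, m: int) -> tuple[PedigreeSet, GenotypeMatrix]:
    individuals: list[Individual] = []
    rows: list[np.ndarray] = []
    iids: list[str] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 5 + 2 * m:
                raise ParseError(
                    f"{path}:{ln}: expected {5 + 2 * m} columns for {m} markers, "
                    f"got {len(parts)}"
                )
            fam, iid, father, mother, sex = parts[:5]
            codes = np.empty(m, dtype=np.int8)
            for j in range(m):
                a, b = parts[5 + 2 * j], parts[6 + 2 * j]
                if a == "0" and b == "0":
                    codes[j] = MISSING
                elif (a, b) in _PED_CODE:
                    codes[j] = _PED_CODE[(a, b)]
                else:
                    raise ParseError(
                        f"{path}:{ln}: malformed allele pair ({a},{b}) at marker {j + 1}"
                    )
            individuals.append(
                Individual(
                    fam,
                    iid,
                    None if father == "0" else father,
                    None if mother == "0" else mother,
                    int(sex) if sex.isdigit() else 0,
                )
            )
            iids.append(iid)
            rows.append(codes)
    pedigrees = PedigreeSet(individuals)
    genotypes = GenotypeMatrix(np.vstack(rows) if rows else np.empty((0, m), np.int8), iids)
    return pedigrees, genotypes


def _read_hla(path) -> HLATable:
    types: dict[str, HLAPair | None] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ParseError(f"{path}:{ln}: expected 3 columns, got {len(parts)}")
            iid, a1, a2 = parts
            a1, a2 = normalize_allele(a1), normalize_allele(a2)
            if (a1 == UNKNOWN) != (a2 == UNKNOWN):
                raise ParseError(
                    f"{path}:{ln}: unknown type must cover both alleles of {iid!r}"
                )
            types[iid] = None if a1 == UNKNOWN else tuple(sorted((a1, a2)))
    return HLATable(types)


def read_population(genotype_file, map_file, hla_file) -> Population:
    """Read a pedigree population from PED + map + HLA-table files.

    Individuals in the HLA table must have genotype rows; individuals
    with genotypes but no HLA row are treated as untyped.  Pedigrees
    with a Mendelian-inconsistent marker have that marker blanked
    (see :func:`clean_mendelian`).
    """
    markers = _read_map(map_file)
    pedigrees, genotypes = _read_ped(genotype_file, len(markers))
    hla = _read_hla(hla_file)
    for iid in hla.types:
        if iid not in genotypes.index:
            raise ParseError(f"HLA table row for {iid!r} has no genotype row")
    for ind in pedigrees.individuals:
        hla.types.setdefault(ind.iid, None)
    clean_mendelian(pedigrees, genotypes)
    return Population(pedigrees, genotypes, markers, hla)


# ---------------------------------------------------------------------------
# writers (round-trip partners of the readers)

_PED_ALLELES = {HOM_REF: ("1", "1"), HET: ("1", "2"), HOM_ALT: ("2", "2"), MISSING: ("0", "0")}


def write_population(pop: Population, prefix) -> tuple[str, str, str]:
    """Write ``<prefix>.ped``, ``<prefix>.map`` and ``<prefix>.hla``."""
    prefix = str(prefix)
    ped_path, map_path, hla_path = prefix + ".ped", prefix + ".map", prefix + ".hla"
    with open(map_path, "w") as fh:
        for mid, c, p in zip(pop.markers.ids, pop.markers.chrom, pop.markers.pos):
            fh.write(f"{mid}\t{c}\t{p}\n")
    with open(ped_path, "w") as fh:
        for ind in pop.pedigrees.individuals:
            row = pop.genotypes.row(ind.iid)
            cols = [ind.family, ind.iid, ind.father or "0", ind.mother or "0", str(ind.sex)]
            for code in row:
                cols.extend(_PED_ALLELES[int(code)])
            fh.write("\t".join(cols) + "\n")
    with open(hla_path, "w") as fh:
        for ind in pop.pedigrees.individuals:
            t = pop.hla.types.get(ind.iid)
            a1, a2 = t if t is not None else (UNKNOWN, UNKNOWN)
            fh.write(f"{ind.iid}\t{a1}\t{a2}\n")
    return ped_path, map_path, hla_path


# ---------------------------------------------------------------------------
# Mendelian screening


def _mendel_ok(child: int, pat: int, mat: int) -> bool:
    def gametes(g: int) -> set[int]:
        return {0: {0}, 1: {0, 1}, 2: {1}, MISSING: {0, 1}}[g]

    if child == MISSING:
        return True
    need = {0: [(0, 0)], 1: [(0, 1), (1, 0)], 2: [(1, 1)]}[child]
    return any(a in gametes(pat) and b in gametes(mat) for a, b in need)


def clean_mendelian(pedigrees: PedigreeSet, genotypes: GenotypeMatrix) -> int:
    """Blank Mendelian-inconsistent markers pedigree-wide, in place.

    For every pedigree and marker, if any child/parent combination is
    impossible under Mendelian transmission, the whole pedigree's
    genotypes at that marker are set to missing (the least destructive
    repair given the error cannot be localized).  Returns the number of
    (pedigree, marker) cells blanked.
    """
    blanked = 0
    m = genotypes.codes.shape[1]
    for family, iids in pedigrees.families.items():
        children = [
            pedigrees.individuals[pedigrees.index[i]]
            for i in iids
            if pedigrees.individuals[pedigrees.index[i]].father is not None
        ]
        if not children:
            continue
        rows = {i: genotypes.index[i] for i in iids}
        for j in range(m):
            ok = all(
                _mendel_ok(
                    int(genotypes.codes[rows[c.iid], j]),
                    int(genotypes.codes[genotypes.index[c.father], j]),
                    int(genotypes.codes[genotypes.index[c.mother], j]),
                )
                for c in children
            )
            if not ok:
                for i in iids:
                    genotypes.codes[rows[i], j] = MISSING
                blanked += 1
    return blanked
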