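"""Mendelian, zero-recombinant haplotype solution spaces of pedigrees.

For one pedigree over a marker window, the set of haplotype
configurations that (a) conflate to the observed genotypes and (b) pass
each child one unmodified haplotype per parent forms an affine space
over GF(2).  The coordinates are

* one *phase* bit ``x[i, l]`` per individual ``i`` and heterozygous
  locus ``l`` (which of the two haplotypes carries the alternate
  allele), and
* one *transmission* bit ``t[c, p]`` per (child, parent) link (which of
  the parent's two haplotypes the child received; created only when the
  parent has at least one heterozygous locus, otherwise the choice is
  unobservable).

Zero recombination makes each transmission a single bit for the whole
window, and every Mendelian constraint is an XOR equation over these
bits.  Gaussian elimination over GF(2) yields the general solution: a
particular assignment plus ``f`` free binary variables, so the space
holds exactly ``2**f`` configurations.  Free bits that do not alter any
haplotype cell (e.g. phase freedom hidden behind missing data) are
projected out so that distinct bit vectors always instantiate distinct
configurations.

Founders have no parental origin, so their haplotype pair is unordered;
the symmetric duplicate is removed by pinning the phase bit of each
founder's first heterozygous locus to 0.  Non-founder pairs are ordered
(paternal, maternal).

Missing genotypes constrain nothing; the corresponding haplotype cells
are filled from the transmitting parent when that parent's allele is
determined and left unknown (``-1``) otherwise.

When no zero-recombinant configuration exists the window is split into
maximal zero-recombinant segments which are stitched left to right,
greedily re-orienting founder haplotypes at each junction to minimize
apparent transmission switches (see :func:`segment_fallback`).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .io_formats import HET, HOM_ALT, HOM_REF, Individual, MISSING


class RecombinantPedigreeError(Exception):
    """No Mendelian zero-recombinant configuration exists for the window."""


Expr = tuple[int, tuple[int, ...]]  # affine GF(2) expression: const ^ XOR(vars)

Configuration = dict[str, tuple[np.ndarray, np.ndarray]]


def _xor_expr(a: Expr, b: Expr) -> Expr:
    return (a[0] ^ b[0], tuple(sorted(set(a[1]) ^ set(b[1]))))


class SolutionSpace:
    """General solution of one pedigree over one window (see module docs)."""

    def __init__(
        self,
        members: list[Individual],
        cells: dict[tuple[str, int], list[Expr | None]],
        particular: np.ndarray,
        basis: np.ndarray,
        trans_vars: dict[tuple[str, str], int],
        n_markers: int,
    ):
        self.members = members
        self.member_ids = [m.iid for m in members]
        self._cells = cells
        self._p = particular  # bool (nvars,)
        self._B = basis  # bool (nvars, f)
        self._trans_vars = trans_vars
        self.n_markers = n_markers

    @property
    def f(self) -> int:
        return self._B.shape[1]

    @property
    def n_solutions(self) -> int:
        return 1 << self.f

    def _assignment(self, bits) -> np.ndarray:
        bits = np.asarray(bits, dtype=bool)
        if bits.shape != (self.f,):
            raise ValueError(f"assignment must have length f={self.f}")
        return self._p ^ ((self._B & bits).sum(axis=1) % 2).astype(bool)

    def instantiate(self, bits) -> Configuration:
        """Haplotype configuration for one free-variable assignment."""
        assign = self._assignment(bits)
        config: Configuration = {}
        for ind in self.members:
            pair = []
            for side in (0, 1):
                h = np.full(self.n_markers, MISSING, dtype=np.int8)
                exprs = self._cells[(ind.iid, side)]
                for l, e in enumerate(exprs):
                    if e is not None:
                        v = e[0]
                        for var in e[1]:
                            v ^= int(assign[var])
                        h[l] = v
                pair.append(h)
            config[ind.iid] = (pair[0], pair[1])
        return config

    def transmissions(self, bits) -> dict[tuple[str, str], int | None]:
        """Resolved transmission bit per (child, parent), if observable."""
        assign = self._assignment(bits)
        out: dict[tuple[str, str], int | None] = {}
        for ind in self.members:
            if ind.father is None:
                continue
            for parent in (ind.father, ind.mother):
                var = self._trans_vars.get((ind.iid, parent))
                out[(ind.iid, parent)] = None if var is None else int(assign[var])
        return out

    def assignments(self):
        """All free-variable bit vectors, lexicographic order."""
        for bits in itertools.product((0, 1), repeat=self.f):
            yield np.array(bits, dtype=bool)

    def enumerate_solutions(self):
        """Yield all ``2**f`` configurations (pairwise distinct)."""
        for bits in self.assignments():
            yield self.instantiate(bits)


# ---------------------------------------------------------------------------
# construction


def _gauss_gf2(rows: list[tuple[frozenset[int], int]], nvars: int):
    """RREF of an XOR system.  Returns (pivot_rows, free_cols) or raises."""
    if rows:
        mat = np.zeros((len(rows), nvars + 1), dtype=bool)
        for r, (vs, c) in enumerate(rows):
            for v in vs:
                mat[r, v] = True
            mat[r, nvars] = bool(c)
    else:
        mat = np.zeros((0, nvars + 1), dtype=bool)
    rank = 0
    pivots: list[int] = []
    for col in range(nvars):
        sel = np.nonzero(mat[rank:, col])[0]
        if sel.size == 0:
            continue
        r = rank + sel[0]
        mat[[rank, r]] = mat[[r, rank]]
        others = np.nonzero(mat[:, col])[0]
        for o in others:
            if o != rank:
                mat[o] ^= mat[rank]
        pivots.append(col)
        rank += 1
        if rank == mat.shape[0]:
            break
    if np.any(mat[rank:, nvars]):
        raise RecombinantPedigreeError(
            "inconsistent zero-recombinant constraint system"
        )
    free = [c for c in range(nvars) if c not in set(pivots)]
    return mat[:rank], pivots, free


def build_solution_space(
    members: list[Individual], geno: dict[str, np.ndarray]
) -> SolutionSpace:
    """Build the zero-recombinant solution space of one pedigree.

    ``geno`` maps member id to the window's genotype codes.  Raises
    :class:`RecombinantPedigreeError` when the constraints admit no
    solution (obligate recombination or residual Mendelian error).
    """
    members = sorted(members, key=lambda i: i.iid)
    in_ped = {m.iid for m in members}
    n_markers = len(next(iter(geno.values()))) if members else 0
    for m in members:
        if len(geno[m.iid]) != n_markers:
            raise ValueError("genotype window length mismatch within pedigree")

    het = {m.iid: [l for l in range(n_markers) if geno[m.iid][l] == HET] for m in members}

    # canonical variable order: per member (sorted id): t_father, t_mother,
    # then phase bits by locus
    x_var: dict[tuple[str, int], int] = {}
    t_var: dict[tuple[str, str], int] = {}
    nv = 0
    for m in members:
        if m.father is not None:
            for parent in (m.father, m.mother):
                if parent in in_ped and het[parent]:
                    t_var[(m.iid, parent)] = nv
                    nv += 1
        for l in het[m.iid]:
            x_var[(m.iid, l)] = nv
            nv += 1

    def hap_expr(iid: str, side: int, l: int) -> Expr | None:
        g = int(geno[iid][l])
        if g == HOM_REF:
            return (0, ())
        if g == HOM_ALT:
            return (1, ())
        if g == HET:
            x = x_var[(iid, l)]
            return (side, (x,)) if side in (0, 1) else None
        return None  # missing

    def transmitted_expr(child: str, parent: str, l: int) -> Expr | None:
        g = int(geno[parent][l])
        if g == HOM_REF:
            return (0, ())
        if g == HOM_ALT:
            return (1, ())
        if g == HET:
            t = t_var.get((child, parent))
            if t is None:  # parent outside pedigree roster slice
                return None
            return (0, (x_var[(parent, l)], t))
        return None

    rows: list[tuple[frozenset[int], int]] = []

    # founder symmetry: pin first het locus phase
    for m in members:
        if (m.father is None or m.father not in in_ped) and het[m.iid]:
            rows.append((frozenset({x_var[(m.iid, het[m.iid][0])]}), 0))

    # Mendelian transmission equations
    for m in members:
        if m.father is None or m.father not in in_ped:
            continue
        for side, parent in ((0, m.father), (1, m.mother)):
            for l in range(n_markers):
                child_e = hap_expr(m.iid, side, l)
                parent_e = transmitted_expr(m.iid, parent, l)
                if child_e is None or parent_e is None:
                    continue
                const, vs = _xor_expr(child_e, parent_e)
                if not vs and const:
                    raise RecombinantPedigreeError(
                        f"locus {l}: child {m.iid} incompatible with {parent}"
                    )
                if vs:
                    rows.append((frozenset(vs), const))

    reduced, pivots, free = _gauss_gf2(rows, nv)

    # particular solution (free bits = 0) and basis over free bits
    particular = np.zeros(nv, dtype=bool)
    basis = np.zeros((nv, len(free)), dtype=bool)
    free_pos = {v: j for j, v in enumerate(free)}
    for j, v in enumerate(free):
        basis[v, j] = True
    for r, pv in enumerate(pivots):
        particular[pv] = reduced[r, nv]
        for v in free:
            basis[pv, free_pos[v]] = reduced[r, v]

    # haplotype cells
    cells: dict[tuple[str, int], list[Expr | None]] = {}
    for m in members:
        for side in (0, 1):
            row_cells: list[Expr | None] = []
            for l in range(n_markers):
                e = hap_expr(m.iid, side, l)
                if e is None and m.father is not None and m.father in in_ped:
                    parent = m.father if side == 0 else m.mother
                    e = transmitted_expr(m.iid, parent, l)
                row_cells.append(e)
            cells[(m.iid, side)] = row_cells

    # project out free bits with no effect on any cell, keeping the
    # lexicographically earliest independent subset -- guarantees
    # distinct bit vectors give distinct configurations
    if free:
        coeff_rows = []
        for row_cells in cells.values():
            for e in row_cells:
                if e and e[1]:
                    c = np.zeros(len(free), dtype=bool)
                    for var in e[1]:
                        c ^= basis[var]
                    if c.any():
                        coeff_rows.append(c)
        kept: list[int] = []
        if coeff_rows:
            cm = np.array(coeff_rows, dtype=bool)
            rank = 0
            for j in range(len(free)):
                sel = np.nonzero(cm[rank:, j])[0]
                if sel.size == 0:
                    continue
                r = rank + sel[0]
                cm[[rank, r]] = cm[[r, rank]]
                for o in np.nonzero(cm[:, j])[0]:
                    if o != rank:
                        cm[o] ^= cm[rank]
                kept.append(j)
                rank += 1
                if rank == cm.shape[0]:
                    break
        basis = basis[:, kept]
    return SolutionSpace(members, cells, particular, basis, t_var, n_markers)


# ---------------------------------------------------------------------------
# recombination fallback


class StitchedSpace:
    """Concatenation of per-segment zero-recombinant spaces.

    Used when the full window admits no zero-recombinant solution.  The
    free variables are the union of the segments' free variables; an
    instantiation stitches the per-segment configurations, greedily
    flipping founder haplotype pairs at each junction so that their
    children's transmissions switch as rarely as possible.  The result
    is always genotype-consistent but not guaranteed
    minimum-recombinant.
    """

    def __init__(self, segments: list[tuple[SolutionSpace, slice]], n_markers: int):
        self.segments = segments
        self.n_markers = n_markers
        self.members = segments[0][0].members
        self.member_ids = [m.iid for m in self.members]
        self._offsets = np.cumsum([0] + [s.f for s, _ in segments])

    @property
    def f(self) -> int:
        return int(self._offsets[-1])

    @property
    def n_solutions(self) -> int:
        return 1 << self.f

    def _split(self, bits):
        bits = np.asarray(bits, dtype=bool)
        if bits.shape != (self.f,):
            raise ValueError(f"assignment must have length f={self.f}")
        return [
            bits[self._offsets[k] : self._offsets[k + 1]]
            for k in range(len(self.segments))
        ]

    def _stitch(self, bits):
        parts = self._split(bits)
        configs = [s.instantiate(b) for (s, _), b in zip(self.segments, parts)]
        trans = [s.transmissions(b) for (s, _), b in zip(self.segments, parts)]
        children_of = {
            m.iid: [c.iid for c in self.members if m.iid in (c.father, c.mother)]
            for m in self.members
            if m.father is None
        }
        for k in range(1, len(configs)):
            for founder, kids in children_of.items():
                votes_keep = votes_flip = 0
                for kid in kids:
                    prev, cur = trans[k - 1].get((kid, founder)), trans[k].get(
                        (kid, founder)
                    )
                    if prev is None or cur is None:
                        continue
                    votes_keep += prev == cur
                    votes_flip += prev == (cur ^ 1)
                if votes_flip > votes_keep:
                    h0, h1 = configs[k][founder]
                    configs[k][founder] = (h1, h0)
                    for kid in kids:
                        if trans[k].get((kid, founder)) is not None:
                            trans[k][(kid, founder)] ^= 1
        return configs, trans

    def instantiate(self, bits) -> Configuration:
        configs, _ = self._stitch(bits)
        out: Configuration = {}
        for m in self.members:
            h0 = np.concatenate([c[m.iid][0] for c in configs])
            h1 = np.concatenate([c[m.iid][1] for c in configs])
            out[m.iid] = (h0, h1)
        return out

    def switch_counts(self, bits) -> dict[tuple[str, str], int]:
        """Transmission switches across junctions per (child, parent)."""
        _, trans = self._stitch(bits)
        counts: dict[tuple[str, str], int] = {}
        for key in trans[0]:
            last = trans[0][key]
            n = 0
            for k in range(1, len(trans)):
                cur = trans[k].get(key)
                if cur is not None and last is not None and cur != last:
                    n += 1
                if cur is not None:
                    last = cur
            counts[key] = n
        return counts

    def assignments(self):
        for bits in itertools.product((0, 1), repeat=self.f):
            yield np.array(bits, dtype=bool)

    def enumerate_solutions(self):
        for bits in self.assignments():
            yield self.instantiate(bits)


def segment_fallback(
    members: list[Individual], geno: dict[str, np.ndarray]
) -> StitchedSpace:
    """Split the window into maximal zero-recombinant prefix segments.

    Each segment boundary is found by binary search (consistency is
    monotone in window growth).  A single locus that is inconsistent on
    its own carries a residual Mendelian error and is blanked for the
    pedigree.
    """
    n_markers = len(next(iter(geno.values())))
    geno = {i: g.copy() for i, g in geno.items()}

    def ok(lo: int, hi: int) -> SolutionSpace | None:
        try:
            return build_solution_space(
                members, {i: g[lo:hi] for i, g in geno.items()}
            )
        except RecombinantPedigreeError:
            return None

    segments: list[tuple[SolutionSpace, slice]] = []
    start = 0
    while start < n_markers:
        if ok(start, start + 1) is None:
            for g in geno.values():
                g[start] = MISSING
        lo, hi = start + 1, n_markers
        while lo < hi:  # largest end with a consistent segment
            mid = (lo + hi + 1) // 2
            if ok(start, mid) is not None:
                lo = mid
            else:
                hi = mid - 1
        segments.append((ok(start, lo), slice(start, lo)))
        start = lo
    return StitchedSpace(segments, n_markers)


def solve_pedigree(members: list[Individual], geno: dict[str, np.ndarray]):
    """Zero-recombinant space, falling back to segment stitching."""
    try:
        return build_solution_space(members, geno)
    except RecombinantPedigreeError:
        return segment_fallback(members, geno)
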