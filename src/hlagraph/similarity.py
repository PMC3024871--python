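"""Haplotype similarity via maximum regions of nearly identical matching.

Two haplotypes over ``{0, 1, unknown}`` are compared locus by locus: a
locus *matches* when both alleles are known and equal, *mismatches*
when both are known and unequal, and carries no evidence otherwise.
Given an integer tolerance ``t_mis >= 1``, a region ``[p, q]`` (1-based,
``p < q``) is a *maximum region of nearly identical matching* when

1. both endpoints are matching loci,
2. no run of more than ``t_mis`` consecutive mismatches lies inside it,
3. its number of matching loci attains the global maximum over all
   regions satisfying 1-2.

The similarity of two length-``n`` haplotypes is that maximum matching
count divided by ``n`` (0 when no valid region exists), a value in
``[0, 1]`` that reaches 1 exactly for identical fully-known haplotypes.
The division by the full window length ``n`` -- unknown loci included --
keeps weights comparable across pairs.

Unknown loci neither match nor mismatch; in particular they interrupt a
run of consecutive mismatches (absence of evidence is not evidence of
divergence).  The tolerance exists to absorb isolated genotyping errors:
a haplotype carrying a shared HLA allele background with a couple of
miscalled SNPs still scores close to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import MISSING

#: default mismatch-run tolerance
DEFAULT_T_MIS = 2

_MATCH, _MISMATCH, _UNKNOWN = 1, 0, -1


@dataclass(frozen=True)
class MatchRegion:
    """A nearly-identical matching region ``[p, q]`` (1-based, inclusive)."""

    p: int
    q: int
    matches: int


def as_haplotype(x) -> np.ndarray:
    """Coerce a string like ``"01-1"`` or a sequence to an int8 array."""
    if isinstance(x, str):
        return np.array(
            [MISSING if c in "-?" else int(c) for c in x], dtype=np.int8
        )
    return np.asarray(x, dtype=np.int8)


def locus_state(a: int, b: int) -> str:
    """Classify one locus pair: ``match`` / ``mismatch`` / ``unknown``."""
    if a == MISSING or b == MISSING:
        return "unknown"
    return "match" if a == b else "mismatch"


def _states(h_i: np.ndarray, h_j: np.ndarray) -> np.ndarray:
    if h_i.shape != h_j.shape:
        raise ValueError("haplotype length mismatch")
    known = (h_i != MISSING) & (h_j != MISSING)
    out = np.full(h_i.shape, _UNKNOWN, dtype=np.int8)
    out[known & (h_i == h_j)] = _MATCH
    out[known & (h_i != h_j)] = _MISMATCH
    return out


def _blocks(states: np.ndarray, t_mis: int):
    """Candidate regions: maximal stretches whose internal mismatch runs
    are all <= t_mis, trimmed to their first/last matching locus.

    A run of more than ``t_mis`` consecutive mismatches can never lie
    inside a valid region, and region endpoints must match, so the
    trimmed stretches between such runs enumerate every candidate.
    Yields (first_match, last_match, match_count) in 0-based indices.
    """
    first = last = -1
    count = 0
    run = 0
    for k, s in enumerate(states):
        if s == _MISMATCH:
            run += 1
            if run > t_mis and first >= 0:
                yield first, last, count
                first, last, count = -1, -1, 0
        else:
            run = 0
            if s == _MATCH:
                if first < 0:
                    first = k
                last = k
                count += 1
    if first >= 0:
        yield first, last, count


def max_match_regions(h_i, h_j, t_mis: int = DEFAULT_T_MIS) -> list[MatchRegion]:
    """All maximum regions of nearly identical matching of two haplotypes.

    Every returned region attains the same (maximal) match count; the
    list is empty when no region with two matching endpoints exists.
    """
    if t_mis < 1:
        raise ValueError("t_mis must be an integer >= 1")
    h_i, h_j = as_haplotype(h_i), as_haplotype(h_j)
    cands = [b for b in _blocks(_states(h_i, h_j), t_mis) if b[2] >= 2]
    if not cands:
        return []
    best = max(c[2] for c in cands)
    return [
        MatchRegion(p + 1, q + 1, n) for p, q, n in cands if n == best
    ]


def similarity(h_i, h_j, t_mis: int = DEFAULT_T_MIS) -> float:
    """Similarity in ``[0, 1]``; symmetric; 1 iff identical fully-known."""
    h_i, h_j = as_haplotype(h_i), as_haplotype(h_j)
    regions = max_match_regions(h_i, h_j, t_mis)
    if not regions:
        return 0.0
    return regions[0].matches / h_i.shape[0]


# -- content-addressed cache ------------------------------------------------

_cache: dict[tuple[bytes, bytes, int], float] = {}


def cached_similarity(h_i: np.ndarray, h_j: np.ndarray, t_mis: int) -> float:
    """Memoized :func:`similarity` keyed by haplotype content.

    The pairwise weights of committed haplotypes are recomputed many
    times during the incremental configuration search; caching by byte
    content makes candidate evaluation cheap.
    """
    a, b = h_i.tobytes(), h_j.tobytes()
    if b < a:
        a, b = b, a
    key = (a, b, t_mis)
    hit = _cache.get(key)
    if hit is None:
        hit = _cache[key] = similarity(h_i, h_j, t_mis)
    return hit


def clear_cache() -> None:
    _cache.clear()
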