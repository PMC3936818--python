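"""Independent oracles used by the test suite.

Each function here recomputes a quantity by a route deliberately different
from the library implementation: exact rational combinatorics for the
hypergeometric tail, literal draw enumeration at tiny sizes, a per-base
origin-tracking map for coordinate lifting, full-CDS translation for
coding effects, and a direct cumulative-sum N50.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

from Bio.Seq import Seq

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def hypergeom_tail_exact(k: int, K: int, n: int, N: int) -> float:
    """P[X >= k] as an exact rational from binomial coefficients."""
    total = comb(N, n)
    acc = Fraction(0)
    for i in range(k, min(n, K) + 1):
        acc += Fraction(comb(K, i) * comb(N - K, n - i), total)
    return float(acc)


def hypergeom_tail_enumerated(k: int, K: int, n: int, N: int) -> float:
    """P[X >= k] by enumerating every size-n draw from an N-element urn
    with K marked items.  Only feasible for tiny N."""
    marked = set(range(K))
    hits = 0
    total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if sum(1 for x in draw if x in marked) >= k:
            hits += 1
    return hits / total


def n50_bruteforce(lengths: list[int]) -> int:
    """N50 straight from the definition: the largest L among the segments
    such that segments of length >= L cover at least half the total."""
    if not lengths:
        return 0
    total = sum(lengths)
    candidates = []
    for L in sorted(set(lengths), reverse=True):
        covered = sum(x for x in lengths if x >= L)
        if 2 * covered >= total:
            candidates.append(L)
    return max(candidates)


def base_tracking_map(seq_len: int, records) -> dict[int, int]:
    """Map of surviving reference positions to variety positions, built by
    explicitly tracking the origin of every base of the edited sequence."""
    new_origins: list[int | None] = []
    cursor = 1
    for rec in sorted(records, key=lambda r: r.pos):
        ref_len = len(rec.ref_allele)
        alt_len = len(rec.alt_allele)
        if ref_len == 1 and alt_len == 1:
            continue  # SNP: base survives in place
        if ref_len == 0:
            new_origins.extend(range(cursor, rec.pos + 1))
            new_origins.extend([None] * alt_len)
            cursor = rec.pos + 1
        else:
            new_origins.extend(range(cursor, rec.pos))
            matched = min(ref_len, alt_len)
            new_origins.extend(range(rec.pos, rec.pos + matched))
            new_origins.extend([None] * (alt_len - matched))
            cursor = rec.pos + ref_len
    new_origins.extend(range(cursor, seq_len + 1))
    return {
        origin: i
        for i, origin in enumerate(new_origins, start=1)
        if origin is not None
    }


def translation_effect(gene, variant, genome) -> str:
    """Coding effect of a CDS SNV by translating the whole mutant CDS and
    diffing the two proteins."""
    local = gene.cds_local_position(variant.pos)
    assert local is not None
    cds = gene.cds_sequence(genome)
    alt = variant.alt_allele
    if gene.strand == "-":
        alt = alt.translate(_COMPLEMENT)[::-1]
    mutant = cds[: local - 1] + alt + cds[local:]
    ref_prot = str(Seq(cds).translate())
    mut_prot = str(Seq(mutant).translate())
    if ref_prot == mut_prot:
        return "synonymous"
    i = next(j for j, (a, b) in enumerate(zip(ref_prot, mut_prot)) if a != b)
    if i == 0:
        return "start_lost"
    if mut_prot[i] == "*":
        return "stop_gained"
    if ref_prot[i] == "*":
        return "stop_lost"
    return "missense"
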