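"""Independent reference implementations used to check the package.

Everything here is deliberately written in the most naive possible style
(explicit loops, exact rational arithmetic, exhaustive search) so that
agreement with the vectorized / optimized library code is meaningful.
"""
from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np

HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1


def brute_sems(calls: np.ndarray, sexes: list[str],
               min_callrate_per_sex: float = 0.9,
               strict_hom_class: bool = False,
               strict_no_missing: bool = False) -> list[tuple[int, str]]:
    """Per-site loop re-deriving the exact sex-matching classification."""
    out = []
    f_idx = [j for j, s in enumerate(sexes) if s == "F"]
    m_idx = [j for j, s in enumerate(sexes) if s == "M"]
    for i in range(calls.shape[0]):
        fc = [int(calls[i, j]) for j in f_idx]
        mc = [int(calls[i, j]) for j in m_idx]
        fnm = [g for g in fc if g != MISSING]
        mnm = [g for g in mc if g != MISSING]
        if not fnm or not mnm:
            continue
        if strict_no_missing:
            if len(fnm) != len(fc) or len(mnm) != len(mc):
                continue
        else:
            if (len(fnm) < min_callrate_per_sex * len(fc)
                    or len(mnm) < min_callrate_per_sex * len(mc)):
                continue

        def all_hom(gs):
            ok = all(g in (HOM_REF, HOM_ALT) for g in gs)
            if ok and strict_hom_class:
                ok = len(set(gs)) == 1
            return ok

        def all_het(gs):
            return all(g == HET for g in gs)

        if all_hom(fnm) and all_het(mnm):
            out.append((i, "XY"))
        elif all_hom(mnm) and all_het(fnm):
            out.append((i, "ZW"))
    return out


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by exact rational hypergeometric enumeration.

    Sums P(X = x) over all tables with the same margins whose probability
    does not exceed that of the observed table (exact arithmetic, so ties
    are handled without floating-point fuzz).  Degenerate margins give 1.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if min(r1, r2, c1, n - c1) == 0:
        return 1.0
    denom = comb(n, c1)

    def pmf(x: int) -> Fraction:
        return Fraction(comb(r1, x) * comb(r2, c1 - x), denom)

    p_obs = pmf(a)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = pmf(x)
        if px <= p_obs:
            total += px
    return float(min(total, Fraction(1)))


def brute_chain_value(hits, max_overlap: int = 10, match: int = 1) -> int:
    """Exhaustive maximum chain value over all hit subsets (n <= ~15).

    A chain is a subset ordered by (qend, qstart) in which each consecutive
    pair satisfies prev.qstart < next.qstart and prev.qend - next.qstart <=
    max_overlap; its value is the score sum minus match * positive overlaps.
    """
    n = len(hits)
    assert n <= 15, "exhaustive search only meant for small instances"
    order = sorted(range(n), key=lambda i: (hits[i].qend, hits[i].qstart))
    best = 0
    for mask in range(1, 1 << n):
        chain = [order[i] for i in range(n) if mask >> i & 1]
        ok = True
        val = 0
        for k, i in enumerate(chain):
            val += hits[i].score
            if k:
                j = chain[k - 1]
                ov = hits[j].qend - hits[i].qstart
                if ov > max_overlap or hits[j].qstart >= hits[i].qstart:
                    ok = False
                    break
                val -= max(0, ov) * match
        if ok and val > best:
            best = val
    return best


def overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start < b_end and b_start < a_end
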