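"""Exact integer-lattice lower-left hull machinery.

Every candidate decoding of the LS model maps to a lattice point
``(r, m)`` — switches and mismatches are integers once the mismatch
penalty is normalized to 1.  The optimal cost at penalty ``beta`` is
``min_i m_i + beta * r_i``, so only points on the *lower-left* convex
hull (strictly decreasing ``m``, strictly increasing slopes) can ever be
optimal for some ``beta > 0``.  All arithmetic here is exact integer /
rational arithmetic: results are identical across platforms and immune
to floating-point rounding.

The breakpoints between adjacent hull vertices,
``beta_i = (m_i - m_{i+1}) / (r_{i+1} - r_i)``, partition ``(0, inf)``
into intervals on which the optimal vertex is constant.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Iterable, Sequence

__all__ = [
    "CostPoint",
    "lower_left_hull",
    "merge_chains",
    "theorem2_breakpoints",
    "region_for_beta",
    "regions_from_breakpoints",
    "chain_to_json",
    "validate_chain",
]


class CostPoint:
    """An exact lattice point (r = switches, m = mismatches) with an
    opaque provenance payload used for path reconstruction."""

    __slots__ = ("r", "m", "prov")

    def __init__(self, r: int, m: int, prov=None):
        if not isinstance(r, int) or not isinstance(m, int):
            raise TypeError("cost coordinates must be exact integers")
        if r < 0 or m < 0:
            raise ValueError("cost coordinates must be nonnegative")
        self.r = r
        self.m = m
        self.prov = prov

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"CostPoint(r={self.r}, m={self.m})"

    def coords(self) -> tuple[int, int]:
        return (self.r, self.m)


def _dedup_min_m(points: Iterable[CostPoint]) -> list[CostPoint]:
    """Keep, for each r, the point with minimal m.  Ties keep the point
    seen first, so callers control tie-breaking by candidate order."""
    best: dict[int, CostPoint] = {}
    for p in points:
        q = best.get(p.r)
        if q is None or p.m < q.m:
            best[p.r] = p
    return [best[r] for r in sorted(best)]


def lower_left_hull(points: Sequence[CostPoint]) -> list[CostPoint]:
    """Strictly convex lower-left chain of a set of lattice points.

    Duplicates in ``r`` are first reduced to the minimal ``m``; points to
    the right of the minimal-m point are discarded (they cost more in
    both coordinates and are never optimal for ``beta > 0``).  The
    remaining monotone chain has strictly decreasing ``m`` and strictly
    increasing (negative) slopes; collinear interior points are removed.

    Candidate order is significant only for tie-breaking of provenance:
    among candidates with identical (r, m), the first wins.
    """
    pts = _dedup_min_m(points)
    if not pts:
        raise ValueError("empty point set")
    # Truncate at the leftmost global-minimum-m point: beyond it every
    # point has more switches and at least as many mismatches.
    m_min = min(p.m for p in pts)
    for i, p in enumerate(pts):
        if p.m == m_min:
            pts = pts[: i + 1]
            break
    # Andrew's monotone-chain lower hull on points sorted by r.  The
    # cross-product test uses exact integer arithmetic; "<= 0" also
    # removes collinear interior points, keeping the chain strictly
    # convex.
    hull: list[CostPoint] = []
    for p in pts:
        while len(hull) >= 2:
            a, b = hull[-2], hull[-1]
            if (b.r - a.r) * (p.m - a.m) - (b.m - a.m) * (p.r - a.r) <= 0:
                hull.pop()
            else:
                break
        hull.append(p)
    return hull


def merge_chains(chains: Sequence[Sequence[CostPoint]]) -> list[CostPoint]:
    """Lower-left hull of the union of several chains.

    By the Krein-Milman argument, the vertices of the global hull are a
    subset of the pooled local vertices, so merging chains loses nothing
    relative to pooling the raw points.
    """
    if not chains:
        raise ValueError("need at least one chain")
    pooled: list[CostPoint] = []
    for ch in chains:
        pooled.extend(ch)
    return lower_left_hull(pooled)


def theorem2_breakpoints(chain: Sequence[CostPoint]) -> list[Fraction]:
    """Exact rational breakpoints between adjacent hull vertices.

    ``beta_i = (m_i - m_{i+1}) / (r_{i+1} - r_i)``, strictly decreasing
    along the chain (a consequence of strict convexity).  A single-vertex
    chain has no breakpoints: one region covers all beta > 0.
    """
    validate_chain(chain)
    bps = [
        Fraction(chain[i].m - chain[i + 1].m, chain[i + 1].r - chain[i].r)
        for i in range(len(chain) - 1)
    ]
    return bps


def validate_chain(chain: Sequence[CostPoint]) -> None:
    """Raise if ``chain`` is not a strictly convex lower-left chain."""
    if len(chain) == 0:
        raise ValueError("empty chain")
    prev_slope: Fraction | None = None
    for i in range(len(chain) - 1):
        a, b = chain[i], chain[i + 1]
        if b.r <= a.r or b.m >= a.m:
            raise ValueError("chain must have strictly increasing r, strictly decreasing m")
        slope = Fraction(b.m - a.m, b.r - a.r)
        if prev_slope is not None and slope <= prev_slope:
            raise ValueError("chain slopes must be strictly increasing (strict convexity)")
        prev_slope = slope


def region_for_beta(
    chain: Sequence[CostPoint],
    breakpoints: Sequence[Fraction],
    beta,
) -> tuple[int, bool]:
    """Index of the optimal vertex at penalty ``beta``, plus a tie flag.

    Returns ``argmin_i m_i + beta * r_i``.  Exactly at a breakpoint two
    adjacent vertices are optimal; the smaller-r vertex is returned and
    the tie is flagged.  Float betas are converted to exact rationals so
    the comparison is by cross-multiplication, never by float rounding.
    """
    if not isinstance(beta, Fraction):
        beta = Fraction(beta)
    if beta <= 0:
        raise ValueError("beta must be positive")
    # The optimal vertex is the last one whose entering breakpoint is <= beta;
    # equivalently scan the decreasing breakpoint list.
    idx = 0
    tie = False
    for i, bp in enumerate(breakpoints):
        if beta > bp:
            break
        idx = i + 1
        if beta == bp:
            idx = i
            tie = True
            break
    return idx, tie


def regions_from_breakpoints(breakpoints: Sequence[Fraction]):
    """Half-open beta intervals, one per vertex, tiling ``(0, inf)``.

    Vertex ``i`` is optimal on ``[beta_i, beta_{i-1})`` where
    ``beta_0 = inf`` (represented as ``None``) and the last interval is
    open at 0.  At the shared endpoint both neighbours are optimal; the
    interval is attached to the smaller-r vertex.
    """
    M = len(breakpoints) + 1
    out = []
    for i in range(M):
        hi = breakpoints[i - 1] if i >= 1 else None  # None == +infinity
        lo = breakpoints[i] if i < M - 1 else Fraction(0)
        out.append((lo, hi))
    return out


def chain_to_json(chain: Sequence[CostPoint], breakpoints: Sequence[Fraction]) -> dict:
    """JSON-friendly dict: vertices as [r, m] pairs, breakpoints as
    reduced [numerator, denominator] pairs."""
    return {
        "vertices": [[p.r, p.m] for p in chain],
        "breakpoints": [[bp.numerator, bp.denominator] for bp in breakpoints],
    }
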