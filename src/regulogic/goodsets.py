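"""Hart's edge-maximizing vertex sets on the k-cube.

For a fixed number P of "on" vertices, minimizing average sensitivity is
the same as maximizing E11, the number of cube edges internal to the on
set (E01 + 2*E11 = k*P with k, P fixed).  Hart's recursion builds an
optimal ("good") set: find r with 2**r < P <= 2**(r+1), fill one r-cube
of an (r+1)-cube with 2**r vertices, and place the remaining P - 2**r
vertices as a good set on the sibling r-cube.

The construction here is deterministic: the recursion always works on
the highest free coordinate, fills the half where that coordinate is 0,
and descends (when no fill happens at a level) into subcubes with the
higher coordinates set to 1; the base case picks the all-ones vertex of
the remaining coordinates.  Reading the binary digits of P most
significant first then yields the canalyzing layers directly: a 1 digit
contributes a negative literal followed by OR, a 0 digit a positive
literal followed by AND — so an odd-P good set induces exactly a nested
canalyzing function, and an even-P good set induces an ineffective
function whose truncation is an NCF on fewer variables.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache

from .bf_core import And, BoolExpr, Literal, Or, TruthTable, bias
from .complexity import average_sensitivity, hypercube_edges

__all__ = [
    "GoodSet",
    "build_good_set",
    "good_set_to_ncf",
    "reduce_even_good_set",
    "min_average_sensitivity",
]


@dataclass(frozen=True)
class GoodSet:
    """A Hart-optimal placement of P vertices on the k-cube."""

    k: int
    P: int
    vertices: frozenset[int]
    dims: tuple[int, ...]            # exponents of the binary expansion of P
    induced_function: TruthTable

    @property
    def E11(self) -> int:
        return hypercube_edges(self.induced_function)[1]


def _good_vertices(k: int, P: int, fixed: int, free: int) -> set[int]:
    """Recursive construction on the subcube spanned by the ``free``
    lowest coordinates, with higher coordinates frozen in ``fixed``."""
    if P == 1 << free:
        return {fixed | m for m in range(1 << free)}
    if P == 1:
        return {fixed | ((1 << free) - 1)}
    # find r with 2^r < P <= 2^(r+1); descend into higher halves (set
    # to 1) until the (r+1)-cube is the current cube
    r = (P - 1).bit_length() - 1
    while free > r + 1:
        free -= 1
        fixed |= 1 << free
    # fill the half with the top coordinate 0, recurse on the sibling
    top = 1 << (free - 1)
    filled = {fixed | m for m in range(top)}
    rest = _good_vertices(k, P - top, fixed | top, free - 1)
    return filled | rest


def build_good_set(k: int, P: int) -> GoodSet:
    """Good set of P vertices on the k-cube (1 <= P < 2**k)."""
    if not 1 <= P < 1 << k:
        raise ValueError(f"P must satisfy 1 <= P < 2**k, got P={P}, k={k}")
    vertices = frozenset(_good_vertices(k, P, 0, k))
    assert len(vertices) == P
    mask = 0
    for v in vertices:
        mask |= 1 << v
    dims = tuple(i for i in range(k) if P >> i & 1)
    return GoodSet(k, P, vertices, dims, TruthTable.from_mask(mask, k))


def _chain_expr(k: int, P: int) -> BoolExpr:
    """Nested canalyzing chain matching the deterministic good set.

    Digits of P (k bits, most significant first) map layer by layer onto
    coordinates x_k down to x_1: digit 1 -> ~x_c OR (...), digit 0 ->
    x_c AND (...); the last layer is the bare literal (positive since P
    is odd).
    """
    assert P % 2 == 1
    bits = [(P >> (k - 1 - j)) & 1 for j in range(k)]     # MSB first
    expr: BoolExpr = Literal(1, positive=True)
    for j in range(k - 2, -1, -1):
        c = k - j
        if bits[j]:
            expr = Or((Literal(c, positive=False), expr))
        else:
            expr = And((Literal(c, positive=True), expr))
    return expr


def good_set_to_ncf(gs: GoodSet) -> BoolExpr:
    """The nested canalyzing expression induced by an odd-P good set."""
    if gs.P % 2 == 0:
        raise ValueError(
            "even-P good sets induce ineffective functions; "
            "use reduce_even_good_set"
        )
    return _chain_expr(gs.k, gs.P)


def reduce_even_good_set(gs: GoodSet) -> tuple[BoolExpr, tuple[int, ...]]:
    """NCF over the effective variables of an even-P good set.

    With t trailing zero bits in P the t lowest inputs are ineffective;
    the induced function equals the good-set function of P >> t on the
    top k - t coordinates, renumbered 1..k-t.
    """
    if gs.P % 2 == 1:
        raise ValueError("good set has odd P; it is already an NCF")
    if gs.P == 0:
        raise ValueError("P must be positive")
    t = (gs.P & -gs.P).bit_length() - 1
    kk = gs.k - t
    expr = _chain_expr(kk, gs.P >> t)
    return expr, tuple(range(1, t + 1))


def min_average_sensitivity(k: int, P: int) -> Fraction:
    """Minimum average sensitivity over the k[P] set.

    Attained by the good-set-induced function; symmetric under
    P -> 2**k - P by output complementation.
    """
    if not 0 <= P <= 1 << k:
        raise ValueError(f"P out of range for k={k}")
    if P in (0, 1 << k):
        return Fraction(0)
    if P > 1 << (k - 1):
        P = (1 << k) - P
    return average_sensitivity(build_good_set(k, P).induced_function)
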