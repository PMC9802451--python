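"""Classifiers for biologically meaningful Boolean function types.

The types form a lattice: effective functions (EF, every input matters),
unate functions (UF, each input purely activating or inhibiting),
canalyzing functions (CF, some input value forces the output), nested
canalyzing functions (NCF, canalyzing recursively down to a single
literal), and read-once functions (RoF, expressible with every variable
appearing exactly once).  NCF ⊆ RoF ⊆ UF ∩ EF, and every RoF has odd
bias while every ineffective function has even bias.

Conventions adopted here:

* Constant functions are ineffective, and they *do* count as canalyzing
  (every input value trivially forces the output); this matches the
  standard canalyzing-function counts 4, 14, 120, 3514 for k = 1..4.
  Constants are never NCFs or RoFs.
* RoF membership is decided by lookup in the recursively generated
  catalog (default bound k <= 6), which contains the *full* set of RoF
  truth tables — the generation enumerates all variable orders and
  signs, so the set is closed under isomorphism and no per-query
  canonicalization is needed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Literal as TLiteral, Optional

from .bf_core import (
    And,
    BoolExpr,
    Literal,
    Or,
    TruthTable,
    _full,
    bias,
    half_mask,
    input_flip_mask,
    var_mask,
)

__all__ = [
    "TypeProfile",
    "FunctionCatalog",
    "CanalyzingInput",
    "effective_inputs",
    "is_effective",
    "truncate_ineffective",
    "input_sign",
    "input_signs",
    "is_unate",
    "canalyzing_inputs",
    "is_canalyzing",
    "is_ncf",
    "ncf_chain",
    "is_rof",
    "build_catalog",
    "catalog_masks",
    "classify",
    "TYPE_PREDICATES",
    "DEFAULT_CATALOG_BOUND",
]

DEFAULT_CATALOG_BOUND = 6


# ---------------------------------------------------------------------------
# mask-level predicates (fast paths used by the census scans)
# ---------------------------------------------------------------------------

def _effective_inputs_mask(mask: int, k: int) -> tuple[int, ...]:
    return tuple(
        i for i in range(1, k + 1) if input_flip_mask(mask, k, i) != mask
    )


def _restrict(mask: int, k: int, i: int, value: int) -> int:
    """Subfunction with x_i fixed; remaining variables renumbered,
    preserving their relative order."""
    s = 1 << (i - 1)
    out = 0
    pos = 0
    for row in range(1 << k):
        if (row >> (i - 1) & 1) == value:
            out |= (mask >> row & 1) << pos
            pos += 1
    return out


def _input_sign_mask(mask: int, k: int, i: int) -> str:
    s = 1 << (i - 1)
    lo_sel = half_mask(k, i)
    bits0 = mask & lo_sel
    bits1 = (mask >> s) & lo_sel
    act = (bits0 & ~bits1 & lo_sel) == 0     # f(x_i=0) <= f(x_i=1)
    inh = (bits1 & ~bits0 & lo_sel) == 0     # f(x_i=0) >= f(x_i=1)
    if act and inh:
        return "both"
    if act:
        return "activating"
    if inh:
        return "inhibiting"
    return "mixed"


def _canalyzing_inputs_mask(mask: int, k: int) -> list[tuple[int, int, int]]:
    full = _full(k)
    out = []
    for i in range(1, k + 1):
        s = 1 << (i - 1)
        lo_sel = half_mask(k, i)
        bits0 = mask & lo_sel
        bits1 = (mask >> s) & lo_sel
        for a, half in ((0, bits0), (1, bits1)):
            if half == 0:
                out.append((i, a, 0))
            elif half == lo_sel:
                out.append((i, a, 1))
    return out


def _is_ncf_mask(mask: int, k: int) -> Optional[list[tuple[int, int, int]]]:
    """Witness chain [(input, canalyzing value a, canalyzed value b), ...]
    if the function is nested canalyzing, else None.

    Ties broken deterministically: ascending input index, canalyzing
    value 0 before 1.
    """
    if k == 1:
        if mask == 0b10:            # f = x1
            return [(1, 0, 0)]
        if mask == 0b01:            # f = ~x1
            return [(1, 0, 1)]
        return None
    if mask in (0, _full(k)):
        return None
    for i, a, b in _canalyzing_inputs_mask(mask, k):
        sub = _restrict(mask, k, i, 1 - a)
        chain = _is_ncf_mask(sub, k - 1)
        if chain is not None:
            # re-label the subfunction's inputs back to original indices
            rest = [j for j in range(1, k + 1) if j != i]
            fixed = [(rest[j - 1], aa, bb) for (j, aa, bb) in chain]
            return [(i, a, b)] + fixed
    return None


# ---------------------------------------------------------------------------
# public classifiers on TruthTable
# ---------------------------------------------------------------------------

def effective_inputs(tt: TruthTable) -> tuple[int, ...]:
    """Inputs i for which some flip of x_i changes the output."""
    return _effective_inputs_mask(tt.mask, tt.k)


def is_effective(tt: TruthTable) -> bool:
    return len(effective_inputs(tt)) == tt.k


def truncate_ineffective(tt: TruthTable) -> TruthTable:
    """Project onto the effective inputs only.

    Fixing the ineffective inputs to any values yields the same reduced
    function, so the projection is well defined.  Raises on constants.
    """
    eff = effective_inputs(tt)
    if not eff:
        raise ValueError("constant function: no effective inputs to keep")
    if len(eff) == tt.k:
        return tt
    mask, k = tt.mask, tt.k
    for i in sorted(set(range(1, k + 1)) - set(eff), reverse=True):
        mask = _restrict(mask, k, i, 0)
        k -= 1
    return TruthTable.from_mask(mask, k)


def input_sign(tt: TruthTable, i: int) -> str:
    """'activating', 'inhibiting', 'both' (=> ineffective) or 'mixed'."""
    if not 1 <= i <= tt.k:
        raise ValueError(f"input {i} out of range")
    return _input_sign_mask(tt.mask, tt.k, i)


def input_signs(tt: TruthTable) -> tuple[str, ...]:
    return tuple(_input_sign_mask(tt.mask, tt.k, i) for i in range(1, tt.k + 1))


def is_unate(tt: TruthTable) -> bool:
    """True iff every input is consistently activating or inhibiting."""
    return all(s != "mixed" for s in input_signs(tt))


@dataclass(frozen=True)
class CanalyzingInput:
    input: int
    canalyzing_value: int
    canalyzed_value: int


def canalyzing_inputs(tt: TruthTable) -> tuple[CanalyzingInput, ...]:
    return tuple(
        CanalyzingInput(*t) for t in _canalyzing_inputs_mask(tt.mask, tt.k)
    )


def is_canalyzing(tt: TruthTable) -> bool:
    """At least one input value forces the output.  Constants qualify."""
    return bool(_canalyzing_inputs_mask(tt.mask, tt.k))


def ncf_chain(tt: TruthTable) -> Optional[tuple[CanalyzingInput, ...]]:
    chain = _is_ncf_mask(tt.mask, tt.k)
    return None if chain is None else tuple(CanalyzingInput(*t) for t in chain)


def is_ncf(tt: TruthTable) -> bool:
    """Nested canalyzing: canalyzing input whose non-canalyzed
    subfunction is recursively nested canalyzing, down to a literal."""
    return _is_ncf_mask(tt.mask, tt.k) is not None


# ---------------------------------------------------------------------------
# catalogs of NCFs and RoFs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FunctionCatalog:
    """The full truth-table set of a function type at fixed k."""

    k: int
    type: str                       # 'NCF' | 'RoF' | 'nonNCF-RoF'
    masks: frozenset[int]

    @property
    def count(self) -> int:
        return len(self.masks)

    def __contains__(self, item) -> bool:
        mask = item.mask if isinstance(item, TruthTable) else int(item)
        return mask in self.masks

    def sorted_masks(self) -> tuple[int, ...]:
        return tuple(sorted(self.masks))


@lru_cache(maxsize=None)
def _rof_masks_on(vars_: frozenset[int], k: int) -> frozenset[int]:
    """All read-once functions over exactly the variable set ``vars_``,
    as masks on the full k-cube (rows of the other variables ignored)."""
    if len(vars_) == 1:
        (v,) = vars_
        m = var_mask(k, v)
        return frozenset((m, m ^ _full(k)))
    pivot = min(vars_)
    rest = sorted(vars_ - {pivot})
    out: set[int] = set()
    for r in range(len(rest) + 1):
        for extra in itertools.combinations(rest, r):
            left = frozenset({pivot, *extra})
            right = vars_ - left
            if not right:
                continue
            lm = _rof_masks_on(left, k)
            rm = _rof_masks_on(right, k)
            for g in lm:
                for h in rm:
                    out.add(g & h)
                    out.add(g | h)
    return frozenset(out)


def _rof_masks(k: int) -> frozenset[int]:
    """Recursive pairing generation: every k-input RoF arises as
    g ⊙ h over a split of the variable set, base case signed literals."""
    return _rof_masks_on(frozenset(range(1, k + 1)), k)


def _ncf_masks(k: int) -> frozenset[int]:
    """Enumerate all nested canalyzing chains
    X_s(1) ⊙ (X_s(2) ⊙ (... X_s(k))) over permutations, signs and
    operators, deduplicating truth tables."""
    full = _full(k)
    lits = {}
    for v in range(1, k + 1):
        m = var_mask(k, v)
        lits[(v, 1)] = m
        lits[(v, 0)] = m ^ full
    if k == 1:
        return frozenset((lits[(1, 1)], lits[(1, 0)]))
    out: set[int] = set()
    sign_choices = list(itertools.product((0, 1), repeat=k))
    op_choices = list(itertools.product((0, 1), repeat=k - 1))  # 1 = AND
    for perm in itertools.permutations(range(1, k + 1)):
        for signs in sign_choices:
            inner = lits[(perm[-1], signs[-1])]
            for ops in op_choices:
                f = inner
                for j in range(k - 2, -1, -1):
                    lit = lits[(perm[j], signs[j])]
                    f = (lit & f) if ops[j] else (lit | f)
                out.add(f)
    return frozenset(out)


@lru_cache(maxsize=None)
def build_catalog(k: int, type: str,
                  bound: int = DEFAULT_CATALOG_BOUND) -> FunctionCatalog:
    """Generate the complete truth-table catalog for NCF, RoF or
    nonNCF-RoF at the given k (k <= bound)."""
    if k > bound:
        raise ValueError(f"catalogs supported for k <= {bound}, got k={k}")
    if type == "RoF":
        masks = _rof_masks(k)
    elif type == "NCF":
        masks = _ncf_masks(k)
    elif type == "nonNCF-RoF":
        masks = frozenset(_rof_masks(k) - _ncf_masks(k))
    else:
        raise ValueError(f"unknown catalog type {type!r}")
    return FunctionCatalog(k=k, type=type, masks=masks)


def catalog_masks(k: int, type: str,
                  bound: int = DEFAULT_CATALOG_BOUND) -> frozenset[int]:
    return build_catalog(k, type, bound).masks


def is_rof(tt: TruthTable, bound: int = DEFAULT_CATALOG_BOUND) -> bool:
    """Read-once membership by catalog lookup (k <= bound)."""
    if tt.k > bound:
        raise ValueError(
            f"RoF test needs the k={tt.k} catalog; bound is {bound}"
        )
    return tt.mask in catalog_masks(tt.k, "RoF", bound)


# ---------------------------------------------------------------------------
# the combined profile
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TypeProfile:
    k: int
    bias: int
    parity: str                                  # 'odd' | 'even'
    is_effective: bool
    ineffective_inputs: tuple[int, ...]
    input_signs: tuple[str, ...]
    is_unate: bool
    is_canalyzing: bool
    canalyzing_inputs: tuple[CanalyzingInput, ...]
    is_ncf: bool
    ncf_chain: Optional[tuple[CanalyzingInput, ...]]
    is_rof: Optional[bool]                       # None: beyond catalog bound


def classify(tt: TruthTable,
             catalog_bound: int = DEFAULT_CATALOG_BOUND) -> TypeProfile:
    """Full type profile of a function.

    ``is_rof`` is None for k beyond the catalog bound (the direct
    classifiers still run at any supported k).
    """
    P = bias(tt)
    eff = effective_inputs(tt)
    signs = input_signs(tt)
    can = canalyzing_inputs(tt)
    chain = ncf_chain(tt)
    if tt.k <= catalog_bound:
        rof: Optional[bool] = tt.mask in catalog_masks(tt.k, "RoF", catalog_bound)
    else:
        rof = None
    return TypeProfile(
        k=tt.k,
        bias=P,
        parity="odd" if P % 2 else "even",
        is_effective=len(eff) == tt.k,
        ineffective_inputs=tuple(
            i for i in range(1, tt.k + 1) if i not in eff
        ),
        input_signs=signs,
        is_unate=all(s != "mixed" for s in signs),
        is_canalyzing=bool(can),
        canalyzing_inputs=can,
        is_ncf=chain is not None,
        ncf_chain=chain,
        is_rof=rof,
    )


# predicate registry used by census, enrichment and rule sampling
TYPE_PREDICATES = {
    "EF": is_effective,
    "IEF": lambda tt: not is_effective(tt),
    "UF": is_unate,
    "EUF": lambda tt: is_effective(tt) and is_unate(tt),
    "CF": is_canalyzing,
    "ECF": lambda tt: is_effective(tt) and is_canalyzing(tt),
    "NCF": is_ncf,
    "RoF": is_rof,
    "nonNCF-RoF": lambda tt: is_rof(tt) and not is_ncf(tt),
    "odd": lambda tt: bias(tt) % 2 == 1,
    "even": lambda tt: bias(tt) % 2 == 0,
}
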