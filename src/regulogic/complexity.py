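"""Boolean complexity and average sensitivity.

*Boolean complexity* is the number of literals in the shortest AND/OR/NOT
formula equivalent to a function.  Finding it is hard in general, so the
pipeline mirrors standard logic-synthesis practice: build four seed
expressions — the full DNF, the full CNF, the Quine–McCluskey minimized
DNF and the Quine–McCluskey minimized CNF — factorize each by recursive
single-literal division, and keep the shortest result.  That value is an
upper bound on the true complexity; for k <= 4 an exact dynamic program
over formula sizes is available as the gold standard.

*Average sensitivity* S_f is the expected number of single-input flips
that change the output, averaged uniformly over assignments.  On the
k-cube it reduces to edge counting: with E01 the number of cube edges
joining differing outputs and E11 the number joining two 1-outputs,
S_f = 2*E01/2**k and E01 + 2*E11 = k*P where P is the bias.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from typing import Iterable, Optional

import numpy as np

from .bf_core import (
    And,
    BoolExpr,
    Const,
    Literal,
    Or,
    TruthTable,
    _full,
    bias,
    expr_to_mask,
    half_mask,
    var_mask,
)

__all__ = [
    "ComplexityRecord",
    "average_sensitivity",
    "hypercube_edges",
    "qm_minimize",
    "factorize",
    "boolean_complexity",
    "boolean_complexity_exact",
    "BudgetExceededError",
    "full_dnf",
    "full_cnf",
]

MAX_QM_K = 6
MAX_EXACT_K = 4
DEFAULT_EXACT_BUDGET = 16


# ---------------------------------------------------------------------------
# average sensitivity and hypercube edges
# ---------------------------------------------------------------------------

def hypercube_edges_mask(mask: int, k: int) -> tuple[int, int]:
    e01 = 0
    e11 = 0
    for i in range(1, k + 1):
        s = 1 << (i - 1)
        lo = half_mask(k, i)
        hi_shifted = (mask >> s) & lo
        lo_bits = mask & lo
        e01 += ((lo_bits ^ hi_shifted)).bit_count()
        e11 += (lo_bits & hi_shifted).bit_count()
    return e01, e11


def hypercube_edges(tt: TruthTable) -> tuple[int, int]:
    """(E01, E11): cube edges with differing ends / both ends 1.

    Satisfies E01 + 2*E11 = k*P.
    """
    return hypercube_edges_mask(tt.mask, tt.k)


def average_sensitivity_mask(mask: int, k: int) -> Fraction:
    e01, _ = hypercube_edges_mask(mask, k)
    return Fraction(2 * e01, 1 << k)


def average_sensitivity(tt: TruthTable) -> Fraction:
    """Mean over all assignments of the number of output-changing
    single-input flips; equals 2*E01/2**k, in [0, k]."""
    return average_sensitivity_mask(tt.mask, tt.k)


# ---------------------------------------------------------------------------
# Quine–McCluskey minimization
# ---------------------------------------------------------------------------

def _prime_implicants(minterms: tuple[int, ...], k: int) -> list[tuple[int, int]]:
    """Prime implicants as (value, dontcare) bit pairs over k inputs."""
    current = {(m, 0) for m in minterms}
    primes: set[tuple[int, int]] = set()
    while current:
        merged: set[tuple[int, int]] = set()
        used: set[tuple[int, int]] = set()
        by_dc: dict[int, list[int]] = {}
        for v, dc in current:
            by_dc.setdefault(dc, []).append(v)
        for dc, values in by_dc.items():
            vset = set(values)
            for v in values:
                for i in range(k):
                    b = 1 << i
                    if dc & b:
                        continue
                    if v | b in vset and not v & b:
                        merged.add((v, dc | b))
                        used.add((v, dc))
                        used.add((v | b, dc))
        primes.update(current - used)
        current = merged
    return sorted(primes)


def _cover_exact(minterms: tuple[int, ...], primes: list[tuple[int, int]],
                 k: int) -> list[tuple[int, int]]:
    """Minimum cover of the minterms by prime implicants.

    Objective: fewest terms, then fewest literals, then lexicographically
    smallest sorted implicant list (Petrick-style branch and bound).
    """
    cover_of = {
        p: frozenset(m for m in minterms if m & ~p[1] == p[0])
        for p in primes
    }
    lit_of = {p: k - p[1].bit_count() for p in primes}
    all_m = frozenset(minterms)
    best: list[Optional[tuple]] = [None]

    def key(sel: tuple[tuple[int, int], ...]) -> tuple:
        return (len(sel), sum(lit_of[p] for p in sel), tuple(sorted(sel)))

    def search(covered: frozenset, sel: tuple) -> None:
        if covered == all_m:
            kk = key(sel)
            if best[0] is None or kk < best[0]:
                best[0] = kk
            return
        # bound on term count: completing needs at least one more term
        if best[0] is not None and len(sel) + 1 > best[0][0]:
            return
        # branch on the uncovered minterm with fewest covering primes
        uncovered = all_m - covered
        target = min(
            uncovered,
            key=lambda m: sum(1 for p in primes if m in cover_of[p]),
        )
        for p in primes:
            if target in cover_of[p]:
                search(covered | cover_of[p], sel + (p,))

    search(frozenset(), ())
    assert best[0] is not None
    return list(best[0][2])


def _implicant_to_and(p: tuple[int, int], k: int) -> BoolExpr:
    v, dc = p
    lits = [
        Literal(i, positive=bool(v >> (i - 1) & 1))
        for i in range(1, k + 1)
        if not dc >> (i - 1) & 1
    ]
    if not lits:
        return Const(True)
    return lits[0] if len(lits) == 1 else And(tuple(lits))


def _implicant_to_clause(p: tuple[int, int], k: int) -> BoolExpr:
    # an implicant of the OFF-set corresponds to a CNF clause that is
    # false exactly on the rows the implicant covers
    v, dc = p
    lits = [
        Literal(i, positive=not (v >> (i - 1) & 1))
        for i in range(1, k + 1)
        if not dc >> (i - 1) & 1
    ]
    if not lits:
        return Const(False)
    return lits[0] if len(lits) == 1 else Or(tuple(lits))


def qm_minimize(tt: TruthTable, target: str = "DNF") -> BoolExpr:
    """Exact-minimum two-level form via Quine–McCluskey + Petrick search.

    ``target='DNF'`` minimizes a sum of products over the ON-set;
    ``target='CNF'`` a product of sums over the OFF-set.  Constants
    return a Const marker.
    """
    if tt.k > MAX_QM_K:
        raise ValueError(f"QM minimization supported for k <= {MAX_QM_K}")
    mask = tt.mask
    if mask == 0:
        return Const(False)
    if mask == _full(tt.k):
        return Const(True)
    if target == "DNF":
        rows = tuple(m for m in range(1 << tt.k) if mask >> m & 1)
    elif target == "CNF":
        rows = tuple(m for m in range(1 << tt.k) if not mask >> m & 1)
    else:
        raise ValueError("target must be 'DNF' or 'CNF'")
    primes = _prime_implicants(rows, tt.k)
    cover = _cover_exact(rows, primes, tt.k)
    if target == "DNF":
        terms = [_implicant_to_and(p, tt.k) for p in cover]
        return terms[0] if len(terms) == 1 else Or(tuple(terms))
    clauses = [_implicant_to_clause(p, tt.k) for p in cover]
    return clauses[0] if len(clauses) == 1 else And(tuple(clauses))


def full_dnf(tt: TruthTable) -> BoolExpr:
    """Minterm expansion (the full canonical DNF)."""
    mask = tt.mask
    if mask == 0:
        return Const(False)
    if mask == _full(tt.k):
        return Const(True)
    terms = [_implicant_to_and((m, 0), tt.k)
             for m in range(1 << tt.k) if mask >> m & 1]
    return terms[0] if len(terms) == 1 else Or(tuple(terms))


def full_cnf(tt: TruthTable) -> BoolExpr:
    """Maxterm expansion (the full canonical CNF)."""
    mask = tt.mask
    if mask == 0:
        return Const(False)
    if mask == _full(tt.k):
        return Const(True)
    clauses = [_implicant_to_clause((m, 0), tt.k)
               for m in range(1 << tt.k) if not mask >> m & 1]
    return clauses[0] if len(clauses) == 1 else And(tuple(clauses))


# ---------------------------------------------------------------------------
# factoring by recursive single-literal division
# ---------------------------------------------------------------------------

_Lit = tuple[int, bool]            # (var, positive)


def _lit_node(lit: _Lit) -> Literal:
    return Literal(lit[0], lit[1])


def _join(op: str, parts: list[BoolExpr]) -> BoolExpr:
    flat: list[BoolExpr] = []
    cls = And if op == "AND" else Or
    for p in parts:
        if isinstance(p, cls):
            flat.extend(p.children)
        else:
            flat.append(p)
    return flat[0] if len(flat) == 1 else cls(tuple(flat))


def _factor_terms(terms: list[frozenset[_Lit]], inner: str) -> BoolExpr:
    """Factor a two-level form given as literal-set terms.

    ``inner='AND'`` means sum-of-products; ``inner='OR'`` means
    product-of-sums (the algorithm is self-dual).  The divisor is the
    most frequent literal, ties broken by lowest variable index then
    positive before negative.
    """
    outer = "OR" if inner == "AND" else "AND"
    if len(terms) == 1:
        lits = sorted(terms[0], key=lambda l: (l[0], not l[1]))
        return _join(inner, [_lit_node(l) for l in lits])
    counts: dict[_Lit, int] = {}
    for t in terms:
        for l in t:
            counts[l] = counts.get(l, 0) + 1
    best = min(counts, key=lambda l: (-counts[l], l[0], not l[1]))
    if counts[best] <= 1:
        parts = [
            _join(inner, [_lit_node(l) for l in
                          sorted(t, key=lambda l: (l[0], not l[1]))])
            for t in terms
        ]
        return _join(outer, parts)
    quotient = [t - {best} for t in terms if best in t]
    remainder = [t for t in terms if best not in t]
    if any(not q for q in quotient):
        # a term equal to the bare divisor absorbs the rest of the quotient
        divided: BoolExpr = _lit_node(best)
    else:
        divided = _join(inner, [_lit_node(best), _factor_terms(quotient, inner)])
    if not remainder:
        return divided
    return _join(outer, [divided, _factor_terms(remainder, inner)])


def _as_terms(e: BoolExpr, inner_cls, outer_cls) -> Optional[list[frozenset[_Lit]]]:
    def term(node) -> Optional[frozenset[_Lit]]:
        if isinstance(node, Literal):
            return frozenset({(node.var, node.positive)})
        if isinstance(node, inner_cls) and all(
            isinstance(c, Literal) for c in node.children
        ):
            return frozenset((c.var, c.positive) for c in node.children)
        return None

    if isinstance(e, outer_cls):
        out = []
        for c in e.children:
            t = term(c)
            if t is None:
                return None
            out.append(t)
        return out
    t = term(e)
    return None if t is None else [t]


def factorize(e: BoolExpr) -> BoolExpr:
    """Equivalent expression with literal count <= the input's.

    Two-level forms (SOP or POS) are factored by recursive extraction of
    the most frequent literal; anything already deeper than two levels
    is returned unchanged.
    """
    if isinstance(e, (Literal, Const)):
        return e
    sop = _as_terms(e, And, Or)
    if sop is not None:
        return _factor_terms(sop, "AND")
    pos = _as_terms(e, Or, And)
    if pos is not None:
        return _factor_terms(pos, "OR")
    return e


# ---------------------------------------------------------------------------
# the four-seed complexity estimate
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComplexityRecord:
    boolean_complexity: int
    exact: bool
    source: str
    average_sensitivity: Fraction
    E01: int
    E11: int
    expression: Optional[BoolExpr] = None


def _estimate(tt: TruthTable) -> tuple[int, str, BoolExpr]:
    candidates = [
        ("qm_dnf", factorize(qm_minimize(tt, "DNF"))),
        ("qm_cnf", factorize(qm_minimize(tt, "CNF"))),
        ("full_dnf", factorize(full_dnf(tt))),
        ("full_cnf", factorize(full_cnf(tt))),
    ]
    source, expr = min(candidates, key=lambda c: c[1].literal_count)
    return expr.literal_count, source, expr


def boolean_complexity(tt: TruthTable, exact: bool = False,
                       budget: int = DEFAULT_EXACT_BUDGET) -> ComplexityRecord:
    """Literal count of the shortest formula found for ``tt``.

    The default pipeline factorizes the four seed expressions and keeps
    the minimum — an upper bound on the true Boolean complexity.  With
    ``exact=True`` (k <= 4) the exhaustive dynamic program replaces the
    heuristic value.
    """
    e01, e11 = hypercube_edges(tt)
    sens = Fraction(2 * e01, 1 << tt.k)
    if tt.mask in (0, _full(tt.k)):
        return ComplexityRecord(0, True, "constant", sens, e01, e11,
                                Const(bool(tt.mask)))
    value, source, expr = _estimate(tt)
    if exact:
        exact_value = boolean_complexity_exact(tt, budget)
        if exact_value < value:
            value, source, expr = exact_value, "exact", None
        return ComplexityRecord(value, True, source, sens, e01, e11, expr)
    return ComplexityRecord(value, False, source, sens, e01, e11, expr)


def complexity_estimate_mask(mask: int, k: int) -> int:
    """Fast path used by full-space scans."""
    if mask in (0, _full(k)):
        return 0
    return _estimate(TruthTable.from_mask(mask, k))[0]


# ---------------------------------------------------------------------------
# exact minimal formula size by dynamic programming (k <= 4)
# ---------------------------------------------------------------------------

class BudgetExceededError(ValueError):
    """No formula within the literal budget realizes the function."""


class _DPState:
    def __init__(self, k: int):
        self.k = k
        n = 1 << (1 << k)
        self.best = np.full(n, 127, dtype=np.int16)
        lits = []
        full = _full(k)
        for v in range(1, k + 1):
            m = var_mask(k, v)
            lits.extend([m, m ^ full])
        level1 = np.unique(np.array(lits, dtype=np.int64))
        self.best[level1] = 1
        self.levels: dict[int, np.ndarray] = {1: level1}
        self.computed_upto = 1

    def extend(self, upto: int) -> None:
        chunk = 2048
        for s in range(self.computed_upto + 1, upto + 1):
            found: list[np.ndarray] = []
            for s1 in range(1, s // 2 + 1):
                a = self.levels.get(s1)
                b = self.levels.get(s - s1)
                if a is None or b is None or len(a) == 0 or len(b) == 0:
                    continue
                for start in range(0, len(a), chunk):
                    blk = a[start:start + chunk, None]
                    found.append(np.unique(blk & b[None, :]))
                    found.append(np.unique(blk | b[None, :]))
            if found:
                cand = np.unique(np.concatenate(found))
                new = cand[self.best[cand] > s]
                self.best[new] = s
                self.levels[s] = new
            else:
                self.levels[s] = np.empty(0, dtype=np.int64)
            self.computed_upto = s


@lru_cache(maxsize=None)
def _dp_state(k: int) -> _DPState:
    return _DPState(k)


def boolean_complexity_exact(tt: TruthTable,
                             budget: int = DEFAULT_EXACT_BUDGET) -> int:
    """True minimal literal count by exhaustive search (k <= 4).

    Cost-1 formulas are the 2k signed literals; a cost-s formula is
    g AND h or g OR h with cost(g) + cost(h) = s.  Raises
    :class:`BudgetExceededError` if no formula within ``budget``
    literals realizes the function.
    """
    if tt.k > MAX_EXACT_K:
        raise ValueError(f"exact search supported for k <= {MAX_EXACT_K}")
    if tt.mask in (0, _full(tt.k)):
        return 0
    state = _dp_state(tt.k)
    while state.best[tt.mask] > state.computed_upto:
        if state.computed_upto >= budget:
            break
        state.extend(min(budget, state.computed_upto + 1))
    value = int(state.best[tt.mask])
    if value > budget:
        raise BudgetExceededError(
            f"no formula with <= {budget} literals found"
        )
    return value
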