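"""Canonical representations of Boolean update rules.

A :class:`TruthTable` stores a k-input Boolean function as its output
column over all 2**k input assignments.  Row indexing follows a fixed
convention throughout the package: the output for the assignment
``(x_1, ..., x_k)`` sits at row ``m`` whose binary digit ``i-1`` equals
``x_i`` — that is, **x_1 is the least-significant bit of the row index**.
The textual serialization prints the output column most-significant row
first, so the printed string reads like vertex labels ``x_k ... x_1``.

Internally most algorithms work on the *mask*: the integer whose bit
``m`` is the output at row ``m``.  Bitwise tricks on masks make
exhaustive scans over all ``2**(2**k)`` functions cheap for small k.

:class:`BoolExpr` is an expression tree over literals, AND and OR in
negation normal form (negations only on literals), which makes literal
counting — the basis of Boolean complexity — well defined.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Iterator, Sequence, Union

__all__ = [
    "TruthTable",
    "BoolExpr",
    "Literal",
    "And",
    "Or",
    "Const",
    "KPDescriptor",
    "bias",
    "complement",
    "parse_expr",
    "format_expr",
    "expr_to_tt",
    "expr_to_mask",
    "negate_expr",
    "canonical_form",
    "canonical_mask",
    "var_mask",
    "input_flip_mask",
    "half_mask",
    "ExprSyntaxError",
]

MAX_K = 10


# ---------------------------------------------------------------------------
# bit-level helpers on masks
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def var_mask(k: int, i: int) -> int:
    """Mask of the positive literal x_i on the k-cube.

    Bit ``m`` is set iff bit ``i-1`` of the row index ``m`` is 1.
    """
    if not 1 <= i <= k:
        raise ValueError(f"variable index {i} out of range 1..{k}")
    n = 1 << k
    m = 0
    for row in range(n):
        if row >> (i - 1) & 1:
            m |= 1 << row
    return m


@lru_cache(maxsize=None)
def half_mask(k: int, i: int) -> int:
    """Mask selecting the rows with x_i = 0."""
    return ~var_mask(k, i) & ((1 << (1 << k)) - 1)


def input_flip_mask(mask: int, k: int, i: int) -> int:
    """Mask of ``f(x XOR e_i)``: rows re-read with input i flipped."""
    s = 1 << (i - 1)
    lo = half_mask(k, i)
    return ((mask >> s) & lo) | ((mask & lo) << s)


@lru_cache(maxsize=None)
def _full(k: int) -> int:
    return (1 << (1 << k)) - 1


# ---------------------------------------------------------------------------
# TruthTable
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TruthTable:
    """A k-input Boolean function as an output bit-vector of length 2**k."""

    k: int
    outputs: tuple[int, ...]

    def __post_init__(self) -> None:
        if not 1 <= self.k <= MAX_K:
            raise ValueError(f"k must be in 1..{MAX_K}, got {self.k}")
        if len(self.outputs) != 1 << self.k:
            raise ValueError(
                f"expected {1 << self.k} outputs for k={self.k}, "
                f"got {len(self.outputs)}"
            )
        if any(o not in (0, 1) for o in self.outputs):
            raise ValueError("outputs must be 0/1")
        object.__setattr__(self, "outputs", tuple(int(o) for o in self.outputs))

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_mask(cls, mask: int, k: int) -> "TruthTable":
        if not 0 <= mask <= _full(k):
            raise ValueError(f"mask {mask:#x} out of range for k={k}")
        return cls(k, tuple(mask >> m & 1 for m in range(1 << k)))

    @classmethod
    def from_string(cls, text: str, k: int | None = None,
                    lsb_first: bool = False) -> "TruthTable":
        """Parse a truth-table string.

        Accepts a binary output column (MSB-first row order by default;
        ``lsb_first=True`` for the alternate dialect) or, for k >= 5, a
        hexadecimal form prefixed with ``0x``.
        """
        text = text.strip()
        if text.lower().startswith("0x"):
            if k is None:
                raise ValueError("hex truth tables require an explicit k")
            return cls.from_mask(int(text, 16), k)
        if not re.fullmatch(r"[01]+", text):
            raise ValueError(f"not a truth-table string: {text!r}")
        n = len(text)
        if n & (n - 1) or n < 2:
            raise ValueError(f"truth-table length {n} is not a power of two >= 2")
        kk = n.bit_length() - 1
        if k is not None and k != kk:
            raise ValueError(f"string length {n} inconsistent with k={k}")
        bits = [int(c) for c in text]
        if not lsb_first:
            bits.reverse()
        return cls(kk, tuple(bits))

    # -- views --------------------------------------------------------------

    @property
    def mask(self) -> int:
        m = 0
        for row, o in enumerate(self.outputs):
            m |= o << row
        return m

    def to_string(self, lsb_first: bool = False) -> str:
        bits = "".join(str(o) for o in self.outputs)
        return bits if lsb_first else bits[::-1]

    def to_hex(self) -> str:
        width = max(1, (1 << self.k) // 4)
        return f"0x{self.mask:0{width}x}"

    def __call__(self, assignment: Sequence[int]) -> int:
        if len(assignment) != self.k:
            raise ValueError("assignment length != k")
        row = sum((1 << i) for i, v in enumerate(assignment) if v)
        return self.outputs[row]

    def __str__(self) -> str:
        return self.to_string()


@dataclass(frozen=True)
class KPDescriptor:
    """Identifies the k[P] set: functions with k inputs and bias P."""

    k: int
    P: int

    def __post_init__(self) -> None:
        if not 0 <= self.P <= 1 << self.k:
            raise ValueError(f"bias {self.P} out of range for k={self.k}")


def bias(tt: TruthTable) -> int:
    """Number of 1s in the output column (the bias P)."""
    return sum(tt.outputs)


def complement(tt: TruthTable) -> TruthTable:
    """Output-complemented function; lands in k[2**k - P]."""
    return TruthTable.from_mask(tt.mask ^ _full(tt.k), tt.k)


# ---------------------------------------------------------------------------
# expressions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Literal:
    var: int            # 1-based input index
    positive: bool = True

    @property
    def literal_count(self) -> int:
        return 1

    def __str__(self) -> str:
        return ("" if self.positive else "~") + f"x{self.var}"


@dataclass(frozen=True)
class And:
    children: tuple["BoolExpr", ...]

    def __post_init__(self) -> None:
        if len(self.children) < 2:
            raise ValueError("AND needs >= 2 children")

    @property
    def literal_count(self) -> int:
        return sum(c.literal_count for c in self.children)


@dataclass(frozen=True)
class Or:
    children: tuple["BoolExpr", ...]

    def __post_init__(self) -> None:
        if len(self.children) < 2:
            raise ValueError("OR needs >= 2 children")

    @property
    def literal_count(self) -> int:
        return sum(c.literal_count for c in self.children)


@dataclass(frozen=True)
class Const:
    value: bool

    @property
    def literal_count(self) -> int:
        return 0

    def __str__(self) -> str:
        return "1" if self.value else "0"


BoolExpr = Union[Literal, And, Or, Const]


def negate_expr(e: BoolExpr) -> BoolExpr:
    """De Morgan negation, keeping the tree in negation normal form."""
    if isinstance(e, Literal):
        return Literal(e.var, not e.positive)
    if isinstance(e, Const):
        return Const(not e.value)
    if isinstance(e, And):
        return Or(tuple(negate_expr(c) for c in e.children))
    return And(tuple(negate_expr(c) for c in e.children))


def max_var(e: BoolExpr) -> int:
    if isinstance(e, Literal):
        return e.var
    if isinstance(e, Const):
        return 0
    return max(max_var(c) for c in e.children)


def expr_to_mask(e: BoolExpr, k: int) -> int:
    if isinstance(e, Literal):
        m = var_mask(k, e.var)
        return m if e.positive else m ^ _full(k)
    if isinstance(e, Const):
        return _full(k) if e.value else 0
    if isinstance(e, And):
        m = _full(k)
        for c in e.children:
            m &= expr_to_mask(c, k)
        return m
    m = 0
    for c in e.children:
        m |= expr_to_mask(c, k)
    return m


def expr_to_tt(e: BoolExpr, k: int) -> TruthTable:
    """Evaluate an expression on all 2**k assignments."""
    mv = max_var(e)
    if mv > k:
        raise ValueError(f"expression uses x{mv} but k={k}")
    return TruthTable.from_mask(expr_to_mask(e, k), k)


# -- parsing ----------------------------------------------------------------

class ExprSyntaxError(ValueError):
    def __init__(self, message: str, pos: int):
        super().__init__(f"{message} (at position {pos})")
        self.pos = pos


_TOKEN = re.compile(r"\s*(?:(x\d+)|([01])|([~!&|+()*]))")


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            if text[pos:].strip() == "":
                break
            raise ExprSyntaxError(f"unexpected character {text[pos]!r}", pos)
        if m.group(1):
            tokens.append(("var", m.group(1), m.start(1)))
        elif m.group(2):
            tokens.append(("const", m.group(2), m.start(2)))
        else:
            tokens.append(("op", m.group(3), m.start(3)))
        pos = m.end()
    tokens.append(("end", "", len(text)))
    return tokens


class _Parser:
    """Recursive-descent parser for the expression grammar.

    Variables ``x1..xk``; negation ``~``/``!``; AND by ``&``, ``*`` or
    juxtaposition; OR by ``+`` or ``|``; parentheses; constants 0/1.
    Negation of a subexpression is pushed onto literals at parse time.
    """

    def __init__(self, text: str):
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self):
        return self.tokens[self.i]

    def next(self):
        t = self.tokens[self.i]
        self.i += 1
        return t

    def parse(self) -> BoolExpr:
        e = self.or_expr()
        kind, val, pos = self.peek()
        if kind != "end":
            raise ExprSyntaxError(f"unexpected {val!r}", pos)
        return e

    def or_expr(self) -> BoolExpr:
        terms = [self.and_expr()]
        while True:
            kind, val, _ = self.peek()
            if kind == "op" and val in "+|":
                self.next()
                terms.append(self.and_expr())
            else:
                break
        return terms[0] if len(terms) == 1 else Or(tuple(terms))

    def and_expr(self) -> BoolExpr:
        factors = [self.unary()]
        while True:
            kind, val, _ = self.peek()
            if kind == "op" and val in "&*":
                self.next()
                factors.append(self.unary())
            elif kind in ("var", "const") or (kind == "op" and val in "~!("):
                factors.append(self.unary())       # juxtaposition
            else:
                break
        return factors[0] if len(factors) == 1 else And(tuple(factors))

    def unary(self) -> BoolExpr:
        kind, val, pos = self.peek()
        if kind == "op" and val in "~!":
            self.next()
            return negate_expr(self.unary())
        return self.atom()

    def atom(self) -> BoolExpr:
        kind, val, pos = self.next()
        if kind == "var":
            return Literal(int(val[1:]))
        if kind == "const":
            return Const(val == "1")
        if kind == "op" and val == "(":
            e = self.or_expr()
            kind, val, pos = self.next()
            if not (kind == "op" and val == ")"):
                raise ExprSyntaxError("expected ')'", pos)
            return e
        raise ExprSyntaxError(f"unexpected {val!r}" if val else "unexpected end of input", pos)


def parse_expr(text: str) -> BoolExpr:
    """Parse an expression string into a negation-normal-form tree."""
    return _Parser(text).parse()


def format_expr(e: BoolExpr, _parent: str = "") -> str:
    """Print an expression; ``parse_expr(format_expr(e))`` is equivalent to e."""
    if isinstance(e, (Literal, Const)):
        return str(e)
    if isinstance(e, And):
        s = " & ".join(format_expr(c, "and") for c in e.children)
        return f"({s})" if _parent == "and" else s
    s = " | ".join(format_expr(c, "or") for c in e.children)
    return f"({s})" if _parent in ("and", "or") else s


# ---------------------------------------------------------------------------
# isomorphism canonicalization
# ---------------------------------------------------------------------------

MAX_CANONICAL_K = 6


@lru_cache(maxsize=None)
def _transforms(k: int) -> tuple[tuple[int, ...], ...]:
    """Row permutations of the k-cube induced by every input permutation
    combined with every input-negation pattern."""
    n = 1 << k
    out = []
    for perm in itertools.permutations(range(k)):
        for neg in range(1 << k):
            rowmap = []
            for m in range(n):
                mm = m ^ neg
                new = 0
                for i in range(k):
                    if mm >> i & 1:
                        new |= 1 << perm[i]
                rowmap.append(new)
            out.append(tuple(rowmap))
    return tuple(out)


def _lex_key(mask: int, k: int) -> int:
    """Pack outputs so that integer order equals lexicographic order on
    the output vector (row 0 first)."""
    n = 1 << k
    key = 0
    for m in range(n):
        key = (key << 1) | (mask >> m & 1)
    return key


def canonical_mask(mask: int, k: int) -> int:
    """Mask of the canonical (lexicographically smallest) representative
    of the input-permutation/input-negation orbit of ``mask``."""
    if k > MAX_CANONICAL_K:
        raise ValueError(
            f"exhaustive canonicalization supported for k <= {MAX_CANONICAL_K}"
        )
    n = 1 << k
    best_key = None
    best = mask
    for rowmap in _transforms(k):
        t = 0
        for m in range(n):
            if mask >> m & 1:
                t |= 1 << rowmap[m]
        key = _lex_key(t, k)
        if best_key is None or key < best_key:
            best_key = key
            best = t
    return best


def canonical_form(tt: TruthTable) -> TruthTable:
    """Canonical representative under input permutations and negations.

    Two functions are isomorphic iff their canonical forms are equal.
    Output complementation is *not* part of the orbit: the notion of
    isomorphism used here is input-side only.
    """
    return TruthTable.from_mask(canonical_mask(tt.mask, tt.k), tt.k)


def all_masks(k: int) -> Iterator[int]:
    """All 2**(2**k) function masks (use only for small k)."""
    return iter(range(1 << (1 << k)))
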