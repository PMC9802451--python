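"""Truth-table plumbing: bias, complementation, parsing, isomorphism."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from regulogic.bf_core import (
    And,
    Const,
    ExprSyntaxError,
    Literal,
    Or,
    TruthTable,
    bias,
    canonical_form,
    complement,
    expr_to_tt,
    format_expr,
    parse_expr,
)
from regulogic.complexity import average_sensitivity


def masks(k):
    return st.integers(min_value=0, max_value=(1 << (1 << k)) - 1)


def tt_from(mask, k):
    return TruthTable.from_mask(mask, k)


class TestTruthTable:
    def test_row_convention_x1_is_lsb(self):
        # f = x1 on k=2: rows 01 and 11 (indices 1, 3) are true
        tt = TruthTable(2, (0, 1, 0, 1))
        assert tt((1, 0)) == 1
        assert tt((0, 1)) == 0

    def test_string_round_trip_msb_and_lsb(self):
        tt = tt_from(0b0001, 2)
        assert tt.to_string() == "0001"
        assert TruthTable.from_string("0001") == tt
        assert TruthTable.from_string("1000", lsb_first=True) == tt

    def test_hex_form(self):
        tt = tt_from(0x8000, 4)
        assert TruthTable.from_string(tt.to_hex(), k=4) == tt

    @pytest.mark.parametrize("text", ["00011", "2x", ""])
    def test_bad_strings_rejected(self, text):
        with pytest.raises(ValueError):
            TruthTable.from_string(text)

    def test_invalid_outputs_rejected(self):
        with pytest.raises(ValueError):
            TruthTable(2, (0, 1, 2, 0))
        with pytest.raises(ValueError):
            TruthTable(2, (0, 1, 0))


class TestBiasComplement:
    def test_worked_example_bias(self, worked_example_tt):
        assert bias(worked_example_tt) == 3

    @pytest.mark.parametrize(
        "mask,k,expected",
        [(0, 2, 0), (0b0110, 2, 2), (0b1000, 2, 1)],
    )
    def test_bias_counts_ones(self, mask, k, expected):
        assert bias(tt_from(mask, k)) == expected

    def test_and2_complement_is_nand2(self):
        nand = complement(tt_from(0b1000, 2))
        assert bias(nand) == 3
        assert nand.outputs == (1, 1, 1, 0)

    @given(masks(3))
    @settings(max_examples=60, deadline=None)
    def test_complement_involution_and_bias_sum(self, mask):
        tt = tt_from(mask, 3)
        assert complement(complement(tt)) == tt
        assert bias(tt) + bias(complement(tt)) == 8

    @given(masks(4))
    @settings(max_examples=40, deadline=None)
    def test_complement_preserves_average_sensitivity(self, mask):
        tt = tt_from(mask, 4)
        assert average_sensitivity(tt) == average_sensitivity(complement(tt))


class TestExpressions:
    def test_parse_structure(self):
        e = parse_expr("x1 & (x2 | x3)")
        assert e == And((Literal(1), Or((Literal(2), Literal(3)))))

    def test_parse_minimal_formula_three_literals(self, worked_example_tt):
        e = parse_expr("~x1 & (~x2 | ~x3)")
        assert e.literal_count == 3
        assert expr_to_tt(e, 3) == worked_example_tt

    def test_negation_pushed_to_literals(self):
        e = parse_expr("~(x1 & x2)")
        assert e == Or((Literal(1, False), Literal(2, False)))

    @pytest.mark.parametrize("text", ["x1 &", "x1 | | x2", "(x1", "~"])
    def test_malformed_raises_with_position(self, text):
        with pytest.raises(ExprSyntaxError) as err:
            parse_expr(text)
        assert "position" in str(err.value)

    def test_expr_to_tt_examples(self, worked_example_tt):
        assert expr_to_tt(parse_expr("~x1 (~x2 + ~x3)"), 3) == worked_example_tt
        assert expr_to_tt(parse_expr("x1"), 1).outputs == (0, 1)
        a = expr_to_tt(parse_expr("x1 x2 (x3 + x4)"), 4)
        b = expr_to_tt(parse_expr("x1 (x2 x3 + x4)"), 4)
        assert a != b  # distinct read-once parenthesizations

    def test_variable_out_of_range(self):
        with pytest.raises(ValueError):
            expr_to_tt(parse_expr("x3"), 2)

    @given(st.recursive(
        st.builds(Literal,
                  st.integers(min_value=1, max_value=3),
                  st.booleans()),
        lambda children: st.builds(
            lambda a, b, isand: (And if isand else Or)((a, b)),
            children, children, st.booleans()),
        max_leaves=8,
    ))
    @settings(max_examples=80, deadline=None)
    def test_format_parse_round_trip(self, expr):
        back = parse_expr(format_expr(expr))
        assert expr_to_tt(back, 3) == expr_to_tt(expr, 3)


def _brute_canonical(mask, k):
    """Independent orbit minimum: evaluate through permuted/negated
    assignments rather than row maps."""
    n = 1 << k
    outputs = [(mask >> m) & 1 for m in range(n)]
    best = None
    for perm in itertools.permutations(range(k)):
        for neg in range(1 << k):
            cand = []
            for m in range(n):
                # x_i of the transformed function
                x = [(m >> i) & 1 for i in range(k)]
                orig = [0] * k
                for i in range(k):
                    orig[i] = x[perm[i]] ^ ((neg >> i) & 1)
                row = sum(1 << i for i in range(k) if orig[i])
                cand.append(outputs[row])
            if best is None or cand < best:
                best = cand
    return best


class TestCanonicalForm:
    def test_isomorphic_pair_shares_canonical_form(self):
        f = expr_to_tt(parse_expr("x1 & (x2 | x3)"), 3)
        g = expr_to_tt(parse_expr("x2 & (x1 | ~x3)"), 3)
        assert canonical_form(f) == canonical_form(g)

    def test_constant_is_fixed_point(self):
        c = tt_from(0, 2)
        assert canonical_form(c) == c

    @given(masks(3))
    @settings(max_examples=25, deadline=None)
    def test_matches_brute_force_oracle(self, mask):
        got = canonical_form(tt_from(mask, 3))
        assert list(got.outputs) == _brute_canonical(mask, 3)

    @given(masks(3))
    @settings(max_examples=25, deadline=None)
    def test_idempotent_and_orbit_constant(self, mask):
        tt = tt_from(mask, 3)
        c = canonical_form(tt)
        assert canonical_form(c) == c
        # a random orbit member: negate input 2, swap inputs 1 and 3
        moved = expr_to_tt(
            parse_expr(format_expr(
                # evaluate original through the relabelling by brute force
                _relabel_expr(tt)
            )), 3)
        assert canonical_form(moved) == c

    def test_large_k_rejected(self):
        with pytest.raises(ValueError):
            canonical_form(TruthTable.from_mask(0, 7))


def _relabel_expr(tt):
    """Full-DNF expression of tt with inputs permuted (1 3) and input 2
    negated — some member of the same isomorphism orbit."""
    from regulogic.bf_core import And, Literal, Or

    terms = []
    k = tt.k
    for row in range(1 << k):
        if not tt.outputs[row]:
            continue
        lits = []
        for i in range(1, k + 1):
            j = {1: 3, 2: 2, 3: 1}[i]
            positive = bool(row >> (i - 1) & 1) ^ (i == 2)
            lits.append(Literal(j, positive))
        terms.append(And(tuple(lits)))
    if not terms:
        return Literal(1) if False else parse_expr("x1 & ~x1")
    return terms[0] if len(terms) == 1 else Or(tuple(terms))
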