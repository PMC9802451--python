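"""Classifiers and catalogs for the biologically meaningful types."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from regulogic.bf_core import TruthTable, expr_to_tt, parse_expr
from regulogic.bf_types import (
    CanalyzingInput,
    _is_ncf_mask,
    build_catalog,
    canalyzing_inputs,
    catalog_masks,
    classify,
    effective_inputs,
    input_sign,
    input_signs,
    is_canalyzing,
    is_effective,
    is_ncf,
    is_rof,
    is_unate,
    ncf_chain,
    truncate_ineffective,
)


def tt_from(mask, k):
    return TruthTable.from_mask(mask, k)


class TestEffective:
    def test_projection_input_is_ineffective(self):
        f = expr_to_tt(parse_expr("x1"), 2)          # ignores x2
        assert effective_inputs(f) == (1,)
        assert not is_effective(f)

    def test_xor_is_effective(self):
        assert is_effective(tt_from(0b0110, 2))

    def test_ineffective_functions_have_even_bias_k3(self):
        # exhaustive over all 256 three-input functions
        for mask in range(256):
            tt = tt_from(mask, 3)
            if not is_effective(tt):
                assert sum(tt.outputs) % 2 == 0

    def test_truncate_projection(self):
        f = expr_to_tt(parse_expr("x1"), 2)
        assert truncate_ineffective(f).outputs == (0, 1)

    def test_truncate_is_identity_on_effective(self):
        tt = tt_from(0b0110, 2)
        assert truncate_ineffective(tt) is tt

    def test_truncate_constant_raises(self):
        with pytest.raises(ValueError):
            truncate_ineffective(tt_from(0, 2))

    @given(st.integers(min_value=0, max_value=255))
    @settings(max_examples=40, deadline=None)
    def test_truncate_forced_ineffective_input(self, sub_mask):
        # build a k=4 function ignoring input 3 by duplicating a k=3
        # function across the x3 axis, then check the truncation
        base = tt_from(sub_mask, 3)
        outputs = []
        for row in range(16):
            r = (row & 0b11) | ((row >> 1) & 0b100)   # drop bit 2 (x3)
            outputs.append(base.outputs[r])
        lifted = TruthTable(4, tuple(outputs))
        if 3 in effective_inputs(lifted):            # constant base etc.
            return
        if not effective_inputs(lifted):
            return
        reduced = truncate_ineffective(lifted)
        if is_effective(base):
            assert reduced == base


class TestSignsAndCanalyzing:
    def test_worked_example_all_inhibiting(self, worked_example_tt):
        assert input_signs(worked_example_tt) == ("inhibiting",) * 3
        assert is_unate(worked_example_tt)

    def test_xor_inputs_mixed(self):
        xor = tt_from(0b0110, 2)
        assert input_signs(xor) == ("mixed", "mixed")
        assert not is_unate(xor)

    def test_both_implies_ineffective_exhaustive_k3(self):
        for mask in range(256):
            tt = tt_from(mask, 3)
            eff = set(effective_inputs(tt))
            for i in range(1, 4):
                if input_sign(tt, i) == "both":
                    assert i not in eff
                if i not in eff:
                    assert input_sign(tt, i) == "both"

    def test_and2_canalyzing_pairs(self):
        got = canalyzing_inputs(tt_from(0b1000, 2))
        assert got == (CanalyzingInput(1, 0, 0), CanalyzingInput(2, 0, 0))

    def test_xor_not_canalyzing(self):
        assert canalyzing_inputs(tt_from(0b0110, 2)) == ()
        assert not is_canalyzing(tt_from(0b0110, 2))

    def test_constants_count_as_canalyzing(self):
        assert is_canalyzing(tt_from(0, 2))
        assert is_canalyzing(tt_from(0b1111, 2))

    def test_canalyzing_count_k4_is_3514(self):
        count = sum(
            1 for mask in range(1 << 16) if is_canalyzing(tt_from(mask, 4))
        )
        assert count == 3514


class TestNcf:
    def test_eq6_chain_is_ncf(self):
        tt = expr_to_tt(parse_expr("x1 & (~x2 | x3)"), 3)
        assert is_ncf(tt)
        chain = ncf_chain(tt)
        assert chain[0] == CanalyzingInput(1, 0, 0)

    def test_majority3_is_not_ncf(self):
        maj = TruthTable(3, tuple(
            1 if bin(r).count("1") >= 2 else 0 for r in range(8)
        ))
        assert not is_ncf(maj)

    def test_constants_are_not_ncf(self):
        assert not is_ncf(tt_from(0, 2))
        assert not is_ncf(tt_from(0b1111, 2))

    def test_recursive_test_agrees_with_catalog_k_le_3(self):
        for k in (1, 2, 3):
            cat = catalog_masks(k, "NCF")
            for mask in range(1 << (1 << k)):
                assert (mask in cat) == (_is_ncf_mask(mask, k) is not None)

    def test_recursive_test_agrees_with_catalog_k4(self):
        cat = catalog_masks(4, "NCF")
        hits = sum(
            1 for mask in range(1 << 16)
            if _is_ncf_mask(mask, 4) is not None
        )
        assert hits == len(cat) == 736

    def test_recursive_test_agrees_with_catalog_k5_sampled(self, rng):
        cat = catalog_masks(5, "NCF")
        members = sorted(cat)
        for idx in rng.integers(0, len(members), size=50):
            assert _is_ncf_mask(members[int(idx)], 5) is not None
        for mask in rng.integers(0, 1 << 32, size=200):
            got = _is_ncf_mask(int(mask), 5) is not None
            assert got == (int(mask) in cat)


class TestCatalogs:
    @pytest.mark.parametrize(
        "k,ncf,rof",
        [(1, 2, 2), (2, 8, 8), (3, 64, 64), (4, 736, 832), (5, 10624, 15104)],
    )
    def test_catalog_counts(self, k, ncf, rof):
        assert build_catalog(k, "NCF").count == ncf
        assert build_catalog(k, "RoF").count == rof
        assert build_catalog(k, "nonNCF-RoF").count == rof - ncf

    def test_k1_rof_catalog_is_the_two_literals(self):
        assert catalog_masks(1, "RoF") == frozenset({0b01, 0b10})

    def test_ncf_subset_of_rof_strict_from_k4(self):
        for k in (1, 2, 3):
            assert catalog_masks(k, "NCF") == catalog_masks(k, "RoF")
        assert catalog_masks(4, "NCF") < catalog_masks(4, "RoF")

    @pytest.mark.parametrize("k", [4, 5])
    def test_all_rofs_have_odd_bias(self, k):
        assert all(m.bit_count() % 2 for m in catalog_masks(k, "RoF"))

    @pytest.mark.parametrize("k", [4, 5])
    def test_low_bias_rofs_are_ncfs(self, k):
        ncf = catalog_masks(k, "NCF")
        for m in catalog_masks(k, "RoF"):
            if m.bit_count() in (1, 3, 5):
                assert m in ncf

    def test_rof_examples(self):
        assert is_rof(expr_to_tt(parse_expr("x1 x2 (x3 + x4)"), 4))
        parity4 = TruthTable(4, tuple(
            bin(r).count("1") % 2 for r in range(16)
        ))
        assert not is_rof(parity4)

    def test_rof_beyond_bound_raises(self):
        with pytest.raises(ValueError):
            is_rof(TruthTable.from_mask(0, 7))

    def test_catalog_is_isomorphism_closed_k3(self):
        from regulogic.bf_core import canonical_mask

        rof = catalog_masks(3, "RoF")
        reps = {canonical_mask(m, 3) for m in rof}
        assert reps <= rof


class TestClassify:
    def test_and2_profile(self):
        p = classify(tt_from(0b1000, 2))
        assert (p.is_effective, p.is_unate, p.is_canalyzing,
                p.is_ncf, p.is_rof) == (True,) * 5
        assert p.bias == 1 and p.parity == "odd"

    def test_xor2_profile(self):
        p = classify(tt_from(0b0110, 2))
        assert p.is_effective and not p.is_unate
        assert not (p.is_canalyzing or p.is_ncf or p.is_rof)
        assert p.parity == "even"

    @given(st.integers(min_value=0, max_value=(1 << 16) - 1))
    @settings(max_examples=150, deadline=None)
    def test_profile_lattice_invariants(self, mask):
        p = classify(tt_from(mask, 4))
        if p.is_ncf:
            assert p.is_rof
        if p.is_rof:
            assert p.is_effective and p.is_unate and p.parity == "odd"
        if not p.is_effective:
            assert p.parity == "even"
        assert p.is_effective == (not p.ineffective_inputs)
        for i, sign in enumerate(p.input_signs, start=1):
            assert (sign == "both") == (i in p.ineffective_inputs)
            if sign == "mixed":
                assert not p.is_unate
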