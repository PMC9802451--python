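"""Census of function types over the space of all 2**(2**k) functions.

Two routes are available: :func:`enumerate_census` classifies every
function by direct scan (practical for k <= 4; k = 5 only behind an
explicit opt-in), and :func:`catalog_census` covers the generated
NCF/RoF catalogs at any k up to the catalog bound, using exact integer
arithmetic for the astronomically small fractions.

Also here: the closed-form inclusion-exclusion count of effective
functions (an independent oracle for the scan) and the full-space
correlation between Boolean complexity and average sensitivity, which
exploits the fact that both quantities are isomorphism invariants —
functions are grouped into input-permutation/negation classes and the
complexity pipeline runs once per class.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from math import comb

import numpy as np

from .bf_core import TruthTable, _full, _transforms, all_masks
from .bf_types import (
    DEFAULT_CATALOG_BOUND,
    _canalyzing_inputs_mask,
    _effective_inputs_mask,
    _input_sign_mask,
    catalog_masks,
)
from .complexity import average_sensitivity_mask, complexity_estimate_mask

__all__ = [
    "CensusTable",
    "enumerate_census",
    "catalog_census",
    "count_effective_closed_form",
    "subtype_fraction",
    "complexity_sensitivity_correlation",
]

MAX_SCAN_K = 5

_SCAN_TYPES = ("EF", "IEF", "UF", "CF", "NCF", "RoF", "nonNCF-RoF",
               "odd", "even")


@dataclass(frozen=True)
class CensusTable:
    """Per-type counts over all functions with exactly k inputs."""

    k: int
    total: int
    counts: dict[str, int]
    parity_counts: dict[tuple[str, str], int] = field(default_factory=dict)

    def fraction(self, type: str) -> Fraction:
        return Fraction(self.counts[type], self.total)

    def fractions(self) -> dict[str, Fraction]:
        return {t: self.fraction(t) for t in self.counts}


def enumerate_census(k: int, allow_slow: bool = False) -> CensusTable:
    """Classify every one of the 2**(2**k) functions.

    ``allow_slow=True`` unlocks k = 5 (a 2**32-function scan; hours).
    Constants count as canalyzing but not as NCF/RoF.
    """
    limit = 4 if not allow_slow else MAX_SCAN_K
    if k > limit:
        raise ValueError(
            f"full scan supported for k <= {limit}"
            + ("" if allow_slow else " (pass allow_slow=True for k=5)")
        )
    ncf = catalog_masks(k, "NCF")
    rof = catalog_masks(k, "RoF")
    counts = {t: 0 for t in _SCAN_TYPES}
    parity_counts = {(t, p): 0 for t in _SCAN_TYPES for p in ("odd", "even")}
    for mask in all_masks(k):
        parity = "odd" if mask.bit_count() % 2 else "even"
        tags = [parity]
        if len(_effective_inputs_mask(mask, k)) == k:
            tags.append("EF")
        else:
            tags.append("IEF")
        if all(
            _input_sign_mask(mask, k, i) != "mixed" for i in range(1, k + 1)
        ):
            tags.append("UF")
        if _canalyzing_inputs_mask(mask, k):
            tags.append("CF")
        if mask in rof:
            tags.append("RoF")
            if mask in ncf:
                tags.append("NCF")
            else:
                tags.append("nonNCF-RoF")
        for t in tags:
            counts[t] += 1
            parity_counts[(t, parity)] += 1
    return CensusTable(k, 1 << (1 << k), counts, parity_counts)


def catalog_census(k: int,
                   bound: int = DEFAULT_CATALOG_BOUND) -> CensusTable:
    """RoF/NCF/nonNCF-RoF counts from the generated catalogs."""
    ncf = catalog_masks(k, "NCF", bound)
    rof = catalog_masks(k, "RoF", bound)
    counts = {
        "RoF": len(rof),
        "NCF": len(ncf),
        "nonNCF-RoF": len(rof) - len(ncf),
    }
    parity_counts = {}
    for t, masks in (("RoF", rof), ("NCF", ncf)):
        odd = sum(1 for m in masks if m.bit_count() % 2)
        parity_counts[(t, "odd")] = odd
        parity_counts[(t, "even")] = len(masks) - odd
    return CensusTable(k, 1 << (1 << k), counts, parity_counts)


def count_effective_closed_form(k: int) -> int:
    """Inclusion-exclusion count of effective k-input functions:
    sum_j (-1)**j C(k, j) 2**(2**(k-j))."""
    if not 1 <= k <= 10:
        raise ValueError("k must be in 1..10")
    return sum(
        (-1) ** j * comb(k, j) * (1 << (1 << (k - j))) for j in range(k + 1)
    )


def subtype_fraction(space_type: str, subtype: str, k: int,
                     allow_slow: bool = False) -> Fraction:
    """|subtype ∩ space_type| / |space_type| in the full function space.

    Catalog pairs (subtype and englobing type both within RoF) work at
    any k up to the catalog bound; other pairs need a full scan (k <= 4
    unless ``allow_slow``).
    """
    catalog_types = {"NCF", "RoF", "nonNCF-RoF"}
    if space_type in catalog_types and subtype in catalog_types:
        sup = catalog_masks(k, space_type)
        sub = catalog_masks(k, subtype)
        if not sup:
            raise ValueError(f"empty type set {space_type} at k={k}")
        return Fraction(len(sub & sup), len(sup))
    census = enumerate_census(k, allow_slow=allow_slow)
    if census.counts.get(space_type, 0) == 0:
        raise ValueError(f"empty type set {space_type} at k={k}")
    # scan again restricted to the englobing set for the intersection
    from .bf_types import TYPE_PREDICATES

    sup_pred = TYPE_PREDICATES[space_type]
    sub_pred = TYPE_PREDICATES[subtype]
    inter = 0
    for mask in all_masks(k):
        tt = TruthTable.from_mask(mask, k)
        if sup_pred(tt) and sub_pred(tt):
            inter += 1
    return Fraction(inter, census.counts[space_type])


# ---------------------------------------------------------------------------
# complexity-vs-sensitivity correlation over the full space
# ---------------------------------------------------------------------------

def _canonical_keys(k: int) -> np.ndarray:
    """For every mask 0..2**(2**k)-1, a label identifying its
    input-permutation/negation class (vectorized over all transforms)."""
    n = 1 << k
    masks = np.arange(1 << n, dtype=np.uint64)
    bits = ((masks[:, None] >> np.arange(n, dtype=np.uint64)[None, :]) & 1)
    best = None
    for rowmap in _transforms(k):
        # lexicographic key of the transformed output vector:
        # old row m lands at new row rowmap[m], whose lex weight is
        # 2**(n-1-rowmap[m])
        w = np.array([1 << (n - 1 - r) for r in rowmap], dtype=np.uint64)
        key = bits @ w
        best = key if best is None else np.minimum(best, key)
    return best


def complexity_sensitivity_correlation(k: int = 4,
                                       max_bias: int = 8) -> float:
    """Pearson correlation between the Boolean-complexity estimate and
    the average sensitivity over all k-input functions with bias
    P <= max_bias.

    Both quantities are constant on isomorphism classes, so the
    complexity pipeline runs once per class and the correlation is
    weighted by class size.
    """
    if k > 4:
        raise ValueError("full-space correlation supported for k <= 4")
    n = 1 << k
    masks = np.arange(1 << n, dtype=np.uint64)
    popcnt = np.array([int(m).bit_count() for m in range(1 << n)])
    keep = popcnt <= max_bias
    keys = _canonical_keys(k)[keep]
    kept_masks = masks[keep]
    uniq, inverse, counts = np.unique(keys, return_inverse=True,
                                      return_counts=True)
    # one representative mask per class
    reps = np.zeros(len(uniq), dtype=np.uint64)
    reps[inverse] = kept_masks          # any member serves as representative
    comp = np.empty(len(uniq))
    sens = np.empty(len(uniq))
    for i, rep in enumerate(reps):
        m = int(rep)
        comp[i] = complexity_estimate_mask(m, k)
        sens[i] = float(average_sensitivity_mask(m, k))
    w = counts.astype(float)
    wsum = w.sum()
    mc = (w * comp).sum() / wsum
    ms = (w * sens).sum() / wsum
    cov = (w * (comp - mc) * (sens - ms)).sum()
    var_c = (w * (comp - mc) ** 2).sum()
    var_s = (w * (sens - ms) ** 2).sum()
    return float(cov / np.sqrt(var_c * var_s))
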