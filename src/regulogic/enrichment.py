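"""Enrichment of function types in a reference rule collection.

Given a collection of update rules harvested from Boolean network
models, these routines compare the relative abundance f1 of a type at
each in-degree k against its abundance f0 in the ensemble of uniformly
random k-input functions.  The enrichment ratio is E = f1/f0; the
relative enrichment of a subtype within an englobing type is
E_R = (f_s1/f1)/(f_s0/f0), which tests whether a subtype's excess is
explained by its parent type's excess alone.

Significance is assessed with an exact one-sided binomial tail
P(X >= observed | n, f0) — the null being that the n reference rules of
in-degree k are drawn independently from the random ensemble.  No
multiple-testing correction is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Iterable, Optional

from scipy import stats

from .bf_core import TruthTable, bias
from .bf_types import (
    DEFAULT_CATALOG_BOUND,
    TYPE_PREDICATES,
    catalog_masks,
    effective_inputs,
    is_canalyzing,
    is_effective,
    is_ncf,
    is_unate,
    truncate_ineffective,
)

__all__ = [
    "RuleRecord",
    "ReferenceDataset",
    "EnrichmentResult",
    "relative_abundance",
    "enrichment_test",
    "relative_enrichment_test",
    "truncated_view",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RuleRecord:
    model_id: str
    node_id: str
    regulators: tuple[str, ...]
    tt: TruthTable

    @property
    def k(self) -> int:
        return self.tt.k


@dataclass(frozen=True)
class ReferenceDataset:
    """A collection of (model, node, rule) records."""

    records: tuple[RuleRecord, ...]

    def __len__(self) -> int:
        return len(self.records)

    def n_k(self, k: int) -> int:
        return sum(1 for r in self.records if r.k == k)

    def in_degree_histogram(self) -> dict[int, int]:
        hist: dict[int, int] = {}
        for r in self.records:
            hist[r.k] = hist.get(r.k, 0) + 1
        return dict(sorted(hist.items()))

    def rules_at(self, k: int) -> tuple[RuleRecord, ...]:
        return tuple(r for r in self.records if r.k == k)


def _type_matches(tt: TruthTable, type: str,
                  catalog_bound: int = DEFAULT_CATALOG_BOUND) -> Optional[bool]:
    """Type membership; None when undecidable (RoF beyond the bound)."""
    if type in ("RoF", "nonNCF-RoF") and tt.k > catalog_bound:
        return None
    return bool(TYPE_PREDICATES[type](tt))


@dataclass(frozen=True)
class EnrichmentResult:
    k: int
    type: str
    f0: float
    f1: float
    enrichment: float
    p_value: float
    n: int
    count: int
    englobing_type: Optional[str] = None


def relative_abundance(ds: ReferenceDataset, type: str, k: int) -> Fraction:
    """Fraction of the k-input reference rules that are of the type.

    Rules whose membership is undecidable (read-once beyond the catalog
    bound) are excluded from numerator and denominator with a log note.
    """
    rules = ds.rules_at(k)
    if not rules:
        raise ValueError(f"no rules with k={k} in the dataset")
    decided = [(_type_matches(r.tt, type)) for r in rules]
    skipped = sum(1 for d in decided if d is None)
    if skipped:
        logger.warning(
            "%d of %d rules at k=%d skipped (RoF status unknown)",
            skipped, len(rules), k,
        )
    kept = [d for d in decided if d is not None]
    if not kept:
        raise ValueError(f"no classifiable rules with k={k}")
    return Fraction(sum(kept), len(kept))


def enrichment_test(ds: ReferenceDataset, type: str, k: int,
                    f0: float) -> EnrichmentResult:
    """Enrichment E = f1/f0 with exact one-sided binomial p-value."""
    if not 0 < f0 < 1:
        raise ValueError(f"f0 must lie in (0, 1), got {f0}")
    rules = ds.rules_at(k)
    if not rules:
        raise ValueError(f"no rules with k={k} in the dataset")
    decided = [d for r in rules if (d := _type_matches(r.tt, type)) is not None]
    n = len(decided)
    count = sum(decided)
    f1 = count / n
    p = float(stats.binom.sf(count - 1, n, f0))      # P(X >= count)
    return EnrichmentResult(k=k, type=type, f0=float(f0), f1=f1,
                            enrichment=f1 / f0, p_value=p, n=n, count=count)


def relative_enrichment_test(
    ds: ReferenceDataset, subtype: str, englobing_type: str, k: int,
    subtype_fraction_full: Optional[float] = None,
) -> EnrichmentResult:
    """Relative enrichment E_R of a subtype within an englobing type.

    ``subtype_fraction_full`` is f_s0/f0, the full-space fraction of the
    englobing type's functions that belong to the subtype; by default it
    is computed with :func:`regulogic.census.subtype_fraction`.  The
    null model draws the reference's englobing-type rules from the
    full-space englobing set, so the p-value is the binomial tail with
    n = the reference count of the englobing type at k.
    """
    if subtype_fraction_full is None:
        from .census import subtype_fraction

        subtype_fraction_full = float(subtype_fraction(englobing_type,
                                                       subtype, k))
    if not 0 < subtype_fraction_full <= 1:
        raise ValueError("subtype fraction must lie in (0, 1]")
    rules = ds.rules_at(k)
    pairs = [
        (s, e)
        for r in rules
        if (s := _type_matches(r.tt, subtype)) is not None
        and (e := _type_matches(r.tt, englobing_type)) is not None
    ]
    n_englobing = sum(1 for _, e in pairs if e)
    if n_englobing == 0:
        raise ValueError(
            f"no {englobing_type} rules with k={k} in the dataset"
        )
    count = sum(1 for s, e in pairs if s and e)
    ratio_ref = count / n_englobing                     # f_s1 / f1
    p = float(stats.binom.sf(count - 1, n_englobing, subtype_fraction_full))
    return EnrichmentResult(
        k=k, type=subtype, f0=float(subtype_fraction_full), f1=ratio_ref,
        enrichment=ratio_ref / subtype_fraction_full, p_value=p,
        n=n_englobing, count=count, englobing_type=englobing_type,
    )


def truncated_view(ds: ReferenceDataset) -> ReferenceDataset:
    """Replace every rule having ineffective inputs by its truncation.

    Constant rules cannot be truncated and are dropped with a warning.
    """
    out = []
    dropped = 0
    for r in ds.records:
        eff = effective_inputs(r.tt)
        if not eff:
            dropped += 1
            continue
        if len(eff) == r.k:
            out.append(r)
        else:
            out.append(
                RuleRecord(
                    model_id=r.model_id,
                    node_id=r.node_id,
                    regulators=tuple(r.regulators[i - 1] for i in eff),
                    tt=truncate_ineffective(r.tt),
                )
            )
    if dropped:
        logger.warning("dropped %d constant rules during truncation", dropped)
    return ReferenceDataset(tuple(out))
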