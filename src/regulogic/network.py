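"""Network average sensitivity under type-constrained rule ensembles.

The network average sensitivity s of a Boolean network model is the
mean of the node-level average sensitivities; s near 1 marks the
critical regime between ordered and chaotic dynamics.  To probe what a
preference for a function type implies dynamically, the wiring of each
model is kept fixed while every node's rule is resampled uniformly from
the chosen type at the node's in-degree, and the distribution of s over
models and replicates is compared with the unperturbed ("biological")
one via empirical confidence-interval overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Optional, Sequence

import numpy as np

from .bf_core import TruthTable, _full
from .bf_types import (
    DEFAULT_CATALOG_BOUND,
    TYPE_PREDICATES,
    build_catalog,
    classify,
)
from .complexity import average_sensitivity

__all__ = [
    "BooleanNetworkModel",
    "SensitivityDistribution",
    "network_average_sensitivity",
    "sample_rule",
    "type_sensitivity_distribution",
    "ci_overlap",
]

DEFAULT_REJECTION_CAP = 10 ** 6

# types drawn by rejection from uniform random functions
_REJECTION_TYPES = ("EF", "UF", "EUF", "CF", "ECF")
# types drawn by index into the generated catalogs
_CATALOG_TYPES = ("NCF", "RoF", "nonNCF-RoF")


@dataclass(frozen=True)
class BooleanNetworkModel:
    """Named nodes with per-node ordered regulator lists and rules.

    Regulator names must resolve to nodes of the model or to declared
    external inputs; self-loops are ordinary regulators.
    """

    name: str
    nodes: tuple[str, ...]
    regulators: dict[str, tuple[str, ...]]
    rules: dict[str, TruthTable]
    external_inputs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        known = set(self.nodes) | set(self.external_inputs)
        for node in self.nodes:
            regs = self.regulators.get(node, ())
            rule = self.rules.get(node)
            if rule is None:
                raise ValueError(f"node {node!r} has no rule")
            if rule.k != len(regs):
                raise ValueError(
                    f"node {node!r}: rule has k={rule.k} but "
                    f"{len(regs)} regulators"
                )
            unknown = [r for r in regs if r not in known]
            if unknown:
                raise ValueError(
                    f"node {node!r}: unknown regulators {unknown}"
                )

    @property
    def in_degrees(self) -> dict[str, int]:
        return {n: len(self.regulators[n]) for n in self.nodes}


def network_average_sensitivity(model: BooleanNetworkModel) -> Fraction:
    """Mean of the node-level average sensitivities."""
    if not model.nodes:
        raise ValueError("empty model")
    total = sum(
        (average_sensitivity(model.rules[n]) for n in model.nodes),
        Fraction(0),
    )
    return total / len(model.nodes)


def sample_rule(k: int, type: str, rng: np.random.Generator,
                max_attempts: int = DEFAULT_REJECTION_CAP,
                catalog_bound: int = DEFAULT_CATALOG_BOUND) -> TruthTable:
    """Uniform draw of a k-input function of the given type.

    Catalog types index the generated NCF/RoF catalogs; the broader
    types use rejection sampling from uniform random functions, which
    is exactly uniform on the type set.  ``type='uniform'`` draws an
    unconstrained random function.
    """
    n = 1 << k
    if type in _CATALOG_TYPES:
        if k > catalog_bound:
            raise ValueError(
                f"{type} sampling needs the k={k} catalog (bound {catalog_bound})"
            )
        masks = build_catalog(k, type, catalog_bound).sorted_masks()
        if not masks:
            raise ValueError(f"no {type} functions exist at k={k}")
        return TruthTable.from_mask(masks[int(rng.integers(len(masks)))], k)
    if type == "uniform":
        bits = rng.integers(0, 2, size=n)
        return TruthTable(k, tuple(int(b) for b in bits))
    if type not in _REJECTION_TYPES:
        raise ValueError(f"unknown rule type {type!r}")
    predicate = TYPE_PREDICATES[type]
    for _ in range(max_attempts):
        bits = rng.integers(0, 2, size=n)
        tt = TruthTable(k, tuple(int(b) for b in bits))
        if predicate(tt):
            return tt
    raise RuntimeError(
        f"rejection sampling of {type} at k={k} exceeded {max_attempts} "
        "attempts; the type is too rare — use a catalog-based type"
    )


@dataclass(frozen=True)
class SensitivityDistribution:
    type: str
    values: tuple[float, ...]          # one per (model, replicate)
    replicates: int

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    def interval(self, level: float = 95.0) -> tuple[float, float]:
        lo = (100.0 - level) / 2.0
        lo_v, hi_v = np.percentile(self.values, [lo, 100.0 - lo])
        return float(lo_v), float(hi_v)


def type_sensitivity_distribution(
    models: Sequence[BooleanNetworkModel],
    type: str,
    replicates: int = 100,
    seed: int | np.random.Generator | None = None,
) -> SensitivityDistribution:
    """Distribution of network average sensitivities when every node's
    rule is resampled from the type at the node's in-degree.

    ``type='biological'`` keeps the models' own rules (one value per
    model, repeated across replicates only notionally: replicates=1).
    """
    if not models:
        raise ValueError("need at least one model")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if type == "biological":
        values = tuple(
            float(network_average_sensitivity(m)) for m in models
        )
        return SensitivityDistribution(type=type, values=values, replicates=1)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    values = []
    for model in models:
        for _ in range(replicates):
            total = 0.0
            for node in model.nodes:
                k = len(model.regulators[node])
                total += float(average_sensitivity(sample_rule(k, type, rng)))
            values.append(total / len(model.nodes))
    return SensitivityDistribution(type=type, values=tuple(values),
                                   replicates=replicates)


def ci_overlap(dist: SensitivityDistribution,
               reference: SensitivityDistribution,
               level: float = 95.0) -> float:
    """Fraction of ``dist`` lying outside the reference's empirical
    central interval (percentiles by linear interpolation)."""
    lo, hi = reference.interval(level)
    values = np.asarray(dist.values)
    return float(np.mean((values < lo) | (values > hi)))
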