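"""Synthetic model collections emulating curated Boolean-network data.

The generator produces collections of small Boolean network models whose
rule statistics mimic the salient features of published model
compilations: an in-degree distribution that decays quickly with k, and
a rule-type mixture heavily weighted toward nested canalyzing functions.
It exists so the enrichment and network-sensitivity pipelines can be
exercised end to end without any external data; it makes no attempt to
reproduce any particular published model.

Defaults: in-degrees 1..4 with probabilities 0.34/0.28/0.22/0.16 (a
rapid decay at desk scale), and a type mixture of 70% NCF, 5% RoF, 8%
CF, 4% UF, 8% EF and 5% unconstrained random rules.  Generation is
reproducible bit for bit from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .bf_core import TruthTable
from .enrichment import ReferenceDataset, RuleRecord
from .network import BooleanNetworkModel, sample_rule

__all__ = ["FixtureSpec", "FixtureCollection", "generate_collection"]

DEFAULT_IN_DEGREE_PROBS = {1: 0.34, 2: 0.28, 3: 0.22, 4: 0.16}
DEFAULT_TYPE_MIXTURE = {
    "NCF": 0.70,
    "RoF": 0.05,
    "CF": 0.08,
    "UF": 0.04,
    "EF": 0.08,
    "uniform": 0.05,
}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic model collection."""

    n_models: int = 20
    nodes_range: tuple[int, int] = (8, 16)          # inclusive bounds
    in_degree_probs: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_IN_DEGREE_PROBS)
    )
    type_mixture: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_MIXTURE)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        lo, hi = self.nodes_range
        if not 1 <= lo <= hi:
            raise ValueError(f"bad nodes_range {self.nodes_range}")
        for name, probs in (("in_degree_probs", self.in_degree_probs),
                            ("type_mixture", self.type_mixture)):
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1, got {total}")
            if any(p < 0 for p in probs.values()):
                raise ValueError(f"{name} has negative probabilities")
        if max(self.in_degree_probs) > hi:
            raise ValueError(
                "largest in-degree exceeds the maximum model size"
            )


@dataclass(frozen=True)
class FixtureCollection:
    models: tuple[BooleanNetworkModel, ...]
    dataset: ReferenceDataset
    rule_types: dict[tuple[str, str], str]      # (model, node) -> type label


def _draw_categorical(rng: np.random.Generator, probs: dict) -> object:
    keys = sorted(probs)
    p = np.array([probs[key] for key in keys], dtype=float)
    p = p / p.sum()
    return keys[int(rng.choice(len(keys), p=p))]


def generate_collection(spec: FixtureSpec,
                        out_dir: str | Path | None = None) -> FixtureCollection:
    """Generate the collection; optionally write one BoolNet-style file
    per model plus a combined reference TSV under ``out_dir``."""
    rng = np.random.default_rng(spec.seed)
    models = []
    records = []
    rule_types: dict[tuple[str, str], str] = {}
    lo, hi = spec.nodes_range
    for m in range(spec.n_models):
        model_id = f"M{m + 1:03d}"
        n_nodes = int(rng.integers(lo, hi + 1))
        nodes = tuple(f"G{j + 1:02d}" for j in range(n_nodes))
        regulators: dict[str, tuple[str, ...]] = {}
        rules: dict[str, TruthTable] = {}
        for node in nodes:
            k = int(_draw_categorical(rng, spec.in_degree_probs))
            k = min(k, n_nodes)          # tiny models cap the in-degree
            regs = tuple(
                nodes[i] for i in sorted(
                    rng.choice(n_nodes, size=k, replace=False)
                )
            )
            type_label = str(_draw_categorical(rng, spec.type_mixture))
            tt = sample_rule(k, type_label, rng)
            regulators[node] = regs
            rules[node] = tt
            rule_types[(model_id, node)] = type_label
            records.append(RuleRecord(model_id, node, regs, tt))
        models.append(
            BooleanNetworkModel(name=model_id, nodes=nodes,
                                regulators=regulators, rules=rules)
        )
    collection = FixtureCollection(
        models=tuple(models),
        dataset=ReferenceDataset(tuple(records)),
        rule_types=rule_types,
    )
    if out_dir is not None:
        from .io import write_boolnet, write_reference_tsv

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for model in collection.models:
            write_boolnet(model, out / f"{model.name}.bnet")
        write_reference_tsv(collection.dataset, out / "reference.tsv")
    return collection
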