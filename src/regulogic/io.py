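"""File formats for rule collections, network models and catalogs.

Reference dataset TSV
    Columns ``model_id, node_id, regulators, output_bits``; regulators
    a comma-separated name list, output bits MSB-first over row indices
    (so the string reads x_k..x_1; see :mod:`regulogic.bf_core`).

BoolNet-style expression files
    A ``targets, factors`` header followed by one ``name, expression``
    line per node, with ``!``, ``&``, ``|`` and parentheses.  Regulator
    order is the order of first appearance in the expression.  Names
    appearing only on the right-hand side become external inputs.

Catalog cache
    A JSON header line (k, type, count, bit order) followed by one hex
    truth table per line.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Iterable, TextIO

import pandas as pd

from .bf_core import TruthTable, expr_to_tt, format_expr, parse_expr
from .bf_types import FunctionCatalog, build_catalog
from .complexity import qm_minimize
from .enrichment import ReferenceDataset, RuleRecord
from .network import BooleanNetworkModel

__all__ = [
    "read_reference_tsv",
    "write_reference_tsv",
    "read_boolnet",
    "write_boolnet",
    "model_to_records",
    "models_to_dataset",
    "save_catalog",
    "load_catalog",
]

_NAME = re.compile(r"[A-Za-z_][A-Za-z0-9_.]*")


# ---------------------------------------------------------------------------
# reference dataset TSV
# ---------------------------------------------------------------------------

def write_reference_tsv(ds: ReferenceDataset, path: str | Path) -> None:
    rows = [
        {
            "model_id": r.model_id,
            "node_id": r.node_id,
            "regulators": ",".join(r.regulators),
            "output_bits": r.tt.to_string(),
        }
        for r in ds.records
    ]
    pd.DataFrame(rows, columns=["model_id", "node_id", "regulators",
                                "output_bits"]).to_csv(
        path, sep="\t", index=False
    )


def read_reference_tsv(path: str | Path,
                       lsb_first: bool = False) -> ReferenceDataset:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"model_id", "node_id", "regulators", "output_bits"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"reference TSV missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        regs = tuple(s for s in str(row.regulators).split(",") if s)
        tt = TruthTable.from_string(str(row.output_bits), lsb_first=lsb_first)
        if tt.k != len(regs):
            raise ValueError(
                f"{row.model_id}/{row.node_id}: {len(regs)} regulators "
                f"but a {tt.k}-input truth table"
            )
        records.append(RuleRecord(str(row.model_id), str(row.node_id),
                                  regs, tt))
    return ReferenceDataset(tuple(records))


# ---------------------------------------------------------------------------
# BoolNet-style expression files
# ---------------------------------------------------------------------------

def _compile_rule(expression: str) -> tuple[tuple[str, ...], TruthTable]:
    """Map names to x1.. in order of first appearance, then evaluate."""
    order: list[str] = []

    def sub(match: re.Match) -> str:
        name = match.group(0)
        if name not in order:
            order.append(name)
        return f"x{order.index(name) + 1}"

    translated = _NAME.sub(sub, expression)
    if not order:
        raise ValueError(f"no regulators in expression {expression!r}")
    expr = parse_expr(translated)
    return tuple(order), expr_to_tt(expr, len(order))


def read_boolnet(path: str | Path,
                 name: str | None = None) -> BooleanNetworkModel:
    lines = Path(path).read_text().splitlines()
    body = [
        ln for ln in lines
        if ln.strip() and not ln.strip().startswith("#")
    ]
    if not body or not body[0].lower().replace(" ", "").startswith(
        "targets,factors"
    ):
        raise ValueError(f"{path}: expected a 'targets, factors' header")
    nodes: list[str] = []
    regulators: dict[str, tuple[str, ...]] = {}
    rules: dict[str, TruthTable] = {}
    for ln in body[1:]:
        target, _, factors = ln.partition(",")
        target = target.strip()
        if not target or not factors.strip():
            raise ValueError(f"{path}: malformed line {ln!r}")
        regs, tt = _compile_rule(factors.strip())
        nodes.append(target)
        regulators[target] = regs
        rules[target] = tt
    external = tuple(
        sorted({r for regs in regulators.values() for r in regs}
               - set(nodes))
    )
    return BooleanNetworkModel(
        name=name or Path(path).stem,
        nodes=tuple(nodes),
        regulators=regulators,
        rules=rules,
        external_inputs=external,
    )


def write_boolnet(model: BooleanNetworkModel, path: str | Path) -> None:
    """Serialize a model; rules are written as minimized DNF expressions
    over the regulator names.

    The format ties a rule's inputs to the names appearing in its
    expression, so regulators that are ineffective in the rule do not
    survive a round trip; constant rules are written as a tautology or
    contradiction in the first regulator to keep the line parseable.
    """
    from .bf_core import Const

    lines = ["targets, factors"]
    for node in model.nodes:
        regs = model.regulators[node]
        expr = qm_minimize(model.rules[node], "DNF")
        if isinstance(expr, Const):
            op = "|" if expr.value else "&"
            lines.append(f"{node}, {regs[0]} {op} !{regs[0]}")
            continue
        text = format_expr(expr)
        # substitute regulator names for x1..xk, longest index first
        for i in range(len(regs), 0, -1):
            text = text.replace(f"x{i}", regs[i - 1])
        text = text.replace("~", "!")
        lines.append(f"{node}, {text}")
    Path(path).write_text("\n".join(lines) + "\n")


def model_to_records(model: BooleanNetworkModel) -> list[RuleRecord]:
    return [
        RuleRecord(model.name, node, model.regulators[node],
                   model.rules[node])
        for node in model.nodes
    ]


def models_to_dataset(
    models: Iterable[BooleanNetworkModel],
) -> ReferenceDataset:
    records: list[RuleRecord] = []
    for m in models:
        records.extend(model_to_records(m))
    return ReferenceDataset(tuple(records))


# ---------------------------------------------------------------------------
# catalog cache files
# ---------------------------------------------------------------------------

def save_catalog(catalog: FunctionCatalog, path: str | Path) -> None:
    header = {
        "k": catalog.k,
        "type": catalog.type,
        "count": catalog.count,
        "bit_order": "lsb-row-0",
    }
    width = max(1, (1 << catalog.k) // 4)
    with open(path, "w") as fh:
        fh.write(json.dumps(header) + "\n")
        for mask in catalog.sorted_masks():
            fh.write(f"{mask:0{width}x}\n")


def load_catalog(path: str | Path) -> FunctionCatalog:
    with open(path) as fh:
        header = json.loads(fh.readline())
        masks = frozenset(int(ln, 16) for ln in fh if ln.strip())
    if len(masks) != header["count"]:
        raise ValueError(
            f"{path}: header count {header['count']} != {len(masks)} entries"
        )
    return FunctionCatalog(k=header["k"], type=header["type"], masks=masks)
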