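"""File formats: BoolNet-style ``.bnet`` rules and SIF edge lists.

The ``.bnet`` dialect: a header line ``targets, factors``, then one line
per node ``NAME, EXPR`` using ``&``, ``|``, ``!`` and parentheses.
Source nodes are written self-referentially (``ABA, ABA``).  Node names
containing spaces or commas are sanitized (documented mapping returned by
the writer) since the dialect reserves those characters.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Mapping

from .expressions import And, Expr, Lit, Or, canonicalize, parse_expression
from .labels import LogicLabel
from .model import BooleanFunction, BooleanModel, ModelError, RegulatoryNetwork

__all__ = ["write_bnet", "read_bnet", "bnet_text", "write_sif", "sif_text"]

_FORBIDDEN = re.compile(r"[\s,&|!()]+")


def sanitize_names(names) -> dict[str, str]:
    """Map raw node names to bnet-safe identifiers (stable, collision-free)."""
    mapping: dict[str, str] = {}
    used: set[str] = set()
    for name in sorted(names):
        safe = _FORBIDDEN.sub("_", name) or "_"
        candidate = safe
        k = 2
        while candidate in used:
            candidate = f"{safe}_{k}"
            k += 1
        used.add(candidate)
        mapping[name] = candidate
    return mapping


def _expr_bnet(e: Expr, names: Mapping[str, str]) -> str:
    if isinstance(e, Lit):
        s = names[e.name]
        return f"!{s}" if e.negated else s
    sep = " & " if isinstance(e, And) else " | "
    parts = []
    for a in e.args:
        s = _expr_bnet(a, names)
        if isinstance(a, (And, Or)):
            s = f"({s})"
        parts.append(s)
    return sep.join(parts)


def bnet_text(model: BooleanModel) -> str:
    names = sanitize_names(model.nodes)
    lines = ["targets, factors"]
    free = sorted(model.nodes - set(model.functions))
    for node in free:
        lines.append(f"{names[node]}, {names[node]}")
    for node in sorted(model.functions):
        expr = canonicalize(model.functions[node].expression)
        lines.append(f"{names[node]}, {_expr_bnet(expr, names)}")
    return "\n".join(lines) + "\n"


def write_bnet(model: BooleanModel, path) -> dict[str, str]:
    """Write the model; returns the raw→sanitized name mapping."""
    Path(path).write_text(bnet_text(model), encoding="utf-8")
    return sanitize_names(model.nodes)


def read_bnet(path_or_text) -> BooleanModel:
    """Read a ``.bnet`` file (or literal text containing a newline)."""
    text = str(path_or_text)
    if "\n" not in text:
        text = Path(text).read_text(encoding="utf-8")
    functions: list[BooleanFunction] = []
    sources: list[str] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if lineno == 1 and line.lower().replace(" ", "") == "targets,factors":
            continue
        if "," not in line:
            raise ModelError(f"bnet line {lineno}: expected 'NAME, EXPR'")
        name, expr_txt = line.split(",", 1)
        name, expr_txt = name.strip(), expr_txt.strip()
        if not name or not expr_txt:
            raise ModelError(f"bnet line {lineno}: empty name or expression")
        try:
            expr = parse_expression(expr_txt)
        except ValueError as exc:
            raise ModelError(f"bnet line {lineno}: {exc}") from exc
        if isinstance(expr, Lit) and not expr.negated and expr.name == name:
            sources.append(name)
        else:
            functions.append(BooleanFunction(name, expr))
    return BooleanModel(functions, sources=sources)


def sif_text(network: RegulatoryNetwork) -> str:
    """One line per edge: ``REGULATOR <relation> TARGET``, tab-separated.

    The relation encodes sign and logic, e.g. ``sufficient``,
    ``necessary_inhibitory``, ``positive_unknown``.
    """
    lines = []
    for e in network.edges:
        if e.logic is LogicLabel.UNKNOWN:
            rel = "positive_unknown" if e.sign == "+" else "negative_unknown"
        else:
            rel = e.logic.value
        lines.append(f"{e.regulator}\t{rel}\t{e.target}")
    return "\n".join(lines) + ("\n" if lines else "")


def write_sif(network: RegulatoryNetwork, path) -> None:
    Path(path).write_text(sif_text(network), encoding="utf-8")
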