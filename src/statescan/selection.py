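"""A small deterministic atom-selection mini-language.

Grammar (case-insensitive keywords, boolean composition)::

    expr     := term {"or" term}
    term     := factor {"and" factor}
    factor   := "not" factor | "(" expr ")" | primitive
    primitive:= "name" values | "resname" values | "chain" values
              | "resseq" ranges | "serial" ranges
              | "hetero" | "water" | "protein" | "all"

``values`` is a comma-separated list (``name CA,CB``); ``ranges`` accepts
integers and ``lo:hi`` inclusive ranges (``resseq 32:38,60``).  An expression
always resolves to the same ordered atom-index list on every model of one
trajectory, because it only consults the shared topology.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np

from .io import StructureModel, Topology, Trajectory

logger = logging.getLogger(__name__)

__all__ = ["Selection", "SelectionError", "select_atoms"]

_WATER_NAMES = ("HOH", "WAT", "TIP3", "SOL")


class SelectionError(ValueError):
    """Raised for a syntactically invalid selection expression."""


@dataclass(frozen=True)
class Selection:
    """A parsed selection expression; resolves against any topology."""

    expression: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "_ast", _parse(self.expression))

    def mask(self, topology: Topology) -> np.ndarray:
        """Boolean per-atom mask over a topology."""
        return self._ast(topology)

    def indices(self, topology: Topology) -> np.ndarray:
        """Ordered atom indices (model atom order) matching the expression."""
        idx = np.flatnonzero(self.mask(topology))
        if idx.size == 0:
            logger.warning("selection %r matched no atoms", self.expression)
        return idx


def select_atoms(obj: Trajectory | StructureModel, sel: Selection | str) -> np.ndarray:
    """Resolve a selection on a trajectory or model; returns ordered indices.

    The result depends only on the topology, so it is identical for every
    frame of a trajectory.
    """
    if isinstance(sel, str):
        sel = Selection(sel)
    return sel.indices(obj.topology)


# --- parser -----------------------------------------------------------------

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def _tokenize(expression: str) -> list[str]:
    if not expression or not expression.strip():
        raise SelectionError("empty selection expression")
    return _TOKEN_RE.findall(expression)


def _parse(expression: str):
    tokens = _tokenize(expression)
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def advance():
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_expr():
        node = parse_term()
        while peek() is not None and peek().lower() == "or":
            advance()
            rhs = parse_term()
            node = _or(node, rhs)
        return node

    def parse_term():
        node = parse_factor()
        while peek() is not None and peek().lower() == "and":
            advance()
            rhs = parse_factor()
            node = _and(node, rhs)
        return node

    def parse_factor():
        tok = peek()
        if tok is None:
            raise SelectionError(f"unexpected end of expression in {expression!r}")
        if tok.lower() == "not":
            advance()
            inner = parse_factor()
            return _not(inner)
        if tok == "(":
            advance()
            inner = parse_expr()
            if peek() != ")":
                raise SelectionError(f"missing ')' in {expression!r}")
            advance()
            return inner
        return parse_primitive()

    def parse_values(keyword: str) -> list[str]:
        tok = peek()
        if tok is None or tok.lower() in ("and", "or", "not") or tok in "()":
            raise SelectionError(f"keyword {keyword!r} requires a value in {expression!r}")
        return advance().split(",")

    def parse_primitive():
        tok = advance().lower()
        if tok == "all":
            return lambda top: np.ones(top.n_atoms, dtype=bool)
        if tok == "hetero":
            return lambda top: top.is_hetero.copy()
        if tok == "water":
            return lambda top: np.isin(top.residue_names, _WATER_NAMES)
        if tok == "protein":
            return lambda top: ~top.is_hetero & ~np.isin(top.residue_names, _WATER_NAMES)
        if tok == "name":
            values = parse_values(tok)
            return lambda top: np.isin(top.names, values)
        if tok == "resname":
            values = parse_values(tok)
            return lambda top: np.isin(top.residue_names, values)
        if tok == "chain":
            values = parse_values(tok)
            return lambda top: np.isin(top.chain_ids, values)
        if tok in ("resseq", "serial"):
            values = parse_values(tok)
            singles, ranges = _parse_int_ranges(values, expression)
            attr = "residue_seqs" if tok == "resseq" else "serials"

            def match(top, singles=singles, ranges=ranges, attr=attr):
                arr = getattr(top, attr)
                mask = np.isin(arr, singles) if singles else np.zeros(top.n_atoms, bool)
                for lo, hi in ranges:
                    mask |= (arr >= lo) & (arr <= hi)
                return mask

            return match
        raise SelectionError(f"unknown selection keyword {tok!r} in {expression!r}")

    node = parse_expr()
    if pos != len(tokens):
        raise SelectionError(f"trailing tokens {tokens[pos:]} in {expression!r}")
    return node


def _parse_int_ranges(values: list[str], expression: str):
    singles: list[int] = []
    ranges: list[tuple[int, int]] = []
    for v in values:
        try:
            if ":" in v:
                lo, hi = v.split(":")
                ranges.append((int(lo), int(hi)))
            else:
                singles.append(int(v))
        except ValueError as exc:
            raise SelectionError(f"invalid integer spec {v!r} in {expression!r}") from exc
    return singles, ranges


def _and(a, b):
    return lambda top: a(top) & b(top)


def _or(a, b):
    return lambda top: a(top) | b(top)


def _not(a):
    return lambda top: ~a(top)
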