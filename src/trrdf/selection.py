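"""A minimal atom-selection grammar.

Deliberately small and stable::

    primary  :=  'all'
              |  'name'    VALUE+
              |  'element' VALUE+
              |  'resname' VALUE+
              |  'chainid' INT+
              |  'resid'   (INT | INT 'to' INT)+
    factor   :=  'not' factor | '(' expr ')' | primary
    term     :=  factor ('and' factor)*
    expr     :=  term ('or' term)*

Multiple values after a keyword are an implicit OR ("name NA CL" matches
either).  ``resid`` refers to the 0-based residue index of the topology
table.  String matching is case-sensitive for atom/residue names (which
are conventionally upper case) and case-insensitive for element symbols.

``resolve_selection`` also accepts a raw sequence of 0-based atom indices
in place of an expression.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

from .errors import EmptySelectionError, SelectionError, TopologyError

__all__ = ["resolve_selection", "select_mask"]

_KEYWORDS = {"name", "element", "resname", "resid", "chainid", "all"}
_OPERATORS = {"and", "or", "not", "to", "(", ")"}
_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def _tokenize(expression: str) -> list[str]:
    return _TOKEN_RE.findall(expression)


class _Parser:
    def __init__(self, tokens: list[str], topology: pd.DataFrame) -> None:
        self.tokens = tokens
        self.pos = 0
        self.topo = topology

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of selection expression")
        self.pos += 1
        return tok

    # expr := term (or term)*
    def expr(self) -> np.ndarray:
        mask = self.term()
        while self.peek() == "or":
            self.next()
            mask = mask | self.term()
        return mask

    # term := factor (and factor)*
    def term(self) -> np.ndarray:
        mask = self.factor()
        while self.peek() == "and":
            self.next()
            mask = mask & self.factor()
        return mask

    def factor(self) -> np.ndarray:
        tok = self.peek()
        if tok == "not":
            self.next()
            return ~self.factor()
        if tok == "(":
            self.next()
            mask = self.expr()
            if self.next() != ")":
                raise SelectionError("unbalanced parenthesis in selection")
            return mask
        return self.primary()

    def _values(self) -> list[str]:
        vals = []
        while True:
            tok = self.peek()
            if tok is None or tok in _OPERATORS or tok in _KEYWORDS:
                break
            vals.append(self.next())
        if not vals:
            raise SelectionError("keyword requires at least one value")
        return vals

    def primary(self) -> np.ndarray:
        tok = self.next()
        n = len(self.topo)
        if tok == "all":
            return np.ones(n, dtype=bool)
        if tok == "name":
            return self.topo["name"].isin(self._values()).to_numpy()
        if tok == "resname":
            return self.topo["resname"].isin(self._values()).to_numpy()
        if tok == "element":
            vals = {v.upper() for v in self._values()}
            return self.topo["element"].str.upper().isin(vals).to_numpy()
        if tok == "chainid":
            ids = [self._int(v) for v in self._values()]
            return self.topo["chain"].isin(ids).to_numpy()
        if tok == "resid":
            return self._resid_mask()
        raise SelectionError(f"unknown selection keyword {tok!r}")

    def _int(self, token: str) -> int:
        try:
            return int(token)
        except ValueError as exc:
            raise SelectionError(f"expected an integer, got {token!r}") from exc

    def _resid_mask(self) -> np.ndarray:
        resid = self.topo["resid"].to_numpy()
        mask = np.zeros(len(self.topo), dtype=bool)
        saw_value = False
        while True:
            tok = self.peek()
            if tok is None or tok in _OPERATORS or tok in _KEYWORDS:
                break
            lo = self._int(self.next())
            saw_value = True
            if self.peek() == "to":
                self.next()
                hi = self._int(self.next())
                if hi < lo:
                    raise SelectionError(f"empty resid range {lo} to {hi}")
                mask |= (resid >= lo) & (resid <= hi)
            else:
                mask |= resid == lo
        if not saw_value:
            raise SelectionError("resid requires at least one value")
        return mask


def select_mask(topology: pd.DataFrame, expression: str) -> np.ndarray:
    """Evaluate a selection expression to a boolean per-atom mask."""
    tokens = _tokenize(expression)
    if not tokens:
        raise SelectionError("empty selection expression")
    parser = _Parser(tokens, topology)
    mask = parser.expr()
    if parser.peek() is not None:
        raise SelectionError(f"trailing tokens in selection: {tokens[parser.pos:]}")
    return mask


def resolve_selection(trajectory_or_topology, expression) -> np.ndarray:
    """Resolve a selection expression or raw index list to sorted atom indices.

    Raises :class:`EmptySelectionError` on zero matches — a silent empty
    group almost always signals a typo in the expression.
    """
    topo = getattr(trajectory_or_topology, "topology", trajectory_or_topology)
    if not isinstance(topo, pd.DataFrame):
        raise TopologyError("expected a Trajectory or a topology DataFrame")
    if isinstance(expression, str):
        mask = select_mask(topo, expression)
        idx = np.flatnonzero(mask).astype(np.intp)
    else:
        idx = np.unique(np.asarray(list(expression), dtype=np.intp))
        if idx.size and (idx[0] < 0 or idx[-1] >= len(topo)):
            raise TopologyError("atom index out of range for this topology")
    if idx.size == 0:
        raise EmptySelectionError(f"selection matched no atoms: {expression!r}")
    return idx
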