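"""Boolean gene-protein-reaction (GPR) rules.

A GPR states which gene combinations enable a reaction: ``and`` joins the
subunits of an enzyme complex (all required), ``or`` joins isozymes (any
suffices).  Rules are parsed from the text renderings common in SBML-fbc
exports: case-insensitive ``and``/``or``, parentheses, gene identifiers as
arbitrary non-whitespace tokens, with ``and`` binding tighter than ``or``.
An empty rule denotes a spontaneous reaction and always evaluates true.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import FrozenSet, Iterable, List, Set, Tuple, Union

__all__ = ["GPRRule", "GPRParseError", "parse_gpr", "evaluate_gpr"]


class GPRParseError(ValueError):
    """Raised when a GPR string cannot be parsed."""


# internal tree: ("gene", id) | ("and", [children]) | ("or", [children]) | None
_Node = Union[Tuple[str, object], None]

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def _tokenize(text: str) -> List[str]:
    return _TOKEN_RE.findall(text)


class _Parser:
    """Recursive descent over:  or_expr := and_expr ('or' and_expr)* ;
    and_expr := atom ('and' atom)* ; atom := gene | '(' or_expr ')'."""

    def __init__(self, tokens: List[str], source: str):
        self.tokens = tokens
        self.pos = 0
        self.source = source

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def parse(self) -> _Node:
        node = self.or_expr()
        if self.peek() is not None:
            raise GPRParseError(
                f"trailing token {self.peek()!r} in GPR {self.source!r}"
            )
        return node

    def or_expr(self) -> _Node:
        parts = [self.and_expr()]
        while self.peek() is not None and self.peek().lower() == "or":
            self.next()
            parts.append(self.and_expr())
        return parts[0] if len(parts) == 1 else ("or", parts)

    def and_expr(self) -> _Node:
        parts = [self.atom()]
        while self.peek() is not None and self.peek().lower() == "and":
            self.next()
            parts.append(self.atom())
        return parts[0] if len(parts) == 1 else ("and", parts)

    def atom(self) -> _Node:
        tok = self.next()
        if tok is None:
            raise GPRParseError(f"unexpected end of GPR {self.source!r}")
        if tok == "(":
            node = self.or_expr()
            if self.next() != ")":
                raise GPRParseError(f"unbalanced parentheses in {self.source!r}")
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GPRParseError(f"unexpected token {tok!r} in GPR {self.source!r}")
        return ("gene", tok)


def parse_gpr(text: str) -> "GPRRule":
    """Parse a GPR string into a :class:`GPRRule`; empty/blank -> empty rule."""
    text = (text or "").strip()
    if not text:
        return GPRRule(None)
    return GPRRule(_Parser(_tokenize(text), text).parse())


def _node_genes(node: _Node, out: Set[str]) -> None:
    if node is None:
        return
    kind, payload = node
    if kind == "gene":
        out.add(payload)  # type: ignore[arg-type]
    else:
        for child in payload:  # type: ignore[union-attr]
            _node_genes(child, out)


def _node_eval(node: _Node, knocked_out: Set[str]) -> bool:
    if node is None:
        return True
    kind, payload = node
    if kind == "gene":
        return payload not in knocked_out
    if kind == "and":
        return all(_node_eval(c, knocked_out) for c in payload)
    return any(_node_eval(c, knocked_out) for c in payload)


def _node_str(node: _Node, parent: str = "") -> str:
    if node is None:
        return ""
    kind, payload = node
    if kind == "gene":
        return str(payload)
    sep = f" {kind} "
    inner = sep.join(_node_str(c, kind) for c in payload)
    # parenthesize an OR nested under an AND (AND binds tighter)
    if kind == "or" and parent == "and":
        return f"({inner})"
    return inner


def _node_dnf(node: _Node) -> List[FrozenSet[str]]:
    """Disjunctive normal form as a list of conjunction gene sets."""
    if node is None:
        return []
    kind, payload = node
    if kind == "gene":
        return [frozenset([payload])]  # type: ignore[list-item]
    if kind == "or":
        seen: Set[FrozenSet[str]] = set()
        out: List[FrozenSet[str]] = []
        for child in payload:
            for conj in _node_dnf(child):
                if conj not in seen:
                    seen.add(conj)
                    out.append(conj)
        return out
    # AND: cross product of child disjunct lists
    parts = [_node_dnf(child) for child in payload]
    seen = set()
    out = []
    for combo in itertools.product(*parts):
        conj = frozenset().union(*combo)
        if conj not in seen:
            seen.add(conj)
            out.append(conj)
    return out


@dataclass(frozen=True)
class GPRRule:
    """A boolean tree over gene identifiers; ``tree is None`` means spontaneous."""

    tree: _Node = None
    _genes: FrozenSet[str] = field(init=False, compare=False, repr=False, default=frozenset())

    def __post_init__(self):
        genes: Set[str] = set()
        _node_genes(self.tree, genes)
        object.__setattr__(self, "_genes", frozenset(genes))

    @classmethod
    def from_string(cls, text: str) -> "GPRRule":
        return parse_gpr(text)

    @property
    def genes(self) -> FrozenSet[str]:
        return self._genes

    @property
    def is_empty(self) -> bool:
        return self.tree is None

    def evaluate(self, knocked_out: Iterable[str]) -> bool:
        """True iff the reaction stays enabled when ``knocked_out`` genes are removed."""
        ko = set(knocked_out)
        return _node_eval(self.tree, ko)

    def to_string(self) -> str:
        return _node_str(self.tree)

    def dnf(self) -> List[FrozenSet[str]]:
        """Disjuncts: minimal-form gene sets any one of which enables the reaction."""
        return _node_dnf(self.tree)

    def n_disjuncts(self) -> int:
        return len(self.dnf()) if self.tree is not None else 0

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


def evaluate_gpr(rule: GPRRule, knocked_out: Iterable[str]) -> bool:
    """Functional form of :meth:`GPRRule.evaluate`."""
    return rule.evaluate(knocked_out)
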