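"""Expression-based atom selection.

Grammar (case-insensitive keywords, whitespace-insensitive)::

    expr   := term (OR term)*
    term   := factor (AND factor)*
    factor := NOT factor | '(' expr ')' | predicate '(' arg ')'
            | 'backbone' | 'all'

Predicates: ``element(SYM)``, ``name(NAME)``, ``residue(RES)``,
``chain(ID)``, ``residueID(N)`` or ``residueID(N-M)``, plus the argument-less
``backbone`` and ``all``.  Evaluation is pure; flags are only written by
:func:`apply_selection`.
"""

from __future__ import annotations

import re
from typing import Optional

from .model import Atom, MolecularSystem

__all__ = [
    "SelectionError",
    "SelectionExpression",
    "parse_expression",
    "apply_selection",
    "deselect",
    "Selector",
]

PREDICATES = ("element", "name", "residue", "chain", "residueid", "backbone", "all")

#: Atom names considered backbone within amino-acid residues.
BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT", "H", "HA"})


class SelectionError(ValueError):
    def __init__(self, message: str, offset: Optional[int] = None):
        if offset is not None:
            message = f"{message} (at offset {offset})"
        super().__init__(message)
        self.offset = offset


class SelectionExpression:
    """A node of the parsed predicate tree."""

    __slots__ = ("kind", "argument", "children")

    def __init__(self, kind: str, argument: Optional[str] = None,
                 children: Optional[list] = None):
        self.kind = kind
        self.argument = argument
        self.children = children or []

    def evaluate(self, atom: Atom, residue=None, chain=None) -> bool:
        k = self.kind
        if k == "and":
            return all(c.evaluate(atom, residue, chain) for c in self.children)
        if k == "or":
            return any(c.evaluate(atom, residue, chain) for c in self.children)
        if k == "not":
            return not self.children[0].evaluate(atom, residue, chain)
        if k == "all":
            return True
        if k == "element":
            return atom.element.upper() == self.argument.upper()
        if k == "name":
            return atom.name.upper() == self.argument.upper()
        if k == "residue":
            return residue is not None and residue.name.upper() == self.argument.upper()
        if k == "chain":
            return chain is not None and chain.id.upper() == self.argument.upper()
        if k == "residueid":
            if residue is None:
                return False
            lo, hi = self.argument
            return lo <= residue.id <= hi
        if k == "backbone":
            return residue is not None and atom.name.upper() in BACKBONE_NAMES
        raise SelectionError(f"unknown node kind {k!r}")  # pragma: no cover

    def __repr__(self) -> str:  # pragma: no cover
        if self.children:
            return f"({self.kind} {' '.join(map(repr, self.children))})"
        return f"{self.kind}({self.argument or ''})"


_TOKEN_RE = re.compile(r"\s*(\(|\)|[A-Za-z_][A-Za-z0-9_]*|\S)")


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0
        self.tokens: list[tuple[str, int]] = []
        pos = 0
        while pos < len(text):
            m = _TOKEN_RE.match(text, pos)
            if not m:
                break
            self.tokens.append((m.group(1), m.start(1)))
            pos = m.end()
        self.index = 0

    def peek(self) -> Optional[tuple[str, int]]:
        return self.tokens[self.index] if self.index < len(self.tokens) else None

    def next(self) -> tuple[str, int]:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of expression", len(self.text))
        self.index += 1
        return tok

    def expect(self, value: str):
        tok = self.peek()
        if tok is None or tok[0] != value:
            offset = tok[1] if tok else len(self.text)
            raise SelectionError(f"expected {value!r}", offset)
        self.index += 1

    def parse(self) -> SelectionExpression:
        expr = self.parse_expr()
        tok = self.peek()
        if tok is not None:
            raise SelectionError(f"unexpected token {tok[0]!r}", tok[1])
        return expr

    def parse_expr(self) -> SelectionExpression:
        terms = [self.parse_term()]
        while True:
            tok = self.peek()
            if tok and tok[0].lower() == "or":
                self.index += 1
                terms.append(self.parse_term())
            else:
                break
        return terms[0] if len(terms) == 1 else SelectionExpression("or", children=terms)

    def parse_term(self) -> SelectionExpression:
        factors = [self.parse_factor()]
        while True:
            tok = self.peek()
            if tok and tok[0].lower() == "and":
                self.index += 1
                factors.append(self.parse_factor())
            else:
                break
        return factors[0] if len(factors) == 1 else SelectionExpression("and", children=factors)

    def parse_factor(self) -> SelectionExpression:
        tok = self.next()
        word, offset = tok
        low = word.lower()
        if low == "not":
            return SelectionExpression("not", children=[self.parse_factor()])
        if word == "(":
            inner = self.parse_expr()
            self.expect(")")
            return inner
        if low in ("all", "backbone"):
            return SelectionExpression(low)
        if low in ("element", "name", "residue", "chain", "residueid"):
            self.expect("(")
            arg_tok = self.peek()
            if arg_tok is None or arg_tok[0] == ")":
                raise SelectionError(
                    f"predicate {word!r} requires an argument",
                    arg_tok[1] if arg_tok else len(self.text))
            parts = []
            while True:
                t = self.peek()
                if t is None:
                    raise SelectionError("unterminated predicate argument", len(self.text))
                if t[0] == ")":
                    break
                parts.append(self.next()[0])
            self.expect(")")
            arg = "".join(parts)
            if low == "residueid":
                m = re.fullmatch(r"(-?\d+)(?:-(-?\d+))?", arg)
                if not m:
                    raise SelectionError(f"bad residueID argument {arg!r}", offset)
                lo = int(m.group(1))
                hi = int(m.group(2)) if m.group(2) else lo
                return SelectionExpression("residueid", argument=(lo, hi))
            return SelectionExpression(low, argument=arg)
        if re.fullmatch(r"[A-Za-z_][A-Za-z0-9_]*", word):
            raise SelectionError(
                f"unknown predicate {word!r}; valid predicates: {', '.join(PREDICATES)}",
                offset)
        raise SelectionError(f"unexpected token {word!r}", offset)


def parse_expression(text: str) -> SelectionExpression:
    """Parse *text* into a :class:`SelectionExpression` tree."""
    parser = _Parser(text)
    if parser.peek() is None:
        raise SelectionError("empty expression", 0)
    return parser.parse()


def apply_selection(system: MolecularSystem, expr) -> int:
    """Set every atom's ``selected`` flag from *expr*; return count selected.

    *expr* may be a tree or an expression string.
    """
    if isinstance(expr, str):
        expr = parse_expression(expr)
    count = 0
    for chain in system.chains:
        for residue in chain.residues:
            for atom in residue.atoms:
                atom.selected = expr.evaluate(atom, residue, chain)
                count += atom.selected
    for mol in system.molecules:
        for atom in mol.atoms:
            atom.selected = expr.evaluate(atom, None, None)
            count += atom.selected
    return count


def deselect(system: MolecularSystem) -> None:
    """Clear all selection flags."""
    system.deselect()


class Selector:
    """Processor-style wrapper: ``system.apply(Selector("element (H)"))``."""

    def __init__(self, expression: str):
        self.expression = parse_expression(expression)
        self.count = 0

    def __call__(self, system: MolecularSystem) -> MolecularSystem:
        self.count = apply_selection(system, self.expression)
        return system
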