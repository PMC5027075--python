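"""The textual contact-expression language.

Whether a candidate residue is "in contact" with a descriptor centre is
decided by a small user-supplied boolean expression over inter-residue
atom distances, e.g.::

    OR(DISTANCE:SCGC <= 6.5,
       AND(DISTANCE:SCGC <= DISTANCE:CA - 0.75, DISTANCE:SCGC <= 8.0))

Supported operators: logical ``OR``/``AND``/``NOT`` (function syntax),
relational ``<  <=  =  >=  >`` (the Unicode forms ``≤ ≥`` are accepted
too), and binary arithmetic ``+``/``-`` on distance terms and numeric
literals (angstrom).  A ``DISTANCE:X`` term is the Euclidean distance
between atom ``X`` of the centre and atom ``X`` of the candidate;
``DISTANCE:X;Y`` pairs atom ``X`` of the centre with atom ``Y`` of the
candidate.  Atom specifiers may name any non-hydrogen atom or one of the
virtual kinds ``CA``, ``CBX``, ``SCGC``.

The grammar (EBNF)::

    expr     = boolean ;
    boolean  = "OR" "(" expr { "," expr } ")"
             | "AND" "(" expr { "," expr } ")"
             | "NOT" "(" expr ")"
             | relation ;
    relation = arith relop arith ;
    relop    = "<" | "<=" | "=" | ">=" | ">" ;
    arith    = term { ("+" | "-") term } ;
    term     = "DISTANCE" ":" atom [ ";" atom ] | number ;
    atom     = letter-or-digit { letter-or-digit | "'" | "*" } ;
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Union

import numpy as np

from .structure_io import Residue, VirtualAtomError, virtual_atom

#: Absolute tolerance for the "=" relation on distances (angstrom).
EQ_TOLERANCE = 1e-6

_LOGICAL = ("OR", "AND", "NOT")


class ExpressionSyntaxError(ValueError):
    """Malformed contact expression; carries the character position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class ExpressionVocabularyError(ValueError):
    """Unknown operator or malformed token in a contact expression."""


class EvaluationError(ValueError):
    """An atom referenced by the expression cannot be resolved."""


# --- expression tree -------------------------------------------------------

@dataclass(frozen=True)
class Distance:
    """Distance between ``center_atom`` of the centre and ``candidate_atom``
    of the candidate residue (both default to the same specifier)."""

    center_atom: str
    candidate_atom: str

    def unparse(self) -> str:
        if self.center_atom == self.candidate_atom:
            return f"DISTANCE:{self.center_atom}"
        return f"DISTANCE:{self.center_atom};{self.candidate_atom}"


@dataclass(frozen=True)
class Literal:
    value: float

    def unparse(self) -> str:
        return f"{self.value:g}"


@dataclass(frozen=True)
class Arith:
    op: str  # '+' or '-'
    left: "NumericNode"
    right: "NumericNode"

    def unparse(self) -> str:
        return f"{self.left.unparse()} {self.op} {self.right.unparse()}"


NumericNode = Union[Distance, Literal, Arith]


@dataclass(frozen=True)
class Relation:
    op: str  # one of < <= = >= >
    left: NumericNode
    right: NumericNode

    def unparse(self) -> str:
        return f"{self.left.unparse()} {self.op} {self.right.unparse()}"


@dataclass(frozen=True)
class Logical:
    op: str  # OR / AND / NOT
    children: tuple

    def unparse(self) -> str:
        inner = ", ".join(c.unparse() for c in self.children)
        return f"{self.op}({inner})"


BoolNode = Union[Relation, Logical]


@dataclass(frozen=True)
class ContactExpression:
    """A parsed contact expression; ``text`` is the canonical rendering."""

    root: BoolNode

    @property
    def text(self) -> str:
        return self.root.unparse()

    def __str__(self) -> str:
        return self.text


# --- tokenizer -------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"""\s*(?:
        (?P<lpar>\()
      | (?P<rpar>\))
      | (?P<comma>,)
      | (?P<semi>;)
      | (?P<colon>:)
      | (?P<relop><=|>=|≤|≥|<|>|=)
      | (?P<plus>\+)
      | (?P<minus>-|−)
      | (?P<number>\d+\.\d+|\d+|\.\d+)
      | (?P<word>[A-Za-z][A-Za-z0-9'*]*)
    )""",
    re.VERBOSE,
)

_RELOP_CANON = {"≤": "<=", "≥": ">="}


@dataclass
class _Token:
    kind: str
    value: str
    pos: int


def _tokenize(text: str) -> list[_Token]:
    tokens: list[_Token] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None or m.end() == pos:
            stripped = text[pos:].lstrip()
            if not stripped:
                break
            bad_at = len(text) - len(stripped)
            raise ExpressionSyntaxError(
                f"unexpected character {text[bad_at]!r}", bad_at
            )
        kind = m.lastgroup
        val = m.group(kind)
        if kind == "relop":
            val = _RELOP_CANON.get(val, val)
        if kind == "minus":
            val = "-"
        tokens.append(_Token(kind, val, m.start(kind)))
        pos = m.end()
    tokens.append(_Token("end", "", len(text)))
    return tokens


# --- parser ----------------------------------------------------------------

class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self) -> _Token:
        return self.tokens[self.i]

    def next(self) -> _Token:
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def expect(self, kind: str) -> _Token:
        tok = self.next()
        if tok.kind != kind:
            raise ExpressionSyntaxError(
                f"expected {kind}, found {tok.value!r}", tok.pos
            )
        return tok

    # boolean level
    def parse_bool(self) -> BoolNode:
        tok = self.peek()
        if tok.kind == "word" and tok.value.upper() in _LOGICAL:
            op = self.next().value.upper()
            self.expect("lpar")
            children = []
            if self.peek().kind == "rpar":
                raise ExpressionSyntaxError(
                    f"{op} requires at least one argument", self.peek().pos
                )
            children.append(self.parse_bool())
            while self.peek().kind == "comma":
                self.next()
                children.append(self.parse_bool())
            self.expect("rpar")
            if op == "NOT" and len(children) != 1:
                raise ExpressionSyntaxError(
                    "NOT takes exactly one argument", tok.pos
                )
            return Logical(op=op, children=tuple(children))
        return self.parse_relation()

    def parse_relation(self) -> Relation:
        left = self.parse_arith()
        tok = self.next()
        if tok.kind != "relop":
            raise ExpressionSyntaxError(
                f"expected a relational operator, found {tok.value!r}", tok.pos
            )
        right = self.parse_arith()
        return Relation(op=tok.value, left=left, right=right)

    def parse_arith(self) -> NumericNode:
        node = self.parse_term()
        while self.peek().kind in ("plus", "minus"):
            op = self.next()
            rhs = self.parse_term()
            node = Arith(op=op.value if op.kind == "minus" else "+", left=node, right=rhs)
        return node

    def parse_term(self) -> NumericNode:
        tok = self.next()
        if tok.kind == "number":
            return Literal(float(tok.value))
        if tok.kind == "word":
            word = tok.value.upper()
            if word != "DISTANCE":
                raise ExpressionVocabularyError(
                    f"unknown operator {tok.value!r} at position {tok.pos}"
                )
            self.expect("colon")
            a = self._atom_name()
            b = a
            if self.peek().kind == "semi":
                self.next()
                b = self._atom_name()
            return Distance(center_atom=a, candidate_atom=b)
        raise ExpressionSyntaxError(
            f"expected a DISTANCE term or number, found {tok.value!r}", tok.pos
        )

    def _atom_name(self) -> str:
        tok = self.next()
        if tok.kind not in ("word", "number"):
            raise ExpressionSyntaxError(
                f"expected an atom name, found {tok.value!r}", tok.pos
            )
        return tok.value.upper()


def parse_expression(text: str) -> ContactExpression:
    """Parse ``text`` into a :class:`ContactExpression`.

    Both ASCII (``<=``) and Unicode (``≤``) relations are accepted; the
    canonical rendering (:attr:`ContactExpression.text`) uses ASCII.
    """
    if not text or not text.strip():
        raise ExpressionSyntaxError("empty expression", 0)
    parser = _Parser(text)
    root = parser.parse_bool()
    tail = parser.peek()
    if tail.kind != "end":
        raise ExpressionSyntaxError(
            f"unexpected trailing input {tail.value!r}", tail.pos
        )
    return ContactExpression(root=root)


# --- evaluation ------------------------------------------------------------

def _resolve(residue: Residue, spec: str, cbx_extension: float) -> np.ndarray:
    try:
        return virtual_atom(residue, spec, cbx_extension=cbx_extension)
    except VirtualAtomError as exc:
        raise EvaluationError(str(exc)) from exc


def _eval_numeric(
    node: NumericNode, center: Residue, candidate: Residue, cbx_extension: float
) -> float:
    if isinstance(node, Literal):
        return node.value
    if isinstance(node, Distance):
        a = _resolve(center, node.center_atom, cbx_extension)
        b = _resolve(candidate, node.candidate_atom, cbx_extension)
        return float(np.linalg.norm(a - b))
    if isinstance(node, Arith):
        lhs = _eval_numeric(node.left, center, candidate, cbx_extension)
        rhs = _eval_numeric(node.right, center, candidate, cbx_extension)
        return lhs + rhs if node.op == "+" else lhs - rhs
    raise TypeError(f"unknown numeric node {node!r}")


def _eval_bool(
    node: BoolNode, center: Residue, candidate: Residue, cbx_extension: float
) -> bool:
    if isinstance(node, Relation):
        lhs = _eval_numeric(node.left, center, candidate, cbx_extension)
        rhs = _eval_numeric(node.right, center, candidate, cbx_extension)
        if node.op == "<":
            return lhs < rhs
        if node.op == "<=":
            return lhs <= rhs
        if node.op == "=":
            return math.isclose(lhs, rhs, rel_tol=0.0, abs_tol=EQ_TOLERANCE)
        if node.op == ">=":
            return lhs >= rhs
        if node.op == ">":
            return lhs > rhs
        raise ValueError(f"unknown relation {node.op!r}")
    if isinstance(node, Logical):
        if node.op == "OR":
            return any(
                _eval_bool(c, center, candidate, cbx_extension) for c in node.children
            )
        if node.op == "AND":
            return all(
                _eval_bool(c, center, candidate, cbx_extension) for c in node.children
            )
        if node.op == "NOT":
            return not _eval_bool(node.children[0], center, candidate, cbx_extension)
    raise TypeError(f"unknown boolean node {node!r}")


def evaluate(
    expr: ContactExpression,
    center: Residue,
    candidate: Residue,
    cbx_extension: float = 1.5,
) -> bool:
    """Evaluate the contact expression for a (centre, candidate) pair."""
    return _eval_bool(expr.root, center, candidate, cbx_extension)


#: The contact expression used throughout the literature for SCGC-based
#: contact detection; the package default for descriptor identification.
DEFAULT_EXPRESSION_TEXT = (
    "OR(DISTANCE:SCGC <= 6.5, "
    "AND(DISTANCE:SCGC <= DISTANCE:CA - 0.75, DISTANCE:SCGC <= 8.0))"
)


def default_expression() -> ContactExpression:
    return parse_expression(DEFAULT_EXPRESSION_TEXT)
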