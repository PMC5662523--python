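"""Molecule search query language: grammar, evaluator, linear-scan search.

Grammar (AND binds tighter than OR; keywords case-insensitive)::

    expr       := term (OR term)*
    term       := factor (AND factor)*
    factor     := '(' expr ')' | comparison | bareword
    comparison := field op literal

Numeric fields ``mass``, ``atomCount``, ``heavyAtomCount`` support
``< <= > >= = !=``; string fields ``name``, ``inchi``, ``inchikey``,
``formula`` support ``=`` (case-insensitive exact) and ``~``
(case-insensitive substring). A bareword desugars to ``name ~ bareword``.
A comparison against a missing optional field is false. Numeric comparisons
are exact on floats; use ranges like ``mass>17 and mass<19``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Iterable, Union

from .model import Molecule

NUMERIC_FIELDS: dict[str, Callable[[Molecule], float]] = {
    "mass": lambda m: m.molecular_mass(),
    "atomcount": lambda m: float(m.atom_count),
    "heavyatomcount": lambda m: float(m.heavy_atom_count()),
}

STRING_FIELDS: dict[str, Callable[[Molecule], str | None]] = {
    "name": lambda m: m.name,
    "inchi": lambda m: m.inchi,
    "inchikey": lambda m: m.inchikey,
    "formula": lambda m: m.hill_formula(),
}

_CANONICAL_FIELD = {
    "mass": "mass",
    "atomcount": "atomCount",
    "heavyatomcount": "heavyAtomCount",
    "name": "name",
    "inchi": "inchi",
    "inchikey": "inchikey",
    "formula": "formula",
}

NUMERIC_OPS = ("<=", ">=", "!=", "<", ">", "=")
STRING_OPS = ("=", "~")


class QuerySyntaxError(ValueError):
    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class Comparison:
    field: str  # canonical spelling, e.g. "heavyAtomCount"
    op: str
    literal: Union[float, str]


@dataclass(frozen=True)
class And:
    left: "Node"
    right: "Node"


@dataclass(frozen=True)
class Or:
    left: "Node"
    right: "Node"


Node = Union[Comparison, And, Or]

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<lpar>\()|(?P<rpar>\))|(?P<op><=|>=|!=|<|>|=|~)"
    r"|(?P<word>[^\s()<>=!~]+))"
)


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None or m.end() == pos:
            raise QuerySyntaxError(f"unexpected character {text[pos]!r}", pos)
        for kind in ("lpar", "rpar", "op", "word"):
            val = m.group(kind)
            if val is not None:
                tokens.append((kind, val, m.start(kind)))
                break
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.pos = 0

    def peek(self) -> tuple[str, str, int] | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> tuple[str, str, int]:
        tok = self.peek()
        if tok is None:
            raise QuerySyntaxError("unexpected end of query", len(self.text))
        self.pos += 1
        return tok

    def parse(self) -> Node:
        node = self.expr()
        tok = self.peek()
        if tok is not None:
            raise QuerySyntaxError(f"unexpected token {tok[1]!r}", tok[2])
        return node

    def expr(self) -> Node:
        node = self.term()
        while self._keyword("or"):
            node = Or(node, self.term())
        return node

    def term(self) -> Node:
        node = self.factor()
        while self._keyword("and"):
            node = And(node, self.factor())
        return node

    def _keyword(self, word: str) -> bool:
        tok = self.peek()
        if tok is not None and tok[0] == "word" and tok[1].lower() == word:
            self.pos += 1
            return True
        return False

    def factor(self) -> Node:
        tok = self.next()
        kind, value, position = tok
        if kind == "lpar":
            node = self.expr()
            closing = self.next()
            if closing[0] != "rpar":
                raise QuerySyntaxError("expected ')'", closing[2])
            return node
        if kind != "word":
            raise QuerySyntaxError(f"unexpected token {value!r}", position)
        follow = self.peek()
        if follow is None or follow[0] != "op":
            # bareword: substring match on name
            return Comparison("name", "~", value)
        _, op, op_pos = self.next()
        lit_tok = self.next()
        if lit_tok[0] != "word":
            raise QuerySyntaxError(f"expected literal, got {lit_tok[1]!r}", lit_tok[2])
        return self._comparison(value, op, lit_tok[1], position, op_pos)

    def _comparison(
        self, field: str, op: str, literal: str, field_pos: int, op_pos: int
    ) -> Comparison:
        key = field.lower()
        if key in NUMERIC_FIELDS:
            if op not in NUMERIC_OPS:
                raise QuerySyntaxError(
                    f"operator {op!r} not valid for numeric field {field!r}", op_pos
                )
            try:
                value = float(literal)
            except ValueError:
                raise QuerySyntaxError(
                    f"numeric field {field!r} compared to non-number {literal!r}",
                    op_pos,
                ) from None
            return Comparison(_CANONICAL_FIELD[key], op, value)
        if key in STRING_FIELDS:
            if op not in STRING_OPS:
                raise QuerySyntaxError(
                    f"operator {op!r} not valid for string field {field!r}", op_pos
                )
            return Comparison(_CANONICAL_FIELD[key], op, literal)
        raise QuerySyntaxError(f"unknown field {field!r}", field_pos)


def parse_query(text: str) -> Node:
    """Parse query text into an AST. Raises :class:`QuerySyntaxError`."""
    if not text.strip():
        raise QuerySyntaxError("empty query", 0)
    return _Parser(text).parse()


def evaluate(ast: Node, mol: Molecule) -> bool:
    """Evaluate an AST against one molecule's derived fields."""
    if isinstance(ast, And):
        return evaluate(ast.left, mol) and evaluate(ast.right, mol)
    if isinstance(ast, Or):
        return evaluate(ast.left, mol) or evaluate(ast.right, mol)
    key = ast.field.lower()
    if key in NUMERIC_FIELDS:
        actual = NUMERIC_FIELDS[key](mol)
        lit = float(ast.literal)
        return {
            "<": actual < lit,
            "<=": actual <= lit,
            ">": actual > lit,
            ">=": actual >= lit,
            "=": actual == lit,
            "!=": actual != lit,
        }[ast.op]
    actual_str = STRING_FIELDS[key](mol)
    if actual_str is None:
        return False
    lit_str = str(ast.literal).lower()
    if ast.op == "=":
        return actual_str.lower() == lit_str
    return lit_str in actual_str.lower()


def print_query(ast: Node) -> str:
    """Canonical fully-parenthesized text form; parse(print(ast)) == ast."""
    if isinstance(ast, And):
        return f"({print_query(ast.left)} and {print_query(ast.right)})"
    if isinstance(ast, Or):
        return f"({print_query(ast.left)} or {print_query(ast.right)})"
    lit = ast.literal
    if isinstance(lit, float):
        lit_text = repr(lit)
    else:
        lit_text = str(lit)
    return f"{ast.field}{ast.op}{lit_text}"


def search(
    molecules: Iterable[tuple[str, Molecule]], query: str
) -> list[dict[str, str | None]]:
    """Filter (id, molecule) pairs with a query, in input (insertion) order.

    Returns summary records with ``id``, ``inchikey`` and ``name``; an empty
    list when nothing matches.
    """
    ast = parse_query(query)
    return [
        {"id": mol_id, "inchikey": mol.inchikey, "name": mol.name}
        for mol_id, mol in molecules
        if evaluate(ast, mol)
    ]
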