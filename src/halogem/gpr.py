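"""Gene--protein--reaction (GPR) boolean rules.

A GPR rule states which gene combinations enable a reaction: ``and``
joins subunits of a complex (all required), ``or`` joins isozymes (any
suffices).  Grammar: gene identifiers, case-insensitive keywords ``and``
/ ``or``, parentheses; ``and`` binds tighter than ``or``, the de-facto
convention for SBML FBC association strings.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["GPRExpression", "GeneRef", "BoolOp", "GPRParseError", "parse_gpr", "evaluate_gpr"]


class GPRParseError(ValueError):
    """Raised on malformed GPR text; carries the character position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (position {position})")
        self.position = position


class GPRExpression:
    """Base class for nodes of a GPR expression tree."""

    def genes(self) -> set[str]:
        raise NotImplementedError

    def evaluate(self, knocked_out: frozenset[str] | set[str]) -> bool:
        raise NotImplementedError

    def to_string(self) -> str:
        raise NotImplementedError

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GPRExpression) and self.to_string() == other.to_string()

    def __hash__(self) -> int:
        return hash(self.to_string())


@dataclass(eq=False)
class GeneRef(GPRExpression):
    gene: str

    def genes(self) -> set[str]:
        return {self.gene}

    def evaluate(self, knocked_out) -> bool:
        return self.gene not in knocked_out

    def to_string(self) -> str:
        return self.gene


@dataclass(eq=False)
class BoolOp(GPRExpression):
    op: str  # "and" | "or"
    children: list[GPRExpression]

    def __post_init__(self) -> None:
        if self.op not in ("and", "or"):
            raise ValueError(f"unknown operator {self.op!r}")
        if len(self.children) < 2:
            raise ValueError("boolean node needs at least two children")

    def genes(self) -> set[str]:
        out: set[str] = set()
        for child in self.children:
            out |= child.genes()
        return out

    def evaluate(self, knocked_out) -> bool:
        if self.op == "and":
            return all(c.evaluate(knocked_out) for c in self.children)
        return any(c.evaluate(knocked_out) for c in self.children)

    def to_string(self) -> str:
        parts = []
        for child in self.children:
            text = child.to_string()
            # an OR child under AND needs parentheses; AND under OR does not
            if self.op == "and" and isinstance(child, BoolOp) and child.op == "or":
                text = f"({text})"
            parts.append(text)
        return f" {self.op} ".join(parts)


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens: list[tuple[str, str, int]] = []
    i = 0
    n = len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if ch in "()":
            tokens.append(("paren", ch, i))
            i += 1
            continue
        j = i
        while j < n and not text[j].isspace() and text[j] not in "()":
            j += 1
        word = text[i:j]
        low = word.lower()
        if low in ("and", "or"):
            tokens.append(("op", low, i))
        elif low in ("&", "&&"):
            tokens.append(("op", "and", i))
        elif low in ("|", "||"):
            tokens.append(("op", "or", i))
        else:
            tokens.append(("id", word, i))
        i = j
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
            raise GPRParseError("unexpected end of expression", len(self.text))
        self.pos += 1
        return tok

    # expr := term ("or" term)* ; term := factor ("and" factor)*
    def parse_expr(self) -> GPRExpression:
        children = [self.parse_term()]
        while True:
            tok = self.peek()
            if tok and tok[0] == "op" and tok[1] == "or":
                self.next()
                children.append(self.parse_term())
            else:
                break
        return children[0] if len(children) == 1 else BoolOp("or", children)

    def parse_term(self) -> GPRExpression:
        children = [self.parse_factor()]
        while True:
            tok = self.peek()
            if tok and tok[0] == "op" and tok[1] == "and":
                self.next()
                children.append(self.parse_factor())
            else:
                break
        return children[0] if len(children) == 1 else BoolOp("and", children)

    def parse_factor(self) -> GPRExpression:
        kind, value, pos = self.next()
        if kind == "id":
            return GeneRef(value)
        if kind == "paren" and value == "(":
            inner = self.parse_expr()
            tok = self.peek()
            if tok is None or tok[1] != ")":
                raise GPRParseError("unbalanced parenthesis", pos)
            self.next()
            return inner
        raise GPRParseError(f"unexpected token {value!r}", pos)


def parse_gpr(text: str) -> GPRExpression | None:
    """Parse a GPR string into an expression tree.

    Empty or whitespace-only text parses to ``None`` (no gene
    association).  Parse--serialize--parse is a fixpoint: the normalized
    string of the returned tree re-parses to an equal tree.
    """
    if text is None or not text.strip():
        return None
    parser = _Parser(text)
    expr = parser.parse_expr()
    trailing = parser.peek()
    if trailing is not None:
        raise GPRParseError(f"unexpected trailing token {trailing[1]!r}", trailing[2])
    return expr


def evaluate_gpr(expr: GPRExpression | None, knocked_out: set[str]) -> bool:
    """True when the reaction remains catalyzable after the knockouts.

    Reactions with no GPR (``expr is None``) are unaffected by any
    knockout.
    """
    if expr is None:
        return True
    return expr.evaluate(frozenset(knocked_out))
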