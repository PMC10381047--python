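"""Tokenizer, AST and recursive-descent parser for LPhy scripts.

An LPhy script is a sequence of semicolon-terminated statements, optionally
grouped into ``data { ... }`` and ``model { ... }`` blocks.  Each statement
binds a case-sensitive variable name with either ``=`` (constant or
deterministic value) or ``~`` (a draw from a generative distribution).
Control flow is deliberately absent from the language: repetition is
expressed through vectorization, never loops, so ``for``/``while``/``if``
are rejected at parse time.

Identifiers may contain any Unicode letter, so Greek symbols (Θ, ψ, κ, π)
are legal variable names and distinct from their ASCII spellings.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import ParseError

__all__ = [
    "Literal",
    "VariableRef",
    "ArrayLiteral",
    "Range",
    "GeneratorCall",
    "MethodCall",
    "BinaryOp",
    "UnaryOp",
    "Statement",
    "ScriptAST",
    "parse_script",
    "parse_expression",
    "unparse",
]

_CONTROL_FLOW = {"for", "while", "if", "else", "do"}
_BLOCK_KEYWORDS = {"data", "model"}

_TOKEN_RE = re.compile(
    r"""
    (?P<WS>[ \t\r]+)
  | (?P<NEWLINE>\n)
  | (?P<COMMENT>//[^\n]*)
  | (?P<FLOAT>(\d+\.\d*|\.\d+)([eE][+-]?\d+)?|\d+[eE][+-]?\d+)
  | (?P<INT>\d+)
  | (?P<STRING>"(?:[^"\\\n]|\\.)*")
  | (?P<IDENT>[^\W\d]\w*)
  | (?P<OP>[=~;,(){}\[\]:.+\-*/])
    """,
    re.VERBOSE | re.UNICODE,
)


@dataclass
class Token:
    kind: str
    text: str
    line: int
    column: int


def tokenize(text: str) -> list[Token]:
    tokens: list[Token] = []
    line, col = 1, 1
    pos = 0
    n = len(text)
    while pos < n:
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise ParseError(f"unexpected character {text[pos]!r}", line, col)
        kind = m.lastgroup
        tok = m.group()
        if kind == "NEWLINE":
            line += 1
            col = 1
        elif kind in ("WS", "COMMENT"):
            col += len(tok)
        else:
            tokens.append(Token(kind, tok, line, col))
            col += len(tok)
        pos = m.end()
    tokens.append(Token("EOF", "", line, col))
    return tokens


# ---------------------------------------------------------------------------
# AST node types.  `text` fields preserve the source spelling of literals so
# downstream consumers (the narrative generator) can echo numbers exactly as
# the modeller wrote them; they do not participate in structural equality.
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Literal:
    value: object  # int | float | bool | str
    text: str = field(default="", compare=False)


@dataclass(frozen=True)
class VariableRef:
    name: str


@dataclass(frozen=True)
class ArrayLiteral:
    elements: tuple


@dataclass(frozen=True)
class Range:
    lo: object
    hi: object


@dataclass(frozen=True)
class GeneratorCall:
    name: str
    args: tuple  # ordered ((argname, Expression), ...); all arguments named


@dataclass(frozen=True)
class MethodCall:
    target: object
    method: str
    args: tuple


@dataclass(frozen=True)
class BinaryOp:
    op: str
    left: object
    right: object


@dataclass(frozen=True)
class UnaryOp:
    op: str
    operand: object


@dataclass(frozen=True)
class Statement:
    lhs: str
    op: str  # "constant_assign" (=) | "stochastic_assign" (~)
    rhs: object


@dataclass(frozen=True)
class ScriptAST:
    data_statements: tuple = ()
    model_statements: tuple = ()


class _Parser:
    def __init__(self, tokens: list[Token]):
        self.tokens = tokens
        self.i = 0

    # -- token helpers ----------------------------------------------------
    @property
    def cur(self) -> Token:
        return self.tokens[self.i]

    def advance(self) -> Token:
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def expect(self, text: str, what: str | None = None) -> Token:
        tok = self.cur
        if tok.text != text or tok.kind == "EOF":
            msg = what or f"expected {text!r}"
            if tok.kind == "EOF":
                raise ParseError(f"{msg}, found end of input", tok.line, tok.column)
            raise ParseError(f"{msg}, found {tok.text!r}", tok.line, tok.column)
        return self.advance()

    def err(self, message: str) -> ParseError:
        return ParseError(message, self.cur.line, self.cur.column)

    # -- script structure -------------------------------------------------
    def parse_script(self) -> ScriptAST:
        data: list[Statement] = []
        model: list[Statement] = []
        seen_blocks = False
        while self.cur.kind != "EOF":
            tok = self.cur
            if tok.kind == "IDENT" and tok.text in _BLOCK_KEYWORDS and self._peek_is("{"):
                seen_blocks = True
                self.advance()
                self.expect("{")
                stmts = self.parse_statements(stop="}")
                self.expect("}", "unmatched '{': expected '}'")
                (data if tok.text == "data" else model).extend(stmts)
            else:
                # console-style snippet: bare statements go to the model block
                if seen_blocks and tok.text not in _BLOCK_KEYWORDS:
                    pass  # bare statements after a block are still accepted
                model.append(self.parse_statement())
        return ScriptAST(tuple(data), tuple(model))

    def _peek_is(self, text: str) -> bool:
        j = self.i + 1
        return j < len(self.tokens) and self.tokens[j].text == text

    def parse_statements(self, stop: str) -> list[Statement]:
        out = []
        while self.cur.kind != "EOF" and self.cur.text != stop:
            out.append(self.parse_statement())
        return out

    def parse_statement(self) -> Statement:
        tok = self.cur
        if tok.kind != "IDENT":
            raise self.err(f"expected a variable name, found {tok.text!r}")
        if tok.text in _CONTROL_FLOW:
            raise self.err("Control flow structures are not allowed")
        lhs = self.advance().text
        op_tok = self.cur
        if op_tok.text == "=":
            op = "constant_assign"
        elif op_tok.text == "~":
            op = "stochastic_assign"
        else:
            raise self.err(f"expected '=' or '~' after {lhs!r}, found {op_tok.text!r}")
        self.advance()
        rhs = self.parse_expr()
        self.expect(";", "missing ';' at end of statement")
        return Statement(lhs, op, rhs)

    # -- expressions ------------------------------------------------------
    def parse_expr(self):
        left = self.parse_additive()
        if self.cur.text == ":":
            self.advance()
            right = self.parse_additive()
            return Range(left, right)
        return left

    def parse_additive(self):
        node = self.parse_multiplicative()
        while self.cur.text in ("+", "-"):
            op = self.advance().text
            node = BinaryOp(op, node, self.parse_multiplicative())
        return node

    def parse_multiplicative(self):
        node = self.parse_unary()
        while self.cur.text in ("*", "/"):
            op = self.advance().text
            node = BinaryOp(op, node, self.parse_unary())
        return node

    def parse_unary(self):
        if self.cur.text == "-":
            self.advance()
            return UnaryOp("-", self.parse_unary())
        return self.parse_postfix()

    def parse_postfix(self):
        node = self.parse_primary()
        while self.cur.text == ".":
            # dotted call: var.method(args)
            nxt = self.tokens[self.i + 1] if self.i + 1 < len(self.tokens) else None
            if nxt is None or nxt.kind != "IDENT":
                raise self.err("expected a method name after '.'")
            self.advance()
            method = self.advance().text
            self.expect("(", f"expected '(' after method name {method!r}")
            args = self.parse_args()
            self.expect(")", "unmatched '(': expected ')'")
            node = MethodCall(node, method, args)
        return node

    def parse_primary(self):
        tok = self.cur
        if tok.kind == "FLOAT":
            self.advance()
            return Literal(float(tok.text), tok.text)
        if tok.kind == "INT":
            self.advance()
            return Literal(int(tok.text), tok.text)
        if tok.kind == "STRING":
            self.advance()
            raw = tok.text[1:-1]
            return Literal(raw.replace('\\"', '"').replace("\\\\", "\\"), tok.text)
        if tok.text == "[":
            self.advance()
            elements = []
            if self.cur.text != "]":
                elements.append(self.parse_expr())
                while self.cur.text == ",":
                    self.advance()
                    elements.append(self.parse_expr())
            self.expect("]", "unmatched '[': expected ']'")
            return ArrayLiteral(tuple(elements))
        if tok.text == "(":
            self.advance()
            inner = self.parse_expr()
            self.expect(")", "unmatched '(': expected ')'")
            return inner
        if tok.kind == "IDENT":
            if tok.text in _CONTROL_FLOW:
                raise self.err("Control flow structures are not allowed")
            if tok.text == "true":
                self.advance()
                return Literal(True, "true")
            if tok.text == "false":
                self.advance()
                return Literal(False, "false")
            name = self.advance().text
            if self.cur.text == "(":
                self.advance()
                args = self.parse_args()
                self.expect(")", "unmatched '(': expected ')'")
                return GeneratorCall(name, args)
            return VariableRef(name)
        raise self.err(f"unexpected token {tok.text!r} in expression")

    def parse_args(self) -> tuple:
        args: list[tuple[str, object]] = []
        if self.cur.text == ")":
            return ()
        while True:
            tok = self.cur
            if tok.kind == "IDENT" and self._peek_is("="):
                name = self.advance().text
                self.advance()  # '='
                value = self.parse_expr()
                if any(n == name for n, _ in args):
                    raise ParseError(f"duplicate argument {name!r}", tok.line, tok.column)
                args.append((name, value))
            else:
                raise ParseError(
                    "arguments must be named (use 'name = value')", tok.line, tok.column
                )
            if self.cur.text == ",":
                self.advance()
                continue
            break
        return tuple(args)


def parse_script(text: str) -> ScriptAST:
    """Parse a full LPhy script into a :class:`ScriptAST`.

    Statements outside any block are treated as model-block statements, so
    console-style snippets parse without ceremony.
    """
    parser = _Parser(tokenize(text))
    return parser.parse_script()


def parse_expression(text: str):
    """Parse a single LPhy expression."""
    parser = _Parser(tokenize(text))
    expr = parser.parse_expr()
    if parser.cur.kind != "EOF":
        raise parser.err(f"unexpected trailing input {parser.cur.text!r}")
    return expr


# ---------------------------------------------------------------------------
# Pretty-printer (inverse of the parser up to whitespace and comments)
# ---------------------------------------------------------------------------


def _fmt_literal(lit: Literal) -> str:
    if isinstance(lit.value, bool):
        return "true" if lit.value else "false"
    if isinstance(lit.value, str):
        escaped = lit.value.replace("\\", "\\\\").replace('"', '\\"')
        return f'"{escaped}"'
    if lit.text:
        return lit.text
    return repr(lit.value)


def unparse(node) -> str:
    """Render an AST node (expression, statement or script) back to source."""
    if isinstance(node, Literal):
        return _fmt_literal(node)
    if isinstance(node, VariableRef):
        return node.name
    if isinstance(node, ArrayLiteral):
        return "[" + ", ".join(unparse(e) for e in node.elements) + "]"
    if isinstance(node, Range):
        return f"{unparse(node.lo)}:{unparse(node.hi)}"
    if isinstance(node, GeneratorCall):
        args = ", ".join(f"{n}={unparse(v)}" for n, v in node.args)
        return f"{node.name}({args})"
    if isinstance(node, MethodCall):
        args = ", ".join(f"{n}={unparse(v)}" for n, v in node.args)
        return f"{unparse(node.target)}.{node.method}({args})"
    if isinstance(node, BinaryOp):
        return f"({unparse(node.left)} {node.op} {unparse(node.right)})"
    if isinstance(node, UnaryOp):
        return f"{node.op}{unparse(node.operand)}"
    if isinstance(node, Statement):
        op = "=" if node.op == "constant_assign" else "~"
        return f"{node.lhs} {op} {unparse(node.rhs)};"
    if isinstance(node, ScriptAST):
        parts = []
        if node.data_statements:
            body = "\n".join("  " + unparse(s) for s in node.data_statements)
            parts.append("data {\n" + body + "\n}")
        body = "\n".join("  " + unparse(s) for s in node.model_statements)
        parts.append("model {\n" + body + "\n}")
        return "\n".join(parts) + "\n"
    raise TypeError(f"cannot unparse {type(node).__name__}")
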