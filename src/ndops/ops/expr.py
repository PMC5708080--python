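"""Expression evaluation for the eval op and the built-in script language.

Grammar (EBNF; see also docs/eval.md):

    expr    = term { ("+" | "-") term } ;
    term    = factor { ("*" | "/") factor } ;
    factor  = "-" factor | postfix ;
    postfix = primary [ "(" [ expr { "," expr } ] ")" ] ;
    primary = NUMBER | STRING | IDENT | "(" expr ")" ;

Binary operators are left-associative with standard precedence and dispatch
through the op-matching engine (``math.add`` and friends), so the same
expression works on scalars and on images. ``+`` on strings concatenates,
rendering non-string operands canonically. Calls ``name(args...)`` resolve
``name`` (dotted or a registered alias) through the op registry.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from ..containers import Dataset, Image
from ..errors import ParseError, UnboundIdentifierError

_TOKEN_RE = re.compile(r"""
    (?P<ws>\s+)
  | (?P<number>\d+\.\d*(?:[eE][+-]?\d+)?|\.\d+(?:[eE][+-]?\d+)?|\d+(?:[eE][+-]?\d+)?)
  | (?P<ident>[A-Za-z_][A-Za-z_0-9]*(?:\.[A-Za-z_][A-Za-z_0-9]*)*)
  | (?P<string>"(?:\\.|[^"\\])*")
  | (?P<punct>[-+*/(),])
""", re.VERBOSE)

_BINARY_OPS = {"+": "math.add", "-": "math.sub",
               "*": "math.mul", "/": "math.div"}


@dataclass(frozen=True)
class Token:
    kind: str
    text: str
    pos: int


def tokenize(expr: str) -> list[Token]:
    tokens = []
    pos = 0
    while pos < len(expr):
        m = _TOKEN_RE.match(expr, pos)
        if m is None:
            raise ParseError(f"unexpected character {expr[pos]!r}", position=pos)
        kind = m.lastgroup
        if kind != "ws":
            tokens.append(Token(kind, m.group(), pos))
        pos = m.end()
    tokens.append(Token("end", "", len(expr)))
    return tokens


# AST nodes: ("num", value) ("str", value) ("ident", name)
# ("call", name, args) ("neg", node) ("bin", opchar, left, right)


class _Parser:
    def __init__(self, expr: str):
        self.tokens = tokenize(expr)
        self.i = 0

    def peek(self) -> Token:
        return self.tokens[self.i]

    def take(self) -> Token:
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def expect(self, text: str) -> Token:
        tok = self.take()
        if tok.text != text:
            raise ParseError(f"expected {text!r}, found {tok.text or 'end'!r}",
                             position=tok.pos)
        return tok

    def parse(self):
        node = self.expr()
        tok = self.peek()
        if tok.kind != "end":
            raise ParseError(f"unexpected trailing {tok.text!r}",
                             position=tok.pos)
        return node

    def expr(self):
        node = self.term()
        while self.peek().text in ("+", "-"):
            op = self.take().text
            node = ("bin", op, node, self.term())
        return node

    def term(self):
        node = self.factor()
        while self.peek().text in ("*", "/"):
            op = self.take().text
            node = ("bin", op, node, self.factor())
        return node

    def factor(self):
        if self.peek().text == "-":
            self.take()
            return ("neg", self.factor())
        return self.postfix()

    def postfix(self):
        tok = self.take()
        if tok.kind == "number":
            text = tok.text
            value = float(text) if any(c in text for c in ".eE") else int(text)
            return ("num", value)
        if tok.kind == "string":
            body = tok.text[1:-1]
            return ("str", body.replace('\\"', '"').replace("\\\\", "\\")
                    .replace("\\n", "\n").replace("\\t", "\t"))
        if tok.kind == "ident":
            if self.peek().text == "(":
                self.take()
                args = []
                if self.peek().text != ")":
                    args.append(self.expr())
                    while self.peek().text == ",":
                        self.take()
                        args.append(self.expr())
                self.expect(")")
                return ("call", tok.text, args)
            return ("ident", tok.text)
        if tok.text == "(":
            node = self.expr()
            self.expect(")")
            return node
        raise ParseError(f"unexpected {tok.text or 'end of expression'!r}",
                         position=tok.pos)


def parse(expr: str):
    return _Parser(expr).parse()


def render(value) -> str:
    """Canonical textual rendering of a value (CLI echo, concatenation)."""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float) and value.is_integer() and abs(value) < 1e15:
        return str(int(value))
    if isinstance(value, Dataset):
        img = value.image
        label = value.name or "dataset"
        return (f"{label} <{img.sample_type.name} "
                f"{'x'.join(map(str, img.shape))}>")
    if isinstance(value, Image):
        return (f"image <{value.sample_type.name} "
                f"{'x'.join(map(str, value.shape))}>")
    return str(value)


def _eval_node(ctx, node, env):
    kind = node[0]
    if kind == "num" or kind == "str":
        return node[1]
    if kind == "ident":
        name = node[1]
        if name not in env:
            raise UnboundIdentifierError(f"unbound identifier {name!r}")
        return env[name]
    if kind == "neg":
        value = _eval_node(ctx, node[1], env)
        if isinstance(value, Image):
            return ctx.ops.run("math.mul", value, -1.0)
        return -value
    if kind == "call":
        _, name, arg_nodes = node
        args = [_eval_node(ctx, a, env) for a in arg_nodes]
        return ctx.ops.run(name, *args)
    if kind == "bin":
        _, op, left_node, right_node = node
        left = _eval_node(ctx, left_node, env)
        right = _eval_node(ctx, right_node, env)
        if op == "+" and (isinstance(left, str) or isinstance(right, str)):
            return ((left if isinstance(left, str) else render(left))
                    + (right if isinstance(right, str) else render(right)))
        return ctx.ops.run(_BINARY_OPS[op], left, right)
    raise ParseError(f"unknown AST node {kind!r}")


def evaluate(ctx, expr: str, bindings: dict | None = None):
    """Parse and evaluate ``expr`` with identifier bindings, dispatching
    operators and calls through the op registry."""
    return _eval_node(ctx, parse(expr), dict(bindings or {}))
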