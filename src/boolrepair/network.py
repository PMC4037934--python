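"""Boolean networks with logical update rules.

A network is a list of named nodes, each carrying an update function given as
a logical expression (AND/OR/NOT over node literals and the constants 0/1).
The state of an N-node network is a Boolean vector of length N in *canonical
order* — the order in which the nodes were declared in the rule file.

Rule files contain one ``NODE = expression`` line per node (``NODE* = expr``
is accepted as a synonym).  Operator precedence is NOT > AND > OR, with
parentheses overriding; keywords are case-insensitive.  Node names may contain
alphanumerics, ``_`` and ``+`` (e.g. ``Ca2+c``).  Lines starting with ``#``
and blank lines are ignored.

Damage (knockout or constitutive expression) is represented by *clamping* a
node: its update function is overridden by a constant, regardless of the
state of its regulators.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping


class RuleParseError(ValueError):
    """Raised when a rule file or expression cannot be parsed."""


class NetworkError(ValueError):
    """Raised for structurally invalid networks or states."""


# ---------------------------------------------------------------------------
# Expression trees
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Expr:
    """Base class for logical expression nodes."""


@dataclass(frozen=True)
class Const(Expr):
    value: int


@dataclass(frozen=True)
class Var(Expr):
    name: str


@dataclass(frozen=True)
class Not(Expr):
    operand: Expr


@dataclass(frozen=True)
class And(Expr):
    left: Expr
    right: Expr


@dataclass(frozen=True)
class Or(Expr):
    left: Expr
    right: Expr


def evaluate_expr(expr: Expr, env: Mapping[str, int]) -> int:
    """Evaluate ``expr`` under a name -> bit environment."""
    if isinstance(expr, Const):
        return expr.value
    if isinstance(expr, Var):
        try:
            return env[expr.name]
        except KeyError:
            raise NetworkError(f"no value supplied for regulator {expr.name!r}")
    if isinstance(expr, Not):
        return 1 - evaluate_expr(expr.operand, env)
    if isinstance(expr, And):
        return evaluate_expr(expr.left, env) and evaluate_expr(expr.right, env)
    if isinstance(expr, Or):
        return evaluate_expr(expr.left, env) or evaluate_expr(expr.right, env)
    raise TypeError(f"unknown expression node {expr!r}")


def expr_variables(expr: Expr) -> tuple[str, ...]:
    """Names of node literals in ``expr``, in first-appearance order."""
    seen: dict[str, None] = {}

    def walk(e: Expr) -> None:
        if isinstance(e, Var):
            seen.setdefault(e.name)
        elif isinstance(e, Not):
            walk(e.operand)
        elif isinstance(e, (And, Or)):
            walk(e.left)
            walk(e.right)

    walk(expr)
    return tuple(seen)


_PREC = {Or: 1, And: 2, Not: 3, Var: 4, Const: 4}


def expr_to_text(expr: Expr) -> str:
    """Render an expression with minimal parentheses (NOT > AND > OR)."""

    def render(e: Expr, parent_prec: int) -> str:
        prec = _PREC[type(e)]
        if isinstance(e, Const):
            s = str(e.value)
        elif isinstance(e, Var):
            s = e.name
        elif isinstance(e, Not):
            s = f"not {render(e.operand, prec)}"
        elif isinstance(e, And):
            s = f"{render(e.left, prec)} and {render(e.right, prec)}"
        else:
            s = f"{render(e.left, prec)} or {render(e.right, prec)}"
        if prec < parent_prec:
            return f"({s})"
        return s

    return render(expr, 0)


# -- parser ------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\s*(\(|\)|[A-Za-z0-9_+]+)")
_KEYWORDS = {"and", "or", "not"}
_CONSTS = {"0": 0, "1": 1, "false": 0, "true": 1}


def _tokenize(text: str) -> list[str]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            if text[pos:].strip():
                raise RuleParseError(
                    f"unexpected character {text[pos:].strip()[0]!r} in {text!r}"
                )
            break
        tokens.append(m.group(1))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, tokens: list[str], source: str):
        self.tokens = tokens
        self.pos = 0
        self.source = source

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise RuleParseError(f"unexpected end of expression in {self.source!r}")
        self.pos += 1
        return tok

    def parse(self) -> Expr:
        e = self.parse_or()
        if self.peek() is not None:
            raise RuleParseError(
                f"trailing token {self.peek()!r} in {self.source!r}"
            )
        return e

    def parse_or(self) -> Expr:
        e = self.parse_and()
        while (tok := self.peek()) is not None and tok.lower() == "or":
            self.next()
            e = Or(e, self.parse_and())
        return e

    def parse_and(self) -> Expr:
        e = self.parse_not()
        while (tok := self.peek()) is not None and tok.lower() == "and":
            self.next()
            e = And(e, self.parse_not())
        return e

    def parse_not(self) -> Expr:
        tok = self.peek()
        if tok is not None and tok.lower() == "not":
            self.next()
            return Not(self.parse_not())
        return self.parse_atom()

    def parse_atom(self) -> Expr:
        tok = self.next()
        if tok == "(":
            e = self.parse_or()
            if self.next() != ")":
                raise RuleParseError(f"unbalanced parentheses in {self.source!r}")
            return e
        if tok == ")":
            raise RuleParseError(f"unexpected ')' in {self.source!r}")
        low = tok.lower()
        if low in _CONSTS:
            return Const(_CONSTS[low])
        if low in _KEYWORDS:
            raise RuleParseError(f"misplaced keyword {tok!r} in {self.source!r}")
        return Var(tok)


def parse_expression(text: str) -> Expr:
    """Parse a single logical expression."""
    tokens = _tokenize(text)
    if not tokens:
        raise RuleParseError("empty expression")
    return _Parser(tokens, text).parse()


# ---------------------------------------------------------------------------
# Update functions, states, networks
# ---------------------------------------------------------------------------

@dataclass
class UpdateFunction:
    """One node's update rule: a logical expression, optionally clamped.

    When ``clamped`` is set (0 or 1) evaluation returns that constant
    regardless of the input state; the original expression is retained so the
    damage can be described and serialized.
    """

    expression: Expr
    clamped: int | None = None
    _regulators: tuple[str, ...] | None = field(
        default=None, repr=False, compare=False
    )

    @property
    def regulators(self) -> tuple[str, ...]:
        if self._regulators is None:
            object.__setattr__(self, "_regulators", expr_variables(self.expression))
        return self._regulators

    def evaluate(self, env: Mapping[str, int]) -> int:
        if self.clamped is not None:
            return self.clamped
        return evaluate_expr(self.expression, env)

    def truth_table(self) -> tuple[int, ...]:
        """Output bit for each of the 2^k regulator combinations.

        Row index bits follow regulator order, first regulator most
        significant: row ``r`` assigns regulator ``j`` the bit
        ``(r >> (k - 1 - j)) & 1``.
        """
        regs = self.regulators
        k = len(regs)
        rows = []
        for r in range(1 << k):
            env = {regs[j]: (r >> (k - 1 - j)) & 1 for j in range(k)}
            rows.append(self.evaluate(env))
        return tuple(rows)

    def text(self) -> str:
        if self.clamped is not None:
            return str(self.clamped)
        return expr_to_text(self.expression)


@dataclass(frozen=True, order=True)
class NetworkState:
    """A Boolean vector of node states in canonical node order."""

    bits: tuple[int, ...]

    @classmethod
    def from_string(cls, s: str) -> "NetworkState":
        s = s.strip()
        if not s or any(c not in "01" for c in s):
            raise NetworkError(f"invalid state string {s!r}")
        return cls(tuple(int(c) for c in s))

    @classmethod
    def from_int(cls, value: int, n: int) -> "NetworkState":
        return cls(tuple((value >> (n - 1 - i)) & 1 for i in range(n)))

    def to_int(self) -> int:
        v = 0
        for b in self.bits:
            v = (v << 1) | b
        return v

    def __str__(self) -> str:
        return "".join(str(b) for b in self.bits)

    def __len__(self) -> int:
        return len(self.bits)


class BooleanNetwork:
    """Named nodes with logical update functions.

    Canonical node order is declaration order; state strings and bit vectors
    follow it.  Instances are treated as immutable: operations such as
    :meth:`clamp` return new networks.
    """

    def __init__(self, node_names: Iterable[str], functions: Mapping[str, UpdateFunction]):
        self.node_names: list[str] = list(node_names)
        if len(set(self.node_names)) != len(self.node_names):
            raise NetworkError("duplicate node names")
        self.functions: dict[str, UpdateFunction] = dict(functions)
        if set(self.functions) != set(self.node_names):
            raise NetworkError("functions must cover exactly the declared nodes")
        self.index: dict[str, int] = {n: i for i, n in enumerate(self.node_names)}
        for name in self.node_names:
            for reg in self.functions[name].regulators:
                if reg not in self.index:
                    raise RuleParseError(
                        f"rule for {name!r} references undeclared node {reg!r}"
                    )
        self._compiled: list[tuple[tuple[int, ...], tuple[int, ...]]] | None = None

    # -- basics ------------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.node_names)

    def env(self, state: NetworkState) -> dict[str, int]:
        if len(state) != self.n:
            raise NetworkError(
                f"state length {len(state)} != network size {self.n}"
            )
        return dict(zip(self.node_names, state.bits))

    def evaluate_node(self, name: str, state: NetworkState) -> int:
        """Next value of one node from the current full state."""
        return self.functions[name].evaluate(self.env(state))

    def state_from_string(self, s: str) -> NetworkState:
        st = NetworkState.from_string(s)
        if len(st) != self.n:
            raise NetworkError(
                f"state string length {len(st)} != network size {self.n}"
            )
        return st

    @property
    def clamps(self) -> dict[str, int]:
        return {
            n: f.clamped
            for n, f in self.functions.items()
            if f.clamped is not None
        }

    # -- damage ------------------------------------------------------------

    def clamp(self, node: str, value: int) -> "BooleanNetwork":
        """Return a copy with ``node`` forced to the constant ``value``."""
        if node not in self.index:
            raise NetworkError(f"unknown node {node!r}")
        if value not in (0, 1):
            raise NetworkError(f"clamp value must be 0 or 1, got {value!r}")
        funcs = dict(self.functions)
        old = funcs[node]
        funcs[node] = UpdateFunction(old.expression, clamped=value)
        return BooleanNetwork(self.node_names, funcs)

    def with_function(self, node: str, expression: Expr) -> "BooleanNetwork":
        """Return a copy with ``node``'s expression replaced (clamp dropped)."""
        if node not in self.index:
            raise NetworkError(f"unknown node {node!r}")
        funcs = dict(self.functions)
        funcs[node] = UpdateFunction(expression)
        return BooleanNetwork(self.node_names, funcs)

    # -- compiled truth-table view (hot path for simulation) ---------------

    def compiled(self) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
        """Per-node (regulator indices, truth table) pairs.

        Clamped nodes compile to an empty regulator tuple with a single-row
        table holding the clamp constant.
        """
        if self._compiled is None:
            out = []
            for name in self.node_names:
                f = self.functions[name]
                if f.clamped is not None:
                    out.append(((), (f.clamped,)))
                else:
                    regs = tuple(self.index[r] for r in f.regulators)
                    out.append((regs, f.truth_table()))
            self._compiled = out
        return self._compiled

    # -- serialization ------------------------------------------------------

    def serialize(self) -> str:
        """Rule-file text reproducing this network's effective logic."""
        return "\n".join(
            f"{name} = {self.functions[name].text()}" for name in self.node_names
        ) + "\n"

    def to_json(self) -> str:
        return json.dumps(
            {
                "nodes": self.node_names,
                "rules": {
                    n: expr_to_text(self.functions[n].expression)
                    for n in self.node_names
                },
                "clamps": self.clamps,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "BooleanNetwork":
        data = json.loads(text)
        funcs = {}
        for name in data["nodes"]:
            f = UpdateFunction(parse_expression(data["rules"][name]))
            if name in data.get("clamps", {}):
                f = UpdateFunction(f.expression, clamped=int(data["clamps"][name]))
            funcs[name] = f
        return cls(data["nodes"], funcs)


def parse_rules(text: str) -> BooleanNetwork:
    """Parse rule-file content into a :class:`BooleanNetwork`.

    One ``NODE = expression`` per non-comment line; declaration order defines
    the canonical state order.
    """
    names: list[str] = []
    funcs: dict[str, UpdateFunction] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise RuleParseError(f"line {lineno}: expected 'NODE = expr': {raw!r}")
        name, _, rhs = line.partition("=")
        name = name.strip()
        if name.endswith("*"):  # BooleanNet-style "NODE* = expr"
            name = name[:-1].strip()
        if not name or not re.fullmatch(r"[A-Za-z0-9_+]+", name):
            raise RuleParseError(f"line {lineno}: invalid node name {name!r}")
        if name in funcs:
            raise RuleParseError(f"line {lineno}: duplicate node {name!r}")
        if not rhs.strip():
            raise RuleParseError(f"line {lineno}: empty expression for {name!r}")
        try:
            expr = parse_expression(rhs)
        except RuleParseError as exc:
            raise RuleParseError(f"line {lineno}: {exc}") from None
        names.append(name)
        funcs[name] = UpdateFunction(expr)
    if not names:
        raise RuleParseError("no rules found")
    return BooleanNetwork(names, funcs)


def clamp_node(net: BooleanNetwork, node: str, value: int) -> BooleanNetwork:
    """Functional form of :meth:`BooleanNetwork.clamp`."""
    return net.clamp(node, value)
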