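"""Boolean network models in the BoolNet text format.

A Boolean network couples ``n`` named components, each carrying a binary
activity ``x_i(t)``, through regulatory rules ``f_i`` built from AND, OR and
NOT.  This module parses, validates, serialises and generates such models in
the "targets, factors" rule-file dialect of the R package BoolNet:

* header line ``targets, factors``;
* one ``name, expression`` line per component;
* operators ``&`` (AND), ``|`` (OR), ``!`` (NOT), parentheses, constants
  ``0``/``1``; component names match ``[A-Za-z_][A-Za-z0-9_]*``;
* lines starting with ``#`` are comments; surrounding whitespace is ignored.

State encoding convention used throughout the package: component ``i`` (file
order, 0-indexed) is bit ``i`` and qubit ``i``; a network state is the integer
``sum(x_i * 2**i)`` (little-endian).  Two string renderers are provided because
printed state strings are ambiguous without a declared bit order: ``file
order`` puts component 0 leftmost, ``register order`` puts the highest qubit
leftmost (so the string is the plain binary expansion of the integer).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "RuleExpr",
    "Var",
    "Const",
    "Not",
    "And",
    "Or",
    "BooleanNetwork",
    "BoolNetParseError",
    "parse_rules",
    "serialize_rules",
    "truth_table",
    "fixture_cortical",
    "generate_random_network",
    "state_to_string",
    "string_to_state",
]


# ---------------------------------------------------------------------------
# Rule expression trees


class RuleExpr:
    """Base class for Boolean rule expression nodes."""

    def evaluate(self, values: dict[str, int]) -> int:
        raise NotImplementedError

    def evaluate_vector(self, columns: dict[str, np.ndarray]) -> np.ndarray:
        """Evaluate over parallel bit columns (one entry per network state)."""
        raise NotImplementedError

    def variables(self) -> set[str]:
        raise NotImplementedError

    def to_text(self) -> str:
        raise NotImplementedError

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"{type(self).__name__}({self.to_text()!r})"


@dataclass(frozen=True)
class Var(RuleExpr):
    name: str

    def evaluate(self, values):
        return values[self.name]

    def evaluate_vector(self, columns):
        return columns[self.name]

    def variables(self):
        return {self.name}

    def to_text(self):
        return self.name


@dataclass(frozen=True)
class Const(RuleExpr):
    value: int

    def evaluate(self, values):
        return self.value

    def evaluate_vector(self, columns):
        n_states = len(next(iter(columns.values()))) if columns else 1
        return np.full(n_states, self.value, dtype=np.uint8)

    def variables(self):
        return set()

    def to_text(self):
        return str(self.value)


@dataclass(frozen=True)
class Not(RuleExpr):
    operand: RuleExpr

    def evaluate(self, values):
        return 1 - self.operand.evaluate(values)

    def evaluate_vector(self, columns):
        return (1 - self.operand.evaluate_vector(columns)).astype(np.uint8)

    def variables(self):
        return self.operand.variables()

    def to_text(self):
        inner = self.operand.to_text()
        if isinstance(self.operand, (And, Or)):
            return f"!({inner})"
        return f"!{inner}"


@dataclass(frozen=True)
class And(RuleExpr):
    left: RuleExpr
    right: RuleExpr

    def evaluate(self, values):
        return self.left.evaluate(values) & self.right.evaluate(values)

    def evaluate_vector(self, columns):
        return self.left.evaluate_vector(columns) & self.right.evaluate_vector(columns)

    def variables(self):
        return self.left.variables() | self.right.variables()

    def to_text(self):
        parts = []
        for side in (self.left, self.right):
            text = side.to_text()
            if isinstance(side, Or):
                text = f"({text})"
            parts.append(text)
        return " & ".join(parts)


@dataclass(frozen=True)
class Or(RuleExpr):
    left: RuleExpr
    right: RuleExpr

    def evaluate(self, values):
        return self.left.evaluate(values) | self.right.evaluate(values)

    def evaluate_vector(self, columns):
        return self.left.evaluate_vector(columns) | self.right.evaluate_vector(columns)

    def variables(self):
        return self.left.variables() | self.right.variables()

    def to_text(self):
        return f"{self.left.to_text()} | {self.right.to_text()}"


# ---------------------------------------------------------------------------
# Network container


@dataclass(frozen=True)
class BooleanNetwork:
    """Ordered components with one regulatory rule per component.

    ``components[i]`` is bit/qubit ``i``; the rule ``rules[i]`` gives the
    synchronous image of component ``i`` evaluated on the current state.
    """

    components: tuple[str, ...]
    rules: tuple[RuleExpr, ...]

    def __post_init__(self):
        if len(self.components) < 1:
            raise ValueError("network needs at least one component")
        if len(set(self.components)) != len(self.components):
            raise ValueError("component names must be unique")
        if len(self.rules) != len(self.components):
            raise ValueError("need exactly one rule per component")
        declared = set(self.components)
        for name, rule in zip(self.components, self.rules):
            undeclared = rule.variables() - declared
            if undeclared:
                raise ValueError(
                    f"rule for {name!r} references undeclared component(s): "
                    f"{sorted(undeclared)}"
                )

    @property
    def n(self) -> int:
        return len(self.components)

    @property
    def n_states(self) -> int:
        return 1 << self.n

    def index(self, component: str) -> int:
        try:
            return self.components.index(component)
        except ValueError:
            raise KeyError(f"no component named {component!r}") from None

    def state_bits(self, state: int) -> tuple[int, ...]:
        if not 0 <= state < self.n_states:
            raise ValueError(f"state {state} out of range for n={self.n}")
        return tuple((state >> i) & 1 for i in range(self.n))

    def bits_to_state(self, bits: Sequence[int]) -> int:
        if len(bits) != self.n:
            raise ValueError("bit vector length must equal n")
        return sum((int(b) & 1) << i for i, b in enumerate(bits))


# ---------------------------------------------------------------------------
# State string rendering

def state_to_string(state: int, n: int, order: str = "register") -> str:
    """Render a state integer as a bit string.

    ``order="register"`` puts the highest qubit leftmost (the plain binary
    expansion, the little-endian convention of the quantum register);
    ``order="file"`` puts component 0 leftmost.
    """
    if not 0 <= state < (1 << n):
        raise ValueError(f"state {state} out of range for n={n}")
    bits = format(state, f"0{n}b")
    if order == "register":
        return bits
    if order == "file":
        return bits[::-1]
    raise ValueError("order must be 'register' or 'file'")


def string_to_state(s: str, order: str = "register") -> int:
    if not s or set(s) - {"0", "1"}:
        raise ValueError(f"not a bit string: {s!r}")
    if order == "register":
        return int(s, 2)
    if order == "file":
        return int(s[::-1], 2)
    raise ValueError("order must be 'register' or 'file'")


# ---------------------------------------------------------------------------
# Parsing


class BoolNetParseError(ValueError):
    """Raised on malformed rule files; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        prefix = f"line {line}: " if line is not None else ""
        super().__init__(prefix + message)


_NAME_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_]*")
_TOKEN_RE = re.compile(r"\s*([A-Za-z_][A-Za-z0-9_]*|[01()&|!])")


def _tokenize(expr: str, line: int) -> list[str]:
    tokens, pos = [], 0
    while pos < len(expr):
        m = _TOKEN_RE.match(expr, pos)
        if m is None:
            rest = expr[pos:].strip()
            if not rest:
                break
            raise BoolNetParseError(f"unexpected character {rest[0]!r} in rule", line)
        tokens.append(m.group(1))
        pos = m.end()
    return tokens


class _ExprParser:
    """Recursive-descent parser: expr := term ('|' term)*; term := factor
    ('&' factor)*; factor := '!' factor | '(' expr ')' | name | 0 | 1."""

    def __init__(self, tokens: list[str], line: int):
        self.tokens = tokens
        self.pos = 0
        self.line = line

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise BoolNetParseError("unexpected end of rule", self.line)
        self.pos += 1
        return tok

    def parse(self) -> RuleExpr:
        expr = self.expr()
        if self.peek() is not None:
            raise BoolNetParseError(
                f"unexpected token {self.peek()!r} after expression", self.line
            )
        return expr

    def expr(self) -> RuleExpr:
        node = self.term()
        while self.peek() == "|":
            self.next()
            node = Or(node, self.term())
        return node

    def term(self) -> RuleExpr:
        node = self.factor()
        while self.peek() == "&":
            self.next()
            node = And(node, self.factor())
        return node

    def factor(self) -> RuleExpr:
        tok = self.next()
        if tok == "!":
            return Not(self.factor())
        if tok == "(":
            node = self.expr()
            if self.peek() != ")":
                raise BoolNetParseError("unbalanced parentheses", self.line)
            self.next()
            return node
        if tok in ("0", "1"):
            return Const(int(tok))
        if _NAME_RE.fullmatch(tok):
            return Var(tok)
        raise BoolNetParseError(f"unexpected token {tok!r}", self.line)


def parse_rules(text: str) -> BooleanNetwork:
    """Parse BoolNet "targets, factors" rule text into a network.

    Component order equals the order of target lines in the file.  Raises
    :class:`BoolNetParseError` (with the offending line number) on a missing
    header, duplicate targets, rules referencing undeclared components, or
    malformed expressions.
    """
    if not text or not text.strip():
        raise BoolNetParseError("empty rule file")

    lines = text.splitlines()
    header_seen = False
    names: list[str] = []
    rules: list[RuleExpr] = []
    rule_lines: dict[str, int] = {}

    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if not header_seen:
            normalized = re.sub(r"\s+", "", line).lower()
            if normalized != "targets,factors":
                raise BoolNetParseError(
                    "expected header 'targets, factors'", lineno
                )
            header_seen = True
            continue
        if "," not in line:
            raise BoolNetParseError("expected 'name, expression'", lineno)
        name_part, expr_part = line.split(",", 1)
        name = name_part.strip()
        if not _NAME_RE.fullmatch(name):
            raise BoolNetParseError(f"invalid component name {name!r}", lineno)
        if name in rule_lines:
            raise BoolNetParseError(
                f"duplicate target {name!r} (first at line {rule_lines[name]})",
                lineno,
            )
        tokens = _tokenize(expr_part, lineno)
        if not tokens:
            raise BoolNetParseError(f"empty rule for {name!r}", lineno)
        rules.append(_ExprParser(tokens, lineno).parse())
        names.append(name)
        rule_lines[name] = lineno

    if not header_seen:
        raise BoolNetParseError("missing 'targets, factors' header")
    if not names:
        raise BoolNetParseError("no rule lines found")

    declared = set(names)
    for name, rule in zip(names, rules):
        undeclared = rule.variables() - declared
        if undeclared:
            raise BoolNetParseError(
                f"rule for {name!r} references undeclared component(s): "
                f"{sorted(undeclared)}",
                rule_lines[name],
            )

    return BooleanNetwork(tuple(names), tuple(rules))


def serialize_rules(net: BooleanNetwork) -> str:
    """Emit the network as BoolNet rule text (round-trips via parse_rules)."""
    lines = ["targets, factors"]
    for name, rule in zip(net.components, net.rules):
        lines.append(f"{name}, {rule.to_text()}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Truth tables


def truth_table(net: BooleanNetwork, component_index: int) -> np.ndarray:
    """Rule output of one component on every network state.

    Entry ``j`` is ``f_i`` evaluated on the state with integer encoding ``j``
    (bit ``i`` of ``j`` is component ``i``); length ``2**n``.
    """
    if not 0 <= component_index < net.n:
        raise IndexError(
            f"component index {component_index} out of range for n={net.n}"
        )
    states = np.arange(net.n_states, dtype=np.int64)
    columns = {
        name: ((states >> i) & 1).astype(np.uint8)
        for i, name in enumerate(net.components)
    }
    out = net.rules[component_index].evaluate_vector(columns)
    return np.broadcast_to(out, states.shape).astype(np.uint8).copy()


# ---------------------------------------------------------------------------
# Fixture & random generation


def fixture_cortical() -> BooleanNetwork:
    """The n=5 mammalian cortical area development network.

    Mutual Fgf8/Sp8 activation against the posterior factors Emx2 and
    Coup_tfi; synchronous dynamics has exactly two fixed-point attractors,
    the anterior (Fgf8, Pax6, Sp8 on) and posterior (Emx2, Coup_tfi on)
    expression phenotypes, printed ``10010`` and ``01101`` in register order.
    """
    text = (
        resources.files("qbnet").joinpath("data/cortical.bnet").read_text("utf-8")
    )
    return parse_rules(text)


def _random_expr(
    rng: np.random.Generator, inputs: list[str], table: np.ndarray
) -> RuleExpr:
    """Build a minterm-form expression realizing ``table`` over ``inputs``."""
    k = len(inputs)
    ones = np.flatnonzero(table)
    if len(ones) == 0:
        return Const(0)
    if len(ones) == table.size:
        return Const(1)
    terms: list[RuleExpr] = []
    for assignment in ones:
        literals: list[RuleExpr] = []
        for b, name in enumerate(inputs):
            bit = (int(assignment) >> b) & 1
            literals.append(Var(name) if bit else Not(Var(name)))
        term = literals[0]
        for lit in literals[1:]:
            term = And(term, lit)
        terms.append(term)
    expr = terms[0]
    for term in terms[1:]:
        expr = Or(expr, term)
    return expr


def generate_random_network(
    n: int, max_in_degree: int, seed: int
) -> BooleanNetwork:
    """Generate a random Boolean network with bounded in-degree.

    Every component's rule depends on at most ``max_in_degree`` components
    (uniform in-degree between 1 and the bound, uniform regulator choice,
    uniform non-constant truth table).  Same seed, same network.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 1 <= max_in_degree <= n:
        raise ValueError("max_in_degree must be in [1, n]")
    rng = np.random.default_rng(seed)
    names = tuple(f"G{i}" for i in range(n))
    rules: list[RuleExpr] = []
    for _ in range(n):
        k = int(rng.integers(1, max_in_degree + 1))
        regulators = [names[j] for j in rng.choice(n, size=k, replace=False)]
        # reject constant tables so every listed regulator can matter
        while True:
            table = rng.integers(0, 2, size=1 << k).astype(np.uint8)
            if 0 < int(table.sum()) < table.size:
                break
        rules.append(_random_expr(rng, regulators, table))
    return BooleanNetwork(names, tuple(rules))
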