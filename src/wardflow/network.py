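"""Rule-based flow networks compiled to linear dynamic models.

A hospital flow network is written as transfer rules over labelled nodes
(wards, porter stages, ...).  Each rule

    a_1 X_1 + ... -> b_1 Y_1 + ...  @ k_j  [channel]

moves items between nodes at a rate governed by the rate constant ``k_j``.
In linear mode every non-source rule is first-order mass action driven by a
single unit-coefficient input node, so the compiled model is the linear ODE

    d/dt eta(t) = A(k) eta(t) + B(k) u(t)

with ``A`` and ``B`` linear and homogeneous in the rate vector ``k``.
Source rules (empty left side) inject items from an exogenous input channel
through ``B``; sink rules (empty right side) remove them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "TransferRule",
    "FlowNetwork",
    "RateParameters",
    "LinearDynamics",
    "NetworkDiagnostics",
    "parse_rule_file",
    "serialize_network",
    "build_system_matrices",
    "rate_jacobians",
    "validate_network",
]


class RuleSyntaxError(ValueError):
    """A rule line does not match the DSL grammar."""


@dataclass(frozen=True)
class TransferRule:
    """One transfer step: input/output stoichiometry plus its rate constant.

    ``driver`` is the single input node whose occupancy drives the flow, or
    the exogenous channel name for source rules (``driver_is_channel``).
    """

    inputs: dict[str, int]
    outputs: dict[str, int]
    rate_name: str
    driver: str
    driver_is_channel: bool = False

    def __post_init__(self) -> None:
        for coef_map, side in ((self.inputs, "input"), (self.outputs, "output")):
            for sp, c in coef_map.items():
                if not (isinstance(c, (int, np.integer)) and c >= 0):
                    raise ValueError(
                        f"{side} coefficient for {sp!r} must be a nonnegative integer, got {c!r}"
                    )
        if not self.inputs and not self.driver_is_channel:
            raise ValueError(
                f"source rule @ {self.rate_name}: needs an exogenous input channel driver"
            )
        if self.inputs:
            if self.driver_is_channel:
                raise ValueError(f"rule @ {self.rate_name}: channel driver on a non-source rule")
            if self.driver not in self.inputs:
                raise ValueError(f"rule @ {self.rate_name}: driver {self.driver!r} is not an input")

    @property
    def is_source(self) -> bool:
        return not self.inputs


@dataclass(frozen=True)
class FlowNetwork:
    """Ordered node/rule/rate registries of a flow network."""

    species: tuple[str, ...]
    rules: tuple[TransferRule, ...]
    rate_names: tuple[str, ...]
    input_channels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.species) < 1:
            raise ValueError("network needs at least one species")
        if len(self.rules) < 1:
            raise ValueError("network needs at least one rule")
        if len(set(self.species)) != len(self.species):
            raise ValueError("species labels must be unique")
        if len(set(self.rate_names)) != len(self.rate_names):
            raise ValueError("rate names must be unique")
        if len(self.rate_names) != len(self.rules):
            raise ValueError("one rate name per rule")
        declared = set(self.species)
        channels = set(self.input_channels)
        for rule, name in zip(self.rules, self.rate_names):
            if rule.rate_name != name:
                raise ValueError("rate_names must align with rules")
            for sp in (*rule.inputs, *rule.outputs):
                if sp not in declared:
                    raise ValueError(f"rule @ {name} references undeclared species {sp!r}")
            if rule.driver_is_channel and rule.driver not in channels:
                raise ValueError(f"rule @ {name} references undeclared channel {rule.driver!r}")

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_rules(self) -> int:
        return len(self.rules)

    def species_index(self, name: str) -> int:
        return self.species.index(name)


@dataclass(frozen=True)
class RateParameters:
    """Rate-constant vector (per-minute units), aligned with a network.

    ``nominal`` holds the mean value k_bar around which perturbations are
    estimated; it defaults to ``values``.
    """

    values: np.ndarray
    names: tuple[str, ...]
    nominal: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if self.nominal is None:
            object.__setattr__(self, "nominal", values.copy())
        else:
            object.__setattr__(self, "nominal", np.asarray(self.nominal, dtype=float))
        if values.ndim != 1 or len(values) != len(self.names):
            raise ValueError("values must be a vector aligned with names")
        if np.any(values < 0) or np.any(self.nominal < 0):
            raise ValueError("rates must be nonnegative")

    @classmethod
    def from_dict(cls, net: FlowNetwork, mapping: dict[str, float]) -> "RateParameters":
        missing = [n for n in net.rate_names if n not in mapping]
        if missing:
            raise ValueError(f"missing rates: {missing}")
        extra = [n for n in mapping if n not in net.rate_names]
        if extra:
            raise ValueError(f"unknown rates: {extra}")
        return cls(np.array([mapping[n] for n in net.rate_names]), net.rate_names)

    def with_values(self, values: np.ndarray) -> "RateParameters":
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass(frozen=True)
class LinearDynamics:
    """Linear (possibly augmented) system dx = A x dt + B u dt + G dw.

    ``Q`` is the intensity of the driving noise ``w`` (the inverse of the
    information matrix describing rate-coefficient uncertainty).
    """

    A: np.ndarray
    B: np.ndarray
    G: np.ndarray
    Q: np.ndarray
    state_labels: tuple[str, ...]
    input_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        A = np.atleast_2d(np.asarray(self.A, dtype=float))
        n = A.shape[0]
        B = np.asarray(self.B, dtype=float).reshape(n, -1)
        G = np.atleast_2d(np.asarray(self.G, dtype=float))
        Q = np.atleast_2d(np.asarray(self.Q, dtype=float))
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "B", B)
        object.__setattr__(self, "G", G)
        object.__setattr__(self, "Q", Q)
        if A.shape != (n, n):
            raise ValueError("A must be square")
        if G.shape[0] != n:
            raise ValueError("G rows must match state dimension")
        q = G.shape[1]
        if Q.shape != (q, q):
            raise ValueError("Q must be q x q with q = G columns")
        if not np.allclose(Q, Q.T, atol=1e-12):
            raise ValueError("Q must be symmetric")
        if np.any(np.linalg.eigvalsh((Q + Q.T) / 2) < -1e-10):
            raise ValueError("Q must be positive semidefinite")
        if len(self.state_labels) != n:
            raise ValueError("state_labels must match state dimension")

    @property
    def n(self) -> int:
        return self.A.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.B.shape[1]


_TERM_RE = re.compile(r"^(?:(\d+)\s+)?([A-Za-z_][A-Za-z0-9_]*)$")
_LINE_RE = re.compile(
    r"^(?P<lhs>[^-@]*?)\s*->\s*(?P<rhs>[^@]*?)\s*@\s*(?P<rate>[A-Za-z_][A-Za-z0-9_]*)"
    r"\s*(?:\[\s*(?P<channel>[A-Za-z_][A-Za-z0-9_]*)\s*\])?\s*$"
)


def _parse_side(text: str, lineno: int) -> dict[str, int]:
    text = text.strip()
    if text == "0":
        return {}
    coefs: dict[str, int] = {}
    for term in text.split("+"):
        m = _TERM_RE.match(term.strip())
        if m is None:
            raise RuleSyntaxError(f"line {lineno}: cannot parse term {term.strip()!r}")
        coef = int(m.group(1)) if m.group(1) else 1
        name = m.group(2)
        coefs[name] = coefs.get(name, 0) + coef
    return coefs


def parse_rule_file(text: str, linear: bool = True) -> FlowNetwork:
    """Parse a rule-DSL document into a :class:`FlowNetwork`.

    Grammar (one rule per line, ``#`` starts a comment, ``0`` is an empty
    side, omitted coefficients are 1)::

        [coef] NODE {+ [coef] NODE} -> [coef] NODE {+ ...} @ RATE ["[" channel "]"]

    In linear mode each non-source rule must have exactly one input node with
    coefficient 1 (its driver); source rules must name an exogenous channel.
    """
    species: list[str] = []
    channels: list[str] = []
    rules: list[TransferRule] = []
    rate_names: list[str] = []

    def register(name: str) -> None:
        if name not in species:
            species.append(name)

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        m = _LINE_RE.match(line)
        if m is None:
            raise RuleSyntaxError(f"line {lineno}: does not match rule grammar: {raw.strip()!r}")
        inputs = _parse_side(m.group("lhs"), lineno)
        outputs = _parse_side(m.group("rhs"), lineno)
        rate = m.group("rate")
        channel = m.group("channel")
        if rate in rate_names:
            raise RuleSyntaxError(f"line {lineno}: duplicate rate name {rate!r}")
        for sp in (*inputs, *outputs):
            register(sp)
        if not inputs:
            if channel is None:
                raise RuleSyntaxError(
                    f"line {lineno}: source rule @ {rate} must declare an input channel"
                )
            driver, driver_is_channel = channel, True
            if channel not in channels:
                channels.append(channel)
        else:
            if channel is not None:
                raise RuleSyntaxError(
                    f"line {lineno}: channel annotation only allowed on source rules"
                )
            if linear:
                if len(inputs) != 1:
                    raise RuleSyntaxError(
                        f"line {lineno}: linear mode requires a single input species"
                    )
                (driver, coef), = inputs.items()
                if coef != 1:
                    raise RuleSyntaxError(
                        f"line {lineno}: linear mode requires unit driver coefficient, got {coef}"
                    )
            else:
                driver = max(inputs, key=inputs.get)
            driver_is_channel = False
        rules.append(TransferRule(inputs, outputs, rate, driver, driver_is_channel))
        rate_names.append(rate)

    if not rules:
        raise RuleSyntaxError("no rules")
    return FlowNetwork(tuple(species), tuple(rules), tuple(rate_names), tuple(channels))


def serialize_network(net: FlowNetwork) -> str:
    """Inverse of :func:`parse_rule_file` (up to whitespace)."""

    def side(coefs: dict[str, int]) -> str:
        if not coefs:
            return "0"
        return " + ".join(f"{c} {sp}" if c != 1 else sp for sp, c in coefs.items())

    lines = []
    for rule in net.rules:
        line = f"{side(rule.inputs)} -> {side(rule.outputs)} @ {rule.rate_name}"
        if rule.driver_is_channel:
            line += f" [{rule.driver}]"
        lines.append(line)
    return "\n".join(lines) + "\n"


def _contributions(net: FlowNetwork) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-rule unit-rate (A, B) contributions; A(k) = sum_j k_j * A_j."""
    n = net.n_species
    m = len(net.input_channels)
    out = []
    for rule in net.rules:
        Aj = np.zeros((n, n))
        Bj = np.zeros((n, max(m, 0)))
        if rule.is_source:
            ch = net.input_channels.index(rule.driver)
            for sp, b in rule.outputs.items():
                Bj[net.species_index(sp), ch] += b
        else:
            d = net.species_index(rule.driver)
            for sp, a in rule.inputs.items():
                Aj[net.species_index(sp), d] -= a
            for sp, b in rule.outputs.items():
                Aj[net.species_index(sp), d] += b
        out.append((Aj, Bj))
    return out


def build_system_matrices(
    net: FlowNetwork,
    k: RateParameters,
    G: np.ndarray | None = None,
    Q: np.ndarray | None = None,
) -> LinearDynamics:
    """Compile the network at rates ``k`` into ``d/dt eta = A eta + B u``.

    ``G`` defaults to the identity on the state rows and ``Q`` to a small
    diagonal noise intensity (overridden from config in filtering use).
    """
    if tuple(k.names) != net.rate_names:
        raise ValueError("rate parameters not aligned with network")
    n = net.n_species
    A = np.zeros((n, n))
    B = np.zeros((n, len(net.input_channels)))
    for kj, (Aj, Bj) in zip(k.values, _contributions(net)):
        A += kj * Aj
        B += kj * Bj
    if G is None:
        G = np.eye(n)
    if Q is None:
        Q = 1e-2 * np.eye(np.atleast_2d(G).shape[1])
    return LinearDynamics(A, B, G, Q, net.species, net.input_channels)


def rate_jacobians(
    net: FlowNetwork, k: RateParameters
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-parameter derivatives (dA/dk_j, dB/dk_j).

    ``A`` and ``B`` are linear in ``k``, so each jacobian is the rule's
    unit-rate contribution and is constant in ``k``.
    """
    if tuple(k.names) != net.rate_names:
        raise ValueError("rate parameters not aligned with network")
    return _contributions(net)


@dataclass(frozen=True)
class NetworkDiagnostics:
    unreachable: frozenset[str]
    absorbing: frozenset[str]
    conserving: bool
    linear_violations: tuple[str, ...] = ()

    def summary(self) -> str:
        lines = [
            f"unreachable: {sorted(self.unreachable) or 'none'}",
            f"absorbing (no outflow): {sorted(self.absorbing) or 'none'}",
            f"unit-conserving: {self.conserving}",
        ]
        if self.linear_violations:
            lines.append("linear-mode violations: " + "; ".join(self.linear_violations))
        return "\n".join(lines)


def validate_network(net: FlowNetwork) -> NetworkDiagnostics:
    """Structural diagnostics: reachability, absorbing nodes, conservation."""
    participating: set[str] = set()
    edges: dict[str, set[str]] = {sp: set() for sp in net.species}
    roots: set[str] = set()
    has_source = any(r.is_source for r in net.rules)
    for rule in net.rules:
        participating.update(rule.inputs)
        participating.update(rule.outputs)
        if rule.is_source:
            roots.update(rule.outputs)
        else:
            for src in rule.inputs:
                edges[src].update(rule.outputs)
    if not has_source:
        # closed network: anything holding initial mass can flow
        roots = {sp for r in net.rules for sp in r.inputs}
    reachable = set(roots)
    frontier = list(roots)
    while frontier:
        for nxt in edges[frontier.pop()]:
            if nxt not in reachable:
                reachable.add(nxt)
                frontier.append(nxt)
    unreachable = (set(net.species) - reachable) | (set(net.species) - participating)

    drivers = {r.driver for r in net.rules if not r.driver_is_channel}
    absorbing = {sp for sp in net.species if sp in participating and sp not in drivers}

    conserving = all(
        sum(r.inputs.values()) == sum(r.outputs.values()) for r in net.rules
    )

    violations = []
    for rule in net.rules:
        if rule.is_source:
            continue
        if len(rule.inputs) != 1 or rule.inputs[rule.driver] != 1:
            violations.append(f"rule @ {rule.rate_name}: not single-unit-driver")
    return NetworkDiagnostics(
        frozenset(unreachable), frozenset(absorbing), conserving, tuple(violations)
    )
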