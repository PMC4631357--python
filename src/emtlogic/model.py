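"""Boolean network models with asynchronous update, clamping, and exact
stable-state enumeration.

A model is a set of named nodes; every node either carries a logical rule or
is declared an *input* (held constant by the dynamics, but free in
stable-state enumeration so that every input combination is explored).
Mutations are expressed as *clamps*: nodes forced permanently ON (gain of
function) or OFF (loss of function); a clamped node never flips regardless of
its rule.

Stable states (fixed points of the asynchronous dynamics, x = f(x) on every
unclamped ruled node) are enumerated exactly by a determining-set method: a
feedback vertex set (FVS) of the regulatory graph is computed once, all
assignments of inputs + FVS are laid out as rows of a numpy array, the
remaining nodes are filled in by truth-table propagation in topological
order, and rows whose FVS nodes fail self-consistency are dropped.  Any
fixed point restricted to the determining set propagates back to itself, so
the search is complete; it touches 2^(|inputs|+|FVS|) candidates instead of
2^n.  Because the FVS depends only on which nodes regulate which — not on
the AND/OR structure of the rules — it is shared by all operator-swap
variants of a model, which is what makes the robustness census cheap.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .expr import (
    And,
    Expr,
    Not,
    Or,
    RuleSyntaxError,
    Var,
    binary_sites,
    evaluate,
    parse_expr,
    rename,
    variables,
)

__all__ = [
    "BooleanModel",
    "NetworkState",
    "OperatorSite",
    "parse_model",
    "validate_clamps",
    "hamming_distance",
]


class NetworkState:
    """A total 0/1 assignment over the nodes of one model.

    Hashable and comparable, so states can live in sets and be sorted;
    ordering is lexicographic over the model's node order.
    """

    __slots__ = ("nodes", "bits")

    def __init__(self, nodes: tuple[str, ...], bits: tuple[int, ...]):
        if len(nodes) != len(bits):
            raise ValueError("state must assign every node")
        self.nodes = nodes
        self.bits = bits

    @classmethod
    def from_dict(cls, nodes: Sequence[str], assignment: Mapping[str, int]) -> "NetworkState":
        missing = [n for n in nodes if n not in assignment]
        if missing:
            raise ValueError(f"state missing nodes: {missing}")
        return cls(tuple(nodes), tuple(int(assignment[n]) for n in nodes))

    def __getitem__(self, node: str) -> int:
        return self.bits[self.nodes.index(node)]

    def as_dict(self) -> dict[str, int]:
        return dict(zip(self.nodes, self.bits))

    def replace(self, **changes: int) -> "NetworkState":
        d = self.as_dict()
        for k, v in changes.items():
            if k not in d:
                raise KeyError(k)
            d[k] = int(v)
        return NetworkState.from_dict(self.nodes, d)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, NetworkState)
            and self.nodes == other.nodes
            and self.bits == other.bits
        )

    def __lt__(self, other: "NetworkState") -> bool:
        return self.bits < other.bits

    def __hash__(self) -> int:
        return hash((self.nodes, self.bits))

    def __repr__(self) -> str:
        on = [n for n, b in zip(self.nodes, self.bits) if b]
        return f"<NetworkState ON={{{', '.join(on)}}}>"


@dataclass(frozen=True)
class OperatorSite:
    """One binary AND/OR occurrence: rule owner, in-order index, operator."""

    node: str
    index: int
    op: str  # "AND" | "OR"


def hamming_distance(a: NetworkState, b: NetworkState) -> int:
    if a.nodes != b.nodes:
        raise ValueError("states belong to different models")
    return sum(x != y for x, y in zip(a.bits, b.bits))


def validate_clamps(model: "BooleanModel", clamps: Mapping[str, int]) -> dict[str, int]:
    out = {}
    for node, bit in clamps.items():
        if node not in model.index:
            raise KeyError(f"clamped node {node!r} is not a model node")
        if bit not in (0, 1):
            raise ValueError(f"clamp value for {node!r} must be 0 or 1")
        out[node] = int(bit)
    return out


@dataclass
class BooleanModel:
    nodes: tuple[str, ...]
    rules: dict[str, Expr]
    inputs: frozenset[str]
    aliases: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.nodes = tuple(self.nodes)
        self.inputs = frozenset(self.inputs)
        declared = set(self.nodes)
        for node in self.nodes:
            if node in self.inputs:
                if node in self.rules:
                    raise ValueError(f"input {node!r} must not carry a rule")
            elif node not in self.rules:
                raise ValueError(f"non-input node {node!r} has no rule")
        for node, rule in self.rules.items():
            unknown = variables(rule) - declared
            if unknown:
                raise ValueError(f"rule for {node!r} references undeclared nodes: {sorted(unknown)}")

    # -- basic structure ---------------------------------------------------
    @cached_property
    def index(self) -> dict[str, int]:
        return {n: i for i, n in enumerate(self.nodes)}

    @property
    def ruled_nodes(self) -> tuple[str, ...]:
        return tuple(n for n in self.nodes if n not in self.inputs)

    def state(self, assignment: Mapping[str, int]) -> NetworkState:
        return NetworkState.from_dict(self.nodes, assignment)

    def regulatory_graph(self) -> nx.DiGraph:
        """Directed graph regulator -> target over all nodes."""
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for node, rule in self.rules.items():
            for reg in variables(rule):
                g.add_edge(reg, node)
        return g

    # -- evaluation --------------------------------------------------------
    def evaluate_rule(self, node: str, state: NetworkState | Mapping[str, int]) -> int:
        if node in self.inputs:
            raise ValueError(f"{node!r} is an input and has no rule; treat it as a constant")
        if node not in self.rules:
            raise KeyError(node)
        mapping = state.as_dict() if isinstance(state, NetworkState) else state
        return evaluate(self.rules[node], mapping)

    def async_successors(
        self, state: NetworkState, clamps: Mapping[str, int] | None = None
    ) -> set[NetworkState]:
        """States one asynchronous (single-bit) flip away.

        A node is eligible to flip when it is unclamped, not an input, and its
        rule disagrees with its current value.  Empty set iff stable.
        """
        clamps = validate_clamps(self, clamps or {})
        mapping = state.as_dict()
        out = set()
        for node in self.ruled_nodes:
            if node in clamps:
                continue
            if evaluate(self.rules[node], mapping) != mapping[node]:
                out.add(state.replace(**{node: 1 - mapping[node]}))
        return out

    def is_stable(self, state: NetworkState, clamps: Mapping[str, int] | None = None) -> bool:
        return not self.async_successors(state, clamps)

    # -- compiled truth tables --------------------------------------------
    @cached_property
    def _compiled(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per ruled node: (regulator index array, truth table over regulators)."""
        return {node: self._compile_rule(self.rules[node]) for node in self.ruled_nodes}

    def _compile_rule(self, rule: Expr) -> tuple[np.ndarray, np.ndarray]:
        regs = sorted(variables(rule), key=self.index.__getitem__)
        k = len(regs)
        tt = np.empty(1 << k, dtype=np.uint8)
        for m in range(1 << k):
            assign = {r: (m >> j) & 1 for j, r in enumerate(regs)}
            tt[m] = evaluate(rule, assign)
        reg_idx = np.array([self.index[r] for r in regs], dtype=np.intp)
        return reg_idx, tt

    def rule_values(self, X: np.ndarray, node: str, compiled=None) -> np.ndarray:
        """Vectorised rule evaluation over rows of a (m, n_nodes) bit matrix."""
        reg_idx, tt = (compiled or self._compiled)[node]
        if reg_idx.size == 0:
            return np.full(X.shape[0], tt[0], dtype=np.uint8)
        weights = (1 << np.arange(reg_idx.size)).astype(np.int64)
        idx = X[:, reg_idx].astype(np.int64) @ weights
        return tt[idx]

    # -- stable-state enumeration -----------------------------------------
    @cached_property
    def feedback_vertex_set(self) -> tuple[str, ...]:
        """Heuristic FVS of the ruled-node regulatory graph (inputs excluded)."""
        g = self.regulatory_graph().subgraph(self.ruled_nodes).copy()
        fvs: list[str] = []
        # self-loops are forced members
        for node in list(g.nodes):
            if g.has_edge(node, node):
                fvs.append(node)
                g.remove_node(node)
        while not nx.is_directed_acyclic_graph(g):
            best, best_score = None, -1
            for scc in nx.strongly_connected_components(g):
                if len(scc) < 2:
                    continue
                for node in scc:
                    score = g.in_degree(node) * g.out_degree(node)
                    if score > best_score or (score == best_score and node < best):
                        best, best_score = node, score
            fvs.append(best)
            g.remove_node(best)
        # minimisation pass: drop members that are not actually needed
        full = self.regulatory_graph().subgraph(self.ruled_nodes)
        for node in sorted(fvs):
            trial = [n for n in fvs if n != node]
            h = full.subgraph([n for n in self.ruled_nodes if n not in trial])
            if nx.is_directed_acyclic_graph(h):
                fvs = trial
        return tuple(sorted(fvs, key=self.index.__getitem__))

    def _enumeration_plan(self, clamps: Mapping[str, int]):
        key = tuple(sorted(clamps.items()))
        cache = self.__dict__.setdefault("_plan_cache", {})
        if key in cache:
            return cache[key]
        plan = self._build_plan(clamps)
        if len(cache) < 4096:
            cache[key] = plan
        return plan

    def _build_plan(self, clamps: Mapping[str, int]):
        branch = [n for n in self.nodes if (n in self.inputs or n in self.feedback_vertex_set) and n not in clamps]
        fixed = dict(clamps)
        determined = set(branch) | set(fixed)
        # topological order of the remaining ruled nodes
        g = self.regulatory_graph().subgraph(
            [n for n in self.ruled_nodes if n not in determined]
        )
        topo = list(nx.topological_sort(g))
        check = [n for n in self.feedback_vertex_set if n not in clamps]
        return branch, fixed, topo, check

    def enumerate_stable_states(
        self,
        clamps: Mapping[str, int] | None = None,
        compiled: dict | None = None,
    ) -> list[NetworkState]:
        """All fixed points, clamped nodes held at their forced values and
        input nodes free (every combination explored).  Returned in
        lexicographic order of the node-order bit vector.

        ``compiled`` lets callers substitute alternative truth tables for a
        structurally identical model (used by the operator-swap census to
        avoid recompiling unchanged rules).
        """
        clamps = validate_clamps(self, clamps or {})
        branch, fixed, topo, check = self._enumeration_plan(clamps)
        tables = compiled or self._compiled

        m = 1 << len(branch)
        X = np.zeros((m, len(self.nodes)), dtype=np.uint8)
        for j, node in enumerate(branch):
            # bit j of the row number; branch order follows node order
            X[:, self.index[node]] = (np.arange(m) >> j) & 1
        for node, bit in fixed.items():
            X[:, self.index[node]] = bit
        for node in topo:
            X[:, self.index[node]] = self.rule_values(X, node, tables)
        ok = np.ones(m, dtype=bool)
        for node in check:
            ok &= self.rule_values(X, node, tables) == X[:, self.index[node]]
        states = [NetworkState(self.nodes, tuple(int(b) for b in row)) for row in X[ok]]
        return sorted(states)

    # -- operator sites ----------------------------------------------------
    def operator_sites(self, node: str | None = None) -> list[OperatorSite]:
        """All binary AND/OR sites, per rule, in written (in-order) position."""
        nodes = [node] if node is not None else list(self.ruled_nodes)
        out = []
        for n in nodes:
            for i, site in enumerate(binary_sites(self.rules[n])):
                out.append(OperatorSite(n, i, site.op))
        return out

    def with_rules(self, replacements: Mapping[str, Expr]) -> "BooleanModel":
        rules = dict(self.rules)
        rules.update(replacements)
        return BooleanModel(self.nodes, rules, self.inputs, dict(self.aliases))

    # -- serialisation -----------------------------------------------------
    def to_text(self) -> str:
        lines = []
        for alias, target in sorted(self.aliases.items()):
            lines.append(f"alias {alias} = {target}")
        for node in self.nodes:
            if node in self.inputs:
                lines.append(f"input {node}")
        for node in self.nodes:
            if node not in self.inputs:
                lines.append(f"{node} = {self.rules[node]}")
        return "\n".join(lines) + "\n"

    def to_boolnet(self) -> str:
        """BoolNet-style 'targets, factors' CSV (inputs as self-activations)."""
        lines = ["targets, factors"]
        for node in self.nodes:
            if node in self.inputs:
                lines.append(f"{node}, {node}")
            else:
                lines.append(f"{node}, {self.rules[node]}")
        return "\n".join(lines) + "\n"

    def checksum(self) -> str:
        return hashlib.sha256(self.to_text().encode()).hexdigest()


def parse_model(text: str) -> BooleanModel:
    """Parse a rule file: ``Name = expr`` lines, ``input Name`` declarations,
    ``alias Name = Canonical`` declarations, ``#`` comments."""
    nodes: list[str] = []
    rules: dict[str, Expr] = {}
    inputs: set[str] = set()
    aliases: dict[str, str] = {}
    pending: list[tuple[str, Expr, int]] = []

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("input "):
            name = line[len("input "):].strip()
            if not name.isidentifier():
                raise RuleSyntaxError(f"bad input name {name!r}", lineno)
            if name in nodes:
                raise RuleSyntaxError(f"duplicate declaration of {name!r}", lineno)
            nodes.append(name)
            inputs.add(name)
            continue
        if line.startswith("alias "):
            try:
                alias, target = (s.strip() for s in line[len("alias "):].split("=", 1))
            except ValueError:
                raise RuleSyntaxError("alias syntax is 'alias NAME = CANONICAL'", lineno)
            aliases[alias] = target
            continue
        if "=" not in line:
            raise RuleSyntaxError("expected 'Name = expression'", lineno)
        name, rhs = (s.strip() for s in line.split("=", 1))
        if not name.isidentifier():
            raise RuleSyntaxError(f"bad node name {name!r}", lineno)
        if name in nodes:
            raise RuleSyntaxError(f"duplicate rule for node {name!r}", lineno)
        nodes.append(name)
        pending.append((name, parse_expr(rhs, lineno), lineno))

    declared = set(nodes)
    for name, expr, lineno in pending:
        expr = rename(expr, aliases)
        unresolved = variables(expr) - declared
        if unresolved:
            raise RuleSyntaxError(
                f"rule for {name!r} references undeclared name(s): {sorted(unresolved)}", lineno
            )
        rules[name] = expr
    return BooleanModel(tuple(nodes), rules, frozenset(inputs), aliases)
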