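"""Probabilistic graphical model construction and forward sampling.

:func:`build_graph` turns a parsed script into a :class:`GraphicalModel`: a
DAG with one named node per statement.  Node kinds follow the statement's
operator and right-hand side:

* ``constant`` — ``=`` with a right-hand side containing no variables and
  no generator calls (a square in the usual PGM drawing);
* ``deterministic`` — ``=`` with a function/method call or an expression
  over other variables (a diamond);
* ``stochastic`` — ``~`` with a generative distribution (a circle).

:func:`clamp` implements data clamping: a model-block stochastic node whose
name matches a data-block node is marked observed and keeps the data value
during sampling — the forward-simulation analogue of conditioning.

:func:`sample` evaluates the graph in statement order (which the
use-before-definition rule makes topological) with one independent,
name-keyed random stream per stochastic node and replicate, so adding an
unrelated node never perturbs another node's draws.

:func:`vectorize` implements the two vectorization mechanisms: an explicit
``replicates=k`` argument (k IID invocations stacked on a new major
dimension) and implicit broadcasting (an argument declared scalar receiving
a length-k vector broadcasts the generator element-wise).  All broadcast
arguments must agree on the major dimension; combining ``replicates`` with
broadcasting is rejected as ambiguous.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from . import parser as ast
from .errors import (
    BroadcastError,
    DuplicateDefinition,
    GraphError,
    InvalidParameter,
    LPhyError,
    ShapeMismatch,
    TypeMismatch,
    UnknownVariable,
)
from .registry import GeneratorRegistry, GeneratorSpec, matches, split_major

__all__ = ["PGMNode", "GraphicalModel", "build_graph", "clamp", "sample", "vectorize", "export_dot"]

_UNSET = object()


@dataclass
class PGMNode:
    name: str
    kind: str  # "constant" | "deterministic" | "stochastic"
    block: str  # "data" | "model"
    rhs: object  # AST expression
    generator: GeneratorSpec | None = None
    parents: list = field(default_factory=list)  # parent node names, in order
    observed: bool = False
    value: object = _UNSET

    @property
    def has_value(self) -> bool:
        return self.value is not _UNSET


class GraphicalModel:
    """The PGM: named nodes plus evaluation order.

    ``nodes`` maps each name to its defining node; when a data-block node
    clamps an equally named model-block stochastic node the stochastic node
    is stored in ``nodes`` and the data-side definition in ``data_shadows``.
    """

    def __init__(self, registry: GeneratorRegistry):
        self.registry = registry
        self.nodes: dict[str, PGMNode] = {}
        self.data_shadows: dict[str, PGMNode] = {}
        self.order: list[PGMNode] = []  # evaluation order: data block, then model

    def node(self, name: str) -> PGMNode:
        return self.nodes[name]

    def by_kind(self, kind: str) -> list:
        return [n for n in self.order if n.kind == kind]

    def children(self, name: str) -> list:
        return [n for n in self.order if name in n.parents]

    def sink_nodes(self) -> list:
        """Nodes no other node depends on, in declaration order."""
        referenced = {p for n in self.order for p in n.parents}
        return [n for n in self.order if n.name not in referenced]

    def sample(self, seed: int) -> dict:
        return sample(self, seed)

    def __repr__(self):
        kinds = {k: len(self.by_kind(k)) for k in ("constant", "deterministic", "stochastic")}
        return f"GraphicalModel({kinds})"


# ---------------------------------------------------------------------------
# Graph construction
# ---------------------------------------------------------------------------


def _walk(expr):
    yield expr
    if isinstance(expr, ast.ArrayLiteral):
        for e in expr.elements:
            yield from _walk(e)
    elif isinstance(expr, ast.Range):
        yield from _walk(expr.lo)
        yield from _walk(expr.hi)
    elif isinstance(expr, ast.GeneratorCall):
        for _, v in expr.args:
            yield from _walk(v)
    elif isinstance(expr, ast.MethodCall):
        yield from _walk(expr.target)
        for _, v in expr.args:
            yield from _walk(v)
    elif isinstance(expr, ast.BinaryOp):
        yield from _walk(expr.left)
        yield from _walk(expr.right)
    elif isinstance(expr, ast.UnaryOp):
        yield from _walk(expr.operand)


def _refs(expr) -> list:
    out = []
    for e in _walk(expr):
        if isinstance(e, ast.VariableRef) and e.name not in out:
            out.append(e.name)
    return out


def build_graph(script: ast.ScriptAST, registry: GeneratorRegistry) -> GraphicalModel:
    """Construct the PGM from a parsed script, resolving generator names and
    overloads and checking that every referenced variable is defined."""
    model = GraphicalModel(registry)

    def add(stmt: ast.Statement, block: str, visible: set):
        name = stmt.lhs
        refs = _refs(stmt.rhs)
        for r in refs:
            if r not in visible:
                raise UnknownVariable(f"variable {r!r} used before definition", name)
        # resolve every generator call appearing anywhere in the expression
        top_call = stmt.rhs if isinstance(stmt.rhs, ast.GeneratorCall) else None
        for e in _walk(stmt.rhs):
            if isinstance(e, ast.GeneratorCall):
                spec = registry.resolve(e.name, {n for n, _ in e.args}, node=name)
                if spec.kind == "generative" and e is not top_call:
                    raise TypeMismatch(
                        f"generative distribution {e.name!r} cannot be nested "
                        "inside an expression",
                        name,
                    )

        if stmt.op == "stochastic_assign":
            if not isinstance(stmt.rhs, ast.GeneratorCall):
                raise TypeMismatch("'~' requires a generative distribution call", name)
            spec = registry.resolve(stmt.rhs.name, {n for n, _ in stmt.rhs.args}, node=name)
            if spec.kind != "generative":
                raise TypeMismatch(
                    f"{stmt.rhs.name!r} is a deterministic function; use '=' not '~'",
                    name,
                )
            kind = "stochastic"
            generator = spec
        else:
            if top_call is not None:
                spec = registry.resolve(top_call.name, {n for n, _ in top_call.args}, node=name)
                if spec.kind == "generative":
                    raise TypeMismatch(
                        f"{top_call.name!r} is a generative distribution; use '~' not '='",
                        name,
                    )
                generator = spec
                kind = "deterministic"
            elif refs or any(
                isinstance(e, (ast.GeneratorCall, ast.MethodCall)) for e in _walk(stmt.rhs)
            ):
                generator = None
                kind = "deterministic"
            else:
                generator = None
                kind = "constant"

        node = PGMNode(name, kind, block, stmt.rhs, generator, refs)
        if block == "data":
            if name in model.nodes:
                raise DuplicateDefinition(f"{name!r} defined twice in the data block", name)
            model.nodes[name] = node
        else:
            existing = model.nodes.get(name)
            if existing is not None:
                if existing.block == "model":
                    raise DuplicateDefinition(f"{name!r} defined twice in the model block", name)
                if kind != "stochastic":
                    raise DuplicateDefinition(
                        f"{name!r} is already defined in the data block", name
                    )
                # a model-block stochastic node sharing a data-block name:
                # the data value will clamp it (see clamp())
                model.data_shadows[name] = existing
            model.nodes[name] = node
        model.order.append(node)

    visible: set = set()
    for stmt in script.data_statements:
        add(stmt, "data", visible)
        visible.add(stmt.lhs)
    for stmt in script.model_statements:
        add(stmt, "model", visible)
        visible.add(stmt.lhs)
    return model


def clamp(model: GraphicalModel) -> GraphicalModel:
    """Mark every model-block stochastic node whose name matches a
    data-block node as observed.  The observed value is bound when the data
    block is evaluated; its dimensions are checked against the generator's
    output at that point (raising ShapeMismatch on disagreement)."""
    for name in model.data_shadows:
        model.nodes[name].observed = True
    return model


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------


def _node_stream(seed: int, name: str, index: int) -> np.random.Generator:
    digest = hashlib.sha256(f"{name}#{index}".encode()).digest()
    key = int.from_bytes(digest[:4], "big") % (2**31)
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), key, index]))


def sample(model: GraphicalModel, seed: int) -> dict:
    """Evaluate every node in dependency order and return the full value
    assignment (name -> value).  Constants are copied, deterministic nodes
    computed, unobserved stochastic nodes drawn from their generative
    distributions, observed nodes bound to their clamped values.  Equal
    seeds yield identical assignments."""
    env: dict[str, object] = {}
    assignment: dict[str, object] = {}

    for node in model.order:
        shadow = model.data_shadows.get(node.name)
        try:
            if node.kind == "stochastic":
                call = node.rhs
                values = {n: _eval(v, env, model, node.name) for n, v in call.args}
                if node.observed and shadow is not None:
                    observed = env[node.name]  # bound by the data block
                    _validate_observed(node.generator, observed, values, node.name)
                    value = observed
                else:
                    factory = _factory(seed, node.name)
                    value = vectorize(node.generator, values, factory, node=node.name)
            else:
                value = _eval(node.rhs, env, model, node.name)
        except LPhyError:
            raise
        except Exception as exc:  # attach the node name to generator errors
            raise GraphError(f"{type(exc).__name__}: {exc}", node.name) from exc
        env[node.name] = value
        assignment[node.name] = value
    return assignment


def _factory(seed, name):
    return lambda i: _node_stream(seed, name, i)


def _validate_observed(spec, observed, values, node):
    if spec.validate_observed is None:
        return
    try:
        spec.validate_observed(observed, values)
    except ShapeMismatch:
        raise
    except LPhyError as exc:
        raise ShapeMismatch(str(exc), node) from exc


def _eval(expr, env, model: GraphicalModel, node: str):
    """Evaluate an expression.  Generative distributions are rejected here:
    they may only appear as the whole right-hand side of a '~' statement."""
    if isinstance(expr, ast.Literal):
        return expr.value
    if isinstance(expr, ast.VariableRef):
        if expr.name not in env:
            raise UnknownVariable(f"variable {expr.name!r} is not defined", node)
        return env[expr.name]
    if isinstance(expr, ast.ArrayLiteral):
        elements = [_eval(e, env, model, node) for e in expr.elements]
        if elements and all(
            isinstance(e, (int, float, np.integer, np.floating)) and not isinstance(e, bool)
            for e in elements
        ):
            return np.asarray(elements)
        return elements
    if isinstance(expr, ast.Range):
        lo = _eval(expr.lo, env, model, node)
        hi = _eval(expr.hi, env, model, node)
        if not all(isinstance(x, (int, np.integer)) for x in (lo, hi)):
            raise TypeMismatch(f"range endpoints must be integers, got {lo!r}:{hi!r}", node)
        if lo > hi:
            raise InvalidParameter(f"range {lo}:{hi} has lo > hi")
        return np.arange(int(lo), int(hi) + 1)
    if isinstance(expr, ast.UnaryOp):
        return -_eval(expr.operand, env, model, node)
    if isinstance(expr, ast.BinaryOp):
        left = _eval(expr.left, env, model, node)
        right = _eval(expr.right, env, model, node)
        try:
            if expr.op == "+":
                return left + right
            if expr.op == "-":
                return left - right
            if expr.op == "*":
                return left * right
            return left / right
        except Exception as exc:
            raise TypeMismatch(f"cannot evaluate {expr.op!r}: {exc}", node) from exc
    if isinstance(expr, ast.GeneratorCall):
        spec = model.registry.resolve(expr.name, {n for n, _ in expr.args}, node=node)
        if spec.kind == "generative":
            raise TypeMismatch(
                f"generative distribution {expr.name!r} cannot be used in an expression",
                node,
            )
        values = {n: _eval(v, env, model, node) for n, v in expr.args}
        return vectorize(spec, values, lambda i: None, node=node)
    if isinstance(expr, ast.MethodCall):
        target = _eval(expr.target, env, model, node)
        values = {n: _eval(v, env, model, node) for n, v in expr.args}
        return _call_method(model, target, expr.method, values, node)
    raise TypeMismatch(f"cannot evaluate expression {expr!r}", node)


def _call_method(model, target, method, values, node):
    if isinstance(target, (list, tuple)):
        try:
            spec = model.registry.resolve_method(target[0], method, node)
        except LPhyError:
            spec = None
        if spec is not None:  # broadcast the method over the vector
            results = [spec.func(t, values) for t in target]
            return _stack(results)
    spec = model.registry.resolve_method(target, method, node)
    return spec.func(target, values)


# ---------------------------------------------------------------------------
# Vectorization
# ---------------------------------------------------------------------------


def _stack(results: list):
    if all(isinstance(r, np.ndarray) for r in results) and len(
        {r.shape for r in results}
    ) == 1:
        return np.stack(results)
    if all(
        isinstance(r, (int, float, np.integer, np.floating)) and not isinstance(r, bool)
        for r in results
    ):
        return np.asarray(results)
    return list(results)


def vectorize(spec: GeneratorSpec, arg_values: dict, rng_factory, node: str | None = None):
    """Invoke ``spec`` with the two vectorization mechanisms resolved.

    ``rng_factory(i)`` supplies the random stream for replicate/broadcast
    element ``i`` (ignored by deterministic functions).  Returns a single
    value, or a stacked vector of values when vectorized.
    """
    values = dict(arg_values)
    replicates = values.pop("replicates", None)
    if replicates is not None:
        if not isinstance(replicates, (int, np.integer)) or replicates < 1:
            raise TypeMismatch(f"replicates must be a positive integer, got {replicates!r}", node)
        replicates = int(replicates)

    filled: dict[str, object] = {}
    broadcast: dict[str, list] = {}
    for p in spec.params:
        if p.name in values:
            v = values.pop(p.name)
            if matches(v, p.kind):
                filled[p.name] = v
            else:
                slices = split_major(v, p.kind)
                if slices is None:
                    raise TypeMismatch(
                        f"argument {p.name!r} of {spec.name!r} expects {p.kind}, "
                        f"got {type(v).__name__}",
                        node,
                    )
                broadcast[p.name] = slices
        elif p.required:
            raise TypeMismatch(f"missing required argument {p.name!r} of {spec.name!r}", node)
        elif p.default is not None:
            filled[p.name] = p.default
    if values:
        raise TypeMismatch(
            f"unknown argument(s) {sorted(values)} for {spec.name!r}", node
        )

    if replicates is not None and broadcast:
        raise BroadcastError(
            f"{spec.name!r}: 'replicates' cannot be combined with implicitly "
            f"vectorized argument(s) {sorted(broadcast)}",
            node,
        )

    if broadcast:
        lengths = {len(v) for v in broadcast.values()}
        if len(lengths) != 1:
            detail = ", ".join(f"{k}: {len(v)}" for k, v in sorted(broadcast.items()))
            raise BroadcastError(
                f"{spec.name!r}: vectorized arguments disagree on major dimension ({detail})",
                node,
            )
        k = lengths.pop()
        results = []
        for i in range(k):
            call_args = dict(filled)
            call_args.update({name: v[i] for name, v in broadcast.items()})
            results.append(spec.func(call_args, rng_factory(i)))
        return _stack(results)

    if replicates is not None:
        return _stack([spec.func(dict(filled), rng_factory(i)) for i in range(replicates)])

    return spec.func(filled, rng_factory(0))


# ---------------------------------------------------------------------------
# DOT export
# ---------------------------------------------------------------------------

_DOT_SHAPE = {"constant": "box", "deterministic": "diamond", "stochastic": "ellipse"}


def export_dot(model: GraphicalModel, hide_constants: bool = False) -> str:
    """Render the PGM as Graphviz DOT text: squares for constants, diamonds
    for deterministic nodes, ellipses for stochastic nodes; observed nodes
    are filled."""
    shown = {}
    for node in model.order:
        if node.name in model.data_shadows and node.block == "data":
            continue  # represented by the observed stochastic node
        if hide_constants and node.kind == "constant":
            continue
        shown[node.name] = node
    lines = ["digraph model {", "  rankdir=TB;"]
    for name, node in shown.items():
        attrs = [f"shape={_DOT_SHAPE[node.kind]}"]
        if node.observed:
            attrs.append("style=filled")
            attrs.append("fillcolor=lightgrey")
        lines.append(f'  "{name}" [{", ".join(attrs)}];')
    for name, node in shown.items():
        for parent in node.parents:
            if parent in shown:
                lines.append(f'  "{parent}" -> "{name}";')
    lines.append("}")
    return "\n".join(lines) + "\n"
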