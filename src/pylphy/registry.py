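"""Generator registry: the bridge between script-level generator names and
Python implementations.

A *generator* is anything that can appear on the right-hand side of a
statement: a generative distribution (used with ``~``) or a deterministic
function / method call (used with ``=``).  Each registered
:class:`GeneratorSpec` declares its argument names and types, which drives

* overload resolution (Java-style: overloads are distinguished by their
  argument-name sets),
* run-time type checking, and
* implicit vectorization — an argument declared scalar that receives a
  vector broadcasts the generator element-wise over that vector.

The registry is a plain runtime object, so extensions can add generators
(with their own narrative templates and citations) without touching the
interpreter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .errors import TypeMismatch, UnknownGenerator
from .seqsim import Alignment, ClockSpec, DataType
from .substmodels import RateMatrix
from .trees import MigrationMatrix, Taxa, TimeTree

__all__ = ["ParamSpec", "GeneratorSpec", "MethodSpec", "GeneratorRegistry"]

_NUMBER = (int, float, np.integer, np.floating)

_OBJECT_KINDS = {
    "taxa": Taxa,
    "tree": TimeTree,
    "ratematrix": RateMatrix,
    "alignment": Alignment,
    "migrationmatrix": MigrationMatrix,
    "datatype": DataType,
    "clock": ClockSpec,
}


def _is_number(v) -> bool:
    return isinstance(v, _NUMBER) and not isinstance(v, bool)


def _is_int(v) -> bool:
    return isinstance(v, (int, np.integer)) and not isinstance(v, bool)


def _is_number_vector(v) -> bool:
    if isinstance(v, np.ndarray):
        return v.ndim == 1 and v.dtype.kind in "if"
    if isinstance(v, (list, tuple)):
        return len(v) > 0 and all(_is_number(x) for x in v)
    return False


def matches(value, kind: str) -> bool:
    """Does ``value`` satisfy type ``kind`` without vectorization?"""
    if kind == "any":
        return True
    if kind == "number":
        return _is_number(value)
    if kind == "int":
        return _is_int(value)
    if kind == "string":
        return isinstance(value, str)
    if kind == "bool":
        return isinstance(value, bool)
    if kind in ("number_vector", "simplex"):
        return _is_number_vector(value)
    if kind == "int_vector":
        if isinstance(value, np.ndarray):
            return value.ndim == 1 and value.dtype.kind == "i"
        return isinstance(value, (list, tuple)) and all(_is_int(x) for x in value)
    if kind == "string_vector":
        if isinstance(value, np.ndarray):
            return value.ndim == 1
        return isinstance(value, (list, tuple)) and all(
            isinstance(x, (str, int, np.integer)) for x in value
        )
    if kind == "taxa":
        # a bare vector of names is accepted and coerced to contemporaneous taxa
        if isinstance(value, Taxa):
            return True
        if isinstance(value, np.ndarray):
            return value.ndim == 1
        return isinstance(value, (list, tuple)) and bool(value) and all(
            isinstance(x, (str, int, np.integer)) for x in value
        )
    cls = _OBJECT_KINDS.get(kind)
    if cls is not None:
        return isinstance(value, cls)
    raise ValueError(f"unknown parameter kind {kind!r}")


def split_major(value, kind: str):
    """If ``value`` is a vector of elements each matching ``kind``, return
    the list of elements (the broadcast slices); otherwise ``None``."""
    if kind in ("number", "int"):
        if isinstance(value, np.ndarray) and value.ndim == 1:
            return list(value)
        if isinstance(value, (list, tuple)) and value and all(_is_number(x) for x in value):
            return list(value)
        return None
    if kind in ("number_vector", "simplex", "int_vector"):
        if isinstance(value, np.ndarray) and value.ndim == 2:
            return [value[i] for i in range(value.shape[0])]
        if isinstance(value, (list, tuple)) and value and all(
            _is_number_vector(x) for x in value
        ):
            return [np.asarray(x, dtype=float) for x in value]
        return None
    cls = _OBJECT_KINDS.get(kind)
    if cls is not None and isinstance(value, (list, tuple)) and value:
        if all(isinstance(x, cls) for x in value):
            return list(value)
    return None


@dataclass
class ParamSpec:
    name: str
    kind: str = "any"
    required: bool = True
    default: object = None
    description: str = ""  # human-readable role, used by the narrative


@dataclass
class GeneratorSpec:
    """A callable generator with its signature and presentation metadata."""

    name: str
    kind: str  # "generative" | "function"
    params: list
    func: Callable  # func(values: dict, rng: Generator | None) -> value
    returns: str = ""  # human-readable description of the produced value
    citations: tuple = ()
    template: str = ""  # narrative sentence template (see narrative module)
    validate_observed: Callable | None = None  # (value, argvalues) -> None

    def param(self, name: str) -> ParamSpec | None:
        for p in self.params:
            if p.name == name:
                return p
        return None

    @property
    def param_names(self) -> set:
        return {p.name for p in self.params}

    @property
    def required_names(self) -> set:
        return {p.name for p in self.params if p.required}

    def accepts(self, argnames: set) -> bool:
        return self.required_names <= argnames <= self.param_names


@dataclass
class MethodSpec:
    """A dotted method call on a value (e.g. ``D.taxa()``)."""

    target_kind: str
    name: str
    func: Callable  # func(target, values: dict) -> value
    params: list = field(default_factory=list)
    returns: str = ""


class GeneratorRegistry:
    """Name -> overload set of generators, plus (type, name) -> methods."""

    def __init__(self):
        self._generators: dict[str, list[GeneratorSpec]] = {}
        self._methods: dict[tuple[str, str], MethodSpec] = {}

    # -- registration -----------------------------------------------------
    def register(self, spec: GeneratorSpec) -> GeneratorSpec:
        self._generators.setdefault(spec.name, []).append(spec)
        return spec

    def register_method(self, spec: MethodSpec) -> MethodSpec:
        self._methods[(spec.target_kind, spec.name)] = spec
        return spec

    def names(self):
        return sorted(self._generators)

    def overloads(self, name: str) -> list:
        return list(self._generators.get(name, ()))

    # -- resolution -------------------------------------------------------
    def resolve(self, name: str, argnames, node: str | None = None) -> GeneratorSpec:
        """Pick the overload whose signature accepts ``argnames`` (the
        ``replicates`` vectorization argument is handled by the engine and
        ignored here)."""
        overloads = self._generators.get(name)
        if not overloads:
            raise UnknownGenerator(f"unknown generator {name!r}", node)
        argnames = set(argnames) - {"replicates"}
        candidates = [s for s in overloads if s.accepts(argnames)]
        if not candidates:
            sigs = "; ".join(
                "(" + ", ".join(p.name for p in s.params) + ")" for s in overloads
            )
            raise TypeMismatch(
                f"no overload of {name!r} accepts arguments "
                f"({', '.join(sorted(argnames))}); known signatures: {sigs}",
                node,
            )
        # prefer the overload with the fewest unfilled optionals
        candidates.sort(key=lambda s: len(s.param_names - argnames))
        return candidates[0]

    def resolve_method(self, target, method: str, node: str | None = None) -> MethodSpec:
        for (kind, name), spec in self._methods.items():
            if name != method:
                continue
            cls = _OBJECT_KINDS.get(kind)
            if cls is not None and isinstance(target, cls):
                return spec
        raise UnknownGenerator(
            f"no method {method!r} for value of type {type(target).__name__}", node
        )
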