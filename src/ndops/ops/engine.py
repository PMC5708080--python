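"""Op registry and matching engine.

Ops are named, typed, prioritized operations registered as plugins. Callers
request an op by name plus argument values; the engine resolves the request to
the best registered implementation, inserting single-hop converters where an
argument is not directly assignable.

Matching total order (best first):

1. ``penalty`` ascending — the number of arguments that needed a converter;
   an exact-type candidate always beats a converter-assisted one;
2. ``specificity`` ascending — the summed type-hierarchy distance from each
   directly-assignable argument type to its parameter type (0 = exact), so
   the most specific implementation wins;
3. ``priority`` descending;
4. descriptor id ascending (deterministic tie-break; ties this deep are also
   logged as warnings).

Execution kinds: *function* ops return a fresh output and leave inputs
untouched; *computer* ops populate a caller-supplied output; *inplace* ops
overwrite a primary input. A *special op* is a resolved match bound to fixed
secondary arguments, reusable over varying primary inputs with no further
matching. Function-op results may optionally be memoized per context, keyed
by op id and a content digest of the arguments.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from ..containers import Dataset, Image
from ..errors import (
    ExecutionError, NdopsError, NoMatchError, RegistrationError, UnknownOpError,
)


@dataclass(frozen=True)
class Param:
    name: str
    type: type
    primary: bool = True


@dataclass(frozen=True)
class OpDescriptor:
    """A registered named, typed operation.

    ``func`` implements function-kind execution ``func(ctx, *args)``;
    ``computer``/``inplace`` optionally implement the other kinds (defaults
    copy the function result into the target). Primary params must precede
    secondary ones; ``arity`` is the primary count. ``chain`` names the ops a
    compositional op is built from (introspection only).
    """

    id: str
    name: str
    params: tuple
    output: type
    func: Callable
    priority: float = 0.0
    aliases: tuple = ()
    kinds: frozenset = frozenset({"function"})
    computer: Optional[Callable] = None
    inplace: Optional[Callable] = None
    chain: tuple = ()

    @property
    def arity(self) -> int:
        return sum(1 for p in self.params if p.primary)

    def __post_init__(self):
        seen_secondary = False
        for p in self.params:
            if not p.primary:
                seen_secondary = True
            elif seen_secondary:
                raise RegistrationError(
                    f"op {self.id}: primary params must precede secondary ones")

    def names(self):
        return (self.name, *self.aliases)


@dataclass(frozen=True)
class OpMatch:
    """Resolution result: descriptor plus per-argument conversion plan
    ("direct" or a converter id), penalty and specificity."""

    descriptor: OpDescriptor
    conversion_plan: tuple
    penalty: int
    specificity: int


def _hierarchy_distance(arg_type: type, param_type: type) -> int:
    mro = arg_type.__mro__
    if param_type in mro:
        return mro.index(param_type)
    return len(mro)  # assignable through an ABC: maximal distance


class SpecialOp:
    """A matched op bound to fixed secondary args, applied to varying primary
    inputs with zero further matching."""

    def __init__(self, service, match: OpMatch, fixed_args: tuple):
        self._service = service
        self.match = match
        self._fixed = fixed_args
        d = match.descriptor
        self.primary_types = tuple(
            p.type for p in d.params[:d.arity])
        self._primary_plan = match.conversion_plan[:d.arity]

    @property
    def arity(self) -> int:
        return self.match.descriptor.arity

    def __call__(self, *primaries):
        if len(primaries) != self.arity:
            raise TypeError(
                f"special op {self.match.descriptor.id} takes "
                f"{self.arity} primary inputs, got {len(primaries)}")
        resolved = []
        for value, ptype, plan in zip(primaries, self.primary_types,
                                      self._primary_plan):
            if plan == "direct":
                if not isinstance(value, ptype):
                    raise TypeError(
                        f"special op {self.match.descriptor.id}: input "
                        f"{value!r} is not a {ptype.__name__}")
                resolved.append(value)
            else:
                resolved.append(
                    self._service.ctx.convert.convert_with(plan, value))
        return self._service._execute(
            self.match.descriptor, tuple(resolved) + self._fixed)


class OpService:
    """Per-context op registry; see module docstring for matching rules."""

    KIND = "service.ops"

    def __init__(self, ctx=None):
        self.ctx = ctx
        self._ops: list[OpDescriptor] = []
        self._by_name: dict[str, list[OpDescriptor]] = {}
        self.match_count = 0          # instrumentation: resolutions performed
        self.exec_counts: dict[str, int] = {}
        self.memoize = False
        self._memo: dict = {}
        if ctx is not None:
            for payload in ctx.plugin_payloads("op"):
                for d in (payload if isinstance(payload, (list, tuple))
                          else [payload]):
                    self.register(d)

    def register(self, descriptor: OpDescriptor) -> int:
        if any(d.id == descriptor.id for d in self._ops):
            raise RegistrationError(f"op id {descriptor.id!r} already registered")
        self._ops.append(descriptor)
        for name in descriptor.names():
            self._by_name.setdefault(name, []).append(descriptor)
        return len(self._ops)

    def all(self) -> list[OpDescriptor]:
        return list(self._ops)

    # -- matching ----------------------------------------------------------

    def _candidate_match(self, d: OpDescriptor, arg_types) -> OpMatch | None:
        if len(d.params) != len(arg_types):
            return None
        plan = []
        penalty = 0
        specificity = 0
        for arg_type, p in zip(arg_types, d.params):
            if issubclass(arg_type, p.type):
                plan.append("direct")
                specificity += _hierarchy_distance(arg_type, p.type)
            else:
                converters = self.ctx.convert.converters_for_types(
                    arg_type, p.type) if self.ctx is not None else []
                if not converters:
                    return None
                plan.append(converters[0].id)
                penalty += 1
        return OpMatch(d, tuple(plan), penalty, specificity)

    def resolve(self, name: str, arg_types: Sequence[type],
                out_type: type | None = None) -> OpMatch:
        """Resolve a request to the best matching registered op."""
        self.match_count += 1
        candidates = self._by_name.get(name)
        if not candidates:
            raise UnknownOpError(f"no op registered under name {name!r}")
        arg_types = tuple(arg_types)
        matches = []
        near_misses = []
        for d in candidates:
            if out_type is not None and not issubclass(d.output, out_type):
                near_misses.append(f"{d.id}: output {d.output.__name__}")
                continue
            m = self._candidate_match(d, arg_types)
            if m is None:
                wanted = ", ".join(p.type.__name__ for p in d.params)
                near_misses.append(f"{d.id}({wanted})")
            else:
                matches.append(m)
        if not matches:
            given = ", ".join(t.__name__ for t in arg_types)
            raise NoMatchError(
                f"no registered {name!r} op accepts ({given}); "
                f"near misses: {near_misses}", near_misses=near_misses)
        matches.sort(key=lambda m: (m.penalty, m.specificity,
                                    -m.descriptor.priority, m.descriptor.id))
        if len(matches) > 1:
            a, b = matches[0], matches[1]
            if (a.penalty, a.specificity, a.descriptor.priority) == \
                    (b.penalty, b.specificity, b.descriptor.priority):
                if self.ctx is not None:
                    self.ctx.log.warn(
                        f"ambiguous match for {name!r}: picked "
                        f"{a.descriptor.id} over {b.descriptor.id} by id order")
        return matches[0]

    # -- execution ---------------------------------------------------------

    def _apply_plan(self, match: OpMatch, args):
        resolved = []
        for value, plan in zip(args, match.conversion_plan):
            if plan == "direct":
                resolved.append(value)
            else:
                resolved.append(self.ctx.convert.convert_with(plan, value))
        return tuple(resolved)

    def _execute(self, d: OpDescriptor, args):
        self.exec_counts[d.id] = self.exec_counts.get(d.id, 0) + 1
        try:
            return d.func(self.ctx, *args)
        except NdopsError:
            raise
        except Exception as exc:  # noqa: BLE001 - wrap op body failure
            raise ExecutionError(f"op {d.id} failed: {exc}", op_id=d.id) from exc

    def run(self, name: str, *args, out_type: type | None = None):
        """Resolve and execute as a function op: converters applied, fresh
        output, inputs unmodified."""
        match = self.resolve(name, tuple(type(a) for a in args), out_type)
        resolved = self._apply_plan(match, args)
        if self.memoize:
            key = (match.descriptor.id, _digest(resolved))
            if key in self._memo:
                return self._memo[key]
            result = self._execute(match.descriptor, resolved)
            self._memo[key] = result
            return result
        return self._execute(match.descriptor, resolved)

    def run_computer(self, name: str, output, *args):
        """Computer kind: populate ``output`` with the op result."""
        match = self.resolve(name, tuple(type(a) for a in args))
        d = match.descriptor
        resolved = self._apply_plan(match, args)
        if d.computer is not None:
            self.exec_counts[d.id] = self.exec_counts.get(d.id, 0) + 1
            d.computer(self.ctx, output, *resolved)
        else:
            _copy_samples(self._execute(d, resolved), output)
        return output

    def run_inplace(self, name: str, *args):
        """Inplace kind: overwrite the first primary input with the result."""
        match = self.resolve(name, tuple(type(a) for a in args))
        d = match.descriptor
        if "inplace" not in d.kinds:
            raise NoMatchError(f"op {d.id} has no inplace kind")
        resolved = self._apply_plan(match, args)
        if d.inplace is not None:
            self.exec_counts[d.id] = self.exec_counts.get(d.id, 0) + 1
            d.inplace(self.ctx, *resolved)
        else:
            _copy_samples(self._execute(d, resolved), resolved[0])
        return resolved[0]

    def instance(self, name: str, bound_types: Sequence[type],
                 constant_args: Sequence = ()) -> SpecialOp:
        """Match once, returning a reusable special op over the bound primary
        input types with the trailing arguments fixed."""
        constant_args = tuple(constant_args)
        arg_types = tuple(bound_types) + tuple(type(a) for a in constant_args)
        match = self.resolve(name, arg_types)
        d = match.descriptor
        fixed = []
        for value, plan in zip(constant_args,
                               match.conversion_plan[d.arity:]):
            fixed.append(value if plan == "direct"
                         else self.ctx.convert.convert_with(plan, value))
        return SpecialOp(self, match, tuple(fixed))

    def eval(self, expr: str, bindings: dict | None = None):
        from .expr import evaluate
        return evaluate(self.ctx, expr, bindings or {})


def _copy_samples(source, target) -> None:
    if isinstance(source, Image) and isinstance(target, Image):
        if source.shape != target.shape:
            raise ExecutionError(
                f"cannot copy result of shape {source.shape} into "
                f"target of shape {target.shape}")
        target.write_block((0,) * source.ndim, source.to_array())
        return
    raise ExecutionError(
        f"cannot copy a {type(source).__name__} result into a "
        f"{type(target).__name__} target")


def _digest(args) -> str:
    h = hashlib.sha1()
    for a in args:
        if isinstance(a, Dataset):
            a = a.image
        if isinstance(a, Image):
            h.update(b"img")
            h.update(a.sample_type.name.encode())
            h.update(repr(a.shape).encode())
            arr = a.to_array()
            try:
                h.update(np.ascontiguousarray(arr).tobytes())
            except (TypeError, ValueError):
                h.update(repr(arr.tolist()).encode())
        else:
            h.update(repr(a).encode())
        h.update(b"|")
    return h.hexdigest()


def checksum(image: Image) -> str:
    """Content digest of an image (purity instrumentation)."""
    return _digest((image,))
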