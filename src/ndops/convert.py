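"""Prioritized type-to-type converter registry.

Converters let a value of one type serve where another is expected — both
directly (``ctx.convert.convert(value, float)``) and automatically during op
matching and module input harvesting, which is what makes string flags,
numbers and image/dataset wrappers interchangeable at call sites.

Conversion is single-hop: a request is satisfied by identity, or by exactly
one registered converter; chains are never formed, so the cost of a match
stays well defined. When several converters apply, the highest priority wins,
with registration order breaking ties deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

from .containers import Dataset, Image, default_axes, wrap_dataset
from .errors import ConversionError


@dataclass(frozen=True)
class ConverterDescriptor:
    """A registered transform from one semantic type to another.

    ``accepts`` may refine applicability at the value level (e.g. only
    numeric strings parse to floats); ``apply`` receives the context so
    converters can use other services.
    """

    id: str
    from_type: type
    to_type: type
    priority: float
    apply: Callable
    accepts: Optional[Callable] = field(default=None)

    def accepts_value(self, value) -> bool:
        if not isinstance(value, self.from_type):
            return False
        if self.accepts is None:
            return True
        try:
            return bool(self.accepts(value))
        except Exception:  # noqa: BLE001 - predicate failure means "no"
            return False


class ConvertService:
    """Per-context converter registry, seeded from `converter` plugins."""

    KIND = "service.convert"

    def __init__(self, ctx=None):
        self.ctx = ctx
        self._converters: list[ConverterDescriptor] = []
        self.applied_log: list[str] = []   # instrumentation: converter ids used
        if ctx is not None:
            for c in ctx.plugin_payloads("converter"):
                self.register(c)

    def register(self, c: ConverterDescriptor) -> int:
        self._converters.append(c)
        return len(self._converters)

    def all(self) -> list[ConverterDescriptor]:
        return list(self._converters)

    def _ranked(self, candidates):
        order = {id(c): i for i, c in enumerate(self._converters)}
        return sorted(candidates, key=lambda c: (-c.priority, order[id(c)]))

    # -- type-level queries (used by op matching) --------------------------

    def converters_for_types(self, from_type: type, to_type: type):
        """Registered converters applicable to any value of ``from_type``
        yielding (a subtype of) ``to_type``, best first."""
        hits = [c for c in self._converters
                if issubclass(from_type, c.from_type)
                and issubclass(c.to_type, to_type)]
        return self._ranked(hits)

    # -- value-level API ---------------------------------------------------

    def can_convert(self, value, to_type: type) -> bool:
        if isinstance(value, to_type):
            return True
        return any(c.accepts_value(value) and issubclass(c.to_type, to_type)
                   for c in self._converters)

    def convert(self, value, to_type: type):
        """Identity when the value already has the target type; otherwise the
        best applicable registered converter, single hop."""
        if isinstance(value, to_type):
            return value
        candidates = self._ranked(
            [c for c in self._converters
             if c.accepts_value(value) and issubclass(c.to_type, to_type)])
        if not candidates:
            tried = [c.id for c in self._converters
                     if issubclass(c.to_type, to_type)]
            raise ConversionError(
                f"cannot convert {value!r} ({type(value).__name__}) to "
                f"{to_type.__name__}; candidates tried: {tried or 'none'}")
        chosen = candidates[0]
        self.applied_log.append(chosen.id)
        return chosen.apply(self.ctx, value)

    def convert_with(self, converter_id: str, value):
        """Apply one specific converter by id (op-match conversion plans)."""
        for c in self._converters:
            if c.id == converter_id:
                if not c.accepts_value(value):
                    raise ConversionError(
                        f"converter {converter_id} rejects value {value!r}")
                self.applied_log.append(c.id)
                return c.apply(self.ctx, value)
        raise ConversionError(f"no converter with id {converter_id!r}")


def can_convert(ctx, value, to_type) -> bool:
    return ctx.convert.can_convert(value, to_type)


def convert(ctx, value, to_type):
    return ctx.convert.convert(value, to_type)


# ---------------------------------------------------------------------------
# Built-in converters


def _parses_as(parser):
    def predicate(s):
        try:
            parser(s)
            return True
        except (ValueError, TypeError):
            return False
    return predicate


STR_TO_FLOAT = ConverterDescriptor(
    id="convert.str-to-float", from_type=str, to_type=float, priority=10,
    apply=lambda ctx, s: float(s), accepts=_parses_as(float))

STR_TO_INT = ConverterDescriptor(
    id="convert.str-to-int", from_type=str, to_type=int, priority=20,
    apply=lambda ctx, s: int(s), accepts=_parses_as(int))

STR_TO_BOOL = ConverterDescriptor(
    id="convert.str-to-bool", from_type=str, to_type=bool, priority=10,
    apply=lambda ctx, s: s.strip().lower() in ("1", "true", "yes", "on"),
    accepts=lambda s: s.strip().lower() in (
        "0", "1", "true", "false", "yes", "no", "on", "off"))

INT_TO_FLOAT = ConverterDescriptor(
    id="convert.int-to-float", from_type=int, to_type=float, priority=100,
    apply=lambda ctx, v: float(v))

FLOAT_TO_INT = ConverterDescriptor(
    id="convert.float-to-int", from_type=float, to_type=int, priority=5,
    apply=lambda ctx, v: int(v), accepts=lambda v: float(v).is_integer())

FLOAT_TO_COMPLEX = ConverterDescriptor(
    id="convert.float-to-complex", from_type=float, to_type=complex,
    priority=50, apply=lambda ctx, v: complex(v))

INT_TO_STR = ConverterDescriptor(
    id="convert.int-to-str", from_type=int, to_type=str, priority=10,
    apply=lambda ctx, v: str(v))

FLOAT_TO_STR = ConverterDescriptor(
    id="convert.float-to-str", from_type=float, to_type=str, priority=10,
    apply=lambda ctx, v: str(v))

# Image <-> Dataset wrapping is by reference: the dataset's image IS the
# wrapped image, so sample edits are visible through both views.
IMAGE_TO_DATASET = ConverterDescriptor(
    id="convert.image-to-dataset", from_type=Image, to_type=Dataset,
    priority=10,
    apply=lambda ctx, img: wrap_dataset(img, default_axes(img.ndim)))

DATASET_TO_IMAGE = ConverterDescriptor(
    id="convert.dataset-to-image", from_type=Dataset, to_type=Image,
    priority=10, apply=lambda ctx, ds: ds.image)

BUILTIN_CONVERTERS = (
    STR_TO_FLOAT, STR_TO_INT, STR_TO_BOOL, INT_TO_FLOAT, FLOAT_TO_INT,
    FLOAT_TO_COMPLEX, INT_TO_STR, FLOAT_TO_STR, IMAGE_TO_DATASET,
    DATASET_TO_IMAGE,
)
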