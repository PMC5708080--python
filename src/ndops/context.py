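"""Application container: plugin index, services, events, objects, preferences.

A :class:`Context` is a self-contained application instance. All runtime state
(which plugins are visible, service singletons, published objects, persisted
preferences) hangs off a context, so several independently configured instances
can coexist in one process without sharing mutable state.

Plugins are declared by :class:`PluginDescriptor` records, loaded either from a
tab-separated text manifest (one descriptor per line) or registered in-process.
Descriptors of one kind are totally ordered by (priority descending, id
ascending). Services are context singletons instantiated lazily on first
request; instantiation may itself request other services, and cycles are
detected and rejected.
"""

from __future__ import annotations

import importlib
import math
import os
import tempfile
from dataclasses import dataclass, field
from typing import Any, Callable, Iterable, Mapping

from .errors import (
    ConfigError,
    CycleError,
    ManifestParseError,
    ServiceLookupError,
)


@dataclass(frozen=True)
class PluginDescriptor:
    """A registered plugin: category, unique id, priority and a factory.

    ``factory`` is called as ``factory(context)`` for service kinds and with no
    regard to its return for payload kinds (converters, ops, formats, sample
    types), where it simply returns the payload object.
    """

    kind: str
    id: str
    priority: float
    factory: Callable[..., Any]
    attributes: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not math.isfinite(self.priority):
            raise ConfigError(f"plugin {self.id!r}: priority must be finite")


def _sort_key(d: PluginDescriptor):
    return (-d.priority, d.id)


class ObjectIndex:
    """Ordered index of published objects, queryable by type.

    The most recently added instance of a type is considered "active"
    (e.g. the active image consumed by module input harvesting).
    """

    def __init__(self):
        self._items: list[Any] = []

    def add(self, obj) -> None:
        self._items.append(obj)

    def remove(self, obj) -> None:
        self._items.remove(obj)

    def all(self) -> list:
        return list(self._items)

    def of_type(self, cls) -> list:
        return [o for o in self._items if isinstance(o, cls)]

    def active(self, cls):
        """Most recently added instance of ``cls``, or None."""
        for o in reversed(self._items):
            if isinstance(o, cls):
                return o
        return None

    def __len__(self):
        return len(self._items)


class PreferenceStore:
    """Flat ``key=value`` string map, optionally persisted to one file.

    Writes are atomic (temp file + rename). Keys are namespaced by the caller
    (module id dot parameter name, by convention).
    """

    def __init__(self, path: str | None = None):
        self._path = path
        self._data: dict[str, str] = {}
        if path is not None and os.path.exists(path):
            with open(path, "r", encoding="utf-8") as fh:
                for line in fh:
                    line = line.rstrip("\n")
                    if not line or line.startswith("#"):
                        continue
                    key, sep, value = line.partition("=")
                    if sep:
                        self._data[key] = value

    def get(self, key: str, default: str | None = None) -> str | None:
        return self._data.get(key, default)

    def put(self, key: str, value: str) -> None:
        self._data[key] = str(value)
        self._save()

    def remove(self, key: str) -> None:
        self._data.pop(key, None)
        self._save()

    def keys(self):
        return list(self._data)

    def _save(self) -> None:
        if self._path is None:
            return
        directory = os.path.dirname(os.path.abspath(self._path))
        os.makedirs(directory, exist_ok=True)
        fd, tmp = tempfile.mkstemp(dir=directory, prefix=".prefs.")
        try:
            with os.fdopen(fd, "w", encoding="utf-8") as fh:
                for key in sorted(self._data):
                    fh.write(f"{key}={self._data[key]}\n")
            os.replace(tmp, self._path)
        except BaseException:
            if os.path.exists(tmp):
                os.unlink(tmp)
            raise


class Log:
    """Minimal leveled message sink kept on the context."""

    LEVELS = ("debug", "info", "warn", "error")

    def __init__(self, level: str = "info"):
        self.level = level
        self.records: list[tuple[str, str]] = []

    def _emit(self, level, message):
        self.records.append((level, str(message)))

    def debug(self, message):
        self._emit("debug", message)

    def info(self, message):
        self._emit("info", message)

    def warn(self, message):
        self._emit("warn", message)

    def error(self, message):
        self._emit("error", message)

    def messages(self, level=None):
        return [m for (lv, m) in self.records if level is None or lv == level]


class Context:
    """One application instance; see module docstring."""

    def __init__(self, descriptors: Iterable[PluginDescriptor] = (),
                 prefs_path: str | None = None):
        self._index: dict[str, list[PluginDescriptor]] = {}
        self._services: dict[str, Any] = {}
        self._instantiating: list[str] = []
        self._subscribers: dict[type, list[Callable]] = {}
        self.objects = ObjectIndex()
        self.prefs = PreferenceStore(prefs_path)
        self.log = Log()
        self.console: list[str] = []   # textual output sink (module echo)
        self.echo = False              # mirror the console sink to stdout
        for d in descriptors:
            self.register_plugin(d)

    # -- plugin index ------------------------------------------------------

    def register_plugin(self, descriptor: PluginDescriptor) -> None:
        bucket = self._index.setdefault(descriptor.kind, [])
        for existing in bucket:
            if existing.id == descriptor.id:
                raise ConfigError(
                    f"duplicate plugin id {descriptor.id!r} for kind "
                    f"{descriptor.kind!r}: {existing} vs {descriptor}")
        bucket.append(descriptor)
        bucket.sort(key=_sort_key)

    def plugins_of(self, kind: str) -> list[PluginDescriptor]:
        """Descriptors of a kind, sorted by (priority desc, id asc)."""
        return list(self._index.get(kind, ()))

    def plugin_payloads(self, kind: str) -> list:
        """Factory products of every plugin of a kind, in priority order."""
        return [d.factory(self) for d in self.plugins_of(kind)]

    # -- services ----------------------------------------------------------

    def get_service(self, kind: str):
        """The singleton service of ``kind``; lazily built from the
        highest-priority descriptor."""
        if kind in self._services:
            return self._services[kind]
        descriptors = self.plugins_of(kind)
        if not descriptors:
            raise ServiceLookupError(f"no service registered for kind {kind!r}")
        if kind in self._instantiating:
            chain = " -> ".join(self._instantiating + [kind])
            raise CycleError(f"service dependency cycle: {chain}")
        self._instantiating.append(kind)
        try:
            instance = descriptors[0].factory(self)
        finally:
            self._instantiating.pop()
        self._services[kind] = instance
        return instance

    # Friendly accessors for the built-in services.
    @property
    def types(self):
        return self.get_service("service.types")

    @property
    def convert(self):
        return self.get_service("service.convert")

    @property
    def ops(self):
        return self.get_service("service.ops")

    @property
    def modules(self):
        return self.get_service("service.modules")

    @property
    def io(self):
        return self.get_service("service.io")

    # -- events ------------------------------------------------------------

    def subscribe(self, event_type: type, handler: Callable) -> None:
        self._subscribers.setdefault(event_type, []).append(handler)

    def unsubscribe(self, event_type: type, handler: Callable) -> None:
        self._subscribers.get(event_type, []).remove(handler)

    def publish(self, event) -> int:
        """Deliver ``event`` to subscribers of its type and every ancestor
        type, most-derived first. A failing subscriber is logged and delivery
        continues. Returns the number of subscribers invoked."""
        count = 0
        for cls in type(event).__mro__:
            if cls is object:
                continue
            for handler in list(self._subscribers.get(cls, ())):
                count += 1
                try:
                    handler(event)
                except Exception as exc:  # noqa: BLE001 - contract: log and go on
                    self.log.error(f"event subscriber {handler!r} failed: {exc}")
        return count


# ---------------------------------------------------------------------------
# Manifest handling


def _resolve_entry(entry: str):
    """Resolve a ``module:attr`` entry point lazily into a factory."""
    module_name, sep, attr = entry.partition(":")
    if not sep or not module_name or not attr:
        raise ManifestParseError(f"bad entry point {entry!r} (expected module:attr)")

    def factory(ctx=None, _cache=[]):
        if not _cache:
            module = importlib.import_module(module_name)
            _cache.append(getattr(module, attr))
        target = _cache[0]
        if isinstance(target, type):
            return target(ctx)
        return target

    return factory


def parse_manifest(text: str) -> list[PluginDescriptor]:
    """Parse manifest text: ``kind<TAB>id<TAB>priority<TAB>module:attr`` lines,
    ``#`` comments and blank lines ignored. Order of lines is preserved as
    registration order."""
    descriptors = []
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise ManifestParseError(
                f"expected 4 tab-separated fields, got {len(parts)}", line_no)
        kind, plugin_id, priority_text, entry = (p.strip() for p in parts)
        if not kind or not plugin_id:
            raise ManifestParseError("empty kind or id field", line_no)
        try:
            priority = float(priority_text)
        except ValueError:
            raise ManifestParseError(
                f"bad priority {priority_text!r}", line_no) from None
        descriptors.append(PluginDescriptor(
            kind=kind, id=plugin_id, priority=priority,
            factory=_resolve_entry(entry), attributes={"entry": entry}))
    return descriptors


def load_plugin_index(source) -> list[PluginDescriptor]:
    """Load descriptors from a manifest path, manifest text, or an iterable of
    already-built descriptors. Returns them in deterministic (declaration)
    order; duplicate (kind, id) pairs are rejected."""
    if isinstance(source, (list, tuple)):
        descriptors = list(source)
    elif isinstance(source, str) and "\t" not in source and os.path.exists(source):
        with open(source, "r", encoding="utf-8") as fh:
            descriptors = parse_manifest(fh.read())
    elif isinstance(source, str):
        descriptors = parse_manifest(source)
    else:
        raise ConfigError(f"unsupported plugin index source: {source!r}")
    seen = {}
    for d in descriptors:
        key = (d.kind, d.id)
        if key in seen:
            raise ConfigError(
                f"duplicate plugin id {d.id!r} for kind {d.kind!r}: "
                f"{seen[key]} vs {d}")
        seen[key] = d
    return descriptors


def builtin_manifest_path() -> str:
    return os.path.join(os.path.dirname(__file__), "resources",
                        "builtin_manifest.txt")


def build_context(descriptors: Iterable[PluginDescriptor] = (),
                  prefs_path: str | None = None) -> Context:
    """Build a context from explicit descriptors only (no built-ins)."""
    return Context(load_plugin_index(list(descriptors)), prefs_path=prefs_path)


def create_context(extra_descriptors: Iterable[PluginDescriptor] = (),
                   prefs_path: str | None = None) -> Context:
    """Build a context from the shipped built-in manifest plus extras."""
    descriptors = load_plugin_index(builtin_manifest_path())
    descriptors.extend(extra_descriptors)
    return Context(load_plugin_index(descriptors), prefs_path=prefs_path)
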