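"""Parameterized modules: typed inputs/outputs, script headers, and the
priority-ordered pre- and post-processing chains.

A module is an executable unit whose typed input and output parameters are
declared up front — either by a Python command callable with explicit
:class:`ParamSpec` records, or by a script whose header lines declare them:

    #@ string name
    #@ int age
    #@output string greeting
    greeting = "Hello " + name + "! You are " + age

Before the body runs, the *preprocessing chain* (plugins of kind
``preprocessor``, executed in descending priority) harvests inputs: provided
values are bound (with automatic conversion), persisted last-used values fill
gaps, the context's active image satisfies a single unresolved image input,
declared defaults apply, and any still-unresolved required input aborts with
a harvest error naming the parameter. After the body, the *postprocessing
chain* routes each output to the highest-priority display handler for its
type — headless, a textual echo for plain values and object-index
registration for images.

The built-in script language is the expression language extended with string
literals and ``+`` concatenation; each body line assigns ``name = expression``.
Other languages are plugin points (kind ``scriptlanguage``).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Callable, Optional

from .containers import Dataset, Image
from .errors import HarvestError, ModuleError, NdopsError, ParseError
from .ops.expr import evaluate, render

_NO_DEFAULT = object()

#: Semantic type labels accepted in script headers.
TYPE_LABELS = {
    "string": str, "str": str,
    "int": int, "integer": int,
    "float": float, "real": float, "double": float, "number": float,
    "bool": bool, "boolean": bool,
    "image": Image, "dataset": Dataset,
}


def resolve_type_label(label: str):
    try:
        return TYPE_LABELS[label]
    except KeyError:
        raise ParseError(f"unknown parameter type {label!r}") from None


@dataclass(frozen=True)
class ParamSpec:
    """One declared parameter: name, semantic type, direction and policy."""

    name: str
    semantic_type: type
    direction: str = "in"            # "in" | "out"
    required: bool = True
    default: object = _NO_DEFAULT
    persist_key: Optional[str] = None

    @property
    def has_default(self) -> bool:
        return self.default is not _NO_DEFAULT

    def __post_init__(self):
        if self.has_default and self.default is not None \
                and not isinstance(self.default, self.semantic_type):
            raise ParseError(
                f"default {self.default!r} for {self.name} is not a "
                f"{self.semantic_type.__name__}")


@dataclass
class ModuleInfo:
    """A parameterized executable unit: parameter specs plus a body, which is
    either a command callable ``body(ctx, inputs) -> outputs`` or a
    ``(language_id, script_text)`` pair."""

    id: str
    params: list
    body: object

    def __post_init__(self):
        names = [p.name for p in self.params]
        if len(names) != len(set(names)):
            raise ParseError(f"duplicate parameter name in module {self.id}")

    def inputs(self):
        return [p for p in self.params if p.direction == "in"]

    def outputs(self):
        return [p for p in self.params if p.direction == "out"]


def parse_script_header(text: str, module_id: str = "script",
                        persist: bool = True) -> ModuleInfo:
    """Parse ``#@ <type> <name>`` input and ``#@output <type> <name>`` output
    declarations; the remaining lines are the body."""
    params = []
    body_lines = []
    seen = set()
    for line_no, raw in enumerate(text.splitlines(), start=1):
        stripped = raw.strip()
        if stripped.startswith("#@output"):
            rest = stripped[len("#@output"):].split()
            direction = "out"
        elif stripped.startswith("#@"):
            rest = stripped[2:].split()
            direction = "in"
        else:
            body_lines.append(raw)
            continue
        if len(rest) != 2:
            raise ParseError(
                f"expected '<type> <name>', got {' '.join(rest)!r}",
                line_no=line_no)
        type_label, name = rest
        try:
            semantic_type = resolve_type_label(type_label)
        except ParseError as exc:
            raise ParseError(str(exc), line_no=line_no) from None
        if name in seen:
            raise ParseError(f"duplicate parameter {name!r}", line_no=line_no)
        seen.add(name)
        # Only plain values persist as last-used defaults; images do not.
        persist_key = f"{module_id}.{name}" \
            if (persist and direction == "in"
                and semantic_type in (str, int, float, bool)) else None
        params.append(ParamSpec(name, semantic_type, direction,
                                persist_key=persist_key))
    return ModuleInfo(module_id, params, ("ndo", "\n".join(body_lines)))


def load_script(path: str, persist: bool = True) -> ModuleInfo:
    module_id = os.path.splitext(os.path.basename(path))[0]
    with open(path, "r", encoding="utf-8") as fh:
        return parse_script_header(fh.read(), module_id, persist=persist)


# ---------------------------------------------------------------------------
# Pre-processing chain


@dataclass(frozen=True)
class Preprocessor:
    id: str
    priority: float
    process: Callable    # process(ctx, info, state) -> None


def _bind_provided(ctx, info, state):
    provided = state["provided"]
    for p in info.inputs():
        if p.name in provided and p.name not in state["resolved"]:
            value = provided[p.name]
            if not isinstance(value, p.semantic_type):
                value = ctx.convert.convert(value, p.semantic_type)
            state["resolved"][p.name] = value


def _load_persisted(ctx, info, state):
    for p in info.inputs():
        if p.name in state["resolved"] or p.persist_key is None:
            continue
        stored = ctx.prefs.get(p.persist_key)
        if stored is None:
            continue
        value = stored if p.semantic_type is str \
            else ctx.convert.convert(stored, p.semantic_type)
        state["resolved"][p.name] = value


def _inject_active_image(ctx, info, state):
    unresolved = [p for p in info.inputs()
                  if p.name not in state["resolved"]
                  and p.semantic_type in (Image, Dataset)]
    if len(unresolved) != 1:
        return  # ambiguous or nothing to do
    p = unresolved[0]
    active = ctx.objects.active(p.semantic_type)
    if active is None and p.semantic_type is Image:
        ds = ctx.objects.active(Dataset)
        active = ds.image if ds is not None else None
    if active is not None:
        state["resolved"][p.name] = active


def _fill_defaults(ctx, info, state):
    for p in info.inputs():
        if p.name not in state["resolved"] and p.has_default:
            state["resolved"][p.name] = p.default


def _check_required(ctx, info, state):
    for p in info.inputs():
        if p.required and p.name not in state["resolved"]:
            raise HarvestError(
                f"required input {p.name!r} of module {info.id!r} "
                f"could not be resolved", param=p.name)


PROVIDED_BINDER = Preprocessor("pre.provided-binder", 100, _bind_provided)
PERSISTED_DEFAULTS = Preprocessor("pre.persisted-defaults", 90, _load_persisted)
ACTIVE_IMAGE_INJECTOR = Preprocessor("pre.active-image", 80,
                                     _inject_active_image)
DECLARED_DEFAULTS = Preprocessor("pre.declared-defaults", 70, _fill_defaults)
REQUIRED_CHECK = Preprocessor("pre.required-check", 60, _check_required)

BUILTIN_PREPROCESSORS = (PROVIDED_BINDER, PERSISTED_DEFAULTS,
                         ACTIVE_IMAGE_INJECTOR, DECLARED_DEFAULTS,
                         REQUIRED_CHECK)


# ---------------------------------------------------------------------------
# Post-processing chain


@dataclass(frozen=True)
class DisplayHandler:
    id: str
    priority: float
    handles: Callable    # handles(value) -> bool
    handle: Callable     # handle(ctx, name, value) -> report string


def _display_text(ctx, name, value):
    line = f"{name} = {render(value)}"
    ctx.console.append(line)
    if ctx.echo:
        print(line)
    return f"text:{name}"


def _register_object(ctx, name, value):
    ctx.objects.add(value)
    return f"object-index:{name}"


TEXT_DISPLAY = DisplayHandler("post.text-display", 0,
                              handles=lambda value: True,
                              handle=_display_text)
OBJECT_REGISTRAR = DisplayHandler(
    "post.object-registrar", 10,
    handles=lambda value: isinstance(value, (Image, Dataset)),
    handle=_register_object)

BUILTIN_POSTPROCESSORS = (TEXT_DISPLAY, OBJECT_REGISTRAR)


# ---------------------------------------------------------------------------
# Module service


class ModuleService:
    """Runs modules through the pre/body/post pipeline."""

    KIND = "service.modules"

    def __init__(self, ctx):
        self.ctx = ctx
        self.last_trace: list[str] = []   # processor execution order

    def _chain(self):
        chain = list(self.ctx.plugin_payloads("preprocessor"))
        chain.sort(key=lambda p: (-p.priority, p.id))
        return chain

    def preprocess(self, info: ModuleInfo, provided: dict) -> dict:
        state = {"provided": dict(provided), "resolved": {}}
        self.last_trace = []
        for processor in self._chain():
            self.last_trace.append(processor.id)
            processor.process(self.ctx, info, state)
        return state["resolved"]

    def _run_script(self, info: ModuleInfo, inputs: dict) -> dict:
        language, text = info.body
        if language != "ndo":
            raise ModuleError(f"no script language {language!r} installed")
        env = dict(inputs)
        for line_no, raw in enumerate(text.splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            name, sep, expression = line.partition("=")
            if not sep:
                raise ParseError(
                    f"expected '<name> = <expression>', got {line!r}",
                    line_no=line_no)
            env[name.strip()] = evaluate(self.ctx, expression.strip(), env)
        outputs = {}
        for p in info.outputs():
            if p.name not in env:
                raise ModuleError(
                    f"script {info.id} never assigned output {p.name!r}")
            outputs[p.name] = env[p.name]
        return outputs

    def run(self, info: ModuleInfo, provided: dict | None = None) -> dict:
        """Harvest inputs, execute the body, persist last-used values, route
        outputs; returns the output map."""
        resolved = self.preprocess(info, provided or {})
        try:
            if callable(info.body):
                outputs = info.body(self.ctx, resolved)
            else:
                outputs = self._run_script(info, resolved)
        except NdopsError:
            raise
        except Exception as exc:  # noqa: BLE001 - wrap module body failure
            raise ModuleError(f"module {info.id} failed: {exc}") from exc
        for p in info.inputs():
            if p.persist_key is not None and p.name in resolved \
                    and isinstance(resolved[p.name], (str, int, float, bool)):
                self.ctx.prefs.put(p.persist_key, render(resolved[p.name]))
        self.postprocess(outputs)
        return outputs

    def postprocess(self, outputs: dict) -> list:
        handlers = list(self.ctx.plugin_payloads("postprocessor"))
        handlers.sort(key=lambda h: (-h.priority, h.id))
        report = []
        for name, value in outputs.items():
            for handler in handlers:
                if handler.handles(value):
                    report.append(handler.handle(self.ctx, name, value))
                    break
            else:
                self.ctx.log.warn(f"no display handler for output {name!r}")
        return report


def run_module(ctx, info: ModuleInfo, provided: dict | None = None) -> dict:
    return ctx.modules.run(info, provided)
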