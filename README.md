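# ndops

A headless, extensible N-dimensional image processing framework for
scientific imaging, written in Python. It is aimed at people who build image
analysis *infrastructure* — pipeline authors, tool developers, and anyone who
needs image algorithms that are agnostic of pixel type, dimensionality, and
storage layout — rather than at interactive end users.

The framework is organized as an application container plus a small set of
cooperating, plugin-extensible subsystems:

- **Plugin context** — a `Context` holds prioritized plugin registries, one
  singleton service per service kind, a typed object index, a hierarchical
  publish/subscribe event bus, and a persisted preference store. Two contexts
  share no mutable state, so independently configured instances can coexist
  in one process.
- **Sample types** — an extensible registry of 21 built-in pixel types, from
  1-bit booleans through `uint12`, 128-bit integers, IEEE reals, complexes
  and arbitrary-precision numbers, with saturating casts (round half-to-even)
  and a bit-packing codec that stores bounded integer samples MSB-first with
  no wasted bits: `uint12` data occupies 12 bits per sample instead of the 16
  a whole-byte container would use, a 33% gain in samples per byte.
- **Containers** — one access contract (coordinate reads/writes, row-major
  iteration, optional mask ROIs) over four layouts: a single buffer
  (`array`), one buffer per 2D plane (`planar`), a disk-backed LRU block
  cache (`cell`, a writeable virtual stack), and computed-on-demand
  (`function`), whose extents may reach 2^63−1. A `Dataset` attaches named,
  physically calibrated axes and per-channel LUT references.
- **Converters** — a prioritized, single-hop type conversion registry used
  directly and automatically during op matching and module harvesting
  (strings parse to numbers, images wrap to datasets by reference, ...).
- **Ops** — named, typed, prioritized operations resolved by a matching
  engine: candidates are ranked by conversion penalty, then type-hierarchy
  specificity, then priority, so the most specific implementation wins and
  exact-type ops always beat converter-assisted ones. Ops come in function /
  computer / inplace kinds, can be bound into reusable *special ops* that
  match once and run many times, and compose: the difference-of-Gaussians is
  literally `dog(I, σ₁, σ₂) = sub(gauss(I, σ₁), gauss(I, σ₂))`, the mean is
  `div(sum, size)`, and the `script.eval` op evaluates expressions such as
  `sub(gauss(image,2),gauss(image,1))` through the same dispatcher.
- **Modules** — executable units with declared typed inputs/outputs
  (`#@ int age`-style script headers or Python callables), harvested by a
  priority-ordered preprocessor chain (provided values → persisted last-used
  values → active image → declared defaults → required check) and routed by
  display handlers afterwards.
- **I/O** — locations, random-access data handles, magic-byte format
  detection, Netpbm PGM/PPM codecs with chunked row reading and canonical
  byte-exact writing, and the raw block store behind cell images.
- **CLI** — `ndops run <script> [--param value]…`, `ndops op <name> <args…>`,
  `ndops info`, with plugin-extensible argument handlers.

## Worked example

```python
import ndops

ctx = ndops.create_context()

img = ndops.make_fixture("noise", ndops.FLOAT64, (8, 7), seed=42)
dog = ctx.ops.run("image.dog", img, 2.0, 1.0)
same = ctx.ops.run("script.eval",
                   "sub(gauss(image,2),gauss(image,1))", {"image": img})
print((dog.to_array() == same.to_array()).all())   # True
print(ctx.ops.run("stats.mean", ndops.make_fixture("gradient",
                                                   ndops.UINT8, (1, 4))))
big = ndops.constant_image(ndops.UINT8, (50000, 50000), 1)
print(ctx.ops.run("stats.sum", big))
```

prints

```
True
1.5
2500000000
```

`True`: the expression evaluator dispatches through the same op registry as
the chained difference-of-Gaussians op, so the two pipelines are the same
computation. `1.5` is the mean of the gradient `[0,1,2,3]`, computed as
`sum/size`. The final line sums a 2.5-billion-sample virtual image blockwise
— only one ~1-Msample block is ever materialized.

From a shell:

```sh
$ ndops op math.add 2 3
result = 5
$ ndops run greet.ndo --name Alice --age 30
greeting = Hello Alice! You are 30
```

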