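# Methods

This note documents the models, contracts and numerical choices behind
`ndops`, including the places where the design space was genuinely open and a
rule had to be fixed.

## Application container

A `Context` is the unit of isolation: plugin index, service singletons,
object index, event subscriptions and preferences all live on it, and the
test suite asserts that operations on one context leave another observably
unchanged. Plugins are declared in a tab-separated text manifest
(`kind, id, priority, module:attr` per line) or registered in-process; the
shipped manifest (`src/ndops/resources/builtin_manifest.txt`) enumerates
every built-in service, sample type, converter, op, format and
pre/post-processor. Descriptors of one kind are totally ordered by priority
descending; **ties break by id ascending** — the ordering had to be total for
deterministic dispatch, and id order is the only intrinsic, stable key.

Services instantiate lazily on first request and may request other services
while initializing; a cycle in that dependency graph is detected and
reported rather than recursing. Event delivery walks the event class's
method-resolution order, most-derived subscribers first, synchronously and
on the calling thread (callers must not assume a delivery thread); a failing
subscriber is logged and delivery continues, so one broken observer cannot
starve the rest.

## Sample types and packing

The built-in registry ships 21 types. The exact catalogue is this package's
own approximation of a full production type system: all power-of-two
unsigned widths 1–128, signed 8–64, `uint12` (the natural width of many
scientific detectors), IEEE reals and complexes, a packed ARGB composite, a
1-bit boolean, and arbitrary-precision integer/decimal types.

Two rules are fixed where a choice had to be made:

- **Packing bit order** is big-endian, MSB-first, final byte zero-padded.
  This makes the packed form byte-compatible with naïve big-endian layouts
  for 8/16/32/64-bit types (verified against numpy's big-endian codecs) and
  gives a single unambiguous on-disk format for sub-byte and 12-bit data.
- **Real→integer casts round half-to-even** and saturate to the target
  bounds. Half-to-even avoids the systematic upward bias of half-up across
  repeated arithmetic, and is the IEEE default, so the pure-Python and
  vectorized numpy paths agree bit-for-bit.

## Containers

All layouts implement one contract: coordinate access, row-major iteration
with the **last dimension fastest**, and rectangular block reads. Iteration
order is fixed so op outputs and ROI streams are deterministic; the last-
fastest convention matches C/numpy order and the Netpbm raster order.
Coordinates are 0-based; ROI bounding boxes are closed intervals; writes
outside a type's range are rejected, not clamped — silent clamping on store
would make arithmetic saturation (an op-level policy) indistinguishable from
data corruption.

The `array` layout refuses plane sizes or totals of 2^31 samples or more and
directs callers to the `cell` layout. Cell images partition the image into
fixed-shape blocks, keep at most `capacity` blocks resident, and evict
**least-recently-used** blocks, persisting dirty ones to a block store (one
`cell_<index>.blk` file per block plus a `key=value` sidecar naming the
sample type and cell shape; bounded integer blocks are bit-packed, real and
complex blocks are stored as big-endian IEEE bytes, since the packing codec
is defined only for bounded integers). A never-written block reads back as
zeros. Eviction happens before admission, so residency never exceeds the
capacity even transiently; the suite asserts this via the `max_resident`
instrumentation counter.

Function-backed images compute samples from coordinates, are read-only, and
allow extents up to 2^63−1. They optionally vectorize rectangular reads
(`block_fn`), which is what keeps reductions over a 50,000×50,000 constant
image at one ~2^20-sample block of peak memory: statistics iterate blocks of
at most 2^20 samples, chosen as a balance between numpy efficiency and
footprint (8 MB of float64 per block).

Planar images hold one buffer per 2D plane of the first two dimensions;
remaining dimensions are linearized row-major.

### Synthetic fixtures

`make_fixture` generates the four deterministic test patterns used
throughout the suite: constant, gradient (row-major index modulo the type's
range), impulse, and seeded uniform noise (integers over the full type range
for integer types; reals in [0, 100)). These probe value propagation, order
sensitivity, point-spread behaviour and saturation, but they are *not*
natural images: they carry no spatial correlation, optics, or acquisition
noise model. Passing tests therefore demonstrate contract correctness
(layout transparency, purity, composition, round-trips) — not
application-level analysis quality on real microscopy data.

## Converters

Conversion is **single-hop**: identity, or exactly one registered converter.
Transitive chains would make the cost of an op match ill-defined (is a
two-hop exact chain better than a one-hop lossy one?) and search quadratic;
every shipped conversion need is expressible in one hop. When several
converters apply, priority decides, then registration order. Image↔Dataset
conversion wraps by reference, so edits through either view stay coherent
and no pixel copies occur.

## Op matching

A request (name, argument types) is scored against every same-name,
same-arity candidate:

1. **penalty** — number of arguments needing a converter (ascending);
2. **specificity** — summed MRO distance of directly-assignable argument
   types to their parameter types (ascending; 0 = exact);
3. **priority** (descending);
4. **descriptor id** (ascending).

Penalty dominates specificity so an exact-type op always beats a
converter-assisted one — the alternative (specificity first) could silently
insert conversions in front of a more general exact implementation. A tie
that survives priority resolves by id order *with a logged warning* rather
than a hard error: ambiguous registries are a packaging bug, but scripts
should keep running deterministically while it is fixed. An exhaustive
brute-force scorer over generated registries (≤ 8 ops, ≤ 3 argument types,
with and without converters) is the oracle for this total order in both the
test suite and the acceptance script.

Function-kind ops return fresh outputs and never mutate inputs (checked by
content digests); computer and inplace kinds fill a preallocated output or
overwrite the first primary input, and all kinds of one op produce identical
values. Special ops bind a resolved match plus fixed secondary arguments and
apply it to varying primary inputs with zero further matching (the
`match_count` instrumentation makes this testable). Memoization is off by
default and opt-in per context; the cache key is (op id, content digest of
arguments), so it is safe exactly because function ops are pure.

Arithmetic policy: results saturate to the output sample type via the same
half-to-even clamp as the cast layer; integer image division divides in real
arithmetic first, then rounds. Division by a zero sample raises a domain
error naming the coordinate for *all* sample types (reals included) —
returning IEEE infinities for reals but erroring for integers would make
layout/kind equivalence type-dependent. Generic (per-sample) and
array-optimized (vectorized) registrations compute integer paths in exact
arbitrary precision and real paths in IEEE double, so specialization never
changes values.

The Gaussian filter uses a sampled (not integrated) Gaussian normalized to
sum 1, radius `max(1, ceil(3σ))`, mirror boundary (reflection without edge
repetition), applied separably per axis; σ = 0 is an exact copy. Sampling,
radius and boundary are all free choices here; 3σ captures > 99.7% of the
kernel mass and mirror boundaries avoid edge darkening on constant images
(a constant stays constant to ≤ 1e−9). The separable pass is delegated to
`scipy.ndimage.correlate1d`; the test oracle is an independent dense
convolution with explicit mirror indexing. The difference-of-Gaussians is
deliberately implemented as a chain of two `filter.gauss` calls and one
`math.sub` — its identity with the manual pipeline is an exact, not
approximate, property. Accelerator-specific op variants (GPU/cluster) exist
only as the priority-based registration extension point.

## Modules

The `#@ <type> <name>` / `#@output <type> <name>` header dialect declares
parameters; the remainder of the file is the body. The single built-in
script language is the expression language (see `docs/eval.md`) extended
with string literals and `+`-concatenation, one `name = expression`
statement per line; other languages are plugin points only. Input
persistence is keyed per (module id, parameter name) in the context
preference store and applies to plain values (strings, numbers, booleans) —
images are not persisted. The active-image injector fires only when exactly
one image-typed input is unresolved; with several, guessing an assignment
would be worse than failing the harvest.

## I/O

Format detection prefers leading magic bytes over filename suffixes (ties:
priority, then name). Netpbm readers produce (height, width[, 3]) datasets
with axes [Y, X(, CHANNEL)] so that row-major iteration equals raster order;
binary rasters are read in configurable row chunks (default 64 rows), and
the suite verifies chunk-size independence. Writers emit the canonical
header (single `\n` separators, no comments), making re-writes byte
identical. Maxval ≤ 255 maps to `uint8`, ≤ 65535 to big-endian `uint16`.
`bytes:<name>` locations resolve to a process-wide named buffer registry so
independent handles observe each other's writes, mirroring file semantics;
they exist for tests and in-memory pipelines.

## Problem sizes

The default verification sizes are: 50 seeded fixtures of 6×5 samples for
layout transparency, 100 for kind equivalence, generated matching registries
totalling a few thousand resolution requests, a 1024×1024 image in 64×64
cells with capacity 4 for the write-back cache, a 50,000×50,000 virtual
constant image for the blockwise reduction, and 50 Netpbm round-trip
fixtures. These sizes exercise every contract (multiple cells per dimension,
thousands of evictions, multi-block reductions) while keeping the full suite
and the acceptance script fast enough to run routinely.

## Known limitations

- ROIs are mask predicates over bounding boxes; there is no ROI algebra or
  serialization.
- No rendering, color blending, coordinate transforms or pyramids; LUTs are
  stored as metadata only.
- Formats ship for Netpbm only; TIFF/compressed formats and remote locations
  are out of scope (the format/location registries are the extension point).
- The op library is a compact core (~40 registrations), not a full
  production catalogue; namespaces such as thresholding and morphology are
  absent by design.
- Arbitrary-precision types support storage and retrieval; no extended
  arithmetic or color-space math for the ARGB composite.
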