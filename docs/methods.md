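# Methods

## The monitoring problem

In a flash X-ray imaging (FXI) experiment, aerosolized particles are
injected into the focus of an X-ray free-electron laser and a pixel
detector records one far-field diffraction frame per pulse, at repetition
rates of order 100 Hz. Most frames are blanks; the operator's immediate
questions — is the particle stream intersecting the beam? is the hit rate
worth keeping? are the detector corrections sane? — must be answered from
the live stream, not offline. `fxmon` is a client–server pipeline for this:
workers translate native events into a common structure, correct each
frame, score it with a lit-pixel hit finder, and publish plot messages that
any number of buffering clients can subscribe to.

## Event model

All data belonging to one pulse is an *event*: a two-level mapping from a
data-type label (`photonPixelDetectors`, `FEL`, `analysis`, …) and a data
key to a record with `name = "<type>/<key>"`, a kind (`image`/`vector`/
`scalar`, inferred from payload dimensionality) and a unit string. Analysis
stages append their outputs as new `analysis`-type records, so the event is
the only interface between stages. Key enumeration is insertion-ordered.
Event ids are `(run_index, frame_index)` pairs, lexicographically ordered;
synthetic sources have no facility timestamps or fiducials to use instead.

## Source translation and work partition

File sources use an HDF5 run dialect (`/entry/data/frames`,
`/entry/data/timestamps`, optional truth and pulse-energy datasets). With
`W` workers, worker `i` reads global frames `i, i+W, i+2W, …` — a
round-robin partition chosen over file-level sharding because it stays
balanced for heterogeneous file sizes. Each frame is delivered to exactly
one worker, exactly once, and translation is lossless (integer ADU are kept
bit-exact until dark subtraction). Ground-truth datasets are deliberately
*not* exposed as event records, so the processing chain cannot peek at the
answer.

Live sources model a DAQ shared-memory feed: a depth-1 most-recent-event
buffer on the consumer, where frames arriving while the consumer is busy
are silently dropped. This is intentionally lossy — monitoring wants the
freshest event, not a backlog. A timeout yields a distinct "source idle"
signal rather than end-of-stream. Workers do not deduplicate live events;
the DAQ is assumed to multiplex distinct events to distinct consumers.

## Detector corrections and hit finding

For a raw frame `F` (integer ADU), the per-event chain is:

1. **Dark subtraction.** `S = F − D` in float64, where the dark image `D`
   is the plain per-pixel mean of a dark run (no outlier rejection).
   Accumulation keeps `(Σframes, count)` per worker; the master merges by
   summing both fields, so the result is independent of frame order and of
   how frames are split across workers (asserted to 1e-10 relative; in
   practice the merged mean matches a stack-and-mean oracle to < 1e-9 ADU).
   Negative values are kept — clipping would bias the noise statistics.
2. **Common-mode correction.** pnCCD-style readouts add a per-row offset
   that fluctuates frame to frame. Per detector row, the offset is
   estimated as the **median of the unlit pixels** (values below a signal
   mask threshold) and subtracted from the whole row. The median is used
   instead of the mean for robustness to residual signal; the mask keeps
   genuine photon signal out of the estimate entirely. If fewer than 10% of
   a row's pixels are unlit, the full-row median is used (a masked estimate
   on a handful of pixels would be noisier than the bias it avoids). The
   mask threshold is a separate knob from the lit threshold, defaulting to
   `lit_threshold / 2`. Rows are whole detector rows; no quadrant
   segmentation is modelled. Correction is applied on the raw frame grid,
   before any geometry handling.
3. **Lit-pixel hit finder.** A pixel is *lit* when its corrected value is
   **strictly greater** than `lit_threshold`; the **hitscore** is the lit
   count, and a frame is a **hit** when `hitscore ≥ hitscore_threshold`
   (inclusive). Strict-then-inclusive is fixed so every boundary case is
   decidable. These two thresholds are the live tunables: the operator
   places the lit threshold in the valley between the noise peak and the
   single-photon peak of the ADU histogram, and the hitscore threshold
   above the blank-frame score level.
4. **ADU histogram.** Equal-width half-open bins over `[lo, hi)` with the
   last bin closed (numpy convention); out-of-range pixels are excluded
   from counts but reported as a total, so pixel number is conserved.

### Numerical choices

- All corrections in 64-bit floats; raw ADU stay integer until subtraction.
- Median of an even count is the midpoint of the two central values. A
  consequence: re-running the common-mode correction is bit-exactly
  idempotent when the median is an order statistic (odd unlit count), but
  only idempotent to ~1e-15 ADU for even counts, where the midpoint
  `(a+b)/2` re-estimates to one rounding error rather than exactly zero.
- Degenerate rows (nothing unlit) fall back to the full-row median; no
  special-casing beyond that.
- The backend itself uses no randomness; all stochasticity lives in the
  synthetic generator.

## Synthetic runs and what they do (not) show

The generator emulates the statistical skeleton of a pnCCD commissioning
dataset, with known ground truth:

| parameter            | default   | meaning                                    |
|----------------------|-----------|--------------------------------------------|
| shape                | 256×256   | detector pixels (rows = common-mode axis)  |
| pedestal             | U[90,110] | per-pixel baseline, drawn once (ADU)       |
| read_noise_sigma     | 3 ADU     | per-pixel Gaussian read noise              |
| common_mode_sigma    | 5 ADU     | sd of the per-row, per-frame offset        |
| photon_adu           | 120 ADU   | deposit per photon (single gain)           |
| saturation           | 65535     | clip level (16-bit)                        |
| hit_fraction         | 0.1       | fraction of frames carrying a particle     |
| photons_per_hit_mean | 500       | Poisson mean of photons per hit frame      |

Hit frames are the first `⌈hit_fraction·n⌉` entries of a seeded
permutation; each receives `K ~ Poisson(mean)` photons placed at pixels
drawn from a centro-symmetric `1/(1+(r/r₀)³)` radial profile (`r₀` =
detector size / 8) — the qualitative shape of forward scattering, not a
physical form factor. The model enforces `photon_adu > 5·read_noise_sigma`
so the planted truth is recoverable in principle; with the defaults, a lit
threshold at `photon_adu/2 = 60` ADU sits ~20 read-noise sigmas from both
peaks, which is why perfect precision/recall on synthetic runs is the
*correctness* bar, not a *performance* claim. Real data adds everything the
generator omits: charge sharing and split events across pixel boundaries,
gain nonuniformity, bad pixels, saturation tails, structured backgrounds
and beamline stray light. Passing here shows the plumbing and the
estimators are right, not that these thresholds would work untouched at a
beamline.

Generation is fully deterministic: the same `(model, recipe)` pair yields a
byte-identical HDF5 file (object timestamps disabled).

## Streaming and clients

Messages are self-describing: a JSON header (source name, plot kind, event
id, plot instructions — labels, limits, log flag, colormap, marker lines,
footer text) plus raw little-endian array bytes with declared dtype/shape,
so image payloads survive the round trip bit-exactly. Pub/sub semantics
throughout: topic = source name, no delivery guarantee to unsubscribed or
slow clients, bounded per-client send queues that drop oldest (freshness
over completeness), and publishing never blocks event processing. The TCP
channel filters on the publisher side, so unsubscribing stops traffic at
the source. History plots send one scalar per event; the trend accumulates
client-side in a per-source buffer that can be resized at any time,
retaining the most recent items. Clients are expected to redraw on their
own period (2 s default) from the newest buffered state; rendering never
back-pressures the backend. The backend re-broadcasts its source catalog
(derived from the output declarations) periodically, so late-joining
clients can populate their source tables without touching frontend code.

Every worker may publish to one fan-in endpoint; a client connected to any
single worker (e.g. the master) sees a consistent stream of that worker's
share.

## Backend, configuration, reload

The stage chain is declarative (YAML): a source section, an ordered stage
list drawn from a registry (extensible from Python via `register_stage`),
output declarations (which record, what plot kind, always vs hits-only),
and a path to a separate parameters file holding the numeric tunables.
Unknown stage names are rejected at load time by name. Reload — via
`request_reload()`, SIGHUP, or `fxmon reload --pid` — re-reads *only* the
parameters file at the next event boundary: events after the barrier use
the new thresholds, the chain structure never changes mid-run, and an
unreadable or invalid file leaves the old parameters in force with a
warning. A failing event is logged with its event id and skipped.

The serial executor interleaves all workers in one process in global frame
order (deterministic; supports live channels and stepping). The process
executor forks one OS process per worker; workers return results and dark
accumulators for the master to merge. Per-event results are identical for
any worker count on file runs.

### Throughput metric

The process executor reports events per second as total events divided by
the busiest worker's event-loop **CPU time** (process startup and
source-open excluded). On a host with at least one core per worker this
equals the wall-clock rate; on an oversubscribed host, a worker's wall
time includes its peers' turns on the CPU, which says nothing about the
backend. The CPU-time form measures what worker scaling is about — a
balanced exactly-once partition and per-event cost that does not grow with
`W` — independently of how many cores the machine happens to have.
Scaling checks compare best-of-3 measurements with a 5% scheduling-noise
margin and assert only monotone non-decrease, never absolute rates, which
are hardware-dependent.

## Problem sizes used by the test suite and acceptance script

Dark calibration is checked on a 10 000-frame default-model run against a
stack-and-mean oracle (< 1e-9 ADU, worker counts 1/2/4); truth recovery on
a 1000-frame run with 10% hits; hit-finder exactness on 1000 random 64×64
frames against a pure-Python count; reload and streaming contracts on
runs of 50–1000 frames; the scaling smoke on a 240-frame run. These sizes
give tight statistical checks while keeping a full suite run in the
low minutes.

## Known limitations

- No facility-native translators (XTC/psana, Karabo); the HDF5 run dialect
  and the TCP live stream are the only sources.
- Single-gain photon model; no charge sharing, gain maps, or bad-pixel
  masks — and therefore no gain calibration stage.
- Common mode is per full row; detectors with quadrant readout would need
  a segmented variant.
- No size filtering, multiple-hit filtering, or scanning (STXM) analyses.
- The headless client buffers and logs; it does not render. Plot
  instructions (markers, colormaps, log flags) travel with the messages
  for any GUI that wants to draw them.
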