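"""The monitoring server: workers, stage chain, publishing, hot reload.

A backend run is a master plus ``W − 1`` slave workers (the master, rank 0,
is itself a processing worker and additionally owns accumulator merging and
catalog announcement).  Each worker opens its own interleaved cursor into
the common source, applies the configured stage chain to every event, and
publishes the declared outputs.  Per-event results (hitscore, hit flag)
depend only on the event, never on the worker count or ordering, so any
``W`` produces identical results on a file run.

Two executors are available:

``serial``
    All workers run in one process, interleaved in global frame order.
    Supports live channels, hot reload and stream sources; used by the CLI
    for single-process runs and by anything that needs deterministic
    stepping.

``process``
    One OS process per worker (``multiprocessing``, fork).  Workers return
    their results and accumulators to the master for merging.  Plot
    publishing is disabled in this mode unless each worker is given its own
    channel via ``channel_factory`` (e.g. TCP publishers to one fan-in
    endpoint).

A failing event is logged with its event id and skipped: monitoring must
not die on one bad frame.

Reloading re-reads only the parameters file; the stage chain itself never
changes mid-run.  The reload barrier falls at an event boundary: every
event processed after it uses the new parameters, everything before keeps
the old ones.  An unreadable or invalid parameters file leaves the old
parameters in force (with a logged warning).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Tuple

import numpy as np

from .analysis import (
    DarkAccumulator,
    classify_hit,
    common_mode_correct,
    count_lit_pixels,
    dark_accumulate,
    dark_finalize,
    dark_merge,
    dark_subtract,
    frame_histogram,
    read_dark_file,
    write_dark_file,
)
from .config import (
    ConfigError,
    OutputSpec,
    Parameters,
    PipelineConfig,
    StageSpec,
    load_parameters,
    register_stage,
)
from .data_sources import (
    END_OF_STREAM,
    SOURCE_IDLE,
    SourceSpec,
    next_event,
    open_source,
)
from .event_model import Event, RecordAbsentError, add_record, get_record
from .streaming import (
    CatalogEntry,
    PlotInstructions,
    PlotMessage,
    SourceCatalog,
    announce_catalog,
    publish,
)

__all__ = [
    "WorkerRole",
    "RunReport",
    "BackendRunner",
    "run_backend",
    "dark_pipeline_config",
    "diffraction_pipeline_config",
]

log = logging.getLogger("fxmon.backend")


@dataclass(frozen=True)
class WorkerRole:
    rank: int

    @property
    def is_master(self) -> bool:
        return self.rank == 0


@dataclass
class RunReport:
    """Master's end-of-run summary."""

    n_workers: int
    events_per_worker: List[int]
    results: List[Tuple[Tuple[int, int], Optional[int], Optional[bool]]]
    n_hits: int = 0
    n_errors: int = 0
    n_messages: int = 0
    dark_path: Optional[str] = None
    elapsed_s: float = 0.0

    @property
    def n_events(self) -> int:
        return sum(self.events_per_worker)

    @property
    def events_per_second(self) -> float:
        return self.n_events / self.elapsed_s if self.elapsed_s > 0 else float("inf")

    def sorted_results(self):
        return sorted(self.results, key=lambda r: r[0])


# ---------------------------------------------------------------------------
# Built-in stages
# ---------------------------------------------------------------------------

class StageContext:
    """Per-worker mutable state threaded through the stage chain."""

    def __init__(self, config: PipelineConfig, params: Parameters):
        self.detector_key = config.source.detector_key
        self.params = params
        self.accumulator = DarkAccumulator()
        self.dark: Optional[np.ndarray] = None
        self.dark_out: Optional[str] = None
        self.histogram_edges: Optional[np.ndarray] = None
        for st in config.stages:
            if st.name == "dark_accumulate" and "dark_out" in st.options:
                self.dark_out = str(st.options["dark_out"])
            if st.name == "dark_subtract":
                dark_file = st.options.get("dark_file")
                if dark_file is None:
                    raise ConfigError("dark_subtract stage needs a dark_file option")
                try:
                    self.dark, _, _ = read_dark_file(str(dark_file))
                except OSError as exc:
                    raise ConfigError(
                        f"cannot start: dark file {dark_file!r} unreadable ({exc})"
                    ) from exc

    def raw_frame(self, evt: Event) -> np.ndarray:
        return get_record(evt, "photonPixelDetectors", self.detector_key).data

    def working_frame(self, evt: Event) -> np.ndarray:
        """Corrected frame if the chain produced one, else the raw frame."""
        try:
            return get_record(evt, "analysis", "corrected").data
        except RecordAbsentError:
            return self.raw_frame(evt)


@register_stage("dark_accumulate")
def _stage_dark_accumulate(evt: Event, ctx: StageContext) -> None:
    dark_accumulate(ctx.accumulator, ctx.raw_frame(evt))


@register_stage("dark_subtract")
def _stage_dark_subtract(evt: Event, ctx: StageContext) -> None:
    assert ctx.dark is not None
    corrected = dark_subtract(ctx.raw_frame(evt), ctx.dark)
    add_record(evt, "analysis", "corrected", corrected, "ADU")


@register_stage("common_mode")
def _stage_common_mode(evt: Event, ctx: StageContext) -> None:
    corrected = common_mode_correct(
        ctx.working_frame(evt), ctx.params.effective_mask_threshold
    )
    add_record(evt, "analysis", "corrected", corrected, "ADU")


@register_stage("histogram")
def _stage_histogram(evt: Event, ctx: StageContext) -> None:
    counts, edges, _ = frame_histogram(ctx.working_frame(evt), ctx.params.histogram_spec())
    ctx.histogram_edges = edges
    add_record(evt, "analysis", "histogram", counts, "pixels")


@register_stage("hitscore")
def _stage_hitscore(evt: Event, ctx: StageContext) -> None:
    score = count_lit_pixels(ctx.working_frame(evt), ctx.params.hit_finder())
    add_record(evt, "analysis", "hitscore", score, "lit pixels")


@register_stage("classify")
def _stage_classify(evt: Event, ctx: StageContext) -> None:
    score = get_record(evt, "analysis", "hitscore").data
    add_record(evt, "analysis", "is_hit", int(classify_hit(score, ctx.params.hit_finder())))


# ---------------------------------------------------------------------------
# Reference pipeline configurations
# ---------------------------------------------------------------------------

def dark_pipeline_config(run_files: List[str], dark_out: str) -> PipelineConfig:
    """Dark-calibration pipeline: accumulate dark frames, save the average."""
    return PipelineConfig(
        source=SourceSpec("file_run", list(run_files)),
        stages=[StageSpec("dark_accumulate", {"dark_out": dark_out})],
        outputs=[],
    )


def diffraction_pipeline_config(
    run_files: List[str],
    dark_file: str,
    parameters: Optional[Parameters] = None,
    parameters_path: Optional[str] = None,
) -> PipelineConfig:
    """Hit-finding pipeline with the three standard monitoring plots.

    Per event: dark subtraction → row common-mode correction → ADU
    histogram (published with the lit threshold as a vertical marker) →
    hitscore (published as a history plot with the hitscore threshold as a
    horizontal marker) → hit classification → corrected frame published as
    "hit image" for hits only.
    """
    return PipelineConfig(
        source=SourceSpec("file_run", list(run_files)),
        stages=[
            StageSpec("dark_subtract", {"dark_file": dark_file}),
            StageSpec("common_mode"),
            StageSpec("histogram"),
            StageSpec("hitscore"),
            StageSpec("classify"),
        ],
        outputs=[
            OutputSpec("histogram", "histogram", "analysis/histogram"),
            OutputSpec("hitscore", "history", "analysis/hitscore"),
            OutputSpec("hit image", "image", "analysis/corrected", when="hits_only"),
        ],
        parameters=parameters or Parameters(),
        parameters_path=parameters_path,
    )


def build_catalog(config: PipelineConfig, params: Parameters) -> SourceCatalog:
    """Derive the announced source catalog from the output declarations."""
    entries = []
    for out in config.outputs:
        instr = PlotInstructions()
        if out.kind == "histogram":
            instr.vline = params.lit_threshold
            instr.xlabel = "ADU"
            instr.log_scale = True
        elif out.kind == "history":
            instr.hline = float(params.hitscore_threshold)
            instr.ylabel = "hitscore"
        entries.append(CatalogEntry(out.name, out.kind, instr))
    return SourceCatalog(entries)


# ---------------------------------------------------------------------------
# Serial runner
# ---------------------------------------------------------------------------

class BackendRunner:
    """Serial executor: all workers interleaved in one process.

    Processes events in global frame order by cycling the worker cursors,
    which makes reload barriers and tests deterministic.  ``run()`` may be
    called with ``max_events`` to step a run in phases (e.g. reload between
    phases); state persists across calls.
    """

    def __init__(
        self,
        config: PipelineConfig,
        n_workers: int = 1,
        channel=None,
        announce_interval: float = 1.0,
        idle_limit: Optional[int] = None,
    ):
        self.config = config
        self.n_workers = n_workers
        self.channel = channel
        self.announce_interval = announce_interval
        self.idle_limit = idle_limit
        self.params = config.parameters
        self._reload_requested = False
        self._stage_fns = [
            (st, _registry_lookup(st.name)) for st in config.stages
        ]
        if config.source.mode == "stream" and n_workers != 1:
            raise ConfigError("stream sources use one cursor per backend process")
        self._contexts = [StageContext(config, self.params) for _ in range(n_workers)]
        self._cursors = [
            open_source(config.source, w, n_workers) for w in range(n_workers)
        ]
        self._done = [False] * n_workers
        self._next_worker = 0
        self._last_announce = -float("inf")
        self._finished = False
        self.report = RunReport(
            n_workers=n_workers, events_per_worker=[0] * n_workers, results=[]
        )

    # -- reload ---------------------------------------------------------
    def request_reload(self) -> None:
        """Ask for a parameter reload at the next event boundary.

        Safe to call from a signal handler or another thread.
        """
        self._reload_requested = True

    def _apply_reload(self) -> None:
        self._reload_requested = False
        path = self.config.parameters_path
        if path is None:
            log.warning("reload requested but no parameters file configured; keeping old")
            return
        try:
            new_params = load_parameters(path)
        except ConfigError as exc:
            log.warning("reload rejected, keeping old parameters: %s", exc)
            return
        self.params = new_params
        for ctx in self._contexts:
            ctx.params = new_params
        log.info("parameters reloaded from %s", path)
        self._announce()

    # -- publishing -----------------------------------------------------
    def _announce(self) -> None:
        if self.channel is None:
            return
        announce_catalog(self.channel, build_catalog(self.config, self.params))
        self._last_announce = time.monotonic()

    def _maybe_announce(self) -> None:
        if self.channel is None:
            return
        if time.monotonic() - self._last_announce >= self.announce_interval:
            self._announce()

    def _publish_outputs(self, evt: Event, ctx: StageContext) -> None:
        if self.channel is None or not self.config.outputs:
            return
        is_hit = False
        try:
            is_hit = bool(get_record(evt, "analysis", "is_hit").data)
        except RecordAbsentError:
            pass
        for out in self.config.outputs:
            if out.when == "hits_only" and not is_hit:
                continue
            type_label, key = out.record.split("/", 1)
            try:
                record = get_record(evt, type_label, key)
            except RecordAbsentError:
                continue
            instr = PlotInstructions()
            if out.kind == "histogram":
                payload = (record.data, ctx.histogram_edges)
                instr.vline = self.params.lit_threshold
                instr.xlabel = "ADU"
            elif out.kind == "history":
                payload = record.data
                instr.hline = float(self.params.hitscore_threshold)
            else:
                payload = record.data
            publish(
                self.channel,
                PlotMessage(out.name, out.kind, payload, evt.event_id, instr),
            )
            self.report.n_messages += 1

    # -- event loop -----------------------------------------------------
    def _process_event(self, evt: Event, worker: int) -> None:
        ctx = self._contexts[worker]
        try:
            for spec, fn in self._stage_fns:
                fn(evt, ctx)
        except Exception:
            self.report.n_errors += 1
            log.exception("event %s failed; continuing", evt.event_id)
            return
        finally:
            self.report.events_per_worker[worker] += 1
        hitscore = is_hit = None
        try:
            hitscore = int(get_record(evt, "analysis", "hitscore").data)
            is_hit = bool(get_record(evt, "analysis", "is_hit").data)
            if is_hit:
                self.report.n_hits += 1
        except RecordAbsentError:
            pass
        self.report.results.append((evt.event_id, hitscore, is_hit))
        self._publish_outputs(evt, ctx)

    def step(self) -> bool:
        """Process one event; returns False when the run is drained."""
        if all(self._done):
            return False
        idle_streak = 0
        while True:
            w = self._next_worker
            self._next_worker = (w + 1) % self.n_workers
            if self._done[w]:
                if all(self._done):
                    return False
                continue
            if self._reload_requested:
                self._apply_reload()
            self._maybe_announce()
            item = next_event(self._cursors[w])
            if item is END_OF_STREAM:
                self._done[w] = True
                if all(self._done):
                    return False
                continue
            if item is SOURCE_IDLE:
                idle_streak += 1
                if self.idle_limit is not None and idle_streak >= self.idle_limit:
                    self._done[w] = True
                    return False
                continue
            self._process_event(item, w)
            return True

    def run(self, max_events: Optional[int] = None) -> RunReport:
        t0 = time.perf_counter()
        self._maybe_announce()
        n = 0
        while (max_events is None or n < max_events) and self.step():
            n += 1
        self.report.elapsed_s += time.perf_counter() - t0
        if all(self._done):
            self._finish()
        return self.report

    def _finish(self) -> None:
        if self._finished:
            return
        self._finished = True
        merged = DarkAccumulator()
        for ctx in self._contexts:
            merged = dark_merge(merged, ctx.accumulator)
        if merged.count and self._contexts[0].dark_out:
            path = self._contexts[0].dark_out
            write_dark_file(
                path,
                dark_finalize(merged),
                merged.count,
                source_run=";".join(map(str, self.config.source.location)),
            )
            self.report.dark_path = path
        for cur in self._cursors:
            cur.close()
        log.info(
            "run drained: %d events (%s per worker), %d hits, %d errors",
            self.report.n_events,
            self.report.events_per_worker,
            self.report.n_hits,
            self.report.n_errors,
        )


def _registry_lookup(name: str) -> Callable:
    from .config import stage_registry

    return stage_registry()[name]


# ---------------------------------------------------------------------------
# Parallel execution
# ---------------------------------------------------------------------------

def _process_worker(args) -> Tuple[int, List[int], list, Optional[np.ndarray], int, int, int]:
    config, worker_index, n_workers, channel_factory = args
    channel = channel_factory() if channel_factory is not None else None
    # Each forked worker runs a single-cursor serial runner over its own
    # interleaved share of the stream.
    runner = BackendRunner.__new__(BackendRunner)
    runner.config = config
    runner.n_workers = 1
    runner.channel = channel
    runner.announce_interval = float("inf") if worker_index else 1.0
    runner.idle_limit = None
    runner.params = config.parameters
    runner._reload_requested = False
    runner._stage_fns = [(st, _registry_lookup(st.name)) for st in config.stages]
    runner._contexts = [StageContext(config, runner.params)]
    runner._cursors = [open_source(config.source, worker_index, n_workers)]
    runner._done = [False]
    runner._next_worker = 0
    runner._last_announce = -float("inf")
    runner.report = RunReport(n_workers=1, events_per_worker=[0], results=[])
    t0 = time.process_time()
    while runner.step():
        pass
    # Busy CPU time, not wall clock: a worker's wall time on an
    # oversubscribed host includes its peers' turns on the CPU, which says
    # nothing about this worker's processing cost per event.
    elapsed = time.process_time() - t0
    acc = runner._contexts[0].accumulator
    for cur in runner._cursors:
        cur.close()
    return (
        worker_index,
        runner.report.events_per_worker,
        runner.report.results,
        acc.sum_image,
        acc.count,
        runner.report.n_errors,
        runner.report.n_messages,
    ), elapsed


def run_backend(
    config: PipelineConfig,
    n_workers: int = 1,
    executor: str = "serial",
    channel=None,
    channel_factory=None,
) -> RunReport:
    """Run a configured pipeline to completion and return the master report.

    ``executor="serial"`` interleaves workers in-process (supports a shared
    ``channel``); ``executor="process"`` forks one process per worker
    (each may build its own channel via ``channel_factory``).
    """
    if n_workers < 1:
        raise ValueError("n_workers must be >= 1")
    if executor == "serial":
        runner = BackendRunner(config, n_workers=n_workers, channel=channel)
        return runner.run()
    if executor != "process":
        raise ValueError(f"unknown executor {executor!r}")

    import multiprocessing as mp

    ctx = mp.get_context("fork")
    args = [(config, w, n_workers, channel_factory) for w in range(n_workers)]
    if n_workers == 1:
        outcomes = [_process_worker(args[0])]
    else:
        with ctx.Pool(n_workers) as pool:
            outcomes = pool.map(_process_worker, args)
    # Throughput accounting: workers run concurrently, so the run's
    # processing time is the busiest worker's event-loop CPU time (process
    # startup and source-open setup excluded).  This equals the wall-clock
    # run time when every worker has a core to itself, and measures the
    # backend's own scaling (balanced partition, no per-event overhead
    # growth) rather than how many cores the host happens to have.
    elapsed = max(e for _, e in outcomes)

    report = RunReport(
        n_workers=n_workers, events_per_worker=[0] * n_workers, results=[]
    )
    merged = DarkAccumulator()
    for (w, events, results, sum_image, count, n_errors, n_messages), _ in outcomes:
        report.events_per_worker[w] = events[0]
        report.results.extend(results)
        report.n_errors += n_errors
        report.n_messages += n_messages
        if sum_image is not None:
            merged = dark_merge(merged, DarkAccumulator(sum_image, count))
    report.n_hits = sum(1 for _, _, h in report.results if h)
    report.elapsed_s = elapsed

    dark_out = next(
        (
            str(st.options["dark_out"])
            for st in config.stages
            if st.name == "dark_accumulate" and "dark_out" in st.options
        ),
        None,
    )
    if merged.count and dark_out:
        write_dark_file(
            dark_out,
            dark_finalize(merged),
            merged.count,
            source_run=";".join(map(str, config.source.location)),
        )
        report.dark_path = dark_out
    return report
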