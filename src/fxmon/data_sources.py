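"""Translation layer: native run data → :class:`~fxmon.event_model.Event`.

Workers read *independently* from a common data source: with ``W`` workers,
worker ``i`` consumes the interleaved share of global frame indices
``i, i+W, i+2W, …`` (round-robin by frame, which keeps load balanced even
when run files have heterogeneous sizes).  Every frame of a finite run is
delivered to exactly one worker, exactly once.

Two source modes exist:

``file_run``
    A list of HDF5 run files (dialect below), read losslessly.

``stream``
    A live, *lossy* feed modelled on a facility DAQ's most-recent-event
    shared-memory contract: each event is available until overwritten by a
    subsequent one, so frames arriving while the consumer is busy are
    dropped.

Run-file dialect (HDF5)
-----------------------
::

    /entry/data/frames        (N, rows, cols)  integer ADU
    /entry/data/timestamps    (N,)             float seconds
    /entry/data/pulse_energy  (N,)             float mJ      [optional]
    /entry/truth/is_hit       (N,)             0/1           [optional]
    /entry/truth/n_photons    (N,)             integer       [optional]
    /entry  @detector_key     string

Frame axis 0 is the event index; image axis 0 is the detector row (the
common-mode axis).  Truth datasets carry ground-truth labels for synthetic
runs; the translation layer deliberately does *not* expose them as event
records, so the processing chain can never peek at the answer.
"""

from __future__ import annotations

import socket
import threading
import time
import urllib.parse
from collections import deque
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import h5py
import numpy as np

from .event_model import Event, add_record
from .wire import decode_blob, encode_blob, recv_frame, send_frame

__all__ = [
    "SourceSpec",
    "SourceCursor",
    "TranslationError",
    "END_OF_STREAM",
    "SOURCE_IDLE",
    "open_source",
    "next_event",
    "write_run_file",
    "read_run_file",
    "LiveEventBuffer",
    "RunStreamServer",
]


class TranslationError(RuntimeError):
    """A native run file could not be translated (malformed or inconsistent)."""


class _Sentinel:
    def __init__(self, name: str):
        self._name = name

    def __repr__(self) -> str:  # pragma: no cover
        return f"<{self._name}>"


#: Returned by :func:`next_event` exactly once when a file-run cursor drains.
END_OF_STREAM = _Sentinel("end_of_stream")
#: Returned by :func:`next_event` when a live source times out (distinct
#: from end-of-stream: the producer may still be alive).
SOURCE_IDLE = _Sentinel("source_idle")


@dataclass
class SourceSpec:
    """Where events come from and which detector record to expose."""

    mode: str  # "file_run" | "stream"
    location: Union[Sequence[str], str]
    detector_key: str = "pnCCD"

    def __post_init__(self) -> None:
        if self.mode not in ("file_run", "stream"):
            raise ValueError(f"unknown source mode {self.mode!r}")
        if self.mode == "file_run":
            if isinstance(self.location, str):
                self.location = [self.location]
            if not self.location:
                raise ValueError("file_run source needs at least one file")


# ---------------------------------------------------------------------------
# Run-file I/O
# ---------------------------------------------------------------------------

def write_run_file(
    path: str,
    frames: np.ndarray,
    timestamps: np.ndarray,
    detector_key: str = "pnCCD",
    is_hit: Optional[np.ndarray] = None,
    n_photons: Optional[np.ndarray] = None,
    pulse_energy: Optional[np.ndarray] = None,
) -> None:
    """Write one run file in the dialect above.

    Object timestamps are disabled (``track_times=False``) so identical
    inputs yield byte-identical files.
    """
    frames = np.asarray(frames)
    if frames.ndim != 3:
        raise ValueError("frames must be (n_events, rows, cols)")
    if not np.issubdtype(frames.dtype, np.integer):
        raise ValueError("frames must be integer ADU")
    n = frames.shape[0]
    timestamps = np.asarray(timestamps, dtype=np.float64)
    if timestamps.shape != (n,):
        raise ValueError("timestamps length does not match n_events")
    if pulse_energy is not None and np.asarray(pulse_energy).shape != (n,):
        raise ValueError("pulse_energy length does not match n_events")
    with h5py.File(path, "w", track_order=False) as f:
        entry = f.create_group("entry", track_order=False)
        entry.attrs["detector_key"] = detector_key
        data = entry.create_group("data")
        data.create_dataset("frames", data=frames, track_times=False)
        data.create_dataset("timestamps", data=timestamps, track_times=False)
        if pulse_energy is not None:
            data.create_dataset(
                "pulse_energy", data=np.asarray(pulse_energy, np.float64), track_times=False
            )
        if is_hit is not None or n_photons is not None:
            truth = entry.create_group("truth")
            if is_hit is not None:
                truth.create_dataset(
                    "is_hit", data=np.asarray(is_hit, np.uint8), track_times=False
                )
            if n_photons is not None:
                truth.create_dataset(
                    "n_photons", data=np.asarray(n_photons, np.int64), track_times=False
                )


def read_run_file(path: str) -> Dict[str, np.ndarray]:
    """Load a whole run file into memory (oracle/test helper).

    Returns a dict with ``frames``, ``timestamps``, ``detector_key`` and,
    when present, ``is_hit`` / ``n_photons`` / ``pulse_energy``.
    """
    out: Dict[str, np.ndarray] = {}
    with h5py.File(path, "r") as f:
        entry = f["entry"]
        out["detector_key"] = entry.attrs["detector_key"]
        out["frames"] = entry["data/frames"][...]
        out["timestamps"] = entry["data/timestamps"][...]
        if "data/pulse_energy" in entry:
            out["pulse_energy"] = entry["data/pulse_energy"][...]
        if "truth" in entry:
            if "is_hit" in entry["truth"]:
                out["is_hit"] = entry["truth/is_hit"][...]
            if "n_photons" in entry["truth"]:
                out["n_photons"] = entry["truth/n_photons"][...]
    return out


# ---------------------------------------------------------------------------
# Cursors
# ---------------------------------------------------------------------------

@dataclass
class _FileInfo:
    path: str
    n_frames: int


@dataclass
class SourceCursor:
    """One worker's independent view into a source.

    ``position`` is the next *global* frame index this worker will consume;
    the invariant ``position ≡ worker_index (mod n_workers)`` holds at all
    times in file mode.
    """

    spec: SourceSpec
    worker_index: int
    n_workers: int
    position: int = 0
    # file mode internals
    _files: List[_FileInfo] = field(default_factory=list, repr=False)
    _handles: Dict[int, h5py.File] = field(default_factory=dict, repr=False)
    _starts: List[int] = field(default_factory=list, repr=False)
    _total: int = 0
    _exhausted: bool = False
    _has_pulse_energy: List[bool] = field(default_factory=list, repr=False)
    # stream mode internals
    _buffer: Optional["LiveEventBuffer"] = field(default=None, repr=False)
    _timeout: float = 1.0
    _receiver: Optional["_StreamReceiver"] = field(default=None, repr=False)

    def close(self) -> None:
        for h in self._handles.values():
            h.close()
        self._handles.clear()
        if self._receiver is not None:
            self._receiver.close()

    # -- file-mode helpers ----------------------------------------------
    def _locate(self, global_index: int) -> Tuple[int, int]:
        """Map a global frame index to (file index, local index)."""
        lo = int(np.searchsorted(self._starts, global_index, side="right")) - 1
        return lo, global_index - self._starts[lo]

    def _handle(self, file_index: int) -> h5py.File:
        h = self._handles.get(file_index)
        if h is None:
            h = h5py.File(self._files[file_index].path, "r")
            self._handles[file_index] = h
        return h


def open_source(spec: SourceSpec, worker_index: int, n_workers: int) -> SourceCursor:
    """Open one worker's cursor into a source.

    File mode validates every file up front: a malformed file raises
    :class:`TranslationError` naming the file, and a detector-shape mismatch
    across files is rejected at open time.
    """
    if n_workers < 1 or not (0 <= worker_index < n_workers):
        raise ValueError("need 0 <= worker_index < n_workers")
    cursor = SourceCursor(spec=spec, worker_index=worker_index, n_workers=n_workers)
    if spec.mode == "file_run":
        shape = None
        start = 0
        for path in spec.location:
            try:
                with h5py.File(path, "r") as f:
                    frames = f["entry/data/frames"]
                    ts = f["entry/data/timestamps"]
                    if frames.ndim != 3 or ts.shape[0] != frames.shape[0]:
                        raise KeyError("inconsistent frame/timestamp layout")
                    fshape = frames.shape[1:]
                    n = frames.shape[0]
                    has_pe = "entry/data/pulse_energy" in f
            except (OSError, KeyError) as exc:
                raise TranslationError(
                    f"cannot translate run file {path!r} (offset {start}): {exc}"
                ) from exc
            if shape is None:
                shape = fshape
            elif fshape != shape:
                raise TranslationError(
                    f"detector shape mismatch: {path!r} has {fshape}, expected {shape}"
                )
            cursor._files.append(_FileInfo(path, n))
            cursor._starts.append(start)
            cursor._has_pulse_energy.append(has_pe)
            start += n
        cursor._total = start
        cursor.position = worker_index
    else:
        cursor._receiver = _StreamReceiver(str(spec.location))
        cursor._buffer = cursor._receiver.buffer
        cursor._timeout = 1.0
    return cursor


def next_event(cursor: SourceCursor) -> Union[Event, _Sentinel]:
    """Translate and return this worker's next event.

    File mode: advances the cursor by ``n_workers`` and returns
    :data:`END_OF_STREAM` exactly once when the worker's share is drained
    (calling again afterwards raises).  Stream mode: blocks up to the
    cursor timeout and returns :data:`SOURCE_IDLE` if nothing arrived, or
    :data:`END_OF_STREAM` when the producer closed the feed.
    """
    if cursor.spec.mode == "file_run":
        return _next_file_event(cursor)
    return _next_stream_event(cursor)


def _next_file_event(cursor: SourceCursor) -> Union[Event, _Sentinel]:
    if cursor.position >= cursor._total:
        if cursor._exhausted:
            raise RuntimeError("cursor already signalled end_of_stream")
        cursor._exhausted = True
        return END_OF_STREAM
    file_index, local = cursor._locate(cursor.position)
    h = cursor._handle(file_index)
    frame = h["entry/data/frames"][local]
    timestamp = float(h["entry/data/timestamps"][local])
    detector_key = h["entry"].attrs["detector_key"]
    evt = Event(event_id=(file_index, local), timestamp=timestamp)
    add_record(evt, "photonPixelDetectors", str(detector_key), frame, "ADU")
    if cursor._has_pulse_energy[file_index]:
        energy = float(h["entry/data/pulse_energy"][local])
        add_record(evt, "FEL", "pulseEnergy", energy, "mJ")
    cursor.position += cursor.n_workers
    return evt


def _next_stream_event(cursor: SourceCursor) -> Union[Event, _Sentinel]:
    assert cursor._buffer is not None
    item = cursor._buffer.pop(timeout=cursor._timeout)
    if item is LIVE_CLOSED:
        if cursor._exhausted:
            raise RuntimeError("cursor already signalled end_of_stream")
        cursor._exhausted = True
        return END_OF_STREAM
    if item is None:
        return SOURCE_IDLE
    meta, arrays = item
    evt = Event(event_id=tuple(meta["event_id"]), timestamp=meta["timestamp"])
    add_record(evt, "photonPixelDetectors", cursor.spec.detector_key, arrays["frame"], "ADU")
    if "pulse_energy" in meta:
        add_record(evt, "FEL", "pulseEnergy", meta["pulse_energy"], "mJ")
    return evt


# ---------------------------------------------------------------------------
# Live-stream plumbing
# ---------------------------------------------------------------------------

LIVE_CLOSED = _Sentinel("live_closed")


class LiveEventBuffer:
    """Bounded most-recent-event buffer (DAQ shared-memory semantics).

    With depth 1 (the default), each pushed event is available only until
    the producer overwrites it: a consumer that sleeps through 10 pushes
    sees just the latest.  ``pop`` hands out each retained event at most
    once, oldest retained first.
    """

    def __init__(self, depth: int = 1):
        if depth < 1:
            raise ValueError("depth must be >= 1")
        self._items: deque = deque(maxlen=depth)
        self._lock = threading.Lock()
        self._cond = threading.Condition(self._lock)
        self._closed = False
        self.n_pushed = 0
        self.n_dropped = 0

    def push(self, item) -> None:
        with self._cond:
            if len(self._items) == self._items.maxlen:
                self.n_dropped += 1
            self._items.append(item)
            self.n_pushed += 1
            self._cond.notify_all()

    def close(self) -> None:
        with self._cond:
            self._closed = True
            self._cond.notify_all()

    def pop(self, timeout: Optional[float] = None):
        """Oldest retained unconsumed item; ``None`` on timeout;
        :data:`LIVE_CLOSED` once drained after close."""
        deadline = None if timeout is None else time.monotonic() + timeout
        with self._cond:
            while not self._items:
                if self._closed:
                    return LIVE_CLOSED
                remaining = None if deadline is None else deadline - time.monotonic()
                if remaining is not None and remaining <= 0:
                    return None
                self._cond.wait(remaining)
            return self._items.popleft()


def _parse_endpoint(endpoint: str) -> Tuple[str, int]:
    parsed = urllib.parse.urlparse(endpoint)
    if parsed.scheme != "tcp" or parsed.port is None:
        raise ValueError(f"endpoint must look like tcp://host:port, got {endpoint!r}")
    host = parsed.hostname or "127.0.0.1"
    return host, parsed.port


class RunStreamServer:
    """Producer side of a live source: pushes events to connected consumers.

    Lossiness lives on the *consumer* (its :class:`LiveEventBuffer`); the
    server just frames and sends.  Used by ``fxmon simulate --stream`` and
    by tests.
    """

    def __init__(self, endpoint: str = "tcp://127.0.0.1:0"):
        host, port = _parse_endpoint(endpoint)
        self._srv = socket.create_server((host, port))
        self._srv.settimeout(0.2)
        self.endpoint = "tcp://%s:%d" % self._srv.getsockname()[:2]
        self._conns: List[socket.socket] = []
        self._lock = threading.Lock()
        self._running = True
        self._accept_thread = threading.Thread(target=self._accept_loop, daemon=True)
        self._accept_thread.start()

    def _accept_loop(self) -> None:
        while self._running:
            try:
                conn, _ = self._srv.accept()
            except socket.timeout:
                continue
            except OSError:
                return
            with self._lock:
                self._conns.append(conn)

    def wait_for_consumer(self, timeout: float = 5.0) -> bool:
        deadline = time.monotonic() + timeout
        while time.monotonic() < deadline:
            with self._lock:
                if self._conns:
                    return True
            time.sleep(0.01)
        return False

    def send(self, event_id, timestamp: float, frame: np.ndarray, **meta) -> None:
        blob = encode_blob(
            {"event_id": list(event_id), "timestamp": timestamp, **meta},
            {"frame": np.asarray(frame)},
        )
        with self._lock:
            dead = []
            for conn in self._conns:
                try:
                    send_frame(conn, blob)
                except OSError:
                    dead.append(conn)
            for conn in dead:
                self._conns.remove(conn)

    def close(self) -> None:
        self._running = False
        self._srv.close()
        with self._lock:
            for conn in self._conns:
                try:
                    conn.shutdown(socket.SHUT_RDWR)
                except OSError:
                    pass
                conn.close()
            self._conns.clear()


class _StreamReceiver:
    """Consumer side: a reader thread filling a depth-1 live buffer."""

    def __init__(self, endpoint: str, depth: int = 1, connect_timeout: float = 5.0):
        host, port = _parse_endpoint(endpoint)
        self.buffer = LiveEventBuffer(depth=depth)
        self._sock = socket.create_connection((host, port), timeout=connect_timeout)
        self._sock.settimeout(None)
        self._thread = threading.Thread(target=self._read_loop, daemon=True)
        self._thread.start()

    def _read_loop(self) -> None:
        try:
            while True:
                frame = recv_frame(self._sock)
                if frame is None:
                    break
                self.buffer.push(decode_blob(frame))
        except OSError:
            pass
        finally:
            self.buffer.close()

    def close(self) -> None:
        try:
            self._sock.shutdown(socket.SHUT_RDWR)
        except OSError:
            pass
        self._sock.close()
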