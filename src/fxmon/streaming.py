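"""Backend→client transport: typed plot messages over publish/subscribe.

The backend publishes self-describing :class:`PlotMessage` objects under a
topic equal to their source name; clients subscribe to the sources they
display and keep a dynamically resizable history buffer per source.  The
transport follows pub/sub semantics: no delivery guarantee to unsubscribed
or slow clients, and publishing never blocks event processing (slow-client
policy is a bounded send queue that drops oldest — monitoring favours
freshness over completeness).

Two interchangeable channels are provided:

* :class:`LocalChannel` — in-process loopback, lossless for keeping-up
  subscribers; used by tests and single-process runs.
* :class:`TcpPublisher` / :class:`TcpSubscriberChannel` — TCP sockets with
  *publisher-side* topic filtering: a client's unsubscribe stops traffic
  for that topic at the source, minimising network load.

Image payloads travel as raw little-endian bytes with declared dtype and
shape, so the serialization round trip is bit-exact.

History plots send only the latest scalar per event; accumulation into a
trend happens client-side in the :class:`ClientBuffer`, keeping messages
O(1) regardless of history length.
"""

from __future__ import annotations

import json
import socket
import threading
import time
import urllib.parse
from collections import deque
from dataclasses import dataclass, field, asdict
from typing import Any, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .wire import decode_blob, encode_blob, recv_frame, send_frame

__all__ = [
    "PlotInstructions",
    "PlotMessage",
    "CatalogEntry",
    "SourceCatalog",
    "ClientBuffer",
    "LocalChannel",
    "TcpPublisher",
    "TcpSubscriberChannel",
    "MonitorClient",
    "UnknownSourceError",
    "serialize_message",
    "deserialize_message",
    "CATALOG_TOPIC",
]

PLOT_KINDS = ("image", "history", "histogram", "vector")
CATALOG_TOPIC = "__catalog__"

#: Default client render period, seconds: plots redraw from the newest
#: buffered state every other second, decoupled from the event rate.
RENDER_PERIOD_S = 2.0


@dataclass
class PlotInstructions:
    """How a client should draw a source: labels, limits, markers, footer."""

    title: str = ""
    xlabel: str = ""
    ylabel: str = ""
    xlim: Optional[Tuple[float, float]] = None
    ylim: Optional[Tuple[float, float]] = None
    log_scale: bool = False
    colormap: str = ""
    hline: Optional[float] = None  # horizontal marker (e.g. hitscore threshold)
    vline: Optional[float] = None  # vertical marker (e.g. lit threshold)
    footer: str = ""

    def to_dict(self) -> dict:
        d = asdict(self)
        d["xlim"] = list(self.xlim) if self.xlim is not None else None
        d["ylim"] = list(self.ylim) if self.ylim is not None else None
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PlotInstructions":
        d = dict(d)
        for k in ("xlim", "ylim"):
            if d.get(k) is not None:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class PlotMessage:
    """One typed payload published from backend to clients.

    plot_kind and payload must agree: image ↔ 2-D array, vector ↔ 1-D
    array, history ↔ single scalar, histogram ↔ (counts, edges) pair.
    """

    source_name: str
    plot_kind: str
    payload: Any
    event_id: Tuple[int, int] = (0, 0)
    instructions: PlotInstructions = field(default_factory=PlotInstructions)

    def __post_init__(self) -> None:
        if self.plot_kind not in PLOT_KINDS:
            raise ValueError(f"unknown plot kind {self.plot_kind!r}")
        _check_payload(self.plot_kind, self.payload)


def _check_payload(kind: str, payload: Any) -> None:
    if kind == "image":
        if np.ndim(payload) != 2:
            raise ValueError("image payload must be 2-D")
    elif kind == "vector":
        if np.ndim(payload) != 1:
            raise ValueError("vector payload must be 1-D")
    elif kind == "history":
        if np.ndim(payload) != 0:
            raise ValueError("history payload must be a single scalar")
    elif kind == "histogram":
        if not (isinstance(payload, tuple) and len(payload) == 2):
            raise ValueError("histogram payload must be (counts, edges)")
        counts, edges = payload
        if np.ndim(counts) != 1 or np.ndim(edges) != 1:
            raise ValueError("histogram counts and edges must be 1-D")


def serialize_message(msg: PlotMessage) -> bytes:
    meta = {
        "source_name": msg.source_name,
        "plot_kind": msg.plot_kind,
        "event_id": list(msg.event_id),
        "instructions": msg.instructions.to_dict(),
    }
    if msg.plot_kind == "histogram":
        counts, edges = msg.payload
        arrays = {"counts": np.asarray(counts), "edges": np.asarray(edges)}
    else:
        arrays = {"payload": np.asarray(msg.payload)}
    return encode_blob(meta, arrays)


def deserialize_message(data: bytes) -> PlotMessage:
    meta, arrays = decode_blob(data)
    kind = meta["plot_kind"]
    if kind == "histogram":
        payload: Any = (arrays["counts"], arrays["edges"])
    elif kind == "history":
        payload = arrays["payload"][()]  # back to a scalar
    else:
        payload = arrays["payload"]
    return PlotMessage(
        source_name=meta["source_name"],
        plot_kind=kind,
        payload=payload,
        event_id=tuple(meta["event_id"]),
        instructions=PlotInstructions.from_dict(meta["instructions"]),
    )


# ---------------------------------------------------------------------------
# Catalog
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CatalogEntry:
    source_name: str
    plot_kind: str
    instructions: PlotInstructions = field(default_factory=PlotInstructions)


@dataclass
class SourceCatalog:
    """The plot sources a running backend publishes.

    Auto-derived from the backend configuration's output declarations;
    clients never edit it.  Re-broadcast periodically and on change so
    late-joining clients can populate their source table.
    """

    entries: List[CatalogEntry] = field(default_factory=list)

    def names(self) -> List[str]:
        return [e.source_name for e in self.entries]

    def serialize(self) -> bytes:
        return encode_blob(
            {
                "catalog": [
                    {
                        "source_name": e.source_name,
                        "plot_kind": e.plot_kind,
                        "instructions": e.instructions.to_dict(),
                    }
                    for e in self.entries
                ]
            }
        )

    @classmethod
    def deserialize(cls, data: bytes) -> "SourceCatalog":
        meta, _ = decode_blob(data)
        return cls(
            [
                CatalogEntry(
                    d["source_name"],
                    d["plot_kind"],
                    PlotInstructions.from_dict(d["instructions"]),
                )
                for d in meta["catalog"]
            ]
        )


# ---------------------------------------------------------------------------
# Channels
# ---------------------------------------------------------------------------

def publish(channel, msg: PlotMessage) -> None:
    """Serialize ``msg`` and send it under topic = its source name."""
    channel.publish_bytes(msg.source_name, serialize_message(msg))


def announce_catalog(channel, catalog: SourceCatalog) -> None:
    channel.publish_bytes(CATALOG_TOPIC, catalog.serialize())


class LocalChannel:
    """In-process pub/sub: per-subscriber topic filters and bounded queues."""

    def __init__(self, queue_size: int = 1024):
        self._queue_size = queue_size
        self._subs: List["LocalSubscriber"] = []
        self._lock = threading.Lock()

    def publish_bytes(self, topic: str, blob: bytes) -> None:
        with self._lock:
            subs = list(self._subs)
        for sub in subs:
            sub._offer(topic, blob)

    def subscriber(self) -> "LocalSubscriber":
        sub = LocalSubscriber(self._queue_size)
        with self._lock:
            self._subs.append(sub)
        return sub

    def close(self) -> None:
        with self._lock:
            self._subs.clear()


class LocalSubscriber:
    def __init__(self, queue_size: int):
        self._topics: set = set()
        self._queue: deque = deque(maxlen=queue_size)
        self._lock = threading.Lock()

    def subscribe(self, topic: str) -> None:
        with self._lock:
            self._topics.add(topic)

    def unsubscribe(self, topic: str) -> None:
        with self._lock:
            self._topics.discard(topic)

    def _offer(self, topic: str, blob: bytes) -> None:
        with self._lock:
            if topic in self._topics:
                self._queue.append((topic, blob))  # deque drops oldest when full

    def poll(self) -> List[Tuple[str, bytes]]:
        """Drain all pending (topic, blob) pairs, oldest first."""
        with self._lock:
            items = list(self._queue)
            self._queue.clear()
        return items

    def close(self) -> None:
        pass


def _parse_endpoint(endpoint: str) -> Tuple[str, int]:
    parsed = urllib.parse.urlparse(endpoint)
    if parsed.scheme != "tcp" or parsed.port is None:
        raise ValueError(f"endpoint must look like tcp://host:port, got {endpoint!r}")
    return parsed.hostname or "127.0.0.1", parsed.port


class TcpPublisher:
    """Publisher end of the TCP channel.

    Each connected client announces its topic set over the same socket
    (subscribe/unsubscribe control frames); filtering happens here, so
    unsubscribed topics cause no network traffic.  Per-client send queues
    are bounded and drop oldest; a slow client never back-pressures the
    backend.
    """

    def __init__(self, endpoint: str = "tcp://127.0.0.1:0", queue_size: int = 256):
        host, port = _parse_endpoint(endpoint)
        self._srv = socket.create_server((host, port))
        self._srv.settimeout(0.2)
        self.endpoint = "tcp://%s:%d" % self._srv.getsockname()[:2]
        self._queue_size = queue_size
        self._clients: List[_TcpClientState] = []
        self._lock = threading.Lock()
        self._running = True
        self._thread = threading.Thread(target=self._accept_loop, daemon=True)
        self._thread.start()

    def _accept_loop(self) -> None:
        while self._running:
            try:
                conn, _ = self._srv.accept()
            except socket.timeout:
                continue
            except OSError:
                return
            state = _TcpClientState(conn, self._queue_size)
            with self._lock:
                self._clients.append(state)

    def publish_bytes(self, topic: str, blob: bytes) -> None:
        framed = _frame_message(topic, blob)
        with self._lock:
            clients = list(self._clients)
        for c in clients:
            if not c.alive:
                with self._lock:
                    if c in self._clients:
                        self._clients.remove(c)
                continue
            c.offer(topic, framed)

    def n_clients(self) -> int:
        with self._lock:
            return sum(1 for c in self._clients if c.alive)

    def close(self) -> None:
        self._running = False
        self._srv.close()
        with self._lock:
            for c in self._clients:
                c.close()
            self._clients.clear()


def _frame_message(topic: str, blob: bytes) -> bytes:
    t = topic.encode()
    return b"M" + len(t).to_bytes(2, "little") + t + blob


def _unframe_message(data: bytes) -> Tuple[str, bytes]:
    tlen = int.from_bytes(data[1:3], "little")
    return data[3 : 3 + tlen].decode(), data[3 + tlen :]


class _TcpClientState:
    def __init__(self, conn: socket.socket, queue_size: int):
        self.conn = conn
        self.topics: set = set()
        self.queue: deque = deque(maxlen=queue_size)
        self.cond = threading.Condition()
        self.alive = True
        threading.Thread(target=self._control_loop, daemon=True).start()
        threading.Thread(target=self._send_loop, daemon=True).start()

    def _control_loop(self) -> None:
        try:
            while self.alive:
                frame = recv_frame(self.conn)
                if frame is None or frame[:1] != b"C":
                    break
                ctl = json.loads(frame[1:].decode())
                with self.cond:
                    if ctl["op"] == "subscribe":
                        self.topics.add(ctl["topic"])
                    elif ctl["op"] == "unsubscribe":
                        self.topics.discard(ctl["topic"])
        except OSError:
            pass
        finally:
            self.close()

    def offer(self, topic: str, framed: bytes) -> None:
        with self.cond:
            if topic in self.topics:
                self.queue.append(framed)
                self.cond.notify()

    def _send_loop(self) -> None:
        try:
            while True:
                with self.cond:
                    while not self.queue:
                        if not self.alive:
                            return
                        self.cond.wait(0.2)
                    framed = self.queue.popleft()
                send_frame(self.conn, framed)
        except OSError:
            self.close()

    def close(self) -> None:
        with self.cond:
            if not self.alive:
                return
            self.alive = False
            self.cond.notify_all()
        try:
            self.conn.shutdown(socket.SHUT_RDWR)
        except OSError:
            pass
        self.conn.close()


class TcpSubscriberChannel:
    """Subscriber end of the TCP channel; poll()-compatible with
    :class:`LocalSubscriber`."""

    def __init__(self, endpoint: str, connect_timeout: float = 5.0, queue_size: int = 1024):
        host, port = _parse_endpoint(endpoint)
        self._sock = socket.create_connection((host, port), timeout=connect_timeout)
        self._sock.settimeout(None)
        self._queue: deque = deque(maxlen=queue_size)
        self._lock = threading.Lock()
        self._closed = False
        self._thread = threading.Thread(target=self._recv_loop, daemon=True)
        self._thread.start()

    def _send_ctl(self, op: str, topic: str) -> None:
        payload = b"C" + json.dumps({"op": op, "topic": topic}).encode()
        try:
            send_frame(self._sock, payload)
        except OSError:
            pass

    def subscribe(self, topic: str) -> None:
        self._send_ctl("subscribe", topic)

    def unsubscribe(self, topic: str) -> None:
        self._send_ctl("unsubscribe", topic)

    def _recv_loop(self) -> None:
        try:
            while True:
                frame = recv_frame(self._sock)
                if frame is None or frame[:1] != b"M":
                    break
                with self._lock:
                    self._queue.append(_unframe_message(frame))
        except OSError:
            pass

    def poll(self) -> List[Tuple[str, bytes]]:
        with self._lock:
            items = list(self._queue)
            self._queue.clear()
        return items

    def close(self) -> None:
        if self._closed:
            return
        self._closed = True
        try:
            self._sock.shutdown(socket.SHUT_RDWR)
        except OSError:
            pass
        self._sock.close()


# ---------------------------------------------------------------------------
# Client side
# ---------------------------------------------------------------------------

class UnknownSourceError(KeyError):
    """Subscription to a source the backend never announced."""

    def __init__(self, source_name: str, available: Sequence[str]):
        super().__init__(
            f"unknown source {source_name!r}; available: {sorted(available)}"
        )
        self.source_name = source_name
        self.available = list(available)


class ClientBuffer:
    """Per-source sliding window of the most recent payloads.

    Holds at most ``capacity`` items (most recent by arrival) and can be
    resized at any time, retaining the ``min(new_capacity, len)`` most
    recent.  History sources accumulate one scalar per message here, which
    is what turns O(1) messages into a trend plot.
    """

    def __init__(self, source_name: str, capacity: int = 100):
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        self.source_name = source_name
        self._items: deque = deque(maxlen=capacity)

    @property
    def capacity(self) -> int:
        return self._items.maxlen  # type: ignore[return-value]

    def append(self, event_id: Tuple[int, int], payload: Any) -> None:
        self._items.append((event_id, payload))

    def resize(self, capacity: int) -> None:
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        self._items = deque(list(self._items)[-capacity:], maxlen=capacity)

    def items(self) -> List[Tuple[Tuple[int, int], Any]]:
        """Buffered (event_id, payload) pairs, oldest retained first."""
        return list(self._items)

    def payloads(self) -> List[Any]:
        return [p for _, p in self._items]

    def __len__(self) -> int:
        return len(self._items)


class MonitorClient:
    """Headless monitoring client: catalog, subscriptions, history buffers.

    Wraps any subscriber (local or TCP).  ``poll()`` drains the transport
    into the per-source buffers; a renderer (GUI or terminal) is expected
    to redraw from the newest buffered state on its own period
    (:data:`RENDER_PERIOD_S` by default) — rendering never back-pressures
    the backend, and multiple clients do not interfere.
    """

    def __init__(self, subscriber, default_capacity: int = 100):
        self._sub = subscriber
        self._default_capacity = default_capacity
        self.catalog = SourceCatalog()
        self.buffers: Dict[str, ClientBuffer] = {}
        self._sub.subscribe(CATALOG_TOPIC)

    def poll(self) -> int:
        """Drain pending messages into buffers; returns messages consumed."""
        n = 0
        for topic, blob in self._sub.poll():
            n += 1
            if topic == CATALOG_TOPIC:
                self.catalog = SourceCatalog.deserialize(blob)
                continue
            buf = self.buffers.get(topic)
            if buf is None:
                continue
            msg = deserialize_message(blob)
            buf.append(msg.event_id, msg.payload)
        return n

    def wait_for_catalog(self, timeout: float = 5.0) -> SourceCatalog:
        deadline = time.monotonic() + timeout
        while time.monotonic() < deadline:
            self.poll()
            if self.catalog.entries:
                return self.catalog
            time.sleep(0.01)
        return self.catalog

    def subscribe(self, source_name: str, capacity: Optional[int] = None) -> ClientBuffer:
        if self.catalog.entries and source_name not in self.catalog.names():
            raise UnknownSourceError(source_name, self.catalog.names())
        buf = ClientBuffer(source_name, capacity or self._default_capacity)
        self.buffers[source_name] = buf
        self._sub.subscribe(source_name)
        return buf

    def unsubscribe(self, source_name: str) -> None:
        self._sub.unsubscribe(source_name)
        self.buffers.pop(source_name, None)

    def dump_hdf5(self, path: str) -> None:
        """Log buffered payloads to HDF5 (for headless test assertions)."""
        import h5py

        with h5py.File(path, "w") as f:
            for name, buf in self.buffers.items():
                grp = f.create_group(name)
                for i, (event_id, payload) in enumerate(buf.items()):
                    if isinstance(payload, tuple):  # histogram
                        sub = grp.create_group(f"{i:06d}")
                        sub.create_dataset("counts", data=np.asarray(payload[0]))
                        sub.create_dataset("edges", data=np.asarray(payload[1]))
                        sub.attrs["event_id"] = list(event_id)
                    else:
                        d = grp.create_dataset(f"{i:06d}", data=np.asarray(payload))
                        d.attrs["event_id"] = list(event_id)

    def close(self) -> None:
        self._sub.close()
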