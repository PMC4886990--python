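"""Low-level wire encoding shared by the streaming layer and live sources.

A *blob* is one self-describing message: a JSON metadata header followed by
the raw bytes of zero or more numpy arrays.  Array bytes travel as C-order
little-endian, with dtype and shape declared in the header, so image
payloads survive the round trip bit-exactly on any host.

Layout::

    u32 header_len | header (UTF-8 JSON) | array bytes, concatenated

The header is a JSON object; the reserved key ``"__arrays__"`` holds an
ordered list of ``{"key", "dtype", "shape", "nbytes"}`` entries describing
the concatenated array section.  Everything else in the header is
caller-defined metadata (JSON-serializable only).

On sockets, blobs are framed as ``u32 total_len | payload``.
"""

from __future__ import annotations

import json
import socket
import struct
from typing import Dict, Tuple

import numpy as np

__all__ = [
    "encode_blob",
    "decode_blob",
    "send_frame",
    "recv_frame",
]

_U32 = struct.Struct("<I")


def _to_wire_array(a: np.ndarray) -> np.ndarray:
    """C-contiguous little-endian version of ``a``, shape preserved."""
    a = np.asarray(a)
    if not a.flags["C_CONTIGUOUS"]:
        a = np.ascontiguousarray(a).reshape(a.shape)  # keeps 0-d as 0-d
    if a.dtype.byteorder == ">":
        a = a.astype(a.dtype.newbyteorder("<"))
    return a


def encode_blob(meta: dict, arrays: Dict[str, np.ndarray] | None = None) -> bytes:
    """Serialize metadata plus named arrays into one byte string."""
    arrays = arrays or {}
    specs = []
    chunks = []
    for key, arr in arrays.items():
        arr = _to_wire_array(np.asarray(arr))
        raw = arr.tobytes()
        specs.append(
            {
                "key": key,
                "dtype": arr.dtype.newbyteorder("<").str,
                "shape": list(arr.shape),
                "nbytes": len(raw),
            }
        )
        chunks.append(raw)
    header = dict(meta)
    header["__arrays__"] = specs
    hbytes = json.dumps(header, separators=(",", ":")).encode()
    return _U32.pack(len(hbytes)) + hbytes + b"".join(chunks)


def decode_blob(data: bytes) -> Tuple[dict, Dict[str, np.ndarray]]:
    """Inverse of :func:`encode_blob`."""
    (hlen,) = _U32.unpack_from(data, 0)
    header = json.loads(data[4 : 4 + hlen].decode())
    specs = header.pop("__arrays__", [])
    arrays: Dict[str, np.ndarray] = {}
    offset = 4 + hlen
    for spec in specs:
        n = spec["nbytes"]
        arr = np.frombuffer(data[offset : offset + n], dtype=np.dtype(spec["dtype"]))
        arrays[spec["key"]] = arr.reshape(spec["shape"]).copy()
        offset += n
    return header, arrays


def send_frame(sock: socket.socket, payload: bytes) -> None:
    sock.sendall(_U32.pack(len(payload)) + payload)


def _recv_exact(sock: socket.socket, n: int) -> bytes | None:
    buf = bytearray()
    while len(buf) < n:
        chunk = sock.recv(n - len(buf))
        if not chunk:
            return None
        buf.extend(chunk)
    return bytes(buf)


def recv_frame(sock: socket.socket) -> bytes | None:
    """Read one length-prefixed frame; ``None`` on orderly EOF."""
    head = _recv_exact(sock, 4)
    if head is None:
        return None
    (n,) = _U32.unpack(head)
    return _recv_exact(sock, n)
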