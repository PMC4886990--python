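"""Facility-agnostic event structure.

Everything downstream of the translation layer operates on :class:`Event`
objects: a two-level mapping from a *data type* label (e.g.
``"photonPixelDetectors"``, ``"analysis"``) and a *data key* (e.g.
``"pnCCD"``, ``"hitscore"``) to a :class:`DataRecord`.  An event holds all
data belonging to a single X-ray pulse — the detector frame plus per-pulse
metadata — regardless of which facility or file format it came from.

Records come in three kinds, inferred from the payload's dimensionality:

========  ==============================  =======================
kind      payload                         typical content
========  ==============================  =======================
image     2-D array                       detector frame (ADU)
vector    1-D array                       histogram counts, traces
scalar    0-D (a single number)           hitscore, pulse energy
========  ==============================  =======================
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Dict, Iterator, List, Tuple, Union

import numpy as np

__all__ = [
    "DataRecord",
    "Event",
    "RecordAbsentError",
    "add_record",
    "get_record",
]

EventId = Tuple[int, int]

#: Record kinds, keyed by payload ndim.
_KIND_BY_NDIM = {0: "scalar", 1: "vector", 2: "image"}


class RecordAbsentError(KeyError):
    """Raised when an event has no record under the requested (type, key).

    Distinct from an empty record: an event may legitimately store an empty
    vector.  Carries both requested labels for diagnostics.
    """

    def __init__(self, type_label: str, key: str):
        super().__init__(f"no record '{type_label}/{key}' in event")
        self.type_label = type_label
        self.key = key


@dataclass
class DataRecord:
    """One named data entry of an event.

    ``name`` is always ``"<type>/<key>"``; ``kind`` is one of
    ``{"image", "scalar", "vector"}`` and matches the dimensionality of
    ``data``.  ``unit`` is a free-text unit label and may be empty.
    """

    name: str
    kind: str
    data: Any
    unit: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("image", "scalar", "vector"):
            raise ValueError(f"unknown record kind {self.kind!r}")
        if infer_kind(self.data) != self.kind:
            raise ValueError(
                f"record {self.name!r}: kind {self.kind!r} does not match "
                f"payload dimensionality"
            )


def infer_kind(data: Any) -> str:
    """Classify a payload as image/vector/scalar from its shape.

    Raises ``ValueError`` for payloads of dimensionality > 2; no record kind
    exists for them.
    """
    ndim = np.ndim(data)
    try:
        return _KIND_BY_NDIM[ndim]
    except KeyError:
        raise ValueError(
            f"payload with ndim={ndim} has no record kind "
            "(only scalar/vector/image are representable)"
        ) from None


@dataclass
class Event:
    """All data belonging to one detector pulse/frame.

    ``event_id`` is a ``(run_index, frame_index)`` pair, ordered
    lexicographically; within one source it is strictly increasing in read
    order.  ``records`` is exactly two levels deep; key enumeration order is
    insertion order.
    """

    event_id: EventId
    timestamp: float = 0.0
    records: Dict[str, Dict[str, DataRecord]] = field(default_factory=dict)

    # -- mapping-style helpers ------------------------------------------
    def types(self) -> List[str]:
        return list(self.records)

    def keys(self, type_label: str) -> List[str]:
        """Second-level keys stored under ``type_label``, in insertion order."""
        return list(self.records.get(type_label, {}))

    def has_record(self, type_label: str, key: str) -> bool:
        return key in self.records.get(type_label, {})

    def __iter__(self) -> Iterator[DataRecord]:
        for by_key in self.records.values():
            yield from by_key.values()

    def __len__(self) -> int:
        return sum(len(v) for v in self.records.values())

    def equal_records(self, other: "Event") -> bool:
        """Record-by-record equality (names, kinds, units, payload values)."""
        if self.types() != other.types():
            return False
        for t in self.types():
            if self.keys(t) != other.keys(t):
                return False
            for k in self.keys(t):
                a, b = self.records[t][k], other.records[t][k]
                if (a.name, a.kind, a.unit) != (b.name, b.kind, b.unit):
                    return False
                if not np.array_equal(np.asarray(a.data), np.asarray(b.data)):
                    return False
        return True


def add_record(
    evt: Event,
    type_label: str,
    key: str,
    data: Any,
    unit: str = "",
) -> DataRecord:
    """Attach ``data`` to ``evt`` as a new record under ``(type_label, key)``.

    The record's kind is inferred from the payload shape.  Re-adding an
    existing (type, key) replaces the previous record; by convention only
    ``"analysis"`` outputs should overwrite, but this is not enforced.

    Returns the stored :class:`DataRecord` (named ``"<type_label>/<key>"``).
    """
    kind = infer_kind(data)  # rejects ndim > 2
    record = DataRecord(name=f"{type_label}/{key}", kind=kind, data=data, unit=unit)
    evt.records.setdefault(type_label, {})[key] = record
    return record


def get_record(evt: Event, type_label: str, key: str) -> DataRecord:
    """Return the record stored under ``(type_label, key)``.

    Raises :class:`RecordAbsentError` if no such record exists — distinct
    from returning an empty record.
    """
    try:
        return evt.records[type_label][key]
    except KeyError:
        raise RecordAbsentError(type_label, key) from None
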