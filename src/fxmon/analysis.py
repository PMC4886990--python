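"""Per-event detector corrections and lit-pixel hit finding.

The processing chain applied to every diffraction frame is::

    raw ADU ─ dark_subtract ─ common_mode_correct ─ count_lit_pixels ─ classify_hit

* **Dark calibration.**  Dark frames (beam off) are averaged into a dark
  image — the per-pixel pedestal estimate — which is subtracted from raw
  frames.  Accumulation keeps a running (sum, count) pair so workers can
  accumulate independently and a master can merge them; averaging is a
  plain mean, in 64-bit arithmetic throughout.

* **Common-mode correction.**  pnCCD-style detectors show a per-readout-row
  additive offset that fluctuates frame to frame.  For each row we estimate
  it as the *median of the unlit pixels* (those below a signal-mask
  threshold, so genuine photon signal does not bias the estimate) and
  subtract it from the whole row.  If fewer than 10% of a row's pixels are
  unlit, the full-row median is used instead.  Median of an even count is
  the midpoint of the two central values.

* **Hit finding.**  A corrected pixel is *lit* when its value strictly
  exceeds ``lit_threshold`` — it is interpreted as containing photons.  The
  number of lit pixels is the **hitscore**; a frame is a **hit** when
  hitscore ≥ ``hitscore_threshold`` (inclusive).  These two thresholds are
  the tunables an operator adjusts live while watching the hitscore history
  and the ADU histogram.

Following the module conventions of the backend, each operation's result is
attached to the event as a new ``"analysis"``-type record.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import h5py
import numpy as np

__all__ = [
    "DarkAccumulator",
    "HitFinderParams",
    "HistogramSpec",
    "dark_accumulate",
    "dark_merge",
    "dark_finalize",
    "write_dark_file",
    "read_dark_file",
    "dark_subtract",
    "common_mode_correct",
    "count_lit_pixels",
    "classify_hit",
    "frame_histogram",
]


@dataclass
class DarkAccumulator:
    """Running per-pixel sum and frame count for dark averaging.

    Mergeable: two accumulators (e.g. from two workers) combine by summing
    both fields, so the final mean is independent of how frames were split.
    """

    sum_image: Optional[np.ndarray] = None
    count: int = 0

    @property
    def shape(self) -> Optional[tuple]:
        return None if self.sum_image is None else self.sum_image.shape


@dataclass(frozen=True)
class HitFinderParams:
    """The two tunables of the lit-pixel hit finder.

    ``lit_threshold``: ADU value a corrected pixel must *strictly exceed*
    to count as lit.  ``hitscore_threshold``: minimum lit-pixel count for a
    hit (inclusive).
    """

    lit_threshold: float
    hitscore_threshold: int

    def __post_init__(self) -> None:
        if not self.lit_threshold > 0:
            raise ValueError("lit_threshold must be > 0")
        if self.hitscore_threshold < 1:
            raise ValueError("hitscore_threshold must be >= 1")


@dataclass(frozen=True)
class HistogramSpec:
    """ADU histogram layout: n_bins equal bins on [lo, hi).

    Bins are half-open ``[edge_i, edge_{i+1})`` with the last bin closed;
    values outside [lo, hi] are discarded from the counts but reported as
    an out-of-range total.
    """

    n_bins: int
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if not self.lo < self.hi:
            raise ValueError("need lo < hi")

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(self.lo, self.hi, self.n_bins + 1)


# ---------------------------------------------------------------------------
# Dark calibration
# ---------------------------------------------------------------------------

def dark_accumulate(acc: DarkAccumulator, frame: np.ndarray) -> DarkAccumulator:
    """Absorb one dark frame into the accumulator (in place).

    A frame whose shape does not match the accumulator is rejected and the
    accumulator left unchanged.
    """
    frame = np.asarray(frame)
    if acc.sum_image is None:
        acc.sum_image = frame.astype(np.float64)
        acc.count = 1
        return acc
    if frame.shape != acc.sum_image.shape:
        raise ValueError(
            f"frame shape {frame.shape} does not match accumulator {acc.sum_image.shape}"
        )
    acc.sum_image += frame
    acc.count += 1
    return acc


def dark_merge(a: DarkAccumulator, b: DarkAccumulator) -> DarkAccumulator:
    """Combine two accumulators (worker merge step)."""
    if a.sum_image is None:
        return DarkAccumulator(
            None if b.sum_image is None else b.sum_image.copy(), b.count
        )
    if b.sum_image is None:
        return DarkAccumulator(a.sum_image.copy(), a.count)
    if a.sum_image.shape != b.sum_image.shape:
        raise ValueError("cannot merge accumulators of different shapes")
    return DarkAccumulator(a.sum_image + b.sum_image, a.count + b.count)


def dark_finalize(acc: DarkAccumulator) -> np.ndarray:
    """Per-pixel mean dark image (float64)."""
    if acc.count < 1 or acc.sum_image is None:
        raise ValueError("no frames accumulated")
    return acc.sum_image / acc.count


def write_dark_file(path: str, dark: np.ndarray, n_frames: int, source_run: str = "") -> None:
    """Write an averaged dark image to ``/data/data`` with provenance attrs."""
    with h5py.File(path, "w", track_order=False) as f:
        grp = f.create_group("data")
        dset = grp.create_dataset(
            "data", data=np.asarray(dark, dtype=np.float64), track_times=False
        )
        dset.attrs["n_frames"] = int(n_frames)
        dset.attrs["source_run"] = source_run


def read_dark_file(path: str) -> Tuple[np.ndarray, int, str]:
    with h5py.File(path, "r") as f:
        dset = f["data/data"]
        return dset[...], int(dset.attrs["n_frames"]), str(dset.attrs["source_run"])


def dark_subtract(frame: np.ndarray, dark: np.ndarray) -> np.ndarray:
    """Element-wise ``frame - dark`` in float64; may be negative, no clipping."""
    frame = np.asarray(frame)
    dark = np.asarray(dark)
    if frame.shape != dark.shape:
        raise ValueError(f"shape mismatch: frame {frame.shape}, dark {dark.shape}")
    return frame.astype(np.float64) - dark


# ---------------------------------------------------------------------------
# Common mode
# ---------------------------------------------------------------------------

#: If fewer than this fraction of a row is unlit, fall back to the full-row
#: median (the masked estimate would rest on too few pixels).
_MIN_UNLIT_FRACTION = 0.10


def common_mode_correct(frame: np.ndarray, signal_mask_threshold: float) -> np.ndarray:
    """Row-wise common-mode correction of a dark-subtracted frame.

    Per detector row (axis 0), subtracts the median of the pixels below
    ``signal_mask_threshold``; rows with < 10% such pixels use the
    full-row median.  Idempotent when no pixel crosses the mask threshold
    after the first pass.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 2:
        raise ValueError("expected a 2-D detector frame")
    n_cols = frame.shape[1]
    unlit = frame < signal_mask_threshold
    n_unlit = unlit.sum(axis=1)

    masked = np.where(unlit, frame, np.nan)
    with np.errstate(all="ignore"):
        offsets = np.nanmedian(masked, axis=1)
    fallback = n_unlit < _MIN_UNLIT_FRACTION * n_cols
    if fallback.any():
        offsets[fallback] = np.median(frame[fallback], axis=1)
    return frame - offsets[:, None]


# ---------------------------------------------------------------------------
# Hit finding & histogram
# ---------------------------------------------------------------------------

def count_lit_pixels(frame: np.ndarray, params: HitFinderParams) -> int:
    """Hitscore: number of pixels strictly above the lit threshold."""
    return int(np.count_nonzero(np.asarray(frame) > params.lit_threshold))


def classify_hit(hitscore: int, params: HitFinderParams) -> bool:
    """True iff the frame is a hit: hitscore ≥ hitscore_threshold."""
    return hitscore >= params.hitscore_threshold


def frame_histogram(frame: np.ndarray, spec: HistogramSpec) -> Tuple[np.ndarray, np.ndarray, int]:
    """ADU histogram of one frame.

    Returns ``(counts, edges, n_out_of_range)``: counts per half-open bin
    (last bin closed, matching :func:`numpy.histogram`), the bin edges, and
    the number of pixel values outside [lo, hi].
    """
    values = np.asarray(frame).ravel()
    counts, edges = np.histogram(values, bins=spec.n_bins, range=(spec.lo, spec.hi))
    out_of_range = int(values.size - counts.sum())
    return counts, edges, out_of_range
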