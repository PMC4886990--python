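"""Synthetic pnCCD-like detector runs with known ground truth.

Real commissioning data for a flash X-ray imaging beamtime consists of a
*dark* run (detector read out with the beam off) and a *diffraction* run
(a stream of shots, a small fraction of which actually hit an injected
particle).  This module generates both kinds as run files in the dialect of
:mod:`fxmon.data_sources`, with the statistical ingredients that make the
downstream corrections nontrivial:

* a fixed per-pixel **pedestal** (the detector baseline),
* per-pixel Gaussian **read noise**,
* a per-row, per-frame Gaussian **common-mode** offset (the row-correlated
  baseline wander that row-wise median correction removes),
* for hit frames, ``K ~ Poisson(photons_per_hit_mean)`` photons placed at
  pixels drawn from a centro-symmetric, radially decaying intensity
  profile, each depositing ``photon_adu`` ADU (single-photon-counting
  regime: one gain value, no charge sharing or split events).

Generation is fully deterministic: the same ``(model, recipe)`` pair yields
a byte-identical run file (HDF5 object timestamps are disabled).  Ground
truth — which frames are hits, how many photons landed, and on which
pixels — is stored in the file's truth datasets and returned in memory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .data_sources import write_run_file

__all__ = [
    "DetectorModel",
    "RunRecipe",
    "RunTruth",
    "default_model",
    "generate_dark_run",
    "generate_diffraction_run",
]

#: Nominal LCLS pulse repetition rate used for synthetic timestamps (Hz).
PULSE_RATE_HZ = 120.0


@dataclass
class DetectorModel:
    """Statistical model of the detector readout.

    Parameters
    ----------
    shape : (rows, cols)
    pedestal : per-pixel baseline image, ADU
    read_noise_sigma : per-pixel Gaussian read-noise sd, ADU
    common_mode_sigma : sd of the per-row, per-frame additive offset, ADU
    photon_adu : ADU deposited per photon (single gain value)
    saturation : maximum representable ADU
    """

    shape: tuple
    pedestal: np.ndarray
    read_noise_sigma: float = 3.0
    common_mode_sigma: float = 5.0
    photon_adu: float = 120.0
    saturation: int = 65535

    def __post_init__(self) -> None:
        self.pedestal = np.asarray(self.pedestal, dtype=np.float64)
        if self.pedestal.shape != tuple(self.shape):
            raise ValueError("pedestal shape does not match detector shape")
        if self.read_noise_sigma < 0 or self.common_mode_sigma < 0:
            raise ValueError("noise sigmas must be >= 0")
        # Lit pixels must be separable from read noise, otherwise planted
        # truth is not recoverable and the fixture is ill-posed.
        if not self.photon_adu > 5 * self.read_noise_sigma:
            raise ValueError("photon_adu must exceed 5 x read_noise_sigma")

    @property
    def frame_dtype(self) -> np.dtype:
        return np.dtype(np.uint16 if self.saturation <= 0xFFFF else np.uint32)


def default_model(pedestal_seed: int = 7) -> DetectorModel:
    """The fixture-default 256×256 detector.

    Pedestal drawn once uniform in [90, 110] ADU from ``pedestal_seed``;
    read noise 3 ADU, common mode 5 ADU, 120 ADU/photon, 16-bit saturation.
    All values are fixture defaults chosen so that a lit-pixel threshold
    between the noise peak and the photon peak is easy to place.
    """
    shape = (256, 256)
    rng = np.random.default_rng(pedestal_seed)
    pedestal = rng.uniform(90.0, 110.0, size=shape)
    return DetectorModel(shape=shape, pedestal=pedestal)


@dataclass
class RunRecipe:
    """What a run should contain.  Same recipe + model ⇒ identical file."""

    n_frames: int
    hit_fraction: float = 0.0
    photons_per_hit_mean: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 0:
            raise ValueError("n_frames must be >= 0")
        if not 0.0 <= self.hit_fraction <= 1.0:
            raise ValueError("hit_fraction must be in [0, 1]")


@dataclass
class RunTruth:
    """Ground truth of a generated run."""

    is_hit: np.ndarray  # (n,) bool
    n_photons: np.ndarray  # (n,) int
    photon_pixels: List[np.ndarray] = field(default_factory=list)  # flat indices, per frame

    def lit_pixel_count(self, i: int) -> int:
        """Number of *distinct* pixels that received photons in frame i."""
        return int(np.unique(self.photon_pixels[i]).size)


def _intensity_profile(shape: tuple) -> np.ndarray:
    """Centro-symmetric, radially decaying photon-placement probabilities.

    A smooth ~1/(1+(r/r0)^3) falloff about the detector centre — the
    qualitative shape of forward scattering from a compact particle, not a
    physical form factor.
    """
    rows, cols = shape
    y = np.arange(rows) - (rows - 1) / 2.0
    x = np.arange(cols) - (cols - 1) / 2.0
    r = np.hypot(y[:, None], x[None, :])
    r0 = max(rows, cols) / 8.0
    p = 1.0 / (1.0 + (r / r0) ** 3)
    return (p / p.sum()).ravel()


def _synthesize(
    model: DetectorModel,
    recipe: RunRecipe,
    path: str,
    with_hits: bool,
) -> RunTruth:
    import h5py

    n = recipe.n_frames
    rows, cols = model.shape
    rng = np.random.default_rng(recipe.seed)

    n_hits = math.ceil(recipe.hit_fraction * n) if with_hits else 0
    # Hit frames = first ceil(hit_fraction * n) entries of a seeded permutation.
    perm = rng.permutation(n)
    is_hit = np.zeros(n, dtype=bool)
    is_hit[perm[:n_hits]] = True

    profile = _intensity_profile(model.shape) if n_hits else None
    n_photons = np.zeros(n, dtype=np.int64)
    photon_pixels: List[np.ndarray] = []

    dtype = model.frame_dtype
    timestamps = np.arange(n, dtype=np.float64) / PULSE_RATE_HZ

    chunk = 256
    with h5py.File(path, "w", track_order=False) as f:
        entry = f.create_group("entry", track_order=False)
        entry.attrs["detector_key"] = "pnCCD"
        data = entry.create_group("data")
        dset = data.create_dataset(
            "frames", shape=(n, rows, cols), dtype=dtype, track_times=False
        )
        data.create_dataset("timestamps", data=timestamps, track_times=False)

        buf = np.empty((min(chunk, n) if n else 0, rows, cols), dtype=dtype)
        filled = 0
        start = 0
        for i in range(n):
            cm = rng.normal(0.0, model.common_mode_sigma, size=rows)
            noise = rng.normal(0.0, model.read_noise_sigma, size=(rows, cols))
            frame = model.pedestal + cm[:, None] + noise
            if is_hit[i]:
                k = int(rng.poisson(recipe.photons_per_hit_mean))
                pix = rng.choice(rows * cols, size=k, replace=True, p=profile)
                n_photons[i] = k
                photon_pixels.append(np.sort(pix))
                if k:
                    counts = np.bincount(pix, minlength=rows * cols)
                    frame += model.photon_adu * counts.reshape(rows, cols)
            else:
                photon_pixels.append(np.empty(0, dtype=np.int64))
            np.clip(np.rint(frame), 0, model.saturation, out=frame)
            buf[filled] = frame.astype(dtype)
            filled += 1
            if filled == buf.shape[0]:
                dset[start : start + filled] = buf[:filled]
                start += filled
                filled = 0
                buf = np.empty((min(chunk, n - start), rows, cols), dtype=dtype)
        if filled:
            dset[start : start + filled] = buf[:filled]

        truth = entry.create_group("truth")
        truth.create_dataset("is_hit", data=is_hit.astype(np.uint8), track_times=False)
        truth.create_dataset("n_photons", data=n_photons, track_times=False)

    return RunTruth(is_hit=is_hit, n_photons=n_photons, photon_pixels=photon_pixels)


def generate_dark_run(model: DetectorModel, recipe: RunRecipe, path: str) -> RunTruth:
    """Write a dark run: pedestal + common mode + read noise, no photons.

    Dark recipes must have ``hit_fraction == 0``; the truth datasets are
    all-zero.
    """
    if recipe.hit_fraction != 0.0:
        raise ValueError("dark runs must have hit_fraction == 0")
    return _synthesize(model, recipe, path, with_hits=False)


def generate_diffraction_run(model: DetectorModel, recipe: RunRecipe, path: str) -> RunTruth:
    """Write a diffraction run: dark background plus planted photon signal.

    Exactly ``ceil(hit_fraction * n_frames)`` frames, chosen by a seeded
    permutation, carry Poisson-distributed photon counts placed on the
    radial intensity profile.  Returns the ground truth including per-frame
    photon pixel indices (the file stores only ``is_hit``/``n_photons``).
    """
    return _synthesize(model, recipe, path, with_hits=True)
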