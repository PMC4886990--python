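"""Declarative, hot-reloadable pipeline configuration.

A backend run is described by a structured config file (YAML) with three
parts, mirroring the source / processing-chain / outputs split of the
monitoring server:

.. code-block:: yaml

    source:
      mode: file_run
      files: [runs/diffraction.h5]
      detector_key: pnCCD
    stages:                      # ordered; names from the stage registry
      - name: dark_subtract
        dark_file: darks/dark.h5
      - name: common_mode
      - name: histogram
      - name: hitscore
      - name: classify
    outputs:
      - {name: histogram,  kind: histogram, record: analysis/histogram, when: always}
      - {name: hitscore,   kind: history,   record: analysis/hitscore,  when: always}
      - {name: hit image,  kind: image,     record: analysis/corrected, when: hits_only}
    parameters: params.yaml      # numeric tunables, re-read on reload

The *structure* (stage chain, outputs) is fixed for the lifetime of a run;
only the parameters file — thresholds and histogram range — is re-read on
reload, so an operator can tune the hit finder live without restarting.
Unknown stage names are rejected at load time, by name.  Custom stages can
be registered in the host language via :func:`register_stage`, preserving
the flexibility of an executable config without its reload hazards.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional

import yaml

from .analysis import HistogramSpec, HitFinderParams
from .data_sources import SourceSpec

__all__ = [
    "ConfigError",
    "StageSpec",
    "OutputSpec",
    "PipelineConfig",
    "Parameters",
    "load_config",
    "load_parameters",
    "register_stage",
    "stage_registry",
]


class ConfigError(ValueError):
    """Configuration rejected at load time."""


# Stage registry: name -> callable(evt, ctx).  Populated by the backend
# module for the built-in stages; users may add their own.
_STAGE_REGISTRY: Dict[str, Callable] = {}


def register_stage(name: str) -> Callable[[Callable], Callable]:
    def deco(fn: Callable) -> Callable:
        _STAGE_REGISTRY[name] = fn
        return fn

    return deco


def stage_registry() -> Dict[str, Callable]:
    return dict(_STAGE_REGISTRY)


@dataclass
class StageSpec:
    name: str
    options: Dict[str, object] = field(default_factory=dict)


@dataclass
class OutputSpec:
    """One plot-source declaration: which record to send, as what, when."""

    name: str
    kind: str  # image | history | histogram | vector
    record: str  # "<type>/<key>"
    when: str = "always"  # always | hits_only

    def __post_init__(self) -> None:
        if self.when not in ("always", "hits_only"):
            raise ConfigError(f"output {self.name!r}: unknown send-condition {self.when!r}")
        if "/" not in self.record:
            raise ConfigError(f"output {self.name!r}: record must be '<type>/<key>'")


@dataclass
class Parameters:
    """The reloadable numeric tunables of the reference pipelines."""

    lit_threshold: float = 60.0
    hitscore_threshold: int = 3
    mask_threshold: Optional[float] = None  # default: lit_threshold / 2
    histogram_bins: int = 100
    histogram_lo: float = -50.0
    histogram_hi: float = 250.0

    def __post_init__(self) -> None:
        if not self.lit_threshold > 0:
            raise ConfigError("lit_threshold must be > 0")
        if int(self.hitscore_threshold) < 1:
            raise ConfigError("hitscore_threshold must be >= 1")
        self.hitscore_threshold = int(self.hitscore_threshold)
        if self.histogram_bins < 1 or not self.histogram_lo < self.histogram_hi:
            raise ConfigError("invalid histogram range")

    @property
    def effective_mask_threshold(self) -> float:
        # Separate knob from lit_threshold: the common-mode mask should be
        # stricter, so residual signal cannot bias the row median.
        return self.lit_threshold / 2.0 if self.mask_threshold is None else self.mask_threshold

    def hit_finder(self) -> HitFinderParams:
        return HitFinderParams(self.lit_threshold, self.hitscore_threshold)

    def histogram_spec(self) -> HistogramSpec:
        return HistogramSpec(self.histogram_bins, self.histogram_lo, self.histogram_hi)


@dataclass
class PipelineConfig:
    source: SourceSpec
    stages: List[StageSpec]
    outputs: List[OutputSpec] = field(default_factory=list)
    parameters: Parameters = field(default_factory=Parameters)
    parameters_path: Optional[str] = None

    def __post_init__(self) -> None:
        for st in self.stages:
            if st.name not in _STAGE_REGISTRY:
                raise ConfigError(
                    f"unknown stage {st.name!r}; registered: {sorted(_STAGE_REGISTRY)}"
                )


def load_parameters(path: str) -> Parameters:
    """Read the tunables file.  Raises :class:`ConfigError` if malformed."""
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot read parameters file {path!r}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"parameters file {path!r} must hold a mapping")
    known = {f for f in Parameters.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown parameters {sorted(unknown)} in {path!r}")
    try:
        return Parameters(**raw)
    except (TypeError, ConfigError) as exc:
        raise ConfigError(f"invalid parameters in {path!r}: {exc}") from exc


def load_config(path: str) -> PipelineConfig:
    """Load and validate a pipeline config file."""
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot read config {path!r}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")

    src = raw.get("source")
    if not isinstance(src, dict) or "mode" not in src:
        raise ConfigError("config needs a 'source' section with a 'mode'")
    location = src.get("files", src.get("endpoint"))
    if location is None:
        raise ConfigError("source needs 'files' (file_run) or 'endpoint' (stream)")
    try:
        source = SourceSpec(
            mode=src["mode"], location=location, detector_key=src.get("detector_key", "pnCCD")
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc

    stages = []
    for entry in raw.get("stages", []):
        if isinstance(entry, str):
            stages.append(StageSpec(entry))
        elif isinstance(entry, dict) and "name" in entry:
            opts = {k: v for k, v in entry.items() if k != "name"}
            stages.append(StageSpec(entry["name"], opts))
        else:
            raise ConfigError(f"malformed stage entry: {entry!r}")

    outputs = []
    for entry in raw.get("outputs", []):
        if not isinstance(entry, dict):
            raise ConfigError(f"malformed output entry: {entry!r}")
        try:
            outputs.append(
                OutputSpec(
                    name=entry["name"],
                    kind=entry["kind"],
                    record=entry["record"],
                    when=entry.get("when", "always"),
                )
            )
        except KeyError as exc:
            raise ConfigError(f"output entry missing {exc}") from exc

    params_path = raw.get("parameters")
    if params_path is not None:
        if not os.path.isabs(params_path):
            params_path = os.path.join(os.path.dirname(os.path.abspath(path)), params_path)
        parameters = load_parameters(params_path)
    else:
        parameters = Parameters()

    return PipelineConfig(
        source=source,
        stages=stages,
        outputs=outputs,
        parameters=parameters,
        parameters_path=params_path,
    )
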