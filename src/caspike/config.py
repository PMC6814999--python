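"""Run configuration: a validated plain key-value (YAML) schema.

All method defaults are baked in and overridable: 1.109 s frame interval,
3×SD event threshold, 15 ms / 3-spike / 100 ms burst criteria, the 10 Hz
fast-spiking cutoff and the 80–120% response-class bounds.  Times are in
seconds; analysis windows are half-open [start, end).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .datatypes import ConfigError

PIPELINES = ("imaging", "ephys", "simulate")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    pipeline: str = "simulate"
    # inputs (analysis pipelines)
    traces: Optional[str] = None
    spikes: Optional[str] = None
    metadata: Optional[str] = None
    movie: Optional[str] = None
    masks: Optional[str] = None
    roi_flags: Optional[str] = None
    outdir: str = "caspike_out"
    seed: int = 0
    # imaging parameters
    frame_interval: float = 1.109
    baseline_window: Optional[tuple[float, float]] = None
    min_fraction: float = 0.1
    k_sd: float = 3.0
    window_s: float = 60.0
    total_activity_mode: str = "events"
    # electrophysiology parameters
    max_intra_isi: float = 0.015
    min_spikes: int = 3
    min_inter_burst: float = 0.100
    fs_cutoff: float = 10.0
    sr_lower: float = 80.0
    sr_upper: float = 120.0
    baseline_duration: float = 600.0
    post_bins_min: tuple[int, ...] = (30, 60, 90)
    response_window_min: tuple[float, float] = (30.0, 60.0)
    burst_rate_mode: str = "bursts_per_s"  # or "in_burst_spikes"
    # simulate parameters
    n_units: int = 80
    duration: float = 4200.0
    injection_time: float = 600.0
    groups: dict = field(default_factory=lambda: {"rag": 7.9, "nrg1": 19.9})
    drugs: tuple[str, ...] = ("saline", "mk801", "dcs", "sarcosine")
    movies: bool = False
    movie_units: int = 2

    def __post_init__(self) -> None:
        if self.pipeline not in PIPELINES:
            raise ConfigError(f"unknown pipeline {self.pipeline!r}; "
                              f"choose from {PIPELINES}")
        if self.burst_rate_mode not in ("bursts_per_s", "in_burst_spikes"):
            raise ConfigError("burst_rate_mode must be 'bursts_per_s' or "
                              "'in_burst_spikes'")
        if self.sr_lower >= self.sr_upper:
            raise ConfigError("need sr_lower < sr_upper")
        if self.seed < 0:
            raise ConfigError("seed must be >= 0")
        if self.baseline_window is not None:
            self.baseline_window = tuple(float(v) for v in self.baseline_window)
            if self.baseline_window[1] <= self.baseline_window[0]:
                raise ConfigError("baseline_window must have positive length")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def require_inputs(self) -> None:
        """Check that the analysis pipeline's referenced paths exist."""
        needed: list[str] = []
        if self.pipeline == "imaging":
            if self.traces is None and self.movie is None:
                raise ConfigError("imaging pipeline needs 'traces' or "
                                  "'movie' + 'masks'")
            if self.movie is not None and self.masks is None:
                raise ConfigError("a movie input needs 'masks'")
            needed = [p for p in (self.traces, self.movie, self.masks,
                                  self.roi_flags) if p]
        elif self.pipeline == "ephys":
            if self.spikes is None or self.metadata is None:
                raise ConfigError("ephys pipeline needs 'spikes' and 'metadata'")
            needed = [self.spikes, self.metadata]
        for p in needed:
            if not Path(p).exists():
                raise ConfigError(f"input path does not exist: {p}")


def load_config(path: Path | str, **overrides) -> RunConfig:
    """Load and validate a YAML run configuration; unknown keys are errors."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a key-value mapping")
    raw.update(overrides)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for key in ("post_bins_min", "drugs", "response_window_min"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    try:
        return RunConfig(**raw)
    except TypeError as exc:  # pragma: no cover - defensive
        raise ConfigError(str(exc)) from exc


__all__ = ["RunConfig", "load_config", "PIPELINES"]
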