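"""Core containers and exceptions shared across the pipeline.

The containers mirror the objects a two-photon / single-unit study produces:
raw ROI fluorescence, ΔF/F traces, detected calcium events and their per-window
metrics on the imaging side; spike trains, burst sets and windowed firing rates
on the electrophysiology side.  They are plain dataclasses with light
validation — the heavy lifting lives in :mod:`caspike.imaging` and
:mod:`caspike.spikes`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

FAST_SPIKING = "fast_spiking"
REGULAR_SPIKING = "regular_spiking"
RESPONSE_CLASSES = ("decrease", "no_change", "increase")


# ---------------------------------------------------------------------------
# exceptions
# ---------------------------------------------------------------------------

class CaspikeError(Exception):
    """Base class for all package errors."""


class ParameterError(CaspikeError, ValueError):
    """Invalid parameter value (negative rate, zero-length window, ...)."""


class ConfigError(CaspikeError, ValueError):
    """Malformed or inconsistent run configuration.  CLI exit code 2."""


class DataError(CaspikeError, ValueError):
    """Invalid or degenerate input data.  CLI exit code 3."""


class FormatError(DataError):
    """Structurally broken input (unsorted spikes, shape mismatch, ...)."""


class ROIError(DataError):
    """Unusable region of interest (e.g. an empty mask)."""


class LayoutError(ParameterError):
    """Invalid synthetic-movie layout (overlapping or out-of-frame somata)."""


class DegenerateBaselineError(DataError):
    """Baseline fluorescence F0 is non-positive; ΔF/F is undefined."""


class InsufficientBaselineError(DataError):
    """Too few baseline frames to estimate F0 and the noise SD."""


class DegenerateNoiseError(DataError):
    """Noise SD is zero on a non-constant trace; the 3×SD rule is undefined."""


class DesignError(DataError):
    """Unusable factorial design (empty cell, single-level factor)."""


# ---------------------------------------------------------------------------
# imaging-side containers
# ---------------------------------------------------------------------------

@dataclass
class FluorescenceTrace:
    """Raw fluorescence of one ROI over frames.

    ``background`` is either a scalar or a per-frame array; subtraction is
    deferred to ΔF/F computation.  ``include_flag`` carries the study's
    "nucleus-filled" manual exclusion: flagged-out ROIs are still processed
    but excluded from group summaries.
    """

    roi_id: str
    frame_times: np.ndarray
    raw_f: np.ndarray
    background: float | np.ndarray = 0.0
    include_flag: bool = True

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.raw_f = np.asarray(self.raw_f, dtype=float)
        if self.frame_times.shape != self.raw_f.shape:
            raise FormatError(
                f"ROI {self.roi_id}: frame_times and raw_f lengths differ"
            )
        if not np.all(np.isfinite(self.raw_f)):
            raise FormatError(f"ROI {self.roi_id}: non-finite fluorescence")
        if self.frame_times.size >= 2:
            dt = np.diff(self.frame_times)
            if np.any(dt <= 0):
                raise FormatError(f"ROI {self.roi_id}: frame times not increasing")
            if np.ptp(dt) > 1e-6:
                raise FormatError(f"ROI {self.roi_id}: non-uniform frame interval")
        bg = np.asarray(self.background, dtype=float)
        if bg.ndim not in (0, 1) or (bg.ndim == 1 and bg.shape != self.raw_f.shape):
            raise FormatError(f"ROI {self.roi_id}: background shape mismatch")

    @property
    def frame_interval(self) -> float:
        if self.frame_times.size < 2:
            return float("nan")
        return float(self.frame_times[1] - self.frame_times[0])


@dataclass
class DFFTrace:
    """ΔF/F trace with its baseline statistics.

    ``noise_mean``/``noise_sd`` are the robust mean and SD of ΔF/F over
    sub-threshold baseline frames; the event threshold is referenced to
    ``noise_mean`` (see :func:`caspike.imaging.detect_events`).
    """

    roi_id: str
    frame_times: np.ndarray
    dff: np.ndarray
    f0: float
    noise_sd: float
    baseline_window: tuple[float, float]
    noise_mean: float = 0.0
    include_flag: bool = True

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.dff = np.asarray(self.dff, dtype=float)
        if self.f0 <= 0:
            raise DegenerateBaselineError(f"ROI {self.roi_id}: F0 = {self.f0} <= 0")
        if not np.all(np.isfinite(self.dff)):
            raise FormatError(f"ROI {self.roi_id}: non-finite dF/F")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")

    @property
    def frame_interval(self) -> float:
        return float(self.frame_times[1] - self.frame_times[0])


@dataclass
class CaEvent:
    """One supra-threshold calcium transient."""

    onset_time: float
    offset_time: float
    peak_time: float
    amplitude: float
    area: float

    def __post_init__(self) -> None:
        if not (self.onset_time <= self.peak_time <= self.offset_time):
            raise ParameterError("event times must satisfy onset <= peak <= offset")
        if self.area < 0:
            raise ParameterError("event area must be >= 0")


@dataclass
class CaMetrics:
    """Per-window activity metrics of one ROI.

    frequency is in events/min; total_activity is integrated event area
    (ΔF/F·s) per minute; amplitude_mean is NaN when the window holds no event.
    """

    roi_id: str
    window: tuple[float, float]
    amplitude_mean: float
    frequency: float
    total_activity: float
    n_events: int = 0


# ---------------------------------------------------------------------------
# electrophysiology-side containers
# ---------------------------------------------------------------------------

@dataclass
class SpikeTrain:
    """Sorted spike times of one unit."""

    unit_id: str
    spike_times: np.ndarray
    recording_span: tuple[float, float]
    injection_time: Optional[float] = None
    group_label: Optional[str] = None

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.size and np.any(np.diff(self.spike_times) <= 0):
            raise FormatError(f"unit {self.unit_id}: spike times not strictly increasing")
        lo, hi = self.recording_span
        if hi <= lo:
            raise ParameterError("recording_span must have positive length")
        if self.spike_times.size and (
            self.spike_times[0] < lo or self.spike_times[-1] > hi
        ):
            raise FormatError(f"unit {self.unit_id}: spikes outside recording span")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)


@dataclass
class BurstCriteria:
    """The three burst rules: intra-burst ISI < 15 ms, >=3 spikes per burst,
    inter-burst interval > 100 ms."""

    max_intra_isi: float = 0.015
    min_spikes: int = 3
    min_inter_burst: float = 0.100

    def __post_init__(self) -> None:
        if self.max_intra_isi <= 0 or self.min_inter_burst <= 0:
            raise ParameterError("burst intervals must be positive")
        if self.min_spikes < 2:
            raise ParameterError("min_spikes must be >= 2")


@dataclass
class BurstSet:
    """Bursts of one unit as (start_s, end_s, n_spikes) triples."""

    unit_id: str
    bursts: list[tuple[float, float, int]]
    criteria: BurstCriteria = field(default_factory=BurstCriteria)

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for start, end, n in self.bursts:
            if n < self.criteria.min_spikes:
                raise ParameterError("burst with fewer spikes than min_spikes")
            if start - prev_end <= self.criteria.min_inter_burst and prev_end > -np.inf:
                raise ParameterError("bursts closer than min_inter_burst")
            if end < start:
                raise ParameterError("burst end before start")
            prev_end = end

    @property
    def n_bursts(self) -> int:
        return len(self.bursts)

    @property
    def starts(self) -> np.ndarray:
        return np.array([b[0] for b in self.bursts], dtype=float)

    @property
    def ends(self) -> np.ndarray:
        return np.array([b[1] for b in self.bursts], dtype=float)

    @property
    def counts(self) -> np.ndarray:
        return np.array([b[2] for b in self.bursts], dtype=int)


@dataclass
class UnitRates:
    """Windowed firing rates of one unit.

    mean_rate counts all spikes; single_rate excludes spikes inside burst
    intervals; burst_rate counts bursts (by start time) per second.
    """

    unit_id: str
    window: tuple[float, float]
    mean_rate: float
    single_rate: float
    burst_rate: float
    in_burst_spike_rate: float = 0.0
    unit_class: Optional[str] = None

    def __post_init__(self) -> None:
        if self.single_rate > self.mean_rate + 1e-12:
            raise ParameterError("single_rate cannot exceed mean_rate")
        if min(self.mean_rate, self.single_rate, self.burst_rate) < 0:
            raise ParameterError("rates must be >= 0")


@dataclass
class DrugResponse:
    """Relative spike rate (%) of one unit and its response class."""

    unit_id: str
    sr_percent: float
    response_class: str
    metric: str = "mean_rate"

    def __post_init__(self) -> None:
        if self.response_class not in RESPONSE_CLASSES + ("undefined",):
            raise ParameterError(f"unknown response class {self.response_class!r}")


__all__ = [
    "FAST_SPIKING",
    "REGULAR_SPIKING",
    "RESPONSE_CLASSES",
    "CaspikeError",
    "ParameterError",
    "ConfigError",
    "DataError",
    "FormatError",
    "ROIError",
    "LayoutError",
    "DegenerateBaselineError",
    "InsufficientBaselineError",
    "DegenerateNoiseError",
    "DesignError",
    "FluorescenceTrace",
    "DFFTrace",
    "CaEvent",
    "CaMetrics",
    "SpikeTrain",
    "BurstCriteria",
    "BurstSet",
    "UnitRates",
    "DrugResponse",
]
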