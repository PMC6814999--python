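"""Synthetic spike trains, fluorescence traces and movies with ground truth.

The generator emulates the study conditions the analysis pipeline is built
for: frontal-cortex units firing a mixture of Poisson single spikes and tight
bursts (intra-burst ISI well under 15 ms, inter-burst gaps well over 100 ms,
so the burst detector's criteria are satisfiable by construction), somatic
GCaMP6s-like fluorescence sampled at ~0.9 Hz (1.109 s/frame) in which bursts
dominate the signal, and pharmacological step changes in rate at a known
injection time.  Every generated object is paired with a :class:`GroundTruth`
record so detector recall, precision and rate recovery can be measured
exactly.

Default group rates follow the study design: control units average 8 Hz,
the disease-model units 20 Hz (a 250% elevation), bursts occur at ~2/min in
both groups, and the NMDAR-antagonist condition suppresses bursting while
raising regular-spiking single-spike rates (~126% of baseline) and lowering
fast-spiking rates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .datatypes import (
    FAST_SPIKING,
    REGULAR_SPIKING,
    FluorescenceTrace,
    LayoutError,
    ParameterError,
    SpikeTrain,
)

#: default frame interval of the two-photon time series, seconds
DEFAULT_FRAME_INTERVAL = 1.109


# ---------------------------------------------------------------------------
# profiles and ground truth
# ---------------------------------------------------------------------------

@dataclass
class SimProfile:
    """Condition profile for spike-train generation.

    Parameters
    ----------
    single_rate
        Mean single-spike (non-burst) rate, Hz, before injection.
    burst_rate
        Burst occurrences per second before injection.  The default
        0.034/s corresponds to ~2 events/min, the control-level calcium
        event frequency.
    burst_size_mean
        Mean spikes per burst; sizes are drawn as 3 + Poisson(mean − 3) so
        every burst satisfies the "more than 2 spikes" rule.
    intra_burst_isi
        Spacing of spikes inside a burst, must be < 0.015 s so generated
        bursts satisfy the detector's ISI rule by construction.
    drug_effect
        Multiplicative single-spike rate factor applied after
        ``injection_time``; either a scalar or a mapping keyed by unit class
        (``fast_spiking`` / ``regular_spiking``).
    drug_burst_effect
        Burst-rate factor after injection; defaults to ``drug_effect``.
    drug_amp_effect
        Factor on transient amplitudes after injection (forwarded to the
        fluorescence model); emulates reduced calcium influx per burst.
    onset_ramp
        Length of a linear ramp from the pre- to the post-injection rate,
        seconds.  0 (default) is a step change.
    rate_cv
        Coefficient of variation of the lognormal unit-to-unit rate
        multiplier (applied to both single and burst rates).
    min_burst_gap
        Enforced minimum gap between consecutive bursts, seconds.  Must be
        > 0.100 s so ground-truth bursts can never merge under the
        detector's inter-burst rule.
    single_refractory
        Dead time between consecutive single spikes, seconds.  Defaults to
        the burst-ISI rule (15 ms) so that spikes labelled "single" in the
        ground truth can never themselves satisfy the operational burst
        definition — otherwise the truth would mislabel chance Poisson
        triplets, which at 8–20 Hz occur about as often as real bursts.
        Singles are drawn from a rate-exact dead-time renewal process
        (mean ISI = refractory + exponential part), so the realised rate
        still converges to ``single_rate``.  Set to 0 for a pure Poisson
        process.
    """

    label: str = "control"
    single_rate: float = 7.9
    burst_rate: float = 0.034
    burst_size_mean: float = 3.0
    intra_burst_isi: float = 0.005
    drug_effect: float | Mapping[str, float] = 1.0
    drug_burst_effect: Optional[float | Mapping[str, float]] = None
    drug_amp_effect: float = 1.0
    injection_time: float = 600.0
    onset_ramp: float = 0.0
    n_units: int = 80
    duration: float = 4200.0
    seed: int = 0
    rate_cv: float = 0.2
    fs_cutoff: float = 10.0
    min_burst_gap: float = 0.100
    single_refractory: float = 0.015

    def __post_init__(self) -> None:
        if self.single_rate < 0 or self.burst_rate < 0:
            raise ParameterError("rates must be >= 0")
        if self.single_refractory < 0:
            raise ParameterError("single_refractory must be >= 0")
        max_factor = max(
            v for v in (
                [1.0] + (list(self.drug_effect.values())
                         if isinstance(self.drug_effect, Mapping)
                         else [float(self.drug_effect)])
            )
        )
        if self.single_rate * max_factor * self.single_refractory >= 0.9:
            raise ParameterError(
                "single_rate too high for the configured refractory dead time"
            )
        if self.duration <= 0:
            raise ParameterError("duration must be > 0")
        if not (0 < self.intra_burst_isi < 0.015):
            raise ParameterError("intra_burst_isi must lie in (0, 0.015) s")
        if self.burst_size_mean < 3:
            raise ParameterError("burst_size_mean must be >= 3")
        if self.min_burst_gap < 0.100:
            raise ParameterError("min_burst_gap must be >= 0.100 s")
        if self.onset_ramp < 0 or self.rate_cv < 0:
            raise ParameterError("onset_ramp and rate_cv must be >= 0")

    def resolve_effect(self, effect, unit_class: str) -> float:
        if effect is None:
            effect = self.drug_effect
        if isinstance(effect, Mapping):
            return float(effect.get(unit_class, 1.0))
        return float(effect)


@dataclass
class GroundTruth:
    """Generator-side truth for one unit: burst windows, transient times and
    the piecewise rates actually used."""

    true_burst_windows: list[tuple[float, float, int]] = field(default_factory=list)
    true_event_times: list[float] = field(default_factory=list)
    true_rates: list[tuple[float, float, float, float]] = field(default_factory=list)
    unit_class: str = REGULAR_SPIKING
    rate_multiplier: float = 1.0

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for start, end, n in self.true_burst_windows:
            if start < prev_end:
                raise ParameterError("ground-truth burst windows overlap or unsorted")
            if n < 2:
                raise ParameterError("ground-truth burst with < 2 spikes")
            prev_end = end


@dataclass
class KernelParams:
    """Double-exponential calcium transient kernel and acquisition noise.

    Amplitudes are ΔF/F peak contributions; a single isolated spike
    contributes one tenth of a burst by default, consistent with burst
    spikes dominating the somatic calcium signal of a slow indicator.
    """

    rise_tau: float = 0.2
    decay_tau: float = 2.6
    amp_per_burst: float = 0.6
    amp_per_single: float = 0.06
    baseline_f0: float = 100.0
    noise_sd: float = 2.0
    drift_amp: float = 1.0
    drift_period: float = 300.0
    frame_interval: float = DEFAULT_FRAME_INTERVAL

    def __post_init__(self) -> None:
        if not (self.decay_tau > self.rise_tau > 0):
            raise ParameterError("need decay_tau > rise_tau > 0")
        if self.noise_sd < 0 or self.frame_interval <= 0:
            raise ParameterError("noise_sd must be >= 0 and frame_interval > 0")
        if self.baseline_f0 <= 0:
            raise ParameterError("baseline_f0 must be > 0")

    @property
    def peak_time(self) -> float:
        """Time of the kernel maximum after event onset, seconds."""
        r, d = self.rise_tau, self.decay_tau
        return r * d / (d - r) * np.log(d / r)

    def kernel(self, t: np.ndarray) -> np.ndarray:
        """Unit-peak double-exponential evaluated at times ``t`` (s >= 0)."""
        t = np.asarray(t, dtype=float)
        raw = np.where(t >= 0, np.exp(-t / self.decay_tau) - np.exp(-t / self.rise_tau), 0.0)
        tp = self.peak_time
        norm = np.exp(-tp / self.decay_tau) - np.exp(-tp / self.rise_tau)
        return raw / norm


# ---------------------------------------------------------------------------
# spike trains
# ---------------------------------------------------------------------------

def _inhomogeneous_poisson(
    rng: np.random.Generator,
    duration: float,
    rate_pre: float,
    rate_post: float,
    t_switch: float,
    ramp: float,
) -> np.ndarray:
    """Event times of a piecewise-linear-rate Poisson process via thinning."""
    rate_max = max(rate_pre, rate_post)
    if rate_max <= 0:
        return np.empty(0)
    n = rng.poisson(rate_max * duration)
    t = np.sort(rng.uniform(0.0, duration, size=n))
    if ramp > 0:
        frac = np.clip((t - t_switch) / ramp, 0.0, 1.0)
    else:
        frac = (t >= t_switch).astype(float)
    rate_t = rate_pre + (rate_post - rate_pre) * frac
    keep = rng.uniform(0.0, rate_max, size=n) < rate_t
    return t[keep]


def _renewal_segment(
    rng: np.random.Generator,
    t_start: float,
    t_end: float,
    rate: float,
    dead: float,
) -> np.ndarray:
    """Dead-time renewal arrivals on [t_start, t_end) with exact mean rate.

    ISIs are ``dead`` plus an exponential whose scale is chosen so the mean
    ISI equals 1/rate (requires rate·dead < 1).
    """
    span = t_end - t_start
    if rate <= 0 or span <= 0:
        return np.empty(0)
    scale = 1.0 / rate - dead  # exponential part of the mean ISI
    times = np.empty(0)
    t_last = t_start
    while True:
        n = int(span * rate * 1.35) + 30
        gaps = dead + rng.exponential(scale, size=n)
        chunk = t_last + np.cumsum(gaps)
        times = np.concatenate([times, chunk])
        if times[-1] >= t_end:
            break
        t_last = float(times[-1])
        span = t_end - t_last
    return times[times < t_end]


def _single_spikes(
    rng: np.random.Generator,
    duration: float,
    rate_pre: float,
    rate_post: float,
    t_switch: float,
    ramp: float,
    dead: float,
) -> np.ndarray:
    """Single-spike times: Poisson when dead = 0, else dead-time renewal.

    Under a ramp the renewal process is approximated by 1-s constant-rate
    sub-segments (ramp defaults to 0, a step change).
    """
    if dead == 0:
        return _inhomogeneous_poisson(
            rng, duration, rate_pre, rate_post, t_switch, ramp
        )
    segments: list[tuple[float, float, float]] = []
    if ramp > 0:
        segments.append((0.0, t_switch, rate_pre))
        edges = np.arange(t_switch, min(t_switch + ramp, duration), 1.0)
        for e0 in edges:
            e1 = min(e0 + 1.0, t_switch + ramp, duration)
            frac = ((e0 + e1) / 2.0 - t_switch) / ramp
            segments.append((e0, e1, rate_pre + (rate_post - rate_pre) * frac))
        if t_switch + ramp < duration:
            segments.append((t_switch + ramp, duration, rate_post))
    else:
        segments = [(0.0, min(t_switch, duration), rate_pre)]
        if t_switch < duration:
            segments.append((t_switch, duration, rate_post))
    parts = [_renewal_segment(rng, a, b, r, dead) for a, b, r in segments]
    return np.concatenate(parts) if parts else np.empty(0)


def simulate_spike_train(
    profile: SimProfile, unit_seed: int
) -> tuple[SpikeTrain, GroundTruth]:
    """Generate one unit's spike train plus its ground truth.

    Single spikes follow a (piecewise) homogeneous Poisson process; bursts
    are Poisson-placed epochs of >=3 regularly spaced spikes.  Post-injection
    rates are scaled by the profile's drug factors, resolved per the unit's
    true class (baseline expected rate above/below ``fs_cutoff``).
    """
    rng = np.random.default_rng([int(profile.seed), int(unit_seed)])

    # unit-level excitability multiplier (lognormal, mean 1, CV = rate_cv)
    if profile.rate_cv > 0:
        sigma = float(np.sqrt(np.log1p(profile.rate_cv**2)))
        mult = float(rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma))
    else:
        mult = 1.0

    single0 = profile.single_rate * mult
    burst0 = profile.burst_rate * mult
    base_rate = single0 + burst0 * profile.burst_size_mean
    unit_class = FAST_SPIKING if base_rate > profile.fs_cutoff else REGULAR_SPIKING

    f_single = profile.resolve_effect(profile.drug_effect, unit_class)
    f_burst = profile.resolve_effect(profile.drug_burst_effect, unit_class)
    t_inj = profile.injection_time

    singles = _single_spikes(
        rng, profile.duration, single0, single0 * f_single, t_inj,
        profile.onset_ramp, profile.single_refractory,
    )
    burst_starts = _inhomogeneous_poisson(
        rng, profile.duration, burst0, burst0 * f_burst, t_inj, profile.onset_ramp
    )

    windows: list[tuple[float, float, int]] = []
    burst_spikes: list[np.ndarray] = []
    prev_end = -np.inf
    for start in burst_starts:
        n = 3 + int(rng.poisson(profile.burst_size_mean - 3.0))
        end = start + (n - 1) * profile.intra_burst_isi
        # keep gaps strictly above the detector's inter-burst rule and stay
        # inside the recording
        if start - prev_end <= profile.min_burst_gap + 1e-9 or end > profile.duration:
            continue
        windows.append((float(start), float(end), n))
        burst_spikes.append(start + np.arange(n) * profile.intra_burst_isi)
        prev_end = end

    # keep singles clear of burst windows (within the refractory margin) so
    # ground-truth burst spike counts and windows stay exact
    if windows and singles.size and profile.single_refractory > 0:
        ws = np.array([w[0] for w in windows])
        we = np.array([w[1] for w in windows])
        d = profile.single_refractory
        idx = np.searchsorted(ws, singles, side="right") - 1
        near_prev = (idx >= 0) & (singles <= we[np.clip(idx, 0, None)] + d)
        has_next = idx + 1 < len(ws)
        near_next = has_next & (ws[np.clip(idx + 1, 0, len(ws) - 1)] - singles <= d)
        singles = singles[~(near_prev | near_next)]

    times = np.concatenate([singles, *burst_spikes]) if windows else singles
    times = np.unique(times)
    times = times[(times >= 0) & (times <= profile.duration)]

    truth = GroundTruth(
        true_burst_windows=windows,
        true_event_times=[],
        true_rates=[
            (0.0, t_inj, single0, burst0),
            (t_inj, profile.duration, single0 * f_single, burst0 * f_burst),
        ],
        unit_class=unit_class,
        rate_multiplier=mult,
    )
    train = SpikeTrain(
        unit_id=f"u{unit_seed:04d}",
        spike_times=times,
        recording_span=(0.0, profile.duration),
        injection_time=t_inj,
        group_label=profile.label,
    )
    return train, truth


# ---------------------------------------------------------------------------
# fluorescence traces
# ---------------------------------------------------------------------------

def simulate_fluorescence(
    spike_train: SpikeTrain,
    truth: GroundTruth,
    kernel: KernelParams,
    seed: int = 0,
    amp_scale_post: float = 1.0,
) -> tuple[FluorescenceTrace, GroundTruth]:
    """Forward-model a GCaMP6s-like trace from a spike train.

    trace = F0 · (1 + Σ transients) + slow sinusoidal drift + white noise,
    sampled at ``kernel.frame_interval``.  Each ground-truth burst contributes
    a transient of peak ``amp_per_burst`` (ΔF/F), each isolated spike
    ``amp_per_single``.  ``amp_scale_post`` scales amplitudes of transients
    starting after the train's injection time (drug effect on calcium load).

    Returns the trace and the *same* truth object with ``true_event_times``
    filled in: onsets of transients whose noise-free peak exceeds
    3·noise_sd/baseline_f0 in ΔF/F units (the detector's nominal threshold).
    """
    rng = np.random.default_rng(int(seed))
    duration = spike_train.recording_span[1]
    n_frames = int(np.floor(duration / kernel.frame_interval))
    if n_frames < 2:
        raise ParameterError("recording shorter than two frames")
    t = np.arange(n_frames) * kernel.frame_interval

    starts = np.array([w[0] for w in truth.true_burst_windows], dtype=float)
    ends = np.array([w[1] for w in truth.true_burst_windows], dtype=float)

    # isolated spikes = spikes outside every burst window
    spikes = spike_train.spike_times
    if starts.size:
        idx = np.searchsorted(starts, spikes, side="right") - 1
        in_burst = (idx >= 0) & (spikes <= ends[np.clip(idx, 0, None)])
    else:
        in_burst = np.zeros(spikes.shape, dtype=bool)
    single_times = spikes[~in_burst]

    events: list[tuple[float, float]] = [(s, kernel.amp_per_burst) for s in starts]
    events += [(s, kernel.amp_per_single) for s in single_times]
    events.sort()

    t_inj = spike_train.injection_time
    dff_clean = np.zeros(n_frames)
    # kernel support truncated where it has decayed to < 5e-5 of the peak
    support = 10.0 * kernel.decay_tau
    n_support = int(np.ceil(support / kernel.frame_interval)) + 1

    onsets = np.array([e[0] for e in events], dtype=float)
    amps = np.array([e[1] for e in events], dtype=float)
    if amp_scale_post != 1.0 and t_inj is not None:
        amps = np.where(onsets >= t_inj, amps * amp_scale_post, amps)
    live = amps > 0
    if live.any():
        on, am = onsets[live], amps[live]
        i0 = np.searchsorted(t, on)  # first frame at/after onset
        j = np.arange(n_support)
        idx = i0[:, None] + j[None, :]
        ok = idx < n_frames
        rel = np.where(ok, t[np.minimum(idx, n_frames - 1)] - on[:, None], 0.0)
        contrib = am[:, None] * kernel.kernel(rel) * ok
        np.add.at(dff_clean, np.minimum(idx, n_frames - 1), contrib)
    event_records = list(zip(onsets.tolist(), amps.tolist()))

    threshold = 3.0 * kernel.noise_sd / kernel.baseline_f0
    truth.true_event_times = [on for on, amp in event_records if amp > threshold]

    drift_phase = rng.uniform(0.0, 2 * np.pi)
    drift = kernel.drift_amp * np.sin(2 * np.pi * t / kernel.drift_period + drift_phase)
    noise = rng.normal(0.0, kernel.noise_sd, size=n_frames) if kernel.noise_sd > 0 else 0.0

    raw_f = kernel.baseline_f0 * (1.0 + dff_clean) + drift + noise
    trace = FluorescenceTrace(
        roi_id=spike_train.unit_id, frame_times=t, raw_f=raw_f, background=0.0
    )
    return trace, truth


# ---------------------------------------------------------------------------
# movies
# ---------------------------------------------------------------------------

@dataclass
class MovieLayout:
    """Placement of circular somata in a synthetic imaging field."""

    shape: tuple[int, int] = (64, 64)
    centers: Sequence[tuple[float, float]] = ((32.0, 32.0),)
    radii: Sequence[float] = (6.0,)
    background: float = 100.0
    gain: float = 1.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if len(self.centers) != len(self.radii):
            raise LayoutError("centers and radii length mismatch")
        h, w = self.shape
        for (cy, cx), r in zip(self.centers, self.radii):
            if not (r <= cy <= h - 1 - r and r <= cx <= w - 1 - r):
                raise LayoutError(f"soma at ({cy},{cx}) r={r} outside frame")
        cs = list(self.centers)
        rs = list(self.radii)
        for i in range(len(cs)):
            for j in range(i + 1, len(cs)):
                d = float(np.hypot(cs[i][0] - cs[j][0], cs[i][1] - cs[j][1]))
                if d <= rs[i] + rs[j]:
                    raise LayoutError(f"somata {i} and {j} overlap")


def simulate_movie(
    traces: Sequence[np.ndarray] | Sequence[FluorescenceTrace],
    layout: MovieLayout,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render traces into a 16-bit movie stack plus binary ROI masks.

    Each frame is ``background`` plus, per soma, a Gaussian blob (sigma =
    radius/2) scaled by that frame's trace value times ``gain``, plus pixel
    noise.  Returns ``(stack, masks)``: stack shaped (frames, H, W) uint16,
    masks shaped (n_rois, H, W) uint8 with 255 inside each soma disk.
    """
    rng = np.random.default_rng(int(seed))
    values = [
        np.asarray(tr.raw_f if isinstance(tr, FluorescenceTrace) else tr, dtype=float)
        for tr in traces
    ]
    if len(values) != len(layout.centers):
        raise LayoutError("number of traces must match number of somata")
    n_frames = len(values[0])
    if any(len(v) != n_frames for v in values):
        raise LayoutError("traces must share a common length")

    h, w = layout.shape
    yy, xx = np.mgrid[0:h, 0:w]
    blobs = []
    masks = np.zeros((len(values), h, w), dtype=np.uint8)
    for i, ((cy, cx), r) in enumerate(zip(layout.centers, layout.radii)):
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        blobs.append(np.exp(-d2 / (2.0 * (r / 2.0) ** 2)))
        masks[i][d2 <= r * r] = 255

    stack = np.empty((n_frames, h, w), dtype=np.uint16)
    for f in range(n_frames):
        img = np.full((h, w), layout.background, dtype=float)
        for i, blob in enumerate(blobs):
            img += layout.gain * values[i][f] * blob
        if layout.noise_sd > 0:
            img += rng.normal(0.0, layout.noise_sd, size=(h, w))
        stack[f] = np.clip(np.round(img), 0, 65535).astype(np.uint16)
    return stack, masks


# ---------------------------------------------------------------------------
# full-study bundles
# ---------------------------------------------------------------------------

#: per-drug post-injection rate factors.  Saline and the two NMDAR
#: co-agonists are nulls; the NMDAR antagonist suppresses bursting (×0.2),
#: lowers fast-spiking rates (×0.5), raises regular-spiking single-spike
#: rates (×1.265) and scales transient amplitudes ×0.4 after injection.
DRUG_EFFECTS: dict[str, dict] = {
    "saline": {},
    "mk801": {
        "drug_effect": {FAST_SPIKING: 0.5, REGULAR_SPIKING: 1.265},
        "drug_burst_effect": 0.2,
        "drug_amp_effect": 0.4,
    },
    "dcs": {},
    "sarcosine": {},
}


def default_study_profiles(
    n_units: int = 80,
    duration: float = 4200.0,
    injection_time: float = 600.0,
    seed: int = 0,
) -> dict[str, SimProfile]:
    """The 2 group × 4 drug condition grid of the study design.

    Control units average 8 Hz and disease-model units 20 Hz (single spikes
    plus ~0.1 Hz of burst spikes); drug factors per :data:`DRUG_EFFECTS`.
    """
    groups = {"rag": 7.9, "nrg1": 19.9}
    profiles = {}
    for gi, (group, rate) in enumerate(groups.items()):
        for di, (drug, extra) in enumerate(DRUG_EFFECTS.items()):
            label = f"{group}-{drug}"
            profiles[label] = SimProfile(
                label=label,
                single_rate=rate,
                n_units=n_units,
                duration=duration,
                injection_time=injection_time,
                seed=int(seed) * 100 + gi * 10 + di,
                **extra,
            )
    return profiles


def simulate_condition(
    profile: SimProfile,
    kernel: KernelParams | None = None,
    with_traces: bool = True,
) -> dict:
    """Simulate every unit of one condition.

    Returns a dict with ``trains``, ``truths`` and (optionally) ``traces``
    lists, all ordered by unit.
    """
    kernel = kernel or KernelParams()
    trains, truths, traces = [], [], []
    for u in range(profile.n_units):
        train, truth = simulate_spike_train(profile, unit_seed=u)
        if with_traces:
            trace, truth = simulate_fluorescence(
                train,
                truth,
                kernel,
                seed=profile.seed * 100003 + u,
                amp_scale_post=profile.drug_amp_effect,
            )
            traces.append(trace)
        trains.append(train)
        truths.append(truth)
    out = {"profile": profile, "trains": trains, "truths": truths}
    if with_traces:
        out["traces"] = traces
    return out


def simulate_study(config) -> dict:
    """Simulate and write a full study bundle; see :mod:`caspike.pipeline`.

    Thin delegation point kept for API symmetry — the file layout and
    manifest writing live in :func:`caspike.pipeline.run_simulate`.
    """
    from .pipeline import run_simulate

    return run_simulate(config)


__all__ = [
    "DEFAULT_FRAME_INTERVAL",
    "DRUG_EFFECTS",
    "SimProfile",
    "GroundTruth",
    "KernelParams",
    "MovieLayout",
    "simulate_spike_train",
    "simulate_fluorescence",
    "simulate_movie",
    "simulate_condition",
    "simulate_study",
    "default_study_profiles",
]
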