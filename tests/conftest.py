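"""Shared fixtures and hypothesis configuration for the test suite."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from caspike import DFFTrace, KernelParams, SimProfile

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

FRAME = 1.109


@pytest.fixture
def quiet_kernel() -> KernelParams:
    """Noise- and drift-free kernel for exact forward-model checks."""
    return dataclasses.replace(KernelParams(), noise_sd=0.0, drift_amp=0.0)


@pytest.fixture
def calibration_profile() -> SimProfile:
    """Well-separated supra-threshold transients for detector calibration:
    bursts only, min 8 s apart (beyond the kernel support), no drift."""
    return SimProfile(
        label="calibration",
        single_rate=0.0,
        burst_rate=0.08,
        min_burst_gap=8.0,
        duration=600.0,
        injection_time=600.0,
        rate_cv=0.0,
        n_units=1,
    )


@pytest.fixture
def calibration_kernel() -> KernelParams:
    """Transients whose sampled peaks clear 5× the detector's operative
    (robustly estimated) noise SD with margin; nominal noise is 2/100 ΔF/F."""
    return dataclasses.replace(KernelParams(), amp_per_burst=0.30,
                               amp_per_single=0.0, drift_amp=0.0)


def make_dff(values, noise_sd=1.0, noise_mean=0.0, frame=FRAME,
             roi_id="roi") -> DFFTrace:
    """DFFTrace with explicitly pinned noise statistics."""
    values = np.asarray(values, dtype=float)
    t = np.arange(values.size) * frame
    return DFFTrace(roi_id=roi_id, frame_times=t, dff=values, f0=1.0,
                    noise_sd=noise_sd, noise_mean=noise_mean,
                    baseline_window=(0.0, float(t[-1]) if t.size else 0.0))


@pytest.fixture
def dff_factory():
    return make_dff
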