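"""Burst segmentation, unit classification and windowed firing rates.

Bursts follow three rules applied to a sorted spike train: every intra-burst
inter-spike interval is below 15 ms, a burst holds more than 2 spikes, and
consecutive bursts are separated by more than 100 ms.  Candidate runs that
satisfy the first two rules but sit closer than 100 ms are merged into one
burst (rather than discarded), which preserves spikes and keeps the
inter-burst invariant true of the output.

Units are classed as fast-spiking when their baseline rate strictly exceeds
10 spikes/s (presumed inhibitory), regular-spiking otherwise.  Drug responses
are expressed as the relative spike rate SR = after/before × 100 (%) and
classed decrease (SR ≤ 80), increase (SR ≥ 120) or no change (80 < SR < 120);
the boundary values go to decrease/increase respectively.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import (
    FAST_SPIKING,
    REGULAR_SPIKING,
    RESPONSE_CLASSES,
    BurstCriteria,
    BurstSet,
    DrugResponse,
    FormatError,
    ParameterError,
    SpikeTrain,
    UnitRates,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# burst segmentation
# ---------------------------------------------------------------------------

def _segment_times(
    times: np.ndarray, criteria: BurstCriteria
) -> list[tuple[float, float, int]]:
    """Core segmentation on a sorted 1-D array of spike times."""
    n = times.size
    if n == 0:
        return []
    if np.any(np.diff(times) < 0):
        raise FormatError("spike times must be sorted")

    # maximal runs of consecutive ISIs < max_intra_isi
    runs: list[tuple[int, int]] = []
    i = 0
    while i < n - 1:
        if times[i + 1] - times[i] < criteria.max_intra_isi:
            j = i + 1
            while j < n - 1 and times[j + 1] - times[j] < criteria.max_intra_isi:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1

    kept = [(a, b) for a, b in runs if b - a + 1 >= criteria.min_spikes]
    if not kept:
        return []

    # merge kept runs whose gap (end of one to start of next) <= min_inter_burst
    merged: list[list[int]] = [list(kept[0])]
    for a, b in kept[1:]:
        if times[a] - times[merged[-1][1]] <= criteria.min_inter_burst:
            merged[-1][1] = b
        else:
            merged.append([a, b])

    bursts = []
    for a, b in merged:
        start, end = float(times[a]), float(times[b])
        # count every spike inside the burst interval (merging can enclose
        # spikes that belonged to neither run)
        count = int(np.searchsorted(times, end, side="right")
                    - np.searchsorted(times, start, side="left"))
        bursts.append((start, end, count))
    return bursts


def segment_bursts(
    train: SpikeTrain | np.ndarray, criteria: Optional[BurstCriteria] = None
) -> BurstSet:
    """Apply the three burst rules to one unit's spike train."""
    criteria = criteria or BurstCriteria()
    if isinstance(train, SpikeTrain):
        times, unit_id = train.spike_times, train.unit_id
    else:
        times, unit_id = np.asarray(train, dtype=float), "unit"
    return BurstSet(unit_id=unit_id, bursts=_segment_times(times, criteria),
                    criteria=criteria)


class BurstSegmenter(BaseEstimator, TransformerMixin):
    """Burst segmentation as a transformer over a long-format spike table.

    ``transform`` takes a DataFrame with columns ``unit_id`` and ``time_s``
    (times sorted within unit) and returns the burst table with columns
    unit_id, start_s, end_s, n_spikes.
    """

    def __init__(self, max_intra_isi: float = 0.015, min_spikes: int = 3,
                 min_inter_burst: float = 0.100):
        self.max_intra_isi = max_intra_isi
        self.min_spikes = min_spikes
        self.min_inter_burst = min_inter_burst

    @property
    def criteria_(self) -> BurstCriteria:
        return BurstCriteria(self.max_intra_isi, self.min_spikes,
                             self.min_inter_burst)

    def fit(self, X=None, y=None):
        self.criteria_  # validates parameters
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not {"unit_id", "time_s"} <= set(X.columns):
            raise FormatError("spike table needs unit_id and time_s columns")
        rows = []
        for unit_id, grp in X.groupby("unit_id", sort=True):
            times = grp["time_s"].to_numpy(dtype=float)
            for s, e, c in _segment_times(times, self.criteria_):
                rows.append(dict(unit_id=unit_id, start_s=s, end_s=e, n_spikes=c))
        return pd.DataFrame(rows,
                            columns=["unit_id", "start_s", "end_s", "n_spikes"])

    def segment(self, times: np.ndarray, unit_id: str = "unit") -> BurstSet:
        return BurstSet(unit_id=unit_id,
                        bursts=_segment_times(np.asarray(times, float),
                                              self.criteria_),
                        criteria=self.criteria_)


# ---------------------------------------------------------------------------
# unit and response classification
# ---------------------------------------------------------------------------

def classify_unit(baseline_rate: float, cutoff: float = 10.0) -> str:
    """fast_spiking iff baseline rate strictly exceeds the cutoff (10 Hz)."""
    if baseline_rate < 0:
        raise ParameterError("baseline_rate must be >= 0")
    return FAST_SPIKING if baseline_rate > cutoff else REGULAR_SPIKING


class UnitClassifier(BaseEstimator):
    """Fast-spiking vs regular-spiking by baseline rate (> cutoff → FS)."""

    classes_ = np.array([FAST_SPIKING, REGULAR_SPIKING], dtype=object)

    def __init__(self, cutoff: float = 10.0):
        self.cutoff = cutoff

    def fit(self, X=None, y=None):
        return self

    def predict(self, X) -> np.ndarray:
        rates = np.asarray(X, dtype=float).ravel()
        if np.any(rates < 0):
            raise ParameterError("rates must be >= 0")
        return np.where(rates > self.cutoff, FAST_SPIKING, REGULAR_SPIKING)


def relative_change(before_rate: float, after_rate: float) -> float:
    """Relative spike rate SR = after/before × 100 (%).

    A zero baseline is flagged (returns NaN and logs) rather than raised:
    such units are excluded from normalized summaries downstream.
    """
    if before_rate < 0 or after_rate < 0:
        raise ParameterError("rates must be >= 0")
    if before_rate == 0:
        logger.warning("undefined-baseline: before_rate = 0; unit excluded "
                       "from normalized summaries")
        return float("nan")
    return after_rate / before_rate * 100.0


def classify_response(sr_percent: float, lower: float = 80.0,
                      upper: float = 120.0) -> str:
    """decrease iff SR ≤ lower, increase iff SR ≥ upper, else no_change.

    NaN SR (undefined baseline) maps to 'undefined'.
    """
    if np.isnan(sr_percent):
        return "undefined"
    if sr_percent < 0:
        raise ParameterError("SR must be >= 0")
    if sr_percent <= lower:
        return "decrease"
    if sr_percent >= upper:
        return "increase"
    return "no_change"


class ResponseClassifier(BaseEstimator):
    """Drug-response classes from relative spike rates (percent)."""

    classes_ = np.array(RESPONSE_CLASSES, dtype=object)

    def __init__(self, lower: float = 80.0, upper: float = 120.0):
        self.lower = lower
        self.upper = upper

    def fit(self, X=None, y=None):
        if self.lower >= self.upper:
            raise ParameterError("need lower < upper")
        return self

    def predict(self, X) -> np.ndarray:
        sr = np.asarray(X, dtype=float).ravel()
        return np.array(
            [classify_response(v, self.lower, self.upper) for v in sr],
            dtype=object,
        )


def fraction_by_class(responses: Iterable[DrugResponse | str]) -> dict[str, float]:
    """Fraction of units per response class (undefined-baseline units dropped)."""
    labels = [
        r.response_class if isinstance(r, DrugResponse) else str(r)
        for r in responses
    ]
    labels = [l for l in labels if l != "undefined"]
    if not labels:
        raise ParameterError("no classifiable units")
    n = len(labels)
    return {c: labels.count(c) / n for c in RESPONSE_CLASSES}


# ---------------------------------------------------------------------------
# windowed rates
# ---------------------------------------------------------------------------

def compute_rates(
    train: SpikeTrain,
    bursts: BurstSet,
    windows: Sequence[tuple[float, float]],
    unit_class: Optional[str] = None,
) -> list[UnitRates]:
    """Mean, single-spike and burst rates per half-open window [start, end).

    single_rate excludes spikes falling inside any burst interval (closed,
    since burst edges are themselves spikes); burst_rate counts bursts by
    their start time.  mean_rate = single_rate + in-burst spike rate always.
    """
    times = train.spike_times
    bstarts, bends = bursts.starts, bursts.ends
    if bstarts.size:
        idx = np.searchsorted(bstarts, times, side="right") - 1
        in_burst = (idx >= 0) & (times <= bends[np.clip(idx, 0, None)] + 1e-12)
    else:
        in_burst = np.zeros(times.shape, dtype=bool)

    out = []
    for w0, w1 in windows:
        dur = w1 - w0
        if dur <= 0:
            raise ParameterError("zero-length analysis window")
        sel = (times >= w0) & (times < w1)
        n_all = int(sel.sum())
        n_in_burst = int((sel & in_burst).sum())
        n_bursts = int(((bstarts >= w0) & (bstarts < w1)).sum()) if bstarts.size else 0
        out.append(
            UnitRates(
                unit_id=train.unit_id,
                window=(float(w0), float(w1)),
                mean_rate=n_all / dur,
                single_rate=(n_all - n_in_burst) / dur,
                burst_rate=n_bursts / dur,
                in_burst_spike_rate=n_in_burst / dur,
                unit_class=unit_class,
            )
        )
    return out


def rates_frame(rates: Sequence[UnitRates]) -> pd.DataFrame:
    """Tabulate :class:`UnitRates` into the standard rates table."""
    return pd.DataFrame(
        [
            dict(unit_id=r.unit_id, window_start_s=r.window[0],
                 window_end_s=r.window[1], mean_rate=r.mean_rate,
                 single_rate=r.single_rate, burst_rate=r.burst_rate,
                 in_burst_spike_rate=r.in_burst_spike_rate,
                 unit_class=r.unit_class)
            for r in rates
        ],
        columns=["unit_id", "window_start_s", "window_end_s", "mean_rate",
                 "single_rate", "burst_rate", "in_burst_spike_rate",
                 "unit_class"],
    )


__all__ = [
    "segment_bursts",
    "classify_unit",
    "compute_rates",
    "relative_change",
    "classify_response",
    "fraction_by_class",
    "rates_frame",
    "BurstSegmenter",
    "UnitClassifier",
    "ResponseClassifier",
]
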