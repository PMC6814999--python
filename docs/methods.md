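# Methods

This note documents the models and procedures implemented in `caspike`,
the defaults they use, the design choices made where reasonable
alternatives exist, and what the synthetic-data tests do and do not show
about real recordings.

## Imaging arm

### ΔF/F and the baseline F₀

Traces are normalized as ΔF/F = (F − F₀)/F₀, with F the background-
subtracted ROI mean. "Mean of the minimum fluorescence during a baseline
period" is operationalised as the mean of the lowest 10% of baseline-window
F values (`min_fraction`, configurable): a single literal minimum frame is
noise-dominated and makes F₀ an order-statistic with high variance, while a
lowest-decile mean is stable and still anchors F₀ to the quiet portion of
the baseline. When no background region is supplied, the per-frame
10th-percentile pixel value serves as background; ΔF/F is invariant to any
common gain on signal and background and to any common additive offset.

A consequence of taking F₀ from the lowest decile is that baseline ΔF/F is
not centred on zero: for pure Gaussian noise the offset is ≈1.75 noise SDs.
The event threshold is therefore referenced to the robust baseline *level*,
not to zero:

```
threshold = noise_mean + k_sd × noise_sd        (k_sd = 3 by default)
```

With a zero-referenced threshold, ~10% of plain noise frames would exceed
3×SD and the detector would be unusable; referencing the baseline level
preserves the "three standard deviations" rule in the form every practical
implementation uses.

### Noise estimation

`noise_mean` and `noise_sd` are robust statistics of baseline ΔF/F. The
default is the median and the MAD-derived SD (1.4826×MAD), which tolerate a
large fraction of baseline frames being contaminated by transient decay
tails. A one-pass clipped estimator (mean/SD after excluding frames more
than 3 initial SDs above the mean) is available as `noise_method="clip"`;
on sparse-transient traces it retains tail frames and overestimates the SD
by ~20–25%, inflating the threshold and costing detector recall, which is
why it is not the default.

### Event detection and metrics

Events are maximal contiguous runs of ΔF/F above threshold — no gap-based
merging of nearby runs. Amplitude is the run maximum, area the trapezoidal
integral of ΔF/F over the run (a single-frame run contributes amplitude ×
frame interval). Per-window metrics use windows tiling the recording from
the first frame (default 60 s; the partial terminal window is dropped);
events belong to the window containing their onset, and a
boundary-straddling event's area counts wholly in its onset window.
"Total activity" defaults to the sum of event areas per minute; an
alternative whole-trace supra-zero integral is available
(`total_activity_mode="trace"`) since either reading of "integrated area
within 1 min" is defensible. Normalization reports each metric as
100 × post-mean / baseline-mean; a zero baseline flags the ROI rather than
raising.

Two detector properties worth knowing. First, at a 1.109 s frame interval
the sampled peak of a transient is an attenuated version of its continuous
peak (worst-phase retention ≈0.86 for the default kernel), so detectability
statements must be made in the sampled domain. Second, a contiguity-only
detector can emit duplicate "fragment" detections when the slow decay tail
re-crosses the threshold under noise; at the calibration operating point
this affects well under 5% of events and the detection calibration
(recall and precision ≥ 0.95 on ground-truth transients) holds with margin.

## Electrophysiology arm

### Burst segmentation

Three rules define a burst: all intra-burst inter-spike intervals
< 15 ms (strict), more than 2 spikes (i.e. ≥ 3, `min_spikes` configurable),
and inter-burst intervals > 100 ms. The implementation chains maximal runs
of sub-15 ms ISIs, keeps runs of ≥3 spikes, then *merges* kept runs whose
gap is ≤ 100 ms rather than deleting either — merging preserves spikes and
guarantees the output satisfies the inter-burst invariant; spikes enclosed
between merged runs are counted into the burst. The segmentation is tested
for exact agreement against a brute-force oracle that checks every
contiguous subsequence on 10⁴ random spike sets, including sets with gaps
placed exactly on the 15 ms and 100 ms boundaries.

### Rates, classes, responses

Per half-open window [start, end): `mean_rate` counts all spikes;
`single_rate` excludes spikes inside burst intervals; `burst_rate` counts
bursts by start time (bursts/s by default; in-burst spikes/s via
`burst_rate_mode` since the literature uses both). Single + in-burst spike
counts always reproduce the total — a conservation property tested on
every generated train.

Units are fast-spiking iff the baseline rate strictly exceeds 10 spikes/s.
Relative spike rate SR = after/before × 100%; a zero baseline is flagged
(NaN, logged) and the unit is excluded from normalized summaries. Response
classes place the boundaries with decrease at SR ≤ 80 and increase at
SR ≥ 120 (the overlap of "reduced by 20% or more" with "between 80 and
120%" is resolved in favour of the directional classes; both bounds are
configurable). Post-injection analysis uses consecutive 30-min bins
labelled 30/60/90 min; response classification uses the 30–60 min window
by default.

## Statistics

Unpaired t-tests default to the equal-variance Student form (Welch by
flag); identical zero-variance samples return t = 0, p = 1 rather than
NaN. The two-way ANOVA is an OLS fit with type-II sums of squares;
Bonferroni post-tests compare group levels pairwise within each treatment
level, with the correction factor equal to the total number of contrasts.
When every value is identical all effect sums of squares vanish and F is
defined as 0 (p = 1); a nonzero effect over an exactly zero residual is
reported as F = ∞. Gaussianity is assumed throughout (no normality gate);
the experimental unit is the soma/unit, as in the reporting convention the
package follows — animal-level aggregation is possible by pre-averaging
before the tests if pseudo-replication is a concern. Type-I error of both
tests is verified to sit in [3.5%, 6.5%] at nominal 5% over 2000 null
replicates.

Time courses report group mean ± SEM of SR per bin with the baseline bin
pinned at exactly 100% (each unit is normalized to itself); missing bins
are reported absent, never imputed.

## Synthetic data generator

The generator emulates the study conditions end to end and is itself
first-class, tested code.

* **Single spikes** default to a dead-time renewal process: ISI = 15 ms
  refractory + exponential, with the exponential scale chosen so the mean
  ISI is exactly 1/rate. The dead time equals the burst ISI rule by design:
  a homogeneous Poisson train at 8–20 Hz produces chance sub-15 ms triplets
  about as often as the profile's true bursts, and those triplets *are*
  bursts under the operational definition — a generator that labelled them
  "single" would carry self-contradictory ground truth. Pure Poisson is
  available via `single_refractory=0`. The renewal process has Poisson mean
  counts (smaller variance), so rate-recovery expectations are unchanged.
* **Bursts** are Poisson-placed epochs of 3 + Poisson(mean − 3) spikes at
  5 ms spacing, thinned so consecutive bursts are separated by more than
  100 ms (configurable, ≥ the detector's inter-burst rule) and single
  spikes are kept a refractory margin away from burst windows; ground-truth
  windows, counts and rates are recorded exactly.
* **Population structure**: each unit draws a lognormal excitability
  multiplier (CV 0.2 by default) applied to both rates; the unit's true
  class follows from its expected baseline rate. The study's reported
  group SEMs imply a much broader spread (CV ≈ 2.5); the narrower default
  keeps desk-scale parameter recovery sharp and is configurable via
  `rate_cv`. Group defaults: control 7.9 Hz singles + 0.034 bursts/s
  (≈ 8 Hz total, ≈ 2 events/min), disease model 19.9 Hz (≈ 20 Hz, a 250%
  elevation), burst rate equal across groups.
* **Drug effects** are step changes at the injection time (optional linear
  onset ramp), resolved per unit class. The antagonist profile uses
  regular-spiking ×1.265 / fast-spiking ×0.5 on singles, ×0.2 on bursts
  and ×0.4 on post-injection transient amplitudes; saline and the two
  co-agonist conditions are nulls.
* **Fluorescence** is a linear forward model: F₀ · (1 + Σ transients) +
  sinusoidal drift + white noise at 1.109 s/frame. Transients are unit-peak
  double exponentials (rise 0.2 s, decay 2.6 s, matching the slow
  indicator's ~1.8 s half-decay — slow enough that ~0.9 Hz sampling retains
  most of the peak); bursts contribute 0.6 ΔF/F and isolated spikes a tenth
  of that, encoding the burst dominance of somatic calcium signals.
  Ground truth lists each transient whose noise-free peak exceeds the
  nominal 3×SD threshold.
* **Movies** render traces as Gaussian somata over a uniform background
  with pixel noise, plus aligned binary masks, for exercising ROI
  extraction.

What passing tests on this generator do **not** show: robustness to motion
artifacts, neuropil contamination, electrode drift, non-stationary
baselines beyond slow sinusoidal drift, spike-sorting errors, or the heavy-
tailed rate distributions of real cortex. The generator is a correctness
harness for the analysis rules, not a biophysical model.

## Problem sizes and numerical choices

The acceptance computations use 80-unit populations at 600–6000 s per unit,
100 calibration traces, 10⁴ oracle spike sets and 2000 null replicates for
the statistical calibration — sizes at which every stochastic check has a
comfortable analytic margin (e.g. the 2.5× rate-ratio recovery has a
relative SE of ≈3% against a 10% tolerance). Times are seconds throughout;
analysis windows are half-open [start, end); burst intervals are closed
(their endpoints are spikes). Event/burst boundary comparisons use strict
inequalities exactly as the rules state them; float-boundary cases are
covered by dedicated oracle inputs. All randomness flows through
`numpy.random.default_rng` seeded from profile/config seeds, and identical
config + seed reproduces byte-identical output files.

## Known limitations

* Event detection has no duplicate suppression (by design, contiguity
  only); heavily overlapping transients merge and near-threshold decay
  tails can fragment. Both are quantified by the calibration rather than
  hidden.
* The imaging arm does not deconvolve spikes from calcium; comparisons
  between the arms are at the level of summary metrics.
* `two_way_anova` targets the balanced and mildly unbalanced designs the
  reporting convention implies; heavily unbalanced designs would warrant a
  mixed model, which is out of scope.
* The CLI's `report` subcommand re-renders tables and figures; it does not
  recompute statistics from raw inputs.
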