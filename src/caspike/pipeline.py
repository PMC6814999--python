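"""End-to-end pipelines binding the analysis stages together.

Three entry points mirror the study's workflow:

* :func:`run_simulate` — write a synthetic study bundle (spike tables, trace
  tables, optional movies, ground-truth manifest) for the configured
  condition grid.
* :func:`run_ephys` — sorted spike tables → bursts → unit classes → windowed
  rates → relative spike rates → response classes → fractions, time course
  and group statistics.
* :func:`run_imaging` — trace tables (or movie + masks) → ΔF/F → calcium
  events → per-window metrics → baseline-normalized percentages → group
  statistics.

All outputs are plain-text tables with provenance headers; identical inputs,
config and seed give byte-identical outputs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .config import RunConfig
from .datatypes import (
    BurstCriteria,
    ConfigError,
    DataError,
    SpikeTrain,
)
from .imaging import (
    compute_dff,
    detect_events,
    extract_roi_traces,
    metrics_frame,
    normalize_to_baseline,
    summarize_activity,
)
from .simulate import (
    DRUG_EFFECTS,
    KernelParams,
    MovieLayout,
    SimProfile,
    simulate_condition,
    simulate_movie,
)
from .spikes import (
    classify_response,
    classify_unit,
    compute_rates,
    fraction_by_class,
    rates_frame,
    relative_change,
    segment_bursts,
)
from .stats import assemble_report, build_timecourse

logger = logging.getLogger(__name__)


def _prov(config: RunConfig) -> dict:
    cfg = config.to_dict()
    cfg.pop("outdir", None)  # hash covers what is computed, not where it lands
    return dict(seed=config.seed, cfg_hash=cio.config_hash(cfg))


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------

def run_simulate(config: RunConfig) -> dict:
    """Write one condition directory per group × drug cell.

    Each directory holds ``spikes.tsv`` (unit_id, time_s), ``units.tsv``
    (unit_id, group, injection_time_s, unit_class), ``traces.csv``
    (frame_time_s + one ROI column per unit), optionally ``movie.tif`` +
    ``masks.tif``, and ``manifest.json`` with profiles, per-unit seeds and
    the full ground truth.
    """
    outdir = Path(config.outdir)
    prov = _prov(config)
    kernel = KernelParams(frame_interval=config.frame_interval)
    unknown = set(config.drugs) - set(DRUG_EFFECTS)
    if unknown:
        raise ConfigError(f"unknown drug profile label(s): {sorted(unknown)}")

    manifest: dict = {"seed": config.seed, "conditions": {}}
    written: dict[str, Path] = {}
    for gi, (group, rate) in enumerate(sorted(config.groups.items())):
        for di, drug in enumerate(config.drugs):
            label = f"{group}-{drug}"
            profile = SimProfile(
                label=label,
                single_rate=float(rate),
                n_units=config.n_units,
                duration=config.duration,
                injection_time=config.injection_time,
                seed=config.seed * 100 + gi * 10 + di,
                **DRUG_EFFECTS[drug],
            )
            sim = simulate_condition(profile, kernel, with_traces=True)
            cdir = outdir / label
            logger.info("condition %s: %d units, %d spikes total", label,
                        profile.n_units,
                        sum(t.n_spikes for t in sim["trains"]))

            spikes = pd.concat(
                [pd.DataFrame({"unit_id": tr.unit_id, "time_s": tr.spike_times})
                 for tr in sim["trains"]],
                ignore_index=True,
            ) if sim["trains"] else pd.DataFrame(columns=["unit_id", "time_s"])
            cio.write_spike_table(spikes, cdir / "spikes.tsv", **prov)

            units = pd.DataFrame(
                [dict(unit_id=tr.unit_id, group=label,
                      injection_time_s=profile.injection_time,
                      t_start_s=tr.recording_span[0],
                      t_end_s=tr.recording_span[1],
                      unit_class=gt.unit_class)
                 for tr, gt in zip(sim["trains"], sim["truths"])]
            )
            cio.write_table(units, cdir / "units.tsv", sep="\t", **prov)

            frame_times = sim["traces"][0].frame_times
            cio.write_trace_table(
                frame_times,
                {tr.roi_id: np.round(tr.raw_f, 6) for tr in sim["traces"]},
                cdir / "traces.csv", **prov,
            )

            if config.movies:
                k = min(config.movie_units, len(sim["traces"]))
                layout = MovieLayout(
                    shape=(64, 64),
                    centers=[(16.0 + 28.0 * (i // 2), 16.0 + 28.0 * (i % 2))
                             for i in range(k)],
                    radii=[6.0] * k,
                )
                stack, masks = simulate_movie(
                    sim["traces"][:k], layout, seed=profile.seed + 7
                )
                cio.write_tiff(stack, cdir / "movie.tif")
                cio.write_tiff(masks, cdir / "masks.tif")

            manifest["conditions"][label] = {
                "profile": {k: v for k, v in vars(profile).items()},
                "units": [
                    dict(unit_id=tr.unit_id, unit_class=gt.unit_class,
                         rate_multiplier=gt.rate_multiplier,
                         true_rates=gt.true_rates,
                         true_burst_windows=gt.true_burst_windows,
                         true_event_times=gt.true_event_times)
                    for tr, gt in zip(sim["trains"], sim["truths"])
                ],
            }
            written[label] = cdir
    cio.write_manifest(manifest, outdir / "manifest.json")
    return {"outdir": outdir, "conditions": written, "manifest": manifest}


# ---------------------------------------------------------------------------
# electrophysiology
# ---------------------------------------------------------------------------

def _post_windows(inj: float, config: RunConfig, span_end: float
                  ) -> list[tuple[str, float, float]]:
    """Consecutive post-injection bins labelled by their right edge (min)."""
    out = []
    prev = 0.0
    for m in config.post_bins_min:
        w0, w1 = inj + prev * 60.0, inj + m * 60.0
        if w1 <= span_end + 1e-6:
            out.append((f"{m}min", w0, w1))
        prev = float(m)
    return out


def run_ephys(config: RunConfig) -> dict:
    """Sorted spikes + metadata → bursts, rates, responses, fractions,
    time course and stats digest."""
    config.require_inputs()
    outdir = Path(config.outdir)
    prov = _prov(config)
    criteria = BurstCriteria(config.max_intra_isi, config.min_spikes,
                             config.min_inter_burst)

    spikes = cio.read_spike_table(config.spikes)
    meta = cio.read_table(config.metadata, sep="\t")
    if not {"unit_id", "group", "injection_time_s"} <= set(meta.columns):
        raise DataError("metadata needs unit_id, group, injection_time_s")

    if len(meta) == 0:
        logger.warning("empty unit list; writing empty tables")
        for name in ("bursts", "rates", "responses", "fractions",
                     "timecourse", "digest"):
            cio.write_table(pd.DataFrame(), outdir / f"{name}.csv", **prov)
        return {"outdir": outdir, "n_units": 0}

    burst_rows, rate_rows, resp_rows, tc_rows = [], [], [], []
    groups: dict[str, str] = {}
    for row in meta.itertuples(index=False):
        unit_id = str(row.unit_id)
        inj = float(row.injection_time_s)
        times = np.sort(
            spikes.loc[spikes["unit_id"].astype(str) == unit_id, "time_s"]
            .to_numpy(dtype=float)
        )
        t_end = getattr(row, "t_end_s", np.nan)
        span_end = float(t_end) if np.isfinite(t_end) else float(
            max(times[-1] if times.size else inj, inj) + 1e-6
        )
        span = (0.0, span_end)
        if not (span[0] <= inj <= span[1]):
            raise DataError(f"unit {unit_id}: injection time outside recording")
        train = SpikeTrain(unit_id=unit_id, spike_times=times,
                           recording_span=span, injection_time=inj,
                           group_label=str(row.group))
        groups[unit_id] = str(row.group)

        bursts = segment_bursts(train, criteria)
        for s, e, c in bursts.bursts:
            burst_rows.append(dict(unit_id=unit_id, start_s=s, end_s=e,
                                   n_spikes=c))

        base_w = (max(0.0, inj - config.baseline_duration), inj)
        windows = [("baseline", *base_w)] + _post_windows(inj, config, span_end)
        base = compute_rates(train, bursts, [base_w])[0]
        uclass = classify_unit(base.mean_rate, config.fs_cutoff)
        for label, w0, w1 in windows:
            r = compute_rates(train, bursts, [(w0, w1)], unit_class=uclass)[0]
            rate_rows.append(dict(unit_id=unit_id, group=str(row.group),
                                  time_bin=label,
                                  **rates_frame([r]).iloc[0].drop("unit_id")
                                  .to_dict()))
            if label != "baseline":
                sr_single = relative_change(base.single_rate, r.single_rate) \
                    if base.single_rate > 0 else float("nan")
                sr_mean = relative_change(base.mean_rate, r.mean_rate) \
                    if base.mean_rate > 0 else float("nan")
                tc_rows.append(dict(unit_id=unit_id, group=str(row.group),
                                    time_bin=label, sr_percent=sr_single,
                                    sr_mean_percent=sr_mean))

        # response classification over the configured post window
        rw0 = inj + config.response_window_min[0] * 60.0
        rw1 = inj + config.response_window_min[1] * 60.0
        if rw1 <= span_end + 1e-6:
            post = compute_rates(train, bursts, [(rw0, rw1)],
                                 unit_class=uclass)[0]
            for metric, before, after in (
                ("mean_rate", base.mean_rate, post.mean_rate),
                ("burst_rate",
                 base.burst_rate if config.burst_rate_mode == "bursts_per_s"
                 else base.in_burst_spike_rate,
                 post.burst_rate if config.burst_rate_mode == "bursts_per_s"
                 else post.in_burst_spike_rate),
            ):
                sr = relative_change(before, after) if before > 0 else float("nan")
                resp_rows.append(dict(
                    unit_id=unit_id, group=str(row.group), metric=metric,
                    unit_class=uclass, sr_percent=sr,
                    response_class=classify_response(sr, config.sr_lower,
                                                     config.sr_upper),
                ))

    bursts_df = pd.DataFrame(burst_rows,
                             columns=["unit_id", "start_s", "end_s", "n_spikes"])
    rates_df = pd.DataFrame(rate_rows)
    resp_df = pd.DataFrame(resp_rows, columns=["unit_id", "group", "metric",
                                               "unit_class", "sr_percent",
                                               "response_class"])
    tc_in = pd.DataFrame(tc_rows, columns=["unit_id", "group", "time_bin",
                                           "sr_percent", "sr_mean_percent"])
    logger.info("ephys: %d units, %d bursts, %d response rows",
                len(meta), len(bursts_df), len(resp_df))

    frac_rows = []
    for (group, metric), grp in resp_df.groupby(["group", "metric"]):
        try:
            fracs = fraction_by_class(grp["response_class"])
        except Exception:
            continue
        for cls, frac in fracs.items():
            frac_rows.append(dict(group=group, metric=metric,
                                  response_class=cls, fraction=frac,
                                  n_units=int(len(grp))))
    frac_df = pd.DataFrame(frac_rows, columns=["group", "metric",
                                               "response_class", "fraction",
                                               "n_units"])

    bins = ["baseline"] + [f"{m}min" for m in config.post_bins_min]
    tc_df = build_timecourse(tc_in, bin_order=bins) if len(tc_in) else \
        pd.DataFrame(columns=["group", "time_bin", "mean_pct", "sem_pct",
                              "n", "absent"])

    # group-comparison digest on per-unit SRs per bin plus baseline rates
    tables = {}
    base_rates = rates_df[rates_df["time_bin"] == "baseline"]
    tables["baseline_mean_rate"] = base_rates.rename(
        columns={"mean_rate": "value"})[["group", "value"]]
    tables["baseline_burst_rate"] = base_rates.rename(
        columns={"burst_rate": "value"})[["group", "value"]]
    for b in bins[1:]:
        sub = tc_in[tc_in["time_bin"] == b].rename(
            columns={"sr_percent": "value"})[["group", "value"]]
        tables[f"single_rate_sr_{b}"] = sub
    report = assemble_report(tables)

    cio.write_table(bursts_df, outdir / "bursts.csv", **prov)
    cio.write_table(rates_df, outdir / "rates.csv", **prov)
    cio.write_table(resp_df, outdir / "responses.csv", **prov)
    cio.write_table(frac_df, outdir / "fractions.csv", **prov)
    cio.write_table(tc_df, outdir / "timecourse.csv", **prov)
    cio.write_table(report["digest"], outdir / "digest.csv", **prov)
    cio.write_manifest(
        {"digest": report["digest"].to_dict(orient="records")},
        outdir / "digest.json",
    )
    return {"outdir": outdir, "n_units": len(meta), "bursts": bursts_df,
            "rates": rates_df, "responses": resp_df, "fractions": frac_df,
            "timecourse": tc_df, "digest": report["digest"]}


# ---------------------------------------------------------------------------
# imaging
# ---------------------------------------------------------------------------

def run_imaging(config: RunConfig) -> dict:
    """Traces (or movie + masks) → ΔF/F → events → metrics → normalized
    percentages → stats digest."""
    config.require_inputs()
    outdir = Path(config.outdir)
    prov = _prov(config)

    if config.traces is not None:
        X = cio.read_trace_table(config.traces)
        t = X.index.to_numpy(dtype=float)
        from .datatypes import FluorescenceTrace

        traces = [
            FluorescenceTrace(roi_id=str(c), frame_times=t,
                              raw_f=X[c].to_numpy(dtype=float))
            for c in X.columns
        ]
    else:
        stack = cio.read_tiff(config.movie)
        masks = cio.read_tiff(config.masks)
        traces = extract_roi_traces(stack, masks,
                                    frame_interval=config.frame_interval)
        t = traces[0].frame_times

    include = {tr.roi_id: True for tr in traces}
    if config.roi_flags:
        flags = cio.read_table(config.roi_flags)
        for row in flags.itertuples(index=False):
            include[str(row.roi_id)] = bool(row.include)

    base_w = config.baseline_window or (float(t[0]),
                                        float(t[0]) + config.baseline_duration)
    if base_w[1] > t[-1] + config.frame_interval:
        raise ConfigError("missing baseline segment: baseline_window extends "
                          "beyond the recording")

    groups: dict[str, str] = {}
    if config.metadata and Path(config.metadata).exists():
        meta = cio.read_table(config.metadata, sep="\t")
        id_col = "unit_id" if "unit_id" in meta.columns else "roi_id"
        groups = {str(r[0]): str(r[1])
                  for r in meta[[id_col, "group"]].itertuples(index=False)}

    event_rows, metric_rows, norm_rows = [], [], []
    for tr in traces:
        tr.include_flag = include.get(tr.roi_id, True)
        dff = compute_dff(tr, baseline_window=base_w,
                          min_fraction=config.min_fraction)
        events = detect_events(dff, k_sd=config.k_sd)
        for ev in events:
            event_rows.append(dict(roi_id=tr.roi_id, onset_s=ev.onset_time,
                                   peak_s=ev.peak_time, offset_s=ev.offset_time,
                                   amplitude=ev.amplitude, area=ev.area))
        metrics = summarize_activity(events, dff, window_s=config.window_s,
                                     total_activity_mode=config.total_activity_mode)
        metric_rows.extend(metrics_frame(metrics).to_dict(orient="records"))
        base_m = [m for m in metrics if m.window[1] <= base_w[1] + 1e-6]
        post_m = [m for m in metrics if m.window[0] >= base_w[1] - 1e-6]
        norm = normalize_to_baseline(post_m, base_m)
        norm_rows.append(dict(roi_id=tr.roi_id,
                              group=groups.get(tr.roi_id, "all"),
                              include=tr.include_flag,
                              amplitude_pct=norm["amplitude_pct"],
                              frequency_pct=norm["frequency_pct"],
                              total_activity_pct=norm["total_activity_pct"],
                              flags=";".join(norm["flags"])))

    events_df = pd.DataFrame(event_rows, columns=["roi_id", "onset_s", "peak_s",
                                                  "offset_s", "amplitude",
                                                  "area"])
    metrics_df = pd.DataFrame(metric_rows)
    norm_df = pd.DataFrame(norm_rows)
    logger.info("imaging: %d ROIs, %d events", len(traces), len(events_df))

    incl = norm_df[norm_df["include"]]
    tables = {
        metric: incl.rename(columns={f"{metric}_pct": "value"})[["group", "value"]]
        for metric in ("amplitude", "frequency", "total_activity")
    }
    report = assemble_report(tables)

    cio.write_table(events_df, outdir / "events.csv", **prov)
    cio.write_table(metrics_df, outdir / "metrics.csv", **prov)
    cio.write_table(norm_df, outdir / "normalized.csv", **prov)
    cio.write_table(report["digest"], outdir / "digest.csv", **prov)
    cio.write_manifest({"digest": report["digest"].to_dict(orient="records")},
                       outdir / "digest.json")
    return {"outdir": outdir, "events": events_df, "metrics": metrics_df,
            "normalized": norm_df, "digest": report["digest"]}


__all__ = ["run_simulate", "run_ephys", "run_imaging"]
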