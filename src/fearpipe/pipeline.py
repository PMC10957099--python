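"""End-to-end orchestration: simulate -> preprocess -> extract/score ->
classify -> stats, driven by a single JSON config with one global seed.

The config is strict — unknown keys anywhere are errors (catching typos in
threshold names) — and every stochastic stage derives its seed from the
global one, so re-running an identical config reproduces byte-identical
CSV/JSON outputs.  ``run_pipeline`` returns a manifest listing every
artifact written, with the parameters and seeds that produced it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .behavior import FreezeParams, TrajectorySeries, detect_freezing, score_freezing
from .miniscope import (ClassifyParams, ExtractionParams, Movie,
                        RoiFilterParams, baseline_activity, classify_cs_cells,
                        cs_trial_activity, extract_components,
                        filter_components, motion_correct)
from .photometry import (DualChannelRecording, PhotometryParams, TimeSeries,
                         align_trials, preprocess, qc_and_correct_reference,
                         trial_responses)
from .protocol import EventTimeline, ProtocolParams, build_timeline
from .stats import bootstrap_diff, dunnett, rank_sum
from .synth import (GroupDesign, MiniscopeSimParams, PhotometrySimParams,
                    TrackingSimParams, simulate_cohort, simulate_miniscope,
                    simulate_photometry, simulate_tracking)

log = logging.getLogger("fearpipe")

_VERSION = "0.1.0"

_FLOAT_FMT = "%.10g"

STAGES = ("simulate", "photometry", "miniscope", "behavior", "stats")

_TOP_KEYS = {"seed", "out_dir", "session", "stages", "inputs", "protocol",
             "photometry_sim", "miniscope_sim", "tracking_sim", "cohort",
             "photometry", "motion_correction", "extraction", "roi_filter",
             "classify", "freezing", "stats", "log_level"}


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# writers / readers (plain-text formats)
# --------------------------------------------------------------------------

def write_photometry_csv(rec: DualChannelRecording, path) -> None:
    df = pd.DataFrame({"t": rec.signal.t, "f465": rec.signal.values,
                       "f405": rec.reference.values})
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_photometry_csv(path) -> DualChannelRecording:
    df = pd.read_csv(path)
    rate = 1.0 / (df["t"].iloc[1] - df["t"].iloc[0])
    rate = float(np.round(rate, 6))
    return DualChannelRecording(
        TimeSeries(float(df["t"].iloc[0]), rate, df["f465"].to_numpy()),
        TimeSeries(float(df["t"].iloc[0]), rate, df["f405"].to_numpy()))


def write_tracking_csv(traj: TrajectorySeries, path) -> None:
    pd.DataFrame({"t": traj.t, "x": traj.x, "y": traj.y}).to_csv(
        path, index=False, float_format=_FLOAT_FMT)


def read_tracking_csv(path) -> TrajectorySeries:
    df = pd.read_csv(path)
    return TrajectorySeries(df["t"].to_numpy(), df["x"].to_numpy(), df["y"].to_numpy())


def write_movie_tiff(movie: Movie, path) -> None:
    tifffile.imwrite(path, movie.frames.astype(np.float32))
    sidecar = Path(path).with_suffix(".json")
    sidecar.write_text(json.dumps({"frame_rate_hz": movie.frame_rate}, indent=2))


def read_movie_tiff(path) -> Movie:
    frames = tifffile.imread(path)
    sidecar = Path(path).with_suffix(".json")
    rate = 20.0
    if sidecar.exists():
        rate = float(json.loads(sidecar.read_text())["frame_rate_hz"])
    return Movie(np.asarray(frames, dtype=np.float32), rate)


# --------------------------------------------------------------------------
# config handling
# --------------------------------------------------------------------------

def _build(cls, section: dict, stage: str):
    try:
        return cls(**section)
    except TypeError as exc:
        raise ConfigError(f"[{stage}] invalid key in {cls.__name__}: {exc}") from None


def validate_config(config: dict) -> dict:
    unknown = set(config) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    stages = config.get("stages", list(STAGES))
    bad = [s for s in stages if s not in STAGES]
    if bad:
        raise ConfigError(f"unknown stages: {bad}")
    if "out_dir" not in config:
        raise ConfigError("config requires 'out_dir'")
    return config


def demo_config(out_dir, seed: int = 0) -> dict:
    """A complete, fast demonstration run over simulated data.

    Uses a compressed protocol (short baseline and inter-trial intervals)
    and a small field of view so the whole pipeline runs in well under a
    minute while exercising every stage.
    """
    return {
        "seed": seed,
        "out_dir": str(out_dir),
        "session": "fc_day1",
        "stages": list(STAGES),
        "protocol": {"baseline_s": 20.0, "iti_range_s": [8.0, 12.0],
                     "post_last_cs_s": 8.0},
        "photometry_sim": {"sample_rate_hz": 50.0, "oversample": 2,
                           "cs_amp_schedule": [0.5, 1.0, 1.5, 2.0, 2.5],
                           "us_amp": 3.0},
        "photometry": {"target_rate_hz": 50.0, "lowcut_cutoff_s": 180.0,
                       "baseline_window_s": [-5.0, 0.0]},
        "miniscope_sim": {"fov": [100, 100], "frame_rate_hz": 5.0,
                          "n_cells": 6, "footprint_radius_px": 6.0,
                          "shift_walk_sd_px": 0.02,
                          "class_fractions": [0.5, 0.2, 0.2, 0.1]},
        "motion_correction": {"template_frames": 50, "max_iter": 5},
        "extraction": {"patch_radius_px": 8, "min_distance_px": 6},
        "roi_filter": {},
        "classify": {},
        "tracking_sim": {"freeze_bout_schedule": [[25.0, 31.0], [50.0, 53.0]],
                         "sample_rate_hz": 20.0},
        "freezing": {},
        "cohort": [
            {"name": "ctrl", "n": 13, "epoch_means": {"cs": 70.0},
             "epoch_sds": {"cs": 15.0}},
            {"name": "mono", "n": 10, "epoch_means": {"cs": 65.0},
             "epoch_sds": {"cs": 15.0}},
            {"name": "di", "n": 7, "epoch_means": {"cs": 30.0},
             "epoch_sds": {"cs": 15.0}},
        ],
        "stats": {"epoch": "cs", "control_group": "ctrl", "n_boot": 2000},
    }


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------

def _seed_for(seed: int, stage: str) -> int:
    tag = zlib.crc32(stage.encode()) % (2**31)
    return int(np.random.SeedSequence([seed, tag]).generate_state(1)[0] % (2**31))


def run_pipeline(config: dict | str | Path) -> dict:
    """Execute the configured stages and return the run manifest."""
    if not isinstance(config, dict):
        config = json.loads(Path(config).read_text())
    config = validate_config(config)
    seed = int(config.get("seed", 0))
    out = Path(config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", list(STAGES))
    session = config.get("session", "fc_day1")
    inputs = config.get("inputs", {})
    logging.basicConfig(level=config.get("log_level", "INFO"))

    manifest = {"package_version": _VERSION, "seed": seed,
                "session": session, "artifacts": [], "params": {}}

    def record(stage, path, **meta):
        manifest["artifacts"].append({"stage": stage, "path": str(path), **meta})

    proto = _build(ProtocolParams, {**config.get("protocol", {}),
                                    "rng_seed": seed}, "protocol")
    # JSON configs carry lists; the dataclass wants tuples
    proto.iti_range_s = tuple(proto.iti_range_s)
    timeline = build_timeline(session, proto)
    tl_path = out / "timeline.json"
    timeline.to_json(tl_path)
    record("protocol", tl_path, n_cs=len(timeline.by_label("cs")))
    manifest["params"]["protocol"] = dataclasses.asdict(proto)

    rec = movie = traj = cohort_df = None

    if "simulate" in stages:
        log.info("simulate: photometry, miniscope, tracking, cohort")
        psim = _build(PhotometrySimParams,
                      {**config.get("photometry_sim", {}),
                       "rng_seed": _seed_for(seed, "photometry")}, "simulate")
        if psim.cs_amp_schedule is not None:
            psim.cs_amp_schedule = tuple(psim.cs_amp_schedule)
        rec, _ = simulate_photometry(timeline, psim)
        write_photometry_csv(rec, out / "photometry_raw.csv")
        record("simulate", out / "photometry_raw.csv")

        msim = _build(MiniscopeSimParams,
                      {**config.get("miniscope_sim", {}),
                       "rng_seed": _seed_for(seed, "miniscope")}, "simulate")
        msim.fov = tuple(msim.fov)
        msim.class_fractions = tuple(msim.class_fractions)
        movie, mtruth = simulate_miniscope(timeline, msim)
        write_movie_tiff(movie, out / "miniscope.tif")
        record("simulate", out / "miniscope.tif", n_frames=movie.n_frames)

        tsim = _build(TrackingSimParams,
                      {**config.get("tracking_sim", {}),
                       "rng_seed": _seed_for(seed, "tracking")}, "simulate")
        tsim.freeze_bout_schedule = tuple(tuple(b) for b in tsim.freeze_bout_schedule)
        traj, _ = simulate_tracking(timeline, tsim)
        write_tracking_csv(traj, out / "tracking.csv")
        record("simulate", out / "tracking.csv")

        designs = [GroupDesign(**g) for g in config.get("cohort", [])]
        if designs:
            cohort_df = simulate_cohort(designs, rng_seed=_seed_for(seed, "cohort"))
            cohort_df.to_csv(out / "cohort_freezing.csv", index=False,
                             float_format=_FLOAT_FMT)
            record("simulate", out / "cohort_freezing.csv", n_animals=sum(g.n for g in designs))

    if "photometry" in stages:
        if rec is None:
            path = inputs.get("photometry_csv")
            if not path or not Path(path).exists():
                raise StageError(f"[photometry] missing input file: {path!r}")
            rec = read_photometry_csv(path)
        log.info("photometry: %d samples at %g Hz", rec.signal.n, rec.signal.rate)
        pparams = _build(PhotometryParams, config.get("photometry", {}), "photometry")
        pparams.response_window_s = tuple(pparams.response_window_s)
        pparams.baseline_window_s = tuple(pparams.baseline_window_s)
        sig = preprocess(rec.signal, pparams)
        ref = preprocess(rec.reference, pparams)
        corrected, qc = qc_and_correct_reference(
            DualChannelRecording(sig, ref), pparams, timeline)
        pd.DataFrame({"t": corrected.t, "z": corrected.values}).to_csv(
            out / "photometry_processed.csv", index=False, float_format=_FLOAT_FMT)
        record("photometry", out / "photometry_processed.csv",
               discard_recommended=qc.discard_recommended)
        pre = -pparams.baseline_window_s[0]
        post = pparams.response_window_s[1] + 5.0
        tm = align_trials(corrected, timeline, "cs", pre, post)
        pd.DataFrame(tm.data).to_csv(out / "cs_trials.csv", index=False,
                                     float_format=_FLOAT_FMT)
        responses = trial_responses(tm, pparams, delta=True)
        responses.to_csv(out / "cs_responses.csv", index=False,
                         float_format=_FLOAT_FMT)
        record("photometry", out / "cs_responses.csv", n_trials=len(responses))

    if "miniscope" in stages:
        if movie is None:
            path = inputs.get("movie_tiff")
            if not path or not Path(path).exists():
                raise StageError(f"[miniscope] missing input file: {path!r}")
            movie = read_movie_tiff(path)
        rows, cols = movie.fov
        mc_cfg = dict(config.get("motion_correction", {}))
        roi1 = tuple(mc_cfg.pop("roi1", (rows // 4, 3 * rows // 4,
                                         cols // 4, 3 * cols // 4)))
        roi2 = tuple(mc_cfg.pop("roi2", (0, rows // 2, 0, cols // 2)))
        log.info("miniscope: motion correction on %d frames", movie.n_frames)
        corrected, shift_trace, mc_report = motion_correct(
            movie, roi1, roi2, **mc_cfg)
        pd.DataFrame({"frame": np.arange(movie.n_frames),
                      "d_row": shift_trace.shifts[:, 0],
                      "d_col": shift_trace.shifts[:, 1]}).to_csv(
            out / "shifts.csv", index=False, float_format=_FLOAT_FMT)
        record("miniscope", out / "shifts.csv", **mc_report)

        eparams = _build(ExtractionParams, config.get("extraction", {}), "miniscope")
        comps = extract_components(corrected, eparams)
        fparams = _build(RoiFilterParams, config.get("roi_filter", {}), "miniscope")
        kept, rejected = filter_components(comps, movie.fov, fparams)
        cparams = _build(ClassifyParams, config.get("classify", {}), "miniscope")
        cparams.fc_early_trials = tuple(cparams.fc_early_trials)
        cparams.fc_late_trials = tuple(cparams.fc_late_trials)
        cparams.retrieval_trials = tuple(cparams.retrieval_trials)

        qc_rows = []
        for i, c in enumerate(kept):
            activity = cs_trial_activity(c.trace, timeline)
            bl = (baseline_activity(c.trace, timeline)
                  if session == "retrieval_day2" else None)
            label, flags = classify_cs_cells(activity, session, cparams,
                                             baseline_samples=bl)
            qc_rows.append({"id": i, "area_frac": c.area_frac, "snr": c.snr,
                            "eccentricity": c.eccentricity, "decision": "kept",
                            "reason": "", "cs_class": label})
        for j, (c, reason) in enumerate(rejected):
            qc_rows.append({"id": len(kept) + j, "area_frac": c.area_frac,
                            "snr": c.snr, "eccentricity": c.eccentricity,
                            "decision": "rejected", "reason": reason,
                            "cs_class": ""})
        pd.DataFrame(qc_rows).to_csv(out / "components_qc.csv", index=False,
                                     float_format=_FLOAT_FMT)
        record("miniscope", out / "components_qc.csv",
               n_kept=len(kept), n_rejected=len(rejected))
        if kept:
            traces = np.stack([c.trace.values for c in kept])
            pd.DataFrame(traces.T).to_csv(out / "component_traces.csv",
                                          index=False, float_format=_FLOAT_FMT)
            record("miniscope", out / "component_traces.csv")

    if "behavior" in stages:
        if traj is None:
            path = inputs.get("tracking_csv")
            if not path or not Path(path).exists():
                raise StageError(f"[behavior] missing input file: {path!r}")
            traj = read_tracking_csv(path)
        fz = _build(FreezeParams, config.get("freezing", {}), "behavior")
        bouts = detect_freezing(traj, fz)
        pd.DataFrame(bouts.bouts, columns=["start", "end"]).to_csv(
            out / "freezing_bouts.csv", index=False, float_format=_FLOAT_FMT)
        scores = score_freezing(bouts, timeline, animal_id="demo")
        scores.to_csv(out / "freezing_scores.csv", index=False,
                      float_format=_FLOAT_FMT)
        record("behavior", out / "freezing_scores.csv", n_bouts=len(bouts))

    if "stats" in stages:
        if cohort_df is None:
            path = inputs.get("cohort_csv")
            if not path or not Path(path).exists():
                raise StageError(f"[stats] missing input file: {path!r}")
            cohort_df = pd.read_csv(path)
        scfg = dict(config.get("stats", {}))
        epoch = scfg.get("epoch")
        ctrl_name = scfg.get("control_group")
        n_boot = int(scfg.get("n_boot", 10_000))
        sub = cohort_df[cohort_df["epoch"] == epoch]
        groups = {g: d["value"].to_numpy() for g, d in sub.groupby("group")}
        if ctrl_name not in groups:
            raise StageError(f"[stats] control group {ctrl_name!r} not in table")
        ctrl = groups.pop(ctrl_name)
        rows = []
        names = sorted(groups)
        for name in names:
            rs = rank_sum(groups[name], ctrl)
            bs = bootstrap_diff(groups[name], ctrl, n_boot=n_boot,
                                seed=_seed_for(seed, f"boot_{name}"))
            rows.append({"comparison": f"{name}_vs_{ctrl_name}", "method": rs.method,
                         "statistic": rs.statistic, "p": rs.p_two_sided,
                         "p_adjusted": np.nan, "n": f"{rs.n}",
                         "bootstrap_p": bs.p_two_sided,
                         "bootstrap_ci_lo": bs.ci_95[0],
                         "bootstrap_ci_hi": bs.ci_95[1]})
        if len(names) >= 2:
            dn = dunnett([ctrl] + [groups[n] for n in names], control_index=0,
                         seed=_seed_for(seed, "dunnett"))
            for name, r in zip(names, dn):
                rows.append({"comparison": f"{name}_vs_{ctrl_name}",
                             "method": r.method, "statistic": r.statistic,
                             "p": r.extra["p_unadjusted"],
                             "p_adjusted": r.p_two_sided, "n": f"{r.n}",
                             "bootstrap_p": np.nan, "bootstrap_ci_lo": np.nan,
                             "bootstrap_ci_hi": np.nan})
        pd.DataFrame(rows).to_csv(out / "stats_results.csv", index=False,
                                  float_format=_FLOAT_FMT)
        record("stats", out / "stats_results.csv", n_comparisons=len(rows))

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
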