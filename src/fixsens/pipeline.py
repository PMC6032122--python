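"""End-to-end orchestration: synth -> preprocess -> detect -> fit ->
resample -> drift -> gain model, with TSV outputs and a run manifest.

Every stage consumes and produces the package's delimited-text formats,
and all randomness derives from one seed, so a rerun with the same
config and seed reproduces byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time as _time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .drift import drift_timecourse
from .gainmodel import GainModelParams, sweep_delay
from .msdetect import detect_microsaccades, direction_histogram, main_sequence
from .preprocess import attach_latency, blink_intervals, exclude_blink_trials
from .psychofit import (FACILITATION_WINDOW, SUPPRESSION_WINDOW, global_fit,
                        orientation_partition, sensitivity_timecourse,
                        window_csf)
from .synth import SynthConfig, simulate_study
from .trace import events_to_frame, write_trials

__all__ = ["run_all", "config_hash"]


def config_hash(cfg: SynthConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _log(manifest, stage, t0, **counts):
    entry = dict(stage=stage, wall_s=round(_time.perf_counter() - t0, 3), **counts)
    manifest["stages"].append(entry)
    return _time.perf_counter()


def run_all(cfg: SynthConfig, seed: int, out_dir, n_subjects: int = 3,
            timecourse_step: float = 0.01, n_matched: int = 20,
            delays=(0.0, 0.04, 0.06, 0.14), write_traces: bool = False) -> dict:
    """Run the full analysis chain on a synthetic study and write all
    tables plus a JSON manifest to ``out_dir``.  Returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__, "seed": int(seed),
        "config_hash": config_hash(cfg), "config": cfg.to_dict(),
        "n_subjects": n_subjects, "stages": [], "outputs": [],
    }
    t0 = _time.perf_counter()

    # --- synth ---------------------------------------------------------
    sessions = simulate_study(cfg, n_subjects=n_subjects, seed=seed)
    t0 = _log(manifest, "synth", t0,
              n_trials=sum(len(s.trials) for s in sessions),
              n_true_events=sum(len(s.events) for s in sessions))

    # --- preprocess + detect per subject -------------------------------
    all_trials, all_events = [], []
    detected_by_subject = {}
    excluded_frac = {}
    for sess in sessions:
        subject = sess.trials["subject"].iloc[0]
        events = detect_microsaccades(sess.trace)
        detected_by_subject[subject] = events
        ivals = blink_intervals(sess.trace, buffer=0.0)
        trials, frac = exclude_blink_trials(sess.trials, ivals, window=0.1)
        excluded_frac[subject] = frac
        trials = attach_latency(trials, events)
        all_trials.append(trials)
        all_events.extend(events)
        if write_traces:
            sess.trace.write(out / f"trace_{subject}.tsv")
            manifest["outputs"].append(f"trace_{subject}.tsv")
    trials = pd.concat(all_trials, ignore_index=True)
    t0 = _log(manifest, "detect", t0, n_detected=len(all_events),
              blink_excluded_frac=float(np.mean(list(excluded_frac.values()))))

    write_trials(trials, out / "trials.tsv")
    events_to_frame(all_events).to_csv(out / "events.tsv", sep="\t", index=False)
    manifest["outputs"] += ["trials.tsv", "events.tsv"]

    # --- Fig 1-style summaries -----------------------------------------
    finite = trials[np.isfinite(trials["tau_s"])]
    hist, edges = np.histogram(finite["tau_s"], bins=np.arange(-1.0, 1.02, 0.05))
    pd.DataFrame({"tau_lo_s": edges[:-1], "tau_hi_s": edges[1:], "n_trials": hist}) \
        .to_csv(out / "latency_hist.tsv", sep="\t", index=False)
    if len(all_events) >= 3:
        r, slope = main_sequence(all_events)
        centers, props = direction_histogram(all_events, n_bins=8)
        pd.DataFrame({"direction_deg": centers, "proportion": props}) \
            .to_csv(out / "direction_hist.tsv", sep="\t", index=False)
        manifest["main_sequence"] = {"r": r, "slope": slope}
        manifest["outputs"].append("direction_hist.tsv")
    manifest["outputs"].append("latency_hist.tsv")
    t0 = _log(manifest, "summaries", t0)

    # --- psychometrics --------------------------------------------------
    if len(all_events) == 0:
        manifest["warning"] = ("no microsaccades detected; "
                               "threshold analysis is baseline-only")
        gf = global_fit(trials)
        tc = pd.DataFrame()
    else:
        gf = global_fit(trials)
        rng = np.random.default_rng(seed)
        tc = sensitivity_timecourse(trials, gf, step=timecourse_step,
                                    rng=rng, n_matched=n_matched)
        tc.to_csv(out / "timecourse.tsv", sep="\t", index=False)
        manifest["outputs"].append("timecourse.tsv")
        for name, win in (("csf_suppression", SUPPRESSION_WINDOW),
                          ("csf_facilitation", FACILITATION_WINDOW)):
            csf = window_csf(trials, win, gf, rng=rng, n_matched=n_matched)
            csf.to_csv(out / f"{name}.tsv", sep="\t", index=False)
            manifest["outputs"].append(f"{name}.tsv")
        part = orientation_partition(trials, gf, rng=rng, n_matched=n_matched)
        part.to_csv(out / "orientation_partition.tsv", sep="\t", index=False)
        manifest["outputs"].append("orientation_partition.tsv")
    manifest["global_fit"] = {
        "lam": gf.lam,
        "mu": {str(k): v for k, v in gf.mu.items()},
        "s": {str(k): v for k, v in gf.s.items()},
    }
    t0 = _log(manifest, "fit", t0, n_trials=len(trials))

    # --- drift ----------------------------------------------------------
    drift_rows = []
    for sess in sessions:
        subject = sess.trials["subject"].iloc[0]
        events = detected_by_subject[subject]
        if len(events) == 0:
            continue
        d = drift_timecourse(sess.trace, events)
        d.insert(0, "subject", subject)
        drift_rows.append(d)
    if drift_rows:
        drift_df = pd.concat(drift_rows, ignore_index=True)
        drift_df.to_csv(out / "drift.tsv", sep="\t", index=False)
        manifest["outputs"].append("drift.tsv")
    t0 = _log(manifest, "drift", t0)

    # --- gain model -----------------------------------------------------
    params = GainModelParams()
    sweep = sweep_delay(params, delays=delays)
    model_rows = []
    for row in sweep.itertuples(index=False):
        df = row.state.to_frame()
        df.insert(0, "t_delay", row.t_delay)
        model_rows.append(df)
    pd.concat(model_rows, ignore_index=True) \
        .to_csv(out / "gain_model.tsv", sep="\t", index=False)
    manifest["outputs"].append("gain_model.tsv")
    manifest["gain_model"] = {
        str(r.t_delay): {"a_scaled": r.a_scaled,
                         "facilitation_peak_t": r.facilitation_peak_t,
                         "facilitation_peak_sf": r.facilitation_peak_sf}
        for r in sweep.itertuples(index=False)
    }
    _log(manifest, "model", t0)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
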