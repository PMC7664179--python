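"""End-to-end replica battery: simulate -> detect (both methods) -> agree.

Runs the full pipeline for forward and backward walking at three belt speeds
each, pools matched pairs and stride times per condition, and emits one
agreement report per (condition, event kind) plus the forward-vs-backward
Mann-Whitney comparisons of absolute event-time differences.  Every summary
carries provenance metadata (seed, package version, config hash) and is
byte-identical across reruns with the same seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, replace

import numpy as np

from . import __version__
from .agreement import mann_whitney_u, match_events, matched_stride_times, \
    report_from_components, DEFAULT_MATCH_TOLERANCE_S
from .detect import PeakParams, detect_trial
from .simulate import battery_configs, simulate_trial

log = logging.getLogger("gaitmark.battery")


def _config_hash(configs) -> str:
    canon = json.dumps([asdict(c) for c in configs], sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_battery(seed: int = 0, scale: float = 0.1, out_dir: str | None = None,
                tolerance_s: float = DEFAULT_MATCH_TOLERANCE_S,
                params: PeakParams | None = None,
                zero_phase: bool = True,
                sim_overrides: dict | None = None) -> dict:
    """Run the simulate/detect/agree battery; return the JSON-ready summary.

    The kinematic (OMC) method is the reference and the IMU method the test,
    so the sign convention of every bias is t_IMU - t_OMC (positive = IMU
    late).  ``scale`` rescales the stride counts of the full-size regime.
    ``sim_overrides`` replaces fields on every trial config (e.g. zeroed
    noise for sensitivity runs).  If ``out_dir`` is given, writes
    ``summary.json`` plus per-trial event tables there.
    """
    configs = battery_configs(scale=scale, seed=seed)
    if sim_overrides:
        configs = [replace(c, **sim_overrides) for c in configs]
    acc: dict[str, dict[str, dict]] = {}
    n_detected = 0
    n_truth = 0
    for cfg in configs:
        trial, truth = simulate_trial(cfg)
        omc = detect_trial(trial, "omc", params=params, sides=cfg.sides,
                           zero_phase=zero_phase)
        imu = detect_trial(trial, "imu", params=params, sides=cfg.sides,
                           zero_phase=zero_phase)
        n_detected += len(omc) + len(imu)
        n_truth += len(truth)
        cond = cfg.condition
        store = acc.setdefault(cond, {})
        for kind in ("IC", "TC"):
            slot = store.setdefault(kind, {"diffs": [], "sa": [], "sb": [],
                                           "unr": 0, "unt": 0})
            for side in cfg.sides:
                pairs = match_events(omc, imu, kind, side, tolerance_s)
                if pairs.n_unmatched_ref or pairs.n_unmatched_test:
                    log.warning("unmatched %s events (%s %s side %s): ref=%d test=%d",
                                kind, cond, cfg.speed_label, side,
                                pairs.n_unmatched_ref, pairs.n_unmatched_test)
                sa, sb = matched_stride_times(pairs)
                slot["diffs"].append(pairs.diffs)
                slot["sa"].append(sa)
                slot["sb"].append(sb)
                slot["unr"] += pairs.n_unmatched_ref
                slot["unt"] += pairs.n_unmatched_test
        if out_dir is not None:
            os.makedirs(out_dir, exist_ok=True)
            from .signals import write_events
            tag = f"{cond.lower()}_{cfg.speed_label}"
            write_events(truth, os.path.join(out_dir, f"{tag}_truth.csv"))
            write_events(omc, os.path.join(out_dir, f"{tag}_omc.csv"))
            write_events(imu, os.path.join(out_dir, f"{tag}_imu.csv"))

    conditions = {}
    abs_diffs: dict[str, dict[str, np.ndarray]] = {}
    for cond, store in acc.items():
        conditions[cond] = {}
        abs_diffs[cond] = {}
        for kind, slot in store.items():
            diffs = np.concatenate(slot["diffs"])
            sa = np.concatenate(slot["sa"])
            sb = np.concatenate(slot["sb"])
            report = report_from_components(kind, diffs, sa, sb,
                                            slot["unr"], slot["unt"])
            conditions[cond][kind] = report.to_dict()
            abs_diffs[cond][kind] = np.abs(diffs) * 1e3

    fw_vs_bw = {}
    if "FW" in abs_diffs and "BW" in abs_diffs:
        for kind in ("IC", "TC"):
            u, p = mann_whitney_u(abs_diffs["FW"][kind], abs_diffs["BW"][kind])
            fw_vs_bw[kind] = {"U": u, "p": p,
                              "n_fw": int(abs_diffs["FW"][kind].size),
                              "n_bw": int(abs_diffs["BW"][kind].size)}
        fw_pool = np.concatenate(list(abs_diffs["FW"].values()))
        bw_pool = np.concatenate(list(abs_diffs["BW"].values()))
        u, p = mann_whitney_u(fw_pool, bw_pool)
        fw_vs_bw["pooled"] = {"U": u, "p": p,
                              "n_fw": int(fw_pool.size), "n_bw": int(bw_pool.size)}

    summary = {
        "meta": {
            "seed": int(seed),
            "scale": float(scale),
            "tolerance_s": float(tolerance_s),
            "zero_phase": bool(zero_phase),
            "version": __version__,
            "config_hash": _config_hash(configs),
            "n_trials": len(configs),
        },
        "conditions": conditions,
        "fw_vs_bw": fw_vs_bw,
        "events": {
            "n_detected_total": int(n_detected),
            "n_truth_total": int(n_truth),
            "n_unmatched_total": int(sum(
                r["n_unmatched_ref"] + r["n_unmatched_test"]
                for c in conditions.values() for r in c.values())),
        },
    }
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        with open(os.path.join(out_dir, "summary.json"), "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return summary


def summary_json(summary: dict) -> str:
    """Canonical serialization used for determinism checks."""
    return json.dumps(summary, indent=2, sort_keys=True)
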