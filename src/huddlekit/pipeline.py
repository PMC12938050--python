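"""End-to-end orchestrator: tracking -> events -> nulls -> states -> HMM report.

``run_pipeline`` executes the full analysis on one or more recordings (read
from disk or simulated on the fly), writing tidy tables and a deterministic
JSON report. Identical config + seed reproduces identical outputs; runtime
metadata (config hash, library versions) goes to a separate run log so the
report JSON stays byte-stable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .arena import SimConfig, simulate_group
from .chance import permutation_null
from .markov import estimate_transitions, sample_states
from .prehuddle import (
    assign_roles,
    clustered_bootstrap,
    decode_windows,
    fit_hmm_select,
    pre_window_features,
    approach_station_ratio,
    windows_table,
)
from .proximity import HuddleCriteria, RegionGrid, classify_state_series, corner_enrichment, events_table, huddling_fraction
from .tracking import read_tracking

__all__ = ["run_pipeline", "StageError", "default_config"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def default_config() -> dict:
    return {
        "inputs": [],  # list of {path, dialect, condition, ...} or {simulate: {...}}
        "criteria": {"distance_cm": 5.0, "min_duration_s": 60.0, "entry_radius_cm": 3.5, "entry_sustain_s": 1.0},
        "permute": {"n_iter": 1000, "seed": 0},
        "markov": {"interval_s": 60.0, "anchor": "range-start"},
        "hmm": {"K_range": [2, 3, 4], "restarts": 10, "B": 200, "seed": 0},
        "output": "huddlekit-out",
        "analyzed_seconds": None,
    }


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    merged = default_config()
    merged.update(config or {})
    return merged


def _criteria(cfg: dict) -> HuddleCriteria:
    c = cfg["criteria"]
    return HuddleCriteria(
        distance_threshold=c.get("distance_cm", 5.0),
        min_duration=c.get("min_duration_s", 60.0),
        entry_radius=c.get("entry_radius_cm", 3.5),
        entry_min_inside=c.get("entry_sustain_s", 1.0),
    )


def _load_recordings(cfg: dict):
    recs = []
    for spec in cfg["inputs"]:
        if "simulate" in spec:
            sim = SimConfig(**spec["simulate"])
            rec, _ = simulate_group(sim)
        else:
            rec = read_tracking(
                spec["path"],
                spec.get("dialect", "csv"),
                fps=spec.get("fps", 30.0),
                pixels_per_cm=spec.get("pixels_per_cm"),
                condition=spec.get("condition", "unknown"),
            )
            if spec.get("recording_id"):
                rec.recording_id = spec["recording_id"]
        if cfg.get("analyzed_seconds"):
            rec.analyzed_range = (0, min(rec.n_frames, int(cfg["analyzed_seconds"] * rec.fps)))
        recs.append(rec)
    if not recs:
        raise ValueError("no inputs configured")
    return recs


def run_pipeline(config, out_dir: str | Path | None = None) -> dict:
    """Run detect -> fraction/permute -> corners -> markov -> roles/HMM.

    Returns the report dict; writes ``events.csv``, ``features.csv`` (when
    dyadic events exist), ``report.json`` and ``run_log.txt`` under the
    configured output directory.
    """
    cfg = _load_config(config)
    out = Path(out_dir or cfg["output"])
    out.mkdir(parents=True, exist_ok=True)
    criteria = _criteria(cfg)
    report: dict = {"recordings": {}}

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as e:  # noqa: BLE001 - abort with stage name
                raise StageError(name, e) from e
        return deco

    recs = stage("read")(lambda: _load_recordings(cfg))

    all_events = {}
    state_series = {}

    @stage("detect")
    def _detect():
        tables = []
        for rec in recs:
            states, events = classify_state_series(rec, criteria)
            all_events[rec.recording_id] = events
            state_series[rec.recording_id] = states
            tables.append(events_table(events, rec))
        pd.concat(tables, ignore_index=True).to_csv(out / "events.csv", index=False)

    @stage("fraction_permute")
    def _permute():
        for rec in recs:
            frac = huddling_fraction(rec, criteria)
            perm = permutation_null(
                rec, criteria, n_iter=cfg["permute"]["n_iter"], seed=cfg["permute"]["seed"]
            )
            report["recordings"][rec.recording_id] = {
                "condition": rec.condition,
                "huddling_fraction": frac,
                "n_events": len(all_events[rec.recording_id]),
                "permutation": perm.to_dict(),
            }

    @stage("corners")
    def _corners():
        enr = corner_enrichment(all_events, RegionGrid(recs[0].arena))
        report["corner_enrichment"] = {
            "proportions": {f"{r}:{a}": p for (r, a), p in enr["proportions"].items()},
            "n_excluded_mice": len(enr["excluded"]),
            "test": enr["test"].to_dict() if enr["test"] else None,
            "null_value": enr["null_value"],
        }

    @stage("markov")
    def _markov():
        seqs = []
        for rec in recs:
            lo, hi = rec.analyzed_range
            try:
                seqs.append(
                    sample_states(
                        state_series[rec.recording_id][lo:hi],
                        rec.fps,
                        cfg["markov"]["interval_s"],
                        recording_id=rec.recording_id,
                    )
                )
            except ValueError:
                continue
        if seqs:
            tm = estimate_transitions(seqs)
            report["markov"] = {
                "counts": tm.counts.tolist(),
                "P": np.round(tm.P, 6).tolist(),
                "undefined_rows": tm.undefined_rows,
                "state_order": tm.state_labels,
            }

    @stage("hmm")
    def _hmm():
        windows, by_animal = [], {}
        for rec in recs:
            for ev in all_events[rec.recording_id]:
                if ev.state != 2:
                    continue
                ra = assign_roles(rec, ev, criteria)
                if ra is None:
                    continue
                for w in pre_window_features(rec, ra, ev):
                    windows.append(w)
                    by_animal.setdefault((rec.recording_id, w.animal), []).append(w)
        report["n_prehuddle_windows"] = len(windows)
        if len(windows) < 2:
            return
        hcfg = cfg["hmm"]
        fit = fit_hmm_select(
            windows, K_range=tuple(hcfg["K_range"]), n_restarts=hcfg["restarts"], seed=hcfg["seed"]
        )
        states = decode_windows(fit, windows)
        windows_table(windows, states).to_csv(out / "features.csv", index=False)
        ratios = approach_station_ratio(states, fit, windows)
        ratios.to_csv(out / "log_ratios.csv", index=False)
        boot = clustered_bootstrap(by_animal, B=hcfg["B"], seed=hcfg["seed"])
        report["hmm"] = {
            "K_selected": fit.K,
            "AIC": round(fit.aic, 6),
            "BIC": round(fit.bic, 6),
            "AIC_by_K": {str(k): round(v, 6) for k, v in fit.aic_by_k.items()},
            "BIC_by_K": {str(k): round(v, 6) for k, v in fit.bic_by_k.items()},
            "P": np.round(fit.P, 6).tolist(),
            "pi": np.round(fit.pi, 6).tolist(),
            "wPersistence": round(fit.wpersistence, 6),
            "state_labels": fit.state_labels,
            "bootstrap": {
                "B": boot.B,
                "median": round(boot.median, 6),
                "ci95": [round(boot.ci95[0], 6), round(boot.ci95[1], 6)],
            },
        }

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    cfg_hash = hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()
    with open(out / "run_log.txt", "w") as fh:
        fh.write(f"huddlekit {__version__}\nconfig sha256 {cfg_hash}\n")
        fh.write(f"numpy {np.__version__}\npandas {pd.__version__}\n")
        fh.write(json.dumps(cfg, indent=2, sort_keys=True, default=str) + "\n")
    return report
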