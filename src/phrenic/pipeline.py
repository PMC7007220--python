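"""Config-driven end-to-end runs.

``run_pipeline`` executes the requested stages - each one simulates its
modality under the configured conditions and analyzes the result with the
corresponding module - and returns a tidy result table (one row per
id/metric) whose ``params_hash`` ties every value to the resolved
configuration.  Runs are deterministic given (config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import breathing, bursts, dendrites, puncta, topography
from .io import validate_config, write_table
from .synth import (
    FiringSimParams,
    simulate_breath_trace,
    simulate_dendrite_image,
    simulate_nerve_recording,
    simulate_puncta_field,
    simulate_soma_map,
)
from .synth.breath import CONDITION_FACTORS

log = logging.getLogger("phrenic.pipeline")

DEFAULT_STAGES = ("nerve", "somata", "dendrites", "puncta", "breath")


def _params_hash(config: dict, seed: int) -> str:
    payload = json.dumps({"config": config, "seed": seed}, sort_keys=True,
                         default=str)
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


def _rows(stage: str, ident: str, metrics: dict[str, tuple[float, str]],
          phash: str) -> list[dict]:
    return [
        {"stage": stage, "id": ident, "metric": name, "value": value,
         "units": units, "params_hash": phash}
        for name, (value, units) in metrics.items()
    ]


def _stage_nerve(cfg: dict, seed: int, phash: str) -> list[dict]:
    conditions = cfg.get("conditions", ["control", "mutant"])
    n_bursts = int(cfg.get("n_bursts", 5))
    split_hz = float(cfg.get("split_hz", 75.0))
    overrides = {k: v for k, v in cfg.items()
                 if k not in ("conditions", "n_bursts", "split_hz")}
    rows = []
    for cond in conditions:
        params = replace(FiringSimParams(**overrides), condition=cond, seed=seed)
        rec, _ = simulate_nerve_recording(params)
        res = bursts.analyze_recording(rec, n_bursts=n_bursts, split_hz=split_hz)
        rows += _rows("nerve", cond, {
            "silent_fraction_pct": (res["mean_silent_fraction_pct"], "%"),
            "peak_frequency_hz": (res["peak_hz"], "Hz"),
            "below_split_pct": (res["below_pct"], "%"),
            "above_split_pct": (res["above_pct"], "%"),
            "burst_rate_per_min": (res["burst_rate_per_min"], "1/min"),
            "mean_burst_duration_s": (res["mean_duration_s"], "s"),
        }, phash)
    return rows


def _stage_somata(cfg: dict, seed: int, phash: str) -> list[dict]:
    conditions = cfg.get("conditions", ["clustered", "dispersed"])
    keys = ("n", "radius_um", "field_um", "margin_um")
    sim_kwargs = {k: cfg[k] for k in keys if k in cfg}
    rows = []
    for cond in conditions:
        soma_map, _ = simulate_soma_map(condition=cond, seed=seed, **sim_kwargs)
        report = topography.cluster_report(
            soma_map, tol_um=float(cfg.get("tol_um", 0.0)),
            shape=cfg.get("shape", "hull"),
            alpha_um=float(cfg.get("alpha_um", 30.0)))
        metrics = {
            "contact_index": (report.contact_index, ""),
            "n_neurons": (float(report.n_neurons), "count"),
        }
        if report.hull_area_um2 is not None:
            metrics["hull_area_um2"] = (report.hull_area_um2, "um^2")
            metrics["density_index"] = (report.density_index, "1/1000um^2")
        rows += _rows("somata", cond, metrics, phash)
    return rows


def _stage_dendrites(cfg: dict, seed: int, phash: str) -> list[dict]:
    conditions = cfg.get("conditions", ["control", "mutant"])
    extent = float(cfg.get("contralateral_extent_um", 50.0))
    rows = []
    for cond in conditions:
        sim = simulate_dendrite_image(
            contralateral_extent_um=extent if cond == "mutant" else 0.0,
            pixel_size_um=float(cfg.get("pixel_size_um", 2.0)),
            ray_sigma_um=float(cfg.get("ray_sigma_um", 12.0)),
            seed=seed)
        gq = dendrites.grid_quantify(sim.image,
                                     span_um=float(cfg.get("span_um", 200.0)))
        ms = dendrites.midline_crossing_stats(sim.image)
        rows += _rows("dendrites", cond, {
            "dorsolateral_fraction": (gq.dorsolateral_fraction, ""),
            "midline_square_fraction": (gq.midline_fraction, ""),
            "dorsal_fraction": (dendrites.dorsal_fraction(sim.image), ""),
            "n_midline_crossings": (float(ms.n_crossing_components), "count"),
            "max_contralateral_um": (ms.max_contralateral_distance_um, "um"),
            "coverage_um2": (dendrites.coverage_area(sim.image), "um^2"),
        }, phash)
    return rows


def _stage_puncta(cfg: dict, seed: int, phash: str) -> list[dict]:
    conditions = cfg.get("conditions", ["control", "mutant"])
    paired = cfg.get("paired_per_soma", {"control": 8, "mutant": 6})
    if not isinstance(paired, dict):
        paired = {c: int(paired) for c in conditions}
    keys = ("n_somata", "distractor_density_per_um2", "apposition_sep_um",
            "field_um")
    sim_kwargs = {k: cfg[k] for k in keys if k in cfg}
    rows = []
    for cond in conditions:
        pre_img, post_img, truth = simulate_puncta_field(
            paired_per_soma=int(paired[cond]), seed=seed, **sim_kwargs)
        ch_pre = puncta.detect_puncta(pre_img, truth.pixel_size_um, label="pre")
        ch_post = puncta.detect_puncta(post_img, truth.pixel_size_um, label="post")
        apps = puncta.match_appositions(
            ch_pre, ch_post, max_sep_um=float(cfg.get("max_sep_um", 0.5)))
        counts = puncta.perisomatic_counts(
            apps, truth.outlines, shell_um=float(cfg.get("shell_um", 2.0)))
        rows += _rows("puncta", cond, {
            "perisomatic_appositions_per_soma":
                (float(np.mean(list(counts.values()))), "count"),
            "n_appositions": (float(apps.n), "count"),
        }, phash)
    return rows


def _stage_breath(cfg: dict, seed: int, phash: str) -> list[dict]:
    conditions = cfg.get("conditions", ["control", "mutant"])
    tv = float(cfg.get("tidal_volume", 0.2))
    bpm = float(cfg.get("breaths_per_min", 150.0))
    n_days = int(cfg.get("n_days", 3))
    kwargs = {k: cfg[k] for k in ("noise_sd", "duration_s") if k in cfg}
    window_s = float(cfg.get("window_s", 30.0))
    rows = []
    averaged = {}
    for cond in conditions:
        f_tv, f_bpm = CONDITION_FACTORS.get(cond, (1.0, 1.0))
        per_day = []
        for day in range(n_days):
            trace = simulate_breath_trace(
                tidal_volume=tv * f_tv, breaths_per_min=bpm * f_bpm,
                subject=cond, day=day, seed=seed * 101 + day, **kwargs)
            per_day.append(breathing.breath_metrics(trace, window_s=window_s))
        avg = breathing.session_average(per_day)
        averaged[cond] = avg
        rows += _rows("breath", cond, {
            "tidal_volume": (avg.tidal_volume, "a.u."),
            "frequency_bpm": (avg.frequency_bpm, "1/min"),
            "minute_ventilation": (avg.minute_ventilation, "a.u./min"),
        }, phash)
    if "control" in averaged:
        for cond, avg in averaged.items():
            if cond == "control":
                continue
            folds = breathing.fold_control(avg, averaged["control"])
            rows += _rows("breath", f"{cond}_fold_control", {
                f"{name}_fold": (value, "") for name, value in folds.items()
            }, phash)
    return rows


_STAGE_RUNNERS = {
    "nerve": _stage_nerve,
    "somata": _stage_somata,
    "dendrites": _stage_dendrites,
    "puncta": _stage_puncta,
    "breath": _stage_breath,
}


def run_pipeline(config: dict | None = None, seed: int = 0,
                 out_dir: str | Path | None = None) -> pd.DataFrame:
    """Execute the configured stages and return the tidy result table.

    ``config`` holds optional per-stage blocks (see
    :data:`phrenic.io.KNOWN_CONFIG_KEYS`); unknown keys are rejected before
    anything runs.  When ``out_dir`` is given, the table and the resolved
    configuration are written beside each other.
    """
    config = dict(config or {})
    validate_config(config)
    seed = int(config.get("seed", seed))
    out_dir = out_dir or config.get("out_dir")
    stages = config.get("stages", list(DEFAULT_STAGES))
    phash = _params_hash(config, seed)
    all_rows: list[dict] = []
    for stage in stages:
        if stage not in _STAGE_RUNNERS:
            raise ValueError(f"unknown pipeline stage {stage!r}")
        t0 = time.perf_counter()
        try:
            all_rows += _STAGE_RUNNERS[stage](config.get(stage, {}), seed, phash)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        log.info("stage %s finished in %.2f s", stage, time.perf_counter() - t0)
    table = pd.DataFrame(
        all_rows, columns=["stage", "id", "metric", "value", "units",
                           "params_hash"])
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_table(table, out / "results.csv")
        (out / "resolved_config.json").write_text(
            json.dumps({"config": config, "seed": seed}, indent=1, default=str))
    return table
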