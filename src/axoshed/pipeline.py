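"""End-to-end pipeline: simulate -> register -> kymograph -> transport ->
co-localization -> volumetry -> dystrophy -> per-animal statistics.

``run_pipeline`` executes the whole chain on a simulation configuration
(one synthetic scene per animal) and emits a deterministic JSON-able report
plus optional CSV outputs.  ``analyze_scene`` runs the measurement side on
a single scene and is the unit the recovery tests exercise.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dystrophy as dys
from . import kymo, synthetic, transport, volumetry
from .config import SceneConfig
from .stacks import COMPARTMENT_LABELS

__all__ = ["analyze_scene", "run_pipeline", "DEFAULT_PIPELINE_CONFIG"]

log = logging.getLogger("axoshed")

DEFAULT_PIPELINE_CONFIG = {
    "seed": 0,
    "n_animals": 2,
    "scene": {"n_particles": 150, "field_length_um": 150.0,
              "drift_per_frame_px": (0.2, 0.1)},
    "transport": {
        "min_prominence": 12.0,
        "max_jump_um": 2.0,
        "max_gap_frames": 2,
        "min_trace_len": 5,
        "swath_width_um": 1.5,
        "reducer": "max",
    },
    "coloc": {"max_dist_um": 0.5, "min_overlap_frac": 0.5},
    "volumetry": {"enabled": True, "shell_um": 3.0},
    "dystrophy": {"enabled": True, "axon_length_um": 1000.0},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _child_seeds(seed: int, n: int) -> list:
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s & 0x7FFFFFFF) for s in state]


def analyze_scene(cfg: SceneConfig, transport_params: dict | None = None,
                  coloc_params: dict | None = None,
                  volumetry_params: dict | None = None,
                  animal: str = "a1", condition: str = "sim") -> dict:
    """Measure one synthetic scene end to end.

    Simulates trajectories, renders and (optionally) drifts the time-lapse,
    registers it, traces the nerve contour, extracts per-swath kymographs
    for the mito and partner channels, links and classifies traces, scores
    two-channel co-localization, and (optionally) measures the z-stack
    outside-axon volumetry.  Returns a dict of measurements plus the ground
    truth needed to score recovery.
    """
    tp = dict(DEFAULT_PIPELINE_CONFIG["transport"])
    tp.update(transport_params or {})
    cp = dict(DEFAULT_PIPELINE_CONFIG["coloc"])
    cp.update(coloc_params or {})
    vp = dict(DEFAULT_PIPELINE_CONFIG["volumetry"])
    vp.update(volumetry_params or {})

    t0 = time.perf_counter()
    particles = synthetic.simulate_trajectories(cfg)
    stack = synthetic.render_timelapse(particles, cfg)
    if any(cfg.drift_per_frame_px):
        stack, _ = synthetic.inject_drift(stack, cfg.drift_per_frame_px)
        shifts = kymo.estimate_drift(stack, reference="first")
        stack = kymo.apply_shifts(stack, shifts)
    log.info("scene %s: rendered+registered in %.1fs", animal,
             time.perf_counter() - t0)

    projection = stack.channel("lc3b").mean(axis=0)
    contour = kymo.trace_nerve_contour(projection, cfg.pixel_size_um)
    swaths = kymo.build_swaths(contour, tp["swath_width_um"])

    traces = {}
    for role in ("mito", "optn"):
        chan_traces = []
        for kg in kymo.extract_swath_kymographs(stack, swaths,
                                                channel_role=role,
                                                reducer=tp["reducer"]):
            peaks = transport.detect_kymo_objects(kg, tp["min_prominence"])
            linked, _ = transport.link_traces(
                peaks, kg.dt_s, max_jump_um=tp["max_jump_um"],
                max_gap_frames=tp["max_gap_frames"],
                min_trace_len=tp["min_trace_len"], channel_role=role,
                source=kg.source)
            chan_traces.extend(linked)
        traces[role] = chan_traces
    log.info("scene %s: %d mito / %d optn traces", animal,
             len(traces["mito"]), len(traces["optn"]))

    table = transport.traces_to_table(traces["mito"], animal=animal,
                                      condition=condition)
    coloc = transport.match_traces(traces["mito"], traces["optn"],
                                   max_dist_um=cp["max_dist_um"],
                                   min_overlap_frac=cp["min_overlap_frac"])
    dedup = transport.deduplicate_stationary(traces["mito"])
    n_stationary_raw = sum(
        t.movement_class == "stationary" for t in traces["mito"])
    n_stationary_dedup = sum(
        t.movement_class == "stationary" for t in dedup)

    result = {
        "animal": animal,
        "truth": synthetic.truth_table(particles),
        "traces": traces,
        "trace_table": table,
        "coloc": coloc,
        "n_stationary_raw": n_stationary_raw,
        "n_stationary_dedup": n_stationary_dedup,
    }

    if vp.get("enabled", True):
        vol = synthetic.render_zstack(particles, cfg)
        mask = volumetry.build_axon_mask(vol)
        outside = volumetry.pct_outside(vol, "mito", mask)
        vt = vol.voxel_truth
        nerve_mask = ((vt == COMPARTMENT_LABELS["axon"])
                      | (vt == COMPARTMENT_LABELS["parenchyma"]))
        part = volumetry.partition_surface(vol, "mito", mask, nerve_mask,
                                           d_um=vp["shell_um"])
        result["volumetry"] = {
            "pct_outside_mito": outside.pct_outside,
            "pct_on_surface": part.pct_on_surface,
            "pct_in_parenchyma": part.pct_in_parenchyma,
            "true_fraction_outside": float(
                (~vol.blob_truth["inside_axon"]).mean()),
        }
    return result


def _dystrophy_block(cfg: SceneConfig, seed: int, axon_length_um: float):
    rng = np.random.default_rng(seed)
    n_prot = max(int(round(cfg.protrusion_density_per_100um
                           * axon_length_um / 100.0)), 1)
    xs = np.sort(rng.uniform(20, axon_length_um - 20, n_prot))
    # enforce separation so calls stay resolvable
    for i in range(1, len(xs)):
        xs[i] = max(xs[i], xs[i - 1] + 8.0)
    flags = rng.random(n_prot) < cfg.protrusion_mito_prob
    scene = synthetic.make_sparse_axon_image(
        axon_length_um, protrusion_x_um=xs, mito_flags=flags, seed=seed)
    calls, density, length = dys.detect_protrusions(
        scene["membrane"], scene["centerline_row"], scene["pixel_size_um"],
        mito=scene["mito"])
    n_mito = sum(c.contains_mito for c in calls)
    vols, masks, truth = synthetic.make_protrusion_series(
        "pinching_off", interval_s=30.0, duration_s=300.0, seed=seed)
    event = dys.track_event(vols, masks, interval_s=30.0)
    return {
        "planted": int(n_prot),
        "detected": len(calls),
        "density_per_100um": density,
        "mito_fraction_pct": 100.0 * n_mito / len(calls) if calls else 0.0,
        "event_kind": event.kind,
        "event_pinch_time_s": event.pinch_time_s,
        "true_pinch_time_s": float(truth.pinch_index * truth.interval_s
                                   + truth.interval_s),
    }


def _round(obj, nd=6):
    if isinstance(obj, dict):
        return {k: _round(v, nd) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round(v, nd) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return round(float(obj), nd)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def run_pipeline(config: dict | None = None,
                 out_dir: str | Path | None = None) -> dict:
    """Run the full simulated study and return the summary report.

    The configuration mirrors :data:`DEFAULT_PIPELINE_CONFIG`; all
    randomness derives from the single master ``seed``.  With ``out_dir``
    set, per-trace and per-animal CSVs, the resolved configuration and the
    summary JSON are written there.
    """
    cfg_all = _merge(DEFAULT_PIPELINE_CONFIG, config or {})
    seed = int(cfg_all["seed"])
    n_animals = int(cfg_all["n_animals"])
    seeds = _child_seeds(seed, n_animals + 1)

    tables, scenes = [], []
    stage_t0 = time.perf_counter()
    for i in range(n_animals):
        scene_cfg = SceneConfig.from_dict(
            _merge(cfg_all["scene"], {"seed": seeds[i]}))
        res = analyze_scene(scene_cfg,
                            transport_params=cfg_all["transport"],
                            coloc_params=cfg_all["coloc"],
                            volumetry_params=cfg_all["volumetry"],
                            animal=f"a{i + 1}")
        scenes.append(res)
        tables.append(res["trace_table"])
    trace_table = pd.concat(tables, ignore_index=True)
    summary = transport.summarize_movement(trace_table)

    report = {
        "seed": seed,
        "n_animals": n_animals,
        "transport": {
            row["measure"]: {"mean": row["mean"], "sem": row["sem"],
                             "n_animals": row["n_animals"]}
            for _, row in summary.group_stats.iterrows()
        },
        "n_traces_total": int(len(trace_table)),
    }

    # pooled co-localization by movement class
    pooled = {}
    for cls in transport.CLASSES:
        n_c = sum(int(s["coloc"].per_class.set_index("movement_class")
                      .loc[cls, "n_coloc"]) for s in scenes)
        n_t = sum(int(s["coloc"].per_class.set_index("movement_class")
                      .loc[cls, "n_total"]) for s in scenes)
        pooled[cls] = {"n_coloc": n_c, "n_total": n_t,
                       "frac_coloc": n_c / n_t if n_t else None}
    report["coloc"] = pooled

    if cfg_all["volumetry"].get("enabled", True):
        v = [s["volumetry"] for s in scenes if "volumetry" in s]
        report["volumetry"] = {
            "pct_outside_mito_mean": float(np.mean(
                [x["pct_outside_mito"] for x in v])),
            "pct_on_surface_mean": float(np.nanmean(
                [x["pct_on_surface"] for x in v])),
            "per_animal": v,
        }

    if cfg_all["dystrophy"].get("enabled", True):
        report["dystrophy"] = _dystrophy_block(
            SceneConfig.from_dict(_merge(cfg_all["scene"],
                                         {"seed": seeds[-1]})),
            seeds[-1], cfg_all["dystrophy"]["axon_length_um"])

    log.info("pipeline complete in %.1fs", time.perf_counter() - stage_t0)
    report = _round(report)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        trace_table.to_csv(out / "traces.csv", index=False)
        summary.per_animal.to_csv(out / "per_animal.csv", index=False)
        (out / "config.yaml").write_text(yaml.safe_dump(_round(cfg_all)))
        (out / "summary.json").write_text(
            json.dumps(report, sort_keys=True, indent=1))
    return report
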