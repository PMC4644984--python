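"""End-to-end demo pipeline: generate, analyse, write artefacts.

``run_all(outdir, seed)`` generates a small synthetic study (two treatment
groups of voltage movies, one calcium movie, viability and expression
micrograph sets, and two capture oracles), runs every analysis stage and
writes CSV/TIFF/JSON artefacts plus a provenance record to ``outdir``. All
randomness derives from the single run-level seed through named substreams,
so a repeated run with the same seed writes byte-identical tables.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from opticard import chr2, excitability, imaging, io, mapping, preprocess, synthetic, transients

__all__ = ["run_all", "stage_seed"]

# named substreams: stage index folded into the run-level seed
_STAGES = ("movies", "micrographs", "oracles", "model")


def stage_seed(seed: int, stage: str) -> int:
    """Derive a deterministic per-stage child seed below 2**31."""
    ss = np.random.SeedSequence([seed, _STAGES.index(stage)])
    return int(ss.generate_state(1)[0] % (2**31))


def run_all(
    outdir: str | Path,
    seed: int = 0,
    config: dict | None = None,
) -> dict[str, Path]:
    """Run the full demo analysis; returns a name -> path map of artefacts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = config or {}
    artefacts: dict[str, Path] = {}

    # --- simulate + transients -------------------------------------------
    mv_seed = stage_seed(seed, "movies")
    groups = {"control": 270.0, "treated": 388.8}
    metrics_by_group: dict[str, list[transients.TransientMetrics]] = {}
    rows = []
    first_movie = None
    for gi, (group, apd) in enumerate(groups.items()):
        metrics_by_group[group] = []
        for si in range(2):
            gt = synthetic.WaveGroundTruth(
                cv=19.1, duration80=apd, n_beats=4, snr=20.0,
                seed=mv_seed + 10 * gi + si,
            )
            shape = (synthetic.n_frames_for(gt, (24, 72), 10.0 / 3.0, 0.05), 24, 72)
            movie, _ = synthetic.gen_voltage_movie(gt, shape)
            if first_movie is None:
                first_movie = movie
            pre = preprocess.preprocess(movie)
            tm = transients.analyze_movie(pre)
            metrics_by_group[group].append(tm)
            for ev in tm.events:
                rows.append({"group": group, "sample": si, "t_start_ms": ev.t_start,
                             "duration80_ms": ev.duration80,
                             "amplitude": ev.amplitude, "measurable": ev.measurable})
    per_event = outdir / "apd_events.csv"
    pd.DataFrame(rows).to_csv(per_event, index=False)
    artefacts["apd_events"] = per_event
    summary = transients.summarize_group(metrics_by_group, reference="control")
    summary_path = outdir / "apd_group_summary.csv"
    summary.to_csv(summary_path)
    artefacts["apd_group_summary"] = summary_path

    # --- mapping on the first movie --------------------------------------
    pre = preprocess.preprocess(first_movie)
    res = mapping.activation_map(pre, beat_window=(0.0, 600.0))
    res = mapping.conduction_velocity(res)
    amap_path = outdir / "activation_map.tif"
    io.save_image_tiff(amap_path, res.activation_map)
    artefacts["activation_map"] = amap_path
    cv_path = outdir / "cv_paths.csv"
    res.cv_paths.to_csv(cv_path, index=False)
    artefacts["cv_paths"] = cv_path
    iso = mapping.isochrones(res)
    iso_path = outdir / "isochrones.json"
    io.save_json(iso_path, {f"{lvl:.3f}": [c.tolist() for c in conts]
                            for lvl, conts in iso.items()})
    artefacts["isochrones"] = iso_path

    # --- micrograph quantification ---------------------------------------
    mg_seed = stage_seed(seed, "micrographs")
    pi_groups, dapi_groups = {}, {}
    for gi, (group, frac) in enumerate({"control": 0.113, "atr_1um": 0.0113}.items()):
        pi_groups[group], dapi_groups[group] = [], []
        for si in range(2):
            gt = synthetic.MicrographGroundTruth(
                n_cells=150, dead_fraction=frac, seed=mg_seed + 10 * gi + si)
            imgs = synthetic.gen_micrographs(gt, "viability", shape=(256, 256))
            pi_groups[group].append(imgs["PI"])
            dapi_groups[group].append(imgs["DAPI"])
    pi_res = imaging.quantify_pi(pi_groups, "control", dapi_by_group=dapi_groups)
    pi_path = outdir / "quant_pi.csv"
    pi_res.group_stats.to_csv(pi_path)
    artefacts["quant_pi"] = pi_path

    chr2_imgs, ctrl_imgs, dapi_imgs = {}, {}, {}
    for ci, (cond, expr) in enumerate({"0": 150.0, "1": 570.0}.items()):
        chr2_imgs[cond], ctrl_imgs[cond], dapi_imgs[cond] = [], [], []
        for si in range(2):
            gt = synthetic.MicrographGroundTruth(
                n_cells=120, expression_per_cell=expr, seed=mg_seed + 1000 + 10 * ci + si)
            imgs = synthetic.gen_micrographs(gt, "expression", shape=(256, 256))
            chr2_imgs[cond].append(imgs["eYFP"])
            dapi_imgs[cond].append(imgs["DAPI"])
            gt0 = synthetic.MicrographGroundTruth(
                n_cells=120, expression_per_cell=0.0, seed=mg_seed + 2000 + 10 * ci + si)
            ctrl_imgs[cond].append(synthetic.gen_micrographs(gt0, "expression",
                                                             shape=(256, 256))["eYFP"])
    eyfp_res = imaging.quantify_eyfp(chr2_imgs, ctrl_imgs, dapi_imgs, "0")
    eyfp_path = outdir / "quant_eyfp.csv"
    eyfp_res.group_stats.to_csv(eyfp_path)
    artefacts["quant_eyfp"] = eyfp_path

    # --- strength-duration excitability ----------------------------------
    or_seed = stage_seed(seed, "oracles")
    durations = [2.0, 5.0, 10.0, 20.0, 50.0]
    sd_rows = []
    fits = {}
    for cond, rheo in {"0um": 0.30, "1um": 0.009}.items():
        oracle = synthetic.gen_capture_oracle(
            synthetic.OracleParams(rheobase=rheo, chronaxie=5.0, seed=or_seed))
        results = [excitability.find_threshold(oracle, d) for d in durations]
        curve = excitability.build_sd_curve(results, condition=cond)
        fit = excitability.fit_rheobase_chronaxie(curve)
        fits[cond] = {"rheobase": fit.rheobase, "chronaxie": fit.chronaxie,
                      "model": fit.model, "flags": fit.flags}
        for _, row in curve.table.iterrows():
            sd_rows.append({"condition": cond, **row.to_dict()})
    sd_path = outdir / "sd_curve.csv"
    pd.DataFrame(sd_rows).to_csv(sd_path, index=False)
    artefacts["sd_curve"] = sd_path
    fit_path = outdir / "sd_fit.json"
    io.save_json(fit_path, fits)
    artefacts["sd_fit"] = fit_path

    # --- ChR2 threshold model --------------------------------------------
    params = chr2.load_params()
    mapping_linear = chr2.AtrMapping(form="linear")
    atr_grid = np.array([0.0, 0.25, 0.5, 1.0, 2.0])
    curve_df = chr2.eth_vs_atr(mapping_linear, atr_grid, pulse_duration=10.0,
                               params=params, rel_precision=0.02)
    model_path = outdir / "eth_vs_atr.csv"
    curve_df.to_csv(model_path, index=False)
    artefacts["eth_vs_atr"] = model_path

    io.write_provenance(outdir / "provenance.json", seed, config,
                        stages=["simulate", "transients", "map", "quantify",
                                "excitability", "model"])
    artefacts["provenance"] = outdir / "provenance.json"
    return artefacts
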