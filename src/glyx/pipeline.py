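"""Top-level analyses wiring simulation, quantification and comparison.

Each experiment generates its inputs with the seeded synthetic module, runs
the corresponding measurement stage and writes tidy CSV results plus a JSON
provenance record (seed, config hash, package version) and the resolved
configuration next to the outputs.  Outputs are bit-reproducible for a fixed
configuration and seed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import camouflage as cam
from . import electrokinetics as ek
from . import synthetic as syn
from . import zstack as zq
from .config import RunConfig, config_hash, dump_config
from .errors import ConfigError
from .synthetic import StackSpec


def run_pipeline(config: RunConfig) -> dict:
    """Execute one named experiment; returns {name: output path}."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    runner = {
        "distribution": _run_distribution,
        "collapse": _run_collapse,
        "mobility": _run_mobility,
        "camouflage": _run_camouflage,
    }.get(config.experiment)
    if runner is None:
        raise ConfigError(f"unknown experiment {config.experiment!r}")

    tables = runner(config)

    outputs = {}
    for name, obj in tables.items():
        if isinstance(obj, pd.DataFrame):
            path = outdir / f"{name}.csv"
            obj.to_csv(path, index=False, float_format="%.10g")
        else:
            path = outdir / f"{name}.json"
            path.write_text(json.dumps(obj, indent=2, sort_keys=True,
                                       default=str))
        outputs[name] = str(path)

    provenance = {
        "package": "glyx",
        "version": __version__,
        "experiment": config.experiment,
        "seed": config.seed,
        "config_hash": config_hash(config),
        "outputs": sorted(outputs),
    }
    prov_path = outdir / "provenance.json"
    prov_path.write_text(json.dumps(provenance, indent=2, sort_keys=True))
    (outdir / "resolved_config.yaml").write_text(dump_config(config))
    outputs["provenance"] = str(prov_path)
    return outputs


# --------------------------------------------------------------------------
# experiments
# --------------------------------------------------------------------------

def _quantify(stack: zq.ZStack, roi: zq.RoiMask, cfg: RunConfig) -> dict:
    start = zq.find_membrane_reference(stack, roi) + 1
    top = zq.estimate_top(stack, roi, start, k_sigma=cfg.quant.k_sigma,
                          stat=cfg.quant.stat,
                          signal_fraction=cfg.quant.signal_fraction)
    q = zq.quadrant_fractions(stack, roi, start, top, stat=cfg.quant.stat)
    inner, outer = zq.inner_outer_shift(q)
    return {"start_slice": start, "top_slice": top,
            "q1": q.q1, "q2": q.q2, "q3": q.q3, "q4": q.q4,
            "inner": inner, "outer": outer,
            "height": (top - start + 1) * stack.z_step}


def _run_distribution(cfg: RunConfig) -> dict:
    """Probe distribution under non-crowded vs crowded grafting."""
    base = cfg.stack_spec(seed=cfg.seed)
    c = cfg.distribution.crowded_accessibility
    conditions = {
        "noncrowded": dataclasses.replace(base, probe_distribution="uniform"),
        "crowded": dataclasses.replace(
            base, probe_distribution="outer",
            outer_z_lo=(1.0 - c) * base.glyx_height,
            seed=syn._subseed(cfg.seed, 1)),
    }
    rows = []
    for condition, spec in conditions.items():
        stack = syn.gen_zstack(spec)
        roi = syn.cell_roi(spec)
        rows.append({"condition": condition, **_quantify(stack, roi, cfg)})
    return {"distribution": pd.DataFrame(rows)}


def _run_collapse(cfg: RunConfig) -> dict:
    """Glycocalyx collapse: height/density series, dose response, dextran."""
    cc = cfg.collapse
    if len(cc.doses) != len(cc.compressions):
        raise ConfigError("doses and compressions must have equal length")
    comp_map = dict(zip(cc.doses, cc.compressions))
    base = cfg.stack_spec(seed=cfg.seed)

    series = syn.gen_collapse_series(
        base, syn.CollapseSeriesSpec(doses=tuple(cc.doses),
                                     compression_map=comp_map,
                                     conserve_mass=cc.conserve_mass,
                                     washout=cc.washout))
    roi = syn.cell_roi(base)
    metric_rows = []
    for point in series:
        m = zq.collapse_metrics(point.stack, roi, point.condition,
                                k_sigma=cfg.quant.k_sigma,
                                signal_fraction=cfg.quant.signal_fraction)
        metric_rows.append({"dose": point.dose, "condition": m.condition,
                            "height": m.height,
                            "density_ratio": m.density_ratio})

    graft_series = syn.gen_graft_series(base, cc.doses, comp_map)
    dose_table = zq.dose_response(graft_series, roi,
                                  k_sigma=cfg.quant.k_sigma,
                                  stat=cfg.quant.stat,
                                  signal_fraction=cfg.quant.signal_fraction)

    # FITC-dextran style: mass-conserving compression with a free-dye
    # reference region and per-slice bleaching, normalized before averaging.
    dex_rows = []
    for condition, c in (("before", 1.0),
                         ("during", comp_map[max(cc.doses)])):
        spec = dataclasses.replace(
            base, probe_distribution="compressed", compression=c,
            conserve_mass=True, include_reference=True,
            bleach_per_slice=cc.bleach_per_slice,
            seed=syn._subseed(cfg.seed, 200 + int(c * 100)))
        stack = syn.gen_zstack(spec)
        cell, outside = syn.cell_roi(spec), syn.outside_roi(spec)
        inside_prof = zq.axial_profile(stack, "probe", cell)
        outside_prof = zq.axial_profile(stack, "probe", outside)
        norm = zq.photobleach_normalize(inside_prof, outside_prof)
        start = zq.find_membrane_reference(stack, cell) + 1
        top = zq.estimate_top(stack, cell, start, k_sigma=cfg.quant.k_sigma,
                              signal_fraction=cfg.quant.signal_fraction)
        dex_rows.append({
            "condition": condition, "compression": c,
            "mean_normalized_mfi": float(np.mean(norm.mfi[start:top + 1]))})

    return {"collapse_metrics": pd.DataFrame(metric_rows),
            "dose_response": dose_table,
            "dextran_normalized": pd.DataFrame(dex_rows)}


def _run_mobility(cfg: RunConfig) -> dict:
    """Mobility curves, a synthetic dataset and the scenario fit."""
    ekc = cfg.electrokinetics
    glx = ekc.glycocalyx()
    el = ekc.electrolyte()
    radius = ekc.graft_radius()
    grid = cfg.mobility.molecules_grid

    curves = []
    for scenario in ek.SCENARIOS:
        curve = ek.mobility_curve(
            glx, el, grid, scenario, graft_segment_radius=radius,
            outer_z_lo=ekc.outer_z_lo, cell_area=ekc.cell_area,
            segments_per_molecule=ekc.segments_per_molecule,
            n_nodes=ekc.n_nodes)
        curve["scenario"] = scenario
        curve["mobility_external"] = curve["mobility"] / ek.MOBILITY_EXTERNAL_UNIT
        curves.append(curve)

    data = syn.gen_mobility_dataset(
        glx, el, cfg.mobility.scenario, grid,
        noise_sd=cfg.mobility.noise_sd, seed=cfg.seed,
        graft_segment_radius=radius, outer_z_lo=ekc.outer_z_lo,
        cell_area=ekc.cell_area, n_nodes=ekc.n_nodes)

    fit = ek.fit_scenario(data, glx, el,
                          free_params=tuple(cfg.mobility.free_params),
                          outer_z_lo=ekc.outer_z_lo, cell_area=ekc.cell_area)
    fit_report = {
        "generating_scenario": cfg.mobility.scenario,
        "best_scenario": fit.best_scenario,
        "indistinguishable": fit.indistinguishable,
        "sse_per_scenario": fit.sse_per_scenario,
        "fitted_params": {s: f.params for s, f in fit.fits.items()},
    }
    return {"mobility_curves": pd.concat(curves, ignore_index=True),
            "mobility_measurements": data,
            "scenario_fit": fit_report}


def _run_camouflage(cfg: RunConfig) -> dict:
    """Synthetic cytometry and the protection/fold/Welch analysis."""
    cc = cfg.camouflage
    tables = []
    for i, (antigen, truths) in enumerate(sorted(cc.truths.items())):
        missing = set(cam.CONDITIONS) - set(truths)
        if missing:
            raise ConfigError(f"antigen {antigen!r} lacks truths for "
                              f"{sorted(missing)}")
        table = syn.gen_cytometry(truths, cv=cc.cv, n_events=cc.n_events,
                                  n_replicates=cc.n_replicates,
                                  seed=syn._subseed(cfg.seed, 300 + i))
        table = table.rename(columns={"group": "condition"})
        table.insert(0, "antigen", antigen)
        tables.append(table)
    mfi_table = pd.concat(tables, ignore_index=True)
    return {"cytometry_mfi": mfi_table,
            "protection": cam.analyze_protection(mfi_table)}
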