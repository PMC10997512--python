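"""End-to-end orchestration of the state-transition analysis.

``run_pipeline`` executes the stages

    simulate-data -> build-space -> fit-potential -> predict -> treat
    -> calibrate -> genes

against a configuration dictionary (or YAML file), writing every
artifact under the output directory together with a manifest recording
inputs, parameters, seeds and content hashes.  Stages communicate only
through serialized artifacts; rerunning with the same configuration
reproduces identical hashes for the deterministic stages.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calibration, dynamics, gene_analysis, potentials, statespace
from .potentials import PotentialModel
from .synthetic import SyntheticConfig, generate_cohort, write_dataset, read_dataset
from .treatment import TreatmentSchedule

__all__ = ["DEFAULT_CONFIG", "load_config", "run_pipeline", "STAGES"]

log = logging.getLogger("cmlstate.pipeline")

STAGES = ("simulate-data", "build-space", "fit-potential", "predict",
          "treat", "calibrate", "genes")

DEFAULT_CONFIG = {
    "seed": 0,
    "synthetic": {"n_genes": 20000},
    "counts": None,          # path to an existing dataset directory
    "fp": {"n_cells": 768, "dt": 0.01, "record_dt": 0.25},
    "calibrate": {"resolution": [8, 8], "reps": 100, "dt": 0.01,
                  "cohort": "TOTO"},
    "genes": {"max_genes_de": 2000, "alpha": 0.05},
    "stages": list(STAGES),
}


def load_config(path=None, **overrides) -> dict:
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    for key, val in overrides.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _record(manifest, stage, outdir, files, params=None):
    manifest["stages"][stage] = {
        "files": {str(f.relative_to(outdir)): _sha256(f) for f in files},
        "params": params or {},
    }


def run_pipeline(config: dict, outdir, stages=None) -> dict:
    """Run the configured stages; returns the manifest dictionary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(stages or config.get("stages") or STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    seed = int(config.get("seed", 0))
    manifest = {"seed": seed, "stages": {}}

    counts = table = truth = None
    model = None
    potential = None
    coords = None
    coords_treat = None

    def need_data():
        nonlocal counts, table
        if counts is None:
            src = config.get("counts") or outdir / "dataset"
            counts, table = read_dataset(src)

    try:
        if "simulate-data" in stages:
            log.info("stage simulate-data")
            syn = SyntheticConfig(seed=seed, **config.get("synthetic", {}))
            counts, table, truth = generate_cohort(syn)
            ddir = outdir / "dataset"
            write_dataset(counts, table, ddir, truth=truth)
            _record(manifest, "simulate-data", outdir,
                    [ddir / "counts.tsv", ddir / "metadata.tsv",
                     ddir / "truth.json"],
                    {"n_genes": syn.n_genes, "seed": seed})

        if "build-space" in stages:
            log.info("stage build-space")
            need_data()
            model = statespace.build_state_space(counts, table)
            mdir = outdir / "statespace"
            model.to_dir(mdir)
            coords = statespace.coordinate_series(model, table)
            coords.to_csv(outdir / "coordinates.tsv", sep="\t")
            coords_treat = statespace.project_samples(
                model, counts[[s for s in counts.columns
                               if table.loc[s, "cohort"] in ("TOTO", "TKI")]]
                .loc[model.genes], table)
            coords_treat.to_csv(outdir / "coordinates_treatment.tsv", sep="\t")
            _record(manifest, "build-space", outdir,
                    [mdir / "loadings.tsv", mdir / "model.json",
                     outdir / "coordinates.tsv",
                     outdir / "coordinates_treatment.tsv"],
                    {"rotation_deg": model.rotation_angle_degrees,
                     "axis": model.disease_axis_index})

        if "fit-potential" in stages:
            log.info("stage fit-potential")
            if coords is None:
                coords = pd.read_csv(outdir / "coordinates.tsv", sep="\t",
                                     index_col=0)
            cml = coords[coords.cohort == "CML"]["coordinate"]
            ctrl = coords[coords.cohort == "control"]["coordinate"]
            potential = potentials.empirical_potential_from_density(cml, ctrl)
            (outdir / "potential.json").write_text(potential.to_json())
            _record(manifest, "fit-potential", outdir,
                    [outdir / "potential.json"],
                    {"kind": potential.kind})

        def load_potential():
            nonlocal potential, coords, coords_treat
            if potential is None:
                potential = PotentialModel.from_json(outdir / "potential.json")
            if coords is None:
                coords = pd.read_csv(outdir / "coordinates.tsv", sep="\t",
                                     index_col=0)
            if coords_treat is None and \
                    (outdir / "coordinates_treatment.tsv").exists():
                coords_treat = pd.read_csv(
                    outdir / "coordinates_treatment.tsv", sep="\t",
                    index_col=0)

        if "predict" in stages:
            log.info("stage predict")
            load_potential()
            need_data()
            fpcfg = config["fp"]
            cml = coords[coords.cohort == "CML"]
            # beta per experimental group: the disease model uses the
            # disease cohort's own MSD slope
            beta = float(max(calibration.estimate_beta_from_slope({
                m: (g.week.to_numpy(), g.coordinate.to_numpy())
                for m, g in cml.groupby("mouse")}), 1e-8))
            obs_paths = {m: (g.sort_values("week").week.to_numpy(),
                             g.sort_values("week").coordinate.to_numpy())
                         for m, g in cml.groupby("mouse")}
            potential, a_opt = calibration.calibrate_amplitude(
                obs_paths, potential, beta,
                reps=config["calibrate"].get("reps", 100), seed=seed)
            (outdir / "potential.json").write_text(potential.to_json())
            c5 = potential.c(5) if potential.kind == "quintic" else \
                potential.critical_points[-1]
            horizon = float(table.week.max())
            predicted, observed, scores = {}, {}, {}
            for mouse, g in cml.groupby("mouse"):
                g = g.sort_values("week")
                x0 = float(g.coordinate.iloc[0])
                d = potential.disease_direction
                if d * (x0 - c5) >= 0:
                    predicted[mouse] = (float(g.week.iloc[0]), True)
                    scores[mouse] = float(g.week.iloc[0])
                else:
                    fp = dynamics.solve_fokker_planck(
                        potential, x0=x0, beta=beta, absorbing_at=c5,
                        t_max=horizon, n_cells=fpcfg["n_cells"],
                        dt=fpcfg["dt"], record_dt=fpcfg["record_dt"])
                    wk, P = dynamics.time_to_disease_probability(fp)
                    t = dynamics.predicted_time_from_curve(wk, P)
                    predicted[mouse] = (t, t is not None)
                    # continuous restricted-mean surrogate for the ordering
                    scores[mouse] = float(np.trapezoid(1.0 - fp.absorbed,
                                                       fp.times))
                observed[mouse] = dynamics.observed_first_crossing(
                    g.week.to_numpy(), g.coordinate.to_numpy(), c5,
                    direction=potential.disease_direction)
            comp = dynamics.compare_survival(predicted, observed,
                                             scores=scores)
            comp.table.to_csv(outdir / "survival.tsv", sep="\t", index=False)
            (outdir / "survival_stats.json").write_text(json.dumps({
                "logrank_stat": comp.logrank_stat,
                "logrank_p": comp.logrank_p,
                "c_index": comp.c_index,
                "beta": beta,
                "amplitude": a_opt,
            }, indent=2))
            _record(manifest, "predict", outdir,
                    [outdir / "survival.tsv", outdir / "survival_stats.json"],
                    {"beta": beta, "amplitude": a_opt})

        if "treat" in stages:
            log.info("stage treat")
            load_potential()
            from .treatment import circuit_treatment
            params = potentials.CircuitParams.reference()
            out = {}
            base = potentials.find_critical_points(
                lambda b: potentials.effective_force(
                    b, params.s_max, params.with_(s=params.s_max)),
                np.linspace(0, 2 * params.x0_b_on_a, 2049))
            out["untreated"] = {"critical_points": base.locations.tolist(),
                                "stable": base.stable.tolist()}
            for kind in ("TOTO", "TKI"):
                treated = circuit_treatment(params.with_(s=params.s_max), kind)
                cps = potentials.find_critical_points(
                    lambda b: potentials.effective_force(b, treated.s, treated),
                    np.linspace(0, 2 * params.x0_b_on_a, 2049))
                out[kind] = {"critical_points": cps.locations.tolist(),
                             "stable": cps.stable.tolist(),
                             "signal": treated.s,
                             "gamma": treated.gamma_circuit}
            (outdir / "treatment_circuit.json").write_text(
                json.dumps(out, indent=2))
            _record(manifest, "treat", outdir,
                    [outdir / "treatment_circuit.json"])

        if "calibrate" in stages:
            log.info("stage calibrate")
            load_potential()
            ccfg = config["calibrate"]
            if potential.kind != "quintic":
                log.warning("calibrate skipped: treatment gradients need a "
                            "quintic landscape, fitted kind is %s",
                            potential.kind)
                manifest["stages"]["calibrate"] = {
                    "files": {}, "params": {"skipped": potential.kind}}
                ccfg = None
        if "calibrate" in stages and ccfg is not None:
            cohort = ccfg.get("cohort", "TOTO")
            pool = coords_treat if cohort in ("TOTO", "TKI") else coords
            sub = pool[pool.cohort == cohort]
            observed = {m: (g.sort_values("week").week.to_numpy(),
                            g.sort_values("week").coordinate.to_numpy())
                        for m, g in sub.groupby("mouse")}
            template = (TreatmentSchedule.toto() if cohort == "TOTO"
                        else TreatmentSchedule.tki())
            res = calibration.grid_search(
                observed, potential, template,
                resolution=tuple(ccfg["resolution"]), reps=ccfg["reps"],
                seed=seed, dt=ccfg["dt"])
            surf = pd.DataFrame(
                [(g, b, res.msd[i, j])
                 for i, g in enumerate(res.gamma_grid)
                 for j, b in enumerate(res.beta_grid)],
                columns=["gamma", "beta", "msd"])
            surf.to_csv(outdir / "msd_surface.tsv", sep="\t", index=False)
            (outdir / "calibration.json").write_text(json.dumps({
                "cohort": cohort, "gamma_opt": res.gamma_opt,
                "beta_opt": res.beta_opt,
                "on_boundary": res.on_boundary}, indent=2))
            _record(manifest, "calibrate", outdir,
                    [outdir / "msd_surface.tsv", outdir / "calibration.json"],
                    {"resolution": ccfg["resolution"], "reps": ccfg["reps"]})

        if "genes" in stages:
            log.info("stage genes")
            load_potential()
            need_data()
            gcfg = config["genes"]
            assigned = gene_analysis.assign_disease_states(
                coords, potential, table, allow_degraded=True)
            assigned.drop(columns=["boundaries"]).to_csv(
                outdir / "disease_states.tsv", sep="\t")
            # limit the DE engine to the most variable genes for tractability
            normed = statespace.normalize_expression(counts)
            nvar = normed.var(axis=1).nlargest(
                min(gcfg["max_genes_de"], len(normed))).index
            sub_counts = counts.loc[nvar]
            hs = assigned.index[assigned.state == "Hs"]
            de_tables, uniq = {}, {}
            for state in ("Es", "Ts", "Ls"):
                members = assigned.index[assigned.state == state]
                if len(members) < 2:
                    continue
                de = gene_analysis.differential_expression(
                    sub_counts, table, hs, members,
                    comparison=f"{state}_vs_Hs")
                de_tables[state] = de
            all_sig = {s: gene_analysis.significant_genes(d, gcfg["alpha"])
                       for s, d in de_tables.items()}
            for s in all_sig:
                others = set().union(*(v for k, v in all_sig.items() if k != s))
                uniq[s] = all_sig[s] - others
            pd.concat(de_tables.values()).to_csv(
                outdir / "de_tables.tsv", sep="\t")
            files = [outdir / "disease_states.tsv", outdir / "de_tables.tsv"]
            # contributions require a fitted state-space model
            if model is not None and de_tables:
                full = pd.concat(de_tables.values())
                recs, mv = gene_analysis.eigengene_contribution(
                    full[full.index.isin(model.genes)], model)
                recs.to_csv(outdir / "contributions.tsv", sep="\t")
                files.append(outdir / "contributions.tsv")
            cml_coords = coords[coords.cohort == "CML"]
            usable = {s: g for s, g in uniq.items() if len(g) >= 3}
            if usable:
                mods = gene_analysis.detect_gene_modules(
                    normed, cml_coords, usable)
                pd.DataFrame(
                    [(i, m.origin, m.median_r, m.direction, g)
                     for i, m in enumerate(mods) for g in m.genes],
                    columns=["module", "origin", "median_r", "direction",
                             "gene"]).to_csv(outdir / "modules.tsv",
                                             sep="\t", index=False)
                files.append(outdir / "modules.tsv")
            degs = set().union(*all_sig.values()) if all_sig else set()
            if degs and potential.kind == "quintic":
                drivers = gene_analysis.find_transition_drivers(
                    normed, cml_coords, potential, sorted(degs))
                drivers.to_csv(outdir / "drivers.tsv", sep="\t", index=False)
                files.append(outdir / "drivers.tsv")
            _record(manifest, "genes", outdir, files,
                    {"max_genes_de": gcfg["max_genes_de"]})
    except Exception as exc:
        manifest["failed_stage"] = getattr(exc, "_stage", "unknown")
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
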