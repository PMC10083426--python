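"""End-to-end pipeline: simulate -> QC -> GRM -> BLUEs -> fits -> CV -> selection.

A single flat key-value config (YAML) drives all stages; the seed is
mandatory and every stage derives its randomness from it.  Each run writes a
JSON manifest listing every artifact with a SHA-256 content hash, so reruns
with the same config are verifiably identical.  Logging goes to stderr; the
manifest path is printed to stdout.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cv as cv_mod
from . import indices, io, qc, reml, sim, spatial

ALL_STAGES = ("simulate", "qc", "grm", "blues", "fit", "cv", "select")

DEFAULTS = {
    "n_lines": 100,
    "n_markers": 500,
    "n_sites": 3,
    "n_reps": 2,
    "missing_rate": 0.05,
    "max_missing": 0.5,
    "min_maf": 0.01,
    "impute": "mean",
    "spatial_grid_step": 0.1,
    "spatial_grid_limit": 0.6,
    "target": "GY",
    "secondary": "PH",
    "oil": "OL",
    "cv_k": 5,
    "cv_repeats": 2,
    "selection_fraction": 0.2,
    "write_vcf": False,
}


@dataclass
class RunConfig:
    seed: int
    outdir: Path
    stages: tuple[str, ...] = ALL_STAGES
    options: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path, overrides: dict | None = None) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError("config must be a flat key-value mapping")
        raw.update({k: v for k, v in (overrides or {}).items() if v is not None})
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        if "seed" not in raw:
            raise ValueError("config is missing the mandatory 'seed'")
        seed = int(raw["seed"])
        outdir = Path(raw.get("outdir", "safgp_run"))
        stages = raw.get("stages", "all")
        if stages in ("all", None):
            stages = ALL_STAGES
        elif isinstance(stages, str):
            stages = tuple(s.strip() for s in stages.split(","))
        unknown = set(stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        opts = dict(DEFAULTS)
        opts.update({k: v for k, v in raw.items() if k in DEFAULTS})
        if not 0 <= float(opts["max_missing"]) <= 1:
            raise ValueError("max_missing must be in [0, 1]")
        if not 0 < float(opts["selection_fraction"]) <= 1:
            raise ValueError("selection_fraction must be in (0, 1]")
        return cls(seed, outdir, tuple(stages), opts)


def _log(stage: str, msg: str, t0: float) -> None:
    print(f"[safgp:{stage}] {msg} ({time.perf_counter() - t0:.1f}s)", file=sys.stderr)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in dependency order; return the manifest."""
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    o = config.options
    t0 = time.perf_counter()
    artifacts: dict[str, Path] = {}
    manifest = {"seed": config.seed, "stages": list(config.stages), "files": {}}

    params = sim.scaled_params(
        config.seed,
        n_lines=int(o["n_lines"]),
        n_markers=int(o["n_markers"]),
        n_sites=int(o["n_sites"]),
        n_reps=int(o["n_reps"]),
        missing_rate=float(o["missing_rate"]),
    )
    target, secondary, oil = o["target"], o["secondary"], o["oil"]

    geno = effects = trial = None
    if "simulate" in config.stages:
        geno = sim.simulate_genotypes(params)
        effects = sim.simulate_true_effects(geno, params)
        trial = sim.simulate_trial(geno, effects, params)
        io.write_dosage_tsv(geno, out / "genotypes.tsv")
        artifacts["genotypes"] = out / "genotypes.tsv"
        if o["write_vcf"]:
            io.write_vcf(geno, out / "genotypes.vcf")
            artifacts["genotypes_vcf"] = out / "genotypes.vcf"
        io.write_trial_csv(trial, out / "trial.csv")
        artifacts["trial"] = out / "trial.csv"
        eff = effects.g_frame()
        eff.to_csv(out / "true_effects.csv", index_label="accession")
        artifacts["true_effects"] = out / "true_effects.csv"
        _log("simulate", f"{params.n_lines} lines x {params.n_markers} markers, "
             f"{params.n_sites} sites", t0)
    else:
        geno = io.read_dosage_tsv(out / "genotypes.tsv")
        trial = io.read_trial_csv(out / "trial.csv")

    filtered = None
    if "qc" in config.stages:
        stats = qc.compute_marker_stats(geno)
        filtered = qc.filter_markers(geno, float(o["max_missing"]), float(o["min_maf"]))
        method = {"mean": "mean_dosage", "knn": "knn"}.get(o["impute"], "none")
        if method != "none":
            filtered = qc.impute_missing(filtered, method=method)
        report = {
            "markers_in": geno.n_markers,
            "markers_out": filtered.n_markers,
            "removed": geno.n_markers - filtered.n_markers,
            "max_missing": float(o["max_missing"]),
            "min_maf": float(o["min_maf"]),
            "impute": o["impute"],
        }
        (out / "qc_report.json").write_text(json.dumps(report, indent=1))
        artifacts["qc_report"] = out / "qc_report.json"
        io.write_dosage_tsv(filtered, out / "genotypes_filtered.tsv")
        artifacts["genotypes_filtered"] = out / "genotypes_filtered.tsv"
        _log("qc", f"{report['markers_out']}/{report['markers_in']} markers kept", t0)

    grm = None
    if "grm" in config.stages:
        if filtered is None:
            filtered = io.read_dosage_tsv(out / "genotypes_filtered.tsv")
        grm = qc.condition_grm(qc.vanraden_grm(filtered))
        io.write_grm_tsv(grm, out / "grm.tsv")
        artifacts["grm"] = out / "grm.tsv"
        _log("grm", f"{grm.n} x {grm.n} VanRaden GRM", t0)

    blues = None
    if "blues" in config.stages:
        traits = [t for t in (target, secondary, oil) if t in trial.columns]
        blues, fits = spatial.fit_site_blues(
            trial, traits,
            grid_step=float(o["spatial_grid_step"]),
            grid_limit=float(o["spatial_grid_limit"]),
        )
        blues.to_csv(out / "blues.csv", index=False)
        artifacts["blues"] = out / "blues.csv"
        (out / "spatial_fits.json").write_text(
            json.dumps([f.__dict__ for f in fits], indent=1)
        )
        artifacts["spatial_fits"] = out / "spatial_fits.json"
        _log("blues", f"{len(fits)} trial/trait spatial fits", t0)

    comps_by_site: dict[tuple[str, str], reml.VarianceComponents] = {}
    gebv_frames = []
    mt_store = {}
    if "fit" in config.stages:
        if blues is None:
            blues = pd.read_csv(out / "blues.csv")
        if grm is None:
            grm = io.read_grm_tsv(out / "grm.tsv")
        sites = list(blues["site"].unique())
        components_out = {}
        for site in sites:
            for tr in (target, oil):
                sub = blues[(blues["site"] == site) & (blues["trait"] == tr)]
                comps, gebv = reml.fit_univariate(sub, grm)
                comps_by_site[(site, tr)] = comps
                g = gebv.assign(site=site, model="UV", trait=tr)
                gebv_frames.append(g)
                components_out[f"uv_{site}_{tr}"] = {
                    "sigma2_A": comps.sigma2_A, "sigma2_e": comps.sigma2_e,
                    "h2": comps.h2, "log_likelihood": comps.log_likelihood,
                }
        first = sites[0]
        for pair in ((target, secondary), (target, oil)):
            sub = blues[(blues["site"] == first) & (blues["trait"].isin(pair))]
            mt, gebv, corrs = reml.fit_multitrait(sub, grm, traits=list(pair))
            mt_store[pair] = mt
            gebv_frames.append(gebv.assign(site=first, model="MT"))
            components_out[f"mt_{first}_{'_'.join(pair)}"] = {
                "traits": mt.traits, "T": mt.T, "R": mt.Rres,
                "h2": {t: mt.h2(t) for t in mt.traits},
                "r_A": corrs[0].r_A, "r_P": corrs[0].r_P,
                "log_likelihood": mt.log_likelihood,
            }
        for tr in (target, oil):
            gx, gebv = reml.fit_gxe(blues, grm, trait=tr)
            gebv_frames.append(gebv.assign(model="gxE"))
            components_out[f"gxe_{tr}"] = gx
        io.write_components_json(components_out, out / "components.json")
        artifacts["components"] = out / "components.json"
        gebvs = pd.concat(gebv_frames, ignore_index=True)
        gebvs.to_csv(out / "gebvs.csv", index=False)
        artifacts["gebvs"] = out / "gebvs.csv"
        _log("fit", f"{len(components_out)} model fits", t0)

    if "cv" in config.stages:
        if blues is None:
            blues = pd.read_csv(out / "blues.csv")
        if grm is None:
            grm = io.read_grm_tsv(out / "grm.tsv")
        first = list(blues["site"].unique())[0]
        site_blues = blues[blues["site"] == first]
        wide = site_blues.pivot_table(index="accession", columns="trait",
                                      values="estimate", aggfunc="first")
        wide = wide.dropna(subset=[target])
        plan = cv_mod.make_folds(list(wide.index), k=int(o["cv_k"]),
                                 repeats=int(o["cv_repeats"]), seed=config.seed)
        results = []
        uv = cv_mod.run_cv(site_blues, grm, plan, "UV", "CV1", target, [])
        results.append(("UV", "UV", uv))
        for scen in ("CV1", "CV2"):
            mt = cv_mod.run_cv(site_blues, grm, plan, "MT", scen, target, [secondary])
            results.append((f"MT_{secondary}", f"MT-{scen}", mt))
        detail = pd.concat(
            [r.detail.assign(site=first, model=m, scenario=s) for m, s, r in results],
            ignore_index=True,
        )
        detail.to_csv(out / "cv_accuracy.csv", index=False)
        artifacts["cv_accuracy"] = out / "cv_accuracy.csv"
        summary = pd.DataFrame(
            [
                {"site": first, "model": m, "scenario": s, "mean": r.mean, "sd": r.sd}
                for m, s, r in results
            ]
        )
        summary.to_csv(out / "cv_summary.csv", index=False)
        artifacts["cv_summary"] = out / "cv_summary.csv"
        _log("cv", "; ".join(f"{m}/{s}: {r.mean:.3f}" for m, s, r in results), t0)

    if "select" in config.stages:
        if blues is None:
            blues = pd.read_csv(out / "blues.csv")
        if grm is None:
            grm = io.read_grm_tsv(out / "grm.tsv")
        frac = float(o["selection_fraction"])
        sites = list(blues["site"].unique())
        if gebv_frames:
            gebvs = pd.concat(gebv_frames, ignore_index=True)
        else:
            gebvs = pd.read_csv(out / "gebvs.csv")
        if not comps_by_site:
            for s in sites:
                sub = blues[(blues["site"] == s) & (blues["trait"] == target)]
                comps_by_site[(s, target)], _ = reml.fit_univariate(sub, grm)
        blue_by_site = {
            s: blues[(blues["site"] == s) & (blues["trait"] == target)]
            .set_index("accession")["estimate"]
            for s in sites
        }
        h2_by_site = {s: comps_by_site[(s, target)].h2 for s in sites}
        reports = []
        for sel_site in sites:
            scores = {}
            scores["PS"] = blue_by_site[sel_site]
            uv_g = gebvs[(gebvs["model"] == "UV") & (gebvs["site"] == sel_site)
                         & (gebvs["trait"] == target)]
            scores["SGS"] = uv_g.set_index("accession")["gebv"]
            for label, sc in scores.items():
                reports += indices.cross_site_response(
                    sel_site, sc, blue_by_site, h2_by_site, frac,
                    index_label=label, trait=target,
                )
        # g x E main-effect GEBVs: one shared ranking evaluated everywhere
        gx_g = gebvs[(gebvs["model"] == "gxE") & (gebvs["trait"] == target)
                     & (gebvs["site"].isna())]
        reports += indices.cross_site_response(
            "combined", gx_g.set_index("accession")["gebv"], blue_by_site,
            h2_by_site, frac, index_label="gxEGS", trait=target,
        )
        rep_df = indices.reports_frame(reports)
        rep_df.to_csv(out / "selection_report.csv", index=False)
        artifacts["selection_report"] = out / "selection_report.csv"
        _log("select", f"{len(rep_df)} selection responses", t0)

    for name, path in artifacts.items():
        manifest["files"][name] = {"path": str(path), "sha256": _sha256(path)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    print(str(out / "manifest.json"))
    return manifest
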