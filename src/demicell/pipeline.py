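"""End-to-end orchestration: synthesize -> detect -> project -> classify -> fit.

A run is driven by a flat config mapping with one section per stage plus a
global seed.  Stages communicate through files in the output directory, so a
single stage can be re-run against cached upstream outputs.  Every run emits
a manifest listing each artifact with its SHA-256 checksum.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import cellmap, clusters, io, kinetics, seqbias, spots, synthdata
from .errors import ParameterError

__all__ = ["DEFAULT_CONFIG", "run_all", "stage_seed"]

logger = logging.getLogger("demicell.pipeline")

STAGES = ("scene", "detect", "project", "classify", "chase", "kinetics", "seqbias")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": list(STAGES),
    "scene": {"n_cells": 36, "pattern": "polar_cluster", "spots_per_cell": 4.0},
    "detect": {"threshold_sd": 5.0, "window_halfsize": 7},
    "project": {"bin_nm": 25.0, "smoothing_nm": 50.0},
    "classify": {"min_intensity_fraction": 0.5, "max_fwhm_px": 5.0, "polar_v_fraction": 0.6},
    "chase": {
        "n_cells_per_timepoint": 500,
        "cell_noise_cv": 0.3,
        "subpopulations": [
            {"label": "no_cluster", "weight": 0.5, "half_life_min": 4.6, "cluster": False},
            {"label": "cluster", "weight": 0.5, "half_life_min": 16.1, "cluster": True},
        ],
    },
    "kinetics": {"n_rounds": 5, "n_cells_per_round": 500},
    "seqbias": {"fasta": None, "classes_csv": None, "n_per_class": 50, "n_codons": 200},
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _merge(defaults: dict, override: dict | None) -> dict:
    out = dict(defaults)
    out.update(override or {})
    return out


def _require(outdir: Path, name: str, stage: str) -> Path:
    path = outdir / name
    if not path.exists():
        raise ParameterError(f"stage {stage!r} needs missing upstream output {name}")
    return path


def run_all(config: dict | None = None, outdir: str | Path = "demicell_run") -> dict:
    """Execute the enabled stages in dependency order; return the manifest.

    The manifest maps stage name -> {file name -> sha256} and records the
    global seed.  Failures abort with a stage-labelled error.
    """
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    seed = int(cfg["seed"])
    enabled = list(cfg.get("stages", STAGES))
    unknown = set(enabled) - set(STAGES)
    if unknown:
        raise ParameterError(f"unknown stage(s): {sorted(unknown)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "stages": {}}

    def emit(stage: str, *names: str) -> None:
        manifest["stages"][stage] = {n: _sha256(outdir / n) for n in names}

    for stage in STAGES:
        if stage not in enabled:
            continue
        logger.info("running stage %s", stage)
        try:
            if stage == "scene":
                sc = _merge(DEFAULT_CONFIG["scene"], cfg.get("scene"))
                spec = synthdata.SceneSpec(seed=stage_seed(seed, "scene"), **sc)
                image, truth = synthdata.generate_scene(spec)
                io.write_image(outdir / "scene.tif", image)
                io.write_csv(truth.cells, outdir / "truth_cells.csv", {"seed": spec.seed})
                io.write_csv(truth.spots, outdir / "truth_spots.csv", {"seed": spec.seed})
                emit(stage, "scene.tif", "truth_cells.csv", "truth_spots.csv")

            elif stage == "detect":
                dc = _merge(DEFAULT_CONFIG["detect"], cfg.get("detect"))
                image = io.read_image(_require(outdir, "scene.tif", stage))
                contours = io.read_contours(_require(outdir, "truth_cells.csv", stage))
                det = spots.DetectionConfig(**dc)
                table = spots.quantify_image(image, det)
                assigned, n_out = spots.assign_spots_to_cells(table, contours)
                io.write_csv(assigned, outdir / "spots.csv",
                             {"seed": seed, "n_discarded_outside": n_out})
                emit(stage, "spots.csv")

            elif stage == "project":
                pc = _merge(DEFAULT_CONFIG["project"], cfg.get("project"))
                table = io.read_csv(_require(outdir, "spots.csv", stage))
                contours = io.read_contours(_require(outdir, "truth_cells.csv", stage))
                norm = cellmap.normalize_spots(table, contours)
                io.write_csv(norm, outdir / "norm_spots.csv", {"seed": seed})
                lmap = cellmap.build_location_map(norm, pc["bin_nm"], pc["smoothing_nm"])
                np.savetxt(outdir / "location_map.csv", lmap.density, delimiter=",")
                prof = cellmap.axial_profile(lmap)
                io.write_csv(prof, outdir / "axial_profile.csv", {"seed": seed})
                zf = cellmap.zone_fractions(norm).rename("fraction").rename_axis("zone")
                io.write_csv(zf.reset_index(), outdir / "zone_fractions.csv", {"seed": seed})
                emit(stage, "norm_spots.csv", "location_map.csv", "axial_profile.csv",
                     "zone_fractions.csv")

            elif stage == "classify":
                cc = _merge(DEFAULT_CONFIG["classify"], cfg.get("classify"))
                norm = io.read_csv(_require(outdir, "norm_spots.csv", stage))
                totals = norm.groupby("cell_id")["I"].sum()
                conf = clusters.ClusterConfig(**cc)
                calls = clusters.classify_cells(norm, totals, conf)
                io.write_csv(calls, outdir / "classification.csv", {"seed": seed})
                frac = clusters.cluster_fraction_by_level(calls, config=conf)
                io.write_csv(frac, outdir / "fraction_by_level.csv", {"seed": seed})
                emit(stage, "classification.csv", "fraction_by_level.csv")

            elif stage == "chase":
                ch = _merge(DEFAULT_CONFIG["chase"], cfg.get("chase"))
                subpops = tuple(
                    synthdata.Subpopulation(**sp) for sp in ch.pop("subpopulations")
                )
                spec = synthdata.ChaseSpec(
                    subpopulations=subpops, seed=stage_seed(seed, "chase"), **ch
                )
                chase = synthdata.generate_chase(spec)
                io.write_csv(chase, outdir / "chase.csv", {"seed": spec.seed})
                emit(stage, "chase.csv")

            elif stage == "kinetics":
                kc = _merge(DEFAULT_CONFIG["kinetics"], cfg.get("kinetics"))
                chase = io.read_csv(_require(outdir, "chase.csv", stage))
                bconf = kinetics.BootstrapConfig(
                    kc["n_rounds"], kc["n_cells_per_round"], seed=stage_seed(seed, "kinetics")
                )
                result = {"pooled": _fit_to_dict(kinetics.estimate_half_life(chase, bconf))}
                if chase["cluster_flag"].nunique() > 1:
                    strata = kinetics.stratified_half_lives(chase, bconf)
                    for flag, fit in strata.items():
                        key = "cluster" if flag else "no_cluster"
                        result[key] = _fit_to_dict(fit)
                io.write_json({"seed": seed, "fits": result}, outdir / "kinetics.json")
                emit(stage, "kinetics.json")

            elif stage == "seqbias":
                qc = _merge(DEFAULT_CONFIG["seqbias"], cfg.get("seqbias"))
                if qc.get("fasta"):
                    records = seqbias.load_records(qc["fasta"], qc.get("classes_csv"))
                else:
                    records = seqbias.generate_records(
                        n_per_class=qc["n_per_class"], n_codons=qc["n_codons"],
                        seed=stage_seed(seed, "seqbias"),
                    )
                dens = pd.DataFrame(
                    [
                        dict(gene_id=r.gene_id, gene_class=r.gene_class,
                             uracil_density=seqbias.uracil_density(r))
                        for r in records
                    ]
                )
                io.write_csv(dens, outdir / "uracil_density.csv", {"seed": seed})
                bias = seqbias.codon_bias(records)
                io.write_csv(bias.table, outdir / "codon_bias.csv", {"seed": seed})
                io.write_json(seqbias.compare_classes(records), outdir / "class_comparison.json")
                emit(stage, "uracil_density.csv", "codon_bias.csv", "class_comparison.json")
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    io.write_json(manifest, outdir / "manifest.json")
    return manifest


def _fit_to_dict(fit: kinetics.DecayFit) -> dict:
    return dict(
        n0=fit.n0,
        lam=fit.lam,
        t_half_min=fit.t_half,
        bootstrap_sd=None if np.isnan(fit.bootstrap_sd) else fit.bootstrap_sd,
        rmse=fit.rmse,
        non_decaying=fit.non_decaying,
    )
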