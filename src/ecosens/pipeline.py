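"""End-to-end orchestration: simulate -> mask -> sensitivity -> imputation
-> biodiversity -> SAR, with manifests and checksum-guarded stage reruns.

CSV is the interchange format between stages; trees travel as newick. Every
row dropped anywhere (EVI mask, degenerate series, undefined SES, small
biomes, non-finite weights) is accounted for in the run manifest.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import biodiversity as bio
from . import sensitivity as sens
from . import spatial_model as sar
from . import synthetic as syn
from . import trait_imputation as imp
from . import trees as treemod
from .config import PipelineConfig
from .exceptions import InputError
from .trees import TreeIndex


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_guard(outdir: Path, stage: str, inputs: List[Path],
                 outputs: List[Path]) -> bool:
    """True if the stage can be skipped (inputs unchanged, outputs present)."""
    marker = outdir / f".{stage}.inputs.json"
    digest = {str(p): _sha256(p) for p in inputs if p.exists()}
    if marker.exists() and all(p.exists() for p in outputs):
        try:
            if json.loads(marker.read_text()) == digest:
                return True
        except json.JSONDecodeError:
            pass
    marker.write_text(json.dumps(digest, indent=0, sort_keys=True))
    return False


# ---------------------------------------------------------------------------
# stages

def stage_simulate(config: PipelineConfig, outdir: Path) -> Dict[str, str]:
    bundle = syn.generate_all(config.synthetic)
    fails = syn.validate_bundle(bundle)
    if fails:
        raise InputError("synthetic bundle failed validation: " + "; ".join(fails))
    return syn.write_bundle(bundle, outdir)


def stage_sensitivity(config: PipelineConfig, outdir: Path) -> Dict[str, int]:
    grid_path = outdir / "grid_series.csv"
    outs = [outdir / "sensitivity.csv", outdir / "limiting_factor.csv",
            outdir / "mask_report.csv"]
    if _stage_guard(outdir, "sensitivity", [grid_path], outs):
        return {"skipped": 1}
    grid = syn.GridData.from_long_frame(pd.read_csv(grid_path))
    report = sens.mask_low_evi(grid)
    table, dropped = sens.estimate_sensitivity(grid, scales=list(config.scales),
                                               cells=report.retained)
    labels = sens.classify_table(table, rule=config.limiting_rule)
    table.to_csv(outs[0], index=False)
    labels.to_csv(outs[1], index=False)
    pd.DataFrame({"cell_id": np.concatenate([report.retained, report.removed]),
                  "retained": [True] * len(report.retained) + [False] * len(report.removed),
                  }).sort_values("cell_id").to_csv(outs[2], index=False)
    return {"cells_masked": int(len(report.removed)),
            "cells_fit": int(table["cell_id"].nunique()),
            "degenerate_cells": len(dropped)}


def stage_impute(config: PipelineConfig, outdir: Path) -> Dict[str, int]:
    traits_path, trees_path = outdir / "traits.csv", outdir / "trees.nwk"
    outs = [outdir / "traits_imputed.csv", outdir / "traits_provenance.csv",
            outdir / "clamp_log.csv"]
    if _stage_guard(outdir, "impute", [traits_path, trees_path], outs):
        return {"skipped": 1}
    traits = pd.read_csv(traits_path, index_col="species")
    tree_set = treemod.read_newick_list(trees_path)
    mcc = bio.mcc_tree(tree_set)
    pe = imp.phylo_eigenvectors(
        mcc,
        variance_threshold=config.pe_variance_threshold,
        n_fixed=config.pe_fixed_count if config.pe_retention == "fixed" else None)
    result = imp.impute_traits(traits, pe)
    result.values.rename_axis("species").to_csv(outs[0])
    result.provenance.rename_axis("species").to_csv(outs[1])
    pd.DataFrame(result.clamp_log,
                 columns=["species", "trait", "raw", "clamped"]).to_csv(
        outs[2], index=False)
    return {"n_imputed": int((result.provenance == "imputed").sum().sum()),
            "n_clamped": len(result.clamp_log),
            "converged": int(result.converged)}


def stage_biodiversity(config: PipelineConfig, outdir: Path) -> Dict[str, int]:
    ins = [outdir / "presence.csv", outdir / "trees.nwk",
           outdir / "traits_imputed.csv", outdir / "biomes.csv"]
    outs = [outdir / "biodiversity_metrics.csv", outdir / "trait_space.csv"]
    if _stage_guard(outdir, "biodiversity", ins, outs):
        return {"skipped": 1}
    presence = pd.read_csv(ins[0], index_col="species")
    presence.columns = presence.columns.astype(int)
    tree_set = treemod.read_newick_list(ins[1])
    mcc = bio.mcc_tree(tree_set)
    traits = pd.read_csv(ins[2], index_col="species")
    biomes = pd.read_csv(ins[3])
    space = bio.trait_space_pca(traits)
    metrics = bio.assemblage_metrics(presence, mcc, space)
    index = TreeIndex.from_dendropy(mcc)
    kwargs = dict(n_reps=config.n_null_reps, seed=config.seed,
                  pool=config.null_pool,
                  biomes=biomes if config.null_pool == "biome" else None)
    ses_pd = bio.ses_null_model("pd", presence, index, **kwargs)
    ses_fric = bio.ses_null_model("fric", presence, space, **kwargs)
    metrics = (metrics
               .merge(ses_pd[["cell_id", "ses", "reason"]]
                      .rename(columns={"ses": "ses_pd", "reason": "ses_pd_reason"}),
                      on="cell_id")
               .merge(ses_fric[["cell_id", "ses", "reason"]]
                      .rename(columns={"ses": "ses_fric", "reason": "ses_fric_reason"}),
                      on="cell_id")
               .merge(biomes, on="cell_id"))
    metrics.to_csv(outs[0], index=False)
    space.coordinates.rename_axis("species").to_csv(outs[1])
    return {"cells": len(metrics),
            "undefined_ses": int(metrics["ses_pd"].isna().sum()
                                 + metrics["ses_fric"].isna().sum()),
            "trait_axes": int(space.n_retained)}


def stage_sar(config: PipelineConfig, outdir: Path) -> Dict[str, object]:
    ins = [outdir / "biodiversity_metrics.csv", outdir / "sensitivity.csv",
           outdir / "limiting_factor.csv", outdir / "grid_series.csv"]
    if _stage_guard(outdir, "sar", ins,
                    [outdir / f"sar_{v}_{s}.csv"
                     for s in config.scales for v in config.climate_vars]):
        return {"skipped": 1}
    metrics = pd.read_csv(ins[0])
    sensitivity = pd.read_csv(ins[1])
    limiting = pd.read_csv(ins[2])
    cells = pd.read_csv(ins[3], usecols=["cell_id", "row", "col"]).drop_duplicates()
    metrics = metrics.merge(cells, on="cell_id")
    info: Dict[str, object] = {}
    fit_manifest = {}
    for scale in config.scales:
        for var in config.climate_vars:
            design = sar.assemble_design(
                metrics, sensitivity, limiting, scale, var,
                min_biome_cells=config.min_biome_cells,
                standardize_response=config.standardize_response)
            weights = sar.build_weights(design.coords,
                                        config.candidate_distances, design.y,
                                        cell_ids=design.cell_ids)
            if weights.isolated.any():
                keep = ~weights.isolated
                design.drop_log["isolated_cells"] = design.cell_ids[~keep].tolist()
                design = sar.DesignSpec(
                    y=design.y[keep], X=design.X[keep].reset_index(drop=True),
                    obs_weights=design.obs_weights[keep],
                    cell_ids=design.cell_ids[keep], coords=design.coords[keep],
                    scale=scale, climate_var=var, drop_log=design.drop_log)
                weights = sar.build_weights(design.coords,
                                            [weights.band_distance], design.y,
                                            cell_ids=design.cell_ids)
            fit = sar.fit_sar_error(design.y, design.X, design.obs_weights, weights)
            tag = f"{var}_{scale}"
            fit.coef_table().to_csv(outdir / f"sar_{tag}.csv", index=False)
            weights.scan_table.to_csv(outdir / f"weights_scan_{tag}.csv", index=False)
            fit_manifest[tag] = {
                "lambda": fit.lam, "loglik": fit.loglik, "n": fit.n,
                "converged": fit.converged, "boundary_flag": fit.boundary_flag,
                "band_distance": weights.band_distance,
                "dropped": {k: len(v) for k, v in design.drop_log.items()},
            }
            info[tag] = fit_manifest[tag]
    with open(outdir / "sar_fits.json", "w") as fh:
        json.dump(fit_manifest, fh, indent=2, sort_keys=True)
    return info


def run_pipeline(config: PipelineConfig, outdir) -> Dict[str, object]:
    """Run every stage in order; returns the run manifest (also written to
    ``run_manifest.json``)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: Dict[str, object] = {"config": config.to_jsonable(),
                                   "seed": config.seed, "stages": {}}
    manifest["stages"]["simulate"] = {"files": sorted(
        Path(p).name for p in stage_simulate(config, out).values())}
    manifest["stages"]["sensitivity"] = stage_sensitivity(config, out)
    manifest["stages"]["impute"] = stage_impute(config, out)
    manifest["stages"]["biodiversity"] = stage_biodiversity(config, out)
    manifest["stages"]["sar"] = stage_sar(config, out)
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# input validation

def validate_inputs(paths: Dict[str, str]) -> Dict[str, List[str]]:
    """Machine-readable validation of externally supplied inputs.

    ``paths`` may contain grid, presence, traits, trees, biomes. Returns a
    report with a (possibly empty) failure list; never raises on content
    problems.
    """
    failures: List[str] = []
    checked: List[str] = []
    presence = traits = tree_labels = None
    if "grid" in paths:
        checked.append("grid")
        try:
            grid = syn.GridData.from_long_frame(pd.read_csv(paths["grid"]))
            if grid.evi.min() < 0 or grid.evi.max() > 1:
                failures.append("grid: EVI outside [0, 1]")
            if grid.precip.min() < 0:
                failures.append("grid: negative precipitation")
        except (InputError, KeyError, ValueError) as exc:
            failures.append(f"grid: {exc}")
    if "presence" in paths:
        checked.append("presence")
        presence = pd.read_csv(paths["presence"], index_col="species")
        vals = presence.to_numpy()
        bad = ~np.isin(vals, (0, 1))
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            failures.append(
                f"presence: non-binary entry {vals[i, j]!r} at species "
                f"{presence.index[i]!r}, cell {presence.columns[j]!r}")
    if "traits" in paths:
        checked.append("traits")
        traits = pd.read_csv(paths["traits"], index_col="species")
        if traits.isna().all(axis=0).any():
            failures.append("traits: a trait has no observed values")
    if "trees" in paths:
        checked.append("trees")
        tree_set = treemod.read_newick_list(paths["trees"])
        sets = {treemod.tip_label_set(t) for t in tree_set}
        if len(sets) > 1:
            failures.append("trees: members have different tip sets")
        tree_labels = set().union(*sets) if sets else set()
    if tree_labels is not None and traits is not None:
        diff = set(traits.index) ^ tree_labels
        if diff:
            failures.append(f"label mismatch tree vs traits: {sorted(diff)[:5]}")
    if tree_labels is not None and presence is not None:
        diff = set(presence.index) ^ tree_labels
        if diff:
            failures.append(f"label mismatch tree vs presence: {sorted(diff)[:5]}")
    if "biomes" in paths and "grid" in paths:
        checked.append("biomes")
        biomes = pd.read_csv(paths["biomes"])
        grid_cells = set(pd.read_csv(paths["grid"], usecols=["cell_id"])["cell_id"])
        if grid_cells - set(biomes["cell_id"]):
            failures.append("biomes: labels do not cover all grid cells")
    return {"checked": checked, "failures": failures}
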