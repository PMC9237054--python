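"""Synthetic study system with known ground truth.

Emulates every input of the analysis at desk scale: gridded monthly climate
(latitudinal baseline + seasonal cycle + trend + noise), a vegetation index
built from known per-cell sensitivity coefficients, spatially coherent
species ranges (discs on the lattice), an ultrametric pure-birth phylogeny
plus an NNI-perturbed tree set, Brownian-motion traits with controllable
phylogenetic signal and missingness, and latitudinal biome bands.

Everything is deterministic under ``(seed, config)``; each generator draws
from its own named stream of the global seed.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import dendropy
import numpy as np
import pandas as pd
from scipy import ndimage

from . import trees as treemod
from .config import (STREAM_BETA, STREAM_CLIMATE, STREAM_EVI, STREAM_PHYLO,
                     STREAM_RANGES, STREAM_TRAITS, SyntheticConfig,
                     int_seed_for, rng_for)
from .exceptions import ConfigurationError, InputError

BIOME_NAMES = ["tundra", "taiga", "temperate_mixed", "grassland",
               "subtropical_dry", "tropical_forest"]


# ---------------------------------------------------------------------------
# containers

@dataclass
class GridData:
    """Aligned per-cell monthly series. Arrays are (n_cells, n_months)."""

    cell_ids: np.ndarray
    row: np.ndarray
    col: np.ndarray
    evi: np.ndarray
    temp: np.ndarray
    precip: np.ndarray
    n_years: int

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_months(self) -> int:
        return self.evi.shape[1]

    def to_long_frame(self) -> pd.DataFrame:
        m = self.n_months
        month_idx = np.arange(m)
        recs = {
            "cell_id": np.repeat(self.cell_ids, m),
            "row": np.repeat(self.row, m),
            "col": np.repeat(self.col, m),
            "year": np.tile(month_idx // 12, self.n_cells),
            "month": np.tile(month_idx % 12 + 1, self.n_cells),
            "evi": self.evi.ravel(),
            "temp": self.temp.ravel(),
            "precip": self.precip.ravel(),
        }
        return pd.DataFrame(recs)

    @classmethod
    def from_long_frame(cls, df: pd.DataFrame) -> "GridData":
        need = {"cell_id", "row", "col", "year", "month", "evi", "temp", "precip"}
        missing = need - set(df.columns)
        if missing:
            raise InputError(f"grid series table missing columns {sorted(missing)}")
        df = df.sort_values(["cell_id", "year", "month"], kind="mergesort")
        counts = df.groupby("cell_id").size()
        m = int(counts.iloc[0])
        if (counts != m).any() or m == 0 or m % 12:
            raise InputError("cells have unequal or non-12-multiple series lengths")
        cells = counts.index.to_numpy()
        first = df.groupby("cell_id").first()
        return cls(
            cell_ids=cells,
            row=first["row"].to_numpy(),
            col=first["col"].to_numpy(),
            evi=df["evi"].to_numpy().reshape(len(cells), m),
            temp=df["temp"].to_numpy().reshape(len(cells), m),
            precip=df["precip"].to_numpy().reshape(len(cells), m),
            n_years=m // 12,
        )


@dataclass
class ClimateGrid:
    temp: np.ndarray     # (n_cells, n_months)
    precip: np.ndarray


@dataclass
class EviResult:
    evi: np.ndarray
    beta_T_field: np.ndarray       # flattened per-cell raw coefficients
    beta_P_field: np.ndarray
    n_clamped: int


@dataclass
class TraitMatrix:
    values: pd.DataFrame        # species x trait, NaN where missing
    mask: pd.DataFrame          # True where missing
    true_values: pd.DataFrame   # complete latent values (ground truth)

    @property
    def observed_min(self) -> pd.Series:
        return self.values.min()

    @property
    def observed_max(self) -> pd.Series:
        return self.values.max()


@dataclass
class SyntheticBundle:
    config: SyntheticConfig
    grid: GridData
    presence: pd.DataFrame              # species x cell binary
    base_tree: dendropy.Tree
    tree_set: List[dendropy.Tree]
    traits: TraitMatrix
    biomes: pd.DataFrame                # cell_id, biome
    beta_T_field: np.ndarray
    beta_P_field: np.ndarray
    truth: Optional[pd.DataFrame] = None  # exact standardized estimands


# ---------------------------------------------------------------------------
# climate

def _cell_grid(config: SyntheticConfig) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    rows, cols = np.divmod(np.arange(config.n_cells), config.n_cols)
    return np.arange(config.n_cells), rows, cols


def generate_climate(config: SyntheticConfig) -> ClimateGrid:
    """Monthly temperature and precipitation for every cell.

    temp = latitudinal baseline + sinusoidal seasonal cycle + linear trend
    + per-year (ENSO-like) interannual anomalies + iid monthly noise;
    precip = seasonal cycle (phase-shifted so the two cycles are not
    collinear) + year effects + noise, truncated at zero.
    """
    config.validate()
    rng = rng_for(config.seed, STREAM_CLIMATE)
    _, rows, _ = _cell_grid(config)
    m = config.n_months
    t = np.arange(m)
    season = np.sin(2 * np.pi * (t % 12) / 12.0)
    season_p = np.sin(2 * np.pi * (t % 12) / 12.0 + config.precip_phase)
    base = config.base_temp + config.lat_gradient * rows
    trend = config.trend_T * t / 120.0  # degC/decade -> per month
    year_T = np.repeat(rng.normal(0.0, config.interannual_sd_T,
                                  size=(config.n_cells, config.n_years)), 12, axis=1)
    year_P = np.repeat(rng.normal(0.0, config.interannual_sd_P,
                                  size=(config.n_cells, config.n_years)), 12, axis=1)
    temp = (base[:, None]
            + config.seasonal_amplitude_T * season[None, :]
            + trend[None, :]
            + year_T
            + rng.normal(0.0, config.noise_sd_T, size=(config.n_cells, m)))
    precip = (config.precip_mean
              + config.seasonal_amplitude_P * season_p[None, :]
              + year_P
              + rng.normal(0.0, config.noise_sd_P, size=(config.n_cells, m)))
    precip = np.clip(precip, 0.0, None)
    return ClimateGrid(temp=temp, precip=precip)


# ---------------------------------------------------------------------------
# beta fields and EVI

def make_beta_fields(config: SyntheticConfig) -> Tuple[np.ndarray, np.ndarray]:
    """True sensitivity fields on the grid (either configured, spatially
    smoothed Gaussian fields, or iid)."""
    if config.beta_T_field is not None and config.beta_P_field is not None:
        return (np.asarray(config.beta_T_field, dtype=float),
                np.asarray(config.beta_P_field, dtype=float))
    rng = rng_for(config.seed, STREAM_BETA)
    shape = (config.n_rows, config.n_cols)
    fields = []
    for mean, sd in ((config.beta_T_mean, config.beta_T_sd),
                     (config.beta_P_mean, config.beta_P_sd)):
        raw = rng.normal(0.0, 1.0, size=shape)
        if config.beta_field_mode == "smooth":
            raw = ndimage.gaussian_filter(raw, sigma=config.beta_smooth_sigma,
                                          mode="reflect")
            s = raw.std()
            if s > 0:
                raw = raw / s
        fields.append(mean + sd * raw)
    bT, bP = fields
    if config.beta_T_field is not None:
        bT = np.asarray(config.beta_T_field, dtype=float)
    if config.beta_P_field is not None:
        bP = np.asarray(config.beta_P_field, dtype=float)
    return bT, bP


def _scale_components(config: SyntheticConfig, series: np.ndarray) -> np.ndarray:
    """Return the climate component the betas act on, per beta_scale_mode.

    ``seasonal_only`` uses within-year anomalies (zero annual mean, so no
    interannual signal survives aggregation). ``interannual_only`` renders
    the year-mean series as a smooth interpolation through year midpoints:
    a piecewise-constant rendering would put year-boundary steps into the
    seasonal band, which the moving-average detrend cannot remove.
    """
    if config.beta_scale_mode == "both":
        return series
    years = config.n_years
    per_year = series.reshape(series.shape[0], years, 12)
    annual = per_year.mean(axis=2)
    if config.beta_scale_mode == "interannual_only":
        t = np.arange(series.shape[1], dtype=float)
        midpoints = 12.0 * np.arange(years) + 5.5
        return np.vstack([np.interp(t, midpoints, annual[i])
                          for i in range(series.shape[0])])
    return series - np.repeat(annual, 12, axis=1)  # within-year anomaly


def _zscore_rows(a: np.ndarray) -> np.ndarray:
    mu = a.mean(axis=1, keepdims=True)
    sd = a.std(axis=1, ddof=1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (a - mu) / sd


def _latent(config: SyntheticConfig, climate: ClimateGrid,
            bT: np.ndarray, bP: np.ndarray) -> np.ndarray:
    zt = _zscore_rows(_scale_components(config, climate.temp))
    zp = _zscore_rows(_scale_components(config, climate.precip))
    return bT.ravel()[:, None] * zt + bP.ravel()[:, None] * zp


def generate_evi(config: SyntheticConfig, climate: ClimateGrid) -> EviResult:
    """Vegetation index built from the true sensitivity fields.

    evi = evi_base + evi_scale * (beta_T z(T) + beta_P z(P) + noise),
    clamped to [0, 1]. The z-scores (and the standardized fits downstream)
    are invariant to the affine map wherever clamping does not bite.
    """
    if climate.temp.shape != (config.n_cells, config.n_months):
        raise InputError("climate arrays do not match the configured grid")
    bT, bP = make_beta_fields(config)
    if bT.shape != (config.n_rows, config.n_cols) or bP.shape != bT.shape:
        raise InputError("beta fields do not match the grid shape")
    rng = rng_for(config.seed, STREAM_EVI)
    latent = _latent(config, climate, bT, bP)
    latent = latent + rng.normal(0.0, config.evi_noise_sd, size=latent.shape)
    evi = config.evi_base + config.evi_scale * latent
    n_clamped = int(np.sum((evi < 0) | (evi > 1)))
    evi = np.clip(evi, 0.0, 1.0)
    return EviResult(evi=evi, beta_T_field=bT.ravel(), beta_P_field=bP.ravel(),
                     n_clamped=n_clamped)


def assemble_grid(config: SyntheticConfig, climate: ClimateGrid,
                  evi: EviResult) -> GridData:
    ids, rows, cols = _cell_grid(config)
    return GridData(cell_ids=ids, row=rows, col=cols, evi=evi.evi,
                    temp=climate.temp, precip=climate.precip,
                    n_years=config.n_years)


def true_sensitivity(config: SyntheticConfig, climate: ClimateGrid) -> pd.DataFrame:
    """Exact standardized estimands per cell and scale.

    The raw beta fields are identified only up to the scale normalization
    of the z-transform, so the exact ground truth for the standardized
    coefficients is obtained by pushing the *noise-free* linear construction
    through the (linear) estimator on the same climate realization. This is
    closed-form evaluation, not a fit to noisy data.
    """
    from . import sensitivity as sens

    bT, bP = make_beta_fields(config)
    latent = _latent(config, climate, bT, bP)
    evi0 = config.evi_base + config.evi_scale * latent  # no noise, no clamp
    ids, rows, cols = _cell_grid(config)
    grid = GridData(cell_ids=ids, row=rows, col=cols, evi=evi0,
                    temp=climate.temp, precip=climate.precip,
                    n_years=config.n_years)
    table, _ = sens.estimate_sensitivity(grid)
    return table[["cell_id", "scale", "beta_T", "beta_P"]].rename(
        columns={"beta_T": "beta_T_true", "beta_P": "beta_P_true"})


# ---------------------------------------------------------------------------
# species ranges

def generate_ranges(config: SyntheticConfig) -> pd.DataFrame:
    """Species x cell binary presence from random discs.

    Centres are biased equatorward (towards row 0) when
    ``richness_gradient > 0``; radii are Gamma-distributed around
    ``range_radius_mean``; every species keeps at least its centre cell.
    """
    config.validate()
    rng = rng_for(config.seed, STREAM_RANGES)
    n_r, n_c = config.n_rows, config.n_cols
    rows_axis = np.arange(n_r)
    if config.richness_gradient != 0 and n_r > 1:
        w = np.exp(-config.richness_gradient * rows_axis / (n_r - 1))
    else:
        w = np.ones(n_r)
    w = w / w.sum()
    species = [f"s{i:04d}" for i in range(config.n_species)]
    rr, cc = np.divmod(np.arange(config.n_cells), n_c)
    incidence = np.zeros((config.n_species, config.n_cells), dtype=np.int8)
    for i in range(config.n_species):
        crow = rng.choice(n_r, p=w) + rng.uniform(-0.5, 0.5)
        ccol = rng.uniform(-0.5, n_c - 0.5)
        if config.range_radius_mean > 0:
            radius = rng.gamma(shape=4.0, scale=config.range_radius_mean / 4.0)
        else:
            radius = 0.0
        inside = (rr - crow) ** 2 + (cc - ccol) ** 2 <= radius ** 2
        if not inside.any():
            r0 = int(np.clip(round(crow), 0, n_r - 1))
            c0 = int(np.clip(round(ccol), 0, n_c - 1))
            inside[r0 * n_c + c0] = True
        incidence[i] = inside
    return pd.DataFrame(incidence, index=species, columns=np.arange(config.n_cells))


# ---------------------------------------------------------------------------
# phylogeny and traits

def generate_phylogeny(config: SyntheticConfig) -> Tuple[dendropy.Tree, List[dendropy.Tree]]:
    """Base ultrametric pure-birth tree plus ``n_trees`` set members, each a
    copy perturbed by a Poisson number of random NNI moves (so the set mixes
    exact copies and nearby topologies, as a posterior sample would)."""
    if config.n_species < 2:
        raise ConfigurationError("generate_phylogeny needs n_species >= 2")
    base = treemod.yule_tree(config.n_species, seed=int_seed_for(config.seed, STREAM_PHYLO),
                             height=config.tree_height)
    pyrng = random.Random(int_seed_for(config.seed, STREAM_PHYLO) ^ 0x5F5F)
    nprng = rng_for(config.seed, STREAM_PHYLO)
    tree_set = []
    for _ in range(config.n_trees):
        k = int(nprng.poisson(config.nni_moves_mean))
        tree_set.append(treemod.nni_perturb(base, k, pyrng))
    return base, tree_set


def generate_traits(config: SyntheticConfig, tree: dendropy.Tree) -> TraitMatrix:
    """Brownian-motion traits along the tree, plus iid observational noise
    and missing-completely-at-random masking.

    Per-edge innovations for the ``n_traits`` traits are drawn jointly from
    a factor-structured correlation (each trait is still marginally BM at
    rate ``bm_rate``); ``n_trait_factors=0`` yields independent traits.
    """
    if config.missing_frac >= 1:
        raise ConfigurationError("missing_frac must be < 1")
    rng = rng_for(config.seed, STREAM_TRAITS)
    p = config.n_traits
    if config.n_trait_factors > 0:
        L = rng.normal(size=(p, config.n_trait_factors))
        R = L @ L.T + 0.5 * np.eye(p)
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
        chol = np.linalg.cholesky(R)
    else:
        chol = np.eye(p)
    labels = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    values: Dict[str, np.ndarray] = {}
    node_vals: Dict[int, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            node_vals[id(node)] = np.zeros(p)
        else:
            bl = float(node.edge.length or 0.0)
            step = chol @ rng.normal(size=p) * np.sqrt(config.bm_rate * bl)
            node_vals[id(node)] = node_vals[id(node.parent_node)] + step
        if node.is_leaf():
            values[node.taxon.label] = node_vals[id(node)]
    true = pd.DataFrame([values[lab] for lab in labels], index=labels,
                        columns=[f"trait_{j+1}" for j in range(p)])
    noisy = true + rng.normal(0.0, config.trait_noise_sd, size=true.shape)
    mask = pd.DataFrame(rng.random(size=true.shape) < config.missing_frac,
                        index=true.index, columns=true.columns)
    observed = noisy.mask(mask)
    return TraitMatrix(values=observed, mask=mask, true_values=noisy)


def couple_beta_to_richness(config: SyntheticConfig, beta_high: float = 0.8,
                            beta_low: float = 0.2,
                            beta_P: float = 0.15) -> SyntheticConfig:
    """Config variant whose true temperature sensitivity decreases linearly
    with species richness (for directionality experiments): cells at the
    richness maximum get |beta_T| = beta_low, cells at the minimum get
    beta_high."""
    presence = generate_ranges(config)
    richness = presence.to_numpy().sum(axis=0).astype(float)
    lo, hi = richness.min(), richness.max()
    rnorm = (richness - lo) / (hi - lo) if hi > lo else np.zeros_like(richness)
    bT = (beta_high - (beta_high - beta_low) * rnorm).reshape(config.n_rows,
                                                             config.n_cols)
    bP = np.full((config.n_rows, config.n_cols), beta_P)
    return replace(config, beta_T_field=bT, beta_P_field=bP)


# ---------------------------------------------------------------------------
# biomes, full bundle, validation, I/O

def generate_biomes(config: SyntheticConfig) -> pd.DataFrame:
    """Latitudinal biome bands (row 0 = warm edge)."""
    ids, rows, _ = _cell_grid(config)
    edges = np.linspace(0, config.n_rows, config.n_biomes + 1)
    band = np.clip(np.searchsorted(edges, rows, side="right") - 1,
                   0, config.n_biomes - 1)
    names = (BIOME_NAMES * (config.n_biomes // len(BIOME_NAMES) + 1))[:config.n_biomes]
    # warmest band (low rows) gets the last (tropical) name
    labels = [names[config.n_biomes - 1 - b] for b in band]
    return pd.DataFrame({"cell_id": ids, "biome": labels})


def generate_all(config: SyntheticConfig, with_truth: bool = True) -> SyntheticBundle:
    climate = generate_climate(config)
    evi = generate_evi(config, climate)
    grid = assemble_grid(config, climate, evi)
    presence = generate_ranges(config)
    base, tree_set = generate_phylogeny(config)
    traits = generate_traits(config, base)
    biomes = generate_biomes(config)
    truth = true_sensitivity(config, climate) if with_truth else None
    return SyntheticBundle(config=config, grid=grid, presence=presence,
                           base_tree=base, tree_set=tree_set, traits=traits,
                           biomes=biomes, beta_T_field=evi.beta_T_field,
                           beta_P_field=evi.beta_P_field, truth=truth)


def validate_bundle(bundle: SyntheticBundle) -> List[str]:
    """Single fixture-validation routine: checks every downstream
    precondition and returns a list of human-readable failures (empty when
    the bundle is clean)."""
    fails = []
    g = bundle.grid
    if not (g.evi.shape == g.temp.shape == g.precip.shape):
        fails.append("grid series shapes differ")
    if g.n_months != 12 * bundle.config.n_years:
        fails.append("series length != 12 * n_years")
    if np.any(~np.isfinite(g.evi)) or g.evi.min() < 0 or g.evi.max() > 1:
        fails.append("EVI outside [0, 1]")
    if g.precip.min() < 0:
        fails.append("negative precipitation")
    pres = bundle.presence.to_numpy()
    if not np.isin(pres, (0, 1)).all():
        fails.append("presence matrix not binary")
    if (pres.sum(axis=1) < 1).any():
        fails.append("a species occupies no cell")
    if not treemod.is_ultrametric(bundle.base_tree, tol=1e-6):
        fails.append("base tree not ultrametric")
    tipset = treemod.tip_label_set(bundle.base_tree)
    if tipset != set(bundle.presence.index):
        fails.append("tree tip set != species pool")
    for t in bundle.tree_set:
        if treemod.tip_label_set(t) != tipset:
            fails.append("a perturbed tree has a different tip set")
            break
    if set(bundle.traits.values.index) != tipset:
        fails.append("trait species != tree tips")
    if bundle.traits.values.isna().all(axis=0).any():
        fails.append("a trait has no observed values")
    if set(bundle.biomes["cell_id"]) != set(g.cell_ids.tolist()):
        fails.append("biome labels do not cover all cells")
    return fails


def write_bundle(bundle: SyntheticBundle, outdir) -> Dict[str, str]:
    """Write the bundle as plain-text interchange files plus a manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "grid": out / "grid_series.csv",
        "presence": out / "presence.csv",
        "traits": out / "traits.csv",
        "traits_true": out / "traits_true.csv",
        "trees": out / "trees.nwk",
        "base_tree": out / "base_tree.nwk",
        "biomes": out / "biomes.csv",
        "truth": out / "true_sensitivity.csv",
        "manifest": out / "synthetic_manifest.json",
    }
    bundle.grid.to_long_frame().to_csv(paths["grid"], index=False)
    bundle.presence.rename_axis("species").to_csv(paths["presence"])
    bundle.traits.values.rename_axis("species").to_csv(paths["traits"])
    bundle.traits.true_values.rename_axis("species").to_csv(paths["traits_true"])
    treemod.write_newick_list(bundle.tree_set, paths["trees"])
    treemod.write_newick_list([bundle.base_tree], paths["base_tree"])
    bundle.biomes.to_csv(paths["biomes"], index=False)
    if bundle.truth is not None:
        bundle.truth.to_csv(paths["truth"], index=False)
    manifest = {
        "config": bundle.config.to_jsonable(),
        "seed": bundle.config.seed,
        "n_cells": int(bundle.grid.n_cells),
        "n_species": int(bundle.presence.shape[0]),
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}
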