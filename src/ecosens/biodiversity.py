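"""Biodiversity dimensions per grid cell and their null-model standardization.

Three richness-type metrics are computed for every cell assemblage:

* species richness — column sums of the binary presence matrix;
* Faith's phylogenetic diversity (PD) — total branch length of the union of
  root-to-tip paths of the assemblage on a maximum-clade-credibility (MCC)
  tree, in the tree's units (millions of years);
* functional richness (FRic) — convex-hull volume of the assemblage in a
  common reduced trait space (correlation-PCA axes jointly explaining at
  least 80% of trait variance).

Raw PD and FRic scale with richness, so both are standardized against a
null model that holds cell richness fixed while drawing assemblage
composition uniformly from the species pool:
SES = (observed - mean(null)) / sd(null).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .config import STREAM_NULL, rng_for
from .exceptions import DegenerateInputError, InputError
from .trees import TreeIndex, clade_sets, tip_label_set


# ---------------------------------------------------------------------------
# richness

def species_richness(presence: pd.DataFrame) -> pd.Series:
    """Per-cell species counts from a binary species x cell matrix."""
    vals = presence.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        bad = np.argwhere(~np.isin(vals, (0, 1)))[0]
        raise InputError(
            f"presence matrix is not binary (species {presence.index[bad[0]]!r}, "
            f"cell {presence.columns[bad[1]]!r})")
    return pd.Series(vals.sum(axis=0), index=presence.columns, name="richness")


# ---------------------------------------------------------------------------
# MCC tree

def mcc_tree(tree_set: Sequence[dendropy.Tree]) -> dendropy.Tree:
    """Maximum clade credibility member of a rooted tree set.

    Each tree is scored by the sum over its internal clades of the log of
    that clade's frequency across the set (equivalently, the product of
    clade frequencies); the highest-scoring member wins, ties broken by
    input order.
    """
    if len(tree_set) == 0:
        raise InputError("empty tree set")
    ref = tip_label_set(tree_set[0])
    freq: Dict[frozenset, int] = {}
    per_tree_clades = []
    for t in tree_set:
        if tip_label_set(t) != ref:
            raise InputError("trees in the set have different tip sets")
        cl = clade_sets(t)
        per_tree_clades.append(cl)
        for c in cl:
            freq[c] = freq.get(c, 0) + 1
    n = len(tree_set)
    best_i, best_score = 0, -np.inf
    for i, cl in enumerate(per_tree_clades):
        score = float(sum(np.log(freq[c] / n) for c in cl))
        if score > best_score + 1e-12:
            best_i, best_score = i, score
    return tree_set[best_i]


# ---------------------------------------------------------------------------
# Faith's PD

def faith_pd(tree, species_subset) -> float:
    """Summed branch length connecting ``species_subset`` to the root.

    ``tree`` may be a dendropy Tree or a prebuilt :class:`TreeIndex`.
    An empty subset returns 0 with a warning.
    """
    index = tree if isinstance(tree, TreeIndex) else TreeIndex.from_dendropy(tree)
    subset = list(species_subset)
    if len(subset) == 0:
        warnings.warn("faith_pd of an empty assemblage is 0", stacklevel=2)
        return 0.0
    idx = index.tip_indices(subset)
    covered = index.masks[:, idx].any(axis=1)
    return float(index.lengths[covered].sum())


def faith_pd_many(index: TreeIndex, subsets: np.ndarray) -> np.ndarray:
    """Vectorized PD for many assemblages.

    ``subsets`` is a (k, n_tips) boolean matrix; returns (k,) PD values.
    """
    cover = index.masks.astype(np.float64) @ subsets.T.astype(np.float64) > 0
    return index.lengths @ cover


# ---------------------------------------------------------------------------
# trait space and FRic

@dataclass
class TraitSpace:
    coordinates: pd.DataFrame       # species x retained axes
    variance_fractions: np.ndarray  # all axes, non-increasing
    n_retained: int

    @property
    def retained_variance(self) -> float:
        return float(self.variance_fractions[:self.n_retained].sum())


def trait_space_pca(traits: pd.DataFrame, target: float = 0.80,
                    min_axes: int = 2) -> TraitSpace:
    """Common reduced trait space from a complete trait matrix.

    Traits are centred and unit-scaled (correlation PCA, appropriate for
    incommensurate units); the smallest axis count whose cumulative variance
    reaches ``target`` is retained, floored at ``min_axes``. All species are
    projected once into this shared space.
    """
    if traits.isna().any().any():
        raise InputError("trait matrix contains missing values; impute first")
    if traits.shape[1] < 2 or traits.shape[0] < 3:
        raise InputError("need >= 2 traits and >= 3 species")
    X = traits.to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise DegenerateInputError("a trait is constant across species")
    X = X / sd
    cov = np.cov(X, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.clip(evals[order], 0, None), evecs[:, order]
    frac = evals / evals.sum()
    cum = np.cumsum(frac)
    k = max(int(np.searchsorted(cum, target - 1e-12) + 1), min_axes)
    k = min(k, X.shape[1])
    scores = X @ evecs[:, :k]
    coords = pd.DataFrame(scores, index=traits.index,
                          columns=[f"pc{j+1}" for j in range(k)])
    return TraitSpace(coordinates=coords, variance_fractions=frac, n_retained=k)


def hull_volume(points: np.ndarray) -> tuple[float, bool]:
    """Convex-hull volume with degenerate handling: fewer than d+1 points or
    an affinely degenerate set yields (0.0, True)."""
    pts = np.asarray(points, dtype=float)
    d = pts.shape[1]
    if pts.shape[0] < d + 1:
        return 0.0, True
    try:
        return float(ConvexHull(pts).volume), False
    except QhullError:
        return 0.0, True


def functional_richness(space: TraitSpace, species_subset) -> tuple[float, bool]:
    """Hull volume of an assemblage in the retained trait space."""
    subset = list(species_subset)
    if len(subset) == 0:
        return 0.0, True
    missing = set(subset) - set(space.coordinates.index)
    if missing:
        raise InputError(f"species not in trait space: {sorted(missing)[:5]}")
    return hull_volume(space.coordinates.loc[subset].to_numpy())


# ---------------------------------------------------------------------------
# assemblage table and SES null model

def ses_value(observed: float, null_values) -> float:
    """SES = (observed - mean(null)) / sd(null), sample (ddof=1) sd.

    Returns NaN when the null distribution has zero variance.
    """
    null = np.asarray(null_values, dtype=float)
    sd = null.std(ddof=1)
    if sd == 0:
        return float("nan")
    return float((observed - null.mean()) / sd)

def assemblage_metrics(presence: pd.DataFrame, tree: dendropy.Tree,
                       space: TraitSpace) -> pd.DataFrame:
    """Observed richness, PD and FRic for every cell."""
    index = TreeIndex.from_dendropy(tree)
    if set(presence.index) - set(index.labels):
        raise InputError("presence matrix contains species absent from the tree")
    rich = species_richness(presence)
    rows = []
    species = presence.index.to_numpy()
    for cell in presence.columns:
        members = species[presence[cell].to_numpy().astype(bool)]
        pd_val = faith_pd(index, members) if len(members) else 0.0
        fric, degen = functional_richness(space, members)
        rows.append({"cell_id": cell, "richness": int(rich[cell]),
                     "pd": pd_val, "fric": fric, "degenerate_fric": degen})
    return pd.DataFrame(rows)


def ses_null_model(metric: str, presence: pd.DataFrame, tree_or_space,
                   n_reps: int = 1000, seed: int = 0,
                   pool: str = "global",
                   biomes: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Richness-constant null model and standardized effect sizes.

    For each cell, ``n_reps`` assemblages of the observed richness are drawn
    uniformly without replacement from the species pool (all species by
    default; the cell's biome pool with ``pool='biome'``), the metric is
    recomputed for each draw, and SES = (obs - mean(null)) / sd(null) with
    the sample (ddof=1) standard deviation. Cells where the null has zero
    variance are reported with a missing SES and a reason code.
    """
    if n_reps < 2:
        raise InputError("n_reps must be >= 2")
    if metric not in ("pd", "fric"):
        raise InputError(f"unknown metric {metric!r}")
    if metric == "pd":
        index = (tree_or_space if isinstance(tree_or_space, TreeIndex)
                 else TreeIndex.from_dendropy(tree_or_space))
        pool_labels = np.asarray(index.labels)
    else:
        space: TraitSpace = tree_or_space
        pool_labels = space.coordinates.index.to_numpy()
        coords_all = space.coordinates.to_numpy()
    label_pos = {lab: i for i, lab in enumerate(pool_labels)}
    species = presence.index.to_numpy()
    rich = species_richness(presence)

    biome_of = None
    if pool == "biome":
        if biomes is None:
            raise InputError("pool='biome' requires a biome table")
        biome_of = dict(zip(biomes["cell_id"], biomes["biome"]))
        # species pool per biome: union of members over the biome's cells
        biome_pools: Dict[str, np.ndarray] = {}
        for b in set(biome_of.values()):
            cells = [c for c in presence.columns if biome_of.get(c) == b]
            members = species[presence[cells].to_numpy().astype(bool).any(axis=1)]
            biome_pools[b] = members

    rng = np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(STREAM_NULL,)))
    rows = []
    for cell in presence.columns:
        members = species[presence[cell].to_numpy().astype(bool)]
        r = int(rich[cell])
        if pool == "biome":
            cell_pool = biome_pools[biome_of[cell]]
        else:
            cell_pool = pool_labels
        if r > len(cell_pool):
            raise InputError(f"cell {cell!r}: richness exceeds pool size")
        if metric == "pd":
            observed = faith_pd(index, members) if r else 0.0
        else:
            observed, _ = functional_richness(space, members)
        reason = None
        if r == 0:
            rows.append({"cell_id": cell, "metric": metric, "observed": observed,
                         "null_mean": np.nan, "null_sd": np.nan, "ses": np.nan,
                         "n_reps": n_reps, "reason": "empty assemblage"})
            continue
        pool_idx = np.asarray([label_pos[s] for s in cell_pool])
        # n_reps uniform subsets without replacement, vectorized
        keys = rng.random((n_reps, len(pool_idx)))
        picks = np.argpartition(keys, r - 1, axis=1)[:, :r]
        if metric == "pd":
            subsets = np.zeros((n_reps, len(pool_labels)), dtype=bool)
            rows_rep = np.repeat(np.arange(n_reps), r)
            subsets[rows_rep, pool_idx[picks].ravel()] = True
            null_vals = faith_pd_many(index, subsets)
        else:
            null_vals = np.empty(n_reps)
            for j in range(n_reps):
                null_vals[j], _ = hull_volume(coords_all[pool_idx[picks[j]]])
        null_mean = float(null_vals.mean())
        null_sd = float(null_vals.std(ddof=1))
        ses = ses_value(observed, null_vals)
        if null_sd == 0:
            reason = "zero null variance"
        rows.append({"cell_id": cell, "metric": metric, "observed": observed,
                     "null_mean": null_mean, "null_sd": null_sd, "ses": ses,
                     "n_reps": n_reps, "reason": reason})
    return pd.DataFrame(rows)
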