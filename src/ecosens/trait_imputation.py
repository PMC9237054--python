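"""Gap-filling of trait matrices with trait-trait regression plus
phylogenetic eigenvectors.

Phylogenetic eigenvectors (PEs) are principal-coordinate axes of the
patristic distance matrix; low-representation axes (below a variance
threshold, 3% by default) are discarded. Missing trait values are filled by
deterministic iterative conditional imputation: each trait is regressed
(ridge-stabilized least squares) on the other traits and the retained PEs,
and its missing entries refreshed from the fit, until the largest change
falls below tolerance. Finally every imputed value is clamped to the
observed per-trait min/max, and each clamp is logged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import dendropy
import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InputError
from .trees import TreeIndex


@dataclass
class PhyloEigenvectors:
    scores: pd.DataFrame            # species x retained eigenvectors
    variance_fractions: np.ndarray  # of all positive eigenvalues, non-increasing
    n_retained: int


@dataclass
class ImputedTraits:
    values: pd.DataFrame            # completed matrix
    provenance: pd.DataFrame        # "observed" | "imputed"
    clamp_log: List[dict] = field(default_factory=list)
    converged: bool = True
    n_iter: int = 0


def phylo_eigenvectors(tree, variance_threshold: float = 0.03,
                       n_fixed: Optional[int] = None) -> PhyloEigenvectors:
    """Principal coordinates of the patristic distance matrix.

    The squared-distance matrix is double-centred (Gower) and
    eigen-decomposed; axes with positive eigenvalues are candidates. By
    default axes whose variance fraction is at least ``variance_threshold``
    are retained; ``n_fixed`` instead keeps the first ``n_fixed`` axes.
    """
    index = tree if isinstance(tree, TreeIndex) else TreeIndex.from_dendropy(tree)
    n = index.n_tips
    if n < 3:
        raise InputError("phylogenetic eigenvectors need at least 3 tips")
    D = index.patristic_matrix()
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-9 * max(evals.max(), 1.0)
    evals_pos, evecs_pos = evals[pos], evecs[:, pos]
    frac = evals_pos / evals_pos.sum()
    if n_fixed is not None:
        k = min(int(n_fixed), len(evals_pos))
    else:
        k = int(np.sum(frac >= variance_threshold))
    if k == 0:
        raise ConfigurationError(
            f"no eigenvector reaches the {variance_threshold:.0%} variance "
            "threshold; lower the threshold")
    scores = evecs_pos[:, :k] * np.sqrt(evals_pos[:k])
    df = pd.DataFrame(scores, index=index.labels,
                      columns=[f"pe{j+1}" for j in range(k)])
    return PhyloEigenvectors(scores=df, variance_fractions=frac, n_retained=k)


def _ridge_fit_predict(X_obs, y_obs, X_mis, ridge):
    """Centred ridge regression; returns predictions for X_mis."""
    xm, ym = X_obs.mean(axis=0), y_obs.mean()
    Xc, yc = X_obs - xm, y_obs - ym
    G = Xc.T @ Xc
    p = G.shape[0]
    alpha = ridge * (np.trace(G) / p if p else 1.0)
    beta = np.linalg.solve(G + alpha * np.eye(p), Xc.T @ yc)
    return ym + (X_mis - xm) @ beta


def impute_traits(trait_matrix: pd.DataFrame,
                  pe: Optional[PhyloEigenvectors] = None,
                  max_iter: int = 100, tol: float = 1e-6,
                  ridge: float = 1e-6) -> ImputedTraits:
    """Fill missing entries of a species x trait matrix.

    Observed entries are never modified. Imputed entries are refreshed
    iteratively from ridge regressions of each trait on all other traits
    plus the retained phylogenetic eigenvectors (if supplied), then clamped
    to the observed per-trait range.
    """
    tm = trait_matrix.copy()
    missing = tm.isna()
    if not missing.any().any():
        return ImputedTraits(values=tm, provenance=pd.DataFrame(
            "observed", index=tm.index, columns=tm.columns))
    if missing.all(axis=0).any():
        bad = missing.all(axis=0).idxmax()
        raise InputError(f"trait {bad!r} has no observed values")
    if pe is None and missing.all(axis=1).any():
        bad = missing.all(axis=1).idxmax()
        raise InputError(
            f"species {bad!r} has no observed traits and no eigenvectors")
    if pe is not None:
        missing_sp = set(tm.index) - set(pe.scores.index)
        if missing_sp:
            raise InputError(
                f"eigenvectors do not cover species {sorted(missing_sp)[:5]}")
        PE = pe.scores.loc[tm.index].to_numpy(dtype=float)
    else:
        PE = np.zeros((len(tm), 0))

    obs_min = tm.min()
    obs_max = tm.max()
    X = tm.to_numpy(dtype=float)
    mis = missing.to_numpy()
    col_means = np.nanmean(X, axis=0)
    for j in range(X.shape[1]):
        X[mis[:, j], j] = col_means[j]

    n_traits = X.shape[1]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        max_change = 0.0
        for j in range(n_traits):
            mj = mis[:, j]
            if not mj.any():
                continue
            others = np.delete(np.arange(n_traits), j)
            Z = np.column_stack([X[:, others], PE])
            pred = _ridge_fit_predict(Z[~mj], X[~mj, j], Z[mj], ridge)
            max_change = max(max_change, float(np.max(np.abs(pred - X[mj, j]))))
            X[mj, j] = pred
        if max_change < tol:
            converged = True
            break

    clamp_log: List[dict] = []
    for j, trait in enumerate(tm.columns):
        lo, hi = float(obs_min[trait]), float(obs_max[trait])
        for i in np.flatnonzero(mis[:, j]):
            v = X[i, j]
            if v < lo or v > hi:
                clamp_log.append({"species": tm.index[i], "trait": trait,
                                  "raw": float(v),
                                  "clamped": lo if v < lo else hi})
                X[i, j] = lo if v < lo else hi

    values = pd.DataFrame(X, index=tm.index, columns=tm.columns)
    # restore observed entries bit-for-bit
    values = values.mask(~missing, trait_matrix)
    provenance = pd.DataFrame(np.where(mis, "imputed", "observed"),
                              index=tm.index, columns=tm.columns)
    return ImputedTraits(values=values, provenance=provenance,
                         clamp_log=clamp_log, converged=converged, n_iter=it)
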