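"""Spatial simultaneous autoregressive (SAR) error models.

The regional biodiversity-stability regression is

    y = X beta + u,   u = lambda W u + eps,   eps_i ~ N(0, sigma^2 / w_i)

where y is the absolute sensitivity of one climate variable at one temporal
scale, X holds z-transformed biodiversity dimensions, biome and
limiting-factor dummies and their interactions, W is a row-standardized
inverse-distance (1/d) weights matrix on the distance band where Moran's I
of the response is strongest, and w_i are observation weights (the inverse
of each sensitivity estimate's confidence-interval range, entering as
inverse error variances).

Estimation maximizes the concentrated log-likelihood over lambda, with
log|I - lambda W| evaluated from the eigenvalues of W (exact, desk-scale;
the fit refuses n > 10,000 rather than switching to approximations); beta
and sigma^2 follow by generalized least squares on the spatially filtered
system.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, sparse
from scipy.spatial import cKDTree
from scipy.stats import norm

from .exceptions import DegenerateInputError, InputError

MAX_EXACT_N = 10_000


# ---------------------------------------------------------------------------
# weights

@dataclass
class SpatialWeights:
    cell_ids: np.ndarray
    coords: np.ndarray                  # (n, 2)
    W: sparse.csr_matrix                # row-standardized
    S: sparse.csr_matrix                # symmetric raw 1/d weights
    band_distance: float
    isolated: np.ndarray                # bool per cell
    scan_table: Optional[pd.DataFrame] = None

    @property
    def n(self) -> int:
        return len(self.cell_ids)

    def eigenvalues(self) -> np.ndarray:
        """Real eigenvalues of the row-standardized W.

        W = D^-1 S with S symmetric, so W is similar to the symmetric
        D^-1/2 S D^-1/2 and has a real spectrum. Isolated cells (zero rows)
        contribute zero eigenvalues.
        """
        if self.n > MAX_EXACT_N:
            raise InputError(
                f"n = {self.n} exceeds the exact-eigenvalue limit "
                f"({MAX_EXACT_N}); thin the data or use a coarser grid")
        d = np.asarray(self.S.sum(axis=1)).ravel()
        live = d > 0
        Sd = self.S.toarray()[np.ix_(live, live)]
        dr = 1.0 / np.sqrt(d[live])
        sym = Sd * dr[:, None] * dr[None, :]
        ev = np.linalg.eigvalsh(sym)
        return np.concatenate([ev, np.zeros(int((~live).sum()))])


def _band_matrix(coords: np.ndarray, distance: float) -> sparse.csr_matrix:
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=distance, output_type="ndarray")
    if pairs.size == 0:
        return sparse.csr_matrix((len(coords), len(coords)))
    d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
    if np.any(d == 0):
        raise InputError("coincident cell coordinates: 1/d weighting undefined")
    w = 1.0 / d
    i = np.concatenate([pairs[:, 0], pairs[:, 1]])
    j = np.concatenate([pairs[:, 1], pairs[:, 0]])
    return sparse.csr_matrix((np.concatenate([w, w]), (i, j)),
                             shape=(len(coords), len(coords)))


def _row_standardize(S: sparse.csr_matrix) -> sparse.csr_matrix:
    d = np.asarray(S.sum(axis=1)).ravel()
    inv = np.where(d > 0, 1.0 / np.where(d > 0, d, 1.0), 0.0)
    return sparse.diags(inv) @ S


def morans_i(values, weights) -> float:
    """Global Moran's I: (n / S0) * (z' W z) / (z' z), z centred values."""
    W = weights.W if isinstance(weights, SpatialWeights) else weights
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise InputError("Moran's I needs at least 3 values")
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0:
        raise DegenerateInputError("constant values have no spatial structure")
    s0 = float(W.sum())
    if s0 == 0:
        raise InputError("weights matrix has no links")
    return float(x.size / s0 * (z @ (W @ z)) / denom)


def build_weights(coords: np.ndarray, candidate_distances: Sequence[float],
                  reference_values, cell_ids: Optional[np.ndarray] = None,
                  max_isolated_frac: float = 0.05) -> SpatialWeights:
    """Choose the distance band where Moran's I of the reference values is
    strongest, with 1/d weighting and row standardization.

    Candidates leaving more than ``max_isolated_frac`` of cells without
    neighbours are skipped with a warning; the scan table records every
    candidate's |I| (NaN where skipped).
    """
    coords = np.asarray(coords, dtype=float)
    ref = np.asarray(reference_values, dtype=float)
    if cell_ids is None:
        cell_ids = np.arange(len(coords))
    if len(coords) != len(ref):
        raise InputError("coords and reference values differ in length")
    if len(candidate_distances) < 1:
        raise InputError("at least one candidate distance is required")
    scan = []
    best = None
    for dist in candidate_distances:
        S = _band_matrix(coords, float(dist))
        iso = np.asarray(S.sum(axis=1)).ravel() == 0
        if iso.mean() > max_isolated_frac:
            warnings.warn(f"band {dist}: {iso.mean():.0%} isolated cells, skipped",
                          stacklevel=2)
            scan.append({"distance": dist, "morans_i": np.nan,
                         "isolated_frac": float(iso.mean()), "skipped": True})
            continue
        W = _row_standardize(S)
        I = morans_i(ref, W)
        scan.append({"distance": dist, "morans_i": I,
                     "isolated_frac": float(iso.mean()), "skipped": False})
        if best is None or abs(I) > abs(best[1]):
            best = (dist, I, S, W, iso)
    scan_df = pd.DataFrame(scan)
    if best is None:
        raise InputError("every candidate distance left too many isolated cells")
    dist, _, S, W, iso = best
    return SpatialWeights(cell_ids=np.asarray(cell_ids), coords=coords, W=W.tocsr(),
                          S=S.tocsr(), band_distance=float(dist), isolated=iso,
                          scan_table=scan_df)


# ---------------------------------------------------------------------------
# design

@dataclass
class DesignSpec:
    y: np.ndarray                   # response, |sensitivity|
    X: pd.DataFrame                 # named design columns (no intercept)
    obs_weights: np.ndarray         # 1 / CI range
    cell_ids: np.ndarray
    coords: np.ndarray              # (n, 2) grid coordinates for weights
    scale: str
    climate_var: str
    drop_log: Dict[str, list] = field(default_factory=dict)


def assemble_design(metrics: pd.DataFrame, sensitivity: pd.DataFrame,
                    limiting: pd.DataFrame, scale: str, climate_var: str,
                    min_biome_cells: int = 10,
                    standardize_response: bool = False) -> DesignSpec:
    """Join per-cell tables into one SAR design.

    ``metrics`` needs cell_id, row, col, biome, richness, ses_pd, ses_fric;
    ``sensitivity`` the per-cell coefficient table; ``limiting`` the
    limiting-factor labels. Continuous predictors are z-transformed; biome
    levels with fewer than ``min_biome_cells`` cells are dropped (rows
    removed, logged); interactions biodiversity x biome and biodiversity x
    limiting factor are included. Observation weights are the inverse
    confidence-interval range of the modelled sensitivity.
    """
    if climate_var not in ("T", "P"):
        raise InputError(f"unknown climate variable {climate_var!r}")
    sens = sensitivity[sensitivity["scale"] == scale]
    lim = limiting[limiting["scale"] == scale][["cell_id", "label"]]
    df = metrics.merge(sens, on="cell_id").merge(lim, on="cell_id")
    log: Dict[str, list] = {}

    # undefined SES rows are excluded upstream of any model
    bad_ses = df["ses_pd"].isna() | df["ses_fric"].isna()
    if bad_ses.any():
        log["undefined_ses"] = df.loc[bad_ses, "cell_id"].tolist()
        df = df[~bad_ses]

    beta_col = f"beta_{climate_var}"
    lo, hi = f"ci_{climate_var}_low", f"ci_{climate_var}_high"
    ci_range = df[hi] - df[lo]
    w = 1.0 / ci_range
    bad_w = ~np.isfinite(w) | (w <= 0)
    if bad_w.any():
        log["nonfinite_weight"] = df.loc[bad_w, "cell_id"].tolist()
        df, w = df[~bad_w], w[~bad_w]

    counts = df["biome"].value_counts()
    small = counts[counts < min_biome_cells].index.tolist()
    if small:
        warnings.warn(f"dropping biome level(s) with < {min_biome_cells} cells: "
                      f"{small}", stacklevel=2)
        log["small_biome_cells"] = df.loc[df["biome"].isin(small), "cell_id"].tolist()
        df = df[~df["biome"].isin(small)]
        w = w.loc[df.index]
    if df.empty:
        raise InputError("no rows left after design filtering")

    def z(col: pd.Series) -> pd.Series:
        sd = col.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise DegenerateInputError(f"column {col.name!r} is constant")
        return (col - col.mean()) / sd

    X = pd.DataFrame(index=df.index)
    bio_terms = {}
    for name, col in (("richness", "richness"), ("pd_ses", "ses_pd"),
                      ("fric_ses", "ses_fric")):
        X[name] = z(df[col].astype(float))
        bio_terms[name] = X[name]

    biome_levels = sorted(df["biome"].unique())
    for lev in biome_levels[1:]:   # first level is the reference
        X[f"biome[{lev}]"] = (df["biome"] == lev).astype(float)
    water = (df["label"] == "water-limited").astype(float)
    minority = int(min(water.sum(), (1 - water).sum()))
    if minority >= 3:
        X["water_limited"] = water
    else:
        # a (near-)constant dummy cannot support its interaction block
        log["degenerate_limiting_factor"] = sorted(df["label"].unique())

    for name, series in bio_terms.items():
        for lev in biome_levels[1:]:
            X[f"{name}:biome[{lev}]"] = series * X[f"biome[{lev}]"]
        if "water_limited" in X:
            X[f"{name}:water_limited"] = series * X["water_limited"]

    y = df[beta_col].abs().to_numpy()
    if standardize_response:
        y = (y - y.mean()) / y.std(ddof=1)
    return DesignSpec(y=y, X=X.reset_index(drop=True),
                      obs_weights=w.to_numpy(),
                      cell_ids=df["cell_id"].to_numpy(),
                      coords=df[["row", "col"]].to_numpy(dtype=float),
                      scale=scale, climate_var=climate_var, drop_log=log)


# ---------------------------------------------------------------------------
# fitting

@dataclass
class SARFit:
    lam: float
    beta: pd.Series
    se: pd.Series
    sigma2: float
    loglik: float
    loglik_lambda0: float
    n: int
    converged: bool
    boundary_flag: bool
    lambda_se: float
    lambda_interval: Tuple[float, float]
    aliased: List[str] = field(default_factory=list)

    def coef_table(self) -> pd.DataFrame:
        zval = self.beta / self.se
        pval = 2 * norm.sf(np.abs(zval))
        return pd.DataFrame({"term": self.beta.index, "estimate": self.beta.values,
                             "se": self.se.values, "z": zval.values, "p": pval})


def _gls_profile(lam: float, y, Xmat, Wy, WX, sw):
    """Weighted GLS on the spatially filtered system for a fixed lambda."""
    ys = (y - lam * Wy) * sw
    Xs = (Xmat - lam * WX) * sw[:, None]
    beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
    resid = ys - Xs @ beta
    sigma2 = float(resid @ resid) / len(y)
    return beta, sigma2, Xs


def fit_sar_error(y, X: pd.DataFrame, obs_weights, weights: SpatialWeights,
                  add_intercept: bool = True) -> SARFit:
    """Maximum-likelihood spatial-error fit.

    The concentrated log-likelihood over the spatial parameter lambda is

        l(lambda) = -n/2 (log 2 pi sigma^2(lambda) + 1)
                    + 1/2 sum log w_i + sum log(1 - lambda e_i)

    with e_i the eigenvalues of W; beta(lambda) and sigma^2(lambda) by
    weighted GLS of (I - lambda W) y on (I - lambda W) X. Standard errors of
    beta come from the GLS information matrix at the optimum; lambda's from
    the numerical curvature of the concentrated likelihood.
    """
    y = np.asarray(y, dtype=float)
    w = np.asarray(obs_weights, dtype=float)
    if np.any(~np.isfinite(w)) or np.any(w <= 0):
        raise InputError("observation weights must be positive and finite")
    if weights.isolated.any():
        raise InputError("weights contain isolated cells; drop them and rebuild")
    names = list(X.columns)
    Xmat = X.to_numpy(dtype=float)
    if add_intercept:
        Xmat = np.column_stack([np.ones(len(y)), Xmat])
        names = ["intercept"] + names
    n, p = Xmat.shape
    if n < p + 2:
        raise InputError(f"n = {n} too small for {p} design columns")
    aliased: list = []
    if np.linalg.matrix_rank(Xmat) < p:
        # drop aliased columns (pivoted QR), keeping earlier columns
        from scipy.linalg import qr
        _, R, piv = qr(Xmat, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        rank = int(np.sum(diag > diag[0] * 1e-10))
        keep = np.sort(piv[:rank])
        aliased = [names[i] for i in range(p) if i not in set(keep)]
        warnings.warn(f"dropping aliased design column(s): {aliased}",
                      stacklevel=2)
        Xmat = Xmat[:, keep]
        names = [names[i] for i in keep]
        p = Xmat.shape[1]

    ev = weights.eigenvalues()
    lam_min = 1.0 / ev.min() if ev.min() < 0 else -np.inf
    lam_max = 1.0 / ev.max() if ev.max() > 0 else np.inf
    lo = lam_min + 1e-6 if np.isfinite(lam_min) else -5.0
    hi = lam_max - 1e-6 if np.isfinite(lam_max) else 0.999999

    Wy = weights.W @ y
    WX = weights.W @ Xmat
    sw = np.sqrt(w)
    logw = 0.5 * float(np.sum(np.log(w)))

    def negloglik(lam: float) -> float:
        _, sigma2, _ = _gls_profile(lam, y, Xmat, Wy, WX, sw)
        if sigma2 <= 0 or not np.isfinite(sigma2):
            return np.inf
        logdet = float(np.sum(np.log1p(-lam * ev)))
        ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1) + logw + logdet
        return -ll

    res = optimize.minimize_scalar(negloglik, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-8})
    lam = float(res.x)
    if not np.isfinite(res.fun):
        raise InputError("non-finite likelihood at the optimum")
    beta, sigma2, Xs = _gls_profile(lam, y, Xmat, Wy, WX, sw)
    loglik = -negloglik(lam)
    ll0 = -negloglik(0.0) if lo < 0.0 < hi else np.nan

    cov = sigma2 * np.linalg.inv(Xs.T @ Xs)
    se = np.sqrt(np.diag(cov))
    h = 1e-5 * max(1.0, abs(lam))
    lam_lo, lam_hi = max(lo, lam - h), min(hi, lam + h)
    curv = ((negloglik(lam_hi) - res.fun) / (lam_hi - lam) -
            (res.fun - negloglik(lam_lo)) / (lam - lam_lo)) / (0.5 * (lam_hi - lam_lo))
    lambda_se = float(1.0 / np.sqrt(curv)) if curv > 0 else np.nan
    boundary = (lam - lo < 1e-4) or (hi - lam < 1e-4)
    if boundary:
        warnings.warn(f"lambda = {lam:.6f} is within 1e-4 of the feasible "
                      "boundary", stacklevel=2)
    return SARFit(lam=lam, beta=pd.Series(beta, index=names),
                  se=pd.Series(se, index=names), sigma2=sigma2,
                  loglik=float(loglik), loglik_lambda0=float(ll0), n=n,
                  converged=bool(res.success), boundary_flag=bool(boundary),
                  lambda_se=lambda_se, lambda_interval=(lo, hi),
                  aliased=aliased)
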