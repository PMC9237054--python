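"""Per-cell sensitivity of vegetation productivity to climate variability.

For every grid cell the monthly enhanced-vegetation-index (EVI) series is
regressed on temperature and precipitation at two temporal scales:

* seasonal — monthly series, detrended with a centred 12-month moving
  average (trend removed, edges dropped), then z-transformed;
* interannual — annual aggregates (mean EVI, mean temperature, cumulative
  precipitation), not detrended, then z-transformed.

Because all series enter the OLS z-scored, the fitted slopes are
standardized coefficients: the sensitivity metric. Cells are classified as
temperature- or water-limited by comparing |beta_T| and |beta_P|.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import DegenerateInputError, InputError

EVI_MASK_THRESHOLD = 0.1


@dataclass
class SensitivityEstimate:
    cell_id: int
    scale: str
    beta_T: float
    beta_P: float
    ci_T: Tuple[float, float]
    ci_P: Tuple[float, float]
    r2: float
    n_obs: int


@dataclass
class LimitingFactorLabel:
    cell_id: int
    scale: str
    label: str          # "temperature-limited" | "water-limited"
    margin: float       # |beta_T| - |beta_P| (or beta_T - beta_P in signed mode)


@dataclass
class MaskReport:
    retained: np.ndarray    # cell ids kept
    removed: np.ndarray     # cell ids dropped
    mean_evi: pd.Series     # per-cell mean EVI indexed by cell id
    threshold: float = EVI_MASK_THRESHOLD


def ztransform(series) -> np.ndarray:
    """Standardize to mean 0, unit sample (ddof=1) standard deviation."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise InputError("ztransform needs a 1-D series of length >= 2")
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateInputError("constant series cannot be z-transformed")
    return (x - x.mean()) / sd


def detrend_moving_average(series, window: int = 12) -> Tuple[np.ndarray, int]:
    """Remove a centred moving-average trend.

    Even windows use the standard half-weight endpoint convention (a 2xW
    moving average). The ``window // 2`` positions lost at each end are
    dropped, not imputed. Returns ``(detrended_interior, offset)`` where
    ``offset`` is the index of the first retained position in the input.
    """
    x = np.asarray(series, dtype=float)
    if window < 2:
        raise InputError("window must be >= 2")
    if x.size < 2 * window:
        raise InputError(f"series of length {x.size} too short for window {window}")
    if window % 2 == 0:
        half = window // 2
        kernel = np.full(window + 1, 1.0 / window)
        kernel[0] = kernel[-1] = 0.5 / window
    else:
        half = (window - 1) // 2
        kernel = np.full(window, 1.0 / window)
    trend = np.convolve(x, kernel, mode="valid")
    interior = x[half:x.size - half]
    return interior - trend, half


def aggregate_annual(evi, temp, precip) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Annual mean EVI, mean temperature and cumulative precipitation."""
    arrs = [np.asarray(a, dtype=float) for a in (evi, temp, precip)]
    n = arrs[0].size
    if any(a.size != n for a in arrs):
        raise InputError("series lengths differ")
    if n == 0 or n % 12 != 0:
        raise InputError("series length must be a positive multiple of 12")
    years = n // 12
    e, t, p = (a.reshape(years, 12) for a in arrs)
    return e.mean(axis=1), t.mean(axis=1), p.sum(axis=1)


def fit_cell_sensitivity(evi_series, temp_series, precip_series,
                         cell_id: int = -1, scale: str = "") -> SensitivityEstimate:
    """OLS of z-scored EVI on z-scored temperature and precipitation.

    Slopes are the standardized sensitivity coefficients; 95% confidence
    intervals come from the t distribution on n - 3 degrees of freedom.
    """
    y = np.asarray(evi_series, dtype=float)
    xt = np.asarray(temp_series, dtype=float)
    xp = np.asarray(precip_series, dtype=float)
    if not (y.size == xt.size == xp.size):
        raise InputError("series lengths differ")
    if y.size < 4:
        raise InputError("at least 4 observations are required")
    X = sm.add_constant(np.column_stack([xt, xp]))
    if np.linalg.matrix_rank(X) < 3:
        raise DegenerateInputError("temperature and precipitation are collinear")
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=0.05)
    return SensitivityEstimate(
        cell_id=int(cell_id), scale=scale,
        beta_T=float(fit.params[1]), beta_P=float(fit.params[2]),
        ci_T=(float(ci[1, 0]), float(ci[1, 1])),
        ci_P=(float(ci[2, 0]), float(ci[2, 1])),
        r2=float(fit.rsquared), n_obs=int(fit.nobs),
    )


def classify_limiting_factor(beta_T: float, beta_P: float, cell_id: int = -1,
                             scale: str = "", rule: str = "absolute") -> LimitingFactorLabel:
    """Temperature- vs water-limited classification.

    Default rule compares absolute sensitivities; ties go to
    temperature-limited. The signed alternative compares raw coefficients.
    """
    if rule == "absolute":
        margin = abs(beta_T) - abs(beta_P)
    elif rule == "signed":
        margin = beta_T - beta_P
    else:
        raise InputError(f"unknown rule {rule!r}")
    label = "temperature-limited" if margin >= 0 else "water-limited"
    return LimitingFactorLabel(cell_id=int(cell_id), scale=scale,
                               label=label, margin=float(margin))


# ---------------------------------------------------------------------------
# grid-level drivers

def mask_low_evi(grid) -> MaskReport:
    """Drop cells whose mean EVI over the whole record is below 0.1.

    The boundary is inclusive: a cell at exactly 0.1 is retained.
    """
    if grid.n_cells == 0:
        raise InputError("empty grid-series collection")
    mean_evi = grid.evi.mean(axis=1)
    keep = mean_evi >= EVI_MASK_THRESHOLD
    return MaskReport(
        retained=np.asarray(grid.cell_ids)[keep],
        removed=np.asarray(grid.cell_ids)[~keep],
        mean_evi=pd.Series(mean_evi, index=grid.cell_ids, name="mean_evi"),
    )


def _seasonal_triplet(evi, temp, precip, window: int = 12):
    de, _ = detrend_moving_average(evi, window)
    dt, _ = detrend_moving_average(temp, window)
    dp, _ = detrend_moving_average(precip, window)
    return ztransform(de), ztransform(dt), ztransform(dp)


def _interannual_triplet(evi, temp, precip):
    ae, at, ap = aggregate_annual(evi, temp, precip)
    return ztransform(ae), ztransform(at), ztransform(ap)


def estimate_sensitivity(grid, scales: Sequence[str] = ("seasonal", "interannual"),
                         cells: Optional[np.ndarray] = None,
                         window: int = 12) -> Tuple[pd.DataFrame, List[dict]]:
    """Fit the sensitivity regression for every (cell, scale).

    Returns a tidy table (one row per cell x scale) and a log of cells
    skipped because a series was degenerate at that scale.
    """
    cell_ids = np.asarray(grid.cell_ids)
    if cells is not None:
        sel = np.isin(cell_ids, np.asarray(cells))
    else:
        sel = np.ones(cell_ids.size, dtype=bool)
    rows, dropped = [], []
    for i in np.flatnonzero(sel):
        cid = int(cell_ids[i])
        for scale in scales:
            try:
                if scale == "seasonal":
                    y, xt, xp = _seasonal_triplet(grid.evi[i], grid.temp[i],
                                                  grid.precip[i], window)
                elif scale == "interannual":
                    y, xt, xp = _interannual_triplet(grid.evi[i], grid.temp[i],
                                                     grid.precip[i])
                else:
                    raise InputError(f"unknown scale {scale!r}")
                est = fit_cell_sensitivity(y, xt, xp, cell_id=cid, scale=scale)
            except DegenerateInputError as exc:
                dropped.append({"cell_id": cid, "scale": scale, "reason": str(exc)})
                continue
            rows.append({
                "cell_id": cid, "scale": scale,
                "beta_T": est.beta_T, "beta_P": est.beta_P,
                "ci_T_low": est.ci_T[0], "ci_T_high": est.ci_T[1],
                "ci_P_low": est.ci_P[0], "ci_P_high": est.ci_P[1],
                "r2": est.r2, "n_obs": est.n_obs,
            })
    return pd.DataFrame(rows), dropped


def classify_table(sens: pd.DataFrame, rule: str = "absolute") -> pd.DataFrame:
    """Limiting-factor labels for every row of a sensitivity table."""
    rows = []
    for _, r in sens.iterrows():
        lab = classify_limiting_factor(r["beta_T"], r["beta_P"],
                                       cell_id=r["cell_id"], scale=r["scale"],
                                       rule=rule)
        rows.append({"cell_id": int(r["cell_id"]), "scale": r["scale"],
                     "label": lab.label, "margin": lab.margin})
    return pd.DataFrame(rows)
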