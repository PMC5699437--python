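"""Spatial mismatch between facets of projected diversity loss.

Predicted functional and phylogenetic diversity (percent of baseline) are
each regressed on predicted species diversity by ordinary least squares
over all defined grid cells; the residual maps show where losses in one
facet are more (negative) or less (positive) severe than species-
diversity losses would suggest. A second-stage regression between the two
residual maps isolates the functional-vs-phylogenetic mismatch after
their shared dependence on species diversity is removed. Residuals are in
percentage points (pp.).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ResidualMap", "ols_residual_map", "second_stage_residuals", "mismatch_extremes"]


@dataclass
class ResidualMap:
    grid: np.ndarray  # residuals (pp.), NaN where undefined
    slope: float
    intercept: float
    n_cells: int


def _fit_residuals(y: np.ndarray, x: np.ndarray) -> ResidualMap:
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape:
        raise ValueError("maps are not aligned")
    ok = np.isfinite(y) & np.isfinite(x)
    n = int(ok.sum())
    if n < 3:
        raise ValueError("need at least 3 defined cells")
    xv, yv = x[ok], y[ok]
    if np.ptp(xv) == 0:
        raise ValueError("predictor map is constant; OLS slope undefined")
    slope, intercept = np.polyfit(xv, yv, 1)
    resid = np.full(y.shape, np.nan)
    resid[ok] = yv - (intercept + slope * xv)
    return ResidualMap(resid, float(slope), float(intercept), n)


def ols_residual_map(y: np.ndarray, x: np.ndarray) -> ResidualMap:
    """Residuals of OLS regression of map ``y`` on map ``x`` over all
    defined cells. Positive residuals: ``y``'s diversity is higher than
    expected from ``x`` alone."""
    return _fit_residuals(y, x)


def second_stage_residuals(
    pd_resid: ResidualMap, fd_resid: ResidualMap, direction: str = "pd_on_fd"
) -> ResidualMap:
    """Residuals of one first-stage residual map regressed on the other,
    exposing the functional-vs-phylogenetic mismatch. ``direction``
    selects which map is the response ('pd_on_fd' or 'fd_on_pd')."""
    if direction == "pd_on_fd":
        return _fit_residuals(pd_resid.grid, fd_resid.grid)
    if direction == "fd_on_pd":
        return _fit_residuals(fd_resid.grid, pd_resid.grid)
    raise ValueError("direction must be 'pd_on_fd' or 'fd_on_pd'")


def mismatch_extremes(resid: ResidualMap) -> tuple[float, float]:
    """(min, max) residual in percentage points over defined cells."""
    vals = resid.grid[np.isfinite(resid.grid)]
    if vals.size == 0:
        raise ValueError("empty residual map")
    return float(vals.min()), float(vals.max())
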