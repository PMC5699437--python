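"""Gridded projection of diversity relative to a semi-natural baseline.

Fitted fixed-effect coefficients are combined with per-cell covariates
(land-use class fractions, reclassified cropland intensity, human
population density, subregion) to predict each facet's effective number
of species in every grid cell, expressed as a percentage of the baseline:
the prediction for a cell made entirely of semi-natural/natural
vegetation with zero human population density. Cell values aggregate the
land-use classes present in the cell by an area-fraction-weighted mean on
the response (effective-number) scale; country means ± spatial standard
errors summarize the maps.
"""

from __future__ import annotations

import importlib.resources

import numpy as np
import pandas as pd

from .models import ModelFit, predict_fixed
from .rasters import INTENSITY_CODES, RasterStack

__all__ = [
    "reclassify_intensity",
    "predict_map",
    "baseline_map",
    "relative_map",
    "country_summary",
    "count_countries_below",
    "load_country_table",
]

#: use-intensity codes -> collapsed cropland intensity level
_CROP_INTENSITY = {"light": "cropland_low", "moderate": "cropland_medium", "intensive": "cropland_high"}


def reclassify_intensity(stack: RasterStack) -> np.ndarray:
    """Per-cell cropland intensity level for cells containing cropland.

    Light/moderate/intensive map to low/medium/high; cells that contain
    cropland but carry a non-cropland intensity class (other or either
    pasture class) are classed low intensity — such cells generally hold
    too little cropland to have been mapped as intensive, so this keeps
    the projected losses conservative. Returns an object array with
    'cropland_low'/'cropland_medium'/'cropland_high' where the cropland
    fraction is positive and None elsewhere.
    """
    frac = stack.layers["frac_cropland"]
    codes = stack.layers["intensity_class"]
    unknown = set(np.unique(codes)) - set(float(k) for k in INTENSITY_CODES)
    if unknown:
        raise ValueError(f"unknown intensity class codes: {sorted(unknown)}")
    out = np.full(stack.shape, None, dtype=object)
    has_crop = frac > 0
    for code, name in INTENSITY_CODES.items():
        sel = has_crop & (codes == float(code))
        out[sel] = _CROP_INTENSITY.get(name, "cropland_low")
    return out


def _cell_class_fractions(stack: RasterStack) -> dict[str, np.ndarray]:
    """Collapse the raw fraction layers to model land-use levels.

    Primary and secondary vegetation pool into 'seminatural'; the whole
    cropland fraction goes to the cell's reclassified intensity level;
    plantation forest has no model level and is renormalized away.
    """
    f = stack.fractions()
    crop_level = reclassify_intensity(stack)
    out = {
        "seminatural": f["primary"] + f["secondary"],
        "pasture": f["pasture"].copy(),
        "urban": f["urban"].copy(),
        "cropland_low": np.zeros(stack.shape),
        "cropland_medium": np.zeros(stack.shape),
        "cropland_high": np.zeros(stack.shape),
    }
    for level in ("cropland_low", "cropland_medium", "cropland_high"):
        sel = crop_level == level
        out[level][sel] = f["cropland"][sel]
    total = sum(out.values())
    if np.any(total <= 0):
        raise ValueError("cells with no modellable land-use fraction")
    return {k: v / total for k, v in out.items()}


def _predict_class_grid(
    fit: ModelFit | dict,
    land_use: str,
    hpd: np.ndarray,
    subregion: np.ndarray,
    log_response: bool,
) -> np.ndarray:
    """Fixed-effect prediction grid for one land-use class at the cells'
    HPD and subregion (HPD log1p-transformed and centred with the
    constants stored at fit time)."""
    centring = fit.centring if isinstance(fit, ModelFit) else fit.get("centring", {})
    hpd_c = np.log1p(np.asarray(hpd, dtype=float).ravel()) - centring.get("hpd_log_mean", 0.0)
    newdata = pd.DataFrame(
        {
            "land_use": land_use,
            "hpd_c": hpd_c,
            "roads_c": 0.0,
            "subregion": np.asarray(subregion).ravel(),
        }
    )
    pred = predict_fixed(fit, newdata)
    if log_response:
        pred = np.exp(pred)
    return pred.reshape(np.asarray(hpd).shape)


def predict_map(
    fit: ModelFit | dict,
    stack: RasterStack,
    log_response: bool = False,
    subregion_labels: dict[float, str] | None = None,
) -> np.ndarray:
    """Per-cell predicted effective number of species: the fraction-
    weighted mean over the land-use classes present in the cell, each
    class evaluated at the cell's HPD and subregion."""
    fracs = _cell_class_fractions(stack)
    hpd = stack.layers["hpd"]
    sub = _subregion_grid(stack, subregion_labels)
    total = np.zeros(stack.shape)
    for level, frac in fracs.items():
        pred = _predict_class_grid(fit, level, hpd, sub, log_response)
        total += frac * pred
    return total


def _subregion_grid(stack: RasterStack, labels: dict[float, str] | None) -> np.ndarray:
    ids = stack.layers["subregion_id"]
    if labels is None:
        labels = {v: f"SR{int(v)}" for v in np.unique(ids)}
    out = np.empty(stack.shape, dtype=object)
    for v, name in labels.items():
        out[ids == v] = name
    if (out == None).any():  # noqa: E711
        raise ValueError("subregion cells without a label mapping")
    return out


def baseline_map(
    fit: ModelFit | dict,
    stack: RasterStack,
    log_response: bool = False,
    subregion_labels: dict[float, str] | None = None,
) -> np.ndarray:
    """Prediction for an uninhabited, fully semi-natural cell: land use
    fixed to the reference level and raw HPD = 0 (transformed and centred
    with the stored constants), per the cell's own subregion."""
    sub = _subregion_grid(stack, subregion_labels)
    zero_hpd = np.zeros(stack.shape)
    return _predict_class_grid(fit, "seminatural", zero_hpd, sub, log_response)


def relative_map(pred: np.ndarray, baseline: np.ndarray) -> np.ndarray:
    """100 × prediction / baseline; 100 means parity with the baseline."""
    pred = np.asarray(pred, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    bad = ~(baseline > 0) & np.isfinite(baseline)
    if bad.any():
        raise ValueError(f"{int(bad.sum())} cells with non-positive baseline")
    out = 100.0 * pred / baseline
    out[~np.isfinite(pred) | ~np.isfinite(baseline)] = np.nan
    return out


def country_summary(
    rel_maps: dict[str, np.ndarray], country: np.ndarray, nodata: float = -9999.0
) -> pd.DataFrame:
    """Per-country, per-facet mean percent-of-baseline with a standard
    error reflecting spatial variation only (sd over cells / sqrt(n))."""
    country = np.asarray(country)
    rows = []
    for cid in np.unique(country[country != nodata]):
        sel = country == cid
        for facet, grid in rel_maps.items():
            vals = np.asarray(grid)[sel]
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                raise ValueError(f"country {cid} has no defined cells for facet {facet}")
            se = float(vals.std(ddof=0) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
            rows.append(
                {
                    "country": cid if not float(cid).is_integer() else int(cid),
                    "facet": facet,
                    "mean": float(vals.mean()),
                    "se": se,
                    "n_cells": int(vals.size),
                }
            )
    return pd.DataFrame(rows)


def count_countries_below(summary: pd.DataFrame, facet: str, threshold: float) -> int:
    """Number of countries whose mean percent-of-baseline for ``facet``
    falls below ``threshold``."""
    if facet not in set(summary["facet"]):
        raise KeyError(f"facet {facet!r} not present in summary")
    sub = summary[summary["facet"] == facet]
    return int((sub["mean"] < threshold).sum())


def load_country_table() -> pd.DataFrame:
    """Packaged EU27 per-country diversity-relative-to-baseline table
    (percent of baseline ± spatial standard error, per facet), in long
    summary form compatible with :func:`count_countries_below`."""
    ref = importlib.resources.files("beediv.data").joinpath("eu27_country_diversity.csv")
    wide = pd.read_csv(ref)
    rows = []
    for _, r in wide.iterrows():
        for facet in ("sd", "fd", "pd"):
            rows.append(
                {
                    "country": r["country"],
                    "facet": facet,
                    "mean": float(r[facet]),
                    "se": float(r[f"{facet}_se"]),
                }
            )
    return pd.DataFrame(rows)
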