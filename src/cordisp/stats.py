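"""ROI-level statistics: median extraction, Pearson correlations and the
five standardized multivariable regression models.

MRI metrics (from the dispersion model: IVF, NDI, ODI; from DTI: FA, AD,
RD, MD) are the responses; histological metrics (CV plus the four staining
fractions MSF, NSF, ASF, uGSF) are the predictors.  The model family:

1. ``m ~ CV + MSF + NSF + ASF + uGSF``  (all histological features)
2. ``m ~ CV + MSF + NSF``               (neuronal features)
3. ``m ~ CV + NSF``                     (dispersion vs neurite density)
4. ``m ~ MSF + NSF``                    (demyelination vs axonal loss)
5. ``m ~ ASF + uGSF``                   (glial features)

"Standardized beta" means ordinary least squares on the z-scored response
*and* predictors, standardized within the analysed group — which makes the
single-predictor beta identical to the Pearson correlation of the pair.
Each group (control, MS) is analysed separately; no multiple-testing
correction is applied (per-test alpha 0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "MRI_METRICS",
    "HISTO_METRICS",
    "MODEL_SPECS",
    "RoiSet",
    "roi_medians",
    "pearson_table",
    "fit_models",
]

log = logging.getLogger(__name__)

MRI_METRICS = ("IVF", "NDI", "ODI", "FA", "AD", "RD", "MD")
HISTO_METRICS = ("CV", "MSF", "NSF", "ASF", "uGSF")

MODEL_SPECS = {
    1: ("CV", "MSF", "NSF", "ASF", "uGSF"),
    2: ("CV", "MSF", "NSF"),
    3: ("CV", "NSF"),
    4: ("MSF", "NSF"),
    5: ("ASF", "uGSF"),
}


@dataclass
class RoiSet:
    """Labelled ROI map on the MRI grid with per-ROI tissue and group."""

    label_map: np.ndarray  # int, 0 = background, values = roi_id
    table: pd.DataFrame  # columns: roi_id, tissue, group (+ free extras)

    def __post_init__(self):
        self.label_map = np.asarray(self.label_map)
        need = {"roi_id", "tissue", "group"}
        if not need <= set(self.table.columns):
            raise ValueError(f"ROI table needs columns {sorted(need)}")
        present = set(np.unique(self.label_map)) - {0}
        declared = set(self.table["roi_id"])
        if not present <= declared:
            raise ValueError(f"undeclared ROI ids in map: {sorted(present - declared)}")
        empty = declared - present
        if empty:
            raise ValueError(f"ROIs with no voxels: {sorted(empty)}")


def roi_medians(metric_maps: dict, rois: RoiSet) -> pd.DataFrame:
    """ROI-wise medians of co-registered metric maps.

    ``metric_maps`` maps a metric name to either a single 2-D map or a list
    of per-section 2-D maps (histology metrics come from one or two
    sections per MRI slice); for multiple sections the per-section ROI
    medians are averaged.  NaN pixels are treated as invalid.  ROIs with no
    valid pixels for some metric are dropped with a warning.
    """
    rows = []
    dropped = []
    for _, r in rois.table.iterrows():
        rid = r["roi_id"]
        sel = rois.label_map == rid
        row = {"roi_id": rid, "tissue": r["tissue"], "group": r["group"]}
        ok = True
        for name, maps in metric_maps.items():
            sections = maps if isinstance(maps, (list, tuple)) else [maps]
            meds = []
            for m in sections:
                vals = np.asarray(m, dtype=float)[sel]
                vals = vals[np.isfinite(vals)]
                if vals.size:
                    meds.append(np.median(vals))
            if not meds:
                ok = False
                break
            row[name] = float(np.mean(meds))
        if ok:
            rows.append(row)
        else:
            dropped.append(rid)
    if dropped:
        log.warning("roi_medians: dropped ROIs with no valid pixels: %s", dropped)
    return pd.DataFrame(rows)


def pearson_table(table: pd.DataFrame, group, mri_metrics=MRI_METRICS,
                  histo_metrics=HISTO_METRICS) -> pd.DataFrame:
    """Within-group Pearson r (and two-sided p on n-2 df) between every
    MRI metric and every histological metric.

    Zero-variance columns yield NaN r with a ``degenerate`` flag instead of
    failing.
    """
    sub = table[table["group"] == group]
    n = len(sub)
    if n < 3:
        raise ValueError(f"group {group!r} has fewer than 3 ROIs")
    rows = []
    for m in mri_metrics:
        for h in histo_metrics:
            x = sub[m].to_numpy(dtype=float)
            y = sub[h].to_numpy(dtype=float)
            degenerate = np.std(x) == 0 or np.std(y) == 0
            if degenerate:
                r_val, p_val = np.nan, np.nan
            else:
                r_val, p_val = sps.pearsonr(x, y)
            rows.append(dict(group=group, mri_metric=m, histo_metric=h,
                             r=r_val, p=p_val, n=n, degenerate=degenerate))
    return pd.DataFrame(rows)


def _zscore(x):
    return (x - x.mean()) / x.std(ddof=1)


def fit_models(table: pd.DataFrame, group, responses=MRI_METRICS,
               model_specs=MODEL_SPECS) -> pd.DataFrame:
    """Standardized multivariable OLS for every (response, model) pair of
    one group.

    Returns one row per coefficient with the standardized beta, its
    two-sided p-value, the model's adjusted R^2 and n.  Zero-variance
    predictors are dropped (flagged ``dropped_predictors``); near-collinear
    designs (condition number > 1e10) are flagged, not fatal.
    """
    sub = table[table["group"] == group]
    n = len(sub)
    rows = []
    for model_id, predictors in model_specs.items():
        usable = [p for p in predictors
                  if p in sub.columns and sub[p].std(ddof=1) > 0]
        dropped = sorted(set(predictors) - set(usable))
        for resp in responses:
            if resp not in sub.columns or sub[resp].std(ddof=1) == 0:
                continue
            if n <= len(usable) + 1:
                raise ValueError(
                    f"group {group!r}: n={n} too small for model {model_id}"
                )
            y = _zscore(sub[resp].to_numpy(dtype=float))
            X = np.column_stack([_zscore(sub[p].to_numpy(dtype=float))
                                 for p in usable])
            design = sm.add_constant(X)
            fit = sm.OLS(y, design).fit()
            flagged = np.linalg.cond(design) > 1e10
            for j, p_name in enumerate(usable):
                rows.append(dict(
                    group=group, model=model_id, response=resp,
                    predictor=p_name, beta=fit.params[j + 1],
                    p=fit.pvalues[j + 1], adj_r2=fit.rsquared_adj, n=n,
                    collinear=flagged,
                    dropped_predictors=",".join(dropped),
                ))
    return pd.DataFrame(rows)
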