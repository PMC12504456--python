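"""Pixel-based suitability maps, co-invasion accounting and group contrasts.

After the best learner has been refit on all observations, this module
turns it into landscape products:

* a probability threshold per genus, chosen as the mean (over the repeated
  cross-validation resamples) of the threshold minimising |Sensitivity -
  Specificity| over the 100-value candidate grid {0.01, 0.02, ..., 1.00}
  (ties broken toward the smallest qualifying threshold),
* 5-m probability surfaces for both genera, their binary masks, and the
  co-invasion mask (the elementwise AND of the two),
* land-cover reclassification of the 9-class source scheme into four broad
  classes (high vegetation, low vegetation, bare ground, built area; water
  kept as its own class),
* coverage accounting in hectares and percent, per site and per broad
  land-cover class,
* Welch two-sample contrasts with Cohen's d between the pixels claimed by
  each genus (positive d means the first group's mean is larger).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grid import RasterGrid
from .classify import ConfusionMatrix, TrainedModel, metrics

__all__ = [
    "ThresholdResult", "SuitabilityMap",
    "select_threshold", "predict_map", "coverage", "reclassify_lulc",
    "class_presence", "group_contrast", "histogram_report",
    "plot_histogram_panels", "THRESHOLD_GRID", "BROAD_CLASSES",
]

# exactly 100 candidate thresholds between 0.01 and 1
THRESHOLD_GRID = np.round(np.arange(1, 101) * 0.01, 2)

PIXEL_AREA_HA = 25.0 / 1e4  # one 5-m pixel in hectares

BROAD_CLASSES = {1: "high_vegetation", 2: "low_vegetation",
                 3: "bare_ground", 4: "built_area", 5: "water"}

# source scheme (Dynamic-World-like codes) -> broad class codes; the
# flooded-vegetation class is folded into low vegetation, snow/ice is
# excluded (nodata)
_SOURCE_TO_BROAD = {
    0: 5,           # water stays its own class
    1: 1,           # trees -> high vegetation
    2: 2, 4: 2, 5: 2, 3: 2,   # grass, crops, shrub, flooded veg -> low veg
    6: 4,           # built
    7: 3,           # bare
    8: np.nan,      # snow/ice excluded
}


@dataclass
class ThresholdResult:
    genus: str
    per_resample: np.ndarray
    mean: float


@dataclass
class SuitabilityMap:
    p_e: RasterGrid
    p_s: RasterGrid
    mask_e: RasterGrid      # 1/0 with NaN nodata
    mask_s: RasterGrid
    mask_co: RasterGrid
    threshold_e: float
    threshold_s: float


def select_threshold(cv_predictions: pd.DataFrame, genus: str = "",
                     ) -> ThresholdResult:
    """Sensitivity/specificity-balanced threshold from CV held-out scores.

    ``cv_predictions`` holds one row per held-out observation with columns
    ``repeat``, ``fold``, ``prob``, ``label``. Per resample, every
    candidate threshold t classifies positive at prob >= t; the t with the
    smallest |Se - Sp| wins (smallest t on ties). Resamples with a single
    observed class are skipped with a warning. The genus threshold is the
    mean over resamples.
    """
    chosen = []
    for (_, _), grp in cv_predictions.groupby(["repeat", "fold"]):
        y = grp["label"].to_numpy(bool)
        p = grp["prob"].to_numpy(float)
        if y.all() or not y.any():
            warnings.warn("resample with one class skipped in threshold search",
                          stacklevel=2)
            continue
        npos, nneg = y.sum(), (~y).sum()
        # vectorised Se/Sp over the whole grid
        pos = p[y][:, None] >= THRESHOLD_GRID[None, :]
        neg = p[~y][:, None] >= THRESHOLD_GRID[None, :]
        se = pos.sum(axis=0) / npos
        sp = 1.0 - neg.sum(axis=0) / nneg
        diff = np.abs(se - sp)
        chosen.append(THRESHOLD_GRID[int(np.argmin(diff))])  # argmin: first/smallest
    if not chosen:
        raise ValueError("no usable resample for threshold selection")
    arr = np.asarray(chosen, dtype=float)
    return ThresholdResult(genus=genus, per_resample=arr, mean=float(arr.mean()))


def predict_map(model_e: TrainedModel, model_s: TrainedModel,
                landmark_features: pd.DataFrame, template: RasterGrid,
                threshold_e: float, threshold_s: float) -> SuitabilityMap:
    """Per-pixel probabilities and binary/co-invasion masks on the 5-m grid.

    ``landmark_features`` carries ``x``/``y`` landmark coordinates plus all
    predictor columns; rows with any missing predictor become nodata in
    every output.
    """
    feats = sorted(set(model_e.feature_names) | set(model_s.feature_names))
    complete = landmark_features[feats].notna().all(axis=1).to_numpy()

    def rasterize(values: np.ndarray) -> RasterGrid:
        out = np.full(template.shape, np.nan)
        rows, cols = template.rowcol(
            landmark_features["x"].to_numpy(float),
            landmark_features["y"].to_numpy(float))
        ok = (rows >= 0) & complete
        out[rows[ok], cols[ok]] = values[ok]
        return template.like(out)

    pe = np.full(len(landmark_features), np.nan)
    ps = np.full(len(landmark_features), np.nan)
    if complete.any():
        sub = landmark_features.loc[complete]
        pe[complete] = model_e.predict_proba(sub)
        ps[complete] = model_s.predict_proba(sub)

    p_e, p_s = rasterize(pe), rasterize(ps)
    mask_e = p_e.like(np.where(np.isnan(p_e.data), np.nan,
                               (p_e.data >= threshold_e).astype(float)))
    mask_s = p_s.like(np.where(np.isnan(p_s.data), np.nan,
                               (p_s.data >= threshold_s).astype(float)))
    co = np.where(np.isnan(mask_e.data) | np.isnan(mask_s.data), np.nan,
                  ((mask_e.data == 1) & (mask_s.data == 1)).astype(float))
    return SuitabilityMap(p_e=p_e, p_s=p_s, mask_e=mask_e, mask_s=mask_s,
                          mask_co=p_e.like(co),
                          threshold_e=threshold_e, threshold_s=threshold_s)


def _mask_count(mask: RasterGrid) -> int:
    return int(np.nansum(mask.data == 1))


def coverage(smap: SuitabilityMap, site_area_ha: float) -> pd.DataFrame:
    """Hectares and percent of site area per category (E, S, co-invasion).

    Each positive 5-m pixel contributes 25 m^2 = 0.0025 ha. Two percentage
    accountings are emitted: against the supplied site area and against the
    valid-pixel area of the map itself (the two can differ slightly when
    the site boundary does not align with whole pixels).
    """
    if site_area_ha <= 0:
        raise ValueError("site area must be positive")
    valid = int(np.sum(~np.isnan(smap.mask_e.data)))
    pixel_area_ha = valid * PIXEL_AREA_HA
    rows = []
    for cat, mask in (("E", smap.mask_e), ("S", smap.mask_s),
                      ("co_invasion", smap.mask_co)):
        ha = _mask_count(mask) * PIXEL_AREA_HA
        rows.append({
            "category": cat,
            "hectares": ha,
            "pct_of_site": 100.0 * ha / site_area_ha,
            "pct_of_pixels": 100.0 * ha / pixel_area_ha if pixel_area_ha else np.nan,
        })
    return pd.DataFrame(rows).set_index("category")


def reclassify_lulc(lulc: RasterGrid) -> RasterGrid:
    """Collapse the 9-class source land-cover scheme into broad classes.

    trees -> high vegetation; grassland, cropland, shrubland (and flooded
    vegetation) -> low vegetation; bare -> bare ground; built -> built
    area; water is retained as its own class; snow/ice becomes nodata.
    Unknown codes raise with the offending code listed.
    """
    data = lulc.data
    out = np.full(data.shape, np.nan)
    codes = np.unique(data[~np.isnan(data)])
    for code in codes:
        icode = int(code)
        if icode != code or icode not in _SOURCE_TO_BROAD:
            raise ValueError(f"unknown land-cover class code {code!r}")
        out[data == code] = _SOURCE_TO_BROAD[icode]
    return lulc.like(out)


def class_presence(smap: SuitabilityMap, broad_lulc: RasterGrid) -> pd.DataFrame:
    """Percent predicted presence per broad land-cover class and category.

    The land-cover raster (any coarser resolution) is resampled to the 5-m
    map grid by nearest (containing) cell. Empty classes are reported as
    NaN rather than raising.
    """
    xs, ys = smap.mask_e.centers()
    cls = broad_lulc.sample(xs, ys).reshape(smap.mask_e.shape)
    rows = []
    for code, name in BROAD_CLASSES.items():
        in_class = (cls == code) & ~np.isnan(smap.mask_e.data)
        denom = int(in_class.sum())
        row = {"class": name, "n_pixels": denom}
        for cat, mask in (("E", smap.mask_e), ("S", smap.mask_s),
                          ("co_invasion", smap.mask_co)):
            if denom == 0:
                row[cat] = np.nan
            else:
                row[cat] = 100.0 * np.sum((mask.data == 1) & in_class) / denom
        rows.append(row)
    return pd.DataFrame(rows).set_index("class")


def group_contrast(values_a, values_b) -> dict:
    """Welch two-sample t-test and pooled-SD Cohen's d between pixel samples.

    Positive d means group A has the larger mean. With zero pooled
    variance, d and p are undefined (NaN), not an error.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    na, nb = len(a), len(b)
    sa2, sb2 = a.var(ddof=1), b.var(ddof=1)
    pooled = np.sqrt(((na - 1) * sa2 + (nb - 1) * sb2) / (na + nb - 2))
    if pooled == 0:
        d = np.nan
        t_stat, p = np.nan, np.nan
        df = np.nan
    else:
        d = (a.mean() - b.mean()) / pooled
        res = stats.ttest_ind(a, b, equal_var=False)
        t_stat, p = float(res.statistic), float(res.pvalue)
        df = float(res.df)
    return {
        "mean_a": float(a.mean()), "sd_a": float(np.sqrt(sa2)), "n_a": na,
        "mean_b": float(b.mean()), "sd_b": float(np.sqrt(sb2)), "n_b": nb,
        "t": t_stat, "df": df, "p": p, "cohens_d": float(d) if d == d else np.nan,
    }


def _masked_values(layer: RasterGrid, smap: SuitabilityMap,
                   mask: RasterGrid | None) -> np.ndarray:
    """Layer values at the map's 5-m pixel centres, optionally masked."""
    xs, ys = smap.mask_e.centers()
    vals = layer.sample(xs, ys)
    keep = ~np.isnan(smap.mask_e.data.ravel())
    if mask is not None:
        keep &= mask.data.ravel() == 1
    return vals[keep & ~np.isnan(vals)]


def histogram_report(smap: SuitabilityMap, layers: dict,
                     bins: int = 30) -> dict:
    """Binned distributions and group means per variable and category.

    Categories: the whole site plus the three masks (E, S, co-invasion).
    Returns ``{variable: {"edges": ..., "counts": {cat: ...},
    "means": {cat: ...}}}``.
    """
    cats = {"site": None, "E": smap.mask_e, "S": smap.mask_s,
            "co_invasion": smap.mask_co}
    report = {}
    for name, layer in layers.items():
        site_vals = _masked_values(layer, smap, None)
        if site_vals.size == 0:
            continue
        edges = np.histogram_bin_edges(site_vals, bins=bins)
        counts, means = {}, {}
        for cat, mask in cats.items():
            vals = _masked_values(layer, smap, mask)
            counts[cat] = np.histogram(vals, bins=edges)[0]
            means[cat] = float(vals.mean()) if vals.size else np.nan
        report[name] = {"edges": edges, "counts": counts, "means": means}
    return report


def plot_histogram_panels(report: dict, path) -> None:
    """One panel per variable: category histograms with group-mean lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    nvar = len(report)
    fig, axes = plt.subplots(nvar, 1, figsize=(6, 2.6 * nvar), squeeze=False)
    colors = {"site": "0.7", "E": "tab:red", "S": "gold",
              "co_invasion": "tab:orange"}
    for ax, (name, rep) in zip(axes.ravel(), report.items()):
        centers = 0.5 * (rep["edges"][:-1] + rep["edges"][1:])
        width = np.diff(rep["edges"]).mean()
        for cat, counts in rep["counts"].items():
            ax.bar(centers, counts, width=width, alpha=0.45,
                   color=colors.get(cat, None), label=cat)
            mean = rep["means"].get(cat)
            if mean is not None and np.isfinite(mean):
                ax.axvline(mean, color=colors.get(cat, "k"), lw=1.2)
        ax.set_xlabel(name)
        ax.set_ylabel("pixels")
    axes.ravel()[0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
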