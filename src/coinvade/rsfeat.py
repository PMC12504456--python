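"""Remote-sensing predictor layers and multi-resolution value extraction.

Derives the RS predictor set from input rasters: multi-temporal min/max
compositing (cloud and gap removal), NDVI = (NIR - Red)/(NIR + Red),
NIRv = NDVI x NIR, land surface temperature in degrees Celsius, 5x5-cell
focal statistics (mean / sd / min with truncated edge windows), canopy
height aggregation from 1 m to 5 m, Rao's quadratic entropy in a moving
window as a spectral-diversity surrogate, and value extraction for points
against a stack of layers kept in their native resolutions.

Missing data policy: a composited pixel is missing only if missing on all
dates; focal statistics use the valid cells of the (possibly truncated)
window; extraction outside a layer's extent yields NaN with a warning, not
an error.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

from .grid import AlignmentError, RasterGrid

__all__ = [
    "composite", "ndvi", "lst", "nirv", "focal_stat", "chm_to_5m",
    "rao_q", "extract_at", "landmarks", "derive_layers",
]

# Landsat Collection-2 surface temperature producer constants; overridable.
LST_SCALE = 0.00341802
LST_OFFSET = 149.0


def composite(stack: list[RasterGrid], reducer: str) -> RasterGrid:
    """Per-pixel min or max over the non-missing dates of a stack."""
    if len(stack) == 0:
        raise ValueError("empty stack")
    first = stack[0]
    for g in stack[1:]:
        first.require_same_grid(g)
    cube = np.stack([g.data for g in stack])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pixels
        if reducer == "min":
            out = np.nanmin(cube, axis=0)
        elif reducer == "max":
            out = np.nanmax(cube, axis=0)
        else:
            raise ValueError(f"unknown reducer {reducer!r}")
    return first.like(out)


def ndvi(red: RasterGrid, nir: RasterGrid) -> RasterGrid:
    """Normalized Difference Vegetation Index, (NIR - Red)/(NIR + Red)."""
    red.require_same_grid(nir)
    denom = nir.data + red.data
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom == 0, np.nan, (nir.data - red.data) / denom)
    return red.like(out)


def lst(thermal_max: RasterGrid, scale: float = LST_SCALE,
        offset: float = LST_OFFSET) -> RasterGrid:
    """Sensor DN -> Kelvin (scale*DN + offset) -> degrees Celsius."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    return thermal_max.like(scale * thermal_max.data + offset - 273.15)


def nirv(ndvi_layer: RasterGrid, nir: RasterGrid) -> RasterGrid:
    """NIR reflectance of vegetation, NDVI x NIR."""
    ndvi_layer.require_same_grid(nir)
    return nir.like(ndvi_layer.data * nir.data)


def _window_view(data: np.ndarray, window: int) -> np.ndarray:
    """All (window x window) neighbourhoods, NaN-padded at the edges.

    Padding with NaN makes edge windows behave exactly like truncated
    windows, since every statistic here ignores NaN cells.
    """
    half = window // 2
    padded = np.pad(data, half, mode="constant", constant_values=np.nan)
    return sliding_window_view(padded, (window, window))


def focal_stat(layer: RasterGrid, stat: str, window: int = 5) -> RasterGrid:
    """Moving-window mean / sd / min over valid cells (sd uses n-1).

    Edge pixels use the truncated window; a pixel is missing only when the
    whole window is.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be odd and positive")
    win = _window_view(layer.data, window)
    flat = win.reshape(layer.nrows, layer.ncols, -1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if stat == "mean":
            out = np.nanmean(flat, axis=-1)
        elif stat == "sd":
            n = np.sum(~np.isnan(flat), axis=-1)
            out = np.nanstd(flat, axis=-1, ddof=1)
            out = np.where(n >= 2, out, np.nan)
        elif stat == "min":
            out = np.nanmin(flat, axis=-1)
        else:
            raise ValueError(f"unknown stat {stat!r}")
    return layer.like(out)


def chm_to_5m(chm_1m: RasterGrid, factor: int = 5) -> tuple[RasterGrid, RasterGrid]:
    """Aggregate a 1-m canopy height model to 5-m mean and sd layers.

    Each 5-m cell receives the mean and sample sd (n-1) of the 25 underlying
    1-m cells, i.e. the 5x5 focal statistic evaluated exactly at 5-m cell
    centres.
    """
    r, c = chm_1m.shape
    if r % factor or c % factor:
        raise AlignmentError("1-m grid does not nest in the coarse grid")
    blocks = chm_1m.data.reshape(r // factor, factor, c // factor, factor)
    blocks = blocks.transpose(0, 2, 1, 3).reshape(r // factor, c // factor, -1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(blocks, axis=-1)
        nvalid = np.sum(~np.isnan(blocks), axis=-1)
        sd = np.where(nvalid >= 2, np.nanstd(blocks, axis=-1, ddof=1), np.nan)
    cell = chm_1m.cell * factor
    mk = lambda a: RasterGrid(a, xmin=chm_1m.xmin, ymax=chm_1m.ymax, cell=cell)
    return mk(mean), mk(sd)


def rao_q(layer: RasterGrid, window: int = 5) -> RasterGrid:
    """Rao's quadratic entropy of pixel values in a moving window.

    Q = sum_{i,j} d_ij p_i p_j over all ordered pairs of the N valid window
    cells, with equal weights p_i = 1/N and d_ij = |v_i - v_j|. Pixels whose
    window holds fewer than 2 valid cells are missing.

    Computed through the sorted-values identity
    ``sum_{i<j} (x_(j) - x_(i)) = sum_k (2k - N + 1) x_(k)``,
    which avoids materialising all N^2 pairs.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be odd and positive")
    win = _window_view(layer.data, window)
    flat = win.reshape(layer.nrows, layer.ncols, -1)
    n = np.sum(~np.isnan(flat), axis=-1)
    s = np.sort(flat, axis=-1)  # NaNs sort to the end
    k = np.arange(flat.shape[-1])
    w = 2.0 * k[None, None, :] - (n[..., None] - 1.0)
    w = np.where(k[None, None, :] < n[..., None], w, 0.0)
    pair_sum = np.nansum(w * s, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        q = 2.0 * pair_sum / np.square(n)
    q = np.where(n >= 2, q, np.nan)
    return layer.like(q)


def landmarks(site_mask: RasterGrid) -> pd.DataFrame:
    """Centre coordinates of every true cell of a mask, row-major order."""
    mask = ~np.isnan(site_mask.data) & (site_mask.data != 0)
    if not mask.any():
        raise ValueError("site mask has no true cells")
    rows, cols = np.nonzero(mask)
    xs = site_mask.xmin + (cols + 0.5) * site_mask.cell
    ys = site_mask.ymax - (rows + 0.5) * site_mask.cell
    return pd.DataFrame({"x": xs, "y": ys})


def extract_at(points: pd.DataFrame, layers: dict) -> pd.DataFrame:
    """Values of every layer at each point (cell containing the point).

    ``points`` needs ``x`` and ``y`` columns; ``layers`` maps variable name
    to :class:`RasterGrid`. No interpolation: multi-resolution stacks stay
    in their native grids, so two points inside one 60-m cell share that
    band's value while differing in the 5-m layers. Points outside a
    layer's extent get NaN there and raise a warning once per layer.
    """
    out = points[["x", "y"]].reset_index(drop=True).copy()
    x = out["x"].to_numpy(float)
    y = out["y"].to_numpy(float)
    for name, layer in layers.items():
        vals = layer.sample(x, y)
        row, _ = layer.rowcol(x, y)
        n_out = int(np.sum(row < 0))
        if n_out:
            warnings.warn(
                f"{n_out} point(s) fall outside layer {name!r}; values set missing",
                stacklevel=2,
            )
        out[name] = vals
    return out


# Table-2 naming of the full RS predictor set, in presentation order.
RS_VARIABLES = [
    "CHMmean", "CHMsd", "NDVI", "LST", "Aerosols", "Blue", "Green", "Red",
    "RedEdge1", "NIR", "SWIR1", "TCDImean", "TCDIsd", "SeLImin",
    "RaoQ_NDVI", "RaoQ_NIRv",
]


def derive_layers(bands: dict, window: int = 5) -> dict:
    """Assemble the 16 RS predictor layers from a scene's raw bands.

    Order of operations for the 30-m products follows the acquisition
    pipeline being emulated: Red and NIR are min-composited across dates
    first, NDVI is computed from the composites (not per date); the thermal
    stack is max-composited (yearly extreme heat) before conversion to
    degrees Celsius.
    """
    chm_mean, chm_sd = chm_to_5m(bands["chm"])
    red_min = composite(bands["red_stack"], "min")
    nir_min = composite(bands["nir_stack"], "min")
    ndvi_layer = ndvi(red_min, nir_min)
    thermal_max = composite(bands["thermal_stack"], "max")
    lst_layer = lst(thermal_max,
                    bands.get("lst_scale", LST_SCALE),
                    bands.get("lst_offset", LST_OFFSET))
    ndvi_10 = ndvi(bands["red"], bands["nir"])
    nirv_10 = nirv(ndvi_10, bands["nir"])
    return {
        "CHMmean": chm_mean,
        "CHMsd": chm_sd,
        "NDVI": ndvi_layer,
        "LST": lst_layer,
        "Aerosols": bands["aerosols"],
        "Blue": bands["blue"],
        "Green": bands["green"],
        "Red": bands["red"],
        "RedEdge1": bands["rededge1"],
        "NIR": bands["nir"],
        "SWIR1": bands["swir1"],
        "TCDImean": focal_stat(bands["tcdi"], "mean", window),
        "TCDIsd": focal_stat(bands["tcdi"], "sd", window),
        "SeLImin": focal_stat(bands["seli"], "min", window),
        "RaoQ_NDVI": rao_q(ndvi_10, window),
        "RaoQ_NIRv": rao_q(nirv_10, window),
    }
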