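"""Synthetic post-mining landscapes with known two-genus niche structure.

The generator emulates the data a field + remote-sensing campaign over
spoil-heap mosaics would deliver: co-registered multi-resolution rasters
(1-m canopy height, multi-date 30-m Red/NIR/thermal stacks, 10/20/60-m
reflectance bands, 10-m disturbance and leaf-area layers, a 10-m land-cover
classification) plus a table of circular vegetation plots with per-species
cover, traits and per-genus presence labels.

Everything is a pure function of :class:`SceneConfig` including its
``rng_seed``; stage-level randomness is derived from the one seed by fixed
sub-seeding, so any stage can be re-run bit-identically.

The two genera have contrasting niches on five spatially autocorrelated
latent gradients:

* genus E (an early-successional ruderal): favoured by high temperature and
  disturbance, suppressed by tall vegetation and late succession;
* genus S (a rhizomatous perennial): favoured by moisture, with an optimum
  at intermediate succession and vegetation height.

Occupancy of the two genera is drawn independently given the latents, so
joint prevalence emerges from niche overlap rather than explicit coupling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit, logit

from .grid import RasterGrid

__all__ = [
    "SceneConfig",
    "LatentFields",
    "TruthLayer",
    "PlotData",
    "Scene",
    "make_latent_fields",
    "make_bands",
    "make_truth",
    "sample_plots",
    "make_scene",
    "write_scene",
    "green_biomass",
    "LULC_CODES",
]


class ConfigurationError(ValueError):
    """The scene configuration is internally inconsistent."""


class CalibrationError(RuntimeError):
    """The requested prevalence cannot be reached under the niche coefficients."""


# Land-cover codes of the 9-class source scheme (Dynamic-World-like).
LULC_CODES = {
    "water": 0,
    "trees": 1,
    "grassland": 2,
    "flooded_vegetation": 3,
    "cropland": 4,
    "shrubland": 5,
    "built": 6,
    "bare": 7,
    "snow_ice": 8,
}


@dataclass
class SceneConfig:
    """All knobs of the synthetic landscape.

    The defaults reproduce the study conditions: 358 circular plots of
    28.3 m^2, ten acquisition dates for the 30-m stacks, ~40% prevalence per
    genus (joint prevalence ~20% emerges from the niche overlap), and layer
    cell sizes of 1/5/10/20/30/60 m nesting inside a common extent.
    """

    extent: float = 1200.0          # metres; must be divisible by 60
    n_dates_landsat: int = 10
    kernel_width: float = 25.0      # Gaussian sigma of latent smoothing, metres

    # per-band additive noise standard deviations (reflectance / native units)
    noise_chm: float = 0.4          # m
    noise_reflectance: float = 0.012
    noise_thermal: float = 0.6      # degrees C equivalent
    noise_tcdi: float = 0.10
    noise_seli: float = 0.08

    cloud_fraction_dates: float = 0.4     # share of dates carrying cloud blobs
    cloud_cover_fraction: float = 0.25    # share of pixels inside a blob

    # how strongly moisture feeds canopy greenness (and through it most
    # optical bands); at 0, moisture reaches the imagery only via the
    # short-wave infrared water-absorption term
    greenness_moisture_weight: float = 0.8

    # logistic niche coefficients on z-scored latent gradients
    niche_e: dict = field(default_factory=lambda: {
        "temperature": 1.1, "disturbance": 0.7,
        "height": -1.0, "succession": -0.6,
    })
    niche_s: dict = field(default_factory=lambda: {
        "moisture": 1.1, "disturbance": 0.5,
        "succession_sq": -0.4, "height_sq": -0.3,
    })
    prevalence_e: float = 0.40
    prevalence_s: float = 0.40

    n_plots: int = 358
    plot_area: float = 28.3         # m^2
    placement: str = "random"       # or "stratified" (by succession terciles)

    n_species_pool: int = 80
    native_fraction: float = 0.8

    rng_seed: int = 0

    # cell sizes per layer family; fixed by the sensor suite being emulated
    cell_chm: float = 1.0
    cell_fine: float = 5.0
    cell_s2: float = 10.0
    cell_s2_20: float = 20.0
    cell_landsat: float = 30.0
    cell_s2_60: float = 60.0

    def validate(self) -> None:
        if self.extent <= 0 or (round(self.extent) % 60) != 0:
            raise ConfigurationError("extent must be a positive multiple of 60 m")
        for p in (self.prevalence_e, self.prevalence_s):
            if not (0.0 < p < 1.0):
                raise ConfigurationError("target prevalences must lie in (0, 1)")
        if self.n_dates_landsat < 1:
            raise ConfigurationError("need at least one acquisition date")
        if self.placement not in ("random", "stratified"):
            raise ConfigurationError(f"unknown placement {self.placement!r}")

    def seeds(self) -> dict:
        """Fixed sub-seeds for each generation stage."""
        ss = np.random.SeedSequence(self.rng_seed)
        names = ["latents", "bands", "truth", "plots"]
        return dict(zip(names, ss.spawn(len(names))))


@dataclass
class LatentFields:
    """The environmental gradients driving every downstream layer.

    All five share the 1-m master grid. ``height`` is a deterministic
    monotone transform of ``succession`` (vegetation grows up as succession
    proceeds), hence nonnegative everywhere.
    """

    temperature: RasterGrid     # degrees C-like
    moisture: RasterGrid        # unitless z-score
    height: RasterGrid          # metres, >= 0
    disturbance: RasterGrid     # unitless z-score
    succession: RasterGrid      # unitless z-score

    def as_dict(self) -> dict:
        return {
            "temperature": self.temperature, "moisture": self.moisture,
            "height": self.height, "disturbance": self.disturbance,
            "succession": self.succession,
        }


@dataclass
class TruthLayer:
    """Ground truth: occupancy probabilities and one Bernoulli realisation."""

    p_e: RasterGrid
    p_s: RasterGrid
    occupancy_e: RasterGrid     # 0/1
    occupancy_s: RasterGrid     # 0/1


@dataclass
class PlotData:
    """Field campaign emulation: plot locations, covers, traits, labels."""

    plots: pd.DataFrame     # plot_id, x, y, area_m2, genusE_present, genusS_present
    cover: pd.DataFrame     # plot_id, species_id, cover_pct
    species: pd.DataFrame   # species_id, SLA, SM, H, LDMC, native_flag, moist_pref


@dataclass
class Scene:
    config: SceneConfig
    latents: LatentFields
    bands: dict
    truth: TruthLayer
    plots: PlotData


# ---------------------------------------------------------------------------
# latent fields
# ---------------------------------------------------------------------------

def _smooth_standard_field(shape, sigma_cells, rng) -> np.ndarray:
    """White noise convolved with a Gaussian kernel, re-standardised.

    With ``sigma_cells == 0`` this is plain white noise (flat variogram).
    """
    z = rng.standard_normal(shape)
    if sigma_cells > 0:
        z = gaussian_filter(z, sigma=sigma_cells, mode="reflect")
    z = (z - z.mean()) / z.std()
    return z


def make_latent_fields(config: SceneConfig) -> LatentFields:
    """Generate the five autocorrelated gradients on the 1-m master grid."""
    config.validate()
    n = int(round(config.extent / config.cell_chm))
    rng = np.random.default_rng(config.seeds()["latents"])
    sigma = config.kernel_width / config.cell_chm

    z_t = _smooth_standard_field((n, n), sigma, rng)
    z_m = _smooth_standard_field((n, n), sigma, rng)
    z_d = _smooth_standard_field((n, n), sigma, rng)
    z_s = _smooth_standard_field((n, n), sigma, rng)

    def g(a):
        return RasterGrid(a, xmin=0.0, ymax=config.extent, cell=config.cell_chm)

    temperature = 35.0 + 5.0 * z_t          # summer-max LST-like, degrees C
    height = 28.0 * expit(1.6 * (z_s - 0.8))  # monotone in succession, 0..28 m

    return LatentFields(
        temperature=g(temperature),
        moisture=g(z_m),
        height=g(height),
        disturbance=g(z_d),
        succession=g(z_s),
    )


# ---------------------------------------------------------------------------
# bands
# ---------------------------------------------------------------------------

def _block_mean(a: np.ndarray, f: int) -> np.ndarray:
    r, c = a.shape
    return a.reshape(r // f, f, c // f, f).mean(axis=(1, 3))


def green_biomass(latents: LatentFields, moisture_weight: float = 0.8) -> np.ndarray:
    """Green-biomass latent in (0, 1): moist, late-successional ground is greener."""
    return expit(1.2 * latents.succession.data
                 + moisture_weight * latents.moisture.data)


def _grid_at(config: SceneConfig, arr: np.ndarray, cell: float) -> RasterGrid:
    return RasterGrid(arr, xmin=0.0, ymax=config.extent, cell=cell)


def make_bands(latents: LatentFields, config: SceneConfig) -> dict:
    """Synthesise every sensor layer from the latent gradients plus noise.

    Returns a dict with keys ``chm``, ``red_stack``, ``nir_stack``,
    ``thermal_stack`` (lists of per-date 30-m grids, thermal in sensor DN),
    ``aerosols``, ``blue``, ``green``, ``red``, ``rededge1``, ``nir``,
    ``swir1`` (reflectance in [0, 1]), ``tcdi``, ``seli`` and ``lulc``.

    A random subset of dates carries cloud blobs that push Red and NIR
    *upward* (bright cloud tops) and the thermal band *downward* (cold cloud
    tops), so per-pixel min (reflectance) and max (thermal) compositing
    removes them.
    """
    config.validate()
    rng = np.random.default_rng(config.seeds()["bands"])
    g1 = green_biomass(latents, config.greenness_moisture_weight)
    cell1 = config.cell_chm

    def agg(a, cell):
        return _block_mean(a, int(round(cell / cell1)))

    def refl(base, cell):
        noisy = base + rng.normal(0.0, config.noise_reflectance, base.shape)
        return _grid_at(config, np.clip(noisy, 0.0, 1.0), cell)

    bands: dict = {}

    # 1-m canopy height model
    chm = latents.height.data + rng.normal(0.0, config.noise_chm, g1.shape)
    bands["chm"] = _grid_at(config, np.clip(chm, 0.0, None), cell1)

    # 30-m multi-date stacks
    f30 = int(round(config.cell_landsat / cell1))
    g30 = _block_mean(g1, f30)
    t30 = _block_mean(latents.temperature.data, f30)
    red_base = np.clip(0.30 - 0.22 * g30, 0.01, 1.0)
    nir_base = np.clip(0.10 + 0.45 * g30, 0.0, 1.0)

    n_dates = config.n_dates_landsat
    cloudy = np.zeros(n_dates, dtype=bool)
    if n_dates > 1 and config.cloud_fraction_dates > 0:
        n_cloudy = int(round(config.cloud_fraction_dates * n_dates))
        n_cloudy = min(n_cloudy, n_dates - 1)  # keep >= 1 clean date
        cloudy[rng.choice(n_dates, size=n_cloudy, replace=False)] = True
    # per-date thermal deficit from the yearly extreme; one date hits the max
    deficit = rng.uniform(0.0, 6.0, n_dates)
    deficit[rng.integers(n_dates)] = 0.0

    red_stack, nir_stack, thermal_stack = [], [], []
    lst_scale, lst_offset = 0.00341802, 149.0
    for d in range(n_dates):
        red_d = red_base + rng.normal(0.0, config.noise_reflectance, g30.shape)
        nir_d = nir_base + rng.normal(0.0, config.noise_reflectance, g30.shape)
        kelvin = t30 + 273.15 - deficit[d] \
            + rng.normal(0.0, config.noise_thermal, g30.shape)
        if cloudy[d]:
            blob = _smooth_standard_field(g30.shape, 2.0, rng)
            mask = blob > np.quantile(blob, 1.0 - config.cloud_cover_fraction)
            red_d = red_d + mask * rng.uniform(0.15, 0.35)
            nir_d = nir_d + mask * rng.uniform(0.15, 0.35)
            kelvin = kelvin - mask * rng.uniform(15.0, 30.0)
        red_stack.append(_grid_at(config, np.clip(red_d, 0.0, 1.0), config.cell_landsat))
        nir_stack.append(_grid_at(config, np.clip(nir_d, 0.0, 1.0), config.cell_landsat))
        dn = (kelvin - lst_offset) / lst_scale
        thermal_stack.append(_grid_at(config, dn, config.cell_landsat))
    bands["red_stack"] = red_stack
    bands["nir_stack"] = nir_stack
    bands["thermal_stack"] = thermal_stack
    bands["lst_scale"], bands["lst_offset"] = lst_scale, lst_offset

    # Sentinel-like reflectance bands
    g10 = agg(g1, config.cell_s2)
    m10 = agg(latents.moisture.data, config.cell_s2)
    d10 = agg(latents.disturbance.data, config.cell_s2)
    h10 = agg(latents.height.data, config.cell_s2)
    g20 = agg(g1, config.cell_s2_20)
    m20 = agg(latents.moisture.data, config.cell_s2_20)
    d60 = agg(latents.disturbance.data, config.cell_s2_60)

    bands["blue"] = refl(np.clip(0.12 - 0.07 * g10 + 0.02 * d10, 0.0, 1.0), config.cell_s2)
    bands["green"] = refl(np.clip(0.15 - 0.06 * g10 + 0.02 * d10, 0.0, 1.0), config.cell_s2)
    bands["red"] = refl(np.clip(0.30 - 0.22 * g10, 0.01, 1.0), config.cell_s2)
    bands["nir"] = refl(np.clip(0.10 + 0.45 * g10, 0.0, 1.0), config.cell_s2)
    bands["rededge1"] = refl(np.clip(0.05 + 0.12 * g20, 0.0, 1.0), config.cell_s2_20)
    bands["swir1"] = refl(np.clip(0.32 - 0.05 * m20 - 0.10 * g20, 0.0, 1.0), config.cell_s2_20)
    bands["aerosols"] = refl(np.clip(0.02 + 0.008 * d60, 0.0, 1.0), config.cell_s2_60)

    # disturbance index and leaf-area proxy, 10 m
    tcdi = 0.5 * d10 + rng.normal(0.0, config.noise_tcdi, d10.shape)
    bands["tcdi"] = _grid_at(config, tcdi, config.cell_s2)
    seli = np.clip(1.5 * g10 + rng.normal(0.0, config.noise_seli, g10.shape), 0.0, None)
    bands["seli"] = _grid_at(config, seli, config.cell_s2)

    # land cover by deterministic thresholds on the latents
    lulc = np.full(h10.shape, LULC_CODES["bare"], dtype=float)
    low = h10 < 2.0
    veg = g10 >= 0.45
    lulc[low & veg & (m10 >= 0.0)] = LULC_CODES["grassland"]
    lulc[low & veg & (m10 < 0.0)] = LULC_CODES["cropland"]
    lulc[(h10 >= 2.0) & (h10 < 5.0)] = LULC_CODES["shrubland"]
    lulc[h10 >= 5.0] = LULC_CODES["trees"]
    lulc[(d10 > 1.8) & (h10 < 2.0)] = LULC_CODES["built"]
    lulc[(m10 > 2.2) & (h10 < 1.0)] = LULC_CODES["water"]
    bands["lulc"] = _grid_at(config, lulc, config.cell_s2)

    return bands


# ---------------------------------------------------------------------------
# truth
# ---------------------------------------------------------------------------

def _zscore(a: np.ndarray) -> np.ndarray:
    return (a - a.mean()) / a.std()


def _niche_logit(latents: LatentFields, coeffs: dict) -> np.ndarray:
    """Linear predictor (without intercept) of one genus's logistic niche."""
    z = {name: _zscore(grid.data) for name, grid in latents.as_dict().items()}
    eta = np.zeros_like(z["temperature"])
    for term, beta in coeffs.items():
        if not np.isfinite(beta):
            raise ConfigurationError(f"niche coefficient {term} is not finite")
        if term.endswith("_sq"):
            eta += beta * z[term[:-3]] ** 2
        else:
            eta += beta * z[term]
    return eta


def _calibrate_intercept(eta: np.ndarray, target: float,
                         tol: float = 1e-4, max_iter: int = 200) -> float:
    """Bisection on the intercept so that mean(expit(b0 + eta)) == target."""
    lo, hi = -40.0, 40.0
    if not (expit(lo + eta).mean() <= target <= expit(hi + eta).mean()):
        raise CalibrationError("target prevalence unreachable under coefficients")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if expit(mid + eta).mean() < target:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def make_truth(latents: LatentFields, config: SceneConfig) -> TruthLayer:
    """Occupancy probabilities and a seeded Bernoulli draw for both genera.

    Intercepts are auto-calibrated by bisection so the spatial mean of each
    probability surface matches the target prevalence to within 0.02.
    """
    config.validate()
    rng = np.random.default_rng(config.seeds()["truth"])
    out = {}
    for genus, coeffs, target in (
        ("e", config.niche_e, config.prevalence_e),
        ("s", config.niche_s, config.prevalence_s),
    ):
        eta = _niche_logit(latents, coeffs)
        b0 = _calibrate_intercept(eta, target)
        p = expit(b0 + eta)
        occ = (rng.random(p.shape) < p).astype(float)
        out["p_" + genus] = latents.temperature.like(p)
        out["occupancy_" + genus] = latents.temperature.like(occ)
    return TruthLayer(**out)


# ---------------------------------------------------------------------------
# plots
# ---------------------------------------------------------------------------

def _species_pool(config: SceneConfig, rng) -> pd.DataFrame:
    n = config.n_species_pool
    ln_sla = rng.normal(3.0, 0.35, n)
    # mesic species tend to carry thin, high-SLA leaves, so a plot's
    # cover-weighted SLA reflects its position on the moisture gradient
    moist_pref = 0.7 * (ln_sla - 3.0) / 0.35 + 0.71 * rng.normal(0.0, 1.0, n)
    pool = pd.DataFrame({
        "species_id": [f"sp{i:03d}" for i in range(n)],
        "SLA": np.exp(ln_sla),                        # cm^2 g^-1, ~20 typical
        "SM": np.exp(rng.normal(-4.5, 1.2, n)),       # g, small herb seeds
        "H": np.exp(rng.normal(0.0, 1.1, n)),         # m, herbs to trees
        "LDMC": np.exp(rng.normal(5.5, 0.25, n)),     # mg g^-1, imputation aid
        "native_flag": rng.random(n) < config.native_fraction,
        "moist_pref": moist_pref,                     # position on moisture axis
    })
    return pool


def sample_plots(truth: TruthLayer, latents: LatentFields,
                 config: SceneConfig) -> PlotData:
    """Place circular plots and emulate the vegetation survey on each.

    Plots are placed without replacement on 1-m cells, either uniformly at
    random or stratified over succession terciles. Species richness rises
    with succession; the community is assembled by trait matching, so
    community-weighted mean height tracks the height gradient and species
    turnover tracks the moisture and succession gradients. Genus labels are
    read off the occupancy truth at the plot centre.
    """
    config.validate()
    rng = np.random.default_rng(config.seeds()["plots"])
    grid = latents.succession
    ncell = grid.nrows * grid.ncols
    n = config.n_plots
    if n > ncell:
        raise ConfigurationError("more plots requested than grid cells")

    z_s = grid.data.ravel()
    if config.placement == "stratified":
        terciles = np.quantile(z_s, [1 / 3, 2 / 3])
        strata = np.digitize(z_s, terciles)
        idx_parts = []
        base, extra = divmod(n, 3)
        for s in range(3):
            cells = np.flatnonzero(strata == s)
            take = base + (1 if s < extra else 0)
            idx_parts.append(rng.choice(cells, size=take, replace=False))
        idx = np.concatenate(idx_parts)
    else:
        idx = rng.choice(ncell, size=n, replace=False)
    rows, cols = np.unravel_index(idx, grid.shape)

    pool = _species_pool(config, rng)
    ln_h_pool = np.log(pool["H"].to_numpy())
    moist_pref = pool["moist_pref"].to_numpy()

    plot_rows, cover_rows = [], []
    for k in range(n):
        r, c = int(rows[k]), int(cols[k])
        x, y = grid.cell_center(r, c)
        zs = latents.succession.data[r, c]
        zm = latents.moisture.data[r, c]
        h = latents.height.data[r, c]

        richness = 2 + rng.poisson(2.5 + 5.0 * expit(1.5 * zs))
        richness = min(richness, int(0.6 * len(pool)))
        mu_h = np.log(h + 0.3)
        w = np.exp(-((ln_h_pool - mu_h) ** 2) / (2 * 0.8 ** 2))
        w *= np.exp(-((moist_pref - zm) ** 2) / (2 * 0.8 ** 2))
        w /= w.sum()
        chosen = rng.choice(len(pool), size=richness, replace=False, p=w)
        covers = np.clip(np.exp(rng.normal(1.5, 0.8, richness)), 0.1, 90.0)

        plot_id = f"plot{k:04d}"
        plot_rows.append({
            "plot_id": plot_id, "x": x, "y": y, "area_m2": config.plot_area,
            "genusE_present": bool(truth.occupancy_e.data[r, c]),
            "genusS_present": bool(truth.occupancy_s.data[r, c]),
        })
        for sp, cov in zip(chosen, covers):
            cover_rows.append({
                "plot_id": plot_id,
                "species_id": pool["species_id"].iloc[sp],
                "cover_pct": float(cov),
            })

    return PlotData(
        plots=pd.DataFrame(plot_rows),
        cover=pd.DataFrame(cover_rows),
        species=pool,
    )


# ---------------------------------------------------------------------------
# assembly and I/O
# ---------------------------------------------------------------------------

def make_scene(config: SceneConfig | None = None) -> Scene:
    """Run all four generation stages under the one configuration."""
    config = config if config is not None else SceneConfig()
    latents = make_latent_fields(config)
    bands = make_bands(latents, config)
    truth = make_truth(latents, config)
    plots = sample_plots(truth, latents, config)
    return Scene(config, latents, bands, truth, plots)


def write_scene(scene: Scene, outdir) -> None:
    """Write rasters as ESRI ASCII grids and tables as CSV."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, obj in scene.bands.items():
        if isinstance(obj, RasterGrid):
            obj.write_ascii(out / f"{name}.asc")
        elif isinstance(obj, list):
            for d, g in enumerate(obj):
                g.write_ascii(out / f"{name}_{d:02d}.asc")
    for name, g in scene.latents.as_dict().items():
        g.write_ascii(out / f"latent_{name}.asc")
    scene.truth.p_e.write_ascii(out / "truth_p_e.asc")
    scene.truth.p_s.write_ascii(out / "truth_p_s.asc")

    # long plot table: one row per plot x species, as surveyed
    merged = scene.plots.cover.merge(scene.plots.species, on="species_id")
    merged = merged.merge(scene.plots.plots, on="plot_id")
    cols = ["plot_id", "x", "y", "species_id", "cover_pct", "native_flag",
            "SLA", "SM", "H", "genusE_present", "genusS_present"]
    merged[cols].to_csv(out / "plots_long.csv", index=False)
    scene.plots.plots.to_csv(out / "plots.csv", index=False)
    scene.plots.species.to_csv(out / "species_pool.csv", index=False)
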