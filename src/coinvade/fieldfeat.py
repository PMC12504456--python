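"""Plot-level field-data predictors: taxonomic, functional and successional.

From a vegetation survey (per-plot species covers) and a species trait
table (specific leaf area SLA, seed mass SM, maximal height H, nativity),
this module computes the field predictor set, each in an all-species
(``_all``) and a natives-only (``_nat``) variant:

* ``nbsp`` — species counts,
* ``SLA`` / ``SM`` / ``H`` — community-weighted mean (CWM) traits,
* ``FRic`` — functional richness, the convex-hull volume of the plot's
  species in trait space standardised over the *full species pool* (so
  hull volumes are comparable across plots and invariant to trait units),
* ``Succession`` — axis 1 of a nonmetric multidimensional scaling (NMDS)
  of the plots' presence-absence composition under Bray-Curtis distance,
  oriented to correlate positively with CWM height.

Plots where the FRic hull is degenerate get a missing value; those are
filled afterwards by a random-forest imputation trained on the remaining
field variables plus leaf dry matter content (the auxiliary trait is used
for imputation only).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr
from sklearn.ensemble import RandomForestRegressor
from sklearn.manifold import MDS

__all__ = [
    "species_counts", "cwm", "fric", "impute_fric", "succession_axis",
    "standardize_traits", "compute_plot_features",
]

TRAIT_COLUMNS = ["SLA", "SM", "H"]


class ZeroDistanceError(ValueError):
    """All plots are compositionally identical; no gradient exists."""


def _present(cover: pd.Series) -> pd.Index:
    """Species ids with cover > 0."""
    cov = cover[cover > 0]
    return cov.index


def species_counts(cover: pd.Series, traits: pd.DataFrame) -> tuple[int, int]:
    """(all-species, natives-only) counts of species with cover > 0.

    ``cover`` is indexed by species_id; ``traits`` is indexed by species_id
    with a boolean ``native_flag`` column.
    """
    if (cover < 0).any():
        raise ValueError("cover values must be nonnegative")
    present = _present(cover)
    native = traits.loc[present, "native_flag"].astype(bool)
    return len(present), int(native.sum())


def cwm(cover: pd.Series, traits: pd.DataFrame, trait: str,
        natives_only: bool = False) -> float:
    """Cover-weighted mean of one trait over a plot's species.

    Species with a missing trait value are dropped from the weighting
    (reference-implementation behaviour). Returns NaN when no species is
    eligible — the sentinel propagates to imputation rather than raising.
    """
    present = _present(cover)
    sub = traits.loc[present]
    if natives_only:
        sub = sub[sub["native_flag"].astype(bool)]
    vals = sub[trait]
    keep = vals.notna()
    sub, vals = sub[keep], vals[keep]
    if len(sub) == 0:
        return float("nan")
    w = cover.loc[sub.index].to_numpy(float)
    return float(np.average(vals.to_numpy(float), weights=w))


def standardize_traits(traits: pd.DataFrame,
                       columns: list[str] = TRAIT_COLUMNS) -> pd.DataFrame:
    """Center/scale trait columns over the full species pool.

    Standardising over the pool (not per plot) keeps plot hull volumes
    comparable and makes FRic invariant to a change of trait units.
    """
    out = traits[columns].copy().astype(float)
    for c in columns:
        v = out[c]
        out[c] = (v - v.mean()) / v.std(ddof=0)
    return out


def _hull_volume(points: np.ndarray) -> float:
    """Convex-hull volume with principal-axis reduction for thin point sets.

    When the number of points does not exceed the trait-space
    dimensionality, the cloud is rotated onto its ``npts - 1`` leading
    principal axes so that points >= axes + 1, mirroring the
    axis-reduction of the standard functional-diversity tooling (a 1-D
    reduction degenerates gracefully to the range). A point set that is
    degenerate *within* full-rank trait space (e.g. collinear species with
    three trait axes available) yields a missing value.
    """
    pts = np.asarray(points, dtype=float)
    npts, ndim = pts.shape
    if npts < 2:
        return float("nan")

    def try_hull(p):
        if p.shape[1] == 1:
            rng_ = p.max() - p.min()
            return float(rng_) if rng_ > 0 else float("nan")
        try:
            return float(ConvexHull(p).volume)
        except QhullError:
            return float("nan")

    if npts > ndim:
        return try_hull(pts)
    # too few points for the full space: reduce to leading principal axes
    centered = pts - pts.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    rank = int(np.sum(s > 1e-10 * max(s[0], 1e-300)))
    axes = min(rank, npts - 1)
    if axes < 1:
        return float("nan")
    return try_hull(centered @ vt[:axes].T)


def fric(cover: pd.Series, traits_std: pd.DataFrame, traits: pd.DataFrame,
         natives_only: bool = False) -> float:
    """Functional richness of one plot: hull volume in standardised trait space.

    ``traits_std`` holds pool-standardised trait values (see
    :func:`standardize_traits`); ``traits`` supplies nativity flags.
    Species missing any trait are dropped; fewer than 2 usable species or a
    degenerate hull yield NaN rather than an exception.
    """
    present = _present(cover)
    if natives_only:
        present = present[traits.loc[present, "native_flag"].astype(bool)]
    pts = traits_std.loc[present].dropna()
    if len(pts) < 2:
        return float("nan")
    return _hull_volume(pts.to_numpy(float))


def impute_fric(features: pd.DataFrame, seed: int = 0,
                targets: tuple[str, ...] = ("FRic_all", "FRic_nat"),
                predictors: list[str] | None = None,
                ) -> tuple[pd.DataFrame, dict]:
    """Fill missing FRic values by random-forest regression.

    The forest is trained on rows with observed FRic, using the remaining
    field variables (plus the auxiliary leaf-dry-matter CWM when present)
    as predictors; the out-of-bag R^2 is reported per target. Imputed rows
    are flagged in ``FRic_imputed``; a table without missing values is
    returned unchanged (aside from the flag column).
    """
    out = features.copy()
    if predictors is None:
        skip = set(targets) | {"FRic_imputed", "Succession"}
        predictors = [
            c for c in out.columns
            if c not in skip and pd.api.types.is_numeric_dtype(out[c])
        ]
    info: dict = {"predictors": list(predictors), "r2": {}}
    flag = pd.Series(False, index=out.index)
    for target in targets:
        if target not in out.columns:
            continue
        missing = out[target].isna()
        if not missing.any():
            info["r2"][target] = None
            continue
        if missing.all():
            raise ValueError(f"all values of {target} are missing; cannot impute")
        X = out.loc[~missing, predictors].to_numpy(float)
        y = out.loc[~missing, target].to_numpy(float)
        rf = RandomForestRegressor(
            n_estimators=500, oob_score=True, random_state=seed, n_jobs=1,
        )
        rf.fit(X, y)
        out.loc[missing, target] = rf.predict(
            out.loc[missing, predictors].to_numpy(float))
        flag |= missing
        info["r2"][target] = float(rf.oob_score_)
    out["FRic_imputed"] = flag
    return out, info


def succession_axis(presence: pd.DataFrame, n_restarts: int = 20,
                    seed: int = 0, orient_by: pd.Series | None = None,
                    ) -> tuple[pd.Series, float]:
    """Axis-1 scores of a 2-D NMDS of plot presence-absence composition.

    ``presence`` is a plots x species 0/1 matrix. Distances are
    Bray-Curtis (equal to Sorensen dissimilarity on presence-absence
    data). The stress-minimising embedding over ``n_restarts`` random
    starts is kept; returns ``(axis1 scores, stress)``.

    The NMDS solution is sign-indeterminate; when ``orient_by`` is given
    (conventionally CWM height), the axis is flipped so the scores
    correlate positively with it.
    """
    mat = presence.to_numpy(float)
    if mat.shape[0] < 3 or mat.shape[1] < 2:
        raise ValueError("need at least 3 plots and 2 species")
    d = squareform(pdist(mat, metric="braycurtis"))
    if np.allclose(d, 0):
        raise ZeroDistanceError("all plots are compositionally identical")
    mds = MDS(
        n_components=2, metric_mds=False, metric="precomputed",
        n_init=n_restarts, random_state=seed, max_iter=300,
        normalized_stress=True, init="random",
    )
    coords = mds.fit_transform(d)
    # align the embedding's major axis with component 1
    coords = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords, full_matrices=False)
    axis1 = coords @ vt[0]
    scores = pd.Series(axis1, index=presence.index, name="Succession")
    if orient_by is not None:
        ob = pd.Series(orient_by).reindex(presence.index)
        ok = ob.notna()
        if ok.sum() >= 3 and scores[ok].std() > 0 and ob[ok].std() > 0:
            r, _ = pearsonr(scores[ok], ob[ok])
            if r < 0:
                scores = -scores
    return scores, float(mds.stress_)


def compute_plot_features(plot_data, seed: int = 0,
                          impute: bool = True) -> tuple[pd.DataFrame, dict]:
    """Full field-feature table for a surveyed scene, one row per plot.

    ``plot_data`` is a :class:`~coinvade.synthgen.PlotData`-like object with
    ``plots``, ``cover`` and ``species`` tables. Returns the feature table
    (indexed by plot_id, including genus labels and coordinates) and a log
    dict (imputation R^2, NMDS stress).
    """
    traits = plot_data.species.set_index("species_id")
    traits_std = standardize_traits(traits)
    cover_wide = plot_data.cover.pivot_table(
        index="plot_id", columns="species_id", values="cover_pct",
        aggfunc="sum", fill_value=0.0,
    )
    plot_ids = plot_data.plots["plot_id"]
    cover_wide = cover_wide.reindex(plot_ids, fill_value=0.0)

    rows = []
    for pid in plot_ids:
        cov = cover_wide.loc[pid]
        n_all, n_nat = species_counts(cov, traits)
        row = {"plot_id": pid, "nbsp_all": n_all, "nbsp_nat": n_nat}
        for tr in TRAIT_COLUMNS:
            row[f"{tr}_all"] = cwm(cov, traits, tr, natives_only=False)
            row[f"{tr}_nat"] = cwm(cov, traits, tr, natives_only=True)
        if "LDMC" in traits.columns:
            row["LDMC_all"] = cwm(cov, traits, "LDMC", natives_only=False)
        row["FRic_all"] = fric(cov, traits_std, traits, natives_only=False)
        row["FRic_nat"] = fric(cov, traits_std, traits, natives_only=True)
        rows.append(row)
    feats = pd.DataFrame(rows).set_index("plot_id")

    presence = (cover_wide > 0).astype(float)
    scores, stress = succession_axis(
        presence, seed=seed, orient_by=feats["H_all"])
    feats["Succession"] = scores

    log = {"nmds_stress": stress}
    if impute:
        feats, info = impute_fric(feats, seed=seed)
        log["fric_imputation"] = info
    meta = plot_data.plots.set_index("plot_id")
    feats = feats.join(meta[["x", "y", "genusE_present", "genusS_present"]])
    return feats, log
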