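"""End-to-end orchestration: scene -> features -> models -> maps.

Thin glue over the stage modules, used by the command-line interface and
by reproduction scripts. The flow mirrors the two-part study design:

1. fuse field + remote-sensing features at the plots and train per-genus
   classifiers (model comparison / ordination stage);
2. train remote-sensing-only classifiers on all plots, pick the
   sensitivity/specificity-balanced threshold per genus from the CV
   held-out probabilities, predict every 5-m landmark pixel and intersect
   the binary masks into the co-invasion layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import classify, fieldfeat, mapping, rsfeat
from .grid import RasterGrid
from .synthgen import Scene

__all__ = [
    "rs_feature_layers", "plot_feature_table", "rs_plot_table",
    "landmark_feature_table",
    "run_mapping_stage", "MappingStage", "FD_VARIABLES",
]

FD_VARIABLES = [
    "nbsp_all", "nbsp_nat", "FRic_all", "FRic_nat", "SLA_all", "SLA_nat",
    "SM_all", "SM_nat", "H_all", "H_nat", "Succession",
]


def rs_feature_layers(scene: Scene) -> dict:
    """The 16 derived remote-sensing predictor layers of a scene."""
    return rsfeat.derive_layers(scene.bands)


def plot_feature_table(scene: Scene, layers: dict | None = None,
                       seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Fused FD + RS feature table at the field plots, with genus labels."""
    layers = layers if layers is not None else rs_feature_layers(scene)
    fd, log = fieldfeat.compute_plot_features(scene.plots, seed=seed)
    pts = fd.reset_index()[["plot_id", "x", "y"]]
    rs = rsfeat.extract_at(pts, layers)
    rs.index = pts["plot_id"]
    fused = fd.join(rs[rsfeat.RS_VARIABLES])
    return fused, log


def rs_plot_table(scene: Scene, layers: dict | None = None) -> pd.DataFrame:
    """RS features at the field plots with genus labels (no field features).

    The mapping stage uses remote-sensing predictors only, so the costly
    plot-level field metrics are skipped here.
    """
    layers = layers if layers is not None else rs_feature_layers(scene)
    pts = scene.plots.plots[["plot_id", "x", "y"]]
    rs = rsfeat.extract_at(pts, layers)
    rs.index = pts["plot_id"].to_numpy()
    labels = scene.plots.plots.set_index("plot_id")
    return rs[rsfeat.RS_VARIABLES].join(
        labels[["genusE_present", "genusS_present"]])


def landmark_feature_table(scene: Scene, layers: dict | None = None,
                           ) -> tuple[pd.DataFrame, RasterGrid]:
    """RS features at every 5-m landmark pixel, plus the 5-m template grid."""
    layers = layers if layers is not None else rs_feature_layers(scene)
    template = layers["CHMmean"]
    site_mask = template.like(np.ones(template.shape))
    pts = rsfeat.landmarks(site_mask)
    feats = rsfeat.extract_at(pts, layers)
    return feats, template


@dataclass
class MappingStage:
    model_e: classify.TrainedModel
    model_s: classify.TrainedModel
    threshold_e: mapping.ThresholdResult
    threshold_s: mapping.ThresholdResult
    suitability: mapping.SuitabilityMap


def run_mapping_stage(scene: Scene, learner: str = "gbm", seed: int = 0,
                      n_folds: int = 10, n_repeats: int = 10,
                      layers: dict | None = None,
                      grid: dict | None = None) -> MappingStage:
    """RS-only final models on all plots, thresholds, and the 5-m maps."""
    layers = layers if layers is not None else rs_feature_layers(scene)
    feats = rs_plot_table(scene, layers)
    X = feats[rsfeat.RS_VARIABLES]
    ss = np.random.SeedSequence(seed)
    seed_e, seed_s = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))

    model_e = classify.train_tuned(
        X, feats["genusE_present"], learner, grid=grid,
        n_folds=n_folds, n_repeats=n_repeats, seed=seed_e)
    model_s = classify.train_tuned(
        X, feats["genusS_present"], learner, grid=grid,
        n_folds=n_folds, n_repeats=n_repeats, seed=seed_s)

    thr_e = mapping.select_threshold(model_e.cv_predictions, genus="E")
    thr_s = mapping.select_threshold(model_s.cv_predictions, genus="S")

    lmk, template = landmark_feature_table(scene, layers)
    smap = mapping.predict_map(model_e, model_s, lmk, template,
                               thr_e.mean, thr_s.mean)
    return MappingStage(model_e=model_e, model_s=model_s,
                        threshold_e=thr_e, threshold_s=thr_s,
                        suitability=smap)
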