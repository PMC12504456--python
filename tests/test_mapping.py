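"""Threshold selection, suitability maps, land cover and contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coinvade.grid import RasterGrid
from coinvade import mapping
from coinvade.classify import TrainedModel
from coinvade.mapping import (
    THRESHOLD_GRID, SuitabilityMap, class_presence, coverage, group_contrast,
    histogram_report, predict_map, reclassify_lulc, select_threshold,
)


def cv_frame(probs, labels, repeat=0, fold=0):
    return pd.DataFrame({"repeat": repeat, "fold": fold,
                         "prob": probs, "label": labels})


def mask_grid(data):
    data = np.asarray(data, dtype=float)
    return RasterGrid(data, xmin=0.0, ymax=data.shape[0] * 5.0, cell=5.0)


def make_map(mask_e, mask_s, p_e=None, p_s=None, te=0.5, ts=0.5):
    me, ms = mask_grid(mask_e), mask_grid(mask_s)
    co = np.where(np.isnan(me.data) | np.isnan(ms.data), np.nan,
                  ((me.data == 1) & (ms.data == 1)).astype(float))
    pe = mask_grid(p_e) if p_e is not None else me.like(me.data * 0.9)
    ps = mask_grid(p_s) if p_s is not None else ms.like(ms.data * 0.9)
    return SuitabilityMap(p_e=pe, p_s=ps, mask_e=me, mask_s=ms,
                          mask_co=me.like(co), threshold_e=te, threshold_s=ts)


# ---------------------------------------------------------------------------
# threshold selection
# ---------------------------------------------------------------------------

def test_threshold_grid_has_exactly_100_candidates():
    assert len(THRESHOLD_GRID) == 100
    assert THRESHOLD_GRID[0] == 0.01 and THRESHOLD_GRID[-1] == 1.0


def test_separable_scores_tie_break_to_smallest_qualifying():
    pred = cv_frame([0.9] * 5 + [0.1] * 5, [True] * 5 + [False] * 5)
    assert select_threshold(pred).mean == pytest.approx(0.11)


def test_exact_labels_select_first_threshold():
    pred = cv_frame([1.0] * 4 + [0.0] * 4, [True] * 4 + [False] * 4)
    assert select_threshold(pred).mean == pytest.approx(0.01)


def test_single_class_resample_skipped_with_warning():
    good = cv_frame([0.8, 0.7, 0.2], [True, True, False], fold=0)
    bad = cv_frame([0.9, 0.8], [True, True], fold=1)
    with pytest.warns(UserWarning):
        res = select_threshold(pd.concat([good, bad]))
    assert len(res.per_resample) == 1


def test_all_single_class_is_an_error():
    with pytest.raises(ValueError):
        select_threshold(cv_frame([0.9, 0.8], [True, True]))


def exhaustive_oracle(probs, labels):
    y = np.asarray(labels, bool)
    best_t, best_diff = None, np.inf
    for t in THRESHOLD_GRID:
        pred = np.asarray(probs) >= t
        se = np.sum(pred & y) / y.sum()
        sp = np.sum(~pred & ~y) / (~y).sum()
        if abs(se - sp) < best_diff - 1e-15:
            best_diff, best_t = abs(se - sp), t
    return best_t


def test_threshold_agrees_with_exhaustive_oracle():
    for seed in range(20):
        rng = np.random.default_rng(seed)
        probs = rng.random(60)
        labels = rng.random(60) < 0.4
        if labels.all() or not labels.any():
            continue
        res = select_threshold(cv_frame(probs, labels))
        assert res.mean == pytest.approx(exhaustive_oracle(probs, labels))


def test_calibrated_scores_recover_balanced_threshold():
    """Positives ~ U(0.4, 1), negatives ~ U(0, 0.6): balance sits near 0.5."""
    means = []
    for seed in range(50):
        rng = np.random.default_rng(seed)
        n_pos = 200
        probs = np.concatenate([rng.uniform(0.4, 1.0, n_pos),
                                rng.uniform(0.0, 0.6, 400 - n_pos)])
        labels = np.arange(400) < n_pos
        means.append(select_threshold(cv_frame(probs, labels)).mean)
    assert abs(np.mean(means) - 0.5) < 0.05


def test_threshold_mean_within_resample_range():
    rng = np.random.default_rng(3)
    frames = []
    for f in range(5):
        frames.append(cv_frame(rng.random(40), rng.random(40) < 0.5, fold=f))
    res = select_threshold(pd.concat(frames))
    assert res.per_resample.min() <= res.mean <= res.per_resample.max()


# ---------------------------------------------------------------------------
# map prediction
# ---------------------------------------------------------------------------

class _Fixed:
    def __init__(self, prob):
        self.prob = prob

    def predict_proba(self, M):
        p = np.full(len(M), self.prob)
        return np.column_stack([1 - p, p])


def fixed_model(prob, features=("f",)):
    X = pd.DataFrame({f: [0.0] for f in features})
    return TrainedModel(
        learner="gbm", feature_names=list(features), best_params={},
        cv_grid=pd.DataFrame(), cv_records=pd.DataFrame(),
        cv_predictions=pd.DataFrame(), cv_auc_mean=np.nan, cv_auc_sd=0.0,
        model=_Fixed(prob), scaler=None, X_train=X,
        y_train=np.array([True]),
    )


def landmark_frame(template):
    xs, ys = template.centers()
    return pd.DataFrame({"x": xs, "y": ys, "f": 0.0})


def test_published_thresholds_classify_half_probability_as_coinvaded():
    template = mask_grid(np.zeros((2, 2)))
    smap = predict_map(fixed_model(0.5), fixed_model(0.5),
                       landmark_frame(template), template,
                       threshold_e=0.457, threshold_s=0.387)
    assert (smap.mask_co.data == 1).all()


def test_subthreshold_probability_empties_the_intersection():
    template = mask_grid(np.zeros((2, 2)))
    smap = predict_map(fixed_model(0.2), fixed_model(0.9),
                       landmark_frame(template), template, 0.457, 0.387)
    assert (smap.mask_e.data == 0).all()
    assert (smap.mask_co.data == 0).all()


def test_intersection_is_elementwise_and():
    smap = make_map([[1, 0], [1, 1]], [[1, 1], [0, 1]])
    np.testing.assert_array_equal(smap.mask_co.data, [[1, 0], [0, 1]])


def test_missing_features_become_nodata_everywhere():
    template = mask_grid(np.zeros((2, 2)))
    lmk = landmark_frame(template)
    lmk.loc[0, "f"] = np.nan
    smap = predict_map(fixed_model(0.9), fixed_model(0.9), lmk, template,
                       0.5, 0.5)
    assert np.isnan(smap.p_e.data.ravel()[0])
    assert np.isnan(smap.mask_co.data.ravel()[0])
    assert (smap.mask_co.data.ravel()[1:] == 1).all()


def test_raising_threshold_never_enlarges_mask():
    rng = np.random.default_rng(1)
    template = mask_grid(np.zeros((6, 6)))
    lmk = landmark_frame(template)
    probs = rng.random(len(lmk))

    class _Var:
        def predict_proba(self, M):
            return np.column_stack([1 - probs, probs])

    model = fixed_model(0.5)
    model.model = _Var()
    prev = None
    for t in (0.2, 0.4, 0.6, 0.8):
        smap = predict_map(model, model, lmk, template, t, t)
        cur = smap.mask_e.data == 1
        if prev is not None:
            assert not (cur & ~prev).any()
        prev = cur


# ---------------------------------------------------------------------------
# coverage accounting
# ---------------------------------------------------------------------------

def counts_map(n_e, n_s, n_co, shape):
    """A map with exact positive-pixel counts (co subset of both)."""
    total = shape[0] * shape[1]
    e = np.zeros(total)
    s = np.zeros(total)
    e[:n_e] = 1
    s[:n_co] = 1
    s[n_e:n_e + (n_s - n_co)] = 1
    return make_map(e.reshape(shape), s.reshape(shape))


def test_coverage_reproduces_published_style_percentages():
    # 28.2 ha co-invaded of a 167.44-ha site -> 16.8%
    smap = counts_map(n_e=13560, n_s=51440, n_co=11280, shape=(260, 260))
    cov = coverage(smap, 167.44)
    assert cov.loc["E", "hectares"] == pytest.approx(33.9)
    assert cov.loc["co_invasion", "hectares"] == pytest.approx(28.2)
    assert round(cov.loc["co_invasion", "pct_of_site"], 1) == 16.8
    assert round(cov.loc["E", "pct_of_site"], 1) == 20.2


def test_coverage_second_site_arithmetic():
    smap = counts_map(n_e=19000, n_s=14240, n_co=5720, shape=(220, 220))
    cov = coverage(smap, 114.39)
    assert cov.loc["E", "hectares"] == pytest.approx(47.5)
    assert round(cov.loc["E", "pct_of_site"], 1) == 41.5
    assert round(cov.loc["co_invasion", "pct_of_site"], 1) == 12.5


def test_empty_masks_give_zero_coverage():
    smap = make_map(np.zeros((4, 4)), np.zeros((4, 4)))
    cov = coverage(smap, 10.0)
    assert (cov["hectares"] == 0).all()
    assert (cov["pct_of_site"] == 0).all()


def test_coinvasion_hectares_bounded_by_each_genus():
    rng = np.random.default_rng(2)
    smap = make_map(rng.random((10, 10)) < 0.5, rng.random((10, 10)) < 0.5)
    cov = coverage(smap, 2.5)
    assert cov.loc["co_invasion", "hectares"] <= min(
        cov.loc["E", "hectares"], cov.loc["S", "hectares"])


def test_area_accounting_closes():
    rng = np.random.default_rng(6)
    smap = make_map(rng.random((12, 12)) < 0.4, rng.random((12, 12)) < 0.6)
    e = smap.mask_e.data == 1
    s = smap.mask_s.data == 1
    co = smap.mask_co.data == 1
    n_only_e = np.sum(e & ~s)
    n_only_s = np.sum(s & ~e)
    n_neither = np.sum(~e & ~s)
    assert n_only_e + n_only_s + np.sum(co) + n_neither == e.size


# ---------------------------------------------------------------------------
# land cover
# ---------------------------------------------------------------------------

def test_all_trees_reclassify_to_high_vegetation():
    g = mask_grid(np.ones((3, 3)))  # code 1 = trees
    out = reclassify_lulc(g)
    assert (out.data == 1).all()


def test_reclassification_partitions_pixels():
    rng = np.random.default_rng(3)
    codes = rng.choice([0, 1, 2, 3, 4, 5, 6, 7], size=(10, 10))
    out = reclassify_lulc(mask_grid(codes))
    assert (~np.isnan(out.data)).sum() == codes.size
    # flooded vegetation (3) folds into low vegetation (2)
    assert (out.data[codes == 3] == 2).all()


def test_snow_ice_excluded_and_unknown_code_rejected():
    out = reclassify_lulc(mask_grid([[8.0, 1.0]]))
    assert np.isnan(out.data[0, 0])
    with pytest.raises(ValueError, match="99"):
        reclassify_lulc(mask_grid([[99.0]]))


def test_class_presence_toy_counts():
    lulc = mask_grid([[1, 1], [7, 6]])          # trees, trees, bare, built
    broad = reclassify_lulc(lulc)
    smap = make_map([[1, 0], [1, 0]], [[1, 1], [0, 0]])
    pres = class_presence(smap, broad)
    assert pres.loc["high_vegetation", "E"] == pytest.approx(50.0)
    assert pres.loc["high_vegetation", "S"] == pytest.approx(100.0)
    assert pres.loc["high_vegetation", "co_invasion"] == pytest.approx(50.0)
    assert pres.loc["bare_ground", "E"] == pytest.approx(100.0)
    assert pres.loc["built_area", "S"] == pytest.approx(0.0)
    assert np.isnan(pres.loc["water", "E"])


def test_class_presence_containment_and_intersection_bound():
    rng = np.random.default_rng(4)
    codes = rng.choice([1, 2, 6, 7], size=(8, 8)).astype(float)
    broad = reclassify_lulc(mask_grid(codes))
    smap = make_map(rng.random((8, 8)) < 0.5, rng.random((8, 8)) < 0.5)
    pres = class_presence(smap, broad)
    ok = pres.dropna()
    assert (ok["co_invasion"] <= ok[["E", "S"]].min(axis=1) + 1e-9).all()
    # mask equal to a class extent -> 100% presence there
    smap2 = make_map((codes == 1).astype(float), np.zeros((8, 8)))
    pres2 = class_presence(smap2, broad)
    assert pres2.loc["high_vegetation", "E"] == pytest.approx(100.0)


# ---------------------------------------------------------------------------
# contrasts
# ---------------------------------------------------------------------------

def test_identical_groups_null_contrast():
    res = group_contrast([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res["cohens_d"] == pytest.approx(0.0)
    assert res["p"] == pytest.approx(1.0)


def test_unit_effect_size():
    res = group_contrast([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
    assert res["cohens_d"] == pytest.approx(1.0)
    assert res["mean_a"] > res["mean_b"]  # positive d: first group larger


def test_zero_variance_contrast_undefined():
    res = group_contrast([2.0, 2.0], [2.0, 2.0])
    assert np.isnan(res["cohens_d"]) and np.isnan(res["p"])


def test_welch_p_agrees_with_permutation_test():
    rng = np.random.default_rng(5)
    a = rng.normal(0.0, 1.0, 60)
    b = rng.normal(0.35, 2.0, 40)
    res = group_contrast(a, b)
    perm = stats.permutation_test(
        (a, b), lambda x, y, axis=-1: (
            (np.mean(x, axis=axis) - np.mean(y, axis=axis))
            / np.sqrt(np.var(x, ddof=1, axis=axis) / x.shape[axis]
                      + np.var(y, ddof=1, axis=axis) / y.shape[axis])),
        n_resamples=4000, alternative="two-sided", random_state=0,
        vectorized=True)
    assert abs(res["p"] - perm.pvalue) < 0.05


def test_group_needs_two_values():
    with pytest.raises(ValueError):
        group_contrast([1.0], [1.0, 2.0])


# ---------------------------------------------------------------------------
# histograms
# ---------------------------------------------------------------------------

def test_histogram_full_mask_equals_site_distribution():
    rng = np.random.default_rng(6)
    smap = make_map(np.ones((6, 6)), np.ones((6, 6)))
    layer = mask_grid(rng.normal(size=(6, 6)))
    rep = histogram_report(smap, {"v": layer})
    np.testing.assert_array_equal(rep["v"]["counts"]["site"],
                                  rep["v"]["counts"]["E"])
    assert rep["v"]["means"]["E"] == pytest.approx(layer.data.mean())


def test_coinvasion_mean_between_genus_means_on_nested_fixture():
    # values increase left to right; E holds the left half plus the middle,
    # S the middle plus the right half, so co-invasion = middle strip
    vals = np.tile(np.arange(8.0), (8, 1))
    e = np.zeros((8, 8)); e[:, :6] = 1
    s = np.zeros((8, 8)); s[:, 2:] = 1
    smap = make_map(e, s)
    rep = histogram_report(smap, {"v": mask_grid(vals)})
    m = rep["v"]["means"]
    lo, hi = sorted([m["E"], m["S"]])
    assert lo <= m["co_invasion"] <= hi


def test_histogram_panels_written_to_file(tmp_path):
    rng = np.random.default_rng(7)
    smap = make_map(rng.random((6, 6)) < 0.5, rng.random((6, 6)) < 0.5)
    rep = histogram_report(smap, {"v": mask_grid(rng.normal(size=(6, 6)))})
    out = tmp_path / "panels.png"
    mapping.plot_histogram_panels(rep, out)
    assert out.stat().st_size > 0
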