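import numpy as np
import pytest

import nichedyn as nd
from nichedyn.sdm import (SuitabilityMap, expand_features,
                          sample_background_cells)


def test_expand_features_layout():
    X = np.array([[1.0, 2.0, 3.0]])
    F = expand_features(X)
    # 3 linear + 3 quadratic + 3 products
    np.testing.assert_allclose(F[0], [1, 2, 3, 1, 4, 9, 2, 3, 6])


def _gaussian_sets(sep, n=100, m=400, seed=0):
    rng = np.random.default_rng(seed)
    pres = rng.standard_normal((n, 2)) * 0.5
    pres[:, 0] += sep
    bkg = rng.standard_normal((m, 2))
    return pres, bkg


def test_fit_model_validation():
    pres, bkg = _gaussian_sets(0.0)
    with pytest.raises(ValueError):
        nd.fit_model(pres[:5], bkg)
    with pytest.raises(ValueError):
        nd.fit_model(pres, bkg[:50])


def test_separable_model_auc_and_replicates():
    pres, bkg = _gaussian_sets(5.0)
    model = nd.fit_model(pres, bkg, n_replicates=5, seed=0)
    assert len(model.replicates) == 5
    assert model.auc_test >= 0.95
    assert model.predict(pres).mean() > model.predict(bkg).mean()


def test_clamping_contract():
    pres, bkg = _gaussian_sets(2.0)
    model = nd.fit_model(pres, bkg, n_replicates=3, seed=1)
    out = np.array([[50.0, -40.0], [-30.0, 80.0]])
    clipped = np.clip(out, model.clamp_min, model.clamp_max)
    np.testing.assert_allclose(model.predict(out, clamp=True),
                               model.predict(clipped, clamp=False))


def test_project_onto_training_region(identical_world):
    w = identical_world
    stack = w["stacks"]["A"]
    pres = w["env"]["A"].values
    bkg = sample_background_cells(stack, 2000, seed=0)
    model = nd.fit_model(pres, bkg, variables=stack.variables,
                         n_replicates=3, seed=0)
    cont = nd.project(model, stack)
    mask = stack.land_mask()
    assert cont.shape == stack.shape
    assert np.isnan(cont[~mask]).all() if (~mask).any() else True
    assert np.nanmin(cont) >= 0 and np.nanmax(cont) <= 1
    # suitability at the presences beats the regional average
    at_pres = model.predict(pres)
    assert at_pres.mean() > np.nanmean(cont)
    with pytest.raises(ValueError):
        bad = nd.SDMModel(variables=["nope"], clamp_min=np.zeros(1),
                          clamp_max=np.ones(1), feat_center=np.zeros(2),
                          feat_scale=np.ones(2))
        nd.project(bad, stack)


def _brute_force_sss(sp, sb):
    cand = np.unique(np.r_[sp, sb])
    best, best_t = -np.inf, None
    for t in cand:
        score = (sp >= t).mean() + (sb < t).mean()
        if score > best:
            best, best_t = score, t
    return best_t


def test_max_sss_separable_and_chance():
    sp = np.full(10, 0.9)
    sb = np.full(20, 0.1)
    assert nd.max_sss_threshold(sp, sb) == 0.9
    rng = np.random.default_rng(0)
    same = rng.random(500)
    t = nd.max_sss_threshold(same, same)
    sens = (same >= t).mean(); spec = (same < t).mean()
    assert sens + spec == pytest.approx(1.0, abs=0.01)


def test_max_sss_matches_brute_force():
    rng = np.random.default_rng(1)
    for _ in range(20):
        sp = rng.random(rng.integers(5, 60))
        sb = rng.random(rng.integers(5, 60))
        assert nd.max_sss_threshold(sp, sb) == _brute_force_sss(sp, sb)


def test_max_sss_identical_scores_warns():
    with pytest.warns(UserWarning, match="identical"):
        assert nd.max_sss_threshold(np.full(3, 0.5), np.full(3, 0.5)) == 0.5


def _toy_map():
    cont = np.array([[0.9, 0.2, np.nan],
                     [0.8, 0.1, 0.3],
                     [0.05, 0.95, 0.4]])
    return SuitabilityMap(region="t", continuous=cont, threshold=0.5,
                          west=0.0, north=3.0, cell_size=1.0)


def test_percent_correctly_predicted_hand_count():
    smap = _toy_map()
    # binary: suitable at (0,0), (1,0), (2,1); NaN at (0,2)
    occ = nd.OccurrenceSet("r",
                           lon=[0.5, 0.5, 1.5, 2.5],
                           lat=[2.5, 1.5, 0.5, 2.5])
    # cells: (0,0) suitable, (1,0) suitable, (2,1) suitable, (0,2) NoData
    # -> 3 suitable of 3 valid = 100
    assert nd.percent_correctly_predicted(smap, occ) == pytest.approx(100.0)
    occ2 = nd.OccurrenceSet("r", lon=[1.5, 1.5, 2.5, 0.5],
                            lat=[2.5, 1.5, 1.5, 0.5])
    # cells (0,1) 0.2, (1,1) 0.1, (1,2) 0.3, (2,0) 0.05 -> all unsuitable
    assert nd.percent_correctly_predicted(smap, occ2) == pytest.approx(0.0)
    occ3 = nd.OccurrenceSet("r", lon=[0.5, 0.5, 1.5, 2.5],
                            lat=[2.5, 1.5, 1.5, 0.5])
    # suitable, suitable, unsuitable, unsuitable -> 50%
    assert nd.percent_correctly_predicted(smap, occ3) == pytest.approx(50.0)


def test_percent_correctly_predicted_errors_without_valid_points():
    smap = _toy_map()
    occ = nd.OccurrenceSet("r", lon=[10.0], lat=[10.0])
    with pytest.raises(ValueError):
        nd.percent_correctly_predicted(smap, occ)


def test_binary_map_contract():
    smap = _toy_map()
    b = smap.binary
    assert np.isnan(b[0, 2])
    assert b[0, 0] == 1.0 and b[1, 1] == 0.0


def test_sample_background_cells(toy_stack):
    vals = sample_background_cells(toy_stack, n=100, seed=0)
    assert vals.shape == (100, 2)
    assert not np.isnan(vals).any()


def test_reciprocal_matrix_nested(identical_world):
    w = identical_world
    df = nd.reciprocal_matrix(w["stacks"], w["occs"], n_replicates=3,
                              n_background=1500, seed=0)
    assert len(df) == 4
    assert set(df.columns) >= {"calibration", "projection", "auc_mean",
                               "auc_sd", "threshold", "pct_predicted"}
    assert ((df["pct_predicted"] >= 0) & (df["pct_predicted"] <= 100)).all()
    # identical niches: reciprocal prediction succeeds both ways
    off = df[df.calibration != df.projection]
    assert (off["pct_predicted"] > 50).all()
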