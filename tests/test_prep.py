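import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nichedyn as nd
from nichedyn.prep import EnvTable, correlation_groups, occurrence_cells


def test_thinning_hand_trace():
    # Points at 0.00, 0.05, 0.09, 0.13 on a line with min_sep 0.05:
    # keep 0.00; keep 0.05 (d=0.05); drop 0.09 (0.04 from 0.05);
    # keep 0.13 (0.08 from 0.05, 0.13 from 0.00).
    occ = nd.OccurrenceSet("r", lon=[0.0, 0.05, 0.09, 0.13],
                           lat=[0.0, 0.0, 0.0, 0.0])
    thinned = nd.thin_occurrences(occ, 0.05)
    assert thinned.lon.tolist() == [0.0, 0.05, 0.13]
    assert thinned.thinned and thinned.min_sep == 0.05


def test_thinning_zero_sep_keeps_all():
    occ = nd.OccurrenceSet("r", lon=[0, 0, 1], lat=[0, 0, 0])
    assert len(nd.thin_occurrences(occ, 0.0)) == 3


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 10_000), st.floats(0.01, 0.5))
def test_thinning_separation_property(seed, min_sep):
    rng = np.random.default_rng(seed)
    n = 40
    occ = nd.OccurrenceSet("r", lon=rng.random(n), lat=rng.random(n))
    t = nd.thin_occurrences(occ, min_sep)
    pts = np.column_stack([t.lon, t.lat])
    if len(t) > 1:
        d = np.hypot(*(pts[:, None, :] - pts[None, :, :]).transpose(2, 0, 1))
        np.fill_diagonal(d, np.inf)
        assert d.min() >= min_sep
    # the first input point always survives
    assert t.lon[0] == occ.lon[0] and t.lat[0] == occ.lat[0]


def test_thinning_greatcircle_metric():
    # 0.05 deg apart in longitude at lat 60: great-circle arc is only
    # ~0.025 deg, so the second point is dropped where the planar
    # metric would keep it.
    occ = nd.OccurrenceSet("r", lon=[0.0, 0.05], lat=[60.0, 60.0])
    assert len(nd.thin_occurrences(occ, 0.04, metric="greatcircle")) == 1
    assert len(nd.thin_occurrences(occ, 0.04, metric="euclidean")) == 2


def test_extract_env_drops_nodata(toy_stack):
    occ = nd.OccurrenceSet("r", lon=[10.25, 11.25, 9.0],
                           lat=[49.75, 49.25, 49.0])
    with pytest.warns(UserWarning, match="dropped"):
        env = nd.extract_env(occ, toy_stack)
    assert len(env) == 1
    assert env.dropped == ["r_1", "r_2"]
    assert env.values[0].tolist() == [0.0, 100.0]


def test_correlation_groups_components():
    rng = np.random.default_rng(0)
    a = rng.standard_normal(200)
    b = a + 0.1 * rng.standard_normal(200)        # tied to a
    c = rng.standard_normal(200)                  # independent
    d = -c + 0.1 * rng.standard_normal(200)       # tied to c (negative r)
    env = EnvTable(variables=["a", "b", "c", "d"], ids=[str(i) for i in range(200)],
                   values=np.column_stack([a, b, c, d]))
    groups = correlation_groups(env, threshold=0.5)
    assert groups == [["a", "b"], ["c", "d"]]


def test_correlation_groups_constant_predictor_warns():
    rng = np.random.default_rng(1)
    env = EnvTable(variables=["a", "k"], ids=[str(i) for i in range(50)],
                   values=np.column_stack([rng.standard_normal(50),
                                           np.full(50, 3.0)]))
    with pytest.warns(UserWarning, match="constant"):
        groups = correlation_groups(env)
    assert ["k"] in groups


def _orthonormal_pair(n=64, seed=0):
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((n, 2))
    A -= A.mean(axis=0)
    Q, _ = np.linalg.qr(A)
    return Q[:, 0], Q[:, 1]


def test_vif_closed_form():
    # x2 = sqrt(0.75) x1 + 0.5 e with x1 perp e -> R^2 exactly 0.75,
    # VIF exactly 4; orthogonal predictors -> VIF 1.
    u, v = _orthonormal_pair()
    env = EnvTable(variables=["x1", "x2"], ids=[str(i) for i in range(len(u))],
                   values=np.column_stack([u, np.sqrt(0.75) * u + 0.5 * v]))
    table = nd.vif(env)
    np.testing.assert_allclose(table["vif"], [4.0, 4.0], atol=1e-9)
    env_orth = EnvTable(variables=["x1", "x2"],
                        ids=[str(i) for i in range(len(u))],
                        values=np.column_stack([u, v]))
    np.testing.assert_allclose(nd.vif(env_orth)["vif"], [1.0, 1.0],
                               atol=1e-9)


def test_vif_inverse_correlation_oracle():
    # For standardized predictors, VIF_j equals the j-th diagonal of the
    # inverse correlation matrix.
    rng = np.random.default_rng(7)
    X = rng.standard_normal((300, 4))
    X[:, 3] = 0.7 * X[:, 0] + 0.3 * X[:, 1] + 0.5 * X[:, 3]
    env = EnvTable(variables=list("abcd"), ids=[str(i) for i in range(300)],
                   values=X)
    oracle = np.diag(np.linalg.inv(np.corrcoef(X, rowvar=False)))
    np.testing.assert_allclose(nd.vif(env)["vif"], oracle, rtol=1e-8)


def test_vif_exact_collinearity_is_infinite():
    rng = np.random.default_rng(2)
    x = rng.standard_normal(50)
    env = EnvTable(variables=["a", "b"], ids=[str(i) for i in range(50)],
                   values=np.column_stack([x, 2 * x]))
    assert np.isinf(nd.vif(env)["vif"]).all()


def test_select_predictors_pipeline():
    rng = np.random.default_rng(3)
    a = rng.standard_normal(200)
    b = a + 0.05 * rng.standard_normal(200)
    c = rng.standard_normal(200)
    env = EnvTable(variables=["a", "b", "c"],
                   ids=[str(i) for i in range(200)],
                   values=np.column_stack([a, b, c]))
    selected, table, groups = nd.select_predictors(env)
    assert groups == [["a", "b"], ["c"]]
    assert selected == ["a", "c"]
    assert isinstance(table, pd.DataFrame) and table["retained"].all()
    # overriding the representative of group 0
    selected2, *_ = nd.select_predictors(env, representatives={0: "b"})
    assert selected2 == ["b", "c"]


def test_occurrence_set_csv_roundtrip(tmp_path):
    occ = nd.OccurrenceSet("r", lon=[1.0, 2.0], lat=[3.0, 4.0])
    occ.write_csv(tmp_path / "occ.csv")
    back = nd.OccurrenceSet.read_csv(tmp_path / "occ.csv")
    assert back.range_label == "r"
    np.testing.assert_allclose(back.lon, occ.lon)
    assert back.ids == occ.ids


def test_occurrence_cells_unique(toy_stack):
    occ = nd.OccurrenceSet("r", lon=[10.2, 10.3, 11.2, 9.0],
                           lat=[49.8, 49.9, 48.2, 0.0])
    cells = occurrence_cells(occ, toy_stack)
    assert cells.shape == (2, 2)  # two points share a cell; one outside
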