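import numpy as np
import pytest

import nichedyn as nd
from nichedyn.espace import upgma_cluster
from nichedyn.prep import EnvTable


def test_background_inside_buffered_hull(identical_world):
    w = identical_world
    occ = w["occs"]["A"]
    bkg = nd.build_background(occ, w["stacks"]["A"], buffer_deg=0.3)
    # every background cell centre lies within 0.3 deg + half a cell
    # diagonal of some occurrence-hull point; cheap necessary check:
    # the bounding box of the cells is within the buffered point bbox
    pad = 0.3 + w["stacks"]["A"].cell_size
    lon, lat = w["stacks"]["A"].cell_centers()
    r, c = bkg.cell_rc.T
    assert lon[r, c].min() >= occ.lon.min() - pad
    assert lon[r, c].max() <= occ.lon.max() + pad
    assert lat[r, c].min() >= occ.lat.min() - pad
    assert lat[r, c].max() <= occ.lat.max() + pad
    assert bkg.cells.shape[1] == len(w["stacks"]["A"].variables)


def test_background_collinear_fallback(toy_stack):
    occ = nd.OccurrenceSet("r", lon=[10.2, 10.8, 11.4],
                           lat=[49.5, 49.5, 49.5])
    with pytest.warns(UserWarning, match="bounding box"):
        bkg = nd.build_background(occ, toy_stack, buffer_deg=0.3)
    assert len(bkg.cells) > 0


def test_pca_env_structure(identical_world):
    space = identical_world["space"]
    L = space.loadings
    # orthonormal loadings, fractions sum to one, components ordered
    np.testing.assert_allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-10)
    assert space.explained_variance.sum() == pytest.approx(1.0)
    assert (np.diff(space.explained_variance) <= 1e-12).all()
    # background scores are centred near zero on both axes
    pooled = np.vstack(list(space.background_scores.values()))
    np.testing.assert_allclose(pooled.mean(axis=0), 0.0, atol=0.2)
    # bounds enclose the pooled background scores
    xmin, xmax, ymin, ymax = space.bounds
    assert xmin < pooled[:, 0].min() and xmax > pooled[:, 0].max()
    assert ymin < pooled[:, 1].min() and ymax > pooled[:, 1].max()


def test_transform_is_linear(identical_world):
    space = identical_world["space"]
    v = identical_world["env"]["A"].values[:5]
    s1 = space.transform(v)
    s2 = space.transform(v * 1.0)  # same data
    np.testing.assert_array_equal(s1, s2)
    # transforming the centre gives the origin
    np.testing.assert_allclose(space.transform(space.center[None, :]),
                               0.0, atol=1e-12)


def test_density_normalization_and_mass_location(identical_world):
    w = identical_world
    for k, dens in w["densities"].items():
        for z in (dens.z_avail, dens.z_occ_raw, dens.z_cor):
            assert z.sum() == pytest.approx(1.0, abs=1e-9)
            assert (z >= 0).all()
        # density mass centre is near the occurrence score centroid
        space = w["space"]
        xmin, xmax, ymin, ymax = space.bounds
        R = space.grid_resolution
        xs = xmin + (np.arange(R) + 0.5) * (xmax - xmin) / R
        ys = ymin + (np.arange(R) + 0.5) * (ymax - ymin) / R
        cx = (dens.z_occ_raw.sum(axis=1) * xs).sum()
        cy = (dens.z_occ_raw.sum(axis=0) * ys).sum()
        np.testing.assert_allclose([cx, cy], w["scores"][k].mean(axis=0),
                                   atol=0.3)


def test_quantile_outline_nested(identical_world):
    dens = identical_world["densities"]["A"]
    m20 = dens.quantile_outline(0.2)
    m80 = dens.quantile_outline(0.8)
    m100 = dens.quantile_outline(1.0)
    assert m20.sum() < m80.sum() <= m100.sum()
    assert (m20 <= m80).all() and (m80 <= m100).all()
    with pytest.raises(ValueError):
        dens.quantile_outline(0.0)


def test_occupancy_policies(identical_world):
    dens = identical_world["densities"]["A"]
    np.testing.assert_array_equal(dens.occupancy("raw"), dens.z_occ_raw)
    np.testing.assert_array_equal(dens.occupancy("corrected"), dens.z_cor)
    with pytest.raises(ValueError):
        dens.occupancy("other")


def test_corrected_density_zero_off_background(identical_world):
    dens = identical_world["densities"]["A"]
    assert (dens.z_cor[dens.z_avail == 0] == 0).all()


def _toy_tables():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((120, 4))
    X[:, 1] = 0.9 * X[:, 0] + 0.2 * X[:, 1]  # correlated pair
    a = EnvTable(variables=list("wxyz"), ids=[f"a{i}" for i in range(60)],
                 values=X[:60])
    b = EnvTable(variables=list("wxyz"), ids=[f"b{i}" for i in range(60)],
                 values=X[60:] + 2.0)
    return {"A": a, "B": b}


def test_standard_pca_kaiser_retention():
    spca = nd.standard_pca(_toy_tables())
    # eigenvalues of a correlation matrix sum to the variable count
    assert spca.eigenvalues.sum() == pytest.approx(4.0)
    assert (spca.eigenvalues[spca.retained] >= 1.0).all()
    dropped = np.setdiff1d(np.arange(4), spca.retained)
    assert (spca.eigenvalues[dropped] < 1.0).all()
    # mean scores live on the retained axes only
    for k in ("A", "B"):
        assert spca.mean_scores[k].shape == (len(spca.retained),)
    # transform reproduces the stored per-range scores on retained axes
    # when retention is the leading block
    if (spca.retained == np.arange(len(spca.retained))).all():
        s = spca.transform(_toy_tables()["A"].values,
                           n_components=len(spca.retained))
        np.testing.assert_allclose(s, spca.scores["A"], atol=1e-10)


def test_upgma_hand_trace():
    # Three points on a line at 0, 1, 5 with squared-euclidean distances
    # d(0,1)=1, d(0,5)=25, d(1,5)=16. UPGMA joins {0,1} at height 1,
    # then {0,1} with {5} at (25+16)/2 = 20.5.
    means = {"p": np.array([0.0]), "q": np.array([1.0]),
             "r": np.array([5.0])}
    Z, newick = upgma_cluster(means)
    assert Z[0, 2] == pytest.approx(1.0)
    assert Z[1, 2] == pytest.approx(20.5)
    # ultrametric newick: leaves of the first join at depth 0.5
    assert "p:0.5" in newick and "q:0.5" in newick
    assert newick.endswith(");")


def test_upgma_requires_two_ranges():
    with pytest.raises(ValueError):
        upgma_cluster({"only": np.array([0.0])})
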