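import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from cortexprox.proximity import (
    PermutationScheme,
    bh_adjust,
    build_contact_graph,
    nn_distance_test,
    pairwise_enrichment,
    permute_labels,
)

from conftest import make_cells


def scheme(**kw):
    kw.setdefault("bin_size_um", 100.0)
    kw.setdefault("n_permutations", 500)
    kw.setdefault("seed", 9)
    return PermutationScheme(**kw)


# -- contact graph ----------------------------------------------------------

def test_contact_rule_direct_cases(tax):
    cells = make_cells([0.0, 10.5], [0.0, 0.0], ["SST 1", "ASC 1"], tax)
    g = build_contact_graph(cells, scale=1.1)  # threshold 1.1*(5+5) = 11
    assert g.n_edges == 1
    far = make_cells([0.0, 100.0], [0.0, 0.0], ["SST 1", "ASC 1"], tax)
    assert build_contact_graph(far, scale=1.1).n_edges == 0


@pytest.mark.parametrize("mode", ["centroid", "boundary"])
def test_graph_matches_allpairs_oracle_500_cells(tax, mode):
    rng = np.random.default_rng(17)
    n = 500
    cells = make_cells(
        rng.uniform(0, 600, n),
        rng.uniform(0, 600, n),
        rng.choice(list(tax.clusters), n),
        tax,
        radii=rng.uniform(3, 7, n),
    )
    g = build_contact_graph(cells, mode=mode, scale=1.1, tolerance_um=1.0)
    got = {
        tuple(sorted(p))
        for p in zip(g.edges["cell_id_a"], g.edges["cell_id_b"])
    }
    xy = cells[["x_um", "y_um"]].to_numpy()
    r = cells["soma_radius_um"].to_numpy()
    ids = cells["cell_id"].to_numpy()
    d = squareform(pdist(xy))
    expect = set()
    for i in range(n):
        for j in range(i + 1, n):
            thr = 1.1 * (r[i] + r[j]) if mode == "centroid" else r[i] + r[j] + 2.0
            if d[i, j] <= thr:
                expect.add(tuple(sorted((ids[i], ids[j]))))
    assert got == expect


def test_boundary_mode_with_polygons_matches_circles(tax):
    from shapely.geometry import Point

    rng = np.random.default_rng(23)
    n = 80
    cells = make_cells(
        rng.uniform(0, 200, n), rng.uniform(0, 200, n),
        rng.choice(list(tax.clusters), n), tax, radii=rng.uniform(3, 6, n),
    )
    polys = {
        row.cell_id: Point(row.x_um, row.y_um).buffer(row.soma_radius_um, quad_segs=64)
        for row in cells.itertuples()
    }
    g_circ = build_contact_graph(cells, mode="boundary", tolerance_um=1.0)
    g_poly = build_contact_graph(cells, mode="boundary", tolerance_um=1.0, polygons=polys)
    to_set = lambda g: {
        tuple(sorted(p)) for p in zip(g.edges["cell_id_a"], g.edges["cell_id_b"])
    }
    # circle-polygon approximation: allow edges whose distance is within
    # discretisation error of the threshold to differ
    sym = to_set(g_circ) ^ to_set(g_poly)
    pos = {cid: (x, y, r) for cid, x, y, r in zip(
        cells.cell_id, cells.x_um, cells.y_um, cells.soma_radius_um)}
    for a, b in sym:
        xa, ya, ra = pos[a]
        xb, yb, rb = pos[b]
        d = np.hypot(xa - xb, ya - yb)
        assert abs(d - (ra + rb + 2.0)) < 0.01


def test_centroid_mode_requires_radii(tax):
    cells = make_cells([0, 10], [0, 0], ["SST 1", "SST 2"], tax)
    cells.loc[0, "soma_radius_um"] = np.nan
    with pytest.raises(ValueError, match="radii"):
        build_contact_graph(cells, mode="centroid")


# -- permutation ------------------------------------------------------------

def test_single_cell_bin_is_fixed_point(tax):
    cells = make_cells([50, 5000], [50, 5000], ["SST 1", "ASC 1"], tax)
    out = permute_labels(cells, scheme(n_permutations=100))
    assert list(out["cluster"]) == ["SST 1", "ASC 1"]


def test_permutation_preserves_per_bin_multisets(tax):
    rng = np.random.default_rng(5)
    n = 800
    cells = make_cells(
        rng.uniform(0, 500, n), rng.uniform(0, 500, n),
        rng.choice(list(tax.clusters), n), tax,
    )
    sch = scheme(bin_size_um=100.0, n_permutations=100)
    out = permute_labels(cells, sch)
    bx = np.floor(cells["x_um"].to_numpy() / 100.0)
    by = np.floor(cells["y_um"].to_numpy() / 100.0)
    for b in set(zip(bx, by)):
        mask = (bx == b[0]) & (by == b[1])
        assert sorted(cells.loc[mask, "cluster"]) == sorted(out.loc[mask, "cluster"])
    # global conservation follows, but check explicitly
    assert (
        cells["cluster"].value_counts().sort_index()
        .equals(out["cluster"].value_counts().sort_index())
    )
    # subclass stays consistent with cluster after the joint shuffle
    assert (out["subclass"] == [tax.subclass_of(c) for c in out["cluster"]]).all()


# -- enrichment -------------------------------------------------------------

def enumeration_case(tax):
    """6 cells in one bin, labels AABBBB, chain geometry; exact null by
    enumerating all label permutations."""
    xs = [0.0, 9.0, 18.0, 27.0, 36.0, 45.0]
    labels = ["SST 1", "SST 1", "ASC 1", "ASC 1", "ASC 1", "ASC 1"]
    cells = make_cells(xs, [0.0] * 6, labels, tax, radii=np.full(6, 5.0))
    graph = build_contact_graph(cells, scale=1.1)  # edges between neighbors (d=9<=11)
    return cells, graph


def test_null_moments_match_exhaustive_enumeration(tax):
    cells, graph = enumeration_case(tax)
    ia, ib = graph.edge_positions(cells)
    base = cells["subclass"].to_numpy()
    counts = []
    for perm in itertools.permutations(range(6)):
        lab = base[list(perm)]
        counts.append(int(((lab[ia] == "SST") & (lab[ib] == "ASC")).sum()
                          + ((lab[ia] == "ASC") & (lab[ib] == "SST")).sum()))
    exact_mean = np.mean(counts)
    exact_sd = np.std(counts, ddof=0)

    res = pairwise_enrichment(
        cells, graph, scheme(bin_size_um=1000.0, n_permutations=4000, seed=2),
        min_expected=0,
    )
    row = res.row("ASC", "SST")
    mc_se = exact_sd / np.sqrt(4000)
    assert row["null_mean"] == pytest.approx(exact_mean, abs=3 * mc_se)
    assert row["null_sd"] == pytest.approx(exact_sd, rel=0.1)


def test_enrichment_deterministic_and_id_invariant(tax):
    rng = np.random.default_rng(8)
    n = 400
    cells = make_cells(
        rng.uniform(0, 400, n), rng.uniform(0, 400, n),
        rng.choice(["SST 1", "ASC 1", "OGC 1"], n), tax,
    )
    graph = build_contact_graph(cells)
    sch = scheme(n_permutations=200)
    a = pairwise_enrichment(cells, graph, sch).table
    b = pairwise_enrichment(cells, graph, sch).table
    pd.testing.assert_frame_equal(a, b)

    renamed = cells.copy()
    renamed["cell_id"] = [f"zz-{i}" for i in range(n)]
    graph2 = build_contact_graph(renamed)
    c = pairwise_enrichment(renamed, graph2, sch).table
    pd.testing.assert_frame_equal(a, c)


def test_enrichment_requires_permutations(tax):
    cells, graph = enumeration_case(tax)
    with pytest.raises(ValueError):
        pairwise_enrichment(cells, graph, scheme(n_permutations=1))


def test_fdr_at_least_p_and_fold_nonnegative(small_human, small_human_graph):
    _, cells, _ = small_human
    res = pairwise_enrichment(cells, small_human_graph, scheme(n_permutations=150))
    t = res.table.dropna(subset=["p"])
    assert (t["fdr"] >= t["p"] - 1e-12).all()
    assert (t["fold_change"].dropna() >= 0).all()


# -- nearest neighbor -------------------------------------------------------

def test_nn_hand_geometry(tax):
    cells = make_cells(
        [0, 1, 2, 10, 11, 12], [0] * 6,
        ["SST 1"] * 3 + ["ASC 1"] * 3, tax,
    )
    res = nn_distance_test(cells, level="subclass", min_cells=3)
    ds, do = res.distances["SST"]
    assert ds.tolist() == [1.0, 1.0, 1.0]
    assert do.tolist() == [10.0, 9.0, 8.0]
    da, doa = res.distances["ASC"]
    assert da.tolist() == [1.0, 1.0, 1.0]
    assert doa.tolist() == [8.0, 9.0, 10.0]


def test_nn_symmetric_null_p_not_extreme(tax):
    """Two interleaved identical-geometry labels: no self-attraction, so
    the one-sided p should not be systematically tiny."""
    rng = np.random.default_rng(12)
    ps = []
    for rep in range(10):
        n = 400
        xs = rng.uniform(0, 1000, n)
        ys = rng.uniform(0, 1000, n)
        labels = np.where(np.arange(n) % 2 == 0, "SST 1", "PVALB 1")
        cells = make_cells(xs, ys, labels, tax)
        res = nn_distance_test(cells, min_cells=3)
        ps.extend(res.table["p"].tolist())
    ps = np.array(ps)
    # under the symmetric null p is uniform: mean ~0.5, few small values
    assert 0.3 < ps.mean() < 0.7
    assert (ps < 0.05).mean() < 0.25


def test_nn_min_cells_excludes_sparse_labels(tax):
    cells = make_cells(
        [0, 1, 2, 10, 11, 12, 50], [0] * 7,
        ["SST 1"] * 3 + ["ASC 1"] * 3 + ["OGC 1"], tax,
    )
    res = nn_distance_test(cells, min_cells=3)
    assert "OGC" not in set(res.table["label"])


# -- BH ---------------------------------------------------------------------

def test_bh_hand_formula():
    out = bh_adjust([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])
    assert bh_adjust([0.3]).tolist() == [0.3]
    assert bh_adjust([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]


def test_bh_nan_excluded_from_family():
    out = bh_adjust([0.01, np.nan, 0.04])
    assert np.isnan(out[1])
    # m = 2: adjusted = min(0.01*2/1, 0.04*2/2) monotone
    assert out[0] == pytest.approx(0.02)
    assert out[2] == pytest.approx(0.04)


def test_bh_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(3)
    for _ in range(5):
        p = rng.uniform(0, 1, 40)
        ours = bh_adjust(p)
        theirs = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, theirs)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])
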