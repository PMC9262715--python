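import itertools

import numpy as np
import pytest
import scipy.sparse as sp

from cortexprox.datamodel import ExpressionMatrix
from cortexprox.interactions import (
    LowPowerError,
    contact_by_depth,
    detect_vessels,
    gad1_opc_fraction,
    ligrec_enrichment,
    multiway_contact_test,
)
from cortexprox.proximity import PermutationScheme, build_contact_graph

from conftest import make_cells


def scheme(**kw):
    kw.setdefault("bin_size_um", 100.0)
    kw.setdefault("n_permutations", 300)
    kw.setdefault("seed", 4)
    return PermutationScheme(**kw)


# -- vessels ----------------------------------------------------------------

def test_hand_built_vessel_with_two_microglia(tax):
    # 5 ENDO cells in a chain at 7 um spacing + 2 contacting MGC + 1 far ASC
    xs = [0, 7, 14, 21, 28, 7, 21, 300]
    ys = [0, 0, 0, 0, 0, 8, -8, 300]
    clusters = ["ENDO 1"] * 5 + ["MGC 1", "MGC 2", "ASC 1"]
    cells = make_cells(xs, ys, clusters, tax, radii=np.full(8, 4.0))
    graph = build_contact_graph(cells, scale=1.1)
    vs = detect_vessels(cells, graph, tax, min_size=3)
    assert vs.n_vessels == 1
    assert len(vs.vessels[0]) == 5
    row = vs.adjacency.iloc[0]
    assert row["MGC"] == 2 and row["ASC"] == 0


def test_no_vascular_cells_gives_empty_vesselset(tax):
    cells = make_cells([0, 10, 20], [0, 0, 0], ["ASC 1", "SST 1", "OGC 1"], tax)
    graph = build_contact_graph(cells)
    vs = detect_vessels(cells, graph, tax)
    assert vs.n_vessels == 0


def test_vessels_match_bruteforce_components(small_human, small_human_graph, tax):
    _, cells, _ = small_human
    vs = detect_vessels(cells, small_human_graph, tax, min_size=3)

    # brute-force BFS over the vascular-restricted edge set
    vasc_ids = set(cells.loc[cells["subclass"].isin(["ENDO", "MURAL"]), "cell_id"])
    adj = {}
    for a, b in zip(
        small_human_graph.edges["cell_id_a"], small_human_graph.edges["cell_id_b"]
    ):
        if a in vasc_ids and b in vasc_ids:
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
    seen, comps = set(), []
    for start in sorted(adj):
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            node = stack.pop()
            if node in comp:
                continue
            comp.add(node)
            stack.extend(adj.get(node, ()))
        seen |= comp
        if len(comp) >= 3:
            comps.append(frozenset(comp))
    assert {frozenset(v) for v in vs.vessels} == set(comps)


def test_human_recruited_vessels_have_more_glia_than_mouse(tax):
    from cortexprox import default_human_config, default_mouse_config, generate_tissue

    h_cells, _ = generate_tissue(default_human_config(section_width_um=3000.0, seed=2), tax)
    m_cells, _ = generate_tissue(default_mouse_config(section_width_um=2000.0, seed=2), tax)
    hv = detect_vessels(h_cells, build_contact_graph(h_cells), tax)
    mv = detect_vessels(m_cells, build_contact_graph(m_cells), tax)
    h_mean = hv.summary.set_index("subclass")["mean"]
    m_mean = mv.summary.set_index("subclass")["mean"]
    assert h_mean["MGC"] > m_mean["MGC"]
    assert h_mean["OGC"] > m_mean["OGC"]


# -- multiway ---------------------------------------------------------------

def test_multiway_hand_count(tax):
    # one L5 IT neuron touching exactly 3 OGC; everything else isolated
    xs = [0, 10, -10, 0, 500, 600]
    ys = [0, 0, 0, 10, 500, 600]
    clusters = ["L5 IT 1", "OGC 1", "OGC 2", "OGC 1", "SST 1", "OGC 3"]
    cells = make_cells(xs, ys, clusters, tax, radii=np.full(6, 5.0))
    graph = build_contact_graph(cells, scale=1.1)
    res = multiway_contact_test(
        cells, graph, tax, scheme(n_permutations=100), k_values=(2, 3, 4)
    )
    assert res.table.set_index("k")["observed"].tolist() == [1, 1, 0]


def test_multiway_no_partners_gives_zero(tax):
    cells = make_cells([0, 10, 20], [0] * 3, ["L5 IT 1", "SST 1", "ASC 1"], tax)
    graph = build_contact_graph(cells)
    res = multiway_contact_test(cells, graph, tax, scheme(n_permutations=100))
    assert (res.table["observed"] == 0).all()


def test_multiway_tail_matches_independent_histogram(small_human, small_human_graph, tax):
    _, cells, _ = small_human
    res = multiway_contact_test(
        cells, small_human_graph, tax, scheme(n_permutations=100), k_values=(2, 3, 4, 5)
    )
    # independent recomputation: per-neuron distinct OGC/OPC contacts
    ids = cells["cell_id"].to_numpy()
    sub = dict(zip(ids, cells["subclass"]))
    klass = dict(zip(ids, cells["class"]))
    partners = {}
    for a, b in zip(
        small_human_graph.edges["cell_id_a"], small_human_graph.edges["cell_id_b"]
    ):
        if klass[a] in ("excitatory", "inhibitory") and sub[b] in ("OGC", "OPC"):
            partners.setdefault(a, set()).add(b)
        if klass[b] in ("excitatory", "inhibitory") and sub[a] in ("OGC", "OPC"):
            partners.setdefault(b, set()).add(a)
    counts = np.array([len(v) for v in partners.values()])
    for k, obs in zip(res.table["k"], res.table["observed"]):
        assert obs == (counts >= k).sum()
    # observed is non-increasing in k
    assert (np.diff(res.table["observed"]) <= 0).all()


# -- GAD1+ OPCs -------------------------------------------------------------

def opc_expression(tax, gad1_counts):
    n = len(gad1_counts)
    cells = make_cells(
        np.arange(n) * 50.0, [100.0] * n, ["OPC 1"] * n, tax
    )
    mat = sp.csr_matrix(np.array([gad1_counts, [1] * n]).T)
    expr = ExpressionMatrix(mat, ["GAD1", "other"], cells["cell_id"].tolist())
    return cells, expr


def test_gad1_fraction_hand_count(tax):
    cells, expr = opc_expression(tax, [0, 0, 3, 5])
    res = gad1_opc_fraction(cells, expr, min_count=1)
    assert res.fraction == 0.5
    assert res.flags.tolist() == [False, False, True, True]
    assert res.sensitivity[3] == 0.5  # counts 3 and 5 both >= 3


def test_gad1_all_zero_and_missing_gene(tax):
    cells, expr = opc_expression(tax, [0, 0, 0, 0])
    assert gad1_opc_fraction(cells, expr).fraction == 0.0
    bad = ExpressionMatrix(
        sp.csr_matrix(np.ones((4, 1))), ["SST"], expr.cell_ids
    )
    with pytest.raises(KeyError, match="GAD1"):
        gad1_opc_fraction(cells, bad)


def test_gad1_requires_opcs(tax):
    cells = make_cells([0], [0], ["ASC 1"], tax)
    expr = ExpressionMatrix(sp.csr_matrix(np.ones((1, 1))), ["GAD1"], cells["cell_id"].tolist())
    with pytest.raises(ValueError, match="OPC"):
        gad1_opc_fraction(cells, expr)


# -- depth-resolved contact -------------------------------------------------

def test_depth_contact_null_ratios_near_one_for_csr_labels(tax):
    rng = np.random.default_rng(6)
    n = 3000
    clusters = rng.choice(
        ["L2/3 IT 1", "L4/5 IT 1", "L5 IT 1", "L6 IT 1", "SST 1", "MGC 1", "ASC 1"],
        n,
        p=[0.2, 0.15, 0.15, 0.1, 0.1, 0.1, 0.2],
    )
    cells = make_cells(
        rng.uniform(0, 1800, n), rng.uniform(0, 1800, n), clusters, tax,
        depths=rng.uniform(0, 1, n),
    )
    graph = build_contact_graph(cells)
    res = contact_by_depth(cells, graph, tax, scheme(n_permutations=300))
    # under random labels every group's observed count sits within the
    # null distribution (|z| < 3.5) and ratios scatter around 1
    z = res.table["z"].dropna()
    assert np.all(np.abs(z) < 3.5)
    assert abs(res.table["ratio"].dropna().mean() - 1.0) < 0.25


def test_depth_contact_expected_matches_exhaustive_enumeration(tax):
    # 4 cells in one bin: one MGC next to one L2/3 IT, two ASC elsewhere
    cells = make_cells(
        [0.0, 10.0, 40.0, 50.0], [0.0] * 4,
        ["MGC 1", "L2/3 IT 1", "ASC 1", "ASC 2"], tax,
    )
    graph = build_contact_graph(cells, scale=1.1)
    sub = cells["subclass"].to_numpy()
    ia, ib = graph.edge_positions(cells)
    counts = []
    for perm in itertools.permutations(range(4)):
        lab = sub[list(perm)]
        counts.append(
            int((((lab[ia] == "L2/3 IT") & (lab[ib] == "MGC"))
                 | ((lab[ib] == "L2/3 IT") & (lab[ia] == "MGC"))).sum())
        )
    exact = np.mean(counts)
    res = contact_by_depth(
        cells, graph, tax,
        scheme(bin_size_um=1000.0, n_permutations=4000, seed=1),
        focal_groups=("L2/3 IT",),
    )
    mc_se = np.std(counts) / np.sqrt(4000)
    assert res.table["null_mean"].iloc[0] == pytest.approx(exact, abs=3 * mc_se)


# -- ligand-receptor --------------------------------------------------------

def test_ligrec_toy_hand_arithmetic(tax):
    """2 contacting pairs with normalized L=2, R=3; all null-pool cells
    have L=1, R=1 -> observed 6, null mean 1, fold 6."""
    # senders: 2 contacting MGC + 4 spare MGC; receivers: 2 contacted
    # L2/3 IT + 4 spare. Contacting pairs at distance 10 (<= 11).
    xs = [0, 10, 100, 110, 300, 320, 340, 360, 400, 420, 440, 460]
    ys = [0] * 12
    clusters = (
        ["MGC 1", "L2/3 IT 1", "MGC 1", "L2/3 IT 1"]
        + ["MGC 1"] * 4 + ["L2/3 IT 1"] * 4
    )
    cells = make_cells(xs, ys, clusters, tax, depths=[0.1] * 12)
    sub = cells["subclass"].to_numpy()
    # counts: contacting senders L=2 (of total 3), null senders L=1 (of 3)
    counts = np.zeros((12, 3), dtype=int)  # genes: LIG, REC, PAD
    for i in range(12):
        if sub[i] == "MGC":
            lig = 2 if i in (0, 2) else 1
            counts[i] = [lig, 0, 3 - lig]
        else:
            rec = 3 if i in (1, 3) else 1
            counts[i] = [0, rec, 3 - rec]
    expr = ExpressionMatrix(sp.csr_matrix(counts), ["LIG", "REC", "PAD"],
                            cells["cell_id"].tolist())
    graph = build_contact_graph(cells, scale=1.1)
    res = ligrec_enrichment(
        cells, expr, graph, (("LIG", "REC"),), tax,
        sender_type="MGC", receiver_type="L2/3 IT",
        scheme=scheme(n_permutations=50), min_pairs=2, norm_scale=3.0,
    )
    row = res.table.iloc[0]
    assert res.n_contacting_pairs == 2
    assert row["observed"] == pytest.approx(6.0)
    assert row["null_mean"] == pytest.approx(1.0)
    assert row["fold_change"] == pytest.approx(6.0)


def test_ligrec_fold_invariant_to_global_library_rescaling(small_human, small_human_graph, tax):
    _, cells, expr = small_human
    pairs = (("A2M", "LRP1"), ("C3", "C3AR1"))
    sch = scheme(n_permutations=60, seed=3)
    res1 = ligrec_enrichment(cells, expr, small_human_graph, pairs, tax, scheme=sch)
    tripled = ExpressionMatrix(expr.matrix * 3, expr.genes, expr.cell_ids)
    res2 = ligrec_enrichment(cells, tripled, small_human_graph, pairs, tax, scheme=sch)
    assert np.allclose(
        res1.table["fold_change"], res2.table["fold_change"], equal_nan=True
    )


def test_ligrec_too_few_pairs_raises(tax):
    cells = make_cells([0, 10, 500], [0, 0, 0], ["MGC 1", "L2/3 IT 1", "MGC 2"], tax)
    counts = sp.csr_matrix(np.ones((3, 2)))
    expr = ExpressionMatrix(counts, ["LIG", "REC"], cells["cell_id"].tolist())
    graph = build_contact_graph(cells)
    with pytest.raises(LowPowerError):
        ligrec_enrichment(
            cells, expr, graph, (("LIG", "REC"),), tax,
            sender_type="MGC", receiver_type="L2/3 IT", min_pairs=10,
        )


def test_ligrec_missing_gene_raises(small_human, small_human_graph, tax):
    _, cells, expr = small_human
    with pytest.raises(KeyError, match="NOPE"):
        ligrec_enrichment(
            cells, expr, small_human_graph, (("NOPE", "LRP1"),), tax
        )
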