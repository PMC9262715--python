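"""Higher-order and molecular interaction analyses.

Builds on the contact graph and the density-preserving permutation
null: blood-vessel detection (connected components of the
endothelial/mural subgraph) with per-vessel glial adjacency counts,
multiway neuron-oligodendrocyte/OPC contact statistics, GAD1-positive
OPC classification, depth-resolved microglia-IT contact ratios, and
contact-conditioned ligand-receptor enrichment scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.stats import norm, spearmanr

from .datamodel import ContactGraph, ExpressionMatrix, normalize_expression
from .proximity import BinPermuter, PermutationScheme, bh_adjust
from .taxonomy import Taxonomy, resolve_subclasses


class LowPowerError(ValueError):
    """Too few qualifying observations for the requested inference."""


# ---------------------------------------------------------------------------
# vessels
# ---------------------------------------------------------------------------

@dataclass
class VesselSet:
    """Connected ENDO/MURAL components and their glial adjacency."""

    vessels: list[list[str]]            # member cell ids per vessel
    adjacency: pd.DataFrame             # vessel, glial subclass counts
    summary: pd.DataFrame               # subclass, mean, sd across vessels

    @property
    def n_vessels(self) -> int:
        return len(self.vessels)


def detect_vessels(
    cells: pd.DataFrame,
    graph: ContactGraph,
    taxonomy: Taxonomy,
    min_size: int = 3,
) -> VesselSet:
    """Vessels = connected components (size >= ``min_size``) of the contact
    graph restricted to endothelial/mural cells; adjacency counts the
    distinct glial cells of each subclass contacting any member."""
    sub = cells["subclass"].to_numpy()
    vasc = np.isin(sub, list(taxonomy.vascular_subclasses))
    ids = cells["cell_id"].to_numpy()
    n = len(cells)
    glial = sorted(taxonomy.glial_subclasses)

    if not vasc.any() or graph.n_edges == 0:
        return VesselSet(
            vessels=[],
            adjacency=pd.DataFrame(columns=["vessel"] + glial),
            summary=pd.DataFrame(
                {"subclass": glial, "mean": np.nan, "sd": np.nan, "n_vessels": 0}
            ),
        )

    ia, ib = graph.edge_positions(cells)
    keep = vasc[ia] & vasc[ib]
    va, vb = ia[keep], ib[keep]
    adj = sp.coo_matrix(
        (np.ones(len(va)), (va, vb)), shape=(n, n)
    )
    ncomp, comp = connected_components(adj + adj.T, directed=False)
    # only vascular nodes carry kept edges, so any component with
    # >= min_size vascular members is entirely vascular
    comp_sizes = np.bincount(comp[vasc], minlength=ncomp)
    vessel_comp_ids = list(np.flatnonzero(comp_sizes >= min_size))

    vessels = [list(ids[comp == c]) for c in vessel_comp_ids]

    # glial adjacency through any graph edge to a member
    rows = []
    for v, c in enumerate(vessel_comp_ids):
        member = comp == c
        touching = set()
        hit_a = member[ia] & np.isin(sub[ib], glial)
        hit_b = member[ib] & np.isin(sub[ia], glial)
        touching = np.union1d(ib[hit_a], ia[hit_b])
        counts = {g: 0 for g in glial}
        for cell in touching:
            counts[sub[cell]] = counts.get(sub[cell], 0) + 1
        rows.append({"vessel": v, **{g: counts[g] for g in glial}})
    adjacency = pd.DataFrame(rows, columns=["vessel"] + glial)

    if len(adjacency):
        summary = pd.DataFrame(
            {
                "subclass": glial,
                "mean": [adjacency[g].mean() for g in glial],
                "sd": [adjacency[g].std(ddof=1) if len(adjacency) > 1 else 0.0 for g in glial],
                "n_vessels": len(adjacency),
            }
        )
    else:
        summary = pd.DataFrame(
            {"subclass": glial, "mean": np.nan, "sd": np.nan, "n_vessels": 0}
        )
    return VesselSet(vessels=vessels, adjacency=adjacency, summary=summary)


# ---------------------------------------------------------------------------
# multiway contacts
# ---------------------------------------------------------------------------

@dataclass
class MultiwayResult:
    """Observed vs null counts of focal cells with >= k partner contacts."""

    table: pd.DataFrame  # k, observed, null_mean, null_sd, z, p, fdr
    focal: str
    partners: tuple[str, ...]


def _multiway_tail(deg: np.ndarray, k_values) -> np.ndarray:
    return np.array([(deg >= k).sum() for k in k_values])


def multiway_contact_test(
    cells: pd.DataFrame,
    graph: ContactGraph,
    taxonomy: Taxonomy,
    scheme: PermutationScheme,
    focal: str = "neurons",
    partner_subclasses: tuple[str, ...] = ("OGC", "OPC"),
    k_values: tuple[int, ...] = (2, 3, 4, 5),
) -> MultiwayResult:
    """Number of focal cells contacting >= k distinct partner-type cells,
    against the label-permutation null; BH across k values."""
    sub = cells["subclass"].to_numpy()
    focal_set = resolve_subclasses(focal, taxonomy)
    n = len(cells)
    ia, ib = graph.edge_positions(cells)

    def tail(sub_arr):
        f = np.isin(sub_arr, list(focal_set))
        p = np.isin(sub_arr, list(partner_subclasses))
        deg = np.zeros(n, dtype=np.int64)
        np.add.at(deg, ia, (f[ia] & p[ib]).astype(np.int64))
        np.add.at(deg, ib, (f[ib] & p[ia]).astype(np.int64))
        deg[~f] = 0
        return _multiway_tail(deg, k_values)

    obs = tail(sub)

    permuter = BinPermuter(cells, scheme.bin_size_um)
    rng = np.random.default_rng(scheme.seed)
    B = scheme.n_permutations
    draws = np.empty((B, len(k_values)))
    for b in range(B):
        draws[b] = tail(sub[permuter.permutation(rng)])
    mean = draws.mean(axis=0)
    sd = draws.std(axis=0, ddof=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (obs - mean) / sd, np.nan)
    p = np.where(np.isfinite(z), norm.sf(z), np.nan)
    table = pd.DataFrame(
        {
            "k": list(k_values),
            "observed": obs,
            "null_mean": mean,
            "null_sd": sd,
            "z": z,
            "p": p,
            "p_empirical": [(1.0 + (draws[:, i] >= obs[i]).sum()) / (B + 1.0) for i in range(len(k_values))],
        }
    )
    table["fdr"] = bh_adjust(table["p"].to_numpy())
    return MultiwayResult(table=table, focal=focal, partners=tuple(partner_subclasses))


# ---------------------------------------------------------------------------
# GAD1+ OPCs
# ---------------------------------------------------------------------------

@dataclass
class Gad1OpcResult:
    fraction: float
    flags: pd.Series                 # per-OPC bool, indexed by cell_id
    n_opc: int
    gad2_positive_fraction: float | None
    slc32a1_positive_fraction: float | None
    sensitivity: dict[int, float]    # min_count -> fraction


def gad1_opc_fraction(
    cells: pd.DataFrame,
    expr: ExpressionMatrix,
    min_count: int = 1,
) -> Gad1OpcResult:
    """Fraction of OPCs with >= ``min_count`` GAD1 transcripts.

    Also reports the GAD2 / SLC32A1 positive fractions among OPCs (when
    those genes are in the panel; both should be near zero) and the
    sensitivity of the GAD1+ fraction to min_count in {1, 2, 3}.
    """
    order = pd.Series(np.arange(expr.n_cells), index=expr.cell_ids)
    opc_ids = cells.loc[cells["subclass"] == "OPC", "cell_id"]
    if len(opc_ids) == 0:
        raise ValueError("no OPC cells in the table")
    rows = order.loc[opc_ids].to_numpy()

    gad1 = expr.counts_for("GAD1")[rows]  # KeyError if GAD1 absent
    flags = gad1 >= min_count

    def _pos_fraction(gene):
        if gene not in expr.genes:
            return None
        return float((expr.counts_for(gene)[rows] >= min_count).mean())

    return Gad1OpcResult(
        fraction=float(flags.mean()),
        flags=pd.Series(flags, index=opc_ids.to_numpy()),
        n_opc=len(rows),
        gad2_positive_fraction=_pos_fraction("GAD2"),
        slc32a1_positive_fraction=_pos_fraction("SLC32A1"),
        sensitivity={k: float((gad1 >= k).mean()) for k in (1, 2, 3)},
    )


# ---------------------------------------------------------------------------
# depth-resolved contact ratios
# ---------------------------------------------------------------------------

@dataclass
class DepthContactResult:
    """Observed/expected contact ratio per focal group, ordered
    superficial -> deep, with the permutation ratio distribution."""

    table: pd.DataFrame      # group, observed, null_mean, ratio, z, p
    null_ratios: pd.DataFrame  # permutation b x group ratio draws
    spearman_rho: float
    partner: str


def contact_by_depth(
    cells: pd.DataFrame,
    graph: ContactGraph,
    taxonomy: Taxonomy,
    scheme: PermutationScheme,
    focal_groups: tuple[str, ...] = (
        "L2/3 IT", "L4/5 IT", "L5 IT", "L6 IT", "inhibitory",
    ),
    partner: str = "MGC",
) -> DepthContactResult:
    """Observed vs expected contact frequency between each focal group
    (ordered superficial to deep) and the partner subclass, plus a
    Spearman trend of the ratio against the depth order."""
    sub = cells["subclass"].to_numpy()
    ia, ib = graph.edge_positions(cells)
    partner_set = resolve_subclasses(partner, taxonomy)
    group_sets = [resolve_subclasses(g, taxonomy) for g in focal_groups]

    def counts(sub_arr):
        p = np.isin(sub_arr, list(partner_set))
        out = np.empty(len(group_sets))
        for gi, gset in enumerate(group_sets):
            f = np.isin(sub_arr, list(gset))
            out[gi] = ((f[ia] & p[ib]) | (f[ib] & p[ia])).sum()
        return out

    obs = counts(sub)
    permuter = BinPermuter(cells, scheme.bin_size_um)
    rng = np.random.default_rng(scheme.seed)
    B = scheme.n_permutations
    draws = np.empty((B, len(group_sets)))
    for b in range(B):
        draws[b] = counts(sub[permuter.permutation(rng)])
    mean = draws.mean(axis=0)
    sd = draws.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(mean > 0, obs / mean, np.nan)
        z = np.where(sd > 0, (obs - mean) / sd, np.nan)
        null_ratios = np.where(mean > 0, draws / mean, np.nan)
    p = np.where(np.isfinite(z), norm.sf(z), np.nan)

    finite = np.isfinite(ratio)
    rho = (
        float(spearmanr(np.arange(len(group_sets))[finite], ratio[finite]).statistic)
        if finite.sum() >= 3
        else float("nan")
    )
    table = pd.DataFrame(
        {
            "group": list(focal_groups),
            "observed": obs,
            "null_mean": mean,
            "null_sd": sd,
            "ratio": ratio,
            "z": z,
            "p": p,
        }
    )
    return DepthContactResult(
        table=table,
        null_ratios=pd.DataFrame(null_ratios, columns=list(focal_groups)),
        spearman_rho=rho,
        partner=partner,
    )


# ---------------------------------------------------------------------------
# ligand-receptor enrichment
# ---------------------------------------------------------------------------

@dataclass
class LigRecResult:
    table: pd.DataFrame  # ligand, receptor, observed, null_mean, null_sd, fold, z, p, fdr
    sender: str
    receiver: str
    n_contacting_pairs: int


def ligrec_enrichment(
    cells: pd.DataFrame,
    expr: ExpressionMatrix,
    graph: ContactGraph,
    pairs: tuple[tuple[str, str], ...],
    taxonomy: Taxonomy,
    sender_type: str = "MGC",
    receiver_type: str = "IT",
    scheme: PermutationScheme | None = None,
    depth_bins: int = 50,
    min_pairs: int = 10,
    norm_scale: float = 1000.0,
) -> LigRecResult:
    """Ligand-receptor enrichment in contacting sender->receiver pairs.

    score(L, R) = mean over contacting (sender, receiver) cell pairs of
    n_L(sender) * n_R(receiver), with n the library-size-normalised
    expression.  The null redraws, per permutation, an equal number of
    non-interacting sender-receiver pairs — senders and receivers not
    involved in any contacting pair, with senders matched on the
    observed senders' depth bins.  Fold, upper-tailed Z and BH-FDR
    across the tested pairs.
    """
    scheme = scheme or PermutationScheme()
    rng = np.random.default_rng(scheme.seed)
    for lig, rec in pairs:
        for g in (lig, rec):
            if g not in expr.genes:
                raise KeyError(f"gene {g!r} not in expression matrix")

    order = pd.Series(np.arange(expr.n_cells), index=expr.cell_ids)
    row_of = order.loc[cells["cell_id"]].to_numpy()
    norm_mat, _ = normalize_expression(expr, scale=norm_scale)

    sub = cells["subclass"].to_numpy()
    s_mask = np.isin(sub, list(resolve_subclasses(sender_type, taxonomy)))
    r_mask = np.isin(sub, list(resolve_subclasses(receiver_type, taxonomy)))
    ia, ib = graph.edge_positions(cells)
    sr = s_mask[ia] & r_mask[ib]
    rs = s_mask[ib] & r_mask[ia]
    senders = np.concatenate([ia[sr], ib[rs]])
    receivers = np.concatenate([ib[sr], ia[rs]])
    n_pairs = len(senders)
    if n_pairs < min_pairs:
        raise LowPowerError(
            f"only {n_pairs} contacting ({sender_type} -> {receiver_type}) "
            f"pairs; need at least {min_pairs}"
        )
    # normalized expression columns for all tested genes
    genes_used = sorted({g for pr in pairs for g in pr})
    gcol = {g: i for i, g in enumerate(genes_used)}
    dense = np.asarray(
        norm_mat[:, [expr.gene_index(g) for g in genes_used]].todense()
    )[row_of]  # aligned to cells row order

    lig_idx = np.array([gcol[lig] for lig, _ in pairs])
    rec_idx = np.array([gcol[rec] for _, rec in pairs])
    obs_score = (dense[senders][:, lig_idx] * dense[receivers][:, rec_idx]).mean(axis=0)

    # null pools: non-interacting senders/receivers (cells of the right
    # type not involved in ANY contacting sender-receiver pair), with
    # senders matched on the observed senders' depth bins
    involved_s = np.zeros(len(cells), dtype=bool)
    involved_s[senders] = True
    involved_r = np.zeros(len(cells), dtype=bool)
    involved_r[receivers] = True
    free_s = s_mask & ~involved_s
    free_r = r_mask & ~involved_r
    if not free_s.any() or not free_r.any():
        raise LowPowerError(
            "no non-interacting sender or receiver cells left for the null"
        )
    depth = cells["depth"].to_numpy(float)
    dmax = max(1.0, float(depth.max()))
    bin_of = np.clip((depth / dmax * depth_bins).astype(int), 0, depth_bins - 1)
    free_s_all = np.flatnonzero(free_s)
    sender_pool = {}
    for b in np.unique(bin_of[senders]):
        pool = np.flatnonzero(free_s & (bin_of == b))
        sender_pool[b] = pool if len(pool) else free_s_all
    receiver_all = np.flatnonzero(free_r)
    sender_bins = bin_of[senders]
    pools = [sender_pool[bb] for bb in sender_bins]

    B = scheme.n_permutations
    draws = np.empty((B, len(pairs)))
    for b in range(B):
        s_draw = np.array([pool[rng.integers(len(pool))] for pool in pools])
        r_draw = receiver_all[rng.integers(len(receiver_all), size=n_pairs)]
        draws[b] = (dense[s_draw][:, lig_idx] * dense[r_draw][:, rec_idx]).mean(axis=0)

    mean = draws.mean(axis=0)
    sd = draws.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(mean > 0, obs_score / mean, np.nan)
        z = np.where(sd > 0, (obs_score - mean) / sd, np.nan)
    p = np.where(np.isfinite(z), norm.sf(z), np.nan)
    table = pd.DataFrame(
        {
            "ligand": [lig for lig, _ in pairs],
            "receptor": [rec for _, rec in pairs],
            "observed": obs_score,
            "null_mean": mean,
            "null_sd": sd,
            "fold_change": fold,
            "z": z,
            "p": p,
        }
    )
    table["fdr"] = bh_adjust(table["p"].to_numpy())
    return LigRecResult(
        table=table,
        sender=sender_type,
        receiver=receiver_type,
        n_contacting_pairs=n_pairs,
    )
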