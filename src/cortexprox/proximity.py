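"""Soma contact graphs, the density-preserving permutation null, pairwise
contact enrichment and the nearest-neighbor self/other test.

The null model shuffles cell-type labels within square spatial bins
while keeping every centroid fixed.  Each bin's per-type counts are
exactly preserved, so the coarse spatial density of every cell type
survives the shuffle while the identity of neighboring cells is
randomised — relabeling at fixed positions is equivalent to re-placing
types at fixed local densities.  Pairwise enrichment compares the
observed number of contacting label pairs with the permutation null via
an upper-tailed Z-test (an empirical permutation p-value is reported
alongside for auditing), with Benjamini-Hochberg FDR control across all
pairs of one analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import mannwhitneyu, norm

from .datamodel import ContactGraph


@dataclass
class PermutationScheme:
    """Density-preserving label-permutation null parameters."""

    bin_size_um: float = 100.0
    n_permutations: int = 1000
    seed: int = 0
    label_level: str = "subclass"

    def __post_init__(self):
        if self.bin_size_um <= 0:
            raise ValueError("bin_size_um must be > 0")
        if self.n_permutations < 100:
            warnings.warn(
                f"n_permutations={self.n_permutations} < 100: inference will "
                "be noisy",
                stacklevel=2,
            )


@dataclass
class EnrichmentResult:
    """Per label-pair contact enrichment against the permutation null."""

    table: pd.DataFrame
    scheme: PermutationScheme
    n_edges: int

    def row(self, a: str, b: str) -> pd.Series:
        lo, hi = sorted((a, b))
        t = self.table
        hit = t[(t["label_a"] == lo) & (t["label_b"] == hi)]
        if len(hit) == 0:
            raise KeyError(f"no enrichment row for pair ({a!r}, {b!r})")
        return hit.iloc[0]


@dataclass
class NNDistanceResult:
    """Nearest-neighbor to-self vs to-other distances per label."""

    table: pd.DataFrame  # label, n, median_self, median_other, p, fdr
    distances: dict[str, tuple[np.ndarray, np.ndarray]] = field(repr=False, default_factory=dict)


# ---------------------------------------------------------------------------
# contact graph
# ---------------------------------------------------------------------------

def build_contact_graph(
    cells: pd.DataFrame,
    mode: str = "centroid",
    scale: float = 1.1,
    tolerance_um: float = 1.0,
    polygons: dict | None = None,
) -> ContactGraph:
    """Build the soma contact/proximity graph.

    centroid mode: edge iff centroid distance <= ``scale`` * (r_i + r_j).
    boundary mode: edge iff the cell outlines, dilated by
    ``tolerance_um``, intersect; without explicit ``polygons`` the soma
    circle is used, reducing to distance <= r_i + r_j + 2*tolerance_um.
    Neighbor candidates come from a k-d tree but the result equals the
    all-pairs rule exactly.
    """
    if len(cells) < 2:
        raise ValueError("contact graph needs at least 2 cells")
    xy = cells[["x_um", "y_um"]].to_numpy(float)
    radii = cells["soma_radius_um"].to_numpy(float)
    if mode == "centroid" and not np.all(np.isfinite(radii)):
        raise ValueError("centroid mode requires finite soma radii for all cells")

    ids = cells["cell_id"].to_numpy()
    tree = cKDTree(xy)

    if mode == "centroid":
        cutoff = scale * 2.0 * float(radii.max())
        pairs = tree.query_pairs(cutoff, output_type="ndarray")
        if len(pairs):
            d = np.linalg.norm(xy[pairs[:, 0]] - xy[pairs[:, 1]], axis=1)
            keep = d <= scale * (radii[pairs[:, 0]] + radii[pairs[:, 1]])
            pairs, d = pairs[keep], d[keep]
        else:
            d = np.empty(0)
        params = {"scale": scale}
    elif mode == "boundary":
        if polygons is None:
            cutoff = 2.0 * float(radii.max()) + 2.0 * tolerance_um
            pairs = tree.query_pairs(cutoff, output_type="ndarray")
            if len(pairs):
                d = np.linalg.norm(xy[pairs[:, 0]] - xy[pairs[:, 1]], axis=1)
                keep = d <= radii[pairs[:, 0]] + radii[pairs[:, 1]] + 2.0 * tolerance_um
                pairs, d = pairs[keep], d[keep]
            else:
                d = np.empty(0)
        else:
            polys = [polygons[i] for i in ids]
            # conservative candidate radius: polygon reach from the centroid
            bound = np.array(
                [p.hausdorff_distance(p.centroid) for p in polys]
            )
            cutoff = 2.0 * float(bound.max()) + 2.0 * tolerance_um
            cand = tree.query_pairs(cutoff, output_type="ndarray")
            keep = []
            for i, j in cand:
                if polys[i].buffer(tolerance_um).intersects(
                    polys[j].buffer(tolerance_um)
                ):
                    keep.append((i, j))
            pairs = np.array(keep, dtype=int).reshape(-1, 2)
            d = (
                np.linalg.norm(xy[pairs[:, 0]] - xy[pairs[:, 1]], axis=1)
                if len(pairs)
                else np.empty(0)
            )
        params = {"tolerance_um": tolerance_um}
    else:
        raise ValueError(f"unknown contact mode {mode!r}")

    edges = pd.DataFrame(
        {
            "cell_id_a": ids[pairs[:, 0]] if len(pairs) else np.empty(0, object),
            "cell_id_b": ids[pairs[:, 1]] if len(pairs) else np.empty(0, object),
            "centroid_distance_um": d,
        }
    )
    return ContactGraph(edges=edges, mode=mode, params=params)


# ---------------------------------------------------------------------------
# density-preserving permutation
# ---------------------------------------------------------------------------

class BinPermuter:
    """Reusable within-bin label permuter over square spatial bins."""

    def __init__(self, cells: pd.DataFrame, bin_size_um: float):
        gx = np.floor(cells["x_um"].to_numpy(float) / bin_size_um).astype(np.int64)
        gy = np.floor(cells["y_um"].to_numpy(float) / bin_size_um).astype(np.int64)
        self.bin_id = (gx - gx.min()) * (gy.max() - gy.min() + 1) + (gy - gy.min()) if len(gx) else gx
        self.n = len(cells)
        self.order0 = np.argsort(self.bin_id, kind="stable")

    def permutation(self, rng: np.random.Generator) -> np.ndarray:
        """Index array ``perm``: permuted_label[i] = label[perm[i]],
        a uniform random within-bin shuffle."""
        order1 = np.lexsort((rng.random(self.n), self.bin_id))
        perm = np.empty(self.n, dtype=np.int64)
        perm[self.order0] = order1
        return perm


def permute_labels(
    cells: pd.DataFrame, scheme: PermutationScheme, rng=None
) -> pd.DataFrame:
    """One density-preserving permutation of the (subclass, cluster) labels.

    Positions are fixed; within every square bin of side
    ``scheme.bin_size_um`` the joint (class, subclass, cluster) label
    triples are shuffled among that bin's cells, so per-bin per-type
    counts are exactly preserved.
    """
    rng = rng or np.random.default_rng(scheme.seed)
    perm = BinPermuter(cells, scheme.bin_size_um).permutation(rng)
    out = cells.copy()
    for col in ("class", "subclass", "cluster"):
        out[col] = cells[col].to_numpy()[perm]
    return out


# ---------------------------------------------------------------------------
# pairwise enrichment
# ---------------------------------------------------------------------------

def _pair_counts(lab_a, lab_b, n_labels):
    lo = np.minimum(lab_a, lab_b)
    hi = np.maximum(lab_a, lab_b)
    return np.bincount(lo * n_labels + hi, minlength=n_labels * n_labels)


def pairwise_enrichment(
    cells: pd.DataFrame,
    graph: ContactGraph,
    scheme: PermutationScheme,
    min_expected: float = 5.0,
) -> EnrichmentResult:
    """Contact enrichment per unordered label pair vs the permutation null.

    Edges are held fixed while labels are permuted within bins.  Pairs
    whose null standard deviation is zero get an undefined p (flagged
    ``degenerate``); pairs with null mean below ``min_expected`` are
    flagged ``low_power``.  FDR is BH over all pairs with a defined p.
    """
    if scheme.n_permutations < 2:
        raise ValueError("n_permutations must be >= 2")
    labels = pd.Categorical(cells[scheme.label_level])
    codes = labels.codes.astype(np.int64)
    names = list(labels.categories)
    K = len(names)

    ia, ib = graph.edge_positions(cells)
    obs = _pair_counts(codes[ia], codes[ib], K)

    permuter = BinPermuter(cells, scheme.bin_size_um)
    rng = np.random.default_rng(scheme.seed)
    B = scheme.n_permutations
    s1 = np.zeros(K * K)
    s2 = np.zeros(K * K)
    ge = np.zeros(K * K)
    for _ in range(B):
        perm = permuter.permutation(rng)
        lab = codes[perm]
        c = _pair_counts(lab[ia], lab[ib], K)
        s1 += c
        s2 += c.astype(float) ** 2
        ge += c >= obs
    mean = s1 / B
    var = np.maximum(s2 / B - mean**2, 0.0)
    sd = np.sqrt(var * B / max(B - 1, 1))

    report = np.flatnonzero((obs > 0) | (s1 > 0))
    rows = []
    for code in report:
        a, b = divmod(code, K)
        with np.errstate(divide="ignore", invalid="ignore"):
            fold = obs[code] / mean[code] if mean[code] > 0 else np.nan
            z = (obs[code] - mean[code]) / sd[code] if sd[code] > 0 else np.nan
        p = float(norm.sf(z)) if np.isfinite(z) else np.nan
        rows.append(
            {
                "label_a": names[a],
                "label_b": names[b],
                "observed": int(obs[code]),
                "null_mean": mean[code],
                "null_sd": sd[code],
                "fold_change": fold,
                "z": z,
                "p": p,
                "p_empirical": (1.0 + ge[code]) / (B + 1.0),
                "degenerate": sd[code] == 0.0,
                "low_power": mean[code] < min_expected,
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["fdr"] = bh_adjust(table["p"].to_numpy())
    else:
        table["fdr"] = []
    return EnrichmentResult(table=table, scheme=scheme, n_edges=graph.n_edges)


# ---------------------------------------------------------------------------
# nearest-neighbor self/other test
# ---------------------------------------------------------------------------

def nn_distance_test(
    cells: pd.DataFrame, level: str = "subclass", min_cells: int = 20
) -> NNDistanceResult:
    """Per label: nearest same-label vs nearest different-label distances,
    Wilcoxon rank-sum one-sided (alternative: self < other), BH across
    labels."""
    xy = cells[["x_um", "y_um"]].to_numpy(float)
    lab = cells[level].to_numpy()
    rows = []
    dists: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    labels = [
        l for l, c in pd.Series(lab).value_counts().items() if c >= max(min_cells, 2)
    ]
    for label in sorted(labels):
        mask = lab == label
        if (~mask).sum() == 0:
            continue
        same = xy[mask]
        other = xy[~mask]
        d_self = cKDTree(same).query(same, k=2)[0][:, 1]
        d_other = cKDTree(other).query(same, k=1)[0]
        stat = mannwhitneyu(d_self, d_other, alternative="less")
        rows.append(
            {
                "label": label,
                "n": int(mask.sum()),
                "median_self": float(np.median(d_self)),
                "median_other": float(np.median(d_other)),
                "p": float(stat.pvalue),
            }
        )
        dists[label] = (d_self, d_other)
    table = pd.DataFrame(rows)
    if len(table):
        table["fdr"] = bh_adjust(table["p"].to_numpy())
    return NNDistanceResult(table=table, distances=dists)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def bh_adjust(p_values) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted p-values (monotone, capped at 1).

    NaN inputs yield NaN outputs and are excluded from the family size m.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    finite = np.isfinite(p)
    q = p[finite]
    if (q < 0).any() or (q > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = q.size
    if m == 0:
        return out
    order = np.argsort(q, kind="stable")
    ranked = q[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[finite] = res
    return out
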