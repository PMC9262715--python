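"""Cortical-depth distributions and depth-resolved E:I statistics.

Depth is the normalised cortical depth (0 = pia, 1 = L6/WM boundary).
``depth_profiles`` bins cells into uniform depth bins and reports
per-cluster densities normalised to unit area, together with the
per-bin excitatory/inhibitory counts, the E:I ratio curve, and its
z-score (standardised per species across bins on the log2 ratio, which
stabilises the variance of the ratio).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import LAYERS


@dataclass
class DepthProfile:
    """Binned depth densities and the E:I depth curve for one species."""

    bin_edges: np.ndarray
    profiles: pd.DataFrame      # long format: cluster, bin, density
    counts: pd.DataFrame        # long format: cluster, bin, count
    ei: pd.DataFrame            # bin, exc, inh, ei_ratio, ei_log2_z
    excluded_clusters: tuple[str, ...] = field(default_factory=tuple)

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1


def layer_assign(cells: pd.DataFrame, layer_boundaries) -> pd.DataFrame:
    """Attach layer labels from depth via half-open intervals.

    ``layer_boundaries`` are the increasing relative depths separating
    L1|L2/3|L4|L5|L6|WM; a depth exactly on a boundary goes to the
    deeper layer, and depth >= the last boundary is white matter.
    """
    bnds = np.asarray(layer_boundaries, float)
    if np.any(np.diff(bnds) <= 0):
        raise ValueError("layer_boundaries must be strictly increasing")
    depth = cells["depth"].to_numpy(float)
    idx = np.searchsorted(bnds, depth, side="right")
    out = cells.copy()
    out["layer"] = np.asarray(LAYERS, dtype=object)[idx]
    return out


def depth_profiles(
    cells: pd.DataFrame,
    n_bins: int = 50,
    min_cells: int = 20,
    max_depth: float | None = None,
) -> DepthProfile:
    """Per-cluster depth densities and the E:I depth curve.

    Clusters with fewer than ``min_cells`` cells are excluded from the
    per-cluster profiles (but still counted in the E:I curve).  Bins
    with zero inhibitory cells give an undefined (NaN) E:I ratio.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    depth = cells["depth"].to_numpy(float)
    if max_depth is None:
        max_depth = max(1.0, float(depth.max()) if len(depth) else 1.0)
    edges = np.linspace(0.0, max_depth, n_bins + 1)
    width = edges[1] - edges[0]
    # right-inclusive last bin so depth == max_depth is counted
    bin_idx = np.clip(np.searchsorted(edges, depth, side="right") - 1, 0, n_bins - 1)

    counts_rows = []
    prof_rows = []
    excluded = []
    cluster_arr = cells["cluster"].to_numpy()
    for cluster in sorted(np.unique(cluster_arr)):
        c = np.bincount(bin_idx[cluster_arr == cluster], minlength=n_bins)
        total = c.sum()
        for b in range(n_bins):
            counts_rows.append((cluster, b, int(c[b])))
        if total < min_cells:
            excluded.append(cluster)
            continue
        dens = c / (total * width)
        for b in range(n_bins):
            prof_rows.append((cluster, b, dens[b]))

    klass = cells["class"].to_numpy()
    exc = np.bincount(bin_idx[klass == "excitatory"], minlength=n_bins)
    inh = np.bincount(bin_idx[klass == "inhibitory"], minlength=n_bins)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ratio = np.where(inh > 0, exc / np.where(inh > 0, inh, 1), np.nan)
        ratio = np.where((inh == 0), np.nan, ratio)
        log2r = np.where((ratio > 0) & np.isfinite(ratio), np.log2(
            np.where((ratio > 0) & np.isfinite(ratio), ratio, 1.0)), np.nan)
    finite = np.isfinite(log2r)
    z = np.full(n_bins, np.nan)
    if finite.sum() >= 2:
        mu, sd = log2r[finite].mean(), log2r[finite].std(ddof=0)
        if sd > 0:
            z[finite] = (log2r[finite] - mu) / sd

    return DepthProfile(
        bin_edges=edges,
        profiles=pd.DataFrame(prof_rows, columns=["cluster", "bin", "density"]),
        counts=pd.DataFrame(counts_rows, columns=["cluster", "bin", "count"]),
        ei=pd.DataFrame(
            {
                "bin": np.arange(n_bins),
                "exc": exc,
                "inh": inh,
                "ei_ratio": ratio,
                "ei_log2_z": z,
            }
        ),
        excluded_clusters=tuple(excluded),
    )
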