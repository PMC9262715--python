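"""Shared in-memory containers: cell table, expression matrix, contact graph.

The cell table is a plain :class:`pandas.DataFrame` with a fixed schema
(one row per segmented cell), validated by :func:`validate_cells`.
Coordinates are physical micrometres with the origin at the section's
top-left corner and y increasing with cortical depth; all distances are
2-D Euclidean (sections are analysed as planar slices).  ``depth`` is
the normalised cortical depth: 0 at the pia, 1 at the L6/white-matter
boundary, values above 1 lie in white matter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

#: Required cell-table columns, in canonical order.
CELL_COLUMNS = (
    "cell_id",
    "x_um",
    "y_um",
    "soma_radius_um",
    "depth",
    "layer",
    "class",
    "subclass",
    "cluster",
    "section_id",
    "species",
)

LAYERS = ("L1", "L2/3", "L4", "L5", "L6", "WM")


class SchemaError(ValueError):
    """Malformed input: missing columns, duplicate ids, bad values."""


def validate_cells(cells: pd.DataFrame, taxonomy=None) -> pd.DataFrame:
    """Validate a cell table against the schema; return it unchanged.

    Raises :class:`SchemaError` naming the offending column or row.  If a
    taxonomy is given, cluster and subclass labels must resolve in it.
    """
    missing = [c for c in CELL_COLUMNS if c not in cells.columns]
    if missing:
        raise SchemaError(f"cell table missing required columns: {missing}")
    dup = cells["cell_id"][cells["cell_id"].duplicated()]
    if len(dup):
        raise SchemaError(f"duplicate cell_id values: {sorted(set(dup))[:10]}")
    for col in ("x_um", "y_um", "soma_radius_um", "depth"):
        vals = pd.to_numeric(cells[col], errors="coerce").to_numpy(float)
        bad = ~np.isfinite(vals)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise SchemaError(f"non-finite value in column {col!r} at row {row}")
    if (cells["soma_radius_um"].to_numpy(float) <= 0).any():
        raise SchemaError("soma_radius_um must be > 0")
    if (cells["depth"].to_numpy(float) < 0).any():
        raise SchemaError("depth must be >= 0")
    bad_layer = set(cells["layer"].unique()) - set(LAYERS)
    if bad_layer:
        raise SchemaError(f"unknown layer labels: {sorted(bad_layer)}")
    if taxonomy is not None:
        taxonomy.validate_labels(cells["cluster"], cells["subclass"])
    return cells


@dataclass
class ExpressionMatrix:
    """Sparse cells x genes transcript-count matrix aligned to a cell table."""

    matrix: sp.csr_matrix
    genes: list[str]
    cell_ids: list[str]

    def __post_init__(self):
        self.matrix = sp.csr_matrix(self.matrix)
        if self.matrix.shape != (len(self.cell_ids), len(self.genes)):
            raise SchemaError(
                f"expression matrix shape {self.matrix.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.genes)} genes"
            )
        if self.matrix.nnz and self.matrix.data.min() < 0:
            raise SchemaError("expression counts must be non-negative")
        data = self.matrix.data
        if data.size and not np.allclose(data, np.round(data)):
            raise SchemaError("expression counts must be integers")

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in expression matrix") from None

    def counts_for(self, gene: str) -> np.ndarray:
        """Dense per-cell count vector for one gene."""
        return np.asarray(
            self.matrix[:, self.gene_index(gene)].todense()
        ).ravel()


def normalize_expression(
    expr: ExpressionMatrix, scale: float = 1000.0
) -> tuple[sp.csr_matrix, np.ndarray]:
    """Library-size normalise so every non-empty cell row sums to ``scale``.

    Returns ``(normalized, zero_flags)`` where ``zero_flags`` marks cells
    whose total count is zero (their rows are left all-zero rather than
    divided by zero).
    """
    if expr.n_cells == 0:
        raise SchemaError("cannot normalize an empty expression matrix")
    totals = np.asarray(expr.matrix.sum(axis=1)).ravel()
    zero = totals == 0
    factors = np.where(zero, 0.0, scale / np.where(zero, 1.0, totals))
    norm = sp.diags(factors) @ expr.matrix.astype(float)
    return sp.csr_matrix(norm), zero


@dataclass
class ContactGraph:
    """Undirected soma contact / proximity edges over one cell table.

    ``edges`` holds one row per unordered pair (cell_id_a < cell_id_b by
    table position) with the centroid distance; ``mode`` and ``params``
    record the rule that produced the edges so it can be re-checked.
    """

    edges: pd.DataFrame  # columns: cell_id_a, cell_id_b, centroid_distance_um
    mode: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        e = self.edges
        if list(e.columns[:3]) != ["cell_id_a", "cell_id_b", "centroid_distance_um"]:
            raise SchemaError(
                "contact graph edges need columns "
                "cell_id_a, cell_id_b, centroid_distance_um"
            )
        if (e["cell_id_a"] == e["cell_id_b"]).any():
            raise SchemaError("contact graph contains self-edges")
        a = e["cell_id_a"].astype(str).to_numpy()
        b = e["cell_id_b"].astype(str).to_numpy()
        lo = np.where(a <= b, a, b)
        hi = np.where(a <= b, b, a)
        if pd.Series(np.char.add(np.char.add(lo, "\x1f"), hi)).duplicated().any():
            raise SchemaError("contact graph contains duplicate pairs")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_positions(self, cells: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """Edge endpoints as integer positions into ``cells`` row order."""
        pos = pd.Series(np.arange(len(cells)), index=cells["cell_id"])
        ia = pos.loc[self.edges["cell_id_a"]].to_numpy()
        ib = pos.loc[self.edges["cell_id_b"]].to_numpy()
        return ia, ib
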