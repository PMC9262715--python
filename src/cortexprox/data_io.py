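"""Readers and writers for the on-disk formats.

Cell tables are UTF-8 comma-separated CSV with a header row ('.' decimal);
expression matrices are MatrixMarket MTX with plain-text TSV sidecars for
the gene and cell-id lists; nucleus outlines go to GeoJSON; generator and
run configs to YAML/JSON.  All readers validate and reject malformed
input rather than silently coercing it.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from .datamodel import CELL_COLUMNS, ExpressionMatrix, SchemaError, validate_cells


# -- cell tables -----------------------------------------------------------

def write_cells(cells: pd.DataFrame, path) -> None:
    """Write a validated cell table to CSV (extra columns are preserved)."""
    validate_cells(cells)
    ordered = [c for c in CELL_COLUMNS if c in cells.columns]
    extra = [c for c in cells.columns if c not in CELL_COLUMNS]
    cells[ordered + extra].to_csv(path, index=False)


def read_cells(path, taxonomy=None) -> pd.DataFrame:
    """Read and validate a cell-table CSV."""
    cells = pd.read_csv(path, dtype={"cell_id": str})
    return validate_cells(cells, taxonomy=taxonomy)


# -- expression matrices ---------------------------------------------------

def write_expression(expr: ExpressionMatrix, prefix) -> None:
    """Write MTX + sidecars: ``<prefix>.mtx``, ``<prefix>.genes.tsv``,
    ``<prefix>.cells.tsv``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(prefix) + ".mtx", expr.matrix.astype(int))
    pd.Series(expr.genes, name="gene").to_csv(
        str(prefix) + ".genes.tsv", sep="\t", index=False, header=False
    )
    pd.Series(expr.cell_ids, name="cell_id").to_csv(
        str(prefix) + ".cells.tsv", sep="\t", index=False, header=False
    )


def read_expression(prefix) -> ExpressionMatrix:
    """Read an MTX + sidecar trio written by :func:`write_expression`."""
    prefix = str(prefix)
    mat = sp.csr_matrix(scipy.io.mmread(prefix + ".mtx"))
    genes = pd.read_csv(prefix + ".genes.tsv", sep="\t", header=None)[0].astype(str).tolist()
    cell_ids = pd.read_csv(prefix + ".cells.tsv", sep="\t", header=None)[0].astype(str).tolist()
    if mat.shape != (len(cell_ids), len(genes)):
        raise SchemaError(
            f"matrix shape {mat.shape} does not match sidecars "
            f"({len(cell_ids)} cells, {len(genes)} genes)"
        )
    return ExpressionMatrix(mat, genes, cell_ids)


# -- nucleus outlines ------------------------------------------------------

def write_nuclei_geojson(cells: pd.DataFrame, path, n_vertices: int = 24) -> None:
    """Write per-cell nucleus outlines as GeoJSON polygons.

    Without segmented outlines the soma circle (centroid + radius) is
    polygonised with ``n_vertices`` vertices.
    """
    theta = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    features = []
    for _, row in cells.iterrows():
        ring = [
            [float(row.x_um + row.soma_radius_um * np.cos(t)),
             float(row.y_um + row.soma_radius_um * np.sin(t))]
            for t in theta
        ]
        ring.append(ring[0])
        features.append(
            {
                "type": "Feature",
                "properties": {"cell_id": row.cell_id},
                "geometry": {"type": "Polygon", "coordinates": [ring]},
            }
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


def read_nuclei_geojson(path) -> dict:
    """Read nucleus outlines back as ``{cell_id: shapely.Polygon}``."""
    from shapely.geometry import shape

    payload = json.loads(Path(path).read_text())
    if payload.get("type") != "FeatureCollection":
        raise SchemaError("expected a GeoJSON FeatureCollection")
    out = {}
    for feat in payload["features"]:
        cid = feat.get("properties", {}).get("cell_id")
        if cid is None:
            raise SchemaError("GeoJSON feature missing a cell_id property")
        out[str(cid)] = shape(feat["geometry"])
    return out


# -- configs ---------------------------------------------------------------

CONFIG_SCHEMA_VERSION = 1


def write_config(config_dict: dict, path) -> None:
    """Write a config mapping as YAML (or JSON when the suffix is .json)."""
    payload = {"schema_version": CONFIG_SCHEMA_VERSION, **config_dict}
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(payload, indent=2))
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))


def read_config(path) -> dict:
    path = Path(path)
    if path.suffix == ".json":
        payload = json.loads(path.read_text())
    else:
        payload = yaml.safe_load(path.read_text())
    version = payload.pop("schema_version", None)
    if version != CONFIG_SCHEMA_VERSION:
        raise SchemaError(
            f"unsupported config schema_version {version!r} "
            f"(expected {CONFIG_SCHEMA_VERSION})"
        )
    return payload
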