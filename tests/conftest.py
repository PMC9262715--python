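import numpy as np
import pandas as pd
import pytest

from cortexprox import (
    build_contact_graph,
    default_human_config,
    default_human_taxonomy,
    generate_tissue,
)


@pytest.fixture(scope="session")
def tax():
    return default_human_taxonomy()


@pytest.fixture(scope="session")
def small_human(tax):
    """One ~8k-cell human section with all default injections, shared
    across tests (generation is deterministic for the fixed seed)."""
    cfg = default_human_config(section_width_um=3000.0, seed=7)
    cells, expr = generate_tissue(cfg, tax)
    return cfg, cells, expr


@pytest.fixture(scope="session")
def small_human_graph(small_human):
    _, cells, _ = small_human
    return build_contact_graph(cells, mode="centroid", scale=1.1)


def make_cells(
    xs,
    ys,
    clusters,
    tax,
    radii=None,
    species="human",
    depths=None,
):
    """Hand-build a minimal valid cell table from positions + cluster labels."""
    n = len(xs)
    radii = radii if radii is not None else np.full(n, 5.0)
    depths = depths if depths is not None else np.clip(np.asarray(ys, float) / 1000.0, 0, 2)
    sub = [tax.subclass_of(c) for c in clusters]
    return pd.DataFrame(
        {
            "cell_id": [f"c{i:04d}" for i in range(n)],
            "x_um": np.asarray(xs, float),
            "y_um": np.asarray(ys, float),
            "soma_radius_um": np.asarray(radii, float),
            "depth": np.asarray(depths, float),
            "layer": ["L2/3" if d < 1 else "WM" for d in depths],
            "class": [tax.class_of_subclass(s) for s in sub],
            "subclass": sub,
            "cluster": list(clusters),
            "section_id": "T1",
            "species": species,
        }
    )
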