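"""Cell-composition proportions and headline ratios.

Reports per-label counts and proportions at the class, subclass or
cluster level within a choice of denominator population (all cells,
neurons, excitatory, inhibitory, or IT neurons), plus the two headline
ratios of cortical cytoarchitecture: the glia-to-neuron ratio (glia =
astrocytes + oligodendrocytes + OPCs + microglia; endothelial and mural
cells are non-neuronal but not glia) and the excitatory-to-inhibitory
neuron ratio.  White-matter cells are excluded by default, as cortical
composition figures conventionally are.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .taxonomy import EXCITATORY, INHIBITORY, Taxonomy

logger = logging.getLogger(__name__)

LEVELS = ("class", "subclass", "cluster")
DENOMINATORS = ("all_cells", "neurons", "excitatory", "inhibitory", "IT")


class EmptyDenominatorError(ValueError):
    """The selected denominator population contains no cells."""


@dataclass
class CompositionResult:
    level: str
    denominator: str
    table: pd.DataFrame          # label, count, proportion
    glia_to_neuron: float
    exc_to_inh: float
    n_denominator: int
    species: str = ""

    def proportion(self, label: str) -> float:
        row = self.table.loc[self.table["label"] == label, "proportion"]
        return float(row.iloc[0]) if len(row) else 0.0


def _denominator_mask(cells: pd.DataFrame, denominator: str, taxonomy: Taxonomy):
    klass = cells["class"].to_numpy()
    if denominator == "all_cells":
        return np.ones(len(cells), dtype=bool)
    if denominator == "neurons":
        return (klass == EXCITATORY) | (klass == INHIBITORY)
    if denominator == "excitatory":
        return klass == EXCITATORY
    if denominator == "inhibitory":
        return klass == INHIBITORY
    if denominator == "IT":
        it = taxonomy.it_subclasses
        return cells["subclass"].isin(it).to_numpy()
    raise ValueError(f"unknown denominator {denominator!r}")


def composition(
    cells: pd.DataFrame,
    taxonomy: Taxonomy,
    level: str = "subclass",
    denominator: str = "all_cells",
    exclude_wm: bool = True,
) -> CompositionResult:
    """Counts and proportions of labels at ``level`` within ``denominator``."""
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}")
    taxonomy.validate_labels(cells["cluster"], cells["subclass"])

    work = cells
    if exclude_wm:
        unset = (work["depth"].to_numpy(float) > 1.0) & (
            ~work["layer"].isin(("WM",)).to_numpy()
        )
        if unset.any():
            logger.warning(
                "%d cells with depth > 1 but layer not WM; treating as WM",
                int(unset.sum()),
            )
        keep = (work["layer"] != "WM").to_numpy() & ~unset
        work = work.loc[keep]

    mask = _denominator_mask(work, denominator, taxonomy)
    pop = work.loc[mask]
    if len(pop) == 0:
        raise EmptyDenominatorError(
            f"denominator {denominator!r} selects no cells"
        )

    counts = pop[level].value_counts().sort_index()
    table = pd.DataFrame(
        {
            "label": counts.index,
            "count": counts.to_numpy(),
            "proportion": counts.to_numpy() / len(pop),
        }
    ).reset_index(drop=True)

    sub = work["subclass"]
    n_glia = int(sub.isin(taxonomy.glial_subclasses).sum())
    n_exc = int((work["class"] == EXCITATORY).sum())
    n_inh = int((work["class"] == INHIBITORY).sum())
    gn = n_glia / (n_exc + n_inh) if (n_exc + n_inh) else math.nan
    ei = n_exc / n_inh if n_inh else math.nan

    species = str(work["species"].iloc[0]) if len(work) else ""
    return CompositionResult(
        level=level,
        denominator=denominator,
        table=table,
        glia_to_neuron=gn,
        exc_to_inh=ei,
        n_denominator=len(pop),
        species=species,
    )


def aggregate_to_subclass(result: CompositionResult, taxonomy: Taxonomy) -> pd.DataFrame:
    """Aggregate a cluster-level composition table up to subclasses."""
    if result.level != "cluster":
        raise ValueError("aggregate_to_subclass needs a cluster-level result")
    t = result.table.copy()
    t["subclass"] = [taxonomy.subclass_of(c) for c in t["label"]]
    agg = t.groupby("subclass", sort=True).agg(
        count=("count", "sum"), proportion=("proportion", "sum")
    ).reset_index().rename(columns={"subclass": "label"})
    return agg


def compare_species(
    human: CompositionResult, mouse: CompositionResult
) -> pd.DataFrame:
    """Per-label human/mouse proportion ratios plus ratio-of-ratios.

    A zero mouse proportion yields an undefined (NaN) ratio, never
    infinity.  The returned frame carries ``attrs`` entries
    ``glia_to_neuron_ratio_of_ratios`` and ``exc_to_inh_ratio_of_ratios``.
    """
    if (human.level, human.denominator) != (mouse.level, mouse.denominator):
        raise ValueError(
            "species comparison requires matching level and denominator"
        )
    merged = pd.merge(
        human.table.rename(columns={"count": "human_count", "proportion": "human_prop"}),
        mouse.table.rename(columns={"count": "mouse_count", "proportion": "mouse_prop"}),
        on="label",
        how="outer",
    ).fillna({"human_count": 0, "mouse_count": 0, "human_prop": 0.0, "mouse_prop": 0.0})
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = merged["human_prop"] / merged["mouse_prop"]
    merged["human_to_mouse_ratio"] = np.where(
        merged["mouse_prop"] > 0, ratio, np.nan
    )
    merged.attrs["glia_to_neuron_ratio_of_ratios"] = (
        human.glia_to_neuron / mouse.glia_to_neuron
        if mouse.glia_to_neuron and math.isfinite(mouse.glia_to_neuron)
        else math.nan
    )
    merged.attrs["exc_to_inh_ratio_of_ratios"] = (
        human.exc_to_inh / mouse.exc_to_inh
        if mouse.exc_to_inh and math.isfinite(mouse.exc_to_inh)
        else math.nan
    )
    return merged
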