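"""Synthetic cortical-tissue generator.

Generates per-section cell tables and sparse expression matrices with
known ground truth, emulating imaging-based spatial transcriptomics of
human temporal cortex and mouse cortex:

* a flat rectangular section with normalised depth = y / cortical
  thickness (0 = pia, 1 = L6/WM boundary, >1 = white matter margin);
* cluster identities drawn from a configured composition, depths from
  per-cluster truncated-Gaussian laminar profiles;
* a hard-core point process (no two independently placed somata closer
  than ``hardcore_distance_um``), placed by dart throwing;
* injected interaction structure — satellite cell pairs at soma-contact
  distance, vessel-like chains of endothelial/mural cells with recruited
  glia, a GAD1-positive OPC subpopulation, and contact-conditioned
  ligand–receptor expression boosts;
* negative-binomial transcript counts with subclass marker structure and
  per-cell lognormal library-size variation.

Interaction injections reposition cells drawn from the base composition,
so they never change the composition ground truth.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import truncnorm

from .datamodel import ExpressionMatrix
from .laminar import layer_assign
from .taxonomy import Taxonomy, TaxonomyError, resolve_subclasses


class GenerationError(RuntimeError):
    """Unsatisfiable generator configuration (e.g. hard-core packing)."""


# ---------------------------------------------------------------------------
# config dataclasses
# ---------------------------------------------------------------------------

@dataclass
class SatelliteSpec:
    """Reposition a fraction of ``partner_subclass`` cells to soma-contact
    distance from cells of ``focal_subclass`` (``partners_per_focal`` each)."""

    focal_subclass: str
    partner_subclass: str
    fraction_of_partner: float
    contact_gap_um: float = 0.5
    partners_per_focal: int = 1


@dataclass
class VesselSpec:
    """Vessel-like chains of ENDO/MURAL cells with optional glial recruits."""

    n_vessels: int = 0
    cells_per_vessel: int = 8
    step_um: float = 7.0
    mural_fraction: float = 0.3
    glial_recruit: dict[str, int] = field(default_factory=dict)


@dataclass
class ExpressionSpec:
    """Negative-binomial count model with cluster marker structure.

    ``nb_dispersion`` is the inverse-size parameter alpha (variance =
    mu + alpha * mu^2); ``marker_sets`` maps cluster -> gene indices whose
    mean is multiplied by ``marker_fold`` in that cluster.
    """

    n_genes: int = 120
    baseline_nb_mean: float = 0.2
    nb_dispersion: float = 0.2
    marker_sets: dict[str, tuple[int, ...]] = field(default_factory=dict)
    marker_fold: float = 50.0
    gene_names: tuple[str, ...] = ()
    library_sigma: float = 0.3


@dataclass
class LigRecSpec:
    """Multiply ligand/receptor means in contacting sender→receiver pairs."""

    ligand_gene: str
    receptor_gene: str
    sender_subclass: str
    receiver_subclass: str
    contact_boost_fold: float = 4.0


@dataclass
class TissueConfig:
    """Full parameterisation of one synthetic section."""

    section_width_um: float
    section_height_um: float  # cortical thickness; depth = y / this
    layer_boundaries: tuple[float, ...]
    density_cells_per_mm2: float
    composition: dict[str, float]  # cluster -> probability (cortical ribbon)
    laminar_profiles: dict[str, tuple[float, float]]  # cluster -> (mean, sd)
    hardcore_distance_um: float
    soma_radius_um: dict[str, tuple[float, float]]  # subclass -> (mean, sd)
    satellite_specs: list[SatelliteSpec] = field(default_factory=list)
    vessel_spec: VesselSpec = field(default_factory=VesselSpec)
    expression_spec: ExpressionSpec = field(default_factory=ExpressionSpec)
    gad1_positive_opc_fraction: float = 0.5
    ligrec_spec: list[LigRecSpec] = field(default_factory=list)
    wm_margin: float = 0.12           # WM band thickness, relative depth
    wm_density_factor: float = 0.8    # WM density relative to cortex
    wm_composition: dict[str, float] = field(default_factory=dict)
    contact_scale: float = 1.1        # centroid-contact scale for injections
    species: str = "human"
    section_id: str = "S1"
    seed: int = 0

    def validate(self) -> None:
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-9:
            raise GenerationError(f"composition sums to {total!r}, not 1")
        bnds = tuple(self.layer_boundaries)
        if any(b2 <= b1 for b1, b2 in zip(bnds, bnds[1:])) or not (
            0 < bnds[0] and bnds[-1] <= 1.0
        ):
            raise GenerationError(
                "layer_boundaries must be strictly increasing within (0, 1]"
            )
        if self.hardcore_distance_um <= 0:
            raise GenerationError("hardcore_distance_um must be > 0")
        fractions = [s.fraction_of_partner for s in self.satellite_specs]
        fractions += [self.gad1_positive_opc_fraction, self.vessel_spec.mural_fraction]
        if any(not (0.0 <= f <= 1.0) for f in fractions):
            raise GenerationError("all fractions must lie in [0, 1]")
        if self.wm_composition:
            wtot = sum(self.wm_composition.values())
            if abs(wtot - 1.0) > 1e-9:
                raise GenerationError(f"wm_composition sums to {wtot!r}, not 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["satellite_specs"] = [asdict(s) for s in self.satellite_specs]
        d["ligrec_spec"] = [asdict(s) for s in self.ligrec_spec]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TissueConfig":
        d = dict(d)
        d["satellite_specs"] = [SatelliteSpec(**s) for s in d.get("satellite_specs", [])]
        d["ligrec_spec"] = [LigRecSpec(**s) for s in d.get("ligrec_spec", [])]
        d["vessel_spec"] = VesselSpec(**d.get("vessel_spec", {}))
        es = dict(d.get("expression_spec", {}))
        es["marker_sets"] = {k: tuple(v) for k, v in es.get("marker_sets", {}).items()}
        es["gene_names"] = tuple(es.get("gene_names", ()))
        d["expression_spec"] = ExpressionSpec(**es)
        d["layer_boundaries"] = tuple(d["layer_boundaries"])
        d["laminar_profiles"] = {k: tuple(v) for k, v in d["laminar_profiles"].items()}
        d["soma_radius_um"] = {k: tuple(v) for k, v in d["soma_radius_um"].items()}
        return cls(**d)


# ---------------------------------------------------------------------------
# hard-core placement grid
# ---------------------------------------------------------------------------

class _HardcoreGrid:
    """Uniform spatial hash for incremental minimum-distance queries."""

    def __init__(self, cell_size: float):
        self.h = float(cell_size)
        self.bins: dict[tuple[int, int], dict[int, tuple[float, float]]] = {}

    def _key(self, x: float, y: float) -> tuple[int, int]:
        return (int(x // self.h), int(y // self.h))

    def ok(self, x: float, y: float, min_dist: float, exclude: int = -1) -> bool:
        gx, gy = self._key(x, y)
        md2 = min_dist * min_dist
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                occ = self.bins.get((gx + dx, gy + dy))
                if not occ:
                    continue
                for idx, (px, py) in occ.items():
                    if idx == exclude:
                        continue
                    if (px - x) ** 2 + (py - y) ** 2 < md2:
                        return False
        return True

    def add(self, idx: int, x: float, y: float) -> None:
        self.bins.setdefault(self._key(x, y), {})[idx] = (x, y)

    def move(self, idx: int, old_xy: tuple[float, float], x: float, y: float) -> None:
        occ = self.bins.get(self._key(*old_xy))
        if occ is not None:
            occ.pop(idx, None)
        self.add(idx, x, y)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _truncnorm_draw(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_tissue(
    config: TissueConfig, taxonomy: Taxonomy
) -> tuple[pd.DataFrame, ExpressionMatrix]:
    """Generate one synthetic section: (cell table, expression matrix).

    The returned cell table carries an extra ``placement`` column
    ("random", "wm", "satellite", "vessel", "recruit") recording how each
    cell was positioned; independently placed cells ("random"/"wm")
    satisfy the hard-core constraint against each other.
    """
    config.validate()
    for cl in config.composition:
        if cl not in taxonomy.cluster_to_subclass:
            raise TaxonomyError(f"composition references unknown cluster {cl!r}")
    for cl in config.wm_composition:
        if cl not in taxonomy.cluster_to_subclass:
            raise TaxonomyError(f"wm_composition references unknown cluster {cl!r}")

    rng = np.random.default_rng(config.seed)
    W, H = config.section_width_um, config.section_height_um
    lam = config.density_cells_per_mm2 / 1e6  # per um^2

    n_cortex = int(rng.poisson(lam * W * H))
    wm_h = config.wm_margin * H
    n_wm = 0
    if config.wm_composition and wm_h > 0:
        n_wm = int(rng.poisson(lam * config.wm_density_factor * W * wm_h))

    # -- identities and depths -------------------------------------------
    clusters_cortex = rng.choice(
        list(config.composition), size=n_cortex, p=list(config.composition.values())
    )
    depth = np.empty(n_cortex + n_wm)
    for cl in np.unique(clusters_cortex):
        idx = np.flatnonzero(clusters_cortex == cl)
        m, s = config.laminar_profiles[cl]
        depth[idx] = _truncnorm_draw(rng, m, s, 0.0, 1.0 - 1e-9, idx.size)
    if n_wm:
        clusters_wm = rng.choice(
            list(config.wm_composition), size=n_wm,
            p=list(config.wm_composition.values()),
        )
        depth[n_cortex:] = rng.uniform(1.0, 1.0 + config.wm_margin, n_wm)
        clusters = np.concatenate([clusters_cortex, clusters_wm])
    else:
        clusters = clusters_cortex

    n = n_cortex + n_wm
    subclass = np.array([taxonomy.subclass_of(c) for c in clusters])
    klass = np.array([taxonomy.class_of_subclass(s) for s in subclass])

    # -- hard-core dart throwing -----------------------------------------
    hc = config.hardcore_distance_um
    grid = _HardcoreGrid(hc)
    xs = np.empty(n)
    ys = depth * H
    budget = 100 * max(n, 1)
    spent = 0
    for i in range(n):
        placed = False
        for _ in range(200):
            spent += 1
            if spent > budget:
                raise GenerationError(
                    f"hard-core packing failed after {budget} attempts: density "
                    f"{config.density_cells_per_mm2}/mm^2 is unsatisfiable with "
                    f"hardcore_distance_um={hc}"
                )
            x = rng.uniform(0.0, W)
            if grid.ok(x, ys[i], hc):
                xs[i] = x
                grid.add(i, x, ys[i])
                placed = True
                break
        if not placed:
            raise GenerationError(
                f"hard-core packing failed for cell {i}: density "
                f"{config.density_cells_per_mm2}/mm^2 conflicts with "
                f"hardcore_distance_um={hc}"
            )

    # -- soma radii (truncated normal, floor 2 um) ------------------------
    radius = np.empty(n)
    for sub in np.unique(subclass):
        idx = np.flatnonzero(subclass == sub)
        m, s = config.soma_radius_um.get(sub, (4.5, 0.8))
        radius[idx] = _truncnorm_draw(rng, m, s, 2.0, np.inf, idx.size)

    placement = np.array(
        ["random"] * n_cortex + ["wm"] * n_wm, dtype=object
    )

    def _reposition(i: int, x: float, y: float) -> None:
        grid.move(i, (xs[i], ys[i]), x, y)
        xs[i], ys[i] = x, y
        depth[i] = y / H

    def _contact_place(i, anchor, gap, avoid=(), tries=24):
        """Place cell i at soma-contact distance from anchor; avoid the
        hard-core zone of everything except the anchor when possible."""
        dist = radius[i] + radius[anchor] + gap
        last = None
        for _ in range(tries):
            theta = rng.uniform(0.0, 2.0 * math.pi)
            x = xs[anchor] + dist * math.cos(theta)
            y = ys[anchor] + dist * math.sin(theta)
            last = (x, y)
            if not (0.0 <= x <= W and 0.0 <= y <= H * (1.0 + config.wm_margin)):
                continue
            if any(
                (x - xs[j]) ** 2 + (y - ys[j]) ** 2 < (0.8 * dist) ** 2
                for j in avoid
            ):
                continue
            if grid.ok(x, y, hc, exclude=anchor):
                _reposition(i, x, y)
                return
        _reposition(i, *last)  # crowded neighbourhood: accept the overlap

    # -- vessels ----------------------------------------------------------
    vs = config.vessel_spec
    if vs.n_vessels > 0 and vs.cells_per_vessel > 1:
        endo_pool = list(np.flatnonzero((subclass == "ENDO") & (placement == "random")))
        mural_pool = list(np.flatnonzero((subclass == "MURAL") & (placement == "random")))
        rng.shuffle(endo_pool)
        rng.shuffle(mural_pool)
        n_mural = int(round(vs.mural_fraction * vs.cells_per_vessel))
        for _v in range(vs.n_vessels):
            members: list[int] = []
            take_m = min(n_mural, len(mural_pool))
            members += [mural_pool.pop() for _ in range(take_m)]
            need = vs.cells_per_vessel - len(members)
            if len(endo_pool) < need:
                break  # vascular pool exhausted for this section size
            members += [endo_pool.pop() for _ in range(need)]
            rng.shuffle(members)
            # self-avoiding random-walk chain
            x0 = rng.uniform(0.05 * W, 0.95 * W)
            y0 = rng.uniform(0.05 * H, 0.95 * H)
            ang = rng.uniform(0.0, 2.0 * math.pi)
            path = [(x0, y0)]
            while len(path) < len(members):
                for _ in range(20):
                    cand_ang = ang + rng.normal(0.0, 0.4)
                    px, py = path[-1]
                    cx = px + vs.step_um * math.cos(cand_ang)
                    cy = py + vs.step_um * math.sin(cand_ang)
                    if not (0.0 <= cx <= W and 0.0 <= cy <= H):
                        continue
                    if any(
                        (cx - qx) ** 2 + (cy - qy) ** 2 < (0.8 * vs.step_um) ** 2
                        for qx, qy in path[:-1]
                    ):
                        continue
                    ang = cand_ang
                    path.append((cx, cy))
                    break
                else:  # walk got stuck; restart direction
                    ang = rng.uniform(0.0, 2.0 * math.pi)
            for i, (x, y) in zip(members, path):
                _reposition(i, x, y)
                placement[i] = "vessel"
            # recruited glia at contact distance from a random chain member
            for gsub, count in vs.glial_recruit.items():
                pool = np.flatnonzero((subclass == gsub) & (placement == "random"))
                if pool.size == 0:
                    continue
                chosen = rng.choice(pool, size=min(count, pool.size), replace=False)
                for i in chosen:
                    anchor = members[int(rng.integers(len(members)))]
                    _contact_place(i, anchor, 0.5, avoid=members)
                    placement[i] = "recruit"

    # -- satellites --------------------------------------------------------
    for spec in config.satellite_specs:
        partner_total = int((subclass == spec.partner_subclass).sum())
        pool = np.flatnonzero(
            (subclass == spec.partner_subclass) & (placement == "random")
        )
        m = min(int(round(spec.fraction_of_partner * partner_total)), pool.size)
        if m == 0:
            continue
        partners = rng.choice(pool, size=m, replace=False)
        k = max(1, spec.partners_per_focal)
        n_focal = math.ceil(m / k)
        focal_pool = np.flatnonzero(
            (subclass == spec.focal_subclass) & (placement == "random")
        )
        focal_pool = np.setdiff1d(focal_pool, partners)
        if focal_pool.size == 0:
            continue
        n_focal = min(n_focal, focal_pool.size)
        focals = rng.choice(focal_pool, size=n_focal, replace=False)
        for j, p in enumerate(partners[: n_focal * k]):
            f = int(focals[j // k])
            _contact_place(int(p), f, spec.contact_gap_um)
            placement[p] = "satellite"

    # -- assemble table ----------------------------------------------------
    cell_ids = [
        f"{config.species}-{config.section_id}-{i:06d}" for i in range(n)
    ]
    cells = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "x_um": xs,
            "y_um": ys,
            "soma_radius_um": radius,
            "depth": depth,
            "class": klass,
            "subclass": subclass,
            "cluster": clusters,
            "section_id": config.section_id,
            "species": config.species,
            "placement": placement,
        }
    )
    cells = layer_assign(cells, config.layer_boundaries)
    cells = cells[
        [
            "cell_id", "x_um", "y_um", "soma_radius_um", "depth", "layer",
            "class", "subclass", "cluster", "section_id", "species", "placement",
        ]
    ]

    expr = _generate_expression(cells, config, taxonomy, rng)
    return cells, expr


def _generate_expression(
    cells: pd.DataFrame, config: TissueConfig, taxonomy: Taxonomy, rng
) -> ExpressionMatrix:
    es = config.expression_spec
    n, G = len(cells), es.n_genes
    genes = list(es.gene_names) or [f"gene_{i:04d}" for i in range(G)]
    if len(genes) != G:
        raise GenerationError(
            f"expression_spec.gene_names has {len(genes)} entries for {G} genes"
        )
    if n == 0:
        return ExpressionMatrix(sp.csr_matrix((0, G), dtype=int), genes, [])

    mu = np.full((n, G), es.baseline_nb_mean)
    cluster_arr = cells["cluster"].to_numpy()
    for cl, gene_idx in es.marker_sets.items():
        rows = np.flatnonzero(cluster_arr == cl)
        if rows.size and len(gene_idx):
            mu[np.ix_(rows, list(gene_idx))] *= es.marker_fold

    # GAD1-positive OPC subpopulation; GAD2 / SLC32A1 silent in all OPCs
    opc = np.flatnonzero(cells["subclass"].to_numpy() == "OPC")
    if opc.size:
        for g in ("GAD2", "SLC32A1"):
            if g in genes:
                mu[opc, genes.index(g)] = 0.0
        if "GAD1" in genes:
            gi = genes.index("GAD1")
            pos = rng.random(opc.size) < config.gad1_positive_opc_fraction
            mu[opc, gi] = np.where(
                pos, es.baseline_nb_mean * es.marker_fold, 0.0
            )

    # contact-conditioned ligand-receptor boosts
    if config.ligrec_spec:
        from .proximity import build_contact_graph

        graph = build_contact_graph(cells, mode="centroid", scale=config.contact_scale)
        ia, ib = graph.edge_positions(cells)
        sub = cells["subclass"].to_numpy()
        for spec in config.ligrec_spec:
            senders = resolve_subclasses(spec.sender_subclass, taxonomy)
            receivers = resolve_subclasses(spec.receiver_subclass, taxonomy)
            s_mask = np.isin(sub, list(senders))
            r_mask = np.isin(sub, list(receivers))
            hit_sr = s_mask[ia] & r_mask[ib]
            hit_rs = s_mask[ib] & r_mask[ia]
            send_cells = np.union1d(ia[hit_sr], ib[hit_rs])
            recv_cells = np.union1d(ib[hit_sr], ia[hit_rs])
            if spec.ligand_gene in genes:
                mu[send_cells, genes.index(spec.ligand_gene)] *= spec.contact_boost_fold
            if spec.receptor_gene in genes:
                mu[recv_cells, genes.index(spec.receptor_gene)] *= spec.contact_boost_fold

    lib = np.exp(rng.normal(0.0, es.library_sigma, n))
    theta = 1.0 / es.nb_dispersion
    lam = rng.gamma(theta, (mu * lib[:, None]) / theta)
    counts = rng.poisson(lam)
    return ExpressionMatrix(
        sp.csr_matrix(counts), genes, cells["cell_id"].tolist()
    )


# ---------------------------------------------------------------------------
# default configs encoding the published human / mouse compositions
# ---------------------------------------------------------------------------

# Human headline numbers: 26% excitatory / 11% inhibitory / 63% non-neuronal,
# glia:neuron = 1.4 (glia = 1.4 x 37% = 51.8%, vascular+other = 11.2%),
# IT = 93% of excitatory split 46/18/19/13/4, inhibitory split 13/26/30/31.
_HUMAN_EXC, _HUMAN_INH = 0.26, 0.11
_HUMAN_GN_RATIO = 1.4
_HUMAN_IT_SHARE = 0.93
_HUMAN_IT_SPLIT = {
    "L2/3 IT": 0.46, "L4/5 IT": 0.18, "L5 IT": 0.19,
    "L6 IT": 0.13, "L6 IT CAR3": 0.04,
}
# Non-IT split among L6 CT / L5 ET / L5-6 NP / L6b is not a published
# number; fixed free parameter (CT-dominant, ET rare).
_HUMAN_NONIT_SPLIT = {"L6 CT": 0.45, "L5 ET": 0.10, "L5/6 NP": 0.20, "L6b": 0.25}
_HUMAN_INH_SPLIT = {"LAMP5": 0.13, "PVALB": 0.26, "SST": 0.30, "VIP": 0.31}
# Glial / vascular splits are free parameters (oligodendrocyte-rich glia).
_HUMAN_GLIA_SPLIT = {"ASC": 0.17 / 0.518, "OGC": 0.24 / 0.518,
                     "OPC": 0.050 / 0.518, "MGC": 0.058 / 0.518}
_HUMAN_VASC_SPLIT = {"ENDO": 0.075 / 0.112, "MURAL": 0.037 / 0.112}

# Mouse constraints: glia:neuron = 1.4/5 = 0.28, E:I = 2.3636 x 3 ~ 6.9
# (three times the human 26/11), non-IT = 29% of excitatory, density 3x human.
_MOUSE_GN_RATIO = _HUMAN_GN_RATIO / 5.0
_MOUSE_EI_RATIO = 3.0 * (_HUMAN_EXC / _HUMAN_INH)
_MOUSE_VASC = 0.06  # free parameter
_MOUSE_IT_SHARE = 0.71
_MOUSE_IT_SPLIT = {
    "L2/3 IT": 0.30, "L4/5 IT": 0.30, "L5 IT": 0.20,
    "L6 IT": 0.18, "L6 IT CAR3": 0.02,
}
_MOUSE_NONIT_SPLIT = {"L6 CT": 0.50, "L5 ET": 0.20, "L5/6 NP": 0.15, "L6b": 0.15}
_MOUSE_INH_SPLIT = {"LAMP5": 0.10, "PVALB": 0.36, "SST": 0.34, "VIP": 0.20}
_MOUSE_GLIA_SPLIT = {"ASC": 0.40, "OGC": 0.35, "OPC": 0.12, "MGC": 0.13}
_MOUSE_VASC_SPLIT = {"ENDO": 0.67, "MURAL": 0.33}

_HUMAN_DENSITY = 1000.0  # cells per mm^2 in 2-D sections (free parameter)
_LAYER_BOUNDARIES = (0.08, 0.35, 0.50, 0.70, 1.0)

# per-subclass laminar band (mean_lo, mean_hi across clusters, per-cluster sd)
_LAMINAR_BANDS = {
    "L2/3 IT": (0.10, 0.32, 0.05),
    "L4/5 IT": (0.38, 0.44, 0.03),
    "L5 IT": (0.48, 0.66, 0.08),
    "L6 IT": (0.70, 0.86, 0.06),
    "L6 IT CAR3": (0.75, 0.85, 0.06),
    "L6 CT": (0.82, 0.92, 0.05),
    "L5 ET": (0.55, 0.65, 0.06),
    "L5/6 NP": (0.65, 0.80, 0.06),
    "L6b": (0.92, 0.97, 0.05),
    "LAMP5": (0.06, 0.25, 0.06),
    "PVALB": (0.30, 0.80, 0.15),
    "SST": (0.30, 0.85, 0.16),
    "VIP": (0.08, 0.35, 0.08),
    "ASC": (0.05, 0.95, 0.10),
    "OGC": (0.70, 0.98, 0.10),
    "OPC": (0.10, 0.90, 0.20),
    "MGC": (0.10, 0.90, 0.20),
    "ENDO": (0.10, 0.90, 0.25),
    "MURAL": (0.10, 0.90, 0.25),
}

# One soma-size distribution shared by all subclasses: the fixed-edge
# label-permutation null assumes contact propensity is exchangeable
# across types, which type-dependent soma radii would violate (larger
# somata collect more edges than a permuted label accounts for).
_SOMA_RADII = {s: (4.5, 0.8) for s in (
    "L2/3 IT", "L4/5 IT", "L5 IT", "L6 IT", "L6 IT CAR3", "L6 CT",
    "L5 ET", "L5/6 NP", "L6b", "LAMP5", "PVALB", "SST", "VIP",
    "ASC", "OGC", "OPC", "MGC", "ENDO", "MURAL",
)}

# marker genes per subclass (shared by its clusters)
_SUBCLASS_MARKERS = {
    "L2/3 IT": ["SLC17A7", "CUX2", "LRP1", "NRXN1", "NLGN1", "CX3CL1",
                "IL34", "BDNF", "EFNA5", "NTRK2", "EPHA4"],
    "L4/5 IT": ["SLC17A7", "RORB", "LRP1", "NRXN1", "NLGN1", "CX3CL1",
                "IL34", "BDNF", "EFNA5", "NTRK2", "EPHA4"],
    "L5 IT": ["SLC17A7", "RORB", "LRP1", "NRXN1", "NLGN1", "CX3CL1",
              "IL34", "BDNF", "EFNA5", "NTRK2", "EPHA4"],
    "L6 IT": ["SLC17A7", "THEMIS", "LRP1", "NRXN1", "NLGN1", "CX3CL1",
              "IL34", "BDNF", "EFNA5", "NTRK2", "EPHA4"],
    "L6 IT CAR3": ["SLC17A7", "CAR3", "LRP1", "NRXN1", "NLGN1", "CX3CL1",
                   "IL34", "BDNF", "EFNA5", "NTRK2", "EPHA4"],
    "L6 CT": ["SLC17A7", "SYT6", "NRXN1"],
    "L5 ET": ["SLC17A7", "FEZF2", "NRXN1"],
    "L5/6 NP": ["SLC17A7", "TSHZ2", "NRXN1"],
    "L6b": ["SLC17A7", "CTGF", "NRXN1"],
    "LAMP5": ["GAD1", "GAD2", "SLC32A1", "LAMP5", "NRXN3"],
    "PVALB": ["GAD1", "GAD2", "SLC32A1", "PVALB", "NRXN3"],
    "SST": ["GAD1", "GAD2", "SLC32A1", "SST", "NRXN3"],
    "VIP": ["GAD1", "GAD2", "SLC32A1", "VIP", "NRXN3"],
    "ASC": ["AQP4", "GJA1", "APOE", "GPR37L1"],
    "OGC": ["PLP1", "MOG", "PSAP"],
    "OPC": ["PDGFRA", "CSPG4"],
    "MGC": ["CX3CR1", "CSF1R", "C3", "C3AR1", "A2M"],
    "ENDO": ["CLDN5", "FLT1"],
    "MURAL": ["ACTA2", "PDGFRB"],
}

#: Bundled demonstration ligand-receptor pair list (10 pairs) used by the
#: interaction analyses and tests; the default human config boosts A2M-LRP1.
DEMO_LIGAND_RECEPTOR_PAIRS = (
    ("A2M", "LRP1"),
    ("APOE", "LRP1"),
    ("C3", "C3AR1"),
    ("CX3CL1", "CX3CR1"),
    ("IL34", "CSF1R"),
    ("PSAP", "GPR37L1"),
    ("BDNF", "NTRK2"),
    ("EFNA5", "EPHA4"),
    ("NRXN1", "NLGN1"),
    ("NRXN3", "NLGN1"),
)


def _cluster_weights(n: int, decay: float = 0.75) -> np.ndarray:
    w = decay ** np.arange(n)
    return w / w.sum()


def _build_composition(taxonomy: Taxonomy, subclass_probs: dict[str, float]) -> dict[str, float]:
    comp: dict[str, float] = {}
    for sub, p in subclass_probs.items():
        cls = taxonomy.clusters_of(sub)
        for cl, w in zip(cls, _cluster_weights(len(cls))):
            comp[cl] = float(p * w)
    total = sum(comp.values())
    return {cl: float(p / total) for cl, p in comp.items()}


def _build_laminar_profiles(taxonomy: Taxonomy) -> dict[str, tuple[float, float]]:
    profiles: dict[str, tuple[float, float]] = {}
    for sub in taxonomy.subclasses:
        lo, hi, sd = _LAMINAR_BANDS[sub]
        cls = taxonomy.clusters_of(sub)
        means = np.linspace(lo, hi, len(cls)) if len(cls) > 1 else [0.5 * (lo + hi)]
        for cl, m in zip(cls, means):
            profiles[cl] = (float(m), sd)
    return profiles


def _build_gene_panel(n_genes: int) -> tuple[list[str], dict[str, list[str]]]:
    named: list[str] = []
    for genes in _SUBCLASS_MARKERS.values():
        for g in genes:
            if g not in named:
                named.append(g)
    if n_genes < len(named):
        raise GenerationError(
            f"n_genes={n_genes} smaller than the {len(named)} named marker genes"
        )
    panel = named + [f"gene_{i:04d}" for i in range(n_genes - len(named))]
    return panel, _SUBCLASS_MARKERS


def _build_expression_spec(taxonomy: Taxonomy, n_genes: int = 120) -> ExpressionSpec:
    panel, subclass_markers = _build_gene_panel(n_genes)
    gidx = {g: i for i, g in enumerate(panel)}
    marker_sets = {
        cl: tuple(gidx[g] for g in subclass_markers[taxonomy.subclass_of(cl)])
        for cl in taxonomy.clusters
    }
    return ExpressionSpec(
        n_genes=n_genes,
        baseline_nb_mean=0.2,
        nb_dispersion=0.2,
        marker_sets=marker_sets,
        marker_fold=50.0,
        gene_names=tuple(panel),
        library_sigma=0.3,
    )


def human_subclass_composition() -> dict[str, float]:
    """Subclass-level human composition implied by the published numbers."""
    glia = _HUMAN_GN_RATIO * (_HUMAN_EXC + _HUMAN_INH)      # 0.518
    vasc = 1.0 - _HUMAN_EXC - _HUMAN_INH - glia             # 0.112
    it = _HUMAN_EXC * _HUMAN_IT_SHARE
    nonit = _HUMAN_EXC * (1.0 - _HUMAN_IT_SHARE)
    probs = {}
    probs.update({s: it * f for s, f in _HUMAN_IT_SPLIT.items()})
    probs.update({s: nonit * f for s, f in _HUMAN_NONIT_SPLIT.items()})
    probs.update({s: _HUMAN_INH * f for s, f in _HUMAN_INH_SPLIT.items()})
    probs.update({s: glia * f for s, f in _HUMAN_GLIA_SPLIT.items()})
    probs.update({s: vasc * f for s, f in _HUMAN_VASC_SPLIT.items()})
    return probs


def mouse_subclass_composition() -> dict[str, float]:
    """Subclass-level mouse composition implied by the published ratios."""
    neurons = (1.0 - _MOUSE_VASC) / (1.0 + _MOUSE_GN_RATIO)
    exc = neurons * _MOUSE_EI_RATIO / (1.0 + _MOUSE_EI_RATIO)
    inh = neurons - exc
    glia = _MOUSE_GN_RATIO * neurons
    it = exc * _MOUSE_IT_SHARE
    nonit = exc * (1.0 - _MOUSE_IT_SHARE)
    probs = {}
    probs.update({s: it * f for s, f in _MOUSE_IT_SPLIT.items()})
    probs.update({s: nonit * f for s, f in _MOUSE_NONIT_SPLIT.items()})
    probs.update({s: inh * f for s, f in _MOUSE_INH_SPLIT.items()})
    probs.update({s: glia * f for s, f in _MOUSE_GLIA_SPLIT.items()})
    probs.update({s: _MOUSE_VASC * f for s, f in _MOUSE_VASC_SPLIT.items()})
    return probs


_WM_SUBCLASS = {"OGC": 0.75, "ASC": 0.15, "MGC": 0.05, "OPC": 0.05}

_REFERENCE_AREA_MM2 = 50.0  # 20 mm x 2.5 mm reference human section


def default_human_config(
    section_width_um: float = 20000.0,
    section_height_um: float = 2500.0,
    seed: int = 7,
    taxonomy: Taxonomy | None = None,
) -> TissueConfig:
    """Default human section (~50,000 cortical cells at the default size).

    Encodes the published human composition and all human-specific
    interaction structure: satellite microglia on IT neurons with a
    depth-decreasing fraction, intra-subclass SST/PVALB/astrocyte
    attraction, multiway neuron-oligodendrocyte/OPC contacts, vessel
    chains with microglia/oligodendrocyte recruitment, a 50% GAD1+ OPC
    subpopulation, and a contact-boosted A2M->LRP1 pair from microglia
    to IT neurons.
    """
    from .taxonomy import default_human_taxonomy

    tax = taxonomy or default_human_taxonomy()
    area = section_width_um * section_height_um / 1e6
    n_vessels = max(1, int(round(60 * area / _REFERENCE_AREA_MM2)))
    return TissueConfig(
        section_width_um=section_width_um,
        section_height_um=section_height_um,
        layer_boundaries=_LAYER_BOUNDARIES,
        density_cells_per_mm2=_HUMAN_DENSITY,
        composition=_build_composition(tax, human_subclass_composition()),
        laminar_profiles=_build_laminar_profiles(tax),
        hardcore_distance_um=8.0,
        soma_radius_um=dict(_SOMA_RADII),
        satellite_specs=[
            # satellite microglia on IT neurons, fraction falling with depth
            # fractions chosen so the observed/expected contact ratio
            # (not just the satellite count) falls from L2/3 to L6
            SatelliteSpec("L2/3 IT", "MGC", 0.20),
            SatelliteSpec("L4/5 IT", "MGC", 0.08),
            SatelliteSpec("L5 IT", "MGC", 0.05),
            SatelliteSpec("L6 IT", "MGC", 0.01),
            # intra-subclass soma attraction: a strong majority of these
            # sparse interneuron subclasses sit in same-subclass pairs,
            # so pairing dominates their sparse background spacing
            SatelliteSpec("SST", "SST", 0.35),
            SatelliteSpec("PVALB", "PVALB", 0.30),
            SatelliteSpec("ASC", "ASC", 0.20),
            # multiway neuron-oligodendrocyte/OPC contacts
            SatelliteSpec("L5 IT", "OGC", 0.12, partners_per_focal=3),
            SatelliteSpec("L6 IT", "OPC", 0.15, partners_per_focal=3),
        ],
        vessel_spec=VesselSpec(
            n_vessels=n_vessels,
            cells_per_vessel=8,
            step_um=7.0,
            mural_fraction=0.3,
            glial_recruit={"MGC": 2, "OGC": 2},
        ),
        expression_spec=_build_expression_spec(tax),
        gad1_positive_opc_fraction=0.5,
        ligrec_spec=[LigRecSpec("A2M", "LRP1", "MGC", "IT", 4.0)],
        wm_margin=0.12,
        wm_density_factor=0.8,
        wm_composition=_build_composition(tax, _WM_SUBCLASS),
        species="human",
        section_id="S1",
        seed=seed,
    )


def default_mouse_config(
    section_width_um: float = 6000.0,
    section_height_um: float = 1000.0,
    seed: int = 7,
    taxonomy: Taxonomy | None = None,
) -> TissueConfig:
    """Default mouse section: 3x the human cell density, glia:neuron 0.28,
    E:I ~6.9, non-IT 29% of excitatory, and NO interaction injections
    (no satellites, no glial recruitment to vessels, no ligand-receptor
    contact boost), matching the species contrasts under study."""
    from .taxonomy import default_mouse_taxonomy

    tax = taxonomy or default_mouse_taxonomy()
    area = section_width_um * section_height_um / 1e6
    n_vessels = max(1, int(round(60 * area / 6.0)))
    return TissueConfig(
        section_width_um=section_width_um,
        section_height_um=section_height_um,
        layer_boundaries=_LAYER_BOUNDARIES,
        density_cells_per_mm2=3.0 * _HUMAN_DENSITY,
        composition=_build_composition(tax, mouse_subclass_composition()),
        laminar_profiles=_build_laminar_profiles(tax),
        hardcore_distance_um=8.0,
        soma_radius_um=dict(_SOMA_RADII),  # soma sizes comparable across species
        satellite_specs=[],
        vessel_spec=VesselSpec(
            n_vessels=n_vessels,
            cells_per_vessel=8,
            step_um=7.0,
            mural_fraction=0.3,
            glial_recruit={},
        ),
        expression_spec=_build_expression_spec(tax),
        gad1_positive_opc_fraction=0.5,
        ligrec_spec=[],
        wm_margin=0.12,
        wm_density_factor=0.8,
        wm_composition=_build_composition(tax, _WM_SUBCLASS),
        species="mouse",
        section_id="S1",
        seed=seed,
    )
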