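"""Three-level cell-type taxonomy: class -> subclass -> cluster.

The taxonomy mirrors the organisation of cortical cell-atlas studies:
three classes (excitatory, inhibitory, non-neuronal), named subclasses
(projection classes for excitatory neurons, canonical interneuron
families, and the major glial / vascular populations) and transcriptomic
clusters nested within subclasses.  Subclass-level boolean flags mark
the groupings the downstream statistics need: glial (ASC, OGC, OPC,
MGC), vascular (ENDO, MURAL) and intratelencephalic (IT) neurons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

EXCITATORY = "excitatory"
INHIBITORY = "inhibitory"
NON_NEURONAL = "non-neuronal"

GLIAL_SUBCLASSES = frozenset({"ASC", "OGC", "OPC", "MGC"})
VASCULAR_SUBCLASSES = frozenset({"ENDO", "MURAL"})
IT_SUBCLASSES = frozenset({"L2/3 IT", "L4/5 IT", "L5 IT", "L6 IT", "L6 IT CAR3"})


class TaxonomyError(ValueError):
    """Raised when labels cannot be resolved against the taxonomy."""


@dataclass(frozen=True)
class Taxonomy:
    """Immutable cluster -> subclass -> class hierarchy with subclass flags."""

    cluster_to_subclass: dict[str, str]
    subclass_to_class: dict[str, str]
    glial_subclasses: frozenset[str] = GLIAL_SUBCLASSES
    vascular_subclasses: frozenset[str] = VASCULAR_SUBCLASSES
    it_subclasses: frozenset[str] = IT_SUBCLASSES
    _subclass_to_clusters: dict[str, tuple[str, ...]] = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self):
        for cl, sub in self.cluster_to_subclass.items():
            if sub not in self.subclass_to_class:
                raise TaxonomyError(
                    f"cluster {cl!r} maps to unknown subclass {sub!r}"
                )
        by_sub: dict[str, list[str]] = {s: [] for s in self.subclass_to_class}
        for cl, sub in self.cluster_to_subclass.items():
            by_sub[sub].append(cl)
        object.__setattr__(
            self,
            "_subclass_to_clusters",
            {s: tuple(cls) for s, cls in by_sub.items()},
        )

    # -- lookups -----------------------------------------------------------
    def subclass_of(self, cluster: str) -> str:
        try:
            return self.cluster_to_subclass[cluster]
        except KeyError:
            raise TaxonomyError(f"unknown cluster {cluster!r}") from None

    def class_of_subclass(self, subclass: str) -> str:
        try:
            return self.subclass_to_class[subclass]
        except KeyError:
            raise TaxonomyError(f"unknown subclass {subclass!r}") from None

    def class_of(self, cluster: str) -> str:
        return self.class_of_subclass(self.subclass_of(cluster))

    @property
    def clusters(self) -> tuple[str, ...]:
        return tuple(self.cluster_to_subclass)

    @property
    def subclasses(self) -> tuple[str, ...]:
        return tuple(self.subclass_to_class)

    def clusters_of(self, subclass: str) -> tuple[str, ...]:
        try:
            return self._subclass_to_clusters[subclass]
        except KeyError:
            raise TaxonomyError(f"unknown subclass {subclass!r}") from None

    def is_glial(self, subclass: str) -> bool:
        return subclass in self.glial_subclasses

    def is_vascular(self, subclass: str) -> bool:
        return subclass in self.vascular_subclasses

    def is_it(self, subclass: str) -> bool:
        return subclass in self.it_subclasses

    def is_neuronal(self, subclass: str) -> bool:
        return self.class_of_subclass(subclass) in (EXCITATORY, INHIBITORY)

    def n_clusters_by_class(self) -> dict[str, int]:
        out = {EXCITATORY: 0, INHIBITORY: 0, NON_NEURONAL: 0}
        for cl in self.cluster_to_subclass:
            out[self.class_of(cl)] += 1
        return out

    def validate_labels(self, clusters, subclasses=None) -> None:
        """Raise TaxonomyError naming the first unresolvable label."""
        known = self.cluster_to_subclass
        for cl in set(clusters):
            if cl not in known:
                raise TaxonomyError(f"unknown cluster label {cl!r}")
        if subclasses is not None:
            for sub in set(subclasses):
                if sub not in self.subclass_to_class:
                    raise TaxonomyError(f"unknown subclass label {sub!r}")


def resolve_subclasses(token: str, taxonomy: Taxonomy) -> tuple[str, ...]:
    """Expand a subclass name or group token into concrete subclasses.

    Recognised group tokens: ``IT``, ``excitatory``, ``inhibitory``,
    ``neuron``/``neurons``, ``non-neuronal``, ``glial``, ``vascular``.
    """
    if token in taxonomy.subclass_to_class:
        return (token,)
    subs = taxonomy.subclasses
    if token == "IT":
        return tuple(s for s in subs if taxonomy.is_it(s))
    if token in (EXCITATORY, INHIBITORY, NON_NEURONAL):
        return tuple(s for s in subs if taxonomy.class_of_subclass(s) == token)
    if token in ("neuron", "neurons"):
        return tuple(s for s in subs if taxonomy.is_neuronal(s))
    if token == "glial":
        return tuple(s for s in subs if taxonomy.is_glial(s))
    if token == "vascular":
        return tuple(s for s in subs if taxonomy.is_vascular(s))
    raise TaxonomyError(f"cannot resolve subclass or group token {token!r}")


# Cluster counts per subclass for the packaged human taxonomy:
# 29 excitatory + 39 inhibitory + 57 non-neuronal = 125 clusters.
_HUMAN_SUBCLASS_SPEC: tuple[tuple[str, str, int], ...] = (
    # (subclass, class, n_clusters)
    ("L2/3 IT", EXCITATORY, 5),
    ("L4/5 IT", EXCITATORY, 4),
    ("L5 IT", EXCITATORY, 4),
    ("L6 IT", EXCITATORY, 4),
    ("L6 IT CAR3", EXCITATORY, 2),
    ("L6 CT", EXCITATORY, 3),
    ("L5 ET", EXCITATORY, 2),
    ("L5/6 NP", EXCITATORY, 2),
    ("L6b", EXCITATORY, 3),
    ("LAMP5", INHIBITORY, 5),
    ("PVALB", INHIBITORY, 9),
    ("SST", INHIBITORY, 13),
    ("VIP", INHIBITORY, 12),
    ("ASC", NON_NEURONAL, 11),
    ("OGC", NON_NEURONAL, 12),
    ("OPC", NON_NEURONAL, 6),
    ("MGC", NON_NEURONAL, 8),
    ("ENDO", NON_NEURONAL, 12),
    ("MURAL", NON_NEURONAL, 8),
)


def default_human_taxonomy() -> Taxonomy:
    """Packaged human cortical taxonomy: 125 clusters (29 EXC / 39 INH / 57 non-neuronal)."""
    cluster_to_subclass: dict[str, str] = {}
    subclass_to_class: dict[str, str] = {}
    for subclass, klass, n in _HUMAN_SUBCLASS_SPEC:
        subclass_to_class[subclass] = klass
        for k in range(1, n + 1):
            cluster_to_subclass[f"{subclass} {k}"] = subclass
    return Taxonomy(cluster_to_subclass, subclass_to_class)


def default_mouse_taxonomy() -> Taxonomy:
    """Mouse taxonomy; shares the human subclass vocabulary.

    Cluster granularity below the subclass level is not constrained for
    mouse, so the same cluster fixture is reused with mouse-specific
    subclass frequencies supplied by the generator config.
    """
    return default_human_taxonomy()
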