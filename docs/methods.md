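# Methods

## The data model

A section is a planar slice: coordinates are physical micrometres,
origin at the top-left, y increasing with cortical depth, and all
distances 2-D Euclidean. Normalized depth is y divided by the cortical
thickness, so 0 is the pia, 1 the L6/white-matter boundary, and values
above 1 lie in white matter. Layers (L1 | L2/3 | L4 | L5 | L6 | WM) are
assigned from depth by half-open intervals — a depth exactly on a
boundary goes to the deeper layer, a convention we state explicitly
because layer boundaries in real sections are approximate. The cell
taxonomy has three levels (class → subclass → cluster); the packaged
human fixture has 125 clusters (29 excitatory, 39 inhibitory, 57
non-neuronal) across 19 subclasses. "Glia" means ASC ∪ OGC ∪ OPC ∪ MGC;
endothelial and mural cells are non-neuronal but not glia.

## The synthetic tissue generator

The generator emulates what a segmented, annotated imaging-based
spatial-transcriptomics section of temporal cortex looks like to the
downstream statistics. It is deliberately stylized: a flat rectangle
(no cortical curvature — depth profiles, not geometry, are the analysis
target), cluster identities drawn i.i.d. from a configured composition,
and per-cluster truncated-Gaussian depth profiles on [0, 1).

**Composition ground truth.** The human defaults encode the published
headline numbers exactly: 26% excitatory / 11% inhibitory / 63%
non-neuronal; glia:neuron 1.4 (hence glia 51.8% of cells, vascular +
other 11.2%); IT neurons 93% of excitatory split 46/18/19/13/4 across
L2/3 IT, L4/5 IT, L5 IT, L6 IT, L6 IT CAR3; inhibitory split 13/26/30/31
across LAMP5/PVALB/SST/VIP. Mouse defaults encode glia:neuron = 0.28
(5× lower than human), E:I ≈ 6.9 (3× the human 26/11), non-IT 29% of
excitatory, and 3× the human areal density. Quantities no atlas table
pins down — the non-IT split among L6 CT/L5 ET/L5-6 NP/L6b, the glial
and vascular splits, mouse per-subclass splits beyond the ratios above,
within-subclass cluster weights (geometric, decay 0.75), and the
absolute human density (1000 cells/mm² in 2-D section) — are free
parameters fixed once in `synth.py` and documented as such.

**White matter.** The configured composition defines the cortical
ribbon (depth < 1). A WM margin (default 0.12 of cortical thickness,
0.8× density) is populated separately from an OGC-dominated
`wm_composition`. This separation makes WM exclusion in the composition
stage exact rather than a source of bias, at the cost of not modelling
clusters that straddle the L6/WM boundary.

**Placement.** Somata are a hard-core process: dart throwing with
rejection (resampling x at fixed depth), a uniform spatial hash for
neighbour queries, and a global budget of 100·n attempts — exceeding it
raises an error naming the density/hard-core conflict (the default
density of 3000 cells/mm² for mouse is well below the ~0.011 cells/µm²
jamming intensity for an 8 µm hard core). Soma radii are truncated
normal (floor 2 µm) with one shared distribution (mean 4.5, sd 0.8 µm)
for **all** subclasses and both species: the fixed-edge label-permutation
null assumes contact propensity is exchangeable across types, and
type-dependent soma sizes would violate that (larger somata collect
more edges than a permuted label accounts for — in real data this is
the regime where segmented-boundary contact and size-matched nulls are
needed).

**Interaction injections** reposition cells already drawn from the base
composition, so they never change composition ground truth:

- *Satellites*: a fraction of a partner subclass is moved to exact
  contact distance r_i + r_j + gap (gap 0.5 µm) from focal cells,
  `partners_per_focal` each. Satellites are exempt from the hard-core
  rule against their designated partner only; placement tries 24 angles
  to avoid third-party overlap, then accepts. Defaults: satellite
  microglia on IT neurons with fractions 0.20/0.08/0.05/0.01 for
  L2/3 IT → L6 IT — chosen so the *observed/expected contact ratio*,
  the quantity the depth-trend analysis reports, decreases with depth;
  intra-subclass attraction for SST (0.35), PVALB (0.30) and ASC
  (0.20) — a strong majority of these sparse interneuron subclasses
  sits in same-subclass pairs, so pairing dominates their large
  background nearest-self distances; and multiway L5 IT–OGC and
  L6 IT–OPC injections with 3 partners per focal neuron.
- *Vessels*: self-avoiding random-walk chains of ENDO/MURAL cells
  (step 7 µm ≈ contact spacing, mural fraction 0.3, ~60 vessels per
  50 mm²), with per-vessel glial recruitment (2 MGC + 2 OGC placed at
  contact distance from a chain member) in human only.
- Mouse defaults carry **no** injections: no satellites, no glial
  recruitment, no expression boost — the cross-species contrasts are
  therefore human-specific by construction.

**Expression.** Counts are negative binomial via a gamma–Poisson
mixture, mean µ and inverse-size dispersion α (variance µ + αµ²;
defaults µ = 0.2, α = 0.2), with a per-cell lognormal library factor
(σ = 0.3) so that library-size normalization is non-trivial. Each
subclass has a fixed marker-gene set whose mean is multiplied by 50 in
its clusters (120-gene panel: named cortical markers plus filler).
OPCs are special-cased: GAD2 and SLC32A1 are silenced in all OPCs, and
GAD1 is expressed at marker level in a Bernoulli(0.5) subpopulation and
exactly zero otherwise — so the GAD1⁺ fraction recovered at
min_count = 1 is the configured 50% minus a ~0.4% negative-binomial
dropout. Ligand–receptor structure: for each configured pair the
ligand mean is boosted (4×) in senders and the receptor mean in
receivers of *contacting* sender→receiver pairs (default A2M → LRP1
from microglia to IT neurons), using the same centroid contact rule as
the analysis.

## The statistics

**Contact graph.** Centroid mode: edge iff d(i,j) ≤ s·(r_i + r_j),
default s = 1.1 (exposed in config; all tests pin it). Boundary mode:
outlines dilated by τ = 1 µm intersect; with circles this reduces to
d ≤ r_i + r_j + 2τ. Neighbour candidates come from a k-d tree with a
radius bound of s·2·max(r); the result is provably identical to the
all-pairs rule and is tested against an O(n²) oracle. Cells near the
section border are kept: because the geometry (and hence the edge set)
is fixed under the null, edge effects cancel between observed and
expected counts.

**Permutation null.** Cells are partitioned into square bins (default
100 µm ≈ several soma diameters: destroys neighbor identity, preserves
laminar density); within each bin the joint (class, subclass, cluster)
label triples are shuffled, positions fixed. Per-bin per-type counts
are exactly preserved. Defaults: 1000 permutations, mandatory seed.
Pairwise enrichment recomputes the per-pair contact counts on the fixed
edge set for each relabeling; the p-value is the upper-tailed normal
tail of z = (obs − mean)/sd, with the empirical permutation p reported
alongside for auditing. Pairs with zero null sd are flagged degenerate
(p undefined); pairs with null mean < 5 are flagged low-power — the
normal approximation is not trusted outside the CLT regime, and
calibration claims are made over unflagged pairs only. BH-FDR is
applied over all pairs of one analysis run, human and mouse corrected
separately. Residual miscalibration from laminar gradients *within* a
bin (sharply banded types such as L4/5 IT) is small at the default bin
size and covered by the replicate calibration test.

**Nearest-neighbor self/other test.** Per label (≥ 20 cells): for each
cell the distance to its nearest same-label and nearest different-label
cell; one-sided Wilcoxon rank-sum (self < other) and BH across labels.
Note the known density asymmetry of this statistic: for a subclass at a
few percent abundance, "self" is drawn from a much sparser point set
than "other", so only strong intra-type attraction can push self below
other — which is why the generator's intra-subclass pairing fractions
are majorities.

**Multiway contacts.** Observed number of focal cells (neurons by
default) with ≥ k distinct partner contacts (partner = OGC ∪ OPC,
matching "oligodendrocytes and/or OPCs"; per-type variants available),
for k = 2…5, against the same permutation null, BH across k.

**Vessels.** Connected components (union-find via sparse csgraph) of
the contact graph restricted to ENDO ∪ MURAL with ≥ 3 members (a
structure, not an isolated cell; exposed in config since real
vessel-identification rules vary); adjacency counts distinct glial
cells of each subclass contacting any member, summarized as mean ± sd
across vessels.

**GAD1⁺ OPCs.** Fraction of OPC cells with ≥ min_count GAD1 transcripts
(default 1 — imaging-based counts are near-binary for low expressors);
sensitivity to min_count ∈ {1,2,3} is reported, and GAD2/SLC32A1
near-absence is verified when those genes are present.

**Depth-resolved contact.** Per focal group (L2/3 IT, L4/5 IT, L5 IT,
L6 IT, inhibitory; superficial → deep), the observed/expected contact
count ratio with the partner subclass (microglia), the permutation
ratio distribution, and a Spearman trend of ratio vs depth order.

**Ligand–receptor.** score(L,R) = mean over contacting (sender,
receiver) cell pairs of n_L(sender)·n_R(receiver), n = library-size
normalized expression (counts per 1000). The null redraws equal-sized
sets of non-interacting pairs — senders and receivers not involved in
any contacting pair, senders matched on the observed senders' depth
bins (bin width = the laminar default) to avoid laminar confounding.
Pairs are treated directionally (sender→receiver); fold, upper-tailed
Z and BH across the tested pairs. A practical caveat the synthetic data
reproduces: boosting one gene inflates the library size of contacting
cells, so after normalization the *other* genes of those cells score
slightly below 1 — a compositional artifact of library-size
normalization, not a depletion signal.

**E:I depth curve.** The z-score standardizes the log2 E:I curve across
depth bins within one species (log2 stabilizes the ratio's variance);
bins with zero inhibitory cells propagate as missing, never infinity.
An across-species per-bin standardization would be an alternative
convention; the across-bin one is implemented and configurable.

## What the synthetic benchmark does and does not show

Passing on generator output demonstrates that the statistics recover
known composition, laminar and interaction structure under hard-core
packing, laminar confounding, library-size variation and injected
attraction, and that the permutation machinery is calibrated on a
pattern whose labels are exchangeable within bins given depth. It does
not exercise: segmentation errors and doublets, anisotropic or curved
laminae, type-dependent soma sizes (see above), spatial expression
gradients within a type, or partial-volume effects at section surfaces
— all present in real imaging data.

## Problem sizes

Default test and validation scales: one ~50,000-cell human section for
composition/GAD1 recovery, a ~18,000-cell mouse section for the
cross-species ratios, twenty ~4,500-cell replicate sections (400
permutations each) for null calibration, and ~8,000/6,000-cell
human/mouse sections (300 permutations) for the directional contrasts.
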