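# cortexprox

Cell-type composition, laminar organization and soma-proximity
statistics for spatially resolved single-cell atlases of the cerebral
cortex — with a synthetic cortical-tissue generator that provides
ground-truth sections for validating every statistic.

Imaging-based spatial transcriptomics (e.g. MERFISH) yields, per tissue
section, a table of segmented cells with centroids, soma sizes and
transcriptomic type labels, plus a sparse cell × gene count matrix.
`cortexprox` implements the downstream analyses such atlases call for:

- **Composition** — per-class/subclass/cluster proportions and the two
  headline ratios of cortical cytoarchitecture, the glia-to-neuron
  ratio G:N = (ASC + OGC + OPC + MGC) / (EXC + INH) and the
  excitatory-to-inhibitory ratio E:I, with white matter excluded by
  convention, and human-vs-mouse ratio-of-ratio comparisons.
- **Laminar organization** — per-cluster cortical-depth densities over
  normalized depth (0 = pia, 1 = L6/WM boundary), layer assignment from
  depth, and the depth-resolved E:I curve with its z-score.
- **Proximity statistics** — a soma contact/proximity graph (centroid
  rule: edge iff d ≤ s·(r_i + r_j), default s = 1.1; or dilated-boundary
  overlap), and a **density-preserving permutation null**: cell-type
  labels are shuffled within square spatial bins (default 100 µm) at
  fixed positions, so each type's coarse spatial density is preserved
  while neighbor identity is randomized. Pairwise contact enrichment is
  reported as fold change obs/E[null] with an upper-tailed Z-test and
  Benjamini–Hochberg FDR; a nearest-neighbor "to self" vs "to other"
  Wilcoxon rank-sum test probes intra-type attraction.
- **Higher-order interactions** — blood-vessel detection (connected
  components of the endothelial/mural contact subgraph) with per-vessel
  glial adjacency; multiway neuron–oligodendrocyte/OPC contact counts
  vs the permutation null; GAD1⁺ OPC classification; depth-resolved
  microglia–IT-neuron contact ratios; and ligand–receptor scores
  (mean of n_L(sender)·n_R(receiver) over contacting pairs, against
  depth-matched non-interacting pairs).

The synthetic generator produces sections with known ground truth:
laminar layer structure, hard-core soma packing, published human/mouse
subclass compositions (26/11/63 class split, G:N = 1.4 human vs 0.28
mouse, E:I = 2.3 vs ~6.9, 3× density difference), injected satellite
and multiway contacts, vessel-like ENDO/MURAL chains with glial
recruitment, a ~50% GAD1⁺ OPC subpopulation, and negative-binomial
expression with marker structure and contact-boosted ligand–receptor
pairs. See `docs/methods.md` for the model and its parameters.

## Worked example

```bash
cortexprox demo --species both --out demo-run --seed 7
```

prints

```
human-S1: n=10918  glia:neuron=1.40  E:I=2.25
mouse-S1: n=8179  glia:neuron=0.29  E:I=7.29
```

i.e. two small synthetic sections whose recovered glia-to-neuron ratios
(1.40 human, 0.29 mouse — a ~5× species difference) and E:I ratios
(2.25 vs 7.29, ~3× lower in human) match the configured ground truth.
`demo-run/<section>/` then contains one TSV per analysis
(`composition.tsv`, `laminar_profiles.tsv`, `enrichment.tsv`,
`nn_test.tsv`, `vessels.tsv`, `multiway.tsv`, `depth_contact.tsv`,
`ligrec.tsv`) plus a `manifest.json` with the config hash and all
derived stage seeds; re-running with the same seed reproduces every
table byte for byte. In `enrichment.tsv` the human section shows, e.g.,
an ASC–ASC row with fold_change ≈ 4.3 at FDR ≈ 0 (injected astrocyte
self-attraction) while chance-level pairs sit at fold ≈ 1.

The same analyses are available as a library:

```python
from cortexprox import (default_human_config, default_human_taxonomy,
                        generate_tissue, composition)
tax = default_human_taxonomy()
cells, expr = generate_tissue(default_human_config(seed=7), tax)
res = composition(cells, tax, level="class")
print(res.table, res.glia_to_neuron, res.exc_to_inh)
```

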