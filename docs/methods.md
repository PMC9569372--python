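# Methods

## The two-layer interactome

Nodes are (gene, layer) pairs.  The protein layer holds PPI endpoints and
transcription factors; the rna layer holds regulon targets.  A gene may
appear on both layers (a TF's protein and its transcript are distinct
nodes), which is also why TF self-regulation is a legal edge.  Gene symbols
are compared case-insensitively (mouse symbol casing is inconsistent across
databases) while the original casing is preserved for output.

PPI confidences are rescaled to (0, 1] (STRING-style 0–1000 scores divided
by 1000).  Duplicate and symmetric rows merge keeping the **maximum**
confidence: combined scores are already integrated evidence, so averaging
would double-discount.  Edge costs:

* PPI: `c = max(1 − confidence, cost_floor)`, floor 0.01.  The source
  material defines costs as representing edge reliability; a minimization
  objective needs reliable edges to be *cheap*, hence the complement.  The
  floor keeps every cost strictly positive so optimal trees stay minimal.
* Regulatory: constant, default 0.5, configurable.  Regulon membership is
  binary evidence across source databases (the per-relation source count is
  retained as an annotation), so no per-edge confidence exists.  The default
  sits in the middle of the PPI cost range: regulatory edges are neither
  free nor penalized relative to typical PPI edges.  Whether the original
  analysis down-weighted one class is unknown; both knobs are exposed
  (`ppi_cost_rule`, `reg_edge_cost`), as is optional score thresholding
  before loading.

## Prizes

Early-contrast up-regulated genes (BH-adjusted p < 0.01 and log2FC > 0,
both strict) prize their **protein** node with `β · log2FC`; late-contrast
up-regulated genes prize their **rna** node likewise.  β defaults to 1 (no
published value exists; the scaling is exposed).  Only up-regulated genes
receive prizes — the network is built from the two up-waves — but
down-regulated genes stay in the DE tables because the focal-regulator
analysis counts shared targets in both directions.  Missing adjusted p
means not significant; it is never imputed.

## The forest optimization

A forest here is a set of node-disjoint trees, **each containing at least
one edge**.  Singletons are excluded deliberately: with the forfeit-style
objective a singleton collects its prize at zero cost, so allowing them
makes every instance trivially solved by collecting all prizes with no
edges — the optimization would never connect anything.  The objective used
for selection is

    f(F) = Σ_{e∈F} c(e) + Σ_{v∉F} p(v) + ω·t(F)

with t the number of trees and ω > 0 the tree-opening cost (default 1.0).
The omega-free part is what `SteinerForest.objective` reports and what can
be recomputed from the forest alone.  Maximizing collected prize minus cost
and minimizing f differ by the constant Σp, so they select the same
forests.

**Exact oracle** (`solve_exact`, ≤ 15 nodes): for every node subset the
minimum spanning cost of its induced subgraph is tabulated (Kruskal), and a
subset-partition dynamic program assembles the cheapest cover by connected
parts, each charged ω.  Because f is separable over parts, a part belongs
to the optimum iff its prize exceeds its spanning cost by more than ω.
Ties break toward the lexicographically smallest node-set list, so the
empty forest wins a tie against any forest.  The O(3^n) program is the test
oracle only; it refuses instances above 15 nodes.

**Primal–dual heuristic** (`solve_pcsf`): Goemans–Williamson moat growth on
the instance augmented with a dummy root.  Each positive-prize node v gets
a root edge priced `ω + min_e c(e)` over v's incident edges — the true
minimum cost of opening a tree at v given that a tree must contain an edge.
(Pricing root edges at plain ω makes moats reach the root before reaching
each other whenever ω is below typical edge costs; the result is a crowd of
singleton clusters that no legal forest can contain.)  Active clusters grow
at unit rate; a tight inter-cluster edge merges two clusters, a cluster
whose dual reaches its prize deactivates, the root's cluster is never
active.  Removing root edges from the merge forest yields candidate trees.
Each is pruned by the strong-pruning dynamic program constrained to keep at
least one edge, and kept iff its net collected prize strictly exceeds ω.
Everything is deterministic: nodes are processed in sorted order and event
ties resolve by (time, event kind, index), so reruns are byte-identical.

**Strong pruning** (`strong_prune`): leaf-to-root DP,
`net(v) = p(v) + Σ_children max(0, net(child) − c)`, evaluated from every
rooting with the best kept subtree returned.  A branch is kept only when
its net strictly exceeds its attaching cost (ties pruned — smaller trees at
equal objective).  The DP cascades: removing an unprofitable leaf can make
its parent unprofitable, which is then removed too.  The objective never
increases and the operation is idempotent.

On 600 seeded instances (≤ 12 nodes, path/star/random topologies) the
heuristic's f never exceeded 1.59× the oracle's and matched the oracle's
forest exactly in 71 % of instances; the factor-2 bound of the
Goemans–Williamson scheme held everywhere.

Regulatory edges are treated as undirected during optimization (PCSF is an
undirected problem); direction is restored when the network is induced.

## From forest to regulator ranking

The regulatory network is the interactome subgraph *induced* on the forest
nodes: edges the optimizer skipped reappear if both endpoints were
selected, with original kind, direction, confidence and cost.  Regulators
are protein nodes with ≥ 1 in-network regulatory out-edge.  Each regulator
gets two descending dense ranks — early log2FC (0 if absent from the early
table) and number of in-network targets up-regulated late — and a composite
rank equal to their mean, ties broken alphabetically.  The exact statistic
behind the original ranking figure is not published; the mean of dense
ranks uses precisely the two criteria its Discussion names and is
deterministic.  The focal analysis reports, for every regulator sharing a
PPI edge with a chosen focal regulator, the shared in-network targets, how
many are up-/down-regulated late (adjusted p < 0.01, sign of log2FC), and
which members of a configurable reprogramming-factor set (default Pou5f1,
Nanog, Sox2, Klf4, Myc) are shared.

## 3D nucleus segmentation

Per z-plane, the DAPI mask is the intersection of a global and a block-local
Otsu threshold: the global threshold rejects dim background, the local map
(per-block Otsu bilinearly interpolated, block 64 px) handles uneven
illumination.  AND is the default combination (OR is available for
sensitivity analysis).  Two guards prevent degenerate thresholds: a
near-constant plane returns an empty mask, and a block whose dynamic range
is below 20 % of the plane's range is treated as background-only (its
threshold is set to the block maximum, so nothing passes locally there) —
otherwise Otsu would split pure background noise.  The stack-level driver
computes the global threshold once over the whole 3D DAPI volume, so
z-planes above and below all nuclei stay empty.

Touching nuclei are split by watershed on the Euclidean distance transform
(computed in µm): seed peaks must be ≥ 5 µm apart (half the 10 µm nominal
nuclear diameter) and ≥ 2.5 µm deep — the depth floor suppresses spurious
maxima from ragged mask borders; a component without any seed keeps a
single label.  2D segments in consecutive planes merge when they are
mutually nearest by centroid distance and within 1 µm, linked greedily by
ascending distance; 3D objects below 100 µm³ are then removed (strictly
below: exactly 100 µm³ survives).  All distances and volumes use physical
micrometers, so anisotropic voxels (z-steps of 1–2 µm) are handled
correctly.

Per-nucleus intensity is the per-voxel mean (total intensity / voxel
count), i.e. intensity normalized to the segmented nuclear volume — the
reading consistent with a "per pixel" marker threshold such as 300.  The
high-marker classification is strictly above threshold.  Colocalization
binarizes each queried channel by Otsu *within* each nucleus and reports
the fraction of nuclear voxels foreground in all queried channels; a
channel constant within a nucleus yields ratio 0 with a warning.  Spheroid
projected area is global Otsu → largest component → hole filling → pixel
count × pixel area.

## Synthetic data

The generators emulate the statistical structure the pipeline targets, not
its genomic scale: defaults are 100 proteins (8 TFs, mean PPI degree 4,
regulons of 5–20 genes) against the original ~15.5 k proteins / 976 k
interactions — the subset-DP oracle and 50-scenario acceptance runs set the
budget, and recovery behavior is scale-free in the planted construction.
PPI graphs come from a preferential-attachment process (hub-dominated
degree distributions, as in real PPI data) with confidences U(0.4, 1).
DE tables are generated directly as (log2FC, padj) pairs — the DE model
itself is out of scope and its tables are pipeline inputs.  The planted
regulator gets early log2FC 3.0 at padj 10⁻⁶; 90 % of its regulon gets late
log2FC 4.0 ± 0.2 at 10⁻⁶; decoy TFs (3 by default) draw early log2FC from
a fixed U(0.5, 1.5) with only 20 % of their regulons late-up; background
genes are null (log2FC ~ N(0, 0.3), padj ~ U(0, 1), giving the expected
~1 % false positives at the 0.01 cutoff).  The decoy range is deliberately
independent of the planted effect size, so sweeping the planted log2FC from
3.0 down through 1.2 to 0.4 moves it from above the decoy range to below
it, and recovery degrades monotonically (measured: 100 % / ~70–87 % / ≤7 %).

Confocal stacks paint oblate ellipsoidal nuclei (xy semi-axis 3.5–5 µm,
z semi-axis 0.8× that) at rejection-sampled centers with a minimum pairwise
distance, apply a 0.5 µm Gaussian blur and additive Gaussian noise clipped
at zero, at 0.3 µm pixels and 1 µm z-steps.  Shot noise is omitted: the
segmentation under test is threshold-based, and Gaussian-after-blur keeps
expectations analytic and runs deterministic.  The blur attenuates measured
per-nucleus means by a uniform ~13 % at the default σ (edge voxels mix with
background), so absolute intensity recovery is tested at a milder blur
while the default-blur tests assert uniformity of the attenuation and rank
preservation (Pearson r ≥ 0.95 against truth).  Passing these tests shows
the chain recovers count, geometry and relative intensity under the stated
noise model; it does not certify performance on real microscopy with depth-
dependent attenuation, shot noise or chromatic offsets.

A single scenario seed fans out to per-generator child seeds
(`numpy.random.SeedSequence` spawn keys), so every stage is independently
reproducible; all generators are pure functions of (parameters, seed).

## Assay closed forms

Relative qPCR quantification: `2^(−ΔΔCt)` with
`ΔΔCt = (Ct_gene,sample − Ct_ref,sample) − (Ct_gene,control − Ct_ref,control)`.
ChIP recovery: `100 · 2^((Ct_input − log2(1/f)) − Ct_IP)` percent for input
fraction f — the standard dilution adjustment; the original input fraction
is unreported, so f is a required argument.

## Numerical choices and limitations

* Floating comparisons in the solvers use a 10⁻¹² tolerance; tie-breaks are
  lexicographic throughout, so identical inputs give byte-identical outputs.
* `compute_rpm` is the only normalization offered; DE statistics are inputs.
* The exact solver is exponential and capped; the heuristic carries the
  usual primal–dual caveat that optimality is only guaranteed within a
  factor of 2 (empirically much closer).
* No identifier mapping beyond case normalization, no live database access,
  no GO enrichment, no robustness ensembles over noise reruns; single
  deterministic solve per configuration.
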